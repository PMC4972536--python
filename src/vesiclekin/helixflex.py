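"""Helix-flexibility trajectory analysis.

Post-processing of C-alpha coordinate trajectories to quantify the
conformational flexibility of a transmembrane helix:

* optimal rigid-body superposition (Kabsch algorithm),
* per-residue root mean square fluctuation (RMSF) computed in
  non-overlapping time windows relative to the iteratively converged
  window-average structure,
* root mean square deviation (RMSD) of a structure relative to an ideal
  alpha-helix of the same length.

Coordinates are stored in Angstrom; RMSF/RMSD are reported in nm, the
convention of the structural literature this analysis serves. Trajectories
are read from and written to multi-model PDB files (MODEL/ENDMDL records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "WindowedRMSF",
    "HelixRMSD",
    "ideal_helix",
    "kabsch_superpose",
    "windowed_rmsf",
    "rmsd_to_ideal",
]

# Textbook alpha-helix geometry: 3.6 residues per turn.
HELIX_RISE = 1.5        # Angstrom per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Angstrom, C-alpha distance from the helix axis


@dataclass
class Trajectory:
    """C-alpha coordinates over frames.

    coords : (n_frames, n_atoms, 3) in Angstrom; atom order is identical
    in every frame. ``residue_ids`` are 1-based residue numbers,
    ``frame_dt`` the frame spacing in ns.
    """

    coords: np.ndarray
    frame_dt: float = 1.0
    residue_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, self.coords.shape[1] + 1)
        self.residue_ids = np.asarray(self.residue_ids)
        if self.residue_ids.size != self.coords.shape[1]:
            raise ValueError("one residue id per atom required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_ns(self) -> float:
        return self.n_frames * self.frame_dt

    def residue_mask(self, region: tuple[int, int] | None) -> np.ndarray:
        """Boolean atom mask for an inclusive 1-based residue range."""
        if region is None:
            return np.ones(self.n_atoms, dtype=bool)
        lo, hi = region
        return (self.residue_ids >= lo) & (self.residue_ids <= hi)

    # -- multi-model PDB I/O ----------------------------------------------

    def save_pdb(self, path: str | Path) -> None:
        """Write as a multi-model PDB of poly-alanine C-alpha atoms."""
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = self.n_atoms
        atoms = struc.AtomArrayStack(self.n_frames, n)
        atoms.coord = self.coords.astype(np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.asarray(self.residue_ids, dtype=int)
        atoms.res_name = np.full(n, "ALA")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        atoms.hetero = np.zeros(n, dtype=bool)
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))

    @classmethod
    def load_pdb(cls, path: str | Path, frame_dt: float = 1.0) -> "Trajectory":
        """Read C-alpha atoms from every MODEL of a multi-model PDB."""
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        ca = stack[:, stack.atom_name == "CA"]
        return cls(coords=np.asarray(ca.coord, dtype=float),
                   frame_dt=frame_dt,
                   residue_ids=np.asarray(ca.res_id[:]))


@dataclass
class WindowedRMSF:
    """Per-residue RMSF of one trajectory window (values in nm)."""

    window_id: int
    window_frames: tuple[int, int]          # [start, end) frame indices
    per_residue_rmsf: np.ndarray            # nm, one per atom
    region_mean: float                      # nm, mean over the residue range
    residue_ids: np.ndarray = field(default=None, repr=False)


@dataclass
class HelixRMSD:
    rmsd_to_ideal: float                    # nm
    residue_range: tuple[int, int] | None


def ideal_helix(n_residues: int) -> np.ndarray:
    """C-alpha coordinates of an ideal alpha-helix.

    Rise 1.5 A/residue, twist 100 deg/residue (3.6 residues/turn), radius
    2.3 A — the canonical geometry; consecutive C-alpha spacing ~3.8 A.
    """
    if n_residues < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    i = np.arange(n_residues)
    phi = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack([HELIX_RADIUS * np.cos(phi),
                            HELIX_RADIUS * np.sin(phi),
                            HELIX_RISE * i])


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Solves for the proper rotation R and translation t minimizing
    ||(mobile @ R.T + t) - reference|| over the selected atoms, via SVD of
    the covariance matrix with the determinant sign corrected so no
    reflection is introduced.

    Returns (R, t, rmsd) with rmsd in the input coordinate units, computed
    over the selection after the transform. Apply as ``mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal atom counts")
    sel = slice(None) if selection is None else np.asarray(selection)
    x = mobile[sel]
    y = reference[sel]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 selected atoms")

    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # collinearity check: rank of the centered selection
    if np.linalg.matrix_rank(x0, tol=1e-8 * max(1.0, np.abs(x0).max())) < 2:
        raise ValueError("degenerate (collinear) atom selection")

    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd


def _superpose_frames(coords: np.ndarray, reference: np.ndarray,
                      fit_mask: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[f], reference,
                                         selection=fit_mask)
        out[f] = coords[f] @ rot.T + trans
    return out


def windowed_rmsf(
    traj: Trajectory,
    window_ns: float,
    discard_ns: float = 0.0,
    region: tuple[int, int] | None = None,
    fit_region: tuple[int, int] | None = None,
    tol_nm: float = 1e-6,
    max_iter: int = 50,
) -> list[WindowedRMSF]:
    """Per-residue RMSF in non-overlapping time windows.

    After discarding the first ``discard_ns``, the trajectory is split into
    non-overlapping windows of ``window_ns`` (partial trailing windows are
    dropped). Within each window, frames are iteratively superposed onto
    the window-average structure until the average moves by less than
    ``tol_nm``; RMSF_i = sqrt(mean_f |r_fi - rbar_i|^2). ``region`` selects
    the residues summarized by ``region_mean``; ``fit_region`` restricts
    the superposition fit selection (default: all atoms).
    """
    frames_per_window = int(window_ns / traj.frame_dt)
    if frames_per_window < 2:
        raise ValueError("window must span at least 2 frames")
    start_frame = int(round(discard_ns / traj.frame_dt))
    available = traj.n_frames - start_frame
    if available < frames_per_window:
        raise ValueError("window longer than available trajectory")

    fit_mask = traj.residue_mask(fit_region)
    region_mask = traj.residue_mask(region)
    n_windows = available // frames_per_window

    results = []
    for w in range(n_windows):
        lo = start_frame + w * frames_per_window
        hi = lo + frames_per_window
        coords = traj.coords[lo:hi]

        ref = coords.mean(axis=0)
        for _ in range(max_iter):
            aligned = _superpose_frames(coords, ref, fit_mask)
            new_ref = aligned.mean(axis=0)
            shift = np.max(np.linalg.norm(new_ref - ref, axis=1))
            ref = new_ref
            if shift < tol_nm * 10.0:   # tol in nm, coords in Angstrom
                break
        aligned = _superpose_frames(coords, ref, fit_mask)
        mean_pos = aligned.mean(axis=0)
        rmsf_A = np.sqrt(np.mean(
            np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
        rmsf_nm = rmsf_A / 10.0
        results.append(WindowedRMSF(
            window_id=w,
            window_frames=(lo, hi),
            per_residue_rmsf=rmsf_nm,
            region_mean=float(rmsf_nm[region_mask].mean()),
            residue_ids=traj.residue_ids,
        ))
    return results


def rmsf_summary(windows: list[WindowedRMSF]) -> tuple[float, float]:
    """Mean and SEM of the region-mean RMSF across windows (nm)."""
    vals = np.array([w.region_mean for w in windows])
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 \
        else float("nan")
    return float(vals.mean()), sem


def rmsd_to_ideal(
    structure: np.ndarray,
    region: tuple[int, int] | None = None,
    residue_ids: np.ndarray | None = None,
) -> HelixRMSD:
    """RMSD of C-alpha coordinates relative to an ideal alpha-helix.

    An ideal helix of the region's length is built and Kabsch-superposed
    onto the selected residues; the residual RMSD (nm) measures departure
    from ideal helicity.
    """
    structure = np.asarray(structure, dtype=float)
    if residue_ids is None:
        residue_ids = np.arange(1, structure.shape[0] + 1)
    if region is not None:
        lo, hi = region
        mask = (residue_ids >= lo) & (residue_ids <= hi)
        coords = structure[mask]
    else:
        coords = structure
    if coords.shape[0] < 4:
        raise ValueError("region must contain at least 4 residues")
    ideal = ideal_helix(coords.shape[0])
    _, _, rmsd_A = kabsch_superpose(ideal, coords)
    return HelixRMSD(rmsd_to_ideal=rmsd_A / 10.0, residue_range=region)


def trajectory_rmsd_to_ideal(
    traj: Trajectory,
    region: tuple[int, int] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Per-frame RMSD to the ideal helix: (mean, SEM, per-frame values) in nm."""
    vals = np.array([
        rmsd_to_ideal(traj.coords[f], region=region,
                      residue_ids=traj.residue_ids).rmsd_to_ideal
        for f in range(traj.n_frames)])
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 \
        else float("nan")
    return float(vals.mean()), sem, vals
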