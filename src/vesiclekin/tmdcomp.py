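"""v-SNARE transmembrane-domain composition scoring.

Beta-branched amino acids (valine, isoleucine) branch at the C-beta atom,
loosening backbone packing and increasing the conformational flexibility
of a transmembrane helix. Exocytotic v-SNARE isoforms differ markedly in
the V/I content of the N-terminal half of their TMD — the half spanning
the vesicle's outer leaflet — and this module scores that composition:
splitting a TMD into halves, counting V/I residues, and producing the
comparison table across the canonical isoforms (synaptobrevin-1,
cellubrevin, synaptobrevin-2, VAMP7, VAMP8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "TMDRecord",
    "CompositionResult",
    "split_halves",
    "count_beta_branched",
    "table1_report",
    "isoform_fixtures",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
BETA_BRANCHED = frozenset("VI")


@dataclass
class TMDRecord:
    """A v-SNARE sequence with its TMD boundaries (1-based inclusive).

    ``n_half``/``c_half`` are filled by :func:`split_halves`, or supplied
    explicitly to pin down a published half assignment that does not
    follow the default midpoint rule (flag ``halves_inferred`` marks
    boundaries that are reconstructed rather than stated).
    """

    name: str
    full_sequence: str
    tmd_start: int
    tmd_end: int
    seq_offset: int = 1         # residue number of full_sequence[0]
    n_half: str | None = None
    c_half: str | None = None
    halves_inferred: bool = False

    def __post_init__(self) -> None:
        self.full_sequence = self.full_sequence.upper()
        _validate_sequence(self.full_sequence, self.name)
        if self.tmd_start > self.tmd_end:
            raise ValueError("tmd_start must be <= tmd_end")

    @property
    def tmd_sequence(self) -> str:
        if self.n_half is not None and self.c_half is not None:
            return self.n_half + self.c_half
        i0 = self.tmd_start - self.seq_offset
        i1 = self.tmd_end - self.seq_offset + 1
        if i0 < 0 or i1 > len(self.full_sequence):
            raise ValueError(
                f"TMD boundaries {self.tmd_start}-{self.tmd_end} outside "
                f"sequence {self.name}")
        return self.full_sequence[i0:i1]


@dataclass
class CompositionResult:
    count_VI: int
    half_length: int
    percent: int            # rounded, ties away from zero


def _validate_sequence(seq: str, name: str = "") -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid amino-acid character {ch!r} at position {pos}"
                + (f" of {name}" if name else ""))


def split_halves(record: TMDRecord) -> TMDRecord:
    """Split the TMD core into N- and C-terminal halves.

    For odd lengths the N-half gets the extra residue (first ceil(L/2)
    residues). Records carrying explicit halves are returned unchanged.
    """
    if record.n_half is not None and record.c_half is not None:
        return record
    core = record.tmd_sequence
    if len(core) < 2:
        raise ValueError("TMD must contain at least 2 residues")
    mid = math.ceil(len(core) / 2)
    return replace(record, n_half=core[:mid], c_half=core[mid:])


def count_beta_branched(half: str) -> CompositionResult:
    """Count V/I residues in a TMD half; percent rounds ties away from zero."""
    if not half:
        raise ValueError("empty sequence half")
    half = half.upper()
    _validate_sequence(half)
    count = sum(1 for ch in half if ch in BETA_BRANCHED)
    percent = math.floor(100 * count / len(half) + 0.5)
    return CompositionResult(count_VI=count, half_length=len(half),
                             percent=percent)


# ---------------------------------------------------------------------------
# canonical isoform fixture
# ---------------------------------------------------------------------------

def isoform_fixtures() -> list[TMDRecord]:
    """The five exocytotic v-SNARE isoforms with their published TMD halves.

    Sequences are the printed mouse TMD regions with flanking residues;
    half assignments follow the published column layout. VAMP7's halves do
    not follow the midpoint rule (11/15 split) and are flagged inferred.
    """
    return [
        TMDRecord("syb1", "KNCKMMIMLGAICAIIVVVIVIYFFT", 97, 114,
                  seq_offset=93, n_half="MMIMLGAIC", c_half="AIIVVVIVI"),
        TMDRecord("cellubrevin", "KNCKMWAIGISVLVIIVIIIIVWCVS", 82, 99,
                  seq_offset=78, n_half="MWAIGISVL", c_half="VIIVIIIIV"),
        TMDRecord("syb2", "KNLKMMIILGVICAIILIIIIVYFST", 95, 112,
                  seq_offset=91, n_half="MMIILGVIC", c_half="AIILIIIIV"),
        TMDRecord("VAMP7", "KNIKLTIIIIIVSIVFIYIIVSLLCGGFTW", 189, 214,
                  seq_offset=185, n_half="LTIIIIIVSIV", c_half="FIYIIVSLLCGGFTW",
                  halves_inferred=True),
        TMDRecord("VAMP8", "KNVKMIVIICVIVLIIVILIILFATG", 76, 93,
                  seq_offset=72, n_half="MIVIICVIV", c_half="LIIVILIIL"),
    ]


def table1_report(records: list[TMDRecord] | None = None) -> pd.DataFrame:
    """V/I composition of the N-terminal TMD half, one row per isoform.

    With no argument, reports the packaged isoform fixture.
    """
    if records is None:
        records = isoform_fixtures()
    rows = []
    for rec in records:
        rec = split_halves(rec)
        comp = count_beta_branched(rec.n_half)
        rows.append({
            "name": rec.name,
            "n_half": rec.n_half,
            "c_half": rec.c_half,
            "count_VI": comp.count_VI,
            "half_length": comp.half_length,
            "percent": comp.percent,
            "halves_inferred": rec.halves_inferred,
        })
    return pd.DataFrame(
        rows, columns=["name", "n_half", "c_half", "count_VI",
                       "half_length", "percent", "halves_inferred"])


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_fasta(records: list[TMDRecord], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqs = [SeqRecord(Seq(r.full_sequence), id=r.name,
                      description=f"tmd={r.tmd_start}-{r.tmd_end} "
                                  f"offset={r.seq_offset}")
            for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path,
               annotations: dict[str, tuple[int, int]] | None = None,
               offsets: dict[str, int] | None = None) -> list[TMDRecord]:
    """Read sequences from FASTA; TMD boundaries from the description line
    (``tmd=start-end offset=o``) or from an ``annotations`` mapping."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        start = end = None
        offset = 1
        for token in rec.description.split():
            if token.startswith("tmd="):
                a, b = token[4:].split("-")
                start, end = int(a), int(b)
            elif token.startswith("offset="):
                offset = int(token[7:])
        if annotations and rec.id in annotations:
            start, end = annotations[rec.id]
        if offsets and rec.id in offsets:
            offset = offsets[rec.id]
        if start is None:
            raise ValueError(f"no TMD annotation for {rec.id}")
        records.append(TMDRecord(rec.id, str(rec.seq), start, end,
                                 seq_offset=offset))
    return records
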