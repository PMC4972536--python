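# vesiclekin

Quantitative analysis of single-vesicle exocytosis for electrophysiology
labs working on neuroendocrine (chromaffin) cells and neurons: carbon-fiber
amperometry, flash-evoked membrane-capacitance kinetics, and the
structural properties of v-SNARE transmembrane domains (TMDs) that shape
fusion-pore behavior.

## What it computes

**Amperometric spike/foot analysis.** Single fusion events appear as a
current spike, often preceded by a prespike "foot" reporting transmitter
flux through the narrow initial fusion pore. The package detects events
on filtered traces (zero-phase Gaussian low-pass, 2 kHz), measures spike
amplitude, charge, 50–90% rise time and half width, locates the foot by
back-extrapolating the maximal-slope line of the spike rise onto the
plateau, and computes the fusion-pore jitter statistics: the *fluctuation
frequency* — contiguous excursions of the 1.2 kHz-filtered current
derivative beyond ±6 pA/ms (≈4× baseline derivative noise), divided by
foot duration — and the threshold-independent rms of the mean-subtracted
derivative. Standard selection rules apply (charge 10–5000 fC, amplitude
>4 pA for frequency analysis, >7 pA for spike characteristics, feet >2 ms
for fluctuation statistics).

**Capacitance burst decomposition.** Flash-evoked capacitance responses
are fit with

    C(t) = A0 + A1·(1 − e^−(t−t₀)/τ1) + A2·(1 − e^−(t−t₀)/τ2) + k·(t − t₀)

for t ≥ t₀ (constant A0 before), where A1/τ1 is the rapidly releasable
pool (RRP), A2/τ2 the slowly releasable pool (SRP), k the sustained rate,
and the shared onset t₀ makes the secretory delay (flash →
back-extrapolated fast component) exactly t₀ − t_flash. Sucrose-evoked
RRP charge with steady-state correction is included.

**TMD composition.** v-SNARE TMDs split into N-/C-terminal halves and
scored for β-branched residues (V/I), whose Cβ branching loosens helix
packing; the packaged fixture covers synaptobrevin-1/-2, cellubrevin,
VAMP7 and VAMP8.

**Helix flexibility.** Kabsch superposition (SVD, reflection-safe),
per-residue Cα RMSF over non-overlapping time windows relative to the
iteratively converged window-average structure, and RMSD relative to an
ideal α-helix (rise 1.5 Å, twist 100°/residue) — all reported in nm.

**Synthetic data.** A first-class generator produces amperometric traces
(foot + flicker + spike kernels on Gaussian noise at 25 kHz), capacitance
responses, and jittered helix trajectories with exact ground truth, so
every estimator is testable end to end.

## Worked example

```python
from vesiclekin import synthgen as sg, amperometry as amp, capkinetics as ck

# one fusion event: 4 ms / 6 pA foot with 4 pore flickers, then a 30 pA spike
ev = sg.EventTruth(onset_time=50.0, foot_duration=4.0, foot_amplitude=6.0,
                   n_flicker=4, spike_amplitude=30.0)
trace, truth = sg.gen_amperometric_trace([ev], duration=0.2, fs=25_000,
                                         baseline_sd=2.0, seed=7)
spike, foot = amp.analyze_trace(trace)[0]
print(f"spike: amplitude {spike.amplitude:.1f} pA, charge {spike.charge:.0f} fC, "
      f"rise {spike.rise_time_50_90:.0f} us, half width {spike.half_width:.2f} ms")
print(f"foot:  duration {foot.duration:.2f} ms, amplitude {foot.amplitude:.1f} pA, "
      f"fluct +{foot.fluct_pos}/-{foot.fluct_neg} ({foot.fluct_frequency:.2f}/ms)")

# flash-evoked capacitance response with 2 fF noise
cm = sg.gen_capacitance_trace(sg.CapTruth(noise_sd=2.0), duration=1.2,
                              fs=2000, seed=7)
fit = ck.fit_exocytotic_burst(cm, flash_time=0.1)
pools = ck.pool_summary(fit)
print(f"RRP {pools.rrp:.1f} fF (tau {fit.tau1*1e3:.1f} ms), "
      f"SRP {pools.srp:.1f} fF (tau {fit.tau2*1e3:.0f} ms), "
      f"sustained {pools.sustained_rate:.1f} fF/s, delay {fit.delay:.2f} ms")
```

prints

```
spike: amplitude 29.4 pA, charge 75 fC, rise 100 us, half width 0.95 ms
foot:  duration 3.95 ms, amplitude 9.4 pA, fluct +4/-4 (2.03/ms)
RRP 49.8 fF (tau 19.3 ms), SRP 80.8 fF (tau 251 ms), sustained 19.5 fF/s, delay 3.50 ms
```

The spike numbers recover the simulated kernel (30 pA peak, 0.1 ms rise
constant); the foot duration and both fluctuation counts match the
inserted ground truth exactly (the foot's mean amplitude exceeds the
6 pA plateau because the flicker oscillations ride on top of it); and
the seven-parameter capacitance fit recovers the generating pools
(A1 = 50 fF, τ1 = 20 ms, A2 = 80 fF, τ2 = 250 ms, k = 20 fF/s) to a few
percent and the 3 ms secretory delay to half a millisecond on this
single noisy trace — the 100-seed study in `scripts/acceptance.py` puts
the median delay error under 0.2 ms.

The same analyses run from the shell:

```
vesiclekin tmd table1
vesiclekin simulate amperometry --seed 1 --out amp.tsv
vesiclekin amperometry analyze amp.tsv --out results/
vesiclekin capacitance fit cm.tsv --flash-time 0.1
vesiclekin helix rmsf traj.pdb --window-ns 10 --discard-ns 10 --region 97:112
```

`vesiclekin tmd table1` prints the packaged isoform table — e.g. the
synaptobrevin-2 N-terminal half `MMIILGVIC` counts 4 V/I residues (44%),
VAMP8's `MIVIICVIV` counts 7 — the composition gradient that parallels
fusion-pore expansion speed across vesicle sizes.

## Layout

- `src/vesiclekin/synthgen.py` — ground-truth generators
- `src/vesiclekin/amperometry.py` — event/foot detection, fluctuation statistics
- `src/vesiclekin/capkinetics.py` — burst fit, secretory delay, sucrose RRP
- `src/vesiclekin/tmdcomp.py` — TMD halves, V/I composition, isoform fixture
- `src/vesiclekin/helixflex.py` — Kabsch, windowed RMSF, RMSD-to-ideal-helix
- `src/vesiclekin/aggregate.py` — mean-of-medians, ECDF, OLS, Mander's coefficient
- `docs/methods.md` — models, estimators, design choices, limitations
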