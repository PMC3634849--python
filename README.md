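# seizdyn

Seizure-dynamics analysis for rodent EEG cohorts: line-length features,
baseline-normalized high-gamma power, inter-electrode synchrony, Racine
behavioral curves, and nonparametric cluster-based group statistics —
driven by a synthetic lithium-pilocarpine cohort generator so that every
stage is testable without access to animal recordings.

## Who this is for

Electrophysiologists and methods developers working with chemoconvulsant
seizure models (e.g. lithium-pilocarpine status epilepticus in rats) who
need to quantify *when* seizures start and *how* they build up, and to
compare those dynamics between a control and an intervention group — for
example, optogenetic silencing of hippocampal pyramidal neurons, which
delays onset and slows early seizure development.

## The statistics at the core

**Line length** of a window is `LL = Σ_k |x[k] − x[k−1]|`, a combined
amplitude/frequency activity measure, computed in sliding 3 s windows
(1.5 s overlap).  Electrographic onset is detected when windowed line
length exceeds the pre-injection baseline mean + 5 SD for 3 consecutive
windows.

**Cumulative line length** over 25 min from seizure onset,

    LL_cum[n] = Σ_{k=2..n} |x[k] − x[k−1]|  /  Σ_{k=2..N} |x[k] − x[k−1]|,

rises monotonically from 0 to 1; constant seizure intensity traces the
diagonal, a slowly building seizure is concave-up beneath it.  Curve
shape, not amplitude, carries the group difference.

**Cluster-based permutation test** for time-resolved group curves:
pointwise two-sample statistics (pooled t, or rank-sum z for ordinal
Racine scores) are thresholded at a pointwise α, contiguous
same-sign runs form clusters scored by their summed statistic, and
cluster p-values come from the permutation distribution of the maximum
absolute cluster mass — family-wise error control over time without
distributional assumptions.  Small designs are enumerated exhaustively.

Also included: one-way ANOVA on onset times (from raw values or published
mean/SEM/n summaries) with Holm-Sidak versus-control correction;
single-Slepian-taper (time-bandwidth 1) high-gamma (70–110 Hz) power in
5 s bins normalized to the pre-light baseline bin and compared with a
Mann-Whitney U test; amplitude-weighted phase-locking and windowed
cross-correlation (2–50 Hz, 1 s windows); and a fiber-tip irradiance
helper (18 mW over a 200 µm core ≈ 570 mW/mm²).

## Worked example

```python
import dataclasses
import numpy as np
from seizdyn import (cluster_permutation_test, default_cohorts, detect_onset,
                     relative_time, standardize)
from seizdyn.synthetic_data import generate_subject, sample_llcum_curves

cfgs = {c.group: c for c in default_cohorts(seed=1)}

# one sham-control animal: synthesize, standardize, detect onset
rec, racine, truth = generate_subject(cfgs["sham_control"], 0)
rec = relative_time(standardize(rec))
onset = detect_onset(rec, "hippocampal_1")
print(f"true onset {truth.onset_s/60:.1f} min, detected {onset/60:.1f} min")

# cohort comparison on cumulative line-length curves (14 control vs 16 experimental)
ctrl = sample_llcum_curves(dataclasses.replace(cfgs["sham_control"], seed=10), 14)
expe = sample_llcum_curves(dataclasses.replace(cfgs["experimental"], seed=20), 16)
res = cluster_permutation_test(ctrl, expe, stat="t", n_perm=1000, seed=3,
                               times=np.arange(ctrl.shape[1], dtype=float))
for c in res.significant(0.05):
    print(f"cluster {c.start_s:.0f}-{c.end_s:.0f} s, mass {c.mass:.0f}, p = {c.p:.4f}")
```

prints

```
true onset 16.6 min, detected 16.9 min
cluster 126-1499 s, mass 23018, p = 0.0010
```

The animal's onset is drawn from the calibrated control distribution
(mean 15.2 min post-injection) and recovered by the line-length detector
to within seconds.  The cluster test finds one significant cluster
spanning essentially the whole 25 min curve: the experimental group's
slowed, remission-interrupted build-up keeps its normalized curves below
the control curves from ~2 min after onset onward, and the permutation
p-value is at the resolution floor of 1000 permutations (1/1001).

The same flow is available from the shell:

```sh
seizdyn simulate --out cohort --seed 1
seizdyn analyze  --cohort cohort --out feats
seizdyn compare  --cohort cohort --features feats --out results --n-perm 1000 --seed 1
```

`compare` writes `report.json`/`report.txt` with the onset ANOVA +
Holm-Sidak table and the cluster tests on cortical and hippocampal
cumulative line-length curves and on Racine score curves.

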