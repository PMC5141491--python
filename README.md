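# mstnet

Phase-lag-index (PLI) functional connectivity and minimum-spanning-tree
(MST) topology analysis for resting-state EEG, with a synthetic-cohort
generator that provides ground-truth coupling topologies for validating
every stage of the pipeline.

## The problem

In several neurological conditions — amyotrophic lateral sclerosis among
them — resting-state functional brain networks appear to reorganize from a
centralized, star-like topology toward a decentralized, line-like one, in
proportion to clinical disability. Testing such claims from EEG requires a
chain of estimators, each with known failure modes: volume conduction
produces spurious zero-lag coupling, connectivity thresholds bias graph
comparisons, and short epochs make network estimates noisy. `mstnet`
implements the standard lag-based, threshold-free analysis chain and — since
clinical EEG of this kind is rarely shared — a simulator whose recordings
have *known* coupling trees, group effects, and disability covariates, so
that the whole pipeline can be validated against ground truth.

## The method

For each subject, band and 8 s epoch:

1. **Preprocessing** — common-average re-reference (configurable exclusion
   set), bad-channel removal, extraction of consecutive 2048-sample epochs,
   zero-phase Butterworth band-pass into delta [1,4), theta [4,8),
   alpha [8,13), beta [13,30) Hz.
2. **Connectivity** — instantaneous phases φ from the analytic signal; for
   every channel pair the phase lag index

   PLI = | ⟨ sign( sin(φᵢ(t) − φⱼ(t)) ) ⟩ₜ | ∈ [0, 1],

   which is blind to phase differences of 0 or π and hence robust to
   instantaneous volume-conduction mixing.
3. **Network** — Kruskal MST of the complete graph with link weight 1 − PLI,
   summarized by leaf fraction L/N, diameter (longest shortest path / (N−1)),
   degree divergence κ = ⟨k²⟩/⟨k⟩, and tree hierarchy
   Th = L / (2(N−1)·B_max) with B_max the maximum normalized betweenness
   (star: Th = 0.5 exactly). Each subject's trees are compared with the MST
   of the control-group average matrix via the dissimilarity
   D = 1 − |shared edges|/(N−1).
4. **Spectra** — Welch PSD (2 s Hamming segments, 50% overlap) and relative
   band power over the [1, 30) Hz range, to check that topology differences
   are not power-driven.
5. **Statistics** — Mann–Whitney group contrasts (exact for small tie-free
   samples) with Benjamini–Hochberg FDR over the four bands per outcome,
   Cohen's d, and Spearman correlations between network metrics and the
   disability score (48 − ALSFRS-R), at subject and single-epoch level.

The simulator realizes the star→path axis directly: channel phases follow
Kuramoto–Sakaguchi dynamics on a known spanning tree (children pulled toward
parent phase + π/4), interpolated between a star and a path per subject, with
patients' interpolation shift increasing with disability. Zero-lag leakage is
added by an explicit mixing matrix.

## Worked example

```python
from mstnet import CohortSpec, RunConfig, run_pipeline

spec = CohortSpec.default(n_channels=19, n_epochs=2, epoch_length=512, seed=11)
res = run_pipeline(RunConfig(cohort=spec, n_epochs=2, epoch_length=512,
                             rereference=False, compute_power=False))
gs = res.group_stats
print(gs[gs.outcome == "leaf_fraction"][
    ["band", "patient_mean", "control_mean", "p_value", "fdr_significant"]
].to_string(index=False))
```

prints

```
 band  patient_mean  control_mean      p_value  fdr_significant
delta      0.527569      0.544408 3.188003e-01            False
theta      0.461153      0.480263 5.454057e-01            False
alpha      0.474937      0.509868 5.933038e-02            False
 beta      0.548872      0.832237 2.541294e-07             True
```

Patients (topology shifted toward a path, 21 subjects) show a far lower
leaf fraction than controls (star-like, 16 subjects) exactly and only in
the beta band — the band carrying the simulated coupling — while the
noise-only bands are null. The patients-only Spearman correlation between
beta leaf fraction and disability in the same run is ρ = −0.51, p = 0.017
(`res.correlations`), recovering the simulated disability–topology slope
with the expected sign.

The same analysis runs from the shell:

```
mstnet simulate --out data/ --seed 7
mstnet analyze --manifest data/manifest.tsv --out results/
mstnet report --results results/ --plots
```

## Layout

- `src/mstnet/simulate.py` — coupled-oscillator cohort generator
- `src/mstnet/preprocess.py` — re-referencing, epoching, filtering
- `src/mstnet/connectivity.py` — analytic-signal phases, PLI
- `src/mstnet/mst.py` — Kruskal MST, topology metrics, dissimilarity
- `src/mstnet/spectral.py` — Welch PSD, relative band power
- `src/mstnet/stats.py` — Mann–Whitney, FDR, Spearman, Cohen's d
- `src/mstnet/pipeline.py`, `src/mstnet/cli.py` — orchestration and CLI
- `docs/methods.md` — model, conventions, and design decisions
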