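# Methods

This note records the models, conventions and numerical choices behind
`mstnet`, in the order data flows through the pipeline. Where the standard
analysis protocol is silent on a detail, the choice made here is stated
together with its rationale and, where relevant, the configuration switch
that changes it. No empirical claim in this note goes beyond what the test
suite and `scripts/acceptance.py` actually compute.

## Synthetic cohort model

**What it emulates.** 61-channel (default) eyes-closed resting EEG at
256 Hz, four 2048-sample (8 s) epochs per subject; a patient group
(default 21) whose functional coupling topology deviates from the control
group's (default 16) star-like organization toward a path-like one in
proportion to a disability covariate on the 0–48 scale (48 − ALSFRS-R).

**Coupling trees.** `make_interpolated_tree(n, shift)` interpolates
between a star centred on node 0 (`shift = 0`) and the path
0–1–…–(n−1) (`shift = 1`) by detaching `round(shift·(n−2))` of the star's
leaves and re-chaining them in index order. The construction is
deterministic, and leaf fraction / diameter are monotone along the family
(tested). Controls use a template tree at shift 0.1 (star-like but not
degenerate); patient *i* uses shift
`clip(0.35 + 0.6·disabilityᵢ/48, 0, 1)`, so patient shifts span ≈0.4–0.85
under the default disability range (uniform integers 4–40; the protocol
literature reports no ALSFRS-R distribution, so a broad uniform range is
used as a convention).

**Phase dynamics.** Each channel carries a narrowband oscillator whose
phase follows Euler-integrated Kuramoto–Sakaguchi dynamics on the coupling
tree: intrinsic frequency drawn as `N(band centre, 0.4 Hz)` clipped to the
carrier band (default beta, 13–30 Hz), phase diffusion of intensity
2 rad/√s, and a pull of gain `coupling_strength × 25 rad/s`, normalized by
node degree, toward each neighbour's phase offset by the coupling lag
(default π/4 — safely away from 0 and π where lag-based connectivity is
blind; zero-lag relationships are produced *only* by the mixing stage).
Degree normalization keeps the per-sample pull bounded for hub nodes
(an un-normalized hub with 57 neighbours makes the Euler step unstable).
Integration starts at the stationary coupled state (children at
parent − lag, perturbed ∝ 1 − coupling), so no locking transient
contaminates the first epoch.

The emitted signal is `amplitude(t) · cos(φ(t)) + sensor noise`:
slow amplitude modulation (OU-filtered noise, τ = 0.5 s, depth 0.2) makes phase-difference distributions concentrated but not
degenerate, like real narrowband EEG; white sensor noise (default SD 0.3
of the unit carrier amplitude) sets the in-band SNR. The carrier is
band-pass filtered to its band before noise is added: phase diffusion
gives the bare cosine Lorentzian sideband tails which would otherwise
carry coherent, tree-structured phase into the *other* analysis bands at
amplitudes comparable to the noise floor (observed during development as
a spurious cross-band topology signal; band-limiting removes it, after
which the non-carrier bands are exactly null between groups).

**Volume conduction.** A separate, purely instantaneous mixing
`out = M · in` with `M_ij ∝ exp(−|i−j|/spread)`, rows normalized to 1
(default spread 1.0; 0 disables). This is a deliberately geometry-free
leakage surrogate: it creates only 0-or-π phase relationships, which the
phase lag index discards by construction — the property the acceptance
checks probe.

**What the generator does not model.** Electrode geometry and realistic
lead fields, ocular/muscle artifacts, 1/f background spectra,
non-stationary band power, or any ALS electrophysiology beyond the
topology-shift abstraction. Passing tests therefore demonstrate that the
estimator chain recovers *this* class of ground truth under zero-lag
mixing and additive noise — not that it would detect effects of clinical
size in real recordings.

## Preprocessing conventions

- Common-average reference: the mean over the non-excluded channels is
  subtracted from every channel (excluded ones included); idempotent. The
  61-channel montage excludes the six fronto-polar channels from the
  reference computation.
- The protocol's three unnamed bad channels are represented by the fixed
  set T7/T8/TP8 in the emulation montage (61 → 58 retained channels);
  bad channels are per-dataset configuration.
- Epochs are cut first (consecutive, non-overlapping, from the start of
  the recording) and then filtered.
- Filter realization (protocol silent): 4th-order Butterworth applied
  forward–backward per epoch (zero phase, effective order 8). Zero phase
  is essential for phase-based connectivity. Order is configurable.
- Band edges are half-open `[low, high)` so delta/theta/alpha/beta
  partition [1, 30) Hz with no double counting at 4/8/13 Hz.
- `edge_trim` (default 0) optionally discards samples at each epoch edge
  before phase statistics, guarding against filter/Hilbert edge effects;
  with 2048-sample epochs these affect only a handful of boundary samples.
- **Referencing caveat (synthetic data).** Common-average re-referencing
  is itself a zero-lag mixing; on a *strongly synchronized* star cohort it
  subtracts the coherent common mode and visibly degrades recovery of the
  hub topology (control leaf fraction 0.84 → 0.63 in development runs)
  while leaving path-like cohorts nearly untouched — masking the very
  contrast under study. Real EEG needs re-referencing because channels
  share a physical reference electrode; the simulator emits
  reference-free signals. `RunConfig.rereference` therefore defaults to
  True (protocol emulation) but the reduced-scale Monte-Carlo validation
  studies run with it disabled. This is a genuine, documented referencing
  caveat of CAR + synchronized sources, not a numerical artifact.

## Connectivity conventions

- PLI per epoch only, never on concatenated epochs.
- `sign(0) = 0`: samples with phase difference exactly 0 or π contribute
  nothing, so PLI of a channel against itself (or a duplicate) is exactly 0.
- Zero-variance channels have undefined phase: they are flagged with a
  warning and their PLI rows set to 0 rather than aborting a cohort run.
- Global mean PLI = mean of the strictly-upper triangle within each epoch,
  then mean over epochs (the two averagings commute at fixed epoch count;
  tested).

## Tree metrics conventions

- MST via Kruskal on link weight 1 − PLI; edges enter the sort in
  lexicographic (i, j) order so weight ties break deterministically.
- Diameter is reported as link count divided by N−1 (group differences in
  the reference literature are on a fractional scale); the raw link count
  is available via `normalize=False`.
- κ = ⟨k²⟩/⟨k⟩, computed as a ratio of integer degree sums so
  integer-valued cases (star: N/2) are exact in floating point.
- Tree hierarchy Th = L/(2·M·B_max) with M = N−1 and B_max the maximum
  betweenness normalized by (N−1)(N−2)/2, so a star's hub has B_max = 1
  and the star scores exactly 0.5. Betweenness on trees is computed in
  O(N) from rooted subtree sizes (pairs through v =
  ((N−1)² − Σ s_c²)/2 over the components of tree − v), validated against
  the generic Brandes implementation. Th is undefined below 3 nodes.
- Dissimilarity is the unweighted edge-overlap complement
  1 − |shared|/(N−1) against the MST of the element-wise mean of all
  control matrices (subjects × epochs).
- Subject-level metrics default to the mean of per-epoch metric values
  (epoch-level metrics demonstrably carry the association of interest);
  the MST-of-mean-matrix alternative is available via
  `aggregation="mean_matrix"`.

## Spectral conventions

Welch PSD with 512-sample (2 s) Hamming segments at 50% overlap — 7
averaged segments per 8 s epoch at 0.5 Hz resolution; all settable.
Relative power sums PSD bins with `low ≤ f < high` and divides by the
[1, 30) Hz total (union of the analysed bands; switchable), so the four
canonical relative powers sum to exactly 1. Segment length is capped at
the epoch length for short-epoch runs.

## Statistical conventions

- Mann–Whitney: exact null distribution when min(n) ≤ 8 and the pooled
  sample is tie-free (verified against full enumeration for sizes up to
  5 vs 5), otherwise normal approximation with continuity and tie
  corrections. Both U (first group) and its rank sum W = U + n₁(n₁+1)/2
  are reported, since software conventions for "W" differ.
- FDR: Benjamini–Hochberg step-up at q = 0.05 over the family of four
  bands, per outcome; no correction across outcome types.
- Cohen's d uses the pooled SD with n−1 denominators. (Published effect
  sizes in the motivating clinical tables are inconsistent with any
  standard d formula given their printed means/SDs and are not targeted.)
- Correlations use patients only (controls have disability 0 by
  definition, which would otherwise inject a mass of tied zeros).
- Single-epoch-level correlations treat each epoch as a point at its
  subject's disability; the returned result carries an explicit caveat
  that such points are not independent and the p-value is computed at an
  inflated n.

## Validation problem sizes

The Monte-Carlo validation studies run at desk scale by choice: a
19-channel 10-20 montage, 2 epochs of 512 samples, with re-referencing
disabled (see the caveat above). Under these conditions the package's own
tests compute: 100 effect cohorts (21 patients / 16 controls) for
direction-of-effect recovery of the beta-band leaf-fraction deficit and
its negative disability correlation; 200 no-coupling cohorts for nominal
5% calibration of the beta-band Mann–Whitney test; 200 draws for the
zero-lag-mixing PLI null; exhaustive Prüfer enumerations at 6 and 7 nodes
for the MST and hierarchy oracles. The full 61-channel, 4×2048-sample
configuration runs end-to-end in well under a minute per cohort and is
exercised for the 58×58 matrix-shape check.

## Known limitations

- The simulator's PLI values under strong coupling (≈0.9 on true edges)
  are far higher than typical resting-state EEG values (≈0.07–0.17);
  the pipeline's detection power on these cohorts is accordingly not an
  estimate of clinical power.
- Path-like ground truth is recovered as path-*like* rather than exactly:
  with lag π/4 per link, two-hop pairs (lag π/2) can show higher PLI than
  direct edges, so recovered trees of path cohorts have somewhat higher
  leaf fractions than the true path. Group separation and correlation
  signs are unaffected (tested).
- EDF export uses a built-in minimal 16-bit writer (one record per second,
  symmetric physical range); round-trip error is bounded by
  range/2¹⁵ and verified against an independent reader. EDF+ annotations
  are not supported.
- No artifact modelling or rejection, no source reconstruction, no
  longitudinal modelling.
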