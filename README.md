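# foldconn

Gyri/sulci-stratified connectome analysis for neonatal MRI cohorts.

Cortical folding concentrates long-range axonal wiring in the gyral crowns,
and preterm birth — which interrupts the third-trimester folding window —
is thought to disrupt gyrus-to-gyrus connectivity specifically, with
downstream consequences for the synchronization of spontaneous BOLD
activity. `foldconn` implements the full analysis chain needed to test that
hypothesis on structural and functional connectomes whose nodes are the
gyral and sulcal parts of each atlas region, and ships a synthetic-cohort
generator with known ground truth so every stage is testable without
access-controlled infant data.

## What it computes

Given a cortical surface with per-vertex curvature `r`, atlas labels and
BOLD signals, plus streamline endpoint assignments:

1. **Fold parcellation** — each of the 32 atlas regions is split at a
   curvature threshold (gyral part `r > r_thr`, sulcal `r < r_thr`,
   default `r_thr = 0.15`), giving `N = 64` ROIs; vertex signals are
   averaged per ROI.
2. **Structural connectivity** — `SC(i,j)` is the number of streamlines
   joining ROIs `i` and `j` over the whole-brain streamline total. Edges
   are classed GG / GS / SS by their endpoints' fold classes, and the
   class-mean strengths `⟨SC_GG⟩, ⟨SC_GS⟩, ⟨SC_SS⟩` and the ratio
   `⟨SC_GG⟩/⟨SC_GS⟩` summarize each connectome.
3. **Phase synchronization** — ROI signals are band-passed (Butterworth
   order 2, 0.02–0.10 Hz, zero-phase), reduced to instantaneous phases
   `φ_j(t)` by the Hilbert transform, and trimmed 50 TR per end
   (TR = 0.392 s). Synchrony is measured by the Kuramoto order parameter
   `r(t) = |M⁻¹ Σ_j exp(iφ_j(t))|` over the global / gyral / sulcal node
   sets (its time mean is the "mean synchronization"), and by the
   phase-locking value `PLV(a,b) = |T⁻¹ Σ_t exp(i(φ_a − φ_b))|`.
4. **Network-based statistics** — edge-wise two-sample t over PLV
   matrices, supra-threshold component extraction (`T > 3.1`), and a
   permutation null (default 5000 relabelings) of the maximal component
   extent giving family-wise-error-corrected cluster p-values.
5. **Hubs** — nodal degree `D_nodal(i) = Σ_{j≠i} PLV(i,j)`, per-subject
   top-5% hub sets, group-level membership ranking with top-10% group
   hubs, gyral/sulcal hub contingency tables and Mann-Whitney U tests.
6. **Group statistics** — Welch's ANOVA, Levene's test, Tukey HSD,
   simple linear regression, and 1:1 greedy propensity-score matching
   for building covariate-balanced cohorts.
7. **Synthetic cohorts** — three-group metadata (FT/PT/PP), block-
   structured connectomes with the GG block attenuated in preterm groups,
   and BOLD-like signals from noisy Kuramoto phase oscillators coupled
   through each subject's SC graph.

## Worked example

```sh
python examples/synchronization_measures.py
```

```
phases: 64 ROIs x 512 samples (50 TR trimmed per end)
mean global synchronization: 0.507
mean gyri synchronization: 0.841
mean sulci synchronization: 0.311
mean off-diagonal PLV: 0.435
```

A full-term-like synthetic subject sits in the partially synchronized
regime (global mean order parameter ≈ 0.5); the gyral subnetwork — denser
internal coupling, tighter intrinsic frequencies — is far more coherent
(0.84) than the sulcal one (0.31). Comparing connectomes across groups:

```sh
python examples/structural_classes.py
```

```
FT: <SC_GG>=6.98e-04  <SC_GS>=3.60e-04  <SC_SS>=1.81e-04  GG/GS=1.94  (planted GG attenuation 1.0)
PT: <SC_GG>=4.90e-04  <SC_GS>=3.58e-04  <SC_SS>=1.84e-04  GG/GS=1.37  (planted GG attenuation 0.7)
```

The preterm-like subject loses ~30% of gyrus-to-gyrus strength while GS
and SS connectivity are untouched, so its GG/GS ratio drops. The other
scripts in `examples/` demonstrate parcellation, NBS on a planted group
difference, hub ranking, and cohort matching/statistics the same way.

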