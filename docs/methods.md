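# Methods

## The two-state ensemble model

The analysis assumes the receptor ligand-binding domain populates two
long-lived conformations — repressive (helix 12 occluding the orthosteric
pocket, corepressor-competent) and active (helix 12 solvent-exposed,
coactivator-competent) — interconverting slowly on the NMR chemical-shift
time scale (milliseconds or longer). Under slow exchange each backbone
amide of a reporter residue contributes one 2D [¹H,¹⁵N] peak per state, and
the integrated volume of each peak is proportional to that state's
population. The headline statistic is the population-weighted ¹H shift
δ̄ = Σ Vᵢδ_H,i / Σ Vᵢ, equivalent to p_rep·δ_H,rep + p_act·δ_H,act when the
peaks sit on the state anchor positions. Weighting uses the ¹H dimension
only; populations come from volumes alone — no exchange-rate fitting
(relaxation dispersion, ZZ-exchange) is attempted.

Key assumptions, and where they can fail on real data: volumes track
populations only if the two states relax comparably (dynamics on other time
scales modulate linewidths and hence volumes); overlapped peaks cannot be
integrated separately and must be excluded (an exclusion-decoy generator
tests this path); residues are treated independently.

## Synthetic data generator

The generator's single latent variable per ligand is `f_rep` ∈ [0,1], the
repressive-state fraction. A series of *n* ligands spans [0,1] uniformly
(descending, so ligand L01 is the strongest inverse agonist, matching
rank-by-corepressor-efficacy numbering). All downstream raw data derive
from it:

- **Spectra** — separable 2D Lorentzian peaks (pure Lorentzian, Gaussian
  fraction 0: TROSY peaks are near-Lorentzian and the fitter assumes the
  same family, keeping round-trips exact) at repressive/active centers with
  volumes f_rep and 1−f_rep times a common scale. Default reporter-residue
  geometry ("G399": rep 8.40/109.5 ppm, act 8.10/108.5 ppm, fwhm
  0.02/0.15 ppm) separates the states by 15 ¹H linewidths, a resolved
  slow-exchange doublet. Grid: 320×256 points over 7.7–8.8 / 106–112 ppm
  (≥5 points per linewidth). Additive i.i.d. Gaussian noise with
  sd = max height / snr; default snr 50. An optional overlap decoy
  ("G284", 1.5 linewidths from the repressive peak) exercises exclusion
  handling.
- **TR-FRET dose-response** — three-parameter sigmoid (Hill slope 1) with
  plateau linked linearly to the favoured-state population
  (top = 0.25 + 0.55·link, bottom = 0.20 in 520/495 ratio units; link =
  f_rep for NCoR1, 1−f_rep for MED1), EC50 drawn once per ligand from
  10^[−7.5,−5.5] M, multiplicative Gaussian noise (CV 2% default),
  triplicate wells as in plate practice. A 12-point half-log dilution from
  100 µM covers every latent EC50.
- **FP saturation** — Y = Bmax·X/(Kd+X) + background with Bmax 120 mP over
  a 60 mP background, protein titrated 12 points 2-fold from 45 µM, and an
  affinity link pKd = 4.0 + 2.5·link: the weak end (Kd = 100 µM) exceeds
  the 45 µM maximum on purpose so those conditions do not saturate and the
  shared-Bmax machinery is genuinely needed. Additive noise (sd 1 mP).
- **Reporter** — sigmoid in fold-over-vehicle units, plateau falling from
  4.0 (full agonism) to 0.1 (full repression) as f_rep rises.
- **qPCR** — Ct tables built so the comparative-Ct method inverts exactly:
  log2 RQ = 2 − 4·f_rep (agonists induce the target gene ~4-fold, strong
  inverse agonists repress to ~0.25-fold vs the vehicle calibrator),
  housekeeping Ct 20, calibrator ΔCt 5, additive Ct noise (sd 0.1 cycles).

Determinism: every generator is a pure function of (parameters, seed); the
master seed expands via `numpy.random.SeedSequence` spawn keys per
(ligand, assay) so streams are independent and bit-reproducible.

What the generator does *not* emulate: peak-shape distortions from
intermediate exchange or differential relaxation, plate-position artefacts,
compound fluorescence interference, covalent-binding kinetics (potency in
the emulated series is deliberately uncorrelated with efficacy), or
biological scatter between assay families beyond independent noise. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to every pathology of real spectra and plates.

## Bloch–McConnell simulator

Two-site exchange with detailed balance (k_AB = p_B·k_ex, k_BA = p_A·k_ex);
the transverse-magnetisation FID s(t) = 1ᵀexp(Lt)M₀ is evaluated by
eigendecomposition of the 2×2 evolution matrix and Fourier transformed with
first-point halving; the one-sided-decay factor of 2 makes site areas equal
populations exactly. It validates the peak-counting model: areas reproduce
(p_A, p_B) within 2% for k_ex ≤ |Δω|/50, and the fast-exchange peak
collapses to the population-weighted offset, agreeing with the two-peak
weighted shift within 1% of the state separation. k_ex is a free parameter
throughout — no value is asserted for any ligand.

## Peak fitting and integration

Noise is estimated as MAD×1.4826 over the quietest quartile of a 4×4
tiling of the grid (tiles ranked by max |intensity|); a literal
lowest-quartile-of-cells rule would bias the estimate far below the true sd
on pure noise, while tile selection merely excludes signal. Picking takes
3×3-neighbourhood maxima above 5× noise with greedy elliptical-norm
suppression (ties: lower ¹H, then lower ¹⁵N ppm). Each seed gets a bounded
least-squares fit of amplitude, centers, widths, and a flat baseline within
a 0.12×0.9 ppm window, with up to three jittered restarts;
non-convergence flags the result rather than raising. Because noise bumps
on a strong peak's tails seed fits that converge to the same optimum,
fitted peaks whose centers coincide within half a linewidth are
deduplicated (best residual wins). Volumes are the analytic model integral;
a direct elliptical grid sum (semi-axes = 3×fwhm, baseline = local median
in a ring at 2–2.5× the radii) is reported as a cross-check — the ellipse
at 3×fwhm contains 79.25% of a 2D Lorentzian's volume analytically, so the
two conventions differ by a stable, shape-dependent factor.

Assignment transfer minimises total chemical-shift-perturbation distance
(CSP = √(Δδ_H² + (α·Δδ_N)²), α = 0.14 default, 0.2 for glycines) by
optimal one-to-one matching with links capped at max_csp = 0.1 ppm.

## Ensemble summaries

Peaks are labelled repressive-/active-like by CSP proximity to anchor
positions (two peaks: minimal-total-distance assignment; one peak: nearest
endpoint, midpoint ties to repressive). A second state below 2% of total
volume is treated as noise and dropped (flagged). Missing residues yield
flagged missing rows, not exceptions, so series tables support pairwise
deletion downstream.

## Pharmacology conventions

Hill slope is fixed at 1 (the "three-parameter" convention). EC50 is
bounded to [min(x)/100, 100·max(x)]; flat curves return
converged=False with bottom=top=mean. The total-binding equation omits a
linear nonspecific term — protein, not tracer, is titrated, and the
fixed-Bmax convention implies the specific-site hyperbola. The shared Bmax
comes from a joint fit across curves whose maximum concentration is ≥5×
their apparent (free-fit) Kd. FP bias defaults to the pKd scale (raw-Kd
differences are scale-dominated); the linear option exists. ddCt
dispersion: RQ limits are 2^−(ΔΔCt∓sd) with sd the replicate spread of
ΔCt — a declared convention, since the original instrument software's
definition is proprietary.

## Correlation analysis

Spearman with average ranks; s is the Pearson correlation of ranks. The
two-sided p is the probability that |s| of an uncorrelated draw meets or
exceeds the observed |s|: full n! enumeration for n ≤ 9 (vectorised), the
t-approximation with n−2 df above, both always computed and the method
labelled. A seeded Monte-Carlo mode (10⁵ draws) covers larger n when an
enumeration-style p is wanted. No multiple-comparison adjustment — raw
p-values with per-pair n, missing data removed pairwise. Ligand ranking
sorts descending by efficacy with ties broken by ligand id.

## Structure comparison

Cα traces are paired by residue-number intersection (disordered residues
drop out) and superposed by closed-form Kabsch SVD with the determinant
sign correction enforcing a proper rotation; for near-identical structures
this is the rigid-body equivalent of flexible-alignment tools. Only one
chain is compared; ligands, peptides, and waters are ignored; first
alternate locations only.

## Problem sizes and numerical choices

Default analyses use a 22-ligand series, 320×256-point spectra at snr 50,
12-point assay curves in triplicate, 200-curve noise-recovery batteries,
and 20 master seeds for the end-to-end correlation study — sizes chosen so
the whole pipeline and its test battery run in minutes on one CPU while
keeping every estimator in its asymptotically informative regime.
Tolerances in tests mirror the estimators' information limits (e.g. a
single 12-point curve at 2% CV bounds EC50 precision at ~6% sd; triplicate
wells bring the 10%-error rate above 95%).

## Known limitations

No raw FID processing, apodization, or phasing; no 3D spectra; no
automated backbone assignment; no exchange-rate estimation; no
covalent-kinetics potency model; no plate-effect normalisation beyond
per-plate controls; PDB parsing covers coordinate records, not mmCIF
dialects. The conformation-activity correlation on synthetic data is an
upper bound on what real series can show, since the generator's readouts
share a single latent variable.
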