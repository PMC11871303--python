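# carnmr

Conformation-activity-relationship (CAR) analysis for a ligand-regulated
nuclear receptor: quantify a two-state (repressive/active) conformational
ensemble of the PPARγ ligand-binding domain from 2D [¹H,¹⁵N] NMR peak
volumes, fit the biochemical/cellular ligand-profiling assays with their
standard conventions, and correlate ensemble position with graded ligand
efficacy across a compound series.

Intended for structural-biology and chemical-biology groups analysing
slow-exchange protein conformational ensembles together with plate-based
pharmacology: the package ships a synthetic-data generator that stands in
for the raw spectra and plates, so the full analysis is reproducible without
instrument data, and every step accepts real peak lists / assay tables in
plain CSV/TSV.

## The model

A backbone amide of a residue reporting on the ensemble shows one 2D NMR
peak per long-lived conformation when exchange is slow on the chemical-shift
time scale. Integrated peak volumes *V* estimate the relative state
populations, and the population-weighted ¹H chemical shift

δ̄ = Σᵢ Vᵢ·δ_H,i / Σᵢ Vᵢ,  p_rep = V_rep / (V_rep + V_act)

summarises where the ensemble sits between the repressive- and active-state
anchor positions. Peaks are fitted as separable 2D Lorentzians (volume =
(π/2)²·A·fwhm_H·fwhm_N) with a direct elliptical-integration cross-check,
and a two-site Bloch–McConnell simulator validates the slow/fast-exchange
peak interpretation.

Functional profiling uses the field's standard fits: the three-parameter
sigmoid y = bottom + (top−bottom)/(1 + EC50/x) for coregulator-recruitment
(TR-FRET) and reporter dose-response curves; the one-site total-binding
hyperbola Y = Bmax·X/(Kd+X) + background with a fixed Bmax shared across
conditions (estimated jointly from the saturating, high-affinity curves) for
fluorescence-polarization binding; a coregulator bias factor defined as the
NCoR1 value minus the MED1 value; and comparative-Ct relative expression
RQ = 2^(−ΔΔCt). Ensemble position is related to each readout by Spearman
rank correlation with two-sided p-values (exact permutation enumeration for
small n, t-approximation otherwise). A Kabsch superposition utility reports
pairwise Cα RMSD between crystal structures.

## Worked example

```
python analysis/01_simulate.py --seed 1     # ligand series + raw data
python analysis/02_fit_spectra.py           # peak fits -> ensemble.csv
python analysis/03_fit_assays.py            # assay fits -> profiles.csv
python analysis/04_car_correlation.py       # Spearman matrices
python analysis/05_structure_rmsd.py        # C-alpha RMSD matrix
```

Output of the run above:

```
22 ligands simulated (seed 1): f_rep spans [0, 1], spectra at snr=50.0 ...
fitted 22 spectra: 18 ligands show two-state ensembles; p_rep range [0.000, 1.000]
profiled 22 ligands (shared Bmax = 119.8 mP); NCoR1 efficacy range [0.25, 0.80]
Spearman of weighted NMR shift vs functional readouts:
ncor1_efficacy       0.998
ncor1_affinity       0.998
med1_efficacy       -0.998
med1_affinity       -0.998
trfret_bias          0.998
fp_bias              0.998
reporter_activity   -0.998
rq_expression       -0.995
```

Reading: the recovered weighted shift tracks corepressor (NCoR1)
recruitment efficacy and affinity positively and coactivator (MED1)
readouts, transcription, and target-gene expression negatively — ligands
that push the ensemble toward the repressive conformation recruit
corepressor, release coactivator, and repress transcription, with |s| ≈ 1
on the synthetic series because its only latent variable is the repressive
fraction.

The same operations are scriptable through a thin CLI
(`carnmr simulate|peaks|assign|ensemble|fit|correlate|rmsd --help`).

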