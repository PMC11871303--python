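#!/usr/bin/env python
"""Fit 2D peaks in every simulated spectrum and quantify the ensemble.

Reads spectra from scratch/spectra/, writes per-ligand peak lists there and
the ensemble summary (delta_bar, p_rep per ligand) to results/ensemble.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from carnmr.ensemble import ensemble_table
from carnmr.pipeline import DEFAULT_ANCHORS, fit_spectrum_peaks
from carnmr.spectra import read_spectrum, write_peaklist

REPO = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--residue", default="G399")
    args = ap.parse_args()

    specdir = REPO / "scratch" / "spectra"
    peaks_by_ligand = {}
    for meta in sorted(specdir.glob("spectrum_*.json")):
        ligand_id = meta.stem.removeprefix("spectrum_")
        spec = read_spectrum(meta.with_suffix(""))
        fitted = fit_spectrum_peaks(spec)
        write_peaklist(fitted, specdir / f"peaks_{ligand_id}.tsv")
        peaks_by_ligand[ligand_id] = fitted

    table = ensemble_table(peaks_by_ligand, args.residue, DEFAULT_ANCHORS)
    out = REPO / "results" / "ensemble.csv"
    table.to_csv(out, index=False)

    n_two_state = int((table["p_rep"].gt(0.01) & table["p_rep"].lt(0.99)).sum())
    print(f"fitted {len(peaks_by_ligand)} spectra: {n_two_state} ligands show "
          f"two-state ensembles; p_rep range "
          f"[{table['p_rep'].min():.3f}, {table['p_rep'].max():.3f}] -> {out}")


if __name__ == "__main__":
    main()
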