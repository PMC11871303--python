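#!/usr/bin/env python
"""Correlate ensemble position with every functional readout.

Builds the CAR table (ensemble + profiles), computes all pairwise Spearman
correlations with two-sided p-values, and ranks ligands by corepressor
recruitment efficacy.  Writes matrices under results/car/.
"""

import argparse
from pathlib import Path

import pandas as pd

from carnmr.correlation import correlation_matrix, rank_ligands

REPO = Path(__file__).resolve().parent.parent


def main() -> None:
    argparse.ArgumentParser().parse_args()
    ens = pd.read_csv(REPO / "results" / "ensemble.csv")
    prof = pd.read_csv(REPO / "results" / "profiles.csv")
    car = ens.rename(columns={"delta_bar_H_ppm": "weighted_shift_H"}).merge(
        prof, on="ligand_id", how="outer")
    outdir = REPO / "results" / "car"
    outdir.mkdir(parents=True, exist_ok=True)
    car.to_csv(outdir / "car_table.csv", index=False)

    numeric = car.drop(columns=["ligand_id", "residue_id", "flags", "p_rep",
                                "ncor1_log_ec50", "med1_log_ec50"],
                       errors="ignore")
    m = correlation_matrix(numeric)
    m.s.to_csv(outdir / "spearman_s.csv")
    m.p.to_csv(outdir / "spearman_p.csv")
    m.n.to_csv(outdir / "spearman_n.csv")
    m.long.to_csv(outdir / "spearman_long.csv", index=False)

    ranked = rank_ligands(car, "ncor1_efficacy")
    shift_row = m.s["weighted_shift_H"].drop("weighted_shift_H").round(3)
    print("Spearman of weighted NMR shift vs functional readouts:")
    print(shift_row.to_string())
    print(f"strongest corepressor recruiter: {ranked[0]}; full matrices -> {outdir}")


if __name__ == "__main__":
    main()
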