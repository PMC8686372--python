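#!/usr/bin/env python
"""Stage 2: Spearman screening, correlated groups and landmark profiles.

Reads ``results/cohort.csv``; writes the full rank-correlation matrix, the
features ranked by association with fetal status, the highly correlated
feature groups and class-proportion profiles for ASTV and LB.
"""

from pathlib import Path

from ctg_interpret import feature_screen as fs
from ctg_interpret.ctg_data import read_ctg_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_ctg_table(RESULTS / "cohort.csv")
    corr = fs.spearman_matrix(ds)
    corr.rho.round(6).to_csv(RESULTS / "spearman_rho.csv")
    ranked = fs.nsp_correlations(corr)
    ranked.to_csv(RESULTS / "nsp_correlations.csv", index=False)

    groups = fs.correlated_groups(corr)
    with open(RESULTS / "correlated_groups.txt", "w") as fh:
        for i, g in enumerate(groups, 1):
            line = f"group {i}: {', '.join(g)}"
            fh.write(line + "\n")
            print(line)

    for feat in ("ASTV", "LB"):
        bp = fs.stacked_proportions(ds, feat, fs.LANDMARK_EDGES[feat])
        table = fs.proportions_table(bp)
        table.to_csv(RESULTS / f"profile_{feat}.csv", index=False)
        print(f"\n{feat} class-proportion profile:")
        print(table.to_string(index=False))

    print("\nfeatures most associated with fetal status:")
    print(ranked.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
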