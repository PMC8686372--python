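#!/usr/bin/env python
"""Stage 1: draw the study cohort and summarise the fetal-state mix.

Writes ``results/cohort.csv`` and ``results/class_summary.csv``.  All later
stages read the cohort file, so the whole analysis is reproducible from the
single seed below.
"""

from pathlib import Path

import pandas as pd

from ctg_interpret.ctg_data import class_counts, validate_records, write_ctg_table
from ctg_interpret.synthetic_ctg import SynthConfig, generate_dataset

SEED = 20260301
N = 2126  # size of the classical antepartum CTG reference table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = generate_dataset(SynthConfig(n=N, seed=SEED))
    report = validate_records(ds, level="warn")
    if report:
        raise SystemExit(f"generated cohort violates invariants: {report.counts}")
    write_ctg_table(ds, RESULTS / "cohort.csv")

    cc = class_counts(ds)
    rows = [{"class": name, "count": cc["counts"][code],
             "proportion": round(cc["proportions"][code], 4)}
            for code, name in [(1, "normal"), (2, "suspicious"), (3, "pathology")]]
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "class_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote {ds.n} records to {RESULTS / 'cohort.csv'}")


if __name__ == "__main__":
    main()
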