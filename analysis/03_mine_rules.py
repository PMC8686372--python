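#!/usr/bin/env python
"""Stage 3: class-guided discretization and association-rule mining.

Reads ``results/cohort.csv``; mines one forward-stepwise rule per fetal
state and writes the rules with their greedy traces.
"""

from pathlib import Path

import pandas as pd

from ctg_interpret import discretize_ara as da
from ctg_interpret.ctg_data import read_ctg_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
CLASS_NAMES = {1: "normal", 2: "suspicious", 3: "pathology"}


def main() -> None:
    ds = read_ctg_table(RESULTS / "cohort.csv")
    bins = da.fit_all_bins(ds, max_bins=8, min_frac=0.05)

    rows = []
    with open(RESULTS / "rules.txt", "w") as fh:
        for cls, name in CLASS_NAMES.items():
            rule, trace = da.forward_stepwise_rule(ds, bins, cls, min_support=5)
            text = da.rule_to_text(rule)
            fh.write(text + "\n")
            print(text)
            for step, (cond, supp, conf) in enumerate(trace.steps, 1):
                rows.append({"class": name, "step": step,
                             "condition": str(cond),
                             "support": round(supp, 4),
                             "confidence": round(conf, 4),
                             "stopping_reason": trace.stopping_reason})
    pd.DataFrame(rows).to_csv(RESULTS / "rule_traces.csv", index=False)


if __name__ == "__main__":
    main()
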