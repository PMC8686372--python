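#!/usr/bin/env python
"""Stage 4: latent-variable models of fetal status.

Reads ``results/cohort.csv``; fits the five-construct measurement model and
the structural model, then writes Wald tables with standardized solutions,
fit indices and the effect decomposition on NSP.
"""

import json
from pathlib import Path

import numpy as np

from ctg_interpret import sem_engine as se
from ctg_interpret.ctg_data import read_ctg_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_ctg_table(RESULTS / "cohort.csv")
    indices = {}
    for preset, builder in [("measurement", se.measurement_model),
                            ("structural", se.structural_model)]:
        model = builder()
        data = se.SEMData.from_frame(ds.frame, model.observed)
        fit = se.fit_ml(model, data)
        table = se.wald_statistics(fit)
        std = se.standardize_solution(fit)
        table["standardized"] = [std.get(p.split(":", 1)[1], np.nan)
                                 for p in table["parameter"]]
        table.to_csv(RESULTS / f"sem_{preset}.csv", index=False)
        indices[preset] = se.fit_indices(fit)
        print(f"{preset}: converged={fit.converged} F_ML={fit.fml:.4f} "
              f"chi2={indices[preset]['chi2']:.1f} df={indices[preset]['df']} "
              f"cfi={indices[preset]['cfi']:.3f} "
              f"rmsea={indices[preset]['rmsea']:.3f}")
        if preset == "structural":
            eff = se.effect_decomposition(fit, "NSP")
            eff.to_csv(RESULTS / "effects_on_nsp.csv", index=False)
            print("\nstandardized effects on fetal status (NSP):")
            print(eff.round(4).to_string(index=False))
    (RESULTS / "fit_indices.json").write_text(
        json.dumps(indices, indent=2, default=float) + "\n")


if __name__ == "__main__":
    main()
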