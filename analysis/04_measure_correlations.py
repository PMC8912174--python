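"""Correlation structure of body measures and shape PCs, per sex.

Height-normalises the 34 torso measures, z-scores them within sex, and
computes Pearson correlation matrices between measures and between
measures and the per-sex re-centred shape-PC scores.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_conditions import RESULTS

from torsoshape import anthro, synth


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort" / "truth.csv")
    scores = pd.read_csv(RESULTS / "pca_scores.csv").drop(
        columns="participant")
    raw = anthro.measure_table_from_frame(truth,
                                          tuple(synth.MEASURE_NAMES))
    normed = anthro.normalise_by_height(raw)
    sex = truth["sex"].to_numpy()

    girths = [m for m in synth.MEASURE_NAMES if m.endswith("_girth")]
    for code, label in ((1, "male"), (-1, "female")):
        mask = sex == code
        zm = anthro.zscore_columns(normed.measures.loc[mask])
        zpc = anthro.zscore_columns(scores.loc[mask])
        corr = anthro.correlation_analysis(
            zm, pd.concat([zm, zpc], axis=1))
        corr.to_csv(RESULTS / f"correlations_{label}.csv", index=False,
                    float_format="%.10g")
        gg = corr[(corr.var_a.isin(girths)) & (corr.var_b.isin(girths))
                  & (corr.var_a != corr.var_b)]
        gpc = corr[corr.var_b.str.startswith("PC")]
        strongest = gpc.loc[gpc.r.abs().idxmax()]
        print(f"{label}: girth-girth |r| median {gg.r.abs().median():.2f} "
              f"(IQR {gg.r.abs().quantile(0.75) - gg.r.abs().quantile(0.25):.2f}); "
              f"strongest measure-PC link {strongest.var_a} ~ "
              f"{strongest.var_b} (r = {strongest.r:.2f})")


if __name__ == "__main__":
    main()
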