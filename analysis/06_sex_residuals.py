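"""Is the measure-unexplained shape variation sexually dimorphic?

Pooled (both-sex) PLS models predict each shape PC from the z-scored
measures; the residuals are then regressed on the binary sex code
(females = -1, males = +1).  A significant slope marks the unexplained
variation within that PC as sex-related.  The postural-lean PC is also
characterised against the generator's ground truth.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_conditions import RESULTS, STUDY_SEED

from torsoshape import anthro, pipeline, regress, synth


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort" / "truth.csv")
    features = pd.read_csv(RESULTS / "features.csv").drop(
        columns="participant")
    scores = pd.read_csv(RESULTS / "pca_scores.csv").drop(
        columns="participant")
    raw = anthro.measure_table_from_frame(truth,
                                          tuple(synth.MEASURE_NAMES))
    Z = anthro.to_zscores(anthro.normalise_by_height(raw)).measures
    sex = truth["sex"].to_numpy()
    rng = np.random.default_rng(STUDY_SEED + 1)

    rows = []
    for pc in scores.columns:
        y = scores[pc].to_numpy()
        ncomp, _, _ = regress.select_ncomponents(
            Z, y, max_components=10, seed=int(rng.integers(2 ** 31 - 1)),
            stratify=sex)
        model = regress.fit_plsr(Z, y, ncomp, y_name=pc)
        resid = y - model.predict(Z.to_numpy())
        res = regress.residuals_on_sex(resid, sex, pc_name=pc)
        rows.append({"pc": pc, "pooled_R2": model.r2,
                     "residual_R2_on_sex": res.r2, "p": res.p,
                     "sex_related": res.sex_related})
        verdict = "sex-related" if res.sex_related else "not sex-related"
        print(f"{pc}: pooled R2 {model.r2:.3f}; residual-on-sex "
              f"R2 {res.r2:.4f}, p {res.p:.3g} -> {verdict}")
    pd.DataFrame(rows).to_csv(RESULTS / "sex_residuals.csv", index=False,
                              float_format="%.10g")

    lean = pipeline.lean_pc_analysis(truth, features.to_numpy(),
                                     seed=STUDY_SEED)
    print(f"\npostural-lean analogue: {lean['pc_name']} "
          f"(|corr with |lean|| = {abs(lean['lean_corr']):.2f}, "
          f"{100 * lean['variance_share']:.1f}% of shape variance) — "
          f"PLS R2 {lean['r2']:.3f}, sex-residual p {lean['sex_residual_p']:.2g}")


if __name__ == "__main__":
    main()
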