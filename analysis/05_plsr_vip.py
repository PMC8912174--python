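"""Per-sex PLS regressions of each shape PC on the 34 body measures.

Components are chosen per model by 10-fold cross-validated MSPE with the
one-standard-error rule.  Reports in-sample R^2 per PC, variable importance
in projection (VIP >= 0.8 flags), and the decomposition of total shape
variance into measure-explained and unexplained parts.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_conditions import RESULTS, STUDY_SEED

from torsoshape import anthro, regress, synth


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort" / "truth.csv")
    scores = pd.read_csv(RESULTS / "pca_scores.csv").drop(
        columns="participant")
    ratios = pd.read_csv(RESULTS / "pca_explained.csv")
    pc_names = list(ratios.pc)
    ratio_map = dict(zip(ratios.pc, ratios.explained_ratio))
    raw = anthro.measure_table_from_frame(truth,
                                          tuple(synth.MEASURE_NAMES))
    normed = anthro.normalise_by_height(raw)
    sex = truth["sex"].to_numpy()
    rng = np.random.default_rng(STUDY_SEED)

    summary, vip_rows, dec_frames = [], [], []
    for code, label in ((1, "male"), (-1, "female")):
        mask = sex == code
        Z = anthro.zscore_columns(normed.measures.loc[mask])
        r2_map = {}
        for pc in pc_names:
            y = scores.loc[mask, pc].to_numpy()
            y = (y - y.mean()) / y.std(ddof=1)
            ncomp, _, _ = regress.select_ncomponents(
                Z, y, max_components=10, seed=int(rng.integers(2 ** 31 - 1)))
            model = regress.fit_plsr(Z, y, ncomp, y_name=pc)
            vips = regress.vip(model)
            r2_map[pc] = model.r2
            summary.append({"sex": label, "pc": pc,
                            "n_components": ncomp, "R2": model.r2,
                            "pct_vip_above_0.8":
                                100.0 * float(np.mean(vips >= 0.8))})
            for name, v in zip(model.x_names, vips):
                vip_rows.append({"sex": label, "pc": pc, "measure": name,
                                 "vip": v, "important": bool(v >= 0.8)})
        dec = regress.variance_decomposition(r2_map, ratio_map)
        dec.insert(0, "sex", label)
        dec_frames.append(dec)
        total = dec[dec.pc == "total"].iloc[0]
        print(f"{label}: measures explain {total.explained_pct:.1f}% of "
              f"total shape variance; per-PC R2 = "
              + ", ".join(f"{pc} {r2_map[pc]:.2f}" for pc in pc_names))

    pd.DataFrame(summary).to_csv(RESULTS / "plsr_summary.csv", index=False,
                                 float_format="%.10g")
    pd.DataFrame(vip_rows).to_csv(RESULTS / "vip.csv", index=False,
                                  float_format="%.10g")
    pd.concat(dec_frames, ignore_index=True).to_csv(
        RESULTS / "variance_decomposition.csv", index=False,
        float_format="%.10g")


if __name__ == "__main__":
    main()
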