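"""Predicted torso shape change across the waist-girth range.

For each sex, the fitted per-PC PLS models are evaluated along the
sample's waist-girth range with stature held at 180 cm (male) / 160 cm
(female) and the remaining measures at their conditional expectation
given waist.  The predicted PC trajectories are also rendered as
reconstructed slice outlines at the smallest, median and largest waist.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_conditions import RESULTS, STUDY_SEED

from torsoshape import anthro, descriptors, regress, synth


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort" / "truth.csv")
    features = pd.read_csv(RESULTS / "features.csv").drop(
        columns="participant")
    raw = anthro.measure_table_from_frame(truth,
                                          tuple(synth.MEASURE_NAMES))
    normed = anthro.normalise_by_height(raw)
    sex = truth["sex"].to_numpy()
    pca = descriptors.fit_shape_pca(features.to_numpy())
    pc_names = [f"PC{i + 1}" for i in range(pca.n_retained)]
    rng = np.random.default_rng(STUDY_SEED + 2)

    outline_rows = []
    for code, label, fixed_h in ((1, "male", 180.0), (-1, "female", 160.0)):
        mask = sex == code
        Z = anthro.zscore_columns(normed.measures.loc[mask])
        models = {}
        for i, pc in enumerate(pc_names):
            y = pca.scores[mask, i]
            ncomp, _, _ = regress.select_ncomponents(
                Z, y, max_components=10, seed=int(rng.integers(2 ** 31 - 1)))
            models[pc] = regress.fit_plsr(Z, y, ncomp, y_name=pc)
        raw_waist = raw.measures.loc[mask, "waist_girth"].to_numpy()
        norm_waist = normed.measures.loc[mask, "waist_girth"].to_numpy()
        sweep = regress.waist_girth_sweep(
            models, Z, raw_waist, fixed_h,
            waist_norm_mean=float(norm_waist.mean()),
            waist_norm_sd=float(norm_waist.std(ddof=1)))
        sweep.to_csv(RESULTS / f"sweep_{label}.csv", index=False,
                     float_format="%.10g")
        span = sweep[pc_names].iloc[-1] - sweep[pc_names].iloc[0]
        print(f"{label}: waist {raw_waist.min():.0f}-{raw_waist.max():.0f} cm "
              f"at stature {fixed_h:.0f} cm; largest PC excursion "
              f"{span.abs().idxmax()} ({span.abs().max():.2f} score units)")

        # reconstructed outlines at the smallest / median / largest waist
        for which, idx in (("smallest", 0), ("median", len(sweep) // 2),
                           ("largest", len(sweep) - 1)):
            pc_point = sweep[pc_names].iloc[idx].to_numpy()
            # mean radius of a unit-centroid-size 25 x 70 configuration
            ref_radius = 1.0 / np.sqrt(25 * 70)
            outlines = descriptors.reconstruct_outlines(
                pca, pc_point, reference_radius=ref_radius)
            for s_idx, r in enumerate(outlines):
                outline_rows.append({"sex": label, "waist_case": which,
                                     "slice_index": s_idx,
                                     **{f"r{k:02d}": v
                                        for k, v in enumerate(r)}})
    pd.DataFrame(outline_rows).to_csv(
        RESULTS / "sweep_outlines.csv", index=False, float_format="%.6g")
    print(f"wrote sweep trajectories and reconstructed outlines to "
          f"{RESULTS}")


if __name__ == "__main__":
    main()
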