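"""Fit the torso shape PCA and test male/female differences.

Reads the feature matrix, fits a centred PCA keeping every component with
at least 1% explained variance, and reports which latent generator mode
each retained PC tracks.  Welch t-tests compare the sexes on every body
measure and every shape PC.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_conditions import RESULTS

from torsoshape import anthro, descriptors, synth


def main() -> None:
    features = pd.read_csv(RESULTS / "features.csv")
    truth = pd.read_csv(RESULTS / "cohort" / "truth.csv")
    X = features.drop(columns="participant").to_numpy()

    pca = descriptors.fit_shape_pca(X)
    pc_names = [f"PC{i + 1}" for i in range(pca.n_retained)]
    pd.DataFrame({"pc": pc_names,
                  "explained_ratio": pca.explained_ratio}).to_csv(
        RESULTS / "pca_explained.csv", index=False, float_format="%.10g")
    scores = pd.DataFrame(pca.scores, columns=pc_names)
    scores.insert(0, "participant", features["participant"])
    scores.to_csv(RESULTS / "pca_scores.csv", index=False,
                  float_format="%.10g")

    print(f"retained {pca.n_retained} shape PCs capturing "
          f"{100 * pca.explained_ratio.sum():.1f}% of descriptor variance")
    lat = truth[list(synth.LATENT_NAMES)].to_numpy()
    for i, pc in enumerate(pc_names):
        cors = [abs(np.corrcoef(pca.scores[:, i], np.abs(lat[:, j]))[0, 1])
                for j in range(5)]
        best = synth.LATENT_NAMES[int(np.argmax(cors))]
        print(f"  {pc}: {100 * pca.explained_ratio[i]:5.1f}% of variance, "
              f"tracks |{best}| (|r| = {max(cors):.2f})")

    sex = truth["sex"].to_numpy()
    both = pd.concat(
        [truth[list(synth.MEASURE_NAMES)], scores[pc_names]], axis=1)
    ttests = anthro.group_difference_tests(both, sex)
    ttests.to_csv(RESULTS / "ttests.csv", index=False, float_format="%.10g")
    n_sig = int(ttests.significant.sum())
    print(f"sex differences: {n_sig}/{len(ttests)} variables significant "
          "at alpha = 0.001")


if __name__ == "__main__":
    main()
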