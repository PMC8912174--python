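"""End-to-end torso-shape pipeline.

Chains the stages — synthetic cohort (or files on disk) -> landmarks ->
anatomical frame, crop, 25 slices, joint centroid-size scaling -> 250-value
spectral descriptor -> shape PCA -> measure normalisation, correlations and
sex difference tests -> pooled PLS + sex-residual analysis -> per-sex PLS
models with CV component selection and VIP -> variance decomposition and the
waist-girth sweep — and writes every result table as CSV.

All randomness flows from ``PipelineConfig.seed``; rerunning an identical
config writes byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, anthro, descriptors, landmarks, regress, synth

CSV_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (defaults follow the protocol)."""

    cohort: synth.CohortSpec | None = None   # synthetic mode
    clouds_dir: str | None = None            # real-data mode
    measures_csv: str | None = None
    landmarks_csv: str | None = None
    n_slices: int = 25
    band_height_mm: float = 2.0
    n_angles: int = 70
    harmonics_kept: int = 10
    pca_min_ratio: float = 0.01
    cv_folds: int = 10
    max_components: int = 10
    force_n_components: int | None = None    # e.g. a global 6
    alpha: float = 0.001
    vip_threshold: float = 0.8
    sweep_height_male_cm: float = 180.0
    sweep_height_female_cm: float = 160.0
    xiphoid_fraction: float = 0.60
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        if self.cohort is None:
            for name in ("clouds_dir", "measures_csv", "landmarks_csv"):
                val = getattr(self, name)
                if val is None:
                    raise ValueError(f"real-data mode requires {name}")
                if not Path(val).exists():
                    raise ValueError(f"{name} path does not exist: {val}")
        for name in ("n_slices", "n_angles", "harmonics_kept", "cv_folds",
                     "max_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def feature_column_names(n_slices: int = 25, keep: int = 10) -> list[str]:
    return [f"s{s:02d}_h{h:02d}" for s in range(n_slices)
            for h in range(1, keep + 1)]


def process_cloud(cloud: np.ndarray, buttock_height: float,
                  neck_height: float, config: PipelineConfig
                  ) -> tuple[np.ndarray, landmarks.LandmarkSet,
                             align.TorsoSlices]:
    """Raw cloud -> landmarks -> frame -> scaled slices -> 250-vector."""
    lms = landmarks.detect_landmarks(cloud, buttock_height, neck_height,
                                     fraction=config.xiphoid_fraction,
                                     half_width=config.band_height_mm / 2.0)
    frame = align.build_frame(lms.L1, lms.L2)
    in_frame = align.transform_to_frame(cloud, frame)
    lower = lms.buttock_height - frame.origin[2]
    upper = lms.xiphoid_height - frame.origin[2]
    cropped = align.crop_torso(in_frame, lower, upper)
    slices = align.extract_slices(cropped, lower, upper,
                                  n_slices=config.n_slices,
                                  band_height=config.band_height_mm)
    scaled = align.scale_slices(slices, reference=1.0, cs_source="resampled")
    features = descriptors.feature_vector_from_slices(
        scaled, n_angles=config.n_angles, keep=config.harmonics_kept)
    return features, lms, scaled


def _load_real_cohort(config: PipelineConfig):
    from . import io as tio

    meas = pd.read_csv(config.measures_csv)
    lmk = pd.read_csv(config.landmarks_csv).set_index("participant")
    clouds, heights = {}, {}
    for pid in meas["participant"]:
        matches = sorted(Path(config.clouds_dir).glob(f"{pid}.*"))
        if not matches:
            raise FileNotFoundError(f"no cloud file for participant {pid}")
        clouds[pid] = tio.read_point_cloud(matches[0])
        heights[pid] = (float(lmk.loc[pid, "buttock_height_mm"]),
                        float(lmk.loc[pid, "neck_height_mm"]))
    return meas, clouds, heights


def lean_pc_analysis(truth: pd.DataFrame, features: np.ndarray,
                     min_ratio: float = 0.01, max_components: int = 8,
                     cv_folds: int = 10, alpha: float = 0.001,
                     seed: int = 0) -> dict:
    """Identify and characterise the postural-lean shape PC.

    Fits the shape PCA, picks the retained PC whose scores correlate most
    strongly with |lean| (the amplitude descriptor discards the lean's
    sign), regresses it on the z-scored body measures by PLS with CV
    component selection, and regresses the residuals on sex.  Returns the
    PC index, its |lean| correlation, variance share, PLS R^2 and the
    sex-residual R^2 / p-value.
    """
    pca = descriptors.fit_shape_pca(features, min_ratio=min_ratio)
    lean = np.abs(truth["lean"].to_numpy(dtype=float))
    sex = truth["sex"].to_numpy()
    cors = [np.corrcoef(pca.scores[:, i], lean)[0, 1]
            for i in range(pca.n_retained)]
    idx = int(np.argmax(np.abs(cors)))
    y = pca.scores[:, idx]
    raw = anthro.measure_table_from_frame(truth,
                                          tuple(synth.MEASURE_NAMES))
    Z = anthro.to_zscores(anthro.normalise_by_height(raw)).measures
    ncomp, _, _ = regress.select_ncomponents(Z, y, max_components,
                                             folds=cv_folds, seed=seed,
                                             stratify=sex)
    model = regress.fit_plsr(Z, y, ncomp)
    resid = y - model.predict(Z.to_numpy())
    sr = regress.residuals_on_sex(resid, sex, alpha=alpha)
    return {"pc_index": idx, "pc_name": f"PC{idx + 1}",
            "lean_corr": float(cors[idx]),
            "variance_share": float(pca.explained_ratio[idx]),
            "n_components": int(ncomp), "r2": float(model.r2),
            "sex_residual_r2": sr.r2, "sex_residual_p": sr.p}


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run computed (also written as CSV)."""

    features: pd.DataFrame
    pca: descriptors.ShapePCModel
    pc_scores: pd.DataFrame
    measures_raw: anthro.MeasureTable
    ttests: pd.DataFrame
    correlations: dict[int, pd.DataFrame]
    sex_residuals: pd.DataFrame
    plsr_summary: pd.DataFrame
    vip_table: pd.DataFrame
    variance_decomposition: pd.DataFrame
    sweeps: dict[int, pd.DataFrame]
    sex_models: dict[int, dict[str, regress.PLSRModel]]
    truth: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.cohort is not None:
        samples = synth.generate_cohort(config.cohort)
        truth = synth.cohort_truth_table(samples)
        meas_df = truth[["participant", "sex", "height_cm", "weight_kg"]
                        + list(synth.MEASURE_NAMES)].copy()
        clouds = {int(r.participant): samples[i].cloud
                  for i, r in enumerate(truth.itertuples())}
        heights = {int(r.participant):
                   (samples[i].buttock_height, samples[i].neck_height)
                   for i, r in enumerate(truth.itertuples())}
    else:
        meas_df, clouds, heights = _load_real_cohort(config)

    # --- per-participant descriptors -----------------------------------
    fcols = feature_column_names(config.n_slices, config.harmonics_kept)
    feats = np.empty((len(meas_df), len(fcols)))
    for i, pid in enumerate(meas_df["participant"]):
        cloud = clouds[pid]
        buttock, neck = heights[pid]
        try:
            feats[i], _, _ = process_cloud(cloud, buttock, neck, config)
        except ValueError as exc:
            raise RuntimeError(
                f"participant {pid}: descriptor stage failed: {exc}") from exc
    features = pd.DataFrame(feats, columns=fcols)
    features.insert(0, "participant", meas_df["participant"].to_numpy())

    # --- shape PCA ------------------------------------------------------
    pca = descriptors.fit_shape_pca(feats, min_ratio=config.pca_min_ratio)
    pc_names = [f"PC{i + 1}" for i in range(pca.n_retained)]
    pc_scores = pd.DataFrame(pca.scores, columns=pc_names)
    sex = meas_df["sex"].to_numpy()

    # --- measure normalisation -----------------------------------------
    raw = anthro.measure_table_from_frame(
        meas_df, measure_columns=tuple(synth.MEASURE_NAMES)
        if config.cohort is not None else None)
    normed = anthro.normalise_by_height(raw)
    z_pooled = anthro.to_zscores(normed)
    Zp = z_pooled.measures

    # --- sex differences and per-sex correlations ----------------------
    both = pd.concat([raw.measures, pc_scores], axis=1)
    ttests = anthro.group_difference_tests(both, sex, alpha=config.alpha)
    correlations = {}
    for s in (1, -1):
        mask = sex == s
        zm = anthro.zscore_columns(normed.measures.loc[mask])
        zpc = anthro.zscore_columns(pc_scores.loc[mask])
        corr = anthro.correlation_analysis(zm, pd.concat([zm, zpc], axis=1),
                                           alpha=config.alpha)
        correlations[s] = corr

    # --- pooled preliminary PLS; residuals on sex -----------------------
    rng = np.random.default_rng(config.seed)
    resid_rows = []
    for pc in pc_names:
        y = pc_scores[pc].to_numpy()
        ncomp = config.force_n_components
        if ncomp is None:
            ncomp, _, _ = regress.select_ncomponents(
                Zp, y, config.max_components,
                folds=min(config.cv_folds, len(y)),
                seed=int(rng.integers(2 ** 31 - 1)), stratify=sex)
        model = regress.fit_plsr(Zp, y, ncomp, y_name=pc)
        resid = y - model.predict(Zp.to_numpy())
        res = regress.residuals_on_sex(resid, sex, alpha=config.alpha,
                                       pc_name=pc)
        resid_rows.append({"pc": pc, "pooled_n_components": ncomp,
                           "pooled_R2": model.r2, "residual_R2_on_sex": res.r2,
                           "p": res.p, "sex_related": res.sex_related})
    sex_residuals = pd.DataFrame(resid_rows)

    # --- per-sex PLS models, VIP, decomposition, sweep ------------------
    plsr_rows, vip_rows = [], []
    sweeps, sex_models = {}, {}
    decomp_frames = []
    pc_ratio_map = {pc: float(pca.explained_ratio[i])
                    for i, pc in enumerate(pc_names)}
    for s, label, fixed_h in ((1, "male", config.sweep_height_male_cm),
                              (-1, "female", config.sweep_height_female_cm)):
        mask = sex == s
        norm_s = normed.measures.loc[mask].reset_index(drop=True)
        Zs = anthro.zscore_columns(norm_s)
        models = {}
        r2_map = {}
        for pc in pc_names:
            y = pc_scores.loc[mask, pc].to_numpy()
            y = (y - y.mean()) / y.std(ddof=1)   # per-sex re-centred z-scores
            ncomp = config.force_n_components
            curve = se = None
            if ncomp is None:
                ncomp, curve, se = regress.select_ncomponents(
                    Zs, y, config.max_components,
                    folds=min(config.cv_folds, len(y)),
                    seed=int(rng.integers(2 ** 31 - 1)))
            model = regress.fit_plsr(Zs, y, ncomp, y_name=pc)
            model = dataclasses.replace(model, mspe_curve=curve, mspe_se=se)
            models[pc] = model
            r2_map[pc] = model.r2
            vips = regress.vip(model)
            plsr_rows.append({"sex": label, "pc": pc,
                              "n_components": model.n_components,
                              "R2": model.r2,
                              "n_vip_above_threshold":
                                  int(np.sum(vips >= config.vip_threshold))})
            for name, v in zip(model.x_names, vips):
                vip_rows.append({"sex": label, "pc": pc, "measure": name,
                                 "vip": v,
                                 "important": bool(v >= config.vip_threshold)})
        sex_models[s] = models
        dec = regress.variance_decomposition(r2_map, pc_ratio_map)
        dec.insert(0, "sex", label)
        decomp_frames.append(dec)

        raw_waist = raw.measures.loc[mask, "waist_girth"].to_numpy()
        norm_waist = norm_s["waist_girth"].to_numpy()
        sweeps[s] = regress.waist_girth_sweep(
            models, Zs, raw_waist, fixed_h,
            waist_norm_mean=float(norm_waist.mean()),
            waist_norm_sd=float(norm_waist.std(ddof=1)))

    plsr_summary = pd.DataFrame(plsr_rows)
    vip_table = pd.DataFrame(vip_rows)
    decomposition = pd.concat(decomp_frames, ignore_index=True)

    result = PipelineResult(
        features=features, pca=pca, pc_scores=pc_scores, measures_raw=raw,
        ttests=ttests, correlations=correlations, sex_residuals=sex_residuals,
        plsr_summary=plsr_summary, vip_table=vip_table,
        variance_decomposition=decomposition, sweeps=sweeps,
        sex_models=sex_models, truth=truth)
    _write_outputs(result, config, outdir, pc_names)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   outdir: Path, pc_names: list[str]) -> None:
    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, index=False, float_format=CSV_FLOAT_FORMAT)

    if result.truth is not None:
        save(result.truth, "truth.csv")
    save(result.features, "features.csv")
    ratios = pd.DataFrame({
        "pc": pc_names,
        "explained_ratio": result.pca.explained_ratio,
    })
    save(ratios, "pca_explained.csv")
    save(result.pc_scores, "pca_scores.csv")
    save(result.ttests, "ttests.csv")
    save(result.correlations[1], "correlations_male.csv")
    save(result.correlations[-1], "correlations_female.csv")
    save(result.sex_residuals, "sex_residuals.csv")
    save(result.plsr_summary, "plsr_summary.csv")
    save(result.vip_table, "vip.csv")
    save(result.variance_decomposition, "variance_decomposition.csv")
    save(result.sweeps[1], "sweep_male.csv")
    save(result.sweeps[-1], "sweep_female.csv")
    with open(outdir / "run_log.txt", "w") as fh:
        import scipy
        import sklearn

        fh.write("torsoshape pipeline run\n")
        fh.write(f"seed = {config.seed}\n")
        fh.write(f"numpy = {np.__version__}, scipy = {scipy.__version__}, "
                 f"pandas = {pd.__version__}, sklearn = {sklearn.__version__}\n")
        for key, val in dataclasses.asdict(config).items():
            fh.write(f"config.{key} = {val!r}\n")
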