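"""End-to-end pipeline orchestration, MDS embedding, and figure rendering.

``run_pipeline`` executes the full workflow from one config:

    generate stimuli -> train the adversarial autoencoder (plus requested
    ablations) -> layer RDMs -> synthesize MEG/fMRI with planted
    geometries -> decoding / correlation RDMs -> Spearman RSA ->
    cluster + bootstrap statistics -> figures + machine-readable summary.

The summary JSON records trend directions (encoder/decoder peak-latency
hierarchies, ROI profile trends), reconstruction errors, latent moments
and every seed; rerunning the same config reproduces it bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aae, rdm as rdm_mod, rsa, stats as stats_mod, synthetic

__all__ = [
    "GeometrySpec",
    "PipelineConfig",
    "MDSEmbedding",
    "mds_embed",
    "run_pipeline",
    "render_figures",
    "demo_config",
    "recovery_config",
]

ENCODER_DEPTH = ["E1", "E2", "E3", "E4", "E5", "E6"]
DECODER_DEPTH = ["D1", "D2", "D3", "D4", "D5", "D6"]
CORRESPONDING_PAIRS = list(zip(ENCODER_DEPTH, DECODER_DEPTH[::-1]))


@dataclass
class GeometrySpec:
    """Where a planted geometry's target RDM comes from, and its timing.

    ``source`` is one of ``layer:<id>`` (a model layer RDM), ``pixel``
    (stimulus pixel-space RDM) or ``categorical`` (block RDM).
    """

    source: str
    latency_ms: float
    width_ms: float = 50.0
    amplitude: float = 1.0
    rescale: bool = False  # map dissimilarities onto a common range


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "pipeline_out"
    # stimuli (condition set, not used for training)
    n_per_category: int = 39
    image_size: int = 64
    # which images define the experimental conditions: the category set
    # ("categories") or spectrally rich probe images ("probes", which
    # differentiate layer geometries much more strongly)
    condition_set: str = "categories"
    # training / evaluation image sets
    train_n_per_category: int = 39
    test_n_per_category: int = 10
    # model
    model: aae.AAEConfig = field(default_factory=aae.AAEConfig)
    ablations: tuple[str, ...] = ("plain_ae", "untrained")
    # MEG synthesis
    meg_geometries: list[GeometrySpec] = field(default_factory=list)
    n_subjects: int = 15
    n_trials: int = 25
    n_sensors: int = 306
    meg_noise_sd: float = 1.0
    # fMRI synthesis
    fmri_n_voxels: int = 300
    fmri_noise_sd: float = 1.0
    categorical_within: float = 0.3
    # decoding
    decoding: rdm_mod.DecodingConfig = field(
        default_factory=rdm_mod.DecodingConfig)
    stride_ms: float = 1.0
    decode_tmin_ms: float | None = None
    decode_tmax_ms: float | None = None
    # statistics
    cluster_def_p: float = 0.01
    cluster_sig_p: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    peak_window_ms: tuple[float, float] = (0.0, 1000.0)
    peak_min_prominence: float | None = None
    ceiling_bound: str = "lower"
    render: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(open(path))
        if "model" in raw:
            raw["model"] = aae.AAEConfig(**{
                **raw["model"],
                "channels_per_block": tuple(
                    raw["model"].get("channels_per_block",
                                     aae.AAEConfig().channels_per_block)),
            })
        if "decoding" in raw:
            raw["decoding"] = rdm_mod.DecodingConfig(**raw["decoding"])
        raw["meg_geometries"] = [GeometrySpec(**g)
                                 for g in raw.get("meg_geometries", [])]
        if "ablations" in raw:
            raw["ablations"] = tuple(raw["ablations"])
        if "peak_window_ms" in raw:
            raw["peak_window_ms"] = tuple(raw["peak_window_ms"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray  # condition x dims
    stress: float


def mds_embed(rdm: rdm_mod.RDM, dims: int = 2, seed: int = 0) -> MDSEmbedding:
    """Metric (SMACOF) MDS of a dissimilarity matrix, seeded."""
    from sklearn.manifold import MDS

    if dims < 1:
        raise ValueError("dims must be >= 1")
    vals = rdm.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("RDM contains non-finite entries")
    try:  # scikit-learn >= 1.9 spelling
        mds = MDS(n_components=dims, metric="precomputed", metric_mds=True,
                  n_init=4, init="random", random_state=seed,
                  normalized_stress=False)
        coords = mds.fit_transform(vals)
    except TypeError:
        mds = MDS(n_components=dims, dissimilarity="precomputed", metric=True,
                  n_init=4, random_state=seed, normalized_stress=False)
        coords = mds.fit_transform(vals)
    return MDSEmbedding(coordinates=coords, stress=float(mds.stress_))


def demo_config(seed: int = 0, output_dir: str = "demo_out") -> PipelineConfig:
    """Small single-CPU configuration exercising every pipeline stage."""
    model = aae.AAEConfig(image_size=32, channels_per_block=(8, 12, 16, 24, 32),
                          latent_dim=16, epochs=8, batch_size=32, seed=seed)
    return PipelineConfig(
        seed=seed, output_dir=output_dir,
        n_per_category=3, image_size=32,
        train_n_per_category=16, test_n_per_category=8,
        model=model, ablations=("untrained",),
        meg_geometries=[
            GeometrySpec(source="layer:E1", latency_ms=120.0, width_ms=40.0,
                         amplitude=0.7),
            GeometrySpec(source="layer:E6", latency_ms=300.0, width_ms=40.0,
                         amplitude=0.7),
        ],
        n_subjects=4, n_trials=16, n_sensors=48, meg_noise_sd=1.0,
        fmri_n_voxels=60, fmri_noise_sd=0.6,
        decoding=rdm_mod.DecodingConfig(n_bins=8, n_assignment_repeats=1),
        stride_ms=40.0, decode_tmin_ms=-80.0, decode_tmax_ms=480.0,
        n_perm=300, n_boot=200, peak_window_ms=(0.0, 480.0),
        peak_min_prominence=0.2,
    )


def recovery_config(seed: int = 0, output_dir: str = "recovery_out"
                    ) -> PipelineConfig:
    """Parameter-recovery configuration: encoder-layer geometries planted
    at increasing latencies on probe conditions, so the recovered
    peak-latency hierarchy can be compared with the planted one."""
    model = aae.AAEConfig(image_size=32, channels_per_block=(8, 12, 16, 24, 32),
                          latent_dim=16, epochs=250, batch_size=32, seed=seed)
    lats = [100.0, 160.0, 220.0, 280.0, 340.0, 400.0]
    return PipelineConfig(
        seed=seed, output_dir=output_dir,
        n_per_category=4, image_size=32, condition_set="probes",
        train_n_per_category=24, test_n_per_category=8,
        model=model, ablations=("untrained",),
        meg_geometries=[
            GeometrySpec(source=f"layer:E{k + 1}", latency_ms=lat,
                         width_ms=30.0, amplitude=0.08, rescale=True)
            for k, lat in enumerate(lats)],
        n_subjects=6, n_trials=24, n_sensors=64, meg_noise_sd=1.0,
        fmri_n_voxels=100, fmri_noise_sd=0.5,
        decoding=rdm_mod.DecodingConfig(n_bins=8, n_assignment_repeats=2),
        stride_ms=10.0, decode_tmin_ms=50.0, decode_tmax_ms=470.0,
        n_perm=500, n_boot=500, peak_window_ms=(50.0, 470.0),
        peak_min_prominence=0.2,
    )


# ---------------------------------------------------------------------------
# pipeline

def _resolve_geometry(spec: GeometrySpec, layer_rdms: dict[str, rdm_mod.RDM],
                      stimuli: synthetic.ImageSet,
                      categorical_within: float) -> synthetic.PlantedGeometry:
    if spec.source.startswith("layer:"):
        lid = spec.source.split(":", 1)[1]
        target = layer_rdms[lid].values
    elif spec.source == "pixel":
        target = rdm_mod.correlation_rdm(
            stimuli.images.reshape(len(stimuli), -1)).values
    elif spec.source == "categorical":
        target = synthetic.categorical_block_rdm(
            len(stimuli), within=categorical_within)
    else:
        raise ValueError(f"unknown geometry source {spec.source!r}")
    if spec.rescale:
        target = synthetic.rescale_rdm(target)
    return synthetic.PlantedGeometry(rdm_target=target,
                                     latency_ms=spec.latency_ms,
                                     width_ms=spec.width_ms,
                                     amplitude=spec.amplitude,
                                     name=spec.source)


def _stage(tag):
    """Decorator-free stage wrapper: re-raise with a stage tag."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{tag}' failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory bundle and writes outputs."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = (np.random.SeedSequence(config.seed).generate_state(10)
             & 0x7FFFFFFF).tolist()
    bundle: dict = {"config": config, "seeds": seeds}

    with _stage("generate_images"):
        if config.condition_set == "categories":
            stimuli = synthetic.generate_image_dataset(
                config.n_per_category, config.image_size, seed=seeds[0])
        elif config.condition_set == "probes":
            stimuli = synthetic.generate_probe_images(
                4 * config.n_per_category, config.image_size, seed=seeds[0])
        else:
            raise ValueError(f"unknown condition_set {config.condition_set!r}")
        train_set = synthetic.generate_image_dataset(
            config.train_n_per_category, config.image_size, seed=seeds[1])
        test_set = synthetic.generate_image_dataset(
            config.test_n_per_category, config.image_size, seed=seeds[2])
        bundle["stimuli"] = stimuli

    with _stage("train"):
        models: dict[str, aae.AAEModel] = {}
        traces: dict[str, aae.TrainingTrace] = {}
        model = aae.build_model(config.model)
        traces["aae"] = aae.train(model, train_set, config.model)
        models["aae"] = model
        if "plain_ae" in config.ablations:
            plain = aae.make_plain_autoencoder(config.model)
            traces["plain_ae"] = aae.train(plain, train_set, config.model)
            models["plain_ae"] = plain
        if "untrained" in config.ablations:
            models["untrained"] = aae.make_untrained_model(config.model)
        bundle["models"], bundle["traces"] = models, traces

    with _stage("evaluate_reconstruction"):
        x_test = aae.images_to_nchw(test_set.images)
        recon_mae: dict[str, float] = {}
        for name, m in models.items():
            fx, _ = m.forward_generator(x_test, train=False)
            recon_mae[name] = aae.reconstruction_loss(x_test, fx, mode="mae")
        untrained_ref = models.get("untrained") or aae.make_untrained_model(
            config.model)
        fx, _ = untrained_ref.forward_generator(x_test, train=False)
        recon_mae.setdefault("untrained", aae.reconstruction_loss(
            x_test, fx, mode="mae"))
        lv = models["aae"].encode(aae.images_to_nchw(test_set.images),
                                  train=False)
        latent_moments = {"mean": float(lv.mean()), "sd": float(lv.std())}
        bundle["recon_mae"], bundle["latent_moments"] = recon_mae, latent_moments

    with _stage("model_rdms"):
        layer_rdms: dict[str, dict[str, rdm_mod.RDM]] = {}
        for name, m in models.items():
            acts = aae.extract_activations(m, stimuli)
            rdms = rdm_mod.model_layer_rdms(acts)
            layer_rdms[name] = {r.source.removeprefix("layer:"): r for r in rdms}
        bundle["layer_rdms"] = layer_rdms
        bundle["layer_similarity"] = rsa.layer_similarity_matrix(
            list(layer_rdms["aae"].values()))

    with _stage("generate_meg"):
        geometries = [_resolve_geometry(g, layer_rdms["aae"], stimuli,
                                        config.categorical_within)
                      for g in config.meg_geometries]
        recording = synthetic.generate_meg_recording(
            geometries, n_subjects=config.n_subjects,
            n_trials=config.n_trials, n_sensors=config.n_sensors,
            noise_sd=config.meg_noise_sd, seed=seeds[3])
        bundle["geometries"] = geometries

    with _stage("decode_meg"):
        preprocessed = rdm_mod.preprocess_meg(recording)
        dec_cfg = rdm_mod.DecodingConfig(
            n_bins=config.decoding.n_bins, svm_c=config.decoding.svm_c,
            n_assignment_repeats=config.decoding.n_assignment_repeats,
            seed=seeds[4])
        trrdms = rdm_mod.time_resolved_rdms(
            preprocessed, dec_cfg, stride_ms=config.stride_ms,
            tmin_ms=config.decode_tmin_ms, tmax_ms=config.decode_tmax_ms)
        bundle["time_resolved_rdms"] = trrdms

    with _stage("generate_fmri"):
        evc_geom = _resolve_geometry(
            GeometrySpec(source="pixel", latency_ms=100.0),
            layer_rdms["aae"], stimuli, config.categorical_within)
        it_geom = _resolve_geometry(
            GeometrySpec(source="categorical", latency_ms=100.0),
            layer_rdms["aae"], stimuli, config.categorical_within)
        roi_rdms: dict[str, list[rdm_mod.RDM]] = {}
        for roi, geom, sd_seed in (("EVC", evc_geom, seeds[5]),
                                   ("IT", it_geom, seeds[6])):
            pats = synthetic.generate_fmri_patterns(
                geom, n_subjects=config.n_subjects,
                n_voxels=config.fmri_n_voxels,
                noise_sd=config.fmri_noise_sd, seed=sd_seed, roi_name=roi)
            roi_rdms[roi] = [
                rdm_mod.correlation_rdm(pats.data[s], source=f"{roi}:s{s}")
                for s in range(config.n_subjects)]
        bundle["roi_rdms"] = roi_rdms

    with _stage("compare"):
        model_rdm_list = [layer_rdms["aae"][lid] for lid in aae.LAYER_IDS]
        series = rsa.layer_time_correlation(model_rdm_list, trrdms)
        profiles: dict[str, rsa.ROICorrelationProfile] = {}
        for roi, rdms_ in roi_rdms.items():
            prof = rsa.roi_correlation_profile(model_rdm_list, rdms_,
                                               roi_name=roi)
            if prof.ceiling is not None and prof.ceiling[0] > 0:
                prof = rsa.normalize_by_ceiling(prof, bound=config.ceiling_bound)
            profiles[roi] = prof
        series_by_model = {"aae": series}
        for name in models:
            if name == "aae":
                continue
            alt_list = [layer_rdms[name][lid] for lid in aae.LAYER_IDS]
            series_by_model[name] = rsa.layer_time_correlation(alt_list, trrdms)
        bundle["series"], bundle["profiles"] = series, profiles
        bundle["series_by_model"] = series_by_model

    with _stage("stats"):
        clusters = stats_mod.cluster_permutation_test(
            series, cluster_def_p=config.cluster_def_p,
            cluster_sig_p=config.cluster_sig_p, n_perm=config.n_perm,
            seed=seeds[7])
        peaks = stats_mod.bootstrap_peak_latency(
            series, n_boot=config.n_boot, seed=seeds[8],
            window_ms=config.peak_window_ms,
            min_prominence=config.peak_min_prominence)
        enc_lat = [peaks.latency(l) for l in ENCODER_DEPTH]
        dec_lat = [peaks.latency(l) for l in DECODER_DEPTH]
        enc_rho, enc_p = _safe_hierarchy(enc_lat)
        dec_rho, dec_p = _safe_hierarchy(dec_lat)
        evc_rho = _profile_trend(profiles["EVC"])
        it_rho = _profile_trend(profiles["IT"])
        enc_prof = {roi: p.values[:, [p.layer_ids.index(l)
                                      for l in ENCODER_DEPTH]]
                    for roi, p in profiles.items()}
        dec_prof = {roi: p.values[:, [p.layer_ids.index(l)
                                      for l in DECODER_DEPTH[::-1]]]
                    for roi, p in profiles.items()}
        paired = {roi: stats_mod.paired_layer_tests(
            enc_prof[roi], dec_prof[roi],
            labels=[f"{e}-{d}" for e, d in CORRESPONDING_PAIRS])
            for roi in profiles}
        bundle.update(clusters=clusters, peaks=peaks, paired_tests=paired)

    with _stage("summarize"):
        lv_idx = series.layer_ids.index("LV")
        lv_max = {name: float(s.subject_mean[lv_idx].max())
                  for name, s in series_by_model.items()}
        summary = {
            "seeds": seeds,
            "n_conditions": len(stimuli),
            "recon_mae": {k: round(v, 10) for k, v in recon_mae.items()},
            "latent_moments": {k: round(v, 10)
                               for k, v in latent_moments.items()},
            "encoder_hierarchy": {
                "latencies_ms": enc_lat, "spearman": _r(enc_rho),
                "p": _r(enc_p),
                "direction": _direction(enc_rho)},
            "decoder_hierarchy": {
                "latencies_ms": dec_lat, "spearman": _r(dec_rho),
                "p": _r(dec_p),
                "direction": _direction(dec_rho)},
            "evc_profile_trend": {"spearman_vs_encoder_depth": _r(evc_rho),
                                  "direction": _direction(evc_rho)},
            "it_profile_trend": {"spearman_vs_encoder_depth": _r(it_rho),
                                 "direction": _direction(it_rho)},
            "noise_ceilings": {roi: list(map(_r, p.ceiling))
                               for roi, p in profiles.items()
                               if p.ceiling is not None},
            "lv_series_max_by_model": {k: _r(v) for k, v in lv_max.items()},
            "n_significant_clusters": {
                lid: len(clusters.significant(lid))
                for lid in series.layer_ids},
        }
        bundle["summary"] = summary
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_tables(bundle, out_dir)

    if config.render:
        with _stage("render"):
            render_figures(bundle, out_dir)
    return bundle


def _r(x) -> float:
    return None if x is None or not np.isfinite(x) else round(float(x), 10)


def _direction(rho: float) -> str:
    if rho is None or not np.isfinite(rho):
        return "undefined"
    if rho > 0:
        return "increasing"
    if rho < 0:
        return "decreasing"
    return "flat"


def _safe_hierarchy(latencies) -> tuple[float, float]:
    lat = np.asarray(latencies, dtype=np.float64)
    if np.any(np.isnan(lat)):
        return np.nan, np.nan
    return stats_mod.hierarchy_correlation(lat)


def _profile_trend(profile: rsa.ROICorrelationProfile) -> float:
    from scipy.stats import spearmanr

    means = [profile.subject_mean[profile.layer_ids.index(l)]
             for l in ENCODER_DEPTH]
    return float(spearmanr(np.arange(len(means)), means).statistic)


def _write_tables(bundle: dict, out_dir: Path) -> None:
    """Tidy CSVs mirroring every figure's underlying numbers."""
    series: rsa.CorrelationSeries = bundle["series"]
    rows = []
    for s in range(series.n_subjects):
        for li, lid in enumerate(series.layer_ids):
            for ti, t in enumerate(series.time_ms):
                rows.append((s, lid, float(t), series.values[s, li, ti]))
    pd.DataFrame(rows, columns=["subject", "layer", "time_ms", "spearman"]
                 ).to_csv(out_dir / "correlation_series.csv", index=False)
    prows = []
    for roi, prof in bundle["profiles"].items():
        for s in range(prof.values.shape[0]):
            for li, lid in enumerate(prof.layer_ids):
                prows.append((roi, s, lid, prof.values[s, li],
                              prof.normalized))
    pd.DataFrame(prows, columns=["roi", "subject", "layer", "spearman",
                                 "normalized"]
                 ).to_csv(out_dir / "roi_profiles.csv", index=False)
    peaks: stats_mod.PeakLatencyResult = bundle["peaks"]
    pd.DataFrame({
        "layer": peaks.layer_ids,
        "peak_ms": peaks.estimate_ms,
        "ci_low_ms": peaks.ci_low_ms,
        "ci_high_ms": peaks.ci_high_ms,
        "n_dropped": peaks.n_dropped,
    }).to_csv(out_dir / "peak_latencies.csv", index=False)
    for name, trace in bundle.get("traces", {}).items():
        df = pd.DataFrame({"epoch": np.arange(len(trace)),
                           "reconstruction_loss": trace.reconstruction_loss})
        if trace.discriminator_loss:
            df["discriminator_loss"] = trace.discriminator_loss
            df["generator_loss"] = trace.generator_loss
        df.to_csv(out_dir / f"training_trace_{name}.csv", index=False)
    np.savetxt(out_dir / "layer_similarity.csv",
               bundle["layer_similarity"].values, delimiter=",",
               header=",".join(bundle["layer_similarity"].layer_ids),
               comments="")
    clusters = bundle["clusters"]
    stats_doc = {
        "clusters": {
            lid: [{"start_ms": float(c.start_ms), "end_ms": float(c.end_ms),
                   "size": int(c.size), "p_value": float(c.p_value)}
                  for c in cl]
            for lid, cl in clusters.clusters.items()},
        "cluster_thresholds": {"definition_p": clusters.cluster_def_p,
                               "significance_p": clusters.cluster_sig_p,
                               "n_permutations": clusters.n_permutations},
        "peak_latencies": {
            lid: {"estimate_ms": _r(peaks.estimate_ms[i]),
                  "ci_ms": [_r(peaks.ci_low_ms[i]), _r(peaks.ci_high_ms[i])],
                  "n_dropped": int(peaks.n_dropped[i])}
            for i, lid in enumerate(peaks.layer_ids)},
        "paired_layer_tests": {
            roi: {lab: {"t": _r(res.statistic[i]),
                        "p_raw": _r(res.p_raw[i]),
                        "p_fdr": _r(res.p_adjusted[i]),
                        "significant": bool(res.significant[i])}
                  for i, lab in enumerate(res.labels)}
            for roi, res in bundle["paired_tests"].items()},
    }
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(stats_doc, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# figures

def render_figures(bundle: dict, out_dir) -> list[Path]:
    """RDM heatmaps, MDS scatters, correlation traces with significance
    bars, and peak-latency panels.  Every figure's numbers are also in the
    CSVs written by the pipeline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    missing = [k for k in ("series", "profiles", "layer_rdms", "peaks",
                           "clusters") if k not in bundle]
    if missing:
        raise ValueError(f"bundle missing inputs: {missing}")

    layer_rdms = bundle["layer_rdms"]["aae"]
    stimuli: synthetic.ImageSet = bundle["stimuli"]
    seeds = bundle["seeds"]

    # RDM heatmaps
    fig, axes = plt.subplots(1, min(4, len(layer_rdms)), figsize=(12, 3.2))
    show = ["E1", "E6", "LV", "D6"][:len(layer_rdms)]
    for ax, lid in zip(np.atleast_1d(axes), show):
        vals = layer_rdms[lid].values
        im = ax.imshow(vals, cmap="viridis", vmin=vals.min(), vmax=vals.max())
        ax.set_title(lid)
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.suptitle("Model layer RDMs (1 - Pearson)")
    p = out_dir / "rdm_heatmaps.png"
    fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
    written.append(p)

    # MDS of ROI mean RDMs, colored by category
    roi_rdms = bundle.get("roi_rdms", {})
    if roi_rdms:
        fig, axes = plt.subplots(1, len(roi_rdms), figsize=(5 * len(roi_rdms), 4))
        for ax, (roi, rdms_) in zip(np.atleast_1d(axes), roi_rdms.items()):
            emb = mds_embed(rsa.mean_rdm(rdms_), dims=2, seed=int(seeds[9]))
            for cat in range(4):
                sel = stimuli.labels == cat
                ax.scatter(emb.coordinates[sel, 0], emb.coordinates[sel, 1],
                           label=stimuli.category_names[cat], s=18)
            ax.set_title(f"{roi} (stress {emb.stress:.2f})")
            ax.legend(fontsize=7)
        p = out_dir / "mds_rois.png"
        fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
        written.append(p)

    # correlation traces with significance bars
    series: rsa.CorrelationSeries = bundle["series"]
    clusters: stats_mod.ClusterResult = bundle["clusters"]
    groups = [("encoder", ENCODER_DEPTH), ("decoder", DECODER_DEPTH),
              ("latent", ["LV"])]
    fig, axes = plt.subplots(1, 3, figsize=(15, 4), sharey=True)
    for ax, (gname, lids) in zip(axes, groups):
        base = series.subject_mean.min() - 0.02
        for k, lid in enumerate(lids):
            if lid not in series.layer_ids:
                continue
            li = series.layer_ids.index(lid)
            ax.plot(series.time_ms, series.subject_mean[li], label=lid, lw=1.2)
            for c in clusters.significant(lid):
                ax.plot([c.start_ms, c.end_ms],
                        [base - 0.01 * k] * 2, lw=2.5)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(gname)
        ax.set_xlabel("time (ms)")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("Spearman R (model, MEG)")
    p = out_dir / "correlation_traces.png"
    fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
    written.append(p)

    # peak latency panel
    peaks: stats_mod.PeakLatencyResult = bundle["peaks"]
    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(peaks.layer_ids))
    err = np.stack([peaks.estimate_ms - peaks.ci_low_ms,
                    peaks.ci_high_ms - peaks.estimate_ms])
    ax.bar(xs, peaks.estimate_ms, yerr=np.nan_to_num(np.abs(err)), capsize=3)
    ax.set_xticks(xs, peaks.layer_ids)
    ax.set_ylabel("first-peak latency (ms)")
    p = out_dir / "peak_latencies.png"
    fig.tight_layout(); fig.savefig(p, dpi=110); plt.close(fig)
    written.append(p)
    return written
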