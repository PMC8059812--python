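"""Shared fixtures.

The expensive objects (a trained desk-scale adversarial autoencoder, a
decoded two-geometry recording, two demo-pipeline runs) are built once
per session and shared between the unit and acceptance tests.
"""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from feedback_rsa import aae, rdm as rdm_mod, rsa, synthetic


@pytest.fixture(scope="session")
def trained_setup():
    """One desk-scale AAE trained to its loss plateau, plus companions.

    Training set: 96 category images (24 per category, 32 px); the
    condition sets are a 40-image category set (held out from training)
    and 16 spectrally rich probe images.
    """
    train_set = synthetic.generate_image_dataset(24, 32, seed=1)
    test_set = synthetic.generate_image_dataset(8, 32, seed=2)
    stimuli = synthetic.generate_image_dataset(10, 32, seed=0)
    probes = synthetic.generate_probe_images(16, 32, seed=5)
    config = aae.desk_scale_config(seed=0, epochs=350)
    model = aae.build_model(config)
    trace = aae.train(model, train_set, config)
    cat_rdms = {r.source.removeprefix("layer:"): r
                for r in rdm_mod.model_layer_rdms(
                    aae.extract_activations(model, stimuli))}
    probe_rdms = {r.source.removeprefix("layer:"): r
                  for r in rdm_mod.model_layer_rdms(
                      aae.extract_activations(model, probes))}
    return {
        "config": config,
        "model": model,
        "trace": trace,
        "train_set": train_set,
        "test_set": test_set,
        "stimuli": stimuli,
        "probes": probes,
        "cat_rdms": cat_rdms,
        "probe_rdms": probe_rdms,
    }


@pytest.fixture(scope="session")
def two_geometry_series():
    """Full synthetic pipeline: two independent geometries planted at
    150 ms and 400 ms, decoded and correlated layer-by-layer."""
    rng = np.random.default_rng(11)
    target_a = synthetic.random_rdm(8, rng)
    target_b = synthetic.random_rdm(8, rng)
    geoms = [
        synthetic.PlantedGeometry(rdm_target=target_a, latency_ms=150.0,
                                  width_ms=30.0, amplitude=0.08, name="A"),
        synthetic.PlantedGeometry(rdm_target=target_b, latency_ms=400.0,
                                  width_ms=30.0, amplitude=0.08, name="B"),
    ]
    rec = synthetic.generate_meg_recording(
        geoms, n_subjects=4, n_trials=24, n_sensors=64, noise_sd=1.0, seed=3)
    pre = rdm_mod.preprocess_meg(rec)
    cfg = rdm_mod.DecodingConfig(n_bins=8, n_assignment_repeats=3, seed=0)
    trrdms = rdm_mod.time_resolved_rdms(pre, cfg, stride_ms=5.0,
                                        tmin_ms=50.0, tmax_ms=500.0)
    model_rdms = [rdm_mod.RDM(values=target_a, source="layer:A"),
                  rdm_mod.RDM(values=target_b, source="layer:B")]
    series = rsa.layer_time_correlation(model_rdms, trrdms)
    return {"series": series, "planted_ms": {"A": 150.0, "B": 400.0},
            "trrdms": trrdms}


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The demo pipeline executed twice with identical configuration."""
    from feedback_rsa import reporting

    out = []
    for tag in ("one", "two"):
        d = tmp_path_factory.mktemp(f"demo_{tag}")
        cfg = reporting.demo_config(seed=0, output_dir=str(d))
        bundle = reporting.run_pipeline(cfg)
        out.append({"dir": d, "bundle": bundle})
    return out
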