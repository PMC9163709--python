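"""Shared fixtures: small seeded synthetic patients and trained models.

Heavy artifacts (the surrogate classifier, the contrastive training run)
are session-scoped so the suite trains each network exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ieegsearch.synthio import (
    MorphologyTemplate,
    SynthPatientSpec,
    example_templates,
    make_event_waveform,
    make_patient,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_patient(pid, style=0, seed=1, n=10, dur=30.0, n_templates=2,
                  missing=()):
    """A compact synthetic patient built from the template library."""
    spec = SynthPatientSpec(
        patient_id=pid,
        templates=example_templates(style)[:n_templates],
        records_per_template=n,
        record_duration_s=dur,
        missing_channels=frozenset(missing),
        seed=seed,
    )
    return make_patient(spec)


def banded_patient(pid, band_index, seed, n=8, dur=30.0):
    """Patient whose seizure template occupies a distinct frequency band."""
    lo = 28.0 + 9.0 * band_index
    tpls = [
        MorphologyTemplate(f"{pid}-base", "baseline"),
        MorphologyTemplate(
            f"{pid}-hfb",
            "seizure_hf_band",
            {"band_hz": (lo, lo + 7.0), "ictal_duration_s": 15.0},
        ),
    ]
    return make_patient(
        SynthPatientSpec(pid, tpls, records_per_template=n,
                         record_duration_s=dur, seed=seed)
    )


@pytest.fixture(scope="session")
def surrogate_backend():
    """Surrogate seizure/non-seizure classifier trained on synthetic images.

    Returns (backend, held-out accuracy). 120 channel images per class,
    30 s records, six epochs.
    """
    from ieegsearch.featex import SurrogateTrainConfig, train_surrogate_classifier
    from ieegsearch.spectro import render_channel

    images, labels = [], []
    for cls, event, params in [
        (0, "baseline", {}),
        (1, "seizure_hf_band", {"band_hz": (55.0, 70.0), "ictal_duration_s": 15.0}),
    ]:
        for i in range(120):
            w = make_event_waveform(event, params, 30, 1000 * cls + i)
            images.append(render_channel(w).pixels)
            labels.append(cls)
    return train_surrogate_classifier(
        images, labels, SurrogateTrainConfig(epochs=6, seed=0)
    )


@pytest.fixture(scope="session")
def clustered_patient():
    """One 3-template patient clustered on spectral-power features.

    Returns (records, cluster model, centroid set).
    """
    from ieegsearch.featex import spectral_power_features
    from ieegsearch.patient_cluster import cluster_patient

    records = small_patient("CP", style=0, seed=2, n=20, n_templates=3)
    feats = np.stack([spectral_power_features(r) for r in records])
    model, cents = cluster_patient(
        [r.record_id for r in records], feats, seed=0
    )
    return records, model, cents


@pytest.fixture(scope="session")
def contrastive_run():
    """A full desk-scale contrastive training run.

    Two training patients, one held-out validation patient (disjoint
    morphology styles), triplets mined from spectral-feature clusterings.
    Returns (model, history, validation triplets, image dict).
    """
    from ieegsearch.cltrain import EmbeddingModel, TrainConfig, train
    from ieegsearch.featex import spectral_power_features
    from ieegsearch.patient_cluster import cluster_patient
    from ieegsearch.spectro import render_tiled
    from ieegsearch.tripletgen import mine_all

    images, triplets = {}, {}
    for pid, style, seed in [("A", 0, 1), ("B", 1, 2), ("C", 2, 3)]:
        records = small_patient(pid, style=style, seed=seed, n=12)
        for r in records:
            images[r.record_id] = render_tiled(r).pixels
        feats = np.stack([spectral_power_features(r) for r in records])
        model, cents = cluster_patient(
            [r.record_id for r in records], feats, seed=0
        )
        triplets[pid] = mine_all(model, cents, seed=0, patient_id=pid)

    cfg = TrainConfig(
        batch_triplets=16, learning_rate=1e-3, max_epochs=5, patience=3,
        margin=1.0, seed=0,
    )
    model = EmbeddingModel(m=32, seed=0)
    model, history = train(
        model, triplets["A"] + triplets["B"], triplets["C"], images, cfg
    )
    return model, history, triplets["C"], images


@pytest.fixture(scope="session")
def retrieval_benchmark(surrogate_backend):
    """Ten banded search patients indexed with the surrogate backend.

    Returns (index, backend, query records list, expected patient ids).
    """
    from ieegsearch.featex import spectral_power_features
    from ieegsearch.patient_cluster import cluster_patient
    from ieegsearch.xsearch import build_index

    backend, _ = surrogate_backend
    search_records = []
    for i in range(10):
        records = banded_patient(f"S{i}", i, seed=200 + i)
        feats = np.stack([spectral_power_features(r) for r in records])
        model, cents = cluster_patient(
            [r.record_id for r in records], feats, seed=0
        )
        by_id = {r.record_id: r for r in records}
        search_records += [by_id[rid] for rid in cents.centroid_ids.values()]
    index = build_index(
        search_records, backend, method="feature_pca_tsne_knn", seed=0
    )
    queries, expected = [], []
    for i in range(10):
        qrec = [
            r for r in banded_patient(f"Q{i}", i, seed=900 + i, n=1)
            if r.ground_truth_template.endswith("hfb")
        ][0]
        queries.append(qrec)
        expected.append(f"S{i}")
    return index, backend, queries, expected
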