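"""Cross-patient similarity search over centroid records.

The search set holds one representative (centroid) record per
within-patient cluster across the search patients. Two retrieval methods
share one ranking contract:

* feature method — per-channel convolutional feature maps are combined
  per record, reduced by a PCA fitted once on the search centroids and
  saved; at query time the query and its 7 channel permutations pass
  through the saved PCA, all points (search + query variants) are jointly
  embedded to 2D by seeded t-SNE, and the k nearest search neighbours of
  each variant are collected (a faster PCA-space kNN mode is available);
* contrastive method — tiled-record images are embedded by a trained
  embedding network and centroids are ranked by Euclidean distance per
  variant.

Variant results are pooled, sorted by distance, deduplicated keeping each
record's best distance, and the top k unique records are returned.

Channel permutations are the dihedral orbit of (1, 2, 3, 4): the four
cyclic rotations and their four reversals — exactly eight orderings
including the identity, preserving channel adjacency in the stacked or
tiled image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import DataError, ParameterError
from .featex import FeatureBackend, combine_record_features, extract_channel_features
from .patient_cluster import ReductionModel, embed_2d
from .records import IEEGRecord, N_CHANNELS
from .spectro import SpectrogramConfig, render_record_channels

#: the 8 channel orderings used for query augmentation (identity first):
#: 4 cyclic rotations of (1,2,3,4) and the 4 reversed cycles.
DIHEDRAL_ORDERINGS: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3),
    (1, 2, 3, 0),
    (2, 3, 0, 1),
    (3, 0, 1, 2),
    (3, 2, 1, 0),
    (2, 1, 0, 3),
    (1, 0, 3, 2),
    (0, 3, 2, 1),
)


def permute_channels(record: IEEGRecord) -> list[IEEGRecord]:
    """The record and its 7 adjacency-preserving channel permutations.

    Missing channels permute as missing. The first variant is the
    original ordering.
    """
    variants = []
    for vi, order in enumerate(DIHEDRAL_ORDERINGS):
        chans = [record.channels[j] for j in order]
        rec = record.with_channels(chans)
        rec.record_id = f"{record.record_id}#p{vi}"
        variants.append(rec)
    return variants


@dataclass
class RankedResult:
    """Top-k unique retrievals, best (smallest distance) first."""

    entries: list[tuple[str, str, float]]  # (patient_id, record_id, score)

    def __post_init__(self) -> None:
        ids = [r for _, r, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise DataError("ranked result contains duplicate record ids")
        scores = [s for _, _, s in self.entries]
        if any(b < a - 1e-12 for a, b in zip(scores, scores[1:])):
            raise DataError("ranked result scores must be non-decreasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def record_ids(self) -> list[str]:
        return [r for _, r, _ in self.entries]


def aggregate_ranks(
    pooled: list[tuple[str, str, float]], k: int = 5
) -> RankedResult:
    """Pool (patient, record, distance) tuples from all variants.

    Sorts ascending by (distance, patient_id, record_id), keeps each
    record's best distance, and truncates to the top k unique records.
    """
    if not pooled:
        raise DataError("no neighbour lists to aggregate")
    best: dict[str, tuple[str, str, float]] = {}
    for pid, rid, d in pooled:
        if rid not in best or d < best[rid][2]:
            best[rid] = (pid, rid, float(d))
    ordered = sorted(best.values(), key=lambda t: (t[2], t[0], t[1]))
    return RankedResult(entries=ordered[:k])


@dataclass
class SearchIndex:
    """Method-specific index over the search centroids."""

    method: str                                # "feature_pca_tsne_knn" | "contrastive_embedding"
    patient_ids: list[str]
    record_ids: list[str]
    vectors: np.ndarray                        # PCA-reduced features or embeddings
    k: int = 5
    seed: int = 0
    pca_model: ReductionModel | None = field(default=None, repr=False)
    channel_maps: list[list[np.ndarray | None]] | None = field(
        default=None, repr=False
    )
    knn_space: str = "tsne_2d"                 # or "pca_50d"

    def __post_init__(self) -> None:
        if self.method not in ("feature_pca_tsne_knn", "contrastive_embedding"):
            raise ParameterError(f"unknown search method {self.method!r}")
        if len(self.record_ids) == 0:
            raise DataError("empty search index")


def build_index(
    centroid_records: list[IEEGRecord],
    extractor,
    method: str = "feature_pca_tsne_knn",
    k: int = 5,
    seed: int = 0,
    spect_cfg: SpectrogramConfig | None = None,
    knn_space: str = "tsne_2d",
) -> SearchIndex:
    """Build the search index over centroid records.

    For the feature method ``extractor`` is a :class:`FeatureBackend`:
    per-channel maps are extracted, combined with zero-fill, and a PCA to
    at most 50 components is fitted on the centroids only and persisted in
    the index for query-time reuse. For the contrastive method
    ``extractor`` is a trained :class:`~ieegsearch.cltrain.EmbeddingModel`
    applied to tiled record images.
    """
    if len(centroid_records) < 2:
        raise DataError("need >=2 centroid records to build an index")
    spect_cfg = spect_cfg or SpectrogramConfig()
    pids = [r.patient_id for r in centroid_records]
    rids = [r.record_id for r in centroid_records]

    if method == "contrastive_embedding":
        from .spectro import render_tiled

        vecs = np.stack(
            [extractor.embed(render_tiled(r, spect_cfg)) for r in centroid_records]
        )
        return SearchIndex(
            method=method, patient_ids=pids, record_ids=rids,
            vectors=vecs, k=k, seed=seed,
        )

    if method != "feature_pca_tsne_knn":
        raise ParameterError(f"unknown search method {method!r}")
    if not isinstance(extractor, FeatureBackend):
        raise ParameterError("feature method needs a FeatureBackend")
    maps: list[list[np.ndarray | None]] = []
    combined = []
    for rec in centroid_records:
        images = render_record_channels(rec, spect_cfg)
        per_ch = [
            None if im is None else extract_channel_features(im, extractor)
            for im in images
        ]
        maps.append(per_ch)
        combined.append(
            combine_record_features(per_ch, set(rec.missing_channels))
        )
    features = np.stack(combined)
    pca = ReductionModel(seed=seed).fit_pca(features)
    return SearchIndex(
        method=method, patient_ids=pids, record_ids=rids,
        vectors=pca.transform(features), k=k, seed=seed,
        pca_model=pca, channel_maps=maps, knn_space=knn_space,
    )


def _query_variant_features(
    record: IEEGRecord, backend: FeatureBackend, spect_cfg: SpectrogramConfig
) -> np.ndarray:
    """Combined features for all 8 channel orderings of a query record.

    Channel images are rendered once; each variant permutes the per-channel
    feature blocks, which is identical to re-rendering the permuted record.
    """
    images = render_record_channels(record, spect_cfg)
    per_ch = [
        None if im is None else extract_channel_features(im, backend)
        for im in images
    ]
    rows = []
    for order in DIHEDRAL_ORDERINGS:
        maps = [per_ch[j] for j in order]
        missing = {i for i, m in enumerate(maps) if m is None}
        rows.append(combine_record_features(maps, missing))
    return np.stack(rows)


def query(
    index: SearchIndex,
    record: IEEGRecord,
    extractor=None,
    k: int | None = None,
    spect_cfg: SpectrogramConfig | None = None,
) -> RankedResult:
    """Retrieve the top-k unique search records for a query record.

    The query is augmented with its 7 channel permutations. Feature
    method: each variant passes through the index's saved PCA, then all
    search points and the 8 variant points are jointly embedded to 2D by
    seeded t-SNE and each variant's k nearest search neighbours are
    collected (``knn_space="pca_50d"`` skips the joint t-SNE and runs kNN
    in the PCA space). Contrastive method: each variant's tiled image is
    embedded and every centroid is ranked by Euclidean distance. Variant
    results are pooled by :func:`aggregate_ranks`.
    """
    k = k or index.k
    spect_cfg = spect_cfg or SpectrogramConfig()
    n_search = len(index.record_ids)

    if index.method == "contrastive_embedding":
        if extractor is None:
            raise ParameterError("contrastive query needs the embedding model")
        from .spectro import render_tiled

        pooled = []
        for variant in permute_channels(record):
            e = extractor.embed(render_tiled(variant, spect_cfg))
            d = np.linalg.norm(index.vectors - e, axis=1)
            take = np.argsort(d, kind="stable")[:k]
            pooled += [
                (index.patient_ids[i], index.record_ids[i], float(d[i]))
                for i in take
            ]
        return aggregate_ranks(pooled, k)

    # feature method
    backend = extractor
    if backend is None:
        raise ParameterError("feature query needs the FeatureBackend")
    if index.pca_model is None:
        raise DataError("index lacks its saved PCA model")
    qrows = _query_variant_features(record, backend, spect_cfg)
    qred = index.pca_model.transform(qrows)

    if index.knn_space == "pca_50d":
        space_search, space_query = index.vectors, qred
    else:
        joint = np.vstack([index.vectors, qred])
        coords = embed_2d(
            joint, ReductionModel(seed=index.seed), fit_pca=True
        )
        space_search, space_query = coords[:n_search], coords[n_search:]

    nn = NearestNeighbors(n_neighbors=min(k, n_search)).fit(space_search)
    dist, idx = nn.kneighbors(space_query)
    pooled = [
        (index.patient_ids[j], index.record_ids[j], float(d))
        for drow, jrow in zip(dist, idx)
        for d, j in zip(drow, jrow)
    ]
    return aggregate_ranks(pooled, k)


# ---------------------------------------------------------------------------
# persistence


def save_index(index: SearchIndex, path) -> None:
    """Persist an index (vectors + PCA + config) to a single .npz archive."""
    payload = {
        "method": index.method,
        "patient_ids": np.array(index.patient_ids),
        "record_ids": np.array(index.record_ids),
        "vectors": index.vectors,
        "k": index.k,
        "seed": index.seed,
        "knn_space": index.knn_space,
    }
    if index.pca_model is not None and index.pca_model.pca is not None:
        p = index.pca_model.pca
        payload.update(
            pca_components=p.components_,
            pca_mean=p.mean_,
            pca_variance=p.explained_variance_,
            pca_seed=index.pca_model.seed,
        )
    np.savez(path, **payload)


def load_index(path) -> SearchIndex:
    from sklearn.decomposition import PCA

    with np.load(path, allow_pickle=False) as z:
        pca_model = None
        if "pca_components" in z:
            pca = PCA(n_components=z["pca_components"].shape[0])
            pca.components_ = z["pca_components"]
            pca.mean_ = z["pca_mean"]
            pca.explained_variance_ = z["pca_variance"]
            pca.whiten = False
            pca_model = ReductionModel(seed=int(z["pca_seed"]), pca=pca)
        return SearchIndex(
            method=str(z["method"]),
            patient_ids=[str(s) for s in z["patient_ids"]],
            record_ids=[str(s) for s in z["record_ids"]],
            vectors=z["vectors"],
            k=int(z["k"]),
            seed=int(z["seed"]),
            pca_model=pca_model,
            knn_space=str(z["knn_space"]),
        )
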