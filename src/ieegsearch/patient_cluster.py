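"""Within-patient clustering and representative-record selection.

Each patient's record-level feature vectors are reduced to the top 50
principal components, embedded to two dimensions with t-SNE, and
clustered with a Bayesian Gaussian mixture whose component budget follows
the heuristic ``max(floor(n_records / 500), 15)``. Because the mixture is
Bayesian with a Dirichlet-process-style weight prior, superfluous
components are left unused, so the effective cluster count is inferred
from the data. Within each cluster the single record nearest the
cluster's mean 2D coordinate is the representative (centroid) record that
goes on to the cross-patient search set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import BayesianGaussianMixture

from .errors import DataError

#: fixed floor on the BGMM component budget
MIN_COMPONENTS = 15
#: records per additional component above the floor
RECORDS_PER_COMPONENT = 500


def choose_n_components(n_records: int) -> int:
    """BGMM component budget: ``max(floor(n_records / 500), 15)``.

    A patient with 2,000 records gets 15 components; one with 20,000 gets
    40. The mixture may use fewer.
    """
    if n_records < 1:
        raise DataError("n_records must be >= 1")
    return max(n_records // RECORDS_PER_COMPONENT, MIN_COMPONENTS)


@dataclass
class ReductionModel:
    """Fitted PCA (to <=50 components) plus t-SNE settings."""

    n_components: int = 50
    perplexity: float = 30.0
    seed: int = 0
    pca: PCA | None = field(default=None, repr=False)

    def fit_pca(self, features: np.ndarray) -> "ReductionModel":
        n, d = features.shape
        k = min(self.n_components, max(n - 1, 1), d)
        self.pca = PCA(n_components=k, whiten=False, random_state=self.seed)
        self.pca.fit(features)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.pca is None:
            raise DataError("PCA not fitted")
        return self.pca.transform(features)


@dataclass
class ClusterModel:
    """Per-record 2D coordinates and BGMM assignments for one patient."""

    record_ids: list[str]
    coords: np.ndarray            # (n, 2)
    assignments: np.ndarray       # cluster id per record
    n_components: int

    @property
    def effective_clusters(self) -> int:
        return int(np.unique(self.assignments).size)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)


@dataclass
class CentroidSet:
    """Representative record per non-empty cluster."""

    centroid_ids: dict[int, str]            # cluster id -> record id
    centroid_indices: dict[int, int]        # cluster id -> row index

    def __len__(self) -> int:
        return len(self.centroid_ids)


def embed_2d(
    features: np.ndarray,
    model: ReductionModel | None = None,
    fit_pca: bool = True,
) -> np.ndarray:
    """PCA to <=50 components followed by t-SNE to 2D.

    Deterministic given the model seed. All-identical feature vectors are
    degenerate for t-SNE; they collapse to coincident points with a
    warning.
    """
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n < 3:
        raise DataError("need >=3 records for a 2D embedding")
    model = model or ReductionModel()
    if fit_pca or model.pca is None:
        model.fit_pca(features)
    reduced = model.transform(features)
    if np.allclose(reduced, reduced[0]):
        warnings.warn("all feature vectors identical; returning coincident points")
        return np.zeros((n, 2))
    perplexity = min(model.perplexity, max((n - 1) / 3.0, 2.0))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=model.seed,
        # PCA init needs >=2 input dims; rank-1 inputs fall back to seeded random
        init="pca" if reduced.shape[1] >= 2 else "random",
        method="exact" if n < 1000 else "barnes_hut",
    )
    return tsne.fit_transform(reduced)


def fit_bgmm(
    points: np.ndarray,
    n_components: int,
    seed: int = 0,
    record_ids: list[str] | None = None,
) -> ClusterModel:
    """Cluster 2D points with a Bayesian Gaussian mixture.

    Full covariances, Dirichlet-process weight prior with concentration
    ``1 / n_components``, up to 500 iterations, five seeded restarts
    keeping the best variational lower bound (a single restart can settle
    on a local optimum that splits one blob across two components).
    Assignments are maximum posterior responsibility; unused components
    are allowed, so the effective cluster count is <= ``n_components``.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape[0] < 1:
        raise DataError("need at least one point")
    n_components = max(1, min(n_components, points.shape[0]))
    bgmm = BayesianGaussianMixture(
        n_components=n_components,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=1.0 / n_components,
        max_iter=500,
        n_init=5,  # restarts avoid split-blob local optima (best ELBO wins)
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny inputs
        labels = bgmm.fit_predict(points)
    ids = record_ids or [f"r{i}" for i in range(points.shape[0])]
    return ClusterModel(
        record_ids=list(ids),
        coords=points,
        assignments=np.asarray(labels),
        n_components=n_components,
    )


def select_centroids(model: ClusterModel) -> CentroidSet:
    """Pick the representative record of each non-empty cluster.

    The representative is the member record with minimal Euclidean
    distance to the cluster's mean 2D coordinate; ties break to the
    lowest record id.
    """
    ids: dict[int, str] = {}
    idx: dict[int, int] = {}
    for cid in np.unique(model.assignments):
        members = model.members(int(cid))
        mean = model.coords[members].mean(axis=0)
        dists = np.linalg.norm(model.coords[members] - mean, axis=1)
        best = np.flatnonzero(np.isclose(dists, dists.min()))
        chosen = min(best, key=lambda b: model.record_ids[members[b]])
        ids[int(cid)] = model.record_ids[members[chosen]]
        idx[int(cid)] = int(members[chosen])
    return CentroidSet(centroid_ids=ids, centroid_indices=idx)


def cluster_patient(
    record_ids: list[str],
    features: np.ndarray,
    seed: int = 0,
    n_components: int | None = None,
) -> tuple[ClusterModel, CentroidSet]:
    """Full within-patient pipeline: embed, cluster, select centroids."""
    n = len(record_ids)
    coords = embed_2d(features, ReductionModel(seed=seed))
    k = n_components if n_components is not None else choose_n_components(n)
    model = fit_bgmm(coords, k, seed=seed, record_ids=record_ids)
    return model, select_centroids(model)


def cluster_report(model: ClusterModel, centroids: CentroidSet, patient_id: str):
    """Tabular cluster report (patient, record, cluster, x, y, is_centroid)."""
    import pandas as pd

    centroid_rows = set(centroids.centroid_indices.values())
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "record_id": model.record_ids,
            "cluster_id": model.assignments,
            "x": model.coords[:, 0],
            "y": model.coords[:, 1],
            "is_centroid": [i in centroid_rows for i in range(len(model.record_ids))],
        }
    )


def plot_clusters(model: ClusterModel, centroids: CentroidSet, path, title="") -> None:
    """2D scatter of a patient's records coloured by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        model.coords[:, 0], model.coords[:, 1],
        c=model.assignments, cmap="tab20", s=12,
    )
    cent = np.array([model.coords[i] for i in centroids.centroid_indices.values()])
    if cent.size:
        ax.scatter(cent[:, 0], cent[:, 1], marker="*", s=160,
                   edgecolors="k", facecolors="none", label="centroid")
        ax.legend()
    ax.set_title(title or "within-patient 2D embedding")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
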