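"""Triplet mining from within-patient 2D embeddings, and the triplet math.

Training units for the contrastive method are (anchor, positive,
negative) record triples mined per patient from the clustered 2D
embedding. Every cluster centroid record is an anchor. Same-cluster
triplets pair each anchor with its ``n_pos`` nearest same-cluster records
as positives and, for each (anchor, positive) pair, the ``n_neg``
same-cluster records immediately farther from the anchor than that
positive — semi-hard negatives by construction in the mining space.
Different-cluster triplets use the ``n_pos`` nearest same-cluster records
as positives and seeded draws from the patient's other clusters as easy
negatives.

The hinge loss and the easy / semi-hard / hard taxonomy are defined on the
anchor-positive and anchor-negative embedding distances:
``l = max(0, margin + d_ap - d_an)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError
from .patient_cluster import CentroidSet, ClusterModel


class TripletSource(str, Enum):
    SAME_CLUSTER = "same_cluster"
    DIFFERENT_CLUSTER = "different_cluster"


class TripletClass(str, Enum):
    EASY = "easy"
    SEMI_HARD = "semi_hard"
    HARD = "hard"


@dataclass(frozen=True)
class Triplet:
    anchor: str
    positive: str
    negative: str
    source: TripletSource
    patient_id: str

    def __post_init__(self) -> None:
        if len({self.anchor, self.positive, self.negative}) != 3:
            raise ParameterError("anchor, positive and negative must be distinct")


@dataclass
class TripletLossParams:
    """Gap parameter of the hinge loss."""

    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ParameterError("margin must be >= 0")


def hinge_loss(d_ap: float, d_an: float, params: TripletLossParams) -> float:
    """Triplet hinge loss ``max(0, margin + d_ap - d_an)``."""
    if d_ap < 0 or d_an < 0:
        raise ParameterError("distances must be nonnegative")
    return max(0.0, params.margin + d_ap - d_an)


def classify_triplet(
    d_ap: float, d_an: float, params: TripletLossParams
) -> TripletClass:
    """Easy / semi-hard / hard taxonomy.

    Easy: the negative is beyond the positive by more than the margin
    (zero loss). Hard: the negative is closer to the anchor than the
    positive. Semi-hard: the negative is farther than the positive but
    within the margin (positive loss).
    """
    if d_an < d_ap:
        return TripletClass.HARD
    if d_ap + params.margin < d_an:
        return TripletClass.EASY
    return TripletClass.SEMI_HARD


def _ranked_same_cluster(model: ClusterModel, anchor_idx: int) -> np.ndarray:
    """Same-cluster member indices sorted by distance to the anchor."""
    cid = model.assignments[anchor_idx]
    members = model.members(int(cid))
    members = members[members != anchor_idx]
    d = np.linalg.norm(model.coords[members] - model.coords[anchor_idx], axis=1)
    order = np.lexsort((members, d))  # distance, then index for stable ties
    return members[order]


def mine_same_cluster(
    model: ClusterModel,
    centroids: CentroidSet,
    n_pos: int = 3,
    n_neg: int = 5,
    patient_id: str = "",
) -> list[Triplet]:
    """Semi-hard triplets within each anchor's own cluster.

    Positives are the ``n_pos`` records nearest the anchor; for each
    (anchor, positive) pair the negatives are the next ``n_neg``
    same-cluster records in distance rank beyond that positive, so every
    mined triplet satisfies ``d(a, p) <= d(a, n)`` in the mining space.
    Counts truncate silently in small clusters.
    """
    triplets: list[Triplet] = []
    for _, anchor_idx in sorted(centroids.centroid_indices.items()):
        ranked = _ranked_same_cluster(model, anchor_idx)
        a_id = model.record_ids[anchor_idx]
        for pi in range(min(n_pos, len(ranked))):
            for ni in range(pi + 1, min(pi + 1 + n_neg, len(ranked))):
                triplets.append(
                    Triplet(
                        anchor=a_id,
                        positive=model.record_ids[ranked[pi]],
                        negative=model.record_ids[ranked[ni]],
                        source=TripletSource.SAME_CLUSTER,
                        patient_id=patient_id,
                    )
                )
    return triplets


def mine_different_cluster(
    model: ClusterModel,
    centroids: CentroidSet,
    n_pos: int = 5,
    n_neg: int = 10,
    seed: int = 0,
    patient_id: str = "",
) -> list[Triplet]:
    """Easy triplets with negatives drawn from the patient's other clusters.

    Positives are the ``n_pos`` records nearest the anchor in its own
    cluster; for each (anchor, positive) pair ``n_neg`` negatives are
    sampled (seeded, without replacement) uniformly from all records in
    other clusters of the same patient. Single-cluster patients yield an
    empty list.
    """
    if model.effective_clusters < 2:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A]))
    triplets: list[Triplet] = []
    for _, anchor_idx in sorted(centroids.centroid_indices.items()):
        cid = model.assignments[anchor_idx]
        others = np.flatnonzero(model.assignments != cid)
        if others.size == 0:
            continue
        ranked = _ranked_same_cluster(model, anchor_idx)
        a_id = model.record_ids[anchor_idx]
        for pi in range(min(n_pos, len(ranked))):
            take = min(n_neg, others.size)
            negs = rng.choice(others, size=take, replace=False)
            for n_idx in negs:
                triplets.append(
                    Triplet(
                        anchor=a_id,
                        positive=model.record_ids[ranked[pi]],
                        negative=model.record_ids[n_idx],
                        source=TripletSource.DIFFERENT_CLUSTER,
                        patient_id=patient_id,
                    )
                )
    return triplets


def mine_all(
    model: ClusterModel,
    centroids: CentroidSet,
    seed: int = 0,
    patient_id: str = "",
) -> list[Triplet]:
    """Default mining: 3/5 same-cluster plus 5/10 different-cluster."""
    return mine_same_cluster(model, centroids, patient_id=patient_id) + (
        mine_different_cluster(model, centroids, seed=seed, patient_id=patient_id)
    )


def triplets_to_frame(triplets: list[Triplet]):
    """Triplet manifest as a table (patient_id, a, p, n, source)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in triplets],
            "a": [t.anchor for t in triplets],
            "p": [t.positive for t in triplets],
            "n": [t.negative for t in triplets],
            "source": [t.source.value for t in triplets],
        }
    )


def triplets_from_frame(df) -> list[Triplet]:
    return [
        Triplet(
            anchor=row.a,
            positive=row.p,
            negative=row.n,
            source=TripletSource(row.source),
            patient_id=row.patient_id,
        )
        for row in df.itertuples()
    ]
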