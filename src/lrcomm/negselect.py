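"""Negative-pair construction by the centroid-distance band rule.

In the positive-unlabeled setting only interacting ligand-receptor pairs are
labelled.  Negatives are drawn from unlabeled candidate pairs: the centroid
of the positive class is computed in pair-feature space, the min and max
positive-to-centroid distances define a band, and the band is shrunk
symmetrically by a threshold ``pre`` in [0, 1]:

    minRange = minDis + (1 - pre) * 0.5 * disLen
    maxRange = maxDis - (1 - pre) * 0.5 * disLen

A candidate whose distance to the centroid falls strictly outside
[minRange, maxRange] is eligible as a negative; boundary hits count as
inside.  ``pre`` defaults to 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqfeat import PairFeature

logger = logging.getLogger(__name__)

DEFAULT_PRE = 0.6


@dataclass(frozen=True)
class NegativeSelectionModel:
    """Positive-class centroid plus the [minRange, maxRange] exclusion band."""

    centroid: np.ndarray
    minDis: float
    maxDis: float
    disLen: float
    minRange: float
    maxRange: float
    pre: float

    def __post_init__(self) -> None:
        tol = 1e-9 * max(1.0, self.maxDis)
        if not (
            self.minDis - tol
            <= self.minRange
            <= self.maxRange + tol
            <= self.maxDis + 2 * tol
        ):
            raise ValueError("band ordering violated: need minDis <= minRange <= maxRange <= maxDis")

    def is_eligible(self, distance: float) -> bool:
        """Strictly outside the band on either side."""
        return distance < self.minRange or distance > self.maxRange


def centroid(positives: list[PairFeature] | np.ndarray) -> np.ndarray:
    """Coordinate-wise mean of the positive pair vectors."""
    X = _as_matrix(positives)
    if X.shape[0] == 0:
        raise ValueError("cannot compute centroid of an empty positive set")
    return X.mean(axis=0)


def distance_to_centroid(b: PairFeature | np.ndarray, a: np.ndarray) -> float:
    """Euclidean distance from a pair vector to the centroid."""
    x = b.x if isinstance(b, PairFeature) else np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.shape != a.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {a.shape}")
    return float(np.linalg.norm(x - a))


def compute_range(
    positive_distances,
    pre: float = DEFAULT_PRE,
    centroid_vec: np.ndarray | None = None,
) -> NegativeSelectionModel:
    """Build the exclusion band from positive-to-centroid distances.

    ``pre=1`` keeps the full [minDis, maxDis] band; ``pre=0`` collapses it to
    the midpoint.
    """
    dists = np.asarray(list(positive_distances), dtype=float)
    if dists.size == 0:
        raise ValueError("positive distance list is empty")
    if not 0.0 <= pre <= 1.0:
        raise ValueError(f"pre={pre} outside [0, 1]")
    min_dis = float(dists.min())
    max_dis = float(dists.max())
    dis_len = max_dis - min_dis
    shrink = (1.0 - pre) * 0.5 * dis_len
    return NegativeSelectionModel(
        centroid=(
            centroid_vec if centroid_vec is not None else np.array([])
        ),
        minDis=min_dis,
        maxDis=max_dis,
        disLen=dis_len,
        minRange=min_dis + shrink,
        maxRange=max_dis - shrink,
        pre=pre,
    )


def fit_selection_model(
    positives: list[PairFeature], pre: float = DEFAULT_PRE
) -> NegativeSelectionModel:
    """Centroid + band in one step from positive PairFeatures."""
    a = centroid(positives)
    dists = [distance_to_centroid(p, a) for p in positives]
    return compute_range(dists, pre=pre, centroid_vec=a)


def select_negatives(
    candidates: list[PairFeature],
    model: NegativeSelectionModel,
    n_neg: int,
    seed: int,
    positive_ids: set[tuple[str, str]] | None = None,
) -> list[PairFeature]:
    """Pick up to ``n_neg`` eligible candidates as negatives (label 0).

    Eligibility: distance to the centroid strictly outside the band, and the
    (ligand, receptor) id pair not among known positives.  If more than
    ``n_neg`` candidates are eligible a seeded uniform subsample (without
    replacement) is drawn; if fewer, all eligible are returned with a warning.
    """
    if n_neg < 1:
        raise ValueError("n_neg must be >= 1")
    positive_ids = positive_ids or set()
    eligible = []
    for c in candidates:
        if (c.ligand_id, c.receptor_id) in positive_ids:
            continue
        if model.is_eligible(distance_to_centroid(c, model.centroid)):
            eligible.append(c)
    logger.info(
        "negative selection: %d candidates, %d eligible, requesting %d",
        len(candidates),
        len(eligible),
        n_neg,
    )
    if len(eligible) < n_neg:
        logger.warning(
            "only %d eligible negatives for requested %d; returning all",
            len(eligible),
            n_neg,
        )
        chosen = list(eligible)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=n_neg, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    return [
        PairFeature(c.ligand_id, c.receptor_id, c.x, y=0) for c in chosen
    ]


def _as_matrix(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        return np.atleast_2d(pairs.astype(float))
    return np.array([p.x for p in pairs], dtype=float)
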