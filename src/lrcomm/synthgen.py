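"""Seeded synthetic fixtures for every pipeline stage.

Three generators cover the pipeline's inputs:

- :func:`gen_sequences` — uniform random protein sequences over the
  20-letter alphabet, encodable by every descriptor block;
- :func:`gen_pair_classification` — pair-feature geometry for the
  positive-unlabeled setting: a positive Gaussian cluster at the origin, and
  unlabeled candidates mixing true negatives (a cluster displaced by
  ``separation`` standard deviations) with decoys overlapping the positives;
  ground-truth labels are retained for oracle testing;
- :func:`gen_expression` — a Poisson(lambda=1) count matrix over balanced
  cell types, with planted ligand/receptor pairs whose rates are multiplied
  by an effect size in the sender/receiver types respectively, so
  "expressed = value > 0" stays meaningful.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cccscore import ExpressionDataset
from .seqfeat import ALPHABET, PairFeature, ProteinRecord


@dataclass(frozen=True)
class PlantedInteraction:
    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    effect_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.effect_multiplier <= 1:
            raise ValueError("effect_multiplier must exceed 1")


@dataclass
class SynthSpec:
    seed: int = 0
    n_pos: int = 200
    n_unlabeled: int = 400
    feature_dim: int = 400
    separation: float = 4.0
    # share of the unlabeled pool that are decoys (hidden interactors); in a
    # positive-unlabeled LRI setting most unlabeled pairs truly do not
    # interact, so decoys are the minority
    decoy_fraction: float = 0.25
    m_types: int = 3
    cells_per_type: int = 50
    n_genes: int = 60
    planted: list[PlantedInteraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_unlabeled", "feature_dim", "m_types",
                     "cells_per_type", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1]")


def gen_sequences(
    n: int, len_min: int = 50, len_max: int = 200, seed: int = 0
) -> list[ProteinRecord]:
    """Uniform random sequences with lengths drawn in [len_min, len_max]."""
    if len_min < 8 or len_max < len_min:
        raise ValueError("need len_min >= 8 and len_max >= len_min")
    rng = np.random.default_rng(seed)
    records = []
    letters = np.array(list(ALPHABET))
    for i in range(n):
        length = int(rng.integers(len_min, len_max + 1))
        seq = "".join(rng.choice(letters, size=length))
        records.append(ProteinRecord(id=f"P{i:04d}", sequence=seq))
    return records


def gen_pair_classification(
    spec: SynthSpec,
) -> tuple[list[PairFeature], list[PairFeature], np.ndarray]:
    """Positive and unlabeled pair features with hidden ground truth.

    Positives ~ N(0, I).  Unlabeled candidates mix true negatives, displaced
    by ``separation`` (in units of the cluster sd) along a fixed random
    direction, with a ``decoy_fraction`` share of decoys drawn from the
    positive cluster.  Returns (positives, unlabeled, truth) where
    truth[i] = 1 marks unlabeled candidate i as a true negative.
    """
    if spec.feature_dim < 2:
        raise ValueError("feature_dim must be >= 2")
    rng = np.random.default_rng(spec.seed)
    d = spec.feature_dim
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)
    offset = spec.separation * direction

    pos_X = rng.normal(size=(spec.n_pos, d))
    n_decoy = int(round(spec.n_unlabeled * spec.decoy_fraction))
    n_far = spec.n_unlabeled - n_decoy
    far_X = rng.normal(size=(n_far, d)) + offset
    decoy_X = rng.normal(size=(n_decoy, d))

    unl_X = np.vstack([far_X, decoy_X])
    truth = np.concatenate([np.ones(n_far, int), np.zeros(n_decoy, int)])
    perm = rng.permutation(spec.n_unlabeled)
    unl_X, truth = unl_X[perm], truth[perm]

    positives = [
        PairFeature(f"L{i:04d}", f"R{i:04d}", pos_X[i], y=1)
        for i in range(spec.n_pos)
    ]
    unlabeled = [
        PairFeature(f"uL{i:04d}", f"uR{i:04d}", unl_X[i], y=None)
        for i in range(spec.n_unlabeled)
    ]
    return positives, unlabeled, truth


def gen_expression(spec: SynthSpec) -> tuple[ExpressionDataset, list[PlantedInteraction]]:
    """Poisson count matrix with planted sender->receiver over-expression.

    Baseline rate is 1 per gene/cell; each planted interaction multiplies the
    ligand's rate in sender-type cells and the receptor's rate in
    receiver-type cells by its effect.  Cell types are balanced.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:03d}" for i in range(spec.n_genes)]
    gene_set = set(genes)
    types = [f"T{i}" for i in range(spec.m_types)]
    for planted in spec.planted:
        for g in (planted.ligand, planted.receptor):
            if g not in gene_set:
                raise ValueError(f"planted gene {g!r} not in the gene list")
        for t in (planted.sender_type, planted.receiver_type):
            if t not in types:
                raise ValueError(f"planted type {t!r} not generated")
    cells, labels = [], []
    for t in types:
        for c in range(spec.cells_per_type):
            cells.append(f"{t}_c{c:03d}")
            labels.append(t)
    lam = np.ones((spec.n_genes, len(cells)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    labels_arr = np.array(labels)
    for planted in spec.planted:
        lam[gene_idx[planted.ligand], labels_arr == planted.sender_type] *= (
            planted.effect_multiplier
        )
        lam[gene_idx[planted.receptor], labels_arr == planted.receiver_type] *= (
            planted.effect_multiplier
        )
    counts = rng.poisson(lam)
    matrix = pd.DataFrame(counts.astype(float), index=genes, columns=cells)
    cell_types = pd.Series(labels, index=cells, name="cell_type")
    return ExpressionDataset(matrix, cell_types), list(spec.planted)


def default_planted(spec: SynthSpec, effect: float = 10.0) -> PlantedInteraction:
    """Convenience: plant gene 0 -> gene 1 from the first to the second type."""
    return PlantedInteraction(
        ligand="G000",
        receptor="G001",
        sender_type="T0",
        receiver_type="T1",
        effect_multiplier=effect,
    )


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
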