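"""Protein sequence feature encoding and dimension reduction.

Each ligand or receptor sequence is encoded as the concatenation of four
descriptor blocks — amino-acid composition (AAC, 20), composition of
k-spaced amino-acid pairs (CKSAAP, 2400 for gaps k=0..5), composition/
transition/distribution over 13 physicochemical properties (CTD, 273) and
conjoint triad (343) — giving a 3036-dimensional vector.  Vectors are
reduced with PCA to d dimensions (default 200) and a ligand-receptor pair
is the 2d concatenation ligand|receptor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

CKSAAP_GAPS = tuple(range(6))
AAC_DIM = 20
CKSAAP_DIM = 400 * len(CKSAAP_GAPS)
CTD_DIM = 273
CTRIAD_DIM = 343
TOTAL_DIM = AAC_DIM + CKSAAP_DIM + CTD_DIM + CTRIAD_DIM  # 3036

BLOCK_LAYOUT = {
    "AAC": (0, AAC_DIM),
    "CKSAAP": (AAC_DIM, AAC_DIM + CKSAAP_DIM),
    "CTD": (AAC_DIM + CKSAAP_DIM, AAC_DIM + CKSAAP_DIM + CTD_DIM),
    "CTriad": (AAC_DIM + CKSAAP_DIM + CTD_DIM, TOTAL_DIM),
}

ENCODER_VERSION = "1"

# 13 physicochemical properties, each splitting the alphabet into 3 disjoint
# groups (the published iFeature groupings).  39 composition + 39 transition +
# 195 distribution entries = 273.
CTD_PROPERTY_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# Conjoint-triad classes: residues grouped by dipole and side-chain volume.
CTRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_CTRIAD_CLASS_OF = {
    aa: ci for ci, grp in enumerate(CTRIAD_CLASSES) for aa in grp
}


def _validate_tables() -> None:
    for prop, groups in CTD_PROPERTY_GROUPS.items():
        joined = "".join(groups)
        if sorted(joined) != sorted(ALPHABET):
            raise AssertionError(f"CTD groups for {prop} are not a partition")
    if sorted("".join(CTRIAD_CLASSES)) != sorted(ALPHABET):
        raise AssertionError("conjoint-triad classes are not a partition")


_validate_tables()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus sanitized amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}; "
                "run sanitize_sequence first"
            )


@dataclass(frozen=True)
class FeatureVector:
    """One encoded protein: ordered values plus named block spans."""

    values: np.ndarray
    block_layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(BLOCK_LAYOUT)
    )

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_layout[name]
        return self.values[lo:hi]


@dataclass(frozen=True)
class PairFeature:
    """A ligand-receptor pair sample: 2d concatenated vector, optional label."""

    ligand_id: str
    receptor_id: str
    x: np.ndarray
    y: int | None = None


def sanitize_sequence(raw: str, record_id: str = "<unnamed>") -> str:
    """Uppercase ``raw`` and strip non-canonical residues (with a warning each).

    Raises ``ValueError`` if nothing canonical remains.
    """
    if not raw:
        raise ValueError(f"record {record_id!r}: empty input sequence")
    upper = raw.upper()
    kept = []
    for ch in upper:
        if ch in _ALPHABET_SET:
            kept.append(ch)
        else:
            logger.warning(
                "record %r: dropping non-canonical residue %r", record_id, ch
            )
    if not kept:
        raise ValueError(
            f"record {record_id!r}: sequence empty after removing "
            "non-canonical residues"
        )
    return "".join(kept)


def encode_aac(seq: str) -> np.ndarray:
    """Amino-acid composition: per-residue frequency, alphabetical order."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.zeros(AAC_DIM)
    for ch in seq:
        counts[_RESIDUE_INDEX[ch]] += 1
    return counts / len(seq)


def encode_cksaap(seq: str, gaps: tuple[int, ...] = CKSAAP_GAPS) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs.

    For gap k, every ordered residue pair (i, i+k+1) is counted and divided by
    the number of such pairs, L-k-1, so each gap block is a distribution.
    Blocks are ordered by increasing k; 400 ordered pairs per block.
    """
    min_len = max(gaps) + 2
    if len(seq) < min_len:
        raise ValueError(
            f"sequence length {len(seq)} below CKSAAP minimum {min_len} "
            f"for gap {max(gaps)}"
        )
    idx = np.array([_RESIDUE_INDEX[ch] for ch in seq])
    out = np.zeros(400 * len(gaps))
    for bi, k in enumerate(gaps):
        left = idx[: len(idx) - k - 1]
        right = idx[k + 1 :]
        pair_codes = left * 20 + right
        block = np.bincount(pair_codes, minlength=400).astype(float)
        out[bi * 400 : (bi + 1) * 400] = block / (len(seq) - k - 1)
    return out


def _ctd_group_indices(seq: str, groups: tuple[str, str, str]) -> np.ndarray:
    lookup = {}
    for gi, grp in enumerate(groups):
        for aa in grp:
            lookup[aa] = gi
    return np.array([lookup[ch] for ch in seq])


def encode_ctd(seq: str) -> np.ndarray:
    """Composition/Transition/Distribution descriptor (13 properties, 273 dims).

    Composition: the fraction of residues in each of the 3 groups (39).
    Transition: the fraction of adjacent pairs crossing each unordered group
    pair (1,2), (1,3), (2,3), denominator L-1 (39).  Distribution: for each
    group, the percent positions (of L) of the 1st, 25%, 50%, 75% and 100%
    occurrence; an absent group contributes five zeros (195).
    """
    L = len(seq)
    if L < 2:
        raise ValueError("CTD requires sequence length >= 2")
    comp, trans, dist = [], [], []
    for groups in CTD_PROPERTY_GROUPS.values():
        g = _ctd_group_indices(seq, groups)
        for gi in range(3):
            comp.append(float(np.mean(g == gi)))
        pairs = list(zip(g[:-1], g[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            n = sum(1 for x, y in pairs if {x, y} == {a, b})
            trans.append(n / (L - 1))
        for gi in range(3):
            positions = np.flatnonzero(g == gi) + 1  # 1-based
            if positions.size == 0:
                dist.extend([0.0] * 5)
                continue
            cnt = positions.size
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(1, int(np.ceil(frac * cnt)))
                dist.append(positions[rank - 1] / L * 100.0)
    return np.array(comp + trans + dist)


def encode_ctriad(seq: str) -> np.ndarray:
    """Conjoint triad: frequencies of all 7^3 class triples over L-2 windows."""
    L = len(seq)
    if L < 3:
        raise ValueError("conjoint triad requires sequence length >= 3")
    cls = np.array([_CTRIAD_CLASS_OF[ch] for ch in seq])
    codes = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    counts = np.bincount(codes, minlength=343).astype(float)
    return counts / (L - 2)


def encode_protein(rec: ProteinRecord) -> FeatureVector:
    """Concatenate AAC|CKSAAP|CTD|CTriad into the 3036-dim vector."""
    try:
        values = np.concatenate(
            [
                encode_aac(rec.sequence),
                encode_cksaap(rec.sequence),
                encode_ctd(rec.sequence),
                encode_ctriad(rec.sequence),
            ]
        )
    except ValueError as exc:
        raise ValueError(f"record {rec.id!r}: {exc}") from exc
    assert values.shape == (TOTAL_DIM,)
    return FeatureVector(values=values)


@dataclass
class PcaModel:
    """Fitted PCA basis: input-space mean, orthonormal components, d."""

    mean: np.ndarray
    components: np.ndarray  # (d, input_dim)
    d: int
    explained_variance: np.ndarray | None = None
    encoder_version: str = ENCODER_VERSION

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z @ self.components + self.mean

    def save(self, path) -> None:
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            d=np.array(self.d),
            explained_variance=(
                self.explained_variance
                if self.explained_variance is not None
                else np.array([])
            ),
            encoder_version=np.array(self.encoder_version),
        )

    @classmethod
    def load(cls, path) -> "PcaModel":
        with np.load(path, allow_pickle=False) as z:
            ev = z["explained_variance"]
            return cls(
                mean=z["mean"],
                components=z["components"],
                d=int(z["d"]),
                explained_variance=ev if ev.size else None,
                encoder_version=str(z["encoder_version"]),
            )


def fit_pca(X: np.ndarray, d: int = 200) -> PcaModel:
    """Fit PCA on the union of all protein feature vectors.

    A single latent space is fitted jointly for ligands and receptors so the
    two halves of a pair vector are commensurable.  Component signs follow a
    fixed convention (largest-magnitude loading positive) so the fit is
    deterministic for a given X.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    if not (1 <= d <= min(X.shape)):
        raise ValueError(
            f"d={d} must be in [1, min(n_rows, n_cols)={min(X.shape)}]"
        )
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return PcaModel(
        mean=pca.mean_,
        components=components,
        d=d,
        explained_variance=pca.explained_variance_.copy(),
    )


def make_pair_vector(lvec: np.ndarray, rvec: np.ndarray) -> np.ndarray:
    """Concatenate reduced ligand and receptor vectors (ligand block first)."""
    lvec = np.ravel(np.asarray(lvec, dtype=float))
    rvec = np.ravel(np.asarray(rvec, dtype=float))
    if lvec.shape != rvec.shape:
        raise ValueError(
            f"ligand/receptor vector length mismatch: {lvec.size} vs {rvec.size}"
        )
    return np.concatenate([lvec, rvec])


def make_pair_feature(
    ligand_id: str,
    receptor_id: str,
    lvec: np.ndarray,
    rvec: np.ndarray,
    y: int | None = None,
) -> PairFeature:
    return PairFeature(
        ligand_id=ligand_id,
        receptor_id=receptor_id,
        x=make_pair_vector(lvec, rvec),
        y=y,
    )


def cksaap_pair_names() -> list[str]:
    """Column names for the CKSAAP block, gap-major then pair order."""
    names = []
    for k in CKSAAP_GAPS:
        for a, b in itertools.product(ALPHABET, repeat=2):
            names.append(f"CKSAAP.gap{k}.{a}{b}")
    return names


def feature_names() -> list[str]:
    """Names for all 3036 columns, block order AAC|CKSAAP|CTD|CTriad."""
    names = [f"AAC.{aa}" for aa in ALPHABET]
    names += cksaap_pair_names()
    for part in ("C", "T", "D"):
        for prop in CTD_PROPERTY_GROUPS:
            if part == "C":
                names += [f"CTD.C.{prop}.g{g}" for g in (1, 2, 3)]
            elif part == "T":
                names += [f"CTD.T.{prop}.{t}" for t in ("12", "13", "23")]
            else:
                names += [
                    f"CTD.D.{prop}.g{g}.{pct}"
                    for g in (1, 2, 3)
                    for pct in ("first", "25", "50", "75", "100")
                ]
    names += [
        f"CTriad.{a}{b}{c}"
        for a in range(1, 8)
        for b in range(1, 8)
        for c in range(1, 8)
    ]
    assert len(names) == TOTAL_DIM
    return names
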