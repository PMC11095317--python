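"""Cell-cell communication strength from filtered ligand-receptor pairs.

Given a genes x cells expression matrix with one cell-type label per cell,
each surviving LRI (ligand u, receptor w) is scored for every ordered
sender/receiver type pair (C_j, C_p) under three schemes:

- cell expression: fraction of C_j cells expressing u times fraction of C_p
  cells expressing w ("expressed" = value strictly positive);
- expression product: mean expression of u over all C_j cells times mean
  expression of w over all C_p cells (zeros included in the means);
- specific expression: each mean normalized by its row sum over all m types
  before the product, rewarding type-restricted expression.

Summing per-LRI scores gives three m x m matrices, each min-max normalized
over its entries, and the final communication strength is the PERT
three-point estimate (max + 4*median + min) / 6 taken element-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THETA = 0.99
METHODS = ("cell_expression", "expression_product", "specific_expression")


class ExpressionDataset:
    """Genes x cells matrix plus a cell-type label per cell."""

    def __init__(
        self,
        matrix: pd.DataFrame,
        cell_types: pd.Series,
    ) -> None:
        if matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if not matrix.columns.equals(cell_types.index):
            cell_types = cell_types.reindex(matrix.columns)
            if cell_types.isna().any():
                missing = cell_types.index[cell_types.isna()].tolist()[:5]
                raise ValueError(f"cells without a type label, e.g. {missing}")
        if (np.asarray(matrix.values) < 0).any():
            raise ValueError("expression values must be non-negative")
        self.matrix = matrix
        self.cell_types = cell_types.astype(str)
        self.types: list[str] = sorted(self.cell_types.unique())

    @property
    def m(self) -> int:
        return len(self.types)

    def cells_of(self, cell_type: str) -> pd.Index:
        if cell_type not in self.types:
            raise KeyError(f"unknown cell type {cell_type!r}")
        return self.cell_types.index[self.cell_types == cell_type]

    # -- summaries used by the scoring schemes ---------------------------
    def expressed_fraction(self, gene: str) -> pd.Series:
        """Per type: fraction of cells with strictly positive expression."""
        expressed = (self.matrix.loc[gene] > 0).astype(float)
        return expressed.groupby(self.cell_types).mean().reindex(self.types)

    def mean_expression(self, gene: str) -> pd.Series:
        """Per type: arithmetic mean over all cells of the type."""
        return (
            self.matrix.loc[gene].groupby(self.cell_types).mean().reindex(self.types)
        )

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(
        cls, matrix_path, types_path, sep: str | None = None
    ) -> "ExpressionDataset":
        """Dense genes x cells table + two-column (cell_id, cell_type) sidecar."""
        matrix_path, types_path = Path(matrix_path), Path(types_path)
        msep = sep or ("\t" if matrix_path.suffix in (".tsv", ".txt") else ",")
        matrix = pd.read_csv(matrix_path, sep=msep, index_col=0)
        tsep = sep or ("\t" if types_path.suffix in (".tsv", ".txt") else ",")
        types = pd.read_csv(types_path, sep=tsep, index_col=0).iloc[:, 0]
        types.index = types.index.astype(str)
        matrix.columns = matrix.columns.astype(str)
        return cls(matrix, types)

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, cells_path, types_path) -> "ExpressionDataset":
        from scipy.io import mmread

        mat = mmread(mtx_path).toarray()
        genes = pd.read_csv(genes_path, header=None).iloc[:, 0].astype(str)
        cells = pd.read_csv(cells_path, header=None).iloc[:, 0].astype(str)
        matrix = pd.DataFrame(mat, index=genes, columns=cells)
        types = pd.read_csv(types_path, sep="\t", index_col=0).iloc[:, 0]
        types.index = types.index.astype(str)
        return cls(matrix, types)

    def to_csv(self, matrix_path, types_path) -> None:
        sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
        self.matrix.to_csv(matrix_path, sep=sep)
        self.cell_types.rename("cell_type").to_csv(
            types_path, sep="\t", index_label="cell_id"
        )


@dataclass(frozen=True)
class ScoredLri:
    """A ligand-receptor pair with an interaction probability and provenance."""

    ligand: str
    receptor: str
    probability: float | None = None
    source: str = "predicted"  # or "known"

    def __post_init__(self) -> None:
        if self.source not in ("known", "predicted"):
            raise ValueError(f"bad source {self.source!r}")
        if self.source == "predicted" and self.probability is None:
            raise ValueError("predicted LRIs need a probability")


@dataclass
class CCCResult:
    """Per-method, normalized and final m x m score matrices plus rankings."""

    methods: dict[str, pd.DataFrame]
    normalized: dict[str, pd.DataFrame]
    final: pd.DataFrame
    lris: list[ScoredLri]
    # contributions[method] is a DataFrame indexed by "ligand->receptor" with
    # one column per ordered (sender, receiver) pair "Cj->Cp"
    contributions: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def types(self) -> list[str]:
        return list(self.final.index)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "source_type": j,
                "target_type": p,
                "weight": self.final.loc[j, p],
                "n_LRIs": len(self.lris),
            }
            for j in self.types
            for p in self.types
        ]
        return pd.DataFrame(rows)


def filter_lris(
    lris: list[ScoredLri],
    theta: float,
    expr: ExpressionDataset,
) -> list[ScoredLri]:
    """Keep predicted LRIs with probability strictly above theta, require both
    genes present and expressed in at least one cell, and deduplicate on
    (ligand, receptor) preferring source=known."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta={theta} outside [0, 1]")
    expressed_any = (expr.matrix > 0).any(axis=1)
    seen: dict[tuple[str, str], ScoredLri] = {}
    for lri in lris:
        if lri.source == "predicted" and not lri.probability > theta:
            continue
        if lri.ligand not in expr.matrix.index or lri.receptor not in expr.matrix.index:
            continue
        if not (expressed_any[lri.ligand] and expressed_any[lri.receptor]):
            continue
        key = (lri.ligand, lri.receptor)
        if key not in seen or (lri.source == "known" and seen[key].source != "known"):
            seen[key] = lri
    kept = list(seen.values())
    if not kept:
        logger.warning("no LRIs survive filtering; CCC scores will be zero")
    return kept


def score_cell_expression(
    u: str, w: str, j: str, p: str, expr: ExpressionDataset
) -> float:
    """(expressing cells of u in C_j / n_j) x (expressing cells of w in C_p / n_p)."""
    return float(expr.expressed_fraction(u)[j] * expr.expressed_fraction(w)[p])


def score_product(u: str, w: str, j: str, p: str, expr: ExpressionDataset) -> float:
    """Mean ligand expression in the sender type times mean receptor expression
    in the receiver type."""
    return float(expr.mean_expression(u)[j] * expr.mean_expression(w)[p])


def score_specific(u: str, w: str, j: str, p: str, expr: ExpressionDataset) -> float:
    """Type-specificity product: each mean normalized by its sum over all types;
    zero when a gene has zero mean everywhere."""
    L = expr.mean_expression(u)
    R = expr.mean_expression(w)
    lf = L[j] / L.sum() if L.sum() > 0 else 0.0
    rf = R[p] / R.sum() if R.sum() > 0 else 0.0
    return float(lf * rf)


def _per_lri_grid(
    method: str, lri: ScoredLri, expr: ExpressionDataset
) -> np.ndarray:
    """m x m score grid of one LRI over all ordered (sender, receiver) pairs."""
    u, w = lri.ligand, lri.receptor
    if method == "cell_expression":
        lv = expr.expressed_fraction(u).to_numpy()
        rv = expr.expressed_fraction(w).to_numpy()
    elif method == "expression_product":
        lv = expr.mean_expression(u).to_numpy()
        rv = expr.mean_expression(w).to_numpy()
    elif method == "specific_expression":
        L = expr.mean_expression(u).to_numpy()
        R = expr.mean_expression(w).to_numpy()
        lv = L / L.sum() if L.sum() > 0 else np.zeros_like(L)
        rv = R / R.sum() if R.sum() > 0 else np.zeros_like(R)
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.outer(lv, rv)


def ccc_matrix(
    method: str, expr: ExpressionDataset, lris: list[ScoredLri]
) -> pd.DataFrame:
    """Sum of per-LRI grids over the filtered set; all ordered type pairs."""
    total = np.zeros((expr.m, expr.m))
    for lri in lris:
        total += _per_lri_grid(method, lri, expr)
    return pd.DataFrame(total, index=expr.types, columns=expr.types)


def minmax_normalize(M: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """(x - min) / (max - min) over all entries; a constant matrix maps to 0."""
    values = M.to_numpy() if isinstance(M, pd.DataFrame) else np.asarray(M, float)
    lo, hi = values.min(), values.max()
    out = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def three_point(g1: float, g2: float, g3: float) -> float:
    """PERT estimate (max + 4*median + min) / 6 of three values."""
    lo, med, hi = sorted((g1, g2, g3))
    return (hi + 4.0 * med + lo) / 6.0


def infer_ccc(
    expr: ExpressionDataset,
    lris: list[ScoredLri],
    theta: float = DEFAULT_THETA,
) -> CCCResult:
    """Filter LRIs, build the three per-method matrices, normalize each with
    min-max scaling, and combine element-wise by the three-point estimate.

    Per-LRI contribution grids are retained for ranking via :func:`top_lris`.
    """
    if expr.m < 2:
        raise ValueError("need at least 2 cell types for CCC inference")
    kept = filter_lris(lris, theta, expr)
    methods: dict[str, pd.DataFrame] = {}
    contributions: dict[str, pd.DataFrame] = {}
    pair_cols = [f"{j}->{p}" for j in expr.types for p in expr.types]
    for method in METHODS:
        grids = {
            f"{l.ligand}->{l.receptor}": _per_lri_grid(method, l, expr).ravel()
            for l in kept
        }
        contrib = pd.DataFrame.from_dict(
            grids, orient="index", columns=pair_cols
        )
        contributions[method] = contrib
        total = (
            contrib.to_numpy().sum(axis=0).reshape(expr.m, expr.m)
            if kept
            else np.zeros((expr.m, expr.m))
        )
        methods[method] = pd.DataFrame(total, index=expr.types, columns=expr.types)
    normalized = {k: minmax_normalize(v) for k, v in methods.items()}
    g = np.stack([normalized[k].to_numpy() for k in METHODS])
    g_sorted = np.sort(g, axis=0)
    final = (g_sorted[2] + 4.0 * g_sorted[1] + g_sorted[0]) / 6.0
    return CCCResult(
        methods=methods,
        normalized=normalized,
        final=pd.DataFrame(final, index=expr.types, columns=expr.types),
        lris=kept,
        contributions=contributions,
    )


def top_lris(
    result: CCCResult, j: str, p: str, k: int = 10
) -> dict[str, pd.Series]:
    """Top-k LRIs for the ordered type pair (j, p), per method and combined.

    The combined ranking applies the three-point estimate to the three
    per-LRI scores after min-max normalizing each method's scores across the
    LRIs of this pair.  Ties break by (score desc, ligand asc, receptor asc).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    col = f"{j}->{p}"
    if not result.contributions or col not in result.contributions[METHODS[0]].columns:
        raise KeyError(f"unknown type pair ({j!r}, {p!r})")
    out: dict[str, pd.Series] = {}
    per_method = {}
    for method in METHODS:
        scores = result.contributions[method][col]
        out[method] = _ranked(scores, k)
        per_method[method] = minmax_normalize(
            scores.to_numpy().reshape(-1, 1)
        ).ravel()
    if len(result.lris) > 0:
        g = np.stack([per_method[m] for m in METHODS])
        g_sorted = np.sort(g, axis=0)
        combined = pd.Series(
            (g_sorted[2] + 4.0 * g_sorted[1] + g_sorted[0]) / 6.0,
            index=result.contributions[METHODS[0]].index,
        )
    else:
        combined = pd.Series(dtype=float)
    out["combined"] = _ranked(combined, k)
    return out


def _ranked(scores: pd.Series, k: int) -> pd.Series:
    if scores.empty:
        return pd.Series(dtype=float)
    frame = scores.rename("score").reset_index()
    parts = frame["index"].str.split("->", expand=True)
    frame["ligand"], frame["receptor"] = parts[0], parts[1]
    frame = frame.sort_values(
        by=["score", "ligand", "receptor"], ascending=[False, True, True]
    )
    top = frame.head(k)
    return pd.Series(top["score"].to_numpy(), index=top["index"].to_numpy())
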