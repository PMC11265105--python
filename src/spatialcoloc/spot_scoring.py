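"""Single-sample gene-set enrichment scores and top-quartile positivity.

A spot's score for a cell type is the running-sum enrichment of the type's
marker set in the spot's expression ranking; positivity is called per type
at the nearest-rank quantile with a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from spatialcoloc.errors import (
    DegenerateSetError,
    GeneSetNotMeasuredError,
    ValidationError,
)
from spatialcoloc.synthgen import ExpressionMatrix

DEFAULT_ALPHA = 0.25
DEFAULT_QUANTILE = 0.75


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; order within a set is preserved."""

    sets: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-spot, per-cell-type enrichment scores (spots x cell_types)."""

    spots: tuple[str, ...]
    cell_types: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.spots), len(self.cell_types)):
            raise ValidationError("score matrix shape inconsistent with labels")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite")


@dataclass(frozen=True)
class PositivityCalls:
    """Boolean positivity per spot and cell type, thresholds recorded."""

    spots: tuple[str, ...]
    cell_types: tuple[str, ...]
    positive: np.ndarray
    quantile: float
    thresholds: tuple[float, ...]

    def __post_init__(self):
        pos = np.asarray(self.positive, dtype=bool)
        object.__setattr__(self, "positive", pos)
        if pos.shape != (len(self.spots), len(self.cell_types)):
            raise ValidationError("positivity shape inconsistent with labels")
        if len(self.thresholds) != len(self.cell_types):
            raise ValidationError("one threshold per cell type required")

    def column(self, cell_type: str) -> np.ndarray:
        return self.positive[:, self.cell_types.index(cell_type)]


def _rank_weights(n: int, alpha: float) -> np.ndarray:
    # descending-rank weight: top-expressed gene gets n, last gets 1
    return np.arange(n, 0, -1, dtype=float) ** alpha


def ssgsea_score(
    expression: Sequence[float],
    genes: Sequence[str],
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Running-sum enrichment of ``gene_set`` in one spot's expression.

    Genes are ranked by descending expression (ties broken by the stable
    input gene order). The score accumulates, along the ranking, the gap
    between the weighted in-set ECDF (steps weighted by descending-rank
    weight ** alpha) and the unweighted out-of-set ECDF.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    if len(gene_set) == 0:
        raise ValidationError("gene set is empty")
    genes = list(genes)
    expr = np.asarray(expression, dtype=float)
    if expr.shape != (len(genes),):
        raise ValidationError("expression vector length must match gene list")

    in_set = np.array([g in set(gene_set) for g in genes])
    k = int(in_set.sum())
    if k == 0:
        raise GeneSetNotMeasuredError("gene set not measured")
    if k == len(genes):
        raise DegenerateSetError(
            "degenerate set: complement within measured genes is empty"
        )

    order = np.argsort(-expr, kind="stable")
    in_ordered = in_set[order]
    n = len(genes)
    w = _rank_weights(n, alpha)

    num = np.where(in_ordered, w, 0.0)
    p_in = np.cumsum(num) / num.sum()
    p_out = np.cumsum(~in_ordered) / float(n - k)
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    alpha: float = DEFAULT_ALPHA,
) -> ScoreMatrix:
    """Apply ``ssgsea_score`` to every (spot, set); columns follow set order."""
    if not isinstance(sets, GeneSetCollection):
        sets = GeneSetCollection({k: tuple(v) for k, v in sets.items()})
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")

    genes = list(expr.genes)
    n = len(genes)
    counts = np.asarray(expr.counts, dtype=float)  # genes x spots
    # one stable descending ranking per spot, shared by all sets
    order = np.argsort(-counts, axis=0, kind="stable")  # genes x spots
    w = _rank_weights(n, alpha)

    out = np.empty((len(expr.spots), len(sets.names)))
    for j, name in enumerate(sets.names):
        members = set(sets.sets[name])
        in_set = np.array([g in members for g in genes])
        k = int(in_set.sum())
        if k == 0:
            raise GeneSetNotMeasuredError(f"gene set not measured: {name!r}")
        if k == n:
            raise DegenerateSetError(f"degenerate set: {name!r} covers all genes")
        in_ordered = in_set[order]  # genes x spots
        num = np.where(in_ordered, w[:, None], 0.0)
        p_in = np.cumsum(num, axis=0) / num.sum(axis=0)
        p_out = np.cumsum(~in_ordered, axis=0) / float(n - k)
        out[:, j] = np.sum(p_in - p_out, axis=0)

    return ScoreMatrix(
        spots=tuple(expr.spots), cell_types=tuple(sets.names), scores=out
    )


def nearest_rank_quantile(values: np.ndarray, quantile: float) -> float:
    """Nearest-rank quantile: smallest value with >= ceil(q*n) values <= it."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    k = int(np.ceil(quantile * n))
    k = min(max(k, 1), n)
    return float(values[k - 1])


def call_positivity(
    scores: ScoreMatrix, quantile: float = DEFAULT_QUANTILE
) -> PositivityCalls:
    """Positive iff score strictly exceeds the per-type nearest-rank quantile."""
    if not 0 < quantile < 1:
        raise ValidationError("quantile must lie strictly between 0 and 1")
    if len(scores.spots) < 2:
        raise ValidationError("at least 2 spots required for positivity calls")

    thresholds = tuple(
        nearest_rank_quantile(scores.scores[:, j], quantile)
        for j in range(len(scores.cell_types))
    )
    positive = scores.scores > np.array(thresholds)[None, :]
    return PositivityCalls(
        spots=scores.spots,
        cell_types=scores.cell_types,
        positive=positive,
        quantile=quantile,
        thresholds=thresholds,
    )
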