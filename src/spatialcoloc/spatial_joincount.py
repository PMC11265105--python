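"""Join-count quantification of spatial dependency between cell-type pairs.

Spots positive for exactly one type of a pair keep that type; co-positive
spots are resolved by coordinate parity (x + y even vs odd); the observed
count of adjacent heterogeneous (A-B) pairs is compared with a
label-permutation null (or the closed-form nonfree-sampling moments) and
expressed as a z-score, significant at |z| >= 3 by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from spatialcoloc.errors import DegenerateNullError, ValidationError
from spatialcoloc.spot_scoring import PositivityCalls
from spatialcoloc.synthgen import SpotGrid

LABEL_BG, LABEL_A, LABEL_B = 0, 1, 2
DEFAULT_Z_CUTOFF = 3.0


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected lattice adjacency; edges as index pairs into grid spots."""

    scheme: str
    spot_ids: tuple[str, ...]
    edge_index: np.ndarray  # (m, 2) int, i < j, lexicographically ordered

    def __post_init__(self):
        e = np.asarray(self.edge_index, dtype=int).reshape(-1, 2)
        object.__setattr__(self, "edge_index", e)
        if np.any(e[:, 0] == e[:, 1]):
            raise ValidationError("self-edge in adjacency graph")

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.spot_ids[i], self.spot_ids[j]) for i, j in self.edge_index
        ]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.spot_ids), dtype=int)
        np.add.at(deg, self.edge_index[:, 0], 1)
        np.add.at(deg, self.edge_index[:, 1], 1)
        return deg


@dataclass(frozen=True)
class LabeledLattice:
    """Per-spot label in {A, B, BG} for one cell-type pair."""

    grid_ref: SpotGrid
    pair: tuple[str, str]
    labels: np.ndarray  # int codes LABEL_BG/LABEL_A/LABEL_B per spot
    assignment_record: tuple[str, ...]

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        if lab.shape != (self.grid_ref.n_spots,):
            raise ValidationError("one label per spot required")
        if len(self.assignment_record) != self.grid_ref.n_spots:
            raise ValidationError("one assignment record per spot required")

    def counts(self) -> tuple[int, int, int]:
        """(n_A, n_B, n_BG)."""
        return (
            int(np.sum(self.labels == LABEL_A)),
            int(np.sum(self.labels == LABEL_B)),
            int(np.sum(self.labels == LABEL_BG)),
        )


@dataclass(frozen=True)
class JoinCountResult:
    pair: tuple[str, str]
    j_obs: int
    null_mean: float
    null_sd: float
    z: Optional[float]
    p_perm: Optional[float]
    n_perm: int
    significant: bool
    method: str
    z_cutoff: float = DEFAULT_Z_CUTOFF
    note: str = ""


@dataclass
class JoinCountConfig:
    scheme: str = "rook"
    null_method: str = "permutation"  # or "analytic"
    n_perm: int = 999
    z_cutoff: float = DEFAULT_Z_CUTOFF
    even_gets: str = "A"
    permute_bg: bool = True  # BG spots take part in the permutation null
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("rook", "queen"):
            raise ValidationError(f"unknown adjacency scheme {self.scheme!r}")
        if self.null_method not in ("permutation", "analytic"):
            raise ValidationError(f"unknown null method {self.null_method!r}")
        if self.even_gets not in ("A", "B"):
            raise ValidationError("even_gets must be 'A' or 'B'")


# ---------------------------------------------------------------------------


def build_adjacency(grid: SpotGrid, scheme: str = "rook") -> AdjacencyGraph:
    """rook = 4-neighbourhood, queen = 8-neighbourhood on the lattice."""
    if scheme == "rook":
        offsets = [(1, 0), (0, 1)]
    elif scheme == "queen":
        offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
    else:
        raise ValidationError(f"unknown adjacency scheme {scheme!r}")

    index = {(x, y): i for i, (_, x, y) in enumerate(grid.spots)}
    edges = []
    for i, (_, x, y) in enumerate(grid.spots):
        for dx, dy in offsets:
            j = index.get((x + dx, y + dy))
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    edges.sort()
    edge_index = (
        np.array(edges, dtype=int) if edges else np.empty((0, 2), dtype=int)
    )
    return AdjacencyGraph(
        scheme=scheme, spot_ids=tuple(grid.spot_ids), edge_index=edge_index
    )


def assign_pair_labels(
    calls: PositivityCalls,
    pair: tuple[str, str],
    grid: SpotGrid,
    even_gets: str = "A",
) -> LabeledLattice:
    """Resolve co-positive spots by the parity of x + y.

    Spots positive only for the first type get A, only the second get B,
    neither get BG. A co-positive spot at (x, y) gets ``even_gets`` when
    x + y is even and the other type when odd.
    """
    type_a, type_b = pair
    for t in pair:
        if t not in calls.cell_types:
            raise ValidationError(f"cell type {t!r} absent from calls")
    if even_gets not in ("A", "B"):
        raise ValidationError("even_gets must be 'A' or 'B'")

    call_index = {s: i for i, s in enumerate(calls.spots)}
    missing = [sid for sid in grid.spot_ids if sid not in call_index]
    if missing:
        raise ValidationError(
            f"grid spots missing from positivity calls: {missing[:5]}"
        )

    pos_a = calls.column(type_a)
    pos_b = calls.column(type_b)

    labels = np.empty(grid.n_spots, dtype=int)
    record = []
    for i, (sid, x, y) in enumerate(grid.spots):
        ci = call_index[sid]
        a, b = bool(pos_a[ci]), bool(pos_b[ci])
        if a and b:
            even = (x + y) % 2 == 0
            take_a = (even_gets == "A") == even
            labels[i] = LABEL_A if take_a else LABEL_B
            record.append("both_even" if even else "both_odd")
        elif a:
            labels[i] = LABEL_A
            record.append("only_a")
        elif b:
            labels[i] = LABEL_B
            record.append("only_b")
        else:
            labels[i] = LABEL_BG
            record.append("neither")

    return LabeledLattice(
        grid_ref=grid, pair=pair, labels=labels, assignment_record=tuple(record)
    )


def _hetero_count(labels: np.ndarray, ei: np.ndarray, ej: np.ndarray) -> int:
    la, lb = labels[ei], labels[ej]
    return int(
        np.sum(
            ((la == LABEL_A) & (lb == LABEL_B))
            | ((la == LABEL_B) & (lb == LABEL_A))
        )
    )


def observed_joins(labels: LabeledLattice, graph: AdjacencyGraph) -> int:
    """Number of edges with one A and one B endpoint (BG edges never count)."""
    if graph.spot_ids != tuple(labels.grid_ref.spot_ids):
        raise ValidationError("labels and graph built on different grids")
    e = graph.edge_index
    if len(e) == 0:
        return 0
    return _hetero_count(labels.labels, e[:, 0], e[:, 1])


def permutation_null(
    labels: LabeledLattice,
    graph: AdjacencyGraph,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Nonfree-sampling null: labels permuted over all spots.

    Returns (null_mean, null_sd, p_perm) with the add-one two-sided
    permutation p-value. Raises DegenerateNullError for single-class
    labelings and for forced (zero-variance) nulls.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    n_a, n_b, _ = labels.counts()
    if n_a < 1 or n_b < 1:
        raise DegenerateNullError("null degenerate: fewer than one A or one B")

    j_obs = observed_joins(labels, graph)
    e = graph.edge_index
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(labels.labels, (n_perm, 1)), axis=1
    )  # n_perm x n
    la = perms[:, e[:, 0]]
    lb = perms[:, e[:, 1]]
    j_null = (
        ((la == LABEL_A) & (lb == LABEL_B))
        | ((la == LABEL_B) & (lb == LABEL_A))
    ).sum(axis=1)

    null_mean = float(j_null.mean())
    null_sd = float(j_null.std(ddof=1))
    dev = np.abs(j_null - null_mean)
    p_perm = float((1 + np.sum(dev >= abs(j_obs - null_mean))) / (n_perm + 1))

    if null_sd == 0.0:
        raise DegenerateNullError(
            "null degenerate: permutation distribution has zero variance",
            null_mean=null_mean,
            null_sd=0.0,
        )
    return null_mean, null_sd, p_perm


def analytic_null(
    labels: LabeledLattice, graph: AdjacencyGraph
) -> tuple[float, float]:
    """Closed-form mean and sd of the A-B join count under label permutation.

    Labels are sampled without replacement conditional on the observed
    (n_A, n_B, n_BG); BG acts as a third colour excluded from the join.
    Moments follow from edge-pair case analysis (shared endpoint vs
    disjoint), verified against exhaustive enumeration on small grids.
    """
    n_a, n_b, n_bg = labels.counts()
    n = labels.grid_ref.n_spots
    if n < 2:
        raise ValidationError("at least 2 spots required")
    if n_a < 1 or n_b < 1:
        raise DegenerateNullError("null degenerate: fewer than one A or one B")
    if graph.spot_ids != tuple(labels.grid_ref.spot_ids):
        raise ValidationError("labels and graph built on different grids")

    m = graph.n_edges
    deg = graph.degrees()
    # unordered edge pairs sharing exactly one endpoint, and disjoint pairs
    s_shared = float(np.sum(deg * (deg - 1) // 2))
    s_disjoint = m * (m - 1) / 2.0 - s_shared

    p1 = 2.0 * n_a * n_b / (n * (n - 1))
    mean = m * p1

    second = m * p1
    if s_shared > 0:
        p2 = n_a * n_b * (n_a + n_b - 2.0) / (n * (n - 1) * (n - 2))
        second += 2.0 * s_shared * p2
    if s_disjoint > 0:
        p3 = (
            4.0
            * n_a
            * (n_a - 1)
            * n_b
            * (n_b - 1)
            / (n * (n - 1) * (n - 2) * (n - 3))
        )
        second += 2.0 * s_disjoint * p3
    var = second - mean**2
    var = max(var, 0.0)  # guard tiny negative round-off
    return float(mean), float(np.sqrt(var))


def _restrict_to_positive(
    labels: LabeledLattice, graph: AdjacencyGraph
) -> tuple[LabeledLattice, AdjacencyGraph]:
    """Subgraph induced on non-BG spots, for the positive-only null option."""
    keep = np.flatnonzero(labels.labels != LABEL_BG)
    remap = {int(old): new for new, old in enumerate(keep)}
    spots = tuple(labels.grid_ref.spots[i] for i in keep)
    sub_grid = SpotGrid(
        n_rows=labels.grid_ref.n_rows,
        n_cols=labels.grid_ref.n_cols,
        spots=spots,
    )
    sub_labels = LabeledLattice(
        grid_ref=sub_grid,
        pair=labels.pair,
        labels=labels.labels[keep],
        assignment_record=tuple(labels.assignment_record[i] for i in keep),
    )
    kept_edges = [
        (remap[int(i)], remap[int(j)])
        for i, j in graph.edge_index
        if int(i) in remap and int(j) in remap
    ]
    edge_index = (
        np.array(kept_edges, dtype=int)
        if kept_edges
        else np.empty((0, 2), dtype=int)
    )
    sub_graph = AdjacencyGraph(
        scheme=graph.scheme,
        spot_ids=tuple(sub_grid.spot_ids),
        edge_index=edge_index,
    )
    return sub_labels, sub_graph


def joincount_z(
    calls: PositivityCalls,
    grid: SpotGrid,
    pair: tuple[str, str],
    config: Optional[JoinCountConfig] = None,
) -> JoinCountResult:
    """Full pipeline for one pair: labels -> adjacency -> joins -> null -> z.

    A degenerate null is reported as a not-computable result (z and p None,
    significant False), never as a silent zero.
    """
    config = config or JoinCountConfig()
    labels = assign_pair_labels(calls, pair, grid, even_gets=config.even_gets)
    graph = build_adjacency(grid, scheme=config.scheme)
    if not config.permute_bg:
        labels, graph = _restrict_to_positive(labels, graph)
    j_obs = observed_joins(labels, graph)

    p_perm = None
    try:
        if config.null_method == "permutation":
            null_mean, null_sd, p_perm = permutation_null(
                labels, graph, n_perm=config.n_perm, seed=config.seed
            )
        else:
            null_mean, null_sd = analytic_null(labels, graph)
    except DegenerateNullError as err:
        return JoinCountResult(
            pair=pair,
            j_obs=j_obs,
            null_mean=float("nan") if err.null_mean is None else err.null_mean,
            null_sd=0.0,
            z=None,
            p_perm=None,
            n_perm=config.n_perm if config.null_method == "permutation" else 0,
            significant=False,
            method=config.null_method,
            z_cutoff=config.z_cutoff,
            note=str(err),
        )

    if null_sd > 0:
        z = (j_obs - null_mean) / null_sd
        significant = abs(z) >= config.z_cutoff
    else:
        z, significant = None, False

    return JoinCountResult(
        pair=pair,
        j_obs=j_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_perm=p_perm,
        n_perm=config.n_perm if config.null_method == "permutation" else 0,
        significant=significant,
        method=config.null_method,
        z_cutoff=config.z_cutoff,
    )


def pairwise_joincount_matrix(
    calls: PositivityCalls,
    grid: SpotGrid,
    config: Optional[JoinCountConfig] = None,
) -> list[JoinCountResult]:
    """One JoinCountResult per unordered cell-type pair, lexicographic order."""
    if len(calls.cell_types) < 2:
        raise ValidationError("at least 2 cell types required")
    config = config or JoinCountConfig()
    pairs = list(itertools.combinations(sorted(calls.cell_types), 2))
    return [joincount_z(calls, grid, pair, config) for pair in pairs]
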