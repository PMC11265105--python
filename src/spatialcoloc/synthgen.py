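"""Synthetic lattices, abundance fields, count matrices and channel pairs.

Every generator is deterministic under its seed and carries enough ground
truth for downstream stages to be checked by parameter recovery or exact
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from spatialcoloc.errors import ValidationError

PATTERNS = ("aggregated", "dispersed", "random")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SpotGrid:
    """Square lattice of spots with 0-based integer coordinates.

    ``spots`` is a list of ``(spot_id, x, y)`` with ``x`` the column index
    and ``y`` the row index. Row-major order, ids stable and deterministic.
    The grid need not be full: readers may construct partial lattices.
    """

    n_rows: int
    n_cols: int
    spots: tuple[tuple[str, int, int], ...]
    geometry: str = "square"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.geometry != "square":
            raise ValidationError(f"unsupported geometry: {self.geometry!r}")
        ids = [s[0] for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate spot_id in grid")
        coords = [(s[1], s[2]) for s in self.spots]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate (x, y) coordinate in grid")
        for sid, x, y in self.spots:
            if not (0 <= x < self.n_cols and 0 <= y < self.n_rows):
                raise ValidationError(
                    f"spot {sid!r} at ({x}, {y}) outside grid bounds"
                )

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def spot_ids(self) -> list[str]:
        return [s[0] for s in self.spots]

    def coords(self) -> np.ndarray:
        """(n_spots, 2) array of (x, y)."""
        return np.array([(x, y) for _, x, y in self.spots], dtype=int)


@dataclass(frozen=True)
class AbundanceField:
    """One non-negative abundance value per spot of ``grid_ref``."""

    grid_ref: SpotGrid
    cell_type: str
    values: np.ndarray
    pattern: str
    truth_params: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.grid_ref.n_spots,):
            raise ValidationError("one abundance value per spot required")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValidationError("abundance values must be finite and >= 0")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Integer count matrix, genes x spots."""

    genes: tuple[str, ...]
    spots: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.genes), len(self.spots)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.spots)} spots"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be integer")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class ChannelImagePair:
    """Two aligned non-negative intensity channels with optional truth sums."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    truth: Optional[tuple[float, float, float, float]] = None
    # truth = (sum_a_total, sum_a_in_b, sum_b_total, sum_b_in_a)

    def __post_init__(self):
        a = np.asarray(self.channel_a, dtype=float)
        b = np.asarray(self.channel_b, dtype=float)
        object.__setattr__(self, "channel_a", a)
        object.__setattr__(self, "channel_b", b)
        if a.ndim != 2 or a.shape != b.shape:
            raise ValidationError("channels must be 2-D arrays of equal shape")
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError("intensities must be non-negative")
        if self.truth is not None:
            sa, sab, sb, sba = self.truth
            if not (0 <= sab <= sa and 0 <= sba <= sb):
                raise ValidationError("truth sums violate bound invariants")


# ---------------------------------------------------------------------------
# generators


def spot_id(x: int, y: int) -> str:
    return f"spot_{y}_{x}"


def gen_spot_lattice(n_rows: int, n_cols: int) -> SpotGrid:
    """Full rectangular lattice, row-major spot order, deterministic ids."""
    if n_rows < 1 or n_cols < 1:
        raise ValidationError("n_rows and n_cols must be >= 1")
    spots = tuple(
        (spot_id(x, y), x, y) for y in range(n_rows) for x in range(n_cols)
    )
    return SpotGrid(n_rows=n_rows, n_cols=n_cols, spots=spots)


def gen_celltype_field(
    grid: SpotGrid,
    cell_type: str,
    pattern: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> AbundanceField:
    """Abundance field with controllable spatial structure.

    aggregated
        Sum of isotropic Gaussian blobs. ``params``: ``centers`` (list of
        (x, y), default the grid centre), ``sigma`` (default 2.0),
        ``amplitude`` (default 1.0), ``binarize_quantile`` (optional q in
        (0, 1): threshold the field at its q-quantile to a 0/1 field).
    dispersed
        Unit mass on one half of the lattice, zero elsewhere. ``params``:
        ``side`` in {"low", "high"} (default "low") selecting the low- or
        high-x half of the columns.
    random
        I.i.d. gamma(2, 0.5) abundance.
    """
    params = dict(params or {})
    if pattern not in PATTERNS:
        raise ValidationError(
            f"unknown pattern {pattern!r}; expected one of {PATTERNS}"
        )
    rng = np.random.default_rng(seed)
    coords = grid.coords().astype(float)

    if pattern == "random":
        values = rng.gamma(shape=2.0, scale=0.5, size=grid.n_spots)
    elif pattern == "dispersed":
        side = params.setdefault("side", "low")
        if side not in ("low", "high"):
            raise ValidationError("dispersed side must be 'low' or 'high'")
        half = grid.n_cols / 2.0
        if side == "low":
            values = (coords[:, 0] < half).astype(float)
        else:
            values = (coords[:, 0] >= half).astype(float)
    else:  # aggregated
        centers = params.setdefault(
            "centers", [((grid.n_cols - 1) / 2.0, (grid.n_rows - 1) / 2.0)]
        )
        sigma = float(params.setdefault("sigma", 2.0))
        amplitude = float(params.setdefault("amplitude", 1.0))
        if sigma <= 0:
            raise ValidationError("sigma must be positive")
        values = np.zeros(grid.n_spots)
        for cx, cy in centers:
            d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
            values += amplitude * np.exp(-d2 / (2.0 * sigma**2))
        q = params.get("binarize_quantile")
        if q is not None:
            if not 0 < q < 1:
                raise ValidationError("binarize_quantile must be in (0, 1)")
            values = (values > np.quantile(values, q)).astype(float)

    params["seed"] = seed
    return AbundanceField(
        grid_ref=grid,
        cell_type=cell_type,
        values=values,
        pattern=pattern,
        truth_params=params,
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance = mean + mean^2 / dispersion."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def gen_expression_matrix(
    grid: SpotGrid,
    fields: Sequence[AbundanceField],
    marker_sets: Mapping[str, Sequence[str]],
    baseline_mean: float = 5.0,
    effect_size: float = 5.0,
    dispersion: float = 10.0,
    seed: int = 0,
    n_background: int = 100,
) -> ExpressionMatrix:
    """Marker counts NB-distributed with mean baseline*(1 + effect*abundance).

    Background genes (``BG0001``...) sit at ``baseline_mean`` everywhere and
    must be disjoint from every marker list.
    """
    if baseline_mean <= 0 or dispersion <= 0:
        raise ValidationError("baseline_mean and dispersion must be positive")
    for f in fields:
        if f.cell_type not in marker_sets:
            raise ValidationError(
                f"no marker set for cell type {f.cell_type!r}"
            )
        if f.grid_ref is not grid and f.grid_ref != grid:
            raise ValidationError("field grid does not match target grid")

    marker_genes: list[str] = []
    for ct in marker_sets:
        for g in marker_sets[ct]:
            if g in marker_genes:
                raise ValidationError(f"marker gene {g!r} used by two sets")
            marker_genes.append(g)
    background = [f"BG{i + 1:04d}" for i in range(n_background)]
    overlap = set(marker_genes) & set(background)
    if overlap:
        raise ValidationError(f"marker genes collide with background pool: {overlap}")

    genes = tuple(marker_genes + background)
    n_spots = grid.n_spots
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(genes), n_spots), dtype=np.int64)

    abundance = {f.cell_type: f.values for f in fields}
    row = 0
    for ct in marker_sets:
        ab = abundance.get(ct, np.zeros(n_spots))
        mean = baseline_mean * (1.0 + effect_size * ab)
        for _ in marker_sets[ct]:
            counts[row] = _nb_counts(rng, mean, dispersion)
            row += 1
    base = np.full(n_spots, baseline_mean)
    for _ in background:
        counts[row] = _nb_counts(rng, base, dispersion)
        row += 1

    return ExpressionMatrix(genes=genes, spots=tuple(grid.spot_ids), counts=counts)


def _pow2_floor(n: int) -> int:
    return 1 << (n.bit_length() - 1)


def _scaled_pow2(base: int, ratio: float) -> int:
    """``base`` scaled by the power of two nearest to ``ratio``, >= 1."""
    k = int(round(np.log2(ratio)))
    if k >= 0:
        return base << k
    return max(base >> (-k), 1)


def _block_sizes(n_pix: int, frac_a: float, frac_b: float):
    """Pick power-of-two block sizes (a_only, overlap, b_only) that fit.

    Out-block sizes track (1 - frac)/frac so per-pixel levels within a
    channel stay within a factor of sqrt(2); power-of-two sizes keep the
    per-pixel values dyadic divisions that re-sum exactly.
    """
    no_overlap = frac_a == 0.0
    n2 = _pow2_floor(max(n_pix // 4, 1))
    while n2 >= 1:
        if no_overlap:
            n1 = n3 = n2
            if 2 * n2 <= n_pix:
                return n1, 0, n3
        else:
            n1 = _scaled_pow2(n2, (1.0 - frac_a) / frac_a) if frac_a < 1 else 0
            n3 = _scaled_pow2(n2, (1.0 - frac_b) / frac_b) if frac_b < 1 else 0
            if n1 + n2 + n3 <= n_pix:
                return n1, n2, n3
        n2 //= 2
    raise ValidationError(
        f"infeasible overlap: fractions ({frac_a}, {frac_b}) do not fit an "
        f"image of {n_pix} pixels"
    )


def gen_channel_pair(
    shape: tuple[int, int],
    sum_a_total: float,
    frac_a_in_b: float,
    sum_b_total: float,
    frac_b_in_a: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ChannelImagePair:
    """Two-channel image with exactly known overlap fractions.

    Three disjoint pixel blocks carry A-only, overlapping, and B-only
    signal; with ideal support masks and zero noise the downstream Manders
    coefficients equal ``frac_a_in_b`` / ``frac_b_in_a``. Block sizes are
    powers of two (so equal per-pixel values re-sum without rounding) and
    are chosen to keep per-pixel levels within a channel within a factor of
    sqrt(2), which lets an automatic histogram threshold recover the
    supports under moderate noise.

    With support masks an overlap region exists iff both fractions are
    positive, so ``frac_a_in_b`` and ``frac_b_in_a`` must be both zero or
    both positive.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValidationError("image shape must be positive")
    if not (0 <= frac_a_in_b <= 1 and 0 <= frac_b_in_a <= 1):
        raise ValidationError("overlap fractions must lie in [0, 1]")
    if sum_a_total <= 0 or sum_b_total <= 0:
        raise ValidationError("channel totals must be positive")
    if (frac_a_in_b == 0) != (frac_b_in_a == 0):
        raise ValidationError(
            "infeasible overlap: with support masks, overlap fractions "
            "must be both zero or both positive"
        )
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    n_pix = h * w
    n1, n2, n3 = _block_sizes(n_pix, frac_a_in_b, frac_b_in_a)

    a = np.zeros(n_pix)
    b = np.zeros(n_pix)
    a_only = slice(0, n1)
    overlap = slice(n1, n1 + n2)
    b_only = slice(n1 + n2, n1 + n2 + n3)

    a_in = frac_a_in_b * sum_a_total
    a_out = sum_a_total - a_in
    b_in = frac_b_in_a * sum_b_total
    b_out = sum_b_total - b_in

    if n1 > 0 and a_out > 0:
        a[a_only] = a_out / n1
    if n3 > 0 and b_out > 0:
        b[b_only] = b_out / n3
    if n2 > 0:  # both fractions positive by the feasibility check
        a[overlap] = a_in / n2
        b[overlap] = b_in / n2

    a = a.reshape(h, w)
    b = b.reshape(h, w)
    # realized sums (before noise) — exact for dyadic inputs because blocks
    # are power-of-two runs of equal dyadic-divided values
    sa, sab = float(a.sum()), float(a.reshape(-1)[overlap].sum())
    sb, sba = float(b.sum()), float(b.reshape(-1)[overlap].sum())

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = np.clip(a + rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)
        b = np.clip(b + rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)

    return ChannelImagePair(channel_a=a, channel_b=b, truth=(sa, sab, sb, sba))


def ideal_masks(pair: ChannelImagePair) -> tuple[np.ndarray, np.ndarray]:
    """Support masks (signal > 0) for a noise-free generated pair."""
    return pair.channel_a > 0, pair.channel_b > 0


def positivity_from_fields(fields: Sequence[AbundanceField], quantile: Optional[float] = None):
    """Ground-truth positivity calls straight from abundance fields.

    With ``quantile`` None a spot is positive where its abundance is > 0
    (natural for binary dispersed/blob fields); otherwise the same strict
    nearest-rank quantile rule used for scores is applied per field.
    Returns a ``spot_scoring.PositivityCalls``.
    """
    from spatialcoloc.spot_scoring import PositivityCalls, nearest_rank_quantile

    if not fields:
        raise ValidationError("at least one field required")
    grid = fields[0].grid_ref
    for f in fields:
        if f.grid_ref != grid:
            raise ValidationError("fields built on different grids")

    thresholds = []
    cols = []
    for f in fields:
        if quantile is None:
            t = 0.0
        else:
            t = nearest_rank_quantile(f.values, quantile)
        thresholds.append(t)
        cols.append(f.values > t)
    return PositivityCalls(
        spots=tuple(grid.spot_ids),
        cell_types=tuple(f.cell_type for f in fields),
        positive=np.column_stack(cols),
        quantile=0.0 if quantile is None else quantile,
        thresholds=tuple(thresholds),
    )


def gen_score_table(
    n_spots: int,
    n_types: int,
    distribution: str = "distinct",
    seed: int = 0,
):
    """Score-matrix fixture for the positivity rule.

    distinct — all scores unique within each type; tied — the value at the
    top-quartile boundary duplicated across the boundary; constant — all
    scores equal. Returns a ``spot_scoring.ScoreMatrix``.
    """
    from spatialcoloc.spot_scoring import ScoreMatrix

    if n_spots < 4:
        raise ValidationError("n_spots must be >= 4")
    if n_types < 1:
        raise ValidationError("n_types must be >= 1")
    if distribution not in ("distinct", "tied", "constant"):
        raise ValidationError(f"unknown distribution {distribution!r}")

    rng = np.random.default_rng(seed)
    scores = np.empty((n_spots, n_types))
    for j in range(n_types):
        if distribution == "constant":
            col = np.full(n_spots, 1.0)
        else:
            # distinct with probability 1; enforce by resampling duplicates
            col = rng.normal(size=n_spots)
            while len(np.unique(col)) < n_spots:  # pragma: no cover
                col = rng.normal(size=n_spots)
            if distribution == "tied":
                order = np.argsort(col)
                k = int(np.ceil(0.75 * n_spots)) - 1  # nearest-rank 75th pct
                boundary = col[order[k]]
                col[order[max(k - 1, 0)]] = boundary
                col[order[min(k + 1, n_spots - 1)]] = boundary
        scores[:, j] = col

    spots = tuple(f"spot{i}" for i in range(n_spots))
    types = tuple(f"type{j}" for j in range(n_types))
    return ScoreMatrix(spots=spots, cell_types=types, scores=scores)
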