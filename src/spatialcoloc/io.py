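"""Readers and writers for the standard on-disk formats.

MTX triplets and CSV for expression, CSV for coordinates / scores / calls,
GMT for gene sets, TIFF/PNG for channel images.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from spatialcoloc.errors import ValidationError
from spatialcoloc.spot_scoring import GeneSetCollection, PositivityCalls, ScoreMatrix
from spatialcoloc.synthgen import ChannelImagePair, ExpressionMatrix, SpotGrid

log = logging.getLogger("spatialcoloc")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read counts from an MTX triplet directory or a genes-x-spots CSV.

    The MTX layout is matrix.mtx + features.tsv + barcodes.tsv; the CSV has
    gene symbols in the first column and one column per spot. Non-integer or
    negative entries are rejected with their location.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_triplet(path)
    return _read_expression_csv(path)


def _read_mtx_triplet(folder: Path) -> ExpressionMatrix:
    mtx = folder / "matrix.mtx"
    feats = folder / "features.tsv"
    bars = folder / "barcodes.tsv"
    for f in (mtx, feats, bars):
        if not f.exists():
            raise ValidationError(f"missing MTX triplet member: {f}")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as err:  # malformed header / body mismatch
        raise ValidationError(f"cannot parse {mtx}: {err}") from err
    genes = feats.read_text().splitlines()
    genes = [line.split("\t")[0] for line in genes if line.strip()]
    spots = [line.strip() for line in bars.read_text().splitlines() if line.strip()]
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(spots)):
        raise ValidationError(
            f"matrix shape {mat.shape} disagrees with "
            f"{len(genes)} features x {len(spots)} barcodes"
        )
    dense = np.asarray(mat.todense())
    return _validated_matrix(genes, spots, dense)


def _read_expression_csv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    return _validated_matrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(),
    )


def _validated_matrix(genes, spots, dense) -> ExpressionMatrix:
    if not np.issubdtype(np.asarray(dense).dtype, np.integer):
        frac = np.asarray(dense, dtype=float)
        bad = np.argwhere(frac != np.round(frac))
        if len(bad):
            i, j = bad[0]
            raise ValidationError(
                f"non-integer count at gene {genes[i]!r}, spot {spots[j]!r}"
            )
        dense = frac.astype(np.int64)
    neg = np.argwhere(dense < 0)
    if len(neg):
        i, j = neg[0]
        raise ValidationError(
            f"negative count at gene {genes[i]!r}, spot {spots[j]!r}"
        )
    return ExpressionMatrix(
        genes=tuple(genes), spots=tuple(spots), counts=np.asarray(dense)
    )


def write_expression_mtx(expr: ExpressionMatrix, folder: str | Path) -> None:
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        folder / "matrix.mtx", scipy.sparse.coo_matrix(expr.counts)
    )
    # mmwrite appends .mtx when absent; normalize to the exact name
    if (folder / "matrix.mtx.mtx").exists():  # pragma: no cover
        (folder / "matrix.mtx.mtx").rename(folder / "matrix.mtx")
    (folder / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in expr.genes)
    )
    (folder / "barcodes.tsv").write_text(
        "".join(f"{s}\n" for s in expr.spots)
    )


def write_expression_csv(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        expr.counts, index=list(expr.genes), columns=list(expr.spots)
    ).to_csv(path)


# ---------------------------------------------------------------------------
# coordinates


def read_coords(path: str | Path) -> tuple[SpotGrid, tuple[int, int]]:
    """Read a spot_id,x,y CSV into a grid normalized to a 0-based origin.

    Returns (grid, (x_offset, y_offset)): offsets subtracted during
    normalization. Shifting either coordinate by one flips every parity, so
    the offset is logged and echoed in run reports.
    """
    df = pd.read_csv(path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"coordinate CSV must have columns {sorted(required)}"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise ValidationError(
                f"non-integer {col} coordinate at row {int(bad.idxmax())}"
            )
        df[col] = vals.astype(int)
    ids = df["spot_id"].astype(str)
    if ids.duplicated().any():
        raise ValidationError(
            f"duplicate spot_id: {ids[ids.duplicated()].iloc[0]!r}"
        )
    if df.duplicated(subset=["x", "y"]).any():
        dup = df[df.duplicated(subset=["x", "y"])].iloc[0]
        raise ValidationError(
            f"duplicate coordinate ({dup['x']}, {dup['y']})"
        )

    x_off, y_off = int(df["x"].min()), int(df["y"].min())
    xs = (df["x"] - x_off).astype(int)
    ys = (df["y"] - y_off).astype(int)
    if x_off or y_off:
        log.warning(
            "coordinates normalized by offset (%d, %d); parity assignments "
            "depend on the origin",
            x_off,
            y_off,
        )
    spots = tuple(zip(ids.tolist(), xs.tolist(), ys.tolist()))
    grid = SpotGrid(
        n_rows=int(ys.max()) + 1, n_cols=int(xs.max()) + 1, spots=spots
    )
    return grid, (x_off, y_off)


def write_coords(grid: SpotGrid, path: str | Path) -> None:
    pd.DataFrame(
        [(sid, x, y) for sid, x, y in grid.spots],
        columns=["spot_id", "x", "y"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then gene symbols, tab-separated.

    Duplicate genes within a set are dropped with a warning; a line without
    genes is an error.
    """
    sets: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValidationError(
                f"{path}:{lineno}: GMT line needs a name, description and "
                "at least one gene"
            )
        name = parts[0]
        genes, seen = [], set()
        for g in parts[2:]:
            g = g.strip()
            if not g:
                continue
            if g in seen:
                log.warning(
                    "%s:%d: duplicate gene %r in set %r dropped",
                    path,
                    lineno,
                    g,
                    name,
                )
                continue
            seen.add(g)
            genes.append(g)
        sets[name] = tuple(genes)
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(genes))
        for name, genes in sets.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# scores / calls


def write_scores_csv(scores: ScoreMatrix, path: str | Path) -> None:
    pd.DataFrame(
        scores.scores,
        index=list(scores.spots),
        columns=list(scores.cell_types),
    ).to_csv(path, index_label="spot_id")


def write_calls(
    calls: PositivityCalls, csv_path: str | Path, json_path: str | Path
) -> None:
    pd.DataFrame(
        calls.positive.astype(int),
        index=list(calls.spots),
        columns=list(calls.cell_types),
    ).to_csv(csv_path, index_label="spot_id")
    Path(json_path).write_text(
        json.dumps(
            {
                "quantile": calls.quantile,
                "thresholds": dict(zip(calls.cell_types, calls.thresholds)),
            },
            indent=2,
        )
    )


def read_calls(csv_path: str | Path, json_path: str | Path) -> PositivityCalls:
    df = pd.read_csv(csv_path, index_col="spot_id")
    meta = json.loads(Path(json_path).read_text())
    types = tuple(df.columns)
    return PositivityCalls(
        spots=tuple(str(s) for s in df.index),
        cell_types=types,
        positive=df.to_numpy().astype(bool),
        quantile=float(meta["quantile"]),
        thresholds=tuple(float(meta["thresholds"][t]) for t in types),
    )


# ---------------------------------------------------------------------------
# images


def write_channel_pair(
    pair: ChannelImagePair, path_a: str | Path, path_b: str | Path
) -> None:
    """Write the two channels as 16-bit TIFFs, rescaled to the full range."""
    import tifffile

    for channel, path in ((pair.channel_a, path_a), (pair.channel_b, path_b)):
        peak = float(channel.max())
        scaled = channel / peak * 65535.0 if peak > 0 else channel
        tifffile.imwrite(str(path), np.round(scaled).astype(np.uint16))


def read_channel(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    return arr
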