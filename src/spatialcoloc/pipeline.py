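"""End-to-end run orchestration: config, staging, outputs, run reports."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from spatialcoloc import __version__, io
from spatialcoloc.errors import ValidationError
from spatialcoloc.image_mcc import MccResult, manders_auto, mcc_timecourse
from spatialcoloc.spatial_joincount import (
    JoinCountConfig,
    pairwise_joincount_matrix,
)
from spatialcoloc.spot_scoring import call_positivity, score_matrix
from spatialcoloc import synthgen

log = logging.getLogger("spatialcoloc")

MODES = ("spatial", "mcc", "synthetic-demo")

_TOP_KEYS = {
    "mode",
    "output_dir",
    "seeds",
    "inputs",
    "generator",
    "scoring",
    "joincount",
    "mcc",
}
_SCORING_KEYS = {"alpha", "quantile"}
_JOINCOUNT_KEYS = {
    "scheme",
    "n_perm",
    "z_cutoff",
    "even_gets",
    "null_method",
    "permute_bg",
}
_MCC_KEYS = {"threshold_method", "fixed_value_a", "fixed_value_b"}
_INPUT_KEYS = {"expression", "coords", "gene_sets", "manifest"}
_GENERATOR_KEYS = {
    "n_rows",
    "n_cols",
    "baseline_mean",
    "effect_size",
    "dispersion",
    "n_background",
    "markers_per_type",
}


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(
            f"unknown config key(s) in {section}: {sorted(unknown)}"
        )


@dataclass
class RunConfig:
    mode: str
    output_dir: str
    seeds: dict[str, int]
    inputs: dict[str, str] = field(default_factory=dict)
    generator: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)
    joincount: dict[str, Any] = field(default_factory=dict)
    mcc: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.seeds:
            raise ValidationError("seeds must be given explicitly")
        for name, value in self.seeds.items():
            if not isinstance(value, int):
                raise ValidationError(f"seed {name!r} must be an integer")
        _check_keys("scoring", self.scoring, _SCORING_KEYS)
        _check_keys("joincount", self.joincount, _JOINCOUNT_KEYS)
        _check_keys("mcc", self.mcc, _MCC_KEYS)
        _check_keys("inputs", self.inputs, _INPUT_KEYS)
        _check_keys("generator", self.generator, _GENERATOR_KEYS)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys("config", raw, _TOP_KEYS)
        try:
            return cls(**raw)
        except TypeError as err:
            raise ValidationError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def joincount_config(self) -> JoinCountConfig:
        return JoinCountConfig(
            seed=self.seeds.get("joincount", self.seeds.get("run", 0)),
            **self.joincount,
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "mode": self.mode,
                "seeds": self.seeds,
                "inputs": self.inputs,
                "generator": self.generator,
                "scoring": self.scoring,
                "joincount": self.joincount,
                "mcc": self.mcc,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    mode: str
    outputs: dict[str, str]
    summary: dict[str, Any]
    version: str
    timings: dict[str, float]
    failures: list[dict] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        for name, out in self.outputs.items():
            if not Path(out).exists():
                raise ValidationError(
                    f"report lists missing output {name}: {out}"
                )
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "mode": self.mode,
                    "outputs": self.outputs,
                    "summary": self.summary,
                    "version": self.version,
                    "timings_s": self.timings,
                    "failures": self.failures,
                },
                indent=2,
                sort_keys=True,
            )
        )


class _Stage:
    """Context manager recording per-stage wall clock into a dict."""

    def __init__(self, timings: dict, name: str):
        self.timings, self.name = timings, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = round(time.perf_counter() - self.t0, 4)
        if exc_type is not None:
            log.error("stage %s failed: %s", self.name, exc)
            if hasattr(exc, "add_note"):
                exc.add_note(f"stage: {self.name}")
        return False


def _require_input(config: RunConfig, key: str) -> Path:
    if key not in config.inputs:
        raise ValidationError(f"stage inputs: missing {key!r} path in config")
    path = Path(config.inputs[key])
    if not path.exists():
        raise ValidationError(f"stage inputs: {key} path does not exist: {path}")
    return path


def run_spatial(config: RunConfig) -> RunReport:
    """expression + coords + GMT -> scores -> calls -> pairwise join counts."""
    if config.mode != "spatial":
        raise ValidationError("run_spatial requires mode=spatial")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    try:
        return _run_spatial_stages(config, outdir, timings, outputs)
    except Exception:
        for out in outputs.values():  # no partial outputs on abort
            Path(out).unlink(missing_ok=True)
        raise


def _run_spatial_stages(
    config: RunConfig,
    outdir: Path,
    timings: dict[str, float],
    outputs: dict[str, str],
) -> RunReport:
    with _Stage(timings, "inputs"):
        expr = io.read_expression(_require_input(config, "expression"))
        grid, offset = io.read_coords(_require_input(config, "coords"))
        sets = io.read_gmt(_require_input(config, "gene_sets"))
        log.info(
            "inputs: %d genes x %d spots, %d sets, grid %dx%d, offset %s",
            len(expr.genes),
            len(expr.spots),
            len(sets.names),
            grid.n_rows,
            grid.n_cols,
            offset,
        )

    with _Stage(timings, "scoring"):
        alpha = float(config.scoring.get("alpha", 0.25))
        scores = score_matrix(expr, sets, alpha=alpha)
        io.write_scores_csv(scores, outdir / "scores.csv")
        outputs["scores"] = str(outdir / "scores.csv")

    with _Stage(timings, "positivity"):
        quantile = float(config.scoring.get("quantile", 0.75))
        calls = call_positivity(scores, quantile=quantile)
        io.write_calls(
            calls, outdir / "calls.csv", outdir / "thresholds.json"
        )
        outputs["calls"] = str(outdir / "calls.csv")
        outputs["thresholds"] = str(outdir / "thresholds.json")

    with _Stage(timings, "joincount"):
        jc_config = config.joincount_config()
        results = pairwise_joincount_matrix(calls, grid, jc_config)
        df = pd.DataFrame(
            [
                {
                    "pair": f"{r.pair[0]}|{r.pair[1]}",
                    "j_obs": r.j_obs,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "z": r.z,
                    "p_perm": r.p_perm,
                    "significant": r.significant,
                    "method": r.method,
                    "note": r.note,
                }
                for r in results
            ]
        )
        df.to_csv(outdir / "joincount.csv", index=False)
        outputs["joincount"] = str(outdir / "joincount.csv")

    report = RunReport(
        config_hash=config.config_hash(),
        mode="spatial",
        outputs=outputs,
        summary={
            "n_spots": len(expr.spots),
            "n_genes": len(expr.genes),
            "cell_types": list(sets.names),
            "coordinate_offset": list(offset),
            "n_pairs": len(results),
            "significant_pairs": [
                f"{r.pair[0]}|{r.pair[1]}" for r in results if r.significant
            ],
        },
        version=__version__,
        timings=timings,
    )
    report.write(outdir / "report.json")
    return report


def run_mcc(config: RunConfig) -> RunReport:
    """Per-image Manders coefficients over a manifest, plus group summary.

    An unreadable image is recorded as a failure; the run continues.
    """
    if config.mode != "mcc":
        raise ValidationError("run_mcc requires mode=mcc")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    failures: list[dict] = []

    with _Stage(timings, "manifest"):
        manifest = pd.read_csv(_require_input(config, "manifest"))
        required = {"image_id", "group_label", "path_a", "path_b"}
        if not required.issubset(manifest.columns):
            raise ValidationError(
                f"manifest must have columns {sorted(required)}"
            )

    method = config.mcc.get("threshold_method", "otsu")
    fixed_a = config.mcc.get("fixed_value_a")
    fixed_b = config.mcc.get("fixed_value_b")

    rows: list[dict] = []
    records: list[tuple[str, MccResult]] = []
    with _Stage(timings, "mcc"):
        for _, entry in manifest.iterrows():
            image_id = str(entry["image_id"])
            try:
                a = io.read_channel(entry["path_a"])
                b = io.read_channel(entry["path_b"])
                pair = synthgen.ChannelImagePair(channel_a=a, channel_b=b)
                res = manders_auto(
                    pair, method=method, fixed_a=fixed_a, fixed_b=fixed_b
                )
            except Exception as err:
                log.error("image %s failed: %s", image_id, err)
                failures.append({"image_id": image_id, "error": str(err)})
                continue
            records.append((str(entry["group_label"]), res))
            rows.append(
                {
                    "image_id": image_id,
                    "group_label": entry["group_label"],
                    "m1": res.m1,
                    "m2": res.m2,
                    "m1_not_computable": res.m1 is None,
                    "m2_not_computable": res.m2 is None,
                    "threshold_a": res.threshold_a,
                    "threshold_b": res.threshold_b,
                    "method": res.method,
                }
            )

    outputs: dict[str, str] = {}
    with _Stage(timings, "summary"):
        pd.DataFrame(rows).to_csv(outdir / "mcc_results.csv", index=False)
        outputs["mcc_results"] = str(outdir / "mcc_results.csv")
        if records:
            summary = mcc_timecourse(records)
            pd.DataFrame(
                {
                    "group_label": summary.groups,
                    "n": summary.n,
                    "mean_m1": summary.mean_m1,
                    "sd_m1": summary.sd_m1,
                    "mean_m2": summary.mean_m2,
                    "sd_m2": summary.sd_m2,
                }
            ).to_csv(outdir / "mcc_group_summary.csv", index=False)
            outputs["mcc_group_summary"] = str(outdir / "mcc_group_summary.csv")

    report = RunReport(
        config_hash=config.config_hash(),
        mode="mcc",
        outputs=outputs,
        summary={
            "n_images": int(len(manifest)),
            "n_ok": len(rows),
            "n_failed": len(failures),
        },
        version=__version__,
        timings=timings,
        failures=failures,
    )
    report.write(outdir / "report.json")
    return report


def run_demo(outdir: str | Path, seed: int = 0) -> RunReport:
    """Self-contained demonstration on generated data.

    Two cell types share aggregated blobs (expected z > 3) and a third is
    confined to the opposite half-lattice; inputs are materialized to disk
    and the spatial pipeline is run on them.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    grid = synthgen.gen_spot_lattice(20, 20)
    blob = {
        "centers": [(5.0, 5.0), (14.0, 14.0)],
        "sigma": 2.5,
        "binarize_quantile": 0.75,
    }
    field_c = synthgen.gen_celltype_field(grid, "TypeC", "random", {}, seed=seed + 2)
    # keep TypeC abundance moderate so its marker ranks (and hence scores)
    # stay variable instead of saturating the running-sum ceiling
    field_c = synthgen.AbundanceField(
        grid_ref=grid,
        cell_type="TypeC",
        values=field_c.values / (4.0 * field_c.values.max()),
        pattern="random",
        truth_params=field_c.truth_params,
    )
    fields = [
        synthgen.gen_celltype_field(grid, "TypeA", "aggregated", dict(blob), seed=seed),
        synthgen.gen_celltype_field(grid, "TypeB", "aggregated", dict(blob), seed=seed + 1),
        field_c,
    ]
    markers = {
        ct: tuple(f"{ct}_M{i}" for i in range(1, 9))
        for ct in ("TypeA", "TypeB", "TypeC")
    }
    expr = synthgen.gen_expression_matrix(
        grid,
        fields,
        markers,
        baseline_mean=5.0,
        effect_size=5.0,
        dispersion=10.0,
        seed=seed + 3,
        n_background=150,
    )

    io.write_expression_csv(expr, inputs / "expression.csv")
    io.write_coords(grid, inputs / "coords.csv")
    from spatialcoloc.spot_scoring import GeneSetCollection

    io.write_gmt(
        GeneSetCollection({k: tuple(v) for k, v in markers.items()}),
        inputs / "markers.gmt",
    )

    config = RunConfig(
        mode="spatial",
        output_dir=str(outdir),
        seeds={"run": seed, "joincount": seed + 4},
        inputs={
            "expression": str(inputs / "expression.csv"),
            "coords": str(inputs / "coords.csv"),
            "gene_sets": str(inputs / "markers.gmt"),
        },
        scoring={"alpha": 0.25, "quantile": 0.75},
        joincount={"scheme": "rook", "n_perm": 999},
    )
    return run_spatial(config)
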