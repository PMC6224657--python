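"""Table and config I/O, schema validation, and the reproducible pipeline runner.

Tabular interchange is tab-delimited text with a header line; configs are
YAML or JSON; machine-readable results and provenance are JSON.  Every
pipeline output gets a provenance sidecar (input checksums, seed,
parameters, package version) so that identical config + seed reruns can be
verified by checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clonality, cohort_stats, selection, synthetic

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "read_config", "run_pipeline"]

logger = logging.getLogger("cskit")

#: Required columns and dtypes per named schema. Extra columns pass through.
SCHEMAS: dict[str, dict[str, type]] = {
    "cohort": {"sample_id": str, "group": str},
    "variants": {
        "sample_id": str,
        "gene": str,
        "protein_change": str,
        "consequence": str,
        "vaf": float,
    },
    "trajectory": {
        "replicate": int,
        "day": float,
        "mutant_count": int,
        "total_count": int,
    },
}

VALID_STAGES = ("synth", "simulate", "predict", "fit", "enrich", "cooccur", "filter", "ccf", "classify")


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a tab-delimited table and validate it against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; valid: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep="\t")
    spec = SCHEMAS[schema]
    for col, typ in spec.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for schema {schema!r}")
        if typ is not str:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise SchemaError(
                    f"{path}: column {col!r} not coercible to {typ.__name__} at row {int(bad[0])}"
                )
            df[col] = coerced.astype(typ) if not coerced.isna().any() else coerced
    logger.info("read %d rows from %s (schema %s)", len(df), path, schema)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def _write_json(payload: Any, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _stage_synth(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    spec = synthetic.CohortSpec(
        **{**cfg.get("cohort", {}), "seed": cfg.get("cohort", {}).get("seed", seed)}
    )
    cohort, variants = synthetic.generate_cohort(spec)
    comp_cfg = cfg.get("competition")
    outputs = [
        write_table(cohort, outdir / "cohort.tsv"),
        write_table(synthetic.variants_to_frame(variants), outdir / "variants.tsv"),
    ]
    if comp_cfg is not None:
        comp = selection.CompetitionSpec(**{**comp_cfg, "seed": comp_cfg.get("seed", seed)})
        trajs = synthetic.generate_competition(comp)
        outputs.append(
            write_table(synthetic.trajectories_to_frame(trajs), outdir / "trajectories.tsv")
        )
    return outputs


def _stage_simulate(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    comp_cfg = dict(cfg.get("competition", {}))
    comp = selection.CompetitionSpec(**{**comp_cfg, "seed": comp_cfg.get("seed", seed)})
    engraft = cfg.get("engraft_frac")
    if engraft is not None:
        trajs = synthetic.generate_chimerism(comp, engraft_frac=float(engraft))
    else:
        trajs = synthetic.generate_competition(comp)
    return [write_table(synthetic.trajectories_to_frame(trajs), outdir / "trajectories.tsv")]


def _stage_predict(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    params = selection.SelectionParams(
        f0=float(cfg["f0"]), r=float(cfg["r"]), model=cfg.get("model", "normalized")
    )
    fractions = selection.predict_trajectory(params, int(cfg.get("n_doses", 4)))
    payload = {"model": params.model, "f0": params.f0, "r": params.r, "fractions": fractions}
    return [_write_json(payload, outdir / "prediction.json")]


def _trajectories_from_table(df: pd.DataFrame) -> list[selection.Trajectory]:
    trajs = []
    for rep, grp in df.groupby("replicate"):
        pts = [
            (float(row.day), int(row.mutant_count), int(row.total_count))
            for row in grp.sort_values("day").itertuples()
        ]
        trajs.append(selection.Trajectory(points=pts, meta={"replicate": int(rep)}))
    return trajs


def _stage_fit(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    df = read_table(cfg["trajectory"], "trajectory")
    trajs = _trajectories_from_table(df)
    pooled = selection.pool_trajectories(trajs)
    schedule = {float(k): int(v) for k, v in cfg["schedule"].items()}
    est = selection.fit_fitness(pooled, schedule, model=cfg.get("model", "normalized"))
    return [_write_json(est, outdir / "fitness.json")]


def _stage_enrich(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    cohort = read_table(cfg["cohort"], "cohort")
    results = cohort_stats.exposure_enrichment(
        cohort,
        outcome_gene=cfg["gene"],
        exposures=list(cfg["exposures"]),
        fdr_method=cfg.get("fdr_method", "fdr_bh"),
    )
    rows = [
        {
            "factor": r.factor,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "or": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p_exact, "q": r.q, "corrected": r.corrected,
            "estimable": r.estimable, "n_excluded": r.table.n_excluded,
        }
        for r in results
    ]
    return [
        write_table(pd.DataFrame(rows), outdir / "enrichment.tsv"),
        _write_json(rows, outdir / "enrichment.json"),
    ]


def _stage_cooccur(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    cohort = read_table(cfg["cohort"], "cohort")
    vdf = read_table(cfg["variants"], "variants") if "variants" in cfg else None
    variants = (
        [
            clonality.VariantRecord(
                sample_id=str(r.sample_id), gene=str(r.gene),
                protein_change=str(r.protein_change), consequence=str(r.consequence),
                vaf=float(r.vaf),
            )
            for r in vdf.itertuples()
        ]
        if vdf is not None
        else []
    )
    matrix = cohort_stats.cooccurrence_matrix(
        variants, cohort, genes=list(cfg["genes"]),
        clonal_only_for=cfg.get("clonal_only_for"),
        fdr_method=cfg.get("fdr_method", "fdr_bh"),
    )
    out = []
    for name, frame in (("log_or", matrix.log_or), ("p", matrix.p), ("q", matrix.q)):
        out.append(write_table(frame.reset_index(names="item"), outdir / f"cooccur_{name}.tsv"))
    return out


def _stage_filter(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    df = read_table(cfg["variants"], "variants")
    min_vaf = float(cfg.get("min_vaf", 0.02))
    kept = df[df["vaf"] >= min_vaf]
    logger.info("filter: retained %d of %d variants", len(kept), len(df))
    return [write_table(kept, outdir / "variants_filtered.tsv")]


def _stage_ccf(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    df = read_table(cfg["variants"], "variants").copy()
    purity = float(cfg.get("purity", 1.0))
    results = [
        clonality.compute_ccf(clonality.CcfInput(vaf=float(v), purity=purity))
        for v in df["vaf"]
    ]
    df["ccf"] = [r.ccf for r in results]
    df["ccf_clamped"] = [r.clamped for r in results]
    return [write_table(df, outdir / "variants_ccf.tsv")]


def _stage_classify(cfg: dict, seed: int, outdir: Path) -> list[Path]:
    df = read_table(cfg["variants"], "variants").copy()
    exon_map = cfg.get("exon_map", clonality.PPM1D_EXON_RANGES)
    parsed = [clonality.classify_consequence(str(pc), exon_map) for pc in df["protein_change"]]
    df["consequence"] = [p[0] for p in parsed]
    df["exon"] = [p[1] for p in parsed]
    df["truncating"] = [p[2] for p in parsed]
    df["clonality"] = [
        clonality.classify_clonal(float(v), threshold=float(cfg.get("clonal_threshold", 0.2)))
        for v in df["vaf"]
    ]
    return [write_table(df, outdir / "variants_classified.tsv")]


_STAGE_FNS = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "predict": _stage_predict,
    "fit": _stage_fit,
    "enrich": _stage_enrich,
    "cooccur": _stage_cooccur,
    "filter": _stage_filter,
    "ccf": _stage_ccf,
    "classify": _stage_classify,
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stage(s); return and write an artifact manifest.

    ``config`` keys: ``stages`` (list) or ``stage`` (one name), ``outdir``,
    ``seed``, plus per-stage parameter blocks keyed by stage name.  Input
    checksums, parameters, seed and package version go into a provenance
    block per stage; rerunning an identical config yields identical
    checksums for deterministic stages.  On stage failure, partial outputs
    are moved under ``outdir/failed/`` and the exception propagates.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    stages = config.get("stages") or [config.get("stage")]
    if not stages or stages == [None]:
        raise ValueError(f"config must name a stage; valid stages: {list(VALID_STAGES)}")
    for st in stages:
        if st not in _STAGE_FNS:
            raise ValueError(f"unknown stage {st!r}; valid stages: {list(VALID_STAGES)}")
    outdir = Path(config.get("outdir", "cskit_out"))
    seed = int(config.get("seed", 0))

    manifest: dict = {"seed": seed, "version": __version__, "stages": {}}
    for st in stages:
        cfg = dict(config.get(st, {}))
        stage_dir = outdir / st
        input_paths = [
            Path(cfg[k])
            for k in ("cohort", "variants", "trajectory")
            if isinstance(cfg.get(k), (str, Path))
        ]
        try:
            outputs = _STAGE_FNS[st](cfg, seed, stage_dir)
        except Exception:
            if stage_dir.exists():
                quarantine = outdir / "failed" / st
                quarantine.parent.mkdir(parents=True, exist_ok=True)
                if quarantine.exists():
                    shutil.rmtree(quarantine)
                shutil.move(str(stage_dir), str(quarantine))
            raise
        provenance = {
            "stage": st,
            "seed": seed,
            "version": __version__,
            "parameters": _jsonable(cfg),
            "inputs": {str(p): _sha256(p) for p in input_paths if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        _write_json(provenance, stage_dir / "provenance.json")
        manifest["stages"][st] = provenance
    _write_json(manifest, outdir / "manifest.json")
    return manifest
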