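"""File formats, configuration and orchestration of the full analysis run.

CSV/TSV schemas mirror the domain tables: one trial CSV per task (UTF-8,
header row, missing RT as an empty field), one flat participant CSV, dense
TSV connectivity matrices with a two-column partition TSV and a one-column
frontoparietal node list. ``run_pipeline`` ties the stages together —
scoring, EF components, optional graph metrics, correlation screens and the
three bootstrap mediation models — writing a manifest with the config hash
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavioral_scoring as bs
from . import ef_components as ef
from . import mediation as med
from . import network_metrics as nm

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A table failed schema validation; the message names the rows."""


TRIAL_SCHEMAS = {
    "switch": {
        "columns": ["participant_id", "block_kind", "cue_kind", "trial_kind",
                    "rt", "correct"],
        "numeric": ["rt"],
    },
    "nback": {
        "columns": ["participant_id", "is_target", "response", "rt"],
        "numeric": ["rt"],
    },
    "stop": {
        "columns": ["participant_id", "trial_kind", "rt", "correct", "ssd",
                    "staircase_id", "stop_outcome"],
        "numeric": ["rt", "ssd"],
    },
}

SSD_RANGE = (0.0, 800.0)


def read_trial_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one task's trial CSV.

    Raises :class:`ValidationError` naming the missing column or the
    offending rows (1-based data row numbers) for non-numeric RT or an SSD
    outside the admissible range.
    """
    if kind not in TRIAL_SCHEMAS:
        raise ValueError(f"unknown trial table kind {kind!r}")
    schema = TRIAL_SCHEMAS[kind]
    table = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in schema["columns"] if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in schema["numeric"]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table[col].notna() & coerced.isna()
        if bad.any():
            rows = (np.flatnonzero(bad) + 1).tolist()
            raise ValidationError(
                f"{path}: non-numeric {col!r} in data row(s) {rows}")
        table[col] = coerced
    if kind == "stop":
        ssd = table.loc[table["trial_kind"] == "stop", "ssd"]
        out = ssd.notna() & ((ssd < SSD_RANGE[0]) | (ssd > SSD_RANGE[1]))
        if out.any():
            rows = (np.asarray(out[out].index) + 1).tolist()
            raise ValidationError(
                f"{path}: ssd outside [{SSD_RANGE[0]:g}, {SSD_RANGE[1]:g}] "
                f"in data row(s) {rows}")
    if kind in ("switch", "stop"):
        table["correct"] = table["correct"].astype(bool)
    if kind == "nback":
        table["is_target"] = table["is_target"].astype(bool)
    return table


def read_participant_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in table.columns:
        raise ValidationError(f"{path}: missing column 'participant_id'")
    if table["participant_id"].duplicated().any():
        dupes = table.loc[table["participant_id"].duplicated(),
                          "participant_id"].tolist()
        raise ValidationError(f"{path}: duplicated participant_id(s) {dupes}")
    return table


def read_connectivity(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Dense TSV with node ids as the header row."""
    table = pd.read_csv(path, sep="\t")
    W = nm.validate_connectivity(table.to_numpy(float))
    return W, [str(c) for c in table.columns]


def read_partition(path: str | Path) -> pd.Series:
    """Two-column TSV (node_id, module) → Series indexed by node id."""
    table = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    for col in ("node_id", "module"):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return table.set_index("node_id")["module"]


def read_fp_nodes(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    switch_trials: str
    nback_trials: str
    stop_trials: str
    participants: str
    outdir: str
    fc_dir: str | None = None
    partition: str | None = None
    fp_nodes: str | None = None
    seed: int = 0
    n_boot: int = 5000
    ci_level: float = 95.0
    partial_correlations: bool = True
    network_scope: str = "full"       # 'full' or 'subgraph'
    dprime_orientation: str = "negated"   # 'negated' or 'raw'
    mediators: tuple[str, ...] = med.DEFAULT_MEDIATORS
    covariates: tuple[str, ...] = med.DEFAULT_COVARIATES

    def __post_init__(self):
        if self.network_scope not in ("full", "subgraph"):
            raise ValueError("network_scope must be 'full' or 'subgraph'")
        if self.dprime_orientation not in ("negated", "raw"):
            raise ValueError("dprime_orientation must be 'negated' or 'raw'")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("mediators", "covariates"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _fc_metrics_table(config: RunConfig) -> pd.DataFrame:
    partition = read_partition(config.partition)
    fp_nodes = read_fp_nodes(config.fp_nodes)
    rows = []
    for path in sorted(Path(config.fc_dir).glob("*.tsv")):
        W, node_ids = read_connectivity(path)
        modules = partition.reindex(node_ids)
        if modules.isna().any():
            missing = [n for n, m in zip(node_ids, modules) if pd.isna(m)]
            raise ValidationError(
                f"{path}: node(s) without module assignment: {missing[:5]}")
        metrics = nm.compute_node_metrics(
            W, node_ids, modules.to_numpy(), fp_nodes, scope=config.network_scope)
        rows.append({"participant_id": path.stem, "pc_fp": metrics.pc_fp,
                     "wmd_fp": metrics.wmd_fp})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write all result files.

    Stages: (1) trial-level scoring of the three tasks; (2) merge with the
    participant table (optionally recomputing pc_fp/wmd_fp from FC matrices);
    (3) EF component construction; (4) correlation screens (EF–EF, age–EF,
    age–brain with the Bonferroni family level); (5) the three bootstrap
    mediation models. Returns a manifest dict (also written to disk).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    switch = stage("read", read_trial_table, config.switch_trials, "switch")
    nback = stage("read", read_trial_table, config.nback_trials, "nback")
    stop = stage("read", read_trial_table, config.stop_trials, "stop")
    participants = stage("read", read_participant_table, config.participants)

    scores = stage("score", bs.score_participants, switch, nback, stop)
    scores_path = outdir / "behavioral_scores.csv"
    scores.to_csv(scores_path, index=False)

    table = participants.merge(scores, on="participant_id", how="inner")
    if config.fc_dir:
        fc = stage("netmetrics", _fc_metrics_table, config)
        table = table.drop(columns=[c for c in ("pc_fp", "wmd_fp")
                                    if c in table.columns])
        table = table.merge(fc, on="participant_id", how="inner")

    dprime_col = "dprime_neg" if config.dprime_orientation == "negated" else "dprime"
    components = stage("components", ef.build_ef_components, table,
                       dprime_column=dprime_col)
    components_path = outdir / "ef_components.csv"
    components.to_csv(components_path, index=False)
    table = table.merge(components, on="participant_id", how="inner")

    cov_cols = list(config.covariates) if config.partial_correlations else None
    ef_corr = stage("correlations", ef.component_correlation_table, table,
                    ["age", *ef.COMPONENT_COLUMNS], cov_cols)
    ef_corr_path = outdir / "ef_correlations.tsv"
    ef_corr.to_csv(ef_corr_path, sep="\t", index=False)

    screen = stage("correlations", med.age_brain_correlation_screen, table,
                   "age", tuple(config.mediators), tuple(config.covariates))
    screen_path = outdir / "age_brain_screen.tsv"
    screen.to_csv(screen_path, sep="\t", index=False)

    base_spec = med.MediationSpec(
        mediator_names=tuple(config.mediators),
        covariate_names=tuple(config.covariates),
        n_boot=config.n_boot,
        ci_level=config.ci_level,
        seed=config.seed,
    )
    results, _ = stage("mediation", med.run_study_models, table, base_spec)
    mediation_files = []
    for yname, result in results.items():
        jpath = outdir / f"mediation_{yname}.json"
        jpath.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        tpath = outdir / f"mediation_{yname}.tsv"
        result.to_frame().to_csv(tpath, sep="\t", index=False)
        mediation_files.extend([str(jpath), str(tpath)])

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_boot": config.n_boot,
        "n_participants_modeled": int(results[next(iter(results))].n_used),
        "outputs": {
            "behavioral_scores": str(scores_path),
            "ef_components": str(components_path),
            "ef_correlations": str(ef_corr_path),
            "age_brain_screen": str(screen_path),
            "mediation": mediation_files,
        },
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
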