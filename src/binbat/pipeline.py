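"""End-to-end orchestration: simulate -> gate -> quantify -> diagnose.

A :class:`RunConfig` carries every tunable of the chain with defaults
matching the assay's printed conventions (1% negative-control
anchoring, 5% positivity threshold, 70% CD32 baseline anchor, the
standard allergen concentration panel).  The config (and its hash) is
serialized into every output for provenance, and identical config +
seed give identical TSV/JSON outputs.
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

from . import __version__
from .activation import (
    ANCHOR_PCT,
    CD32_ANCHOR,
    POSITIVITY_THRESHOLD,
    anchor_cd63_cutoff,
    percent_activated,
    positivity,
)
from .binning import DEFAULT_BIN_WIDTH, DEFAULT_MIN_CELLS, build_grid, render_grid
from .diagnostics import cohort_report, exclude_nonresponders, summaries_to_frame
from .events import (
    CD63,
    FCERI,
    ChannelMap,
    EventTable,
    PatientRecord,
    default_display_transform,
    read_events_csv,
)
from .exceptions import BinbatError, ConfigError, DataIntegrityError
from .gating import DEFAULT_MIN_BASOPHILS, apply_gate, auto_gate
from .synthetic import CohortSpec, simulate_cohort, write_cohort

log = logging.getLogger("binbat")


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    manifest: str = "manifest.csv"
    event_dir: str = "."
    output_dir: str = "out"
    channel_map: dict | None = None  # semantic marker -> file column
    gating_strategy: str = "valley"
    min_basophils: int = DEFAULT_MIN_BASOPHILS
    refine_cd32: bool = False
    bin_width: float = DEFAULT_BIN_WIDTH
    min_cells: int = DEFAULT_MIN_CELLS
    anchor_pct: float = ANCHOR_PCT
    positivity_threshold: float = POSITIVITY_THRESHOLD
    cd32_anchor: float = CD32_ANCHOR
    youden_tie_break: str = "specificity"
    ci_method: str = "wilson"
    log10_floor: float = 1.0
    seed: int = 0
    n_events: int = 100_000
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        # paths do not influence results, so they are not part of the hash
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("manifest", "event_dir", "output_dir")}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return f"# binbat {__version__} config_hash={config.hash}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, sep="\t", index=False)


def read_run_tsv(path) -> pd.DataFrame:
    """Read a TSV written by this pipeline (skipping the provenance line)."""
    return pd.read_csv(path, sep="\t", comment="#")


def run_simulate(config: RunConfig, spec: CohortSpec, *, force: bool = False) -> Path:
    """Write a synthetic cohort dataset into the configured output directory."""
    outdir = Path(config.output_dir)
    cohort = simulate_cohort(dataclasses.replace(spec, seed=spec.seed or config.seed))
    write_cohort(cohort, outdir, n_events=config.n_events, force=force)
    (outdir / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "config_hash": config.hash,
                    "version": __version__}, indent=2, default=str))
    log.info("simulated cohort with %d patients into %s", len(cohort.patients), outdir)
    return outdir


def _load_sample(config: RunConfig, rel_path: str) -> EventTable:
    path = Path(config.event_dir) / rel_path
    cmap = ChannelMap(config.channel_map) if config.channel_map else None
    return read_events_csv(path, cmap)


def run_analyze(config: RunConfig) -> Path:
    """Gate, anchor and quantify every sample listed in the manifest.

    Produces ``activation.tsv`` (one row per sample), per-sample gate
    reports in ``gates.json``, and optional PRI bin plots.  Per-sample
    failures are logged and flagged, not fatal: the run continues.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.event_dir) / config.manifest
    if not manifest_path.exists():
        raise DataIntegrityError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    needed = {"patient_id", "condition", "replicate", "file"}
    if not needed.issubset(manifest.columns):
        raise DataIntegrityError(
            f"manifest lacks required columns {sorted(needed - set(manifest.columns))}")
    if "allergen" in manifest.columns:
        manifest["allergen"] = manifest["allergen"].fillna("")

    gate_reports: dict = {}
    basophil_cd63: dict = {}  # manifest row index -> gated CD63 values
    rows = []
    for idx, rec in manifest.iterrows():
        key = (rec["patient_id"], rec["condition"],
               rec.get("allergen", ""), rec["replicate"], idx)
        try:
            table = _load_sample(config, rec["file"])
            gate = auto_gate(table, strategy=config.gating_strategy,
                             min_basophils=config.min_basophils,
                             refine_cd32=config.refine_cd32,
                             on_unimodal="empty")
            work = default_display_transform(table, floor=config.log10_floor)
            baso = apply_gate(work, gate)
            gate_reports[f"{rec['patient_id']}:{rec['condition']}:"
                         f"{rec.get('allergen', '')}:{rec['replicate']}"] = gate.report()
            basophil_cd63[idx] = baso.values(CD63)
            rows.append({
                "patient_id": rec["patient_id"], "condition": rec["condition"],
                "allergen": rec.get("allergen", ""),
                "concentration_ug_per_ml": rec.get("concentration_ug_per_ml", ""),
                "replicate": rec["replicate"], "n_basophils": gate.n_basophils,
                "qc_pass": gate.qc.get("qc_pass", True),
                "error": "",
            })
            if config.make_plots and gate.qc.get("qc_pass", False):
                plot_dir = outdir / "plots"
                plot_dir.mkdir(exist_ok=True)
                cutoff_preview = float(np.quantile(baso.values(CD63), 0.99)) if baso.n_events else 0.0
                grid = build_grid(baso, FCERI, CD63, CD63, cutoff_preview,
                                  bin_width=config.bin_width, min_cells=config.min_cells,
                                  x_thr=gate.fceri_threshold, y_thr=cutoff_preview)
                render_grid(grid, "MSI",
                            plot_dir / f"{rec['patient_id']}_{rec['condition']}_"
                                       f"{rec.get('allergen', '') or 'na'}_r{rec['replicate']}.png")
        except (BinbatError, OSError) as exc:
            log.warning("sample %s failed: %s", key, exc)
            rows.append({
                "patient_id": rec["patient_id"], "condition": rec["condition"],
                "allergen": rec.get("allergen", ""),
                "concentration_ug_per_ml": rec.get("concentration_ug_per_ml", ""),
                "replicate": rec["replicate"], "n_basophils": 0,
                "qc_pass": False, "error": str(exc),
            })

    result = pd.DataFrame(rows, index=manifest.index)
    # anchor one cutoff per patient-replicate set on its negative control
    cutoffs: dict = {}
    for (pid, rep), grp in result.groupby(["patient_id", "replicate"]):
        nc_idx = grp.index[grp["condition"] == "negative_control"]
        nc = [basophil_cd63[i] for i in nc_idx if i in basophil_cd63]
        if nc and nc[0].size:
            cutoffs[(pid, rep)] = anchor_cd63_cutoff(nc[0], config.anchor_pct)

    pcts, flags, cuts = [], [], []
    for i, row in result.iterrows():
        cutoff = cutoffs.get((row["patient_id"], row["replicate"]))
        values = basophil_cd63.get(i)
        if values is None or cutoff is None or values.size == 0:
            pcts.append(np.nan); flags.append(False); cuts.append(np.nan)
            continue
        pct = percent_activated(values, cutoff)
        pcts.append(pct)
        flags.append(positivity(pct, config.positivity_threshold))
        cuts.append(cutoff)
    result["cutoff"] = cuts
    result["pct_cd63_pos"] = pcts
    result["positive"] = flags

    _write_tsv(result, outdir / "activation.tsv", config)
    (outdir / "gates.json").write_text(json.dumps(
        {"version": __version__, "config_hash": config.hash, "gates": gate_reports},
        indent=2, default=str))
    log.info("analyzed %d samples -> %s", len(result), outdir / "activation.tsv")
    return outdir


def run_diagnose(config: RunConfig) -> Path:
    """Cohort-level diagnostics from a completed analysis run.

    Applies non-responder exclusion first, then computes a Table-1-style
    diagnostic summary per marker (BAT %CD63+ per allergen, clamped
    sIgE markers when a sIgE panel is present) and the per-patient
    reactivity classification.
    """
    outdir = Path(config.output_dir)
    act_path = outdir / "activation.tsv"
    if not act_path.exists():
        raise DataIntegrityError(f"activation table not found: {act_path}")
    activation = read_run_tsv(act_path)
    manifest = pd.read_csv(Path(config.event_dir) / config.manifest)
    status = manifest[["patient_id", "cohort", "status"]].drop_duplicates("patient_id")

    patients = [PatientRecord(patient_id=r.patient_id, cohort=r.cohort, status=r.status)
                for r in status.itertuples()]
    evaluable, excl_log = exclude_nonresponders(
        patients, activation, threshold=config.positivity_threshold)
    keep = {p.patient_id for p in evaluable}

    wide = activation[activation["patient_id"].isin(keep)
                      & (activation["condition"] == "allergen")]
    wide = (wide.groupby(["patient_id", "allergen"])["pct_cd63_pos"].mean()
            .unstack("allergen").add_prefix("bat_").reset_index())
    wide = wide.merge(status[["patient_id", "status"]], on="patient_id")

    sige_path = Path(config.event_dir) / "sige.csv"
    if sige_path.exists():
        sige = pd.read_csv(sige_path)
        sige = sige.rename(columns={c: f"sige_{c}" for c in sige.columns
                                    if c != "patient_id"})
        wide = wide.merge(sige, on="patient_id", how="left")

    summaries, classes = cohort_report(wide, tie_break=config.youden_tie_break)
    table = summaries_to_frame(summaries)
    _write_tsv(table, outdir / "diagnostics.tsv", config)
    _write_tsv(classes, outdir / "reactivity_classes.tsv", config)
    _write_tsv(wide, outdir / "patient_table.tsv", config)
    (outdir / "diagnostics.json").write_text(json.dumps({
        "version": __version__, "config_hash": config.hash,
        "evaluable_patients": sorted(keep),
        "n_evaluable": len(keep),
        "exclusions": excl_log,
        "summaries": table.to_dict(orient="records"),
    }, indent=2, default=str))
    log.info("diagnostics for %d evaluable patients -> %s", len(keep), outdir)
    return outdir
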