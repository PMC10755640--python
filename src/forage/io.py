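"""Session-log and configuration I/O, plus the end-to-end pipeline.

Session-log CSV schema (UTF-8, comma-separated, ``.`` decimal, LF line
endings; header required), one row per trial::

    subject_id,genotype,sex,session_id,trial_index,block_index,
    high_side,choice,rewarded,iti_s,nolick_s

``choice`` may be ``none``; missing numeric values are empty fields.
Malformed rows are reported with their line number.  ``subjects.csv``
carries one row per subject: ``subject_id,genotype,sex,seizure_flag``.

The pipeline (simulate -> analyze -> compare -> report) is the programmatic
core behind the command line; every stage writes plain-text artifacts and
the run is summarized in a manifest whose inputs fully determine the
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort
from .metrics import reversal_aligned_by_subject, subject_metrics
from .stats import ALPHA, compare_metric_tables
from .task_engine import LEFT, NONE, RIGHT, Session, TaskConfig, Trial

log = logging.getLogger("forage")

CSV_COLUMNS = ["subject_id", "genotype", "sex", "session_id", "trial_index",
               "block_index", "high_side", "choice", "rewarded", "iti_s",
               "nolick_s"]


class SchemaError(ValueError):
    """A session log violates the CSV schema; the message names the row."""


# ---------------------------------------------------------------------------
# Session-log CSV
# ---------------------------------------------------------------------------

def sessions_to_frame(sessions: List[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append((s.subject_id, s.genotype, s.sex, s.session_id,
                         t.index, t.block_index, t.high_side, t.choice,
                         int(t.rewarded),
                         "" if t.iti_s is None else repr(float(t.iti_s)),
                         "" if t.nolick_duration_s is None
                         else repr(float(t.nolick_duration_s))))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_sessions(cohort: Cohort, path) -> None:
    """Write a cohort's trials to the session-log CSV (plus subjects.csv
    next to it when ``path`` is inside a directory)."""
    path = Path(path)
    frame = sessions_to_frame(cohort.sessions)
    frame.to_csv(path, index=False, lineterminator="\n")
    cohort.subjects.to_csv(path.with_name("subjects.csv"), index=False,
                           lineterminator="\n")


def _parse_float(value, line: int, col: str) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float)
                                        and pd.isna(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"line {line}: {col}={value!r} is not a number")


def read_sessions(path, subjects_path=None) -> Cohort:
    """Parse a session-log CSV into a :class:`Cohort`.

    Round-trips losslessly with :func:`write_sessions`.  Schema violations
    (unknown columns, invalid enum values, non-monotone trial indices)
    raise :class:`SchemaError` naming the offending line (1-based, header
    = line 1).  An empty file with a valid header yields an empty cohort.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != CSV_COLUMNS:
        raise SchemaError(
            f"header mismatch: expected {CSV_COLUMNS}, got "
            f"{list(frame.columns)}")

    sessions: List[Session] = []
    current: Optional[Session] = None
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        key = (row.subject_id, row.session_id)
        if row.genotype not in ("WT", "HET"):
            raise SchemaError(f"line {line}: invalid genotype {row.genotype!r}")
        if row.sex not in ("M", "F"):
            raise SchemaError(f"line {line}: invalid sex {row.sex!r}")
        if row.high_side not in (LEFT, RIGHT):
            raise SchemaError(f"line {line}: invalid high_side "
                              f"{row.high_side!r}")
        if row.choice not in (LEFT, RIGHT, NONE):
            raise SchemaError(f"line {line}: invalid choice {row.choice!r}")
        if row.rewarded not in ("0", "1", "True", "False"):
            raise SchemaError(f"line {line}: invalid rewarded "
                              f"{row.rewarded!r}")
        try:
            t_index = int(row.trial_index)
            b_index = int(row.block_index)
        except ValueError:
            raise SchemaError(f"line {line}: non-integer trial/block index")

        if current is None or (current.subject_id,
                               current.session_id) != key:
            if t_index != 0:
                raise SchemaError(
                    f"line {line}: session {key} does not start at "
                    f"trial_index 0")
            current = Session(subject_id=row.subject_id,
                              genotype=row.genotype, sex=row.sex,
                              variant="full_freely_moving",
                              session_id=row.session_id)
            sessions.append(current)
        else:
            prev = current.trials[-1]
            if t_index != prev.index + 1:
                raise SchemaError(
                    f"line {line}: non-monotone trial_index {t_index} "
                    f"after {prev.index}")
            if b_index == prev.block_index + 1:
                current.block_boundaries.append(t_index)
            elif b_index != prev.block_index:
                raise SchemaError(
                    f"line {line}: block_index jumped from "
                    f"{prev.block_index} to {b_index}")
        nolick = _parse_float(row.nolick_s, line, "nolick_s")
        if nolick is not None:
            # the schema does not carry the variant; no-lick timing marks
            # head-fixed sessions
            current.variant = "headfixed_bandit"
        current.trials.append(Trial(
            index=t_index, block_index=b_index, high_side=row.high_side,
            choice=row.choice,
            rewarded=row.rewarded in ("1", "True"),
            iti_s=_parse_float(row.iti_s, line, "iti_s"),
            nolick_duration_s=nolick))

    if subjects_path is None:
        candidate = path.with_name("subjects.csv")
        subjects_path = candidate if candidate.exists() else None
    if subjects_path is not None:
        subjects = pd.read_csv(subjects_path)
        subjects["seizure_flag"] = subjects["seizure_flag"].astype(bool)
    else:
        meta = {(s.subject_id): (s.genotype, s.sex) for s in sessions}
        subjects = pd.DataFrame(
            [{"subject_id": k, "genotype": v[0], "sex": v[1],
              "seizure_flag": False} for k, v in sorted(meta.items())],
            columns=["subject_id", "genotype", "sex", "seizure_flag"])
    return Cohort(subjects=subjects, sessions=sessions)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_cohort_spec(path) -> CohortSpec:
    """Read a cohort spec from YAML.

    Recognized keys mirror :class:`CohortSpec`; curriculum entries may be
    preset names or inline task-config mappings (``variant`` plus any
    :class:`TaskConfig` field).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "curriculum" in raw:
        resolved = []
        for entry in raw["curriculum"]:
            if isinstance(entry, dict):
                resolved.append(TaskConfig(**entry))
            else:
                resolved.append(entry)
        raw["curriculum"] = resolved
    return CohortSpec(**raw)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    outputs: Dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _spec_hash(spec: CohortSpec) -> str:
    payload = repr(spec).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def pipeline_run(spec: CohortSpec, outdir,
                 n_after: int = 10) -> RunManifest:
    """simulate -> analyze -> compare -> report, all artifacts to ``outdir``.

    Writes the session-log and subjects CSVs, a per-subject metric table,
    per-genotype reversal-aligned curves, a JSON comparison report and a
    markdown summary.  Output bytes are a pure function of the spec (the
    manifest's timestamp is the only run-dependent value and lives outside
    the analysis artifacts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_spec_hash(spec),
                           master_seed=spec.master_seed,
                           version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    log.info("simulate: seed=%d subjects/cell=%d", spec.master_seed,
             spec.n_per_cell)
    try:
        cohort = generate_cohort(spec)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed on spec "
                           f"{_spec_hash(spec)}: {exc}") from exc
    sessions_csv = outdir / "sessions.csv"
    write_sessions(cohort, sessions_csv)
    manifest.outputs["sessions"] = str(sessions_csv)
    manifest.outputs["subjects"] = str(outdir / "subjects.csv")

    log.info("analyze: %d sessions", len(cohort.sessions))
    try:
        table = subject_metrics(cohort.sessions)
        curves = []
        for genotype in ("WT", "HET"):
            cs = reversal_aligned_by_subject(
                cohort.sessions_for(genotype=genotype), n_after=n_after)
            cs.insert(0, "genotype", genotype)
            curves.append(cs)
        curve_frame = pd.concat(curves, ignore_index=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc
    metrics_csv = outdir / "subject_metrics.csv"
    table.to_csv(metrics_csv, index=False, lineterminator="\n")
    curves_csv = outdir / "reversal_curves.csv"
    curve_frame.to_csv(curves_csv, index=False, lineterminator="\n")
    manifest.outputs["metrics"] = str(metrics_csv)
    manifest.outputs["curves"] = str(curves_csv)

    log.info("compare: WT vs HET, alpha=%.2f", ALPHA)
    try:
        wt = table[table.genotype == "WT"]
        het = table[table.genotype == "HET"]
        report = compare_metric_tables(wt, het)
    except Exception as exc:
        raise RuntimeError(f"stage 'compare' failed: {exc}") from exc
    stats_json = outdir / "comparison.json"
    stats_json.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
    manifest.outputs["comparison"] = str(stats_json)

    try:
        md = render_report(spec, report)
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc
    report_md = outdir / "report.md"
    report_md.write_text(md, encoding="utf-8")
    manifest.outputs["report"] = str(report_md)

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n",
                                          encoding="utf-8")
    return manifest


def render_report(spec: CohortSpec, comparison: Dict) -> str:
    """Markdown summary of the genotype comparison (deterministic bytes
    for a given spec)."""
    lines = [
        "# Synthetic cohort genotype comparison",
        "",
        f"- master seed: {spec.master_seed}",
        f"- subjects per genotype x sex cell: {spec.n_per_cell}",
        f"- injected genotype effect size: {spec.effect_size}",
        f"- significance level: {comparison['alpha']}",
        f"- Bonferroni family size: {comparison['m']}",
        "",
        "| metric | U | p | p (Bonferroni) | significant |",
        "|---|---|---|---|---|",
    ]
    for name, r in sorted(comparison["metrics"].items()):
        lines.append(
            f"| {name} | {r['U']:.1f} | {r['p']:.4f} | "
            f"{r['p_adjusted']:.4f} | {'yes' if r['significant'] else 'no'} |")
    lines.append("")
    if comparison["any_significant"]:
        lines.append("Conclusion: at least one metric differs between "
                     "genotypes after Bonferroni correction.")
    else:
        lines.append("Conclusion: no genotype effect detected on any metric "
                     "after Bonferroni correction.")
    lines.append("")
    return "\n".join(lines)
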