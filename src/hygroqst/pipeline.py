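"""End-to-end orchestration: data -> temperature summaries -> group ANOVAs
-> individual profiling -> abnormality summary -> rendered report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .anova import AnovaTable, MixedDesignData, mixed_anova, paired_contrast
from .data_model import (Dataset, Group, Mode, Quality, Session, Site,
                         read_dataset, summarize_cohort)
from .profiling import (AbnormalitySummary, ProfilingConfig, SensoryProfile,
                        normative_from_dataset, profile_cohort,
                        read_normative_csv, summarize_abnormalities)
from .temperature import (DEFAULT_WINDOW_S, session_group_summary,
                          summarize_sessions)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report",
           "mode_design", "session_design", "anova_frame", "profiles_frame"]

SESSION_ORDER = [Session.NEUTRAL, Session.HEAT, Session.COLD]


def mode_design(dataset: Dataset, site: Site, quality: Quality,
                session: Session = Session.NEUTRAL,
                response: str = "wetness") -> MixedDesignData:
    """Group x stimulation-mode design for one site/quality cell."""
    site, quality, session = Site.parse(site), Quality.parse(quality), Session.parse(session)
    values: Dict[str, Dict[Mode, float]] = {}
    for r in dataset.ratings:
        if r.site is site and r.quality is quality and r.session is session:
            values.setdefault(r.participant_id, {})[r.mode] = getattr(r, response)
    subjects, groups, rows = [], [], []
    for p in dataset.participants:
        cell = values.get(p.id)
        if cell and Mode.STATIC in cell and Mode.DYNAMIC in cell:
            subjects.append(p.id)
            groups.append(str(p.group))
            rows.append([cell[Mode.STATIC], cell[Mode.DYNAMIC]])
    return MixedDesignData(subjects=subjects, groups=groups,
                           responses=np.array(rows),
                           within_levels=["STATIC", "DYNAMIC"])


def session_design(dataset: Dataset, mode: Mode = Mode.DYNAMIC,
                   response: str = "wetness") -> MixedDesignData:
    """Group x session design on ratings collapsed over site and quality."""
    mode = Mode.parse(mode)
    sums: Dict[str, Dict[Session, list]] = {}
    for r in dataset.ratings:
        if r.mode is mode:
            sums.setdefault(r.participant_id, {}).setdefault(r.session, []).append(
                getattr(r, response))
    subjects, groups, rows = [], [], []
    for p in dataset.participants:
        per = sums.get(p.id)
        if per and all(s in per for s in SESSION_ORDER):
            subjects.append(p.id)
            groups.append(str(p.group))
            rows.append([float(np.mean(per[s])) for s in SESSION_ORDER])
    return MixedDesignData(subjects=subjects, groups=groups,
                           responses=np.array(rows),
                           within_levels=[s.name for s in SESSION_ORDER])


def anova_frame(table: AnovaTable) -> pd.DataFrame:
    rows = []
    for e in table.effects.values():
        rows.append({"effect": e.name, "ss": e.ss, "df": e.df,
                     "df_corrected": e.df_corrected, "ms": e.ms,
                     "F": np.nan if e.f is None else e.f,
                     "p": np.nan if e.p is None else e.p,
                     "percent_total": e.percent_total})
    df = pd.DataFrame(rows)
    df.attrs["epsilon"] = table.epsilon
    return df


def profiles_frame(profiles: List[SensoryProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for (site, quality), c in sorted(p.cells.items(),
                                         key=lambda kv: (kv[0][0].name, kv[0][1].name)):
            rows.append({"participant_id": p.participant_id, "site": site.name,
                         "quality": quality.name,
                         "raw_mm": np.nan if c.raw_value is None else c.raw_value,
                         "z": c.z, "label": str(c.label)})
    return pd.DataFrame(rows, columns=["participant_id", "site", "quality",
                                       "raw_mm", "z", "label"])


@dataclass
class PipelineConfig:
    participants_csv: str
    ratings_csv: str
    temperatures_csv: Optional[str] = None
    normative_csv: Optional[str] = None
    output_dir: str = "results"
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    window_s: Tuple[float, float] = DEFAULT_WINDOW_S
    seed: int = 0
    verbosity: int = 1

    def content_hash(self) -> str:
        blob = json.dumps({
            "participants_csv": str(self.participants_csv),
            "ratings_csv": str(self.ratings_csv),
            "temperatures_csv": None if self.temperatures_csv is None else str(self.temperatures_csv),
            "normative_csv": None if self.normative_csv is None else str(self.normative_csv),
            "log_offset": self.profiling.log_offset,
            "threshold": self.profiling.threshold,
            "transform": self.profiling.transform.value,
            "window_s": list(self.window_s),
            "seed": self.seed,
        }, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    cohort_summary: pd.DataFrame
    temperature_sessions: Optional[pd.DataFrame]
    temperature_contrasts: Optional[pd.DataFrame]
    mode_anovas: Dict[str, pd.DataFrame]
    session_anova: Optional[pd.DataFrame]
    session_contrasts: Optional[pd.DataFrame]
    profiles: pd.DataFrame
    abnormalities: Optional[AbnormalitySummary]
    provenance: Dict[str, object]


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic given identical inputs."""
    load = _stage("read")
    dataset = load(read_dataset, cfg.participants_csv, cfg.ratings_csv,
                   cfg.temperatures_csv)
    logger.info("loaded %d participants, %d ratings, %d temperature samples",
                len(dataset.participants), len(dataset.ratings),
                len(dataset.temperatures))

    cohort = _stage("cohort_summary")(summarize_cohort, dataset.participants)

    temp_sessions = temp_contrasts = None
    if dataset.temperatures:
        temp_sessions = _stage("temperature")(summarize_sessions,
                                              dataset.temperatures, cfg.window_s)
        cells, contrasts = _stage("temperature")(
            session_group_summary, temp_sessions, dataset.participants)
        temp_contrasts = contrasts

    mode_anovas: Dict[str, pd.DataFrame] = {}
    sites_present = {r.site for r in dataset.ratings}
    sessions_present = {r.session for r in dataset.ratings}
    if Session.NEUTRAL in sessions_present:
        for site in sorted(sites_present, key=lambda s: s.name):
            for quality in Quality:
                design = mode_design(dataset, site, quality)
                if len(design.subjects) >= 4:
                    table = _stage("mode_anova")(mixed_anova, design)
                    mode_anovas[f"{site.name}/{quality.name}"] = anova_frame(table)

    session_anova = session_contrasts = None
    if sessions_present >= set(SESSION_ORDER):
        design = session_design(dataset)
        table = _stage("session_anova")(mixed_anova, design)
        session_anova = anova_frame(table)
        rows = []
        idx = {lvl: i for i, lvl in enumerate(design.within_levels)}
        for a, b in (("HEAT", "NEUTRAL"), ("COLD", "NEUTRAL"), ("HEAT", "COLD")):
            res = paired_contrast(design.responses[:, idx[a]], design.responses[:, idx[b]])
            rows.append({"comparison": f"{a} - {b}", "mean_difference": res.difference,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "p": res.p_adjusted})
        session_contrasts = pd.DataFrame(rows)

    if cfg.normative_csv is not None:
        refs = _stage("normative")(read_normative_csv, cfg.normative_csv, cfg.profiling)
    else:
        ctr_ids = dataset.group_ids(Group.CTR)
        refs = _stage("normative")(normative_from_dataset, dataset, cfg.profiling) \
            if ctr_ids else {}

    profiles_df = pd.DataFrame()
    abnormalities = None
    if refs and dataset.group_ids(Group.MS):
        profiles = _stage("profiling")(profile_cohort, dataset, refs, cfg.profiling)
        profiles_df = profiles_frame(profiles)
        abnormalities = _stage("profiling")(summarize_abnormalities, profiles)

    provenance = {"config_sha256": cfg.content_hash(), "seed": cfg.seed,
                  "software_version": __version__,
                  "n_participants": len(dataset.participants),
                  "n_ratings": len(dataset.ratings),
                  "n_temperature_samples": len(dataset.temperatures)}
    return RunReport(cohort_summary=cohort, temperature_sessions=temp_sessions,
                     temperature_contrasts=temp_contrasts, mode_anovas=mode_anovas,
                     session_anova=session_anova, session_contrasts=session_contrasts,
                     profiles=profiles_df, abnormalities=abnormalities,
                     provenance=provenance)


def _fmt(df: pd.DataFrame, decimals: Dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in decimals.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.{nd}f}")
    return out


def _md_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
    return "\n".join(lines)


def render_report(report: RunReport, output_dir, formats=("md", "csv")) -> List[Path]:
    """Write the report as markdown plus per-table CSVs.

    mm and degC values are shown at 1 decimal, z-scores at 2 decimals.
    The markdown body is timestamp-free so identical runs are byte-identical.
    """
    for f in formats:
        if f not in ("md", "csv"):
            raise DataError(f"unsupported report format {f!r}")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    tables: Dict[str, pd.DataFrame] = {"cohort_summary": report.cohort_summary}
    if report.temperature_sessions is not None:
        tables["temperature_sessions"] = report.temperature_sessions
        tables["temperature_contrasts"] = report.temperature_contrasts
    for name, df in report.mode_anovas.items():
        tables[f"anova_mode_{name.replace('/', '_').lower()}"] = df
    if report.session_anova is not None:
        tables["anova_session"] = report.session_anova
        tables["session_contrasts"] = report.session_contrasts
    if not report.profiles.empty:
        tables["sensory_profiles"] = report.profiles

    if "csv" in formats:
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)

    if "md" in formats:
        lines = ["# Hygrosensory QST analysis report", ""]
        lines += ["## Provenance", ""]
        for k, v in report.provenance.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        one_dp = {c: 1 for c in ("age_mean", "age_sd", "height_mean", "height_sd",
                                 "mass_mean", "mass_sd", "edss_mean", "edss_sd",
                                 "mean_tsk_c", "mean_trec_c", "mean_difference",
                                 "ci_low", "ci_high", "mean", "sd", "raw_mm")}
        for name, df in tables.items():
            lines.append(f"## {name}")
            lines.append("")
            shown = _fmt(df, {**one_dp, "z": 2, "p": 4, "F": 2,
                              "percent_total": 2, "ss": 2, "ms": 2,
                              "df_corrected": 1})
            lines.append(_md_table(shown))
            lines.append("")
        lines.append("## Abnormality summary")
        lines.append("")
        if report.abnormalities is None or report.abnormalities.n_flagged == 0:
            lines.append("none flagged")
        else:
            ab = report.abnormalities
            lines.append(f"- flagged: {sorted(ab.flagged_participants)} "
                         f"({ab.n_flagged}/{ab.n_assessed}, "
                         f"proportion {ab.proportion:.2f})")
            for pid, (nsites, nquals, sites, quals) in sorted(ab.patterns.items()):
                lines.append(f"- {pid}: {nsites} site(s) {list(sites)}, "
                             f"{nquals} quality(ies) {list(quals)}")
        lines.append("")
        p = outdir / "report.md"
        p.write_text("\n".join(lines), encoding="utf-8")
        written.append(p)
    return written
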