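"""Individual hygrosensory profiling against normative references.

The procedure standard in quantitative sensory testing: a patient's VAS
wetness rating for a (site, stimulus quality) cell is log10-transformed
and expressed as a z-score against the log-scale mean and SD of a pooled
normative (healthy control) sample for the same cell,

    z = (log10(x + c) - mean_log) / sd_log ,

with an offset ``c`` (default 1 mm) so that ratings of 0 stay finite.
Perceptions less intense than the normative mean give negative z; a cell
with z < -1.96 is classified as a loss of hygrosensory function, z > +1.96
as a gain (outside the normative 95% interval), otherwise normal.  Exact
ties with the threshold are classified NORMAL (strict inequalities).

Normative references are always recomputed from raw control values —
log-scale moments cannot be recovered from published raw-scale summaries.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .data_model import (DataError, Dataset, Group, Mode, PerceptualRating,
                         Quality, Session, Site)

logger = logging.getLogger(__name__)

__all__ = [
    "Transform", "Label", "ProfilingConfig", "NormativeReference",
    "SensoryProfileCell", "SensoryProfile", "AbnormalitySummary",
    "log_transform", "build_normative", "z_score", "classify",
    "profile_participant", "profile_cohort", "profiles_from_z",
    "summarize_abnormalities", "normative_from_dataset",
    "read_normative_csv", "write_normative_csv",
]


class Transform(enum.Enum):
    LOG10 = "LOG10"
    RAW = "RAW"


class Label(enum.Enum):
    LOSS = "LOSS"
    NORMAL = "NORMAL"
    GAIN = "GAIN"

    def __str__(self):
        return self.value


@dataclass(frozen=True)
class ProfilingConfig:
    log_offset: float = 1.0    # mm added before log10 so 0 stays finite
    threshold: float = 1.96    # |z| beyond which a cell is abnormal
    transform: Transform = Transform.LOG10

    def __post_init__(self):
        if self.threshold <= 0:
            raise DataError("threshold must be > 0")
        if self.log_offset < 0:
            raise DataError("log_offset must be >= 0")


def log_transform(x: float, cfg: ProfilingConfig = ProfilingConfig()) -> float:
    """log10(x + offset) under LOG10; identity under RAW.  x is mm, >= 0."""
    if x < 0:
        raise DataError(f"VAS value {x} is negative")
    if cfg.transform is Transform.RAW:
        return float(x)
    shifted = x + cfg.log_offset
    if shifted <= 0:
        raise DataError(f"x + log_offset = {shifted} is not positive")
    return math.log10(shifted)


@dataclass
class NormativeReference:
    """Pooled control ratings for one (site, quality), with recomputed moments."""

    site: Site
    quality: Quality
    values: np.ndarray        # raw mm ratings
    n: int = field(init=False)
    mean_raw: float = field(init=False)
    sd_raw: float = field(init=False)
    mean_log: float = field(init=False)
    sd_log: float = field(init=False)
    log_offset: float = 1.0

    def __post_init__(self):
        self.site = Site.parse(self.site)
        self.quality = Quality.parse(self.quality)
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise DataError("a normative reference needs at least 2 values")
        if np.any((v < 0) | (v > 100)):
            raise DataError("normative values must lie in [0, 100]")
        self.values = v
        self.n = int(v.size)
        self.mean_raw = float(v.mean())
        self.sd_raw = float(v.std(ddof=1))
        logs = np.log10(v + self.log_offset)
        self.mean_log = float(logs.mean())
        self.sd_log = float(logs.std(ddof=1))
        if self.sd_raw == 0.0:
            raise DataError(
                f"all normative values identical for ({self.site}, {self.quality}); "
                "profiling impossible for that cell")


def build_normative(values: Sequence[float], site: Site, quality: Quality,
                    cfg: ProfilingConfig = ProfilingConfig()) -> NormativeReference:
    return NormativeReference(site=site, quality=quality,
                              values=np.asarray(values, dtype=float),
                              log_offset=cfg.log_offset)


def z_score(x: float, ref: NormativeReference,
            cfg: ProfilingConfig = ProfilingConfig()) -> float:
    """Standardize one rating against its normative reference.

    Below-normative perception gives negative z; strictly increasing in x.
    """
    if cfg.transform is Transform.LOG10:
        if ref.sd_log <= 0:
            raise DataError("degenerate normative reference (sd_log = 0)")
        return (log_transform(x, cfg) - ref.mean_log) / ref.sd_log
    if ref.sd_raw <= 0:
        raise DataError("degenerate normative reference (sd_raw = 0)")
    return (float(x) - ref.mean_raw) / ref.sd_raw


def classify(z: float, cfg: ProfilingConfig = ProfilingConfig()) -> Label:
    """Strict threshold rule: LOSS iff z < -t, GAIN iff z > +t, else NORMAL."""
    if not math.isfinite(z):
        raise DataError(f"non-finite z {z}")
    if z < -cfg.threshold:
        return Label.LOSS
    if z > cfg.threshold:
        return Label.GAIN
    return Label.NORMAL


@dataclass(frozen=True)
class SensoryProfileCell:
    participant_id: str
    site: Site
    quality: Quality
    raw_value: Optional[float]  # mm; None when only z is known
    z: float
    label: Label


@dataclass
class SensoryProfile:
    """Grid of z-scored cells for one participant."""

    participant_id: str
    cells: Dict[Tuple[Site, Quality], SensoryProfileCell] = field(default_factory=dict)

    def add(self, cell: SensoryProfileCell) -> None:
        key = (cell.site, cell.quality)
        if key in self.cells:
            raise DataError(f"duplicate profile cell {key} for {self.participant_id}")
        self.cells[key] = cell

    def abnormal_cells(self) -> List[SensoryProfileCell]:
        return [c for c in self.cells.values() if c.label is not Label.NORMAL]

    @property
    def flagged(self) -> bool:
        return bool(self.abnormal_cells())


def profile_participant(ratings: Iterable[PerceptualRating],
                        refs: Mapping[Tuple[Site, Quality], NormativeReference],
                        cfg: ProfilingConfig = ProfilingConfig(),
                        mode: Mode = Mode.DYNAMIC,
                        session: Session = Session.NEUTRAL) -> SensoryProfile:
    """Profile one participant's wetness ratings for one session/mode.

    Cells without a normative reference (e.g. the forearm, for which no
    normative data set exists) are skipped with a logged warning.
    """
    selected = [r for r in ratings if r.mode is Mode.parse(mode)
                and r.session is Session.parse(session)]
    if not selected:
        raise DataError("no ratings for the requested session/mode")
    pid = selected[0].participant_id
    profile = SensoryProfile(participant_id=pid)
    for r in selected:
        if r.participant_id != pid:
            raise DataError("profile_participant received ratings from several participants")
        ref = refs.get((r.site, r.quality))
        if ref is None:
            logger.debug("no normative reference for (%s, %s); cell skipped",
                         r.site, r.quality)
            continue
        z = z_score(r.wetness, ref, cfg)
        profile.add(SensoryProfileCell(participant_id=pid, site=r.site,
                                       quality=r.quality, raw_value=r.wetness,
                                       z=z, label=classify(z, cfg)))
    return profile


def profile_cohort(dataset: Dataset,
                   refs: Mapping[Tuple[Site, Quality], NormativeReference],
                   cfg: ProfilingConfig = ProfilingConfig(),
                   group: Group = Group.MS,
                   mode: Mode = Mode.DYNAMIC,
                   session: Session = Session.NEUTRAL) -> List[SensoryProfile]:
    """One SensoryProfile per participant of ``group``."""
    ids = dataset.group_ids(group)
    by_pid: Dict[str, list] = {pid: [] for pid in ids}
    missing = set()
    for r in dataset.ratings:
        if r.participant_id in by_pid:
            by_pid[r.participant_id].append(r)
            if (r.site, r.quality) not in refs:
                missing.add((r.site, r.quality))
    if missing:
        logger.warning("no normative reference for %s; those cells are skipped",
                       sorted((s.name, q.name) for s, q in missing))
    return [profile_participant(rs, refs, cfg, mode, session)
            for pid, rs in by_pid.items() if rs]


def profiles_from_z(z_table: pd.DataFrame,
                    cfg: ProfilingConfig = ProfilingConfig()) -> List[SensoryProfile]:
    """Build profiles from precomputed z-scores (columns: participant_id,
    site, quality, z, optional wetness_mm), bypassing the z computation.

    Used when only published z-scores are available, not the normative raw
    values behind them.
    """
    profiles: Dict[str, SensoryProfile] = {}
    for _, row in z_table.iterrows():
        pid = str(row["participant_id"])
        profile = profiles.setdefault(pid, SensoryProfile(participant_id=pid))
        z = float(row["z"])
        raw = float(row["wetness_mm"]) if "wetness_mm" in row else None
        profile.add(SensoryProfileCell(
            participant_id=pid, site=Site.parse(row["site"]),
            quality=Quality.parse(row["quality"]), raw_value=raw,
            z=z, label=classify(z, cfg)))
    return list(profiles.values())


@dataclass
class AbnormalitySummary:
    flagged_participants: Set[str]
    n_flagged: int
    n_assessed: int
    proportion: float
    #: participant id -> (n distinct sites, n distinct qualities, sites, qualities)
    patterns: Dict[str, tuple]


def summarize_abnormalities(profiles: Sequence[SensoryProfile]) -> AbnormalitySummary:
    """Flag participants with >= 1 abnormal (LOSS or GAIN) cell."""
    if not profiles:
        raise DataError("no profiles to summarize")
    flagged = {}
    for p in profiles:
        abnormal = p.abnormal_cells()
        if abnormal:
            sites = sorted({c.site.name for c in abnormal})
            qualities = sorted({c.quality.name for c in abnormal})
            flagged[p.participant_id] = (len(sites), len(qualities),
                                         tuple(sites), tuple(qualities))
    return AbnormalitySummary(
        flagged_participants=set(flagged), n_flagged=len(flagged),
        n_assessed=len(profiles),
        proportion=len(flagged) / len(profiles), patterns=flagged)


def normative_from_dataset(dataset: Dataset,
                           cfg: ProfilingConfig = ProfilingConfig(),
                           group: Group = Group.CTR,
                           mode: Mode = Mode.DYNAMIC,
                           session: Session = Session.NEUTRAL,
                           sites: Optional[Sequence[Site]] = None
                           ) -> Dict[Tuple[Site, Quality], NormativeReference]:
    """Pool a dataset's control ratings into per-(site, quality) references."""
    ids = set(dataset.group_ids(group))
    pooled: Dict[Tuple[Site, Quality], list] = {}
    for r in dataset.ratings:
        if (r.participant_id in ids and r.mode is Mode.parse(mode)
                and r.session is Session.parse(session)):
            if sites is None or r.site in sites:
                pooled.setdefault((r.site, r.quality), []).append(r.wetness)
    return {key: build_normative(vals, key[0], key[1], cfg)
            for key, vals in pooled.items()}


# ---- normative file format: one row per control observation ---------------

NORMATIVE_COLUMNS = ["site", "quality", "value_mm", "source_id"]


def write_normative_csv(refs: Mapping[Tuple[Site, Quality], NormativeReference],
                        path) -> None:
    rows = []
    for (site, quality), ref in refs.items():
        for i, v in enumerate(ref.values):
            rows.append({"site": str(site), "quality": str(quality),
                         "value_mm": float(v), "source_id": f"ctrl{i + 1}"})
    pd.DataFrame(rows, columns=NORMATIVE_COLUMNS).to_csv(path, index=False)


def read_normative_csv(path, cfg: ProfilingConfig = ProfilingConfig()
                       ) -> Dict[Tuple[Site, Quality], NormativeReference]:
    df = pd.read_csv(path, dtype={"site": str, "quality": str, "value_mm": float})
    missing = [c for c in ("site", "quality", "value_mm") if c not in df.columns]
    if missing:
        from .data_model import MissingColumnError
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    refs = {}
    for (site_s, quality_s), sub in df.groupby(["site", "quality"]):
        site, quality = Site.parse(site_s), Quality.parse(quality_s)
        refs[(site, quality)] = build_normative(sub["value_mm"].to_numpy(),
                                                site, quality, cfg)
    return refs
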