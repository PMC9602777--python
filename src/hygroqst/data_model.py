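"""Core domain types and delimited-text I/O for the hygrosensory QST pipeline.

The pipeline operates on three flat tables:

* ``participants.csv`` — one row per participant (MS patients and healthy
  controls), with anthropometrics and, for the MS group, the EDSS
  disability score and disease course.
* ``ratings.csv`` — one visual-analogue-scale (VAS) observation per row:
  a wetness and a thermal rating (mm on a 100-mm scale) for one
  participant x session x skin site x stimulus quality x stimulation mode
  cell.
* ``temperatures.csv`` — 2-Hz records of six local skin temperatures plus
  rectal temperature during each environmental session.

All files are comma-delimited UTF-8 with a mandatory header row.
Enumerated fields are serialized as upper-snake strings and parsed
case-insensitively.  Missing optional fields are encoded as the empty
string (never 0 — an EDSS of 0 is a valid score).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group", "Sex", "Session", "Site", "Quality", "Mode", "MSType",
    "Stimulus", "Participant", "PerceptualRating", "TemperatureSample",
    "Dataset", "DataError", "MissingColumnError", "OutOfRangeError",
    "UnknownParticipantError", "DuplicateRatingError", "EmptyGroupError",
    "read_dataset", "write_dataset", "summarize_cohort",
]


class _CIEnum(enum.Enum):
    """Enum with case-insensitive string parsing."""

    @classmethod
    def parse(cls, value):
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper().replace("-", "_").replace(" ", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"{value!r} is not a valid {cls.__name__}") from None

    def __str__(self) -> str:  # serialized form
        return self.name


class Group(_CIEnum):
    MS = enum.auto()
    CTR = enum.auto()


class Sex(_CIEnum):
    M = enum.auto()
    F = enum.auto()


class Session(_CIEnum):
    NEUTRAL = enum.auto()
    HEAT = enum.auto()
    COLD = enum.auto()


class Site(_CIEnum):
    FINGER_PAD = enum.auto()
    FOREARM = enum.auto()
    FOREHEAD = enum.auto()


class Quality(_CIEnum):
    COLD_WET = enum.auto()
    NEUTRAL_WET = enum.auto()
    WARM_WET = enum.auto()


class Mode(_CIEnum):
    STATIC = enum.auto()
    DYNAMIC = enum.auto()


class MSType(_CIEnum):
    RR = enum.auto()  # relapsing-remitting
    PP = enum.auto()  # primary progressive
    SP = enum.auto()  # secondary progressive


# Probe temperature is determined by the stimulus quality; contact area and
# water content are fixed properties of the wet probe.
PROBE_TEMPERATURE_C = {
    Quality.COLD_WET: 25.0,
    Quality.NEUTRAL_WET: 30.0,
    Quality.WARM_WET: 35.0,
}
PROBE_CONTACT_AREA_CM2 = 1.32
PROBE_WATER_CONTENT_ML = 0.8


class DataError(ValueError):
    """Base class for dataset validation failures."""


class MissingColumnError(DataError):
    pass


class OutOfRangeError(DataError):
    pass


class UnknownParticipantError(DataError):
    pass


class DuplicateRatingError(DataError):
    pass


class EmptyGroupError(DataError):
    pass


@dataclass(frozen=True)
class Stimulus:
    """A wet stimulus: temperature-controlled probe wrapped in saturated cotton."""

    quality: Quality
    contact_area_cm2: float = PROBE_CONTACT_AREA_CM2
    water_content_ml: float = PROBE_WATER_CONTENT_ML

    @property
    def probe_temperature_c(self) -> float:
        return PROBE_TEMPERATURE_C[self.quality]


@dataclass
class Participant:
    id: str
    group: Group
    sex: Sex
    age: float            # years
    height: float         # meters
    mass: float           # kilograms
    ethnicity: str = ""
    edss: Optional[float] = None   # 0-10 in 0.5 steps, MS only
    ms_type: Optional[MSType] = None
    medications: str = ""

    def __post_init__(self):
        self.group = Group.parse(self.group)
        self.sex = Sex.parse(self.sex)
        if self.ms_type is not None and self.ms_type != "":
            self.ms_type = MSType.parse(self.ms_type)
        else:
            self.ms_type = None
        if self.age <= 0:
            raise OutOfRangeError(f"participant {self.id}: age must be > 0")
        if not (1.0 < self.height < 2.5):
            raise OutOfRangeError(f"participant {self.id}: height {self.height} m outside (1.0, 2.5)")
        if self.mass <= 0:
            raise OutOfRangeError(f"participant {self.id}: mass must be > 0")
        if self.edss is not None:
            if self.group is not Group.MS:
                raise OutOfRangeError(f"participant {self.id}: EDSS present but group is {self.group}")
            if not (0.0 <= self.edss <= 10.0) or round(self.edss * 2) != self.edss * 2:
                raise OutOfRangeError(f"participant {self.id}: EDSS {self.edss} not in 0..10 by 0.5")


@dataclass(frozen=True)
class PerceptualRating:
    """One VAS observation: wetness (0 dry .. 100 wet) and thermal (0 cold .. 100 hot)."""

    participant_id: str
    session: Session
    site: Site
    quality: Quality
    mode: Mode
    wetness: float  # mm
    thermal: float  # mm

    def __post_init__(self):
        object.__setattr__(self, "session", Session.parse(self.session))
        object.__setattr__(self, "site", Site.parse(self.site))
        object.__setattr__(self, "quality", Quality.parse(self.quality))
        object.__setattr__(self, "mode", Mode.parse(self.mode))
        for name in ("wetness", "thermal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise OutOfRangeError(
                    f"{name} rating {v} mm outside [0, 100] "
                    f"(participant {self.participant_id}, {self.site}/{self.quality}/{self.mode})"
                )

    @property
    def key(self):
        return (self.participant_id, self.session, self.site, self.quality, self.mode)


#: physiologically plausible bounds for any skin/rectal thermistor reading, degC
TEMP_BOUNDS_C = (10.0, 45.0)

#: the six local skin channels, in file-column order
SKIN_CHANNELS = ("cheek", "chest", "forearm", "hand", "thigh", "back")


@dataclass(frozen=True)
class TemperatureSample:
    """One 2-Hz record: six local skin temperatures plus rectal temperature."""

    participant_id: str
    session: Session
    time: float  # seconds from session start
    cheek: float
    chest: float
    forearm: float
    hand: float
    thigh: float
    back: float
    rectal: float

    def __post_init__(self):
        object.__setattr__(self, "session", Session.parse(self.session))
        if self.time < 0:
            raise OutOfRangeError(f"sample time {self.time} s is negative")
        lo, hi = TEMP_BOUNDS_C
        for name in SKIN_CHANNELS + ("rectal",):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise OutOfRangeError(
                    f"{name} temperature {v} degC outside ({lo}, {hi}) "
                    f"(participant {self.participant_id}, t={self.time}s)"
                )

    def channels(self) -> dict:
        return {name: getattr(self, name) for name in SKIN_CHANNELS}


@dataclass
class Dataset:
    """Validated container tying participants, ratings and temperature series."""

    participants: list = field(default_factory=list)
    ratings: list = field(default_factory=list)
    temperatures: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = {p.id for p in self.participants}
        if len(ids) != len(self.participants):
            raise DuplicateRatingError("duplicate participant ids")
        seen = set()
        for r in self.ratings:
            if r.participant_id not in ids:
                raise UnknownParticipantError(
                    f"rating references unknown participant {r.participant_id!r}")
            if r.key in seen:
                raise DuplicateRatingError(f"duplicate rating key {r.key}")
            seen.add(r.key)
        last = {}
        for t in self.temperatures:
            if t.participant_id not in ids:
                raise UnknownParticipantError(
                    f"temperature sample references unknown participant {t.participant_id!r}")
            k = (t.participant_id, t.session)
            if k in last and t.time < last[k]:
                raise OutOfRangeError(f"temperature samples out of time order for {k}")
            last[k] = t.time

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise UnknownParticipantError(pid)

    def group_ids(self, group: Group) -> list:
        return [p.id for p in self.participants if p.group is Group.parse(group)]

    # ---- tabular views -------------------------------------------------

    def participants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append({
                "id": p.id, "group": str(p.group), "sex": str(p.sex),
                "age_yr": p.age, "height_m": p.height, "mass_kg": p.mass,
                "ethnicity": p.ethnicity,
                "edss": "" if p.edss is None else p.edss,
                "ms_type": "" if p.ms_type is None else str(p.ms_type),
                "medications": p.medications,
            })
        return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)

    def ratings_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": r.participant_id, "session": str(r.session),
            "site": str(r.site), "quality": str(r.quality), "mode": str(r.mode),
            "wetness_mm": r.wetness, "thermal_mm": r.thermal,
        } for r in self.ratings]
        return pd.DataFrame(rows, columns=RATING_COLUMNS)

    def temperatures_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": t.participant_id, "session": str(t.session),
            "time_s": t.time, "cheek_c": t.cheek, "chest_c": t.chest,
            "forearm_c": t.forearm, "hand_c": t.hand, "thigh_c": t.thigh,
            "back_c": t.back, "rectal_c": t.rectal,
        } for t in self.temperatures]
        return pd.DataFrame(rows, columns=TEMPERATURE_COLUMNS)


PARTICIPANT_COLUMNS = ["id", "group", "sex", "age_yr", "height_m", "mass_kg",
                       "ethnicity", "edss", "ms_type", "medications"]
RATING_COLUMNS = ["participant_id", "session", "site", "quality", "mode",
                  "wetness_mm", "thermal_mm"]
TEMPERATURE_COLUMNS = ["participant_id", "session", "time_s", "cheek_c", "chest_c",
                       "forearm_c", "hand_c", "thigh_c", "back_c", "rectal_c"]


def _read_csv(path, required_columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    return df


def _as_float(value, context):
    try:
        return float(value)
    except (TypeError, ValueError):
        raise OutOfRangeError(f"{context}: cannot parse number from {value!r}") from None


def read_dataset(participants_path, ratings_path, temperatures_path=None) -> Dataset:
    """Load and validate a dataset from its delimited-text files.

    Raises a distinct :class:`DataError` subclass per failure mode:
    missing column, out-of-range value, unknown participant reference,
    duplicate rating key.
    """
    pdf = _read_csv(participants_path, PARTICIPANT_COLUMNS)
    participants = []
    for _, row in pdf.iterrows():
        participants.append(Participant(
            id=row["id"], group=Group.parse(row["group"]), sex=Sex.parse(row["sex"]),
            age=_as_float(row["age_yr"], "age_yr"),
            height=_as_float(row["height_m"], "height_m"),
            mass=_as_float(row["mass_kg"], "mass_kg"),
            ethnicity=row["ethnicity"],
            edss=None if row["edss"] == "" else _as_float(row["edss"], "edss"),
            ms_type=None if row["ms_type"] == "" else row["ms_type"],
            medications=row["medications"],
        ))

    rdf = _read_csv(ratings_path, RATING_COLUMNS)
    ratings = []
    for _, row in rdf.iterrows():
        ratings.append(PerceptualRating(
            participant_id=row["participant_id"], session=row["session"],
            site=row["site"], quality=row["quality"], mode=row["mode"],
            wetness=_as_float(row["wetness_mm"], "wetness_mm"),
            thermal=_as_float(row["thermal_mm"], "thermal_mm"),
        ))

    temperatures = []
    if temperatures_path is not None:
        tdf = _read_csv(temperatures_path, TEMPERATURE_COLUMNS)
        for _, row in tdf.iterrows():
            temperatures.append(TemperatureSample(
                participant_id=row["participant_id"], session=row["session"],
                time=_as_float(row["time_s"], "time_s"),
                cheek=_as_float(row["cheek_c"], "cheek_c"),
                chest=_as_float(row["chest_c"], "chest_c"),
                forearm=_as_float(row["forearm_c"], "forearm_c"),
                hand=_as_float(row["hand_c"], "hand_c"),
                thigh=_as_float(row["thigh_c"], "thigh_c"),
                back=_as_float(row["back_c"], "back_c"),
                rectal=_as_float(row["rectal_c"], "rectal_c"),
            ))

    return Dataset(participants=participants, ratings=ratings, temperatures=temperatures)


def write_dataset(dataset: Dataset, directory) -> dict:
    """Write the three dataset CSVs under ``directory``; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": directory / "participants.csv",
        "ratings": directory / "ratings.csv",
        "temperatures": directory / "temperatures.csv",
    }
    dataset.participants_frame().to_csv(paths["participants"], index=False, encoding="utf-8")
    dataset.ratings_frame().to_csv(paths["ratings"], index=False, encoding="utf-8")
    dataset.temperatures_frame().to_csv(paths["temperatures"], index=False, encoding="utf-8")
    return paths


def summarize_cohort(participants: Sequence[Participant],
                     groups: Optional[Iterable[Group]] = None) -> pd.DataFrame:
    """Per-group mean/SD (n-1 denominator) of age, height, mass and EDSS.

    With a single participant the SD is undefined and reported as NaN.
    """
    if groups is None:
        groups = sorted({p.group for p in participants}, key=lambda g: g.name)
    rows = []
    for g in groups:
        g = Group.parse(g)
        members = [p for p in participants if p.group is g]
        if not members:
            raise EmptyGroupError(f"no participants in group {g}")
        row = {"group": str(g), "n": len(members)}
        for attr in ("age", "height", "mass", "edss"):
            vals = np.array([getattr(p, attr) for p in members
                             if getattr(p, attr) is not None], dtype=float)
            if vals.size == 0:
                row[f"{attr}_mean"] = np.nan
                row[f"{attr}_sd"] = np.nan
            else:
                row[f"{attr}_mean"] = vals.mean()
                row[f"{attr}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
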