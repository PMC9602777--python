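"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates the quantitative-sensory-testing study design:

* VAS wetness ratings drawn per (site, quality, mode, session) cell from a
  normal distribution truncated to the 0-100 mm scale (exact truncated
  normal, so no spurious mass accumulates at the anchors).
* A dynamic-vs-static wetness increment per site, added to the cell mean
  before truncation (defaults are the study's observed dynamic-minus-static
  contrasts: finger pad 15.5 mm, forearm 12.4 mm, forehead 19.7 mm).
* An additive session shift on wetness (defaults 0 / +4.75 / -4.75 mm for
  the thermoneutral / heat / cold sessions, so heat - cold ~ 9.5 mm).
* 2-Hz six-channel skin temperature traces constructed so the weighted mean
  skin temperature over the final 15 min equals the session target
  (30.9 / 34.8 / 26.5 degC) up to configurable noise, with rectal
  temperature stable near 37 degC.
* Injectable "hygrosensory loss" participants whose wetness ratings at
  chosen (site, quality) cells sit near the scale floor.

Everything is deterministic given the configured seed (NumPy PCG64; the
generator algorithm is recorded in the provenance output).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.stats import truncnorm

from .data_model import (DataError, Dataset, Group, Mode, MSType, Participant,
                         PerceptualRating, Quality, Session, Sex, Site,
                         TemperatureSample, UnknownParticipantError)
from .study_data import DYNAMIC_INCREMENT_MM, NORMATIVE_SUMMARY, SESSION_MEAN_TSK_C
from .temperature import TSK_WEIGHTS

__all__ = [
    "CellDistribution", "SessionConfig", "LossInjection", "SimulationConfig",
    "default_config", "generate_cohort", "generate_temperatures",
    "inject_loss", "draw_truncated_vas", "save_config", "load_config",
    "provenance",
]

RNG_ALGORITHM = "numpy-PCG64"

VAS_LO, VAS_HI = 0.0, 100.0


@dataclass(frozen=True)
class CellDistribution:
    """Static-mode baseline wetness distribution for one (site, quality)."""

    site: Site
    quality: Quality
    mean: float  # mm
    sd: float    # mm

    def __post_init__(self):
        object.__setattr__(self, "site", Site.parse(self.site))
        object.__setattr__(self, "quality", Quality.parse(self.quality))
        if not (VAS_LO <= self.mean <= VAS_HI):
            raise DataError(f"cell mean {self.mean} outside [0, 100]")
        if self.sd <= 0:
            raise DataError("cell sd must be > 0")


@dataclass(frozen=True)
class SessionConfig:
    session: Session
    target_mean_tsk: float   # degC, window-averaged target
    tsk_noise_sd: float      # degC, between-participant spread of mean Tsk
    wetness_shift: float     # mm, additive shift on all wetness cell means
    ambient_temp: float      # degC
    ambient_rh: float        # %

    def __post_init__(self):
        object.__setattr__(self, "session", Session.parse(self.session))
        if not (20.0 < self.target_mean_tsk < 40.0):
            raise DataError(f"target mean Tsk {self.target_mean_tsk} outside (20, 40)")


@dataclass(frozen=True)
class LossInjection:
    """Replace one participant's (site, quality) wetness cells with floor draws."""

    participant_id: str
    site: Site
    quality: Quality
    floor_mean: float = 2.0  # mm
    floor_sd: float = 2.0    # mm

    def __post_init__(self):
        object.__setattr__(self, "site", Site.parse(self.site))
        object.__setattr__(self, "quality", Quality.parse(self.quality))


@dataclass
class SimulationConfig:
    seed: int
    n_ms: int = 12
    n_ctr: int = 11
    cell_distributions: List[CellDistribution] = field(default_factory=list)
    session_configs: List[SessionConfig] = field(default_factory=list)
    injections: List[LossInjection] = field(default_factory=list)
    dynamic_increment: Dict[Site, float] = field(default_factory=dict)
    session_duration_s: float = 3000.0
    sample_hz: float = 2.0
    rectal_mean: float = 37.0
    rectal_noise_sd: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise DataError("seed is mandatory")
        seen = set()
        for c in self.cell_distributions:
            key = (c.site, c.quality)
            if key in seen:
                raise DataError(f"duplicate cell distribution for {key}")
            seen.add(key)

    def cell(self, site: Site, quality: Quality) -> CellDistribution:
        for c in self.cell_distributions:
            if c.site is site and c.quality is quality:
                return c
        raise DataError(f"no cell distribution for ({site}, {quality})")

    def session(self, session: Session) -> SessionConfig:
        session = Session.parse(session)
        for s in self.session_configs:
            if s.session is session:
                return s
        raise DataError(f"no session config for {session}")


#: Forearm has no published normative distribution; this static baseline is
#: the package's own choice of a plausible hairy-skin cell (see docs/methods).
_FOREARM_STATIC = (40.0, 25.0)

_AMBIENT = {  # (temperature degC, relative humidity %)
    Session.NEUTRAL: (24.0, 49.5),
    Session.HEAT: (38.8, 49.5),
    Session.COLD: (12.9, 46.5),
}


def default_cell_distributions() -> List[CellDistribution]:
    """Static baselines chosen so DYNAMIC cell means hit the published
    normative dynamic means (static mean = dynamic mean - site increment)."""
    cells = []
    for (site, quality), (mean, sd, _n) in NORMATIVE_SUMMARY.items():
        cells.append(CellDistribution(site=site, quality=quality,
                                      mean=mean - DYNAMIC_INCREMENT_MM[site], sd=sd))
    for quality in Quality:
        cells.append(CellDistribution(site=Site.FOREARM, quality=quality,
                                      mean=_FOREARM_STATIC[0], sd=_FOREARM_STATIC[1]))
    return cells


def default_session_configs(tsk_noise_sd: float = 0.5) -> List[SessionConfig]:
    shifts = {Session.NEUTRAL: 0.0, Session.HEAT: +4.75, Session.COLD: -4.75}
    return [
        SessionConfig(session=s, target_mean_tsk=SESSION_MEAN_TSK_C[s.name],
                      tsk_noise_sd=tsk_noise_sd, wetness_shift=shifts[s],
                      ambient_temp=_AMBIENT[s][0], ambient_rh=_AMBIENT[s][1])
        for s in (Session.NEUTRAL, Session.HEAT, Session.COLD)
    ]


def default_config(seed: int, n_ms: int = 12, n_ctr: int = 11,
                   injections: Sequence[LossInjection] = (),
                   tsk_noise_sd: float = 0.5) -> SimulationConfig:
    """The study conditions: 12 MS + 11 CTR, published cell parameters."""
    return SimulationConfig(
        seed=seed, n_ms=n_ms, n_ctr=n_ctr,
        cell_distributions=default_cell_distributions(),
        session_configs=default_session_configs(tsk_noise_sd),
        injections=list(injections),
        dynamic_increment=dict(DYNAMIC_INCREMENT_MM),
    )


def draw_truncated_vas(mean: float, sd: float, size: int, rng: np.random.Generator,
                       lo: float = VAS_LO, hi: float = VAS_HI) -> np.ndarray:
    """Exact truncated-normal draws on the VAS scale.

    Sampling is by inverse CDF, which realizes the same law as rejection
    sampling (no clamping, so no spurious mass at the anchors).  ``sd = 0``
    degenerates to the clipped mean.
    """
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# Thermal VAS (0 cold .. 100 hot) cell means by stimulus quality.  The
# generator keeps thermal ratings deliberately simple: no mode or session
# structure, just quality-ordered means (see docs/methods for what this
# does and does not emulate).
_THERMAL_MEAN = {Quality.COLD_WET: 30.0, Quality.NEUTRAL_WET: 50.0, Quality.WARM_WET: 65.0}
_THERMAL_SD = 15.0


def _synth_participants(cfg: SimulationConfig, rng: np.random.Generator) -> List[Participant]:
    participants = []
    specs = [(Group.MS, "MS", cfg.n_ms), (Group.CTR, "CTR", cfg.n_ctr)]
    edss_grid = np.arange(1.0, 7.5, 0.5)
    for group, prefix, n in specs:
        for i in range(n):
            pid = f"{prefix}{i + 1:02d}"
            sex = Sex.M if rng.random() < 0.4 else Sex.F
            age = float(np.clip(rng.normal(48.0, 11.0), 18.0, 80.0))
            height = float(np.clip(rng.normal(1.72, 0.10), 1.45, 2.10))
            mass = float(np.clip(rng.normal(76.0, 17.0), 42.0, 140.0))
            edss = float(rng.choice(edss_grid)) if group is Group.MS else None
            ms_type = MSType(rng.choice([m.value for m in MSType], p=[0.6, 0.25, 0.15])) \
                if group is Group.MS else None
            participants.append(Participant(
                id=pid, group=group, sex=sex, age=round(age, 1),
                height=round(height, 2), mass=round(mass, 1),
                ethnicity="", edss=edss, ms_type=ms_type))
    return participants


def generate_cohort(cfg: SimulationConfig, with_temperatures: bool = False) -> Dataset:
    """Generate a full synthetic Dataset; deterministic given ``cfg.seed``.

    Wetness ratings per cell are truncated-normal draws around
    ``static mean (+ site dynamic increment for DYNAMIC) + session shift``.
    Loss injections from ``cfg.injections`` are applied before return.
    """
    rng = np.random.default_rng(cfg.seed)
    participants = _synth_participants(cfg, rng)
    pids = [p.id for p in participants]
    n = len(pids)

    ratings: List[PerceptualRating] = []
    for session_cfg in cfg.session_configs:
        for site in Site:
            for quality in Quality:
                cell = cfg.cell(site, quality)
                for mode in (Mode.STATIC, Mode.DYNAMIC):
                    mean = cell.mean + session_cfg.wetness_shift
                    if mode is Mode.DYNAMIC:
                        mean += cfg.dynamic_increment.get(site, 0.0)
                    wet = draw_truncated_vas(mean, cell.sd, n, rng)
                    thermal = draw_truncated_vas(_THERMAL_MEAN[quality], _THERMAL_SD, n, rng)
                    for pid, w, th in zip(pids, wet, thermal):
                        ratings.append(PerceptualRating(
                            participant_id=pid, session=session_cfg.session,
                            site=site, quality=quality, mode=mode,
                            wetness=float(w), thermal=float(th)))

    temperatures: List[TemperatureSample] = []
    if with_temperatures:
        for pid in pids:
            for session_cfg in cfg.session_configs:
                temperatures.extend(generate_temperatures(cfg, pid, session_cfg.session))

    dataset = Dataset(participants=participants, ratings=ratings,
                      temperatures=temperatures)
    if cfg.injections:
        dataset = inject_loss(dataset, cfg.injections,
                              rng=np.random.default_rng([cfg.seed, 0x10C5]))
    return dataset


# Fixed channel offsets about the mean-Tsk level (degC); the back channel is
# solved at import time so the weighted offsets sum to zero exactly, making
# the weighted mean analytically equal to the target profile.
_CHANNEL_OFFSETS = {"cheek": 2.0, "chest": 1.0, "forearm": -0.5, "hand": -3.0, "thigh": 0.5}
_CHANNEL_OFFSETS["back"] = -sum(TSK_WEIGHTS[c] * v for c, v in _CHANNEL_OFFSETS.items()) \
    / TSK_WEIGHTS["back"]


def _session_rng(cfg: SimulationConfig, participant_id: str, session: Session):
    tag = zlib.crc32(f"{participant_id}/{session.name}".encode())
    return np.random.default_rng([cfg.seed, tag])


def generate_temperatures(cfg: SimulationConfig, participant_id: str,
                          session: Session) -> List[TemperatureSample]:
    """2-Hz temperature series over the 50-min session.

    The mean-Tsk level ramps linearly from the thermoneutral baseline to the
    session target over the first 35 min and holds the target over the final
    15 min, mimicking the chamber protocol.  Channels are the level plus
    fixed site offsets whose weighted sum is zero, plus noise scaled by the
    session's ``tsk_noise_sd`` (a participant-level offset dominating a small
    per-sample jitter).  With ``tsk_noise_sd = 0`` the window-averaged mean
    Tsk equals the target exactly.
    """
    session = Session.parse(session)
    scfg = cfg.session(session)
    rng = _session_rng(cfg, participant_id, session)

    n = int(round(cfg.session_duration_s * cfg.sample_hz))
    t = np.arange(n) / cfg.sample_hz
    baseline = cfg.session(Session.NEUTRAL).target_mean_tsk \
        if any(s.session is Session.NEUTRAL for s in cfg.session_configs) else 30.9
    ramp_end = cfg.session_duration_s - 900.0
    level = np.where(t < ramp_end,
                     baseline + (scfg.target_mean_tsk - baseline) * t / ramp_end,
                     scfg.target_mean_tsk)

    participant_offset = rng.normal(0.0, scfg.tsk_noise_sd) if scfg.tsk_noise_sd > 0 else 0.0
    rectal_offset = rng.normal(0.0, cfg.rectal_noise_sd) if cfg.rectal_noise_sd > 0 else 0.0

    order = ("cheek", "chest", "forearm", "hand", "thigh", "back")
    jitter = rng.normal(0.0, scfg.tsk_noise_sd, size=(n, 6)) \
        if scfg.tsk_noise_sd > 0 else np.zeros((n, 6))
    rectal_jitter = rng.normal(0.0, 0.02, size=n) \
        if cfg.rectal_noise_sd > 0 else np.zeros(n)
    offsets = np.array([_CHANNEL_OFFSETS[name] for name in order])
    channels = level[:, None] + offsets[None, :] + participant_offset + jitter
    rectal = cfg.rectal_mean + rectal_offset + rectal_jitter

    samples = []
    for i in range(n):
        c = channels[i]
        samples.append(TemperatureSample(
            participant_id=participant_id, session=session, time=float(t[i]),
            cheek=float(c[0]), chest=float(c[1]), forearm=float(c[2]),
            hand=float(c[3]), thigh=float(c[4]), back=float(c[5]),
            rectal=float(rectal[i])))
    return samples


def inject_loss(dataset: Dataset, injections: Sequence[LossInjection],
                rng: Optional[np.random.Generator] = None) -> Dataset:
    """Return a new Dataset with designated cells replaced by floor draws.

    A loss injection is a property of the participant, so it applies to the
    (site, quality) cell in every session and both stimulation modes.  All
    other ratings are untouched.
    """
    if not injections:
        return dataset
    if rng is None:
        rng = np.random.default_rng(0)
    known = {p.id for p in dataset.participants}
    targets = {}
    for inj in injections:
        if inj.participant_id not in known:
            raise UnknownParticipantError(
                f"injection references unknown participant {inj.participant_id!r}")
        targets[(inj.participant_id, inj.site, inj.quality)] = inj

    hit = set()
    new_ratings = []
    for r in dataset.ratings:
        key = (r.participant_id, r.site, r.quality)
        inj = targets.get(key)
        if inj is None:
            new_ratings.append(r)
        else:
            hit.add(key)
            floor = float(draw_truncated_vas(inj.floor_mean, inj.floor_sd, 1, rng)[0])
            new_ratings.append(replace(r, wetness=floor))
    missed = set(targets) - hit
    if missed:
        raise DataError(f"injections target cells absent from the dataset: {sorted(missed)}")
    return Dataset(participants=dataset.participants, ratings=new_ratings,
                   temperatures=dataset.temperatures)


# ---------------------------------------------------------------------------
# config serialization and provenance

def _config_dict(cfg: SimulationConfig) -> dict:
    return {
        "seed": cfg.seed, "n_ms": cfg.n_ms, "n_ctr": cfg.n_ctr,
        "rng": RNG_ALGORITHM,
        "session_duration_s": cfg.session_duration_s, "sample_hz": cfg.sample_hz,
        "rectal_mean": cfg.rectal_mean, "rectal_noise_sd": cfg.rectal_noise_sd,
        "cell_distributions": [
            {"site": str(c.site), "quality": str(c.quality), "mean": c.mean, "sd": c.sd}
            for c in cfg.cell_distributions],
        "session_configs": [
            {"session": str(s.session), "target_mean_tsk": s.target_mean_tsk,
             "tsk_noise_sd": s.tsk_noise_sd, "wetness_shift": s.wetness_shift,
             "ambient_temp": s.ambient_temp, "ambient_rh": s.ambient_rh}
            for s in cfg.session_configs],
        "injections": [
            {"participant_id": i.participant_id, "site": str(i.site),
             "quality": str(i.quality), "floor_mean": i.floor_mean,
             "floor_sd": i.floor_sd}
            for i in cfg.injections],
        "dynamic_increment": {str(k): v for k, v in cfg.dynamic_increment.items()},
    }


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True),
                          encoding="utf-8")


def load_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SimulationConfig(
        seed=d["seed"], n_ms=d["n_ms"], n_ctr=d["n_ctr"],
        session_duration_s=d.get("session_duration_s", 3000.0),
        sample_hz=d.get("sample_hz", 2.0),
        rectal_mean=d.get("rectal_mean", 37.0),
        rectal_noise_sd=d.get("rectal_noise_sd", 0.1),
        cell_distributions=[CellDistribution(**c) for c in d["cell_distributions"]],
        session_configs=[SessionConfig(**s) for s in d["session_configs"]],
        injections=[LossInjection(**i) for i in d.get("injections", [])],
        dynamic_increment={Site.parse(k): v
                           for k, v in d.get("dynamic_increment", {}).items()},
    )


def provenance(cfg: SimulationConfig) -> dict:
    """Seed, RNG algorithm and config hash for reproducibility records."""
    blob = json.dumps(_config_dict(cfg), sort_keys=True).encode()
    return {"seed": cfg.seed, "rng": RNG_ALGORITHM,
            "config_sha256": hashlib.sha256(blob).hexdigest()}
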