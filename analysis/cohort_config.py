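"""Shared study conditions for the analysis scripts.

Two deterministic synthetic cohorts mirror the study:

* the *tested* cohort — 12 MS + 11 CTR participants, three of the MS
  participants injected with hygrosensory loss following the published
  abnormality patterns (two sites/two qualities, two sites/two qualities,
  one site/two qualities);
* the *normative* cohort — 51 healthy controls pooled into the
  per-(site, quality) reference distributions.

Every script regenerates what it needs from these seeds, so each one can
be run on its own.
"""

from hygroqst.data_model import Quality, Site
from hygroqst.synthetic import LossInjection, SimulationConfig, default_config

COHORT_SEED = 42
NORMATIVE_SEED = 1042

#: loss injections mimicking the published per-participant patterns
INJECTIONS = [
    LossInjection("MS01", Site.FOREHEAD, Quality.COLD_WET),
    LossInjection("MS01", Site.FOREHEAD, Quality.WARM_WET),
    LossInjection("MS01", Site.FINGER_PAD, Quality.WARM_WET),
    LossInjection("MS02", Site.FOREHEAD, Quality.COLD_WET),
    LossInjection("MS02", Site.FINGER_PAD, Quality.NEUTRAL_WET),
    LossInjection("MS10", Site.FINGER_PAD, Quality.COLD_WET),
    LossInjection("MS10", Site.FINGER_PAD, Quality.WARM_WET),
]


def tested_cohort_config() -> SimulationConfig:
    return default_config(seed=COHORT_SEED, n_ms=12, n_ctr=11,
                          injections=INJECTIONS)


def normative_cohort_config() -> SimulationConfig:
    return default_config(seed=NORMATIVE_SEED, n_ms=0, n_ctr=51)
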