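import numpy as np
import pytest

from hygroqst.data_model import (Dataset, Group, Mode, Participant,
                                 PerceptualRating, Quality, Session, Sex, Site,
                                 TemperatureSample)


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Two participants, a few ratings, a short temperature trace."""
    participants = [
        Participant(id="MS1", group=Group.MS, sex=Sex.M, age=40, height=1.7,
                    mass=70, edss=3.0),
        Participant(id="C1", group=Group.CTR, sex=Sex.F, age=41, height=1.65,
                    mass=60, medications="none – véritable"),
    ]
    ratings = [
        PerceptualRating("MS1", Session.NEUTRAL, Site.FOREHEAD, Quality.COLD_WET,
                         Mode.STATIC, wetness=40.0, thermal=30.0),
        PerceptualRating("MS1", Session.NEUTRAL, Site.FOREHEAD, Quality.COLD_WET,
                         Mode.DYNAMIC, wetness=55.0, thermal=28.0),
        PerceptualRating("C1", Session.NEUTRAL, Site.FOREHEAD, Quality.COLD_WET,
                         Mode.STATIC, wetness=50.0, thermal=35.0),
    ]
    temperatures = [
        TemperatureSample("MS1", Session.NEUTRAL, t, 33.0, 34.0, 32.0, 31.0,
                          34.5, 33.5, 37.0)
        for t in (0.0, 0.5, 1.0)
    ]
    return Dataset(participants=participants, ratings=ratings,
                   temperatures=temperatures)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
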