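"""Individual-level data printed by the motivating study.

The quantitative-sensory-testing study of skin wetness perception in
multiple sclerosis that this package reanalyzes printed, at the
individual level: the characteristics of its 12 MS participants, and the
dynamic wetness perceptions (mm VAS) with their z-scores for the
forehead and finger pad under the thermoneutral session.  Those printed
values are inputs to this package — they let the profiling and summary
stages be exercised and checked against the study's own group-level
numbers without access to the deposited raw data set.

Note: the printed z-scores cannot be recomputed here because the
normative raw values behind them (n = 51 forehead, n = 31 finger pad)
live in the study's supplementary deposit; only their raw-scale
summaries are printed (see :data:`NORMATIVE_SUMMARY`).
"""

from __future__ import annotations

import pandas as pd

from .data_model import Group, MSType, Participant, Quality, Sex, Site

__all__ = [
    "ms_participants", "wetness_z_table", "NORMATIVE_SUMMARY",
    "SESSION_MEAN_TSK_C", "DYNAMIC_INCREMENT_MM",
]

# id, sex, age (yr), height (m), mass (kg), ethnicity, EDSS, MS course
_MS_ROWS = [
    ("1",  "M", 38, 1.66, 69.0,  "A",  1.0, "RR", ""),
    ("2",  "F", 58, 1.73, 68.9,  "WE", 6.5, "RR", ""),
    ("3",  "F", 59, 1.60, 47.8,  "WE", 6.5, "PP", ""),
    ("4",  "M", 44, 1.78, 76.3,  "WE", 1.0, "RR", ""),
    ("5",  "F", 51, 1.57, 99.4,  "WE", 6.5, "PP", "Baclofen"),
    ("6",  "M", 63, 1.97, 96.0,  "WE", 6.5, "SP", ""),
    ("7",  "F", 33, 1.68, 104.7, "WE", 3.5, "RR", ""),
    ("8",  "M", 61, 1.78, 89.5,  "WE", 6.0, "PP", ""),
    ("9",  "F", 53, 1.74, 61.1,  "WE", 6.0, "PP", ""),
    ("10", "M", 47, 1.92, 77.6,  "WE", 7.0, "RR", "Copaxone"),
    ("11", "F", 33, 1.63, 63.7,  "WE", 3.5, "RR", ""),
    ("12", "F", 40, 1.61, 63.6,  "A",  3.0, "RR", ""),
]


def ms_participants() -> list:
    """The 12 MS participants with their printed individual characteristics."""
    return [
        Participant(id=pid, group=Group.MS, sex=Sex.parse(sex), age=age,
                    height=height, mass=mass, ethnicity=eth, edss=edss,
                    ms_type=MSType.parse(mstype), medications=meds)
        for pid, sex, age, height, mass, eth, edss, mstype, meds in _MS_ROWS
    ]


# Dynamic wetness perception (mm) and z-score per MS participant, for the
# thermoneutral session.  One block per profiled site; qualities ordered
# cold-wet, neutral-wet, warm-wet.
_FOREHEAD = {
    "1":  ((0, -5.31), (39, 0.39), (0, -3.28)),
    "2":  ((3, -2.26), (59, 0.59), (46, 0.42)),
    "3":  ((14, -0.92), (28, 0.22), (26, 0.08)),
    "4":  ((62, 0.39), (34, 0.32), (1, -1.83)),
    "5":  ((88, 0.70), (57, 0.58), (30, 0.16)),
    "6":  ((48, 0.17), (56, 0.57), (52, 0.50)),
    "7":  ((95, 0.77), (90, 0.81), (86, 0.80)),
    "8":  ((63, 0.41), (56, 0.57), (58, 0.56)),
    "9":  ((98, 0.80), (79, 0.74), (19, -0.11)),
    "10": ((73, 0.54), (58, 0.59), (62, 0.60)),
    "11": ((60, 0.37), (34, 0.32), (24, 0.03)),
    "12": ((97, 0.79), (79, 0.74), (76, 0.72)),
}
_FINGER_PAD = {
    "1":  ((46, -0.80), (44, 0.01), (0, -3.34)),
    "2":  ((62, -0.04), (0, -8.52), (1, -1.92)),
    "3":  ((55, -0.35), (63, 0.52), (76, 0.60)),
    "4":  ((65, 0.08), (70, 0.66), (52, 0.38)),
    "5":  ((82, 0.67), (46, 0.08), (24, -0.08)),
    "6":  ((32, -1.73), (69, 0.64), (63, 0.49)),
    "7":  ((62, -0.04), (33, -0.39), (91, 0.71)),
    "8":  ((56, -0.30), (60, 0.45), (66, 0.52)),
    "9":  ((48, -0.69), (48, 0.14), (61, 0.47)),
    "10": ((0, -16.47), (23, -0.89), (0, -3.34)),
    "11": ((51, -0.54), (52, 0.25), (55, 0.41)),
    "12": ((63, 0.00), (55, 0.33), (49, 0.34)),
}

_QUALITY_ORDER = (Quality.COLD_WET, Quality.NEUTRAL_WET, Quality.WARM_WET)


def wetness_z_table() -> pd.DataFrame:
    """Long table of the 72 printed (wetness mm, z-score) cells.

    Columns: participant_id, site, quality, wetness_mm, z.
    """
    rows = []
    for site, block in ((Site.FOREHEAD, _FOREHEAD), (Site.FINGER_PAD, _FINGER_PAD)):
        for pid, cells in block.items():
            for quality, (wp, z) in zip(_QUALITY_ORDER, cells):
                rows.append({"participant_id": pid, "site": str(site),
                             "quality": str(quality),
                             "wetness_mm": float(wp), "z": float(z)})
    return pd.DataFrame(rows)


#: Printed normative summaries (dynamic wetness, thermoneutral):
#: (site, quality) -> (mean mm, SD mm, n).  Raw values are in the study's
#: supplementary deposit; no forearm normative reference exists.
NORMATIVE_SUMMARY = {
    (Site.FOREHEAD, Quality.COLD_WET): (53.7, 27.4, 51),
    (Site.FOREHEAD, Quality.NEUTRAL_WET): (40.6, 29.3, 51),
    (Site.FOREHEAD, Quality.WARM_WET): (41.3, 28.6, 51),
    (Site.FINGER_PAD, Quality.COLD_WET): (67.7, 21.1, 31),
    (Site.FINGER_PAD, Quality.NEUTRAL_WET): (51.7, 24.2, 31),
    (Site.FINGER_PAD, Quality.WARM_WET): (47.6, 28.6, 31),
}

#: Session-level mean skin temperature the protocol produced, degC.
SESSION_MEAN_TSK_C = {"NEUTRAL": 30.9, "HEAT": 34.8, "COLD": 26.5}

#: Group-level dynamic-minus-static wetness increments per site (mm), taken
#: from the cold-wet (finger pad, forehead) and warm-wet (forearm) contrasts.
DYNAMIC_INCREMENT_MM = {Site.FINGER_PAD: 15.5, Site.FOREARM: 12.4, Site.FOREHEAD: 19.7}
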