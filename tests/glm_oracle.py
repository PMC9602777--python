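"""Brute-force least-squares oracle for the mixed-design ANOVA.

Computes every sum of squares as the squared norm of a difference of
explicit orthogonal projections onto design subspaces, built from dummy
indicator matrices and evaluated with ``numpy.linalg.lstsq``.  Nothing is
shared with the implementation under test, which uses closed-form cell
means.
"""

import numpy as np
from scipy import stats


def _project(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return x @ beta


def mixed_anova_oracle(groups, y):
    """Return dict of SS/df/F/p for group, subjects, within, interaction, error.

    ``groups``: length-n sequence of group labels; ``y``: (n, m) responses.
    No sphericity correction (uncorrected dfs), matching the classical
    decomposition.
    """
    y = np.asarray(y, dtype=float)
    n, m = y.shape
    labels = np.asarray(groups)
    group_names = list(dict.fromkeys(labels))
    g = len(group_names)

    obs = y.reshape(-1)            # subject-major flattening
    n_obs = obs.size
    subj_idx = np.repeat(np.arange(n), m)
    level_idx = np.tile(np.arange(m), n)
    group_idx = np.repeat([group_names.index(l) for l in labels], m)

    ones = np.ones((n_obs, 1))
    x_group = np.eye(g)[group_idx]
    x_subj = np.eye(n)[subj_idx]
    x_level = np.eye(m)[level_idx]
    cell_idx = group_idx * m + level_idx
    x_cell = np.eye(g * m)[cell_idx]
    x_group_level = np.hstack([x_group, x_level])
    x_full = np.hstack([x_subj, x_cell])

    p1 = _project(ones, obs)
    pg = _project(x_group, obs)
    ps = _project(x_subj, obs)
    pw = _project(x_level, obs)
    pgw = _project(x_group_level, obs)
    pc = _project(x_cell, obs)
    pf = _project(x_full, obs)

    ss = {
        "group": float(((pg - p1) ** 2).sum()),
        "subjects_within_groups": float(((ps - pg) ** 2).sum()),
        "within": float(((pw - p1) ** 2).sum()),
        "interaction": float(((pc - pgw) ** 2).sum()),
        "within_error": float(((obs - pf) ** 2).sum()),
    }
    df = {
        "group": g - 1,
        "subjects_within_groups": n - g,
        "within": m - 1,
        "interaction": (g - 1) * (m - 1),
        "within_error": (n - g) * (m - 1),
    }
    ms = {k: ss[k] / df[k] for k in ss}
    out = {k: {"ss": ss[k], "df": df[k], "ms": ms[k]} for k in ss}
    for name, err in (("group", "subjects_within_groups"),
                      ("within", "within_error"),
                      ("interaction", "within_error")):
        f = ms[name] / ms[err]
        out[name]["f"] = f
        out[name]["p"] = float(stats.f.sf(f, df[name], df[err]))
    return out
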