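"""Two-way mixed-design ANOVA and companions, written from first principles.

The design is one between-subjects factor (group, e.g. MS vs CTR) crossed
with one within-subjects factor (2 or 3 levels: stimulation mode, or
environmental session), complete cases only.  Because every subject
provides every within level, cell counts are proportional and the classical
sums-of-squares decomposition is orthogonal:

* between-subjects stratum: group effect tested against subjects-within-
  groups variation;
* within-subjects stratum: within main effect and group x within
  interaction tested against the subject x within residual.

For three or more within levels the Greenhouse-Geisser epsilon (computed
from the pooled within-group covariance matrix) multiplies the
within-stratum degrees of freedom before p-values are taken; effect sizes
are reported as percent of total variation (100 * SS_effect / SS_total,
with subjects-within-groups included in the total).

Post hoc machinery: Tukey's HSD driven by a studentized-range CDF evaluated
by adaptive quadrature, the Sidak step-down-free adjustment, paired t
contrasts, a one-sample Kolmogorov-Smirnov normality check, and a
noncentral-F a-priori power / sample-size computation for Cohen's f.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize, special, stats

from .data_model import DataError

__all__ = [
    "MixedDesignData", "EffectResult", "AnovaTable", "PosthocResult",
    "PosthocMethod", "PowerSpec", "mixed_anova", "gg_epsilon",
    "corrected_dfs", "studentized_range_cdf", "studentized_range_crit",
    "tukey_hsd", "sidak_adjust", "paired_contrast", "ks_normality",
    "anova_power", "sample_size_for_power",
]


@dataclass
class MixedDesignData:
    """Complete-case subject x within-level response matrix with group labels."""

    subjects: List[str]
    groups: List[str]           # group label per subject (2 levels expected)
    responses: np.ndarray       # shape (n_subjects, n_within_levels)
    within_levels: List[str]

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        n, m = self.responses.shape
        if len(self.subjects) != n or len(self.groups) != n:
            raise DataError("subjects/groups length must match response rows")
        if len(self.within_levels) != m:
            raise DataError("within_levels length must match response columns")
        if m < 2:
            raise DataError("need at least 2 within levels")
        if np.isnan(self.responses).any():
            raise DataError("complete cases required: missing cells found")
        for g in self.group_names:
            if sum(1 for x in self.groups if x == g) < 2:
                raise DataError(f"need >= 2 subjects in group {g!r}")

    @property
    def group_names(self) -> List[str]:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def by_group(self) -> Dict[str, np.ndarray]:
        labels = np.asarray(self.groups)
        return {g: self.responses[labels == g] for g in self.group_names}


@dataclass
class EffectResult:
    name: str
    ss: float
    df: float              # uncorrected, integral for the design
    df_corrected: float    # after multiplying by epsilon where applicable
    ms: float
    f: Optional[float]
    p: Optional[float]
    percent_total: float
    error_term: Optional[str] = None


@dataclass
class AnovaTable:
    effects: Dict[str, EffectResult]
    epsilon: float
    ss_total: float
    degenerate: bool = False

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


def gg_epsilon(responses: np.ndarray,
               groups: Optional[Sequence[str]] = None) -> float:
    """Greenhouse-Geisser epsilon from the (pooled) within-level covariance.

    With group labels the covariance matrix is pooled across groups
    (weights n_i - 1).  Epsilon is computed from the double-centered
    matrix and clipped to its theoretical range [1/(m-1), 1]; with two
    within levels it is exactly 1.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim != 2:
        raise DataError("responses must be a subject x level matrix")
    n, m = y.shape
    if m < 2:
        raise DataError("need at least 2 within levels")
    if n < 2:
        raise DataError("need at least 2 subjects")
    if groups is None:
        s = np.cov(y, rowvar=False, ddof=1)
    else:
        labels = np.asarray(groups)
        pooled = np.zeros((m, m))
        dof = 0
        for g in dict.fromkeys(labels):
            sub = y[labels == g]
            if sub.shape[0] < 2:
                raise DataError(f"need >= 2 subjects in group {g!r}")
            pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False, ddof=1)
            dof += sub.shape[0] - 1
        s = pooled / dof
    c = np.eye(m) - np.full((m, m), 1.0 / m)
    sc = c @ s @ c
    trace = np.trace(sc)
    denom = (m - 1) * np.trace(sc @ sc)
    if denom <= 0:
        return 1.0  # spherical to machine precision (e.g. zero variance)
    eps = trace ** 2 / denom
    return float(np.clip(eps, 1.0 / (m - 1), 1.0))


def corrected_dfs(epsilon: float, df1: float, df2: float) -> Tuple[float, float]:
    """Multiply a within-stratum df pair by the sphericity correction."""
    return epsilon * df1, epsilon * df2


def mixed_anova(data: MixedDesignData, apply_gg: Optional[bool] = None) -> AnovaTable:
    """Classical mixed-design ANOVA table.

    ``apply_gg=None`` (default) applies the Greenhouse-Geisser correction
    whenever there are 3+ within levels, matching the convention of
    reporting corrected fractional dfs unconditionally.
    """
    y = data.responses
    n, m = y.shape
    labels = np.asarray(data.groups)
    group_names = data.group_names
    g = len(group_names)

    grand = y.mean()
    subj_means = y.mean(axis=1)
    level_means = y.mean(axis=0)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())

    ss_group = 0.0
    ss_cells = 0.0
    for name in group_names:
        rows = y[labels == name]
        ni = rows.shape[0]
        ss_group += m * ni * (rows.mean() - grand) ** 2
        ss_cells += ni * ((rows.mean(axis=0) - grand) ** 2).sum()
    ss_subj = ss_between_subj - ss_group
    ss_within = float(n * ((level_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_within
    ss_error = ss_total - ss_between_subj - ss_within - ss_inter
    # guard tiny negative round-off
    ss_inter = max(ss_inter, 0.0)
    ss_error = max(ss_error, 0.0)

    df_group = g - 1
    df_subj = n - g
    df_within = m - 1
    df_inter = (g - 1) * (m - 1)
    df_error = (n - g) * (m - 1)

    if apply_gg is None:
        apply_gg = m >= 3
    eps = gg_epsilon(y, data.groups) if m >= 3 else 1.0
    eps_used = eps if apply_gg else 1.0

    ms_subj = ss_subj / df_subj
    ms_error = ss_error / df_error
    degenerate = ms_subj <= 0 or ms_error <= 0

    def effect(name, ss, df, ms_err, df_err, error_term, use_eps):
        ms = ss / df
        e = eps_used if use_eps else 1.0
        if ms_err > 0:
            fval = ms / ms_err
            p = float(stats.f.sf(fval, e * df, e * df_err))
        else:
            fval, p = None, None
        return EffectResult(name=name, ss=float(ss), df=df, df_corrected=e * df,
                            ms=float(ms), f=fval, p=p,
                            percent_total=100.0 * ss / ss_total if ss_total > 0 else 0.0,
                            error_term=error_term)

    effects = {
        "group": effect("group", ss_group, df_group, ms_subj, df_subj,
                        "subjects_within_groups", use_eps=False),
        "within": effect("within", ss_within, df_within, ms_error, df_error,
                         "within_error", use_eps=True),
        "interaction": effect("interaction", ss_inter, df_inter, ms_error, df_error,
                              "within_error", use_eps=True),
        "subjects_within_groups": EffectResult(
            name="subjects_within_groups", ss=float(ss_subj), df=df_subj,
            df_corrected=df_subj, ms=float(ms_subj), f=None, p=None,
            percent_total=100.0 * ss_subj / ss_total if ss_total > 0 else 0.0),
        "within_error": EffectResult(
            name="within_error", ss=float(ss_error), df=df_error,
            df_corrected=eps_used * df_error, ms=float(ms_error), f=None, p=None,
            percent_total=100.0 * ss_error / ss_total if ss_total > 0 else 0.0),
    }
    return AnovaTable(effects=effects, epsilon=eps, ss_total=ss_total,
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# studentized range distribution, by adaptive quadrature

# Gauss-Legendre nodes for the inner (range-probability) integral; the
# integrand is analytic and supported where the normal density lives, so a
# fixed high-order rule reaches ~1e-12 absolute accuracy.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)
_SQRT2PI = math.sqrt(2.0 * math.pi)


def _prange_fixed_scale(q: float, k: int) -> float:
    """P(range of k iid standard normals <= q), known scale."""
    if q <= 0:
        return 0.0
    lo, hi = -9.0, 9.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS
    pdf = np.exp(-0.5 * z * z) / _SQRT2PI
    integrand = pdf * (special.ndtr(z) - special.ndtr(z - q)) ** (k - 1)
    return float(k * np.dot(w, integrand))


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range for k means and ``df`` error df.

    Evaluated by integrating the fixed-scale range probability against the
    chi distribution of the scale estimate (absolute tolerance ~1e-8).
    """
    if k < 2:
        raise DataError("studentized range needs k >= 2")
    if df < 1:
        raise DataError("error df must be >= 1")
    if q <= 0:
        return 0.0
    if not math.isfinite(df):
        return _prange_fixed_scale(q, k)
    # density of W = s/sigma: chi(df) scaled by sqrt(df)
    log_norm = (df / 2.0) * math.log(df) - (df / 2.0 - 1.0) * math.log(2.0) \
        - special.gammaln(df / 2.0)

    def outer(w):
        logf = log_norm + (df - 1.0) * math.log(w) - df * w * w / 2.0
        return math.exp(logf) * _prange_fixed_scale(q * w, k)

    val, _ = integrate.quad(outer, 0.0, np.inf, epsabs=1e-9, limit=200)
    return min(val, 1.0)


def studentized_range_crit(k: int, df: float, alpha: float = 0.05) -> float:
    """Upper alpha critical value q such that P(Q > q) = alpha."""
    return float(optimize.brentq(
        lambda q: studentized_range_cdf(q, k, df) - (1.0 - alpha), 1e-3, 100.0,
        xtol=1e-10))


class PosthocMethod(enum.Enum):
    TUKEY = "TUKEY"
    SIDAK = "SIDAK"
    PAIRED_T = "PAIRED_T"


@dataclass
class PosthocResult:
    comparison: str
    difference: float
    ci_low: float
    ci_high: float
    p_adjusted: Optional[float]
    method: PosthocMethod
    degenerate: bool = False


def tukey_hsd(means: Sequence[float], ns: Sequence[int], ms_error: float,
              df_error: float, labels: Optional[Sequence[str]] = None,
              alpha: float = 0.05) -> List[PosthocResult]:
    """Tukey(-Kramer) HSD over all pairwise level differences.

    p-values come from the studentized-range distribution; simultaneous
    (1 - alpha) CIs are ``difference +/- q_crit * SE`` with
    ``SE = sqrt(MS_error / 2 * (1/n_i + 1/n_j))``.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.size
    if k < 2:
        raise DataError("Tukey HSD needs k >= 2 level means")
    if df_error < 1:
        raise DataError("error df must be >= 1")
    if labels is None:
        labels = [f"level{i + 1}" for i in range(k)]
    qcrit = studentized_range_crit(k, df_error, alpha)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(ms_error / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se > 0:
            qobs = abs(diff) / se
            p = 1.0 - studentized_range_cdf(qobs, k, df_error)
            lo, hi = diff - qcrit * se, diff + qcrit * se
            out.append(PosthocResult(f"{labels[i]} - {labels[j]}", float(diff),
                                     lo, hi, float(min(max(p, 0.0), 1.0)),
                                     PosthocMethod.TUKEY))
        else:
            out.append(PosthocResult(f"{labels[i]} - {labels[j]}", float(diff),
                                     diff, diff, None, PosthocMethod.TUKEY,
                                     degenerate=True))
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, capped at 1."""
    if not (0.0 <= p <= 1.0):
        raise DataError(f"p = {p} outside [0, 1]")
    if m < 1:
        raise DataError("m must be >= 1")
    return min(1.0 - (1.0 - p) ** m, 1.0)


def paired_contrast(a: Sequence[float], b: Sequence[float],
                    conf: float = 0.95) -> PosthocResult:
    """Mean paired difference a - b with a t-based confidence interval."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise DataError("paired contrast needs >= 2 paired observations")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = d.std(ddof=1)
    if sd == 0:
        return PosthocResult("paired", mean, mean, mean, None,
                             PosthocMethod.PAIRED_T, degenerate=True)
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 1)
    tval = mean / se
    p = float(2.0 * stats.t.sf(abs(tval), n - 1))
    return PosthocResult("paired", mean, mean - tcrit * se, mean + tcrit * se,
                         p, PosthocMethod.PAIRED_T)


def ks_normality(sample: Sequence[float]) -> Tuple[float, float]:
    """One-sample KS test against a normal with sample-estimated mean/SD.

    The asymptotic Kolmogorov p-value is anti-conservative when the
    parameters are estimated from the same sample (it under-rejects);
    this matches the everyday "KS normality check" convention.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise DataError("KS normality check needs n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("constant sample: KS normality check undefined")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PowerSpec:
    effect_size_f: float   # Cohen's f
    alpha: float = 0.05
    power: float = 0.8
    k_groups: int = 2

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise DataError("alpha and power must lie in (0, 1)")
        if self.k_groups < 2:
            raise DataError("need k >= 2 groups")


def anova_power(f: float, k: int, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the one-way fixed-effects F test, noncentrality f^2 * k * n."""
    df1 = k - 1
    df2 = k * (n_per_group - 1)
    if df2 < 1:
        raise DataError("error df < 1: increase n per group")
    lam = f * f * k * n_per_group
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sample_size_for_power(spec: PowerSpec, n_max: int = 10000) -> int:
    """Smallest integer n per group reaching the requested power."""
    if spec.effect_size_f <= 0:
        raise DataError("effect size f must be > 0 (power never reached at f = 0)")
    for n in range(2, n_max + 1):
        if anova_power(spec.effect_size_f, spec.k_groups, n, spec.alpha) >= spec.power:
            return n
    raise DataError(f"power {spec.power} not reached with n <= {n_max}")
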