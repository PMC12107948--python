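"""Trial statistics: exact tests, group summaries, mixed models, sample size.

Comparisons mirror small-pilot practice: Fisher's exact test for binary
endpoints (counts are small), Wilcoxon rank-sum for continuous endpoints
(medians with interquartile ranges), a random-intercept linear mixed model
for repeated daily measures with a treatment-by-time interaction, and the
classical two-proportion / two-mean sample-size formulas with attrition
inflation for trial planning.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

__all__ = [
    "LMMSpec",
    "TwoByTwo",
    "daily_group_means",
    "fisher_exact_two_sided",
    "fit_lmm",
    "sample_size_two_means",
    "sample_size_two_proportions",
    "summarize_groups",
    "wilcoxon_rank_sum",
]

logger = logging.getLogger(__name__)

#: Relative slack when comparing hypergeometric point probabilities, to
#: absorb floating-point ties between equally likely tables.
_POINT_PROB_SLACK = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Events/non-events by arm: a, c = arm 1; b, d = arm 2."""

    a: int  # events, arm 1
    b: int  # events, arm 2
    c: int  # non-events, arm 1
    d: int  # non-events, arm 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ContractError("the table is empty")


def fisher_exact_two_sided(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value by the point-probability method.

    Conditional on both margins, sums the hypergeometric probabilities of
    every table no more probable than the observed one (within a small
    relative slack for floating-point ties).  A table with an empty margin
    admits a single outcome; p = 1 by convention (logged).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row_events = a + b
    col_arm1 = a + c
    if row_events == 0 or col_arm1 == 0 or (c + d) == 0 or (b + d) == 0:
        logger.info("degenerate 2x2 margin (%s); p = 1", table)
        return 1.0
    rv = stats.hypergeom(n_total, row_events, col_arm1)
    k_min = max(0, row_events + col_arm1 - n_total)
    k_max = min(row_events, col_arm1)
    support = np.arange(k_min, k_max + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(a)
    p = float(pmf[pmf <= observed * (1.0 + _POINT_PROB_SLACK)].sum())
    return min(1.0, p)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is <=20 and there are
    no ties; otherwise the normal approximation with continuity and tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _median_iqr(values: np.ndarray) -> str:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return f"{q50:.1f} [{q25:.1f}-{q75:.1f}]"


def summarize_groups(
    df: pd.DataFrame,
    arm_col: str,
    binary_cols: list[str] | tuple[str, ...] = (),
    continuous_cols: list[str] | tuple[str, ...] = (),
    arms: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-arm comparison table: n (%) + Fisher p, median [IQR] + Wilcoxon p.

    One row per requested variable; columns are the two arm summaries and
    the p-value.  Variables with no non-missing values in either arm are
    emitted with missing markers.
    """
    if arms is None:
        arms = tuple(sorted(df[arm_col].dropna().unique()))
    if len(arms) != 2:
        raise ContractError(f"exactly two arms required, got {arms}")
    g1 = df[df[arm_col] == arms[0]]
    g2 = df[df[arm_col] == arms[1]]
    rows = []
    for col in binary_cols:
        v1, v2 = g1[col].dropna().astype(bool), g2[col].dropna().astype(bool)
        if v1.empty and v2.empty:
            rows.append({"variable": col, arms[0]: "-", arms[1]: "-", "p": math.nan})
            continue
        e1, e2 = int(v1.sum()), int(v2.sum())
        p = fisher_exact_two_sided(
            TwoByTwo(a=e1, b=e2, c=len(v1) - e1, d=len(v2) - e2)
        )
        rows.append(
            {
                "variable": col,
                arms[0]: f"{e1}/{len(v1)} ({100 * e1 / max(1, len(v1)):.0f}%)",
                arms[1]: f"{e2}/{len(v2)} ({100 * e2 / max(1, len(v2)):.0f}%)",
                "p": p,
            }
        )
    for col in continuous_cols:
        v1 = g1[col].dropna().to_numpy(dtype=float)
        v2 = g2[col].dropna().to_numpy(dtype=float)
        if v1.size == 0 or v2.size == 0:
            rows.append({"variable": col, arms[0]: "-", arms[1]: "-", "p": math.nan})
            continue
        rows.append(
            {
                "variable": col,
                arms[0]: _median_iqr(v1),
                arms[1]: _median_iqr(v2),
                "p": wilcoxon_rank_sum(v1, v2),
            }
        )
    return pd.DataFrame(rows, columns=["variable", arms[0], arms[1], "p"])


@dataclass(frozen=True)
class LMMSpec:
    """Column mapping for the repeated-measures mixed model."""

    outcome: str
    treatment: str = "treatment"
    time: str = "days_since_randomization"
    pre_randomization: str | None = "days_t0_to_randomization"
    group: str = "patient_id"


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> pd.DataFrame:
    """Random-intercept linear mixed model with treatment x time interaction.

    Fixed effects: treatment, days from vasopressor start to randomization
    (linear), days since randomization (linear), and treatment x time.
    Fit by REML with Wald 95% CIs; a singular or non-converged REML fit
    falls back to maximum likelihood with a warning.

    Returns a table of fixed effects: estimate, standard error, and the
    95% CI bounds, indexed by term name.
    """
    import statsmodels.formula.api as smf

    required = [spec.outcome, spec.treatment, spec.time, spec.group]
    if spec.pre_randomization is not None:
        required.append(spec.pre_randomization)
    d = data[required].dropna()
    if d[spec.group].nunique() < 4:
        raise ContractError("need >=2 participants per arm with repeated measures")
    rhs = [spec.treatment, spec.time, f"{spec.treatment}:{spec.time}"]
    if spec.pre_randomization is not None:
        rhs.insert(1, spec.pre_randomization)
    formula = f"{spec.outcome} ~ " + " + ".join(rhs)
    model = smf.mixedlm(formula, d, groups=d[spec.group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
        if not result.converged:
            logger.warning("REML fit did not converge; refitting by ML")
            result = model.fit(reml=False)
    fe = result.fe_params
    se = result.bse_fe
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "estimate": fe,
            "se": se,
            "ci_low": fe - z * se,
            "ci_high": fe + z * se,
        }
    )


def _z(q: float) -> float:
    return float(stats.norm.ppf(q))


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    attrition: float = 0.0,
) -> int:
    """Total N for a two-arm comparison of proportions.

    Per-group n uses the classical normal-approximation formula with pooled
    variance under the null and unpooled under the alternative:

        n = [z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2)]^2
            / (p1 - p2)^2

    The unrounded total 2n is inflated by 1/(1 - attrition) and then
    rounded up once.
    """
    for name, v in (("alpha", alpha), ("power", power)):
        if not 0.0 < v < 1.0:
            raise ContractError(f"{name} must be in (0, 1)")
    if not 0.0 <= attrition < 1.0:
        raise ContractError("attrition must be in [0, 1)")
    if p1 == p2:
        raise ContractError("p1 must differ from p2")
    pbar = (p1 + p2) / 2.0
    num = _z(1 - alpha / 2) * math.sqrt(2 * pbar * (1 - pbar)) + _z(power) * math.sqrt(
        p1 * (1 - p1) + p2 * (1 - p2)
    )
    n_per_group = (num / (p1 - p2)) ** 2
    total = 2.0 * n_per_group / (1.0 - attrition)
    return math.ceil(total)


def sample_size_two_means(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> tuple[int, int]:
    """(per-group n, total) for a two-arm comparison of means.

    n = 2 (z_{1-a/2} + z_{1-b})^2 sd^2 / delta^2, rounded up per group.
    """
    if sd <= 0:
        raise ContractError("sd must be positive")
    if delta == 0:
        raise ContractError("delta must be non-zero")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ContractError("alpha and power must be in (0, 1)")
    n = 2.0 * (_z(1 - alpha / 2) + _z(power)) ** 2 * sd**2 / delta**2
    per_group = math.ceil(n)
    return per_group, 2 * per_group


def daily_group_means(
    data: pd.DataFrame,
    outcome: str,
    arm_col: str = "arm",
    day_col: str = "day",
) -> pd.DataFrame:
    """Per-day per-arm mean with a t-based 95% CI.

    Days with no data are absent; singleton cells report the mean with
    missing CI bounds.
    """
    rows = []
    for (day, arm), grp in data.groupby([day_col, arm_col], sort=True):
        values = grp[outcome].dropna().to_numpy(dtype=float)
        if values.size == 0:
            continue
        mean = float(values.mean())
        if values.size >= 2:
            half = float(
                stats.t.ppf(0.975, values.size - 1)
                * values.std(ddof=1)
                / math.sqrt(values.size)
            )
            lo, hi = mean - half, mean + half
        else:
            lo = hi = math.nan
        rows.append(
            {
                "day": day,
                "arm": arm,
                "n": values.size,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows, columns=["day", "arm", "n", "mean", "ci_low", "ci_high"])
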