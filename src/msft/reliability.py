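"""Method-agreement statistics: ICC, Cronbach's α, Bland–Altman.

Validating a sensor-based test against its manual counterpart is a two-rater
agreement problem: n subjects measured by k = 2 methods.  The toolkit
implements the ANOVA-based intraclass correlation family —

* one-way random model: subjects random, rater effect absorbed into error;
  single measures ICC(1,1) = (MSB − MSW) / (MSB + (k−1) MSW) and average
  measures ICC(1,k) = (MSB − MSW) / MSB;
* two-way consistency model: subject and rater main effects; single
  ICC(C,1) = (MSB − MSE) / (MSB + (k−1) MSE) and average
  ICC(C,k) = (MSB − MSE) / MSB —

with 95% confidence bounds from the standard F-quantile constructions, plus
Cronbach's α (which for k raters is identically the two-way consistency
average-measures ICC) and Bland–Altman limits of agreement
(mean difference ± 1.96 SD of the differences).

All mean squares use sample (n−1) denominators at the ANOVA level, i.e. the
textbook expected-mean-square definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedStatisticError, ValidationError

ICC_MODELS = ("oneway_random", "twoway_consistency")
ICC_UNITS = ("single", "average")

#: canonical row order of the case-study report
REPORT_ITEM_ORDER = (
    "chair_stand",
    "arm_curl",
    "two_min_step",
    "sit_reach",
    "back_scratch",
    "up_and_go",
)


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class PairedResults:
    """n subjects measured by two methods on one test item.

    method_a holds the manually administered scores, method_b the
    sensor-assisted ones.  Listwise completeness is required.
    """

    subject_ids: tuple
    method_a: tuple
    method_b: tuple
    test_code: str = ""

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if not (n == len(self.method_a) == len(self.method_b)):
            raise ValidationError("subject_ids and both method columns must align")
        if n < 3:
            raise ValidationError("at least 3 subjects required")
        values = np.asarray(self.method_a + self.method_b, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("missing or non-finite values are not allowed")

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack(
            [np.asarray(self.method_a, float), np.asarray(self.method_b, float)]
        )


@dataclass(frozen=True)
class IccEstimate:
    value: float
    model: str
    unit: str
    ci_low: float
    ci_high: float
    conf: float


@dataclass(frozen=True)
class ReliabilityReport:
    test_code: str
    icc: float
    icc_model: str
    icc_unit: str
    ci_low: float
    ci_high: float
    cronbach_alpha: float
    icc_label: str
    alpha_label: str


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    points: tuple  # ((pair mean, pair difference), ...)


# ---------------------------------------------------------------------------
# ANOVA building blocks

def _as_matrix(data) -> np.ndarray:
    m = np.asarray(data, dtype=float)
    if m.ndim != 2:
        raise ValidationError("data must be an n x k matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValidationError(f"need n >= 3 subjects and k >= 2 raters, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValidationError("missing or non-finite values are not allowed")
    return m


def _mean_squares(m: np.ndarray) -> dict[str, float]:
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_within = float(((m - row_means[:, None]) ** 2).sum())
    ss_rater = n * float(((col_means - grand) ** 2).sum())
    ss_error = float(
        ((m - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    )
    return {
        "msb": ss_between / (n - 1),
        "msw": ss_within / (n * (k - 1)),
        "msc": ss_rater / (k - 1),
        "mse": ss_error / ((n - 1) * (k - 1)),
        "n": n,
        "k": k,
    }


def cronbach_alpha(data) -> float:
    """Cronbach's α = k/(k−1) · (1 − Σ item variances / total-score variance),
    all variances with n−1 denominators."""
    m = _as_matrix(data)
    n, k = m.shape
    total_var = float(m.sum(axis=1).var(ddof=1))
    if total_var == 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    item_var = float(m.var(axis=0, ddof=1).sum())
    return k / (k - 1) * (1.0 - item_var / total_var)


def icc(data, model: str = "twoway_consistency", unit: str = "average",
        conf: float = 0.95) -> IccEstimate:
    """ICC point estimate with an F-based confidence interval.

    The two-way consistency / average-measures form is the default because
    it is the coefficient that equals Cronbach's α for the same matrix; the
    one-way random model is available for designs where raters are not
    crossed with subjects.
    """
    if model not in ICC_MODELS:
        raise ValidationError(f"model must be one of {ICC_MODELS}")
    if unit not in ICC_UNITS:
        raise ValidationError(f"unit must be one of {ICC_UNITS}")
    if not 0 < conf < 1:
        raise ValidationError("conf must lie in (0, 1)")
    m = _as_matrix(data)
    ms = _mean_squares(m)
    n, k = ms["n"], ms["k"]
    msb = ms["msb"]
    if msb == 0:
        raise UndefinedStatisticError("between-subject mean square is zero")
    if model == "oneway_random":
        denom_ms, df2 = ms["msw"], n * (k - 1)
    else:
        denom_ms, df2 = ms["mse"], (n - 1) * (k - 1)
    df1 = n - 1

    if denom_ms == 0:
        # perfect agreement: estimate 1 with a degenerate upper bound
        point = 1.0
        f_obs = np.inf
    else:
        f_obs = msb / denom_ms
        if unit == "single":
            point = (msb - denom_ms) / (msb + (k - 1) * denom_ms)
        else:
            point = (msb - denom_ms) / msb

    alpha2 = (1.0 - conf) / 2.0
    f_upper_quant = stats.f.ppf(1 - alpha2, df1, df2)
    f_lower_quant = stats.f.ppf(1 - alpha2, df2, df1)
    fl = f_obs / f_upper_quant
    fu = f_obs * f_lower_quant
    if unit == "single":
        lo = (fl - 1) / (fl + k - 1) if np.isfinite(fl) else 1.0
        hi = (fu - 1) / (fu + k - 1) if np.isfinite(fu) else 1.0
    else:
        lo = 1 - 1 / fl if fl > 0 else -np.inf
        hi = 1 - 1 / fu if np.isfinite(fu) else 1.0
    lo, hi = min(lo, point), max(hi, point)
    return IccEstimate(float(point), model, unit, float(lo), float(hi), conf)


def bland_altman(pairs: PairedResults) -> BlandAltmanResult:
    """Differences a − b against pair means, with 1.96-SD limits of agreement."""
    a = np.asarray(pairs.method_a, float)
    b = np.asarray(pairs.method_b, float)
    diff = a - b
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    points = tuple(zip(((a + b) / 2.0).tolist(), diff.tolist()))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        points=points,
    )


def plot_bland_altman(result: BlandAltmanResult, ax=None, title: str | None = None):
    """Render the classic agreement plot: differences vs means, mean line in
    black, limits of agreement in red.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means, diffs = zip(*result.points) if result.points else ((), ())
    ax.scatter(means, diffs, color="tab:blue", zorder=3)
    ax.axhline(result.mean_diff, color="black", label="mean difference")
    for limit in (result.loa_low, result.loa_high):
        ax.axhline(limit, color="red", linestyle="--")
    ax.set_xlabel("mean of the two methods")
    ax.set_ylabel("difference (manual − sensor)")
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# interpretation and the case-study report

def interpret_icc(value: float) -> str:
    """Reliability label; boundary values fall in the lower band."""
    if value <= 0.4:
        return "poor"
    if value <= 0.75:
        return "fair-to-good"
    return "excellent"


def interpret_alpha(value: float) -> str:
    if value <= 0.5:
        return "unacceptable"
    if value <= 0.9:
        return "poor-to-good"
    return "excellent"


def interpret(icc_value: float, alpha_value: float) -> tuple[str, str]:
    return interpret_icc(icc_value), interpret_alpha(alpha_value)


def load_paired_results(path=None) -> dict[str, PairedResults]:
    """Load a long-format paired-results CSV (``subject_id,test_code,method,
    value``; methods ``sft``/``msft``).  Defaults to the packaged seven-
    volunteer case-study table.  Raises :class:`DataError` naming the
    subject/item of any missing cell."""
    if path is None:
        text = resources.files("msft.data").joinpath("case_study_pairs.csv").read_text("utf-8")
        df = pd.read_csv(pd.io.common.StringIO(text))
    else:
        df = pd.read_csv(path)
    required = {"subject_id", "test_code", "method", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"paired-results CSV must have columns {sorted(required)}")
    out: dict[str, PairedResults] = {}
    for code, group in df.groupby("test_code", sort=False):
        wide = group.pivot_table(
            index="subject_id", columns="method", values="value", aggfunc="first"
        )
        for method in ("sft", "msft"):
            if method not in wide.columns:
                raise DataError(f"{code}: method {method!r} column missing")
        incomplete = wide[wide.isna().any(axis=1)]
        if not incomplete.empty:
            subj = incomplete.index[0]
            raise DataError(f"missing value for subject {subj}, item {code!r}")
        out[code] = PairedResults(
            subject_ids=tuple(wide.index),
            method_a=tuple(wide["sft"].astype(float)),
            method_b=tuple(wide["msft"].astype(float)),
            test_code=code,
        )
    if not out:
        raise DataError("paired-results CSV holds no data")
    return out


def reliability_report(
    pairs: PairedResults,
    icc_model: str = "twoway_consistency",
    icc_unit: str = "average",
    conf: float = 0.95,
) -> ReliabilityReport:
    m = pairs.matrix
    est = icc(m, model=icc_model, unit=icc_unit, conf=conf)
    alpha = cronbach_alpha(m)
    icc_label, alpha_label = interpret(est.value, alpha)
    return ReliabilityReport(
        test_code=pairs.test_code,
        icc=est.value,
        icc_model=icc_model,
        icc_unit=icc_unit,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        cronbach_alpha=alpha,
        icc_label=icc_label,
        alpha_label=alpha_label,
    )


def agreement_table(
    fixture=None,
    icc_model: str = "twoway_consistency",
    icc_unit: str = "average",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-item agreement report over a paired-results table (default: the
    packaged case study): ICC with CI, Cronbach's α, and interpretation
    labels, one row per test item."""
    pairs_by_item = load_paired_results(fixture) if not isinstance(fixture, dict) else fixture
    order = [c for c in REPORT_ITEM_ORDER if c in pairs_by_item]
    order += [c for c in pairs_by_item if c not in order]
    rows = []
    for code in order:
        rep = reliability_report(pairs_by_item[code], icc_model, icc_unit, conf)
        rows.append(
            {
                "test_code": code,
                "icc": rep.icc,
                "ci_low": rep.ci_low,
                "ci_high": rep.ci_high,
                "cronbach_alpha": rep.cronbach_alpha,
                "icc_model": rep.icc_model,
                "icc_unit": rep.icc_unit,
                "icc_label": rep.icc_label,
                "alpha_label": rep.alpha_label,
            }
        )
    return pd.DataFrame(rows).set_index("test_code")
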