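"""Method-comparison statistics against a reference (HPLC) concentration vector.

Per-sample percent error uses the reference as the baseline
(|estimate - reference| / reference * 100); group summaries are the mean
and sample SD (n-1) of per-sample errors, computed per replicate before
averaging.  Agreement between the two methods is summarised by an OLS
regression of the estimates on the reference and a two-sided paired
t-test (alpha = 0.05; no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ALPHA",
    "DegenerateTestError",
    "MethodComparison",
    "percent_error",
    "paired_t_test",
    "agreement_regression",
    "comparison_report",
]

ALPHA = 0.05


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined for the given data."""


@dataclass(frozen=True)
class MethodComparison:
    """Summary of agreement between estimates and reference in one group."""

    group: str
    n: int
    mean_error: float  # %
    sd_error: float  # % (sample SD; NaN for n = 1)
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def percent_error(estimate: float, reference: float) -> float:
    """Absolute percent error of ``estimate`` with the reference as baseline."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return abs(estimate - reference) / reference * 100.0


def paired_t_test(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test on matched concentration vectors.

    Returns ``(t, p, n)``.  Identical vectors give (0, 1, n) — perfect
    agreement is not a degenerate case — but a non-zero constant shift,
    whose differences have zero variance, has an undefined statistic and
    raises :class:`DegenerateTestError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    if np.all(d == 0.0):
        return 0.0, 1.0, n
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateTestError(
            "differences have zero variance (constant non-zero shift); "
            "the paired t statistic is undefined"
        )
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), n


def agreement_regression(x, y) -> tuple[float, float, float]:
    """OLS of estimates ``y`` on reference ``x``: returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matched 1-D vectors with n >= 3")
    if np.unique(x).size < 2:
        raise ValueError("reference vector has zero variance")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return float(fit.slope), float(fit.intercept), min(max(r2, 0.0), 1.0)


def _summarise(group: str, est: np.ndarray, ref: np.ndarray) -> MethodComparison:
    errors = np.array([percent_error(e, r) for e, r in zip(est, ref)])
    n = errors.size
    mean_err = float(errors.mean())
    sd_err = float(errors.std(ddof=1)) if n > 1 else float("nan")
    slope = intercept = r2 = t = p = float("nan")
    if n >= 3:
        try:
            slope, intercept, r2 = agreement_regression(ref, est)
        except ValueError:
            pass
    if n >= 2:
        try:
            t, p, _ = paired_t_test(est, ref)
        except DegenerateTestError:
            pass
    return MethodComparison(group, n, mean_err, sd_err, slope, intercept, r2, t, p)


def comparison_report(
    estimates: pd.DataFrame,
    references: pd.DataFrame,
    by: str | None = None,
) -> pd.DataFrame:
    """Per-group and overall comparison of estimates against a reference.

    Both tables need columns ``sample_id`` and ``concentration_mg_per_L``;
    the grouping column ``by`` (e.g. a growth-stage label) may live in
    either table.  Samples are matched by id; unmatched ids raise.  The
    result has one row per group plus an ``overall`` row, ordered by group
    label, with columns group, n, mean_error_pct, sd_error_pct, slope,
    intercept, r_squared, t_statistic, p_value.
    """
    for name, df in (("estimates", estimates), ("references", references)):
        need = {"sample_id", "concentration_mg_per_L"}
        if not need <= set(df.columns):
            raise ValueError(f"{name} table must have columns {sorted(need)}")
    e_ids = set(estimates["sample_id"])
    r_ids = set(references["sample_id"])
    if e_ids != r_ids:
        missing = sorted((e_ids ^ r_ids))
        raise ValueError(f"unmatched sample ids: {missing}")

    merged = estimates.merge(
        references, on="sample_id", suffixes=("_est", "_ref"), validate="one_to_one"
    )
    if by is not None:
        if by not in merged.columns:
            # grouping column may carry an _est/_ref suffix after the merge
            for suffixed in (f"{by}_est", f"{by}_ref"):
                if suffixed in merged.columns:
                    merged[by] = merged[suffixed]
                    break
            else:
                raise ValueError(f"grouping column {by!r} not found")

    rows = []
    if by is not None:
        for label, grp in merged.groupby(by, sort=True):
            rows.append(
                _summarise(
                    str(label),
                    grp["concentration_mg_per_L_est"].to_numpy(),
                    grp["concentration_mg_per_L_ref"].to_numpy(),
                )
            )
    rows.append(
        _summarise(
            "overall",
            merged["concentration_mg_per_L_est"].to_numpy(),
            merged["concentration_mg_per_L_ref"].to_numpy(),
        )
    )
    return pd.DataFrame(
        [
            (c.group, c.n, c.mean_error, c.sd_error, c.slope, c.intercept,
             c.r_squared, c.t_statistic, c.p_value)
            for c in rows
        ],
        columns=[
            "group", "n", "mean_error_pct", "sd_error_pct", "slope",
            "intercept", "r_squared", "t_statistic", "p_value",
        ],
    )


def format_report(report: pd.DataFrame) -> str:
    """Human-readable text rendering of a comparison report."""
    lines = ["method comparison vs reference", "-" * 34]
    for _, row in report.iterrows():
        sd = f" +/- {row.sd_error_pct:.2f}" if np.isfinite(row.sd_error_pct) else ""
        extra = ""
        if np.isfinite(row.r_squared):
            extra += f", R^2 = {row.r_squared:.4f}"
        if np.isfinite(row.p_value):
            sig = "ns" if row.p_value >= ALPHA else "significant"
            extra += f", paired t p = {row.p_value:.3f} ({sig})"
        lines.append(
            f"{row.group}: n = {row.n}, error = {row.mean_error_pct:.2f}{sd} %{extra}"
        )
    return "\n".join(lines)
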