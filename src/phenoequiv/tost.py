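"""Two one-sided tests (TOST) of equivalence for two independent proportions.

Conventions
-----------
``analytic`` (default for new analyses)
    Center of the interval is the unrounded difference of proportions;
    critical value is the exact normal quantile, so the confidence-interval
    criterion and the max one-sided p-value criterion agree exactly.
``printed_table``
    Center is the difference of the one-decimal-rounded percentage
    prevalences and the critical value is 1.645; this reproduces the
    published table cell-for-cell.  The standard error always comes from the
    unrounded proportions.

Everything difference-scaled (diff, se, CI bounds, delta) is expressed in
percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

from phenoequiv.prevalence import round_half_up

__all__ = ["TostInput", "TostResult", "equivalence_table", "tost_two_proportions"]

CONVENTIONS = ("analytic", "printed_table")


@dataclass(frozen=True)
class TostInput:
    n1: int
    N1: int
    n2: int
    N2: int
    delta: float = 2.5
    alpha: float = 0.05
    convention: str = "analytic"

    def __post_init__(self) -> None:
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("denominators must be >= 1")
        if not (0 <= self.n1 <= self.N1 and 0 <= self.n2 <= self.N2):
            raise ValueError("numerators must satisfy 0 <= n <= N")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass(frozen=True)
class TostResult:
    p1_hat: float
    p2_hat: float
    diff: float            # percentage points; center per convention
    se: float              # percentage points, unpooled Wald
    ci_low: float
    ci_high: float
    z_lower: float
    z_upper: float
    p_lower: float
    p_upper: float
    p_tost: float
    equivalent: bool
    warnings: tuple[str, ...] = field(default=())


def _one_sided(diff: float, se: float, delta: float) -> tuple[float, float, float, float]:
    """z and p for H0: diff <= -delta and H0: diff >= +delta."""
    if se > 0:
        z_lower = (diff + delta) / se
        z_upper = (diff - delta) / se
    else:
        z_lower = math.inf if diff + delta > 0 else (-math.inf if diff + delta < 0 else 0.0)
        z_upper = math.inf if diff - delta > 0 else (-math.inf if diff - delta < 0 else 0.0)
    p_lower = float(norm.sf(z_lower))
    p_upper = float(norm.cdf(z_upper))
    return z_lower, z_upper, p_lower, p_upper


def tost_two_proportions(inp: TostInput) -> TostResult:
    """Unpooled-Wald TOST for the difference of two independent proportions."""
    p1 = inp.n1 / inp.N1
    p2 = inp.n2 / inp.N2
    se = 100.0 * math.sqrt(p1 * (1 - p1) / inp.N1 + p2 * (1 - p2) / inp.N2)

    warns: list[str] = []
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        warns.append("degenerate proportion (0 or 1): Wald standard error unreliable")

    if inp.convention == "printed_table":
        diff = round_half_up(100.0 * p1, 1) - round_half_up(100.0 * p2, 1)
        z_crit = 1.645
    else:
        diff = 100.0 * (p1 - p2)
        z_crit = float(norm.ppf(1 - inp.alpha))

    ci_low = diff - z_crit * se
    ci_high = diff + z_crit * se
    z_lower, z_upper, p_lower, p_upper = _one_sided(diff, se, inp.delta)
    # equivalence iff the 100(1-2*alpha)% CI lies strictly inside (-delta, +delta)
    equivalent = (-inp.delta < ci_low) and (ci_high < inp.delta)

    return TostResult(
        p1_hat=p1,
        p2_hat=p2,
        diff=diff,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        z_lower=z_lower,
        z_upper=z_upper,
        p_lower=p_lower,
        p_upper=p_upper,
        p_tost=max(p_lower, p_upper),
        equivalent=equivalent,
        warnings=tuple(warns),
    )


def equivalence_table(
    counts_cp1: pd.DataFrame,
    counts_cp2: pd.DataFrame,
    delta: float = 2.5,
    alpha: float = 0.05,
    convention: str = "analytic",
) -> pd.DataFrame:
    """Per-stratum TOST over two matched prevalence tables.

    Inputs are prevalence tables with columns dimension, level, numerator,
    denominator (one row per stratum, including overall).  Strata must align
    one-to-one; unmatched strata raise with the offending keys listed.
    """
    k1 = list(zip(counts_cp1["dimension"], counts_cp1["level"]))
    k2 = list(zip(counts_cp2["dimension"], counts_cp2["level"]))
    unmatched = set(k1) ^ set(k2)
    if unmatched:
        raise ValueError(f"unmatched strata between the two tables: {sorted(unmatched)}")
    c2 = {k: row for k, (_, row) in zip(k2, counts_cp2.iterrows())}

    rows = []
    for key, (_, r1) in zip(k1, counts_cp1.iterrows()):
        r2 = c2[key]
        res = tost_two_proportions(
            TostInput(
                n1=int(r1["numerator"]), N1=int(r1["denominator"]),
                n2=int(r2["numerator"]), N2=int(r2["denominator"]),
                delta=delta, alpha=alpha, convention=convention,
            )
        )
        rows.append(
            {
                "dimension": key[0],
                "level": key[1],
                "n1": int(r1["numerator"]), "N1": int(r1["denominator"]),
                "n2": int(r2["numerator"]), "N2": int(r2["denominator"]),
                "prev1_pct": 100.0 * res.p1_hat,
                "prev2_pct": 100.0 * res.p2_hat,
                "diff_pp": res.diff,
                "se_pp": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_lower": res.p_lower,
                "p_upper": res.p_upper,
                "p_tost": res.p_tost,
                "reject_null": res.equivalent,
            }
        )
    return pd.DataFrame(rows)
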