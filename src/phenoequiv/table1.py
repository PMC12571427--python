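"""Embedded published stratum counts and the table-reproduction check.

The fixture carries, for each of the 11 strata (3 age bands, 5 race/ethnicity
groups, 2 sexes, overall), the published numerator/denominator pair for each
phenotype together with the published display values (prevalences, percentage
point difference, 90% CI, reject-null decision).  :func:`reproduce_table1`
recomputes every display cell from the raw counts under the printed-table
convention and flags cell-level agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from phenoequiv.prevalence import round_half_up
from phenoequiv.tost import TostInput, tost_two_proportions

__all__ = ["TABLE1_ROWS", "Table1Row", "table1_counts", "reproduce_table1", "format_table1"]


@dataclass(frozen=True)
class Table1Row:
    dimension: str
    level: str
    n1: int
    N1: int
    n2: int
    N2: int
    prev1: float       # published CP 1 prevalence, %
    prev2: float       # published CP 2 prevalence, %
    diff: float        # published percentage-point difference
    ci_low: float
    ci_high: float
    reject_null: bool  # published equivalence decision


TABLE1_ROWS: tuple[Table1Row, ...] = (
    Table1Row("age_group", "18-24", 1506, 88952, 412, 196113, 1.7, 0.2, 1.5, 1.4, 1.6, True),
    Table1Row("age_group", "25-34", 4105, 128848, 4568, 302385, 3.2, 1.5, 1.7, 1.6, 1.8, True),
    Table1Row("age_group", "35-44", 8394, 121714, 13589, 276832, 6.9, 4.9, 2.0, 1.9, 2.1, True),
    Table1Row("race_ethnicity", "african_american", 3401, 62064, 4393, 118634, 5.5, 3.7, 1.8, 1.6, 2.0, True),
    Table1Row("race_ethnicity", "asian", 353, 8900, 696, 28771, 4.0, 2.4, 1.6, 1.2, 2.0, True),
    Table1Row("race_ethnicity", "hispanic", 2063, 38432, 2253, 74144, 5.4, 3.0, 2.4, 2.2, 2.6, False),
    Table1Row("race_ethnicity", "white", 7853, 210135, 9706, 457682, 3.7, 2.1, 1.6, 1.5, 1.7, True),
    Table1Row("race_ethnicity", "other", 335, 19983, 1521, 96099, 1.7, 1.6, 0.1, -0.1, 0.3, True),
    Table1Row("sex", "female", 8009, 207979, 10488, 428534, 3.9, 2.4, 1.5, 1.4, 1.6, True),
    Table1Row("sex", "male", 5996, 131535, 8081, 346796, 4.6, 2.3, 2.3, 2.2, 2.4, True),
    Table1Row("overall", "overall", 14005, 339514, 18569, 775330, 4.1, 2.4, 1.7, 1.6, 1.8, True),
)


def table1_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published counts as two prevalence tables (CP 1, CP 2)."""
    cp1 = pd.DataFrame(
        {"dimension": r.dimension, "level": r.level,
         "numerator": r.n1, "denominator": r.N1} for r in TABLE1_ROWS
    )
    cp2 = pd.DataFrame(
        {"dimension": r.dimension, "level": r.level,
         "numerator": r.n2, "denominator": r.N2} for r in TABLE1_ROWS
    )
    return cp1, cp2


def reproduce_table1(delta: float = 2.5, alpha: float = 0.05) -> pd.DataFrame:
    """Recompute every display cell from the embedded counts.

    Returns one row per stratum with computed values, published values, and a
    boolean match flag per cell (prevalences, difference, CI bounds, reject
    decision), all under the printed-table convention.
    """
    rows = []
    for r in TABLE1_ROWS:
        res = tost_two_proportions(
            TostInput(r.n1, r.N1, r.n2, r.N2, delta=delta, alpha=alpha,
                      convention="printed_table")
        )
        prev1 = round_half_up(100.0 * res.p1_hat, 1)
        prev2 = round_half_up(100.0 * res.p2_hat, 1)
        diff = round_half_up(res.diff, 1)
        ci_low = round_half_up(res.ci_low, 1)
        ci_high = round_half_up(res.ci_high, 1)
        rows.append(
            {
                "dimension": r.dimension,
                "level": r.level,
                "n1": r.n1, "N1": r.N1, "n2": r.n2, "N2": r.N2,
                "prev1_computed": prev1, "prev1_published": r.prev1,
                "prev2_computed": prev2, "prev2_published": r.prev2,
                "diff_computed": diff, "diff_published": r.diff,
                "ci_low_computed": ci_low, "ci_low_published": r.ci_low,
                "ci_high_computed": ci_high, "ci_high_published": r.ci_high,
                "reject_computed": res.equivalent, "reject_published": r.reject_null,
                "match_prev1": prev1 == r.prev1,
                "match_prev2": prev2 == r.prev2,
                "match_diff": diff == r.diff,
                "match_ci": (ci_low == r.ci_low) and (ci_high == r.ci_high),
                "match_reject": res.equivalent == r.reject_null,
            }
        )
    return pd.DataFrame(rows)


def format_table1(df: pd.DataFrame | None = None) -> str:
    """Human-readable comparison of computed vs published cells."""
    df = reproduce_table1() if df is None else df
    lines = [
        f"{'stratum':<28}{'CP1 n/N (%)':>24}{'CP2 n/N (%)':>24}"
        f"{'diff (90% CI)':>22}{'reject?':>9}{'match':>7}"
    ]
    for _, r in df.iterrows():
        match = all(r[c] for c in
                    ("match_prev1", "match_prev2", "match_diff", "match_ci", "match_reject"))
        lines.append(
            f"{r['dimension'] + '/' + r['level']:<28}"
            f"{f'{r.n1}/{r.N1} ({r.prev1_computed})':>24}"
            f"{f'{r.n2}/{r.N2} ({r.prev2_computed})':>24}"
            f"{f'{r.diff_computed} ({r.ci_low_computed} to {r.ci_high_computed})':>22}"
            f"{'Yes' if r.reject_computed else 'No':>9}"
            f"{'ok' if match else 'MISMATCH':>7}"
        )
    return "\n".join(lines)
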