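"""Two-sample t-tests recomputed from printed group summaries.

Published animal tables usually report mean ± SD and n per group rather
than raw values; Welch's unequal-variance t-test is fully determined by
those summaries:

    t  = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b)
    df = (s_a²/n_a + s_b²/n_b)² / [ (s_a²/n_a)²/(n_a−1) + (s_b²/n_b)²/(n_b−1) ]

with a two-sided p from the t distribution.  A pooled-variance (classic
Student) variant is available behind a flag; the Welch form is the default
because it reproduces the printed p-values of the diet-study weight table
from its summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import InputError, ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary: mean ± SD with sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"{self.label}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"{self.label}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_sided: float


def welch_t_from_summary(
    a: GroupSummary, b: GroupSummary, pooled: bool = False
) -> TTestResult:
    """Unpaired two-sample t-test from (mean, SD, n) summaries.

    Welch by default; ``pooled=True`` uses the pooled-variance form with
    df = n_a + n_b − 2.  Two identical zero-variance groups are degenerate.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if a.sd == 0 and b.sd == 0:
        raise InputError("both groups have zero SD; t is undefined")
    if pooled:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = (sp2 * (1 / a.n + 1 / b.n)) ** 0.5
        df = float(a.n + b.n - 2)
    else:
        se = (va + vb) ** 0.5
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_two_sided=float(min(p, 1.0)))


def table_report(
    rows: list[tuple[str, GroupSummary, GroupSummary]],
    pooled: bool = False,
    p_floor: float = 1e-4,
) -> pd.DataFrame:
    """One comparison per row: means ± SD, t, df, p, and a display p.

    p-values below ``p_floor`` display as "<0.0001" (journal convention);
    the numeric column is unrounded.
    """
    if not rows:
        raise InputError("no comparisons to report")
    out = []
    for name, a, b in rows:
        res = welch_t_from_summary(a, b, pooled=pooled)
        out.append({
            "variable": name,
            "group_a": a.label, "mean_a": a.mean, "sd_a": a.sd, "n_a": a.n,
            "group_b": b.label, "mean_b": b.mean, "sd_b": b.sd, "n_b": b.n,
            "t": res.t, "df": res.df, "p": res.p_two_sided,
            "p_display": (
                f"<{p_floor:.4f}".rstrip("0")
                if res.p_two_sided < p_floor
                else f"{res.p_two_sided:.4f}"
            ),
        })
    return pd.DataFrame(out)
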