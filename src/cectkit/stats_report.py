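"""Nonparametric statistical reporting for small cartilage cohorts.

Small-n cohort data from cadaver tissue are rarely normal, so association is
measured by Spearman's rank correlation: a Shapiro-Wilk gate documents the
non-normality, ``spearman_ci`` provides ρ with a Fisher-z confidence
interval (variance 1.06/(n-3), the standard rank-correlation correction)
and a p value that is exact (full permutation enumeration) for n <= 9 and
t-approximate otherwise, and ``build_table`` assembles the signed,
significance-flagged correlation matrix between diffusion characteristics
and structural/functional parameters.

No multiple-testing correction is applied; the table reports raw p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import atanh, factorial, tanh

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SpearmanResult", "CorrelationTable", "spearman_ci", "normality_gate", "build_table"]


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all orderings of the second rank vector."""
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho_perm = (ry_c @ rx_c) / denom
    count = int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))
    return count / factorial(n)


def spearman_ci(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> SpearmanResult:
    """Spearman ρ with Fisher-z confidence interval and p value.

    Ranks use average ranks for ties.  p is exact by full enumeration for
    n <= 9 and uses the t approximation
    ``t = rho sqrt((n-2)/(1-rho^2))`` otherwise.  The CI transforms
    ``z = atanh(rho)`` with standard error ``sqrt(1.06/(n-3))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    keep = np.isfinite(x) & np.isfinite(y)  # pairwise deletion
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("at least 4 complete pairs are required")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    if abs(rho) >= 1.0 - 1e-15:
        lo = hi = rho
    else:
        se = np.sqrt(1.06 / (n - 3))
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        z = atanh(rho)
        lo, hi = tanh(z - zcrit * se), tanh(z + zcrit * se)
    return SpearmanResult(rho=rho, ci_low=float(lo), ci_high=float(hi), p=float(p), n=n)


def normality_gate(x: np.ndarray) -> tuple[float, float, bool]:
    """Shapiro-Wilk statistic, p, and a flag that is True when the sample is
    compatible with normality (p >= 0.05)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 2000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 2000")
    if np.all(x == x[0]):
        raise ValueError("normality test undefined for a constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p >= 0.05)


@dataclass
class CorrelationTable:
    """Long-format correlation table with rendering helpers."""

    data: pd.DataFrame  # columns: row_var, col_var, rho, ci_low, ci_high, p, significant

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    def to_markdown(self) -> str:
        """Markdown rendering: sign-coded cells, significant ones in bold,
        magnitude shaded by repeating the sign symbol (one per 0.25 of |ρ|)."""
        rows = sorted(self.data["row_var"].unique())
        cols = list(dict.fromkeys(self.data["col_var"]))
        lines = ["| | " + " | ".join(cols) + " |", "|---" * (len(cols) + 1) + "|"]
        lookup = {(r.row_var, r.col_var): r for r in self.data.itertuples()}
        for rv in rows:
            cells = []
            for cv in cols:
                r = lookup[(rv, cv)]
                shade = ("+" if r.rho >= 0 else "−") * max(1, int(abs(r.rho) / 0.25) + 1)
                cell = f"{shade} {r.rho:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"
                if r.significant:
                    cell = f"**{cell}**"
                cells.append(cell)
            lines.append(f"| {rv} | " + " | ".join(cells) + " |")
        lines.append("")
        lines.append("Bold: p < 0.05; symbol count shades |ρ| in steps of 0.25.")
        return "\n".join(lines)


def build_table(
    cohort: pd.DataFrame,
    row_vars: tuple[str, ...] = ("p_max_pct", "tau_h"),
    col_vars: tuple[str, ...] | None = None,
    level: float = 0.95,
) -> CorrelationTable:
    """Spearman correlation table between diffusion and tissue parameters.

    ``row_vars`` are the diffusion characteristics; ``col_vars`` default to
    every other numeric column.  Missing columns are reported by name, never
    silently dropped.
    """
    if col_vars is None:
        numeric = cohort.select_dtypes("number").columns
        col_vars = tuple(c for c in numeric if c not in row_vars and c != "latent_pg")
    missing = [c for c in (*row_vars, *col_vars) if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {missing}")
    records = []
    for rv in row_vars:
        for cv in col_vars:
            res = spearman_ci(cohort[rv].to_numpy(), cohort[cv].to_numpy(), level=level)
            records.append(
                {
                    "row_var": rv,
                    "col_var": cv,
                    "rho": res.rho,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "significant": res.significant,
                    "n": res.n,
                }
            )
    return CorrelationTable(pd.DataFrame.from_records(records))
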