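"""Rank-based group comparison: Kruskal–Wallis screen across censoring
categories and median (IQR) summary tables.

The screen asks whether a continuous nutrition outcome (growth z-score,
micronutrient level, haemoglobin) differs across a metal's censoring
categories (below_lod / lod_loq / quantified). No multiple-testing
correction is applied — each outcome x metal test is reported with its raw
p-value at alpha = 0.05, and the output metadata flags this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal–Wallis test result.

    ``h`` is the rank statistic already divided by the tie-correction
    factor ``C = 1 - sum(t^3 - t) / (N^3 - N)``; ``p`` comes from the
    chi-square reference with ``df = groups - 1`` (or from exact
    permutation when requested).
    """

    h: float
    df: int
    p: float
    group_ns: dict[str, int]
    tie_correction: float
    n_dropped: int = 0
    method: str = "chi2"

    @property
    def n(self) -> int:
        return sum(self.group_ns.values())


def _tie_correction(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    n = values.size
    if n < 2:
        return 1.0
    return 1.0 - float(np.sum(counts**3 - counts)) / float(n**3 - n)


def kruskal_wallis(
    values,
    groups,
    exact_max_n: int = 0,
    n_perm_exact: int = 10_000,
    rng: np.random.Generator | None = None,
) -> KWResult:
    """Kruskal–Wallis H test of a numeric outcome across group labels.

    Missing values are dropped pairwise (the count is recorded in
    ``n_dropped``). Mid-ranks are used for ties and H is divided by the
    tie-correction factor. The chi-square approximation is the default
    reference; if every group has fewer than ``exact_max_n`` records a
    Monte-Carlo permutation p-value with ``n_perm_exact`` label shuffles is
    used instead (off by default, ``exact_max_n=0``).

    Raises
    ------
    DataError
        Fewer than two groups, or a group left empty after missing-drop.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise DataError("values and groups must have the same length")
    keep = np.isfinite(values) & (groups != None)  # noqa: E711 — None labels count as missing
    n_dropped = int(values.size - keep.sum())
    all_labels = [g for g in pd.unique(groups[groups != None])]  # noqa: E711
    values, groups = values[keep], groups[keep]

    if len(all_labels) < 2:
        raise DataError(f"need >= 2 non-empty groups, got {all_labels}")
    samples = [values[groups == g] for g in all_labels]
    empty = [str(g) for g, s in zip(all_labels, samples) if s.size == 0]
    if empty:
        raise DataError(f"group(s) empty after dropping missing values: {empty}")
    labels = all_labels
    group_ns = {str(g): int(s.size) for g, s in zip(labels, samples)}

    tie = _tie_correction(values)
    if tie == 0.0:  # every value identical: no rank variation at all
        return KWResult(0.0, len(labels) - 1, 1.0, group_ns, 0.0, n_dropped)

    h, p = stats.kruskal(*samples)
    h = float(h)
    df = len(labels) - 1
    method = "chi2"

    if exact_max_n and max(s.size for s in samples) < exact_max_n:
        rng = rng or np.random.default_rng()
        sizes = np.array([s.size for s in samples])
        count = 0
        pooled = values.copy()
        for _ in range(n_perm_exact):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            hp, _ = stats.kruskal(*parts)
            if hp >= h - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm_exact)
        method = "permutation"

    return KWResult(h, df, float(p), group_ns, tie, n_dropped, method)


def median_iqr_table(
    cohort: pd.DataFrame,
    outcomes: list[str],
    group_col: str,
) -> pd.DataFrame:
    """Per group x outcome: n, median, p25, p75 and IQR (p75 - p25).

    Quantiles use linear interpolation between closest order statistics,
    the same rule as the numeric branch of the censored percentile
    summary. Returns a tidy frame with one row per (group, outcome).
    """
    missing = [c for c in outcomes + [group_col] if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"columns not in cohort: {missing}")
    rows = []
    for g, sub in cohort.groupby(group_col, sort=False, observed=True):
        for out in outcomes:
            x = pd.to_numeric(sub[out], errors="coerce").dropna()
            if x.empty:
                rows.append(
                    {"group": g, "outcome": out, "n": 0, "median": np.nan,
                     "p25": np.nan, "p75": np.nan, "iqr": np.nan}
                )
                continue
            p25, med, p75 = np.percentile(x, [25, 50, 75])
            rows.append(
                {"group": g, "outcome": out, "n": int(x.size), "median": float(med),
                 "p25": float(p25), "p75": float(p75), "iqr": float(p75 - p25)}
            )
    return pd.DataFrame(rows)


def kw_screen_table(
    cohort: pd.DataFrame,
    outcomes: list[str],
    group_col: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table-style screen: median (IQR) per category plus a p-value row.

    One row per group per outcome with the Kruskal–Wallis p-value repeated
    per outcome and a significance marker at ``alpha``. Metadata columns
    record that p-values are raw (no multiplicity correction).
    """
    summary = median_iqr_table(cohort, outcomes, group_col)
    pvals = {}
    for out in outcomes:
        res = kruskal_wallis(
            pd.to_numeric(cohort[out], errors="coerce").to_numpy(),
            cohort[group_col].to_numpy(object),
        )
        pvals[out] = res.p
    summary["p_value"] = summary["outcome"].map(pvals)
    summary["significant"] = summary["p_value"] < alpha
    summary.attrs["alpha"] = alpha
    summary.attrs["multiplicity_correction"] = "none (raw per-test p-values)"
    return summary
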