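"""Correlation analysis and optimal-configuration ranking.

Pearson correlations (two-sided p from the t-distribution with n - 2
degrees of freedom, alpha = 0.05) between the QRS-derived and
tissue-derived dyssynchrony biomarkers, and stable rankings of pacing
configurations under each optimisation criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .delineation import BiomarkerRow

ALPHA = 0.05

CRITERIA = {"MIN_QRSD": "QRSd", "MIN_TAT": "TAT", "MIN_T90": "t90"}

#: the three pre-specified biomarker pairs (x, y)
CORRELATION_PAIRS = (("QRSd", "TAT"), ("QRSa", "TAT"), ("t90QRSa", "t90"))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    pair_label: tuple[str, str]

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation coefficient outside [-1, 1]")
        if self.n < 3:
            raise ValueError("need at least 3 samples")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def pearson(x: Sequence[float], y: Sequence[float],
            pair_label=("x", "y")) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = _sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size), pair_label=tuple(pair_label))


def biomarker_table(rows: Iterable[BiomarkerRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in rows])
    if df.empty:
        raise ValueError("empty biomarker table")
    return df


def correlation_suite(table) -> dict[tuple[str, str], CorrelationResult]:
    """The three pre-specified correlations on a biomarker table.

    ``table`` is a DataFrame (or iterable of BiomarkerRow) with columns
    QRSd, TAT, QRSa, t90QRSa, t90.  Rows with missing values are
    dropped; at least 3 complete rows are required.
    """
    if not isinstance(table, pd.DataFrame):
        table = biomarker_table(table)
    needed = {"QRSd", "TAT", "QRSa", "t90QRSa", "t90"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    clean = table.dropna(subset=sorted(needed))
    if len(clean) < 3:
        raise ValueError("need at least 3 complete biomarker rows")
    out = {}
    for xcol, ycol in CORRELATION_PAIRS:
        out[(xcol, ycol)] = pearson(clean[xcol], clean[ycol], (xcol, ycol))
    return out


def _sort_key_columns(df: pd.DataFrame) -> list[str]:
    aux = [c for c in ("rv_site", "lv_site", "AVD", "VVD", "config_id")
           if c in df.columns]
    return aux


def rank_configs(table, criterion: str):
    """Stable ascending ranking by one criterion.

    Returns ``(ranked DataFrame, optimum row)``.  Ties are broken by the
    lexicographic order of (rv_site, lv_site, AVD, VVD) where available,
    else config_id; the tie-break columns are part of the sort, so the
    result is reproducible.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"one of {sorted(CRITERIA)}")
    if not isinstance(table, pd.DataFrame):
        table = biomarker_table(table)
    if table.empty:
        raise ValueError("empty biomarker table")
    col = CRITERIA[criterion]
    ranked = table.sort_values([col] + _sort_key_columns(table),
                               kind="stable").reset_index(drop=True)
    return ranked, ranked.iloc[0]


def optimum_report(table) -> str:
    """Plain-text summary: optimum configuration per criterion, noting
    whether the QRS-duration optimum coincides with the t90 optimum."""
    if not isinstance(table, pd.DataFrame):
        table = biomarker_table(table)
    lines = []
    optima = {}
    for crit in sorted(CRITERIA):
        _, best = rank_configs(table, crit)
        optima[crit] = best["config_id"]
        lines.append(f"{crit:>9}: {best['config_id']} "
                     f"({CRITERIA[crit]} = {best[CRITERIA[crit]]:.1f} ms)")
    same = optima["MIN_QRSD"] == optima["MIN_T90"]
    lines.append("QRSd optimum and t90 optimum "
                 + ("coincide" if same else "differ")
                 + " on this grid.")
    return "\n".join(lines)
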