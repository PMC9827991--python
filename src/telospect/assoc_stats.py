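"""Cross-species association statistics for telomeric repeat traits.

Pearson and Spearman correlations between repeat abundance (Mb/1C), genome
proportion, SNV heterogeneity, genome size and karyotype composition
(chromosome and telocentric counts per 2n), with per-pair complete-case
handling, plus the fold-range summary (max/min) of abundances across
species.  |r| >= 0.7 is flagged as a strong relationship.  P-values use
the t-approximation (Pearson) and the large-sample approximation
(Spearman); no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRONG_THRESHOLD = 0.7

#: The six default variable pairs of the cross-species analysis.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("abundance_Mb_1C", "GP_percent"),
    ("abundance_Mb_1C", "snv_count"),
    ("abundance_Mb_1C", "genome_size_Mb_1C"),
    ("chromosome_number_2n", "telocentric_count_2n"),
    ("chromosome_number_2n", "genome_size_Mb_1C"),
    ("telocentric_count_2n", "genome_size_Mb_1C"),
)


def _validate(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation; returns (r, p) at full double precision."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation with average ranks for ties; returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    variable_1: str
    variable_2: str
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float

    @property
    def strong(self) -> bool:
        """Strong relationship: |r| >= 0.7 (inclusive boundary)."""
        return abs(self.pearson_r) >= STRONG_THRESHOLD


def correlation_table(
    records: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> list[CorrelationResult]:
    """One correlation row per variable pair, pairwise complete cases.

    Pairs with fewer than 3 complete cases are skipped with a warning.
    """
    out = []
    for v1, v2 in pairs:
        if v1 not in records.columns or v2 not in records.columns:
            logger.warning("pair (%s, %s) skipped: column missing", v1, v2)
            continue
        sub = records[[v1, v2]].dropna()
        if len(sub) < 3:
            logger.warning("pair (%s, %s) skipped: only %d complete cases", v1, v2, len(sub))
            continue
        r, pr = pearson(sub[v1], sub[v2])
        rho, ps = spearman(sub[v1], sub[v2])
        out.append(
            CorrelationResult(
                variable_1=v1,
                variable_2=v2,
                n=len(sub),
                pearson_r=r,
                pearson_p=pr,
                spearman_rho=rho,
                spearman_p=ps,
            )
        )
    return out


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular rendering of correlation results (r/rho to 5 decimals)."""
    return pd.DataFrame(
        [
            {
                "variable_1": c.variable_1,
                "variable_2": c.variable_2,
                "n": c.n,
                "pearson_r": round(c.pearson_r, 5),
                "pearson_p": c.pearson_p,
                "spearman_rho": round(c.spearman_rho, 5),
                "spearman_p": c.spearman_p,
                "strong": c.strong,
            }
            for c in results
        ]
    )


def fold_range(values) -> float:
    """max/min fold factor across strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValueError("all values must be positive and finite")
    return float(v.max() / v.min())
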