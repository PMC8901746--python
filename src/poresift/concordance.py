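"""Control-vs-depletion composition concordance.

Compares paired abundance tables via per-taxon fold deviations binned by
read-count strata, Bray-Curtis dissimilarity over the union of retained
taxa, and Spearman rank correlation with a pairwise-case exclusion rule
(fewer than two taxa shared by both tables precludes correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import AbundanceTable

__all__ = [
    "PairedAbundance",
    "FoldDeviationSummary",
    "SpearmanResult",
    "STRATA",
    "pair_tables",
    "fold_deviation",
    "bray_curtis",
    "bray_curtis_pair",
    "spearman_with_exclusion",
    "pair_report",
]

#: Count strata, keyed by max(count_a, count_b): [lo, hi)
STRATA = (
    (30, 100),
    (100, 500),
    (500, 1000),
    (1000, math.inf),
)

#: Below this many shared taxa the p-value is flagged as weakly powered.
FEW_PAIRWISE_CASES = 10

EXACT_PERMUTATION_MAX_N = 8


@dataclass
class PairedAbundance:
    taxon: str
    count_a: int
    count_b: int
    proportion_a: float
    proportion_b: float
    stratum: Optional[tuple[float, float]]


@dataclass
class FoldDeviationSummary:
    overall_mean_fold: float
    per_stratum: dict[tuple[float, float], tuple[float, int]]  # -> (mean |fold-1|, n)
    n_taxa: int
    zero_in_a: list[str]  # taxa absent in the control table, never divided


@dataclass
class SpearmanResult:
    rho: Optional[float]
    p_value: Optional[float]
    n_pairs: int
    excluded: bool
    reason: Optional[str] = None
    few_pairwise_cases: bool = False
    method: Optional[str] = None  # "exact" or "t-approx"


def _stratum_of(max_count: int) -> Optional[tuple[float, float]]:
    for lo, hi in STRATA:
        if lo <= max_count < hi:
            return (lo, hi)
    return None


def pair_tables(a: AbundanceTable, b: AbundanceTable) -> list[PairedAbundance]:
    """Join two abundance tables over the union of their retained taxa.

    Only taxa passing each table's own min-read filter enter (i.e. present
    in at least one table); a taxon absent from one side gets count 0 and
    proportion 0 there.  The stratum is keyed by max(count_a, count_b).
    """
    counts_a, counts_b = a.counts(), b.counts()
    props_a, props_b = a.proportions(), b.proportions()
    taxa = sorted(set(counts_a) | set(counts_b))
    out = []
    for taxon in taxa:
        ca, cb = counts_a.get(taxon, 0), counts_b.get(taxon, 0)
        out.append(
            PairedAbundance(
                taxon=taxon,
                count_a=ca,
                count_b=cb,
                proportion_a=props_a.get(taxon, 0.0),
                proportion_b=props_b.get(taxon, 0.0),
                stratum=_stratum_of(max(ca, cb)),
            )
        )
    return out


def fold_deviation(pairs: Sequence[PairedAbundance]) -> FoldDeviationSummary:
    """Per-taxon fold = proportion_b / proportion_a, aggregated by stratum.

    Taxa with proportion_a == 0 are reported separately and never divided.
    Per-stratum aggregate is the mean absolute deviation of the fold from 1;
    the overall aggregate is the plain mean fold.
    """
    folds: list[float] = []
    zero_in_a: list[str] = []
    by_stratum: dict[tuple[float, float], list[float]] = {}
    for pair in pairs:
        if pair.proportion_a == 0:
            zero_in_a.append(pair.taxon)
            continue
        fold = pair.proportion_b / pair.proportion_a
        folds.append(fold)
        if pair.stratum is not None:
            by_stratum.setdefault(pair.stratum, []).append(fold)
    per_stratum = {
        stratum: (float(np.mean(np.abs(np.asarray(vals) - 1.0))), len(vals))
        for stratum, vals in sorted(by_stratum.items())
    }
    overall = float(np.mean(folds)) if folds else float("nan")
    return FoldDeviationSummary(
        overall_mean_fold=overall,
        per_stratum=per_stratum,
        n_taxa=len(folds),
        zero_in_a=zero_in_a,
    )


def bray_curtis(p: Sequence[float], q: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|p_i - q_i| / sum(p_i + q_i)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    denom = float(np.sum(p + q))
    if denom == 0:
        raise ValueError("both vectors are zero")
    return float(np.sum(np.abs(p - q)) / denom)


def bray_curtis_pair(pairs: Sequence[PairedAbundance]) -> float:
    """Bray-Curtis over the union of retained taxa, renormalized to sum 1.

    Taxa absent from one table contribute zero on that side (included, in
    contrast to the fold statistics which skip them).
    """
    p = np.array([pair.proportion_a for pair in pairs], dtype=float)
    q = np.array([pair.proportion_b for pair in pairs], dtype=float)
    if p.sum() > 0:
        p = p / p.sum()
    if q.sum() > 0:
        q = q / q.sum()
    return bray_curtis(p, q)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2)) * float(np.sum(ry**2)))
    if denom == 0:
        return float("nan")
    return float(np.sum(rx * ry) / denom)


def spearman_with_exclusion(pairs: Sequence[PairedAbundance]) -> SpearmanResult:
    """Spearman correlation over taxa observed in BOTH tables.

    Samples with fewer than two such pairwise cases are excluded (no
    correlation is computable from a single shared taxon).  The two-sided
    p-value is exact (full permutation enumeration) for n <= 8 shared taxa
    and the t-approximation above; results with fewer than 10 shared taxa
    are flagged as weakly powered.
    """
    shared = [p for p in pairs if p.count_a > 0 and p.count_b > 0]
    n = len(shared)
    if n < 2:
        return SpearmanResult(
            rho=None,
            p_value=None,
            n_pairs=n,
            excluded=True,
            reason=f"only {n} pairwise case(s); at least 2 required",
        )
    x = np.array([p.proportion_a for p in shared])
    y = np.array([p.proportion_b for p in shared])
    rho = _spearman_rho(x, y)
    if math.isnan(rho):
        return SpearmanResult(
            rho=None,
            p_value=None,
            n_pairs=n,
            excluded=True,
            reason="constant ranks on one side",
        )
    if n <= EXACT_PERMUTATION_MAX_N:
        count = 0
        total = 0
        for perm in permutations(y):
            r = _spearman_rho(x, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p_value = count / total
        method = "exact"
    else:
        p_value = float(stats.spearmanr(x, y).pvalue)
        method = "t-approx"
    return SpearmanResult(
        rho=rho,
        p_value=p_value,
        n_pairs=n,
        excluded=False,
        few_pairwise_cases=n < FEW_PAIRWISE_CASES,
        method=method,
    )


def pair_report(
    samples: Sequence[tuple[str, AbundanceTable, AbundanceTable]],
) -> pd.DataFrame:
    """Per-sample concordance table (one row per control/depletion pair)."""
    rows = []
    for name, table_a, table_b in samples:
        pairs = pair_tables(table_a, table_b)
        fd = fold_deviation(pairs)
        bc = bray_curtis_pair(pairs) if pairs else float("nan")
        sp = spearman_with_exclusion(pairs)
        row: dict[str, object] = {
            "sample": name,
            "n_pairs": sp.n_pairs,
            "mean_fold": fd.overall_mean_fold,
            "bray_curtis": bc,
            "rho": sp.rho,
            "p_value": sp.p_value,
            "excluded": sp.excluded,
            "few_pairwise_cases": sp.few_pairwise_cases,
        }
        for (lo, hi), (dev, n) in fd.per_stratum.items():
            hi_label = "inf" if math.isinf(hi) else int(hi)
            row[f"dev_{int(lo)}_{hi_label}"] = dev
        rows.append(row)
    return pd.DataFrame(rows)
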