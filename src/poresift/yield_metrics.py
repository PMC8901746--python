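"""Run-level accounting: totals, rejection rates, microbial bases, cohorts.

The central object is :class:`RunSummary`, the machine twin of a per-run
yield table: total reads/bases, per-category read counts, rejection
percentage, and microbial bases counted from the kept (accepted +
no_decision, or control) fractions only.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classification import LineageMap, TaxonAssignment, UNCLASSIFIED_TAXID
from .composition import CategoryContent, KEPT_CATEGORIES
from .io_readuntil import CategorizedRead, Category

__all__ = [
    "RunSummary",
    "DecisionLengthSummary",
    "CohortSummary",
    "summarize_run",
    "fold_change",
    "decision_length_distribution",
    "cohort_summary",
]

MICROBIAL_POLICIES = ("bacteria_archaea", "non_human_classified")


@dataclass
class RunSummary:
    run_id: str
    total_reads: int
    total_bases: int
    rejected_reads: int
    rejected_pct: float
    accepted_reads: int
    no_decision_reads: int
    control_reads: int
    microbial_bases: int
    unclassified_reads: int
    median_read_length: dict[str, float]  # per category plus "overall"
    microbial_policy: str = "bacteria_archaea"


@dataclass
class DecisionLengthSummary:
    """Quantiles and histogram of bases consumed until the decision."""

    category: str
    n: int
    quantiles: dict[str, float]  # p5, p25, p50, p75, p95
    bin_edges: list[float]
    bin_counts: list[int]
    used_length_proxy: bool = False


@dataclass
class CohortSummary:
    per_sample: pd.DataFrame
    aggregates: dict[str, tuple[float, float]]  # name -> (mean, sample sd)
    excluded: dict[str, list[str]]  # category -> sample ids below threshold
    min_category_reads: int


def summarize_run(
    reads: Sequence[CategorizedRead],
    assignments: Optional[Iterable[TaxonAssignment]] = None,
    lineage: Optional[LineageMap] = None,
    run_id: str = "run",
    microbial_policy: str = "bacteria_archaea",
) -> RunSummary:
    """Build the per-run accounting table.

    ``microbial_bases`` counts only reads in the kept fractions (accepted,
    no_decision, or control for runs without a decision log) whose lineage
    superkingdom is Bacteria/Archaea — or, under policy
    ``non_human_classified``, any classified non-human lineage.
    """
    if not reads:
        raise ValueError("empty run")
    if microbial_policy not in MICROBIAL_POLICIES:
        raise ValueError(
            f"unknown microbial policy {microbial_policy!r}; "
            f"choose from {MICROBIAL_POLICIES}"
        )
    by_read = (
        {a.read_id: a.taxid for a in assignments} if assignments is not None else {}
    )

    cat_counts = {c: 0 for c in Category}
    lengths_by_cat: dict[Category, list[int]] = {c: [] for c in Category}
    total_bases = 0
    microbial_bases = 0
    unclassified = 0
    for cr in reads:
        cat_counts[cr.category] += 1
        lengths_by_cat[cr.category].append(cr.read.length_bp)
        total_bases += cr.read.length_bp
        taxid = by_read.get(cr.read.read_id, UNCLASSIFIED_TAXID)
        if taxid == UNCLASSIFIED_TAXID:
            unclassified += 1
            continue
        if cr.category not in KEPT_CATEGORIES or lineage is None:
            continue
        lin = lineage.lookup(taxid)
        if lin.superkingdom == "unresolved":
            continue
        if microbial_policy == "bacteria_archaea":
            is_microbial = lin.superkingdom in ("Bacteria", "Archaea")
        else:
            is_microbial = not lin.is_human
        if is_microbial:
            microbial_bases += cr.read.length_bp

    total = len(reads)
    rejected = cat_counts[Category.REJECTED]
    has_log = any(
        cat_counts[c] for c in (Category.ACCEPTED, Category.REJECTED, Category.NO_DECISION)
    )
    medians = {
        cat.value: float(statistics.median(lens))
        for cat, lens in lengths_by_cat.items()
        if lens
    }
    medians["overall"] = float(
        statistics.median(cr.read.length_bp for cr in reads)
    )
    return RunSummary(
        run_id=run_id,
        total_reads=total,
        total_bases=total_bases,
        rejected_reads=rejected,
        rejected_pct=round(100.0 * rejected / total, 2) if has_log else 0.0,
        accepted_reads=cat_counts[Category.ACCEPTED],
        no_decision_reads=cat_counts[Category.NO_DECISION],
        control_reads=cat_counts[Category.CONTROL],
        microbial_bases=microbial_bases,
        unclassified_reads=unclassified,
        median_read_length=medians,
        microbial_policy=microbial_policy,
    )


def fold_change(
    numerator: Union[RunSummary, float, int],
    denominator: Union[RunSummary, float, int],
    field_name: Optional[str] = None,
) -> float:
    """Plain ratio of a field (or of two numbers).

    Rounding to 2 decimals is left to the report layer.
    """
    def value(x):
        if isinstance(x, RunSummary):
            if field_name is None:
                raise ValueError("field_name required for RunSummary inputs")
            return getattr(x, field_name)
        return x

    num, den = value(numerator), value(denominator)
    if den == 0:
        raise ZeroDivisionError("fold_change denominator is zero")
    return num / den


def decision_length_distribution(
    reads: Sequence[CategorizedRead], bin_width: int = 100
) -> dict[str, DecisionLengthSummary]:
    """Per-category quantiles + histogram of bp consumed until the decision.

    Categories without any ``bp_to_decision`` fall back to read length as a
    proxy for rejected reads (truncated reads: emitted length equals bases
    consumed); the proxy usage is flagged in the summary.
    """
    out: dict[str, DecisionLengthSummary] = {}
    by_cat: dict[Category, list[CategorizedRead]] = {}
    for cr in reads:
        by_cat.setdefault(cr.category, []).append(cr)
    for cat, members in by_cat.items():
        values = [cr.bp_to_decision for cr in members if cr.bp_to_decision is not None]
        proxy = False
        if not values and cat is Category.REJECTED:
            values = [cr.read.length_bp for cr in members]
            proxy = True
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        qs = np.quantile(arr, [0.05, 0.25, 0.50, 0.75, 0.95])
        lo = float(np.floor(arr.min() / bin_width) * bin_width)
        hi = float(np.ceil(arr.max() / bin_width) * bin_width)
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(arr, bins=edges)
        out[cat.value] = DecisionLengthSummary(
            category=cat.value,
            n=len(arr),
            quantiles={
                "p5": float(qs[0]),
                "p25": float(qs[1]),
                "p50": float(qs[2]),
                "p75": float(qs[3]),
                "p95": float(qs[4]),
            },
            bin_edges=[float(e) for e in edges],
            bin_counts=[int(c) for c in counts],
            used_length_proxy=proxy,
        )
    return out


def _category_pct(summary: RunSummary, count: int) -> float:
    return 100.0 * count / summary.total_reads if summary.total_reads else 0.0


def cohort_summary(
    pairs: Sequence[
        tuple[
            tuple[RunSummary, Optional[Mapping[str, CategoryContent]]],
            tuple[RunSummary, Optional[Mapping[str, CategoryContent]]],
        ]
    ],
    min_category_reads: int = 100,
    sample_ids: Optional[Sequence[str]] = None,
) -> CohortSummary:
    """Aggregate paired control/depletion runs into a cohort table.

    Each pair element is ``(RunSummary, content)`` where ``content`` is the
    per-category output of :func:`poresift.composition.category_content`
    (may be ``None``).  Reports per-sample read-count fold (rejected reads
    included) and category percentages; cohort aggregates are arithmetic
    mean and sample standard deviation (ddof=1).  Per-category human and
    bacterial means exclude samples whose category holds fewer than
    ``min_category_reads`` reads; excluded sample ids are listed.
    """
    if len(pairs) < 2:
        raise ValueError("cohort_summary requires at least 2 pairs")
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1:02d}" for i in range(len(pairs))]

    rows = []
    excluded: dict[str, list[str]] = {}
    for sid, ((ctrl_sum, ctrl_content), (dep_sum, dep_content)) in zip(
        sample_ids, pairs
    ):
        row: dict[str, object] = {
            "sample": sid,
            "control_reads": ctrl_sum.total_reads,
            "depletion_reads": dep_sum.total_reads,
            "fold": fold_change(dep_sum, ctrl_sum, "total_reads"),
            "rejected_pct": _category_pct(dep_sum, dep_sum.rejected_reads),
            "accepted_pct": _category_pct(dep_sum, dep_sum.accepted_reads),
            "no_decision_pct": _category_pct(dep_sum, dep_sum.no_decision_reads),
        }
        if ctrl_content is not None and "all" in ctrl_content:
            row["control_human_pct"] = ctrl_content["all"].human_pct
            row["control_bacterial_pct"] = ctrl_content["all"].bacterial_pct
        if dep_content is not None:
            for cat in ("rejected", "accepted", "no_decision"):
                content = dep_content.get(cat)
                if content is None:
                    continue
                row[f"{cat}_n"] = content.n_reads
                row[f"{cat}_human_pct"] = content.human_pct
                row[f"{cat}_bacterial_pct"] = content.bacterial_pct
                if content.n_reads < min_category_reads:
                    excluded.setdefault(cat, []).append(sid)
        rows.append(row)

    df = pd.DataFrame(rows)

    def agg(col: str, exclude: Optional[list[str]] = None):
        if col not in df.columns:
            return None
        series = df.set_index("sample")[col].dropna()
        if exclude:
            series = series.drop(index=exclude, errors="ignore")
        if len(series) == 0:
            return None
        mean = float(series.mean())
        sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
        return (mean, sd)

    aggregates: dict[str, tuple[float, float]] = {}
    for col in ("fold", "rejected_pct", "accepted_pct", "no_decision_pct",
                "control_human_pct", "control_bacterial_pct"):
        got = agg(col)
        if got is not None:
            aggregates[col] = got
    for cat in ("rejected", "accepted", "no_decision"):
        for kind in ("human", "bacterial"):
            got = agg(f"{cat}_{kind}_pct", exclude=excluded.get(cat))
            if got is not None:
                aggregates[f"{cat}_{kind}_pct"] = got

    return CohortSummary(
        per_sample=df,
        aggregates=aggregates,
        excluded=excluded,
        min_category_reads=min_category_reads,
    )
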