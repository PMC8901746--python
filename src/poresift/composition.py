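"""Abundance tables and per-category human/bacterial content.

Proportions can be computed against two denominators: the whole run
including rejected reads (the convention used when comparing depletion runs
to controls) or the reads of a single decision category.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .classification import Lineage, LineageMap, TaxonAssignment, UNCLASSIFIED_TAXID
from .io_readuntil import CategorizedRead, Category

__all__ = [
    "AbundanceTable",
    "CategoryContent",
    "abundance_table",
    "category_content",
    "KEPT_CATEGORIES",
]

#: Categories whose reads count as "kept" (sequenced to completion).
KEPT_CATEGORIES = frozenset(
    {Category.ACCEPTED, Category.NO_DECISION, Category.CONTROL}
)

DENOMINATOR_POLICIES = ("all_reads_incl_rejected", "category_reads")


@dataclass
class AbundanceTable:
    """Per-taxon read counts and proportions at one rank for one run."""

    run_id: str
    rank: str
    rows: list[tuple[str, int, float]]  # (taxon, count, proportion), sorted
    denominator: int
    denominator_policy: str
    min_reads: int
    dropped_reads: int  # reads in taxa below the min_reads threshold
    unclassified_reads: int

    def proportions(self) -> dict[str, float]:
        return {taxon: prop for taxon, _, prop in self.rows}

    def counts(self) -> dict[str, int]:
        return {taxon: count for taxon, count, _ in self.rows}

    def to_tsv(self, path: os.PathLike | str) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            fh.write(
                f"# run_id={self.run_id} rank={self.rank} "
                f"denominator_policy={self.denominator_policy} "
                f"denominator={self.denominator} min_reads={self.min_reads}\n"
            )
            fh.write("taxon\tcount\tproportion\n")
            for taxon, count, prop in self.rows:
                fh.write(f"{taxon}\t{count}\t{prop:.6g}\n")
        return path


@dataclass
class CategoryContent:
    """Human/bacterial/other/unclassified percentages for one read category."""

    category: str
    n_reads: int
    human_pct: float
    bacterial_pct: float
    other_pct: float
    unclassified_pct: float
    flagged_low: bool = False


def _taxon_at_rank(lineage: Lineage, rank: str) -> Optional[str]:
    if rank == "genus":
        return lineage.genus
    if rank == "species":
        return lineage.species
    if rank == "superkingdom":
        return lineage.superkingdom
    raise ValueError(f"unsupported rank {rank!r}")


def abundance_table(
    reads: Sequence[CategorizedRead],
    assignments: Iterable[TaxonAssignment],
    lineage: LineageMap,
    rank: str = "genus",
    denominator_policy: str = "all_reads_incl_rejected",
    min_reads: int = 30,
    categories: Optional[Iterable[Category]] = None,
    run_id: str = "run",
    bacteria_only: bool = True,
) -> AbundanceTable:
    """Tabulate per-taxon read counts at ``rank``.

    Taxa with fewer than ``min_reads`` reads are dropped (the dropped read
    mass is reported).  Rows are sorted by count descending, ties broken
    alphabetically.  ``categories`` restricts the reads that are counted;
    the denominator is the whole run (``all_reads_incl_rejected``) or the
    counted reads only (``category_reads``).
    """
    if denominator_policy not in DENOMINATOR_POLICIES:
        raise ValueError(
            f"unknown denominator policy {denominator_policy!r}; "
            f"choose from {DENOMINATOR_POLICIES}"
        )
    cat_filter = None if categories is None else frozenset(categories)
    by_read = {a.read_id: a.taxid for a in assignments}

    counts: Counter[str] = Counter()
    n_total = len(reads)
    n_counted = 0
    unclassified = 0
    for cr in reads:
        if cat_filter is not None and cr.category not in cat_filter:
            continue
        n_counted += 1
        taxid = by_read.get(cr.read.read_id, UNCLASSIFIED_TAXID)
        if taxid == UNCLASSIFIED_TAXID:
            unclassified += 1
            continue
        lin = lineage.lookup(taxid)
        if bacteria_only and lin.superkingdom not in ("Bacteria", "Archaea"):
            continue
        taxon = _taxon_at_rank(lin, rank)
        if taxon is None:
            continue
        counts[taxon] += 1

    denominator = (
        n_total if denominator_policy == "all_reads_incl_rejected" else n_counted
    )
    kept = {t: c for t, c in counts.items() if c >= min_reads}
    dropped = sum(c for t, c in counts.items() if c < min_reads)
    rows = [
        (taxon, count, count / denominator if denominator else 0.0)
        for taxon, count in sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return AbundanceTable(
        run_id=run_id,
        rank=rank,
        rows=rows,
        denominator=denominator,
        denominator_policy=denominator_policy,
        min_reads=min_reads,
        dropped_reads=dropped,
        unclassified_reads=unclassified,
    )


def _content_of(
    label: str,
    members: list[int],
    taxids: list[int],
    lineage: LineageMap,
    min_category_reads: int,
) -> CategoryContent:
    n = len(members)
    human = bacterial = other = unclassified = 0
    for i in members:
        taxid = taxids[i]
        if taxid == UNCLASSIFIED_TAXID:
            unclassified += 1
            continue
        lin = lineage.lookup(taxid)
        if lin.superkingdom == "unresolved":
            unclassified += 1
        elif lin.is_human:
            human += 1
        elif lin.superkingdom == "Bacteria":
            bacterial += 1
        else:
            other += 1
    pct = lambda c: 100.0 * c / n if n else 0.0
    return CategoryContent(
        category=label,
        n_reads=n,
        human_pct=pct(human),
        bacterial_pct=pct(bacterial),
        other_pct=pct(other),
        unclassified_pct=pct(unclassified),
        flagged_low=n < min_category_reads,
    )


def category_content(
    reads: Sequence[CategorizedRead],
    assignments: Iterable[TaxonAssignment],
    lineage: LineageMap,
    min_category_reads: int = 100,
) -> dict[str, CategoryContent]:
    """Human/bacterial/other/unclassified percentages per decision category.

    Percentages use the category's own reads as denominator.  Besides one
    entry per category present, the result includes ``"all"`` (whole run)
    and, for decision-log runs, ``"accepted+no_decision"`` (the kept
    fraction).  Categories with fewer than ``min_category_reads`` reads are
    flagged, not suppressed.
    """
    by_read = {a.read_id: a.taxid for a in assignments}
    taxids = [
        by_read.get(cr.read.read_id, UNCLASSIFIED_TAXID) for cr in reads
    ]
    groups: dict[str, list[int]] = {}
    for i, cr in enumerate(reads):
        groups.setdefault(cr.category.value, []).append(i)

    out: dict[str, CategoryContent] = {}
    for label, members in groups.items():
        out[label] = _content_of(label, members, taxids, lineage, min_category_reads)
    decision_cats = {Category.ACCEPTED.value, Category.REJECTED.value,
                     Category.NO_DECISION.value}
    if decision_cats & set(groups):
        kept = [
            i
            for i, cr in enumerate(reads)
            if cr.category in (Category.ACCEPTED, Category.NO_DECISION)
        ]
        out["accepted+no_decision"] = _content_of(
            "accepted+no_decision", kept, taxids, lineage, min_category_reads
        )
    out["all"] = _content_of(
        "all", list(range(len(reads))), taxids, lineage, min_category_reads
    )
    return out
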