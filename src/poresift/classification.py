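"""Per-read taxonomic classification tables and lineage lookup.

Consumes classifier output (centrifuge-, kraken2- or plain-style TSV) plus a
pre-digested taxid->lineage map.  Also provides a truth-oracle classifier for
synthetic runs, which replaces a real classifier when the true taxid of every
read is known.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonAssignment",
    "Lineage",
    "LineageMap",
    "UNRESOLVED",
    "read_classification",
    "resolve_best_hits",
    "read_lineage_map",
    "write_lineage_map",
    "oracle_classify",
]

UNCLASSIFIED_TAXID = 0


@dataclass
class TaxonAssignment:
    read_id: str
    taxid: int
    score: Optional[float] = None


@dataclass(frozen=True)
class Lineage:
    taxid: int
    superkingdom: str
    genus: Optional[str] = None
    species: Optional[str] = None

    @property
    def is_human(self) -> bool:
        return self.species == "Homo sapiens"


#: Sentinel for taxids absent from the lineage map.
UNRESOLVED = Lineage(taxid=-1, superkingdom="unresolved")


class LineageMap(dict):
    """taxid -> :class:`Lineage`; unknown taxids resolve to :data:`UNRESOLVED`."""

    def lookup(self, taxid: int) -> Lineage:
        return self.get(taxid, UNRESOLVED)


def resolve_best_hits(
    rows: Iterable[TaxonAssignment],
) -> tuple[list[TaxonAssignment], int]:
    """Collapse multi-row reads to one assignment each.

    Highest score wins; score ties between different taxids demote the read
    to unclassified (taxid 0) rather than fabricating a resolution.  Returns
    ``(assignments, n_ties)``; input order of first appearance is preserved.
    """
    best: dict[str, TaxonAssignment] = {}
    tied: dict[str, bool] = {}
    order: list[str] = []
    for row in rows:
        cur = best.get(row.read_id)
        if cur is None:
            best[row.read_id] = row
            tied[row.read_id] = False
            order.append(row.read_id)
            continue
        cur_score = cur.score if cur.score is not None else 0.0
        new_score = row.score if row.score is not None else 0.0
        if new_score > cur_score:
            best[row.read_id] = row
            tied[row.read_id] = False
        elif new_score == cur_score and row.taxid != cur.taxid:
            tied[row.read_id] = True
    n_ties = 0
    out = []
    for rid in order:
        if tied[rid]:
            n_ties += 1
            out.append(TaxonAssignment(read_id=rid, taxid=UNCLASSIFIED_TAXID))
        else:
            out.append(best[rid])
    if n_ties:
        logger.info("%d reads had tied best hits and were left unclassified", n_ties)
    return out, n_ties


def _parse_centrifuge(path) -> Iterator[TaxonAssignment]:
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return
        for rownum, row in enumerate(reader, start=2):
            try:
                taxid = int(row["taxID"])
            except (KeyError, ValueError):
                raise ValueError(
                    f"{path}: non-integer or missing taxID at row {rownum}"
                ) from None
            score = float(row["score"]) if row.get("score") else None
            yield TaxonAssignment(read_id=row["readID"], taxid=taxid, score=score)


def _parse_kraken2(path) -> Iterator[TaxonAssignment]:
    with open(path) as fh:
        for rownum, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: too few columns at row {rownum}")
            try:
                taxid = int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer taxid {fields[2]!r} at row {rownum}"
                ) from None
            if fields[0] == "U":
                taxid = UNCLASSIFIED_TAXID
            yield TaxonAssignment(read_id=fields[1], taxid=taxid)


def _parse_plain(path) -> Iterator[TaxonAssignment]:
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return
        for rownum, row in enumerate(reader, start=2):
            try:
                taxid = int(row["taxid"])
            except (KeyError, ValueError):
                raise ValueError(
                    f"{path}: non-integer or missing taxid at row {rownum}"
                ) from None
            score = float(row["score"]) if row.get("score") else None
            yield TaxonAssignment(read_id=row["read_id"], taxid=taxid, score=score)


_DIALECTS = {
    "centrifuge": _parse_centrifuge,
    "kraken2": _parse_kraken2,
    "plain": _parse_plain,
}


def read_classification(
    path: os.PathLike | str, dialect: str = "centrifuge"
) -> list[TaxonAssignment]:
    """Read a per-read classification table and resolve multi-hits.

    Parameters
    ----------
    path:
        TSV in the named dialect.
    dialect:
        One of ``centrifuge`` (header: readID/seqID/taxID/score/...),
        ``kraken2`` (no header: C|U, read_id, taxid, ...) or ``plain``
        (header: read_id, taxid[, score]).
    """
    try:
        parser = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}"
        ) from None
    assignments, _ = resolve_best_hits(parser(path))
    return assignments


def read_lineage_map(path: os.PathLike | str) -> LineageMap:
    """Read a 4-column (taxid, superkingdom, genus, species) TSV with header."""
    out = LineageMap()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            taxid = int(row["taxid"])
            lineage = Lineage(
                taxid=taxid,
                superkingdom=row["superkingdom"],
                genus=row.get("genus") or None,
                species=row.get("species") or None,
            )
            if taxid in out and out[taxid] != lineage:
                raise ValueError(
                    f"{path}: conflicting duplicate rows for taxid {taxid} "
                    f"(row {rownum})"
                )
            out[taxid] = lineage
    return out


def write_lineage_map(lineages: Iterable[Lineage], path: os.PathLike | str) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("taxid\tsuperkingdom\tgenus\tspecies\n")
        for lin in lineages:
            fh.write(
                f"{lin.taxid}\t{lin.superkingdom}\t{lin.genus or ''}\t"
                f"{lin.species or ''}\n"
            )
    return path


def oracle_classify(
    truth_path: os.PathLike | str,
    misclassification_rate: float = 0.0,
    unclassified_rate: float = 0.0,
    seed: Optional[int] = None,
    fastq_ids: Optional[set[str]] = None,
) -> list[TaxonAssignment]:
    """Emit the true taxid for each read of a synthetic truth table.

    Optional corruption: each read is independently left unclassified with
    probability ``unclassified_rate``, else misassigned to a uniformly chosen
    *different* known taxid with probability ``misclassification_rate``.
    """
    read_ids: list[str] = []
    taxids: list[int] = []
    with open(truth_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            read_ids.append(row["read_id"])
            taxids.append(int(row["taxid"]))
    if fastq_ids is not None:
        missing = [rid for rid in read_ids if rid not in fastq_ids]
        if missing:
            logger.warning(
                "%d truth-table reads missing from FASTQ (first: %s)",
                len(missing),
                missing[0],
            )
    assigned = np.asarray(taxids, dtype=np.int64)
    if unclassified_rate > 0 or misclassification_rate > 0:
        rng = np.random.default_rng(seed)
        n = len(assigned)
        universe = np.unique(assigned)
        u = rng.random(n)
        unclassified = u < unclassified_rate
        mis = (~unclassified) & (
            rng.random(n) < misclassification_rate
        )
        if mis.any() and len(universe) > 1:
            # draw a uniformly random *different* taxid
            idx = rng.integers(0, len(universe) - 1, size=int(mis.sum()))
            cur = np.searchsorted(universe, assigned[mis])
            idx[idx >= cur] += 1
            assigned = assigned.copy()
            assigned[mis] = universe[idx]
        if unclassified.any():
            assigned = assigned.copy()
            assigned[unclassified] = UNCLASSIFIED_TAXID
    return [
        TaxonAssignment(read_id=rid, taxid=int(t))
        for rid, t in zip(read_ids, assigned)
    ]
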