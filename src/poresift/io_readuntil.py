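"""FASTQ and adaptive-sampling decision-log I/O and read categorization.

A sequencing run with adaptive sampling produces, besides the basecalled
FASTQ, a decision log (CSV) recording for each evaluated molecule whether the
sequencer kept sequencing it (``stop_receiving``), ejected it from the pore
(``unblock``), or never reached a verdict (``no_decision``).  This module
parses both files, joins them per read, and assigns each read to one of the
categories ``accepted`` / ``rejected`` / ``no_decision`` (or ``control`` for
runs without a decision log).
"""

from __future__ import annotations

import csv
import gzip
import logging
import os
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Decision",
    "Category",
    "ReadRecord",
    "DecisionRecord",
    "CategorizedRead",
    "FastqParseError",
    "DecisionLogError",
    "read_fastq",
    "read_decision_log",
    "categorize",
    "split_by_category",
    "DECISION_SYNONYMS",
    "READ_ID_COLUMNS",
    "DECISION_COLUMNS",
]


class Decision(str, Enum):
    """Verdict emitted by the sequencer for a single molecule."""

    UNBLOCK = "unblock"
    STOP_RECEIVING = "stop_receiving"
    NO_DECISION = "no_decision"


class Category(str, Enum):
    """Final per-read category after joining FASTQ and decision log."""

    ACCEPTED = "accepted"
    REJECTED = "rejected"
    NO_DECISION = "no_decision"
    CONTROL = "control"


#: Versioned synonym table (case-insensitive) for decision-log values.
DECISION_SYNONYMS = {
    "unblock": Decision.UNBLOCK,
    "rejected": Decision.UNBLOCK,
    "stop_receiving": Decision.STOP_RECEIVING,
    "accepted": Decision.STOP_RECEIVING,
    "stop": Decision.STOP_RECEIVING,
    "no_decision": Decision.NO_DECISION,
    "proceed": Decision.NO_DECISION,
    "none": Decision.NO_DECISION,
}

#: Accepted header names for the mandatory columns.
READ_ID_COLUMNS = ("read_id", "read-id", "id")
DECISION_COLUMNS = ("decision", "action", "end_reason")

DECISION_TO_CATEGORY = {
    Decision.UNBLOCK: Category.REJECTED,
    Decision.STOP_RECEIVING: Category.ACCEPTED,
    Decision.NO_DECISION: Category.NO_DECISION,
}


@dataclass
class ReadRecord:
    """One basecalled read; sequence/quality are opaque payloads."""

    read_id: str
    length_bp: int
    sequence: Optional[str] = None
    quality: Optional[str] = None


@dataclass
class DecisionRecord:
    """One decision event from the read-until log."""

    read_id: str
    decision: Decision
    channel: Optional[int] = None
    bp_at_decision: Optional[int] = None


@dataclass
class CategorizedRead:
    """A read joined to its final decision category."""

    read: ReadRecord
    category: Category
    bp_to_decision: Optional[int] = None


class FastqParseError(ValueError):
    pass


class DecisionLogError(ValueError):
    pass


def _open_text(path: os.PathLike | str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: os.PathLike | str) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a (optionally gzipped) FASTQ.

    Raises :class:`FastqParseError` on malformed records (naming the byte
    offset of the offending record) and on duplicate read ids.
    """
    seen: set[str] = set()
    offset = 0
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if header == "":
                return
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: malformed FASTQ header at byte offset {offset}: "
                    f"{header[:60]!r}"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if qual == "":
                raise FastqParseError(
                    f"{path}: truncated FASTQ record (line count not a "
                    f"multiple of 4) at byte offset {offset}"
                )
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: malformed FASTQ separator at byte offset {offset}"
                )
            read_id = header[1:].split(None, 1)[0].strip() if header[1:].strip() else ""
            if not read_id:
                raise FastqParseError(
                    f"{path}: empty read id at byte offset {offset}"
                )
            if read_id in seen:
                raise FastqParseError(f"{path}: duplicate read_id {read_id!r}")
            seen.add(read_id)
            sequence = seq.rstrip("\n")
            yield ReadRecord(
                read_id=read_id,
                length_bp=len(sequence),
                sequence=sequence,
                quality=qual.rstrip("\n"),
            )
            offset += len(header) + len(seq) + len(plus) + len(qual)


def _find_column(fieldnames: Iterable[str], candidates: tuple[str, ...]) -> Optional[str]:
    lowered = {name.strip().lower(): name for name in fieldnames}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def read_decision_log(path: os.PathLike | str) -> Iterator[DecisionRecord]:
    """Stream normalized :class:`DecisionRecord` objects from a read-until CSV.

    Header names and decision-value synonyms follow the versioned tables
    :data:`READ_ID_COLUMNS`, :data:`DECISION_COLUMNS` and
    :data:`DECISION_SYNONYMS`.  Unknown extra columns are ignored.
    """
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        id_col = _find_column(reader.fieldnames, READ_ID_COLUMNS)
        dec_col = _find_column(reader.fieldnames, DECISION_COLUMNS)
        if id_col is None:
            raise DecisionLogError(
                f"{path}: missing read-id column (accepted names: "
                f"{', '.join(READ_ID_COLUMNS)})"
            )
        if dec_col is None:
            raise DecisionLogError(
                f"{path}: missing decision column (accepted names: "
                f"{', '.join(DECISION_COLUMNS)})"
            )
        chan_col = _find_column(reader.fieldnames, ("channel",))
        bp_col = _find_column(reader.fieldnames, ("sequence_length",))
        for rownum, row in enumerate(reader, start=2):
            raw = (row[dec_col] or "").strip().lower()
            try:
                decision = DECISION_SYNONYMS[raw]
            except KeyError:
                raise DecisionLogError(
                    f"{path}: unrecognized decision value {row[dec_col]!r} "
                    f"at row {rownum}"
                ) from None
            channel = None
            if chan_col and row.get(chan_col, "").strip():
                channel = int(row[chan_col])
            bp = None
            if bp_col and row.get(bp_col, "").strip():
                bp = int(row[bp_col])
            yield DecisionRecord(
                read_id=row[id_col].strip(),
                decision=decision,
                channel=channel,
                bp_at_decision=bp,
            )


def categorize(
    reads: Iterable[ReadRecord],
    decisions: Optional[Iterable[DecisionRecord]] = None,
) -> list[CategorizedRead]:
    """Join reads with their decision records and assign categories.

    With ``decisions=None`` every read is categorized ``control``.  Otherwise
    the LAST decision record per read (in log order) determines the category:
    ``unblock`` -> rejected, ``stop_receiving`` -> accepted, ``no_decision``
    -> no_decision.  Reads absent from the log are classed ``no_decision``
    (warning logged with a count); log records without a matching read are
    counted and dropped.
    """
    if decisions is None:
        return [CategorizedRead(read=r, category=Category.CONTROL) for r in reads]

    last: dict[str, DecisionRecord] = {}
    for rec in decisions:
        last[rec.read_id] = rec  # later rows overwrite: final decision wins

    out: list[CategorizedRead] = []
    missing_from_log = 0
    matched_ids: set[str] = set()
    for read in reads:
        rec = last.get(read.read_id)
        if rec is None:
            missing_from_log += 1
            out.append(CategorizedRead(read=read, category=Category.NO_DECISION))
            continue
        matched_ids.add(read.read_id)
        out.append(
            CategorizedRead(
                read=read,
                category=DECISION_TO_CATEGORY[rec.decision],
                bp_to_decision=rec.bp_at_decision,
            )
        )
    unmatched_log = len(last) - len(matched_ids)
    if missing_from_log:
        logger.warning(
            "%d reads absent from the decision log were classed 'no_decision'",
            missing_from_log,
        )
    if unmatched_log:
        logger.warning(
            "%d decision-log records had no matching read and were dropped",
            unmatched_log,
        )
    return out


def split_by_category(
    reads: list[CategorizedRead], outdir: os.PathLike | str
) -> dict[str, Path]:
    """Write one FASTQ per non-empty category plus a 3-column sidecar TSV.

    Returns a mapping of artifact name (category or ``"categories"``) to
    path.  Requires sequence payloads to be present on every read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handles: dict[Category, IO[str]] = {}
    paths: dict[str, Path] = {}
    tsv_path = outdir / "categories.tsv"
    try:
        with open(tsv_path, "w", newline="") as tsv:
            tsv.write("read_id\tcategory\tbp_to_decision\n")
            for cr in reads:
                if cr.read.sequence is None:
                    raise ValueError(
                        f"read {cr.read.read_id} has no sequence payload; "
                        "cannot write FASTQ"
                    )
                cat = cr.category
                if cat not in handles:
                    path = outdir / f"{cat.value}.fastq"
                    handles[cat] = open(path, "w")
                    paths[cat.value] = path
                qual = cr.read.quality if cr.read.quality is not None else "I" * cr.read.length_bp
                handles[cat].write(
                    f"@{cr.read.read_id}\n{cr.read.sequence}\n+\n{qual}\n"
                )
                bp = "" if cr.bp_to_decision is None else str(cr.bp_to_decision)
                tsv.write(f"{cr.read.read_id}\t{cat.value}\t{bp}\n")
    finally:
        for fh in handles.values():
            fh.close()
    paths["categories"] = tsv_path
    return paths
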