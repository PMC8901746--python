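"""Synthetic adaptive-sampling run generator.

Generates desk-scale sequencing runs (FASTQ + decision CSV + truth TSV, and
PAF for mock-community fixtures) with the statistical structure the analysis
pipeline assumes: a host/bacterial read mixture, the three-way decision
process, truncated rejected reads, and paired control/depletion cohorts with
deterministic per-sample parameter variation.

Two generation modes exist:

* direct category/composition draws (:func:`draw_run`) — fast, used for
  parameter-recovery checks;
* a pore-time mechanistic mode (:func:`draw_run_duration`) in which a fixed
  run duration is filled read by read, so rejection frees pore time and the
  emitted read count grows — used for qualitative yield properties only.

Sequences are random nucleotides; truth lives only in the sidecar TSV, and
read ids carry no class information.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .classification import Lineage, write_lineage_map

__all__ = [
    "Taxon",
    "TAXA",
    "BoundedDist",
    "PoreTimeModel",
    "SimPreset",
    "RunDraw",
    "SimRun",
    "PRESETS",
    "get_preset",
    "preset_names",
    "quantile_spread",
    "cohort15_parameters",
    "build_cohort_presets",
    "draw_run",
    "draw_run_duration",
    "simulate_run",
    "simulate_cohort",
    "simulate_cohort_sample",
    "simulate_mock",
    "COHORT15_PARAMS",
]


@dataclass(frozen=True)
class Taxon:
    label: str
    taxid: int
    superkingdom: str
    genus: Optional[str]
    species: Optional[str]

    @property
    def truth_class(self) -> str:
        if self.species == "Homo sapiens":
            return "human"
        if self.superkingdom == "Bacteria":
            return f"bacterial:{self.genus}"
        return "other"


#: Tiny illustrative taxonomy used by all synthetic runs.  Human detection
#: downstream is keyed on lineage, so these taxids are arbitrary labels.
TAXA: dict[str, Taxon] = {
    t.label: t
    for t in [
        Taxon("human", 9606, "Eukaryota", "Homo", "Homo sapiens"),
        Taxon("Gardnerella", 2702, "Bacteria", "Gardnerella", "Gardnerella vaginalis"),
        Taxon("Lactobacillus", 1578, "Bacteria", "Lactobacillus", "Lactobacillus iners"),
        Taxon("Ureaplasma", 2129, "Bacteria", "Ureaplasma", "Ureaplasma parvum"),
        Taxon("Prevotella", 838, "Bacteria", "Prevotella", "Prevotella intermedia"),
    ]
}

#: Default share of the bacterial remainder per genus (illustrative values,
#: never used as recovery targets).
GENUS_WEIGHTS: dict[str, float] = {
    "Gardnerella": 0.40,
    "Lactobacillus": 0.35,
    "Ureaplasma": 0.15,
    "Prevotella": 0.10,
}


def _mix(human_fraction: float, genus_weights: Optional[Mapping[str, float]] = None) -> dict[str, float]:
    """Composition dict: given human fraction, split the rest over genera."""
    weights = dict(genus_weights or GENUS_WEIGHTS)
    total_w = sum(weights.values())
    rest = 1.0 - human_fraction
    mix = {"human": human_fraction}
    for label, w in weights.items():
        mix[label] = rest * w / total_w
    return mix


@dataclass(frozen=True)
class BoundedDist:
    """Bounded distribution parameterized by (min, max, median).

    Sampled as a two-piece uniform: with probability 1/2 uniform on
    [lo, median], else uniform on [median, hi] — bounds and median are exact.
    """

    lo: float
    hi: float
    median: float

    def __post_init__(self):
        if not (self.lo <= self.median <= self.hi):
            raise ValueError(
                f"BoundedDist requires lo <= median <= hi, got {self}"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        upper = rng.random(n) < 0.5
        u = rng.random(n)
        out = np.where(
            upper,
            self.median + u * (self.hi - self.median),
            self.lo + u * (self.median - self.lo),
        )
        return out


@dataclass(frozen=True)
class PoreTimeModel:
    """Pore occupancy model for duration-based generation."""

    speed_bp_s: float = 450.0
    capture_s: float = 1.0
    unblock_s: float = 0.5


CATEGORIES = ("rejected", "accepted", "no_decision")


@dataclass
class SimPreset:
    """Fully parameterized scenario for the generator.

    Either ``category_probs`` + ``category_composition`` (direct mode), or
    ``composition`` + ``per_class_decision`` (class-conditional mode), or
    ``composition`` alone (control run: no decision log).
    """

    name: str
    composition: Optional[dict[str, float]] = None
    category_probs: Optional[dict[str, float]] = None
    category_composition: Optional[dict[str, dict[str, float]]] = None
    per_class_decision: Optional[dict[str, dict[str, float]]] = None
    bp_to_decision: dict[str, BoundedDist] = field(
        default_factory=lambda: {
            "rejected": BoundedDist(400, 800, 600),
            "accepted": BoundedDist(3000, 5000, 4000),
        }
    )
    read_length_median: float = 2500.0
    read_length_sigma: float = 0.55
    pore_time: Optional[PoreTimeModel] = None

    @property
    def has_decision_log(self) -> bool:
        return self.category_probs is not None or self.per_class_decision is not None

    def validate(self) -> None:
        def check_probs(name: str, probs: Mapping[str, float], labels=None):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"{self.name}: {name} sums to {total}, not 1")
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{self.name}: {name}[{key}]={p} not in [0,1]")
                if labels is not None and key not in labels:
                    raise ValueError(f"{self.name}: unknown key {key!r} in {name}")

        if self.category_probs is not None:
            check_probs("category_probs", self.category_probs, CATEGORIES)
            if self.category_composition is None:
                raise ValueError(
                    f"{self.name}: category_probs requires category_composition"
                )
            for cat, comp in self.category_composition.items():
                check_probs(f"category_composition[{cat}]", comp, TAXA)
        elif self.per_class_decision is not None:
            if self.composition is None:
                raise ValueError(
                    f"{self.name}: per_class_decision requires composition"
                )
            check_probs("composition", self.composition, TAXA)
            for label, probs in self.per_class_decision.items():
                check_probs(f"per_class_decision[{label}]", probs, CATEGORIES)
        else:
            if self.composition is None:
                raise ValueError(f"{self.name}: composition required")
            check_probs("composition", self.composition, TAXA)
        if self.read_length_median <= 0 or self.read_length_sigma < 0:
            raise ValueError(f"{self.name}: invalid read-length distribution")


@dataclass
class RunDraw:
    """In-memory realization of one run (arrays aligned by read index)."""

    preset_name: str
    labels: np.ndarray  # class label per read (str)
    taxids: np.ndarray  # int
    categories: np.ndarray  # str: rejected/accepted/no_decision/control
    full_length: np.ndarray  # int, pre-truncation length
    emitted_length: np.ndarray  # int, length present in the FASTQ
    bp_to_decision: np.ndarray  # float, NaN where no decision bp applies
    has_decision_log: bool

    @property
    def n_reads(self) -> int:
        return len(self.labels)

    def category_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.categories, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


@dataclass
class SimRun:
    run_id: str
    preset_name: str
    seed: int
    paths: dict[str, Path]
    n_reads: int
    category_counts: dict[str, int]


def _draw_lengths(preset: SimPreset, n: int, rng: np.random.Generator) -> np.ndarray:
    lengths = rng.lognormal(
        mean=math.log(preset.read_length_median), sigma=preset.read_length_sigma, size=n
    )
    return np.maximum(np.rint(lengths).astype(np.int64), 1)


def _draw_categorical(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.asarray(keys, dtype=object)[idx]


def draw_run(preset: SimPreset, n_reads: int, rng: np.random.Generator) -> RunDraw:
    """Draw one run in memory (no files)."""
    preset.validate()
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")

    if preset.category_probs is not None:
        categories = _draw_categorical(rng, preset.category_probs, n_reads)
        labels = np.empty(n_reads, dtype=object)
        for cat in CATEGORIES:
            mask = categories == cat
            n_cat = int(mask.sum())
            if n_cat:
                labels[mask] = _draw_categorical(
                    rng, preset.category_composition[cat], n_cat
                )
    elif preset.per_class_decision is not None:
        labels = _draw_categorical(rng, preset.composition, n_reads)
        categories = np.empty(n_reads, dtype=object)
        for label, probs in preset.per_class_decision.items():
            mask = labels == label
            n_cls = int(mask.sum())
            if n_cls:
                categories[mask] = _draw_categorical(rng, probs, n_cls)
    else:
        labels = _draw_categorical(rng, preset.composition, n_reads)
        categories = np.full(n_reads, "control", dtype=object)

    full_length = _draw_lengths(preset, n_reads, rng)
    emitted = full_length.copy()
    bp = np.full(n_reads, np.nan)

    rejected = categories == "rejected"
    if rejected.any():
        dist = preset.bp_to_decision["rejected"]
        draws = np.rint(dist.sample(rng, int(rejected.sum()))).astype(np.int64)
        # a rejected read is truncated at the decision point; it can never be
        # longer than the molecule itself
        truncated = np.minimum(draws, full_length[rejected])
        emitted[rejected] = truncated
        bp[rejected] = truncated

    accepted = categories == "accepted"
    if accepted.any() and "accepted" in preset.bp_to_decision:
        dist = preset.bp_to_decision["accepted"]
        draws = np.rint(dist.sample(rng, int(accepted.sum()))).astype(np.int64)
        bp[accepted] = np.minimum(draws, full_length[accepted])

    taxids = np.asarray([TAXA[label].taxid for label in labels], dtype=np.int64)
    return RunDraw(
        preset_name=preset.name,
        labels=labels,
        taxids=taxids,
        categories=categories,
        full_length=full_length,
        emitted_length=emitted,
        bp_to_decision=bp,
        has_decision_log=preset.has_decision_log,
    )


def draw_run_duration(
    preset: SimPreset,
    duration_s: float,
    rng: np.random.Generator,
    batch: int = 10_000,
) -> RunDraw:
    """Fill a fixed run duration read by read (pore-time mechanistic mode).

    Each read occupies ``capture_s + emitted_length/speed`` seconds of pore
    time, plus ``unblock_s`` when rejected.  Rejection therefore frees pore
    time and increases the emitted read count for the same duration.
    """
    if preset.pore_time is None:
        raise ValueError(f"{preset.name}: pore_time model not configured")
    pt = preset.pore_time
    draws: list[RunDraw] = []
    elapsed = 0.0
    total = 0
    while elapsed < duration_s:
        d = draw_run(preset, batch, rng)
        per_read = (
            pt.capture_s
            + d.emitted_length / pt.speed_bp_s
            + np.where(d.categories == "rejected", pt.unblock_s, 0.0)
        )
        cum = elapsed + np.cumsum(per_read)
        n_fit = int(np.searchsorted(cum, duration_s, side="right"))
        if n_fit < batch:
            draws.append(_slice_draw(d, n_fit))
            total += n_fit
            break
        draws.append(d)
        total += batch
        elapsed = float(cum[-1])
    return _concat_draws(draws, preset)


def _slice_draw(d: RunDraw, n: int) -> RunDraw:
    return RunDraw(
        preset_name=d.preset_name,
        labels=d.labels[:n],
        taxids=d.taxids[:n],
        categories=d.categories[:n],
        full_length=d.full_length[:n],
        emitted_length=d.emitted_length[:n],
        bp_to_decision=d.bp_to_decision[:n],
        has_decision_log=d.has_decision_log,
    )


def _concat_draws(draws: Sequence[RunDraw], preset: SimPreset) -> RunDraw:
    if not draws:
        empty = np.asarray([], dtype=object)
        return RunDraw(
            preset_name=preset.name,
            labels=empty,
            taxids=np.asarray([], dtype=np.int64),
            categories=empty.copy(),
            full_length=np.asarray([], dtype=np.int64),
            emitted_length=np.asarray([], dtype=np.int64),
            bp_to_decision=np.asarray([], dtype=float),
            has_decision_log=preset.has_decision_log,
        )
    return RunDraw(
        preset_name=preset.name,
        labels=np.concatenate([d.labels for d in draws]),
        taxids=np.concatenate([d.taxids for d in draws]),
        categories=np.concatenate([d.categories for d in draws]),
        full_length=np.concatenate([d.full_length for d in draws]),
        emitted_length=np.concatenate([d.emitted_length for d in draws]),
        bp_to_decision=np.concatenate([d.bp_to_decision for d in draws]),
        has_decision_log=draws[0].has_decision_log,
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _write_fastq(
    path: Path,
    read_ids: Sequence[str],
    lengths: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> None:
    with open(path, "wb") as fh:
        for start in range(0, len(read_ids), chunk):
            ls = lengths[start : start + chunk]
            total = int(ls.sum())
            seq_bytes = _BASES[rng.integers(0, 4, total, dtype=np.uint8)].tobytes()
            parts = []
            offset = 0
            for rid, length in zip(read_ids[start : start + chunk], ls):
                length = int(length)
                seq = seq_bytes[offset : offset + length]
                offset += length
                parts.append(
                    b"@%s\n%s\n+\n%s\n" % (rid.encode(), seq, b"I" * length)
                )
            fh.write(b"".join(parts))


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def simulate_run(
    preset: SimPreset,
    n_reads: int,
    seed: int,
    outdir: os.PathLike | str,
    run_id: str = "run",
    duration_s: Optional[float] = None,
) -> SimRun:
    """Materialize one run: FASTQ, decision CSV (if any), truth TSV, lineage
    map and a manifest JSON with checksums.

    ``duration_s`` switches to the pore-time mechanistic mode (``n_reads``
    is then ignored).
    """
    preset.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if duration_s is not None:
        draw = draw_run_duration(preset, duration_s, rng)
    else:
        draw = draw_run(preset, n_reads, rng)

    n = draw.n_reads
    read_ids = [f"{run_id}-{i:08d}" for i in range(n)]
    paths: dict[str, Path] = {}

    fastq = outdir / f"{run_id}.fastq"
    _write_fastq(fastq, read_ids, draw.emitted_length, rng)
    paths["fastq"] = fastq

    if draw.has_decision_log:
        decisions = outdir / f"{run_id}.read_until.csv"
        decision_of = {
            "rejected": "unblock",
            "accepted": "stop_receiving",
            "no_decision": "no_decision",
        }
        channels = rng.integers(1, 513, size=n)
        with open(decisions, "w", newline="") as fh:
            fh.write("read_id,channel,decision,sequence_length\n")
            for rid, chan, cat, bp in zip(
                read_ids, channels, draw.categories, draw.bp_to_decision
            ):
                bp_s = "" if math.isnan(bp) else str(int(bp))
                fh.write(f"{rid},{chan},{decision_of[cat]},{bp_s}\n")
        paths["decisions"] = decisions

    truth = outdir / f"{run_id}.truth.tsv"
    with open(truth, "w", newline="") as fh:
        fh.write("read_id\ttaxid\tclass\tcategory\tbp_to_decision\tfull_length\n")
        for rid, label, taxid, cat, bp, full in zip(
            read_ids,
            draw.labels,
            draw.taxids,
            draw.categories,
            draw.bp_to_decision,
            draw.full_length,
        ):
            bp_s = "" if math.isnan(bp) else str(int(bp))
            fh.write(
                f"{rid}\t{taxid}\t{TAXA[label].truth_class}\t{cat}\t{bp_s}\t{full}\n"
            )
    paths["truth"] = truth

    lineage = outdir / "lineage.tsv"
    write_lineage_map(
        [
            Lineage(t.taxid, t.superkingdom, t.genus, t.species)
            for t in TAXA.values()
        ],
        lineage,
    )
    paths["lineage"] = lineage

    manifest = outdir / f"{run_id}.manifest.json"
    with open(manifest, "w") as fh:
        json.dump(
            {
                "preset": preset.name,
                "run_id": run_id,
                "seed": int(seed),
                "n_reads": n,
                "category_counts": draw.category_counts(),
                "rng": "numpy.random.default_rng (PCG64)",
                "checksums": {k: _checksum(p) for k, p in paths.items()},
            },
            fh,
            indent=2,
        )
    paths["manifest"] = manifest
    return SimRun(
        run_id=run_id,
        preset_name=preset.name,
        seed=int(seed),
        paths=paths,
        n_reads=n,
        category_counts=draw.category_counts(),
    )


# --------------------------------------------------------------------------
# Named presets
# --------------------------------------------------------------------------

#: Human fraction of the single-sample control run.
CONTROL_HUMAN_FRACTION = 0.8793
#: Single-sample depletion run: rejection probability and per-fraction
#: human content.
DEPLETION_REJECTED_P = 0.8101
DEPLETION_KEPT_HUMAN = 0.3473
DEPLETION_REJECTED_HUMAN = 0.998
#: Share of kept (non-rejected) reads that get an explicit accept decision;
#: most kept reads end in the no_decision category.
ACCEPTED_SHARE_OF_KEPT = 0.041
#: Single-sample enrichment run.
ENRICHMENT_REJECTED_P = 0.9593
ENRICHMENT_KEPT_HUMAN = 0.0829
ENRICHMENT_REJECTED_MIX = {
    "Gardnerella": 0.0548,
    "Lactobacillus": 0.0241,
    "Prevotella": 0.0220,  # "other microbial"
}


def _single_sample_control() -> SimPreset:
    return SimPreset(
        name="single_sample_control",
        composition=_mix(CONTROL_HUMAN_FRACTION),
    )


def _depletion_category_probs(
    rejected_p: float, accepted_share: float = ACCEPTED_SHARE_OF_KEPT
) -> dict[str, float]:
    kept = 1.0 - rejected_p
    return {
        "rejected": rejected_p,
        "accepted": kept * accepted_share,
        "no_decision": kept * (1.0 - accepted_share),
    }


def _single_sample_depletion() -> SimPreset:
    kept_mix = _mix(DEPLETION_KEPT_HUMAN)
    return SimPreset(
        name="single_sample_depletion",
        category_probs=_depletion_category_probs(DEPLETION_REJECTED_P),
        category_composition={
            "rejected": _mix(DEPLETION_REJECTED_HUMAN),
            "accepted": dict(kept_mix),
            "no_decision": dict(kept_mix),
        },
        bp_to_decision={
            "rejected": BoundedDist(400, 800, 600),
            "accepted": BoundedDist(3000, 5000, 4000),
        },
    )


def _single_sample_enrichment() -> SimPreset:
    kept_mix = _mix(ENRICHMENT_KEPT_HUMAN)
    rejected_mix = dict(ENRICHMENT_REJECTED_MIX)
    rejected_mix["Ureaplasma"] = 0.0
    rejected_mix["human"] = 1.0 - sum(rejected_mix.values())
    kept = 1.0 - ENRICHMENT_REJECTED_P
    return SimPreset(
        name="single_sample_enrichment",
        category_probs={
            "rejected": ENRICHMENT_REJECTED_P,
            # the enrichment protocol actively accepts targets, so the kept
            # fraction splits evenly between explicit accepts and no_decision
            "accepted": kept * 0.5,
            "no_decision": kept * 0.5,
        },
        category_composition={
            "rejected": rejected_mix,
            "accepted": dict(kept_mix),
            "no_decision": dict(kept_mix),
        },
        bp_to_decision={
            "rejected": BoundedDist(400, 800, 600),
            "accepted": BoundedDist(400, 800, 500),
        },
    )


PRESETS = {
    "single_sample_control": _single_sample_control,
    "single_sample_depletion": _single_sample_depletion,
    "single_sample_enrichment": _single_sample_enrichment,
}


def preset_names() -> list[str]:
    return sorted(PRESETS) + ["cohort15"]


def get_preset(name: str) -> SimPreset:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(preset_names())}"
        ) from None


# --------------------------------------------------------------------------
# Cohort construction
# --------------------------------------------------------------------------

#: (mean, sd, lower bound, upper bound) of the deterministic per-sample
#: parameter spreads of the 15-sample paired cohort.
COHORT15_PARAMS = {
    "control_human_pct": (97.59, 7.63, 0.0, 100.0),
    "rejected_pct": (92.05, 7.42, 0.0, 100.0),
    "rejected_human_pct": (99.80, 0.09, 0.0, 100.0),
    "read_fold": (1.70, 0.27, 0.0, None),
}

#: Human content of the kept depletion fractions (cohort defaults).
COHORT_NO_DECISION_HUMAN = 0.2506
COHORT_ACCEPTED_HUMAN = 0.0123


def quantile_spread(
    m: float,
    s: float,
    n: int = 15,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Deterministic n-point spread with mean exactly m and spread s.

    Values are the symmetric standard-normal quantiles at p=(i-0.5)/n scaled
    by s, clipped to [lo, hi]; non-clipped values are then shifted so the
    arithmetic mean equals m exactly (iterating when the shift pushes more
    values against a bound).
    """
    p = (np.arange(1, n + 1) - 0.5) / n
    vals = m + s * stats.norm.ppf(p)
    lo_v = -np.inf if lo is None else lo
    hi_v = np.inf if hi is None else hi
    pinned = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        out_of_range = (vals < lo_v) | (vals > hi_v)
        vals = np.clip(vals, lo_v, hi_v)
        pinned |= out_of_range
        free = ~pinned
        if not free.any():
            break
        delta = (m * n - vals.sum()) / free.sum()
        if abs(delta) < 1e-12:
            break
        vals[free] += delta
    return vals


def cohort15_parameters() -> list[dict[str, float]]:
    """Per-sample deterministic parameter sets of the 15-sample cohort."""
    spreads = {
        key: quantile_spread(m, s, n=15, lo=lo, hi=hi)
        for key, (m, s, lo, hi) in COHORT15_PARAMS.items()
    }
    return [
        {key: float(spreads[key][i]) for key in spreads} | {"sample_index": i + 1}
        for i in range(15)
    ]


def build_cohort_presets(
    n_reads: int,
) -> list[tuple[str, SimPreset, int, SimPreset, int]]:
    """Build (sample_id, control preset, n_control, depletion preset,
    n_depletion) for each of the 15 cohort samples.

    Control and depletion of a sample share the same bacterial genus mix;
    the depletion read count encodes the sample's read-count fold (rejected
    reads included).
    """
    out = []
    for params in cohort15_parameters():
        i = int(params["sample_index"])
        sid = f"sample_{i:02d}"
        h = params["control_human_pct"] / 100.0
        r = params["rejected_pct"] / 100.0
        rh = params["rejected_human_pct"] / 100.0
        control = SimPreset(
            name=f"cohort15_control_{i:02d}", composition=_mix(h)
        )
        depletion = SimPreset(
            name=f"cohort15_depletion_{i:02d}",
            category_probs=_depletion_category_probs(r),
            category_composition={
                "rejected": _mix(rh),
                "accepted": _mix(COHORT_ACCEPTED_HUMAN),
                "no_decision": _mix(COHORT_NO_DECISION_HUMAN),
            },
            bp_to_decision={
                "rejected": BoundedDist(400, 800, 600),
                "accepted": BoundedDist(3000, 5000, 4000),
            },
        )
        n_dep = max(1, int(round(params["read_fold"] * n_reads)))
        out.append((sid, control, n_reads, depletion, n_dep))
    return out


@dataclass
class CohortSim:
    outdir: Path
    samples: list[dict[str, object]]  # sample_id, control: SimRun, depletion: SimRun


def simulate_cohort_sample(
    index: int, n_reads: int, seed: int, outdir: os.PathLike | str
) -> tuple[str, SimRun, SimRun]:
    """Materialize one cohort sample pair (``index`` is 0-based).

    Seeding is derived from the cohort seed so that generating samples one
    at a time is byte-identical to :func:`simulate_cohort`.
    """
    if not 0 <= index < 15:
        raise ValueError("cohort sample index must be in [0, 15)")
    outdir = Path(outdir)
    sid, control, n_ctrl, depletion, n_dep = build_cohort_presets(n_reads)[index]
    child = np.random.SeedSequence(seed).spawn(15)[index].spawn(2)
    ctrl_run = simulate_run(
        control,
        n_ctrl,
        seed=int(child[0].generate_state(1)[0]),
        outdir=outdir / sid / "control",
        run_id=f"{sid}_control",
    )
    dep_run = simulate_run(
        depletion,
        n_dep,
        seed=int(child[1].generate_state(1)[0]),
        outdir=outdir / sid / "depletion",
        run_id=f"{sid}_depletion",
    )
    return sid, ctrl_run, dep_run


def write_cohort_params(outdir: os.PathLike | str) -> Path:
    params = cohort15_parameters()
    path = Path(outdir) / "cohort_params.tsv"
    with open(path, "w", newline="") as fh:
        keys = [k for k in params[0] if k != "sample_index"]
        fh.write("sample\t" + "\t".join(keys) + "\n")
        for p in params:
            fh.write(
                f"sample_{int(p['sample_index']):02d}\t"
                + "\t".join(f"{p[k]:.6f}" for k in keys)
                + "\n"
            )
    return path


def simulate_cohort(
    n_reads: int, seed: int, outdir: os.PathLike | str
) -> CohortSim:
    """Materialize the 15 paired control/depletion cohort runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort_params(outdir)
    samples = []
    for index in range(15):
        sid, ctrl_run, dep_run = simulate_cohort_sample(index, n_reads, seed, outdir)
        samples.append({"sample_id": sid, "control": ctrl_run, "depletion": dep_run})
    return CohortSim(outdir=outdir, samples=samples)


# --------------------------------------------------------------------------
# Mock community fixtures
# --------------------------------------------------------------------------

def simulate_mock(
    expected: Mapping[str, float],
    bias: Optional[Mapping[str, float]],
    n_reads: int,
    seed: int,
    outdir: os.PathLike | str,
    run_id: str = "mock",
    read_length_median: float = 2500.0,
    read_length_sigma: float = 0.55,
) -> dict[str, Path]:
    """Generate a mock-community PAF + truth TSV.

    Per-read organism is drawn proportional to ``expected * bias`` (organisms
    absent from the bias map default to 1.0); each read gets one primary PAF
    record whose block length follows the read-length distribution.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    bias = bias or {}
    organisms = sorted(expected)
    weights = np.asarray(
        [expected[o] * bias.get(o, 1.0) for o in organisms], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("expected*bias has zero total mass")
    probs = weights / weights.sum()
    picks = rng.choice(len(organisms), size=n_reads, p=probs)
    lengths = np.maximum(
        np.rint(
            rng.lognormal(math.log(read_length_median), read_length_sigma, n_reads)
        ).astype(np.int64),
        50,
    )
    paf = outdir / f"{run_id}.paf"
    truth = outdir / f"{run_id}.truth.tsv"
    tlen = 5_000_000
    with open(paf, "w") as pf, open(truth, "w", newline="") as tf:
        tf.write("read_id\torganism\tblock_length\n")
        for i, (pick, length) in enumerate(zip(picks, lengths)):
            organism = organisms[int(pick)]
            rid = f"{run_id}-{i:08d}"
            length = int(length)
            matches = int(round(length * 0.95))
            pf.write(
                f"{rid}\t{length}\t0\t{length}\t+\t{organism}\t{tlen}\t0\t"
                f"{length}\t{matches}\t{length}\t60\ttp:A:P\n"
            )
            tf.write(f"{rid}\t{organism}\t{length}\n")
    return {"paf": paf, "truth": truth}
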