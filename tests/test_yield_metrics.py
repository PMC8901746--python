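import math

import numpy as np
import pytest

from poresift import synthetic_data as synth
from poresift.classification import TaxonAssignment
from poresift.composition import CategoryContent, category_content
from poresift.io_readuntil import Category
from poresift.yield_metrics import (
    cohort_summary,
    decision_length_distribution,
    fold_change,
    summarize_run,
)

from conftest import make_categorized


def _assign(reads, taxid):
    return [TaxonAssignment(cr.read.read_id, taxid) for cr in reads]


class TestFoldChange:
    def test_enrichment_over_depletion(self):
        # printed read counts: 5.67e6 vs 3.79e6
        assert round(fold_change(5.67e6, 3.79e6), 2) == 1.50

    def test_depletion_over_control(self):
        assert round(fold_change(3.79e6, 2.73e6), 2) == 1.39

    def test_identity(self):
        assert fold_change(123.0, 123.0) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(1.0, 0.0)

    def test_run_summary_field(self, lineage_map):
        reads = [make_categorized(f"r{i}", Category.CONTROL) for i in range(10)]
        s = summarize_run(reads)
        assert fold_change(s, s, "total_reads") == 1.0


class TestSummarizeRun:
    def test_empty_run_errors(self):
        with pytest.raises(ValueError, match="empty run"):
            summarize_run([])

    def test_zero_rejected(self):
        reads = [make_categorized(f"r{i}", Category.CONTROL, 100) for i in range(4)]
        s = summarize_run(reads)
        assert s.rejected_pct == 0.0
        assert s.total_bases == 400
        assert s.median_read_length["overall"] == 100

    def test_microbial_bases_kept_fractions_only(self, lineage_map):
        # bacterial read in 'rejected' must NOT count; kept bacterial does
        reads = [
            make_categorized("acc", Category.ACCEPTED, 1000),
            make_categorized("nd", Category.NO_DECISION, 500),
            make_categorized("rej", Category.REJECTED, 700),
            make_categorized("hum", Category.ACCEPTED, 900),
        ]
        assignments = [
            TaxonAssignment("acc", 1578),   # Lactobacillus
            TaxonAssignment("nd", 2702),    # Gardnerella
            TaxonAssignment("rej", 1578),   # bacterial but rejected
            TaxonAssignment("hum", 9606),
        ]
        s = summarize_run(reads, assignments, lineage_map)
        assert s.microbial_bases == 1500
        assert s.microbial_bases <= s.total_bases
        assert s.rejected_reads == 1
        assert s.rejected_pct == 25.0

    def test_microbial_policy_non_human(self, lineage_map):
        reads = [
            make_categorized("euk", Category.ACCEPTED, 300),
            make_categorized("hum", Category.ACCEPTED, 400),
        ]
        # a non-human eukaryote counts only under the widened policy
        from poresift.classification import Lineage, LineageMap

        lm = LineageMap(lineage_map)
        lm[4932] = Lineage(4932, "Eukaryota", "Saccharomyces", "S. cerevisiae")
        assignments = [TaxonAssignment("euk", 4932), TaxonAssignment("hum", 9606)]
        narrow = summarize_run(reads, assignments, lm)
        wide = summarize_run(reads, assignments, lm,
                             microbial_policy="non_human_classified")
        assert narrow.microbial_bases == 0
        assert wide.microbial_bases == 300

    def test_category_conservation(self):
        reads = (
            [make_categorized(f"a{i}", Category.ACCEPTED) for i in range(3)]
            + [make_categorized(f"r{i}", Category.REJECTED) for i in range(5)]
            + [make_categorized(f"n{i}", Category.NO_DECISION) for i in range(2)]
        )
        s = summarize_run(reads)
        assert s.accepted_reads + s.rejected_reads + s.no_decision_reads == s.total_reads

    @pytest.mark.parametrize("n", [10_000, 100_000])
    def test_rejected_pct_converges_to_preset(self, n):
        # binomial oracle on the preset rejection probability
        preset = synth.get_preset("single_sample_depletion")
        rng = np.random.default_rng(1)
        draw = synth.draw_run(preset, n, rng)
        p = synth.DEPLETION_REJECTED_P
        observed = (draw.categories == "rejected").mean()
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * sd


class TestDecisionLengthDistribution:
    def test_single_read_all_quantiles_equal(self):
        reads = [make_categorized("r", Category.REJECTED, 600, bp_to_decision=500)]
        out = decision_length_distribution(reads)
        assert set(out["rejected"].quantiles.values()) == {500.0}

    def test_rejected_bounds_from_synthetic_default(self):
        preset = synth.get_preset("single_sample_depletion")
        draw = synth.draw_run(preset, 5000, np.random.default_rng(2))
        reads = [
            make_categorized(f"r{i}", Category.REJECTED, int(l), bp_to_decision=int(b))
            for i, (l, b) in enumerate(
                zip(
                    draw.emitted_length[draw.categories == "rejected"],
                    draw.bp_to_decision[draw.categories == "rejected"],
                )
            )
        ]
        out = decision_length_distribution(reads)["rejected"]
        assert out.quantiles["p5"] >= 400
        assert out.quantiles["p95"] <= 800
        qs = [out.quantiles[k] for k in ("p5", "p25", "p50", "p75", "p95")]
        assert qs == sorted(qs)

    def test_median_order_statistic_oracle(self):
        # uniform integers on 1..1000: the sample median's SE is
        # 1/(2 f sqrt(n)) = 500/sqrt(n); check p50 within 3 SE of 500
        n = 10_000
        rng = np.random.default_rng(3)
        values = rng.integers(1, 1001, n)
        reads = [
            make_categorized(f"r{i}", Category.REJECTED, 2000, bp_to_decision=int(v))
            for i, v in enumerate(values)
        ]
        out = decision_length_distribution(reads)["rejected"]
        se = 500 / math.sqrt(n)
        assert abs(out.quantiles["p50"] - 500) < 3 * se

    def test_length_proxy_flagged(self):
        reads = [make_categorized(f"r{i}", Category.REJECTED, 650) for i in range(10)]
        out = decision_length_distribution(reads)["rejected"]
        assert out.used_length_proxy
        assert out.quantiles["p50"] == 650

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(4)
        reads = [
            make_categorized(f"r{i}", Category.REJECTED, 900,
                             bp_to_decision=int(v))
            for i, v in enumerate(rng.integers(400, 801, 500))
        ]
        out = decision_length_distribution(reads)["rejected"]
        assert sum(out.bin_counts) == 500


def _pair(n_control, n_dep_rejected, n_dep_kept, sid="s"):
    ctrl = [make_categorized(f"{sid}c{i}", Category.CONTROL) for i in range(n_control)]
    dep = [
        make_categorized(f"{sid}r{i}", Category.REJECTED)
        for i in range(n_dep_rejected)
    ] + [
        make_categorized(f"{sid}k{i}", Category.ACCEPTED) for i in range(n_dep_kept)
    ]
    return summarize_run(ctrl), summarize_run(dep)


class TestCohortSummary:
    def test_requires_two_pairs(self):
        c, d = _pair(10, 15, 5)
        with pytest.raises(ValueError, match="2 pairs"):
            cohort_summary([((c, None), (d, None))])

    def test_identical_pairs_fold(self):
        c1, d1 = _pair(10, 15, 5, "a")
        c2, d2 = _pair(10, 15, 5, "b")
        out = cohort_summary([((c1, None), (d1, None)), ((c2, None), (d2, None))])
        mean, sd = out.aggregates["fold"]
        assert mean == 2.0
        assert sd == 0.0

    def test_small_accepted_fractions_excluded(self, lineage_map):
        # samples whose accepted category holds 4, 20 and 92 reads all fall
        # below the default threshold of 100 and are excluded from the
        # accepted-category means
        pairs = []
        sizes = [4, 20, 92]
        for i, n_acc in enumerate(sizes):
            ctrl, dep = _pair(100, 200, n_acc, sid=f"s{i}")
            dep_reads = [
                make_categorized(f"s{i}r{j}", Category.REJECTED) for j in range(200)
            ] + [
                make_categorized(f"s{i}k{j}", Category.ACCEPTED) for j in range(n_acc)
            ]
            assignments = _assign(dep_reads, 9606)
            content = category_content(dep_reads, assignments, lineage_map)
            pairs.append(((ctrl, None), (dep, content)))
        out = cohort_summary(pairs)
        assert sorted(out.excluded["accepted"]) == [
            "sample_01", "sample_02", "sample_03",
        ]
        # with every sample excluded there is no accepted-category mean
        assert "accepted_human_pct" not in out.aggregates

    def test_category_mean_excludes_only_small(self, lineage_map):
        pairs = []
        for i, n_acc in enumerate([50, 200]):
            ctrl, _ = _pair(100, 100, n_acc, sid=f"t{i}")
            dep_reads = [
                make_categorized(f"t{i}r{j}", Category.REJECTED) for j in range(100)
            ] + [
                make_categorized(f"t{i}k{j}", Category.ACCEPTED) for j in range(n_acc)
            ]
            assignments = _assign(dep_reads, 2702)  # all bacterial
            content = category_content(dep_reads, assignments, lineage_map)
            dep = summarize_run(dep_reads)
            pairs.append(((ctrl, None), (dep, content)))
        out = cohort_summary(pairs)
        assert out.excluded["accepted"] == ["sample_01"]
        mean, sd = out.aggregates["accepted_bacterial_pct"]
        assert mean == 100.0 and sd == 0.0

    def test_cohort15_designed_fold_recovered(self):
        # preset-construction oracle: per-sample read counts are built from
        # the deterministic fold parameters, so measured folds average to
        # the designed mean up to rounding of read counts
        n = 4000
        presets = synth.build_cohort_presets(n)
        folds = [n_dep / n_ctrl for _, _, n_ctrl, _, n_dep in presets]
        designed = [p["read_fold"] for p in synth.cohort15_parameters()]
        assert abs(np.mean(folds) - np.mean(designed)) < 1e-3
        assert abs(np.mean(folds) - 1.70) < 1e-3
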