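import json
import math

import numpy as np
import pytest

from poresift import synthetic_data as synth
from poresift.synthetic_data import (
    BoundedDist,
    PoreTimeModel,
    SimPreset,
    draw_run,
    draw_run_duration,
    get_preset,
    quantile_spread,
    simulate_run,
)


class TestBoundedDist:
    def test_bounds_and_median(self):
        dist = BoundedDist(400, 800, 600)
        rng = np.random.default_rng(1)
        x = dist.sample(rng, 20_000)
        assert x.min() >= 400 and x.max() <= 800
        # exact median by construction; order-statistic SE ~ (hi-lo)/4/sqrt(n)
        assert abs(np.median(x) - 600) < 3 * 100 / math.sqrt(20_000) * 2

    def test_invalid_median(self):
        with pytest.raises(ValueError):
            BoundedDist(400, 800, 900)


class TestPresetValidation:
    def test_named_presets_valid(self):
        for name in ("single_sample_control", "single_sample_depletion",
                     "single_sample_enrichment"):
            get_preset(name).validate()

    def test_unknown_preset_lists_names(self):
        with pytest.raises(ValueError, match="single_sample_control"):
            get_preset("bogus")

    def test_bad_composition_sum(self):
        preset = SimPreset(name="x", composition={"human": 0.5})
        with pytest.raises(ValueError, match="sums"):
            preset.validate()

    def test_validation_before_files(self, tmp_path):
        preset = SimPreset(name="x", composition={"human": 2.0, "Gardnerella": -1.0})
        with pytest.raises(ValueError):
            simulate_run(preset, 10, 1, tmp_path / "never")
        assert not (tmp_path / "never").exists() or not any(
            (tmp_path / "never").iterdir()
        )


class TestDrawRun:
    def test_degenerate_all_rejected_short(self):
        preset = SimPreset(
            name="deg",
            category_probs={"rejected": 1.0, "accepted": 0.0, "no_decision": 0.0},
            category_composition={
                "rejected": {"human": 1.0},
                "accepted": {"human": 1.0},
                "no_decision": {"human": 1.0},
            },
        )
        draw = draw_run(preset, 2000, np.random.default_rng(2))
        assert set(draw.categories) == {"rejected"}
        assert set(draw.labels) == {"human"}
        assert draw.emitted_length.max() <= 800

    def test_rejected_truncated_to_bp(self):
        preset = get_preset("single_sample_depletion")
        draw = draw_run(preset, 5000, np.random.default_rng(3))
        rej = draw.categories == "rejected"
        assert np.array_equal(draw.emitted_length[rej], draw.bp_to_decision[rej])
        assert (draw.emitted_length[rej] <= draw.full_length[rej]).all()
        # kept reads are full length
        assert np.array_equal(draw.emitted_length[~rej], draw.full_length[~rej])

    def test_bp_at_decision_leq_length(self):
        preset = get_preset("single_sample_depletion")
        draw = draw_run(preset, 5000, np.random.default_rng(4))
        has_bp = ~np.isnan(draw.bp_to_decision)
        assert (draw.bp_to_decision[has_bp] <= draw.emitted_length[has_bp]).all()

    def test_category_frequencies_3sd_at_1e4(self):
        preset = get_preset("single_sample_enrichment")
        n = 10_000
        draw = draw_run(preset, n, np.random.default_rng(5))
        for cat, p in preset.category_probs.items():
            observed = (draw.categories == cat).mean()
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * sd + 1e-12

    def test_control_human_fraction_binomial(self):
        preset = get_preset("single_sample_control")
        n = 50_000
        draw = draw_run(preset, n, np.random.default_rng(6))
        p = synth.CONTROL_HUMAN_FRACTION
        observed = (draw.labels == "human").mean()
        assert abs(observed - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_per_class_decision_mode(self):
        preset = SimPreset(
            name="pc",
            composition={"human": 0.9, "Lactobacillus": 0.1},
            per_class_decision={
                "human": {"rejected": 1.0, "accepted": 0.0, "no_decision": 0.0},
                "Lactobacillus": {"rejected": 0.0, "accepted": 1.0,
                                  "no_decision": 0.0},
            },
        )
        draw = draw_run(preset, 3000, np.random.default_rng(7))
        assert (draw.categories[draw.labels == "human"] == "rejected").all()
        assert (draw.categories[draw.labels == "Lactobacillus"] == "accepted").all()


class TestSimulateRun:
    def test_truth_fastq_bijection(self, tmp_path):
        from poresift.io_readuntil import read_fastq

        run = simulate_run(get_preset("single_sample_depletion"), 1500, 8,
                           tmp_path, run_id="bij")
        fastq_ids = {r.read_id for r in read_fastq(run.paths["fastq"])}
        truth_ids = set()
        with open(run.paths["truth"]) as fh:
            fh.readline()
            for line in fh:
                truth_ids.add(line.split("\t", 1)[0])
        assert fastq_ids == truth_ids
        assert len(fastq_ids) == 1500

    def test_read_ids_carry_no_truth(self, tmp_path):
        run = simulate_run(get_preset("single_sample_control"), 100, 9,
                           tmp_path, run_id="anon")
        with open(run.paths["truth"]) as fh:
            fh.readline()
            for line in fh:
                rid, taxid, cls, cat, *_ = line.split("\t")
                assert taxid not in rid
                assert "human" not in rid and cat not in rid

    def test_same_seed_identical_outputs(self, tmp_path):
        kwargs = dict(n_reads=500, seed=123, run_id="det")
        r1 = simulate_run(get_preset("single_sample_depletion"),
                          outdir=tmp_path / "a", **kwargs)
        r2 = simulate_run(get_preset("single_sample_depletion"),
                          outdir=tmp_path / "b", **kwargs)
        m1 = json.loads(r1.paths["manifest"].read_text())
        m2 = json.loads(r2.paths["manifest"].read_text())
        assert m1["checksums"] == m2["checksums"]

    def test_manifest_counts_match(self, tmp_path):
        run = simulate_run(get_preset("single_sample_depletion"), 800, 10, tmp_path)
        manifest = json.loads(run.paths["manifest"].read_text())
        assert manifest["n_reads"] == 800
        assert sum(manifest["category_counts"].values()) == 800
        assert manifest["seed"] == 10


class TestQuantileSpread:
    def test_mean_exact_no_clipping(self):
        vals = quantile_spread(92.05, 7.42)
        assert len(vals) == 15
        assert np.mean(vals) == pytest.approx(92.05, abs=1e-9)

    def test_mean_exact_with_clipping(self):
        vals = quantile_spread(97.59, 7.63, lo=0, hi=100)
        assert vals.max() <= 100.0
        assert (vals == 100.0).any()  # some values pinned at the bound
        assert np.mean(vals) == pytest.approx(97.59, abs=1e-9)

    def test_s_zero_identical(self):
        vals = quantile_spread(50.0, 0.0)
        assert (vals == 50.0).all()

    def test_spread_close_to_target_sd(self):
        vals = quantile_spread(1.70, 0.27)
        # quantile construction slightly under-disperses vs the target sd
        assert 0.2 < np.std(vals, ddof=1) < 0.35
        assert np.mean(vals) == pytest.approx(1.70, abs=1e-12)


class TestCohortConstruction:
    def test_parameter_means(self):
        params = synth.cohort15_parameters()
        for key, (m, s, lo, hi) in synth.COHORT15_PARAMS.items():
            values = [p[key] for p in params]
            assert np.mean(values) == pytest.approx(m, abs=1e-9)

    def test_fold_mean_before_sampling(self):
        presets = synth.build_cohort_presets(10_000)
        folds = [n_dep / n_ctrl for _, _, n_ctrl, _, n_dep in presets]
        assert np.mean(folds) == pytest.approx(1.70, abs=1e-3)

    def test_pairs_share_genus_mix(self):
        for _, control, _, depletion, _ in synth.build_cohort_presets(1000)[:3]:
            ctrl_bact = {
                k: v for k, v in control.composition.items() if k != "human"
            }
            dep_bact = depletion.category_composition["accepted"]
            # same genus weights drive both sides
            ctrl_ratio = ctrl_bact["Gardnerella"] / ctrl_bact["Lactobacillus"]
            dep_ratio = dep_bact["Gardnerella"] / dep_bact["Lactobacillus"]
            assert ctrl_ratio == pytest.approx(dep_ratio)

    def test_sample_generation_matches_cohort(self, tmp_path):
        # generating sample 0 alone is byte-identical to the full cohort path
        sid, ctrl, dep = synth.simulate_cohort_sample(0, 300, 77, tmp_path / "solo")
        cohort = synth.simulate_cohort(300, 77, tmp_path / "full")
        full_ctrl = cohort.samples[0]["control"]
        m_solo = json.loads(ctrl.paths["manifest"].read_text())
        m_full = json.loads(full_ctrl.paths["manifest"].read_text())
        assert m_solo["checksums"] == m_full["checksums"]


class TestPoreTimeModel:
    def test_depletion_yields_more_reads_for_fixed_duration(self):
        # occupancy-time accounting: rejecting host molecules at ~600 bp
        # frees pore time, so the same duration emits strictly more reads
        pt = PoreTimeModel(speed_bp_s=450, capture_s=1.0, unblock_s=0.5)
        control = SimPreset(
            name="ctl", composition={"human": 0.9, "Lactobacillus": 0.1},
            pore_time=pt,
        )
        depletion = SimPreset(
            name="dep",
            category_probs={"rejected": 0.9, "accepted": 0.005,
                            "no_decision": 0.095},
            category_composition={
                "rejected": {"human": 1.0},
                "accepted": {"Lactobacillus": 1.0},
                "no_decision": {"human": 0.5, "Lactobacillus": 0.5},
            },
            pore_time=pt,
        )
        duration = 20_000.0
        rng = np.random.default_rng(55)
        n_control = draw_run_duration(control, duration, rng).n_reads
        n_depletion = draw_run_duration(depletion, duration, rng).n_reads
        assert n_depletion > n_control

    def test_requires_pore_time_model(self):
        preset = get_preset("single_sample_control")
        with pytest.raises(ValueError, match="pore_time"):
            draw_run_duration(preset, 100.0, np.random.default_rng(1))
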