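import json
import math

import numpy as np
import pytest

import realcsf as r
from realcsf.focal import FocalScore
from realcsf.gas import GASResult
from realcsf.report import ReportError, arm_report_frame, focal_report_frame


def gas_result(gas, threshold=0.25, sample_id="s"):
    return GASResult(sample_id=sample_id, gas=gas, positive=gas >= threshold, threshold=threshold)


def focal_score(z, gene="EGFR", threshold=7.5):
    return FocalScore(gene, observed=100, lam=50.0, z=z, positive=z >= threshold, scorable=True)


class TestCompositeCall:
    @pytest.mark.parametrize(
        "gas,z,positive,evidence",
        [
            (0.30, 0.0, True, "gas"),
            (0.10, 15.0, True, "focal"),
            (0.30, 15.0, True, "both"),
            (0.10, 0.0, False, "none"),
        ],
    )
    def test_or_gate_truth_table(self, gas, z, positive, evidence):
        call = r.composite_call(gas_result(gas), [focal_score(z)])
        assert call.positive is positive
        assert call.evidence == evidence

    def test_sample_mismatch_rejected(self):
        from realcsf.segmentation import ArmZScores

        with pytest.raises(ReportError, match="mismatch"):
            r.composite_call(gas_result(0.3, sample_id="a"), [], ArmZScores("b"))


def wilson_oracle(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval, written out directly."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestWilson:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = r.wilson_interval(k, n)
            olo, ohi = wilson_oracle(k, n)
            assert lo == pytest.approx(olo, abs=1e-10)
            assert hi == pytest.approx(ohi, abs=1e-10)

    def test_sensitivity_example(self):
        # 63 of 85 positive: sensitivity 74.1%, CI inside (63%, 83%)
        lo, hi = r.wilson_interval(63, 85)
        assert 63 / 85 == pytest.approx(0.741, abs=0.001)
        assert 0.63 < lo < hi < 0.83

    def test_perfect_specificity_lower_bound(self):
        # 0 false positives in 34: specificity 100%, lower bound ~89.8%
        lo, hi = r.wilson_interval(34, 34)
        assert hi == pytest.approx(1.0, abs=1e-12)
        assert lo == pytest.approx(0.898, abs=0.005)

    def test_single_observation_no_error(self):
        lo, hi = r.wilson_interval(1, 1)
        assert 0.0 < lo < 1.0 and hi == 1.0


class TestCohortSummary:
    def make_call(self, sample_id, positive):
        gas = gas_result(0.9 if positive else 0.01, sample_id=sample_id)
        return r.composite_call(gas, [])

    def test_counts_and_intervals(self):
        calls = (
            [self.make_call(f"c{i}", i < 63) for i in range(85)]
            + [self.make_call(f"n{i}", False) for i in range(34)]
        )
        truth = {f"c{i}": True for i in range(85)} | {f"n{i}": False for i in range(34)}
        table = r.cohort_summary(calls, truth).set_index("metric")
        sens = table.loc["sensitivity"]
        assert sens["k"] == 63 and sens["n"] == 85
        spec = table.loc["specificity"]
        assert spec["estimate"] == 1.0
        assert spec["ci_low"] == pytest.approx(wilson_oracle(34, 34)[0], abs=1e-10)

    def test_missing_truth_rejected(self):
        with pytest.raises(ReportError, match="truth"):
            r.cohort_summary([self.make_call("x", True)], {})

    def test_empty_rejected(self):
        with pytest.raises(ReportError):
            r.cohort_summary([], {})


@pytest.fixture(scope="module")
def toy_pipeline(toy_assay):
    """A GAS model trained on the toy assay for end-to-end report tests."""
    X, y = r.make_gas_curriculum(
        toy_assay["grid"], toy_assay["prop"], toy_assay["panel"], 50, 50, seed=23
    )
    model = r.train_gas(X, y, list(toy_assay["grid"].arm_names), seed=23)
    windows = [
        r.make_focal_window("ONC1", "toy1", 3_000_000, 4_500_000, toy_assay["grid"], flank=0)
    ]
    for w in windows:
        toy_assay["panel"].register_window(w)
    return {**toy_assay, "model": model, "windows": windows}


class TestFullGenomePipeline:
    def test_gbm_like_sample_positive_with_both_evidence(self, hg19_assay, gas_model):
        # chr7 gain + chr10 loss at 20% tumor fraction with an 8-copy EGFR
        # amplification: the classic glioblastoma profile fires both gates
        grid, prop, panel = hg19_assay["grid"], hg19_assay["prop"], hg19_assay["panel"]
        egfr = next(w for w in hg19_assay["windows"] if w.gene_name == "EGFR")
        cfg = r.SimulationConfig(
            seed=909, depth=1_000_000, tumor_fraction=0.2,
            arm_events=[r.ArmEvent("chr7p", 3), r.ArmEvent("chr7q", 3),
                        r.ArmEvent("chr10p", 1), r.ArmEvent("chr10q", 1)],
            focal_events=[r.FocalEvent(egfr, 8)],
        )
        v, _ = r.simulate_interval_vector(cfg, prop, grid, "gbm")
        call = r.score_sample(v, panel, gas_model, windows=hg19_assay["windows"], seed=0)
        assert call.positive and call.evidence == "both"
        arm_calls = {a.arm: a.call for a in call.arm_scores}
        assert arm_calls["chr7p"] == "gain" and arm_calls["chr10q"] == "loss"
        assert next(f for f in call.focal_scores if f.gene_name == "EGFR").positive

    def test_euploid_sample_negative(self, hg19_assay, gas_model):
        cfg = r.SimulationConfig(seed=910, depth=1_000_000)
        v, _ = r.simulate_interval_vector(
            cfg, hg19_assay["prop"], hg19_assay["grid"], "eu")
        call = r.score_sample(
            v, hg19_assay["panel"], gas_model, windows=hg19_assay["windows"], seed=0)
        assert not call.positive and call.evidence == "none"


class TestScoreSample:
    def test_euploid_sample_negative(self, toy_pipeline):
        cfg = r.SimulationConfig(seed=71, depth=1_000_000)
        v, _ = r.simulate_interval_vector(cfg, toy_pipeline["prop"], toy_pipeline["grid"], "eu")
        call = r.score_sample(v, toy_pipeline["panel"], toy_pipeline["model"],
                              windows=toy_pipeline["windows"], seed=1)
        assert not call.positive and call.evidence == "none"

    def test_tumor_sample_positive_with_both_evidence(self, toy_pipeline):
        cfg = r.SimulationConfig(
            seed=72, depth=1_000_000, tumor_fraction=0.3,
            arm_events=[r.ArmEvent(a, 3) for a in ["toy1p", "toy1q"]]
            + [r.ArmEvent(a, 1) for a in ["toy2p", "toy2q"]],
            focal_events=[r.FocalEvent(toy_pipeline["windows"][0], 10)],
        )
        v, _ = r.simulate_interval_vector(cfg, toy_pipeline["prop"], toy_pipeline["grid"], "tu")
        call = r.score_sample(v, toy_pipeline["panel"], toy_pipeline["model"],
                              windows=toy_pipeline["windows"], seed=1)
        assert call.positive and call.evidence == "both"
        arm_calls = {a.arm: a.call for a in call.arm_scores}
        assert arm_calls["toy1p"] == "gain" and arm_calls["toy2q"] == "loss"

    def test_rerun_same_seed_byte_identical_json(self, toy_pipeline, tmp_path):
        cfg = r.SimulationConfig(seed=73, depth=1_000_000)
        v, _ = r.simulate_interval_vector(cfg, toy_pipeline["prop"], toy_pipeline["grid"], "det")
        for run in ("a", "b"):
            r.score_sample(v, toy_pipeline["panel"], toy_pipeline["model"],
                           windows=toy_pipeline["windows"], seed=9,
                           out_prefix=tmp_path / run)
        assert (tmp_path / "a.call.json").read_bytes() == (tmp_path / "b.call.json").read_bytes()

    def test_json_record_is_self_describing(self, toy_pipeline, tmp_path):
        cfg = r.SimulationConfig(seed=74, depth=1_000_000)
        v, _ = r.simulate_interval_vector(cfg, toy_pipeline["prop"], toy_pipeline["grid"], "sd")
        call = r.score_sample(v, toy_pipeline["panel"], toy_pipeline["model"],
                              windows=toy_pipeline["windows"], seed=1,
                              out_prefix=tmp_path / "sd")
        doc = json.loads((tmp_path / "sd.call.json").read_text())
        assert doc["thresholds"]["gas_threshold"] == 0.25
        assert doc["thresholds"]["focal_threshold"] == 7.5
        assert len(doc["arms"]) == len(toy_pipeline["grid"].arm_names)
        assert arm_report_frame(call).shape[0] == len(doc["arms"])
        assert focal_report_frame(call).shape[0] == 1
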