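import numpy as np
import pytest
from scipy import stats

import realcsf as r
from realcsf.panel import NormalizedProfile
from realcsf.segmentation import DEFAULT_MIN_WIDTH, stable_arm_seed


def oracle_boundaries(x, min_width=DEFAULT_MIN_WIDTH):
    """Independent exhaustive-search segmentation: at each level pick the
    split maximizing the pooled two-sample |t| (scipy), recursing on every
    admissible segment (no significance gate)."""
    bounds = {0, len(x)}

    def recurse(lo, hi):
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_width:
            return
        best_t, best_k = -1.0, None
        for k in range(min_width, n - min_width + 1):
            t = stats.ttest_ind(seg[:k], seg[k:], equal_var=True).statistic
            if np.isfinite(t) and abs(t) > best_t:
                best_t, best_k = abs(t), k
        if best_k is None:
            return
        bounds.add(lo + best_k)
        recurse(lo, lo + best_k)
        recurse(lo + best_k, hi)

    recurse(0, len(x))
    return sorted(bounds)


class TestSegmentArm:
    def test_constant_vector_single_segment(self):
        segs = r.segment_arm(np.zeros(50), seed=1)
        assert len(segs) == 1
        assert (segs[0].start_index, segs[0].end_index) == (0, 50)

    def test_step_breakpoint_recovered(self):
        rng = np.random.default_rng(21)
        x = np.concatenate([rng.normal(0, 0.5, 25), rng.normal(3, 0.5, 25)])
        segs = r.segment_arm(x, seed=2)
        assert len(segs) == 2
        assert abs(segs[0].end_index - 25) <= 2
        # independent check: a single exhaustive max-|t| scan picks the same cut
        from scipy import stats

        ts = [
            abs(stats.ttest_ind(x[:k], x[k:], equal_var=True).statistic)
            for k in range(3, len(x) - 2)
        ]
        assert segs[0].end_index == 3 + int(np.argmax(ts))

    def test_null_rarely_split(self):
        rng = np.random.default_rng(3)
        n_single = sum(
            len(r.segment_arm(rng.normal(size=50), seed=s)) == 1 for s in range(200)
        )
        assert n_single >= 190

    def test_short_arm_flagged(self):
        segs = r.segment_arm(np.array([1.0, 2.0]), min_width=3, seed=0)
        assert len(segs) == 1 and segs[0].flagged_short

    @pytest.mark.parametrize("n", range(6, 13))
    def test_exhaustive_oracle_equivalence(self, n):
        """Ungated recursive splitting equals the exhaustive-search oracle on
        every segment boundary, for many random vectors of length <= 12."""
        rng = np.random.default_rng(n)
        for rep in range(30):
            x = rng.normal(size=n)
            if rep % 3 == 0:  # mix in step signals
                x[: n // 2] += 2.0
            segs = r.segment_arm(x, alpha=1.0, n_perm=1, seed=rep)
            got = sorted({s.start_index for s in segs} | {n})
            assert got == oracle_boundaries(x), f"n={n} rep={rep}"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=60)
        x[30:] += 1.0
        a = r.segment_arm(x, seed=123)
        b = r.segment_arm(x, seed=123)
        assert [(s.start_index, s.end_index) for s in a] == [
            (s.start_index, s.end_index) for s in b
        ]

    def test_stable_arm_seed_range(self):
        s = stable_arm_seed("sample1", "chr5q", 17)
        assert 0 <= s < 2**31 - 1
        assert s == stable_arm_seed("sample1", "chr5q", 17)


def make_profile(grid, z):
    return NormalizedProfile("s", grid, z.copy(), grid.scored.copy())


class TestMasking:
    def test_spike_masked_as_outlier(self, toy_grid):
        idx = toy_grid.arm_interval_indices("toy1p")
        rng = np.random.default_rng(4)
        z = np.zeros(toy_grid.n_intervals)
        z[toy_grid.scored] = rng.normal(size=int(toy_grid.scored.sum()))
        z[idx[10]] = 12.0
        profile = make_profile(toy_grid, z)
        segs = r.segment_arm(z[idx], "toy1p", seed=5)
        r.mask_germline_and_outliers(profile, idx, segs)
        assert not profile.retained[idx[10]]
        assert profile.mask_reason[int(idx[10])] == "outlier"
        assert profile.retained[np.delete(idx, 10)].all()

    def test_short_high_segment_masked_as_germline(self, toy_assay):
        # an inherited 2-interval CNV at z ~ 6 inside a euploid arm is
        # excluded, and the arm's Z_w falls back to the null range
        grid, panel = toy_assay["grid"], toy_assay["panel"]
        cfg = r.SimulationConfig(seed=31, depth=1_000_000)
        v, _ = r.simulate_interval_vector(cfg, toy_assay["prop"], grid, "g")
        profile = r.pca_normalize(v, panel)
        idx = grid.arm_interval_indices("toy2q")
        profile.z[idx[5:7]] += 6.0
        segs = r.segment_arm(profile.z[idx], "toy2q", seed=6)
        r.mask_germline_and_outliers(profile, idx, segs)
        zw, m = r.arm_zw(profile, idx)
        assert m <= len(idx) - 2
        assert abs(zw) < 3.0

    def test_whole_arm_shift_not_masked_as_germline(self, toy_grid):
        idx = toy_grid.arm_interval_indices("toy1q")
        z = np.zeros(toy_grid.n_intervals)
        rng = np.random.default_rng(8)
        z[toy_grid.scored] = rng.normal(size=int(toy_grid.scored.sum()))
        z[idx] += 6.0  # tumor-like arm-wide event, width >> germline_max
        profile = make_profile(toy_grid, z)
        segs = r.segment_arm(z[idx], "toy1q", seed=7)
        r.mask_germline_and_outliers(profile, idx, segs)
        assert profile.retained[idx].sum() >= len(idx) - 2  # outlier rule only


class TestArmZw:
    def test_zero_profile(self, toy_grid):
        profile = make_profile(toy_grid, np.zeros(toy_grid.n_intervals))
        zw, m = r.arm_zw(profile, toy_grid.arm_interval_indices("toy1p"))
        assert zw == 0.0

    def test_stouffer_arithmetic(self, toy_grid):
        idx = toy_grid.arm_interval_indices("toy1p")[:4]
        z = np.zeros(toy_grid.n_intervals)
        z[idx] = 2.0
        profile = make_profile(toy_grid, z)
        zw, m = r.arm_zw(profile, idx, min_retained=4)
        assert zw == pytest.approx(4.0)  # 8 / sqrt(4)
        assert m == 4

    def test_too_few_retained_flagged(self, toy_grid):
        idx = toy_grid.arm_interval_indices("toy1p")[:4]
        profile = make_profile(toy_grid, np.zeros(toy_grid.n_intervals))
        zw, m = r.arm_zw(profile, idx, min_retained=10)
        assert zw is None and m == 4

    def test_antisymmetry(self, toy_grid):
        rng = np.random.default_rng(11)
        z = np.zeros(toy_grid.n_intervals)
        z[toy_grid.scored] = rng.normal(size=int(toy_grid.scored.sum()))
        idx = toy_grid.arm_interval_indices("toy3q")
        p1 = make_profile(toy_grid, z)
        p2 = make_profile(toy_grid, -z)
        assert r.arm_zw(p1, idx)[0] == -r.arm_zw(p2, idx)[0]

    def test_null_calibration_toy(self, toy_assay):
        zws = []
        for seed in range(60, 90):
            cfg = r.SimulationConfig(seed=seed, depth=1_000_000)
            v, _ = r.simulate_interval_vector(cfg, toy_assay["prop"], toy_assay["grid"], f"n{seed}")
            profile = r.pca_normalize(v, toy_assay["panel"])
            scores = r.score_arms(profile, toy_assay["grid"], base_seed=1)
            zws.extend(s.zw for s in scores if s.zw is not None)
        zws = np.array(zws)
        assert abs(zws.mean()) < 0.25
        assert 0.8 < zws.std() < 1.25


class TestCallArm:
    @pytest.mark.parametrize(
        "zw,call,borderline",
        [
            (8.0, "gain", False),
            (-8.0, "loss", False),
            (6.0, "neutral", True),
            (-6.0, "neutral", True),
            (3.0, "neutral", False),
            (7.5, "neutral", True),  # gain requires Z strictly above 7.5
            (None, "neutral", False),
        ],
    )
    def test_thresholds(self, zw, call, borderline):
        assert r.call_arm(zw) == (call, borderline)
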