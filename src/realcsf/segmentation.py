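"""Per-arm segmentation, germline/outlier masking, and arm-level Z_w.

Segmentation is recursive binary splitting: within a segment, the split
point maximizing the pooled two-sample |t| statistic between left and right
halves is found by exhaustive search, and its significance is assessed by a
permutation test on the segment's values.  Splitting recurses while the
permutation p-value is below alpha.  This is the binary-split variant of
circular binary segmentation appropriate for arm-bounded profiles.

Arm-level evidence is the Stouffer combination Z_w = sum(z_i) / sqrt(m) over
the m retained intervals of the arm; under a euploid null with unit-scale
residuals Z_w is approximately standard normal, so fixed thresholds on Z_w
control per-arm false calls directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome import ArmDefinition, IntervalGrid
from .panel import NormalizedProfile

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_WIDTH = 3
DEFAULT_N_PERM = 1000
DEFAULT_GAIN_THRESHOLD = 7.5
DEFAULT_LOSS_THRESHOLD = -7.5
BORDERLINE_THRESHOLD = 5.0
DEFAULT_OUTLIER_MAD_MULT = 4.0
DEFAULT_GERMLINE_MAX_INTERVALS = 6  # < 3 Mb at 500-kb intervals
DEFAULT_GERMLINE_Z = 4.0
DEFAULT_MIN_RETAINED = 10
_MAD_TO_SD = 1.4826  # consistency constant for a normal distribution


@dataclass(frozen=True)
class Segment:
    arm: str
    start_index: int  # position within the arm's retained-value vector, half-open
    end_index: int
    mean: float
    n_intervals: int
    p_value: float | None = None  # p of the split that created this segment's parent
    flagged_short: bool = False


def _all_split_t(x: np.ndarray, min_width: int) -> np.ndarray:
    """Pooled two-sample t at every admissible split of x (vectorized).

    Returns array of length n-1 with NaN at splits leaving a side shorter
    than min_width.
    """
    n = len(x)
    k = np.arange(1, n)
    csum = np.cumsum(x)
    total = csum[-1]
    csq = np.cumsum(x**2)
    total_sq = csq[-1]
    n_l = k.astype(float)
    n_r = n - n_l
    mean_l = csum[:-1] / n_l
    mean_r = (total - csum[:-1]) / n_r
    ss_l = csq[:-1] - n_l * mean_l**2
    ss_r = (total_sq - csq[:-1]) - n_r * mean_r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.sqrt(np.maximum(ss_l + ss_r, 0.0) / np.maximum(n - 2, 1))
        t = (mean_l - mean_r) / (pooled * np.sqrt(1.0 / n_l + 1.0 / n_r))
    t[~np.isfinite(t)] = 0.0
    bad = (n_l < min_width) | (n_r < min_width)
    t[bad] = np.nan
    return t


def _max_split(x: np.ndarray, min_width: int) -> tuple[int, float] | None:
    t = _all_split_t(x, min_width)
    if np.all(np.isnan(t)):
        return None
    best = int(np.nanargmax(np.abs(t)))
    return best + 1, float(abs(t[best]))


def _perm_pvalue(
    x: np.ndarray,
    observed_t: float,
    min_width: int,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float,
    block: int = 100,
) -> float:
    """Permutation p-value of max|t| with block-wise early stopping.

    Blocks of permutations are evaluated until either all n_perm are done or
    the exceedance count already guarantees p > alpha.
    """
    exceed = 0
    done = 0
    n = len(x)
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.stack([rng.permutation(x) for _ in range(b)])
        # vectorized max|t| per permuted row
        k = np.arange(1, n)
        csum = np.cumsum(perms, axis=1)
        csq = np.cumsum(perms**2, axis=1)
        total = csum[:, -1:]
        total_sq = csq[:, -1:]
        n_l = k.astype(float)
        n_r = n - n_l
        mean_l = csum[:, :-1] / n_l
        mean_r = (total - csum[:, :-1]) / n_r
        ss = (csq[:, :-1] - n_l * mean_l**2) + (total_sq - csq[:, :-1]) - n_r * mean_r**2
        with np.errstate(divide="ignore", invalid="ignore"):
            pooled = np.sqrt(np.maximum(ss, 0.0) / max(n - 2, 1))
            t = (mean_l - mean_r) / (pooled * np.sqrt(1.0 / n_l + 1.0 / n_r))
        t[~np.isfinite(t)] = 0.0
        t[:, (n_l < min_width) | (n_r < min_width)] = 0.0
        max_t = np.abs(t).max(axis=1)
        exceed += int((max_t >= observed_t).sum())
        done += b
        # early stop: even if no further exceedances occur, p-hat is already
        # far above alpha (one-sided lower bound on the final p-value)
        if (exceed + 1) / (n_perm + 1) > 4 * alpha and exceed >= 10:
            return (exceed + 1) / (done + 1)
    return (exceed + 1) / (n_perm + 1)


def segment_arm(
    values: np.ndarray,
    arm_name: str = "arm",
    alpha: float = DEFAULT_ALPHA,
    min_width: int = DEFAULT_MIN_WIDTH,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[Segment]:
    """Segment one arm's per-interval values into constant-mean pieces."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < min_width:
        return [
            Segment(arm_name, 0, n, float(x.mean()) if n else 0.0, n, flagged_short=True)
        ]
    rng = np.random.default_rng(seed)
    boundaries = [0, n]
    pvals: dict[tuple[int, int], float] = {}
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        if len(seg) < 2 * min_width:
            continue
        found = _max_split(seg, min_width)
        if found is None:
            continue
        split, t_obs = found
        p = _perm_pvalue(seg, t_obs, min_width, n_perm, rng, alpha)
        if p <= alpha:
            cut = lo + split
            boundaries.append(cut)
            pvals[(lo, hi)] = p
            stack.append((lo, cut))
            stack.append((cut, hi))
    boundaries = sorted(set(boundaries))
    segments = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        segments.append(
            Segment(arm_name, lo, hi, float(x[lo:hi].mean()), hi - lo)
        )
    return segments


def stable_arm_seed(sample_id: str, arm_name: str, base_seed: int = 0) -> int:
    """Deterministic per-(sample, arm) seed below 2^31."""
    h = zlib.crc32(f"{sample_id}:{arm_name}:{base_seed}".encode())
    return int(h % (2**31 - 1))


def mask_germline_and_outliers(
    profile: NormalizedProfile,
    arm_indices: np.ndarray,
    segments: list[Segment],
    outlier_mad_mult: float = DEFAULT_OUTLIER_MAD_MULT,
    germline_max_intervals: int = DEFAULT_GERMLINE_MAX_INTERVALS,
    germline_z: float = DEFAULT_GERMLINE_Z,
) -> None:
    """Mask germline CNVs and outlier intervals on one arm, in place.

    Outliers: intervals deviating from their segment mean by more than
    ``outlier_mad_mult`` robust SDs (1.4826 x MAD within the segment).
    Germline events: short segments (< germline_max_intervals, i.e. < ~3 Mb)
    with |mean z| > germline_z — too focal to be an arm-level tumor event,
    consistent with an inherited copy-number variant.
    """
    z = profile.z
    for seg in segments:
        idx = arm_indices[seg.start_index : seg.end_index]
        vals = z[idx]
        if seg.n_intervals < germline_max_intervals and abs(seg.mean) > germline_z:
            profile.exclude(idx, "germline")
            continue
        mad = np.median(np.abs(vals - np.median(vals)))
        robust_sd = _MAD_TO_SD * mad
        if robust_sd > 0:
            outliers = idx[np.abs(vals - seg.mean) > outlier_mad_mult * robust_sd]
            profile.exclude(outliers, "outlier")


def arm_zw(profile: NormalizedProfile, arm_indices: np.ndarray, min_retained: int = DEFAULT_MIN_RETAINED) -> tuple[float | None, int]:
    """Stouffer Z_w over the arm's retained intervals; (None, m) when m < minimum."""
    retained = arm_indices[profile.retained[arm_indices]]
    m = len(retained)
    if m < min_retained:
        return None, m
    return float(profile.z[retained].sum() / np.sqrt(m)), m


def call_arm(
    zw: float | None,
    gain_thresh: float = DEFAULT_GAIN_THRESHOLD,
    loss_thresh: float = DEFAULT_LOSS_THRESHOLD,
) -> tuple[str, bool]:
    """Gain/loss/neutral call plus borderline flag (5 < |Z_w| <= 7.5)."""
    if zw is None:
        return "neutral", False
    if zw > gain_thresh:
        return "gain", False
    if zw < loss_thresh:
        return "loss", False
    borderline = abs(zw) > BORDERLINE_THRESHOLD
    return "neutral", borderline


@dataclass
class ArmScore:
    arm: str
    zw: float | None
    m: int
    call: str
    borderline: bool
    excluded: bool = False  # too few retained intervals; feature imputed 0

    @property
    def feature_value(self) -> float:
        return 0.0 if self.zw is None else self.zw


@dataclass
class ArmZScores:
    """Per-arm Z_w statistics for one sample, in scored-arm order."""

    sample_id: str
    scores: list[ArmScore] = field(default_factory=list)

    @property
    def arm_names(self) -> list[str]:
        return [s.arm for s in self.scores]

    def feature_vector(self) -> np.ndarray:
        return np.array([s.feature_value for s in self.scores])

    def __iter__(self):
        return iter(self.scores)


def score_arms(
    profile: NormalizedProfile,
    grid: IntervalGrid,
    arms: list[ArmDefinition] | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_width: int = DEFAULT_MIN_WIDTH,
    n_perm: int = DEFAULT_N_PERM,
    base_seed: int = 0,
    outlier_mad_mult: float = DEFAULT_OUTLIER_MAD_MULT,
    germline_max_intervals: int = DEFAULT_GERMLINE_MAX_INTERVALS,
    germline_z: float = DEFAULT_GERMLINE_Z,
    min_retained: int = DEFAULT_MIN_RETAINED,
    gain_thresh: float = DEFAULT_GAIN_THRESHOLD,
    loss_thresh: float = DEFAULT_LOSS_THRESHOLD,
) -> ArmZScores:
    """Segment, mask and score every scored arm of one normalized profile."""
    from .genome import enumerate_scored_arms

    if arms is None:
        arm_names = list(grid.arm_names) or [a.name for a in enumerate_scored_arms(grid.layout)]
    else:
        arm_names = [a.name for a in arms]
    result = ArmZScores(sample_id=profile.sample_id)
    for arm_name in arm_names:
        idx = grid.arm_interval_indices(arm_name)
        idx = idx[profile.retained[idx]]
        seed = stable_arm_seed(profile.sample_id, arm_name, base_seed)
        segments = segment_arm(
            profile.z[idx], arm_name, alpha=alpha, min_width=min_width, n_perm=n_perm, seed=seed
        )
        mask_germline_and_outliers(
            profile,
            idx,
            segments,
            outlier_mad_mult=outlier_mad_mult,
            germline_max_intervals=germline_max_intervals,
            germline_z=germline_z,
        )
        zw, m = arm_zw(profile, idx, min_retained=min_retained)
        call, borderline = call_arm(zw, gain_thresh, loss_thresh)
        result.scores.append(
            ArmScore(arm=arm_name, zw=zw, m=m, call=call, borderline=borderline, excluded=zw is None)
        )
    return result
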