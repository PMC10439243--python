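"""Composite calling and per-sample report assembly.

A sample is positive when EITHER the Global Aneuploidy Score is at or above
its threshold OR any focal gene window scores positive (Boolean OR gate);
the evidence field records which branch fired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .counts import bin_counts, read_counts_table
from .focal import DEFAULT_FOCAL_THRESHOLD, FocalScore, score_focal_windows
from .gas import DEFAULT_GAS_THRESHOLD, GASModel, GASResult, gas_score
from .genome import FocalWindow, load_default_focal_windows
from .panel import ReferencePanel, pca_normalize
from .segmentation import ArmZScores, score_arms

CALL_SCHEMA_VERSION = 1


class ReportError(ValueError):
    pass


@dataclass
class RealCSFCall:
    sample_id: str
    gas_result: GASResult
    focal_scores: list[FocalScore]
    arm_scores: ArmZScores
    positive: bool
    evidence: str  # gas | focal | both | none
    thresholds: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": CALL_SCHEMA_VERSION,
            "sample_id": self.sample_id,
            "positive": bool(self.positive),
            "evidence": self.evidence,
            "gas": {
                "score": self.gas_result.gas,
                "positive": bool(self.gas_result.positive),
                "threshold": self.gas_result.threshold,
            },
            "focal": [
                {
                    "gene": f.gene_name,
                    "observed": f.observed,
                    "lambda": f.lam,
                    "z": f.z,
                    "positive": bool(f.positive),
                    "scorable": bool(f.scorable),
                }
                for f in self.focal_scores
            ],
            "arms": [
                {
                    "arm": a.arm,
                    "zw": a.zw,
                    "m": a.m,
                    "call": a.call,
                    "borderline": bool(a.borderline),
                    "excluded": bool(a.excluded),
                }
                for a in self.arm_scores
            ],
            "thresholds": self.thresholds,
        }


def composite_call(
    gas: GASResult,
    focal: list[FocalScore],
    arm_scores: ArmZScores | None = None,
    thresholds: dict | None = None,
) -> RealCSFCall:
    """OR-gate decision with evidence attribution."""
    if arm_scores is not None and arm_scores.sample_id != gas.sample_id:
        raise ReportError(
            f"sample_id mismatch: arms {arm_scores.sample_id!r} vs gas {gas.sample_id!r}"
        )
    any_focal = any(f.positive for f in focal)
    positive = gas.positive or any_focal
    if gas.positive and any_focal:
        evidence = "both"
    elif gas.positive:
        evidence = "gas"
    elif any_focal:
        evidence = "focal"
    else:
        evidence = "none"
    return RealCSFCall(
        sample_id=gas.sample_id,
        gas_result=gas,
        focal_scores=focal,
        arm_scores=arm_scores or ArmZScores(sample_id=gas.sample_id),
        positive=positive,
        evidence=evidence,
        thresholds=thresholds or {},
    )


def score_sample(
    counts,
    panel: ReferencePanel,
    gas_model: GASModel,
    windows: list[FocalWindow] | None = None,
    gas_threshold: float = DEFAULT_GAS_THRESHOLD,
    focal_threshold: float = DEFAULT_FOCAL_THRESHOLD,
    seed: int = 0,
    n_perm: int = 1000,
    out_prefix=None,
) -> RealCSFCall:
    """Run the full pipeline on one sample.

    ``counts`` is a path to a counts TSV, a SampleCounts, or an
    IntervalVector.  When ``out_prefix`` is given, writes <prefix>.arms.tsv,
    <prefix>.focal.tsv and <prefix>.call.json.
    """
    from .counts import IntervalVector, SampleCounts

    grid = panel.grid
    if isinstance(counts, (str,)) or hasattr(counts, "__fspath__"):
        counts = read_counts_table(counts)
    if isinstance(counts, SampleCounts):
        vector = bin_counts(counts, grid)
    elif isinstance(counts, IntervalVector):
        vector = counts
    else:
        raise ReportError(f"unsupported counts input: {type(counts).__name__}")
    if windows is None:
        windows = load_default_focal_windows(grid)

    profile = pca_normalize(vector, panel)
    arm_scores = score_arms(profile, grid, base_seed=seed, n_perm=n_perm)
    gas = gas_score(gas_model, arm_scores, threshold=gas_threshold)
    focal = score_focal_windows(
        vector, panel, windows, vector.total_autosomal_coverage, threshold=focal_threshold
    )
    from .segmentation import DEFAULT_GAIN_THRESHOLD, DEFAULT_LOSS_THRESHOLD

    thresholds = {
        "gas_threshold": gas_threshold,
        "focal_threshold": focal_threshold,
        "gain_threshold": DEFAULT_GAIN_THRESHOLD,
        "loss_threshold": DEFAULT_LOSS_THRESHOLD,
        "seed": seed,
    }
    call = composite_call(gas, focal, arm_scores, thresholds)
    if out_prefix is not None:
        write_reports(call, out_prefix)
    return call


def arm_report_frame(call: RealCSFCall) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": call.sample_id,
            "arm": [a.arm for a in call.arm_scores],
            "zw": [a.zw for a in call.arm_scores],
            "m": [a.m for a in call.arm_scores],
            "call": [a.call for a in call.arm_scores],
            "borderline": [a.borderline for a in call.arm_scores],
        }
    )


def focal_report_frame(call: RealCSFCall) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": call.sample_id,
            "gene": [f.gene_name for f in call.focal_scores],
            "observed": [f.observed for f in call.focal_scores],
            "lambda": [f.lam for f in call.focal_scores],
            "z": [f.z for f in call.focal_scores],
            "call": ["positive" if f.positive else "negative" for f in call.focal_scores],
        }
    )


def write_reports(call: RealCSFCall, prefix) -> None:
    prefix = str(prefix)
    arm_report_frame(call).to_csv(prefix + ".arms.tsv", sep="\t", index=False)
    focal_report_frame(call).to_csv(prefix + ".focal.tsv", sep="\t", index=False)
    with open(prefix + ".call.json", "w") as fh:
        json.dump(call.to_json_dict(), fh, indent=2, sort_keys=True)


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def cohort_summary(calls: list[RealCSFCall], truth: dict[str, bool]) -> pd.DataFrame:
    """Sensitivity/specificity with Wilson 95% CIs.

    ``truth`` maps sample_id -> True (cancer) / False (non-cancer).
    """
    pos_calls = {c.sample_id: c.positive for c in calls}
    missing = [s for s in pos_calls if s not in truth]
    if missing:
        raise ReportError(f"no truth label for samples: {missing[:5]}")
    cancer = [s for s in pos_calls if truth[s]]
    normal = [s for s in pos_calls if not truth[s]]
    rows = []
    if cancer:
        k = sum(pos_calls[s] for s in cancer)
        lo, hi = wilson_interval(k, len(cancer))
        rows.append(
            {"metric": "sensitivity", "k": k, "n": len(cancer),
             "estimate": k / len(cancer), "ci_low": lo, "ci_high": hi}
        )
    if normal:
        k = sum(not pos_calls[s] for s in normal)
        lo, hi = wilson_interval(k, len(normal))
        rows.append(
            {"metric": "specificity", "k": k, "n": len(normal),
             "estimate": k / len(normal), "ci_low": lo, "ci_high": hi}
        )
    if not rows:
        raise ReportError("no samples in either class")
    return pd.DataFrame(rows)
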