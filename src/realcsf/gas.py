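"""Global Aneuploidy Score: an RBF-kernel SVM over the 39 arm-level Z_w
features, emitting a calibrated probability in [0, 1] that a sample is
aneuploid.  Positive at score >= 0.25 by default.

The fitted model is persisted as JSON (support vectors, dual coefficients,
kernel width, Platt calibration constants), and scoring always goes through
the stored arrays, so a serialized model reproduces its scores exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .segmentation import ArmZScores

DEFAULT_GAS_THRESHOLD = 0.25
FEATURE_CLIP = 50.0
MODEL_SCHEMA_VERSION = 1


class GASError(ValueError):
    """Invalid training input or model/feature mismatch."""


@dataclass
class GASModel:
    feature_order: list[str]
    support_vectors: np.ndarray  # (n_sv, 39)
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    gamma: float
    prob_a: float
    prob_b: float
    flip_sign: bool  # orientation of the Platt mapping toward P(aneuploid)
    metadata: dict = field(default_factory=dict)

    def decision_value(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.clip(features, -FEATURE_CLIP, FEATURE_CLIP))
        if X.shape[1] != len(self.feature_order):
            raise GASError(
                f"expected {len(self.feature_order)} features, got {X.shape[1]}"
            )
        d2 = (
            (X**2).sum(axis=1, keepdims=True)
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)
        )
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def score(self, features: np.ndarray) -> np.ndarray:
        """Calibrated P(aneuploid) via the stored Platt sigmoid."""
        d = self.decision_value(features)
        p = 1.0 / (1.0 + np.exp(self.prob_a * d + self.prob_b))
        if self.flip_sign:
            p = 1.0 - p
        return p


@dataclass
class GASResult:
    sample_id: str
    gas: float
    positive: bool
    threshold: float


def train_gas(
    features: np.ndarray,
    labels: np.ndarray,
    feature_order: list[str],
    seed: int = 17,
    min_per_class: int = 50,
    metadata: dict | None = None,
) -> GASModel:
    """Fit the RBF-SVM with canonical default hyperparameters.

    ``labels`` is binary: 1 = aneuploid, 0 = euploid.  Probability output is
    Platt calibration on internal 5-fold cross-validation (the library's
    standard scheme).  Deterministic given ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != len(feature_order):
        raise GASError(f"features must be (n, {len(feature_order)})")
    if not np.all(np.isfinite(X)):
        raise GASError("non-finite feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise GASError(f"need both classes, got labels {classes.tolist()}")
    if counts.min() < min_per_class:
        raise GASError(f"need >= {min_per_class} samples per class, got {counts.tolist()}")
    Xc = np.clip(X, -FEATURE_CLIP, FEATURE_CLIP)
    with warnings.catch_warnings():
        # the library's probability-calibrated SVC interface is in a
        # deprecation cycle; the fitted arrays are extracted immediately
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(kernel="rbf", probability=True, random_state=seed)
        svc.fit(Xc, y)
        prob_a, prob_b = float(svc.probA_[0]), float(svc.probB_[0])
    gamma = svc._gamma if np.isscalar(svc._gamma) else float(svc._gamma)
    model = GASModel(
        feature_order=list(feature_order),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(gamma),
        prob_a=prob_a,
        prob_b=prob_b,
        flip_sign=False,
        metadata={
            "n_euploid": int(counts[classes.tolist().index(0)]),
            "n_aneuploid": int(counts[classes.tolist().index(1)]),
            "seed": int(seed),
            "schema_version": MODEL_SCHEMA_VERSION,
            **(metadata or {}),
        },
    )
    # orient the Platt sigmoid toward P(aneuploid): sklearn's internal sign
    # conventions depend on class order, so fix the orientation empirically
    idx1 = np.flatnonzero(y == 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ref = svc.predict_proba(Xc[idx1])[:, list(svc.classes_).index(1)]
    direct = model.score(Xc[idx1])
    if np.mean(np.abs(direct - ref)) > np.mean(np.abs((1.0 - direct) - ref)):
        model.flip_sign = True
    return model


def gas_score(
    model: GASModel,
    arm_scores: ArmZScores | np.ndarray,
    threshold: float = DEFAULT_GAS_THRESHOLD,
) -> GASResult:
    """Score one sample; positive iff GAS >= threshold."""
    if isinstance(arm_scores, ArmZScores):
        if arm_scores.arm_names != model.feature_order:
            raise GASError("arm feature order differs from model feature order")
        features = arm_scores.feature_vector()
        sample_id = arm_scores.sample_id
    else:
        features = np.asarray(arm_scores, dtype=float)
        sample_id = "sample"
    gas = float(model.score(features)[0])
    return GASResult(sample_id=sample_id, gas=gas, positive=gas >= threshold, threshold=threshold)


def save_gas_model(model: GASModel, path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "feature_order": model.feature_order,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "gamma": model.gamma,
        "prob_a": model.prob_a,
        "prob_b": model.prob_b,
        "flip_sign": model.flip_sign,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_gas_model(path) -> GASModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise GASError(f"unsupported model schema: {doc.get('schema_version')}")
    return GASModel(
        feature_order=list(doc["feature_order"]),
        support_vectors=np.asarray(doc["support_vectors"], dtype=float),
        dual_coef=np.asarray(doc["dual_coef"], dtype=float),
        intercept=float(doc["intercept"]),
        gamma=float(doc["gamma"]),
        prob_a=float(doc["prob_a"]),
        prob_b=float(doc["prob_b"]),
        flip_sign=bool(doc["flip_sign"]),
        metadata=dict(doc["metadata"]),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:12]
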