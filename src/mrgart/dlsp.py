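"""Adaptive-strategy prediction (DLSP): frozen registration encoder + MLP head.

The classifier reuses the encoder of a trained registration network as a
fixed feature extractor: the ROI-masked 2-channel input (reference and daily
image, each masked then min-max normalized) is pushed through the frozen
encoder; the deepest feature maps are pooled (global average pooling by
default) into a feature vector feeding two cascaded fully connected layers
ending in a sigmoid that outputs the probability of ATS (replan). Only the
FC parameters train, with binary cross-entropy; the encoder stays bitwise
identical to its source registration model.

The decision rule is strict: ATS iff probability > threshold (default 0.64,
the operating point balancing accuracy, sensitivity and specificity);
a probability exactly at the threshold yields ATP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, leaky_relu, sigmoid
from .dlir import RegistrationConfig, RegistrationModel, _minmax
from .io_preprocess import ROIMask
from .labeler import StrategyLabel
from .volume import Volume3D


@dataclass
class ClassifierConfig:
    """Head architecture and training recipe for the strategy classifier."""

    fc_hidden: int = 64
    learning_rate: float = 1e-5
    epochs: int = 300
    batch_size: int = 2
    # L2 penalty on the FC weights added to the BCE objective; 0 reproduces
    # the plain recipe, the desk preset enables it (hundreds of features vs
    # ~a hundred training fractions)
    weight_decay: float = 0.0
    decision_threshold: float = 0.64
    # bridge from the deepest encoder maps to the FC head: "flatten" keeps
    # the coarse spatial layout (measurably more label signal on phantom
    # cohorts), "gap" is the compact global-average alternative
    pooling: str = "flatten"
    standardize_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.pooling not in ("gap", "flatten"):
            raise ValueError("pooling must be 'gap' or 'flatten'")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "ClassifierConfig":
        """Preset for CPU runs: higher learning rate on the small FC head."""
        kw = dict(learning_rate=1e-3, epochs=300, batch_size=8,
                  weight_decay=3e-2, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PredictionResult:
    """Probability of ATS plus the thresholded strategy label."""

    probability: float
    label: StrategyLabel
    threshold_used: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        expected = StrategyLabel.ATS if self.probability > self.threshold_used else StrategyLabel.ATP
        if self.label != expected:
            raise ValueError("label inconsistent with probability and threshold")


def apply_roi(pair: Tuple[np.ndarray, np.ndarray], roi) -> np.ndarray:
    """Mask both channels of a (moving, fixed) pair with a binary ROI.

    Masking happens *before* intensity normalization, so voxels outside the
    ROI cannot influence the classifier at all. Returns the 2-channel array
    in encoder channel order (m, f).
    """
    moving, fixed = pair
    roi_data = roi.mask.data if isinstance(roi, ROIMask) else (
        roi.data if isinstance(roi, Volume3D) else np.asarray(roi))
    roi_bin = (np.asarray(roi_data) > 0.5).astype(np.float64)
    m = np.asarray(moving.data if isinstance(moving, Volume3D) else moving, dtype=np.float64)
    f = np.asarray(fixed.data if isinstance(fixed, Volume3D) else fixed, dtype=np.float64)
    if m.shape != f.shape or m.shape != roi_bin.shape:
        raise ValueError("pair and ROI must share a grid")
    if not roi_bin.any():
        raise ValueError("ROI mask is empty")
    return np.stack([_minmax(m * roi_bin), _minmax(f * roi_bin)])


def bce_loss(labels: Sequence[int], probs: Sequence[float], eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps]."""
    y = np.asarray([int(v) for v in labels], dtype=np.float64)
    p = np.asarray(probs, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


class StrategyClassifier:
    """Frozen registration encoder feeding a two-layer FC head."""

    def __init__(self, reg_model: RegistrationModel, config: ClassifierConfig):
        self.config = config
        self.reg_config: RegistrationConfig = reg_model.config
        self.encoder_signature = list(reg_model.encoder_signature)
        # frozen copies of the encoder parameters (never trained)
        self.encoder_params: Dict[str, Tensor] = {
            k: Tensor(v.data.copy(), requires_grad=False)
            for k, v in reg_model.params.items() if k.startswith("enc")
        }
        self._encoder_snapshot = {k: v.data.copy() for k, v in self.encoder_params.items()}
        self._n_features: Optional[int] = None
        self.fc_params: Dict[str, Tensor] = {}
        self.feature_mean: Optional[np.ndarray] = None
        self.feature_std: Optional[np.ndarray] = None

    # -- encoder ------------------------------------------------------------
    def verify_frozen(self) -> bool:
        """Bitwise check that encoder parameters never changed."""
        return all(
            np.array_equal(self.encoder_params[k].data, v)
            for k, v in self._encoder_snapshot.items()
        )

    def _encoder_deepest(self, x2ch: np.ndarray) -> np.ndarray:
        cfg = self.reg_config
        x = Tensor(np.asarray(x2ch, dtype=np.dtype(cfg.dtype)))
        from .autodiff import conv3d  # local to avoid a cycle at import time

        for lvl in range(cfg.n_levels):
            x = leaky_relu(
                conv3d(x, self.encoder_params[f"enc{lvl}.w"],
                       self.encoder_params[f"enc{lvl}.b"], stride=cfg.stride),
                cfg.leaky_relu_alpha,
            )
        return np.asarray(x.data, dtype=np.float64)

    def extract_features(self, x2ch: np.ndarray) -> np.ndarray:
        """Deepest encoder features pooled to the head's input vector."""
        feats = self._encoder_deepest(x2ch)
        if self.config.pooling == "gap":
            vec = feats.mean(axis=(1, 2, 3))
        else:
            vec = feats.ravel()
        if self._n_features is None:
            self._n_features = vec.size
            self._init_head(vec.size)
        elif vec.size != self._n_features:
            raise ValueError(
                f"encoder produced {vec.size} features but the head expects "
                f"{self._n_features}: input shape mismatch"
            )
        return vec

    # -- head ---------------------------------------------------------------
    def _init_head(self, n_features: int) -> None:
        rng = np.random.default_rng(self.config.seed + 10)
        h = self.config.fc_hidden
        self.fc_params = {
            "fc1.w": Tensor(rng.normal(0, np.sqrt(2.0 / n_features), (n_features, h)),
                            requires_grad=True),
            "fc1.b": Tensor(np.zeros(h), requires_grad=True),
            "fc2.w": Tensor(rng.normal(0, np.sqrt(1.0 / h), (h, 1)), requires_grad=True),
            "fc2.b": Tensor(np.zeros(1), requires_grad=True),
        }

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return feats
        return (feats - self.feature_mean) / self.feature_std

    def head_forward(self, feats: np.ndarray) -> Tensor:
        """FC head on a (batch, n_features) matrix -> (batch,) probability."""
        z = Tensor(np.atleast_2d(self._standardize(feats)))
        h = leaky_relu(z @ self.fc_params["fc1.w"] + self.fc_params["fc1.b"],
                       self.reg_config.leaky_relu_alpha)
        logits = h @ self.fc_params["fc2.w"] + self.fc_params["fc2.b"]
        return sigmoid(logits.reshape((logits.data.shape[0],)))

    def n_trainable_parameters(self) -> int:
        return int(sum(p.data.size for p in self.fc_params.values()))

    def predict_probability(self, x2ch: np.ndarray) -> float:
        return float(self.head_forward(self.extract_features(x2ch)).data[0])

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"enc__{k.replace('.', '_')}": v.data for k, v in self.encoder_params.items()}
        arrays.update({f"fc__{k.replace('.', '_')}": v.data for k, v in self.fc_params.items()})
        if self.feature_mean is not None:
            arrays["feature_mean"] = self.feature_mean
            arrays["feature_std"] = self.feature_std
        meta = {"config": asdict(self.config), "reg_config": asdict(self.reg_config),
                "n_features": self._n_features}
        np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "StrategyClassifier":
        with np.load(Path(path)) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            reg_cfg = RegistrationConfig(**meta["reg_config"])
            reg_model = RegistrationModel(reg_cfg)
            clf = cls(reg_model, ClassifierConfig(**meta["config"]))
            for k in list(clf.encoder_params):
                clf.encoder_params[k].data = npz[f"enc__{k.replace('.', '_')}"].copy()
            clf._encoder_snapshot = {k: v.data.copy() for k, v in clf.encoder_params.items()}
            if meta["n_features"] is not None:
                clf._init_head(int(meta["n_features"]))
                clf._n_features = int(meta["n_features"])
                for k in list(clf.fc_params):
                    clf.fc_params[k].data = npz[f"fc__{k.replace('.', '_')}"].copy()
            if "feature_mean" in npz:
                clf.feature_mean = npz["feature_mean"].copy()
                clf.feature_std = npz["feature_std"].copy()
        return clf


def build_classifier(reg_model: RegistrationModel, config: ClassifierConfig
                     ) -> StrategyClassifier:
    """Copy and freeze the registration encoder; attach an untrained head."""
    return StrategyClassifier(reg_model, config)


def _case_input(case) -> np.ndarray:
    return apply_roi((case.moving, case.fixed), case.roi_mask)


def train_dlsp(classifier: StrategyClassifier, cases: Sequence, config: ClassifierConfig
               ) -> Tuple[StrategyClassifier, List[float]]:
    """Train the FC head on labeled cases; the encoder never moves.

    Encoder features are extracted once per case (the encoder is frozen, so
    recomputation per epoch would be wasted work), optionally standardized
    with training-set statistics stored in the classifier, then the head is
    optimized with Adam on mean BCE. Returns the classifier and the
    per-epoch BCE history.
    """
    labels = np.array([int(c.label) for c in cases], dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        warnings.warn("single-class training set: downstream AUC is undefined",
                      stacklevel=2)
    feats = np.stack([classifier.extract_features(_case_input(c)) for c in cases])
    if config.standardize_features:
        classifier.feature_mean = feats.mean(axis=0)
        classifier.feature_std = feats.std(axis=0) + 1e-8
    opt = Adam(classifier.fc_params.values(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 20)
    eps = 1e-7
    history: List[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(cases))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            p = classifier.head_forward(feats[idx])
            y = labels[idx]
            pc = p * (1.0 - 2 * eps) + eps
            bce = (Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).mean() * -1.0
            loss = bce
            if config.weight_decay > 0:
                w1, w2 = classifier.fc_params["fc1.w"], classifier.fc_params["fc2.w"]
                loss = loss + config.weight_decay * ((w1 * w1).mean() + (w2 * w2).mean())
            loss.backward()
            opt.step()
            epoch_losses.append(float(bce.data))  # history tracks the BCE itself
        history.append(float(np.mean(epoch_losses)))
    if not classifier.verify_frozen():
        raise RuntimeError("encoder parameters changed during DLSP training")
    return classifier, history


def predict(classifier: StrategyClassifier, case, threshold: Optional[float] = None
            ) -> PredictionResult:
    """Probability + strategy for one case; ATS iff p > threshold (ties ATP)."""
    thr = classifier.config.decision_threshold if threshold is None else float(threshold)
    p = classifier.predict_probability(_case_input(case))
    label = StrategyLabel.ATS if p > thr else StrategyLabel.ATP
    return PredictionResult(probability=p, label=label, threshold_used=thr)
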