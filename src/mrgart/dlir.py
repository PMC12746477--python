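"""Unsupervised multimodal deformable image registration (DLIR).

A 3D U-Net ``g_theta(f, m)`` maps a 2-channel volume (moving reference image
``m`` concatenated with fixed daily image ``f``) to a dense displacement
field ``u`` on the fixed grid; a trilinear spatial transformer warps ``m``
into ``w(x) = m(x + u(x))``. Training minimizes

    L = -MI(f, w) + lambda1 * L_smooth(u) + lambda2 * L2(u)

where MI is mutual information over the intensity joint distribution (the
similarity that survives a modality change, unlike intensity differences),
``L_smooth`` is the summed squared forward-difference gradient of ``u`` and
``L2`` the summed squared displacement. The differentiable training
estimator of MI uses Gaussian Parzen soft-binning; an exact hard-binned
estimator with identical bin edges serves as its oracle and as the
reporting/e valuation path.

Defaults follow the clinical recipe: 4 encoder/decoder levels, kernel 3,
stride 2, LeakyReLU(0.2), linear field head, lambda1 = 1e-2,
lambda2 = 1e-5, Adam at 1e-4 for 200 epochs with batch size 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, concat, conv3d, leaky_relu, upsample2, warp_trilinear
from .volume import DisplacementField, Volume3D


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Architecture and training hyper-parameters of the registration net."""

    n_levels: int = 4
    kernel_size: int = 3
    stride: int = 2
    base_channels: int = 8
    leaky_relu_alpha: float = 0.2
    lambda1: float = 1e-2
    lambda2: float = 1e-5
    mi_bins: int = 32
    mi_sigma_ratio: float = 1.0  # Parzen kernel width as a fraction of bin width
    # Gaussian pre-smoothing (voxels) of both images inside the MI loss only;
    # damps the sub-voxel interpolation artifact of MI registration and
    # widens the capture range (network input stays unsmoothed)
    mi_presmooth_vox: float = 0.0
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 1
    seed: int = 0
    dtype: str = "float32"
    # divide the summed regularizers by the voxel count inside the training
    # objective so the lambda weights are grid-size independent; the public
    # total_loss keeps the raw sums
    normalize_regularizers: bool = True
    # instance-specific refinement at inference: after the amortized forward
    # pass, optimize the predicted field per case against the same objective
    # (0 disables; used by the desk-scale preset where the amortized network
    # alone cannot close the registration within the short training budget)
    refine_steps: int = 0
    refine_lr: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be non-negative")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.refine_steps < 0:
            raise ValueError("refine_steps must be non-negative")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 30, **overrides) -> "RegistrationConfig":
        """Preset for small-volume CPU runs (64x64x32 grids).

        Raises the learning rate so the short epoch budget suffices, uses
        per-voxel regularizer weights calibrated for desk-scale intensity
        statistics (see docs/methods.md), sharpens the Parzen kernel, and
        enables instance-specific refinement at inference.
        """
        kw = dict(base_channels=8, mi_bins=32, mi_sigma_ratio=0.5,
                  mi_presmooth_vox=1.0, lambda1=1.0, lambda2=3e-2,
                  learning_rate=1e-3, epochs=epochs, seed=seed,
                  refine_steps=150, refine_lr=0.1)
        kw.update(overrides)
        return cls(**kw)

    def validate_shape(self, shape: Sequence[int]) -> None:
        div = self.stride**self.n_levels
        for ax, s in enumerate(shape):
            if s % div != 0:
                raise ValueError(
                    f"input axis {ax} has size {s}, not divisible by "
                    f"stride^n_levels = {div}"
                )


def encoder_output_shape(input_shape: Sequence[int], n_levels: int = 4,
                         stride: int = 2) -> Tuple[int, ...]:
    """Spatial shape of the deepest encoder feature maps (halving per level)."""
    shape = list(input_shape)
    for _ in range(n_levels):
        shape = [s // stride for s in shape]
    return tuple(shape)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class RegistrationModel:
    """U-Net registration network with parameters held as autodiff tensors."""

    def __init__(self, config: RegistrationConfig):
        self.config = config
        c = config.base_channels
        self.enc_channels: List[int] = [c] + [2 * c] * (config.n_levels - 1)
        self.dec_channels: List[int] = [2 * c] * (config.n_levels - 1) + [c]
        self.params: Dict[str, Tensor] = {}
        self.encoder_signature: List[Dict[str, int]] = []
        self._init_params()

    # -- construction -------------------------------------------------------
    def _add_conv(self, name: str, cin: int, cout: int, rng, head: bool = False) -> None:
        k = self.config.kernel_size
        fan_in = cin * k**3
        std = 1e-3 if head else np.sqrt(2.0 / fan_in)
        dt = np.dtype(self.config.dtype)
        w = rng.normal(0.0, std, size=(cout, cin, k, k, k)).astype(dt)
        b = np.zeros(cout, dtype=dt)
        self.params[f"{name}.w"] = Tensor(w, requires_grad=True)
        self.params[f"{name}.b"] = Tensor(b, requires_grad=True)

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        cin = 2
        for lvl, cout in enumerate(self.enc_channels):
            self._add_conv(f"enc{lvl}", cin, cout, rng)
            self.encoder_signature.append(
                {"layer": lvl, "in_channels": cin, "out_channels": cout,
                 "kernel": cfg.kernel_size, "stride": cfg.stride}
            )
            cin = cout
        skip = list(reversed(self.enc_channels[:-1])) + [2]  # encoder skips, then input
        for lvl, cout in enumerate(self.dec_channels):
            self._add_conv(f"dec{lvl}", cin + skip[lvl], cout, rng)
            cin = cout
        self._add_conv("field_head", cin, 3, rng, head=True)

    # -- forward ------------------------------------------------------------
    def _conv(self, name: str, x: Tensor, stride: int) -> Tensor:
        return conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], stride=stride)

    def encoder_forward(self, x: Tensor) -> List[Tensor]:
        """All encoder feature maps, shallowest to deepest."""
        cfg = self.config
        feats = []
        for lvl in range(cfg.n_levels):
            x = leaky_relu(self._conv(f"enc{lvl}", x, cfg.stride), cfg.leaky_relu_alpha)
            feats.append(x)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        """2-channel (m, f) input -> 3-component displacement field tensor."""
        cfg = self.config
        self.config.validate_shape(x.data.shape[1:])
        feats = self.encoder_forward(x)
        skips = list(reversed(feats[:-1])) + [x]
        z = feats[-1]
        for lvl in range(cfg.n_levels):
            z = upsample2(z)
            z = concat([z, skips[lvl]], axis=0)
            z = leaky_relu(self._conv(f"dec{lvl}", z, 1), cfg.leaky_relu_alpha)
        return self._conv("field_head", z, 1)  # linear activation

    def make_input(self, fixed: np.ndarray, moving: np.ndarray) -> Tensor:
        """Min-max normalize each image and stack as channels (m, f)."""
        dt = np.dtype(self.config.dtype)
        return Tensor(np.stack([_minmax(moving), _minmax(fixed)]).astype(dt))

    # -- persistence --------------------------------------------------------
    def parameter_arrays(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def save(self, path: str | Path) -> None:
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(Path(path), __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RegistrationModel":
        with np.load(Path(path)) as npz:
            cfg = RegistrationConfig(**json.loads(bytes(npz["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k].data = npz[k.replace(".", "__")].copy()
        return model


def build_network(config: RegistrationConfig) -> RegistrationModel:
    """Construct the U-Net with deterministic seeded initialization."""
    return RegistrationModel(config)


# ---------------------------------------------------------------------------
# spatial transformer
# ---------------------------------------------------------------------------


def warp(moving: Volume3D, field: DisplacementField) -> Volume3D:
    """Warp ``moving`` by ``field``: ``w(x) = m(x + u(x))``, border-clamped.

    Trilinear interpolation; exact at integer grid points (a zero field is
    the identity). Mask volumes are re-thresholded to stay binary.
    """
    if moving.shape != field.grid_shape:
        raise ValueError(f"shape mismatch: moving {moving.shape} vs field {field.grid_shape}")
    m = np.asarray(moving.data, dtype=np.float64)
    out = warp_trilinear(m, Tensor(np.asarray(field.u, dtype=np.float64))).data
    if moving.modality == "mask":
        out = (out > 0.5).astype(np.float64)
    return moving.with_data(out)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


@dataclass
class IntensityJointDistribution:
    """Binned joint intensity distribution of a fixed/warped image pair."""

    joint: np.ndarray
    marginal_f: np.ndarray
    marginal_w: np.ndarray
    bin_edges_f: np.ndarray
    bin_edges_w: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.joint.sum(), 1.0, atol=1e-6):
            raise ValueError("joint distribution must sum to 1")
        if np.any(self.joint < -1e-12):
            raise ValueError("joint distribution must be non-negative")
        if not (np.allclose(self.marginal_f, self.joint.sum(axis=1), atol=1e-9)
                and np.allclose(self.marginal_w, self.joint.sum(axis=0), atol=1e-9)):
            raise ValueError("marginals must equal the joint's row/column sums")


def _minmax(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-12:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def _as_array(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume3D) else v, dtype=np.float64)


def _dist_from_joint(joint: np.ndarray, edges: np.ndarray) -> IntensityJointDistribution:
    return IntensityJointDistribution(
        joint=joint, marginal_f=joint.sum(axis=1), marginal_w=joint.sum(axis=0),
        bin_edges_f=edges, bin_edges_w=edges,
    )


def mutual_information_hard(
    f, w, bins: int = 32, mask: Optional[np.ndarray] = None
) -> Tuple[float, IntensityJointDistribution]:
    """Exact hard-binned MI in nats over min-max normalized intensities.

    This is the test oracle for the differentiable Parzen estimator and the
    reporting estimator; ``mask`` restricts the voxel population.
    """
    fa, wa = _as_array(f).ravel(), _as_array(w).ravel()
    if fa.shape != wa.shape:
        raise ValueError("shape mismatch between images")
    if mask is not None:
        mask = np.asarray(mask).astype(bool).ravel()
        if not mask.any():
            raise ValueError("empty mask")
        fa, wa = fa[mask], wa[mask]
    fn, wn = _minmax(fa), _minmax(wa)
    edges = np.linspace(0.0, 1.0, bins + 1)
    if np.ptp(fa) < 1e-12 or np.ptp(wa) < 1e-12:
        # a flat image carries no information: MI is exactly zero
        joint, _, _ = np.histogram2d(fn, wn, bins=[edges, edges])
        return 0.0, _dist_from_joint(joint / joint.sum(), edges)
    joint, _, _ = np.histogram2d(fn, wn, bins=[edges, edges])
    joint /= joint.sum()
    pf, pw = joint.sum(axis=1), joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pf, pw)
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    return max(mi, 0.0), _dist_from_joint(joint, edges)


def _parzen_weights(v: np.ndarray, bins: int, sigma_ratio: float) -> np.ndarray:
    centers = (np.arange(bins) + 0.5) / bins
    sigma = sigma_ratio / bins
    k = np.exp(-0.5 * ((v[:, None] - centers[None, :]) / sigma) ** 2)
    return k / k.sum(axis=1, keepdims=True)


def _parzen_mi_fused(wn: Tensor, wf_over_n: np.ndarray, bins: int,
                     sigma: float, eps: float) -> Tensor:
    """Parzen MI of normalized intensities ``wn`` against fixed-image soft
    weights ``wf_over_n`` (shape (n, bins), rows already divided by n), as a
    single op with an analytic backward pass (the op-by-op graph would
    materialize many (n, bins) temporaries)."""
    dt = wn.data.dtype
    centers = ((np.arange(bins) + 0.5) / bins).astype(dt)
    v = wn.data
    d = v[:, None] - centers[None, :]
    k = np.exp(d * d * (-0.5 / sigma**2))
    s = k.sum(axis=1, keepdims=True)
    ww = k / s
    joint = wf_over_n.T @ ww  # (bins, bins), rows ~ f, cols ~ w
    pf = joint.sum(axis=1, keepdims=True)
    pw = joint.sum(axis=0, keepdims=True)
    log_term = np.log(joint + eps) - np.log(pf * pw + eps)
    mi = float((joint * log_term).sum())

    def bwd(g):
        # d mi / d joint, accounting for the marginals' dependence on joint
        a = (joint * (pw / (pf * pw + eps))).sum(axis=1, keepdims=True)
        b = (joint * (pf / (pf * pw + eps))).sum(axis=0, keepdims=True)
        djoint = log_term + joint / (joint + eps) - a - b
        gww = wf_over_n @ djoint  # (n, bins)
        # through the row-normalized Gaussian assignment
        dk = gww / s - ((gww * k).sum(axis=1, keepdims=True)) / (s * s)
        dwn = (dk * k * (-d / sigma**2)).sum(axis=1)  # dK/dwn = K*(c-v)/sigma^2
        wn._accum(np.asarray(g) * dwn.astype(dt))

    return Tensor._result(np.asarray(mi, dtype=dt), (wn,), bwd)


def soft_mutual_information_tensor(
    f_arr: np.ndarray, w: Tensor, bins: int = 32, sigma_ratio: float = 1.0,
    eps: float = 1e-10, mask: Optional[np.ndarray] = None,
    f_weights: Optional[np.ndarray] = None
) -> Tensor:
    """Differentiable Parzen-window MI of a constant ``f`` and a tensor ``w``.

    Both images are min-max normalized (the normalization constants of ``w``
    are treated as stop-gradient); intensities are softly assigned to
    ``bins`` Gaussian kernels of width ``sigma_ratio`` bin widths; the joint
    distribution is the normalized product of the two assignment matrices.
    As ``sigma_ratio -> 0`` this approaches the hard-binned estimator.
    ``f_weights`` may carry the precomputed ``(n, bins)`` soft-assignment
    matrix of ``f`` divided by ``n`` (it is constant across optimization
    steps; see :func:`precompute_f_weights`).
    """
    n_total = f_arr.size
    lo, hi = float(w.data.min()), float(w.data.max())
    if hi - lo < 1e-12:
        return Tensor(np.zeros((), dtype=w.data.dtype))
    wflat = w.reshape((n_total,))
    if mask is not None:
        idx = np.flatnonzero(np.asarray(mask).ravel())
        if idx.size == 0:
            raise ValueError("empty mask")
        wflat = wflat[idx]
    if f_weights is None:
        f_weights = precompute_f_weights(f_arr, bins, sigma_ratio, mask=mask,
                                         dtype=w.data.dtype)
    wn = (wflat - lo) * (1.0 / (hi - lo))
    sigma = sigma_ratio / bins
    return _parzen_mi_fused(wn, f_weights, bins, sigma, eps)


def precompute_f_weights(f_arr: np.ndarray, bins: int, sigma_ratio: float,
                         mask: Optional[np.ndarray] = None,
                         dtype=np.float32) -> np.ndarray:
    """Soft-assignment matrix of the fixed image, rows divided by n."""
    fn = _minmax(np.asarray(f_arr, dtype=np.float64).ravel())
    if mask is not None:
        fn = fn[np.flatnonzero(np.asarray(mask).ravel())]
    return (_parzen_weights(fn, bins, sigma_ratio) / fn.size).astype(dtype)


def mutual_information(
    f, w, bins: int = 32, mask: Optional[np.ndarray] = None,
    estimator: str = "hard", sigma_ratio: float = 1.0,
) -> Tuple[float, IntensityJointDistribution]:
    """MI between fixed and warped images, with its joint distribution.

    ``estimator='hard'`` is the exact binned value; ``'soft'`` evaluates the
    differentiable Parzen estimate used by training (same bin edges).
    """
    if estimator == "hard":
        return mutual_information_hard(f, w, bins=bins, mask=mask)
    if estimator != "soft":
        raise ValueError(f"unknown estimator {estimator!r}")
    fa, wa = _as_array(f), _as_array(w)
    if fa.shape != wa.shape:
        raise ValueError("shape mismatch between images")
    mi = soft_mutual_information_tensor(
        fa, Tensor(wa), bins=bins, sigma_ratio=sigma_ratio,
        mask=mask,
    )
    # joint under the same soft weights, for inspection
    fn = _minmax(fa.ravel())
    wn = _minmax(wa.ravel())
    if mask is not None:
        sel = np.asarray(mask).astype(bool).ravel()
        fn, wn = fn[sel], wn[sel]
    wf = _parzen_weights(fn, bins, sigma_ratio)
    ww = _parzen_weights(wn, bins, sigma_ratio)
    joint = wf.T @ ww / fn.size
    edges = np.linspace(0.0, 1.0, bins + 1)
    return float(mi.data), _dist_from_joint(joint, edges)


# ---------------------------------------------------------------------------
# field regularizers
# ---------------------------------------------------------------------------


def _field_array(field) -> np.ndarray:
    u = field.u if isinstance(field, DisplacementField) else np.asarray(field)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError(f"expected field of shape (3, nx, ny, nz), got {u.shape}")
    return np.asarray(u, dtype=np.float64)


def smoothness_loss(field) -> float:
    """Sum of squared forward-difference spatial gradients of ``u``.

    The last voxel along each axis contributes a zero difference (zero
    padding of the gradient), so only interior forward differences count.
    """
    u = _field_array(field)
    total = 0.0
    for ax in range(1, 4):
        d = np.diff(u, axis=ax)
        total += float(np.sum(d * d))
    return total


def l2_penalty(field) -> float:
    """Sum of squared displacement components over all voxels."""
    u = _field_array(field)
    return float(np.sum(u * u))


def _smoothness_tensor(u: Tensor) -> Tensor:
    dx = u[:, 1:, :, :] - u[:, :-1, :, :]
    dy = u[:, :, 1:, :] - u[:, :, :-1, :]
    dz = u[:, :, :, 1:] - u[:, :, :, :-1]
    return (dx * dx).sum() + (dy * dy).sum() + (dz * dz).sum()


def total_loss(f, m, field, config: RegistrationConfig,
               estimator: str = "hard") -> Tuple[float, Dict[str, float]]:
    """Registration objective ``-MI(f, warp(m, u)) + l1*smooth + l2*L2``.

    Computed over entire volumes (no ROI masking during registration
    training); components are returned for logging. The ``estimator``
    selects the MI flavour; the regularizer terms are the raw voxel sums.
    """
    u = _field_array(field)
    fa, ma = _as_array(f), _as_array(m)
    if fa.shape != ma.shape or fa.shape != u.shape[1:]:
        raise ValueError("inconsistent shapes between images and field")
    w = warp_trilinear(ma, Tensor(u)).data
    mi, _ = mutual_information(fa, w, bins=config.mi_bins, estimator=estimator,
                               sigma_ratio=config.mi_sigma_ratio)
    smooth = smoothness_loss(u)
    l2 = l2_penalty(u)
    value = -mi + config.lambda1 * smooth + config.lambda2 * l2
    return value, {"similarity": -mi, "smoothness": smooth, "l2": l2,
                   "mi": mi, "total": value}


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------


def _presmooth(arr: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return arr
    from scipy import ndimage

    return ndimage.gaussian_filter(arr, sigma_vox).astype(arr.dtype)


def _prep_case(model: RegistrationModel, f_arr: np.ndarray, m_arr: np.ndarray):
    """Per-case constants for the training loss: network input, presmoothed
    moving channel, and the fixed channel's cached Parzen weights."""
    cfg = model.config
    x = model.make_input(f_arr, m_arr)  # channels (m, f), min-max normalized
    m_pre = _presmooth(x.data[0], cfg.mi_presmooth_vox)
    f_pre = _presmooth(x.data[1], cfg.mi_presmooth_vox)
    fw = precompute_f_weights(f_pre, cfg.mi_bins, cfg.mi_sigma_ratio,
                              dtype=x.data.dtype)
    return x, m_pre, f_pre, fw


def _training_loss(model: RegistrationModel, x: Tensor, m_pre: np.ndarray,
                   f_pre: np.ndarray, fw: np.ndarray) -> Tensor:
    cfg = model.config
    u = model.forward(x)
    w = warp_trilinear(m_pre, u)
    mi = soft_mutual_information_tensor(
        f_pre, w, bins=cfg.mi_bins, sigma_ratio=cfg.mi_sigma_ratio, f_weights=fw)
    smooth = _smoothness_tensor(u)
    l2 = (u * u).sum()
    scale = 1.0 / float(x.data[0].size) if cfg.normalize_regularizers else 1.0
    return (-1.0) * mi + (cfg.lambda1 * scale) * smooth + (cfg.lambda2 * scale) * l2


def train_dlir(cases: Sequence, config: RegistrationConfig,
               model: Optional[RegistrationModel] = None
               ) -> Tuple[RegistrationModel, List[float]]:
    """Train the registration network on synthetic or preprocessed cases.

    ``cases`` must expose ``.fixed`` and ``.moving`` :class:`Volume3D`
    attributes on a common grid. Returns the trained model and the per-epoch
    mean loss history; identical seeds give identical trajectories.
    """
    if len(cases) < 1:
        raise ValueError("need at least one training case")
    shape = cases[0].fixed.shape
    config.validate_shape(shape)
    if model is None:
        model = build_network(config)
    pairs = [_prep_case(model, np.asarray(c.fixed.data, np.float64),
                        np.asarray(c.moving.data, np.float64)) for c in cases]
    opt = Adam(model.params.values(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: List[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                loss = _training_loss(model, *pairs[i])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {_epoch}, case {i}: "
                        f"{float(loss.data)!r}"
                    )
                loss.backward(np.asarray(1.0 / len(batch), dtype=loss.data.dtype))
                losses.append(float(loss.data))
            opt.step()
        history.append(float(np.mean(losses)))
    return model, history


def instance_refine(f_arr: np.ndarray, m_arr: np.ndarray, u_init: np.ndarray,
                    config: RegistrationConfig,
                    steps: Optional[int] = None) -> np.ndarray:
    """Optimize a displacement field per case against the training objective.

    Starting from ``u_init`` (typically the amortized network prediction),
    Adam minimizes the same soft-MI + regularizer objective for this single
    pair. Deterministic (no randomness is involved); used at inference when
    ``config.refine_steps > 0``.
    """
    steps = config.refine_steps if steps is None else int(steps)
    dt = np.dtype(config.dtype)
    fn = _presmooth(_minmax(f_arr), config.mi_presmooth_vox).astype(dt)
    mn = _presmooth(_minmax(m_arr), config.mi_presmooth_vox).astype(dt)
    fw = precompute_f_weights(fn, config.mi_bins, config.mi_sigma_ratio, dtype=dt)
    u = Tensor(np.asarray(u_init, dtype=dt), requires_grad=True)
    opt = Adam([u], lr=config.refine_lr)
    n = float(np.prod(f_arr.shape))
    for _ in range(steps):
        opt.zero_grad()
        w = warp_trilinear(mn, u)
        mi = soft_mutual_information_tensor(fn, w, bins=config.mi_bins,
                                            sigma_ratio=config.mi_sigma_ratio,
                                            f_weights=fw)
        loss = ((-1.0) * mi + (config.lambda1 / n) * _smoothness_tensor(u)
                + (config.lambda2 / n) * (u * u).sum())
        loss.backward()
        opt.step()
    return u.data.astype(np.float64)


def register(model: RegistrationModel, fixed: Volume3D, moving: Volume3D,
             refine_steps: Optional[int] = None
             ) -> Tuple[DisplacementField, Volume3D]:
    """Estimate the displacement field for a pair and warp the moving image.

    The amortized network prediction ``g_theta(f, m)`` is optionally
    followed by deterministic instance-specific refinement of the same
    objective (``refine_steps`` overrides the model config; 0 disables).
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving volumes must share a grid")
    model.config.validate_shape(fixed.shape)
    f_arr = np.asarray(fixed.data, np.float64)
    m_arr = np.asarray(moving.data, np.float64)
    x = model.make_input(f_arr, m_arr)
    u = model.forward(x)
    u_arr = u.data.astype(np.float64)
    steps = model.config.refine_steps if refine_steps is None else int(refine_steps)
    if steps > 0:
        u_arr = instance_refine(f_arr, m_arr, u_arr, model.config, steps)
    field = DisplacementField(u_arr, spacing=fixed.spacing)
    return field, warp(moving, field)
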