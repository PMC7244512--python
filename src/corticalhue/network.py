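"""The hierarchical hue-processing network: mLGN, mV1, mV2 and mV4 layers.

Each layer applies Gaussian receptive fields (normalized kernels, edge
replication at borders) followed by a piecewise-linear rectifier.  mLGN
cells are single-opponent differences of centre and surround cone drives and
operate in the linear regime (tau = -1).  mV1 half-wave rectifies smoothed
mLGN signals.  mV2 contains the six single-opponent ("additive") types plus
eight multiplicative types formed by gating an L/M-opponent mV1 signal with
an S-opponent mV1 signal.  mV4 cells are rectified weighted sums of all 14
mV2 types, with weights given by a Gaussian of the distance between each
mV2 cell's tuning-peak hue and the mV4 cell's target hue on the MB circle.

Because every kernel is normalized and borders replicate the edge pixel,
spatially uniform stimuli propagate through the cascade as per-pixel algebra.
:meth:`HueModel.centre_responses` exploits this closed form; it is exactly the
model evaluated on a uniform field (the equivalence is covered by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colourspace import hsl_to_rgb, mb_hue_angle, rgb_to_lms
from .config import (
    MLGN_TYPES,
    MV2_ADDITIVE_TYPES,
    MV2_MULTIPLICATIVE_TYPES,
    MV2_TYPES,
    MV4_TYPES,
    LayerConfig,
    OpponentCellSpec,
    RectifierParams,
    default_config,
    default_opponent_specs,
)
from .errors import ConfigError, InputDomainError
from .stimuli import hue_circle_samples

__all__ = [
    "LayerResponses",
    "V4WeightMatrix",
    "rectify",
    "gaussian_kernel",
    "convolve_gaussian",
    "mlgn_response",
    "mv1_response",
    "mv2_additive",
    "mv2_multiplicative",
    "mv2_pooling",
    "compute_mv4_weights",
    "mv4_response",
    "HueModel",
]


@dataclass
class LayerResponses:
    """Named, ordered collection of 2-D response maps for one model layer."""

    layer_name: str
    maps: dict

    def __getitem__(self, label: str) -> np.ndarray:
        return self.maps[label]

    @property
    def labels(self) -> tuple:
        return tuple(self.maps)

    def stack(self) -> np.ndarray:
        return np.stack(list(self.maps.values()))


@dataclass
class V4WeightMatrix:
    """mV2 -> mV4 weights w (6 x 14, rows sum to 1) and peak distances d (deg)."""

    w: np.ndarray
    d: np.ndarray
    row_labels: tuple = MV4_TYPES
    col_labels: tuple = MV2_TYPES


def rectify(p, params: RectifierParams):
    """Piecewise-linear rectifier: tau below threshold, m*p + b in the linear
    band, and 1 above the saturation threshold."""
    v = params.m * np.asarray(p, float) + params.b
    return np.where(v < params.tau, params.tau, np.where(v <= params.s, v, 1.0))


def _kernel_1d(sigma: float, size: int) -> np.ndarray:
    x = np.arange(size, dtype=float) - (size - 1) / 2.0
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel of odd side ``size`` whose entries sum to 1."""
    if sigma <= 0:
        raise InputDomainError("sigma must be > 0")
    if size <= 0 or size % 2 == 0:
        raise InputDomainError("kernel size must be a positive odd integer")
    g = _kernel_1d(sigma, size)
    k = np.outer(g, g)
    return k / k.sum()


def _check_kernel_fits(size: int, shape) -> None:
    if size > min(shape[:2]):
        raise ConfigError(
            f"kernel side {size} exceeds image size {tuple(shape[:2])}"
        )


def convolve_gaussian(img: np.ndarray, sigma: float, size: int) -> np.ndarray:
    """Same-size convolution with a normalized Gaussian, edge-replication padding.

    Separable implementation; matches a direct windowed sum with replicated
    borders to floating-point accuracy.
    """
    if size % 2 == 0:
        raise InputDomainError("kernel size must be odd")
    _check_kernel_fits(size, img.shape)
    g = _kernel_1d(sigma, size)
    out = ndimage.convolve1d(np.asarray(img, float), g, axis=0, mode="nearest")
    return ndimage.convolve1d(out, g, axis=1, mode="nearest")


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def mlgn_response(
    cones: np.ndarray, spec: OpponentCellSpec, rect: RectifierParams
) -> np.ndarray:
    """Single-opponent mLGN map: rectified difference of centre and surround
    cone drives, each cone convolved with its own Gaussian spread."""
    spec.validate()
    size = _odd(spec.rf_size)
    _check_kernel_fits(size, cones.shape)
    h, w = cones.shape[:2]
    acc = np.zeros((h, w))
    for i in range(3):
        if spec.centre_weights[i] != 0.0:
            acc += spec.centre_weights[i] * convolve_gaussian(
                cones[..., i], spec.centre_sigmas[i], size
            )
        if spec.surround_weights[i] != 0.0:
            acc -= spec.surround_weights[i] * convolve_gaussian(
                cones[..., i], spec.surround_sigmas[i], size
            )
    return rectify(spec.sign * acc, rect)


def mv1_response(lgn_map: np.ndarray, cfg: LayerConfig) -> np.ndarray:
    """mV1 map: Gaussian smoothing of an mLGN map, then half-wave rectification."""
    size = _odd(cfg.rf_sizes["mV1"])
    return rectify(convolve_gaussian(lgn_map, cfg.sigma_mv1, size), cfg.rectifier)


def _smooth_mv2(v1_map: np.ndarray, cfg: LayerConfig) -> np.ndarray:
    return convolve_gaussian(v1_map, cfg.sigma_mv2, _odd(cfg.rf_sizes["mV2"]))


def mv2_additive(v1_map: np.ndarray, cfg: LayerConfig) -> np.ndarray:
    """Single-opponent mV2 map: like mV1 but with the larger mV2 receptive field."""
    return rectify(_smooth_mv2(v1_map, cfg), cfg.rectifier)


def mv2_multiplicative(
    v1_lm_map: np.ndarray,
    v1_s_map: np.ndarray,
    cfg: LayerConfig,
    gain: float = 1.0,
) -> np.ndarray:
    """Multiplicative mV2 map: elementwise product of the smoothed L/M-opponent
    and S-opponent mV1 maps, amplified by ``gain``, then rectified."""
    if v1_lm_map.shape != v1_s_map.shape:
        raise InputDomainError("factor maps must have identical shapes")
    prod = _smooth_mv2(v1_lm_map, cfg) * _smooth_mv2(v1_s_map, cfg)
    return rectify(gain * prod, cfg.rectifier)


def mv2_pooling(
    v2_additive_map: np.ndarray, cfg: LayerConfig, threshold: float
) -> np.ndarray:
    """Pooled mV2 variant: window-averaged same-type single-opponent responses
    passed through the rectifier with a subtractive threshold (iceberg).

    The windowed sum over a ``pooling_window`` x ``pooling_window``
    neighbourhood is normalized by the window area (slope 1/k^2), the
    threshold is subtracted (base rate -threshold), and the result is
    half-wave rectified: only the tip of the pooled tuning curve survives,
    narrowing the apparent selectivity without moving peak positions.
    """
    k = cfg.pooling_window
    _check_kernel_fits(k, v2_additive_map.shape)
    pooled = ndimage.uniform_filter(np.asarray(v2_additive_map, float), size=k, mode="nearest")
    rect = RectifierParams(m=1.0, b=-threshold, tau=0.0, s=cfg.rectifier.s)
    return rectify(pooled, rect)


def compute_mv4_weights(
    v2_peak_hues: np.ndarray, targets_deg: np.ndarray, sigma: float
) -> V4WeightMatrix:
    """Gaussian-of-distance weights from 14 mV2 peak hues to 6 target hues.

    Both peak hues and targets are MB-plane angles in degrees.  Each row is
    normalized to sum to 1.
    """
    if sigma <= 0:
        raise InputDomainError("sigma must be > 0")
    peaks = np.asarray(v2_peak_hues, float)
    targets = np.asarray(targets_deg, float)
    diff = np.abs(targets[:, None] - peaks[None, :]) % 360.0
    d = np.minimum(diff, 360.0 - diff)
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    w = w / w.sum(axis=1, keepdims=True)
    return V4WeightMatrix(w=w, d=d)


def mv4_response(
    v2_maps: LayerResponses, weights: V4WeightMatrix, cfg: LayerConfig
) -> LayerResponses:
    """Six mV4 maps: rectified weighted sums of Gaussian-smoothed mV2 maps."""
    if tuple(v2_maps.labels) != MV2_TYPES:
        raise InputDomainError(
            "mV4 requires the 14 mV2 maps in canonical order"
        )
    size = _odd(cfg.rf_sizes["mV4"])
    smoothed = [
        convolve_gaussian(v2_maps[label], cfg.sigma_mv4, size) for label in MV2_TYPES
    ]
    out = {}
    for i, name in enumerate(MV4_TYPES):
        acc = sum(weights.w[i, j] * smoothed[j] for j in range(len(MV2_TYPES)))
        out[name] = rectify(acc, cfg.rectifier)
    return LayerResponses("mV4", out)


def _mult_pairs():
    return [tuple(label.split(" x ")) for label in MV2_MULTIPLICATIVE_TYPES]


class HueModel:
    """The configured network plus its calibration state.

    Calibration runs the closed-form uniform-stimulus pipeline over the
    tuning stimulus set to (1) fix the multiplicative amplification gain,
    (2) fix each pooled cell's iceberg threshold, (3) measure the 14 mV2
    tuning-peak hues, and (4) build the mV2->mV4 weight matrix.
    """

    def __init__(self, cfg: LayerConfig | None = None, specs=None):
        self.cfg = cfg if cfg is not None else default_config()
        self.cfg.validate()
        self.specs = (
            tuple(specs)
            if specs is not None
            else default_opponent_specs(self.cfg.rf_sizes["mLGN"])
        )
        for s in self.specs:
            s.validate()
        self._spec_by_name = {s.name: s for s in self.specs}
        if tuple(self._spec_by_name) != MLGN_TYPES:
            raise ConfigError("opponent specs must cover the six canonical types")
        self._calibrated = False
        self._gain = None
        self._pool_thresholds = None
        self._mv2_peaks = None
        self._weights = None
        self._stim_hues = None
        self._stim_angles = None

    # -- closed-form pipeline on uniform stimuli ---------------------------

    def _lgn_value(self, cone_triple: np.ndarray, spec: OpponentCellSpec) -> float:
        v = float(
            np.dot(spec.centre_weights, cone_triple)
            - np.dot(spec.surround_weights, cone_triple)
        )
        return float(rectify(spec.sign * v, self.cfg.rectifier_mlgn))

    def centre_responses(self, hue_deg: float, saturation=None, lightness=None) -> dict:
        """Per-layer centre-pixel responses to a uniform HSL field (closed form)."""
        self.calibrate()
        cfg = self.cfg
        s = cfg.stimulus_saturation if saturation is None else saturation
        l = cfg.stimulus_lightness if lightness is None else lightness
        cones = rgb_to_lms(hsl_to_rgb(hue_deg, s, l))
        return self._centre_from_cones(cones)

    def _centre_from_cones(self, cones: np.ndarray, gain=None, pool_thresholds=None) -> dict:
        cfg = self.cfg
        gain = self._gain if gain is None else gain
        lgn = {t: self._lgn_value(cones, self._spec_by_name[t]) for t in MLGN_TYPES}
        v1 = {t: float(rectify(lgn[t], cfg.rectifier)) for t in MLGN_TYPES}
        v2 = {t: float(rectify(v1[t], cfg.rectifier)) for t in MV2_ADDITIVE_TYPES}
        for lm, sx in _mult_pairs():
            v2[f"{lm} x {sx}"] = float(rectify(gain * v1[lm] * v1[sx], cfg.rectifier))
        out = {"mLGN": lgn, "mV1": v1, "mV2": v2}
        thresholds = self._pool_thresholds if pool_thresholds is None else pool_thresholds
        if thresholds:
            out["mV2-pooled"] = {
                t: float(
                    rectify(
                        v2[t],
                        RectifierParams(m=1.0, b=-thresholds[t], tau=0.0,
                                        s=cfg.rectifier.s),
                    )
                )
                for t in MV2_ADDITIVE_TYPES
            }
        if self._weights is not None:
            v2vec = np.array([v2[t] for t in MV2_TYPES])
            out["mV4"] = {
                name: float(rectify(self._weights.w[i] @ v2vec, cfg.rectifier))
                for i, name in enumerate(MV4_TYPES)
            }
        return out

    # -- calibration -------------------------------------------------------

    def calibrate(self) -> "HueModel":
        if self._calibrated:
            return self
        cfg = self.cfg
        hues = hue_circle_samples(cfg.n_tuning_hues)
        cones = [
            rgb_to_lms(hsl_to_rgb(h, cfg.stimulus_saturation, cfg.stimulus_lightness))
            for h in hues
        ]
        angles = np.array([float(mb_hue_angle(c)) for c in cones])

        # raw (gain = 1) responses over the stimulus set
        raw = [self._centre_from_cones(c, gain=1.0, pool_thresholds={}) for c in cones]
        add_peak = max(r["mV2"][t] for r in raw for t in MV2_ADDITIVE_TYPES)
        mult_raw_peak = max(
            r["mV2"][t] for r in raw for t in MV2_MULTIPLICATIVE_TYPES
        )
        if cfg.multiplicative_gain is not None:
            self._gain = float(cfg.multiplicative_gain)
        elif mult_raw_peak > 0:
            self._gain = float(add_peak / mult_raw_peak)
        else:
            self._gain = 1.0

        # pooled-cell iceberg thresholds: a fixed fraction of the cell's
        # maximal pooled (window-averaged, here uniform) response
        self._pool_thresholds = {
            t: cfg.pooling_threshold_frac * max(r["mV2"][t] for r in raw)
            for t in MV2_ADDITIVE_TYPES
        }

        # mV2 peak hues with the calibrated gain
        order = np.argsort(angles)
        resp = [self._centre_from_cones(c, pool_thresholds={}) for c in cones]
        peaks = []
        for t in MV2_TYPES:
            curve = np.array([r["mV2"][t] for r in resp])
            peaks.append(tuning_peak_raw(angles[order], curve[order]))
        self._mv2_peaks = np.array(peaks)

        targets = np.array(
            [
                float(mb_hue_angle(rgb_to_lms(hsl_to_rgb(h, cfg.stimulus_saturation,
                                                         cfg.stimulus_lightness))))
                for h in cfg.v4_target_hues
            ]
        )
        self._target_angles = targets
        self._weights = compute_mv4_weights(self._mv2_peaks, targets, cfg.v4_weight_sigma)
        self._stim_hues = hues
        self._stim_angles = angles
        self._calibrated = True
        return self

    # -- spatial pipeline --------------------------------------------------

    def run_model(self, cones: np.ndarray) -> dict:
        """Run the full spatial network on an H x W x 3 cone image.

        Returns a dict of :class:`LayerResponses` for mLGN (6 maps), mV1 (6),
        mV2 (14) and mV4 (6), each map the same spatial size as the input.
        """
        self.calibrate()
        cfg = self.cfg
        cones = np.asarray(cones, float)
        if cones.ndim != 3 or cones.shape[-1] != 3:
            raise InputDomainError("cone image must be H x W x 3")
        lgn = LayerResponses(
            "mLGN",
            {
                t: mlgn_response(cones, self._spec_by_name[t], cfg.rectifier_mlgn)
                for t in MLGN_TYPES
            },
        )
        v1 = LayerResponses(
            "mV1", {t: mv1_response(lgn[t], cfg) for t in MLGN_TYPES}
        )
        smoothed = {t: _smooth_mv2(v1[t], cfg) for t in MLGN_TYPES}
        v2_maps = {t: rectify(smoothed[t], cfg.rectifier) for t in MV2_ADDITIVE_TYPES}
        for lm, sx in _mult_pairs():
            v2_maps[f"{lm} x {sx}"] = rectify(
                self._gain * smoothed[lm] * smoothed[sx], cfg.rectifier
            )
        v2 = LayerResponses("mV2", v2_maps)
        v4 = mv4_response(v2, self._weights, cfg)
        return {"mLGN": lgn, "mV1": v1, "mV2": v2, "mV4": v4}

    def run_pooled(self, cones: np.ndarray) -> LayerResponses:
        """The six pooled mV2 variant maps for a cone image."""
        self.calibrate()
        cfg = self.cfg
        lgn = {
            t: mlgn_response(cones, self._spec_by_name[t], cfg.rectifier_mlgn)
            for t in MLGN_TYPES
        }
        v1 = {t: mv1_response(lgn[t], cfg) for t in MLGN_TYPES}
        return LayerResponses(
            "mV2-pooled",
            {
                t: mv2_pooling(mv2_additive(v1[t], cfg), cfg, self._pool_thresholds[t])
                for t in MV2_ADDITIVE_TYPES
            },
        )

    # -- calibrated state --------------------------------------------------

    @property
    def weight_matrix(self) -> V4WeightMatrix:
        self.calibrate()
        return self._weights

    @property
    def multiplicative_gain(self) -> float:
        self.calibrate()
        return self._gain

    @property
    def pooling_thresholds(self) -> dict:
        self.calibrate()
        return dict(self._pool_thresholds)

    @property
    def mv2_peak_hues(self) -> np.ndarray:
        self.calibrate()
        return self._mv2_peaks.copy()

    @property
    def stimulus_mb_angles(self) -> np.ndarray:
        self.calibrate()
        return self._stim_angles.copy()

    @property
    def stimulus_hues(self) -> np.ndarray:
        self.calibrate()
        return self._stim_hues.copy()

    @property
    def mv4_target_angles(self) -> np.ndarray:
        self.calibrate()
        return self._target_angles.copy()


def tuning_peak_raw(angles_deg: np.ndarray, responses: np.ndarray) -> float:
    """Peak hue of a sampled tuning curve (angles sorted ascending).

    The circular position of the maximum response; when the maximum is
    attained on a contiguous circular run of neighbouring samples, the
    circular mean of that run.  Used by both calibration and the analysis
    module (which adds validation and the TuningCurve wrapper).
    """
    responses = np.asarray(responses, float)
    angles_deg = np.asarray(angles_deg, float)
    mx = responses.max()
    scale = max(abs(mx), 1.0)
    at_max = np.isclose(responses, mx, rtol=0.0, atol=1e-9 * scale)
    idx = np.flatnonzero(at_max)
    if len(idx) == len(responses):
        from .errors import NoPeakError

        raise NoPeakError("tuning curve is constant; no peak")
    if len(idx) > 1:
        # keep only the contiguous circular run containing the argmax
        n = len(responses)
        run = {int(np.argmax(responses))}
        changed = True
        while changed:
            changed = False
            for i in list(run):
                for j in ((i - 1) % n, (i + 1) % n):
                    if at_max[j] and j not in run:
                        run.add(j)
                        changed = True
        idx = np.array(sorted(run))
    a = np.radians(angles_deg[idx])
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)
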