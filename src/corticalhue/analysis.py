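"""Tuning-curve analysis: peaks, Kiper bandwidths, histograms, weight splits.

The tuning protocol presents uniform hue fields (fixed saturation and
lightness, hues equally spaced in HSL) and records each neuron's response at
the image centre.  Curves are indexed by the stimulus hue's MacLeod-Boynton
angle, so the hue circle is non-uniformly sampled; responses between samples
are linearly interpolated on the circle.

Bandwidth follows the half-height convention of Kiper and colleagues for V2
colour cells: on each side of the peak, the threshold is halfway between the
peak response and the response 90 deg away; the bandwidth is the mean of the
two angular offsets at which the interpolated curve first crosses its
side's threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    MLGN_TYPES,
    MV2_ADDITIVE_TYPES,
    MV2_MULTIPLICATIVE_TYPES,
    MV2_TYPES,
    MV4_TYPES,
)
from .errors import InputDomainError, NoPeakError, UndefinedBandwidthError
from .network import HueModel, V4WeightMatrix, tuning_peak_raw

__all__ = [
    "TuningCurve",
    "PeakRecord",
    "measure_tuning",
    "measure_all_tunings",
    "tuning_peak",
    "tuning_bandwidth",
    "bandwidth_table",
    "circular_distance",
    "unique_hue_distances",
    "contribution_split",
    "layer_peak_records",
]


@dataclass
class TuningCurve:
    """Responses of one neuron type over the hue circle, indexed by MB angle."""

    angles_deg: np.ndarray
    responses: np.ndarray
    neuron_label: str = ""

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.responses = np.asarray(self.responses, float)
        if self.angles_deg.shape != self.responses.shape:
            raise InputDomainError("angles and responses must have equal length")
        if len(self.angles_deg) >= 2 and np.any(np.diff(self.angles_deg) <= 0):
            raise InputDomainError("angles must be strictly increasing")


@dataclass(frozen=True)
class PeakRecord:
    neuron_label: str
    layer: str
    peak_deg: float


def _layer_of(label: str, layer: str | None) -> str:
    if layer is not None:
        return layer
    if label in MV4_TYPES:
        return "mV4"
    if label in MV2_MULTIPLICATIVE_TYPES:
        return "mV2"
    return "mV1"


def measure_tuning(
    model: HueModel,
    neuron_label: str,
    layer: str = "mV2",
    n_hues: int | None = None,
    spatial: bool = False,
) -> TuningCurve:
    """Tuning curve of one neuron over the hue stimulus set.

    With ``spatial=True`` every stimulus is rendered as a full uniform image
    and run through the spatial network, reading the centre pixel; the
    default closed form is exactly equivalent for uniform stimuli and far
    cheaper.
    """
    model.calibrate()
    curves = measure_all_tunings(model, n_hues=n_hues, spatial=spatial)
    if layer not in curves or neuron_label not in curves[layer]:
        raise KeyError(f"unknown neuron {neuron_label!r} in layer {layer!r}")
    return curves[layer][neuron_label]


def measure_all_tunings(
    model: HueModel, n_hues: int | None = None, spatial: bool = False
) -> dict:
    """Tuning curves for every neuron type in every layer.

    Returns ``{layer: {label: TuningCurve}}`` with layers mLGN, mV1, mV2
    (14 types), mV2-pooled (6) and mV4 (6).
    """
    from .stimuli import StimulusSpec, hue_circle_samples, uniform_hue_field
    from .colourspace import hsl_to_rgb, mb_hue_angle, rgb_to_lms

    model.calibrate()
    cfg = model.cfg
    n = cfg.n_tuning_hues if n_hues is None else n_hues
    hues = hue_circle_samples(n)
    angles = np.array(
        [
            float(
                mb_hue_angle(
                    rgb_to_lms(
                        hsl_to_rgb(h, cfg.stimulus_saturation, cfg.stimulus_lightness)
                    )
                )
            )
            for h in hues
        ]
    )
    order = np.argsort(angles)
    per_layer: dict = {}
    for h in hues:
        if spatial:
            img = uniform_hue_field(
                StimulusSpec(h, cfg.stimulus_saturation, cfg.stimulus_lightness,
                             cfg.image_size)
            )
            layers = model.run_model(img)
            c = cfg.image_size // 2
            resp = {
                name: {lab: float(lr[lab][c, c]) for lab in lr.labels}
                for name, lr in layers.items()
            }
            pooled = model.run_pooled(img)
            resp["mV2-pooled"] = {lab: float(pooled[lab][c, c]) for lab in pooled.labels}
        else:
            resp = model.centre_responses(h)
        for layer, vals in resp.items():
            bucket = per_layer.setdefault(layer, {})
            for lab, v in vals.items():
                bucket.setdefault(lab, []).append(v)
    out = {}
    for layer, bucket in per_layer.items():
        out[layer] = {
            lab: TuningCurve(angles[order], np.asarray(vals)[order], lab)
            for lab, vals in bucket.items()
        }
    return out


def tuning_peak(curve: TuningCurve) -> float:
    """Peak hue: circular argmax, plateau-of-maxima resolved by circular mean."""
    return tuning_peak_raw(curve.angles_deg, curve.responses)


def _interp_circular(angles: np.ndarray, responses: np.ndarray, query: float) -> float:
    """Linear interpolation on the circle (angles sorted ascending)."""
    q = query % 360.0
    n = len(angles)
    idx = np.searchsorted(angles, q)
    i0 = (idx - 1) % n
    i1 = idx % n
    a0 = angles[i0]
    span = (angles[i1] - a0) % 360.0
    if span == 0:
        return float(responses[i0])
    t = ((q - a0) % 360.0) / span
    return float(responses[i0] * (1 - t) + responses[i1] * t)


def tuning_bandwidth(curve: TuningCurve, step: float = 0.05) -> float:
    """Half-height tuning bandwidth (deg), averaged over both sides of the peak.

    Raises :class:`UndefinedBandwidthError` when the response never falls to
    the threshold within 90 deg on either side, and :class:`NoPeakError` for
    a constant curve.
    """
    pk = tuning_peak(curve)
    ang, resp = curve.angles_deg, curve.responses
    r_peak = _interp_circular(ang, resp, pk)
    offsets = []
    for sign in (1.0, -1.0):
        r90 = _interp_circular(ang, resp, pk + sign * 90.0)
        if r_peak <= r90:
            raise UndefinedBandwidthError(
                f"{curve.neuron_label}: response at 90 deg is not below the peak"
            )
        thr = r90 + 0.5 * (r_peak - r90)
        prev = r_peak
        crossing = None
        xs = np.arange(step, 90.0 + step / 2, step)
        for x in xs:
            r = _interp_circular(ang, resp, pk + sign * x)
            if r <= thr:
                frac = (prev - thr) / (prev - r) if prev != r else 0.0
                crossing = (x - step) + frac * step
                break
            prev = r
        if crossing is None:
            raise UndefinedBandwidthError(
                f"{curve.neuron_label}: no half-height crossing within 90 deg"
            )
        offsets.append(crossing)
    return float(np.mean(offsets))


def bandwidth_table(model: HueModel, spatial: bool = False) -> dict:
    """Kiper bandwidths for the additive, multiplicative and pooled mV2 cells.

    Returns a dict with per-population ``{label: bandwidth}`` mappings and
    their means.
    """
    curves = measure_all_tunings(model, spatial=spatial)
    add = {t: tuning_bandwidth(curves["mV2"][t]) for t in MV2_ADDITIVE_TYPES}
    mult = {t: tuning_bandwidth(curves["mV2"][t]) for t in MV2_MULTIPLICATIVE_TYPES}
    pooled = {t: tuning_bandwidth(curves["mV2-pooled"][t]) for t in MV2_ADDITIVE_TYPES}
    return {
        "additive": add,
        "multiplicative": mult,
        "pooled": pooled,
        "mean_additive": float(np.mean(list(add.values()))),
        "mean_multiplicative": float(np.mean(list(mult.values()))),
        "mean_pooled": float(np.mean(list(pooled.values()))),
    }


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two hues, in [0, 180]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return float(np.minimum(d, 360.0 - d)) if np.ndim(d) == 0 else np.minimum(d, 360.0 - d)


def layer_peak_records(model: HueModel, spatial: bool = False) -> dict:
    """Tuning-peak records per layer: ``{layer: [PeakRecord, ...]}``.

    mLGN peaks are measured on the linear (signed) responses; all other
    layers on their rectified curves.
    """
    curves = measure_all_tunings(model, spatial=spatial)
    out = {}
    for layer in ("mLGN", "mV1", "mV2", "mV4"):
        recs = []
        for lab, c in curves[layer].items():
            try:
                recs.append(PeakRecord(lab, layer, tuning_peak(c)))
            except NoPeakError:
                continue
        out[layer] = recs
    return out


def unique_hue_distances(peaks_by_layer: dict, reference_angles: dict) -> dict:
    """Minimum peak distance per layer to each unique-hue reference angle.

    ``peaks_by_layer`` maps layer name to a list of :class:`PeakRecord`;
    ``reference_angles`` maps the four unique-hue names to MB angles (deg).
    """
    out = {}
    for layer, records in peaks_by_layer.items():
        if not records:
            raise InputDomainError(f"layer {layer!r} has no peak records")
        out[layer] = {
            name: float(min(circular_distance(r.peak_deg, ref) for r in records))
            for name, ref in reference_angles.items()
        }
    return out


def contribution_split(weights: V4WeightMatrix) -> dict:
    """Per-mV4 percentage of input weight from single-opponent vs multiplicative
    mV2 cells.  The two percentages sum to 100 for each neuron."""
    n_add = len(MV2_ADDITIVE_TYPES)
    out = {}
    for i, name in enumerate(weights.row_labels):
        add = float(weights.w[i, :n_add].sum() * 100.0)
        mult = float(weights.w[i, n_add:].sum() * 100.0)
        out[name] = {"single_opponent": add, "multiplicative": mult}
    return out
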