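"""System-level experiments: hue-distance correlation and sparse hue reconstruction.

The correlation experiment mirrors the cluster/patch analysis of colour maps
in extrastriate cortex: the six mV4 maps are stacked (magenta, red, yellow,
green, cyan, blue from top to bottom) so that each spatial column is a
"model cluster" of six "model patches".  For every pair of 12 stimulus hues
(30-deg HSL spacing) the distance between the maximally activated patches is
correlated with an ordinal hue distance (values 0..5.5 in 0.5 steps,
starting at 0 for magenta).

The reconstruction experiment asks whether a sparse linear combination of
the six mV4 responses can represent a fixed hue across 500 random
saturation/lightness conditions, via L1-regularized least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso

from .config import MV4_STACK_ORDER, MV4_TYPES
from .errors import InputDomainError, UndefinedCorrelationError
from .network import HueModel, LayerResponses
from .stimuli import StimulusSpec, hue_circle_samples, uniform_hue_field

__all__ = [
    "ClusterStack",
    "ReconstructionResult",
    "hue_value_map",
    "stack_mv4",
    "patch_distance",
    "hue_value_distance",
    "hue_patch_correlation",
    "reconstruct_hue",
]


@dataclass
class ClusterStack:
    """Ordered 3-D stack of the six mV4 maps (order x H x W)."""

    order: tuple
    stack: np.ndarray

    def winner(self, y: int, x: int) -> int:
        """Index of the maximally activated patch in the cluster at (y, x)."""
        return int(np.argmax(self.stack[:, y, x]))


@dataclass(frozen=True)
class ReconstructionResult:
    hue_deg: float
    weights: dict
    lam: float
    seed: int
    n_samples: int

    @property
    def dominant(self) -> str:
        return max(self.weights, key=lambda k: self.weights[k])


def stack_mv4(mv4: LayerResponses, order: tuple = MV4_STACK_ORDER) -> ClusterStack:
    """Stack the six mV4 maps in the given top-to-bottom order."""
    if set(mv4.labels) != set(MV4_TYPES) or len(mv4.labels) != 6:
        raise InputDomainError("expected exactly the six canonical mV4 maps")
    return ClusterStack(tuple(order), np.stack([mv4[name] for name in order]))


def patch_distance(winner_a: int, winner_b: int) -> int:
    """Absolute stack-index distance between two winning patches."""
    if not (0 <= winner_a <= 5 and 0 <= winner_b <= 5):
        raise InputDomainError("winner indices must lie in 0..5")
    return abs(int(winner_a) - int(winner_b))


def hue_value_map(n_hues: int = 12) -> dict:
    """Ordinal values for the stimulus hues: 0 for magenta (HSL 300), then
    0.5 steps following the HSL hue circle, up to 5.5."""
    hues = hue_circle_samples(n_hues)
    step = 6.0 / n_hues
    return {
        float(h): float((((h - 300.0) % 360.0) / 360.0) * n_hues * step)
        for h in hues
    }


def hue_value_distance(h_a: float, h_b: float, value_map: dict | None = None) -> float:
    """Absolute difference of the ordinal values assigned to two stimulus hues."""
    vm = hue_value_map() if value_map is None else value_map
    try:
        return abs(vm[float(h_a % 360.0)] - vm[float(h_b % 360.0)])
    except KeyError as exc:
        raise InputDomainError(f"hue {exc.args[0]} is not in the stimulus set") from None


def _winners(model: HueModel, hues, spatial: bool) -> dict:
    cfg = model.cfg
    winners = {}
    for h in hues:
        if spatial:
            img = uniform_hue_field(
                StimulusSpec(h, cfg.stimulus_saturation, cfg.stimulus_lightness,
                             cfg.image_size)
            )
            cs = stack_mv4(model.run_model(img)["mV4"])
            c = cfg.image_size // 2
            winners[float(h)] = cs.winner(c, c)
        else:
            resp = model.centre_responses(h)["mV4"]
            winners[float(h)] = int(
                np.argmax([resp[name] for name in MV4_STACK_ORDER])
            )
    return winners


def hue_patch_correlation(
    model: HueModel, n_hues: int = 12, spatial: bool = False
) -> tuple[float, float, "pd.DataFrame"]:
    """Pearson correlation between hue-value distances and patch distances.

    Presents each of ``n_hues`` uniform hue fields, finds the maximally
    activated patch in the central model cluster, and correlates the patch
    index distance with the ordinal hue distance over all unordered pairs.
    Returns (r, p, pair table).
    """
    import pandas as pd

    hues = hue_circle_samples(n_hues)
    vm = hue_value_map(n_hues)
    winners = _winners(model, hues, spatial)
    rows = []
    for i in range(n_hues):
        for j in range(i + 1, n_hues):
            ha, hb = float(hues[i]), float(hues[j])
            rows.append(
                {
                    "hue_a": ha,
                    "hue_b": hb,
                    "hue_distance": hue_value_distance(ha, hb, vm),
                    "patch_distance": patch_distance(winners[ha], winners[hb]),
                }
            )
    table = pd.DataFrame(rows)
    if table["hue_distance"].nunique() < 2 or table["patch_distance"].nunique() < 2:
        raise UndefinedCorrelationError("a distance variable has zero variance")
    r, p = stats.pearsonr(table["hue_distance"], table["patch_distance"])
    return float(r), float(p), table


def reconstruct_hue(
    model: HueModel,
    hue_deg: float,
    n_samples: int | None = None,
    lam: float | None = None,
    seed: int = 0,
) -> ReconstructionResult:
    """Sparse linear read-out of a fixed hue from the six mV4 responses.

    Saturation and lightness are sampled independently and uniformly on
    (0, 1); each sample is rendered as a uniform field of the given hue and
    the six centre-pixel mV4 responses are collected.  Each sample's response
    vector is divisively normalized (population normalization), the target is
    the hue expressed as a number in (0, 2*pi], and the weights solve an
    L1-penalized least-squares problem.  Reported weights are normalized to
    sum to 1.
    """
    cfg = model.cfg
    n = cfg.reconstruction_samples if n_samples is None else int(n_samples)
    lam = cfg.reconstruction_lambda if lam is None else float(lam)
    if lam < 0:
        raise InputDomainError("lambda must be >= 0")
    if n < 6:
        raise InputDomainError("need at least 6 samples")
    rng = np.random.default_rng(seed)
    sat = rng.uniform(0.0, 1.0, n)
    light = rng.uniform(0.0, 1.0, n)
    X = np.empty((n, 6))
    for i in range(n):
        resp = model.centre_responses(hue_deg, sat[i], light[i])["mV4"]
        X[i] = [resp[name] for name in MV4_TYPES]
    sums = X.sum(axis=1)
    keep = sums > 1e-12
    if not np.any(keep):
        raise InputDomainError("all mV4 responses are zero; cannot reconstruct")
    Xn = X[keep] / sums[keep, None]
    target = np.radians(hue_deg if (hue_deg % 360.0) != 0 else 360.0)
    y = np.full(Xn.shape[0], target)
    if lam == 0:
        coef, *_ = np.linalg.lstsq(Xn, y, rcond=None)
    else:
        coef = Lasso(alpha=lam, fit_intercept=False, max_iter=200000).fit(Xn, y).coef_
    total = coef.sum()
    if abs(total) < 1e-12:
        raise InputDomainError("degenerate fit: all weights zero (lambda too large?)")
    w = coef / total
    return ReconstructionResult(
        hue_deg=float(hue_deg),
        weights={name: float(w[i]) for i, name in enumerate(MV4_TYPES)},
        lam=lam,
        seed=seed,
        n_samples=n,
    )
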