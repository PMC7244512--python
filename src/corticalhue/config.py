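"""Configuration objects for the hue-processing network.

Everything the network and the experiments depend on lives here: rectifier
settings, receptive-field sizes, Gaussian spreads, the opponent-cell weight
table, the mV2->mV4 weighting rule, and experiment parameters.  A YAML file
with any subset of keys overrides the defaults; validation errors name the
offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import ConfigError

__all__ = [
    "RectifierParams",
    "OpponentCellSpec",
    "LayerConfig",
    "default_config",
    "default_opponent_specs",
    "load_config",
    "dump_config",
    "config_digest",
    "MLGN_TYPES",
    "MV2_ADDITIVE_TYPES",
    "MV2_MULTIPLICATIVE_TYPES",
    "MV2_TYPES",
    "MV4_TYPES",
    "MV4_STACK_ORDER",
]

#: Canonical neuron-type orderings used everywhere in the package.
MLGN_TYPES = ("L-on", "L-off", "M-on", "M-off", "S-on", "S-off")
MV2_ADDITIVE_TYPES = MLGN_TYPES
MV2_MULTIPLICATIVE_TYPES = tuple(
    f"{lm} x {s}" for lm in ("L-on", "L-off", "M-on", "M-off") for s in ("S-on", "S-off")
)
MV2_TYPES = MV2_ADDITIVE_TYPES + MV2_MULTIPLICATIVE_TYPES
MV4_TYPES = ("red", "yellow", "green", "cyan", "blue", "magenta")
#: Top-to-bottom order of the stacked mV4 maps (a spatial column = one cluster).
MV4_STACK_ORDER = ("magenta", "red", "yellow", "green", "cyan", "blue")


@dataclass(frozen=True)
class RectifierParams:
    """Piecewise-linear rectifier phi: slope m, base rate b, threshold tau, saturation s."""

    m: float = 1.0
    b: float = 0.0
    tau: float = 0.0
    s: float = 1.0

    def validate(self, key: str = "rectifier") -> None:
        if not self.tau <= self.s:
            raise ConfigError(f"{key}: tau ({self.tau}) must not exceed s ({self.s})")


@dataclass(frozen=True)
class OpponentCellSpec:
    """One single-opponent centre-surround cell type.

    ``sign`` is +1 for on-cells (excitatory centre) and -1 for off-cells.
    Weights are non-negative; the sign of the surround contribution is
    carried by the difference-of-Gaussians structure, and the overall
    polarity by ``sign``.
    """

    name: str
    centre_weights: tuple[float, float, float]
    surround_weights: tuple[float, float, float]
    centre_sigmas: tuple[float, float, float]
    surround_sigmas: tuple[float, float, float]
    rf_size: int
    sign: int = 1

    def validate(self) -> None:
        key = f"opponent_specs[{self.name}]"
        for w in (*self.centre_weights, *self.surround_weights):
            if not (w >= 0 and w == w):
                raise ConfigError(f"{key}: weights must be finite and >= 0")
        for s in (*self.centre_sigmas, *self.surround_sigmas):
            if not s > 0:
                raise ConfigError(f"{key}: sigmas must be > 0")
        for sc, ss in zip(self.centre_sigmas, self.surround_sigmas):
            if ss < sc:
                raise ConfigError(f"{key}: surround sigma must be >= centre sigma")
        if self.sign not in (-1, 1):
            raise ConfigError(f"{key}: sign must be +1 or -1")
        if self.rf_size <= 0:
            raise ConfigError(f"{key}: rf_size must be positive")


def default_opponent_specs(rf_size: int = 19, white_lms=None) -> tuple[OpponentCellSpec, ...]:
    """The six single-opponent mLGN cell types.

    Centre: a single cone with weight 1.  Surround: L and M cones with
    balanced weights chosen so that an achromatic uniform stimulus produces a
    null response (centre drive equals surround drive at the white point);
    the S cone never contributes to the surround.  Off-cells are the
    sign-flipped on-cells.
    """
    if white_lms is None:
        from .colourspace import white_point_lms

        white_lms = white_point_lms()
    lw, mw = float(white_lms[0]), float(white_lms[1])
    sigma_c = rf_size / 8.0
    sigma_s = rf_size / 4.0
    sc = (sigma_c, sigma_c, sigma_c)
    ss = (sigma_s, sigma_s, sigma_s)
    specs = []
    for cone, idx in (("L", 0), ("M", 1), ("S", 2)):
        centre = [0.0, 0.0, 0.0]
        centre[idx] = 1.0
        bal = float(white_lms[idx]) / (lw + mw)
        surround = (bal, bal, 0.0)
        for onoff, sign in (("on", 1), ("off", -1)):
            specs.append(
                OpponentCellSpec(
                    name=f"{cone}-{onoff}",
                    centre_weights=tuple(centre),
                    surround_weights=surround,
                    centre_sigmas=sc,
                    surround_sigmas=ss,
                    rf_size=rf_size,
                    sign=sign,
                )
            )
    return tuple(specs)


@dataclass(frozen=True)
class LayerConfig:
    """Full network + experiment configuration."""

    image_size: int = 256
    #: kernel side lengths per layer; they double layer-to-layer.
    rf_sizes: dict = field(
        default_factory=lambda: {"mLGN": 19, "mV1": 38, "mV2": 76, "mV4": 152}
    )
    #: Gaussian spreads for the smoothing stages (pixels); default rf/6.
    sigma_mv1: float = 38 / 6
    sigma_mv2: float = 76 / 6
    sigma_mv4: float = 152 / 6
    rectifier_mlgn: RectifierParams = field(
        default_factory=lambda: RectifierParams(tau=-1.0, s=1.0)
    )
    rectifier: RectifierParams = field(default_factory=RectifierParams)
    #: HSL hues of the six mV4 neuron types, 60 deg apart with red at 0.
    v4_target_hues: tuple = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
    #: Std dev (deg) of the Gaussian turning mV2-peak distance into mV4 weight.
    v4_weight_sigma: float = 30.0
    #: Side of the square mV2 pooling neighbourhood (pixels, odd).
    pooling_window: int = 3
    #: Iceberg threshold for pooled cells, as a fraction of the cell's maximal
    #: pooled response over the calibration stimulus set.
    pooling_threshold_frac: float = 0.5
    #: Post-product amplification for multiplicative mV2 cells.  None means
    #: auto-calibrate so the strongest multiplicative peak matches the
    #: strongest additive peak over the calibration stimulus set.
    multiplicative_gain: float | None = None
    #: Number of hues in the tuning stimulus set.
    n_tuning_hues: int = 60
    stimulus_saturation: float = 1.0
    stimulus_lightness: float = 0.5
    #: L1 penalty for the hue-reconstruction regression.
    reconstruction_lambda: float = 0.03
    reconstruction_samples: int = 500
    #: Unique-hue reference angles (deg, MB plane).  Editable placeholders for
    #: psychophysically measured unique hues; the package does not assert
    #: literature values as its own.
    unique_hue_references: dict = field(
        default_factory=lambda: {"red": 18.0, "yellow": 75.0, "green": 150.0, "blue": 255.0}
    )

    def validate(self) -> None:
        for layer in ("mLGN", "mV1", "mV2", "mV4"):
            if layer not in self.rf_sizes:
                raise ConfigError(f"rf_sizes: missing layer {layer!r}")
            if int(self.rf_sizes[layer]) <= 0:
                raise ConfigError(f"rf_sizes[{layer}]: must be positive")
        if self.image_size <= 0:
            raise ConfigError("image_size: must be positive")
        for key, sig in (("sigma_mv1", self.sigma_mv1), ("sigma_mv2", self.sigma_mv2),
                         ("sigma_mv4", self.sigma_mv4)):
            if not sig > 0:
                raise ConfigError(f"{key}: must be > 0")
        self.rectifier_mlgn.validate("rectifier_mlgn")
        self.rectifier.validate("rectifier")
        if len(self.v4_target_hues) != 6:
            raise ConfigError("v4_target_hues: exactly six hues required")
        if not self.v4_weight_sigma > 0:
            raise ConfigError("v4_weight_sigma: must be > 0")
        if self.pooling_window <= 0 or self.pooling_window % 2 == 0:
            raise ConfigError("pooling_window: must be a positive odd integer")
        if not 0 < self.pooling_threshold_frac < 1:
            raise ConfigError("pooling_threshold_frac: must lie in (0, 1)")
        if self.multiplicative_gain is not None and not self.multiplicative_gain > 0:
            raise ConfigError("multiplicative_gain: must be > 0 (or null for auto)")
        if self.n_tuning_hues < 1:
            raise ConfigError("n_tuning_hues: must be >= 1")
        for key, v in (("stimulus_saturation", self.stimulus_saturation),
                       ("stimulus_lightness", self.stimulus_lightness)):
            if not 0 <= v <= 1:
                raise ConfigError(f"{key}: must lie in [0, 1]")
        if self.reconstruction_lambda < 0:
            raise ConfigError("reconstruction_lambda: must be >= 0")
        if self.reconstruction_samples < 6:
            raise ConfigError("reconstruction_samples: must be >= 6")
        for name in ("red", "yellow", "green", "blue"):
            if name not in self.unique_hue_references:
                raise ConfigError(f"unique_hue_references: missing {name!r}")


_KNOWN_KEYS = set(LayerConfig.__dataclass_fields__)


def default_config() -> LayerConfig:
    cfg = LayerConfig()
    cfg.validate()
    return cfg


def _coerce(cfg_dict: dict) -> LayerConfig:
    unknown = set(cfg_dict) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(cfg_dict)
    for key in ("rectifier", "rectifier_mlgn"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = RectifierParams(**kwargs[key])
    if "v4_target_hues" in kwargs:
        kwargs["v4_target_hues"] = tuple(float(h) for h in kwargs["v4_target_hues"])
    cfg = replace(LayerConfig(), **kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | None = None) -> LayerConfig:
    """Load a YAML config; an empty or missing file yields the full defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return default_config()
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return _coerce(data)


def dump_config(cfg: LayerConfig, path: str) -> None:
    """Write a config back to YAML; ``load(dump(load(x)))`` is idempotent."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_digest(cfg: LayerConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()
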