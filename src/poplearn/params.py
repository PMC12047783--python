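"""Parameter containers for the observer model.

The model has six parameters fitted per observer — the warp shape
(``a``, ``w_b``, ``sigma_b``), the pre- and post-training gains
(``g_pre``, ``g_post``) and a lapse parameter ``lapse`` — and five
parameters shared across observers: neuron count ``n``, tuning FWHM
``w_t``, baseline rate ``b``, motor-noise SD ``sigma_m`` and the SD of
the post-training gain profile ``sigma_g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["WarpSpec", "SharedParams", "TuningChangeSpec", "ObserverParams"]


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraint."""


@dataclass(frozen=True)
class WarpSpec:
    """Shape of the neural-density template that warps the direction axis.

    ``a`` sets the flat base of the density (large ``a`` flattens the
    normalized density toward uniform), ``w_b`` the width in degrees of
    the high-density plateau centered on the boundary, and ``sigma_b``
    the softness in degrees of the plateau's edges.
    """

    a: float
    w_b: float
    sigma_b: float

    def __post_init__(self):
        if self.a < 0:
            raise InvalidParameterError(f"warp amplitude a must be >= 0, got {self.a}")
        if self.w_b < 0:
            raise InvalidParameterError(f"w_b must be >= 0, got {self.w_b}")
        if self.sigma_b <= 0:
            raise InvalidParameterError(f"sigma_b must be > 0, got {self.sigma_b}")


@dataclass(frozen=True)
class SharedParams:
    """Parameters shared across observers.

    n : neuron count (default 10)
    w_t : tuning-curve full width at half maximum, degrees (default 71)
    b : baseline firing rate, spikes/trial (default 1)
    sigma_m : motor-noise SD on estimation responses, degrees (default 2)
    sigma_g : SD of the Gaussian post-training gain profile, in degrees of
        the homogeneous (unwarped) coordinate; default 36 = one
        inter-neuron spacing at n=10, which corresponds to a few degrees
        of stimulus space in a strongly warped population
    """

    n: int = 10
    w_t: float = 71.0
    b: float = 1.0
    sigma_m: float = 2.0
    sigma_g: float = 36.0

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError(f"need at least 2 neurons, got {self.n}")
        if self.w_t <= 0:
            raise InvalidParameterError("w_t must be > 0")
        if self.b < 0:
            raise InvalidParameterError("baseline b must be >= 0")
        if self.sigma_m < 0:
            raise InvalidParameterError("sigma_m must be >= 0")
        if self.sigma_g <= 0:
            raise InvalidParameterError("sigma_g must be > 0")


@dataclass(frozen=True)
class TuningChangeSpec:
    """Post-training density change for the tuning-change ("TC") variants.

    After training the density template gains two additive Gaussian bumps
    centered on the trained directions (±4° by default), re-allocating
    neurons toward them instead of raising their gain.
    """

    amplitude: float
    sigma: float = 4.0
    center: float = 4.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidParameterError("TC amplitude must be >= 0")
        if self.sigma <= 0:
            raise InvalidParameterError("TC sigma must be > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Per-observer parameters plus the shared configuration.

    ``warp=None`` means an identity (unwarped, homogeneous) encoding.
    ``tuning_change`` is only set for the TC model variants and replaces
    the gain elevation with a post-training density change.
    """

    g_pre: float
    g_post: float
    lapse: float = 0.0
    warp: WarpSpec | None = None
    shared: SharedParams = field(default_factory=SharedParams)
    tuning_change: TuningChangeSpec | None = None

    def __post_init__(self):
        if self.g_pre <= 0:
            raise InvalidParameterError(f"g_pre must be > 0, got {self.g_pre}")
        if self.g_post < self.g_pre:
            raise InvalidParameterError(
                f"g_post ({self.g_post}) must be >= g_pre ({self.g_pre})"
            )
        if not 0.0 <= self.lapse <= 1.0:
            raise InvalidParameterError(f"lapse must be in [0, 1], got {self.lapse}")

    def to_dict(self) -> dict:
        d = {
            "g_pre": self.g_pre,
            "g_post": self.g_post,
            "lapse": self.lapse,
            "warp": None if self.warp is None else asdict(self.warp),
            "shared": asdict(self.shared),
            "tuning_change": None
            if self.tuning_change is None
            else asdict(self.tuning_change),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        return cls(
            g_pre=d["g_pre"],
            g_post=d["g_post"],
            lapse=d.get("lapse", 0.0),
            warp=None if d.get("warp") is None else WarpSpec(**d["warp"]),
            shared=SharedParams(**d.get("shared", {})),
            tuning_change=None
            if d.get("tuning_change") is None
            else TuningChangeSpec(**d["tuning_change"]),
        )
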