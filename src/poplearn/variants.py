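"""Model variants: the full observer and its reduced / alternative forms.

Each variant fixes which mechanisms are active and which per-observer
parameters are free:

``full``        warping + conditional inference + gain change
``no_GC``       no gain change (g_post tied to g_pre)
``no_BA``       no boundary avoidance (identity warp)
``no_CI``       estimates are unconditional posterior means
``TC``          gain change replaced by a post-training density increase
                at the trained directions (bump amplitude and width free)
``TC_reduced``  as TC with the bump width fixed at 4°

Free parameters are carried as a flat vector inside documented box
bounds; ``g_post`` is parameterized as ``g_pre + dg`` with ``dg >= 0`` so
the g_post >= g_pre constraint is a box constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ObserverParams, SharedParams, WarpSpec, TuningChangeSpec

__all__ = ["ModelVariant", "make_variant", "VARIANT_NAMES"]

# Documented box bounds for each free parameter.
BOUNDS = {
    "a": (0.0, 100.0),
    "w_b": (0.0, 90.0),
    "sigma_b": (0.5, 30.0),
    "g_pre": (1.0, 100.0),
    "dg": (0.0, 200.0),  # g_post - g_pre
    "lapse": (0.0, 0.5),
    "tc_amp": (0.0, 2000.0),
    "tc_sigma": (1.0, 20.0),
}

_VARIANT_PARAMS = {
    "full": ("a", "w_b", "sigma_b", "g_pre", "dg", "lapse"),
    "no_GC": ("a", "w_b", "sigma_b", "g_pre", "lapse"),
    "no_BA": ("g_pre", "dg", "lapse"),
    "no_CI": ("a", "w_b", "sigma_b", "g_pre", "dg", "lapse"),
    "TC": ("a", "w_b", "sigma_b", "g_pre", "lapse", "tc_amp", "tc_sigma"),
    "TC_reduced": ("a", "w_b", "sigma_b", "g_pre", "lapse", "tc_amp"),
}

VARIANT_NAMES = tuple(_VARIANT_PARAMS)


@dataclass(frozen=True)
class ModelVariant:
    """A named model variant with its free-parameter layout."""

    name: str
    param_names: tuple
    conditional: bool

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [BOUNDS[p] for p in self.param_names]

    def build_params(self, x, shared: SharedParams | None = None) -> ObserverParams:
        """Materialize ``ObserverParams`` from a free-parameter vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValueError(
                f"variant {self.name!r} expects {self.n_free} parameters, got {x.shape}"
            )
        v = dict(zip(self.param_names, x))
        shared = shared or SharedParams()
        warp = None
        if "a" in v:
            warp = WarpSpec(a=v["a"], w_b=v["w_b"], sigma_b=v["sigma_b"])
        tc = None
        if self.name in ("TC", "TC_reduced"):
            tc = TuningChangeSpec(
                amplitude=v["tc_amp"], sigma=v.get("tc_sigma", 4.0)
            )
        g_pre = v["g_pre"]
        g_post = g_pre + v.get("dg", 0.0)
        return ObserverParams(
            g_pre=g_pre,
            g_post=g_post,
            lapse=v["lapse"],
            warp=warp,
            shared=shared,
            tuning_change=tc,
        )


def make_variant(name: str) -> ModelVariant:
    """Look up a model variant by name."""
    if name not in _VARIANT_PARAMS:
        raise ValueError(
            f"unknown model variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        )
    return ModelVariant(
        name=name,
        param_names=_VARIANT_PARAMS[name],
        conditional=(name != "no_CI"),
    )
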