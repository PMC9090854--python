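"""Simpler depthwise dermal transport models, for side-by-side comparison.

Three classical one-dimensional steady-state descriptions of concentration vs
depth under a constant applied flux J at z = 0:

* **homogeneous** membrane: pure diffusion to a perfect sink at depth L,
  giving the linear profile ``C(z) = J (L − z) / D``;
* **distributed elimination**: diffusion with first-order removal k_el
  (capillary uptake smeared over depth) on a semi-infinite domain,
  ``C(z) = J/√(D k_el) · exp(−√(k_el/D) z)``;
* **convection–dispersion–elimination**: adds downward convection at speed v
  with a lumped dispersion coefficient, ``C(z) = C₀ e^{λ₋ z}`` where λ₋ is the
  nonpositive root of ``D λ² − v λ − k_el = 0`` and C₀ follows from flux
  continuity ``J = v C(0) − D C′(0)``.

These are reference curves used to contrast the full plexus simulation's
depth profile (which plateaus and rises below the plexus) with the linear and
exponential declines the simpler models predict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sensitivity import DepthProfile

__all__ = [
    "DepthModelSpec",
    "homogeneous_steady",
    "distributed_elimination_steady",
    "convection_dispersion_steady",
    "steady_profile",
    "compare_models",
    "calibrate_to_profile",
]

MODELS = ("homogeneous", "distributed_elimination", "convection_dispersion_elimination")


@dataclass(frozen=True)
class DepthModelSpec:
    """Coefficients for one depthwise model (SI units).

    ``D`` is the diffusion (or lumped dispersion) coefficient (m²/s), ``k_el``
    the first-order elimination rate (1/s), ``v`` the downward convection
    speed (m/s), ``L`` the sink depth (m, homogeneous model only) and ``J``
    the applied flux.
    """

    model: str
    D: float
    k_el: float = 0.0
    v: float = 0.0
    L: float | None = None
    J: float = 1.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.k_el < 0 or self.v < 0:
            raise ValueError("k_el and v must be nonnegative")


def _depths_m(depths_um) -> np.ndarray:
    return np.asarray(depths_um, dtype=float) * 1e-6


def homogeneous_steady(spec: DepthModelSpec, depths_um: Sequence[float]) -> DepthProfile:
    """Linear diffusion profile to a sink at depth L, clipped at the sink."""
    if spec.L is None or spec.L <= 0:
        raise ValueError("homogeneous model requires a positive sink depth L")
    z = _depths_m(depths_um)
    c = np.clip(spec.J * (spec.L - z) / spec.D, 0.0, None)
    return DepthProfile(np.asarray(depths_um, float), c, "homogeneous")


def distributed_elimination_steady(
    spec: DepthModelSpec, depths_um: Sequence[float]
) -> DepthProfile:
    """Exponential profile of diffusion with distributed first-order removal."""
    if spec.k_el <= 0:
        raise ValueError(
            "distributed elimination requires k_el > 0; with no elimination use "
            "the homogeneous model"
        )
    z = _depths_m(depths_um)
    kappa = np.sqrt(spec.k_el / spec.D)
    c = spec.J / np.sqrt(spec.D * spec.k_el) * np.exp(-kappa * z)
    return DepthProfile(np.asarray(depths_um, float), c, "distributed_elimination")


def decay_constant(spec: DepthModelSpec) -> float:
    """Nonpositive spatial eigenvalue λ₋ of D λ² − v λ − k_el = 0 (1/m)."""
    if spec.k_el == 0 and spec.v == 0:
        raise ValueError("degenerate model: both v and k_el are zero")
    disc = np.sqrt(spec.v**2 + 4.0 * spec.D * spec.k_el)
    return (spec.v - disc) / (2.0 * spec.D)


def convection_dispersion_steady(
    spec: DepthModelSpec, depths_um: Sequence[float]
) -> DepthProfile:
    """Convection–dispersion–elimination profile C₀ e^{λ₋ z}.

    With v = 0 this reduces exactly to the distributed-elimination model; with
    k_el = 0 and v > 0 the profile is constant (pure downward convection
    sustains the concentration).
    """
    lam = decay_constant(spec)
    c0 = spec.J / (spec.v - spec.D * lam)
    z = _depths_m(depths_um)
    c = c0 * np.exp(lam * z)
    return DepthProfile(np.asarray(depths_um, float), c, "convection_dispersion_elimination")


_DISPATCH = {
    "homogeneous": homogeneous_steady,
    "distributed_elimination": distributed_elimination_steady,
    "convection_dispersion_elimination": convection_dispersion_steady,
}


def steady_profile(spec: DepthModelSpec, depths_um: Sequence[float]) -> DepthProfile:
    return _DISPATCH[spec.model](spec, depths_um)


def calibrate_to_profile(
    profile: DepthProfile, D: float, J: float = 1.0, v: float = 0.0
) -> dict[str, DepthModelSpec]:
    """Reference-model coefficients anchored to a simulated profile.

    The published comparison gives no coefficients for the simple models, so
    they are pinned to the full simulation at the surface: the homogeneous
    sink depth makes the linear profile pass through C(0) with slope J/D, and
    the elimination rates make the exponential models start at the same C(0)
    (flux continuity then fixes their gradients). ``v`` for the
    convection–dispersion model is the superficial blood speed (loop volume
    flow per unit cell area).
    """
    c0 = float(profile.concentrations[0])
    if c0 <= 0:
        raise ValueError("profile top concentration must be positive")
    L = c0 * D / J
    k_el_dist = (J / c0) ** 2 / D
    specs = {
        "homogeneous": DepthModelSpec("homogeneous", D=D, L=L, J=J),
        "distributed_elimination": DepthModelSpec(
            "distributed_elimination", D=D, k_el=k_el_dist, J=J
        ),
    }
    if v > 0:
        # match C(0): J = C0 (v - D λ₋)  =>  -D λ₋ = J/C0 - v  =>  solve for k_el
        g = J / c0 - v
        if g <= 0:
            k_el = 0.0
        else:
            lam = -g / D
            k_el = D * lam**2 - v * lam
        specs["convection_dispersion_elimination"] = DepthModelSpec(
            "convection_dispersion_elimination", D=D, k_el=max(k_el, 0.0), v=v, J=J
        )
    return specs


def compare_models(
    specs: Mapping[str, DepthModelSpec],
    depths_um: Sequence[float],
    simulation_profile: DepthProfile | None = None,
) -> pd.DataFrame:
    """Aligned, surface-normalized concentration–depth table.

    Every column is scaled to 1 at z = 0 so the models' depth shapes can be
    compared irrespective of the applied-flux scale. The simulation profile,
    when given, must share the depth grid.
    """
    depths = np.asarray(depths_um, dtype=float)
    cols: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        c = steady_profile(spec, depths).concentrations
        if c[0] == 0:
            raise ValueError(f"model {name!r} has zero surface concentration")
        cols[name] = c / c[0]
    if simulation_profile is not None:
        if len(simulation_profile.depths_um) != len(depths) or not np.allclose(
            simulation_profile.depths_um, depths
        ):
            raise ValueError("simulation profile depth grid does not match")
        c = simulation_profile.concentrations
        if c[0] == 0:
            raise ValueError("simulation profile has zero surface concentration")
        cols["plexus_simulation"] = c / c[0]
    out = pd.DataFrame(cols, index=pd.Index(depths, name="depth_um"))
    return out.reset_index()
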