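"""Iron-core dissolution: map a removed-iron fraction d onto radial
density models and converted-lattice powder patterns.

Three geometric routes describe how the ferrihydrite core of an
encapsulated ferritin loses scattering mass as iron is reduced and
released: shrinkage from the core surface inward, a uniform density
decrease at constant radius, or hollowing from the center outward.  d is
the fraction of iron *scattering mass* removed; within the remaining
iron region the density stays at the intact ferrihydrite value (surface
and center routes) or is scaled down uniformly (uniform route), so all
routes conserve iron mass exactly: the core band carries (1-d) times the
intact excess mass.  The protein shell is untouched and solvent fills
vacated volume.  All three routes coincide at d=0 (intact ferritin) and
d=1 (apoferritin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formfactors import RadialShellModel
from .lattice import LatticeSpec, LineShapeParams, PatternEngine
from .profiles import ScatteringProfile

__all__ = [
    "ROUTES",
    "ConversionState",
    "reduced_core_model",
    "converted_lattice_profile",
    "conversion_series",
]

#: dissolution route labels: surface-inward, uniform, center-outward
ROUTES = ("surface", "uniform", "center")


@dataclass(frozen=True)
class ConversionState:
    """A dissolution route at removed-iron fraction d, acting on a base
    two-band (core + protein shell) ferritin model."""

    route: str
    d: float
    base: RadialShellModel

    def __post_init__(self):
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("removed-iron fraction d must lie in [0, 1]")
        if len(self.base.boundaries) != 2:
            raise ValueError("base model must have exactly core and shell bands")


def reduced_core_model(state: ConversionState) -> RadialShellModel:
    """Radial model of a partially dissolved core.

    surface: core radius scales as (1-d)^(1/3) at fixed density;
    uniform: density scales as (1-d) at fixed radius;
    center:  an inner solvent void of radius R_core d^(1/3) opens up.
    """
    r_core, r_outer = state.base.boundaries
    rho_core, rho_shell = state.base.contrasts
    d = state.d
    if d == 0.0:
        return state.base
    if d == 1.0 or rho_core == 0.0:
        return RadialShellModel((r_core, r_outer), (0.0, rho_shell))
    # clip shrinking/growing radii strictly inside (0, r_core) so the band
    # structure stays valid for d arbitrarily close to the endpoints; the
    # relative iron-mass error of the clip is ~1e-12
    lo, hi = r_core * 1e-9, r_core * (1.0 - 1e-12)
    if state.route == "surface":
        r_new = float(np.clip(r_core * (1.0 - d) ** (1.0 / 3.0), lo, hi))
        return RadialShellModel((r_new, r_core, r_outer), (rho_core, 0.0, rho_shell))
    if state.route == "uniform":
        return RadialShellModel((r_core, r_outer), (rho_core * (1.0 - d), rho_shell))
    # center route
    r_void = float(np.clip(r_core * d ** (1.0 / 3.0), lo, hi))
    return RadialShellModel((r_void, r_core, r_outer), (0.0, rho_core, rho_shell))


def _guest_override(spec: LatticeSpec, state: ConversionState) -> dict:
    """Replace every guest-bearing species' guest with the reduced model."""
    reduced = reduced_core_model(state)
    override = {}
    for label, voxel in spec.species.items():
        if voxel is not None and voxel.guest is not None:
            override[label] = reduced
    if not override:
        raise ValueError("lattice spec has no guest-bearing species to convert")
    return override


def converted_lattice_profile(
    spec: LatticeSpec,
    state: ConversionState,
    lineshape: LineShapeParams,
    q,
    engine: PatternEngine | None = None,
) -> ScatteringProfile:
    """Powder pattern of the lattice with guests at dissolution state d.

    Passing a prebuilt :class:`PatternEngine` for ``spec`` reuses the
    reflection enumeration and frame orientation averages across states.
    """
    q = np.asarray(q, dtype=float)
    if engine is None:
        engine = PatternEngine(spec, q_max=float(q[-1]) * 1.02)
    return engine.pattern(
        lineshape,
        q,
        guest_override=_guest_override(spec, state),
        metadata={"route": state.route, "d_true": state.d},
    )


def conversion_series(
    spec: LatticeSpec,
    route: str,
    d_schedule,
    lineshape: LineShapeParams,
    q,
    base: RadialShellModel | None = None,
) -> list[ScatteringProfile]:
    """One profile per (time, d) point of a nondecreasing schedule.

    The base ferritin model defaults to the guest of the spec's first
    guest-bearing species.  Metadata on each profile carries the ground
    truth (time, d).
    """
    schedule = [(float(t), float(d)) for t, d in d_schedule]
    times = [t for t, _ in schedule]
    ds = [d for _, d in schedule]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("schedule times must be nondecreasing")
    if any(d2 < d1 for d1, d2 in zip(ds, ds[1:])):
        raise ValueError("schedule d values must be nondecreasing")
    if base is None:
        guests = [v.guest for v in spec.species.values() if v is not None and v.guest is not None]
        if not guests:
            raise ValueError("spec has no guest to convert and no base was given")
        base = guests[0]
    q = np.asarray(q, dtype=float)
    engine = PatternEngine(spec, q_max=float(q[-1]) * 1.02)
    profiles = []
    for t, d in schedule:
        state = ConversionState(route, d, base)
        prof = converted_lattice_profile(spec, state, lineshape, q, engine=engine)
        prof.metadata["time_h"] = t
        profiles.append(prof)
    return profiles
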