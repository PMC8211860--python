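"""Measurement-like synthetic profiles and named scenarios.

Each scenario reproduces one experimental system studied with in-situ
SAXS -- free proteins, protein voxels, single/double layers, 3D
lattices, and the time-resolved iron-release conversion of the SC
ferritin array -- as a fully parameterized generator with ground truth
attached, so every analysis stage is testable without external data.

Scenario constants are the study's: square single layer at 55 nm and its
sqrt(2) half-filled variant; double layer at 57 nm in-plane; full SC at
58.3 nm; half-filled FCC at 115.9 nm; tetragonal pattern on the
four-color 58.6 nm cell; guest offsets 1.5 nm (Off1) and 3.5 nm (Off2);
conversion endpoints d = 0.66, 0.75, 0.61 for the surface, uniform and
center routes on the 4.8 %-compacted 55.9 nm lattice.  Bragg peaks are
resolution-limited Gaussians (sigma 2e-4 inverse Angstroms, narrow
enough to baseline-resolve the closest printed pair, FCC (111)/(200));
noise follows a linear variance law calibrated so the first four Bragg
peaks keep a signal-to-noise ratio of at least ~20.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .dissolution import ConversionState, conversion_series, converted_lattice_profile
from .formfactors import (
    OrientationScheme,
    VoxelModel,
    apoferritin_model,
    ferritin_model,
    octahedron_frame,
    powder_intensity,
)
from .lattice import (
    LatticeSpec,
    LineShapeParams,
    double_layer,
    powder_pattern,
    rocksalt_cubic,
    simple_cubic,
    square_alternating,
    square_lattice,
    tetragonal_facing_pairs,
)
from .profiles import ScatteringProfile, write_profile

__all__ = [
    "NoiseModel",
    "Scenario",
    "SCENARIO_NAMES",
    "simulate_measurement",
    "make_scenario",
    "write_fixtures",
]

# scenario lattice constants, nm
A_SL = 55.0
A_DL = 57.0
A_SC = 58.3
A_FCC = 115.9
A_TET = 58.6
A_CONVERSION = 55.9        # compacted SC lattice of the conversion study
OFF1_NM = 1.5
OFF2_NM = 3.5
D_ENDPOINTS = {"surface": 0.66, "uniform": 0.75, "center": 0.61}

#: default resolution-limited line shape for lattice scenarios
SCENARIO_LINESHAPE = LineShapeParams(width=2e-4, shape="gaussian")

_ORIENTATION_NODES = 2000


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise with variance alpha * I + floor.

    ``alpha`` is the signal-proportional (counting-statistics-like)
    coefficient; ``floor`` the constant variance floor.  The same seed
    always reproduces the same draw.
    """

    alpha: float
    floor: float
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.floor <= 0:
            raise ValueError("need alpha >= 0 and floor > 0 for positive variance")

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return np.sqrt(self.alpha * np.maximum(intensity, 0.0) + self.floor)


def simulate_measurement(truth: ScatteringProfile, noise: NoiseModel) -> ScatteringProfile:
    """Draw one noisy measurement of a noiseless model profile."""
    if np.any(truth.intensity < 0):
        raise ValueError("truth profile must be nonnegative")
    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma(truth.intensity)
    measured = truth.intensity + sigma * rng.standard_normal(truth.intensity.shape)
    md = dict(truth.metadata)
    md["noise_alpha"] = noise.alpha
    md["noise_floor"] = noise.floor
    md["noise_seed"] = noise.seed
    return ScatteringProfile(q=truth.q.copy(), intensity=measured, sigma=sigma, metadata=md)


def _lattice_noise(profile: ScatteringProfile) -> tuple[float, float]:
    """Variance-law coefficients giving the first four Bragg peaks SNR >~ 20."""
    peaks = analysis.find_peaks(profile, min_prominence=0.05)
    heights = sorted(p.height for p in sorted(peaks, key=lambda p: p.center)[:4])
    h = heights[0] if heights else float(np.max(profile.intensity)) * 1e-3
    return h / 1600.0, (h / 40.0) ** 2


def _smooth_noise(profile: ScatteringProfile) -> tuple[float, float]:
    """Variance law for smooth (form-factor) curves: SNR 100 at the maximum."""
    peak = float(np.max(profile.intensity))
    return peak / 1.0e4, (peak * 1.0e-5) ** 2


@dataclass
class Scenario:
    """A named generating model plus ground truth.

    ``truth_profile`` regenerates the noiseless curve bit-identically;
    ``measure(seed)`` adds one reproducible noise draw.  Conversion
    scenarios also expose the full time series.
    """

    name: str
    kind: str                       # "formfactor" | "lattice" | "conversion"
    q: np.ndarray
    truth: dict
    voxel: VoxelModel | None = None
    spec: LatticeSpec | None = None
    lineshape: LineShapeParams | None = None
    route: str | None = None
    schedule: tuple = ()
    _noise: tuple | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def truth_profile(self) -> ScatteringProfile:
        if "profile" not in self._cache:
            if self.kind == "formfactor":
                prof = powder_intensity(
                    self.voxel, self.q, OrientationScheme.fibonacci(_ORIENTATION_NODES)
                )
            elif self.kind == "lattice":
                prof = powder_pattern(self.spec, self.lineshape, self.q)
            else:  # conversion endpoint
                state = ConversionState(
                    self.route, self.truth["d_final"], self.truth["base_guest"]
                )
                prof = converted_lattice_profile(self.spec, state, self.lineshape, self.q)
            prof.metadata["scenario"] = self.name
            self._cache["profile"] = prof
        return self._cache["profile"]

    def series(self) -> list[ScatteringProfile]:
        """Noiseless profiles along the d(t) schedule (conversion only)."""
        if self.kind != "conversion":
            raise ValueError(f"scenario {self.name!r} has no time series")
        if "series" not in self._cache:
            self._cache["series"] = conversion_series(
                self.spec, self.route, self.schedule, self.lineshape, self.q
            )
        return self._cache["series"]

    @property
    def noise(self) -> tuple[float, float]:
        if self._noise is None:
            fn = _smooth_noise if self.kind == "formfactor" else _lattice_noise
            self._noise = fn(self.truth_profile())
        return self._noise

    def measure(self, seed: int = 0) -> ScatteringProfile:
        alpha, floor = self.noise
        return simulate_measurement(self.truth_profile(), NoiseModel(alpha, floor, seed))

    def measure_series(self, seed: int = 0) -> list[ScatteringProfile]:
        alpha, floor = self.noise
        out = []
        for k, prof in enumerate(self.series()):
            out.append(simulate_measurement(prof, NoiseModel(alpha, floor, seed + 1000 * k)))
        return out


def _conversion_schedule(d_end: float, t_max: float = 9.0, tau: float = 1.5, n: int = 10):
    """Saturating exponential d(t) reaching d_end at t_max (hours)."""
    t = np.linspace(0.0, t_max, n)
    d = d_end * (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-t_max / tau))
    return tuple((float(ti), float(di)) for ti, di in zip(t, d))


def _q_lattice():
    return np.geomspace(0.002, 0.08, 600)


def _q_formfactor():
    return np.geomspace(0.004, 0.25, 500)


def _build(name: str) -> Scenario:
    frame = octahedron_frame()
    ferr = ferritin_model()
    apo = apoferritin_model()
    empty_voxel = VoxelModel(frame)
    ferr_voxel = VoxelModel(frame, ferr)

    if name == "free_ferritin":
        return Scenario(name, "formfactor", _q_formfactor(),
                        {"core_radius": 4.0, "outer_radius": 6.0},
                        voxel=VoxelModel(None, ferr))
    if name == "free_apoferritin":
        return Scenario(name, "formfactor", _q_formfactor(),
                        {"core_radius": 4.0, "outer_radius": 6.0, "core_contrast": 0.0},
                        voxel=VoxelModel(None, apo))
    if name == "empty_octa":
        return Scenario(name, "formfactor", np.geomspace(0.004, 0.12, 500),
                        {"edge": 27.8}, voxel=empty_voxel)
    if name in ("voxel_off0", "voxel_off1", "voxel_off2"):
        off = {"voxel_off0": 0.0, "voxel_off1": OFF1_NM, "voxel_off2": OFF2_NM}[name]
        return Scenario(name, "formfactor", np.geomspace(0.004, 0.12, 500),
                        {"edge": 27.8, "offset": off},
                        voxel=VoxelModel(frame, ferr, (0.0, 0.0, off)))
    if name == "sl_full":
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "square", "constant": A_SL},
                        spec=square_lattice(A_SL, ferr_voxel), lineshape=SCENARIO_LINESHAPE)
    if name == "sl_half":
        a = A_SL * np.sqrt(2.0)
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "square", "constant": a},
                        spec=square_alternating(a, ferr_voxel, empty_voxel),
                        lineshape=SCENARIO_LINESHAPE)
    if name == "dl":
        off2_voxel = VoxelModel(frame, ferr, (0.0, 0.0, OFF2_NM))
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "square", "constant": A_DL},
                        spec=double_layer(A_DL, off2_voxel), lineshape=SCENARIO_LINESHAPE)
    if name == "sc_full":
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "sc", "constant": A_SC},
                        spec=simple_cubic(A_SC, ferr_voxel), lineshape=SCENARIO_LINESHAPE)
    if name == "fcc_half":
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "fcc", "constant": A_FCC,
                         "voxel_spacing": A_FCC / 2.0},
                        spec=rocksalt_cubic(A_FCC, ferr_voxel, empty_voxel),
                        lineshape=SCENARIO_LINESHAPE)
    if name == "tet_pattern":
        up = VoxelModel(frame, ferr, (0.0, 0.0, OFF2_NM))
        down = VoxelModel(frame, ferr, (0.0, 0.0, -OFF2_NM))
        return Scenario(name, "lattice", _q_lattice(),
                        {"symmetry": "tetragonal", "constant": A_TET,
                         "c_pair": 2 * A_TET, "offset": OFF2_NM},
                        spec=tetragonal_facing_pairs(A_TET, 2 * A_TET, up, down),
                        lineshape=SCENARIO_LINESHAPE)
    if name.startswith("conversion_route"):
        route = {"conversion_route1": "surface",
                 "conversion_route2": "uniform",
                 "conversion_route3": "center"}[name]
        d_end = D_ENDPOINTS[route]
        return Scenario(name, "conversion", _q_lattice(),
                        {"symmetry": "sc", "constant": A_CONVERSION,
                         "route": route, "d_final": d_end, "base_guest": ferr},
                        spec=simple_cubic(A_CONVERSION, ferr_voxel),
                        lineshape=SCENARIO_LINESHAPE, route=route,
                        schedule=_conversion_schedule(d_end))
    raise KeyError(
        f"unknown scenario {name!r}; registry: {', '.join(SCENARIO_NAMES)}"
    )


SCENARIO_NAMES = (
    "free_ferritin", "free_apoferritin",
    "voxel_off0", "voxel_off1", "voxel_off2", "empty_octa",
    "sl_full", "sl_half", "dl", "sc_full", "fcc_half", "tet_pattern",
    "conversion_route1", "conversion_route2", "conversion_route3",
)


def make_scenario(name: str) -> Scenario:
    """Build a fully parameterized scenario from the registry."""
    return _build(name)


def write_fixtures(outdir, seed: int = 0) -> list[str]:
    """Write one noisy profile plus a ground-truth sidecar per scenario."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for k, name in enumerate(SCENARIO_NAMES):
        sc = make_scenario(name)
        prof = sc.measure(seed + k)
        path = os.path.join(outdir, f"{name}.dat")
        write_profile(prof, path)
        sidecar = os.path.join(outdir, f"{name}.truth.txt")
        with open(sidecar, "w") as fh:
            fh.write(f"name = {name}\n")
            fh.write(f"kind = {sc.kind}\n")
            fh.write(f"seed = {seed + k}\n")
            for key, value in sc.truth.items():
                if key == "base_guest":
                    continue
                fh.write(f"{key} = {value}\n")
            if sc.schedule:
                sched = "; ".join(f"{t}:{d:.4f}" for t, d in sc.schedule)
                fh.write(f"schedule = {sched}\n")
        written.extend([path, sidecar])
    return written
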