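"""Scattering amplitudes for core-shell spheres, finite cylinders, and
twelve-cylinder octahedral wireframes hosting an optional guest protein.

All geometry lives in nanometres; momentum transfer crosses the public
interface in inverse Angstroms and is converted internally
(``q[nm^-1] = 10 * q[A^-1]``).  Excess scattering-length densities
("contrasts") are relative to solvent in arbitrary consistent units; the
defaults below put hydrated ferrihydrite, protein and solvated DNA
six-helix bundles in the ratio 11 : 1 : 1.4, motivated by their electron
densities.  Model observables used downstream (peak positions, relative
intensity trends) are insensitive to the exact ratio.

The composite "voxel" -- a wireframe DNA octahedron with a ferritin or
apoferritin guest at a prescribed internal offset -- is the unit scatterer
of every lattice in this package.  Solution scattering averages the voxel
intensity over orientations; a deterministic Fibonacci-sphere quadrature
is the default, with a seeded Monte-Carlo rotation average available as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .profiles import ScatteringProfile

__all__ = [
    "Q_NM_PER_ANG",
    "CONTRAST_CORE",
    "CONTRAST_PROTEIN",
    "CONTRAST_DNA",
    "BUNDLE_RADIUS_NM",
    "OCTA_EDGE_NM",
    "RadialShellModel",
    "CylinderElement",
    "FrameModel",
    "VoxelModel",
    "OrientationScheme",
    "sphere_kernel",
    "shell_amplitude",
    "cylinder_amplitude",
    "voxel_amplitude",
    "powder_intensity",
    "powder_mean_amplitude",
    "ferritin_model",
    "apoferritin_model",
    "octahedron_frame",
]

# q[nm^-1] = Q_NM_PER_ANG * q[A^-1]
Q_NM_PER_ANG = 10.0

# Default solvent-relative contrasts (iron core : protein shell : DNA bundle)
CONTRAST_CORE = 11.0
CONTRAST_PROTEIN = 1.0
CONTRAST_DNA = 1.4

# Six-helix-bundle cylinder radius and fitted octahedron edge length, nm
BUNDLE_RADIUS_NM = 3.0
OCTA_EDGE_NM = 27.8

# Ferritin geometry: ~8 nm iron core inside a ~12 nm protein shell
FERRITIN_CORE_RADIUS_NM = 4.0
FERRITIN_OUTER_RADIUS_NM = 6.0

_SMALL = 1e-4  # series-expansion threshold for oscillatory kernels


def sphere_kernel(x):
    """Normalized uniform-sphere amplitude kernel 3(sin x - x cos x)/x^3.

    Defined for x >= 0 with the removable singularity at 0 handled by a
    series expansion; ``sphere_kernel(0) == 1``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sphere_kernel argument must be nonnegative")
    out = np.empty_like(x)
    # the closed form loses ~3 eps/x^2 digits to cancellation, so the
    # series branch extends to 1e-2 where both are ~1e-12 accurate
    small = x < 1e-2
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0 - xs**6 / 15120.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out if out.ndim else float(out)


def _sinc(x):
    """sin(x)/x with the limit handled (numpy sinc is sin(pi x)/(pi x))."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def _cyl_cross_section(x):
    """2 J1(x)/x, the circular-cross-section factor, with series at small x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SMALL
    xs = x[small]
    out[small] = 1.0 - xs**2 / 8.0 + xs**4 / 192.0
    xl = x[~small]
    out[~small] = 2.0 * j1(xl) / xl
    return out


@dataclass(frozen=True)
class RadialShellModel:
    """Piecewise-constant radial contrast profile of a spherical particle.

    ``boundaries`` are outer radii (nm) of successive bands from the
    center outward; ``contrasts`` holds one solvent-relative excess
    density per band.  Ferritin is core+shell, apoferritin the same
    geometry with zero core contrast, and the iron-dissolution states add
    an inner void or a depleted core band.
    """

    boundaries: tuple
    contrasts: tuple

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        c = tuple(float(x) for x in self.contrasts)
        if len(b) == 0:
            raise ValueError("RadialShellModel needs at least one band")
        if len(b) != len(c):
            raise ValueError("need exactly one contrast per band")
        if b[0] <= 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be positive and strictly increasing")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "contrasts", c)

    @property
    def outer_radius(self) -> float:
        return self.boundaries[-1]

    def total_mass(self) -> float:
        """Total excess scattering mass (contrast x volume summed over bands)."""
        r = np.concatenate(([0.0], np.asarray(self.boundaries)))
        vols = 4.0 / 3.0 * np.pi * np.diff(r**3)
        return float(np.dot(vols, self.contrasts))

    def band_mass(self, index: int) -> float:
        r = np.concatenate(([0.0], np.asarray(self.boundaries)))
        vol = 4.0 / 3.0 * np.pi * (r[index + 1] ** 3 - r[index] ** 3)
        return float(vol * self.contrasts[index])


def ferritin_model(
    core_radius: float = FERRITIN_CORE_RADIUS_NM,
    outer_radius: float = FERRITIN_OUTER_RADIUS_NM,
    core_contrast: float = CONTRAST_CORE,
    shell_contrast: float = CONTRAST_PROTEIN,
) -> RadialShellModel:
    """Core-shell ferritin: iron core inside a protein shell."""
    return RadialShellModel((core_radius, outer_radius), (core_contrast, shell_contrast))


def apoferritin_model(
    core_radius: float = FERRITIN_CORE_RADIUS_NM,
    outer_radius: float = FERRITIN_OUTER_RADIUS_NM,
    shell_contrast: float = CONTRAST_PROTEIN,
) -> RadialShellModel:
    """Coreless ferritin: solvent-filled cavity inside the protein shell."""
    return RadialShellModel((core_radius, outer_radius), (0.0, shell_contrast))


def shell_amplitude(model: RadialShellModel, q) -> np.ndarray:
    """Real isotropic amplitude of a radial-shell sphere at q (A^-1).

    Superposition of uniform-sphere amplitudes weighted by the contrast
    *steps* at each boundary; at q -> 0 it equals the total excess
    scattering mass.
    """
    q_nm = np.atleast_1d(np.asarray(q, dtype=float)) * Q_NM_PER_ANG
    contrasts = list(model.contrasts) + [0.0]
    amp = np.zeros_like(q_nm)
    for i, radius in enumerate(model.boundaries):
        step = contrasts[i] - contrasts[i + 1]
        if step == 0.0:
            continue
        amp += step * (4.0 / 3.0) * np.pi * radius**3 * sphere_kernel(q_nm * radius)
    return amp if np.ndim(q) else float(amp[0])


@dataclass(frozen=True)
class CylinderElement:
    """A finite homogeneous cylinder between two endpoints (nm)."""

    endpoint_a: tuple
    endpoint_b: tuple
    radius: float = BUNDLE_RADIUS_NM
    contrast: float = CONTRAST_DNA

    def __post_init__(self):
        a = np.asarray(self.endpoint_a, dtype=float)
        b = np.asarray(self.endpoint_b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("endpoints must be 3-vectors")
        if np.linalg.norm(b - a) <= 0:
            raise ValueError("cylinder must have positive length")
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        object.__setattr__(self, "endpoint_a", tuple(a))
        object.__setattr__(self, "endpoint_b", tuple(b))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.endpoint_b, self.endpoint_a)))

    @property
    def axis(self) -> np.ndarray:
        d = np.subtract(self.endpoint_b, self.endpoint_a)
        return d / np.linalg.norm(d)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.endpoint_a) + np.asarray(self.endpoint_b))

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius**2 * self.length)


@dataclass(frozen=True)
class FrameModel:
    """A rigid wireframe built from cylinder elements."""

    elements: tuple
    label: str = "frame"

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise ValueError("frame needs at least one element")

    @property
    def circumradius(self) -> float:
        pts = np.array(
            [e.endpoint_a for e in self.elements] + [e.endpoint_b for e in self.elements]
        )
        return float(np.max(np.linalg.norm(pts, axis=1)))


def octahedron_frame(
    edge: float = OCTA_EDGE_NM,
    radius: float = BUNDLE_RADIUS_NM,
    contrast: float = CONTRAST_DNA,
) -> FrameModel:
    """Twelve-cylinder octahedral wireframe, centroid at the origin.

    Vertices sit on the +-x, +-y, +-z axes at distance edge/sqrt(2); each
    of the 12 edges is one six-helix-bundle cylinder.
    """
    if edge <= 0:
        raise ValueError("edge length must be positive")
    s = edge / np.sqrt(2.0)
    verts = [
        np.array([s, 0, 0]), np.array([-s, 0, 0]),
        np.array([0, s, 0]), np.array([0, -s, 0]),
        np.array([0, 0, s]), np.array([0, 0, -s]),
    ]
    elements = []
    for i in range(6):
        for j in range(i + 1, 6):
            if np.allclose(verts[i], -verts[j]):
                continue  # opposite vertices are not connected
            elements.append(
                CylinderElement(tuple(verts[i]), tuple(verts[j]), radius, contrast)
            )
    assert len(elements) == 12
    return FrameModel(tuple(elements), label="octahedron")


@dataclass(frozen=True)
class VoxelModel:
    """A frame plus an optional spherical guest at a 3D offset (nm)."""

    frame: FrameModel | None
    guest: RadialShellModel | None = None
    guest_offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        off = np.asarray(self.guest_offset, dtype=float)
        if off.shape != (3,):
            raise ValueError("guest_offset must be a 3-vector")
        if self.frame is not None and np.linalg.norm(off) >= self.frame.circumradius:
            raise ValueError("guest offset places guest outside the frame")
        object.__setattr__(self, "guest_offset", tuple(off))

    def total_mass(self) -> float:
        mass = 0.0
        if self.frame is not None:
            mass += sum(e.contrast * e.volume for e in self.frame.elements)
        if self.guest is not None:
            mass += self.guest.total_mass()
        return mass


def cylinder_amplitude(elem: CylinderElement, q_vectors) -> np.ndarray:
    """Complex amplitude of a finite cylinder at 3D q vectors (A^-1).

    Standard separable finite-cylinder amplitude (axial sinc times
    circular-cross-section Bessel factor) carrying the phase of the
    element's center position.
    """
    qv = np.asarray(q_vectors, dtype=float)
    single = qv.ndim == 1
    qv = np.atleast_2d(qv) * Q_NM_PER_ANG  # nm^-1
    u = elem.axis
    center = elem.center
    half = elem.length / 2.0
    q_par = qv @ u
    q_perp = np.linalg.norm(qv - q_par[..., None] * u, axis=-1)
    amp = (
        elem.contrast
        * elem.volume
        * _sinc(q_par * half)
        * _cyl_cross_section(q_perp * elem.radius)
    ).astype(complex)
    amp *= np.exp(1j * (qv @ center))
    return amp[0] if single else amp


def voxel_amplitude(voxel: VoxelModel, q_vectors) -> np.ndarray:
    """Coherent complex amplitude of a voxel at 3D q vectors (A^-1)."""
    qv = np.asarray(q_vectors, dtype=float)
    single = qv.ndim == 1
    qv2 = np.atleast_2d(qv)
    amp = np.zeros(qv2.shape[:-1], dtype=complex)
    if voxel.frame is not None:
        for elem in voxel.frame.elements:
            amp = amp + cylinder_amplitude(elem, qv2)
    if voxel.guest is not None:
        qmag = np.linalg.norm(qv2, axis=-1)
        phase = np.exp(1j * Q_NM_PER_ANG * (qv2 @ np.asarray(voxel.guest_offset)))
        amp = amp + shell_amplitude(voxel.guest, qmag) * phase
    return amp[0] if single else amp


@dataclass(frozen=True)
class OrientationScheme:
    """Unit q-directions with normalized weights for powder averaging.

    Every scatterer handled here (cylinders, spheres) is axially
    symmetric about its own axis, so averaging the intensity over q
    directions is equivalent to averaging over full body rotations; no
    spin angle is needed.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 3 or nodes.shape[0] == 0:
            raise ValueError("nodes must be a nonempty (N, 3) array")
        if weights.shape != (nodes.shape[0],) or np.any(weights < 0):
            raise ValueError("weights must be nonnegative, one per node")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def fibonacci(cls, n: int = 2000) -> "OrientationScheme":
        """Deterministic equal-weight Fibonacci-spiral sphere covering."""
        if n < 1:
            raise ValueError("need at least one node")
        i = np.arange(n, dtype=float)
        golden = (1.0 + np.sqrt(5.0)) / 2.0
        z = 1.0 - (2.0 * i + 1.0) / n
        phi = 2.0 * np.pi * i / golden
        r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        nodes = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        return cls(nodes, np.full(n, 1.0 / n))

    @classmethod
    def monte_carlo(cls, n: int, seed: int) -> "OrientationScheme":
        """Seeded uniform-random directions (oracle mode)."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n, 3))
        nodes = v / np.linalg.norm(v, axis=1, keepdims=True)
        return cls(nodes, np.full(n, 1.0 / n))


def powder_mean_amplitude(
    voxel: VoxelModel,
    q,
    scheme: OrientationScheme | None = None,
) -> np.ndarray:
    """Orientation-averaged (signed, real) scattering amplitude on a q grid.

    For a centrosymmetric scatterer the mean amplitude is real; it is the
    coherent amplitude entering Bragg structure factors in the decoupling
    approximation, and its sign oscillations drive the interference
    between frame and guest at the lattice peak positions.
    """
    q = np.asarray(q, dtype=float)
    if scheme is None:
        scheme = OrientationScheme.fibonacci()
    qvecs = q[None, :, None] * scheme.nodes[:, None, :]
    amp = voxel_amplitude(voxel, qvecs)
    return np.einsum("d,dq->q", scheme.weights, amp.real)


def powder_intensity(
    voxel: VoxelModel,
    q,
    scheme: OrientationScheme | None = None,
) -> ScatteringProfile:
    """Orientation-averaged scattered intensity of a voxel on a q grid (A^-1).

    The weighted mean of |amplitude|^2 over the scheme's directions; for a
    lone spherical guest the result is exactly orientation-independent.
    """
    q = np.asarray(q, dtype=float)
    if scheme is None:
        scheme = OrientationScheme.fibonacci()
    qvecs = q[None, :, None] * scheme.nodes[:, None, :]  # (Nd, Nq, 3)
    amp = voxel_amplitude(voxel, qvecs)
    intensity = np.einsum("d,dq->q", scheme.weights, np.abs(amp) ** 2)
    return ScatteringProfile(q=q, intensity=intensity, metadata={"model": "powder_intensity"})
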