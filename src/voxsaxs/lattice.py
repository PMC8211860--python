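"""Reflection enumeration, structure factors with voxel bases, and 1D
powder patterns for 2D and 3D voxel lattices.

A lattice is a set of Bravais vectors (nm) plus a basis of voxel species
at fractional coordinates.  Powder patterns are built reflection-by-
reflection: every reciprocal point q_hkl within range contributes
``multiplicity x |F_hkl|^2`` attenuated by a Debye-Waller factor, dressed
with a finite line shape, and weighted by a Lorentz factor (q^-2 for 3D
powders, q^-1 for powder-averaged 2D layers).

Frames in these lattices are orientationally locked -- vertex-to-vertex
bonds align every octahedron with the lattice axes -- so the structure
factor evaluates the frame amplitude exactly along each reciprocal
vector of a reflection's star (real for the centrosymmetric frames used
here).  The sign oscillations of that directional amplitude against the
positive guest amplitude drive the peak suppressions and enhancements
observed when guests appear, move off-center, or dissolve.  Spherical
guests are exact; their internal offsets enter as explicit phases at
each reciprocal vector.  The brute-force Debye sum over a finite
cluster is provided as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .formfactors import (
    Q_NM_PER_ANG,
    OrientationScheme,
    VoxelModel,
    powder_intensity,
    powder_mean_amplitude,
    shell_amplitude,
    voxel_amplitude,
)
from .profiles import ScatteringProfile

__all__ = [
    "LatticeSpec",
    "Reflection",
    "ReflectionList",
    "LineShapeParams",
    "enumerate_reflections",
    "structure_factor",
    "powder_pattern",
    "PatternEngine",
    "debye_sum_oracle",
    "simple_cubic",
    "square_lattice",
    "rocksalt_cubic",
    "square_alternating",
    "double_layer",
    "tetragonal_facing_pairs",
]

DEBYE_PARTICLE_CAP = 500


@dataclass(frozen=True)
class LatticeSpec:
    """Bravais vectors, basis-site occupancy and species definitions.

    ``vectors`` holds 2 or 3 lattice vectors in nm; ``basis`` is a tuple of
    ``(species_label, fractional_coordinates)``; ``species`` maps each
    label to its :class:`VoxelModel`.  ``n_layers`` marks a finite stack
    count along the last vector: reflections probing that direction are
    Scherrer-broadened accordingly (used for the double-layer system).
    """

    dimensionality: int
    vectors: tuple
    basis: tuple
    species: dict
    symmetry_label: str = ""
    n_layers: int | None = None

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        vecs = tuple(np.asarray(v, dtype=float) for v in self.vectors)
        if len(vecs) != self.dimensionality:
            raise ValueError("need one lattice vector per dimension")
        A = np.array(vecs)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("lattice vectors must be linearly independent")
        if len(self.basis) == 0:
            raise ValueError("need at least one basis site")
        basis = []
        for label, frac in self.basis:
            frac = np.asarray(frac, dtype=float)
            if frac.shape != (self.dimensionality,):
                raise ValueError("fractional coordinate dimensionality mismatch")
            if np.any(frac < 0) or np.any(frac >= 1):
                raise ValueError("fractional coordinates must lie in [0, 1)")
            if label not in self.species:
                raise ValueError(f"basis references unknown species {label!r}")
            basis.append((label, tuple(frac)))
        object.__setattr__(self, "vectors", vecs)
        object.__setattr__(self, "basis", tuple(basis))

    @property
    def direct_matrix(self) -> np.ndarray:
        """Rows are the lattice vectors (nm)."""
        return np.array(self.vectors)

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """Columns are the reciprocal vectors (nm^-1), a_i . b_j = 2 pi d_ij."""
        return 2.0 * np.pi * np.linalg.inv(self.direct_matrix)

    def q_of_hkl(self, hkl) -> float:
        """|q| of a reflection in A^-1."""
        g = self.reciprocal_matrix @ np.asarray(hkl, dtype=float)
        return float(np.linalg.norm(g) / Q_NM_PER_ANG)

    def scaled(self, factor: float) -> "LatticeSpec":
        """Uniformly scale all lattice vectors by ``factor``."""
        return replace(self, vectors=tuple(np.asarray(v) * factor for v in self.vectors))


@dataclass(frozen=True)
class Reflection:
    """One symmetry-degenerate group of reciprocal points."""

    hkl: tuple          # representative indices
    q: float            # A^-1
    multiplicity: int
    F2: float           # multiplicity-averaged squared structure factor
    members: tuple = field(repr=False, default=())

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.F2 < 0:
            raise ValueError("squared structure factor must be nonnegative")


class ReflectionList(list):
    """Ascending-q list of :class:`Reflection` entries."""

    @property
    def q(self) -> np.ndarray:
        return np.array([r.q for r in self])


def _hkl_candidates(spec: LatticeSpec, q_max: float):
    """All integer index tuples (excluding the origin) with q <= q_max."""
    q_max_nm = q_max * Q_NM_PER_ANG
    A = spec.direct_matrix
    ranges = []
    for i in range(spec.dimensionality):
        hmax = int(np.ceil(q_max_nm * np.linalg.norm(A[i]) / (2 * np.pi))) + 1
        ranges.append(np.arange(-hmax, hmax + 1))
    grids = np.meshgrid(*ranges, indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=-1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ spec.reciprocal_matrix.T
    q = np.linalg.norm(g, axis=1) / Q_NM_PER_ANG
    keep = q <= q_max * (1 + 1e-12)
    return hkl[keep], q[keep]


def _representative(members) -> tuple:
    """Canonical indices for a degenerate group: |h| >= |k| >= |l|, lexicographic min."""
    return min(tuple(sorted((abs(int(x)) for x in m), reverse=True)) for m in members)


def enumerate_reflections(
    spec: LatticeSpec,
    q_max: float,
    species_amplitudes: dict | None = None,
) -> ReflectionList:
    """Enumerate symmetry-distinct reflections with q <= q_max (A^-1).

    Reflections are grouped by degenerate |q|; each group carries its
    multiplicity and the group-averaged squared structure factor.  With no
    amplitude table given, every species scatters as a unit point, so
    basis-geometry extinctions (which then have zero weight) are visible.
    Extinct reflections are retained.
    """
    hkl, q = _hkl_candidates(spec, q_max)
    out = ReflectionList()
    if hkl.shape[0] == 0:
        warnings.warn("q_max is below the first allowed reflection; empty list")
        return out
    order = np.argsort(q, kind="stable")
    hkl, q = hkl[order], q[order]
    # group by degenerate q (relative tolerance)
    groups: list[list[int]] = [[0]]
    for i in range(1, len(q)):
        if q[i] - q[groups[-1][0]] <= 1e-9 * max(q[i], 1e-12) + 1e-15:
            groups[-1].append(i)
        else:
            groups.append([i])
    if species_amplitudes is None:
        species_amplitudes = {label: 1.0 for label in spec.species}
    for idx in groups:
        members = tuple(tuple(int(x) for x in hkl[i]) for i in idx)
        q0 = float(np.mean(q[idx]))
        amps = (
            species_amplitudes(q0) if callable(species_amplitudes) else species_amplitudes
        )
        F2 = float(np.mean([structure_factor(spec, m, amps) for m in members]))
        out.append(
            Reflection(
                hkl=_representative(members),
                q=q0,
                multiplicity=len(members),
                F2=F2,
                members=members,
            )
        )
    return out


def structure_factor(spec: LatticeSpec, hkl, species_amplitudes: dict) -> float:
    """|F|^2 of one reflection given per-species isotropic amplitudes.

    An amplitude entry may be a scalar (whole-voxel effective amplitude)
    or a ``(frame_amplitude, guest_amplitude)`` pair; in the latter case
    the species' guest offset enters as an explicit phase at the actual
    reciprocal vector of ``hkl``.
    """
    hkl = np.asarray(hkl, dtype=float)
    g_nm = spec.reciprocal_matrix @ hkl  # nm^-1
    F = 0.0 + 0.0j
    for label, frac in spec.basis:
        if label not in species_amplitudes:
            raise KeyError(f"no amplitude supplied for species {label!r}")
        entry = species_amplitudes[label]
        phase = np.exp(2j * np.pi * float(np.dot(hkl, frac)))
        if np.isscalar(entry):
            site_amp = complex(entry)
        else:
            frame_amp, guest_amp = entry
            voxel = spec.species[label]
            offset = np.zeros(3)
            if voxel is not None:
                offset = np.asarray(voxel.guest_offset, dtype=float)
            g3 = np.zeros(3)
            g3[: g_nm.size] = g_nm
            site_amp = frame_amp + guest_amp * np.exp(1j * float(np.dot(g3, offset)))
        F += site_amp * phase
    return float(np.abs(F) ** 2)


@dataclass(frozen=True)
class LineShapeParams:
    """Peak dressing for powder patterns.

    width is the Lorentzian half-width at half-maximum (or Gaussian sigma)
    in A^-1; dw_sigma the RMS site displacement in nm for the
    Debye-Waller factor; the background is ``bg_coeff * q^-bg_exp +
    bg_const``.  ``lorentz_power`` overrides the dimension-derived
    default (2 for 3D, 1 for 2D).
    """

    width: float = 4e-4
    dw_sigma: float = 2.0
    scale: float = 1.0
    bg_coeff: float = 0.0
    bg_exp: float = 4.0
    bg_const: float = 0.0
    shape: str = "lorentzian"
    lorentz_power: int | None = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.dw_sigma < 0:
            raise ValueError("Debye-Waller RMS must be nonnegative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError("shape must be 'lorentzian' or 'gaussian'")


def _peak_profile(q, q0, width, shape):
    """Unit-area line shape centered at q0."""
    if shape == "lorentzian":
        return (width / np.pi) / ((q - q0) ** 2 + width**2)
    return np.exp(-0.5 * ((q - q0) / width) ** 2) / (width * np.sqrt(2 * np.pi))


class PatternEngine:
    """Precomputed reflection table and frame amplitudes for one lattice.

    The frame contribution is independent of the guest state, so sweeping
    guest states (e.g. an iron-dissolution series) reuses the reflection
    enumeration and all directional frame amplitudes.
    """

    def __init__(
        self,
        spec: LatticeSpec,
        q_max: float,
        orientation_nodes: int = 1000,
    ):
        self.spec = spec
        self.orientation_nodes = orientation_nodes
        self.reflections = enumerate_reflections(spec, q_max)
        self._labels = list(spec.species)
        self._precompute_forms()

    def _frame_directional(self, label: str, g3_ang: np.ndarray) -> float:
        """Frame amplitude of a species along one reciprocal vector (A^-1)."""
        voxel = self.spec.species[label]
        if voxel is None or voxel.frame is None:
            return 0.0
        return float(voxel_amplitude(VoxelModel(voxel.frame), g3_ang).real)

    def _precompute_forms(self) -> None:
        """Per-reflection quadratic forms in the guest amplitudes.

        For each member m of a reflection's star, the frame part
        FS(m) = sum_s A_frame,s(q_m) P_s(m) is fixed, while the guest part
        is sum_s g_s G_s(m) with P_s the basis phase sum of species s and
        G_s additionally carrying the guest-offset phase.  Summing |F|^2
        over the star reduces to c0 + 2 c1.g + g.C2.g, precomputed here.
        """
        B = self.spec.reciprocal_matrix
        labels = self._labels
        if not self.reflections:
            self._forms = []
            return
        members_per = [np.array(r.members, dtype=float) for r in self.reflections]
        counts = [m.shape[0] for m in members_per]
        H = np.concatenate(members_per)                   # (M, dim)
        g_nm = H @ B.T                                    # (M, dim), nm^-1
        G3 = np.zeros((H.shape[0], 3))
        G3[:, : g_nm.shape[1]] = g_nm
        P_all = np.zeros((len(labels), H.shape[0]), dtype=complex)
        G_all = np.zeros_like(P_all)
        FS_all = np.zeros(H.shape[0], dtype=complex)
        for si, label in enumerate(labels):
            voxel = self.spec.species[label]
            fracs = np.array(
                [frac for blabel, frac in self.spec.basis if blabel == label], dtype=float
            )
            if fracs.size == 0:
                continue
            site_sum = np.exp(2j * np.pi * (H @ fracs.T)).sum(axis=1)
            offset = np.asarray(voxel.guest_offset) if voxel is not None else np.zeros(3)
            guest_phase = np.exp(1j * (G3 @ offset))
            P_all[si] = site_sum
            G_all[si] = site_sum * guest_phase
            if voxel is not None and voxel.frame is not None:
                frame_dir = voxel_amplitude(
                    VoxelModel(voxel.frame), G3 / Q_NM_PER_ANG
                ).real
                FS_all += frame_dir * site_sum
        self._forms = []
        start = 0
        for c in counts:
            sl = slice(start, start + c)
            start += c
            FS = FS_all[sl]
            G = G_all[:, sl]
            c0 = float(np.sum(np.abs(FS) ** 2))
            c1 = np.real(G @ FS.conj())
            C2 = np.real(G @ G.conj().T)
            self._forms.append((c0, c1, C2))

    def _guest_amps(self, index: int, guest_override: dict | None) -> np.ndarray:
        refl = self.reflections[index]
        g = np.zeros(len(self._labels))
        for si, label in enumerate(self._labels):
            voxel = self.spec.species[label]
            guest = None if voxel is None else voxel.guest
            if guest_override is not None and label in guest_override:
                guest = guest_override[label]
            g[si] = shell_amplitude(guest, refl.q) if guest is not None else 0.0
        return g

    def species_amplitudes(self, index: int, guest_override: dict | None = None) -> dict:
        """(frame, guest) amplitude table at reflection ``index``.

        The frame entry is the directional amplitude along the reflection's
        representative member, for use with :func:`structure_factor`.
        """
        refl = self.reflections[index]
        B = self.spec.reciprocal_matrix
        amps = {}
        g = self._guest_amps(index, guest_override)
        for si, label in enumerate(self._labels):
            h = np.asarray(refl.members[0], dtype=float)
            g_nm = B @ h
            g3 = np.zeros(3)
            g3[: g_nm.size] = g_nm
            amps[label] = (self._frame_directional(label, g3 / Q_NM_PER_ANG), g[si])
        return amps

    def peak_weights(self, guest_override: dict | None = None) -> np.ndarray:
        """Summed |F|^2 over each reflection's star."""
        weights = np.empty(len(self.reflections))
        for i in range(len(self.reflections)):
            g = self._guest_amps(i, guest_override)
            c0, c1, C2 = self._forms[i]
            weights[i] = c0 + 2.0 * float(c1 @ g) + float(g @ C2 @ g)
        return weights

    def pattern(
        self,
        lineshape: LineShapeParams,
        q,
        guest_override: dict | None = None,
        metadata: dict | None = None,
    ) -> ScatteringProfile:
        q = np.asarray(q, dtype=float)
        power = lineshape.lorentz_power
        if power is None:
            power = 2 if self.spec.dimensionality == 3 else 1
        weights = self.peak_weights(guest_override)
        intensity = np.zeros_like(q)
        c_nm = (
            np.linalg.norm(self.spec.vectors[-1]) if self.spec.n_layers else None
        )
        for refl, w in zip(self.reflections, weights):
            if w <= 0:
                continue
            q_nm = refl.q * Q_NM_PER_ANG
            dw = np.exp(-(q_nm**2) * lineshape.dw_sigma**2)
            width = lineshape.width
            if self.spec.n_layers is not None and refl.members[0][-1] != 0:
                # Scherrer broadening from a finite out-of-plane stack
                width = width + 2 * np.pi / (self.spec.n_layers * c_nm) / Q_NM_PER_ANG
            intensity += w * dw * _peak_profile(q, refl.q, width, lineshape.shape)
        intensity *= lineshape.scale * q ** (-float(power))
        intensity += lineshape.bg_coeff * q ** (-lineshape.bg_exp) + lineshape.bg_const
        md = {"model": "powder_pattern", "symmetry": self.spec.symmetry_label}
        if metadata:
            md.update(metadata)
        return ScatteringProfile(q=q, intensity=intensity, metadata=md)


def powder_pattern(
    spec: LatticeSpec,
    lineshape: LineShapeParams,
    q,
    orientation_nodes: int = 1000,
) -> ScatteringProfile:
    """1D powder pattern of a voxel lattice on a q grid (A^-1)."""
    q = np.asarray(q, dtype=float)
    engine = PatternEngine(spec, q_max=float(q[-1]) * 1.02, orientation_nodes=orientation_nodes)
    return engine.pattern(lineshape, q)


def debye_sum_oracle(positions, amplitudes, q) -> ScatteringProfile:
    """Exact powder intensity of a finite set of isotropic scatterers.

    I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij); positions in nm, q in A^-1.
    ``amplitudes`` is an (N,) constant array or an (N, len(q)) table.
    Quadratic in particle count, hence capped at 500 particles.
    """
    positions = np.asarray(positions, dtype=float)
    q = np.asarray(q, dtype=float)
    n = positions.shape[0]
    if n > DEBYE_PARTICLE_CAP:
        raise ValueError(f"particle count {n} exceeds cap {DEBYE_PARTICLE_CAP}")
    f = np.asarray(amplitudes, dtype=float)
    if f.ndim == 1:
        f = np.broadcast_to(f[:, None], (n, q.size))
    q_nm = q * Q_NM_PER_ANG
    r = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    # sinc(x) with numpy convention sin(pi x)/(pi x)
    sinc = np.sinc(q_nm[:, None, None] * r[None, :, :] / np.pi)
    intensity = np.einsum("iq,jq,qij->q", f, f, sinc)
    return ScatteringProfile(q=q, intensity=intensity, metadata={"model": "debye_sum"})


# ---------------------------------------------------------------------------
# Lattice constructors for the systems studied here


def simple_cubic(a: float, voxel: VoxelModel, label: str = "sc") -> LatticeSpec:
    """Simple cubic lattice of one voxel species, constant a (nm)."""
    e = np.eye(3) * a
    return LatticeSpec(3, tuple(e), (("v", (0.0, 0.0, 0.0)),), {"v": voxel}, label)


def square_lattice(a: float, voxel: VoxelModel, label: str = "square") -> LatticeSpec:
    """2D square single layer, constant a (nm)."""
    e = np.eye(2) * a
    return LatticeSpec(2, tuple(e), (("v", (0.0, 0.0)),), {"v": voxel}, label)


def square_alternating(
    a_cell: float, filled: VoxelModel, empty: VoxelModel, label: str = "square-half"
) -> LatticeSpec:
    """Checkerboard half-filled single layer on the sqrt(2)-doubled cell.

    ``a_cell`` is the constant of the filled sublattice (sqrt(2) x the
    underlying voxel spacing); the empty voxel sits at the cell center.
    The cell vectors run along the voxel-grid diagonals so that the
    octahedra stay vertex-bonded along the cartesian axes.
    """
    h = a_cell / np.sqrt(2.0)
    vecs = (np.array([h, h]), np.array([-h, h]))
    return LatticeSpec(
        2,
        vecs,
        (("full", (0.0, 0.0)), ("empty", (0.5, 0.5))),
        {"full": filled, "empty": empty},
        label,
    )


def rocksalt_cubic(
    a_cell: float, filled: VoxelModel, empty: VoxelModel, label: str = "fcc-half"
) -> LatticeSpec:
    """Half-filled 3D array: alternating filled/empty voxels, FCC cell.

    ``a_cell`` is the doubled (FCC) cell constant, i.e. twice the voxel
    spacing; filled voxels occupy the FCC positions, empty ones the
    octahedral holes.
    """
    e = np.eye(3) * a_cell
    filled_sites = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    empty_sites = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    basis = tuple(("full", s) for s in filled_sites) + tuple(("empty", s) for s in empty_sites)
    return LatticeSpec(3, tuple(e), basis, {"full": filled, "empty": empty}, label)


def double_layer(
    a: float, voxel: VoxelModel, label: str = "double-layer"
) -> LatticeSpec:
    """Two stacked square layers on a cubic cell of constant a (nm).

    Indexed on the simple-cubic cell (layer spacing equals the in-plane
    constant); ``n_layers=2`` marks the finite out-of-plane extent, so
    l != 0 reflections emerge broadened -- the signature distinguishing a
    double from a single layer.
    """
    e = np.eye(3) * a
    return LatticeSpec(
        3, tuple(e), (("v", (0.0, 0.0, 0.0)),), {"v": voxel}, label, n_layers=2
    )


def tetragonal_facing_pairs(
    a: float, c_pair: float, voxel_up: VoxelModel, voxel_down: VoxelModel,
    label: str = "tetragonal",
) -> LatticeSpec:
    """Stacked double layers of off-centered voxels facing each other.

    Cell (a, a, c_pair) with two voxels along z whose guests are shifted
    toward each other; the alternating guest offsets make the protein
    sublattice tetragonal and generate weak odd-l superlattice
    reflections at low q for large shifts.
    """
    vecs = (np.array([a, 0, 0]), np.array([0, a, 0]), np.array([0, 0, c_pair]))
    return LatticeSpec(
        3,
        vecs,
        (("up", (0.0, 0.0, 0.0)), ("down", (0.0, 0.0, 0.5))),
        {"up": voxel_up, "down": voxel_down},
        label,
    )
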