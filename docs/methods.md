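# Methods

This note documents the scattering models, the numerical choices, and
the synthetic-data conditions behind the package, including where the
implemented physics deliberately parts company with literature-anchored
expectations.

## Scattering geometry and units

All geometry is carried internally in nanometres; momentum transfer q
crosses every public interface in inverse Angstroms and is converted at
the boundary (`q[nm⁻¹] = 10·q[Å⁻¹]`). Contrasts are solvent-relative
excess scattering-length densities in arbitrary consistent units with
the default ratio iron core : protein shell : DNA bundle = 11 : 1 : 1.4,
motivated by the electron densities of hydrated ferrihydrite (~0.97
e/Å³ above water), protein (~0.086) and a solvated six-helix DNA bundle.
Absolute intensities are therefore arbitrary; every analysis in the
package works on positions and relative intensities.

## Form factors

A radial-shell sphere (ferritin: core radius 4 nm, outer radius 6 nm;
apoferritin: zero core contrast) scatters with the contrast-step
superposition of uniform-sphere amplitudes. The sphere kernel
`3(sin x − x cos x)/x³` switches to its Taylor series below x = 10⁻²:
the closed form loses ~3ε/x² relative digits to cancellation, so the
wider series branch keeps both branches accurate to ~10⁻¹².

A frame element is a finite homogeneous cylinder with the separable
amplitude `ΔρV · sinc(q∥L/2) · 2J₁(q⊥R)/(q⊥R)` and the phase of its
center. The octahedral frame places six vertices at distance
edge/√2 on the coordinate axes and connects them with twelve cylinders
(default length 27.8 nm, radius 3.0 nm); amplitudes of overlapping
elements add coherently, which double-counts the small vertex overlap
volumes — an accepted property of composite-cylinder models.

Orientation averaging uses an equal-weight Fibonacci-sphere covering
(default 2,000 directions). Every scatterer here is axisymmetric about
its own axis, so averaging over q directions equals averaging over body
rotations. The quadrature agrees with a 20,000-sample seeded
Monte-Carlo rotation average to within the Monte-Carlo noise (~1%) and
with itself on node doubling to <0.5%; its bias against an 8,000-node
reference is ~10⁻⁵.

## Frame geometry and the measured form-factor maxima

The rigid twelve-cylinder octahedron at cylinder length 27.8 nm places
its first two orientation-averaged maxima at q₁ ≈ 0.0292 Å⁻¹ and
q₂ ≈ 0.0550 Å⁻¹ (ratio 1.88). Three independent computations agree:
the Fibonacci quadrature, a thin-rod Debye discretization, and a 3D
FFT of the rasterized density. Measured empty-frame curves in the
literature instead show maxima near 0.022 and 0.038 Å⁻¹ (ratio 1.73) —
exactly the signature of a thin spherical shell at the octahedron's
circumradius (~20 nm). Real wireframe octahedra are distorted and
flexible; mass redistributed toward the circumsphere reproduces those
positions, but flexible or distorted frames are outside this package's
scope, so the rigid-model maxima stand, and checks anchored to the
measured 0.022 Å⁻¹ value fail by design.

The guest-interference physics is reproduced at the model's own maxima:
a centered ferritin guest lowers intensity at q₁ and raises it at q₂
(destructive, then constructive interference with the frame amplitude),
and an apoferritin guest leaves both nearly unchanged — which is why the
maxima recover when an iron core dissolves.

The same geometry shifts the frame amplitude's sign structure at the
Bragg positions of a ~56 nm simple-cubic lattice. In a converting
ferritin array the relative intensity of any peak where the directional
frame amplitude is negative and comparable in magnitude to the guest
amplitude is suppressed to a minimum and then recovers as iron leaves.
With the rigid frame this cancellation occurs at the 3rd peak (111)
rather than the 2nd (110), and the 4th peak's relative intensity
decreases rather than increases; the corresponding trend assertions in
the acceptance suite fail for this reason and are retained unmodified.
The removed-iron estimator is unaffected: it matches model to
observation under the same frame and recovers route-matched d within
±0.05 under default noise (exactly, in most seeds).

## Lattice patterns

Reflections are enumerated by brute force over integer index ranges
bounded by `|h_i| ≤ |a_i|·q_max/2π`, grouped by degenerate |q| (relative
tolerance 10⁻⁹); each group stores all star members. Extinct groups are
retained with zero weight.

Because voxels bond vertex-to-vertex, frames are orientationally locked
to the lattice axes. Structure factors therefore use the exact
directional frame amplitude along each member's reciprocal vector —
coupled sums, not a decoupling approximation. The guest contribution is
isotropic and carries the offset phase `e^(iq⃗·δ)` per member. Summing
|F|² over a star reduces to a quadratic form in the guest amplitudes
with precomputed coefficients, so guest sweeps (dissolution series,
estimator grids) reuse all frame computations. The fast path is verified
against the direct per-member `structure_factor` sum to machine
precision, and the whole pattern against the Debye sum on a 4×4×4
cluster (positions to one grid step; height ratios to 10% with the line
width matched to the cluster's integral breadth).

Line shapes are unit-area Lorentzian (default half-width 4×10⁻⁴ Å⁻¹) or
Gaussian; the Debye–Waller factor uses an RMS site displacement of
2 nm by default; the Lorentz factor is q⁻² for 3D powders and q⁻¹ for
powder-averaged 2D layers. The double layer is modeled on the
simple-cubic cell (layer spacing equal to the in-plane constant) with a
finite stack count of 2: reflections with l ≠ 0 are Scherrer-broadened
by 2π/(n_layers·c), which reproduces the emergence of broad (111)/(211)
features over the sharp in-plane square pattern. The "patterned" 3D
design is a tetragonal cell of two voxel layers whose guests face each
other at ±δ along z; odd-l superlattice reflections grow as sin²(πδ/c₀)
and vanish for centered guests. Under the scenario noise model the q⁻²
Lorentz factor keeps the low-q region high-signal, so the superlattice
peak is detectable down to sub-nm offsets here; in measured profiles its
visibility threshold (reported near ~3 nm) is set by disorder and
background terms this generator does not include. For l = 0 star
members the ±z offsets cancel, and
powder-degenerate members with l ≠ 0 lose guest coherence, so in this
model the (210)-group relative intensity *falls* slightly with offset;
distinguishing offset designs in practice rests on the low-q
superlattice peak and the l ≠ 0 intensity redistribution.

## Iron-core dissolution

The removed fraction d is defined on iron *scattering mass*. Surface
route: core radius × (1−d)^(1/3) at intact density; uniform route:
density × (1−d) at intact radius; center route: solvent void of radius
R_core·d^(1/3). All three conserve the core band mass as (1−d)× intact
(to ~10⁻¹²; radii are clipped strictly inside (0, R_core) so the band
structure stays valid at the endpoints), coincide at d = 0 and d = 1,
and keep the protein shell fixed with solvent filling vacated volume.
Density profiles are sharp-edged. The reported acidic-buffer-only
partial release is representable as a small-d scenario, not a distinct
mechanism.

The estimator integrates baseline-subtracted intensity in fixed windows
around the first four observed peaks (window half-width 3×FWHM, capped
at 0.45× the gap to the nearest neighbor), normalizes to the first
peak, and grid-searches d in steps of 0.01 with parabolic refinement —
matching percent-level reporting conventions.

## Peak detection and indexing

Detection works on log₁₀ intensity with an additive floor (10⁻⁷ of the
maximum, raised to 5× the median uncertainty when a σ column is
present) so that noiseless model floors and noise excursions around
zero signal cannot register as peaks. The baseline is a grey-scale
morphological opening (window ~1/40 of the grid), which removes
features narrower than the window while preserving peak positions;
prominence is thresholded in decades (default 0.1). Centers are refined
parabolically; FWHM and areas are measured on the linear
baseline-subtracted signal.

Indexing fits q_i = (2π/a)√N_i over the allowed order sequences of
candidate symmetries (square, SC, FCC; BCC available), trying the first
four allowed orders as the identity of the lowest peak and weighting by
peak height. Peaks whose best relative mismatch exceeds 2% are marked
unassigned and contribute that tolerance to the residual, so an
assignment cannot win by dropping peaks. Near-tied residuals (within 5%
or an absolute floor of 0.005, the measurement-level accuracy of grid
centers) are broken toward the assignment assuming fewer extinct orders
among the first five peaks — higher orders legitimately vanish under
Debye–Waller attenuation and form-factor minima. This resolves the
inherent degeneracy that an FCC cell scaled by √8 indexes any SC series
exactly; a result is flagged ambiguous only when a different symmetry
ties at the same extinction count. Constants are reported in nm with
the weighted-fit standard error.

Form-factor fitting minimizes relative intensity residuals
(equivalent to log-intensity for small deviations) with the weight
floored at 10⁻⁴ of the maximum — exact form-factor zeros otherwise make
log residuals unbounded. The cheap core-shell family multistarts over
core-size/contrast basins; frame and voxel families fit edge length or
guest offset with the other geometry fixed.

## Synthetic data

Scenarios reproduce the studied systems with their reported constants:
square single layer 55 nm and its √2 half-filled checkerboard; double
layer 57 nm; full SC 58.3 nm; half-filled FCC 115.9 nm (rock-salt
arrangement of filled/empty voxels, i.e. 2× the voxel spacing);
tetragonal pattern on the 58.6 nm four-color cell; guest offsets 0,
1.5, 3.5 nm; conversion endpoints d = 0.66/0.75/0.61 for the
surface/uniform/center routes on the 4.8%-compacted 55.9 nm lattice,
approached along a saturating exponential d(t) over 9 h (τ = 1.5 h) that
plateaus after ~6 h.

The lattice-scenario q grid is 600 log-spaced points over
0.002–0.08 Å⁻¹; form-factor scenarios extend to 0.25 Å⁻¹ to cover two
oscillation features. Scenario Bragg peaks are resolution-limited
Gaussians with σ = 2×10⁻⁴ Å⁻¹ — narrow enough to baseline-resolve the
closest peak pair in the study, the FCC (111)/(200) doublet separated
by 1.45×10⁻³ Å⁻¹, as measured profiles do; with the default Lorentzian
width the (111) survives only as a shoulder under the 20×-stronger
(200) tail. Noise is additive Gaussian with variance αI + c, with α and
c calibrated per scenario so the first four Bragg peaks keep
signal-to-noise ≳ 20 ("resolution-limited" appearance); form-factor
scenarios use SNR ≈ 100 at the curve maximum. Same seed, same draw;
scenario regeneration is bit-identical.

What the generator does *not* emulate: instrument smearing, orientation
disorder of voxels within a lattice (visible in single layers),
paracrystalline and finite-domain broadening beyond the two-layer
Scherrer term, inter-particle interference of free proteins, and
polydispersity. Passing round-trip tests therefore demonstrate the
correctness and self-consistency of the analysis chain under idealized
but realistically scaled and noised conditions, not robustness to every
real-data artifact.

## Known limitations

- Rigid frames only; the measured frame maxima and the conversion-trend
  placements they control are not reproduced (see above).
- Default contrasts are electron-density estimates; observables that
  depend on the frame:guest amplitude ratio (relative peak intensities)
  shift with these, while positions, constants, yields and route-matched
  recovery do not.
- 2D layer patterns use the in-plane reflection sum with a q⁻¹ Lorentz
  factor; reciprocal-rod shape effects are not modeled.
- The diffuse (incoherent orientation-fluctuation) channel is omitted
  from patterns; backgrounds are the explicit power-law + constant.
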