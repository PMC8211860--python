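import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxsaxs.formfactors import VoxelModel, ferritin_model, shell_amplitude
from voxsaxs.lattice import (
    LatticeSpec,
    LineShapeParams,
    PatternEngine,
    debye_sum_oracle,
    double_layer,
    enumerate_reflections,
    powder_pattern,
    rocksalt_cubic,
    simple_cubic,
    square_lattice,
    structure_factor,
    tetragonal_facing_pairs,
)

SPHERE = VoxelModel(None, ferritin_model())


def brute_force_sc_orders(a_nm, q_max):
    """Independent enumeration of distinct h^2+k^2+l^2 values in range."""
    n_max = int((q_max * 10 * a_nm / (2 * np.pi)) ** 2)
    reachable = set()
    m = int(np.sqrt(n_max)) + 1
    for h in range(m + 1):
        for k in range(m + 1):
            for l in range(m + 1):
                n = h * h + k * k + l * l
                if 0 < n <= n_max:
                    reachable.add(n)
    return sorted(reachable)


class TestEnumerateReflections:
    def test_sc_583_within_005_gives_19_orders(self):
        spec = simple_cubic(58.3, SPHERE)
        refl = enumerate_reflections(spec, 0.05)
        orders = brute_force_sc_orders(58.3, 0.05)
        assert len(refl) == len(orders) == 19
        got = sorted(round((r.q * 583 / (2 * np.pi)) ** 2) for r in refl)
        assert got == orders
        assert 7 not in got and 15 not in got  # not sums of three squares

    def test_sc_111_position(self):
        spec = simple_cubic(58.3, SPHERE)
        q111 = spec.q_of_hkl((1, 1, 1))
        assert q111 == pytest.approx(2 * np.pi * np.sqrt(3) / 583, rel=1e-12)
        assert float(f"{q111:.2g}") == 0.019

    def test_fcc_first_five_position_ratios(self):
        spec = rocksalt_cubic(115.9, SPHERE, VoxelModel(None, ferritin_model(core_contrast=0)))
        refl = enumerate_reflections(spec, 0.035, {"full": 1.0, "empty": 0.0})
        qs = np.array([r.q for r in refl if r.F2 > 1e-9][:5])
        expected = np.array([1.0, np.sqrt(4 / 3), np.sqrt(8 / 3), np.sqrt(11 / 3), 2.0])
        np.testing.assert_allclose(qs / qs[0], expected, rtol=1e-9)

    def test_multiplicities(self):
        spec = simple_cubic(58.3, SPHERE)
        refl = enumerate_reflections(spec, 0.025)
        mult = {r.hkl: r.multiplicity for r in refl}
        assert mult[(1, 0, 0)] == 6
        assert mult[(1, 1, 0)] == 12
        assert mult[(1, 1, 1)] == 8

    def test_qmax_below_first_peak_warns_and_is_empty(self):
        spec = simple_cubic(58.3, SPHERE)
        with pytest.warns(UserWarning, match="below the first"):
            refl = enumerate_reflections(spec, 0.005)
        assert len(refl) == 0

    def test_extinct_reflections_retained_with_zero_weight(self):
        empty = VoxelModel(None, ferritin_model(core_contrast=0.0, shell_contrast=0.0))
        spec = rocksalt_cubic(115.9, SPHERE, empty)
        refl = enumerate_reflections(spec, 0.02, {"full": 1.0, "empty": 1.0})
        # with equal amplitudes the doubled cell is a half-spacing SC lattice:
        # mixed-parity reflections are extinct but still listed
        mixed = [r for r in refl if len({m % 2 for m in r.hkl}) > 1]
        assert mixed and all(r.F2 == pytest.approx(0.0, abs=1e-18) for r in mixed)

    @given(st.floats(min_value=0.5, max_value=3.0))
    @settings(max_examples=10, deadline=None)
    def test_scaling_covariance(self, s):
        spec = simple_cubic(58.3, SPHERE)
        refl = enumerate_reflections(spec, 0.03)
        scaled = enumerate_reflections(spec.scaled(s), 0.03 / s * (1 + 1e-12))
        assert len(refl) == len(scaled)
        np.testing.assert_allclose(
            [r.q for r in scaled], [r.q / s for r in refl], rtol=1e-9
        )


class TestStructureFactor:
    def test_single_site_is_squared_amplitude(self):
        spec = simple_cubic(58.3, SPHERE)
        assert structure_factor(spec, (2, 1, 0), {"v": 3.5}) == pytest.approx(12.25)

    def test_half_filled_selection_rules_match_two_site_sum(self):
        # direct two-site sum on the doubled cell: the guest-difference part
        # survives only for all-same-parity hkl (FCC rule)
        spec = rocksalt_cubic(100.0, SPHERE, VoxelModel(None, ferritin_model(core_contrast=0)))
        for hkl in [(h, k, l) for h in range(5) for k in range(h + 1) for l in range(k + 1)][1:]:
            got = structure_factor(spec, hkl, {"full": 1.0, "empty": 0.0})
            same_parity = len({x % 2 for x in hkl}) == 1
            # brute force over the 8 basis sites
            brute = 0j
            for label, frac in spec.basis:
                amp = 1.0 if label == "full" else 0.0
                brute += amp * np.exp(2j * np.pi * np.dot(hkl, frac))
            assert got == pytest.approx(abs(brute) ** 2, abs=1e-9)
            if not same_parity:
                assert got == pytest.approx(0.0, abs=1e-9)

    def test_guest_offset_phase_continuous_at_zero(self):
        a = 58.6
        up = VoxelModel(None, ferritin_model(), (0, 0, 1e-7))
        spec = tetragonal_facing_pairs(a, 2 * a, up, up)
        centered = tetragonal_facing_pairs(
            a, 2 * a, VoxelModel(None, ferritin_model()), VoxelModel(None, ferritin_model())
        )
        amps = {"up": (0.0, 5.0), "down": (0.0, 5.0)}
        for hkl in [(1, 0, 0), (1, 1, 2), (2, 1, 0)]:
            assert structure_factor(spec, hkl, amps) == pytest.approx(
                structure_factor(centered, hkl, amps), rel=1e-6
            )

    def test_missing_species_amplitude_raises(self):
        spec = simple_cubic(58.3, SPHERE)
        with pytest.raises(KeyError):
            structure_factor(spec, (1, 0, 0), {})


class TestPowderPattern:
    def test_peak_positions_match_enumeration(self, q_lattice):
        spec = simple_cubic(58.3, SPHERE)
        ls = LineShapeParams(width=2e-4, dw_sigma=0.0, shape="gaussian")
        prof = powder_pattern(spec, ls, q_lattice)
        refl = enumerate_reflections(spec, 0.03)
        for r in refl[:4]:
            sel = (q_lattice > r.q * 0.97) & (q_lattice < r.q * 1.03)
            qmax = q_lattice[sel][np.argmax(prof.intensity[sel])]
            assert abs(qmax - r.q) < np.diff(q_lattice).max()

    def test_positions_independent_of_lineshape_scale_linear(self, q_lattice):
        spec = simple_cubic(58.3, SPHERE)
        p1 = powder_pattern(spec, LineShapeParams(width=2e-4, scale=1.0), q_lattice)
        p2 = powder_pattern(spec, LineShapeParams(width=2e-4, scale=7.5), q_lattice)
        np.testing.assert_allclose(p2.intensity, 7.5 * p1.intensity, rtol=1e-12)

    def test_lorentz_power_defaults(self):
        q = np.geomspace(0.005, 0.05, 300)
        ls = LineShapeParams()
        p3 = powder_pattern(simple_cubic(58.3, SPHERE), ls, q)
        p2 = powder_pattern(square_lattice(55.0, SPHERE), ls, q)
        assert p3.metadata["model"] == "powder_pattern"
        # explicit override reproduces the 2D default on the 2D lattice
        p2b = powder_pattern(
            square_lattice(55.0, SPHERE), LineShapeParams(lorentz_power=1), q
        )
        np.testing.assert_allclose(p2.intensity, p2b.intensity, rtol=1e-12)

    def test_double_layer_broadens_out_of_plane_reflections(self, ferritin_voxel, q_lattice):
        dl = double_layer(57.0, ferritin_voxel)
        ls = LineShapeParams(width=2e-4, shape="gaussian")
        prof = powder_pattern(dl, ls, q_lattice)
        # the (111) region shows a broad bump, far lower than the sharp (100)
        q100 = 2 * np.pi / 570
        q111 = q100 * np.sqrt(3)
        h100 = np.interp(q100, q_lattice, prof.intensity)
        h111 = np.interp(q111, q_lattice, prof.intensity)
        assert h111 > 0
        assert h111 < 0.05 * h100

    def test_nonnegative_before_background(self, ferritin_voxel, q_lattice):
        spec = simple_cubic(58.3, ferritin_voxel)
        prof = powder_pattern(spec, LineShapeParams(width=2e-4), q_lattice)
        assert np.all(prof.intensity >= 0)


class TestDebyeOracle:
    def test_single_particle_gives_form_factor(self):
        q = np.geomspace(0.01, 0.05, 20)
        f = shell_amplitude(ferritin_model(), q)
        prof = debye_sum_oracle(np.zeros((1, 3)), f[None, :], q)
        np.testing.assert_allclose(prof.intensity, f**2, rtol=1e-12)

    def test_two_point_closed_form(self):
        d = 10.0
        q = np.array([0.01, 0.02, 0.037])
        prof = debye_sum_oracle([[0, 0, 0], [0, 0, d]], np.array([2.0, 2.0]), q)
        q_nm = q * 10
        expected = 2 * 4.0 * (1 + np.sin(q_nm * d) / (q_nm * d))
        np.testing.assert_allclose(prof.intensity, expected, rtol=1e-12)

    def test_first_interference_maximum_approaches_reciprocal_spacing(self):
        # oracle self-convergence on growing SC clusters
        a = 58.3
        q = np.linspace(0.006, 0.014, 400)
        peaks = []
        for n in (3, 5):
            pos = np.array(
                [[i, j, k] for i in range(n) for j in range(n) for k in range(n)], float
            ) * a
            prof = debye_sum_oracle(pos, np.ones(n**3), q)
            peaks.append(q[np.argmax(prof.intensity)])
        target = 2 * np.pi / (a * 10)
        assert abs(peaks[1] - target) < abs(peaks[0] - target) + 1e-5
        assert peaks[1] == pytest.approx(target, rel=0.02)

    def test_particle_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            debye_sum_oracle(np.zeros((501, 3)), np.ones(501), np.array([0.01]))


class TestPatternVsDebye:
    def test_sc_cluster_peak_positions_and_height_ratios(self):
        # 4x4x4 SC crystal of ferritin spheres: the Debye sum is exact, the
        # reflection-sum pattern uses a width matched to the finite size
        a = 58.3
        n = 4
        q = np.geomspace(0.008, 0.03, 600)
        pos = np.array(
            [[i, j, k] for i in range(n) for j in range(n) for k in range(n)], float
        ) * a
        amps = shell_amplitude(ferritin_model(), q)
        deb = debye_sum_oracle(pos, np.broadcast_to(amps, (n**3, q.size)), q)
        width = 2 * np.pi / (n * a * 10) / np.pi  # equal integral breadth
        pat = powder_pattern(
            simple_cubic(a, SPHERE),
            LineShapeParams(width=width, dw_sigma=0.0),
            q,
        )
        refl = enumerate_reflections(simple_cubic(a, SPHERE), 0.028)
        step = np.diff(q).max()
        h_deb, h_pat = [], []
        for r in refl:
            sel = (q > r.q - 4 * width) & (q < r.q + 4 * width)
            i_deb = np.argmax(deb.intensity[sel])
            i_pat = np.argmax(pat.intensity[sel])
            assert abs(q[sel][i_deb] - q[sel][i_pat]) <= step + 1e-12
            h_deb.append(deb.intensity[sel][i_deb])
            h_pat.append(pat.intensity[sel][i_pat])
        r_deb = np.array(h_deb) / h_deb[0]
        r_pat = np.array(h_pat) / h_pat[0]
        np.testing.assert_allclose(r_deb, r_pat, rtol=0.10)


class TestLatticeSpecValidation:
    def test_rejects_dependent_vectors(self):
        with pytest.raises(ValueError, match="independent"):
            LatticeSpec(2, (np.array([1.0, 0]), np.array([2.0, 0])), (("v", (0, 0)),), {"v": SPHERE})

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError, match="fractional"):
            LatticeSpec(2, (np.array([1.0, 0]), np.array([0, 1.0])), (("v", (0, 1.0)),), {"v": SPHERE})

    def test_rejects_unknown_species(self):
        with pytest.raises(ValueError, match="unknown species"):
            LatticeSpec(2, (np.array([1.0, 0]), np.array([0, 1.0])), (("w", (0, 0)),), {"v": SPHERE})


class TestHalfFilledEquivalence:
    def test_guest_difference_peaks_match_fcc_on_doubled_cell(self):
        # half-filled SC with spacing a0: the guest-difference component
        # produces exactly the FCC reflections of the 2*a0 cell
        a0 = 57.95
        spec = rocksalt_cubic(2 * a0, SPHERE, VoxelModel(None, ferritin_model(core_contrast=0)))
        refl = enumerate_reflections(spec, 0.03, {"full": 1.0, "empty": 0.0})
        allowed = sorted(r.q for r in refl if r.F2 > 1e-9)
        fcc_expect = sorted(
            2 * np.pi * np.sqrt(n) / (2 * a0 * 10) for n in (3, 4, 8, 11, 12, 16)
        )
        np.testing.assert_allclose(allowed[:6], fcc_expect, rtol=1e-9)


class TestTetragonalPattern:
    """Off-centered facing guest pairs generate odd-l superlattice
    reflections whose intensity grows ~sin^2 with the offset and
    vanishes for centered guests."""

    @staticmethod
    def _spec(offset):
        a = 58.6
        up = VoxelModel(None, ferritin_model(), (0, 0, offset))
        down = VoxelModel(None, ferritin_model(), (0, 0, -offset))
        return tetragonal_facing_pairs(a, 2 * a, up, down)

    def test_superlattice_weight_grows_as_sin_squared(self):
        a = 58.6
        q001 = 2 * np.pi / (2 * a * 10)
        weights = {}
        for off in (1.5, 3.5):
            eng = PatternEngine(self._spec(off), 0.008)
            i001 = int(np.argmin(np.abs(eng.reflections.q - q001)))
            weights[off] = eng.peak_weights()[i001]
        expected = (np.sin(np.pi * 3.5 / a) / np.sin(np.pi * 1.5 / a)) ** 2
        assert weights[3.5] / weights[1.5] == pytest.approx(expected, rel=0.01)

    def test_zero_offset_has_no_superlattice_peak(self):
        eng = PatternEngine(self._spec(0.0), 0.008)
        q001 = 2 * np.pi / (2 * 58.6 * 10)
        i001 = int(np.argmin(np.abs(eng.reflections.q - q001)))
        assert eng.peak_weights()[i001] == pytest.approx(0.0, abs=1e-12)

    def test_off2_scenario_shows_low_q_superlattice_peak(self, q_lattice):
        from voxsaxs.analysis import find_peaks
        from voxsaxs.formfactors import octahedron_frame
        from voxsaxs.synthetic import NoiseModel, simulate_measurement, _lattice_noise

        a = 58.6
        up = VoxelModel(octahedron_frame(), ferritin_model(), (0, 0, 3.5))
        down = VoxelModel(octahedron_frame(), ferritin_model(), (0, 0, -3.5))
        spec = tetragonal_facing_pairs(a, 2 * a, up, down)
        ls = LineShapeParams(width=2e-4, shape="gaussian")
        truth = powder_pattern(spec, ls, q_lattice)
        alpha, floor = _lattice_noise(truth)
        obs = simulate_measurement(truth, NoiseModel(alpha, floor, seed=0))
        peaks = sorted(find_peaks(obs), key=lambda p: p.center)
        q001 = 2 * np.pi / (2 * a * 10)
        assert peaks and abs(peaks[0].center - q001) < 3 * np.diff(q_lattice).max()
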