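"""Inverse analyses: peak detection, symmetry indexing, relative-intensity
tracking, reduction-degree estimation, form-factor fitting, and
encapsulation-yield arithmetic.

Peak positions encode lattice periodicities through q_hkl = 2 pi
sqrt(N)/a with N = h^2+k^2+l^2 restricted by the symmetry's selection
rules; indexing is a weighted least-squares fit of observed positions to
candidate N sequences, with the winning symmetry chosen by residual and
ties broken toward the assignment assuming fewer missing (extinct)
orders.  The removed-iron fraction of a converting ferritin lattice is
estimated by matching the relative integrated intensities of the first
four Bragg peaks against the dissolution forward model on a d grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import ndimage, signal

import lmfit

from .dissolution import ConversionState, ROUTES, converted_lattice_profile
from .formfactors import (
    OrientationScheme,
    RadialShellModel,
    VoxelModel,
    ferritin_model,
    octahedron_frame,
    powder_intensity,
    shell_amplitude,
)
from .lattice import LatticeSpec, LineShapeParams, PatternEngine
from .profiles import ScatteringProfile

__all__ = [
    "PeakObservation",
    "IndexingResult",
    "ReductionEstimate",
    "CountData",
    "AmbiguityError",
    "FitError",
    "find_peaks",
    "index_peaks",
    "relative_intensities",
    "estimate_reduction",
    "fit_form_factor",
    "count_yield",
]


@dataclass(frozen=True)
class PeakObservation:
    """One detected Bragg peak."""

    center: float   # q, A^-1
    height: float   # baseline-subtracted
    area: float     # baseline-subtracted integral, I*dq
    width: float    # FWHM, A^-1

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass
class IndexingResult:
    """Outcome of symmetry indexing a peak list."""

    symmetry: str
    constant: float                 # nm
    constant_sd: float              # nm
    assignments: list               # [(q, hkl tuple or None, N or None), ...]
    residual: float                 # weighted RMS relative error in q
    ambiguous: bool = False
    alternatives: list = field(default_factory=list)   # [(symmetry, constant, residual)]


@dataclass
class ReductionEstimate:
    """Removed-iron fraction estimate with its objective trace."""

    route: str
    d_hat: float
    objective: float
    trace: pd.DataFrame             # columns d, objective


@dataclass(frozen=True)
class CountData:
    """Direct particle counts from micrographs."""

    total: int
    filled: int
    empty: int

    def __post_init__(self):
        if min(self.total, self.filled, self.empty) < 0:
            raise ValueError("counts must be nonnegative")
        if self.filled + self.empty != self.total:
            raise ValueError("filled + empty must equal total")


class AmbiguityError(ValueError):
    """Raised when the peak list cannot single out one symmetry."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best-so-far parameters."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


# ---------------------------------------------------------------------------
# Peak detection


def find_peaks(
    profile: ScatteringProfile,
    min_prominence: float = 0.1,
    q_window: tuple | None = None,
) -> list[PeakObservation]:
    """Detect Bragg peaks above a smoothed baseline.

    Works on log-intensity: a running-median baseline (wide compared to
    the instrumental peak width) is subtracted and local maxima with at
    least ``min_prominence`` decades of prominence are kept.  Centers are
    refined parabolically; heights and areas are baseline-subtracted;
    widths are FWHM from the half-prominence crossings.
    """
    if len(profile) < 5:
        raise ValueError("profile too short for peak detection")
    q, I = profile.q, profile.intensity
    if q_window is not None:
        mask = (q >= q_window[0]) & (q <= q_window[1])
        if mask.sum() < 5:
            raise ValueError("q_window leaves too few points")
        q, I = q[mask], I[mask]
    if np.max(I) <= 0:
        raise ValueError("profile has no positive intensity")
    # additive floor caps the dynamic range so that noiseless model floors
    # (and numerically-extinct reflections) cannot masquerade as peaks; with
    # uncertainties present it is raised to the noise level so that noise
    # excursions around zero signal stay below the prominence threshold
    floor = np.max(I) * 1e-7
    if profile.sigma is not None:
        sig = profile.sigma if q_window is None else profile.sigma[mask]
        floor = max(floor, 5.0 * float(np.median(sig)))
    y = np.log10(np.maximum(I, 0.0) + floor)
    # morphological opening removes features narrower than the window,
    # leaving a baseline that hugs the curve between peaks and preserves
    # peak positions exactly
    win = max(9, 2 * (len(q) // 40) + 1)
    baseline = ndimage.grey_opening(y, size=win, mode="nearest")
    resid = y - baseline
    idx, props = signal.find_peaks(resid, prominence=min_prominence)
    if idx.size == 0:
        return []
    peaks = []
    base_lin = 10.0**baseline
    excess = np.maximum(I - base_lin, 0.0)
    min_dq = float(np.diff(q).min())
    for i in idx:
        # parabolic sub-grid refinement of the center
        if 0 < i < len(q) - 1:
            denom = resid[i - 1] - 2 * resid[i] + resid[i + 1]
            shift = 0.5 * (resid[i - 1] - resid[i + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            center = q[i] + shift * (q[min(i + 1, len(q) - 1)] - q[max(i - 1, 0)]) / 2.0
        else:
            center = q[i]
        height = float(I[i] - base_lin[i])
        if height <= 0:
            continue
        # FWHM by scanning the linear baseline-subtracted signal outward
        half = excess[i] / 2.0
        li = i
        while li > 0 and excess[li] > half:
            li -= 1
        ri = i
        while ri < len(q) - 1 and excess[ri] > half:
            ri += 1
        if li < i and excess[li + 1] > excess[li]:
            frac = (half - excess[li]) / (excess[li + 1] - excess[li])
            q_left = q[li] + frac * (q[li + 1] - q[li])
        else:
            q_left = q[li]
        if ri > i and excess[ri - 1] > excess[ri]:
            frac = (half - excess[ri]) / (excess[ri - 1] - excess[ri])
            q_right = q[ri] - frac * (q[ri] - q[ri - 1])
        else:
            q_right = q[ri]
        width = max(q_right - q_left, min_dq)
        lo = np.searchsorted(q, center - 3 * width)
        hi = np.searchsorted(q, center + 3 * width)
        lo, hi = max(lo, 0), min(hi, len(q))
        if hi - lo >= 2:
            area = float(np.trapezoid(np.maximum(I[lo:hi] - base_lin[lo:hi], 0.0), q[lo:hi]))
        else:
            area = height * width
        peaks.append(PeakObservation(center=float(center), height=height, area=area, width=float(width)))
    return peaks


# ---------------------------------------------------------------------------
# Symmetry indexing


def _allowed_orders(symmetry: str, n_max: int = 60) -> list[int]:
    """Allowed h^2+k^2(+l^2) values for a symmetry, ascending."""
    allowed = set()
    m = int(math.isqrt(n_max)) + 1
    if symmetry == "square":
        for h in range(m + 1):
            for k in range(m + 1):
                n = h * h + k * k
                if 0 < n <= n_max:
                    allowed.add(n)
    elif symmetry == "sc":
        for h in range(m + 1):
            for k in range(m + 1):
                for l in range(m + 1):
                    n = h * h + k * k + l * l
                    if 0 < n <= n_max:
                        allowed.add(n)
    elif symmetry == "fcc":
        for h in range(-m, m + 1):
            for k in range(-m, m + 1):
                for l in range(-m, m + 1):
                    if (h % 2 == k % 2 == l % 2) and (h, k, l) != (0, 0, 0):
                        n = h * h + k * k + l * l
                        if n <= n_max:
                            allowed.add(n)
    elif symmetry == "bcc":
        for h in range(-m, m + 1):
            for k in range(-m, m + 1):
                for l in range(-m, m + 1):
                    if (h + k + l) % 2 == 0 and (h, k, l) != (0, 0, 0):
                        n = h * h + k * k + l * l
                        if n <= n_max:
                            allowed.add(n)
    else:
        raise ValueError(f"unknown symmetry {symmetry!r}")
    return sorted(allowed)


def _hkl_label(symmetry: str, n: int) -> tuple:
    """Smallest index triple (or pair) realizing order n."""
    m = int(math.isqrt(n)) + 1
    best = None
    if symmetry == "square":
        for h in range(m + 1):
            for k in range(h + 1):
                if h * h + k * k == n:
                    cand = (h, k)
                    best = cand if best is None or cand < best else best
        return best
    for h in range(m + 1):
        for k in range(h + 1):
            for l in range(k + 1):
                if h * h + k * k + l * l != n:
                    continue
                if symmetry == "fcc" and not (h % 2 == k % 2 == l % 2):
                    continue
                if symmetry == "bcc" and (h + k + l) % 2 != 0:
                    continue
                cand = (h, k, l)
                best = cand if best is None or cand < best else best
    return best


def _fit_assignment(q_obs, weights, orders, start_index, unassigned_tol=0.02):
    """Greedy assignment of peaks to allowed orders, then weighted LS for
    the slope s = 2 pi / a.  Returns (slope, residual, Ns, n_skipped)."""
    s = q_obs[0] / math.sqrt(orders[start_index])
    for _ in range(3):
        Ns, used = [], start_index - 1
        for qi in q_obs:
            target = (qi / s) ** 2
            # next allowed order closest to target, strictly after the last used
            best_j, best_err = None, None
            for j in range(used + 1, len(orders)):
                err = abs(math.sqrt(orders[j]) * s - qi) / qi
                if best_err is None or err < best_err:
                    best_j, best_err = j, err
                if orders[j] > target * 1.8 + 2:
                    break
            if best_j is None or best_err > unassigned_tol:
                Ns.append(None)
            else:
                Ns.append(orders[best_j])
                used = best_j
        assigned = [(qi, w, n) for qi, w, n in zip(q_obs, weights, Ns) if n is not None]
        if len(assigned) < max(3, min(3, len(q_obs))):
            return None
        qa = np.array([x[0] for x in assigned])
        wa = np.array([x[1] for x in assigned])
        rn = np.sqrt([x[2] for x in assigned])
        s = float(np.sum(wa * rn * qa) / np.sum(wa * rn * rn))
    # residual over ALL peaks: an unassigned peak contributes at least the
    # unassigned tolerance, so assignments cannot win by dropping peaks
    rel_all = np.array(
        [
            abs(qi - s * math.sqrt(n)) / qi if n is not None else unassigned_tol
            for qi, n in zip(q_obs, Ns)
        ]
    )
    w_all = np.asarray(weights, dtype=float)
    residual = float(np.sqrt(np.sum(w_all * rel_all**2) / np.sum(w_all)))
    # variance of the slope from the weighted fit scatter
    dof = max(len(qa) - 1, 1)
    var_s = float(np.sum(wa * (qa - s * rn) ** 2) / np.sum(wa) / dof / np.mean(rn**2))
    n_used = [n for n in Ns if n is not None]
    return s, math.sqrt(max(var_s, 0.0)), residual, Ns, n_used


def index_peaks(
    peaks,
    candidates=("sc", "fcc", "square"),
    ambiguity_ratio: float = 0.05,
    ambiguity_floor: float = 0.005,
    unassigned_tol: float = 0.02,
) -> IndexingResult:
    """Assign a symmetry and lattice constant to a peak list.

    For each candidate symmetry the observed positions are fit to
    q_i = (2 pi / a) sqrt(N_i) over its allowed N sequence (trying the
    first few allowed orders as the identity of the lowest observed
    peak).  The symmetry with the smallest height-weighted relative
    residual wins; residuals within ``ambiguity_ratio`` of each other are
    tied and broken toward the assignment assuming fewer extinct orders,
    with the result flagged ambiguous.
    """
    peaks = sorted(peaks, key=lambda p: p.center)
    if len(peaks) < 3:
        raise AmbiguityError(
            f"need >= 3 peaks for a unique assignment, got {len(peaks)}",
            candidates=list(candidates),
        )
    q_obs = np.array([p.center for p in peaks])
    weights = np.array([p.height for p in peaks])
    weights = weights / weights.max()

    scored = []
    for sym in candidates:
        orders = _allowed_orders(sym)
        for start in range(4):
            fit = _fit_assignment(q_obs, weights, orders, start, unassigned_tol)
            if fit is None:
                continue
            s, s_sd, residual, Ns, n_used = fit
            # extinct orders assumed: allowed N skipped within the span of the
            # first few (strong) peaks -- high-order peaks disappear for
            # benign reasons (Debye-Waller, form-factor minima) and must not
            # count against an assignment
            head = Ns[:5]
            n_unassigned = sum(1 for n in head if n is None)
            used_head = [n for n in head if n is not None]
            skipped = 0
            if used_head:
                skipped = sum(
                    1
                    for n in orders
                    if used_head[0] <= n <= used_head[-1] and n not in used_head
                )
            scored.append((sym, s, s_sd, residual, Ns, skipped + n_unassigned))
    if not scored:
        raise AmbiguityError("no candidate symmetry indexes these peaks", list(candidates))

    best_res = min(x[3] for x in scored)
    # two assignments are tied when their residuals differ by less than the
    # measurement-level floor (peak centers are only grid-accurate)
    window = max(ambiguity_ratio * best_res, ambiguity_floor)
    tied = [x for x in scored if x[3] <= best_res + window]
    tied.sort(key=lambda x: (x[5], x[3]))
    sym, s, s_sd, residual, Ns, n_ext = tied[0]
    # genuinely ambiguous only if a different symmetry ties at the same
    # number of assumed extinctions; the FCC-mimics-SC degeneracy (scaled
    # cell with many extinct orders) is resolved, not ambiguous
    ambiguous = any(x[0] != sym and x[5] == n_ext for x in tied[1:])

    a_nm = 2.0 * np.pi / (s * 10.0)  # q in A^-1 -> a in nm
    a_sd = a_nm * s_sd / s
    assignments = [
        (float(qi), _hkl_label(sym, n) if n is not None else None, n)
        for qi, n in zip(q_obs, Ns)
    ]
    alternatives = sorted(
        {(x[0], round(2.0 * np.pi / (x[1] * 10.0), 2), round(x[3], 6)) for x in scored[1:]},
        key=lambda t: t[2],
    )
    return IndexingResult(
        symmetry=sym,
        constant=float(a_nm),
        constant_sd=float(a_sd),
        assignments=assignments,
        residual=float(residual),
        ambiguous=ambiguous,
        alternatives=list(alternatives),
    )


# ---------------------------------------------------------------------------
# Relative intensities and reduction estimation


def relative_intensities(
    peaks,
    pairs=((3, 4), (1, 3)),
    statistic: str = "area",
) -> pd.Series:
    """Ratio table over 1-based peak indices in ascending q.

    Returns each peak normalized to the 1st (``I2/I1``, ...) plus one
    entry per requested pair (``r3/4`` is peak3/peak4).  Missing peaks
    yield NaN, never zero.
    """
    if statistic not in ("area", "height"):
        raise ValueError("statistic must be 'area' or 'height'")
    peaks = sorted(peaks, key=lambda p: p.center)
    values = [getattr(p, statistic) for p in peaks]

    def get(i):
        return values[i - 1] if 1 <= i <= len(values) else np.nan

    out = {}
    for i in range(2, max(len(values), 1) + 1):
        out[f"I{i}/I1"] = get(i) / get(1)
    for i, j in pairs:
        out[f"r{i}/{j}"] = get(i) / get(j)
    return pd.Series(out, dtype=float)


def _window_areas(profile: ScatteringProfile, centers, half_widths) -> np.ndarray:
    """Background-subtracted integrals over fixed q windows.

    The background under each window is the chord between the window
    edges, so the statistic matches between model and observation even
    when their continuous baselines differ.
    """
    q, I = profile.q, profile.intensity
    areas = np.empty(len(centers))
    for k, (c, hw) in enumerate(zip(centers, half_widths)):
        lo = np.searchsorted(q, c - hw)
        hi = np.searchsorted(q, c + hw)
        lo, hi = max(lo, 1), min(hi, len(q) - 1)
        if hi - lo < 3:
            areas[k] = np.nan
            continue
        qs, Is = q[lo:hi], I[lo:hi]
        chord = Is[0] + (Is[-1] - Is[0]) * (qs - qs[0]) / (qs[-1] - qs[0])
        areas[k] = np.trapezoid(np.maximum(Is - chord, 0.0), qs)
    return areas


def estimate_reduction(
    observed: ScatteringProfile,
    spec: LatticeSpec,
    route: str,
    lineshape: LineShapeParams,
    d_grid=None,
    base: RadialShellModel | None = None,
    n_peaks: int = 4,
    min_prominence: float = 0.05,
) -> ReductionEstimate:
    """Estimate the removed-iron fraction d by peak-ratio matching.

    A grid search over d minimizes the squared discrepancy of the first
    ``n_peaks`` relative integrated intensities (each normalized to the
    1st peak) between the dissolution forward model and the observation,
    followed by local parabolic refinement around the grid minimum.
    """
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}")
    if d_grid is None:
        d_grid = np.arange(0.0, 1.0001, 0.01)
    d_grid = np.asarray(d_grid, dtype=float)
    if base is None:
        guests = [v.guest for v in spec.species.values() if v is not None and v.guest is not None]
        if not guests:
            raise ValueError("spec has no guest-bearing species")
        base = guests[0]

    obs_peaks = find_peaks(observed, min_prominence=min_prominence)
    if len(obs_peaks) < n_peaks:
        raise ValueError(
            f"observation shows {len(obs_peaks)} peaks; need {n_peaks} to index against the lattice"
        )
    obs_peaks = sorted(obs_peaks, key=lambda p: p.center)[:n_peaks]
    grid_step = float(np.median(np.diff(observed.q)))
    centers = [p.center for p in obs_peaks]
    half_widths = []
    for k, p in enumerate(obs_peaks):
        hw = max(3.0 * p.width, 8 * grid_step)
        gaps = []
        if k > 0:
            gaps.append(centers[k] - centers[k - 1])
        if k < len(centers) - 1:
            gaps.append(centers[k + 1] - centers[k])
        if gaps:
            hw = min(hw, 0.45 * min(gaps))
        half_widths.append(hw)

    obs_areas = _window_areas(observed, centers, half_widths)
    if np.any(~np.isfinite(obs_areas)) or obs_areas[0] <= 0:
        raise ValueError("could not integrate all observed peaks")
    obs_ratios = obs_areas[1:] / obs_areas[0]

    engine = PatternEngine(spec, q_max=float(observed.q[-1]) * 1.02)

    def objective(d):
        state = ConversionState(route, float(np.clip(d, 0.0, 1.0)), base)
        model = converted_lattice_profile(spec, state, lineshape, observed.q, engine=engine)
        areas = _window_areas(model, centers, half_widths)
        if areas[0] <= 0 or np.any(~np.isfinite(areas)):
            return np.inf
        ratios = areas[1:] / areas[0]
        return float(np.sum((ratios - obs_ratios) ** 2))

    trace = np.array([objective(d) for d in d_grid])
    i_min = int(np.argmin(trace))
    d_hat, obj = float(d_grid[i_min]), float(trace[i_min])
    # parabolic refinement on the three points around the minimum
    if 0 < i_min < len(d_grid) - 1 and np.all(np.isfinite(trace[i_min - 1 : i_min + 2])):
        y0, y1, y2 = trace[i_min - 1 : i_min + 2]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            shift = 0.5 * (y0 - y2) / denom
            if abs(shift) <= 1.0:
                d_ref = float(d_grid[i_min] + shift * (d_grid[i_min + 1] - d_grid[i_min]))
                obj_ref = objective(d_ref)
                if obj_ref <= obj:
                    d_hat, obj = d_ref, obj_ref
    df = pd.DataFrame({"d": d_grid, "objective": trace})
    return ReductionEstimate(route=route, d_hat=d_hat, objective=obj, trace=df)


# ---------------------------------------------------------------------------
# Form-factor fitting


_FAMILIES = ("core_shell", "frame", "voxel")


def fit_form_factor(
    profile: ScatteringProfile,
    family: str,
    bounds: dict | None = None,
    orientation_nodes: int = 600,
    **fixed,
):
    """Bounded least-squares fit of a form-factor family on log-intensity.

    Families:
      ``core_shell`` -- radii and core contrast of a core-shell sphere;
      ``frame``      -- cylinder (edge) length of the empty octahedron;
      ``voxel``      -- guest offset magnitude of a frame+ferritin voxel.

    Returns an lmfit ``MinimizerResult``-backed mapping of parameter
    values and standard errors; raises :class:`FitError` (carrying the
    best-so-far result) on non-convergence.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    if len(profile) < 20:
        raise ValueError("profile covers too few points to constrain the family")
    q, I = profile.q, profile.intensity
    good = I > 0
    q, I = q[good], I[good]
    # relative residuals (equivalent to log-intensity for small deviations)
    # with a floor that keeps the weight finite through form-factor zeros
    floor = float(np.max(I)) * 1e-4
    bounds = dict(bounds or {})

    params = lmfit.Parameters()

    def add(name, value, lo, hi):
        lo, hi = bounds.get(name, (lo, hi))
        if name in fixed:
            params.add(name, value=float(fixed[name]), vary=False)
        else:
            params.add(name, value=value, min=lo, max=hi)

    if family == "core_shell":
        add("core_radius", 3.5, 1.0, 6.0)
        add("outer_radius", 6.5, 4.0, 10.0)
        add("core_contrast", 8.0, 0.0, 40.0)
        params.add("log_scale", value=0.0, min=-12, max=12)

        def model_lin(p):
            m = RadialShellModel(
                (min(p["core_radius"].value, p["outer_radius"].value - 1e-3), p["outer_radius"].value),
                (p["core_contrast"].value, 1.0),
            )
            return shell_amplitude(m, q) ** 2

    elif family == "frame":
        add("edge", 30.0, 18.0, 45.0)
        add("radius", 3.0, 1.0, 6.0)
        if "radius" not in fixed and "radius" not in bounds:
            params["radius"].vary = False
        params.add("log_scale", value=0.0, min=-12, max=12)
        scheme = OrientationScheme.fibonacci(orientation_nodes)

        def model_lin(p):
            voxel = VoxelModel(octahedron_frame(p["edge"].value, p["radius"].value))
            return powder_intensity(voxel, q, scheme).intensity

    else:  # voxel
        add("offset", 1.0, 0.0, 8.0)
        add("edge", 27.8, 18.0, 45.0)
        if "edge" not in fixed and "edge" not in bounds:
            params["edge"].vary = False
        params.add("log_scale", value=0.0, min=-12, max=12)
        scheme = OrientationScheme.fibonacci(orientation_nodes)
        guest = fixed.pop("guest", ferritin_model())

        def model_lin(p):
            voxel = VoxelModel(
                octahedron_frame(p["edge"].value),
                guest,
                (0.0, 0.0, p["offset"].value),
            )
            return powder_intensity(voxel, q, scheme).intensity

    def residual(p):
        scaled = 10.0 ** p["log_scale"].value * model_lin(p)
        return (scaled - I) / (I + floor)

    def run(start_overrides):
        trial = params.copy()
        for key, value in start_overrides.items():
            if trial[key].vary:
                trial[key].value = value
        trial["log_scale"].value = float(
            np.log10(I[0]) - np.log10(max(model_lin(trial)[0], 1e-300))
        )
        return lmfit.minimize(residual, trial, method="least_squares")

    if family == "core_shell":
        # cheap model: multistart over core size/contrast basins
        starts = [
            {"core_radius": r0, "core_contrast": c0}
            for r0 in (2.5, 4.5)
            for c0 in (5.0, 12.0)
        ]
    else:
        starts = [{}]
    result = None
    for start in starts:
        trial_result = run(start)
        if result is None or trial_result.chisqr < result.chisqr:
            result = trial_result
    if not result.success:
        raise FitError("form-factor fit did not converge", result=result)
    out = {
        name: (result.params[name].value, result.params[name].stderr)
        for name in result.params
    }
    out["_residual"] = float(np.sqrt(np.mean(result.residual**2)))
    out["_result"] = result
    return out


# ---------------------------------------------------------------------------
# Yield arithmetic


def count_yield(counts: CountData) -> float:
    """Encapsulation yield in percent, rounded half-up to one decimal."""
    if counts.total == 0:
        raise ValueError("total count must be positive")
    pct = Decimal(100 * counts.filled) / Decimal(counts.total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
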