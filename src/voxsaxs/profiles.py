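"""1D scattering profiles and their plain-text serialization.

A :class:`ScatteringProfile` is the exchange object between every stage of
the pipeline: forward simulation, noise injection, peak analysis and
fitting.  On disk it is the de-facto standard SAXS ``.dat`` layout --
2 or 3 whitespace- (or comma-) separated columns ``q  I  [sigma]`` with
``#``-prefixed header lines.  The external momentum-transfer unit is
always inverse Angstroms; files declaring ``q_unit: nm^-1`` are converted
on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatteringProfile", "read_profile", "write_profile"]


@dataclass
class ScatteringProfile:
    """A 1D scattering curve I(q).

    Parameters
    ----------
    q : array
        Momentum transfer in inverse Angstroms, strictly increasing.
    intensity : array
        Scattered intensity, arbitrary but consistent units.
    sigma : array, optional
        One-standard-deviation uncertainty per point; ``None`` when the
        curve is a noiseless model.
    metadata : dict
        Free-form key/value annotations (scenario name, ground truth, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a nonempty 1D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity and q must have identical shapes")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("q contains non-finite values")
        dq = np.diff(self.q)
        if np.any(dq <= 0):
            row = int(np.argmax(dq <= 0)) + 1
            raise ValueError(f"q must be strictly increasing (violated at row {row + 1})")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have identical shapes")
            if np.any(self.sigma <= 0):
                raise ValueError("uncertainties must be positive when present")

    def __len__(self) -> int:
        return self.q.size


_UNIT_ALIASES_NM = {"nm^-1", "nm-1", "1/nm", "nm⁻¹"}
_UNIT_ALIASES_ANG = {"a^-1", "a-1", "1/a", "ang^-1", "angstrom^-1", "å⁻¹", "a⁻¹"}


def read_profile(path, q_unit: str = "A^-1") -> ScatteringProfile:
    """Read a 2- or 3-column ASCII profile.

    ``#`` header lines of the form ``key: value`` or ``key = value`` are
    collected into metadata; a ``q_unit`` header (or the ``q_unit``
    argument) of ``nm^-1`` triggers division of q by 10 on load.
    """
    metadata: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([^:=]+?)\s*[:=]\s*(.*)$", line)
                if m:
                    metadata[m.group(1).strip()] = m.group(2).strip()
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                values = [float(p) for p in parts if p]
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable data at line {lineno}") from exc
            if len(values) < 2:
                raise ValueError(f"{path}: expected >= 2 columns, got {len(values)} at line {lineno}")
            rows.append(values[:3])

    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q, intensity = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if ncol >= 3 else None

    unit = str(metadata.get("q_unit", q_unit)).strip().lower()
    if unit in _UNIT_ALIASES_NM:
        q = q / 10.0
    elif unit not in _UNIT_ALIASES_ANG:
        raise ValueError(f"unrecognized q unit declaration: {unit!r}")

    dq = np.diff(q)
    if np.any(dq <= 0):
        row = int(np.argmax(dq <= 0)) + 2  # 1-based, first offending data row
        raise ValueError(f"{path}: q not strictly increasing at data row {row}")
    return ScatteringProfile(q=q, intensity=intensity, sigma=sigma, metadata=metadata)


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column (or 2-column when sigma is absent) text."""
    with open(path, "w") as fh:
        fh.write("# q_unit: A^-1\n")
        cols = "q[A^-1] intensity" + (" sigma" if profile.sigma is not None else "")
        fh.write(f"# columns: {cols}\n")
        for key, value in profile.metadata.items():
            if key in ("q_unit", "columns"):
                continue
            fh.write(f"# {key}: {value}\n")
        if profile.sigma is not None:
            for qi, ii, si in zip(profile.q, profile.intensity, profile.sigma):
                fh.write(f"{qi:.9e} {ii:.9e} {si:.9e}\n")
        else:
            for qi, ii in zip(profile.q, profile.intensity):
                fh.write(f"{qi:.9e} {ii:.9e}\n")
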