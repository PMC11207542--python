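"""Reading and writing 1D reduced SAXS profiles.

Profiles are (q, I, optional sigma) column text files in the de-facto reduced
``.dat`` dialect: whitespace- or comma-delimited, ``#`` comments, 2-3 numeric
columns in the order q, I, sigma.  Internally q is always nm^-1; files in
Angstrom^-1 are converted on read (q x 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["ScatteringProfile", "read_profile", "write_profile", "ProfileError"]

logger = logging.getLogger(__name__)

#: recognized q-unit flags and the factor converting to nm^-1
_Q_UNIT_FACTORS = {
    "nm^-1": 1.0, "1/nm": 1.0, "nm-1": 1.0,
    "A^-1": 10.0, "1/A": 10.0, "angstrom^-1": 10.0, "A-1": 10.0,
}


class ProfileError(ValueError):
    """Malformed or physically invalid profile data."""


@dataclass
class ScatteringProfile:
    """A 1D reduced SAXS profile: momentum transfer, intensity, uncertainty.

    q : strictly increasing, positive, nm^-1.
    intensity : arbitrary units, same length as q.
    sigma : optional 1-sigma uncertainties, all > 0.
    metadata : free-form provenance (sample id, source q units, seed, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ProfileError("q and intensity must be 1D arrays of equal length")
        if self.q.size == 0:
            raise ProfileError("empty profile")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.intensity))):
            raise ProfileError("non-finite values in profile")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ProfileError("q must be positive and strictly increasing")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ProfileError("sigma length does not match q")
            if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
                raise ProfileError("sigma must be finite and > 0")

    def __len__(self) -> int:
        return self.q.size

    def window(self, q_min: float, q_max: float) -> "ScatteringProfile":
        """Restrict to q_min <= q <= q_max."""
        mask = (self.q >= q_min) & (self.q <= q_max)
        if not mask.any():
            raise ProfileError(f"q window [{q_min}, {q_max}] contains no data points")
        return ScatteringProfile(
            self.q[mask], self.intensity[mask],
            None if self.sigma is None else self.sigma[mask],
            dict(self.metadata))


def read_profile(path, q_units: str = "nm^-1",
                 allow_negative: bool = False) -> ScatteringProfile:
    """Read a 2-3 column ASCII profile and convert q to nm^-1.

    Parameters
    ----------
    path : file path.
    q_units : units of the q column in the file ("nm^-1" or "A^-1" aliases);
        Angstrom^-1 data are multiplied by 10.
    allow_negative : keep negative intensities (e.g. oversubtracted buffer)
        instead of rejecting the file.
    """
    if q_units not in _Q_UNIT_FACTORS:
        raise ProfileError(f"unknown q units {q_units!r}; "
                           f"expected one of {sorted(_Q_UNIT_FACTORS)}")
    path = Path(path)
    rows = []
    ncols = None
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise ProfileError(f"non-numeric data line in {path}: {raw!r}") from exc
        if ncols is None:
            ncols = len(vals)
            if ncols < 2:
                raise ProfileError(f"{path}: need at least 2 columns (q, I)")
        rows.append(vals[:3])
    if not rows:
        raise ProfileError(f"{path}: no data rows")
    width = min(len(r) for r in rows)
    if width < 2:
        raise ProfileError(f"{path}: need at least 2 columns (q, I)")
    data = np.array([r[:width] for r in rows], dtype=float)
    finite = np.all(np.isfinite(data), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_profile: dropped %d non-finite rows from %s",
                    n_dropped, path)
    data = data[finite]
    if data.shape[0] == 0:
        raise ProfileError(f"{path}: no finite data rows")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) <= 0):
        raise ProfileError(f"{path}: q not strictly increasing after sort "
                           "(duplicate q values)")
    q = data[:, 0] * _Q_UNIT_FACTORS[q_units]
    intensity = data[:, 1]
    if np.any(intensity < 0) and not allow_negative:
        raise ProfileError(
            f"{path}: negative intensities found; pass allow_negative=True "
            "to keep them")
    sigma = None
    if data.shape[1] >= 3:
        sigma = data[:, 2]
        if np.any(sigma <= 0):
            raise ProfileError(f"{path}: non-positive sigma values")
    meta = {"source": str(path), "source_q_units": q_units,
            "n_dropped_rows": n_dropped}
    return ScatteringProfile(q, intensity, sigma, meta)


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as deterministic full-precision column text."""
    path = Path(path)
    cols = [profile.q, profile.intensity]
    names = "q_nm^-1 intensity_au"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        names += " sigma_au"
    lines = ["# reduced SAXS profile", "# q units: nm^-1"]
    for key, val in sorted(profile.metadata.items()):
        lines.append(f"# {key}: {val}")
    lines.append(f"# columns: {names}")
    np.savetxt(path, np.column_stack(cols), fmt="%.17g",
               header="\n".join(l[2:] for l in lines), comments="# ")
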