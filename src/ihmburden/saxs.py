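"""Chi goodness of fit between model and experimental scattering profiles.

chi = sqrt( (1/M) * sum_i ((Iexp(q_i) - c*I(q_i)) / sigma(q_i))^2 )

where the experimental profile is measured at M points q_i with per-point
errors sigma(q_i).  A model that agrees with the data to within the noise
gives chi close to 1.  The model profile is linearly interpolated onto the
experimental q grid (extrapolation is refused); the multiplicative scale c
can be fitted in closed form, optionally together with an additive offset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ScatteringProfile:
    q: np.ndarray       # momentum transfer, 1/Angstrom, strictly increasing
    I: np.ndarray       # intensity, arbitrary units
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", i)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma length differs from q")
            if np.any(s <= 0):
                raise ValueError("sigma must be positive everywhere")
        if i.shape != q.shape:
            raise ValueError("I length differs from q")
        if q.size == 0:
            raise ValueError("empty profile")
        if np.any(q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")

    @property
    def m(self) -> int:
        return int(self.q.size)


def read_profile(source: str | Path | io.TextIOBase) -> ScatteringProfile:
    """Read a whitespace-delimited .dat profile with 2 or 3 columns."""
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_profile(fh)
    rows = []
    ncol = None
    for lineno, line in enumerate(source, 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if ncol is None:
            ncol = len(parts)
            if ncol not in (2, 3):
                raise ValueError(f"line {lineno}: expected 2 or 3 columns, got {ncol}")
        elif len(parts) != ncol:
            raise ValueError(f"line {lineno}: inconsistent column count")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError("no data rows in profile")
    arr = np.asarray(rows)
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return ScatteringProfile(arr[:, 0], arr[:, 1], sigma)


def write_profile(profile: ScatteringProfile, dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "wt", encoding="utf-8") as fh:
            write_profile(profile, fh)
        return
    cols = [profile.q, profile.I] + ([profile.sigma] if profile.sigma is not None else [])
    for row in zip(*cols):
        dest.write(" ".join(f"{x:.8g}" for x in row) + "\n")


@dataclass(frozen=True)
class ChiResult:
    chi: float
    M: int
    scale: float
    offset: float = 0.0


def chi(model: ScatteringProfile, exp: ScatteringProfile,
        fit_scale: bool = False, fit_offset: bool = False,
        q_max: float | None = None) -> ChiResult:
    """Error-weighted RMS discrepancy between model and experiment.

    The model is interpolated onto the experimental grid; points beyond the
    model's q range are an error (no extrapolation).  With ``fit_scale`` the
    least-squares multiplicative constant is used; ``fit_offset`` fits an
    additive constant jointly with the scale.
    """
    if exp.sigma is None:
        raise ValueError("experimental profile must carry per-point errors")
    mask = np.ones(exp.m, dtype=bool)
    if q_max is not None:
        mask &= exp.q <= q_max
    if not mask.any():
        raise ValueError("no experimental points in the requested q range")
    q = exp.q[mask]
    if q.min() < model.q.min() or q.max() > model.q.max():
        raise ValueError("model profile does not cover the experimental q range")
    i_exp = exp.I[mask]
    sig = exp.sigma[mask]
    i_mod = np.interp(q, model.q, model.I)

    w = 1.0 / sig
    if fit_offset:
        # weighted least squares for Iexp ~ c*Imod + b
        a_mat = np.column_stack([i_mod * w, w])
        coef, *_ = np.linalg.lstsq(a_mat, i_exp * w, rcond=None)
        scale, offset = float(coef[0]), float(coef[1])
    elif fit_scale:
        denom = float(np.sum((i_mod * w) ** 2))
        if denom == 0:
            raise ValueError("model profile is identically zero on the grid")
        scale = float(np.sum(i_exp * i_mod * w * w) / denom)
        offset = 0.0
    else:
        scale, offset = 1.0, 0.0
    resid = (i_exp - scale * i_mod - offset) * w
    m = int(q.size)
    return ChiResult(chi=float(np.sqrt(np.mean(resid ** 2))), M=m,
                     scale=scale, offset=offset)
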