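"""Swaying duty-cycle model linking head orientation to SRX/DRX populations.

In relaxed striated muscle each myosin molecule contributes one blocked head
(docked, parallel to the filament axis) and one free head that sways away
for a fraction D_s of the time (the swaying duty cycle) and is docked for
the remainder.  Fluorescence polarization measures the fractions of heads
parallel (f_par) and perpendicular (f_per) to the filament axis.  With
blocked heads always parallel:

    N_par/2N = (2 - D_s)/2,   N_per/2N = D_s/2,
    R = N_par/N_per = (2 - D_s)/D_s   =>   D_s = 2/(1 + R),
    SRX/DRX = (2 - D_s)/D_s.

The model requires f_par >= 0.5: blocked heads alone account for half of
all heads, so a parallel fraction below one half is inconsistent with the
premise that blocked heads stay docked.
"""

from __future__ import annotations

from dataclasses import dataclass

_TOL = 1e-9


@dataclass(frozen=True)
class OrientationFractions:
    f_par: float
    f_per: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_par <= 1.0 and 0.0 <= self.f_per <= 1.0):
            raise ValueError("orientation fractions must lie in [0, 1]")
        if abs(self.f_par + self.f_per - 1.0) > _TOL:
            raise ValueError("orientation fractions must sum to 1")


@dataclass(frozen=True)
class DutyCycleResult:
    R: float            # parallel / perpendicular head ratio
    D_s: float          # swaying duty cycle
    srx_drx: float      # SRX : DRX head-count ratio
    frac_par: float     # (2 - D_s)/2, fraction of heads parallel
    frac_per: float     # D_s/2, fraction of heads perpendicular

    @property
    def srx_fraction(self) -> float:
        """Fraction of all heads in the SRX state (= frac_par)."""
        return self.frac_par


class ModelViolation(ValueError):
    """The orientation data are inconsistent with the docked-blocked-head model."""


def duty_cycle(of: OrientationFractions) -> DutyCycleResult:
    """Derive D_s and the SRX/DRX ratio from orientation fractions."""
    if of.f_per <= 0:
        raise ModelViolation("perpendicular fraction must be positive")
    if of.f_par < 0.5 - _TOL:
        raise ModelViolation(
            "parallel fraction below 0.5: blocked heads alone exceed the "
            "parallel pool, D_s would exceed 1")
    r = of.f_par / of.f_per
    d_s = 2.0 / (1.0 + r)
    return DutyCycleResult(R=r, D_s=d_s, srx_drx=(2.0 - d_s) / d_s,
                           frac_par=(2.0 - d_s) / 2.0, frac_per=d_s / 2.0)


def srx_drx_from_ds(d_s: float) -> float:
    """SRX/DRX head-count ratio for an assumed swaying duty cycle."""
    if not 0.0 < d_s <= 1.0:
        raise ValueError(f"duty cycle must lie in (0, 1], got {d_s}")
    return (2.0 - d_s) / d_s


def relative_atp_rate(srx_fraction: float, fold_inhibition: float = 5.0) -> float:
    """Relaxed ATP turnover relative to an all-DRX population.

    Heads in SRX hydrolyse ATP at 1/fold_inhibition of the DRX rate, so the
    population-average relative rate is (1 - s) + s/fold.
    """
    if not 0.0 <= srx_fraction <= 1.0:
        raise ValueError("srx_fraction must lie in [0, 1]")
    if fold_inhibition < 1.0:
        raise ValueError("fold_inhibition must be >= 1")
    return (1.0 - srx_fraction) + srx_fraction / fold_inhibition
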