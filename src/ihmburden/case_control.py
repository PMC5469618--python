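"""Rare-variant carrier prevalence: odds ratio, etiologic fraction, test.

Cases and a reference population are compared on the number of individuals
carrying a rare missense variant in a region of interest, assuming each
rare variant occurs in a distinct individual (individual-level genotypes
are unavailable for aggregate reference panels).  The etiologic fraction
EF = (OR - 1)/OR estimates the probability that a rare variant found in a
case is disease-causing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .enrichment import binom_test


@dataclass(frozen=True)
class CohortCounts:
    site_label: str
    carriers_cases: int
    n_cases: int
    carriers_controls: int
    n_controls: int

    def __post_init__(self) -> None:
        for name in ("carriers_cases", "n_cases", "carriers_controls", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.carriers_cases > self.n_cases:
            raise ValueError("more case carriers than cases")
        if self.carriers_controls > self.n_controls:
            raise ValueError("more control carriers than controls")


def odds_ratio(c: CohortCounts, correction: str = "none") -> float:
    """Carrier odds ratio; returns math.inf when controls have no carriers.

    ``correction="haldane"`` adds 0.5 to every cell (classic zero-cell
    continuity correction); the default applies none.
    """
    a, n1 = c.carriers_cases, c.n_cases
    b, n0 = c.carriers_controls, c.n_controls
    if correction == "haldane":
        a2, b2 = a + 0.5, b + 0.5
        d1, d0 = (n1 - a) + 0.5, (n0 - b) + 0.5
        return (a2 / d1) / (b2 / d0)
    if correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    if a == n1:
        raise ValueError("all cases are carriers; enable a continuity correction")
    if b == 0:
        return math.inf if a > 0 else float("nan")
    return (a / (n1 - a)) / (b / (n0 - b))


def etiologic_fraction(or_value: float) -> float:
    """EF = (OR - 1)/OR; 1.0 in the infinite-OR limit.

    OR < 1 yields a negative value (protective direction); the caller can
    detect it by sign.
    """
    if math.isinf(or_value):
        return 1.0
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return (or_value - 1.0) / or_value


def prevalence_test(c: CohortCounts, sided: str = "two") -> float:
    """Binomial test of case carrier prevalence against the control rate."""
    if c.n_controls == 0:
        raise ValueError("control cohort size must be positive")
    p0 = c.carriers_controls / c.n_controls
    return binom_test(c.carriers_cases, c.n_cases, p0, sided=sided)


def woolf_ci(c: CohortCounts, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-OR confidence interval (extension; requires non-zero cells)."""
    from scipy.stats import norm
    a, b = c.carriers_cases, c.carriers_controls
    d1, d0 = c.n_cases - a, c.n_controls - b
    if min(a, b, d1, d0) == 0:
        raise ValueError("Woolf interval undefined with a zero cell")
    se = math.sqrt(1 / a + 1 / b + 1 / d1 + 1 / d0)
    z = norm.ppf(0.5 + level / 2)
    log_or = math.log(odds_ratio(c))
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


@dataclass(frozen=True)
class BurdenResult:
    counts: CohortCounts
    odds_ratio: float
    etiologic_fraction: float
    p_value: float

    @property
    def protective(self) -> bool:
        return self.etiologic_fraction < 0


def burden(c: CohortCounts, correction: str = "none") -> BurdenResult:
    orv = odds_ratio(c, correction=correction)
    return BurdenResult(c, orv, etiologic_fraction(orv), prevalence_test(c))


def load_counts_table(source: str | Path | io.TextIOBase) -> list[CohortCounts]:
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"site_label", "carriers_cases", "n_cases",
                "carriers_controls", "n_controls"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return [
        CohortCounts(str(r.site_label), int(r.carriers_cases), int(r.n_cases),
                     int(r.carriers_controls), int(r.n_controls))
        for r in df.itertuples()
    ]


def burden_table(counts: list[CohortCounts], correction: str = "none") -> str:
    """TSV of OR / EF / p per region row (rows treated independently)."""
    lines = ["site_label\tcarriers_cases\tn_cases\tcarriers_controls\t"
             "n_controls\todds_ratio\tetiologic_fraction\tp_value"]
    for c in counts:
        r = burden(c, correction=correction)
        or_str = "inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.2f}"
        lines.append(f"{c.site_label}\t{c.carriers_cases}\t{c.n_cases}\t"
                     f"{c.carriers_controls}\t{c.n_controls}\t{or_str}\t"
                     f"{r.etiologic_fraction:.3f}\t{r.p_value:.3g}")
    return "\n".join(lines) + "\n"
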