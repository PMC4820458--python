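"""Quantitative arithmetic and statistics for phage-challenge experiments.

Covers the numbers a biocontrol study reports: phage dosing from a
multiplicity of infection (MOI), percent reductions of counts or metabolite
concentrations, tyramine unit conversion (mM to mg/kg of cheese), host-range
tabulation from spot assays, qPCR cell quantification through a standard
curve, and the two-sample Student's t-test used for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TYRAMINE_MOLAR_MASS",
    "HostRangeRecord",
    "HostRangeSummary",
    "StandardCurve",
    "TTestResult",
    "moi_dose",
    "percent_reduction",
    "check_reported_reduction",
    "tyramine_mm_to_mgkg",
    "host_range_summary",
    "load_host_range",
    "qpcr_cells",
    "two_sample_t",
]

#: Molar mass of tyramine (4-hydroxyphenethylamine), g/mol.
TYRAMINE_MOLAR_MASS = 137.179

Origin = Literal["type_strain", "dairy", "meat", "human", "clinical"]


@dataclass(frozen=True)
class HostRangeRecord:
    """One strain of a spot-assay host-range panel."""

    strain: str
    origin: Origin
    susceptible: bool


class HostRangeSummary(NamedTuple):
    n_susceptible: int
    n_total: int
    percent: float
    by_origin: dict[str, tuple[int, int]]  # origin -> (susceptible, total)


@dataclass(frozen=True)
class StandardCurve:
    """qPCR standard curve Ct = intercept + slope·log10(N).

    Coefficients are runtime configuration; the defaults (slope −3.32,
    the theoretical slope of a 100%-efficient reaction, intercept 40)
    are placeholders to be replaced by a laboratory's own calibration.
    """

    slope: float = -3.32
    intercept: float = 40.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard-curve slope must be non-zero")
        if self.slope > 0:
            raise ValueError(
                "standard-curve slope must be negative (Ct decreases with "
                "template amount)"
            )

    def ct(self, cells: float) -> float:
        """Forward map: Ct expected for N cell equivalents."""
        if cells <= 0:
            raise ValueError("cell number must be positive")
        return self.intercept + self.slope * np.log10(cells)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    significant: bool


def moi_dose(moi: float, host_density: float) -> float:
    """Phage inoculum (pfu/ml) delivering ``moi`` against ``host_density``
    (cfu/ml): dose = MOI × host density."""
    if moi <= 0 or host_density <= 0:
        raise ValueError("moi and host_density must be positive")
    return moi * host_density


def percent_reduction(control: float, treated: float) -> float:
    """Percent reduction of the treated value relative to the control:
    100·(1 − treated/control).  100% iff treated is zero; negative when the
    treated value exceeds the control."""
    if control <= 0:
        raise ValueError("control value must be positive")
    if treated < 0:
        raise ValueError("treated value must be non-negative")
    return 100.0 * (1.0 - treated / control)


def check_reported_reduction(
    control: float,
    treated: float,
    reported_percent: float,
    tol_percent: float = 1.0,
) -> tuple[float, bool]:
    """Recompute a percent reduction and compare it with a reported figure.

    Returns (computed percent, consistent?), where consistency means the
    computed value is within ``tol_percent`` percentage points of the
    reported one after rounding to integer precision.  Useful for flagging
    claims that do not follow from the printed raw numbers.
    """
    computed = percent_reduction(control, treated)
    return computed, abs(round(computed) - reported_percent) <= tol_percent


def tyramine_mm_to_mgkg(conc_mm: float) -> float:
    """Convert a tyramine concentration in mM to mg per kg of cheese.

    Assumes 1 kg of cheese ≈ 1 L of aqueous phase (unit density), the
    conversion customary in the food-safety literature, so
    mg/kg = mM × M(tyramine) with M = 137.179 g/mol.
    """
    if conc_mm < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mm * TYRAMINE_MOLAR_MASS


def host_range_summary(records: Sequence[HostRangeRecord]) -> HostRangeSummary:
    """Tabulate a spot-assay panel: susceptible count, total, percent, and a
    per-origin breakdown."""
    if not records:
        raise ValueError("empty host-range table")
    strains = [r.strain for r in records]
    if len(set(strains)) != len(strains):
        dupes = sorted({s for s in strains if strains.count(s) > 1})
        raise ValueError(f"duplicate strains: {dupes}")
    n_total = len(records)
    n_susc = sum(r.susceptible for r in records)
    by_origin: dict[str, tuple[int, int]] = {}
    for r in records:
        s, t = by_origin.get(r.origin, (0, 0))
        by_origin[r.origin] = (s + r.susceptible, t + 1)
    return HostRangeSummary(
        n_susceptible=n_susc,
        n_total=n_total,
        percent=round(100.0 * n_susc / n_total, 1),
        by_origin=by_origin,
    )


def load_host_range(path: str | Path | None = None) -> list[HostRangeRecord]:
    """Read a host-range TSV (strain, origin, susceptible).

    With no path, loads the packaged panel of 27 E. faecalis strains of
    dairy, meat, human, clinical and type-strain origin spot-tested against
    phage Q69.
    """
    if path is None:
        from importlib.resources import files

        path = files("phagerflp").joinpath("data/host_range_q69.tsv")  # type: ignore[assignment]
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain", "origin", "susceptible"}
    if not required.issubset(df.columns):
        raise ValueError(f"host-range table needs columns {sorted(required)}")
    truthy = {"true": True, "1": True, "+": True, "false": False, "0": False, "-": False, "–": False}
    records = []
    for row in df.itertuples(index=False):
        flag = truthy.get(str(row.susceptible).strip().lower())
        if flag is None:
            raise ValueError(
                f"strain {row.strain!r}: unrecognized susceptibility "
                f"{row.susceptible!r}"
            )
        records.append(HostRangeRecord(row.strain, row.origin, flag))
    return records


def qpcr_cells(ct: float, curve: StandardCurve) -> float:
    """Cell number from a qPCR cycle threshold: N = 10^((Ct − intercept)/slope).

    Exact inverse of the standard curve's forward map Ct(N).
    """
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def two_sample_t(
    a: Iterable[float],
    b: Iterable[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    Set ``welch=True`` for the unequal-variance variant.  Degenerate input
    (zero pooled variance, as from identical constant replicates) raises
    rather than returning an infinite statistic.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance: degenerate input")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )
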