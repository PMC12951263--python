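"""Gestational-age dating and gestation-adjusted centile conversion.

Early-pregnancy biometry (gestational sac mean diameter, yolk sac mean
diameter, crown-rump length, embryonic heart rate) is interpreted against
gestation-specific reference distributions.  A :class:`ReferenceCurve`
models a marker's reference distribution at each gestational age as a
Gaussian on either the natural or the log measurement scale, parameterised
by polynomial median and SD functions of gestational age in days.  The
centile of a crude measurement is then ``100 * Phi(z)`` with
``z = (t(value) - median(ga)) / sd(ga)`` and ``t`` the identity or the
natural logarithm.

The published growth charts this package's default curves stand in for do
not print their coefficients; the defaults shipped in
``data/reference_curves.json`` are smooth, monotone, clinically plausible
approximations and are labelled as such in their ``provenance`` field.
Every categorical analysis downstream operates on centiles and is
invariant to the particular curve parameterisation (exact centile
round-trip is part of the test suite).
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Marker",
    "DatingMethod",
    "DatingInfo",
    "DatingError",
    "Measurement",
    "ReferenceCurve",
    "CentileResult",
    "ga_days",
    "to_centile",
    "from_centile",
    "to_centile_array",
    "from_centile_array",
    "load_curves",
    "default_curves",
]

#: days from conception back to the notional last menstrual period
CONCEPTION_OFFSET_DAYS = 14


class Marker(str, enum.Enum):
    """The four sonographic markers measured at the last live scan."""

    GSMD = "GSMD"
    YSMD = "YSMD"
    CRL = "CRL"
    HR = "HR"


class DatingMethod(str, enum.Enum):
    LMP = "lmp"
    CONCEPTION = "conception"
    EMBRYO_TRANSFER = "embryo_transfer"


class DatingError(ValueError):
    """Raised when dating information is inconsistent or incomplete."""


@dataclass(frozen=True)
class DatingInfo:
    """Pregnancy dating anchor plus the scan date to be aged.

    Exactly the fields demanded by ``method`` must be present: an LMP date,
    a conception date, or an embryo-transfer date together with the
    embryo's age in days at transfer (typically 3 or 5).
    """

    method: DatingMethod
    scan_date: _dt.date
    lmp_date: Optional[_dt.date] = None
    conception_date: Optional[_dt.date] = None
    transfer_date: Optional[_dt.date] = None
    transfer_day: Optional[int] = None

    def __post_init__(self) -> None:
        method = DatingMethod(self.method)
        object.__setattr__(self, "method", method)
        required = {
            DatingMethod.LMP: ("lmp_date",),
            DatingMethod.CONCEPTION: ("conception_date",),
            DatingMethod.EMBRYO_TRANSFER: ("transfer_date", "transfer_day"),
        }[method]
        for name in required:
            if getattr(self, name) is None:
                raise DatingError(f"dating method {method.value!r} requires {name}")


def ga_days(dating: DatingInfo) -> int:
    """Gestational age in completed days at ``dating.scan_date``.

    LMP dating counts days from the last menstrual period; conception and
    embryo-transfer dating add the conventional 14-day offset (transfer
    additionally adds the embryo's age at transfer).
    """
    m = dating.method
    if m is DatingMethod.LMP:
        days = (dating.scan_date - dating.lmp_date).days
    elif m is DatingMethod.CONCEPTION:
        days = (dating.scan_date - dating.conception_date).days + CONCEPTION_OFFSET_DAYS
    else:
        days = (
            (dating.scan_date - dating.transfer_date).days
            + CONCEPTION_OFFSET_DAYS
            + int(dating.transfer_day)
        )
    if days < 0:
        raise DatingError(
            f"scan date {dating.scan_date} precedes the dating anchor (ga = {days} days)"
        )
    return days


@dataclass(frozen=True)
class Measurement:
    """One crude measurement: mm for GSMD/YSMD/CRL, bpm for HR."""

    marker: Marker
    value: float
    ga_days: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", Marker(self.marker))
        if not self.value > 0:
            raise ValueError(f"{self.marker.value} measurement must be positive, got {self.value}")


@dataclass(frozen=True)
class CentileResult:
    """Centile in (0, 100) and the standard-normal deviate implying it."""

    centile: float
    z: float


@dataclass(frozen=True)
class ReferenceCurve:
    """Gestation-indexed Gaussian reference model for one marker.

    ``median_coeffs`` and ``sd_coeffs`` are polynomial coefficients in
    ascending order, evaluated at gestational age in days, on the curve's
    measurement scale (natural mm/bpm, or log mm).
    """

    marker: Marker
    scale: str  # "natural" | "log"
    ga_domain_days: tuple[int, int]
    median_coeffs: Sequence[float]
    sd_coeffs: Sequence[float]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", Marker(self.marker))
        if self.scale not in ("natural", "log"):
            raise ValueError(f"scale must be 'natural' or 'log', got {self.scale!r}")
        lo, hi = self.ga_domain_days
        if not lo < hi:
            raise ValueError("ga_domain_days must be an increasing pair")
        ga = np.arange(lo, hi + 1)
        if np.any(self._sd(ga) <= 0):
            raise ValueError(f"{self.marker.value} curve: sd must be positive on the GA domain")
        if np.any(self.median(ga) <= 0):
            raise ValueError(f"{self.marker.value} curve: median must be positive on the GA domain")

    def _check_domain(self, ga: float) -> None:
        lo, hi = self.ga_domain_days
        if not (lo <= ga <= hi):
            raise ValueError(
                f"gestational age {ga} d outside {self.marker.value} curve domain [{lo}, {hi}]"
            )

    def _median_scaled(self, ga):
        return np.polynomial.polynomial.polyval(ga, np.asarray(self.median_coeffs, float))

    def _sd(self, ga):
        return np.polynomial.polynomial.polyval(ga, np.asarray(self.sd_coeffs, float))

    def median(self, ga):
        """Median measurement on natural units at gestational age ``ga``."""
        m = self._median_scaled(ga)
        return np.exp(m) if self.scale == "log" else m


def to_centile(m: Measurement, curve: ReferenceCurve) -> CentileResult:
    """Convert a crude measurement to its gestation-adjusted centile."""
    if m.marker is not curve.marker:
        raise ValueError(f"measurement marker {m.marker.value} != curve marker {curve.marker.value}")
    curve._check_domain(m.ga_days)
    t = np.log(m.value) if curve.scale == "log" else m.value
    z = float((t - curve._median_scaled(m.ga_days)) / curve._sd(m.ga_days))
    return CentileResult(centile=100.0 * float(stats.norm.cdf(z)), z=z)


def from_centile(marker: Marker, centile: float, ga_days: int, curve: ReferenceCurve) -> float:
    """Inverse centile mapping: the measurement sitting at ``centile``.

    Exact inverse of :func:`to_centile` (round-trip within 1e-9), used by
    the synthetic-cohort generator to synthesise crude measurements from
    drawn centiles.
    """
    if Marker(marker) is not curve.marker:
        raise ValueError(f"marker {marker} != curve marker {curve.marker.value}")
    if not 0.0 < centile < 100.0:
        raise ValueError(f"centile must lie strictly inside (0, 100), got {centile}")
    curve._check_domain(ga_days)
    z = float(stats.norm.ppf(centile / 100.0))
    t = float(curve._median_scaled(ga_days)) + z * float(curve._sd(ga_days))
    return float(np.exp(t)) if curve.scale == "log" else t


def to_centile_array(values, ga, curve: ReferenceCurve) -> np.ndarray:
    """Vectorised :func:`to_centile` over parallel value/GA arrays."""
    values = np.asarray(values, dtype=float)
    ga = np.asarray(ga, dtype=float)
    lo, hi = curve.ga_domain_days
    if np.any((ga < lo) | (ga > hi)):
        raise ValueError(f"gestational ages outside {curve.marker.value} domain [{lo}, {hi}]")
    t = np.log(values) if curve.scale == "log" else values
    z = (t - curve._median_scaled(ga)) / curve._sd(ga)
    return 100.0 * stats.norm.cdf(z)


def from_centile_array(centiles, ga, curve: ReferenceCurve) -> np.ndarray:
    """Vectorised :func:`from_centile` over parallel centile/GA arrays."""
    centiles = np.asarray(centiles, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if np.any((centiles <= 0) | (centiles >= 100)):
        raise ValueError("centiles must lie strictly inside (0, 100)")
    lo, hi = curve.ga_domain_days
    if np.any((ga < lo) | (ga > hi)):
        raise ValueError(f"gestational ages outside {curve.marker.value} domain [{lo}, {hi}]")
    z = stats.norm.ppf(centiles / 100.0)
    t = curve._median_scaled(ga) + z * curve._sd(ga)
    return np.exp(t) if curve.scale == "log" else t


def load_curves(path) -> dict[Marker, ReferenceCurve]:
    """Load a per-marker curve config (JSON list of curve objects)."""
    with open(path) as fh:
        entries = json.load(fh)
    return _curves_from_entries(entries)


def _curves_from_entries(entries) -> dict[Marker, ReferenceCurve]:
    curves: dict[Marker, ReferenceCurve] = {}
    for e in entries:
        c = ReferenceCurve(
            marker=Marker(e["marker"]),
            scale=e["scale"],
            ga_domain_days=tuple(e["ga_domain_days"]),
            median_coeffs=e["median_coeffs"],
            sd_coeffs=e["sd_coeffs"],
            provenance=e.get("provenance", ""),
        )
        curves[c.marker] = c
    return curves


def default_curves() -> dict[Marker, ReferenceCurve]:
    """The packaged default reference curves (plausible approximations)."""
    text = resources.files("tetradscreen.data").joinpath("reference_curves.json").read_text()
    return _curves_from_entries(json.loads(text))
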