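"""Per-pregnancy extreme-marker flags and the tetrad-of-aneuploidy composite.

The tetrad of aneuploidy is the simultaneous presence, on the last live
scan, of a small gestational sac (GSMD < 5th centile), an enlarged yolk
sac (YSMD >= 95th centile), a short embryo (CRL < 5th centile) and
bradycardia (HR < 5th centile).  This module codes each marker 0/1
against its cut-off and combines the four into the composite, and filters
the cohort to the <= 10 weeks' gestation stratum.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .biometry import DatingInfo, Marker
from .cutoffs import CutoffSpec

__all__ = [
    "Karyotype",
    "Amnion",
    "PregnancyRecord",
    "MarkerFlags",
    "preselected_cutoffs",
    "compute_flags",
    "subgroup",
    "TEN_WEEKS_DAYS",
]

logger = logging.getLogger(__name__)

#: "<= 10 weeks' gestation" as completed days, inclusive
TEN_WEEKS_DAYS = 70

#: GA beyond which the amniotic sac is assessable (7 + 0 weeks)
AMNION_MIN_GA_DAYS = 49


class Karyotype(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"


class Amnion(str, enum.Enum):
    YES = "yes"
    NO = "no"
    NOT_ASSESSED = "not_assessed"


@dataclass
class PregnancyRecord:
    """One miscarried pregnancy: last-live-scan biometry, maternal
    covariates and the cytogenetic outcome."""

    id: str
    ga_last_live_days: int
    karyotype: Optional[Karyotype]
    dating: Optional[DatingInfo] = None
    gsmd_mm: Optional[float] = None
    ysmd_mm: Optional[float] = None
    crl_mm: Optional[float] = None
    hr_bpm: Optional[float] = None
    amnion_present: Amnion = Amnion.NOT_ASSESSED
    maternal_age_years: Optional[float] = None
    bmi: Optional[float] = None
    ethnicity: Optional[str] = None
    gravidity: Optional[int] = None
    parity: Optional[int] = None
    prior_miscarriages: Optional[int] = None
    conception_mode: Optional[str] = None  # "spontaneous" | "art"
    abnormality_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.karyotype is not None:
            self.karyotype = Karyotype(self.karyotype)
        self.amnion_present = Amnion(self.amnion_present)
        if not self.ga_last_live_days > 0:
            raise ValueError(f"record {self.id}: ga_last_live_days must be positive")
        if (
            self.ga_last_live_days <= AMNION_MIN_GA_DAYS
            and self.amnion_present is not Amnion.NOT_ASSESSED
        ):
            raise ValueError(
                f"record {self.id}: amniotic sac recorded at GA <= {AMNION_MIN_GA_DAYS} days"
            )


@dataclass(frozen=True)
class MarkerFlags:
    """Binary extreme-centile indicators plus the composite."""

    gsmd_small: bool
    ysmd_large: bool
    crl_short: bool
    bradycardia: bool
    tetrad: bool
    missing: tuple[Marker, ...] = ()


def preselected_cutoffs() -> dict[Marker, CutoffSpec]:
    """The preselected cut-offs: < 5th centile for GSMD, CRL and HR
    (bradycardia), >= 95th centile for YSMD."""
    return {
        Marker.GSMD: CutoffSpec(Marker.GSMD, 5.0, "below"),
        Marker.YSMD: CutoffSpec(Marker.YSMD, 95.0, "at_or_above"),
        Marker.CRL: CutoffSpec(Marker.CRL, 5.0, "below"),
        Marker.HR: CutoffSpec(Marker.HR, 5.0, "below"),
    }


def compute_flags(
    record_id: str,
    centiles: Mapping[Marker, Optional[float]],
    cutoffs: Mapping[Marker, CutoffSpec],
    strict_missing: bool = False,
) -> MarkerFlags:
    """Code each marker against its cut-off and form the tetrad.

    A missing centile codes its flag (and hence the tetrad) false, with a
    logged warning, matching binary 0/1 coding of the extremes.  With
    ``strict_missing`` a record missing any of the four measurements
    raises instead of silently coding 0.
    """
    for mk in Marker:
        if mk not in cutoffs:
            raise ValueError(f"cut-off missing for marker {mk.value}")
    flags: dict[Marker, bool] = {}
    missing: list[Marker] = []
    for mk in Marker:
        c = centiles.get(mk)
        if c is None:
            if strict_missing:
                raise ValueError(f"record {record_id}: missing {mk.value} measurement")
            logger.warning("record %s: missing %s centile coded as non-extreme", record_id, mk.value)
            missing.append(mk)
            flags[mk] = False
        else:
            flags[mk] = cutoffs[mk].is_extreme(float(c))
    tetrad = all(flags.values())
    return MarkerFlags(
        gsmd_small=flags[Marker.GSMD],
        ysmd_large=flags[Marker.YSMD],
        crl_short=flags[Marker.CRL],
        bradycardia=flags[Marker.HR],
        tetrad=tetrad,
        missing=tuple(missing),
    )


def subgroup(
    records: Sequence[PregnancyRecord], max_ga_days: int = TEN_WEEKS_DAYS
) -> list[PregnancyRecord]:
    """Records whose last live scan fell at or before ``max_ga_days``
    (default 70 days = 10 completed weeks, inclusive); order preserved."""
    return [r for r in records if r.ga_last_live_days <= max_ga_days]
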