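"""Cohort CSV reading and writing.

One row per pregnancy.  Dating columns (ISO 8601 dates) describe how
gestational age is anchored; crude measurements are in mm (GSMD, YSMD,
CRL) and bpm (HR); the karyotype outcome is ``normal``/``abnormal`` with
an optional free-text abnormality label.
"""

from __future__ import annotations

import datetime as _dt
import math
from typing import Optional, Sequence

import pandas as pd

from .biometry import DatingInfo, DatingMethod, ga_days
from .tetrad import Amnion, Karyotype, PregnancyRecord

__all__ = ["COHORT_COLUMNS", "read_cohort", "write_cohort", "records_to_frame"]

COHORT_COLUMNS = [
    "id", "dating_method", "lmp_date", "conception_date", "transfer_date",
    "transfer_day", "scan_date", "ga_last_live_days", "gsmd_mm", "ysmd_mm",
    "crl_mm", "hr_bpm", "amnion_present", "maternal_age_years", "bmi",
    "ethnicity", "gravidity", "parity", "prior_miscarriages",
    "conception_mode", "karyotype", "abnormality_label",
]


def _opt(v):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and v == "":
        return None
    return v


def _date(v) -> Optional[_dt.date]:
    v = _opt(v)
    return None if v is None else _dt.date.fromisoformat(str(v))


def read_cohort(path) -> list[PregnancyRecord]:
    """Read a cohort CSV into validated :class:`PregnancyRecord` objects."""
    df = pd.read_csv(path, dtype={"id": str})
    records = []
    for _, row in df.iterrows():
        method = _opt(row.get("dating_method"))
        dating = None
        if method is not None:
            dating = DatingInfo(
                method=DatingMethod(method),
                scan_date=_date(row.get("scan_date")),
                lmp_date=_date(row.get("lmp_date")),
                conception_date=_date(row.get("conception_date")),
                transfer_date=_date(row.get("transfer_date")),
                transfer_day=(
                    int(row["transfer_day"]) if _opt(row.get("transfer_day")) is not None else None
                ),
            )
        ga = _opt(row.get("ga_last_live_days"))
        ga = int(ga) if ga is not None else (ga_days(dating) if dating else None)
        records.append(
            PregnancyRecord(
                id=str(row["id"]),
                ga_last_live_days=ga,
                karyotype=_opt(row.get("karyotype")),
                dating=dating,
                gsmd_mm=_opt(row.get("gsmd_mm")),
                ysmd_mm=_opt(row.get("ysmd_mm")),
                crl_mm=_opt(row.get("crl_mm")),
                hr_bpm=_opt(row.get("hr_bpm")),
                amnion_present=_opt(row.get("amnion_present")) or Amnion.NOT_ASSESSED,
                maternal_age_years=_opt(row.get("maternal_age_years")),
                bmi=_opt(row.get("bmi")),
                ethnicity=_opt(row.get("ethnicity")),
                gravidity=_opt(row.get("gravidity")),
                parity=_opt(row.get("parity")),
                prior_miscarriages=_opt(row.get("prior_miscarriages")),
                conception_mode=_opt(row.get("conception_mode")),
                abnormality_label=_opt(row.get("abnormality_label")),
            )
        )
    return records


def records_to_frame(records: Sequence[PregnancyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.dating
        rows.append({
            "id": r.id,
            "dating_method": d.method.value if d else None,
            "lmp_date": d.lmp_date.isoformat() if d and d.lmp_date else None,
            "conception_date": d.conception_date.isoformat() if d and d.conception_date else None,
            "transfer_date": d.transfer_date.isoformat() if d and d.transfer_date else None,
            "transfer_day": d.transfer_day if d else None,
            "scan_date": d.scan_date.isoformat() if d else None,
            "ga_last_live_days": r.ga_last_live_days,
            "gsmd_mm": r.gsmd_mm,
            "ysmd_mm": r.ysmd_mm,
            "crl_mm": r.crl_mm,
            "hr_bpm": r.hr_bpm,
            "amnion_present": r.amnion_present.value,
            "maternal_age_years": r.maternal_age_years,
            "bmi": r.bmi,
            "ethnicity": r.ethnicity,
            "gravidity": r.gravidity,
            "parity": r.parity,
            "prior_miscarriages": r.prior_miscarriages,
            "conception_mode": r.conception_mode,
            "karyotype": r.karyotype.value if r.karyotype else None,
            "abnormality_label": r.abnormality_label,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[PregnancyRecord], path) -> None:
    """Write records to the cohort CSV schema."""
    records_to_frame(records).to_csv(path, index=False)
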