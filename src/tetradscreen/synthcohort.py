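"""Synthetic miscarriage cohorts with the study's statistical structure.

Two flavours:

``generate_cohort``
    Samples cohorts from a parameterised model.  Per karyotype group,
    each marker's centile follows a two-component mixture: with
    probability ``extreme_prob`` it falls in the extreme region beyond
    the marker's cut-off (uniform there), otherwise in the remaining
    centile range following a rescaled Beta body.  Co-occurrence of
    extremes within a record is induced by a Gaussian copula driven by a
    shared latent "severity" variable (equicorrelation ``rho``), since
    the study reports no joint marker distribution.  Crude measurements
    are synthesised from the drawn centiles through the reference-curve
    inverse, so the analysis pipeline's centile conversion recovers them
    exactly.

``fixture_cohort``
    A deterministic 158-record cohort whose flag-by-karyotype
    cross-tabulations equal the published categorical counts exactly
    (112/46 abnormal/normal split, 42/5 small sacs, 19/2 enlarged yolk
    sacs, 71/11 short embryos, 61/16 bradycardias, nine nested
    tetrad-positive cases - all chromosomally abnormal), along with the
    published amniotic-sac denominators, missing-BMI count, ethnicity,
    conception-mode and abnormality-label composition.  The joint cell
    assignment beyond the published margins is a documented block
    allocation (no normal-karyotype record carries all four flags; the
    tetrad cases sit in the <= 70-day stratum).  The same construction is
    frozen in the packaged CSV ``data/fixture_cohort.csv``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .biometry import Marker, DatingInfo, DatingMethod, ReferenceCurve, default_curves, from_centile_array
from .cutoffs import CutoffSpec
from .io import read_cohort
from .tetrad import Amnion, Karyotype, PregnancyRecord, preselected_cutoffs

__all__ = [
    "MarkerMixture",
    "CohortConfig",
    "reference_cohort_config",
    "generate_cohort",
    "build_fixture_cohort",
    "fixture_cohort",
]

_SCAN_BASE_DATE = _dt.date(2023, 1, 2)


@dataclass(frozen=True)
class MarkerMixture:
    """Group-conditional centile law for one marker: ``extreme_prob``
    mass beyond the cut-off (uniform), a Beta(a, b) body elsewhere."""

    extreme_prob: float
    beta_a: float = 1.0
    beta_b: float = 1.0

    def validate(self, label: str, errors: list[str]) -> None:
        if not 0.0 <= self.extreme_prob <= 1.0:
            errors.append(f"{label}.extreme_prob not in [0, 1]: {self.extreme_prob}")
        if self.beta_a <= 0 or self.beta_b <= 0:
            errors.append(f"{label}: Beta shape parameters must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the sampled synthetic cohort."""

    n: int = 158
    p_abnormal: float = 112 / 158
    # marker -> (normal-group mixture, abnormal-group mixture)
    markers: Mapping[Marker, tuple[MarkerMixture, MarkerMixture]] = None
    rho: float = 0.5
    maternal_age: Mapping[Karyotype, tuple[float, float, float]] = None  # (median, q1, q3) years
    bmi: Mapping[Karyotype, tuple[float, float, float]] = None  # (median, q1, q3) kg/m2
    missing_bmi_prob: float = 40 / 158
    ga_days_range: tuple[int, int] = (42, 97)
    p_ga_beyond_49: float = 78 / 158
    amnion_prob: Mapping[Karyotype, float] = None  # P(present | GA > 49 d)
    p_art: float = 27 / 158
    abnormality_mix: Mapping[str, float] = None

    def validate(self) -> None:
        errors: list[str] = []
        if self.n <= 0:
            errors.append(f"n must be positive: {self.n}")
        for name in ("p_abnormal", "missing_bmi_prob", "p_ga_beyond_49", "p_art"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} not in [0, 1]: {v}")
        if not -1 / 3 < self.rho < 1.0:
            errors.append(f"rho must be in (-1/3, 1) for a valid 4-marker equicorrelation: {self.rho}")
        for mk in Marker:
            if mk not in self.markers:
                errors.append(f"markers missing {mk.value}")
                continue
            self.markers[mk][0].validate(f"markers[{mk.value}][normal]", errors)
            self.markers[mk][1].validate(f"markers[{mk.value}][abnormal]", errors)
        for grp in Karyotype:
            if not 0.0 <= self.amnion_prob[grp] <= 1.0:
                errors.append(f"amnion_prob[{grp.value}] not in [0, 1]")
        total = sum(self.abnormality_mix.values())
        if abs(total - 1.0) > 1e-9:
            errors.append(f"abnormality_mix weights sum to {total}, expected 1")
        if errors:
            raise ValueError("invalid cohort config: " + "; ".join(errors))


def reference_cohort_config() -> CohortConfig:
    """Config pre-filled to the published cohort's marginal frequencies:
    n = 158 with 112/158 abnormal; extreme-centile probabilities 5/46 vs
    42/112 (GSMD), 2/46 vs 19/112 (YSMD), 11/46 vs 71/112 (CRL) and
    16/46 vs 61/112 (bradycardia); maternal age 35 (33-38) vs 38 (34-41)
    years; 78/158 scanned beyond 49 days; 40/158 missing BMI."""
    return CohortConfig(
        n=158,
        p_abnormal=112 / 158,
        markers={
            Marker.GSMD: (
                MarkerMixture(5 / 46, beta_a=1.2, beta_b=1.8),
                MarkerMixture(42 / 112, beta_a=1.0, beta_b=2.5),
            ),
            Marker.YSMD: (
                MarkerMixture(2 / 46, beta_a=1.0, beta_b=2.0),
                MarkerMixture(19 / 112, beta_a=1.2, beta_b=1.6),
            ),
            Marker.CRL: (
                MarkerMixture(11 / 46, beta_a=1.0, beta_b=2.2),
                MarkerMixture(71 / 112, beta_a=0.9, beta_b=2.8),
            ),
            Marker.HR: (
                MarkerMixture(16 / 46, beta_a=1.5, beta_b=1.5),
                MarkerMixture(61 / 112, beta_a=1.5, beta_b=1.8),
            ),
        },
        rho=0.5,
        maternal_age={
            Karyotype.NORMAL: (35.0, 33.0, 38.0),
            Karyotype.ABNORMAL: (38.0, 34.0, 41.0),
        },
        bmi={
            Karyotype.NORMAL: (23.4, 20.9, 26.2),
            Karyotype.ABNORMAL: (24.5, 22.0, 29.0),
        },
        missing_bmi_prob=40 / 158,
        ga_days_range=(42, 97),
        p_ga_beyond_49=78 / 158,
        amnion_prob={Karyotype.NORMAL: 13 / 19, Karyotype.ABNORMAL: 26 / 59},
        p_art=27 / 158,
        abnormality_mix={
            "trisomy 16": 19 / 112,
            "trisomy 15": 10 / 112,
            "trisomy 22": 9 / 112,
            "other trisomy": 39 / 112,
            "triploidy": 20 / 112,
            "monosomy X": 9 / 112,
            "other": 6 / 112,
        },
    )


def _mixture_centile(u: np.ndarray, mix: MarkerMixture, spec: CutoffSpec) -> np.ndarray:
    """Inverse-CDF map of uniforms to the two-component centile mixture.

    The extreme region sits at the low tail of ``u`` for "below" cut-offs
    and at the high tail for "at-or-above" ones, so a copula latent
    driving ``u`` toward the oriented tail produces co-extreme records.
    """
    ep = mix.extreme_prob
    body = stats.beta(mix.beta_a, mix.beta_b)
    out = np.empty_like(u)
    if spec.direction == "below":
        lo_region = u < ep
        out[lo_region] = spec.threshold * (u[lo_region] / ep) if ep > 0 else 0.0
        v = (u[~lo_region] - ep) / (1 - ep) if ep < 1 else np.array([])
        out[~lo_region] = spec.threshold + (100 - spec.threshold) * body.ppf(v)
    else:
        hi_region = u > 1 - ep
        if ep > 0:
            out[hi_region] = spec.threshold + (100 - spec.threshold) * ((u[hi_region] - (1 - ep)) / ep)
        v = u[~hi_region] / (1 - ep) if ep < 1 else np.array([])
        out[~hi_region] = spec.threshold * body.ppf(v)
    return np.clip(out, 0.01, 99.99)


def _lognormal_from_quartiles(rng, median: float, q1: float, q3: float, size: int) -> np.ndarray:
    sigma = (np.log(q3) - np.log(q1)) / (2 * stats.norm.ppf(0.75))
    return np.exp(rng.normal(np.log(median), sigma, size))


def generate_cohort(
    config: CohortConfig,
    seed: int,
    curves: Optional[Mapping[Marker, ReferenceCurve]] = None,
    cutoffs: Optional[Mapping[Marker, CutoffSpec]] = None,
) -> list[PregnancyRecord]:
    """Sample a reproducible synthetic cohort from ``config``."""
    config.validate()
    curves = curves or default_curves()
    cutoffs = cutoffs or preselected_cutoffs()
    rng = np.random.default_rng(seed)
    n = config.n

    abnormal = rng.random(n) < config.p_abnormal
    # gestational age of the last live scan
    lo, hi = config.ga_days_range
    beyond = rng.random(n) < config.p_ga_beyond_49
    ga = np.where(
        beyond,
        rng.integers(50, hi + 1, n),
        rng.integers(lo, min(49, hi) + 1, n),
    ).astype(int)

    # Gaussian copula: shared severity + marker-specific noise
    severity = rng.normal(size=n)
    centiles: dict[Marker, np.ndarray] = {}
    for mk in Marker:
        eps = rng.normal(size=n)
        z = np.sqrt(config.rho) * severity + np.sqrt(1 - config.rho) * eps
        u = stats.norm.cdf(z if cutoffs[mk].direction == "below" else -z)
        c = np.empty(n)
        for is_abn, grp_idx in ((False, 0), (True, 1)):
            sel = abnormal == is_abn
            c[sel] = _mixture_centile(u[sel], config.markers[mk][grp_idx], cutoffs[mk])
        centiles[mk] = c

    values = {mk: from_centile_array(centiles[mk], ga, curves[mk]) for mk in Marker}

    age = np.empty(n)
    bmi = np.empty(n)
    for grp, sel in ((Karyotype.NORMAL, ~abnormal), (Karyotype.ABNORMAL, abnormal)):
        m, q1, q3 = config.maternal_age[grp]
        age[sel] = _lognormal_from_quartiles(rng, m, q1, q3, int(sel.sum()))
        m, q1, q3 = config.bmi[grp]
        bmi[sel] = _lognormal_from_quartiles(rng, m, q1, q3, int(sel.sum()))
    bmi_missing = rng.random(n) < config.missing_bmi_prob
    art = rng.random(n) < config.p_art
    amnion_u = rng.random(n)

    labels = list(config.abnormality_mix)
    weights = np.array([config.abnormality_mix[k] for k in labels])
    label_draw = rng.choice(len(labels), size=n, p=weights / weights.sum())

    prior = rng.integers(2, 5, n)
    parity = rng.integers(0, 2, n)

    records = []
    for i in range(n):
        grp = Karyotype.ABNORMAL if abnormal[i] else Karyotype.NORMAL
        scan = _SCAN_BASE_DATE + _dt.timedelta(days=int(i))
        if ga[i] > 49:
            amnion = Amnion.YES if amnion_u[i] < config.amnion_prob[grp] else Amnion.NO
        else:
            amnion = Amnion.NOT_ASSESSED
        records.append(
            PregnancyRecord(
                id=f"S{i:05d}",
                ga_last_live_days=int(ga[i]),
                karyotype=grp,
                dating=DatingInfo(
                    method=DatingMethod.LMP,
                    scan_date=scan,
                    lmp_date=scan - _dt.timedelta(days=int(ga[i])),
                ),
                gsmd_mm=round(float(values[Marker.GSMD][i]), 6),
                ysmd_mm=round(float(values[Marker.YSMD][i]), 6),
                crl_mm=round(float(values[Marker.CRL][i]), 6),
                hr_bpm=round(float(values[Marker.HR][i]), 6),
                amnion_present=amnion,
                maternal_age_years=round(float(age[i]), 1),
                bmi=None if bmi_missing[i] else round(float(bmi[i]), 1),
                ethnicity=None,
                gravidity=int(prior[i] + parity[i] + 1),
                parity=int(parity[i]),
                prior_miscarriages=int(prior[i]),
                conception_mode="art" if art[i] else "spontaneous",
                abnormality_label=labels[label_draw[i]] if abnormal[i] else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# deterministic fixture reproducing the published categorical counts
# ---------------------------------------------------------------------------

def _block(indices: range) -> set[int]:
    return set(indices)


def _spread(kind: str, idx_in_cat: int, n_cat: int) -> float:
    """Deterministic centile placement within a flag category."""
    frac = idx_in_cat / max(n_cat - 1, 1)
    if kind == "low":            # < 5th centile
        return 1.0 + 3.6 * frac
    if kind == "high_incl":      # >= 95th centile (yolk sac rule)
        # kept clear of the 95.0 boundary so the centile survives the
        # measurement round-trip through the reference curves
        return 95.2 + 3.8 * frac
    if kind == "high_excl":      # > 95th centile (descriptive extremes)
        return 95.5 + 3.5 * frac
    return 6.0 + 88.0 * frac     # body, well inside (5, 95)


def _assign_centiles(n: int, cats: dict[str, set[int]], kind_of_cat: dict[str, str]) -> list[float]:
    out = [None] * n
    for cat, members in cats.items():
        for j, idx in enumerate(sorted(members)):
            out[idx] = _spread(kind_of_cat[cat], j, len(members))
    body = [i for i in range(n) if out[i] is None]
    for j, idx in enumerate(body):
        out[idx] = _spread("body", j, len(body))
    return out


_ABN_TRISOMY_CYCLE = ["trisomy 21", "trisomy 13", "trisomy 18", "trisomy 7", "trisomy 14", "trisomy 2"]
_ABN_OTHER = ["unbalanced translocation", "tetraploidy", "complex rearrangement",
              "partial monosomy", "marker chromosome", "unbalanced translocation"]


def _abnormality_label(i: int) -> str:
    if i in (0, 1, 2, 3, 4, 5):
        return "trisomy 16"
    if i == 6:
        return "trisomy 10"
    if i == 7:
        return "trisomy 10 with multiple deletions"
    if i == 8:
        return "triploidy"
    if 9 <= i <= 21:
        return "trisomy 16"
    if 22 <= i <= 31:
        return "trisomy 15"
    if 32 <= i <= 40:
        return "trisomy 22"
    if 41 <= i <= 77:
        return _ABN_TRISOMY_CYCLE[(i - 41) % len(_ABN_TRISOMY_CYCLE)]
    if 78 <= i <= 96:
        return "triploidy"
    if 97 <= i <= 105:
        return "monosomy X"
    return _ABN_OTHER[(i - 106) % len(_ABN_OTHER)]


def _ethnicity(i: int, blocks: Sequence[tuple[int, str]]) -> Optional[str]:
    for upto, label in blocks:
        if i < upto:
            return label
    return None


def build_fixture_cohort(curves: Optional[Mapping[Marker, ReferenceCurve]] = None) -> list[PregnancyRecord]:
    """Construct the deterministic 158-record fixture cohort in code.

    Block allocation of flags (record indices within each karyotype
    group; all blocks chosen so every published margin is hit exactly and
    the nine tetrad cases are nested and abnormal):

    abnormal (n = 112): small sac 0-41; sac > 95th 75-76; enlarged yolk
    sac 0-8 and 65-74; yolk sac < 5th 42-64; short embryo 0-70;
    bradycardia 0-60; tachycardia 61-66; GA > 49 d for 53-111 (amnion
    present 53-78).  Tetrad = 0-8 exactly.

    normal (n = 46): small sac 0-4; sac > 95th 32-33; enlarged yolk sac
    0-1; yolk sac < 5th 18-31; short embryo 0-10; embryo > 95th 34;
    bradycardia 2-17; tachycardia 18-21; GA > 49 d for 27-45 (amnion
    present 27-39).  No record carries all four flags.
    """
    curves = curves or default_curves()

    groups = {
        Karyotype.ABNORMAL: {
            "n": 112,
            "gsmd": {"low": _block(range(0, 42)), "high_excl": _block(range(75, 77))},
            "ysmd": {"high_incl": _block(range(0, 9)) | _block(range(65, 75)),
                     "low": _block(range(42, 65))},
            "crl": {"low": _block(range(0, 71))},
            "hr": {"low": _block(range(0, 61)), "high_excl": _block(range(61, 67))},
            "ga_beyond": _block(range(53, 112)),
            "amnion_yes": _block(range(53, 79)),
            "bmi_missing": _block(range(0, 28)),
            "art": _block(range(93, 112)),
            "prior3": _block(range(0, 67)),
            "ethnicity_blocks": [(65, "Caucasian"), (90, "Mixed/Other"), (98, "Afro-Caribbean"),
                                 (106, "East Asian"), (111, "South Asian")],
            "age_base": 34.0,
        },
        Karyotype.NORMAL: {
            "n": 46,
            "gsmd": {"low": _block(range(0, 5)), "high_excl": _block(range(32, 34))},
            "ysmd": {"high_incl": _block(range(0, 2)), "low": _block(range(18, 32))},
            "crl": {"low": _block(range(0, 11)), "high_excl": _block(range(34, 35))},
            "hr": {"low": _block(range(2, 18)), "high_excl": _block(range(18, 22))},
            "ga_beyond": _block(range(27, 46)),
            "amnion_yes": _block(range(27, 40)),
            "bmi_missing": _block(range(0, 12)),
            "art": _block(range(38, 46)),
            "prior3": _block(range(0, 28)),
            "ethnicity_blocks": [(23, "Caucasian"), (38, "Mixed/Other"), (41, "Afro-Caribbean"),
                                 (44, "East Asian"), (46, "South Asian")],
            "age_base": 31.0,
        },
    }

    kind_maps = {
        "gsmd": {"low": "low", "high_excl": "high_excl"},
        "ysmd": {"high_incl": "high_incl", "low": "low"},
        "crl": {"low": "low", "high_excl": "high_excl"},
        "hr": {"low": "low", "high_excl": "high_excl"},
    }
    marker_of = {"gsmd": Marker.GSMD, "ysmd": Marker.YSMD, "crl": Marker.CRL, "hr": Marker.HR}

    records: list[PregnancyRecord] = []
    counter = 0
    for grp in (Karyotype.ABNORMAL, Karyotype.NORMAL):
        g = groups[grp]
        n = g["n"]
        cents = {
            key: _assign_centiles(n, g[key], kind_maps[key]) for key in ("gsmd", "ysmd", "crl", "hr")
        }
        for i in range(n):
            beyond = i in g["ga_beyond"]
            ga = (52 + (i * 7) % 25) if beyond else (42 + i % 8)
            scan = _SCAN_BASE_DATE + _dt.timedelta(days=counter)
            if i in g["art"]:
                dating = DatingInfo(
                    method=DatingMethod.EMBRYO_TRANSFER,
                    scan_date=scan,
                    transfer_date=scan - _dt.timedelta(days=ga - 19),
                    transfer_day=5,
                )
            else:
                dating = DatingInfo(
                    method=DatingMethod.LMP,
                    scan_date=scan,
                    lmp_date=scan - _dt.timedelta(days=ga),
                )
            amnion = (
                (Amnion.YES if i in g["amnion_yes"] else Amnion.NO)
                if beyond
                else Amnion.NOT_ASSESSED
            )
            prior = 3 + (i % 2) if i in g["prior3"] else 2
            parity = (0, 0, 1, 0)[i % 4]
            values = {
                key: float(
                    from_centile_array([cents[key][i]], [ga], curves[marker_of[key]])[0]
                )
                for key in cents
            }
            records.append(
                PregnancyRecord(
                    id=f"F{counter:03d}",
                    ga_last_live_days=ga,
                    karyotype=grp,
                    dating=dating,
                    gsmd_mm=round(values["gsmd"], 6),
                    ysmd_mm=round(values["ysmd"], 6),
                    crl_mm=round(values["crl"], 6),
                    hr_bpm=round(values["hr"], 6),
                    amnion_present=amnion,
                    maternal_age_years=float(g["age_base"] + (i * 5) % 11),
                    bmi=None if i in g["bmi_missing"] else round(19.5 + (i * 3) % 14 * 0.75, 1),
                    ethnicity=_ethnicity(i, g["ethnicity_blocks"]),
                    gravidity=prior + parity + 1,
                    parity=parity,
                    prior_miscarriages=prior,
                    conception_mode="art" if i in g["art"] else "spontaneous",
                    abnormality_label=_abnormality_label(i) if grp is Karyotype.ABNORMAL else None,
                )
            )
            counter += 1
    return records


def fixture_cohort() -> list[PregnancyRecord]:
    """The packaged frozen fixture cohort (identical to
    :func:`build_fixture_cohort` under the default curves)."""
    path = resources.files("tetradscreen.data").joinpath("fixture_cohort.csv")
    with resources.as_file(path) as p:
        return read_cohort(p)
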