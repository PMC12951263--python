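"""End-to-end analysis: cohort CSV in, machine-readable report out.

Stages, in order: centile conversion, cut-off selection (the preselected
extreme-centile cut-offs by default, or the empirical 5-bin
frequency-ratio derivation on request), marker flags and the tetrad
composite, descriptive group comparisons, univariable odds ratios in the
all-gestational-age and <= 10-weeks strata, diagnostic accuracy with
paired McNemar comparisons against the tetrad, and logistic modelling.
Every reported estimate is computed by the corresponding module
operation; the report serialises losslessly to JSON and is reproducible
bit-for-bit under fixed inputs and seed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biometry import Marker, ReferenceCurve, default_curves, load_curves, to_centile_array
from .contingency import (
    DxAccuracy, PairedTable, TwoByTwo, dx_accuracy, fisher_exact, mcnemar,
    odds_ratio, or_ci_logit,
)
from .cutoffs import (
    BIN_EDGES, CentileHistogram, CutoffSpec, N_BINS, bin_centiles, derive_cutoff,
    frequency_ratio,
)
from .descriptive import summarize_categorical, summarize_continuous
from .io import read_cohort
from .regression import Covariate, DesignSpec, fit_logistic
from .synthcohort import _SCAN_BASE_DATE  # noqa: F401  (re-exported for examples)
from .tetrad import (
    AMNION_MIN_GA_DAYS, Amnion, Karyotype, MarkerFlags, PregnancyRecord,
    TEN_WEEKS_DAYS, compute_flags, preselected_cutoffs, subgroup,
)

__all__ = ["run_analysis", "validate_cohort", "write_report", "cohort_centiles", "cohort_flags"]

logger = logging.getLogger(__name__)

_MARKER_COLUMNS = {
    Marker.GSMD: "gsmd_mm",
    Marker.YSMD: "ysmd_mm",
    Marker.CRL: "crl_mm",
    Marker.HR: "hr_bpm",
}
_FEATURE_LABELS = {
    "gsmd_small": "GSMD < 5th centile",
    "ysmd_large": "YSMD >= 95th centile",
    "crl_short": "CRL < 5th centile",
    "bradycardia": "Bradycardia",
    "tetrad": "Tetrad of aneuploidy",
}


def cohort_centiles(
    records: Sequence[PregnancyRecord], curves: Mapping[Marker, ReferenceCurve]
) -> pd.DataFrame:
    """Per-record centiles for the four markers (NaN where unmeasured)."""
    out = {"id": [r.id for r in records]}
    ga = np.array([r.ga_last_live_days for r in records], dtype=float)
    for mk, col in _MARKER_COLUMNS.items():
        vals = np.array(
            [getattr(r, col) if getattr(r, col) is not None else np.nan for r in records]
        )
        cent = np.full(len(records), np.nan)
        ok = ~np.isnan(vals)
        if ok.any():
            cent[ok] = to_centile_array(vals[ok], ga[ok], curves[mk])
        out[f"{mk.value.lower()}_centile"] = cent
    return pd.DataFrame(out)


def cohort_flags(
    records: Sequence[PregnancyRecord],
    centiles: pd.DataFrame,
    cutoffs: Mapping[Marker, CutoffSpec],
    strict_missing: bool = False,
) -> pd.DataFrame:
    """Marker flags and tetrad status per record, as 0/1 columns."""
    rows = []
    for i, r in enumerate(records):
        cent = {
            mk: (
                None
                if np.isnan(centiles.iloc[i][f"{mk.value.lower()}_centile"])
                else float(centiles.iloc[i][f"{mk.value.lower()}_centile"])
            )
            for mk in Marker
        }
        f = compute_flags(r.id, cent, cutoffs, strict_missing=strict_missing)
        rows.append({
            "id": r.id,
            "gsmd_small": int(f.gsmd_small),
            "ysmd_large": int(f.ysmd_large),
            "crl_short": int(f.crl_short),
            "bradycardia": int(f.bradycardia),
            "tetrad": int(f.tetrad),
        })
    return pd.DataFrame(rows)


def _analysis_frame(
    records: Sequence[PregnancyRecord],
    centiles: pd.DataFrame,
    flags: pd.DataFrame,
) -> pd.DataFrame:
    df = centiles.merge(flags, on="id")
    df["ga_last_live_days"] = [r.ga_last_live_days for r in records]
    df["abnormal"] = [
        None if r.karyotype is None else int(r.karyotype is Karyotype.ABNORMAL) for r in records
    ]
    for attr in ("maternal_age_years", "bmi", "gravidity", "parity", "prior_miscarriages"):
        df[attr] = [getattr(r, attr) for r in records]
    df["ethnicity"] = [r.ethnicity for r in records]
    df["conception_mode"] = [r.conception_mode for r in records]
    df["amnion"] = [r.amnion_present.value for r in records]
    return df


def _or_block(df: pd.DataFrame) -> dict:
    """Univariable odds-ratio rows for each marker flag and the tetrad."""
    out = {}
    abn = df["abnormal"] == 1
    for feat, label in _FEATURE_LABELS.items():
        flag = df[feat] == 1
        a = int((flag & abn).sum())
        b = int((flag & ~abn).sum())
        c = int((~flag & abn).sum())
        d = int((~flag & ~abn).sum())
        try:
            t = TwoByTwo(a, b, c, d)
            entry = {
                "counts": {"a": a, "b": b, "c": c, "d": d},
                "odds_ratio": odds_ratio(t, correct_zero=True),
                "ci": list(or_ci_logit(t, correct_zero=True)),
                "corrected": t.has_zero,
                "fisher_p": fisher_exact(t),
            }
        except ValueError as exc:
            entry = {"counts": {"a": a, "b": b, "c": c, "d": d}, "error": str(exc)}
        out[label] = entry
    return out


def _metric_dict(m) -> Optional[dict]:
    return None if m is None else {"estimate": m.estimate, "ci": [m.lo, m.hi]}


def _accuracy_block(df: pd.DataFrame) -> dict:
    """Diagnostic accuracy of each feature plus paired McNemar tests
    against the tetrad within the diseased / non-diseased strata."""
    out = {}
    abn = df["abnormal"] == 1
    tet = df["tetrad"] == 1
    for feat, label in _FEATURE_LABELS.items():
        flag = df[feat] == 1
        tp = int((flag & abn).sum())
        fp = int((flag & ~abn).sum())
        fn = int((~flag & abn).sum())
        tn = int((~flag & ~abn).sum())
        acc = dx_accuracy(tp, fp, fn, tn)
        entry = {
            "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
            "sensitivity": _metric_dict(acc.sensitivity),
            "specificity": _metric_dict(acc.specificity),
            "ppv": _metric_dict(acc.ppv),
            "npv": _metric_dict(acc.npv),
            "accuracy": _metric_dict(acc.accuracy),
        }
        if feat != "tetrad":
            for strat_name, sel in (("sensitivity", abn), ("specificity", ~abn)):
                p = PairedTable(
                    both_pos=int((flag & tet & sel).sum()),
                    marker_only=int((flag & ~tet & sel).sum()),
                    tetrad_only=int((~flag & tet & sel).sum()),
                    both_neg=int((~flag & ~tet & sel).sum()),
                )
                stat, pval, method = mcnemar(p)
                entry[f"mcnemar_{strat_name}"] = {
                    "statistic": stat, "p": pval, "method": method,
                    "discordant": p.discordant,
                }
        out[label] = entry
    return out


def _term_dict(t) -> dict:
    return {
        "estimate": t.estimate, "se": t.se, "or": t.odds_ratio,
        "ci_lo": t.ci_lo, "ci_hi": t.ci_hi, "p": t.p,
    }


def _regression_block(df: pd.DataFrame) -> dict:
    """Multivariable model (three continuous centiles + bradycardia) and
    the four-way interaction model."""
    frame = df.rename(columns={
        "gsmd_centile": "gsmd", "ysmd_centile": "ysmd", "crl_centile": "crl"
    }).copy()
    frame["abnormal"] = frame["abnormal"].astype(float)
    out = {}
    spec = DesignSpec(
        outcome="abnormal",
        covariates=(
            Covariate("gsmd", "continuous"),
            Covariate("ysmd", "continuous"),
            Covariate("crl", "continuous"),
            Covariate("bradycardia", "binary"),
        ),
    )
    try:
        fit = fit_logistic(frame, spec)
        out["multivariable"] = {
            "terms": {k: _term_dict(v) for k, v in fit.terms.items()},
            "n_used": fit.n_used, "converged": fit.converged, "separated": fit.separated,
            "tjur_r2": fit.tjur_r2, "hosmer_lemeshow": fit.hosmer_lemeshow, "vif": fit.vif,
        }
    except (ValueError, RuntimeError) as exc:
        out["multivariable"] = {"error": str(exc)}

    frame["four_way"] = (
        frame["gsmd_small"] * frame["ysmd_large"] * frame["crl_short"] * frame["bradycardia"]
    )
    try:
        fit4 = fit_logistic(
            frame, DesignSpec(outcome="abnormal", covariates=(Covariate("four_way", "binary"),))
        )
        out["four_way_interaction"] = {
            "terms": {k: _term_dict(v) for k, v in fit4.terms.items()},
            "n_used": fit4.n_used, "converged": fit4.converged, "separated": fit4.separated,
            "tjur_r2": fit4.tjur_r2,
        }
    except (ValueError, RuntimeError) as exc:
        out["four_way_interaction"] = {"error": str(exc)}
    return out


def _descriptive_block(records: Sequence[PregnancyRecord], df: pd.DataFrame, seed: int) -> dict:
    """Baseline (Table-1-style) and sonographic (Table-2-style) group
    comparisons."""
    abn = df["abnormal"] == 1

    def split(col):
        x = df.loc[~abn, col].astype(float).to_numpy()
        y = df.loc[abn, col].astype(float).to_numpy()
        return x, y

    def cat_counts(col, levels):
        c0 = [int(((df[col] == lv) & ~abn).sum()) for lv in levels]
        c1 = [int(((df[col] == lv) & abn).sum()) for lv in levels]
        return c0, c1

    baseline = []
    for col, name in (
        ("maternal_age_years", "Maternal age at conception (years)"),
        ("bmi", "Body mass index (kg/m2)"),
        ("gravidity", "Gravidity"),
        ("parity", "Parity"),
        ("ga_last_live_days", "GA at last live scan (days)"),
    ):
        try:
            baseline.append(summarize_continuous(name, *split(col)).__dict__)
        except ValueError:
            pass
    eth_levels = ["Caucasian", "Mixed/Other", "Afro-Caribbean", "East Asian", "South Asian"]
    if df["ethnicity"].notna().any():
        baseline += [s.__dict__ for s in summarize_categorical(
            "Ethnicity", *cat_counts("ethnicity", eth_levels), eth_levels, seed=seed)]
    prior3 = df["prior_miscarriages"].astype(float) >= 3
    baseline += [s.__dict__ for s in summarize_categorical(
        ">= 3 prior miscarriages",
        [int((prior3 & ~abn).sum()), int((~prior3 & ~abn).sum())],
        [int((prior3 & abn).sum()), int((~prior3 & abn).sum())],
        ["yes", "no"], seed=seed)]
    if df["conception_mode"].notna().any():
        baseline += [s.__dict__ for s in summarize_categorical(
            "Mode of conception", *cat_counts("conception_mode", ["spontaneous", "art"]),
            ["spontaneous", "ART"], seed=seed)]

    sono = []
    for mk in Marker:
        col = f"{mk.value.lower()}_centile"
        sono.append(summarize_continuous(f"{mk.value} centile", *split(col)).__dict__)
    for feat in ("gsmd_small", "ysmd_large", "crl_short", "bradycardia", "tetrad"):
        pos = df[feat] == 1
        sono += [s.__dict__ for s in summarize_categorical(
            _FEATURE_LABELS[feat],
            [int((pos & ~abn).sum()), int((~pos & ~abn).sum())],
            [int((pos & abn).sum()), int((~pos & abn).sum())],
            ["yes", "no"], seed=seed)]
    assessed = df["amnion"] != Amnion.NOT_ASSESSED.value
    if assessed.any():
        sono += [s.__dict__ for s in summarize_categorical(
            "Amniotic sac present (GA > 49 d)",
            [int(((df["amnion"] == lv) & ~abn).sum()) for lv in ("no", "yes")],
            [int(((df["amnion"] == lv) & abn).sum()) for lv in ("no", "yes")],
            ["no", "yes"], seed=seed)]
    return {"baseline": baseline, "sonographic": sono}


def _cutoff_block(df: pd.DataFrame, derive: bool) -> tuple[dict[Marker, CutoffSpec], dict]:
    if not derive:
        cut = preselected_cutoffs()
        return cut, {
            "mode": "preselected",
            "cutoffs": {
                mk.value: {"threshold": c.threshold, "direction": c.direction}
                for mk, c in cut.items()
            },
        }
    abn = df["abnormal"] == 1
    cut: dict[Marker, CutoffSpec] = {}
    tables = {}
    for mk in (Marker.GSMD, Marker.YSMD, Marker.CRL):
        col = f"{mk.value.lower()}_centile"
        hist = bin_centiles(
            mk,
            df.loc[~abn, col].dropna().to_numpy(),
            df.loc[abn, col].dropna().to_numpy(),
        )
        spec = derive_cutoff(hist)
        cut[mk] = spec
        tables[mk.value] = {
            "bins": [
                {
                    "lo": BIN_EDGES[i], "hi": BIN_EDGES[i + 1],
                    "n_normal": hist.counts_normal[i],
                    "n_abnormal": hist.counts_abnormal[i],
                    "pct_normal": 100 * hist.counts_normal[i] / hist.n_normal,
                    "pct_abnormal": 100 * hist.counts_abnormal[i] / hist.n_abnormal,
                    "ratio": frequency_ratio(hist, i),
                }
                for i in range(N_BINS)
            ],
            "selected": {"threshold": spec.threshold, "direction": spec.direction,
                         "ratio": spec.ratio},
        }
    cut[Marker.HR] = preselected_cutoffs()[Marker.HR]  # bradycardia definition is fixed
    return cut, {"mode": "derived", "tables": tables,
                 "cutoffs": {mk.value: {"threshold": c.threshold, "direction": c.direction}
                             for mk, c in cut.items()}}


def run_analysis(
    cohort,
    curves: Optional[Mapping[Marker, ReferenceCurve]] = None,
    derive_cutoffs: bool = False,
    subgroup_max_ga: int = TEN_WEEKS_DAYS,
    strict_missing: bool = False,
    seed: int = 0,
) -> dict:
    """Run the full analysis on a cohort (path to CSV or record list)."""
    if isinstance(cohort, (str, Path)):
        records = read_cohort(cohort)
    else:
        records = list(cohort)
    curves = curves or default_curves()
    records = [r for r in records if r.karyotype is not None]
    logger.info("analysis cohort: %d records with a karyotype result", len(records))

    centiles = cohort_centiles(records, curves)
    df = _analysis_frame(records, centiles, cohort_flags(
        records, centiles, preselected_cutoffs(), strict_missing=strict_missing))
    cutoffs, cutoff_report = _cutoff_block(df, derive_cutoffs)
    flags = cohort_flags(records, centiles, cutoffs, strict_missing=strict_missing)
    df = _analysis_frame(records, centiles, flags)

    n_abn = int((df["abnormal"] == 1).sum())
    n_norm = int((df["abnormal"] == 0).sum())
    report = {
        "provenance": {
            "package": "tetradscreen",
            "version": __version__,
            "seed": seed,
            "options": {
                "derive_cutoffs": derive_cutoffs,
                "subgroup_max_ga": subgroup_max_ga,
                "strict_missing": strict_missing,
            },
        },
        "flow": {
            "records_in": len(records),
            "abnormal_karyotype": n_abn,
            "normal_karyotype": n_norm,
            "subgroup_le_max_ga": int((df["ga_last_live_days"] <= subgroup_max_ga).sum()),
        },
        "cutoffs": cutoff_report,
    }
    report["provenance"]["config_hash"] = hashlib.sha256(
        json.dumps(report["provenance"]["options"], sort_keys=True).encode()
        + str(len(records)).encode()
    ).hexdigest()[:16]

    if n_abn == 0 or n_norm == 0:
        logger.warning("only one karyotype group present; comparison stages skipped")
        report["skipped"] = "only one karyotype group present"
        return report

    sub = df[df["ga_last_live_days"] <= subgroup_max_ga]
    report["descriptive"] = _descriptive_block(records, df, seed)
    report["univariable_or"] = {"all_ga": _or_block(df)}
    report["accuracy"] = {"all_ga": _accuracy_block(df)}
    report["regression"] = {"all_ga": _regression_block(df)}
    if 0 < len(sub) < len(df):
        if (sub["abnormal"] == 1).any() and (sub["abnormal"] == 0).any():
            report["univariable_or"]["subgroup"] = _or_block(sub)
            report["accuracy"]["subgroup"] = _accuracy_block(sub)
            report["regression"]["subgroup"] = _regression_block(sub)
        else:
            report["univariable_or"]["subgroup"] = {
                "skipped": "only one karyotype group in the subgroup"}
    report["notes"] = [
        "Univariable odds ratios use the Haldane-Anscombe 0.5 correction with "
        "Woolf logit intervals when a zero cell is present.",
        "Published diagnostic-accuracy confidence bounds for the composite "
        "correspond to the full-cohort tetrad cross-tabulation; subgroup "
        "denominators are reported separately and may differ.",
    ]
    return report


def write_report(report: dict, outdir) -> None:
    """Serialise the report: one JSON plus per-table CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    if "descriptive" in report:
        for key, name in (("baseline", "table1_baseline"), ("sonographic", "table2_sonographic")):
            pd.DataFrame(report["descriptive"][key]).to_csv(outdir / f"{name}.csv", index=False)
    if "univariable_or" in report:
        rows = []
        for stratum, block in report["univariable_or"].items():
            for label, e in block.items():
                if not isinstance(e, dict) or "counts" not in e:
                    continue
                rows.append({
                    "stratum": stratum, "feature": label, **e["counts"],
                    "odds_ratio": e.get("odds_ratio"),
                    "ci_lo": (e.get("ci") or [None, None])[0],
                    "ci_hi": (e.get("ci") or [None, None])[1],
                    "fisher_p": e.get("fisher_p"),
                })
        pd.DataFrame(rows).to_csv(outdir / "table3_univariable_or.csv", index=False)
    if "accuracy" in report:
        rows = []
        for stratum, block in report["accuracy"].items():
            for label, e in block.items():
                if "counts" not in e:
                    continue
                row = {"stratum": stratum, "feature": label, **e["counts"]}
                for metric in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
                    m = e.get(metric)
                    row[metric] = m["estimate"] if m else None
                    row[f"{metric}_lo"] = m["ci"][0] if m else None
                    row[f"{metric}_hi"] = m["ci"][1] if m else None
                rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "table4_accuracy.csv", index=False)
    if report.get("cutoffs", {}).get("mode") == "derived":
        rows = []
        for mk, tab in report["cutoffs"]["tables"].items():
            for b in tab["bins"]:
                rows.append({"marker": mk, **b})
        pd.DataFrame(rows).to_csv(outdir / "figureS1_cutoff_bins.csv", index=False)


def validate_cohort(path) -> dict:
    """Schema and invariant checks on a cohort CSV, row by row."""
    df = pd.read_csv(path, dtype={"id": str})
    violations: list[dict] = []

    def flag(idx, column, message):
        violations.append({"row": int(idx), "column": column, "message": message})

    for idx, row in df.iterrows():
        ga = row.get("ga_last_live_days")
        if pd.isna(ga) or ga <= 0:
            flag(idx, "ga_last_live_days", f"must be a positive integer, got {ga!r}")
            ga = None
        for col in ("gsmd_mm", "ysmd_mm", "crl_mm", "hr_bpm"):
            v = row.get(col)
            if pd.notna(v) and v <= 0:
                flag(idx, col, f"must be positive, got {v}")
        k = row.get("karyotype")
        if pd.notna(k) and k not in ("normal", "abnormal"):
            flag(idx, "karyotype", f"unknown karyotype {k!r}")
        am = row.get("amnion_present")
        if (
            pd.notna(am) and am != "not_assessed"
            and ga is not None and ga <= AMNION_MIN_GA_DAYS
        ):
            flag(idx, "amnion_present", f"recorded at GA <= {AMNION_MIN_GA_DAYS} days")
        method = row.get("dating_method")
        if pd.notna(method):
            required = {"lmp": ["lmp_date"], "conception": ["conception_date"],
                        "embryo_transfer": ["transfer_date", "transfer_day"]}.get(method)
            if required is None:
                flag(idx, "dating_method", f"unknown method {method!r}")
            else:
                for col in required + ["scan_date"]:
                    if pd.isna(row.get(col)):
                        flag(idx, col, f"required by dating method {method!r}")
    return {
        "n_rows": len(df),
        "violations": violations,
        "n_violations": len(violations),
        "missing_per_column": {c: int(df[c].isna().sum()) for c in df.columns},
    }
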