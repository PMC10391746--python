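"""End-to-end pipeline orchestration and paper-style summary tables.

``run_pipeline`` executes score → trajectory metrics → infections →
outcome statistics on a cohort and writes one CSV per result plus a
machine-readable manifest with SHA-256 checksums.  All numbers are computed
here once; rendered tables and figures only re-shape CSV values.  Outputs
are written only after every stage succeeds, so a failing stage leaves no
partial bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import HematotoxError, StatisticalError
from .infections import cumulative_incidence_infection, summarize_infections
from .score import score_cohort
from .stats import (cox_fit, fisher_exact, km_fit, logistic_fit, logrank,
                    mann_whitney, nrm_cuminc, roc, spearman)
from .trajectories import cytopenia_flags, neutropenia_metrics

COX_COVARIATES = ["egfr_lt60", "ldh_above_uln", "ecog_ge2", "bm_gt50", "ht_high"]


@dataclass
class RunConfig:
    out_dir: str | Path = "results"
    leniency_days: int = 3
    interpolation: str = "locf"
    horizon_days: int = 100
    infection_horizon_days: int = 90
    followup_months: float = 12.0
    figures: bool = True
    seed: int | None = None


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    manifest: dict = field(default_factory=dict)
    out_dir: Path | None = None


class StageError(HematotoxError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _covariate_frame(cohort: Cohort, scores) -> pd.DataFrame:
    rows = []
    for r in cohort:
        if r.patient_id not in scores.results or r.outcome is None:
            continue
        c = r.covariates
        rows.append({
            "patient_id": r.patient_id,
            "egfr_lt60": int(c.egfr is not None and c.egfr < 60),
            "ldh_above_uln": int(bool(c.ldh_above_uln)),
            "ecog_ge2": int(c.ecog is not None and c.ecog >= 2),
            "bm_gt50": int(c.bm_plasma_cell_pct is not None
                           and c.bm_plasma_cell_pct > 50),
            "ht_high": int(scores.results[r.patient_id].risk_class == "high"),
            "pfs_time": r.outcome.pfs_time, "pfs_event": r.outcome.pfs_event,
            "os_time": r.outcome.os_time, "os_event": r.outcome.os_event,
        })
    return pd.DataFrame(rows)


def _km_table(curve, group, endpoint) -> pd.DataFrame:
    return pd.DataFrame({
        "endpoint": endpoint, "group": group, "time": curve.times,
        "survival": curve.survival, "ci_lower": curve.ci_lower,
        "ci_upper": curve.ci_upper, "n_at_risk": curve.at_risk,
    })


def run_pipeline(cohort: Cohort, config: RunConfig | None = None) -> PipelineResult:
    """Run the full analysis and write the result bundle to ``config.out_dir``."""
    config = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}
    log: list[dict] = []

    # ---- stage: score -------------------------------------------------
    stage = "score"
    try:
        scores = score_cohort(cohort, leniency_days=config.leniency_days)
        tables["scores"] = scores.table
        log.append({"stage": stage, "n_in": len(cohort),
                    "n_out": len(scores.table),
                    "n_unscoreable": len(scores.unscoreable)})
    except Exception as e:
        raise StageError(stage, e) from e
    cls_by_id = dict(zip(scores.table.patient_id, scores.table.risk_class))
    groups = {pid: f"HT-{c}" for pid, c in cls_by_id.items()}
    scored = [r for r in cohort if r.patient_id in cls_by_id]

    # ---- stage: hematotox metrics ------------------------------------
    stage = "hematotox"
    try:
        rows = []
        for r in scored:
            m = neutropenia_metrics(r, horizon=config.horizon_days,
                                    mode=config.interpolation)
            f = cytopenia_flags(r)
            rows.append({"patient_id": r.patient_id,
                         "risk_class": cls_by_id[r.patient_id],
                         "score": int(scores.results[r.patient_id].total),
                         **{k: getattr(m, k) for k in (
                             "severe_days_d0_60", "phenotype",
                             "phenotype_low_confidence", "severe_d0_30",
                             "severe_d31_100", "protracted_severe",
                             "profound_d0_100", "protracted_profound",
                             "prolonged")},
                         **{k: getattr(f, k) for k in (
                             "severe_thrombocytopenia_d0_30",
                             "severe_thrombocytopenia_d31_100",
                             "severe_anemia_d0_30", "severe_anemia_d31_100")}})
        metrics = pd.DataFrame(rows)
        tables["metrics"] = metrics
        log.append({"stage": stage, "n_in": len(scored), "n_out": len(metrics)})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: infections -------------------------------------------
    stage = "infections"
    try:
        summary = summarize_infections(scored, horizon=config.infection_horizon_days)
        per_pat = summary.per_patient.copy()
        per_pat["risk_class"] = per_pat.patient_id.map(cls_by_id)
        tables["infections"] = per_pat
        tables["infection_tally"] = summary.event_tally
        curve_rows = []
        inc_rows = []
        for cat in ("any", "severe", "bacterial", "viral", "fungal"):
            comp = cumulative_incidence_infection(
                scored, groups, category=cat,
                horizon=config.infection_horizon_days)
            for g, curve in comp.curves.items():
                for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
                    curve_rows.append({"category": cat, "group": g, "day": t,
                                       "cumulative_incidence": 1 - s,
                                       "n_at_risk": n})
            inc_rows.append({"category": cat, "chi2": comp.chi2,
                             "p_value": comp.p_value})
        tables["infection_curves"] = pd.DataFrame(curve_rows)
        tables["infection_logrank"] = pd.DataFrame(inc_rows)
        log.append({"stage": stage, "n_in": len(scored),
                    "n_events": summary.n_events})
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- stage: outcomes ---------------------------------------------
    stage = "outcomes"
    try:
        metrics = tables["metrics"]
        outcome_rows = []
        # ROC of the score against >= 14-day severe neutropenia
        endpoint = metrics["severe_days_d0_60"] >= 14
        if endpoint.nunique() == 2:
            rr = roc(metrics["score"], endpoint)
            tables["roc"] = rr.thresholds.assign(auc=rr.auc, p_value=rr.p_value)
            outcome_rows.append({"name": "auc_severe_ge14d", "value": rr.auc,
                                 "p_value": rr.p_value})
        r_s, p_s, slope = spearman(metrics["score"], metrics["severe_days_d0_60"])
        outcome_rows.append({"name": "spearman_score_vs_days", "value": r_s,
                             "p_value": p_s})
        outcome_rows.append({"name": "slope_days_per_point", "value": slope,
                             "p_value": np.nan})

        df = _covariate_frame(cohort, scores)
        km_rows = []
        for endpoint_name, tcol, ecol in (("pfs", "pfs_time", "pfs_event"),
                                          ("os", "os_time", "os_event")):
            sub = {g: df[df.ht_high == int(g == "HT-high")]
                   for g in ("HT-low", "HT-high")}
            for g, d in sub.items():
                if len(d):
                    km_rows.append(_km_table(km_fit(d[tcol], d[ecol]),
                                             g, endpoint_name))
            if all(len(d) for d in sub.values()):
                chi2, p = logrank(sub["HT-low"][tcol], sub["HT-low"][ecol],
                                  sub["HT-high"][tcol], sub["HT-high"][ecol])
                outcome_rows.append({"name": f"logrank_{endpoint_name}",
                                     "value": chi2, "p_value": p})
                try:
                    uni = cox_fit(df, ["ht_high"], tcol, ecol)
                    outcome_rows.append(
                        {"name": f"univariate_hr_{endpoint_name}",
                         "value": uni.ratio("ht_high"),
                         "p_value": float(uni.table.loc["ht_high", "p"])})
                except StatisticalError:
                    pass
                try:
                    mv = cox_fit(df, COX_COVARIATES, tcol, ecol)
                    tables[f"cox_{endpoint_name}"] = mv.table.reset_index(
                        names="covariate")
                except StatisticalError:
                    pass
        tables["km"] = pd.concat(km_rows, ignore_index=True)

        curves, (chi2_nrm, p_nrm) = nrm_cuminc(scored, groups=groups)
        nrm_rows = []
        for g, c in curves.items():
            for t, v in zip(c.times, c.incidence["NRM"]):
                nrm_rows.append({"group": g, "time": t, "nrm_incidence": v})
        overall = nrm_cuminc(scored)
        outcome_rows.append({"name": "nrm_1yr_overall",
                             "value": overall.at("NRM", config.followup_months),
                             "p_value": np.nan})
        outcome_rows.append({"name": "nrm_logrank", "value": chi2_nrm,
                             "p_value": p_nrm})
        tables["nrm"] = pd.DataFrame(nrm_rows)

        logi = df.merge(metrics[["patient_id", "phenotype"]], on="patient_id")
        logi = logi.merge(per_pat[["patient_id", "severe_d0_90"]], on="patient_id")
        logi["aplastic"] = (logi.phenotype == "aplastic").astype(int)
        logi["severe_infection"] = logi.severe_d0_90.astype(int)
        for name, col in (("aplastic", "aplastic"),
                          ("infection", "severe_infection")):
            try:
                fit = logistic_fit(logi, COX_COVARIATES, col)
                tables[f"logistic_{name}"] = fit.table.reset_index(
                    names="covariate")
            except StatisticalError:
                pass

        tables["outcome_summary"] = pd.DataFrame(outcome_rows)
        tables["group_tests"] = _group_tests(scored, cls_by_id, metrics, per_pat)
        tables["table1"] = _table1(scored, cls_by_id)
        tables["table2"] = _table2(metrics, per_pat)
        log.append({"stage": stage, "n_in": len(df)})
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- write bundle -------------------------------------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_patients": len(cohort), "files": {},
                "log": log, "seed": config.seed}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["files"][f"{name}.csv"] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    if config.figures:
        _render_figures(tables, out)
    return PipelineResult(tables=tables, manifest=manifest, out_dir=out)


def _group_tests(records, cls_by_id, metrics, infections) -> pd.DataFrame:
    rows = []
    for analyte in ("anc", "hemoglobin", "platelets", "crp", "ferritin"):
        vals = {"low": [], "high": []}
        for r in records:
            v = r.baseline.value(analyte)
            if v is not None:
                vals[cls_by_id[r.patient_id]].append(v)
        if vals["low"] and vals["high"]:
            t = mann_whitney(vals["low"], vals["high"])
            rows.append({"variable": f"baseline_{analyte}",
                         "test": "mann_whitney", "p_value": t.p_value})
    low = metrics[metrics.risk_class == "low"]
    high = metrics[metrics.risk_class == "high"]
    if len(low) and len(high):
        t = mann_whitney(low.severe_days_d0_60, high.severe_days_d0_60)
        rows.append({"variable": "severe_neutropenia_days",
                     "test": "mann_whitney", "p_value": t.p_value})
        for flag in ("protracted_severe", "prolonged"):
            table = [[int(high[flag].sum()), int((~high[flag]).sum())],
                     [int(low[flag].sum()), int((~low[flag]).sum())]]
            t = fisher_exact(table)
            rows.append({"variable": flag, "test": "fisher_exact",
                         "p_value": t.p_value})
    inf_low = infections[infections.risk_class == "HT-low"
                         if "HT-low" in set(infections.risk_class)
                         else infections.risk_class == "low"]
    inf_high = infections[infections.risk_class.isin(["HT-high", "high"])]
    if len(inf_low) and len(inf_high):
        table = [[int(inf_high.severe_d0_90.sum()),
                  int((~inf_high.severe_d0_90).sum())],
                 [int(inf_low.severe_d0_90.sum()),
                  int((~inf_low.severe_d0_90).sum())]]
        t = fisher_exact(table)
        rows.append({"variable": "severe_infection_d0_90",
                     "test": "fisher_exact", "p_value": t.p_value})
    return pd.DataFrame(rows)


def _table1(records, cls_by_id) -> pd.DataFrame:
    rows = []
    for analyte in ("crp", "ferritin", "anc", "platelets", "hemoglobin"):
        row = {"characteristic": f"median_{analyte}"}
        for cls in ("low", "high"):
            vals = [r.baseline.value(analyte) for r in records
                    if cls_by_id[r.patient_id] == cls
                    and r.baseline.value(analyte) is not None]
            row[cls] = float(np.median(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _table2(metrics, infections) -> pd.DataFrame:
    rows = []
    def rate(df, col):
        vals = df[col].dropna() if df[col].dtype == object else df[col]
        return float(np.mean(vals.astype(bool))) if len(vals) else np.nan
    for col in ("severe_d0_30", "severe_d31_100", "protracted_severe",
                "profound_d0_100", "protracted_profound", "prolonged",
                "severe_thrombocytopenia_d0_30", "severe_thrombocytopenia_d31_100",
                "severe_anemia_d0_30", "severe_anemia_d31_100"):
        row = {"characteristic": col}
        for cls in ("low", "high"):
            row[cls] = rate(metrics[metrics.risk_class == cls], col)
        rows.append(row)
    for cls in ("low", "high"):
        sub = metrics[metrics.risk_class == cls]
        for pheno in ("quick", "intermittent", "aplastic"):
            rows.append({"characteristic": f"phenotype_{pheno}", cls:
                         float((sub.phenotype == pheno).mean()) if len(sub)
                         else np.nan})
    df = pd.DataFrame(rows)
    return df.groupby("characteristic", sort=False).first().reset_index()


def _render_figures(tables: dict, out: Path) -> None:
    """Presentation-only plots of already-written CSV values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "km" in tables and len(tables["km"]):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, endpoint in zip(axes, ("pfs", "os")):
            sub = tables["km"][tables["km"].endpoint == endpoint]
            for g, d in sub.groupby("group"):
                ax.step(d.time, d.survival, where="post", label=g)
            ax.set_xlabel("months"); ax.set_ylabel("survival")
            ax.set_title(endpoint.upper()); ax.set_ylim(0, 1.02); ax.legend()
        fig.tight_layout(); fig.savefig(out / "fig_km.png", dpi=120)
        plt.close(fig)
    if "infection_curves" in tables and len(tables["infection_curves"]):
        sub = tables["infection_curves"]
        cats = sub.category.unique()
        fig, axes = plt.subplots(1, len(cats), figsize=(3.2 * len(cats), 3.2),
                                 squeeze=False)
        for ax, cat in zip(axes[0], cats):
            d0 = sub[sub.category == cat]
            for g, d in d0.groupby("group"):
                ax.step(d.day, d.cumulative_incidence, where="post", label=g)
            ax.set_title(cat); ax.set_xlabel("day")
            ax.set_ylabel("cumulative incidence"); ax.set_ylim(0, 1); ax.legend()
        fig.tight_layout(); fig.savefig(out / "fig_infections.png", dpi=120)
        plt.close(fig)
    if "roc" in tables and len(tables["roc"]):
        d = tables["roc"]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1 - d.specificity, d.sensitivity, marker="o")
        ax.plot([0, 1], [0, 1], ls="--", color="gray")
        ax.set_xlabel("1 - specificity"); ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {d.auc.iloc[0]:.2f}")
        fig.tight_layout(); fig.savefig(out / "fig_roc.png", dpi=120)
        plt.close(fig)
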