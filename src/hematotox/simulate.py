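"""Synthetic BCMA CAR-T cohorts with the statistical structure the
analysis assumes, so the whole pipeline runs with no external data.

Two latent risk strata drive the baseline-lab draws (log-normal for ANC,
platelets, CRP and ferritin; normal for hemoglobin), with locations set to
the published group medians.  Everything downstream — the neutrophil
trajectory, infection events, survival — is conditioned on the risk class
*recomputed from the generated labs*, because the study's strata are
defined by the computed score, not by latent biology; patients may cross
over between latent stratum and computed class, and the crossover rate is
reported by :func:`calibration_report`.

Default calibration targets (group medians / rates the generated cohorts
converge to as n grows):

* baseline labs — low: Hb 11.6 g/dl, plt 181 G/l, ANC 2.95 G/l,
  CRP 0.45 mg/dl, ferritin 86 ng/ml; high: 8.5 / 63 / 1.77 / 1.02 / 811.
* severe-neutropenia duration: negative-binomial with mean
  ``intercept + 2.48 x score`` days (median 9 days in the high class,
  3 in the low class); a contiguous run of >= 14 days is the aplastic
  phenotype.
* severe (grade >= 3) infection in days 0–90: 40% high / 5% low; any-grade
  58% / 23%; onset days are drawn with elevated weight while ANC < 0.5.
* survival (months): PFS median 5.4 high / 14.9 low; OS median 10.5 high /
  60 low (a "beyond follow-up" stand-in for a median that is never
  reached); 1-year NRM 12.7% / 2.1%; administrative censoring at 12 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (BaselineLabs, Cohort, Covariates, InfectionEvent,
                     LabSeries, OutcomeRecord, PatientRecord)
from .errors import ConfigError
from .score import score_components, select_baseline_labs


def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class GeneratorConfig:
    n_patients: int = 200
    target_low_fraction: float = 0.558  # 63/113

    # per-stratum lab medians (canonical units) and log-scale spreads
    lab_medians_low: dict = _d(anc=2.95, hemoglobin=11.6, platelets=181.0,
                               crp=0.45, ferritin=86.0)
    lab_medians_high: dict = _d(anc=1.77, hemoglobin=8.5, platelets=63.0,
                                crp=1.02, ferritin=811.0)
    lab_sigmas_low: dict = _d(anc=0.45, hemoglobin=1.2, platelets=0.30,
                              crp=0.9, ferritin=1.0)
    lab_sigmas_high: dict = _d(anc=0.50, hemoglobin=1.0, platelets=0.50,
                               crp=0.9, ferritin=1.0)

    # severe-neutropenia duration: NB mean = intercept + slope * score
    duration_intercept: float = 2.0
    duration_slope: float = 2.48
    duration_dispersion: float = 6.0  # NB size parameter r (larger = tighter)

    # trajectory shape
    nadir_day_range: tuple = (2, 6)       # inclusive ints
    recovery_plateau_range: tuple = (1.6, 3.2)
    second_dip_prob: dict = _d(low=0.35, high=0.56)

    # infections, conditioned on the computed class
    any_infection_prob: dict = _d(low=0.23, high=0.58)
    severe_infection_prob: dict = _d(low=0.05, high=0.40)
    second_event_prob: float = 0.16
    neutropenic_onset_weight: float = 4.0  # extra weight while ANC < 0.5

    # survival (months), conditioned on the computed class
    pfs_median: dict = _d(low=14.9, high=5.4)
    os_median: dict = _d(low=60.0, high=10.5)  # low ~ "not reached"
    nrm_1yr: dict = _d(low=0.021, high=0.127)
    followup_months: float = 12.0
    nrm_cause_probs: dict = _d(infection=5 / 7, CRS=1 / 7, cardiotoxicity=1 / 7)

    # covariates, conditioned on the computed class
    egfr_ge60_prob: dict = _d(low=0.84, high=0.62)
    ldh_above_uln_prob: dict = _d(low=0.206, high=0.46)
    ecog_ge2_prob: dict = _d(low=0.0, high=0.24)
    bm_gt50_prob: dict = _d(low=0.111, high=0.42)
    prior_bcma_prob: dict = _d(low=0.04, high=0.22)

    # cytopenias other than neutropenia
    severe_thrombo_d0_30_prob: dict = _d(low=0.27, high=0.78)
    thrombo_persist_prob: dict = _d(low=0.20, high=0.68)
    severe_anemia_d0_30_prob: dict = _d(low=0.222, high=0.84)
    anemia_persist_prob: dict = _d(low=0.43, high=0.57)

    vgpr_or_better_prob: dict = _d(low=0.70, high=0.44)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        probs = [self.target_low_fraction, self.second_event_prob]
        for d in (self.second_dip_prob, self.any_infection_prob,
                  self.severe_infection_prob, self.nrm_1yr,
                  self.egfr_ge60_prob, self.ldh_above_uln_prob,
                  self.ecog_ge2_prob, self.bm_gt50_prob, self.prior_bcma_prob,
                  self.severe_thrombo_d0_30_prob, self.thrombo_persist_prob,
                  self.severe_anemia_d0_30_prob, self.anemia_persist_prob,
                  self.vgpr_or_better_prob, self.nrm_cause_probs):
            probs.extend(d.values())
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for cls in ("low", "high"):
            if self.severe_infection_prob[cls] > self.any_infection_prob[cls]:
                raise ConfigError("severe infection prob exceeds any-infection prob")


_ANALYTE_ROUND = {"anc": 2, "hemoglobin": 1, "platelets": 0, "crp": 2,
                  "ferritin": 0}


def _draw_labs(rng, medians, sigmas) -> dict:
    out = {}
    for a, med in medians.items():
        if a == "hemoglobin":
            v = rng.normal(med, sigmas[a])
        else:
            v = np.exp(rng.normal(np.log(med), sigmas[a]))
        v = max(v, {"anc": 0.05, "hemoglobin": 4.0, "platelets": 3.0,
                    "crp": 0.01, "ferritin": 5.0}[a])
        out[a] = round(float(v), _ANALYTE_ROUND[a])
        if _ANALYTE_ROUND[a] == 0:
            out[a] = float(int(out[a]))
    return out


def _anc_trajectory(rng, cfg: GeneratorConfig, baseline_anc: float,
                    duration: int, second_dip: bool):
    """Daily latent ANC over days 0..100 plus the intended phenotype."""
    horizon = 100
    anc = np.empty(horizon + 1)
    onset = int(rng.integers(cfg.nadir_day_range[0], cfg.nadir_day_range[1] + 1))
    plateau = rng.uniform(*cfg.recovery_plateau_range)
    a0 = min(max(baseline_anc, 0.8), 6.0)

    if duration > 0:
        duration = int(min(duration, horizon - onset - 4))
        # decline into the severe run
        for d in range(onset):
            frac = d / max(onset, 1)
            anc[d] = max(0.55, a0 + frac * (0.7 - a0))
        run = rng.uniform(0.05, 0.45, size=duration)
        if duration >= 9 and rng.random() < 0.4:
            core = min(duration - 2, max(7, duration // 2))
            start = 1 + (duration - 2 - core) // 2
            run[start:start + core] = rng.uniform(0.02, 0.09, size=core)
        anc[onset:onset + duration] = run
        d = onset + duration
        level = 0.6
        while d <= horizon and level < plateau:
            anc[d] = level
            level += 0.35
            d += 1
        anc[d:] = plateau
        run_span = (onset, onset + duration - 1)
    else:
        nadir = rng.uniform(0.6, 1.4)
        nadir_day = onset + 2
        for d in range(horizon + 1):
            if d <= nadir_day:
                anc[d] = a0 + (nadir - a0) * d / nadir_day
            elif d <= nadir_day + 6:
                anc[d] = nadir + (plateau - nadir) * (d - nadir_day) / 6
            else:
                anc[d] = plateau
        run_span = None

    # plateau jitter, kept safely above the prolonged/dip threshold
    settled = anc >= plateau - 1e-9
    anc[settled] = np.maximum(anc[settled] * rng.lognormal(0, 0.08, settled.sum()),
                              1.05)

    dip_span = None
    if second_dip and duration < 14:
        rec_done = (onset + duration + 8) if duration > 0 else 12
        dip_start = int(rng.integers(25, 46))
        dip_start = max(dip_start, rec_done + 2, 25)
        dip_len = int(rng.integers(2, 6))
        if dip_start + dip_len <= 95:
            anc[dip_start:dip_start + dip_len] = rng.uniform(0.55, 0.95,
                                                             size=dip_len)
            dip_span = (dip_start, dip_start + dip_len - 1)

    anc = np.round(np.maximum(anc, 0.01), 2)
    if duration >= 14:
        intended = "aplastic"
    elif dip_span is not None:
        intended = "intermittent"
    else:
        intended = "quick"
    return anc, run_span, dip_span, intended


def _sample_days(rng, run_span, dip_span, horizon: int = 100) -> list[int]:
    """Draw days every 1–3 days: daily through day 30 and around the severe
    run and any late dip, every 3 days otherwise."""
    days = set(range(0, 31))
    if run_span is not None:
        days.update(range(max(0, run_span[0] - 1), min(horizon, run_span[1] + 2)))
    if dip_span is not None:
        days.update(range(max(0, dip_span[0] - 1), min(horizon, dip_span[1] + 2)))
    d = 31
    while d <= horizon:
        days.add(d)
        d += int(rng.integers(2, 4))
    days.add(horizon)
    return sorted(dy for dy in days if 0 <= dy <= horizon)


def _piecewise(knots: list[tuple[int, float]], horizon: int = 100) -> np.ndarray:
    xs = np.array([k[0] for k in knots], dtype=float)
    ys = np.array([k[1] for k in knots], dtype=float)
    return np.interp(np.arange(horizon + 1), xs, ys)


def generate_cohort(config: GeneratorConfig, seed: int) -> Cohort:
    """Generate a fully populated cohort; deterministic under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    latent: dict[str, str] = {}
    intended_phenotype: dict[str, str] = {}
    horizon = 100

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        latent_high = rng.random() >= config.target_low_fraction
        medians = config.lab_medians_high if latent_high else config.lab_medians_low
        sigmas = config.lab_sigmas_high if latent_high else config.lab_sigmas_low
        labs = _draw_labs(rng, medians, sigmas)
        sample_day = int(rng.integers(-2, 1))
        baseline = BaselineLabs(
            anc=labs["anc"], anc_day=sample_day,
            hemoglobin=labs["hemoglobin"], hemoglobin_day=sample_day,
            platelets=labs["platelets"], platelets_day=sample_day,
            crp=labs["crp"], crp_day=sample_day,
            ferritin=labs["ferritin"], ferritin_day=sample_day,
        )
        ht = score_components(baseline)
        cls = ht.risk_class
        score = ht.total
        latent[pid] = "high" if latent_high else "low"

        # --- neutrophil trajectory ------------------------------------
        mu = config.duration_intercept + config.duration_slope * score
        r = config.duration_dispersion
        duration = int(rng.negative_binomial(r, r / (r + mu)))
        second_dip = rng.random() < config.second_dip_prob[cls]
        anc_daily, run_span, dip_span, intended = _anc_trajectory(
            rng, config, labs["anc"], duration, second_dip)
        intended_phenotype[pid] = intended
        days = _sample_days(rng, run_span, dip_span, horizon)
        anc_series = LabSeries(tuple(days), tuple(float(anc_daily[d]) for d in days))

        # --- platelets -------------------------------------------------
        p0 = max(labs["platelets"], 20.0)
        sev_plt = rng.random() < config.severe_thrombo_d0_30_prob[cls]
        persist_plt = sev_plt and rng.random() < config.thrombo_persist_prob[cls]
        nadir_day = int(rng.integers(7, 15))
        if sev_plt:
            nadir = rng.uniform(12, 45)
            v30 = rng.uniform(20, 45) if persist_plt else rng.uniform(55, 120)
            v60 = rng.uniform(25, 48) if persist_plt else rng.uniform(80, 170)
            v100 = rng.uniform(40, 90) if persist_plt else rng.uniform(90, 200)
        else:
            nadir = rng.uniform(55, max(65.0, 0.8 * p0))
            v30 = rng.uniform(0.7 * p0, 1.0 * p0)
            v60 = rng.uniform(0.8 * p0, 1.1 * p0)
            v100 = rng.uniform(0.8 * p0, 1.2 * p0)
        plt_daily = _piecewise([(0, p0), (nadir_day, nadir), (30, v30),
                                (60, v60), (100, v100)])
        plt_days = sorted(set(list(range(0, 31, 3)) + [nadir_day]
                              + list(range(33, 101, 7))))
        plt_series = LabSeries(tuple(plt_days),
                               tuple(float(round(plt_daily[d])) for d in plt_days))

        # --- hemoglobin / transfusions --------------------------------
        h0 = min(max(labs["hemoglobin"], 6.5), 16.0)
        sev_an = rng.random() < config.severe_anemia_d0_30_prob[cls]
        persist_an = sev_an and rng.random() < config.anemia_persist_prob[cls]
        hb_nadir_day = int(rng.integers(8, 19))
        if sev_an:
            hb_nadir = rng.uniform(6.4, 7.8)
            hb30 = rng.uniform(6.8, 7.9) if persist_an else rng.uniform(8.3, 9.5)
            hb60 = rng.uniform(7.0, 8.8) if persist_an else rng.uniform(8.8, 10.5)
        else:
            # a baseline already below ~8 cannot avoid the severe flag; keep flat
            hb_nadir = min(max(8.05, h0 - rng.uniform(0.3, 2.5)), h0)
            hb30 = rng.uniform(hb_nadir, max(h0, hb_nadir + 0.05))
            hb60 = rng.uniform(hb_nadir, max(h0, hb_nadir + 0.05) + 0.5)
        hb_daily = _piecewise([(0, h0), (hb_nadir_day, hb_nadir), (30, hb30),
                               (60, hb60), (100, hb60 + 0.3)])
        hb_days = sorted(set(list(range(0, 31, 3)) + [hb_nadir_day]
                             + list(range(33, 101, 7))))
        hb_series = LabSeries(tuple(hb_days),
                              tuple(float(round(hb_daily[d], 1)) for d in hb_days))

        prbc_days: list[int] = []
        if sev_an:
            for k in range(int(rng.integers(1, 4))):
                prbc_days.append(int(np.clip(hb_nadir_day + 2 * k
                                             + int(rng.integers(-1, 2)), 0, 30)))
            if persist_an:
                prbc_days.append(int(rng.integers(40, 75)))
        plt_tx_days: list[int] = []
        if sev_plt and rng.random() < 0.7:
            for k in range(int(rng.integers(1, 3))):
                plt_tx_days.append(int(np.clip(nadir_day + 3 * k, 0, 30)))
            if persist_plt and rng.random() < 0.35:
                plt_tx_days.append(int(rng.integers(35, 70)))
        other_events: list[tuple[int, str]] = []
        if rng.random() < (0.62 if cls == "high" else 0.444):
            other_events.append((int(rng.integers(5, 15)), "gcsf"))
        if rng.random() < (0.14 if cls == "high" else 0.048):
            other_events.append((int(rng.integers(25, 60)), "tpo_agonist"))

        # --- infections -------------------------------------------------
        infections: list[InfectionEvent] = []
        p_any = config.any_infection_prob[cls]
        p_sev = config.severe_infection_prob[cls]
        infected = rng.random() < p_any
        if infected:
            severe_first = rng.random() < p_sev / p_any
            weights = 1.0 + config.neutropenic_onset_weight * (anc_daily[:91] < 0.5)
            weights /= weights.sum()
            onset = int(rng.choice(91, p=weights))
            if severe_first:
                grade = int(rng.choice([3, 4, 5],
                                       p=[.65, .25, .10] if cls == "high"
                                       else [.90, .10, 0.0]))
            else:
                grade = int(rng.choice([1, 2], p=[.45, .55]))
            category = str(rng.choice(
                ["bacterial", "viral", "fungal", "clinical_syndrome"],
                p=[.52, .28, .05, .15]))
            source = str(rng.choice(
                ["bloodstream", "respiratory", "gastrointestinal", "urinary",
                 "skin", "other"], p=[.28, .34, .14, .12, .07, .05]))
            infections.append(InfectionEvent(onset, category, source, grade))
            if rng.random() < config.second_event_prob:
                onset2 = int(rng.choice(91, p=weights))
                # a later mild event never changes the severe flag
                grade2 = int(rng.choice([1, 2], p=[.5, .5]))
                category2 = str(rng.choice(
                    ["bacterial", "viral", "fungal", "clinical_syndrome"],
                    p=[.45, .35, .05, .15]))
                infections.append(InfectionEvent(
                    onset2, category2, "other", grade2))
        infections.sort(key=lambda e: (e.onset_day, e.category, e.grade))

        # --- survival ---------------------------------------------------
        lam_nrm = -np.log(1 - config.nrm_1yr[cls]) / 12.0
        lam_pfs = np.log(2) / config.pfs_median[cls]
        lam_prog = max(lam_pfs - lam_nrm, 1e-6)
        t_nrm = rng.exponential(1 / lam_nrm)
        t_prog = rng.exponential(1 / lam_prog)
        fu = config.followup_months
        m_pp = max(config.os_median[cls] - config.pfs_median[cls], 1.0)
        if min(t_nrm, t_prog) >= fu:
            outcome = OutcomeRecord(pfs_time=round(fu, 2), pfs_event=0,
                                    os_time=round(fu, 2), os_event=0,
                                    death_cause="none",
                                    response=_draw_response(rng, config, cls))
        elif t_nrm < t_prog:
            t = round(t_nrm, 2)
            cp = config.nrm_cause_probs
            cause = str(rng.choice(list(cp.keys()), p=list(cp.values())))
            outcome = OutcomeRecord(pfs_time=t, pfs_event=1, os_time=t,
                                    os_event=1, death_cause=cause,
                                    response=_draw_response(rng, config, cls))
        else:
            t_p = round(t_prog, 2)
            t_death = t_prog + rng.exponential(m_pp / np.log(2))
            if t_death < fu:
                outcome = OutcomeRecord(pfs_time=t_p, pfs_event=1,
                                        os_time=round(t_death, 2), os_event=1,
                                        death_cause="progression",
                                        response=_draw_response(rng, config, cls))
            else:
                outcome = OutcomeRecord(pfs_time=t_p, pfs_event=1,
                                        os_time=round(fu, 2), os_event=0,
                                        death_cause="none",
                                        response=_draw_response(rng, config, cls))

        # --- covariates -------------------------------------------------
        ge60 = rng.random() < config.egfr_ge60_prob[cls]
        egfr = float(round(rng.uniform(61, 120) if ge60 else rng.uniform(20, 59), 1))
        if rng.random() < config.ecog_ge2_prob[cls]:
            ecog = int(rng.choice([2, 3], p=[.85, .15]))
        else:
            ecog = int(rng.choice([0, 1], p=[.5, .5]))
        if rng.random() < config.bm_gt50_prob[cls]:
            bm = float(round(rng.uniform(51, 95), 1))
        else:
            bm = float(round(min(np.exp(rng.normal(np.log(4), 1.0)), 50.0), 1))
        crs = int(rng.choice([0, 1, 2, 3, 4], p=[.2, .35, .3, .12, .03])
                  if cls == "high"
                  else rng.choice([0, 1, 2, 3], p=[.35, .4, .2, .05]))
        icans = int(rng.choice([0, 1, 2, 3, 4], p=[.45, .2, .19, .12, .04])
                    if cls == "high"
                    else rng.choice([0, 1, 2], p=[.7, .2, .1]))
        cov = Covariates(
            egfr=egfr,
            ldh_above_uln=bool(rng.random() < config.ldh_above_uln_prob[cls]),
            ecog=ecog,
            bm_plasma_cell_pct=bm,
            prior_bcma_therapy=bool(rng.random() < config.prior_bcma_prob[cls]),
            crs_max_grade=crs,
            icans_max_grade=icans,
            hospital_days=int(10 + min(duration, 60) + rng.poisson(3)),
        )

        records.append(PatientRecord(
            patient_id=pid,
            ld_start_day=-5,
            baseline=baseline,
            anc_series=anc_series,
            platelet_series=plt_series,
            hemoglobin_series=hb_series,
            platelet_transfusion_days=tuple(sorted(set(plt_tx_days))),
            prbc_transfusion_days=tuple(sorted(set(prbc_days))),
            other_events=tuple(sorted(other_events)),
            infections=tuple(infections),
            outcome=outcome,
            covariates=cov,
        ))

    return Cohort(records=records,
                  meta={"latent_stratum": latent,
                        "intended_phenotype": intended_phenotype})


def _draw_response(rng, config: GeneratorConfig, cls: str) -> str:
    if rng.random() < config.vgpr_or_better_prob[cls]:
        return str(rng.choice(["sCR", "CR", "VGPR"], p=[.35, .3, .35]))
    return str(rng.choice(["PR", "SD", "PD"], p=[.45, .15, .40]))


def calibration_report(cohort: Cohort,
                       config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Group-wise summary of a generated cohort against its targets.

    Rows: lab medians, median severe-neutropenia days, severe-infection
    rates, KM median PFS/OS, plus report-only discrimination metrics (AUC
    for the >= 14-day endpoint, regression slope of duration on score) and
    the latent-vs-computed crossover rate.
    """
    from .infections import summarize_infections
    from .score import score_cohort
    from .stats import km_fit, roc, spearman
    from .trajectories import severe_neutropenia_days

    config = config or GeneratorConfig()
    scores = score_cohort(cohort)
    cls_by_id = dict(zip(scores.table.patient_id, scores.table.risk_class))
    score_by_id = dict(zip(scores.table.patient_id, scores.table.total))
    inf = summarize_infections(cohort.records)
    sev_by_id = dict(zip(inf.per_patient.patient_id, inf.per_patient.severe_d0_90))

    rows = []
    durations, totals = [], []
    by_cls = {"low": [], "high": []}
    for r in cohort:
        c = cls_by_id.get(r.patient_id)
        if c is None:
            continue
        by_cls[c].append(r)
        durations.append(severe_neutropenia_days(r))
        totals.append(score_by_id[r.patient_id])

    targets = {
        ("low", "anc"): config.lab_medians_low["anc"],
        ("high", "anc"): config.lab_medians_high["anc"],
        ("low", "ferritin"): config.lab_medians_low["ferritin"],
        ("high", "ferritin"): config.lab_medians_high["ferritin"],
        ("low", "platelets"): config.lab_medians_low["platelets"],
        ("high", "platelets"): config.lab_medians_high["platelets"],
        ("low", "hemoglobin"): config.lab_medians_low["hemoglobin"],
        ("high", "hemoglobin"): config.lab_medians_high["hemoglobin"],
        ("low", "crp"): config.lab_medians_low["crp"],
        ("high", "crp"): config.lab_medians_high["crp"],
    }
    for (cls, analyte), target in targets.items():
        vals = [r.baseline.value(analyte) for r in by_cls[cls]]
        obs = float(np.median(vals)) if vals else np.nan
        rows.append({"group": cls, "metric": f"median_{analyte}",
                     "observed": obs, "target": target})
    for cls in ("low", "high"):
        ds = [severe_neutropenia_days(r) for r in by_cls[cls]]
        rows.append({"group": cls, "metric": "median_severe_neutropenia_days",
                     "observed": float(np.median(ds)) if ds else np.nan,
                     "target": 3.0 if cls == "low" else 9.0})
        sev = [bool(sev_by_id[r.patient_id]) for r in by_cls[cls]]
        rows.append({"group": cls, "metric": "severe_infection_rate",
                     "observed": float(np.mean(sev)) if sev else np.nan,
                     "target": config.severe_infection_prob[cls]})
        pfs = km_fit([r.outcome.pfs_time for r in by_cls[cls]],
                     [r.outcome.pfs_event for r in by_cls[cls]])
        os_ = km_fit([r.outcome.os_time for r in by_cls[cls]],
                     [r.outcome.os_event for r in by_cls[cls]])
        rows.append({"group": cls, "metric": "km_median_pfs_months",
                     "observed": pfs.median, "target": config.pfs_median[cls]})
        rows.append({"group": cls, "metric": "km_median_os_months",
                     "observed": os_.median, "target": config.os_median[cls]})

    n_low = len(by_cls["low"])
    rows.append({"group": "all", "metric": "fraction_low",
                 "observed": n_low / max(len(cohort), 1),
                 "target": config.target_low_fraction})
    latent = cohort.meta.get("latent_stratum")
    if latent:
        crossed = [pid for pid, c in cls_by_id.items() if latent.get(pid) != c]
        rows.append({"group": "all", "metric": "latent_crossover_rate",
                     "observed": len(crossed) / max(len(cls_by_id), 1),
                     "target": np.nan})
    if len(set(np.asarray(durations) >= 14)) == 2:
        rows.append({"group": "all", "metric": "auc_severe_ge14d",
                     "observed": roc(totals, np.asarray(durations) >= 14).auc,
                     "target": np.nan})
    if len(durations) >= 3 and np.ptp(totals) > 0:
        _, _, slope = spearman(totals, durations)
        rows.append({"group": "all", "metric": "slope_days_per_point",
                     "observed": slope, "target": config.duration_slope})
    df = pd.DataFrame(rows)
    df["relative_deviation"] = (df["observed"] - df["target"]) / df["target"]
    return df


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
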