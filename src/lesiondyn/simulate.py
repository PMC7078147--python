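"""Synthetic multi-lesion mCRC-like trial generator.

Emulates the structure of a metastatic colorectal cancer trial with
lesion-level tumor-size follow-up: each patient carries 1-10 target
lesions spread over up to five lesions per organ class, assessed at
baseline and on a periodic visit schedule.  Every lesion follows a
biexponential shrink-regrow trajectory

    TS(t) = B * (exp(-k_s * t) + exp(k_g * t) - 1)

with class-shared rate parameters.  Each organ class follows one of three
dynamic types: *response* (shrink-dominant rates), *divergent*
progression (growth-dominant, probability ``p_div``) or *stable* disease
(flat latent trajectory, probability ``p_stable``), mirroring the three
response patterns seen in solid-tumor trials; observed stable lesions
fluctuate around their baseline size through measurement noise alone, so
their pairwise CCs scatter around zero ("undefined relation").  With
probability ``lag_prob`` a class responds with a delay of a whole number
of visits.
KRAS-mutated patients respond less (attenuated shrink rate).  Observed
sizes add lesion-level lognormal measurement noise and are rounded to
whole millimetres (SLD) or to products of rounded diameters (SOPD).

Overall survival is drawn from an exponential hazard multiplied by
exp(sum beta_j x_j) where the heterogeneity covariate is the TRUE
noise-free between-class concordance (median zero-shift CC of the latent
class trajectories), alongside early tumor shrinkage, baseline tumor
size, ECOG and KRAS.  Censoring combines an independent exponential
dropout process and administrative cut-off.

Every latent quantity is written to a truth log so pipeline-level
parameter-recovery tests can compare estimate against truth.  A single
global seed drives per-patient substreams, so patient i's data are
unchanged when only ``n_patients`` changes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .crosscorr import cc_at_lag
from .trial_data import LesionRecord, LesionSeries, PatientCovariates

ORGAN_TEXTS: Mapping[str, tuple[str, ...]] = {
    "liver": ("LIVER RIGHT LOBE", "LIVER LEFT LOBE",
              "HEPATIC LESION SEGMENT IV", "LIVER"),
    "lung": ("RIGHT LOWER LOBE LUNG", "LUNG LEFT UPPER LOBE",
             "PULMONARY NODULE", "LUNG"),
    "lymph_node": ("PARA-AORTIC LYMPH NODE", "MESENTERIC LYMPH NODES",
                   "RETROPERITONEAL ADENOPATHY", "CERVICAL LYMPH NODE"),
    "other_digestive": ("PERITONEUM", "SPLEEN", "OMENTUM", "GASTRIC WALL"),
    "other_specified": ("ADRENAL GLAND", "KIDNEY LEFT", "OVARY",
                        "ABDOMINAL WALL"),
    "primary": ("SIGMOID COLON", "RECTUM", "ASCENDING COLON"),
}

MAX_LESIONS_PER_ORGAN = 5
MAX_LESIONS_PER_PATIENT = 10


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic trial.

    Defaults emulate an mCRC cetuximab trial: q8w assessments to week 48,
    liver-dominant organ involvement with ~38% of patients carrying
    lesions in more than one class, 8% measurement CV, 40% KRAS-mutation
    prevalence with halved shrink rate, and a survival hazard ratio of
    0.74 per unit of between-class concordance.
    """

    n_patients: int = 500
    seed: int = 0
    metric: str = "SLD"

    # assessment schedule: baseline + every `visit_interval` weeks to `horizon`
    visit_interval: float = 8.0
    horizon: float = 48.0
    dropout_prob: float = 0.05      # per post-baseline visit, whole assessment missed

    # organ involvement
    organ_weights: tuple[tuple[str, float], ...] = (
        ("liver", 0.52), ("lung", 0.16), ("lymph_node", 0.17), ("other", 0.15))
    n_organ_probs: tuple[float, ...] = (0.62, 0.28, 0.10)  # P(1, 2, 3 organs)
    p_primary: float = 0.15          # extra primary-site lesion
    mean_extra_lesions: float = 0.8  # Poisson mean for lesions beyond 1 per organ
    p_missing_organ_text: float = 0.02

    # lesion trajectories (rates in 1/week)
    baseline_size_median: float = 30.0
    baseline_size_sigma: float = 0.5
    min_baseline_size: float = 10.0
    k_s: float = 0.04                # shrink rate, responding class
    k_g: float = 0.005               # regrowth rate, responding class
    k_s_div: float = 0.005           # shrink rate, divergent (progressing) class
    k_g_div: float = 0.025           # growth rate, divergent class
    patient_rate_sigma: float = 0.2  # lognormal sd of per-patient rate multiplier
    noise_sd: float = 0.08           # lognormal sd of per-measurement noise

    # heterogeneity controls
    p_div: float = 0.25              # P(class follows divergent dynamics)
    p_stable: float = 0.10           # P(class is stable: flat latent trajectory)
    lag_prob: float = 0.10           # P(class responds with a visit delay)
    lag_magnitude: int = 1           # delay, in visits

    # covariates
    p_kras_mut: float = 0.40
    kras_ks_factor: float = 0.5      # shrink-rate multiplier in KRASmut patients
    p_ecog_not_active: float = 0.30
    p_cetuximab: float = 0.5
    p_surgery: float = 0.03

    # survival model (exponential baseline hazard, centered covariates)
    base_hazard: float = 0.008       # per week
    beta_cc: float = math.log(0.74)  # per unit of true median concordance
    beta_ets: float = math.log(0.5)  # per unit of true early shrinkage
    beta_ecog: float = math.log(1.6)
    beta_ts0: float = 0.003          # per mm of true baseline total size
    beta_kras: float = 0.0
    cc_ref: float = 0.8              # centering constants (reference patient)
    ets_ref: float = 0.3
    ts0_ref: float = 60.0
    censor_rate: float = 0.002       # per week, independent dropout
    os_admin_censor: float = 160.0   # weeks

    def validate(self) -> None:
        probs = {
            "dropout_prob": self.dropout_prob, "p_primary": self.p_primary,
            "p_missing_organ_text": self.p_missing_organ_text,
            "p_div": self.p_div, "p_stable": self.p_stable,
            "lag_prob": self.lag_prob,
            "p_kras_mut": self.p_kras_mut,
            "p_ecog_not_active": self.p_ecog_not_active,
            "p_cetuximab": self.p_cetuximab, "p_surgery": self.p_surgery,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must be in [0, 1]")
        rates = {"k_s": self.k_s, "k_g": self.k_g, "k_s_div": self.k_s_div,
                 "k_g_div": self.k_g_div, "base_hazard": self.base_hazard,
                 "censor_rate": self.censor_rate, "noise_sd": self.noise_sd}
        for name, r in rates.items():
            if r < 0:
                raise ValueError(f"{name}={r} must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.visit_interval <= 0 or self.horizon < self.visit_interval:
            raise ValueError("need horizon >= visit_interval > 0")
        if self.metric not in ("SLD", "SOPD"):
            raise ValueError(f"metric must be SLD or SOPD, got {self.metric!r}")
        if abs(sum(w for _, w in self.organ_weights) - 1.0) > 1e-9:
            raise ValueError("organ_weights must sum to 1")
        if abs(sum(self.n_organ_probs) - 1.0) > 1e-9:
            raise ValueError("n_organ_probs must sum to 1")
        if self.lag_magnitude < 0:
            raise ValueError("lag_magnitude must be >= 0")
        if self.p_div + self.p_stable > 1.0:
            raise ValueError("p_div + p_stable must not exceed 1")

    @property
    def schedule(self) -> np.ndarray:
        return np.arange(0.0, self.horizon + 1e-9, self.visit_interval)


def _trajectory(t: np.ndarray, k_s: float, k_g: float, delay: float) -> np.ndarray:
    te = np.maximum(t - delay, 0.0)
    return np.exp(-k_s * te) + np.exp(k_g * te) - 1.0


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


def simulate_trial(config: SimConfig,
                   ) -> tuple[list[LesionRecord], list[PatientCovariates], dict]:
    """Generate one synthetic trial.

    Returns ``(lesion records, patient covariates, truth log)``.  The truth
    log maps patient id to its latent state (classes, divergence flags,
    delays, true concordance and shrinkage, linear predictor) plus a
    ``config`` echo; see :func:`divergent_pair_fraction` for the realized
    discordant-pair share.
    """
    config.validate()
    schedule = config.schedule
    organ_names = [name for name, _ in config.organ_weights]
    organ_probs = np.array([w for _, w in config.organ_weights])

    records: list[LesionRecord] = []
    covariates: list[PatientCovariates] = []
    truth: dict = {"config": dataclasses.asdict(config), "patients": {}}

    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i)
        pid = f"P{i:05d}"

        kras = "mut" if rng.random() < config.p_kras_mut else "wt"
        ecog = ("not_fully_active" if rng.random() < config.p_ecog_not_active
                else "fully_active")
        arm = "cetuximab" if rng.random() < config.p_cetuximab else "control"
        surgery_time = None
        if rng.random() < config.p_surgery:
            surgery_time = float(rng.uniform(config.visit_interval, config.horizon))

        # organ classes: distinct metastatic organs + optional primary site
        n_organs = int(rng.choice(len(config.n_organ_probs),
                                  p=np.asarray(config.n_organ_probs)) + 1)
        organs = list(rng.choice(organ_names, size=min(n_organs, len(organ_names)),
                                 replace=False, p=organ_probs))
        classes = []
        for organ in organs:
            if organ == "other":
                organ = str(rng.choice(["other_digestive", "other_specified"]))
            classes.append(organ)
        if rng.random() < config.p_primary:
            classes.append("primary")

        m = float(rng.lognormal(0.0, config.patient_rate_sigma))
        kf = config.kras_ks_factor if kras == "mut" else 1.0

        dyn_type = {}
        for c in classes:
            u = rng.random()
            if u < config.p_div:
                dyn_type[c] = "divergent"
            elif u < config.p_div + config.p_stable:
                dyn_type[c] = "stable"
            else:
                dyn_type[c] = "response"
        lagged = {c: (config.lag_magnitude if rng.random() < config.lag_prob else 0)
                  for c in classes}

        # patient visit schedule: baseline always kept
        kept = [0.0] + [float(t) for t in schedule[1:]
                        if rng.random() >= config.dropout_prob]
        visits = np.array(kept)

        lesion_idx = 0
        n_total = 0
        class_true: dict[str, np.ndarray] = {}
        for cls in classes:
            if dyn_type[cls] == "divergent":
                ks, kg = config.k_s_div * m, config.k_g_div * m
            elif dyn_type[cls] == "stable":
                ks, kg = 0.0, 0.0
            else:
                ks, kg = config.k_s * m * kf, config.k_g * m
            delay = lagged[cls] * config.visit_interval
            shape = _trajectory(schedule, ks, kg, delay)
            shape_obs = _trajectory(visits, ks, kg, delay)

            budget = MAX_LESIONS_PER_PATIENT - n_total
            if budget <= 0:
                continue  # lesion cap reached: class carries no lesions
            n_lesions = min(1 + int(rng.poisson(config.mean_extra_lesions)),
                            MAX_LESIONS_PER_ORGAN, budget)
            n_total += n_lesions

            texts = ORGAN_TEXTS[cls]
            cls_sum = np.zeros_like(shape)
            for _ in range(n_lesions):
                lesion_idx += 1
                lid = f"L{lesion_idx}"
                B = max(float(rng.lognormal(np.log(config.baseline_size_median),
                                            config.baseline_size_sigma)),
                        config.min_baseline_size)
                cls_sum += B * shape
                organ_text = str(texts[int(rng.integers(len(texts)))])
                if cls != "primary" and rng.random() < config.p_missing_organ_text:
                    organ_text = ""
                lesion_type = "primary" if cls == "primary" else (
                    "node" if cls == "lymph_node" else "metastatic")
                noise = np.exp(config.noise_sd * rng.standard_normal(visits.size))
                diam = B * shape_obs * noise
                if config.metric == "SLD":
                    sizes = np.round(diam)
                else:
                    sizes = np.round(diam) ** 2
                for t, s in zip(visits, sizes):
                    records.append(LesionRecord(pid, lid, organ_text, lesion_type,
                                                float(t), float(max(s, 0.0)),
                                                config.metric))
            class_true[cls] = cls_sum

        # true (noise-free) concordance between class trajectories
        cls_names = sorted(class_true)
        # flat (stable) classes have no latent dynamics; their true
        # concordance with anything is 0 ("no relation"), not undefined
        pair_cc = {}
        for a in range(len(cls_names)):
            for b in range(a + 1, len(cls_names)):
                ca, cb = cls_names[a], cls_names[b]
                v = cc_at_lag(class_true[ca], class_true[cb], 0)
                pair_cc[f"{ca}|{cb}"] = v if np.isfinite(v) else 0.0
        true_median_cc = (float(np.median(list(pair_cc.values())))
                          if pair_cc else None)
        cc_cov = true_median_cc if true_median_cc is not None else 1.0

        total_true = np.zeros(schedule.size)
        for c in cls_names:
            total_true += class_true[c]
        ts0_true = float(total_true[0])
        ts8_true = float(total_true[1]) if schedule.size > 1 else ts0_true
        ets_true = (ts0_true - ts8_true) / ts0_true if ts0_true > 0 else 0.0

        lp = (config.beta_cc * (cc_cov - config.cc_ref)
              + config.beta_ets * (ets_true - config.ets_ref)
              + config.beta_ecog * (1.0 if ecog == "not_fully_active" else 0.0)
              + config.beta_ts0 * (ts0_true - config.ts0_ref)
              + config.beta_kras * (1.0 if kras == "mut" else 0.0))
        hazard = config.base_hazard * math.exp(lp)
        t_death = float(rng.exponential(1.0 / hazard))
        t_cens = config.os_admin_censor
        if config.censor_rate > 0:
            t_cens = min(t_cens, float(rng.exponential(1.0 / config.censor_rate)))
        os_time = max(min(t_death, t_cens), 1e-3)
        os_event = int(t_death <= t_cens)

        covariates.append(PatientCovariates(pid, arm, kras, ecog,
                                            os_time, os_event, surgery_time))
        truth["patients"][pid] = {
            "classes": cls_names,
            "dynamic_type": {c: dyn_type[c] for c in cls_names},
            "divergent": {c: dyn_type[c] == "divergent" for c in cls_names},
            "lag_visits": {c: lagged[c] for c in cls_names},
            "pair_cc_true": pair_cc,
            "true_median_cc": true_median_cc,
            "cc_covariate": cc_cov,
            "ts0_true": ts0_true,
            "ets_true": ets_true,
            "linear_predictor": lp,
            "arm": arm,
            "kras": kras,
        }
    return records, covariates, truth


def divergent_pair_fraction(truth: dict, arm: str | None = None) -> float:
    """Realized share of inter-class pairs with truly opposite dynamics.

    A pair counts as divergent when one class responds (shrinks) and the
    other progresses (grows).  Pairs involving a stable class have no
    opposite dynamics (their true relation is "undefined"), and two
    divergent classes grow concordantly, so neither counts.
    """
    discordant = 0
    total = 0
    for info in truth["patients"].values():
        if arm is not None and info["arm"] != arm:
            continue
        classes = info["classes"]
        types = info["dynamic_type"]
        for a in range(len(classes)):
            for b in range(a + 1, len(classes)):
                total += 1
                if {types[classes[a]], types[classes[b]]} == {"response",
                                                              "divergent"}:
                    discordant += 1
    if total == 0:
        raise ValueError("truth log has no inter-class pairs")
    return discordant / total


# ---------------------------------------------------------------------------
# canned fixtures

FIXTURES = ("two_lesion_mirror", "delayed_lung", "three_mode_cc")


def make_fixture(name: str):
    """Deterministic tiny datasets with hand-verifiable structure.

    - ``two_lesion_mirror``: one patient, two liver lesions with
      y = 40 - x, so their zero-shift CC is exactly -1.
      Returns (records, covariates).
    - ``delayed_lung``: one patient whose lung lesion repeats the liver
      lesion one visit later, so the maximum CC is 1 at |lag| = 1 while
      the zero-shift CC is below 1.  Returns (records, covariates).
    - ``three_mode_cc``: a seeded sample of 900 CC-like values with modes
      near -0.9 / 0.15 / 0.9 (sd 0.05, 300 per mode), for which the elbow
      method selects k = 3.  Returns a 1-D numpy array.
    """
    if name == "two_lesion_mirror":
        times = [0.0, 8.0, 16.0, 24.0]
        x = [30.0, 25.0, 20.0, 15.0]
        y = [40.0 - v for v in x]
        records = [LesionRecord("P1", "L1", "LIVER", "metastatic", t, v, "SLD")
                   for t, v in zip(times, x)]
        records += [LesionRecord("P1", "L2", "LIVER", "metastatic", t, v, "SLD")
                    for t, v in zip(times, y)]
        covariates = [PatientCovariates("P1", "cetuximab", "wt", "fully_active",
                                        100.0, 1)]
        return records, covariates
    if name == "delayed_lung":
        times = [0.0, 8.0, 16.0, 24.0, 32.0, 40.0]
        liver = [40.0, 30.0, 22.0, 16.0, 12.0, 10.0]
        lung = [liver[0]] + liver[:-1]   # responds one visit later
        records = [LesionRecord("P1", "L1", "LIVER", "metastatic", t, v, "SLD")
                   for t, v in zip(times, liver)]
        records += [LesionRecord("P1", "L2", "LUNG", "metastatic", t, v, "SLD")
                    for t, v in zip(times, lung)]
        covariates = [PatientCovariates("P1", "cetuximab", "wt", "fully_active",
                                        100.0, 1)]
        return records, covariates
    if name == "three_mode_cc":
        rng = np.random.default_rng(20240613)
        modes = np.repeat([-0.9, 0.15, 0.9], 300)
        values = modes + 0.05 * rng.standard_normal(modes.size)
        return np.clip(values, -1.0, 1.0)
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")


def fixture_series(name: str) -> dict[str, dict[str, LesionSeries]]:
    """Convenience: a dataset fixture assembled into per-lesion series."""
    from .trial_data import build_series
    records, _ = make_fixture(name)
    return build_series(records)
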