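"""Seeded synthetic limb-level cohorts with ground-truth treatment effects.

The generator emulates the statistical structure a limb-level observational
gait study presents to a causal analysis:

* limbs nested in individuals, tied together by a per-subject standard
  normal *severity* latent (more severe -> worse exam measures, higher
  GMFCS, more prior/interval treatment);
* mixed covariate types — continuous exam measures, ordinal clinical
  scores, categorical classifications — all loading on severity;
* treatment assignment pi(x) = expit(f(x) + lambda * tau1_std(x)) whose
  linear predictor f(x) tracks severity (prognosis-based confounding) and,
  when ``targeted_selection_strength`` (lambda) > 0, also the standardized
  expected benefit tau1(x) — *targeted selection*;
* heterogeneous treatment effects tau_k(x) that attenuate along a
  four-level causal chain (body structures -> specific kinematic ->
  overall kinematic -> functional mobility);
* a 23-item mobility questionnaire whose difficulty-weighted average is
  the functional-mobility score, plus structured missingness (categorical
  gaps, item non-response, optionally severity-dependent).

Effect heterogeneity is driven by centered age, which is independent of the
severity latent, so that at lambda = 0 the propensity is uncorrelated with
the effect while confounding through severity remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from scipy.special import expit, logit

LEVELS = (
    "body_structures",
    "specific_kinematic",
    "overall_kinematic",
    "functional_mobility",
)

#: default 13 treatment names (broad orthopedic/neurological categories)
TREATMENTS = (
    "selective_dorsal_rhizotomy",
    "neurotoxin_injection",
    "rectus_transfer",
    "femoral_derotation_osteotomy",
    "tibial_derotation_osteotomy",
    "psoas_release",
    "adductor_release",
    "hamstrings_lengthening",
    "calf_muscle_lengthening",
    "distal_femoral_extension_osteotomy",
    "patellar_advancement",
    "foot_ankle_bone",
    "foot_ankle_soft_tissue",
)

N_FAQ_ITEMS = 23

#: fixed difficulty weights of the 23 mobility items (a free parameter of
#: the emulation; harder skills weigh more)
DEFAULT_FAQ_WEIGHTS = np.round(np.linspace(0.6, 3.0, N_FAQ_ITEMS), 3)

CONTINUOUS_COVARIATES = [
    # (name, mean, residual sd, severity loading)
    ("ank_dors_0", 5.0, 7.0, -4.0),
    ("pop_ang_uni", 40.0, 10.0, 6.0),
    ("anteversion", 30.0, 9.0, 4.0),
    ("bimal_angle", 15.0, 7.0, 3.0),
    ("speed_dimless", 0.38, 0.07, -0.05),
]

ORDINAL_COVARIATES = [
    # (name, n_levels, severity loading); generated by thresholding a
    # latent Gaussian so the score rises (or falls) with severity
    ("spas_pf", 5, 1.2),       # modified Ashworth 0-4
    ("strength_pf", 6, -1.0),  # manual muscle test 0-5
]

MOTOR_CONTROL_LEVELS = ("absent", "diminished", "typical")


@dataclass
class EffectProfile:
    """Per-level mean effects and their heterogeneity.

    tau_k(x) = deltas[k] * (1 + het_gamma * age_std)          (default)
    tau_k(x) = deltas[k] + atten_k * heterogeneity(cohort)    (callable given)

    where atten_k = deltas[k]/deltas[0] (1 when deltas[0] == 0).  A
    monotone-decreasing ``deltas`` encodes attenuation along the causal
    chain.
    """

    deltas: tuple = (0.45, 0.22, 0.10, 0.02)
    het_gamma: float = 0.3
    heterogeneity: Callable | None = None

    def __post_init__(self):
        if len(self.deltas) != len(LEVELS):
            raise ValueError(f"delta profile must have length {len(LEVELS)}")


@dataclass
class SyntheticConfig:
    n_subjects: int = 400
    limbs_per_subject: int = 2
    within_subject_corr: float = 0.5
    n_treatments: int = 13
    targeted_selection_strength: float = 1.0  # lambda
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    noise_sd: tuple = (1.0, 1.0, 1.0, 0.6)
    treated_fraction: float = 0.30       # index treatment prevalence target
    co_treatment_rates: tuple | None = None  # defaults to 0.05..0.2 ramp
    confounding_strength: float = 1.2    # severity coefficient in f(x)
    drift_severity_slope: float = -0.35  # natural-history change per severity unit
    missingness_rates: dict = field(default_factory=lambda: {
        "gmfcs": 0.20,
        "ank_dors_0": 0.05,
        "motor_control": 0.03,
        "spas_pf": 0.02,
        "strength_pf": 0.02,
        "faq_items": 0.04,
    })
    severity_dependent_missingness: bool = True
    followup_years_range: tuple = (0.9, 2.5)
    faq_weights: np.ndarray = field(default_factory=lambda: DEFAULT_FAQ_WEIGHTS.copy())
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not (0.0 <= self.within_subject_corr < 1.0):
            raise ValueError("within_subject_corr must be in [0, 1)")
        for r in self.missingness_rates.values():
            if not (0.0 <= r <= 1.0):
                raise ValueError("missingness rates must be in [0, 1]")
        if any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be > 0")
        if self.n_treatments < 1 or self.n_treatments > len(TREATMENTS):
            raise ValueError(f"n_treatments must be in 1..{len(TREATMENTS)}")

    @property
    def treatments(self) -> tuple:
        return TREATMENTS[: self.n_treatments]


@dataclass
class SyntheticTruth:
    """Ground truth: per-treatment, per-level individual effects and ATT."""

    tau: dict            # {treatment: {level: ndarray over limbs}}
    treated: dict        # {treatment: boolean ndarray}
    change_sd: dict      # {level: realized SD of outcome change, all limbs}
    config_echo: dict
    pi: dict = None      # {treatment: assignment probability per limb}

    def att(self, treatment: str, level: str) -> float:
        """Realized true ATT = mean individual effect over treated limbs."""
        mask = self.treated[treatment]
        if mask.sum() == 0:
            return float("nan")
        return float(np.mean(self.tau[treatment][level][mask]))

    def att_d(self, treatment: str, level: str) -> float:
        """True ATT in Cohen's-d units (standardized by change SD)."""
        return self.att(treatment, level) / self.change_sd[level]

    def to_json(self, path) -> None:
        payload = {
            "att": {t: {lv: self.att(t, lv) for lv in LEVELS} for t in self.tau},
            "att_d": {t: {lv: self.att_d(t, lv) for lv in LEVELS} for t in self.tau},
            "change_sd": self.change_sd,
            "tau": {t: {lv: v.tolist() for lv, v in d.items()}
                    for t, d in self.tau.items()},
            "treated": {t: v.astype(int).tolist() for t, v in self.treated.items()},
            "config": self.config_echo,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _prevalence_offset(raw, target, tol=1e-10):
    """Intercept c with mean(expit(raw + c)) = target, by bisection."""
    lo, hi = logit(target) - raw.max() - 1, logit(target) - raw.min() + 1
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(raw + mid).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def null_change_sd(config: SyntheticConfig) -> dict:
    """Per-level SD of the outcome change under the same design with all
    treatment effects zeroed.

    Lets effect sizes be stated in change-SD units: pass
    ``deltas = d_target * null_change_sd(cfg)[level]``.
    """
    from dataclasses import replace
    cfg0 = replace(config, effect_profile=EffectProfile(
        deltas=(0.0,) * len(LEVELS), het_gamma=0.0))
    _, truth0 = generate_cohort(cfg0)
    return dict(truth0.change_sd)


def _ordinal_from_latent(latent, n_levels, rng):
    """Threshold latent + N(0,1) noise at equally spaced normal quantiles."""
    from scipy.stats import norm
    z = (latent + rng.standard_normal(latent.shape)) / np.sqrt(1 + np.var(latent))
    cuts = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.digitize(z, cuts)


def generate_cohort(config: SyntheticConfig):
    """Generate a limb-level cohort and its ground truth.

    Returns (cohort, truth).  The cohort is complete; apply
    :func:`inject_missingness` to blank entries per the configured rates.
    """
    rng = np.random.RandomState(config.seed)
    ns = config.n_subjects
    lps = config.limbs_per_subject
    n = ns * lps
    rho = config.within_subject_corr

    # --- subject/limb latents ---
    sev_subj = rng.standard_normal(ns)
    sev_limb = (np.sqrt(rho) * np.repeat(sev_subj, lps)
                + np.sqrt(1 - rho) * rng.standard_normal(n))

    subject_id = np.repeat(np.arange(ns), lps)
    limb_id = np.arange(n)
    side = np.tile(["L", "R"], n)[:n] if lps == 2 else np.array(
        [f"limb{j}" for j in range(lps)] * ns)

    # --- subject-level covariates ---
    age_subj = np.clip(9.4 + 3.7 * rng.standard_normal(ns), 3.0, 24.0)
    age = np.repeat(age_subj, lps)
    sex = np.repeat(np.where(rng.rand(ns) < 0.58, "M", "F"), lps)
    gmfcs_code = _ordinal_from_latent(sev_subj * 1.5, 4, rng)  # per subject
    gmfcs = np.repeat(np.array(["I", "II", "III", "IV"])[gmfcs_code], lps)
    topo_logits = np.column_stack([
        -1.0 - 0.8 * sev_subj, 1.2 - 0.1 * sev_subj,
        -0.5 + 0.5 * sev_subj, -1.2 + 0.8 * sev_subj])
    topo_p = np.exp(topo_logits)
    topo_p /= topo_p.sum(axis=1, keepdims=True)
    topo_names = np.array(["hemiplegia", "diplegia", "triplegia", "quadriplegia"])
    topo_subj = np.array([topo_names[rng.choice(4, p=p)] for p in topo_p])
    topography = np.repeat(topo_subj, lps)

    df = pd.DataFrame({
        "subject_id": subject_id,
        "limb_id": limb_id,
        "side": side,
        "age": age,
        "sex": sex,
        "gmfcs": gmfcs,
        "topography": topography,
    })

    # --- limb-level exam covariates ---
    for name, mean, sd, load in CONTINUOUS_COVARIATES:
        df[name] = mean + load * sev_limb + sd * rng.standard_normal(n)
    for name, n_levels, load in ORDINAL_COVARIATES:
        df[name] = _ordinal_from_latent(load * sev_limb, n_levels, rng).astype(str)
    mc_code = _ordinal_from_latent(-1.0 * sev_limb, 3, rng)
    df["motor_control"] = np.array(MOTOR_CONTROL_LEVELS)[mc_code]
    df["kvv_rom"] = np.abs(6.0 + 3.0 * rng.standard_normal(n))
    lo, hi = config.followup_years_range
    df["follow_up_years"] = rng.uniform(lo, hi, n)

    treatments = config.treatments
    k = len(treatments)

    # --- prior treatment flags (shift baselines; covariate-dependent) ---
    base_rates = np.linspace(0.05, 0.20, k)
    for j, t in enumerate(treatments):
        p = expit(logit(base_rates[j]) + 0.5 * sev_limb)
        df[f"prior_{t}"] = (rng.rand(n) < p).astype(int)

    # --- individual treatment effects tau_k(x) ---
    profile = config.effect_profile
    age_std = (age - age.mean()) / age.std() if age.std() > 0 else np.zeros(n)
    deltas = np.asarray(profile.deltas, dtype=float)
    if profile.heterogeneity is not None:
        h = np.asarray(profile.heterogeneity(df), dtype=float)
        if deltas[0] != 0:
            atten = deltas / deltas[0]
        else:
            atten = np.ones(len(LEVELS))
        tau_levels = [deltas[kk] + atten[kk] * h for kk in range(len(LEVELS))]
    else:
        g = 1.0 + profile.het_gamma * age_std
        tau_levels = [deltas[kk] * g for kk in range(len(LEVELS))]

    # --- interval (index) treatment assignment with targeted selection ---
    lam = config.targeted_selection_strength
    tau1 = tau_levels[0]
    tau1_sd = tau1.std()
    tau1_std = (tau1 - tau1.mean()) / tau1_sd if tau1_sd > 0 else np.zeros(n)
    rates = config.co_treatment_rates
    if rates is None:
        rates = tuple([config.treated_fraction]
                      + list(np.linspace(0.05, 0.20, k - 1)))
    z = {}
    pis = {}
    raw = config.confounding_strength * sev_limb + lam * tau1_std
    for j, t in enumerate(treatments):
        pi = expit(raw + _prevalence_offset(raw, rates[j]))
        pis[t] = pi
        z[t] = (rng.rand(n) < pi).astype(int)
        df[f"interval_{t}"] = z[t]

    # --- baseline outcomes (levels 1-3 direct; level 4 via FAQ items) ---
    n_prior = sum(df[f"prior_{t}"] for t in treatments).to_numpy()
    base_params = {  # (intercept, severity slope, noise sd)
        "body_structures": (10.0, -1.5, 1.0),
        "specific_kinematic": (20.0, -2.0, 1.2),
        "overall_kinematic": (85.0, -8.0, 4.0),
    }
    baselines = {}
    for lv, (b0, bs, bn) in base_params.items():
        baselines[lv] = (b0 + bs * sev_limb + 0.2 * n_prior
                         + bn * rng.standard_normal(n))
        df[f"{lv}_baseline"] = baselines[lv]

    # 23-item questionnaire: ordinal skills 0-5 from a latent mobility score
    mobility = 2.5 - 1.0 * sev_limb + 0.5 * rng.standard_normal(n)
    difficulties = np.linspace(-1.5, 1.5, N_FAQ_ITEMS)
    items = np.clip(np.round(
        mobility[:, None] - difficulties[None, :]
        + 0.8 * rng.standard_normal((n, N_FAQ_ITEMS))), 0, 5)
    w = np.asarray(config.faq_weights, dtype=float)
    faqt_true = items @ w / w.sum()
    baselines["functional_mobility"] = faqt_true
    df["functional_mobility_baseline"] = faqt_true
    for jj in range(N_FAQ_ITEMS):
        df[f"faq_item_{jj + 1:02d}"] = items[:, jj]

    # --- follow-up outcomes along the causal chain ---
    fu_c = df["follow_up_years"].to_numpy() - (lo + hi) / 2
    change_sd = {}
    for kk, lv in enumerate(LEVELS):
        drift = config.drift_severity_slope * sev_limb + 0.15 * fu_c
        effect = np.zeros(n)
        for t in treatments:
            effect += z[t] * tau_levels[kk]
        noise = config.noise_sd[kk] * rng.standard_normal(n)
        change = drift + effect + noise
        df[f"{lv}_followup"] = baselines[lv] + change
        change_sd[lv] = float(change.std(ddof=1))

    truth = SyntheticTruth(
        tau={t: {lv: tau_levels[kk].copy() for kk, lv in enumerate(LEVELS)}
             for t in treatments},
        treated={t: z[t].astype(bool) for t in treatments},
        change_sd=change_sd,
        config_echo={
            "n_subjects": ns, "limbs_per_subject": lps,
            "targeted_selection_strength": lam,
            "deltas": list(deltas), "seed": config.seed,
        },
        pi=pis,
    )
    return df, truth


def inject_missingness(cohort: pd.DataFrame,
                       config: SyntheticConfig) -> pd.DataFrame:
    """Blank entries per the configured per-variable rates.

    Categorical gaps become NaN (downstream encoding maps them to the
    "Miss" level); questionnaire items are blanked per item.  When
    ``severity_dependent_missingness`` is on, the per-row blanking odds
    shift with GMFCS level, emulating informative missingness.  Outcome
    columns are never blanked.
    """
    rates = config.missingness_rates
    for r in rates.values():
        if not (0.0 <= r <= 1.0):
            raise ValueError("rate outside [0, 1]")
    out = cohort.copy()
    rng = np.random.RandomState(config.seed + 1)
    n = len(out)

    sev_proxy = np.zeros(n)
    if config.severity_dependent_missingness and "gmfcs" in out.columns:
        sev_map = {"I": -1.0, "II": 0.0, "III": 1.0, "IV": 2.0}
        sev_proxy = out["gmfcs"].map(sev_map).fillna(0.0).to_numpy()

    def _mask(rate):
        if rate in (0.0, 1.0):
            return rng.rand(n) < rate
        shift = 0.4 * sev_proxy
        p = expit(logit(rate) + shift - np.mean(shift))
        return rng.rand(n) < p

    for col, rate in rates.items():
        if col == "faq_items":
            for c in out.columns:
                if c.startswith("faq_item_"):
                    m = _mask(rate)
                    out.loc[m, c] = np.nan
        elif col in out.columns:
            m = _mask(rate)
            if out[col].dtype == object:
                out[col] = out[col].astype(object)
            out.loc[m, col] = np.nan
    return out


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    # ordinal scores travel as strings
    for name, _, _ in ORDINAL_COVARIATES:
        if name in df.columns:
            df[name] = df[name].map(
                lambda v: v if pd.isna(v) else str(int(float(v))))
    return df
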