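"""Eligibility filtering, missing-data handling, FAQt construction, and
covariate-balance metrics.

Conventions: nine months = 0.75 years, 30 months = 2.5 years.  Missing
categorical/ordinal entries become the literal level "Miss" (a legal level
everywhere downstream), which protects against data that are not missing
completely at random.  Missing continuous covariates are handled by
listwise deletion in the modeling layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FAQT_MIN_ITEMS = 18


@dataclass
class EligibilityRules:
    """Cohort entry rules: age under 25 years, follow-up in [9, 30) months,
    knee varus-valgus range of motion no more than 15 degrees."""

    max_age: float = 25.0
    min_followup: float = 0.75
    max_followup: float = 2.5
    kvv_limit: float = 15.0

    def __post_init__(self):
        if not (0 < self.min_followup < self.max_followup):
            raise ValueError("need 0 < min_followup < max_followup")
        if self.max_age <= 0 or self.kvv_limit <= 0:
            raise ValueError("bounds must be positive")


def filter_eligible(cohort: pd.DataFrame,
                    rules: EligibilityRules | None = None) -> pd.DataFrame:
    """Drop rows violating any eligibility rule; removal counts are logged
    and attached as ``result.attrs['removal_counts']``."""
    rules = rules or EligibilityRules()
    for col in ("age", "follow_up_years", "kvv_rom"):
        if col not in cohort.columns:
            raise KeyError(f"missing required column {col!r}")
    bad_age = cohort["age"] >= rules.max_age
    bad_fu = ((cohort["follow_up_years"] < rules.min_followup)
              | (cohort["follow_up_years"] >= rules.max_followup))
    bad_kvv = cohort["kvv_rom"] > rules.kvv_limit
    counts = {"age": int(bad_age.sum()), "followup": int(bad_fu.sum()),
              "kvv_rom": int(bad_kvv.sum())}
    log.info("eligibility removals: %s", counts)
    out = cohort.loc[~(bad_age | bad_fu | bad_kvv)].copy()
    out.attrs["removal_counts"] = counts
    return out


def encode_missing_categorical(cohort: pd.DataFrame) -> pd.DataFrame:
    """Replace blanks in categorical/ordinal (non-numeric) columns with the
    literal level "Miss"; numeric columns pass through untouched."""
    out = cohort.copy()
    for c in out.columns:
        if out[c].dtype == object or isinstance(out[c].dtype, pd.CategoricalDtype):
            col = out[c].astype(object)
            out[c] = np.where(pd.isna(col), "Miss", col)
    return out


def compute_faqt(items, weights, min_present: int = FAQT_MIN_ITEMS) -> float:
    """Difficulty-weighted average of mobility-skill items.

    Returns sum(w_i * y_i) / sum(w_i) over non-missing items when at least
    ``min_present`` items are present, NaN otherwise.
    """
    items = np.asarray(items, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if items.shape != weights.shape:
        raise ValueError("items and weights must have the same length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    present = ~np.isnan(items)
    if present.sum() < min_present:
        return float("nan")
    w = weights[present]
    return float(np.dot(w, items[present]) / w.sum())


def _ridge_fit(X, y, alpha=1.0):
    """Closed-form ridge with intercept; returns (coef, intercept)."""
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    A = Xc.T @ Xc + alpha * np.eye(X.shape[1])
    coef = np.linalg.solve(A, Xc.T @ (y - ym))
    return coef, ym - xm @ coef


def impute_faqt(cohort: pd.DataFrame, weights=None,
                item_prefix: str = "faq_item_",
                target: str = "functional_mobility_baseline",
                min_present: int = FAQT_MIN_ITEMS) -> pd.DataFrame:
    """Construct the functional-mobility score, imputing near-complete rows.

    Rows with all items present get the score directly.  Rows with at least
    ``min_present`` items get the missing items filled by a single-pass
    ridge regression of each item on the observed items (trained on
    complete rows), then scored.  Rows below the threshold keep the score
    missing and are excluded from functional-mobility analyses downstream.
    """
    item_cols = [c for c in cohort.columns if c.startswith(item_prefix)]
    if not item_cols:
        raise KeyError(f"no columns with prefix {item_prefix!r}")
    if weights is None:
        from .synthdata import DEFAULT_FAQ_WEIGHTS
        weights = DEFAULT_FAQ_WEIGHTS[: len(item_cols)]
    weights = np.asarray(weights, dtype=float)

    out = cohort.copy()
    items = out[item_cols].to_numpy(dtype=float)
    n, p = items.shape
    n_present = (~np.isnan(items)).sum(axis=1)
    complete = n_present == p

    # one ridge model per item, trained on complete rows
    models = {}
    if complete.sum() >= p + 2:
        Xc = items[complete]
        for j in range(p):
            others = [k for k in range(p) if k != j]
            models[j] = (others, *_ridge_fit(Xc[:, others], Xc[:, j]))

    filled = items.copy()
    for i in range(n):
        if complete[i] or n_present[i] < min_present:
            continue
        miss = np.flatnonzero(np.isnan(items[i]))
        for j in miss:
            if j in models:
                others, coef, icpt = models[j]
                row = items[i, others]
                # a predictor may itself be missing; fall back to its mean
                row = np.where(np.isnan(row), np.nanmean(items[:, others], axis=0), row)
                filled[i, j] = row @ coef + icpt
            else:
                filled[i, j] = np.nanmean(items[:, j])

    scores = np.full(n, np.nan)
    ok = n_present >= min_present
    if ok.any():
        w = weights
        scores[ok] = filled[ok] @ w / w.sum()
    out[target] = scores
    return out


def compute_smd(x_treated, x_control, kind: str = "continuous") -> float:
    """Standardized mean difference between two groups.

    continuous: |mean difference| / pooled SD.  factor: Yang-Dalton
    multivariate form sqrt(d' S^- d) over K-1 level proportions, with S the
    average of the two multinomial covariance matrices (pseudo-inverse when
    singular).
    """
    if kind == "continuous":
        xt = np.asarray(x_treated, dtype=float)
        xc = np.asarray(x_control, dtype=float)
        if len(xt) < 2 or len(xc) < 2:
            raise ValueError("need >= 2 observations per group")
        pooled = np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2)
        if pooled == 0:
            warnings.warn("zero pooled variance; SMD set to 0")
            return 0.0
        return float(abs(xt.mean() - xc.mean()) / pooled)
    if kind != "factor":
        raise ValueError("kind must be 'continuous' or 'factor'")
    xt = pd.Series(list(x_treated), dtype=object).astype(str)
    xc = pd.Series(list(x_control), dtype=object).astype(str)
    if len(xt) < 2 or len(xc) < 2:
        raise ValueError("need >= 2 observations per group")
    levels = sorted(set(xt) | set(xc))
    if len(levels) < 2:
        warnings.warn("single factor level in both groups; SMD set to 0")
        return 0.0
    pt = np.array([(xt == lv).mean() for lv in levels])[1:]
    pc = np.array([(xc == lv).mean() for lv in levels])[1:]
    d = pt - pc
    St = np.diag(pt) - np.outer(pt, pt)
    Sc = np.diag(pc) - np.outer(pc, pc)
    S = (St + Sc) / 2
    val = float(d @ np.linalg.pinv(S) @ d)
    return float(np.sqrt(max(val, 0.0)))


@dataclass
class BalanceReport:
    """Raw vs matched covariate balance plus co-treatment rate differences."""

    smd: pd.DataFrame          # columns: covariate, class, kind, raw, matched
    rate_diff: pd.DataFrame    # columns: treatment, prior_diff, interval_diff (matched, proportions)

    def to_csv(self, path) -> None:
        self.smd.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"smd": self.smd.to_dict(orient="records"),
                "rate_diff": self.rate_diff.to_dict(orient="records")}


def _col_kind(s: pd.Series) -> str:
    return "continuous" if pd.api.types.is_numeric_dtype(s) else "factor"


def balance_report(cohort: pd.DataFrame, matched_pairs,
                   covariate_sets: dict, treatment: str,
                   co_treatments=None) -> BalanceReport:
    """Balance diagnostics for one treatment's matching design.

    ``matched_pairs`` is a sequence of (treated limb_id, control limb_id);
    ``covariate_sets`` maps a class label (e.g. "exam", "kinematic",
    "propensity") to a list of columns.  Raw SMDs compare all treated vs
    all controls; matched SMDs the paired subsets.  Rate differences
    (treated minus control, proportions) cover prior and interval
    co-treatment flags on the matched groups.
    """
    pairs = list(matched_pairs)
    if not pairs:
        raise ValueError("empty match set")
    idx = cohort.set_index("limb_id")
    t_ids = [a for a, _ in pairs]
    c_ids = [b for _, b in pairs]
    missing = (set(t_ids) | set(c_ids)) - set(idx.index)
    if missing:
        raise KeyError(f"pairs reference unknown limb_ids: {sorted(missing)[:5]}")
    z = cohort[f"interval_{treatment}"].to_numpy().astype(bool)
    treated_all = cohort.loc[z]
    control_all = cohort.loc[~z]
    mt = idx.loc[t_ids]
    mc = idx.loc[c_ids]

    rows = []
    for cls, cols in covariate_sets.items():
        for c in cols:
            kind = _col_kind(cohort[c])
            raw = compute_smd(treated_all[c].dropna(), control_all[c].dropna(), kind)
            mat = compute_smd(mt[c].dropna(), mc[c].dropna(), kind)
            rows.append({"covariate": c, "class": cls, "kind": kind,
                         "raw": raw, "matched": mat})
    smd = pd.DataFrame(rows)

    if co_treatments is None:
        co_treatments = [c[len("interval_"):] for c in cohort.columns
                         if c.startswith("interval_")]
        co_treatments = [t for t in co_treatments if t != treatment]
    rd = []
    for t in co_treatments:
        rec = {"treatment": t}
        for flavor in ("prior", "interval"):
            col = f"{flavor}_{t}"
            if col in cohort.columns:
                rec[f"{flavor}_diff"] = float(mt[col].mean() - mc[col].mean())
        rd.append(rec)
    return BalanceReport(smd=smd, rate_diff=pd.DataFrame(rd))
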