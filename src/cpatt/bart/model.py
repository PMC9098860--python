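"""Bayesian Additive Regression Trees: public fitting/prediction API.

A sum of ``m`` small regression trees with a regularizing tree prior
``p(split at depth d) = base * (1 + d)^(-power)``, conjugate normal leaf
priors and a scaled inverse-chi-squared noise prior, sampled by
Metropolis-within-Gibbs (grow / prune / change moves).  Continuous
responses are internally rescaled to [-0.5, 0.5]; binary responses use
Albert-Chib latent-normal augmentation with sigma fixed at 1 and return
probabilities through the normal CDF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from . import _kernels
from ._kernels import INTERNAL, LEAF


@dataclass
class BartParams:
    """Sampler hyperparameters.

    Defaults are the published defaults of the standard BART tool family:
    50 trees, tree prior base 0.95 / power 2, leaf scale k = 2, noise prior
    nu = 3 at the q = 0.90 quantile, and a grow/prune/change proposal mix
    of 0.28/0.28/0.44.
    """

    n_trees: int = 50
    base: float = 0.95
    power: float = 2.0
    k: float = 2.0
    nu: float = 3.0
    q: float = 0.90
    n_burn: int = 250
    n_keep: int = 1000
    p_grow: float = 0.28
    p_prune: float = 0.28
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.base < 1.0):
            raise ValueError("base must be in (0, 1)")
        if self.power <= 0:
            raise ValueError("power must be > 0")
        if self.n_trees < 1 or self.n_keep < 1:
            raise ValueError("n_trees and n_keep must be >= 1")


class CovariateSchema:
    """Maps a mixed-type covariate frame to a numeric design matrix.

    Numeric columns pass through; object/categorical columns are one-hot
    encoded over the levels seen at fit time ("Miss" is an ordinary level).
    A level unseen at fit time encodes as all-zero indicators.
    """

    def __init__(self):
        self.numeric_cols: list[str] = []
        self.factor_levels: dict[str, list] = {}
        self.columns: list[str] = []

    def fit(self, X: pd.DataFrame) -> "CovariateSchema":
        self.numeric_cols = []
        self.factor_levels = {}
        for c in X.columns:
            if pd.api.types.is_numeric_dtype(X[c]):
                self.numeric_cols.append(c)
            else:
                levels = sorted(pd.unique(X[c].astype(str).fillna("Miss")))
                self.factor_levels[c] = levels
        self.columns = list(self.numeric_cols)
        for c, levels in self.factor_levels.items():
            self.columns += [f"{c}={lv}" for lv in levels]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        n = len(X)
        out = np.zeros((n, len(self.columns)), dtype=np.float64)
        j = 0
        for c in self.numeric_cols:
            if c not in X.columns:
                raise ValueError(f"schema mismatch: missing column {c!r}")
            col = np.asarray(X[c], dtype=np.float64)
            if np.isnan(col).any():
                raise ValueError(f"missing numeric entries in column {c!r}")
            out[:, j] = col
            j += 1
        for c, levels in self.factor_levels.items():
            if c not in X.columns:
                raise ValueError(f"schema mismatch: missing column {c!r}")
            vals = X[c].astype(str).to_numpy()
            for lv in levels:
                out[:, j] = vals == lv
                j += 1
        return out


def _as_design(X, schema: CovariateSchema | None):
    if isinstance(X, pd.DataFrame):
        if schema is None:
            schema = CovariateSchema().fit(X)
        return schema.transform(X), schema
    Xa = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if Xa.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(Xa).any():
        raise ValueError("missing numeric entries in X")
    return Xa, schema


@dataclass
class BartPosterior:
    """Retained draws of the sum-of-trees posterior."""

    feat: np.ndarray        # (n_keep, m, K) int16
    thresh: np.ndarray      # (n_keep, m, K) float64 (cutpoints are observed values)
    state: np.ndarray       # (n_keep, m, K) int8
    leaf_val: np.ndarray    # (n_keep, m, K) float32
    sigma2: np.ndarray      # (n_keep,) on training scale (internal)
    center: float
    scale: float
    probit: bool = False
    schema: CovariateSchema | None = None
    in_sample_fit: np.ndarray | None = None  # (n_keep, n) internal scale
    params: BartParams | None = None

    @property
    def n_keep(self) -> int:
        return self.state.shape[0]

    @property
    def sigma_draws(self) -> np.ndarray:
        """Noise-SD draws on the original outcome scale."""
        return np.sqrt(self.sigma2) * self.scale

    def _eval(self, Xa: np.ndarray) -> np.ndarray:
        return _kernels.predict_forests(
            self.feat.astype(np.int64), self.thresh.astype(np.float64),
            self.state, self.leaf_val.astype(np.float64),
            np.ascontiguousarray(Xa, dtype=np.float64))

    def predict_draws(self, Xnew) -> np.ndarray:
        """(n_keep, n_new) posterior draws on the original scale
        (probabilities for a probit fit)."""
        Xa, _ = _as_design(Xnew, self.schema)
        raw = self._eval(Xa)
        if self.probit:
            return ndtr(raw)
        return raw * self.scale + self.center

    def predict(self, Xnew) -> np.ndarray:
        return self.predict_draws(Xnew).mean(axis=0)

    def to_json(self) -> str:
        payload = {
            "feat": self.feat.tolist(),
            "thresh": self.thresh.astype(float).tolist(),
            "state": self.state.tolist(),
            "leaf_val": self.leaf_val.astype(float).tolist(),
            "sigma2": self.sigma2.tolist(),
            "center": self.center,
            "scale": self.scale,
            "probit": self.probit,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "BartPosterior":
        d = json.loads(s)
        return cls(feat=np.array(d["feat"], dtype=np.int16),
                   thresh=np.array(d["thresh"], dtype=np.float64),
                   state=np.array(d["state"], dtype=np.int8),
                   leaf_val=np.array(d["leaf_val"], dtype=np.float32),
                   sigma2=np.array(d["sigma2"]),
                   center=d["center"], scale=d["scale"],
                   probit=d["probit"])


def _sigma_prior_lambda(sigma_hat2: float, nu: float, q: float) -> float:
    """Scale lambda of the nu*lambda/chi2_nu prior placing mass q below
    the data-based guess sigma_hat."""
    return sigma_hat2 * stats.chi2.ppf(1.0 - q, nu) / nu


def fit_bart(X, y, params: BartParams | None = None) -> BartPosterior:
    """Fit BART to a continuous response.

    X may be a pandas DataFrame (factors one-hot encoded; "Miss" is a
    legal level) or a numeric matrix with no missing entries.
    """
    params = params or BartParams()
    Xa, schema = _as_design(X, None)
    y = np.asarray(y, dtype=np.float64)
    if len(y) != Xa.shape[0]:
        raise ValueError("length of y must match rows of X")
    ymin, ymax = float(np.min(y)), float(np.max(y))
    center = 0.5 * (ymin + ymax)
    scale = ymax - ymin
    m = params.n_trees
    if scale <= 0:
        # zero-variance guard: the posterior collapses to the constant
        K0 = 2 ** (params.max_depth + 1) - 1
        nk0 = params.n_keep
        state = np.zeros((nk0, m, K0), dtype=np.int8)
        state[:, :, 0] = 1  # all-stump forest, leaves at 0 on internal scale
        return BartPosterior(feat=np.zeros((nk0, m, K0), dtype=np.int16),
                             thresh=np.zeros((nk0, m, K0)),
                             state=state,
                             leaf_val=np.zeros((nk0, m, K0), dtype=np.float32),
                             sigma2=np.full(nk0, 1e-12),
                             center=center, scale=1.0, probit=False,
                             schema=schema,
                             in_sample_fit=np.zeros((nk0, Xa.shape[0]),
                                                    dtype=np.float32),
                             params=params)
    ys = (y - center) / scale
    K = 2 ** (params.max_depth + 1) - 1
    tau2 = (0.5 / (params.k * np.sqrt(m))) ** 2
    sd = float(np.std(ys, ddof=1)) if len(ys) > 1 else 0.0
    sigma_hat2 = sd ** 2 if sd > 0 else 1e-6
    lam = _sigma_prior_lambda(sigma_hat2, params.nu, params.q)

    nk = params.n_keep
    keep_feat = np.zeros((nk, m, K), dtype=np.int16)
    keep_thresh = np.zeros((nk, m, K), dtype=np.float64)
    keep_state = np.zeros((nk, m, K), dtype=np.int8)
    keep_leafval = np.zeros((nk, m, K), dtype=np.float32)
    keep_fit = np.zeros((nk, Xa.shape[0]), dtype=np.float32)
    keep_sigma2 = np.zeros(nk, dtype=np.float64)

    _kernels.run_bart(Xa, ys, m, params.max_depth, params.base, params.power,
                      tau2, params.nu, lam, params.p_grow, params.p_prune,
                      params.n_burn, nk, params.seed,
                      keep_feat, keep_thresh, keep_state, keep_leafval,
                      keep_fit, keep_sigma2)

    return BartPosterior(feat=keep_feat, thresh=keep_thresh,
                         state=keep_state, leaf_val=keep_leafval,
                         sigma2=keep_sigma2, center=center, scale=scale,
                         probit=False, schema=schema,
                         in_sample_fit=keep_fit, params=params)


def predict_bart(post: BartPosterior, Xnew):
    """Posterior draws and posterior-mean prediction at new rows."""
    draws = post.predict_draws(Xnew)
    return draws, draws.mean(axis=0)


def fit_bart_probit(X, z, params: BartParams | None = None) -> BartPosterior:
    """Probit BART for a binary response via Albert-Chib augmentation.

    Returned posterior predicts probabilities.  The latent-normal noise SD
    is fixed at 1; the leaf prior scale is 3 / (k * sqrt(m)) so the latent
    function spans roughly +/-3.
    """
    params = params or BartParams()
    Xa, schema = _as_design(X, None)
    z = np.asarray(z)
    if not np.isin(z, [0, 1]).all():
        raise ValueError("z must be binary 0/1")
    z = z.astype(np.float64)
    if z.min() == z.max():
        raise ValueError("degenerate propensity: all-one or all-zero z")
    n = Xa.shape[0]
    m = params.n_trees
    K = 2 ** (params.max_depth + 1) - 1
    tau2 = (3.0 / (params.k * np.sqrt(m))) ** 2

    rng = np.random.RandomState(params.seed ^ 0x5EED)
    _kernels.set_seed(params.seed)

    feat = np.zeros((m, K), dtype=np.int64)
    thresh = np.zeros((m, K), dtype=np.float64)
    state = np.zeros((m, K), dtype=np.int8)
    leaf_val = np.zeros((m, K), dtype=np.float64)
    leaf_of = np.zeros((m, n), dtype=np.int64)
    state[:, 0] = LEAF
    fit = np.zeros(n, dtype=np.float64)
    use_row = np.ones(n, dtype=np.uint8)
    depth_of = np.zeros(K, dtype=np.int64)
    for k in range(1, K):
        depth_of[k] = depth_of[(k - 1) // 2] + 1
    scratch_vals = np.empty(n, dtype=np.float64)
    scratch_nodes = np.empty(K, dtype=np.int64)

    nk = params.n_keep
    keep_feat = np.zeros((nk, m, K), dtype=np.int16)
    keep_thresh = np.zeros((nk, m, K), dtype=np.float64)
    keep_state = np.zeros((nk, m, K), dtype=np.int8)
    keep_leafval = np.zeros((nk, m, K), dtype=np.float32)
    keep_fit = np.zeros((nk, n), dtype=np.float32)

    w = np.where(z == 1, 0.5, -0.5)  # latent init
    eps = 1e-10
    for it in range(params.n_burn + nk):
        # latent truncated-normal draw given current fit
        u = rng.random_sample(n)
        p0 = np.clip(ndtr(-fit), eps, 1 - eps)  # P(w < 0)
        uu = np.where(z == 1, p0 + u * (1 - p0), u * p0)
        w = fit + ndtri(np.clip(uu, eps, 1 - eps))
        _kernels.sweep_forest(Xa, w, fit, use_row, feat, thresh, state,
                              leaf_val, leaf_of, 1.0, tau2,
                              params.base, params.power,
                              params.p_grow, params.p_prune,
                              params.max_depth, depth_of,
                              scratch_vals, scratch_nodes)
        if it >= params.n_burn:
            j = it - params.n_burn
            keep_feat[j] = feat
            keep_thresh[j] = thresh
            keep_state[j] = state
            keep_leafval[j] = leaf_val
            keep_fit[j] = fit

    return BartPosterior(feat=keep_feat, thresh=keep_thresh,
                         state=keep_state, leaf_val=keep_leafval,
                         sigma2=np.ones(nk), center=0.0, scale=1.0,
                         probit=True, schema=schema,
                         in_sample_fit=keep_fit, params=params)


def evaluate_propensity(scores, z, threshold: float = 0.5):
    """Confusion-matrix metrics at a threshold plus rank-statistic AUC.

    Returns (accuracy, sensitivity, specificity, auc).
    """
    scores = np.asarray(scores, dtype=np.float64)
    z = np.asarray(z).astype(int)
    if z.min() == z.max():
        raise ValueError("single-class held-out set")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (z == 1)))
    tn = int(np.sum((pred == 0) & (z == 0)))
    fp = int(np.sum((pred == 1) & (z == 0)))
    fn = int(np.sum((pred == 0) & (z == 1)))
    acc = (tp + tn) / len(z)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ranks = stats.rankdata(scores)
    n1 = int(z.sum())
    n0 = len(z) - n1
    auc = (ranks[z == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return acc, sens, spec, auc
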