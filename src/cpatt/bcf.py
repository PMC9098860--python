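"""Bayesian Causal Forest: y = mu(x, pihat) + tau(x) * z + eps.

The outcome is decomposed into a prognostic forest ``mu`` — which sees the
covariates plus the estimated propensity score — and a treatment-moderating
forest ``tau`` multiplying the treatment indicator.  Feeding the propensity
estimate to ``mu`` lets the prognostic fit absorb targeted selection
(assignment that tracks expected prognosis/benefit), which otherwise leaks
regularization-induced confounding into the effect estimate.

The moderating forest gets a stronger prior toward heterogeneity here than
a plain BART fit would (its own tree-prior base/power and a tighter leaf
scale), and only treated rows inform its leaves; its value is still tracked
for every row so in-sample effect draws exist everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart import _kernels
from .bart.model import CovariateSchema, _as_design, _sigma_prior_lambda


@dataclass
class BcfParams:
    """Causal-forest hyperparameters.

    ``ntree_moderate`` and ``base_moderate`` default high (200 and 0.95)
    to accommodate substantial outcome heterogeneity across observations;
    the remaining tree-prior settings are the reference defaults.
    """

    ntree_control: int = 200
    ntree_moderate: int = 200
    base_control: float = 0.95
    power_control: float = 2.0
    base_moderate: float = 0.95
    power_moderate: float = 3.0
    tau_leaf_scale_mult: float = 0.674  # leaf SD = mult * SD(y) / sqrt(ntree_moderate)
    k_control: float = 2.0
    nu: float = 3.0
    q: float = 0.90
    n_burn: int = 1000
    n_keep: int = 1000
    p_grow: float = 0.28
    p_prune: float = 0.28
    max_depth: int = 6
    pihat_in_tau: bool = False  # switch: also feed the propensity to the tau forest
    seed: int = 0

    def __post_init__(self):
        if self.ntree_control < 1 or self.ntree_moderate < 1:
            raise ValueError("tree counts must be >= 1")
        for b in (self.base_control, self.base_moderate):
            if not (0.0 < b < 1.0):
                raise ValueError("tree-prior base must be in (0, 1)")


@dataclass
class BcfPosterior:
    """Retained draws of the causal-forest decomposition."""

    tau_draws_internal: np.ndarray   # (n_keep, n) on internal scale
    mu_draws_internal: np.ndarray    # (n_keep, n)
    sigma2: np.ndarray               # (n_keep,) internal scale
    center: float
    scale: float
    z: np.ndarray
    schema_mu: CovariateSchema | None = None
    schema_tau: CovariateSchema | None = None
    params: BcfParams | None = None

    @property
    def n_keep(self) -> int:
        return self.tau_draws_internal.shape[0]

    @property
    def tau_draws(self) -> np.ndarray:
        """(n_keep, n) per-observation treatment-effect draws, outcome units."""
        return self.tau_draws_internal * self.scale

    @property
    def mu_draws(self) -> np.ndarray:
        return self.mu_draws_internal * self.scale + self.center

    @property
    def yhat_draws(self) -> np.ndarray:
        """Fitted outcome per draw: mu-part + z * tau-part (bookkeeping sum)."""
        return self.mu_draws + self.z[None, :] * self.tau_draws

    @property
    def sigma_draws(self) -> np.ndarray:
        return np.sqrt(self.sigma2) * self.scale

    def att(self, rows=None) -> float:
        """Posterior-mean ATT over the given (default: all treated) rows."""
        return float(np.mean(bcf_tau_draws(self, rows)))


def fit_bcf(X, z, pihat, y, params: BcfParams | None = None) -> BcfPosterior:
    """Fit the causal forest.

    X : covariate frame/matrix (no missing numerics; "Miss" is a level).
    z : binary treatment indicator.
    pihat : estimated propensity in (0, 1), entered as a covariate of the
        prognostic forest (and of the moderating forest if
        ``params.pihat_in_tau``).
    """
    params = params or BcfParams()
    z = np.asarray(z).astype(np.float64)
    if not np.isin(z, [0.0, 1.0]).all():
        raise ValueError("z must be binary 0/1")
    n_treat = int(z.sum())
    if n_treat < 10 or len(z) - n_treat < 10:
        raise ValueError("refusing to fit: fewer than 10 treated or 10 control rows")
    pihat = np.asarray(pihat, dtype=np.float64)
    if np.any(pihat <= 0) or np.any(pihat >= 1):
        raise ValueError("pihat must be strictly inside (0, 1)")
    y = np.asarray(y, dtype=np.float64)

    if isinstance(X, pd.DataFrame):
        schema = CovariateSchema().fit(X)
        Xa = schema.transform(X)
    else:
        Xa, schema = _as_design(X, None)
    X_mu = np.ascontiguousarray(np.column_stack([Xa, pihat]))
    if params.pihat_in_tau:
        X_tau = X_mu
    else:
        X_tau = np.ascontiguousarray(Xa)

    ymin, ymax = float(y.min()), float(y.max())
    center = 0.5 * (ymin + ymax)
    scale = ymax - ymin
    if scale <= 0:
        scale = 1.0
    ys = (y - center) / scale
    sd = float(np.std(ys, ddof=1)) if len(ys) > 1 else 0.0
    sigma_hat2 = sd ** 2 if sd > 0 else 1e-6

    tau2_mu = (0.5 / (params.k_control * np.sqrt(params.ntree_control))) ** 2
    tau_leaf_sd = params.tau_leaf_scale_mult * max(sd, 1e-6) / np.sqrt(params.ntree_moderate)
    tau2_tau = tau_leaf_sd ** 2
    lam = _sigma_prior_lambda(sigma_hat2, params.nu, params.q)

    nk = params.n_keep
    n = len(y)
    keep_mu = np.zeros((nk, n), dtype=np.float64)
    keep_tau = np.zeros((nk, n), dtype=np.float64)
    keep_sigma2 = np.zeros(nk, dtype=np.float64)

    _kernels.run_bcf(X_mu, X_tau, ys, z,
                     params.ntree_control, params.ntree_moderate,
                     params.max_depth,
                     params.base_control, params.power_control,
                     params.base_moderate, params.power_moderate,
                     tau2_mu, tau2_tau, params.nu, lam,
                     params.p_grow, params.p_prune,
                     params.n_burn, nk, params.seed,
                     keep_mu, keep_tau, keep_sigma2)

    return BcfPosterior(tau_draws_internal=keep_tau,
                        mu_draws_internal=keep_mu,
                        sigma2=keep_sigma2, center=center, scale=scale,
                        z=z, schema_mu=schema, schema_tau=schema,
                        params=params)


def bcf_tau_draws(post: BcfPosterior, rows=None) -> np.ndarray:
    """(n_keep, len(rows)) treatment-effect draws at training rows.

    ``rows`` indexes the training data (the ATT is in-sample by
    definition); default = all treated rows.
    """
    if rows is None:
        rows = np.flatnonzero(post.z == 1)
    rows = np.asarray(rows)
    n = post.tau_draws_internal.shape[1]
    if rows.size and (rows.min() < 0 or rows.max() >= n):
        raise IndexError("unknown row id in rows")
    return post.tau_draws[:, rows]
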