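"""Numba kernels for the sum-of-trees MCMC sampler.

Trees live in fixed-size heap arrays (node k has children 2k+1, 2k+2), one
forest = a block of per-tree arrays.  Node states: 0 = unused, 1 = leaf,
2 = internal.  Numeric split rule: x < threshold goes left.  All covariates
are numeric by the time they reach these kernels (factors are one-hot
encoded upstream).

The Metropolis-within-Gibbs move set is grow / prune / change, with the
conjugate normal leaf prior integrated out (Chipman-George-McCulloch style
marginal likelihood).  Leaf values are redrawn from their conjugate normal
posterior after every tree update, and sigma^2 from a scaled
inverse-chi-squared full conditional.

`use_row` masks which rows contribute likelihood (all rows for a plain BART
fit; treated rows only for the treatment-moderating forest of a causal
forest).  Tree membership is tracked for every row regardless, so the forest
can be evaluated everywhere.
"""

import numpy as np
from numba import njit

UNUSED = 0
LEAF = 1
INTERNAL = 2


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _log_ml(n, s, sigma2, tau2):
    """Log marginal likelihood of a leaf (up to shared constants).

    n, s = count and sum of partial residuals of likelihood rows in the
    leaf; tau2 = leaf-prior variance.
    """
    if n == 0:
        return 0.0
    v = sigma2 + n * tau2
    return 0.5 * np.log(sigma2 / v) + 0.5 * tau2 * s * s / (sigma2 * v)


@njit(cache=True)
def _n_unique_cuts(vals):
    """Number of valid cutpoints = (#unique values) - 1.

    Fast paths avoid sorting for constant and two-valued columns (the
    common case for one-hot indicators); otherwise vals is sorted in
    place so a k-th unique value can be selected afterwards.
    """
    m = vals.shape[0]
    if m < 2:
        return 0
    lo = vals[0]
    hi = vals[0]
    for i in range(1, m):
        v = vals[i]
        if v < lo:
            lo = v
        elif v > hi:
            hi = v
    if lo == hi:
        return 0
    two = True
    for i in range(m):
        v = vals[i]
        if v != lo and v != hi:
            two = False
            break
    if two:
        return 1
    vals.sort()
    u = 1
    for i in range(1, m):
        if vals[i] != vals[i - 1]:
            u += 1
    return u - 1


@njit(cache=True)
def _kth_unique_above_min(vals, k):
    """k-th unique value (1-based) above the minimum of a sorted array."""
    u = 0
    for i in range(1, vals.shape[0]):
        if vals[i] != vals[i - 1]:
            u += 1
            if u == k:
                return vals[i]
    return vals[vals.shape[0] - 1]


@njit(cache=True)
def _select_cut(vals, ncut):
    """Uniform draw among the valid cutpoints counted by _n_unique_cuts
    (which sorted vals unless it took the two-valued fast path)."""
    if ncut == 1:
        hi = vals[0]
        for i in range(1, vals.shape[0]):
            if vals[i] > hi:
                hi = vals[i]
        return hi
    kth = 1 + int(np.random.random() * ncut)
    return _kth_unique_above_min(vals, kth)


@njit(cache=True)
def sweep_forest(X, y, fit, use_row,
                 feat, thresh, state, leaf_val, leaf_of,
                 sigma2, tau2, base, power,
                 p_grow, p_prune, max_depth, depth_of,
                 scratch_vals, scratch_nodes):
    """One Gibbs sweep over every tree of a forest (in place).

    fit[i] must equal the forest's current prediction for row i; it is kept
    consistent.  y is the (possibly latent / residualized) response the
    forest targets.  Returns nothing.
    """
    m, K = state.shape
    n, p = X.shape
    old_g = np.empty(n, dtype=np.float64)

    nrow_all = np.zeros(K, dtype=np.int64)
    n_eff = np.zeros(K, dtype=np.int64)
    s_eff = np.zeros(K, dtype=np.float64)

    for t in range(m):
        # ---- collect leaves and terminal parents ----
        n_leaves = 0
        n_tp = 0
        for k in range(K):
            nrow_all[k] = 0
            n_eff[k] = 0
            s_eff[k] = 0.0
            if state[t, k] == LEAF:
                scratch_nodes[n_leaves] = k
                n_leaves += 1
        # terminal parents (both children leaves)
        for k in range(K):
            if state[t, k] == INTERNAL:
                c1 = 2 * k + 1
                c2 = 2 * k + 2
                if state[t, c1] == LEAF and state[t, c2] == LEAF:
                    scratch_nodes[K - 1 - n_tp] = k  # store from the back
                    n_tp += 1

        is_stump = (n_leaves == 1)

        # this tree's current per-row contribution old_g (partial residual
        # R_i = y_i - fit_i + old_g[i] throughout), all-row counts per leaf
        # (split validity), and likelihood stats per leaf — one pass
        for i in range(n):
            k = leaf_of[t, i]
            g = leaf_val[t, k]
            old_g[i] = g
            nrow_all[k] += 1
            if use_row[i]:
                r = y[i] - fit[i] + g
                n_eff[k] += 1
                s_eff[k] += r

        # growable leaves: depth < max_depth and >= 2 rows
        n_growable = 0
        for j in range(n_leaves):
            k = scratch_nodes[j]
            if depth_of[k] < max_depth and nrow_all[k] >= 2:
                n_growable += 1

        # ---- choose a move ----
        u = np.random.random()
        if is_stump:
            move = 0  # grow
        elif u < p_grow:
            move = 0
        elif u < p_grow + p_prune:
            move = 1  # prune
        else:
            move = 2  # change

        if move == 0 and n_growable > 0:
            # -------------------- GROW --------------------
            # pick uniformly among growable leaves
            pick = int(np.random.random() * n_growable)
            ell = -1
            cnt = 0
            for j in range(n_leaves):
                k = scratch_nodes[j]
                if depth_of[k] < max_depth and nrow_all[k] >= 2:
                    if cnt == pick:
                        ell = k
                        break
                    cnt += 1
            v = int(np.random.random() * p)
            # gather values of X[:, v] for rows in leaf ell
            nv = 0
            for i in range(n):
                if leaf_of[t, i] == ell:
                    scratch_vals[nv] = X[i, v]
                    nv += 1
            vals = scratch_vals[:nv]
            ncut = _n_unique_cuts(vals)
            if ncut > 0:
                cut = _select_cut(vals, ncut)
                # stats of proposed children
                nL = 0
                sL = 0.0
                nR = 0
                sR = 0.0
                for i in range(n):
                    if leaf_of[t, i] == ell and use_row[i]:
                        r = y[i] - fit[i] + old_g[i]
                        if X[i, v] < cut:
                            nL += 1
                            sL += r
                        else:
                            nR += 1
                            sR += r
                d = depth_of[ell]
                psd = base * (1.0 + d) ** (-power)
                psc = base * (2.0 + d) ** (-power)
                if depth_of[ell] + 1 >= max_depth:
                    psc = 0.0  # children cannot split: depth cap truncates the prior
                # structure prior ratio; the uniform splitting-rule prior
                # 1/(p*ncut) cancels the matching factor of the grow
                # proposal density, so neither appears below
                log_prior = np.log(psd) + 2.0 * np.log(1.0 - psc) - np.log(1.0 - psd)
                log_ml = (_log_ml(nL, sL, sigma2, tau2)
                          + _log_ml(nR, sR, sigma2, tau2)
                          - _log_ml(n_eff[ell], s_eff[ell], sigma2, tau2))
                # forward proposal prob
                pg = 1.0 if is_stump else p_grow
                # number of terminal parents after the grow
                n_tp_new = n_tp + 1
                if ell > 0:
                    par = (ell - 1) // 2
                    sib = 2 * par + 1 if ell == 2 * par + 2 else 2 * par + 2
                    if state[t, sib] == LEAF:
                        n_tp_new -= 1  # parent was a tp, no longer
                log_q = (np.log(p_prune) - np.log(n_tp_new)
                         - (np.log(pg) - np.log(n_growable)))
                if np.log(np.random.random()) < log_prior + log_ml + log_q:
                    # accept
                    c1 = 2 * ell + 1
                    c2 = 2 * ell + 2
                    state[t, ell] = INTERNAL
                    feat[t, ell] = v
                    thresh[t, ell] = cut
                    state[t, c1] = LEAF
                    state[t, c2] = LEAF
                    leaf_val[t, c1] = 0.0
                    leaf_val[t, c2] = 0.0
                    n_eff[c1] = nL
                    s_eff[c1] = sL
                    n_eff[c2] = nR
                    s_eff[c2] = sR
                    for i in range(n):
                        if leaf_of[t, i] == ell:
                            if X[i, v] < cut:
                                leaf_of[t, i] = c1
                            else:
                                leaf_of[t, i] = c2

        elif move == 1 and n_tp > 0:
            # -------------------- PRUNE --------------------
            pick = int(np.random.random() * n_tp)
            k = scratch_nodes[K - 1 - pick]
            c1 = 2 * k + 1
            c2 = 2 * k + 2
            nM = n_eff[c1] + n_eff[c2]
            sM = s_eff[c1] + s_eff[c2]
            # reverse grow needs the cutpoint count for the current split var
            v = feat[t, k]
            nv = 0
            for i in range(n):
                kk = leaf_of[t, i]
                if kk == c1 or kk == c2:
                    scratch_vals[nv] = X[i, v]
                    nv += 1
            vals = scratch_vals[:nv]
            ncut = _n_unique_cuts(vals)
            if ncut > 0:
                d = depth_of[k]
                psd = base * (1.0 + d) ** (-power)
                psc = base * (2.0 + d) ** (-power)
                if d + 1 >= max_depth:
                    psc = 0.0
                log_prior = -(np.log(psd) + 2.0 * np.log(1.0 - psc)
                              - np.log(1.0 - psd))
                log_ml = (_log_ml(nM, sM, sigma2, tau2)
                          - _log_ml(n_eff[c1], s_eff[c1], sigma2, tau2)
                          - _log_ml(n_eff[c2], s_eff[c2], sigma2, tau2))
                # growable-leaf count of the pruned tree
                n_growable_new = 0
                for j in range(n_leaves):
                    kk = scratch_nodes[j]
                    if kk != c1 and kk != c2:
                        if depth_of[kk] < max_depth and nrow_all[kk] >= 2:
                            n_growable_new += 1
                if depth_of[k] < max_depth and nv >= 2:
                    n_growable_new += 1
                # rule prior of the removed split cancels the reverse-grow
                # rule-proposal density (same candidate set)
                pruned_is_stump = (n_leaves == 2)
                pg = 1.0 if pruned_is_stump else p_grow
                log_q = (np.log(pg) - np.log(n_growable_new)
                         - (np.log(p_prune) - np.log(n_tp)))
                if np.log(np.random.random()) < log_prior + log_ml + log_q:
                    state[t, k] = LEAF
                    state[t, c1] = UNUSED
                    state[t, c2] = UNUSED
                    leaf_val[t, k] = 0.0
                    n_eff[k] = nM
                    s_eff[k] = sM
                    for i in range(n):
                        kk = leaf_of[t, i]
                        if kk == c1 or kk == c2:
                            leaf_of[t, i] = k

        elif move == 2 and n_tp > 0:
            # -------------------- CHANGE --------------------
            pick = int(np.random.random() * n_tp)
            k = scratch_nodes[K - 1 - pick]
            c1 = 2 * k + 1
            c2 = 2 * k + 2
            v_old = feat[t, k]
            v_new = int(np.random.random() * p)
            # rows under node k
            nv = 0
            for i in range(n):
                kk = leaf_of[t, i]
                if kk == c1 or kk == c2:
                    scratch_vals[nv] = X[i, v_new]
                    nv += 1
            n_under = nv
            vals = scratch_vals[:nv]
            ncut_new = _n_unique_cuts(vals)
            if ncut_new > 0:
                cut_new = _select_cut(vals, ncut_new)
                # old-split cutpoint count for the reverse proposal
                nv = 0
                for i in range(n):
                    kk = leaf_of[t, i]
                    if kk == c1 or kk == c2:
                        scratch_vals[nv] = X[i, v_old]
                        nv += 1
                ncut_old = _n_unique_cuts(scratch_vals[:nv])
                if ncut_old > 0:
                    nL = 0
                    sL = 0.0
                    nR = 0
                    sR = 0.0
                    nLa = 0
                    for i in range(n):
                        kk = leaf_of[t, i]
                        if kk == c1 or kk == c2:
                            if X[i, v_new] < cut_new:
                                nLa += 1
                            if use_row[i]:
                                r = y[i] - fit[i] + old_g[i]
                                if X[i, v_new] < cut_new:
                                    nL += 1
                                    sL += r
                                else:
                                    nR += 1
                                    sR += r
                    # both children keep >= 1 row by cutpoint construction
                    log_ml = (_log_ml(nL, sL, sigma2, tau2)
                              + _log_ml(nR, sR, sigma2, tau2)
                              - _log_ml(n_eff[c1], s_eff[c1], sigma2, tau2)
                              - _log_ml(n_eff[c2], s_eff[c2], sigma2, tau2))
                    # rule-prior ratio ncut_old/ncut_new cancels the
                    # proposal ratio ncut_new/ncut_old: ML ratio only
                    if np.log(np.random.random()) < log_ml:
                        feat[t, k] = v_new
                        thresh[t, k] = cut_new
                        n_eff[c1] = nL
                        s_eff[c1] = sL
                        n_eff[c2] = nR
                        s_eff[c2] = sR
                        for i in range(n):
                            kk = leaf_of[t, i]
                            if kk == c1 or kk == c2:
                                if X[i, v_new] < cut_new:
                                    leaf_of[t, i] = c1
                                else:
                                    leaf_of[t, i] = c2

        # ---- redraw every leaf value from its conjugate posterior ----
        # n_eff/s_eff were updated in place by whichever move was accepted,
        # so they reflect the current memberships (residuals w.r.t. old_g)
        for k in range(K):
            if state[t, k] == LEAF:
                denom = sigma2 + n_eff[k] * tau2
                post_mean = tau2 * s_eff[k] / denom
                post_sd = np.sqrt(sigma2 * tau2 / denom)
                leaf_val[t, k] = post_mean + post_sd * np.random.standard_normal()
        for i in range(n):
            fit[i] += leaf_val[t, leaf_of[t, i]] - old_g[i]


@njit(cache=True)
def draw_sigma2(y, fit, use_row, nu, lam):
    n_eff = 0
    sse = 0.0
    for i in range(y.shape[0]):
        if use_row[i]:
            d = y[i] - fit[i]
            sse += d * d
            n_eff += 1
    return (nu * lam + sse) / np.random.chisquare(nu + n_eff)


@njit(cache=True)
def run_bart(X, y, m, max_depth, base, power, tau2, nu, lam,
             p_grow, p_prune, n_burn, n_keep, seed,
             keep_feat, keep_thresh, keep_state, keep_leafval,
             keep_fit, keep_sigma2):
    """Full continuous-outcome BART run; fills the keep_* arrays in place."""
    np.random.seed(seed)
    n, p = X.shape
    K = 2 ** (max_depth + 1) - 1
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

    # sigma2 init: variance of y
    mu0 = 0.0
    for i in range(n):
        mu0 += y[i]
    mu0 /= n
    s2 = 0.0
    for i in range(n):
        s2 += (y[i] - mu0) ** 2
    sigma2 = s2 / max(n - 1, 1)
    if sigma2 <= 0.0:
        sigma2 = 1e-12

    total = n_burn + n_keep
    for it in range(total):
        sweep_forest(X, y, fit, use_row, feat, thresh, state, leaf_val,
                     leaf_of, sigma2, tau2, base, power, p_grow, p_prune,
                     max_depth, depth_of, scratch_vals, scratch_nodes)
        sigma2 = draw_sigma2(y, fit, use_row, nu, lam)
        if it >= n_burn:
            j = it - n_burn
            for t in range(m):
                for k in range(K):
                    keep_feat[j, t, k] = feat[t, k]
                    keep_thresh[j, t, k] = thresh[t, k]
                    keep_state[j, t, k] = state[t, k]
                    keep_leafval[j, t, k] = leaf_val[t, k]
            for i in range(n):
                keep_fit[j, i] = fit[i]
            keep_sigma2[j] = sigma2


@njit(cache=True)
def predict_forests(keep_feat, keep_thresh, keep_state, keep_leafval, Xnew):
    """Evaluate every kept forest draw on new rows -> (n_keep, n_new)."""
    n_keep, m, K = keep_state.shape
    n_new = Xnew.shape[0]
    out = np.zeros((n_keep, n_new), dtype=np.float64)
    for j in range(n_keep):
        for t in range(m):
            for i in range(n_new):
                k = 0
                while keep_state[j, t, k] == INTERNAL:
                    if Xnew[i, keep_feat[j, t, k]] < keep_thresh[j, t, k]:
                        k = 2 * k + 1
                    else:
                        k = 2 * k + 2
                out[j, i] += keep_leafval[j, t, k]
    return out


@njit(cache=True)
def update_leaf_scale(leaf_val, state, leaf_of, use_row, sig, s0,
                      step=0.3, n_mh=3):
    """MH update (log-scale random walk) of a forest's leaf-prior SD under
    a half-normal hyperprior with scale s0, given current leaf values.

    This adaptive shrinkage is what lets a moderating forest collapse
    toward zero when the data carry no effect, instead of cheaply
    absorbing residual confounding across many trees.  Only data-informed
    leaves (reached by at least one likelihood row) enter the update;
    empty leaves hold fresh prior draws, which carry no information about
    the scale and would only make it sticky.
    """
    m, K = state.shape
    n = leaf_of.shape[1]
    informed = np.zeros((m, K), dtype=np.uint8)
    for t in range(m):
        for i in range(n):
            if use_row[i]:
                informed[t, leaf_of[t, i]] = 1
    ssq = 0.0
    cnt = 0
    for t in range(m):
        for k in range(K):
            if state[t, k] == LEAF and informed[t, k]:
                v = leaf_val[t, k]
                ssq += v * v
                cnt += 1
    if cnt == 0:
        return sig
    for _ in range(n_mh):
        prop = sig * np.exp(step * np.random.standard_normal())
        lp_new = (-cnt * np.log(prop) - ssq / (2.0 * prop * prop)
                  - (prop * prop) / (2.0 * s0 * s0) + np.log(prop))
        lp_old = (-cnt * np.log(sig) - ssq / (2.0 * sig * sig)
                  - (sig * sig) / (2.0 * s0 * s0) + np.log(sig))
        if np.log(np.random.random()) < lp_new - lp_old:
            sig = prop
    return sig


@njit(cache=True)
def run_bcf(X_mu, X_tau, y, z, m_mu, m_tau, max_depth,
            base_mu, power_mu, base_tau, power_tau,
            tau2_mu, tau2_tau, nu, lam, p_grow, p_prune,
            n_burn, n_keep, seed,
            keep_mu, keep_tau, keep_sigma2):
    """Bayesian causal forest run: y = mu(x, pihat) + tau(x) * z + eps.

    keep_mu / keep_tau are (n_keep, n) and receive per-row draws of the
    prognostic and moderating forests on the outcome's internal scale.
    """
    np.random.seed(seed)
    n = y.shape[0]
    K = 2 ** (max_depth + 1) - 1

    feat_m = np.zeros((m_mu, K), dtype=np.int64)
    thr_m = np.zeros((m_mu, K), dtype=np.float64)
    st_m = np.zeros((m_mu, K), dtype=np.int8)
    lv_m = np.zeros((m_mu, K), dtype=np.float64)
    lo_m = np.zeros((m_mu, n), dtype=np.int64)
    st_m[:, 0] = LEAF

    feat_t = np.zeros((m_tau, K), dtype=np.int64)
    thr_t = np.zeros((m_tau, K), dtype=np.float64)
    st_t = np.zeros((m_tau, K), dtype=np.int8)
    lv_t = np.zeros((m_tau, K), dtype=np.float64)
    lo_t = np.zeros((m_tau, n), dtype=np.int64)
    st_t[:, 0] = LEAF

    fit_mu = np.zeros(n, dtype=np.float64)
    fit_tau = np.zeros(n, dtype=np.float64)
    all_rows = np.ones(n, dtype=np.uint8)
    treated = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        treated[i] = 1 if z[i] > 0 else 0

    depth_of = np.zeros(K, dtype=np.int64)
    for k in range(1, K):
        depth_of[k] = depth_of[(k - 1) // 2] + 1
    scratch_vals = np.empty(n, dtype=np.float64)
    scratch_nodes = np.empty(K, dtype=np.int64)

    mu0 = 0.0
    for i in range(n):
        mu0 += y[i]
    mu0 /= n
    s2 = 0.0
    for i in range(n):
        s2 += (y[i] - mu0) ** 2
    sigma2 = s2 / max(n - 1, 1)
    if sigma2 <= 0.0:
        sigma2 = 1e-12

    y_work = np.empty(n, dtype=np.float64)
    resid = np.empty(n, dtype=np.float64)

    # adaptive leaf scale of the moderating forest: half-normal hyperprior
    # with scale sqrt(tau2_tau)
    s0_tau = np.sqrt(tau2_tau)
    sig_tau = s0_tau

    total = n_burn + n_keep
    for it in range(total):
        # mu forest targets y - z*tau
        for i in range(n):
            y_work[i] = y[i] - z[i] * fit_tau[i]
        sweep_forest(X_mu, y_work, fit_mu, all_rows, feat_m, thr_m, st_m,
                     lv_m, lo_m, sigma2, tau2_mu, base_mu, power_mu,
                     p_grow, p_prune, max_depth, depth_of,
                     scratch_vals, scratch_nodes)
        # tau forest targets (y - mu) on treated rows
        for i in range(n):
            y_work[i] = y[i] - fit_mu[i]
        sweep_forest(X_tau, y_work, fit_tau, treated, feat_t, thr_t, st_t,
                     lv_t, lo_t, sigma2, sig_tau * sig_tau, base_tau,
                     power_tau, p_grow, p_prune, max_depth, depth_of,
                     scratch_vals, scratch_nodes)
        sig_tau = update_leaf_scale(lv_t, st_t, lo_t, treated, sig_tau, s0_tau)
        # sigma2 from the full residual
        for i in range(n):
            resid[i] = y[i] - fit_mu[i] - z[i] * fit_tau[i]
        sse = 0.0
        for i in range(n):
            sse += resid[i] * resid[i]
        sigma2 = (nu * lam + sse) / np.random.chisquare(nu + n)
        if it >= n_burn:
            j = it - n_burn
            for i in range(n):
                keep_mu[j, i] = fit_mu[i]
                keep_tau[j, i] = fit_tau[i]
            keep_sigma2[j] = sigma2
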