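"""Numba Gibbs-sampler kernels for the animal and marker-regression models.

All kernels use single-site (scalar or 2-vector) updates with residual
bookkeeping, so one sweep costs O(number of records + nonzeros of A-inverse
+ n * m for markers).  The pedigree random effect is parameterized through
the sparse inverse of the numerator relationship matrix (CSR triplets), so
no dense solve ever happens inside the chain.

Each kernel seeds numba's own RNG from the integer it is given, making
runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def _inv_gaussian(mu, lam):
    """One draw from InverseGaussian(mu, lam) (Michael-Schucany-Haas).

    For very large mu/lam the naive formula cancels catastrophically; the
    smaller root then equals lam/chi2_1 (the Levy limit), used directly.
    """
    v = np.random.standard_normal()
    y = v * v
    w = y * mu / lam
    if w > 1e6:
        x = mu / w  # = lam / y, the Levy-limit root
    else:
        x = mu * (1.0 + 0.5 * (w - np.sqrt(w * (w + 4.0))))
        if x <= 0.0:
            x = mu * 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _inv_gamma(shape, scale):
    """One draw from InvGamma(shape, scale) via 1/Gamma(shape, 1/scale)."""
    return scale / np.random.gamma(shape, 1.0)


@njit(cache=True)
def _quad_form_csr(indptr, indices, data, x):
    """x' Q x for CSR matrix Q."""
    total = 0.0
    for i in range(x.shape[0]):
        row = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            row += data[jj] * x[indices[jj]]
        total += x[i] * row
    return total


@njit(cache=True)
def _cross_form_csr(indptr, indices, data, a):
    """a' Q a (2x2) for a with two columns."""
    out = np.zeros((2, 2))
    n = a.shape[0]
    for i in range(n):
        r0 = 0.0
        r1 = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            j = indices[jj]
            r0 += data[jj] * a[j, 0]
            r1 += data[jj] * a[j, 1]
        out[0, 0] += a[i, 0] * r0
        out[0, 1] += a[i, 0] * r1
        out[1, 0] += a[i, 1] * r0
        out[1, 1] += a[i, 1] * r1
    return out


@njit(cache=True)
def _inv_wishart_2x2(S, df):
    """One draw from InvWishart(S, df) for a 2x2 scale matrix S."""
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    Sinv00 = S[1, 1] / det
    Sinv11 = S[0, 0] / det
    Sinv10 = -S[1, 0] / det
    # cholesky of S^-1
    l11 = np.sqrt(Sinv00)
    l21 = Sinv10 / l11
    l22 = np.sqrt(Sinv11 - l21 * l21)
    # Bartlett factor
    c11 = np.sqrt(np.random.chisquare(df))
    c22 = np.sqrt(np.random.chisquare(df - 1.0))
    n21 = np.random.standard_normal()
    a11 = l11 * c11
    a21 = l21 * c11 + l22 * n21
    a22 = l22 * c22
    # W = (LB)(LB)' ~ Wishart(S^-1, df); return W^-1
    W00 = a11 * a11
    W01 = a11 * a21
    W11 = a21 * a21 + a22 * a22
    detW = W00 * W11 - W01 * W01
    out = np.empty((2, 2))
    out[0, 0] = W11 / detW
    out[1, 1] = W00 / detW
    out[0, 1] = -W01 / detW
    out[1, 0] = -W01 / detW
    return out


@njit(cache=True)
def _gaussian_loglik_dev(e, sig_e):
    """-2 log N(e | 0, sig_e I)."""
    N = e.shape[0]
    return N * np.log(2.0 * np.pi * sig_e) + (e @ e) / sig_e


# ---------------------------------------------------------------------------
# univariate animal model
# ---------------------------------------------------------------------------


@njit(cache=True)
def animal_univariate(
    y, rec_block, n_blocks,
    ind_rec_ptr, ind_rec_idx,
    ai_indptr, ai_indices, ai_data,
    niter, burnin, thin,
    nu_a, Sa, nu_e, Se, fixed_prior_var,
    seed,
):
    """Gibbs sampler for y = block + a + e with a ~ N(0, A sigma2_a).

    Records are grouped per individual by (ind_rec_ptr, ind_rec_idx);
    individuals without records are still sampled (their conditional is
    driven by relatives), which yields pedigree predictions for free.

    Returns thinned chains (sigma2_a, sigma2_e, deviance), posterior
    means of a and b, and the thinned chain of a.
    """
    np.random.seed(seed)
    N = y.shape[0]
    n_ind = ind_rec_ptr.shape[0] - 1
    n_keep = (niter - burnin) // thin

    nblock = np.zeros(n_blocks)
    for r in range(N):
        nblock[rec_block[r]] += 1.0

    a = np.zeros(n_ind)
    b = np.zeros(n_blocks)
    sig_a = Sa if Sa > 0 else 0.1
    sig_e = Se if Se > 0 else 0.1
    e = y.copy()

    chain_sa = np.empty(n_keep)
    chain_se = np.empty(n_keep)
    chain_dev = np.empty(n_keep)
    a_chain = np.empty((n_keep, n_ind))
    a_mean = np.zeros(n_ind)
    b_mean = np.zeros(n_blocks)
    kept = 0

    delta = np.zeros(n_blocks)
    for it in range(niter):
        # --- block effects ---
        sums = np.zeros(n_blocks)
        for r in range(N):
            sums[rec_block[r]] += e[r] + b[rec_block[r]]
        for j in range(n_blocks):
            prec = nblock[j] / sig_e + 1.0 / fixed_prior_var
            mean = (sums[j] / sig_e) / prec
            new = mean + np.random.standard_normal() / np.sqrt(prec)
            delta[j] = new - b[j]
            b[j] = new
        for r in range(N):
            e[r] -= delta[rec_block[r]]

        # --- breeding values, single-site ---
        for i in range(n_ind):
            dii = 0.0
            neigh = 0.0
            for jj in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[jj]
                if j == i:
                    dii += ai_data[jj]
                else:
                    neigh += ai_data[jj] * a[j]
            num = -neigh / sig_a
            nrec_i = 0.0
            for rr in range(ind_rec_ptr[i], ind_rec_ptr[i + 1]):
                r = ind_rec_idx[rr]
                num += (e[r] + a[i]) / sig_e
                nrec_i += 1.0
            prec = nrec_i / sig_e + dii / sig_a
            new = num / prec + np.random.standard_normal() / np.sqrt(prec)
            d = new - a[i]
            for rr in range(ind_rec_ptr[i], ind_rec_ptr[i + 1]):
                e[ind_rec_idx[rr]] -= d
            a[i] = new

        # --- variance components ---
        qf = _quad_form_csr(ai_indptr, ai_indices, ai_data, a)
        sig_a = _inv_gamma(0.5 * (nu_a + n_ind), 0.5 * (nu_a * Sa + qf))
        sse = e @ e
        sig_e = _inv_gamma(0.5 * (nu_e + N), 0.5 * (nu_e * Se + sse))

        if it >= burnin and (it - burnin) % thin == 0:
            chain_sa[kept] = sig_a
            chain_se[kept] = sig_e
            chain_dev[kept] = _gaussian_loglik_dev(e, sig_e)
            a_chain[kept] = a
            a_mean += a
            b_mean += b
            kept += 1

    a_mean /= kept
    b_mean /= kept
    return chain_sa, chain_se, chain_dev, a_mean, b_mean, a_chain


# ---------------------------------------------------------------------------
# bivariate (two-site) animal model
# ---------------------------------------------------------------------------


@njit(cache=True)
def animal_bivariate(
    y, rec_block, rec_site, n_blocks,
    ind_rec, ind_site,
    ai_indptr, ai_indices, ai_data,
    niter, burnin, thin,
    nu_c, Vc, nu_e, Ve, fixed_prior_var,
    seed,
):
    """Gibbs sampler for the two-site model with genetic covariance C x A.

    Each individual has at most one record (ind_rec = record index or -1)
    observed at site ind_site; the residual covariance across sites is
    structurally zero.  Returns thinned chains of (C11, C22, C12,
    sigma2_e1, sigma2_e2, deviance), posterior mean of a (n x 2), and the
    thinned chains of a at the observed site.
    """
    np.random.seed(seed)
    N = y.shape[0]
    n_ind = ind_rec.shape[0]
    n_keep = (niter - burnin) // thin

    nblock = np.zeros(n_blocks)
    block_site = np.zeros(n_blocks, dtype=np.int64)
    for r in range(N):
        nblock[rec_block[r]] += 1.0
        block_site[rec_block[r]] = rec_site[r]

    a = np.zeros((n_ind, 2))
    b = np.zeros(n_blocks)
    C = np.eye(2) * (Vc if Vc > 0 else 0.1)
    sig_e = np.full(2, Ve if Ve > 0 else 0.1)
    e = y.copy()

    chain = np.empty((n_keep, 6))
    a_mean = np.zeros((n_ind, 2))
    a_obs_chain = np.empty((n_keep, n_ind))
    kept = 0

    delta = np.zeros(n_blocks)
    for it in range(niter):
        # --- block effects (site-specific residual variance) ---
        sums = np.zeros(n_blocks)
        for r in range(N):
            sums[rec_block[r]] += e[r] + b[rec_block[r]]
        for j in range(n_blocks):
            se = sig_e[block_site[j]]
            prec = nblock[j] / se + 1.0 / fixed_prior_var
            mean = (sums[j] / se) / prec
            new = mean + np.random.standard_normal() / np.sqrt(prec)
            delta[j] = new - b[j]
            b[j] = new
        for r in range(N):
            e[r] -= delta[rec_block[r]]

        # --- C inverse ---
        detC = C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
        Ci00 = C[1, 1] / detC
        Ci11 = C[0, 0] / detC
        Ci01 = -C[0, 1] / detC

        # --- breeding values: 2-vector single-site updates ---
        for i in range(n_ind):
            dii = 0.0
            n0 = 0.0
            n1 = 0.0
            for jj in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[jj]
                if j == i:
                    dii += ai_data[jj]
                else:
                    n0 += ai_data[jj] * a[j, 0]
                    n1 += ai_data[jj] * a[j, 1]
            # prior precision block and rhs
            P00 = dii * Ci00
            P11 = dii * Ci11
            P01 = dii * Ci01
            r0 = -(Ci00 * n0 + Ci01 * n1)
            r1 = -(Ci01 * n0 + Ci11 * n1)
            rec = ind_rec[i]
            if rec >= 0:
                s = ind_site[i]
                se = sig_e[s]
                if s == 0:
                    P00 += 1.0 / se
                    r0 += (e[rec] + a[i, 0]) / se
                else:
                    P11 += 1.0 / se
                    r1 += (e[rec] + a[i, 1]) / se
            # sample from N(P^-1 r, P^-1) via 2x2 cholesky of P
            L00 = np.sqrt(P00)
            L10 = P01 / L00
            L11 = np.sqrt(P11 - L10 * L10)
            # mean: solve P mu = r
            z0 = r0 / L00
            z1 = (r1 - L10 * z0) / L11
            mu1 = z1 / L11
            mu0 = (z0 - L10 * mu1) / L00
            # noise: solve L' x = z with z standard normal
            g0 = np.random.standard_normal()
            g1 = np.random.standard_normal()
            x1 = g1 / L11
            x0 = (g0 - L10 * x1) / L00
            new0 = mu0 + x0
            new1 = mu1 + x1
            if rec >= 0:
                if ind_site[i] == 0:
                    e[rec] -= new0 - a[i, 0]
                else:
                    e[rec] -= new1 - a[i, 1]
            a[i, 0] = new0
            a[i, 1] = new1

        # --- genetic covariance matrix ---
        S = _cross_form_csr(ai_indptr, ai_indices, ai_data, a)
        S[0, 0] += nu_c * Vc
        S[1, 1] += nu_c * Vc
        C = _inv_wishart_2x2(S, nu_c + n_ind)

        # --- site residual variances ---
        for s in range(2):
            sse = 0.0
            ns = 0.0
            for r in range(N):
                if rec_site[r] == s:
                    sse += e[r] * e[r]
                    ns += 1.0
            sig_e[s] = _inv_gamma(0.5 * (nu_e + ns), 0.5 * (nu_e * Ve + sse))

        if it >= burnin and (it - burnin) % thin == 0:
            chain[kept, 0] = C[0, 0]
            chain[kept, 1] = C[1, 1]
            chain[kept, 2] = C[0, 1]
            chain[kept, 3] = sig_e[0]
            chain[kept, 4] = sig_e[1]
            dev = 0.0
            for r in range(N):
                se = sig_e[rec_site[r]]
                dev += np.log(2.0 * np.pi * se) + e[r] * e[r] / se
            chain[kept, 5] = dev
            a_mean += a
            for i in range(n_ind):
                a_obs_chain[kept, i] = a[i, ind_site[i]]
            kept += 1

    a_mean /= kept
    return chain, a_mean, a_obs_chain


# ---------------------------------------------------------------------------
# whole-genome marker regression (ridge / Bayesian LASSO, +- polygenic)
# ---------------------------------------------------------------------------


@njit(cache=True)
def marker_gibbs(
    y, Z,
    ind_rec_ptr, ind_rec_idx,
    ai_indptr, ai_indices, ai_data,
    use_polygenic, use_lasso,
    niter, burnin, thin,
    nu_u, Su, nu_a, Sa, nu_e, Se,
    lambda_shape, lambda_rate,
    sample_sigma_u, sample_sigma_e,
    init_sigma_u, init_sigma_e,
    seed,
):
    """Gibbs sampler for y = mu + Z u + (a) + e.

    Ridge: u_k ~ N(0, sigma2_u) with a common scaled-inv-chi2 variance.
    LASSO: u_k ~ N(0, sigma2_e tau2_k), 1/tau2_k inverse-Gaussian, and
    lambda^2 ~ Gamma(lambda_shape, lambda_rate) updated from the data.
    Z must be Fortran-ordered with columns in canonical (marker-ID) order;
    rows align with the records in y.  The polygenic effect, when active,
    runs over all pedigree individuals via the sparse A-inverse.

    Returns posterior-mean u, mu, a, thinned chains of
    (sigma2_u, sigma2_a, sigma2_e, lambda2, deviance).
    """
    np.random.seed(seed)
    N = y.shape[0]
    m = Z.shape[1]
    n_ind = ind_rec_ptr.shape[0] - 1
    n_keep = (niter - burnin) // thin

    zz = np.empty(m)
    for k in range(m):
        tot = 0.0
        for r in range(N):
            tot += Z[r, k] * Z[r, k]
        zz[k] = tot

    u = np.zeros(m)
    a = np.zeros(n_ind)
    mu = 0.0
    sig_u = init_sigma_u
    sig_e = init_sigma_e
    sig_a = Sa if Sa > 0 else 0.1
    tau2 = np.ones(m)
    lam2 = lambda_shape / lambda_rate if use_lasso else 0.0
    e = y.copy()

    u_mean = np.zeros(m)
    a_mean = np.zeros(n_ind)
    mu_mean = 0.0
    chain = np.empty((n_keep, 5))
    kept = 0

    for it in range(niter):
        # --- intercept (flat prior) ---
        tot = 0.0
        for r in range(N):
            tot += e[r] + mu
        new_mu = tot / N + np.random.standard_normal() * np.sqrt(sig_e / N)
        for r in range(N):
            e[r] -= new_mu - mu
        mu = new_mu

        # --- marker effects, canonical order ---
        for k in range(m):
            if zz[k] == 0.0:
                u[k] = 0.0
                continue
            prior_var = sig_e * tau2[k] if use_lasso else sig_u
            old = u[k]
            num = zz[k] * old
            for r in range(N):
                num += Z[r, k] * e[r]
            prec = zz[k] / sig_e + 1.0 / prior_var
            mean = (num / sig_e) / prec
            new = mean + np.random.standard_normal() / np.sqrt(prec)
            d = new - old
            for r in range(N):
                e[r] -= d * Z[r, k]
            u[k] = new

        # --- polygenic effect ---
        if use_polygenic:
            for i in range(n_ind):
                dii = 0.0
                neigh = 0.0
                for jj in range(ai_indptr[i], ai_indptr[i + 1]):
                    j = ai_indices[jj]
                    if j == i:
                        dii += ai_data[jj]
                    else:
                        neigh += ai_data[jj] * a[j]
                num = -neigh / sig_a
                nrec_i = 0.0
                for rr in range(ind_rec_ptr[i], ind_rec_ptr[i + 1]):
                    r = ind_rec_idx[rr]
                    num += (e[r] + a[i]) / sig_e
                    nrec_i += 1.0
                prec = nrec_i / sig_e + dii / sig_a
                new = num / prec + np.random.standard_normal() / np.sqrt(prec)
                d = new - a[i]
                for rr in range(ind_rec_ptr[i], ind_rec_ptr[i + 1]):
                    e[ind_rec_idx[rr]] -= d
                a[i] = new
            qf = _quad_form_csr(ai_indptr, ai_indices, ai_data, a)
            sig_a = _inv_gamma(0.5 * (nu_a + n_ind), 0.5 * (nu_a * Sa + qf))

        # --- shrinkage hyperparameters ---
        uu = u @ u
        if use_lasso:
            sum_tau2 = 0.0
            for k in range(m):
                mu_ig = np.sqrt(lam2 * sig_e / (u[k] * u[k] + 1e-30))
                inv_tau2 = _inv_gaussian(mu_ig, lam2)
                tau2[k] = 1.0 / inv_tau2
                sum_tau2 += tau2[k]
            lam2 = np.random.gamma(lambda_shape + m, 1.0) / (
                lambda_rate + 0.5 * sum_tau2
            )
        elif sample_sigma_u:
            sig_u = _inv_gamma(0.5 * (nu_u + m), 0.5 * (nu_u * Su + uu))

        # --- residual variance ---
        if sample_sigma_e:
            sse = e @ e
            if use_lasso:
                scaled = 0.0
                for k in range(m):
                    scaled += u[k] * u[k] / tau2[k]
                sig_e = _inv_gamma(
                    0.5 * (nu_e + N + m), 0.5 * (nu_e * Se + sse + scaled)
                )
            else:
                sig_e = _inv_gamma(0.5 * (nu_e + N), 0.5 * (nu_e * Se + sse))

        if it >= burnin and (it - burnin) % thin == 0:
            chain[kept, 0] = sig_u
            chain[kept, 1] = sig_a
            chain[kept, 2] = sig_e
            chain[kept, 3] = lam2
            chain[kept, 4] = _gaussian_loglik_dev(e, sig_e)
            u_mean += u
            a_mean += a
            mu_mean += mu
            kept += 1

    u_mean /= kept
    a_mean /= kept
    mu_mean /= kept
    return u_mean, mu_mean, a_mean, chain
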