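"""Numba core of the adaptive Metropolis-within-Gibbs sampler.

State per chain: log φ per gene, ΔM per (regime, codon), Δη per codon
(reference entries frozen at 0), log s_φ. One sweep:

1. per-gene random walk on log φ (independent accept/reject per gene);
2. per-family block random walks: one block per (family, regime) on that
   regime's ΔM entries (only that regime's genes enter the ratio), one
   block per family on the shared Δη entries;
3. random walk on log s_φ (φ-prior + half-normal prior term only);
4. scale handling: by default φ is renormalized to sample mean 1 after
   every sweep with Δη absorbing the factor (the likelihood is exactly
   invariant under φ→cφ, Δη→Δη/c, so this fixes the conventional gauge);
   alternatively a likelihood-invariant MH scale move with Jacobian c^{-K}
   leaves the pinning to the priors.

The per-(gene, family) log-likelihood terms are cached and refreshed
incrementally on acceptance, so a sweep costs about three full likelihood
passes. Proposal scales adapt by Robbins-Monro toward the target
acceptance rate during burn-in only; adaptation is frozen afterwards so
the post-burn-in kernel satisfies detailed balance. Randomness comes from
numba's np.random state, seeded once per chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False, inline="always")
def _fam_ll_one(counts, g, a, b, dM, deta, r, p):
    """Log-likelihood contribution of family slice [a, b) for gene g."""
    mx = -1.0e300
    for j in range(a, b):
        z = -(dM[r, j] + deta[j] * p)
        if z > mx:
            mx = z
    s = 0.0
    tot = 0.0
    ll = 0.0
    for j in range(a, b):
        z = -(dM[r, j] + deta[j] * p)
        s += math.exp(z - mx)
        cj = counts[g, j]
        if cj > 0.0:
            ll += cj * z
            tot += cj
    if tot > 0.0:
        return ll - tot * (mx + math.log(s))
    return 0.0


@njit(cache=False)
def per_gene_loglik(counts, fam_ptr, dM, deta, phi, regime, out):
    """Multinomial log-likelihood per gene (constant dropped).

    counts : (G, M) active-codon counts grouped contiguously by family
    fam_ptr : (F+1,) family slice boundaries; dM : (R, M); deta : (M,)
    """
    G = counts.shape[0]
    F = fam_ptr.size - 1
    for g in range(G):
        ll = 0.0
        for f in range(F):
            ll += _fam_ll_one(
                counts, g, fam_ptr[f], fam_ptr[f + 1], dM, deta, regime[g], phi[g]
            )
        out[g] = ll


@njit(cache=False)
def family_loglik(counts, a, b, dM, deta, phi, regime, genes):
    """Total log-likelihood of one family slice [a, b) over the given genes."""
    total = 0.0
    for gi in range(genes.size):
        g = genes[gi]
        total += _fam_ll_one(counts, g, a, b, dM, deta, regime[g], phi[g])
    return total


@njit(cache=False)
def _phi_logprior(logphi, s, mu_factor):
    m = mu_factor * s * s
    G = logphi.size
    tot = 0.0
    for g in range(G):
        d = logphi[g] - m
        tot += d * d
    return -G * math.log(s) - tot / (2.0 * s * s)


@njit(cache=False)
def _run_chain_jit(
    counts,  # (G, M) float64
    fam_ptr,  # (F+1,) int64
    free_mask,  # (M,) bool
    regime,  # (G,) int64
    n_regimes,  # int
    iterations,
    burn_in,
    thin,
    target,
    adapt,  # bool
    tau,
    hn_scale,
    mu_factor,  # 0.0 (mean-log-zero) or -0.5 (E[phi]=1)
    fix_phi_mean,  # project onto mean(phi)=1 each sweep instead of scale move
    seed,
    dM,  # (R, M) initial, modified in place
    deta,  # (M,) initial
    logphi,  # (G,) initial
    s_phi0,
):
    np.random.seed(seed)
    G, M = counts.shape
    F = fam_ptr.size - 1
    R = n_regimes
    s_phi = s_phi0
    tau2 = tau * tau
    hn2 = hn_scale * hn_scale

    free_idx = np.flatnonzero(free_mask)
    K = free_idx.size
    regime_genes = np.empty((R, G), dtype=np.int64)
    regime_n = np.zeros(R, dtype=np.int64)
    for g in range(G):
        r = regime[g]
        regime_genes[r, regime_n[r]] = g
        regime_n[r] += 1

    ls_phi = np.full(G, math.log(0.2))
    ls_dM = np.full((F, R), math.log(0.05))
    ls_deta = np.full(F, math.log(0.02))
    ls_s = math.log(0.1)
    ls_scale = math.log(0.05)

    n_keep = (iterations - burn_in) // thin
    out_dM = np.empty((n_keep, R, K))
    out_deta = np.empty((n_keep, K))
    out_phi = np.empty((n_keep, G))
    out_s = np.empty(n_keep)
    out_ll = np.empty(n_keep)

    acc_counts = np.zeros(5)  # phi, dM, deta, s, scale
    prop_counts = np.zeros(5)

    phi = np.exp(logphi)
    # cached per-(gene, family) log-likelihood terms and per-gene totals
    ll_fam = np.empty((G, F))
    ll_cur = np.zeros(G)
    for g in range(G):
        t = 0.0
        for f in range(F):
            v = _fam_ll_one(
                counts, g, fam_ptr[f], fam_ptr[f + 1], dM, deta, regime[g], phi[g]
            )
            ll_fam[g, f] = v
            t += v
        ll_cur[g] = t

    old_block = np.empty(M)
    scratch = np.empty(G)
    fam_row = np.empty(F)
    kept = 0
    for it in range(iterations):
        adapting = adapt and it < burn_in
        gamma = (1.0 / (1.0 + it / 50.0) ** 0.6) if adapting else 0.0

        # ---- per-gene log-phi random walk ----
        mu = mu_factor * s_phi * s_phi
        for g in range(G):
            lp_p = logphi[g] + math.exp(ls_phi[g]) * np.random.standard_normal()
            p_p = math.exp(lp_p)
            r = regime[g]
            ll_new = 0.0
            for f in range(F):
                fam_row[f] = _fam_ll_one(counts, g, fam_ptr[f], fam_ptr[f + 1], dM, deta, r, p_p)
                ll_new += fam_row[f]
            d0 = logphi[g] - mu
            d1 = lp_p - mu
            la = (ll_new - ll_cur[g]) + (d0 * d0 - d1 * d1) / (2.0 * s_phi * s_phi)
            ok = math.log(np.random.random()) < la
            if ok:
                logphi[g] = lp_p
                phi[g] = p_p
                ll_cur[g] = ll_new
                for f in range(F):
                    ll_fam[g, f] = fam_row[f]
                acc_counts[0] += 1.0
            prop_counts[0] += 1.0
            if adapting:
                ls_phi[g] += gamma * ((1.0 if ok else 0.0) - target)
                if ls_phi[g] < -9.2:
                    ls_phi[g] = -9.2
                elif ls_phi[g] > 1.6:
                    ls_phi[g] = 1.6

        # ---- per-family blocks ----
        for f in range(F):
            a = fam_ptr[f]
            b = fam_ptr[f + 1]
            nfree = 0
            for j in range(a, b):
                if free_mask[j]:
                    nfree += 1
            if nfree == 0:
                continue
            # ΔM block per regime (cached current values; only proposal computed)
            for r in range(R):
                n_r = regime_n[r]
                if n_r == 0:
                    continue
                genes_r = regime_genes[r]
                cur = 0.0
                for gi in range(n_r):
                    cur += ll_fam[genes_r[gi], f]
                step = math.exp(ls_dM[f, r])
                dpr = 0.0
                for j in range(a, b):
                    if free_mask[j]:
                        old_block[j] = dM[r, j]
                        dM[r, j] = old_block[j] + step * np.random.standard_normal()
                        dpr += (old_block[j] * old_block[j] - dM[r, j] * dM[r, j]) / (2.0 * tau2)
                prop = 0.0
                for gi in range(n_r):
                    g = genes_r[gi]
                    scratch[g] = _fam_ll_one(counts, g, a, b, dM, deta, r, phi[g])
                    prop += scratch[g]
                ok = math.log(np.random.random()) < (prop - cur) + dpr
                if ok:
                    for gi in range(n_r):
                        g = genes_r[gi]
                        ll_cur[g] += scratch[g] - ll_fam[g, f]
                        ll_fam[g, f] = scratch[g]
                    acc_counts[1] += 1.0
                else:
                    for j in range(a, b):
                        if free_mask[j]:
                            dM[r, j] = old_block[j]
                prop_counts[1] += 1.0
                if adapting:
                    ls_dM[f, r] += gamma * ((1.0 if ok else 0.0) - target)
                    if ls_dM[f, r] < -9.2:
                        ls_dM[f, r] = -9.2
                    elif ls_dM[f, r] > 0.7:
                        ls_dM[f, r] = 0.7
            # Δη block (shared across regimes; all genes contribute)
            cur = 0.0
            for g in range(G):
                cur += ll_fam[g, f]
            step = math.exp(ls_deta[f])
            dpr = 0.0
            for j in range(a, b):
                if free_mask[j]:
                    old_block[j] = deta[j]
                    deta[j] = old_block[j] + step * np.random.standard_normal()
                    dpr += (old_block[j] * old_block[j] - deta[j] * deta[j]) / (2.0 * tau2)
            prop = 0.0
            for g in range(G):
                scratch[g] = _fam_ll_one(counts, g, a, b, dM, deta, regime[g], phi[g])
                prop += scratch[g]
            ok = math.log(np.random.random()) < (prop - cur) + dpr
            if ok:
                for g in range(G):
                    ll_cur[g] += scratch[g] - ll_fam[g, f]
                    ll_fam[g, f] = scratch[g]
                acc_counts[2] += 1.0
            else:
                for j in range(a, b):
                    if free_mask[j]:
                        deta[j] = old_block[j]
            prop_counts[2] += 1.0
            if adapting:
                ls_deta[f] += gamma * ((1.0 if ok else 0.0) - target)
                if ls_deta[f] < -9.2:
                    ls_deta[f] = -9.2
                elif ls_deta[f] > 0.7:
                    ls_deta[f] = 0.7

        # ---- log s_phi random walk (phi-prior + half-normal prior) ----
        ls = math.log(s_phi)
        ls_p = ls + math.exp(ls_s) * np.random.standard_normal()
        s_p = math.exp(ls_p)
        la = (
            _phi_logprior(logphi, s_p, mu_factor)
            - _phi_logprior(logphi, s_phi, mu_factor)
            - (s_p * s_p - s_phi * s_phi) / (2.0 * hn2)
            + (ls_p - ls)
        )
        ok = math.log(np.random.random()) < la
        if ok:
            s_phi = s_p
            acc_counts[3] += 1.0
        prop_counts[3] += 1.0
        if adapting:
            ls_s += gamma * ((1.0 if ok else 0.0) - target)
            if ls_s < -9.2:
                ls_s = -9.2
            elif ls_s > 0.7:
                ls_s = 0.7

        # ---- scale handling (likelihood exactly invariant; caches stay valid) ----
        if fix_phi_mean:
            c = phi.mean()
            lc = math.log(c)
            for g in range(G):
                logphi[g] -= lc
                phi[g] /= c
            for ki in range(K):
                deta[free_idx[ki]] *= c
        else:
            # MH scale move phi -> c*phi, deta -> deta/c with Jacobian c^{-K}
            eps = math.exp(ls_scale) * np.random.standard_normal()
            c = math.exp(eps)
            mu = mu_factor * s_phi * s_phi
            dpr = 0.0
            for g in range(G):
                d0 = logphi[g] - mu
                d1 = logphi[g] + eps - mu
                dpr += (d0 * d0 - d1 * d1) / (2.0 * s_phi * s_phi)
            for ki in range(K):
                j = free_idx[ki]
                nv = deta[j] / c
                dpr += (deta[j] * deta[j] - nv * nv) / (2.0 * tau2)
            la = dpr - eps * K
            ok = math.log(np.random.random()) < la
            if ok:
                for g in range(G):
                    logphi[g] += eps
                    phi[g] = math.exp(logphi[g])
                for ki in range(K):
                    deta[free_idx[ki]] /= c
                acc_counts[4] += 1.0
            prop_counts[4] += 1.0
            if adapting:
                ls_scale += gamma * ((1.0 if ok else 0.0) - target)
                if ls_scale < -9.2:
                    ls_scale = -9.2
                elif ls_scale > 0.0:
                    ls_scale = 0.0

        # ---- store thinned post-burn-in sample ----
        if it >= burn_in and (it - burn_in) % thin == 0:
            for r in range(R):
                for ki in range(K):
                    out_dM[kept, r, ki] = dM[r, free_idx[ki]]
            for ki in range(K):
                out_deta[kept, ki] = deta[free_idx[ki]]
            out_phi[kept] = phi
            out_s[kept] = s_phi
            out_ll[kept] = ll_cur.sum()
            kept += 1

    return (
        out_dM[:kept],
        out_deta[:kept],
        out_phi[:kept],
        out_s[:kept],
        out_ll[:kept],
        acc_counts,
        prop_counts,
    )


def run_chain(
    counts: np.ndarray,
    fam_ptr: np.ndarray,
    free_mask: np.ndarray,
    regime: np.ndarray,
    n_regimes: int,
    config,
    priors,
    seed: int,
    init_dM: np.ndarray,
    init_deta: np.ndarray,
    init_phi: np.ndarray,
    init_s_phi: float = 1.0,
) -> dict:
    """Run one chain; returns thinned post-burn-in samples and acceptance rates."""
    dM = np.ascontiguousarray(init_dM, dtype=np.float64).copy()
    deta = np.asarray(init_deta, dtype=np.float64).copy()
    logphi = np.log(np.asarray(init_phi, dtype=np.float64))
    out = _run_chain_jit(
        np.ascontiguousarray(counts, dtype=np.float64),
        np.asarray(fam_ptr, dtype=np.int64),
        np.asarray(free_mask, dtype=np.bool_),
        np.asarray(regime, dtype=np.int64),
        n_regimes,
        config.iterations,
        config.burn_in,
        config.thin,
        config.target_acceptance,
        config.adapt,
        priors.tau,
        priors.s_phi_scale,
        0.0 if getattr(priors, "mean_log_zero", False) else -0.5,
        bool(getattr(priors, "fix_phi_mean", True)),
        int(seed) % (2**31 - 1),
        dM,
        deta,
        logphi,
        float(init_s_phi),
    )
    out_dM, out_deta, out_phi, out_s, out_ll, acc, prop = out
    names = ["phi", "dM", "deta", "s", "scale"]
    rates = {n: float(acc[i] / max(prop[i], 1.0)) for i, n in enumerate(names)}
    return {
        "samples": {
            "dM": out_dM,
            "deta": out_deta,
            "phi": out_phi,
            "s_phi": out_s,
            "loglik": out_ll,
        },
        "acceptance_rates": rates,
        "free_idx": np.flatnonzero(free_mask),
    }
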