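"""Bayesian selection-mutation-drift model of synonymous codon usage.

For an amino acid with :math:`n_{aa}` synonymous codons, the probability of
observing codon *i* in gene *g* is

.. math::

    p_{i,g} = \\frac{e^{-\\Delta M_i - \\Delta\\eta_i \\phi_g}}
                   {\\sum_j^{n_{aa}} e^{-\\Delta M_j - \\Delta\\eta_j \\phi_g}}

where ΔM is mutation bias and Δη the selection coefficient of codon *i*
relative to the family's reference codon (the alphabetically last member,
both fixed at 0 for the reference), and φ_g is the gene's evolutionary
average expression, lognormal with mean 1 a priori. Observed codon counts
per family are multinomial with these probabilities. Selection on codon
usage is assumed weak (Nₑs ≪ 1); ΔM and Δη are composite, dimensionless
coefficients — Nₑ, s and mutation rates are not separately identified.

Two model forms:

* **ConstMut** — a single genome-wide set of mutation biases.
* **VarMut** — one ΔM set per mutation regime (e.g. clusters from
  :mod:`codonregimes.regime_clustering`), with selection coefficients Δη
  shared across regimes and a single φ per gene.

Fitting is by adaptive Metropolis-within-Gibbs MCMC (see ``_sampler``);
model comparison uses DIC = D(θ̄) + 2·p_D with p_D = D̄ − D(θ̄) (lower is
better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _sampler
from .genetic_code import GeneticCode, SENSE_CODONS
from .genome_io import CODON_INDEX, CodonCountTable
from .regime_clustering import RegimeAssignment

__all__ = [
    "MCMCConfig",
    "PriorConfig",
    "RocSempprModel",
    "RocSempprResults",
    "codon_probabilities",
    "gene_log_likelihood",
    "log_prior",
    "deviance",
    "dic_from_deviances",
    "rescale_to_AT_reference",
    "identify_optimal_codons",
    "convergence_check",
    "compare_models",
]


@dataclass
class MCMCConfig:
    """Sampler settings. ``desk()`` is the default working scale;
    ``full_scale()`` (200,000 iterations, thin 10, 50,000 burn-in, two
    chains) is the long-run configuration for real-genome analyses."""

    iterations: int = 20_000
    thin: int = 10
    burn_in: int = 5_000
    n_chains: int = 2
    seed: int = 0
    target_acceptance: float = 0.3
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if (self.iterations - self.burn_in) // self.thin < 1:
            raise ValueError("config retains zero post-burn-in samples")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def desk(cls, **kw) -> "MCMCConfig":
        return cls(**kw)

    @classmethod
    def full_scale(cls, **kw) -> "MCMCConfig":
        kw.setdefault("iterations", 200_000)
        kw.setdefault("thin", 10)
        kw.setdefault("burn_in", 50_000)
        kw.setdefault("n_chains", 2)
        return cls(**kw)


@dataclass
class PriorConfig:
    """Weakly-informative priors: ΔM, Δη ~ Normal(0, τ²); s_φ ~ Half-Normal.

    The φ prior is lognormal with location −s_φ²/2 so E[φ] = 1 a priori;
    ``mean_log_zero=True`` switches to the location-0 convention.

    ``fix_phi_mean=True`` (default) additionally renormalizes φ to sample
    mean 1 after every sweep, absorbing the factor into Δη. The likelihood
    is exactly invariant under (φ·c, Δη/c), so without this gauge fixing
    the scale is identified only through the priors, and with many weakly
    constrained Δη parameters the posterior volume along the ridge drags
    the scale away from 1; pinning the conventional mean-1 scale exactly is
    how the quotient model is usually sampled. Setting it False enables a
    likelihood-invariant MH scale move and leaves the pinning to the prior.
    """

    tau: float = 10.0
    s_phi_scale: float = 2.0
    mean_log_zero: bool = False
    fix_phi_mean: bool = True


# ---------------------------------------------------------------------------
# likelihood primitives (reference numpy implementations)
# ---------------------------------------------------------------------------


def codon_probabilities(delta_m: np.ndarray, delta_eta: np.ndarray, phi: float) -> np.ndarray:
    """Family codon probabilities softmax(−ΔM − Δη·φ), overflow-safe."""
    dm = np.asarray(delta_m, dtype=float)
    de = np.asarray(delta_eta, dtype=float)
    if not (np.all(np.isfinite(dm)) and np.all(np.isfinite(de)) and np.isfinite(phi)):
        raise ValueError("non-finite inputs")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    z = -(dm + de * phi)
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def gene_log_likelihood(
    counts: np.ndarray,
    genetic_code: GeneticCode,
    delta_m_row: np.ndarray,
    delta_eta: np.ndarray,
    phi: float,
) -> float:
    """Σ_families Σ_i c_i log p_i for one gene (multinomial constant dropped)."""
    c = np.asarray(counts)
    ll = 0.0
    for fam in genetic_code.multi_codon_families:
        idx = np.array([CODON_INDEX[x] for x in fam.codons])
        cf = c[idx]
        if cf.sum() == 0:
            continue
        p = codon_probabilities(delta_m_row[idx], delta_eta[idx], phi)
        ll += float(np.sum(cf * np.log(p)))
    return ll


def log_prior(
    delta_m: np.ndarray,
    delta_eta: np.ndarray,
    phi: np.ndarray,
    s_phi: float,
    genetic_code: GeneticCode,
    priors: PriorConfig = PriorConfig(),
) -> float:
    """Joint log prior: lognormal φ (E[φ]=1), Normal(0, τ²) coefficients,
    half-normal s_φ. Returns −inf for s_φ ≤ 0 or non-positive φ."""
    if s_phi <= 0 or np.any(np.asarray(phi) <= 0):
        return -np.inf
    phi = np.asarray(phi, dtype=float)
    mu = 0.0 if priors.mean_log_zero else -0.5 * s_phi**2
    lp = float(
        np.sum(stats.norm.logpdf(np.log(phi), mu, s_phi) - np.log(phi))
    )  # lognormal density in phi
    free = _free_codon_indices(genetic_code)
    dm = np.atleast_2d(delta_m)
    lp += float(np.sum(stats.norm.logpdf(dm[:, free], 0, priors.tau)))
    lp += float(np.sum(stats.norm.logpdf(np.asarray(delta_eta)[free], 0, priors.tau)))
    lp += float(stats.halfnorm.logpdf(s_phi, scale=priors.s_phi_scale))
    return lp


def _free_codon_indices(genetic_code: GeneticCode) -> np.ndarray:
    free = []
    for fam in genetic_code.multi_codon_families:
        ref = fam.reference
        free.extend(CODON_INDEX[c] for c in fam.codons if c != ref)
    return np.array(sorted(free))


def deviance(
    count_table: CodonCountTable,
    genetic_code: GeneticCode,
    delta_m: np.ndarray,
    delta_eta: np.ndarray,
    phi: np.ndarray,
    regimes: np.ndarray | None = None,
) -> float:
    """−2 × total log-likelihood at the given parameter values.

    ``delta_m`` may be (61,) for one regime or (R, 61) with ``regimes``
    giving each gene's regime index.
    """
    dm = np.atleast_2d(np.asarray(delta_m, dtype=float))
    reg = np.zeros(count_table.n_genes, dtype=int) if regimes is None else np.asarray(regimes)
    ll = 0.0
    for g in range(count_table.n_genes):
        ll += gene_log_likelihood(
            count_table.counts[g], genetic_code, dm[reg[g]], delta_eta, float(phi[g])
        )
    return -2.0 * ll


def dic_from_deviances(deviance_samples: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """(DIC, p_D) from per-sample deviances and the deviance at the
    posterior mean: p_D = D̄ − D(θ̄), DIC = D(θ̄) + 2 p_D."""
    d = np.asarray(deviance_samples, dtype=float)
    if d.size == 0:
        raise ValueError("empty deviance trace")
    d_bar = float(d.mean())
    p_d = d_bar - deviance_at_mean
    return deviance_at_mean + 2.0 * p_d, p_d


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class RocSempprModel:
    """Selection-mutation-drift codon usage model bound to a count table.

    Parameters
    ----------
    count_table : CodonCountTable
    regimes : RegimeAssignment, array of int, or None
        None fits the ConstMut form (one mutation-bias set); an assignment
        or integer vector fits VarMut (ΔM per regime, shared Δη).
    genetic_code : GeneticCode or str
    priors : PriorConfig
    """

    def __init__(
        self,
        count_table: CodonCountTable,
        regimes: RegimeAssignment | np.ndarray | None = None,
        genetic_code: GeneticCode | str = "standard",
        priors: PriorConfig | None = None,
    ) -> None:
        self.count_table = count_table
        self.genetic_code = (
            genetic_code
            if isinstance(genetic_code, GeneticCode)
            else GeneticCode.from_name(genetic_code)
        )
        self.priors = priors or PriorConfig()
        if regimes is None:
            self.regime_index = np.zeros(count_table.n_genes, dtype=np.int64)
        elif isinstance(regimes, RegimeAssignment):
            if list(regimes.gene_ids) != list(count_table.gene_ids):
                raise ValueError("regime assignment gene ids do not match count table")
            self.regime_index = regimes.regime_index()
        else:
            self.regime_index = np.asarray(regimes, dtype=np.int64)
            if self.regime_index.shape != (count_table.n_genes,):
                raise ValueError("regimes must have one entry per gene")
        self.n_regimes = int(self.regime_index.max()) + 1
        self._build_arrays()

    @property
    def is_varmut(self) -> bool:
        return self.n_regimes > 1

    def _build_arrays(self) -> None:
        gc = self.genetic_code
        cols: list[int] = []
        fam_ptr = [0]
        free_mask: list[bool] = []
        fam_ids: list[str] = []
        for fam in gc.multi_codon_families:
            fam_ids.append(fam.family_id)
            for c in fam.codons:
                cols.append(CODON_INDEX[c])
                free_mask.append(c != fam.reference)
            fam_ptr.append(len(cols))
        self._cols = np.array(cols)
        self._fam_ptr = np.array(fam_ptr, dtype=np.int64)
        self._free_mask = np.array(free_mask)
        self._fam_ids = fam_ids
        self._counts_active = self.count_table.counts[:, self._cols].astype(np.float64)

    # -- initial values ----------------------------------------------------
    def _loglike_active(self, dM_act: np.ndarray, deta_act: np.ndarray, phi: np.ndarray) -> float:
        out = np.empty(self.count_table.n_genes)
        _sampler.per_gene_loglik(
            self._counts_active, self._fam_ptr, np.ascontiguousarray(np.atleast_2d(dM_act)),
            np.asarray(deta_act, dtype=float), np.asarray(phi, dtype=float),
            self.regime_index, out,
        )
        return float(out.sum())

    def _pooled_dM(self) -> np.ndarray:
        """Pooled log-frequency-ratio ΔM start per regime (φ→0 moment estimate)."""
        R, M = self.n_regimes, self._cols.size
        dM = np.zeros((R, M))
        for r in range(R):
            rows = self.regime_index == r
            pooled = self._counts_active[rows].sum(axis=0) + 0.5
            for f in range(len(self._fam_ids)):
                a, b = self._fam_ptr[f], self._fam_ptr[f + 1]
                # reference is last within the family slice (alphabetical order)
                ref_val = pooled[b - 1]
                dM[r, a:b] = np.log(ref_val / pooled[a:b])
                dM[r, a:b][~self._free_mask[a:b]] = 0.0
        return dM

    def _moment_init(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-codon (ΔM, Δη) start by weighted regression of smoothed
        per-gene log count ratios y ≈ −ΔM − Δη·φ on the given φ vector:
        the pooled slope gives −Δη, per-regime intercepts give −ΔM."""
        M = self._cols.size
        dM = np.zeros((self.n_regimes, M))
        deta = np.zeros(M)
        C = self._counts_active
        for f in range(len(self._fam_ids)):
            a, b = int(self._fam_ptr[f]), int(self._fam_ptr[f + 1])
            ref = C[:, b - 1] + 0.5
            fam_tot = C[:, a:b].sum(axis=1) + 1e-9
            for j in range(a, b - 1):
                y = np.log((C[:, j] + 0.5) / ref)
                xm = np.average(phi, weights=fam_tot)
                ym = np.average(y, weights=fam_tot)
                sxx = np.average((phi - xm) ** 2, weights=fam_tot)
                slope = (
                    np.average((phi - xm) * (y - ym), weights=fam_tot) / sxx
                    if sxx > 1e-12
                    else 0.0
                )
                deta[j] = -slope
                for r in range(self.n_regimes):
                    rows = self.regime_index == r
                    if not np.any(rows):
                        continue
                    ym_r = np.average(y[rows], weights=fam_tot[rows])
                    xm_r = np.average(phi[rows], weights=fam_tot[rows])
                    dM[r, j] = -(ym_r - slope * xm_r)
        return dM, deta

    def _initial_state(self, chain: int, rng: np.random.Generator, s0: float = 1.5):
        """Likelihood-oriented start: rank-normal scores of the first CA axis
        define a candidate φ ordering; the orientation (and a flat fallback)
        with the highest initial log-likelihood after a moment fit of
        (ΔM, Δη) wins. Later chains perturb the winner for dispersed starts.

        The orientation step matters: the likelihood has a reflected local
        mode (φ ranking inverted, Δη sign-flipped) that plain random starts
        fall into about half the time.
        """
        G = self.count_table.n_genes
        mu0 = 0.0 if self.priors.mean_log_zero else -0.5 * s0**2
        try:
            from .regime_clustering import correspondence_analysis

            ca = correspondence_analysis(self.count_table.frequencies(), n_components=1)
            axis = ca.row_coordinates[:, 0]
        except Exception:
            axis = np.zeros(G)
        if np.ptp(axis) <= 1e-12:
            phi0 = np.exp(mu0 + s0 * 0.0) * np.ones(G)
            best = (self._pooled_dM(), np.zeros(self._cols.size), phi0)
        else:
            ranks = stats.rankdata(axis, method="average")
            z = stats.norm.ppf((ranks - 0.5) / G)
            best, best_ll = None, -np.inf
            for orient in (1.0, -1.0):
                phi_c = np.exp(mu0 + s0 * orient * z)
                dM_c, deta_c = self._moment_init(phi_c)
                ll = self._loglike_active(dM_c, deta_c, phi_c)
                if ll > best_ll:
                    best, best_ll = (dM_c, deta_c, phi_c), ll
        dM0, deta0, phi0 = best
        if chain > 0:
            # dispersed start within the oriented basin
            phi0 = np.exp(np.log(phi0) + 0.75 * rng.standard_normal(G))
            dM0 = self._pooled_dM() if chain % 2 == 1 else dM0 + 0.2 * rng.standard_normal(dM0.shape)
            deta0 = deta0 * rng.uniform(0.5, 1.5)
        dM0 = dM0.copy()
        dM0[:, ~self._free_mask] = 0.0
        deta0 = deta0.copy()
        deta0[~self._free_mask] = 0.0
        return dM0, deta0, phi0, s0

    def loglike(self, delta_m: np.ndarray, delta_eta: np.ndarray, phi: np.ndarray) -> float:
        """Total log-likelihood (fast kernel path)."""
        dm = np.atleast_2d(np.asarray(delta_m, dtype=float))[:, self._cols]
        de = np.asarray(delta_eta, dtype=float)[self._cols]
        out = np.empty(self.count_table.n_genes)
        _sampler.per_gene_loglik(
            self._counts_active, self._fam_ptr, np.ascontiguousarray(dm), de,
            np.asarray(phi, dtype=float), self.regime_index, out,
        )
        return float(out.sum())

    def fit(self, config: MCMCConfig | None = None) -> "RocSempprResults":
        config = config or MCMCConfig()
        chains = []
        for chain in range(config.n_chains):
            rng = np.random.default_rng((config.seed, chain))
            dM0, deta0, phi0, s0 = self._initial_state(chain, rng)
            res = _sampler.run_chain(
                self._counts_active,
                self._fam_ptr,
                self._free_mask,
                self.regime_index,
                self.n_regimes,
                config,
                self.priors,
                seed=int(rng.integers(2**31 - 1)),
                init_dM=dM0,
                init_deta=deta0,
                init_phi=phi0,
                init_s_phi=s0,
            )
            chains.append(res)
        return RocSempprResults(self, config, chains)


class RocSempprResults:
    """Posterior summaries, trace access, DIC and diagnostics for a fit."""

    def __init__(self, model: RocSempprModel, config: MCMCConfig, chains: list[dict]) -> None:
        self.model = model
        self.config = config
        self._chains = chains
        self._summarize()

    # -- trace plumbing ----------------------------------------------------
    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate([c["samples"][name] for c in self._chains], axis=0)

    @property
    def n_samples(self) -> int:
        return sum(c["samples"]["s_phi"].size for c in self._chains)

    def _summarize(self) -> None:
        m = self.model
        free_in_active = np.flatnonzero(m._free_mask)
        codon61_of_free = m._cols[free_in_active]

        dM_s = self.stacked("dM")  # (S, R, K)
        deta_s = self.stacked("deta")  # (S, K)
        phi_s = self.stacked("phi")

        self.free_codons = [SENSE_CODONS[i] for i in codon61_of_free]
        self._codon61_of_free = codon61_of_free

        self.delta_m_mean = np.zeros((m.n_regimes, 61))
        self.delta_m_sd = np.zeros((m.n_regimes, 61))
        self.delta_m_mean[:, codon61_of_free] = dM_s.mean(axis=0)
        self.delta_m_sd[:, codon61_of_free] = dM_s.std(axis=0, ddof=1)
        self.delta_eta_mean = np.zeros(61)
        self.delta_eta_sd = np.zeros(61)
        self.delta_eta_mean[codon61_of_free] = deta_s.mean(axis=0)
        self.delta_eta_sd[codon61_of_free] = deta_s.std(axis=0, ddof=1)
        self.phi_mean = phi_s.mean(axis=0)
        self.phi_sd = phi_s.std(axis=0, ddof=1)
        self.s_phi_mean = float(self.stacked("s_phi").mean())

        dev_samples = -2.0 * self.stacked("loglik")
        dev_at_mean = -2.0 * m.loglike(self.delta_m_mean, self.delta_eta_mean, self.phi_mean)
        self.mean_deviance = float(dev_samples.mean())
        self.deviance_at_mean = float(dev_at_mean)
        self.dic, self.p_d = dic_from_deviances(dev_samples, dev_at_mean)
        self.acceptance_rates = [c["acceptance_rates"] for c in self._chains]

    # -- public surface ----------------------------------------------------
    @property
    def predicted_expression(self) -> pd.Series:
        """Posterior-mean φ per gene (the model's predicted expression)."""
        return pd.Series(self.phi_mean, index=self.model.count_table.gene_ids, name="phi_mean")

    def optimal_codons(self) -> dict[str, str]:
        return identify_optimal_codons(self.delta_eta_mean, self.model.genetic_code)

    def parameter_table(self) -> pd.DataFrame:
        """Per (family, codon, regime) posterior summaries with the optimal
        flag and AT-partner rescaled coefficients."""
        gc = self.model.genetic_code
        optimal = self.optimal_codons()
        rescaled = rescale_to_AT_reference(self.delta_m_mean, self.delta_eta_mean, gc)
        rows = []
        for fam in gc.multi_codon_families:
            for codon in fam.codons:
                i = CODON_INDEX[codon]
                key = (fam.family_id, codon)
                for r in range(self.model.n_regimes):
                    rows.append(
                        {
                            "family": fam.family_id,
                            "codon": codon,
                            "regime": r,
                            "deltaM_mean": self.delta_m_mean[r, i],
                            "deltaM_sd": self.delta_m_sd[r, i],
                            "deltaEta_mean": self.delta_eta_mean[i],
                            "deltaEta_sd": self.delta_eta_sd[i],
                            "optimal_flag": optimal.get(fam.family_id) == codon,
                            "rescaled_deltaM_vs_AT": rescaled["delta_m"].get(key, (np.nan,) * self.model.n_regimes)[r]
                            if key in rescaled["delta_m"]
                            else np.nan,
                            "rescaled_deltaEta_vs_AT": rescaled["delta_eta"].get(key, np.nan),
                        }
                    )
        return pd.DataFrame(rows)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.model.count_table.gene_ids,
                "phi_mean": self.phi_mean,
                "phi_sd": self.phi_sd,
                "regime": self.model.regime_index,
            }
        )

    def convergence(self, psrf_threshold: float = 1.1, phi_spearman_threshold: float = 0.95):
        return convergence_check(self, psrf_threshold, phi_spearman_threshold)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Selection-mutation-drift codon usage model"
            + (" (VarMut)" if m.is_varmut else " (ConstMut)"),
            f"genes: {m.count_table.n_genes}   regimes: {m.n_regimes}   "
            f"genetic code: {m.genetic_code.code_name}",
            f"chains: {self.config.n_chains}   retained samples: {self.n_samples}"
            f"   (iterations {self.config.iterations}, burn-in {self.config.burn_in},"
            f" thin {self.config.thin})",
            f"DIC: {self.dic:.1f}   p_D: {self.p_d:.1f}   mean deviance: {self.mean_deviance:.1f}",
            f"posterior mean s_phi: {self.s_phi_mean:.3f}   mean phi: {self.phi_mean.mean():.3f}",
        ]
        if self.config.n_chains >= 2:
            conv = self.convergence()
            lines.append(
                f"max split-PSRF: {conv['max_psrf']:.4f}   "
                f"cross-chain phi Spearman: {conv['phi_spearman']:.4f}   "
                f"converged: {conv['converged']}"
            )
        opt = self.optimal_codons()
        lines.append("optimal codons: " + ", ".join(f"{f}:{c}" for f, c in sorted(opt.items())))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# post-fit analyses
# ---------------------------------------------------------------------------


def rescale_to_AT_reference(
    delta_m: np.ndarray, delta_eta: np.ndarray, genetic_code: GeneticCode
) -> dict:
    """Re-express coefficients of GC-ending codons against their AT-ending
    partner (NNG − NNA, NNC − NNT) so a positive value means the GC-ending
    codon is disfavored relative to its AT partner.

    AT-ending codons keep their value relative to the family reference.
    Families lacking any AT/GC third-position pairing are skipped.
    """
    dm = np.atleast_2d(np.asarray(delta_m, dtype=float))
    de = np.asarray(delta_eta, dtype=float)
    out_m: dict[tuple[str, str], tuple] = {}
    out_eta: dict[tuple[str, str], float] = {}
    skipped = []
    for fam in genetic_code.multi_codon_families:
        members = set(fam.codons)
        pair_found = False
        for codon in fam.codons:
            partner = None
            if codon[2] == "G" and codon[:2] + "A" in members:
                partner = codon[:2] + "A"
            elif codon[2] == "C" and codon[:2] + "T" in members:
                partner = codon[:2] + "T"
            if partner is not None:
                pair_found = True
                i, j = CODON_INDEX[codon], CODON_INDEX[partner]
                out_m[(fam.family_id, codon)] = tuple(dm[:, i] - dm[:, j])
                out_eta[(fam.family_id, codon)] = float(de[i] - de[j])
            elif codon[2] in "AT":
                i = CODON_INDEX[codon]
                out_m[(fam.family_id, codon)] = tuple(dm[:, i])
                out_eta[(fam.family_id, codon)] = float(de[i])
        if not pair_found:
            # GC-ending codon without an AT partner in the family: report
            # against the family's existing AT member if there is one
            gcs = [c for c in fam.codons if c[2] in "GC"]
            ats = [c for c in fam.codons if c[2] in "AT"]
            if gcs and ats:
                at = ats[-1]
                for codon in gcs:
                    i, j = CODON_INDEX[codon], CODON_INDEX[at]
                    out_m[(fam.family_id, codon)] = tuple(dm[:, i] - dm[:, j])
                    out_eta[(fam.family_id, codon)] = float(de[i] - de[j])
            elif not ats or not gcs:
                skipped.append(fam.family_id)
    return {"delta_m": out_m, "delta_eta": out_eta, "skipped_families": skipped}


def identify_optimal_codons(delta_eta: np.ndarray, genetic_code: GeneticCode) -> dict[str, str]:
    """Per-family optimal codon: minimum Δη (reference at 0); larger Δη
    lowers a codon's probability as φ grows, so the minimum is the codon
    favored in highly expressed genes. Ties break alphabetically."""
    de = np.asarray(delta_eta, dtype=float)
    out = {}
    for fam in genetic_code.multi_codon_families:
        vals = [(float(de[CODON_INDEX[c]]), c) for c in fam.codons]
        out[fam.family_id] = min(vals)[1]
    return out


def _split_psrf(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter."""
    halves = []
    for c in chains:
        n = len(c) // 2
        if n < 2:
            return np.nan
        halves.extend([c[:n], c[n : 2 * n]])
    x = np.array(halves, dtype=float)
    m, n = x.shape
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def convergence_check(
    results: RocSempprResults,
    psrf_threshold: float = 1.1,
    phi_spearman_threshold: float = 0.95,
) -> dict:
    """Cross-chain diagnostics: split-PSRF for every codon coefficient and
    log s_φ, plus Spearman between chains' posterior-mean φ vectors."""
    chains = results._chains
    if len(chains) < 2:
        return {"available": False, "converged": False, "reason": "single chain"}
    psrfs = {}
    K = chains[0]["samples"]["deta"].shape[1]
    R = chains[0]["samples"]["dM"].shape[1]
    for k in range(K):
        codon = results.free_codons[k]
        psrfs[f"deta_{codon}"] = _split_psrf([c["samples"]["deta"][:, k] for c in chains])
        for r in range(R):
            psrfs[f"dM_r{r}_{codon}"] = _split_psrf([c["samples"]["dM"][:, r, k] for c in chains])
    psrfs["log_s_phi"] = _split_psrf([np.log(c["samples"]["s_phi"]) for c in chains])

    phi_means = [c["samples"]["phi"].mean(axis=0) for c in chains]
    rhos = [
        float(stats.spearmanr(phi_means[i], phi_means[j]).statistic)
        for i in range(len(chains))
        for j in range(i + 1, len(chains))
    ]
    phi_rho = min(rhos)
    max_psrf = float(np.nanmax(list(psrfs.values())))
    return {
        "available": True,
        "psrf": psrfs,
        "max_psrf": max_psrf,
        "phi_spearman": phi_rho,
        "converged": bool(max_psrf < psrf_threshold and phi_rho >= phi_spearman_threshold),
    }


def compare_models(
    fit_const: RocSempprResults,
    fit_var: RocSempprResults,
    empirical_expression: pd.Series | None = None,
) -> dict:
    """ConstMut-vs-VarMut comparison record.

    Reports Spearman(predicted φ, empirical) per model and their difference,
    ΔDIC = DIC_VarMut − DIC_ConstMut (negative favors VarMut; lower DIC is
    better), per-family optimal-codon agreement, and the change in the
    AT-rescaled selection coefficients between models.
    """
    ids_c = list(fit_const.model.count_table.gene_ids)
    ids_v = list(fit_var.model.count_table.gene_ids)
    if ids_c != ids_v:
        raise ValueError("fits are not on the same gene set")
    out: dict = {"delta_dic": fit_var.dic - fit_const.dic, "dic_const": fit_const.dic, "dic_var": fit_var.dic}

    if empirical_expression is not None:
        emp = empirical_expression.reindex(ids_c)
        common = emp.notna()
        if common.sum() < 3:
            raise ValueError("too few genes shared with empirical expression")
        rc = float(stats.spearmanr(fit_const.phi_mean[common.to_numpy()], emp[common]).statistic)
        rv = float(stats.spearmanr(fit_var.phi_mean[common.to_numpy()], emp[common]).statistic)
        out.update(
            spearman_const=rc,
            spearman_var=rv,
            delta_spearman=rv - rc,
            n_genes_compared=int(common.sum()),
        )

    opt_c = fit_const.optimal_codons()
    opt_v = fit_var.optimal_codons()
    agree = {f: opt_c[f] == opt_v[f] for f in opt_c}
    out["optimal_codon_agreement"] = agree
    out["n_optimal_agree"] = sum(agree.values())
    out["n_families"] = len(agree)

    gc = fit_const.model.genetic_code
    resc_c = rescale_to_AT_reference(fit_const.delta_m_mean, fit_const.delta_eta_mean, gc)
    resc_v = rescale_to_AT_reference(fit_var.delta_m_mean, fit_var.delta_eta_mean, gc)
    out["rescaled_deltaEta_change"] = {
        key: resc_v["delta_eta"][key] - resc_c["delta_eta"][key] for key in resc_c["delta_eta"]
    }
    return out
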