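# Methods

## The model

For an amino acid with `n_aa` synonymous codons, the probability of finding
codon *i* at one of that amino acid's positions in gene *g* is

    p_ig = exp(−ΔM_i − Δη_i φ_g) / Σ_j exp(−ΔM_j − Δη_j φ_g)

a softmax over the synonymous family. ΔM_i (mutation bias) collects every
expression-independent force on codon choice — mutation bias proper, biased
gene conversion, and similar non-adaptive processes; Δη_i (selection
coefficient) is the expression-scaled selective disfavor of codon *i*;
φ_g > 0 is the gene's evolutionary-average expression (protein production
rate), lognormal across genes with mean fixed at 1 by convention. Both
coefficient types are measured relative to a reference codon per family —
the alphabetically last member — whose coefficients are identically 0.
Observed codon counts per gene and family are multinomial with these
probabilities; the multinomial normalizing constant is dropped everywhere
(it is constant in the parameters, so likelihood ratios, posterior shapes
and DIC differences are unaffected). Selection is assumed weak (Nₑs ≪ 1);
Nₑ, s and mutation rates are not separately identified — ΔM and Δη are
composite, dimensionless quantities.

Families follow the standard nuclear code with serine split into the
four-codon TCN box and the two-codon AGY box (40 free coefficients per
parameter type); the `ctg_ser` variant moves CTG out of leucine into a
singleton serine family (39 free coefficients), for yeasts of the CTG-Ser
clade.

Two model forms:

* **ConstMut**: one genome-wide ΔM set.
* **VarMut**: one ΔM set per mutation regime (typically the two CLARA
  clusters), Δη shared across regimes, and a single φ per gene.

With identical ΔM in all regimes the VarMut likelihood equals ConstMut's
exactly (tested).

## Regime hypothesis: CA + CLARA

Genes evolving under different non-adaptive biases are hypothesized from
codon usage alone: per-gene frequencies over the 61 sense codons enter a
correspondence analysis; genes are clustered on the first 4 row principal
coordinates with CLARA (k-medoids on subsamples); the cluster with the
lower median GC3 is labeled `lower_gc3`.

Numerical choices:

* CA rows are normalized to profiles first (equal row masses), so long
  genes do not dominate and coordinates are invariant to rescaling any row.
  Zero-mass codon columns are dropped with a warning. Axis signs are fixed
  by making the largest-magnitude loading positive.
* Row *principal* coordinates (standard coordinates × singular values) feed
  the clustering; this is the common reading of "principal components of a
  CA".
* PAM is the classic BUILD+SWAP with Euclidean distance, always taking the
  best improving swap, ties resolved toward the lowest index; it is fully
  deterministic. CLARA draws `n_subsets = 5` subsets of fraction 0.5
  without replacement (seeded generator), runs PAM on each, assigns all
  points to the nearest medoid, and keeps the medoid set with the smallest
  full-data mean dissimilarity.
* k = 2 by default; k = 3 inserts a `mid_gc3` label.

## MCMC sampler

Adaptive Metropolis-within-Gibbs over (log φ per gene; ΔM per family ×
regime; Δη per family; log s_φ):

* per-gene random walks on log φ, accepted independently;
* per-family block random walks: the ΔM entries of one family in one
  regime move jointly (only that regime's genes enter the ratio), then the
  family's Δη entries move jointly;
* a random walk on log s_φ, whose conditional involves only the φ prior
  and its half-normal prior;
* proposal scales adapt by Robbins–Monro toward ~0.3 acceptance during
  burn-in only, so the post-burn-in kernel is a fixed Markov kernel
  satisfying detailed balance.

Priors: ΔM, Δη ~ Normal(0, 10²) (weakly informative); s_φ ~ Half-Normal(0,
2); φ ~ Lognormal(−s_φ²/2, s_φ), i.e. E[φ] = 1 a priori.

**Scale gauge.** The likelihood is exactly invariant under φ → cφ, Δη →
Δη/c. With 40 weakly constrained Δη coefficients, posterior volume along
this ridge overwhelms the soft prior pinning: chains drift to tiny φ /
inflated Δη while s_φ balloons to absorb the shifted log-φ location. The
sampler therefore renormalizes φ to sample mean 1 after every sweep, with
Δη absorbing the factor — a gauge fixing of the conventional mean-1 scale
(the likelihood is invariant, so cached likelihood terms remain valid and
no other update is affected). The prior-pinned alternative, with a
Jacobian-correct likelihood-invariant MH scale move, remains available via
`PriorConfig(fix_phi_mean=False)`; it is useful for studying the ridge but
is not recommended for inference.

**Initialization.** The posterior has a reflected local mode — φ ranking
inverted and Δη sign-flipped — that random starts enter about half the
time and practically never leave at desk scale. Starts are therefore
oriented by the data: rank-normal scores of the first CA axis provide a
candidate φ ordering; for both orientations a moment fit of (ΔM, Δη) is
computed by weighted least squares on smoothed per-gene log count ratios
(slope ↦ −Δη, per-regime intercept ↦ −ΔM), and the orientation with the
higher initial likelihood wins. Chain 0 starts there; later chains perturb
the winner strongly (log-φ noise of SD 0.75, coefficient noise, ΔM reset
to the pooled-frequency estimate on odd chains) so that multi-chain
agreement remains a meaningful convergence check within the correct basin.

**Point estimates and DIC.** "Predicted expression" is the posterior mean
of φ over retained samples. DIC = D(θ̄) + 2 p_D with p_D = D̄ − D(θ̄),
where D̄ averages the deviance over retained samples and D(θ̄) plugs in
posterior means of all parameters (φ included). Lower DIC is better;
ΔDIC is reported as VarMut − ConstMut.

**Convergence.** Split-chain potential scale reduction for every free
coefficient and log s_φ (threshold 1.1), plus the minimum pairwise
Spearman between chains' posterior-mean φ vectors (threshold 0.95).

Default working configuration: 20,000 iterations, thin 10, burn-in 5,000,
two chains (`MCMCConfig.desk()`); the long-run configuration for real-genome
analyses (200,000 / 10 / 50,000 / 2) is `MCMCConfig.full_scale()`.

## Synthetic genomes

The generator emulates exactly the structure the analysis assumes: genes
laid out on chromosomes in contiguous regime blocks (geometric block
lengths, default mean 50 genes); φ lognormal with mean 1 (s_φ = 1.5, a
typical fitted magnitude); per-gene lengths discretized lognormal with
median 400 codons (typical yeast CDS scale); codon counts multinomial per
family with the model probabilities (ΔM ~ U(−2, 2), Δη ~ U(−0.5, 0.5) per
free codon); amino-acid family usage uniform over families; observed
expression = φ × lognormal(0, σ_obs = 0.3) noise, standing in for RNA-seq
abundances used only for validation correlations. Regime-2 mutation biases
add a GC-directed shift (+δ on AT-ending codons, reference-renormalized):
δ = 1.0 (`two_regime_strong`) realizes a median-GC3 gap ≈ 0.15, above the
0.1 threshold used to call a separation strong; δ = 0.2
(`two_regime_weak`) realizes ≈ 0.03–0.05. `null_blocks` scatters two
*identical*-parameter labels gene-by-gene, making labels independent of
GC3 by construction. Simulations are fully determined by scenario + seed
(byte-identical FASTA on rerun).

What the generator does **not** emulate: amino-acid composition differences
between genes, length–expression correlation, codon autocorrelation along a
sequence, context-dependent mutation, and any phylogenetic structure.
Passing recovery tests therefore show the estimator is correct under its
own model assumptions, not that those assumptions hold in real genomes.

## Downstream statistics

* RSCU_i = count_i / (family total / n_aa), over pooled counts; singleton
  families are excluded (RSCU ≡ 1).
* CAI: weights w_i = RSCU_i(reference set) / max family RSCU; per-gene CAI
  is the count-weighted geometric mean of weights over multi-codon
  families. Reference RSCU of 0 is floored at 0.01 before weighting
  (conventional guard against −∞ log weights). The automatic reference set
  takes the top 5% of genes along CA axis 1, oriented to correlate
  positively with an expression proxy (total codon count if none given).
* Expression extremes: top/bottom 5% by expression; ties broken by gene id
  (descending for the high set, ascending for the low set, so tied input
  still yields disjoint sets).
* GC3 landscape: per chromosome, genes ordered by ordinal position
  (windows are gene-count windows, not base-pair windows). Moving mode:
  centered 20-gene average, truncated at ends. Non-overlapping mode:
  consecutive 20-gene bins, final partial bin kept if ≥ half a window. The
  landscape statistic is the Spearman correlation between window mean GC3
  and the fraction of window genes labeled `higher_gc3`, pooled across
  chromosomes (one pooled test, matching how the scatter is usually
  summarized, rather than per-chromosome tests). Note the statistic is
  tie-capped: when labels recover regime blocks almost perfectly, most
  windows are pure 0/1 in label fraction and the attainable Spearman with
  balanced tie groups is ≈ 0.87 plus the boundary-window contribution, so
  values near 0.9 — not near 1 — are the expected signature of a strongly
  blocked genome.

## Problem sizes used by the test battery

Recovery and model-comparison checks run at desk scale, chosen so the whole
battery stays comfortably reproducible on a single CPU: single-regime
recovery at 1,500 genes with the default two-chain configuration;
ConstMut-vs-VarMut contrast on a 2,000-gene two-regime genome with one
chain per fit; the over-clustering check at 1,000 genes, 12,000 iterations,
one chain, five seeds. The long-run MCMC configuration remains available
as a preset for real-data work.

## Known limitations

* φ for weakly expressed genes is intrinsically poorly ordered when
  selection coefficients are small (|Δη| ≤ 0.5): the per-gene Fisher
  information about log φ vanishes as φ → 0. Under the generator's default
  conditions even the maximum-likelihood estimate computed with the *true*
  coefficients reaches only Spearman ≈ 0.7 against true φ; posterior means
  match that ceiling. Headline rank correlations on such data measure the
  information available, not sampler quality.
* DIC uses posterior means of all parameters (φ included) in D(θ̄); other
  conventions marginalize φ. Differences between models fitted to the same
  data are comparable either way.
* CLARA's subset count (5) and the use of principal (rather than standard)
  CA coordinates are configurable; neither choice is sharp on synthetic
  data.
* The filter rules reject any CDS with ambiguity codes rather than
  partially counting it, keeping multinomial totals exact.
* The initiator ATG and terminal stop are excluded from counts
  (`count_start_codon=True` restores the initiator for compatibility
  checks).
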