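# codonregimes

Selection on synonymous codon usage is usually inferred from the covariation
between codon frequencies and gene expression. But the non-adaptive forces
that also shape codon usage — mutation bias, GC-biased gene conversion,
replication-timing effects — are not constant within a genome: many genomes
carry long GC-rich or GC-poor blocks of genes. When one genome mixes two
such "mutation regimes", a model that assumes a single genome-wide mutation
bias misreads the regime structure as (or against) selection: predicted
expression decorrelates from reality and "optimal" codons can be
misidentified. `codonregimes` implements the full workflow for detecting
this situation and correcting for it, aimed at people studying codon usage
in yeasts and other microbial eukaryotes:

1. **genome_io** — read a CDS FASTA, apply the usual gene filters
   (ATG start, length divisible by 3, no internal stop, no ambiguity
   codes), count sense codons per gene (initiator and terminal stop
   excluded), compute GC3.
2. **regime_clustering** — hypothesize mutation regimes without any
   expression data: correspondence analysis of per-gene codon frequencies,
   CLARA k-medoids on the first 4 principal coordinates, clusters labeled
   `lower_gc3` / `higher_gc3` by median GC3, plus a Kolmogorov–Smirnov
   test between the clusters' GC3 distributions.
3. **roc_semppr** — Bayesian fitting of the selection-mutation-drift
   codon model: for each synonymous family the probability of codon *i*
   in gene *g* is

       p_ig = exp(−ΔM_i − Δη_i φ_g) / Σ_j exp(−ΔM_j − Δη_j φ_g)

   with mutation bias ΔM, selection coefficient Δη (both relative to the
   alphabetically last codon of the family), and latent lognormal
   expression φ (mean 1). `RocSempprModel(table).fit()` gives the
   **ConstMut** form (one ΔM set); passing a regime assignment gives
   **VarMut** (ΔM per regime, shared Δη, one φ per gene). Results carry
   posterior means and SDs, predicted expression, DIC, convergence
   diagnostics, optimal codons, and AT-partner-rescaled coefficients.
4. **synthetic_genome** — generators for genomes with known ΔM/Δη/φ,
   regime blocks along chromosomes and noisy observed expression, so the
   whole pipeline is testable end to end without external data.
5. **analysis_pipeline** — RSCU, CAI, expression extremes, 20-gene GC3
   window profiles (moving and non-overlapping) and the window
   correlation between mean GC3 and higher-cluster fraction, plus
   `run_full_analysis` orchestrating everything.

Serine is handled as two families (TCN and AGY); the CTG-Ser clade
translation (CTG as a singleton serine group) is available with
`genetic_code="ctg_ser"`.

## Worked example

```python
import codonregimes as cr
from scipy import stats

# a synthetic genome whose two mutation regimes differ in GC3 by ~0.15
sc = cr.build_preset("two_regime_strong", n_genes=2000, seed=0)
table, expression, truth = cr.simulate_count_table(sc)

assignment = cr.cluster_genes(table, k=2, seed=0)
print(assignment.delta_median_gc3)          # 0.167

cfg = cr.MCMCConfig(iterations=20_000, burn_in=5_000, n_chains=1, seed=1)
fit_const = cr.RocSempprModel(table).fit(cfg)
fit_var = cr.RocSempprModel(table, regimes=assignment).fit(cfg)

phi_true = truth.per_gene["phi_true"]
print(stats.spearmanr(fit_const.phi_mean, phi_true).statistic)  # 0.595
print(stats.spearmanr(fit_var.phi_mean, phi_true).statistic)    # 0.786
print(fit_var.dic - fit_const.dic)                              # -30930.1
```

Reading: the clustering recovers the two regimes almost perfectly (here
99.5% of genes). The single-mutation-bias fit misreads the regime
structure and its predicted expression correlates at only 0.60 with the
truth; letting mutation bias differ between the two clusters raises that
to 0.79 and lowers DIC by ~31,000 (lower is better) — the signature of a
genome where intragenomic mutation-bias variation masks selection. On a
genuinely homogeneous genome the same forced split *lowers* the
correlation (by ~0.1–0.2 in our tests): splitting is not a free action,
which is why the DIC comparison matters.

A fitted model prints a compact summary:

```
>>> print(fit.summary())
Selection-mutation-drift codon usage model (ConstMut)
genes: 1500   regimes: 1   genetic code: standard
chains: 2   retained samples: 3000   (iterations 20000, burn-in 5000, thin 10)
DIC: 977323.2   p_D: 995.7   mean deviance: 976327.6
posterior mean s_phi: 1.510   mean phi: 1.000
max split-PSRF: 1.0702   cross-chain phi Spearman: 0.9993   converged: True
optimal codons: Ala:GCC, Arg:CGA, Asn:AAC, ...
```

There is also a CLI for shell use:

```bash
codonregimes simulate --preset two_regime_strong --n-genes 2000 --seed 0 --out sim/
codonregimes cluster --fasta sim/genes.fasta --metadata sim/metadata.tsv --out clust/
codonregimes fit --fasta sim/genes.fasta --model varmut --clusters clust/assignment.tsv --out fit/
codonregimes run-all --preset two_regime_strong --out run/
```

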