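"""Downstream statistics and the end-to-end orchestration.

Covers the validation and landscape analyses that sit around clustering and
model fitting: Spearman comparison of predicted vs empirical expression,
RSCU and CAI, GC3 sliding-window and non-overlapping-window chromosome
profiles, and the ConstMut-vs-VarMut report on a synthetic genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, SENSE_CODONS
from .genome_io import CODON_INDEX, CodonCountTable
from .regime_clustering import HIGHER, RegimeAssignment, cluster_genes, ks_compare_gc3, correspondence_analysis


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, asymptotic p).

    Returns (nan, nan) with a warning for constant input, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman undefined")
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def rscu(pooled_counts: np.ndarray, genetic_code: GeneticCode) -> pd.Series:
    """Relative synonymous codon usage over a pooled gene set.

    RSCU_i = count_i / (family total / n_aa): the observed count relative
    to the expectation under unbiased synonymous usage. Single-codon
    families are excluded (RSCU ≡ 1 by definition); families with zero
    total yield NaN entries.
    """
    c = np.asarray(pooled_counts, dtype=float)
    out = {}
    for fam in genetic_code.multi_codon_families:
        idx = [CODON_INDEX[x] for x in fam.codons]
        tot = c[idx].sum()
        for codon, i in zip(fam.codons, idx):
            out[codon] = c[i] / (tot / fam.n_codons) if tot > 0 else np.nan
    return pd.Series(out).sort_index()


def expression_extremes(
    expression: pd.Series, fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Top and bottom expression quantile gene sets.

    Ties are broken by gene id — descending for the high set, ascending for
    the low set — so fully tied input still yields disjoint sets.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(expression)
    k = int(np.floor(n * fraction))
    if k < 1:
        raise ValueError("too few genes for non-empty extreme sets")
    if expression.nunique() == 1:
        warnings.warn("all expression values equal; extremes split by gene id")
    df = expression.rename("x").rename_axis("gene_id").reset_index()
    high = df.sort_values(["x", "gene_id"], ascending=[False, False], kind="mergesort")[
        "gene_id"
    ].head(k).tolist()
    low = df.sort_values(["x", "gene_id"], ascending=[True, True], kind="mergesort")[
        "gene_id"
    ].head(k).tolist()
    return high, low


def cai(
    count_table: CodonCountTable,
    reference_gene_set: list[str],
    genetic_code: GeneticCode,
    zero_floor: float = 0.01,
) -> pd.Series:
    """Codon Adaptation Index per gene.

    Weights w_i = RSCU_i(reference) / max family RSCU(reference); CAI is
    the geometric mean of a gene's codon weights over multi-codon families,
    exp(Σ c_i log w_i / Σ c_i). Reference RSCU values of 0 are floored at
    ``zero_floor`` so unused reference codons give large negative — not
    infinite — log weights.
    """
    if not reference_gene_set:
        raise ValueError("empty reference gene set")
    ref_rows = [count_table.gene_ids.index(g) for g in reference_gene_set]
    pooled = count_table.counts[ref_rows].sum(axis=0)
    ref_rscu = rscu(pooled, genetic_code)

    w = np.zeros(61)
    usable = np.zeros(61, dtype=bool)
    for fam in genetic_code.multi_codon_families:
        vals = ref_rscu[list(fam.codons)].to_numpy(dtype=float)
        if np.all(np.isnan(vals)):
            continue
        vals = np.where(np.isnan(vals) | (vals <= 0), zero_floor, vals)
        vals = vals / vals.max()
        for codon, v in zip(fam.codons, vals):
            w[CODON_INDEX[codon]] = v
            usable[CODON_INDEX[codon]] = True

    logw = np.where(usable, np.log(np.where(usable, w, 1.0)), 0.0)
    c = count_table.counts
    tot = (c * usable).sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.exp((c * logw).sum(axis=1) / tot)
    return pd.Series(vals, index=count_table.gene_ids, name="cai")


def ca_reference_set(
    count_table: CodonCountTable,
    fraction: float = 0.05,
    expression_proxy: pd.Series | None = None,
) -> list[str]:
    """Automatic CAI reference set from the first CA axis.

    The first principal axis of the codon-frequency CA is oriented so it
    correlates positively with the expression proxy (total codon count per
    gene when no proxy is given); the top ``fraction`` genes along the
    oriented axis form the reference set.
    """
    ca = correspondence_analysis(count_table.frequencies(), n_components=1)
    axis = ca.row_coordinates[:, 0]
    if expression_proxy is not None:
        proxy = expression_proxy.reindex(count_table.gene_ids).to_numpy(dtype=float)
    else:
        proxy = count_table.counts.sum(axis=1).astype(float)
    rho, _ = stats.spearmanr(axis, proxy)
    if rho < 0:
        axis = -axis
    k = max(int(np.floor(fraction * count_table.n_genes)), 1)
    order = np.argsort(-axis, kind="mergesort")
    return [count_table.gene_ids[i] for i in order[:k]]


@dataclass
class WindowProfile:
    """Per-window GC3 landscape along chromosomes."""

    table: pd.DataFrame  # chromosome, window, mean_gc3, frac_higher, n_genes
    mode: str  # moving | nonoverlapping
    window_size: int


def window_profile(
    count_table: CodonCountTable,
    labels: np.ndarray | pd.Series,
    window_size: int = 20,
    mode: str = "nonoverlapping",
) -> WindowProfile:
    """GC3 windows along each chromosome (genes ordered by position).

    ``moving``: a centered ``window_size``-gene moving average per gene
    position, truncated at chromosome ends. ``nonoverlapping``: consecutive
    ``window_size``-gene bins; a final partial bin is kept when it holds at
    least half a window. Each window reports mean GC3 and the fraction of
    its genes labeled ``higher_gc3``.
    """
    if mode not in ("moving", "nonoverlapping"):
        raise ValueError("mode must be 'moving' or 'nonoverlapping'")
    if count_table.coords is None:
        raise ValueError("count table has no coordinates")
    lab = np.asarray(labels)
    is_higher = (lab == HIGHER).astype(float)
    df = pd.DataFrame(
        {
            "chromosome": count_table.coords["chromosome"].to_numpy(),
            "position": count_table.coords["position"].to_numpy(),
            "gc3": count_table.gc3,
            "higher": is_higher,
        }
    )
    if df[["chromosome", "position"]].isna().any().any():
        raise ValueError("coordinates required for all genes")
    rows = []
    half = window_size // 2
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("position", kind="mergesort").reset_index(drop=True)
        n = len(sub)
        if mode == "moving":
            if n < window_size:
                warnings.warn(f"{chrom}: fewer than {window_size} genes; skipped")
                continue
            for i in range(n):
                lo, hi = max(0, i - half), min(n, i - half + window_size)
                win = sub.iloc[lo:hi]
                rows.append((chrom, i, win["gc3"].mean(), win["higher"].mean(), len(win)))
        else:
            n_full = n // window_size
            for wi in range(n_full):
                win = sub.iloc[wi * window_size : (wi + 1) * window_size]
                rows.append((chrom, wi, win["gc3"].mean(), win["higher"].mean(), len(win)))
            rem = n - n_full * window_size
            if rem >= max(window_size // 2, 1) and rem > 0:
                win = sub.iloc[n_full * window_size :]
                rows.append((chrom, n_full, win["gc3"].mean(), win["higher"].mean(), len(win)))
    table = pd.DataFrame(
        rows, columns=["chromosome", "window", "mean_gc3", "frac_higher", "n_genes"]
    )
    return WindowProfile(table=table, mode=mode, window_size=window_size)


def window_correlation(profile: WindowProfile) -> tuple[float, float]:
    """Spearman between window mean GC3 and the fraction of higher-GC3
    genes, pooled across chromosomes."""
    if profile.mode != "nonoverlapping":
        raise ValueError("window correlation is defined on non-overlapping windows")
    t = profile.table
    if len(t) < 3:
        raise ValueError("need at least 3 windows")
    return spearman(t["mean_gc3"].to_numpy(), t["frac_higher"].to_numpy())


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    spearman_const: float
    spearman_var: float
    delta_spearman: float
    dic_const: float
    dic_var: float
    delta_dic: float
    ks_d: float
    ks_p: float
    delta_median_gc3: float
    optimal_codons_const: dict
    optimal_codons_var: dict
    window_rho: float
    window_p: float
    cluster_sizes: dict

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def run_full_analysis(
    count_table: CodonCountTable,
    expression: pd.Series | None = None,
    k: int = 2,
    seed: int = 0,
    mcmc_config=None,
    window_size: int = 20,
    genetic_code: GeneticCode | str = "standard",
) -> tuple[AnalysisReport, dict]:
    """Cluster → ConstMut fit → VarMut fit → comparison → windows.

    Returns the report plus a dict of intermediate artifacts (regime
    assignment, both fits, window profile). All randomness derives from
    ``seed``.
    """
    from .roc_semppr import MCMCConfig, RocSempprModel, compare_models

    gc = genetic_code if isinstance(genetic_code, GeneticCode) else GeneticCode.from_name(genetic_code)
    assignment = cluster_genes(count_table, k=k, seed=seed)
    gc3 = count_table.gc3
    low = gc3[assignment.labels == assignment.label_names[0]]
    high = gc3[assignment.labels == assignment.label_names[-1]]
    ks_d, ks_p = ks_compare_gc3(low, high)

    cfg = mcmc_config or MCMCConfig(seed=seed)
    fit_const = RocSempprModel(count_table, regimes=None, genetic_code=gc).fit(cfg)
    fit_var = RocSempprModel(count_table, regimes=assignment, genetic_code=gc).fit(cfg)
    comp = compare_models(fit_const, fit_var, expression)

    window_rho = window_p = float("nan")
    if count_table.coords is not None and not count_table.coords.isna().any().any():
        prof = window_profile(count_table, assignment.labels, window_size, "nonoverlapping")
        window_rho, window_p = window_correlation(prof)
    else:
        prof = None

    sizes = {name: int(np.sum(assignment.labels == name)) for name in assignment.label_names}
    report = AnalysisReport(
        spearman_const=comp.get("spearman_const", float("nan")),
        spearman_var=comp.get("spearman_var", float("nan")),
        delta_spearman=comp.get("delta_spearman", float("nan")),
        dic_const=fit_const.dic,
        dic_var=fit_var.dic,
        delta_dic=comp["delta_dic"],
        ks_d=ks_d,
        ks_p=ks_p,
        delta_median_gc3=assignment.delta_median_gc3,
        optimal_codons_const=fit_const.optimal_codons(),
        optimal_codons_var=fit_var.optimal_codons(),
        window_rho=window_rho,
        window_p=window_p,
        cluster_sizes=sizes,
    )
    artifacts = {
        "assignment": assignment,
        "fit_const": fit_const,
        "fit_var": fit_var,
        "window_profile": prof,
        "comparison": comp,
    }
    return report, artifacts
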