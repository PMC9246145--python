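"""Synthetic genomes with known mutation-bias regimes, selection, and expression.

Genes are laid out on chromosomes in contiguous regime blocks; per-gene
expression φ is lognormal with mean 1; codon counts are multinomial within
each synonymous family with probabilities softmax(−ΔM_regime − Δη·φ).
Every simulation emits a ``SyntheticTruth`` carrying the generating
parameters and labels so recovery tests never reach into simulator
internals.

Presets
-------
``single_regime``
    one set of mutation biases genome-wide (the well-specified case).
``two_regime_strong``
    two regimes whose mutation biases differ by a GC-directed shift large
    enough that the realized median-GC3 gap exceeds 0.1 (the regime
    separation treated as "strong" in the landscape analyses).
``two_regime_weak``
    same structure with a small shift (median-GC3 gap around 0.03).
``null_blocks``
    two bookkeeping labels with *identical* parameters scattered gene-by-gene
    (block length 1): labels are independent of GC3 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, SENSE_CODONS
from .genome_io import CODON_INDEX, GeneRecord

_AT_ENDING = np.array([c[2] in "AT" for c in SENSE_CODONS])


@dataclass
class SimulationScenario:
    """Generating parameters for a synthetic genome."""

    n_genes: int = 2000
    n_chromosomes: int = 8
    n_regimes: int = 1
    gene_length_median: int = 400  # codons (sense codons drawn per gene)
    gene_length_log_sd: float = 0.35
    min_gene_length: int = 50
    s_phi: float = 1.5
    delta_m_range: tuple[float, float] = (-2.0, 2.0)
    delta_eta_range: tuple[float, float] = (-0.5, 0.5)
    gc_shift: float = 0.0  # regime-r ΔM shift disfavoring AT-ending codons
    regimes_identical: bool = False  # null: labels only, shared parameters
    mean_block_length: float = 50.0  # genes per regime block
    regime_proportions: tuple[float, ...] = (1.0,)
    sigma_obs: float = 0.3  # lognormal sd of observed-expression noise
    family_weights: dict[str, float] | None = None  # None = uniform
    genetic_code: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_regimes < 1:
            raise ValueError("sizes must be positive")
        if abs(sum(self.regime_proportions) - 1.0) > 1e-9:
            raise ValueError("regime proportions must sum to 1")
        if len(self.regime_proportions) != self.n_regimes:
            raise ValueError("one proportion per regime required")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated genome."""

    scenario: SimulationScenario
    per_gene: pd.DataFrame  # gene_id, chromosome, position, regime, phi, ...
    delta_m: np.ndarray  # (n_regimes, 61), reference entries 0
    delta_eta: np.ndarray  # (61,), reference entries 0
    s_phi: float
    delta_median_gc3: float  # realized gap between extreme regimes (0 if 1 regime)


def sample_expression(n: int, s_phi: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Lognormal expression with location −s_phi²/2 so that E[φ] = 1."""
    if s_phi <= 0:
        raise ValueError("s_phi must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.lognormal(mean=-0.5 * s_phi**2, sigma=s_phi, size=n)


def sample_regime_blocks(
    n_genes: int,
    n_chromosomes: int,
    mean_block_length: float,
    regime_proportions: tuple[float, ...],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Lay genes on chromosomes with regimes in contiguous blocks.

    Block lengths are geometric with the given mean; each block's regime is
    drawn from ``regime_proportions``. ``mean_block_length=1`` scatters
    regimes gene-by-gene (no physical clustering).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mean_block_length < 1:
        raise ValueError("mean_block_length must be >= 1")
    props = np.asarray(regime_proportions, dtype=float)
    n_regimes = len(props)
    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes)
    per_chrom[: n_genes % n_chromosomes] += 1

    rows = []
    for ci, n_c in enumerate(per_chrom):
        pos = 0
        while pos < n_c:
            if mean_block_length <= 1:
                blen = 1
            else:
                blen = int(rng.geometric(1.0 / mean_block_length))
            blen = min(blen, n_c - pos)
            regime = int(rng.choice(n_regimes, p=props))
            for _ in range(blen):
                pos += 1
                rows.append((f"chr{ci + 1}", pos, regime))
    return pd.DataFrame(rows, columns=["chromosome", "position", "regime"])


def codon_probability_matrix(
    genetic_code: GeneticCode, delta_m_row: np.ndarray, delta_eta: np.ndarray, phi: float
) -> dict[str, np.ndarray]:
    """Per-family codon probabilities softmax(−ΔM − Δη·φ) for one gene."""
    out = {}
    for fam in genetic_code.families:
        idx = [CODON_INDEX[c] for c in fam.codons]
        z = -(delta_m_row[idx] + delta_eta[idx] * phi)
        z -= z.max()
        p = np.exp(z)
        out[fam.family_id] = p / p.sum()
    return out


def simulate_gene_counts(
    genetic_code: GeneticCode,
    delta_m_row: np.ndarray,
    delta_eta: np.ndarray,
    phi: float,
    length: int,
    rng: np.random.Generator,
    family_weights: dict[str, float] | None = None,
    emit_sequence: bool = False,
) -> tuple[np.ndarray, str | None]:
    """Draw a gene's 61-codon count vector (and optionally its CDS string).

    Family usage is multinomial over amino-acid families; within a family,
    codons are multinomial with the model probabilities. The emitted CDS is
    ATG + shuffled codons + TAA, so re-reading it through the genome reader
    reproduces the count vector exactly.
    """
    fams = genetic_code.families
    if family_weights is None:
        w = np.full(len(fams), 1.0 / len(fams))
    else:
        w = np.array([family_weights.get(f.family_id, 0.0) for f in fams], dtype=float)
        w = w / w.sum()
    fam_counts = rng.multinomial(length, w)
    probs = codon_probability_matrix(genetic_code, delta_m_row, delta_eta, phi)
    counts = np.zeros(61, dtype=np.int64)
    for fam, n_f in zip(fams, fam_counts):
        if n_f == 0:
            continue
        idx = np.array([CODON_INDEX[c] for c in fam.codons])
        counts[idx] += rng.multinomial(n_f, probs[fam.family_id])
    seq = None
    if emit_sequence:
        codons = np.repeat(np.arange(61), counts)
        rng.shuffle(codons)
        seq = "ATG" + "".join(SENSE_CODONS[i] for i in codons) + "TAA"
    return counts, seq


def simulate_observed_expression(
    phi: np.ndarray, sigma_obs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Noisy observed abundance: φ times multiplicative lognormal(0, σ_obs) noise."""
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma_obs == 0:
        return np.asarray(phi, dtype=float).copy()
    return np.asarray(phi) * rng.lognormal(0.0, sigma_obs, size=len(phi))


def draw_parameters(
    scenario: SimulationScenario, genetic_code: GeneticCode, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ground-truth (ΔM per regime, Δη) with reference entries fixed at 0.

    Regime 0 mutation biases are uniform draws; regime r adds ``gc_shift``·r
    to every AT-ending codon (disfavoring AT, i.e. shifting usage toward
    GC-ending codons), renormalized so the reference codon stays at 0. With
    ``regimes_identical`` all regimes share regime 0's parameters.
    """
    dm = np.zeros((scenario.n_regimes, 61))
    deta = np.zeros(61)
    base = np.zeros(61)
    for fam in genetic_code.multi_codon_families:
        idx = [CODON_INDEX[c] for c in fam.codons]
        ref = CODON_INDEX[fam.reference]
        for i in idx:
            if i != ref:
                base[i] = rng.uniform(*scenario.delta_m_range)
                deta[i] = rng.uniform(*scenario.delta_eta_range)
    for r in range(scenario.n_regimes):
        shift = 0.0 if scenario.regimes_identical else scenario.gc_shift * r
        raw = base + shift * _AT_ENDING
        for fam in genetic_code.multi_codon_families:
            idx = [CODON_INDEX[c] for c in fam.codons]
            ref = CODON_INDEX[fam.reference]
            dm[r, idx] = raw[idx] - raw[ref]
            dm[r, ref] = 0.0
    return dm, deta


def simulate_genome(
    scenario: SimulationScenario, emit_sequences: bool = False
) -> tuple[list[GeneRecord], pd.DataFrame, SyntheticTruth]:
    """Generate a full synthetic genome.

    Returns (gene records with sequences if requested, observed-expression
    table, truth). Downstream code either rebuilds counts from the emitted
    sequences through genome_io (a true end-to-end test) or uses
    :func:`simulate_count_table` directly.
    """
    records, counts, expr_df, truth = _simulate(scenario, emit_sequences)
    return records, expr_df, truth


def simulate_count_table(scenario: SimulationScenario):
    """Generate counts directly as a CodonCountTable (no sequence emission)."""
    from .genome_io import CodonCountTable

    records, counts, expr_df, truth = _simulate(scenario, emit_sequences=False)
    gc3 = counts[:, _gc3_mask()].sum(axis=1) / counts.sum(axis=1)
    coords = truth.per_gene.set_index("gene_id")[["chromosome", "position"]]
    table = CodonCountTable(
        gene_ids=list(truth.per_gene["gene_id"]), counts=counts, gc3=gc3, coords=coords
    )
    return table, expr_df, truth


def _gc3_mask() -> np.ndarray:
    return np.array([c[2] in "GC" for c in SENSE_CODONS])


def _simulate(scenario: SimulationScenario, emit_sequences: bool):
    rng = np.random.default_rng(scenario.seed)
    gc = GeneticCode.from_name(scenario.genetic_code)
    layout = sample_regime_blocks(
        scenario.n_genes,
        scenario.n_chromosomes,
        scenario.mean_block_length,
        scenario.regime_proportions,
        rng,
    )
    phi = sample_expression(scenario.n_genes, scenario.s_phi, rng)
    dm, deta = draw_parameters(scenario, gc, rng)
    lengths = np.maximum(
        np.round(
            np.exp(rng.normal(np.log(scenario.gene_length_median), scenario.gene_length_log_sd, scenario.n_genes))
        ).astype(int),
        scenario.min_gene_length,
    )

    gene_ids = [f"g{i:05d}" for i in range(scenario.n_genes)]
    counts = np.zeros((scenario.n_genes, 61), dtype=np.int64)
    records: list[GeneRecord] = []
    regimes = layout["regime"].to_numpy()
    for i in range(scenario.n_genes):
        c, seq = simulate_gene_counts(
            gc, dm[regimes[i]], deta, phi[i], int(lengths[i]), rng,
            scenario.family_weights, emit_sequence=emit_sequences,
        )
        counts[i] = c
        records.append(
            GeneRecord(
                gene_id=gene_ids[i],
                sequence=seq or "",
                chromosome=str(layout["chromosome"].iloc[i]),
                position_index=int(layout["position"].iloc[i]),
            )
        )
    obs = simulate_observed_expression(phi, scenario.sigma_obs, rng)
    gc3 = counts[:, _gc3_mask()].sum(axis=1) / counts.sum(axis=1)

    per_gene = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": layout["chromosome"],
            "position": layout["position"],
            "regime": regimes,
            "phi_true": phi,
            "expression_obs": obs,
            "length_codons": lengths,
            "gc3": gc3,
        }
    )
    if scenario.n_regimes >= 2 and not scenario.regimes_identical:
        med = per_gene.groupby("regime")["gc3"].median()
        delta = float(med.max() - med.min())
    else:
        delta = 0.0
    truth = SyntheticTruth(
        scenario=scenario,
        per_gene=per_gene,
        delta_m=dm,
        delta_eta=deta,
        s_phi=scenario.s_phi,
        delta_median_gc3=delta,
    )
    expr_df = pd.DataFrame({"gene_id": gene_ids, "expression": obs})
    return records, counts, expr_df, truth


PRESETS = ("single_regime", "two_regime_strong", "two_regime_weak", "null_blocks")


def build_preset(name: str, n_genes: int = 2000, seed: int = 0, **overrides) -> SimulationScenario:
    """Named simulation scenarios used throughout the test battery."""
    if name == "single_regime":
        sc = SimulationScenario(n_genes=n_genes, n_regimes=1, regime_proportions=(1.0,), seed=seed)
    elif name == "two_regime_strong":
        sc = SimulationScenario(
            n_genes=n_genes, n_regimes=2, regime_proportions=(0.6, 0.4),
            gc_shift=1.0, mean_block_length=50.0, seed=seed,
        )
    elif name == "two_regime_weak":
        sc = SimulationScenario(
            n_genes=n_genes, n_regimes=2, regime_proportions=(0.6, 0.4),
            gc_shift=0.2, mean_block_length=50.0, seed=seed,
        )
    elif name == "null_blocks":
        sc = SimulationScenario(
            n_genes=n_genes, n_regimes=2, regime_proportions=(0.5, 0.5),
            gc_shift=0.0, regimes_identical=True, mean_block_length=1.0, seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return replace(sc, **overrides) if overrides else sc


def write_simulation(
    scenario: SimulationScenario, out_dir: str | Path
) -> SyntheticTruth:
    """Simulate and write FASTA, metadata TSV, expression TSV and truth tables."""
    from .genome_io import write_fasta
    import json
    from dataclasses import asdict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, expr_df, truth = simulate_genome(scenario, emit_sequences=True)
    write_fasta(records, out / "genes.fasta")
    truth.per_gene[["gene_id", "chromosome", "position"]].to_csv(
        out / "metadata.tsv", sep="\t", index=False
    )
    expr_df.to_csv(out / "expression.tsv", sep="\t", index=False)
    truth.per_gene.to_csv(out / "truth_per_gene.tsv", sep="\t", index=False)
    params = pd.DataFrame(
        {
            "codon": list(SENSE_CODONS),
            **{f"delta_m_regime{r}": truth.delta_m[r] for r in range(scenario.n_regimes)},
            "delta_eta": truth.delta_eta,
        }
    )
    params.to_csv(out / "truth_parameters.tsv", sep="\t", index=False)
    scen = asdict(scenario)
    scen["delta_median_gc3_realized"] = truth.delta_median_gc3
    (out / "scenario.json").write_text(json.dumps(scen, indent=2, default=str))
    return truth
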