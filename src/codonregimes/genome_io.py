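"""Reading coding sequences, gene filtering, codon counting, and GC3.

Genes enter the analysis as a ``CodonCountTable``: a genes × 61 matrix of
sense-codon counts plus per-gene GC3 and optional chromosome coordinates.
Filters follow the usual CDS sanity rules: canonical ATG start, length a
multiple of three, no internal stop, no ambiguity codes. The initiator ATG
and a terminal stop codon are excluded from counts by default (initiation
is constrained independently of synonymous codon choice and stop codons are
not sense codons); ``count_start_codon=True`` restores the initiator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import GeneticCode, SENSE_CODONS, STOP_CODONS

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_GC3_MASK = np.array([c[2] in "GC" for c in SENSE_CODONS])


@dataclass
class GeneRecord:
    gene_id: str
    sequence: str
    chromosome: str | None = None
    position_index: int | None = None


@dataclass
class CodonCountTable:
    """Genes × 61 sense-codon counts with per-gene GC3 and coordinates."""

    gene_ids: list[str]
    counts: np.ndarray  # (n_genes, 61) int
    gc3: np.ndarray  # (n_genes,) float in [0, 1]
    coords: pd.DataFrame | None = None  # index gene_id, columns chromosome/position

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), 61):
            raise ValueError("counts must be n_genes x 61")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every retained gene must have positive codon count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def frequencies(self) -> np.ndarray:
        """Per-gene codon frequencies (rows sum to 1)."""
        tot = self.counts.sum(axis=1, keepdims=True)
        return self.counts / tot

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=list(SENSE_CODONS))

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def read_cds_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a CDS FASTA; gene id is the first whitespace token of the header."""
    records = [
        GeneRecord(gene_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def filter_genes(
    records: Iterable[GeneRecord],
    exclusion_ids: Iterable[str] = (),
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Apply CDS filters; returns retained records and a rejection report.

    A gene is retained iff its id is not excluded, its length is a multiple
    of three, it starts with ATG, contains no internal stop codon (a
    terminal stop is allowed), and uses only A/C/G/T.
    """
    excluded = set(exclusion_ids)
    retained: list[GeneRecord] = []
    reasons: list[tuple[str, str]] = []
    for rec in records:
        reason = _rejection_reason(rec, excluded)
        if reason is None:
            retained.append(rec)
        else:
            reasons.append((rec.gene_id, reason))
    report = pd.DataFrame(reasons, columns=["gene_id", "reason"])
    return retained, report


def _rejection_reason(rec: GeneRecord, excluded: set[str]) -> str | None:
    seq = rec.sequence
    if rec.gene_id in excluded:
        return "excluded_id"
    if len(seq) == 0 or len(seq) % 3 != 0:
        return "length_not_multiple_of_three"
    if any(b not in "ACGT" for b in seq):
        return "ambiguous_bases"
    if seq[:3] != "ATG":
        return "non_canonical_start"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        return "internal_stop"
    if len(codons) < 2 or (len(codons) == 2 and codons[1] in STOP_CODONS):
        return "no_countable_codons"
    return None


def count_codons(
    rec: GeneRecord,
    genetic_code: GeneticCode | None = None,
    count_start_codon: bool = False,
) -> np.ndarray:
    """61-vector of sense-codon counts for a filtered gene.

    The terminal stop codon (if present) is excluded; the initiator ATG is
    excluded unless ``count_start_codon``.
    """
    seq = rec.sequence
    if _rejection_reason(rec, set()) is not None:
        raise ValueError(f"gene {rec.gene_id} does not pass CDS filters")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not count_start_codon:
        codons = codons[1:]
    out = np.zeros(61, dtype=np.int64)
    for c in codons:
        out[CODON_INDEX[c]] += 1
    return out


def gc3_percent(count_vector: np.ndarray) -> float:
    """Fraction of counted codons whose third base is G or C."""
    v = np.asarray(count_vector)
    total = v.sum()
    if total <= 0:
        raise ValueError("count vector sums to zero")
    return float(v[_GC3_MASK].sum() / total)


def build_count_table(
    records: Sequence[GeneRecord],
    genetic_code: GeneticCode | None = None,
    metadata: pd.DataFrame | None = None,
    count_start_codon: bool = False,
) -> CodonCountTable:
    """Assemble a CodonCountTable from filtered records, in input order.

    ``metadata`` (optional) has columns gene_id, chromosome, position; ids
    not matching any record trigger a warning and coords stay absent for
    unmatched genes.
    """
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in record set")
    counts = np.stack(
        [count_codons(r, genetic_code, count_start_codon) for r in records]
    )
    gc3 = np.array([gc3_percent(row) for row in counts])

    coords = None
    if metadata is not None:
        meta = metadata.set_index("gene_id") if "gene_id" in metadata.columns else metadata
        unknown = set(meta.index) - set(ids)
        if unknown:
            warnings.warn(f"{len(unknown)} metadata gene ids not in record set")
        coords = meta.reindex(ids)[["chromosome", "position"]]
    else:
        # fall back to FASTA order within any chromosome info on the records
        if any(r.chromosome is not None for r in records):
            coords = pd.DataFrame(
                {
                    "chromosome": [r.chromosome for r in records],
                    "position": [r.position_index for r in records],
                },
                index=ids,
            )
    return CodonCountTable(gene_ids=ids, counts=counts, gc3=gc3, coords=coords)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata TSV must have columns {sorted(required)}")
    return df


def read_exclusion_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_fasta(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
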