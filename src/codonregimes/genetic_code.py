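"""Codon family structure for the standard nuclear code and the CTG-Ser variant.

The selection-mutation-drift model treats each set of synonymous codons
("family") independently, with one family member fixed as the reference
(coefficients 0). Following common practice for this model, the four-codon
serine box TCN and the two-codon box AGY are treated as separate families
(they are not exchangeable by single synonymous substitutions), and in
CTG-Ser clade yeasts CTG (translated as serine) becomes its own singleton
family. The reference codon of every family is its alphabetically last
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = "ACGT"

#: the 61 sense codons of the standard code, alphabetical
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

# amino acid -> member codons under the standard code, serine split into
# the TCN box ("Ser4") and the AGY box ("Ser2")
_STANDARD_FAMILIES: dict[str, tuple[str, ...]] = {
    "Ala": ("GCA", "GCC", "GCG", "GCT"),
    "Arg": ("AGA", "AGG", "CGA", "CGC", "CGG", "CGT"),
    "Asn": ("AAC", "AAT"),
    "Asp": ("GAC", "GAT"),
    "Cys": ("TGC", "TGT"),
    "Gln": ("CAA", "CAG"),
    "Glu": ("GAA", "GAG"),
    "Gly": ("GGA", "GGC", "GGG", "GGT"),
    "His": ("CAC", "CAT"),
    "Ile": ("ATA", "ATC", "ATT"),
    "Leu": ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG"),
    "Lys": ("AAA", "AAG"),
    "Met": ("ATG",),
    "Phe": ("TTC", "TTT"),
    "Pro": ("CCA", "CCC", "CCG", "CCT"),
    "Ser4": ("TCA", "TCC", "TCG", "TCT"),
    "Ser2": ("AGC", "AGT"),
    "Thr": ("ACA", "ACC", "ACG", "ACT"),
    "Trp": ("TGG",),
    "Tyr": ("TAC", "TAT"),
    "Val": ("GTA", "GTC", "GTG", "GTT"),
}


@dataclass(frozen=True)
class CodonFamily:
    family_id: str
    codons: tuple[str, ...]  # alphabetical
    reference: str  # alphabetically last member

    @property
    def n_codons(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class GeneticCode:
    """Partition of the 61 sense codons into synonymous families.

    Parameters
    ----------
    code_name : {"standard", "ctg_ser"}
        ``ctg_ser`` moves CTG out of the leucine family into a singleton
        serine family (CTG-Ser clade yeasts).
    """

    code_name: str
    families: tuple[CodonFamily, ...]
    codon_to_family: dict[str, str] = field(repr=False)
    stop_codons: frozenset[str] = STOP_CODONS

    @classmethod
    def from_name(cls, code_name: str = "standard") -> "GeneticCode":
        if code_name not in ("standard", "ctg_ser"):
            raise ValueError(f"unknown genetic code {code_name!r}")
        fam_map = dict(_STANDARD_FAMILIES)
        if code_name == "ctg_ser":
            fam_map["Leu"] = tuple(c for c in fam_map["Leu"] if c != "CTG")
            fam_map["SerCTG"] = ("CTG",)
        families = tuple(
            CodonFamily(fid, tuple(sorted(members)), max(members))
            for fid, members in sorted(fam_map.items())
        )
        c2f = {c: f.family_id for f in families for c in f.codons}
        return cls(code_name=code_name, families=families, codon_to_family=c2f)

    def family(self, family_id: str) -> CodonFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    @property
    def multi_codon_families(self) -> tuple[CodonFamily, ...]:
        """Families with at least two members (the ones carrying parameters)."""
        return tuple(f for f in self.families if f.n_codons >= 2)

    @property
    def n_free_parameters(self) -> int:
        """Number of free coefficients per parameter type: sum of (n_aa - 1)."""
        return sum(f.n_codons - 1 for f in self.families)
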