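"""Core domain types shared across the triage pipeline.

The unit of analysis is a single alternate allele at a single genomic
site, carrying the functional annotation (gene symbol, consequence term,
protein change) produced by an upstream annotator, plus per-sample
genotype dosages. Multi-allelic VCF records are split on read, so every
:class:`AnnotatedVariant` holds exactly one alt allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

#: Valid one-letter amino-acid codes (the 20 standard residues).
AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Dosage value used for a missing genotype.
MISSING = None


class TriageError(Exception):
    """Base class for errors raised by the triage pipeline."""


class ProteinChangeError(TriageError):
    """A protein-change token could not be parsed."""


@dataclass(frozen=True)
class ProteinVariant:
    """A protein-level change in compact notation (e.g. G12A, C303*, K100fs).

    Parameters
    ----------
    gene : str
        Gene symbol the change belongs to.
    aa_ref : str
        One-letter code of the reference residue.
    aa_pos : int
        1-based residue position.
    aa_alt : str
        One-letter code of the substituted residue, ``'*'`` for a stop
        gain, or ``'fs'`` for a frameshift.
    """

    gene: str
    aa_ref: str
    aa_pos: int
    aa_alt: str

    def __post_init__(self) -> None:
        if self.aa_ref not in AA_CODES:
            raise ProteinChangeError(
                f"invalid reference residue {self.aa_ref!r} in "
                f"{self.gene} {self.aa_ref}{self.aa_pos}{self.aa_alt}"
            )
        if self.aa_pos < 1:
            raise ProteinChangeError(f"residue position must be >= 1, got {self.aa_pos}")
        if self.aa_alt not in AA_CODES and self.aa_alt not in ("*", "fs"):
            raise ProteinChangeError(f"invalid substituted residue {self.aa_alt!r}")
        if self.aa_ref == self.aa_alt:
            raise ProteinChangeError(
                f"synonymous token {self.aa_ref}{self.aa_pos}{self.aa_alt} is not a variant"
            )

    @property
    def is_frameshift(self) -> bool:
        return self.aa_alt == "fs"

    @property
    def is_stop(self) -> bool:
        return self.aa_alt == "*"

    def __str__(self) -> str:
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


#: Genomic allele key used throughout: (chrom, pos, ref, alt).
VariantKey = Tuple[str, int, str, str]


@dataclass
class AnnotatedVariant:
    """One alt allele at one site with its functional annotation.

    ``sample_genotypes`` maps sample id to the dosage of *this* alt
    allele in {0, 1, 2} or ``None`` for a missing genotype. Phased and
    unphased genotypes are treated identically.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "unannotated"
    protein_change: Optional[ProteinVariant] = None
    protein_change_raw: str = ""
    sample_genotypes: Dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"genomic position must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError(f"alt must be a single allele, got {self.alt!r}")
        for sample, dosage in self.sample_genotypes.items():
            if dosage is not None and dosage not in (0, 1, 2):
                raise ValueError(f"dosage for {sample} must be 0/1/2/missing, got {dosage!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def position_key(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)

    def carriers(self) -> list[str]:
        """Sample ids with dosage >= 1 of this allele."""
        return [s for s, d in self.sample_genotypes.items() if d is not None and d >= 1]

    @property
    def change_label(self) -> str:
        """Human-readable protein-change label, falling back to the raw token."""
        if self.protein_change is not None:
            return str(self.protein_change)
        return self.protein_change_raw
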