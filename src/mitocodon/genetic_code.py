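"""Genetic-code tables and the synonymous-family structure derived from them.

Two NCBI translation tables are supported: table 1 (the standard code) and
table 2 (vertebrate mitochondrial).  Everything downstream — RSCU, ENC, CAI,
GC3s, PR2 — depends on how sense codons partition into synonymous families,
so that partition is derived programmatically from the table rather than
hard-coded.  Under table 2 the census is 12 two-fold, 6 four-fold and 2
six-fold families (60 sense codons); under table 1 it additionally has
one-fold (Met, Trp) and three-fold (Ile) families (61 sense codons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

BASES = "TCAG"
STOP = "*"

_SUPPORTED_TABLES = (1, 2)


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id outside the supported set."""


class InvalidSequenceError(ValueError):
    """Raised when a CDS contains characters outside the IUPAC alphabet."""


# IUPAC nucleotide alphabet; codons with any non-ACGT member are excluded
# from counts rather than resolved.
IUPAC_BASES = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class SynonymousFamily:
    """A set of codons translated to the same amino acid.

    ``degeneracy`` equals the size of ``codons``; six-fold families (Leu,
    Ser under table 2) may optionally be split into their 2- and 4-codon
    subfamilies, a convention some legacy codon-usage tools follow.
    """

    amino_acid: str
    codons: tuple[str, ...]
    degeneracy: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "degeneracy", len(self.codons))


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon → amino acid, stop set, start set.

    Codons are stored as DNA triplets throughout; reports that want
    RNA-style rendering (CUA, GUA, ...) convert at the output boundary
    with :func:`to_rna`.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in self.codon_to_aa.items() if aa != STOP)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All sense codons synonymous with ``codon`` (including itself)."""
        aa = self.codon_to_aa[codon]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon under table {self.table_id}")
        return tuple(c for c in self.sense_codons if self.codon_to_aa[c] == aa)


def all_codons() -> list[str]:
    return [a + b + c for a in BASES for b in BASES for c in BASES]


def to_rna(codon: str) -> str:
    """Render a DNA triplet in RNA style for reports (CTA → CUA)."""
    return codon.replace("T", "U")


def from_rna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def load_code(table_id: int) -> GeneticCode:
    """Load translation table 1 (standard) or 2 (vertebrate mitochondrial)."""
    if table_id not in _SUPPORTED_TABLES:
        raise UnsupportedCodeError(
            f"translation table {table_id!r} not supported (use 1 or 2)"
        )
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    mapping = {c: STOP for c in bio.stop_codons}
    mapping.update(bio.forward_table)
    # order the 64 codons canonically (TCAG nesting, CodonW-style)
    codon_to_aa = {c: mapping[c] for c in all_codons()}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(bio.start_codons),
        stop_codons=frozenset(bio.stop_codons),
    )


def synonymous_families(
    code: GeneticCode, split_sixfold: bool = False
) -> list[SynonymousFamily]:
    """Partition the sense codons into synonymous families.

    With ``split_sixfold=True`` the six-codon families (Leu, Ser) are split
    into the two subfamilies that differ in their first two bases, yielding
    a 2-fold and a 4-fold family each.
    """
    by_aa: dict[str, list[str]] = {}
    for codon, aa in code.codon_to_aa.items():
        if aa == STOP:
            continue
        by_aa.setdefault(aa, []).append(codon)
    families: list[SynonymousFamily] = []
    for aa, codons in by_aa.items():
        if split_sixfold and len(codons) == 6:
            by_prefix: dict[str, list[str]] = {}
            for c in codons:
                by_prefix.setdefault(c[:2], []).append(c)
            for sub in by_prefix.values():
                families.append(SynonymousFamily(aa, tuple(sub)))
        else:
            families.append(SynonymousFamily(aa, tuple(codons)))
    families.sort(key=lambda f: f.codons[0])
    return families


def degeneracy_census(code: GeneticCode, split_sixfold: bool = False) -> dict[int, int]:
    """Number of synonymous families per degeneracy class."""
    census: dict[int, int] = {}
    for fam in synonymous_families(code, split_sixfold=split_sixfold):
        census[fam.degeneracy] = census.get(fam.degeneracy, 0) + 1
    return census


def translate(cds: str, code: GeneticCode) -> tuple[str, bool]:
    """Translate a CDS codon by codon.

    Returns ``(protein, incomplete)`` where ``incomplete`` flags a trailing
    partial codon (dropped from the translation).  Stop codons render as
    ``*``; the caller decides whether an internal stop is an error.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) < 3:
        raise InvalidSequenceError("CDS shorter than one codon")
    bad = set(seq) - IUPAC_BASES
    if bad:
        raise InvalidSequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    protein = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if set(codon) <= set("ACGT"):
            protein.append(code.codon_to_aa[codon])
        else:
            protein.append("X")
    return "".join(protein), len(seq) % 3 != 0
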