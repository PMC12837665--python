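"""Base composition, strand skews, positional GC content and PR2 coordinates.

Vertebrate mitogenomes are AT-rich and strand-asymmetric: the heavy strand
is enriched in A over T and depleted in G relative to C, quantified by

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

both dimensionless in [-1, 1].  Positional GC content (GC1/GC2/GC3) is the
G+C percentage at each codon position of a coding-sequence set; GC3s
restricts the third position to codons from synonymously variable families,
and the PR2 (parity rule 2) coordinates A3/(A3+T3) and G3/(G3+C3) are taken
over fourfold-degenerate third positions only, where (0.5, 0.5) indicates
no strand bias.

Internal representation is fractions; report columns carry explicit unit
styles (GC 0.430 vs GC1 50.51%) to mirror the conventional table layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genetic_code import GeneticCode
from .mito_io import CodingSequence


class UndefinedSkewError(ValueError):
    """A+T or G+C is zero, so the corresponding skew is undefined."""


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionStats:
    """Base fractions (as percentages) and strand skews of one sequence."""

    a: float
    c: float
    g: float
    t: float

    @property
    def at_content(self) -> float:
        return self.a + self.t

    @property
    def gc_content(self) -> float:
        return self.g + self.c

    @property
    def at_skew(self) -> float:
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        return (self.g - self.c) / (self.g + self.c)


@dataclass(frozen=True)
class PositionalGC:
    """GC content by codon position; gc1-gc3 are percentages, gc_all and
    gc3s fractions (the mixed styles of the conventional table layout)."""

    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    gc3s: float


def base_composition(
    seq: str | None = None, *, percentages: Mapping[str, float] | None = None
) -> CompositionStats:
    """Composition and skews from a raw sequence or from printed percentages.

    Ambiguity codes are ignored when counting from a sequence; percentages
    must cover A/C/G/T and sum to ~100.
    """
    if (seq is None) == (percentages is None):
        raise ValueError("provide exactly one of seq or percentages")
    if seq is not None:
        s = seq.upper()
        if not s:
            raise EmptyInputError("empty sequence")
        counts = {b: s.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            raise EmptyInputError("sequence has no unambiguous bases")
        pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    else:
        pct = {b.upper(): float(v) for b, v in percentages.items()}
        missing = set("ACGT") - set(pct)
        if missing:
            raise ValueError(f"percentages missing bases {sorted(missing)}")
        if abs(sum(pct[b] for b in "ACGT") - 100.0) > 0.5:
            raise ValueError("percentages do not sum to ~100")
    if pct["A"] + pct["T"] == 0 or pct["G"] + pct["C"] == 0:
        raise UndefinedSkewError("A+T or G+C is zero; skew undefined")
    return CompositionStats(a=pct["A"], c=pct["C"], g=pct["G"], t=pct["T"])


def _counted_codons(
    cds_set: Iterable[CodingSequence], code: GeneticCode
) -> list[str]:
    """Codons entering positional statistics: complete, unambiguous, non-stop."""
    out = []
    for cds in cds_set:
        for codon in cds.codons():
            if set(codon) <= set("ACGT") and not code.is_stop(codon):
                out.append(codon)
    return out


def fourfold_prefixes(code: GeneticCode) -> frozenset[str]:
    """Dinucleotide prefixes whose third position is fully degenerate."""
    prefixes = set()
    for p in (a + b for a in "TCAG" for b in "TCAG"):
        aas = {code.codon_to_aa[p + third] for third in "TCAG"}
        if len(aas) == 1 and "*" not in aas:
            prefixes.add(p)
    return frozenset(prefixes)


def gc_by_position(
    cds_set: Sequence[CodingSequence], code: GeneticCode
) -> PositionalGC:
    """Positional GC over a coding-sequence set (stop codons excluded).

    gc3s is restricted to third positions of codons whose synonymous family
    has degeneracy >= 2 under ``code`` — under the vertebrate mitochondrial
    code that is every sense codon, so gc3s and gc3 coincide there; under
    the standard code Met and Trp are excluded.
    """
    codons = _counted_codons(cds_set, code)
    if not codons:
        raise EmptyInputError("no complete unambiguous codons in input")
    n = len(codons)
    gc_at = [0, 0, 0]
    for codon in codons:
        for i, base in enumerate(codon):
            if base in "GC":
                gc_at[i] += 1
    syn = [c for c in codons if len(code.family_of(c)) >= 2]
    gc3s_count = sum(1 for c in syn if c[2] in "GC")
    return PositionalGC(
        gc1=100.0 * gc_at[0] / n,
        gc2=100.0 * gc_at[1] / n,
        gc3=100.0 * gc_at[2] / n,
        gc_all=(gc_at[0] + gc_at[1] + gc_at[2]) / (3.0 * n),
        gc3s=gc3s_count / len(syn) if syn else float("nan"),
    )


def pr2_coordinates(
    cds_set: Sequence[CodingSequence], code: GeneticCode
) -> tuple[float, float]:
    """PR2 coordinates (A3/(A3+T3), G3/(G3+C3)) at fourfold-degenerate sites."""
    prefixes = fourfold_prefixes(code)
    thirds = [
        c[2] for c in _counted_codons(cds_set, code) if c[:2] in prefixes
    ]
    if not thirds:
        raise EmptyInputError("no fourfold-degenerate codons in input")
    a3 = thirds.count("A")
    t3 = thirds.count("T")
    g3 = thirds.count("G")
    c3 = thirds.count("C")
    if a3 + t3 == 0 or g3 + c3 == 0:
        raise EmptyInputError("degenerate third-position composition")
    return a3 / (a3 + t3), g3 / (g3 + c3)


# ---------------------------------------------------------------------------
# printed-table fixtures and aggregation


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("mitocodon.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_table1() -> pd.DataFrame:
    """Per-species genome composition rows (printed values, as strings)."""
    return _load_fixture("table1_composition.tsv")


def load_table2() -> pd.DataFrame:
    """Per-species CAI/ENC/GC rows (printed values, as strings)."""
    return _load_fixture("table2_codon_indices.tsv")


def printed_decimals(value: str) -> int:
    s = value.strip().rstrip("%")
    return len(s.split(".")[1]) if "." in s else 0


def parse_printed(value: str) -> float:
    return float(value.strip().rstrip("%").replace(",", ""))


def aggregate_mean(table: pd.DataFrame, column: str) -> float:
    """Arithmetic mean of a printed column, at report precision.

    Means are reported with at least two decimals, or at the rows' own
    precision when that is finer — the convention of the comparative-table
    mean rows (e.g. integer genome lengths average to 16,540.33 while
    three-decimal ENC rows average to three decimals).
    """
    if len(table) == 0:
        raise EmptyInputError("empty table")
    values = [parse_printed(v) for v in table[column]]
    decimals = max(2, max(printed_decimals(v) for v in table[column]))
    return round(sum(values) / len(values), decimals)
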