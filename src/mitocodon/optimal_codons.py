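"""Optimal-codon identification by the ENC-ranked ΔRSCU procedure.

Without expression data, per-gene ENC serves as an expression proxy: genes
are ranked by ENC and the top and bottom fractions (default 10%, so a
single gene each for the 13 mitochondrial PCGs) form the high- and
low-expression sets.  A codon is called optimal when its RSCU exceeds 1 in
the high-expression set, falls below 1 in the low-expression set, and the
two differ by more than a threshold (default |ΔRSCU| > 0.08).

Which ENC extreme represents high expression is genuinely ambiguous in
practice: strong translational selection predicts low ENC (high bias) in
highly expressed genes — the ``direction="methods"`` default — but some
analyses take the highest-ENC gene as the high-expression proxy
(``direction="results"``).  Both are supported; the flag changes only
which gene set is labelled "high".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TextIO

from .codon_usage import CodonCountTable, rscu
from .genetic_code import GeneticCode, to_rna

DEFAULT_FRACTION = 0.10
DEFAULT_THRESHOLD = 0.08


class InvalidFractionError(ValueError):
    """The requested group fraction makes the high and low sets overlap."""


@dataclass(frozen=True)
class ExpressionSplit:
    high_set: tuple[str, ...]
    low_set: tuple[str, ...]
    group_fraction: float
    direction: str


@dataclass
class OptimalCodonRow:
    codon: str  # DNA triplet internally
    amino_acid: str
    rscu_high: float | None
    rscu_low: float | None
    delta_rscu: float | None
    optimal: bool


@dataclass
class OptimalCodonReport:
    rows: list[OptimalCodonRow]
    threshold: float

    def optimal_codons(self, rna: bool = True) -> list[str]:
        out = [r.codon for r in self.rows if r.optimal]
        return [to_rna(c) for c in out] if rna else out

    @property
    def n_optimal(self) -> int:
        return sum(r.optimal for r in self.rows)

    def to_tsv(self, handle_or_path: str | Path | TextIO) -> None:
        lines = ["codon\tamino_acid\trscu_high\trscu_low\tdelta_rscu\toptimal"]
        fmt = lambda v: f"{v:.4f}" if v is not None else "NA"
        for r in self.rows:
            lines.append(
                f"{to_rna(r.codon)}\t{r.amino_acid}\t{fmt(r.rscu_high)}\t"
                f"{fmt(r.rscu_low)}\t{fmt(r.delta_rscu)}\t{int(r.optimal)}"
            )
        text = "\n".join(lines) + "\n"
        if isinstance(handle_or_path, (str, Path)):
            Path(handle_or_path).write_text(text)
        else:
            handle_or_path.write(text)


def expression_split(
    enc_by_gene: Mapping[str, float],
    fraction: float = DEFAULT_FRACTION,
    direction: str = "methods",
) -> ExpressionSplit:
    """Split genes into high/low expression proxies by ENC rank.

    Group size is max(1, floor(fraction * G)); ties in ENC fall back to
    name order so the split is deterministic.  ``direction="methods"``
    takes the lowest-ENC genes as high expression; ``"results"`` takes the
    highest-ENC genes.
    """
    if direction not in ("methods", "results"):
        raise ValueError("direction must be 'methods' or 'results'")
    genes = {g: e for g, e in enc_by_gene.items() if e is not None and not math.isnan(e)}
    if len(genes) < 2:
        raise ValueError("need at least two genes with defined ENC")
    size = max(1, math.floor(fraction * len(genes)))
    if 2 * size > len(genes):
        raise InvalidFractionError(
            f"fraction {fraction} gives overlapping groups of {size} from {len(genes)} genes"
        )
    ranked = sorted(genes, key=lambda g: (genes[g], g))  # ascending ENC
    low_enc = tuple(ranked[:size])
    high_enc = tuple(ranked[-size:])
    if direction == "methods":
        high, low = low_enc, high_enc
    else:
        high, low = high_enc, low_enc
    return ExpressionSplit(
        high_set=high, low_set=low, group_fraction=fraction, direction=direction
    )


def identify_optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    code: GeneticCode,
    threshold: float = DEFAULT_THRESHOLD,
    split_sixfold: bool = False,
) -> OptimalCodonReport:
    """Per-codon ΔRSCU report between high- and low-expression count tables.

    A codon with a zero-count family in either table can never be optimal
    (its RSCU there is undefined).  All three criteria are strict
    inequalities.
    """
    if high.total == 0 or low.total == 0:
        raise ValueError("both count tables must be non-empty")
    rscu_h = rscu(high, code, split_sixfold=split_sixfold)
    rscu_l = rscu(low, code, split_sixfold=split_sixfold)
    rows = []
    for codon, aa in code.codon_to_aa.items():
        if aa == "*":
            continue
        rh = rscu_h.get(codon)
        rl = rscu_l.get(codon)
        delta = rh - rl if rh is not None and rl is not None else None
        optimal = (
            rh is not None
            and rl is not None
            and rh > 1.0
            and rl < 1.0
            and abs(delta) > threshold
        )
        rows.append(OptimalCodonRow(codon, aa, rh, rl, delta, optimal))
    return OptimalCodonReport(rows=rows, threshold=threshold)
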