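"""Codon counting and codon-usage-bias indices: RSCU, ENC and CAI.

Relative synonymous codon usage for codon j of amino acid i with
degeneracy n_i and observed counts x_ij is

    RSCU_ij = x_ij * n_i / sum_j x_ij

so RSCU sums to n_i within each family and 1 means no bias.

Wright's effective number of codons estimates, per synonymous family with
n observed codons at frequencies p_j,

    F_hat = (n * sum p_j^2 - 1) / (n - 1)

averages F_hat within each degeneracy class k, and reports

    ENC = N_1 + sum_k N_k / F_bar_k

where N_k is the number of families of degeneracy k in the genetic code.
ENC ranges from the number of families (~20, maximal bias) up to the
sense-codon count (61 standard, 60 vertebrate mitochondrial; no bias).
The null expectation of ENC from GC3s alone (the curve drawn in ENC-GC3s
plots) is ENC* = 2 + s + 29 / (s^2 + (1-s)^2).

The codon adaptation index is the geometric mean over a gene's codons of
the relative adaptiveness w_ij = RSCU_ij / max_j RSCU_ij taken from a
reference codon-usage table; stop codons and single-codon families carry
no synonymous signal and are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .genetic_code import (
    GeneticCode,
    SynonymousFamily,
    synonymous_families,
    to_rna,
)
from .mito_io import CodingSequence

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    pass


class UndefinedENCError(ValueError):
    """No degeneracy class has an estimable family."""


@dataclass
class CodonCountTable:
    """Per-codon counts x_ij for a gene or gene set (sense codons only)."""

    counts: dict[str, int]
    scope: str = ""
    code_id: int = 2
    n_stops_excluded: int = 0
    n_partial_excluded: int = 0
    n_ambiguous_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.code_id != other.code_id:
            raise ValueError("cannot add tables under different codes")
        merged = dict(self.counts)
        for c, x in other.counts.items():
            merged[c] = merged.get(c, 0) + x
        return CodonCountTable(
            counts=merged,
            scope=f"{self.scope}+{other.scope}".strip("+"),
            code_id=self.code_id,
            n_stops_excluded=self.n_stops_excluded + other.n_stops_excluded,
            n_partial_excluded=self.n_partial_excluded + other.n_partial_excluded,
            n_ambiguous_excluded=self.n_ambiguous_excluded + other.n_ambiguous_excluded,
        )


@dataclass
class RSCUTable:
    """Per-codon RSCU; codons of families with zero count are missing (None)."""

    values: dict[str, float | None]
    scope: str = ""

    def get(self, codon: str) -> float | None:
        return self.values.get(codon)


@dataclass
class CUBIndices:
    """Bundle of codon-usage-bias indices for one gene or gene set."""

    enc: float
    cai: float | None
    gc3s: float
    positional: object = None
    scope: str = ""


def count_codons(
    cds: CodingSequence | Iterable[CodingSequence],
    code: GeneticCode,
    scope: str | None = None,
) -> CodonCountTable:
    """Count complete sense codons of one CDS or a CDS set.

    Stop codons, the trailing partial codon of an incomplete stop and
    codons containing non-ACGT bases are excluded and tallied separately.
    """
    cds_list = [cds] if isinstance(cds, CodingSequence) else list(cds)
    counts: dict[str, int] = {}
    n_stop = n_partial = n_ambig = 0
    for one in cds_list:
        if len(one.nt) % 3:
            n_partial += 1
        for codon in one.codons():
            if not set(codon) <= set("ACGT"):
                n_ambig += 1
            elif code.is_stop(codon):
                n_stop += 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
    label = scope if scope is not None else (
        cds_list[0].gene if len(cds_list) == 1 else "+".join(c.gene for c in cds_list)
    )
    return CodonCountTable(
        counts=counts,
        scope=label,
        code_id=code.table_id,
        n_stops_excluded=n_stop,
        n_partial_excluded=n_partial,
        n_ambiguous_excluded=n_ambig,
    )


def rscu(
    counts: CodonCountTable, code: GeneticCode, split_sixfold: bool = False
) -> RSCUTable:
    values: dict[str, float | None] = {}
    for fam in synonymous_families(code, split_sixfold=split_sixfold):
        fam_total = sum(counts.get(c) for c in fam.codons)
        for c in fam.codons:
            if fam_total == 0:
                values[c] = None
            else:
                values[c] = counts.get(c) * fam.degeneracy / fam_total
    return RSCUTable(values=values, scope=counts.scope)


def _family_homozygosity(counts: CodonCountTable, fam: SynonymousFamily) -> tuple[float | None, int]:
    """Wright's F_hat for one family; None when n < 2 or F_hat <= 0."""
    x = [counts.get(c) for c in fam.codons]
    n = sum(x)
    if n < 2:
        return None, n
    s = sum((xi / n) ** 2 for xi in x)
    f = (n * s - 1) / (n - 1)
    if f <= 0:
        return None, n
    return f, n


def enc(
    counts: CodonCountTable, code: GeneticCode, split_sixfold: bool = False
) -> float:
    """Wright's effective number of codons for a count table.

    Degeneracy-class sizes N_k come from the genetic code, never from the
    data.  A class with no estimable family is interpolated when it is the
    3-fold class (F_bar_3 ~ (F_bar_2 + F_bar_4)/2) and otherwise dropped,
    with the result rescaled by the represented sense-codon count; either
    fallback is logged.  The result is clipped above at the sense-codon
    count.
    """
    fams = synonymous_families(code, split_sixfold=split_sixfold)
    class_n: dict[int, int] = {}
    class_f: dict[int, list[float]] = {}
    for fam in fams:
        class_n[fam.degeneracy] = class_n.get(fam.degeneracy, 0) + 1
        if fam.degeneracy == 1:
            continue
        f, _ = _family_homozygosity(counts, fam)
        if f is not None:
            class_f.setdefault(fam.degeneracy, []).append(f)
    fbar = {k: sum(v) / len(v) for k, v in class_f.items()}
    if not fbar:
        raise UndefinedENCError(f"{counts.scope or 'table'}: no estimable synonymous family")
    if 3 in class_n and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
        logger.info("%s: interpolated F_bar for the 3-fold class", counts.scope)
    total = class_n.get(1, 0)  # single-codon families contribute N_1 directly
    represented = class_n.get(1, 0)
    sense = len(code.sense_codons)
    for k, nk in class_n.items():
        if k == 1:
            continue
        if k in fbar:
            total += nk / fbar[k]
            represented += nk * k
        else:
            logger.info("%s: degeneracy class %d unrepresented; rescaling", counts.scope, k)
    if represented < sense:
        total *= sense / represented
    return min(total, float(sense))


def expected_enc(gc3s: float) -> float:
    """Null ENC expected from GC3s composition alone (ENC-GC3s plot curve)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError("gc3s must be a fraction in [0, 1]")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def relative_adaptiveness(
    reference: CodonCountTable,
    code: GeneticCode,
    smoothing: float = 0.5,
    split_sixfold: bool = False,
) -> dict[str, float]:
    """w_ij = RSCU_ij / max_j RSCU_ij from a reference count table.

    Within each family observed in the reference, zero-count codons receive
    a pseudo-count (default 0.5) before the RSCU computation so that log w
    stays finite.  Families never observed in the reference yield no w.
    """
    w: dict[str, float] = {}
    for fam in synonymous_families(code, split_sixfold=split_sixfold):
        raw = [reference.get(c) for c in fam.codons]
        if sum(raw) == 0:
            continue
        x = [xi if xi > 0 else smoothing for xi in raw]
        tot = sum(x)
        rscu_fam = [xi * fam.degeneracy / tot for xi in x]
        m = max(rscu_fam)
        for c, r in zip(fam.codons, rscu_fam):
            w[c] = r / m
    return w


def cai(
    counts: CodonCountTable,
    reference: CodonCountTable,
    code: GeneticCode,
    smoothing: float = 0.5,
    split_sixfold: bool = False,
) -> float:
    """Codon adaptation index of ``counts`` against a reference table.

    Geometric mean of w over the gene's codons, excluding stop codons
    (never counted) and families of degeneracy 1; codons whose family is
    absent from the reference are skipped with a warning.
    """
    if counts.total == 0:
        raise EmptyInputError(f"{counts.scope or 'gene'}: no codons to score")
    w = relative_adaptiveness(reference, code, smoothing=smoothing, split_sixfold=split_sixfold)
    deg1 = {
        c
        for fam in synonymous_families(code, split_sixfold=split_sixfold)
        if fam.degeneracy == 1
        for c in fam.codons
    }
    log_sum = 0.0
    n = 0
    skipped = 0
    for codon, x in counts.counts.items():
        if codon in deg1:
            continue
        if codon not in w:
            skipped += x
            continue
        log_sum += x * math.log(w[codon])
        n += x
    if n == 0:
        raise EmptyInputError(f"{counts.scope or 'gene'}: no scorable codons for CAI")
    if skipped:
        logger.warning("%s: %d codons outside the reference families skipped", counts.scope, skipped)
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# TSV I/O (CodonW-style 64-row layout, RNA rendering at the boundary)


def write_codon_report(
    counts: CodonCountTable,
    code: GeneticCode,
    handle_or_path: str | Path | TextIO,
    rscu_table: RSCUTable | None = None,
) -> None:
    if rscu_table is None:
        rscu_table = rscu(counts, code)
    lines = ["codon\tamino_acid\tcount\trscu"]
    for codon, aa in code.codon_to_aa.items():
        if aa == "*":
            lines.append(f"{to_rna(codon)}\t*\t0\t")
            continue
        r = rscu_table.get(codon)
        lines.append(
            f"{to_rna(codon)}\t{aa}\t{counts.get(codon)}\t"
            + (f"{r:.4f}" if r is not None else "NA")
        )
    text = "\n".join(lines) + "\n"
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def read_reference_counts(
    source: str | Path | TextIO, code: GeneticCode, scope: str = "reference"
) -> CodonCountTable:
    """Read a codon/count TSV (RNA or DNA triplets) as a reference table."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    counts: dict[str, int] = {}
    for line in text.splitlines():
        parts = line.strip().split("\t")
        if len(parts) < 2 or parts[0].lower() == "codon":
            continue
        codon = parts[0].upper().replace("U", "T")
        column = parts[2] if len(parts) > 2 and parts[1].isalpha() else parts[1]
        try:
            x = int(column)
        except ValueError:
            continue
        if codon in code.codon_to_aa and not code.is_stop(codon) and x > 0:
            counts[codon] = counts.get(codon, 0) + x
    return CodonCountTable(counts=counts, scope=scope, code_id=code.table_id)
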