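"""Independent brute-force oracles for the codon-usage statistics.

These reimplement each definition directly from the NCBI translation tables
shipped with Biopython, sharing no code with the package: plain loops over
explicitly enumerated synonymous families.  They exist so the package
implementations can be cross-checked on arbitrary count tables.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable

BASES = "TCAG"


def families(table_id: int) -> dict[str, list[str]]:
    """amino acid -> synonymous codons, enumerated straight from the table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for a in BASES:
        for b in BASES:
            for c in BASES:
                codon = a + b + c
                if codon in table.stop_codons:
                    continue
                fams.setdefault(table.forward_table[codon], []).append(codon)
    return fams


def rscu_oracle(counts: dict[str, int], table_id: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for codons in families(table_id).values():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        for c in codons:
            out[c] = counts.get(c, 0) * len(codons) / total
    return out


def enc_oracle(counts: dict[str, int], table_id: int) -> float:
    """Wright's estimator by direct evaluation.

    Assumes every degeneracy class has at least one family with n >= 2 and
    positive homozygosity (true for the tables it is used on in tests).
    """
    by_class: dict[int, list[float]] = {}
    n_classes: dict[int, int] = {}
    for codons in families(table_id).values():
        k = len(codons)
        n_classes[k] = n_classes.get(k, 0) + 1
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in codons) - 1) / (n - 1)
        if f > 0:
            by_class.setdefault(k, []).append(f)
    enc = float(n_classes.get(1, 0))
    for k, nk in n_classes.items():
        if k == 1:
            continue
        fs = by_class.get(k)
        if fs is None and k == 3:
            f2 = sum(by_class[2]) / len(by_class[2])
            f4 = sum(by_class[4]) / len(by_class[4])
            fbar = (f2 + f4) / 2
        else:
            fbar = sum(fs) / len(fs)
        enc += nk / fbar
    sense = sum(len(c) for c in families(table_id).values())
    return min(enc, float(sense))


def cai_oracle(
    gene: dict[str, int], reference: dict[str, int], table_id: int, smoothing: float = 0.5
) -> float:
    w: dict[str, float] = {}
    for codons in families(table_id).values():
        if len(codons) == 1:
            continue
        raw = [reference.get(c, 0) for c in codons]
        if sum(raw) == 0:
            continue
        x = [v if v > 0 else smoothing for v in raw]
        rscu = [v * len(codons) / sum(x) for v in x]
        top = max(rscu)
        for c, r in zip(codons, rscu):
            w[c] = r / top
    log_sum, n = 0.0, 0
    for c, x in gene.items():
        if c in w:
            log_sum += x * math.log(w[c])
            n += x
    return math.exp(log_sum / n)


def optimal_oracle(
    high: dict[str, int], low: dict[str, int], table_id: int, threshold: float = 0.08
) -> set[str]:
    """DNA codons passing all three optimality inequalities, checked directly."""
    rh = rscu_oracle(high, table_id)
    rl = rscu_oracle(low, table_id)
    out = set()
    for c in set(rh) & set(rl):
        if rh[c] > 1.0 and rl[c] < 1.0 and abs(rh[c] - rl[c]) > threshold:
            out.add(c)
    return out
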