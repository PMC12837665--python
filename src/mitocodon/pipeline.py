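"""Orchestration: per-species reports, comparative tables, correlations and
supermatrix export.

This layer glues the single-purpose modules into the analyses a comparative
mitogenomics study runs per species (composition, codon-usage indices,
start/stop census, optimal codons) and across species (Table-style
summaries with a mean row, Pearson correlations among GC components, and
export of the concatenated 13-gene supermatrix that downstream phylogenetic
tools align and analyse).  Concatenation is deliberately unaligned: the
export feeds an external aligner, so the partition table describes the raw
gene boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from scipy import stats

from . import composition as comp
from .codon_usage import (
    CodonCountTable,
    RSCUTable,
    cai,
    count_codons,
    enc,
    rscu,
)
from .genetic_code import GeneticCode, load_code
from .mito_io import (
    CodingSequence,
    MitogenomeRecord,
    PCG_NAMES,
    extract_pcgs,
    gene_order,
)
from .optimal_codons import (
    DEFAULT_FRACTION,
    DEFAULT_THRESHOLD,
    ExpressionSplit,
    OptimalCodonReport,
    expression_split,
    identify_optimal_codons,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    code_id: int = 2
    cai_reference: str = "self"  # pooled 13-PCG counts of the same genome
    optimal_fraction: float = DEFAULT_FRACTION
    optimal_threshold: float = DEFAULT_THRESHOLD
    direction: str = "methods"
    split_sixfold: bool = False

    def validate(self) -> None:
        if self.code_id not in (1, 2):
            raise ValueError(f"unsupported code_id {self.code_id}")
        if not 0 < self.optimal_fraction <= 0.5:
            raise ValueError("optimal_fraction must be in (0, 0.5]")
        if self.optimal_threshold < 0:
            raise ValueError("optimal_threshold must be >= 0")
        if self.direction not in ("methods", "results"):
            raise ValueError("direction must be 'methods' or 'results'")

    def header_lines(self) -> list[str]:
        return [
            f"# code_id={self.code_id} cai_reference={self.cai_reference} "
            f"optimal_fraction={self.optimal_fraction} "
            f"optimal_threshold={self.optimal_threshold} "
            f"direction={self.direction} split_sixfold={self.split_sixfold}"
        ]


@dataclass
class SpeciesReport:
    species: str
    accession: str
    genome_length: int
    genome_composition: comp.CompositionStats
    cds_set: list[CodingSequence]
    per_gene: pd.DataFrame  # gene, length_bp, start_codon, stop_codon, enc
    pooled_counts: CodonCountTable
    pooled_rscu: RSCUTable
    positional: comp.PositionalGC
    pr2: tuple[float, float]
    enc_pooled: float
    cai_pooled: float
    split: ExpressionSplit
    optimal: OptimalCodonReport
    order: list[tuple[str, str]]

    def stop_codon_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for _, row in self.per_gene.iterrows():
            key = row["stop_codon"] if row["stop_codon"] else "none"
            census[key] = census.get(key, 0) + 1
        return census

    def start_codon_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for _, row in self.per_gene.iterrows():
            census[row["start_codon"]] = census.get(row["start_codon"], 0) + 1
        return census


def run_species_report(rec: MitogenomeRecord, config: AnalysisConfig) -> SpeciesReport:
    """Full per-species analysis bundle."""
    config.validate()
    code = load_code(config.code_id)
    cds_set = extract_pcgs(rec, code)
    if not cds_set:
        raise ValueError(f"{rec.accession}: no coding sequences extracted")
    per_gene_rows = []
    enc_by_gene: dict[str, float] = {}
    counts_by_gene: dict[str, CodonCountTable] = {}
    for cds in cds_set:
        counts = count_codons(cds, code)
        counts_by_gene[cds.gene] = counts
        try:
            e = enc(counts, code, split_sixfold=config.split_sixfold)
        except Exception as exc:  # tiny genes may defeat the estimator
            logger.warning("%s/%s: ENC undefined (%s)", rec.accession, cds.gene, exc)
            e = float("nan")
        enc_by_gene[cds.gene] = e
        per_gene_rows.append(
            {
                "gene": cds.gene,
                "length_bp": len(cds.nt),
                "start_codon": cds.start_codon,
                "stop_codon": cds.stop_codon or "",
                "enc": e,
            }
        )
    pooled = count_codons(cds_set, code, scope=f"{rec.accession}|13PCG")
    pooled_rscu = rscu(pooled, code, split_sixfold=config.split_sixfold)
    positional = comp.gc_by_position(cds_set, code)
    pr2 = comp.pr2_coordinates(cds_set, code)
    enc_pooled = enc(pooled, code, split_sixfold=config.split_sixfold)
    reference = pooled  # self-referential default; see AnalysisConfig
    cai_pooled = cai(pooled, reference, code, split_sixfold=config.split_sixfold)
    split = expression_split(
        enc_by_gene, fraction=config.optimal_fraction, direction=config.direction
    )
    high = sum(
        (counts_by_gene[g] for g in split.high_set[1:]),
        counts_by_gene[split.high_set[0]],
    )
    low = sum(
        (counts_by_gene[g] for g in split.low_set[1:]),
        counts_by_gene[split.low_set[0]],
    )
    optimal = identify_optimal_codons(
        high, low, code, threshold=config.optimal_threshold,
        split_sixfold=config.split_sixfold,
    )
    return SpeciesReport(
        species=rec.species,
        accession=rec.accession,
        genome_length=len(rec),
        genome_composition=comp.base_composition(rec.sequence),
        cds_set=cds_set,
        per_gene=pd.DataFrame(per_gene_rows),
        pooled_counts=pooled,
        pooled_rscu=pooled_rscu,
        positional=positional,
        pr2=pr2,
        enc_pooled=enc_pooled,
        cai_pooled=cai_pooled,
        split=split,
        optimal=optimal,
        order=gene_order(rec),
    )


# ---------------------------------------------------------------------------
# comparative tables


def build_comparative_tables(
    records: Sequence[MitogenomeRecord], config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species composition and codon-index tables with a mean row.

    Values are formatted strings at report precision (composition to two
    decimals, skews to five, indices to three) so re-runs are byte-stable;
    the mean row follows the printed-value aggregation policy of
    :func:`mitocodon.composition.aggregate_mean`.
    """
    labels = [r.species or r.accession for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicated species labels in input records")
    rows1, rows2 = [], []
    for rec in records:
        rep = run_species_report(rec, config)
        c = rep.genome_composition
        rows1.append(
            {
                "species": rec.species or rec.accession,
                "length_bp": str(rep.genome_length),
                "A": f"{c.a:.2f}", "C": f"{c.c:.2f}",
                "G": f"{c.g:.2f}", "T": f"{c.t:.2f}",
                "AT": f"{c.at_content:.2f}", "GC": f"{c.gc_content:.2f}",
                "at_skew": f"{c.at_skew:.5f}", "gc_skew": f"{c.gc_skew:.5f}",
            }
        )
        p = rep.positional
        rows2.append(
            {
                "species": rec.species or rec.accession,
                "CAI": f"{rep.cai_pooled:.3f}",
                "ENC": f"{rep.enc_pooled:.3f}",
                "GC3s": f"{p.gc3s:.3f}",
                "GC": f"{p.gc_all:.3f}",
                "GC1": f"{p.gc1:.2f}%", "GC2": f"{p.gc2:.2f}%", "GC3": f"{p.gc3:.2f}%",
            }
        )
    t1 = pd.DataFrame(rows1)
    t2 = pd.DataFrame(rows2)
    return append_mean_row(t1), append_mean_row(t2)


def append_mean_row(table: pd.DataFrame, label: str = "Mean value") -> pd.DataFrame:
    """Append a mean row computed from the printed per-species strings."""
    mean_row = {"species": label}
    for col in table.columns:
        if col == "species":
            continue
        value = comp.aggregate_mean(table, col)
        suffix = "%" if table[col].iloc[0].strip().endswith("%") else ""
        mean_row[col] = f"{value}{suffix}"
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)


def write_table(
    table: pd.DataFrame, config: AnalysisConfig, handle_or_path: str | Path | TextIO
) -> None:
    text = "\n".join(config.header_lines()) + "\n" + table.to_csv(sep="\t", index=False)
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def correlation_matrix(
    table: pd.DataFrame, columns: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise Pearson r with two-sided p (t transform, n-2 df).

    Zero-variance columns flag their pairs as undefined rather than raising.
    P-values are reported raw, without multiple-testing correction.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    numeric = {
        col: pd.Series([comp.parse_printed(str(v)) for v in table[col]], dtype=float)
        for col in columns
    }
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            xa, xb = numeric[a], numeric[b]
            if xa.std(ddof=0) == 0 or xb.std(ddof=0) == 0:
                rows.append(
                    {"a": a, "b": b, "r": float("nan"), "p": float("nan"),
                     "significant": False, "undefined": True}
                )
                continue
            r, p = stats.pearsonr(xa, xb)
            rows.append(
                {"a": a, "b": b, "r": float(r), "p": float(p),
                 "significant": bool(p < alpha), "undefined": False}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# supermatrix export


@dataclass
class Supermatrix:
    sequences: dict[str, str]  # species -> concatenated nt
    partitions: list[tuple[str, int, int]]  # gene, 1-based inclusive range
    genes: tuple[str, ...]

    def write_fasta(self, handle_or_path: str | Path | TextIO) -> None:
        lines = []
        for name, seq in self.sequences.items():
            lines.append(f">{name.replace(' ', '_')}")
            for i in range(0, len(seq), 70):
                lines.append(seq[i : i + 70])
        _write("\n".join(lines) + "\n", handle_or_path)

    def write_phylip(self, handle_or_path: str | Path | TextIO) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("PHYLIP export requires equal sequence lengths (align first)")
        n, m = len(self.sequences), lengths.pop()
        lines = [f" {n} {m}"]
        for name, seq in self.sequences.items():
            lines.append(f"{name.replace(' ', '_')}  {seq}")
        _write("\n".join(lines) + "\n", handle_or_path)

    def write_nexus(self, handle_or_path: str | Path | TextIO) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("NEXUS export requires equal sequence lengths (align first)")
        n, m = len(self.sequences), lengths.pop()
        lines = [
            "#NEXUS", "BEGIN DATA;",
            f"  DIMENSIONS NTAX={n} NCHAR={m};",
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "  MATRIX",
        ]
        for name, seq in self.sequences.items():
            lines.append(f"    {name.replace(' ', '_')}  {seq}")
        lines += ["  ;", "END;"]
        _write("\n".join(lines) + "\n", handle_or_path)

    def write_partitions(self, handle_or_path: str | Path | TextIO) -> None:
        lines = [f"DNA, {g} = {s}-{e}" for g, s, e in self.partitions]
        _write("\n".join(lines) + "\n", handle_or_path)


def _write(text: str, handle_or_path: str | Path | TextIO) -> None:
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def export_supermatrix(
    records: Sequence[MitogenomeRecord],
    genes: Sequence[str] = PCG_NAMES,
    config: AnalysisConfig | None = None,
    missing: str = "error",
) -> Supermatrix:
    """Concatenate the requested genes per species in canonical order.

    ``missing`` controls species lacking a requested gene: "error",
    "drop-species", or "drop-gene".  The partition table is taken from the
    first species' gene lengths; when species disagree in a gene's length
    (raw, unaligned data) a warning is logged — ranges are exact only after
    alignment or for equal-length inputs.
    """
    config = config or AnalysisConfig()
    code = load_code(config.code_id)
    genes = [g for g in PCG_NAMES if g in set(genes)]
    per_species: dict[str, dict[str, str]] = {}
    for rec in records:
        label = rec.species or rec.accession
        per_species[label] = {c.gene: c.nt for c in extract_pcgs(rec, code)}
    present = [g for g in genes if all(g in d for d in per_species.values())]
    absent = [g for g in genes if g not in present]
    if absent:
        if missing == "error":
            raise ValueError(f"genes missing in some species: {absent}")
        if missing == "drop-gene":
            genes = present
        elif missing == "drop-species":
            per_species = {
                s: d for s, d in per_species.items() if all(g in d for g in genes)
            }
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    if not genes or not per_species:
        raise ValueError("no shared genes to concatenate")
    lengths_differ = any(
        len({len(d[g]) for d in per_species.values()}) > 1 for g in genes
    )
    if lengths_differ:
        logger.warning("gene lengths differ across species; partition ranges are nominal")
    sequences = {s: "".join(d[g] for g in genes) for s, d in per_species.items()}
    first = next(iter(per_species.values()))
    partitions = []
    pos = 0
    for g in genes:
        n = len(first[g])
        partitions.append((g, pos + 1, pos + n))
        pos += n
    return Supermatrix(sequences=sequences, partitions=partitions, genes=tuple(genes))
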