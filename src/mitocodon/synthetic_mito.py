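"""Synthetic circular mitogenome records with controlled codon usage.

The generator emulates the compositional structure of a vertebrate
mitochondrial genome so that every statistic in this package — composition,
skews, positional GC, RSCU/ENC/CAI and the optimal-codon procedure — can be
exercised end to end without downloading any real record:

* 13 protein-coding genes in the canonical vertebrate order, interleaved
  with placeholder tRNA/rRNA features and one control region;
* ND6 (and the conventional eight tRNAs) on the light strand;
* AT-rich composition with positive AT-skew and negative GC-skew, achieved
  through third-position codon weights rather than post-hoc sequence
  editing, so composition and codon statistics stay mutually consistent;
* COI initiated by GTG, the others by ATG; a mix of complete (TAA/TAG) and
  incomplete (T--, TA-) stop codons.

Synonymous codon choice within each amino-acid family is controlled either
by explicit per-family probability vectors, by a Dirichlet concentration
parameter alpha (alpha -> inf: uniform usage; alpha -> 0: one codon per
family), or by default third-position base weights.  All randomness flows
from one seeded generator; the same spec and seed reproduce the same
record byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genetic_code import GeneticCode, from_rna, load_code, synonymous_families
from .mito_io import CodingSequence, GeneFeature, MitogenomeRecord, PCG_NAMES


class InfeasibleSpecError(ValueError):
    pass


#: Canonical vertebrate mitochondrial gene order, linearized at tRNA-Phe.
CANONICAL_ORDER: tuple[tuple[str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "H"),
    ("12S", "rRNA", "H"),
    ("tRNA-Val", "tRNA", "H"),
    ("16S", "rRNA", "H"),
    ("tRNA-Leu", "tRNA", "H"),
    ("ND1", "PCG", "H"),
    ("tRNA-Ile", "tRNA", "H"),
    ("tRNA-Gln", "tRNA", "L"),
    ("tRNA-Met", "tRNA", "H"),
    ("ND2", "PCG", "H"),
    ("tRNA-Trp", "tRNA", "H"),
    ("tRNA-Ala", "tRNA", "L"),
    ("tRNA-Asn", "tRNA", "L"),
    ("tRNA-Cys", "tRNA", "L"),
    ("tRNA-Tyr", "tRNA", "L"),
    ("COI", "PCG", "H"),
    ("tRNA-Ser", "tRNA", "L"),
    ("tRNA-Asp", "tRNA", "H"),
    ("COII", "PCG", "H"),
    ("tRNA-Lys", "tRNA", "H"),
    ("ATP8", "PCG", "H"),
    ("ATP6", "PCG", "H"),
    ("COIII", "PCG", "H"),
    ("tRNA-Gly", "tRNA", "H"),
    ("ND3", "PCG", "H"),
    ("tRNA-Arg", "tRNA", "H"),
    ("ND4L", "PCG", "H"),
    ("ND4", "PCG", "H"),
    ("tRNA-His", "tRNA", "H"),
    ("tRNA-Ser", "tRNA", "H"),
    ("tRNA-Leu", "tRNA", "H"),
    ("ND5", "PCG", "H"),
    ("ND6", "PCG", "L"),
    ("tRNA-Glu", "tRNA", "L"),
    ("CYTB", "PCG", "H"),
    ("tRNA-Thr", "tRNA", "H"),
    ("tRNA-Pro", "tRNA", "L"),
    ("D-loop", "control", "H"),
)

# body-codon counts (start codon excluded) close to real teleost gene sizes
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND1": 322, "ND2": 347, "COI": 515, "COII": 229, "ATP8": 54,
    "ATP6": 226, "COIII": 260, "ND3": 115, "ND4L": 97, "ND4": 459,
    "ND5": 607, "ND6": 171, "CYTB": 379,
}

# loosely teleost-mitochondrial amino-acid frequencies (normalized on use)
DEFAULT_AA_PROBS: dict[str, float] = {
    "L": 0.16, "I": 0.09, "T": 0.09, "A": 0.08, "S": 0.07, "F": 0.06,
    "V": 0.06, "G": 0.06, "M": 0.05, "P": 0.05, "N": 0.04, "Y": 0.04,
    "W": 0.03, "H": 0.03, "Q": 0.03, "K": 0.03, "E": 0.03, "D": 0.02,
    "R": 0.02, "C": 0.01,
}

# third-position base weights: A > T gives positive AT-skew, C > G gives
# negative GC-skew, A+T ~ 0.72 at the (least constrained) third position
DEFAULT_THIRD_WEIGHTS: dict[str, float] = {"A": 0.48, "T": 0.24, "C": 0.20, "G": 0.08}

DEFAULT_STOPS: dict[str, str] = {
    "ND1": "TAG", "ND2": "T", "ND3": "T", "ND4": "T", "CYTB": "T", "COII": "TA",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic mitogenome.

    ``gene_lengths`` are body codons per gene (start codon excluded, stop
    excluded); ``codon_probs`` maps amino acid -> {codon: prob} and
    overrides the default third-position weighting globally, while
    ``codon_probs_by_gene`` does the same for single genes (used to plant
    known optimal codons).  ``alpha`` switches synonymous choice to a
    per-family Dirichlet draw.  ``at_richness`` sets the A+T fraction of
    the non-coding placeholder blocks; with the default codon weights the
    assembled genome comes out near 58% A+T with positive AT-skew and
    negative GC-skew.
    """

    species: str = "Synthetibagrus exemplaris"
    accession: str = "SYN000001"
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    codon_probs: Mapping[str, Mapping[str, float]] | None = None
    codon_probs_by_gene: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None
    alpha: float | None = None
    third_position_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THIRD_WEIGHTS)
    )
    aa_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_PROBS))
    at_richness: float = 0.50
    strand_skew: int = 1  # sign of the target AT-skew
    l_strand_genes: frozenset[str] = frozenset({"ND6"})
    start_codons: Mapping[str, str] = field(default_factory=lambda: {"COI": "GTG"})
    stop_tails: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STOPS))
    incomplete_stops: bool = True
    code_id: int = 2
    seed: int = 0

    def validate(self) -> None:
        for gene, n in self.gene_lengths.items():
            if n < 30:
                raise InfeasibleSpecError(f"{gene}: gene length {n} < 30 codons")
        if not 0.30 <= self.at_richness <= 0.90:
            raise InfeasibleSpecError(f"at_richness {self.at_richness} outside [0.30, 0.90]")
        w = self.third_position_weights
        if min(w.values()) < 0 or sum(w.values()) <= 0:
            raise InfeasibleSpecError("third-position weights must be non-negative, not all zero")
        skew3 = w["A"] - w["T"]
        if self.strand_skew and math.copysign(1, skew3) != math.copysign(1, self.strand_skew):
            raise InfeasibleSpecError(
                "third-position weights contradict the requested AT-skew sign"
            )
        for probs in (self.codon_probs or {}).values():
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise InfeasibleSpecError("codon probability vectors must sum to 1")
        for gene_probs in (self.codon_probs_by_gene or {}).values():
            for probs in gene_probs.values():
                if abs(sum(probs.values()) - 1.0) > 1e-6:
                    raise InfeasibleSpecError("codon probability vectors must sum to 1")


def _normalize_probs(probs: Mapping[str, float]) -> dict[str, float]:
    probs = {from_rna(c): p for c, p in probs.items()}
    total = sum(probs.values())
    return {c: p / total for c, p in probs.items()}


def _family_probs(
    spec: SyntheticSpec, code: GeneticCode, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon probability vectors under the spec's controls."""
    out: dict[str, dict[str, float]] = {}
    for fam in synonymous_families(code):
        if spec.alpha is None:
            w = [spec.third_position_weights[c[2]] for c in fam.codons]
        elif math.isinf(spec.alpha):
            w = [1.0] * fam.degeneracy
        elif spec.alpha <= 0:
            hot = rng.integers(fam.degeneracy)
            w = [1.0 if i == hot else 0.0 for i in range(fam.degeneracy)]
        else:
            w = list(rng.dirichlet([spec.alpha] * fam.degeneracy))
        total = sum(w)
        out[fam.amino_acid] = {c: x / total for c, x in zip(fam.codons, w)}
    for aa, probs in (spec.codon_probs or {}).items():
        out[aa] = _normalize_probs(probs)
    return out


def _sample_gene_body(
    n_codons: int,
    fam_probs: dict[str, dict[str, float]],
    aa_probs: Mapping[str, float],
    rng: np.random.Generator,
) -> list[str]:
    aas = sorted(aa_probs)
    p = np.array([aa_probs[a] for a in aas], dtype=float)
    p /= p.sum()
    aa_seq = rng.choice(len(aas), size=n_codons, p=p)
    body = np.empty(n_codons, dtype=object)
    for i, aa in enumerate(aas):  # vectorized per family
        positions = np.flatnonzero(aa_seq == i)
        if positions.size == 0:
            continue
        fam = fam_probs[aa]
        codons = sorted(fam)
        probs = np.array([fam[c] for c in codons], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(codons), size=positions.size, p=probs)
        body[positions] = np.array(codons, dtype=object)[draws]
    return body.tolist()


def _classify_tail(tail: str) -> tuple[str, bool]:
    if len(tail) == 3:
        return tail, True
    return ("TA-" if tail == "TA" else "T--"), False


def generate_cds_set(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> list[CodingSequence]:
    """Generate the 13 coding sequences in reading orientation."""
    spec.validate()
    code = code or load_code(spec.code_id)
    rng = np.random.default_rng(spec.seed)
    fam_probs = _family_probs(spec, code, rng)
    out = []
    for gene in PCG_NAMES:
        if gene not in spec.gene_lengths:
            continue
        probs = dict(fam_probs)
        for aa, vec in ((spec.codon_probs_by_gene or {}).get(gene) or {}).items():
            probs[aa] = _normalize_probs(vec)
        body = _sample_gene_body(spec.gene_lengths[gene], probs, spec.aa_probs, rng)
        start = spec.start_codons.get(gene, "ATG")
        tail = spec.stop_tails.get(gene, "TAA")
        if not spec.incomplete_stops and len(tail) < 3:
            tail = "TAA"
        nt = start + "".join(body) + tail
        stop, complete = _classify_tail(tail)
        out.append(
            CodingSequence(gene=gene, nt=nt, start_codon=start, stop_codon=stop, complete=complete)
        )
    return out


def _random_block(n: int, rng: np.random.Generator, at: float) -> str:
    # strand-asymmetric placeholder blocks: A over T, C over G, as on the
    # deposited H strand of vertebrate mitogenomes
    p = np.array([at * 0.66, at * 0.34, (1 - at) * 0.70, (1 - at) * 0.30])
    return "".join(np.array(list("ATCG"))[rng.choice(4, size=n, p=p / p.sum())])


_BLOCK_LENGTHS = {"tRNA": 70, "12S": 950, "16S": 1650, "D-loop": 890}


def generate_genome_record(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> MitogenomeRecord:
    """Assemble a full circular record in the canonical vertebrate order.

    Genes with an annotated incomplete stop abut the next feature directly
    (their completion depends on polyadenylation of an exactly cut
    transcript); other junctions carry a 1-4 nt spacer.
    """
    spec.validate()
    code = code or load_code(spec.code_id)
    cds_by_gene = {c.gene: c for c in generate_cds_set(spec, code)}
    rng = np.random.default_rng(spec.seed + 1)  # layout stream, separate from codons
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, fclass, strand in CANONICAL_ORDER:
        if fclass == "PCG":
            if name not in cds_by_gene:
                continue
            block = cds_by_gene[name].nt
            if name in spec.l_strand_genes:
                strand = "L"
        elif fclass == "tRNA":
            block = _random_block(_BLOCK_LENGTHS["tRNA"], rng, spec.at_richness)
        elif fclass == "rRNA":
            block = _random_block(_BLOCK_LENGTHS[name], rng, spec.at_richness)
        else:
            block = _random_block(_BLOCK_LENGTHS["D-loop"], rng, min(spec.at_richness + 0.05, 0.9))
        placed = (
            str(Seq(block).reverse_complement()) if strand == "L" else block
        )
        start = pos + 1
        end = pos + len(placed)
        features.append(GeneFeature(name, name, start, end, strand, fclass))
        parts.append(placed)
        pos = end
        incomplete = (
            fclass == "PCG" and cds_by_gene[name].complete is False
        )
        if not incomplete:
            spacer = int(rng.integers(1, 5))
            parts.append(_random_block(spacer, rng, spec.at_richness))
            pos += spacer
    return MitogenomeRecord(
        species=spec.species, accession=spec.accession,
        sequence="".join(parts), features=features,
    )


_FEATURE_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "D-loop"}


def write_genbank(rec: MitogenomeRecord, handle_or_path: str | Path | TextIO) -> None:
    """Serialize a record as a GenBank flat file (round-trips through the parser)."""
    seqrec = SeqRecord(
        Seq(rec.sequence),
        id=rec.accession,
        name=rec.accession[:16],
        description=f"{rec.species} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": rec.species,
        },
    )
    for f in rec.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
        qualifiers = {"gene": [f.name_canonical]}
        if f.feature_class == "tRNA":
            qualifiers["product"] = [f.name_canonical]
        seqrec.features.append(
            SeqFeature(loc, type=_FEATURE_TYPE[f.feature_class], qualifiers=qualifiers)
        )
    if isinstance(handle_or_path, (str, Path)):
        with open(handle_or_path, "w") as fh:
            SeqIO.write(seqrec, fh, "genbank")
    else:
        SeqIO.write(seqrec, handle_or_path, "genbank")


# ---------------------------------------------------------------------------
# plain-text spec serialization (key = value)

_CONFIG_FIELDS = (
    "species", "accession", "alpha", "at_richness", "strand_skew",
    "incomplete_stops", "code_id", "seed",
)


def spec_to_config(spec: SyntheticSpec, handle_or_path: str | Path | TextIO) -> None:
    lines = [f"{k} = {getattr(spec, k)}" for k in _CONFIG_FIELDS]
    lines.append(
        "gene_lengths = " + ",".join(f"{g}:{n}" for g, n in spec.gene_lengths.items())
    )
    text = "\n".join(lines) + "\n"
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def spec_from_config(source: str | Path | TextIO) -> SyntheticSpec:
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    kwargs: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = (x.strip() for x in line.partition("="))
        if key == "gene_lengths":
            kwargs[key] = {
                g: int(n) for g, n in (item.split(":") for item in value.split(","))
            }
        elif key in ("species", "accession"):
            kwargs[key] = value
        elif key == "alpha":
            kwargs[key] = None if value == "None" else float(value)
        elif key == "at_richness":
            kwargs[key] = float(value)
        elif key == "incomplete_stops":
            kwargs[key] = value == "True"
        elif key in ("strand_skew", "code_id", "seed"):
            kwargs[key] = int(value)
    return SyntheticSpec(**kwargs)
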