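"""Reading annotated mitogenomes and extracting oriented protein-coding genes.

A vertebrate mitogenome is a circular molecule of roughly 16–17 kb carrying
13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one control region
(D-loop).  All genes except ND6 and eight tRNAs sit on the heavy (H) strand.
This module parses GenBank flat files into :class:`MitogenomeRecord`,
normalizes the many gene-name spellings found in deposited records
(cox1/COX1/CO1 → COI, nad4l → ND4L, cob → CYTB, ...), reverse-complements
light-strand genes into reading orientation, and classifies start and stop
codons, including the incomplete stops ("T--", "TA-") completed in vivo by
post-transcriptional polyadenylation.

Coordinates are GenBank-style 1-based inclusive at the interface and 0-based
half-open internally.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import STOP, GeneticCode, translate

logger = logging.getLogger(__name__)

PCG_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB",
)

#: Anchor for linearizing the circular gene order.
GENE_ORDER_ANCHOR = "tRNA-Phe"

UNMAPPED = "unmapped"


class ParseError(ValueError):
    pass


class EmptyAnnotationError(ParseError):
    pass


class IntegrityError(ValueError):
    """An in-frame internal stop codon, naming the offending gene."""


_AA3 = {
    "ala": "Ala", "arg": "Arg", "asn": "Asn", "asp": "Asp", "cys": "Cys",
    "gln": "Gln", "glu": "Glu", "gly": "Gly", "his": "His", "ile": "Ile",
    "leu": "Leu", "lys": "Lys", "met": "Met", "phe": "Phe", "pro": "Pro",
    "ser": "Ser", "thr": "Thr", "trp": "Trp", "tyr": "Tyr", "val": "Val",
}

_AA1 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

_PCG_SYNONYMS = {
    "nd1": "ND1", "nad1": "ND1", "nadh1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nadh4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh6": "ND6",
    "coi": "COI", "co1": "COI", "cox1": "COI", "coxi": "COI", "mtco1": "COI",
    "coii": "COII", "co2": "COII", "cox2": "COII", "coxii": "COII",
    "coiii": "COIII", "co3": "COIII", "cox3": "COIII", "coxiii": "COIII",
    "atp6": "ATP6", "atpase6": "ATP6", "atpase 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atpase 8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cyt b": "CYTB", "cytochromeb": "CYTB",
}

_PRODUCT_PATTERNS = [
    (re.compile(r"nadh\s*dehydrogenase\s*subunit\s*4\s*l", re.I), "ND4L"),
    (re.compile(r"nadh\s*dehydrogenase\s*subunit\s*([1-6])", re.I), "ND{}"),
    (re.compile(r"cytochrome\s*c\s*oxidase\s*subunit\s*(iii|3)", re.I), "COIII"),
    (re.compile(r"cytochrome\s*c\s*oxidase\s*subunit\s*(ii|2)", re.I), "COII"),
    (re.compile(r"cytochrome\s*c\s*oxidase\s*subunit\s*(i|1)", re.I), "COI"),
    (re.compile(r"atp\s*synthase\s*(f0\s*)?subunit\s*6", re.I), "ATP6"),
    (re.compile(r"atp\s*synthase\s*(f0\s*)?subunit\s*8", re.I), "ATP8"),
    (re.compile(r"cytochrome\s*b", re.I), "CYTB"),
]


def normalize_gene_name(raw: str) -> str:
    """Map an annotated gene/product name onto the canonical vocabulary.

    Returns one of the 13 PCG names, a ``tRNA-Xxx`` / ``12S`` / ``16S`` /
    ``D-loop`` label, or :data:`UNMAPPED` — unmapped is a value, not an
    error.
    """
    if not raw:
        return UNMAPPED
    key = raw.strip().lower()
    compact = re.sub(r"[\s_\-]+", "", key)
    if compact in _PCG_SYNONYMS:
        return _PCG_SYNONYMS[compact]
    for pat, name in _PRODUCT_PATTERNS:
        m = pat.search(key)
        if m:
            return name.format(*m.groups()) if "{}" in name else name
    m = re.search(r"trn[a]?[\s\-_]?([a-z]{1,3})\b", key)
    if m:
        aa = m.group(1)
        if aa in _AA3:
            return f"tRNA-{_AA3[aa]}"
        if len(aa) == 1 and aa.upper() in _AA1:
            return f"tRNA-{_AA1[aa.upper()]}"
    m = re.search(r"trna[\s\-_]?([a-z]{3})", key)
    if m and m.group(1) in _AA3:
        return f"tRNA-{_AA3[m.group(1)]}"
    if "12s" in compact or "srrna" in compact or "smallsubunitribosomalrna" in compact:
        return "12S"
    if "16s" in compact or "lrrna" in compact or "largesubunitribosomalrna" in compact:
        return "16S"
    if "dloop" in compact or "controlregion" in compact:
        return "D-loop"
    return UNMAPPED


@dataclass
class GeneFeature:
    """One annotated feature on the circular genome (1-based inclusive)."""

    name_raw: str
    name_canonical: str
    start: int
    end: int
    strand: str  # "H" or "L"
    feature_class: str  # PCG | tRNA | rRNA | control
    wraps_origin: bool = False

    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    species: str
    accession: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Feature sequence in reading orientation (L strand → revcomp)."""
        n = len(self.sequence)
        if feat.wraps_origin:
            nt = self.sequence[feat.start - 1 :] + self.sequence[: feat.end]
        else:
            nt = self.sequence[feat.start - 1 : feat.end]
        if feat.strand == "L":
            nt = str(Seq(nt).reverse_complement())
        return nt

    def pcg_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == "PCG"]


@dataclass
class CodingSequence:
    """An extracted PCG in reading orientation.

    ``stop_codon`` is the annotated triplet, ``"TA-"`` or ``"T--"`` for
    incomplete stops, or ``None`` when no stop is recognisable.  The
    trailing 1–2 nt of an incomplete stop stay in ``nt`` but are never
    counted as a codon.
    """

    gene: str
    nt: str
    start_codon: str
    stop_codon: str | None
    complete: bool

    def __len__(self) -> int:
        return len(self.nt)

    def codons(self) -> list[str]:
        """Complete triplets, including any trailing full stop codon."""
        n = len(self.nt) - len(self.nt) % 3
        return [self.nt[i : i + 3] for i in range(0, n, 3)]


def _classify_feature(ftype: str, canonical: str) -> str | None:
    if ftype == "CDS":
        return "PCG"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        return "rRNA"
    if ftype in ("D-loop", "misc_feature") and canonical == "D-loop":
        return "control"
    return None


def parse_genbank(source: str | Path | TextIO) -> MitogenomeRecord:
    """Parse one GenBank flat file into a :class:`MitogenomeRecord`."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        try:
            rec = SeqIO.read(handle, "genbank")
        except ValueError as exc:
            raise ParseError(f"not a well-formed GenBank record: {exc}") from exc
    finally:
        if close:
            handle.close()
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError("record has no ORIGIN sequence")
    genome_len = len(seq)
    if not 10_000 <= genome_len <= 25_000:
        logger.warning(
            "%s: genome length %d outside the 10-25 kb mitogenome window",
            rec.id, genome_len,
        )
    features: list[GeneFeature] = []
    for feat in rec.features:
        raw = (
            feat.qualifiers.get("gene", [""])[0]
            or feat.qualifiers.get("product", [""])[0]
        )
        canonical = normalize_gene_name(raw)
        fclass = _classify_feature(feat.type, canonical)
        if fclass is None:
            continue
        parts = feat.location.parts
        wraps = len(parts) > 1 and int(parts[0].end) == genome_len and int(parts[-1].start) == 0
        start = int(parts[0].start) + 1  # to 1-based inclusive
        end = int(parts[-1].end)
        strand = "L" if feat.location.strand == -1 else "H"
        features.append(
            GeneFeature(raw, canonical, start, end, strand, fclass, wraps_origin=wraps)
        )
    if not any(f.feature_class == "PCG" for f in features):
        raise EmptyAnnotationError(f"{rec.id}: no CDS features annotated")
    n_control = sum(1 for f in features if f.feature_class == "control")
    if n_control == 0:
        logger.warning("%s: no control region annotated", rec.id)
    species = rec.annotations.get("organism", "") or rec.description
    return MitogenomeRecord(
        species=species, accession=rec.id, sequence=seq, features=features
    )


def _classify_stop(nt: str, code: GeneticCode) -> tuple[str | None, bool]:
    """Stop codon of an oriented CDS: triplet, "TA-", "T--", or None."""
    r = len(nt) % 3
    if r == 1:
        return ("T--", False) if nt.endswith("T") else (None, False)
    if r == 2:
        return ("TA-", False) if nt.endswith("TA") else (None, False)
    last = nt[-3:]
    if code.is_stop(last):
        return last, True
    return None, False


def extract_pcgs(
    rec: MitogenomeRecord, code: GeneticCode, check_internal_stops: bool = True
) -> list[CodingSequence]:
    """Extract the 13 PCGs in reading orientation with codon classification.

    Light-strand genes (ND6 in the canonical arrangement) are
    reverse-complemented.  Duplicate annotations of one canonical gene keep
    the longest span.  Fewer than 13 canonical PCGs is a logged warning,
    not an error; an in-frame internal stop is an :class:`IntegrityError`.
    """
    by_gene: dict[str, GeneFeature] = {}
    for feat in rec.pcg_features():
        name = feat.name_canonical
        if name == UNMAPPED:
            logger.warning("%s: CDS %r not mapped to a canonical PCG", rec.accession, feat.name_raw)
            continue
        if name in by_gene:
            keep = max(by_gene[name], feat, key=GeneFeature.span)
            logger.warning("%s: duplicate %s annotation; keeping the longest", rec.accession, name)
            by_gene[name] = keep
        else:
            by_gene[name] = feat
    missing = set(PCG_NAMES) - set(by_gene)
    if missing:
        logger.warning("%s: missing PCGs %s", rec.accession, sorted(missing))
    out: list[CodingSequence] = []
    for name in PCG_NAMES:
        if name not in by_gene:
            continue
        nt = rec.feature_sequence(by_gene[name])
        stop, complete = _classify_stop(nt, code)
        cds = CodingSequence(
            gene=name, nt=nt, start_codon=nt[:3], stop_codon=stop, complete=complete
        )
        if check_internal_stops:
            body = nt[: len(nt) - len(nt) % 3]
            if complete:
                body = body[:-3]
            protein, _ = translate(body, code)
            if STOP in protein:
                raise IntegrityError(
                    f"{rec.accession}: internal stop codon in {name} "
                    f"(position {protein.index(STOP) + 1})"
                )
        out.append(cds)
    return out


def gene_order(rec: MitogenomeRecord, anchor: str = GENE_ORDER_ANCHOR) -> list[tuple[str, str]]:
    """Ordered (canonical name, strand) pairs around the circle.

    Features are sorted by start coordinate, then rotated so the anchor
    (tRNA-Phe by vertebrate convention) comes first when present.
    """
    feats = sorted(rec.features, key=lambda f: (f.start, f.end))
    order = [(f.name_canonical, f.strand) for f in feats]
    names = [n for n, _ in order]
    if anchor in names:
        i = names.index(anchor)
        order = order[i:] + order[:i]
    return order


def compare_gene_order(
    a: list[tuple[str, str]], b: list[tuple[str, str]]
) -> tuple[bool, int | None]:
    """Whether two linearized orders are identical; index of first divergence."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return False, i
    if len(a) != len(b):
        return False, min(len(a), len(b))
    return True, None


def write_cds_fasta(
    cds_set: Iterable[CodingSequence], accession: str, handle_or_path: str | Path | TextIO
) -> None:
    """One FASTA record per gene, header ``accession|gene|strand`` (H after orientation)."""
    lines = []
    for cds in cds_set:
        strand = "L" if cds.gene == "ND6" else "H"
        lines.append(f">{accession}|{cds.gene}|{strand}")
        for i in range(0, len(cds.nt), 70):
            lines.append(cds.nt[i : i + 70])
    text = "\n".join(lines) + "\n"
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def write_feature_table(rec: MitogenomeRecord, handle_or_path: str | Path | TextIO) -> None:
    """TSV gene-feature table: name, canonical, start, end, strand, class."""
    lines = ["name_raw\tname_canonical\tstart\tend\tstrand\tfeature_class"]
    for f in rec.features:
        lines.append(
            f"{f.name_raw}\t{f.name_canonical}\t{f.start}\t{f.end}\t{f.strand}\t{f.feature_class}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(handle_or_path, (str, Path)):
        Path(handle_or_path).write_text(text)
    else:
        handle_or_path.write(text)


def fetch_genbank(accession: str, email: str = "mitocodon@example.org") -> MitogenomeRecord:
    """Optional convenience: download one record from NCBI (network required)."""
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="nucleotide", id=accession, rettype="gb", retmode="text") as h:
        text = h.read()
    return parse_genbank(io.StringIO(text))
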