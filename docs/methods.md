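# Methods

## Genetic codes and synonymous families

All statistics are defined relative to an NCBI translation table: table 2
(vertebrate mitochondrial; stops UAA/UAG/AGA/AGG, UGA = Trp, AUA = Met,
GTG among the initiators) or table 1 (standard).  Codons are DNA triplets
internally; reports render RNA triplets at the output boundary only.
Synonymous families and their degeneracy census are derived
programmatically from the table — under table 2 that yields 12 two-fold,
6 four-fold and 2 six-fold families over 60 sense codons, under table 1
additionally the one-fold (Met, Trp) and three-fold (Ile) families over
61 — so the table-1/table-2 differences propagate automatically.  Six-fold
families (Leu, Ser) are kept whole by default; `split_sixfold=True`
divides them into their 2- and 4-codon subfamilies, a convention some
legacy codon-usage tools apply, and changes ENC's class structure
accordingly.

## Coding-sequence extraction

GenBank coordinates are 1-based inclusive at the interface and converted
once to 0-based half-open internally.  Light-strand genes are
reverse-complemented into reading orientation before any counting.  Stop
codons are classified from the CDS length remainder: a trailing `T` is an
incomplete `T--` stop, `TA` an incomplete `TA-`, and a length divisible by
three with a terminal stop triplet is complete.  The 1–2 nt remainder of
an incomplete stop is never padded and never counted as a codon.
Annotated stop codons are excluded from all codon-usage counts (they carry
no synonymous signal and the classical tools exclude them); start codons
are included.  Codons containing IUPAC ambiguity codes are excluded from
counts and tallied separately.  Duplicate annotations of one canonical
gene keep the longest span with a warning; an in-frame internal stop
raises an integrity error naming the gene.

## Composition statistics

Whole-genome composition uses the deposited H-strand sequence.  Skews are
(A−T)/(A+T) and (G−C)/(G+C).  Positional GC is computed over all counted
codons of a CDS set; GC3s restricts the third position to codons whose
family has degeneracy ≥ 2 (all sense codons under table 2, so GC3s and
GC3 coincide there; Met and Trp drop out under table 1).  PR2 coordinates
use third positions of fourfold-degenerate sites, defined as dinucleotide
prefixes whose four completions encode one amino acid — this includes the
4-codon blocks of the six-fold Leu and Ser families, the standard
convention for PR2 plots.

Comparative tables report composition percentages to two decimals, skews
to five, and indices (CAI/ENC/GC3s/GCall) to three; GC1–GC3 carry a `%`
style and GC3s/GCall a fraction style, mirroring the conventional mixed
layout.  Mean rows are arithmetic means of the printed per-species values,
reported with at least two decimals or the rows' own precision when finer;
this is the convention under which integer genome lengths average to
16,540.33 in the packaged reference table.  Means recomputed from raw
sequences can differ from means of rounded rows; only the printed-row
aggregation is labelled as the table mean.

## Codon-usage indices

**RSCU** follows the textbook definition; families with zero total count
are reported missing rather than zero.

**ENC** uses Wright's estimator.  Per family with n ≥ 2 observed codons,
F̂ = (nΣp̂² − 1)/(n − 1); F̂ ≤ 0 (possible at very small n) is treated as
inestimable.  Class sizes N_k always come from the genetic code, never
from the data.  When a whole degeneracy class is inestimable the 3-fold
class is interpolated as (F̄₂ + F̄₄)/2 when its neighbours exist; any
other missing class is dropped and the partial sum rescaled by the ratio
of total to represented sense codons.  Both fallbacks are logged; they
matter only for very short genes (ATP8-sized and below).  The result is
clipped above at the sense-codon count.

**CAI** defaults to a self-referential reference: the pooled 13-PCG codon
counts of the same genome.  This makes CAI a measure of how typical a
gene's usage is of its own mitogenome rather than adaptation to an
external translational machinery, and such values are not comparable to
CAI computed against an organism-specific reference file (typical
self-referential pooled values sit near 0.7; published mitogenome CAI
values near 0.16 imply an external reference that can be supplied through
`read_reference_counts`).  Zero-count reference codons within an observed
family receive a pseudo-count of 0.5 (configurable) so log w stays finite.
Stop codons and one-fold families are excluded from the geometric mean.

**Optimal codons.**  Genes are ranked by ENC; group size is
max(1, ⌊fraction·G⌋) with fraction 0.10, giving single-gene groups for 13
PCGs; ENC ties break by gene name so the split is deterministic.  Which
ENC extreme counts as "high expression" is ambiguous in the literature —
translational selection predicts low ENC in highly expressed genes, yet
some published analyses proxy high expression by the highest-ENC gene.
Both are implemented behind a `direction` flag: `"methods"` (default)
takes lowest-ENC as high expression, `"results"` the highest.  A codon is
optimal iff RSCU > 1 in the high set, RSCU < 1 in the low set and
|ΔRSCU| > 0.08, all strict; codons whose family is unobserved in either
set are never optimal.

## Synthetic data generator

The generator emulates the features of a vertebrate mitogenome that these
statistics consume: 13 PCGs of realistic teleost lengths in the canonical
gene order, interleaved with placeholder tRNA/rRNA blocks and a control
region; ND6 on the light strand; COI initiated by GTG and the rest by
ATG; ND1 ending TAG, ND2/ND3/ND4/CYTB ending `T--`, COII ending `TA-`,
the others TAA.  Synonymous codon choice is controlled by per-family
probability vectors; the default weights third positions A:T:C:G =
0.48:0.24:0.20:0.08, and non-coding blocks draw bases with A:T = 66:34
and C:G = 70:30 at an AT fraction of 0.50, chosen once so the assembled
genome lands in the empirically typical regime (~58% A+T, AT-skew ≈ +0.07,
GC-skew ≈ −0.24).  Composition targets are achieved entirely through these
sampling probabilities — never by post-hoc sequence editing — so
composition and codon statistics remain mutually consistent.  A Dirichlet
concentration parameter `alpha` replaces the default weighting when set
(α → ∞ uniform synonymous usage, α → 0 one codon per family), and explicit
per-gene vectors allow planting known optimal codons.  All randomness
flows from a single seeded NumPy generator; a spec and seed reproduce a
record byte for byte.

What the generator does **not** emulate: real tRNA/rRNA secondary
structure (those blocks are random sequence), origin-proximal skew
gradients, codon autocorrelation along genes, amino-acid composition
differences between genes, and between-species phylogenetic covariance.
Passing tests on synthetic data therefore validate the statistics and the
plumbing, not biological conclusions about any real taxon.

## Pipeline and numerical choices

Pearson correlations use the exact product-moment r with two-sided p from
the t transform (n − 2 df) via SciPy; p-values are reported raw, with no
multiple-testing correction, since the comparative-table use case reports
a handful of planned pairs.  Zero-variance columns flag their pairs as
undefined rather than raising.  Supermatrix export concatenates unaligned
CDS in canonical gene order — alignment and tree inference are external
steps — and writes partition ranges from the first species' gene lengths;
ranges tile exactly for equal-length inputs (and for any aligned matrix),
and a warning is emitted when raw lengths differ across species.  All
writers are deterministic: identical inputs and configuration produce
byte-identical output, with the configuration echoed into each header.

## Problem sizes in the test suite

Property tests run on 25–100 random count tables per invariant; sampling
checks use 200 replicate genes of 500 codons for the ENC consistency
bound, 10⁶ codons (uniform amino-acid usage, ~5×10⁴ per family) for
parameter recovery within 1% absolute, and 6,000-codon gene pairs for
planted-optimal-codon recovery.  These sizes keep the full suite under a
few seconds while leaving the binomial noise floor well below each
asserted tolerance.

## Known limitations

Published per-species ENC/CAI/GC3s values computed with other tools can
differ from this package's output through their (often undocumented)
translation-table and reference-set defaults; the self-referential CAI in
particular is not comparable to EMBOSS `cai` with an external reference
file.  Records whose annotation lacks canonical gene names fall back to
product-string matching and may need manual mapping.  ENC for genes
shorter than ~50 codons depends on the missing-class fallback and should
be interpreted with care.
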