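import io
import math

import numpy as np
import pytest

from mitocodon.codon_usage import CodonCountTable, count_codons, enc, rscu
from mitocodon.genetic_code import synonymous_families
from mitocodon.mito_io import extract_pcgs, gene_order, parse_genbank
from mitocodon.optimal_codons import identify_optimal_codons
from mitocodon.synthetic_mito import (
    CANONICAL_ORDER,
    InfeasibleSpecError,
    SyntheticSpec,
    generate_cds_set,
    generate_genome_record,
    spec_from_config,
    spec_to_config,
    write_genbank,
)


class TestSpecValidation:
    def test_short_gene_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            SyntheticSpec(gene_lengths={"ND1": 20}).validate()

    def test_contradictory_skew_rejected(self):
        spec = SyntheticSpec(
            third_position_weights={"A": 0.1, "T": 0.5, "C": 0.2, "G": 0.2},
            strand_skew=1,
        )
        with pytest.raises(InfeasibleSpecError):
            spec.validate()

    def test_unnormalized_probs_rejected(self):
        spec = SyntheticSpec(codon_probs={"K": {"AAA": 0.5, "AAG": 0.2}})
        with pytest.raises(InfeasibleSpecError):
            spec.validate()

    def test_config_roundtrip(self):
        spec = SyntheticSpec(seed=9, alpha=2.5, at_richness=0.45)
        buf = io.StringIO()
        spec_to_config(spec, buf)
        buf.seek(0)
        back = spec_from_config(buf)
        assert (back.seed, back.alpha, back.at_richness) == (9, 2.5, 0.45)
        assert dict(back.gene_lengths) == dict(spec.gene_lengths)


class TestGenerateCdsSet:
    def test_deterministic_given_seed(self):
        a = generate_cds_set(SyntheticSpec(seed=5))
        b = generate_cds_set(SyntheticSpec(seed=5))
        assert [c.nt for c in a] == [c.nt for c in b]
        c = generate_cds_set(SyntheticSpec(seed=6))
        assert [x.nt for x in a] != [x.nt for x in c]

    def test_thirteen_genes_with_annotated_codons(self, code2):
        cds_set = generate_cds_set(SyntheticSpec(seed=1))
        assert len(cds_set) == 13
        by_gene = {c.gene: c for c in cds_set}
        assert by_gene["COI"].start_codon == "GTG"
        assert all(c.start_codon in code2.start_codons for c in cds_set)
        assert by_gene["ND2"].stop_codon == "T--" and not by_gene["ND2"].complete
        assert by_gene["COII"].stop_codon == "TA-"
        assert by_gene["ATP6"].stop_codon == "TAA" and by_gene["ATP6"].complete

    def test_uniform_alpha_gives_flat_rscu(self, code2):
        # ~10k codons per family (uniform amino-acid usage) concentrates
        # every RSCU within 0.1 of 1 under uniform synonymous choice
        aa_uniform = {f.amino_acid: 1 / 20 for f in synonymous_families(code2)}
        spec = SyntheticSpec(
            seed=2, alpha=math.inf, gene_lengths={"ND1": 200_000},
            aa_probs=aa_uniform, stop_tails={},
        )
        counts = count_codons(generate_cds_set(spec, code2), code2)
        values = rscu(counts, code2).values
        assert all(abs(v - 1.0) < 0.1 for v in values.values() if v is not None)

    def test_degenerate_alpha_gives_minimal_enc(self, code2):
        # one codon per family; Met pinned to ATG so the mandatory ATG
        # start codon does not split the Met family
        spec = SyntheticSpec(
            seed=2, alpha=0.0, gene_lengths={"ND1": 5_000},
            codon_probs={"M": {"ATG": 1.0}},
        )
        counts = count_codons(generate_cds_set(spec, code2), code2)
        assert enc(counts, code2) == pytest.approx(20.0, abs=1e-6)

    def test_realized_frequencies_converge_to_probs(self, code2):
        """Parameter recovery: ~50k codons per family pins the realized
        per-codon frequencies within 1% absolute of the spec's vectors."""
        aa_uniform = {f.amino_acid: 1 / 20 for f in synonymous_families(code2)}
        for seed in (0, 1, 2):
            spec = SyntheticSpec(
                seed=seed, gene_lengths={"ND1": 1_000_000}, aa_probs=aa_uniform,
                stop_tails={},
            )
            counts = count_codons(generate_cds_set(spec, code2), code2)
            weights = spec.third_position_weights
            for fam in synonymous_families(code2):
                fam_total = sum(counts.get(c) for c in fam.codons)
                assert fam_total > 40_000
                norm = sum(weights[c[2]] for c in fam.codons)
                for c in fam.codons:
                    target = weights[c[2]] / norm
                    assert abs(counts.get(c) / fam_total - target) < 0.01


class TestPlantedOptimalCodons:
    def test_planted_set_recovered_exactly(self, code2):
        """Codons planted over-used in a designated high gene and under-used
        in a low gene are recovered exactly; all other families are given a
        strong shared bias so they cannot leak into the optimal set."""
        planted = {"L": "CTA", "P": "CCC", "E": "GAA", "G": "GGC"}
        shared = {}
        for fam in synonymous_families(code2):
            if fam.amino_acid in planted:
                continue
            probs = {c: 0.1 / (fam.degeneracy - 1) if fam.degeneracy > 1 else 1.0 for c in fam.codons}
            probs[fam.codons[0]] = 1.0 if fam.degeneracy == 1 else 0.9
            shared[fam.amino_acid] = probs
        def biased(target, p_hit):
            fam = next(f for f in synonymous_families(code2) if target in f.codons)
            rest = (1 - p_hit) / (fam.degeneracy - 1)
            return {c: (p_hit if c == target else rest) for c in fam.codons}
        high_probs = dict(shared)
        low_probs = dict(shared)
        for aa, codon in planted.items():
            high_probs[aa] = biased(codon, 0.8)
            low_probs[aa] = biased(codon, 0.03)
        spec = SyntheticSpec(
            seed=4,
            gene_lengths={"ND3": 6000, "ND6": 6000},
            codon_probs_by_gene={"ND3": high_probs, "ND6": low_probs},
            stop_tails={},
        )
        cds = {c.gene: c for c in generate_cds_set(spec, code2)}
        report = identify_optimal_codons(
            count_codons(cds["ND3"], code2), count_codons(cds["ND6"], code2), code2
        )
        assert set(report.optimal_codons(rna=False)) == set(planted.values())


class TestGenomeRecord:
    def test_canonical_order_and_length(self, synthetic_record):
        order = gene_order(synthetic_record)
        expected = [
            (name, "L" if (name, cls) == ("ND6", "PCG") else strand)
            for name, cls, strand in CANONICAL_ORDER
        ]
        assert [o[0] for o in order] == [e[0] for e in expected]
        assert dict(order)["ND6"] == "L"
        assert 15_000 <= len(synthetic_record) <= 18_000

    def test_feature_spans_tile_sequence(self, synthetic_record):
        covered = sum(f.span() for f in synthetic_record.features)
        assert covered <= len(synthetic_record)
        starts = [f.start for f in synthetic_record.features]
        assert starts == sorted(starts)

    def test_roundtrip_codon_counts_equal_generator(self, genbank_text, default_spec, code2):
        parsed = parse_genbank(io.StringIO(genbank_text))
        from_record = count_codons(extract_pcgs(parsed, code2), code2)
        from_generator = count_codons(generate_cds_set(default_spec, code2), code2)
        assert from_record.counts == from_generator.counts

    def test_composition_emulates_mitogenome(self, synthetic_record):
        from mitocodon.composition import base_composition

        c = base_composition(synthetic_record.sequence)
        assert c.at_content > 55.0
        assert c.at_skew > 0
        assert c.gc_skew < -0.15
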