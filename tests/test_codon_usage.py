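import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from mitocodon.codon_usage import (
    CodonCountTable,
    EmptyInputError,
    UndefinedENCError,
    cai,
    count_codons,
    enc,
    expected_enc,
    read_reference_counts,
    relative_adaptiveness,
    rscu,
)
from mitocodon.genetic_code import load_code, synonymous_families
from mitocodon.mito_io import CodingSequence


def _cds(nt, gene="ND1", stop=None, complete=True):
    return CodingSequence(gene=gene, nt=nt, start_codon=nt[:3], stop_codon=stop, complete=complete)


def _random_table(rng, code, low=0, high=30) -> CodonCountTable:
    counts = {c: int(rng.integers(low, high + 1)) for c in code.sense_codons}
    return CodonCountTable(counts={c: x for c, x in counts.items() if x}, code_id=code.table_id)


class TestCountCodons:
    def test_stop_excluded(self, code2):
        t = count_codons(_cds("ATGCCTTAA", stop="TAA"), code2)
        assert t.counts == {"ATG": 1, "CCT": 1}
        assert t.n_stops_excluded == 1

    def test_partial_excluded(self, code2):
        t = count_codons(_cds("ATGCC"), code2)
        assert t.counts == {"ATG": 1}

    def test_ambiguous_excluded(self, code2):
        t = count_codons(_cds("ATGANNCCT"), code2)
        assert t.counts == {"ATG": 1, "CCT": 1}
        assert t.n_ambiguous_excluded == 1

    def test_additivity(self, code2):
        a, b = _cds("ATGCCT"), _cds("CCTGGA", gene="ND2")
        combined = count_codons([a, b], code2)
        summed = count_codons(a, code2) + count_codons(b, code2)
        assert combined.counts == summed.counts == {"ATG": 1, "CCT": 2, "GGA": 1}


class TestRSCU:
    def test_equal_usage_is_unity(self, code2):
        t = CodonCountTable({c: 7 for c in code2.sense_codons}, code_id=2)
        values = rscu(t, code2).values
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_twofold_three_one(self, code2):
        t = CodonCountTable({"AAA": 3, "AAG": 1}, code_id=2)  # Lys
        r = rscu(t, code2)
        assert r.get("AAA") == pytest.approx(1.5)
        assert r.get("AAG") == pytest.approx(0.5)

    def test_fourfold_concentrated(self, code2):
        t = CodonCountTable({"GGA": 4}, code_id=2)
        r = rscu(t, code2)
        assert r.get("GGA") == pytest.approx(4.0)
        assert r.get("GGC") == pytest.approx(0.0)

    def test_unobserved_family_is_missing_not_zero(self, code2):
        t = CodonCountTable({"GGA": 4}, code_id=2)
        assert rscu(t, code2).get("AAA") is None

    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_degeneracy(self, seed):
        code = load_code(2)
        t = _random_table(np.random.default_rng(seed), code)
        r = rscu(t, code)
        for fam in synonymous_families(code):
            vals = [r.get(c) for c in fam.codons]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(fam.degeneracy)
                assert all(v >= 0 for v in vals)

    @pytest.mark.parametrize("table_id", [1, 2])
    def test_oracle_equivalence(self, table_id):
        code = load_code(table_id)
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = _random_table(rng, code)
            mine = rscu(t, code)
            ref = oracles.rscu_oracle(t.counts, table_id)
            for codon in code.sense_codons:
                expected = ref.get(codon)
                got = mine.get(codon)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected)


class TestENC:
    def test_uniform_limits(self, code1, code2):
        for code, limit in ((code1, 61.0), (code2, 60.0)):
            t = CodonCountTable({c: 500 for c in code.sense_codons}, code_id=code.table_id)
            assert enc(t, code) == pytest.approx(limit)

    def test_single_codon_per_family_is_twenty(self, code2):
        counts = {f.codons[0]: 100 for f in synonymous_families(code2)}
        t = CodonCountTable(counts, code_id=2)
        assert enc(t, code2) == pytest.approx(20.0)

    def test_bounds_on_random_tables(self, code2):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = _random_table(rng, code2, low=1, high=40)
            e = enc(t, code2)
            assert 20.0 <= e <= 60.0

    def test_oracle_equivalence(self, code2):
        rng = np.random.default_rng(13)
        for _ in range(100):
            t = _random_table(rng, code2, low=1, high=40)
            assert enc(t, code2) == pytest.approx(oracles.enc_oracle(t.counts, 2))

    def test_sampling_consistency_near_uniform_limit(self, code2):
        """Mean ENC of uniform-multinomial genes (500 codons) sits within 2
        of the closed-form maximum of 60."""
        rng = np.random.default_rng(2024)
        sense = list(code2.sense_codons)
        values = []
        for _ in range(200):
            draw = rng.choice(len(sense), size=500)
            counts: dict[str, int] = {}
            for i in draw:
                counts[sense[i]] = counts.get(sense[i], 0) + 1
            values.append(enc(CodonCountTable(counts, code_id=2), code2))
        assert abs(np.mean(values) - 60.0) < 2.0

    def test_empty_table_undefined(self, code2):
        with pytest.raises(UndefinedENCError):
            enc(CodonCountTable({}, code_id=2), code2)

    def test_small_gene_missing_class_fallback(self, code2):
        # only two-fold families observed: 4- and 6-fold classes dropped,
        # result rescaled but still within bounds
        counts = {"AAA": 5, "AAG": 5, "GAA": 8, "GAG": 2}
        e = enc(CodonCountTable(counts, code_id=2), code2)
        assert 20.0 <= e <= 60.0


class TestExpectedENC:
    @pytest.mark.parametrize("s,value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    def test_curve_maximum_near_half(self):
        grid = np.linspace(0, 1, 1001)
        values = [expected_enc(s) for s in grid]
        argmax = grid[int(np.argmax(values))]
        assert 0.48 <= argmax <= 0.53
        assert 60.4 <= max(values) <= 60.6

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestCAI:
    def test_all_preferred_codons_score_one(self, code2):
        reference = CodonCountTable(
            {c: (10 if i == 0 else 3) for f in synonymous_families(code2) for i, c in enumerate(f.codons)},
            code_id=2,
        )
        gene = CodonCountTable(
            {f.codons[0]: 5 for f in synonymous_families(code2)}, code_id=2
        )
        assert cai(gene, reference, code2) == pytest.approx(1.0)

    def test_hand_geometric_mean(self, code2):
        # 2-fold Lys reference (3,1): w = (1, 1/3); gene uses one of each
        reference = CodonCountTable({"AAA": 3, "AAG": 1}, code_id=2)
        gene = CodonCountTable({"AAA": 1, "AAG": 1}, code_id=2)
        assert cai(gene, reference, code2) == pytest.approx(math.sqrt(1 / 3))

    def test_matches_brute_force_on_self_reference(self, code2):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = _random_table(rng, code2, low=1, high=25)
            assert cai(t, t, code2) == pytest.approx(
                oracles.cai_oracle(t.counts, t.counts, 2)
            )

    def test_monotone_under_preferred_replacement(self, code2):
        """Moving any codon's count onto its family's preferred codon never
        decreases CAI."""
        rng = np.random.default_rng(17)
        reference = _random_table(rng, code2, low=1, high=30)
        w = relative_adaptiveness(reference, code2)
        gene = _random_table(rng, code2, low=0, high=10)
        base = cai(gene, reference, code2)
        for fam in synonymous_families(code2):
            preferred = max(fam.codons, key=lambda c: w.get(c, 0))
            for codon in fam.codons:
                if codon == preferred or gene.get(codon) == 0:
                    continue
                counts = dict(gene.counts)
                moved = counts.pop(codon)
                counts[preferred] = counts.get(preferred, 0) + moved
                better = cai(CodonCountTable(counts, code_id=2), reference, code2)
                assert better >= base - 1e-12

    def test_zero_count_reference_codon_smoothed(self, code2):
        reference = CodonCountTable({"AAA": 10}, code_id=2)  # AAG unseen
        gene = CodonCountTable({"AAG": 4}, code_id=2)
        value = cai(gene, reference, code2)
        assert 0 < value < 1 and math.isfinite(value)

    def test_empty_gene_rejected(self, code2):
        with pytest.raises(EmptyInputError):
            cai(CodonCountTable({}, code_id=2), CodonCountTable({"AAA": 1}, code_id=2), code2)


def test_reference_table_roundtrip(tmp_path, code2):
    from mitocodon.codon_usage import write_codon_report

    t = CodonCountTable({"AAA": 3, "AAG": 1, "GGA": 5}, code_id=2)
    path = tmp_path / "ref.tsv"
    write_codon_report(t, code2, path)
    back = read_reference_counts(path, code2)
    assert back.counts == t.counts
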