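from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinlr.errors import (
    DuplicatePositionError,
    MalformedTokenError,
    NoComparablePositionsError,
    PositionOutOfRangeError,
    SequenceError,
    ValidationError,
)
from kinlr.mtdna import (
    HaplotypeDatabase,
    MtEvidenceParams,
    MtHaplotype,
    count_db_matches,
    diff,
    match_probability,
    mtdna_lr,
    no_mutation_prob,
    parse_profile_table,
    parse_ranges,
    parse_variant_profile,
    profile_from_fasta,
    profiles_to_text,
    second_relative_lr,
)

CONTROL = parse_ranges("16093-16320 73-188")
HV2 = parse_ranges("73-188")
TOY = parse_ranges("1-1000")  # toy mini-reference coordinates


def toy_reference(rng, length=1000):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestVariantProfiles:
    def test_empty_profile_is_reference_identical(self):
        hap = parse_variant_profile("", HV2)
        assert hap.variants == frozenset()

    def test_two_tokens(self):
        hap = parse_variant_profile("16126C 73G", CONTROL)
        assert hap.variants == {"16126C", "73G"}

    def test_substitution_outside_ranges_rejected(self):
        with pytest.raises(PositionOutOfRangeError):
            parse_variant_profile("16400T", parse_ranges("16093-16320"))

    @pytest.mark.parametrize("token", ["16126X", "C16126", "16126", "73GG", "del249"])
    def test_malformed_tokens_rejected(self, token):
        with pytest.raises(MalformedTokenError):
            parse_variant_profile(token, CONTROL)

    def test_duplicate_position_rejected(self):
        with pytest.raises(DuplicatePositionError):
            parse_variant_profile("73G 73A", HV2)

    def test_indel_tokens_are_opaque(self):
        hap = parse_variant_profile("315.1C 249DEL 16126C", CONTROL)
        assert {"315.1C", "249DEL"} <= hap.variants

    def test_tokens_uppercased(self):
        hap = parse_variant_profile("73g", HV2)
        assert hap.variants == {"73G"}


class TestProfileFromFasta:
    def test_identity_gives_empty_set(self, rng):
        ref = toy_reference(rng)
        assert profile_from_fasta(ref, ref, TOY).variants == frozenset()

    def test_single_mutation(self, rng):
        ref = toy_reference(rng)
        pos = 500
        base = "A" if ref[pos - 1] != "A" else "C"
        seq = ref[: pos - 1] + base + ref[pos:]
        assert profile_from_fasta(seq, ref, TOY).variants == {f"{pos}{base}"}

    def test_n_positions_ignored(self, rng):
        ref = toy_reference(rng)
        seq = "N" + ref[1:]
        assert profile_from_fasta(seq, ref, TOY).variants == frozenset()

    def test_hundred_random_mutations_match_bruteforce_diff(self, rng):
        ref = toy_reference(rng)
        positions = rng.choice(1000, size=100, replace=False) + 1
        seq = list(ref)
        for pos in positions:
            alternatives = [b for b in "ACGT" if b != ref[pos - 1]]
            seq[pos - 1] = alternatives[int(rng.integers(3))]
        seq = "".join(seq)
        expected = {
            f"{i + 1}{seq[i]}" for i in range(1000) if seq[i] != ref[i]
        }
        assert profile_from_fasta(seq, ref, TOY).variants == expected

    def test_length_mismatch_rejected(self, rng):
        ref = toy_reference(rng)
        with pytest.raises(SequenceError):
            profile_from_fasta(ref[:-1], ref, TOY)

    def test_non_iupac_rejected(self, rng):
        ref = toy_reference(rng)
        with pytest.raises(SequenceError):
            profile_from_fasta("R" + ref[1:], ref, TOY)


@st.composite
def token_sets(draw):
    positions = draw(
        st.lists(st.integers(min_value=73, max_value=188), min_size=0, max_size=6, unique=True)
    )
    bases = draw(st.lists(st.sampled_from("ACGT"), min_size=len(positions), max_size=len(positions)))
    return frozenset(f"{p}{b}" for p, b in zip(positions, bases))


class TestDiff:
    def test_identical_haplotypes_match(self):
        h = parse_variant_profile("73G 16126C", CONTROL)
        assert diff(h, h) == []

    def test_single_difference_at_8994(self):
        # whole-molecule profiles differing only at position 8,994
        whole = parse_ranges("1-16569")
        h1 = parse_variant_profile("73G 8994A 16126C", whole)
        h2 = parse_variant_profile("73G 16126C", whole)
        assert diff(h1, h2) == ["8994A"]

    def test_comparison_restricted_to_shared_ranges(self):
        h1 = parse_variant_profile("73G 16126C", CONTROL)
        h2 = parse_variant_profile("73G", HV2)
        # 16126C lies outside the shared range and must not count
        assert diff(h1, h2) == []

    def test_disjoint_ranges_raise(self):
        h1 = parse_variant_profile("73G", HV2)
        h2 = parse_variant_profile("16126C", parse_ranges("16093-16320"))
        with pytest.raises(NoComparablePositionsError):
            diff(h1, h2)

    @given(a=token_sets(), b=token_sets())
    @settings(deadline=None, max_examples=60)
    def test_matches_bruteforce_symmetric_difference(self, a, b):
        h1 = MtHaplotype(a, HV2)
        h2 = MtHaplotype(b, HV2)
        assert set(diff(h1, h2)) == a ^ b
        assert diff(h1, h2) == diff(h2, h1)
        assert diff(h1, h1) == []


class TestDatabaseMatching:
    def test_empty_database(self):
        q = parse_variant_profile("73G", HV2)
        assert count_db_matches(HaplotypeDatabase([]), q, HV2).matches == 0

    def test_five_copies(self):
        q = parse_variant_profile("73G", HV2)
        db = HaplotypeDatabase([(f"r{i}", q) for i in range(5)])
        assert count_db_matches(db, q, HV2) == (5, 0)

    def test_noncovering_records_skipped(self):
        q = parse_variant_profile("73G", CONTROL)
        db = HaplotypeDatabase(
            [
                ("covers", parse_variant_profile("73G", CONTROL)),
                ("partial", parse_variant_profile("73G", HV2)),
            ]
        )
        assert count_db_matches(db, q, CONTROL) == (1, 1)

    def test_planted_matches_recovered(self, rng):
        q = parse_variant_profile("73G 150T", HV2)
        records, planted = [], 0
        for i in range(1000):
            if rng.random() < 0.05:
                records.append((f"r{i}", q))
                planted += 1
            else:
                pos = int(rng.integers(74, 149))
                records.append((f"r{i}", parse_variant_profile(f"{pos}A", HV2)))
        got = count_db_matches(HaplotypeDatabase(records), q, HV2)
        assert got == (planted, 0)

    def test_duplicate_record_ids_rejected(self):
        q = parse_variant_profile("", HV2)
        with pytest.raises(ValidationError):
            HaplotypeDatabase([("a", q), ("a", q)])

    def test_profile_table_roundtrip(self, rng):
        records = [
            (f"s{i}", parse_variant_profile(f"{int(rng.integers(74, 188))}C", HV2))
            for i in range(5)
        ]
        text = profiles_to_text(HaplotypeDatabase(records))
        assert profiles_to_text(parse_profile_table(text)) == text


class TestMatchProbability:
    def test_zero_match_british_database(self):
        assert match_probability(0, 1831) == 2 / 1832

    def test_zero_match_european_database(self):
        assert match_probability(0, 26127) == 2 / 26128

    def test_plain_frequency(self):
        assert match_probability(5, 10, add_relative=False, pseudocount=0) == 0.5

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValidationError):
            match_probability(11, 10)

    @given(
        k=st.integers(min_value=0, max_value=50),
        n=st.integers(min_value=1, max_value=30000),
    )
    @settings(deadline=None, max_examples=60)
    def test_conservatism_exceeds_plain_frequency(self, k, n):
        k = min(k, n)
        assert match_probability(k, n) > k / n


class TestNoMutationProb:
    def test_zero_meioses_certain(self):
        assert no_mutation_prob(0.3, 0) == 1.0

    def test_genealogical_rate_19_meioses(self):
        # frozen from the exact rational power (317/327)**19
        expected = float(Fraction(317, 327) ** 19)
        assert no_mutation_prob(10 / 327, 19) == pytest.approx(expected, rel=1e-12)
        assert round(no_mutation_prob(10 / 327, 19), 4) == 0.5543

    def test_genealogical_rate_21_meioses(self):
        expected = float(Fraction(317, 327) ** 21)
        assert no_mutation_prob(10 / 327, 21) == pytest.approx(expected, rel=1e-12)
        assert round(no_mutation_prob(10 / 327, 21), 2) == 0.52

    def test_domain_violations(self):
        with pytest.raises(ValidationError):
            no_mutation_prob(1.0, 5)
        with pytest.raises(ValidationError):
            no_mutation_prob(0.1, -1)

    @given(
        mu=st.floats(min_value=1e-6, max_value=0.2),
        m=st.integers(min_value=0, max_value=40),
    )
    @settings(deadline=None, max_examples=60)
    def test_strictly_decreasing_in_m(self, mu, m):
        assert no_mutation_prob(mu, m) > no_mutation_prob(mu, m + 1)

    @given(
        mu=st.floats(min_value=1e-8, max_value=1e-3),
        m=st.integers(min_value=0, max_value=20),
    )
    @settings(deadline=None, max_examples=60)
    def test_linearisation_bound_for_small_rates(self, mu, m):
        p = no_mutation_prob(mu, m)
        assert abs(p - (1 - m * mu)) <= (m * mu) ** 2 + 1e-15


class TestMtdnaLr:
    def test_neutral_evidence(self):
        assert mtdna_lr(MtEvidenceParams(mu=0.0, m=19, p_match=1.0)) == 1.0

    def test_published_numerator_against_british_database(self):
        params = MtEvidenceParams(
            mu=10 / 327, m=19, p_match=2 / 1832, p_no_mutation=0.52
        )
        assert mtdna_lr(params) == pytest.approx(0.52 * 1832 / 2, rel=1e-12)
        assert mtdna_lr(params) == pytest.approx(476.3, abs=0.05)

    def test_round_numbers(self):
        assert mtdna_lr(MtEvidenceParams(mu=0.0, m=0, p_match=0.001, p_no_mutation=0.5)) == 500.0

    def test_invalid_match_probability_rejected(self):
        with pytest.raises(ValidationError):
            MtEvidenceParams(mu=0.01, m=5, p_match=0.0)


class TestSecondRelative:
    def test_cancels_to_one(self):
        assert second_relative_lr() == 1.0

    def test_product_unchanged(self):
        import math

        lrs = [1.84, 42.0]
        with_item = lrs + [second_relative_lr(), second_relative_lr()]
        assert math.prod(with_item) == math.prod(lrs)
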