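"""In-silico PCR: binding-site search, amplicon pairing, specificity matrix.

The load-bearing check is oracle equivalence: the vectorised search must
reproduce a naive character-by-character sliding window on randomly generated
primer/template instances, on both strands, across mismatch budgets.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lavermux.insilico_pcr import (
    TemplateSeq,
    find_binding_sites,
    predict_amplicons,
    reverse_complement,
    specificity_matrix,
)
from lavermux.panel_model import PanelValidationError

from oracles import naive_binding_sites, revcomp as oracle_revcomp

DNA = "ACGT"


def _random_dna(rng, n, alphabet=DNA):
    return "".join(rng.choice(list(alphabet), n))


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGT", "ACGT"),
            ("GGTGCATGGCCGTTCTTAGT", "ACTAAGAACGGCCATGCACC"),
            ("NRY", "RYN"),
        ],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character_rejected(self):
        with pytest.raises(PanelValidationError):
            reverse_complement("ACGU")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_involution_and_oracle_agreement(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq
        assert reverse_complement(seq) == oracle_revcomp(seq)


class TestFindBindingSites:
    def test_self_complementary_primer_hits_both_strands(self):
        t = TemplateSeq(id="t", sequence="TTACGTTT")
        sites = find_binding_sites("ACGT", t, max_mismatch=0, anchor_len=0)
        assert [(s.strand, s.start) for s in sites] == [("plus", 2), ("minus", 2)]

    def test_planted_primer_recovered_at_exact_offset(self, panel):
        rng = np.random.default_rng(1)
        ha_f = panel.pair_for("NH").forward
        tmpl = _random_dna(rng, 200)
        tmpl = tmpl[:10] + ha_f.sequence + tmpl[10 + len(ha_f):]
        sites = find_binding_sites(
            ha_f, TemplateSeq(id="t", sequence=tmpl), max_mismatch=0
        )
        plus = [s for s in sites if s.strand == "plus"]
        assert [(s.start, s.mismatches) for s in plus] == [(10, 0)]

    def test_all_N_template_never_matches(self):
        t = TemplateSeq(id="n", sequence="N" * 100)
        assert find_binding_sites("ACGTACGTACGT", t, max_mismatch=0) == []

    def test_primer_longer_than_template_yields_empty(self):
        t = TemplateSeq(id="t", sequence="ACGT")
        assert find_binding_sites("ACGTACGT", t, max_mismatch=2) == []

    def test_oracle_equivalence_on_random_instances(self):
        """>=200 random primer/template pairs, mismatch budgets 0-2, with a
        mutated primer copy planted so positive hits are exercised too."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(70):
            m = int(rng.integers(12, 28))
            n = int(rng.integers(120, 900))
            primer = _random_dna(rng, m)
            tmpl = list(_random_dna(rng, n, alphabet="ACGTN"))
            # plant a copy carrying up to 2 mutations outside the 3' anchor
            planted = list(primer)
            for pos in rng.choice(max(1, m - 3), size=int(rng.integers(0, 3)),
                                  replace=False):
                planted[pos] = DNA[(DNA.index(planted[pos]) + 1) % 4]
            off = int(rng.integers(0, n - m))
            tmpl[off:off + m] = planted
            tmpl = "".join(tmpl)
            t = TemplateSeq(id="t", sequence=tmpl)
            for mm in (0, 1, 2):
                got = [
                    (s.strand, s.start, s.mismatches)
                    for s in find_binding_sites(primer, t, mm, anchor_len=3)
                ]
                assert got == naive_binding_sites(primer, tmpl, mm, 3)
                checked += 1
        assert checked >= 200

    def test_site_set_is_monotone_in_mismatch_budget(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            primer = _random_dna(rng, int(rng.integers(12, 22)))
            t = TemplateSeq(id="t", sequence=_random_dna(rng, 400))
            prev: set = set()
            for mm in (0, 1, 2, 3):
                cur = {
                    (s.strand, s.start)
                    for s in find_binding_sites(primer, t, mm, anchor_len=3)
                }
                assert prev <= cur
                prev = cur

    def test_strand_symmetry_against_reverse_complemented_template(self):
        """Minus-strand hits equal plus-strand hits on the reverse-complemented
        template, with coordinates mirrored."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            primer = _random_dna(rng, int(rng.integers(12, 22)))
            seq = _random_dna(rng, 300)
            t = TemplateSeq(id="t", sequence=seq)
            t_rc = TemplateSeq(id="rc", sequence=reverse_complement(seq))
            minus = {
                s.start for s in find_binding_sites(primer, t, 2, 3)
                if s.strand == "minus"
            }
            plus_on_rc = {
                len(seq) - s.end
                for s in find_binding_sites(primer, t_rc, 2, 3)
                if s.strand == "plus"
            }
            assert minus == plus_on_rc


class TestPredictAmplicons:
    def test_constructed_template_forces_the_length(self, panel):
        rng = np.random.default_rng(5)
        pair = panel.pair_for("NY")
        seq = (
            pair.forward.sequence
            + _random_dna(rng, 50)
            + reverse_complement(pair.reverse.sequence)
        )
        amps = predict_amplicons(pair, TemplateSeq(id="t", sequence=seq))
        assert len(amps) == 1
        assert amps[0].length_bp == len(pair.forward) + 50 + len(pair.reverse)

    def test_two_forward_sites_give_two_products(self, panel):
        rng = np.random.default_rng(6)
        pair = panel.pair_for("PS")
        fwd = pair.forward.sequence
        rev_rc = reverse_complement(pair.reverse.sequence)
        seq = fwd + _random_dna(rng, 30) + fwd + _random_dna(rng, 30) + rev_rc
        amps = predict_amplicons(pair, TemplateSeq(id="t", sequence=seq))
        short = len(fwd) + 30 + len(rev_rc)
        long = short + 30 + len(fwd)
        assert sorted(a.length_bp for a in amps) == [short, long]

    def test_opposite_orientation_template_is_amplified(self, panel):
        """A template given as the reverse strand still yields the product."""
        rng = np.random.default_rng(8)
        pair = panel.pair_for("NT")
        seq = (
            pair.forward.sequence
            + _random_dna(rng, 40)
            + reverse_complement(pair.reverse.sequence)
        )
        flipped = reverse_complement(seq)
        amps = predict_amplicons(pair, TemplateSeq(id="t", sequence=flipped))
        assert [a.length_bp for a in amps] == [len(seq)]

    def test_length_cap_suppresses_long_products(self, panel):
        rng = np.random.default_rng(9)
        pair = panel.pair_for("NS")
        seq = (
            pair.forward.sequence
            + _random_dna(rng, 400)
            + reverse_complement(pair.reverse.sequence)
        )
        t = TemplateSeq(id="t", sequence=seq)
        assert predict_amplicons(pair, t, max_amplicon_bp=300) == []
        assert len(predict_amplicons(pair, t, max_amplicon_bp=3000)) == 1


class TestSpecificityMatrix:
    def test_reference_set_is_diagonal_with_all_ones_control(
        self, panel, reference_set
    ):
        m = specificity_matrix(panel, reference_set)
        target_cols = [f"{c}_synthetic" for c in ("NY", "NT", "NH", "ND", "PS", "NS")]
        species_rows = ["NY", "NT", "NH", "ND", "PS", "NS"]
        sub = m.loc[species_rows, target_cols]
        assert (sub.values == np.eye(6)).all()
        assert (m.loc["CTRL"] == 1).all()
        decoy_cols = [c for c in m.columns if c not in target_cols]
        assert len(decoy_cols) == 11
        assert (m.loc[species_rows, decoy_cols] == 0).all().all()

    def test_random_template_column_is_all_zero(self, panel):
        rng = np.random.default_rng(7)
        t = TemplateSeq(id="rand", sequence=_random_dna(rng, 500))
        m = specificity_matrix(panel, [t])
        assert (m["rand"] == 0).all()

    def test_empty_template_list_gives_empty_matrix(self, panel):
        m = specificity_matrix(panel, [])
        assert m.shape[1] == 0
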