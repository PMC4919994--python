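"""Binding-site search and in silico PCR."""

import numpy as np
import pytest

from primerscope import (
    DegeneratePrimer,
    TargetSequence,
    find_best_site,
    in_silico_pcr,
    reverse_complement,
)
from primerscope.pcr import NoAmplicon
from primerscope.primers import PrimerSet, expand_degenerate, mismatch_count


def _seq(id_, s, gene="16S"):
    return TargetSequence(id=id_, gene=gene, sequence=s, cluster="6A")


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


PRIMER = DegeneratePrimer("probe", "GGAGRAAAGCAGGGGATCG", "forward")


def test_exact_planted_site_found_at_offset(rng):
    planted = expand_degenerate(PRIMER)[0]
    template = _seq("t1", _rand(rng, 10) + planted + _rand(rng, 30))
    m = find_best_site(template, PRIMER, "plus")
    assert (m.start, m.end, m.mismatch_total) == (10, 10 + len(PRIMER), 0)
    assert m.mismatch_positions == ()


def test_no_match_above_cutoff():
    template = _seq("t2", "A" * 40)
    primer = DegeneratePrimer("g10", "GGGGGGGGGG", "forward")
    assert find_best_site(template, primer, "plus", max_mismatch=2) is None


def test_template_shorter_than_primer_is_contract_error():
    with pytest.raises(ValueError, match="shorter"):
        find_best_site(_seq("t3", "ACGTACGT"), PRIMER, "plus")


def test_best_site_equals_exhaustive_oracle(rng):
    """Independent oracle: re-scan every window with mismatch_count."""
    k = len(PRIMER)
    for i in range(100):
        template = _seq(f"r{i}", _rand(rng, 80))
        m = find_best_site(template, PRIMER, "plus")
        scores = [
            mismatch_count(PRIMER, template.sequence[s : s + k])[0]
            for s in range(80 - k + 1)
        ]
        assert m.mismatch_total == min(scores)
        assert m.start == scores.index(min(scores))  # 5'-most tie-break


def test_strand_symmetry(rng):
    """Minus-strand search equals plus-strand search on the reverse complement."""
    for i in range(50):
        s = _rand(rng, 70)
        t_plus = _seq("p", s)
        t_rc = _seq("rc", reverse_complement(s))
        m_minus = find_best_site(t_plus, PRIMER, "minus")
        m_plus = find_best_site(t_rc, PRIMER, "plus")
        assert m_minus.mismatch_total == m_plus.mismatch_total
        # minus-strand coordinates map to the reverse complement's frame;
        # equal-score ties may resolve to different windows, so compare the
        # actually-annealed window only when the site is unique
        window_minus = reverse_complement(s[m_minus.start : m_minus.end])
        window_plus = t_rc.sequence[m_plus.start : m_plus.end]
        assert (
            mismatch_count(PRIMER, window_minus)[0]
            == mismatch_count(PRIMER, window_plus)[0]
        )


def test_match_monotone_in_max_mismatch(rng):
    for i in range(30):
        template = _seq(f"m{i}", _rand(rng, 60))
        found = [
            find_best_site(template, PRIMER, "plus", max_mismatch=k) is not None
            for k in range(0, 8)
        ]
        # once found, raising the cutoff never loses the match
        assert found == sorted(found)


def _build_template(rng, primer_set, insert_len=75, pad=15):
    fwd = expand_degenerate(primer_set.forwards[0])[0]
    rev = expand_degenerate(primer_set.reverse)[0]
    s = (
        _rand(rng, pad)
        + fwd
        + _rand(rng, insert_len)
        + reverse_complement(rev)
        + _rand(rng, pad)
    )
    return TargetSequence(
        id="built", gene=primer_set.target_gene, sequence=s, cluster="6A"
    )


def test_in_silico_pcr_recovers_constructed_product(rng, ps16):
    amp = in_silico_pcr(_build_template(rng, ps16, insert_len=75), ps16, max_mismatch=1)
    assert amp
    assert amp.inter_primer_length == 75
    assert amp.total_length == 75 + len(ps16.forwards[0]) + len(ps16.reverse)
    assert amp.sequence == amp.sequence.upper() and len(amp.sequence) == 75


def test_in_silico_pcr_missing_reverse_site(rng, ps16):
    fwd = expand_degenerate(ps16.forwards[0])[0]
    t = TargetSequence(
        id="fwd-only", gene="16S", sequence=_rand(rng, 20) + fwd + _rand(rng, 80)
    )
    res = in_silico_pcr(t, ps16, max_mismatch=1)
    assert isinstance(res, NoAmplicon) and res.reason == "no-reverse"


def test_in_silico_pcr_length_bounds(rng, ps16):
    tight = PrimerSet(
        name="tight",
        forwards=ps16.forwards,
        reverse=ps16.reverse,
        target_gene="16S",
        amplicon_length_bounds=(80, 100),  # excludes the 116 bp product
    )
    res = in_silico_pcr(_build_template(rng, tight, insert_len=75), tight, 1)
    assert isinstance(res, NoAmplicon) and res.reason == "length-out-of-bounds"


def test_amplicon_length_arithmetic(rng, psamoa):
    for insert in (400, 452, 500):
        amp = in_silico_pcr(_build_template(rng, psamoa, insert), psamoa, 2)
        assert amp
        assert amp.total_length - amp.inter_primer_length == len(
            psamoa.forwards[0]
        ) + len(psamoa.reverse)
        assert amp.forward_match.end <= amp.reverse_match.start
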