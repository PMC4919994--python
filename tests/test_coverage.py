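"""Coverage tables against the generator ledger, and library composition."""

from collections import Counter

import pytest

from primerscope import (
    CloneLibrary,
    PlantSpec,
    coverage_table,
    fraction_covered,
    make_dataset,
    summarize_library,
)
from primerscope.coverage import CoverageCell


@pytest.fixture(scope="module")
def amoa_dataset(psamoa):
    specs = [
        PlantSpec("6A", "amoA", 12, (1, 2), (1, 2), seed=11),
        PlantSpec("7", "amoA", 12, (0, 1), (0, 1), seed=12),
    ]
    return make_dataset(specs, psamoa)


def test_zero_mismatch_plant_gives_full_coverage(ps16):
    specs = [PlantSpec("6A", "16S", 10, (0, 0), (0, 0), seed=3)]
    seqs, _ = make_dataset(specs, ps16)
    summary = coverage_table(seqs, ps16)
    for role in ("forward", "reverse", "set"):
        assert fraction_covered(summary, "6A", role, 0) == 1.0


def test_histograms_match_generator_ledger(amoa_dataset, psamoa):
    """The ledger is an exact oracle for the coverage histograms."""
    seqs, ledger = amoa_dataset
    summary = coverage_table(seqs, psamoa)
    for cluster, grp in ledger.groupby("cluster"):
        assert summary.cell(cluster, "forward").histogram == Counter(
            grp["fwd_mismatches"]
        )
        assert summary.cell(cluster, "reverse").histogram == Counter(
            grp["rev_mismatches"]
        )
        assert summary.cell(cluster, "set").histogram == Counter(
            grp["fwd_mismatches"] + grp["rev_mismatches"]
        )


def test_cluster_6a_set_mismatches_span_two_to_four(amoa_dataset, psamoa):
    seqs, _ = amoa_dataset
    summary = coverage_table(seqs, psamoa)
    cell = summary.cell("6A", "set")
    assert cell.min_mismatches >= 2
    assert cell.max_mismatches <= 4


def test_sequence_count_conservation(amoa_dataset, psamoa):
    seqs, _ = amoa_dataset
    # one extra sequence too short to contain either priming region
    from primerscope import TargetSequence

    extra = TargetSequence(id="stub", gene="amoA", sequence="ACGT" * 15, cluster="7")
    summary = coverage_table(seqs + [extra], psamoa, max_mismatch_scan=3)
    for role in ("forward", "reverse", "set"):
        tallied = sum(
            cell.n_sequences for (c, r), cell in summary.cells.items() if r == role
        )
        unavailable = sum(
            n for (c, r), n in summary.unavailable.items() if r == role
        )
        assert tallied + unavailable == summary.n_input == len(seqs) + 1


def test_coverage_contract_errors(ps16, psamoa, amoa_dataset):
    seqs, _ = amoa_dataset
    with pytest.raises(ValueError, match="empty"):
        coverage_table([], psamoa)
    with pytest.raises(ValueError, match="primer set targets"):
        coverage_table(seqs, ps16)


def test_fraction_covered_is_monotone_and_reaches_one(amoa_dataset, psamoa):
    seqs, _ = amoa_dataset
    summary = coverage_table(seqs, psamoa)
    for (cluster, role), cell in summary.cells.items():
        fracs = [cell.fraction_at_most(m) for m in range(0, len(psamoa.reverse) + 1)]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0


def test_fraction_at_most_from_histogram():
    cell = CoverageCell()
    for m, k in {0: 3, 1: 1, 2: 1}.items():
        for _ in range(k):
            cell.add(m, 0)
    assert cell.fraction_at_most(1) == pytest.approx(0.8)


def test_unknown_cell_lookup_errors(amoa_dataset, psamoa):
    seqs, _ = amoa_dataset
    summary = coverage_table(seqs, psamoa)
    with pytest.raises(KeyError):
        fraction_covered(summary, "nope", "forward", 0)


def test_plot_coverage_writes_figure(tmp_path, amoa_dataset, psamoa):
    from primerscope.coverage import plot_coverage

    seqs, _ = amoa_dataset
    out = tmp_path / "cov.png"
    fig = plot_coverage(coverage_table(seqs, psamoa), path=out)
    assert out.stat().st_size > 0
    assert len(fig.axes) == 3


# -- clone-library composition -------------------------------------------------


def test_library_false_positive_share_rounds_to_headline_percent():
    # 82 clones, 5 of them outside the AOB vocabulary -> 6%
    labels = ["6A"] * 70 + ["0"] * 7 + ["non-AOB"] * 5
    lib = CloneLibrary(name="isl-16s", gene="16S", labels=labels)
    s = summarize_library(lib, target_clusters={"6A", "7", "0", "other-AOB"})
    assert s.n == 82
    assert s.percent_non_target_rounded == 6
    assert s.percent_non_target == pytest.approx(100 * 5 / 82)
    assert s.table["percent"].sum() == pytest.approx(100.0)


def test_all_target_library_has_zero_non_target():
    lib = CloneLibrary(name="x", gene="amoA", labels=["7"] * 43)
    s = summarize_library(lib, target_clusters={"6A", "7"})
    assert s.percent_non_target == 0.0


def test_even_mixture_and_permutation_invariance(rng):
    labels = ["6A"] * 25 + ["7"] * 25
    perm = list(rng.permutation(labels))
    s1 = summarize_library(CloneLibrary("a", "16S", labels), {"6A", "7"})
    s2 = summarize_library(CloneLibrary("a", "16S", perm), {"6A", "7"})
    assert s1.table.equals(s2.table)
    assert set(s1.table["percent"]) == {50.0}
    assert s1.percent_non_target == 0.0
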