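"""Mismatch -> efficiency model, simulated qPCR, and clone-library sampling."""

import math

import numpy as np
import pytest

from primerscope import (
    BiasReport,
    CommunityProfile,
    EfficiencyModel,
    QuantEstimate,
    bias_report,
    cluster_mismatches_from_coverage,
    copy_corrected_cells,
    expected_clone_fractions,
    relative_efficiency,
    signal_attenuation,
    simulate_clone_library,
    simulate_qpcr,
)
from primerscope.coverage import CoverageCell, CoverageSummary


@pytest.mark.parametrize(
    "m,t,model,expected",
    [
        (0, 0, EfficiencyModel(), 1.0),
        (2, 0, EfficiencyModel(rho=0.5), 0.25),
        (2, 1, EfficiencyModel(rho=0.5, rho3=0.1), 0.025),
        (1, 1, EfficiencyModel(rho=0.5, rho3=0.1), 0.05),
    ],
)
def test_relative_efficiency_closed_form(m, t, model, expected):
    assert relative_efficiency(m, t, model) == pytest.approx(expected)


def test_relative_efficiency_contract():
    with pytest.raises(ValueError):
        relative_efficiency(1, 2, EfficiencyModel())


def test_model_parameter_ranges():
    for bad in (dict(e0=0), dict(e0=1.2), dict(rho=-0.1), dict(rho3=2), dict(n_q=0)):
        with pytest.raises(ValueError):
            EfficiencyModel(**bad)


def test_attenuation_inverts_to_fifty_fold():
    """Closed-form inversion: the eta that makes one cluster appear 50x low."""
    model = EfficiencyModel(e0=0.95, n_q=30)
    eta = ((0.02 ** (1 / 30)) * (1 + model.e0) - 1) / model.e0
    assert signal_attenuation(eta, model) == pytest.approx(0.02, rel=1e-12)


COMM = CommunityProfile(cells={"6A": 6e7, "7": 4e7})


def test_qpcr_no_bias_limit_is_exact():
    est = simulate_qpcr(COMM, {"6A": (0, 0), "7": (0, 0)}, EfficiencyModel(), "amoA")
    assert est.apparent_copies == pytest.approx(COMM.total_copies("amoA"), rel=0)
    assert est.corrected_cells == pytest.approx(COMM.total_cells, rel=0)


def test_qpcr_zero_efficiency_cluster_vanishes():
    model = EfficiencyModel(rho=0.0)  # any mismatch kills amplification
    est = simulate_qpcr(COMM, {"6A": (1, 0), "7": (0, 0)}, model, "16S")
    matched = COMM.cells["7"] * COMM.copies("16S", "7")
    assert est.apparent_copies == pytest.approx(matched, rel=1e-6)


def test_qpcr_missing_cluster_entry_is_error():
    with pytest.raises(ValueError, match="no mismatch entry"):
        simulate_qpcr(COMM, {"6A": (0, 0)}, EfficiencyModel(), "16S")


@pytest.mark.parametrize(
    "copies,per_cell,expected",
    [(3e8, 1, 3e8), (6e6, 2, 3e6), (123.0, 1, 123.0)],
)
def test_copy_correction(copies, per_cell, expected):
    assert copy_corrected_cells(copies, per_cell) == expected


def test_copy_correction_contract():
    with pytest.raises(ValueError):
        copy_corrected_cells(10, 0)


def _estimate(gene, cells, cpc=1.0):
    return QuantEstimate(
        gene=gene,
        apparent_copies=cells * cpc,
        corrected_cells=cells,
        per_cluster_copies={"6A": cells * cpc},
        copies_per_cell_used=cpc,
    )


def test_bias_report_ratio_arithmetic():
    assert bias_report(_estimate("16S", 1e6), _estimate("amoA", 1e6)).ratio == 1.0
    r = bias_report(_estimate("16S", 5e7), _estimate("amoA", 1e6, cpc=2.0))
    assert r.ratio == pytest.approx(50.0)
    assert not r.infinite


def test_bias_report_zero_amoa_is_flagged_infinite():
    r = bias_report(_estimate("16S", 1e6), _estimate("amoA", 0.0))
    assert r.infinite and math.isinf(r.ratio)


def test_ratio_monotone_in_rho_and_cluster_fraction():
    """Across a 5x5 grid: non-increasing in rho, non-decreasing in the
    mismatched cluster's cell fraction."""
    rhos = np.linspace(0.2, 1.0, 5)
    fracs = np.linspace(0.1, 0.9, 5)

    def ratio(rho, frac):
        model = EfficiencyModel(rho=rho)
        comm = CommunityProfile(cells={"6A": 1e8 * frac, "7": 1e8 * (1 - frac)})
        mm = {"6A": (3, 0), "7": (0, 0)}
        est16 = simulate_qpcr(comm, {c: (0, 0) for c in comm.cells}, model, "16S")
        esta = simulate_qpcr(comm, mm, model, "amoA")
        return bias_report(est16, esta).ratio

    for frac in fracs:
        col = [ratio(r, frac) for r in rhos]
        assert all(a >= b - 1e-12 for a, b in zip(col, col[1:]))
    for rho in rhos:
        row = [ratio(rho, f) for f in fracs]
        assert all(a <= b + 1e-12 for a, b in zip(row, row[1:]))
    assert ratio(1.0, 0.5) == pytest.approx(1.0)  # no-penalty limit


def test_ratio_monotone_in_cycle_number():
    ratios = []
    for n_q in (10, 20, 30, 40):
        model = EfficiencyModel(n_q=n_q)
        est16 = simulate_qpcr(COMM, {c: (0, 0) for c in COMM.cells}, model, "16S")
        esta = simulate_qpcr(COMM, {"6A": (3, 0), "7": (0, 0)}, model, "amoA")
        ratios.append(bias_report(est16, esta).ratio)
    assert ratios == sorted(ratios)


# -- clone-library simulation ---------------------------------------------------


def test_single_cluster_library_is_pure():
    comm = CommunityProfile(cells={"6A": 1e6})
    lib = simulate_clone_library(comm, {"6A": (3, 0)}, EfficiencyModel(), "amoA",
                                 n_clones=43, seed=7)
    assert lib.labels == ["6A"] * 43


def test_library_seed_determinism():
    args = (COMM, {"6A": (2, 0), "7": (0, 0)}, EfficiencyModel(), "amoA")
    a = simulate_clone_library(*args, n_clones=92, seed=5)
    b = simulate_clone_library(*args, n_clones=92, seed=5)
    c = simulate_clone_library(*args, n_clones=92, seed=6)
    assert a.labels == b.labels
    assert a.n == c.n == 92


def test_equal_efficiency_library_tracks_cell_fractions():
    """With no bias, empirical frequencies sit within 3 SE of cell fractions."""
    mm = {"6A": (0, 0), "7": (0, 0)}
    n_clones, n_seeds = 50, 200
    count_6a = 0
    for seed in range(n_seeds):
        lib = simulate_clone_library(COMM, mm, EfficiencyModel(), "16S",
                                     n_clones=n_clones, seed=seed)
        count_6a += lib.labels.count("6A")
    p = COMM.cells["6A"] / COMM.total_cells
    n_total = n_clones * n_seeds
    se = math.sqrt(p * (1 - p) / n_total)
    assert abs(count_6a / n_total - p) < 3 * se


def test_expected_fractions_sum_to_one():
    fr = expected_clone_fractions(COMM, {"6A": (3, 0), "7": (0, 0)},
                                  EfficiencyModel(), "amoA")
    assert sum(fr.values()) == pytest.approx(1.0)
    assert fr["6A"] < fr["7"]


# -- coverage -> mismatch inputs -----------------------------------------------


def _summary_from_means(fwd_counts, rev_counts):
    cells = {}
    for role, counts in (("forward", fwd_counts), ("reverse", rev_counts)):
        cell = CoverageCell()
        for m in counts:
            cell.add(m, 0)
        cells[("6A", role)] = cell
    return CoverageSummary("x", "amoA", {"forward": "f", "reverse": "r"},
                           cells, {}, len(fwd_counts))


def test_cluster_mismatches_rounded_mean_per_primer():
    # forward mean 1.75 -> 2, reverse mean 1.25 -> 1: set total 3
    s = _summary_from_means([1, 2, 2, 2], [1, 1, 1, 2])
    assert cluster_mismatches_from_coverage(s) == {"6A": (3, 0)}
    # half-to-even at the .5 boundary: mean 0.5 -> 0, mean 1.5 -> 2
    s2 = _summary_from_means([0, 1], [1, 2])
    assert cluster_mismatches_from_coverage(s2) == {"6A": (2, 0)}


def test_cluster_mismatches_min_statistic():
    s = _summary_from_means([1, 2, 2, 2], [1, 1, 1, 2])
    assert cluster_mismatches_from_coverage(s, statistic="min") == {"6A": (2, 0)}
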