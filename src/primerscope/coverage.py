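"""Per-cluster primer coverage tables and clone-library composition.

Coverage of a primer over a set of target sequences is summarized per
(cluster, primer) cell as a mismatch histogram: how many sequences present
0, 1, 2, ... positional mismatches at their best binding site.  For a primer
set three cells are kept per cluster:

``forward``
    the forward mixture, collapsed to the minimum mismatch count over its
    members (a mixture anneals through its best-matching oligo);
``reverse``
    the single reverse primer;
``set``
    the primer-set total, i.e. forward + reverse mismatches summed, tallied
    only for sequences where both priming regions are available.

A priming region counts as *unavailable* for a sequence when no window scores
within ``max_mismatch_scan`` or when the best window contains more than 5%
non-ACGT letters; such sequences are excluded from that primer's histogram
but tallied, so input counts are conserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pcr import BindingMatch, _best_forward, _scan
from .primers import PrimerSet
from .sequences import TargetSequence

__all__ = [
    "CoverageCell",
    "CoverageSummary",
    "CloneLibrary",
    "LibrarySummary",
    "coverage_table",
    "fraction_covered",
    "summarize_library",
]

ROLES = ("forward", "reverse", "set")

#: Maximum tolerated share of non-ACGT letters in a priming window before the
#: region is considered unavailable for coverage purposes.
MAX_AMBIGUOUS_FRACTION = 0.05


@dataclass
class CoverageCell:
    """Mismatch histogram for one (cluster, primer-role) cell."""

    n_sequences: int = 0
    histogram: Counter = field(default_factory=Counter)
    three_prime_sum: int = 0

    def add(self, mismatches: int, three_prime: int) -> None:
        self.n_sequences += 1
        self.histogram[mismatches] += 1
        self.three_prime_sum += three_prime

    @property
    def mean_mismatches(self) -> float:
        if self.n_sequences == 0:
            raise ValueError("empty coverage cell has no mean")
        return sum(m * c for m, c in self.histogram.items()) / self.n_sequences

    @property
    def mean_three_prime(self) -> float:
        if self.n_sequences == 0:
            raise ValueError("empty coverage cell has no mean")
        return self.three_prime_sum / self.n_sequences

    @property
    def min_mismatches(self) -> int:
        return min(self.histogram)

    @property
    def max_mismatches(self) -> int:
        return max(self.histogram)

    def fraction_at_most(self, m: int) -> float:
        if self.n_sequences == 0:
            raise ValueError("empty coverage cell has no coverage fraction")
        return sum(c for k, c in self.histogram.items() if k <= m) / self.n_sequences


@dataclass
class CoverageSummary:
    """Per-cluster mismatch histograms for one primer set."""

    primer_set_name: str
    gene: str
    primer_labels: dict[str, str]  # role -> primer name(s)
    cells: dict[tuple[str, str], CoverageCell]  # (cluster, role) -> cell
    unavailable: dict[tuple[str, str], int]  # (cluster, role) -> count
    n_input: int

    def clusters(self) -> list[str]:
        return sorted({c for c, _ in self.cells})

    def cell(self, cluster: str, role: str) -> CoverageCell:
        try:
            return self.cells[(cluster, role)]
        except KeyError:
            raise KeyError(
                f"no coverage cell for cluster {cluster!r}, primer {role!r}"
            ) from None

    def pooled(self, role: str) -> CoverageCell:
        """All clusters pooled (sequence-count weighted) for one primer role."""
        pool = CoverageCell()
        for (_, r), cell in self.cells.items():
            if r == role:
                pool.n_sequences += cell.n_sequences
                pool.histogram.update(cell.histogram)
                pool.three_prime_sum += cell.three_prime_sum
        return pool

    def per_cluster_average(self, role: str, m: int) -> float:
        """Unweighted mean over clusters of the fraction with <= m mismatches."""
        fracs = [
            cell.fraction_at_most(m)
            for (_, r), cell in self.cells.items()
            if r == role and cell.n_sequences > 0
        ]
        if not fracs:
            raise ValueError(f"no populated cells for primer {role!r}")
        return sum(fracs) / len(fracs)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: cluster, primer, mismatches, count."""
        rows = [
            {
                "cluster": cluster,
                "primer": self.primer_labels[role],
                "role": role,
                "mismatches": m,
                "count": c,
            }
            for (cluster, role), cell in sorted(self.cells.items())
            for m, c in sorted(cell.histogram.items())
        ]
        return pd.DataFrame(
            rows, columns=["cluster", "primer", "role", "mismatches", "count"]
        )


def coverage_table(
    sequences: Iterable[TargetSequence],
    primer_set: PrimerSet,
    max_mismatch_scan: int = 6,
) -> CoverageSummary:
    """Tabulate best-site mismatches per cluster for one primer set.

    Each sequence contributes to the ``forward`` and ``reverse`` cells of its
    cluster independently (a sequence lacking one priming region still counts
    for the other), and to the ``set`` cell only when both regions are
    available.  Deterministic given inputs.

    Raises
    ------
    ValueError
        On an empty input collection, a sequence whose gene does not match
        the primer set's target gene, or a missing cluster annotation.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("coverage_table: empty sequence collection")

    cells: dict[tuple[str, str], CoverageCell] = {}
    unavailable: dict[tuple[str, str], int] = {}
    labels = {
        "forward": primer_set.forward_label,
        "reverse": primer_set.reverse.name,
        "set": primer_set.name,
    }

    for seq in seqs:
        if seq.gene != primer_set.target_gene:
            raise ValueError(
                f"sequence {seq.id!r} is {seq.gene}, primer set targets "
                f"{primer_set.target_gene}"
            )
        if seq.cluster is None:
            raise ValueError(f"sequence {seq.id!r} has no cluster annotation")
        cluster = seq.cluster

        fwd = _best_forward(seq, primer_set)
        rev = (
            _scan(seq.sequence, seq.id, primer_set.reverse, "minus")
            if len(seq) >= len(primer_set.reverse)
            else None
        )
        matches: dict[str, BindingMatch | None] = {"forward": fwd, "reverse": rev}

        ok: dict[str, BindingMatch] = {}
        for role, m in matches.items():
            if (
                m is None
                or m.mismatch_total > max_mismatch_scan
                or m.ambiguous_fraction > MAX_AMBIGUOUS_FRACTION
            ):
                unavailable[(cluster, role)] = unavailable.get((cluster, role), 0) + 1
            else:
                ok[role] = m
                cells.setdefault((cluster, role), CoverageCell()).add(
                    m.mismatch_total, m.three_prime_mismatches
                )
        if len(ok) == 2:
            cells.setdefault((cluster, "set"), CoverageCell()).add(
                ok["forward"].mismatch_total + ok["reverse"].mismatch_total,
                ok["forward"].three_prime_mismatches
                + ok["reverse"].three_prime_mismatches,
            )
        else:
            unavailable[(cluster, "set")] = unavailable.get((cluster, "set"), 0) + 1

    return CoverageSummary(
        primer_set_name=primer_set.name,
        gene=primer_set.target_gene,
        primer_labels=labels,
        cells=cells,
        unavailable=unavailable,
        n_input=len(seqs),
    )


def plot_coverage(summary: CoverageSummary, path=None):
    """Per-cluster mismatch histograms, one panel per primer role.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = summary.clusters()
    roles = [r for r in ROLES if any(k[1] == r for k in summary.cells)]
    fig, axes = plt.subplots(1, len(roles), figsize=(4 * len(roles), 3.2),
                             sharey=True, squeeze=False)
    max_m = max((max(c.histogram) for c in summary.cells.values()), default=0)
    xs = list(range(max_m + 1))
    width = 0.8 / max(len(clusters), 1)
    for ax, role in zip(axes[0], roles):
        for i, cluster in enumerate(clusters):
            cell = summary.cells.get((cluster, role))
            if cell is None:
                continue
            fr = [cell.histogram.get(m, 0) / cell.n_sequences for m in xs]
            ax.bar([x + i * width for x in xs], fr, width=width,
                   label=f"{cluster} (n={cell.n_sequences})")
        ax.set_title(f"{summary.primer_labels[role]} ({role})")
        ax.set_xlabel("mismatches")
        ax.set_xticks([x + width * (len(clusters) - 1) / 2 for x in xs], xs)
    axes[0][0].set_ylabel("fraction of sequences")
    axes[0][-1].legend(fontsize=8)
    fig.suptitle(f"{summary.gene} primer coverage by cluster")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def fraction_covered(
    summary: CoverageSummary, cluster: str, primer: str, m: int
) -> float:
    """Fraction of a cluster's sequences with at most ``m`` mismatches.

    ``primer`` is a role label: ``forward``, ``reverse`` or ``set``.
    """
    return summary.cell(cluster, primer).fraction_at_most(m)


@dataclass
class CloneLibrary:
    """A cloning-sequencing library: one cluster label per clone."""

    name: str
    gene: str
    labels: list[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"clone library {self.name!r} is empty")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class LibrarySummary:
    """Composition of a clone library with non-target accounting."""

    library_name: str
    n: int
    table: pd.DataFrame  # cluster, count, percent
    percent_non_target: float  # unrounded
    percent_non_target_rounded: int  # headline figure


def summarize_library(
    library: CloneLibrary, target_clusters: Sequence[str] | set[str]
) -> LibrarySummary:
    """Per-cluster composition and the share of non-target (false-positive) clones.

    Percentages sum to 100 within rounding; the headline non-target figure is
    rounded to the nearest integer percent, and the exact value is reported
    alongside.  Invariant under permutation of the clone labels.
    """
    targets = set(target_clusters)
    if not targets:
        raise ValueError("target_clusters must be non-empty")
    counts = Counter(library.labels)
    n = library.n
    table = pd.DataFrame(
        [
            {"cluster": c, "count": k, "percent": 100.0 * k / n}
            for c, k in sorted(counts.items())
        ]
    )
    non_target = sum(k for c, k in counts.items() if c not in targets)
    pct = 100.0 * non_target / n
    return LibrarySummary(
        library_name=library.name,
        n=n,
        table=table,
        percent_non_target=pct,
        percent_non_target_rounded=round(pct),
    )
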