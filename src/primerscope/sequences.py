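"""Annotated target sequences and the cluster vocabulary.

Cluster assignment (Nitrosomonas Cluster 6A = the N. oligotropha lineage,
Cluster 7 = the N. europaea/eutropha lineage, "0" = Nitrosospira-type) is an
*input annotation*: in practice it comes from phylogenetic placement, which
this package deliberately does not re-implement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["DEFAULT_CLUSTERS", "TargetSequence"]

#: Default controlled vocabulary of cluster labels.  Extensible: collections
#: may declare extra labels, but annotations must come from a declared set.
DEFAULT_CLUSTERS: tuple[str, ...] = ("6A", "7", "0", "other-AOB", "non-AOB")

GENES = ("16S", "amoA")


@dataclass
class TargetSequence:
    """One target-gene sequence with its cluster annotation.

    ``ledger`` is only populated for synthetic records: it holds the planted
    mismatch counts/positions and insert length that the matching engine is
    guaranteed (by construction) to recover.
    """

    id: str
    gene: str
    sequence: str
    cluster: str | None = None
    source: str = "user"
    ledger: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.gene not in GENES:
            raise ValueError(f"sequence {self.id!r}: gene must be one of {GENES}")
        if self.source not in ("synthetic", "user"):
            raise ValueError(f"sequence {self.id!r}: bad source {self.source!r}")

    def __len__(self) -> int:
        return len(self.sequence)
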