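"""Degenerate (IUPAC) primer definitions and positional matching.

A degenerate primer is a mixture of concrete oligonucleotides: each IUPAC
letter stands for a set of bases, and a template position *matches* iff the
template base is a member of the primer letter's set.  Degeneracy in the
primer is therefore "free" (the mixture contains an oligo for every
expansion), while any template base outside the set — including ambiguity
letters such as N on the template side — counts as a mismatch.  Under this
convention the positional mismatch count equals the minimum Hamming distance
over the full expansion of the primer, which is what the matching engine
exploits to avoid enumerating expansions.

Matching is purely positional: no melting temperature, duplex stability or
secondary-structure modelling is attempted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "IUPAC_SETS",
    "COMPLEMENT",
    "DegeneratePrimer",
    "PrimerSet",
    "InvalidPrimerError",
    "expand_degenerate",
    "mismatch_count",
    "reverse_complement",
    "default_primer_sets",
]

#: IUPAC nucleotide codes -> the set of concrete bases each stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Number of bases at the primer's 3' end treated as the extension-critical
#: window when reporting three-prime mismatches.
THREE_PRIME_WINDOW = 3


class InvalidPrimerError(ValueError):
    """Raised when a primer sequence violates the IUPAC alphabet contract."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (case-insensitive)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"cannot complement non-IUPAC letter {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class DegeneratePrimer:
    """A single (possibly degenerate) primer, written 5'->3'.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"CTO189fA/B"``.
    sequence : str
        IUPAC nucleotide string, 5'->3', length >= 10.
    orientation : {"forward", "reverse"}
        Which strand the primer anneals to in the assay.
    """

    name: str
    sequence: str
    orientation: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for i, letter in enumerate(seq):
            if letter not in IUPAC_SETS:
                raise InvalidPrimerError(
                    f"primer {self.name!r}: non-IUPAC character {letter!r} "
                    f"at position {i}"
                )
        if len(seq) < 10:
            raise InvalidPrimerError(
                f"primer {self.name!r}: length {len(seq)} < 10"
            )
        if self.orientation not in ("forward", "reverse"):
            raise InvalidPrimerError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        """Number of concrete oligos in the mixture this primer denotes."""
        d = 1
        for letter in self.sequence:
            d *= len(IUPAC_SETS[letter])
        return d


@dataclass(frozen=True)
class PrimerSet:
    """A qPCR primer set: one or more forward primers (a mixture) + one reverse.

    ``amplicon_length_bounds`` are inclusive bounds on the *total* product
    length (both primer footprints included).
    """

    name: str
    forwards: tuple[DegeneratePrimer, ...]
    reverse: DegeneratePrimer
    target_gene: str
    amplicon_length_bounds: tuple[int, int]

    def __post_init__(self) -> None:
        if isinstance(self.forwards, list):
            object.__setattr__(self, "forwards", tuple(self.forwards))
        if not self.forwards:
            raise ValueError(f"primer set {self.name!r}: needs >=1 forward primer")
        lo, hi = self.amplicon_length_bounds
        if not (1 <= lo <= hi):
            raise ValueError(
                f"primer set {self.name!r}: bad amplicon bounds ({lo}, {hi})"
            )
        if self.target_gene not in ("16S", "amoA"):
            raise ValueError(
                f"primer set {self.name!r}: target_gene must be '16S' or "
                f"'amoA', got {self.target_gene!r}"
            )

    @property
    def forward_label(self) -> str:
        """Joint label for the forward mixture (e.g. ``CTO189fA/B+CTO189fC``)."""
        return "+".join(p.name for p in self.forwards)


def _as_sequence(primer: DegeneratePrimer | str, what: str = "primer") -> str:
    """Accept either a DegeneratePrimer or a bare IUPAC string."""
    seq = (primer if isinstance(primer, str) else primer.sequence).upper()
    for i, letter in enumerate(seq):
        if letter not in IUPAC_SETS:
            raise InvalidPrimerError(
                f"{what}: non-IUPAC character {letter!r} at position {i}"
            )
    return seq


def _expansions(sequence: str) -> Iterator[str]:
    pools = [sorted(IUPAC_SETS[letter]) for letter in sequence]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def expand_degenerate(primer: DegeneratePrimer | str) -> list[str]:
    """Enumerate every concrete ACGT oligo in the primer mixture.

    Returns the deduplicated expansion in lexicographic order; its length
    equals :attr:`DegeneratePrimer.degeneracy`.  Accepts a bare IUPAC string
    as well as a :class:`DegeneratePrimer`.
    """
    return list(_expansions(_as_sequence(primer)))


def mismatch_count(
    primer: DegeneratePrimer | str, window: str
) -> tuple[int, list[int]]:
    """Positional mismatches between a primer and a template window.

    The window is read on the strand the primer anneals to, aligned 5'->3'
    with the primer, and must have exactly the primer's length.  A position
    matches iff the template base is in the primer letter's IUPAC set;
    template letters outside ACGT never satisfy membership and so count as
    mismatches.  The returned total equals the minimum Hamming distance over
    the primer's full expansion.

    Returns
    -------
    (mismatch_total, mismatch_positions)
        Positions are 0-based from the primer's 5' end.
    """
    window = window.upper()
    pseq = _as_sequence(primer)
    if len(window) != len(pseq):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pseq)}"
        )
    positions = [
        i for i, (p, b) in enumerate(zip(pseq, window)) if b not in IUPAC_SETS[p]
    ]
    return len(positions), positions


def three_prime_mismatches(
    primer: DegeneratePrimer | str, positions: list[int]
) -> int:
    """Count of mismatch positions inside the 3'-terminal window."""
    cutoff = len(_as_sequence(primer)) - THREE_PRIME_WINDOW
    return sum(1 for p in positions if p >= cutoff)


def default_primer_sets() -> dict[str, PrimerSet]:
    """The two packaged AOB primer sets.

    Sequences are transcribed from the primary publications that introduced
    the assays: the CTO189f mixture (three forward variants, two of which are
    written as one degenerate oligo) with the RT1r reverse primer for the
    betaproteobacterial AOB 16S rRNA gene (116 bp product: 75 bases between
    the priming sites), and the amoA-1F / amoA-2R pair for the amoA gene
    (491 bp product).  Both are returned keyed by set name; callers may
    supply their own definitions instead via the YAML loader in
    :mod:`primerscope.io`.
    """
    cto_ab = DegeneratePrimer("CTO189fA/B", "GGAGRAAAGCAGGGGATCG", "forward")
    cto_c = DegeneratePrimer("CTO189fC", "GGAGGAAAGTAGGGGATCG", "forward")
    rt1r = DegeneratePrimer("RT1r", "CGTCCTCTCAGACCARCTACTG", "reverse")
    amoa1f = DegeneratePrimer("amoA-1F", "GGGGTTTCTACTGGTGGT", "forward")
    amoa2r = DegeneratePrimer("amoA-2R", "CCCCTCKGSAAAGCCTTCTTC", "reverse")
    return {
        "CTO189-RT1r": PrimerSet(
            name="CTO189-RT1r",
            forwards=(cto_ab, cto_c),
            reverse=rt1r,
            target_gene="16S",
            amplicon_length_bounds=(80, 250),
        ),
        "amoA1F-2R": PrimerSet(
            name="amoA1F-2R",
            forwards=(amoa1f,),
            reverse=amoa2r,
            target_gene="amoA",
            amplicon_length_bounds=(300, 700),
        ),
    }
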