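"""Binding-site search and in silico PCR product extraction.

All coordinates are 0-based, half-open, and always reported on the plus
strand of the template, regardless of which strand a primer anneals to.
The "best" binding site for a primer is the window with the smallest
positional mismatch total; ties are broken by the smallest plus-strand start,
and (for forward mixtures) by the declaration order of the mixture members.
"""

from __future__ import annotations

from dataclasses import dataclass

from .primers import (
    DegeneratePrimer,
    PrimerSet,
    mismatch_count,
    reverse_complement,
    three_prime_mismatches,
)
from .sequences import TargetSequence

__all__ = ["BindingMatch", "Amplicon", "NoAmplicon", "find_best_site", "in_silico_pcr"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class BindingMatch:
    """Best binding site of one primer on one template.

    ``start``/``end`` delimit the footprint on the template's plus strand;
    ``mismatch_positions`` are 0-based from the primer's 5' end;
    ``ambiguous_fraction`` is the share of non-ACGT template letters in the
    window (used to exclude low-quality priming regions from coverage).
    """

    primer_name: str
    template_id: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatch_total: int
    mismatch_positions: tuple[int, ...]
    three_prime_mismatches: int
    ambiguous_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mismatch_positions) != self.mismatch_total:
            raise ValueError("mismatch_positions inconsistent with mismatch_total")
        if not 0 <= self.three_prime_mismatches <= self.mismatch_total:
            raise ValueError("three_prime_mismatches out of range")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``inter_primer_length`` counts the bases strictly between the two primer
    footprints; ``total_length`` includes both footprints.  Both are reported
    because "amplicon length" is used with either convention in the
    literature.
    """

    template_id: str
    forward_match: BindingMatch
    reverse_match: BindingMatch
    inter_primer_length: int
    total_length: int
    sequence: str  # inter-primer region, plus strand

    def __bool__(self) -> bool:
        return True


@dataclass(frozen=True)
class NoAmplicon:
    """Machine-readable in silico PCR failure.

    ``reason`` is one of ``no-forward``, ``no-reverse``,
    ``length-out-of-bounds``.
    """

    template_id: str
    reason: str

    def __bool__(self) -> bool:
        return False


def _ambiguous_fraction(window: str) -> float:
    return sum(1 for b in window if b not in _ACGT) / len(window)


def _scan(
    seq: str,
    template_id: str,
    primer: DegeneratePrimer,
    strand: str,
    region_start: int = 0,
) -> BindingMatch | None:
    """Best window for ``primer`` on one strand; None only for empty region.

    Iterates plus-strand starts in increasing order and keeps strict
    improvements, so ties resolve to the 5'-most plus-strand start.
    """
    k = len(primer)
    n = len(seq)
    best: tuple[int, int] | None = None  # (mismatch_total, start)
    best_positions: tuple[int, ...] = ()
    for s in range(region_start, n - k + 1):
        window = seq[s : s + k]
        if strand == "minus":
            window = reverse_complement(window)
        total, positions = mismatch_count(primer, window)
        if best is None or total < best[0]:
            best = (total, s)
            best_positions = tuple(positions)
            if total == 0:
                break
    if best is None:
        return None
    total, s = best
    window = seq[s : s + k]
    return BindingMatch(
        primer_name=primer.name,
        template_id=template_id,
        strand=strand,
        start=s,
        end=s + k,
        mismatch_total=total,
        mismatch_positions=best_positions,
        three_prime_mismatches=three_prime_mismatches(primer, list(best_positions)),
        ambiguous_fraction=_ambiguous_fraction(window),
    )


def find_best_site(
    template: TargetSequence,
    primer: DegeneratePrimer,
    search_strand: str = "plus",
    max_mismatch: int | None = None,
) -> BindingMatch | None:
    """Exhaustively scan one strand of a template for the primer's best site.

    A minus-strand search reads each window as its reverse complement (the
    strand the primer would anneal to) but reports coordinates on the plus
    strand.  Returns ``None`` if the best site exceeds ``max_mismatch``
    (``None`` disables the cutoff).

    Raises
    ------
    ValueError
        If the template is shorter than the primer.
    """
    if search_strand not in ("plus", "minus"):
        raise ValueError(f"search_strand must be 'plus' or 'minus', got {search_strand!r}")
    if len(template) < len(primer):
        raise ValueError(
            f"template {template.id!r} (len {len(template)}) shorter than "
            f"primer {primer.name!r} (len {len(primer)})"
        )
    match = _scan(template.sequence, template.id, primer, search_strand)
    if match is None:
        return None
    if max_mismatch is not None and match.mismatch_total > max_mismatch:
        return None
    return match


def _best_forward(
    template: TargetSequence, primer_set: PrimerSet
) -> BindingMatch | None:
    """Best plus-strand site over all forward-mixture members.

    The member with the smallest mismatch total wins; ties by 5'-most start,
    then by declaration order in the mixture.
    """
    best: BindingMatch | None = None
    for primer in primer_set.forwards:
        if len(template) < len(primer):
            continue
        m = _scan(template.sequence, template.id, primer, "plus")
        if m is None:
            continue
        if (
            best is None
            or m.mismatch_total < best.mismatch_total
            or (m.mismatch_total == best.mismatch_total and m.start < best.start)
        ):
            best = m
    return best


def in_silico_pcr(
    template: TargetSequence,
    primer_set: PrimerSet,
    max_mismatch: int = 3,
) -> Amplicon | NoAmplicon:
    """Predict the PCR product of a primer set on one template.

    The forward site is the best plus-strand site over the whole forward
    mixture; the reverse site is the best minus-strand site of the reverse
    primer located entirely 3' of the forward footprint.  An amplicon is
    returned only if both sites are within ``max_mismatch`` and the total
    product length falls inside the set's ``amplicon_length_bounds``;
    otherwise a :class:`NoAmplicon` carries the failure reason.
    """
    fwd = _best_forward(template, primer_set)
    if fwd is None or fwd.mismatch_total > max_mismatch:
        return NoAmplicon(template.id, "no-forward")

    rev_primer = primer_set.reverse
    if len(template) - fwd.end < len(rev_primer):
        return NoAmplicon(template.id, "no-reverse")
    rev = _scan(template.sequence, template.id, rev_primer, "minus", region_start=fwd.end)
    if rev is None or rev.mismatch_total > max_mismatch:
        return NoAmplicon(template.id, "no-reverse")

    total_length = rev.end - fwd.start
    lo, hi = primer_set.amplicon_length_bounds
    if not lo <= total_length <= hi:
        return NoAmplicon(template.id, "length-out-of-bounds")

    inter = rev.start - fwd.end
    return Amplicon(
        template_id=template.id,
        forward_match=fwd,
        reverse_match=rev,
        inter_primer_length=inter,
        total_length=total_length,
        sequence=template.sequence[fwd.end : rev.start],
    )
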