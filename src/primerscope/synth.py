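"""Synthetic target-gene sequences with planted primer-mismatch profiles.

Every emitted sequence is built as

    5' pad + forward priming site + insert + revcomp(reverse priming site) + 3' pad

where the priming sites start from a random concrete expansion of the primer
(for the 16S forward mixture: of a random mixture member) into which exactly
the drawn number of substitutions is planted at random non-repeating primer
positions, and pads/insert are uniform-ACGT random sequence.  A candidate is
rejected and redrawn unless the matching engine recovers exactly the planted
picture — same binding-site starts, same mismatch counts and positions, and
the planted insert length — both under a whole-template scan (what coverage
uses) and under in silico PCR.  This guarantee is what lets the generator
ledger serve as an exact oracle for the analysis stages.

Sequences are random, not homologs of real AOB genes: the analysis depends
only on priming-region structure.  Real sequences can be substituted through
the standard FASTA + cluster-TSV inputs at any stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import CommunityProfile
from .pcr import _best_forward, _scan, in_silico_pcr
from .primers import IUPAC_SETS, DegeneratePrimer, PrimerSet, reverse_complement
from .sequences import TargetSequence

__all__ = [
    "PlantSpec",
    "GenerationError",
    "make_template",
    "make_dataset",
    "make_community",
    "preset_specs",
    "PRESETS",
]

_BASES = np.array(list("ACGT"))

#: Default inserts (bases strictly between the priming sites): 75 for the
#: CTO189-RT1r 16S assay (116 bp product) and 452 for the amoA-1F/2R assay
#: (491 bp product).
DEFAULT_INSERT = {"16S": 75, "amoA": 452}

PAD_RANGE = (20, 60)
MAX_REDRAWS = 100


class GenerationError(RuntimeError):
    """Raised when a planted-mismatch spec cannot be realized (over-constrained)."""


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one batch of synthetic sequences of a single cluster.

    Mismatch and insert-length ranges are inclusive; draws are uniform.
    ``three_prime_bias`` steers planted mismatch positions ``toward`` or
    ``away`` from the primer's 3'-terminal window (default: uniform).
    """

    cluster: str
    gene: str
    n_sequences: int
    fwd_mismatch_range: tuple[int, int]
    rev_mismatch_range: tuple[int, int]
    insert_length_range: tuple[int, int] | None = None
    seed: int = 0
    three_prime_bias: str | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        for lo, hi in (self.fwd_mismatch_range, self.rev_mismatch_range):
            if not 0 <= lo <= hi:
                raise ValueError(f"bad mismatch range ({lo}, {hi})")
        if self.three_prime_bias not in (None, "toward", "away"):
            raise ValueError(f"bad three_prime_bias {self.three_prime_bias!r}")

    def insert_range(self) -> tuple[int, int]:
        if self.insert_length_range is not None:
            return self.insert_length_range
        d = DEFAULT_INSERT[self.gene]
        return (d, d)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length else ""


def _position_weights(length: int, bias: str | None, k: int) -> np.ndarray | None:
    if bias is None:
        return None
    w = np.ones(length)
    if bias == "toward":
        w[-3:] = 10.0
    elif k <= length - 3:  # away: exclude the 3' window when possible
        w[-3:] = 0.0
    return w / w.sum()


def _planted_site(
    rng: np.random.Generator, primer: DegeneratePrimer, k: int, bias: str | None
) -> tuple[str, tuple[int, ...]]:
    """A concrete window with exactly k substitutions vs this primer."""
    if k > len(primer):
        raise GenerationError(
            f"cannot plant {k} mismatches in {len(primer)}-base primer {primer.name!r}"
        )
    site = [str(rng.choice(sorted(IUPAC_SETS[c]))) for c in primer.sequence]
    positions = rng.choice(
        len(primer), size=k, replace=False, p=_position_weights(len(primer), bias, k)
    )
    for pos in positions:
        allowed = sorted(set("ACGT") - IUPAC_SETS[primer.sequence[pos]])
        if not allowed:  # N in the primer matches everything
            raise GenerationError(
                f"primer {primer.name!r} position {pos} is N; cannot plant a mismatch"
            )
        site[pos] = str(rng.choice(allowed))
    return "".join(site), tuple(sorted(int(p) for p in positions))


def make_template(
    spec: PlantSpec, primer_set: PrimerSet, rng: np.random.Generator, seq_id: str
) -> TargetSequence:
    """Build one synthetic template honouring ``spec``; verified or redrawn.

    The returned sequence carries its ledger entry (planted counts,
    positions, insert length, binding-site starts).  Raises
    :class:`GenerationError` after 100 failed redraws.
    """
    if spec.gene != primer_set.target_gene:
        raise ValueError(
            f"spec gene {spec.gene!r} != primer set target {primer_set.target_gene!r}"
        )
    k_f = int(rng.integers(spec.fwd_mismatch_range[0], spec.fwd_mismatch_range[1] + 1))
    k_r = int(rng.integers(spec.rev_mismatch_range[0], spec.rev_mismatch_range[1] + 1))
    ins_lo, ins_hi = spec.insert_range()
    insert_len = int(rng.integers(ins_lo, ins_hi + 1))

    for _ in range(MAX_REDRAWS):
        fwd_primer = primer_set.forwards[int(rng.integers(len(primer_set.forwards)))]
        fwd_site, fwd_pos = _planted_site(rng, fwd_primer, k_f, spec.three_prime_bias)
        rev_site, rev_pos = _planted_site(
            rng, primer_set.reverse, k_r, spec.three_prime_bias
        )
        pad5 = _random_seq(rng, int(rng.integers(*PAD_RANGE)))
        pad3 = _random_seq(rng, int(rng.integers(*PAD_RANGE)))
        insert = _random_seq(rng, insert_len)
        seq = pad5 + fwd_site + insert + reverse_complement(rev_site) + pad3

        fwd_start = len(pad5)
        rev_start = fwd_start + len(fwd_primer) + insert_len
        template = TargetSequence(
            id=seq_id, gene=spec.gene, sequence=seq, cluster=spec.cluster,
            source="synthetic",
        )

        # Whole-template recovery (what coverage_table sees).
        best_f = _best_forward(template, primer_set)
        best_r = _scan(seq, seq_id, primer_set.reverse, "minus")
        if best_f is None or best_r is None:
            continue
        if (best_f.start, best_f.mismatch_total, best_f.mismatch_positions) != (
            fwd_start, k_f, fwd_pos,
        ):
            continue
        if (best_r.start, best_r.mismatch_total, best_r.mismatch_positions) != (
            rev_start, k_r, rev_pos,
        ):
            continue
        # Amplicon recovery (what in_silico_pcr sees).
        amp = in_silico_pcr(template, primer_set, max_mismatch=max(k_f, k_r))
        if not amp or amp.inter_primer_length != insert_len:
            continue

        template.ledger = {
            "fwd_primer": fwd_primer.name,
            "fwd_mismatches": k_f,
            "fwd_positions": fwd_pos,
            "fwd_three_prime": best_f.three_prime_mismatches,
            "fwd_start": fwd_start,
            "rev_mismatches": k_r,
            "rev_positions": rev_pos,
            "rev_three_prime": best_r.three_prime_mismatches,
            "rev_start": rev_start,
            "insert_length": insert_len,
        }
        return template
    raise GenerationError(
        f"could not realize spec for cluster {spec.cluster!r} "
        f"(fwd={k_f}, rev={k_r}) after {MAX_REDRAWS} redraws"
    )


def make_dataset(
    specs: list[PlantSpec], primer_set: PrimerSet
) -> tuple[list[TargetSequence], pd.DataFrame]:
    """Generate a full synthetic dataset plus its generator ledger.

    Deterministic given the specs' seeds: each spec drives its own random
    stream.  Returns the sequences (cluster-annotated, ledgered) and a tidy
    ledger table with one row per sequence.
    """
    if not specs:
        raise ValueError("make_dataset: no specs given")
    sequences: list[TargetSequence] = []
    rows = []
    for si, spec in enumerate(specs):
        rng = np.random.default_rng(spec.seed)
        for i in range(spec.n_sequences):
            seq_id = f"{spec.gene}_{spec.cluster}_s{si}_{i:04d}"
            t = make_template(spec, primer_set, rng, seq_id)
            sequences.append(t)
            rows.append({"id": t.id, "cluster": t.cluster, "gene": t.gene, **t.ledger})
    ledger = pd.DataFrame(rows)
    return sequences, ledger


# ---------------------------------------------------------------------------
# Presets
#
# Scenario presets emulate the two waterworks communities; database-like
# presets emulate broad reference-database snapshots.  Counts are
# order-of-magnitude stand-ins (the real per-cluster database counts live in
# a supplement this package does not ship) and are scalable.
#
# Planted profiles, per gene:
# * amoA, Cluster 6A: forward and reverse mismatches drawn so the primer-set
#   total spans 2-4 (every sequence >= 2, forward slightly heavier) — one
#   quarter each of (1,1), (2,1), (2,1), (2,2).
# * amoA, other clusters: half perfectly matched, half with one mismatch per
#   primer, so the per-set mean sits at ~1.
# * 16S, scenario presets: three quarters perfectly matched, one quarter with
#   a single forward mismatch (the forward mixture is the slightly weaker
#   primer); the per-primer rounded mean is 0, treating the 16S assay as the
#   accurate reference it empirically was.
# * 16S, database-like preset: per cluster, 8% of records carry two forward
#   mismatches and 2% two reverse mismatches, so pooled coverage at <=1
#   mismatch lands at 92% (forward) and 98% (reverse).
# ---------------------------------------------------------------------------

PRESETS = ("islevbro-like", "langerod-like", "rdp-16s-like", "fungene-amoa-like")

_DB_CLUSTERS = ("6A", "7", "0", "other-AOB")


def _quarters_6a(gene: str, n: int, seed: int) -> list[PlantSpec]:
    """Cluster 6A amoA profile: per-set mismatch total spans 2-4 (mean 3)."""
    q = max(n // 4, 1)
    combos = [(1, 1), (2, 1), (2, 1), (2, 2)]
    return [
        PlantSpec("6A", gene, q, (f, f), (r, r), seed=seed + j)
        for j, (f, r) in enumerate(combos)
    ]


def _half_matched(cluster: str, gene: str, n: int, seed: int) -> list[PlantSpec]:
    h = max(n // 2, 1)
    return [
        PlantSpec(cluster, gene, h, (0, 0), (0, 0), seed=seed),
        PlantSpec(cluster, gene, h, (1, 1), (1, 1), seed=seed + 1),
    ]


def _site_16s(cluster: str, n: int, seed: int) -> list[PlantSpec]:
    q = max(n // 4, 1)
    return [
        PlantSpec(cluster, "16S", 3 * q, (0, 0), (0, 0), seed=seed),
        PlantSpec(cluster, "16S", q, (1, 1), (0, 0), seed=seed + 1),
    ]


def _db_16s(cluster: str, n: int, seed: int) -> list[PlantSpec]:
    # per 50 records: 46 with <=1 forward mismatch, 4 with 2; 49 with <=1
    # reverse mismatch, 1 with 2.
    u = max(n // 50, 1)
    return [
        PlantSpec(cluster, "16S", 45 * u, (0, 1), (0, 1), seed=seed),
        PlantSpec(cluster, "16S", 4 * u, (2, 2), (0, 1), seed=seed + 1),
        PlantSpec(cluster, "16S", u, (0, 1), (2, 2), seed=seed + 2),
    ]


def preset_specs(
    preset: str, gene: str, base_seed: int = 0, scale: int = 1
) -> list[PlantSpec]:
    """PlantSpec lists for the packaged presets, per gene.

    ``scale`` multiplies every batch size; ``base_seed`` offsets every spec
    seed, so distinct seeds give distinct (but internally deterministic)
    datasets.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    s = base_seed

    if preset == "rdp-16s-like":
        if gene != "16S":
            raise ValueError("rdp-16s-like is a 16S preset")
        specs: list[PlantSpec] = []
        for i, cl in enumerate(_DB_CLUSTERS):
            specs += _db_16s(cl, 50 * scale, s + 10 * i)
        return specs

    if preset == "fungene-amoa-like":
        if gene != "amoA":
            raise ValueError("fungene-amoa-like is an amoA preset")
        specs = _quarters_6a("amoA", 48 * scale, s)
        specs += _half_matched("7", "amoA", 48 * scale, s + 10)
        specs += _half_matched("0", "amoA", 48 * scale, s + 20)
        return specs

    if preset == "islevbro-like":
        # Cluster 6A strongly dominant, Cluster 7 absent, minor
        # Nitrosospira-type ("0") fraction.
        if gene == "16S":
            return _site_16s("6A", 48 * scale, s) + _site_16s("0", 8 * scale, s + 10)
        return _quarters_6a("amoA", 48 * scale, s) + _half_matched(
            "0", "amoA", 8 * scale, s + 10
        )

    # langerod-like: Clusters 6A and 7 co-dominant.
    if gene == "16S":
        return _site_16s("6A", 24 * scale, s) + _site_16s("7", 24 * scale, s + 10)
    return _quarters_6a("amoA", 24 * scale, s) + _half_matched(
        "7", "amoA", 24 * scale, s + 10
    )


#: Clone-library sizes used by the scenario presets (clones actually
#: sequenced in the motivating surveys: 82/77 for 16S, 43/92 for amoA).
PRESET_LIBRARY_SIZES = {
    "islevbro-like": {"16S": 82, "amoA": 43},
    "langerod-like": {"16S": 77, "amoA": 92},
}


def make_community(preset, copies_per_cell: dict[str, int] | None = None) -> CommunityProfile:
    """Community profiles for the scenario presets (cells per g sample).

    ``islevbro-like``: 3e8 cells/g, all Cluster 6A, Cluster 7 absent (the
    strong-6A-dominance case).  ``langerod-like``: 3e6 cells/g, Clusters 6A
    and 7 co-dominant (50/50).  A dict of per-cluster cells passes through
    as a custom profile.
    """
    kwargs = {"copies_per_cell": copies_per_cell} if copies_per_cell else {}
    if isinstance(preset, dict):
        return CommunityProfile(cells=dict(preset), **kwargs)
    if preset == "islevbro-like":
        return CommunityProfile(cells={"6A": 3.0e8, "7": 0.0}, **kwargs)
    if preset == "langerod-like":
        return CommunityProfile(cells={"6A": 1.5e6, "7": 1.5e6}, **kwargs)
    raise ValueError(f"unknown community preset {preset!r}")
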