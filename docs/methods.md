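# Methods

## Degenerate-primer matching

A primer is a mixture of concrete oligos: each IUPAC letter denotes a set of
bases and a template position matches iff the template base is a member of
the primer letter's set. Degeneracy on the primer side is therefore "free"
(the mixture physically contains an oligo for every expansion), while any
template letter outside the primer letter's set — including template
ambiguity codes such as N — counts as a mismatch. Under this convention the
positional mismatch count equals the minimum Hamming distance over the full
expansion, which the engine computes directly without enumeration; the test
suite verifies the equivalence against a brute-force expansion oracle.

Binding-site search is exhaustive over all windows of primer length on the
requested strand (minus-strand windows are read as their reverse
complement), with deterministic tie-breaking: smallest mismatch total, then
5′-most plus-strand start, then declaration order of forward-mixture
members. Matching is purely positional — no melting temperature, duplex
thermodynamics or secondary structure — because the analysis this package
supports is mismatch-count based. The last 3 bases of each primer form the
3′-critical window; 3′ mismatches are reported and fed to the efficiency
model but never veto a match.

In silico PCR takes the best forward-mixture site on the plus strand, then
the best reverse-primer site on the minus strand located entirely 3′ of the
forward footprint, and returns the product iff both sites pass the mismatch
cutoff and the total length falls within the primer set's configured bounds.
Both length conventions are reported: `total_length` (both primer
footprints included; the convention of published product sizes, 116 bp for
CTO189–RT1r and 491 bp for amoA-1F/2R) and `inter_primer_length` (bases
strictly between the footprints, 75 and 452 respectively). Sequences whose
best priming window contains more than 5% non-ACGT letters, or no window
within the scan cutoff (default 6 mismatches), are tallied as "region
unavailable" and excluded from that primer's coverage histogram, so coverage
is computed only over sequences whose priming region is actually observable.

## Packaged primer sets

The two assay definitions ship as explicit configuration, transcribed from
the publications that introduced them:

| primer | sequence (5′→3′) | role |
|---|---|---|
| CTO189fA/B | `GGAGRAAAGCAGGGGATCG` | 16S forward (2 oligos) |
| CTO189fC | `GGAGGAAAGTAGGGGATCG` | 16S forward |
| RT1r | `CGTCCTCTCAGACCARCTACTG` | 16S reverse |
| amoA-1F | `GGGGTTTCTACTGGTGGT` | amoA forward |
| amoA-2R | `CCCCTCKGSAAAGCCTTCTTC` | amoA reverse |

Internal consistency check: 75 inter-primer bases + 19 + 22 primer bases =
the published 116 bp product of the 16S assay. The loader refuses a missing
or malformed primer YAML; the packaged set is only used on explicit opt-in
(`builtin`), so a disputed transcription can always be overridden.

## Coverage tables

Per (cluster, primer) cell: the mismatch histogram over best binding sites,
its mean, min/max, mean 3′-window count, and coverage fractions
(`fraction_at_most(m)`). The forward mixture is collapsed to the minimum
over members. A third, "set" cell tallies forward + reverse totals for
sequences where both regions are available — the primer-*set* mismatch load
used by the bias model. Pooled (count-weighted) and per-cluster-averaged
coverage fractions are both available, since the two poolings can differ
when cluster sizes are uneven.

Cluster labels (6A, 7, 0 = Nitrosospira-type, other-AOB, non-AOB) are input
annotations: assignment requires phylogenetic placement, which is out of
scope here. Clone-library summaries report per-cluster percentages at full
precision and the non-target share additionally rounded to the nearest
integer percent as the headline figure (5 non-AOB clones in a library of
82 → 6%).

## The amplification-bias model

Relative per-cycle efficiency of a template with `m` total and `t`
3′-window mismatches:

    eta(m, t) = rho^(m − t) · (rho · rho3)^t,   eta(0, 0) = 1.

A pool of `N` such templates amplified for `n_q` cycles yields signal
∝ `N (1 + e0·eta)^{n_q}`; read against a perfectly matched standard curve it
appears as

    N_apparent = N · ((1 + e0·eta) / (1 + e0))^{n_q}.

Apparent copies are summed over clusters (`cells × copies-per-cell ×
attenuation`) and converted to cells with a scalar per-gene copy number
(defaults: 16S = 1 rRNA operon; amoA = 2, the midpoint of the typical 1–3
*amo* operons; per-cluster overrides supported). The bias report is the
ratio of 16S- to amoA-based cell estimates, with per-cluster decomposition
and all parameters embedded; a zero denominator is reported as an infinite
ratio with a flag rather than an exception.

Clone libraries are multinomial draws with cluster weights
`cells × copies-per-cell × attenuation(eta, n_p)` where `n_p` (default 30)
is the number of pre-cloning end-point PCR cycles; one seeded generator per
call makes libraries reproducible.

### Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| `e0` | 0.95 | per-cycle efficiency, perfect template |
| `rho` | 0.92 | efficiency retention per internal mismatch |
| `rho3` | 0.1 | extra retention per 3′-window mismatch |
| `n_q` | 30 | cycles at quantification |
| `n_p` | 30 | pre-cloning PCR cycles |

No quantitative mismatch→efficiency mapping exists for these assays; the
functional form (geometric per-mismatch penalty, multiplicative 3′ factor)
and the defaults are this package's own calibration, chosen so that at 30
cycles 0–1 mismatches cost ≲3-fold apparent signal while 2–4 mismatches span
roughly one to two orders of magnitude (~10×, ~30×, ~87× at 2, 3, 4). That
places a 6A-dominated community's 16S/amoA ratio in the tens — consistent
with field observations of up to ~50-fold discrepancies — while leaving
well-matched clusters quantified within a few-fold. A 3′ mismatch is an
order of magnitude more damaging than an internal one (`rho·rho3 ≈ 0.09`),
reflecting the outsized effect of 3′-terminal mispairing on extension. All
parameters are config-exposed and reported in every output; the ratio's
qualitative conclusions (limits, monotonicity in `rho`, cluster fraction and
cycle number) hold for any admissible parameter values and are asserted as
property tests.

### From coverage to model inputs

Cluster-level mismatch inputs default to the per-primer rounded mean
(Python's round-half-to-even), forward and reverse summed; a `min` statistic
is available, and inputs can also be supplied directly. Three-prime counts
always use the rounded mean. The statistic used is recorded in every report.

## Synthetic data

Each template is `pad + forward site + insert + revcomp(reverse site) + pad`
with uniform-ACGT pads (20–60 nt) and insert. Priming sites start from a
random concrete expansion of a (randomly chosen) mixture member and receive
exactly the drawn number of substitutions at random non-repeating positions,
each to a base outside the primer letter's set. A candidate is rejected and
redrawn (up to 100 times, then a generation error signals an over-constrained
spec) unless the matching engine recovers exactly the planted picture —
same site starts, same mismatch counts *and positions*, same insert length —
both under whole-template scans and under in silico PCR. This reject-and-
redraw loop is what makes the generator ledger an exact oracle: coverage
tables on generated data must reproduce it bit-for-bit, and the test suite
asserts that at >500 sequences per preset. An optional bias steers planted
positions toward or away from the 3′ window for efficiency-model
experiments.

Default inserts are 75 nt (16S) and 452 nt (amoA), matching the two assays'
published product sizes. Generated sequences are random, not homologs of
real AOB genes — the analysis depends only on priming-region structure — so
passing tests demonstrate the pipeline's correctness on known mismatch
structure, not coverage of real databases; real sequences enter through the
standard FASTA + cluster-TSV inputs.

### Presets

Planted per-primer mismatch profiles, chosen to reproduce the qualitative
structure of the two assays' coverage:

* **amoA, Cluster 6A**: quarters of (fwd, rev) = (1,1), (2,1), (2,1), (2,2) —
  every sequence has 2–4 primer-set mismatches, forward slightly heavier,
  rounded-mean set load 3.
* **amoA, Clusters 7 and 0**: half perfect, half (1,1) — mean set load 1,
  rounded per-primer mean 0.
* **16S, scenario presets**: three quarters perfect, one quarter with a
  single forward mismatch — the 16S assay acts as the accurate reference.
* **16S, database-like preset** (`rdp-16s-like`): per cluster, 8% of records
  carry two forward mismatches and 2% two reverse mismatches, so pooled
  coverage at ≤1 mismatch is 92% (forward) and 98% (reverse).

Batch sizes (~50 per cluster at scale 1) are order-of-magnitude stand-ins
for database snapshots and scale linearly via the `scale` argument.

Community presets (cells per g sample, magnitudes within the empirically
observed 3×10⁶–3×10⁸ range): `islevbro-like` = 3×10⁸ cells, all Cluster 6A,
Cluster 7 absent (the strong-dominance case); `langerod-like` = 3×10⁶ cells,
6A and 7 at 50% each (co-dominance). Clone-library sizes follow the
motivating surveys (82/77 clones for 16S, 43/92 for amoA). With the default
calibration these yield a ~31-fold islevbro-like ratio, a ~1.9-fold
langerod-like ratio, and an expected langerod-like amoA library 6A share of
~3% against ~50% in the 16S library.

## Numerical and design notes

* Coordinates are 0-based, half-open, always on the template's plus strand.
* Ties everywhere resolve deterministically (see matching section); given
  identical seeds, datasets, libraries and report files are byte-identical,
  and every output file embeds the hash of its configuration.
* `simulate_qpcr` is exact arithmetic, no sampling; only clone-library
  simulation consumes randomness (one `numpy` generator per call).
* Degenerate inputs: empty sequence collections, gene/primer-set mismatches,
  missing cluster mismatch entries and non-positive copy numbers raise
  contract errors; an all-zero clone-library weight vector is an error
  rather than a silent uniform draw.
* Test problem sizes: the ledger-recovery suite uses ~500–600 sequences per
  preset and the scenario suite 200 library seeds — large enough for the
  binomial checks' 3-standard-error bands, small enough to keep the full
  suite under a minute.

## Limitations

* Cluster assignment is an input; no phylogenetic placement is performed.
* The efficiency model is deterministic and positional: no primer-dimer,
  inhibitor, chemistry or stochastic early-cycle effects, and no
  thermodynamic weighting of mismatch identity or position beyond the 3′
  window.
* The 16S/amoA ratio is a model illustration of how mismatch load of a
  dominant cluster propagates to quantification; its magnitude tracks the
  calibration above and should not be read as a prediction for any specific
  primer–template pair without assay-specific efficiency data.
* Archaeal ammonia oxidizers, TaqMan probes, and qPCR standard-curve
  calibration are out of scope.
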