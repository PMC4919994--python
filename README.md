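# primerscope

In silico coverage, specificity and quantification-bias analysis for
degenerate qPCR primer sets targeting ammonia-oxidizing bacteria (AOB).

## The problem

AOB abundance in environmental samples — e.g. the rapid sand filters of
drinking-water treatment plants, where AOB remove ammonium — is routinely
estimated by qPCR with one of two marker genes: the phylogenetic 16S rRNA
gene (primer mixture CTO189a/b/c with reverse primer RT1r) or the functional
gene *amoA* (primer pair amoA-1F / amoA-2R). The two assays can disagree by
more than an order of magnitude on the *same* DNA extract. primerscope
implements the computational side of diagnosing that disagreement:

1. **IUPAC-aware in silico PCR** — locate the best binding site of each
   (possibly degenerate) primer on every target sequence and extract the
   predicted product. A primer letter matches a template base iff the base
   is in the letter's IUPAC set, so the positional mismatch count equals the
   minimum Hamming distance over the primer mixture's full expansion.
2. **Per-cluster coverage tables** — mismatch histograms per *Nitrosomonas*
   cluster (6A = *N. oligotropha* lineage, 7 = *N. europaea/eutropha*
   lineage, Nitrosospira-type "0", …) for forward, reverse, and the
   primer-set total, plus clone-library composition summaries with
   non-target (false-positive) accounting.
3. **An amplification-bias model** — a template with `m` total and `t`
   3′-window mismatches amplifies at relative efficiency
   `η = ρ^(m−t) · (ρ·ρ₃)^t`, and after `n_q` cycles appears, against a
   perfectly matched standard curve, attenuated by
   `((1 + e₀η) / (1 + e₀))^{n_q}`. Apparent copies are converted to cells
   with per-cell gene copy numbers (one rRNA operon; typically 1–3 *amo*
   operons), and the headline statistic is the ratio of 16S- to amoA-based
   cell estimates. Clone libraries are drawn multinomially with the same
   amplification weighting.
4. **A planted-mismatch sequence generator** — synthetic target sets whose
   per-cluster mismatch profiles are known exactly (and provably recovered
   by the matching engine), so the entire pipeline runs and is testable
   without any sequence download. Real sequences drop in via FASTA plus a
   two-column cluster TSV.

With the default calibration, 0–1 primer-set mismatches cost ≲3-fold signal,
while the 2–4 mismatches characteristic of Cluster 6A *amoA* templates cost
one to two orders of magnitude — enough to make the *amoA* assay
underestimate a 6A-dominated community ~30-fold while both assays agree on a
6A/7 co-dominated one.

## Worked example

```python
from primerscope import (CommunityProfile, EfficiencyModel, bias_report,
                         relative_efficiency, signal_attenuation, simulate_qpcr)

model = EfficiencyModel()                    # e0=0.95, rho=0.92, rho3=0.1, n_q=30
community = CommunityProfile(cells={"6A": 3.0e8})   # cells per g sand
est16 = simulate_qpcr(community, {"6A": (0, 0)}, model, "16S")
esta  = simulate_qpcr(community, {"6A": (3, 0)}, model, "amoA")
print(bias_report(est16, esta).ratio)
```

prints `30.65...`: a community of 3×10⁸ AOB cells/g whose 16S priming sites
are perfect but whose *amoA* sites carry 3 primer-set mismatches yields a
16S estimate of 3×10⁸ cells/g and an *amoA* estimate of 9.8×10⁶ cells/g
(after dividing its 2×10⁷ apparent copies by 2 *amo* operons per cell) — a
~30-fold underestimate by the functional-gene assay.

The `examples/` scripts walk through each capability (in silico PCR,
coverage tables, the bias model, and the end-to-end scenario contrast);
`examples/04_waterworks_scenarios.py` shows the full pipeline output for a
6A-dominated and a 6A/7 co-dominated community, including the simulated
clone libraries in which Cluster 6A drops below 5% of *amoA* clones under
co-dominance even though quantification stays consistent (ratio < 3).

## Command line

```bash
primerscope synth    --preset langerod-like --gene amoA --seed 1 --out data/
primerscope pcr      --fasta data/sequences.fasta --primers builtin \
                     --primer-set amoA1F-2R --max-mismatch 4 --out pcr.tsv
primerscope coverage --fasta data/sequences.fasta --clusters data/clusters.tsv \
                     --primers builtin --primer-set amoA1F-2R --out cov.tsv
primerscope simulate --community comm.yaml --coverage cov16.tsv --coverage cov.tsv \
                     --seed 1 --out bias.json
primerscope report   --preset islevbro-like --seed 1 --out report/
```

Primer definitions are configuration (`--primers primers.yaml`); the
`builtin` keyword opts into the packaged transcriptions of the two AOB
assays. Exit codes: 0 success, 2 config error, 3 format error, 4 generation
error.

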