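# Methods

## The analysis model

`cnvburden` treats a case-control CNV screen as a sequence of carrier-level
2×2 comparisons. The unit of analysis is the *individual*, not the deletion
event: for every predicate (any qualifying deletion; a deletion touching a
protein-coding gene, a brain-expressed gene, a hotspot critical region, or
a gene of a curated set), a subject is a carrier if at least one of their
retained deletions satisfies it. Denominators are the full cohort sizes,
including subjects with no calls. This matches how such screens are
reported (cohort-sized denominators) and makes results insensitive to a
minority of subjects carrying two or more deletions.

### QC filter

A deletion enters the analysis set iff all gates pass:

| gate       | rule                                   | boundary  |
|------------|----------------------------------------|-----------|
| state      | copy-number loss only                  | —         |
| size       | ≥ 400 kb                               | inclusive |
| probes     | ≥ 200 array probes                     | inclusive |
| frequency  | cohort carrier frequency < 1%          | strict    |
| artifact   | ≤ 10% of the call inside artifact regions | strict rejection above 10% |

Before call-level filtering, samples with more than 50 autosomal deletions
(counting deletions > 40 kb with > 20 probes) are excluded outright —
hypervariable call profiles indicate degraded DNA or array failure, and
their cohort membership would otherwise bias carrier counts.

The frequency gate needs a notion of "the same variant in different
people". Two calls are linked when their reciprocal overlap is ≥ 50% in
both directions, clusters are single-linkage connected components, and a
cluster's frequency is its number of distinct carriers divided by the
total sample count. This is the community-standard recurrence rule for
array CNVs; both the 50% threshold and the interpretation of the 10%
artifact overlap (fraction of the *call*, not of the artifact region) are
configurable, since published screens rarely state either precisely.

Filter gates are a conjunction, so the retained set is order-independent;
the rejection tally attributes each removed call to the first failing gate
in the fixed order state → size → probes → frequency → artifact. The filter
is idempotent, and loosening any single threshold can only grow the
retained set (both properties are tested).

### Spectrum classification

Retained case deletions are partitioned, in precedence order:

1. **hotspot_recurrent** — the call covers ≥ 50% of a rearrangement-hotspot
   critical region. Recurrent NAHR-mediated deletions span the whole
   region, so requiring half of the *region* (not of the call) avoids
   labelling incidental edge overlaps; the threshold is configurable. Among
   several qualifying hotspots the greatest covered fraction wins, ties
   resolving to genomic order.
2. **shared_nonhotspot** — ≥ 1 bp overlap with any retained control
   deletion. A reciprocal-overlap rule is available but ≥ 1 bp is the
   default reading of "overlaps the deletions found in controls".
3. **case_only_genic** — overlaps ≥ 1 protein-coding gene
   (largest-transcript span, ≥ 1 bp — the most inclusive reading of
   "encompassing a gene").
4. **case_only_nongenic** — none of the above.

### Statistics

- Pearson χ² (df = 1) **without** continuity correction. The uncorrected
  statistic is what published burden tables report; the Yates-corrected
  version does not reproduce them.
- Fisher's exact test when any expected cell < 5 (Cochran's rule), two
  sided by the probability-summation convention (all fixed-margin tables
  with hypergeometric probability ≤ the observed one); the tail-doubling
  rule is available behind a flag. The accompanying odds ratio is the
  conditional MLE.
- Odds ratios are cross-products with Woolf log-interval CIs. With a zero
  cell the point estimate is 0/∞ and the CI falls back to the exact
  conditional interval, giving the customary one-sided bound. Both the
  cross-product and conditional-MLE estimators are exposed because they
  differ visibly for sparse tables (11.54 vs 11.48-style discrepancies) and
  published tables do not always say which was used.
- Attributable risk is the difference of carrier percentages. The headline
  value rounds each percentage to one decimal first — that is how quoted
  values derive from printed tables — and the raw difference is returned
  alongside.
- Deletion sizes are compared with a two-sided Wilcoxon-Mann-Whitney test:
  exact enumeration when both groups have n ≤ 20, tie-corrected normal
  approximation otherwise, with medians and IQRs reported.

### Gene sets

Analysis sets (neurodevelopmental, ASD-related) are consumed as symbol
lists; unresolvable symbols are reported, never silently dropped. Matched
control sets guard against generic genic burden: they are drawn uniformly
without replacement from the annotation after removing the analysis sets
and all genes overlapping hotspot or artifact regions (non-brain control
sets additionally restrict the pool to genes not flagged brain-expressed).
The sampling seed is mandatory. The hotspot-excluded variant removes every
gene overlapped by an *observed* hotspot-class deletion in either cohort —
not the static hotspot regions — and drops hotspot carriers from both
cohorts before re-testing, isolating the signal that is not explained by
the recurrent deletions.

Term overrepresentation of the deleted-gene list uses the hypergeometric
upper tail against a configurable background (default: the annotation
size) with Benjamini-Hochberg adjustment; a term is reported significant at
adjusted p < 5% when the overlap has more than two genes and, if a control
gene list is analysed in parallel, the term is not significant there.
Rank-based enrichment scores of web tools are deliberately out of scope;
the FDR gate is the decision rule implemented.

### Network connectivity

The direct-connectivity statistic is the number of PPI edges with both
endpoints in the seed-gene set. The null distribution relabels seed status
among network nodes *within degree bins* — permuted seed sets have the
observed degree profile, so hub genes cannot manufacture significance.
Bins hold nodes of equal degree, pooled upward to a minimum of 10 nodes
(configurable); isolated nodes are left out of the shuffle entirely, which
both saves work and makes results invariant to adding disconnected nodes.
The estimator p = (1 + #{perm ≥ obs})/(n_perm + 1) is never zero and is
exact-valid under the within-bin exchangeable null. Per-gene significance
compares each seed's count of seed neighbours to the same permutations.

Caveat: in a small sparse graph, seeds that are also the unique
highest-degree nodes (e.g. a planted clique) can occupy a degree bin of
their own, making within-bin relabelling powerless; coarser bins
(`min_bin_size` ≳ 50) restore power at the cost of looser degree matching.
Indirect (common-neighbour) connectivity is out of scope.

## The synthetic generator

The generator emulates the study conditions of a genome-wide microdeletion
screen on a SNP 6.0-class array:

- cohort sizes default to 1,366 cases / 5,234 controls;
- seven hotspot loci at their hg19 critical regions with per-cohort
  carrier rates equal to the observed carrier counts over those cohort
  sizes (e.g. 13/1,366 vs 14/5,234 at 15q11.2);
- two risk gene sets sized proportionally to the annotation (1,547 and
  1,669 out of 18,299 genes at full scale) with planted carrier odds
  ratios 4.6 and 4.1 and the observed control carrier rates;
- deletion sizes log-normal with median 650 kb (between the reported case
  and control medians of 713 and 589 kb), σ = 0.55;
- probe counts Poisson with 0.6 probes/kb, the array's approximate
  marker density;
- benign common polymorphisms at 5% frequency (3 fixed loci), plus
  sub-400 kb, low-probe, artifact-region and duplication decoys.

The effect model is carrier-probability based: a category with control
carrier rate r and planted odds ratio OR gives cases carrier probability
r·OR/(1 − r + r·OR), so the expected carrier table has exactly that odds
ratio. Each sample carries at most one deletion per category plus an
optional background draw, so double-carriers occur. Breakpoint mechanics,
probe intensities and calling error profiles are *not* simulated —
passing tests demonstrate correctness of the carrier-level pipeline on
well-formed calls, not robustness to caller artefacts beyond the planted
decoy classes.

Two truth-alignment choices keep the ground truth and the filter from
disagreeing by chance: probe counts of planted qualifying deletions are
drawn from a Poisson truncated at the 200-probe floor, and qualifying
deletions are re-placed if they would overlap artifact regions. Every
planted call is recorded in a truth table with its category and expected
filter outcome; the test suite checks the retained set equals the
qualifying truth set exactly.

Determinism: the annotation and cohort streams derive from separate
children of the master seed, so identical parameters reproduce all output
files byte-identically; replicate cohorts against a fixed annotation use an
explicit cohort seed.

## Problem sizes in the validation experiments

The heavy experiments run at the full cohort scale (1,366/5,234) but on a
reduced synthetic annotation of 600 genes — carrier-level statistics
depend on carrier rates, not on how many genes tile the genome. The
recovery experiment uses 200 replicates of three planted odds ratios
(1.9/4.1/7.5, 60-gene sets, 1% control carrier rate), checking pooled
Woolf-CI coverage; the null experiment uses 400 replicates at OR 1 with a
3% carrier rate, checking type-I error at α = 0.05; network calibration
uses 500 random-seed replicates (400-node graph, mean degree 20, 60
seeds, 199 permutations) against a KS uniformity test, and a planted
12-gene clique at 999 permutations. Exact-test oracle equivalence is
verified exhaustively for all tables with total ≤ 30 and on seeded random
tables up to total 200.

## Known limitations

- The frequency filter's recurrence clustering is a design decision;
  screens that computed frequency per exact call will differ at loci with
  heterogeneous breakpoints near the 1% boundary.
- Woolf CIs undercover slightly for sparse tables; the exact conditional
  interval is used for zero cells but not otherwise.
- The Fisher/χ² selection rule (expected < 5) is a convention; both tests
  are always computable via the API.
- Covariate adjustment (ancestry, sex, batch) and multiple-testing
  correction across burden rows are out of scope; reported p-values are
  nominal and two-sided.
- X/Y chromosomes are excluded by design throughout.
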