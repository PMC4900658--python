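# Methods

Statistical models, default parameters, and numerical choices behind
`panelqc`. Everything here is implemented in the package; no empirical
claim is made that the package cannot recompute.

## Genotype representation

Calls are diploid, biallelic, and coded by minor-allele dosage:
`0` homozygous major, `1` heterogeneous (non-homozygous; in inbred
material usually residual non-fixation or pooled-tissue mixture),
`2` homozygous minor, `-1` missing. A matrix is *canonical* when each
marker's major allele is the more frequent one in that matrix (ties broken
alphabetically); readers canonicalize on load, and the simulator emits
canonical matrices. Round-trip identity through the three file formats is
guaranteed for canonical matrices; a non-canonical matrix re-reads as its
canonical equivalent (same genotypes, reoriented coding).

## Marker statistics

For a marker with major-allele count `n_A` and minor count `n_a` over
non-missing calls (homozygotes contribute two copies, heterogeneous calls
one of each):

- `maf = n_a / (n_A + n_a)`, undefined (NaN) for all-missing markers.
- `het_rate` = heterogeneous calls / non-missing calls;
  `missing_rate` = missing calls / all entries. The denominators differ
  deliberately: heterogeneity is a property of successful calls,
  missingness of the assay.
- `PIC = 1 − (p² + q²) − 2p²q²` (biallelic form; maximum 0.375 at
  `p = 0.5`).
- Mutation classes pair complementary substitutions:
  `AG_TC` (transitions), `AC_TG`, `AT_CG`.
- LD `r² = D² / (p_A q_A p_B q_B)` treats jointly homozygous entries as
  haplotypes; heterogeneous calls are excluded, and markers monomorphic in
  the usable set raise an error rather than returning 0/0.

## Identity metrics

Per locus, two calls sharing `s ∈ {0, 1, 2}` alleles are at distance
`2 − s`; the allele-sharing distance averages over jointly non-missing
loci (range 0–2). Similarity is exactly `1 − d/2`. Pairs with **no**
jointly non-missing locus are *undefined* (NaN), never 0: reporting
distance 0 for a pair the data cannot compare would be a false identity
claim. Tree building refuses undefined pairs and asks for an expanded
marker set.

Trees use complete-linkage agglomeration (SciPy) exported as Newick, with
branch lengths as parent-minus-child merge heights and children ordered by
smallest leaf label so output is label-order invariant. Ordination is
classical PCoA (scikit-bio, exact `eigh` solver); negative eigenvalue mass
inside the requested axes is flagged, not silently dropped.

## Marker filtering

`FilterThresholds` screens on missing rate, MAF, heterogeneity, coverage
range, and map placement. Presets:

| preset | max_missing | min_maf | max_het | coverage | placed |
|---|---|---|---|---|---|
| `INITIAL_SCREEN` | 0.40 | 0.05 | 0.10 | — | no |
| `STRINGENT_QC` | 0.20 | — | 0.06 | [2, 15] | yes |

Thresholds are inclusive (a marker *at* the bound survives). Removed
markers carry the list of rules they failed.

## Panel selection

**Grouping.** Markers are observations, entries variables; missing calls
are mean-imputed per marker, PCA reduces to `n_components` (default 3)
axes, and K-means (default `k = 5`, ≥ 10 restarts, seeded) clusters them.
A group's *distance score* (for PGD allocation) is its centroid's mean
distance to the other centroids.

**Allocation.** Marker quotas per group follow largest-remainder
apportionment of the target size with per-group caps and a minimum of one
where feasible; weights are equal (`NG`), group-size proportional (`PG`),
or distance-score proportional (`PGD`), with `RANDOM` ignoring groups.

**Uniform genomic spread.** Chromosome quotas are length-proportional
(largest remainder); each chromosome is cut into equal-width bins and the
marker nearest each bin midpoint is taken; empty bins forfeit their slot.
Chromosome lengths default to the maximum observed position, overridable
via a `chrom_lengths` mapping; unplaced markers (chromosome `"0"`) are
rejected.

**Evaluation and optimization.** A panel's score is the proportion of
unordered entry pairs with zero jointly non-missing differing panel
markers (*undistinguished*); pairs with no overlap at all count as
undistinguished — the conservative reading for QC. Pair mismatch counts
are computed by one-hot matrix products, so replicated optimization stays
vectorized. The optimizer draws `reps` random subsets (deduplicated),
always containing the mandatory markers, and ranks by
`(undistinguished proportion ↑, min pairwise mismatches ↓→ negated,
mean mismatches ↓→ negated, draw order)`. Rapid panels are optimized over
the broad panel's markers only, so nestedness holds by construction;
mandatory (e.g. trait-diagnostic) markers default to none.

**Trait scan.** Case/control allele counts form a 2×2 table tested by the
Pearson chi-square with 1 df and *no* continuity correction,
`n(ad − bc)² / (r₁r₂c₁c₂)`; pooled-monomorphic markers score (0, 1). The
best marker minimizes p, ties broken by larger statistic, then order.

## Assignment and purity

`IdentityClassifier.assign` reorients query markers to the reference
coding, computes similarity on the panel, and returns the best-matching
reference with verdicts: `MATCH` (best = declared), `MISLABELED`
(best ≠ declared), `AMBIGUOUS` (top-two similarities within `1e-9`).
References with no usable overlap are dropped with a warning; queries with
no usable calls raise. The purity census compares each sampled individual
with the entry's reference profile on the panel; an individual exceeding
`mismatch_tolerance` (default 1) differing calls is an off-type, unusable
individuals (no overlap) are excluded and reported, and the entry passes
when off-types ≤ `threshold` (default 2).

## Sampling statistics

Detection power is `1 − (1 − p)ⁿ`, computed as `−expm1(n·log1p(−p))` for
accuracy at small `p`. The required sample size is
`ceil(log1p(−target)/log1p(−p))` with an explicit ±1 verification loop
against floating-point edge cases. Note the conventional one-decimal
display of `1 − 0.99³⁸⁴ = 0.97892` as "97.8%" truncates rather than
rounds; `panelqc power` prints the rounded `0.979`.

The posterior upper limit on the off-type proportion after `k` off-types
in `n` is the `credibility` quantile of Beta(`k + a`, `n − k + b`). The
default prior is Jeffreys, `(a, b) = (½, ½)`; with `method="quantile"`
the bound is the one-sided `c` quantile, with `method="central"` the upper
end of the central interval (the `(1 + c)/2` quantile). Both prior and
method are exposed because tabulated bounds in the field vary in exactly
these two conventions; e.g. `k = 2, n = 192` gives 2.5% only under
particular prior/interval choices, while `k = 1, n = 192` robustly rounds
to 2% under Jeffreys.

## Simulator

`simulate_reference_panel` draws, per marker, a global minor-allele
frequency `0.05 + 0.45·Beta(1.2, 3.0)` (a low-MAF-heavy spectrum, mean
realized MAF ≈ 0.16, typical of sequencing-based SNP discovery in inbred
panels); each of `n_groups` groups perturbs it uniformly within
`±divergence` (clipped to [0.01, 0.99]); lines are assigned to groups
round-robin and drawn homozygous from their group frequency; residual
heterogeneity (default 5%) and missingness (default 18%) are overlaid
independently, so the surviving heterogeneous fraction is
`het·(1 − missing)`. Read depth is Gamma(shape 1.6, mean 7) per marker.
Positions are uniform without replacement over ten maize-scale
chromosomes with length-proportional marker quotas; mutation classes are
drawn with probabilities (0.607, 0.195, 0.198). Every planted fact is
returned in a `GroundTruth` record, and identical configs and seeds are
bit-identical.

**Regenerations** copy a parent line per generation; each marker drifts
with probability `drift_rate` — a homozygote flips to the opposite
homozygote (so one generation at rate ε has expected similarity `1 − ε`
to its parent at fully homozygous loci), a heterogeneous call resolves to
a random homozygote. `purify=True` additionally fixes each residual
heterogeneous call with probability ½ per generation, halving
heterogeneity in expectation. **Off-type injection** replaces each
individual independently with probability `rate` by a contaminant profile
and applies explicit label swaps; injecting an entry's own profile as its
contaminant warns, since such off-types are undetectable by construction.
**Trait introgression** fixes carriers homozygous minor (everyone else
homozygous major) at the chosen markers, making them perfectly concordant
with the binary trait.

### Simulator scope and limitations

The simulator is a test harness, not a population-genetic model: no
linkage or recombination map (markers drift independently), no pedigree
beyond single-parent regeneration chains, no allele-frequency evolution
across generations, no genotyping-error model separate from missingness,
and contaminants are whole-profile replacements rather than segregants or
outcross products. Group structure is symmetric by construction
(round-robin assignment, equal divergence), so it cannot represent nested
or admixed population structure. Conclusions about real germplasm should
rest on real data; the simulator's role is planted-truth verification of
the analysis machinery.

## Numerical and reproducibility choices

- All stochastic procedures take explicit seeds; CLI commands without a
  `--seed` draw one, print it to stderr, and record it in output metadata.
- Tabular outputs begin with `#`-prefixed metadata: package version,
  resolved seed, input paths with SHA-256 checksum prefixes.
- Similarity/distance arithmetic uses exact complements
  (`similarity = 1 − d/2` holds to equality, not tolerance).
- Quantities that are undefined (all-missing marker MAF, zero-overlap
  pair distance) are NaN or errors, never silently 0.
- Problem-size defaults (broad panel ≈ 80, rapid ≈ 10, census gate of 2
  off-types at tolerance 1, sample sizes 48–384) are package defaults
  chosen to match common QC practice for inbred collections; all are
  parameters, not constants.
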