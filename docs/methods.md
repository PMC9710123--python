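# Methods

## Model and procedure

`teenrich` estimates, per TE family/subfamily, whether a ChIP-seq sample
carries more read-mapping mass at that family's copies than expected from
the input control, using three components.

**Ambiguity-weighted counting.** Every read `r` carries all `N_r` genomic
mappings the aligner reported and its length `L_r`. Its i-th mapping
overlapping TE copy `k` by `l` reference bases adds `l/(N_r·L_r)` to the
copy's family. Each read therefore distributes exactly one unit of mass over
the genome (a read whose mappings all lie inside a family's copies
contributes exactly 1 to it, regardless of `N_r`), and a family's count
`C_K` is a real-valued number of read-equivalents. Overlap uses the
mapping's reference extent (CIGAR walk), so soft-clipped bases never
contribute, while `L_r` stays the full read length. Copies are merged
within a family beforehand, so no base is double-counted within a family;
bases shared by copies of two different families count toward both, which
is what the per-family sum implies.

**Input-conditioned background.** The input control's per-base coverage,
with every mapping weighted `1/N_r`, is normalised per chromosome into
`p_n = cov_n/cov_c`; chromosomes are weighted `w_c ∝ cov_c`, making
genome-wide draw frequencies proportional to `cov_n`. Zero-coverage bases
(outside the "effective genome") have probability exactly zero. A simulated
read is produced by drawing a position, drawing one of the input reads
covering it with probability `p_r = 1/(cov_n·N_r)` (these sum to 1 at any
effective position), and translating *all* of that read's mappings so the
selected mapping is centred on the drawn position. Re-centring symmetrises
the simulation; mappings pushed over a chromosome end are truncated, and
mappings pushed entirely out are dropped with `N_r` recomputed. The chain
"position, then read" is algebraically identical to drawing one
(mapping-segment, offset) cell with weight `1/N_r`: the implementation uses
that joint form, fully vectorised, and the test suite verifies the
equivalence empirically (total-variation distance of the joint empirical
distribution against `p_n·p_r` on a small model).

**Empirical testing.** `N` simulated libraries (default 100) of exactly the
sample's size are drawn and counted identically to the sample. The
P-value is `|{b : C_K^(b) ≥ C_K^sample}|/N` — ties count against the
sample, `p = 0` is printed as `<1/N` — and the Fold-Change is
`C_K^sample / mean_b C_K^(b)`. Families with `p < α` (default 0.01) are
flagged enriched. No multiple-testing correction and no library-size
normalisation are applied; since counts are real-valued, exact ties are
essentially impossible and the p-values are valid (slightly conservative)
by exchangeability.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `N` (`--iterations`) | 100 | simulated input libraries; sets the p-value floor 1/N. 10 already gives usable fold-changes; 100 supports the p<0.01 rule. |
| `alpha` | 0.01 | enrichment call threshold on the empirical p-value. |
| `min_copies` | 50 (CLI) | smallest merged copy number for a family to be reported; small families give unstable fold-changes (few background hits). |
| `level` | `name` | counting unit: rmsk `repName` (subfamily) or `repFamily` (family). |
| `downsample` | 20,000,000 | read cap for very deep libraries (applied uniformly at the read level, mappings kept intact). |
| `window`/`step`/`percentile` | 100 / 50 / 99.997 | artifact detection: mapping counts per sliding window, thresholded per chromosome *and* genome-wide over non-zero windows. |

## Numerical and design choices

* Coordinates are 0-based half-open throughout; "immediately adjacent"
  copies merge at zero gap (`end_i == start_j`).
* The percentile threshold uses linear interpolation between order
  statistics (numpy's default); a window is masked only if *strictly* above
  both its chromosome's and the genome's threshold (the conservative
  reading; `mode="either"` switches to the union rule).
* The centre of a mapping of span `s` is `start + (s−1)//2`
  (left-of-centre for even spans), fixed for determinism.
* Per-base coverage is accumulated by a difference-array cumulative sum; an
  integer overlap count restores exact zeros where the float running sum
  leaves ~1e-15 residue, preserving the "zero coverage ⇒ zero probability"
  contract.
* A region mask is applied at *mapping granularity*: any mapping overlapping
  the mask is removed whole from both the sample and the input before
  modelling and counting, emptied reads are dropped and `N_r` recomputed,
  and the simulated library size equals the post-mask sample size. This
  keeps the read mass removed from the sample and the coverage mass removed
  from the background proportional, which is exactly the condition under
  which masking an artifact shared by both libraries leaves the fold-changes
  of unrelated families unchanged. (Coverage-level masking with
  renormalisation is also exposed via `build_probability_model(cov, mask)`.)
* Zero background mean: FC is 1 when the sample count is also 0, and an
  infinite sentinel flagged "unstable" otherwise.
* Iteration `i` of the simulation uses RNG seed `seed + i` only, so
  iterations can run in any order (or in parallel) with identical results;
  reports are byte-deterministic given (inputs, seed, N).
* Fold-change expectations: reads partially overlapping copy edges are not
  enriched by a planted/true signal, and enriched mass renormalises the
  rest of the library, so a fold-`e` enrichment over copies of length `c`
  with reads of length `L` and interior mass fraction `m` is recovered at
  roughly `(e·(c−L) + L)/c / (1 + (e−1)·m)` — e.g. ≈2.7–2.8 for a 3× pull
  at kilobase-scale copies. This is a property of the estimand, not a bias.
* Coverage vectors are dense per chromosome: memory is ~8 bytes/base, the
  intended regime being fixture-to-tens-of-Mb genomes; a sparse backend
  would be needed for mammalian-scale chromosomes in constrained memory.

## The synthetic-data generator

`fixtures` builds genomes with planted TE copies, annotations, and
read-mapping libraries with *known* multimapping structure: copies of a
family with zero divergence are exact duplicates, and a read drawn from the
interior of one of `m` identical copies carries the `m` homologous mappings
(`N_r = m`). Per-copy point substitutions at a configurable rate break
homology locally — a read overlapping a divergent site maps only to its
origin copy — emulating the fact that copies of real families are often not
identical. Input-control bias is emulated by per-family density multipliers
(`region_weights`); ChIP signal by per-family enrichment folds applied on
top; artifact regions by a few thousand stacked unimapper reads spread over
a ~200 bp locus (wider than one detection window, as real satellite hot
regions are — a locus fully contained in two overlapping windows ties them
at the top, which a strictly-greater threshold cannot flag). Ground-truth
per-read origins are recorded so tests can compare recovered counts against
planted mass exactly.

What the generator does **not** emulate: sequencing errors and base
qualities, GC and mappability biases, fragment-length distributions,
paired-end layouts, and divergence patterns of real repeat phylogenies.
Passing tests therefore demonstrate the estimator's statistical behaviour
(formula correctness, sampler fidelity, null calibration, signal recovery,
masking neutrality) under controlled ambiguity, not performance on any
particular real dataset.

In the validation studies the planted-signal fixture uses one LINE-sized
target family (6 × 2.5 kb) among SINE-sized bystanders: a credible pull-down
target carries appreciable read mass, and because empirical p-values reach
`p = 0` with probability `1/(N+1)` per family under the null, a specificity
check across many bystander families is only informative when the target's
mass visibly deflates the bystanders' sample shares. Problem sizes
throughout the suite (genomes of 40–300 kb, libraries of 600–30,000 reads,
100 simulations, 15–200 repeated runs) were chosen as the smallest at which
the binomial/Monte-Carlo error of each checked statistic is comfortably
inside its assertion band.

## Known limitations

* Single-ended reads only; paired-end data must be collapsed upstream.
* The background model conditions on the *realised* input library: with
  shallow inputs, fold-change noise is dominated by input sampling error.
* Simulated background counts track the input's counts up to an edge effect
  of order `L/c` at copy boundaries (re-centred reads smooth coverage by
  half a read length), typically a few percent.
* Enrichment is reported per family/subfamily, never per individual copy —
  individual-copy attribution of multimapper mass is not identifiable.
* The artifact filter derives its mask from the data; it does not use
  published blacklists, and the 99.997th percentile was designed for
  genomes with compact satellite hot spots.
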