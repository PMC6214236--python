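# Methods

## Model and procedure

`hierphase` phases heterozygous, bi-allelic SNPs in a diploid sample from
short-read data. The pipeline:

1. **Fragment extraction.** Each read pair becomes one fragment: a sparse
   string over the variant sites with `0` for the reference allele, `1`
   for the alternate, and `-` for anything else (third base, base below
   the quality threshold, deletion, or no coverage). Mates sharing a name
   are merged; if they disagree at a shared site, that site becomes `-`
   (the observation is unreliable and the method has no quality model to
   arbitrate). Fragments calling fewer than two sites carry no phase
   information and are dropped.
2. **Block construction.** Two sites are connected when a fragment calls
   both; connectivity is transitive, and each connected component is a
   variant block — an isolated phasing problem. Sites with no informative
   coverage are reported as unphaseable singletons.
3. **Pair scoring.** Every directly observed pair gets a confidence score
   (below) for each of the two pairings allowed under the heterozygous
   assumption (both sites stay heterozygous, so mating haplotype 1 of one
   site with haplotype 1 or 2 of the other exhausts the options).
4. **Hierarchical assembly.** Starting from one cluster per site, the
   assembler repeatedly merges the two clusters joined by the best
   remaining observed pair; single linkage makes the pair ranking static,
   so a lazy priority queue gives exact selection. An n-site block takes
   exactly n−1 merges.
5. **Local MEC fallback.** Certain merges are decided by a two-candidate
   minimum-error-correction vote instead of the score (triggers below).

## The confidence score

For a pair with N informative reads split as n1/n2 (the two expected
haplotype cells of the candidate pairing) and n3 (the other two cells):

    MS = log2[ C(N,n1) C(N-n1,n2) P1^n1 P2^n2 P3^n3 ]
    F  = log2[ C(N,N/2) C(N,N/2) P1^(N/2) P2^(N/2) ]
    NS = MS - F
    c  = N / (largest pair N in the block),  sigmoid(c) = 1/(1+e^-(c-0.5))
    CS = log2(sigmoid(c)) + NS

Defaults: `P1 = P2 = 0.49`, `P3 = 1 - P1 - P2 = 0.02`. P3 prices an
unexpected read at `log2(0.02/0.49) ≈ -4.6` bits, which is what makes the
score robust: a candidate explaining most reads as errors is crushed
regardless of how balanced its two cells look.

Numerical choices and their consequences:

* All combinatorics run through log-gamma, so `C(N, N/2)` is well defined
  for odd N and no factorial overflows occur. MS of an impossible outcome
  (some `P_i = 0` with `n_i > 0`) is −∞, a returned sentinel rather than
  an exception.
* The product form `sigmoid(c) × NS` is undefined as a log argument for
  negative NS, so the coverage weight enters additively in log space
  (`CS = log2(sigmoid(c)) + NS`), which keeps the documented range
  (−∞, 0].
* F deliberately contains `C(N,N/2)` twice. The factor therefore exceeds
  the balanced-case MS by `log2 C(N,N/2)`, and NS at a perfectly balanced
  table is `-log2 C(N,N/2)` — slightly *decreasing* in N. The practical
  effect is that among clean balanced pairs, shallower pairs rank first;
  the sigmoid term (bounded within ≈ 0.73 bits) does not reverse this.
  Error-bearing pairs still rank far below clean ones at any depth. The
  alternative single-`C` normalization (NS = 0 at balance) was considered
  and rejected to keep the printed formula.
* Pair classification: a *singleton* pair has all N reads in one cell
  (only one haplotype observed); a *low-coverage* pair has N below the
  block median of pair depths (median with the usual even-count mean
  convention; strictly below counts as low). Both are "ambiguous" and are
  deferred behind normal pairs during assembly, singletons before
  low-coverage pairs — a singleton's one observed cell is usually genuine
  cis information even though its score is extremely low.
* Merge selection order: pair class, then CS (higher first), then genomic
  distance (closer first — nearer variants are more reliable), then
  leftmost site index for determinism.

## Local MEC vote

A merge of clusters X and Y has only two outcomes; the vote recruits the
overlapping fragments, charges each the minimum mismatches against either
haplotype of a candidate, and takes the cheaper candidate. Triggers:

* **Embedded merging:** the position-sorted union of X and Y alternates
  clusters at ≥ `min_junctions` boundaries (default 3). Scope: fragments
  touching both clusters.
* **Ambiguous lead with ≥ 2 junctions:** scope widens to every fragment of
  the block (restricted to X ∪ Y it is the only part that can differ).
* **Exact CS tie** between the two candidate joins.

Penalty ties go to the cis candidate and flag the merge low-confidence; an
empty recruitment scope falls back to the score-led choice, flagged. An
exhaustive MEC solver (`brute_force_mec`, 2^(n−1) enumeration, n ≤ 16)
exists purely as a test oracle and is not reachable from the phasing path.

## Evaluation metrics

Prediction and truth are compared at the sites both phased, anchoring the
prediction to whichever truth haplotype matches at the first common site
(this makes every metric invariant to global complement of either input).
The disagreement pattern is decomposed into **switch** errors (template
changes at a boundary) and **flip** errors (single mis-phased sites) by
dynamic programming that minimizes the total number of events; among
equal-cost decompositions the one with fewer flips is taken, so two
adjacent mis-phased sites count as two switches while an isolated site is
one flip (two adjacent template toggles collapse). The *phasing error
rate* is pooled errors over pooled phased decisions (a block of n phased
sites contributes n−1 decisions); the *perfect ratio* is the fraction of
blocks with zero errors. *QAN50* splits each block at its switch errors,
weights each sub-block's phased span (bp) by its phased-variant
proportion, and takes the N50 of the weighted spans (descending cumulative
sum reaching half the total). The *EC rate* is the minimum number of
fragment-character corrections implied by a solution divided by all
fragment characters at its sites.

## Synthetic data generator

The simulator emulates paired-end sequencing over simulated variant
blocks directly at the fragment level. Per block: variant positions are
uniform without replacement over a span of 80 bp per variant (matching the
density of the study region this design mirrors, ~8,800 variants in
720 kb); truth haplotype 1 is uniform over {0,1} per site. Read pairs are
2 × 250 bp with insert length Normal(850, 50); the pair count is set so
that mean base depth equals the configured coverage (grid 20/30/40). Each
pair originates from haplotype 1 with probability `skew` (0.5 balanced
down to 0.1 = 10/90) and each covered site is corrupted with probability
`seq_error` (grid 0.002/0.01/0.03) — by default flipped to the opposite
allele, the worst case for phasing; optionally dropped to `-`.
The full condition grid (3 coverages × 3 error rates × 5 skews) yields the
45 study conditions; per-run seeds derive from one master seed.

What the generator does **not** emulate: read mapping. There are no
mismapped or chimeric fragments, no reference bias, and no soft-clipping,
so absolute error rates sit well below what the same conditions produce
through an aligner-based pipeline, and the extreme-skew degradation is
much milder — with clean fragments even a 3× minority coverage leaves the
multinomial score a clear margin. Passing simulation tests therefore
demonstrate the algorithm's behaviour under sampling noise and sequencing
error, not its robustness to alignment artifacts. Trend tests on the
grid use pooled rates over ≥ 25 replicates with a scaled block roster
(one or two blocks per size class of 30/50/100/200/500) and treat a
decrease between adjacent error levels as a failure only when
statistically significant (one-sided Fisher exact, α = 0.01), since the
underlying rates are small enough for single stray errors to invert the
ordering.

## Defaults that matter

| parameter | default | meaning |
| --- | --- | --- |
| `p1`, `p2` | 0.49 | likelihood of each haplotype cell |
| `p3` | 0.02 | likelihood of an unexpected (error) read |
| `min_junctions` | 3 | embedded-merge threshold for the local MEC vote |
| low-coverage threshold | block median pair depth | ambiguous-pair cutoff |
| `min_mapq`, `min_baseq` | 0 | no read filtering during block discovery |
| read geometry | 2×250 bp, insert 850±50 | simulator sequencing model |

## Known limitations

* Only heterozygous bi-allelic SNPs are phased; indels, multi-allelic
  sites, and polyploid genomes are out of scope.
* The score is count-based; base qualities do not weight the likelihoods.
* The mate-conflict rule (`-` at disagreeing shared sites) discards rather
  than arbitrates information.
* `brute_force_mec` is exponential and intentionally capped at 16 sites.
* The simulator's lack of mapping noise means absolute accuracy numbers
  from it should not be read as predictions for aligner-based data.
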