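# Methods

This note documents the models and procedures implemented in
`archminer`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic test data
does and does not show about real data.

## Hit retention

A per-domain hit survives filtering iff

* conditional E-value < `evalue_max` **and** independent E-value <
  `evalue_max` (both strict; default 0.01), and
* expected per-residue alignment accuracy ≥ `acc_min` (inclusive;
  default 0.6).

Both E-values are checked because either one alone can be optimistic:
the conditional E-value assumes the sequence is a true target, the
independent one does not. The asymmetric strictness (strict `<` on
E-values, inclusive `≥` on accuracy) is deliberate and pinned by tests;
users changing thresholds should keep it in mind at exact boundaries.

## Most-likely domain architecture

Two hits on the same protein *conflict* when the number of residues
their spans share is at least `overlap_threshold` (default 0.4,
inclusive) of the shorter span. Spans are envelope coordinates
(`env_from..env_to`, 1-based inclusive) by default: the envelope is the
search engine's estimate of the full region a domain occupies, which is
the right quantity for deciding whether two domain placements compete
for the same residues. `FilterParams(overlap_on="ali")` switches to
alignment coordinates for users who prefer the narrower spans.

Each hit scores `max(0, −log10(i-Evalue))`; when the E-value underflows
to exactly 0 the bit score is substituted, since the logarithm cannot be
computed. The clamp at zero keeps every retained hit's contribution
non-negative, so maximizing total score never prefers *dropping* a valid
weak hit — without it, custom thresholds above 1 would make the optimum
depend on sign artifacts. Base 10 is a convention; any logarithm base
rescales all scores by one constant and leaves the selected subset
unchanged except where bit scores are mixed in (a property test pins
this). Mixed scoring (−log10 E alongside bit scores within one protein)
is possible when only some hits underflow; it is accepted as defined
rather than papered over.

The most-likely architecture is the exact maximum-total-score subset of
pairwise non-conflicting hits. Because the 40%-of-the-shorter rule makes
conflict non-transitive, the problem is maximum-weight independent set
on a general conflict graph, not interval scheduling; a
branch-and-bound over hits in (env_from, env_to, name) order with a
suffix-sum bound solves it exactly (pruning only strictly worse
branches, so score ties are still explored). Per-protein hit counts are
small in practice, and the solver is verified against exhaustive subset
enumeration on 500 random instances. Ties are broken deterministically:
more domains first, then the lexicographically smallest sequence of
(env_from, domain name). Totals are summed in that same canonical order
so reported scores are bit-reproducible.

## Family rules

A rule has a name, an optional comment, a mandatory domain list and an
optional forbidden list. A protein matches when its most-likely
architecture (not its full hit list) contains every mandatory domain,
none of the forbidden ones, and — where a mandatory entry carries an
E-value ceiling — at least one hit of that domain has independent
E-value strictly below the ceiling. Scoping the forbidden check to the
architecture is intentional: a rejected overlapping hit elsewhere in the
protein should not veto a family call; `forbidden_scope` is exposed for
users who want the stricter variant. Listing the same mandatory name
k times requires k distinct hits, which is how multi-module rules are
expressed. A protein may match several rules; all matches are reported
in rule-file order, and the shipped example rules file separates
families with forbidden lists instead of relying on precedence.

Per-domain ceilings apply to the independent E-value, consistent with
the score source.

## Profile enrichment

One iteration: build a profile from the current seeds → search the
dataset → keep hits passing retention → for each newly matching
sequence, feed back the *matched envelope region* (profiles model
domains; merging whole proteins would dilute the alignment with
unrelated flanking sequence) → merge with the current seeds → cluster
at `identity_threshold` (default 0.90) and keep one representative per
cluster → count.

Convergence: a count difference of exactly 0 stops immediately. A
counter increments whenever the difference is negative or equal to
`counter_increment_diff` (default 1), and reaching `counter_limit`
(default 3) also stops. The counter never resets after a larger jump —
its purpose is to cut short long tails of nearly-stalled iterations, and
a reset would prolong exactly the runs it exists to shorten. A
`max_iterations` valve (default 50) guarantees termination on
pathological inputs and is reported as non-convergence, never success.

Identity is computed on a global pairwise alignment (match +1, mismatch
−1, gap −2, linear) as identical pairs over alignment columns, excluding
terminal-gap columns so a domain contained in a longer sequence is
judged on the aligned core. Clustering is greedy centroid: records in
decreasing length order (ties by id) join the first centroid they match
at ≥ threshold or found a new cluster. Greedy clustering under a
non-transitive similarity cannot guarantee that no two centroids are
within the threshold of each other; the guarantee it does give — every
input is a centroid or within threshold of one — is what the tests
assert.

## Search backends

**hmmer** (default): profile HMMs through pyhmmer, i.e. the actual
HMMER3 implementation in-process. The seed alignment comes from the
package's center-star progressive aligner (center = seed with maximal
summed pairwise score; pairwise alignments merged under
once-a-gap-always-a-gap); profile construction and search then follow
the standard hmmbuild/hmmsearch path, and the per-domain output table is
ingested by the package's own reader.

**builtin**: a position-specific scoring matrix with empirical
E-values, fully self-contained and deterministic. The seed MSA (same
center-star aligner) is reduced to columns with ≤ 50% gaps — a crude
match-column selection that avoids modeling insert states — and each
column's log-odds in bits derive from frequencies with pseudocounts,
`f = (count + 0.1) / (depth + 2.0)`, against a uniform background of
1/20. Searching scores every length-L window of each target and keeps
the best window per sequence (single-domain assumption; multi-domain
fixtures come from the synthetic generator, not this backend). E-values
are empirical: with per-sequence maximum scores over `null_shuffles`
(default 200) residue-shuffled copies of each dataset sequence as the
null, `E = dataset_size × (1 + #{null ≥ score}) / (1 + #null)`. Note
the resolution floor: E cannot fall below roughly
`1/null_shuffles × 1`, so with fewer than ~100 shuffles no hit can pass
the default 0.01 cut — 200 is the smallest default with comfortable
margin. The accuracy proxy is the fraction of window positions with
positive column log-odds, a monotone stand-in for a posterior per-residue
accuracy that suffices to exercise the ≥ 0.6 filter. The builtin
backend reports values quantized at the output table's printed
precision (E-values to 3 significant figures, bit scores to 0.1,
accuracy to 0.01), so annotating from a written table is bit-identical
to annotating in-process.

## Synthetic data

The generator plants mutated copies of fixed per-domain consensus
sequences (pseudo-random, keyed by domain name) between random linkers,
emits matching per-domain hit tables directly from the ground truth
(true hits drawn log-uniform in E ∈ [1e-30, 1e-3], accuracy in
[0.7, 1.0]; spurious hits above the E cut; optional weaker competitors
overlapping ≥ 40% of each true span), and builds enrichment datasets
with members stratified across a divergence ladder (defaults 5%, 15%,
25% substitution) plus shuffled decoys. Default study sizes: 3 seeds,
20 members, 80 decoys for enrichment; 10 complete + 5 partial + 5
hybrid + 10 decoy proteins for classification; 500 random instances of
≤ 12 hits for the solver oracle; 100 fixtures for duplicate resolution.
These sizes make every check run comfortably on a laptop while keeping
the decision boundaries (E-value floor, identity threshold, overlap
threshold) genuinely exercised.

What this does *not* show: real proteomes have compositional bias,
repeats, true multi-domain and split-domain architectures, and homology
at divergences far beyond 25%; real profile quality depends on alignment
subtleties the center-star heuristic ignores. Passing the synthetic
suite demonstrates the engines' logic (filtering, resolution,
classification, convergence) is correct, not that profile sensitivity
matches a tuned HMMER workflow on biological data — for that, use the
hmmer backend on real inputs.

## Degenerate inputs and edge behavior

Empty hit lists resolve to an empty architecture with score 0; proteins
with no surviving hits are counted in the log but excluded from
results. Sequences shorter than the profile are skipped by the builtin
search. Alignment gap characters (`-`) are stripped on FASTA input;
other non-alphabet characters are rejected outright. Duplicate sequence
ids, duplicate profile names in a database, and hits referencing unknown
proteins are hard errors naming the offender. All coordinates are
1-based inclusive end-to-end; conversion happens nowhere.
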