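# Methods

This note documents the model behind `irfootprint`, the parameters that
matter, the synthetic data used to validate it, and the numerical and design
choices a maintainer should know about.

## The prediction model

The pipeline rests on three biological assumptions, applied in order:

1. **Operon assumption.** Adjacent genes sharing the regulator's strand are
   co-transcribed with it when the intergenic gap is small.  The operon is
   grown in both directions from the regulator while the neighbor shares the
   strand and the gap is at most `max_intergenic_gap` (default 100 bp — a
   typical upper bound for co-transcribed bacterial gene spacing; the
   underlying heuristic is stated only qualitatively in the literature, so
   the cap is configurable).
2. **Autoregulation assumption.** The operator sits in the promoter the
   regulator's operon shares with its upstream neighbor — the *inter-operon
   region*, bounded by the operon's 5′ edge and the nearest neighboring
   feature.  The canonical geometry is a divergently transcribed neighbor;
   a co-directional neighbor still yields a region but is flagged
   (`co-directional`) as lower confidence rather than rejected.  Regions
   are clamped to `max_region_len` = 800 bp measured back from the operon
   boundary (covers typical σ70 promoters without swallowing whole genes)
   and rejected below `min_region_len` = 20 bp (shorter than any plausible
   dimeric site).  Coordinates are 0-based half-open on the forward strand
   everywhere; GenBank's 1-based inclusive convention is converted at the
   parser boundary only.
3. **Conservation assumption.** Among homologs, the operator is conserved
   while flanking promoter sequence drifts, so stacking the seed's best hit
   from each homolog region concentrates signal at operator positions.

## Inverted-repeat score

For arms of length `a` at spacer `g`, position `k` of the left arm pairs
with position `a−1−k` of the right arm; a pair is a *match* when the bases
are reverse-complementary.  The score is

    s = w_m·x + w_y·y + p(g)

with defaults `w_m = +2`, `w_y = −2`, and the banded spacer adjustment
`p`: 0–4 → +4, 5–6 → +2, 7–8 → 0, 9–10 → −2, 11–12 → −4, 13–14 → −6,
15–16 → −8, 17–18 → −10.  Beyond 18 the default policy is to refuse the
spacer; an `extrapolate` policy continues the −2-per-2-bases progression.

A published form of this score assigns mismatches the same weight as
matches (`+2·y`).  Under that convention every equal-length arm pairing
scores identically, which contradicts the score's stated purpose (favoring
longer, better-paired repeats while tolerating imperfect ones), so the
package defaults to the penalized form and keeps the literal form behind
`RepeatScoreParams.literal_paper()` for comparison.

The scan enumerates arm lengths 4–20 and spacers 0–18 (the gap table's
domain; both configurable) at every offset.  Ties on `s` resolve
deterministically: longer arms, then smaller spacer, then leftmost start.
Arms admit substitutions but not indels; the "discontinuity" the score
tolerates is the spacer between half-sites.  `N` bases never match.  The
scan reports nothing when no candidate reaches the score floor (default
`2·min_arm`, a perfect minimum-length repeat with a zero-adjustment
spacer).  A deliberately naive exhaustive enumerator
(`enumerate_all_repeats`) serves as the test oracle; the vectorized scanner
is asserted equivalent to it, tie-break included, on a thousand random
sequences.

## Instance location and consensus

The seed is located in each homolog region by an ungapped sliding window on
both strands, scored with match +2 / mismatch −2.  Because extraction is
ungapped and at seed length, accepted instances are columns-aligned by
construction and the consensus is a well-defined 4×x count matrix — no MSA
is needed (an MSA refinement hook would slot in between location and
consensus if indel tolerance were ever added).  A hit is accepted at
`accept_frac` = 0.6 of the seed's self-alignment score, i.e. at least 80%
sequence identity to the seed; random 20-mers clear that bar in well under
5% of 200-bp regions (property-tested).  The query's own seed joins the
instance stack, and at least `min_instances` = 4 instances are required —
below that, the prediction is refused as `too-few-homologs` rather than
reported on thin evidence.  Dominant-base ties break A<C<G<T; `N` positions
are excluded from their column's counts.

Conservation is `c = (Σₒ bₒ²)/x` over the dominant-base frequencies `bₒ`.
Squaring makes `c` an identity-weighted mean (a column at frequency 1
contributes 1, a uniform column 1/16), so `c` discriminates sharply between
conserved cores and drifting flanks.  `c` is invariant under instance
reordering and under reverse-complementing all instances together.

Diagnostics partition every non-crash failure: `operator-not-in-region`
(no usable promoter-side sequence), `search-miss` (no repeat above the
floor), `too-few-homologs` (hit collection or instance location starved the
consensus).  Each maps to a distinct CLI exit code (3, 4, 5).

## Homolog acquisition

Backends are pluggable behind a three-method protocol (protein, context
record, homolog search).  The fixture backend reads a JSON archive and is
the only backend tests touch; the live NCBI adapter (stdlib urllib, retry
with exponential backoff) is a convenience whose payloads are meant to be
cached into the fixture schema, making every rerun offline and
bit-identical.  Hit filters default to identity ∈ [30, 95]% (drop
near-duplicate self-hits that add no information and remote noise that may
not share the operator), coverage ≥ 70%, 30 hits maximum — declared
defaults, all configurable, since no canonical cutoffs exist for this task.

## Operator comparison (benchmark harness)

Predicted and validated operators are aligned by Smith–Waterman
(Biopython's `PairwiseAligner`, `mode="local"`) with match +2, mismatch −3,
gap open 10, gap extend 0.5, over both strands.  Significance uses the
Karlin–Altschul formula `E = K·m·n·e^(−λS)` with search space `m·n` the
product of the two lengths.  λ is solved numerically (Brent's method) from
`Σ pᵢpⱼ e^(λ sᵢⱼ) = 1` at uniform base composition — λ ≈ 0.64 for the
default scheme.  `K` is a declared constant, 0.3, the typical order of
magnitude for ungapped DNA statistics; with gap costs this prohibitive the
optimal alignments are effectively ungapped, and the resulting null is
conservative (< 5% of random 20-mer pairs reach E < 0.01, Monte-Carlo
checked over 1,000 pairs).  E-values decrease monotonically in score at
fixed lengths, and the comparison is symmetric for equal-length inputs.

Large-scale literature benchmarks require live sequence databases and a
curated validated-operator dataset; the package ships the harness
(per-pair and per-family tables, missing predictions flagged rather than
dropped, fractions over zero compared pairs reported as NA) plus toy
fixtures, and treats the full-scale run as an online workflow.

## Synthetic regulons and what they do (not) show

`simfix` generates the statistical structure the algorithm assumes, with
ground truth: an ancestral contig (divergent neighbor ← 150 bp region →
regulator → co-directional downstream gene) carrying a perfect inverted
repeat (7-bp arms, 4-bp spacer, score 2·7+4 = 18) at a random offset, and
20 homolog contexts mutated per base at 0.05 within the operator versus
0.35 in background — a strong conservation contrast; homolog proteins
drift at 0.2 per residue (~80% identity, inside the default filter
window).  Substitutions only, so planted offsets stay exact.  Everything
derives from one integer seed; archives are byte-identical across runs.

Recovery is scored by best ungapped offset/strand registration of the
consensus against the planted operator, as the fraction of *planted*
positions matched — a consensus that correctly extends the operator into
flanking sequence (the scanner may absorb a fortuitously complementary
flank pair into longer arms) still counts as recovered.

At these defaults the pipeline recovers the planted operator (≥ 90%
identity) in roughly nine out of ten regulons.  The residual failures are
informative: occasionally the 150 bp random background contains a spurious
inverted repeat that outscores or tie-beats the planted one (a perfect
arm-7 repeat arises by chance in ~4% of such regions, and long imperfect
arms can score higher still); the spurious seed is not conserved across
homologs, instance location starves, and the run ends `too-few-homologs`.
This is the search-miss failure mode known from real operator prediction,
reproduced in miniature — not a defect of the scanner, which is provably
equivalent to exhaustive enumeration.  The inverted-rate negative control
(operator mutating at 0.5, background frozen) fails recovery as it must,
confirming that success comes from the conservation contrast and not from
the scan alone.

What the synthetic data does **not** emulate: phylogenetic correlation
among homologs (all are independent draws from the ancestor), indels,
compositional bias, operator loss or migration to non-orthologous
promoters, and multi-operator promoters.  Passing on simulations therefore
demonstrates correctness of the machinery under the model's assumptions,
not field accuracy on real genomes.

## Determinism and numerical notes

- All simulation randomness flows through `numpy.random.default_rng(seed)`;
  no global RNG state.  JSON is written with sorted keys; reports embed the
  full effective configuration and package version, and identical
  inputs/configs reproduce byte-identical archives and reports.
- Consensus frequency columns sum to 1 within 1e−9 (exact rational counts
  divided once).
- The scanner's iteration order (arm descending, spacer ascending, offset
  ascending) realizes the tie-break with a strictly-greater update — no
  explicit comparator needed, and `numpy.argmax`'s first-max convention
  supplies the leftmost rule within a scan row.
- Degenerate inputs: regions shorter than two minimum arms, all-homopolymer
  regions, empty hit lists, and absent context records all resolve to
  diagnostics or absence markers, never exceptions, on the pipeline path.

## Known limitations

- Direct repeats (tandem half-sites) are out of scope; only inverted
  repeats are scanned.
- No indel tolerance within arms or instances; a single insertion in a real
  operator's half-site would shift registration and depress its score.
- Only the promoter-side flank of the regulator's operon is searched; if
  the true operator lies on the other flank or in a non-adjacent promoter,
  the prediction fails with `operator-not-in-region` (upstream-only search
  keeps the autoregulation assumption explicit rather than diluting it).
- The Karlin–Altschul `K` is a declared constant, not computed from the
  full lattice theory; E-values are calibrated (conservative null) rather
  than exact.
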