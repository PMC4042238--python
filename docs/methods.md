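# Methods

## The normalized-rate model

The question is whether a non-coding region's substitution rate changed
at two events on the rodent lineage: a chromosomal inversion (which
predates the mouse–rat split but postdates the primate–rodent split) and
the birth of an antisense lncRNA gene pair (after the mouse–rat split,
on the mouse branch). Absolute rates are unidentifiable without a
calibrated clock, so the region is measured *relative to* concatenated
exons of four flanking genes, which are assumed to evolve at one rate
r_R across the whole tree. The test region carries three stage rates:
r0 before the inversion, r1 between the events, r2 after gene birth.

On the ultrametric tree (((mouse, rat), human), dog) with divergence
times t_MR < t_HR < t_HD, and timing fractions k1 (of t_HR, elapsed
since the inversion) and k2 (of t_MR, elapsed since gene birth), the
expected pairwise distances are path integrals of rate along the
connecting lineage paths:

- human–dog: the whole path predates both events, d = 2 r0 t_HD;
- human–rat: (1+k1) t_HR of the path at r0, (1−k1) t_HR at r1;
- mouse–rat: (1+k2) t_MR at r1, (1−k2) t_MR at r2.

Dividing by the reference distances 2 r_R t_XY gives the normalized
average rates; writing ρi = ri/r_R:

    r_averHD = ρ0
    r_averHR = [(1+k1) ρ0 + (1−k1) ρ1] / 2
    r_averMR = [(1+k2) ρ1 + (1−k2) ρ2] / 2

The divisor 2 is forced by the division (the reference path for a pair
has total length 2 t_XY); it is what makes r_averHR → r_averHD in the
k1 → 1 limit and makes all three ratios equal when the rates do not
change. An uncorrected variant without the divisor is retained behind
`printed_form=True` for comparison with analyses that used that form;
its HR/MR ratios are exactly twice the corrected ones, so qualitative
orderings among {HR, MR} are unaffected but comparisons against HD are
not meaningful in that form.

**Inference.** Only the ordering of stage rates is robustly identified:
r_averHR below r_averHD implies ρ1 < ρ0 (rate reduced after the
inversion), and a depressed r_averMR implies a reduced ρ2. The
"unchanged" verdict needs an explicit band: the default tolerance is 2%
relative, exposed as a parameter, because distance-ratio estimates at
realistic alignment lengths carry percent-level sampling noise (tests
that deliberately simulate no change use 5%, ≈3σ at 10⁵ sites). Because
the event times are only bracketed, `rate_ratio_scan` solves the model
exactly at every grid point of (k1, k2) ∈ (0,1)² (default step 0.05)
and reports feasible ranges of each ρ; the inversion is linear, so
forward-then-solve round-trips to machine precision, and ρ1 is monotone
in k1 with slope sign given by r_averHR − r_averHD.

Error propagation through the inversion is strongly asymmetric: at
k = 0.5, ρ2 = 4 r_averMR − 12 r_averHR + 9 ρ0, so distance noise is
amplified roughly ninefold into ρ2. Point estimates of ρ2 from a single
locus are therefore indicative only; the scan's interval summary is the
honest output.

## Distance estimation

Pairwise distances use pairwise deletion (a site is dropped for a pair
when either sequence has a gap or ambiguity) and closed-form corrections:
JC69, d = −(3/4) ln(1 − 4p/3), or K80 from transition/transversion
proportions. Divergences at or beyond the formula domains (p ≥ 3/4;
1−2P−Q ≤ 0 or 1−2Q ≤ 0) raise a saturation error naming the pair rather
than returning a number. The default model for real alignments is K80
(mammalian non-coding sequence is transition-biased); the simulation
studies use JC69 so estimator and generator share one model. Neighbor
joining is delegated to scikit-bio's Saitou–Nei implementation;
determinism is inherited from it, and topology checks in the tests use
the four-point condition as an independent oracle.

## Column curation

Manual removal of low-similarity sites is replaced by a deterministic
filter: gap-containing columns are dropped, then every column covered by
any sliding window (default 10 columns) whose mean pairwise identity
falls below a threshold (default 0.5) is removed, iterating to a fixed
point so the operation is idempotent; the per-column keep/drop mask is
retained for audit. The rule is deliberately conservative — a failing
window removes its good flanking columns too. On *simulated* alignments
the identity filter must be disabled (threshold 0): simulated divergence
is real signal, and at human–dog distances near one substitution per
site the filter would preferentially delete divergent columns and bias
every distance downward.

## The simulator

Sequences are gap-free (alignment is positional identity), with an
i.i.d. uniform root and JC69 evolution applied branchwise: a site
substitutes with probability 3/4 (1 − e^{−4L/3}) for branch path length
L and moves uniformly to one of the other three bases. Rate changes are
realized as events on the tree: the inversion on the rodent stem at time
(1−k1) t_HR before present (feasibility requires this to land on the
stem, i.e. k1 ≤ 1 − t_MR/t_HR), and gene birth on the mouse terminal
branch at (1−k2) t_MR. The mouse-only birth placement is the unique one
whose path integrals reproduce all three model equations exactly, and it
matches the biology (the gene is mouse-specific); a symmetric placement
splitting the post-birth segment across both rodent tips is available
but leaks an r2 segment into the human–rat path. Users who want other
conventions can simulate directly from per-branch expected path lengths.
A single integer seed drives one RNG through a fixed traversal order, so
output is bit-identical for identical inputs.

Default divergence times (0.05, 0.2, 0.25) are in arbitrary units with
plausible mammalian proportions (mouse–rat ≈ 1/4 of human–rodent); only
rate × time products matter. The study conditions for the rate-shift
experiment are r0=2, r1=1, r2=0.5, r_R=1, k1=k2=0.5, 10⁵ sites — a
doubling before the inversion and a halving after gene birth, large
enough to separate cleanly from noise at that length.

**Conserved-element stand-ins.** The two real curated conserved-element
alignments are not bundled (they come from a supplementary download), so
the pipeline is exercised on synthetic stand-ins: stage rates obtained
by inverting the model at the elements' reported normalized rates —
CE1 (inside the inversion): (2.5971, 2.0603, 1.406) at k1=k2=0.2, giving
ρ = (2.597, 1.255, 1.632); CE2 (outside): (1.6694, 2.1832, 1.5047) at
k1=k2=0.05, giving ρ = (1.669, 2.751, 0.127). The CE2 timing is forced:
its ratios admit positive stage rates only for k2 ≲ 0.06 under this
model. By construction the stand-ins reproduce the reported ratios in
expectation, so what the passing checks show is that the *pipeline*
(filtering, distance estimation, normalization, calling) preserves the
qualitative patterns — HD > HR > MR inside the inversion, HR > HD > MR
outside — not that the real alignments would yield those numbers under
every distance model.

What the simulations do not emulate: indels and alignment error,
context-dependent or transition-biased substitution, rate variation
across sites, and selection acting differentially within the region.
Passing tests demonstrate correctness of the estimators and algebra
under the generating model, not robustness to those violations.

## Region mapping

**Inversions.** For each query species a majority strand is computed
over its blocks, weighted by reference-anchored block length (ties to
'+'); maximal runs of minority-strand blocks, in reference order, are
reported as merged reference intervals when consecutive blocks are at
most 1 kb apart (configurable) — alignment chains fragment single
rearrangement events, so per-block reporting would overcount. Blocks are
sorted internally; input order does not matter.

**Feature coverage.** A feature counts as covered by a species when at
least half its length (configurable) intersects that species' blocks,
partial when less, absent at zero; it is flagged inverted when more than
half of the covering bases come from minority-strand blocks, so a
feature can be "partial + inverted".

**TE tables.** RepeatMasker `.out` records are parsed with classes
collapsed to SINE/LINE/DNA/LTR/Other; simple repeats and low-complexity
records can be excluded when restricting to ancient mobile elements.
The shared-element filter groups records by curated symbol (or repeat
name + locus) and keeps groups present in ≥ 2 species including mouse.
The bundled curated fixture encodes eleven such elements (A–K) plus two
single-species decoys; the composition table for the last exon of the
antisense gene is encoded behind a two-reading switch ("J" vs a second
"I") because the published composition is ambiguous between a distinct
PB1D10 element and a duplicated B1F listing.

**ORFs.** The scanner reports every AUG-initiated, stop-terminated frame
of at least `min_aa` amino acids (default 30), sense-strand by default
with a six-frame option, sorted longest first, plus the count of
sense-strand AUGs upstream of the longest ORF. Coordinates are half-open
on the forward strand, stop codon included in the span; length excludes
the stop. The transcript fixture is a synthetic stand-in (the real cDNA
is an accession download): 2.9 kb built from {A,C,T} outside three
planted AUGs, so its sense-strand ORF architecture is exactly the
planted one — two ~70 aa upstream frames, then a 105 aa longest ORF —
reproducing the diagnostic non-coding pattern, not the real sequence.

## Numerical and interface choices

- Coordinates 0-based half-open everywhere; MAF negative-strand source
  coordinates converted on input (start′ = srcSize − start − size).
- Interval overlap for TE/feature composition is any-overlap (≥ 1 bp,
  half-open), so boundary contact is not overlap.
- Grid values in the (k1, k2) scan are multiples of the step strictly
  inside (0, 1); solving at k = 1 is a division by zero and is rejected.
- Alignments are plain per-species strings (four species × ≤ 10⁵ sites;
  no need for compressed containers); audit artifacts (filter masks,
  concatenation offsets) ride in an alignment `meta` dict.
- Problem sizes in tests and the acceptance script (10⁵ sites, 20
  replicates, 50–100 randomized fixtures) were chosen to put sampling
  error well below the effect sizes under study while keeping any single
  check in the seconds range.

## Known limitations

- The reference-rate assumption (flanking exons clock-like across all
  four lineages) is untested within the package; violations alias into
  every ρ.
- No significance test accompanies the ordering call; the tolerance band
  is a reporting convention, not an error rate.
- K80 estimates on strongly diverged pairs can saturate; the package
  refuses rather than extrapolates, so very deep test regions may
  require the JC69 model or longer alignments.
- The inversion caller assumes a single reference chromosome chain per
  query and does not model nested or overlapping rearrangements.
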