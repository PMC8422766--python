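# Methods

## Distance definitions and numerical choices

Frequencies are n(m)/N per strand, read 5′→3′, with the window scan linear
(N = L − k + 1), not circular. When a sequence contains bases outside
{A,C,G,T} — hard-masked N, soft-masked lowercase in raw mode, or IUPAC
ambiguity codes (mapped to N on load) — every window touching such a base
is skipped and N becomes the number of valid windows. This keeps
frequencies summing to 1, distances in [0, 2], and masked-genome runs
well-defined; the alternative (keeping N = L − k + 1 as denominator) would
deflate every frequency on masked input. Skipped windows are tallied so
callers can reconcile window bookkeeping exactly.

k-mers are rank-encoded lexicographically in base 4 (A=0, C=1, G=2, T=3);
the reverse-complement rank is computed arithmetically and cached as a
permutation, so the strand-symmetrized vector f + f∘rc used by D2 is a
single permuted add. k is capped at 12 (the 4^k count table must stay in
memory); beyond the KL limit ≈ 0.7·ln L a warning is logged (once per
k/KL combination) but computation proceeds — the limit is where inversion
symmetry starts failing at the 10% level and sampling noise dominates, not
where the definitions break. The printed heuristic gives KL = 10 for a
4.6 Mb chromosome even though empirical practice for bacteria is k ≈ 7–8;
we implement the formula as printed and treat it as advisory only.

Two zero-distance identities are deliberately distinguished. D2(S, rc(S))
= 0 holds *identically* (the symmetrized vector is rc-invariant).
D1(S, rc(S)) = Σ|f(m) − f(rc(m))| is the inversion-symmetry deficit of S
itself: exactly zero only for exactly symmetric sequences (e.g.
S = W + rc(W), which is rc-invariant), small but positive for random or
real sequences. Tests assert the exact zero only where it truly holds.

Distance inequalities (D2 ≤ D1, triangle, monotonicity in k, the
inversion-immunity bound 4R(k−1)/N) are asserted with 1e-12 absolute
slack: the bounds can be saturated exactly, and float summation over 4^k
terms carries rounding at that scale. Monotonicity in k is conditioned on
every (k−1)- and k-mer being realized on both strands; tests enforce the
condition rather than assume it.

## Synteny proximities

Alignment input is the standard 12-column tabular format; orientation is
read off the subject coordinate order (s_start > s_end ⇒ inverse).
Identity filtering is strict (> 90 by default, configurable — the
threshold is arbitrary but guarantees near-identity). Coordinates are
1-based inclusive; covered length of [a, b] is b − a + 1. Block intervals
live on the query genome, and `run_aligner` makes the shorter genome the
query so coverage and the min(L1, L2) denominator refer to the same
sequence. Overlapping intervals are merged within each orientation class
by default (repeated HSPs would otherwise double-count; the raw-sum
behaviour remains available via `merge_overlaps=False`). Direct and
inverse unions may still overlap each other, so P_SYN ≤ 2 in general and
≤ 1 when they do not.

## Matched pairs and KDR

The matching interpretation: after dropping edges > 1, the greedy loop
removes both endpoint *chromosomes* of each selected minimal edge — a
greedy matching, so no chromosome is used twice and the distance vector is
non-decreasing. Edge-only removal (all sub-threshold edges in sorted
order) is available behind `remove_vertices=False`. Ties on the distance
value break lexicographically on (row_id, col_id) for determinism; the
median of an even-length vector is the mean of the two middle values. An
all-above-threshold matrix returns an explicit empty result rather than
raising. KDR divides the unmasked minimal D2 by the masked minimal D2 of
the same chromosome sets at the same k (default 8) and is undefined when
the masked minimum is zero.

## What the generator emulates — and what it does not

`synthetic_evolve` produces the two study designs the package analyzes:

* **Strain pairs**: an i.i.d. random ancestor (uniform composition by
  default) evolves by non-overlapping segmental inversions (each segment
  replaced by its reverse complement in place) followed by uniform point
  substitutions on descendant coordinates, so all ground-truth positions
  share one coordinate system. Ground-truth synteny blocks are the
  unchanged segments between breakpoints (direct) and the inverted
  intervals (inverse), with identity 100·(1 − substitutions/length),
  mirroring what an aligner would report.
* **Masked/unmasked contrasts**: two strains share an ancestral backbone
  and the positions of low-complexity tracts (homologous loci), but each
  strain draws independent tandem-repeat motifs (1–3 bp) per tract,
  emitted lowercase. Loading in masked mode removes exactly those tracts;
  unmasked mode keeps the fast-diverging repeat content.

Study conditions, chosen once at desk scale: the correlation cohort uses
20 pairs of 50 kb ancestors with substitution rates 0.01→0.18 and 1→6
inversions of 0.5–5 kb; the ladder deliberately crosses the 90% identity
threshold so proximities respond as well as distances (real strain pairs
sit at much lower divergence on multi-Mb chromosomes — the compression
trades realism of scale for a computable cohort). The KDR cohort uses 3
chromosomes × 30 kb per genome, 5 tracts of 0.4–1.6 kb per chromosome
(~17% of sequence) and background substitution rate 0.02, which keeps
same-ancestor unmasked distances below the matching threshold of 1 while
leaving a nonzero masked minimum.

What the generator does **not** emulate: realistic base composition and
codon structure, transition/transversion bias, indels, nested or
overlapping inversions (sampling is rejection-based and non-overlapping,
which keeps ground-truth blocks well-defined), horizontal transfer, and
genome-scale lengths. Passing tests therefore demonstrate correctness of
the definitions and the direction and strength of the qualitative signals
(negative distance–proximity correlation, KDR > 1), not quantitative
agreement with any real-genome values — which would require multi-Mb
reference downloads that are out of scope here.

## Degenerate inputs and tie-breaks

Zero valid windows (all-N after masking) is an error for frequency-based
operations, reported as such. Empty FASTA yields an empty list with a
warning; sequence before the first header is a parse error with line
number. Inversion/tract placement that cannot satisfy the non-overlap
constraint after bounded retries raises with advice rather than looping.
`random_genome` with a degenerate composition (e.g. all A) is allowed —
useful for worked examples.

## Known limitations

`run_aligner` shells out to blastn with `-outfmt 6` defaults; HSP
filtering beyond identity/length (e-value tuning, soft-masking flags) is
the caller's business. Spectra are dense int64 vectors — k = 12 costs
~134 MB each; there is no disk-backed counting or sketching by design.
The KL-limit formula is advisory and known to overestimate the practical
k for bacteria-sized chromosomes.
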