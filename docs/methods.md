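# Methods

This note records the model, the defaults and the design choices behind
`biss`, and what the synthetic benchmark does and does not demonstrate.

## Read model and seeding

Bisulfite chemistry is strictly one-way: an unmethylated C on the strand a
read derives from appears as T; methylated Cs stay C. For a directional
library (methylated adapters) each read is therefore tested exactly twice
against the forward reference: as-is with reference-C/read-T treated as a
match ("CT mode", Watson origin), and reverse-complemented with
reference-G/read-A as a match ("GA mode", Crick origin). A read C over a
reference T is always a mismatch; this asymmetry is what distinguishes the
approach from three-letter mapping, which collapses C and T on both sides
and discards the information carried by retained read Cs.

Seeding uses a hash of all genomic k-mers under a 2-bit packing
(A=00, C=01, G=10, T=11, leftmost base most significant). The asymmetric
look-up is realized at build time: each genomic k-mer's position list is
additionally keyed by every C→T substitution variant (2^(#C) keys, built by
XOR on the packed integer) for CT mode, and every G→A variant for GA mode.
A read k-mer then resolves with one probe. The alternative was to expand
the *read* k-mer at query time (T→C switches); that is mathematically
identical but exponential in the read's T count, and converted reads are
T-rich — index-side expansion is exponential only in the genomic C count,
which is small in an AT-rich genome (the expected blow-up per k-mer is
(1+gc/2)^k ≈ 7× at GC 0.36, k = 12).

Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| k | 12 | seed length; 4^12 key space keeps hash collisions trivial |
| t_exclusion | 8 | read k-mers with ≥ 8 Ts (CT) / As (GA) never seed; such seeds match half the genome in converted space. Variants that T-rich are also not stored (they could only be hit by an excluded query) |
| min_seeds | 2 | a candidate locus needs ≥ 2 seeds — a single shared k-mer is noise |
| offset_tol | 3 | seeds cluster when their diagonals differ by ≤ 3 nt, allowing small indels between read and genome |
| band_halfwidth | 4 | Smith–Waterman band of ± 4 diagonals around the seed cluster's median diagonal = offset_tol + 1 |

## Alignment and filtering

Local alignment uses match +4, mismatch −2 and a **linear** gap penalty of
−10 per gap column. No open/extend pair is used: with 56-bp reads and these
magnitudes a second consecutive gap column is almost never profitable, which
is consistent with the ±3 nt diagonal tolerance of the seeding stage. The
banded dynamic program is exact within the band and reduces to full
Smith–Waterman when the band covers the matrix (this equivalence is tested
against an independent full-matrix implementation).

A read is **unique** when exactly one alignment attains the maximal score
across all candidate regions and both modes; any tie (including across
modes, e.g. palindromic repeats) makes it ambiguous and it is discarded.
Unique reads must further pass a bisulfite-excluded identity of ≥ 0.85:
matches plus bisulfite-consistent columns over all aligned columns, gap
columns included in the denominator (the conservative reading — the
alternative, dropping bisulfite columns from the denominator, differs only
by that count). `N` never seeds and scores as a mismatch against everything.
Reads shorter than k+1 are reported unmapped.

## Pileup and calling

Watson and Crick cytosines are independent sites, keyed (contig, forward
position, strand); a CG dyad is two sites. Evidence is directional:
CT-mode alignments feed only Watson sites (read C → methylated count n_C,
read T → converted count n_T, anything else → n_other), GA-mode alignments
only Crick sites (G/A in forward projection). Coverage for testing is
n = n_C + n_T; other bases do not enter n but set the **adaptive error**
p_site = max(p₀, n_other / (n_C + n_T + n_other)), capped just below 1 —
a high non-C/T fraction flags mis-mapped reads, and inflating the error
rather than the coverage makes the test reject such sites. Duplicates are
not removed (no duplicate model exists for the data generated here).

Calling is pooled-then-refined:

1. **Pooled test.** Sites with pooled n < 2 are X. The rest get the exact
   one-sided upper tail P(X ≥ n_C), X ~ Binomial(n, p_site), BH-corrected
   over exactly the tested set; adjusted p < α = 0.05 ⇒ preliminary M.
2. **Per-run refinement.** Only the preliminary M list is re-examined.
   Within each run, the preliminary-M sites with run coverage ≥ 2 are
   re-tested with the run's own counts and adaptive error, BH-corrected
   within that run's re-tested set; adjusted p < α is a vote for M. A site
   stays M only under a strict majority of its testable runs (a 1–1 tie
   demotes); with zero testable runs the pooled decision stands.

The per-run BH scope was a genuinely open choice: correcting each run over
*all* its covered sites (≈ the genome's cytosine count of mostly-null
tests) swamps low-coverage true positives — measured on the standard
scenario it costs ~12 points of recall — whereas the refinement stage is
defined as a re-examination of the methylated list, so the correction is
applied within that list. Strict majority was kept for ties: "majority"
means more than half, and the conservative direction is the method's
stated character.

Sequence context (CG / CHG / CHH, H ∈ {A, C, T}) reads the two bases 3' of
the cytosine on its own strand; contexts running off a contig or through a
non-ACGT base are NA (NA sites are still called, but excluded from context
summaries). Coordinates are 0-based half-open everywhere internally and in
TSVs; SAM POS and bedGraph follow their own conventions at the boundary.

## Simulator

The generator emulates the study design the method targets: an i.i.d.
random genome at GC 0.36 (crucifer-like), methylation propensities by
context CG 0.24 / CHG 0.07 / CHH 0.02 (CG-dominated, as observed in plant
methylomes), partial methylation degrees θ ~ Beta(5, 1) at methylated sites
(right-skewed: most methylated sites are near-fully methylated across
molecules), 56-bp single-end reads in 3 runs with conversion rates
0.995 / 0.99 / 0.90 (one deliberately poor run, the situation the per-run
vote exists for), substitution sequencing error 0.005, strands sampled
evenly, 20× pooled theoretical coverage (read count = coverage × genome
length / (read length × runs)). Per covered cytosine the read shows C if
the molecule drew methylated (Bernoulli(θ)), else T with the run's
conversion rate; errors substitute uniformly afterwards. Reads never
overlap contig ends. Everything is deterministic given (config, seed).

What the simulator does **not** model: PCR duplicates, quality-score decay
along the read, indel sequencing errors (indel handling is exercised by
direct alignment tests instead), adapter read-through, genuine genomic
repeat structure (random genomes are nearly repeat-free, so the benchmark's
100% unique-mapping figure does not transfer to a repeat-rich genome), CG
dyad symmetry, or spatial autocorrelation of methylation. Passing the
benchmark therefore demonstrates correctness of the machinery and
calibration under the stated noise model, not real-data mapping rates.

## Benchmark scale and measured behaviour

The standard scenario (100 kb, 3 runs, ≈ 35,700 reads, 20×) runs the whole
pipeline in well under a minute and is the scale used by the acceptance
tests; it is large enough that the binomial machinery sees ~33,000 tested
sites. Measured there: mapping of error-free reads is 100% unique and
position-correct, and ≥ 99.9% position-correct with 0.5% errors; M-call
precision ≈ 0.997–0.999. Recall over determined sites is ≈ 0.90 in
expectation (5 seeds: 0.894–0.907): the dominant false-negative class is
true methylcytosines whose coverage splits 2–3 reads per run across exactly
two testable runs that then vote 1–1 and demote — the strict-majority rule
working as specified. Level RMSE against θ on well-covered M sites is
≈ 0.09–0.10, essentially the binomial sampling floor at ~20 reads. The
global-rate reports use both denominators (all cytosines, and classified
cytosines only) since both conventions appear in practice; the level
histogram's "what-if" rate re-counts every classified site with level above
a threshold (default 0.4) as methylated, quantifying the test's
conservatism.

## Numerical and degenerate-input choices

* Binomial tails are exact (`scipy.stats.binom.sf`), never
  normal-approximated; BH is `statsmodels`' step-up, verified against a
  from-scratch oracle.
* Alignment ties inside the DP prefer diagonal over vertical over
  horizontal moves; this affects only the reported path, never the score.
* Empty alignments (score 0) are legal and reported as unmapped.
* Zero-depth sites never reach the error estimator; the level is undefined
  (NA) at n = 0.
* The index refuses empty genomes, warns on contigs shorter than k, and
  silently skips k-mers overlapping non-ACGT characters.
* Congruency requires identical site universes; level correlation requires
  ≥ 2 shared defined sites.
* The window scan counts "C-content" as cytosines on both strands, i.e.
  (C+G)/length of the forward window — matching how sites are called.
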