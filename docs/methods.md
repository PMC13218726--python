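# Methods

## Scope and model

karyocourt decides, for each *breakpoint* between two chromosome-scale
assemblies of the same genome (a place where one assembly holds two
scaffolds where the other holds one), whether the split reflects a real
chromosome boundary or a repeat-driven assembly artifact, and derives
the consensus haploid chromosome count. The decision combines four
independent lines of evidence computed by separate modules:

1. **Trans Hi-C contact rates** (`hic_contacts`, `breakpoint_stats`).
   Deduplicated UU pairs are tallied in a single pass into per-scaffold-
   pair trans counts T_ij, within-scaffold counts I_i (separation
   strictly > 1 kb; shorter pairs are tallied separately so totals are
   conserved), and 500 kb trans-end density tracks. Rates are
   r_ij = T_ij / ((L_i/Mb)(L_j/Mb)). The empirical p of a breakpoint
   pair is the fraction of **all** scaffold-pair rates of its own
   assembly (zero-count pairs included, the pair itself included) at or
   above r_obs, so p ∈ [1/n, 1] and can never be zero. Including
   zero-count pairs is conservative: it inflates the background and
   therefore p. Breakpoints of one assembly can be tested jointly with a
   one-tailed (greater) Wilcoxon rank-sum against the background; the
   exact null distribution is used when the pooled sample is tie-free
   and n·m ≤ 10⁴, otherwise midranks with tie and continuity correction
   (both via scipy). The comparison against within-scaffold rates
   I_i/(L_i/Mb)² is reported as context (breakpoint rates should sit
   *below* typical intra rates — disrupted cis contacts are a minority
   of a chromosome's contacts).

2. **Read depth at the junction** (`junction_evidence`). Per-1 kb mean
   depth at MAPQ ≥ 10 (CIGAR reference-consuming operations M/=/X/D/N;
   duplicates excluded). The coverage fold is
   F = median(flank bins)/median(core bins) on a ±200 kb
   junction-centered track with a 50 kb central core. The flank is the
   *outer annulus* beyond 100 kb of the junction rather than everything
   outside the core: repeat islands at real junctions extend well beyond
   50 kb, and a flank starting at the core edge would be dominated by
   the anomaly it is meant to normalize against (measured on the
   simulator's own extreme junction, that geometry returns F ≈ 1). The
   exclusion radius is a parameter (`junction_exclude`, 0 restores the
   flank-at-core-edge definition). F ≥ 2 flags low mappability; a zero
   core median flags F as infinite.

3. **Spanning reads**: distinct query names with (primary or
   supplementary) alignments within 10 kb of both junction-abutting
   scaffold termini. Their absence is expected at unassembled junctions;
   the count is reported but no verdict rule depends on it.

4. **Repeat landscape**: masked fraction of the terminal 200 kb windows
   of the split scaffolds (junction side), per collapsed repeat class
   (SINE, LINE, DNA incl. rolling-circle, LTR, simple, low-complexity,
   unknown, other; anything unmatched falls through to "other"),
   intervals clipped and merged within class before summing, the total
   from the merged union. Controls are both termini of the
   nearest-length uninvolved scaffold from the joined assembly.
   `repeat_enriched` is junction mean > control mean of the total
   masked fraction.

**Verdict rule** (`adjudicate`): merge when p ≤ 0.05; else merge when
low-mappability AND repeat-enriched (the rescue path for junctions whose
Hi-C signal was destroyed by a repeat island); else merge when the
breakpoint is collinear on a single outgroup chromosome (an upgrade that
never downgrades a statistical merge); else keep_split. Verdicts carry
the list of fired rules. Adjusted count per assembly =
chromosome-scale scaffold count − merge verdicts; consensus requires
agreement.

**Chromosome-scale scaffolds.** Real assemblies carry kb-scale unplaced
debris alongside ~100 Mb chromosomes. Walking down the length-sorted
scaffolds, the count cuts at the first ≥ 10× length drop that occurs
after ≥ 95% of the bases are already included; without such a drop the
whole assembly counts. A pure mass-prefix rule (smallest set holding
95%) was rejected because it truncates debris-free assemblies whose
chromosomes merely vary in length.

**Breakpoint detection** from a whole-genome alignment (PAF, blocks
< 10 kb dropped): for each scaffold, partner coverage is aggregated per
opposing scaffold; exactly two partners each holding ≥ 20% of its
aligned bases and jointly ≥ 50% define a breakpoint, with the junction
at the boundary between the partners' spans; 1-to-1 matches emit
nothing and ≥ 3-way partner sets are reported as complex and excluded
from testing. Detection runs in both directions of one PAF.

## Sex-chromosome calling

In a ZZ/Z0 system the female Z shows half depth. Windowed depth
(500 kb windows in practice; any window size works) is normalized to the
median of the first chromosome (overridable), each chromosome's windows
are rank-sum-tested (one-sided, less) against all remaining chromosomes,
p-values are BH-adjusted, and a chromosome is called only with q < 0.05
and ≥ 10% decrease in median normalized depth. The decrease gate is what
keeps the test calibrated at desk scale: with many precise windows the
rank-sum alone would flag sub-percent fluctuations. Chromosomes with
fewer than 5 windows are excluded with a warning. Zero-depth windows are
retained (depletion is signal).

qPCR: ΔCq = mean(A_Cq) − mean(S_Cq) over replicates, call by sign with a
dead zone ε (default 0). The positive-ΔCq-male convention is the field's
stated rule even though it is the reverse of the naive copy-number
expectation for a ZZ male; the raw ΔCq is surfaced so users can audit.

## The simulator

`synthetic_data` emulates the statistical structure of such a study, on
a 1 kb lattice (chromosome lengths multiples of 1 kb, split positions
rounded) so depth bins lift exactly between truth and assemblies.

* **Genome**: K chromosomes; per-1 kb masked fraction drawn from a Beta
  distribution with mean `repeat_base_mean` and concentration 50,
  switched to `repeat_junction_mean` (or a per-split override) within
  ±100 kb of each planned split. One repeat interval per bin, with a
  class drawn mostly "unknown" near junctions.
* **Assemblies**: chromosomes split at planted positions; the liftover
  is exact and invertible; split junctions on the same chromosome must
  be ≥ 200 kb apart so junction windows don't overlap.
* **Hi-C pairs**: with probability 1−β cis — chromosome ∝ length, first
  end uniform, separation from P(s) ∝ s^(−α) truncated to
  [s_min, L] by inverse CDF, random direction, off-chromosome draws
  resampled *within type*; with probability β trans — both ends uniform
  over the genome, same-chromosome draws resampled within type.
  (Resampling within type matters: sharing one rejection pool across
  types biases the emitted trans fraction below β because trans
  attempts are rejected more often.) Each end is then lost with
  probability γ·density(bin); a lost end discards the whole pair,
  mimicking unmapped-mate filtering, and n_pairs counts emitted pairs.
  Both derived assemblies receive the *same* true-coordinate library,
  lifted — one sequencing library mapped to two assemblies.
* **Depth**: per-1 kb bin Poisson(λ·(1−γ·density)·c), c = 0.5 on the Z
  chromosome for Z0, drawn once in true coordinates (so the two
  assemblies see consistent depth) and aggregated to 500 kb means.
* **qPCR**: replicate Cq = base ± noise with a noiseless ΔCq of
  +1 cycle (male) / −1 (female), one copy-number doubling.

Defaults (the study conditions): K = 8 chromosomes evenly spaced over
3–10 Mb (desk scale; a K = 46, 2–6 Mb preset exists for the
karyotype-scale smoke run), α = 1.0 (canonical contact-decay exponent),
β = 0.1, s_min = 1 kb, n_pairs = 5·10⁵ emitted pairs, λ = 23 (a typical
HiFi coverage for a large genome), γ = 0.3 (0.8 in the rescue scenario),
masked fractions 0.67 baseline / 0.72 junctions (a ~67%-masked genome
with enriched junction windows), with one extreme 0.999 junction in the
rescue scenario. Chromosome lengths are deterministic given K rather than
drawn, so scenario geometry is stable across seeds. All randomness
derives from a single seed via tagged substreams; every output is
byte-identical across repeated runs.

**What the simulator does not model** — and hence what passing tests do
not show about real data: read-level sequence (no FASTQ, no alignment
ambiguity beyond the scalar mappability loss), restriction-site and
library biases in Hi-C, diploidy/heterozygosity and phasing,
translocations or inversions (only split/fusion), real repeat taxonomy
(classes are labels with the right marginal fractions, not sequences),
and chromosome-length distributions of real karyotypes. The calibration
results (null uniformity of the empirical p, detection power, consensus
recovery) are statements about the model's statistical shape at these
problem sizes, chosen so the full suite runs in minutes on one CPU.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; conversions only at
  format boundaries (RepeatMasker `.out` is 1-based inclusive; SAM via
  pysam). The pairs dialect is read with 0-based positions.
* Pairs are canonically ordered (scaffold order index, then position);
  strand fields are carried but unused by any statistic.
* Control selection ties break toward the smaller order index.
* The empirical-p background requires ≥ 20 scaffold-pair rates
  (configurable); fewer is an error advising more scaffolds.
* Median-based coverage folds are quantized at low depth (integer 1 kb
  bins); at λ ≈ 23 and γ = 0.8 the rescue-junction fold estimator sits
  at ~2.2–2.7 against the 2.0 threshold, with a small (<1%) chance of
  quantizing below it. Known limitation rather than a bug.
* `coverage_fold` with a zero core median returns F = ∞ flagged
  infinite and low-mappability.
* Scaffolds shorter than one bin produce a single partial bin with a
  warning; windows of zero length are errors.
* BH adjustment via `scipy.stats.false_discovery_control`; rank-sum via
  `scipy.stats.mannwhitneyu` (exact/asymptotic switch as above). Both
  are standard steps deliberately delegated to scipy; the counting
  statistics, empirical test, and decision logic are implemented here
  and verified against hand-written enumeration and per-record oracles
  in the test suite.

## Known limitations

Breakpoints supported by 3+-way alignment partner sets are excluded
rather than decomposed; the pipeline assumes exactly two assemblies
(outgroups enter only through the collinearity flag); no assembly
correction output (AGP/FASTA) is produced — the deliverable is the
audit-ready report; and the verdict thresholds (p ≤ 0.05, fold ≥ 2) are
codifications of narrative reasoning, exposed as parameters rather than
claimed as optimal.
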