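# Methods

## Model and procedure

`bsimp` operates on windows of `w` consecutive context cytosines taken
from one (chromosome, strand, context) stream. Within a window, the data
form a read × site matrix with entries methylated (1), unmethylated (0)
or missing. Rows fall into three classes: **complete** (no missing
entry), **eligible** (exactly one missing entry) and **observed-only**
(two or more). The method rests on two assumptions: cells within a
population share local methylation patterns, and nearby cytosines are
strongly correlated — together they make a read's observed statuses
informative about the one it lacks.

For an eligible row missing site `j`, the imputed probability of
methylation is the conditional frequency of methylation at `j` among the
window's complete rows whose statuses at the other `w−1` sites equal the
row's subpattern. Formally this is an application of the law of total
probability over subpatterns; because the eligible row's subpattern is
fully observed, exactly one term survives and the rule reduces to a
direct conditional lookup. When no complete row matches the subpattern,
the probability falls back to the column mean: the methylation level at
`j` over **all** rows observed there, observed-only rows included. A
window is imputed only if it holds at least two complete rows.

The conditioning set is the window's original complete rows, frozen
before any imputation: imputed rows never feed other imputations within
the same window, so results are independent of the order rows are
visited. Observed data are never altered.

Imputation is strictly window-local. A read spanning several overlapping
windows may receive a different imputation in each; every profile is
self-consistent for its own window. The read-level export
(`impute_read_level`) resolves this by taking, for each cell, the
assignment from the leftmost window that imputes it.

## Assignment of hard statuses

Three modes turn `p(m_ij = 1)` into a status:

- `sample` (default): Bernoulli draw from a per-cell random substream
  seeded by (seed, chromosome, strand, window start, read id, site
  index). Keying on coordinates rather than iteration order makes runs
  reproducible regardless of read order, and sampling is unbiased in
  expectation.
- `threshold`: 1 above 0.5, 0 below, and *unassigned* at exactly 0.5 —
  ties are left unimputed rather than pushed in either direction.
- `none`: probabilities only.

Unassigned cells are excluded from pattern copy numbers (profiles contain
only realized patterns) but their rows' observed statuses still count
toward per-site totals, and the probabilities are still reported.

## Windows and coordinates

Coordinates are 1-based and always refer to the cytosine's own base; a
minus-strand site is reported at the forward-strand G coordinate (the
Bismark/CGmap convention — the dominant one among methylation callers,
chosen here as a documented convention). Cytosines within 2 bp of a
chromosome end, or whose trinucleotide contains a non-ACGT base, have
undefined context and are skipped. Soft-masked lowercase bases are
treated as uppercase.

Windows never cross a chromosome or strand boundary and, by default, may
span any genomic distance between consecutive context sites (window size
is fixed in cytosines, not bases); an optional `max_gap` suppresses
windows with large gaps. A window is materialized only when at least one
read contributes a call inside it, and a read appears as a row only if it
has at least one call at the window's sites — a read whose alignment span
merely crosses the window without calling any of its sites carries no
information and is omitted. Within a row, a site without a call is
missing whether it lies inside or outside the read's span: the method
distinguishes only observed versus not.

Pattern copy numbers are indexed by the pattern's binary value with site
1 as the most significant bit and methylated = 1 (`UUU` = 0 … `MMM` =
2^w − 1), so outputs are bit-exact across implementations.

## Input handling

SAM/BAM records must carry a Bismark-style per-base call string (tag
`XM` by default; z/Z = CG, x/X = CHG, h/H = CHH, uppercase =
methylated). The strand a read reports on comes from the bisulfite
conversion tag (`XG`) when present, else the alignment strand. Paired
mates sharing a name are merged into one fragment — one molecule, one
cell; where mates overlap with conflicting calls the higher-base-quality
call wins and ties drop the position, treating the conflict as technical
noise. Calls at positions absent from the site index are dropped with a
logged tally. A plain per-call TSV dialect (`read_id chrom strand
position status`) is accepted interchangeably and is what the simulator
writes.

## Screening filters

`screen` emits a window when, after imputation: the number of complete
rows is at least `min_complete` (≥ 2 always, since imputation itself
needs two complete patterns); every site's depth is at least
`min_depth`; and the window methylation statistic is at least
`min_level`. The window statistic is the **maximum** per-site level by
default — it keeps windows with any appreciably methylated site, which
is the useful behaviour when screening mostly unmethylated non-CpG
contexts — and can be switched to the mean. CLI defaults (w = 3,
`min_complete` = 8, `min_depth` = 8) reflect common practice for CpG
heterogeneity screening: 8 is the smallest number of reads that can
exhibit all 2^3 patterns.

## The synthetic-data generator

The generator emulates the sampling process that creates partial
patterns in bulk data: a region of evenly spaced context cytosines; K
binary epiallele patterns with mixture weights (the shared-pattern
assumption made literal); reads of fixed length with uniform starts
(WGBS-like; a fixed-start RRBS-like mode exists), so window-boundary
reads observe truncated patterns; and i.i.d. per-call flip noise ε
standing in for bisulfite-conversion failure and sequencing error
together. Every call is logged in a truth table (epiallele, pre-noise
status, flip indicator).

Defaults are the study conditions used throughout the evaluation
harnesses and acceptance checks: mean depth 18 (a moderate WGBS depth at
which imputation is most useful), read length 100 bp, CpG spacing 25 bp
(CpG-island-like density, ~4 sites per read), two complementary
epialleles at weights 0.5/0.5, regions of 60 sites (desk scale — enough
windows for stable fractions while keeping runs in seconds).

What the generator does **not** model: sequence-level errors (indels,
quality strings), PCR duplicates, non-uniform coverage biases,
context-dependent conversion efficiency, or correlated noise along a
read. Passing tests therefore demonstrate the method's behaviour under
its own assumptions — clean epiallele mixtures with boundary
missingness — not its accuracy on any particular real library.

## Evaluation designs

- **Mask-and-impute accuracy**: windows restricted to their complete
  rows (truth known); k statuses hidden per window (default 2, at most
  one per read, at least two rows untouched); recovery scored per window
  and averaged across windows. Predictions use threshold mode with ties
  worth half credit, removing sampling variance from the headline
  number. The column-mean baseline predicts every masked cell from the
  site's unmasked methylation level. An `oracle` method (predicts truth)
  self-tests the harness.

  Exactness claims about the conditional rule presuppose that the
  conditioning information exists. A random mask can delete the only
  complete representative of a masked read's epiallele — most often in
  shallow boundary windows — forcing the column-mean fallback, which
  cannot be exact. The optional `require_subpattern_support` switch
  restricts the experiment to the premise regime by skipping (with a
  log) placements that leave a masked subpattern unrepresented; it is
  used for the noise-free exactness check and left off when benchmarking
  against the baseline, since it would also remove the baseline's
  hardest cells.

- **Coverage scan**: for each downsampling ratio (default grid 0.28,
  0.44, 0.56, 0.83, 1.0 — expected depths 5/8/10/15/18 over 18), the
  fraction of window starts holding ≥ `min_complete` complete patterns
  before and after imputation, and the fraction of sites at depth ≥
  `min_depth` likewise. Denominators are all window offsets (or sites)
  of the streams the reads report on. Imputation can only add complete
  rows, so after-coverage dominates before-coverage at equal settings.

- **Level bias**: per-site methylation levels recomputed from a
  downsampled library, raw and after read-level imputation, compared to
  the full-depth library as truth; the statistic is the mean absolute
  difference over sites covered in every compared arm.

## Numerical choices and degenerate inputs

- Probabilities are exact rationals realized in floating point
  (numerator/denominator of small integer counts); no tolerance is
  involved in the rule itself.
- Column mean is undefined (and raises) when no read is observed at the
  site; this cannot occur through the imputation path, which is gated on
  two complete rows.
- Sites with zero depth report level 0 in profiles and are excluded from
  the window-level statistic.
- `min_complete` < 2, w < 2, downsampling ratios outside (0, 1],
  mixture weights not summing to 1, and ε ≥ 0.5 are rejected up front.
- Determinism: all randomness flows from explicit seeds; the sampling
  assignment uses SHA-256-derived 31-bit substream seeds per cell.

## Known limitations

- The imputer uses only within-window information — no model training,
  no iterative refinement, no borrowing across windows. This is the
  point of the method (speed, transparency) but means it cannot help
  windows with fewer than two complete patterns.
- Only single-missing rows are imputed; observed-only rows contribute to
  column means and site counts but never to pattern counts.
- Heterogeneity statistics themselves (entropy, epipolymorphism, etc.)
  are downstream of the emitted profiles and out of scope.
- The column-mean fallback ignores pattern structure by construction;
  when a subpattern is unrepresented the imputation is only as good as
  the site's marginal level.
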