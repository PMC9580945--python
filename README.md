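# bsimp

Probabilistic recovery of partially observed read-level methylation
patterns, with genome-wide pattern profiling, for bisulfite (WGBS/RRBS)
and EM-seq data.

## The problem

Methylation heterogeneity — how variable the local methylation state is
across the cells of a bulk sample — is estimated from *methylation
patterns*: the ordered vector of binary statuses a single read shows at
`w` consecutive context cytosines (CG, CHG or CHH). Each read stands for
one molecule, hence one cell, so read identity matters. But shotgun reads
start and end wherever they like, so most reads observe only part of a
window's pattern, and at common depths too few *complete* patterns remain
for heterogeneity analysis.

`bsimp` imputes the single missing status of each *eligible* read (a read
missing exactly one status in a window) from the window's complete
patterns. Writing `m_ij` for the status of read `i` at window site `j`,
the imputed probability is the conditional frequency among complete
patterns that share the read's observed subpattern `m_{i,−j}`:

```
p(m_ij = 1) = #{complete rows matching m_{i,−j}, methylated at j}
              ─────────────────────────────────────────────────
              #{complete rows matching m_{i,−j}}
```

By the law of total probability the sum over subpatterns collapses to
this single term, because `m_{i,−j}` is fully observed. When no complete
pattern matches, the probability falls back to the *column mean* — the
methylation level at `j` over all reads observed there. Only windows with
at least two complete patterns are imputed. Windows slide one cytosine at
a time (w−1 sites shared between neighbours), and each emitted window is
profiled as a vector: chromosome, position, strand, the copy number of
each of the `2^w` possible patterns, and the methylated/unmethylated
counts at every site — ready for downstream methylation-level and
heterogeneity statistics.

## Worked example

Simulate a 12-CpG region mixing two complementary epialleles
(all-methylated / all-unmethylated, 50:50) at 18x depth, then screen it:

```
$ bsimp simulate --out demo --n-sites 12 --spacing 25 \
      --epialleles 111111,000000 --depth 18 --seed 1
simulated 54 reads over 12 CG sites -> demo

$ bsimp screen --fasta demo/reference.fa --reads demo/reads.tsv \
      --out demo/screen --min-complete 2 --min-depth 0 --seed 1 --forward-only
wrote 10 window profiles to demo/screen/profiles.tsv

$ head -4 demo/screen/profiles.tsv | cut -f1-14
chrom  start  strand  n_complete  UUU  UUM  UMU  UMM  MUU  MUM  MMU  MMM  meth_1  unmeth_1
sim1   11     +       13          9    0    0    0    0    0    0    4    4       9
sim1   36     +       21          15   0    0    0    0    0    0    6    6       15
sim1   61     +       26          17   0    0    0    0    0    0    9    9       17
```

Each row is one window start. `n_complete` counts rows complete *after*
imputation; the eight pattern columns are copy numbers (site 1 is the
leftmost letter, `M` = methylated): the window at position 11 holds 9
copies of `UUU` and 4 of `MMM` and none of the mixed patterns — exactly
the two simulated epialleles. `meth_j`/`unmeth_j` give per-site counts
for methylation levels.

The mask-and-impute evaluation on the same data recovers hidden statuses
perfectly while the column-mean baseline cannot separate the two
epialleles:

```
$ bsimp evaluate-mask --fasta demo/reference.fa --reads demo/reads.tsv \
      --out demo/mask --seed 1 --forward-only
bsimp: accuracy 1.0000 over 9 windows (18 masked statuses)
column_mean: accuracy 0.7222 over 9 windows (18 masked statuses)
```

`bsimp evaluate-coverage` and `bsimp evaluate-bias` run the matching
depth-downsampling and methylation-level-bias designs; every subcommand
writes a `run_manifest.json` (parameters, input checksums, seed) beside
its outputs.

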