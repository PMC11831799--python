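# ovgraph

Coverage-guided, iterative construction of read overlap graphs for noisy
long reads (ONT / PacBio), with a bundled read simulator, an evaluation
bench, optional transitive graph expansion, and a read-realignment contig
misjoin detector.

## Who this is for

Developers and benchmarkers of long-read *de novo* assembly pipelines who
need the overlap-graph stage — the usual memory and runtime bottleneck of
overlap-layout-consensus assembly — as a standalone, testable component,
exercisable entirely offline on simulated data with exact ground truth.

## The method

Instead of all-against-all alignment, a small set of **seed reads** acts
as a *virtual reference*: if the seeds jointly cover the donor genome,
every read can join the graph by being mapped onto a seed.  Construction
iterates:

1. select seeds — the longest 3% of reads initially, then 10% of the
   reads whose estimated coverage is below `T_RC = median × P_RC`;
2. index the seed batch with canonical minimizers (k = 15, window of 5
   k-mer starts) under an invertible 64-bit hash;
3. chain each query's minimizer matches into **alignment skeletons** by
   sparse dynamic programming: match blocks i → j may chain when
   `D_q > −k`, `D_s > −k`, `|D_q − D_s| < δ·min(D_q, D_s)` (δ = 0.25),
   scored by `S(j) = max_i S(i) + w(i→j) − p(i→j)` with matched bases as
   weight and a diagonal-drift-dominated gap penalty;
4. keep **confident read overlaps** (CROs): implied overlap ≥ 500 bp,
   matched bases ≥ 100, per-side overhang ≤ 2000 bp, best 2 per query;
5. re-estimate per-read coverage over 1-kb windows from direct edges and
   shared-seed projections, and stop when almost no read is left
   low-covered.

The conservative core graph can then be densified with
`infer_transitive`, which composes coordinate maps of edges sharing a
read and admits inferred overlaps passing the same geometry checks.
See `docs/methods.md` for the full model, parameters and limitations.

## Worked example

```sh
ovgraph simulate reads.fa truth.tsv --genome-len 100000 --depth 30 \
        --err-rate 0.13 --seed 11
# 256 reads over a 100000 bp genome
ovgraph overlap reads.fa overlaps.paf --set rng_seed=5
# 527 overlaps over 256 reads
head -2 overlaps.paf
```

```
read0  3460  0  3460  -  read2    6374  2   3467  211  3460  255  cv:f:52.5  sk:i:211
read0  3460  0  3460  -  read169  5937  11  3495  193  3460  255  cv:f:52.5  sk:i:193
```

Standard PAF: read0 (3460 bp) overlaps read2 reverse-strand over its full
length with 211 matched bases; the `cv:f:` tag is the estimated
sequencing coverage of the query read (high values mark likely repeats)
and `sk:i:` the skeleton chaining score.

```sh
ovgraph eval reads.fa overlaps.paf --truth-tsv truth.tsv --genome-len 100000
```

```
precision    1.0000
sensitivity  0.0764
r_pct        0.9922
c_pct        1.0000
gap_num      0
con_num      1
```

Every reported overlap is a true one (precision 1.0); the core graph
keeps only ~8% of all true pairs (it is deliberately sparse — at most two
confident overlaps per query) yet 99.2% of reads have a correct overlap
recovered (R%), the connected reads cover the whole genome (C% = 1, no
gaps) in a single component.  `ovgraph expand` raises sensitivity toward
~97% over five transitive iterations without losing precision, and
`ovgraph asmqc` realigns reads to contigs and splits them at verified
high-coverage / low-coverage / clipping regions.

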