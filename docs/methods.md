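# Methods

## The measurement model

PARE (parallel analysis of RNA ends) sequences RNAs from ligated adapters on
free 5′-monophosphates, so the elementary observation is a strand-specific
count of read 5′ ends per genomic position. Two signal classes dominate a
yeast degradome: decapping products, whose 5′ ends coincide with transcript
starts, and endonucleolytic products. For the RNase III enzyme Rnt1, the
latter come in a characteristic geometry: the enzyme docks on a terminal
A/UGNN tetraloop and cleaves the double-stranded stem 14 nt upstream and
16 nt downstream of the loop, producing 5′ ends spaced
14 + loop + 16 nt apart (34 nt for a tetraloop) and an excised duplex with a
2-nt 3′ overhang.

Counts are scaled to cpm (`count × 10⁶ / library_size`). The library size is
the sample's total primary aligned reads when supplied, falling back to the
total counted ends; both conventions are supported because only their ratio
between samples matters for the comparison statistic.

## Site calling

The comPARE score at a position is
`log2((wt_cpm + c) / (mut_cpm + c))` with pseudocount `c = 0.01` cpm added
to **both** samples. A site is called when every index-paired replicate
satisfies `wt_cpm ≥ min_wt_cpm` and `score ≥ min_score`. Defaults:

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 0.01 cpm | keeps the ratio finite at mutant zeros |
| `min_wt_cpm` | 1 cpm | removes very rare 5′ ends |
| `min_score` | 4 | ≥ 16-fold genotype ratio |
| merge `max_gap` | 5 nt | imprecise-cleavage event merging |
| pair spacing | 34 ± 4 nt | two-sided cleavage; tolerance absorbs bulges |
| `orphan_window` | 200 nt | clustering of unannotated events |
| TSS window | ± 25 nt | decapping-read capture around the start site |

Thresholds are inclusive (≥), evaluated in double precision with no
rounding. Replicates are paired by index and never pooled; a single
replicate failing either cutoff vetoes the site. Positions with
`score ≤ −min_score` (signal gained in the mutant) are available as a
separate diagnostic and are never called as cleavage sites.

Classification priority for events is ncRNA > CDS > intron > 5′UTR > 3′UTR
on the sense strand, then antisense, then intergenic. The priority is chosen
so ncRNA targets (e.g. intron-hosted snoRNAs) are never demoted by their
host context. Substrates are the union of events sharing an overlapping
gene-level feature; intergenic events cluster by single-linkage distance
within the orphan window. Both merging and clustering are idempotent and
partition the called sites.

## Stem-loop scanner and cleavage geometry

The scanner anchors at loop-pattern matches (default `[AU]GNN`; 3–5-nt
loops via the pattern) and requires the loop-closing pair to pair. It then
extends pairing outward, maximizing the number of nested pairs subject to:
Watson–Crick or G·U pairs; at most 2 single-nucleotide bulges per arm; no
two consecutive bulges on the same arm (larger asymmetries terminate the
stem; a mismatch costs one bulge on each arm). The maximization is exact
(memoized search over the ≤ `window² × 9` state space), so it provably
agrees with brute-force enumeration of all nested pairings, and the
reconstruction tie-break — pair over bulge, 5′-arm bulge over 3′-arm —
makes the reported structure deterministic.

Cleavage prediction walks 14 paired steps down the 5′ arm and 16 down the
3′ arm; bulged nucleotides traversed on the way extend the *linear*
distances (one 5′-arm bulge within the first 14 steps → 15 nt upstream,
matching the known behavior of bulged substrates), and the step-count
difference fixes the 2-nt 3′ overhang. Arms shorter than the required steps
yield one-sided or empty predictions. A two-arm nested scanner cannot infer
asymmetric arm support from sequence (every pair consumes one base per arm),
so variant structures — e.g. multibranch junctions that support only the
downstream site — are encoded by explicit per-arm step overrides on the
`Hairpin` object and validated through the same geometry code.

There is no thermodynamic folding. The stem score (WC = 2, G·U = 1, −2 per
bulge) is a coarse stability ranking sufficient to order a stem against a
point-mutated variant; it is not a free energy and printed ΔG values of real
substrates are deliberately not reproduced.

## The synthetic degradome

The simulator is the package's test bed: it generates a random genome with
gene cassettes, a matching annotation, and count tracks with known truth.
Defaults describe a small but realistic experiment: 50 genes of 400–800 nt
(10% ncRNA), 200-nt intergenic spacers, 20 genes carrying a perfect 20-bp
stem capped by an A/UGNN tetraloop in mid-CDS, per-gene expression depth
log-normal (median 400 read units, σ = 0.5), cleavage efficiency 0.8 per
site, decapping rate 0.9, two replicates per genotype, library size 2 × 10⁶.
With poly(A)+ weighting (cleavage × 1, decapping × 0.2) the expected
cleavage:decapping read ratio is ~9:1, i.e. a planted degradome fraction of
~0.9; poly(A)− weighting reverses the factors. Those weightings are a
stand-in for oligo(dT) selection chemistry, not a model of it.

Background is a sparse decay-hotspot landscape: 2% of positions carry a
Gamma-distributed Poisson rate (shape = dispersion 10) scaled so the
marginal per-position mean is 0.2, giving a negative-binomial marginal.
Crucially the hotspot rates are **shared** between genotypes and replicates
and only the Poisson sampling differs per library: degradome background
consists of real decay intermediates present in both strains, which is
exactly why a genotype-ratio statistic separates enzyme-dependent peaks
from it. Fully independent per-sample noise would not be background in any
biologically meaningful sense for this design.

Nuclear retention gates in vivo cleavage: the retained subset (an exact
rounded count, so small-n ratios are well defined; default fraction 1.0) is
cleaved in vivo, while in vitro mode cleaves every competent hairpin — so
the in vitro target set strictly contains the in vivo set, and with a
retention fraction of 1/7 the simulator reproduces a ~7× in vitro excess.
NET-seq tracks plant 3′-end peaks exactly 1 nt transcript-upstream of the
cleavage 5′ ends of co-transcriptionally cleaved genes. A dosing helper
converts molecule counts and compartment volumes to concentration
(2,512 molecules in 0.6 fL ≈ 7 μM).

What the simulator does **not** emulate: read-level sequencing (errors,
mappability, multi-mapping), positional cleavage jitter (planted peaks are
exact; the ±1-nt matching tolerance therefore exercises the bookkeeping,
not biological imprecision), transcript-body degradation ladders, overlapping
genes, introns in simulated annotations, and competition between cleavage
and decapping on the same molecule (rates are independent). Passing
recovery tests therefore demonstrates the correctness of the counting,
scoring, thresholding, and coordinate arithmetic under realistic noise —
not performance on real libraries, where background structure and library
depth differ.

## Numerical and design choices

- Coordinates are 0-based half-open internally; bedGraph/BED output 0-based,
  GFF3 converted from 1-based on read. Minus-strand reads count at their
  rightmost aligned base (the RNA 5′ end).
- Event anchors are the member position with maximal mean WT cpm (ties to
  the lower coordinate); pairing is greedy nearest-to-34-first, each event
  in at most one pair.
- Degradome fractions are undefined (NaN), not zero, when a gene has
  neither cleavage nor decapping reads.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; fixture and track outputs are bit-identical
  for a fixed seed and version. Test problem sizes (50-gene genomes,
  10 seeds) are chosen to make recovery statistics meaningful at
  interactive runtimes.

## Known limitations

- The scanner reports at most one stem per loop anchor and no pseudoknots
  or multibranch topologies; the downstream-only case is representable but
  not discoverable from sequence alone.
- Substrate clustering for unannotated regions uses a fixed distance
  window; with very dense intergenic signal this can chain distinct
  transcripts into one substrate.
- cpm normalization assumes library sizes are comparable between genotypes;
  no attempt is made to correct for composition effects.
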