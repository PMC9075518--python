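# Methods

## The domain model

The α-crystallin domain (ACD) is represented from the β3-strand to the
β9-strand; β2 is too poorly conserved to anchor on, and β6/β10 are not
universally present.  The model is a chain of segments

```
β3(6) – L34(4–9) – β4(6) – L45(3–7) – β5(5) – L57(4–14) – β7(6) – L78(8) – β8(5) – L89(4) – β9(6)
```

with strand blocks at fixed widths and three variable-length loops.  L78
and L89 are modelled at fixed width because their contents — the L-P and
V-D doublets and the L89 glycine — are the most rigidly conserved elements
of the domain; keeping them rigid makes the β7→β9 block a deterministic
function of the β9 anchor position.  Total model width is 72 columns
(loops profiled at their widest form); core lengths between 60 and 85
residues are accepted, which covers both the short-L57 A1-type cores
(63–69 aa) and the longer 71–79 aa cores of the other groups.

### Scoring

Each column holds log-odds scores `log2(((c + b) / (N + 1)) / b)` with
count `c` over the seed alignment's non-gap residues, column depth `N`,
and uniform background `b = 1/20`.  The background-proportional
pseudocount avoids −∞ and scores equally frequent residues identically;
X scores 0 (an unknown residue is evidence for nothing).  The seed
alignment is the set of six template cores (five monomeric subclusters
plus the diverged upstream core of the dimeric template) projected onto
the model columns; its consensus realizes the universal motifs.

### Detection

A candidate requires, in order: (a) a β9-motif match, which pins the core
end; (b) an L78 doublet (L-P or V-D) inside the implied L78 window; and
(c) a PSSM score at or above the threshold over the implied β3→β9 window,
maximized over the allowed loop lengths.  Loops are scored with at most
one internal gap (maximum over split points, left part anchored left,
right part anchored right), matching the generator's indel model of at
most one indel per loop.  Unscored loop insertions and skipped loop
columns carry no explicit gap penalty — the seed alignment already
represents short-loop forms as gaps, so their columns are shallow and
cheap to skip.  Overlapping candidates are resolved greedily by score
(ties: leftmost).  One hit makes a protein monomeric, two tandem hits
dimeric; for two hits, ranks follow start coordinates.

### Threshold calibration

The threshold is the 99.9th percentile of the detector's own score
statistic under a motif-gated null: 10,000 shuffled uniform-composition
windows, each given a forced β9-motif match (sampled over the motif's
allowed residues) and one L78 doublet at a random in-loop offset, scored
by the same anchored layout maximization (seed 1; fully vectorised, ~3 s).
Conditioning the null on the motif gates matters: a decoy that happens to
carry a β9 motif gets the motif's columns "for free", and a null that
ignored this would sit ~40 bits too low.  Template cores score 180–214
bits against a threshold of about −27 bits, so detection is effectively
limited by the motif gates, as intended.  The threshold is recomputed
deterministically on demand (cached per process) rather than shipped as a
constant.

## Physicochemistry

* **GRAVY**: mean Kyte–Doolittle hydropathy; X excluded from the average.
* **Molecular weight**: sum of average residue masses plus one water;
  X contributes the mean residue mass.
* **pI**: bisection on [0, 14] for the root of the Henderson–Hasselbalch
  net charge (termini plus D, E, C, Y acidic and K, R, H basic), to
  |charge| < 1e−4.  Net charge is strictly decreasing in pH, so the root
  is unique.  The default pKa table ("sms") is the EMBOSS-style set used
  by the Sequence Manipulation Suite family of calculators (N-term 8.6,
  C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); a
  "lehninger" table is selectable, and the table name is recorded in run
  provenance because small pI offsets between tables are expected.
* **Group summaries** report interquartile ranges (linear interpolation
  between order statistics, the numpy default) over complete sequences
  only; truncated ORFs are profiled but never summarized.

## Classification rules

Rules run in precedence order A1 → A2 → B1 → B3 → B2-fallback, with
`unassigned` reserved for proteins lacking a detected domain.  A1 demands
core ≤ 69 aa, protein < 130 aa, pI < 4.8 and no arginine in β7; A2 demands
length ≥ 300 and pI ≥ 8.5; B1 fires on the lysine-rich β5-L57 motif or the
serine-rich L34 motif (the acidic L57-β7 stretch corroborates but is not
required); B3 fires on either of its two signatures; B2 is the residual
class, mirroring the weak B2/B3 separation seen in tree-based analyses.
Numeric cut-offs deliberately sit outside the published interquartile
ranges (e.g. A2 length ≥ 300 against a reported 359–381) so that dispersion
beyond the IQR does not leak across classes; all cut-offs are plain
constants overridable per call and per run config.  The classifier refuses
dimeric input — the subcluster structure is defined for single-domain
proteins only.

Consensus calling uses *strictly greater than* the threshold frequency:
an exact 50/50 column has no consensus at t = 0.5, which matches the usual
"at 50% conservation" convention and keeps the call unambiguous.

## Alignment and trees

Cores are re-anchored with the detection machinery (score gate disabled)
and laid into the model column space: strand residues map one-to-one,
loop residues are placed by affine-gap pairwise alignment (BLOSUM62, gap
open 10, extend 1) against the model's loop consensus, insertions get
extra columns, and all-gap columns are dropped.  Cores matching fewer
than the required anchors are excluded with a warning rather than
poisoning the alignment.  Distances are uncorrected p-distances with
pairwise (not listwise) gap deletion, preserving signal in ragged loops.
Neighbor joining follows Saitou–Nei; negative branch lengths are clamped
to zero with the deficit moved to the sibling edge, preserving the joined
pair's path length.  Bootstrap resamples columns with replacement (default
100 replicates, seed mandatory); supports are the percentage of replicate
trees containing each internal bipartition.  p-distance NJ is a deliberate
methodological simplification of likelihood-based inference: it is exact
on additive matrices and recovers the coarse subcluster structure that the
downstream analyses need, at desk scale and fully deterministically.

## The synthetic generator

The generator emulates the statistical structure of real sHsp
repertoires, not their phylogenetic history.  Each subcluster has one
deterministic template whose fixed positions carry the signature motifs at
their anchor regions and whose filler positions are chosen by a greedy
composition tuner so that protein and core land inside the subcluster's
published interquartile boxes for length, MW, pI and GRAVY (the tuner aims
slightly inside each box so finished templates never sit on an edge).  The
dimeric template carries a downstream B2-like core and an upstream core
diverged at ~45% of positions — upstream domains of two-domain sHsps form
their own cluster, well separated from all monomeric groups.

Noise: substitutions hit filler positions only, at separate strand and
loop/flank rates (defaults 0.01/0.05 — strands of the β-sandwich are
conserved, loops and disordered flanks drift); signature-motif and anchor
positions are invariant, because they are precisely the residues whose
empirical conservation defines the groups.  Indels are confined to the
variable loops, at most one per core, clamped to the detection spans.
Back-translation draws uniformly among synonymous codons; transcripts get
random UTRs, and a configurable fraction is truncated mid-CDS to exercise
the completeness rule.  All randomness flows from one mandatory seed and
outputs are byte-identical across runs.

What passing tests on this substrate do **not** show: robustness to real
assembly artifacts (chimeras, frameshifts), to homologs whose motifs have
genuinely decayed, or to compositional biases beyond the modelled boxes.
The generator's conservation structure is idealized; sensitivity on real
data will be bounded above by these results.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale repertoires (tens of plants, ~100
decoys, 100 bootstrap replicates) — large enough to exercise every rule
conjunction and bipartition, small enough to run in seconds to a couple of
minutes.  Ties in greedy hit selection break leftmost; consensus ties
break alphabetically; bisection runs 100 iterations or to |charge| < 1e−4;
pairs with zero comparable alignment columns get NaN distances and a
warning.  Degenerate inputs (empty FASTA, duplicate ids, non-IUPAC
symbols, ragged seed alignments, < 3 taxa) raise typed errors early.

## Known limitations

* The detector requires an intact β9 motif and an L78 doublet; a true sHsp
  with a degenerate β9 (rare, but possible in fast-evolving lineages) is
  invisible to it.
* Classifier cut-offs were codified from published group statistics, not
  fitted to the deposited per-accession memberships; borderline proteins
  near the A1/B boundaries may differ from tree-based assignments.
* The aligner confines gaps to loops by construction; genuine strand
  indels (not observed in the modelled families) would be mis-placed.
* p-distances saturate for deeply diverged cores; the trees are for
  cluster structure, not for dating or branch-length interpretation.
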