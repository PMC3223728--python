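# Methods

This note documents the models behind `orfsieve`, the defaults and why they
were chosen, and what the synthetic pipeline does and does not show about
real filtered-library data.

## Synthetic genome

`generate_genome` emulates an intronless bacterial genome with annotated
single-CDS genes. Gene lengths are uniform over the multiples of 3 in
`gene_length_range` (default 300–3000 nt, bracketing typical
domain-to-protein coding lengths); bodies are i.i.d. draws from the 61
sense codons followed by a random stop, so every gene is stop-free on its
coding strand by construction. No codon-usage table is applied: the
downstream analysis is driven entirely by frame and stop-codon statistics,
which random sense codons reproduce, not by codon biology. Genes are placed
without overlap by splitting the non-genic sequence into random intergenic
gaps (uniform composition over gap vectors), with strands assigned by fair
coin; intergenic sequence is i.i.d. with P(G) = P(C) = gc/2 (default GC
0.5). Coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive.

Length draws are resampled (up to 1000 times, deterministically under the
seed) until they pack into the genome; generation fails explicitly when
packing is impossible. A strict a-priori bound of the form
n_genes × max_length ≤ genome_length would wrongly reject standard settings
such as 50 genes of up to 3 kb in 100 kb, which pack easily in expectation,
so feasibility is enforced at generation time instead.

## Fragmentation and cloning

Fragments model nebulisation plus blunt cloning: start positions uniform,
lengths truncated-normal on [200, 800] nt with sd 120 (a `uniform` law is
available), orientation a fair coin, sampling with replacement. The
location parameter of the truncated normal is solved so that the *realised*
mean equals the requested mean (default 400 nt, the observed average of
cloned inserts; naive truncation of N(400, 120²) at the asymmetric bounds
would inflate the average to ≈ 412). The insert sequence is the plus-strand
slice or its reverse complement according to the cloned orientation.

## Selection model

The fusion-ORF rule is exact: insert length divisible by 3 and no frame-0
stop codon. The insert is read in frame 0 from its first base — the vector
junction contributes no frame offset; the real junction geometry of the
three vectors is not published, and offset 0 is the simplest consistent
choice. Amber suppression (TAG read-through, as in a supE host) is a flag,
off by default.

Survival is a parameterised stand-in, not a fit to measured curves: each
clone has a MIC (`mic_nonorf` = 0.25 µg/mL for non-ORFs; fusion ORFs
interpolate `mic_base` = 0.5 to `mic_max` = 150 µg/mL linearly in folding
quality) and survives plating at concentration a with probability
`expit(slope · (log₂ MIC − log₂ a))`, slope 2 per doubling; a = 0 means
chloramphenicol-only plating and survival 1. These defaults put a random
fragment library in a ~1–2% survival regime at the stringent end of the
0.25–100 µg/mL series, the regime from which libraries are sequenced. The
"filter to ~1% survival" behaviour is expressed as choosing the lowest
concentration in the sweep whose survival rate is at or below the target
(default 0.01), falling back to the most stringent concentration when the
sweep never reaches it.

Folding quality is class-conditional: genic inserts draw Beta(5, 2) (mean
5/7), non-genic stop-free inserts Beta(2, 5) (mean 2/7). The shapes are a
design choice encoding only stochastic dominance of genic over non-genic
folding — the mechanism by which the reporter enriches genic frames beyond
what stop-codon statistics alone provide; their absolute scale is not a
biological claim. Leaders (Sec/SRP/TAT) are modelled as independent
libraries with separate random streams; no mechanistic translocation
differences are simulated, so inter-leader differences in output are purely
sampling noise unless per-leader parameters are supplied.

## Sequencing errors

The 454-style error model applies per-base substitutions (default 1e-3)
and homopolymer indels: a run of length L ≥ 3 gains or loses one base with
probability min(1, 5e-3·L), increasing with run length as flow-miscall
errors do. The rates are plausible placeholders, not measured values; the
analysis is insensitive to them because error-bearing reads are discarded
by the perfect-match filter rather than error-corrected.

## Mapping and classification

Mapping is exact-substring only (forward and reverse-complement, all
occurrences). This mirrors how the headline frame statistics are computed
in practice: only reads matching the reference 100% at full length allow
unambiguous start/end/frame assignment, and approximate alignment of the
remaining reads is deliberately out of scope. Reads are assumed to be
reported in vector orientation, so the cloned frame is frame 0 of the read
as given.

Classification order: a read failing the fusion-ORF rule is `non_orf`;
otherwise it is `genic_orf` iff some overlapping gene has the same strand
and codon lattice — `(start_read − start_gene) mod 3 = 0` for `+` genes,
`(end_gene − end_read) mod 3 = 0` for `−` genes — with at least one
complete in-frame codon shared (the overlap threshold is configurable; a
whole-containment requirement is deliberately not imposed); otherwise
`nongenic_orf`. Multi-hit reads are classified by the hit with the highest
class priority (genic over non-genic) and flagged `multimapped`; synthetic
genomes are essentially repeat-free so this rarely triggers.

For the chance-level estimate (`frame_match_fraction`), a fragment
overlapping several genes is scored against the gene with the largest
overlap. This keeps the chance expectation exactly 1/6 = 2 strands × 3
offsets; scoring "any overlapping gene" would inflate the expectation for
fragments spanning two genes. No ORF or minimum-overlap filtering is
applied there, since the quantity being estimated is pure frame chance.

## Metrics

Focus is `(depth − 1)/(coverage − 1)`: its defining endpoints are 1 when
all reads share a common region (depth = coverage) and 0 when no two reads
overlap (depth = 1), and it is monotone in overlap concentration between
them. Only the endpoints are externally fixed; this formula is our
explicit, endpoint-consistent choice. A single-read gene gets Focus 1 by
convention (a singleton trivially shares its own region); pass
`singleton_focus=None` for NaN. Depth is maximum per-base pileup — the
standard, testable reading of "number of overlapping sequences". Window
histograms assign reads by start coordinate (midpoint available) into
40-kb windows by default. Fold coverage is the plain arithmetic
`n_clones · mean_insert / genome_length`.

## Problem sizes and what the tests show

The default study conditions are a 100 kb genome with 50 genes, 20,000
clones per leader, and 100,000 fragments for the chance-level estimate —
sizes at which Monte-Carlo standard errors are small (the 1/6 estimate has
SE ≈ 0.12 percentage points at n = 10⁵) while everything runs in seconds
on one core. The synthetic pipeline demonstrates the *mechanisms*: the 1/6
chance level, the monotone survival curves, genic enrichment among
survivors, and the report arithmetic. It does not reproduce
experiment-specific percentages (e.g. an ORF fraction below 1 among
survivors, which in real data reflects weak lactamase read-through,
suppressed stops and cloning artifacts that are not modelled), leader-
specific biology, repeat-rich genomes, or amplification bias along the
genome (real libraries can show one strongly over-represented region;
fragments here are uniform by construction).

## Numerical and degenerate-input choices

All randomness flows from one integer seed through spawned
`numpy.random.Generator` streams, so identical configurations reproduce
identical artifacts byte for byte. Fractions with zero denominators are
NaN; a gene with no reads has depth 0 and undefined Focus. Reads shorter
than 20 nt are refused by the mapper (too likely to hit by chance).
Classification is invariant under translation of all coordinates, and the
report identity genic = ORF-fraction × genic-given-ORF holds exactly by
construction.
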