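# Methods

This note documents the models, conventions and numerical choices behind
mirpeaks, and what the synthetic-data validation does and does not show.

## Coordinates and formats

All internal coordinates are 1-based and closed on both ends, matching
miRBase GFF3; BED input/output converts at the I/O boundary (0-based
half-open), and the two conversions compose to the identity. Strand is
explicit everywhere. GFF3 support is deliberately limited to the miRBase
dialect (`miRNA_primary_transcript` / `miRNA` with `Derives_from`
linkage); repeats are consumed as a UCSC rmsk-style TSV of which only the
repeat class is interpreted; coverage is emitted as fixedStep wiggle with
one track per chromosome/strand.

## Informative reads

A mapped read is *informative* when its length is 18–27 nt and it does not
overlap — by even one nucleotide, on either strand, since repeat masking is
positional — a repeat of class rRNA, scRNA, snRNA, tRNA, srpRNA, RNA or
MARNA. Informative-read totals are the per-sample denominators of every RPM
value. Known-miRNA reads are counted among *all* mapped reads by
strand-aware overlap with mature-miRNA intervals (a flag switches to
pre-miRNA intervals), so a library's known-read portion may exceed 100% of
its informative count in principle; the portion is reported rounded half-up
to two decimals. Quality trimming removes the maximal 3' suffix of
below-threshold calls (default Phred 30); adapter clipping truncates at the
leftmost exact occurrence of the adapter or of a terminal adapter prefix of
at least 5 nt, discarding reads shorter than 15 nt. Adapter matching is
exact; mismatch tolerance would be a configuration extension.

## Discovery model

Per group, informative reads are pooled into a per-position, per-strand RPM
track: value = overlap count × 10⁶ / group informative total. Tracks and
discovery are strand-specific because the reads are stranded and all
downstream counting is strand-aware; candidates from the groups are
unioned by same-strand interval overlap, keeping the maximum span.

A *peak* is a maximal run of consecutive positions ≥ 0.9 RPM (the
threshold is inclusive). This run definition makes the four calling
parameters well-defined: peak length 18–50 nt, valley width (inner edge to
inner edge, exclusive) 8–30 nt, and an isolation rule rejecting a pair when
a third called peak sits less than 50 nt from either flank, which prevents
tandem loci from merging. Under the run definition, thresholding the peak
maximum and thresholding every peak position are the same thing; users
plugging an alternative peak definition should note the distinction. A
peak joins at most one emitted pair (left-to-right scan), so candidate
intervals are disjoint.

Candidate filters: (1) overlap with a known pre-miRNA on either strand;
(2) overlap with an excluded-class repeat; (3) hairpin failure; (4) more
than 15 exact genome-wide occurrences of the candidate sequence (both
strands, overlapping matches counted; a palindromic sequence counts once
per position). Exact-match scanning replaces alignment-based hit counting;
it is deterministic at desk scale and a lower bound on alignment hits, so
filter (4) is slightly more permissive than an aligner-based count would
be. The same occurrence scan drives duplicate-expression merging.

The hairpin verdict uses an internal O(n²) dynamic program that maximises
base pairs over *single-hairpin* structures: fully nested pair chains with
one terminal loop of ≥ 3 nt, Watson–Crick plus GU wobble pairs. A sequence
passes with ≥ 14 pairs and a paired-base fraction 2·pairs/length ≥ 0.25.
These defaults accept every planted synthetic hairpin and reject
homopolymers, but random sequences of typical candidate length (40–80 nt)
frequently reach 14 nested pairs, so the hairpin gate is a weak filter on
its own — as any secondary-structure-only criterion is. The function is a
plug-in point: an external thermodynamic folder can be substituted behind
the same contract.

Calling parameters can be tuned by exhaustive grid search maximising the
number of expressed known pre-miRNAs overlapped by a candidate; ties prefer
a stricter threshold, then a smaller peak-length/gap window, then grid
order.

## Expression

Counting is strand-aware ≥1-nt overlap; border-straddling reads contribute
exactly 1. RPM divides by the *informative* total even when counting all
mapped reads, and the informative-only counting variant never exceeds the
all-reads variant per cell. Novel pre-miRNA intervals longer than 50 nt are
split into two equal halves to mimic the 5′/3′ mature products; the
genomic-left half receives floor(L/2) nt — the unique convention consistent
with splitting a 57-nt locus 28+29 and an 81-nt locus 40+41 — and strand
determines which half is 5p. (The tier module's stem-loop score applies at
"50 nt or longer" while expression splits at "longer than 50 nt"; both
thresholds are kept as stated for their respective operations rather than
harmonised.) Candidates whose occurrence intervals overlap are pooled into
one feature (raw counts summed, RPM recomputed, member ids concatenated
lexicographically), which compensates for multimapped reads having been
placed at one random copy. Features with all-zero counts are retained so
downstream filters stay explicit.

## Tier classification

Both demotion rules read boundaries literally: "less than 0.5" strict,
"between 0.5 and 0.85" closed, "higher than 3" and "higher than 0.05"
strict; all are configurable. The l/r/m counts use all mapped reads on the
candidate's strand (an informative-only variant is a flag): the score
exists to catch non-miRNA signal, which is exactly what the informative
filter removes. A read straddling the internal border counts in l, r and
m. A ≥50-nt locus with no shoulder reads gets score 0 (logged) rather than
a division error, since a candidate with reads on neither half cannot have
been called from those reads in the first place.

## Differential expression

Group means are arithmetic means of per-sample RPM (mean-of-RPM, not
RPM-of-pooled-counts; configurable). The extremum condition
min ≥ factor × max is accepted only when the minimum is positive, so
all-zero features are never called. The ≥3-reads guard uses raw counts and
applies only to up-in-EF calls, as stated. Raising the factor from 2 to 10
is strictly more stringent: no not-significant feature can become
directional. P-values, dispersion modelling and FDR control are
deliberately out of scope — the classifier is itself the safeguard against
the two-replicate EF group.

## The synthetic cohort

The generator plants hairpins as arm + loop + reverse-complement(arm), so
the hairpin test holds by construction, in three 200-kb chromosomes, with
30 known loci (annotated pre + two matures), 20 novel loci, and 40
RNA-class repeat regions. Eleven libraries (7 iPSC + 2 ESC forming the PSC
group, 2 EF) target 40,000 informative reads each — a deliberately
desk-scale depth; per-arm read counts are Poisson around planted
expectations, with per-position expected totals kept self-consistent so the
truth table's expected RPM values match pipeline-computed RPM to Poisson
error. Per-arm abundances are log-uniform (known loci 20–3000 expected
reads/arm/sample, novel 30–1000), echoing the orders-of-magnitude spread of
real miRNA expression in which a few loci dominate the library.

Novel loci comprise 12 differentially expressed loci (3 per direction ×
factor {6, 20}; planted factors are at least twice the classifier's
extremum factor so recovery is a property of the method, not of luck at
this depth), a two-copy family with identical flanks (exercising duplicate
merging), one locus whose sequence is embedded at 16 placements (exercising
the >15-occurrence filter; its reads scatter uniformly over the placements,
mirroring random multimapper placement), two "dirty" loci that violate one
tier rule each, and plain nulls. Dirt is injected as out-of-length (30–34
nt) reads — loop-straddling reads at 0.1 per locus read for the stem-loop
rule, arm-anchored outward-extending reads at 1.5 per locus read for the
ratio rule — so it is invisible to the informative-read coverage tracks and
discovery geometry while being counted among all mapped reads, exactly the
contrast the tier scores measure.

Hairpin geometry defaults are arm 22–25 nt and loop 12–26 nt: reads carry
±2 nt end wobble (60% exact, 15% ±1, 5% ±2, lengths clamped to 18–27 nt),
so an observed called peak can differ from the planted arm by up to 4 nt
and the observed valley from the planted loop by up to 4 nt; these ranges
are precisely the ones for which the observed double-peak signal is
guaranteed to stay inside the caller's default windows (peak 18–50, gap
8–30). Mature-length noise distributions are discrete over 18–27 nt with
mode 22, so informative-length histograms peak in the 21–25 nt range
typical of real libraries.

Noise classes (fractions of depth): repeat-region reads 2% (informative
length, excluded by the repeat rule), out-of-length reads 2%, uniform
background 0.5%. Background and out-of-length reads are placed outside a
100-nt buffer around planted loci: at these depths a *single* stray read
already exceeds the 0.9 RPM threshold, so unbuffered background would
violate the isolation rule at arbitrary planted loci — real multi-million
read groups suppress singleton noise through the threshold itself, which a
scaled-down cohort cannot. This is the main respect in which passing tests
overstate real-data behaviour: on real libraries, background *does* sit
next to true loci, and discovery recall there depends on depth and the
threshold in a way the synthetic cohort does not probe. Other realism
limits: no sequencing errors or isomiR end heterogeneity, no expression
correlation between clustered loci, noise composition is stylised, and
multimapper placement is uniform rather than alignment-driven.

Everything derives from `numpy.random.default_rng([seed, stream])`, so a
seed reproduces every file byte-for-byte.

## Problem sizes and determinism

Default validation runs use the 600-kb genome, ~460k reads per cohort and
seeds fixed in the tests: peak calling is checked against a brute-force
scan on one hundred 10-kb random tracks, fold-change recovery over twenty
seeded cohorts, and discovery/tier scoring on one default cohort. The
acceptance script re-runs the full analysis on one cohort derived from the
given seed. All checks are deterministic given the seed.

## Known limitations

* Exact-match occurrence counting undercounts relative to an aligner that
  tolerates mismatches; loci duplicated with variation are not merged.
* The internal folder maximises pairs, not free energy; a marginal hairpin
  with many weak pairs can pass where a thermodynamic folder would fail.
* Single-nucleotide-resolution isolation: the isolation rule keys on called
  peaks only, so sub-threshold neighbouring signal does not disqualify a
  pair.
* The pipeline consumes already-mapped reads; mapping ambiguity is assumed
  resolved upstream (one random placement per multimapper).
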