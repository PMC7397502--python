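# Methods

## Scope and model

`exposig` analyses clone-expansion mutagenesis experiments: a panel of
control clones accumulating mutations from endogenous background
processes, and a panel of exposed clones additionally carrying a
carcinogen-driven process. The analysis treats each clone's somatic
variant calls (VCF) as a draw from a mixture of mutational processes
and asks three questions: what is the exposure process's spectrum,
which known signatures does it resemble, and where in the genome do the
mutations fall relative to genes and transcription.

## Channel schemes

**SBS96.** Single-base substitutions are reported on the strand where
the mutated base is a pyrimidine. A purine-centred call is
reverse-complemented (reference, alternate, and flanks, with the flanks
swapped), so the six substitution classes are C>A, C>G, C>T, T>A, T>C,
T>G, each in 16 flanking contexts. Canonical order is class-major, then
5′ flank, then 3′ flank, each A<C<G<T.

**DBS78.** Doublet substitutions require both positions to change
(16 refs × 9 alts = 144 raw cases). A doublet and its reverse
complement denote the same event; collapsing leaves 78 channels over
the ten conventional reference doublets (AC, AT, CC, CG, CT, GC, TA,
TC, TG, TT). For the four palindromic references the alt
representative is fixed once as the lexicographic minimum of
{alt, revcomp(alt)}; any fixed choice is valid if applied consistently
to data and catalogues, and this one is stated here and encoded in the
packaged label table. Doublet records in which only one base changes
have no channel and are skipped with a counted warning rather than
silently split.

**ID83.** Indels are classified by event type and length. 1-bp events
collapse G→C and A→T and record the reference homopolymer run length:
for deletions the run containing the deleted base (bins 1–6+), for
insertions the run of reference bases matching the inserted base (bins
0–5+). Longer events record the repeat-unit count of the
inserted/deleted sequence in the reference (including the deleted copy
for deletions); deletions at non-repetitive sites are sub-classified
by microhomology, the longest overlap between the deleted sequence's
prefix/suffix and the adjacent reference. Runs, repeat copies and
microhomology are scanned in both directions, so channels are
invariant to placement within a repeat tract and to strand. Indels are
left-aligned at load time when a reference is available, giving a
canonical placement. Label strings follow the widespread
`1:Del:C:2`-style convention so standard catalogue files load directly.

All three label tables ship as TSVs under `exposig/data/`; their order
is normative and the in-code tables are tested byte-identical to them.

Adjacent same-sample SNV pairs can be merged into doublet records
(`merge_adjacent_snvs`), supporting callers that emit MNVs as
individual SNVs. Runs of ≥3 consecutive SNVs fit neither the SBS nor
the DBS scheme and are flagged and excluded rather than split, which
would bias both catalogues.

## Catalogues and class summaries

A catalogue is a samples × channels integer matrix; records that
cannot be classified ('N' contexts, half-changed doublets) are counted
per sample, never silently dropped. The six-class summary computes
percentages per clone and then averages across clones (clones are the
replicates; the spread is the n−1 sample standard deviation). The
across-class test is a one-way ANOVA with the six classes as groups and
clones as replicates, followed by Tukey HSD over the 15 class pairs.
Degenerate inputs are resolved explicitly: zero between-class variation
reports F=0, p=1; non-zero separation with zero replicate variance
reports infinite F with p floored at the smallest positive double.

## Exposure-signature derivation

The default derivation is mean-subtract: per-channel mean count across
exposed clones minus per-channel mean across control clones, negative
excesses floored at zero, renormalised to sum 1. The floor encodes the
assumption that the exposure only adds mutations. `support` is the
total positive excess — the number of mutations attributed to the
exposure. A `pooled` variant subtracts raw pooled counts instead,
useful as a sensitivity check when clone numbers are unbalanced (with
equal clone counts it is identical up to scale). Whether counts,
proportions or per-Mb rates are the right subtraction basis is an open
design question in this kind of analysis; counts are the default here
because the clones share one genome and sequencing design, making
per-clone totals directly comparable. No pseudocount is added by
default (a `pseudocount` parameter exists, default 0) so sparse
channels are not silently altered. An all-non-positive excess raises
an error instead of returning a zero vector.

## Catalogue comparison

Cosine similarity is the standard shape metric for non-negative
profiles; rankings use a stable sort so ties preserve catalogue column
order. Identical vectors short-circuit to exactly 1.0. Exposure
refitting solves non-negative least squares (scipy's active-set NNLS);
the contract is agreement with a dense 1e-3 grid search on
two-signature problems, which the test suite and acceptance script
verify. No reference catalogue is bundled; COSMIC-format TSVs load as
ordinary user files.

## Selection statistics

**Gene enrichment.** Under the null, mutations fall uniformly on an
effective genome of length G, so a gene with footprint f expects
λ = N·f/G of N total mutations. Upper and lower tails are Poisson by
default with an exact-binomial option (they agree closely whenever
f/G ≤ 1e-3). Over- and under-mutation are controlled as two separate
one-sided Benjamini–Hochberg families at q < 0.05, mirroring the
separate "overmutated" and "protected" calls such analyses report. A
trinucleotide-composition-adjusted null is a possible extension but is
deliberately not the default: the stated null is uniform placement.

**Rate vs transcription.** Genes with expression values are ranked and
split into equal-size bins (deciles by default); each bin's rate is
its mutation count divided by its footprint in Mb, and the rate is
regressed on the bin's mean expression rank (default), mean expression,
or mean log10 expression by OLS. Gene-level bins (rather than genomic
windows) are used because expression is a per-gene quantity. Flat
rates report slope 0 with p=1; an exactly linear set of bins reports
R²=1 with the p-value at its floor.

## Simulator

The generator emulates the study design the analysis assumes: i.i.d.
random reference contigs at a configurable GC fraction (default 0.41,
human-like), control clones drawing from a background process and
exposed clones from background + exposure, with per-clone burdens as
Poisson means. Default study conditions are 3 control and 4 exposed
clones; the default derivation-recovery experiment uses background
burden 3000 and exposure burden 5000 mutations per clone.

The default process spectra encode the qualitative structure of
polycyclic-aromatic-hydrocarbon mutagenesis against an endogenous
background: the background SBS spectrum is transition-enriched (C>T
0.42, T>C 0.33 of mass, uniform across contexts within class), the
exposure SBS spectrum is C>A-dominated (0.75 of mass, with a mild
5′-flank preference), the exposure DBS spectrum is CC>AA-dominated
with TG>AT and TG>CA, and the exposure indel spectrum concentrates on
single C deletions in homopolymer runs of two to four C/G. Background
DBS/indel toys favour C>T-containing doublets and T-homopolymer
slippage. Doublets are 2% and indels 5% of each process's events by
default, matching the minor contribution of these event types to
substitution-dominated mutagenesis. All six spectra ship as TSVs under
`exposig/data/`.

Sites are sampled channel-conditionally from precomputed indexes
(trinucleotide centre positions, doublet starts, maximal homopolymer
runs by base and exact length), so classifying the emitted records
reproduces the generating channel exactly — the suite asserts 100%
truth agreement. Site search is implemented for the 1-bp portion of
the indel scheme (the portion the exposure/background toys use);
requesting a ≥2-bp indel channel raises an error naming the channel.
Events keep at least one untouched reference base between them within
a clone, so independent SNVs never form accidental doublets.

When `expression_rate_slope` β is set, substitution placement weight
inside a gene becomes 1 + β·expression (uniform elsewhere),
implemented as weighted sampling within each context pool. Because
placed events block their immediate neighbourhood, very high local
densities slightly saturate hot regions and shrink the realised slope;
recovery experiments therefore use densities where blocking is
negligible (≲1% of bases blocked), stated alongside each experiment.

The master seed fans out via `SeedSequence.spawn` — stream 0 the
reference, stream 1 gene placement/expression, streams 2+ the clones
in sample-sheet order — so a study regenerates byte-identically from
its config, and per-clone streams are independent.

**What the simulator does not model**, and hence what passing recovery
tests do not establish about real data: sequencing and variant-calling
errors, coverage bias, subclonal structure, chromatin- or
replication-timing-dependent mutation rates, transcription-strand
bias, and real genome composition (repeats, GC heterogeneity). The
simulator validates the analysis machinery, not the upstream calling
pipeline.

## Numerical and I/O conventions

VCF and mutation records are 1-based inclusive; BED is 0-based
half-open; conversions happen only at the I/O boundary. By default
only PASS/'.' VCF records are kept (`keep_all_filters` disables this;
variant-caller FILTER policies vary, so the choice is explicit).
Signature catalogue columns are renormalised to unit sum at load;
channel label sets are validated exactly against one scheme, with
missing, duplicated, unknown or negative entries fatal. Catalogue
matrices are written channels-as-rows and re-read in either
orientation. Profile weight sums are maintained to 1 within 1e-9.
P-value floors use the smallest positive double rather than 0 so
downstream log-transforms stay finite.

## Problem sizes used in the shipped experiments

The acceptance script and test suite run the recovery experiment on a
0.5 Mb two-contig genome (burdens 3000/5000 across 3+4 clones,
~41 000 mutations), the null calibration on 200 genes × 20 replicates
(18 000 placements each), and the regression recovery on a 1.5 Mb
genome with 150 expressed genes and 8 000 coupled substitutions.
These sizes give sampling errors comfortably inside the asserted
bounds while the generator's site-blocking stays negligible.

## Known limitations

- The DBS palindromic-alt representatives differ from some published
  catalogue conventions (the collapse classes are identical); loading
  a catalogue that uses different representatives for the four
  palindromic refs will fail label validation rather than mis-assign.
- The uniform-placement enrichment null ignores sequence composition;
  genes with unusual trinucleotide content under a highly
  context-specific process will deviate from it for reasons other
  than selection.
- `merge_adjacent_snvs` merges unphased adjacent SNVs; without phase
  information a coincidental pair on opposite haplotypes would be
  merged incorrectly (rare at clone-level mutation densities).
- The simulator draws mutations independently given the signature;
  it does not model kataegis-like clustering.
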