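# Methods

## The mapping problem

`bsapilla` implements bulked-segregant analysis by sequencing (BSA-Seq)
for a monogenic dominant trait in a selfing crop — the motivating case is
husk papilla density in foxtail millet, where plants with papillate husks
take up water and germinate faster than smooth-husked plants.  Two inbred
parents fixed for alternate alleles are crossed; the F2 segregates
3:1 phenotypically (dominant trait) and 1:2:1 per marker.  Thirty
individuals from each phenotypic extreme are pooled into a papilla bulk
and a non-papilla bulk, both bulks are sequenced, and pooled allele
frequencies are compared marker by marker.

## The delta index

With the papilla parent P1 designated as the reference parent, the
per-bulk index at a marker is the fraction of reads carrying the non-P1
allele: 0 when the bulk matches P1 entirely, 1 when it is completely
mismatched.  The delta index is

    delta = index(non-papilla bulk) − index(papilla bulk).

For a dominant locus with perfect tail bulks, the non-papilla bulk is
homozygous non-P1 at the causal locus (index 1) while the papilla bulk
mixes P1/P1 and P1/P2 genotypes in a 1:2 ratio (non-P1 allele frequency
(0·1 + 1·2)/(2·3) = 1/3), so the expected delta at the causal locus is
1 − 1/3 = **2/3**, decaying as (2/3)(1 − 2r) with recombination fraction
r and fluctuating around 0 at unlinked markers.  The index is
read-count based (depth-weighted within a marker, unweighted across
markers), which matches its continuous 0–1 semantics; markers with zero
depth in either bulk are excluded and counted rather than imputed.

## Marker screen

Only parental homozygous-differential sites are informative.  The screen
keeps sites where both parents are homozygous for different alleles and
drops heterozygous-parent, non-differential, missing and low-depth
(either bulk total depth < 8 by default; standard pooled-sequencing
practice, configurable) sites, with a report that exactly partitions the
input.  Multi-allelic and symbolic sites are dropped (optionally split)
at load.  "P1 allele" is whichever VCF allele parent 1 carries, REF or
ALT, so the index convention does not depend on which parent matches the
assembly.  Sites are classified SNP when both alleles have length 1,
InDel otherwise; SNP and InDel tracks then flow through identical
machinery.

## Windows and candidate intervals

The windowing scheme is a design choice of this package: sliding windows
of 1 Mb with 100 kb steps (configurable), arithmetic mean of the marker
deltas inside each window.  A window qualifies when it holds at least 5
markers (guards against single-marker artifacts; configurable) and
|mean delta| >= 0.5.  The 0.5 screening line is treated as inclusive
(>=).  Qualifying windows on a chromosome are merged while they overlap
or touch; each merged interval reports its span, supporting marker
count, and the position and value of its peak |delta| marker.  Empty
windows are flagged and never thresholded.  Coordinates are 1-based
inclusive internally; BED exports are 0-based half-open.  Per-chromosome
summaries count **markers** (not windows) with |delta| >= threshold and
report the global |delta| argmax; counting markers is an interpretation,
flagged here because window-counting is equally defensible.  A
permutation band (sign-flip of marker deltas, quantile of |window
mean|) is available but off by default — the analysis uses the fixed
0.5 line, not a simulation-based envelope.

## Co-localization and expression filtering

Genes (GFF3 `gene` features, identity from the ID/Name attribute,
duplicates rejected) are assigned to intervals by any-bp overlap under
inclusive coordinates, strand-agnostic — the most permissive standard
rule; an optional stricter mode additionally requires the gene to
contain an above-threshold variant.  Candidate gene sets from two
independent F2 populations are intersected per marker class, and the
SNP-common and InDel-common sets are unioned (inclusion–exclusion holds
by construction) into the final co-localized list.

Expression over four husk/panicle stages (S1 panicle-branch
differentiation, S2 heading, S3 husk pollination, S4 husk filling;
replicate FPKM columns averaged arithmetically) is discretized per stage:
high at FPKM >= 1, off below 0.1, low in between.  The cutoffs are
community-standard defaults — "highly expressed" is not defined more
precisely by the motivating study — and both are configurable.  Labels
are assigned in precedence order (all-off, all-high, high-first-two,
high-second-only, high-last-two, low-first-three, other) so they are
mutually exclusive and exhaustive.  Because papilla cells are fully
differentiated by the pollination stage (S3), the candidate filter keeps
genes peaking in the first two stages: label `high_first_two` **or**
`high_second_only`.  Admitting the second-only pattern is deliberate:
the five-candidate outcome the pipeline reproduces counts one gene
highly expressed only at the second stage among the candidates, so the
union of the two early-peak patterns is the reading consistent with a
five-gene selection from the 4 + 1 early-peak genes of the 72-gene
partition.

## Segregation testing

Observed (dominant, recessive) counts are tested against an a:b ratio
with the uncorrected chi-square goodness-of-fit statistic on one degree
of freedom.  No Yates continuity correction is applied: the corrected
statistic for a 128:36 split against 3:1 would be ~0.659, whereas the
uncorrected value 0.813 is the convention these reports follow.
Observed ratios are rendered to one decimal as "x.x:1".  Water uptake is
Wr% = (Wa − Wb)/Wb × 100 and germination is the germinated fraction;
time-course ANOVA of uptake curves is out of scope (routine,
off-the-shelf).

## The simulator

The synthetic generator produces exactly the structure the analysis
assumes, so that every downstream guarantee can be tested against a
planted truth:

- **Genome**: 9 chromosomes × 40 Mb by default, 2,000 markers per
  chromosome at uniform random positions, causal locus at
  chr5:20,000,000 (moved onto the nearest marker so the locus is always
  genotyped).  ~15% of markers are InDels, the rest SNPs; parental
  REF/ALT orientation is randomized per site (~30% of sites have P1
  homozygous-ALT) to exercise the orientation logic.
- **Genetic map**: linear bp→cM at 3 cM/Mb per chromosome (no map is
  available for calibration; a constant rate is simple and adjustable).
- **Gametes**: first-order Markov chain along ordered markers with
  Haldane's function r = (1 − e^(−2d))/2, no interference.  Each F2 is
  the union of two independent F1 gametes.
- **Phenotype**: papilla iff >= 1 P1 allele at the causal marker
  (dominant; the papilla allele rides the P1 parent, mirroring the
  papillate paternal lines of the motivating cross), or homozygous P1
  under the recessive flag.  A null genome (no causal locus) assigns
  phenotypes as independent Bernoulli(3/4) draws so bulk composition is
  unrelated to genotype.
- **Bulks**: 30 per phenotype class by default, sampled uniformly
  without replacement.
- **Reads**: per marker, depth ~ Poisson(λ = 50 by default); each read
  flips allele with probability e (default 0.002, a typical post-filter
  short-read error rate), so the non-P1 count is
  Binomial(depth, f(1−e) + (1−f)e) with f the bulk's true non-P1
  frequency.
- **Fixtures**: parent VCFs (homozygous opposite alleles), bulk VCFs
  with pooled AD fields, a GFF3 of genes tiled every 100 kb, and an FPKM
  matrix with planted stage patterns; the genes nearest the causal locus
  are planted with the high-first-two pattern so the full pipeline has a
  known candidate truth.  All outputs are byte-identical under a fixed
  seed.

The default F2 size is n = 300 — comfortably above the ~164–182 plants
typical of real populations of this kind, chosen so both 30-plant bulks
exist with near certainty while the run stays at seconds.  What the
simulator does **not** emulate: mapping/calling artifacts (multi-allelic
noise, allele-depth bias, mismapping), segregation distortion, linkage
between phenotype misclassification and genotype, and polygenic or
incompletely penetrant traits.  Passing tests therefore demonstrate the
statistical machinery under the stated model, not robustness to real
sequencing pathologies.

## Replicate studies and problem sizes

`bsapilla.studies` measures the operating characteristics; the
acceptance script replays them from scratch:

- **Delta expectation**: 200 replicates on a 2 × 40 Mb genome (11
  markers each), n = 240 F2, bulks of 30 at 50×; mean delta at the
  causal marker vs the exact 2/3 and at an unlinked mid-chromosome-2
  marker vs 0.
- **Locus recovery**: 50 seeded runs at the full default scale (9 × 40
  Mb, 2,000 markers/chromosome, n = 300): fraction of runs whose called
  SNP interval contains the causal position, and whose chromosome
  summary puts both the above-threshold count maximum and the |delta|
  argmax on chromosome 5.
- **Null control**: 50 runs of the null genome: overall fraction of
  markers at |delta| >= 0.5 and the number of runs calling any
  >= 5-marker interval.
- **Segregation calibration**: 200 cohorts of n = 300; fraction passing
  the 3:1 chi-square at alpha = 0.01.

These sizes give Monte-Carlo standard errors well inside the assertion
bands (e.g. SE of the causal-delta mean ≈ 0.006 against a ±0.05 band)
while the whole battery runs in well under a minute.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; replicate studies derive child seeds from a
  `SeedSequence` so replicates are independent and reproducible.
- Threshold comparisons use `>=` everywhere (documented boundary
  inclusion).
- Zero-depth markers: excluded from index tracks, counted.
- Empty window-track / empty interval list / all-zero delta track:
  summaries report no argmax; plots render without error.
- A causal position falling between markers is attached to the nearest
  marker at map construction.
- Chi-square with a zero expected cell, negative depths, off-unit
  thresholds, and inconsistent filter reports all raise `ValueError`
  eagerly.

## Known limitations

- Counts that depend on the real sequencing data (genome-wide screened
  site totals, per-population interval gene counts, specific gene
  identities) are not reproducible without the raw reads; the package
  verifies the method's structure and statistics on synthetic truth
  instead.
- The windowing scheme, the marker-vs-window counting convention, and
  the expression cutoffs are explicit interpretations where the
  originating analysis left the choice unstated; all are configurable.
- Single biallelic locus only: no multi-locus models, no quantitative
  phenotypes, no structural variants, no selfing beyond F2.
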