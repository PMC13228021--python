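# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions that make results reproducible.

## Simulated study conditions

The simulator generates strains on a 16-chromosome layout whose lengths
and centromere positions are the budding-yeast chromosomes downscaled
10× (~1.2 Mb total).  The downscaling keeps whole-pipeline tests in
seconds while preserving relative chromosome sizes, so "small
chromosomes are aneuploid more often" scenarios remain representable.
Defaults define the study conditions and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| heterozygous SNV density | 1 per 300 bp | gives ~4,000 assessable het sites genome-wide at 1/10 scale, comparable (after scaling) to a moderately heterozygous diploid |
| mean depth | 80× | typical short-read resequencing depth for yeast |
| site depth model | Poisson(mean × copy/ploidy) | no per-site depth distribution is established for such data; Poisson is the minimal model and is config-exposed |
| window width | 1 kb (≙ 10 kb real scale) | ≥ 23 windows even on the shortest chromosome |
| window depth model | Poisson read counts at 150 bp reads, rescaled to depth | gives ~4 % depth CV per window, a realistic shot-noise floor |
| homozygous-site support | 0.995 | real data never shows 100 % support; a residual error rate keeps the 90 % rule non-trivial |
| InDel repeat-context fraction | 0.82 | the dominant replication-slippage share of small InDels |
| ploidy | one of {2, 3, 4} | the range observed across industrial strain collections |

At a heterozygous site with *a* alternate copies of *c*,
`alt_depth ~ Binomial(depth, a/c)`; LOH-tract sites are flipped to
homozygous (alt- or ref-fixed with equal probability) before sampling.
Tract classes are geometric by construction: interstitial tracts keep a
clear gap to both ends, terminal tracts abut an end, UPD covers the
chromosome.  Every planted tract is guaranteed at least one emitted
site (a site is added at the tract midpoint if sampling left none).

HGT contigs carry mutated copies of reference ORFs with
`round((1 − identity) × length)` substitutions at uniformly chosen
distinct positions and no indels, so realized substitution identity
equals the request to within rounding; telomeric contigs end in ≥ 8
tandem copies of the TG-rich telomere motif.  Planted InDels hit
mononucleotide runs (≥ 4 bp) or dinucleotide microsatellites (≥ 3
units) for the repeat fraction — an exact count, `round(f·n)` — and
screened repeat-free context otherwise.

**What the simulator does not emulate:** mappability and GC biases,
read-level errors and quality scores, recombination as a forward
process over generations, subclonal mixtures, and real yeast sequence
composition (the reference sequence is i.i.d. random, so repeat density
is lower than in real subtelomeres).  Passing recovery tests therefore
demonstrates correctness of the inference logic under the stated noise
model, not robustness to alignment artifacts in real data.

## Ploidy inference

Candidates are restricted to {2, 3, 4}; higher ploidies are nearly
unidentifiable from allele fractions at these depths.  The score is the
mixture log-likelihood minus (c − 1)·log n — a BIC-style penalty that
counts mixture components, chosen because the model family is nested in
practice (the tetraploid mixture contains the diploid 50 % component).
Discrimination of 4n from 2n rests entirely on the 25 %/75 % components,
which is why per-candidate scores are always exposed.  Ties break toward
the smaller ploidy.  Sites are usable at total depth ≥ 10 with support
inside (0.10, 0.90); fewer than 200 usable sites yields *undetermined*
rather than a guess.  When aneuploid chromosomes are known from a prior
coverage analysis they can be excluded, since a trisomic chromosome in a
diploid contributes 1/3–2/3 fractions that mimic triploidy.

## Aneuploidy and segmental CNVs

Chromosome copy number uses the per-chromosome **median** of the
normalized depth ratio (robust to segmental events), scaled by the
baseline ploidy and rounded half-up; exact .5 estimates therefore round
up, and the 80 % window-support gate decides whether the call stands.
Chromosomes where no copy state reaches 80 % support (e.g. subclonal or
heavily rearranged) are reported euploid with a low support fraction
rather than forced into a discrete call.  Segmental events need ≥ 3
consecutive windows deviating ≥ 0.3 copies in one direction; boundaries
are window-resolution by design (no split-read evidence is consumed).
"Terminal" means within two window widths of a chromosome end.
Known depth-artifact contigs (rDNA, mitochondrial) can be deny-listed.

## LOH

The 90 % read-support rule is applied two-sidedly (support ≤ 10 % is
also homozygous): alternate-allele support of a reference-homozygous
site is near 0, and the mirrored comparison is written as
`(1 − support) ≥ threshold` so the rule is exactly symmetric in floating
point.  The same threshold serves all ploidies; triploid 33 %/66 % modes
affect heterozygous-site detection, not the homozygosity cut.

Run segmentation is a greedy left-to-right scan for maximal tolerant
runs: a run starts and ends homozygous, contains no two adjacent
heterozygous calls, and tolerates at most one heterozygous interruption
per 50 sites (`floor(0.02 × run length)`); runs need ≥ 10 member sites.
The tolerance absorbs isolated genotyping errors without bridging real
heterozygous blocks.

Positional classes: UPD when a segment contains ≥ 95 % of the
chromosome's assessed sites; terminal when it reaches within 3 assessed
sites of either outermost assessed site; interstitial otherwise.  The
homozygosity denominator is the **assessed span** (first-to-last SNV per
chromosome), not the chromosome length — where no SNVs exist,
homozygosity is simply unobservable.

The pattern statistic is the fraction of total LOH length inside the
terminal 20 % of each arm (arms split at the centromere; 20 % separates
telomere-proximal mitotic events from a uniform meiotic background and
is config-exposed).  The null re-places each segment uniformly along its
chromosome, length-preserving, 1,000 seeded permutations.  Calls:
fully-homozygous at ≥ 99 % genome homozygosity; mitotic-dominated above
the null's 95th percentile; meiotic-dominated inside the central 90 %;
undetermined below the 5th percentile or with < 3 segments.

## Variant statistics

Divergence uses `years = ΔSNV / μ × g / 8760` with μ = 5×10⁻³ SNVs per
genome per division and g = 2 h; the SNV count is used as-is (no
division over the two lineages), which reproduces the conventional
endpoint estimates for these rates.  Pairwise distance is the symmetric
difference over exact (chrom, pos, alt) records — a shared position with
two different alternate alleles counts twice — and zygosity is ignored.
Codon-level effect annotation is an upstream annotator's job; the module
consumes labels, computing only frameshift status natively
(|Δlength| mod 3 ≠ 0 for coding InDels).

InDel repeat context examines a ≥ 21 bp reference window centred on the
anchor base, counting the event's own bases: deletions are assessed on
the reference sequence, insertions on the post-insertion sequence.
Mononucleotide runs ≥ 4 bp take precedence over microsatellites (≥ 3
tandem units of a 2–6 bp motif overlapping the event).

## Additional genes

Identity is defined over **global** alignment columns (match +1,
mismatch −1, gap −2, end gaps penalized; gaps count in the
denominator) — stricter and fully deterministic, unlike a local-alignment
identity which depends on the reported high-scoring pair.  The DP row
recurrence resolves the within-row gap dependency with a running
maximum; traceback tie-breaks are fixed (diagonal, gap-in-reference,
gap-in-query) so identity is reproducible, and the whole procedure is
verified column-for-column against an independent nested-loop oracle.
The additional threshold is inclusive (identity exactly 85.0 →
additional).  Candidate pairs must share ≥ 5 exact 15-mers; queries with
no candidate are additional with identity recorded as 0.  Comparison is
nucleotide-level, not protein-level.  Telomeric ends require ≥ 8 tandem
motif copies, each ≥ 90 % conserved, within the terminal 500 bp.

## Phenotype analysis

Relative biomass is endpoint OD under stress over endpoint OD in plain
medium (the readout time is config-level, not hard-coded).  Condition
clustering uses correlation distance with average linkage by default;
constant columns are rejected by name because their correlation is
undefined.  The fermentation period ends at the CO₂-loss plateau — the
first sampling interval after fermentation onset whose 8 h increment
falls below 0.05 g/100 mL — falling back to the full sampled range; the
fermentation-rate proxy is the ethanol titer linearly interpolated at
half that period.  Correlations are raw Pearson *r* with pairwise
deletion of missing strains; no multiple-testing correction is applied
by default (permutation p-values and Benjamini–Hochberg are available
behind flags) because the per-condition coefficients are reported as
estimates, not as a significance screen.

## Numerical conventions and edge cases

- Internal coordinates are 0-based half-open; variant tables and VCF are
  1-based at the boundary; BED is 0-based half-open.
- Sorting and normalization are idempotent; every reader/writer pair
  round-trips byte-equivalently after canonical sorting.
- Multiallelic VCF rows split into one biallelic record per alternate
  allele; zero-total-depth records are dropped with a logged count.
- Copy-number rounding is half-up (not banker's).
- 1 %-wide support bins are centred on integer percentages, so the
  triploid two-copy mode (true fraction 66.67 %) reports as the 67 bin.
- Empty inputs yield *undetermined*/NaN results, never exceptions,
  wherever the quantity is merely unobservable; impossible inputs
  (inverted windows, out-of-range tracts, zero-depth sites) raise.

## Known limitations

- Ploidy calls above 4n are out of scope; 4n vs 2n discrimination
  degrades at low depth where 25 %/75 % and 50 % overlap.
- CNV boundaries are window-resolution; no base-pair breakpoints.
- The LOH mechanism is inferred only genome-wide (positional pattern),
  never per event.
- The additional-gene screen measures sequence divergence only; it does
  not assign donor species.
- Recovery rates quoted by the test suite (e.g. ≥ 29/30 ploidy calls,
  ≥ 95 % CNV precision/recall) are properties of the simulator's noise
  model at its default depth, not guarantees on arbitrary real data.
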