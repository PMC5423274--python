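# Methods

`gbskit` models the design questions behind genotyping-by-sequencing (GBS)
in plant breeding: how many usable SNP markers a restriction-enzyme
protocol can deliver at a given sequencing effort, how read depth limits
genotype calling across ploidies, how missing-data handling affects
genomic prediction, and when genomic selection beats phenotypic selection
per year and per euro. This note records the models, the defaults and the
reasoning behind design choices; every number quoted here is computed by
the test suite or by `scripts/acceptance.py`, not asserted from memory.

## In-silico digestion and tag spectra

A restriction enzyme is a (possibly degenerate) IUPAC recognition string
plus a top-strand cut offset. Default enzymes use the standard
recognition sites ApeKI = G^CWGC, PstI = CTGCA^G, MspI = C^CGG; they are
plain data and can be replaced. Only sites palindromic under IUPAC
degeneracy are accepted (single-strand scanning is then complete);
non-palindromic enzymes are rejected at construction rather than silently
mishandled. All recognition matches are honoured, including overlapping
ones — a conservative superset verified in tests against a brute-force
scanner and against Bio.Restriction.

Coordinates are 0-based half-open. Fragments partition each chromosome
exactly (the concatenation of fragment sequences reproduces the input);
chromosome ends are labelled `CHROM_END`. If two enzymes cut at the same
coordinate the boundary is labelled with the alphabetically first enzyme
name — an arbitrary but deterministic tie-break for a vanishingly rare
event.

Amplifiability: a single-enzyme library needs an enzyme cut at both
fragment ends (chromosome-end fragments are dropped); a two-enzyme
common-adapter library keeps only fragments cut by *different* enzymes at
the two ends.

Tags are 64 bp read inward from each amplifiable cut, the right-end tag
reverse-complemented into read orientation. Fragments shorter than the
tag length follow a truncate-to-insert policy (no N padding); the two
tags of such a fragment are exact reverse complements, so only one is
kept. This mirrors read-through behaviour without modelling adapters.
Tag counts in this package are therefore *amplifiable fragment ends*, not
clustered unique sequences; with a sequenced reference the two coincide
up to repeat collapse.

Spectra: fragment-size classes default to 100-bp bins from 0 to 1400 plus
an open `>1400` class (15 classes); GC classes default to edges
0/0.15/0.25/0.35/0.45/0.55/0.65/1.0 (7 classes, equal 0.10 widths with
open ends). The class *counts* are the established convention; the exact
edges are a package choice, made so that 0.35 is an edge — the value
around which polymerase GC bias is usually described — and both are
configurable via `BinSpec`.

## Read sampling and amplification bias

Each genotype in a multiplexed library receives a fixed read budget,
allocated over tags by an independent multinomial draw with probabilities
proportional to per-fragment amplification weights. Weights factorise as
`size_weight(length) x gc_weight(gc)`: a log-normal kernel in fragment
length (PCR favours an intermediate size band) times a logistic in GC
fraction. Presets:

* `uniform` — all weights equal (the in-silico expectation);
* `kapa_like` — nearly flat (size amplitude 0.15, GC range 0.95–1.05): a
  polymerase with uniform amplification across sizes and GC;
* `neb_like` — size kernel centred at 250 bp (amplitude 3, baseline 0.3)
  and GC logistic rising from 0.6 to 1.6 around 0.35: a selective
  polymerase that over-amplifies 100–500 bp and GC-rich fragments.

No parametric bias fit exists to calibrate against, so the presets are
qualitative and *sign-testable*: tests assert the direction of enrichment
(100–500 bp over >1000 bp; GC>35% over GC<35%) and that the uniform
preset's observed-vs-expected deviations vanish as reads grow, not any
particular magnitude.

Downsampling to a common read number — the fair-comparison step when
libraries differ in yield — is multivariate hypergeometric thinning:
reads are removed uniformly without replacement, so column totals are
exact and per-tag expectations scale linearly. Read conservation (column
sums exactly equal the budget) is an invariant, not a statistical
property.

Scale: simulations run at desk scale — read budgets in the 10³–10⁵ range
over genomes of 30–150 kb yielding tens to hundreds of tags — standing in
for the 1.25–2.5 M reads per genotype over genome-scale tag sets of real
libraries. Because allocation is multinomial, per-tag depth depends on
budget and tag count only through the reads-per-tag ratio, which the
defaults keep in the realistic 5–100× range.

## Depth thresholds and genotype calling

Reads are modelled as error-free draws of the true alleles. At a truly
heterozygous locus with majority-allele fraction `f`, the probability
that all `n` reads show one allele — a heterozygote miscalled homozygous
— is `f^n + (1-f)^n`. The worst case over heterozygote dose classes is
`f = 1/2` for diploids and `f = 3/4` for autotetraploids (simplex/triplex
classes). The smallest `n` keeping this below alpha = 0.05 is 6 for
outbred diploids and 11 for autotetraploid homozygous calls; at depth 11
the tetraploid miscall probability is 4.22%. Note the minor-allele term
`(1/4)^11 ≈ 2.4e-7` is invisible at three significant figures, so the
same 4.22% results with or without it. A corollary the solver makes
explicit: a single read always looks homozygous (miscall probability 1),
so no error rate below 1 ever admits depth 1 — the solver's floor is 2.
For inbred material the binomial model does not apply (no heterozygotes
to protect); minimum depths of 2–4 are conventions, and the shipped
inbred rule uses 3 (configurable to 4 when residual heterozygosity is
expected, e.g. F6 lines).

Calls distinguish three classes — two homozygotes and one pooled
heterozygote class (tetraploid Aaaa/AAaa/AAAa collapse to code 1).
Allele-dosage resolution would need roughly 48× depth and is out of
scope. The calling rule is: both alleles seen and total depth ≥
`min_depth_het` → heterozygote; one allele seen at depth ≥
`min_depth_hom` → that homozygote; otherwise missing. The analytic
missing-rate expectation (`expected_missing_rate`) sums these outcomes
over an arbitrary depth distribution and is cross-checked against Monte
Carlo in tests; its heterozygote allele fraction defaults to 1/2 and is a
parameter so tetraploid dose classes can be analysed.

## Synthetic data

Genomes are i.i.d. base sequences with P(G) = P(C) = gc/2 — the simplest
composition model that makes GC-bin analyses meaningful. Recognition
sites can be planted exactly `k` times: sites are written at
non-overlapping random positions and chance background matches are
repaired by point mutation until the pattern count is exact, so a genome
with `k` planted sites yields exactly `k` internal cuts.

Panels: each tag locus segregates with probability `snp_rate`; allele
frequencies are uniform on [0.025, 0.5] by default so the 2.5% MAF filter
boundary is actually exercised. Inbred genotypes are homozygous (dose 0
or ploidy); outbred genotypes draw doses from Binomial(ploidy, p), a
Hardy-Weinberg-like choice made in the absence of a stated population
model. SNPs live in the 64-bp tag window (only tag-window variation is
observable in GBS), so one biallelic locus per tag is simulated.

Traits are additive: QTL sampled among segregating loci with N(0,1)
effects, plus Gaussian noise scaled so var(g)/var(y) equals the requested
heritability. True breeding values are always returned, so calling error
and prediction accuracy against truth are computable.

The end-to-end generator composes digestion → tag extraction → biased
read allocation → binomial allele sampling at each tag (alt reads ~
Binomial(depth, dose/ploidy)) → depth-rule calling. Missingness arises
from the depth rules and from nothing else. What the generator does *not*
emulate: linkage and recombination maps (loci are exchangeable),
sequencing error, barcode/adapter artefacts, repeat families, or
lane-level competition between genotypes beyond the fixed budget.
Passing tests therefore demonstrate the internal consistency of the
pipeline and the direction of its trade-offs, not calibrated error rates
on real libraries.

## Genomic prediction

Filtering: markers with minor allele frequency strictly below 2.5%
(heterozygotes contribute one copy of each allele; computed over
non-missing calls) are removed, the boundary retained; markers missing in
more than the threshold fraction (default 30%) are removed.

Imputation is K-nearest-neighbour (k = 5 by default; the literature
rarely states k, and 5 is small enough to respect family structure in
panels of 50–300 genotypes): neighbours by Euclidean distance over
jointly observed loci rescaled by locus count, distance-weighted mean
code rounded back to {0,1,2}. Observed entries are never altered. A
genotype sharing no observed locus with any other is an error naming the
genotype, not a silent mean fill.

The predictor is ridge-regression BLUP: `(W'W + λI)u = W'(y - ȳ)` on the
column-centred marker matrix. λ defaults to a Haseman–Elston
method-of-moments estimate — regress off-diagonal products of centred
phenotypes on the genomic relationship matrix `K = WW'/c` (c = mean
diagonal) to get σ²_g, then `λ = c·σ²_e/σ²_g` — with a log-grid inner-CV
fallback when the moment estimate is degenerate (σ²_g ≤ 0 or ≥ var(y)).
The moment route is deterministic and assumption-light; the fallback only
engages where moments fail.

Predictive ability is the correlation between cross-validation
predictions and observed phenotypes, pooled over the held-out folds of
each repetition and averaged over repetitions (default 10×10; fold-wise
correlations are also recorded but are noisy at small n). No rescaling by
the square root of heritability is applied — abilities are deliberately
conservative estimates of accuracy.

The missing-threshold sweep re-runs filter → impute → cross-validate per
threshold. Relaxing the threshold admits more markers but noisier
imputations; on sparse-coverage simulations ability at a 30% threshold
beats 0% in the majority of seeded runs, reproducing the
information-vs-imputation-noise trade-off qualitatively. The magnitude
and the exact peak location depend on coverage structure and are not
asserted.

## Selection-gain framework

Gain per year: `ΔG_P = i_P·h·s_A·r_gP/t_P` for phenotypic selection (h →
H for inbreds, from `H² = σ²_g/(σ²_g + σ²_ge/e + σ²_e/(e·r))`) and
`ΔG_G = i_G·r_A·s_A·r_gG/t_G` for genomic selection. Defaults `s_A = 1`
and `r_g = 1` put results in breeding-value standard deviations per year;
the ratio ΔG_G/ΔG_P is invariant to both.

Selection intensity is the infinite-population truncated-normal mean
`φ(z)/p` (z the 1−p normal quantile), verified against numerical
integration to 1e-6. A finite-sample order-statistics alternative
(`selection_intensity_finite`, expected mean of the top k of N) is
provided but never applied silently; at k = 15, N = 300 it gives 2.05 vs
2.06 — immaterial at these scales.

Equal-cost scaling: with phenotypic and genomic costs per genotype, the
same budget evaluates `N_G = N_P·cost_P/cost_G` genomic candidates, and
`i_G` follows from selecting k of N_G. The shipped alfalfa scenario
(h = 0.46, 15/300, 5-year cycle, 255 €/genotype vs r_A = 0.32, 1-year
cycle, 34 €/genotype) yields 2250 genomic candidates, i_G = 2.80 and a
4.72-fold per-year advantage. The shipped pea scenario (H = 0.84,
i_P = 2.06, 2-year cycle vs r_A = 0.48, t_G = 0.5) carries i_G = 2.39 as
a direct input, as in the original worked comparison; note that the
truncated-normal value at p = 15/1800 would be ≈2.73, a known
inconsistency in the source arithmetic that the package preserves on the
input side precisely because intensities are accepted as direct inputs.
With those inputs the pea comparison gives 0.865 vs 2.294 (2.65-fold).

Break-even accuracy solves `ΔG_G = factor·ΔG_P` in closed form
(`r_A = factor·acc_P·i_P·r_gP·t_G/(i_G·r_gG·t_P)`); composing it with the
comparison reproduces the factor exactly (round-trip identity, tested).
Multi-trait sizing is independent per-trait culling:
`N = k·(1/rate)^n_traits`, rounded up — e.g. 10 finalists, 4 traits at a
20% rate need 6,250 candidates. Cost-ratio summaries take min = low_P /
high_G, max = high_P/low_G and midpoint = mean_P/mean_G of the printed
ranges.

## Numerical and interface choices

* All randomness flows through `numpy.random.Generator` seeded
  explicitly; identical seeds give bitwise-identical outputs (tested).
* Genotype codes are 0/1/2 with NaN for missing in `pandas` frames; depth
  tables are tags × genotypes integer frames; everything serialises to
  TSV. FASTA I/O uses Biopython.
* Spectra with zero input return zero counts rather than NaN frequencies;
  values beyond the last size bin fall into the open-ended class.
* The CLI (`gbskit simulate|digest|sample|thresholds|predict|gain`)
  writes a `manifest.json` (subcommand, parameters, seed, version) next
  to every artefact so any output is reproducible from its manifest.

## Known limitations

* Tag identity is positional (fragment end), not sequence-clustered; real
  pipelines cluster reads and can merge repeats.
* The miscall model ignores sequencing error and mapping error; real
  thresholds would shift slightly upward under either.
* The bias presets are qualitative; fitting real observed-vs-expected
  spectra would require data this package does not ship.
* Selection-gain arithmetic is single-cycle and deterministic: no drift,
  no reduction of variance under selection, no economic discounting, and
  genetic correlations between selection and target environments are
  user inputs, not estimates.
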