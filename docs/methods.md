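# Methods

This note documents the models and numerical choices behind `famspace`:
what each analysis computes, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the design decisions
taken where more than one reasonable convention exists.

## Rank-encoded sequence-space PCA

Given a multiple sequence alignment, every residue is replaced by the
occurrence rank of its symbol within its column: the most frequent symbol
in a column receives rank 1, the next rank 2, and so on; symbols with
equal counts are ordered alphabetically by one-letter code. This turns the
alignment into an integer matrix on a common scale whose principal
components capture covarying patterns of residue usage across sequences.
PCA is computed by singular value decomposition of the column-mean-centred
matrix, with no unit-variance scaling — ranks are already commensurate
across columns, and scaling would inflate the weight of nearly conserved
columns whose small variance is mostly noise.

Conventions that are free choices and therefore fixed explicitly:

- **Rank direction.** Most frequent symbol = rank 1. The direction only
  reflects the principal axes, so any fixed convention yields the same
  analysis; this one makes "low rank = majority residue" intuitive.
- **Gap handling.** Default `gap_as_symbol`: the gap character competes in
  the per-column ranking like any residue (it is often the majority
  character in gappy columns, and treating it as data keeps the matrix
  complete and deterministic). Alternative `gap_worst_rank` always assigns
  gaps (max observed rank) + 1. Within a count tie the gap sorts after
  every amino acid, so amino acids keep their alphabetical tie-break.
- **Sign convention.** Each component's sign is chosen so its
  largest-magnitude loading entry is positive, making outputs
  reproducible.
- **Constant columns** (fully conserved positions) are retained with zero
  loading rather than dropped, so loading indices remain alignment column
  indices.

Family separation in a chosen score subspace is quantified as the mean
silhouette width over labelled sequences (Euclidean distance). Singleton
families are excluded with a warning since a one-member cluster has no
within-cluster distance. Values near 1 indicate tight, well-separated
family clusters; values near 0 indicate no structure.

## Position classification and structure mapping

Per-column conservation classes come from the loading magnitudes of one
chosen component (by default the second, which in family-labelled
alignments typically carries the between-family contrast): with
`m = |loading| / max|loading|`, a column is *variable* when `m > 0.30`,
*conserved* when `m < 0.10`, and *intermediate* otherwise. Both
inequalities are strict, so values exactly at a threshold are
intermediate. Magnitudes rather than signed loadings are used because the
component sign is a convention; the classification is invariant to
rescaling or flipping the loading vector. The classification can be
projected through an alignment-column-to-residue map onto structure
chains/residue numbers for colouring; duplicate residue targets resolve
last-writer-wins with a logged warning.

## Sequence-logo information content

For a column with observed residue frequencies `p_i` over an alphabet of
`A = 20` amino acids, the Shannon entropy is `H = -sum p_i log2 p_i` and
the information content `IC = log2(A) - H - e_n`, clamped at zero, with
the small-sample correction `e_n = (A - 1) / (2 ln 2 n)` for `n` observed
residues. Gaps are excluded from the frequencies (standard logo
convention). The correction is off by default so that closed-form checks
(`IC = log2 20 ≈ 4.32` bits for a fully conserved column; one bit less for
an equal two-symbol split) hold exactly; enabling it reproduces the
conventional logo estimator, which at very small `n` can exceed `log2 A`
and is why IC is clamped below at zero. Motif windows (e.g. Walker A/B
boxes of AAA modules) are specified in ungapped residue coordinates of a
reference sequence and mapped through its gaps onto alignment columns.

## Gene co-occurrence

Presence/absence calls per genome are inputs (producing them by homology
search is out of scope). For a gene pair the 2x2 contingency table over
genomes is tabulated; *nestedness* means gene A never occurs without gene
B. Because the biological claim ("A occurs only where B is present") is
directional, the attached test is the one-sided Fisher exact test for
positive association by default, with a two-sided option. No
phylogenetic correction is attempted: genomes are treated as independent
observations, which overstates significance when presence is clade-
correlated — the p-value is a descriptive summary, not a controlled
inference across a phylogeny.

## Hill-equation binding fits

The binding signal of a labelled species titrated with partner
concentration `S` is modelled as

    y(S) = U + (B - U) * S^h / (Kd^h + S^h)

with unbound signal `U`, bound signal `B`, midpoint `Kd` and Hill
coefficient `h`. Fitting is unweighted least squares
(`scipy.optimize.curve_fit`) on the raw signal, with no ligand-depletion
correction — the plain Hill form is the fitted contract. Auto-initialisation
uses the lowest-concentration signal for `U`, the highest for `B`, the
concentration nearest the half-signal for `Kd`, and `h = 1`. Bounds
`Kd in (0, 100 * max S]` and `h in (0, 10]` stabilise the fit: an
unbounded Hill coefficient is unidentifiable on sparse curves.
Non-convergence is reported through the `converged` flag, never silently.
Replicates are pooled by default, with per-replicate fits available by
fitting each curve separately.

## ATPase turnover and assembly fraction

In the pyruvate-kinase/lactate-dehydrogenase coupled assay, one NADH is
oxidised per ATP hydrolysed, so the ATP hydrolysis rate in µM min⁻¹ is
`|dA340/dt| / (eps * l)` with the NADH extinction coefficient
`eps = 6.22 mM⁻¹ cm⁻¹` and optical path `l` in cm. The path length must
be supplied by the caller — in plate-based assays it depends on fill
volume and well geometry and is not a universal constant. Dividing by the
ring-complex concentration (µM) gives turnover in ATP min⁻¹ complex⁻¹.

Size-exclusion traces are integrated per named elution window
(trapezoidal rule) after subtracting a straight baseline drawn between
the trace values at the window endpoints. The assembled fraction is
`(hexamer + dodecamer) / (monomer + hexamer + dodecamer)` peak area, a
quantity invariant to uniform scaling of all areas. Auto-derived windows
in the simulator span the peak centre ± 4σ: with endpoint-baseline
subtraction a ± 3σ window would clip ~2.7% of a Gaussian peak's area by
construction (6σ · amplitude · e^-4.5 under the baseline plus the tails),
while ± 4σ keeps the integral within ~0.1% of the closed form
`amplitude · σ · sqrt(2π)`. Overlapping auto-windows are clipped at their
midpoints and logged; strongly overlapping species would need
deconvolution, which is out of scope.

## Differential LFQ proteomics

Per protein, the log2 fold change is the difference of group means of
log2 intensities (or the log2 ratio of raw means when `log_transform` is
off), with the sign convention positive = higher in the knockout group.
The two-sided p-value always comes from a t-test on log2 intensities,
where intensity noise is approximately multiplicative. Welch's test is
the default (robust to unequal group variances); Student's t is available
— at five replicates per group Welch's Satterthwaite approximation is
slightly conservative (empirical type-I error ≈ 0.044 at nominal 0.05
under an equal-variance normal model, where Student's t is exact), a
known small-sample property worth keeping in mind when comparing counts
between the two tests. Zero intensities are missing values: the default
policy drops them per protein; `impute_min` substitutes half the smallest
positive intensity in the table. Proteins with fewer than two usable
values in a group are reported with a non-computable p-value and counted
as unchanged.

Volcano classification uses an inclusive fold-change cut
(`|log2 fc| >= log2 1.5`) and a strict p cut (`p < 0.05`), both
configurable; raw p-values are filtered by default, with a
Benjamini–Hochberg adjustment available but off. The COG summary tallies
accumulated/depleted proteins per functional class, excluding proteins
without a class and class S (function unknown), in alphabetical class
order.

## Synthetic data generators

All generators are pure functions of (configuration, seed) built on
`numpy.random.default_rng`, and each returns ground truth alongside the
data, so every downstream analysis can be validated by parameter
recovery.

**Family alignments.** A global consensus of length 300 carries four
embedded motif blocks mimicking the Walker A/B boxes of two tandem AAA
modules (e.g. `GPPGTGKT`, `ILLFDE`). Each of three families (20 sequences
each) derives its own consensus by mutating each site of the N-terminal
variable region (columns 1–90) with probability `p_v = 0.4` — two family
consensuses are then expected to differ at ~63% of variable-region sites,
modelling family-divergent N-domains against conserved ATPase modules.
Every sequence then receives independent per-site substitution noise
(`p_c = 0.05` outside blocks, the block's own rate inside) and per-site
Bernoulli gaps (probability 0.02, chosen as a typical alignment gap load;
site-wise gaps rather than indel blocks keep column bookkeeping exact).
Substitutions draw uniformly over the 19 non-consensus residues — no
exchangeability matrix — so the generator reproduces the variance
structure the PCA consumes, not realistic amino-acid chemistry or
phylogenetic correlation. Passing recovery tests therefore demonstrate
that the pipeline finds family-discriminating columns under idealised
independence, not performance on real alignments with tree-structured
correlation or indel blocks.

**Binding curves** add i.i.d. Gaussian noise to Hill values on a 1.5-fold
dilution series spanning 0.09–3.5 µM (ten points), the design used in the
titration experiments; recovery tests use generating constants 0.36 and
0.56 µM. **Chromatograms** are sums of Gaussians plus baseline and
optional noise, with windows auto-derived as above. **LFQ tables** draw
per-protein base log2 abundances from N(25, 2), replicate noise N(0, σ)
in log2 units with σ = 0.4, five replicates per group, and spike 10% of
proteins at ±1.5 log2 units in the knockout group (half each direction).
σ = 0.4 is calibrated so the combined volcano rule (fold change and
p-value together) detects spiked proteins essentially always while the
fold-change cut keeps the false-discovery proportion near 0.1: at
substantially larger σ the rejection region is governed by the p-value
alone and the false-discovery proportion among volcano calls rises toward
the raw-p expectation (~1/3 at these spike fractions), which no longer
represents a well-powered LFQ design. Real LFQ data additionally feature
missing-not-at-random dropouts, per-protein variance heterogeneity and
normalisation artefacts, none of which are simulated; the calibration
checks the statistics, not MaxQuant-style preprocessing.

## Problem sizes

Default test and acceptance runs use the generator defaults above: a
60 x 300 alignment, 100-replicate Hill recovery per dissociation
constant, exhaustive Fisher enumeration for table totals up to 30, and 50
seeded LFQ tables (1000 proteins spiked, 2000 null) for
sensitivity/false-discovery and type-I calibration. These sizes give
stable statistics (binomial 99% intervals of ±0.18 percentage points on
the type-I error) while keeping a full run in seconds.

## Known limitations

- The rank encoding discards residue identity beyond frequency order;
  two columns with the same frequency spectrum are indistinguishable.
- Silhouette-based separation assumes roughly convex clusters in score
  space; elongated clines can score low despite clean separation.
- The co-occurrence test ignores phylogenetic non-independence.
- The published differential-proteomics comparison tables (per-protein
  fold changes and p-values) are distributed as supplementary spreadsheet
  files; the volcano filter reproduces their reported accumulated/depleted
  counts only when those tables are supplied as TSV under `data/`
  (columns `protein`, `log2_fc`, `p_value`). The corresponding checks
  report this requirement when the files are absent.
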