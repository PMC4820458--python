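# Methods

## Virtual digestion

A genome is a named IUPAC nucleotide string with an explicit topology flag.
Restriction-site search is exact, top-strand only (HindIII's site is
palindromic, so one strand suffices): an ambiguity code in the genome —
including N — never matches a recognition base, so candidate sites running
through ambiguous stretches are conservatively dropped rather than expanded
into all compatible sequences. All overlapping occurrences are reported
(impossible for AAGCTT, possible for other enzymes); duplicate cut
coordinates are collapsed. Coordinates are 0-based half-open internally and
1-based only in human-readable reports.

Topology default is **linear**: phage DNA packaged in virions and extracted
for digestion is linear. Database records of the same phages may be
deposited as circular/replicative forms, so topology is a per-genome flag
and the pipeline records which mode was used. A linear genome with *k*
sites yields *k*+1 fragments including the terminal ones; a circular genome
yields *k* fragments, with the origin-spanning fragment fusing the two
linear ends; in both cases fragment lengths sum exactly to the genome
length (property-tested over random genomes of both topologies, and the
site finder is tested against a naive all-offsets scan oracle).

## Gel model

Migration follows a single log-linear regime, d(s) = a − b·log₁₀(s) with
b > 0 (mm per decade of size). This is adequate for the 0.5–25 kb range a
0.8% agarose gel resolves; no reptation correction is applied for very
large fragments, a documented limitation. The model is calibrated from a
ladder of ≥ 3 (size, distance) pairs by ordinary least squares on
log₁₀(size); the RMS residual is reported with the fit.

Lane rendering adds Gaussian noise **on distance** (not size), drops
fragments outside the detection window (default 100 bp – 50 kb), and merges
bands closer than the resolution limit (default 0.5 mm) into a single band
carrying the summed multiplicity at the mean position. Inferred sizes are
rounded to integer bp. Band distances are kept at full floating-point
precision in memory and rounded to 0.01 mm only in the lane TSV writer:
quantizing positions in memory would alone shift a ~30 kb fragment by
several bp through the exponential inversion and defeat the noiseless
round-trip identity (digest → render → infer equal to within ±1 bp), which
is the model's main internal check. The genome-size estimate is the
multiplicity-weighted sum of inferred band sizes and is biased low whenever
small fragments fall below detection — the report says so.

Every stochastic operation takes an explicit seed; there is no global RNG
state.

## Band matching and similarity

Two bands are the same band when their sizes agree within a relative
tolerance applied to their mean: |s₁ − s₂| ≤ tol·(s₁+s₂)/2, tol = 0.01 by
default. The tolerance is applied to molecular weight (the quantity the
profiles actually carry); applying it to gel run position instead would
require fixing a migration model first, and is available by running
profiles through the gel round trip.

Correspondence between two profiles is a maximum-cardinality one-to-one
matching over compatible pairs. It is computed as a rectangular assignment
problem (scipy's Hungarian solver) in which compatible pairs cost their
size discrepancy and incompatible pairs a big-M penalty chosen to dominate
any achievable discrepancy total: the optimum therefore maximizes the
number of matched bands first and minimizes total |Δsize| second, in one
deterministic solve. (A sorted two-pointer greedy would find the same
cardinality for this ratio-band compatibility structure, but the assignment
formulation gives the discrepancy-minimal matching without a separate
tie-break pass.) Symmetry is guaranteed by canonicalizing the argument
order before solving. The matcher is validated against exhaustive
enumeration of all one-to-one matchings on profiles of up to 8 bands.

Similarity is the Dice / Nei–Li band-sharing coefficient S = 2m/(n₁+n₂) —
the de-facto standard of gel-analysis software for band data — with Jaccard
available behind a flag. Distances 1 − S populate a symmetric matrix in
[0, 1]. Empty profiles are rejected: an uncut lane still carries its single
full-length band.

## UPGMA

Classic (size-weighted) UPGMA, not WPGMA: after merging A and B,
d(AB, C) = (|A|·d(A,C) + |B|·d(B,C))/(|A|+|B|), which equals the plain mean
over all leaf pairs. The merge node sits at height d_min/2, so branch
lengths are parent height minus child height and every tree is ultrametric
(checked to 1e-9). Equal minimal distances are resolved on the
lexicographically smallest pair of cluster minimum labels, and Newick
children are ordered by smallest subtree label — output is deterministic
across platforms and input orderings. On an input matrix that is already
ultrametric, the cophenetic matrix of the output tree reproduces the input
exactly. The implementation is cross-checked against scipy's `average`
linkage cophenetic distances on random matrices.

The cophenetic matrix of a general tree can exceed 1, so the distance-matrix
container carries a `unit_interval` flag: band-sharing distances enforce
[0, 1], cophenetic matrices do not.

## Biocontrol arithmetic

- `moi_dose(moi, host_density)` = MOI × host density (pfu/ml).
- `percent_reduction(control, treated)` = 100·(1 − treated/control); 100%
  iff the treated value is zero. `check_reported_reduction` recomputes a
  reduction from raw values and flags a quoted percentage that is not
  within one point of the computed one after integer rounding — useful
  because published percentages do not always follow from the printed raw
  counts.
- `tyramine_mm_to_mgkg(c)` = c × 137.179 (tyramine's molar mass, g/mol),
  assuming 1 kg of cheese ≈ 1 L of aqueous phase — the unit-density
  convention customary in the food-safety literature; the constant lives
  here because this is the only place it is needed.
- `host_range_summary` tabulates a spot-assay panel (susceptible count,
  total, percent to one decimal, per-origin breakdown). The packaged panel
  is a 27-strain *E. faecalis* collection of dairy, meat, human, clinical
  and type-strain origin.
- `qpcr_cells(ct, curve)` inverts the standard curve
  Ct = intercept + slope·log₁₀(N). The default coefficients
  (slope −3.32, the theoretical slope of a 100%-efficient reaction;
  intercept 40) are labelled placeholders — real use requires the
  laboratory's own calibration, which is why the curve is runtime
  configuration.
- `two_sample_t` is the pooled-variance Student's t (the test the assays'
  statistics call for), two-sided, with Welch's variant behind a flag.
  Degenerate zero-variance input raises instead of returning ±∞. Checked
  against an independently written textbook formula to 1e-10.

## Synthetic data generator

The generator emulates an RFLP typing study's inputs:

- **Genomes**: i.i.d. bases at a target GC fraction (default 0.37,
  enterococcal-phage-like), lengths defaulting to 40 kb within the 17–148 kb
  span of sequenced *E. faecalis* phages.
- **Evolution**: point substitutions along a user-supplied Newick tree with
  branch lengths in expected substitutions per site — along a branch of
  length ℓ each site mutates with probability 1 − e^(−ℓ) to a uniformly
  chosen *different* base. No indels: keeping lengths fixed keeps digest
  profiles directly comparable, and site gain/loss alone carries the signal
  RFLP typing measures. This deliberately omits real phage-genome features —
  mosaicism/recombination, modular architecture, terminal repeats, indels —
  so passing tests demonstrate the pipeline's correctness on clock-like
  substitution divergence, not robustness to rearrangement-driven profile
  change.
- **Challenge tables**: triplicate control-vs-phage observations with
  lognormal multiplicative noise (the standard model for plate counts),
  parameterized by the arithmetic mean, an effect fraction and a single
  coefficient-of-variation knob (default 0.1); the lognormal μ is offset by
  σ²/2 so the arithmetic mean is preserved.

All generators are bit-for-bit reproducible from their seed.

## Problem sizes used in validation

The reference checks run at sizes chosen to exercise realistic genome
scales while completing in seconds: the gel round trip on genomes of
16,945–147,589 bp (the span of the phage panel) plus a 31,280 bp genome;
topology recovery on 20 independent 6-taxon panels of 40 kb genomes
(within-clade branches 0.002 substitutions/site, 0.05 between — recovery
of the true clade split is required in ≥ 90% of panels, and observed in
95–100% across seeds); matching-oracle comparison on profiles of ≤ 8 bands
(exhaustive enumeration beyond that is factorial); t-test calibration on
1000 null simulations (observed type-I rate ≈ 0.05–0.06 at α = 0.05).

## Known limitations

- Single log-linear mobility regime; no band-intensity or densitometric
  modelling, no pulsed-field gels, no image analysis.
- No methylation sensitivity, star activity, partial or double digests.
- Substitution-only evolution (see above).
- The qPCR default curve is a placeholder, not a calibration.
- Gel-position (rather than molecular-weight) tolerance is exercised only
  through the explicit gel round-trip mode.
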