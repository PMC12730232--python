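# Methods

## Mass calculus

Element masses are the standard monoisotopic values (C 12 exactly,
H 1.00782503, N 14.0030740, O 15.9949146, P 30.9737615, S 31.9720707,
Na 22.9897693, K 38.9637065 Da); the proton is carried as H minus the
electron (1.00727646 Da). Isotope labels are exact mass shifts —
Δ(¹³C−¹²C) = 1.0033548, Δ(¹⁵N−¹⁴N) = 0.9970349 Da per substituted atom —
applied on top of the unlabeled formula, never by rewriting it, so
labeled-minus-unlabeled differences are exact by construction. The electron
mass is subtracted for cations and added for anions; at the 100 ppm
assignment tolerance it never changes an assignment (0.55 mDa ≈ 0.7 ppm at
*m/z* 800), but it keeps the arithmetic honest.

Class composition rules cover the glycerolipid, glycerophospholipid (diacyl
and lyso) and ceramide families. Each rule was cross-checked two ways: in
the test suite against an independent constructor that assembles every
species atom-by-atom from backbone + headgroup + chains − condensation
waters, and against ~70 literature ion assignments, of which all but two
agree within 100 ppm. The two outliers ([LPC 16:0+K]⁺ reported at 535.3,
[PE 20:0+Na]⁺ at 547.32) deviate by ~1 Da from the standard adduct
arithmetic; the source material does not explain them, so the consistency
checker reports them as flagged exceptions rather than forcing agreement.
Fatty-acid ¹³C precursors are modeled as singly labeled: every reported
labeled-ion *m/z* sits +1.0034 above its unlabeled form, which fixes the
convention. Sterols and cholesteryl esters have no closed-form rule (ring
systems break the acyl hydrogen arithmetic) and require explicit elemental
formulas; the one sterol in the reference surface is carried as C28H42O6.

Labeled shorthand uses `;O_k` suffixes counted relative to each class's
baseline (the ceramide family's baseline is `;O2`), and each `O-` ether
prefix substitutes −O+2H.

## Binning and datacubes

Spectra are binned to a uniform 0.05 Da axis over 100–1000 Da (18 000 bins),
half-open `[start + i·w, start + (i+1)·w)`; at *m/z* 800 a bin spans
62.5 ppm, which is why the 100 ppm annotation tolerance is the natural
floor. Bin assignment adds a 10⁻⁹ relative guard before flooring so exact
boundary values land in the upper bin despite floating-point division error
(5·10⁻¹¹ Da — far below anything chemically meaningful). Counts are summed,
not averaged, into bins (they are ion counts), stored sparsely
(pixels × bins CSR), and conserved exactly by binning and by imzML round
trips. imzML files are written in processed mode by default — per pixel,
the nonzero bins with their centers as the m/z array — because a continuous
128×128×18000 cube costs ~1.2 GB on disk for no information gain; since the
stored m/z are bin centers, re-binning on read is exact. Continuous mode is
available where interoperability demands it.

## ROI selection and normalization

Cell areas are found on marker-ion images: the phosphocholine headgroup
(184.07) in positive polarity, the sum of palmitate and stearate windows
(255.23, 283.26) in negative; windows default to ±1 bin. The marker image
is thresholded (Otsu by default, or a fixed fraction of the maximum) and
split into 4-connected components; components under 20 pixels — roughly the
smallest credible cell footprint at 128×128 over a 600 µm field — are
discarded. This replaces interactive vendor-software ROI drawing with a
reproducible operator; externally drawn masks can be supplied as PNG or TSV
pixel lists to bypass it.

Each ROI's spectrum is the per-bin sum over its pixels. Substrate
interference bins are zeroed *before* total-ion normalization (the order is
fixed and tested); whole 0.05 Da bins are removed because the instrumental
peak width at this binning is below one bin. The default interference list —
In⁺ 114.904 plus two cluster peaks per polarity — is a documented stand-in
for whatever the actual substrate contributes and is fully configurable.
Normalized spectra sum to 1 over retained bins, making cells of different
sizes and acquisitions of different doses comparable; every downstream
statistic is computed on these fractions.

## Abundance profile

Peaks are strict local maxima of the mean normalized spectrum above 10⁻⁴ of
the spectrum maximum and above a prominence of twice the median absolute
deviation of the whole spectrum (the median tracks the chemical background
because lipid peaks occupy a tiny bin fraction). The 45 most intense peaks
per polarity are ranked (ties to lower *m/z*), annotated at 100 ppm, and
summarized as per-class counts over the 90 entries. Entries are counted per
top peak, not per unique species — a lipid seen as [M+H]⁺ and [M+Na]⁺
counts twice, matching how such profiles are reported — with a
`unique_species` option that collapses adduct duplicates.

## Turnover comparison

`TurnoverModel` mean-centers the combined treated+control matrix
(unit-variance and Pareto scaling are options; centering-only is the
default because TIC-normalized intensities already share a scale) and takes
principal components by SVD. Among the leading three components — the depth
a SIMCA-style scores plot examines — the one whose scores best separate the
groups (largest pooled two-sample |t|) is chosen; if no leading component
reaches |t| ≥ 1 the selection is declared empty rather than inventing a
discriminant. The top 5% of bins by |loading| on that component are tested.
Restricting the search to leading components is deliberate: optimizing
group separation over all ~n components selects pure noise directions under
the null and inflates the downstream tests severely (measured: ~12–13%
false-positive fraction at nominal α = 0.05, versus ~5% with the leading-3
restriction — see the calibration below).

Each selected peak gets a two-sided Mann–Whitney U test: U from rank sums
with midranks for ties; exact enumeration of all C(n₁+n₂, n₁) group splits
when n₁+n₂ ≤ 20, otherwise the normal approximation with tie-corrected
variance and a 0.5 continuity correction. Direction is the sign of the
difference of group means of normalized intensity. Significance defaults to
raw p ≤ 0.05; Benjamini–Hochberg adjustment is a flag, and both p and
adjusted p are reported when used. Peaks lying within tolerance of a
library ion plus the arm's label shift carry an `isotope_shift` flag; at
100 ppm this flag can fire coincidentally (e.g. a PC potassium adduct
sitting one ¹⁵N shift above an unrelated PG sodium adduct), which is why it
is a flag and not an assignment.

Selection before testing is data-dependent and biases p-values toward
significance. This is quantified rather than hidden: on 500 null replicates
(incorporation f = 0, 8 vs 20 spectra at the default generator conditions)
the significant fraction among selected peaks is ≈ 0.05 (required window
0.02–0.09). When a real effect exists, the separating component aligns with
the group split and the selected noise bins are enriched for chance
differences — a well-known property of select-then-test workflows; the
`select=False` (test-all-peaks) mode bypasses selection entirely.

## The synthetic-data generator

The generator emulates the acquisition the analysis assumes, not the
instrument: per (pixel, bin) Poisson counts around an expected spectrum
composed of (a) on cell pixels, a 122-ion lipidome with delta-into-bin
peaks at the theoretical ion *m/z* (instrument peak width < bin width at
0.05 Da binning) and geometrically decaying intensities (ratio 0.93 per
abundance rank); (b) on background pixels, three indium-substrate peaks per
polarity; (c) everywhere, a uniform chemical floor (0.005 counts/pixel/bin).
Defaults: 128×128 pixels, 5 elliptical cells of 5–9 px semi-axes per field,
2000 expected lipid counts per cell pixel per polarity, 20 control and 8
treated ROI spectra per comparison (matching the emulated study's group
sizes), everything seeded. The top-90 lipidome entries carry the class mix
30 PC / 10 PS / 10 Cer / 8 SHexCer / 8 PE, and planted ions are validated
to sit at least two bins apart within each (polarity, arm) so ground truth
stays unambiguous.

Incorporation is intensity transfer at a fixed fraction f per target
species — a pseudo-steady-state picture of a multi-day incubation — not a
kinetic model; f defaults to 0.3, the smallest effect size at which the
power guarantee is stated. Labeling conserves each species' total expected
intensity exactly. Noiseless mode returns the expected signal itself
(lipids + substrate, no Poisson draws and no uniform floor) and exists for
exact-recovery checks: segmentation returns the planted masks, the profile
returns the planted ranks and class fractions identically.

Replicate-heavy statistical studies (power, null calibration) simulate at
the ROI-spectrum level — Poisson draws around per-ROI expected spectra with
lognormal (σ = 0.2) cell-size scatter — rather than rendering full images
per replicate, because the ROI spectrum is the statistical unit and the
imaging path (render → segment → sum) is exercised separately. Problem
sizes used by the shipped checks: 200 replicates for power, 500 for null
calibration, both at 8 vs 20 spectra on the full 18 000-bin axis.

## What passing tests do and do not show

The generator draws independent Poisson counts around a known truth. Real
ToF-SIMS data add matrix effects, detector saturation, topography,
charging, peak-shape tails across bins, and correlated biological
variability between cells — none of which are modeled. Recovery guarantees
on synthetic data therefore validate the *pipeline logic* (binning,
segmentation, normalization order, selection, test calibration, label
arithmetic), not instrument- or biology-level accuracy. Likewise the
abundance class mix planted here mirrors the headline composition of a real
neuronal membrane profile, but recovering it exactly says nothing about
real cells — it says the pipeline does not distort what it is given.

## Known limitations

- Sum-composition resolution only: no sn-positions, double-bond positions
  or geometry (omega-3 vs omega-6 is an incubation condition, not a
  spectral distinction), no isotope-envelope deconvolution, no MS/MS.
- Single-charge ions only; ST/CE require explicit formulas.
- The exact vendor substrate-peak list and the original PCA component/
  loading cutoffs are unknown; defaults are declared stand-ins.
- Turnover is direction/significance at one time point, not a rate.
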