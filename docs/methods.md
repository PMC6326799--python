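# Methods

This note documents the models, defaults and numerical choices behind
`nucfish`: what each stage computes, what the simulator does and does not
emulate, and where the design was genuinely open.

## Conventions

All physical quantities are micrometres; arrays are ordered `(z, y, x)` with
0-based voxel indices and voxel centres at `index * voxel_size`. Every
stochastic routine takes an explicit integer seed; nothing touches global
random state. The pipeline derives per-stage child seeds from the master
seed by hashing `"{seed}:{stage}"`, so stages are independently reproducible.

## The %DAPI coordinate system

A profile is a set of intensities sampled by trilinear interpolation at
evenly spaced positions along a line running cytoplasm → nuclear rim →
nucleolus. The sampling step defaults to half the smallest voxel dimension
(0.05 µm at the default 0.1 µm voxels). Each channel is rescaled to 0–100
with an affine map (floor → 0, maximum → 100). The floor is the profile's
1st percentile by default, which damps single-sample noise on real,
undeconvolved data; the exact minimum is available
(`normalize_profile(..., robust_min=False)`) and is what the unit tests use
on tiny hand-built profiles. Normalization is idempotent and invariant
under positive affine transforms of the raw intensities, and the DAPI peak
maps to exactly 100.

A query position is reported as a `DapiCoordinate`: the interpolated
normalized DAPI value (percent) plus the flank — *cytoplasmic* before the
DAPI argmax, *nucleolar* after it. The `depth` property maps the two flanks
onto one monotone axis (0 → 100 → 200) so positions on opposite flanks can
be ordered. All argmax operations break ties toward the profile start; this
is tested.

Two border calibrations aggregate per-profile values (mean, sd, n, fraction
below a 33.3% threshold):

* **marker peak** — %DAPI at the intensity maximum of a pore-ring marker; a
  marker that peaks on the profile boundary (monotone channel) warns and
  returns the boundary value;
* **intersection** — the first sign change of (normalized marker −
  normalized DAPI) walking in from the cytoplasmic end, located by linear
  interpolation; no sign change is an error, and a profile on which the
  estimator fails is dropped from the calibration rather than poisoned.

Per-spot rays run from the far cytoplasmic side through the spot to the
DAPI-weighted nucleus centroid (half-max threshold, intensity-weighted
centre of mass). A manual-line protocol cannot be reproduced
deterministically; the centroid ray is, and on ellipsoidal nuclei it is a
radial section like the published profiles. Four orthogonal in-plane rays
per nucleus are used for whole-nucleus calibration (the angular placement of
profiles is not fixed by the source procedure; orthogonal rays are the
symmetric default).

Focus-plane selection picks the z-plane with maximal intensity variance in a
chosen channel — the classic "maximum variance" focus heuristic — with
ties to the lowest index.

## Simulator

**Geometry.** Cell and nucleus are concentric ellipsoids (defaults: cell
semi-axes 1.8 × 2.6 × 2.6 µm, nucleus 1.0 × 1.1 × 1.1 µm) with a spherical
nucleolus (radius 0.35 µm) offset 0.3 µm from the nucleus centre. Ellipsoids
give closed-form inside/outside tests and an analytic ray/surface crossing,
which is the oracle every border estimator is validated against.

**Molecules.** Species fix the colour set (intact = red+ir+green, 5′ part =
red+ir, 3′ part = ir+green; a read-through molecule also carries all three
colours and is distinguished only by a two-gene probe map). Locations are
constructive: nucleus molecules stay clear of the surface band, cytoplasm
molecules clear of it on the outside, and periphery molecules anchor *on*
the nuclear surface with probes laid out along the local normal at ±0.2 µm —
5′-most probe outermost when the molecule is oriented 5′-out. Orientation is
an independent Bernoulli draw per periphery molecule at the configured
fraction, so measured fractions inherit binomial spread. All probes of one
molecule stay within the 0.5 µm compaction cap.

Same-channel spots of *different* molecules are kept separable by the
optics: the generator enforces a minimum separation of 0.6 µm measured in a
PSF-scaled metric (axial distances count for less because axial resolution
is ~2.3× worse). Two same-colour foci closer than the PSF are physically one
focus; since crowded-field analysis is out of scope, the ground truth is
kept recoverable by construction. This bounds the feasible per-scene
density (a dense-packing request fails loudly rather than silently
degrading).

**Optics.** DAPI is rendered as a smoothed indicator (nucleoplasm 1.0,
nucleolus 0.35, cytoplasm 0; Gaussian edge softness 0.15 µm), the pore ring
as a Gaussian shell on the nuclear surface, the cytoplasmic marker as a
smoothed cell-minus-nucleus fill. Each probe position adds a 3D Gaussian
with σ = (0.30, 0.13, 0.13) µm integrating to `photon_scale` counts.
Defaults: voxels 0.1 µm isotropic, background 10 counts, `photon_scale`
5000 (peak ≈ 65 counts above background, a realistic smFISH signal-to-noise
regime of ~7 over the Poisson background) — spot-intensity statistics are
not published for this system, so `photon_scale` is an explicitly free
parameter. Noise is Poisson on signal+background by default; a
variance-matched Gaussian mode and a noise-free mode exist for
variance-controlled and exactness tests. No chromatic shift, aberrations or
deconvolution are simulated.

**LFQ matrices.** Per-protein log2 abundance ~ N(25, 2²); replicate noise
sd 0.3; enriched proteins shifted by +2 log2 units in the second condition
(an on/off-like enrichment, the regime the nuclei-purification experiment
targets). Missingness is logistic in the per-value log2 abundance (midpoint
22, slope 1 per log2 unit), i.e. missing-not-at-random, and a few
reverse/contaminant/only-by-site rows are planted for the filter to remove.

**Sequences and hit tables.** Protein sequences are i.i.d. over the 20
amino acids with a 2% background glutamine rate; planted Q-rich 60-mers are
frame-aligned with ≥7 Q, and background windows are post-edited below the
threshold so planted counts are exact ground truth. Homology hit tables
plant reciprocal pairs (reverse e-value < 1e-5), non-reciprocal hits and
weak-reciprocal hits, so every branch of the RBH rule is exercised.

**What passing does and does not show.** The simulator has ideal ellipsoidal
geometry, flat backgrounds, isolated cells and exactly-Gaussian spots.
Passing recovery tests therefore validates the *estimators and rules*, not
their robustness to segmentation errors, autofluorescence gradients,
overlapping cells or chromatic misalignment, none of which are modelled.

## Spot analysis

Detection: local maxima above `median + k·1.4826·MAD` with the
neighbourhood matched to the PSF extent, brightest-first suppression of
duplicates within one PSF (ellipsoidal, 2σ per axis), and sub-voxel
refinement by least-squares fit of a fixed-σ 3D Gaussian (amplitude,
position, offset) on a ±2σ window. The default k = 7: at the default stack
size (~2×10⁵ voxels of Poisson background) k = 5 would admit several
pure-noise maxima per channel per stack, while genuine spots sit more than
20 robust sigmas above background; k is configurable.

Grouping: for each channel pair, mutual nearest neighbours within the
0.5 µm pairing radius are linked; links are merged ascending by length,
refusing any merge that would put two same-channel spots in one molecule
(equivalently: conflicting chains drop their longest link). The result is
independent of spot input order, and on scene-density fields it matches an
exhaustive max-links/min-total-distance oracle (at unrealistically dense
overlap, mutual-nearest-neighbour linking and the global optimum can
legitimately differ).

Location: the only hard rule published for the periphery is the band — any
signal in [10, 66.6] %DAPI (edges inclusive, configurable). Outside the
band the assignment is this package's decision: *cytoplasm* iff every
signal is below 10% on the cytoplasmic flank, otherwise *nucleus*
(including everything on the nucleolar flank). The 33.3% single-signal rule
is kept as a calibration statistic (`fraction_below_33`), not a classifier,
because it is probabilistic, not definitional. A molecule whose ray cannot
be evaluated is flagged unclassifiable and excluded from tallies.

Orientation: eligibility requires 5′ and internal spots whose connecting
segment (sampled at 64 points) hits the half-max DAPI nucleus mask;
"5′-first" compares flank-aware depths, not bare percents, so a 5′ spot
past the peak cannot masquerade as "further out". Zero eligible molecules
reports an undefined fraction (None), never 0. Analyses operate on the 3D
stack; note that projection analyses of real data can misclassify molecules
whose 5′ end loops back after export — one reason measured fractions sit
below 100% even for uniformly oriented molecules.

## Enrichment statistics

The moderated statistic is d = (mean₂ − mean₁)/(se_Welch + S0) with
S0 = 0.5; at S0 = 0 it *is* the Welch t statistic (verified against an
independent implementation to 1e-10). The contrast uses sorted condition
labels (so relabelling negates every d), overridable. The null comes from
balanced relabelings of the six sample columns with the identity split and
its complement excluded — a null containing the true grouping would
re-observe every real effect and saturate the estimated FDR at ~10%, which
is precisely what balanced permutation schemes avoid. 250 draws with
replacement by default; exact enumeration of the 18 splits is available and
used in tests. The estimated FDR at a threshold is the mean (median
optional) permutation exceedance count over the observed count, and the
significant set is the largest one with estimated FDR ≤ 0.05 (the empirical
FDR curve need not be monotone, so all candidate thresholds are evaluated).
The frontier is symmetric in |d|; per-side asymmetric frontiers are out of
scope.

Filtering keeps rows with ≥2 quantified replicates *in at least one
condition* by default — the stricter per-condition variant would discard
exactly the on/off proteins the experiment is designed to find — and the
alternative is one flag away. Imputation is per sample column (each column
re-centred by its own observed mean/sd), drawing missing values from
N(m − 1.8·s, (0.3·s)²); whether the original analysis environment imputed
per column or globally, and used mean- or median-based FDR estimation, is
not recorded, so both choices are explicit parameters here.

With triplicates, permutation-FDR power is intrinsically limited: a planted
shift of 2 within-group sd gives d ≈ 0.8 against a null d spread of ~0.33,
and the FDR-0.05 frontier lands where recall is ~15–20%. The power check
therefore plants the generator's default +2 log2-unit effect (recall ≥80%,
typically ≥85%); small-effect detection at triplicate scale is a
documented limitation, not a bug.

## Sequence statistics

`qrich_scan` divides the sequence into consecutive non-overlapping 60-mers
from a configurable frame offset (default 0; a sliding mode exists for
sensitivity analysis but is not the default, since "divided into 60-mers"
describes a partition). The trailing remainder below 60 aa is not scored.
The scored residue defaults to glutamine (Q): the statistic is named
*Q-rich* and prion-like low-complexity regions are glutamine-rich, but the
source description of the rule says "glutamate" — the residue is therefore
a parameter (`residue="E"` reproduces the literal reading). Density is
windows per 100 aa over the full sequence length.

`rbh_classify` takes the forward top hit (lowest e-value, ties by higher
bit score then lexicographic subject id), requires the reverse top hit of
that subject to be the original protein, and applies the strict e < 1e-5
cutoff to the *reverse* hit by default (the literal reading of the rule);
`cutoff_on="forward"` and `"both"` are available since the placement is
ambiguous. Proteins with no qualifying taxon are *unique*; otherwise
*shared_in_k*.

## Problem sizes

The test suite and acceptance script run at deliberately modest sizes — 40
calibration scenes, 25 scenes × 8 border molecules per orientation
fraction (200 eligible molecules), 50 Poisson scenes for count recovery, 25
null simulations of 200 proteins, 1,000 random sequences for the scan
oracle — chosen so the whole validation runs in well under a minute while
keeping binomial/Monte-Carlo error far below the tested tolerances.

## Known limitations

* One cell per scene; no segmentation of crowded fields.
* The nucleus locator is a half-max DAPI threshold + centroid; it assumes a
  single bright nucleus.
* Profile estimators on raw noisy data benefit from the optional 1-D
  profile smoothing; the published workflow deconvolved its stacks, which
  this package deliberately does not emulate.
* Permutation FDR with triplicates cannot resolve sub-sd effects (above).
* The simulator's free parameters (`photon_scale`, nucleolar DAPI level,
  periphery probe separation) are stated defaults, not measured values.
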