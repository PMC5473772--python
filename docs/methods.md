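# Methods

## Array design and assembly simulation

The hybrid array alternates two 17-bp operator motifs: OL1 (λcI) and UAS
(Gal4). The published construct does not include the exact motif and spacer
sequences, so the defaults are the canonical lambda OL1 operator
(`TACCTCTGGCGGTGATA`) and the Gal4 UAS consensus (`CGGAGGACTGTCCTCCG`); both
are user-overridable (`OperatorMotif`), and no downstream quantity depends on
the specific bases. OL1 is split at its midpoint (left half = first 9 nt);
the split point is configurable.

A building block reads `OL1-tail + spacer + UAS + spacer + OL1-head`. Spacers
(default 6 nt each) are random with a fixed dinucleotide at their first two
positions (`CT`, `AG`); randomisation is retried (bounded at 500 draws) until
no BpiI (`GAAGAC`) or BsaI (`GGTCTC`) recognition site occurs on either
strand anywhere in the doubled block (the doubling catches sites spanning
junctions). The 4-nt ligation overhang is the last four bases of the OL1
head, i.e. it lies *inside* the motif: the ligation scar is motif interior,
so concatenating a fragment ending in `OL1[:9]` with one starting at
`OL1[9:]` literally reconstitutes the motif. One assembly cycle checks
overhang compatibility, concatenates the sequences, sums the unit counts and
increments the step index; `assemble_to_target` requires a power-of-two
target (the scheme doubles the insert each cycle) and reaches *N* units in
`1 + log2(N)` steps, counting the initial block construction.

A raw *n*-unit ligation product carries *n − 1* internal full OL1 sites and
two terminal half-sites. Finalisation appends the missing tail half-site so
the emitted construct contains exactly *n* complete OL1 motifs next to *n*
UAS motifs — making the printed motif count directly checkable by substring
scan. The motif counter scans both strands non-overlappingly and
de-duplicates intervals (palindromic motifs are counted once per physical
site). Coordinates are 0-based half-open internally, 1-based inclusive in
GenBank output.

The reporter split partitions a 238-residue protein after residue 154 into a
154-residue N-fragment and an 84-residue C-fragment, applying the I152L
substitution (which suppresses spontaneous self-assembly of the halves)
before splitting. The bundled `SYNTHETIC_VENUS_LIKE` sequence is a synthetic
stand-in of the correct length with Ile at 152 — not the real mVenus
sequence, which is not redistributed here; all split arithmetic is
independent of residue identity.

## Occupancy model

Each adjacent OL1/UAS pair is one reconstitution site; a 64-unit array has 64
sites. Binding of the functional reporter-pair pool *P* to *S* total sites is
a single-class equilibrium (independent identical sites, no cooperativity):

    bound = K (P − bound)(S − bound)

solved in closed form as the smaller quadratic root, written in the
numerically stable form `2PS / (P + S + K_d + sqrt((P+S+K_d)² − 4PS))` with
`K_d = 1/affinity` in molecules per cell. Degenerate inputs return zeros;
infinite affinity returns `min(P, S)`. The model makes the copy-number
saturation argument quantitative: total bound signal is concave and
sub-linear in array count, approaching the pool size, while per-array
occupancy collapses.

Two background channels exist for the split system: a fraction of the
*unbound* pool self-assembles in the cytoplasm
(`free_complementation_rate`, default 0.002 — small because of I152L), and an
optional "assembly platform" mode (`platform_release_rate`, default 0)
diverts a fraction of complemented protein off the array into a
bound-proportional diffuse term, reflecting the alternative interpretation
that complemented proteins may leave the DNA while remaining fluorescent.
Both interpretations are therefore representable; the default is pure
equilibrium binding.

Defaults are order-of-magnitude choices, not measurements: 2000 reporter
pairs per cell for the induced bicistronic split system, 300 molecules for
the single full-length fusion (modelled as more weakly expressed), affinity
10 (K_d = 0.1 molecules — tight operator binding), 64 sites per array. The
limiting-pool scenario uses 110 pairs against 20 arrays (1280 sites), i.e. a
pool well below the total site count, which is the stated mechanism for
sub-linear multicopy response.

## Synthetic microscopy

Cells are capsules (rectangle plus semicircular caps) with area drawn from a
truncated normal (mean 250 px², SD 60), width ~9 px, random orientation,
placed by rejection sampling with a minimum 6-px gap between cell boundaries
so that diffraction skirts of neighbours never touch; geometry is in pixels
throughout (no physical pixel size is assumed). Per-cell expression varies
log-normally (CV 0.3) and feeds back through the titration, so focus and
diffuse components covary across cells as they do in real populations.

Photon composition per cell: cytoplasmic fluorescence (unbound pool for the
full-length construct; spontaneously complemented plus platform-released
protein for the split construct; zero for the empty control) plus
autofluorescence (3 photons/px) follow a cylindrical projection profile
(chord depth, brighter over the axis), normalised so integrated photons equal
level × area exactly. Each array copy contributes one focus on the central
80% of the midline with photon yield `bound_per_array ×
brightness_per_fluorophore` (default 25 photons per bound fluorophore over
the exposure; strain-specific exposure times are absorbed into this factor
and the gain). The frame is blurred with an isotropic Gaussian PSF (σ = 1.3
px, truncated at 4σ; the 12-px placement margin keeps blur losses at zero so
photon totals are conserved to floating-point precision), then Poisson shot
noise, linear gain (20 counts/photon, EM-CCD-like), offset (10 counts),
Gaussian read noise (SD 2 counts), rounding and clipping to 16 bits. With
these defaults no pixel approaches the 65,535 ceiling, so the 65,000
saturation filter is inert on synthetic data — it is exercised by direct unit
tests instead.

What the generator does *not* emulate: phase-contrast channels, 3-D or
time-lapse imaging, cell–cell contact and overlap, focus colocalisation
between sister loci, fluorophore maturation kinetics, photobleaching, and
uneven illumination. Passing regime tests therefore show that the analysis
pipeline recovers the intended statistical structure from data with realistic
noise and geometry — not that it would survive every artifact of a real
microscope session.

## Segmentation

Detection runs on the fluorescence channel only (no phase channel is
rendered). A plain global Otsu threshold fails in the low-background regime:
the class split lands between cytoplasm and the bright foci, not between
background and cytoplasm. The detector therefore thresholds the
log-transformed image with multi-class Otsu (3- and 4-class cuts pooled),
choosing the lowest cut that keeps the foreground a minority of the frame,
with a contrast guard (foreground mean must exceed background mean by 4
background SDs — a pure-noise frame yields an empty mask), hole filling, a
radius-2 opening to break diffraction-skirt bridges between neighbours,
8-connected components and an area filter (50–5000 px). Object-level
precision and recall against ground truth are ≥0.95 across all default
regimes; matching uses truth-coverage > 0.5 (one-to-one, greedy) so that a
detector including the diffraction skirt is not penalised.

All downstream analyses in the shipped pipelines use the simulator's
ground-truth mask, not the detector: the claims under test concern the
statistics, not detection quality.

## Quantification and population analysis

Per cell: signal = mean of the brightest `ceil(0.10 n)` pixels, background =
mean of the dimmest `ceil(0.50 n)` pixels (each at least one pixel; ceiling
chosen so tiny cells never yield empty sets; ties at the set boundary are
broken by taking exactly the computed count after a stable sort). Ratio =
signal/background, flagged infinite when the background is exactly zero.
Filters are strict: maximum pixel < 65,000 *and* ratio > 5. The 65,000 cutoff
is read as a saturation guard on the cell's maximum pixel; a whole-cell-mean
reading is available via `intensity_filter_mode="cell_mean"` since the
published phrasing admits either.

Area binning uses disjoint half-open 10-px bins by default (bin counts are
then unambiguous), with a 1-px-step sliding-window mode available; windows
with fewer than 10 cells are dropped. Control subtraction removes the control
population's grand mean from each cell, clamping negatives to zero with a
flag; it is applied per cell before binning or fold-change computation.
Regression of background on signal is unweighted OLS (via
`scipy.stats.linregress`, cross-checked against the covariance/variance
closed form) after excluding cells above the axis caps (65,000 on signal,
15,000 on background). Fold change divides control-subtracted means, strain b
over strain a; with `subset_fraction = 0.5` each strain is first restricted
to its brightest half by whole-cell mean — subsetting happens *before*
control subtraction, a deliberate ordering choice since the published
procedure does not state one.

## Problem sizes and seeds

The test suite runs the regime-reproduction checks on 10 seeds × 4 regimes ×
100 cells and the copy-number checks on populations of 200–1000 cells split
across 512×512-px fields of ~60 cells; these sizes give sampling error well
inside the asserted bands (the 2-copy fold-change SE at n = 1000 is ~1%)
while keeping a full run under a minute. All randomness derives from
explicit seeds via named `SeedSequence` substreams: population geometry and
camera noise are separate streams, and analysis parameters never touch
simulation output.

## Known limitations

* The occupancy model ignores cooperativity, dimerisation of λcI, partial
  occupancy correlations between adjacent half-site pairs, and maturation
  delays; `affinity` lumps protein–DNA binding and complementation into one
  constant.
* Motif/spacer default sequences are placeholders for the unpublished
  originals (flagged in `arrays.py`); enzyme-site avoidance is guaranteed
  only for the defaults or any motif pair that admits a clean spacer draw.
* The renderer is 2-D with a single Gaussian PSF; real widefield PSFs have
  heavier tails, which would raise measured backgrounds slightly.
* The detector is tuned for sparse fields of separated cells; confluent or
  touching cells would require watershed-style splitting, which is out of
  scope.
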