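# Methods

This note documents the models, conventions and numerical choices behind
`vesselmap`, and what the simulation-based validation does and does not
demonstrate.

## Proteoform bookkeeping

Canonical amyloid-region sequences (ABri 1–34, ADan 1–34, Aβ 1–42) are
embedded as constants with loud import-time consistency checks: the two
BRI2-derived peptides must agree over residues 1–22 and carry exactly two
cysteines; Aβ carries none. A species is a span `[start, end]` of one
region plus flags for N-terminal pyroglutamate and the number of disulfide
bridges; validation enforces that pE sits on Glu/Gln and that bridges do not
exceed `⌊n_Cys/2⌋`.

**Masses.** Neutral monoisotopic mass is the sum of residue masses
(pyteomics `std_aa_mass`) plus one water, −18.010565 Da per pE formed from
Glu (−17.026549 from Gln), −2 × 1.007825 Da per disulfide bridge. The Gln
route is implemented but unused by the shipped species (every pE position
here is Glu). `[M+H]+` adds one proton mass per charge.

**Hydrophobic fraction.** `100 × (hydrophobic residues) / length`, reported
to one decimal with round-half-away-from-zero. The hydrophobic class
{A, F, I, L, M, V, W} was fixed by exhaustive subset search against the
seven reference one-decimal percentages for ABri1-34/1-29, ADan1-34/1-29/
1-28 and Aβ1-40/1-42; twelve subsets reproduce all seven and the chosen one
is the conventional aliphatic+aromatic class (Cys, Gly, Tyr and Pro
excluded). ADan1-33 is a known edge: the integer-count rule gives
14/33 = 42.4%, while ~42.2% has been reported by fractional-weight
calculators; it is therefore excluded from the golden set.

**Subgroups.** FULL_LENGTH requires the complete canonical span
(34 for ABri/ADan, 42 for Aβ) with an unmodified N-terminus; C_TRUNCATED is
`end < canonical`; N_TRUNCATED is `start > 1` *or* (by default) a
position-1 pE — the convention under which pE1-dominated deposits read as
majority N-terminally modified. The pE1 convention is a switch
(`pe1_counts_as_n_truncated`) because the alternative reading is also
defensible. Categories overlap by design; fractions need not sum to 100.

**Disease rosters.** The FBD (8 ABri), FDD (16 ADan+Aβ) and CAA+ (15 Aβ)
species lists match the reported counts and the described
truncation/modification patterns (ABri x-34/x-29 with 2-x and 3-x species;
ADan x-34/x-33/x-29/x-28 with 3-x but no 2-x; Aβ x-40/x-42 with 3pE/11pE
species plus Aβ1-37). They are synthetic reconstructions for the simulators
and examples, not reference data, and no per-species measured value is
asserted against them.

## Hyperspectral LCO pipeline

The stack is `rows × cols × 32` channels spanning 405–750 nm (≈11 nm
spacing). Steps and conventions:

* **Projection** — pointwise maximum over channels.
* **Background** — subtract a Gaussian blur of the projection
  (σ = 200 px default, reflective padding to avoid dark-edge artifacts).
  Negative values are kept (no clamp): clamping would shift the histogram
  fed to Otsu.
* **Otsu** — 256 equal-width bins over the observed [min, max]
  (`skimage.filters.threshold_otsu`), bit-reproducible; an exhaustive
  between-class-variance maximiser serves as the independent oracle in the
  tests. A constant image raises (degenerate histogram). If the foreground
  would cover more than `max_foreground_fraction` (default 0.4) of the
  field, the field is treated as vessel-free: on a featureless image Otsu
  bisects the noise floor rather than separating vessels.
* **Closing** — disk structuring element, radius 5 px default; this is what
  fills the unstained vessel lumen.
* **Components** — 8-connectivity; ROIs below `min_roi_pixels`
  (default 50 at 300 nm pixels, i.e. specks ≪ one capillary cross-section)
  are dropped. Each ROI carries the channel-wise mean spectrum; the
  full-field mean spectrum is returned alongside for comparison.
* **Ratio** — intensity at the channel nearest 500 nm over the channel
  nearest 580 nm (nearest-channel lookup; linear interpolation behind a
  flag). The statistic is invariant to any scalar normalization of the
  spectrum, so the max-normalization used for plotting never affects it.
  A zero denominator raises rather than returning infinity.

## MSI pipeline

* **TIC normalization** rescales each pixel to the dataset-mean
  pre-normalization TIC (not 1.0), preserving the intensity scale for
  cross-ROI comparison; the target is configurable. Zero-TIC pixels are
  dropped with a warning.
* **Segmentation** is bisecting k-means on bin-integrated intensity
  vectors: the leaf with the largest within-cluster SSE is repeatedly split
  by 2-means (`sklearn` KMeans, 10 restarts, seeded) until the requested
  leaf count; the split history is recorded. Vessel leaves are those with
  the highest mean signal over species-annotated bins. Coarse uniform bins
  (3 Da) are used as segmentation features — fine peak bins are only
  detected afterwards, on vessel pixels.
* **Peak detection** runs on the average spectrum of the vessel pixels,
  accumulated onto a 0.25 Da grid. Noise is 1.4826 × MAD of the
  first-differenced spectrum (robust, insensitive to the sparse peaks);
  peaks must exceed the baseline (median) by `SNR × noise` (default 3).
  Bin edges sit at the nearest flanking local minima, truncated at half the
  distance to the neighbouring peak and capped at ±0.35% of the centre m/z
  (≈ peak width for linear-TOF at ~4 kDa), so neighbouring proteoforms a
  couple of Da apart keep separate bins and bins never overlap.
* **Integration** sums centroid intensities inside `[left, right]` per
  pixel (trapezoidal integration applies only to profile-mode input).
  Bins are annotated with the species whose theoretical `[M+H]+` falls
  nearest (tolerance 2 Da).
* **Statistics.** Relative quantification divides per-ROI mean intensities
  by the reference species (default: the strongest annotated species, i.e.
  the largest peptide peak); ROIs lacking the reference are dropped with a
  warning. Subgroup fractions are intensity-weighted per ROI and averaged
  across ROIs, separately per precursor family. The coverage threshold for
  "target-positive" pixels is background mean + 2 SD of the off-vessel
  pixels (no rule is standard; this one is documented and configurable).
  SPSC is Pearson on TIC-normalized intensities (Spearman behind a flag);
  a zero-variance species yields NaN rows/columns, not 0.

## Synthetic data: what it emulates, what it does not

**LCO simulator.** Vessels are elliptical rings (wall stained, lumen not —
CAA is vascular-wall deposition, and the hole exercises the closing step)
placed without overlap by rejection sampling (bounded retries, then error).
Wall pixels carry `w·q(λ) + (1−w)·h(λ)` with unit-peak Gaussian endmembers
(centres 500/580 nm, sd 30 nm) sampled at the 32 channel centres; the
planted ratio is evaluated analytically at the 500/580-nearest channels,
and `weight_for_ratio` inverts that map in closed form. Background is a
faint tilted plane (2% of vessel amplitude, ±50% tilt) and noise is
per-pixel, per-channel Gaussian (default sd 10% of amplitude, clipped at
zero). Defaults: 600 × 600 px, 50 vessels, outer radii 8–14 px, lumina
3–4 px, planted ratios uniform in [0.5, 2.0].

**MSI simulator.** Each pixel gets one centroid peak per present species at
its theoretical `[M+H]+` with ~20 ppm position jitter (the Aβ3-42/Aβ1-40
pair sits only 1.9 Da apart, so jitter is kept at mass-accuracy scale
rather than linear-TOF peak-width scale to keep the recovery benchmark
well-posed). Intensities are log-normal: a per-vessel, per-species scatter
(log-sd 0.15) times a per-pixel field with configurable cross-species
correlation (log-sd 0.35) — the planted co-localization structure. A smooth
multiplicative gain field (log-sd 0.3, 20 px scale) models acquisition
drift and is exactly what TIC normalization must remove. Background pixels
carry only "matrix" peaks at positions drawn clear (±10 Da) of species
masses — this also gives the background a non-zero TIC, making the
segmentation problem non-trivial after normalization.

In the FDD-like preset the Aβ species are *focal*: confined to a contiguous
subregion covering 13.3% of each vessel's pixels and scaled so the expected
Aβ share of total amyloid signal is 4.6%. Inside the focal subregion the
ADan means are reduced so the expected total amyloid per pixel stays
uniform across the vessel (co-deposition displaces); this keeps the planted
fractions invariant under TIC normalization, which is what makes their
recovery a well-posed check. The preset's relative abundances were chosen
once so the analytic subgroup fractions land at ADan ≈ 6.5 / 69 / 81.5 /
63% and Aβ ≈ 14.5 / 74.5 / 71.5 / 30.5% (full-length / C-trunc / N-trunc /
pE). Ground truth (ratios, relative abundances, fractions, correlations)
is always computed analytically from the configuration plus placement
bookkeeping, never re-measured from the generated arrays.

**Not emulated:** physical TOF peak shapes and isotope envelopes, optics
point-spread, tissue autofluorescence spectra, ionization-efficiency
differences between peptides, and registration between the two modalities.
Passing recovery tests therefore shows the *algorithms* are correct and
well-calibrated under realistic noise/structure — not that real-tissue
accuracy matches these numbers.

## Problem sizes and determinism

The validation workloads are sized for a laptop-class single core: LCO
recovery on one 600 × 600 × 32 field with 50 vessels; MSI recovery on a
150 × 150 grid (22 500 spectra) with 75 vessels and 16 species; SPSC on
500 masked pixels; Otsu-oracle agreement on 100 random 64 × 64 images.
Every stochastic component (simulators, k-means restarts) is driven by an
explicit seed; `scripts/acceptance.py` derives independent sub-seeds from
its `--seed` via `numpy.random.SeedSequence`. Identical inputs and seeds
give bit-identical outputs.

## Known limitations

* The hydrophobic class is calibrated to integer residue counting; tools
  using fractional hydrophobicity weights will differ for some spans
  (ADan1-33 being the documented case).
* Bisecting k-means feature scaling follows the TIC-normalized intensities
  directly (no autoscaling); heavily skewed real data may cluster better
  after log or unit-variance scaling, neither of which is applied by
  default.
* The coverage threshold rule (mean + 2 SD of off-vessel background) is a
  convention; published analyses rarely state theirs.
* imzML I/O supports processed (per-pixel axis) mode; continuous-mode files
  read fine through the same parser but are not round-tripped as such.
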