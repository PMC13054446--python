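# Methods

## The assay and its forward model

Each droplet is a closed reaction vessel of volume `V` (default 10 pL,
fixed by the cell suspension density of 30×10⁶ cells/mL and the target
mean occupancy of 0.3 cells/droplet: 0.3 / 3×10⁷ mL⁻¹ = 10 pL). Cell
counts per droplet are independent Poisson(λ). A secreting cell releases
IgG at a constant rate `s` (molecules/s); every secreted molecule is
captured on the beadline, treated as instantaneous relative to the
7.5-minute frame interval (nanobody capture on nanobeads is fast
compared with secretion accumulation) and capped at a capture capacity
(default 10⁷ molecules, effectively unlimited over a 37.5-minute
acquisition at ≤800 molecules/s).

Within each frame the captured IgG, expressed as a molar site
concentration `S(t) = s·t/(N_A·V)`, is assumed at binding equilibrium
with both fluorescent reagents independently:

* **red** — anti-IgG detector, total 75 nM, detector K_D 1 nM. The
  detector affinity is not measured by the assay; 1 nM makes detector
  binding near-saturating so the red channel tracks the *amount* of
  captured IgG, which is the quantity the channel is used for.
* **green** — antigen, total 30 nM, bound with the cell's own K_D.

Both equilibria use the 1:1 conservation quadratic with depletion,
evaluated in the cancellation-free product form (`binding.py`); the two
reactions are treated as independent because they address different
epitopes (Fc vs antigen-binding site). IgG is treated as monovalent for
both partners, matching the single 1:1 constant the assay reports.
Relocation per channel is `R_c = 1 + κ_c·B_c/F_c` with gain `κ_c`
(default 15 in both channels, chosen so that the slowest calibrated
secretor, 4 molecules/s, just clears the 1.2 relocation floor within
one acquisition). `R` is 1 at t = 0 and strictly increasing while
capture is unsaturated.

## Rendering conventions

Droplets are drawn as disks on a jittered square grid (monodisperse, no
overlap, chamber auto-sized unless given); an explicit chamber too small
for the requested droplet count is a hard error. Background intensity is
proportional to the free fluorophore fraction (conservation inside the
closed droplet), the beadline is a horizontal 3-px bar of length 0.6
droplet diameters through the center at `background × R_c(t)` — the
field axis is fixed by the chamber, so horizontal-and-centered is a pure
rendering convention shared with the measurement side. Cells are dark
disks in the red channel, placed off the beadline and apart from each
other so the dark-disk detector can resolve them; multi-cell droplets
beyond the flag threshold may still merge optically, which only makes
the MULTI_CELL flag conservative. Noise classes: Gaussian read noise,
optional Poisson shot noise, a movement class (3-px shift on alternate
frames, exceeding the 2-px QC tolerance) and a bright-speck artifact
class. Pixels are clipped to 16 bits with a warning on overflow.

What the generator does **not** emulate: optics (PSF, defocus),
droplet polydispersity, photobleaching, autofluorescence, illumination
gradients, chamber tiling, or secretion-rate variation in time. Passing
tests therefore demonstrate the correctness of the analysis chain under
the model's own assumptions, not robustness to every real-microscope
failure mode.

## Measurement side

Droplet segmentation is thresholding (Otsu refined to the midpoint of
the two class means — plain Otsu can settle inside the dark-oil noise
peak on oil-dominated images) plus connected components with hole
filling and a circularity ≥ 0.8 filter; border-touching regions skip the
circularity filter so they can be flagged EDGE and excluded downstream.
Background is computed **per droplet** (droplet pixels minus beadline,
detected cells and specks). Relocation is the beadline/background mean
ratio, which makes every downstream quantity invariant to a global
intensity rescaling. Movement tracking re-segments each frame
permissively (no circularity filter) because strong secretors relocate
most fluorophore onto the beadline late in the acquisition, leaving a
bar-shaped remnant whose centroid is still the droplet center.

Positivity filters on the red trace: max > 1.2, net difference
> 0.025, least-squares slope ≥ 0.004 per frame interval. Two
interpretation choices are deliberate: "minimum relocation > 1.2" is
read as a floor on the *achieved* (maximum) relocation, since traces
start at 1.0 by construction; and the slope is per 7.5-minute frame
interval, which makes 0.004 × 5 intervals commensurate with the 0.025
net-difference threshold (per-minute units would let the slope criterion
dominate six-fold).

## Calibration and inversion

The calibration panel encodes four clones spanning 0.1–100 nM K_D at
four in-droplet concentrations (1–30 nM); the assay's own panel K_D
values are not published, so the synthetic panel simply spans the
working window. Because `R − 1` is linear in the gain, the gains have a
closed-form least-squares solution; the fit refuses degenerate panels
(fewer than two distinct concentrations or K_D values) and reports a
residual RMS.

Rate inversion converts the red trace to captured molecules per frame
and averages the slopes of frames 2–6 against the first-frame baseline,
damping any capture-lag transient. Estimates outside 4–800 molecules/s
are censored to the boundary and flagged (`BELOW_4`/`ABOVE_800`) rather
than dropped — the window is a calibration validity range, not a
filter. K_D inversion uses the final frame (largest signal):
`θ = B_green/S`, `K_D = F_green(1−θ)/θ`. Estimates below 2.3 nM are
algebraic continuations of the same inversion, flagged `EXTRAPOLATED`
and floored at 10 pM; at or above 100 nM the cell is `NONSPECIFIC`; a
baseline green trace yields `NO_GREEN_SIGNAL` (a secretor of irrelevant
specificity). Classes: LOW K_D ≥ 10 nM, HIGH K_D < 1 nM, MEDIUM
between.

## Default cohort composition

The default `CohortSpec` emulates an antibody-secreting-cell-rich
acquisition so a 2,000-droplet demo yields a statistically useful number
of positives: 25% of encapsulated cells secrete IgG (at most one
secretor per droplet — multi-secretor droplets are sub-percent events at
these settings and are unresolvable by the assay anyway), 40% of
secretors are antigen-specific (between the reported average >20% and
~50% peak). Rates are log-normal (ln-mean 3.317, ln-SD 0.6; mean ≈ 33
molecules/s) truncated to 4–800. Specific affinities follow a 90/8/2%
low/medium/high mixture, uniform within 10–100, 1–10 and 0.2–1 nM —
reproducing the observed predominance of low-affinity cells (>80%,
≤2.3% high) with a mean near the reported ~50–65 nM. Nonspecific
secretors carry K_D = 10 µM, far outside the window.

## Serum-level fits

The SPR steady-state model is fitted by bounded least squares on the
five-point concentration series (2000, 667, 222, 74, 25 nM); the fit is
flagged *extrapolated* when the largest injected concentration is below
the fitted K_D, because the plateau was never approached (the
micromolar early-disease sera trip this guard; 120 nM sera do not). The
specific-IgG percentage formula is implemented exactly as the
instrument defines it, with default molar masses 63 kDa (antigen
monomer — the dimer is a configurable alternative) and 150 kDa (IgG).
The ELISA ED50 is a descending 4PL in reciprocal dilution, censored to
the measured 300–218,700 range; a flat series cannot be sided from its
ODs alone, so a `baseline_od` parameter (default 0.2 absorbance)
decides between "no titer" (<300) and "saturated" (>218,700).

## Statistics

Mann-Whitney between consecutive timepoints and Kruskal-Wallis across
the three age groups (6–12, 23–35, 54–87 weeks) are standard scipy
calls; Dunn's pairwise follow-up (rank-based z with tie correction,
Bonferroni adjustment) is implemented locally. Strata under 3
observations are skipped with notice. Mean affinity is the arithmetic
mean on the nM scale (a geometric option exists, off by default);
extrapolated affinities enter summaries at the 10 pM floor, which makes
per-timepoint means insensitive to the unbounded tail of the algebraic
extrapolation.

## Problem sizes and tolerances

The test suite exercises: encapsulation statistics at 10⁵ droplets
(χ² against the Poisson law at α = 0.01) and 8×10⁴ droplets for the
1–2-cell count; rendered round trips at 12–1,000 droplets (relocation
reproduced within 1%, forward–inverse identity within 1% for rates and
5% for K_D, noiseless); a 2,500-droplet empty-emulsion false-positive
check (<1% with read and shot noise); and 1,000 null simulations of the
Mann-Whitney test (p > 0.05 in ≥94%). The depletion solver is checked
against an independent bisection root to 10⁻⁹ relative. These sizes
keep the whole suite around a minute on one CPU while leaving every
statistical assertion well-powered.

## Known limitations

* Cell counting reads dark disks in the red channel; overlapping cells
  in crowded droplets can undercount, so MULTI_CELL exclusion is
  conservative at high occupancy (irrelevant at the default λ = 0.3).
* K_D inversion uses a single (final) frame; with heavy noise an
  averaged-frame estimator would be preferable.
* The movement flag tracks centroids of re-segmented frames; droplets
  that vanish entirely in a frame (extreme relocation plus noise) are
  not assessable for movement in that interval.
* Equilibrium-within-frame breaks down for off-rates slower than the
  frame interval (sub-100 pM K_D at typical on-rates); extrapolated
  affinities below the 2.3 nM window inherit this model error, which is
  one reason they are reported as extrapolated.
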