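# dropmap

Analysis pipeline for a droplet-microfluidic single-cell antibody
secretion assay ("DropMap"), together with a synthetic-data generator
that makes every stage testable without a microscope.

In the assay, single cells from spleen, lymph node or bone marrow are
encapsulated in ~10 pL water-in-oil droplets together with paramagnetic
nanobeads (coated with an anti-κ light-chain nanobody), a fluorescent
antigen (30 nM GPI, green channel) and a fluorescent anti-IgG detector
(75 nM, red channel). Under a magnetic field the beads align into a
"beadline". Secreted IgG is captured on the beadline; the detector and
the antigen then relocate onto it in proportion to how much IgG has
accumulated and how tightly it binds the antigen. Imaging the chamber
every 7.5 minutes over 37.5 minutes yields, per droplet and channel, the
dimensionless **relocation** ratio

    R_c(t) = beadline mean intensity / background mean intensity

from which the pipeline computes, per cell, the **IgG secretion rate**
(molecules/s, calibrated range 4–800) and the **affinity K_D** for the
antigen (calibrated range 2.3–100 nM; lower values extrapolated, K_D ≥
100 nM treated as not antigen-specific). Cells are binned into
low- (K_D ≥ 10 nM), medium- and high-affinity (K_D < 1 nM) classes.

## Model

The forward in-droplet model treats capture as instantaneous and binding
as 1:1 equilibrium within each frame. With secretion rate `s`, captured
IgG presents a molar site concentration `S(t) = s·t / (N_A·V)`. Each
reagent (total `L`, dissociation constant `K_D`) binds with depletion,
the bound complex being the stable root of

    B² − (S + L + K_D)·B + S·L = 0,

and the relocation in channel `c` is `R_c = 1 + κ_c · B_c / (L_c − B_c)`
with a per-channel gain `κ_c` fitted from a calibration panel of
monoclonal antibodies of known K_D encapsulated at known concentrations.
Inversion runs the model backwards: the red channel gives `S(t)` and
hence the rate; the green:red relationship gives the fractional
occupancy `θ` and hence `K_D = L_free·(1−θ)/θ` with depletion
correction.

A droplet is called IgG-secreting when its red trace exceeds 1.2 at its
maximum, rises by more than 0.025 over the acquisition, and has a
least-squares slope of at least 0.004 per frame interval. Droplets with
more than two cells, movement above 2 px between frames, fluorescence
artifacts, or cut by the image border are excluded.

Serum-level helpers implement the SPR steady-state 1:1 fit
`R_eq = Rmax·C/(K_D + C)`, the antigen-specific IgG percentage
`% = Rmax/capture·(M_GPI/M_IgG)·100`, and a censored four-parameter
logistic ELISA ED50 (reported as <300 / >218,700 outside the dilution
series).

## Worked example

```bash
dropmap demo --out-dir demo_run --seed 7 --n-droplets 2000
```

generates a 2,000-droplet in-silico cohort (Poisson loading at 0.3
cells/droplet), renders the two-channel 16-bit TIFF stacks, re-analyzes
them from the pixels up, and prints the run report:

```json
{
  "n_segmented": 2000,
  "n_excluded": {"ZERO_CELL": 1457, "MULTI_CELL": 10},
  "n_analyzed": 533,
  "n_positive": 158,
  "kd_flags": {"IN_RANGE": 74, "NONSPECIFIC_GE_100": 82, "EXTRAPOLATED_LT_2.3": 2},
  "summary_totals": {
    "n_igg_sc": 158,
    "n_gpi_specific": 76,
    "percent_low_affinity": 90.79,
    "percent_high_affinity": 1.32,
    "mean_kd_nm": 47.42
  },
  "n_true_secretors": 164
}
```

Reading: of 2,000 segmented droplets, 1,457 contained no cell and 10
held more than two cells; 533 were analyzed; 158 were called
IgG-secreting (164 true secretors were generated — the misses sit in
excluded droplets); 76 of the positives bound the antigen within the
100 nM window, of which 90.8% were low-affinity — the class structure
the generator emulates. Per-cell values land in `demo_run/master.tsv`
(one row per called cell: rate, K_D, censor flags, specificity,
affinity class), with intermediate tables (`relocation.tsv`,
`calls.tsv`) and `report.json` alongside.

The same stages are available individually (`dropmap synth`, `segment`,
`call`, `infer`, `serology`, `summarize`, `run-all`) and as library
functions.

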