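# Methods

## Attenuation model and inversion

The package models broadband diffuse reflectance with the modified
Beer–Lambert law: OD(λ) = −ln(I/I₀) = μₐ(λ)·DPF(λ)·d + G, with
μₐ(λ) = Σᵢ εᵢ(λ)·Cᵢ over oxy- and deoxyhemoglobin. Units are fixed
throughout: concentrations in mM, pathlengths in cm (the source–detector
separation is stored in mm, the field convention, and converted
internally), extinction coefficients in mM⁻¹·cm⁻¹ on a natural-log
basis. Fixing the basis and units at the data-file boundary removes the
two classic silent errors of this analysis (a stray ln 10 from
log₁₀-basis tables, and a 10× from mm/cm confusion).

Differential measurements cancel G under the assumption that G, DPF and
ε are time-invariant between the two acquisitions. The two-wavelength
inversion of ΔOD at 740/840 nm is solved in closed form (explicit 2×2
determinant inversion); more than two wavelengths are solved by ordinary
least squares on rows εᵢ(λ)·DPF(λ)·d. Both paths report the design-matrix
condition number and refuse to solve above a configurable cap (default
1e8). The closed-form and least-squares routes are deliberately kept as
two independent code paths and cross-checked in the tests.

Absolute StO₂ is not observable from CW data. The reported StO₂ is
obtained by adding the recovered changes to an explicit, configurable
baseline state (default 0.70 saturation, 0.1 mM total hemoglobin) and is
flagged semi-quantitative in the output; the baseline assumption travels
with every estimate. Negative reconstructed concentrations (possible
under noise) are clamped to zero and flagged rather than rejected, so
noisy acquisitions remain auditable instead of disappearing.

### Band extraction

OD at an analysis wavelength is extracted as the mean over a small boxcar
band (±2 grid points, ±4 nm at the default 2 nm grid) in the time-series
and pipeline layers, with strict single-pixel extraction available and
used by the low-level `delta_od` default. Band averaging is the natural
reading of a 2048-pixel spectrometer feeding a two-wavelength analysis:
single-pixel extraction passes the full per-pixel noise into the 2×2
inversion (≈2.6 pp mean absolute StO₂ error at 1% multiplicative noise in
our calibration), while a ±4 nm band brings it to ≈1.1 pp. To keep the
band exactly consistent with the forward model, the inversion averages
its extinction coefficients over the identical band (DPF is taken at the
band center; within a symmetric few-nm band the residual mismatch is
below 1e-6 mM, and zero for single-pixel extraction).

### Wavelength handling

Requested wavelengths snap to the nearest grid point within ±2 nm
(configurable); the grid points actually used are recorded in the
result. DPF is linearly interpolated between table entries and never
extrapolated — outside the tabulated span the lookup raises, because
small DPF errors propagate directly into concentration errors. The
forward simulator, which needs DPF on the full 650–1050 nm grid, uses a
linear extension of the (740, 3.50)–(840, 3.01) anchor pair floored at 1;
this is a simulation device, not an analysis claim.

## Optical constants

The bundled extinction table (`data/hb_extinction_synthetic.tsv`) is a
synthetic, shape-accurate stand-in for the standard literature
compilations of human hemoglobin absorption: deoxy-Hb peak near 760 nm,
isosbestic crossing near 795 nm, HbO₂ > Hb above ~830 nm, sampled every
5 nm over 650–1050 nm. The individual numbers are smoothed representative
values, not a digitization of a published table; they are appropriate for
simulation and for differential (concentration-change) analysis, where
only self-consistency between forward model and inversion matters, and
can be replaced by any user table in the same format for absolute work.
THb is stored as the exact pointwise sum of the HbO₂ and Hb columns.

## Synthetic study generator

The generator emulates a 15-animal longitudinal implant study: 7 Mg,
4 Ti, 4 sham subjects, both hindlimbs, days {0, 1, 3, 7, 14, 45}, with
the implant effect applied to the implanted (left) limb and the
contralateral limb held at baseline. Per subject × limb × timepoint the
true saturation is baseline + group/day offset + N(0, σ²_subj + σ²_extra),
clipped to [0.02, 0.98]; total hemoglobin varies per subject
(sd 0.005 mM). G is drawn once per subject/limb (uniform in [0.5, 1.5])
and held fixed across timepoints, matching the differential-analysis
assumption; an optional per-timepoint G jitter exists to probe violations
of that assumption. Instrument noise is independent multiplicative
Gaussian per wavelength (default 1% relative, truncated to stay
positive).

The planted trajectories encode the study's qualitative hemodynamics and
were calibrated (once) so that the three longitudinal patterns hold
robustly at the default sample sizes:

- **Mg**: StO₂ dips −10 pp at day 1, recovering to 0 offset by day 45,
  with inflated between-subject spread at days 1–3 (extra sd 8 and 6 pp)
  — the gas-evolution signature of alloy corrosion, modeled statistically
  rather than as explicit bubble optics.
- **Ti / sham**: moderate post-surgical dips (−8 / −6 pp at day 1) that
  persist through day 45 (−5 / −4 pp), with no extra variance.
- **Rash**: one Ti subject develops a skin rash from day 3 on, adding
  +10 pp StO₂ (elevated superficial blood flow) and a `skin="rash"` flag.

Because no quantitative effect sizes exist to copy (the source
observations are figure-level patterns), these defaults are honest
parameterizations, fully exposed in `StudyDesign`, not measured facts;
baseline StO₂ 0.70 and THb 0.1 mM are likewise configuration values
typical of perfused soft tissue, not reported numbers.

What the generator does *not* emulate: radiative-transfer/Monte-Carlo
photon transport, wavelength-dependent scattering, skin layering,
additional chromophores (water, lipid, melanin), spectrally correlated
instrument drift. Passing tests therefore demonstrate correctness of the
analysis chain under the MBLL's own assumptions, not robustness to every
physical effect present in real tissue.

## StO₂ time series and group summaries

Every timepoint is differenced directly against the pre-surgery day-0
acquisition (not chained through intermediate days, so errors do not
accumulate); day 0 itself maps to the assumed baseline exactly, which
also means its recovered between-subject spread is zero by construction.
The group trend summary (mean, sd, median, n, min, max per group × day)
excludes acquisitions with a flagged skin artifact: the rash reflects
superficial skin blood flow, not implant biology, and is analyzed
separately (below). The full per-subject table keeps all rows.

## PCA exploration

Spectra are assembled into an acquisitions × wavelengths matrix of
optical densities (raw-intensity mode available), normalized per spectrum
— default standard normal variate (SNV), which removes per-acquisition
multiplicative gain and additive offset; unit-vector and max-scaling are
selectable — and decomposed by column-mean-centered PCA (scikit-learn,
full SVD). Two components are retained by default; the full eigenvalue
spectrum is kept for scree inspection. Signs follow the convention that
each loading's largest-magnitude element is positive, making repeated
fits bit-reproducible.

Outliers are flagged by robust score distance: per-component z-scores
against the median and MAD of the scores, squared distance referred to a
χ²(k) tail at level α (default 0.01), so the null flag rate is calibrated
to α. A zero MAD (degenerate, e.g. identical spectra) marks rows at the
median as unremarkable instead of erroring. Removal is a separate,
itemized step — excluded acquisitions are listed in the report, never
silently dropped.

Score-space comparisons operationalize two visual patterns as numbers:

- **Group separation** (skin-rash case): Euclidean distance between group
  centroids in the retained score space, with a label-permutation p-value
  (999 permutations, seeded). The damaged-skin comparison runs as a
  separate PCA restricted to the affected days (3–14), on the
  pre-exclusion matrix — the rash rows are the object of study there and
  must not be removed by the generic outlier screen first. The main
  decomposition conversely excludes damaged-skin rows.
- **Timepoint similarity** (healing): centroid distance between a group's
  day-0 and day-45 scores; a small distance means the group's spectra
  returned near their pre-surgical state. On the default design the Mg
  group's distance is the smallest of the three groups in ≈95 of 100
  seeds.

## Numerical and procedural choices

- Tolerances: noise-free forward→inverse round trips are exact to
  ≤1e-9 mM (tested at 1e-9; achieved ~1e-15); closed-form vs least-squares
  agreement to 1e-12 relative.
- The noisy-recovery calibration (1% noise, 100 replicate subjects with
  subject-level variability zeroed so the measured error is pure noise
  propagation) gives ≈1.1 pp mean absolute StO₂ error with no systematic
  bias (95% t-interval for the mean error covers zero).
- Scenario statistics are computed at fixed seeds with problem sizes
  chosen for fast, deterministic runs: 10 study replicates for the
  early-variability ratios, 100 seeds for the healing comparison, 40
  null replicates (199 permutations each) for the rash null calibration.
- Ties in wavelength snapping resolve to the lower index (`argmin` on the
  distance); band windows are truncated at the grid edges.
- The pipeline is deterministic end to end under its seed: identical
  configurations write byte-identical reports.

## Known limitations

- StO₂ values inherit the baseline assumption entirely; a subject whose
  true day-0 state differs from the assumed baseline has its whole series
  shifted accordingly. This is intrinsic to CW-NIRS, not fixable in
  software, and is why the outputs are flagged semi-quantitative.
- DPF values are literature constants at two wavelengths; their validity
  across healing states (edema, gas pockets) is assumed.
- The two-wavelength inversion is exactly determined: it has no residual
  to diagnose model violations. The ≥3-wavelength least-squares path
  exists partly for that purpose.
- Permutation p-values have resolution 1/(n_permutations + 1).
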