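"""Modified Beer-Lambert law: OD, differential OD, inversion, StO2.

Continuous-wave NIRS measures only attenuation, so absolute chromophore
concentrations are out of reach (the geometry term G is unknown).  Treating
two acquisitions differentially cancels G and leaves a linear system

    dOD(lambda) = sum_i eps_i(lambda) * dC_i * DPF(lambda) * d,

which, evaluated at (at least) two wavelengths, yields the changes in
oxy- and deoxyhemoglobin concentration between the two timepoints.  A
semi-quantitative tissue oxygen saturation then follows by anchoring the
changes to an assumed baseline state (StO2 fraction and total hemoglobin);
the assumption is carried in the output and the estimate is flagged as
semi-quantitative, never absolute.

All logarithms are natural; extinction coefficients must be natural-log
basis mM^-1 cm^-1 (the chromophore_db loader guarantees this for the
bundled table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import (
    HB,
    HBO2,
    ChromophoreSet,
    ProbeGeometry,
    dpf_at,
    extinction_at,
)
from .errors import (
    BaselineMissingError,
    ConditioningError,
    DomainError,
    GridAlignmentError,
    SaturationUndefinedError,
    WavelengthResolutionError,
)
from .synthetic import AcquisitionMeta, ReferenceSpectrum, Spectrum, StudyRecord

#: Default analysis wavelength pair (nm), matched to the DPF table.
DEFAULT_WAVELENGTHS = (740.0, 840.0)


@dataclass(frozen=True)
class ODSpectrum:
    """Optical density OD(lambda) = ln(I0/I), dimensionless."""

    grid: np.ndarray
    od: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, float))
        object.__setattr__(self, "od", np.asarray(self.od, float))
        if not np.all(np.isfinite(self.od)):
            raise ValueError("OD values must be finite")


@dataclass(frozen=True)
class DeltaOD:
    """Differential optical density between two timepoints at selected wavelengths.

    ``bands`` records, per selected wavelength, the grid points whose OD was
    averaged (a single point by default; a boxcar band when band extraction
    is on).  The inversion averages its extinction/DPF rows over the same
    points, keeping the linear model exactly consistent with the extraction.
    """

    wavelengths: tuple[float, ...]  # grid points actually used (band centers)
    requested: tuple[float, ...]  # wavelengths as requested before snapping
    values: np.ndarray
    timepoints: tuple[int, int]
    bands: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if len(self.wavelengths) < 1:
            raise ValueError("at least one wavelength required")
        if self.timepoints[0] == self.timepoints[1]:
            raise ValueError("differential OD needs two distinct timepoints")
        if not self.bands:
            object.__setattr__(self, "bands", tuple((w,) for w in self.wavelengths))


@dataclass(frozen=True)
class DeltaConcentration:
    """Concentration changes (mM) between two timepoints, with inversion diagnostics."""

    d_hbo2: float
    d_hb: float
    timepoints: tuple[int, int]
    wavelengths: tuple[float, ...]
    condition_number: float


@dataclass(frozen=True)
class OxygenationEstimate:
    """Semi-quantitative StO2 (%) under an explicit baseline assumption.

    CW-NIRS yields concentration *changes*; turning them into a saturation
    requires assuming the baseline state.  That assumption (baseline StO2
    fraction and total hemoglobin in mM) travels with the value, and
    ``semi_quantitative`` is always True to keep the caveat visible.
    ``clamped`` marks estimates where noise pushed a reconstructed
    concentration negative and it was clamped to zero.
    """

    sto2_percent: float
    timepoint: int
    baseline_sto2: float
    baseline_thb_mm: float
    clamped: bool = False
    semi_quantitative: bool = True
    subject: str = ""
    group: str = ""
    limb: str = ""
    skin: str = "normal"


def compute_od(spectrum: Spectrum, reference: ReferenceSpectrum) -> ODSpectrum:
    """Optical density of one acquisition against the incident spectrum.

    ``od(lambda) = ln(I0(lambda)) - ln(I(lambda))``, pointwise on the shared
    grid.  Positive wherever the tissue attenuates.
    """
    if spectrum.grid.shape != reference.grid.shape or not np.allclose(
        spectrum.grid, reference.grid
    ):
        raise GridAlignmentError("spectrum and reference are on different wavelength grids")
    if np.any(spectrum.intensity <= 0) or np.any(reference.intensity <= 0):
        raise DomainError("intensities must be positive to take logarithms")
    od = np.log(reference.intensity) - np.log(spectrum.intensity)
    return ODSpectrum(grid=spectrum.grid, od=od, meta=spectrum.meta)


def _snap_wavelengths(
    grid: np.ndarray, wavelengths: tuple[float, ...], tol_nm: float
) -> np.ndarray:
    idx = np.empty(len(wavelengths), dtype=int)
    for j, wl in enumerate(wavelengths):
        i = int(np.argmin(np.abs(grid - wl)))
        if abs(grid[i] - wl) > tol_nm:
            raise WavelengthResolutionError(
                f"requested {wl} nm is {abs(grid[i] - wl):.2f} nm from the nearest "
                f"grid point ({grid[i]} nm), beyond the {tol_nm} nm snap tolerance"
            )
        idx[j] = i
    return idx


def delta_od(
    od_t1: ODSpectrum,
    od_t2: ODSpectrum,
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS,
    snap_tol_nm: float = 2.0,
    boxcar_halfwidth: int = 0,
) -> DeltaOD:
    """Differential OD, ``OD(t2) - OD(t1)``, at the selected wavelengths.

    Requested wavelengths snap to the nearest grid point within
    ``snap_tol_nm`` (the spectrometer grid rarely lands exactly on 740/840);
    the grid points actually used are recorded in the result.  With
    ``boxcar_halfwidth = k > 0`` the OD at each selected point is replaced
    by the mean over ±k neighbouring grid points before differencing, which
    suppresses per-pixel noise; the band membership is recorded so the
    inversion can average its coefficient rows identically.
    """
    if od_t1.grid.shape != od_t2.grid.shape or not np.allclose(od_t1.grid, od_t2.grid):
        raise GridAlignmentError("OD spectra are on different wavelength grids")
    grid = od_t1.grid
    idx = _snap_wavelengths(grid, tuple(wavelengths), snap_tol_nm)
    bands = []
    for i in idx:
        lo = max(0, i - boxcar_halfwidth)
        hi = min(grid.size, i + boxcar_halfwidth + 1)
        bands.append(tuple(float(w) for w in grid[lo:hi]))

    def extract(od: np.ndarray) -> np.ndarray:
        vals = np.empty(idx.size)
        for j, i in enumerate(idx):
            lo = max(0, i - boxcar_halfwidth)
            hi = min(od.size, i + boxcar_halfwidth + 1)
            vals[j] = od[lo:hi].mean()
        return vals

    values = extract(od_t2.od) - extract(od_t1.od)
    return DeltaOD(
        wavelengths=tuple(float(grid[i]) for i in idx),
        requested=tuple(float(w) for w in wavelengths),
        values=values,
        timepoints=(od_t1.meta.timepoint, od_t2.meta.timepoint),
        bands=tuple(bands),
    )


def _design_matrix(
    dod: DeltaOD,
    geom: ProbeGeometry,
    chrom: ChromophoreSet,
    names: tuple[str, str],
) -> np.ndarray:
    # One row per selected wavelength: extinction averaged over the same
    # band the OD was averaged over (single point by default), times the
    # effective pathlength DPF(center) * d in cm.
    A = np.empty((len(dod.wavelengths), len(names)))
    for j, (center, band) in enumerate(zip(dod.wavelengths, dod.bands)):
        pathlength = dpf_at(geom, center) * geom.d_cm
        for i, name in enumerate(names):
            eps = np.mean(np.asarray(extinction_at(chrom, name, np.asarray(band))))
            A[j, i] = eps * pathlength
    return A


def solve_concentration_changes(
    dod: DeltaOD,
    geom: ProbeGeometry,
    chrom: ChromophoreSet,
    names: tuple[str, str] = (HBO2, HB),
    method: str = "auto",
    cond_cap: float = 1e8,
) -> DeltaConcentration:
    """Invert the differential-OD system to (dHbO2, dHb) in mM.

    With exactly two wavelengths the 2x2 system is solved in closed form
    (explicit determinant inversion); with more, by ordinary least squares
    on rows ``eps_i(lambda) * DPF(lambda) * d``.  ``method`` can force
    ``"closed_form"`` or ``"lstsq"`` (the two agree to machine precision on
    two-wavelength systems, a cross-check the tests exploit).  The design
    matrix condition number is reported, and a value above ``cond_cap``
    raises :class:`ConditioningError` naming the wavelengths.
    """
    if len(dod.wavelengths) < 2:
        raise ValueError("inversion needs at least two wavelengths")
    A = _design_matrix(dod, geom, chrom, names)
    cond = float(np.linalg.cond(A))
    if not np.isfinite(cond) or cond > cond_cap:
        raise ConditioningError(
            f"extinction system at wavelengths {dod.wavelengths} nm is "
            f"ill-conditioned (cond = {cond:.3g} > {cond_cap:.3g})"
        )
    if method == "auto":
        method = "closed_form" if A.shape == (2, 2) else "lstsq"
    if method == "closed_form":
        if A.shape != (2, 2):
            raise ValueError("closed-form solve requires exactly two wavelengths")
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        d1 = (A[1, 1] * dod.values[0] - A[0, 1] * dod.values[1]) / det
        d2 = (-A[1, 0] * dod.values[0] + A[0, 0] * dod.values[1]) / det
        sol = np.array([d1, d2])
    elif method == "lstsq":
        sol, *_ = np.linalg.lstsq(A, dod.values, rcond=None)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DeltaConcentration(
        d_hbo2=float(sol[0]),
        d_hb=float(sol[1]),
        timepoints=dod.timepoints,
        wavelengths=dod.wavelengths,
        condition_number=cond,
    )


def compute_sto2(
    dc: DeltaConcentration,
    baseline_sto2: float = 0.70,
    baseline_thb_mm: float = 0.1,
) -> OxygenationEstimate:
    """Convert concentration changes to StO2 (%) under a baseline assumption.

    The baseline state is reconstructed as HbO2 = s*T + dHbO2 and
    Hb = (1-s)*T + dHb with s the assumed baseline saturation and T the
    assumed total hemoglobin (mM); StO2 = 100 * HbO2 / (HbO2 + Hb).
    Negative reconstructed concentrations (noise) are clamped to zero and
    the estimate flagged rather than rejected.
    """
    if baseline_thb_mm <= 0:
        raise ValueError("baseline total hemoglobin must be positive")
    if not 0.0 <= baseline_sto2 <= 1.0:
        raise ValueError("baseline StO2 must be a fraction in [0, 1]")
    hbo2 = baseline_sto2 * baseline_thb_mm + dc.d_hbo2
    hb = (1.0 - baseline_sto2) * baseline_thb_mm + dc.d_hb
    clamped = hbo2 < 0 or hb < 0
    hbo2, hb = max(hbo2, 0.0), max(hb, 0.0)
    if hbo2 + hb == 0:
        raise SaturationUndefinedError("total hemoglobin is zero after clamping")
    return OxygenationEstimate(
        sto2_percent=100.0 * hbo2 / (hbo2 + hb),
        timepoint=dc.timepoints[1],
        baseline_sto2=baseline_sto2,
        baseline_thb_mm=baseline_thb_mm,
        clamped=clamped,
    )


def sto2_timeseries(
    records: list[StudyRecord],
    geom: ProbeGeometry,
    chrom: ChromophoreSet,
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS,
    baseline_sto2: float = 0.70,
    baseline_thb_mm: float = 0.1,
    baseline_timepoint: int = 0,
    snap_tol_nm: float = 2.0,
    boxcar_halfwidth: int = 2,
) -> list[OxygenationEstimate]:
    """StO2 time series for one subject/limb from its acquisitions.

    Every later timepoint is differenced against the pre-surgery day-0
    acquisition (never against the previous timepoint, so errors do not
    accumulate), inverted at the configured wavelength pair, and converted
    to StO2 under the configured baseline.  Day 0 itself maps to the
    baseline StO2 exactly.

    Extraction defaults to a small boxcar band (±2 grid points around each
    analysis wavelength) rather than a single pixel: a broadband
    spectrometer oversamples the spectrum, and averaging a few-nm band
    suppresses per-pixel noise without biasing the band value (the
    inversion averages its coefficients over the identical band).  Set
    ``boxcar_halfwidth=0`` for strict single-pixel extraction.
    """
    by_t = {r.spectrum.meta.timepoint: r for r in records}
    if baseline_timepoint not in by_t:
        raise BaselineMissingError(
            f"no baseline (day {baseline_timepoint}) acquisition among timepoints "
            f"{sorted(by_t)}"
        )
    base = by_t[baseline_timepoint]
    od0 = compute_od(base.spectrum, base.reference)
    out: list[OxygenationEstimate] = []
    for t in sorted(by_t):
        meta = by_t[t].spectrum.meta
        ident = dict(subject=meta.subject, group=meta.group, limb=meta.limb,
                     skin=meta.skin)
        if t == baseline_timepoint:
            out.append(
                OxygenationEstimate(
                    sto2_percent=100.0 * baseline_sto2,
                    timepoint=t,
                    baseline_sto2=baseline_sto2,
                    baseline_thb_mm=baseline_thb_mm,
                    **ident,
                )
            )
            continue
        od_t = compute_od(by_t[t].spectrum, by_t[t].reference)
        dod = delta_od(od0, od_t, wavelengths, snap_tol_nm=snap_tol_nm,
                       boxcar_halfwidth=boxcar_halfwidth)
        dc = solve_concentration_changes(dod, geom, chrom)
        est = compute_sto2(dc, baseline_sto2, baseline_thb_mm)
        out.append(
            OxygenationEstimate(
                sto2_percent=est.sto2_percent,
                timepoint=t,
                baseline_sto2=baseline_sto2,
                baseline_thb_mm=baseline_thb_mm,
                clamped=est.clamped,
                **ident,
            )
        )
    return out
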