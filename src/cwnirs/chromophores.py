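"""Optical constants: hemoglobin extinction curves, DPF table, probe geometry.

Continuous-wave NIRS analysis needs three ingredients that are fixed a
priori rather than measured: the molar extinction coefficients
``epsilon_i(lambda)`` of the absorbing chromophores (here oxy- and
deoxyhemoglobin, with total hemoglobin as their sum), the differential
pathlength factor DPF(lambda) that converts the geometric source-detector
separation into an effective photon pathlength, and the probe geometry
itself.  This module bundles all three and exposes interpolating lookups.

Unit contract (kept rigid to avoid silent order-of-magnitude errors):
concentrations are in mM, pathlengths in cm (the source-detector distance
``d`` is *stored* in mm, the field convention, and converted internally),
and extinction coefficients are in mM^-1 cm^-1 on a **natural-log** basis,
so that ``mu_a = sum_i epsilon_i * C_i`` drops directly into
``OD = -ln(I/I0) = mu_a * DPF * d + G`` with no hidden ln(10) factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UnknownChromophoreError, WavelengthRangeError

_DATA_DIR = Path(__file__).parent / "data"

#: Canonical chromophore identifiers used throughout the package.
HBO2, HB, THB = "HbO2", "Hb", "THb"


@dataclass(frozen=True)
class ChromophoreSet:
    """Named absorbers with extinction coefficient curves on a shared grid.

    Parameters
    ----------
    grid
        Wavelengths in nm, strictly increasing.
    epsilon
        Mapping from chromophore name to its extinction curve on ``grid``,
        in mM^-1 cm^-1, natural-log basis.
    """

    grid: np.ndarray
    epsilon: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        eps = {k: np.asarray(v, dtype=float) for k, v in self.epsilon.items()}
        object.__setattr__(self, "epsilon", eps)
        for name, curve in eps.items():
            if curve.shape != grid.shape:
                raise ValueError(f"curve for {name!r} not defined on the full grid")
            if np.any(curve < 0):
                raise ValueError(f"negative extinction values for {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.epsilon)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector separation, DPF table, and geometry constant G.

    ``d_mm`` is the source-detector separation in mm (default 8 mm, chosen
    for a penetration depth reaching a femoral implant-tissue interface).
    ``dpf`` maps wavelength (nm) to the dimensionless differential
    pathlength factor; the default carries the literature values at the
    two analysis wavelengths, 3.50 at 740 nm and 3.01 at 840 nm.  ``g`` is
    the unknown geometry-dependent attenuation offset; it enters only the
    forward simulation, because differential measurements cancel it.
    """

    d_mm: float = 8.0
    dpf: dict[float, float] = field(
        default_factory=lambda: {740.0: 3.50, 840.0: 3.01}
    )
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.d_mm <= 0:
            raise ValueError("source-detector separation must be positive")
        if not self.dpf or any(v <= 0 for v in self.dpf.values()):
            raise ValueError("all DPF values must be positive")
        object.__setattr__(
            self, "dpf", dict(sorted((float(k), float(v)) for k, v in self.dpf.items()))
        )

    @property
    def d_cm(self) -> float:
        """Separation converted to cm, the unit used in the attenuation product."""
        return self.d_mm / 10.0


def load_extinction_table(path: str | Path | None = None) -> ChromophoreSet:
    """Load an extinction table from a delimited text file.

    The format is one comment/header block (``#`` lines plus one column
    header line), then one row per wavelength: wavelength in nm followed by
    one column per chromophore.  Values must already be in mM^-1 cm^-1 on
    the natural-log basis (log10-basis tabulations must be multiplied by
    ln 10 before shipping; the bundled file header records this).

    With no ``path`` the bundled hemoglobin table is loaded and the THb
    column is validated to equal HbO2 + Hb pointwise.
    """
    bundled = path is None
    path = Path(path) if path is not None else _DATA_DIR / "hb_extinction_synthetic.tsv"
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not names:
                names = line.split("\t")[1:]
                continue
            rows.append([float(x) for x in line.split("\t")])
    data = np.array(rows, dtype=float)
    cset = ChromophoreSet(
        grid=data[:, 0],
        epsilon={name: data[:, i + 1] for i, name in enumerate(names)},
    )
    if bundled:
        np.testing.assert_allclose(
            cset.epsilon[THB], cset.epsilon[HBO2] + cset.epsilon[HB], atol=1e-9
        )
    return cset


def extinction_at(
    cset: ChromophoreSet, name: str, wavelength: float | np.ndarray
) -> float | np.ndarray:
    """Extinction coefficient of ``name`` at ``wavelength`` (nm), mM^-1 cm^-1.

    Linear interpolation between bracketing grid points; exact on a grid
    point.  Raises :class:`UnknownChromophoreError` for an unknown name and
    :class:`WavelengthRangeError` outside the table span (no extrapolation).
    """
    if name not in cset.epsilon:
        raise UnknownChromophoreError(
            f"unknown chromophore {name!r}; available: {cset.names}"
        )
    wl = np.asarray(wavelength, dtype=float)
    lo, hi = cset.span
    if np.any(wl < lo) or np.any(wl > hi):
        raise WavelengthRangeError(
            f"wavelength {wavelength} nm outside extinction table span [{lo}, {hi}] nm"
        )
    out = np.interp(wl, cset.grid, cset.epsilon[name])
    return float(out) if np.isscalar(wavelength) else out


def dpf_at(geom: ProbeGeometry, wavelength: float | np.ndarray) -> float | np.ndarray:
    """DPF at ``wavelength`` (nm): exact table value, or linear interpolation
    between the nearest entries.  Never extrapolates — small DPF errors
    propagate directly into concentration errors, so outside the tabulated
    span a :class:`WavelengthRangeError` is raised instead of a guess.
    """
    table_wl = np.array(list(geom.dpf), dtype=float)
    table_v = np.array(list(geom.dpf.values()), dtype=float)
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < table_wl[0]) or np.any(wl > table_wl[-1]):
        raise WavelengthRangeError(
            f"wavelength {wavelength} nm outside DPF table span "
            f"[{table_wl[0]}, {table_wl[-1]}] nm"
        )
    out = np.interp(wl, table_wl, table_v)
    return float(out) if np.isscalar(wavelength) else out


def penetration_depth_range(geom: ProbeGeometry) -> tuple[float, float]:
    """Approximate photon penetration depth range in mm.

    Diffuse photons interrogate, on average, a depth of about one third to
    one half of the source-detector separation, so an 8 mm probe probes
    roughly 2.7-4 mm below the surface.
    """
    return geom.d_mm / 3.0, geom.d_mm / 2.0


def simulation_dpf_table(
    span: tuple[float, float] = (650.0, 1050.0),
    anchors: dict[float, float] | None = None,
) -> dict[float, float]:
    """A DPF table covering a full spectrometer span, for forward simulation.

    The inversion only ever needs DPF at the analysis wavelengths, but the
    forward model evaluates the attenuation at every grid point, so the
    two-entry default table is linearly extended from its anchor pair
    (default 740 nm -> 3.50, 840 nm -> 3.01; DPF decreases gently with
    wavelength in soft tissue) and floored at 1 to stay physical.
    """
    anchors = anchors or {740.0: 3.50, 840.0: 3.01}
    (w1, v1), (w2, v2) = sorted(anchors.items())[:2]
    slope = (v2 - v1) / (w2 - w1)

    def value(w: float) -> float:
        return max(1.0, v1 + slope * (w - w1))

    table = {float(w): value(w) for w in span}
    table.update(anchors)
    return dict(sorted(table.items()))
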