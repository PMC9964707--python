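"""Forward simulation of a longitudinal diffuse-reflectance implant study.

The package's downstream stages (optical-density computation, MBLL
inversion, PCA exploration) are exercised on synthetic data that emulate a
rodent biodegradable-implant experiment: three groups (Mg alloy, titanium,
sham surgery), both hindlimbs measured at days 0, 1, 3, 7, 14 and 45 after
implantation, with group-specific tissue-oxygenation trajectories planted
in the ground truth.

The forward model is the modified Beer-Lambert law itself,

    I(lambda) = I0(lambda) * exp(-(mu_a(lambda) * DPF(lambda) * d + G)),
    mu_a(lambda) = sum_i epsilon_i(lambda) * C_i,

so the generator doubles as the oracle for the inversion: a noise-free
simulated pair must invert back to the planted concentration change
exactly.  The planted effects encode the study's qualitative hemodynamics:
the Mg group shows a large, highly variable StO2 excursion at days 1-3
(gas evolution from alloy corrosion) that returns to baseline by day 45,
while Ti and sham show a moderate post-surgical depression that persists;
one Ti subject develops a skin rash from day 3 on with persistently
elevated StO2.  Every record stores its true concentration state in a
sidecar so recovery can be scored, and the study can be read back blinded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .chromophores import (
    HB,
    HBO2,
    ChromophoreSet,
    ProbeGeometry,
    dpf_at,
    extinction_at,
    load_extinction_table,
    simulation_dpf_table,
)
from .errors import GridAlignmentError, ParseError

GROUPS = ("Mg", "Ti", "sham")
TIMEPOINTS = (0, 1, 3, 7, 14, 45)


@dataclass(frozen=True)
class ConcentrationState:
    """Chromophore concentrations in mM (non-negative)."""

    hbo2: float
    hb: float

    def __post_init__(self) -> None:
        if self.hbo2 < 0 or self.hb < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def thb(self) -> float:
        return self.hbo2 + self.hb

    @property
    def sto2(self) -> float:
        """True tissue oxygen saturation as a fraction."""
        return self.hbo2 / self.thb

    def as_dict(self) -> dict[str, float]:
        return {HBO2: self.hbo2, HB: self.hb}


@dataclass(frozen=True)
class AcquisitionMeta:
    subject: str
    group: str
    limb: str
    timepoint: int
    skin: str = "normal"

    @property
    def key(self) -> str:
        return f"{self.subject}_{self.limb}_d{self.timepoint:02d}"


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Incident-light spectrum I0(lambda) in arbitrary counts."""

    grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        _check_spectral_arrays(self.grid, self.intensity)
        object.__setattr__(self, "grid", np.asarray(self.grid, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))


@dataclass(frozen=True)
class Spectrum:
    """Detected diffuse-reflectance spectrum I(lambda) with acquisition metadata."""

    grid: np.ndarray
    intensity: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        _check_spectral_arrays(self.grid, self.intensity)
        object.__setattr__(self, "grid", np.asarray(self.grid, float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, float))


def _check_spectral_arrays(grid, intensity) -> None:
    grid = np.asarray(grid, float)
    intensity = np.asarray(intensity, float)
    if grid.ndim != 1 or grid.shape != intensity.shape:
        raise ValueError("grid and intensity must be 1-D arrays of equal length")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if grid[0] < 650.0 or grid[-1] > 1050.0:
        raise ValueError("grid must lie within the 650-1050 nm instrument range")
    if np.any(intensity <= 0):
        raise ValueError("intensities must be positive")


# --------------------------------------------------------------------------
# study design


def _default_sto2_offsets() -> dict[str, dict[int, float]]:
    # StO2 offset from baseline (fraction) per group and day.  Mg: large early
    # excursion decaying to ~0 by day 45 (faster soft-tissue recovery); Ti and
    # sham: moderate post-surgical depression that persists through day 45.
    return {
        "Mg": {0: 0.0, 1: -0.10, 3: -0.08, 7: -0.04, 14: -0.02, 45: 0.0},
        "Ti": {0: 0.0, 1: -0.08, 3: -0.07, 7: -0.06, 14: -0.055, 45: -0.05},
        "sham": {0: 0.0, 1: -0.06, 3: -0.055, 7: -0.05, 14: -0.045, 45: -0.04},
    }


def _default_sto2_extra_sd() -> dict[str, dict[int, float]]:
    # Extra between-subject StO2 spread (fraction) on top of the base
    # subject noise; only the Mg group is inflated, at days 1 and 3.
    zeros = {t: 0.0 for t in TIMEPOINTS}
    return {
        "Mg": {0: 0.0, 1: 0.08, 3: 0.06, 7: 0.0, 14: 0.0, 45: 0.0},
        "Ti": dict(zeros),
        "sham": dict(zeros),
    }


@dataclass
class StudyDesign:
    """Parameters of the synthetic longitudinal study.

    Defaults emulate the animal experiment the package targets: 15 subjects
    split 7 Mg / 4 Ti / 4 sham, six timepoints, baseline StO2 0.70 with
    0.1 mM total hemoglobin, Mg-specific early variance inflation, one
    rash-affected Ti subject, and 1% multiplicative instrument noise.
    """

    subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"Mg": 7, "Ti": 4, "sham": 4}
    )
    timepoints: tuple[int, ...] = TIMEPOINTS
    limbs: tuple[str, ...] = ("left", "right")
    implanted_limb: str = "left"
    baseline_sto2: float = 0.70
    baseline_thb_mm: float = 0.1
    thb_subject_sd: float = 0.005
    sto2_subject_sd: float = 0.02
    sto2_offsets: dict[str, dict[int, float]] = field(default_factory=_default_sto2_offsets)
    sto2_extra_sd: dict[str, dict[int, float]] = field(default_factory=_default_sto2_extra_sd)
    rash_subject: bool = True
    rash_onset_day: int = 3
    rash_sto2_offset: float = 0.10
    g_range: tuple[float, float] = (0.5, 1.5)
    g_jitter_sd: float = 0.0
    noise_rel: float = 0.01
    grid_step_nm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(int(t) for t in self.timepoints)
        if any(t < 0 for t in tps) or list(tps) != sorted(tps):
            raise ValueError("timepoints must be non-negative and sorted")
        self.timepoints = tps
        if not 0.0 <= self.baseline_sto2 <= 1.0:
            raise ValueError("baseline StO2 must be a fraction in [0, 1]")
        if self.noise_rel < 0:
            raise ValueError("noise level must be non-negative")
        if self.baseline_thb_mm <= 0:
            raise ValueError("baseline total hemoglobin must be positive")

    def subject_ids(self) -> Iterator[tuple[str, str]]:
        for group in self.subjects_per_group:
            for i in range(self.subjects_per_group[group]):
                yield group, f"{group}{i + 1:02d}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sto2_offsets"] = {g: {str(t): v for t, v in m.items()} for g, m in d["sto2_offsets"].items()}
        d["sto2_extra_sd"] = {g: {str(t): v for t, v in m.items()} for g, m in d["sto2_extra_sd"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        for key in ("timepoints", "limbs", "g_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("sto2_offsets", "sto2_extra_sd"):
            if key in d:
                d[key] = {g: {int(t): float(v) for t, v in m.items()} for g, m in d[key].items()}
        return cls(**d)


@dataclass(frozen=True)
class StudyRecord:
    spectrum: Spectrum
    reference: ReferenceSpectrum
    truth: ConcentrationState | None


@dataclass
class StudyDataset:
    """A simulated (or loaded) study: one record per subject x limb x timepoint."""

    design: StudyDesign | None
    records: list[StudyRecord]

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def filter(self, **criteria) -> "StudyDataset":
        """Subset records by metadata equality, e.g. ``filter(group="Mg", limb="left")``."""
        out = [
            r
            for r in self.records
            if all(getattr(r.spectrum.meta, k) == v for k, v in criteria.items())
        ]
        return StudyDataset(design=self.design, records=out)

    def true_sto2(self) -> dict[str, float]:
        """Map acquisition key -> true StO2 fraction (requires truth)."""
        out = {}
        for r in self.records:
            if r.truth is None:
                raise ValueError("dataset is blinded: no truth available")
            out[r.spectrum.meta.key] = r.truth.sto2
        return out


# --------------------------------------------------------------------------
# forward model


def default_reference(grid: np.ndarray | None = None) -> ReferenceSpectrum:
    """A smooth broadband lamp spectrum over the instrument range.

    Tungsten-halogen-like: a wide Gaussian peaking near 900 nm on a
    constant pedestal, in arbitrary counts.
    """
    if grid is None:
        grid = np.arange(650.0, 1050.0 + 1e-9, 2.0)
    grid = np.asarray(grid, float)
    intensity = 5000.0 + 40000.0 * np.exp(-0.5 * ((grid - 900.0) / 150.0) ** 2)
    return ReferenceSpectrum(grid=grid, intensity=intensity)


def default_simulation_geometry(d_mm: float = 8.0, g: float = 0.0) -> ProbeGeometry:
    """Probe geometry whose DPF table spans the full 650-1050 nm grid."""
    return ProbeGeometry(d_mm=d_mm, dpf=simulation_dpf_table(), g=g)


def simulate_spectrum(
    state: ConcentrationState,
    geom: ProbeGeometry,
    chrom: ChromophoreSet,
    ref: ReferenceSpectrum,
    noise_rel: float = 0.0,
    rng: np.random.Generator | int | None = None,
    meta: AcquisitionMeta | None = None,
) -> Spectrum:
    """Simulate one detected spectrum from the attenuation model.

    Noise-free, the output is exactly
    ``I0 * exp(-(mu_a * DPF * d + G))`` with ``mu_a = sum_i eps_i * C_i``
    evaluated on the reference grid.  With ``noise_rel > 0`` each intensity
    is multiplied by an independent Gaussian factor ``1 + noise_rel * z``
    truncated below at 0.05 to preserve positivity; the draw is
    deterministic for a fixed ``rng`` seed.
    """
    grid = ref.grid
    lo, hi = chrom.span
    if grid[0] < lo or grid[-1] > hi:
        raise GridAlignmentError(
            f"chromophore curves (span [{lo}, {hi}] nm) do not cover the "
            f"reference grid [{grid[0]}, {grid[-1]}] nm"
        )
    mu_a = np.zeros_like(grid)
    for name, conc in state.as_dict().items():
        mu_a += extinction_at(chrom, name, grid) * conc
    attenuation = mu_a * dpf_at(geom, grid) * geom.d_cm + geom.g
    intensity = ref.intensity * np.exp(-attenuation)
    if noise_rel > 0:
        rng = np.random.default_rng(rng)
        factors = np.maximum(1.0 + noise_rel * rng.standard_normal(grid.size), 0.05)
        intensity = intensity * factors
    meta = meta or AcquisitionMeta("sim", "sim", "left", 0)
    return Spectrum(grid=grid, intensity=intensity, meta=meta)


def simulate_study(
    design: StudyDesign,
    geom: ProbeGeometry | None = None,
    chrom: ChromophoreSet | None = None,
    ref: ReferenceSpectrum | None = None,
) -> StudyDataset:
    """Generate the full synthetic study from a design.

    For every subject, limb and timepoint the true StO2 is drawn as
    baseline + group/timepoint offset + N(0, base^2 + extra^2); group
    effects apply to the implanted limb only, the contralateral limb stays
    at baseline.  G is drawn once per subject/limb (differential analysis
    assumes it is constant over time; ``g_jitter_sd`` can break that
    assumption deliberately).  Reproducible bit-for-bit under the design
    seed.
    """
    geom = geom or default_simulation_geometry()
    chrom = chrom or load_extinction_table()
    grid = np.arange(650.0, 1050.0 + 1e-9, design.grid_step_nm)
    ref = ref or default_reference(grid)
    rng = np.random.default_rng(design.seed)

    rash_id = None
    if design.rash_subject and design.subjects_per_group.get("Ti", 0) > 0:
        rash_id = "Ti01"

    records: list[StudyRecord] = []
    for group, subject in design.subject_ids():
        thb = max(0.01, design.baseline_thb_mm + design.thb_subject_sd * rng.standard_normal())
        for limb in design.limbs:
            g_subject = rng.uniform(*design.g_range)
            for t in design.timepoints:
                implanted = limb == design.implanted_limb
                offset = design.sto2_offsets[group].get(t, 0.0) if implanted else 0.0
                extra = design.sto2_extra_sd[group].get(t, 0.0) if implanted else 0.0
                skin = "normal"
                if subject == rash_id and t >= design.rash_onset_day:
                    skin = "rash"
                    if implanted:
                        offset += design.rash_sto2_offset
                sd = float(np.hypot(design.sto2_subject_sd, extra))
                sto2 = design.baseline_sto2 + offset + sd * rng.standard_normal()
                sto2 = float(np.clip(sto2, 0.02, 0.98))
                state = ConcentrationState(hbo2=sto2 * thb, hb=(1.0 - sto2) * thb)
                g_t = g_subject + (
                    design.g_jitter_sd * rng.standard_normal() if design.g_jitter_sd > 0 else 0.0
                )
                geom_t = ProbeGeometry(d_mm=geom.d_mm, dpf=geom.dpf, g=g_t)
                meta = AcquisitionMeta(subject, group, limb, t, skin)
                spec = simulate_spectrum(
                    state, geom_t, chrom, ref, noise_rel=design.noise_rel, rng=rng, meta=meta
                )
                records.append(StudyRecord(spectrum=spec, reference=ref, truth=state))
    return StudyDataset(design=design, records=records)


# --------------------------------------------------------------------------
# plain-text persistence

_MANIFEST_HEADER = "file\tsubject\tgroup\tlimb\ttimepoint\tskin"
_TRUTH_HEADER = "key\tHbO2_mM\tHb_mM"
_SPECTRUM_HEADER = "wavelength_nm\tintensity"


def write_study(dataset: StudyDataset, directory: str | Path) -> None:
    """Write a study as plain-text files: one two-column file per acquisition,
    a manifest, a shared reference spectrum, a truth sidecar (separate so
    the pipeline can be run blinded), and the design as JSON."""
    directory = Path(directory)
    (directory / "spectra").mkdir(parents=True, exist_ok=True)
    manifest_lines = [_MANIFEST_HEADER]
    truth_lines = [_TRUTH_HEADER]
    ref = dataset.records[0].reference if dataset.records else None
    for rec in dataset.records:
        m = rec.spectrum.meta
        fname = f"spectra/{m.key}.tsv"
        _write_xy(directory / fname, rec.spectrum.grid, rec.spectrum.intensity)
        manifest_lines.append(f"{fname}\t{m.subject}\t{m.group}\t{m.limb}\t{m.timepoint}\t{m.skin}")
        if rec.truth is not None:
            truth_lines.append(f"{m.key}\t{rec.truth.hbo2:.12g}\t{rec.truth.hb:.12g}")
    (directory / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    if len(truth_lines) > 1:
        (directory / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    if ref is not None:
        _write_xy(directory / "reference.tsv", ref.grid, ref.intensity)
    if dataset.design is not None:
        (directory / "design.json").write_text(
            json.dumps(dataset.design.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def _write_xy(path: Path, x: np.ndarray, y: np.ndarray) -> None:
    lines = [_SPECTRUM_HEADER]
    lines += [f"{a:.12g}\t{b:.12g}" for a, b in zip(x, y)]
    path.write_text("\n".join(lines) + "\n")


def _read_xy(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _SPECTRUM_HEADER:
        raise ParseError(f"{path}:1: expected header {_SPECTRUM_HEADER!r}")
    x, y = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{i}: expected two tab-separated columns")
        try:
            x.append(float(parts[0]))
            y.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from None
    return np.array(x), np.array(y)


def read_study(directory: str | Path, blinded: bool = False) -> StudyDataset:
    """Read a study written by :func:`write_study`.

    With ``blinded=True`` the truth sidecar is ignored and every record's
    truth is ``None``; spectra and metadata are identical either way.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.tsv"
    with open(manifest_path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MANIFEST_HEADER:
        raise ParseError(f"{manifest_path}:1: expected header {_MANIFEST_HEADER!r}")

    truth: dict[str, ConcentrationState] = {}
    truth_path = directory / "truth.tsv"
    if not blinded and truth_path.exists():
        with open(truth_path) as fh:
            tlines = fh.read().splitlines()
        if not tlines or tlines[0] != _TRUTH_HEADER:
            raise ParseError(f"{truth_path}:1: expected header {_TRUTH_HEADER!r}")
        for i, line in enumerate(tlines[1:], start=2):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{truth_path}:{i}: expected three columns")
            truth[parts[0]] = ConcentrationState(float(parts[1]), float(parts[2]))

    rx, ry = _read_xy(directory / "reference.tsv")
    ref = ReferenceSpectrum(grid=rx, intensity=ry)

    design = None
    design_path = directory / "design.json"
    if design_path.exists():
        design = StudyDesign.from_dict(json.loads(design_path.read_text()))

    records = []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"{manifest_path}:{i}: expected six columns")
        fname, subject, group, limb, timepoint, skin = parts
        meta = AcquisitionMeta(subject, group, limb, int(timepoint), skin)
        x, y = _read_xy(directory / fname)
        spec = Spectrum(grid=x, intensity=y, meta=meta)
        records.append(
            StudyRecord(spectrum=spec, reference=ref, truth=truth.get(meta.key))
        )
    return StudyDataset(design=design, records=records)
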