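"""Exploratory PCA of longitudinal NIRS spectra.

The score space of a PCA fitted to (normalized) spectra is used for three
comparisons: flagging aberrant acquisitions (robust outlier detection),
quantifying how far a condition's spectra sit from the rest (e.g. a
skin-rash subject vs normal skin, via centroid distance plus a label
permutation test), and measuring how spectrally similar two timepoints are
within a group (the day-45 vs day-0 healing comparison: a group whose
tissue has returned to its pre-surgical state has a small centroid
distance between those days).

PCA itself is delegated to scikit-learn with a deterministic sign
convention (each loading's largest-magnitude element is made positive) so
repeated fits on identical data are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import (
    DegenerateRowError,
    GroupingError,
    InsufficientDataError,
)
from .mbll import compute_od
from .synthetic import StudyDataset


@dataclass
class SpectraMatrix:
    """Acquisitions x wavelengths matrix with row metadata.

    ``values`` holds one spectrum per row (raw intensity, OD, or a
    normalized version); ``meta`` is a DataFrame aligned with the rows,
    carrying subject, group, limb, timepoint and skin condition.
    """

    values: np.ndarray
    grid: np.ndarray
    meta: pd.DataFrame
    kind: str = "od"  # "od" | "intensity", possibly suffixed by normalization

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.grid = np.asarray(self.grid, float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.size:
            raise ValueError("values must be 2-D with one column per grid point")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata rows must match spectra rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra matrix contains missing/non-finite values")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def select(self, mask: np.ndarray) -> "SpectraMatrix":
        mask = np.asarray(mask)
        return SpectraMatrix(
            values=self.values[mask],
            grid=self.grid,
            meta=self.meta.loc[mask].reset_index(drop=True),
            kind=self.kind,
        )


def assemble_matrix(dataset: StudyDataset, kind: str = "od") -> SpectraMatrix:
    """Stack a study's acquisitions into a SpectraMatrix.

    ``kind="od"`` converts each spectrum to optical density against its
    reference (the usual input for spectral PCA); ``kind="intensity"``
    keeps raw counts.
    """
    if not dataset.records:
        raise GroupingError("empty dataset")
    grid = dataset.records[0].spectrum.grid
    rows, meta_rows = [], []
    for rec in dataset.records:
        if kind == "od":
            rows.append(compute_od(rec.spectrum, rec.reference).od)
        elif kind == "intensity":
            rows.append(rec.spectrum.intensity)
        else:
            raise ValueError(f"unknown kind {kind!r}")
        m = rec.spectrum.meta
        meta_rows.append(
            dict(key=m.key, subject=m.subject, group=m.group, limb=m.limb,
                 timepoint=m.timepoint, skin=m.skin)
        )
    return SpectraMatrix(
        values=np.vstack(rows), grid=grid, meta=pd.DataFrame(meta_rows), kind=kind
    )


def normalize_spectra(m: SpectraMatrix, method: str = "snv") -> SpectraMatrix:
    """Per-spectrum normalization.

    ``"snv"`` (standard normal variate, the default): each row is centered
    to mean 0 and scaled to standard deviation 1, which removes
    per-acquisition multiplicative gain and additive offset.  ``"unit"``
    scales each row to unit Euclidean norm; ``"max"`` divides by the row
    maximum.  Metadata is untouched.
    """
    x = m.values
    if method == "snv":
        sd = x.std(axis=1, ddof=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DegenerateRowError(
                f"zero-variance spectra cannot be SNV-normalized: "
                f"{list(m.meta['key'].iloc[bad])}"
            )
        out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    elif method == "unit":
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms == 0):
            raise DegenerateRowError("zero rows cannot be unit-normalized")
        out = x / norms[:, None]
    elif method == "max":
        mx = np.abs(x).max(axis=1)
        if np.any(mx == 0):
            raise DegenerateRowError("zero rows cannot be max-normalized")
        out = x / mx[:, None]
    elif method == "none":
        out = x.copy()
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return SpectraMatrix(values=out, grid=m.grid, meta=m.meta.copy(),
                         kind=f"{m.kind}+{method}" if method != "none" else m.kind)


@dataclass
class PCAModel:
    """A fitted PCA: loadings, scores, full eigenvalue spectrum, provenance."""

    n_components: int
    loadings: np.ndarray  # (k, p), orthonormal rows
    scores: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # full spectrum, for scree inspection
    explained_variance_ratio: np.ndarray  # full spectrum
    mean: np.ndarray
    preprocessing: str
    meta: pd.DataFrame = field(repr=False, default=None)

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Data reconstructed from the first ``k`` retained components (centered)."""
        k = self.n_components if k is None else k
        return self.scores[:, :k] @ self.loadings[:k]


def fit_pca(m: SpectraMatrix, n_components: int = 2) -> PCAModel:
    """Column-mean-centered PCA of a spectra matrix.

    Two components is the default working choice for these spectra (the
    eigenvalue spectrum is computed in full so a scree plot can justify
    it).  Deterministic: component signs follow the convention that each
    loading's largest-magnitude element is positive.
    """
    n, p = m.values.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least two acquisitions")
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}], got {n_components}")
    pca = PCA(n_components=max_k, svd_solver="full")
    scores_full = pca.fit_transform(m.values)
    loadings = pca.components_
    # sign convention: largest-|.| element of each loading positive
    flip = np.sign(loadings[np.arange(max_k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores_full = scores_full * flip[None, :]
    return PCAModel(
        n_components=n_components,
        loadings=loadings[:n_components],
        scores=scores_full[:, :n_components],
        eigenvalues=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        preprocessing=m.kind,
        meta=m.meta.copy(),
    )


@dataclass
class OutlierReport:
    """Robust score-space outlier flags with full per-row distances."""

    flagged: list[str]  # acquisition keys
    distances: pd.DataFrame  # key, per-component z, squared distance, p-value
    alpha: float
    threshold: float


def detect_outliers(model: PCAModel, alpha: float = 0.01) -> OutlierReport:
    """Flag acquisitions with extreme PCA scores.

    Each retained component's scores are robustly standardized against
    their median and MAD; the squared robust distance (sum of squared
    z-scores over k components) is referred to a chi-square(k) law, and a
    row is flagged when its tail probability is <= ``alpha`` (so the null
    flag rate is calibrated to alpha).  Needs at least 4 rows for the MAD
    to be meaningful.
    """
    scores = model.scores
    n, k = scores.shape
    if n < 4:
        raise InsufficientDataError("outlier detection needs at least 4 acquisitions")
    med = np.median(scores, axis=0)
    mad = stats.median_abs_deviation(scores, axis=0, scale="normal")
    # a zero MAD means the bulk of the component is constant: rows at the
    # median are unremarkable (z = 0), any deviation is infinitely surprising
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (scores - med) / mad
    z[np.isnan(z)] = 0.0
    d2 = np.sum(z**2, axis=1)
    pvals = stats.chi2.sf(d2, df=k)
    flag = pvals <= alpha
    keys = list(model.meta["key"]) if model.meta is not None else [str(i) for i in range(n)]
    dist = pd.DataFrame({"key": keys, "squared_distance": d2, "p_value": pvals,
                         "flagged": flag})
    for j in range(k):
        dist[f"z_pc{j + 1}"] = z[:, j]
    return OutlierReport(
        flagged=[keys[i] for i in np.flatnonzero(flag)],
        distances=dist,
        alpha=alpha,
        threshold=float(stats.chi2.isf(alpha, df=k)),
    )


@dataclass
class SeparationSummary:
    """Centroid distance between two labeled sets of scores, with permutation p."""

    key: str
    group_a: str
    group_b: str
    centroid_distance: float
    p_value: float
    n_a: int
    n_b: int
    n_permutations: int


def _centroid_distance(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    return float(np.linalg.norm(scores_a.mean(axis=0) - scores_b.mean(axis=0)))


def score_group_separation(
    model: PCAModel,
    key: str,
    group_a: str,
    group_b: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> SeparationSummary:
    """How separated are two metadata groups in score space?

    Euclidean distance between the group centroids over the retained
    components, with a label-permutation p-value (one-sided: how often a
    random relabeling achieves a distance at least as large).
    """
    labels = model.meta[key].to_numpy()
    in_a, in_b = labels == group_a, labels == group_b
    if not in_a.any() or not in_b.any():
        raise GroupingError(f"empty group for {key!r}: {group_a!r} or {group_b!r}")
    scores = model.scores[in_a | in_b]
    is_a = (labels[in_a | in_b]) == group_a
    obs = _centroid_distance(scores[is_a], scores[~is_a])
    rng = np.random.default_rng(seed)
    n_a = int(is_a.sum())
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(is_a.size)
        pa = perm[:n_a]
        mask = np.zeros(is_a.size, dtype=bool)
        mask[pa] = True
        if _centroid_distance(scores[mask], scores[~mask]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return SeparationSummary(
        key=key,
        group_a=group_a,
        group_b=group_b,
        centroid_distance=obs,
        p_value=p,
        n_a=n_a,
        n_b=int((~is_a).sum()),
        n_permutations=n_permutations,
    )


@dataclass
class TimepointSimilarity:
    """Score-space centroid distance between two timepoints within a group."""

    group: str
    timepoint_a: int
    timepoint_b: int
    centroid_distance: float
    n_a: int
    n_b: int


def timepoint_similarity(
    model: PCAModel,
    group: str,
    t_a: int,
    t_b: int,
    group_key: str = "group",
    time_key: str = "timepoint",
) -> TimepointSimilarity:
    """Centroid distance between a group's scores at two timepoints.

    A small day-45 vs day-0 distance means the group's spectra have
    returned close to their pre-surgical state (the healing comparison).
    """
    meta = model.meta
    in_g = meta[group_key].to_numpy() == group
    t = meta[time_key].to_numpy()
    a = in_g & (t == t_a)
    b = in_g & (t == t_b)
    if not a.any() or not b.any():
        raise GroupingError(
            f"group {group!r} missing timepoint {t_a if not a.any() else t_b}"
        )
    return TimepointSimilarity(
        group=group,
        timepoint_a=t_a,
        timepoint_b=t_b,
        centroid_distance=_centroid_distance(model.scores[a], model.scores[b]),
        n_a=int(a.sum()),
        n_b=int(b.sum()),
    )


def timepoint_similarity_table(
    model: PCAModel, t_a: int, t_b: int, group_key: str = "group"
) -> pd.DataFrame:
    """Per-group centroid distance between two timepoints, as a table."""
    rows = []
    for g in pd.unique(model.meta[group_key]):
        s = timepoint_similarity(model, g, t_a, t_b, group_key=group_key)
        rows.append(dict(group=g, timepoint_a=t_a, timepoint_b=t_b,
                         centroid_distance=s.centroid_distance, n_a=s.n_a, n_b=s.n_b))
    return pd.DataFrame(rows)
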