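"""Eigenbrain decomposition: robust scaling, participant-by-voxel SVD,
Horn's parallel analysis and projection of new subjects.

The model
---------
Each reference-normalized image is median-centred and scaled by its
interquartile range (a robust per-subject standardization), then stacked
into a participant-by-voxel matrix ``X`` (rows = subjects, columns =
brain-mask voxels).  The thin SVD ``X = U S V^T`` yields:

* eigenbrains: rows of ``V^T`` — orthonormal bipolar spatial patterns of
  relative metabolism (opposing poles of relative hypo-/hyper-metabolism);
* per-subject scores ``U S`` — the signed "eigenvalues" describing how
  strongly, and in which direction, each subject expresses each pattern;
* the covariance share of component k, ``100 * s_k^2 / sum_j s_j^2``.

How many components are signal rather than chance structure is decided by
Horn's parallel analysis: each row of ``X`` is independently permuted to
destroy spatial covariance while preserving each subject's value
distribution, the permuted spectra are recomputed many times, and
components are retained while the observed squared singular value exceeds
the chosen percentile of its null distribution (stopping at the first
failure).

Sign convention: the direction of each eigenbrain is mathematically
arbitrary; we flip each one so its maximum-|loading| voxel is positive and
record the flips, keeping scores reproducible.

The scikit-learn estimator :class:`EigenbrainDecomposition` wraps these
steps as a transformer; the module-level functions expose each step
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .grid import TemplateGrid
from .images import SubjectImage, flatten

__all__ = [
    "ImageMatrix",
    "Decomposition",
    "HornResult",
    "EigenbrainDecomposition",
    "robust_scale",
    "build_matrix",
    "svd_decompose",
    "pct_covariance",
    "pct_covariance_abs",
    "horn_parallel",
    "project",
    "align_components",
    "save_decomposition",
]


# ---------------------------------------------------------------------------
# Robust per-image scaling
# ---------------------------------------------------------------------------

def robust_scale(vector: np.ndarray, subject_id: str = "") -> np.ndarray:
    """Median-centre and IQR-scale one masked-voxel vector.

    Quantiles use linear interpolation between order statistics (the
    numpy default).  A flat image (zero IQR) is an error: it carries no
    spatial information and would divide by zero.
    """
    x = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"subject {subject_id or '<unnamed>'}: non-finite values")
    med = np.median(x)
    q25, q75 = np.percentile(x, [25.0, 75.0])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError(f"subject {subject_id or '<unnamed>'}: zero IQR (flat image)")
    return (x - med) / iqr


def _robust_scale_rows(values: np.ndarray, ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.median(values, axis=1)
    q25, q75 = np.percentile(values, [25.0, 75.0], axis=1)
    iqr = q75 - q25
    bad = ~(iqr > 0)
    if bad.any():
        which = [str(ids[i]) for i in np.flatnonzero(bad)]
        raise ValueError(f"zero IQR (flat image) for subjects: {', '.join(which)}")
    scaled = (values - med[:, None]) / iqr[:, None]
    return scaled, med, iqr


@dataclass(frozen=True)
class ImageMatrix:
    """Robust-scaled participant-by-voxel matrix."""

    values: np.ndarray  # subjects x masked voxels, each row median 0 / IQR 1
    subject_ids: tuple[str, ...]
    voxel_index: np.ndarray  # flat grid indices of the mask voxels
    scaling_median: np.ndarray  # per-subject pre-scaling median
    scaling_iqr: np.ndarray  # per-subject pre-scaling IQR

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def build_matrix(images, grid: TemplateGrid) -> ImageMatrix:
    """Stack normalized subject images into a scaled participant-by-voxel matrix.

    Rows are ordered by subject id (deterministic regardless of input
    order).  Every image must be reference-normalized and on the grid.
    """
    images = list(images)
    ids = [im.subject_id for im in images]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    for im in images:
        if not im.normalized:
            raise ValueError(f"subject {im.subject_id}: image is not reference-normalized")
    order = np.argsort(np.asarray(ids, dtype=object))
    images = [images[i] for i in order]
    raw = np.stack([flatten(im, grid) for im in images])
    scaled, med, iqr = _robust_scale_rows(raw, [im.subject_id for im in images])
    return ImageMatrix(
        values=scaled,
        subject_ids=tuple(im.subject_id for im in images),
        voxel_index=grid.voxel_index,
        scaling_median=med,
        scaling_iqr=iqr,
    )


# ---------------------------------------------------------------------------
# SVD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Decomposition:
    eigenbrains: np.ndarray  # components x voxels, orthonormal rows
    singular_values: np.ndarray  # nonincreasing, nonnegative
    scores: np.ndarray  # subjects x components ("eigenvalues", signed)
    pct_covariance: np.ndarray  # squared-share, sums to 100 over full rank
    k_retained: int
    sign_flips: np.ndarray  # boolean per component: True if flipped
    subject_ids: tuple[str, ...] = ()
    voxel_index: np.ndarray | None = None
    horn: "HornResult | None" = None


def svd_decompose(matrix: ImageMatrix, k_retained: int | None = None) -> Decomposition:
    """Thin SVD of the scaled matrix with the fixed sign convention."""
    X = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # flip each eigenbrain so its maximum-|loading| voxel is positive
    peak = np.argmax(np.abs(Vt), axis=1)
    flips = Vt[np.arange(Vt.shape[0]), peak] < 0
    Vt = np.where(flips[:, None], -Vt, Vt)
    scores = U * s  # columns flip with the eigenbrains
    scores = np.where(flips[None, :], -scores, scores)
    k = int(k_retained) if k_retained is not None else len(s)
    return Decomposition(
        eigenbrains=Vt,
        singular_values=s,
        scores=scores,
        pct_covariance=pct_covariance(s),
        k_retained=k,
        sign_flips=flips,
        subject_ids=matrix.subject_ids,
        voxel_index=matrix.voxel_index,
    )


def pct_covariance(singular_values) -> np.ndarray:
    """Covariance share per component: 100 * s_k^2 / sum s^2 (default)."""
    s = np.asarray(
        singular_values.singular_values
        if isinstance(singular_values, Decomposition)
        else singular_values,
        dtype=float,
    )
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("all-zero singular spectrum")
    return 100.0 * s**2 / total


def pct_covariance_abs(singular_values) -> np.ndarray:
    """Alternative reading: absolute-value share 100 * s_k / sum s."""
    s = np.asarray(
        singular_values.singular_values
        if isinstance(singular_values, Decomposition)
        else singular_values,
        dtype=float,
    )
    total = float(np.sum(s))
    if total <= 0:
        raise ValueError("all-zero singular spectrum")
    return 100.0 * s / total


# ---------------------------------------------------------------------------
# Horn's parallel analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HornResult:
    k_retained: int
    observed_spectrum: np.ndarray  # squared singular values
    null_percentile_spectrum: np.ndarray
    n_null: int
    percentile: float
    seed: int


def _squared_spectrum(X: np.ndarray) -> np.ndarray:
    """Squared singular values via the smaller Gram matrix."""
    n, p = X.shape
    G = X @ X.T if n <= p else X.T @ X
    w = np.linalg.eigvalsh(G)[::-1]
    return np.clip(w, 0.0, None)


def horn_parallel(
    matrix: ImageMatrix | np.ndarray,
    n_null: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> HornResult:
    """Component retention by parallel analysis with within-row permutation.

    Each null replicate independently permutes the entries of every row,
    preserving each subject's intensity distribution while destroying
    spatial covariance.  Retention stops at the first component whose
    observed squared singular value does not exceed the stated percentile
    of its null distribution (contiguous-prefix rule).
    """
    X = matrix.values if isinstance(matrix, ImageMatrix) else np.asarray(matrix, dtype=float)
    if n_null < 20:
        raise ValueError("n_null must be >= 20")
    if not (50.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (50, 100)")
    observed = _squared_spectrum(X)
    rng = np.random.default_rng(seed)
    null = np.empty((n_null, len(observed)))
    for b in range(n_null):
        null[b] = _squared_spectrum(rng.permuted(X, axis=1))
    thresh = np.percentile(null, percentile, axis=0)
    above = observed > thresh
    k = int(np.argmin(above)) if not above.all() else len(observed)
    return HornResult(
        k_retained=k,
        observed_spectrum=observed,
        null_percentile_spectrum=thresh,
        n_null=int(n_null),
        percentile=float(percentile),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Projection of (new) subjects
# ---------------------------------------------------------------------------

def project(image: SubjectImage, decomposition: Decomposition, grid: TemplateGrid) -> np.ndarray:
    """Per-component scores of one image: robust-scale, then inner products
    with the eigenbrains.  A training image reproduces its stored score row."""
    if not image.normalized:
        raise ValueError(f"subject {image.subject_id}: image is not reference-normalized")
    vec = robust_scale(flatten(image, grid), subject_id=image.subject_id)
    return decomposition.eigenbrains @ vec


# ---------------------------------------------------------------------------
# Alignment against planted truth (test harness)
# ---------------------------------------------------------------------------

def align_components(estimated: np.ndarray | Decomposition, truth: np.ndarray):
    """Match estimated components to reference patterns by |Pearson r|.

    Greedy one-to-one assignment without reuse (implemented exactly via the
    Hungarian algorithm on -|r|).  Returns a list of
    ``(est_index, truth_index, signed_r, flip_needed)`` tuples.
    """
    est = estimated.eigenbrains if isinstance(estimated, Decomposition) else np.asarray(estimated)
    tru = np.asarray(truth, dtype=float)
    if tru.size == 0:
        raise ValueError("empty truth")
    est = np.atleast_2d(est)
    tru = np.atleast_2d(tru)
    ez = (est - est.mean(axis=1, keepdims=True))
    tz = (tru - tru.mean(axis=1, keepdims=True))
    ez /= np.linalg.norm(ez, axis=1, keepdims=True)
    tz /= np.linalg.norm(tz, axis=1, keepdims=True)
    r = ez @ tz.T  # est x truth signed correlations
    rows, cols = linear_sum_assignment(-np.abs(r))
    return [
        (int(i), int(j), float(r[i, j]), bool(r[i, j] < 0)) for i, j in zip(rows, cols)
    ]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_decomposition(dec: Decomposition, grid: TemplateGrid, out_dir) -> None:
    """Write eigenbrain maps (one NIfTI per retained component plus a 4-D
    stack), scores + covariance shares as CSV, and the Horn result as JSON."""
    import json
    from pathlib import Path

    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = dec.k_retained if dec.k_retained > 0 else dec.eigenbrains.shape[0]
    vols = [grid.unflatten(dec.eigenbrains[i]) for i in range(k)]
    for i, vol in enumerate(vols, start=1):
        nib.save(grid.to_nifti(vol), str(out / f"eigenbrain_{i:02d}.nii.gz"))
    stack = np.stack(vols, axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, grid.affine), str(out / "eigenbrains_4d.nii.gz"))
    scores = pd.DataFrame(dec.scores[:, :k],
                          columns=[f"EB{i + 1}" for i in range(k)])
    scores.insert(0, "subject_id", list(dec.subject_ids))
    scores.to_csv(out / "scores.csv", index=False)
    pd.DataFrame({
        "component": [f"EB{i + 1}" for i in range(len(dec.pct_covariance))],
        "pct_covariance": dec.pct_covariance,
    }).to_csv(out / "pct_covariance.csv", index=False)
    if dec.horn is not None:
        h = dec.horn
        (out / "horn.json").write_text(json.dumps({
            "k_retained": h.k_retained,
            "observed_spectrum": list(map(float, h.observed_spectrum)),
            "null_percentile_spectrum": list(map(float, h.null_percentile_spectrum)),
            "n_null": h.n_null,
            "percentile": h.percentile,
            "seed": h.seed,
        }))


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class EigenbrainDecomposition(BaseEstimator, TransformerMixin):
    """SVD eigenbrain transformer over robust-scaled subject images.

    Parameters
    ----------
    retain : {"horn", "all"} or int, default "horn"
        How many components count as signal.  "horn" runs parallel
        analysis at fit time; an integer fixes the count; "all" keeps the
        full thin rank.
    n_null, percentile, random_state
        Parallel-analysis settings (ignored unless ``retain == "horn"``).
    row_scale : bool, default True
        Median-centre and IQR-scale each row of the input.  Set False if
        the matrix is already scaled (e.g. an :class:`ImageMatrix`).
    column_center : bool, default False
        Additionally remove the voxel-wise mean before the SVD.  Off by
        default: only per-image centring/scaling is part of the model.

    Attributes
    ----------
    components_ : (rank, n_voxels) orthonormal eigenbrain maps.
    singular_values_, scores_, pct_covariance_ : full-rank spectra/scores.
    n_components_ : retained component count K.
    horn_ : :class:`HornResult` when ``retain == "horn"``.
    """

    def __init__(
        self,
        retain="horn",
        n_null: int = 100,
        percentile: float = 95.0,
        random_state: int = 0,
        row_scale: bool = True,
        column_center: bool = False,
    ):
        self.retain = retain
        self.n_null = n_null
        self.percentile = percentile
        self.random_state = random_state
        self.row_scale = row_scale
        self.column_center = column_center

    def _prepare(self, X: np.ndarray, ids=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a subjects x voxels matrix")
        if self.row_scale:
            X, _, _ = _robust_scale_rows(X, ids if ids is not None else range(X.shape[0]))
        if self.column_center:
            X = X - getattr(self, "column_mean_", X.mean(axis=0))
        return X

    def fit(self, X, y=None, subject_ids=None):
        if isinstance(X, ImageMatrix):
            subject_ids = X.subject_ids
            X = X.values
            scaler_off = True
        else:
            scaler_off = False
        Xs = np.asarray(X, dtype=float)
        if self.row_scale and not scaler_off:
            Xs, _, _ = _robust_scale_rows(Xs, subject_ids if subject_ids is not None else range(len(Xs)))
        if self.column_center:
            self.column_mean_ = Xs.mean(axis=0)
            Xs = Xs - self.column_mean_
        mat = ImageMatrix(
            values=Xs,
            subject_ids=tuple(subject_ids) if subject_ids is not None else tuple(map(str, range(len(Xs)))),
            voxel_index=np.arange(Xs.shape[1]),
            scaling_median=np.zeros(len(Xs)),
            scaling_iqr=np.ones(len(Xs)),
        )
        if self.retain == "horn":
            horn = horn_parallel(mat, n_null=self.n_null, percentile=self.percentile,
                                 seed=self.random_state)
            k = horn.k_retained
        elif self.retain == "all":
            horn, k = None, min(Xs.shape)
        else:
            horn, k = None, int(self.retain)
        dec = svd_decompose(mat, k_retained=k)
        self.decomposition_ = Decomposition(
            eigenbrains=dec.eigenbrains,
            singular_values=dec.singular_values,
            scores=dec.scores,
            pct_covariance=dec.pct_covariance,
            k_retained=k,
            sign_flips=dec.sign_flips,
            subject_ids=dec.subject_ids,
            voxel_index=dec.voxel_index,
            horn=horn,
        )
        self.components_ = dec.eigenbrains
        self.singular_values_ = dec.singular_values
        self.scores_ = dec.scores
        self.pct_covariance_ = dec.pct_covariance
        self.n_components_ = k
        self.horn_ = horn
        self.n_features_in_ = Xs.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Project subjects onto the retained eigenbrains (scores)."""
        check_is_fitted(self, "components_")
        if isinstance(X, ImageMatrix):
            Xs = X.values
        else:
            Xs = self._prepare(X)
        k = self.n_components_ if self.n_components_ > 0 else self.components_.shape[0]
        return Xs @ self.components_[:k].T

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y, **fit_params)
        k = self.n_components_ if self.n_components_ > 0 else self.components_.shape[0]
        return self.scores_[:, :k]
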