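"""Voxel-wise Z-score group-contrast maps and matched-control selection.

Group differences in metabolism are summarized descriptively: each group's
mean image is scaled voxel-wise by its own standard deviation and the two
scaled means are subtracted (``ratio`` mode, the default), or the mean
difference is scaled by the comparison group's SD (``standardized_difference``).
No inference is attached to these maps.

Controls are matched to a patient group on sample size, age and sex:
within each sex stratum a greedy nearest-age pass assigns one control per
patient without replacement, ties broken by the smaller subject id, so the
selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import TemplateGrid
from .images import SubjectImage

__all__ = ["ZMap", "match_controls", "zscore_map", "summarize_zmap"]

_MODES = ("ratio", "standardized_difference")


@dataclass(frozen=True)
class ZMap:
    values: np.ndarray  # 3-D volume, zero outside the brain mask
    group_a: str
    group_b: str
    mode: str
    n_a: int
    n_b: int
    excluded_voxels: int


def match_controls(patients: pd.DataFrame, controls: pd.DataFrame, seed: int = 0) -> list[str]:
    """Select one control per patient, stratified by sex, nearest in age.

    Both tables need ``subject_id``, ``sex`` and ``age_scan`` columns.
    Deterministic: patients are processed in subject-id order within each
    stratum and age ties are broken by the smaller control id (``seed`` is
    accepted for interface stability but the procedure is deterministic).
    """
    selected: list[str] = []
    for sex, pat in patients.groupby("sex"):
        pool = controls[controls["sex"] == sex]
        if len(pool) < len(pat):
            raise ValueError(
                f"insufficient controls for sex {sex!r}: need {len(pat)}, have {len(pool)}"
            )
        avail = pool.sort_values("subject_id").reset_index(drop=True)
        taken = np.zeros(len(avail), dtype=bool)
        for _, row in pat.sort_values("subject_id").iterrows():
            dist = np.abs(avail["age_scan"].to_numpy(dtype=float) - float(row["age_scan"]))
            dist[taken] = np.inf
            best = int(np.argmin(dist))  # argmin keeps the first (lowest id) on ties
            taken[best] = True
            selected.append(str(avail.loc[best, "subject_id"]))
    return selected


def _stack(images, grid: TemplateGrid) -> np.ndarray:
    vols = []
    for im in images:
        im.validate(grid)
        vols.append(np.asarray(im.values, dtype=float))
    return np.stack(vols)


def zscore_map(
    images_a,
    images_b,
    grid: TemplateGrid,
    mode: str = "ratio",
    group_a: str = "A",
    group_b: str = "B",
) -> ZMap:
    """Voxel-wise Z contrast between two groups of images.

    ratio (default):              Z(v) = m_a/s_a - m_b/s_b
    standardized_difference:      Z(v) = (m_a - m_b) / s_b

    SDs use the n-1 denominator.  Voxels where either group SD is < 1e-8
    are set to 0 and counted in ``excluded_voxels`` rather than erroring
    (masks often contain constant pad voxels in synthetic data).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    A = _stack(images_a, grid)
    B = _stack(images_b, grid)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs >= 2 images")
    m_a, s_a = A.mean(axis=0), A.std(axis=0, ddof=1)
    m_b, s_b = B.mean(axis=0), B.std(axis=0, ddof=1)
    bad = (s_a < 1e-8) | (s_b < 1e-8)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "ratio":
            z = m_a / s_a - m_b / s_b
        else:
            z = (m_a - m_b) / s_b
    z = np.where(bad, 0.0, z)
    z = np.where(grid.brain_mask, z, 0.0)
    excluded = int(np.sum(bad & grid.brain_mask))
    return ZMap(values=z, group_a=group_a, group_b=group_b, mode=mode,
                n_a=len(A), n_b=len(B), excluded_voxels=excluded)


def summarize_zmap(zmap: ZMap, grid: TemplateGrid, threshold: float = 0.3) -> dict:
    """Extremes and suprathreshold voxel counts of a Z-map over the mask."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = zmap.values[grid.brain_mask]
    return {
        "max_abs_z": float(np.max(np.abs(vals))),
        "max_z": float(np.max(vals)),
        "min_z": float(np.min(vals)),
        "n_above": int(np.sum(vals > threshold)),
        "n_below": int(np.sum(vals < -threshold)),
        "threshold": float(threshold),
        "excluded_voxels": zmap.excluded_voxels,
    }
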