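"""Meta-analytic spatial decoding of eigenbrains against topic maps.

Each eigenbrain is correlated voxel-wise (over the brain mask) with a set
of labelled topic maps — e.g. meta-analytic association maps for mental
functions — and the topics are ranked by signed correlation.  The analysis
is descriptive by design: direction and relative strength guide the
interpretation, and no p-values are produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import TemplateGrid

__all__ = ["TopicMap", "DecodingResult", "decode"]


@dataclass(frozen=True)
class TopicMap:
    label: str
    values: np.ndarray  # 3-D volume on the TemplateGrid


@dataclass(frozen=True)
class DecodingResult:
    eigenbrain_index: int
    table: pd.DataFrame  # topic, r; sorted by signed r, descending


def decode(
    eigenbrain_map: np.ndarray,
    topics,
    grid: TemplateGrid,
    eigenbrain_index: int = 0,
    method: str = "pearson",
) -> DecodingResult:
    """Rank topic maps by spatial correlation with one eigenbrain.

    ``eigenbrain_map`` may be a 3-D volume or an already-masked vector.
    Correlations are computed over brain-mask voxels only; ``method`` is
    "pearson" (default) or "spearman".
    """
    topics = list(topics)
    if not topics:
        raise ValueError("need at least one topic map")
    labels = [t.label for t in topics]
    if len(set(labels)) != len(labels):
        raise ValueError("topic labels must be unique")
    eb = np.asarray(eigenbrain_map, dtype=float)
    ev = grid.flatten(eb) if eb.ndim == 3 else eb
    if ev.shape != (grid.n_voxels,):
        raise ValueError("eigenbrain map does not match the grid mask")
    if np.std(ev) == 0:
        raise ValueError("zero-variance eigenbrain over the mask")
    rows = []
    for t in topics:
        tv = np.asarray(t.values, dtype=float)
        tv = grid.flatten(tv) if tv.ndim == 3 else tv
        if np.std(tv) == 0:
            raise ValueError(f"zero-variance topic map {t.label!r} over the mask")
        if method == "pearson":
            r = float(stats.pearsonr(ev, tv).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(ev, tv).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        rows.append({"topic": t.label, "r": r})
    table = pd.DataFrame(rows).sort_values("r", ascending=False, kind="stable")
    table = table.reset_index(drop=True)
    return DecodingResult(eigenbrain_index=eigenbrain_index, table=table)
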