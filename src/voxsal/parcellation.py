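"""Regional scoring: from voxelwise saliency to per-area and per-lobe profiles.

An area's regional saliency is the probability-weighted average of the
saliency volume over that area's membership field:

    score_a = sum_v p_a(v) * M(v) / sum_v p_a(v)

The denominator is the area's total probability mass, the unique convention
under which a constant map scores that constant for every area.  Areas are
scored independently, so overlapping probabilistic support is handled
naturally.  Grid mismatch between map and atlas is an error — inputs are
assumed co-registered to one space.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import GridMismatchError, ProbabilisticAtlas, SaliencyMap, SubjectRecord


def regional_scores(smap: SaliencyMap, atlas: ProbabilisticAtlas) -> np.ndarray:
    """Per-area probability-weighted mean saliency for one subject."""
    if tuple(smap.values.shape) != tuple(atlas.grid_shape):
        raise GridMismatchError(
            f"saliency grid {smap.values.shape} != atlas grid {atlas.grid_shape}"
        )
    flat_p = atlas.probs.reshape(atlas.n_areas, -1).astype(np.float64)
    mass = flat_p.sum(axis=1)
    scores = flat_p @ smap.values.reshape(-1).astype(np.float64)
    out = np.full(atlas.n_areas, np.nan)
    ok = mass > 0
    out[ok] = scores[ok] / mass[ok]
    if not ok.all():
        bad = [atlas.labels[i].name for i in np.where(~ok)[0]]
        warnings.warn(f"areas with zero probability mass scored NaN: {bad}", RuntimeWarning)
    return out


def regional_matrix(
    maps: Sequence[SaliencyMap], atlas: ProbabilisticAtlas
) -> pd.DataFrame:
    """Subjects x areas regional saliency matrix (rows indexed by subject id)."""
    rows = {m.subject_id: regional_scores(m, atlas) for m in maps}
    return pd.DataFrame.from_dict(rows, orient="index", columns=atlas.area_names)


def _mean_halfwidth(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    hw = float(1.96 * np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, hw


def class_profiles(
    matrix: pd.DataFrame, subjects: Sequence[SubjectRecord]
) -> pd.DataFrame:
    """Per-class per-area mean saliency with 95% half-widths.

    Rows are a MultiIndex (class, area); callers restrict the matrix to
    correctly classified subjects beforehand (see
    ``stats.exclude_misclassified``).
    """
    by_id = {s.id: s for s in subjects}
    classes = sorted({by_id[i].true_class for i in matrix.index if i in by_id})
    if not classes:
        raise ValueError("no subjects from the matrix found in the subject list")
    records = []
    for cls in classes:
        ids = [i for i in matrix.index if i in by_id and by_id[i].true_class == cls]
        if len(ids) < 2:
            raise ValueError(f"need >= 2 subjects for class {cls}, got {len(ids)}")
        sub = matrix.loc[ids]
        for area in matrix.columns:
            mean, hw = _mean_halfwidth(sub[area].to_numpy())
            records.append((cls, area, mean, hw, len(ids)))
    return pd.DataFrame(
        records, columns=["class", "area", "mean", "halfwidth", "n"]
    ).set_index(["class", "area"])


def lobe_aggregate(
    matrix: pd.DataFrame,
    atlas: ProbabilisticAtlas,
    subjects: Sequence[SubjectRecord],
) -> pd.DataFrame:
    """Coarser lobe-level profiles: per-subject unweighted mean over member
    areas, then class mean with 95% half-width per (lobe, hemisphere, class).
    """
    name_to_label = {lab.name: lab for lab in atlas.labels}
    unmapped = [c for c in matrix.columns if c not in name_to_label]
    if unmapped:
        raise ValueError(f"areas missing lobe/hemisphere annotation: {unmapped}")
    by_id = {s.id: s for s in subjects}
    groups: dict[tuple[str, str], list[str]] = {}
    for c in matrix.columns:
        lab = name_to_label[c]
        groups.setdefault((lab.lobe, lab.hemisphere), []).append(c)

    records = []
    for (lobe, hemi), areas in sorted(groups.items()):
        per_subject = matrix[areas].mean(axis=1)
        for cls in sorted({by_id[i].true_class for i in matrix.index if i in by_id}):
            ids = [i for i in matrix.index if i in by_id and by_id[i].true_class == cls]
            vals = per_subject.loc[ids].to_numpy()
            mean, hw = _mean_halfwidth(vals)
            records.append((lobe, hemi, cls, mean, hw, len(ids)))
    return pd.DataFrame(
        records, columns=["lobe", "hemisphere", "class", "mean", "halfwidth", "n"]
    ).set_index(["lobe", "hemisphere", "class"])
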