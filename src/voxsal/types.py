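"""Core in-memory containers shared across the pipeline.

The unit of image data is a :class:`VolumeGrid` — a 3D scalar field with an
affine, mirroring how a single-channel NIfTI volume is held in memory.  The
parcellation is a :class:`ProbabilisticAtlas`: a stack of per-area probability
fields on one grid plus a label table (name, hemisphere, lobe, functional
networks).  Subjects are plain records carrying class, clinical metrics and
bookkeeping (fold, prediction).  Saliency maps carry provenance so downstream
stages can assert the hold-out routing contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

PD = "PD"
CT = "CT"
CLASSES = (CT, PD)  # index 0 = CT, index 1 = PD; PD is the positive class


class GridMismatchError(ValueError):
    """Two volumetric objects do not share a voxel grid."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with an affine mapping voxel to world coordinates."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid requires 3D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class AreaLabel:
    """One atlas area: contiguous integer index plus anatomical annotations."""

    index: int
    name: str
    hemisphere: str  # "L", "R" or "midline"
    lobe: str
    networks: frozenset[str]


@dataclass
class ProbabilisticAtlas:
    """Per-area membership probability fields on a shared grid.

    ``probs`` is shaped ``(n_areas, *grid_shape)``.  Every voxel carries a
    probability per area rather than a hard label; overlapping support is
    legitimate, but the per-voxel sum across areas never exceeds 1.
    """

    probs: np.ndarray
    labels: list[AreaLabel]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        self.validate()

    @property
    def n_areas(self) -> int:
        return self.probs.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.probs.shape[1:])  # type: ignore[return-value]

    @property
    def area_names(self) -> list[str]:
        return [lab.name for lab in self.labels]

    def validate(self) -> None:
        if self.probs.ndim != 4:
            raise ValueError("atlas probs must be (n_areas, nx, ny, nz)")
        if len(self.labels) != self.n_areas:
            raise ValueError("label count does not match probability stack")
        if self.probs.min() < 0 or self.probs.max() > 1 + 1e-6:
            raise ValueError("atlas probabilities must lie in [0, 1]")
        voxel_sum = self.probs.sum(axis=0)
        if voxel_sum.max() > 1 + 1e-9:
            raise ValueError("per-voxel probability sum exceeds 1")
        mass = self.probs.reshape(self.n_areas, -1).sum(axis=1)
        if np.any(mass <= 0):
            bad = [self.labels[i].name for i in np.where(mass <= 0)[0]]
            raise ValueError(f"areas with zero probability mass: {bad}")
        idx = [lab.index for lab in self.labels]
        if sorted(idx) != list(range(self.n_areas)):
            raise ValueError("label indices must be unique and contiguous from 0")


@dataclass
class SubjectRecord:
    """One participant: diagnosis, clinical metrics, covariates, bookkeeping.

    Clinical metrics use NaN for "missing".  Control subjects carry no motor
    score, disease duration or medication dose — all association analyses run
    over the patient cohort only.
    """

    id: str
    true_class: str
    updrs_p3: float = np.nan
    moca: float = np.nan
    ledd: float = np.nan
    years_onset: float = np.nan
    handedness: str = "missing"  # "R", "L", "ambi" or "missing"
    medicated: bool = False
    latent_severity: float = np.nan  # synthetic cohorts only
    fold: Optional[int] = None
    predicted_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.true_class == CT:
            for name in ("updrs_p3", "years_onset", "ledd"):
                if np.isfinite(getattr(self, name)):
                    raise ValueError(f"control subject {self.id} has {name} set")
        if not self.medicated and np.isfinite(self.ledd) and self.ledd > 0:
            raise ValueError(f"unmedicated subject {self.id} has positive LEDD")


@dataclass
class SaliencyMap:
    """Non-negative voxelwise class-importance volume with provenance."""

    values: np.ndarray
    subject_id: str
    fold: Optional[int] = None
    class_channel: str = PD
    normalized: bool = False
    zero_warning: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("saliency map must be 3D")
        if self.class_channel not in CLASSES:
            raise ValueError(f"unknown class channel {self.class_channel!r}")

    def copy_with(self, **kwargs) -> "SaliencyMap":
        return replace(self, **kwargs)


def subjects_to_frame(subjects: Sequence[SubjectRecord]):
    """Tabulate subject records (one row per subject) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for s in subjects:
        rows.append(
            dict(
                id=s.id,
                true_class=s.true_class,
                updrs_p3=s.updrs_p3,
                moca=s.moca,
                ledd=s.ledd,
                years_onset=s.years_onset,
                handedness=s.handedness,
                medicated=s.medicated,
                latent_severity=s.latent_severity,
                fold=s.fold if s.fold is not None else -1,
                predicted_class=s.predicted_class or "",
            )
        )
    return pd.DataFrame(rows).set_index("id")
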