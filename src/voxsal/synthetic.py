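"""Synthetic cohort generator: phantom atlases, volumes and clinical tables.

The generator emulates the statistical structure the downstream analysis
assumes about a two-class structural-MRI study:

* a probabilistic parcellation (Gaussian-blob probability fields with
  hemisphere/lobe/functional-network annotations),
* patient volumes whose intensity is reduced inside designated "effect"
  areas, with the reduction scaled by a positive, right-skewed latent
  severity plus a shared per-network factor (so same-network areas co-vary
  across subjects),
* heterogeneous scan quality: per-subject random blur and additive noise,
* clinical scores linearly coupled to the latent severity — a motor score
  increasing with severity and a cognitive score (ceiling 30) decreasing
  with it — with configurable missingness and a medicated subgroup carrying
  a dose measure.

Phantoms, not anatomy: there is no template brain, no registration, no
scanner-vendor structure beyond blur/noise.  Every output is a pure function
of (spec, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import CT, PD, AreaLabel, ProbabilisticAtlas, SubjectRecord, VolumeGrid

SYNTHETIC_LOBES = ("frontal", "temporal", "parietal", "occipital", "limbic", "subcortical")


class AtlasPlacementError(RuntimeError):
    """The grid is too small to place the requested number of distinct blobs."""


class CohortConfigError(ValueError):
    """Inconsistent cohort specification."""


def make_atlas(
    n_areas: int,
    grid_shape: tuple[int, int, int],
    n_networks: int = 4,
    seed: int = 0,
    blob_sigma: Optional[float] = None,
    min_center_dist: Optional[float] = None,
) -> ProbabilisticAtlas:
    """Generate a phantom probabilistic atlas of Gaussian-blob areas.

    Blob centers are rejection-sampled to be mutually distinct; each area's
    probability field is a unit-amplitude Gaussian, and voxels where the
    stacked sum exceeds 1 are renormalized so the per-voxel total stays a
    probability.  Areas are annotated round-robin with synthetic lobes and
    functional networks; hemisphere is read off the blob center's
    x-coordinate (left half => "L").
    """
    if n_areas < 2 and n_areas != 1:
        raise ValueError("n_areas must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 3:
        raise ValueError("grid_shape must be a triple of dims >= 3")
    rng = np.random.default_rng(seed)

    if blob_sigma is None:
        blob_sigma = max(1.5, min(grid_shape) / 12.0)
    if min_center_dist is None:
        min_center_dist = 1.5 * blob_sigma

    margin = min(blob_sigma, min(grid_shape) / 4.0)
    centers: list[np.ndarray] = []
    max_tries = 2000 * n_areas
    for _ in range(max_tries):
        if len(centers) == n_areas:
            break
        cand = np.array(
            [round(rng.uniform(margin, g - 1 - margin)) for g in grid_shape],
            dtype=np.float64,
        )  # voxel-aligned centers: a blob peaks at exactly 1 on its center voxel
        if all(np.linalg.norm(cand - c) >= min_center_dist for c in centers):
            centers.append(cand)
    if len(centers) < n_areas:
        raise AtlasPlacementError(
            f"could not place {n_areas} blob centers at least {min_center_dist:.2f} "
            f"voxels apart on grid {grid_shape}"
        )

    ax = [np.arange(g, dtype=np.float64) for g in grid_shape]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    probs = np.empty((n_areas,) + grid_shape, dtype=np.float64)
    for i, c in enumerate(centers):
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        probs[i] = np.exp(-d2 / (2.0 * blob_sigma**2))

    probs = probs.astype(np.float32)
    voxel_sum = probs.sum(axis=0, dtype=np.float64)
    over = voxel_sum > 1.0
    if np.any(over):
        # renormalize with a sliver of headroom so float32 rounding cannot
        # push the per-voxel sum back above 1
        probs[:, over] = (probs[:, over] / (voxel_sum[over] * (1.0 + 1e-6))).astype(
            np.float32
        )

    mid_x = (grid_shape[0] - 1) / 2.0
    lobes = itertools.cycle(SYNTHETIC_LOBES)
    labels = []
    for i, (c, lobe) in enumerate(zip(centers, lobes)):
        hemi = "L" if c[0] < mid_x else "R"
        labels.append(
            AreaLabel(
                index=i,
                name=f"area{i:03d}_{lobe[:4]}_{hemi}",
                hemisphere=hemi,
                lobe=lobe,
                networks=frozenset({f"net{i % n_networks}"}),
            )
        )
    return ProbabilisticAtlas(probs=probs, labels=labels)


@dataclass
class CohortSpec:
    """Generative settings for one synthetic two-class cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 30 subjects per class on a 32-cubed grid, a 40-intensity-unit
    planted effect per unit severity, log-normal severity with median 1,
    per-network latent factors, and blur/noise heterogeneity spanning the
    plausible range of a mixed-scanner T1w dataset rescaled to [0, 255].
    """

    n_per_class: int = 30
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    effect_areas: tuple[int, ...] = ()
    effect_size: float = 50.0  # intensity units per unit severity, per area
    severity_sigma: float = 0.4  # log-normal scale; median fixed at 1
    network_factor_sd: float = 0.3
    area_noise_sd: float = 0.3  # per subject/area expression heterogeneity
    texture_sd: float = 8.0  # subject-specific anatomical texture, intensity units
    texture_sigma: float = 2.5  # correlation length of the texture, voxels
    template_amp: float = 10.0  # sd of the shared template's spatial structure
    blur_sd_range: tuple[float, float] = (0.5, 1.5)
    noise_amp_range: tuple[float, float] = (1.0, 5.0)
    alpha_updrs: float = 15.0  # motor-score points per unit severity
    alpha_moca: float = 4.0  # cognitive-score points lost per unit severity
    moca_ceiling: float = 28.0
    updrs_noise_sd: float = 4.0
    moca_noise_sd: float = 1.5
    years_scale: float = 2.3  # years since onset per unit severity
    years_noise_sd: float = 0.8
    med_fraction: float = 0.36
    missing_updrs: float = 0.1
    missing_moca: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise CohortConfigError("n_per_class must be >= 1")
        if self.effect_size < 0:
            raise CohortConfigError("effect_size must be >= 0")
        for name in ("blur_sd_range", "noise_amp_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise CohortConfigError(f"{name} must be ordered and non-negative")
        if not 0 <= self.med_fraction <= 1:
            raise CohortConfigError("med_fraction must be in [0, 1]")
        if self.effect_size > 0 and len(self.effect_areas) == 0:
            raise CohortConfigError("effect_size > 0 requires non-empty effect_areas")


def recovery_spec(atlas: ProbabilisticAtlas, seed: int = 0, **overrides) -> CohortSpec:
    """Default planted-effect spec: effect areas = members of network 'net0'."""
    effect = tuple(
        lab.index for lab in atlas.labels if "net0" in lab.networks
    )
    kwargs = dict(grid_shape=atlas.grid_shape, effect_areas=effect, seed=seed)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _network_of(label: AreaLabel) -> str:
    # areas belong to one primary network in synthetic atlases
    return sorted(label.networks)[0]


def make_cohort(
    spec: CohortSpec,
    atlas: ProbabilisticAtlas,
    return_effects: bool = False,
):
    """Simulate subjects and volumes with the planted regional effect.

    Returns ``(subjects, volumes)`` — or ``(subjects, volumes, effects)`` with
    ``effects`` the (n_subjects, n_areas) matrix of per-subject effect
    magnitudes actually applied (zero for controls and non-effect areas) —
    useful for verifying the generator's own network-correlation structure.
    """
    if tuple(atlas.grid_shape) != tuple(spec.grid_shape):
        raise CohortConfigError("spec grid_shape does not match atlas grid")
    bad = set(spec.effect_areas) - set(range(atlas.n_areas))
    if bad:
        raise CohortConfigError(f"effect_areas not in atlas: {sorted(bad)}")

    rng = np.random.default_rng(spec.seed)
    grid = spec.grid_shape

    # Common template: a smooth random field, one draw per cohort, mapped to a
    # mid-gray band so planted reductions stay inside [0, 255] after noise.
    raw = gaussian_filter(rng.standard_normal(grid), sigma=min(grid) / 8.0)
    raw = (raw - raw.mean()) / (raw.std() + 1e-12)
    template = 140.0 + spec.template_amp * raw

    networks = sorted({_network_of(lab) for lab in atlas.labels})
    net_index = {n: i for i, n in enumerate(networks)}
    area_net = np.array([net_index[_network_of(lab)] for lab in atlas.labels])

    flat_probs = atlas.probs.reshape(atlas.n_areas, -1).astype(np.float64)

    subjects: list[SubjectRecord] = []
    volumes: list[VolumeGrid] = []
    effects = np.zeros((2 * spec.n_per_class, atlas.n_areas))

    order = [(PD, i) for i in range(spec.n_per_class)] + [
        (CT, i) for i in range(spec.n_per_class)
    ]
    for row, (cls, i) in enumerate(order):
        sid = f"{cls}{i:03d}"
        s_i = float(rng.lognormal(mean=0.0, sigma=spec.severity_sigma))
        f_net = rng.normal(0.0, spec.network_factor_sd, size=len(networks))

        # smoothing shrinks the field's variance, so rescale to the target sd:
        # subjects must differ by anatomy-scale structure, not hairline noise
        texture = gaussian_filter(rng.standard_normal(grid), sigma=spec.texture_sigma)
        texture *= spec.texture_sd / max(texture.std(), 1e-12)
        vol = template + texture

        if cls == PD and spec.effect_size > 0:
            eps = rng.normal(0.0, spec.area_noise_sd, size=len(spec.effect_areas))
            deficit = np.zeros(grid[0] * grid[1] * grid[2])
            for j, a in enumerate(spec.effect_areas):
                mag = spec.effect_size * (s_i + f_net[area_net[a]] + eps[j])
                effects[row, a] = mag
                deficit += mag * flat_probs[a]
            vol = vol - deficit.reshape(grid)

        blur_sd = rng.uniform(*spec.blur_sd_range)
        if blur_sd > 0:
            vol = gaussian_filter(vol, sigma=blur_sd)
        amp = rng.uniform(*spec.noise_amp_range)
        vol = vol + rng.uniform(0.0, max(amp, 1e-12), size=grid)
        vol = np.clip(vol, 0.0, 255.0)

        if cls == PD:
            updrs = max(0.0, spec.alpha_updrs * s_i + rng.normal(0, spec.updrs_noise_sd))
            moca = float(
                np.clip(
                    spec.moca_ceiling
                    - spec.alpha_moca * s_i
                    - rng.normal(0, spec.moca_noise_sd),
                    0.0,
                    30.0,
                )
            )
            years = max(0.1, spec.years_scale * s_i + rng.normal(0, spec.years_noise_sd))
            medicated = bool(rng.uniform() < spec.med_fraction)
            ledd = (
                max(50.0, 300.0 * s_i + rng.normal(0, 100.0)) if medicated else np.nan
            )
            if rng.uniform() < spec.missing_updrs:
                updrs = np.nan
            if rng.uniform() < spec.missing_moca:
                moca = np.nan
            handed = rng.choice(["R", "L"], p=[0.97, 0.03])
            rec = SubjectRecord(
                id=sid,
                true_class=PD,
                updrs_p3=updrs,
                moca=moca,
                ledd=ledd,
                years_onset=years,
                handedness=str(handed),
                medicated=medicated,
                latent_severity=s_i,
            )
        else:
            handed = rng.choice(["R", "L", "ambi", "missing"], p=[0.85, 0.10, 0.04, 0.01])
            rec = SubjectRecord(
                id=sid,
                true_class=CT,
                handedness=str(handed),
                latent_severity=s_i,
            )
        subjects.append(rec)
        volumes.append(VolumeGrid(data=vol, affine=atlas.affine.copy()))

    if return_effects:
        return subjects, volumes, effects
    return subjects, volumes
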