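"""Gradient-weighted class activation mapping (GradCAM) for the 3D classifier.

For a chosen class channel h, the channel weights are the spatial mean of
the gradient of the pre-softmax class score y^h with respect to the
designated feature maps A^c:

    W_c^h = (1/N) * sum_{x,y,z} dy^h / dA^c_{x,y,z}

and the saliency volume is the half-rectified weighted sum of the feature
maps, trilinearly upsampled to the input grid:

    M = ReLU( sum_c W_c^h * A^c )

The gradient target is the class *score*, not the loss: a map computed on
the predicted class then mirrors that prediction whether or not it is
correct, which is the behavior the hold-out routing relies on.  A
``grad_target="loss"`` option backpropagates the cross-entropy instead.

The designated layer is the output of the final residual stage — the
deepest layer with spatial extent, taken before dropout and pooling — and
maps are computed in deterministic eval mode.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .model import ResidualClassifier3D
from .training import FoldAssignment, predict
from .types import CLASSES, SaliencyMap, SubjectRecord, VolumeGrid


def _upsample_trilinear(vol: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Corner-aligned trilinear interpolation onto ``out_shape``."""
    if vol.shape == tuple(out_shape):
        return vol.astype(np.float32)
    coords = np.meshgrid(
        *[
            np.linspace(0.0, s - 1.0, o) if o > 1 else np.zeros(1)
            for s, o in zip(vol.shape, out_shape)
        ],
        indexing="ij",
    )
    return map_coordinates(
        vol.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    ).astype(np.float32)


def gradcam_weights(
    model: ResidualClassifier3D,
    volume: np.ndarray,
    class_channel: str,
    grad_target: str = "score",
) -> tuple[np.ndarray, np.ndarray]:
    """Channel weights W_c^h and feature maps A for one input volume.

    ``volume`` is the preprocessed model input (already rescaled); a
    leading batch/channel axis is added here.
    """
    if class_channel not in CLASSES:
        raise ValueError(f"unknown class channel {class_channel!r}")
    h = CLASSES.index(class_channel)
    x = np.asarray(volume, dtype=np.float32)[None, None]
    logits, feats = model.forward_features(x, train=False)
    if grad_target == "score":
        glogits = np.zeros_like(logits)
        glogits[0, h] = 1.0
    elif grad_target == "loss":
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        glogits = probs.copy()
        glogits[0, h] -= 1.0
    else:
        raise ValueError(f"grad_target must be 'score' or 'loss', got {grad_target!r}")
    dfeats = model.backward_to_features(glogits.astype(np.float32))
    if not np.all(np.isfinite(dfeats)):
        raise FloatingPointError("non-finite gradients at the designated layer")
    weights = dfeats[0].mean(axis=(1, 2, 3))  # (1/N) * spatial sum
    return weights.astype(np.float64), feats[0].astype(np.float64)


def gradcam(
    model: ResidualClassifier3D,
    volume,
    class_channel: str,
    subject_id: str = "",
    fold: Optional[int] = None,
    rescale_input: bool = True,
    grad_target: str = "score",
    upsample: bool = True,
) -> SaliencyMap:
    """Compute the saliency volume for one subject and one class channel."""
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    x = data / 255.0 if rescale_input else data
    weights, feats = gradcam_weights(model, x, class_channel, grad_target=grad_target)
    cam = np.tensordot(weights, feats, axes=(0, 0))
    cam = np.maximum(cam, 0.0)  # ReLU applied to the weighted sum
    if upsample:
        cam = _upsample_trilinear(cam, data.shape)
    return SaliencyMap(
        values=cam,
        subject_id=subject_id,
        fold=fold,
        class_channel=class_channel,
    )


def normalize_map(smap: SaliencyMap, brain_mask: Optional[np.ndarray] = None) -> SaliencyMap:
    """Divide by the mean over the brain mask so the masked mean is 1.

    Regional group means are only comparable across subjects under a shared
    per-map scale; an all-zero map is returned unchanged with a warning flag.
    """
    mask = (
        np.ones(smap.values.shape, dtype=bool)
        if brain_mask is None
        else np.asarray(brain_mask, dtype=bool)
    )
    if mask.shape != smap.values.shape:
        raise ValueError("brain mask shape does not match saliency map")
    mean = float(smap.values[mask].mean()) if mask.any() else 0.0
    if mean <= 0.0:
        import warnings

        warnings.warn(
            f"saliency map for {smap.subject_id!r} is zero over the mask; "
            "returned unnormalized",
            RuntimeWarning,
            stacklevel=2,
        )
        return smap.copy_with(zero_warning=True)
    return smap.copy_with(values=smap.values / mean, normalized=True)


def holdout_maps(
    models: dict[int, ResidualClassifier3D],
    folds: FoldAssignment,
    subjects: Sequence[SubjectRecord],
    volumes: Sequence,
    normalize: bool = True,
    brain_mask: Optional[np.ndarray] = None,
    rescale_input: bool = True,
) -> list[SaliencyMap]:
    """One map per subject from the model where the subject was held out.

    Each subject's map is computed on the class channel that model
    *predicts* for them (mirroring misclassifications), and the prediction
    is recorded on the subject record.
    """
    maps: list[SaliencyMap] = []
    for s, vol in zip(subjects, volumes):
        fold = folds.membership.get(s.id, s.fold)
        if fold is None or fold not in models:
            raise KeyError(f"no trained model for subject {s.id} (fold {fold})")
        model = models[fold]
        pred, _ = predict(model, [vol], rescale_input=rescale_input)
        s.predicted_class = pred[0]
        s.fold = fold
        smap = gradcam(
            model,
            vol,
            class_channel=pred[0],
            subject_id=s.id,
            fold=fold,
            rescale_input=rescale_input,
        )
        if normalize:
            smap = normalize_map(smap, brain_mask)
        maps.append(smap)
    return maps
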