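"""Grad-CAM evidence volumes and a quantitative localization check.

Grad-CAM weighs each channel of a chosen convolutional stage by the
spatial average of the class-score gradient with respect to that
stage's activations, forms the ReLU of the weighted activation sum,
and trilinearly upsamples the result to the input grid.  On phantoms,
where lesion masks are known, the localization score (mean CAM weight
inside the lesion mask over mean outside) quantifies whether the
high-weighted regions coincide with the simulated lesions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .architecture import MCIDetector
from .data_io import Volume, write_volume

__all__ = ["CAMVolume", "grad_cam", "localization_score", "save_cam", "cam_panels"]


@dataclasses.dataclass
class CAMVolume:
    """Non-negative class-evidence weights on the input grid."""

    weights: np.ndarray
    layer_name: str
    target_class: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if self.weights.ndim != 3:
            raise ValueError("CAM weights must be rank 3")
        if self.weights.min() < 0:
            raise ValueError("CAM weights must be non-negative")


def grad_cam(
    model: MCIDetector,
    volume: Volume,
    target_class: int = 1,
    layer: str = "stage4",
) -> CAMVolume:
    """Gradient-weighted class activation map for one volume."""
    if layer not in model.feature_layers:
        raise ValueError(
            f"unknown layer {layer!r}; valid layers: {model.feature_layers}"
        )
    if target_class not in range(model.config.n_classes):
        raise ValueError(f"target_class must be < {model.config.n_classes}")

    model.eval()
    x = ad.Tensor(volume.voxels[None, None].astype(np.float32), requires_grad=True)
    feats = model.features(x)
    act = feats[layer]
    score = feats["logits"][0, target_class]
    model.zero_grad()
    score.backward()
    if act.grad is None:
        raise RuntimeError(f"no gradient reached layer {layer!r}")

    grad = act.grad[0]          # (C, d, h, w)
    activation = act.data[0]
    channel_w = grad.mean(axis=(1, 2, 3))
    cam = np.maximum((channel_w[:, None, None, None] * activation).sum(axis=0), 0.0)
    cam = ad.trilinear_resize_array(cam, volume.voxels.shape)
    cam = np.maximum(cam, 0.0)  # interpolation may ring slightly negative
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return CAMVolume(weights=cam, layer_name=layer, target_class=int(target_class))


def localization_score(cam: CAMVolume, mask: np.ndarray) -> float:
    """Mean CAM weight inside the lesion mask divided by the mean outside.

    Values above 1 mean the evidence map concentrates on the lesioned
    region.  Invariant under positive rescaling of the CAM; returns
    +inf when all weight lies inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cam.weights.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match CAM shape {cam.weights.shape}"
        )
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError("mask must be nonempty and not cover the whole volume")
    inside = float(cam.weights[mask].mean())
    outside = float(cam.weights[~mask].mean())
    if outside == 0.0:
        return float("inf") if inside > 0 else float("nan")
    return inside / outside


def save_cam(cam: CAMVolume, volume: Volume, path) -> Path:
    """Store the CAM as a NIfTI volume aligned with its input scan."""
    out = Volume(
        voxels=cam.weights,
        subject_id=volume.subject_id,
        scan_id=f"{volume.scan_id}.cam{cam.target_class}",
        label=volume.label,
        spacing=volume.spacing,
    )
    return write_volume(out, path)


def cam_panels(cam: CAMVolume, volume: Volume, path) -> Path:
    """Mid-slice overlay panels along each axis (cosmetic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, axis in zip(axes, range(3)):
        mid = volume.voxels.shape[axis] // 2
        sl = [slice(None)] * 3
        sl[axis] = mid
        ax.imshow(volume.voxels[tuple(sl)].T, cmap="gray", origin="lower")
        ax.imshow(cam.weights[tuple(sl)].T, cmap="coolwarm", alpha=0.45, origin="lower")
        ax.set_title(f"axis {axis}, slice {mid}")
        ax.axis("off")
    fig.suptitle(f"Grad-CAM ({cam.layer_name}, class {cam.target_class}) — {volume.scan_id}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path
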