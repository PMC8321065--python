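"""Grad-CAM visual explanations for fingerprint-branch predictions.

For a chosen convolutional stage of the 3D ResNet branch, the class
score's gradient is averaged over that stage's spatial extent to give
one weight per channel; the rectified, weighted sum of the stage's
activations is trilinearly upsampled to the brain grid and normalised
to [0, 1].  Explanations attribute through the image branch only — the
connectivity-vector branch has no spatial layout to map a heatmap onto.

An input-gradient mode (summed absolute gradient of the class score
with respect to the fingerprint itself) is available as an alternative
attribution at voxel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.image as mimage
from matplotlib import colormaps
import numpy as np
from scipy.ndimage import map_coordinates

from . import nn
from .connectome import ConnectivityVector, FingerprintMap
from .dataio import CLASS_NAMES, Volume4D
from .errors import GeometryError, ValidationError
from .models import MLP, MultimodalNet, ResNet3d, _single_batch


@dataclass
class SaliencyMap:
    """Nonnegative (H, W, D) heat volume; max-normalised unless degenerate."""

    heat: np.ndarray
    target_class: str
    source_layer: str
    degenerate: bool = False  # all-zero map (nothing drove the class score)

    def __post_init__(self):
        self.heat = np.asarray(self.heat, dtype=np.float64)
        if self.heat.ndim != 3:
            raise ValidationError("saliency heat must be 3D (H,W,D)")
        if self.heat.min(initial=0.0) < -1e-9:
            raise ValidationError("saliency must be nonnegative")


def _upsample_trilinear(vol: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Resample a small 3D grid onto ``target`` by linear interpolation
    between cell centers (edge values extended)."""
    coords = np.meshgrid(
        *[
            np.clip((np.arange(t) + 0.5) * s / t - 0.5, 0, s - 1)
            for t, s in zip(target, vol.shape)
        ],
        indexing="ij",
    )
    return map_coordinates(vol, np.stack(coords), order=1, mode="nearest")


def cam_from_activation(activation: np.ndarray, gradient: np.ndarray) -> np.ndarray:
    """The Grad-CAM formula: per-channel weights = spatial mean of the
    gradient; map = ReLU of the weighted activation sum.

    ``activation``/``gradient``: (C, x, y, z) arrays from one stage.
    """
    weights = gradient.mean(axis=(1, 2, 3))
    cam = np.tensordot(weights, activation, axes=(0, 0))
    return np.maximum(cam, 0.0)


def _resnet_branch(network) -> ResNet3d:
    if isinstance(network, MultimodalNet):
        return network.resnet
    if isinstance(network, ResNet3d):
        return network
    if isinstance(network, MLP):
        raise ValidationError(
            "Grad-CAM needs the image branch; an MLP has no spatial layers")
    raise ValidationError(f"unsupported network type {type(network).__name__}")


def grad_cam(network, fingerprint: FingerprintMap,
             connectivity: ConnectivityVector | None = None,
             target_class: str = "ASD", layer: str = "layer4",
             method: str = "layer") -> SaliencyMap:
    """Explain one prediction as a heat volume over the brain grid.

    ``method="layer"`` is standard Grad-CAM at the named convolutional
    stage; ``method="input"`` returns the summed absolute gradient of
    the class score with respect to the fingerprint input.
    """
    if target_class not in CLASS_NAMES:
        raise ValidationError(f"unknown target class {target_class!r}")
    resnet = _resnet_branch(network)
    stages = resnet.conv_stages()
    if layer not in stages:
        raise ValidationError(
            f"unknown layer {layer!r}; valid layers: {sorted(stages)}")
    if method not in ("layer", "input"):
        raise ValidationError("method must be 'layer' or 'input'")
    target_idx = CLASS_NAMES.index(target_class)
    grid = fingerprint.corr.shape[:3]

    module = stages[layer]
    module.capture = True
    try:
        network.eval()
        if isinstance(network, MultimodalNet):
            if connectivity is None:
                raise ValidationError(
                    "multimodal explanation requires a connectivity vector")
            fp, vec = _single_batch(fingerprint, connectivity)
            logits = network(fp, vec)
        else:
            fp = np.moveaxis(np.asarray(fingerprint.corr, dtype=nn.DTYPE), 3, 0)[None]
            logits = network(fp)
        dlogits = np.zeros_like(logits)
        dlogits[0, target_idx] = 1.0
        dinput = network.backward(dlogits)
        if method == "input":
            d_img = dinput[0] if isinstance(dinput, tuple) else dinput
            heat = np.abs(d_img[0]).sum(axis=0)  # sum over region channels
        else:
            act = module.cap_out[0].astype(np.float64)
            grad = module.cap_grad[0].astype(np.float64)
            cam = cam_from_activation(act, grad)
            heat = _upsample_trilinear(cam, grid)
    finally:
        module.capture = False
        module.cap_out = None
        module.cap_grad = None

    peak = float(heat.max(initial=0.0))
    degenerate = peak <= 0.0
    if not degenerate:
        heat = heat / peak
    else:
        heat = np.zeros(grid)
    return SaliencyMap(heat=heat, target_class=target_class,
                       source_layer=layer if method == "layer" else "input",
                       degenerate=degenerate)


def _to_background(anatomical) -> np.ndarray:
    if isinstance(anatomical, Volume4D):
        return np.asarray(anatomical.data, dtype=np.float64).mean(axis=3)
    arr = np.asarray(anatomical, dtype=np.float64)
    if arr.ndim != 3:
        raise ValidationError("anatomical background must be 3D (H,W,D)")
    return arr


def _blend_section(bg2d: np.ndarray, heat2d: np.ndarray, alpha: float) -> np.ndarray:
    lo, hi = bg2d.min(), bg2d.max()
    gray = (bg2d - lo) / (hi - lo) if hi > lo else np.zeros_like(bg2d)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    color = colormaps["hot"](heat2d)[..., :3]
    w = (alpha * heat2d)[..., None]  # zero heat leaves the anatomy untouched
    return (1.0 - w) * rgb + w * color


def overlay(saliency: SaliencyMap, anatomical, out_dir: str | Path,
            prefix: str = "overlay", alpha: float = 0.6) -> list[Path]:
    """Write mid-volume cross-sections (sagittal/coronal/axial PNGs) with
    the heatmap alpha-blended over the grayscale anatomy."""
    bg = _to_background(anatomical)
    if bg.shape != saliency.heat.shape:
        raise GeometryError(
            f"anatomy grid {bg.shape} != saliency grid {saliency.heat.shape}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mids = [s // 2 for s in bg.shape]
    sections = {
        "sagittal": (bg[mids[0]], saliency.heat[mids[0]]),
        "coronal": (bg[:, mids[1]], saliency.heat[:, mids[1]]),
        "axial": (bg[:, :, mids[2]], saliency.heat[:, :, mids[2]]),
    }
    paths = []
    for name, (b2, h2) in sections.items():
        img = _blend_section(b2, h2, alpha)
        path = out_dir / f"{prefix}_{name}.png"
        mimage.imsave(path, np.clip(img, 0, 1))
        paths.append(path)
    return paths


def saliency_region_means(saliency: SaliencyMap, atlas_labels: np.ndarray,
                          effect_regions: list[int]) -> tuple[float, float]:
    """Mean heat inside vs outside the ground-truth effect regions."""
    labels = np.asarray(atlas_labels)
    if labels.shape != saliency.heat.shape:
        raise GeometryError("atlas grid does not match saliency grid")
    inside = np.isin(labels, effect_regions)
    if not inside.any() or inside.all():
        raise ValidationError("effect regions must be a proper subset of the grid")
    return float(saliency.heat[inside].mean()), float(saliency.heat[~inside].mean())
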