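"""CAM and Grad-CAM saliency maps.

CAM projects the dense softmax weights back onto the last convolutional
feature maps: M_c(x, y) = sum_k w_kc f_k(x, y).  It requires the
conv -> global-average-pool -> dense-softmax architecture.

Grad-CAM generalises this to arbitrary CNNs by replacing the classifier
weights with channel weights alpha_kc = (1/Z) sum_ij dy^c / dA^k_ij — the
spatially averaged gradient of the pre-softmax class score with respect to
the last-conv activations — and applying a ReLU to the weighted sum:
L^c = ReLU(sum_k alpha_kc A^k).  On a CAM-compatible model the chain rule
through mean-GAP gives alpha_kc = w_kc / Z exactly, so the binarized
Grad-CAM and binarized ReLU(CAM) masks coincide; that equivalence is pinned
by a test.

CAM values are kept signed (ReLU appears only in the Grad-CAM definition);
min-max normalisation to [0, 1] happens once, via :func:`normalize01`,
immediately before Otsu thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .models import ModelAdapter

__all__ = [
    "SaliencyMap",
    "ChannelWeights",
    "CamCompatibilityError",
    "cam",
    "grad_cam",
    "upsample",
    "normalize01",
]


class CamCompatibilityError(ValueError):
    """Raised when CAM is requested for an architecture that cannot supply it."""


@dataclass
class SaliencyMap:
    """A real-valued attention grid tagged with its provenance."""

    values: np.ndarray  # (h, w) floats
    method: str  # "CAM" | "GradCAM"
    model_id: str
    class_index: int
    source_size: tuple[int, int]
    target_size: Optional[tuple[int, int]] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("saliency values must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency values must be finite")


@dataclass(frozen=True)
class ChannelWeights:
    """Grad-CAM channel weights alpha_kc with the pooling size Z = h*w."""

    alpha: np.ndarray  # (K,)
    z: int
    class_index: int


def _resolve_class(adapter: ModelAdapter, image: np.ndarray, class_c) -> int:
    if class_c is None or class_c == "predicted":
        return int(np.argmax(adapter.probabilities(image)))
    return int(class_c)


def cam(adapter: ModelAdapter, image: np.ndarray, class_c=None) -> SaliencyMap:
    """Class activation map M_c = sum_k w_kc f_k, raw (signed, unnormalised).

    ``class_c=None`` (or ``"predicted"``) uses the predicted class.
    """
    if not getattr(adapter, "cam_compatible", False):
        raise CamCompatibilityError(
            f"architecture not CAM-compatible: model {adapter.id!r} must end "
            "in global average pooling followed by a single dense softmax layer"
        )
    c = _resolve_class(adapter, image, class_c)
    fmaps = adapter.feature_maps(image)  # (h, w, K)
    weights = adapter.classifier_weights(c)  # (K,)
    values = fmaps @ weights
    return SaliencyMap(
        values=values, method="CAM", model_id=adapter.id, class_index=c,
        source_size=values.shape,
    )


def grad_cam_weights(adapter: ModelAdapter, image: np.ndarray, class_c: int) -> ChannelWeights:
    """alpha_kc: spatial mean of dy^c/dA^k over the feature grid."""
    grads = adapter.feature_gradients(image, class_c)  # (h, w, K)
    h, w, _ = grads.shape
    return ChannelWeights(alpha=grads.mean(axis=(0, 1)), z=h * w, class_index=class_c)


def grad_cam(
    adapter: ModelAdapter, image: np.ndarray, class_c=None, layer: Optional[str] = None
) -> SaliencyMap:
    """Gradient-weighted CAM: ReLU(sum_k alpha_kc A^k) at the last conv layer.

    Only the target class's score gradient enters (the backward seed is the
    one-hot vector of ``class_c``).  ``layer`` selects the feature layer; the
    bundled models expose only their last convolutional layer (the default).
    """
    if layer is not None and layer != "last_conv":
        raise ValueError(
            f"layer {layer!r} not available: adapters expose only 'last_conv'"
        )
    c = _resolve_class(adapter, image, class_c)
    fmaps = adapter.feature_maps(image)
    if fmaps.ndim != 3 or fmaps.shape[0] < 1 or fmaps.shape[1] < 1:
        raise ValueError("feature layer has no spatial extent")
    cw = grad_cam_weights(adapter, image, c)
    values = np.maximum(fmaps @ cw.alpha, 0.0)
    return SaliencyMap(
        values=values, method="GradCAM", model_id=adapter.id, class_index=c,
        source_size=values.shape,
    )


def upsample(
    smap: SaliencyMap, target: tuple[int, int], method: str = "bilinear"
) -> SaliencyMap:
    """Resample a saliency map to input resolution.

    Bilinear interpolation on an align-corners grid (source corners map to
    target corners), so values never overshoot the source min/max and
    upsampling to the source size is the identity.  ``method="nearest"`` is
    available for ablation.
    """
    h, w = smap.values.shape
    th, tw = target
    if th < h or tw < w:
        raise ValueError(
            f"target size {target} smaller than source {(h, w)}: downsampling "
            "is not supported"
        )
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if (th, tw) == (h, w):
        values = smap.values.copy()
    else:
        rows = np.linspace(0, h - 1, th) if th > 1 else np.zeros(1)
        cols = np.linspace(0, w - 1, tw) if tw > 1 else np.zeros(1)
        grid = np.meshgrid(rows, cols, indexing="ij")
        order = 1 if method == "bilinear" else 0
        values = ndi.map_coordinates(
            smap.values, np.stack([g.ravel() for g in grid]), order=order,
            mode="nearest",
        ).reshape(th, tw)
    return SaliencyMap(
        values=values, method=smap.method, model_id=smap.model_id,
        class_index=smap.class_index, source_size=smap.source_size,
        target_size=(th, tw), degenerate=smap.degenerate,
    )


def normalize01(smap: SaliencyMap) -> SaliencyMap:
    """Affine rescale to [0, 1]; a constant map becomes all-zero and is
    flagged degenerate."""
    v = smap.values
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        values = (v - lo) / (hi - lo)
        degenerate = False
    else:
        values = np.zeros_like(v)
        degenerate = True
    return SaliencyMap(
        values=values, method=smap.method, model_id=smap.model_id,
        class_index=smap.class_index, source_size=smap.source_size,
        target_size=smap.target_size, degenerate=degenerate,
    )
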