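"""Cross-model and cross-method agreement aggregation.

Per-image IoU and centre-of-mass distances are aggregated three ways:

* :func:`pairwise_agreement` — for every unordered model pair and one
  saliency method, the per-image and mean IoU / CaD between the two models'
  Otsu-binarized maps (optionally restricted to tumour images);
* :func:`method_agreement` — CAM vs Grad-CAM of the *same* model;
* :func:`summarize_table2` — per-pair rows combining both methods with the
  relative percentage differences E_IoU and E_CaD, plus an unweighted
  column-mean "Avr" row.

E_IoU = (IoU_CAM - IoU_GradCAM) / IoU_CAM * 100 and likewise E_CaD; a
positive value means Grad-CAM agreed less (IoU) or its centres sat closer
(CaD) than CAM's.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import masks_metrics as mm
from .saliency import SaliencyMap, normalize01

logger = logging.getLogger(__name__)

__all__ = [
    "PairAgreement",
    "MethodDelta",
    "pairwise_agreement",
    "method_agreement",
    "e_iou",
    "e_cad",
    "make_deltas",
    "summarize_table2",
    "round_half_away",
]


@dataclass
class PairAgreement:
    """Mean and per-image agreement for one (model pair, method) cell."""

    model_a: str
    model_b: str
    method: str
    per_image: list  # (image_id, iou, cad)
    mean_iou: float
    mean_cad: float
    subset: str = "all"

    def __post_init__(self) -> None:
        if self.model_a > self.model_b:
            raise ValueError("model_a must sort before model_b (canonical order)")


@dataclass
class MethodDelta:
    """One CAM-vs-Grad-CAM comparison row for a model pair."""

    pair: tuple[str, str]
    iou_cam: float
    iou_gradcam: float
    cad_cam: float
    cad_gradcam: float
    e_iou: float = field(init=False)
    e_cad: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_iou = e_iou(self.iou_cam, self.iou_gradcam)
        self.e_cad = e_cad(self.cad_cam, self.cad_gradcam)


def _mask_and_com(smap: SaliencyMap, com_normalisation: str):
    """Normalise, threshold and locate one map; degenerate maps get an empty
    mask and a centre at the grid centre (the uniform-map limit)."""
    norm = normalize01(smap)
    h, w = norm.values.shape
    if norm.degenerate:
        logger.warning(
            "degenerate saliency map (model %s): empty mask, centre CoM",
            smap.model_id,
        )
        mask = mm.BinaryMask(np.zeros((h, w), dtype=bool), threshold=1.0)
        com = mm.CentreOfMass(
            (w - 1) / 2, (h - 1) / 2, 0.0, com_normalisation, ref_size=(w, h)
        )
        return mask, com
    thr = mm.otsu_threshold(norm)
    mask = mm.binarize(norm, thr)
    com = mm.centre_of_mass(norm, normalisation=com_normalisation)
    return mask, com


def pairwise_agreement(
    maps: Mapping[tuple[str, str], SaliencyMap],
    method: str,
    subset: str = "all",
    labels: Optional[Mapping[str, int]] = None,
    com_normalisation: str = "mass",
) -> list[PairAgreement]:
    """Per-pair IoU/CaD agreement over all images, one method.

    ``maps`` is keyed by (image_id, model_id) and must be complete over the
    image x model grid; all maps must share one (upsampled) size.
    ``subset="tumour_only"`` keeps label-1 images and requires ``labels``.
    """
    if subset not in ("all", "tumour_only"):
        raise ValueError(f"unknown subset {subset!r}")
    image_ids = sorted({k[0] for k in maps})
    model_ids = sorted({k[1] for k in maps})
    if subset == "tumour_only":
        if labels is None:
            raise ValueError("subset='tumour_only' requires image labels")
        image_ids = [i for i in image_ids if labels[i] == 1]

    for image_id, model_id in itertools.product(image_ids, model_ids):
        if (image_id, model_id) not in maps:
            raise KeyError(f"missing saliency map for image {image_id!r}, model {model_id!r}")

    # binarize and locate each map once
    cache = {
        key: _mask_and_com(maps[key], com_normalisation)
        for key in itertools.product(image_ids, model_ids)
    }

    out = []
    for model_a, model_b in itertools.combinations(model_ids, 2):
        per_image = []
        for image_id in image_ids:
            mask_a, com_a = cache[(image_id, model_a)]
            mask_b, com_b = cache[(image_id, model_b)]
            h, w = mask_a.mask.shape
            pair_iou = mm.iou(mask_a, mask_b)
            pair_cad = mm.cartesian_distance(com_a, com_b, w, h)
            per_image.append((image_id, pair_iou, pair_cad))
        out.append(
            PairAgreement(
                model_a=model_a, model_b=model_b, method=method,
                per_image=per_image,
                mean_iou=float(np.mean([r[1] for r in per_image])),
                mean_cad=float(np.mean([r[2] for r in per_image])),
                subset=subset,
            )
        )
    return out


def method_agreement(
    maps_cam: Mapping[tuple[str, str], SaliencyMap],
    maps_gradcam: Mapping[tuple[str, str], SaliencyMap],
    com_normalisation: str = "mass",
) -> list[PairAgreement]:
    """CAM vs Grad-CAM agreement of the same model, per model.

    Returned records reuse :class:`PairAgreement` with ``model_a = model_b``
    = the model and ``method = "CAMvsGradCAM"``.
    """
    keys = sorted(maps_cam)
    for key in keys:
        if key not in maps_gradcam:
            raise KeyError(f"missing Grad-CAM map for (image, model) {key!r}")
    model_ids = sorted({k[1] for k in keys})
    out = []
    for model_id in model_ids:
        per_image = []
        for image_id in sorted({k[0] for k in keys if k[1] == model_id}):
            mask_c, com_c = _mask_and_com(maps_cam[(image_id, model_id)], com_normalisation)
            mask_g, com_g = _mask_and_com(maps_gradcam[(image_id, model_id)], com_normalisation)
            h, w = mask_c.mask.shape
            per_image.append(
                (
                    image_id,
                    mm.iou(mask_c, mask_g),
                    mm.cartesian_distance(com_c, com_g, w, h),
                )
            )
        out.append(
            PairAgreement(
                model_a=model_id, model_b=model_id, method="CAMvsGradCAM",
                per_image=per_image,
                mean_iou=float(np.mean([r[1] for r in per_image])),
                mean_cad=float(np.mean([r[2] for r in per_image])),
            )
        )
    return out


def e_iou(iou_cam: float, iou_gradcam: float) -> float:
    """Relative IoU difference (IoU_CAM - IoU_GradCAM) / IoU_CAM, in percent."""
    if iou_cam <= 0:
        raise ValueError("e_iou undefined for IoU_CAM <= 0")
    return (iou_cam - iou_gradcam) / iou_cam * 100.0


def e_cad(cad_cam: float, cad_gradcam: float) -> float:
    """Relative CaD difference (CaD_CAM - CaD_GradCAM) / CaD_CAM, in percent."""
    if cad_cam <= 0:
        raise ValueError("e_cad undefined for CaD_CAM <= 0")
    return (cad_cam - cad_gradcam) / cad_cam * 100.0


def make_deltas(
    cam_pairs: Sequence[PairAgreement], gradcam_pairs: Sequence[PairAgreement]
) -> list[MethodDelta]:
    """Join per-pair CAM and Grad-CAM means into comparison rows."""
    grad_by_pair = {(p.model_a, p.model_b): p for p in gradcam_pairs}
    deltas = []
    for cp in cam_pairs:
        key = (cp.model_a, cp.model_b)
        if key not in grad_by_pair:
            raise KeyError(f"no Grad-CAM agreement for pair {key!r}")
        gp = grad_by_pair[key]
        deltas.append(
            MethodDelta(
                pair=key, iou_cam=cp.mean_iou, iou_gradcam=gp.mean_iou,
                cad_cam=cp.mean_cad, cad_gradcam=gp.mean_cad,
            )
        )
    return deltas


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def summarize_table2(
    deltas: Sequence[MethodDelta],
    metric_decimals: int = 4,
    percent_decimals: int = 2,
) -> pd.DataFrame:
    """Per-pair comparison table plus an "Avr" row of unweighted column means.

    Metric columns (IoU, CaD) are rounded to ``metric_decimals``, the E
    percentage columns to ``percent_decimals``, both half away from zero.
    The Avr row averages the unrounded per-pair values; its E cells are left
    empty, matching the printed layout.
    """
    if not deltas:
        raise ValueError("summarize_table2 requires at least one delta")
    rows = []
    for d in sorted(deltas, key=lambda d: d.pair):
        rows.append(
            {
                "pair": f"{d.pair[0]} + {d.pair[1]}",
                "iou_cam": round_half_away(d.iou_cam, metric_decimals),
                "iou_gradcam": round_half_away(d.iou_gradcam, metric_decimals),
                "e_iou_pct": round_half_away(d.e_iou, percent_decimals),
                "cad_cam": round_half_away(d.cad_cam, metric_decimals),
                "cad_gradcam": round_half_away(d.cad_gradcam, metric_decimals),
                "e_cad_pct": round_half_away(d.e_cad, percent_decimals),
            }
        )
    avr = {
        "pair": "Avr",
        "iou_cam": round_half_away(float(np.mean([d.iou_cam for d in deltas])), metric_decimals),
        "iou_gradcam": round_half_away(float(np.mean([d.iou_gradcam for d in deltas])), metric_decimals),
        "e_iou_pct": float("nan"),
        "cad_cam": round_half_away(float(np.mean([d.cad_cam for d in deltas])), metric_decimals),
        "cad_gradcam": round_half_away(float(np.mean([d.cad_gradcam for d in deltas])), metric_decimals),
        "e_cad_pct": float("nan"),
    }
    rows.append(avr)
    return pd.DataFrame(rows)
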