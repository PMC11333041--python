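"""Center/periphery partition, CTCF, and labeling-occupancy analysis.

The contact is split into a central oval ROI holding ¾ of its area and the
remaining peripheral quarter annulus: a similar ellipse with both semi-axes
scaled by √0.75 has exactly ¾ of the area, so the center ROI is the set of
contact pixels whose normalized elliptical radius (from the contact's own
second moments) is ≤ √0.75 — the two masks partition the contact pixel set
exactly.

CTCF (corrected total cell fluorescence) is
``integrated density − ROI area × background mean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters

from cemap.io import ResultTable, RoiMask
from cemap.morphometry import ContactMeasure

CENTER_AREA_FRACTION = 0.75


@dataclass
class PartitionRois:
    center: RoiMask
    periphery: RoiMask
    contact: ContactMeasure


@dataclass
class CtcfValue:
    integrated_density: float  # intensity · px
    roi_area: int              # px
    background_mean: float     # intensity
    ctcf: float                # intensity · px; may be negative (flagged)

    @property
    def negative(self) -> bool:
        return self.ctcf < 0


@dataclass
class OccupancyResult:
    fractions: dict[str, float]   # per-channel labeled fraction of the ROI
    unlabeled: float
    thresholds: dict[str, float]
    exclusive: bool
    roi_provenance: str


def _elliptical_radius(mask: np.ndarray) -> np.ndarray:
    """Normalized elliptical radius of every pixel w.r.t. the mask's own
    second-moment ellipse (1.0 on the fitted outline)."""
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dy = ys - cy
    dx = xs - cx
    # covariance of the pixel cloud; the ellipse with the same moments has
    # semi-axes 2*sqrt(eigenvalues)
    cov = np.cov(np.vstack([dx, dy]))
    evals, evecs = np.linalg.eigh(cov)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    d = np.stack([xx - cx, yy - cy], axis=-1) @ evecs
    semi = 2.0 * np.sqrt(np.maximum(evals, 1e-12))
    return np.sqrt((d[..., 0] / semi[0]) ** 2 + (d[..., 1] / semi[1]) ** 2)


def partition_center_periphery(
    contact_mask: RoiMask | np.ndarray,
    measure: ContactMeasure,
) -> PartitionRois:
    """Split an en-face contact into the central ¾-area oval and the
    peripheral ¼ annulus."""
    if measure.view != "en-face":
        raise ValueError(
            "center/periphery partition is defined only for en-face contacts"
        )
    mask = contact_mask.mask if isinstance(contact_mask, RoiMask) else np.asarray(
        contact_mask, dtype=bool
    )
    if not mask.any():
        raise ValueError("empty contact mask")
    rho = _elliptical_radius(mask)
    center = mask & (rho <= math.sqrt(CENTER_AREA_FRACTION))
    periphery = mask & ~center
    return PartitionRois(
        center=RoiMask(center, provenance="center"),
        periphery=RoiMask(periphery, provenance="periphery"),
        contact=measure,
    )


def ctcf(
    image: np.ndarray,
    roi: RoiMask | np.ndarray,
    background_roi: RoiMask | np.ndarray,
) -> CtcfValue:
    arr = np.asarray(image, dtype=float)
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    bg = (
        background_roi.mask
        if isinstance(background_roi, RoiMask)
        else np.asarray(background_roi, dtype=bool)
    )
    if not mask.any():
        raise ValueError("empty ROI")
    if not bg.any():
        raise ValueError("empty background ROI")
    if (mask & bg).any():
        raise ValueError("ROI and background ROI must be disjoint")
    integrated = float(arr[mask].sum())
    area = int(mask.sum())
    bg_mean = float(arr[bg].mean())
    return CtcfValue(
        integrated_density=integrated,
        roi_area=area,
        background_mean=bg_mean,
        ctcf=integrated - area * bg_mean,
    )


def default_background_roi(
    image: np.ndarray, contact_mask: np.ndarray, q: float = 0.10
) -> RoiMask:
    """Helper background: the modal-intensity decile outside the contact."""
    arr = np.asarray(image, dtype=float)
    outside = ~np.asarray(contact_mask, dtype=bool)
    vals = arr[outside]
    lo, hi = np.quantile(vals, [0.5 - q / 2, 0.5 + q / 2])
    return RoiMask(outside & (arr >= lo) & (arr <= hi), provenance="background")


def center_periphery_analysis(
    images: dict[str, np.ndarray],
    partition: PartitionRois,
    background_roi: RoiMask | np.ndarray,
) -> ResultTable:
    """Normalized fluorescence density per channel in each partition ROI.

    Per ROI: CTCF / ROI area per channel, then normalized to the larger
    channel value within that ROI (the paper's normalization, under which
    the dominant channel reads 1.0).
    """
    if len(images) != 2:
        raise ValueError("center_periphery_analysis expects exactly two channels")
    rows = []
    for roi_name, roi in (("center", partition.center), ("periphery", partition.periphery)):
        dens = {}
        for ch, img in images.items():
            val = ctcf(img, roi, background_roi)
            dens[ch] = val.ctcf / val.roi_area
        top = max(dens.values())
        for ch, d in dens.items():
            rows.append(
                {
                    "roi": roi_name,
                    "channel": ch,
                    "ctcf_per_area": d,
                    "normalized": d / top if top != 0 else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    return ResultTable(
        df, {"roi": "", "channel": "", "ctcf_per_area": "intensity", "normalized": ""}
    )


def channel_comparison(values_a, values_b) -> tuple[float, float]:
    """Student's t-test across contacts for one ROI (channel A vs B)."""
    t, p = stats.ttest_ind(np.asarray(values_a), np.asarray(values_b))
    return float(t), float(p)


def occupancy(
    images: dict[str, np.ndarray],
    roi: RoiMask | np.ndarray,
    thresholds: dict[str, float] | None = None,
    exclusive: bool = True,
    roi_provenance: str = "contact-outline",
) -> OccupancyResult:
    """Labeled-area fraction of the ROI per channel, plus the unlabeled rest.

    A pixel is labeled for a channel when its intensity exceeds that
    channel's threshold (Otsu within the ROI when not given). With
    ``exclusive`` (default), pixels above threshold in several channels are
    assigned to the channel with the larger plateau-normalized intensity
    (intensity over the channel's robust in-ROI maximum), so the
    per-channel fractions and the unlabeled fraction sum to 1 and the
    crossover between two abutting blurred structures falls on their true
    boundary.
    """
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    n_roi = mask.sum()
    names = list(images)
    thr: dict[str, float] = {}
    above = {}
    for ch in names:
        arr = np.asarray(images[ch], dtype=float)
        if thresholds is not None and ch in thresholds:
            t = float(thresholds[ch])
        else:
            vals = arr[mask]
            t = float(filters.threshold_otsu(vals)) if vals.max() > vals.min() else float(
                vals.max()
            )
        thr[ch] = t
        above[ch] = (arr > t) & mask
    if exclusive and len(names) > 1:
        # plateau-normalized intensity decides contested pixels
        def plateau(ch):
            arr = np.asarray(images[ch], dtype=float)
            return max(float(np.percentile(arr[mask], 99.5)), 1e-12)

        scores = np.stack(
            [np.asarray(images[ch], dtype=float) / plateau(ch) for ch in names]
        )
        any_above = np.any([above[ch] for ch in names], axis=0)
        winner = np.argmax(scores, axis=0)
        fractions = {}
        for i, ch in enumerate(names):
            assigned = above[ch] & any_above & (winner == i)
            # a pixel above only one channel's threshold belongs to it even
            # if the other channel's normalized intensity is larger
            sole = above[ch]
            for j, other in enumerate(names):
                if j != i:
                    sole = sole & ~above[other]
            fractions[ch] = float((assigned | sole).sum() / n_roi)
        unlabeled = float(1.0 - sum(fractions.values()))
    else:
        fractions = {ch: float(above[ch].sum() / n_roi) for ch in names}
        none_above = mask & ~np.any([above[ch] for ch in names], axis=0)
        unlabeled = float(none_above.sum() / n_roi)
    return OccupancyResult(
        fractions=fractions,
        unlabeled=unlabeled,
        thresholds=thr,
        exclusive=exclusive,
        roi_provenance=roi_provenance,
    )
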