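"""Contact outline fitting, diameters, expansion factors, isotropy statistics.

Diameters are defined as the major/minor axis lengths of the second-moment
(ellipse-of-inertia) fit of the contact mask, which stays reproducible on
concave outlines; users comparing with caliper/Feret diameters should expect
small systematic differences on non-elliptical contacts.

The short-to-long diameter ratio (S/L) is the isotropy statistic: physical
expansion that is isotropic leaves the per-contact S/L distribution
unchanged. Group S/L statistics use the mean of per-contact ratios;
expansion factors use ratios of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure, morphology

from cemap.io import ProjectedImage, RoiMask


@dataclass
class ContactMeasure:
    """Fitted oval contact descriptor (all lengths µm, areas µm²)."""

    long_diameter: float
    short_diameter: float
    area: float
    view: str = "en-face"
    channel: str = ""
    centroid: tuple[float, float] = (0.0, 0.0)  # (y, x) µm
    orientation: float = 0.0                    # rad
    touches_border: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.short_diameter <= self.long_diameter):
            raise ValueError("need 0 < S <= L")
        if self.area <= 0:
            raise ValueError("area must be > 0")

    @property
    def sl_ratio(self) -> float:
        return self.short_diameter / self.long_diameter


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    p_value: float
    normal_fit_a: tuple[float, float]  # (mean, sd) MLE
    normal_fit_b: tuple[float, float]


class NoContactError(ValueError):
    """No connected component above threshold."""


def fit_contact_outline(
    image: np.ndarray | ProjectedImage,
    pixel_size: float | None = None,
    threshold: float | None = None,
    closing_radius: float = 0.0,
    channel: str = "",
    view: str = "en-face",
) -> tuple[RoiMask, ContactMeasure]:
    """Segment the dominant bright oval and fit its ellipse of inertia.

    ``image`` may be a 2D array plus ``pixel_size`` (µm/px) or a
    ProjectedImage (single channel selected by ``channel``). The mask is the
    largest connected component above ``threshold`` (Otsu when None), after
    morphological closing with radius ``closing_radius`` µm (useful when the
    contact is labeled by discrete puncta rather than filled).
    """
    if isinstance(image, ProjectedImage):
        if not channel:
            channel = next(iter(image.channels))
        arr = image.channel(channel)
        pixel_size = image.pixel_size_xy
    else:
        arr = np.asarray(image, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for raw arrays")
    if threshold is None:
        threshold = filters.threshold_otsu(arr)
    binary = arr > threshold
    if closing_radius > 0:
        r_px = max(1, round(closing_radius / pixel_size))
        binary = morphology.closing(binary, morphology.disk(r_px))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary)
    if labels.max() == 0:
        raise NoContactError(f"no component above threshold {threshold:g}")
    props = measure.regionprops(labels)
    biggest = max(props, key=lambda p: p.area)
    mask = labels == biggest.label

    touches = (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    L = biggest.axis_major_length * pixel_size
    S = biggest.axis_minor_length * pixel_size
    A = biggest.area * pixel_size**2
    cy, cx = biggest.centroid
    meas = ContactMeasure(
        long_diameter=L,
        short_diameter=S,
        area=A,
        view=view,
        channel=channel,
        centroid=(cy * pixel_size, cx * pixel_size),
        orientation=float(biggest.orientation),
        touches_border=bool(touches),
    )
    return RoiMask(mask, provenance="contact-outline"), meas


def expansion_factor(
    mean_long_expanded: float,
    mean_long_nonexpanded: float,
    mean_area_expanded: float,
    mean_area_nonexpanded: float,
) -> tuple[float, float]:
    """Linear and areal expansion factors from group means.

    linear = ratio of mean long diameters; areal = ratio of mean areas.
    """
    vals = (mean_long_expanded, mean_long_nonexpanded,
            mean_area_expanded, mean_area_nonexpanded)
    if any(v <= 0 for v in vals):
        raise ValueError("all inputs must be > 0")
    return (
        mean_long_expanded / mean_long_nonexpanded,
        mean_area_expanded / mean_area_nonexpanded,
    )


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided two-sample Student's t-test plus per-group normal MLE fits."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both groups degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b)
    return GroupComparison(
        mean_a=a.mean(),
        sem_a=a.std(ddof=1) / np.sqrt(a.size),
        n_a=a.size,
        mean_b=b.mean(),
        sem_b=b.std(ddof=1) / np.sqrt(b.size),
        n_b=b.size,
        t_statistic=float(t),
        p_value=float(p),
        normal_fit_a=(a.mean(), a.std()),
        normal_fit_b=(b.mean(), b.std()),
    )
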