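"""Synthetic club-ending scenes with known ground truth.

The generator builds a concave oval synaptic contact carrying three marker
systems — gap-junction (GJ) puncta of widely variable size, an interleaved
adherens-junction (AJ) region mutually exclusive with the puncta, and
glutamate-receptor (GluR2) patches whose centroids are confined to the
peripheral quarter-area annulus — applies a (optionally anisotropic)
expansion transform, and renders calibrated confocal-like stacks through a
Gaussian-PSF + Poisson/Gaussian-noise imaging model. Every draw is recorded
so each downstream measurement can be checked against a known answer.

Scene coordinates are the contact's local frame: u along the long axis, v
along the short axis (µm, origin at the contact center), w the height above
the contact plane. The contact surface is the paraboloid cap
``w = c * rho**2`` with ``rho**2 = (u/a)**2 + (v/b)**2``, so the concavity
depth at the rim equals ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from cemap.io import CalibratedStack, write_stack


class PlacementError(RuntimeError):
    """Puncta could not be placed disjointly (over-dense configuration)."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class ContactGeometry:
    """Oval contact on a paraboloid cap.

    a, b are the long/short semi-axes (µm); ``concavity`` is the height of
    the rim above the center (µm, 0 = flat 'en face' contact).
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    a: float = 1.055
    b: float = 0.81
    orientation: float = 0.0  # rad, long axis vs image x
    concavity: float = 0.26

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        if self.concavity < 0:
            raise ValueError("concavity must be >= 0")

    @property
    def area(self) -> float:
        """Projected (planform) contact area, µm²."""
        return math.pi * self.a * self.b

    def surface_height(self, u, v):
        rho2 = (np.asarray(u) / self.a) ** 2 + (np.asarray(v) / self.b) ** 2
        return self.concavity * rho2

    def surface_normal(self, u, v):
        """Unit normal of the cap, pointing toward +w (postsynaptic side)."""
        fu = 2.0 * self.concavity * np.asarray(u) / self.a**2
        fv = 2.0 * self.concavity * np.asarray(v) / self.b**2
        norm = np.sqrt(fu**2 + fv**2 + 1.0)
        return -fu / norm, -fv / norm, 1.0 / norm


@dataclass
class PunctaLayout:
    """Marker geometry on the contact surface (contact-frame µm).

    ``gj``, ``glur2`` and ``unlabeled`` are (N, 3) arrays of (u, v, radius).
    GJ disks are pairwise disjoint with at least ``min_edge_gap`` between
    edges; every GluR2 patch centroid lies in the peripheral annulus holding
    ¼ of the contact area; ``unlabeled`` patches are bare-membrane regions
    carrying no marker. The AJ region is derived at rasterization time as
    the contact minus the other three systems (GJ optionally dilated by
    ``aj_guard`` first), so AJ and GJ are disjoint but — with the default
    zero guard — directly abutting, the interleaved arrangement seen at
    real contacts.
    """

    gj: np.ndarray
    glur2: np.ndarray
    min_edge_gap: float
    aj_guard: float = 0.0
    unlabeled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gj = np.atleast_2d(np.asarray(self.gj, dtype=float))
        self.glur2 = np.atleast_2d(np.asarray(self.glur2, dtype=float))
        if self.unlabeled is None:
            self.unlabeled = np.zeros((0, 3))
        self.unlabeled = np.atleast_2d(np.asarray(self.unlabeled, dtype=float))
        if self.gj.size and self.gj.shape[1] != 3:
            raise ValueError("gj must be (N, 3): u, v, radius")

    @property
    def n_puncta(self) -> int:
        return 0 if self.gj.size == 0 else len(self.gj)

    def gj_areas(self) -> np.ndarray:
        if self.gj.size == 0:
            return np.zeros(0)
        return math.pi * self.gj[:, 2] ** 2


@dataclass
class ExpansionTransform:
    """Linear expansion by factor k; the short axis scales by k * r."""

    k: float = 3.9
    r: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.r > 0):
            raise ValueError("k and r must be > 0")

    @property
    def areal(self) -> float:
        return self.k**2 * self.r


#: marker name -> which layout mask it labels
MARKER_MASKS: dict[str, str] = {
    "Cx35.5": "gj",
    "Cx34.1": "gj",
    "ZO1": "gj",
    "N-cadherin": "aj",
    "b-catenin": "aj",
    "GluR2": "glur2",
}

#: default displacement of each marker along the local surface normal, µm
#: (post-expansion image scale). Cx35.5 is the presynaptic reference plane;
#: the postsynaptic hemichannel connexin sits ~0.03 µm away and the
#: postsynaptic scaffold ZO1 ~0.21 µm away.
DEFAULT_OFFSETS: dict[str, float] = {
    "Cx35.5": 0.0,
    "Cx34.1": 0.03,
    "ZO1": 0.21,
    "N-cadherin": 0.0,
    "b-catenin": 0.0,
    "GluR2": 0.0,
}


@dataclass
class ImagingModel:
    """Confocal-like rendering model (all lengths µm, image scale).

    PSF defaults are the midpoints of the instrument's stated lateral
    (248.9–322 nm FWHM) and axial (429.4–557.0 nm FWHM) resolution ranges,
    converted to Gaussian sigmas (FWHM / 2.355).
    """

    lateral_sigma: float = 0.28 / 2.355
    axial_sigma: float = 0.49 / 2.355
    pixel_size_xy: float = 0.05
    z_step: float = 0.25
    photon_scale: float = 500.0
    read_noise_sd: float = 3.0
    background: float = 10.0
    offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    #: bookkeeping for the secondary-antibody swap control
    fluorophores: dict[str, str] = field(default_factory=dict)
    #: per-fluorophore residual chromatic displacement along the normal, µm
    chromatic_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, val in (
            ("lateral_sigma", self.lateral_sigma),
            ("axial_sigma", self.axial_sigma),
            ("pixel_size_xy", self.pixel_size_xy),
            ("z_step", self.z_step),
            ("photon_scale", self.photon_scale),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(d < 0 for d in self.offsets.values()):
            raise ValueError("marker offsets must be >= 0")

    def marker_offset(self, marker: str) -> float:
        d = self.offsets.get(marker, 0.0)
        fluo = self.fluorophores.get(marker)
        if fluo is not None:
            d += self.chromatic_offsets.get(fluo, 0.0)
        return d

    def swap_fluorophores(self, marker_a: str, marker_b: str) -> "ImagingModel":
        """Return a model with the two markers' fluorophores exchanged."""
        fluo = dict(self.fluorophores)
        fluo[marker_a], fluo[marker_b] = (
            fluo.get(marker_b, "fluoB"),
            fluo.get(marker_a, "fluoA"),
        )
        return replace(self, fluorophores=fluo)


@dataclass
class GroundTruth:
    """The generator's answers for one scene."""

    n_puncta: int
    punctum_areas_pre: np.ndarray     # µm², biological (pre-expansion) scale
    punctum_areas: np.ndarray         # µm², current coordinate scale
    contact_long_diameter_pre: float
    contact_short_diameter_pre: float
    contact_long_diameter: float
    contact_short_diameter: float
    glur2_count: int
    offsets: dict[str, float] = field(default_factory=dict)
    occupancy: dict[str, float] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    mask_pixel_size: float | None = None
    mask_origin: tuple[float, float] | None = None

    @property
    def sl_ratio_pre(self) -> float:
        return self.contact_short_diameter_pre / self.contact_long_diameter_pre

    @property
    def sl_ratio(self) -> float:
        return self.contact_short_diameter / self.contact_long_diameter


@dataclass
class SyntheticScene:
    geometry: ContactGeometry
    layout: PunctaLayout
    ground_truth: GroundTruth
    expanded: bool = False


# --------------------------------------------------------------------------
# generator configuration


def _lognormal_params(mean: float, lower: float, tail: float = 0.005):
    """(mu, sigma) of a log-normal with the given mean whose ``tail``
    quantile sits at ``lower``."""
    z = stats.norm.ppf(1.0 - tail)
    c = math.log(mean) - math.log(lower)
    sigma = -z + math.sqrt(z * z + 2.0 * c)
    mu = math.log(mean) - sigma**2 / 2.0
    return mu, sigma


@dataclass
class GeneratorConfig:
    """Study conditions for the scene generator.

    Lengths/areas suffixed ``_post`` are given on the post-expansion image
    scale (the scale on which the source measurements were made) and are
    converted to the pre-expansion frame through ``expansion`` at sampling
    time. Contact long and short diameters are drawn independently per
    scene, with group SDs back-computed from reported SEMs (L: 0.037·√38,
    S: 0.026·√38, puncta count: 1.287·√11).

    The punctum-area law is a log-normal clipped to ``area_range_post``,
    with its mean set so that mean count × mean area reproduces the
    reported average junctional area per contact (≈12,425 connexons at
    12,000 connexons/µm², i.e. ≈0.378 µm² per punctum on the image scale)
    and its lower 0.5% quantile at the smallest reported punctum.
    """

    # contact ellipse, pre-expansion
    long_diameter_mean: float = 2.11
    long_diameter_sd: float = 0.228
    short_diameter_mean: float = 1.62
    short_diameter_sd: float = 0.160
    concavity: float = 0.26           # pre-expansion µm (~1.0 µm expanded)
    # GJ puncta
    count_mean: float = 36.73
    count_sd: float = 4.27
    count_min: int = 5
    mean_area_post: float = 12425.0 / 12000.0 * 13.4 / 36.73
    area_range_post: tuple[float, float] = (0.06, 1.99)
    min_edge_gap_post: float = 0.05
    # GluR2 patches
    glur2_count_range: tuple[int, int] = (8, 12)
    glur2_radius_range_post: tuple[float, float] = (0.7, 1.05)
    # bare-membrane (unlabeled) patches
    unlabeled_count_range: tuple[int, int] = (10, 16)
    unlabeled_radius_range_post: tuple[float, float] = (0.3, 0.52)
    # AJ construction: 0 means AJ directly abuts the GJ/GluR2 systems
    aj_guard_post: float = 0.0
    # expansion applied downstream of sampling
    expansion: ExpansionTransform = field(default_factory=ExpansionTransform)
    # rejection-sampling budgets
    max_position_attempts: int = 20000
    max_area_redraws: int = 80
    max_contact_redraws: int = 40
    #: densest effective disk packing accepted before the contact is redrawn
    packing_limit: float = 0.48

    def area_distribution(self):
        """Frozen log-normal of post-expansion punctum areas (before clipping)."""
        mu, sigma = _lognormal_params(self.mean_area_post, self.area_range_post[0])
        return stats.lognorm(s=sigma, scale=math.exp(mu))


# --------------------------------------------------------------------------
# sampling


def _truncated_normal(rng, mean, sd, lo, hi=np.inf):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal draw failed; check config bounds")


def _uniform_in_ellipse(rng, a, b, n):
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    rho = np.sqrt(rng.uniform(0.0, 1.0, n))
    return a * rho * np.cos(theta), b * rho * np.sin(theta)


def _sample_punctum_radius(config: GeneratorConfig, rng) -> float:
    """Pre-expansion radius of one punctum; post-expansion area is drawn from
    the clipped log-normal."""
    dist = config.area_distribution()
    area_post = float(np.clip(dist.ppf(rng.uniform()), *config.area_range_post))
    k_area = config.expansion.areal
    return math.sqrt(area_post / (math.pi * k_area))


def _place_gj_disks(config, geometry, radii, rng):
    radii = sorted(radii, reverse=True)
    kr = config.expansion.k * math.sqrt(config.expansion.r)
    gap = config.min_edge_gap_post / kr

    placed_u: list[float] = []
    placed_v: list[float] = []
    placed_r: list[float] = []
    redraws = 0
    batch = 512
    for r in radii:
        while True:
            ok = False
            if geometry.a - r > 0 and geometry.b - r > 0:
                for _ in range(max(1, config.max_position_attempts // batch)):
                    cu, cv = _uniform_in_ellipse(
                        rng, geometry.a - r, geometry.b - r, batch
                    )
                    if placed_r:
                        pu = np.asarray(placed_u)
                        pv = np.asarray(placed_v)
                        pr = np.asarray(placed_r)
                        d2 = (cu[:, None] - pu) ** 2 + (cv[:, None] - pv) ** 2
                        free = np.all(d2 >= (pr + r + gap) ** 2, axis=1)
                    else:
                        free = np.ones(batch, dtype=bool)
                    idx = np.flatnonzero(free)
                    if idx.size:
                        placed_u.append(float(cu[idx[0]]))
                        placed_v.append(float(cv[idx[0]]))
                        placed_r.append(r)
                        ok = True
                        break
            if ok:
                break
            redraws += 1
            if redraws > config.max_area_redraws:
                raise PlacementError(
                    f"could not place punctum after {redraws} area redraws; "
                    "configuration too dense"
                )
            r = _sample_punctum_radius(config, rng)
    return np.column_stack([placed_u, placed_v, placed_r])


def _place_glur2(config, geometry, rng):
    n = rng.integers(config.glur2_count_range[0], config.glur2_count_range[1] + 1)
    kr = config.expansion.k * math.sqrt(config.expansion.r)
    lo, hi = (x / kr for x in config.glur2_radius_range_post)
    out = []
    for _ in range(n):
        r = rng.uniform(lo, hi)
        # area-uniform elliptical coordinate in the peripheral quarter annulus
        rho = math.sqrt(rng.uniform(0.75, 1.0))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        out.append((geometry.a * rho * math.cos(theta),
                    geometry.b * rho * math.sin(theta), r))
    return np.asarray(out).reshape(-1, 3)


def _place_unlabeled(config, geometry, rng):
    n = rng.integers(
        config.unlabeled_count_range[0], config.unlabeled_count_range[1] + 1
    )
    kr = config.expansion.k * math.sqrt(config.expansion.r)
    lo, hi = (x / kr for x in config.unlabeled_radius_range_post)
    u, v = _uniform_in_ellipse(rng, geometry.a, geometry.b, int(n))
    r = rng.uniform(lo, hi, int(n))
    return np.column_stack([u, v, r])


def sample_contact(
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticScene:
    """Draw one pre-expansion contact scene with full ground truth."""
    config = config or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng()

    n = max(config.count_min, round(rng.normal(config.count_mean, config.count_sd)))
    kr = config.expansion.k * math.sqrt(config.expansion.r)
    gap = config.min_edge_gap_post / kr

    # redraw the contact (and, in rare extreme draws, the area set — never the
    # count, which is the calibrated quantity) until the puncta can pack
    geometry = radii = None
    for _ in range(20):
        radii = [_sample_punctum_radius(config, rng) for _ in range(n)]
        eff_area = sum(math.pi * (r + gap / 2.0) ** 2 for r in radii)
        for _ in range(config.max_contact_redraws):
            L = _truncated_normal(
                rng, config.long_diameter_mean, config.long_diameter_sd, 0.5
            )
            S = _truncated_normal(
                rng, config.short_diameter_mean, config.short_diameter_sd, 0.4, L
            )
            if eff_area <= config.packing_limit * math.pi * (L / 2.0) * (S / 2.0):
                geometry = ContactGeometry(
                    a=L / 2.0, b=S / 2.0, orientation=0.0,
                    concavity=config.concavity,
                )
                break
        if geometry is not None:
            break
    if geometry is None:
        raise PlacementError(
            "no contact draw could accommodate the drawn puncta set; "
            "configuration too dense"
        )
    gj = _place_gj_disks(config, geometry, radii, rng)
    glur2 = _place_glur2(config, geometry, rng)
    unlabeled = _place_unlabeled(config, geometry, rng)
    layout = PunctaLayout(
        gj=gj,
        glur2=glur2,
        unlabeled=unlabeled,
        min_edge_gap=config.min_edge_gap_post / kr,
        aj_guard=config.aj_guard_post / kr,
    )
    areas_pre = layout.gj_areas()
    gt = GroundTruth(
        n_puncta=layout.n_puncta,
        punctum_areas_pre=areas_pre,
        punctum_areas=areas_pre.copy(),
        contact_long_diameter_pre=2 * geometry.a,
        contact_short_diameter_pre=2 * geometry.b,
        contact_long_diameter=2 * geometry.a,
        contact_short_diameter=2 * geometry.b,
        glur2_count=len(glur2),
    )
    return SyntheticScene(geometry=geometry, layout=layout, ground_truth=gt)


def apply_expansion(scene: SyntheticScene, transform: ExpansionTransform) -> SyntheticScene:
    """Scale a scene: k along the long axis, k·r along the short axis.

    Disk radii scale by k·√r (area-preserving for the slightly anisotropic
    case); heights scale by k. With r = 1 every area scales by exactly k².
    """
    k, r = transform.k, transform.r
    kr = k * math.sqrt(r)
    geom = scene.geometry
    new_geom = ContactGeometry(
        center=tuple(c * k for c in geom.center),
        a=geom.a * k,
        b=geom.b * k * r,
        orientation=geom.orientation,
        concavity=geom.concavity * k,
    )

    def scale_disks(disks):
        if disks.size == 0:
            return disks.copy()
        out = disks.copy()
        out[:, 0] *= k
        out[:, 1] *= k * r
        out[:, 2] *= kr
        return out

    layout = PunctaLayout(
        gj=scale_disks(scene.layout.gj),
        glur2=scale_disks(scene.layout.glur2),
        unlabeled=scale_disks(scene.layout.unlabeled),
        min_edge_gap=scene.layout.min_edge_gap * kr,
        aj_guard=scene.layout.aj_guard * kr,
    )
    gt = scene.ground_truth
    new_gt = replace(
        gt,
        punctum_areas=gt.punctum_areas_pre * transform.areal,
        contact_long_diameter=gt.contact_long_diameter_pre * k,
        contact_short_diameter=gt.contact_short_diameter_pre * k * r,
        masks={},
        occupancy={},
        mask_pixel_size=None,
        mask_origin=None,
    )
    return SyntheticScene(
        geometry=new_geom, layout=layout, ground_truth=new_gt, expanded=True
    )


# --------------------------------------------------------------------------
# rasterization


def _disk_mask(shape, origin, pixel, disks):
    mask = np.zeros(shape, dtype=bool)
    u0, v0 = origin
    ny, nx = shape
    for cu, cv, r in np.atleast_2d(disks):
        if disks.size == 0:
            break
        ix0 = max(0, int((cu - r - u0) / pixel) - 1)
        ix1 = min(nx, int((cu + r - u0) / pixel) + 2)
        iy0 = max(0, int((cv - r - v0) / pixel) - 1)
        iy1 = min(ny, int((cv + r - v0) / pixel) + 2)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        xs = u0 + (np.arange(ix0, ix1) + 0.5) * pixel
        ys = v0 + (np.arange(iy0, iy1) + 0.5) * pixel
        dd = (xs[None, :] - cu) ** 2 + (ys[:, None] - cv) ** 2
        mask[iy0:iy1, ix0:ix1] |= dd <= r**2
    return mask


def _circular_footprint(radius_px: int):
    if radius_px < 1:
        return None
    r = radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def rasterize_layout(
    scene: SyntheticScene,
    pixel_size: float,
    margin: float = 0.5,
):
    """Rasterize the scene's marker systems onto a contact-frame grid.

    Returns ``(masks, origin)`` where masks holds boolean images named
    contact, gj, glur2, aj, unlabeled (pixel centers at
    ``origin + (index + 0.5) * pixel_size``). The four labeled/unlabeled
    masks partition the contact exactly, so ground-truth occupancy fractions
    sum to one by construction.
    """
    geom = scene.geometry
    u0 = -(geom.a + margin)
    v0 = -(geom.b + margin)
    nx = int(math.ceil(2 * (geom.a + margin) / pixel_size))
    ny = int(math.ceil(2 * (geom.b + margin) / pixel_size))
    xs = u0 + (np.arange(nx) + 0.5) * pixel_size
    ys = v0 + (np.arange(ny) + 0.5) * pixel_size
    rho2 = (xs[None, :] / geom.a) ** 2 + (ys[:, None] / geom.b) ** 2
    contact = rho2 <= 1.0

    gj = _disk_mask((ny, nx), (u0, v0), pixel_size, scene.layout.gj) & contact
    glur2_raw = _disk_mask((ny, nx), (u0, v0), pixel_size, scene.layout.glur2) & contact
    bare_raw = (
        _disk_mask((ny, nx), (u0, v0), pixel_size, scene.layout.unlabeled) & contact
    )

    guard_px = round(scene.layout.aj_guard / pixel_size)
    if guard_px >= 1:
        foot = _circular_footprint(guard_px)
        gj_block = ndimage.binary_dilation(gj, structure=foot)
        glur2 = glur2_raw & ~gj_block
        glur2_block = ndimage.binary_dilation(glur2, structure=foot)
    else:
        gj_block = gj
        glur2 = glur2_raw & ~gj
        glur2_block = glur2
    # priority: GJ > GluR2 > bare membrane > AJ; complements keep the
    # partition exact
    aj = contact & ~gj_block & ~glur2_block & ~bare_raw
    unlabeled = contact & ~gj & ~glur2 & ~aj

    masks = {
        "contact": contact,
        "gj": gj,
        "glur2": glur2,
        "aj": aj,
        "unlabeled": unlabeled,
    }
    return masks, (u0, v0)


def ground_truth_occupancy(masks: dict[str, np.ndarray]) -> dict[str, float]:
    n = masks["contact"].sum()
    return {
        "gj": masks["gj"].sum() / n,
        "aj": masks["aj"].sum() / n,
        "glur2": masks["glur2"].sum() / n,
        "unlabeled": masks["unlabeled"].sum() / n,
    }


# --------------------------------------------------------------------------
# rendering


def _deposit_trilinear(vol: np.ndarray, gz, gy, gx) -> None:
    """Scatter unit weights at fractional voxel coordinates with trilinear
    spreading (avoids sub-voxel quantization bias in rendered positions)."""
    nz, ny, nx = vol.shape
    z0 = np.floor(gz).astype(int)
    y0 = np.floor(gy).astype(int)
    x0 = np.floor(gx).astype(int)
    fz = gz - z0
    fy = gy - y0
    fx = gx - x0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                iz = np.clip(z0 + dz, 0, nz - 1)
                iy = np.clip(y0 + dy, 0, ny - 1)
                ix = np.clip(x0 + dx, 0, nx - 1)
                np.add.at(vol, (iz, iy, ix), wz * wy * wx)


def render(
    scene: SyntheticScene,
    model: ImagingModel | None = None,
    rng: np.random.Generator | None = None,
    channels: tuple[str, ...] = ("Cx35.5", "ZO1"),
    view: str = "en-face",
    noise: bool = True,
    margin: float = 0.6,
) -> CalibratedStack:
    """Render a scene into a calibrated multi-channel z-stack.

    Each marker's mask is deposited at its surface position, displaced along
    the local surface normal by the model's offset for that marker, blurred
    with the anisotropic Gaussian PSF (lateral in the image plane, axial
    along the camera axis), and read out as
    ``Poisson(photon_scale * density + background) + N(0, read_noise)``,
    clipped at zero.

    view 'en-face' projects along the contact normal (camera axis = w);
    view 'side' looks along the short axis (camera axis = v), so normal
    offsets of a flat contact fall in the image plane.
    """
    model = model or ImagingModel()
    rng = rng if rng is not None else np.random.default_rng()
    if view not in ("en-face", "side"):
        raise ValueError("view must be 'en-face' or 'side'")

    px = model.pixel_size_xy
    zs = model.z_step
    masks, (u0, v0) = rasterize_layout(scene, px, margin=margin)
    ny_m, nx_m = masks["contact"].shape
    xs = u0 + (np.arange(nx_m) + 0.5) * px
    ys = v0 + (np.arange(ny_m) + 0.5) * px

    geom = scene.geometry
    max_off = max((model.marker_offset(m) for m in channels), default=0.0)
    w_lo = -margin
    w_hi = geom.concavity + max_off + margin

    if view == "en-face":
        nx, ny = nx_m, ny_m
        nz = max(3, int(math.ceil((w_hi - w_lo) / zs)) + 1)
    else:
        nx = nx_m
        ny = max(8, int(math.ceil((w_hi - w_lo) / px)) + 1)
        nz = max(3, int(math.ceil(2 * (geom.b + margin) / zs)) + 1)

    out_channels: dict[str, np.ndarray] = {}
    sig_vox = (model.axial_sigma / zs, model.lateral_sigma / px,
               model.lateral_sigma / px)
    for marker in channels:
        key = MARKER_MASKS.get(marker)
        if key is None:
            raise KeyError(f"unknown marker {marker!r}; known: {sorted(MARKER_MASKS)}")
        m = masks[key]
        iy, ix = np.nonzero(m)
        vol = np.zeros((nz, ny, nx))
        if iy.size:
            uu = xs[ix]
            vv = ys[iy]
            ww = geom.surface_height(uu, vv)
            d = model.marker_offset(marker)
            if d:
                n_u, n_v, n_w = geom.surface_normal(uu, vv)
                uu = uu + d * n_u
                vv = vv + d * n_v
                ww = ww + d * n_w
            if view == "en-face":
                gz = (ww - w_lo) / zs
                gy = (vv - v0) / px
                gx = (uu - u0) / px
            else:
                gz = (vv - v0) / zs
                gy = (ww - w_lo) / px
                gx = (uu - u0) / px
            _deposit_trilinear(vol, gz, gy, gx)
            if view == "side":
                # one mask pixel covers px of depth but lands on one z plane;
                # renormalize so plateau density stays ~1 per voxel footprint
                vol *= zs / px
        vol = ndimage.gaussian_filter(vol, sigma=sig_vox)
        expected = model.photon_scale * vol + model.background
        if noise:
            img = rng.poisson(expected).astype(float)
            img += rng.normal(0.0, model.read_noise_sd, size=img.shape)
            img = np.clip(img, 0.0, None)
        else:
            img = expected
        out_channels[marker] = img

    gt = scene.ground_truth
    gt.masks = masks
    gt.mask_pixel_size = px
    gt.mask_origin = (u0, v0)
    gt.occupancy = ground_truth_occupancy(masks)
    gt.offsets = {m: model.marker_offset(m) for m in channels}

    return CalibratedStack(
        channels=out_channels,
        pixel_size_xy=px,
        z_step=zs,
        expansion_state="expanded" if scene.expanded else "non-expanded",
        metadata={"view": view, "synthetic": True},
    )


def single_punctum_scene(
    radius: float,
    concavity: float = 0.0,
    contact_scale: float = 2.5,
) -> SyntheticScene:
    """A minimal expanded scene holding one centered GJ punctum.

    Used for controlled line-scan experiments: render it with view='side'
    and a flat geometry so pre/postsynaptic normal offsets fall in the
    image plane.
    """
    half = max(1.0, contact_scale * radius)
    geom = ContactGeometry(a=half, b=half, concavity=concavity)
    layout = PunctaLayout(
        gj=np.array([[0.0, 0.0, radius]]),
        glur2=np.zeros((0, 3)),
        min_edge_gap=0.1,
        aj_guard=0.05,
    )
    area = math.pi * radius**2
    gt = GroundTruth(
        n_puncta=1,
        punctum_areas_pre=np.array([area / ExpansionTransform().areal]),
        punctum_areas=np.array([area]),
        contact_long_diameter_pre=2 * half / 3.9,
        contact_short_diameter_pre=2 * half / 3.9,
        contact_long_diameter=2 * half,
        contact_short_diameter=2 * half,
        glur2_count=0,
    )
    return SyntheticScene(geometry=geom, layout=layout, ground_truth=gt, expanded=True)


# --------------------------------------------------------------------------
# dataset generation


def generate_dataset(
    config: GeneratorConfig | None = None,
    n_scenes: int = 1,
    seed: int = 0,
    model: ImagingModel | None = None,
    channels: tuple[str, ...] = ("Cx35.5", "ZO1"),
    view: str = "en-face",
    noise: bool = True,
    out_dir: str | Path | None = None,
):
    """Generate ``n_scenes`` expanded, rendered scenes deterministically.

    Returns ``(pairs, manifest)`` where pairs is a list of
    ``(CalibratedStack, GroundTruth)`` and manifest a DataFrame with one row
    per scene. If ``out_dir`` is given, stacks are written as OME-TIFF and
    the manifest plus a per-scene ground-truth table as CSV.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    config = config or GeneratorConfig()
    model = model or ImagingModel()
    rng = np.random.default_rng(seed)

    pairs = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_scenes):
        scene = sample_contact(config, rng)
        scene = apply_expansion(scene, config.expansion)
        stack = render(scene, model, rng, channels=channels, view=view, noise=noise)
        gt = scene.ground_truth
        pairs.append((stack, gt))
        row = {
            "scene": i,
            "seed": seed,
            "n_puncta": gt.n_puncta,
            "glur2_count": gt.glur2_count,
            "long_diameter_um": gt.contact_long_diameter,
            "short_diameter_um": gt.contact_short_diameter,
            "total_gj_area_um2": float(gt.punctum_areas.sum()),
        }
        row.update({f"occ_{k}": v for k, v in gt.occupancy.items()})
        if out_dir is not None:
            stack_path = out_dir / f"scene_{i:03d}.ome.tif"
            write_stack(stack, stack_path)
            row["stack_path"] = stack_path.name
            gt_path = out_dir / f"scene_{i:03d}_truth.csv"
            pd.DataFrame(
                {
                    "punctum_area_um2": gt.punctum_areas,
                    "punctum_area_pre_um2": gt.punctum_areas_pre,
                }
            ).to_csv(gt_path, index=False)
            row["truth_path"] = gt_path.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return pairs, manifest
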