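"""Two-channel line-scan profiles and subpixel pre/post peak offsets.

A line scan crosses a punctum roughly along the local contact normal; each
channel's intensity profile along the line has one peak, localized to
subpixel precision by a Gaussian fit around the discrete maximum (3-point
parabolic interpolation as fallback). The signed offset d is the channel-B
peak position minus the channel-A peak position along the line (positive =
B farther from the line start); group statistics use |d|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from cemap.io import ResultTable


@dataclass
class LineProfile:
    positions: np.ndarray          # µm along the line, uniform, increasing
    intensities: dict[str, np.ndarray]
    p0: tuple[float, float]        # (y, x) µm
    p1: tuple[float, float]
    width: float                   # µm averaged perpendicular to the line

    def __post_init__(self) -> None:
        d = np.diff(self.positions)
        if len(self.positions) < 3 or not np.all(d > 0):
            raise ValueError("positions must be increasing with >= 3 samples")
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("positions must be uniformly spaced")
        for name, arr in self.intensities.items():
            if len(arr) != len(self.positions):
                raise ValueError(f"channel {name!r} length mismatch")

    def channel(self, name: str) -> np.ndarray:
        return self.intensities[name]


@dataclass
class PeakFit:
    position: float       # µm along the line
    at_boundary: bool     # maximum on the profile edge -> exclude from stats
    method: str           # 'gaussian' or 'parabolic'
    r_squared: float      # fit quality (1.0 for exact)


@dataclass
class PeakOffset:
    position_a: float
    position_b: float
    offset: float         # signed, µm (B minus A)
    fit_a: PeakFit
    fit_b: PeakFit

    @property
    def excluded(self) -> bool:
        return self.fit_a.at_boundary or self.fit_b.at_boundary


def extract_profile(
    images: dict[str, np.ndarray],
    p0: tuple[float, float],
    p1: tuple[float, float],
    pixel_size: float,
    width: float = 0.0,
    step: float | None = None,
) -> LineProfile:
    """Sample intensities along the segment p0 -> p1 ((y, x) in µm).

    Bilinear interpolation at uniform steps (default: one pixel), averaged
    over ``width`` µm perpendicular to the line.
    """
    first = next(iter(images.values()))
    ny, nx = first.shape
    if width < 0:
        raise ValueError("width must be >= 0")
    y0, x0 = p0
    y1, x1 = p1
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise ValueError("zero-length line")
    for (yy, xx) in (p0, p1):
        if not (0 <= yy <= (ny - 1) * pixel_size and 0 <= xx <= (nx - 1) * pixel_size):
            raise ValueError(f"endpoint ({yy:g}, {xx:g}) µm outside the image")
    if step is None:
        step = pixel_size
    n = int(np.floor(length / step)) + 1
    t = np.arange(n) * step
    uy = (y1 - y0) / length
    ux = (x1 - x0) / length
    # perpendicular unit vector for width averaging
    py_, px_ = -ux, uy
    if width > 0:
        n_off = max(1, int(np.floor(width / pixel_size)))
        offs = np.linspace(-width / 2, width / 2, 2 * n_off + 1)
    else:
        offs = np.array([0.0])

    intensities = {}
    for name, img in images.items():
        arr = np.asarray(img, dtype=float)
        if arr.shape != (ny, nx):
            raise ValueError("all channels must share one shape")
        acc = np.zeros(n)
        for o in offs:
            ys = (y0 + t * uy + o * py_) / pixel_size
            xs = (x0 + t * ux + o * px_) / pixel_size
            acc += ndimage.map_coordinates(
                arr, np.vstack([ys, xs]), order=1, mode="nearest"
            )
        intensities[name] = acc / len(offs)
    return LineProfile(positions=t, intensities=intensities, p0=p0, p1=p1, width=width)


def _gaussian(x, amp, mu, sigma, base):
    return base + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def locate_peak(
    positions: np.ndarray,
    intensities: np.ndarray,
    window: float = 0.18,
) -> PeakFit:
    """Subpixel position of the profile's global maximum.

    Gaussian fit to samples within ±``window`` µm of the discrete maximum;
    falls back to 3-point parabolic interpolation when the fit fails or
    wanders out of the window.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return PeakFit(position=float(x[i]), at_boundary=True, method="boundary",
                       r_squared=0.0)
    sel = np.abs(x - x[i]) <= window
    xs, ys = x[sel], y[sel]
    if xs.size >= 4:
        try:
            sigma0 = max(window / 2.0, (x[1] - x[0]))
            p0 = [y[i] - ys.min(), x[i], sigma0, ys.min()]
            popt, _ = optimize.curve_fit(_gaussian, xs, ys, p0=p0, maxfev=2000)
            mu = float(popt[1])
            if xs[0] <= mu <= xs[-1] and popt[0] > 0:
                resid = ys - _gaussian(xs, *popt)
                ss_tot = float(((ys - ys.mean()) ** 2).sum())
                r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
                return PeakFit(position=mu, at_boundary=False, method="gaussian",
                               r_squared=r2)
        except (RuntimeError, ValueError):
            pass
    # 3-point parabola through (i-1, i, i+1)
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    dx = x[1] - x[0]
    return PeakFit(position=float(x[i] + delta * dx), at_boundary=False,
                   method="parabolic", r_squared=0.0)


def peak_offset(
    profile: LineProfile,
    channel_a: str,
    channel_b: str,
    window: float = 0.18,
) -> PeakOffset:
    """Signed peak-to-peak distance (channel B minus channel A) along the line."""
    fit_a = locate_peak(profile.positions, profile.channel(channel_a), window)
    fit_b = locate_peak(profile.positions, profile.channel(channel_b), window)
    return PeakOffset(
        position_a=fit_a.position,
        position_b=fit_b.position,
        offset=fit_b.position - fit_a.position,
        fit_a=fit_a,
        fit_b=fit_b,
    )


def offset_stats(groups: dict[str, np.ndarray]) -> tuple[ResultTable, dict]:
    """Group means ± SEM of |d|, one-way ANOVA, and Tukey HSD pairs.

    ``groups`` maps condition name (e.g. 'cx-cx', 'cx-zo1', 'cx-zo1-swapped')
    to an array of signed offsets; statistics are on magnitudes.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    mags = {k: np.abs(np.asarray(v, dtype=float)) for k, v in groups.items()}
    for k, v in mags.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    rows = [
        {
            "group": k,
            "mean_abs_offset": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
            "n": int(v.size),
        }
        for k, v in mags.items()
    ]
    f_stat, p = stats.f_oneway(*mags.values())
    values = np.concatenate(list(mags.values()))
    labels = np.concatenate([[k] * len(v) for k, v in mags.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairs = [
        {
            "group_1": str(res[0]),
            "group_2": str(res[1]),
            "mean_diff": float(res[2]),
            "p_adj": float(res[3]),
        }
        for res in tukey.summary().data[1:]
    ]
    table = ResultTable(
        pd.DataFrame(rows),
        {"group": "", "mean_abs_offset": "µm", "sem": "µm", "n": ""},
    )
    return table, {"anova_f": float(f_stat), "anova_p": float(p), "tukey": pairs}


def auto_line_through_punctum(
    centroid: tuple[float, float],
    contact_center: tuple[float, float],
    half_length: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of a line through a punctum centroid along the outward
    radial (local contact-normal) direction, (y, x) µm."""
    cy, cx = centroid
    oy, ox = contact_center
    d = np.hypot(cy - oy, cx - ox)
    if d == 0:
        uy, ux = 1.0, 0.0
    else:
        uy, ux = (cy - oy) / d, (cx - ox) / d
    return (
        (cy - half_length * uy, cx - half_length * ux),
        (cy + half_length * uy, cx + half_length * ux),
    )
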