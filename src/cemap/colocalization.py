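"""Thresholded Manders colocalization between two channels within an ROI.

M1 is the fraction of above-threshold channel-A intensity lying in pixels
where channel B is also above threshold; M2 is the symmetric quantity for B
over A. Thresholds are selected independently per channel (Otsu within the
ROI by default, or manual values, or the Costes joint regression search) and
recorded with each result. Raw (unthresholded) Manders coefficients are the
manual (0, 0) case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters

from cemap.io import ResultTable, RoiMask
import pandas as pd


@dataclass
class MandersResult:
    m1: float | None   # None when the denominator vanished
    m2: float | None
    threshold_a: float
    threshold_b: float
    roi_pixels: int

    @property
    def defined(self) -> bool:
        return self.m1 is not None and self.m2 is not None


def _as_mask(roi) -> np.ndarray:
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def _costes_thresholds(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Costes regression-based joint threshold search.

    Fit B = slope * A + intercept over the ROI, then walk a candidate
    threshold T down from max(A); the Costes pair is (T, slope*T+intercept)
    at the highest T for which the below-threshold pixels are uncorrelated
    (Pearson r <= 0).
    """
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant-intensity channel; Costes search undefined")
    slope, intercept = np.polyfit(a, b, 1)
    for t in np.linspace(a.max(), a.min(), 256):
        tb = slope * t + intercept
        below = (a < t) | (b < tb)
        if below.sum() < 2:
            continue
        x, y = a[below], b[below]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if r <= 0:
            return float(t), float(tb)
    return float(a.min()), float(slope * a.min() + intercept)


def select_thresholds(
    img_a: np.ndarray,
    img_b: np.ndarray,
    roi,
    method: str = "otsu",
    manual: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Independent per-channel thresholds within the ROI."""
    mask = _as_mask(roi)
    a = np.asarray(img_a, dtype=float)[mask]
    b = np.asarray(img_b, dtype=float)[mask]
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires manual=(tA, tB)")
        return float(manual[0]), float(manual[1])
    if method == "otsu":
        if a.max() == a.min() or b.max() == b.min():
            raise ValueError("constant-intensity channel; Otsu undefined")
        return float(filters.threshold_otsu(a)), float(filters.threshold_otsu(b))
    if method == "costes":
        return _costes_thresholds(a, b)
    raise ValueError(f"unknown threshold method {method!r}")


def manders(
    img_a: np.ndarray,
    img_b: np.ndarray,
    roi,
    threshold_a: float,
    threshold_b: float,
) -> MandersResult:
    """Thresholded Manders coefficients over the ROI.

    A zero denominator (no above-threshold signal in a channel) yields an
    undefined coefficient (None), never a silent zero.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask = _as_mask(roi)
    if mask.shape != a.shape:
        raise ValueError("ROI shape must match image shape")
    av = a[mask]
    bv = b[mask]
    a_above = av > threshold_a
    b_above = bv > threshold_b
    sum_a = av[a_above].sum()
    sum_b = bv[b_above].sum()
    m1 = float(av[a_above & b_above].sum() / sum_a) if sum_a > 0 else None
    m2 = float(bv[a_above & b_above].sum() / sum_b) if sum_b > 0 else None
    return MandersResult(
        m1=m1,
        m2=m2,
        threshold_a=float(threshold_a),
        threshold_b=float(threshold_b),
        roi_pixels=int(mask.sum()),
    )


def coloc_batch(
    image_pairs: list[tuple[np.ndarray, np.ndarray, object]],
    method: str = "otsu",
    manual: tuple[float, float] | None = None,
) -> tuple[ResultTable, dict[str, float]]:
    """Per-contact Manders coefficients plus their means ± SEM.

    ``image_pairs`` holds (img_a, img_b, roi) triples, one per contact.
    Undefined results are kept in the table (NaN) but excluded from means.
    """
    if not image_pairs:
        raise ValueError("need at least one contact")
    rows = []
    for i, (img_a, img_b, roi) in enumerate(image_pairs):
        ta, tb = select_thresholds(img_a, img_b, roi, method=method, manual=manual)
        res = manders(img_a, img_b, roi, ta, tb)
        rows.append(
            {
                "contact": i,
                "m1": np.nan if res.m1 is None else res.m1,
                "m2": np.nan if res.m2 is None else res.m2,
                "threshold_a": res.threshold_a,
                "threshold_b": res.threshold_b,
                "roi_pixels": res.roi_pixels,
            }
        )
    df = pd.DataFrame(rows)
    m1 = df["m1"].dropna()
    m2 = df["m2"].dropna()
    summary = {
        "mean_m1": float(m1.mean()) if len(m1) else float("nan"),
        "sem_m1": float(m1.std(ddof=1) / np.sqrt(len(m1))) if len(m1) > 1 else float("nan"),
        "mean_m2": float(m2.mean()) if len(m2) else float("nan"),
        "sem_m2": float(m2.std(ddof=1) / np.sqrt(len(m2))) if len(m2) > 1 else float("nan"),
        "n": int(len(df)),
        "n_undefined": int(df["m1"].isna().sum() + df["m2"].isna().sum()),
    }
    units = {c: "" for c in df.columns}
    units["roi_pixels"] = "px"
    return ResultTable(df, units), summary
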