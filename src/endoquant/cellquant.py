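"""Per-cell ROI quantification of epifluorescence images.

Mirrors the manual-ROI workflow used for surface-marker and uptake-probe
quantification: cells are delineated as regions of interest (here supplied
as a label image or polygon table — the package performs no segmentation),
the mean pixel intensity inside each cell ROI is measured, and the mean of
a coverslip-background ROI on the same image is subtracted to give the net
mean per cell.  Images are checked for pixel saturation, and per-cell
Pearson correlation between two channels provides a colocalization index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "CellROI",
    "CellMeasurement",
    "rois_from_labels",
    "rois_from_polygons",
    "mean_roi_intensity",
    "background_subtract",
    "saturation_check",
    "pearson_coefficient",
    "measure_cells",
]


@dataclass(frozen=True)
class CellROI:
    """A region of interest: a boolean pixel mask plus its role."""

    roi_id: str
    mask: np.ndarray  # boolean, same shape as the image
    role: str = "cell"  # cell | background

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if not self.mask.any():
            raise ValueError(f"ROI {self.roi_id!r} is empty")
        if self.role not in ("cell", "background"):
            raise ValueError("role must be 'cell' or 'background'")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellMeasurement:
    """One cell's quantification with its condition/experiment labels."""

    roi_id: str
    condition: str
    experiment_id: str
    measure: str  # surface-marker | uptake | pearson_r
    raw_mean: float = float("nan")
    bg_mean: float = float("nan")
    net_mean: float = float("nan")
    pearson_r: float = float("nan")
    saturated_fraction: float = 0.0
    negative_net: bool = False


def rois_from_labels(label_image: np.ndarray, background_label: int = 0) -> list[CellROI]:
    """Cell ROIs from a label image; ``background_label`` pixels form one
    background ROI (default: everything outside the cells)."""
    label_image = np.asarray(label_image)
    rois = [
        CellROI(roi_id=str(int(lab)), mask=label_image == lab, role="cell")
        for lab in np.unique(label_image)
        if lab != background_label
    ]
    bg_mask = label_image == background_label
    if bg_mask.any():
        rois.append(CellROI(roi_id="background", mask=bg_mask, role="background"))
    return rois


def rois_from_polygons(table: pd.DataFrame, shape: tuple[int, int]) -> list[CellROI]:
    """ROIs from a polygon table with columns (roi_id, role, row, col);
    vertices are grouped by roi_id in row order."""
    required = {"roi_id", "role", "row", "col"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"polygon table missing columns: {sorted(missing)}")
    rois = []
    for roi_id, grp in table.groupby("roi_id", sort=False):
        rr, cc = _draw_polygon(grp["row"].to_numpy(float), grp["col"].to_numpy(float), shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        rois.append(CellROI(roi_id=str(roi_id), mask=mask, role=str(grp["role"].iloc[0])))
    return rois


def mean_roi_intensity(image: np.ndarray, roi: CellROI) -> float:
    """Arithmetic mean of the pixel intensities inside the ROI."""
    image = np.asarray(image, dtype=float)
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    return float(image[roi.mask].mean())


def background_subtract(cell_raw: float, bg_raw: float) -> tuple[float, bool]:
    """Net mean = cell mean - background mean.

    Negative nets are retained (clipping would bias condition averages) but
    flagged.  Returns ``(net, negative_flag)``.
    """
    if not (np.isfinite(cell_raw) and np.isfinite(bg_raw)):
        raise ValueError("cell and background means must be finite")
    net = float(cell_raw - bg_raw)
    return net, net < 0


def saturation_check(
    image: np.ndarray, bit_depth: int = 16, roi: CellROI | None = None
) -> tuple[float, bool]:
    """Fraction of pixels at the camera maximum (2**bit_depth - 1).

    Restricted to ``roi`` when given.  Returns ``(fraction, warn)`` with
    ``warn`` set whenever any pixel is saturated.
    """
    if bit_depth not in (8, 12, 16):
        raise ValueError("bit_depth must be 8, 12 or 16")
    image = np.asarray(image)
    values = image[roi.mask] if roi is not None else image.ravel()
    frac = float(np.mean(values >= 2**bit_depth - 1))
    return frac, frac > 0.0


def pearson_coefficient(ch1: np.ndarray, ch2: np.ndarray, roi: CellROI) -> float:
    """Pearson correlation of the two channels over the ROI pixels.

    The plain coefficient over all ROI pixels, with no intensity threshold
    or Costes masking.  Zero variance in either channel makes the
    coefficient undefined; NaN is returned (never 0, which would be a real
    colocalization value).
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    if ch1.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    v1 = ch1[roi.mask]
    v2 = ch2[roi.mask]
    if v1.size < 3:
        raise ValueError("ROI must contain at least 3 pixels")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return float("nan")
    return float(pearsonr(v1, v2).statistic)


def measure_cells(
    image: np.ndarray,
    rois: list[CellROI],
    condition: str,
    experiment_id: str,
    measure: str = "surface-marker",
    bit_depth: int = 16,
    ch2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Quantify every cell ROI on one image.

    One background ROI per image is applied to all cells of that image.
    With ``ch2`` given and ``measure="pearson_r"``, the per-cell Pearson
    coefficient is computed instead of (in addition to) intensity.
    Returns a tidy DataFrame, one row per cell.
    """
    cells = [r for r in rois if r.role == "cell"]
    bgs = [r for r in rois if r.role == "background"]
    if not cells:
        raise ValueError("no cell ROIs supplied")
    if not bgs:
        raise ValueError("no background ROI supplied")
    bg_mean = mean_roi_intensity(image, bgs[0])
    records = []
    for roi in cells:
        raw = mean_roi_intensity(image, roi)
        net, neg = background_subtract(raw, bg_mean)
        sat, _ = saturation_check(image, bit_depth=bit_depth, roi=roi)
        r = pearson_coefficient(image, ch2, roi) if ch2 is not None else float("nan")
        records.append(
            {
                "roi_id": roi.roi_id, "condition": condition,
                "experiment_id": experiment_id, "measure": measure,
                "raw_mean": raw, "bg_mean": bg_mean, "net_mean": net,
                "pearson_r": r, "saturated_fraction": sat, "negative_net": neg,
            }
        )
    return pd.DataFrame.from_records(records)
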