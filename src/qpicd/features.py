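"""Per-cell morphological and quantitative-phase features.

Eleven features are computed for one cell in one frame:

* morphology — cell area, circularity ``4 pi A / P^2``, eccentricity
  (minor/major axis of the moment-fitted ellipse), solidity;
* whole-cell phase — optical volume ``sum(dphi) (lambda / 2 pi) dx dy``
  (proportional to dry mass) and the population standard deviation of the
  phase over the cell;
* intracellular distribution — the cell is split into a central region C
  (the largest connected region with phase above 1.1x the within-cell Otsu
  threshold, after morphological closing) and its peripheral complement P.
  Mean central / peripheral phase, their ratio, the fried-egg score
  (area(C) / cell area) and the nuclear-edge score (mean phase-gradient
  magnitude over a two-pixel elliptical band at the nuclear boundary, 0
  when no qualifying ellipse is found) quantify the redistribution of dry
  mass during cell death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel, label as sk_label, regionprops
from skimage.morphology import closing as _closing, disk

from .core import PhaseImage, TimeLapseStack

logger = logging.getLogger(__name__)

__all__ = [
    "CellRegions",
    "otsu_threshold",
    "split_central_peripheral",
    "morphological_features",
    "whole_cell_phase_features",
    "nuclear_edge_score",
    "compute_feature_vector",
    "extract_feature_table",
]

#: Factor applied to the Otsu threshold when defining the central region.
CENTRAL_THRESHOLD_FACTOR = 1.1

#: Nuclear-edge validity window on ellipse-to-cell area ratio.
EDGE_AREA_RATIO = (0.1, 0.3)
#: Maximum major/minor axis ratio of a valid nuclear-edge ellipse.
EDGE_MAX_ELONGATION = 2.5
#: Band-average gradient must exceed this multiple of the mean cell phase.
EDGE_GRADIENT_FACTOR = 0.6


def otsu_threshold(values: Sequence[float], n_bins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance over a histogram.

    The histogram spans ``[min, max]`` of ``values`` with ``n_bins`` equal
    bins; the returned threshold is the upper edge of the splitting bin.
    When several splits achieve the maximal between-class variance (which
    happens exactly when the histogram has an empty valley), the middle of
    the maximizing plateau is returned, centring the threshold in the
    valley.  Constant input is rejected.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need at least two finite values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("cannot threshold constant input")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu0 = np.divide(csum, w0, out=np.zeros_like(csum), where=w0 > 0)
    mu1 = np.divide(csum[-1] + counts[-1] * centers[-1] - csum, w1,
                    out=np.zeros_like(csum), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    best = sigma_b.max()
    plateau = np.flatnonzero(np.isclose(sigma_b, best, rtol=1e-12, atol=0.0))
    split = int(plateau[(len(plateau) - 1) // 2])
    return float(edges[split + 1])


@dataclass
class CellRegions:
    """Partition of one cell mask into central (C) and peripheral (P) parts.

    ``central | peripheral == cell`` and the two are disjoint; ``central``
    is a single connected region (possibly empty for flat cells).  The
    nuclear-edge band ``edge`` is filled in by :func:`nuclear_edge_score`.
    """

    cell: np.ndarray
    central: np.ndarray
    peripheral: np.ndarray
    threshold: float
    edge: np.ndarray | None = field(default=None)

    @property
    def has_central(self) -> bool:
        return bool(self.central.any())


def split_central_peripheral(
    image: PhaseImage, cell_mask: np.ndarray, closing_radius: int = 2
) -> CellRegions:
    """Split a cell into its high-phase central region and the periphery.

    The candidate region is ``phase > 1.1 * Otsu(within-cell phase)``,
    smoothed by morphological closing (disc radius ``closing_radius``); C is
    its largest 4-connected component clipped to the cell.  Cells whose
    phase histogram yields no candidate (e.g. uniform-phase cells) get an
    empty C, for which the central statistics are undefined (NaN) and the
    fried-egg score is 0.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    phase = image.phase
    inside = phase[cell_mask]
    empty = np.zeros_like(cell_mask)
    try:
        thr = otsu_threshold(inside)
    except ValueError:
        return CellRegions(cell_mask, empty, cell_mask.copy(), np.nan)
    candidate = cell_mask & (phase > CENTRAL_THRESHOLD_FACTOR * thr)
    if candidate.any():
        candidate = _closing(candidate, disk(closing_radius)) & cell_mask
    if not candidate.any():
        return CellRegions(cell_mask, empty, cell_mask.copy(), thr)
    lab = sk_label(candidate, connectivity=1)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    central = lab == sizes.argmax()
    peripheral = cell_mask & ~central
    return CellRegions(cell_mask, central, peripheral, thr)


def morphological_features(
    cell_mask: np.ndarray, pixel_size: float
) -> tuple[float, float, float, float]:
    """(area um^2, circularity, eccentricity, solidity) of one cell mask.

    Perimeter uses the Crofton estimate so a rasterized disc has
    circularity close to 1; eccentricity is the minor/major axis-length
    ratio of the moment-fitted ellipse (1 for a circle).  Masks smaller
    than 5 px or disconnected are rejected.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_px = int(cell_mask.sum())
    if n_px < 5:
        raise ValueError("mask too small (< 5 px) for moment features")
    lab = sk_label(cell_mask, connectivity=1)
    if lab.max() != 1:
        raise ValueError("cell mask must be a single connected component")
    props = regionprops(lab)[0]
    area_px = props.area
    perimeter = props.perimeter_crofton
    circularity = 4.0 * np.pi * area_px / perimeter**2 if perimeter > 0 else np.nan
    major = props.axis_major_length
    minor = props.axis_minor_length
    eccentricity = minor / major if major > 0 else 1.0
    solidity = props.solidity
    return (
        float(area_px) * pixel_size**2,
        float(circularity),
        float(eccentricity),
        float(solidity),
    )


def whole_cell_phase_features(
    image: PhaseImage, cell_mask: np.ndarray
) -> tuple[float, float]:
    """(optical volume um^3, phase sd rad) over the cell mask.

    Optical volume integrates the phase over the cell area and scales by
    ``wavelength / (2 pi)``; it is proportional to the cell's dry mass.
    The standard deviation is the population sd (divisor = pixel count).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    inside = image.phase[cell_mask]
    volume = float(inside.sum() * (image.wavelength / (2.0 * np.pi)) * image.pixel_area)
    return volume, float(inside.std())


def _gradient_magnitude(image: PhaseImage) -> np.ndarray:
    """|grad(phase)| by central differences, in radians per micrometre."""
    gy, gx = np.gradient(image.phase, image.pixel_size)
    return np.hypot(gx, gy)


def _ellipse_band(
    shape: tuple[int, int], xc: float, yc: float, a: float, b: float, theta: float,
    width_px: float = 2.0,
) -> np.ndarray:
    """Two-pixel-wide band along an ellipse outline (row/col = y/x)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - xc
    dy = yy - yc
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    # local radius of the ellipse along this direction, px
    r_local = a * b / np.hypot(b * np.cos(ang), a * np.sin(ang))
    dist = np.abs(rho - 1.0) * r_local
    return dist <= width_px / 2.0


def nuclear_edge_score(
    image: PhaseImage, regions: CellRegions
) -> tuple[float, np.ndarray]:
    """Mean gradient magnitude over the detected nuclear-edge band.

    Steps: (1) threshold the gradient magnitude within C by Otsu to get a
    high-gradient region H; (2) fit an ellipse outline to each of the two
    largest connected components of H and rank the candidates by the mean
    gradient over a two-pixel band along the fitted ellipse; (3) a
    candidate is valid iff the ellipse/cell area ratio lies in (0.1, 0.3),
    its elongation (major/minor) is below 2.5 and the band-average gradient
    exceeds 0.6x the mean cell phase; (4) the score is the band-average
    gradient of the best valid candidate and 0 when none qualifies.

    Returns ``(score, band_mask)``; the band is empty when the score is 0.
    """
    empty = np.zeros_like(regions.cell)
    if not regions.has_central:
        return 0.0, empty
    gradmag = _gradient_magnitude(image)
    grads_in_c = gradmag[regions.central]
    try:
        gthr = otsu_threshold(grads_in_c)
    except ValueError:
        return 0.0, empty
    high = regions.central & (gradmag > gthr)
    if not high.any():
        return 0.0, empty
    lab = sk_label(high, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    cell_area = float(regions.cell.sum())
    mean_phase = float(image.phase[regions.cell].mean())
    candidates = []
    for comp_label in order[:2]:
        if sizes[comp_label] < 5:
            continue
        ys, xs = np.nonzero(lab == comp_label)
        with np.errstate(divide="ignore", invalid="ignore"):
            model = EllipseModel.from_estimate(np.column_stack([xs, ys]).astype(float))
        if not model:
            continue
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = model.theta
        if a < b:  # normalise so a is the semi-major axis
            a, b = b, a
            theta += np.pi / 2
        if not np.isfinite([xc, yc, a, b]).all() or b <= 1.0 or a > max(image.shape):
            continue
        band = _ellipse_band(image.shape, xc, yc, a, b, theta) & regions.cell
        if not band.any():
            continue
        band_grad = float(gradmag[band].mean())
        area_ratio = np.pi * a * b / cell_area
        valid = (
            EDGE_AREA_RATIO[0] < area_ratio < EDGE_AREA_RATIO[1]
            and a / b < EDGE_MAX_ELONGATION
            and band_grad > EDGE_GRADIENT_FACTOR * mean_phase
        )
        candidates.append((band_grad, valid, band))
    candidates.sort(key=lambda c: c[0], reverse=True)
    for band_grad, valid, band in candidates:
        if valid:
            return band_grad, band
    return 0.0, empty


def compute_feature_vector(image: PhaseImage, cell_mask: np.ndarray) -> dict[str, float]:
    """All 11 features of one cell in one frame.

    Degenerate cells without a central region report NaN for the central
    and peripheral means and their ratio, 0 for the fried-egg and
    nuclear-edge scores.
    """
    area, circularity, eccentricity, solidity = morphological_features(
        cell_mask, image.pixel_size
    )
    volume, phase_sd = whole_cell_phase_features(image, cell_mask)
    regions = split_central_peripheral(image, cell_mask)
    if regions.has_central:
        mean_c = float(image.phase[regions.central].mean())
        mean_p = (
            float(image.phase[regions.peripheral].mean())
            if regions.peripheral.any()
            else np.nan
        )
        ratio = mean_p / mean_c if mean_c != 0 else np.nan
        fried_egg = float(regions.central.sum() / regions.cell.sum())
        edge_score, edge_band = nuclear_edge_score(image, regions)
        regions.edge = edge_band
    else:
        mean_c = mean_p = ratio = np.nan
        fried_egg = 0.0
        edge_score = 0.0
    return {
        "cell_area": area,
        "circularity": circularity,
        "eccentricity": eccentricity,
        "solidity": solidity,
        "optical_volume": volume,
        "phase_sd": phase_sd,
        "mean_central_phase": mean_c,
        "mean_peripheral_phase": mean_p,
        "peripheral_to_central_ratio": ratio,
        "fried_egg_score": fried_egg,
        "nuclear_edge_score": edge_score,
    }


def extract_feature_table(
    stack: TimeLapseStack,
    label_images: Sequence[np.ndarray],
    tracks: Sequence,
    complete_only: bool = True,
) -> pd.DataFrame:
    """Long-format feature table: one row per (track, frame), 11 columns.

    ``label_images`` are the per-frame label maps the tracks refer to
    (arrays or :class:`~qpicd.segment.LabelImage`).  Tracks must span the
    whole movie when ``complete_only`` is set; rows for masks that fail
    feature extraction carry NaN features.
    """
    from .segment import LabelImage  # local import to avoid a cycle

    times = stack.times_h
    n_frames = len(stack)
    rows = []
    kept = 0
    for track in tracks:
        if complete_only and not track.complete(n_frames):
            continue
        kept += 1
        for frame_idx, lbl, _area in track.points:
            labels = label_images[frame_idx]
            arr = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
            mask = arr == lbl
            try:
                feats = compute_feature_vector(stack[frame_idx], mask)
            except ValueError:
                feats = {name: np.nan for name in _feature_names()}
            rows.append(
                {"track_id": track.track_id, "frame": frame_idx, "t_hours": times[frame_idx], **feats}
            )
    if not rows:
        logger.warning("no complete tracks: empty feature table")
        return pd.DataFrame(
            columns=["track_id", "frame", "t_hours", *_feature_names()]
        )
    return pd.DataFrame(rows)


def _feature_names() -> tuple[str, ...]:
    from .synthetic import FEATURE_NAMES

    return FEATURE_NAMES
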