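"""Resolution-enhancement evaluation: resolvability scores and reliability.

The central metric is the *resolvability score* of a pair of adjacent 2D
peaks.  With peak heights ``h_i``, ``h_j`` and the valley-floor height
``h_v`` between them,

    score = 1 - 2 h_v / (h_i + h_j),   clipped to [0, 1],

so a fully resolved pair (valley down to baseline) scores 1 and a merged
pair (valley as high as the peaks) scores 0.  Pairs are found on the HR
spectrum: every picked peak is paired with its three nearest neighbours,
duplicates are removed, and pairs farther apart than 30 pixels are
discarded.  The HR pair positions are then matched into the LR and SR
grids (scaled by the grid-size ratio, refined inside a small search
window) and scored there, so all three resolutions are scored on the same
physical pairs.

The reliability analysis treats a higher-resolution acquisition (HHR) as
ground truth for peak existence: peaks detected in LR and SR at a sweep of
thresholds are matched to HHR peaks within a 2-pixel tolerance (greedy
nearest-first one-to-one assignment), and the fraction of the *additional*
SR peaks (beyond the LR count) that match truth measures how much of the
gained detail is real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import Spectrum2D

__all__ = [
    "Peak",
    "PeakPair",
    "ResolvabilityRecord",
    "pick_peaks",
    "form_pairs",
    "match_position",
    "valley_height",
    "resolvability",
    "categorize",
    "score_pairs",
    "summarize",
    "reliability",
    "records_to_frame",
]

#: Score bins: [0, 0.2) poorly, [0.2, 0.6) partially, [0.6, 1.0] well resolved.
CATEGORY_EDGES = (0.2, 0.6)


@dataclass(frozen=True)
class Peak:
    row: int
    col: int
    height: float

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class PeakPair:
    peak_a: Peak
    peak_b: Peak
    distance_px: float


@dataclass
class ResolvabilityRecord:
    pair_id: int
    pair: PeakPair
    heights: dict      # resolution -> (h_i, h_j, h_v)
    scores: dict       # resolution -> score
    categories: dict   # resolution -> label
    matched: dict      # resolution -> bool (distinct matched maxima found)


def pick_peaks(s: Spectrum2D, threshold_frac: float = 0.01) -> list[Peak]:
    """8-neighbour local maxima at >= threshold_frac x global max.

    A pixel belongs to a maximum if it equals the maximum over its 3x3
    neighbourhood; connected components of such pixels (plateaus) yield one
    peak each, at the component pixel with the smallest (row, col).
    Plateau handling matters for J-Res data: under the between-row J = 0
    convention a singlet's apex straddles the two centre rows with equal
    intensity, so it has no strictly greater pixel.  Returned sorted by
    height descending, ties broken by (row, col).
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    g = s.grid.astype(np.float64)
    gmax = g.max(initial=0.0)
    if gmax <= 0:
        return []
    neigh_max = ndimage.maximum_filter(g, size=3, mode="constant", cval=-np.inf)
    mask = (g == neigh_max) & (g >= threshold_frac * gmax)
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    peaks = []
    for comp in range(1, n_labels + 1):
        rows, cols = np.nonzero(labels == comp)
        i = np.lexsort((cols, rows))[0]
        r, c = int(rows[i]), int(cols[i])
        peaks.append(Peak(r, c, float(g[r, c])))
    peaks.sort(key=lambda p: (-p.height, p.row, p.col))
    return peaks


def form_pairs(peaks: list[Peak], k: int = 3, max_dist_px: float = 30.0) -> list[PeakPair]:
    """Union over peaks of their k nearest neighbours, deduplicated,
    dropping pairs farther apart than ``max_dist_px``.

    Nearest-neighbour ties are broken by (distance, row, col) of the
    neighbour; self-pairs are excluded.
    """
    if not peaks:
        return []
    coords = np.array([[p.row, p.col] for p in peaks], dtype=np.float64)
    n = len(peaks)
    seen: set[tuple[int, int]] = set()
    pairs: list[PeakPair] = []
    if n == 1:
        return pairs
    tree = cKDTree(coords)
    kq = min(k + 1, n)
    dists, _ = tree.query(coords, k=kq)
    dists = np.atleast_2d(dists)
    for i in range(n):
        # all candidates up to the k-th neighbour distance, so boundary ties
        # are resolved by the documented (distance, row, col) rule rather
        # than by k-d tree internals
        radius = float(dists[i, kq - 1]) + 1e-9
        cand = []
        for j in tree.query_ball_point(coords[i], radius):
            if j == i:
                continue
            d = float(np.hypot(*(coords[i] - coords[j])))
            cand.append((d, peaks[j].row, peaks[j].col, j))
        cand.sort()
        for dist, _, _, jdx in cand[:k]:
            if dist > max_dist_px or dist <= 0:
                continue
            key = (min(i, jdx), max(i, jdx))
            if key in seen:
                continue
            seen.add(key)
            a, b = peaks[key[0]], peaks[key[1]]
            pairs.append(PeakPair(a, b, dist))
    return pairs


def match_position(p: Peak, s: Spectrum2D, window_px: int = 3,
                   source_shape: tuple[int, int] | None = None) -> Peak:
    """Locate the peak ``p`` (picked on a possibly different grid) in ``s``.

    Coordinates are mapped by the per-axis grid-size ratio and rounded,
    then the highest strict local maximum within the ±``window_px`` box is
    returned; if the box contains no local maximum, its maximum-intensity
    pixel is returned.  Boxes extending past the grid edge are clipped.
    ``window_px`` is expressed in source-grid pixels and scales with the
    coordinate mapping, so the search covers the same physical
    neighbourhood on a coarser grid (a fixed pixel window on a half-size
    grid would capture unrelated neighbouring peaks).
    """
    h, w = s.shape
    if source_shape is None:
        r, c = p.row, p.col
        win_r = win_c = window_px
    else:
        r = int(round(p.row * h / source_shape[0]))
        c = int(round(p.col * w / source_shape[1]))
        win_r = max(1, int(np.ceil(window_px * h / source_shape[0] - 1e-9)))
        win_c = max(1, int(np.ceil(window_px * w / source_shape[1] - 1e-9)))
    r = min(max(r, 0), h - 1)
    c = min(max(c, 0), w - 1)
    r0, r1 = max(r - win_r, 0), min(r + win_r + 1, h)
    c0, c1 = max(c - win_c, 0), min(c + win_c + 1, w)
    # context so box-edge pixels see their true neighbours
    R0, R1 = max(r0 - 1, 0), min(r1 + 1, h)
    C0, C1 = max(c0 - 1, 0), min(c1 + 1, w)
    sub = s.grid[R0:R1, C0:C1].astype(np.float64)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(sub, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    best: tuple | None = None
    for rr in range(r0, r1):
        for cc in range(c0, c1):
            v = float(s.grid[rr, cc])
            if sub[rr - R0, cc - C0] > neigh_max[rr - R0, cc - C0]:
                cand = (1, v, -(abs(rr - r) + abs(cc - c)), -rr, -cc)
            else:
                cand = (0, v, -(abs(rr - r) + abs(cc - c)), -rr, -cc)
            if best is None or cand > best:
                best = cand
    _, v, _, nr, nc = best
    return Peak(-nr, -nc, v)


def valley_height(s: Spectrum2D, a: Peak, b: Peak) -> float:
    """Minimum intensity along the straight line between two peaks.

    The profile is sampled at unit steps with bilinear interpolation;
    endpoints included.  Axis-aligned profiles reduce to the exact grid
    slice.
    """
    if (a.row, a.col) == (b.row, b.col):
        raise ValueError("valley requires two distinct peak positions")
    dist = float(np.hypot(a.row - b.row, a.col - b.col))
    n = int(np.ceil(dist)) + 1
    rows = np.linspace(a.row, b.row, n)
    cols = np.linspace(a.col, b.col, n)
    profile = ndimage.map_coordinates(s.grid.astype(np.float64),
                                      [rows, cols], order=1, mode="nearest")
    return float(profile.min())


def resolvability(h_i: float, h_j: float, h_v: float, variant: str = "mean") -> float:
    """Resolvability score in [0, 1].

    ``variant="mean"`` (default): ``1 - 2 h_v / (h_i + h_j)``.
    ``variant="min"``: ``1 - h_v / min(h_i, h_j)``.
    Both give 1 when the valley reaches baseline and 0 when it reaches the
    (equal) peak heights; scores are clipped to [0, 1].
    """
    if h_i <= 0 or h_j <= 0:
        raise ValueError("peak heights must be positive")
    if h_v < 0:
        h_v = 0.0
    if variant == "mean":
        score = 1.0 - 2.0 * h_v / (h_i + h_j)
    elif variant == "min":
        score = 1.0 - h_v / min(h_i, h_j)
    else:
        raise ValueError(f"unknown resolvability variant {variant!r}")
    return float(min(max(score, 0.0), 1.0))


def categorize(score: float) -> str:
    """Score category: bins closed on the left, 1.0 counted as well resolved."""
    lo, hi = CATEGORY_EDGES
    if score < lo:
        return "poorly resolved"
    if score < hi:
        return "partially resolved"
    return "well resolved"


def score_pairs(
    hr: Spectrum2D,
    lr: Spectrum2D,
    sr: Spectrum2D,
    pairs: list[PeakPair],
    window_px: int = 3,
    variant: str = "mean",
) -> list[ResolvabilityRecord]:
    """Score each HR-derived peak pair in the HR, LR and SR spectra.

    HR pair positions are matched into each spectrum (coordinates scaled by
    the grid-size ratio for LR), heights taken at the matched maxima and
    the valley measured along the straight line between them.  A pair whose
    two members match to the same pixel in some resolution is flagged
    (``matched[res] = False``) and scored 0 there (fully merged), never
    silently dropped.
    """
    specs = {"HR": hr, "LR": lr, "SR": sr}
    records: list[ResolvabilityRecord] = []
    for pid, pair in enumerate(pairs):
        heights: dict = {}
        scores: dict = {}
        cats: dict = {}
        matched: dict = {}
        for name, spec in specs.items():
            src = hr.shape if spec.shape != hr.shape else None
            ma = match_position(pair.peak_a, spec, window_px, source_shape=src)
            mb = match_position(pair.peak_b, spec, window_px, source_shape=src)
            if ma.position == mb.position:
                matched[name] = False
                h = max(ma.height, 0.0)
                heights[name] = (ma.height, mb.height, h)
                scores[name] = 0.0
            else:
                matched[name] = True
                hv = valley_height(spec, ma, mb)
                heights[name] = (ma.height, mb.height, hv)
                if ma.height <= 0 or mb.height <= 0:
                    scores[name] = 0.0
                else:
                    scores[name] = resolvability(ma.height, mb.height, hv, variant)
            cats[name] = categorize(scores[name])
        records.append(ResolvabilityRecord(pid, pair, heights, scores, cats, matched))
    return records


def records_to_frame(records: list[ResolvabilityRecord]) -> pd.DataFrame:
    """One row per pair: coordinates, distance, per-resolution h and scores."""
    rows = []
    for rec in records:
        row = {
            "pair_id": rec.pair_id,
            "row_a": rec.pair.peak_a.row, "col_a": rec.pair.peak_a.col,
            "row_b": rec.pair.peak_b.row, "col_b": rec.pair.peak_b.col,
            "distance_px": rec.pair.distance_px,
        }
        for res in ("HR", "LR", "SR"):
            hi, hj, hv = rec.heights[res]
            row[f"h_i_{res}"] = hi
            row[f"h_j_{res}"] = hj
            row[f"h_v_{res}"] = hv
            row[f"score_{res}"] = rec.scores[res]
            row[f"category_{res}"] = rec.categories[res]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records: list[ResolvabilityRecord], bin_width: int = 10) -> dict:
    """Aggregate resolvability records.

    Returns improvement fractions (SR >= LR and SR > LR), the Pearson
    correlation of HR vs SR scores (``None`` if either side has zero
    variance), medians per resolution, and per-distance-bin mean scores.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize")
    hr = np.array([r.scores["HR"] for r in records])
    lr = np.array([r.scores["LR"] for r in records])
    sr = np.array([r.scores["SR"] for r in records])
    dist = np.array([r.pair.distance_px for r in records])

    if hr.std() == 0 or sr.std() == 0:
        corr = None
    else:
        corr = float(np.corrcoef(hr, sr)[0, 1])

    bins: dict[str, dict] = {}
    for lo in range(0, int(dist.max()) + bin_width, bin_width):
        sel = (dist >= lo) & (dist < lo + bin_width)
        if not sel.any():
            continue
        bins[f"{lo}-{lo + bin_width}px"] = {
            "n": int(sel.sum()),
            "mean_HR": float(hr[sel].mean()),
            "mean_LR": float(lr[sel].mean()),
            "mean_SR": float(sr[sel].mean()),
        }
    return {
        "n_pairs": len(records),
        "frac_sr_ge_lr": float(np.mean(sr >= lr)),
        "frac_sr_gt_lr": float(np.mean(sr > lr)),
        "corr_hr_sr": corr,
        "median_HR": float(np.median(hr)),
        "median_LR": float(np.median(lr)),
        "median_SR": float(np.median(sr)),
        "distance_bins": bins,
    }


def _greedy_match(cand: np.ndarray, truth: np.ndarray, tol_px: float) -> int:
    """Greedy nearest-first one-to-one matching; returns the match count."""
    if len(cand) == 0 or len(truth) == 0:
        return 0
    tree = cKDTree(truth)
    # all candidate-truth pairs within tolerance, nearest first
    pairs = []
    for i, pt in enumerate(cand):
        for j in tree.query_ball_point(pt, tol_px):
            d = float(np.hypot(*(pt - truth[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    n = 0
    for _, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        n += 1
    return n


def reliability(
    lr: Spectrum2D,
    sr: Spectrum2D,
    truth: Spectrum2D,
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.10),
    truth_threshold: float = 0.005,
    tol_px: float = 2.0,
) -> pd.DataFrame:
    """Threshold-sweep reliability of SR peaks against a ground-truth grid.

    Truth peaks are picked at ``truth_threshold`` on the higher-resolution
    ground-truth spectrum.  For each detection threshold, LR and SR peaks
    are picked, their coordinates scaled to the truth grid, and matched to
    truth greedily within ``tol_px``.  The gained-peak fraction is the
    share of the additional SR detections (beyond the LR count) accounted
    for by additional true-positive matches; with no LR peaks it is
    computed over all SR peaks.
    """
    truth_peaks = pick_peaks(truth, truth_threshold)
    t_coords = np.array([[p.row, p.col] for p in truth_peaks], dtype=np.float64)
    th, tw = truth.shape
    rows = []
    for thr in thresholds:
        row: dict = {"threshold": thr, "n_truth": len(truth_peaks)}
        counts = {}
        matches = {}
        for name, spec in (("lr", lr), ("sr", sr)):
            peaks = pick_peaks(spec, thr)
            h, w = spec.shape
            coords = np.array(
                [[p.row * th / h, p.col * tw / w] for p in peaks], dtype=np.float64
            ).reshape(-1, 2)
            counts[name] = len(peaks)
            matches[name] = _greedy_match(coords, t_coords, tol_px)
        additional = counts["sr"] - counts["lr"]
        gained = max(matches["sr"] - matches["lr"], 0)
        if additional > 0:
            frac = min(gained / additional, 1.0)
        else:
            frac = 0.0
        row.update(
            lr_detected=counts["lr"], sr_detected=counts["sr"],
            lr_matched=matches["lr"], sr_matched=matches["sr"],
            additional_sr=additional, gained_matched=gained,
            gained_fraction=frac,
        )
        rows.append(row)
    return pd.DataFrame(rows)
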