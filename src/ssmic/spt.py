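"""Single-particle tracking of immune complexes in time-lapse stacks.

Detection (difference-of-Gaussians with subpixel refinement), LAP linking
with gap closing, track filtering, time-averaged mean-squared displacement,
power-law (anomalous diffusion) fitting, instantaneous speeds, and
kymographs.

The mobility model is MSD(tau) = 4 D tau^alpha for diffusion in the
membrane plane: alpha = 1 is Brownian motion, alpha < 1 subdiffusion
(confinement), alpha > 1 superdiffusion (directed transport).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionFit",
    "detect",
    "link",
    "filter_tracks",
    "msd",
    "ensemble_msd",
    "fit_alpha",
    "instantaneous_speeds",
    "straightness",
    "kymograph",
]


@dataclass
class Trajectory:
    """Time-ordered subpixel particle positions.

    frames are integer acquisition indices (strictly increasing; missing
    frames are gaps bridged by the linker); positions are (x, y) in um.
    """

    frames: np.ndarray
    positions: np.ndarray
    frame_time: float = 0.050
    intensities: np.ndarray | None = None
    track_id: int = -1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n, 2) matching frames")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def gaps(self) -> np.ndarray:
        """True where the step *into* this localization skipped frames."""
        g = np.zeros(len(self.frames), dtype=bool)
        g[1:] = np.diff(self.frames) > 1
        return g


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory (or an ensemble average)."""

    lags: np.ndarray       # s
    msd: np.ndarray        # um^2
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class DiffusionFit:
    """Power-law fit MSD = 4 D tau^alpha on log-log axes."""

    alpha: float
    D_apparent: float      # um^2/s
    fit_lags: int
    r_squared: float

    def __post_init__(self):
        if self.fit_lags < 2:
            raise ValueError("need at least 2 lags for a power-law fit")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _gauss2d(coords, A, x0, y0, s, off):
    x, y = coords
    return (A * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s ** 2)) + off).ravel()


def _refine_subpixel(frame: np.ndarray, peak, window: int = 7):
    """2D Gaussian fit in a window around the peak; center-of-mass fallback."""
    h = window // 2
    r, c = peak
    r0, r1 = max(r - h, 0), min(r + h + 1, frame.shape[0])
    c0, c1 = max(c - h, 0), min(c + h + 1, frame.shape[1])
    patch = frame[r0:r1, c0:c1].astype(float)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    try:
        p0 = (patch.max() - patch.min(), c, r, 1.5, patch.min())
        popt, _ = optimize.curve_fit(_gauss2d, (xx, yy), patch.ravel(), p0=p0, maxfev=800)
        x0, y0 = popt[1], popt[2]
        if not (c0 - 1 <= x0 <= c1 and r0 - 1 <= y0 <= r1):
            raise RuntimeError("fit center escaped window")
        return x0, y0
    except (RuntimeError, ValueError):
        w = np.clip(patch - patch.min(), 0, None)
        tot = w.sum()
        if tot == 0:
            return float(c), float(r)
        return float((w * xx).sum() / tot), float((w * yy).sum() / tot)


def detect(frame: np.ndarray, dog_sigma1: float = 3.0, dog_sigma2: float = 1.5,
           threshold: float | None = None, pixel_size: float = 0.110,
           min_distance: int = 3):
    """Detect diffraction-limited spots in one frame.

    A difference-of-Gaussians filter (sigma_1 = 3.0, sigma_2 = 1.5 pixels)
    suppresses background; local maxima above ``threshold`` (default:
    mean + 4 sd of the DoG response) are refined to subpixel precision by a
    2D Gaussian fit.  Returns an (n, 3) array of (x_um, y_um, intensity).
    """
    if dog_sigma1 <= 0 or dog_sigma2 <= 0:
        raise ValueError("DoG sigmas must be positive")
    img = np.asarray(frame, dtype=float)
    if img.size and img.max() > 0 and np.mean(img == img.max()) > 0.01:
        warnings.warn("frame appears saturated; localization may be biased")
    lo, hi = min(dog_sigma1, dog_sigma2), max(dog_sigma1, dog_sigma2)
    dog = ndimage.gaussian_filter(img, lo) - ndimage.gaussian_filter(img, hi)
    if threshold is None:
        # robust noise-referenced default so bright spots do not inflate it
        med = np.median(dog)
        mad = np.median(np.abs(dog - med))
        threshold = float(med + 4.0 * 1.4826 * mad)
        if threshold <= 0:
            return np.empty((0, 3))
    peaks = peak_local_max(dog, min_distance=min_distance, threshold_abs=threshold,
                           exclude_border=False)
    out = np.empty((len(peaks), 3))
    for i, (r, c) in enumerate(peaks):
        x, y = _refine_subpixel(img, (r, c))
        out[i] = (x * pixel_size, y * pixel_size, img[r, c])
    return out


# ---------------------------------------------------------------------------
# LAP linking
# ---------------------------------------------------------------------------

def _lap_match(costs: np.ndarray, alt_cost: float):
    """Solve a LAP with birth/death alternatives; return matched (i, j) pairs.

    The cost matrix is augmented with diagonal blocks of ``alt_cost`` so
    that any particle may instead start or terminate a track, the standard
    construction for frame-to-frame LAP tracking.
    """
    n, m = costs.shape
    if n == 0 or m == 0:
        return []
    big = 1e12
    top = np.hstack([costs, np.full((n, n), big)])
    np.fill_diagonal(top[:, m:], alt_cost)
    bot = np.hstack([np.full((m, m), big), costs.T * 0.0])
    np.fill_diagonal(bot[:, :m], alt_cost)
    full = np.vstack([top, bot])
    rows, cols = optimize.linear_sum_assignment(full)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m]


def link(detections, max_link: float = 0.5, gap_close: float = 0.25,
         max_gap: int = 2, frame_time: float = 0.050):
    """Link per-frame detections into trajectories.

    Two-pass linear-assignment (LAP) linking: frame-to-frame assignment with
    squared-displacement cost under a ``max_link`` distance cap, then a gap
    closing pass joining track ends to later track starts within
    ``gap_close`` um and at most ``max_gap`` missing frames.  Defaults match
    membrane-bound IC tracking (500 nm link, 250 nm gap close, 2 frames).

    Parameters
    ----------
    detections : dict or sequence
        Mapping frame -> (n, >=2) array of (x_um, y_um[, intensity]), or a
        sequence indexed by frame.
    """
    if not isinstance(detections, dict):
        detections = {i: d for i, d in enumerate(detections)}
    frames = sorted(detections)
    dets = {f: np.asarray(detections[f], dtype=float).reshape(-1, np.asarray(detections[f]).shape[-1] if np.asarray(detections[f]).size else 2)
            for f in frames}

    # pass 1: frame-to-frame
    segments = []          # each: list of (frame, x, y, intensity)
    active = {}            # index in previous frame -> segment index
    prev_f = None
    for f in frames:
        cur = dets[f]
        new_active = {}
        if prev_f is not None and f == prev_f + 1 and len(cur) and active:
            prev_idx = list(active)
            prev_xy = np.array([segments[active[i]][-1][1:3] for i in prev_idx])
            d2 = ((prev_xy[:, None, :] - cur[None, :, :2]) ** 2).sum(-1)
            d2[d2 > max_link ** 2] = 1e12
            for r, c in _lap_match(d2, alt_cost=max_link ** 2):
                if d2[r, c] <= max_link ** 2:
                    seg = active[prev_idx[r]]
                    inten = cur[c, 2] if cur.shape[1] > 2 else np.nan
                    segments[seg].append((f, cur[c, 0], cur[c, 1], inten))
                    new_active[c] = seg
        for c in range(len(cur)):
            if c not in new_active:
                inten = cur[c, 2] if cur.shape[1] > 2 else np.nan
                segments.append([(f, cur[c, 0], cur[c, 1], inten)])
                new_active[c] = len(segments) - 1
        active, prev_f = new_active, f

    # pass 2: gap closing between segment ends and starts
    ends = np.array([s[-1][:3] for s in segments])    # frame, x, y
    starts = np.array([s[0][:3] for s in segments])
    n = len(segments)
    if n:
        cost = np.full((n, n), 1e12)
        for i in range(n):
            dt = starts[:, 0] - ends[i, 0] - 1          # missing frames
            d2 = ((starts[:, 1:3] - ends[i, 1:3]) ** 2).sum(-1)
            ok = (dt >= 1) & (dt <= max_gap) & (d2 <= gap_close ** 2)
            cost[i, ok] = d2[ok]
        pairs = [(r, c) for r, c in _lap_match(cost, alt_cost=gap_close ** 2)
                 if cost[r, c] < 1e11]
        # merge chains end->start
        succ = dict(pairs)
        merged_into = set(succ.values())
        order = [i for i in range(n) if i not in merged_into]
        chains = []
        for i in order:
            chain = list(segments[i])
            j = i
            while j in succ:
                j = succ[j]
                chain.extend(segments[j])
            chains.append(chain)
    else:
        chains = []

    out = []
    for tid, chain in enumerate(chains):
        arr = np.array(chain)
        out.append(Trajectory(frames=arr[:, 0].astype(int),
                              positions=arr[:, 1:3], frame_time=frame_time,
                              intensities=arr[:, 3], track_id=tid))
    return out


def straightness(traj: Trajectory) -> float:
    """Net displacement over path length; 1 for a perfectly straight track."""
    steps = np.diff(traj.positions, axis=0)
    path = np.sum(np.linalg.norm(steps, axis=1))
    if path == 0:
        return 0.0
    net = np.linalg.norm(traj.positions[-1] - traj.positions[0])
    return float(net / path)


def filter_tracks(trajectories, min_length: int = 10,
                  linearity_cutoff: float = 0.9):
    """Keep tracks with >= ``min_length`` localizations and drop linear ones.

    Linear (high-straightness) trajectories correspond to actively
    transported, internalized complexes and are excluded from the membrane
    mobility analysis.
    """
    kept = [t for t in trajectories
            if len(t) >= min_length and straightness(t) <= linearity_cutoff]
    if trajectories and not kept:
        warnings.warn("all tracks removed by filtering")
    return kept


# ---------------------------------------------------------------------------
# MSD and diffusion fitting
# ---------------------------------------------------------------------------

def msd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all ordered position pairs at each lag.

    Gap frames simply contribute no pairs at the affected lags; lags with
    zero pairs are omitted.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 localizations")
    frames, pos = traj.frames, traj.positions
    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = span
    max_lag = min(max_lag, span)
    # frame-indexed position grid with NaN at gap frames
    grid = np.full((span + 1, 2), np.nan)
    grid[frames - frames[0]] = pos
    lags, vals, npairs = [], [], []
    for lag in range(1, max_lag + 1):
        d = grid[lag:] - grid[:-lag]
        sq = np.einsum("ij,ij->i", d, d)
        cnt = int(np.sum(~np.isnan(sq)))
        if cnt:
            lags.append(lag * traj.frame_time)
            vals.append(float(np.nansum(sq) / cnt))
            npairs.append(cnt)
    return MSDCurve(np.array(lags), np.array(vals), np.array(npairs))


def ensemble_msd(msd_curves, max_lag: int | None = None) -> MSDCurve:
    """Average per-trajectory MSD curves lag-by-lag (unweighted mean).

    Condition-level curves are means of per-trajectory time-averaged MSDs,
    so each trajectory contributes equally regardless of length.
    """
    from collections import defaultdict
    acc, cnt = defaultdict(float), defaultdict(int)
    for c in msd_curves:
        for lag, m in zip(c.lags, c.msd):
            acc[round(float(lag), 9)] += m
            cnt[round(float(lag), 9)] += 1
    lags = sorted(acc)
    if max_lag is not None:
        lags = lags[:max_lag]
    return MSDCurve(np.array(lags), np.array([acc[l] / cnt[l] for l in lags]),
                    np.array([cnt[l] for l in lags]))


def fit_alpha(msd_curves, n_lags: int = 10, mode: str = "ensemble"):
    """Fit MSD = 4 D tau^alpha by least squares on log-log axes.

    ``ensemble`` mode averages per-trajectory MSD curves and fits one line
    over the first ``n_lags`` lags; ``per_track`` returns a list of fits.
    The slope is alpha and the intercept log(4 D).
    """
    if isinstance(msd_curves, MSDCurve):
        msd_curves = [msd_curves]
    if mode == "per_track":
        return [fit_alpha([c], n_lags=n_lags, mode="ensemble") for c in msd_curves]
    if mode != "ensemble":
        raise ValueError("mode must be 'ensemble' or 'per_track'")

    curve = ensemble_msd(msd_curves) if len(msd_curves) > 1 else msd_curves[0]
    sel = slice(0, n_lags)
    lags, vals = curve.lags[sel], curve.msd[sel]
    good = vals > 0
    lags, vals = lags[good], vals[good]
    if len(lags) < 2:
        raise ValueError("fewer than 2 usable (positive) MSD lags")
    lx, ly = np.log(lags), np.log(vals)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(alpha=float(slope), D_apparent=float(np.exp(intercept) / 4.0),
                        fit_lags=len(lags), r_squared=float(r2))


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """|dr|/dt per consecutive frame pair, um/s; gap steps excluded."""
    if len(traj) < 2:
        raise ValueError("need at least 2 localizations")
    df = np.diff(traj.frames)
    disp = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    keep = df == 1
    return disp[keep] / (df[keep] * traj.frame_time)


def kymograph(time_stack: np.ndarray, path: np.ndarray, width: int = 1,
              spacing: float = 1.0) -> np.ndarray:
    """Sample intensity along a polyline per frame -> (position, time) image.

    ``path`` is an (m, 2) polyline in (x, y) pixel coordinates; samples are
    taken every ``spacing`` pixels by bilinear interpolation; ``width`` > 1
    averages that many samples across the perpendicular direction.
    """
    stack = np.asarray(time_stack, dtype=float)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise ValueError("path must be an (m>=2, 2) polyline")
    if (path[:, 0].min() < 0 or path[:, 1].min() < 0
            or path[:, 0].max() > stack.shape[2] - 1
            or path[:, 1].max() > stack.shape[1] - 1):
        raise ValueError("path lies outside the image")

    # resample the polyline at uniform arc length
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0], np.cumsum(seglen)])
    s = np.arange(0, arclen[-1] + 1e-9, spacing)
    xs = np.interp(s, arclen, path[:, 0])
    ys = np.interp(s, arclen, path[:, 1])

    # perpendicular offsets for width averaging
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(width) - (width - 1) / 2.0

    kymo = np.empty((len(s), stack.shape[0]))
    for t in range(stack.shape[0]):
        acc = np.zeros(len(s))
        for o in offsets:
            coords = np.vstack([ys + o * ny, xs + o * nx])
            acc += ndimage.map_coordinates(stack[t], coords, order=1, mode="nearest")
        kymo[:, t] = acc / width
    return kymo
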