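"""Synthetic ground-truth data for every pipeline stage.

Each generator emulates one class of raw data from the study — two-channel
z-stacks of filamentous actin plus immune-complex (IC) spots, 2D switching-
diffusion trajectories, rendered time-lapse movies, AFM force-indentation
curves, SSM-B cell contact movies, and NF-kB (p65) translocation images —
and returns machine-readable ground truth sufficient to score the matching
analysis stage.  All generators are bit-reproducible under a fixed seed.

Physical conventions follow the imaging setup: 110 nm pixels, 0.5 um
z-steps, 50 ms frames for particle tracking, 20 s frames for cell-scale
live imaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import ForceCurve, IndenterModel
from .imgproc import ImageStack
from .spt import Trajectory

__all__ = [
    "SpotFieldTruth",
    "SwitchingModel",
    "ForceCurveTruth",
    "make_spot_filament_stack",
    "simulate_trajectories",
    "render_movie",
    "make_force_curve",
    "make_contact_movie",
    "make_nfkb_cell",
]


# ---------------------------------------------------------------------------
# Spot-on-filament phantoms (enrichment-ratio ground truth)
# ---------------------------------------------------------------------------

@dataclass
class SpotFieldTruth:
    """Ground truth for a spot/filament phantom.

    intensity_on_fraction is the fraction of total spot intensity carried
    by spots whose centers lie on the filament mask — the quantity the
    enrichment ratio R estimates.
    """

    spot_centers: np.ndarray       # (n, 3) x, y, z in um
    spot_intensities: np.ndarray   # photons per spot
    on_actin_flags: np.ndarray     # bool per spot
    filament_mask: np.ndarray      # (z, y, x) boolean voxel mask
    intensity_on_fraction: float

    @property
    def filament_mask_2d(self) -> np.ndarray:
        return self.filament_mask.any(axis=0)


def _random_filament_image(shape, n_filaments, rng, turn_sd=0.15):
    """Random smoothed walks dilated to ~3 px width, binarized at half max.

    Walk length is kept moderate so the ridges stay sparse curvilinear
    structures (a few percent of the field), as dorsal ruffles are.
    """
    ny, nx = shape
    canvas = np.zeros(shape)
    points = []
    n_steps = int(0.55 * (ny + nx))
    for i in range(n_filaments):
        # start positions stratified in angle about the field center so the
        # ruffle network covers the whole dorsal surface, as on a cell
        phi = 2 * np.pi * (i + rng.uniform(0.1, 0.9)) / n_filaments
        r0 = rng.uniform(0.15, 0.35) * min(ny, nx)
        y = np.clip(ny / 2 + r0 * np.sin(phi), 0.1 * ny, 0.9 * ny)
        x = np.clip(nx / 2 + r0 * np.cos(phi), 0.1 * nx, 0.9 * nx)
        theta = phi + np.pi / 2 + rng.normal(0, 0.5)
        for _ in range(n_steps):
            theta += rng.normal(0, turn_sd)
            y += np.sin(theta)
            x += np.cos(theta)
            if not (3 <= y < ny - 3 and 3 <= x < nx - 3):
                theta += np.pi  # bounce back into the field
                y = np.clip(y, 3, ny - 4)
                x = np.clip(x, 3, nx - 4)
                continue
            canvas[int(round(y)), int(round(x))] = 1.0
            points.append((int(round(y)), int(round(x))))
    if canvas.max() == 0:
        raise RuntimeError("filament rendering produced an empty image")
    # constant-amplitude ridge profile: Gaussian of the distance to the walk,
    # giving uniform brightness along the filament and ~3 px width at half max
    dist = ndimage.distance_transform_edt(canvas == 0)
    profile = np.exp(-dist ** 2 / (2 * 1.1 ** 2))
    mask = profile > 0.5
    ridge = [(y, x) for y, x in points if mask[y, x]]
    return profile, mask, ridge


def _place_spots(mask, ridge, n_on, n_off, rng, min_sep=7, off_margin=5,
                 off_band=18):
    """Spot centers: on-spots at ridge-center pixels, off-spots >= margin away.

    Off-spots are kept within ``off_band`` px of the filament network so
    that on- and off-populations share the same coarse spatial density, as
    ICs do on the ruffled dorsal surface.
    """
    dist = ndimage.distance_transform_edt(~mask)
    placed = []

    def far_enough(y, x):
        return all((y - py) ** 2 + (x - px) ** 2 >= min_sep ** 2 for py, px in placed)

    on_pts, off_pts = [], []
    ridge_idx = rng.permutation(len(ridge))
    for i in ridge_idx:
        if len(on_pts) == n_on:
            break
        y, x = ridge[i]
        if far_enough(y, x):
            on_pts.append((y, x))
            placed.append((y, x))
    if len(on_pts) < n_on:
        raise RuntimeError("could not place all on-filament spots; "
                           "increase field size or filament count")
    ny, nx = mask.shape
    tries = 0
    while len(off_pts) < n_off:
        tries += 1
        if tries > 50000:
            raise RuntimeError("could not place all off-filament spots")
        # jitter a ridge point sideways so off-spot density tracks the
        # filament network density across the cell surface
        yr, xr = ridge[int(rng.integers(len(ridge)))]
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(off_margin + 1, off_band)
        y = int(round(yr + rad * np.sin(ang)))
        x = int(round(xr + rad * np.cos(ang)))
        if not (4 <= y < ny - 4 and 4 <= x < nx - 4):
            continue
        if off_margin <= dist[y, x] <= off_band and far_enough(y, x):
            off_pts.append((y, x))
            placed.append((y, x))
    return on_pts, off_pts


def _add_gaussian_spot(plane, x_px, y_px, sigma, total):
    """Accumulate an integrated-intensity ``total`` Gaussian at subpixel position."""
    ny, nx = plane.shape
    h = int(np.ceil(4 * sigma))
    r0, r1 = max(int(y_px) - h, 0), min(int(y_px) + h + 1, ny)
    c0, c1 = max(int(x_px) - h, 0), min(int(x_px) + h + 1, nx)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    g = np.exp(-((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2 * sigma ** 2))
    plane[r0:r1, c0:c1] += total * g / (2 * np.pi * sigma ** 2)


def make_spot_filament_stack(shape=(9, 256, 256), n_spots=50, on_fraction=None,
                             snr=5.0, seed=0, pixel_size=0.110, z_step=0.5,
                             n_filaments=6, background=20.0, psf_sigma=1.5,
                             intensity_cv_sigma=0.3):
    """Two-channel z-stack: filaments (ch 0) + diffraction-limited spots (ch 1).

    Filaments are random curvilinear ridges ~3 px wide, in focus at the
    central z-slice and progressively defocused away from it; spots are
    Gaussian-PSF blobs (sigma ~1.5 px) at the focal plane, a stated fraction
    of whose total intensity lies on the filament mask.  Spot photon budgets
    are drawn log-normally (sigma 0.3) around a mean set by ``snr`` to mimic
    IC size heterogeneity.  Poisson noise is applied to both channels.

    Returns ``(ImageStack, SpotFieldTruth)``.
    """
    nz, ny, nx = shape
    if nz <= 0 or ny <= 0 or nx <= 0:
        raise ValueError("stack shape must be positive")
    if n_spots == 0:
        if on_fraction is not None:
            raise ValueError("on_fraction is meaningless with zero spots")
        on_fraction_eff = None
    else:
        on_fraction_eff = 0.5 if on_fraction is None else float(on_fraction)
        if not 0 <= on_fraction_eff <= 1:
            raise ValueError("on_fraction must lie in [0, 1]")
    if snr <= 0:
        raise ValueError("snr must be positive")

    rng = np.random.default_rng(seed)
    fil_img, mask2d, ridge = _random_filament_image((ny, nx), n_filaments, rng)

    z_focus = nz // 2
    # peak amplitude A with Poisson peak SNR = A / sqrt(A + background)
    amp_mean = 0.5 * (snr ** 2 + np.sqrt(snr ** 4 + 4 * snr ** 2 * background))

    # spot placement and intensity budget
    if n_spots > 0:
        f = on_fraction_eff
        if f == 1.0:
            n_on = n_spots
        elif f == 0.0:
            n_on = 0
        else:
            n_on = int(np.clip(round(f * n_spots), 1, n_spots - 1))
        n_off = n_spots - n_on
        on_pts, off_pts = _place_spots(mask2d, ridge, n_on, n_off, rng)
        pts = on_pts + off_pts
        flags = np.array([True] * n_on + [False] * n_off)
        amps = amp_mean * np.exp(rng.normal(0, intensity_cv_sigma, n_spots))
        intens = amps * 2 * np.pi * psf_sigma ** 2
        # rescale the two groups so the on-intensity fraction is exact
        total = intens.sum()
        s_on, s_off = intens[flags].sum(), intens[~flags].sum()
        if 0 < f < 1:
            intens[flags] *= f * total / s_on
            intens[~flags] *= (1 - f) * total / s_off
        centers_px = np.array([(x, y) for y, x in pts], dtype=float)
    else:
        flags = np.zeros(0, dtype=bool)
        intens = np.zeros(0)
        centers_px = np.zeros((0, 2))

    # render channels; filaments defocus away from the focal slice
    fil_peak = 2.0 * amp_mean
    pixels = np.zeros((2, nz, ny, nx))
    sigma_z_spot = 0.7  # slices
    for s in range(nz):
        dz = s - z_focus
        blur = 0.5 + 1.2 * abs(dz)
        fil_w = np.exp(-dz ** 2 / (2 * 1.0 ** 2))
        pixels[0, s] = background + fil_peak * fil_w * ndimage.gaussian_filter(fil_img, blur)
        plane = np.zeros((ny, nx))
        spot_w = np.exp(-dz ** 2 / (2 * sigma_z_spot ** 2))
        if spot_w > 1e-3:
            for (x, y), inten in zip(centers_px, intens):
                _add_gaussian_spot(plane, x, y, psf_sigma, inten * spot_w)
        pixels[1, s] = background + plane
    pixels = rng.poisson(pixels).astype(float)

    mask3d = np.zeros((nz, ny, nx), dtype=bool)
    for s in range(nz):
        if np.exp(-(s - z_focus) ** 2 / 2.0) > 0.5:
            mask3d[s] = mask2d

    centers_um = np.column_stack([
        centers_px[:, 0] * pixel_size,
        centers_px[:, 1] * pixel_size,
        np.full(len(centers_px), z_focus * z_step),
    ]) if len(centers_px) else np.zeros((0, 3))
    frac = float(intens[flags].sum() / intens.sum()) if intens.sum() > 0 else float("nan")

    stack = ImageStack(pixels, pixel_size=pixel_size, z_step=z_step,
                       channel_names=["filament", "ic"])
    truth = SpotFieldTruth(centers_um, intens, flags, mask3d, frac)
    return stack, truth


# ---------------------------------------------------------------------------
# Switching-diffusion trajectories
# ---------------------------------------------------------------------------

@dataclass
class SwitchingModel:
    """K-state switching-diffusion model for membrane-bound particles.

    Each hidden state k has diffusion constant D[k] (um^2/s); the stationary
    weights pi give the initial state distribution and T is the per-frame
    row-stochastic transition matrix.  An optional reflecting circular
    boundary of ``confinement_radius`` um around each trajectory's origin
    produces subdiffusive (alpha < 1) ensemble MSDs.
    """

    D: np.ndarray
    pi: np.ndarray | None = None
    T: np.ndarray | None = None
    confinement_radius: float | None = None
    frame_time: float = 0.050

    def __post_init__(self):
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        if np.any(self.D < 0):
            raise ValueError("diffusion constants must be >= 0")
        k = len(self.D)
        if self.pi is None:
            self.pi = np.full(k, 1.0 / k)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if self.T is None:
            self.T = np.eye(k)
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (k, k) or not np.allclose(self.T.sum(axis=1), 1.0):
            raise ValueError("T must be a row-stochastic (K, K) matrix")

    @property
    def n_states(self) -> int:
        return len(self.D)


def simulate_trajectories(model: SwitchingModel, n_traj: int, n_frames: int,
                          loc_noise_sd: float = 0.0, seed: int = 0):
    """Simulate 2D switching-diffusion trajectories with known state labels.

    Each step from frame t to t+1 is an isotropic 2D Gaussian displacement
    with total variance 4 D_k dt (i.e. 2 D_k dt per axis) in the hidden
    state k active at frame t; states evolve by the transition matrix T.
    Localization noise of sd ``loc_noise_sd`` um per axis is added
    independently at every frame.

    Returns ``(trajectories, labels)`` where labels has shape
    ``(n_traj, n_frames - 1)`` giving the state of each step.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if loc_noise_sd < 0:
        raise ValueError("loc_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    k = model.n_states
    dt = model.frame_time
    step_sd = np.sqrt(2.0 * model.D * dt)   # per axis

    # hidden state paths, vectorized across trajectories
    labels = np.empty((n_traj, n_frames - 1), dtype=int)
    cum_T = np.cumsum(model.T, axis=1)
    state = (rng.random(n_traj)[:, None] > np.cumsum(model.pi)[None, :]).sum(axis=1)
    for t in range(n_frames - 1):
        labels[:, t] = state
        u = rng.random(n_traj)
        state = (u[:, None] > cum_T[state]).sum(axis=1)

    steps = rng.normal(0.0, 1.0, (n_traj, n_frames - 1, 2)) * step_sd[labels][:, :, None]
    if model.confinement_radius is None:
        pos = np.concatenate([np.zeros((n_traj, 1, 2)), np.cumsum(steps, axis=1)],
                             axis=1)
    else:
        r = model.confinement_radius
        pos = np.zeros((n_traj, n_frames, 2))
        for t in range(n_frames - 1):
            nxt = pos[:, t] + steps[:, t]
            # radial fold-back at the reflecting boundary about each origin
            dist = np.linalg.norm(nxt, axis=1)
            over = dist > r
            while over.any():
                scale = (2 * r - dist[over]) / dist[over]
                nxt[over] *= scale[:, None]
                dist = np.linalg.norm(nxt, axis=1)
                over = dist > r
            pos[:, t + 1] = nxt
    if loc_noise_sd > 0:
        pos = pos + rng.normal(0, loc_noise_sd, pos.shape)

    frames = np.arange(n_frames)
    trajectories = [Trajectory(frames=frames.copy(), positions=pos[i],
                               frame_time=dt, track_id=i)
                    for i in range(n_traj)]
    return trajectories, labels


def render_movie(trajectories, shape=(64, 64), pixel_size=0.110, psf_sigma=1.5,
                 photon_rate=500.0, background=10.0, bleach=None, noise=True,
                 seed=0, offset_um=None):
    """Render trajectories into a time-lapse stack with Gaussian PSF spots.

    Spots are drawn at subpixel positions each frame with integrated
    intensity ``photon_rate`` photons (optionally decayed by a per-frame
    ``bleach`` factor to exercise photobleach correction); Poisson noise is
    applied unless ``noise=False``.  Trajectory coordinates are in um with
    an optional global ``offset_um`` shift into the field of view;
    positions outside the field are clipped with a warning.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_frames = int(max(t.frames.max() for t in trajectories)) + 1 if trajectories else 0
    if offset_um is None:
        offset_um = np.zeros(2)
    offset_um = np.asarray(offset_um, dtype=float)

    clipped = False
    movie = np.full((n_frames, ny, nx), float(background))
    for traj in trajectories:
        for f, p in zip(traj.frames, traj.positions):
            x_px = (p[0] + offset_um[0]) / pixel_size
            y_px = (p[1] + offset_um[1]) / pixel_size
            if not (0 <= x_px < nx and 0 <= y_px < ny):
                clipped = True
                x_px = np.clip(x_px, 0, nx - 1)
                y_px = np.clip(y_px, 0, ny - 1)
            amp = photon_rate * (bleach ** f if bleach is not None else 1.0)
            _add_gaussian_spot(movie[f], x_px, y_px, psf_sigma, amp)
    if clipped:
        warnings.warn("some trajectory positions fell outside the field of view "
                      "and were clipped")
    if noise:
        movie = rng.poisson(movie).astype(float)
    frame_time = trajectories[0].frame_time if trajectories else 0.050
    return ImageStack(movie[None], pixel_size=pixel_size, frame_time=frame_time,
                      channel_names=["ic"])


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

@dataclass
class ForceCurveTruth:
    """Ground truth for one synthetic force-indentation curve."""

    E_true: float            # Pa
    contact_index: int       # sample index of the contact point
    baseline_slope: float = 0.0   # N/m of pre-contact drift
    noise_sd: float = 0.0         # N of force noise

    def __post_init__(self):
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")


def make_force_curve(truth: ForceCurveTruth, indenter: IndenterModel | None = None,
                     ramp_size: float = 5.0, n_samples: int = 500, seed: int = 0,
                     spring_constant: float = 0.03, ramp_speed: float = 10.0) -> ForceCurve:
    """Synthesize an AFM approach curve from the pyramidal contact model.

    Pre-contact deflection is baseline (plus optional linear drift and
    noise); past the contact point the cantilever deflection d solves
    ``k d = c tan(theta) E/(1-nu^2) ((z - z0) - d)^2`` so that the recorded
    curve is exactly consistent with the forward model at ``E_true``.
    """
    if ramp_size <= 0:
        raise ValueError("ramp_size must be positive")
    if truth.contact_index >= n_samples:
        raise ValueError("contact_index beyond curve length")
    if indenter is None:
        indenter = IndenterModel()
    rng = np.random.default_rng(seed)

    z_um = np.linspace(0.0, ramp_size, n_samples)
    z0_um = z_um[truth.contact_index]
    k = spring_constant                      # N/m
    C = indenter.prefactor * truth.E_true    # N/m^2 multiplying delta^2 (SI)

    u = np.clip(z_um - z0_um, 0, None) * 1e-6   # m
    # solve C (u - d)^2 = k d for d (take the physical root d < u)
    disc = (2 * C * u + k) ** 2 - 4 * C ** 2 * u ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(u > 0, (2 * C * u + k - np.sqrt(disc)) / (2 * C), 0.0)
    d_um = d * 1e6

    drift_um = truth.baseline_slope * (z_um * 1e-6) / k * 1e6
    noise_um = rng.normal(0, truth.noise_sd / k, n_samples) * 1e6 if truth.noise_sd > 0 else 0.0
    deflection = d_um + drift_um + noise_um
    return ForceCurve(z_um=z_um, deflection_um=deflection, spring_constant=k,
                      ramp_size=ramp_size, ramp_speed=ramp_speed,
                      meta={"E_true": truth.E_true, "contact_index": truth.contact_index})


# ---------------------------------------------------------------------------
# SSM-B cell contact movies
# ---------------------------------------------------------------------------

def make_contact_movie(contact_intervals, speeds=None, n_frames: int = 80,
                       shape=(160, 160), pixel_size: float = 0.325,
                       frame_interval: float = 20.0, footprint_radius: float = 5.0,
                       cell_radius: float = 3.0, approach_gap: float = 1.0,
                       background: float = 20.0, cell_photons: float = 4000.0,
                       max_link: float = 7.0, noise: bool = True, seed: int = 0):
    """Two-channel movie of B cells contacting a static SSM footprint.

    ``contact_intervals`` is one list of non-overlapping inclusive
    ``(start_frame, end_frame)`` intervals per cell.  During a contact
    interval a cell's centroid sits inside the SSM footprint (a disk of
    ``footprint_radius`` um at the field center); outside contact it stays
    beyond the footprint dilated by one cell radius plus ``approach_gap``
    so the contact classification is unambiguous.  Inter-frame steps are
    kept below the linking cap; a user-specified crawl speed exceeding the
    cap triggers a warning.

    Returns ``(ImageStack, truth)`` where truth records per-cell centroid
    paths (um), the contact intervals, the footprint mask, and calibration.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    center = np.array([nx * pixel_size / 2.0, ny * pixel_size / 2.0])
    n_cells = len(contact_intervals)
    if speeds is None:
        speeds = [0.15] * n_cells           # um per frame while parked
    for s in speeds:
        if s > max_link:
            warnings.warn("crawl speed exceeds the linking radius; tracks may split")

    # parked just beyond the contact zone (footprint + one cell radius),
    # close enough that the entry/exit step stays under the linking cap
    r_out = footprint_radius + cell_radius + approach_gap
    r_in = min(footprint_radius - 1.5, footprint_radius * 0.6)
    wander = min(1.0, cell_radius)

    paths = np.zeros((n_cells, n_frames, 2))
    for ci, intervals in enumerate(contact_intervals):
        ivs = sorted(intervals)
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if c <= b:
                raise ValueError("contact intervals must be non-overlapping per cell")
        contact = np.zeros(n_frames, dtype=bool)
        for a, b in ivs:
            if not (0 <= a <= b < n_frames):
                raise ValueError("contact interval outside the movie")
            contact[a:b + 1] = True
        # approach directions stratified so cells keep separate sectors
        phi = 2 * np.pi * (ci + rng.uniform(0.25, 0.75)) / max(n_cells, 1)
        ray = np.array([np.cos(phi), np.sin(phi)])
        perp = np.array([-ray[1], ray[0]])
        s_park = 0.0
        for t in range(n_frames):
            if contact[t]:
                wob = 0.3 * np.array([np.cos(0.7 * t), np.sin(0.7 * t)])
                paths[ci, t] = center + ray * r_in + wob
            else:
                s_park += speeds[ci]
                paths[ci, t] = center + ray * r_out + perp * (s_park % wander)

    # render: channel 0 = cells (Cal-520), channel 1 = SSM footprint
    yy, xx = np.mgrid[0:ny, 0:nx]
    xum, yum = xx * pixel_size, yy * pixel_size
    rr = np.hypot(xum - center[0], yum - center[1])
    footprint = rr <= footprint_radius
    ssm_plane = background + 150.0 / (1 + np.exp((rr - footprint_radius) / 0.3))

    sigma_px = cell_radius / 1.7 / pixel_size
    movie = np.zeros((2, n_frames, ny, nx))
    for t in range(n_frames):
        plane = np.full((ny, nx), float(background))
        for ci in range(n_cells):
            _add_gaussian_spot(plane, paths[ci, t, 0] / pixel_size,
                               paths[ci, t, 1] / pixel_size, sigma_px, cell_photons)
        movie[0, t] = plane
        movie[1, t] = ssm_plane
    if noise:
        movie = rng.poisson(movie).astype(float)

    stack = ImageStack(movie, pixel_size=pixel_size, frame_time=frame_interval,
                       channel_names=["cells", "ssm"])
    truth = {
        "paths_um": paths,
        "contact_intervals": [sorted(iv) for iv in contact_intervals],
        "footprint_mask": footprint,
        "footprint_center_um": center,
        "footprint_radius_um": footprint_radius,
        "cell_radius_um": cell_radius,
        "frame_interval_s": frame_interval,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# NF-kB translocation phantoms
# ---------------------------------------------------------------------------

def make_nfkb_cell(ratio: float, noise: float = 0.0, shape=(96, 96),
                   cell_radius: int = 32, nucleus_radius: int = 13,
                   base_intensity: float = 100.0, seed: int = 0):
    """Cell phantom with a prescribed nuclear/cytosolic p65 intensity ratio.

    The nucleus (disk) lies strictly inside the cell (concentric disk);
    nuclear mean intensity / cytosolic mean intensity equals ``ratio``
    before noise.  With ratio 1 and no noise the image is uniform.

    Returns ``(image, nucleus_mask, cell_mask, ratio)``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if nucleus_radius >= cell_radius:
        raise ValueError("nucleus mask must lie strictly inside the cell mask")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - ny / 2.0, xx - nx / 2.0)
    cell = rr <= cell_radius
    nucleus = rr <= nucleus_radius
    image = np.full(shape, base_intensity, dtype=float)
    image[nucleus] = ratio * base_intensity
    if noise > 0:
        image = image + rng.normal(0, noise * base_intensity, shape)
    return image, nucleus, cell, float(ratio)
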