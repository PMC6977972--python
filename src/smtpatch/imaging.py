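"""Synthetic single-molecule movies: emitters, optics and EMCCD camera.

Generates ground-truth trajectories of sparse membrane-bound emitters
(Poisson appearance, gamma/exponential/fixed residence, photobleaching,
2D Brownian motion) and renders them into realistic image stacks:
pixel-integrated Gaussian PSF on a constant fluorescent background,
followed by EMCCD photon shot noise, electron-multiplication excess noise
and Gaussian read noise, digitized to camera counts.

The camera defaults are the printed constants of the Andor iXon used for
the real recordings (read noise 88.8 e-, noise factor 1.41, 49 e-/count,
EM gain 167, AD offset 105 counts); the optics default to 178 nm pixels
and a 160 nm PSF sigma, and frames are 0.1 s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "OpticsModel",
    "CameraModel",
    "EmitterSimParams",
    "TruthTrackSet",
    "ImageStack",
    "generate_truth_tracks",
    "expected_photon_map",
    "apply_emccd_noise",
    "render_movie",
]


@dataclass(frozen=True)
class OpticsModel:
    """Imaging geometry: pixel pitch and PSF width, both in nm."""

    pixel_size: float = 178.0
    psf_sigma: float = 160.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")


@dataclass(frozen=True)
class CameraModel:
    """EMCCD constants (electrons, counts) used for rendering and noise."""

    read_noise_e: float = 88.8
    noise_factor: float = 1.41
    electrons_per_count: float = 49.0
    em_gain: float = 167.0
    ad_offset: float = 105.0

    def __post_init__(self) -> None:
        for name in ("read_noise_e", "noise_factor", "electrons_per_count", "em_gain", "ad_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def counts_per_photon(self) -> float:
        return self.em_gain / self.electrons_per_count


@dataclass(frozen=True)
class EmitterSimParams:
    """Emitter kinetics and photon budget for a synthetic movie.

    Defaults emulate the sparse-labeling operating regime of the real
    recordings: ~0.1 s frames, residence of order 1-2 s (gamma dwell
    kinetics), diffusion in the 500-4000 nm^2/s band, photobleaching at
    ~0.15 s^-1, and a photon budget placing spots comfortably above the
    detection threshold (peak SNR ~ 5).
    """

    field_size: int = 64
    duration: float = 20.0
    frame_interval: float = 0.1
    birth_rate: float = 1.0
    residence_model: str = "gamma"   # gamma | exponential | fixed
    residence_shape: float = 2.0
    residence_scale: float = 1.0     # seconds (scale for gamma, mean for exp, value for fixed)
    diffusion_D: float = 3000.0      # nm^2/s
    bleach_rate: float = 0.15        # s^-1
    background_photons: float = 20.0  # photons / pixel / frame
    photons_per_frame: float = 400.0  # expected photons / emitter / frame
    pool_bleach_rate: float = 0.0     # s^-1 decay of the appearance rate
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame")
        if self.residence_model not in ("gamma", "exponential", "fixed"):
            raise ValueError("residence_model must be gamma, exponential or fixed")
        for name in ("birth_rate", "bleach_rate", "background_photons",
                     "photons_per_frame", "pool_bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.diffusion_D < 0:
            raise ValueError("diffusion_D must be >= 0")
        if self.field_size < 8:
            raise ValueError("field_size must be at least 8 pixels")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval + 1e-9))


@dataclass
class TruthTrackSet:
    """Ground-truth emitters and their per-frame positions (nm).

    ``emitters`` has one row per molecule (id, birth_time_s, residence_s,
    bleach_time_s, lifetime_s, end_cause, n_frames); ``positions`` one row
    per visible frame (id, frame, x_nm, y_nm).  A molecule is visible in a
    frame if it is alive at the frame midpoint.
    """

    emitters: pd.DataFrame
    positions: pd.DataFrame
    params: EmitterSimParams
    optics: OpticsModel

    @property
    def n_emitters(self) -> int:
        return len(self.emitters)


@dataclass
class ImageStack:
    """A rendered movie: (frames, H, W) uint16 counts plus metadata."""

    data: np.ndarray
    frame_interval: float
    optics: OpticsModel
    camera: CameraModel

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be a (frames, H, W) array")
        if np.any(self.data < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def save(self, path) -> None:
        meta = {
            "frame_interval_s": self.frame_interval,
            "optics": asdict(self.optics),
            "camera": asdict(self.camera),
        }
        tifffile.imwrite(path, self.data, description=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if data.ndim == 2:
            data = data[None]
        return cls(
            data=data,
            frame_interval=float(meta["frame_interval_s"]),
            optics=OpticsModel(**meta["optics"]),
            camera=CameraModel(**meta["camera"]),
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] by reflection at both walls."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def _draw_residence(params: EmitterSimParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.residence_model == "gamma":
        return rng.gamma(params.residence_shape, params.residence_scale, n)
    if params.residence_model == "exponential":
        return rng.exponential(params.residence_scale, n)
    return np.full(n, params.residence_scale)


def generate_truth_tracks(
    params: EmitterSimParams,
    optics: OpticsModel | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTrackSet:
    """Simulate ground-truth emitter appearances, motion and disappearance.

    Births follow a Poisson process at ``birth_rate`` over ``duration``;
    the observed lifetime is min(residence, bleach time ~ Exp(bleach_rate));
    positions take Brownian steps of per-axis variance 2 D dt between frame
    midpoints, reflecting at the field boundary.
    """
    optics = optics or OpticsModel()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    field_nm = params.field_size * optics.pixel_size
    dt = params.frame_interval
    n_frames = params.n_frames
    midpoints = (np.arange(n_frames) + 0.5) * dt

    # pool_bleach_rate > 0 emulates depletion of the labeled pool: the
    # appearance rate decays as exp(-k t), so spot counts per frame decay
    # at ~k, the signal the photobleach-rate estimator reads out.
    k = params.pool_bleach_rate
    if k > 0:
        mean_births = params.birth_rate * (1.0 - np.exp(-k * params.duration)) / k
        n_births = rng.poisson(mean_births)
        u = rng.uniform(0.0, 1.0, n_births)
        births = np.sort(
            -np.log(1.0 - u * (1.0 - np.exp(-k * params.duration))) / k
        )
    else:
        n_births = rng.poisson(params.birth_rate * params.duration)
        births = np.sort(rng.uniform(0.0, params.duration, n_births))
    residence = _draw_residence(params, n_births, rng)
    if params.bleach_rate > 0:
        bleach = rng.exponential(1.0 / params.bleach_rate, n_births)
    else:
        bleach = np.full(n_births, np.inf)
    lifetime = np.minimum(residence, bleach)
    cause = np.where(bleach < residence, "bleach", "unbind")

    em_rows = []
    pos_rows = []
    step_sd = np.sqrt(2.0 * params.diffusion_D * dt)
    for i in range(n_births):
        death = births[i] + lifetime[i]
        frames = np.nonzero((midpoints >= births[i]) & (midpoints < death))[0]
        nfr = frames.size
        if nfr > 0:
            x0 = rng.uniform(0.0, field_nm)
            y0 = rng.uniform(0.0, field_nm)
            dx = rng.normal(0.0, step_sd, nfr - 1) if nfr > 1 else np.empty(0)
            dy = rng.normal(0.0, step_sd, nfr - 1) if nfr > 1 else np.empty(0)
            xs = _reflect(x0 + np.concatenate(([0.0], np.cumsum(dx))), 0.0, field_nm)
            ys = _reflect(y0 + np.concatenate(([0.0], np.cumsum(dy))), 0.0, field_nm)
            pos_rows.append(
                pd.DataFrame({"id": i, "frame": frames, "x_nm": xs, "y_nm": ys})
            )
        em_rows.append(
            (i, births[i], residence[i], bleach[i], lifetime[i], cause[i], nfr)
        )

    emitters = pd.DataFrame(
        em_rows,
        columns=[
            "id", "birth_time_s", "residence_s", "bleach_time_s",
            "lifetime_s", "end_cause", "n_frames",
        ],
    )
    if pos_rows:
        positions = pd.concat(pos_rows, ignore_index=True)
    else:
        positions = pd.DataFrame(columns=["id", "frame", "x_nm", "y_nm"])
    return TruthTrackSet(emitters=emitters, positions=positions, params=params, optics=optics)


def _gaussian_pixel_integral(
    shape: tuple[int, int],
    x_nm: float,
    y_nm: float,
    optics: OpticsModel,
) -> np.ndarray:
    """Fraction of a unit 2D Gaussian integrated over each pixel.

    Pixel (r, c) covers [c-0.5, c+0.5] x [r-0.5, r+0.5] in pixel units;
    the origin sits at the center of the top-left pixel.
    """
    a = optics.pixel_size
    s = optics.psf_sigma / a
    cx = x_nm / a
    cy = y_nm / a
    h, w = shape
    # restrict to a window +/- 6 sigma around the emitter for speed
    r0 = max(int(np.floor(cy - 6 * s - 1)), 0)
    r1 = min(int(np.ceil(cy + 6 * s + 1)) + 1, h)
    c0 = max(int(np.floor(cx - 6 * s - 1)), 0)
    c1 = min(int(np.ceil(cx + 6 * s + 1)) + 1, w)
    out = np.zeros(shape)
    if r0 >= r1 or c0 >= c1:
        return out
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    sq2s = np.sqrt(2.0) * s
    fy = 0.5 * (erf((rows - cy + 0.5) / sq2s) - erf((rows - cy - 0.5) / sq2s))
    fx = 0.5 * (erf((cols - cx + 0.5) / sq2s) - erf((cols - cx - 0.5) / sq2s))
    out[r0:r1, c0:c1] = np.outer(fy, fx)
    return out


def expected_photon_map(
    truth: TruthTrackSet,
    frame: int,
    optics: OpticsModel | None = None,
    include_background: bool = True,
) -> np.ndarray:
    """Noise-free expected photons per pixel for one frame."""
    optics = optics or truth.optics
    params = truth.params
    shape = (params.field_size, params.field_size)
    photons = np.full(shape, params.background_photons if include_background else 0.0)
    field_nm = params.field_size * optics.pixel_size
    rows = truth.positions[truth.positions["frame"] == frame]
    for _, row in rows.iterrows():
        x, y = row["x_nm"], row["y_nm"]
        if not (0.0 <= x <= field_nm and 0.0 <= y <= field_nm):
            warnings.warn("emitter outside field; clipped to boundary")
            x = min(max(x, 0.0), field_nm)
            y = min(max(y, 0.0), field_nm)
        photons += params.photons_per_frame * _gaussian_pixel_integral(shape, x, y, optics)
    return photons


def apply_emccd_noise(
    photon_map: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator | int | None = None,
    digitize: bool = True,
) -> np.ndarray:
    """Convert expected photons/pixel into noisy camera counts.

    Poisson shot noise, then a variance-matched multiplicative spread
    reproducing the EM-register excess noise factor F (output variance
    F^2 g^2 n electrons^2 for n expected photons), then Gaussian read
    noise, conversion to counts and the AD offset.  With ``digitize`` the
    result is rounded and clipped to the 16-bit range, adding the usual
    1/12 counts^2 quantization variance.
    """
    photon_map = np.asarray(photon_map, dtype=float)
    if np.any(photon_map < 0):
        raise ValueError("photon_map must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = camera.em_gain
    e = camera.electrons_per_count
    f2 = camera.noise_factor**2
    k = rng.poisson(photon_map).astype(float)
    electrons = k * g
    if f2 > 1.0:
        electrons = electrons + rng.normal(0.0, g * np.sqrt((f2 - 1.0) * k))
    electrons = electrons + rng.normal(0.0, camera.read_noise_e, photon_map.shape)
    counts = camera.ad_offset + electrons / e
    if digitize:
        counts = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return counts


def render_movie(
    truth: TruthTrackSet,
    optics: OpticsModel | None = None,
    camera: CameraModel | None = None,
    noise: bool = True,
    rng: np.random.Generator | int | None = None,
) -> ImageStack:
    """Render a ground-truth track set into a camera-count image stack."""
    optics = optics or truth.optics
    camera = camera or CameraModel()
    params = truth.params
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    frames = []
    for f in range(params.n_frames):
        photons = expected_photon_map(truth, f, optics)
        if noise:
            frames.append(apply_emccd_noise(photons, camera, rng))
        else:
            counts = camera.ad_offset + photons * camera.counts_per_photon
            frames.append(np.clip(np.rint(counts), 0, 65535).astype(np.uint16))
    return ImageStack(
        data=np.stack(frames),
        frame_interval=params.frame_interval,
        optics=optics,
        camera=camera,
    )
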