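"""Simulated block-design fMRI datasets with two delayed activation foci.

The generator emulates a single-slice echo-planar acquisition of a block
paradigm: a boxcar task time course is convolved with a gamma-variate
hemodynamic response function (HRF) and used to modulate the baseline
intensity of two non-overlapping, Gaussian-smoothed regions of interest
(ROIs).  i.i.d. Gaussian noise is added on top, with a standard deviation
expressed as a fraction of the mean in-brain baseline intensity so that the
contrast-to-noise ratio CNR = dS / sigma is well defined.

Default parameters: 15 s ON / 15 s OFF blocks, TR = 3 s, 60 scans, 2 %
peak signal change, ~2 cm ROI diameter, 3 mm FWHM in-plane smoothing,
64 x 64 matrix with 3.75 mm voxels, and noise levels quoted as fractions
(0.33 %, ..., 1.33 %) of the mean baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass(frozen=True)
class HRFParams:
    """Gamma-variate HRF h(t) = k * t**shape * exp(-t/scale) for t >= 0.

    ``shape`` is dimensionless, ``scale`` is in seconds.  ``k`` only fixes an
    overall amplitude; sampled responses are renormalised to unit peak, so the
    peak percent signal change is carried entirely by :class:`ROISpec`.
    """

    k: float = 1.0
    shape: float = 8.60
    scale: float = 0.547

    def __post_init__(self) -> None:
        if self.k <= 0 or self.shape <= 0 or self.scale <= 0:
            raise ValueError("HRF parameters k, shape and scale must all be positive")


@dataclass(frozen=True)
class Paradigm:
    """Block paradigm: alternating ON/OFF epochs sampled every TR seconds."""

    on_duration: float = 15.0
    off_duration: float = 15.0
    total_duration: float = 180.0
    tr: float = 3.0

    def __post_init__(self) -> None:
        if self.on_duration + self.off_duration <= 0:
            raise ValueError("on_duration + off_duration must be positive")
        if self.total_duration <= 0 or self.tr <= 0:
            raise ValueError("total_duration and tr must be positive")
        n = self.total_duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_duration must be an integer multiple of tr")

    @property
    def n_scans(self) -> int:
        return int(round(self.total_duration / self.tr))


@dataclass(frozen=True)
class ROISpec:
    """A circular activation focus.

    ``center`` is in (row, col) voxel coordinates (floats allowed),
    ``diameter`` and ``smoothing_fwhm`` in millimetres, ``delay`` in seconds
    relative to task onset, ``peak_change`` as a fraction of baseline at the
    ROI centre.
    """

    center: tuple[float, float]
    diameter: float = 20.0
    smoothing_fwhm: float = 3.0
    delay: float = 0.0
    peak_change: float = 0.02

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.peak_change < 0:
            raise ValueError("peak_change must be non-negative")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


def default_rois(delay: float = 5.0, peak_change: float = 0.02) -> list[ROISpec]:
    """The standard two-ROI layout: symmetric foci, ROI #2 delayed by ``delay``."""
    return [
        ROISpec(center=(32.0, 21.0), delay=0.0, peak_change=peak_change),
        ROISpec(center=(32.0, 43.0), delay=delay, peak_change=peak_change),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    rois: tuple[ROISpec, ...] = tuple(default_rois())
    noise_sigma: float = 0.0033
    paradigm: Paradigm = Paradigm()
    hrf: HRFParams = HRFParams()
    grid_shape: tuple[int, int] = (64, 64)
    voxel_size: float = 3.75
    supersample_dt: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.grid_shape) != 2:
            raise ValueError("grid_shape must be 2D (a single slice is simulated)")
        if isinstance(self.rois, list):
            object.__setattr__(self, "rois", tuple(self.rois))


@dataclass
class ImageSequence:
    """A 4D-in-spirit (here: 2D slice x time) scalar field plus in-brain mask."""

    data: np.ndarray  # (*grid_shape, T)
    mask: np.ndarray  # (*grid_shape,) boolean
    tr: float

    def __post_init__(self) -> None:
        if self.data.shape[:-1] != self.mask.shape:
            raise ValueError("data spatial shape must match mask shape")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least two time points")
        if not self.mask.any():
            raise ValueError("mask selects no voxels")

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_matrix(self) -> np.ndarray:
        """Return the (T, N) data matrix over in-mask voxels (spatial ICA layout)."""
        return self.data[self.mask, :].T

    def save_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.eye(4)
        img = nib.Nifti1Image(self.data[:, :, None, :].astype(np.float32), affine)
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr))
        nib.save(img, str(path))


@dataclass
class GroundTruth:
    """Per-ROI weighted masks and activation time courses, plus the zero-delay
    reference response used as the GLM regressor / CTR template."""

    roi_masks: list[np.ndarray]  # each (*grid_shape,), values in [0, 1]
    roi_timecourses: list[np.ndarray]  # each (T,), unit peak
    expected_response: np.ndarray  # (T,), zero-delay boxcar (*) HRF

    def __post_init__(self) -> None:
        for m in self.roi_masks:
            if not (m > 0.5).any():
                raise ValueError("each ROI mask needs at least one voxel above 0.5")
        n = len(self.expected_response)
        if any(len(tc) != n for tc in self.roi_timecourses):
            raise ValueError("time courses must all have the same length")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import nibabel as nib

        for i, m in enumerate(self.roi_masks, start=1):
            nib.save(
                nib.Nifti1Image(m[:, :, None].astype(np.float32), np.eye(4)),
                str(out / f"roi{i}_mask.nii.gz"),
            )
        with open(out / "timecourses.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["scan", "expected_response"] + [f"roi{i}" for i in range(1, len(self.roi_timecourses) + 1)])
            for t in range(len(self.expected_response)):
                w.writerow([t, self.expected_response[t]] + [tc[t] for tc in self.roi_timecourses])


# ---------------------------------------------------------------------------
# elementary pieces


def gamma_hrf(t_grid: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the gamma-variate HRF on ``t_grid`` (seconds), unit peak.

    h(t) = k t^shape exp(-t/scale) for t >= 0 and 0 for t < 0; the samples are
    divided by their maximum so downstream amplitude scaling is explicit.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1:
        raise ValueError("t_grid must be one-dimensional")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    h = np.zeros_like(t)
    pos = t > 0
    h[pos] = params.k * t[pos] ** params.shape * np.exp(-t[pos] / params.scale)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def block_boxcar(paradigm: Paradigm, dt: float | None = None) -> np.ndarray:
    """Binary ON/OFF task indicator sampled every ``dt`` (default: TR) seconds.

    The run starts with an ON epoch at t = 0; sample i represents time i * dt.
    """
    if dt is None:
        dt = paradigm.tr
    n = paradigm.total_duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("total_duration must be an integer multiple of the sampling step")
    n = int(round(n))
    t = np.arange(n) * dt
    period = paradigm.on_duration + paradigm.off_duration
    return (np.mod(t, period) < paradigm.on_duration).astype(float)


def activation_timecourse(
    paradigm: Paradigm,
    hrf: HRFParams = HRFParams(),
    delay: float = 0.0,
    supersample_dt: float = 0.25,
) -> np.ndarray:
    """Task response at TR resolution: delayed boxcar convolved with the HRF.

    The boxcar and HRF are built on a supersampled grid (default 0.25 s) so
    that sub-TR onsets such as 1.25 s with TR = 3 s are represented exactly;
    ``delay`` must therefore be an integer multiple of ``supersample_dt``.
    The convolution is normalised to unit peak before the delay shift, so a
    delayed ROI keeps the same peak amplitude.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    shift = delay / supersample_dt
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(
            f"delay {delay} s is not representable on the {supersample_dt} s supersampled grid"
        )
    shift = int(round(shift))
    step = paradigm.tr / supersample_dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("tr must be an integer multiple of supersample_dt")
    step = int(round(step))

    box = block_boxcar(paradigm, dt=supersample_dt)
    t_hrf = np.arange(0.0, 32.0 + supersample_dt, supersample_dt)
    h = gamma_hrf(t_hrf, hrf)
    conv = np.convolve(box, h)[: len(box)]
    peak = conv.max()
    if peak > 0:
        conv = conv / peak
    if shift:
        conv = np.concatenate([np.zeros(shift), conv[:-shift]])
    return conv[::step][: paradigm.n_scans]


def roi_mask(
    spec: ROISpec,
    grid_shape: tuple[int, int] = (64, 64),
    voxel_size: float = 3.75,
) -> np.ndarray:
    """Weighted spatial map of one ROI: a binary disc smoothed with a 2D
    Gaussian kernel (sigma = FWHM / 2.3548, converted to voxels) and
    renormalised to unit maximum."""
    radius_vox = 0.5 * spec.diameter / voxel_size
    r0, c0 = spec.center
    if not (radius_vox <= r0 <= grid_shape[0] - 1 - radius_vox) or not (
        radius_vox <= c0 <= grid_shape[1] - 1 - radius_vox
    ):
        raise ValueError("ROI disc does not fit inside the grid")
    rr, cc = np.meshgrid(np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij")
    disc = ((rr - r0) ** 2 + (cc - c0) ** 2 <= radius_vox**2).astype(float)
    sigma_vox = spec.smoothing_fwhm * FWHM_TO_SIGMA / voxel_size
    if sigma_vox > 0:
        m = gaussian_filter(disc, sigma=sigma_vox, truncate=4.0)
    else:
        m = disc
    peak = m.max()
    if peak > 0:
        m = m / peak
    m[m < 1e-12] = 0.0
    return m


def make_phantom(
    grid_shape: tuple[int, int] = (64, 64),
    semi_axes: tuple[float, float] = (20.0, 26.0),
    base_intensity: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical 2D "brain" phantom: smooth radial intensity profile inside an
    ellipse, zero outside; returns (baseline image, boolean in-brain mask)."""
    rr, cc = np.meshgrid(np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij")
    cr, ccol = (grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0
    rho2 = ((rr - cr) / semi_axes[0]) ** 2 + ((cc - ccol) / semi_axes[1]) ** 2
    mask = rho2 <= 1.0
    baseline = np.where(mask, base_intensity * (1.0 - 0.4 * rho2), 0.0)
    return baseline, mask


def simulate(
    config: SimulationConfig,
    baseline: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ImageSequence, GroundTruth]:
    """Generate one dataset and its ground truth.

    data(v, t) = baseline(v) * (1 + sum_r peak_change_r * m_r(v) * tc_r(t)) + eps(v, t)

    with eps i.i.d. N(0, (noise_sigma * mean in-mask baseline)^2).  A user
    baseline image (plus mask) may replace the built-in elliptical phantom.
    Reproducible: the noise stream is derived from ``config.seed``.
    """
    if baseline is None:
        baseline, mask = make_phantom(config.grid_shape)
    if mask is None:
        mask = baseline > 0
    if baseline.shape != tuple(config.grid_shape):
        raise ValueError("baseline image shape must match grid_shape")

    masks = [roi_mask(r, config.grid_shape, config.voxel_size) for r in config.rois]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] * masks[j]).max() > 0:
                raise ValueError(f"ROI masks {i} and {j} overlap after smoothing")

    tcs = [
        activation_timecourse(config.paradigm, config.hrf, r.delay, config.supersample_dt)
        for r in config.rois
    ]
    expected = activation_timecourse(config.paradigm, config.hrf, 0.0, config.supersample_dt)

    T = config.paradigm.n_scans
    modulation = np.zeros(config.grid_shape + (T,))
    for r, m, tc in zip(config.rois, masks, tcs):
        modulation += r.peak_change * m[..., None] * tc[None, None, :]
    data = baseline[..., None] * (1.0 + modulation)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
        sigma = config.noise_sigma * baseline[mask].mean()
        data = data + rng.normal(0.0, sigma, size=data.shape)

    seq = ImageSequence(data=data, mask=mask.astype(bool), tr=config.paradigm.tr)
    truth = GroundTruth(roi_masks=masks, roi_timecourses=tcs, expected_response=expected)
    return seq, truth


def cnr(peak_change: float, noise_sigma: float) -> float:
    """Contrast-to-noise ratio CNR = dS / sigma (both as fractions of baseline)."""
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    return peak_change / noise_sigma


def config_for_cell(
    delay: float,
    noise_sigma: float,
    seed: int = 0,
    peak_change: float = 0.02,
) -> SimulationConfig:
    """Convenience: the standard two-ROI study configuration for one grid cell."""
    return SimulationConfig(
        rois=tuple(default_rois(delay=delay, peak_change=peak_change)),
        noise_sigma=noise_sigma,
        seed=seed,
    )
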