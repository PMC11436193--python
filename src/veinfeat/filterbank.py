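"""Construction of 2D Log-Gabor filter banks in the polar frequency domain.

A Log-Gabor filter is a band-pass filter whose radial transfer function is a
Gaussian on a *logarithmic* frequency axis.  Unlike a Gabor filter it has no
DC component and its octave bandwidth is unbounded, which makes it a good
model of the frequency response of visual cortical cells and a good detector
of curvilinear vascular texture.  The 2D filter is separable in polar
frequency coordinates::

    logG(r, theta) = exp(-(ln(r/f0))^2 / (2 (ln sigma_r)^2))       (radial)
                   * exp(-d(theta, theta0)^2 / (2 sigma_theta^2))  (angular)

where ``f0`` is the centre frequency (cycles/pixel), ``sigma_r`` in (0, 1)
sets the radial bandwidth (0.75 ~ 1 octave, 0.55 ~ 2 octaves), ``theta0`` is
the orientation of the angular lobe (wave-vector angle) and ``sigma_theta``
the angular bandwidth.  ``d`` is the wrapped angular difference, so the lobe
is continuous across the +/- pi seam.

Filters are built directly on the FFT frequency grid of the target image
shape and applied by frequency-domain multiplication, i.e. circular
convolution.  Only one angular lobe is kept (the transfer function is not
symmetrised about the origin), so spatial responses are complex; downstream
code uses their real part.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FilterBankConfig",
    "FrequencyGrid",
    "LogGaborFilter",
    "LogGaborBank",
    "wavelength_schedule",
    "center_frequency",
    "orientation_angles",
    "angular_sigma",
    "radial_transfer",
    "angular_transfer",
    "bandwidth_in_octaves",
    "frequency_grid",
    "build_filter",
    "build_bank",
]


@dataclass(frozen=True)
class FilterBankConfig:
    """Scalar parameters of the multi-scale / multi-orientation bank.

    Defaults follow the reference operating point for 32x32 vein ROIs:
    smallest wavelength 2 px (Nyquist), radial scaling 2.2, radial bandwidth
    ratio 0.55 (~2 octaves), 4 scales, 10 candidate orientations, angular
    scaling 1.3.
    """

    wmin: float = 2.0
    m_factor: float = 2.2
    t_factor: float = 1.3
    sigma_r: float = 0.55
    n_scales: int = 4
    n_orientations: int = 10
    image_shape: tuple[int, int] = (32, 32)

    def __post_init__(self) -> None:
        if self.wmin < 2:
            raise ValueError(
                f"wmin must be >= 2 px (Nyquist wavelength), got {self.wmin}"
            )
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("n_scales and n_orientations must be >= 1")
        if self.n_scales > 1 and self.m_factor < 1:
            raise ValueError("m_factor must be >= 1 when n_scales > 1")
        if not 0 < self.sigma_r < 1:
            raise ValueError(f"sigma_r must lie in (0, 1), got {self.sigma_r}")
        if self.t_factor <= 0:
            raise ValueError("t_factor must be positive")
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"invalid image_shape {self.image_shape}")


@dataclass(frozen=True)
class FrequencyGrid:
    """Per-pixel polar frequency coordinates of an FFT-ordered grid.

    ``radius`` is the normalized radial frequency in cycles/pixel
    (per-axis normalization, range [0, ~0.707]); ``angle`` the polar angle
    in (-pi, pi].  The DC bin carries radius 0 and is handled specially by
    :func:`build_filter`.
    """

    radius: np.ndarray
    angle: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.radius.shape


def frequency_grid(image_shape: tuple[int, int]) -> FrequencyGrid:
    """Polar FFT frequency grid for ``image_shape`` (DC at index [0, 0])."""
    rows, cols = image_shape
    v = np.fft.fftfreq(rows)[:, None]  # row (y) frequency
    u = np.fft.fftfreq(cols)[None, :]  # column (x) frequency
    radius = np.hypot(u, v)
    angle = np.arctan2(np.broadcast_to(v, (rows, cols)),
                       np.broadcast_to(u, (rows, cols)))
    return FrequencyGrid(radius=radius, angle=angle)


def wavelength_schedule(config: FilterBankConfig) -> list[float]:
    """Wavelengths (px) of the radial scales: ``wmin * m_factor**(S-1)``."""
    return [config.wmin * config.m_factor ** (s - 1)
            for s in range(1, config.n_scales + 1)]


def center_frequency(wavelength: float) -> float:
    """Centre frequency f0 = 1/wavelength (cycles/pixel)."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    return 1.0 / wavelength


def orientation_angles(n_orientations: int) -> list[float]:
    """Candidate lobe angles ``i * pi / n_orientations``, i = 0..n-1."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    return [i * math.pi / n_orientations for i in range(n_orientations)]


def angular_sigma(t_factor: float, n_orientations: int) -> float:
    """Angular bandwidth ``sigma_theta = t_factor * pi / n_orientations``."""
    if t_factor <= 0 or n_orientations < 1:
        raise ValueError("t_factor must be > 0 and n_orientations >= 1")
    return t_factor * math.pi / n_orientations


def radial_transfer(r: np.ndarray | float, f0: float,
                    sigma_r: float) -> np.ndarray | float:
    """Radial Log-Gabor response, Gaussian on a log frequency axis.

    Defined for r > 0 and forced to 0 at r = 0 (the filter has no DC
    component).  Peaks at 1 when r = f0.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    denom = 2.0 * math.log(sigma_r) ** 2
    out[pos] = np.exp(-np.log(r[pos] / f0) ** 2 / denom)
    if out.ndim == 0:
        return float(out)
    return out


def angular_transfer(theta: np.ndarray | float, theta0: float,
                     sigma_theta: float) -> np.ndarray | float:
    """Angular Gaussian lobe with wrapped difference, continuous across pi.

    The difference ``theta - theta0`` is wrapped into (-pi, pi] via
    atan2(sin, cos) so the lobe does not tear at the angular seam.
    """
    if sigma_theta <= 0:
        raise ValueError("sigma_theta must be positive")
    theta = np.asarray(theta, dtype=float)
    d = np.arctan2(np.sin(theta - theta0), np.cos(theta - theta0))
    out = np.exp(-(d ** 2) / (2.0 * sigma_theta ** 2))
    if out.ndim == 0:
        return float(out)
    return out


def bandwidth_in_octaves(sigma_r: float) -> float:
    """Half-amplitude bandwidth of the radial transfer, in octaves.

    Closed form ``2 sqrt(2 ln 2) |ln sigma_r| / ln 2``; e.g. sigma_r = 0.75
    gives ~0.98 octaves and 0.55 gives ~2.03 octaves.
    """
    if not 0 < sigma_r < 1:
        raise ValueError("sigma_r must lie in (0, 1)")
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * abs(math.log(sigma_r)) / math.log(2.0)


@dataclass(frozen=True)
class LogGaborFilter:
    """One frequency-domain transfer array with its polar metadata."""

    transfer: np.ndarray          # real-valued, FFT order, values in [0, 1]
    scale_index: int              # 1-based radial scale S
    wavelength: float             # px
    f0: float                     # cycles/px
    theta0: float                 # radians
    sigma_theta: float            # radians

    @property
    def shape(self) -> tuple[int, int]:
        return self.transfer.shape

    def spatial_kernel(self) -> np.ndarray:
        """Complex spatial-domain kernel (inverse FFT of the transfer)."""
        return np.fft.ifft2(self.transfer)


@dataclass(frozen=True)
class LogGaborBank:
    """Ordered collection of filters, scale-major then ascending theta0."""

    filters: tuple[LogGaborFilter, ...]
    config: FilterBankConfig

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)

    def __getitem__(self, i: int) -> LogGaborFilter:
        return self.filters[i]

    def at_scale(self, scale_index: int) -> list[LogGaborFilter]:
        """Filters of one 1-based radial scale, ascending theta0."""
        return [f for f in self.filters if f.scale_index == scale_index]

    def save(self, path: str | Path) -> None:
        """Write the bank to a zip archive of .npy arrays + JSON metadata."""
        path = Path(path)
        meta = {
            "config": {
                "wmin": self.config.wmin,
                "m_factor": self.config.m_factor,
                "t_factor": self.config.t_factor,
                "sigma_r": self.config.sigma_r,
                "n_scales": self.config.n_scales,
                "n_orientations": self.config.n_orientations,
                "image_shape": list(self.config.image_shape),
            },
            "filters": [
                {
                    "scale_index": f.scale_index,
                    "wavelength": f.wavelength,
                    "f0": f.f0,
                    "theta0": f.theta0,
                    "sigma_theta": f.sigma_theta,
                }
                for f in self.filters
            ],
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            for i, f in enumerate(self.filters):
                import io

                buf = io.BytesIO()
                np.save(buf, f.transfer)
                zf.writestr(f"transfer_{i:04d}.npy", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "LogGaborBank":
        path = Path(path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            cfg = meta["config"]
            config = FilterBankConfig(
                wmin=cfg["wmin"], m_factor=cfg["m_factor"],
                t_factor=cfg["t_factor"], sigma_r=cfg["sigma_r"],
                n_scales=cfg["n_scales"],
                n_orientations=cfg["n_orientations"],
                image_shape=tuple(cfg["image_shape"]),
            )
            filters = []
            for i, fm in enumerate(meta["filters"]):
                import io

                buf = io.BytesIO(zf.read(f"transfer_{i:04d}.npy"))
                transfer = np.load(buf)
                filters.append(LogGaborFilter(transfer=transfer, **fm))
        return cls(filters=tuple(filters), config=config)


def build_filter(config: FilterBankConfig, scale_index: int,
                 theta0: float,
                 grid: FrequencyGrid | None = None) -> LogGaborFilter:
    """Build one 2D Log-Gabor filter: radial x angular on the FFT grid.

    The DC bin is forced to zero (its radius is substituted before the log
    is taken, avoiding the singularity at the origin).
    """
    if not 1 <= scale_index <= config.n_scales:
        raise ValueError(f"scale_index {scale_index} out of range")
    if grid is None:
        grid = frequency_grid(config.image_shape)
    wavelength = config.wmin * config.m_factor ** (scale_index - 1)
    f0 = center_frequency(wavelength)
    sigma_theta = angular_sigma(config.t_factor, config.n_orientations)

    radius = grid.radius.copy()
    dc = radius == 0
    radius[dc] = 1.0  # dummy value; zeroed below
    radial = np.exp(-np.log(radius / f0) ** 2
                    / (2.0 * math.log(config.sigma_r) ** 2))
    angular = angular_transfer(grid.angle, theta0, sigma_theta)
    transfer = radial * angular
    transfer[dc] = 0.0
    return LogGaborFilter(
        transfer=transfer, scale_index=scale_index, wavelength=wavelength,
        f0=f0, theta0=float(theta0), sigma_theta=sigma_theta,
    )


def build_bank(config: FilterBankConfig) -> LogGaborBank:
    """Assemble the full candidate bank, n_scales x n_orientations filters.

    Ordering is scale-major (S = 1..n_scales), then ascending theta0.  The
    construction is fully deterministic in the config.
    """
    grid = frequency_grid(config.image_shape)
    thetas = orientation_angles(config.n_orientations)
    filters = tuple(
        build_filter(config, s, th, grid=grid)
        for s in range(1, config.n_scales + 1)
        for th in thetas
    )
    return LogGaborBank(filters=filters, config=config)
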