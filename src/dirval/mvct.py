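"""kVCT -> MVCT image-quality transform and noise-power-spectrum tools.

The transform has three steps: (a) in-plane pre-smoothing of the image,
(b) dynamic-range scaling through a monotone kVCT->MVCT intensity curve, and
(c) injection of spectrally shaped noise.  The noise model starts from a
Gaussian white-noise image mask (GWNIM, sigma = ``sigma_frac`` x a reference
intensity scale), splits it into its positive- and negative-definite parts,
shapes each part in frequency space with the amplitude filter derived from a
measured radial NPS, recombines positive minus negative, and finally blurs
the noise pattern with a small Gaussian to soften the salt-and-pepper look.
A fresh pattern is drawn for every CT slice; realizations differ only in
their noise seeds.

The NPS itself is estimated from two consecutive scans of a uniform phantom
section: the scaled difference image cancels the deterministic anatomy, and
mean-subtracted ROI periodograms ``NPS = dx*dy/(Nx*Ny) * |DFT|^2`` are
averaged over ROIs and slices, then radially binned.  With this convention
the integral of the NPS over the 2D frequency plane equals the noise
variance (Parseval), so units are HU^2 mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import GeometryError, Image3D

__all__ = [
    "RadialNPS",
    "MVCTParams",
    "estimate_nps",
    "synth_noise_slice",
    "kv_to_mv_intensity",
    "make_mvct",
    "gaussian_mtf_power",
]


@dataclass(frozen=True)
class RadialNPS:
    """Radially averaged noise power spectrum.

    freq: radial spatial frequency bin centres, mm^-1, strictly increasing
    and bounded by the Nyquist frequency of the estimation grid.
    power: noise power per bin, HU^2 mm^2, non-negative.
    """

    freq: np.ndarray
    power: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freq.ndim != 1 or freq.shape != power.shape:
            raise ValueError("freq and power must be matching 1D arrays")
        if np.any(np.diff(freq) <= 0):
            raise ValueError("freq bins must be strictly increasing")
        nyquist = 0.5 / min(self.pixel_spacing)
        if freq[-1] > nyquist + 1e-9:
            raise ValueError(f"freq exceeds Nyquist {nyquist:.4g} mm^-1")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "power", power)

    def interp_power(self, f: np.ndarray) -> np.ndarray:
        """Power at arbitrary radial frequencies (clamped at the bin ends)."""
        return np.interp(np.abs(f), self.freq, self.power)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"freq_mm^-1": self.freq, "power_HU2mm2": self.power}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, pixel_spacing=(1.0, 1.0)) -> "RadialNPS":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            freq=df["freq_mm^-1"].to_numpy(),
            power=df["power_HU2mm2"].to_numpy(),
            pixel_spacing=tuple(pixel_spacing),
        )


@dataclass(frozen=True)
class MVCTParams:
    """Knobs of the kVCT->MVCT quality transform.

    sigma_frac: GWNIM sigma as a fraction of ``ref_scale_hu`` (default 0.04,
    i.e. 4% of the 1000 HU water-to-air range -> 40 HU pre-filtering).
    smooth_noise_px: Gaussian blur applied to the *noise pattern* (pixels).
    presmooth_px: in-plane Gaussian applied to the anatomy before remapping.
    intensity_curve: monotone (kv_hu, mv_hu) control points; None = identity.
    """

    sigma_frac: float = 0.04
    smooth_noise_px: float = 0.5
    presmooth_px: float = 0.7
    intensity_curve: tuple[tuple[float, float], ...] | None = None
    n_realizations: int = 3
    seed: int = 0
    ref_scale_hu: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma_frac <= 0:
            raise ValueError("sigma_frac must be positive")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.intensity_curve is not None:
            _validate_curve(self.intensity_curve)


def _validate_curve(curve) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("intensity curve needs >= 2 (kv, mv) control points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("curve kv values must be strictly increasing")
    if np.any(np.diff(y) < 0):
        raise ValueError("curve mv values must be monotone non-decreasing")
    return x, y


# ---------------------------------------------------------------------------
# NPS estimation
# ---------------------------------------------------------------------------


def estimate_nps(
    scan1: Image3D,
    scan2: Image3D,
    roi_size: int = 32,
    roi_positions: list[tuple[int, int]] | None = None,
    slices: list[int] | None = None,
    n_bins: int | None = None,
) -> RadialNPS:
    """Estimate the radial NPS from two aligned scans of a uniform region.

    ``roi_positions`` are in-plane upper-left corners of square ROIs of side
    ``roi_size`` pixels (default: a centred 2x2 tiling); ``slices`` selects z
    indices (default all).  Fewer than 2 ROI x slice samples raises a high-
    variance warning.
    """
    if not scan1.grid.same_geometry(scan2.grid, tol=1e-6):
        raise GeometryError("NPS scans must share one grid")
    nx, ny, nz = scan1.grid.size
    dx, dy = scan1.grid.spacing[0], scan1.grid.spacing[1]
    if roi_positions is None:
        cx, cy = nx // 2, ny // 2
        roi_positions = [
            (cx - roi_size, cy - roi_size),
            (cx, cy - roi_size),
            (cx - roi_size, cy),
            (cx, cy),
        ]
    for i0, j0 in roi_positions:
        if i0 < 0 or j0 < 0 or i0 + roi_size > nx or j0 + roi_size > ny:
            raise GeometryError(f"ROI at {(i0, j0)} leaves the volume")
    if slices is None:
        slices = list(range(nz))
    if len(roi_positions) * len(slices) < 2:
        import warnings

        warnings.warn("fewer than 2 ROI samples: NPS estimate has high variance")

    diff = (scan1.values - scan2.values) / np.sqrt(2.0)
    acc = np.zeros((roi_size, roi_size))
    count = 0
    for k in slices:
        for i0, j0 in roi_positions:
            patch = diff[i0 : i0 + roi_size, j0 : j0 + roi_size, k]
            patch = patch - patch.mean()
            acc += np.abs(np.fft.fft2(patch)) ** 2
            count += 1
    nps2d = acc / count * (dx * dy) / (roi_size * roi_size)

    fx = np.fft.fftfreq(roi_size, d=dx)
    fy = np.fft.fftfreq(roi_size, d=dy)
    fr = np.hypot(*np.meshgrid(fx, fy, indexing="ij"))
    nyquist = 0.5 / max(dx, dy)
    if n_bins is None:
        n_bins = roi_size // 2
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    flat = nps2d.ravel()
    fr_flat = fr.ravel()
    keep = fr_flat > 0  # DC is forced to zero by mean subtraction: exclude it
    which = np.digitize(fr_flat[keep], edges) - 1
    flat = flat[keep]
    freq_list, power_list = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            freq_list.append(0.5 * (edges[b] + edges[b + 1]))
            power_list.append(flat[sel].mean())
    return RadialNPS(
        freq=np.asarray(freq_list), power=np.asarray(power_list), pixel_spacing=(dx, dy)
    )


# ---------------------------------------------------------------------------
# Noise synthesis
# ---------------------------------------------------------------------------


def _amplitude_filter(
    shape: tuple[int, int], nps: RadialNPS, spacing: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS amplitude filter H(f) = sqrt(NPS(|f|)) / rms over the plane.

    The unit-RMS normalization preserves total noise power (a flat NPS gives
    the identity filter), so ``sigma_frac`` keeps its meaning as the output
    noise scale.
    """
    fx = np.fft.fftfreq(shape[0], d=spacing[0])
    fy = np.fft.fftfreq(shape[1], d=spacing[1])
    fr = np.hypot(*np.meshgrid(fx, fy, indexing="ij"))
    h = np.sqrt(nps.interp_power(fr))
    rms = np.sqrt(np.mean(h**2))
    if rms == 0:
        raise ValueError("all-zero NPS gives a degenerate filter")
    return h / rms


def synth_noise_slice(
    shape: tuple[int, int],
    nps: RadialNPS,
    params: MVCTParams,
    seed,
    spacing: tuple[float, float] | None = None,
) -> np.ndarray:
    """Synthesize one 2D MVCT-quality noise pattern (HU).

    Procedure: draw the GWNIM with sigma = sigma_frac x ref_scale_hu; split
    into positive and negative definite parts; DFT each part; multiply by the
    normalized amplitude filter; inverse DFT; recombine positive minus
    negative; blur with a Gaussian of ``smooth_noise_px`` pixels.
    Deterministic for a given seed.
    """
    if spacing is None:
        spacing = nps.pixel_spacing
    rng = np.random.default_rng(seed)
    sigma = params.sigma_frac * params.ref_scale_hu
    white = rng.normal(0.0, sigma, size=shape)
    h = _amplitude_filter(tuple(shape), nps, tuple(spacing))
    pos = np.maximum(white, 0.0)
    neg = np.maximum(-white, 0.0)
    pos_f = np.fft.ifft2(np.fft.fft2(pos) * h).real
    neg_f = np.fft.ifft2(np.fft.fft2(neg) * h).real
    noise = pos_f - neg_f
    if params.smooth_noise_px > 0:
        noise = ndimage.gaussian_filter(noise, params.smooth_noise_px, mode="wrap")
    return noise


def kv_to_mv_intensity(img: Image3D, curve) -> Image3D:
    """Piecewise-linear HU remap through monotone control points, clamped at
    the curve endpoints."""
    x, y = _validate_curve(curve)
    return Image3D(grid=img.grid, values=np.interp(img.values, x, y))


def gaussian_mtf_power(freq: np.ndarray, sigma_px: float, spacing_mm: float) -> np.ndarray:
    """Squared MTF of a Gaussian blur of ``sigma_px`` pixels at radial
    frequency ``freq`` (mm^-1) — the factor the blur multiplies an NPS by."""
    sigma_mm = sigma_px * spacing_mm
    return np.exp(-((2.0 * np.pi * sigma_mm * np.asarray(freq)) ** 2))


def make_mvct(kvct: Image3D, nps: RadialNPS, params: MVCTParams) -> list[Image3D]:
    """Produce ``n_realizations`` MVCT-quality volumes from a kVCT volume.

    Each realization shares the deterministic part (presmoothed, remapped
    anatomy) and receives an independent, freshly seeded noise pattern per CT
    slice; realization r uses base seed ``params.seed + r``.
    """
    base = kvct.values
    if params.presmooth_px > 0:
        base = ndimage.gaussian_filter(
            base, (params.presmooth_px, params.presmooth_px, 0.0), mode="nearest"
        )
    if params.intensity_curve is not None:
        x, y = _validate_curve(params.intensity_curve)
        base = np.interp(base, x, y)
    nx, ny, nz = kvct.grid.size
    spacing = (kvct.grid.spacing[0], kvct.grid.spacing[1])
    out = []
    for r in range(params.n_realizations):
        vol = base.copy()
        for k in range(nz):
            noise = synth_noise_slice(
                (nx, ny), nps, params, seed=[params.seed + r, k], spacing=spacing
            )
            vol[:, :, k] += noise
        out.append(Image3D(grid=kvct.grid, values=vol))
    return out
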