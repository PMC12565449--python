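"""Hand-crafted multi-scale texture radiomics.

The nodule is filtered in-plane with Laplacian-of-Gaussian (LoG) band-pass
kernels at spatial scales (SSF) of 2-6 mm; SSF = 0 means no filtration.
The closed form sampled at integer pixel offsets is

    LoG(x, y) = -1/(pi sigma^4) (1 - (x^2+y^2)/(2 sigma^2))
                exp(-(x^2+y^2)/(2 sigma^2)),

with sigma in pixels (sigma_mm / in-plane spacing).  Kernels are truncated
at radius ceil(4 sigma) and shifted by a constant to sum exactly to zero,
which makes them band-pass: a constant image responds with zero and adding
a constant HU offset to the volume leaves every filtered feature unchanged.

For each scale, responses at all in-mask voxels of all nodule-bearing
slices are pooled into one sample over which six first-order statistics are
computed — Mean, SD (population), Entropy (base-2 Shannon entropy of a
64-bin histogram over the sample range), MPP (mean of strictly positive
values), Skewness and excess Kurtosis (population moments).  Filtration is
two-dimensional per slice, matching the 2-D closed form, while the
statistics are volumetric by pooling voxels across slices.  The flattened
vector is SSF-major, statistic-minor: 6 scales x 6 statistics = 36 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .dataio import CTVolume, NoduleMask

__all__ = [
    "SSF_VALUES", "STATISTIC_NAMES", "FEATURE_NAMES",
    "LoGKernel", "RadiomicVector", "log_closed_form", "build_log_kernel",
    "filter_slice", "histogram_stats", "extract_radiomics",
]

SSF_VALUES = (0, 2, 3, 4, 5, 6)            # mm; 0 = no filtration
STATISTIC_NAMES = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")
FEATURE_NAMES = tuple(f"ssf{s}_{stat}" for s in SSF_VALUES
                      for stat in STATISTIC_NAMES)
ENTROPY_BINS = 64


def log_closed_form(x, y, sigma: float):
    """The analytic LoG at offsets (x, y) for scale ``sigma`` (pixels)."""
    r2 = np.asarray(x, dtype=np.float64) ** 2 + np.asarray(y, dtype=np.float64) ** 2
    return (-1.0 / (np.pi * sigma**4)
            * (1.0 - r2 / (2.0 * sigma**2))
            * np.exp(-r2 / (2.0 * sigma**2)))


@dataclass
class LoGKernel:
    sigma_mm: float
    sigma_px: float
    raw: np.ndarray      # closed-form samples
    kernel: np.ndarray   # zero-sum (band-pass) weights
    truncation_radius_px: int

    def __post_init__(self):
        k = self.kernel
        assert k.shape[0] == k.shape[1] and k.shape[0] % 2 == 1
        assert abs(k.sum()) <= 1e-12


def build_log_kernel(sigma_mm: float, in_plane_spacing_mm: float) -> LoGKernel:
    """Sample the closed form on a (2R+1)^2 grid, R = ceil(4 sigma_px), then
    shift by a constant so the weights sum to zero."""
    if sigma_mm <= 0 or in_plane_spacing_mm <= 0:
        raise ValueError("sigma and spacing must be positive")
    sigma_px = sigma_mm / in_plane_spacing_mm
    if sigma_px < 0.5:
        raise ValueError(
            f"scale below resolution: sigma {sigma_mm} mm is {sigma_px:.2f} px "
            f"at {in_plane_spacing_mm} mm spacing"
        )
    radius = int(np.ceil(4.0 * sigma_px))
    offsets = np.arange(-radius, radius + 1)
    raw = log_closed_form(offsets[:, None], offsets[None, :], sigma_px)
    kernel = raw - raw.mean()
    kernel -= kernel.sum() / kernel.size  # second pass kills rounding residue
    return LoGKernel(sigma_mm=float(sigma_mm), sigma_px=float(sigma_px),
                     raw=raw, kernel=kernel, truncation_radius_px=radius)


def filter_slice(slice_hu: np.ndarray, kernel: LoGKernel | None) -> np.ndarray:
    """2-D convolution with reflective boundary handling.

    ``kernel=None`` is the SSF = 0 case: the raw HU slice is returned.
    """
    sl = np.asarray(slice_hu, dtype=np.float64)
    if sl.ndim != 2:
        raise ValueError("filter_slice expects a 2-D slice")
    if kernel is None:
        return sl.copy()
    k = kernel.kernel
    if k.shape[0] > min(sl.shape):
        raise ValueError(
            f"kernel {k.shape} larger than slice {sl.shape}"
        )
    r = kernel.truncation_radius_px
    padded = np.pad(sl, r, mode="symmetric")
    # kernel is point-symmetric, so convolution equals correlation
    return fftconvolve(padded, k, mode="valid")


@dataclass
class Stats:
    mean: float
    sd: float
    entropy: float
    mpp: float
    skewness: float
    kurtosis: float
    flags: list[str] = field(default_factory=list)

    def as_tuple(self):
        return (self.mean, self.sd, self.entropy, self.mpp,
                self.skewness, self.kurtosis)


def histogram_stats(values: np.ndarray) -> Stats:
    """Six first-order statistics of a 1-D sample (population moments)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in sample")
    flags: list[str] = []
    mean = float(v.mean())
    sd = float(v.std())  # population SD

    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        hist, _ = np.histogram(v, bins=ENTROPY_BINS, range=(vmin, vmax))
        p = hist[hist > 0] / v.size
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0

    pos = v[v > 0]
    if pos.size:
        mpp = float(pos.mean())
    else:
        mpp = 0.0
        flags.append("mpp_no_positive")

    if sd > 0:
        z = (v - mean) / sd
        skewness = float((z**3).mean())
        kurtosis = float((z**4).mean() - 3.0)
    else:
        skewness = kurtosis = 0.0
        flags.append("zero_sd_moments")

    return Stats(mean=mean, sd=sd, entropy=entropy, mpp=mpp,
                 skewness=skewness, kurtosis=kurtosis, flags=flags)


@dataclass
class RadiomicVector:
    case_id: str
    values: np.ndarray                 # (36,), FEATURE_NAMES order
    flags: dict[str, list[str]] = field(default_factory=dict)
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite radiomic features")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def extract_radiomics(volume: CTVolume, mask: NoduleMask,
                      ssf_values=SSF_VALUES) -> RadiomicVector:
    """Pooled-voxel multi-scale statistics over the nodule region."""
    mask.validate_against(volume)
    _, dy, dx = volume.spacing_mm
    if abs(dy - dx) > 0.01 * max(dy, dx):
        raise ValueError(
            f"anisotropic in-plane spacing ({dy}, {dx}) beyond 1% tolerance"
        )
    slice_hits = np.flatnonzero(
        mask.mask.reshape(mask.mask.shape[0], -1).any(axis=1))

    values, flag_map = [], {}
    for ssf in ssf_values:
        kernel = None if ssf == 0 else build_log_kernel(float(ssf), dx)
        pooled = []
        for idx in slice_hits:
            filt = filter_slice(volume.voxels[idx], kernel)
            pooled.append(filt[mask.mask[idx].astype(bool)])
        stats = histogram_stats(np.concatenate(pooled))
        values.extend(stats.as_tuple())
        if stats.flags:
            flag_map[f"ssf{ssf}"] = stats.flags
    names = tuple(f"ssf{s}_{stat}" for s in ssf_values
                  for stat in STATISTIC_NAMES)
    return RadiomicVector(case_id=volume.case_id,
                          values=np.array(values), flags=flag_map, names=names)
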