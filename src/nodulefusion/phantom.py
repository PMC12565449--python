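"""Synthetic CT phantoms with two-class nodules.

Each phantom is a chest-like volume: an elliptical body of soft tissue
(0 HU) in air (-1000 HU) containing two ellipsoidal lung fields
(about -800 HU with parenchymal noise).  One sub-3-cm nodule sits inside a
lung field: a ground-glass ellipsoid (about -500 HU) with an optional solid
core (about +20 HU), an irregular in-plane boundary, and additive
band-limited texture.  The two diagnostic groups differ in

* coarse-band texture variance (a class multiplier on the SD of noise
  smoothed at the 6 mm scale) — G2, the invasive group, is more
  heterogeneous;
* boundary irregularity amplitude (relative modulation of the nodule
  radius by a low-order angular Fourier series) — larger for G2;
* solid-core fraction (relative core radius) — larger for G2.

These placements mirror where invasiveness is expected to express on CT:
texture heterogeneity and shape.  Magnitudes are free parameters of the
generator; the defaults below define the ``separable`` preset used by the
package's own evaluation runs.

Everything is deterministic under a fixed seed, at both the case and the
cohort level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from .dataio import CTVolume, NoduleMask, CohortTable, write_volume, write_mask

__all__ = ["ClassEffects", "PhantomSpec", "PhantomTruth", "preset_spec",
           "generate_case", "generate_case_full", "generate_cohort"]


@dataclass(frozen=True)
class ClassEffects:
    """Class-conditional effect sizes."""

    coarse_sd_multiplier: float = 1.0   # scales the coarse-band texture SD
    irregularity_amplitude: float = 0.05  # relative boundary modulation
    solid_core_fraction: float = 0.15   # core radius / nodule radius

    def __post_init__(self):
        if self.coarse_sd_multiplier <= 0:
            raise ValueError("coarse_sd_multiplier must be > 0")
        if not (0 <= self.solid_core_fraction < 1):
            raise ValueError("solid_core_fraction must lie in [0, 1)")
        if self.irregularity_amplitude < 0:
            raise ValueError("irregularity_amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and class-effect parameters of the generator."""

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (2.0, 0.7, 0.7)
    radius_range_mm: tuple[float, float] = (4.0, 14.0)
    n_slices_visible: int | tuple[int, int] = (2, 25)
    lung_hu: float = -800.0
    body_hu: float = 0.0
    air_hu: float = -1000.0
    ggo_hu: float = -500.0
    core_hu: float = 20.0
    parenchyma_noise_sd: float = 20.0
    base_coarse_texture_sd: float = 40.0  # HU, in the 6 mm band, before multiplier
    fine_texture_sd: float = 10.0         # HU, in the 2 mm band, both classes
    coarse_scale_mm: float = 6.0
    fine_scale_mm: float = 2.0
    texture_halo_mm: float = 12.0  # texture extends into the peri-nodular halo
    clip_hu: tuple[float, float] = (-1024.0, 400.0)
    g1: ClassEffects = field(default_factory=lambda: ClassEffects(
        coarse_sd_multiplier=1.0, irregularity_amplitude=0.05,
        solid_core_fraction=0.15))
    g2: ClassEffects = field(default_factory=lambda: ClassEffects(
        coarse_sd_multiplier=2.5, irregularity_amplitude=0.18,
        solid_core_fraction=0.55))

    def __post_init__(self):
        if self.radius_range_mm[1] * 2 >= 30.0:
            raise ValueError("nodule diameter must stay below 30 mm")
        lo, hi = (self.n_slices_visible if isinstance(self.n_slices_visible, tuple)
                  else (self.n_slices_visible, self.n_slices_visible))
        if lo < 2 or hi > 25:
            raise ValueError("n_slices_visible must lie within [2, 25]")

    def effects(self, label: str) -> ClassEffects:
        if label == "G1":
            return self.g1
        if label == "G2":
            return self.g2
        raise ValueError(f"unknown label {label!r}")


def preset_spec(name: str = "separable", **overrides) -> PhantomSpec:
    """Named presets: ``separable`` (default class effects), ``hard``
    (small effects) and ``null`` (identical classes)."""
    if name == "separable":
        spec = PhantomSpec()
    elif name == "hard":
        spec = PhantomSpec(
            g1=ClassEffects(1.0, 0.06, 0.20),
            g2=ClassEffects(1.3, 0.09, 0.30),
        )
    elif name == "null":
        eff = ClassEffects(1.0, 0.08, 0.25)
        spec = PhantomSpec(g1=eff, g2=eff)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(spec, **overrides) if overrides else spec


@dataclass
class PhantomTruth:
    """Generator-side ground truth recorded alongside each case."""

    lung_mask: np.ndarray
    n_slices_visible: int
    center: tuple[int, int, int]   # (slice, row, col)
    radius_mm: float
    label: str


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = 0.0
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _lung_fields(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Body mask plus left/right lung ellipsoids."""
    nz, nr, nc = shape
    body = _ellipsoid(shape, (nz / 2, nr / 2, nc / 2),
                      (nz, 0.45 * nr, 0.47 * nc))  # body spans all slices
    lungs = []
    for side in (-1, +1):
        lungs.append(_ellipsoid(
            shape,
            (nz / 2, nr / 2, nc / 2 + side * 0.21 * nc),
            (0.44 * nz, 0.33 * nr, 0.185 * nc)))
    return body, lungs[0], lungs[1]


def _band_noise(rng, shape, sigma_vox) -> np.ndarray:
    """White noise smoothed at sigma (voxels), rescaled to unit SD."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox,
                            mode="reflect")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _angular_profile(rng, n_harmonics: int = 4):
    """Random in-plane boundary modulation g(theta) with unit variance."""
    orders = np.arange(2, 2 + n_harmonics)
    c = rng.standard_normal(n_harmonics) / orders
    d = rng.standard_normal(n_harmonics) / orders
    norm = math.sqrt(0.5 * float((c**2 + d**2).sum()))
    if norm > 0:
        c, d = c / norm, d / norm

    def g(theta):
        acc = np.zeros_like(theta)
        for m, cm, dm in zip(orders, c, d):
            acc += cm * np.cos(m * theta) + dm * np.sin(m * theta)
        return acc

    return g


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

def generate_case_full(spec: PhantomSpec, label: str, seed: int
                       ) -> tuple[CTVolume, NoduleMask, PhantomTruth]:
    """Generate one phantom case together with its ground truth."""
    eff = spec.effects(label)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    nz, nr, nc = spec.shape
    dz, dy, dx = spec.spacing_mm

    body, lung_l, lung_r = _lung_fields(spec.shape)
    lung = lung_l | lung_r

    vol = np.full(spec.shape, spec.air_hu)
    vol[body] = spec.body_hu
    parenchyma = _band_noise(rng, spec.shape, (0.5, 1.0, 1.0))
    vol[lung] = spec.lung_hu + spec.parenchyma_noise_sd * parenchyma[lung]

    # ---- nodule geometry -------------------------------------------------
    radius_mm = float(rng.uniform(*spec.radius_range_mm))
    if isinstance(spec.n_slices_visible, tuple):
        natural = int(round(2.0 * radius_mm / dz))
        n_slices = int(np.clip(natural, *spec.n_slices_visible))
    else:
        n_slices = int(spec.n_slices_visible)
    if n_slices > nz - 6:
        raise ValueError("nodule does not fit in grid along the slice axis")

    side = rng.choice([0, 1])
    lung_center_col = nc / 2 + (-1 if side == 0 else +1) * 0.21 * nc
    semi_r, semi_c = 0.33 * nr, 0.185 * nc
    # fractional offset inside the lung; nodule radius capped to the room left
    # (0.75 margin and the modulation clip below keep the irregular boundary
    # strictly inside the lung ellipsoid)
    pr, pc = rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3)
    cy = int(round(nr / 2 + pr * semi_r))
    cx = int(round(lung_center_col + pc * semi_c))
    room = min((0.8 - abs(pr)) * semi_r, (0.8 - abs(pc)) * semi_c) * 0.75
    r_px = min(radius_mm / dx, room)
    if r_px < 2.0:
        raise ValueError("nodule does not fit in grid")
    radius_mm = r_px * dx

    z_lo = max(n_slices // 2 + 1, int(0.32 * nz))
    z_hi = min(nz - n_slices // 2 - 2, int(0.68 * nz))
    if z_hi < z_lo:
        raise ValueError("nodule does not fit in grid along the slice axis")
    cz = int(rng.integers(z_lo, z_hi + 1))

    g = _angular_profile(rng)
    rows = np.arange(nr)[:, None] - cy
    cols = np.arange(nc)[None, :] - cx
    dist = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    modulation = np.clip(1.0 + eff.irregularity_amplitude * g(theta), 0.6, 1.45)

    k0 = cz - (n_slices - 1) // 2
    slice_idx = np.arange(k0, k0 + n_slices)
    u = (slice_idx - (k0 + (n_slices - 1) / 2.0)) / (n_slices / 2.0 + 0.5)
    mask = np.zeros(spec.shape, dtype=np.uint8)
    core = np.zeros(spec.shape, dtype=bool)
    for k, uk in zip(slice_idx, u):
        rk = max(r_px * math.sqrt(max(1.0 - uk * uk, 0.0)), 1.2)
        mask[k] = (dist <= rk * modulation).astype(np.uint8)
        if eff.solid_core_fraction > 0 and abs(uk) <= eff.solid_core_fraction:
            core[k] = dist <= eff.solid_core_fraction * rk

    inside = mask.astype(bool)
    vol[inside] = spec.ggo_hu
    vol[core & inside] = spec.core_hu

    # ---- band-limited texture inside the nodule --------------------------
    zs = slice(max(k0 - 2, 0), min(k0 + n_slices + 2, nz))
    pad = int(4 * spec.coarse_scale_mm / dx) + 2
    rs = slice(max(cy - int(r_px) - pad, 0), min(cy + int(r_px) + pad, nr))
    cs = slice(max(cx - int(r_px) - pad, 0), min(cx + int(r_px) + pad, nc))
    sub_shape = vol[zs, rs, cs].shape
    # texture is injected at the correlation length sigma/sqrt(2), where a
    # Gaussian-correlated field has maximal power in the LoG band of scale
    # sigma, so the class effect lands in the intended radiomic band
    s_fine = spec.fine_scale_mm / math.sqrt(2.0)
    s_coarse = spec.coarse_scale_mm / math.sqrt(2.0)
    fine = _band_noise(rng, sub_shape, (0.0, s_fine / dy, s_fine / dx))
    coarse = _band_noise(rng, sub_shape, (0.0, s_coarse / dy, s_coarse / dx))
    texture = (spec.fine_texture_sd * fine
               + spec.base_coarse_texture_sd * eff.coarse_sd_multiplier * coarse)
    # the lesion's heterogeneity extends into a peri-nodular halo (invasive
    # lesions distort surrounding parenchyma); without the halo, mask
    # clipping would suppress almost all coarse-band power in small nodules
    halo_px = spec.texture_halo_mm / dx
    sub_mask = inside[zs, rs, cs]
    sub_lung = lung[zs, rs, cs]
    weight = np.zeros(sub_shape)
    for j in range(sub_shape[0]):
        if sub_mask[j].any():
            d = ndimage.distance_transform_edt(~sub_mask[j])
            weight[j] = gaussian_filter((d <= halo_px).astype(float), 3.0)
    weight *= sub_mask | sub_lung  # texture never paints body or air
    sub = vol[zs, rs, cs]
    vol[zs, rs, cs] = sub + texture * weight

    np.clip(vol, *spec.clip_hu, out=vol)

    case_id = f"{label.lower()}_{seed:06d}"
    volume = CTVolume(voxels=vol, spacing_mm=spec.spacing_mm, case_id=case_id)
    nodule = NoduleMask(mask=mask, case_id=case_id)
    truth = PhantomTruth(lung_mask=lung, n_slices_visible=n_slices,
                         center=(cz, cy, cx), radius_mm=radius_mm, label=label)
    return volume, nodule, truth


def generate_case(spec: PhantomSpec, label: str, seed: int
                  ) -> tuple[CTVolume, NoduleMask]:
    volume, mask, _ = generate_case_full(spec, label, seed)
    return volume, mask


def case_seed(master_seed: int, label: str, index: int) -> int:
    """Deterministic per-case seed derived from the cohort master seed."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                 0 if label == "G1" else 1, int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(spec: PhantomSpec, n_per_class: int, out_dir: str | Path,
                    seed: int) -> tuple[CohortTable, Path]:
    """Write ``2 * n_per_class`` NIfTI volume/mask pairs plus a cohort CSV.

    Per-case seeds derive deterministically from the master seed, so
    regeneration with the same seed reproduces identical files.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in ("G1", "G2"):
        for i in range(n_per_class):
            s = case_seed(seed, label, i)
            volume, mask, _ = generate_case_full(spec, label, s)
            cid = f"{label.lower()}_{i:03d}"
            volume.case_id = cid
            mask.case_id = cid
            vpath = out_dir / f"{cid}_vol.nii.gz"
            mpath = out_dir / f"{cid}_mask.nii.gz"
            write_volume(volume, vpath)
            write_mask(mask, volume, mpath)
            rows.append({"case_id": cid, "volume": vpath.name,
                         "mask": mpath.name, "label": label})
    frame = pd.DataFrame(rows)
    csv_path = out_dir / "cohort.csv"
    frame.to_csv(csv_path, index=False)
    return CohortTable(frame=frame), csv_path


def generate_cases_in_memory(spec: PhantomSpec, n_per_class: int, seed: int
                             ) -> list[tuple[CTVolume, NoduleMask, PhantomTruth]]:
    """Cohort generation without touching disk (used by tests and the
    evaluation driver)."""
    cases = []
    for label in ("G1", "G2"):
        for i in range(n_per_class):
            s = case_seed(seed, label, i)
            volume, mask, truth = generate_case_full(spec, label, s)
            cid = f"{label.lower()}_{i:03d}"
            volume.case_id = cid
            mask.case_id = cid
            cases.append((volume, mask, truth))
    return cases
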