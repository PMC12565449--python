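"""Data containers, file I/O, cohort bookkeeping, configuration and logging.

Volumes and masks travel as NIfTI; the cohort is a CSV with header
``case_id,volume,mask,label``.  Arrays are indexed ``(slice, row, col)``,
0-based, with the slice index increasing along the acquisition axis.
Intensities are raw Hounsfield units at load time — all normalisation is
deferred to the preprocessing stage so the radiomic path sees unmodified HU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("nodulefusion")

VALID_LABELS = ("G1", "G2")
#: positive class for sensitivity/precision: G2, the invasive group
POSITIVE_LABEL = "G2"


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with voxel spacing in millimetres."""

    voxels: np.ndarray          # (slice, row, col), HU
    spacing_mm: tuple[float, float, float]  # (slice thickness, row, col)
    case_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.voxels.ndim}-D for case "
                f"{self.case_id!r}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"non-finite voxels in case {self.case_id!r}")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(
                f"spacing must be three positive values, got {self.spacing_mm}"
            )
        self.spacing_mm = sp
        dz = sp[0]
        if not (0.5 <= dz <= 5.0):
            raise ValueError(
                f"slice thickness {dz} mm outside accepted [0.5, 5.0] range"
            )
        if not (1.0 <= dz <= 3.0):
            warnings.warn(
                f"slice thickness {dz} mm outside the typical 1-3 mm "
                "acquisition range",
                stacklevel=2,
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class NoduleMask:
    """Binary nodule region of interest congruent with its volume."""

    mask: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"mask values must be binary for {self.case_id!r}")
        self.mask = m.astype(np.uint8)
        if self.mask.sum() == 0:
            raise ValueError(f"empty region of interest for case {self.case_id!r}")

    def validate_against(self, volume: CTVolume) -> None:
        if self.mask.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match volume shape "
                f"{volume.voxels.shape} for case {self.case_id!r}"
            )


@dataclass
class CohortTable:
    """Validated case table: case_id, volume path, mask path, G1/G2 label."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = ["case_id", "volume", "mask", "label"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        dupes = self.frame["case_id"][self.frame["case_id"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate case_id: {sorted(set(dupes))}")
        bad = set(self.frame["label"]) - set(VALID_LABELS)
        if bad:
            raise ValueError(
                f"unknown labels {sorted(bad)}; allowed labels are {VALID_LABELS}"
            )
        counts = self.frame["label"].value_counts()
        if set(counts.index) != set(VALID_LABELS):
            raise ValueError("both classes G1 and G2 must be present")

    @property
    def case_ids(self) -> list[str]:
        return list(self.frame["case_id"])

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.frame["case_id"], self.frame["label"]))

    def counts(self) -> dict[str, int]:
        return self.frame["label"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# run configuration (defaults = the published training protocol)
# ---------------------------------------------------------------------------

def _stage(**kw):
    return field(default_factory=lambda: StageConfig(**kw))


@dataclass
class StageConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 128
    weight_decay: float = 0.0
    patience: int | None = None
    dropout: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError(f"learning rate must be > 0, got {self.learning_rate}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.patience is not None and self.patience < 0:
            raise ValueError("patience must be >= 0")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class RunConfig:
    """Per-stage hyperparameters.

    The defaults are the published protocol: Adam for the auto-encoder
    (1e-4 pre-training over 200 epochs at batch 128; 1e-6 fine-tuning over
    50 epochs at batch 64), Adam 1e-3 for the temporal encoder (200 epochs,
    batch 64, dropout 0.3), AdamW 1e-5 for the spatial encoder (50 epochs,
    batch 1, weight decay 0.05, patience 10, dropout 0.1) and AdamW 1e-3
    for the fusion head (20 epochs, batch 8, weight decay 0.05, patience 5).
    """

    cae_pretrain: StageConfig = _stage(
        optimizer="adam", learning_rate=1e-4, epochs=200, batch_size=128)
    cae_finetune: StageConfig = _stage(
        optimizer="adam", learning_rate=1e-6, epochs=50, batch_size=64)
    cae_transformer: StageConfig = _stage(
        optimizer="adam", learning_rate=1e-3, epochs=200, batch_size=64,
        dropout=0.3)
    spatial: StageConfig = _stage(
        optimizer="adamw", learning_rate=1e-5, epochs=50, batch_size=1,
        weight_decay=0.05, patience=10, dropout=0.1)
    cca: StageConfig = _stage(
        optimizer="adamw", learning_rate=1e-3, epochs=20, batch_size=8,
        weight_decay=0.05, patience=5)
    seed: int = 42
    reduced: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_STAGE_KEYS = ("cae_pretrain", "cae_finetune", "cae_transformer", "spatial", "cca")
_STAGE_FIELDS = {f.name for f in dataclasses.fields(StageConfig)}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML/JSON document; absent keys keep the
    published defaults, unknown keys are rejected."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"malformed config document at {path}")
        doc.update(loaded)
    if overrides:
        doc.update(overrides)

    cfg = RunConfig()
    for key, value in doc.items():
        if key in _STAGE_KEYS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            stage = getattr(cfg, key)
            for k, v in value.items():
                if k not in _STAGE_FIELDS:
                    raise ValueError(f"unknown key {key}.{k!r}")
                setattr(stage, k, v)
            stage.__post_init__()  # re-validate after overrides
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "reduced":
            cfg.reduced = bool(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> CTVolume:
    """Read a 3-D NIfTI volume; spacing is taken from the header zooms.

    On-disk NIfTI axes are (col, row, slice) per the affine convention used
    by :func:`write_volume`; they are transposed to (slice, row, col) here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    voxels = np.ascontiguousarray(data.T.astype(np.float64))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels=voxels, spacing_mm=spacing, case_id=path.stem)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CTVolume to NIfTI such that read_volume round-trips exactly."""
    path = Path(path)
    dz, dy, dx = volume.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(volume.voxels.T.astype(np.float64), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    return path


def write_mask(mask: NoduleMask, volume: CTVolume, path: str | Path) -> Path:
    mask.validate_against(volume)
    dz, dy, dx = volume.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(mask.mask.T.astype(np.uint8), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, volume: CTVolume) -> NoduleMask:
    """Read a mask NIfTI; any nonzero voxel becomes 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask, got {data.ndim}-D in {path}")
    binary = (data.T != 0).astype(np.uint8)
    if binary.sum() == 0:
        raise ValueError(f"empty region of interest in {path}")
    mask = NoduleMask(mask=binary, case_id=volume.case_id)
    mask.validate_against(volume)
    return mask


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Optional DICOM-series reader (requires pydicom)."""
    import pydicom  # local import: optional dependency

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    first = datasets[0]
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        dz = abs(float(datasets[1].ImagePositionPatient[2])
                 - float(datasets[0].ImagePositionPatient[2]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(voxels=np.stack(slices), spacing_mm=(dz, dy, dx),
                    case_id=directory.name)


def load_cohort(csv_path: str | Path, check_files: bool = True) -> CohortTable:
    """Load and validate the cohort CSV; row order is preserved."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(f"cohort table not found: {csv_path}")
    frame = pd.read_csv(csv_path, dtype={"case_id": str})
    table = CohortTable(frame=frame)
    if check_files:
        base = csv_path.parent
        for _, row in frame.iterrows():
            for col in ("volume", "mask"):
                p = Path(row[col])
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(
                        f"case {row['case_id']}: missing {col} file {p}"
                    )
    log.info("cohort %s: %s", csv_path.name, table.counts())
    return table


def resolve_case_paths(table: CohortTable, csv_path: str | Path
                       ) -> list[tuple[str, Path, Path, str]]:
    base = Path(csv_path).parent
    out = []
    for _, row in table.frame.iterrows():
        vp, mp = Path(row["volume"]), Path(row["mask"])
        out.append((row["case_id"],
                    vp if vp.is_absolute() else base / vp,
                    mp if mp.is_absolute() else base / mp,
                    row["label"]))
    return out
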