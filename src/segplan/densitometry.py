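"""Quantitative-CT lung densitometry primitives.

Converts voxel phantoms (Hounsfield-unit volume + integer segment label map)
into per-segment tissue/air volumes and the tissue-to-air ratio (TAR), and
builds the validated :class:`LungModel` consumed by the treatment planner.

TAR is expressed in percent throughout: ``TAR = 100 * tissue_ml / air_ml``.
Lower TAR means less dense, more emphysematous tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEFT_TREATABLE",
    "RIGHT_TREATABLE",
    "LINGULA",
    "LOWER_LOBES",
    "MERGED_APICOPOSTERIOR",
    "SegmentDensitometry",
    "LungModel",
    "VoxelPhantom",
    "tissue_fraction_from_hu",
    "summarize_segment",
    "build_lung_model",
    "read_segment_table",
    "write_segment_table",
    "generate_phantom",
    "save_phantom",
    "load_phantom",
]

# Canonical anatomy: left upper lobe has 5 segments (LB4/LB5 form the
# lingula, never treated); right upper lobe has 3, all treatable.
LEFT_TREATABLE = ("LB1", "LB2", "LB3")
RIGHT_TREATABLE = ("RB1", "RB2", "RB3")
LINGULA = ("LB4", "LB5")
LOWER_LOBES = ("LLL", "RLL")
MERGED_APICOPOSTERIOR = "LB1+2"  # LB1 and LB2 treated as one segment

_UPPER_SEGMENTS = LEFT_TREATABLE + LINGULA + RIGHT_TREATABLE
_ALL_TABLE_IDS = _UPPER_SEGMENTS + LOWER_LOBES


class DensitometryError(ValueError):
    """Raised for invalid densitometry inputs (volumes, labels, tables)."""


@dataclass(frozen=True)
class SegmentDensitometry:
    """Tissue/air volumes (ml) of one bronchopulmonary segment.

    ``tar`` is the tissue-to-air ratio in percent; the total volume is the
    sum of the two compartments.
    """

    segment_id: str
    tissue_volume: float
    air_volume: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tissue_volume) and np.isfinite(self.air_volume)):
            raise DensitometryError(
                f"{self.segment_id}: volumes must be finite, got "
                f"tissue={self.tissue_volume}, air={self.air_volume}"
            )
        if self.tissue_volume < 0:
            raise DensitometryError(
                f"{self.segment_id}: negative tissue volume {self.tissue_volume}"
            )
        if self.air_volume <= 0:
            raise DensitometryError(
                f"{self.segment_id}: air volume must be > 0 (TAR undefined), "
                f"got {self.air_volume}"
            )

    @property
    def total_volume(self) -> float:
        return self.tissue_volume + self.air_volume

    @property
    def tar(self) -> float:
        """Tissue-to-air ratio in percent."""
        return 100.0 * self.tissue_volume / self.air_volume

    @staticmethod
    def merge(segments: Sequence["SegmentDensitometry"], segment_id: str) -> "SegmentDensitometry":
        """Volume-aggregated union of segments (e.g. LB1+LB2 -> LB1+2)."""
        return SegmentDensitometry(
            segment_id=segment_id,
            tissue_volume=sum(s.tissue_volume for s in segments),
            air_volume=sum(s.air_volume for s in segments),
        )


@dataclass(frozen=True)
class LungModel:
    """Both upper lobes' segmental densitometry plus lower-lobe TARs.

    Parameters
    ----------
    segments
        Mapping of segment id to :class:`SegmentDensitometry` covering the
        five left-upper-lobe segments (LB1..LB5) and the three right ones
        (RB1..RB3).  The merged LB1+2 entry is derived on access.
    lower_lobe_tar
        TAR (percent) of the left and right lower lobes, keyed ``left`` /
        ``right``; must be positive.
    denominator
        Lobe-volume convention for treatment fractions: ``"treatable"``
        (default; the left denominator excludes the lingula) or
        ``"anatomical"`` (whole lobe including LB4/LB5).
    """

    segments: Mapping[str, SegmentDensitometry]
    lower_lobe_tar: Mapping[str, float]
    denominator: str = "treatable"

    def __post_init__(self) -> None:
        missing = [s for s in _UPPER_SEGMENTS if s not in self.segments]
        if missing:
            raise DensitometryError(f"missing upper-lobe segments: {missing}")
        unknown = [s for s in self.segments if s not in _UPPER_SEGMENTS]
        if unknown:
            raise DensitometryError(f"unknown segment ids: {unknown}")
        for side in ("left", "right"):
            tar = self.lower_lobe_tar.get(side)
            if tar is None or not np.isfinite(tar) or tar <= 0:
                raise DensitometryError(
                    f"lower-lobe TAR for side {side!r} must be positive, got {tar}"
                )
        if self.denominator not in ("treatable", "anatomical"):
            raise DensitometryError(
                f"denominator must be 'treatable' or 'anatomical', got {self.denominator!r}"
            )

    def segment(self, segment_id: str) -> SegmentDensitometry:
        """Look up a segment, deriving the merged LB1+2 on demand."""
        if segment_id == MERGED_APICOPOSTERIOR:
            return SegmentDensitometry.merge(
                [self.segments["LB1"], self.segments["LB2"]], MERGED_APICOPOSTERIOR
            )
        try:
            return self.segments[segment_id]
        except KeyError:
            raise DensitometryError(f"unknown segment id {segment_id!r}") from None

    def treatable_ids(self, side: str) -> tuple[str, ...]:
        if side == "left":
            return LEFT_TREATABLE
        if side == "right":
            return RIGHT_TREATABLE
        raise DensitometryError(f"side must be 'left' or 'right', got {side!r}")

    def side_of(self, segment_id: str) -> str:
        return "left" if segment_id.startswith("L") else "right"

    def lobe_volume(self, side: str) -> float:
        """Upper-lobe denominator volume (ml) under the configured convention."""
        ids = list(self.treatable_ids(side))
        if side == "left" and self.denominator == "anatomical":
            ids += list(LINGULA)
        return sum(self.segments[s].total_volume for s in ids)


def tissue_fraction_from_hu(hu):
    """Tissue fraction of a voxel under the linear two-compartment model.

    Air is -1000 HU (fraction 0), water-density tissue is 0 HU (fraction 1);
    values outside [-1000, 0] are clipped.  Accepts scalars or arrays.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise DensitometryError("Hounsfield values must be finite")
    frac = np.clip((hu + 1000.0) / 1000.0, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


@dataclass(frozen=True)
class VoxelPhantom:
    """Synthetic CT stand-in: HU grid + integer segment label map.

    ``voxel_volume`` is ml per voxel (isotropic by default; anisotropic
    spacing is folded into this single per-voxel volume).
    """

    hu_grid: np.ndarray
    label_grid: np.ndarray
    voxel_volume: float
    label_table: Mapping[int, str]
    spacing_mm: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        if self.hu_grid.shape != self.label_grid.shape:
            raise DensitometryError(
                f"grid shapes differ: {self.hu_grid.shape} vs {self.label_grid.shape}"
            )
        if not self.voxel_volume > 0:
            raise DensitometryError(f"voxel_volume must be > 0, got {self.voxel_volume}")
        present = set(np.unique(self.label_grid).tolist()) - {0}
        unmapped = present - set(self.label_table)
        if unmapped:
            raise DensitometryError(f"labels missing from label_table: {sorted(unmapped)}")

    def label_for(self, segment_id: str) -> int:
        for label, seg in self.label_table.items():
            if seg == segment_id:
                return label
        raise DensitometryError(f"segment {segment_id!r} not in label table")


def summarize_segment(phantom: VoxelPhantom, segment_label: int) -> SegmentDensitometry:
    """Per-segment tissue/air volumes and TAR from a voxel phantom.

    Tissue volume is the voxel volume times the tissue fraction summed over
    the segment's voxels; air volume is the complement.
    """
    mask = phantom.label_grid == segment_label
    if not mask.any():
        raise DensitometryError(f"segment label {segment_label} absent from phantom")
    frac = tissue_fraction_from_hu(phantom.hu_grid[mask])
    tissue = float(phantom.voxel_volume * frac.sum())
    air = float(phantom.voxel_volume * (1.0 - frac).sum())
    segment_id = phantom.label_table.get(int(segment_label), str(segment_label))
    return SegmentDensitometry(segment_id=segment_id, tissue_volume=tissue, air_volume=air)


def _rows_to_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(list(table), columns=["segment_id", "tissue_ml", "air_ml"])
    required = {"segment_id", "tissue_ml", "air_ml"}
    if not required.issubset(df.columns):
        raise DensitometryError(
            f"segment table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    df["segment_id"] = df["segment_id"].astype(str).str.strip().str.upper()
    return df


def build_lung_model(table, denominator: str = "treatable") -> LungModel:
    """Validate a (segment_id, tissue_ml, air_ml) table into a LungModel.

    The table must contain each of LB1..LB5, RB1..RB3 and the lower lobes
    LLL/RLL exactly once.  An explicit LB1+2 row, if present, must equal the
    LB1+LB2 volume sums; otherwise the merged segment is derived on demand.
    """
    df = _rows_to_frame(table)
    ids = df["segment_id"].tolist()
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise DensitometryError(f"duplicate segment rows: {dupes}")
    unknown = sorted(set(ids) - set(_ALL_TABLE_IDS) - {MERGED_APICOPOSTERIOR})
    if unknown:
        raise DensitometryError(f"unknown segment ids: {unknown}")
    missing = sorted(set(_ALL_TABLE_IDS) - set(ids))
    if missing:
        raise DensitometryError(f"missing segment rows: {missing}")

    by_id = {
        row.segment_id: SegmentDensitometry(
            segment_id=row.segment_id,
            tissue_volume=float(row.tissue_ml),
            air_volume=float(row.air_ml),
        )
        for row in df.itertuples()
    }
    if MERGED_APICOPOSTERIOR in by_id:
        merged = by_id.pop(MERGED_APICOPOSTERIOR)
        expect = SegmentDensitometry.merge(
            [by_id["LB1"], by_id["LB2"]], MERGED_APICOPOSTERIOR
        )
        if not (
            np.isclose(merged.tissue_volume, expect.tissue_volume, rtol=1e-6)
            and np.isclose(merged.air_volume, expect.air_volume, rtol=1e-6)
        ):
            raise DensitometryError(
                "explicit LB1+2 row inconsistent with LB1 + LB2 volume sums"
            )
    lower = {"left": by_id.pop("LLL").tar, "right": by_id.pop("RLL").tar}
    return LungModel(segments=by_id, lower_lobe_tar=lower, denominator=denominator)


def read_segment_table(path: str | Path, denominator: str = "treatable") -> LungModel:
    """Read a segment table (CSV with header segment_id,tissue_ml,air_ml, or
    a JSON list of such records) and build the LungModel."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return build_lung_model(df, denominator=denominator)


def write_segment_table(model: LungModel, path: str | Path) -> None:
    """Write a LungModel back to the canonical CSV dialect."""
    rows = []
    for seg_id in _UPPER_SEGMENTS:
        s = model.segments[seg_id]
        rows.append((seg_id, s.tissue_volume, s.air_volume))
    # Lower lobes are carried as TAR only; emit a nominal 1000 ml air volume
    # with the tissue volume that reproduces the TAR.
    for seg_id, side in (("LLL", "left"), ("RLL", "right")):
        tar = model.lower_lobe_tar[side]
        rows.append((seg_id, 10.0 * tar, 1000.0))
    pd.DataFrame(rows, columns=["segment_id", "tissue_ml", "air_ml"]).to_csv(
        Path(path), index=False, float_format="%.6f"
    )


def _fraction_for_tar(tar_percent: float) -> float:
    # TAR = 100 f / (1 - f)  =>  f = TAR / (100 + TAR)
    if not np.isfinite(tar_percent) or tar_percent <= 0:
        raise DensitometryError(f"target TAR must be positive and finite, got {tar_percent}")
    return tar_percent / (100.0 + tar_percent)


def generate_phantom(
    spec: Mapping[str, tuple[float, float]] | Mapping[str, Mapping[str, float]],
    seed: int | np.random.Generator = 0,
    voxel_volume: float = 0.001,
    hu_noise_sd: float = 30.0,
) -> VoxelPhantom:
    """Build a reproducible voxel phantom from per-segment (TAR %, volume ml).

    Each segment occupies a slab of the grid; its mean HU is set so the
    recovered TAR matches the target (HU = -1000 * (1 - f), f = TAR/(100+TAR))
    with zero-mean Gaussian HU noise on top.  Noise well inside the
    [-1000, 0] clip window keeps the recovered TAR unbiased.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries = []
    for seg_id, val in spec.items():
        if isinstance(val, Mapping):
            tar, vol = float(val["tar"]), float(val["volume_ml"])
        else:
            tar, vol = float(val[0]), float(val[1])
        if vol <= 0:
            raise DensitometryError(f"{seg_id}: volume must be > 0, got {vol}")
        entries.append((str(seg_id).upper(), tar, vol))

    slabs_hu, slabs_label, label_table = [], [], {}
    for label, (seg_id, tar, vol) in enumerate(entries, start=1):
        f = _fraction_for_tar(tar)
        n_vox = max(1, int(round(vol / voxel_volume)))
        mean_hu = -1000.0 * (1.0 - f)
        hu = mean_hu + rng.normal(0.0, hu_noise_sd, size=n_vox)
        slabs_hu.append(hu)
        slabs_label.append(np.full(n_vox, label, dtype=np.int16))
        label_table[label] = seg_id

    flat_hu = np.concatenate(slabs_hu)
    flat_label = np.concatenate(slabs_label)
    # Pad to a rectangular 3-D grid; padding voxels are label 0 (background).
    nx = int(np.ceil(flat_hu.size ** (1 / 3)))
    total = nx * nx * int(np.ceil(flat_hu.size / (nx * nx)))
    hu_grid = np.full(total, -1000.0, dtype=np.float32)
    label_grid = np.zeros(total, dtype=np.int16)
    hu_grid[: flat_hu.size] = flat_hu
    label_grid[: flat_label.size] = flat_label
    shape = (nx, nx, total // (nx * nx))
    return VoxelPhantom(
        hu_grid=hu_grid.reshape(shape),
        label_grid=label_grid.reshape(shape),
        voxel_volume=voxel_volume,
        label_table=label_table,
    )


def save_phantom(phantom: VoxelPhantom, stem: str | Path) -> tuple[Path, Path, Path]:
    """Write <stem>_hu.nii.gz, <stem>_labels.nii.gz and <stem>_labels.json."""
    import nibabel as nib

    stem = Path(stem)
    affine = np.diag(list(phantom.spacing_mm) + [1.0])
    hu_path = stem.with_name(stem.name + "_hu.nii.gz")
    lab_path = stem.with_name(stem.name + "_labels.nii.gz")
    json_path = stem.with_name(stem.name + "_labels.json")
    nib.save(nib.Nifti1Image(phantom.hu_grid.astype(np.float32), affine), hu_path)
    nib.save(nib.Nifti1Image(phantom.label_grid.astype(np.int16), affine), lab_path)
    json_path.write_text(
        json.dumps(
            {
                "voxel_volume_ml": phantom.voxel_volume,
                "labels": {str(k): v for k, v in phantom.label_table.items()},
            },
            indent=2,
        )
    )
    return hu_path, lab_path, json_path


def load_phantom(stem: str | Path) -> VoxelPhantom:
    """Inverse of :func:`save_phantom`."""
    import nibabel as nib

    stem = Path(stem)
    hu = np.asarray(nib.load(stem.with_name(stem.name + "_hu.nii.gz")).dataobj, dtype=np.float32)
    lab = np.asarray(
        nib.load(stem.with_name(stem.name + "_labels.nii.gz")).dataobj, dtype=np.int16
    )
    meta = json.loads(stem.with_name(stem.name + "_labels.json").read_text())
    return VoxelPhantom(
        hu_grid=hu,
        label_grid=lab,
        voxel_volume=float(meta["voxel_volume_ml"]),
        label_table={int(k): v for k, v in meta["labels"].items()},
    )


def phantom_to_lung_model(
    phantom: VoxelPhantom, denominator: str = "treatable"
) -> LungModel:
    """Summarize every labelled segment of a phantom into a LungModel."""
    rows = []
    for label, seg_id in phantom.label_table.items():
        s = summarize_segment(phantom, label)
        rows.append((seg_id, s.tissue_volume, s.air_volume))
    return build_lung_model(rows, denominator=denominator)
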