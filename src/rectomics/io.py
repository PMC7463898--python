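"""Volumes, masks and study cases: reading, resampling and ROI geometry.

Conventions
-----------
Voxel arrays are indexed ``[x, y, z]`` with the section (slice) index on the
third axis; ``spacing`` is the physical voxel size in mm as ``(dx, dy, dz)``.
All geometry downstream is computed in physical millimetres using the header
spacing, so anisotropic voxels are handled explicitly rather than assumed
away.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

MaskRole = Literal["entire_wall", "lumen", "primary_tumor"]

#: Most consistently occurring acquisition resolution in the discovery
#: cohort; the default resampling target for every case (mm).
DEFAULT_SPACING: tuple[float, float, float] = (0.781, 0.781, 4.0)


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities; must be finite.
    spacing : tuple of float
        Voxel size in mm, ``(in-plane x, in-plane y, section thickness)``.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class Mask:
    """A binary ROI aligned to a :class:`Volume`, tagged with its role."""

    voxels: np.ndarray
    role: MaskRole
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {v.shape}")
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask voxels must be binary (0/1)")
            v = v.astype(bool)
        if self.role not in ("entire_wall", "lumen", "primary_tumor"):
            raise ValueError(f"unknown mask role {self.role!r}")
        if self.role in ("entire_wall", "lumen") and not v.any():
            raise ValueError(f"{self.role} mask is empty")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def section_areas(self) -> np.ndarray:
        """Voxel counts per section (third axis)."""
        return self.voxels.sum(axis=(0, 1))


@dataclass
class StudyCase:
    """One patient study: T2w volume, the three annotations and metadata."""

    case_id: str
    volume: Volume
    wall: Mask
    lumen: Mask
    primary: Mask
    ypT_group: Literal["ypT0-2", "ypT3-4"]
    institution: str = "inst1"
    field_T: float = 3.0
    sex: Literal["M", "F"] = "M"
    cohort: str = "discovery"

    def __post_init__(self):
        shape = self.volume.shape
        for m in (self.wall, self.lumen, self.primary):
            if m.shape != shape:
                raise ValueError(
                    f"mask {m.role} shape {m.shape} does not match volume {shape}"
                )
        if self.ypT_group not in ("ypT0-2", "ypT3-4"):
            raise ValueError(f"unknown ypT group {self.ypT_group!r}")

    @property
    def masks(self) -> dict[str, Mask]:
        return {"entire_wall": self.wall, "lumen": self.lumen, "primary_tumor": self.primary}


# ---------------------------------------------------------------------------
# NIfTI / DICOM input
# ---------------------------------------------------------------------------

def _from_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin


def _from_dicom_series(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"{path}: no DICOM files found")
    slices = [pydicom.dcmread(str(f)) for f in files]
    # order along the slice axis by ImagePositionPatient z (fall back to
    # InstanceNumber when positions are missing)
    if all(hasattr(s, "ImagePositionPatient") for s in slices):
        order = np.argsort([float(s.ImagePositionPatient[2]) for s in slices])
    else:
        order = np.argsort([int(s.InstanceNumber) for s in slices])
    slices = [slices[i] for i in order]
    files = [files[i] for i in order]
    zpos = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    gaps = np.diff(zpos)
    if len(gaps) and (np.ptp(gaps) > 1e-3 * abs(np.median(gaps)) + 1e-6):
        bad = [files[i + 1].name for i in np.where(
            np.abs(gaps - np.median(gaps)) > 1e-3 * abs(np.median(gaps)) + 1e-6)[0]]
        raise ValueError(
            f"inconsistent slice spacing in DICOM series {path}: "
            f"irregular gaps at slices {bad}"
        )
    dz = float(np.median(gaps)) if len(gaps) else float(
        getattr(slices[0], "SliceThickness", 1.0))
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    # pixel_array is (row, col) = (y, x); stack to (x, y, z)
    vol = np.stack([s.pixel_array.T for s in slices], axis=-1).astype(np.float64)
    ipp = slices[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return vol, (dx, dy, abs(dz)), origin


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI file or a DICOM series directory into a :class:`Volume`.

    Spacing is taken from the header.  A DICOM series with irregular slice
    gaps (e.g. a missing slice) raises a ``ValueError`` naming the offending
    slices.
    """
    path = Path(path)
    if path.is_dir():
        voxels, spacing, origin = _from_dicom_series(path)
    else:
        voxels, spacing, origin = _from_nifti(path)
    return Volume(voxels=voxels, spacing=spacing, origin=origin)


def read_mask(path: str | os.PathLike, role: MaskRole) -> Mask:
    """Read a 0/1 label NIfTI as a role-tagged mask."""
    voxels, spacing, origin = _from_nifti(Path(path))
    return Mask(voxels=voxels > 0.5, role=role, spacing=spacing, origin=origin)


def write_volume(v: Volume | Mask, path: str | os.PathLike) -> None:
    """Write a volume or mask as NIfTI with its spacing in the affine."""
    import nibabel as nib

    data = v.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(v.spacing) + [1.0])
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(v: Volume | Mask,
             target_spacing: Sequence[float] = DEFAULT_SPACING,
             mode: Literal["linear", "nearest"] | None = None):
    """Resample a volume (linear) or mask (nearest) to ``target_spacing``.

    The physical extent is preserved to within one voxel.  Masks must use
    nearest-neighbour interpolation and remain binary.
    """
    import SimpleITK as sitk

    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    is_mask = isinstance(v, Mask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    if is_mask and mode == "linear":
        raise ValueError("masks must be resampled with mode='nearest'")

    data = v.voxels.astype(np.uint8) if is_mask else v.voxels
    # SimpleITK uses (z, y, x) array order
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)

    new_size = [max(1, int(round(n * s / t)))
                for n, s, t in zip(v.shape, v.spacing, target_spacing)]
    interp = sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear
    out = sitk.Resample(img, new_size, sitk.Transform(), interp,
                        img.GetOrigin(), target_spacing, img.GetDirection(),
                        0, img.GetPixelID(), True)  # NN-extrapolate at edges
    arr = sitk.GetArrayFromImage(out).transpose(2, 1, 0)
    if is_mask:
        return Mask(voxels=arr > 0, role=v.role,
                    spacing=target_spacing, origin=v.origin)
    return Volume(voxels=np.asarray(arr, dtype=np.float64),
                  spacing=target_spacing, origin=v.origin)


def resample_case(case: StudyCase,
                  target_spacing: Sequence[float] = DEFAULT_SPACING) -> StudyCase:
    """Resample a whole study case (volume linearly, masks nearest)."""
    return StudyCase(
        case_id=case.case_id,
        volume=resample(case.volume, target_spacing, "linear"),
        wall=resample(case.wall, target_spacing, "nearest"),
        lumen=resample(case.lumen, target_spacing, "nearest"),
        primary=resample(case.primary, target_spacing, "nearest"),
        ypT_group=case.ypT_group, institution=case.institution,
        field_T=case.field_T, sex=case.sex, cohort=case.cohort,
    )


# ---------------------------------------------------------------------------
# Primary-tumor sub-volume selection
# ---------------------------------------------------------------------------

def select_primary_subvolume(rp: Mask) -> tuple[int, ...]:
    """Pick the three consecutive sections analysed for texture.

    Returns the indices of the largest annotated 2D section of the primary
    tumour region together with its two neighbours.  Ties on area break
    toward the lower index; when the maximal section sits at either end of
    the annotated span, the 3-section window is shifted inward.  If fewer
    than 3 sections are annotated, all available sections are returned with
    a warning.
    """
    areas = rp.section_areas()
    annotated = np.where(areas > 0)[0]
    if annotated.size == 0:
        raise ValueError("primary tumor mask has no annotated sections")
    if annotated.size < 3:
        warnings.warn(
            f"primary tumor spans only {annotated.size} section(s); "
            "using all available sections", stacklevel=2)
        return tuple(int(i) for i in annotated)
    lo, hi = int(annotated[0]), int(annotated[-1])
    best = lo + int(np.argmax(areas[lo:hi + 1]))  # argmax ties -> lower index
    start = min(max(best - 1, lo), hi - 2)
    return (start, start + 1, start + 2)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Raises for two empty masks, where the coefficient is undefined.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        raise ValueError("dice undefined for two empty masks")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)
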