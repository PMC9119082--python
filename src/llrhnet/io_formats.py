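"""File formats and slice geometry.

NIfTI volumes are handled with nibabel; 2D images and label masks are 8-bit
PNGs (label masks use a fixed palette so classes stay distinguishable when
viewed).  3D volumes are processed slice-by-slice: ``extract_axial_slices``
cuts a volume along its anatomical superior-inferior axis (derived from the
NIfTI affine, so it is independent of how the array axes happen to be
stored), and ``stack_predictions`` reassembles predicted 2D label maps into
a volume with the template's geometry, ready for volume-mode metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

LABEL_PALETTE = [0, 0, 0, 220, 60, 40, 60, 120, 220]  # bg, class 1, class 2


@dataclass
class VolumeRecord:
    """A 3D intensity (or label) volume with its geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    axis_order: tuple[str, str, str]  # anatomical codes per array axis, e.g. R,A,S
    source_path: str | None = None

    def __post_init__(self):
        if self.voxels.ndim != 3:
            raise ValueError("volume must have exactly 3 dimensions")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def axial_axis(self) -> int:
        """Array axis running superior-inferior (the slicing axis)."""
        for i, code in enumerate(self.axis_order):
            if code in ("S", "I"):
                return i
        raise ValueError("affine declares no superior-inferior axis")


def read_volume(path: str | Path) -> VolumeRecord:
    """Load a NIfTI volume; raises a format error for anything else."""
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        raise ValueError(f"expected a NIfTI file (.nii/.nii.gz), got '{path.name}'")
    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several unrelated types
        raise ValueError(f"unreadable NIfTI file {path}: {e}") from e
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim} dims (field: dim)")
    codes = nib.orientations.aff2axcodes(img.affine)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeRecord(voxels=data, spacing=spacing, affine=img.affine,
                        axis_order=codes, source_path=str(path))


def write_volume(vol: VolumeRecord, path: str | Path):
    path = Path(path)
    img = nib.Nifti1Image(vol.voxels, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def extract_axial_slices(vol: VolumeRecord) -> list[np.ndarray]:
    """Ordered 2D slices along the anatomical axial (S-I) axis."""
    ax = vol.axial_axis
    return [np.take(vol.voxels, i, axis=ax) for i in range(vol.voxels.shape[ax])]


def stack_predictions(slices: list[np.ndarray], template: VolumeRecord) -> VolumeRecord:
    """Reassemble predicted 2D slices into a volume in the template geometry."""
    ax = template.axial_axis
    n = template.voxels.shape[ax]
    if len(slices) != n:
        raise ValueError(f"got {len(slices)} slices, template has {n}")
    expected = tuple(s for i, s in enumerate(template.voxels.shape) if i != ax)
    for k, s in enumerate(slices):
        if s.shape != expected:
            raise ValueError(f"slice {k} shape {s.shape} != template {expected}")
    stacked = np.stack(slices, axis=ax)
    return VolumeRecord(voxels=stacked, spacing=template.spacing,
                        affine=template.affine, axis_order=template.axis_order)


def resize_image(image: np.ndarray, target: tuple[int, int],
                 kind: str = "intensity") -> np.ndarray:
    """Bilinear resize for intensities, nearest-neighbour for label masks."""
    if min(target) <= 0:
        raise ValueError("target dims must be positive")
    image = np.asarray(image)
    if tuple(image.shape) == tuple(target):
        return image.copy()
    if kind == "labels":
        out = _sk_resize(image, target, order=0, preserve_range=True,
                         anti_aliasing=False)
        return out.astype(image.dtype)
    if kind != "intensity":
        raise ValueError("kind must be 'intensity' or 'labels'")
    return _sk_resize(image.astype(np.float64), target, order=1,
                      preserve_range=True, anti_aliasing=False)


# ---------------------------------------------------------------------------
# PNG slices and label masks
# ---------------------------------------------------------------------------

def write_image_png(image: np.ndarray, path: str | Path):
    """Write a float image (rescaled to [0,255]) as 8-bit grayscale PNG."""
    arr = np.asarray(image, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi - lo < 1e-12 else (arr - lo) / (hi - lo)
    Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG back to float intensities in [0,1]."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


def write_labels_png(labels: np.ndarray, path: str | Path):
    """Write an integer label mask as a paletted PNG (values preserved)."""
    img = Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    img.putpalette(LABEL_PALETTE + [0] * (768 - len(LABEL_PALETTE)))
    img.save(path)


def read_labels_png(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError(f"label PNG must be paletted or grayscale, got {img.mode}")
    return np.asarray(img, dtype=np.uint8)


def write_sample(sample, out_dir: Path, stem: str, fmt: str = "png") -> dict:
    """Persist one phantom sample; returns relative file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        if sample.image.ndim == 3:
            img_paths = []
            for ch in range(sample.image.shape[0]):
                p = out_dir / f"{stem}_ch{ch}.png"
                _write_exact_png(sample.image[ch], p)
                img_paths.append(p.name)
            image_entry = img_paths
        else:
            p = out_dir / f"{stem}_img.png"
            _write_exact_png(sample.image, p)
            image_entry = p.name
        lp = out_dir / f"{stem}_lbl.png"
        if lp.exists():
            raise FileExistsError(f"output path collision: {lp}")
        write_labels_png(sample.labels, lp)
        return {"image": image_entry, "labels": lp.name}
    if fmt == "nifti":
        affine = np.eye(4)
        img = sample.image if sample.image.ndim == 3 else sample.image[None]
        ip = out_dir / f"{stem}_img.nii"
        lp = out_dir / f"{stem}_lbl.nii"
        if ip.exists() or lp.exists():
            raise FileExistsError(f"output path collision: {ip}")
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine), str(ip))
        nib.save(nib.Nifti1Image(sample.labels[None].astype(np.uint8), affine),
                 str(lp))
        return {"image": ip.name, "labels": lp.name}
    raise ValueError("fmt must be 'png' or 'nifti'")


def _write_exact_png(image: np.ndarray, path: Path):
    """Quantise intensities to 8-bit with a fixed [-0.25, 1.25] window so
    that regeneration from the same spec is bit-identical."""
    if path.exists():
        raise FileExistsError(f"output path collision: {path}")
    clipped = np.clip((np.asarray(image) + 0.25) / 1.5, 0.0, 1.0)
    Image.fromarray((clipped * 255).round().astype(np.uint8), mode="L").save(path)
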