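"""Multimodal MRI preprocessing: NIfTI loading, per-modality z-scoring over
brain voxels, fixed-size brain-centered cropping, one-hot label encoding and
geometric augmentation.

The on-disk layout is BraTS-style: one directory per case holding
``<case>_t1.nii.gz``, ``_t1ce``, ``_t2``, ``_flair`` and optionally
``_seg`` for the labels. Native volumes are 240 x 240 x 155 at 1 mm
isotropic; training crops to 160 x 192 x 128 centered on the brain. Crops
record their offset so predictions can be pasted back onto the native grid
for export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MODALITIES", "MultimodalVolume", "PreprocessedCase",
    "load_case", "save_case", "zscore_normalize", "crop_to_brain", "uncrop",
    "one_hot_encode", "one_hot_decode", "augment", "preprocess_case",
    "save_prediction",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
DEFAULT_CROP = (160, 192, 128)


@dataclass
class MultimodalVolume:
    """One case: the four co-registered modalities plus optional labels."""

    modalities: dict            # name -> (D, H, W) float array
    labels: np.ndarray | None = None
    spacing: tuple = (1.0, 1.0, 1.0)
    case_id: str = "case"
    affine: np.ndarray | None = None

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.modalities]
        if missing:
            raise ValueError(f"missing modalities: {missing}")
        shapes = {m: self.modalities[m].shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modalities disagree on shape: {shapes}")
        if self.labels is not None and self.labels.shape != self.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != image shape {self.shape}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple:
        return self.modalities[MODALITIES[0]].shape

    def stack(self) -> np.ndarray:
        return np.stack([self.modalities[m] for m in MODALITIES])


@dataclass
class PreprocessedCase:
    """Network-ready case: stacked z-scored image, one-hot labels, and the
    crop offset for pasting predictions back onto the native grid."""

    image: np.ndarray                      # (4, d, h, w) float32
    onehot: np.ndarray | None              # (M, d, h, w) uint8
    crop_offset: tuple                     # voxel offset of crop in native grid
    native_shape: tuple
    classes: tuple = (1, 2, 4)
    spacing: tuple = (1.0, 1.0, 1.0)
    case_id: str = "case"

    @property
    def labels(self) -> np.ndarray | None:
        if self.onehot is None:
            return None
        return one_hot_decode(self.onehot, self.classes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _case_paths(case_dir: Path) -> dict:
    case_dir = Path(case_dir)
    cid = case_dir.name
    paths = {m: case_dir / f"{cid}_{m}.nii.gz" for m in MODALITIES}
    paths["seg"] = case_dir / f"{cid}_seg.nii.gz"
    return paths


def load_case(source) -> MultimodalVolume:
    """Load a case from a BraTS-style directory, or from an explicit mapping
    {'t1': path, ..., 'seg': path (optional)}."""
    if isinstance(source, (str, Path)):
        paths = _case_paths(Path(source))
        case_id = Path(source).name
        if not paths["seg"].exists():
            paths.pop("seg")
    else:
        paths = dict(source)
        case_id = Path(paths[MODALITIES[0]]).name.split("_")[0]
    for m in MODALITIES:
        if m not in paths or not Path(paths[m]).exists():
            raise FileNotFoundError(f"missing modality '{m}' "
                                    f"(looked for {paths.get(m)})")
    imgs, affines = {}, {}
    for m in MODALITIES:
        img = nib.load(str(paths[m]))
        imgs[m] = np.asarray(img.dataobj, dtype=np.float32)
        affines[m] = img.affine
    ref = MODALITIES[0]
    for m in MODALITIES[1:]:
        if imgs[m].shape != imgs[ref].shape:
            raise ValueError(
                f"{paths[m]}: shape {imgs[m].shape} disagrees with "
                f"{paths[ref]}: {imgs[ref].shape}")
        if not np.allclose(affines[m], affines[ref], atol=1e-4):
            raise ValueError(f"{paths[m]}: affine disagrees with {paths[ref]}")
    labels = None
    if "seg" in paths and Path(paths["seg"]).exists():
        seg = nib.load(str(paths["seg"]))
        if seg.shape != imgs[ref].shape:
            raise ValueError(
                f"{paths['seg']}: label shape {seg.shape} disagrees with "
                f"image shape {imgs[ref].shape}")
        labels = np.rint(np.asarray(seg.dataobj)).astype(np.int16)
    affine = affines[ref]
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affine))
    return MultimodalVolume(modalities=imgs, labels=labels, spacing=spacing,
                            case_id=case_id, affine=affine)


def save_case(volume: MultimodalVolume, out_dir) -> Path:
    """Write a case in the BraTS directory layout; returns the case dir."""
    case_dir = Path(out_dir) / volume.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    for m in MODALITIES:
        nib.save(nib.Nifti1Image(volume.modalities[m].astype(np.float32),
                                 volume.affine),
                 str(case_dir / f"{volume.case_id}_{m}.nii.gz"))
    if volume.labels is not None:
        nib.save(nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine),
                 str(case_dir / f"{volume.case_id}_seg.nii.gz"))
    return case_dir


def save_prediction(labels: np.ndarray, affine: np.ndarray, path):
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine),
             str(path))


# ---------------------------------------------------------------------------
# Normalisation / cropping / encoding
# ---------------------------------------------------------------------------

def zscore_normalize(volume: np.ndarray) -> np.ndarray:
    """Standardise to zero mean / unit variance over *nonzero* (brain) voxels
    only; the zero background is left untouched."""
    volume = np.asarray(volume, dtype=np.float32)
    mask = volume != 0
    if not mask.any():
        raise ValueError("cannot z-score an all-zero volume")
    vals = volume[mask]
    std = float(vals.std())
    if std == 0.0:
        raise ValueError("cannot z-score a constant volume (zero std)")
    out = np.zeros_like(volume)
    out[mask] = (vals - float(vals.mean())) / std
    return out


def _brain_bbox(stack: np.ndarray):
    """Bounding box (lo, hi exclusive) of the union of nonzero voxels."""
    mask = np.any(stack != 0, axis=0)
    if not mask.any():
        raise ValueError("no nonzero voxels to crop around")
    coords = np.argwhere(mask)
    return coords.min(axis=0), coords.max(axis=0) + 1


def crop_to_brain(image: np.ndarray, labels: np.ndarray | None = None,
                  target_shape=DEFAULT_CROP):
    """Fixed-size crop centered on the nonzero bounding box of the stacked
    modalities (channel-first). Returns (cropped image, cropped labels or
    None, crop_offset). The offset may be negative when zero padding was
    needed near an edge; `uncrop` understands it either way."""
    image = np.asarray(image)
    target_shape = tuple(int(t) for t in target_shape)
    lo, hi = _brain_bbox(image)
    extent = hi - lo
    over = [(int(e), int(t)) for e, t in zip(extent, target_shape) if e > t]
    if over:
        raise ValueError(
            f"brain extent {tuple(int(e) for e in extent)} exceeds crop "
            f"target {target_shape}; refusing to truncate labels")
    center = (lo + hi) / 2.0
    start = np.rint(center - np.asarray(target_shape) / 2.0).astype(int)
    # keep the brain box inside the window, then keep the window on-grid
    start = np.minimum(start, lo)
    start = np.maximum(start, hi - np.asarray(target_shape))
    shape = np.asarray(image.shape[1:])

    out_img = np.zeros((image.shape[0],) + target_shape, dtype=image.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.asarray(target_shape), shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    s_src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    s_dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    out_img[(slice(None),) + s_dst] = image[(slice(None),) + s_src]
    out_lab = None
    if labels is not None:
        labels = np.asarray(labels)
        out_lab = np.zeros(target_shape, dtype=labels.dtype)
        out_lab[s_dst] = labels[s_src]
    return out_img, out_lab, tuple(int(s) for s in start)


def uncrop(cropped: np.ndarray, crop_offset: tuple, native_shape: tuple,
           fill=0) -> np.ndarray:
    """Paste a cropped volume back onto the native grid."""
    cropped = np.asarray(cropped)
    out = np.full(native_shape, fill, dtype=cropped.dtype)
    start = np.asarray(crop_offset)
    shape = np.asarray(native_shape)
    tgt = np.asarray(cropped.shape)
    src_lo = np.maximum(-start, 0)
    dst_lo = np.maximum(start, 0)
    n = np.minimum(start + tgt, shape) - dst_lo
    s_src = tuple(slice(a, a + k) for a, k in zip(src_lo, n))
    s_dst = tuple(slice(a, a + k) for a, k in zip(dst_lo, n))
    out[s_dst] = cropped[s_src]
    return out


def one_hot_encode(labels: np.ndarray, classes=(1, 2, 4)) -> np.ndarray:
    """Binary channel per class (background is not a channel — the network
    heads are independent sigmoids, so absence of every class encodes
    background)."""
    labels = np.asarray(labels)
    classes = tuple(classes)
    present = set(np.unique(labels).tolist())
    unexpected = sorted(present - set(classes) - {0})
    if unexpected:
        raise ValueError(f"unexpected label values {unexpected}; "
                         f"classes are {classes}")
    return np.stack([(labels == c) for c in classes]).astype(np.uint8)


def one_hot_decode(onehot: np.ndarray, classes=(1, 2, 4)) -> np.ndarray:
    """Inverse of `one_hot_encode` for mutually exclusive channels."""
    onehot = np.asarray(onehot)
    out = np.zeros(onehot.shape[1:], dtype=np.int16)
    for ch, c in enumerate(classes):
        out[onehot[ch] > 0] = c
    return out


def n4_bias_correct(volume: np.ndarray, spacing=(1.0, 1.0, 1.0),
                    shrink_factor: int = 4) -> np.ndarray:
    """Optional N4 bias-field correction, delegated to SimpleITK. Intended
    for scanner data; synthetic phantoms have no bias field and skip this."""
    import SimpleITK as sitk  # deliberate lazy import: optional step

    img = sitk.GetImageFromArray(np.asarray(volume, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    mask = sitk.Cast(img != 0, sitk.sitkUInt8)
    small = sitk.Shrink(img, [shrink_factor] * 3)
    small_mask = sitk.Shrink(mask, [shrink_factor] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(small, small_mask)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    corrected = sitk.GetArrayFromImage(img) / np.exp(
        sitk.GetArrayFromImage(log_field))
    return np.where(np.asarray(volume) != 0, corrected, 0.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _augment_matrix(rng: np.random.Generator, shape, max_rotate_deg: float,
                    max_shear: float, max_shift: int):
    angles = np.deg2rad(rng.uniform(-max_rotate_deg, max_rotate_deg, size=3))
    shears = rng.uniform(-max_shear, max_shear, size=3)
    shift = rng.integers(-max_shift, max_shift + 1, size=3).astype(float)
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shear = np.eye(3)
    shear[0, 1], shear[1, 2], shear[0, 2] = shears
    matrix = rot_x @ rot_y @ rot_z @ shear
    center = (np.asarray(shape) - 1) / 2.0
    # ndimage.affine_transform maps output coords through `matrix @ o + offset`
    offset = center - matrix @ (center + shift)
    return matrix, offset, shift


def augment(case: PreprocessedCase, seed: int, max_rotate_deg: float = 10.0,
            max_shear: float = 0.1, max_shift: int = 10) -> PreprocessedCase:
    """Random small-angle rotation + shear + integer shift, applied with the
    same geometric parameters to image (linear interpolation) and labels
    (nearest neighbour). Deterministic under `seed`; zero magnitudes leave
    the case unchanged."""
    rng = np.random.default_rng(seed)
    shape = case.image.shape[1:]
    matrix, offset, shift = _augment_matrix(
        rng, shape, max_rotate_deg, max_shear, max_shift)
    identity_linear = np.allclose(matrix, np.eye(3))
    image = np.empty_like(case.image)
    if identity_linear:
        for ch in range(case.image.shape[0]):  # pure integer shift: exact
            image[ch] = ndimage.shift(case.image[ch], shift, order=0,
                                      mode="constant", cval=0.0)
        onehot = None
        if case.onehot is not None:
            onehot = np.stack([
                ndimage.shift(case.onehot[ch], shift, order=0,
                              mode="constant", cval=0)
                for ch in range(case.onehot.shape[0])]).astype(np.uint8)
    else:
        for ch in range(case.image.shape[0]):
            image[ch] = ndimage.affine_transform(
                case.image[ch], matrix, offset=offset, order=1,
                mode="constant", cval=0.0)
        onehot = None
        if case.onehot is not None:
            onehot = np.stack([
                ndimage.affine_transform(case.onehot[ch], matrix, offset=offset,
                                         order=0, mode="constant", cval=0)
                for ch in range(case.onehot.shape[0])]).astype(np.uint8)
    return PreprocessedCase(image=image, onehot=onehot,
                            crop_offset=case.crop_offset,
                            native_shape=case.native_shape,
                            classes=case.classes, spacing=case.spacing,
                            case_id=case.case_id)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def preprocess_case(volume: MultimodalVolume, target_shape=DEFAULT_CROP,
                    classes=(1, 2, 4)) -> PreprocessedCase:
    """z-score each modality over its brain voxels, crop to the fixed window,
    one-hot the labels."""
    normalized = np.stack([zscore_normalize(volume.modalities[m])
                           for m in MODALITIES])
    image, labels, offset = crop_to_brain(normalized, volume.labels,
                                          target_shape=target_shape)
    onehot = one_hot_encode(labels, classes) if labels is not None else None
    return PreprocessedCase(image=image.astype(np.float32), onehot=onehot,
                            crop_offset=offset, native_shape=volume.shape,
                            classes=tuple(classes), spacing=volume.spacing,
                            case_id=volume.case_id)
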