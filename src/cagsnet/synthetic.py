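"""Synthetic multimodal brain-tumor phantoms.

Each phantom is a brain ellipsoid on a zero background carrying a nested
tumor: an edema shell (label 2) enclosing a tumor core whose rim enhances
(label 4) around a necrotic/non-enhancing center (label 1). Per-modality
intensities are piecewise constant with Gaussian noise and follow the
qualitative contrast rules of real glioma MRI:

* enhancing tumor is bright in T1ce relative to T1;
* edema is brightest in FLAIR (and bright in T2);
* the necrotic core is darker than the enhancing rim in T1ce.

These phantoms exercise every stage of the pipeline — I/O layout,
normalisation, cropping, one-hot encoding, training, inference, metrics —
without external data. They make no attempt at MRI physics (no partial
volume, no texture, no bias field unless requested).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import MODALITIES, MultimodalVolume, save_case

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "TISSUE_MEANS"]

# tissue -> modality -> mean intensity (arbitrary units)
TISSUE_MEANS = {
    "brain": {"t1": 1.0, "t1ce": 1.0, "t2": 1.0, "flair": 1.0},
    "ed":    {"t1": 0.8, "t1ce": 0.9, "t2": 1.6, "flair": 1.9},
    "et":    {"t1": 0.9, "t1ce": 1.8, "t2": 1.2, "flair": 1.3},
    "ncr":   {"t1": 0.7, "t1ce": 0.5, "t2": 1.4, "flair": 1.2},
}


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one phantom.

    Semi-axes are in voxels and must nest strictly:
    ED > ET(=TC boundary) > NCR. The tumor center is in voxel coordinates
    (defaults to the volume center)."""

    shape: tuple = (64, 64, 64)
    brain_radius_fraction: float = 0.42
    tumor_center: tuple | None = None
    ed_semi_axes: tuple = (14.0, 12.0, 10.0)
    et_semi_axes: tuple = (9.0, 8.0, 7.0)
    ncr_semi_axes: tuple = (5.0, 4.0, 3.5)
    tissue_means: dict = field(default_factory=lambda: TISSUE_MEANS)
    noise_sd: float = 0.05
    bias_field: bool = False
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    case_id: str = "phantom-000"

    def __post_init__(self):
        for outer, inner, names in (
                (self.ed_semi_axes, self.et_semi_axes, ("ED", "ET")),
                (self.et_semi_axes, self.ncr_semi_axes, ("ET", "NCR"))):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError(
                    f"{names[0]} semi-axes {outer} must strictly enclose "
                    f"{names[1]} semi-axes {inner}")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> MultimodalVolume:
    """Deterministically render one phantom from its spec."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    center = np.asarray(shape) / 2.0 - 0.5
    brain_axes = np.asarray(shape) * spec.brain_radius_fraction
    brain = _ellipsoid(shape, center, brain_axes)
    t_center = (center if spec.tumor_center is None
                else np.asarray(spec.tumor_center, dtype=float))
    ed = _ellipsoid(shape, t_center, spec.ed_semi_axes) & brain
    tc = _ellipsoid(shape, t_center, spec.et_semi_axes) & brain
    ncr = _ellipsoid(shape, t_center, spec.ncr_semi_axes) & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[ed] = 2          # edema shell
    labels[tc] = 4          # enhancing rim (overwrites inside TC)
    labels[ncr] = 1         # necrotic / non-enhancing center

    region_of = {"ed": ed & ~tc, "et": tc & ~ncr, "ncr": ncr}
    modalities = {}
    for m in MODALITIES:
        vol = np.zeros(shape, dtype=np.float32)
        vol[brain] = spec.tissue_means["brain"][m]
        for tissue, mask in region_of.items():
            vol[mask] = spec.tissue_means[tissue][m]
        if spec.bias_field:
            vol *= _smooth_bias(shape, rng)
        if spec.noise_sd > 0:
            vol[brain] += rng.normal(0.0, spec.noise_sd,
                                     size=int(brain.sum())).astype(np.float32)
        modalities[m] = vol
    affine = np.diag(list(spec.spacing) + [1.0])
    return MultimodalVolume(modalities=modalities, labels=labels,
                            spacing=spec.spacing, case_id=spec.case_id,
                            affine=affine)


def _smooth_bias(shape, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative field in [0.8, 1.2] (exercises the N4
    hook; off by default)."""
    grids = np.meshgrid(*[np.linspace(0, np.pi, s) for s in shape],
                        indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, size=3)
    field = sum(np.cos(g + p) for g, p in zip(grids, phase)) / 3.0
    return (1.0 + 0.2 * field).astype(np.float32)


def random_spec(rng: np.random.Generator, shape=(64, 64, 64),
                case_id: str = "phantom") -> PhantomSpec:
    """A randomized nested tumor: center jittered inside the brain, sizes
    drawn within fixed nesting-safe ranges."""
    shape = tuple(int(s) for s in shape)
    center = np.asarray(shape) / 2.0 - 0.5
    jitter = rng.uniform(-0.08, 0.08, size=3) * np.asarray(shape)
    ed = rng.uniform(0.18, 0.24, size=3) * np.asarray(shape)
    et = ed * rng.uniform(0.60, 0.70, size=3)
    ncr = et * rng.uniform(0.45, 0.55, size=3)
    return PhantomSpec(shape=shape, tumor_center=tuple(center + jitter),
                       ed_semi_axes=tuple(ed), et_semi_axes=tuple(et),
                       ncr_semi_axes=tuple(ncr),
                       seed=int(rng.integers(0, 2 ** 31)), case_id=case_id)


def generate_dataset(n: int, seed: int, out_dir, shape=(64, 64, 64)) -> list:
    """Write `n` randomized phantoms in the BraTS directory layout plus a
    manifest.csv; returns the case directories."""
    if n < 1:
        raise ValueError(f"need n >= 1 cases, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    case_dirs, rows = [], []
    for i in range(n):
        spec = random_spec(rng, shape=shape, case_id=f"phantom-{i:03d}")
        volume = generate_phantom(spec)
        case_dirs.append(save_case(volume, out_dir))
        counts = {f"n_label{c}": int((volume.labels == c).sum())
                  for c in (1, 2, 4)}
        rows.append({"case_id": spec.case_id, "seed": spec.seed,
                     "shape": "x".join(map(str, shape)), **counts})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return case_dirs
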