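"""Generate a small synthetic dataset and push one case through
preprocessing.

Each phantom is a brain ellipsoid with a nested tumor (edema shell around an
enhancing rim around a necrotic center) whose modality contrasts follow real
glioma MRI: enhancement bright in T1ce, edema bright in FLAIR, necrosis dark
in T1ce.
"""

import tempfile
from pathlib import Path

import numpy as np

from cagsnet.preprocessing import load_case, preprocess_case
from cagsnet.synthetic import generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    dirs = generate_dataset(n=3, seed=0, out_dir=Path(tmp) / "data",
                            shape=(64, 64, 64))
    print(f"wrote {len(dirs)} cases:", [d.name for d in dirs])

    vol = load_case(dirs[0])
    print(f"case {vol.case_id}: image {vol.shape}, labels "
          f"{sorted(np.unique(vol.labels).tolist())}")
    for c, name in ((1, "NCR/NET"), (2, "ED"), (4, "ET")):
        print(f"  label {c} ({name}): {(vol.labels == c).sum()} voxels")
    t1ce = vol.modalities["t1ce"]
    print(f"  T1ce mean over ET {t1ce[vol.labels == 4].mean():.2f} vs "
          f"NCR {t1ce[vol.labels == 1].mean():.2f} (enhancement contrast)")

    case = preprocess_case(vol, target_shape=(64, 64, 64))
    brain = case.image[0] != 0
    print(f"preprocessed: image {case.image.shape}, one-hot "
          f"{case.onehot.shape}, crop offset {case.crop_offset}")
    print(f"  z-scored T1 brain voxels: mean {case.image[0][brain].mean():+.1e}, "
          f"std {case.image[0][brain].std():.4f}")
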