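"""On-disk dataset layout, preprocessing and patient-level partitioning.

Layout::

    root/images/<patient_id>/<level_name>_<slice_idx>.png   8-bit grayscale
    root/manifest.csv   columns: patient_id, level_name, level_index, path

Splitting is always by PATIENT, never by image: a subject contributes slices
to exactly one of train/test and to exactly one cross-validation fold, so no
patient's anatomy leaks across partitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .synthetic_data import DEFAULT_LEVEL_NAMES, SyntheticCohort

__all__ = [
    "DatasetManifest",
    "SplitPlan",
    "default_level_map",
    "export_cohort",
    "read_manifest",
    "write_manifest",
    "load_image",
    "patient_split",
    "kfold_by_patient",
    "preprocess_image",
]

MANIFEST_COLUMNS = ["patient_id", "level_name", "level_index", "path"]


def default_level_map(n_levels: int) -> dict[str, int]:
    """T12, L1.. for the 5-level study; generic ``LVL<k>`` otherwise."""
    if n_levels == len(DEFAULT_LEVEL_NAMES):
        return {name: i for i, name in enumerate(DEFAULT_LEVEL_NAMES)}
    return {f"LVL{i}": i for i in range(n_levels)}


@dataclass
class DatasetManifest:
    """Table of slice records plus the level-name map, anchored at ``root``."""

    frame: pd.DataFrame
    level_map: dict[str, int]
    root: Path

    @property
    def n_levels(self) -> int:
        return len(self.level_map)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.frame["patient_id"].unique())

    def rows_for_patients(self, ids) -> pd.DataFrame:
        return self.frame[self.frame["patient_id"].isin(set(ids))]


@dataclass
class SplitPlan:
    """Disjoint train/test patient sets plus fold assignments on train."""

    train_patient_ids: list[str]
    test_patient_ids: list[str]
    folds: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.train_patient_ids) & set(self.test_patient_ids):
            raise ValueError("train and test patient sets overlap")
        if self.folds and set(self.folds) != set(self.train_patient_ids):
            raise ValueError("fold assignments must cover exactly the training patients")

    def fold_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.folds.items() if f == fold)

    @property
    def n_folds(self) -> int:
        return len(set(self.folds.values())) if self.folds else 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_patient_ids": self.train_patient_ids,
                    "test_patient_ids": self.test_patient_ids,
                    "folds": self.folds,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        plan = cls(
            train_patient_ids=list(d["train_patient_ids"]),
            test_patient_ids=list(d["test_patient_ids"]),
            folds={k: int(v) for k, v in d.get("folds", {}).items()},
        )
        plan.validate()
        return plan


# ---------------------------------------------------------------------------
# export / read / write
# ---------------------------------------------------------------------------


def export_cohort(cohort: SyntheticCohort, root: str | Path) -> DatasetManifest:
    """Write a cohort as 8-bit grayscale PNGs + manifest.csv under ``root``."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    level_map = default_level_map(cohort.config.n_levels)
    names = {i: n for n, i in level_map.items()}
    rows = []
    for patient in cohort.patients:
        pdir = root / "images" / patient.patient_id
        pdir.mkdir(exist_ok=True)
        per_level_idx: dict[int, int] = {}
        for img, lab in patient.slices:
            k = per_level_idx.get(lab.c, 0)
            per_level_idx[lab.c] = k + 1
            rel = f"images/{patient.patient_id}/{names[lab.c]}_{k:02d}.png"
            arr8 = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr8, mode="L").save(root / rel)
            rows.append((patient.patient_id, names[lab.c], lab.c, rel))
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = DatasetManifest(frame=frame, level_map=level_map, root=root)
    write_manifest(manifest, root / "manifest.csv")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.frame[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(
    path: str | Path, level_map: dict[str, int] | None = None
) -> DatasetManifest:
    """Load and validate a manifest CSV; ``root`` is the CSV's directory."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing manifest at {path}")
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest missing required columns {missing}")
    if frame.empty:
        raise ValueError(f"manifest at {path} contains no rows")
    if level_map is None:
        n_levels = int(frame["level_index"].max()) + 1
        level_map = default_level_map(n_levels)
    for idx, row in frame.iterrows():
        name = row["level_name"]
        if name not in level_map:
            raise ValueError(f"row {idx}: unknown level name {name!r}")
        if int(row["level_index"]) != level_map[name]:
            raise ValueError(f"row {idx}: level_index inconsistent with map for {name!r}")
    if frame["path"].duplicated().any():
        raise ValueError("manifest contains duplicate image paths")
    root = path.parent
    for idx, rel in frame["path"].items():
        if not (root / rel).exists():
            raise ValueError(f"row {idx}: image file {rel!r} not found under {root}")
    return DatasetManifest(frame=frame, level_map=level_map, root=root)


def load_image(manifest: DatasetManifest, rel_path: str) -> np.ndarray:
    """Read one slice as float in [0, 1]."""
    with Image.open(manifest.root / rel_path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


def patient_split(
    manifest: DatasetManifest, ratio: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Shuffle patients with ``seed``; first ``floor(ratio * n)`` go to train.

    84 patients at ratio 0.8 give the study's 67 train / 17 test partition.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    ids = manifest.patient_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train = int(np.floor(ratio * len(ids)))
    plan = SplitPlan(
        train_patient_ids=sorted(perm[:n_train]),
        test_patient_ids=sorted(perm[n_train:]),
    )
    plan.validate()
    return plan


def kfold_by_patient(train_ids, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Assign training patients to ``k`` folds differing in size by at most 1.

    67 patients at k = 10 yield seven folds of 7 and three of 6.
    """
    ids = sorted(train_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of patients ({len(ids)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    # larger folds first: sizes ceil then floor
    folds: dict[str, int] = {}
    sizes = [(len(ids) + k - 1 - f) // k for f in range(k)]
    pos = 0
    for f, size in enumerate(sizes):
        for pid in perm[pos : pos + size]:
            folds[pid] = f
        pos += size
    return folds


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_image(
    image: np.ndarray,
    target_size: tuple[int, int],
    border_threshold: float = 0.02,
) -> np.ndarray:
    """Crop black margins, aspect-preserving resize, pad to ``target_size``.

    1. strip maximal border rows/columns whose intensities all fall below
       ``border_threshold`` x the image maximum (scanner margins);
    2. resize the content with a single scale factor on both axes so anatomy
       is never distorted;
    3. pad symmetrically with zeros to exactly ``target_size``;
    4. min-max normalise to [0, 1] (the desk-scale CNN convention).

    A fully black image short-circuits to a zero canvas with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    th, tw = target_size
    peak = img.max()
    if peak <= 0:
        warnings.warn("fully black image; returning a zero canvas")
        return np.zeros((th, tw))

    keep = img > border_threshold * peak
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    img = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]

    h, w = img.shape
    scale = min(th / h, tw / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    content = _sk_resize(img, (nh, nw), anti_aliasing=True, preserve_range=True)

    out = np.zeros((th, tw))
    top, left = (th - nh) // 2, (tw - nw) // 2
    out[top : top + nh, left : left + nw] = content
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    return out
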