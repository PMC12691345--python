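"""Seeded generator of vertebral-series-like ordinal image cohorts.

The real study data — axial CT slices from ~84 patients at five ordered
vertebral levels (T12, L1..L4), 4-6 slices per level per patient — is private.
This module emulates its *structure* so every downstream stage (preprocessing,
patient-level splitting, training, evaluation) is exercisable end to end:

* each slice is a grayscale canvas with a bright elliptical "vertebral body"
  flanked by two smaller lateral structures;
* level identity is encoded geometrically: the body's vertical position and
  radius and the flanking offsets shift monotonically by ``level_separation``
  per level step, so adjacent levels look more alike than distant ones;
* a per-patient random effect jitters the whole geometry coherently across
  that patient's slices, inducing within-patient correlation and making
  patient-level splits genuinely harder than random slice splits;
* i.i.d. Gaussian pixel noise with sd ``noise_sd``, clipped to [0, 1].

All randomness flows from one ``numpy`` generator seeded by the config; the
same config yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encodings import OrdinalLabel

__all__ = [
    "SyntheticConfig",
    "PatientSeries",
    "SyntheticCohort",
    "generate_cohort",
    "cohort_difficulty_profile",
    "DEFAULT_LEVEL_NAMES",
]

DEFAULT_LEVEL_NAMES = ("T12", "L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generation parameters.

    ``level_separation`` is the geometric shift per level step expressed as a
    fraction of the image height; ``noise_sd`` the pixel-noise sd on a [0, 1]
    intensity scale; ``patient_effect_sd`` the sd of the shared per-patient
    geometric jitter (same units as ``level_separation``). The defaults give a
    strong ordinal signal (separation = 3 x noise sd) mirroring the clear
    anatomical differences between vertebral levels.
    """

    n_patients: int = 84
    n_levels: int = 5
    slices_per_level_range: tuple[int, int] = (4, 6)
    image_size: tuple[int, int] = (64, 64)
    level_separation: float = 0.15
    noise_sd: float = 0.05
    patient_effect_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        lo, hi = self.slices_per_level_range
        if not 1 <= lo <= hi:
            raise ValueError("slices_per_level_range must satisfy 1 <= min <= max")
        if min(self.image_size) < 8:
            raise ValueError("image_size must be at least 8x8")
        if self.level_separation < 0:
            raise ValueError("level_separation must be >= 0")
        if self.noise_sd < 0 or self.patient_effect_sd < 0:
            raise ValueError("noise_sd and patient_effect_sd must be >= 0")


@dataclass
class PatientSeries:
    """One patient's slices: list of (image, level) pairs."""

    patient_id: str
    slices: list[tuple[np.ndarray, OrdinalLabel]]

    def level_counts(self, n_levels: int) -> np.ndarray:
        counts = np.zeros(n_levels, dtype=int)
        for _, lab in self.slices:
            counts[lab.c] += 1
        return counts


@dataclass
class SyntheticCohort:
    patients: list[PatientSeries]
    config: SyntheticConfig

    @property
    def n_slices(self) -> int:
        return sum(len(p.slices) for p in self.patients)

    def level_counts(self) -> np.ndarray:
        """Per-level slice counts over the whole cohort."""
        total = np.zeros(self.config.n_levels, dtype=int)
        for p in self.patients:
            total += p.level_counts(self.config.n_levels)
        return total


def _ellipse(canvas: np.ndarray, cy: float, cx: float, ry: float, rx: float,
             intensity: float) -> None:
    """Additively draw a soft-edged ellipse (in-place)."""
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / max(ry, 1e-6)) ** 2 + ((xx - cx) / max(rx, 1e-6)) ** 2
    canvas += intensity * np.clip(1.2 - r2, 0.0, 1.0).clip(max=1.0)


def _render_slice(
    level: int, cfg: SyntheticConfig, patient_fx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    h, w = cfg.image_size
    sep = cfg.level_separation
    # centred level coordinate so the mid-level sits mid-canvas
    u = level - (cfg.n_levels - 1) / 2.0
    jit = 0.2 * sep * rng.standard_normal(3)  # small per-slice geometric wobble

    img = np.zeros((h, w))
    # vertebral body: vertical position and (slightly) radius grow with level.
    # Coefficients keep extreme levels overlapping at the default separation so
    # pixel-space distance keeps growing with rank distance instead of
    # saturating once the ellipses disengage.
    cy = h * np.clip(0.5 + 0.45 * sep * u + patient_fx[0] + jit[0], 0.15, 0.85)
    body_r = h * np.clip(0.16 + 0.08 * sep * u + patient_fx[1] + jit[1], 0.06, 0.40)
    _ellipse(img, cy, w * 0.5, body_r, body_r * 1.25, 0.9)
    # flanking structures (transverse-process stand-ins) swing outward with level
    off = w * np.clip(0.26 + 0.35 * sep * u + patient_fx[2] + jit[2], 0.08, 0.44)
    for side in (-1.0, 1.0):
        _ellipse(img, cy, w * 0.5 + side * off, h * 0.05, w * 0.07, 0.55)

    if cfg.noise_sd > 0:
        img += cfg.noise_sd * rng.standard_normal((h, w))
    return np.clip(img, 0.0, 1.0)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort deterministically from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.slices_per_level_range
    width = len(str(max(config.n_patients - 1, 1)))
    patients = []
    for pi in range(config.n_patients):
        patient_fx = config.patient_effect_sd * rng.standard_normal(3)
        slices: list[tuple[np.ndarray, OrdinalLabel]] = []
        for level in range(config.n_levels):
            n_slices = int(rng.integers(lo, hi + 1))
            for _ in range(n_slices):
                img = _render_slice(level, config, patient_fx, rng)
                slices.append((img, OrdinalLabel(level, config.n_levels)))
        patients.append(PatientSeries(patient_id=f"P{pi:0{width}d}", slices=slices))
    return SyntheticCohort(patients=patients, config=config)


def cohort_difficulty_profile(
    cohort: SyntheticCohort, max_per_level: int = 40, seed: int = 0
) -> np.ndarray:
    """Matrix of mean Euclidean inter-level image distances.

    Entry (j, k) averages pixel-space distances between level-j and level-k
    slices (subsampled to ``max_per_level`` per level for tractability). When
    the level signal dominates the noise, each row increases away from the
    diagonal: adjacent levels are more alike than distant ones — the structure
    the ordinal losses exploit.
    """
    n_levels = cohort.config.n_levels
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    rng = np.random.default_rng(seed)
    by_level: list[list[np.ndarray]] = [[] for _ in range(n_levels)]
    for p in cohort.patients:
        for img, lab in p.slices:
            by_level[lab.c].append(img.ravel())
    stacks = []
    for imgs in by_level:
        arr = np.array(imgs)
        if arr.shape[0] > max_per_level:
            arr = arr[rng.choice(arr.shape[0], max_per_level, replace=False)]
        stacks.append(arr)
    out = np.zeros((n_levels, n_levels))
    for j in range(n_levels):
        for k in range(j, n_levels):
            a, b = stacks[j], stacks[k]
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
            if j == k:
                mask = ~np.eye(a.shape[0], dtype=bool)
                out[j, k] = d[mask].mean() if mask.any() else 0.0
            else:
                out[j, k] = out[k, j] = d.mean()
    return out
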