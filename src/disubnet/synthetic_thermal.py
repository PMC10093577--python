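"""Synthetic grayscale thermal pig scenes.

The study's FLIR-camera dataset is not publicly deposited, so this module
generates stand-in scenes with the same class structure: four treatment
groups (IAF/IBF = a single pig imaged in isolation, PAF/PBF = a pair of
pigs), imaged before or after feeding.  A scene is a 112x112 grayscale
image in [0, 1]: a cool background with a mild vertical gradient, one or two
warm elliptical pig bodies with smoothed edges, a post-feeding intensity
increment on the bodies of the after-feeding classes, and additive Gaussian
pixel noise.

Everything is deterministic given (label, params, seed).  The defaults are
synthetic calibration constants chosen for guaranteed class separability;
they are not fitted to real FLIR imagery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "IMAGE_SIZE",
    "SceneParams",
    "ThermalScene",
    "DatasetManifest",
    "SceneSet",
    "generate_scene",
    "plan_dataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "scene_components",
    "threshold_classify",
    "largest_remainder",
]

#: fixed class order used everywhere (confusion matrices, manifests, one-hot)
CLASS_NAMES = ("IAF", "IBF", "PAF", "PBF")
_AFTER_FEEDING = frozenset({"IAF", "PAF"})
_SINGLE_PIG = frozenset({"IAF", "IBF"})
IMAGE_SIZE = 112
SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SceneParams:
    """Generation constants for one scene family.

    Intensities are dimensionless in [0, 1].  ``feeding_delta`` is added to
    the body intensity of after-feeding classes and must exceed twice the
    pixel noise so the before/after contrast survives averaging over a body.
    """

    background_level: float = 0.2
    background_gradient: float = 0.0005  # intensity per row, top to bottom
    body_base: float = 0.6
    feeding_delta: float = 0.15
    blob_axes: tuple[tuple[float, float], tuple[float, float]] = ((11.0, 13.0), (7.5, 9.0))
    noise_sd: float = 0.05
    overlap_allowed: bool = False
    edge_softness: float = 2.0  # Gaussian sigma (pixels) smoothing blob edges

    def __post_init__(self) -> None:
        if not self.feeding_delta > 2 * self.noise_sd:
            raise ValueError(
                "feeding_delta must exceed 2 * noise_sd so the feeding contrast "
                "is separable by construction"
            )
        (a_lo, a_hi), (b_lo, b_hi) = self.blob_axes
        if not (0 < a_lo <= a_hi and 0 < b_lo <= b_hi):
            raise ValueError("blob_axes ranges must be positive and ordered")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneParams":
        doc = yaml.safe_load(text)
        doc["blob_axes"] = tuple(tuple(r) for r in doc["blob_axes"])
        return cls(**doc)


@dataclass(frozen=True)
class ThermalScene:
    """One synthetic image with its label and generation provenance."""

    image: np.ndarray  # (112, 112) float in [0, 1]
    label: str
    n_pigs: int
    body_mean_intensity: float
    seed: int

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ValueError(f"unknown label {self.label!r}")
        expected = 1 if self.label in _SINGLE_PIG else 2
        if self.n_pigs != expected:
            raise ValueError(f"label {self.label} implies {expected} pigs, got {self.n_pigs}")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(label: str, params: SceneParams = SceneParams(),
                   seed: int = 0) -> ThermalScene:
    """Render one scene; deterministic given (label, params, seed).

    Bodies are placed uniformly at random with a margin keeping the full
    ellipse inside the frame; with ``overlap_allowed=False`` a second pig is
    re-drawn until it clears the first (an impossible placement raises).
    """
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, CLASS_NAMES.index(label)]))
    size = IMAGE_SIZE
    n_pigs = 1 if label in _SINGLE_PIG else 2

    rows = np.arange(size, dtype=np.float64)[:, None]
    img = params.background_level + params.background_gradient * rows * np.ones((1, size))

    body = params.body_base + (params.feeding_delta if label in _AFTER_FEEDING else 0.0)
    (a_lo, a_hi), (b_lo, b_hi) = params.blob_axes
    margin = a_hi + 3 * params.edge_softness
    if 2 * margin >= size:
        raise ValueError("blob axes too large for the frame")

    placed: list[tuple[float, float, float]] = []  # (cy, cx, a)
    mask_total = np.zeros((size, size), dtype=bool)
    for _ in range(n_pigs):
        for attempt in range(200):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(b_lo, b_hi)
            theta = rng.uniform(0, np.pi)
            if params.overlap_allowed or all(
                np.hypot(cy - py, cx - px) > a + pa + 4 * params.edge_softness + 4
                for py, px, pa in placed
            ):
                placed.append((cy, cx, a))
                mask_total |= _ellipse_mask(size, cy, cx, a, b, theta)
                break
        else:
            raise ValueError("could not place a pig body inside the frame")

    soft = ndimage.gaussian_filter(mask_total.astype(np.float64), params.edge_softness)
    img = img * (1 - soft) + body * soft
    img += rng.normal(0.0, params.noise_sd, size=(size, size))
    img = np.clip(img, 0.0, 1.0)

    fg = soft > 0.9  # body interior; the smoothed rim would dilute the mean
    mean_fg = float(img[fg].mean()) if fg.any() else 0.0
    return ThermalScene(image=img, label=label, n_pigs=n_pigs,
                        body_mean_intensity=mean_fg, seed=seed)


# ---------------------------------------------------------------------------
# dataset planning


def largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``n`` by the largest-remainder rule."""
    raw = np.asarray(fractions, dtype=np.float64) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


@dataclass
class DatasetManifest:
    """Path/label/split table plus the planning inputs that produced it."""

    frame: pd.DataFrame  # columns: path, label, split
    split_fractions: tuple[float, float, float]
    class_proportions: dict[str, float]
    seed: int

    def counts(self) -> pd.DataFrame:
        return self.frame.groupby(["label", "split"], observed=True).size().unstack(fill_value=0)

    def split_sizes(self) -> dict[str, int]:
        sizes = self.frame["split"].value_counts().to_dict()
        return {s: int(sizes.get(s, 0)) for s in SPLIT_NAMES}

    def non_training_size(self) -> int:
        """The combined validation+test pool (the 40% complement of training)."""
        sizes = self.split_sizes()
        return sizes["val"] + sizes["test"]


def plan_dataset(n: int,
                 class_proportions: dict[str, float] | None = None,
                 split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0) -> DatasetManifest:
    """Apportion ``n`` scenes over classes and splits (no rendering).

    Class counts use the largest-remainder rule on ``class_proportions``;
    split assignment is stratified per class with the same rule, then rows
    are shuffled deterministically.
    """
    if class_proportions is None:
        class_proportions = {c: 1.0 / len(CLASS_NAMES) for c in CLASS_NAMES}
    if set(class_proportions) != set(CLASS_NAMES):
        raise ValueError(f"class_proportions must cover exactly {CLASS_NAMES}")
    if abs(sum(class_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if n < len(CLASS_NAMES):
        raise ValueError(f"need at least {len(CLASS_NAMES)} scenes, got {n}")

    per_class = largest_remainder(n, np.array([class_proportions[c] for c in CLASS_NAMES]))
    rows = []
    idx = 0
    for cls, total in zip(CLASS_NAMES, per_class):
        per_split = largest_remainder(int(total), np.asarray(split_fractions))
        for split, count in zip(SPLIT_NAMES, per_split):
            for _ in range(count):
                rows.append((f"{cls}/{cls}_{idx:06d}.png", cls, split))
                idx += 1
    frame = pd.DataFrame(rows, columns=["path", "label", "split"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    return DatasetManifest(frame=frame, split_fractions=tuple(split_fractions),
                           class_proportions=dict(class_proportions), seed=seed)


class SceneSet:
    """Lazily rendered scene collection backing a manifest.

    Scene ``i`` is rendered on demand with a per-row seed derived from the
    manifest seed and the row's position, so repeated access (and repeated
    runs) is byte-identical.
    """

    def __init__(self, manifest: DatasetManifest, params: SceneParams):
        self.manifest = manifest
        self.params = params

    def __len__(self) -> int:
        return len(self.manifest.frame)

    def row_seed(self, i: int) -> int:
        mix = np.random.SeedSequence([self.manifest.seed, int(i)])
        return int(mix.generate_state(1, dtype=np.uint32)[0])

    def __getitem__(self, i: int) -> ThermalScene:
        row = self.manifest.frame.iloc[i]
        return generate_scene(row["label"], self.params, seed=self.row_seed(i))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(images (n, 112, 112, 1) float32, integer labels) for training."""
        n = len(self)
        x = np.empty((n, IMAGE_SIZE, IMAGE_SIZE, 1), dtype=np.float32)
        y = np.empty(n, dtype=np.int64)
        for i in range(n):
            scene = self[i]
            x[i, :, :, 0] = scene.image
            y[i] = CLASS_NAMES.index(scene.label)
        return x, y

    def split_arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero((self.manifest.frame["split"] == split).to_numpy())
        if idx.size == 0:
            raise ValueError(f"split {split!r} is empty")
        x = np.empty((idx.size, IMAGE_SIZE, IMAGE_SIZE, 1), dtype=np.float32)
        y = np.empty(idx.size, dtype=np.int64)
        for j, i in enumerate(idx):
            scene = self[int(i)]
            x[j, :, :, 0] = scene.image
            y[j] = CLASS_NAMES.index(scene.label)
        return x, y


def generate_dataset(n: int,
                     class_proportions: dict[str, float] | None = None,
                     params: SceneParams = SceneParams(),
                     split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> tuple[SceneSet, DatasetManifest]:
    """Plan a manifest and attach a lazily rendered scene collection."""
    manifest = plan_dataset(n, class_proportions, split_fractions, seed)
    return SceneSet(manifest, params), manifest


# ---------------------------------------------------------------------------
# disk round-trip


def write_dataset(scenes: SceneSet, manifest: DatasetManifest, root_dir: str | Path) -> None:
    """8-bit grayscale PNGs under class subdirectories plus manifest.csv."""
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    for i in range(len(scenes)):
        row = manifest.frame.iloc[i]
        scene = scenes[i]
        out = root / row["path"]
        out.parent.mkdir(parents=True, exist_ok=True)
        arr = np.round(scene.image * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out)
    manifest.frame.to_csv(root / "manifest.csv", index=False)


class _LoadedScenes(SceneSet):
    def __init__(self, manifest: DatasetManifest, root: Path):
        super().__init__(manifest, SceneParams())
        self.root = root

    def __getitem__(self, i: int) -> ThermalScene:
        row = self.manifest.frame.iloc[i]
        arr = np.asarray(Image.open(self.root / row["path"]).convert("L"), dtype=np.float64)
        img = arr / 255.0
        n_pigs = 1 if row["label"] in _SINGLE_PIG else 2
        return ThermalScene(image=img, label=row["label"], n_pigs=n_pigs,
                            body_mean_intensity=float("nan"), seed=-1)


def read_dataset(root_dir: str | Path) -> tuple[SceneSet, DatasetManifest]:
    """Inverse of :func:`write_dataset` on quantized images."""
    root = Path(root_dir)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest.csv under {root}")
    frame = pd.read_csv(manifest_path)
    bad = set(frame["label"]) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"manifest contains unknown labels: {sorted(bad)}")
    for p, lbl in zip(frame["path"], frame["label"]):
        if not str(p).startswith(f"{lbl}/"):
            raise ValueError(f"path {p!r} not under its label directory {lbl!r}")
        if not (root / p).exists():
            raise FileNotFoundError(f"image listed in manifest is missing: {p}")
    manifest = DatasetManifest(frame=frame, split_fractions=(0.6, 0.2, 0.2),
                               class_proportions={}, seed=-1)
    return _LoadedScenes(manifest, root), manifest


# ---------------------------------------------------------------------------
# desk-scale reference classifier


def scene_components(image: np.ndarray, params: SceneParams = SceneParams(),
                     min_size: int = 20) -> int:
    """Count connected warm regions above the background/body midpoint.

    Isolated noise spikes are excluded by ``min_size`` (pixels); pig bodies
    span hundreds of pixels, so the count equals the number of pigs for
    default parameters.
    """
    thresh = 0.5 * (params.background_level + params.body_base)
    labels, n = ndimage.label(image > thresh)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(image), labels, index=np.arange(1, n + 1))
    return int((sizes >= min_size).sum())


def threshold_classify(image: np.ndarray, params: SceneParams = SceneParams()) -> str:
    """Two-threshold rule: foreground pixel count -> 1 vs 2 pigs; foreground
    mean intensity -> before vs after feeding.

    This desk-scale oracle guarantees the CNN task is learnable: if two fixed
    thresholds separate the classes, a convolutional model certainly can.
    """
    thresh = 0.5 * (params.background_level + params.body_base)
    fg = image > thresh
    (a_lo, a_hi), (b_lo, b_hi) = params.blob_axes
    # 1.5x the mean single-body area sits above any one smoothed body and
    # below any two, because the axis ranges keep max/min body area < 2
    area_cut = 1.5 * np.pi * 0.5 * (a_lo + a_hi) * 0.5 * (b_lo + b_hi)
    paired = fg.sum() > area_cut
    # body-core pixels still include part of the smoothed rim, which pulls
    # both class means down by a similar amount; the midpoint of the diluted
    # means sits near body_base + delta/4
    core = image > params.body_base - 0.5 * params.feeding_delta
    mean_core = image[core].mean() if core.any() else 0.0
    after = mean_core > params.body_base + 0.25 * params.feeding_delta
    if paired:
        return "PAF" if after else "PBF"
    return "IAF" if after else "IBF"
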