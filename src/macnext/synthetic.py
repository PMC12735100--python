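"""Synthetic agar-plate colony image generator.

The reference bacterial image collection (18,221 colony photographs, 24
species, blood-agar plates) is private, so this module emulates its
*structure*: the exact per-class sample counts (scalable), a class-per-folder
PNG layout with a CSV manifest, and strong class imbalance (2562 vs 177
samples). Images are procedurally rendered plates — a red-brown agar disc
under a mild illumination gradient, carrying a random number of roughly
circular colonies whose color, size, border roughness, surface grain and
optional hemolysis-like halo ring are class parameters.

The morphology parameterization is invented plumbing: it is tuned only so
that classes are visually plate-like and separable (a learnable signal), and
it makes no claim of biological fidelity to any species. Rendering is a pure
function of (spec, size, seed), so full datasets are reproducible byte for
byte.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "TABLE1_CLASSES",
    "TABLE1_TOTAL",
    "ClassSpec",
    "DatasetManifest",
    "table1_manifest",
    "default_class_specs",
    "render_plate_image",
    "generate_dataset",
    "render_arrays",
]

#: (class id, species name, sample count) of the reference 24-class collection.
TABLE1_CLASSES: list[tuple[int, str, int]] = [
    (1, "Acinetobacter baumannii", 535),
    (2, "Burkholderia cepacia", 272),
    (3, "Citrobacter freundii", 337),
    (4, "Hemolytic Escherichia coli", 1860),
    (5, "Non-hemolytic Escherichia coli", 2562),
    (6, "Enterobacter aerogenes", 292),
    (7, "Enterobacter cloacae", 208),
    (8, "Enterococcus gallinarum", 215),
    (9, "Enterococcus faecalis", 2214),
    (10, "Enterococcus faecium", 1013),
    (11, "Klebsiella oxytoca", 882),
    (12, "Klebsiella pneumoniae", 1378),
    (13, "Morganella morganii", 177),
    (14, "Proteus mirabilis", 387),
    (15, "Staphylococcus saprophyticus", 209),
    (16, "Staphylococcus aureus", 1364),
    (17, "Staphylococcus epidermidis", 2078),
    (18, "Staphylococcus haemolyticus", 311),
    (19, "Staphylococcus hominis", 527),
    (20, "Stenotrophomonas maltophilia", 306),
    (21, "Streptococcus pyogenes", 199),
    (22, "Streptococcus agalactiae", 265),
    (23, "Streptococcus anginosus", 256),
    (24, "Streptococcus mitis", 374),
]

TABLE1_TOTAL = sum(c for _, _, c in TABLE1_CLASSES)  # 18,221

#: ids of species rendered with a hemolysis-like halo ring (beta-hemolytic
#: colonies clear the blood agar around themselves).
_HALO_CLASSES = {4, 16, 18, 21, 22}


@dataclass
class ClassSpec:
    """Morphology parameters of one synthetic colony class."""

    class_id: int
    species_name: str
    colony_radius: tuple[float, float]  # mean, spread (pixels at 224px scale)
    colony_count: tuple[float, float]  # mean, spread per plate
    base_color: tuple[int, int, int]
    halo: bool = False
    halo_width: float = 4.0  # ring width, pixels at 224px scale
    halo_shift: tuple[int, int, int] = (35, 25, 10)  # additive RGB shift
    border_roughness: float = 0.08  # radial perturbation amplitude in [0, 1]
    texture_grain: float = 0.03  # multiplicative surface-noise scale

    def __post_init__(self):
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError(f"base_color out of RGB range: {self.base_color}")
        if self.colony_radius[0] <= 0 or self.colony_count[0] <= 0:
            raise ValueError("colony radius and count means must be positive")
        if not (0 <= self.border_roughness <= 1):
            raise ValueError("border_roughness must lie in [0, 1]")


@dataclass
class DatasetManifest:
    """Per-class image counts plus the scale and seed that produced them."""

    entries: list[tuple[int, str, int]]  # (class_id, species_name, count)
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(c < 1 for _, _, c in self.entries):
            raise ValueError("all per-class counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.entries)

    def counts(self) -> dict[int, int]:
        return {cid: c for cid, _, c in self.entries}


def table1_manifest(scale: float = 1.0, min_per_class: int = 1, seed: int = 0) -> DatasetManifest:
    """Reference class structure scaled by ``scale``.

    Per-class count = max(round(scale * reference count), min_per_class),
    with banker's (round-half-even) rounding; scale 1.0 reproduces the
    reference counts verbatim (total 18,221).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    entries = [
        (cid, name, max(int(round(scale * count)), min_per_class))
        for cid, name, count in TABLE1_CLASSES
    ]
    return DatasetManifest(entries, scale=scale, seed=seed)


# 24 visually distinct colony colors: whites, creams, grays, yellows, pinks —
# the palette colonies show on blood agar, spread out for separability.
_PALETTE: list[tuple[int, int, int]] = [
    (228, 225, 215), (202, 198, 182), (240, 232, 190), (185, 170, 150),
    (246, 242, 235), (214, 196, 120), (170, 160, 160), (236, 210, 170),
    (198, 214, 186), (252, 238, 148), (160, 140, 120), (222, 222, 230),
    (140, 150, 135), (244, 218, 205), (205, 180, 95), (250, 248, 200),
    (178, 188, 200), (232, 186, 140), (150, 125, 105), (210, 235, 215),
    (243, 200, 110), (190, 205, 150), (165, 180, 115), (255, 225, 235),
]


def default_class_specs(num_classes: int = 24) -> list[ClassSpec]:
    """Deterministic per-class morphology table.

    Every pair of classes differs in at least two parameters: the base
    colors are pairwise distinct, and the (radius, count) combination cycles
    with coprime periods 6 and 5 so it is unique for up to 30 classes.
    """
    if not (1 <= num_classes <= 24):
        raise ValueError("num_classes must be between 1 and 24")
    specs = []
    for i, (cid, name, _) in enumerate(TABLE1_CLASSES[:num_classes]):
        specs.append(
            ClassSpec(
                class_id=cid,
                species_name=name,
                colony_radius=(9.0 + 2.5 * (i % 6), 1.5),
                colony_count=(3.0 + (i % 5), 1.0),
                base_color=_PALETTE[i],
                halo=cid in _HALO_CLASSES,
                halo_width=3.5 + 1.5 * (i % 3),
                border_roughness=0.04 + 0.035 * (i % 4),
                texture_grain=0.02 + 0.012 * (i % 3),
            )
        )
    return specs


def render_plate_image(spec: ClassSpec, height: int, width: int, seed: int) -> np.ndarray:
    """Render one plate as an (H, W, 3) uint8 array; pure in (spec, size, seed)."""
    if height < 32 or width < 32:
        raise ValueError(f"image sides must be >= 32, got {height}x{width}")
    rng = np.random.default_rng(seed)
    sc = min(height, width) / 224.0  # morphology parameters are in 224px units

    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    plate_r = 0.47 * min(height, width)
    rr = np.hypot(yy - cy, xx - cx)

    # Agar disc over a dark bench background, mild directional illumination.
    img = np.empty((height, width, 3), np.float64)
    img[...] = (38.0, 36.0, 40.0)
    theta_l = rng.uniform(0, 2 * np.pi)
    grad = 1.0 + 0.12 * (
        np.cos(theta_l) * (xx - cx) + np.sin(theta_l) * (yy - cy)
    ) / max(plate_r, 1.0)
    vignette = 1.0 - 0.10 * (rr / plate_r) ** 2
    agar = np.array([158.0, 52.0, 46.0])  # sheep-blood agar red-brown
    disc = rr <= plate_r
    shade = (grad * vignette)[..., None]
    img[disc] = (agar[None, :] * shade[disc]).clip(0, 255)

    n_colonies = max(1, int(round(rng.normal(spec.colony_count[0], spec.colony_count[1]))))
    base = np.array(spec.base_color, np.float64)
    halo_shift = np.array(spec.halo_shift, np.float64)

    for _ in range(n_colonies):
        # position inside the plate, away from the rim
        ang = rng.uniform(0, 2 * np.pi)
        rad = plate_r * 0.78 * np.sqrt(rng.uniform())
        py, px = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        r0 = max(2.0, rng.normal(spec.colony_radius[0], spec.colony_radius[1]) * sc)

        dist = np.hypot(yy - py, xx - px)
        theta = np.arctan2(yy - py, xx - px)
        # lobed border: a few low-order harmonics with random phase
        wobble = np.zeros_like(theta)
        for m in (2, 3, 5):
            wobble += rng.uniform(0.3, 1.0) * np.sin(m * theta + rng.uniform(0, 2 * np.pi))
        redge = r0 * (1.0 + spec.border_roughness * wobble / 3.0)

        if spec.halo:
            ring = (dist >= redge) & (dist <= redge + spec.halo_width * sc) & disc
            img[ring] = np.clip(img[ring] + halo_shift[None, :], 0, 255)

        body = (dist <= redge) & disc
        if not body.any():
            continue
        # domed shading plus per-pixel surface grain
        dome = 0.80 + 0.30 * np.clip(1.0 - (dist[body] / np.maximum(redge[body], 1e-9)) ** 2, 0, 1)
        grain = 1.0 + spec.texture_grain * rng.standard_normal(int(body.sum()))
        img[body] = np.clip(base[None, :] * (dome * grain)[:, None], 0, 255)

    img += rng.normal(0.0, 2.0, size=img.shape)  # sensor noise
    return np.clip(img, 0, 255).astype(np.uint8)


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def image_seed(global_seed: int, class_id: int, index: int) -> int:
    """Stable per-image seed; adding classes never perturbs existing images."""
    ss = np.random.SeedSequence((int(global_seed), int(class_id), int(index)))
    return int(ss.generate_state(1)[0])


def generate_dataset(
    manifest: DatasetManifest,
    specs: list[ClassSpec],
    out_dir: str | Path,
    image_size: int = 224,
) -> Path:
    """Write the class-per-folder PNG layout plus ``manifest.csv``.

    Layout: ``<out_dir>/<class_id>_<species>/<index>.png``; the CSV columns
    are (path, class_id, species_name, seed). Deterministic in
    (manifest, specs, image_size).
    """
    by_id = {s.class_id: s for s in specs}
    missing = [cid for cid, _, _ in manifest.entries if cid not in by_id]
    if missing:
        raise ValueError(f"no ClassSpec for manifest classes {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cid, name, count in manifest.entries:
        spec = by_id[cid]
        folder = out_dir / f"{cid:02d}_{_slug(name)}"
        folder.mkdir(exist_ok=True)
        for idx in range(count):
            seed = image_seed(manifest.seed, cid, idx)
            arr = render_plate_image(spec, image_size, image_size, seed)
            rel = f"{folder.name}/{idx:05d}.png"
            Image.fromarray(arr).save(out_dir / rel)
            rows.append((rel, cid, name, seed))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class_id", "species_name", "seed"])
        writer.writerows(rows)
    return out_dir / "manifest.csv"


def render_arrays(
    manifest: DatasetManifest,
    specs: list[ClassSpec],
    image_size: int = 64,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """In-memory dataset: images (N, 3, H, W) float32 in [0, 1], label indices,
    and the ordered class names. Same per-image seeding as the on-disk layout.
    """
    by_id = {s.class_id: s for s in specs}
    images, labels, names = [], [], []
    for k, (cid, name, count) in enumerate(sorted(manifest.entries)):
        names.append(f"{cid:02d}_{_slug(name)}")
        spec = by_id[cid]
        for idx in range(count):
            arr = render_plate_image(spec, image_size, image_size, image_seed(manifest.seed, cid, idx))
            images.append(arr.transpose(2, 0, 1).astype(np.float32) / 255.0)
            labels.append(k)
    return np.stack(images), np.asarray(labels, np.int64), names
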