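"""Synthetic fundus-style cohorts with a controllable branching-geometry effect.

The generator produces what a 45° macula-centred fundus photograph shows at
desk scale: a branching vascular tree rendered as dark anti-aliased curves on
a bright, unevenly illuminated textured disc, together with the exact binary
vessel mask and the ground-truth bifurcation table.

Branching geometry follows an optimality rule: at every bifurcation the
parent and daughter calibers satisfy d_p^m = d_1^m + d_2^m with the Murray
exponent m = 3 by default (minimum-work branching), and the daughter split is
controlled by the branching asymmetry ratio

    alpha = (min(d1, d2) / max(d1, d2))^2  in (0, 1],

the ratio of the squares of the two daughter widths. The two simulated
cohorts ("hypertension" / "non-hypertension") differ only through a
configurable shift of the mean asymmetry ratio (and optionally of the mean
bifurcation opening angle) — a purely bifurcation-local effect — or, in the
negative-control "diffuse" mode, through a uniform caliber rescaling with
bifurcation geometry untouched.

Coordinates are image coordinates throughout: origin top-left, x = column,
y = row, 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError

HYPERTENSION = "hypertension"
CONTROL = "non-hypertension"
LABELS = (HYPERTENSION, CONTROL)


@dataclass
class SimulatorConfig:
    """Knobs of the synthetic vascular world.

    ``class_effect`` is the additive shift applied to ``asymmetry_mean`` for
    the hypertension class in the default ``effect_mode="bifurcation"``;
    ``angle_effect`` (degrees) optionally shifts the mean opening angle as
    well. In ``effect_mode="diffuse"`` the same ``class_effect`` instead acts
    as a relative caliber change (root diameter scaled by 1 + class_effect)
    and bifurcation geometry is identical between classes.
    """

    image_size: int = 128
    tree_depth: int = 6
    n_roots: int = 4
    root_diameter: float = 5.0
    murray_exponent: float = 3.0
    angle_mean: float = 75.0
    angle_sd: float = 12.0
    asymmetry_mean: float = 0.80
    asymmetry_sd: float = 0.12
    class_effect: float = -0.25
    angle_effect: float = 0.0
    effect_mode: str = "bifurcation"
    length_diameter_ratio: float = 8.0
    length_jitter: float = 0.25
    background_level: float = 0.80
    background_texture_sd: float = 0.05
    illumination_gradient: float = 0.15
    vessel_contrast: float = 0.55
    dark_vessels: bool = True
    two_eye_probability: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")
        if self.murray_exponent <= 0:
            raise ConfigurationError("murray_exponent must be > 0")
        if not 0 < self.angle_mean < 180:
            raise ConfigurationError("angle_mean must lie in (0, 180) degrees")
        if self.effect_mode not in ("bifurcation", "diffuse"):
            raise ConfigurationError("effect_mode must be 'bifurcation' or 'diffuse'")
        shifted = self.asymmetry_mean
        if self.effect_mode == "bifurcation":
            shifted = self.asymmetry_mean + self.class_effect
        for value in (self.asymmetry_mean, shifted):
            if not 0 < value <= 1:
                raise ConfigurationError(
                    "asymmetry mean (including class_effect shift) must be in (0, 1]"
                )
        if self.tree_depth < 0 or self.n_roots < 1:
            raise ConfigurationError("tree_depth must be >= 0 and n_roots >= 1")

    def for_label(self, label: str) -> "SimulatorConfig":
        """Per-class config with the planted effect applied."""
        if label not in LABELS:
            raise ConfigurationError(f"unknown label {label!r}")
        if label == CONTROL:
            return self
        if self.effect_mode == "bifurcation":
            return dataclasses.replace(
                self,
                asymmetry_mean=self.asymmetry_mean + self.class_effect,
                angle_mean=self.angle_mean + self.angle_effect,
            )
        return dataclasses.replace(
            self, root_diameter=self.root_diameter * (1.0 + self.class_effect)
        )


@dataclass
class Bifurcation:
    node: int
    x: float
    y: float
    parent_diameter: float
    d1: float
    d2: float
    angle_deg: float
    asymmetry: float


@dataclass
class VascularTree:
    """Geometric ground truth: node positions, tapered segments, bifurcations."""

    nodes: list  # (x, y) tuples
    segments: list  # (parent_node, child_node, diameter)
    bifurcations: list  # Bifurcation records


@dataclass
class FundusImage:
    pixels: np.ndarray  # float in [0, 1], (H, W)
    label: str | None = None
    subject_id: str | None = None
    provenance: str = "raw"


@dataclass
class VesselMask:
    pixels: np.ndarray  # uint8 in {0, 1}, same shape as its image


def _murray_daughters(parent: float, asymmetry: float, m: float) -> tuple[float, float]:
    """Daughter calibers solving d_p^m = d1^m + d2^m at the given asymmetry.

    asymmetry = (d2/d1)^2 with d1 >= d2, so d2 = d1 * sqrt(asymmetry) and
    d1 = d_p / (1 + asymmetry^(m/2))^(1/m).
    """
    d1 = parent / (1.0 + asymmetry ** (m / 2.0)) ** (1.0 / m)
    return d1, d1 * np.sqrt(asymmetry)


def sample_tree(config: SimulatorConfig, seed: int) -> VascularTree:
    """Sample one vascular tree from the configured branching distribution.

    Trees grow from ``n_roots`` trunks near an off-centre optic-disc point,
    bifurcating recursively. Growth stops at ``tree_depth`` generations, when
    a branch thins below 1 pixel, or at the field-of-view boundary. When only
    the thin daughter would fall below 1 pixel the thick daughter continues
    as a plain (non-bifurcating) extension, so every recorded bifurcation has
    exactly two live daughter segments.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    size = config.image_size
    center = np.array([size / 2.0, size / 2.0])
    fov_radius = 0.48 * size

    nodes: list[tuple[float, float]] = []
    segments: list[tuple[int, int, float]] = []
    bifurcations: list[Bifurcation] = []

    def add_node(pt) -> int:
        nodes.append((float(pt[0]), float(pt[1])))
        return len(nodes) - 1

    # optic disc sits on a ring at ~2/3 of the FOV radius, random azimuth
    disc_angle = rng.uniform(0, 2 * np.pi)
    disc = center + 0.66 * fov_radius * np.array([np.cos(disc_angle), np.sin(disc_angle)])

    def grow(node_idx: int, pt, direction: float, diameter: float, generation: int):
        length = config.length_diameter_ratio * diameter
        length *= 1.0 + config.length_jitter * rng.uniform(-1, 1)
        length = max(length, 3.0)
        end = pt + length * np.array([np.cos(direction), np.sin(direction)])
        clipped = False
        off = end - center
        dist = np.hypot(*off)
        if dist > fov_radius - 1.0:
            # clip the endpoint to the field of view and stop this branch
            t = (fov_radius - 1.0) / dist
            end = center + off * t
            clipped = True
        end_idx = add_node(end)
        segments.append((node_idx, end_idx, float(diameter)))
        if clipped or generation >= config.tree_depth or diameter < 1.0:
            return
        asymmetry = float(
            np.clip(rng.normal(config.asymmetry_mean, config.asymmetry_sd), 0.05, 1.0)
        )
        opening = float(np.clip(rng.normal(config.angle_mean, config.angle_sd), 10.0, 170.0))
        d1, d2 = _murray_daughters(diameter, asymmetry, config.murray_exponent)
        if d1 < 1.0:
            return
        if d2 < 1.0:
            # thin daughter dies off: continue the trunk without a bifurcation
            jitter = np.deg2rad(rng.normal(0.0, 0.25 * config.angle_sd))
            grow(end_idx, end, direction + jitter, d1, generation + 1)
            return
        # thicker daughter deviates less, split weighted by squared caliber
        w1 = d2**2 / (d1**2 + d2**2)
        w2 = 1.0 - w1
        side = rng.choice([-1.0, 1.0])
        opening_rad = np.deg2rad(opening)
        grow(end_idx, end, direction - side * w1 * opening_rad, d1, generation + 1)
        grow(end_idx, end, direction + side * w2 * opening_rad, d2, generation + 1)
        bifurcations.append(
            Bifurcation(
                node=end_idx,
                x=float(end[0]),
                y=float(end[1]),
                parent_diameter=float(diameter),
                d1=float(d1),
                d2=float(d2),
                angle_deg=opening,
                asymmetry=asymmetry,
            )
        )

    towards_macula = np.arctan2(center[1] - disc[1], center[0] - disc[0])
    spread = np.deg2rad(100.0)
    for i in range(config.n_roots):
        frac = (i + 0.5) / config.n_roots - 0.5
        direction = towards_macula + frac * spread + rng.normal(0, 0.1)
        root_idx = add_node(disc + rng.normal(0, 1.0, size=2))
        grow(root_idx, np.array(nodes[root_idx]), direction, config.root_diameter, 0)

    return VascularTree(nodes=nodes, segments=segments, bifurcations=bifurcations)


def _coverage(tree: VascularTree, size: int) -> np.ndarray:
    """Per-pixel vessel coverage in [0, 1]: anti-aliased capsule rasterization.

    A pixel's coverage for one segment is a unit ramp on the signed distance
    from the pixel centre to the segment's centreline capsule of radius
    max(diameter/2, 0.8); segment coverages combine by maximum. The 0.8 px
    floor keeps sub-pixel branches and their centrelines representable on
    the grid.
    """
    cov = np.zeros((size, size), dtype=np.float64)
    if not tree.segments:
        return cov
    nodes = np.asarray(tree.nodes, dtype=np.float64)
    for a_idx, b_idx, diameter in tree.segments:
        a, b = nodes[a_idx], nodes[b_idx]
        radius = max(diameter / 2.0, 0.8)
        pad = radius + 1.5
        x0 = max(int(np.floor(min(a[0], b[0]) - pad)), 0)
        x1 = min(int(np.ceil(max(a[0], b[0]) + pad)) + 1, size)
        y0 = max(int(np.floor(min(a[1], b[1]) - pad)), 0)
        y1 = min(int(np.ceil(max(a[1], b[1]) + pad)) + 1, size)
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-12:
            t = np.zeros_like(xs, dtype=np.float64)
        else:
            t = np.clip(((xs - a[0]) * ab[0] + (ys - a[1]) * ab[1]) / denom, 0.0, 1.0)
        px = a[0] + t * ab[0]
        py = a[1] + t * ab[1]
        dist = np.hypot(xs - px, ys - py)
        alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        np.maximum(cov[y0:y1, x0:x1], alpha, out=cov[y0:y1, x0:x1])
    return cov


def render(
    tree: VascularTree, config: SimulatorConfig, seed: int
) -> tuple[FundusImage, VesselMask]:
    """Rasterize a tree onto a textured, unevenly lit fundus-style disc."""
    config.validate()
    rng = np.random.default_rng(seed)
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    center = size / 2.0
    fov = np.hypot(xx - center, yy - center) <= 0.48 * size

    # smooth illumination plane + low-frequency texture on the disc
    theta = rng.uniform(0, 2 * np.pi)
    plane = ((xx - center) * np.cos(theta) + (yy - center) * np.sin(theta)) / size
    background = config.background_level + config.illumination_gradient * plane
    texture = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 24.0)
    sd = texture.std()
    if sd > 0:
        background += config.background_texture_sd * texture / sd
    cov = _coverage(tree, size)
    if config.dark_vessels:
        img = background - config.vessel_contrast * cov
    else:
        img = background + config.vessel_contrast * cov
    img = np.where(fov, img, 0.02)
    img = np.clip(img, 0.0, 1.0)
    mask = ((cov >= 0.5) & fov).astype(np.uint8)
    return FundusImage(pixels=img, provenance="raw"), VesselMask(pixels=mask)


@dataclass
class CohortRecord:
    subject_id: str
    label: str
    image: FundusImage
    mask: VesselMask
    bifurcations: list  # Bifurcation records
    tree: VascularTree | None = None


@dataclass
class Cohort:
    records: list = field(default_factory=list)
    config: SimulatorConfig | None = None

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def by_label(self, label: str) -> list:
        return [r for r in self.records if r.label == label]


def generate_cohort(config: SimulatorConfig, n_per_class: int, seed: int) -> Cohort:
    """Generate a labeled two-class cohort of images, masks and annotations.

    Subjects may contribute two images ("two eyes", probability
    ``two_eye_probability``); both eyes carry independent trees but share
    the subject id, which is what the grouped fold splitter keys on.
    """
    config.validate()
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    master = np.random.SeedSequence(seed)
    eye_seeds = master.spawn(2 * 2 * n_per_class + 16)
    pair_rng = np.random.default_rng(master.spawn(1)[0])
    records = []
    counter = iter(range(len(eye_seeds)))
    for class_idx, label in enumerate(LABELS):
        class_config = config.for_label(label)
        produced = 0
        subject = 0
        while produced < n_per_class:
            subject_id = f"{label[:3]}-{subject:04d}"
            n_eyes = 2 if pair_rng.random() < config.two_eye_probability else 1
            n_eyes = min(n_eyes, n_per_class - produced)
            for _ in range(n_eyes):
                ss = eye_seeds[next(counter)]
                tree_seed, render_seed = ss.generate_state(2) % (2**31)
                tree = sample_tree(class_config, int(tree_seed))
                image, mask = render(tree, class_config, int(render_seed))
                image.label = label
                image.subject_id = subject_id
                records.append(
                    CohortRecord(
                        subject_id=subject_id,
                        label=label,
                        image=image,
                        mask=mask,
                        bifurcations=tree.bifurcations,
                        tree=tree,
                    )
                )
                produced += 1
            subject += 1
    return Cohort(records=records, config=config)


# ---------------------------------------------------------------------------
# serialization


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write PNG images/masks, per-image bifurcation JSON and a manifest CSV.

    The manifest records the coordinate convention (origin top-left,
    x = column, y = row, 0-based) alongside every path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "bifurcations").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(cohort.records):
        stem = f"{i:05d}_{rec.subject_id}"
        image_path = out / "images" / f"{stem}.png"
        mask_path = out / "masks" / f"{stem}.png"
        bif_path = out / "bifurcations" / f"{stem}.json"
        Image.fromarray(_to_uint8(rec.image.pixels)).save(image_path)
        Image.fromarray(rec.mask.pixels * 255).save(mask_path)
        bif_path.write_text(
            json.dumps(
                {
                    "coordinates": "origin top-left, x=column, y=row, 0-based",
                    "bifurcations": [
                        {
                            "x": b.x,
                            "y": b.y,
                            "d_parent": b.parent_diameter,
                            "d1": b.d1,
                            "d2": b.d2,
                            "angle_deg": b.angle_deg,
                            "asymmetry": b.asymmetry,
                        }
                        for b in rec.bifurcations
                    ],
                },
                indent=1,
            )
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "image_path": str(image_path.relative_to(out)),
                "mask_path": str(mask_path.relative_to(out)),
                "bifurcation_path": str(bif_path.relative_to(out)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def manifest_checksum(cohort_dir: str | Path) -> str:
    """SHA-256 over the manifest and every artifact it references."""
    root = Path(cohort_dir)
    h = hashlib.sha256()
    manifest = root / "manifest.csv"
    h.update(manifest.read_bytes())
    df = pd.read_csv(manifest)
    for _, row in df.iterrows():
        for col in ("image_path", "mask_path", "bifurcation_path"):
            h.update((root / row[col]).read_bytes())
    return h.hexdigest()


def mean_asymmetry(record: CohortRecord) -> float:
    """Per-image mean branching asymmetry ratio from the annotation table."""
    if not record.bifurcations:
        return float("nan")
    return float(np.mean([b.asymmetry for b in record.bifurcations]))
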