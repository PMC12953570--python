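"""Synthetic small-pest scene generator, YOLO-format label I/O, splits.

Scenes emulate the field regime the detector targets: 640x640 RGB
frames, a textured vegetation-like background (multi-octave value noise
tinted green), and small (roughly 10-60 px) elliptical targets whose
hue and aspect ratio are class-specific, so an 11-way taxonomy is
learnable but visually subdued.  Low-contrast mode draws object colours
within a bounded distance of the local background.  Everything is a
pure function of the spec and its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class BoxAnnotation:
    """Normalized center-format box, YOLO text dialect."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError(f"box size must lie in (0, 1], got {self.w}x{self.h}")
        for lo, hi in ((self.cx - self.w / 2, self.cx + self.w / 2),
                       (self.cy - self.h / 2, self.cy + self.h / 2)):
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(f"box extends outside image: {self}")

    def corners(self) -> Tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass(frozen=True)
class SceneSpec:
    image_size: int = 640
    num_classes: int = 11
    objects_per_image: Tuple[int, int] = (3, 8)
    object_size_px: Tuple[int, int] = (10, 60)
    contrast: str = "med"  # low | med | high
    background_octaves: int = 4
    background_base_period: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.object_size_px[1] >= self.image_size:
            raise ValueError("object sizes must be smaller than the image")
        if self.objects_per_image[0] < 0:
            raise ValueError("object counts must be >= 0")
        if self.contrast not in ("low", "med", "high"):
            raise ValueError(f"contrast must be low|med|high, got {self.contrast}")


@dataclass(frozen=True)
class SplitSpec:
    ratios: Tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.ratios) or sum(self.ratios) <= 0:
            raise ValueError(f"ratios must be nonnegative with positive sum: {self.ratios}")


# ---------------------------------------------------------------------------
# background


def _value_noise(rng: np.random.Generator, size: int, period: int) -> np.ndarray:
    """Bilinear-interpolated lattice noise with the given grid period."""
    n = size // period + 2
    lattice = rng.random((n, n))
    coords = np.arange(size) / period
    i0 = coords.astype(int)
    frac = coords - i0
    a = lattice[np.ix_(i0, i0)]
    b = lattice[np.ix_(i0, i0 + 1)]
    c = lattice[np.ix_(i0 + 1, i0)]
    d = lattice[np.ix_(i0 + 1, i0 + 1)]
    fy, fx = frac[:, None], frac[None, :]
    return (a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx
            + c * fy * (1 - fx) + d * fy * fx)


def _background(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    s = spec.image_size
    acc = np.zeros((s, s))
    amp, total = 1.0, 0.0
    period = spec.background_base_period
    for _ in range(spec.background_octaves):
        acc += amp * _value_noise(rng, s, max(2, period))
        total += amp
        amp *= 0.5
        period //= 2
    tex = acc / total
    # vegetation tint: green-dominated with textured luminance
    img = np.empty((s, s, 3))
    img[..., 0] = 0.18 + 0.25 * tex
    img[..., 1] = 0.35 + 0.35 * tex
    img[..., 2] = 0.12 + 0.18 * tex
    return img


# ---------------------------------------------------------------------------
# objects


def _class_style(class_id: int, num_classes: int) -> Tuple[np.ndarray, float]:
    """Deterministic per-class colour direction and aspect ratio."""
    hue = class_id / max(num_classes, 1)
    colour = np.array([
        0.5 + 0.5 * np.cos(2 * np.pi * hue),
        0.5 + 0.5 * np.cos(2 * np.pi * (hue + 1 / 3)),
        0.5 + 0.5 * np.cos(2 * np.pi * (hue + 2 / 3)),
    ])
    aspect = 1.0 + 1.5 * ((class_id * 7) % num_classes) / max(num_classes, 1)
    return colour, aspect


def _render_ellipse(img, cy, cx, ry, rx, angle, colour):
    """Anti-aliased filled rotated ellipse; returns the coverage mask."""
    s = img.shape[0]
    pad = int(np.ceil(max(ry, rx))) + 2
    y0, y1 = max(0, int(cy) - pad), min(s, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(s, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / rx
    v = (-sa * dx + ca * dy) / ry
    r = np.sqrt(u * u + v * v)
    # ~1px smooth edge for antialiasing
    edge = 1.0 / max(min(rx, ry), 1.0)
    alpha = np.clip((1.0 - r) / edge + 0.5, 0.0, 1.0)
    region = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = region * (1 - alpha[..., None]) + colour[None, None] * alpha[..., None]
    mask = np.zeros((s, s), dtype=bool)
    mask[y0:y1, x0:x1] = alpha >= 0.5
    return mask


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, List[BoxAnnotation]]:
    """Render one scene; returns (H, W, 3) float image in [0, 1] and
    tight annotations derived from the rendered coverage masks."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    img = _background(rng, spec)
    lo, hi = spec.objects_per_image
    n_objects = int(rng.integers(lo, hi + 1))
    annotations: List[BoxAnnotation] = []
    occupied = np.zeros((s, s), dtype=bool)
    for _ in range(n_objects):
        placed = False
        for _attempt in range(60):
            class_id = int(rng.integers(spec.num_classes))
            colour, aspect = _class_style(class_id, spec.num_classes)
            size = rng.uniform(*spec.object_size_px)
            rx = size / 2
            ry = rx / aspect
            angle = rng.uniform(0, np.pi)
            # rotated half-extents of the bounding box
            ex = np.hypot(rx * np.cos(angle), ry * np.sin(angle))
            ey = np.hypot(rx * np.sin(angle), ry * np.cos(angle))
            cx = rng.uniform(ex + 1, s - ex - 1)
            cy = rng.uniform(ey + 1, s - ey - 1)
            y0, y1 = int(cy - ey), int(np.ceil(cy + ey))
            x0, x1 = int(cx - ex), int(np.ceil(cx + ex))
            if occupied[y0:y1, x0:x1].any():
                continue
            if spec.contrast != "high":
                local = img[max(0, y0) : y1, max(0, x0) : x1].reshape(-1, 3).mean(axis=0)
                dist = 0.6 if spec.contrast == "med" else 0.25
                colour = local + dist * (colour - local)
            mask = _render_ellipse(img, cy, cx, ry, rx, angle, colour)
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            bx0, bx1 = xs.min(), xs.max() + 1
            by0, by1 = ys.min(), ys.max() + 1
            annotations.append(BoxAnnotation(
                class_id,
                cx=(bx0 + bx1) / 2 / s, cy=(by0 + by1) / 2 / s,
                w=(bx1 - bx0) / s, h=(by1 - by0) / s,
            ))
            occupied[y0:y1, x0:x1] = True
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place object {len(annotations) + 1}/{n_objects}; "
                "scene too crowded for the requested sizes")
    # mild sensor noise
    img = np.clip(img + rng.normal(0, 0.012, img.shape), 0.0, 1.0)
    return img, annotations


# ---------------------------------------------------------------------------
# YOLO label dialect


def write_yolo_labels(annotations: Sequence[BoxAnnotation], path) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> List[BoxAnnotation]:
    out: List[BoxAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(fields)}")
            try:
                cid = int(fields[0])
                vals = [float(v) for v in fields[1:]]
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: unparsable numeric field: {e}") from None
            try:
                out.append(BoxAnnotation(cid, *vals))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from None
    return out


def save_image(img: np.ndarray, path) -> None:
    Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0


# ---------------------------------------------------------------------------
# splits


def split_sizes(n_items: int, ratios: Sequence[float]) -> Tuple[int, ...]:
    """Largest-remainder apportionment of ``n_items * ratio``; remainder
    ties go to later partitions (so 4565 at 8:1:1 -> 3652/456/457)."""
    total = float(sum(ratios))
    quotas = [n_items * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    leftover = n_items - sum(sizes)
    order = sorted(range(len(ratios)),
                   key=lambda i: (quotas[i] - sizes[i], i), reverse=True)
    for i in order[:leftover]:
        sizes[i] += 1
    return tuple(sizes)


def split_dataset(n_items: int, spec: SplitSpec,
                  labels: Optional[Sequence[int]] = None):
    """Deterministic shuffle + ratio split; returns index arrays.

    With ``labels`` the shuffle is stratified: items of each label are
    distributed over the partitions in proportion.
    """
    n_parts = sum(1 for r in spec.ratios if r > 0)
    if n_items < n_parts:
        raise ValueError(f"{n_items} items cannot fill {n_parts} nonempty partitions")
    rng = np.random.default_rng(spec.seed)
    if labels is None:
        order = rng.permutation(n_items)
        sizes = split_sizes(n_items, spec.ratios)
        bounds = np.cumsum(sizes)[:-1]
        parts = np.split(order, bounds)
    else:
        labels = np.asarray(labels)
        buckets = [[] for _ in spec.ratios]
        for lab in np.unique(labels):
            idx = rng.permutation(np.nonzero(labels == lab)[0])
            sizes = split_sizes(len(idx), spec.ratios)
            start = 0
            for b, sz in zip(buckets, sizes):
                b.extend(idx[start : start + sz])
                start += sz
        parts = [np.array(sorted(b), dtype=int) for b in buckets]
    return tuple(np.asarray(pt, dtype=int) for pt in parts)


# ---------------------------------------------------------------------------
# dataset on disk


def generate_dataset(out_dir, n_images: int, spec: SceneSpec,
                     split: Optional[SplitSpec] = None) -> dict:
    """Write PNG images, YOLO label files and a YAML manifest."""
    import yaml

    img_dir = os.path.join(out_dir, "images")
    lab_dir = os.path.join(out_dir, "labels")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(lab_dir, exist_ok=True)
    names = []
    for i in range(n_images):
        scene_spec = replace(spec, seed=spec.seed + i)
        img, anns = generate_scene(scene_spec)
        name = f"scene_{i:05d}"
        save_image(img, os.path.join(img_dir, name + ".png"))
        write_yolo_labels(anns, os.path.join(lab_dir, name + ".txt"))
        names.append(name)
    manifest = {
        "images": "images",
        "labels": "labels",
        "items": names,
        "class_names": [f"class_{c:02d}" for c in range(spec.num_classes)],
        "image_size": spec.image_size,
    }
    if split is not None:
        parts = split_dataset(n_images, split)
        manifest["splits"] = {k: [names[i] for i in idx]
                              for k, idx in zip(("train", "val", "test"), parts)}
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
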