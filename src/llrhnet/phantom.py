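"""Seeded synthetic multi-lesion phantoms.

Two archetypes reproduce the structural difficulties of abdominal-CT and
brain-MRI lesion data without any downloads:

* ``organ_with_inclusions`` — one large smooth organ blob (class 1)
  containing several small inclusions (class 2), like a liver bearing
  tumours on a 2D CT slice;
* ``scattered_bilateral`` — small bright class-1 lesions scattered in the
  left half of the field with class-2 lesions mirrored across the vertical
  midline, like co-occurring stroke and white-matter-hyperintensity lesions.
  The mirror placement is a deliberate long-range cue: the position of a
  class-2 lesion is predictable only from the far-away class-1 lesion, so
  models that integrate long-range context have signal that purely local
  models lack.

Blob outlines are circles perturbed by a random low-order radial Fourier
series (smooth organic boundaries).  The clean per-class mean-intensity
image is blurred (sigma = 1 px) before Gaussian noise is added, so boundary
pixels are genuinely ambiguous once ``boundary_contrast`` — the separation
of adjacent class means measured in units of the noise sigma — drops to 1
or below.  Identical spec + seed gives bit-identical samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, label as cc_label

ARCHETYPES = ("organ_with_inclusions", "scattered_bilateral")


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults are desk scale (128 px).

    ``intensity_means`` may be given explicitly per class (background,
    class 1, class 2); when None, means are spaced ``boundary_contrast *
    noise_sigma`` apart (0.18 apart in the noiseless case) starting at 0.30.
    """

    image_size: int = 128
    archetype: str = "organ_with_inclusions"
    organ_radius_range: tuple[float, float] = (0.25, 0.36)  # fraction of size
    n_inclusions: tuple[int, int] = (2, 5)
    inclusion_radius_range: tuple[float, float] = (5.0, 12.0)  # pixels at 128
    intensity_means: tuple[float, float, float] | None = None
    boundary_contrast: float = 2.0
    noise_sigma: float = 0.05
    blur_sigma: float = 1.0
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}")
        if self.boundary_contrast <= 0:
            raise ValueError("boundary_contrast must be > 0")
        if self.organ_radius_range[0] <= 0 or self.inclusion_radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if self.inclusion_radius_range[1] >= self.organ_radius_range[0] * self.image_size:
            raise ValueError("inclusion radii must be smaller than the organ radius")
        if self.intensity_means is not None and not np.all(np.isfinite(self.intensity_means)):
            raise ValueError("intensity means must be finite")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")

    def class_means(self) -> np.ndarray:
        """Default per-class mean intensities.

        ``organ_with_inclusions``: background < organ < inclusion, spaced by
        the boundary contrast.  ``scattered_bilateral``: both lesion classes
        are equally bright — they are distinguishable only by the mirrored
        placement, so class identity is a long-range (not intensity) cue.
        """
        if self.intensity_means is not None:
            return np.asarray(self.intensity_means, dtype=float)
        step = self.boundary_contrast * self.noise_sigma if self.noise_sigma > 0 else 0.18
        if self.archetype == "scattered_bilateral":
            return np.array([0.30, 0.30 + 2 * step, 0.30 + 2 * step])
        return 0.30 + step * np.arange(3)


@dataclass
class PhantomSample:
    """A generated image/label pair plus provenance."""

    image: np.ndarray          # (H,W) or (2,H,W) float in [0,1]-ish range
    labels: np.ndarray         # (H,W) uint8 in {0,1,2}
    spec_echo: PhantomSpec
    class_areas: dict[int, int] = field(default_factory=dict)


class PlacementError(RuntimeError):
    """Raised when a geometric constraint cannot be satisfied after retries."""


def _blob_mask(size: int, center: tuple[float, float], radius: float,
               rng: np.random.Generator, roughness: float = 0.15,
               n_harmonics: int = 4) -> np.ndarray:
    """Rasterise a circle with randomized radial Fourier perturbation.

    Harmonic amplitudes decay as 2^-k and sum to at most ``2 * roughness *
    radius``, so the outline is irregular but never collapses inward.
    """
    amp = rng.uniform(0.0, roughness, size=n_harmonics) * radius \
        / 2.0 ** np.arange(n_harmonics)
    phase = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_edge = radius + sum(
        amp[k] * np.cos((k + 1) * theta + phase[k]) for k in range(n_harmonics)
    )
    return r <= r_edge


def _scale(spec: PhantomSpec) -> float:
    # pixel-denominated defaults are calibrated at 128 px
    return spec.image_size / 128.0


def generate_sample(spec: PhantomSpec) -> PhantomSample:
    """Draw one phantom; deterministic given ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    labels = np.zeros((size, size), dtype=np.uint8)
    s = _scale(spec)
    rlo, rhi = (r * s for r in spec.inclusion_radius_range)

    if spec.archetype == "organ_with_inclusions":
        organ_r = rng.uniform(*spec.organ_radius_range) * size
        margin = organ_r * 1.25
        cy = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
        cx = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
        organ = _blob_mask(size, (cy, cx), organ_r, rng, roughness=0.12)
        labels[organ] = 1
        n_inc = int(rng.integers(spec.n_inclusions[0], spec.n_inclusions[1] + 1))
        placed = 0
        rhi_eff = rhi  # proposal radius anneals down when placements keep failing
        for attempt in range(150 * n_inc):
            if placed == n_inc:
                break
            if attempt and attempt % 50 == 0:
                rhi_eff = max(rlo, 0.8 * rhi_eff)
            r = rng.uniform(rlo, rhi_eff)
            # keep the inclusion proposal inside the (perturbed) organ outline;
            # the exact containment check below is authoritative
            rad_pos = rng.uniform(0, max(organ_r * 0.78 - r, 1.0))
            ang = rng.uniform(0, 2 * np.pi)
            icy, icx = cy + rad_pos * np.sin(ang), cx + rad_pos * np.cos(ang)
            blob = _blob_mask(size, (icy, icx), r, rng, roughness=0.2)
            if not blob.any():
                continue
            if (labels[blob] == 1).all():  # inside organ, not touching other inclusions
                labels[blob] = 2
                placed += 1
        if placed < n_inc:
            raise PlacementError(
                f"could only place {placed}/{n_inc} inclusions inside the organ")
    else:  # scattered_bilateral
        n_pairs = int(rng.integers(spec.n_inclusions[0], spec.n_inclusions[1] + 1))
        placed = 0
        for _ in range(150 * n_pairs):
            if placed == n_pairs:
                break
            r = rng.uniform(rlo, rhi)
            cy = rng.uniform(r + 1, size - r - 1)
            cx = rng.uniform(r + 1, size / 2 - r - 2)  # class 1 in the left half
            blob1 = _blob_mask(size, (cy, cx), r, rng, roughness=0.2)
            blob2 = _blob_mask(size, (cy, size - 1 - cx), r, rng, roughness=0.2)
            if (labels[blob1] == 0).all() and (labels[blob2] == 0).all():
                labels[blob1] = 1
                labels[blob2] = 2
                placed += 1
        if placed < n_pairs:
            raise PlacementError(
                f"could only place {placed}/{n_pairs} mirrored lesion pairs")

    means = spec.class_means()
    clean = means[labels]
    if spec.blur_sigma > 0:
        clean = gaussian_filter(clean, spec.blur_sigma)
    image = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    if spec.n_channels == 2:
        # second modality: contrast-remapped copy plus independent noise
        remap = means[0] + 1.4 * (clean - means[0])
        ch2 = remap + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
        image = np.stack([image, ch2], axis=0)
    areas = {c: int((labels == c).sum()) for c in (0, 1, 2)}
    return PhantomSample(image.astype(np.float64), labels, spec, areas)


def count_components(labels: np.ndarray, cls: int) -> int:
    """Number of 8-connected components of one class (test oracle helper)."""
    _, n = cc_label(labels == cls, structure=np.ones((3, 3), dtype=int))
    return int(n)


# ---------------------------------------------------------------------------
# Datasets on disk
# ---------------------------------------------------------------------------

def generate_dataset(spec: PhantomSpec, n: int, split=(0.6, 0.2, 0.2),
                     out_dir: str | Path | None = None,
                     fmt: str = "png") -> dict:
    """Generate ``n`` samples with per-sample seeds ``spec.seed + i``.

    Returns a manifest dict (also written as ``manifest.json`` when
    ``out_dir`` is given) recording the spec, the per-sample seeds and the
    train/val/test membership.  With ``out_dir=None`` the samples stay in
    memory under the ``"samples"`` key.
    """
    if n < 3:
        raise ValueError("need n >= 3 to populate all three splits")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_test = n - n_train - n_val
    membership = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)

    entries, samples = [], []
    for i in range(n):
        sub = PhantomSpec(**{**asdict(spec), "seed": spec.seed + i})
        sample = generate_sample(sub)
        samples.append(sample)
        entry = {"index": i, "seed": sub.seed, "split": membership[i]}
        if out_dir is not None:
            from .io_formats import write_sample
            paths = write_sample(sample, Path(out_dir), f"sample_{i:04d}", fmt=fmt)
            entry.update(paths)
        entries.append(entry)

    manifest = {
        "spec": asdict(spec),
        "n": n,
        "split": list(split),
        "format": fmt,
        "samples": entries,
    }
    if out_dir is not None:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
    else:
        manifest["in_memory"] = samples
    return manifest


def regenerate_from_manifest(manifest: dict) -> list[PhantomSample]:
    """Rebuild every sample recorded in a manifest (bit-identical)."""
    spec = PhantomSpec(**_spec_from_dict(manifest["spec"]))
    return [generate_sample(PhantomSpec(**{**asdict(spec), "seed": e["seed"]}))
            for e in manifest["samples"]]


def _spec_from_dict(d: dict) -> dict:
    d = dict(d)
    for key in ("organ_radius_range", "n_inclusions", "inclusion_radius_range"):
        if key in d:
            d[key] = tuple(d[key])
    if d.get("intensity_means") is not None:
        d["intensity_means"] = tuple(d["intensity_means"])
    return d
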