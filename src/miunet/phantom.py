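"""Paired-contrast short-axis cardiac phantoms with ground-truth masks.

The simulator emulates the statistical structure joint multi-contrast
segmentation relies on: two spatially co-located images of the same
anatomy, one cine-SSFP-like (bright blood, clear blood/myocardium
delineation, high SNR) and one LGE-like (dark myocardium, bright blood
pool, patchy bright enhancement inside the wall, lower SNR), with
optional rigid inter-contrast misregistration.

Geometry is the minimal shape family showing the three segmented
structures on a short-axis slice: a disc left-ventricular cavity (LVC,
label 1), an annular myocardial wall (LVM, label 2) whose septal sector
— the sector facing the right ventricle — can be thickened to mimic
hypertrophic-cardiomyopathy asymmetry, and a crescent-shaped right
ventricle (RV, label 3) hugging the epicardium.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._exceptions import ConfigurationError, GeometryError

__all__ = [
    "AnatomyModel",
    "ContrastModel",
    "LabeledSlice",
    "ContrastPair",
    "GeometryRanges",
    "ssfp_preset",
    "lge_preset",
    "sample_anatomy",
    "render_pair",
    "generate_dataset",
]

BACKGROUND, LVC, LVM, RV = 0, 1, 2, 3


@dataclass(frozen=True)
class AnatomyModel:
    """Geometric description of one short-axis slice."""

    image_size: int
    lv_center: tuple[float, float]  # (row, col), pixels
    lvc_radius: float
    wall_thickness_base: float
    septal_thickening_factor: float  # >= 1, applied to the wall sector facing the RV
    rv_crescent: tuple[float, float]  # (angular extent rad, thickness px)
    enhancement_patches: tuple[tuple[tuple[float, float], float, float], ...] = ()
    # each patch: ((row, col) center, radius px, intensity boost)

    def validate(self):
        max_wall = self.wall_thickness_base * self.septal_thickening_factor
        if self.lvc_radius + max_wall >= self.image_size / 2:
            raise GeometryError(
                "heart does not fit in frame: "
                f"lvc_radius {self.lvc_radius} + max wall {max_wall} "
                f">= half image size {self.image_size / 2}"
            )
        if self.septal_thickening_factor < 1:
            raise GeometryError("septal_thickening_factor must be >= 1")


@dataclass(frozen=True)
class ContrastModel:
    """Piecewise-constant intensity model for one acquisition contrast."""

    class_means: tuple[float, float, float, float]  # background, LVC, LVM, RV
    noise_sigma: float
    enhancement_visible: bool = False
    misregistration: tuple[int, int] = (0, 0)  # (dy, dx) pixels


@dataclass
class LabeledSlice:
    """One grayscale image in [0, 1] plus its integer class mask."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise GeometryError("image and mask shapes differ")


@dataclass
class ContrastPair:
    """The paired unit consumed by the joint model."""

    cine: LabeledSlice
    lge: LabeledSlice
    anatomy_id: str = ""


def ssfp_preset(noise_sigma: float = 0.02) -> ContrastModel:
    """Cine-SSFP-like: bright blood, mid-gray wall, high SNR."""
    return ContrastModel(
        class_means=(0.05, 0.90, 0.40, 0.80), noise_sigma=noise_sigma
    )


def lge_preset(
    noise_sigma: float = 0.15, misregistration: tuple[int, int] = (0, 0)
) -> ContrastModel:
    """LGE-like: nulled (dark) myocardium, bright blood, visible enhancement, lower SNR."""
    return ContrastModel(
        class_means=(0.05, 0.80, 0.15, 0.70),
        noise_sigma=noise_sigma,
        enhancement_visible=True,
        misregistration=misregistration,
    )


@dataclass(frozen=True)
class GeometryRanges:
    """Uniform sampling intervals for anatomy parameters (pixel units at 128)."""

    image_size: int = 128
    lvc_radius: tuple[float, float] = (14.0, 22.0)
    wall_thickness: tuple[float, float] = (6.0, 10.0)
    septal_thickening: tuple[float, float] = (1.2, 2.0)
    center_jitter: float = 4.0  # max |offset| of LV center from frame center
    rv_extent: tuple[float, float] = (1.6, 2.6)  # radians
    rv_thickness: tuple[float, float] = (8.0, 14.0)
    n_patches: tuple[int, int] = (1, 3)
    patch_radius: tuple[float, float] = (2.0, 4.0)
    patch_boost: tuple[float, float] = (0.35, 0.55)

    def scaled(self, image_size: int) -> "GeometryRanges":
        """Rescale all pixel-unit ranges to another frame size."""
        f = image_size / self.image_size
        sc = lambda t: (t[0] * f, t[1] * f)
        return dataclasses.replace(
            self,
            image_size=image_size,
            lvc_radius=sc(self.lvc_radius),
            wall_thickness=sc(self.wall_thickness),
            center_jitter=self.center_jitter * f,
            rv_thickness=sc(self.rv_thickness),
            patch_radius=sc(self.patch_radius),
        )


def _check_range(name, lo, hi):
    if lo > hi:
        raise ConfigurationError(f"invalid range for {name}: min {lo} > max {hi}")


def sample_anatomy(params: GeometryRanges, seed: int) -> AnatomyModel:
    """Draw one anatomy uniformly from the configured ranges (deterministic in seed)."""
    for name in ("lvc_radius", "wall_thickness", "septal_thickening",
                 "rv_extent", "rv_thickness", "patch_radius", "patch_boost"):
        lo, hi = getattr(params, name)
        _check_range(name, lo, hi)
    _check_range("n_patches", *params.n_patches)
    rng = np.random.default_rng(seed)
    size = params.image_size
    c0 = (size - 1) / 2.0
    center = (
        c0 + rng.uniform(-params.center_jitter, params.center_jitter),
        c0 + rng.uniform(-params.center_jitter, params.center_jitter),
    )
    lvc_r = rng.uniform(*params.lvc_radius)
    wall = rng.uniform(*params.wall_thickness)
    septal = rng.uniform(*params.septal_thickening)
    rv_ext = rng.uniform(*params.rv_extent)
    rv_th = rng.uniform(*params.rv_thickness)

    anatomy = AnatomyModel(
        image_size=size,
        lv_center=center,
        lvc_radius=lvc_r,
        wall_thickness_base=wall,
        septal_thickening_factor=septal,
        rv_crescent=(rv_ext, rv_th),
        enhancement_patches=(),
    )
    anatomy.validate()

    # enhancement patches: mid-wall positions at random angles, radius capped
    # by the local half-thickness so the patch stays inside the LVM annulus
    n_patches = int(rng.integers(params.n_patches[0], params.n_patches[1] + 1))
    patches = []
    for _ in range(n_patches):
        theta = rng.uniform(0, 2 * np.pi)
        local_wall = _wall_at(anatomy, theta)
        r_mid = lvc_r + local_wall / 2.0
        radius = min(rng.uniform(*params.patch_radius), local_wall / 2.0)
        boost = rng.uniform(*params.patch_boost)
        pc = (center[0] + r_mid * np.sin(theta), center[1] + r_mid * np.cos(theta))
        patches.append((pc, radius, boost))
    return dataclasses.replace(anatomy, enhancement_patches=tuple(patches))


# the RV sits on the left of the LV (angle pi in (sin, cos) parametrization)
_RV_ANGLE = np.pi


def _wall_at(anatomy: AnatomyModel, theta: float) -> float:
    """Wall thickness at polar angle theta; septal sector is thickened."""
    extent = anatomy.rv_crescent[0]
    d = np.angle(np.exp(1j * (theta - _RV_ANGLE)))
    if abs(d) <= extent / 2:
        return anatomy.wall_thickness_base * anatomy.septal_thickening_factor
    return anatomy.wall_thickness_base


def rasterize_mask(anatomy: AnatomyModel) -> np.ndarray:
    """Render the integer label mask {0 bg, 1 LVC, 2 LVM, 3 RV}."""
    anatomy.validate()
    size = anatomy.image_size
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rr - anatomy.lv_center[0], cc - anatomy.lv_center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    extent, rv_th = anatomy.rv_crescent
    d = np.angle(np.exp(1j * (theta - _RV_ANGLE)))
    septal = np.abs(d) <= extent / 2
    wall = np.where(
        septal,
        anatomy.wall_thickness_base * anatomy.septal_thickening_factor,
        anatomy.wall_thickness_base,
    )
    r_epi = anatomy.lvc_radius + wall

    mask = np.zeros((size, size), dtype=np.int64)
    mask[(r >= anatomy.lvc_radius) & (r < r_epi)] = LVM
    mask[r < anatomy.lvc_radius] = LVC
    rv_region = septal & (r >= r_epi) & (r < r_epi + rv_th)
    mask[rv_region & (mask == BACKGROUND)] = RV
    return mask


def _render_image(
    anatomy: AnatomyModel,
    mask: np.ndarray,
    model: ContrastModel,
    rng: np.random.Generator,
) -> np.ndarray:
    means = np.asarray(model.class_means, dtype=np.float64)
    image = means[mask]
    if model.enhancement_visible:
        size = anatomy.image_size
        rr, cc = np.mgrid[0:size, 0:size].astype(float)
        for (py, px), radius, boost in anatomy.enhancement_patches:
            patch = (np.hypot(rr - py, cc - px) <= radius) & (mask == LVM)
            image[patch] += boost
    if model.noise_sigma > 0:
        image = image + rng.normal(0.0, model.noise_sigma, image.shape)
    return np.clip(image, 0.0, 1.0)


def _shift_with_fill(arr: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def render_pair(
    anatomy: AnatomyModel,
    cine_model: ContrastModel | None = None,
    lge_model: ContrastModel | None = None,
    seed: int = 0,
    anatomy_id: str = "",
) -> ContrastPair:
    """Rasterize one anatomy under both contrasts.

    The LGE-side misregistration is a rigid integer-pixel translation of
    both its image and mask; pixels shifted in from outside the frame are
    background.
    """
    cine_model = cine_model if cine_model is not None else ssfp_preset()
    lge_model = lge_model if lge_model is not None else lge_preset()
    for m in (cine_model, lge_model):
        dy, dx = m.misregistration
        if max(abs(dy), abs(dx)) >= anatomy.image_size / 8:
            raise ConfigurationError(
                f"misregistration {m.misregistration} too large for "
                f"image size {anatomy.image_size}"
            )
    mask = rasterize_mask(anatomy)
    rng = np.random.default_rng(seed)
    cine_img = _render_image(anatomy, mask, cine_model, rng)
    lge_img = _render_image(anatomy, mask, lge_model, rng)

    cine_mask, lge_mask = mask, mask.copy()
    dy, dx = lge_model.misregistration
    if (dy, dx) != (0, 0):
        lge_img = _shift_with_fill(lge_img, dy, dx, lge_model.class_means[BACKGROUND])
        lge_mask = _shift_with_fill(lge_mask, dy, dx, BACKGROUND)
    return ContrastPair(
        cine=LabeledSlice(cine_img, cine_mask),
        lge=LabeledSlice(lge_img, lge_mask),
        anatomy_id=anatomy_id,
    )


def generate_pairs(
    n_pairs: int,
    params: GeometryRanges | None = None,
    seed: int = 0,
    misregistration: tuple[int, int] = (0, 0),
    cine_noise: float = 0.02,
    lge_noise: float = 0.15,
) -> list[ContrastPair]:
    """Generate `n_pairs` in memory; per-pair seeds derive from `seed`."""
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    params = params if params is not None else GeometryRanges()
    root = np.random.SeedSequence(seed)
    pairs = []
    for i, child in enumerate(root.spawn(n_pairs)):
        sub = child.generate_state(2)
        anatomy = sample_anatomy(params, int(sub[0]))
        pair = render_pair(
            anatomy,
            ssfp_preset(cine_noise),
            lge_preset(lge_noise, misregistration),
            seed=int(sub[1]),
            anatomy_id=f"anat{i:04d}",
        )
        pairs.append(pair)
    return pairs


def generate_dataset(
    n_pairs: int,
    params: GeometryRanges | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
    misregistration: tuple[int, int] = (0, 0),
    cine_noise: float = 0.02,
    lge_noise: float = 0.15,
) -> Path:
    """Write a phantom dataset archive plus a JSON manifest.

    Regeneration with identical arguments is byte-identical.
    """
    from .cli_io import write_archive  # deferred: cli_io imports phantom types

    params = params if params is not None else GeometryRanges()
    pairs = generate_pairs(
        n_pairs, params, seed, misregistration, cine_noise, lge_noise
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    archive = out_dir / "phantoms.zip"
    manifest = {
        "seed": seed,
        "n_pairs": n_pairs,
        "params": dataclasses.asdict(params),
        "misregistration": list(misregistration),
        "noise": {"cine": cine_noise, "lge": lge_noise},
        "entries": [p.anatomy_id for p in pairs],
    }
    write_archive(pairs, archive, provenance=manifest)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return archive
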