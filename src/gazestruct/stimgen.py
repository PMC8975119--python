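"""Search-stimulus composition and the screened stimulus pool.

A search stimulus is a 1280x1024 grayscale background into which a
circular 235-px target patch cropped from a *different* source image is
inserted at one of 10 ring locations.  To hide contour cues, every ring
location's circular contour is blurred on the background (decoy circles)
and the inserted target gets a blurred border.  Stimuli are rendered in
three monochromatic hues (green 90 deg, blue 210 deg, red 330 deg) by an
HSL transform that keeps the gray value as lightness.

The ring is implemented with diameter ~710 px (radius 355 px): the quoted
710-px center distance cannot be a radius on a 1024-px-tall image, so it
is read as the diameter of the location ring; the radius is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import GrayImage
from .imagestats import PropertySet, DiffVector, compute_properties
from . import salience as _salience

__all__ = [
    "LocationRing",
    "TargetPatch",
    "RatedProperties",
    "StimulusSpec",
    "ComposedStimulus",
    "ring_locations",
    "sample_patches",
    "compose_stimulus",
    "monochromatize",
    "build_pool",
]

HUES = (90, 210, 330)
HUE_NAMES = {90: "green", 210: "blue", 330: "red"}
CATEGORIES = ("vegetation", "natural_element", "artifact")


@dataclass(frozen=True)
class LocationRing:
    """Ten candidate target centers on a circle around the image center."""

    center: tuple[int, int]
    radius: float
    positions: tuple[tuple[int, int], ...]

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TargetPatch:
    source_id: str
    patch_index: int
    center_in_source: tuple[int, int]
    diameter: int
    pixels: GrayImage


@dataclass(frozen=True)
class RatedProperties:
    """Standardized continuous ratings of a background image."""

    curvature: float
    regularity: float
    symmetry: float
    depth: float


@dataclass(frozen=True)
class StimulusSpec:
    background_id: str
    target_source_id: str
    patch_index: int
    location_idx: int
    hue: int
    bg_category: str
    tg_category: str
    bg_depth_class: str
    tg_depth_class: str
    rated: RatedProperties
    child_dissimilarity: float
    adult_dissimilarity: float
    props_bg: PropertySet
    diffs: DiffVector
    target_salience: float = float("nan")
    rival_salience: float = float("nan")

    @property
    def category_congruency(self) -> str:
        return "congruent" if self.bg_category == self.tg_category else "incongruent"

    @property
    def depth_congruency(self) -> str:
        return "congruent" if self.bg_depth_class == self.tg_depth_class else "incongruent"


@dataclass(frozen=True)
class ComposedStimulus:
    image: GrayImage
    hard_mask: np.ndarray
    soft_mask: np.ndarray
    location_idx: int


def ring_locations(
    width: int = 1280,
    height: int = 1024,
    radius: float = 355.0,
    n: int = 10,
    phase_deg: float = 0.0,
    target_diameter: int = 235,
) -> LocationRing:
    """Place ``n`` target centers equally spaced on a circle.

    Positions are rounded to integer pixels; an error is raised if any
    target disk would leave the image.
    """
    cx, cy = width // 2, height // 2
    if radius + target_diameter / 2 > min(width, height) / 2:
        raise ValueError("target disks would exit the image at this ring radius")
    positions = []
    for k in range(n):
        ang = np.deg2rad(phase_deg + k * 360.0 / n)
        positions.append((int(round(cx + radius * np.cos(ang))), int(round(cy + radius * np.sin(ang)))))
    return LocationRing(center=(cx, cy), radius=radius, positions=tuple(positions))


def _disk_mask(shape: tuple[int, int], center_xy: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2


def sample_patches(
    src: GrayImage,
    source_id: str,
    n: int = 5,
    diameter: int = 235,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> list[TargetPatch]:
    """Sample ``n`` circular patches with full-disk containment.

    Centers are drawn uniformly with rejection until all pairwise center
    distances are at least ``diameter / 2``; deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = diameter / 2.0
    lo_x, hi_x = int(np.ceil(r)), int(src.width - np.ceil(r))
    lo_y, hi_y = int(np.ceil(r)), int(src.height - np.ceil(r))
    if lo_x > hi_x or lo_y > hi_y:
        raise ValueError(f"source {src.width}x{src.height} too small for diameter {diameter}")
    centers: list[tuple[int, int]] = []
    for _ in range(max_attempts):
        x = int(rng.integers(lo_x, hi_x + 1))
        y = int(rng.integers(lo_y, hi_y + 1))
        if all((x - px) ** 2 + (y - py) ** 2 >= (diameter / 2) ** 2 for px, py in centers):
            centers.append((x, y))
            if len(centers) == n:
                break
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} patches of diameter {diameter} with pairwise "
            f"center distance >= {diameter/2:.0f} px in {max_attempts} attempts"
        )
    side = diameter
    patches = []
    for i, (x, y) in enumerate(centers):
        x0 = min(max(0, x - side // 2), src.width - side)
        y0 = min(max(0, y - side // 2), src.height - side)
        crop = GrayImage(src.levels[y0 : y0 + side, x0 : x0 + side])
        patches.append(TargetPatch(source_id, i, (x, y), diameter, crop))
    return patches


def _soft_disk(shape, center_xy, radius, sigma) -> np.ndarray:
    """Disk indicator smoothed by a Gaussian with finite (3 sigma) support."""
    hard = _disk_mask(shape, center_xy, radius).astype(np.float64)
    if sigma <= 0:
        return hard
    return ndimage.gaussian_filter(hard, sigma, truncate=3.0)


def decoy_contours(
    bg: GrayImage,
    ring: LocationRing,
    target_diameter: int = 235,
    annulus_width: float = 24.0,
    blur_sigma: float = 8.0,
) -> GrayImage:
    """Blur the circular contour of every ring location on the background."""
    arr = bg.normalized
    blurred = ndimage.gaussian_filter(arr, blur_sigma, truncate=3.0)
    yy, xx = np.mgrid[0 : bg.height, 0 : bg.width]
    r_t = target_diameter / 2.0
    ann = np.zeros_like(arr)
    for (x, y) in ring.positions:
        dist = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
        ann[np.abs(dist - r_t) <= annulus_width / 2.0] = 1.0
    weight = np.clip(ndimage.gaussian_filter(ann, blur_sigma / 2.0, truncate=3.0), 0.0, 1.0)
    return GrayImage.from_normalized((1 - weight) * arr + weight * blurred)


def compose_stimulus(
    bg: GrayImage,
    patch: TargetPatch,
    ring: LocationRing,
    location_idx: int,
    blur_sigma: float = 8.0,
    decoy: bool = True,
    annulus_width: float = 24.0,
    decoyed_bg: GrayImage | None = None,
) -> ComposedStimulus:
    """Insert a target patch over a decoy-blurred background.

    The patch is composited with a soft disk mask whose edge is a
    Gaussian-smoothed step (sigma = ``blur_sigma``, support 3 sigma), so
    pixels farther than 3 sigma outside the disk equal the decoy-blurred
    background exactly.  ``hard_mask`` is the unsmoothed disk used for
    gaze-contingent hit detection.
    """
    if not (0 <= location_idx < ring.n):
        raise ValueError("invalid location index")
    if decoyed_bg is not None:
        base = decoyed_bg
    elif decoy:
        base = decoy_contours(bg, ring, patch.diameter, annulus_width, blur_sigma)
    else:
        base = bg
    arr = base.normalized
    x, y = ring.positions[location_idx]
    r = patch.diameter / 2.0
    if patch.pixels.width != patch.diameter or patch.pixels.height != patch.diameter:
        raise ValueError("patch crop must be diameter x diameter")

    canvas = arr.copy()
    x0, y0 = x - patch.diameter // 2, y - patch.diameter // 2
    if x0 < 0 or y0 < 0 or x0 + patch.diameter > bg.width or y0 + patch.diameter > bg.height:
        raise ValueError("target disk exits the image")
    canvas[y0 : y0 + patch.diameter, x0 : x0 + patch.diameter] = patch.pixels.normalized

    soft = _soft_disk(arr.shape, (x, y), r, blur_sigma)
    hard = _disk_mask(arr.shape, (x, y), r)
    out = soft * canvas + (1 - soft) * arr
    return ComposedStimulus(
        image=GrayImage.from_normalized(out),
        hard_mask=hard,
        soft_mask=soft,
        location_idx=location_idx,
    )


def monochromatize(img: GrayImage, hue_deg: float, saturation: float = 1.0) -> np.ndarray:
    """Map gray values to a single hue via HSL (hue, saturation, lightness).

    The gray value becomes the lightness channel, so extracting
    L = (max + min) / 2 from the output recovers the input gray.  Returns
    an (H, W, 3) uint8 RGB array.
    """
    L = img.normalized
    S = float(saturation)
    C = (1.0 - np.abs(2.0 * L - 1.0)) * S
    hp = (hue_deg % 360.0) / 60.0
    X = C * (1.0 - abs(hp % 2.0 - 1.0))
    zero = np.zeros_like(L)
    sector = int(hp)
    rgb_by_sector = {
        0: (C, X, zero),
        1: (X, C, zero),
        2: (zero, C, X),
        3: (zero, X, C),
        4: (X, zero, C),
        5: (C, zero, X),
    }
    r, g, b = rgb_by_sector[sector % 6]
    m = L - C / 2.0
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)


@dataclass
class Catalog:
    """Source images with labels, ratings, dissimilarities and patches."""

    images: dict[str, GrayImage]
    categories: dict[str, str]
    depth_classes: dict[str, str]
    rated: dict[str, RatedProperties]
    child_dissimilarity: pd.DataFrame
    adult_dissimilarity: pd.DataFrame
    patches: dict[str, list[TargetPatch]]

    @property
    def image_ids(self) -> list[str]:
        return list(self.images)


def build_pool(
    catalog: Catalog,
    ring: LocationRing | None = None,
    theta_target: float = 0.25,
    theta_rival: float = 0.10,
    seed: int = 0,
    n_candidates: int | None = 400,
    screen: bool = True,
    blur_sigma: float = 8.0,
    target_pool_size: int | None = None,
    prop_kw: dict | None = None,
) -> pd.DataFrame:
    """Build the screened stimulus pool manifest.

    Candidate (background, target source, patch, location) combinations are
    enumerated; when ``n_candidates`` is set, a seeded stratified subsample
    (balanced over category x depth congruency cells) is evaluated instead
    of the full cross, which keeps the synthetic pipeline tractable.  Each
    candidate is composed, optionally screened by salience, and survivors
    get their property set, difference variables and congruency labels,
    then are expanded by the three hues.  Returns one manifest row per
    StimulusSpec.
    """
    rng = np.random.default_rng(seed)
    if ring is None:
        first = next(iter(catalog.images.values()))
        ring = ring_locations(first.width, first.height)
    prop_kw = prop_kw or {}

    combos = [
        (bg, tg, pi, li)
        for bg in catalog.image_ids
        for tg in catalog.image_ids
        if tg != bg
        for pi in range(len(catalog.patches[tg]))
        for li in range(ring.n)
    ]
    if n_candidates is not None and n_candidates < len(combos):
        # stratify by congruency cell AND category pair so the design stage
        # has supply in every balance cell it must fill
        cells: dict[tuple, list] = {}
        for c in combos:
            bg, tg = c[0], c[1]
            key = (
                "congruent" if catalog.categories[bg] == catalog.categories[tg] else "incongruent",
                "congruent" if catalog.depth_classes[bg] == catalog.depth_classes[tg] else "incongruent",
                catalog.categories[bg],
                catalog.categories[tg],
            )
            cells.setdefault(key, []).append(c)
        per_cell = int(np.ceil(n_candidates / len(cells)))
        combos = []
        for key in sorted(cells):
            block = cells[key]
            take = min(per_cell, len(block))
            idx = rng.choice(len(block), size=take, replace=False)
            combos.extend(block[i] for i in sorted(idx))

    from .imagestats import tile_property_matrix, diff_from_tile_matrices

    bg_props_cache: dict[str, PropertySet] = {}
    decoy_cache: dict[str, GrayImage] = {}
    bg_tiles_cache: dict[str, np.ndarray] = {}
    rows = []
    for bg_id, tg_id, pi, li in combos:
        bg = catalog.images[bg_id]
        patch = catalog.patches[tg_id][pi]
        if bg_id not in decoy_cache:
            decoy_cache[bg_id] = decoy_contours(bg, ring, patch.diameter, blur_sigma=blur_sigma)
        comp = compose_stimulus(
            bg, patch, ring, li, blur_sigma=blur_sigma, decoyed_bg=decoy_cache[bg_id]
        )
        t_sal, r_sal = float("nan"), float("nan")
        if screen:
            smap = _salience.salience_map(comp.image)
            res = _salience.screen_target(
                smap,
                [tuple(map(float, p)) for p in ring.positions],
                li,
                patch.diameter / 2.0,
                theta_target,
                theta_rival,
            )
            t_sal, r_sal = res.target_salience, res.rival_salience
            if not res.accepted:
                continue
        if bg_id not in bg_props_cache:
            bg_props_cache[bg_id] = compute_properties(bg, **prop_kw)
            # difference variables are computed against the background as
            # presented, i.e. with the decoy contours already blurred in
            bg_tiles_cache[bg_id] = tile_property_matrix(decoy_cache[bg_id], **prop_kw)
        pc = tile_property_matrix(comp.image, **prop_kw)
        diffs = diff_from_tile_matrices(bg_tiles_cache[bg_id], pc)
        spec = StimulusSpec(
            background_id=bg_id,
            target_source_id=tg_id,
            patch_index=pi,
            location_idx=li,
            hue=0,
            bg_category=catalog.categories[bg_id],
            tg_category=catalog.categories[tg_id],
            bg_depth_class=catalog.depth_classes[bg_id],
            tg_depth_class=catalog.depth_classes[tg_id],
            rated=catalog.rated[bg_id],
            child_dissimilarity=float(catalog.child_dissimilarity.loc[bg_id, tg_id]),
            adult_dissimilarity=float(catalog.adult_dissimilarity.loc[bg_id, tg_id]),
            props_bg=bg_props_cache[bg_id],
            diffs=diffs,
            target_salience=t_sal,
            rival_salience=r_sal,
        )
        rows.append(spec)
        if target_pool_size is not None and len(rows) >= target_pool_size:
            break
    if not rows:
        raise ValueError(
            f"empty pool after screening (theta_target={theta_target}, "
            f"theta_rival={theta_rival}); lower the thresholds or disable screening"
        )

    records = []
    for spec in rows:
        for hue in HUES:
            s = replace(spec, hue=hue)
            records.append(spec_to_record(s))
    return pd.DataFrame.from_records(records)


def spec_to_record(spec: StimulusSpec) -> dict:
    """Flatten a StimulusSpec to one manifest row."""
    d = spec.diffs
    r = spec.rated
    p = spec.props_bg
    return {
        "background_id": spec.background_id,
        "target_source_id": spec.target_source_id,
        "patch_index": spec.patch_index,
        "location_idx": spec.location_idx,
        "hue": spec.hue,
        "color": HUE_NAMES.get(spec.hue, str(spec.hue)),
        "bg_category": spec.bg_category,
        "tg_category": spec.tg_category,
        "bg_depth_class": spec.bg_depth_class,
        "tg_depth_class": spec.tg_depth_class,
        "category_congruency": spec.category_congruency,
        "depth_congruency": spec.depth_congruency,
        "curvature": r.curvature,
        "regularity": r.regularity,
        "symmetry": r.symmetry,
        "depth": r.depth,
        "child_dissimilarity": spec.child_dissimilarity,
        "adult_dissimilarity": spec.adult_dissimilarity,
        "bg_luminance": p.luminance,
        "bg_alpha": p.alpha,
        "bg_deviation": p.deviation,
        "bg_entropy": p.entropy,
        "bg_skew": p.skew,
        "diff_luminance": d.diff_luminance,
        "diff_alpha": d.diff_alpha,
        "diff_deviation": d.diff_deviation,
        "diff_entropy": d.diff_entropy,
        "diff_skew": d.diff_skew,
        "target_salience": spec.target_salience,
        "rival_salience": spec.rival_salience,
    }
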