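"""Ground-truth synthetic scenes for exercising the whole pipeline.

Two regimes are emulated:

* **Colonies** of densely packed counterstained stem-cell nuclei with a
  reporter-positive subpopulation (graded reporter brightness) and a second
  nuclear marker whose intensity is multiplied by a configurable fold change
  in reporter(+) cells, plus sparse larger, dimmer feeder-cell nuclei.
* **Striped tissue**: small nuclei tiling the whole section, two spatially
  collinear factors (B, C) confined to stripes, and a target factor A whose
  per-nucleus level is ``baseline - effect * C + noise`` — dependent on C
  only, never on B, the causal asymmetry additive models must recover.

Nuclei in dense colonies press against each other, so they are modeled as a
bounded Voronoi tessellation of seed points: each nucleus is the set of
pixels nearest to its seed and within ~1.2 radii of it, with a dim 1-pixel
inter-nuclear boundary. Cells are therefore non-overlapping yet space-
filling, as in a confluent colony; isolated cells (feeders) come out round.
Everything is deterministic under the supplied seed, and every scene carries
its pixel-level ground truth (labeled nucleus masks, per-cell class and true
intensity levels, the planted parameters).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import ImageChannel, MultiChannelImage, read_channel, write_channel

__all__ = [
    "SyntheticScene",
    "PlacementError",
    "generate_colony",
    "generate_striped_tissue",
    "add_impulse_noise",
    "add_debris",
    "save_scene",
    "load_scene_image",
]


class PlacementError(RuntimeError):
    """Nucleus placement failed (canvas too crowded for the request)."""


@dataclass(frozen=True)
class SyntheticScene:
    """A generated image set plus its ground truth.

    Attributes
    ----------
    image : MultiChannelImage
    nucleus_masks : int ndarray (height, width)
        Nucleus id per pixel, -1 outside every nucleus.
    cell_table : DataFrame
        Per nucleus: center, radius, class label and true (noise-free) mean
        intensity per channel.
    planted_params : dict
        The generator configuration, including the seed.
    """

    image: MultiChannelImage
    nucleus_masks: np.ndarray
    cell_table: pd.DataFrame
    planted_params: dict


# --------------------------------------------------------------------------
# rasterisation helpers

def _rasterize(height: int, width: int, centers: np.ndarray,
               radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bounded-Voronoi nucleus raster.

    Returns ``labels`` (nucleus id, -1 background) and ``coverage`` in
    [0, 1]: 1 in nucleus interiors, reduced on the thin inter-nuclear
    boundary, rolling off smoothly at free edges (anti-aliasing).
    """
    yy, xx = np.mgrid[0:height, 0:width]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    tree = cKDTree(centers)
    k = min(2, len(centers))
    dist, idx = tree.query(pix, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    d1 = dist[:, 0]
    lab = idx[:, 0]
    reach = 1.2 * radii[lab]
    # 3-px soft roll-off at free edges: out-of-focus light at colony rims
    edge_cov = np.clip((reach - d1) / 3.0 + 0.5, 0.0, 1.0).reshape(height, width)

    # close the scalloped dips where neighbouring cell outlines meet: packed
    # cells deform to fill those interstices, so the tissue support is smooth
    rr = 4
    dyx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
    disk = (dyx[0] ** 2 + dyx[1] ** 2) <= rr**2
    support = ndimage.binary_closing(
        edge_cov >= 0.5, structure=disk, border_value=0
    )

    lab = lab.reshape(height, width)
    labels = np.where(support, lab, -1)
    filled = support & (edge_cov < 0.5)  # interstices recovered by closing
    coverage = np.where(filled, 0.85, edge_cov)
    if k == 2:
        margin = (dist[:, 1] - d1).reshape(height, width)
        coverage = np.where(
            (labels >= 0) & (margin < 1.0), coverage * 0.88, coverage
        )
    return labels, coverage


def _to_channel(name: str, field: np.ndarray, background: float,
                noise_sigma: float, rng: np.random.Generator,
                bit_depth: int = 8) -> ImageChannel:
    img = field + background + rng.normal(0.0, noise_sigma, size=field.shape)
    hi = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return ImageChannel(
        name=name,
        pixels=np.clip(np.rint(img), 0, hi).astype(dtype),
        bit_depth=bit_depth,
    )


# --------------------------------------------------------------------------
# colony scenes

def _place_clustered(rng: np.random.Generator, height: int, width: int,
                     n: int, radius_range: tuple[float, float],
                     n_colonies: int, max_attempts: int = 10_000
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping seed placement by rejection sampling, grown outward
    from colony centers so nuclei pack into dense clusters."""
    r_lo, r_hi = radius_range
    margin = r_hi + 2.0
    # colony anchors: evenly spread, small jitter, biased toward the center
    # so compact colonies fit the canvas and leave void at the borders
    base = np.linspace(0.5, n_colonies - 0.5, n_colonies) / n_colonies
    colony_centers = np.column_stack(
        [base * width, np.full(n_colonies, height * 0.5)]
    ) * 0.0
    for i, frac in enumerate(base):
        colony_centers[i] = (
            np.array([width, height]) * (0.5 if n_colonies == 1 else frac)
            + rng.uniform(-0.04, 0.04, 2) * np.array([width, height])
        )
    centers: list[np.ndarray] = []
    radii: list[float] = []
    colony_of: list[int] = []
    attempts = 0
    for i in range(n):
        r = rng.uniform(r_lo, r_hi)
        col = i % n_colonies
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"placed only {len(centers)}/{n} nuclei after "
                    f"{max_attempts} attempts; canvas too crowded"
                )
            members = [j for j, c in enumerate(colony_of) if c == col]
            if not members:
                pos = colony_centers[col] + rng.normal(0, 2.0, size=2)
            else:
                j = members[int(rng.integers(len(members)))]
                theta = rng.uniform(0, 2 * np.pi)
                # compressed packing: colony nuclei press into each other's
                # territory; the Voronoi raster keeps them disjoint
                d = (r + radii[j]) * rng.uniform(0.74, 0.82)
                pos = centers[j] + d * np.array([np.cos(theta), np.sin(theta)])
            if not (margin <= pos[0] <= width - margin
                    and margin <= pos[1] <= height - margin):
                continue
            if centers:
                dd = np.linalg.norm(np.array(centers) - pos, axis=1)
                if np.any(dd < 0.72 * (np.array(radii) + r)):
                    continue
            centers.append(pos)
            radii.append(r)
            colony_of.append(col)
            break
    return np.array(centers), np.array(radii)


def generate_colony(
    width: int = 240,
    height: int = 240,
    n_nuclei: int = 41,
    radius_range: tuple[float, float] = (15.0, 19.0),
    fraction_reporter_pos: float = 0.6,
    marker_fold_change: float = 1.17,
    background: float = 6.0,
    noise_sigma: float = 3.0,
    n_feeder: int = 2,
    n_colonies: int = 1,
    counterstain_level: float = 160.0,
    reporter_level: float = 180.0,
    marker_level: float = 120.0,
    brightness_sigma: float = 0.10,
    bit_depth: int = 8,
    seed: int | None = None,
    channel_names: tuple[str, str, str] = ("H33342", "EGFP", "antiOct4"),
) -> SyntheticScene:
    """Dense stem-cell colony with reporter(+)/(-) subpopulations.

    Three channels: counterstain (all nuclei), reporter (bright only in
    reporter(+) nuclei, with graded per-cell levels), and a nuclear marker
    whose level is multiplied by ``marker_fold_change`` in reporter(+)
    cells. ``n_feeder`` sparse, larger, dimmer nuclei model feeder cells.
    """
    if not 0.0 <= fraction_reporter_pos <= 1.0:
        raise ValueError("fraction_reporter_pos must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    centers, radii = _place_clustered(
        rng, height, width, n_nuclei, radius_range, n_colonies
    )
    classes = np.where(
        rng.uniform(size=n_nuclei) < fraction_reporter_pos,
        "reporter(+)", "reporter(-)",
    ).astype(object)

    # feeders: isolated, larger, dimmer; dropped at the freest spot each time
    feeder_r = radius_range[1] * 1.3
    for _ in range(n_feeder):
        cand = rng.uniform(
            [feeder_r * 0.8, feeder_r * 0.8],
            [width - feeder_r * 0.8, height - feeder_r * 0.8],
            size=(4000, 2),
        )
        dd = np.linalg.norm(centers[None, :, :] - cand[:, None, :], axis=2)
        clearance = (dd - 0.78 * (radii + feeder_r)[None, :]).min(axis=1)
        best = int(np.argmax(clearance))
        if clearance[best] < 0:
            raise PlacementError("could not place feeder nuclei")
        centers = np.vstack([centers, cand[best]])
        radii = np.append(radii, feeder_r * rng.uniform(0.9, 1.1))
        classes = np.append(classes, "feeder")

    n_cells = len(radii)
    labels, coverage = _rasterize(height, width, centers, radii)

    bright = rng.lognormal(0.0, brightness_sigma, size=n_cells)
    is_pos = classes == "reporter(+)"
    is_feeder = classes == "feeder"
    cs_level = counterstain_level * bright * np.where(is_feeder, 0.42, 1.0)
    rep_level = np.where(
        is_pos, reporter_level * rng.uniform(0.55, 1.0, size=n_cells), 0.0
    )
    mk_level = (
        marker_level
        * rng.lognormal(0.0, brightness_sigma, size=n_cells)
        * np.where(is_pos, marker_fold_change, 1.0)
        * np.where(is_feeder, 0.35, 1.0)
    )

    def field(levels: np.ndarray) -> np.ndarray:
        lut = np.append(levels, 0.0)  # background slot for label -1
        return lut[labels] * coverage

    channels = (
        _to_channel(channel_names[0], field(cs_level), background, noise_sigma, rng, bit_depth),
        _to_channel(channel_names[1], field(rep_level), background, noise_sigma, rng, bit_depth),
        _to_channel(channel_names[2], field(mk_level), background, noise_sigma, rng, bit_depth),
    )
    image = MultiChannelImage(image_id=f"colony-seed{seed}", channels=channels)
    cell_table = pd.DataFrame(
        {
            "nucleus_id": np.arange(n_cells),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "radius": radii,
            "cell_class": classes,
            f"{channel_names[0]}_level": cs_level,
            f"{channel_names[1]}_level": rep_level,
            f"{channel_names[2]}_level": mk_level,
        }
    )
    params = dict(
        kind="colony", width=width, height=height, n_nuclei=n_nuclei,
        radius_range=radius_range, fraction_reporter_pos=fraction_reporter_pos,
        marker_fold_change=marker_fold_change, background=background,
        noise_sigma=noise_sigma, n_feeder=n_feeder, seed=seed,
    )
    return SyntheticScene(image, labels, cell_table, params)


# --------------------------------------------------------------------------
# striped tissue scenes

def generate_striped_tissue(
    width: int = 800,
    height: int = 800,
    n_stripes: int = 3,
    ripply_effect: float = 0.6,
    noise_sigma: float = 3.0,
    nucleus_radius: float = 11.0,
    stripe_width: float | None = None,
    baseline_a: float = 150.0,
    level_b: float = 180.0,
    level_c: float = 170.0,
    counterstain_level: float = 170.0,
    background: float = 4.0,
    cell_noise_a: float = 8.0,
    brightness_sigma: float = 0.25,
    seed: int | None = None,
    channel_names: tuple[str, str, str, str] = ("DAPI", "Tbx6", "Mesp2", "Ripply2"),
) -> SyntheticScene:
    """Tissue section: stripes of two collinear factors, one causal.

    Four channels (counterstain + factors A/B/C, default names Tbx6/Mesp2/
    Ripply2 for A/B/C). Small nuclei tile the whole section (jittered
    hexagonal seeds, bounded Voronoi cells). B and C are high inside
    ``n_stripes`` horizontal bands with independent per-nucleus brightness;
    the per-nucleus A level is

        A_i = baseline_a - ripply_effect * C_i + Normal(0, cell_noise_a),

    independent of B given C — the planted asymmetry that additive-model
    inference must recover. ``ripply_effect = 0`` gives the null scene.
    """
    if n_stripes < 1:
        raise ValueError("n_stripes must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = 2.0 * nucleus_radius * 0.95
    ys = np.arange(spacing / 2, height - spacing / 4, spacing * np.sqrt(3) / 2)
    centers = []
    for row, y in enumerate(ys):
        xs = np.arange(spacing / 2 + (row % 2) * spacing / 2, width - 1, spacing)
        for x in xs:
            centers.append((x, y))
    centers = np.asarray(centers, dtype=np.float64)
    centers += rng.uniform(-0.22 * spacing, 0.22 * spacing, size=centers.shape)
    centers[:, 0] = np.clip(centers[:, 0], 1.0, width - 2.0)
    centers[:, 1] = np.clip(centers[:, 1], 1.0, height - 2.0)
    n_cells = len(centers)
    radii = rng.uniform(0.85 * nucleus_radius, 1.15 * nucleus_radius, n_cells)
    labels, coverage = _rasterize(height, width, centers, radii)

    if stripe_width is None:
        stripe_width = height / (8.0 * n_stripes)
    stripe_centers = (np.arange(n_stripes) + 0.5) * height / n_stripes
    y_cell = centers[:, 1]
    profile = np.zeros(n_cells)
    for yc in stripe_centers:
        profile += np.exp(-0.5 * ((y_cell - yc) / stripe_width) ** 2)
    profile = np.clip(profile, 0.0, 1.0)

    dapi = counterstain_level * rng.lognormal(0.0, 0.08, n_cells)
    b_lv = level_b * profile * rng.lognormal(0.0, brightness_sigma, n_cells) + 2.0
    c_lv = level_c * profile * rng.lognormal(0.0, brightness_sigma, n_cells) + 2.0
    a_lv = np.clip(
        baseline_a - ripply_effect * c_lv + rng.normal(0.0, cell_noise_a, n_cells),
        1.0, None,
    )

    def field(levels: np.ndarray) -> np.ndarray:
        lut = np.append(levels, 0.0)
        return lut[labels] * coverage

    channels = (
        _to_channel(channel_names[0], field(dapi), background, noise_sigma, rng),
        _to_channel(channel_names[1], field(a_lv), background, noise_sigma, rng),
        _to_channel(channel_names[2], field(b_lv), background, noise_sigma, rng),
        _to_channel(channel_names[3], field(c_lv), background, noise_sigma, rng),
    )
    image = MultiChannelImage(image_id=f"tissue-seed{seed}", channels=channels)
    cell_table = pd.DataFrame(
        {
            "nucleus_id": np.arange(n_cells),
            "cx": centers[:, 0],
            "cy": centers[:, 1],
            "radius": radii,
            "cell_class": np.where(profile > 0.5, "stripe", "interstripe"),
            "stripe_profile": profile,
            f"{channel_names[0]}_level": dapi,
            f"{channel_names[1]}_level": a_lv,
            f"{channel_names[2]}_level": b_lv,
            f"{channel_names[3]}_level": c_lv,
        }
    )
    params = dict(
        kind="striped_tissue", width=width, height=height, n_stripes=n_stripes,
        ripply_effect=ripply_effect, noise_sigma=noise_sigma,
        nucleus_radius=nucleus_radius, stripe_width=stripe_width, seed=seed,
    )
    return SyntheticScene(image, labels, cell_table, params)


# --------------------------------------------------------------------------
# corruption injectors

def add_impulse_noise(channel: ImageChannel, p: float,
                      seed: int | None = None) -> ImageChannel:
    """Set a random fraction ``p`` of pixels to the maximum intensity.

    ``p`` must stay below 0.5: at half the pixels and beyond, even the
    median loses its robustness guarantee.
    """
    if not 0.0 <= p < 0.5:
        raise ValueError(f"impulse fraction must lie in [0, 0.5), got {p}")
    if p == 0.0:
        return channel
    rng = np.random.default_rng(seed)
    n = channel.pixels.size
    n_hit = int(round(p * n))
    flat = channel.pixels.copy().ravel()
    hit = rng.choice(n, size=n_hit, replace=False)
    flat[hit] = 2**channel.bit_depth - 1
    return ImageChannel(
        name=channel.name,
        pixels=flat.reshape(channel.pixels.shape),
        bit_depth=channel.bit_depth,
    )


def add_debris(channel: ImageChannel, n_blobs: int,
               brightness: int | None = None,
               blob_radius: float = 3.0,
               seed: int | None = None,
               centers: list[tuple[float, float]] | None = None) -> ImageChannel:
    """Add small bright irregular blobs (contaminating debris).

    Each blob is a disk of radius ``blob_radius`` with a ragged edge,
    saturated by default. Blob centers may be supplied explicitly (they must
    lie inside the canvas) or are drawn uniformly.
    """
    if n_blobs == 0:
        return channel
    hi = 2**channel.bit_depth - 1
    value = hi if brightness is None else int(brightness)
    h, w = channel.pixels.shape
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = [
            (rng.uniform(0, w - 1), rng.uniform(0, h - 1)) for _ in range(n_blobs)
        ]
    if len(centers) != n_blobs:
        raise ValueError("need one center per blob")
    px = channel.pixels.copy()
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in centers:
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise ValueError(f"blob center ({cx}, {cy}) outside the canvas")
        rr = np.hypot(xx - cx, yy - cy)
        ragged = blob_radius * (0.7 + 0.6 * rng.uniform(size=(h, w)))
        px[rr <= ragged] = value
    return ImageChannel(name=channel.name, pixels=px, bit_depth=channel.bit_depth)


# --------------------------------------------------------------------------
# serialization

def save_scene(scene: SyntheticScene, directory: str | Path) -> dict[str, Path]:
    """Write each channel as a grayscale TIFF plus the cell table as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ch in scene.image.channels:
        p = directory / f"{scene.image.image_id}_{ch.name}.tif"
        write_channel(ch, p)
        paths[ch.name] = p
    table = directory / f"{scene.image.image_id}_cells.csv"
    scene.cell_table.to_csv(table, index=False, float_format="%.17g")
    paths["cell_table"] = table
    return paths


def load_scene_image(paths: dict[str, Path], image_id: str) -> MultiChannelImage:
    """Re-read the channel TIFFs written by :func:`save_scene`."""
    channels = tuple(
        read_channel(p, name) for name, p in paths.items() if name != "cell_table"
    )
    return MultiChannelImage(image_id=image_id, channels=channels)
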