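"""Seeded, ground-truthed synthetic DAB-IHC section images.

Emulates brightfield lumbar spinal-cord sections stained with a brown
chromogen (DAB): dark-brown cell bodies and diffuse brown neuropil staining
on a bluish counterstained tissue background, surrounded by white slide.
Every scene carries exact ground truth (cell label mask, tissue mask,
positive-stain mask) so the image-quantification code can be validated
without real microscopy data.

The palette and physical scale are fixtures, not claims about any real
instrument: 0.65 um/px, soma equivalent diameters 15-40 um, brown
(130, 80, 40) on bluish-gray (190, 190, 210).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw as skdraw


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed in the tissue region."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic section.

    ``diffuse_fraction`` is the target fraction of tissue area covered by
    DAB-positive stain *in total* (somata plus diffuse neuropil blobs); the
    generator adds diffuse blobs until the realized fraction is within
    +/- 0.01 of the target.
    """

    canvas_px: tuple[int, int] = (1024, 1024)
    um_per_pixel: float = 0.65
    tissue_shape: str = "ellipse"  # "ellipse" or "butterfly"
    n_cells: int = 30
    cell_diameter_um: tuple[float, float] = (15.0, 40.0)
    n_touching_pairs: int = 0
    diffuse_fraction: float = 0.10
    stain_color: tuple[int, int, int] = (130, 80, 40)
    diffuse_color: tuple[int, int, int] = (150, 110, 80)
    tissue_color: tuple[int, int, int] = (190, 190, 210)
    background_color: tuple[int, int, int] = (255, 255, 255)
    noise_sd: float = 0.0
    blur_sigma_um: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cell_diameter_um
        if not (0 < lo <= hi):
            raise ValueError("cell_diameter_um must be positive with min <= max")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must be in [0, 1]")
        if self.n_cells < 0 or self.n_touching_pairs < 0:
            raise ValueError("counts must be non-negative")
        if 2 * self.n_touching_pairs > self.n_cells:
            raise ValueError("every touching pair counts 2 toward n_cells")
        if self.tissue_shape not in ("ellipse", "butterfly"):
            raise ValueError(f"unknown tissue_shape {self.tissue_shape!r}")


@dataclass
class GroundTruth:
    """Exact per-pixel truth for one scene.

    ``diffuse_mask_true`` is the full DAB-positive mask (cell somata plus
    diffuse blobs); ``diffuse_area_fraction_true`` is its realized fraction
    of tissue area. ``diffuse_shortfall`` flags scenes where the target
    fraction could not be met within +/- 0.01.
    """

    cell_label_mask: np.ndarray
    cell_count: int
    cell_centroids: list[tuple[float, float]]
    tissue_mask_true: np.ndarray
    diffuse_mask_true: np.ndarray
    diffuse_area_fraction_true: float
    diffuse_shortfall: bool = False


@dataclass
class RenderedSection:
    rgb: np.ndarray  # uint8, (rows, cols, 3)
    um_per_pixel: float
    truth: GroundTruth
    seed: int


def _tissue_mask(config: SceneConfig) -> np.ndarray:
    rows, cols = config.canvas_px
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2.0, cols / 2.0
    if config.tissue_shape == "ellipse":
        a, b = 0.42 * rows, 0.40 * cols
        return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
    # butterfly: two laterally offset, overlapping lobes
    a, b = 0.38 * rows, 0.26 * cols
    off = 0.18 * cols
    left = ((rr - cy) / a) ** 2 + ((cc - (cx - off)) / b) ** 2 <= 1.0
    right = ((rr - cy) / a) ** 2 + ((cc - (cx + off)) / b) ** 2 <= 1.0
    return left | right


def _draw_soma(labels, label, center, equiv_radius_px, ecc, angle, only_free=False):
    """Rasterize one elliptical soma; returns pixel count actually painted."""
    a = equiv_radius_px / np.sqrt(ecc)
    b = equiv_radius_px * np.sqrt(ecc)
    rr, cc = skdraw.ellipse(
        center[0], center[1], a, b, shape=labels.shape, rotation=angle
    )
    if only_free:
        free = labels[rr, cc] == 0
        rr, cc = rr[free], cc[free]
    labels[rr, cc] = label
    return rr.size


def build_scene(config: SceneConfig) -> GroundTruth:
    """Place cells and diffuse stain; deterministic given ``config.seed``.

    Placement is rejection sampling against the tissue distance transform
    (cells fully inside tissue, pairwise separation >= 2 px except the
    requested touching pairs, which abut over a 1-3 px contact).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissue = _tissue_mask(config)
    dist_in = ndi.distance_transform_edt(tissue)
    labels = np.zeros(config.canvas_px, dtype=np.uint16)
    scale = config.um_per_pixel

    lo, hi = config.cell_diameter_um
    # sample equivalent diameters off the extremes so rasterized equivalent
    # diameters stay inside the configured range
    pad = min(1.0, 0.45 * (hi - lo)) if hi > lo else 0.0

    placed: list[tuple[float, float, float]] = []  # (row, col, max semi-axis px)

    def try_place(radius_px, partner=None, max_attempts=400):
        for _ in range(max_attempts):
            if partner is None:
                r = rng.integers(0, tissue.shape[0])
                c = rng.integers(0, tissue.shape[1])
            else:
                pr, pc, prad = partner
                theta = rng.uniform(0, 2 * np.pi)
                d = prad + radius_px - 1.0  # slight overlap -> 1-3 px contact
                r = pr + d * np.sin(theta)
                c = pc + d * np.cos(theta)
                if not (0 <= r < tissue.shape[0] and 0 <= c < tissue.shape[1]):
                    continue
            if dist_in[int(r), int(c)] < radius_px + 1:
                continue
            ok = True
            for qr, qc, qrad in placed:
                if partner is not None and (qr, qc, qrad) == partner:
                    continue
                gap = 1.0 if partner is None else 2.0
                if np.hypot(r - qr, c - qc) < radius_px + qrad + gap + 1:
                    ok = False
                    break
            if ok:
                return float(r), float(c)
        raise PlacementError(
            f"could not place a cell of radius {radius_px:.1f} px after "
            f"{max_attempts} attempts (tissue too small or too crowded)"
        )

    label = 0
    # touching pairs first (circular members so the contact geometry is exact)
    for _ in range(config.n_touching_pairs):
        d1 = rng.uniform(lo + pad, hi - pad)
        d2 = rng.uniform(lo + pad, hi - pad)
        r1, r2 = d1 / 2 / scale, d2 / 2 / scale
        c1 = try_place(r1)
        placed.append((*c1, r1))
        c2 = try_place(r2, partner=placed[-1])
        label += 1
        _draw_soma(labels, label, c1, r1, 1.0, 0.0)
        label += 1
        _draw_soma(labels, label, c2, r2, 1.0, 0.0, only_free=True)
        placed.append((*c2, r2))

    for _ in range(config.n_cells - 2 * config.n_touching_pairs):
        d = rng.uniform(lo + pad, hi - pad)
        ecc = rng.uniform(0.80, 1.0)
        angle = rng.uniform(0, np.pi)
        req = d / 2 / scale
        center = try_place(req / np.sqrt(ecc))  # clearance for the long axis
        label += 1
        _draw_soma(labels, label, center, req, ecc, angle)
        placed.append((*center, req / np.sqrt(ecc)))

    cell_mask = labels > 0
    centroids = [
        tuple(map(float, ndi.center_of_mass(labels == k)))
        for k in range(1, label + 1)
    ]

    # diffuse neuropil blobs: grow the positive mask toward the target fraction
    diffuse = cell_mask.copy()
    tissue_n = int(tissue.sum())
    frac = diffuse[tissue].sum() / tissue_n
    shortfall = False
    if frac > config.diffuse_fraction + 0.01:
        shortfall = True  # somata alone overshoot the requested fraction
    tr, tc = np.nonzero(tissue)
    it = 0
    while frac < config.diffuse_fraction - 0.005:
        it += 1
        if it > 20000:
            shortfall = True
            break
        remaining_px = (config.diffuse_fraction - frac) * tissue_n
        rad = float(np.clip(np.sqrt(remaining_px / np.pi), 2.0, 25.0))
        k = rng.integers(0, tr.size)
        rr, cc = skdraw.disk((tr[k], tc[k]), rad, shape=tissue.shape)
        keep = tissue[rr, cc]
        diffuse[rr[keep], cc[keep]] = True
        frac = diffuse[tissue].sum() / tissue_n

    return GroundTruth(
        cell_label_mask=labels,
        cell_count=label,
        cell_centroids=centroids,
        tissue_mask_true=tissue,
        diffuse_mask_true=diffuse,
        diffuse_area_fraction_true=float(frac),
        diffuse_shortfall=shortfall,
    )


def render_section(truth: GroundTruth, config: SceneConfig) -> RenderedSection:
    """Paint the scene, then blur and add seeded Gaussian noise."""
    rgb = np.empty((*config.canvas_px, 3), dtype=float)
    rgb[...] = config.background_color
    rgb[truth.tissue_mask_true] = config.tissue_color
    # diffuse neuropil stain is a lighter brown than soma stain, as in real
    # DAB material where cell bodies accumulate far more chromogen
    rgb[truth.diffuse_mask_true] = config.diffuse_color
    rgb[truth.cell_label_mask > 0] = config.stain_color
    if config.blur_sigma_um > 0:
        sigma_px = config.blur_sigma_um / config.um_per_pixel
        rgb = ndi.gaussian_filter(rgb, sigma=(sigma_px, sigma_px, 0))
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 1_000_003)
        rgb = rgb + rng.normal(0.0, config.noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return RenderedSection(
        rgb=rgb, um_per_pixel=config.um_per_pixel, truth=truth, seed=config.seed
    )


def generate_scene(config: SceneConfig) -> RenderedSection:
    """Convenience: build_scene + render_section."""
    return render_section(build_scene(config), config)


def generate_fixture_set(out_dir, manifest: list[SceneConfig]) -> Path:
    """Write one PNG + 16-bit label TIFF + JSON sidecar per config, plus a CSV
    manifest; returns the manifest path. Byte-identical on re-run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, cfg in enumerate(manifest):
        stem = f"scene_{i:03d}"
        sec = generate_scene(cfg)
        try:
            iio.imwrite(out / f"{stem}.png", sec.rgb)
            tifffile.imwrite(out / f"{stem}_labels.tif", sec.truth.cell_label_mask)
            sidecar = {
                "seed": cfg.seed,
                "cell_count": sec.truth.cell_count,
                "diffuse_area_fraction_true": sec.truth.diffuse_area_fraction_true,
                "um_per_pixel": cfg.um_per_pixel,
            }
            (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        except OSError as exc:
            raise OSError(f"failed writing fixture files for {out / stem}: {exc}") from exc
        rows.append(
            {
                "file": f"{stem}.png",
                "seed": cfg.seed,
                "cell_count": sec.truth.cell_count,
                "diffuse_fraction": sec.truth.diffuse_area_fraction_true,
                "um_per_pixel": cfg.um_per_pixel,
            }
        )
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
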