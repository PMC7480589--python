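"""Synthetic imaging-flow-cytometry cell images with known ground truth.

The generator emulates the two MFG-E8-eGFP staining phenotypes seen on
apoptotic versus EV-decorated cells:

* **apoptotic** — the cell body is stained almost completely (configurable
  coverage fraction, default well above 60%), plus a few densely stained
  membrane blebs at the periphery; total fluorescence is high.
* **ev** — the cell body itself is unstained (fluorescence at background
  level) but carries very few (1-4), or even only one, intensely stained
  punctate spots of subcellular size attached at the body periphery.

Brightfield shows the same cell body for both classes (slightly dark disc
with rim darkening and granular texture), so class information lives in the
fluorescence channel only.

A separate batch-effect transform models acquisition/protocol shifts, most
importantly the *in-vitro* staining pattern in which fluorescent staining is
evenly distributed inside the cell: the within-body fluorescence pattern is
replaced by a uniform fill at the cell's mean stain level (with a gain and
background offset), while punctate bright detail is preserved. The transform
never touches labels or ground truth.

Noise model: Poisson photon noise on the clean signal plus additive Gaussian
read noise, clamped to the 16-bit range — a standard camera model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph

from .io import (CellImage, CellRecord, DatasetManifest, write_cell_image,
                 ground_truth_to_provenance, IMAGE_SIZE)

__all__ = [
    "GeneratorConfig",
    "BatchEffectConfig",
    "GroundTruth",
    "generate_cell",
    "generate_cells",
    "generate_dataset",
    "apply_batch_effect",
    "generate_spot_pair",
]

_GRID_R, _GRID_C = np.indices((IMAGE_SIZE, IMAGE_SIZE)).astype(np.float64)


@dataclass
class GeneratorConfig:
    """Morphology, staining and noise parameters of the synthetic cells.

    Intensity units are 16-bit camera counts. Defaults are parameterised from
    the qualitative phenotype descriptions (no raw images are available to
    measure them from) and are deliberately generous in class contrast: the
    classes must be separable by design for the learning problem to be
    well-posed.
    """

    # cell body geometry (pixels)
    radius_mean: float = 9.5
    radius_sd: float = 1.0
    radius_min: float = 7.0
    radius_max: float = 12.0
    center_jitter: float = 1.5
    ellipticity_min: float = 0.85  # minor/major axis ratio lower bound

    # brightfield appearance (counts)
    bf_base: float = 18000.0
    bf_body_contrast: float = -2500.0
    bf_rim_darkening: float = -5000.0
    bf_texture_sd: float = 900.0

    # fluorescence background (counts)
    fl_background: float = 1500.0

    # apoptotic phenotype
    stain_coverage_min: float = 0.70
    stain_coverage_max: float = 0.95
    stain_level: float = 12000.0
    stain_patchiness: float = 2.0  # clumpiness of the in-vivo staining pattern
    bleb_count_mean: float = 3.0
    bleb_count_max: int = 6
    bleb_radius_min: float = 1.3
    bleb_radius_max: float = 2.4
    bleb_intensity: float = 18000.0

    # EV phenotype
    spot_count_weights: tuple = (0.4, 0.3, 0.2, 0.1)  # P(k spots), k = 1..4
    spot_radius_min: float = 1.0
    spot_radius_max: float = 2.5
    spot_amplitude: float = 20000.0
    spot_annulus: tuple = (0.8, 1.1)  # placement radius as multiple of body radius
    spot_min_separation: float = 14.0  # spots stay distinct after 4-px dilation

    # optics / noise
    psf_sigma: float = 0.6
    photon_gain: float = 8.0
    read_noise_sd: float = 1311.0  # 2% of the 16-bit dynamic range

    def spot_count_distribution(self) -> np.ndarray:
        w = np.asarray(self.spot_count_weights, dtype=float)
        return w / w.sum()


@dataclass
class BatchEffectConfig:
    """Acquisition-shift transform applied to the fluorescence channel.

    ``mode``:
      * ``none`` — identity.
      * ``in_vitro_uniform`` — evenly distributed staining: the within-body
        fluorescence pattern becomes a uniform fill at ``gain * mean-stain
        + offset``; small-scale bright detail (spots, bleb tips) is kept.
      * ``gain_shift`` — fluorescence ``* gain + offset``, clamped to 16 bit.
    """

    mode: str = "none"
    gain: float = 1.0
    offset: float = 0.0
    detail_radius: int = 3  # structure size preserved by in_vitro_uniform

    def __post_init__(self) -> None:
        if self.mode not in ("none", "in_vitro_uniform", "gain_shift"):
            raise ValueError(f"unknown batch-effect mode {self.mode!r}")

    @classmethod
    def in_vitro(cls) -> "BatchEffectConfig":
        """The default in-vitro staining shift.

        Evenly distributed staining plus a global background elevation from
        excess dye (~18% of full scale): the within-body pattern is replaced
        by a uniform fill and the whole cell interior is brightened, while
        punctate bright detail is preserved. Applied to the annotated
        (in-vitro stained) training cohort in the batch-effect trial, with
        the in-vivo-like cells as the test domain.
        """
        return cls(mode="in_vitro_uniform", gain=1.0, offset=12000.0)


@dataclass
class GroundTruth:
    """Per-cell generator truth; arrays are not serialised to manifests."""

    label: str
    seed: int
    spot_count: int  # EV: attached-vesicle spots; apoptotic: bleb count
    spot_centers: list  # [(row, col), ...]
    stain_coverage: float  # fraction of the body mask that is stained
    clean_fluorescence: np.ndarray | None = field(default=None, repr=False)
    clean_brightfield: np.ndarray | None = field(default=None, repr=False)
    body_mask: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("clean_fluorescence", "clean_brightfield", "body_mask")}
        d["spot_centers"] = [[round(float(r), 3), round(float(c), 3)]
                             for r, c in self.spot_centers]
        d["stain_coverage"] = round(float(self.stain_coverage), 4)
        return json.dumps(d, sort_keys=True)


def _soft_disk(center, radius, edge=1.0) -> np.ndarray:
    d = np.hypot(_GRID_R - center[0], _GRID_C - center[1])
    return np.clip((radius - d) / edge + 0.5, 0.0, 1.0)


def _body_geometry(rng: np.random.Generator, cfg: GeneratorConfig):
    r = float(np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd),
                      cfg.radius_min, cfg.radius_max))
    c = IMAGE_SIZE / 2 - 0.5
    center = (c + rng.uniform(-cfg.center_jitter, cfg.center_jitter),
              c + rng.uniform(-cfg.center_jitter, cfg.center_jitter))
    ecc = rng.uniform(cfg.ellipticity_min, 1.0)
    theta = rng.uniform(0, np.pi)
    return center, r, ecc, theta


def _body_distance(center, ecc, theta) -> np.ndarray:
    """Elliptical distance map (equals the major-axis radius on the outline)."""
    dr, dc = _GRID_R - center[0], _GRID_C - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return np.hypot(u, v / ecc)


def _smooth_noise(rng, sd, sigma=1.5) -> np.ndarray:
    return ndi.gaussian_filter(rng.normal(0.0, sd, (IMAGE_SIZE, IMAGE_SIZE)), sigma)


def _place_points(rng, center, radii, k, min_sep):
    """k points at the given radii from center, pairwise >= min_sep apart."""
    pts: list[tuple[float, float]] = []
    sep = min_sep
    tries = 0
    while len(pts) < k:
        rho = rng.uniform(*radii)
        ang = rng.uniform(0, 2 * np.pi)
        p = (center[0] + rho * np.sin(ang), center[1] + rho * np.cos(ang))
        if not (1.0 <= p[0] <= IMAGE_SIZE - 2 and 1.0 <= p[1] <= IMAGE_SIZE - 2):
            tries += 1
        elif all(np.hypot(p[0] - q[0], p[1] - q[1]) >= sep for q in pts):
            pts.append(p)
        else:
            tries += 1
        if tries > 200:  # relax separation rather than fail; count is preserved
            sep *= 0.8
            tries = 0
    return pts


def _camera(clean: np.ndarray, rng: np.random.Generator,
            cfg: GeneratorConfig) -> np.ndarray:
    sig = np.clip(clean, 0, None)
    noisy = sig
    if cfg.photon_gain > 0:  # photon_gain <= 0 disables shot noise
        noisy = rng.poisson(sig / cfg.photon_gain) * cfg.photon_gain
    if cfg.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.read_noise_sd, sig.shape)
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)


def generate_cell(label: str, cfg: GeneratorConfig | None = None,
                  seed: int = 0, object_id: int = 0,
                  ) -> tuple[CellImage, GroundTruth]:
    """Generate one labelled cell; deterministic given (label, cfg, seed)."""
    if label not in ("apoptotic", "ev"):
        raise ValueError(f"class must be 'apoptotic' or 'ev', got {label!r}")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)

    center, radius, ecc, theta = _body_geometry(rng, cfg)
    dist = _body_distance(center, ecc, theta)
    body_soft = np.clip((radius - dist) + 0.5, 0.0, 1.0)  # anti-aliased body
    body_mask = dist <= radius

    # brightfield: flat background, darker body with granular texture, dark rim
    rim = np.clip(1.0 - np.abs(dist - radius) / 1.5, 0.0, 1.0)
    bf = (cfg.bf_base
          + body_soft * (cfg.bf_body_contrast + _smooth_noise(rng, cfg.bf_texture_sd))
          + rim * cfg.bf_rim_darkening)
    bf = ndi.gaussian_filter(bf, cfg.psf_sigma)

    # fluorescence
    fl = np.full((IMAGE_SIZE, IMAGE_SIZE), cfg.fl_background, dtype=np.float64)
    spot_centers: list[tuple[float, float]] = []
    if label == "apoptotic":
        coverage = rng.uniform(cfg.stain_coverage_min, cfg.stain_coverage_max)
        # unstained cap: cut the body along a random direction at the
        # coverage quantile of the projected coordinate
        ang = rng.uniform(0, 2 * np.pi)
        proj = (_GRID_R - center[0]) * np.sin(ang) + (_GRID_C - center[1]) * np.cos(ang)
        inside = proj[body_mask]
        cut = np.quantile(inside, coverage) if inside.size else 0.0
        stained = body_soft * (proj <= cut)
        # in-vivo staining is patchy/clumpy, not even: modulate the stain by
        # a strictly positive clump field with mean ~1 over the stained area
        clumps = np.clip(1.0 + cfg.stain_patchiness * _smooth_noise(rng, 1.0, 1.2),
                         0.25, None)
        sel = stained > 0.5
        if sel.any():
            clumps = clumps / clumps[sel].mean()
        fl = fl + stained * cfg.stain_level * clumps
        n_bleb = int(np.clip(rng.poisson(cfg.bleb_count_mean), 1, cfg.bleb_count_max))
        bleb_pts = _place_points(rng, center, (0.95 * radius, 1.15 * radius),
                                 n_bleb, 2.5)
        for p in bleb_pts:
            rad = rng.uniform(cfg.bleb_radius_min, cfg.bleb_radius_max)
            fl = fl + cfg.bleb_intensity * _soft_disk(p, rad)
        spot_centers = bleb_pts
        true_count = n_bleb
    else:
        coverage = 0.0
        k = int(1 + rng.choice(len(cfg.spot_count_weights),
                               p=cfg.spot_count_distribution()))
        pts = _place_points(rng, center,
                            (cfg.spot_annulus[0] * radius,
                             cfg.spot_annulus[1] * radius),
                            k, cfg.spot_min_separation)
        for p in pts:
            rad = rng.uniform(cfg.spot_radius_min, cfg.spot_radius_max)
            amp = cfg.spot_amplitude * rng.uniform(0.8, 1.2)
            fl = fl + amp * _soft_disk(p, rad)
        spot_centers = pts
        true_count = k
    fl = ndi.gaussian_filter(fl, cfg.psf_sigma)

    pixels = np.stack([_camera(bf, rng, cfg), _camera(fl, rng, cfg)])
    gt = GroundTruth(label=label, seed=int(seed), spot_count=true_count,
                     spot_centers=spot_centers, stain_coverage=float(coverage),
                     clean_fluorescence=fl, clean_brightfield=bf,
                     body_mask=body_mask)
    return CellImage(object_id, pixels), gt


def estimate_body_mask(brightfield: np.ndarray) -> np.ndarray:
    """Cell body from brightfield alone: Otsu on the (darker-than-background)
    image, largest connected component, holes filled."""
    bf = np.asarray(brightfield, dtype=np.float64)
    thr = skfilters.threshold_otsu(bf)
    mask = bf < thr
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    closed = ndi.binary_closing(mask, structure=skmorph.disk(2))
    return ndi.binary_fill_holes(closed)


def apply_batch_effect(image: CellImage, cfg: BatchEffectConfig) -> CellImage:
    """Apply the batch-effect transform to the fluorescence channel.

    Never alters the label or ground truth (it only sees pixels).
    """
    if cfg.mode == "none":
        return CellImage(image.object_id, image.pixels.copy(),
                         dict(image.channel_roles))
    fl = image.pixels[1].astype(np.float64)
    if cfg.mode == "gain_shift":
        new_fl = fl * cfg.gain + cfg.offset
    else:  # in_vitro_uniform
        body = estimate_body_mask(image.pixels[0])
        detail = fl - ndi.grey_opening(
            fl, footprint=skmorph.disk(cfg.detail_radius))
        detail = np.clip(detail, 0, None)
        base = fl - detail
        fill = float(base[body].mean()) if body.any() else float(base.mean())
        # soft fill boundary: a sharp step at the body outline would itself
        # look like small-scale bright detail downstream
        mask_s = ndi.gaussian_filter(body.astype(np.float64), 2.0)
        new_base = base * (1 - mask_s) + (fill * cfg.gain + cfg.offset) * mask_s
        new_fl = new_base + detail * cfg.gain
    new_fl = np.clip(np.round(new_fl), 0, 65535).astype(np.uint16)
    return CellImage(image.object_id,
                     np.stack([image.pixels[0], new_fl]),
                     dict(image.channel_roles))


def generate_cells(n_apoptotic: int, n_ev: int,
                   cfg: GeneratorConfig | None = None,
                   batch_cfg: BatchEffectConfig | None = None,
                   seed: int = 0, shuffle: bool = True,
                   ) -> tuple[np.ndarray, np.ndarray, list[GroundTruth]]:
    """Generate a cohort in memory.

    Returns ``(pixels, labels, ground_truths)`` with pixels of shape
    ``(n, 2, 32, 32)`` uint16 and labels an object array of class names.
    Fully deterministic given the seed (per-cell seeds are spawned from it).
    """
    if n_apoptotic < 0 or n_ev < 0:
        raise ValueError("cell counts must be non-negative")
    cfg = cfg or GeneratorConfig()
    batch_cfg = batch_cfg or BatchEffectConfig()
    master = np.random.default_rng(seed)
    n = n_apoptotic + n_ev
    cell_seeds = master.integers(0, 2**31 - 1, size=n)
    labels = np.array(["apoptotic"] * n_apoptotic + ["ev"] * n_ev, dtype=object)
    order = master.permutation(n) if shuffle else np.arange(n)
    pixels = np.empty((n, 2, IMAGE_SIZE, IMAGE_SIZE), dtype=np.uint16)
    gts: list[GroundTruth] = []
    out_labels = labels[order]
    for i, lab in enumerate(out_labels):
        img, gt = generate_cell(lab, cfg, seed=int(cell_seeds[i]), object_id=i)
        if batch_cfg.mode != "none":
            img = apply_batch_effect(img, batch_cfg)
        pixels[i] = img.pixels
        gts.append(gt)
    return pixels, out_labels, gts


def generate_dataset(n_apoptotic: int, n_ev: int,
                     cfg: GeneratorConfig | None = None,
                     batch_cfg: BatchEffectConfig | None = None,
                     seed: int = 0, out_dir=None, materialize: bool = True,
                     name: str = "synthetic",
                     ) -> DatasetManifest:
    """Generate a labelled dataset as a manifest, optionally writing TIFs.

    With ``materialize=False`` only the records (labels, per-cell seeds,
    planned file names) are created — useful for count-level checks at the
    scale of the full annotated training corpora without touching the disk.
    """
    cfg = cfg or GeneratorConfig()
    batch_cfg = batch_cfg or BatchEffectConfig()
    master = np.random.default_rng(seed)
    n = n_apoptotic + n_ev
    cell_seeds = master.integers(0, 2**31 - 1, size=n)
    labels = np.array(["apoptotic"] * n_apoptotic + ["ev"] * n_ev, dtype=object)
    order = master.permutation(n)
    labels = labels[order]
    records = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for i, lab in enumerate(labels):
        pths = (f"{name}/{i}_Ch0.ome.tif", f"{name}/{i}_Ch1.ome.tif")
        if materialize:
            img, gt = generate_cell(lab, cfg, seed=int(cell_seeds[i]), object_id=i)
            if batch_cfg.mode != "none":
                img = apply_batch_effect(img, batch_cfg)
            prov = gt.to_json()
            if out_dir is not None:
                pths = tuple(str(p) for p in write_cell_image(img, out_dir))
        else:
            prov = ground_truth_to_provenance(
                {"label": str(lab), "seed": int(cell_seeds[i])})
        records.append(CellRecord(i, pths, label=str(lab), provenance=prov))
    manifest = DatasetManifest(records, name=name)
    if out_dir is not None:
        manifest.to_csv(out_dir / f"{name}_manifest.csv")
    return manifest


def generate_spot_pair(colocalised: bool, cfg: GeneratorConfig | None = None,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two fluorescence channels of one EV-decorated cell.

    Channel B carries spots at the same positions as channel A when
    ``colocalised`` (independent positions otherwise); each channel has its
    own noise realisation. Used to exercise colocalisation analytics against
    a known colocalisation rate.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    center, radius, ecc, theta = _body_geometry(rng, cfg)
    k = int(1 + rng.choice(len(cfg.spot_count_weights),
                           p=cfg.spot_count_distribution()))
    annulus = (cfg.spot_annulus[0] * radius, cfg.spot_annulus[1] * radius)
    pts_a = _place_points(rng, center, annulus, k, cfg.spot_min_separation)
    pts_b = pts_a if colocalised else _place_points(
        rng, center, annulus, k, cfg.spot_min_separation)
    chans = []
    for pts in (pts_a, pts_b):
        fl = np.full((IMAGE_SIZE, IMAGE_SIZE), cfg.fl_background)
        for p in pts:
            rad = rng.uniform(cfg.spot_radius_min, cfg.spot_radius_max)
            fl = fl + cfg.spot_amplitude * _soft_disk(p, rad)
        chans.append(_camera(ndi.gaussian_filter(fl, cfg.psf_sigma), rng, cfg))
    return chans[0], chans[1]
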