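"""Seeded synthetic fluorescence micrographs with known ground truth.

Two phantom families mirror the channels of a loaded-fibroblast experiment:

* **cell phantoms** — an elliptical cell filled with straight fibre segments
  whose orientations are drawn from an axial von Mises distribution, so the
  true orientation concentration ``kappa`` is known exactly (``kappa = 0``
  is isotropic, large ``kappa`` approaches parallel fibres);
* **nucleus phantoms** — an elliptical nucleus carrying bright punctate
  foci over a uniform background, emulating heterochromatin texture, so the
  true focus count driving edge density is known.

``generate_study`` arranges phantoms into a 3-group x 3-timepoint design
(unloaded / physiological / pathological at 1 h, 6 h, 24 h) whose group
means follow a configurable effect template: a transient physiological
alignment response that decays over 24 h, a delayed pathological alignment
response appearing only at 24 h, and chromatin condensation strongly
elevated early after pathological load.  Everything is deterministic given
the seed.

Orientations are axial (a fibre has no polarity, period pi), so sampling
uses the doubled-angle trick: ``theta = vonmises(2*mu, kappa) / 2 mod pi``.
Noise is additive Gaussian clipped to the intensity range; no optical PSF
is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse, line_aa

from .images import Micrograph, RegionMask

__all__ = [
    "CellPhantomParams",
    "NucleusPhantomParams",
    "StudyConfig",
    "StudyRecord",
    "GROUPS",
    "TIMEPOINTS",
    "DEFAULT_KAPPA_TEMPLATE",
    "DEFAULT_FOCI_TEMPLATE",
    "sample_axial_vonmises",
    "render_cell",
    "render_nucleus",
    "generate_study",
    "write_study",
]

GROUPS = ("unloaded", "physiological", "pathological")
TIMEPOINTS = ("1h", "6h", "24h")


@dataclass(frozen=True)
class CellPhantomParams:
    """Ground-truth parameters of one synthetic cell image.

    Lengths in pixels; ``orientation_kappa`` is the von Mises concentration
    of the fibre orientations (0 = isotropic, ``inf`` = all parallel);
    ``noise_sd`` is the Gaussian noise standard deviation on the unit
    intensity scale.
    """

    semi_major: float = 170.0
    semi_minor: float = 85.0
    n_fibres: int = 200
    orientation_kappa: float = 1.0
    mean_orientation: float = 0.0
    fibre_width: float = 2.0
    noise_sd: float = 0.02
    background: float = 0.12

    def __post_init__(self) -> None:
        if self.semi_minor > self.semi_major:
            raise ValueError("semi_minor must not exceed semi_major")
        if self.n_fibres < 0:
            raise ValueError("n_fibres must be >= 0")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class NucleusPhantomParams:
    """Ground-truth parameters of one synthetic nucleus image."""

    semi_major: float = 60.0
    semi_minor: float = 45.0
    n_foci: int = 15
    focus_radius: float = 3.0
    focus_contrast: float = 1.0
    noise_sd: float = 0.02
    background: float = 0.4

    def __post_init__(self) -> None:
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")
        if self.focus_contrast < 0:
            raise ValueError("focus_contrast must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_axial_vonmises(
    mean: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` axial orientations in [0, pi).

    Axial data have period pi, so the doubled angles ``2*theta`` are
    von Mises distributed around ``2*mean`` with concentration ``kappa``.
    ``kappa = 0`` degenerates to the uniform distribution on [0, pi);
    ``kappa = inf`` to the point mass at ``mean``.
    """
    if n == 0:
        return np.empty(0)
    if np.isinf(kappa):
        return np.full(n, mean % np.pi)
    if kappa == 0:
        return rng.uniform(0.0, np.pi, size=n)
    doubled = rng.vonmises(2.0 * mean, kappa, size=n)
    return (doubled / 2.0) % np.pi


def _ellipse_mask(
    canvas: int, semi_major: float, semi_minor: float, rotation: float
) -> np.ndarray:
    c = canvas / 2.0
    # skimage's ellipse rotation is counter-clockwise about the row axis;
    # pass the negated angle so `rotation` is the standard x-axis convention.
    rr, cc = ellipse(
        c, c, semi_minor, semi_major, shape=(canvas, canvas), rotation=-rotation
    )
    mask = np.zeros((canvas, canvas), dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_segment(
    img: np.ndarray, r0: float, c0: float, theta: float, length: float, width: float,
    amp: float = 0.35,
) -> None:
    """Additively accumulate an anti-aliased straight segment of given width.

    Additive accumulation (rather than a max overlay) keeps crossings
    brighter than single fibres and avoids saturating dense regions into a
    structureless blob.
    """
    dr = -np.sin(theta) * length / 2.0  # image rows grow downward
    dc = np.cos(theta) * length / 2.0
    # Parallel 1-px strokes offset perpendicular to the segment; the fibre
    # direction in (row, col) coordinates is (-sin, cos), so (cos, sin) is
    # its perpendicular.
    n_strokes = max(1, int(round(width)))
    pr, pc = np.cos(theta), np.sin(theta)
    offsets = (np.arange(n_strokes) - (n_strokes - 1) / 2.0)
    h, w = img.shape
    for off in offsets:
        rr0 = int(round(r0 + pr * off - dr))
        cc0 = int(round(c0 + pc * off - dc))
        rr1 = int(round(r0 + pr * off + dr))
        cc1 = int(round(c0 + pc * off + dc))
        rr0 = min(max(rr0, 0), h - 1); cc0 = min(max(cc0, 0), w - 1)
        rr1 = min(max(rr1, 0), h - 1); cc1 = min(max(cc1, 0), w - 1)
        rr, cc, val = line_aa(rr0, cc0, rr1, cc1)
        np.add.at(img, (rr, cc), val * amp)


def _finish(
    tex: np.ndarray,
    mask: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    bit_depth: int,
    pixel_size: float,
    channel_role: str,
    n_slices: int,
) -> Micrograph:
    """Clip, add noise, quantise, and optionally expand into a Z-stack."""
    img = np.clip(tex, 0.0, 1.0)
    img[~mask] = 0.0
    if n_slices > 1:
        # Focal-plane envelope: full intensity at the central slice,
        # Gaussian fall-off away from focus; independent noise per slice.
        z = np.arange(n_slices)
        env = np.exp(-0.5 * ((z - (n_slices - 1) / 2.0) / (n_slices / 4.0)) ** 2)
        stack = img[None, :, :] * env[:, None, None]
        if noise_sd > 0:
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        out = np.clip(stack, 0.0, 1.0)
    else:
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        out = np.clip(img, 0.0, 1.0)
    if bit_depth == 8:
        pix = np.round(out * 255).astype(np.uint8)
    elif bit_depth == 16:
        pix = np.round(out * 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return Micrograph(pix, pixel_size=pixel_size, channel_role=channel_role)


def render_cell(
    params: CellPhantomParams,
    seed: int,
    canvas: int = 512,
    bit_depth: int = 8,
    pixel_size: float = 0.1,
    n_slices: int = 1,
) -> tuple[Micrograph, RegionMask]:
    """Render one fibre-textured elliptical cell and its ground-truth mask.

    Fibres are chord-length anti-aliased segments through random interior
    points, clipped to the elliptical mask; the ellipse long axis follows
    ``mean_orientation``.  Deterministic given ``seed``.
    """
    if 2 * params.semi_major >= canvas:
        raise ValueError(
            f"phantom (major axis {2 * params.semi_major}) exceeds canvas {canvas}"
        )
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(canvas, params.semi_major, params.semi_minor,
                         params.mean_orientation)
    tex = np.zeros((canvas, canvas), dtype=np.float64)
    thetas = sample_axial_vonmises(
        params.mean_orientation, params.orientation_kappa, params.n_fibres, rng
    )
    # Random interior anchor points: rejection-free sampling in the ellipse
    # by transforming the unit disc.
    u = np.sqrt(rng.uniform(0, 1, size=params.n_fibres))
    phi = rng.uniform(0, 2 * np.pi, size=params.n_fibres)
    ex = u * np.cos(phi) * params.semi_major
    ey = u * np.sin(phi) * params.semi_minor
    cosr, sinr = np.cos(params.mean_orientation), np.sin(params.mean_orientation)
    cx = canvas / 2.0 + ex * cosr - ey * sinr
    cy = canvas / 2.0 - (ex * sinr + ey * cosr)  # rows grow downward
    # Variable fibre lengths (fractions of the cell's long axis) so the
    # texture stays fibrous rather than filling the cell with full chords.
    lengths = 2.0 * params.semi_major * rng.uniform(0.3, 0.9, size=params.n_fibres)
    for i in range(params.n_fibres):
        _draw_segment(tex, cy[i], cx[i], thetas[i], lengths[i], params.fibre_width)
    tex = params.background + (1.0 - params.background) * np.clip(tex, 0, 1)
    tex[~mask] = 0.0
    micro = _finish(tex, mask, params.noise_sd, rng, bit_depth, pixel_size,
                    "cytoskeleton", n_slices)
    return micro, RegionMask(mask)


def render_nucleus(
    params: NucleusPhantomParams,
    seed: int,
    canvas: int = 512,
    bit_depth: int = 8,
    pixel_size: float = 0.1,
    n_slices: int = 1,
) -> tuple[Micrograph, RegionMask]:
    """Render one focus-textured elliptical nucleus and its mask.

    ``n_foci`` bright discs of radius ``focus_radius`` at intensity
    ``background * (1 + focus_contrast)`` are placed uniformly inside the
    ellipse (shrunk by the focus radius so discs stay interior).
    Deterministic given ``seed``.
    """
    if 2 * params.semi_major >= canvas:
        raise ValueError(
            f"phantom (major axis {2 * params.semi_major}) exceeds canvas {canvas}"
        )
    rng = np.random.default_rng(seed)
    mask = _ellipse_mask(canvas, params.semi_major, params.semi_minor, 0.0)
    tex = np.full((canvas, canvas), params.background, dtype=np.float64)
    a = max(params.semi_major - params.focus_radius - 1, 1.0)
    b = max(params.semi_minor - params.focus_radius - 1, 1.0)
    u = np.sqrt(rng.uniform(0, 1, size=params.n_foci))
    phi = rng.uniform(0, 2 * np.pi, size=params.n_foci)
    fx = canvas / 2.0 + u * np.cos(phi) * a
    fy = canvas / 2.0 + u * np.sin(phi) * b
    level = min(params.background * (1.0 + params.focus_contrast), 1.0)
    for i in range(params.n_foci):
        rr, cc = disk((fy[i], fx[i]), params.focus_radius, shape=tex.shape)
        tex[rr, cc] = level
    tex[~mask] = 0.0
    micro = _finish(tex, mask, params.noise_sd, rng, bit_depth, pixel_size,
                    "nucleus", n_slices)
    return micro, RegionMask(mask)


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------

#: Fibre-orientation concentration means per (group, timepoint): the
#: physiological alignment response peaks at 1 h and decays by 24 h; the
#: pathological response is absent early and appears at 24 h.
DEFAULT_KAPPA_TEMPLATE: dict[tuple[str, str], float] = {
    ("unloaded", "1h"): 0.5, ("unloaded", "6h"): 0.5, ("unloaded", "24h"): 0.5,
    ("physiological", "1h"): 4.0, ("physiological", "6h"): 2.5,
    ("physiological", "24h"): 0.6,
    ("pathological", "1h"): 0.5, ("pathological", "6h"): 0.7,
    ("pathological", "24h"): 3.5,
}

#: Heterochromatin focus-count means per (group, timepoint): condensation is
#: strongly elevated early after pathological load and decays toward basal
#: by 24 h; the physiological response is a modest transient at 1 h.
DEFAULT_FOCI_TEMPLATE: dict[tuple[str, str], float] = {
    ("unloaded", "1h"): 15, ("unloaded", "6h"): 15, ("unloaded", "24h"): 15,
    ("physiological", "1h"): 25, ("physiological", "6h"): 16,
    ("physiological", "24h"): 15,
    ("pathological", "1h"): 60, ("pathological", "6h"): 58,
    ("pathological", "24h"): 22,
}


@dataclass(frozen=True)
class StudyConfig:
    """Design parameters of a synthetic loading study.

    ``n_per_group`` cells (and nuclei) are generated for every
    group x timepoint combination, split round-robin over ``n_wells`` wells
    and ``n_plates`` plates.  Group effects enter through the two templates
    mapping (group, timepoint) to a mean fibre concentration and a mean
    focus count; per-image parameters jitter around the means
    (multiplicative log-normal for kappa, rounded Gaussian for foci).
    """

    n_per_group: int = 10
    n_wells: int = 3
    n_plates: int = 3
    canvas_cell: int = 512
    canvas_nucleus: int = 512
    bit_depth: int = 8
    pixel_size: float = 0.1
    n_slices: int = 1
    kappa_template: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_KAPPA_TEMPLATE)
    )
    foci_template: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FOCI_TEMPLATE)
    )
    kappa_jitter: float = 0.2  # log-normal sigma on kappa
    foci_jitter: float = 0.1   # relative Gaussian sd on focus count
    cell_params: CellPhantomParams = field(default_factory=CellPhantomParams)
    nucleus_params: NucleusPhantomParams = field(default_factory=NucleusPhantomParams)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 images per group per timepoint")


@dataclass
class StudyRecord:
    """One generated image pair with its design metadata and ground truth."""

    image_id: str
    group: str
    timepoint: str
    well: str
    plate: str
    cell_image: Micrograph
    cell_mask: RegionMask
    nucleus_image: Micrograph
    nucleus_mask: RegionMask
    cell_truth: CellPhantomParams
    nucleus_truth: NucleusPhantomParams


def generate_study(
    config: StudyConfig, seed: int
) -> tuple[list[StudyRecord], pd.DataFrame, pd.DataFrame]:
    """Generate the full 3 x 3 design in memory.

    Returns ``(records, design, truth)`` where ``design`` is the tidy
    experiment table (image_id, group, timepoint, well, plate) and ``truth``
    holds the per-image generator parameters.  Byte-identical for identical
    ``(config, seed)``.
    """
    root = np.random.default_rng(seed)
    records: list[StudyRecord] = []
    idx = 0
    for group in GROUPS:
        for tp in TIMEPOINTS:
            kappa_mean = config.kappa_template[(group, tp)]
            foci_mean = config.foci_template[(group, tp)]
            for rep in range(config.n_per_group):
                rng = np.random.default_rng(root.integers(0, 2**31))
                kappa = float(
                    kappa_mean * np.exp(rng.normal(0.0, config.kappa_jitter))
                )
                n_foci = max(
                    0,
                    int(round(rng.normal(foci_mean, config.foci_jitter * foci_mean))),
                )
                mean_ori = float(rng.uniform(0, np.pi))
                scale = float(rng.uniform(0.9, 1.1))
                cp = replace(
                    config.cell_params,
                    orientation_kappa=kappa,
                    mean_orientation=mean_ori,
                    semi_major=config.cell_params.semi_major * scale,
                    semi_minor=config.cell_params.semi_minor * scale,
                )
                np_ = replace(
                    config.nucleus_params,
                    n_foci=n_foci,
                    semi_major=config.nucleus_params.semi_major * scale,
                    semi_minor=config.nucleus_params.semi_minor * scale,
                )
                cell_seed = int(rng.integers(0, 2**31))
                nuc_seed = int(rng.integers(0, 2**31))
                cell_img, cell_mask = render_cell(
                    cp, cell_seed, canvas=config.canvas_cell,
                    bit_depth=config.bit_depth, pixel_size=config.pixel_size,
                    n_slices=config.n_slices,
                )
                nuc_img, nuc_mask = render_nucleus(
                    np_, nuc_seed, canvas=config.canvas_nucleus,
                    bit_depth=config.bit_depth, pixel_size=config.pixel_size,
                    n_slices=config.n_slices,
                )
                records.append(
                    StudyRecord(
                        image_id=f"img{idx:04d}",
                        group=group,
                        timepoint=tp,
                        well=f"w{rep % config.n_wells + 1}",
                        plate=f"p{rep % config.n_plates + 1}",
                        cell_image=cell_img,
                        cell_mask=cell_mask,
                        nucleus_image=nuc_img,
                        nucleus_mask=nuc_mask,
                        cell_truth=cp,
                        nucleus_truth=np_,
                    )
                )
                idx += 1
    design = pd.DataFrame(
        [
            {
                "image_id": r.image_id, "group": r.group, "timepoint": r.timepoint,
                "well": r.well, "plate": r.plate,
            }
            for r in records
        ]
    )
    truth = pd.DataFrame(
        [
            {
                "image_id": r.image_id, "group": r.group, "timepoint": r.timepoint,
                "orientation_kappa": r.cell_truth.orientation_kappa,
                "mean_orientation": r.cell_truth.mean_orientation,
                "n_fibres": r.cell_truth.n_fibres,
                "n_foci": r.nucleus_truth.n_foci,
                "focus_contrast": r.nucleus_truth.focus_contrast,
                "cell_semi_major": r.cell_truth.semi_major,
                "cell_semi_minor": r.cell_truth.semi_minor,
                "nucleus_semi_major": r.nucleus_truth.semi_major,
                "nucleus_semi_minor": r.nucleus_truth.semi_minor,
            }
            for r in records
        ]
    )
    return records, design, truth


def write_study(
    records: list[StudyRecord],
    design: pd.DataFrame,
    truth: pd.DataFrame,
    output_dir: str | Path,
) -> Path:
    """Write the generated study to disk: TIFFs plus design and truth CSVs."""
    out = Path(output_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for r in records:
        r.cell_image.to_tiff(img_dir / f"{r.image_id}_cell.tif")
        r.cell_mask.to_tiff(img_dir / f"{r.image_id}_cell_mask.tif")
        r.nucleus_image.to_tiff(img_dir / f"{r.image_id}_nucleus.tif")
        r.nucleus_mask.to_tiff(img_dir / f"{r.image_id}_nucleus_mask.tif")
    design.to_csv(out / "design.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return out
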