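"""Seeded synthetic inputs with ground truth for every pipeline stage.

The early fly embryo is a syncytium: cortical nuclei sit under polygonal
F-actin caps separated by thin actin-rich furrows. This module emulates
the measurement substrates of the analysis — cap/nucleus images, actin
co-sedimentation densitometry tables, TIRF line profiles across filament
bundles, and centrosome/spindle point annotations — from explicit,
validated specifications, so that every downstream estimator can be
checked against known truth.

Caps are laid out as a jittered lattice of nucleus sites; each pixel is
assigned to its nearest site (a Voronoi-like tessellation) and painted as
a cap interior when it falls within that cap's target radius, with bright
ridges along compartment boundaries. A configurable fraction of lattice
sites is left empty, emulating nuclear fallout, and a second small-area
mode in the cap-size mixture emulates the bimodal size distributions seen
in perturbed embryos.

All randomness in one call flows from a single integer seed through one
``numpy.random.Generator``; identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.ndimage import gaussian_filter

from .tirf_bundling import LineProfile

__all__ = [
    "CapFieldSpec",
    "GroundTruth",
    "BindingSimSpec",
    "TirfFieldSpec",
    "generate_cap_field",
    "generate_binding_table",
    "generate_tirf_profiles",
    "generate_point_geometry",
    "hill_curve",
]

#: High-speed pelleting F-actin concentration series (μM), including the
#: zero-actin reaction used for the nonspecific-pelleting correction.
DEFAULT_CONCENTRATIONS_UM = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0)

#: Fixed total band intensity (supernatant + pellet) in arbitrary
#: densitometry units; estimators must be invariant to this scale.
_TOTAL_BAND_INTENSITY = 1000.0


class CapFieldSpec(BaseModel):
    """Parameters of a synthetic actin-cap (or nuclear) field.

    ``n_caps`` is the number of lattice sites; ``fallout_fraction`` of them
    are left empty (background), so the number of painted caps is
    ``n_caps - round(fallout_fraction * n_caps)``. Cap target areas are
    drawn from a two-mode Gaussian mixture: with probability
    ``small_cap_fraction`` from the small mode (default centred at 30 μm²,
    the size of small caps in perturbed embryos), else from the main mode.
    Targets steer the relative cell sizes of the tessellation (see
    :func:`generate_cap_field`); realized per-cap areas are recorded as
    ground truth.
    """

    model_config = ConfigDict(frozen=True)

    field_size_px: tuple[int, int] = (320, 320)
    pixel_size_um: float = Field(0.35, gt=0)
    n_caps: int = Field(100, ge=1)
    cap_area_mean_um2: float = Field(120.0, gt=0)
    cap_area_sd_um2: float = Field(20.0, gt=0)
    small_cap_fraction: float = Field(0.0, ge=0, le=1)
    small_cap_area_mean_um2: float = Field(30.0, gt=0)
    small_cap_area_sd_um2: float = Field(8.0, gt=0)
    fallout_fraction: float = Field(0.0, ge=0, le=1)
    ridge_intensity: float = Field(230.0, ge=0)
    interior_intensity: float = Field(115.0, ge=0)
    background_intensity: float = Field(25.0, ge=0)
    psf_sigma_px: float = Field(0.8, ge=0)
    noise_sd: float = Field(12.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CapFieldSpec":
        if not (
            self.ridge_intensity > self.interior_intensity > self.background_intensity
        ):
            raise ValueError("require ridge_intensity > interior_intensity > background_intensity")
        field_area = self.field_size_px[0] * self.field_size_px[1] * self.pixel_size_um**2
        mixture_mean = (
            self.small_cap_fraction * self.small_cap_area_mean_um2
            + (1 - self.small_cap_fraction) * self.cap_area_mean_um2
        )
        if self.n_caps * mixture_mean > field_area:
            raise ValueError("n_caps × mean cap area exceeds the field area")
        return self


@dataclass
class GroundTruth:
    """Painted geometry of a synthetic field, exact by construction.

    ``label_map`` holds consecutive labels 1..n for cap interiors+ridges
    (0 = background); ``table`` records per-cap realized area (μm²),
    centroid (μm, x=column axis) and the drawn target area.
    """

    label_map: np.ndarray
    pixel_size_um: float
    table: pd.DataFrame  # label, area_um2, centroid_x_um, centroid_y_um, target_area_um2

    @property
    def n_caps(self) -> int:
        return len(self.table)


def _lattice_sites(spec: CapFieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of ``n_caps`` sites (row, col in px), min spacing enforced."""
    h, w = spec.field_size_px
    gr = max(1, round(math.sqrt(spec.n_caps * h / w)))
    gc = math.ceil(spec.n_caps / gr)
    while gr * gc < spec.n_caps:
        gr += 1
    cy, cx = h / gr, w / gc
    cells = rng.permutation(gr * gc)[: spec.n_caps]
    rows = (cells // gc + 0.5) * cy + rng.uniform(-0.3, 0.3, spec.n_caps) * cy
    cols = (cells % gc + 0.5) * cx + rng.uniform(-0.3, 0.3, spec.n_caps) * cx
    return np.column_stack([rows, cols])


def generate_cap_field(spec: CapFieldSpec) -> tuple["Image2D", GroundTruth]:
    """Render a cap field image and its exact ground truth.

    Each cap is one cell of a power (Laguerre) tessellation of the
    jittered site lattice: pixel → argmin over sites of
    ``|x − s_k|² − r_k²`` with weight r_k² from the drawn target area, so
    larger targets claim larger cells and the field is tiled completely
    except where fallout left a site empty (those cells are background).
    Compartment boundaries are painted as a ~2 px ridge (1 px ring inside
    each adjoining cap). The :class:`GroundTruth` label map and table
    describe the painted geometry exactly (areas recomputed from the
    painted map, so map and table agree to the pixel).
    """
    from .image import Image2D  # local import to avoid cycle at module load

    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    px = spec.pixel_size_um

    sites = _lattice_sites(spec, rng)
    n_empty = round(spec.fallout_fraction * spec.n_caps)
    empty = np.zeros(spec.n_caps, dtype=bool)
    empty[rng.permutation(spec.n_caps)[:n_empty]] = True

    # target areas from the two-mode mixture
    is_small = rng.random(spec.n_caps) < spec.small_cap_fraction
    areas = np.where(
        is_small,
        rng.normal(spec.small_cap_area_mean_um2, spec.small_cap_area_sd_um2, spec.n_caps),
        rng.normal(spec.cap_area_mean_um2, spec.cap_area_sd_um2, spec.n_caps),
    )
    areas = np.clip(areas, 4 * px**2, None)  # a cap occupies at least ~4 px
    weights_px2 = areas / math.pi / px**2  # r_k² in px²
    target_px = areas / px**2

    # power-diagram assignment over the pixel grid; a few fixed-point
    # weight updates pull realized cell areas toward their targets
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")

    def assign(wts: np.ndarray) -> np.ndarray:
        best = np.full((h, w), np.inf)
        out = np.zeros((h, w), dtype=np.int64)
        for k in range(spec.n_caps):
            power = (rr - sites[k, 0]) ** 2 + (cc - sites[k, 1]) ** 2 - wts[k]
            closer = power < best
            best[closer] = power[closer]
            out[closer] = k
        return out

    for _ in range(4):
        site = assign(weights_px2)
        realized = np.bincount(site.ravel(), minlength=spec.n_caps).astype(float)
        weights_px2 = weights_px2 + (target_px - realized) / math.pi
    site = assign(weights_px2)

    gt = np.where(empty[site], 0, site + 1)

    # relabel painted caps consecutively from 1
    present = np.unique(gt[gt > 0])
    remap = np.zeros(spec.n_caps + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    gt = remap[gt]

    # ridges: 1-px ring inside each cap along any 4-connected boundary to a
    # different compartment or to background; caps clipped by the field of
    # view get no ridge along the image border (the furrow is out of frame)
    ridge = np.zeros((h, w), dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = gt.copy()  # border-replicated: no ridge along the image edge
        rs = slice(max(dr, 0), h + min(dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        rs2 = slice(max(-dr, 0), h + min(-dr, 0))
        cs2 = slice(max(-dc, 0), w + min(-dc, 0))
        shifted[rs, cs] = gt[rs2, cs2]
        ridge |= (gt > 0) & (shifted != gt)

    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    img[gt > 0] = spec.interior_intensity
    img[ridge] = spec.ridge_intensity
    if spec.psf_sigma_px > 0:
        # diffraction: the painted scene as the microscope would render it
        img = gaussian_filter(img, spec.psf_sigma_px, mode="reflect")
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)

    table = _ground_truth_table(gt, px, areas, present)
    return Image2D(img, px, channel_name="synthetic-caps"), GroundTruth(gt, px, table)


def _ground_truth_table(
    gt: np.ndarray, px: float, target_areas: np.ndarray, present: np.ndarray
) -> pd.DataFrame:
    labels = np.arange(1, gt.max() + 1) if gt.max() > 0 else np.array([], dtype=int)
    rows = []
    for lab in labels:
        mask = gt == lab
        n = int(mask.sum())
        r, c = np.nonzero(mask)
        rows.append(
            {
                "label": int(lab),
                "area_um2": n * px**2,
                "centroid_x_um": float(c.mean()) * px,
                "centroid_y_um": float(r.mean()) * px,
                "target_area_um2": float(target_areas[present[lab - 1] - 1]),
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "area_um2", "centroid_x_um", "centroid_y_um", "target_area_um2"]
    )


# ---------------------------------------------------------------------------
# co-sedimentation densitometry


def hill_curve(conc_um, kd_um: float, h: float, plateau: float = 1.0):
    """Cooperative binding curve f(A) = plateau·A^h / (K_d^h + A^h)."""
    a = np.asarray(conc_um, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = plateau * a**h / (kd_um**h + a**h)
    return np.where(a == 0, 0.0, f)


class BindingSimSpec(BaseModel):
    """Ground-truth model and noise for a simulated pelleting assay.

    Defaults reproduce the study conditions of the high-speed assay: seven
    F-actin concentrations (0–4 μM, the 0 reaction providing the
    nonspecific-pelleting control) and three replicates.
    """

    model_config = ConfigDict(frozen=True)

    true_kd_um: float = Field(0.45, gt=0)
    true_h: float = Field(2.9, gt=0)
    true_plateau: float = Field(1.0, gt=0, le=1)
    concentrations_um: tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    nonspecific_pellet_fraction: float = Field(0.05, ge=0, lt=1)
    noise_sd: float = Field(0.02, ge=0, lt=0.2)
    n_replicates: int = Field(3, ge=1)
    condition: str = "BtszB-CT"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "BindingSimSpec":
        if min(self.concentrations_um) < 0:
            raise ValueError("concentrations must be nonnegative")
        if 0.0 not in self.concentrations_um:
            raise ValueError("concentrations must include 0 (nonspecific control)")
        return self


def generate_binding_table(spec: BindingSimSpec) -> pd.DataFrame:
    """Simulate supernatant/pellet band intensities for each reaction.

    Pellet fraction at actin concentration A is
    ``p0 + (1 - p0) · plateau · A^h/(K_d^h + A^h)`` plus Gaussian noise,
    clipped to [0, 1]; band intensities are the fraction times a fixed
    total, so absolute densitometry units carry no information.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    p0 = spec.nonspecific_pellet_fraction
    for conc in spec.concentrations_um:
        bound = float(hill_curve(conc, spec.true_kd_um, spec.true_h, spec.true_plateau))
        for rep in range(1, spec.n_replicates + 1):
            p = p0 + (1 - p0) * bound
            if spec.noise_sd > 0:
                p += rng.normal(0.0, spec.noise_sd)
            p = float(np.clip(p, 0.0, 1.0))
            rows.append(
                {
                    "actin_conc_um": conc,
                    "replicate": rep,
                    "supernatant_intensity": (1 - p) * _TOTAL_BAND_INTENSITY,
                    "pellet_intensity": p * _TOTAL_BAND_INTENSITY,
                    "condition": spec.condition,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TIRF line profiles


class TirfFieldSpec(BaseModel):
    """Synthetic line profiles across single filaments and bundles.

    Each profile is a Gaussian of width ``psf_sigma_px`` whose amplitude
    is the filament count times ``single_filament_amplitude`` (fluorescence
    adds linearly within a diffraction-limited bundle). Bundle counts are
    ``2 + Poisson(filaments_per_bundle_mean - 2)``.
    """

    model_config = ConfigDict(frozen=True)

    n_filaments: int = Field(40, ge=1)
    n_bundles: int = Field(40, ge=0)
    filaments_per_bundle_mean: float = Field(3.4, ge=2)
    psf_sigma_px: float = Field(1.5, gt=0)
    single_filament_amplitude: float = Field(100.0, gt=0)
    background_level: float = Field(20.0, ge=0)
    noise_sd: float = Field(5.0, ge=0)
    pixel_size_nm: float = Field(143.0, gt=0)
    n_samples: int = Field(21, ge=7)
    seed: int = 0


def generate_tirf_profiles(spec: TirfFieldSpec) -> list[tuple[LineProfile, int]]:
    """Return (profile, true filament count) pairs, singles then bundles."""
    rng = np.random.default_rng(spec.seed)
    counts = [1] * spec.n_filaments + [
        int(2 + rng.poisson(spec.filaments_per_bundle_mean - 2))
        for _ in range(spec.n_bundles)
    ]
    x = np.arange(spec.n_samples, dtype=float)
    out = []
    for count in counts:
        center = (spec.n_samples - 1) / 2 + rng.uniform(-0.5, 0.5)
        amp = count * spec.single_filament_amplitude
        y = spec.background_level + amp * np.exp(
            -((x - center) ** 2) / (2 * spec.psf_sigma_px**2)
        )
        if spec.noise_sd > 0:
            y = np.clip(y + rng.normal(0.0, spec.noise_sd, y.shape), 0.0, None)
        out.append(
            (LineProfile(positions=x, intensities=y, pixel_size_nm=spec.pixel_size_nm), count)
        )
    return out


# ---------------------------------------------------------------------------
# centrosome / spindle point annotations


def generate_point_geometry(
    n_pairs: int,
    separation_um: float,
    angle_deg: float,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Nuclear centers with centrosome pairs at a set angle and separation.

    The two centrosomes of each nucleus subtend ``angle_deg`` at the
    nuclear center and lie ``separation_um`` apart (so at 180° they sit
    diametrically opposite). Isotropic Gaussian jitter of SD ``jitter_um``
    is added to each centrosome coordinate. Spindle-pole columns duplicate
    the centrosome positions (metaphase poles coincide with centrosomes).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 < angle_deg <= 180:
        raise ValueError("angle_deg must be in (0, 180]")
    rng = np.random.default_rng(seed)
    alpha = math.radians(angle_deg)
    radius = separation_um / (2 * math.sin(alpha / 2))

    spacing = 4 * separation_um
    side = math.ceil(math.sqrt(n_pairs))
    idx = np.arange(n_pairs)
    nx = (idx % side) * spacing
    ny = (idx // side) * spacing

    phi = rng.uniform(0, 2 * math.pi, n_pairs)
    rows = []
    for i in range(n_pairs):
        pts = {}
        for name, ang in (("a", phi[i] - alpha / 2), ("b", phi[i] + alpha / 2)):
            cx = nx[i] + radius * math.cos(ang)
            cy = ny[i] + radius * math.sin(ang)
            if jitter_um > 0:
                cx += rng.normal(0, jitter_um)
                cy += rng.normal(0, jitter_um)
            pts[name] = (cx, cy)
        rows.append(
            {
                "nucleus_id": i + 1,
                "nucleus_x_um": nx[i],
                "nucleus_y_um": ny[i],
                "centrosome_a_x_um": pts["a"][0],
                "centrosome_a_y_um": pts["a"][1],
                "centrosome_b_x_um": pts["b"][0],
                "centrosome_b_y_um": pts["b"][1],
                "spindle_a_x_um": pts["a"][0],
                "spindle_a_y_um": pts["a"][1],
                "spindle_b_x_um": pts["b"][0],
                "spindle_b_y_um": pts["b"][1],
            }
        )
    return pd.DataFrame(rows)
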