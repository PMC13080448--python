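"""Ground-truthed synthetic inputs for every analysis stage.

Each generator emulates the statistical structure a downstream stage
assumes and emits a truth table listing every planted object, so recovery
can be scored exactly without any external data:

* metaphase FISH frames: a dense DAPI chromosome cluster, two (configurable)
  green centromere-8 objects, and red MYC foci planted either scattered off
  the chromosome mass (the double-minute phenotype) or on it (the HSR-like
  phenotype), with PSF blur and Gaussian background noise;
* aggregate fields: non-overlapping disks with lognormal diameters;
* compressive stress-strain curves: a compliant toe followed by a linear
  elastic region of known slope, plus additive noise;
* Ct tables with planted log2 fold-changes and a silent housekeeping gene.

Foci are rendered as Gaussian intensity blobs (sigma = radius / 2) then
blurred, matching the diffraction-limited spot appearance that
threshold-based detection assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .io_core import RasterImage, FishImage

MAX_PLACEMENT_TRIES = 1000

EC_FOCUS = "EC_FOCUS"
INTRA_FOCUS = "INTRA_FOCUS"
CHR8 = "CHR8"
CHROMOSOME_MASK = "CHROMOSOME_MASK"
AGGREGATE = "AGGREGATE"


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without violating separation."""


@dataclass
class GroundTruth:
    """Planted-object table plus the masks the objects were planted against.

    ``table`` has one row per object with columns
    (cell_id, object_class, row_px, col_px, radius_px, area_px,
    diameter_um, area_um2); columns not meaningful for a class are NaN.
    ``masks`` holds the noiseless binary DAPI and chr8 masks for metaphase
    frames, the oracle for overlap-classification tests.
    """

    table: pd.DataFrame
    masks: dict = field(default_factory=dict)

    def rows(self, object_class: str) -> pd.DataFrame:
        return self.table[self.table["object_class"] == object_class]


# ---------------------------------------------------------------------------
# metaphase FISH frames
# ---------------------------------------------------------------------------

@dataclass
class MetaphaseSpec:
    """Parameters of one synthetic metaphase spread.

    The double-minute regime scatters ``n_ec_foci`` red spots off the
    chromosome mass; the HSR-like regime plants ``n_intrachromosomal_foci``
    on it. Planted foci are pairwise separated by at least
    ``min_separation_px`` (default 4x focus radius, comfortably above the
    2x-radius floor) so well-separated recovery is well defined.
    """

    n_ec_foci: int = 40
    n_intrachromosomal_foci: int = 0
    n_chr8: int = 2
    focus_radius_px: float = 3.0
    centromere_radius_px: float = 5.0
    chromosome_mask_style: Mapping = field(
        default_factory=lambda: {"n_blobs": 30, "cluster_radius_frac": 0.22}
    )
    background_noise_sd: float = 0.02
    psf_sigma_px: float = 0.8
    image_size_px: int = 256
    min_separation_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ec_foci, self.n_intrachromosomal_foci, self.n_chr8) < 0:
            raise ValueError("object counts must be >= 0")
        if self.focus_radius_px <= 0 or self.centromere_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.background_noise_sd < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise sd and PSF sigma must be nonnegative")
        if self.image_size_px < 16:
            raise ValueError("image_size_px too small")
        if self.min_separation_px is None:
            self.min_separation_px = 4.0 * self.focus_radius_px
        if self.min_separation_px < 2.0 * self.focus_radius_px:
            raise ValueError("min_separation_px below the 2x-radius floor")


def _gaussian_blob(shape: tuple, center: tuple, sigma: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


def _render_spots(shape: tuple, centers: Sequence[tuple], sigma: float) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    for c in centers:
        out += _gaussian_blob(shape, c, sigma)
    return out


def _chromosome_mask(size: int, style: Mapping, rng: np.random.Generator) -> np.ndarray:
    """Union of elongated blobs confined to a central disk."""
    mask = np.zeros((size, size), dtype=bool)
    n_blobs = int(style.get("n_blobs", 30))
    cluster_r = float(style.get("cluster_radius_frac", 0.22)) * size
    center = size / 2.0
    for _ in range(n_blobs):
        theta = rng.uniform(0, 2 * np.pi)
        rad = cluster_r * np.sqrt(rng.uniform())
        cy = center + rad * np.sin(theta)
        cx = center + rad * np.cos(theta)
        length = rng.uniform(0.04, 0.07) * size
        width = rng.uniform(0.012, 0.02) * size
        rr, cc = draw_ellipse(
            cy, cx, length, width, shape=mask.shape,
            rotation=rng.uniform(0, np.pi),
        )
        mask[rr, cc] = True
    return mask


def _sample_positions(
    n: int,
    allowed: np.ndarray,
    min_separation: float,
    rng: np.random.Generator,
    what: str,
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers on True pixels of ``allowed``,
    pairwise separated by ``min_separation``. Bounded retries; exceeding
    them is an error, never silent truncation."""
    coords = np.argwhere(allowed)
    if n > 0 and len(coords) == 0:
        raise PlacementError(f"no admissible pixels to place {what}")
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(MAX_PLACEMENT_TRIES):
            r, c = coords[rng.integers(len(coords))]
            if all((r - p[0]) ** 2 + (c - p[1]) ** 2 >= min_separation**2 for p in placed):
                placed.append((float(r), float(c)))
                break
        else:
            raise PlacementError(
                f"could not place {n} {what} with separation {min_separation:g}px "
                f"after {MAX_PLACEMENT_TRIES} tries; image too small"
            )
    return placed


def generate_metaphase(spec: MetaphaseSpec) -> tuple[FishImage, GroundTruth]:
    """Render one three-channel metaphase frame and its truth table.

    Red (MYC) contains exactly ``n_ec_foci`` spots disjoint from the DAPI
    and chr8 masks plus ``n_intrachromosomal_foci`` spots inside the DAPI
    mask; green contains ``n_chr8`` centromere objects on the chromosome
    mass; blue contains the chromosome cluster. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    shape = (size, size)

    dapi_mask = _chromosome_mask(size, spec.chromosome_mask_style, rng)

    # chr8 centromeres sit on the chromosome mass, away from its rim
    interior = ndimage.distance_transform_edt(dapi_mask) >= spec.centromere_radius_px / 2
    chr8_centers = _sample_positions(
        spec.n_chr8, interior, 2 * spec.centromere_radius_px + 2, rng, "chr8 objects"
    )
    chr8_mask = np.zeros(shape, dtype=bool)
    for c in chr8_centers:
        rr, cc = draw_disk(c, spec.centromere_radius_px, shape=shape)
        chr8_mask[rr, cc] = True

    # EC foci live strictly off both masks: keep a clearance so blur cannot
    # bleed a detected focus onto the chromosome mass
    clearance = 2 * spec.focus_radius_px + 2 * spec.psf_sigma_px + 1
    off_mask = ndimage.distance_transform_edt(~(dapi_mask | chr8_mask)) >= clearance
    border = int(np.ceil(2 * spec.focus_radius_px))
    off_mask[:border, :] = off_mask[-border:, :] = False
    off_mask[:, :border] = off_mask[:, -border:] = False
    ec_centers = _sample_positions(
        spec.n_ec_foci, off_mask, spec.min_separation_px, rng, "EC foci"
    )

    # HSR-like signals clump on the chromosome mass; they only need the
    # 2x-radius separation floor since overlap removal merges them anyway
    in_mask = ndimage.distance_transform_edt(dapi_mask) >= spec.focus_radius_px / 2
    intra_centers = _sample_positions(
        spec.n_intrachromosomal_foci, in_mask, 2.0 * spec.focus_radius_px, rng,
        "intrachromosomal foci",
    )

    sigma_focus = spec.focus_radius_px / 2.0
    red = _render_spots(shape, ec_centers + intra_centers, sigma_focus)
    green = _render_spots(shape, chr8_centers, spec.centromere_radius_px / 2.0)
    blue = ndimage.gaussian_filter(dapi_mask.astype(float), 1.0)

    channels = []
    for plane in (red, green, blue):
        if spec.psf_sigma_px > 0:
            plane = ndimage.gaussian_filter(plane, spec.psf_sigma_px)
        if spec.background_noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.background_noise_sd, shape)
        channels.append(np.clip(plane, 0.0, 1.0))
    pixels = np.stack(channels, axis=2)

    rows = []
    for r, c in ec_centers:
        rows.append((0, EC_FOCUS, r, c, spec.focus_radius_px))
    for r, c in intra_centers:
        rows.append((0, INTRA_FOCUS, r, c, spec.focus_radius_px))
    for r, c in chr8_centers:
        rows.append((0, CHR8, r, c, spec.centromere_radius_px))
    table = pd.DataFrame(
        rows, columns=["cell_id", "object_class", "row_px", "col_px", "radius_px"]
    )
    mask_row = pd.DataFrame(
        [(0, CHROMOSOME_MASK, np.nan, np.nan, np.nan)], columns=table.columns
    )
    table = pd.concat([table, mask_row], ignore_index=True)
    table["area_px"] = np.where(
        table["object_class"] == CHROMOSOME_MASK,
        float(dapi_mask.sum()),
        np.pi * table["radius_px"] ** 2,
    )

    image = FishImage(
        pixels=pixels, pixel_size_um=1.0,
        channel_roles={"MYC": 0, "CHR8": 1, "DAPI": 2},
    )
    truth = GroundTruth(table=table, masks={"dapi": dapi_mask, "chr8": chr8_mask})
    return image, truth


# ---------------------------------------------------------------------------
# aggregate fields
# ---------------------------------------------------------------------------

@dataclass
class AggregateFieldSpec:
    """Lognormal disk field emulating a confocal aggregate projection.

    Diameters are lognormal with the given median (um) and log-sd; disks do
    not overlap under the default policy.
    """

    n_aggregates: int = 50
    median_diameter_um: float = 150.0
    sigma_log: float = 0.5
    field_size_um: float = 2000.0
    pixel_size_um: float = 2.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be >= 0")
        if self.median_diameter_um <= 0 or self.field_size_um <= 0:
            raise ValueError("sizes must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def generate_aggregate_field(
    spec: AggregateFieldSpec,
) -> tuple[RasterImage, GroundTruth]:
    """Plant non-overlapping binary disks; truth lists diameter and centroid."""
    rng = np.random.default_rng(spec.seed)
    size_px = int(round(spec.field_size_um / spec.pixel_size_um))
    img = np.zeros((size_px, size_px), dtype=np.uint8)

    diam_um = np.exp(
        rng.normal(np.log(spec.median_diameter_um), spec.sigma_log, spec.n_aggregates)
    )
    diam_um = np.sort(diam_um)[::-1]  # place large disks first

    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    rows = []
    for d_um in diam_um:
        r_px = (d_um / 2.0) / spec.pixel_size_um
        for _try in range(MAX_PLACEMENT_TRIES):
            cy = rng.uniform(r_px, size_px - r_px)
            cx = rng.uniform(r_px, size_px - r_px)
            ok = spec.allow_overlap or all(
                (cy - p[0]) ** 2 + (cx - p[1]) ** 2 >= (r_px + p[2] + 1) ** 2
                for p in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place a {d_um:.0f}um aggregate without overlap"
            )
        rr, cc = draw_disk((cy, cx), r_px, shape=img.shape)
        img[rr, cc] = 1
        placed.append((cy, cx, r_px))
        rows.append(
            (0, AGGREGATE, cy, cx, r_px, float(len(rr)), d_um,
             len(rr) * spec.pixel_size_um**2)
        )

    table = pd.DataFrame(
        rows,
        columns=["cell_id", "object_class", "row_px", "col_px", "radius_px",
                 "area_px", "diameter_um", "area_um2"],
    )
    image = RasterImage(pixels=img, pixel_size_um=spec.pixel_size_um)
    return image, GroundTruth(table=table)


# ---------------------------------------------------------------------------
# compressive stress-strain curves
# ---------------------------------------------------------------------------

@dataclass
class CurveSpec:
    """Compression curve with a compliant toe and a linear elastic region.

    The toe (strain < ``toe_strain``) ramps quadratically so the slope grows
    from 0 to the true modulus and joins the linear branch with continuous
    value and slope; past the toe the slope is exactly
    ``true_modulus_kpa``. Noise is additive iid Gaussian on stress.
    """

    true_modulus_kpa: float = 22.2
    toe_strain: float = 0.05
    max_strain: float = 0.3
    n_points: int = 500
    noise_sd_kpa: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.toe_strain < self.max_strain <= 1):
            raise ValueError("require 0 <= toe_strain < max_strain <= 1")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.true_modulus_kpa <= 0:
            raise ValueError("true modulus must be positive")
        if self.noise_sd_kpa < 0:
            raise ValueError("noise sd must be nonnegative")


def generate_stress_strain(spec: CurveSpec):
    """Return a :class:`~ecfoam.mechanics.StressStrainCurve` per the spec."""
    from .mechanics import StressStrainCurve

    rng = np.random.default_rng(spec.seed)
    strain = np.linspace(0.0, spec.max_strain, spec.n_points)
    E, t = spec.true_modulus_kpa, spec.toe_strain
    if t > 0:
        stress = np.where(
            strain < t,
            E * strain**2 / (2 * t),          # slope 0 -> E across the toe
            E * (strain - t) + E * t / 2.0,   # slope exactly E past the toe
        )
    else:
        stress = E * strain
    if spec.noise_sd_kpa > 0:
        stress = stress + rng.normal(0.0, spec.noise_sd_kpa, spec.n_points)
    return StressStrainCurve(strain=strain, stress_kpa=stress)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class CtSpec:
    """Design of a synthetic qPCR experiment.

    ``log2_fold_changes[gene][group]`` plants the true log2 fold-change of
    each gene in each non-reference group; the housekeeping gene carries no
    group effect. Each sample receives a common loading shift
    (``sample_shift_sd``, Ct units) that housekeeping normalization must
    cancel.
    """

    genes: Sequence[str] = ("MYC", "PVT1", "GAPDH")
    groups: Sequence[str] = ("bulk", "foam")
    reference_group: str = "bulk"
    baseline_ct: Mapping[str, float] = field(
        default_factory=lambda: {"MYC": 22.0, "PVT1": 25.0, "GAPDH": 18.0}
    )
    log2_fold_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    housekeeping: str = "GAPDH"
    noise_sd_ct: float = 0.2
    sample_shift_sd: float = 0.5
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.housekeeping not in self.genes:
            raise ValueError("housekeeping gene must be among genes")
        if self.reference_group not in self.groups:
            raise ValueError("reference_group must be among groups")
        for g in self.genes:
            if g not in self.baseline_ct:
                raise ValueError(f"baseline Ct missing for {g}")


def generate_ct_table(spec: CtSpec) -> pd.DataFrame:
    """Tidy Ct table (sample, group, gene, replicate, ct).

    Ct = baseline - planted log2FC + per-sample loading shift + noise; the
    housekeeping gene never carries a group effect.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.groups:
        for rep in range(1, spec.n_replicates + 1):
            sample = f"{group}_{rep}"
            shift = rng.normal(0.0, spec.sample_shift_sd) if spec.sample_shift_sd else 0.0
            for gene in spec.genes:
                lfc = 0.0
                if gene != spec.housekeeping:
                    lfc = float(spec.log2_fold_changes.get(gene, {}).get(group, 0.0))
                noise = rng.normal(0.0, spec.noise_sd_ct) if spec.noise_sd_ct else 0.0
                ct = spec.baseline_ct[gene] - lfc + shift + noise
                rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
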