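"""Synthetic IHC core rendering and DAB quantification.

Brightfield IHC color is modeled with the Beer–Lambert law: each pixel's
optical density ``OD = -log10(I / I0)`` is a non-negative mixture of a
hematoxylin vector (blue nuclear counterstain) and a DAB vector (brown
chromogen marking MMR protein expression).  ``separate_stains`` inverts
that mixture; ``render_core`` runs it forward over a synthetic 2 mm core
with elliptical nuclei and pixel-level ground truth, so quantification
can be validated by recovery.  ``measure_section`` turns an image into
the per-section measurement triple: the stained-pixel fraction

    W = (# stained pixels in the core section) / (# total pixels in the
        core section)

(with "total" read as tissue pixels, excluding glass), the mean
strong-positive intensity ``B`` on a 0–100 scale, and a conventional
histoscore ``100·(weak + 2·moderate + 3·strong)`` on 0–300.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .config import ConfigurationError

# Ruifrok & Johnston optical-density vectors for hematoxylin and DAB.
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])


class MeasurementError(ValueError):
    """Raised when an image cannot be quantified (e.g. empty tissue mask)."""


@dataclass
class StainModel:
    """Stain vectors and DAB positivity thresholds.

    ``positivity_thresholds`` are the weak/moderate and moderate/strong
    DAB-OD boundaries; ``detection_floor`` is the OD below which a pixel
    counts as unstained.  ``positivity_scale`` maps DAB OD onto the
    0–100 positivity axis used for ``B`` (OD >= scale saturates at 100).
    """

    hematoxylin_vector: np.ndarray = field(default_factory=lambda: _HEMATOXYLIN.copy())
    dab_vector: np.ndarray = field(default_factory=lambda: _DAB.copy())
    detection_floor: float = 0.15
    positivity_thresholds: tuple[float, float] = (0.40, 0.80)
    positivity_scale: float = 1.25
    background_intensity: float = 255.0

    def __post_init__(self):
        self.hematoxylin_vector = np.asarray(self.hematoxylin_vector, dtype=float)
        self.dab_vector = np.asarray(self.dab_vector, dtype=float)
        self.hematoxylin_vector /= np.linalg.norm(self.hematoxylin_vector)
        self.dab_vector /= np.linalg.norm(self.dab_vector)
        t1, t2 = self.positivity_thresholds
        if not (0 < self.detection_floor < t1 < t2):
            raise ConfigurationError(
                "need 0 < detection_floor < weak/moderate < moderate/strong"
            )
        if np.linalg.matrix_rank(self.stain_matrix()) < 3:
            raise ConfigurationError("stain vectors are linearly dependent")

    def stain_matrix(self) -> np.ndarray:
        """Rows: hematoxylin, DAB, and their (normalized) cross product."""
        residual = np.cross(self.hematoxylin_vector, self.dab_vector)
        norm = np.linalg.norm(residual)
        if norm < 1e-12:
            raise ConfigurationError("stain vectors are linearly dependent")
        return np.stack([self.hematoxylin_vector, self.dab_vector, residual / norm])


@dataclass
class CoreGeometry:
    """Raster geometry of a rendered core.

    Nuclei sit on a jittered square grid; spacing and radii are chosen so
    the nuclear union covers most of the tissue disk, as in a
    cell-dense tumor core, which lets the renderer hit stained-pixel
    fractions up to ~0.9.
    """

    image_size: int = 512
    core_radius_frac: float = 0.47
    nucleus_spacing: float = 7.0
    nucleus_radius_range: tuple[float, float] = (3.8, 5.0)
    position_jitter: float = 1.2
    hematoxylin_od: float = 0.55
    hematoxylin_od_sd: float = 0.06
    stroma_od: float = 0.08
    od_noise_sd: float = 0.015

    def validate(self) -> None:
        r = self.image_size * self.core_radius_frac
        if r < self.nucleus_radius_range[1] * 2:
            raise ConfigurationError("core too small to place any nucleus")
        if self.nucleus_spacing <= 0 or self.nucleus_radius_range[0] <= 0:
            raise ConfigurationError("nucleus geometry must be positive")


POSITIVITY_LEVELS = ("negative", "weak", "moderate", "strong")


@dataclass
class SyntheticCoreImage:
    """A rendered core with its pixel-level ground truth."""

    pixels: np.ndarray          # (H, W, 3) uint8
    tissue_mask: np.ndarray     # (H, W) bool
    nucleus_labels: np.ndarray  # (H, W) int, 0 = background
    truth_positivity: np.ndarray  # per-nucleus level index into POSITIVITY_LEVELS
    truth_dab_mask: np.ndarray  # (H, W) bool, pixels rendered DAB-positive

    def __post_init__(self):
        if not (
            self.pixels.shape[:2]
            == self.tissue_mask.shape
            == self.nucleus_labels.shape
            == self.truth_dab_mask.shape
        ):
            raise ConfigurationError("raster shapes disagree")

    @property
    def truth_stained_fraction(self) -> float:
        """Ground-truth W: DAB-positive pixels over tissue pixels."""
        return float(self.truth_dab_mask.sum() / self.tissue_mask.sum())


@dataclass
class SectionMeasurement:
    """Quantification of one core section (one core, one MMR protein)."""

    core_id: str
    protein: str
    B: float
    W: float
    stained_pixels: int
    total_pixels: int
    histoscore: float
    positivity_fractions: tuple[float, float, float, float]


def rgb_to_od(pixels: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image."""
    i = np.maximum(pixels.astype(float), 1.0)
    return -np.log10(i / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Invert :func:`rgb_to_od`, quantizing back to uint8."""
    i = background_intensity * np.power(10.0, -od)
    return np.clip(np.round(i), 0, 255).astype(np.uint8)


def separate_stains(pixels: np.ndarray, model: StainModel) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB image into hematoxylin and DAB OD rasters.

    Per-pixel OD is projected onto the stain basis by inverting the
    stain matrix; negative concentrations (noise) are clamped to zero.
    """
    od = rgb_to_od(pixels, model.background_intensity)
    try:
        inv = np.linalg.inv(model.stain_matrix())
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in model
        raise ConfigurationError("singular stain matrix") from exc
    conc = od @ inv
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1]


def combine_stains(
    hematoxylin_od: np.ndarray, dab_od: np.ndarray, model: StainModel
) -> np.ndarray:
    """Forward Beer–Lambert mixing of stain OD rasters into RGB."""
    conc = np.stack(
        [hematoxylin_od, dab_od, np.zeros_like(hematoxylin_od)], axis=-1
    )
    od = conc @ model.stain_matrix()
    return od_to_rgb(od, model.background_intensity)


def _place_nuclei(
    geometry: CoreGeometry, rng: np.random.Generator
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Jittered-grid elliptical nuclei clipped to the core disk.

    Returns per-nucleus pixel coordinate arrays and the disk mask.
    """
    size = geometry.image_size
    center = (size - 1) / 2.0
    radius = size * geometry.core_radius_frac
    yy, xx = np.mgrid[0:size, 0:size]
    tissue = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2

    nuclei = []
    step = geometry.nucleus_spacing
    rmin, rmax = geometry.nucleus_radius_range
    grid = np.arange(step / 2, size, step)
    for gy in grid:
        for gx in grid:
            cy = gy + rng.uniform(-geometry.position_jitter, geometry.position_jitter)
            cx = gx + rng.uniform(-geometry.position_jitter, geometry.position_jitter)
            if (cy - center) ** 2 + (cx - center) ** 2 > (radius - rmax) ** 2:
                continue
            a = rng.uniform(rmin, rmax)
            b = rng.uniform(rmin, rmax)
            phi = rng.uniform(0, np.pi)
            rr, cc = ellipse(cy, cx, a, b, shape=(size, size), rotation=phi)
            if rr.size:
                nuclei.append((rr, cc))
    if not nuclei:
        raise ConfigurationError("geometry too small to place any nucleus")
    return nuclei, tissue


def render_core(
    latent_W: float,
    latent_B: float,
    geometry: CoreGeometry | None = None,
    model: StainModel | None = None,
    seed: int = 0,
) -> SyntheticCoreImage:
    """Render a core section whose stained-pixel fraction matches
    ``latent_W`` and whose strong-positive intensity matches ``latent_B``.

    Nuclei are accumulated into the DAB-positive set, in random order,
    until the stained pixel count reaches ``latent_W`` times the tissue
    area (placement granularity: one nucleus, ~50 px out of ~200k).
    DAB-positive nuclei carry OD ``positivity_scale * latent_B / 100``,
    so measured ``B`` recovers ``latent_B``; all nuclei carry a
    hematoxylin counterstain.  Deterministic per seed.
    """
    geometry = geometry or CoreGeometry()
    geometry.validate()
    model = model or StainModel()
    if not 0.0 <= latent_W <= 1.0:
        raise ConfigurationError("latent_W must be in [0, 1]")
    if not 0.0 <= latent_B <= 100.0:
        raise ConfigurationError("latent_B must be in [0, 100]")
    rng = np.random.default_rng(seed)

    nuclei, tissue = _place_nuclei(geometry, rng)
    size = geometry.image_size
    labels = np.zeros((size, size), dtype=np.int32)
    for k, (rr, cc) in enumerate(nuclei, start=1):
        labels[rr, cc] = k
    labels[~tissue] = 0

    h_od = np.where(tissue, geometry.stroma_od, 0.0)
    for rr, cc in nuclei:
        h_od[rr, cc] = rng.normal(geometry.hematoxylin_od, geometry.hematoxylin_od_sd)

    dab_nucleus_od = model.positivity_scale * latent_B / 100.0
    target = int(round(latent_W * tissue.sum()))
    dab_mask = np.zeros((size, size), dtype=bool)
    order = rng.permutation(len(nuclei))
    positive = np.zeros(len(nuclei), dtype=bool)
    stained_px = 0
    for k in order:
        if stained_px >= target:
            break
        rr, cc = nuclei[k]
        newly = ~dab_mask[rr, cc]
        dab_mask[rr, cc] = True
        stained_px += int(newly.sum())
        positive[k] = True
    dab_od = np.where(dab_mask, dab_nucleus_od, 0.0)

    if geometry.od_noise_sd > 0:
        h_od = h_od + rng.normal(0, geometry.od_noise_sd, h_od.shape)
        dab_od = dab_od + rng.normal(0, geometry.od_noise_sd, dab_od.shape) * dab_mask
    h_od = np.clip(h_od, 0, None) * tissue
    dab_od = np.clip(dab_od, 0, None) * tissue
    dab_mask &= tissue

    pixels = combine_stains(h_od, dab_od, model)

    floor, (t1, t2) = model.detection_floor, model.positivity_thresholds
    if dab_nucleus_od < floor:
        level = 0
    elif dab_nucleus_od < t1:
        level = 1
    elif dab_nucleus_od < t2:
        level = 2
    else:
        level = 3
    truth_positivity = np.where(positive, level, 0).astype(np.int8)
    if level == 0:
        dab_mask = np.zeros_like(dab_mask)

    return SyntheticCoreImage(
        pixels=pixels,
        tissue_mask=tissue,
        nucleus_labels=labels,
        truth_positivity=truth_positivity,
        truth_dab_mask=dab_mask,
    )


def segment_nuclei(
    hematoxylin_od: np.ndarray,
    min_size: int = 12,
    threshold: float | None = None,
    separate_touching: bool = False,
) -> np.ndarray:
    """Label nuclei in a hematoxylin-OD raster.

    Thresholds (Otsu by default), fills holes, removes specks smaller
    than ``min_size`` pixels, and labels connected components.  With
    ``separate_touching``, a distance-transform watershed splits merged
    nuclei.  An empty labeling is a valid result.
    """
    od = np.asarray(hematoxylin_od, dtype=float)
    if not np.all(np.isfinite(od)):
        raise MeasurementError("hematoxylin OD raster contains non-finite values")
    if threshold is None:
        if np.ptp(od) < 1e-9:
            return np.zeros(od.shape, dtype=np.int32)
        threshold = threshold_otsu(od)
    mask = od > threshold
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        return np.zeros(od.shape, dtype=np.int32)
    if not separate_touching:
        return cc_label(mask).astype(np.int32)
    distance = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(distance, sigma=1.0)
    peaks = (smooth == ndi.maximum_filter(smooth, size=5)) & (distance > 1.0)
    markers = cc_label(peaks)
    if markers.max() == 0:
        return cc_label(mask).astype(np.int32)
    return watershed(-smooth, markers, mask=mask).astype(np.int32)


def measure_section(
    pixels: np.ndarray,
    tissue_mask: np.ndarray,
    model: StainModel | None = None,
    core_id: str = "",
    protein: str = "",
    restrict_to_nuclei: bool = True,
    nucleus_labels: np.ndarray | None = None,
) -> SectionMeasurement:
    """Quantify one core section into (B, W, histoscore).

    ``W`` is the stained-pixel count over the tissue-pixel count.  ``B``
    is the mean DAB positivity (OD rescaled to 0–100 by the model's
    ``positivity_scale``) over strong-bin pixels, 0 when that bin is
    empty.  Positivity fractions (negative/weak/moderate/strong, summing
    to 1) are taken over the analysis region — nucleus pixels when
    ``restrict_to_nuclei`` (MMR staining is nuclear), tissue pixels
    otherwise — and yield the 0–300 histoscore.  When restriction is on
    and no label raster is given, nuclei are segmented from the
    hematoxylin channel.
    """
    model = model or StainModel()
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise MeasurementError("empty tissue mask")
    h_od, dab_od = separate_stains(pixels, model)

    if restrict_to_nuclei:
        if nucleus_labels is None:
            nucleus_labels = segment_nuclei(h_od * tissue_mask)
        region = (nucleus_labels > 0) & tissue_mask
        if not region.any():  # no nuclei found: fall back to whole tissue
            region = tissue_mask
    else:
        region = tissue_mask

    dab = dab_od[region]
    floor, (t1, t2) = model.detection_floor, model.positivity_thresholds
    stained = dab >= floor
    stained_pixels = int(stained.sum())
    total_pixels = int(tissue_mask.sum())
    W = stained_pixels / total_pixels

    n_region = dab.size
    weak = float(((dab >= floor) & (dab < t1)).sum() / n_region)
    moderate = float(((dab >= t1) & (dab < t2)).sum() / n_region)
    strong = float((dab >= t2).sum() / n_region)
    negative = 1.0 - weak - moderate - strong
    histoscore = 100.0 * (weak + 2.0 * moderate + 3.0 * strong)

    strong_px = dab[dab >= t2]
    B = (
        float(np.mean(np.clip(strong_px / model.positivity_scale, 0, 1)) * 100.0)
        if strong_px.size
        else 0.0
    )
    return SectionMeasurement(
        core_id=core_id,
        protein=protein,
        B=B,
        W=W,
        stained_pixels=stained_pixels,
        total_pixels=total_pixels,
        histoscore=histoscore,
        positivity_fractions=(negative, weak, moderate, strong),
    )


def measure_core_image(
    image: SyntheticCoreImage,
    model: StainModel | None = None,
    core_id: str = "",
    protein: str = "",
    restrict_to_nuclei: bool = True,
    use_truth_labels: bool = False,
) -> SectionMeasurement:
    """Convenience wrapper: quantify a rendered synthetic core."""
    return measure_section(
        image.pixels,
        image.tissue_mask,
        model=model,
        core_id=core_id,
        protein=protein,
        restrict_to_nuclei=restrict_to_nuclei,
        nucleus_labels=image.nucleus_labels if use_truth_labels else None,
    )
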