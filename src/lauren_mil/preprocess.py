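"""Whole-slide tessellation, tile quality control and Macenko stain normalization.

A slide is cut into a non-overlapping grid of tiles of fixed *physical* edge
length (default 256 µm) which are resampled to a fixed pixel size (default
224 px, i.e. an effective resolution of 256/224 ≈ 1.14 µm/px).  Tiles without
tissue or out of focus are rejected by their *edge quantity* — the fraction of
pixels marked by a Canny edge detector on the grayscale tile — and the
remaining tiles are color-standardized with the Macenko method: stain vectors
are estimated from the extreme angular percentiles of the optical-density
point cloud and per-pixel stain concentrations are remapped to a reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize, rotate

# ---------------------------------------------------------------------------
# Constants (canonical Macenko defaults; ImageNet channel statistics)
# ---------------------------------------------------------------------------

#: Transmitted intensity of a blank (stain-free) pixel on an 8-bit scanner.
I0 = 255.0
#: Numerical guard added to intensities before the log transform.
OD_EPS = 1e-6
#: Optical-density transparency threshold: pixels with any channel below this
#: are treated as background when estimating stain vectors.
OD_BETA = 0.15
#: Robust angular percentile for the extreme stain directions (1st/99th).
ANGLE_ALPHA = 1.0
#: Percentile used for the per-stain maximum concentration.
CONC_PERCENTILE = 99.0
#: Minimum number of foreground OD pixels required to fit stain vectors.
MIN_FG_PIXELS = 100

#: Widely used reference H&E stain vectors (columns: hematoxylin, eosin) in
#: RGB optical-density space.
DEFAULT_HE_OD = np.array(
    [[0.650, 0.072],
     [0.704, 0.990],
     [0.286, 0.105]]
)
DEFAULT_HE_OD /= np.linalg.norm(DEFAULT_HE_OD, axis=0, keepdims=True)
#: Plausible maximum concentrations to pair with the default vectors.
DEFAULT_MAX_CONC = np.array([1.5, 1.0])

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

DEFAULT_TILE_UM = 256.0
DEFAULT_TILE_PX = 224
DEFAULT_EDGE_THRESHOLD = 0.02


class InsufficientTissueError(ValueError):
    """Raised when a tile has too few foreground pixels to fit stain vectors."""


class EmptySlideError(ValueError):
    """Raised when quality control rejects every tile of a slide."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class SlideImage:
    """An RGB pixel grid with physical scale — the unit of classification.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    mpp : microns per pixel (isotropic)
    slide_id : identifier used in logs and caches
    """

    pixels: np.ndarray
    mpp: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.mpp

    @property
    def height_um(self) -> float:
        return self.pixels.shape[0] * self.mpp


@dataclass
class TileRecord:
    """One tessellated tile with its grid position and QC state."""

    pixels: np.ndarray          # (tile_px, tile_px, 3) uint8
    grid_col: int
    grid_row: int
    origin_um: tuple[float, float]  # physical (x, y) of the top-left corner
    edge_quantity: float | None = None
    qc_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.grid_col < 0 or self.grid_row < 0:
            raise ValueError("grid indices must be non-negative")


@dataclass
class TileSet:
    """Ordered tiles from one slide plus the tessellation geometry."""

    slide_id: str
    tiles: list[TileRecord]
    tile_um: float = DEFAULT_TILE_UM
    tile_px: int = DEFAULT_TILE_PX
    grid_shape: tuple[int, int] = (0, 0)  # (n_rows, n_cols)

    @property
    def effective_mpp(self) -> float:
        """Physical resolution of a resampled tile: tile_um / tile_px."""
        return self.tile_um / self.tile_px

    def __len__(self) -> int:
        return len(self.tiles)


@dataclass
class StainReference:
    """A fitted Macenko reference: stain matrix plus maximum concentrations.

    ``stain_matrix`` holds two unit-norm RGB optical-density vectors as
    columns, hematoxylin first (by convention the vector with the larger
    blue-channel OD).  ``max_concentrations`` are the per-stain 99th-percentile
    concentrations of the tissue the reference was fitted on.
    """

    stain_matrix: np.ndarray        # (3, 2)
    max_concentrations: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit-norm")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max concentrations must be positive")


def default_reference() -> StainReference:
    """The package-wide target reference used when none is fitted."""
    return StainReference(DEFAULT_HE_OD.copy(), DEFAULT_MAX_CONC.copy())


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

def tessellate(
    slide: SlideImage,
    tile_um: float = DEFAULT_TILE_UM,
    tile_px: int = DEFAULT_TILE_PX,
) -> TileSet:
    """Cut a slide into a non-overlapping grid of fixed-physical-size tiles.

    Each tile covers ``tile_um`` µm of tissue and is resampled to
    ``tile_px`` × ``tile_px`` pixels.  Partial tiles at the right/bottom edges
    are dropped.  A slide smaller than one tile yields an empty TileSet with a
    warning.
    """
    if tile_um / slide.mpp < 1:
        raise ValueError("tile_um must cover at least one source pixel")
    src_px = tile_um / slide.mpp  # source pixels per tile edge (float)
    h, w = slide.pixels.shape[:2]
    n_cols = int(np.floor(w / src_px + 1e-9))
    n_rows = int(np.floor(h / src_px + 1e-9))
    tiles: list[TileRecord] = []
    for r in range(n_rows):
        y0, y1 = round(r * src_px), round((r + 1) * src_px)
        for c in range(n_cols):
            x0, x1 = round(c * src_px), round((c + 1) * src_px)
            crop = slide.pixels[y0:y1, x0:x1]
            if crop.shape[:2] != (tile_px, tile_px):
                crop = resize(
                    crop.astype(float) / 255.0,
                    (tile_px, tile_px),
                    anti_aliasing=crop.shape[0] > tile_px,
                    preserve_range=False,
                )
                crop = np.clip(np.round(crop * 255.0), 0, 255).astype(np.uint8)
            tiles.append(
                TileRecord(
                    pixels=crop,
                    grid_col=c,
                    grid_row=r,
                    origin_um=(c * tile_um, r * tile_um),
                )
            )
    if not tiles:
        warnings.warn(
            f"slide {slide.slide_id!r} is smaller than one {tile_um} µm tile",
            stacklevel=2,
        )
    return TileSet(
        slide_id=slide.slide_id,
        tiles=tiles,
        tile_um=tile_um,
        tile_px=tile_px,
        grid_shape=(n_rows, n_cols),
    )


# ---------------------------------------------------------------------------
# Quality control by edge quantity
# ---------------------------------------------------------------------------

def edge_quantity(tile: TileRecord | np.ndarray, sigma: float = 1.0) -> float:
    """Fraction of pixels marked by a Canny edge detector on the gray tile.

    Blank tiles score 0; sharp tissue scores high; blurring a textured tile
    strictly lowers its score.  Deterministic in the pixel values.
    """
    pixels = tile.pixels if isinstance(tile, TileRecord) else tile
    gray = rgb2gray(pixels)
    edges = canny(gray, sigma=sigma)
    return float(edges.mean())


def qc_filter(
    tiles: TileSet,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> TileSet:
    """Keep tiles whose edge quantity is at least ``threshold``.

    Order is preserved and edge quantities are computed on demand.  Raises
    :class:`EmptySlideError` if nothing survives.
    """
    kept: list[TileRecord] = []
    for t in tiles.tiles:
        if t.edge_quantity is None:
            t.edge_quantity = edge_quantity(t)
        t.qc_pass = t.edge_quantity >= threshold
        if t.qc_pass:
            kept.append(t)
    if tiles.tiles and not kept:
        raise EmptySlideError(
            f"QC removed every tile of slide {tiles.slide_id!r} "
            f"(threshold={threshold})"
        )
    return TileSet(
        slide_id=tiles.slide_id,
        tiles=kept,
        tile_um=tiles.tile_um,
        tile_px=tiles.tile_px,
        grid_shape=tiles.grid_shape,
    )


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Beer–Lambert transform: OD = −log10((I + ε) / I0), flattened to n×3."""
    arr = pixels.reshape(-1, 3).astype(float)
    return -np.log10((arr + OD_EPS) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse Beer–Lambert transform back to clipped uint8 RGB."""
    rgb = I0 * np.power(10.0, -od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _nnls_two_stain(stain_matrix: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Non-negative least squares for a two-column stain matrix, vectorized.

    Solves min ||M c − od|| s.t. c ≥ 0 per pixel.  With two stains the KKT
    cases are explicit: the unconstrained solution if it is feasible,
    otherwise the better of the two single-stain projections.
    """
    m1, m2 = stain_matrix[:, 0], stain_matrix[:, 1]
    conc = od @ np.linalg.pinv(stain_matrix).T  # (n, 2) unconstrained
    c1_only = np.maximum(od @ m1, 0.0)  # unit-norm columns: m·m = 1
    c2_only = np.maximum(od @ m2, 0.0)
    neg1, neg2 = conc[:, 0] < 0, conc[:, 1] < 0
    # exactly one component negative -> clamp it, project on the other stain
    only1 = neg1 & ~neg2
    only2 = neg2 & ~neg1
    conc[only1, 0] = 0.0
    conc[only1, 1] = c2_only[only1]
    conc[only2, 1] = 0.0
    conc[only2, 0] = c1_only[only2]
    # both negative -> take the better single-stain fit (or zero)
    both = neg1 & neg2
    if np.any(both):
        r1 = np.sum((od[both] - c1_only[both, None] * m1) ** 2, axis=1)
        r2 = np.sum((od[both] - c2_only[both, None] * m2) ** 2, axis=1)
        use1 = r1 <= r2
        cb = np.zeros((both.sum(), 2))
        cb[use1, 0] = c1_only[both][use1]
        cb[~use1, 1] = c2_only[both][~use1]
        conc[both] = cb
    return conc


def macenko_fit(
    pixels: np.ndarray,
    beta: float = OD_BETA,
    alpha: float = ANGLE_ALPHA,
    min_pixels: int = MIN_FG_PIXELS,
) -> StainReference:
    """Estimate H&E stain vectors and maximum concentrations from a tile.

    Transparent pixels (OD magnitude below ``beta``) are discarded; the
    remaining OD cloud is projected onto its top-2 principal plane and the
    ``alpha`` / ``100−alpha`` percentiles of the in-plane angle give the two
    extreme stain directions.  The transparency cut uses the OD norm rather
    than a per-channel floor: eosin absorbs almost no red light, so any
    per-channel floor would discard exactly the eosin-dominated pixels whose
    angle the method needs.  Hematoxylin is the vector with the larger
    blue-channel OD.
    """
    od = rgb_to_od(pixels)
    fg = od[np.linalg.norm(od, axis=1) >= beta]
    if fg.shape[0] < min_pixels:
        raise InsufficientTissueError(
            f"insufficient tissue: {fg.shape[0]} foreground OD pixels "
            f"(need {min_pixels})"
        )
    cov = np.cov(fg, rowvar=False)
    _, evecs = np.linalg.eigh(cov)
    plane = evecs[:, -2:]  # columns span the top-2 principal plane
    # deterministic orientation of the basis
    for j in range(2):
        if plane[np.argmax(np.abs(plane[:, j])), j] < 0:
            plane[:, j] *= -1
    proj = fg @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    vecs = []
    for ang in (lo, hi):
        v = plane @ np.array([np.cos(ang), np.sin(ang)])
        if v.sum() < 0:  # stain vectors live in the positive OD orthant
            v = -v
        vecs.append(v / np.linalg.norm(v))
    # hematoxylin first: larger blue-channel OD
    vecs.sort(key=lambda v: -v[2])
    stain_matrix = np.column_stack(vecs)
    conc = _nnls_two_stain(stain_matrix, fg)
    max_conc = np.percentile(conc, CONC_PERCENTILE, axis=0)
    max_conc = np.maximum(max_conc, 1e-6)
    return StainReference(stain_matrix, max_conc)


def macenko_normalize(
    pixels: np.ndarray,
    source: StainReference,
    target: StainReference | None = None,
) -> np.ndarray:
    """Remap a tile from its source stain appearance to the target reference.

    Per-pixel concentrations are recovered under the source matrix by
    non-negative least squares, each stain's maximum concentration is rescaled
    to the target's, and the tile is re-rendered under the target matrix.
    """
    if target is None:
        target = default_reference()
    cross = np.cross(source.stain_matrix[:, 0], source.stain_matrix[:, 1])
    if np.linalg.norm(cross) < 1e-6:
        raise ValueError("singular source stain matrix")
    shape = pixels.shape
    od = rgb_to_od(pixels)
    conc = _nnls_two_stain(source.stain_matrix, od)
    conc *= (target.max_concentrations / source.max_concentrations)[None, :]
    od_new = conc @ target.stain_matrix.T
    return od_to_rgb(od_new).reshape(shape)


def normalize_tileset(
    tiles: TileSet,
    target: StainReference | None = None,
    fit_on: str = "slide",
) -> TileSet:
    """Macenko-normalize every tile of a slide against one target reference.

    With ``fit_on='slide'`` a single source reference is fitted on a pooled
    pixel sample from all tiles (robust for tiles individually short on
    tissue); ``fit_on='tile'`` fits per tile.
    """
    if target is None:
        target = default_reference()
    if not tiles.tiles:
        return tiles
    out: list[TileRecord] = []
    source = None
    if fit_on == "slide":
        sample = np.concatenate(
            [t.pixels[::4, ::4].reshape(-1, 3) for t in tiles.tiles]
        )
        source = macenko_fit(sample)
    for t in tiles.tiles:
        src = source if source is not None else macenko_fit(t.pixels)
        out.append(
            TileRecord(
                pixels=macenko_normalize(t.pixels, src, target),
                grid_col=t.grid_col,
                grid_row=t.grid_row,
                origin_um=t.origin_um,
                edge_quantity=t.edge_quantity,
                qc_pass=t.qc_pass,
            )
        )
    return TileSet(
        slide_id=tiles.slide_id,
        tiles=out,
        tile_um=tiles.tile_um,
        tile_px=tiles.tile_px,
        grid_shape=tiles.grid_shape,
    )


# ---------------------------------------------------------------------------
# Training-time augmentation and channel standardization
# ---------------------------------------------------------------------------

def augment(
    pixels: np.ndarray,
    seed: int | None = None,
    angle: float | None = None,
    flip: bool | None = None,
) -> np.ndarray:
    """Seeded random rotation in [0°, 360°) and vertical flip with prob 0.5.

    Explicit ``angle``/``flip`` override the draw.  Rotations by multiples of
    90° are exact (no interpolation), so four 90° turns are the identity.
    """
    if angle is None or flip is None:
        rng = np.random.default_rng(seed)
        if angle is None:
            angle = float(rng.uniform(0.0, 360.0))
        if flip is None:
            flip = bool(rng.random() < 0.5)
    out = pixels
    if angle % 90 == 0:
        out = np.rot90(out, k=int(angle // 90) % 4, axes=(0, 1))
    elif angle % 360 != 0:
        rot = rotate(
            out.astype(float) / 255.0, angle, mode="reflect", preserve_range=False
        )
        out = np.clip(np.round(rot * 255.0), 0, 255).astype(np.uint8)
    if flip:
        out = out[::-1, :, :]
    return np.ascontiguousarray(out)


def standardize_imagenet(pixels: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] and z-score each channel with the ImageNet statistics."""
    return (pixels.astype(float) / 255.0 - IMAGENET_MEAN) / IMAGENET_STD
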