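"""Per-tile feature extraction behind a frozen-extractor contract.

Downstream code depends only on the contract: a QC-passed, stain-normalized
tile set maps to an (n_tiles × d) matrix of finite features, deterministic
for a fixed extractor and seed.  The default extractor is a desk-scale
stand-in for a large frozen histology network: handcrafted first- and
second-order texture statistics (channel moments, gray/edge histograms,
gray-level co-occurrence properties) pushed through a fixed-seed Gaussian
random projection up to the working dimension (2048 by default, matching the
bag layout of large pretrained extractors).  Any callable mapping an
(n, 224, 224, 3) uint8 stack to (n, d) can be slotted in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray, rgb2hed
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import sobel_h, sobel_v
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .preprocess import TileSet, standardize_imagenet

DEFAULT_FEATURE_DIM = 2048
_GLCM_LEVELS = 32
_GLCM_DISTANCES = (1, 3)
_GLCM_ANGLES = (0.0, np.pi / 2)
_GLCM_PROPS = ("contrast", "homogeneity", "energy", "correlation")


@dataclass
class FeatureBag:
    """The feature matrix of one slide plus tile bookkeeping.

    Rows align with ``grid_coords`` (grid_row, grid_col) of the retained
    tiles; the bag is the unit the MIL classifier consumes.
    """

    slide_id: str
    features: np.ndarray           # (n_tiles, d) float32
    grid_coords: np.ndarray        # (n_tiles, 2) int
    extractor_name: str = "texture-stats"
    seed: int = 0
    grid_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.grid_coords.shape[0]:
            raise ValueError("feature rows and tile coordinates disagree")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("bag contains non-finite features")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def _nuclear_morphometry(pixels: np.ndarray) -> np.ndarray:
    """Shape statistics of the hematoxylin-positive objects in a tile.

    Color deconvolution isolates the hematoxylin channel; its bright blobs
    are the stained structures.  Gland cross-sections are large annuli with
    lumina (holes), discohesive nuclei are many small solid dots, so object
    count, size, hole fraction, Euler number and eccentricity carry the
    morphology that plain intensity statistics miss.
    """
    hema = rgb2hed(pixels)[:, :, 0]
    thr = hema.mean() + hema.std()
    mask = hema > thr
    frac = mask.mean()
    if not mask.any():
        return np.zeros(8)
    filled = binary_fill_holes(mask)
    hole_frac = float(filled.mean() - frac)
    lab, n_obj = cc_label(mask, return_num=True)
    euler = float(
        np.sign(e := sum(r.euler_number for r in regionprops(lab)))
        * np.log1p(abs(e))
    )
    areas = np.bincount(lab.ravel())[1:]
    ecc = np.mean([r.eccentricity for r in regionprops(lab)
                   if r.area >= 5] or [0.0])
    return np.array(
        [
            frac,
            hole_frac,
            np.log1p(n_obj),
            euler,
            np.log1p(np.median(areas)),
            np.log1p(areas.max()),
            ecc,
            np.log1p(areas.mean()),
        ]
    )


def tile_statistics(pixels: np.ndarray) -> np.ndarray:
    """Handcrafted texture and morphometry descriptor of one tile (66 values).

    Channel moments on ImageNet-standardized channels; 16-bin gray histogram;
    gradient-magnitude and gradient-orientation histograms; GLCM contrast /
    homogeneity / energy / correlation at distances 1 and 3 px along two
    axes; log gradient energy; hematoxylin-blob morphometry (count, size,
    holes, Euler number, eccentricity).  Purely per-tile — no state across
    tiles.
    """
    std = standardize_imagenet(pixels)
    moments = []
    for ch in range(3):
        v = std[:, :, ch].ravel()
        moments += [v.mean(), v.std(), float(sps.skew(v))]
    gray = rgb2gray(pixels)
    ghist, _ = np.histogram(gray, bins=16, range=(0.0, 1.0), density=True)
    gx, gy = sobel_v(gray), sobel_h(gray)
    mag = np.hypot(gx, gy)
    mhist, _ = np.histogram(mag, bins=8, range=(0.0, 1.0), density=True)
    ori = np.arctan2(gy, gx)
    ohist, _ = np.histogram(ori, bins=8, range=(-np.pi, np.pi), weights=mag)
    ohist = ohist / (mag.sum() + 1e-9)
    q = np.clip((gray * _GLCM_LEVELS).astype(np.uint8), 0, _GLCM_LEVELS - 1)
    glcm = graycomatrix(q, distances=_GLCM_DISTANCES, angles=_GLCM_ANGLES,
                        levels=_GLCM_LEVELS, symmetric=True, normed=True)
    props = [graycoprops(glcm, p).ravel() for p in _GLCM_PROPS]
    grad_energy = np.log1p((mag ** 2).mean())
    morph = _nuclear_morphometry(pixels)
    feats = np.concatenate(
        [moments, ghist, mhist, ohist, np.concatenate(props), [grad_energy],
         morph]
    )
    return np.nan_to_num(feats, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class TextureStatExtractor:
    """Fixed-seed random projection of handcrafted texture statistics.

    The raw statistics live on very different scales (histogram densities vs
    log blob areas), so before projection each one is normalized by a robust
    scaler (median/IQR) calibrated once on the first batch of tiles the
    extractor sees and frozen thereafter — the analogue of the frozen
    normalization statistics a pretrained network ships with.  Calibration is
    permutation-invariant in the tiles; after it, identical tiles always map
    to identical rows.  The projection matrix is drawn once from ``seed``.
    """

    dim: int = DEFAULT_FEATURE_DIM
    seed: int = 0
    name: str = "texture-stats"
    _projection: np.ndarray | None = field(default=None, repr=False)
    _center: np.ndarray | None = field(default=None, repr=False)
    _scale: np.ndarray | None = field(default=None, repr=False)

    def _ensure_projection(self, n_stats: int) -> np.ndarray:
        if self._projection is None or self._projection.shape[0] != n_stats:
            rng = np.random.default_rng(self.seed)
            self._projection = rng.normal(
                0.0, 1.0 / np.sqrt(n_stats), size=(n_stats, self.dim)
            ).astype(np.float32)
        return self._projection

    def calibrate(self, stats: np.ndarray) -> None:
        """Freeze the robust per-statistic scaler on a reference sample."""
        self._center = np.median(stats, axis=0)
        q75, q25 = np.percentile(stats, [75, 25], axis=0)
        self._scale = np.maximum(q75 - q25, 1e-3)

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        stats = np.stack([tile_statistics(t) for t in tiles]).astype(np.float32)
        if self._center is None:
            self.calibrate(stats)
        stats = (stats - self._center) / self._scale
        # bound the dynamic range so no single extreme tile dominates a bag
        np.clip(stats, -4.0, 4.0, out=stats)
        proj = self._ensure_projection(stats.shape[1])
        return (stats @ proj).astype(np.float32)


def extract_features(
    tiles: TileSet,
    extractor=None,
    seed: int = 0,
    dim: int = DEFAULT_FEATURE_DIM,
) -> FeatureBag:
    """Map a QC-passed tile set to its feature bag.

    ``extractor`` is any callable from an (n, H, W, 3) uint8 stack to an
    (n, d) float matrix; by default a :class:`TextureStatExtractor` with the
    given seed and dimension.  Raises on an empty tile set.
    """
    if len(tiles) == 0:
        raise ValueError(f"slide {tiles.slide_id!r} has no tiles to featurize")
    if extractor is None:
        extractor = TextureStatExtractor(dim=dim, seed=seed)
    stack = np.stack([t.pixels for t in tiles.tiles])
    feats = np.asarray(extractor(stack), dtype=np.float32)
    coords = np.array([(t.grid_row, t.grid_col) for t in tiles.tiles])
    return FeatureBag(
        slide_id=tiles.slide_id,
        features=feats,
        grid_coords=coords,
        extractor_name=getattr(extractor, "name", type(extractor).__name__),
        seed=seed,
        grid_shape=tiles.grid_shape,
    )
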