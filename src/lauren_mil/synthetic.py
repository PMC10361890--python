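"""Synthetic whole-slide images and clinical cohorts with planted structure.

The generator stands in for scanned H&E resection slides and their case
tables.  It is deliberately not photorealistic: its job is to reproduce the
*statistical* structure the downstream analysis assumes, with a known ground
truth at every level —

* slides carry spatially contiguous regions of two distinguishable tissue
  textures ("intestinal-like" gland rings vs "diffuse-like" scattered nuclei)
  plus background, out-of-focus and mucin-pool artifacts, with a per-pixel
  truth mask;
* pixels are rendered through a Beer–Lambert stain model (per-pixel
  hematoxylin/eosin concentrations, per-slide stain intensity variation), so
  stain normalization operates on the same physics it assumes;
* each case has a latent Laurén subtype, a noisy pathologist label emulating
  interobserver discordance, an optional noisy "model" label, exponential
  survival with a class-dependent hazard ratio, and independent censoring.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .preprocess import DEFAULT_HE_OD, I0, SlideImage

INTESTINAL = "intestinal"
DIFFUSE = "diffuse"
MIXED = "mixed"

# per-pixel truth-mask codes
NEUTRAL, SIGNAL, BACKGROUND, BLUR, MUCIN = 0, 1, 2, 3, 4
MASK_NAMES = {NEUTRAL: "neutral", SIGNAL: "signal", BACKGROUND: "background",
              BLUR: "blur", MUCIN: "mucin"}

#: Edge length of one texture region block, matching the tessellation tile.
REGION_BLOCK_UM = 256.0


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSlideConfig:
    """Physical geometry and composition of one synthetic slide.

    ``signal_fraction`` is the fraction of *tissue* area carrying the class
    texture; the rest of the tissue is neutral stroma.  Background, blur and
    mucin fractions refer to the whole slide area and must sum to ≤ 1.
    ``stain_scale`` multiplies the hematoxylin/eosin concentration fields,
    emulating batch-to-batch staining intensity differences.
    """

    width_um: float = 1536.0
    height_um: float = 1536.0
    mpp: float = REGION_BLOCK_UM / 224.0   # ≈1.14 µm/px: tiles need no resampling
    signal_class: str = INTESTINAL
    signal_fraction: float = 0.3
    background_fraction: float = 0.2
    blur_fraction: float = 0.05
    mucin_fraction: float = 0.05
    stain_scale: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        for name in ("signal_fraction", "background_fraction",
                     "blur_fraction", "mucin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_fraction + self.blur_fraction + self.mucin_fraction > 1:
            raise ValueError("background + blur + mucin fractions exceed 1")
        if self.signal_class not in (INTESTINAL, DIFFUSE):
            raise ValueError(f"unknown signal_class {self.signal_class!r}")


@dataclass
class SyntheticSlide:
    """A rendered slide plus its per-pixel ground-truth class map."""

    image: np.ndarray            # (H, W, 3) uint8
    tile_truth_mask: np.ndarray  # (H, W) uint8, MASK codes
    mpp: float
    config: SyntheticSlideConfig
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.tile_truth_mask.shape:
            raise ValueError("image and truth mask shapes differ")

    def to_slide_image(self) -> SlideImage:
        return SlideImage(self.image, self.mpp, self.slide_id)


@dataclass
class CohortConfig:
    """Population-level parameters of a synthetic gastric-cancer cohort.

    Survival is exponential with hazard ``baseline_hazard ×
    hazard_ratio^(1 if diffuse else 0)`` (months⁻¹), with independent
    exponential censoring calibrated so a baseline-hazard subject is censored
    with probability ``censoring_rate``.  The pathologist label flips from
    the latent subtype with probability ``label_noise``; the simulated model
    label flips independently with probability ``model_label_noise``.
    """

    n_patients: int = 200
    p_diffuse: float = 0.3
    label_noise: float = 0.15
    model_label_noise: float = 0.3
    hazard_ratio: float = 1.46
    baseline_hazard: float = 0.015     # events per month for intestinal type
    censoring_rate: float = 0.3
    cancer_death_fraction: float = 0.8  # of OS events counted in CSS
    stain_variation: float = 0.15       # half-width of per-slide stain scaling
    two_observers: bool = False         # independent original/revised labels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        for name in ("p_diffuse", "label_noise", "model_label_noise",
                     "censoring_rate", "cancer_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class CaseRecord:
    """One patient: labels at every provenance level, survival, covariates."""

    case_id: str
    latent_class: str
    pathologist_label: str
    model_label: str | None = None
    label_original: str | None = None
    label_revised: str | None = None
    survival: dict[str, tuple[float, bool]] = field(default_factory=dict)
    covariates: dict[str, float | str] = field(default_factory=dict)
    slide_config: SyntheticSlideConfig | None = None
    slide_path: str | None = None

    def make_slide(self) -> SyntheticSlide:
        """Materialize this case's slide on demand (slides are not cached)."""
        if self.slide_config is None:
            raise ValueError(f"case {self.case_id} has no slide config")
        return generate_slide(self.slide_config, slide_id=self.case_id)


# ---------------------------------------------------------------------------
# Texture primitives (concentration-space painters)
# ---------------------------------------------------------------------------

def _disk_patch(shape: tuple[int, int], cy: float, cx: float, r: float) -> tuple:
    """Index arrays of the disk (cy, cx, r) clipped to ``shape``."""
    y0, y1 = max(0, int(cy - r) - 1), min(shape[0], int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(shape[1], int(cx + r) + 2)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    ys, xs = np.nonzero(inside)
    return ys + y0, xs + x0


def _neutral_stroma(shape, rng) -> tuple[np.ndarray, np.ndarray]:
    """Pink stroma: eosin-dominated with smooth and granular variation."""
    smooth = gaussian_filter(rng.normal(0, 1, shape), 6)
    speckle = rng.normal(0, 1, shape)
    c_e = 0.40 + 0.10 * smooth + 0.12 * speckle
    c_h = 0.10 + 0.03 * gaussian_filter(rng.normal(0, 1, shape), 3)
    # sparse stromal nuclei
    for _ in range(rng.integers(15, 30)):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ys, xs = _disk_patch(shape, cy, cx, rng.uniform(1.2, 2.2))
        c_h[ys, xs] += 0.55
    return np.clip(c_h, 0, None), np.clip(c_e, 0, None)


def _paint_glands(c_h, c_e, rng) -> None:
    """Intestinal-like texture: ring-shaped glands with clear lumina."""
    shape = c_h.shape
    n = rng.integers(9, 14)
    for _ in range(n):
        r_out = rng.uniform(10, 17)
        r_in = r_out - rng.uniform(3.0, 4.5)
        cy = rng.uniform(r_out, shape[0] - r_out)
        cx = rng.uniform(r_out, shape[1] - r_out)
        ys, xs = _disk_patch(shape, cy, cx, r_out)
        c_h[ys, xs] += 0.95
        ys, xs = _disk_patch(shape, cy, cx, r_in)
        c_h[ys, xs] -= 0.95          # hollow the ring
        c_e[ys, xs] *= 0.25          # lumen clears the eosin
    np.clip(c_h, 0, None, out=c_h)


def _paint_scattered_nuclei(c_h, rng) -> None:
    """Diffuse-like texture: many small discohesive nuclei."""
    shape = c_h.shape
    n = rng.integers(150, 220)
    for _ in range(n):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ys, xs = _disk_patch(shape, cy, cx, rng.uniform(1.5, 3.0))
        c_h[ys, xs] += 0.90


def _mucin_pool(shape, rng) -> tuple[np.ndarray, np.ndarray]:
    """Pale wispy extracellular mucin: faint, smooth, nearly featureless."""
    base = gaussian_filter(rng.normal(0, 1, shape), 8)
    c_e = np.clip(0.06 + 0.02 * base, 0, None)
    c_h = np.clip(0.10 + 0.03 * base, 0, None)
    return c_h, c_e


def _render_block(kind: int, signal_class: str, shape, rng):
    """Concentration fields (c_h, c_e) for one region block."""
    if kind == BACKGROUND:
        noise = rng.normal(0, 0.004, shape)
        return np.clip(0.005 + noise, 0, None), np.clip(0.005 + noise, 0, None)
    if kind == MUCIN:
        return _mucin_pool(shape, rng)
    c_h, c_e = _neutral_stroma(shape, rng)
    if kind == SIGNAL:
        if signal_class == INTESTINAL:
            _paint_glands(c_h, c_e, rng)
        else:
            _paint_scattered_nuclei(c_h, rng)
    elif kind == BLUR:
        # heavy low-pass of ordinary tissue emulates an out-of-focus region
        c_h = gaussian_filter(c_h, 7)
        c_e = gaussian_filter(c_e, 7)
    return c_h, c_e


def _grow_block_classes(n_rows, n_cols, counts: dict[int, int], rng) -> np.ndarray:
    """Assign class codes to a block grid as contiguous random blobs."""
    labels = np.full((n_rows, n_cols), NEUTRAL, dtype=np.uint8)
    free = np.ones((n_rows, n_cols), dtype=bool)
    for kind, count in counts.items():
        placed = 0
        while placed < count:
            idx = np.argwhere(free)
            if len(idx) == 0:
                break
            frontier = [tuple(idx[rng.integers(len(idx))])]
            while frontier and placed < count:
                i = rng.integers(len(frontier))
                r, c = frontier.pop(i)
                if not free[r, c]:
                    continue
                labels[r, c] = kind
                free[r, c] = False
                placed += 1
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols and free[rr, cc]:
                        frontier.append((rr, cc))
    return labels


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------

def generate_slide(config: SyntheticSlideConfig, slide_id: str = "synthetic") -> SyntheticSlide:
    """Render one synthetic slide and its per-pixel ground-truth mask.

    The slide area is divided into 256-µm blocks; background, blur, mucin and
    signal blocks are grown as contiguous blobs at the configured fractions
    (signal as a fraction of tissue blocks) and each block is painted with its
    texture in H/E concentration space before a single Beer–Lambert rendering
    pass.  Same config ⇒ bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    w_px = int(round(config.width_um / config.mpp))
    h_px = int(round(config.height_um / config.mpp))
    block_px = max(1, int(round(REGION_BLOCK_UM / config.mpp)))
    n_rows = max(1, h_px // block_px)
    n_cols = max(1, w_px // block_px)
    n_blocks = n_rows * n_cols

    n_bg = int(round(config.background_fraction * n_blocks))
    n_blur = int(round(config.blur_fraction * n_blocks))
    n_mucin = int(round(config.mucin_fraction * n_blocks))
    n_tissue = n_blocks - n_bg - n_blur - n_mucin
    n_signal = int(round(config.signal_fraction * n_tissue))
    labels = _grow_block_classes(
        n_rows, n_cols,
        {BACKGROUND: n_bg, BLUR: n_blur, MUCIN: n_mucin, SIGNAL: n_signal},
        rng,
    )

    c_h = np.zeros((h_px, w_px))
    c_e = np.zeros((h_px, w_px))
    mask = np.full((h_px, w_px), BACKGROUND, dtype=np.uint8)
    for r in range(n_rows):
        for c in range(n_cols):
            sl = (slice(r * block_px, (r + 1) * block_px),
                  slice(c * block_px, (c + 1) * block_px))
            kind = int(labels[r, c])
            bh, be = _render_block(kind, config.signal_class,
                                   (block_px, block_px), rng)
            c_h[sl], c_e[sl] = bh, be
            mask[sl] = kind
    # remainder strips (beyond the block grid) stay background-white

    sh, se = config.stain_scale
    stains = DEFAULT_HE_OD.astype(np.float32)
    c_h = (c_h * sh).astype(np.float32)
    c_e = (c_e * se).astype(np.float32)
    # OD = c_h·h + c_e·e per channel; I = I0·10^(−OD), done in float32
    ln10 = np.float32(np.log(10.0))
    image = np.empty((h_px, w_px, 3), dtype=np.uint8)
    for ch in range(3):
        od = c_h * stains[ch, 0] + c_e * stains[ch, 1]
        np.exp(od * -ln10, out=od)
        np.round(od * np.float32(I0), out=od)
        image[:, :, ch] = np.clip(od, 0, 255).astype(np.uint8)
    return SyntheticSlide(image, mask, config.mpp, config, slide_id)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _flip(label: str, p: float, rng) -> str:
    if rng.random() < p:
        return DIFFUSE if label == INTESTINAL else INTESTINAL
    return label


def generate_cohort(
    config: CohortConfig,
    slide_template: SyntheticSlideConfig | None = None,
    include_slides: bool = True,
) -> list[CaseRecord]:
    """Draw a cohort of cases with latent subtypes, labels and survival.

    Each case gets its own slide seed (slides are materialized lazily with
    :meth:`CaseRecord.make_slide` to bound memory); the slide's signal class
    follows the latent subtype.  With ``include_slides=False`` the cases
    carry no slide configs — sufficient for survival-only experiments.
    """
    rng = np.random.default_rng(config.seed)
    template = slide_template or SyntheticSlideConfig()
    cases: list[CaseRecord] = []
    for i in range(config.n_patients):
        latent = DIFFUSE if rng.random() < config.p_diffuse else INTESTINAL
        path_label = _flip(latent, config.label_noise, rng)
        model_label = _flip(latent, config.model_label_noise, rng)
        if config.two_observers:
            original = _flip(latent, config.label_noise, rng)
            revised = path_label
        else:
            original = revised = path_label

        rate = config.baseline_hazard * (
            config.hazard_ratio if latent == DIFFUSE else 1.0
        )
        t_event = rng.exponential(1.0 / rate)
        if config.censoring_rate > 0:
            rate_c = config.baseline_hazard * config.censoring_rate / (
                1.0 - config.censoring_rate
            )
            t_cens = rng.exponential(1.0 / rate_c)
        else:
            t_cens = np.inf
        os_time = float(min(t_event, t_cens))
        os_event = bool(t_event <= t_cens)
        # cancer-specific survival: a fixed share of deaths is cancer-caused
        cancer_death = os_event and (rng.random() < config.cancer_death_fraction)
        css = (os_time, bool(cancer_death))
        # disease-free survival: relapse precedes death on event cases
        if os_event:
            dfs = (os_time * float(rng.uniform(0.5, 1.0)), True)
        else:
            dfs = (os_time, False)

        covariates = {
            "age": float(np.round(rng.normal(65.0, 10.0), 1)),
            "sex": "male" if rng.random() < 0.6 else "female",
            "stage": int(rng.choice([1, 2, 3, 4], p=[0.2, 0.3, 0.3, 0.2])),
        }

        slide_config = None
        if include_slides:
            s_h = 1.0 + float(rng.uniform(-config.stain_variation,
                                          config.stain_variation))
            s_e = 1.0 + float(rng.uniform(-config.stain_variation,
                                          config.stain_variation))
            slide_config = dataclasses.replace(
                template,
                signal_class=latent,
                stain_scale=(s_h, s_e),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        cases.append(
            CaseRecord(
                case_id=f"case_{i:04d}",
                latent_class=latent,
                pathologist_label=path_label,
                model_label=model_label,
                label_original=original,
                label_revised=revised,
                survival={"OS": (os_time, os_event), "CSS": css, "DFS": dfs},
                covariates=covariates,
                slide_config=slide_config,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Tabular / on-disk interfaces
# ---------------------------------------------------------------------------

def cohort_to_dataframe(cases: list[CaseRecord]) -> pd.DataFrame:
    """Flatten a cohort into the case table the survival module consumes."""
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "latent_class": c.latent_class,
            "pathologist_label": c.pathologist_label,
            "model_label": c.model_label,
            "label_original": c.label_original,
            "label_revised": c.label_revised,
            "slide_path": c.slide_path,
        }
        for ep, (t, e) in c.survival.items():
            row[f"{ep.lower()}_months"] = t
            row[f"{ep.lower()}_event"] = e
        row.update(c.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def save_slide(slide: SyntheticSlide, path: str | Path) -> None:
    """Write a slide as PNG plus a JSON sidecar carrying mpp and slide id."""
    from PIL import Image

    path = Path(path)
    Image.fromarray(slide.image).save(path)
    sidecar = {"mpp": slide.mpp, "slide_id": slide.slide_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_slide(path: str | Path) -> SlideImage:
    """Read a PNG slide and its JSON sidecar back into a SlideImage."""
    from PIL import Image

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(pixels, float(meta["mpp"]), str(meta["slide_id"]))
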