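"""Explainability: top-scoring tiles and whole-slide attention/score heatmaps.

Heatmaps rearrange the per-tile attention weights and class scores of a
prediction onto the slide's tessellation grid (rejected tiles stay null), so
the maps are a lossless view of the evidence the classifier used.  Top tiles
are drawn from correctly classified cases, most confident first, and within
a case ranked by the tile-level probability of the predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .attmil import PredictionRecord
from .preprocess import TileSet
from .synthetic import DIFFUSE


@dataclass
class HeatmapGrid:
    """Attention and prediction-score grids on the tessellation layout.

    ``attention`` holds the bag's softmax weights (non-null cells sum to 1);
    ``prediction`` holds the per-tile diffuse-probability.  NaN marks tiles
    rejected by QC or outside the bag.
    """

    slide_id: str
    attention: np.ndarray   # (n_rows, n_cols) float, NaN = rejected
    prediction: np.ndarray  # (n_rows, n_cols) float, NaN = rejected

    def __post_init__(self) -> None:
        if self.attention.shape != self.prediction.shape:
            raise ValueError("grid shapes differ")

    @property
    def n_tiles(self) -> int:
        return int(np.isfinite(self.attention).sum())


@dataclass
class TopTile:
    """Reference to one highly scoring tile of one case."""

    case_id: str
    grid_row: int
    grid_col: int
    tile_score: float       # probability of the predicted class
    case_confidence: float


def top_tiles(
    predictions: list[PredictionRecord],
    true_labels: dict[str, str],
    k: int = 10,
) -> list[TopTile]:
    """The k highest-scoring tiles per correctly classified case.

    Cases are restricted to those whose predicted label matches the truth
    and ordered by slide-level confidence (most confident first); within a
    case, tiles rank by the tile-level probability of the predicted class,
    ties broken by (grid_row, grid_col).  Invariant to tile input order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    correct = [p for p in predictions if p.label == true_labels[p.case_id]]
    correct.sort(key=lambda p: (-p.confidence, p.case_id))
    out: list[TopTile] = []
    for rec in correct:
        cls_idx = 1 if rec.label == DIFFUSE else 0
        scores = rec.tile_scores[:, cls_idx]
        coords = rec.grid_coords
        if coords is None:
            coords = np.column_stack([np.zeros_like(scores, dtype=int),
                                      np.arange(len(scores))])
        order = sorted(
            range(len(scores)),
            key=lambda i: (-scores[i], int(coords[i, 0]), int(coords[i, 1])),
        )
        for i in order[:k]:
            out.append(
                TopTile(
                    case_id=rec.case_id,
                    grid_row=int(coords[i, 0]),
                    grid_col=int(coords[i, 1]),
                    tile_score=float(scores[i]),
                    case_confidence=rec.confidence,
                )
            )
    return out


def build_heatmap(prediction: PredictionRecord, tiles: TileSet) -> HeatmapGrid:
    """Scatter per-tile attention and scores onto the tessellation grid."""
    if prediction.case_id != tiles.slide_id:
        raise ValueError(
            f"prediction is for {prediction.case_id!r}, tiles for "
            f"{tiles.slide_id!r}"
        )
    n_rows, n_cols = tiles.grid_shape
    att = np.full((n_rows, n_cols), np.nan)
    pred = np.full((n_rows, n_cols), np.nan)
    coords = prediction.grid_coords
    for i, (r, c) in enumerate(np.asarray(coords, dtype=int)):
        att[r, c] = prediction.attention[i]
        pred[r, c] = prediction.tile_scores[i, 1]
    return HeatmapGrid(tiles.slide_id, att, pred)


def render_heatmaps(
    prediction: PredictionRecord,
    tiles: TileSet,
    out_dir: str | Path | None = None,
) -> HeatmapGrid:
    """Build the grids and optionally write PNG overlays and CSV exports.

    Attention renders as brightness; the tile score as a diverging red
    (intestinal) to blue (diffuse) map.  Rejected tiles are transparent.
    """
    grid = build_heatmap(prediction, tiles)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, data, cmap, vmin, vmax in (
            ("attention", grid.attention, "gray", 0.0, None),
            ("prediction", grid.prediction, "RdBu", 0.0, 1.0),
        ):
            fig, ax = plt.subplots(figsize=(4, 4))
            masked = np.ma.masked_invalid(data)
            im = ax.imshow(masked, cmap=cmap, vmin=vmin, vmax=vmax)
            ax.set_title(f"{grid.slide_id}: {name}")
            ax.set_xticks([])
            ax.set_yticks([])
            fig.colorbar(im, ax=ax, fraction=0.046)
            fig.savefig(out_dir / f"{grid.slide_id}_{name}.png", dpi=100,
                        bbox_inches="tight")
            plt.close(fig)
            pd.DataFrame(data).to_csv(
                out_dir / f"{grid.slide_id}_{name}.csv", index=False
            )
    return grid
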