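"""Shared fixtures: a small trained synthetic cohort reused across tests.

The expensive fixture (slide rendering -> tessellation -> QC -> Macenko ->
features -> five-fold CV) is session-scoped and deliberately small: 40
cases of 4x4-tile slides with noiseless labels, 64 stand-in features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from lauren_mil.attmil import AttMILConfig, CVResult, train_crossval
from lauren_mil.features import FeatureBag, TextureStatExtractor
from lauren_mil.pipeline import slide_to_bag
from lauren_mil.synthetic import (
    CaseRecord,
    CohortConfig,
    SyntheticSlideConfig,
    generate_cohort,
)


@dataclass
class CohortRun:
    cases: list[CaseRecord]
    bags: list[FeatureBag]
    tile_truth: dict[str, np.ndarray]
    cv: CVResult

    @property
    def labels(self) -> dict[str, str]:
        return {c.case_id: c.pathologist_label for c in self.cases}


@pytest.fixture(scope="session")
def small_cohort_run() -> CohortRun:
    """40 separable cases, small slides, trained with five-fold CV."""
    cohort = CohortConfig(n_patients=40, label_noise=0.0, seed=11)
    template = SyntheticSlideConfig(width_um=1024.0, height_um=1024.0,
                                    signal_fraction=0.3)
    cases = generate_cohort(cohort, slide_template=template)
    extractor = TextureStatExtractor(dim=64, seed=11)
    bags, truth = [], {}
    for case in cases:
        bag, _, tile_truth, _ = slide_to_bag(
            case.make_slide(), extractor, with_truth=True
        )
        bags.append(bag)
        truth[case.case_id] = tile_truth
    labels = {c.case_id: c.pathologist_label for c in cases}
    cv = train_crossval(bags, labels, AttMILConfig(dim=64), seed=11)
    return CohortRun(cases, bags, truth, cv)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def gaussian_bags(
    n_bags: int = 30,
    n_tiles: int = 12,
    dim: int = 16,
    separation: float = 2.0,
    seed: int = 0,
):
    """Tiny synthetic MIL problem without any imaging: two Gaussian classes.

    Half the tiles of each bag carry the class mean, the rest are neutral
    noise — enough structure for quick optimizer and metric tests.
    """
    rng = np.random.default_rng(seed)
    bags, labels = [], {}
    for i in range(n_bags):
        label = "diffuse" if i % 2 else "intestinal"
        shift = separation if label == "diffuse" else -separation
        X = rng.normal(size=(n_tiles, dim))
        X[: n_tiles // 2, 0] += shift
        bag = FeatureBag(
            slide_id=f"g{i:03d}",
            features=X.astype(np.float32),
            grid_coords=np.column_stack(
                [np.zeros(n_tiles, dtype=int), np.arange(n_tiles)]
            ),
            grid_shape=(1, n_tiles),
        )
        bags.append(bag)
        labels[bag.slide_id] = label
    return bags, labels
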