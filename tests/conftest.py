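"""Shared fixtures: small synthetic scenarios and the published level matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vegrisk.synthetic import ScenarioConfig

# Published risk-level matrix of the 2019 national assessment: 20
# provinces/cities x 9 vegetable categories, ordinal levels 1 (lowest risk)
# to 5. Used as *input* to the grading/reporting operations.
_LEVEL_COLUMNS = [
    "leafy",
    "root_and_potato",
    "melon",
    "brassica",
    "solanaceous",
    "legume",
    "bean_sprouts",
    "fresh_edible_fungus",
    "bulb",
]
_LEVEL_ROWS: dict[str, list[int]] = {
    "Shanghai": [1, 1, 2, 1, 1, 1, 2, 5, 2],
    "Inner Mongolia": [1, 2, 2, 1, 2, 1, 1, 2, 2],
    "Beijing": [2, 1, 1, 1, 1, 1, 1, 2, 2],
    "Jilin": [1, 2, 1, 1, 1, 1, 1, 1, 1],
    "Sichuan": [2, 3, 2, 1, 2, 2, 2, 5, 2],
    "Ningxia": [1, 1, 1, 1, 2, 2, 2, 1, 2],
    "Guangdong": [1, 1, 1, 1, 1, 1, 4, 1, 2],
    "Guangxi": [2, 1, 1, 1, 1, 1, 1, 1, 2],
    "Jiangsu": [1, 1, 2, 1, 1, 1, 1, 3, 1],
    "Jiangxi": [1, 1, 1, 1, 2, 1, 1, 1, 2],
    "Hebei": [1, 1, 1, 1, 2, 1, 1, 1, 2],
    "Henan": [1, 1, 1, 1, 2, 1, 1, 3, 2],
    "Zhejiang": [1, 2, 2, 1, 2, 1, 2, 3, 2],
    "Hubei": [1, 1, 2, 1, 1, 1, 1, 3, 1],
    "Hunan": [1, 1, 3, 1, 2, 1, 2, 1, 2],
    "Fujian": [1, 3, 1, 1, 3, 1, 1, 1, 2],
    "Liaoning": [2, 1, 1, 1, 2, 1, 1, 3, 1],
    "Shaanxi": [2, 2, 1, 1, 2, 1, 1, 5, 2],
    "Qinghai": [1, 1, 2, 1, 1, 1, 2, 1, 1],
    "Heilongjiang": [1, 1, 2, 1, 2, 1, 1, 2, 2],
}


@pytest.fixture(scope="session")
def published_levels() -> pd.DataFrame:
    rows = [
        {"region": region, "category": cat, "risk_level": level}
        for region, levels in _LEVEL_ROWS.items()
        for cat, level in zip(_LEVEL_COLUMNS, levels)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_scenario() -> ScenarioConfig:
    """The full-size reference scenario (20 x 9, 5 tiers, 30 samples)."""
    return ScenarioConfig.default(seed=11)


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A quick 6 x 3 scenario with 3 planted tiers for unit-level runs."""
    return ScenarioConfig.default(
        n_regions=6, n_categories=3, samples_per_combination=20, n_tiers=3, seed=5
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
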