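"""Shared naming conventions and regulatory constants.

The 2019 Chinese national vegetable monitoring programme covers nine vegetable
categories across 20 provinces/cities; GB 2762 sets category-specific maximum
lead levels. Toxicological reference values for lead follow JECFA / US EPA:
an oral reference dose (RfD) of 3.5 ug/(kg*day) and a BMDL01 of
0.6 ug/(kg*day), with a 60 kg reference adult body weight.
"""

from __future__ import annotations

# Nine vegetable category identifiers (snake_case) used throughout.
CATEGORIES: tuple[str, ...] = (
    "leafy",
    "root_and_potato",
    "melon",
    "brassica",
    "solanaceous",
    "legume",
    "bean_sprouts",
    "fresh_edible_fungus",
    "bulb",
)

# The 20 provinces/cities of the monitoring programme.
REGIONS: tuple[str, ...] = (
    "Shanghai",
    "Inner Mongolia",
    "Beijing",
    "Jilin",
    "Sichuan",
    "Ningxia",
    "Guangdong",
    "Guangxi",
    "Jiangsu",
    "Jiangxi",
    "Hebei",
    "Henan",
    "Zhejiang",
    "Hubei",
    "Hunan",
    "Fujian",
    "Liaoning",
    "Shaanxi",
    "Qinghai",
    "Heilongjiang",
)

# National maximum levels for lead (mg/kg): 0.3 for Brassica and leafy
# vegetables, 0.2 for legume vegetables, 0.1 for everything else.
LIMIT_PRESET_MG_PER_KG: dict[str, float] = {
    "leafy": 0.3,
    "brassica": 0.3,
    "legume": 0.2,
    "root_and_potato": 0.1,
    "melon": 0.1,
    "solanaceous": 0.1,
    "bean_sprouts": 0.1,
    "fresh_edible_fungus": 0.1,
    "bulb": 0.1,
}

RFD_UG_PER_KG_DAY: float = 3.5
BMDL01_UG_PER_KG_DAY: float = 0.6
BODY_WEIGHT_KG: float = 60.0
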