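"""Per-100-ml nutrient accounting.

Each food category maps to a record of calories and macronutrients per
100 ml; an item's nutrient content is its estimated volume times the
record, and a meal is the sum of its items. When a fine-grained category
has no record the lookup falls back to its hyper categories (whose records
default to the mean of their children's).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

TABLE_COLUMNS = ("key", "kcal_per_100ml", "cho_g", "pro_g", "fat_g")


class NutritionError(ValueError):
    pass


@dataclass(frozen=True)
class NutrientRecord:
    """Calories and macronutrients per 100 ml of food volume."""

    key: str
    kcal_per_100ml: float
    cho_g_per_100ml: float
    pro_g_per_100ml: float
    fat_g_per_100ml: float

    def __post_init__(self) -> None:
        for name in ("kcal_per_100ml", "cho_g_per_100ml", "pro_g_per_100ml", "fat_g_per_100ml"):
            if getattr(self, name) < 0:
                raise NutritionError(f"record '{self.key}': {name} is negative")
        atwater = 4.0 * self.cho_g_per_100ml + 4.0 * self.pro_g_per_100ml + 9.0 * self.fat_g_per_100ml
        if abs(self.kcal_per_100ml - atwater) / max(self.kcal_per_100ml, 1.0) > 0.5:
            warnings.warn(
                f"record '{self.key}': kcal inconsistent with macros "
                f"({self.kcal_per_100ml:.0f} vs Atwater {atwater:.0f})",
                stacklevel=3,
            )


class NutrientTable:
    """Keyed collection of :class:`NutrientRecord`."""

    def __init__(self, records):
        self._records: dict[str, NutrientRecord] = {}
        for r in records:
            if r.key in self._records:
                raise NutritionError(f"duplicate nutrient key '{r.key}'")
            self._records[r.key] = r

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: str) -> bool:
        return key in self._records

    def get(self, key: str) -> NutrientRecord:
        return self._records[key]

    def keys(self):
        return self._records.keys()

    def write(self, path) -> None:
        rows = [
            {
                "key": r.key,
                "kcal_per_100ml": r.kcal_per_100ml,
                "cho_g": r.cho_g_per_100ml,
                "pro_g": r.pro_g_per_100ml,
                "fat_g": r.fat_g_per_100ml,
            }
            for r in self._records.values()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_nutrient_table(path) -> NutrientTable:
    """Read the CSV dialect ``key,kcal_per_100ml,cho_g,pro_g,fat_g``."""
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise NutritionError(f"nutrient table missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        for col in TABLE_COLUMNS[1:]:
            if float(row[col]) < 0:
                raise NutritionError(f"row {i + 1}, column '{col}': negative value")
        records.append(
            NutrientRecord(
                key=str(row["key"]),
                kcal_per_100ml=float(row["kcal_per_100ml"]),
                cho_g_per_100ml=float(row["cho_g"]),
                pro_g_per_100ml=float(row["pro_g"]),
                fat_g_per_100ml=float(row["fat_g"]),
            )
        )
    return NutrientTable(records)


@dataclass(frozen=True)
class ItemNutrients:
    category: str
    resolved_key: str          # record actually used (fallback provenance)
    level_used: str
    volume_ml: float
    kcal: float
    cho_g: float
    pro_g: float
    fat_g: float


def _mean_of_children(table: NutrientTable, taxonomy, hyper_name: str, level: str):
    """Synthesize a hyper-category record as the mean of its children."""
    if level == "hyper2":
        children = [f for f in taxonomy.fine_names if taxonomy.fine_to_hyper2[f] == hyper_name]
    else:
        h2s = [h for h in taxonomy.hyper2_names if taxonomy.hyper2_to_hyper1[h] == hyper_name]
        children = [f for f in taxonomy.fine_names if taxonomy.fine_to_hyper2[f] in h2s]
    recs = [
        table.get(taxonomy.nutrient_key(c)) for c in children
        if taxonomy.nutrient_key(c) in table
    ]
    if not recs:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # means of valid records are valid
        return NutrientRecord(
            key=f"{hyper_name} (mean of {len(recs)} children)",
            kcal_per_100ml=float(np.mean([r.kcal_per_100ml for r in recs])),
            cho_g_per_100ml=float(np.mean([r.cho_g_per_100ml for r in recs])),
            pro_g_per_100ml=float(np.mean([r.pro_g_per_100ml for r in recs])),
            fat_g_per_100ml=float(np.mean([r.fat_g_per_100ml for r in recs])),
        )


def _resolve_record(category: str, table: NutrientTable, taxonomy):
    """Record for a category at any level, walking up the hierarchy."""
    attempted = []
    key = taxonomy.nutrient_key(category) if taxonomy is not None else category
    attempted.append(key)
    if key in table:
        level = "fine"
        if taxonomy is not None and category in taxonomy.hyper2_names:
            level = "hyper2"
        elif taxonomy is not None and category in taxonomy.hyper1_names:
            level = "hyper1"
        return table.get(key), level
    if taxonomy is None:
        raise NutritionError(f"no nutrient record for {attempted}")
    # fine -> hyper2 -> hyper1 chain
    chain = []
    if category in taxonomy.fine_names:
        h2 = taxonomy.fine_to_hyper2[category]
        chain = [("hyper2", h2), ("hyper1", taxonomy.hyper2_to_hyper1[h2])]
    elif category in taxonomy.hyper2_names:
        chain = [("hyper2", category), ("hyper1", taxonomy.hyper2_to_hyper1[category])]
    elif category in taxonomy.hyper1_names:
        chain = [("hyper1", category)]
    for level, name in chain:
        key = taxonomy.nutrient_key(name)
        attempted.append(key)
        if key in table:
            return table.get(key), level
        synth = _mean_of_children(table, taxonomy, name, level)
        if synth is not None:
            return synth, level
    raise NutritionError(
        f"category '{category}' has no nutrient record at any level "
        f"(tried {attempted})"
    )


def nutrients_for(
    category: str, volume_ml: float, table: NutrientTable, taxonomy=None
) -> ItemNutrients:
    """Scale the category's per-100-ml record by the item volume."""
    if volume_ml < 0:
        raise NutritionError("volume must be >= 0")
    record, level = _resolve_record(category, table, taxonomy)
    f = volume_ml / 100.0
    return ItemNutrients(
        category=category,
        resolved_key=record.key,
        level_used=level,
        volume_ml=volume_ml,
        kcal=f * record.kcal_per_100ml,
        cho_g=f * record.cho_g_per_100ml,
        pro_g=f * record.pro_g_per_100ml,
        fat_g=f * record.fat_g_per_100ml,
    )


@dataclass
class MealEstimate:
    """Per-item nutrients plus meal totals."""

    items: list  # of ItemNutrients
    total_volume_ml: float = 0.0
    total_kcal: float = 0.0
    total_cho_g: float = 0.0
    total_pro_g: float = 0.0
    total_fat_g: float = 0.0

    def __post_init__(self) -> None:
        self.total_volume_ml = float(sum(i.volume_ml for i in self.items))
        self.total_kcal = float(sum(i.kcal for i in self.items))
        self.total_cho_g = float(sum(i.cho_g for i in self.items))
        self.total_pro_g = float(sum(i.pro_g for i in self.items))
        self.total_fat_g = float(sum(i.fat_g for i in self.items))

    def to_dict(self) -> dict:
        return {
            "items": [asdict(i) for i in self.items],
            "totals": {
                "volume_ml": self.total_volume_ml,
                "kcal": self.total_kcal,
                "cho_g": self.total_cho_g,
                "pro_g": self.total_pro_g,
                "fat_g": self.total_fat_g,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assemble_meal(items, table: NutrientTable, taxonomy=None) -> MealEstimate:
    """Combine (recognition, volume) pairs into a meal report.

    ``items`` is a list of ``(category_or_scores, VolumeEstimate)``; the
    first element may be a plain category name or a
    :class:`dietvision.recognition.RecognitionScores`.
    """
    seen = set()
    rows = []
    for scores, vol in items:
        if vol.item_id in seen:
            raise NutritionError(f"duplicate item id {vol.item_id}")
        seen.add(vol.item_id)
        category = scores if isinstance(scores, str) else scores.chosen_label
        if category is None:
            raise NutritionError(f"item {vol.item_id}: recognition carries no label")
        rows.append(nutrients_for(category, vol.volume_ml, table, taxonomy))
    return MealEstimate(items=rows)
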