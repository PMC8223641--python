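"""Food-frequency questionnaire processing.

Converts FFQ responses (frequency category x portions x portion size)
into daily intakes in g/day using a per-gram food composition table,
aggregates items into food groups, and energy-adjusts intakes with the
nutrient density method (g per 1000 kcal; energy-% for macronutrients
via Atwater factors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default mapping from the 7-level consumption-frequency scale to
#: consumption days per day. Overridable everywhere it is used.
DEFAULT_FREQUENCY_MAP: dict[str, float] = {
    "never": 0.0,
    "1/month": 1.0 / 30.0,
    "2-3/month": 2.5 / 30.0,
    "1/week": 1.0 / 7.0,
    "2-4/week": 3.0 / 7.0,
    "5-6/week": 5.5 / 7.0,
    "daily": 1.0,
}

#: Atwater energy conversion factors in kcal per gram.
ATWATER_KCAL_PER_G: dict[str, float] = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "fat": 9.0,
    "alcohol": 7.0,
}

#: Name of the composition column holding energy content (kcal per gram).
ENERGY_COLUMN = "energy"


class FFQError(ValueError):
    """Raised for invalid FFQ responses, composition tables or group maps."""


@dataclass
class IntakeMatrix:
    """Daily dietary intake per subject, with energy-adjusted views.

    All raw matrices are in g/day (subjects in rows). The density views
    created by :func:`energy_adjust` are in g per 1000 kcal, and
    ``energy_pct`` holds the percentage of total energy contributed by
    each Atwater macronutrient.
    """

    items: pd.DataFrame
    nutrients: pd.DataFrame
    kcal: pd.Series
    groups: pd.DataFrame = field(default_factory=pd.DataFrame)
    items_density: pd.DataFrame | None = None
    nutrients_density: pd.DataFrame | None = None
    groups_density: pd.DataFrame | None = None
    energy_pct: pd.DataFrame | None = None
    excluded_subjects: list = field(default_factory=list)

    @property
    def subjects(self) -> pd.Index:
        return self.items.index

    def validate(self) -> None:
        for name, df in (("items", self.items), ("nutrients", self.nutrients),
                         ("groups", self.groups)):
            if len(df) and (df.to_numpy() < -1e-12).any():
                raise FFQError(f"negative values in intake matrix '{name}'")


def read_composition(path) -> pd.DataFrame:
    """Read a food composition TSV (item_id, then per-gram nutrient columns).

    Column names may carry a ``nutrient:unit`` suffix; the unit part is
    stripped and stored in ``df.attrs['units']``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    units = {}
    renamed = {}
    for col in df.columns:
        if ":" in col:
            name, unit = col.split(":", 1)
            renamed[col] = name
            units[name] = unit
    df = df.rename(columns=renamed)
    df.attrs["units"] = units
    _validate_composition(df)
    return df


def _validate_composition(composition: pd.DataFrame) -> None:
    if (composition.to_numpy() < 0).any():
        raise FFQError("composition table contains negative per-gram contents")
    if ENERGY_COLUMN in composition.columns:
        if (composition[ENERGY_COLUMN] >= 10.0).any():
            bad = composition.index[composition[ENERGY_COLUMN] >= 10.0].tolist()
            raise FFQError(
                f"energy content >= 10 kcal/g is not plausible per gram: {bad}")


def compute_daily_intake(
    responses: pd.DataFrame,
    composition: pd.DataFrame,
    frequency_map: dict[str, float] | None = None,
) -> IntakeMatrix:
    """Convert FFQ responses into per-subject daily intakes.

    ``responses`` needs columns subject_id, item_id, frequency_level,
    portions, portion_g. Item g/day is (consumption days per day) x
    portions x portion size; nutrient g/day and kcal follow from the
    per-gram composition table.
    """
    frequency_map = dict(DEFAULT_FREQUENCY_MAP if frequency_map is None
                         else frequency_map)
    required = {"subject_id", "item_id", "frequency_level", "portions", "portion_g"}
    missing = required - set(responses.columns)
    if missing:
        raise FFQError(f"responses table missing columns: {sorted(missing)}")
    _validate_composition(composition)

    unknown_items = sorted(set(responses["item_id"]) - set(composition.index))
    if unknown_items:
        raise FFQError(
            f"items absent from the composition table: {unknown_items}")
    unknown_freq = sorted(set(responses["frequency_level"]) - set(frequency_map))
    if unknown_freq:
        raise FFQError(
            f"unknown frequency levels: {unknown_freq}; "
            f"known: {sorted(frequency_map)}")
    if (responses["portions"] < 0).any() or (responses["portion_g"] < 0).any():
        raise FFQError("portions and portion_g must be non-negative")

    days_per_day = responses["frequency_level"].map(frequency_map)
    g_per_day = days_per_day * responses["portions"] * responses["portion_g"]
    items = (
        responses.assign(g_per_day=g_per_day)
        .pivot_table(index="subject_id", columns="item_id",
                     values="g_per_day", aggfunc="sum", fill_value=0.0)
        .astype(float)
    )
    items.columns.name = None
    items.index.name = "subject_id"

    comp = composition.loc[items.columns]
    nutrients = items @ comp
    if ENERGY_COLUMN in nutrients.columns:
        kcal = nutrients.pop(ENERGY_COLUMN)
    else:
        kcal = pd.Series(np.nan, index=items.index)
    kcal.name = "kcal"
    return IntakeMatrix(items=items, nutrients=nutrients, kcal=kcal)


def read_group_map(path) -> pd.Series:
    """Read an item -> food-group map TSV (columns item_id, group_id)."""
    df = pd.read_csv(path, sep="\t")
    return group_map_from_frame(df)


def group_map_from_frame(df: pd.DataFrame) -> pd.Series:
    dup = df["item_id"][df["item_id"].duplicated()]
    if len(dup):
        raise FFQError(
            f"items mapped to more than one group: {sorted(set(dup))}")
    return df.set_index("item_id")["group_id"]


def aggregate_food_groups(intake: IntakeMatrix,
                          group_map: pd.Series | dict) -> IntakeMatrix:
    """Sum member item columns into food-group columns.

    Items absent from the map pass through untouched in ``items``; an
    item mapped to two groups is a hard error.
    """
    if isinstance(group_map, dict):
        group_map = pd.Series(group_map)
    if group_map.index.duplicated().any():
        dup = sorted(set(group_map.index[group_map.index.duplicated()]))
        raise FFQError(f"items mapped to more than one group: {dup}")
    mapped = [i for i in intake.items.columns if i in group_map.index]
    if not mapped:
        groups = pd.DataFrame(index=intake.items.index)
    else:
        groups = intake.items[mapped].T.groupby(group_map.loc[mapped]).sum().T
        groups.columns.name = None
    return replace(intake, groups=groups)


def energy_adjust(intake: IntakeMatrix,
                  atwater: dict[str, float] | None = None) -> IntakeMatrix:
    """Energy-adjust intakes with the nutrient density method.

    Foods, groups and nutrients are expressed per 1000 kcal of total
    intake; macronutrients with an Atwater factor additionally as
    energy-%. Subjects with non-positive total energy cannot be
    adjusted: they are excluded from every view (raw views included)
    and listed in ``excluded_subjects``.
    """
    atwater = ATWATER_KCAL_PER_G if atwater is None else atwater
    kcal = intake.kcal
    bad = kcal.index[~(kcal > 0)].tolist()
    if bad:
        logger.warning("excluding %d subject(s) with non-positive kcal: %s",
                       len(bad), bad)
    keep = kcal.index[kcal > 0]
    items = intake.items.loc[keep]
    nutrients = intake.nutrients.loc[keep]
    groups = intake.groups.loc[keep] if len(intake.groups) else intake.groups
    kcal = kcal.loc[keep]

    per_1000 = lambda df: df.div(kcal, axis=0) * 1000.0  # noqa: E731
    macros = [m for m in atwater if m in nutrients.columns]
    energy_pct = pd.DataFrame(
        {m: nutrients[m] * atwater[m] / kcal * 100.0 for m in macros},
        index=keep,
    )
    return replace(
        intake,
        items=items, nutrients=nutrients, groups=groups, kcal=kcal,
        items_density=per_1000(items),
        nutrients_density=per_1000(nutrients),
        groups_density=per_1000(groups) if len(groups.columns) else groups,
        energy_pct=energy_pct,
        excluded_subjects=list(intake.excluded_subjects) + bad,
    )


def intake_from_matrix(items: pd.DataFrame, kcal: pd.Series) -> IntakeMatrix:
    """Build an IntakeMatrix directly from an item g/day matrix.

    Used when daily intakes are already available (e.g. the synthetic
    generator emits g/day directly rather than raw FFQ responses).
    """
    items = items.astype(float)
    return IntakeMatrix(
        items=items,
        nutrients=pd.DataFrame(index=items.index),
        kcal=kcal.astype(float).reindex(items.index),
    )
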