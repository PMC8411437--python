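"""The damage index as data: categories, items, grading levels and caps.

The canonical instrument (8 categories, 18 items, maximum total 27) ships as
a bundled YAML document; :func:`canonical_addi` loads it. All scoring logic
is driven by :class:`InstrumentDefinition`, so alternative or modified
instruments can be supplied from file.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from addikit.errors import InstrumentError

__all__ = [
    "GradingLevel",
    "ItemDefinition",
    "CategoryDefinition",
    "InstrumentDefinition",
    "canonical_addi",
    "load_instrument",
    "read_instrument",
    "save_instrument",
    "instrument_json_schema",
]


class GradingLevel(BaseModel):
    """One severity level of a graded item."""

    model_config = ConfigDict(extra="forbid")

    label: str
    points: int = Field(ge=1)
    criterion: str = ""


class ItemDefinition(BaseModel):
    """A single damage item, graded (``levels``) or ungraded (``base_points``)."""

    model_config = ConfigDict(extra="forbid")

    item_id: str
    name: str
    category_id: str
    base_points: int = Field(default=0, ge=0)
    levels: list[GradingLevel] = Field(default_factory=list)
    pediatric_only: bool = False
    applicable_sex: Literal["any", "female_relevant"] = "any"
    criterion: str = ""

    @model_validator(mode="after")
    def _check_structure(self) -> "ItemDefinition":
        if self.levels:
            if len(self.levels) < 2:
                raise ValueError(f"graded item {self.item_id!r} needs >=2 levels")
            pts = [lv.points for lv in self.levels]
            if any(b <= a for a, b in zip(pts, pts[1:])):
                raise ValueError(
                    f"item {self.item_id!r}: level points must be strictly increasing"
                )
            labels = [lv.label for lv in self.levels]
            if len(set(labels)) != len(labels):
                raise ValueError(f"item {self.item_id!r}: duplicate level labels")
            if self.base_points != 0:
                raise ValueError(
                    f"graded item {self.item_id!r} must have base_points = 0"
                )
        elif self.base_points < 1:
            raise ValueError(f"ungraded item {self.item_id!r} needs base_points >= 1")
        return self

    @property
    def graded(self) -> bool:
        return bool(self.levels)

    @property
    def max_points(self) -> int:
        return self.levels[-1].points if self.levels else self.base_points

    def points_for(self, label: str) -> int:
        """Points awarded for an asserted grade label.

        Ungraded items accept only the label ``"present"``.
        """
        if not self.levels:
            if label == "present":
                return self.base_points
            raise KeyError(label)
        for lv in self.levels:
            if lv.label == label:
                return lv.points
        raise KeyError(label)


class CategoryDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    category_id: str
    name: str
    max_points: int = Field(ge=1)
    item_ids: list[str] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_items_unique(self) -> "CategoryDefinition":
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError(f"category {self.category_id!r}: duplicate item_ids")
        return self


class InstrumentDefinition(BaseModel):
    """A complete damage instrument: categories with caps and member items.

    ``max_total`` is derived (sum of category caps); if supplied it must
    match.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    version: str
    categories: list[CategoryDefinition]
    items: list[ItemDefinition]
    max_total: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_instrument(self) -> "InstrumentDefinition":
        cat_ids = [c.category_id for c in self.categories]
        if len(set(cat_ids)) != len(cat_ids):
            raise ValueError("duplicate category_id")
        item_ids = [it.item_id for it in self.items]
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item_id")
        by_cat: dict[str, CategoryDefinition] = {
            c.category_id: c for c in self.categories
        }
        by_item = {it.item_id: it for it in self.items}
        membership: dict[str, str] = {}
        for cat in self.categories:
            for iid in cat.item_ids:
                if iid in membership:
                    raise ValueError(f"item {iid!r} listed in more than one category")
                if iid not in by_item:
                    raise ValueError(f"category {cat.category_id!r} lists unknown item {iid!r}")
                membership[iid] = cat.category_id
        for it in self.items:
            if it.category_id not in by_cat:
                raise ValueError(f"item {it.item_id!r} references unknown category")
            if membership.get(it.item_id) != it.category_id:
                raise ValueError(
                    f"item {it.item_id!r} not listed by its category {it.category_id!r}"
                )
            cap = by_cat[it.category_id].max_points
            if it.max_points > cap:
                raise ValueError(
                    f"item {it.item_id!r} max points {it.max_points} exceeds "
                    f"category cap {cap}"
                )
        for cat in self.categories:
            member_sum = sum(by_item[iid].max_points for iid in cat.item_ids)
            if cat.max_points > member_sum:
                raise ValueError(
                    f"category {cat.category_id!r} cap {cat.max_points} exceeds "
                    f"member item sum {member_sum}"
                )
        derived = sum(c.max_points for c in self.categories)
        if self.max_total not in (0, derived):
            raise ValueError(
                f"max_total {self.max_total} != sum of category caps {derived}"
            )
        object.__setattr__(self, "max_total", derived)
        return self

    # -- lookups ---------------------------------------------------------

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def category(self, category_id: str) -> CategoryDefinition:
        for c in self.categories:
            if c.category_id == category_id:
                return c
        raise KeyError(category_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def category_ids(self) -> list[str]:
        return [c.category_id for c in self.categories]

    def category_of(self, item_id: str) -> str:
        return self.item(item_id).category_id


def canonical_addi() -> InstrumentDefinition:
    """The bundled canonical instrument (8 categories, 18 items, max 27)."""
    text = (resources.files("addikit") / "data" / "addi_v1.yaml").read_text()
    return load_instrument(text)


def load_instrument(source: Union[str, Mapping, Path]) -> InstrumentDefinition:
    """Parse an instrument from YAML/JSON text, a mapping or a file path.

    Raises :class:`addikit.errors.InstrumentError` on schema or invariant
    violations, naming the offending field.
    """
    if isinstance(source, Path):
        return read_instrument(source)
    if isinstance(source, Mapping):
        data = source
    else:
        try:
            data = yaml.safe_load(source)
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise InstrumentError(f"unparseable instrument document: {exc}") from exc
    if not isinstance(data, Mapping):
        raise InstrumentError("instrument document must be a mapping")
    try:
        return InstrumentDefinition.model_validate(data)
    except Exception as exc:
        raise InstrumentError(f"invalid instrument: {exc}") from exc


def read_instrument(path: Union[str, Path]) -> InstrumentDefinition:
    return load_instrument(Path(path).read_text())


def _as_document(instr: InstrumentDefinition) -> dict:
    doc = instr.model_dump(mode="json")
    # stable field order, drop default-empty criterion strings on levels
    return doc


def save_instrument(instr: InstrumentDefinition, fmt: str = "yaml") -> str:
    """Serialize with deterministic field ordering; ``load(save(x)) == x``."""
    doc = _as_document(instr)
    if fmt == "yaml":
        return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=88)
    if fmt == "json":
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def instrument_json_schema() -> dict:
    """JSON Schema for third-party validation of instrument documents."""
    return InstrumentDefinition.model_json_schema()
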