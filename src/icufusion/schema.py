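"""Clinical parameter schema: item types, impute defaults, missingness.

The packaged default schema describes the 17 clinical parameters routinely
charted alongside bedside chest radiographs in the first 48 h of an ICU
stay (vital signs, Glasgow Coma Scale sub-scores, basic labs and body
constitution).  Two of them are recorded for no stay at all and are removed
by :func:`drop_all_missing_items` before modelling, leaving 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["SchemaItem", "ParameterSchema", "load_schema", "default_schema",
           "drop_all_missing_items"]


@dataclass(frozen=True)
class SchemaItem:
    """One clinical parameter: its type, unit, impute default and missingness."""

    name: str
    kind: str  # "continuous" | "categorical"
    unit: str = ""
    default: float | int = 0.0
    categories: tuple | None = None
    missing_fraction: float = 0.0
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError(f"{self.name}: missing_fraction outside [0, 1]")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"{self.name}: categorical item needs categories")
            if self.default not in self.categories:
                raise ValueError(
                    f"{self.name}: default {self.default!r} not among categories"
                )


@dataclass(frozen=True)
class ParameterSchema:
    """Ordered collection of clinical parameters."""

    items: tuple[SchemaItem, ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate item names in schema")

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def K(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, name: str) -> SchemaItem:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(it.name == name for it in self.items)

    def index(self, name: str) -> int:
        for i, it in enumerate(self.items):
            if it.name == name:
                return i
        raise KeyError(name)

    def feature_layout(self) -> tuple[list[str], list[str]]:
        """Encoded feature names and, parallel to them, the source item of each.

        Continuous items contribute one feature; categorical items one
        indicator feature per category.
        """
        feature_names: list[str] = []
        source_item: list[str] = []
        for it in self.items:
            if it.kind == "continuous":
                feature_names.append(it.name)
                source_item.append(it.name)
            else:
                for c in it.categories:
                    feature_names.append(f"{it.name}={c}")
                    source_item.append(it.name)
        return feature_names, source_item

    @property
    def n_features(self) -> int:
        return len(self.feature_layout()[0])

    def to_dict(self) -> dict:
        out = []
        for it in self.items:
            d = {
                "name": it.name,
                "kind": it.kind,
                "unit": it.unit,
                "default": it.default,
                "missing_fraction": it.missing_fraction,
                "mean": it.mean,
                "sd": it.sd,
            }
            if it.categories is not None:
                d["categories"] = list(it.categories)
            out.append(d)
        return {"items": out}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def content_hash(self) -> str:
        import hashlib

        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _schema_from_dict(doc: dict) -> ParameterSchema:
    items = []
    for raw in doc["items"]:
        cats = raw.get("categories")
        items.append(
            SchemaItem(
                name=raw["name"],
                kind=raw["kind"],
                unit=raw.get("unit") or "",
                default=raw["default"],
                categories=tuple(cats) if cats is not None else None,
                missing_fraction=float(raw.get("missing_fraction", 0.0)),
                mean=raw.get("mean"),
                sd=raw.get("sd"),
            )
        )
    return ParameterSchema(tuple(items))


def load_schema(path: str | Path) -> ParameterSchema:
    doc = yaml.safe_load(Path(path).read_text())
    return _schema_from_dict(doc)


def default_schema() -> ParameterSchema:
    """The packaged 17-item clinical parameter schema."""
    text = resources.files("icufusion.data").joinpath("clinical_schema.yaml").read_text()
    return _schema_from_dict(yaml.safe_load(text))


def drop_all_missing_items(schema: ParameterSchema) -> ParameterSchema:
    """Remove items that are missing for every stay (missing_fraction == 1).

    Such items carry no information and would contribute only constant
    impute defaults; with the packaged schema this is the 17 -> 15 reduction
    (capillary refill rate and the GCS total are never charted).
    """
    kept = tuple(it for it in schema.items if it.missing_fraction < 1.0)
    if not kept:
        raise ValueError("all items are fully missing; no usable parameters")
    return ParameterSchema(kept)
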