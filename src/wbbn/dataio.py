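"""Reading and writing discretized categorical clinical datasets.

Two on-disk dialects are supported:

* the LUCS-KDD ``.num`` format — one record per line, each record a list of
  positive integer *item* identifiers, where an item encodes one discretized
  value of one attribute (or one class label);
* plain CSV of raw attribute values, discretized on the fly through an
  :class:`AttributeSchema` that maps raw ranges onto item identifiers.

The schema for the Wisconsin breast-cancer layout (nine cytological
attributes binned low/high onto items 1–18, class benign/malignant on items
19/20) ships as :func:`wbc_schema` and is also expressible in YAML.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING_MARKERS = ("?", "")


class SchemaError(ValueError):
    """The schema itself is inconsistent."""


class SchemaViolationError(ValueError):
    """A record contradicts the schema (unknown item, duplicate attribute)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class Bin:
    """One discretized value of one attribute.

    ``low``/``high`` bound the raw values mapped onto this bin (inclusive);
    they may be ``None`` for purely categorical bins matched by ``label``.
    """

    item: int
    label: str = ""
    low: float | None = None
    high: float | None = None

    def covers(self, raw) -> bool:
        if self.low is not None and self.high is not None:
            try:
                v = float(raw)
            except (TypeError, ValueError):
                return False
            return self.low <= v <= self.high
        return str(raw) == self.label


@dataclass(frozen=True)
class Attribute:
    name: str
    bins: tuple[Bin, ...]

    @property
    def items(self) -> tuple[int, ...]:
        return tuple(b.item for b in self.bins)

    @property
    def arity(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class AttributeSchema:
    """Layout of attributes, their discretized bins and the class attribute.

    Item identifiers must be positive, globally unique and form one
    contiguous block per attribute. Exactly one class attribute exists;
    ``class_positive_item`` names the bin meaning the positive (malignant)
    label.
    """

    attributes: tuple[Attribute, ...]
    class_attribute: Attribute
    class_positive_item: int

    def __post_init__(self):
        seen: set[int] = set()
        for attr in (*self.attributes, self.class_attribute):
            if attr.arity < 2:
                raise SchemaError(f"attribute {attr.name!r} has < 2 bins")
            items = attr.items
            if any(i <= 0 for i in items):
                raise SchemaError(f"attribute {attr.name!r} has non-positive item ids")
            if list(items) != list(range(items[0], items[0] + len(items))):
                raise SchemaError(f"items of {attr.name!r} are not a contiguous block")
            if seen & set(items):
                raise SchemaError(f"items of {attr.name!r} collide with another attribute")
            seen |= set(items)
        if self.class_positive_item not in self.class_attribute.items:
            raise SchemaError("class_positive_item is not a class bin")

    # -- lookups -----------------------------------------------------------
    @property
    def class_items(self) -> tuple[int, ...]:
        return self.class_attribute.items

    @property
    def class_negative_item(self) -> int:
        others = [i for i in self.class_items if i != self.class_positive_item]
        return others[0]

    @property
    def attribute_items(self) -> tuple[int, ...]:
        return tuple(i for a in self.attributes for i in a.items)

    @property
    def max_item(self) -> int:
        return max((*self.attribute_items, *self.class_items))

    def item_owner(self, item: int) -> Attribute:
        for attr in (*self.attributes, self.class_attribute):
            if item in attr.items:
                return attr
        raise SchemaViolationError(f"item {item} is not defined by the schema")

    def owner_map(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for attr in (*self.attributes, self.class_attribute):
            for i in attr.items:
                out[i] = attr.name
        return out

    def item_label(self, item: int) -> str:
        attr = self.item_owner(item)
        b = attr.bins[attr.items.index(item)]
        return f"{attr.name}={b.label or item}"

    # -- YAML --------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "AttributeSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "AttributeSchema":
        def mk_attr(d):
            bins = tuple(
                Bin(
                    item=int(b["item"]),
                    label=str(b.get("label", "")),
                    low=b.get("low"),
                    high=b.get("high"),
                )
                for b in d["bins"]
            )
            return Attribute(name=str(d["name"]), bins=bins)

        return cls(
            attributes=tuple(mk_attr(a) for a in doc["attributes"]),
            class_attribute=mk_attr(doc["class"]),
            class_positive_item=int(doc["positive"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        def attr_doc(a: Attribute) -> dict:
            return {
                "name": a.name,
                "bins": [
                    {
                        k: v
                        for k, v in (
                            ("item", b.item),
                            ("label", b.label),
                            ("low", b.low),
                            ("high", b.high),
                        )
                        if v not in (None, "")
                    }
                    for b in a.bins
                ],
            }

        doc = {
            "attributes": [attr_doc(a) for a in self.attributes],
            "class": attr_doc(self.class_attribute),
            "positive": self.class_positive_item,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


WBC_ATTRIBUTE_NAMES = (
    "clump_thickness",
    "uniformity_of_cellsize",
    "uniformity_of_cellshape",
    "marginal_adhesion",
    "single_epithelial_cellsize",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
)


def wbc_schema() -> AttributeSchema:
    """Default Wisconsin breast-cancer schema: items 1–20.

    Each cytological attribute takes raw values 1–10, binned low (1–5) /
    high (6–10) onto consecutive odd/even items; the class occupies items
    19 (benign) and 20 (malignant, the positive label).
    """
    attrs = []
    for k, name in enumerate(WBC_ATTRIBUTE_NAMES):
        lo, hi = 2 * k + 1, 2 * k + 2
        attrs.append(
            Attribute(
                name,
                (
                    Bin(item=lo, label="1-5", low=1, high=5),
                    Bin(item=hi, label="6-10", low=6, high=10),
                ),
            )
        )
    cls = Attribute(
        "class",
        (Bin(item=19, label="benign"), Bin(item=20, label="malignant")),
    )
    return AttributeSchema(attributes=tuple(attrs), class_attribute=cls, class_positive_item=20)


def synthetic_schema(n_attributes: int, names: Sequence[str] | None = None) -> AttributeSchema:
    """Table-1-style layout for ``n_attributes`` binary attributes: attribute
    *k* owns items ``2k+1``/``2k+2`` and the class owns the final pair."""
    names = list(names) if names is not None else [f"att{k + 1}" for k in range(n_attributes)]
    attrs = tuple(
        Attribute(
            names[k],
            (Bin(item=2 * k + 1, label="0"), Bin(item=2 * k + 2, label="1")),
        )
        for k in range(n_attributes)
    )
    base = 2 * n_attributes
    cls = Attribute("class", (Bin(item=base + 1, label="no"), Bin(item=base + 2, label="yes")))
    return AttributeSchema(attributes=attrs, class_attribute=cls, class_positive_item=base + 2)


# ---------------------------------------------------------------------------


@dataclass
class ItemDataset:
    """Records as item-id sets under a shared :class:`AttributeSchema`.

    A complete record holds exactly one item per attribute plus one class
    item. Records flagged in ``missing`` lack at least one attribute's item
    (or the class item) and are removed by :func:`drop_missing` before any
    modelling step.
    """

    schema: AttributeSchema
    records: list[frozenset[int]]
    missing: list[bool] = field(default_factory=list)

    def __post_init__(self):
        if not self.missing:
            self.missing = [False] * len(self.records)
        if len(self.missing) != len(self.records):
            raise ValueError("missing flags and records differ in length")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def class_item(self, idx: int) -> int:
        rec = self.records[idx]
        for c in self.schema.class_items:
            if c in rec:
                return c
        raise SchemaViolationError(f"record {idx} has no class item")

    def item_matrix(self) -> np.ndarray:
        """Boolean membership matrix, shape ``(n_records, max_item + 1)``."""
        m = np.zeros((self.n_records, self.schema.max_item + 1), dtype=bool)
        for r, rec in enumerate(self.records):
            m[r, list(rec)] = True
        return m

    def to_value_frame(self) -> pd.DataFrame:
        """Records as a DataFrame of bin indices, one column per attribute
        plus the class column; requires a missing-free dataset."""
        if any(self.missing):
            raise ValueError("drop_missing before converting to a value frame")
        cols: dict[str, list[int]] = {}
        attrs = (*self.schema.attributes, self.schema.class_attribute)
        for attr in attrs:
            idx_of = {item: i for i, item in enumerate(attr.items)}
            col = []
            for rec in self.records:
                hit = [idx_of[i] for i in rec if i in idx_of]
                col.append(hit[0])
            cols[attr.name] = col
        return pd.DataFrame(cols, dtype=np.int64)


def _classify_record(items: Iterable[int], schema: AttributeSchema, where: str) -> tuple[frozenset[int], bool]:
    """Validate one record; returns (record, missing_flag)."""
    rec = frozenset(items)
    owners = schema.owner_map()
    per_attr: dict[str, int] = {}
    for item in rec:
        if item not in owners:
            raise SchemaViolationError(f"{where}: item {item} not in schema")
        name = owners[item]
        per_attr[name] = per_attr.get(name, 0) + 1
        if per_attr[name] > 1:
            raise SchemaViolationError(f"{where}: two items of attribute {name!r}")
    expected = [a.name for a in schema.attributes] + [schema.class_attribute.name]
    missing = any(per_attr.get(name, 0) == 0 for name in expected)
    return rec, missing


def read_num(path: str | Path, schema: AttributeSchema) -> ItemDataset:
    """Read a LUCS-KDD ``.num`` file: one whitespace-separated record per
    non-empty line. Items are validated against the schema; a record that
    lacks some attribute's item is kept but flagged missing."""
    records: list[frozenset[int]] = []
    flags: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                items = [int(t) for t in tokens]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer token ({exc})") from None
            if any(i <= 0 for i in items):
                raise ParseError(f"{path}:{lineno}: non-positive item id")
            rec, miss = _classify_record(items, schema, f"{path}:{lineno}")
            records.append(rec)
            flags.append(miss)
    return ItemDataset(schema=schema, records=records, missing=flags)


def write_num(ds: ItemDataset, path: str | Path) -> None:
    """Write records in the ``.num`` dialect (items ascending per line)."""
    with open(path, "w") as fh:
        for rec in ds.records:
            fh.write(" ".join(str(i) for i in sorted(rec)) + "\n")


def read_csv_discretize(
    path: str | Path,
    schema: AttributeSchema,
    missing_markers: Sequence[str] = MISSING_MARKERS,
) -> ItemDataset:
    """Read a headered CSV of raw values and discretize through the schema.

    Each attribute column's raw value is mapped to the covering bin's item;
    the class column is matched against class-bin labels. Cells equal to a
    missing marker flag the record as missing. A raw value outside every
    declared bin raises, as does an unknown class label.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ItemDataset(schema=schema, records=[], missing=[])
        needed = [a.name for a in schema.attributes] + [schema.class_attribute.name]
        for name in needed:
            if name not in reader.fieldnames:
                raise ParseError(f"{path}: missing column {name!r}")
        records, flags = [], []
        for lineno, row in enumerate(reader, start=2):
            items: list[int] = []
            miss = False
            for attr in (*schema.attributes, schema.class_attribute):
                raw = (row[attr.name] or "").strip()
                if raw in missing_markers:
                    miss = True
                    continue
                hit = [b.item for b in attr.bins if b.covers(raw)]
                if not hit:
                    kind = "class label" if attr is schema.class_attribute else "value"
                    raise ParseError(
                        f"{path}:{lineno}: {kind} {raw!r} outside declared bins of {attr.name!r}"
                    )
                items.append(hit[0])
            records.append(frozenset(items))
            flags.append(miss)
    return ItemDataset(schema=schema, records=records, missing=flags)


def read_uci_wbc(path: str | Path) -> ItemDataset:
    """Read the raw UCI Breast Cancer Wisconsin (Original) data file.

    The file is headerless CSV: a sample id followed by nine attribute
    values in 1–10 and the class code (2 = benign, 4 = malignant); missing
    cells are ``?``. The id column is dropped and values are discretized
    through :func:`wbc_schema`.
    """
    schema = wbc_schema()
    records, flags = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != 11:
                raise ParseError(f"{path}:{lineno}: expected 11 fields, got {len(cells)}")
            items: list[int] = []
            miss = False
            for attr, raw in zip(schema.attributes, cells[1:10]):
                raw = raw.strip()
                if raw in MISSING_MARKERS:
                    miss = True
                    continue
                hit = [b.item for b in attr.bins if b.covers(raw)]
                if not hit:
                    raise ParseError(f"{path}:{lineno}: value {raw!r} outside 1-10")
                items.append(hit[0])
            cls = cells[10].strip()
            if cls == "2":
                items.append(schema.class_negative_item)
            elif cls == "4":
                items.append(schema.class_positive_item)
            elif cls in MISSING_MARKERS:
                miss = True
            else:
                raise ParseError(f"{path}:{lineno}: unknown class code {cls!r}")
            records.append(frozenset(items))
            flags.append(miss)
    return ItemDataset(schema=schema, records=records, missing=flags)


def drop_missing(ds: ItemDataset) -> tuple[ItemDataset, int]:
    """Remove records flagged missing; returns the clean dataset and the
    number of records removed."""
    keep = [i for i, m in enumerate(ds.missing) if not m]
    removed = ds.n_records - len(keep)
    return (
        ItemDataset(
            schema=ds.schema,
            records=[ds.records[i] for i in keep],
            missing=[False] * len(keep),
        ),
        removed,
    )
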