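"""Reading, validating and integer-encoding discrete microdata tables.

A released dataset is an ``n_D x d`` table of nominal or ordinal attributes,
assumed to be a uniform i.i.d. sample from a population of known size ``n``.
Every distinct raw value is replaced by an integer code in ``1..K`` per
attribute; code 0 is reserved as the lower-bound sentinel of the latent
integration rectangle (``F(0) = 0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A column or declared attribute does not match the table."""


class InputError(ValueError):
    """The input file or column is empty or malformed."""


@dataclass
class AttributeSchema:
    """One attribute's name, kind and integer support.

    Codes are consecutive integers ``1..cardinality``; code 0 is reserved
    for the lower integration sentinel and never appears in data.
    """

    name: str
    kind: str  # "nominal" or "ordinal"
    observed_support: list[int] = field(default_factory=list)
    cardinality: int = 0

    def __post_init__(self):
        if self.kind not in ("nominal", "ordinal"):
            raise SchemaError(f"attribute {self.name!r}: kind must be "
                              f"'nominal' or 'ordinal', got {self.kind!r}")
        if self.observed_support and not self.cardinality:
            self.cardinality = len(self.observed_support)
        if self.observed_support:
            if list(self.observed_support) != list(range(1, self.cardinality + 1)):
                raise SchemaError(
                    f"attribute {self.name!r}: codes must be consecutive "
                    f"integers starting at 1")


@dataclass
class MicrodataTable:
    """Integer-coded sample ``D`` with its schema and codebook.

    ``rows`` is an ``n_D x d`` integer matrix; ``codebook`` maps, per
    attribute, each original value to its code.
    """

    rows: np.ndarray
    schema: list[AttributeSchema]
    codebook: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 2:
            raise InputError("rows must be a 2-D matrix")
        if self.rows.shape[0] < 1 or self.rows.shape[1] < 1:
            raise InputError("table must have at least one row and one column")
        if self.rows.shape[1] != len(self.schema):
            raise SchemaError("row width does not match schema")
        for j, att in enumerate(self.schema):
            col = self.rows[:, j]
            if col.min() < 1 or col.max() > att.cardinality:
                raise SchemaError(
                    f"attribute {att.name!r}: codes outside 1..{att.cardinality}")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.rows.shape[1]

    @property
    def kinds(self) -> list[str]:
        return [a.kind for a in self.schema]

    def decode(self) -> pd.DataFrame:
        """Recover the original values through the codebook."""
        out = {}
        for j, att in enumerate(self.schema):
            inverse = {code: value for value, code in
                       self.codebook[att.name].items()}
            out[att.name] = [inverse[c] for c in self.rows[:, j]]
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rows, columns=[a.name for a in self.schema]).to_csv(
            path, index=False)

    def codebook_json(self) -> str:
        return json.dumps({name: {str(k): int(v) for k, v in mapping.items()}
                           for name, mapping in self.codebook.items()},
                          indent=1)


def encode_values(column, kind: str = "nominal", order=None):
    """Map raw values of one column to integer codes ``1..K``.

    For ordinal attributes the code order follows ``order`` when declared,
    otherwise the natural sort order of the distinct values.  For nominal
    attributes the initial order is first appearance (a seeded permutation
    is applied later, at marginal-fitting time).

    Returns ``(codes, codebook_entry)``.
    """
    values = list(column)
    if len(values) == 0:
        raise InputError("cannot encode an empty column")
    if kind == "ordinal":
        if order is not None:
            distinct = list(order)
            missing = set(values) - set(distinct)
            if missing:
                raise SchemaError(f"values {sorted(map(str, missing))} absent "
                                  f"from the declared ordinal order")
        else:
            distinct = sorted(set(values))
    else:
        seen = dict.fromkeys(values)  # preserves first-appearance order
        distinct = list(seen)
    codebook_entry = {v: i + 1 for i, v in enumerate(distinct)}
    codes = np.array([codebook_entry[v] for v in values], dtype=np.int64)
    return codes, codebook_entry


def read_table(path, config) -> MicrodataTable:
    """Read a delimited text file and encode it under ``config``.

    ``config`` is a mapping (or path to a YAML/JSON file) with an
    ``attributes`` list of ``{name, kind, order?}`` entries; a top-level
    ``population_size`` is carried by the caller, not the table.  Missing
    values are rejected unless ``missing_as_category`` is set in the config,
    in which case they become their own code.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    attributes = config.get("attributes")
    if not attributes:
        raise SchemaError("config must declare an 'attributes' list")
    sep = config.get("separator", ",")
    df = pd.read_csv(path, sep=sep, dtype="object", keep_default_na=False,
                     na_values=[""])
    if df.shape[0] == 0:
        raise InputError(f"{path}: no data rows")
    missing_ok = bool(config.get("missing_as_category", False))
    cols, schema, codebook = [], [], {}
    for att in attributes:
        name = att["name"]
        if name not in df.columns:
            raise SchemaError(f"column {name!r} declared in config is absent "
                              f"from {path}")
        raw = df[name]
        if raw.isna().any():
            if not missing_ok:
                raise InputError(
                    f"column {name!r} contains missing values; set "
                    f"missing_as_category to model them as their own code")
            raw = raw.fillna("<missing>")
        codes, entry = encode_values(raw.tolist(), att.get("kind", "nominal"),
                                     att.get("order"))
        cols.append(codes)
        codebook[name] = entry
        schema.append(AttributeSchema(name=name, kind=att.get("kind", "nominal"),
                                      observed_support=list(range(1, len(entry) + 1))))
    return MicrodataTable(rows=np.column_stack(cols), schema=schema,
                          codebook=codebook)


def subsample(table: MicrodataTable, fraction: float, seed: int) -> MicrodataTable:
    """Uniform sample without replacement of ``round(fraction * n_D)`` rows.

    Rounding is half-up so that printed sample sizes match ``n_S = p * n``.
    Deterministic under a fixed seed.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_out = int(np.floor(fraction * table.n_rows + 0.5))
    if n_out < 1:
        raise ValueError(
            f"fraction {fraction} of {table.n_rows} rows rounds to zero")
    if fraction == 1.0:
        return MicrodataTable(rows=table.rows.copy(), schema=table.schema,
                              codebook=table.codebook)
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_rows, size=n_out, replace=False)
    return MicrodataTable(rows=table.rows[np.sort(idx)], schema=table.schema,
                          codebook=table.codebook)
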