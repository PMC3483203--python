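"""Dinucleotide physicochemical property scales.

Twelve normalized structural/thermodynamic scales (A-philicity, base
stacking, B-DNA twist, bendability, bending stiffness, denaturation,
duplex disrupt energy, duplex free energy, propeller twist, protein
deformation, protein-DNA twist, Z-DNA), each mapping the 16 dinucleotides
to a dimensionless value.  The built-in table ships as package data and
its values are canonical constants: they are not regenerated by
:func:`normalize_scale`, which is a utility for user-supplied raw scales.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DINUCLEOTIDES",
    "PROPERTY_IDS",
    "PROPERTY_NAMES",
    "PropertyScale",
    "PropertyTable",
    "builtin_table",
    "lookup",
    "normalize_scale",
]

#: The 16 dinucleotides in fixed lexicographic order (AA ... TT).
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

#: Property identifiers in the frozen concatenation order.
PROPERTY_IDS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 13))

#: Human-readable names, parallel to PROPERTY_IDS.
PROPERTY_NAMES: tuple[str, ...] = (
    "A-philicity",
    "base stacking",
    "B-DNA twist",
    "bendability",
    "DNA bending stiffness",
    "DNA denaturation",
    "duplex disrupt energy",
    "duplex free energy",
    "propeller twist",
    "protein deformation",
    "protein-DNA twist",
    "Z-DNA",
)

_PROPERTY_INDEX = {p: i for i, p in enumerate(PROPERTY_IDS)}


class PropertyTableError(Exception):
    """Raised when the packaged property table is missing or malformed."""


@dataclass(frozen=True)
class PropertyScale:
    """One normalized dinucleotide scale.

    Parameters
    ----------
    property_id : str
        Identifier ``P1`` ... ``P12``.
    name : str
        Human-readable property name (e.g. ``"bendability"``).
    values : mapping
        Dinucleotide -> normalized value; exactly the 16 keys AA ... TT.
        Values are finite but not guaranteed to lie within [-1, 1].
    """

    property_id: str
    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(DINUCLEOTIDES):
            missing = set(DINUCLEOTIDES) - keys
            extra = keys - set(DINUCLEOTIDES)
            raise PropertyTableError(
                f"scale {self.property_id!r}: expected the 16 dinucleotides, "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        arr = np.asarray([self.values[d] for d in DINUCLEOTIDES], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise PropertyTableError(
                f"scale {self.property_id!r} contains non-finite values"
            )

    def as_array(self) -> np.ndarray:
        """Values as a length-16 array in DINUCLEOTIDES order."""
        return np.asarray([self.values[d] for d in DINUCLEOTIDES], dtype=float)


@dataclass(frozen=True)
class PropertyTable:
    """Ordered collection of the 12 property scales.

    The order is frozen (P1 A-philicity ... P12 Z-DNA) and determines the
    block layout of the concatenated feature encoding.
    """

    scales: tuple[PropertyScale, ...]

    def __post_init__(self) -> None:
        if len(self.scales) != 12:
            raise PropertyTableError(
                f"expected 12 property scales, got {len(self.scales)}"
            )
        ids = tuple(s.property_id for s in self.scales)
        if ids != PROPERTY_IDS:
            raise PropertyTableError(f"property order must be {PROPERTY_IDS}, got {ids}")

    @functools.cached_property
    def matrix(self) -> np.ndarray:
        """12 x 16 array: rows = properties in order, columns = dinucleotides."""
        m = np.vstack([s.as_array() for s in self.scales])
        m.setflags(write=False)
        return m

    def scale(self, property_id: str) -> PropertyScale:
        try:
            return self.scales[_PROPERTY_INDEX[property_id]]
        except KeyError:
            raise KeyError(
                f"unknown property id {property_id!r}; expected one of {PROPERTY_IDS}"
            ) from None


def lookup(table: PropertyTable, dinuc: str, property_id: str) -> float:
    """Return the normalized value of ``property_id`` for ``dinuc``.

    Case-insensitive in the dinucleotide.  Raises ``ValueError`` for any
    dinucleotide outside {A,C,G,T}^2 (ambiguity policy is decided by the
    caller, e.g. the encoding layer).
    """
    d = dinuc.upper()
    if d not in _DINUC_INDEX:
        raise ValueError(
            f"invalid dinucleotide {dinuc!r}: must be two characters from A/C/G/T"
        )
    i = _PROPERTY_INDEX.get(property_id)
    if i is None:
        raise KeyError(
            f"unknown property id {property_id!r}; expected one of {PROPERTY_IDS}"
        )
    return float(table.matrix[i, _DINUC_INDEX[d]])


@functools.lru_cache(maxsize=1)
def builtin_table() -> PropertyTable:
    """Load the packaged 16 x 12 normalized property table."""
    ref = resources.files("nucphyschem.data") / "dinucleotide_properties.tsv"
    try:
        with ref.open("r") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise PropertyTableError("packaged property table is missing") from exc
    expected_cols = ["dinucleotide", *PROPERTY_IDS]
    if list(df.columns) != expected_cols or len(df) != 16:
        raise PropertyTableError(
            f"malformed property table: columns={list(df.columns)}, rows={len(df)}"
        )
    df = df.set_index("dinucleotide")
    scales = []
    for pid, name in zip(PROPERTY_IDS, PROPERTY_NAMES):
        values = {d: float(df.loc[d, pid]) for d in DINUCLEOTIDES}
        scales.append(PropertyScale(property_id=pid, name=name, values=values))
    return PropertyTable(scales=tuple(scales))


def normalize_scale(raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max rescale a raw dinucleotide scale onto [-1, +1].

    x -> 2 (x - min) / (max - min) - 1 over the 16 values, so the output
    attains -1 and +1 exactly.  Invariant under positive affine transforms
    of the input and idempotent on scales already spanning [-1, 1].

    Raises ``ValueError`` on a constant scale (max == min), for which the
    rescale is undefined, and on missing/invalid keys or non-finite values.
    """
    keys = {k.upper() for k in raw}
    if keys != set(DINUCLEOTIDES):
        raise ValueError(
            "raw scale must define exactly the 16 dinucleotides AA..TT; "
            f"got {sorted(keys)}"
        )
    vals = {k.upper(): float(v) for k, v in raw.items()}
    arr = np.asarray([vals[d] for d in DINUCLEOTIDES])
    if not np.all(np.isfinite(arr)):
        raise ValueError("raw scale contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("constant scale: min == max, normalization undefined")
    return {d: float(2.0 * (vals[d] - lo) / (hi - lo) - 1.0) for d in DINUCLEOTIDES}
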