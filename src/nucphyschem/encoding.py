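"""Sequence -> physicochemical profile encoding.

A DNA sequence of length L is slid over with a 2-bp window, step 1,
producing an (L-1)-long profile per property; the 12 profiles are
concatenated property-major into a 12*(L-1)-component feature vector
(1788-D for the canonical 150-bp fragments).  Block i (length L-1)
belongs to property P(i), ordered by window start position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import PROPERTY_IDS, PropertyTable, _PROPERTY_INDEX, builtin_table

__all__ = [
    "DNASequence",
    "FeatureMatrix",
    "encode_property",
    "encode_full",
    "encode_fasta",
    "encode_records",
    "load_training_matrix",
    "class_mean_profiles",
    "read_fasta",
    "write_fasta",
]

LABEL_NUCLEOSOME = "nucleosome"
LABEL_LINKER = "linker"

# A=0 C=1 G=2 T=3; anything else = -1 (ambiguous)
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class AmbiguousBaseError(ValueError):
    """A sequence window contains a base outside {A, C, G, T}."""


@dataclass
class DNASequence:
    """A DNA sequence with an optional class label.

    Residues are uppercased on construction; the alphabet is checked at
    encoding time according to the ambiguity policy in force there.
    """

    id: str
    residues: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) < 2:
            raise ValueError(f"sequence {self.id!r}: length must be >= 2")

    def __len__(self) -> int:
        return len(self.residues)


def dinucleotide_codes(seq: DNASequence) -> np.ndarray:
    """Per-window dinucleotide codes 0..15 (-1 where a base is ambiguous)."""
    b = _BASE_CODE[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    codes = 4 * b[:-1] + b[1:]
    codes[(b[:-1] < 0) | (b[1:] < 0)] = -1
    return codes


def _checked_codes(seq: DNASequence, policy: Literal["strict", "skip"]) -> np.ndarray:
    codes = dinucleotide_codes(seq)
    if policy == "strict":
        bad = np.flatnonzero(codes < 0)
        if bad.size:
            raise AmbiguousBaseError(
                f"sequence {seq.id!r}: ambiguous base in 2-bp window starting at "
                f"position {int(bad[0]) + 1} (1-based); only A/C/G/T are accepted "
                "under the strict policy"
            )
    elif policy != "skip":
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    return codes


def encode_property(
    seq: DNASequence,
    property_id: str,
    table: Optional[PropertyTable] = None,
    policy: Literal["strict", "skip"] = "strict",
) -> np.ndarray:
    """Encode one sequence under a single property scale.

    Returns the (L-1)-long profile: element p (0-based) is the table value
    of the dinucleotide starting at sequence position p.  Under the "skip"
    policy, windows overlapping ambiguous bases are NaN.
    """
    table = table if table is not None else builtin_table()
    i = _PROPERTY_INDEX.get(property_id)
    if i is None:
        raise KeyError(f"unknown property id {property_id!r}")
    codes = _checked_codes(seq, policy)
    profile = np.where(codes >= 0, table.matrix[i, np.clip(codes, 0, 15)], np.nan)
    return profile.astype(float)


def encode_full(
    seq: DNASequence,
    table: Optional[PropertyTable] = None,
    policy: Literal["strict", "skip"] = "strict",
) -> np.ndarray:
    """Concatenated 12-property feature vector of length 12*(L-1).

    The first L-1 components come from P1 (A-philicity), the next L-1 from
    P2 (base stacking), ..., the last L-1 from P12 (Z-DNA).
    """
    table = table if table is not None else builtin_table()
    codes = _checked_codes(seq, policy)
    block = table.matrix[:, np.clip(codes, 0, 15)]  # 12 x (L-1)
    if np.any(codes < 0):
        block = block.copy()
        block[:, codes < 0] = np.nan
    return block.ravel()


@dataclass
class FeatureMatrix:
    """Encoded samples with parallel class labels.

    ``X`` is (n_samples, n_features); ``y`` is a boolean array, True for
    nucleosome-forming (positive) rows; ``ids`` carries the FASTA record
    identifiers in ingest order.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("labels must be parallel to rows")
        if not self.ids:
            self.ids = [f"seq{i + 1}" for i in range(self.X.shape[0])]

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.y).sum())

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        widths = {p.X.shape[1] for p in parts}
        if len(widths) != 1:
            raise ValueError(f"feature widths differ: {sorted(widths)}")
        return FeatureMatrix(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            ids=[i for p in parts for i in p.ids],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Debug/interop export: id, label, then one column per feature."""
        import pandas as pd

        df = pd.DataFrame(self.X)
        df.insert(0, "label", np.where(self.y, LABEL_NUCLEOSOME, LABEL_LINKER))
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[DNASequence]:
    """Read a FASTA file into DNASequence records (uppercased)."""
    records = [
        DNASequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[DNASequence], path: str | Path) -> None:
    """Write DNASequence records as FASTA (sequence lines wrapped)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def encode_records(
    records: Sequence[DNASequence],
    table: Optional[PropertyTable] = None,
    expected_length: Optional[int] = None,
    label: Optional[str] = None,
) -> FeatureMatrix:
    """Encode a homogeneous batch of sequences into a FeatureMatrix."""
    table = table if table is not None else builtin_table()
    if expected_length is not None:
        bad = [r.id for r in records if len(r) != expected_length]
        if bad:
            raise ValueError(
                f"{len(bad)} record(s) do not have the expected length "
                f"{expected_length}: {', '.join(bad[:10])}"
                + (" ..." if len(bad) > 10 else "")
            )
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(
            "records must share one length to form a rectangular matrix; "
            f"got lengths {sorted(lengths)}"
        )
    X = np.vstack([encode_full(r, table) for r in records])
    labels = [label if label is not None else (r.label or LABEL_NUCLEOSOME) for r in records]
    y = np.asarray([lab == LABEL_NUCLEOSOME for lab in labels], dtype=bool)
    return FeatureMatrix(X=X, y=y, ids=[r.id for r in records])


def encode_fasta(
    path: str | Path,
    table: Optional[PropertyTable] = None,
    expected_length: Optional[int] = None,
    label: str = LABEL_NUCLEOSOME,
) -> FeatureMatrix:
    """Encode every record of one FASTA file, assigning it one class label.

    Training data follows the two-file convention: one positive
    (nucleosome) and one negative (linker) FASTA, each encoded with its
    file-level label and concatenated via :meth:`FeatureMatrix.concat` or
    :func:`load_training_matrix`.
    """
    return encode_records(
        read_fasta(path), table=table, expected_length=expected_length, label=label
    )


def load_training_matrix(
    pos_path: str | Path,
    neg_path: str | Path,
    table: Optional[PropertyTable] = None,
    expected_length: Optional[int] = 150,
) -> FeatureMatrix:
    """Encode a positive and a negative FASTA into one labeled matrix."""
    pos = encode_fasta(pos_path, table, expected_length, label=LABEL_NUCLEOSOME)
    neg = encode_fasta(neg_path, table, expected_length, label=LABEL_LINKER)
    return FeatureMatrix.concat([pos, neg])


def class_mean_profiles(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Component-wise class means (positive, negative).

    These are the per-class standard vectors whose 12 per-property blocks
    form the classic 12-panel profile comparison between nucleosomal and
    linker sequences.
    """
    if matrix.n_pos == 0 or matrix.n_neg == 0:
        raise ValueError("both classes must be non-empty to form mean profiles")
    return matrix.X[matrix.y].mean(axis=0), matrix.X[~matrix.y].mean(axis=0)


def feature_name(index: int, block_width: int = 149) -> str:
    """Decode a 0-based feature index to e.g. ``"P4:pos73"`` (1-based pos)."""
    if index < 0 or index >= 12 * block_width:
        raise IndexError(f"feature index {index} out of range for block width {block_width}")
    return f"{PROPERTY_IDS[index // block_width]}:pos{index % block_width + 1}"
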