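"""Sliding-window scanning of arbitrary-length sequences.

A query of length L >= 150 resolves into L - 149 overlapping 150-bp
windows (step 1 bp), numbered #1 ... #(L-149) by 1-based start position.
Each window is encoded and classified; runs of consecutive windows sharing
a label are merged into segment calls.  No smoothing beyond run-merging is
applied, so expanding the calls reproduces the per-window label vector
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from . import cd_classifier
from .cd_classifier import CDModel
from .encoding import (
    LABEL_LINKER,
    LABEL_NUCLEOSOME,
    DNASequence,
    dinucleotide_codes,
)
from .properties import PropertyTable, builtin_table

__all__ = ["SegmentCall", "scan", "window_feature_matrix", "expand_calls", "calls_to_bed"]

WINDOW_BP = 150
PROFILE_LEN = WINDOW_BP - 1  # 149


@dataclass(frozen=True)
class SegmentCall:
    """A maximal run of consecutive same-label windows on one sequence."""

    sequence_id: str
    first_window: int  # 1-based window start index
    last_window: int
    label: str

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


def window_feature_matrix(
    seq: DNASequence,
    table: Optional[PropertyTable] = None,
    policy: Literal["strict", "skip"] = "strict",
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every 150-bp window of a long sequence.

    Returns ``(X, valid)`` where X is (L-149, 1788) and ``valid`` flags
    windows free of ambiguous bases.  The per-property profile of the whole
    sequence is computed once; window vectors are overlapping slices of it,
    which keeps genome-scale scanning cheap.
    """
    table = table if table is not None else builtin_table()
    L = len(seq)
    if L < WINDOW_BP:
        raise ValueError(
            f"sequence {seq.id!r} is {L} bp, shorter than the {WINDOW_BP}-bp window"
        )
    codes = dinucleotide_codes(seq)
    bad = codes < 0
    if policy == "strict" and bad.any():
        off = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(
            f"sequence {seq.id!r}: ambiguous base near position {off}; "
            "use the 'skip' policy to drop affected windows"
        )
    profile = table.matrix[:, np.clip(codes, 0, 15)]  # 12 x (L-1)
    # windows of 149 consecutive profile columns -> (12, W, 149)
    win = np.lib.stride_tricks.sliding_window_view(profile, PROFILE_LEN, axis=1)
    X = np.ascontiguousarray(win.transpose(1, 0, 2).reshape(-1, 12 * PROFILE_LEN))
    n_windows = L - PROFILE_LEN
    if bad.any():
        bad_any = np.convolve(bad.astype(int), np.ones(PROFILE_LEN, dtype=int), "valid")
        valid = bad_any == 0
    else:
        valid = np.ones(n_windows, dtype=bool)
    return X, valid


def scan(
    seq: DNASequence,
    model: CDModel,
    table: Optional[PropertyTable] = None,
    policy: Literal["strict", "skip"] = "strict",
) -> list[SegmentCall]:
    """Classify every window of ``seq`` and merge runs into segment calls.

    For a clean sequence the calls tile windows #1 .. #(L-149) without gaps
    and consecutive calls alternate labels.  Under the "skip" policy,
    windows overlapping ambiguous bases are omitted and break runs.
    """
    X, valid = window_feature_matrix(seq, table, policy)
    labels_bool, _ = cd_classifier.predict_batch(
        cd_classifier.project(X, model), model
    )
    calls: list[SegmentCall] = []
    start = None
    current = None
    for w in range(X.shape[0]):
        if not valid[w]:
            if start is not None:
                calls.append(_call(seq.id, start, w, current))
                start = None
            continue
        lab = LABEL_NUCLEOSOME if labels_bool[w] else LABEL_LINKER
        if start is None:
            start, current = w, lab
        elif lab != current:
            calls.append(_call(seq.id, start, w, current))
            start, current = w, lab
    if start is not None:
        calls.append(_call(seq.id, start, X.shape[0], current))
    return calls


def _call(seq_id: str, start0: int, end0_excl: int, label: str) -> SegmentCall:
    return SegmentCall(
        sequence_id=seq_id,
        first_window=start0 + 1,
        last_window=end0_excl,
        label=label,
    )


def expand_calls(calls: list[SegmentCall]) -> list[str]:
    """Per-window label vector reconstructed from merged calls."""
    labels: list[str] = []
    for c in calls:
        labels.extend([c.label] * c.n_windows)
    return labels


def calls_to_bed(calls: list[SegmentCall], path: str | Path) -> None:
    """Write merged segment calls as BED.

    Window #w covers the 0-based half-open interval [w-1, w+149) of the
    input sequence; a merged call spans from its first window's start to
    its last window's end.
    """
    with open(path, "w") as fh:
        for c in calls:
            chrom_start = c.first_window - 1
            chrom_end = c.last_window - 1 + WINDOW_BP
            fh.write(
                f"{c.sequence_id}\t{chrom_start}\t{chrom_end}\t{c.label}\t0\t+\n"
            )
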