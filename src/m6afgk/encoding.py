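"""0/1 presence encoding of sequences over a mined feature set.

Each feature vector component j is the indicator c(S, P_j): 1 iff pattern
P_j occurs at least once (wildcards matching any base) in sequence S.
"Matches" is occurrence as a gapped substring, not whole-sequence equality:
mined patterns span at most 2k nucleotides and could never equal a full
51-nt window.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FeatureMismatchError
from .mining import FeatureSet, GappedKmerPattern, matches, present_pattern_keys
from .sequence_data import SampleRecord


def indicator(sequence: str, pattern: GappedKmerPattern) -> int:
    return 1 if matches(pattern, sequence) else 0


def encode(sequence: str, features: FeatureSet) -> np.ndarray:
    """Binary feature vector; dimension = |features| (possibly 0)."""
    vec = np.zeros(len(features), dtype=np.int8)
    if len(features) == 0:
        return vec
    by_layout = _layout_index(features)
    for (layout, chars) in present_pattern_keys(sequence, by_layout):
        col = by_layout[layout].get(chars)
        if col is not None:
            vec[col] = 1
    return vec


def _layout_index(features: FeatureSet) -> dict[tuple[int, ...], dict[str, int]]:
    """Group feature columns by gap layout for single-pass scanning."""
    index: dict[tuple[int, ...], dict[str, int]] = {}
    for col, pat in enumerate(features):
        layout = tuple(i for i, c in enumerate(pat.text) if c != "N")
        index.setdefault(layout, {})[
            "".join(pat.text[i] for i in layout)
        ] = col
    return index


def encode_corpus(records: Sequence[SampleRecord],
                  features: FeatureSet,
                  expected_dim: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (rows in input order) and aligned label vector."""
    if expected_dim is not None and expected_dim != len(features):
        raise FeatureMismatchError(
            f"feature set has {len(features)} patterns, expected {expected_dim}"
        )
    X = np.zeros((len(records), len(features)), dtype=np.int8)
    y = np.array([r.label for r in records], dtype=int)
    if len(features) == 0:
        return X, y
    by_layout = _layout_index(features)
    layouts = list(by_layout)
    for row, rec in enumerate(records):
        for (layout, chars) in present_pattern_keys(rec.sequence, layouts):
            col = by_layout[layout].get(chars)
            if col is not None:
                X[row, col] = 1
    return X, y


def write_design_matrix(records: Sequence[SampleRecord], X: np.ndarray,
                        features: FeatureSet, path: str | Path) -> None:
    """Dense TSV export: id, label, one 0/1 column per pattern."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\t" + "\t".join(p.text for p in features) + "\n")
        for rec, row in zip(records, X):
            fh.write(f"{rec.id}\t{rec.label}\t" + "\t".join(map(str, row)) + "\n")


def write_sparse_matrix(records: Sequence[SampleRecord], X: np.ndarray,
                        features: FeatureSet, path: str | Path) -> None:
    """Coordinate-format text export (row, col, 1) for large feature sets."""
    rows, cols = np.nonzero(X)
    with open(path, "w") as fh:
        fh.write(f"%rows={len(records)} cols={len(features)}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t1\n")
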