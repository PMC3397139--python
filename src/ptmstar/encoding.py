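"""Numeric encoding of sequence windows under an amino-acid index set.

A width-w window and a d-member index set give a w*d feature vector in
position-major layout: for each window position, the d index values of the
residue at that position.  By default each index is min-max scaled to [0,1]
over its 20 canonical values, so sigmoid-unit networks see bounded inputs;
the padding/ambiguity residue 'X' is encoded as the mean of an index's 20
(scaled) values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dataset import LabeledWindow
from .indices import IndexSet
from .io_formats import ALPHABET, AMINO_ACIDS

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


def encoding_table(index_set: IndexSet, scaling: bool = True) -> np.ndarray:
    """Lookup table of shape (21, d): one row per alphabet letter
    (A..Y then X), one column per index-set member.

    With ``scaling`` each column is min-max scaled to [0,1] over the 20
    amino-acid values (a constant index maps to 0.5 everywhere).  The 'X'
    row is the column mean over the 20 amino acids.
    """
    d = index_set.dimension
    table = np.empty((len(ALPHABET), d), dtype=float)
    for j, idx in enumerate(index_set.members):
        col = np.array([idx.values[aa] for aa in AMINO_ACIDS], dtype=float)
        if scaling:
            lo, hi = col.min(), col.max()
            col = np.full_like(col, 0.5) if hi == lo else (col - lo) / (hi - lo)
        table[: len(AMINO_ACIDS), j] = col
        table[_CODE["X"], j] = col.mean()
    return table


def encode_window(
    residues: str,
    index_set: IndexSet,
    scaling: bool = True,
    table: np.ndarray | None = None,
) -> np.ndarray:
    """Encode one window as a flat vector of length ``len(residues) * d``.

    Layout is position-major: coordinates (p*d)..((p+1)*d - 1) hold the d
    index values of the residue at 0-based position p.
    """
    if table is None:
        table = encoding_table(index_set, scaling)
    codes = np.array([_CODE[ch] for ch in residues], dtype=np.intp)
    return table[codes].reshape(-1)


def encode_dataset(
    windows: Sequence[LabeledWindow],
    index_set: IndexSet,
    scaling: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode labelled windows into a feature matrix and a 0/1 label vector.

    Row order follows the input; returns (n, w*d) floats and (n,) ints.
    An empty input yields an empty (0, w*d-compatible) matrix.
    """
    table = encoding_table(index_set, scaling)
    if not windows:
        return np.empty((0, 0), dtype=float), np.empty((0,), dtype=int)
    codes = np.array(
        [[_CODE[ch] for ch in w.residues] for w in windows], dtype=np.intp
    )
    x = table[codes].reshape(len(windows), -1)
    y = np.array([w.label for w in windows], dtype=int)
    return x, y
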