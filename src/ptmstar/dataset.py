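"""Window extraction, labelling and train/test splitting for one PTM type.

A protein is dissected into overlapping 9-residue windows, one centred on
every position (termini padded with 'X').  Windows centred on annotated
sites of the PTM type under study are positives; windows centred on an
unannotated residue of a modifiable type form the negative pool.  Exact
duplicate 9-mers are removed, positives are split 67/33 into train/test,
and negatives are then drawn at a 1:5 positive:negative ratio per split so
the class balance is exact in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ProteinRecord, SiteAnnotation

logger = logging.getLogger(__name__)

POSITIVE = 1
NEGATIVE = 0

DEFAULT_WIDTH = 9


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-width sequence window with a binary label for one PTM type."""

    protein_id: str
    center_position: int  # 1-based position of the window centre
    residues: str
    label: int  # POSITIVE (1) or NEGATIVE (0)
    ptm_type: str

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0:
            raise ValueError("window width must be odd")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def center_residue(self) -> str:
        return self.residues[len(self.residues) // 2]


@dataclass(frozen=True)
class DatasetSplit:
    """A train/test split with an exact negatives-per-positive ratio."""

    train: tuple[LabeledWindow, ...]
    test: tuple[LabeledWindow, ...]
    seed: int
    ratio: int
    train_fraction: float

    def counts(self) -> dict[str, int]:
        return {
            "train_pos": sum(w.label == POSITIVE for w in self.train),
            "train_neg": sum(w.label == NEGATIVE for w in self.train),
            "test_pos": sum(w.label == POSITIVE for w in self.test),
            "test_neg": sum(w.label == NEGATIVE for w in self.test),
        }


def extract_windows(
    protein: ProteinRecord, width: int = DEFAULT_WIDTH
) -> list[tuple[int, str]]:
    """All width-residue windows of a protein, one per position.

    Returns ``(center_position, residues)`` pairs with 1-based centres
    1..L; positions within (width-1)/2 of a terminus are padded with 'X'.
    """
    if width < 3 or width % 2 == 0:
        raise ValueError(f"width must be odd and >= 3, got {width}")
    half = width // 2
    padded = "X" * half + protein.sequence + "X" * half
    return [
        (pos, padded[pos - 1 : pos - 1 + width])
        for pos in range(1, len(protein.sequence) + 1)
    ]


def build_labeled_windows(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    ptm_type: str,
    target_residues: set[str] | None = None,
    width: int = DEFAULT_WIDTH,
) -> tuple[list[LabeledWindow], list[LabeledWindow]]:
    """Label windows for one PTM type: (positives, negative_pool).

    Positives are the windows centred on annotated positions of
    ``ptm_type``.  The negative pool holds windows whose centre residue is
    in ``target_residues`` (default: the residue types observed at the
    positive centres) and whose centre carries no annotation of any PTM
    type.  Exact duplicate 9-mers are removed from both sets (first
    occurrence kept) and any 9-mer that occurs among positives is excluded
    from the pool.
    """
    by_id = {p.id: p for p in proteins}
    for ann in annotations:
        if ann.protein_id not in by_id:
            raise KeyError(f"annotation references unknown protein {ann.protein_id!r}")
        if ann.position > len(by_id[ann.protein_id]):
            raise ValueError(
                f"annotation {ann.protein_id}:{ann.position} beyond sequence "
                f"length {len(by_id[ann.protein_id])}"
            )

    annotated_any = {(a.protein_id, a.position) for a in annotations}
    positive_sites = [
        (a.protein_id, a.position) for a in annotations if a.ptm_type == ptm_type
    ]

    windows_by_protein = {p.id: dict(extract_windows(p, width)) for p in proteins}

    positives: list[LabeledWindow] = []
    seen_pos: set[str] = set()
    observed_centers: set[str] = set()
    for pid, pos in positive_sites:
        residues = windows_by_protein[pid][pos]
        observed_centers.add(residues[width // 2])
        if residues in seen_pos:
            continue
        seen_pos.add(residues)
        positives.append(
            LabeledWindow(pid, pos, residues, POSITIVE, ptm_type)
        )

    if target_residues is None:
        target_residues = observed_centers
    off_target = [
        w for w in positives if w.center_residue not in target_residues
    ]
    if off_target:
        logger.warning(
            "%d positive window(s) centred outside target residues %s; kept",
            len(off_target), sorted(target_residues),
        )

    pool: list[LabeledWindow] = []
    seen_neg: set[str] = set()
    for protein in proteins:
        for pos, residues in windows_by_protein[protein.id].items():
            if residues[width // 2] not in target_residues:
                continue
            if (protein.id, pos) in annotated_any:
                continue
            if residues in seen_pos or residues in seen_neg:
                continue
            seen_neg.add(residues)
            pool.append(
                LabeledWindow(protein.id, pos, residues, NEGATIVE, ptm_type)
            )
    return positives, pool


def split_dataset(
    positives: Sequence[LabeledWindow],
    negative_pool: Sequence[LabeledWindow],
    ratio: int = 5,
    train_fraction: float = 0.67,
    seed: int = 0,
) -> DatasetSplit:
    """Split positives train/test and sample negatives at an exact ratio.

    ``round(train_fraction * n_positives)`` positives (round half up) go to
    the training set, the rest to test.  Negatives are drawn uniformly
    without replacement from the pool: ``ratio`` per train positive and per
    test positive, so both splits have the exact 1:ratio class balance.
    Deterministic given ``seed``.
    """
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("no positive windows to split")
    n_train_pos = int(np.floor(train_fraction * n_pos + 0.5))  # round half up
    n_test_pos = n_pos - n_train_pos
    n_train_neg = ratio * n_train_pos
    n_test_neg = ratio * n_test_pos
    needed = n_train_neg + n_test_neg
    if len(negative_pool) < needed:
        raise ValueError(
            f"insufficient negatives: need {needed} "
            f"({ratio} per positive), pool has {len(negative_pool)}"
        )

    rng = np.random.default_rng(seed)
    pos_order = rng.permutation(n_pos)
    train_pos = [positives[i] for i in pos_order[:n_train_pos]]
    test_pos = [positives[i] for i in pos_order[n_train_pos:]]

    neg_idx = rng.choice(len(negative_pool), size=needed, replace=False)
    train_neg = [negative_pool[i] for i in neg_idx[:n_train_neg]]
    test_neg = [negative_pool[i] for i in neg_idx[n_train_neg:]]

    return DatasetSplit(
        train=tuple(train_pos + train_neg),
        test=tuple(test_pos + test_neg),
        seed=seed,
        ratio=ratio,
        train_fraction=train_fraction,
    )
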