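"""n-star voting consensus over families of A/R/P-optimised networks.

An ensemble of N networks votes on each candidate window; the vote sum S_p
(0..N) grades the prediction, and a site is called positive "with n-star
quality" when at least n members vote positive (so an S_p of m makes every
n <= m true and (m+1)-star false).  Six schemes are built from the trained
families:

* C10 — the 10 AUC-optimised networks of one feature set (hidden sizes
  2..20);
* C20 — those plus the 10 recall-optimised networks;
* C30 — all 30 A/R/P networks of one feature set;
* C3  — the best A, R and P network of one feature set, each chosen by
  maximum evaluation AUC (the MAT selector);
* C9  — the C3 triple for each of the three HQI feature sets;
* C12 — the C9 members plus the triple of a fourth (legacy 10-index)
  feature set.

A per-PTM meta-consensus then keeps whichever scheme scores the highest
consensus AUC on the evaluation split.  Consensus AUC treats S_p/N as a
graded score with tie-aware (Mann-Whitney) AUC; the vote fraction S_p/N is
reported as a confidence, which is a vote share, not a calibrated
probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import metrics
from .dataset import LabeledWindow
from .encoding import encode_dataset, encode_window
from .indices import IndexSet
from .mlp import MLPModel, forward

#: the six canonical schemes and their ensemble sizes
SCHEME_SIZES = {"C10": 10, "C20": 20, "C30": 30, "C3": 3, "C9": 9, "C12": 12}
#: fixed tie-break order for the meta-consensus (first wins ties)
META_TIE_ORDER = ("C12", "C30", "C20", "C10", "C9", "C3")
_OBJECTIVE_RANK = {"A": 0, "R": 1, "P": 2}
_HIDDEN_SIZES = tuple(range(2, 21, 2))


@dataclass(frozen=True)
class StarResult:
    """Vote outcome for one window: S_p votes out of N members."""

    s_p: int
    n_members: int
    votes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.s_p <= self.n_members:
            raise ValueError(f"S_p={self.s_p} outside 0..{self.n_members}")

    @property
    def star(self) -> int:
        return self.s_p

    @property
    def confidence(self) -> float:
        return self.s_p / self.n_members

    def positive_at(self, n: int) -> bool:
        """n-star decision: positive iff at least n members voted positive."""
        if not 1 <= n <= self.n_members:
            raise ValueError(f"n must be in 1..{self.n_members}, got {n}")
        return n <= self.s_p


@dataclass(frozen=True)
class ConsensusEnsemble:
    """An ordered set of member networks under one scheme id."""

    scheme_id: str
    members: tuple[MLPModel, ...]

    def __post_init__(self) -> None:
        expected = SCHEME_SIZES.get(self.scheme_id)
        if expected is not None and len(self.members) != expected:
            raise ValueError(
                f"scheme {self.scheme_id} needs {expected} members, "
                f"got {len(self.members)}"
            )

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def feature_set_ids(self) -> tuple[str, ...]:
        return tuple(m.feature_set_id or "" for m in self.members)


@dataclass(frozen=True)
class SchemeEvaluation:
    """Per-n recall/precision plus the consensus AUC of one ensemble.

    ``auc`` grades windows by the vote count S_p (tie-aware); this is the
    score the star semantics are built on.  ``mean_score_auc`` instead
    grades by the mean of the members' continuous outputs, which keeps each
    network's ranking information: binarised votes discard it, so near the
    performance ceiling the vote-count AUC can sit slightly below a single
    network's, while the averaged score does not.
    """

    scheme_id: str
    per_n: dict[int, metrics.EvalResult]
    auc: float
    mean_score_auc: float


def binary_vote(
    model: MLPModel, x: np.ndarray, feature_set_id: str | None = None
) -> int:
    """One member's vote: 1 iff the network score reaches its threshold.

    A score exactly at the threshold counts as positive (>= convention).
    If ``feature_set_id`` names the encoding actually used, it must match
    the model's feature set.
    """
    if (
        feature_set_id is not None
        and model.feature_set_id is not None
        and feature_set_id != model.feature_set_id
    ):
        raise ValueError(
            f"feature-set mismatch: vector encoded with {feature_set_id!r}, "
            f"model trained on {model.feature_set_id!r}"
        )
    return int(forward(model, x) >= model.threshold)


def mat_select(
    models: Sequence[MLPModel], eval_x: np.ndarray, eval_y: np.ndarray
) -> MLPModel:
    """Max-AUC-over-evaluation-data (MAT): the member with the highest
    evaluation AUC.  Ties go to the smaller hidden size, then to objective
    order A < R < P."""
    if not models:
        raise ValueError("mat_select needs at least one model")
    best_key: tuple[float, int, int] | None = None
    best: MLPModel | None = None
    for m in models:
        a = metrics.auc(forward(m, eval_x), eval_y)
        key = (
            -a,
            m.hidden_k,
            _OBJECTIVE_RANK.get(m.objective_tag or "A", 0),
        )
        if best_key is None or key < best_key:
            best_key, best = key, m
    assert best is not None
    return best


def _family_models(
    family: Mapping[tuple[str, int], MLPModel], objective: str
) -> list[MLPModel]:
    models = [
        family[(objective, k)] for k in _HIDDEN_SIZES
        if (objective, k) in family
    ]
    if len(models) != len(_HIDDEN_SIZES):
        raise ValueError(
            f"family is missing {objective}-models: have hidden sizes "
            f"{sorted(k for o, k in family if o == objective)}"
        )
    return models


def _mat_triple(
    family: Mapping[tuple[str, int], MLPModel],
    eval_x: np.ndarray,
    eval_y: np.ndarray,
) -> list[MLPModel]:
    return [
        mat_select(_family_models(family, obj), eval_x, eval_y)
        for obj in ("A", "R", "P")
    ]


def build_ensemble(
    scheme_id: str,
    families: Mapping[str, Mapping[tuple[str, int], MLPModel]],
    eval_data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    feature_set: str | None = None,
) -> ConsensusEnsemble:
    """Assemble one of the six consensus schemes from trained families.

    ``families`` maps feature-set id -> train_family output; ``eval_data``
    maps feature-set id -> (encoded eval matrix, labels) and is used by the
    MAT selector.  Single-family schemes (C10/C20/C30/C3) take the sole
    family or the one named by ``feature_set``; C9 uses the first three
    families in mapping order and C12 the first four.  Member order is
    deterministic: hidden size ascending within objective, objectives A, R,
    P, feature sets in mapping order.
    """
    if scheme_id not in SCHEME_SIZES:
        raise ValueError(f"unknown scheme {scheme_id!r}")

    def eval_for(fs: str) -> tuple[np.ndarray, np.ndarray]:
        if fs not in eval_data:
            raise ValueError(
                f"scheme {scheme_id}: no evaluation data for feature set {fs!r}"
            )
        return eval_data[fs]

    if scheme_id in ("C10", "C20", "C30", "C3"):
        if feature_set is None:
            if len(families) != 1:
                raise ValueError(
                    f"scheme {scheme_id} needs feature_set= when several "
                    f"families are supplied ({sorted(families)})"
                )
            feature_set = next(iter(families))
        if feature_set not in families:
            raise ValueError(
                f"scheme {scheme_id}: missing family for feature set "
                f"{feature_set!r}"
            )
        family = families[feature_set]
        if scheme_id == "C3":
            ex, ey = eval_for(feature_set)
            members = _mat_triple(family, ex, ey)
        else:
            objectives = {"C10": "A", "C20": "AR", "C30": "ARP"}[scheme_id]
            members = [
                m for obj in objectives for m in _family_models(family, obj)
            ]
        return ConsensusEnsemble(scheme_id, tuple(members))

    n_needed = {"C9": 3, "C12": 4}[scheme_id]
    if len(families) < n_needed:
        raise ValueError(
            f"scheme {scheme_id} needs {n_needed} feature-set families, "
            f"got {len(families)} ({sorted(families)})"
        )
    members = []
    for fs in list(families)[:n_needed]:
        ex, ey = eval_for(fs)
        members.extend(_mat_triple(families[fs], ex, ey))
    return ConsensusEnsemble(scheme_id, tuple(members))


def consensus_score(
    ensemble: ConsensusEnsemble,
    window: LabeledWindow,
    encoders: Mapping[str, IndexSet],
    scaling: bool = True,
) -> StarResult:
    """Vote an ensemble on one window, encoding per member feature set."""
    votes = []
    cache: dict[str, np.ndarray] = {}
    for m in ensemble.members:
        fs = m.feature_set_id or ""
        if fs not in cache:
            if fs not in encoders:
                raise ValueError(f"no encoder (index set) for feature set {fs!r}")
            cache[fs] = encode_window(window.residues, encoders[fs], scaling)
        votes.append(binary_vote(m, cache[fs], feature_set_id=fs))
    return StarResult(
        s_p=int(sum(votes)), n_members=ensemble.n_members, votes=tuple(votes)
    )


def score_matrix(
    ensemble: ConsensusEnsemble,
    windows: Sequence[LabeledWindow],
    encoders: Mapping[str, IndexSet],
    scaling: bool = True,
) -> np.ndarray:
    """(n_windows, N) matrix of continuous member scores, vectorised per
    feature set."""
    encoded: dict[str, np.ndarray] = {}
    for fs in set(ensemble.feature_set_ids):
        if fs not in encoders:
            raise ValueError(f"no encoder (index set) for feature set {fs!r}")
        encoded[fs], _ = encode_dataset(windows, encoders[fs], scaling)
    scores = np.empty((len(windows), ensemble.n_members), dtype=float)
    for j, m in enumerate(ensemble.members):
        scores[:, j] = np.asarray(forward(m, encoded[m.feature_set_id or ""]))
    return scores


def vote_matrix(
    ensemble: ConsensusEnsemble,
    windows: Sequence[LabeledWindow],
    encoders: Mapping[str, IndexSet],
    scaling: bool = True,
) -> np.ndarray:
    """(n_windows, N) binary vote matrix (score >= member threshold)."""
    scores = score_matrix(ensemble, windows, encoders, scaling)
    thresholds = np.array([m.threshold for m in ensemble.members])
    return (scores >= thresholds).astype(int)


def evaluate_scheme(
    ensemble: ConsensusEnsemble,
    test_windows: Sequence[LabeledWindow],
    encoders: Mapping[str, IndexSet],
    scaling: bool = True,
) -> SchemeEvaluation:
    """Recall/precision of the n-star decision for every n, plus the
    consensus AUC of the graded score S_p/N."""
    labels = np.array([w.label for w in test_windows], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation windows must contain both classes")
    scores = score_matrix(ensemble, test_windows, encoders, scaling)
    thresholds = np.array([m.threshold for m in ensemble.members])
    votes = (scores >= thresholds).astype(int)
    s_p = votes.sum(axis=1)
    n_members = ensemble.n_members
    consensus_auc = metrics.auc(s_p / n_members, labels)
    mean_score_auc = metrics.auc(scores.mean(axis=1), labels)
    per_n: dict[int, metrics.EvalResult] = {}
    for n in range(1, n_members + 1):
        pred = (s_p >= n).astype(int)
        per_n[n] = metrics.EvalResult(
            auc=consensus_auc,
            recall=metrics.recall(pred, labels),
            precision=metrics.precision(pred, labels),
            n_pos=int((labels == 1).sum()),
            n_neg=int((labels == 0).sum()),
        )
    return SchemeEvaluation(
        scheme_id=ensemble.scheme_id, per_n=per_n, auc=consensus_auc,
        mean_score_auc=mean_score_auc,
    )


def meta_consensus(
    schemes: Mapping[str, ConsensusEnsemble],
    eval_windows: Sequence[LabeledWindow],
    encoders: Mapping[str, IndexSet],
    scaling: bool = True,
) -> tuple[str, ConsensusEnsemble, dict[str, float]]:
    """Pick the scheme with the highest consensus AUC on the evaluation
    windows.  Ties are broken by the fixed order C12 > C30 > C20 > C10 >
    C9 > C3.  Returns (scheme_id, ensemble, per-scheme AUCs)."""
    if not schemes:
        raise ValueError("meta_consensus needs at least one scheme")
    aucs = {
        sid: evaluate_scheme(ens, eval_windows, encoders, scaling).auc
        for sid, ens in schemes.items()
    }

    def rank(sid: str) -> int:
        return (
            META_TIE_ORDER.index(sid)
            if sid in META_TIE_ORDER
            else len(META_TIE_ORDER)
        )

    best = min(schemes, key=lambda sid: (-aucs[sid], rank(sid)))
    return best, schemes[best], aucs
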