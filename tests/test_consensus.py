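"""n-star consensus: votes, scheme assembly, star semantics, evaluation and
the per-PTM meta-consensus."""

from itertools import product

import numpy as np
import pytest

from ptmstar import consensus, metrics
from ptmstar.consensus import (
    ConsensusEnsemble,
    StarResult,
    binary_vote,
    build_ensemble,
    consensus_score,
    evaluate_scheme,
    mat_select,
    meta_consensus,
)
from ptmstar.dataset import LabeledWindow
from ptmstar.indices import IndexSet
from ptmstar.io_formats import AMINO_ACIDS, AminoAcidIndex
from ptmstar.mlp import MLPModel, forward

from conftest import make_constant_model


@pytest.fixture(scope="module")
def center_detector_setup():
    """A d=1 'is serine' index plus networks keyed on the window centre,
    giving members that are always correct on S-vs-T-centred windows."""
    values = {aa: (1.0 if aa == "S" else 0.0) for aa in AMINO_ACIDS}
    index_set = IndexSet(
        "S-FLAG", (AminoAcidIndex("SFLAG00101", "serine flag", values),)
    )

    def detector():
        # coordinate 4 (the centre, position-major d=1) drives the output
        w1 = np.zeros((1, 9))
        w1[0, 4] = 30.0
        return MLPModel(
            w1=w1, b1=np.array([-15.0]), w2=np.array([30.0]), b2=-15.0,
            feature_set_id="S-FLAG",
        )

    windows = [
        LabeledWindow("P1", 5, "AAAASAAAA", 1, "PTM"),
        LabeledWindow("P1", 9, "RKLWSTPGH", 1, "PTM"),
        LabeledWindow("P2", 5, "AAAATAAAA", 0, "PTM"),
        LabeledWindow("P2", 9, "RKLWTSPGH", 0, "PTM"),
    ]
    return index_set, detector, windows


@pytest.fixture(scope="module")
def recovery_schemes(recovery_family):
    """The four single-feature-set schemes built from the trained family."""
    fs = recovery_family["index_set"].name
    families = {fs: recovery_family["family"]}
    eval_data = {fs: recovery_family["test"]}
    return {
        sid: build_ensemble(sid, families, eval_data)
        for sid in ("C10", "C20", "C30", "C3")
    }


# ---------------------------------------------------------------------------
# votes and star semantics


def test_binary_vote_thresholding():
    x = np.zeros(9)
    assert binary_vote(make_constant_model(True), x) == 1
    assert binary_vote(make_constant_model(False), x) == 0


def test_score_exactly_at_threshold_votes_positive():
    model = MLPModel(  # all-zero network scores exactly 0.5 = threshold
        w1=np.zeros((1, 9)), b1=np.zeros(1), w2=np.zeros(1), b2=0.0
    )
    assert forward(model, np.zeros(9)) == 0.5
    assert binary_vote(model, np.zeros(9)) == 1


def test_binary_vote_feature_set_mismatch():
    model = make_constant_model(True, feature_set_id="HQI-8")
    with pytest.raises(ValueError, match="feature-set mismatch"):
        binary_vote(model, np.zeros(9), feature_set_id="HQI-24")


def test_star_result_semantics():
    result = StarResult(s_p=7, n_members=10, votes=(1,) * 7 + (0,) * 3)
    assert result.star == 7
    assert result.confidence == 0.7
    assert result.positive_at(7) and not result.positive_at(8)
    with pytest.raises(ValueError):
        StarResult(s_p=11, n_members=10, votes=())


def test_star_monotonicity_exhaustive():
    """positive_at(n) implies positive_at(n-1) for every vote vector."""
    for n_members in (3, 10):
        for votes in product((0, 1), repeat=n_members):
            result = StarResult(
                s_p=sum(votes), n_members=n_members, votes=votes
            )
            for n in range(2, n_members + 1):
                assert (not result.positive_at(n)) or result.positive_at(n - 1)


# ---------------------------------------------------------------------------
# MAT selection


def test_mat_select_single_model(recovery_family):
    model = recovery_family["family"][("A", 2)]
    test_x, test_y = recovery_family["test"]
    assert mat_select([model], test_x, test_y) is model


def test_mat_select_is_argmax(recovery_family):
    test_x, test_y = recovery_family["test"]
    models = [recovery_family["family"][("A", k)] for k in range(2, 21, 2)]
    best = mat_select(models, test_x, test_y)
    aucs = [metrics.auc(forward(m, test_x), test_y) for m in models]
    assert metrics.auc(forward(best, test_x), test_y) == max(aucs)


def test_mat_select_tie_breaks_by_hidden_size_then_objective():
    x = np.zeros((4, 9))
    y = np.array([0, 1, 0, 1])
    tied = [
        make_constant_model(True, hidden_k=4, objective_tag="A"),
        make_constant_model(True, hidden_k=2, objective_tag="P"),
        make_constant_model(True, hidden_k=2, objective_tag="R"),
    ]
    assert mat_select(tied, x, y).hidden_k == 2
    assert mat_select(tied, x, y).objective_tag == "R"


# ---------------------------------------------------------------------------
# scheme assembly


@pytest.mark.parametrize(
    "scheme_id, expected_n", [("C10", 10), ("C20", 20), ("C30", 30), ("C3", 3)]
)
def test_single_family_scheme_sizes(tiny_families, scheme_id, expected_n):
    families, eval_data = tiny_families
    hqi8_only = {"HQI-8": families["HQI-8"]}
    ensemble = build_ensemble(
        scheme_id, hqi8_only, {"HQI-8": eval_data["HQI-8"]}
    )
    assert ensemble.n_members == expected_n


def test_c10_uses_only_auc_models(tiny_families):
    families, eval_data = tiny_families
    ensemble = build_ensemble(
        "C10", {"HQI-8": families["HQI-8"]}, {"HQI-8": eval_data["HQI-8"]}
    )
    assert all(m.objective_tag == "A" for m in ensemble.members)
    assert [m.hidden_k for m in ensemble.members] == list(range(2, 21, 2))


def test_c9_and_c12_cross_feature_schemes(tiny_families):
    families, eval_data = tiny_families
    hqi_only = {
        fs: families[fs] for fs in ("HQI-8", "HQI-24", "HQI-40")
    }
    c9 = build_ensemble("C9", hqi_only, eval_data)
    assert c9.n_members == 9
    assert set(c9.feature_set_ids) == {"HQI-8", "HQI-24", "HQI-40"}
    c12 = build_ensemble("C12", families, eval_data)
    assert c12.n_members == 12
    assert set(c12.feature_set_ids) == set(families)
    # each feature set contributes one A, one R and one P network
    for fs in families:
        tags = sorted(
            m.objective_tag for m in c12.members if m.feature_set_id == fs
        )
        assert tags == ["A", "P", "R"]


def test_missing_family_errors_name_the_scheme(tiny_families):
    families, eval_data = tiny_families
    hqi_only = {fs: families[fs] for fs in ("HQI-8", "HQI-24", "HQI-40")}
    with pytest.raises(ValueError, match="C12"):
        build_ensemble("C12", hqi_only, eval_data)
    with pytest.raises(ValueError, match="C30.*HQI-24"):
        build_ensemble(
            "C30", {"HQI-8": families["HQI-8"]},
            {"HQI-8": eval_data["HQI-8"]}, feature_set="HQI-24",
        )


def test_ensemble_size_is_validated():
    with pytest.raises(ValueError, match="needs 3 members"):
        ConsensusEnsemble("C3", (make_constant_model(True),))


# ---------------------------------------------------------------------------
# scoring


def test_unanimous_and_single_vote_scoring(center_detector_setup):
    index_set, _, windows = center_detector_setup
    encoders = {"S-FLAG": index_set}
    members = tuple(
        make_constant_model(v, feature_set_id="S-FLAG") for v in (True,) * 3
    )
    result = consensus_score(
        ConsensusEnsemble("C3", members), windows[0], encoders
    )
    assert result.s_p == 3 and all(result.positive_at(n) for n in (1, 2, 3))

    one_vote = tuple(
        make_constant_model(v, feature_set_id="S-FLAG")
        for v in (True, False, False)
    )
    result = consensus_score(
        ConsensusEnsemble("C3", one_vote), windows[0], encoders
    )
    assert result.s_p == 1
    assert result.positive_at(1)
    assert not result.positive_at(2)


def test_sp30_decomposes_into_objective_family_sums(
    recovery_schemes, recovery_family, recovery_data
):
    """The C30 vote sum is the sum of its A, R and P blocks."""
    c30 = recovery_schemes["C30"]
    encoders = {recovery_family["index_set"].name: recovery_family["index_set"]}
    windows = recovery_data["split"].test[:200]
    votes = consensus.vote_matrix(c30, windows, encoders)
    s_p = votes.sum(axis=1)
    blocks = [votes[:, i : i + 10].sum(axis=1) for i in (0, 10, 20)]
    np.testing.assert_array_equal(s_p, blocks[0] + blocks[1] + blocks[2])
    # the A block is exactly the C10 ensemble's vote sum
    c10_votes = consensus.vote_matrix(recovery_schemes["C10"], windows, encoders)
    np.testing.assert_array_equal(blocks[0], c10_votes.sum(axis=1))


# ---------------------------------------------------------------------------
# evaluation


def test_always_correct_ensemble_scores_perfectly(center_detector_setup):
    index_set, detector, windows = center_detector_setup
    members = tuple(detector() for _ in range(3))
    evaluation = evaluate_scheme(
        ConsensusEnsemble("C3", members), windows, {"S-FLAG": index_set}
    )
    assert evaluation.auc == 1.0
    for result in evaluation.per_n.values():
        assert result.recall == 1.0 and result.precision == 1.0


def test_scheme_evaluation_properties(
    recovery_schemes, recovery_family, recovery_data
):
    encoders = {recovery_family["index_set"].name: recovery_family["index_set"]}
    windows = recovery_data["split"].test
    evaluation = evaluate_scheme(recovery_schemes["C30"], windows, encoders)
    recalls = [evaluation.per_n[n].recall for n in range(1, 31)]
    assert all(a >= b for a, b in zip(recalls, recalls[1:]))
    # AUC from the vote fraction equals AUC from the raw vote sum
    votes = consensus.vote_matrix(recovery_schemes["C30"], windows, encoders)
    labels = np.array([w.label for w in windows])
    assert evaluation.auc == pytest.approx(
        metrics.auc(votes.sum(axis=1), labels)
    )


def test_averaged_ensemble_retains_single_network_quality(
    recovery_schemes, recovery_family, recovery_data
):
    """The graded (mean-score) C30 ensemble is at least as good as the
    average of its members, the assertable form of consensus retaining
    single-network prediction quality."""
    encoders = {recovery_family["index_set"].name: recovery_family["index_set"]}
    evaluation = evaluate_scheme(
        recovery_schemes["C30"], recovery_data["split"].test, encoders
    )
    test_x, test_y = recovery_family["test"]
    single_aucs = [
        metrics.auc(forward(m, test_x), test_y)
        for m in recovery_schemes["C30"].members
    ]
    assert evaluation.mean_score_auc >= np.mean(single_aucs)


# ---------------------------------------------------------------------------
# meta-consensus


def test_meta_consensus_single_scheme(
    recovery_schemes, recovery_family, recovery_data
):
    encoders = {recovery_family["index_set"].name: recovery_family["index_set"]}
    best_id, best, _ = meta_consensus(
        {"C30": recovery_schemes["C30"]}, recovery_data["split"].test, encoders
    )
    assert best_id == "C30" and best is recovery_schemes["C30"]


def test_meta_consensus_is_argmax(
    recovery_schemes, recovery_family, recovery_data
):
    """The chosen scheme's evaluation AUC is maximal over all candidates
    (checked against an exhaustive loop)."""
    encoders = {recovery_family["index_set"].name: recovery_family["index_set"]}
    windows = recovery_data["split"].test
    best_id, _, aucs = meta_consensus(recovery_schemes, windows, encoders)
    exhaustive = {
        sid: evaluate_scheme(ens, windows, encoders).auc
        for sid, ens in recovery_schemes.items()
    }
    assert aucs == exhaustive
    assert exhaustive[best_id] == max(exhaustive.values())
    assert len(aucs) == 4


def test_meta_consensus_tie_break_order(center_detector_setup):
    index_set, _, windows = center_detector_setup
    encoders = {"S-FLAG": index_set}
    # constant voters -> every scheme has AUC 0.5; order decides
    c3 = ConsensusEnsemble(
        "C3", tuple(make_constant_model(True, feature_set_id="S-FLAG")
                    for _ in range(3))
    )
    c9 = ConsensusEnsemble(
        "C9", tuple(make_constant_model(True, feature_set_id="S-FLAG")
                    for _ in range(9))
    )
    best_id, _, _ = meta_consensus({"C3": c3, "C9": c9}, windows, encoders)
    assert best_id == "C9"  # C9 outranks C3 in the fixed tie order
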