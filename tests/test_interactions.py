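"""Ligand-receptor pair scoring, filtering, normalization, shift tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

import splicemut as sm
from splicemut.interactions import (EmptyLRIntersectionError,
                                    aggregate_by_condition, read_lr_table)


def _adata(X, donor, cell_type, genes=None):
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = genes or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame({"donor": donor, "cell_type": cell_type},
                       index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs,
                      var=pd.DataFrame(index=genes))


def _lr(pairs):
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])


def test_hand_computed_products():
    """Sender expresses (2,3), receiver (4,5) -> LR scores (8,15)."""
    X = [[2, 3, 0, 0], [0, 0, 4, 5]]
    adata = _adata(X, ["d"] * 2, ["S", "R"], genes=["L1", "L2", "R1", "R2"])
    pi = sm.lr_scores(adata, _lr([("L1", "R1"), ("L2", "R2")]), ["S"], ["R"])
    assert pi.scores.shape == (1, 2)
    np.testing.assert_allclose(pi.scores[0], [8.0, 15.0])


def test_zero_ligand_gives_zero_score():
    X = [[0, 7], [5, 3]]
    adata = _adata(X, ["d"] * 2, ["S", "R"], genes=["L", "R"])
    pi = sm.lr_scores(adata, _lr([("L", "R")]), ["S"], ["R"])
    assert pi.scores[0, 0] == 0.0
    assert pi.n_nonzero[0] == 0


def test_scores_match_nested_loop_oracle():
    rng = np.random.default_rng(0)
    n, g = 20, 8
    X = rng.random((n, g)) * (rng.random((n, g)) > 0.3)
    donor = rng.choice(["d1", "d2"], n)
    ctype = rng.choice(["S", "R"], n)
    adata = _adata(X, donor, ctype)
    lr = _lr([("g0", "g4"), ("g1", "g5"), ("g2", "g6")])
    pi = sm.lr_scores(adata, lr, ["S"], ["R"])
    seen = set()
    for k in range(len(pi.pairs)):
        s = int(pi.pairs.loc[k, "sender_cell"][1:])
        r = int(pi.pairs.loc[k, "receiver_cell"][1:])
        assert donor[s] == donor[r]
        seen.add((s, r))
        for e, (lig, rec) in enumerate([("g0", "g4"), ("g1", "g5"), ("g2", "g6")]):
            li, ri = int(lig[1:]), int(rec[1:])
            assert pi.scores[k, e] == pytest.approx(X[s, li] * X[r, ri], abs=1e-12)
    # exhaustive within-donor pairing
    expected_pairs = {
        (s, r) for s in range(n) for r in range(n)
        if donor[s] == donor[r] and ctype[s] == "S" and ctype[r] == "R"
    }
    assert seen == expected_pairs


def test_scores_scale_linearly_with_ligand_expression():
    X = np.array([[2.0, 0.0], [0.0, 3.0]])
    adata = _adata(X, ["d"] * 2, ["S", "R"], genes=["L", "R"])
    base = sm.lr_scores(adata, _lr([("L", "R")]), ["S"], ["R"]).scores[0, 0]
    adata2 = _adata(X * [5.0, 1.0], ["d"] * 2, ["S", "R"], genes=["L", "R"])
    scaled = sm.lr_scores(adata2, _lr([("L", "R")]), ["S"], ["R"]).scores[0, 0]
    assert scaled == pytest.approx(5 * base)


def test_missing_lr_pairs_dropped_and_empty_rejected():
    adata = _adata([[1.0]], ["d"], ["S"], genes=["gX"])
    with pytest.raises(EmptyLRIntersectionError):
        sm.lr_scores(adata, _lr([("A", "B")]), ["S"], ["S"])


def test_subsampling_respects_cap_and_seed():
    rng = np.random.default_rng(1)
    X = rng.random((30, 2))
    adata = _adata(X, ["d"] * 30, ["S"] * 15 + ["R"] * 15, genes=["L", "R"])
    lr = _lr([("L", "R")])
    a = sm.lr_scores(adata, lr, ["S"], ["R"], max_pairs_per_donor=40, seed=3)
    b = sm.lr_scores(adata, lr, ["S"], ["R"], max_pairs_per_donor=40, seed=3)
    assert len(a.pairs) == 40
    pd.testing.assert_frame_equal(a.pairs, b.pairs)


def test_min_interaction_filter_keeps_five_and_up():
    """Pairs with 3/4/5/6 nonzero LR scores: the default filter keeps
    exactly those with >= 5."""
    from splicemut.interactions import PairInteractions
    scores = np.zeros((4, 6))
    for i, k in enumerate([3, 4, 5, 6]):
        scores[i, :k] = 1.0
    pi = PairInteractions(
        pairs=pd.DataFrame({"sender_cell": list("abcd"),
                            "receiver_cell": list("wxyz"),
                            "donor": ["d"] * 4,
                            "sender_type": ["S"] * 4,
                            "receiver_type": ["R"] * 4}),
        scores=scores, lr_table=_lr([(f"L{i}", f"R{i}") for i in range(6)]))
    kept = sm.filter_min_interactions(pi)
    assert list(kept.pairs["sender_cell"]) == ["c", "d"]
    ident = sm.filter_min_interactions(pi, min_n=0)
    assert len(ident.pairs) == 4
    # retained set equals a direct count over the score vectors
    direct = [i for i in range(4) if (scores[i] > 0).sum() >= 5]
    assert list(kept.scores.sum(axis=1)) == [scores[i].sum() for i in direct]


def test_summary_counts_possible_pairs_per_donor():
    """2 senders x 3 receivers in one donor, all pairs retained ->
    normalized value 1."""
    rng = np.random.default_rng(2)
    X = np.abs(rng.random((5, 2))) + 0.5
    adata = _adata(X, ["d1"] * 5, ["S", "S", "R", "R", "R"], genes=["L", "R"])
    pi = sm.lr_scores(adata, _lr([("L", "R")]), ["S"], ["R"])
    kept = sm.filter_min_interactions(pi, min_n=1)
    summary = sm.summarize_interactions(kept, adata.obs)
    row = summary.iloc[0]
    assert row["n_possible"] == 6
    assert row["n_retained"] == 6
    assert row["normalized"] == pytest.approx(1.0)


def test_summary_matches_brute_force_grouping():
    rng = np.random.default_rng(3)
    n = 40
    X = rng.random((n, 4)) * (rng.random((n, 4)) > 0.4)
    donor = rng.choice(["d1", "d2", "d3"], n)
    ctype = rng.choice(["S", "R", "O"], n)
    adata = _adata(X, donor, ctype)
    lr = _lr([("g0", "g2"), ("g1", "g3")])
    pi = sm.lr_scores(adata, lr, ["S"], ["R"])
    kept = sm.filter_min_interactions(pi, min_n=1)
    summary = sm.summarize_interactions(kept, adata.obs).set_index(
        ["donor", "sender_type", "receiver_type"])
    for d in ["d1", "d2", "d3"]:
        n_s = int(((donor == d) & (ctype == "S")).sum())
        n_r = int(((donor == d) & (ctype == "R")).sum())
        retained = 0
        for i in np.flatnonzero((donor == d) & (ctype == "S")):
            for j in np.flatnonzero((donor == d) & (ctype == "R")):
                nz = sum(X[i, a] * X[j, b] > 0 for a, b in [(0, 2), (1, 3)])
                retained += nz >= 1
        if ("d", "S", "R") == (d, "S", "R") and (d, "S", "R") in summary.index:
            row = summary.loc[(d, "S", "R")]
            assert row["n_possible"] == n_s * n_r
            assert row["n_retained"] == retained


def test_zero_cell_denominator_is_missing():
    X = [[1.0, 1.0]]
    adata = _adata(X, ["d1"], ["S"], genes=["L", "R"])
    meta = pd.DataFrame({"donor": ["d1", "d2"], "cell_type": ["S", "S"]},
                        index=["c0", "c1"])
    from splicemut.interactions import PairInteractions
    pi = PairInteractions(
        pairs=pd.DataFrame({"sender_cell": ["c0"], "receiver_cell": ["c0"],
                            "donor": ["d1"], "sender_type": ["S"],
                            "receiver_type": ["R"]}),
        scores=np.ones((1, 1)), lr_table=_lr([("L", "R")]))
    summary = sm.summarize_interactions(pi, meta)
    d2 = summary[(summary["donor"] == "d2")]
    assert d2["normalized"].isna().all()


def test_equal_retained_fractions_give_unit_odds_ratio():
    summary = pd.DataFrame({
        "donor": ["d1", "d2"],
        "sender_type": ["S", "S"], "receiver_type": ["R", "R"],
        "n_retained": [20, 40], "n_possible": [100, 200],
        "normalized": [0.2, 0.2], "condition": ["A", "B"],
    })
    orr, p = sm.interaction_shift_test(summary, "S", "R", "A", "B")
    assert orr == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_shift_test_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(50):
        ret_a, ret_b = rng.integers(0, 8, 2)
        pos_a, pos_b = ret_a + rng.integers(1, 8), ret_b + rng.integers(1, 8)
        summary = pd.DataFrame({
            "donor": ["d1", "d2"],
            "sender_type": ["S", "S"], "receiver_type": ["R", "R"],
            "n_retained": [ret_a, ret_b], "n_possible": [pos_a, pos_b],
            "normalized": [0.0, 0.0], "condition": ["A", "B"],
        })
        orr, p = sm.interaction_shift_test(summary, "S", "R", "A", "B")
        expected = stats.fisher_exact(
            [[ret_a, pos_a - ret_a], [ret_b, pos_b - ret_b]])[1]
        assert p == pytest.approx(expected, abs=1e-12)


def test_condition_aggregation_is_ratio_of_sums():
    summary = pd.DataFrame({
        "donor": ["d1", "d2"], "sender_type": ["S", "S"],
        "receiver_type": ["R", "R"], "n_retained": [1, 3],
        "n_possible": [10, 10], "normalized": [0.1, 0.3],
        "condition": ["A", "A"],
    })
    agg = aggregate_by_condition(summary)
    assert agg.loc[0, "normalized"] == pytest.approx(0.2)


def test_mds_ligand_boost_detected_with_power():
    """When stromal ligand levels double in MDS, the sender-receiver
    shift test flags MDS over Control with OR > 1 at p < 0.05 in >= 90%
    of replicates."""
    hits = 0
    n_rep = 10
    for seed in range(n_rep):
        rng = np.random.default_rng(500 + seed)
        n_per = 40
        frames, Xs = [], []
        for donor, cond, boost in [("d1", "Control", 1.0), ("d2", "Control", 1.0),
                                   ("d3", "MDS", 2.0), ("d4", "MDS", 2.0)]:
            X = rng.poisson(0.5, size=(n_per, 6)).astype(float)
            half = n_per // 2
            # doubled ligand levels raise the rate, hence detection frequency
            X[:half, :3] = rng.poisson(0.5 * boost, size=(half, 3))
            Xs.append(X)
            frames.append(pd.DataFrame({
                "donor": [donor] * n_per,
                "cell_type": ["S"] * half + ["R"] * half}))
        obs = pd.concat(frames, ignore_index=True)
        obs.index = pd.Index([f"c{i}" for i in range(len(obs))])
        adata = ad.AnnData(X=sparse.csr_matrix(np.vstack(Xs)), obs=obs,
                           var=pd.DataFrame(index=[f"g{j}" for j in range(6)]))
        lr = _lr([("g0", "g3"), ("g1", "g4"), ("g2", "g5")])
        pi = sm.lr_scores(adata, lr, ["S"], ["R"])
        kept = sm.filter_min_interactions(pi, min_n=2)
        cond = pd.Series({"d1": "Control", "d2": "Control",
                          "d3": "MDS", "d4": "MDS"})
        summary = sm.summarize_interactions(kept, obs, condition_of_donor=cond)
        orr, p = sm.interaction_shift_test(summary, "S", "R", "MDS", "Control")
        if orr > 1 and p < 0.05:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_lr_table_reader_validates(tmp_path):
    path = tmp_path / "lr.tsv"
    pd.DataFrame({"ligand": ["L1", "L1"], "receptor": ["R1", "R1"],
                  "source": ["x", "y"]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_lr_table(path)
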