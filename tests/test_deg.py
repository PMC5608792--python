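"""Differential expression: moderated-t limits and oracles (including R limma),
BH step-up equivalence, DEG gating boundaries, enrichment arithmetic and the
superordinate rollup."""

import subprocess
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crestmig import deg
from crestmig import synthetic as syn


# --- moderated t -----------------------------------------------------------------


def test_d0_zero_equals_ordinary_paired_t():
    sim = syn.simulate_expression(500, 5, 10, 10, 1.2, 0.4, seed=1)
    res = deg.paired_moderated_t(sim.values, sim.design, d0_override=0.0)
    diffs = deg.paired_differences(sim.values, sim.design).to_numpy()
    t_ref = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(5))
    np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-10)


def test_d0_infinite_gives_common_variance_z_statistic():
    sim = syn.simulate_expression(500, 5, 0, 0, 0.0, 0.4, seed=2)
    res = deg.paired_moderated_t(sim.values, sim.design,
                                 d0_override=np.inf, s0_sq_override=0.16)
    diffs = deg.paired_differences(sim.values, sim.design).to_numpy()
    z_ref = diffs.mean(axis=1) / np.sqrt(0.16 / 5)
    np.testing.assert_allclose(res["t"].to_numpy(), z_ref, atol=1e-10)
    assert np.isinf(res["df_total"].iloc[0])


def test_identical_arms_give_zero_logfc_and_p_one():
    sim = syn.simulate_expression(100, 3, 0, 0, 0.0, 0.4, seed=3)
    for lot in ("lot1", "lot2", "lot3"):
        sim.values[f"{lot}_treated"] = sim.values[f"{lot}_control"]
    res = deg.paired_moderated_t(sim.values, sim.design)
    assert (res["logFC"] == 0).all()
    assert (res["p"] == 1.0).all()


def test_variance_prior_recovers_simulation_hyperparameters():
    sim = syn.simulate_expression(20000, 5, 0, 0, 0.0, 0.4, seed=4, d0=4.0)
    diffs = deg.paired_differences(sim.values, sim.design).to_numpy()
    params = deg.fit_variance_prior(diffs.var(axis=1, ddof=1), d=4)
    assert params.d0 == pytest.approx(4.0, rel=0.25)
    assert params.s0_sq == pytest.approx(0.16, rel=0.15)


def test_moderated_t_matches_r_limma(tmp_path):
    """Independent oracle: limma's eBayes on the same paired differences."""
    sim = syn.simulate_expression(400, 4, 10, 10, 1.2, 0.4, seed=7)
    res = deg.paired_moderated_t(sim.values, sim.design)
    diffs = deg.paired_differences(sim.values, sim.design)
    diffs_path = tmp_path / "diffs.tsv"
    diffs.to_csv(diffs_path, sep="\t")
    out_path = tmp_path / "limma.csv"
    script = tmp_path / "run.R"
    script.write_text(
        "suppressMessages(library(limma))\n"
        f'd <- as.matrix(read.delim("{diffs_path}", row.names=1))\n'
        "fit <- eBayes(lmFit(d, design=matrix(1, ncol(d), 1)))\n"
        "out <- data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior)\n"
        f'write.csv(out, "{out_path}")\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    lm = pd.read_csv(out_path, index_col=0)
    assert res.attrs["moderation"]["d0"] == pytest.approx(lm["d0"].iloc[0], abs=1e-6)
    np.testing.assert_allclose(res["t"].to_numpy(), lm["t"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(res["p"].to_numpy(), lm["p"].to_numpy(), atol=1e-8)


def test_missing_arm_rejected():
    sim = syn.simulate_expression(50, 3, 0, 0, 0.0, 0.4, seed=5)
    design = sim.design[sim.design["sample"] != "lot2_treated"]
    with pytest.raises(ValueError, match="lot"):
        deg.paired_moderated_t(sim.values, design)


# --- BH ---------------------------------------------------------------------------


def _bh_brute_force(p):
    """Literal step-up definition: p~(i) = min_{j >= i} min(1, m p_(j) / j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_bh_hand_example():
    np.testing.assert_allclose(
        deg.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_unchanged():
    assert deg.bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(200):
        m = rng.integers(1, 40)
        p = rng.random(m)
        if rng.random() < 0.3:  # inject ties
            p[: m // 2] = np.round(p[: m // 2], 1)
        np.testing.assert_allclose(deg.bh_adjust(p), _bh_brute_force(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.random(500)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(deg.bh_adjust(p), ref, atol=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_properties(p):
    p = np.array(p)
    adj = deg.bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    assert (adj <= 1.0).all()
    # monotone: ordering of adjusted p respects ordering of raw p
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        deg.bh_adjust(np.array([0.5, 1.2]))


# --- DEG calling -------------------------------------------------------------------


def test_call_deg_boundaries():
    res = pd.DataFrame({
        "logFC": [0.9, 0.8, np.log2(1.8), -np.log2(1 / 0.55), 0.9],
        "p_adj": [0.01, 0.01, 0.05, 0.05, 0.06],
    })
    res["FC"] = 2.0 ** res["logFC"]
    out = deg.call_degs(res)
    assert list(out["call"]) == ["up", "none", "up", "down", "none"]


def test_call_deg_threshold_validation():
    res = pd.DataFrame({"FC": [1.0], "p_adj": [0.5], "logFC": [0.0]})
    with pytest.raises(ValueError):
        deg.call_degs(res, fc_up=0.5, fc_down=0.6)


def test_planted_signal_recovered_with_controlled_fdr():
    sim = syn.simulate_expression(10000, 5, 100, 100, 1.5, 0.4, seed=11)
    called = deg.call_degs(deg.paired_moderated_t(sim.values, sim.design))
    hit = called["call"] != "none"
    truth = sim.truth != 0
    recall = (hit & truth).sum() / truth.sum()
    fdr = (hit & ~truth).sum() / max(int(hit.sum()), 1)
    assert recall >= 0.8
    assert fdr <= 0.075
    # directions agree with the planted signs
    up_probes = called.index[called["call"] == "up"]
    assert (sim.truth.loc[up_probes] >= 0).all()


# --- enrichment --------------------------------------------------------------------


def _hypergeom_tail(M, K, n, k):
    return sum(comb(K, i) * comb(M - K, n - i) for i in range(k, min(K, n) + 1)) / comb(M, n)


def test_fisher_hand_example():
    universe = [f"g{i}" for i in range(20)]
    degs = universe[:5]
    sets = {"s": universe[:3] + ["g10"]}  # overlap 3, set size 4
    out = deg.fisher_enrichment(degs, sets, universe)
    assert out["p"].iloc[0] == pytest.approx((480 + 16) / 15504, abs=1e-10)


@pytest.mark.parametrize("M,K,n,k", [(20, 4, 5, 3), (30, 10, 8, 5), (25, 6, 6, 0), (12, 3, 4, 2)])
def test_fisher_matches_enumeration(M, K, n, k):
    """Fisher p equals the hypergeometric tail sum by direct enumeration."""
    universe = [f"g{i}" for i in range(M)]
    gene_set = universe[:K]
    degs = universe[:k] + universe[K : K + (n - k)]  # overlap exactly k
    out = deg.fisher_enrichment(degs, {"s": gene_set}, universe)
    assert out["overlap"].iloc[0] == k
    assert out["p"].iloc[0] == pytest.approx(_hypergeom_tail(M, K, n, k), abs=1e-12)


def test_fisher_zero_overlap_p_is_one():
    universe = [f"g{i}" for i in range(20)]
    out = deg.fisher_enrichment(universe[:5], {"s": universe[18:]}, universe)
    assert out["p"].iloc[0] <= 1.0
    assert out["p"].iloc[0] == pytest.approx(
        _hypergeom_tail(20, 2, 5, 0), abs=1e-12
    )


def test_fisher_empty_universe_rejected():
    with pytest.raises(ValueError):
        deg.fisher_enrichment(["a"], {"s": ["a"]}, [])


def test_planted_enriched_set_ranks_first():
    rng = np.random.default_rng(5)
    universe = [f"g{i}" for i in range(2000)]
    wins = 0
    for s in range(20):
        rng = np.random.default_rng(s)
        planted = list(rng.choice(universe, 40, replace=False))
        degs = planted[:25] + list(rng.choice(universe, 50, replace=False))
        sets = {"planted": planted}
        for j in range(50):
            sets[f"rand{j}"] = list(rng.choice(universe, 40, replace=False))
        out = deg.fisher_enrichment(degs, sets, universe)
        wins += int(out.sort_values("p")["set"].iloc[0] == "planted")
    assert wins >= 19


# --- rollup ------------------------------------------------------------------------


def test_superordinate_rollup_counts_and_fractions():
    enr = pd.DataFrame({
        "set": ["mig1", "met1", "unk1", "ns"],
        "p_adj": [0.01, 0.02, 0.03, 0.8],
        "significant": [True, True, True, False],
    })
    cmap = {"mig1": "migration/adhesion", "met1": "metabolism"}
    out = deg.superordinate_rollup(enr, cmap)
    as_dict = dict(zip(out["class"], out["count"]))
    assert as_dict["migration/adhesion"] == 1
    assert as_dict["metabolism"] == 1
    assert as_dict["others"] == 1  # unmapped falls through
    assert out["fraction"].sum() == pytest.approx(1.0)


def test_superordinate_rollup_empty_is_all_zero():
    enr = pd.DataFrame({"set": ["a"], "p_adj": [0.9], "significant": [False]})
    out = deg.superordinate_rollup(enr, {})
    assert out["count"].sum() == 0
    assert out["fraction"].sum() == 0.0


def test_rollup_rejects_unknown_class():
    enr = pd.DataFrame({"set": ["a"], "p_adj": [0.01], "significant": [True]})
    with pytest.raises(ValueError):
        deg.superordinate_rollup(enr, {"a": "nonsense-class"})


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\tg4\n")
    sets = deg.read_gmt(path)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g2", "g4"]}
    path.write_text("setA\tdesc\tg1\nsetA\tdesc\tg2\n")
    with pytest.raises(ValueError, match="duplicate"):
        deg.read_gmt(path)
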