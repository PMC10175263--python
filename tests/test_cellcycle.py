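"""Phase scoring, circular embedding, Kuiper test, signal removal."""

import numpy as np
import pandas as pd
import pytest

from cdkp import cellcycle as cc
from cdkp.simulate import default_cell_truth, default_marker_sets, simulate_cells

MARKERS = default_marker_sets(n_per_phase=4)


def _sets_of(d):
    return cc.PhaseGeneSets(d)


class TestPhaseScores:
    def _expr(self, values: dict, cells=("c1",)):
        return pd.DataFrame(values, index=list(cells))

    def test_mean(self):
        sets = _sets_of(
            {"M": ["g1", "g2"], "M/G1": ["g3"], "G1/S": ["g4"], "S": ["g5"],
             "G2/M": ["g6"]}
        )
        expr = self._expr({"g1": [2.0], "g2": [4.0], "g3": [0.0], "g4": [0.0],
                           "g5": [0.0], "g6": [0.0]})
        E_ik, E_i = cc.phase_scores(expr, sets)
        assert E_ik.loc["c1", "M"] == pytest.approx(3.0)
        assert list(E_i.columns) == ["g1", "g2", "g3", "g4", "g5", "g6"]

    def test_all_zero_cell(self):
        sets = _sets_of({k: [f"{k}x"] for k in cc.PHASES})
        expr = self._expr({f"{k}x": [0.0] for k in cc.PHASES})
        E_ik, _ = cc.phase_scores(expr, sets)
        assert (E_ik.loc["c1"] == 0).all()

    def test_gene_order_invariance(self):
        sets = _sets_of(
            {"M": ["a", "b"], "M/G1": ["c"], "G1/S": ["d"], "S": ["e"], "G2/M": ["f"]}
        )
        expr = self._expr({"a": [1.0], "b": [5.0], "c": [0.0], "d": [0.0],
                           "e": [0.0], "f": [0.0]})
        E1, _ = cc.phase_scores(expr, sets)
        E2, _ = cc.phase_scores(expr[list(expr.columns)[::-1]], sets)
        pd.testing.assert_frame_equal(E1, E2)

    def test_missing_phase_errors(self):
        sets = _sets_of({k: [f"{k}x"] for k in cc.PHASES})
        expr = self._expr({"Mx": [1.0]})  # only M markers present
        with pytest.raises(ValueError):
            cc.phase_scores(expr, sets)

    def test_duplicate_gene_across_sets_rejected(self):
        with pytest.raises(ValueError):
            _sets_of({"M": ["dup"], "M/G1": ["dup"], "G1/S": ["a"], "S": ["b"],
                      "G2/M": ["c"]})


class TestCoarseClassify:
    def test_argmax(self):
        E = pd.DataFrame(
            [{"M": 1.0, "M/G1": 0.0, "G1/S": 0.0, "S": 3.0, "G2/M": 2.0}], index=["c"]
        )
        assert cc.coarse_classify(E).iloc[0] == "S"

    def test_tie_break_canonical_order(self):
        E = pd.DataFrame([{k: 1.0 for k in cc.PHASES}], index=["c"])
        assert cc.coarse_classify(E).iloc[0] == "M"


class TestCosineDistance:
    def test_bounds(self):
        profiles = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]],
            index=list("abcd"),
        )
        D = cc.cosine_distance_matrix(profiles)
        assert D[0, 1] == pytest.approx(0.0)  # identical
        assert D[0, 2] == pytest.approx(1.0)  # orthogonal
        assert D[0, 3] == pytest.approx(2.0)  # anti-parallel

    def test_zero_profile_rejected(self):
        profiles = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            cc.cosine_distance_matrix(profiles)


class TestEmbedding:
    def test_polar_consistency_and_canonical_anchor(self):
        adata = simulate_cells(default_cell_truth(seed=3), MARKERS, 300, 10)
        norm = cc.normalize_counts(adata.to_df())
        E_ik, E_i = cc.phase_scores(norm, MARKERS)
        coarse = cc.coarse_classify(E_ik)
        emb = cc.embed_cells(E_i, coarse, seed=0)
        assert np.allclose(emb["r"] * np.cos(emb["theta"]), emb["D1"], atol=1e-9)
        assert np.allclose(emb["r"] * np.sin(emb["theta"]), emb["D2"], atol=1e-9)
        assert ((emb["theta"] >= 0) & (emb["theta"] < 2 * np.pi)).all()
        mg1 = emb.loc[coarse == "M/G1", "theta"].to_numpy()
        mean = np.angle(np.exp(1j * mg1).mean()) % (2 * np.pi)
        assert abs(mean - cc.MG1_REFERENCE_ANGLE) < 1e-6

    def test_too_few_cells(self):
        E = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            cc.embed_cells(E)

    def test_recovers_planted_order(self):
        markers = default_marker_sets()
        adata = simulate_cells(default_cell_truth(seed=1), markers, 400, 10)
        norm = cc.normalize_counts(adata.to_df())
        E_ik, E_i = cc.phase_scores(norm, markers)
        coarse = cc.coarse_classify(E_ik)
        emb = cc.embed_cells(E_i, coarse, seed=0)
        r = cc.circular_correlation(
            emb["theta"].to_numpy(), adata.obs["theta_true"].to_numpy()
        )
        assert r > 0.9


class TestPhaseRanges:
    def test_uniform_labels(self):
        theta = pd.Series(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        coarse = pd.Series(["S"] * 100)
        rmap, assigned = cc.assign_phase_ranges(theta, coarse, n_bins=10)
        assert set(rmap.bin_labels) == {"S"}
        assert (assigned == "S").all()

    def test_bin_mode(self):
        theta = pd.Series([0.1, 0.2, 0.3, 0.15])
        coarse = pd.Series(["S", "S", "S", "M"])
        rmap, _ = cc.assign_phase_ranges(theta, coarse, n_bins=6)
        assert rmap.label_of(0.2) == "S"

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            cc.assign_phase_ranges(pd.Series([0.0]), pd.Series(["M"]), n_bins=3)


class TestKuiper:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 2 * np.pi, 100)
        v, p = cc.kuiper_test(a, a)
        assert v < 0.05
        assert p > 0.9

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.0, 2.0, 80) % (2 * np.pi)
        b = rng.uniform(0, 2 * np.pi, 90)
        v0 = cc.kuiper_statistic(a, b)
        for rot in (0.7, 2.0, 5.1):
            v = cc.kuiper_statistic((a + rot) % (2 * np.pi), (b + rot) % (2 * np.pi))
            assert v == pytest.approx(v0, abs=1e-12)

    def test_antipodal_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        uniform = rng.uniform(0, 2 * np.pi, 500)
        lumps = np.concatenate(
            [rng.vonmises(0.0, 8.0, 250), rng.vonmises(np.pi, 8.0, 250)]
        ) % (2 * np.pi)
        v, p = cc.kuiper_test(lumps, uniform)
        assert p < 0.001
        # permutation oracle on a subsample (asymptotic vs exact null)
        sub_a, sub_b = lumps[:60], uniform[:60]
        v1, p_asym = cc.kuiper_test(sub_a, sub_b)
        pooled = np.concatenate([sub_a, sub_b])
        hits = 0
        n_perm = 2000
        perm_rng = np.random.default_rng(3)
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            if cc.kuiper_statistic(perm[:60], perm[60:]) >= v1:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        agree = abs(p_asym - p_perm) < 0.02 or (p_asym < 5e-4 and p_perm < 5e-4)
        assert agree

    def test_small_sample_uses_permutation(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 2 * np.pi, 8)
        b = rng.uniform(0, 2 * np.pi, 8)
        v, p = cc.kuiper_test(a, b, n_perm=500, seed=0)
        assert 0 < p <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cc.kuiper_test(np.array([]), np.array([1.0] * 10))


class TestSignalRemoval:
    @pytest.fixture(scope="class")
    def pipeline(self):
        adata = simulate_cells(default_cell_truth(seed=2), MARKERS, 500, 30)
        norm = cc.normalize_counts(adata.to_df())
        E_ik, E_i = cc.phase_scores(norm, MARKERS)
        coarse = cc.coarse_classify(E_ik)
        emb = cc.embed_cells(E_i, coarse, seed=0)
        resid = cc.remove_cellcycle_signal(norm, E_ik, emb["theta"])
        return norm, E_ik, emb, resid

    def test_marker_theta_dependence_removed(self, pipeline):
        norm, E_ik, emb, resid = pipeline
        th = emb["theta"].to_numpy()
        for gene in [c for c in norm.columns if "MK" in c][:10]:
            y = resid[gene].to_numpy()
            fit = cc._periodic_loess(th, y, span=0.3)
            assert 1 - np.var(y - fit) / np.var(y) < 0.05

    def test_background_preserved(self, pipeline):
        norm, _, _, resid = pipeline
        rs = [
            np.corrcoef(norm[g], resid[g])[0, 1]
            for g in norm.columns
            if g.startswith("BG")
        ]
        assert np.median(rs) > 0.95

    def test_idempotent(self, pipeline):
        norm, E_ik, emb, resid = pipeline
        again = cc.remove_cellcycle_signal(resid, E_ik, emb["theta"])
        delta = np.linalg.norm(again.to_numpy() - resid.to_numpy())
        assert delta / np.linalg.norm(resid.to_numpy()) < 1e-6

    def test_constant_gene_zero_centered(self):
        rng = np.random.default_rng(5)
        n = 120
        theta = pd.Series(rng.uniform(0, 2 * np.pi, n))
        expr = pd.DataFrame({"const": np.full(n, 3.0), "noise": rng.normal(size=n)})
        E_ik = pd.DataFrame(
            {k: np.cos(theta + i) for i, k in enumerate(cc.PHASES)}
        )
        resid = cc.remove_cellcycle_signal(expr, E_ik, theta)
        assert np.allclose(resid["const"], 0.0, atol=1e-9)


class TestExpandMarkers:
    @pytest.fixture(scope="class")
    def result(self):
        markers = default_marker_sets()
        adata = simulate_cells(default_cell_truth(seed=6), markers, 600, 40)
        norm = cc.normalize_counts(adata.to_df())
        rng = np.random.default_rng(7)
        s_marker = markers["S"][len(markers["S"]) // 2]
        norm["CAND_S"] = norm[s_marker] + rng.normal(0, 0.05, len(norm))
        # anti-correlated with every phase: negative of the pan-marker mean
        norm["CAND_ANTI"] = -norm[markers.all_genes].mean(axis=1)
        return cc.expand_markers(norm, markers)

    def test_copy_of_s_marker_assigned_s(self, result):
        assert result.loc["CAND_S", "phase"] == "S"

    def test_background_not_assigned(self, result):
        bg = [g for g in result.index if g.startswith("BG")]
        assert result.loc[bg, "phase"].notna().mean() < 0.05

    def test_anticorrelated_not_assigned(self, result):
        assert result.loc["CAND_ANTI", "phase"] is None

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            cc.expand_markers(pd.DataFrame(np.zeros((10, 3))), MARKERS)
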