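"""TF enrichment, regulon activity, ligand ranking, AUC markers, module score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichegraph import drivers as drv


def masks(n_target, n_bg):
    t = np.zeros(n_target + n_bg, bool)
    t[:n_target] = True
    return t, ~t


class TestTFExpression:
    def test_planted_tf_retained(self, atlas_norm, dataset):
        vals, obs = atlas_norm
        _, _, truth = dataset
        target = (obs["cell_type"] == "AberrantTrAT").to_numpy()
        bg = obs["cell_type"].isin(["AT1", "AT2", "trAT"]).to_numpy()
        res = drv.enrich_tf_expression(vals, target, bg, truth.driver_tfs)
        assert set(res.loc[res.selected, "tf"]) == set(truth.driver_tfs)

    def test_logfc_gate_excludes_small_shift(self):
        rng = np.random.default_rng(0)
        n = 400
        t, b = masks(n, n)
        # highly significant but logFC 0.4 < 0.5
        x = np.concatenate([rng.normal(1.4, 0.1, n), rng.normal(1.0, 0.1, n)])
        vals = pd.DataFrame({"TF1": x})
        res = drv.enrich_tf_expression(vals, t, b, ["TF1"])
        assert res.iloc[0]["p_adj"] < 1e-10
        assert 0.3 < res.iloc[0]["logfc"] < 0.5
        assert not res.iloc[0]["selected"]

    def test_null_tf_rarely_selected(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            t, b = masks(50, 50)
            vals = pd.DataFrame({"TF1": rng.normal(size=100)})
            res = drv.enrich_tf_expression(vals, t, b, ["TF1"])
            hits += int(res.iloc[0]["selected"])
        assert hits <= 3  # ≥95% of null simulations excluded

    def test_empty_background_errors(self):
        vals = pd.DataFrame({"TF1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="background"):
            drv.enrich_tf_expression(vals, [True, True], [False, False], ["TF1"])


class TestRegulonActivity:
    def test_uniformly_up_targets_positive_difference(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(100, 5)),
                            columns=[f"g{i}" for i in range(5)])
        vals.iloc[:30, :3] += 2.0  # targets up in the first 30 cells
        act = drv.regulon_activity(vals, {"TF": ["g0", "g1", "g2"]})
        assert act["TF"][:30].mean() > act["TF"][30:].mean()

    def test_zero_variance_genes_give_zero_activity(self):
        vals = pd.DataFrame(np.ones((10, 3)), columns=["a", "b", "c"])
        act = drv.regulon_activity(vals, {"TF": ["a", "b", "c"]})
        assert np.allclose(act["TF"], 0.0)

    def test_single_gene_weighted_regulon_is_zscore(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50),
                             "c": rng.normal(size=50)})
        act = drv.regulon_activity(vals, {"TF": {"a": 2.0, "b": 0.0, "c": 0.0}},
                                   min_targets=3)
        z = (vals["a"] - vals["a"].mean()) / vals["a"].std(ddof=0)
        assert np.allclose(act["TF"], z)

    def test_small_regulon_skipped(self):
        vals = pd.DataFrame({"a": [1.0, 2.0]})
        act = drv.regulon_activity(vals, {"TF": ["a", "missing1", "missing2"]})
        assert "TF" not in act.columns


class TestTFActivity:
    def test_delta_gate(self):
        rng = np.random.default_rng(3)
        t, b = masks(300, 300)
        act = pd.DataFrame({
            "TF_small": np.concatenate([rng.normal(0.3, 0.05, 300),
                                        rng.normal(0.0, 0.05, 300)]),
            "TF_big": np.concatenate([rng.normal(1.0, 0.05, 300),
                                      rng.normal(0.0, 0.05, 300)]),
        })
        res = drv.enrich_tf_activity(act, t, b)
        by_tf = res.set_index("tf")
        assert not by_tf.loc["TF_small", "selected"]  # diff 0.3 <= 0.5
        assert by_tf.loc["TF_big", "selected"]

    def test_intersection_variant_is_subset(self):
        r1 = pd.DataFrame({"tf": ["A", "B"], "selected": [True, True]})
        r2 = pd.DataFrame({"tf": ["B", "C"], "selected": [True, True]})
        out = drv.enrich_tf_activity_multi([r1, r2])
        assert out == ["B"]
        assert set(out) <= {"A", "B"} and set(out) <= {"B", "C"}


class TestUnion:
    def _res(self, tfs):
        return pd.DataFrame({"tf": tfs, "selected": [True] * len(tfs)})

    def test_published_arithmetic(self):
        # 38 expression TFs, 15 activity TFs, overlap 2 → 51 unique
        e = self._res([f"E{i}" for i in range(36)] + ["X1", "X2"])
        a = self._res([f"A{i}" for i in range(13)] + ["X1", "X2"])
        u = drv.union_tfs(e, a)
        assert len(u) == 51
        assert (u.set_index("tf").loc["X1", "source"] == "both")

    def test_disjoint_and_identical(self):
        assert len(drv.union_tfs(self._res(["a", "b", "c"]), self._res(["d", "e"]))) == 5
        u = drv.union_tfs(self._res(["a", "b"]), self._res(["a", "b"]))
        assert list(u["tf"]) == ["a", "b"]
        assert (u["source"] == "both").all()

    def test_inclusion_exclusion_identity(self):
        e, a = self._res(["a", "b", "c", "d"]), self._res(["c", "d", "e"])
        u = drv.union_tfs(e, a)
        assert len(u) == 4 + 3 - 2


class TestRankLigands:
    def test_toy_recurrence_example(self):
        pot = pd.DataFrame([[0.9, 0.8, 0.1], [0.2, 0.3, 0.9]],
                           index=["L1", "L2"], columns=["TF1", "TF2", "TF3"])
        res = drv.rank_ligands(["TF1", "TF2", "TF3"], pot, k=1)
        by = res.set_index("ligand")
        assert by.loc["L1", "recurrence"] == 2 and by.loc["L1", "selected"]
        assert by.loc["L2", "recurrence"] == 1 and not by.loc["L2", "selected"]

    def test_saturation_when_k_exceeds_ligands(self):
        rng = np.random.default_rng(4)
        pot = pd.DataFrame(rng.uniform(size=(5, 3)),
                           index=[f"L{i}" for i in range(5)],
                           columns=["T1", "T2", "T3"])
        res = drv.rank_ligands(["T1", "T2", "T3"], pot, k=10)
        assert (res["recurrence"] == 3).all()

    def test_tie_at_rank_k_lexicographic(self):
        pot = pd.DataFrame({"TF1": [0.5, 0.5, 0.9]},
                           index=["Lb", "La", "Lc"])
        res = drv.rank_ligands(["TF1"], pot, k=2)
        kept = set(res["ligand"])
        assert "Lc" in kept and "La" in kept and "Lb" not in kept

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pot = pd.DataFrame(rng.uniform(size=(20, 4)),
                           index=[f"L{i:02d}" for i in range(20)],
                           columns=list("ABCD"))
        r1 = drv.rank_ligands(list("ABCD"), pot, k=5)
        perm = pot.sample(frac=1, axis=0, random_state=0).sample(
            frac=1, axis=1, random_state=1)
        r2 = drv.rank_ligands(list("ABCD"), perm, k=5)
        pd.testing.assert_frame_equal(
            r1.sort_values("ligand").reset_index(drop=True),
            r2.sort_values("ligand").reset_index(drop=True))

    def test_missing_tf_skipped(self):
        pot = pd.DataFrame({"TF1": [0.9]}, index=["L1"])
        res = drv.rank_ligands(["TF1", "GHOST"], pot, k=1,
                               min_recurrence=1)
        assert list(res["ligand"]) == ["L1"]


class TestFilterReceptors:
    def _atlas(self, frac, seed=0):
        import anndata as ad
        from scipy import sparse
        rng = np.random.default_rng(seed)
        n = 200
        col = (rng.uniform(size=n) < frac).astype(float) * 3
        X = sparse.csr_matrix(np.column_stack([col, np.ones(n)]))
        obs = pd.DataFrame({"cell_type": ["tgt"] * n},
                           index=[f"c{i}" for i in range(n)])
        return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["R1", "other"]))

    def _cands(self):
        return pd.DataFrame({"ligand": ["L1"], "recurrence": [2],
                             "selected": [True]})

    def _rmap(self):
        return pd.DataFrame({"receptor_genes": ["R1"]}, index=["L1"])

    def test_fraction_gate_across_atlases(self):
        a_hi, a_mid = self._atlas(0.5, 1), self._atlas(0.06, 2)
        a_lo = self._atlas(0.002, 3)
        mask = np.ones(200, bool)
        keep = drv.filter_receptors(self._cands(), [a_hi, a_mid], [mask, mask],
                                    self._rmap())
        assert list(keep["ligand"]) == ["L1"]
        drop = drv.filter_receptors(self._cands(), [a_hi, a_lo], [mask, mask],
                                    self._rmap())
        assert drop.empty

    def test_manual_additions_flagged(self):
        a = self._atlas(0.5)
        mask = np.ones(200, bool)
        out = drv.filter_receptors(self._cands(), [a], [mask], self._rmap(),
                                   manual_additions=["SPP1"])
        assert out.set_index("ligand").loc["SPP1", "manual"]
        assert not out.set_index("ligand").loc["L1", "manual"]

    def test_empty_manual_is_identity(self):
        a = self._atlas(0.5)
        mask = np.ones(200, bool)
        o1 = drv.filter_receptors(self._cands(), [a], [mask], self._rmap())
        o2 = drv.filter_receptors(self._cands(), [a], [mask], self._rmap(),
                                  manual_additions=[])
        pd.testing.assert_frame_equal(o1, o2)


class TestAUC:
    def test_perfect_separation(self):
        assert drv.auc_one_vs_rest(np.array([5, 6, 7]), np.array([0, 1, 2])) == 1.0

    def test_identical_distributions(self):
        assert drv.auc_one_vs_rest(np.array([1, 2, 3]), np.array([1, 2, 3])) == pytest.approx(0.5)

    def test_hand_counted_example(self):
        # in (3,4) vs out (1,2,5): 4 of 6 concordant pairs
        auc = drv.auc_one_vs_rest(np.array([3, 4]), np.array([1, 2, 5]))
        assert auc == pytest.approx(4 / 6)

    def test_markers_threshold_boundary(self):
        vals = pd.DataFrame({"g": [3.0, 4.0, 1.0, 2.0, 5.0]})
        csg_065 = drv.auc_markers(vals, ["X", "X", "o", "o", "o"], threshold=0.65)
        csg_070 = drv.auc_markers(vals, ["X", "X", "o", "o", "o"], threshold=0.70)
        assert csg_065["X"] == ["g"]
        assert csg_070["X"] == []

    def test_matches_concordance_oracle_exactly(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.integers(0, 6, size=(30, 8)).astype(float))
        vals.columns = [f"g{j}" for j in range(8)]
        types = rng.choice(["A", "B", "C"], size=30)
        csgs = drv.auc_markers(vals, types, threshold=0.65)
        for t in "ABC":
            mask = types == t
            for g in vals.columns:
                x, y = vals.loc[mask, g].to_numpy(), vals.loc[~mask, g].to_numpy()
                conc = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
                auc = conc / (len(x) * len(y))
                assert (g in csgs[t]) == (auc >= 0.65)


class TestModuleScore:
    def _vals(self, seed=0, n=60, g=300):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, g)),
                            columns=[f"g{j}" for j in range(g)])

    def test_null_centered_on_zero(self):
        means = []
        for seed in range(50):
            vals = self._vals(seed)
            s = drv.module_score(vals, [f"g{j}" for j in range(10)], seed=seed)
            means.append(s.mean())
        assert abs(np.mean(means)) < 0.05

    def test_program_shift_recovered_between_cell_groups(self):
        """A +2 shift of the gene set in half the cells yields a score
        contrast of ≈2 between shifted and unshifted cells (controls are
        matched on overall average expression, so the contrast isolates the
        planted program)."""
        rng = np.random.default_rng(1)
        n, g = 60, 300
        base = np.linspace(0, 50, g)
        vals = pd.DataFrame(base + rng.normal(0, 1.0, size=(n, g)),
                            columns=[f"g{j}" for j in range(g)])
        genes = [f"g{j}" for j in range(15, g, 30)]  # spread across bins
        vals.loc[vals.index[:30], genes] += 2.0
        s = drv.module_score(vals, genes, seed=0)
        delta = s.iloc[:30].mean() - s.iloc[30:].mean()
        assert delta == pytest.approx(2.0, abs=0.3)

    def test_seeded_determinism(self):
        vals = self._vals(2)
        s1 = drv.module_score(vals, ["g0", "g1", "g2"], seed=7)
        s2 = drv.module_score(vals, ["g0", "g1", "g2"], seed=7)
        pd.testing.assert_series_equal(s1, s2)

    def test_unresolvable_set_errors(self):
        with pytest.raises(ValueError, match="no genes"):
            drv.module_score(self._vals(3), ["missing"])
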