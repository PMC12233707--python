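"""Variance stabilization, PCA, top-N selection, z-score heatmaps,
volcano annotation, family trends."""

import numpy as np
import pandas as pd
import pytest

from tdrprof.diffexpr import DesignInfo, size_factors, wald_test
from tdrprof.profiles import (
    family_group,
    family_trends,
    run_pca,
    top_n_fragments,
    variance_stabilize,
    volcano_table,
    zscore_heatmap,
)


def test_variance_stabilize_values():
    cm = pd.DataFrame({"a": [0, 3], "b": [0, 3]})
    sf = pd.Series([1.0, 1.0], index=["a", "b"])
    v = variance_stabilize(cm, sf)
    assert v.iloc[0, 0] == 0.0  # log2(0/1 + 1)
    assert v.iloc[1, 0] == 2.0  # log2(3/1 + 1)


def test_variance_stabilize_scale_identity():
    """Doubling a sample's counts and its size factor leaves it unchanged."""
    rng = np.random.default_rng(0)
    cm = pd.DataFrame(rng.integers(0, 500, size=(30, 3)), columns=list("abc"))
    sf = pd.Series([0.9, 1.0, 1.1], index=list("abc"))
    v1 = variance_stabilize(cm, sf)
    cm2, sf2 = cm.copy(), sf.copy()
    cm2["b"] = cm2["b"] * 2
    sf2["b"] = sf2["b"] * 2
    v2 = variance_stabilize(cm2, sf2)
    assert np.allclose(v1, v2)


def test_variance_stabilize_rejects_nonpositive_factor():
    cm = pd.DataFrame({"a": [1], "b": [1]})
    with pytest.raises(ValueError):
        variance_stabilize(cm, pd.Series([1.0, 0.0], index=["a", "b"]))


class TestPCA:
    def test_duplicated_samples_identical_coords(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=20), "d": rng.normal(size=20)}
        )
        proj = run_pca(m)
        assert np.allclose(proj.coordinates.loc["a"], proj.coordinates.loc["b"])

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(20, 6)))
        proj = run_pca(m)
        evr = proj.explained_variance_ratio
        assert (np.diff(evr) <= 1e-9).all()  # non-increasing
        assert evr.sum() <= 1 + 1e-9

    def test_matches_brute_force_eigendecomposition(self):
        """6 samples x 20 features: projections agree (up to sign) with an
        eigendecomposition of the feature covariance."""
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        proj = run_pca(m)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (X.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        V = V[:, order]
        for j in range(3):
            ours = proj.coordinates.iloc[:, j].to_numpy()
            theirs = Xc @ V[:, j]
            assert np.allclose(np.abs(ours), np.abs(theirs), atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(15, 5)))
        p1 = run_pca(m)
        p2 = run_pca(m.copy())
        assert np.allclose(p1.coordinates, p2.coordinates)
        for j in range(p1.loadings.shape[1]):
            col = p1.loadings.iloc[:, j]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(ValueError):
            run_pca(m)


def _frag_table(rows, samples):
    recs = []
    for name, fam, counts in rows:
        r = dict(family_id=fam, name=name, start_label=1, end_label=30,
                 frag_class="five_half")
        r.update(dict(zip(samples, counts)))
        recs.append(r)
    return pd.DataFrame(recs)


class TestTopN:
    def test_small_family_returns_all(self):
        t = _frag_table(
            [(f"f{i}", "His-GUG", [i + 1, i + 2]) for i in range(5)], ["a", "b"]
        )
        assert len(top_n_fragments(t, "His-GUG", 20)) == 5

    def test_tie_breaks_lexicographically(self):
        t = _frag_table(
            [("zzz", "His-GUG", [10, 0]), ("aaa", "His-GUG", [0, 10]),
             ("mmm", "His-GUG", [20, 20])],
            ["a", "b"],
        )
        assert top_n_fragments(t, "His-GUG", 2) == ["mmm", "aaa"]

    def test_absent_family_empty_with_warning(self, caplog):
        t = _frag_table([("f", "His-GUG", [1])], ["a"])
        with caplog.at_level("WARNING"):
            assert top_n_fragments(t, "Sec-UCA") == []
        assert "Sec-UCA" in caplog.text

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        rows = [(f"n{i:03d}", "His-GUG", list(rng.integers(0, 100, 4))) for i in range(40)]
        t = _frag_table(rows, ["a", "b", "c", "d"])
        got = top_n_fragments(t, "His-GUG", 20)
        oracle = sorted(rows, key=lambda r: (-sum(r[2]), r[0]))[:20]
        assert got == [r[0] for r in oracle]


class TestZHeatmap:
    def test_rows_are_zscores(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(10, 3, size=(8, 5)),
                         index=[f"f{i}" for i in range(8)])
        hm = zscore_heatmap(m)
        Z = hm.matrix.to_numpy()
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=1), 1, atol=1e-9)

    def test_constant_rows_zero_and_last(self):
        m = pd.DataFrame(
            {"a": [1.0, 5.0, 3.0], "b": [1.0, 6.0, 4.0], "c": [1.0, 7.0, 5.0]},
            index=["const", "x", "y"],
        )
        hm = zscore_heatmap(m)
        assert hm.row_order[-1] == "const"
        assert np.allclose(hm.matrix.loc["const"], 0.0)

    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"f{i}" for i in range(6)])
        m.loc["f5"] = m.loc["f0"] * 3 + 2  # identical after z-scoring
        hm = zscore_heatmap(m)
        i0, i5 = hm.row_order.index("f0"), hm.row_order.index("f5")
        assert abs(i0 - i5) == 1

    def test_merge_structure_matches_naive_agglomeration(self):
        """10-row fixture: average-linkage merges equal a brute-force
        O(n^3) agglomeration (same partitions at the same heights)."""
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(10, 6)), index=[f"f{i}" for i in range(10)])
        Z = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=0)).T.to_numpy()

        # naive average-linkage on Euclidean distances
        clusters = {i: [i] for i in range(10)}
        merges = []
        d = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or avg < best[0]:
                        best = (avg, a, b)
            h, a, b = best
            merges.append((h, frozenset(clusters[a] + clusters[b])))
            clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)

        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import pdist

        link = average(pdist(Z))
        members = {i: frozenset([i]) for i in range(10)}
        for k, (a, b, h, _cnt) in enumerate(link):
            members[10 + k] = members[int(a)] | members[int(b)]
            exp_h, exp_set = merges[k]
            assert h == pytest.approx(exp_h)
            assert members[10 + k] == exp_set

        hm = zscore_heatmap(m)
        assert set(hm.row_order) == set(m.index)


class TestVolcano:
    def test_family_groups(self):
        assert family_group("His-GUG") == "HisGUG"
        assert family_group("Lys-CUU") == "LysCUU"
        assert family_group("Glu-CUC") == "other"

    def test_table_annotation_and_na_exclusion(self):
        de = pd.DataFrame(
            dict(
                base_mean=[100, 50, 10],
                log2fc=[-2.5, 0.2, np.nan],
                se=[0.5, 0.5, np.nan],
                wald=[-5.0, 0.4, np.nan],
                pvalue=[1e-6, 0.7, np.nan],
                padj=[3e-6, 0.8, np.nan],
            ),
            index=["His-GUG:G1-G34", "Glu-CUC:T1-T35", "Lys-CUU:A1-C30"],
        )
        vt = volcano_table(de)
        assert len(vt) == 2  # NA padj excluded
        his = vt[vt["fragment"] == "His-GUG:G1-G34"].iloc[0]
        assert his["family_group"] == "HisGUG"
        assert his["significant"]
        assert his["neg_log10_padj"] == pytest.approx(-np.log10(3e-6))
        assert vt.iloc[1]["family_group"] == "other"


def test_family_trends_totals():
    d = DesignInfo(
        samples=("a1", "a2", "b1", "b2"),
        timepoints=("0h", "0h", "24h", "24h"),
        replicates=(1, 2, 1, 2),
    )
    norm = pd.DataFrame(
        [[10.0, 12, 5, 6], [5, 6, 2, 3], [100, 90, 110, 95]],
        index=["His-GUG:G1-G34", "His-GUG:G-1-G34", "Lys-CUU:C1-A35"],
        columns=list(d.samples),
    )
    tr = family_trends(norm, d).set_index("family_id")
    assert tr.loc["His-GUG", "a1"] == 15.0
    assert tr.loc["His-GUG", "mean_0h"] == pytest.approx((15 + 18) / 2)
    assert tr.loc["Lys-CUU", "mean_24h"] == pytest.approx(102.5)


class TestSimulatedStructure:
    """Properties on the synthetic study design (counts-only, fast)."""

    @staticmethod
    def _cm_from_truth(truth):
        cm = truth.counts_wide().round().astype(int)
        cm.index = [f"{a}:{b}..{c}" for a, b, c in cm.index]
        return cm

    def test_replicate_clustering_in_pc_space(self):
        """With programmed between-timepoint effects well above the NB
        noise, replicates of a timepoint sit closer together in PC1-PC2
        than samples from different timepoints (>= 9/10 seeds)."""
        from tdrprof.simdata import SimConfig, make_reference, simulate_counts

        successes = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            ref, decoys = make_reference(cfg)
            truth = simulate_counts(cfg, ref, decoys)
            cm = self._cm_from_truth(truth)
            sf = size_factors(cm)
            proj = run_pca(variance_stabilize(cm, sf))
            P = proj.coordinates[["PC1", "PC2"]].to_numpy()
            design = cfg.design()
            within, between = [], []
            for i in range(len(design.samples)):
                for j in range(i + 1, len(design.samples)):
                    dist = np.linalg.norm(P[i] - P[j])
                    if design.timepoints[i] == design.timepoints[j]:
                        within.append(dist)
                    else:
                        between.append(dist)
            successes += np.mean(within) < np.mean(between)
        assert successes >= 9

    def test_programmed_downregulation_has_negative_log2fc(self):
        """Fragments simulated as clearly down at 24 h carry a negative
        estimated log2fc in >= 95% of seeded runs."""
        from tdrprof.simdata import SimConfig, make_reference, simulate_counts

        total = correct = 0
        for seed in range(20):
            cfg = SimConfig(seed=100 + seed)
            ref, decoys = make_reference(cfg)
            truth = simulate_counts(cfg, ref, decoys)
            cm = self._cm_from_truth(truth)
            res = wald_test(cm, cfg.design(), ("0h", "24h"))
            down = [
                f"{s.family_id}:{s.start_label}..{s.end_label}"
                for s in cfg.fragment_specs
                if s.log2fc[-1] <= -1.0
            ]
            for f in down:
                total += 1
                correct += res.loc[f, "log2fc"] < 0
        assert correct / total >= 0.95
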