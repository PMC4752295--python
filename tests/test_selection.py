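import numpy as np
import pandas as pd
import pytest

from ecgstab.selection import (compute_vif, forward_select,
                               greedy_redundancy_removal,
                               mean_correlation_matrix, select_features)


def make_table(rng, n_subjects=20, windows=12, n_features=20, feature_fn=None):
    rows = []
    for s in range(n_subjects):
        for w in range(windows):
            feats = (feature_fn(rng, s, w) if feature_fn
                     else rng.normal(size=n_features))
            row = {"subject_id": f"s{s:02d}", "window_index": w, "stage": w % 3,
                   "severity": 0.0, "label": "normal"}
            row.update({f"f{j:03d}": feats[j] for j in range(len(feats))})
            rows.append(row)
    return pd.DataFrame(rows)


def exact_corr_pair(rng, n, rho):
    """Two columns with sample correlation exactly rho (Gram-Schmidt)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    return x, rho * x + np.sqrt(1 - rho ** 2) * z


class TestMeanCorrelation:
    def test_duplicate_feature_entry_one(self):
        rng = np.random.default_rng(0)
        table = make_table(rng, 5, 10, 3)
        table["f002"] = table["f000"] * 2.0 + 1.0
        C = mean_correlation_matrix(table)
        assert np.isclose(C.loc["f000", "f002"], 1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(1)
        table = make_table(rng, 20, 50, 10)
        C = mean_correlation_matrix(table).to_numpy()
        off = C[~np.eye(len(C), dtype=bool)]
        assert np.all(off < 0.2)

    def test_average_of_subject_correlations(self):
        rng = np.random.default_rng(2)
        rows = []
        for sid, rho in (("a", 0.8), ("b", 0.6)):
            x, y = exact_corr_pair(rng, 40, rho)
            for w in range(40):
                rows.append({"subject_id": sid, "window_index": w, "stage": 0,
                             "severity": 0.0, "label": "normal",
                             "g1": x[w], "g2": y[w]})
        C = mean_correlation_matrix(pd.DataFrame(rows))
        assert np.isclose(C.loc["g1", "g2"], 0.7, atol=1e-9)

    def test_constant_feature_flagged_redundant(self):
        rng = np.random.default_rng(3)
        table = make_table(rng, 5, 10, 3)
        table["f001"] = 7.0
        C = mean_correlation_matrix(table)
        assert np.all(C.loc["f001"] == 1.0)


class TestGreedyRemoval:
    def test_nothing_above_threshold(self):
        C = pd.DataFrame(np.eye(4) + 0.3, columns=list("abcd"), index=list("abcd"))
        np.fill_diagonal(C.values, 1.0)
        kept, removed = greedy_redundancy_removal(C)
        assert removed == [] and kept == list("abcd")

    def test_trio_removes_hub_only(self):
        names = list("abc")
        C = pd.DataFrame([[1.0, 0.95, 0.95], [0.95, 1.0, 0.2], [0.95, 0.2, 1.0]],
                         columns=names, index=names)
        kept, removed = greedy_redundancy_removal(C)
        assert [r[0] for r in removed] == ["a"]
        assert removed[0][1] == 2
        assert kept == ["b", "c"]

    def test_random_matrices_clean_and_match_naive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 60
            A = rng.uniform(0, 1, (n, n))
            C = (A + A.T) / 2
            np.fill_diagonal(C, 1.0)
            names = [f"f{i}" for i in range(n)]
            Cdf = pd.DataFrame(C, columns=names, index=names)
            kept, removed = greedy_redundancy_removal(Cdf, 0.9)
            # post-hoc exhaustive rescan: no surviving pair >= threshold
            sub = Cdf.loc[kept, kept].to_numpy()
            np.fill_diagonal(sub, 0.0)
            assert np.all(sub < 0.9)
            # independent naive greedy reimplementation
            alive = set(names)
            naive_removed = []
            while True:
                counts = {i: sum(1 for j in alive if j != i and Cdf.loc[i, j] >= 0.9)
                          for i in alive}
                worst = max(alive, key=lambda i: (counts[i], -names.index(i)))
                if counts[worst] == 0:
                    break
                alive.remove(worst)
                naive_removed.append(worst)
            assert [r[0] for r in removed] == naive_removed

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.5, 1, (30, 30))
        C = (A + A.T) / 2
        np.fill_diagonal(C, 1.0)
        names = [f"f{i}" for i in range(30)]
        Cdf = pd.DataFrame(C, columns=names, index=names)
        kept, _ = greedy_redundancy_removal(Cdf)
        kept2, removed2 = greedy_redundancy_removal(Cdf.loc[kept, kept])
        assert kept2 == kept and removed2 == []


class TestForwardSelect:
    def _planted_table(self, rng, n_decoys=50, effect=3.0):
        def gen(rng, s, w):
            return rng.normal(size=n_decoys + 3)
        table = make_table(rng, 20, 12, n_decoys + 3, gen)
        planted = ["f000", "f001", "f002"]
        noise_sd = 1.0
        y = sum(effect * noise_sd * table[p] for p in planted)
        table["severity"] = y + rng.normal(0, noise_sd, len(table))
        return table, planted

    def test_recovers_planted_features(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table, planted = self._planted_table(rng)
            report = forward_select(table, k=3, seed=seed)
            hits += set(report.selected) == set(planted)
        assert hits >= 9

    def test_null_response_low_cv_r2(self):
        r2s = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            table = make_table(rng, 20, 12, 30)
            table["severity"] = rng.normal(size=len(table))
            report = forward_select(table, k=3, seed=seed)
            # held-out R2 of the selected model, subject-wise 10-fold
            feats = report.selected
            subs = table["subject_id"].to_numpy()
            uniq = np.random.default_rng(seed).permutation(np.unique(subs))
            sse = sst = 0.0
            for fold in np.array_split(uniq, 10):
                te = np.isin(subs, fold)
                X_tr = np.column_stack([np.ones((~te).sum()), table.loc[~te, feats]])
                X_te = np.column_stack([np.ones(te.sum()), table.loc[te, feats]])
                beta, *_ = np.linalg.lstsq(X_tr, table.loc[~te, "severity"], rcond=None)
                resid = table.loc[te, "severity"] - X_te @ beta
                sse += float(resid @ resid)
                sst += float(np.sum((table.loc[te, "severity"]
                                     - table.loc[~te, "severity"].mean()) ** 2))
            r2s.append(1 - sse / sst)
        assert np.median(r2s) <= 0.05

    def test_single_candidate_equals_ols(self):
        rng = np.random.default_rng(6)
        table = make_table(rng, 12, 10, 1)
        table["severity"] = 2.0 * table["f000"] + rng.normal(0, 0.1, len(table))
        report = forward_select(table, k=1, candidates=["f000"], seed=0)
        assert report.selected == ["f000"]
        x, y = table["f000"].to_numpy(), table["severity"].to_numpy()
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        est = report.stats.loc[report.stats["term"] == "f000", "estimate"].iloc[0]
        assert np.isclose(est, slope, rtol=1e-9)

    def test_k_too_large(self):
        rng = np.random.default_rng(7)
        table = make_table(rng, 12, 5, 3)
        with pytest.raises(ValueError):
            forward_select(table, k=10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        table, _ = self._planted_table(rng, n_decoys=20)
        a = forward_select(table, k=5, seed=3)
        b = forward_select(table, k=5, seed=3)
        assert a.selected == b.selected
        assert a.step_r2 == b.step_r2


class TestVif:
    def test_orthogonal_features_vif_one(self):
        n = 64
        t = np.arange(n)
        table = pd.DataFrame({
            "subject_id": "s0", "window_index": t, "stage": 0, "severity": 0.0,
            "label": "normal",
            "c1": np.cos(2 * np.pi * t / n), "c2": np.sin(2 * np.pi * t / n),
            "c3": np.cos(4 * np.pi * t / n)})
        vifs = compute_vif(table, ["c1", "c2", "c3"])
        for v in vifs.values():
            assert np.isclose(v, 1.0, atol=1e-9)

    def test_correlation_09_closed_form(self):
        rng = np.random.default_rng(9)
        x, y = exact_corr_pair(rng, 200, 0.9)
        table = pd.DataFrame({"subject_id": "s0", "window_index": range(200),
                              "stage": 0, "severity": 0.0, "label": "normal",
                              "x": x, "y": y})
        vifs = compute_vif(table, ["x", "y"])
        assert np.isclose(vifs["x"], 1.0 / (1.0 - 0.81), rtol=1e-6)

    def test_duplicate_infinite(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        table = pd.DataFrame({"subject_id": "s0", "window_index": range(50),
                              "stage": 0, "severity": 0.0, "label": "normal",
                              "x": x, "y": 2 * x})
        with pytest.warns(UserWarning):
            vifs = compute_vif(table, ["x", "y"])
        assert np.isinf(vifs["x"])


def test_select_features_end_to_end():
    rng = np.random.default_rng(11)
    table = make_table(rng, 15, 10, 12)
    table["f011"] = table["f000"] * 1.5  # redundant duplicate
    table["severity"] = table["f001"] * 3 + rng.normal(0, 1, len(table))
    report = select_features(table, k=2, seed=0)
    assert "f011" in [r[0] for r in report.removed] or "f000" in [r[0] for r in report.removed]
    assert "f001" in report.selected
    assert {"term", "estimate", "std_error", "t_ratio", "p_value", "vif"} <= set(report.stats.columns)
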