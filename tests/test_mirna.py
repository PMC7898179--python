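"""miRNA detection, template matching, prioritization, target networks."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dmvstates import mirna


def make_counts(endog: np.ndarray, neg: np.ndarray, groups: list[str]) -> mirna.MiRNACounts:
    n_samples = endog.shape[1]
    samples = [f"s{i}" for i in range(n_samples)]
    probes = [f"miR-{i}" for i in range(endog.shape[0])]
    negs = [f"NEG_{i}" for i in range(neg.shape[0])]
    counts = pd.DataFrame(np.vstack([endog, neg]), index=probes + negs,
                          columns=samples)
    return mirna.MiRNACounts(
        counts=counts,
        is_negative_control=pd.Series([False] * len(probes) + [True] * len(negs),
                                      index=counts.index),
        groups=pd.Series(groups, index=samples),
    )


GROUPS6 = ["control", "control", "LAD", "LAD", "RIPC+LAD", "RIPC+LAD"]


class TestDetect:
    def test_all_zero_counts_detect_nothing(self):
        c = make_counts(np.zeros((3, 6)), np.zeros((2, 6)), GROUPS6)
        assert mirna.detect(c) == []

    def test_probe_exactly_at_background_not_detected(self):
        neg = np.full((3, 6), 10)  # background mean 10, SD 0
        endog = np.vstack([np.full(6, 10), np.full(6, 11)])
        c = make_counts(endog, neg, GROUPS6)
        assert mirna.detect(c) == ["miR-1"]

    def test_monotone_in_k_sd(self):
        rng = np.random.default_rng(3)
        endog = rng.poisson(30, size=(40, 6))
        neg = rng.poisson(15, size=(6, 6))
        c = make_counts(endog, neg, GROUPS6)
        sets = [set(mirna.detect(c, k_sd=k)) for k in (0.5, 1.5, 2.5, 4.0)]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_planted_above_background_recovered(self):
        rng = np.random.default_rng(4)
        high = rng.poisson(400, size=(150, 6))
        low = rng.poisson(15, size=(250, 6))
        neg = rng.poisson(15, size=(8, 6))
        c = make_counts(np.vstack([high, low]), neg, GROUPS6)
        detected = set(mirna.detect(c))
        planted = {f"miR-{i}" for i in range(150)}
        assert planted <= detected
        false_calls = len(detected - planted)
        assert false_calls / 250 < 0.1

    def test_missing_negative_controls_rejected(self):
        counts = pd.DataFrame(np.ones((2, 4)), columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError, match="negative-control"):
            mirna.MiRNACounts(
                counts=counts,
                is_negative_control=pd.Series(False, index=counts.index),
                groups=pd.Series(["a", "a", "b", "b"], index=counts.columns),
            )


class TestTemplateMatch:
    def test_profile_equal_to_template_scores_one(self):
        profiles = pd.DataFrame([[0, 0, 1, 1, 0, 0.0]], index=["m"],
                                columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(GROUPS6, index=profiles.columns)
        out = mirna.template_match(profiles, groups, n_perm=2000, seed=0)
        assert out.loc["m", "score"] == pytest.approx(1.0)
        # exact permutation p: 2!4!/6! = 1/15 of orderings reproduce |r|=1
        assert out.loc["m", "p"] == pytest.approx(1 / 15, abs=0.02)

    def test_zero_variance_profile(self):
        profiles = pd.DataFrame([[3.0] * 6], index=["m"],
                                columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(GROUPS6, index=profiles.columns)
        out = mirna.template_match(profiles, groups, n_perm=200, seed=0)
        assert out.loc["m", "score"] == 0.0
        assert out.loc["m", "p"] == 1.0

    def test_p_matches_exhaustive_label_enumeration(self):
        """Permutation p agrees with the exact enumeration over all 720
        orderings of the six sample labels (90 distinct assignments)."""
        rng = np.random.default_rng(9)
        profile = rng.normal(size=6)
        profiles = pd.DataFrame([profile], index=["m"],
                                columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(GROUPS6, index=profiles.columns)
        template = np.array([0, 0, 1, 1, 0, 0.0])
        x = (profile - profile.mean()) / profile.std()
        obs = np.abs(np.mean(x * (template - template.mean()) / template.std()))
        exceed = total = 0
        for perm in permutations(range(6)):
            t = template[list(perm)]
            score = np.abs(np.mean(x * (t - t.mean()) / t.std()))
            exceed += score >= obs - 1e-12
            total += 1
        p_exact = exceed / total
        out = mirna.template_match(profiles, groups, n_perm=20000, seed=1)
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(out.loc["m", "p"] - p_exact) <= 4 * mc_sd + 1e-4

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(12)
        profiles = pd.DataFrame(rng.normal(size=(1000, 6)),
                                index=[f"m{i}" for i in range(1000)],
                                columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(GROUPS6, index=profiles.columns)
        out = mirna.template_match(profiles, groups, n_perm=499, seed=5)
        from scipy import stats as sps
        # permutation p values are discrete; compare achieved level at a few cuts
        for alpha in (0.1, 0.25, 0.5):
            rate = (out["p"] <= alpha).mean()
            assert abs(rate - alpha) < 0.06

    def test_template_missing_group_rejected(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=["m"],
                                columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(GROUPS6, index=profiles.columns)
        with pytest.raises(ValueError, match="template lacks"):
            mirna.template_match(profiles, groups, template={"control": 0.0})


class TestPrioritize:
    def matches(self):
        return pd.DataFrame(
            {"score": [0.9, 0.8, 0.2], "p": [0.001, 0.2, 0.7],
             "abundance": [8.0, 9.0, 2.0]},
            index=["hit", "weak_p", "weak_all"],
        )

    def test_filters_compose(self):
        folds = pd.Series([4.0, 3.0, 1.1], index=self.matches().index)
        out = mirna.prioritize(self.matches(), folds,
                               detected=["hit", "weak_p", "weak_all"])
        assert list(out.index) == ["hit"]

    def test_down_regulation_passes_fold_cut(self):
        folds = pd.Series([0.25], index=["hit"])
        out = mirna.prioritize(self.matches().loc[["hit"]], folds, detected=["hit"],
                               abundance_quantile=0.0)
        assert list(out.index) == ["hit"]

    def test_infinite_fold_cut_empties_list(self):
        folds = pd.Series([4.0, 3.0, 1.1], index=self.matches().index)
        out = mirna.prioritize(self.matches(), folds,
                               detected=list(self.matches().index),
                               fold_cut=np.inf)
        assert len(out) == 0

    def test_output_subset_of_detected(self):
        folds = pd.Series([4.0, 3.0, 1.1], index=self.matches().index)
        out = mirna.prioritize(self.matches(), folds, detected=["weak_p"])
        assert set(out.index) <= {"weak_p"}


class TestTargetNetwork:
    def hits(self):
        return pd.DataFrame({
            "miRNA": ["miR-a", "miR-a", "miR-b"],
            "gene": ["Gria1", "Gabra1", "Scn1a"],
            "mirwalk": [True, True, True],
            "rna22": [True, False, False],
            "miranda": [False, False, False],
            "targetscan": [False, False, False],
        })

    def test_consensus_rule_single_edge(self):
        g = mirna.target_network(["miR-a"], self.hits(),
                                 expressed_genes=["Gria1", "Gabra1"])
        assert g.has_edge("miR-a", "Gria1")
        assert not g.has_node("Gabra1")  # one algorithm only

    def test_expression_filter_removes_gene(self):
        g = mirna.target_network(["miR-a"], self.hits(), expressed_genes=["Gabra1"])
        assert g.number_of_edges() == 0

    def test_empty_expressed_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mirna.target_network(["miR-a"], self.hits(), expressed_genes=[])

    def test_absent_candidate_warned_and_isolated(self):
        with pytest.warns(UserWarning, match="miR-z"):
            g = mirna.target_network(["miR-z"], self.hits(),
                                     expressed_genes=["Gria1"])
        assert g.has_node("miR-z")
        assert g.degree("miR-z") == 0

    def test_random_hit_table_matches_filter_oracle(self):
        rng = np.random.default_rng(30)
        mirs = [f"miR-{i}" for i in range(4)]
        genes = [f"G{i}" for i in range(12)]
        algs = ["mirwalk", "rna22", "miranda", "targetscan"]
        rows = []
        for m in mirs:
            for g in genes:
                rows.append({"miRNA": m, "gene": g,
                             **{a: bool(rng.random() < 0.4) for a in algs}})
        hits = pd.DataFrame(rows)
        expressed = genes[:8]
        net = mirna.target_network(mirs, hits, expressed_genes=expressed)
        for _, row in hits.iterrows():
            votes = sum(row[a] for a in algs)
            should = votes >= 2 and row["gene"] in expressed
            assert net.has_edge(row["miRNA"], row["gene"]) == should
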