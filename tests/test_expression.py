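import numpy as np
import pandas as pd
import pytest

from agpkit.expression import (
    CtTable,
    call_regulation,
    ddct_fold_change,
    normalize_and_cluster,
    overlap_summary,
)
from agpkit.synthetic import CtSimSpec, generate_ct_table


def make_table(effects, noise_sd=0.0, seed=0, genes=("g1", "g2", "g3")):
    ct, _ = generate_ct_table(
        CtSimSpec(genes=genes, effects=effects, noise_sd=noise_sd, seed=seed)
    )
    return CtTable(ct, reference="ref")


class TestFoldChange:
    def test_flat_table_all_ones(self):
        fc = ddct_fold_change(make_table({}))
        assert np.allclose(fc.to_numpy(dtype=float), 1.0)

    def test_one_cycle_shift_doubles(self):
        fc = ddct_fold_change(make_table({("g1", "ABA", 4): 1.0}))
        assert fc.loc["g1", ("ABA", 4)] == pytest.approx(2.0)
        assert fc.loc["g1", ("ABA", 12)] == pytest.approx(1.0)

    def test_planted_effects_recovered_exactly_at_zero_noise(self):
        effects = {
            ("g1", "ABA", 4): 2.0,
            ("g1", "MeJA", 12): -1.5,
            ("g2", "GA", 4): 3.0,
        }
        fc = ddct_fold_change(make_table(effects))
        for (gene, treatment, tp), eff in effects.items():
            assert fc.loc[gene, (treatment, tp)] == pytest.approx(2.0 ** eff)

    def test_reference_gene_always_one(self):
        fc = ddct_fold_change(make_table({("g1", "ABA", 4): 2.0}, noise_sd=0.3))
        assert np.allclose(fc.loc["ref"].to_numpy(dtype=float), 1.0)

    def test_missing_reference_rejected(self):
        ct, _ = generate_ct_table(CtSimSpec(genes=("g1",)))
        with pytest.raises(ValueError):
            CtTable(ct[ct.gene != "ref"], reference="ref")

    def test_missing_control_rejected(self):
        ct, _ = generate_ct_table(CtSimSpec(genes=("g1",)))
        table = CtTable(ct[ct.treatment != "water"], reference="ref")
        with pytest.raises(ValueError):
            ddct_fold_change(table)


class TestRegulationCalls:
    def fc_frame(self, values):
        cols = pd.MultiIndex.from_product([["ABA"], [4, 12]])
        return pd.DataFrame([values], index=["g"], columns=cols)

    @pytest.mark.parametrize(
        "values,direction,onset,recovered",
        [
            ((2.5, 1.1), "up", 4, True),
            ((1.1, 0.95), "nc", None, False),
            ((0.9, 0.4), "down", 12, False),
            ((2.0, 2.0), "up", 4, False),
            ((0.4, 0.6), "down", 4, True),
        ],
    )
    def test_rule_application(self, values, direction, onset, recovered):
        (call,) = call_regulation(self.fc_frame(values))
        assert (call.direction, call.onset, call.recovered) == (direction, onset, recovered)

    def test_monotone_in_fold_change(self):
        rng = np.random.default_rng(0)
        rank = {"down": 0, "nc": 1, "up": 2}
        for _ in range(100):
            base = rng.uniform(0.2, 4.0, size=2)
            raised = base * rng.uniform(1.0, 3.0, size=2)
            (c1,) = call_regulation(self.fc_frame(tuple(base)))
            (c2,) = call_regulation(self.fc_frame(tuple(raised)))
            assert rank[c2.direction] >= rank[c1.direction]

    def test_planted_directions_recovered_over_noise(self):
        effects = {
            ("g1", "ABA", 4): 2.5,
            ("g2", "GA", 12): -2.0,
            ("g3", "MeJA", 4): 2.0,
            ("g3", "MeJA", 12): 2.0,
        }
        table = make_table(effects, noise_sd=0.2, seed=4)
        calls = call_regulation(ddct_fold_change(table))
        got = {
            (c.gene, c.treatment): c.direction for c in calls if c.direction != "nc"
        }
        assert got == {
            ("g1", "ABA"): "up",
            ("g2", "GA"): "down",
            ("g3", "MeJA"): "up",
        }

    def test_reference_gene_never_called(self):
        calls = call_regulation(
            ddct_fold_change(make_table({("g1", "ABA", 4): 3.0}))
        )
        assert all(
            c.direction == "nc" for c in calls if c.gene == "ref"
        )


class TestOverlap:
    def make_calls(self, up_sets):
        from agpkit.expression import RegulationCall

        genes = sorted(set().union(*up_sets.values()) | {"filler"})
        calls = []
        for treatment, ups in up_sets.items():
            for g in genes:
                d = "up" if g in ups else "nc"
                calls.append(RegulationCall(g, treatment, d, 4 if d == "up" else None, False))
        return calls

    def test_identical_sets_concentrate_in_triple(self):
        s = {"a", "b", "c", "d", "e"}
        calls = self.make_calls({"ABA": s, "GA": s, "MeJA": s})
        venn = overlap_summary(calls)
        assert venn["up"]["ABA+GA+MeJA"] == 5
        assert sum(venn["up"].values()) == 5

    def test_disjoint_sets_are_singleton_regions(self):
        calls = self.make_calls({"ABA": {"a"}, "GA": {"b"}, "MeJA": {"c"}})
        venn = overlap_summary(calls)
        assert venn["up"]["ABA"] == venn["up"]["GA"] == venn["up"]["MeJA"] == 1
        assert venn["up"]["ABA+GA+MeJA"] == 0

    def test_regions_sum_to_marginals(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            t: {g for g in genes if rng.random() < 0.4} for t in ("ABA", "GA", "MeJA")
        }
        calls = self.make_calls(sets)
        venn = overlap_summary(calls)
        for t in sets:
            marginal = sum(v for k, v in venn["up"].items() if t in k.split("+"))
            assert marginal == len(sets[t])

    def test_inconsistent_universe_rejected(self):
        from agpkit.expression import RegulationCall

        calls = [
            RegulationCall("a", "ABA", "up", 4, False),
            RegulationCall("b", "GA", "nc", None, False),
        ]
        with pytest.raises(ValueError):
            overlap_summary(calls)


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 2]],
            index=["a", "b", "c"],
        )
        tree = normalize_and_cluster(m)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2]) == {0.0, 1.0}

    def test_anticorrelated_distance_two(self):
        from agpkit.expression import _normalize_rows, _pearson_distance

        m = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["a", "b"])
        norm, _ = _normalize_rows(m)
        d = _pearson_distance(norm.loc["a"].to_numpy(), norm.loc["b"].to_numpy())
        assert d == pytest.approx(2.0)

    def test_planted_clusters_recovered_at_k3(self):
        rng = np.random.default_rng(2)
        patterns = {1: [0, 1, 2, 3, 4], 2: [4, 3, 2, 1, 0], 3: [0, 2, 0, 2, 0]}
        rows, labels, truth = [], [], {}
        for cid, pat in patterns.items():
            for i in range(4):
                g = f"c{cid}_{i}"
                rows.append(np.asarray(pat, dtype=float) + rng.normal(0, 0.05, 5))
                labels.append(g)
                truth[g] = cid
        tree = normalize_and_cluster(pd.DataFrame(rows, index=labels))
        got = tree.cut(3)
        # same planted pattern -> same cluster; different patterns -> different
        for ga in labels:
            for gb in labels:
                assert (got[ga] == got[gb]) == (truth[ga] == truth[gb])

    def test_zero_variance_row_excluded_with_warning(self):
        m = pd.DataFrame(
            [[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["flat", "a", "b"],
        )
        with pytest.warns(UserWarning, match="flat"):
            tree = normalize_and_cluster(m)
        assert tree.excluded == ("flat",)
        assert tree.genes == ("a", "b")

    def test_order_invariant_up_to_ties(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.normal(size=(6, 5)), index=[f"g{i}" for i in range(6)]
        )
        t1 = normalize_and_cluster(m)
        perm = ["g3", "g0", "g5", "g1", "g4", "g2"]
        t2 = normalize_and_cluster(m.loc[perm])
        def merge_heights(t):
            return sorted(np.round(t.linkage[:, 2], 10))
        assert merge_heights(t1) == merge_heights(t2)
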