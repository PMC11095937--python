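import numpy as np

import pytest

from chemosig.chem import (
    GROUPS,
    call_presence,
    cluster_samples,
    concentration_index,
    intersection_counts,
    pairwise_categorize,
    quantile_normalize,
    reduce_rows,
    six_way_categorize,
    unique_compounds,
)
from chemosig.synth import lipocalin_design, simulate_compound_table

from conftest import make_table

G1, G2 = "male-C57BL/6", "female-C57BL/6"


def table_from_counts(counts_matrix):
    """counts_matrix: dict group -> list of detection counts per compound."""
    full = {g: counts_matrix.get(g, [0] * len(next(iter(counts_matrix.values()))))
            for g in GROUPS}
    return make_table(full)


class TestPresence:
    @pytest.mark.parametrize("n_det, present, enriched", [
        (0, False, False),
        (2, False, False),
        (3, True, False),
        (5, True, False),
        (6, True, True),
        (10, True, True),
    ])
    def test_threshold_rules(self, n_det, present, enriched):
        t = table_from_counts({G1: [n_det]})
        calls = call_presence(t)
        row = calls[(calls.compound_id == "c0") & (calls.group == G1)].iloc[0]
        assert row.n_detected == n_det
        assert row.present == present
        assert row.enriched == enriched

    def test_enriched_implies_present(self):
        rng = np.random.default_rng(0)
        t = table_from_counts({g: list(rng.integers(0, 11, 8)) for g in GROUPS})
        calls = call_presence(t)
        assert (calls.loc[calls.enriched, "present"]).all()

    def test_invalid_threshold_order_rejected(self):
        t = table_from_counts({G1: [5]})
        with pytest.raises(ValueError, match="k_enriched"):
            call_presence(t, k_present=6, k_enriched=3)

    def test_adding_a_detection_never_revokes_presence(self):
        for k in range(10):
            a = call_presence(table_from_counts({G1: [k]}))
            b = call_presence(table_from_counts({G1: [k + 1]}))
            get = lambda c: c[(c.group == G1)].iloc[0]
            assert get(b).present >= get(a).present
            assert get(b).enriched >= get(a).enriched


class TestPairwise:
    def test_generic_specific_absent(self):
        t = table_from_counts({G1: [5, 5, 0, 0], G2: [5, 0, 5, 0]})
        cats = pairwise_categorize(call_presence(t), G1, G2)
        assert cats["c0"] == "generic"
        assert cats["c1"] == f"specific:{G1}"
        assert cats["c2"] == f"specific:{G2}"
        assert cats["c3"] == "absent"


class TestSixWay:
    def test_planted_patterns(self):
        male_groups = [g for g in GROUPS if g.startswith("male-")]
        t = table_from_counts({
            g: [
                7,                                  # generic
                7 if g in male_groups else 0,       # sex-specific male
                7 if g.endswith("wild") else 0,     # strain-specific wild
                7 if g == "female-wild" else 0,     # exclusive
                7 if g in (G1, "male-BALB/c") else 0,  # 2 of 3 male strains
                0,                                  # nowhere
            ]
            for g in GROUPS
        })
        cats = six_way_categorize(call_presence(t))
        assert cats.loc["c0", "category"] == "generic"
        assert cats.loc["c0", "pattern"] == "111111"
        assert cats.loc["c1", "category"] == "sex_specific:male"
        assert cats.loc["c2", "category"] == "strain_specific:wild"
        assert cats.loc["c3", "category"] == "exclusive:female-wild"
        assert cats.loc["c4", "category"] == "uncategorized"
        assert cats.loc["c5", "category"] == "uncategorized"

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        t = table_from_counts({g: list(rng.integers(0, 11, 20)) for g in GROUPS})
        cats = six_way_categorize(call_presence(t))
        assert len(cats) == 20
        assert cats["category"].notna().all()

    def test_missing_group_rejected(self):
        t = table_from_counts({G1: [5]})
        calls = call_presence(t)
        with pytest.raises(ValueError, match="missing"):
            six_way_categorize(calls[calls.group == G1])


class TestIntersections:
    def test_uniform_table_single_pattern(self):
        t = table_from_counts({g: [7, 7, 7] for g in GROUPS})
        inter, totals = intersection_counts(call_presence(t))
        assert len(inter) == 1
        assert inter.iloc[0]["count"] == 3
        assert (totals == 3).all()

    def test_singleton_patterns(self):
        t = table_from_counts({G1: [7, 0], "male-BALB/c": [0, 7]})
        inter, _ = intersection_counts(call_presence(t))
        assert len(inter) == 2
        assert set(inter["count"]) == {1}

    def test_planted_design_counts_match_exactly(self):
        from chemosig.synth import CompoundDesign

        design = CompoundDesign(detection_dropout=0.0, seed=6)
        table, truth = simulate_compound_table(design)
        inter, _ = intersection_counts(call_presence(table))
        planted = truth["pattern"].map(
            lambda p: "".join("1" if g in p.split(";") else "0" for g in GROUPS)
        ).value_counts()
        observed = inter.set_index("pattern")["count"]
        assert observed.sort_index().equals(planted.sort_index())


class TestUniqueAndReduce:
    @pytest.mark.parametrize("c1, c2, unique_to_1", [
        (4, 0, True),
        (10, 1, False),
        (3, 0, False),
        (10, 0, True),
    ])
    def test_unique_rule(self, c1, c2, unique_to_1):
        t = table_from_counts({G1: [c1], G2: [c2]})
        uniq = unique_compounds(t, G1, G2)
        assert (("c0" in uniq[G1]) == unique_to_1)

    @pytest.mark.parametrize("c1, c2, kept", [
        (3, 3, False),
        (4, 0, True),
        (0, 4, True),
        (10, 10, True),
        (0, 0, False),
    ])
    def test_row_reduction_rule(self, c1, c2, kept):
        t = table_from_counts({G1: [c1], G2: [c2]})
        reduced = reduce_rows(t, G1, G2)
        assert (("c0" in reduced.abundance.index) == kept)


class TestConcentrationIndex:
    def test_identities(self):
        t = table_from_counts({G1: [10, 10, 10], G2: [10, 10, 0]})
        # equal means; 2:1 means; one-sided
        t.abundance.loc["c1", [c for c in t.abundance.columns
                               if c.startswith(f"{G1}-")]] *= 2.0
        ci = concentration_index(t, G1, G2)
        assert ci.loc["c0", "ci"] == pytest.approx(0.0)
        assert ci.loc["c1", "ci"] == pytest.approx(1.0 / 3.0)
        assert ci.loc["c2", "ci"] == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        t = table_from_counts({g: list(rng.integers(0, 11, 10)) for g in GROUPS})
        a = concentration_index(t, G1, G2)
        b = concentration_index(t, G2, G1)
        assert np.allclose(a["ci"], -b["ci"])
        assert ((a["ci"] >= -1) & (a["ci"] <= 1)).all()

    def test_zero_both_groups_excluded(self):
        t = table_from_counts({G1: [0], G2: [0], "male-wild": [5]})
        ci = concentration_index(t, G1, G2)
        assert "c0" not in ci.index


class TestOracleEquivalence:
    """Exhaustive rule oracle on enumerated detection-count tables: the
    vectorized calls agree with direct per-compound counting loops."""

    def brute_counts(self, table, threshold=0.0):
        out = {}
        groups = table.groups
        for comp in table.abundance.index:
            out[comp] = {}
            for g in GROUPS:
                cols = groups.index[groups == g]
                out[comp][g] = int(
                    sum(table.abundance.loc[comp, c] > threshold for c in cols)
                )
        return out

    def test_random_tables_match_bruteforce(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n_comp = int(rng.integers(1, 9))
            counts = {g: list(rng.integers(0, 3, n_comp)) for g in GROUPS}
            t = make_table(counts, n_per_group=2)
            brute = self.brute_counts(t)
            calls = call_presence(t, k_present=1, k_enriched=2)
            for _, row in calls.iterrows():
                bc = brute[row.compound_id][row.group]
                assert row.n_detected == bc
                assert row.present == (bc >= 1)
                assert row.enriched == (bc >= 2)
            cats = six_way_categorize(calls)
            for comp in t.abundance.index:
                enriched_in = {g for g in GROUPS if brute[comp][g] >= 2}
                cat = cats.loc[comp, "category"]
                sexes = {g.split("-")[0] for g in enriched_in}
                strains = {g.split("-", 1)[1] for g in enriched_in}
                if len(enriched_in) == 6:
                    assert cat == "generic"
                elif len(enriched_in) == 3 and len(sexes) == 1 and len(strains) == 3:
                    assert cat == f"sex_specific:{sexes.pop()}"
                elif len(enriched_in) == 2 and len(strains) == 1 and len(sexes) == 2:
                    assert cat == f"strain_specific:{strains.pop()}"
                elif len(enriched_in) == 1:
                    assert cat == f"exclusive:{enriched_in.pop()}"
                else:
                    assert cat == "uncategorized"


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        t = make_table({G1: [0, 0, 0]}, n_per_group=10)
        # overwrite two samples with known columns
        t.abundance.loc[:, :] = 0.0
        t.abundance.iloc[:, 0] = [1.0, 2.0, 3.0]
        t.abundance.iloc[:, 1] = [4.0, 5.0, 6.0]
        sub = t.abundance.iloc[:, :2]
        qn = quantile_normalize(
            type(t)(abundance=sub, compound_meta=t.compound_meta,
                    sample_meta=t.sample_meta.iloc[:2])
        )
        expect = np.array([2.5, 3.5, 4.5])
        assert np.allclose(qn.abundance.iloc[:, 0], expect)
        assert np.allclose(qn.abundance.iloc[:, 1], expect)

    def test_identical_columns_unchanged(self):
        t = make_table({G1: [5, 5]}, n_per_group=2)
        t.abundance.loc[:, :] = [[1.0] * 12, [7.0] * 12]
        qn = quantile_normalize(t)
        assert np.allclose(qn.abundance, t.abundance)

    def test_single_row_gets_global_mean(self):
        t = make_table({G1: [0]}, n_per_group=2)
        t.abundance.loc[:, :] = np.arange(1.0, 13.0)[None, :]
        qn = quantile_normalize(t)
        assert np.allclose(qn.abundance.to_numpy(), np.arange(1.0, 13.0).mean())

    def test_idempotence(self):
        rng = np.random.default_rng(23)
        t = make_table({g: list(rng.integers(0, 11, 6)) for g in GROUPS})
        t.abundance.loc[:, :] = rng.gamma(2.0, 50.0, t.abundance.shape)
        once = quantile_normalize(t)
        twice = quantile_normalize(once)
        assert np.allclose(once.abundance, twice.abundance, atol=1e-9)

    def test_column_multisets_identical(self):
        rng = np.random.default_rng(29)
        t = make_table({g: [0] * 5 for g in GROUPS})
        t.abundance.loc[:, :] = rng.gamma(2.0, 50.0, t.abundance.shape)
        qn = quantile_normalize(t)
        ref = np.sort(qn.abundance.iloc[:, 0].to_numpy())
        for j in range(qn.abundance.shape[1]):
            assert np.allclose(np.sort(qn.abundance.iloc[:, j].to_numpy()), ref)


class TestClustering:
    def test_disjoint_markers_cluster_perfectly(self):
        # each group has its own exclusive marker compounds, no noise
        counts = {}
        for i, g in enumerate(GROUPS):
            counts[g] = [10 if j // 2 == i else 0 for j in range(12)]
        t = make_table(counts)
        result = cluster_samples(t, k=6, normalize=False)
        assert result.agreement == 1.0

    def test_constant_table_rejected(self):
        t = make_table({g: [10] * 2 for g in GROUPS})
        with pytest.raises(ValueError, match="constant|degenerate"):
            cluster_samples(t, normalize=False)

    def test_lipocalin_like_table_recovers_groups(self):
        """27 marker proteins, 60 samples, 10% dropout: nearly every sample
        joins the cluster dominated by its own sex/strain group."""
        table, _ = simulate_compound_table(lipocalin_design(seed=3))
        result = cluster_samples(table, family="lipocalin", k=6)
        assert result.n_agreeing >= 55
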