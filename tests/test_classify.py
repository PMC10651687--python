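import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmtcycle import classify as cls
from tmtcycle import diffabund as da
from tmtcycle import normalize as nm
from tmtcycle import syndata as sd
from tmtcycle.exceptions import DataError, DesignError, ParameterError

from conftest import make_matrix


def contrast_from_q(qs, label="c"):
    """Build a ContrastResult carrying given q-values (p set equal to q)."""
    table = pd.DataFrame(
        {
            "feature_id": [f"P{i:03d}" for i in range(len(qs))],
            "log2fc": [-1.0] * len(qs),  # KO higher than WT -> direction "up"
            "t": 0.0,
            "p": qs,
            "q": qs,
            "n_a": 4,
            "n_b": 4,
            "zero_variance": False,
        }
    )
    return da.ContrastResult(label=label, table=table)


class TestCallDependent:
    def test_boundary_strictly_below(self):
        dep = cls.call_dependent(contrast_from_q([0.049]))
        assert dep["dependent"].iloc[0]

    def test_boundary_at_alpha_not_dependent(self):
        dep = cls.call_dependent(contrast_from_q([0.05]))
        assert not dep["dependent"].iloc[0]

    def test_direction_from_sign(self):
        contrast = contrast_from_q([0.01, 0.01])
        contrast.table.loc[1, "log2fc"] = 2.0  # WT above KO -> down in KO
        dep = cls.call_dependent(contrast)
        assert list(dep["direction"]) == ["up", "down"]

    def test_recall_and_fdr_on_planted_labels(self):
        # calibrated noise (see decisions ledger): sigma=0.15 gives the
        # near-complete recall the decision rule is specified to reach
        params = sd.SimParams(
            n_proteins=3000, n_genes=5, sigma=0.15, frac_dependent=0.1,
            frac_flagged=0.0, seed=17,
        )
        design = sd.generate_design(params)
        matrix, truth = sd.simulate_proteome(design, params)
        norm = nm.reference_normalize(matrix, design)
        dep = cls.call_dependent(
            da.pairwise_ttest(norm, design, "WT_AL", "KO_AL")
        )
        called = dep["dependent"]
        planted = truth["dependent"]
        recall = (called & planted).sum() / planted.sum()
        fdr = (called & ~planted).sum() / max(called.sum(), 1)
        assert recall >= 0.95
        assert fdr <= 0.05 + 0.03


RESCUE_ORACLE = {
    # (sig WTvsKO, sig REvsKO, sig WTvsRE) -> (dichotomy, threeway)
    (False, False, False): ("not_applicable", "not_applicable"),
    (False, False, True): ("not_applicable", "not_applicable"),
    (False, True, False): ("not_applicable", "not_applicable"),
    (False, True, True): ("not_applicable", "not_applicable"),
    (True, False, False): ("nonrescued", "nonrescued"),
    (True, False, True): ("nonrescued", "nonrescued"),
    (True, True, False): ("rescued", "rescued"),
    (True, True, True): ("nonrescued", "partial"),
}


class TestClassifyRescue:
    def _classify(self, q_triple, mode):
        q1, q2, q3 = q_triple
        dep = cls.call_dependent(contrast_from_q([q1], "WT:KO"))
        return cls.classify_rescue(
            dep,
            contrast_from_q([q2], "RE:KO"),
            contrast_from_q([q3], "WT:RE"),
            mode=mode,
        )["rescue"].iloc[0]

    def test_rescued_example(self):
        assert self._classify((0.01, 0.02, 0.50), "dichotomy") == "rescued"

    def test_nonrescued_example(self):
        assert self._classify((0.01, 0.80, 0.01), "dichotomy") == "nonrescued"

    def test_partial_mode_difference(self):
        assert self._classify((0.01, 0.02, 0.01), "dichotomy") == "nonrescued"
        assert self._classify((0.01, 0.02, 0.01), "threeway") == "partial"

    @pytest.mark.parametrize(
        "pattern", list(itertools.product([False, True], repeat=3))
    )
    def test_exhaustive_truth_table(self, pattern):
        qs = tuple(0.01 if sig else 0.5 for sig in pattern)
        expected_dich, expected_three = RESCUE_ORACLE[pattern]
        assert self._classify(qs, "dichotomy") == expected_dich
        assert self._classify(qs, "threeway") == expected_three

    def test_dichotomy_partitions_dependent(self):
        rng = np.random.default_rng(0)
        qs = rng.random(200)
        dep = cls.call_dependent(contrast_from_q(list(qs)))
        labels = cls.classify_rescue(
            dep,
            contrast_from_q(list(rng.random(200))),
            contrast_from_q(list(rng.random(200))),
        )
        n_dep = int(labels["dependent"].sum())
        rescued = (labels["rescue"] == "rescued").sum()
        nonrescued = (labels["rescue"] == "nonrescued").sum()
        assert rescued + nonrescued == n_dep
        assert (
            (labels["rescue"] == "not_applicable") == ~labels["dependent"]
        ).all()

    def test_missing_contrast_feature(self):
        dep = cls.call_dependent(contrast_from_q([0.01, 0.02]))
        with pytest.raises(DataError):
            cls.classify_rescue(
                dep, contrast_from_q([0.01]), contrast_from_q([0.01, 0.5])
            )

    def test_rescue_accuracy_on_planted_labels(self):
        params = sd.SimParams(
            n_proteins=2000, n_genes=5, sigma=0.15, frac_dependent=0.1,
            frac_rescued_given_dependent=0.5, frac_flagged=0.0, seed=23,
        )
        design = sd.generate_design(params)
        matrix, truth = sd.simulate_proteome(design, params)
        norm = nm.reference_normalize(matrix, design)
        dep = cls.call_dependent(
            da.pairwise_ttest(norm, design, "WT_AL", "KO_AL")
        )
        labels = cls.classify_rescue(
            dep,
            da.pairwise_ttest(norm, design, "RE_AL", "KO_AL"),
            da.pairwise_ttest(norm, design, "WT_AL", "RE_AL"),
        )
        called_dep = labels.index[labels["dependent"]]
        truth_label = np.where(truth.loc[called_dep, "rescued"],
                               "rescued", "nonrescued")
        acc = (labels.loc[called_dep, "rescue"] == truth_label).mean()
        assert acc >= 0.9

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        qs = list(rng.random(50))
        dep = cls.call_dependent(contrast_from_q(qs))
        q2, q3 = list(rng.random(50)), list(rng.random(50))
        labels = cls.classify_rescue(
            dep, contrast_from_q(q2), contrast_from_q(q3)
        )
        perm = rng.permutation(50)
        def permuted(vals):
            c = contrast_from_q([vals[i] for i in perm])
            c.table["feature_id"] = [f"P{i:03d}" for i in perm]
            return c
        dep_p = cls.call_dependent(permuted(qs))
        labels_p = cls.classify_rescue(
            dep_p, permuted(q2), permuted(q3)
        )
        pd.testing.assert_frame_equal(
            labels.sort_index(), labels_p.sort_index()
        )


class TestFeedingResponsive:
    def test_planted_feeding_effect_recovered(self):
        params = sd.SimParams(
            n_proteins=2000, n_genes=5, sigma=0.15, frac_dependent=0.0,
            frac_feeding_responsive={"WT": 0.0, "KO": 0.0, "RE": 0.1},
            frac_flagged=0.0, seed=31,
        )
        design = sd.generate_design(params)
        matrix, truth = sd.simulate_proteome(design, params)
        norm = nm.reference_normalize(matrix, design)
        resp = cls.call_feeding_responsive(norm, design, "RE")
        planted = truth["feeding_responsive_RE"]
        recall = (resp["responsive"] & planted).sum() / planted.sum()
        assert recall >= 0.95
        # no planted feeding effects in WT -> false-call rate bounded
        resp_wt = cls.call_feeding_responsive(norm, design, "WT")
        fdr_wt = resp_wt["responsive"].sum() / len(resp_wt)
        assert fdr_wt <= 0.05

    def test_alpha_zero_empty(self, normalized, bundle):
        resp = cls.call_feeding_responsive(
            normalized, bundle["design"], "WT", alpha=0.0
        )
        assert not resp["responsive"].any()

    def test_relaxed_superset(self, normalized, bundle):
        resp = cls.call_feeding_responsive(normalized, bundle["design"], "KO")
        assert (resp["responsive"] <= resp["responsive_relaxed"]).all()

    def test_missing_arm(self, normalized, bundle):
        design = bundle["design"]
        design = design[
            ~((design["genotype"] == "WT") & (design["feeding"] == "TRF"))
        ]
        with pytest.raises(DesignError, match="TRF"):
            cls.call_feeding_responsive(normalized, design, "WT")


class TestCrossTissueOverlap:
    def test_disjoint(self):
        out = cls.cross_tissue_overlap({"a"}, {"b"}, {"a", "b"})
        assert out["overlap"] == 0

    def test_equal_sets(self):
        out = cls.cross_tissue_overlap(
            {"a", "b", "c"}, {"a", "b", "c"}, {"a", "b", "z"}
        )
        assert out["overlap"] == 2  # |{a,b,c} ∩ detected_both|

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        both=st.sets(st.integers(0, 30)),
    )
    def test_matches_brute_force(self, a, b, both):
        out = cls.cross_tissue_overlap(a, b, both)
        assert out["overlap"] == len({x for x in both if x in a and x in b})
        assert out["a_only"] == len({x for x in both if x in a and x not in b})
        assert out["b_only"] == len({x for x in both if x in b and x not in a})


def fisher_oracle(table):
    """Exhaustive enumeration of the conditional (hypergeometric) null."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = {x: stats.hypergeom.pmf(x, n, col1, row1) for x in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-10))


class TestSecretedFraction:
    def test_enriched_example(self):
        # 20/100 secreted affected vs 30/900 non-secreted affected
        universe = {f"u{i}" for i in range(1000)}
        secreted = {f"u{i}" for i in range(100)}
        affected = {f"u{i}" for i in range(20)} | {
            f"u{i}" for i in range(100, 130)
        }
        res = cls.secreted_fraction_test(affected, secreted, universe)
        assert res.odds_ratio > 1
        oracle_p = fisher_oracle(res.table)
        assert res.p == pytest.approx(oracle_p, rel=1e-6)

    def test_empty_affected_p_one(self):
        universe = {f"u{i}" for i in range(50)}
        secreted = {f"u{i}" for i in range(10)}
        res = cls.secreted_fraction_test(set(), secreted, universe)
        assert res.p == 1.0
        assert res.pct_affected_secreted == 0.0

    def test_secreted_must_be_subset(self):
        with pytest.raises(ParameterError):
            cls.secreted_fraction_test({"a"}, {"zz"}, {"a", "b"})

    def test_empty_universe(self):
        with pytest.raises(ParameterError):
            cls.secreted_fraction_test(set(), set(), set())

    def test_enrichment_parameter_recovery(self):
        # planted odds multiplier recovered across replicates
        ors = []
        for seed in range(8):
            params = sd.SimParams(
                n_proteins=8000, n_genes=5, frac_dependent=0.3,
                frac_secreted=0.1, secreted_enrichment=4.0, seed=seed + 100,
            )
            design = sd.generate_design(params)
            _, truth = sd.simulate_proteome(design, params)
            res = cls.secreted_fraction_test(
                set(truth.index[truth["dependent"]]),
                set(truth.index[truth["secreted"]]),
                set(truth.index),
            )
            ors.append(res.odds_ratio)
        assert np.mean(ors) == pytest.approx(4.0, rel=0.15)


class TestSubunitSetAverage:
    def test_singleton_identity(self, normalized):
        fid = normalized.feature_ids[0]
        out = cls.subunit_set_average(normalized, [fid])
        pd.testing.assert_series_equal(
            out, normalized.values.loc[fid], check_names=False
        )

    def test_symmetric_pair_zero(self):
        vals = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        matrix = make_matrix(vals, ["s1", "s2", "s3"], scale="log2-normalized")
        out = cls.subunit_set_average(matrix, ["P000", "P001"])
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_matches_direct_mean_oracle(self, normalized):
        rng = np.random.default_rng(9)
        members = list(
            rng.choice(normalized.feature_ids, size=12, replace=False)
        )
        out = cls.subunit_set_average(normalized, members)
        oracle = normalized.values.loc[sorted(set(members))].to_numpy().mean(axis=0)
        np.testing.assert_allclose(out.to_numpy(), oracle, atol=1e-12)

    def test_missing_members_listed(self, normalized):
        with pytest.raises(DataError, match="NOPE"):
            cls.subunit_set_average(normalized, ["NOPE"])

    def test_empty_set(self, normalized):
        with pytest.raises(ParameterError):
            cls.subunit_set_average(normalized, [])


class TestSummarizePercent:
    @pytest.mark.parametrize(
        "part,whole,decimals,expected",
        [
            (674, 5613, 2, 12.01),
            (80, 3114, 2, 2.57),
            (502, 5613, 2, 8.94),
            (113, 5613, 2, 2.01),
            (9, 23, 0, 39.0),
            (0, 10, 2, 0.0),
            (10, 10, 2, 100.0),
        ],
    )
    def test_values(self, part, whole, decimals, expected):
        assert cls.summarize_percent(part, whole, decimals) == expected

    def test_half_up_rounding(self):
        assert cls.summarize_percent(1, 8, 1) == 12.5
        assert cls.summarize_percent(1, 800, 2) == 0.13  # 0.125 rounds up

    def test_whole_zero(self):
        with pytest.raises(ParameterError):
            cls.summarize_percent(0, 0)

    def test_part_exceeds_whole(self):
        with pytest.raises(ParameterError):
            cls.summarize_percent(5, 4)

    @settings(max_examples=50, deadline=None)
    @given(
        part=st.integers(0, 10_000),
        whole=st.integers(1, 10_000),
        decimals=st.integers(0, 4),
    )
    def test_complement_rounding_bound(self, part, whole, decimals):
        part = min(part, whole)
        total = cls.summarize_percent(part, whole, decimals) + \
            cls.summarize_percent(whole - part, whole, decimals)
        bound = 10.0 ** (1 - decimals)
        assert 100 - bound <= total <= 100 + bound
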