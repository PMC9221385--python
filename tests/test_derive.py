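import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import baitsig as bs
from baitsig.io import ValidationError
from conftest import random_log2_matrix
from oracles import pearson_brute


class TestCorrelateBait:
    def test_identical_row_has_r_one_and_passes(self, toy_matrix):
        res = bs.correlate_bait(toy_matrix, "bait")
        assert res.loc["twin", "r"] == pytest.approx(1.0)
        assert bool(res.loc["twin", "passes"])

    def test_anticorrelated_row_fails_direction_filter(self, toy_matrix):
        res = bs.correlate_bait(toy_matrix, "bait")
        assert res.loc["anti", "r"] == pytest.approx(-1.0)
        assert not bool(res.loc["anti", "passes"])
        both = bs.correlate_bait(toy_matrix, "bait",
                                 bs.AnalysisConfig(direction="both"))
        assert bool(both.loc["anti", "passes"])

    def test_bait_excluded_from_own_result(self, toy_matrix):
        res = bs.correlate_bait(toy_matrix, "bait")
        assert "bait" not in res.index

    def test_constant_genes_excluded_with_warning(self, toy_matrix, caplog):
        with caplog.at_level("WARNING", logger="baitsig"):
            res = bs.correlate_bait(toy_matrix, "bait")
        assert "zero" not in res.index and "flat" not in res.index
        assert any("constant" in r.message for r in caplog.records)

    def test_missing_bait_named_in_error(self, toy_matrix):
        with pytest.raises(ValidationError, match="EPAS1"):
            bs.correlate_bait(toy_matrix, "EPAS1")

    def test_too_few_samples_rejected(self):
        m = bs.ExpressionMatrix(
            values=pd.DataFrame(np.arange(6.0).reshape(2, 3),
                                index=["a", "b"], columns=["s1", "s2", "s3"]),
            scale="log2")
        with pytest.raises(ValidationError, match="4 samples"):
            bs.correlate_bait(m, "a")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pearson_formula(self, seed):
        """r and the t-transform p agree with definitional evaluation to
        1e-10 on small random matrices."""
        rng = np.random.default_rng(seed)
        m = random_log2_matrix(rng, rng.integers(3, 10), rng.integers(4, 10))
        bait = m.gene_ids[0]
        res = bs.correlate_bait(m, bait)
        x = m.values.loc[bait].tolist()
        for g in res.index:
            r_exp, p_exp = pearson_brute(x, m.values.loc[g].tolist())
            assert res.loc[g, "r"] == pytest.approx(r_exp, abs=1e-10)
            assert res.loc[g, "p"] == pytest.approx(p_exp, abs=1e-10)


class TestBaitSetsAndOverlaps:
    def test_one_table_per_bait(self, derived):
        assert derived.bait_sets_.n_baits == 10
        assert set(derived.bait_sets_.tables) == set(derived.bait_sets_.bait_ids)

    def test_single_bait_counts_are_binary(self, toy_matrix):
        sets = bs.build_bait_sets(toy_matrix, ["bait"])
        counts = bs.count_overlaps(sets)
        assert set(counts.unique()) <= {0, 1}

    def test_missing_baits_all_listed(self, toy_matrix):
        with pytest.raises(ValidationError) as exc:
            bs.build_bait_sets(toy_matrix, ["bait", "GHOST1", "GHOST2"])
        assert "GHOST1" in str(exc.value) and "GHOST2" in str(exc.value)

    def test_high_module_r_saturates_counts(self):
        """At module_r=0.9 every module gene passes for every bait."""
        m, _, truth = bs.generate_dataset(bs.SyntheticConfig(seed=2, module_r=0.9))
        sets = bs.build_bait_sets(m, list(truth.bait_ids))
        counts = bs.count_overlaps(sets)
        assert (counts.loc[list(truth.module_ids)] == 10).all()

    def test_overlap_counting_boundaries(self):
        """A gene passing 5 of 10 baits is kept at k=5; 4 of 10 is not."""
        tables = {}
        for i in range(10):
            passing = ["five"] if i < 5 else []
            if i < 4:
                passing.append("four")
            idx = ["five", "four", "none"]
            tables[f"b{i}"] = pd.DataFrame(
                {"r": 0.9, "p": 0.0001, "passes": [g in passing for g in idx]}, index=idx)
        sets = bs.BaitCorrelationSets(bait_ids=tuple(tables), tables=tables)
        counts = bs.count_overlaps(sets)
        assert counts.loc["five"] == 5 and counts.loc["four"] == 4 and counts.loc["none"] == 0
        sig = bs.assemble_signature(counts, overlap_k=5)
        assert list(sig.members) == ["five"]


class TestAssembleSignature:
    COUNTS = pd.Series({"a": 10, "b": 9, "c": 5, "d": 4})

    def test_threshold_and_ordering(self):
        sig = bs.assemble_signature(self.COUNTS, overlap_k=5, bait_ids=["bait0"] * 0)
        assert list(sig.members) == ["a", "b", "c"]

    def test_top_ranking_threshold(self):
        sig = bs.assemble_signature(self.COUNTS, overlap_k=9)
        assert list(sig.members) == ["a", "b"]

    def test_all_below_threshold_gives_empty_signature(self):
        sig = bs.assemble_signature(pd.Series({"a": 2, "b": 1}), overlap_k=5,
                                    bait_ids=["x"] * 0)
        assert len(sig) == 0

    def test_k_above_bait_count_is_error(self):
        with pytest.raises(ValidationError, match="exceeds"):
            bs.assemble_signature(self.COUNTS, overlap_k=11, bait_ids=[f"b{i}" for i in range(10)])

    def test_baits_removed_and_recorded(self):
        counts = pd.Series({"a": 10, "bait1": 10})
        sig = bs.assemble_signature(counts, overlap_k=5,
                                    bait_ids=[f"bait{i}" for i in range(1, 11)])
        assert list(sig.members) == ["a"]
        assert sig.provenance["baits_removed_from_members"]

    def test_tie_break_is_lexicographic(self):
        counts = pd.Series({"zz": 7, "aa": 7, "mm": 9})
        sig = bs.assemble_signature(counts, overlap_k=5)
        assert list(sig.members) == ["mm", "aa", "zz"]


class TestSingleGeneScan:
    def test_self_excluded(self, toy_matrix):
        res = bs.correlate_single_gene_scan(toy_matrix, "noisy")
        assert "noisy" not in res.index

    def test_null_fraction_near_zero(self):
        rng = np.random.default_rng(12)
        m = random_log2_matrix(rng, 200, 50)
        scan = bs.correlate_single_gene_scan(m, m.gene_ids[0])
        sig = bs.Signature("random", tuple(m.gene_ids[1:101]))
        assert bs.signature_correlated_fraction(scan, sig) < 0.05

    def test_module_carrier_recovers_planted_genes(self):
        """Scanning a gene that carries the latent hypoxia factor flags at
        least 90% of the planted module (the EPAS1-style correlate scan)."""
        m, _, truth = bs.generate_dataset(bs.SyntheticConfig(seed=4, module_r=0.8))
        scan = bs.correlate_single_gene_scan(m, truth.bait_ids[0])
        sig = bs.Signature("module", truth.module_ids)
        assert bs.signature_correlated_fraction(scan, sig) >= 0.9


class TestBaitConsistencyRank:
    @staticmethod
    def _dataset(seed, shift_genes=(), shift=2.0, n=30, n_genes=30):
        # unit residual noise, matching the generator's stated world
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        samples = [f"s{i:03d}" for i in range(2 * n)]
        m = bs.ExpressionMatrix(values=pd.DataFrame(
            rng.normal(8, 1, size=(n_genes, 2 * n)), index=genes, columns=samples),
            scale="log2")
        labels = pd.Series([True] * n + [False] * n, index=m.sample_ids)
        vals = m.values.copy()
        for g in shift_genes:
            vals.loc[g, labels[labels].index] += shift
        return bs.ExpressionMatrix(values=vals, scale="log2"), labels

    def test_consistent_gene_ranks_first(self):
        """A gene shifted +2 log2 in hypoxic samples of all three datasets
        gets consistency 3 and outranks unshifted genes."""
        datasets = [self._dataset(s, shift_genes=["g000"]) for s in (1, 2, 3)]
        out = bs.bait_consistency_rank(datasets, [f"g{i:03d}" for i in range(10)])
        assert out.iloc[0]["gene"] == "g000"
        assert out.iloc[0]["consistency_count"] == 3
        assert (out.iloc[1:]["consistency_count"] == 0).all()

    def test_identical_distributions_not_counted(self):
        datasets = [self._dataset(5)]
        out = bs.bait_consistency_rank(datasets, ["g001"])
        assert out.iloc[0]["consistency_count"] == 0

    def test_sort_contract_with_ties(self):
        datasets = [self._dataset(s, shift_genes=["g002", "g001"]) for s in (7, 8)]
        out = bs.bait_consistency_rank(datasets, ["g000", "g001", "g002"])
        assert list(out["gene"][:2]) == ["g001", "g002"]  # tie broken lexicographically

    def test_missing_labels_rejected(self):
        m, _ = self._dataset(9)
        with pytest.raises(ValidationError, match="hypoxia"):
            bs.bait_consistency_rank([(m, None)], ["g000"])


class TestDeriverEstimator:
    def test_sklearn_params_protocol(self):
        est = bs.BaitSignatureDeriver(baits=["a"], r_threshold=0.5)
        est2 = clone(est)
        assert est2.get_params()["r_threshold"] == 0.5
        est2.set_params(min_overlap_k=3)
        assert est2.min_overlap_k == 3

    def test_fit_requires_baits(self, toy_matrix):
        with pytest.raises(ValidationError, match="baits"):
            bs.BaitSignatureDeriver().fit(toy_matrix)

    def test_get_signature_at_custom_k(self, derived):
        sig_all = derived.get_signature(overlap_k=1)
        assert set(derived.signature_.members) <= set(sig_all.members)

    def test_functional_wrapper_matches_estimator(self, default_dataset, derived):
        m, _, truth = default_dataset
        sig = bs.derive_signature(m, list(truth.bait_ids))
        assert sig.members == derived.signature_.members
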