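from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mirrorsep as ms
from mirrorsep.group_stats import mann_whitney


def oracle_permutation_p(x, y):
    """Exhaustive two-sided permutation p of the Mann-Whitney U statistic.

    Independent route: U is computed by direct pairwise comparison counts
    (ties worth 1/2), not by ranking.
    """
    pooled = list(x) + list(y)
    n = len(x)
    total = len(pooled)

    def u_of(indices):
        group1 = [pooled[i] for i in indices]
        group2 = [pooled[i] for i in range(total) if i not in set(indices)]
        u = 0.0
        for a in group1:
            for b in group2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mid = n * (total - n) / 2.0
    dev_obs = abs(u_of(tuple(range(n))) - mid)
    hits = sum(abs(u_of(idx) - mid) >= dev_obs - 1e-9
               for idx in combinations(range(total), n))
    return hits / comb(total, n)


class TestMannWhitney:
    def test_fully_separated_groups_match_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [11, 12, 13, 14, 15]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(oracle_permutation_p(x, y))
        assert p == pytest.approx(2 / comb(10, 5))
        assert p < 0.05

    def test_identical_groups_not_significant(self):
        summary = ms.term_significance([5, 5, 5], [5, 5, 5])
        assert not summary.significant
        assert summary.p_value == 1.0

    def test_symmetry_and_reciprocal_ratio(self):
        x = [1.0, 2.0, 3.5, 4.0]
        y = [2.5, 5.0, 6.0, 7.5]
        a = ms.term_significance(x, y)
        b = ms.term_significance(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.mean_ratio == pytest.approx(1.0 / b.mean_ratio)

    @given(st.integers(3, 7), st.integers(3, 7),
           st.lists(st.integers(0, 9), min_size=14, max_size=14),
           )
    @settings(max_examples=60, deadline=None)
    def test_small_samples_match_enumeration(self, n, m, values):
        x = values[:n]
        y = values[n:n + m]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(oracle_permutation_p(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 12)
        p1 = ms.term_significance(x, y).p_value
        p2 = ms.term_significance(np.exp(x), np.exp(y)).p_value
        assert p1 == pytest.approx(p2)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            ms.term_significance([1, 2], [1, 2, 3])

    def test_welch_flag(self):
        x = [1.0, 1.1, 0.9, 1.05, 0.95]
        y = [2.0, 2.1, 1.9, 2.05, 1.95]
        summary = ms.term_significance(x, y, method="welch")
        assert summary.significant


class TestNmtNormalize:
    def test_three_domain_example(self):
        means = pd.DataFrame({"term": [2.0, -4.0, 1.0]},
                             index=["d1", "d2", "d3"])
        nmt = ms.nmt_normalize(means)
        assert nmt["term"].tolist() == pytest.approx([0.5, -1.0, 0.25])

    def test_single_domain(self):
        nmt = ms.nmt_normalize(pd.DataFrame({"t": [-7.0]}, index=["d"]))
        assert nmt["t"].iloc[0] == pytest.approx(-1.0)

    def test_bounds_and_extremum(self):
        rng = np.random.default_rng(12)
        means = pd.DataFrame(rng.normal(0, 10, size=(6, 4)),
                             columns=list("abcd"))
        nmt = ms.nmt_normalize(means)
        assert (nmt.abs().values <= 1.0 + 1e-12).all()
        for col in nmt.columns:
            assert nmt[col].abs().max() == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        means = pd.DataFrame(rng.normal(0, 5, size=(5, 3)), columns=list("xyz"))
        once = ms.nmt_normalize(means)
        twice = ms.nmt_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_term_rejected(self):
        means = pd.DataFrame({"good": [1.0, 2.0], "zero": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero"):
            ms.nmt_normalize(means)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, _ = ms.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = ms.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 7.1, 6.3, 8.0, 9.9, 0.5])
        y = np.array([2.0, 3.1, 2.9, 4.8, 5.2, 6.0, 6.6, 7.9, 9.1, 1.1])
        r, _ = ms.pearson(x, y)
        oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.pearson([1, 1, 1], [1, 2, 3])


def _toy_tables(n_domains=3, n_per_group=10, shift=3.0, seed=0):
    """Domain tables with a shifted 'sep' term and a constant 'ref' term."""
    rng = np.random.default_rng(seed)
    tables = {}
    for d in range(n_domains):
        proper = pd.DataFrame({
            "label": "proper",
            "sep": rng.normal(0.0, 1.0, n_per_group),
            "noise": rng.normal(0.0, 1.0, n_per_group),
            "ref": 4.25,
        })
        mirror = pd.DataFrame({
            "label": "mirror",
            "sep": rng.normal(shift, 1.0, n_per_group),
            "noise": rng.normal(0.0, 1.0, n_per_group),
            "ref": 4.25,
        })
        tables[f"d{d}"] = pd.concat([proper, mirror], ignore_index=True)
    return tables


class TestSignificanceMatrix:
    def test_shape_and_pattern(self):
        tables = _toy_tables()
        flags, pvals = ms.significance_matrix(tables)
        assert flags.shape == (3, 3)
        assert pvals.shape == (3, 3)
        assert flags["sep"].all()
        assert not flags["ref"].any()

    def test_constant_column_never_significant(self):
        flags, pvals = ms.significance_matrix(_toy_tables())
        assert (pvals["ref"] == 1.0).all()

    def test_propagates_small_group_error(self):
        bad = {"d0": pd.DataFrame({"label": ["proper", "proper", "mirror",
                                             "mirror", "mirror"],
                                   "t": [1.0, 2, 3, 4, 5]})}
        with pytest.raises(ValueError):
            ms.significance_matrix(bad)


class TestDomainSummaries:
    def _model_tables(self):
        return {
            "d0": pd.DataFrame({
                "label": ["proper"] * 3 + ["mirror"] * 3,
                "rmsd_to_ref": [2.0, 2.5, 1.5, 8.0, 9.0, 7.0],
                "phi_plus_ratio": [0.02, 0.05, 0.0, 0.9, 0.95, 1.0],
            }),
            "d1": pd.DataFrame({
                "label": ["proper"] * 3 + ["mirror"] * 3,
                "rmsd_to_ref": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
                "phi_plus_ratio": [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            }),
        }

    def test_structural_difference(self):
        summaries = ms.domain_summaries(self._model_tables())
        by_id = {s.domain: s for s in summaries}
        assert by_id["d0"].structural_difference == pytest.approx(2.0 / 8.0)
        assert by_id["d1"].structural_difference == pytest.approx(1.0)

    def test_counts_match_flag_row_sums(self):
        tables = _toy_tables()
        flags, _ = ms.significance_matrix(tables)
        model_tables = {
            d: pd.DataFrame({
                "label": t["label"],
                "rmsd_to_ref": np.linspace(1, 2, len(t)),
                "phi_plus_ratio": np.linspace(0, 1, len(t)),
            }) for d, t in tables.items()
        }
        summaries = ms.domain_summaries(model_tables, flags)
        for s in summaries:
            assert s.n_significant_terms == flags.loc[s.domain].sum()

    def test_empty_group_rejected(self):
        bad = {"d": pd.DataFrame({"label": ["proper"] * 4,
                                  "rmsd_to_ref": [1.0] * 4,
                                  "phi_plus_ratio": [0.1] * 4})}
        with pytest.raises(ValueError):
            ms.domain_summaries(bad)


def test_mixed_difficulty_gives_negative_terms_vs_similarity_correlation(tables):
    """Harder domains (structural_difference near 1) should show fewer
    significant terms: the correlation across a mixed batch is negative."""
    difficulty = [(1.0, 0.0), (4.0, 0.0), (10.0, 0.1), (25.0, 0.3),
                  (60.0, 0.6), (90.0, 0.9)]
    flags_tables = {}
    model_tables = {}
    from conftest import MINI_BUNDLE_SEQ
    for seed, (sigma, frac) in enumerate(difficulty):
        spec = ms.EnsembleSpec(sequence=MINI_BUNDLE_SEQ, n_proper=8, n_mirror=8,
                               dihedral_sigma=sigma, outlier_fraction=frac,
                               seed=seed)
        ens = ms.make_ensemble(spec, domain_id=f"dom{seed}")
        rows = []
        for lm in ens.models:
            rows.append({
                "label": lm.true_label,
                "rmsd_to_ref": lm.rmsd_to_reference,
                "rama": ms.rama_score(lm.model, tables),
                "p_aa_p": ms.p_aa_p_score(lm.model, tables),
                "phi_plus_ratio": ms.phi_plus_ratio(lm.model).phi_plus_ratio,
            })
        df = pd.DataFrame(rows)
        flags_tables[ens.domain_id] = df[["label", "rama", "p_aa_p",
                                          "phi_plus_ratio"]]
        model_tables[ens.domain_id] = df[["label", "rmsd_to_ref",
                                          "phi_plus_ratio"]]
    flags, _ = ms.significance_matrix(flags_tables)
    summaries = ms.domain_summaries(model_tables, flags)
    n_sig = [s.n_significant_terms for s in summaries]
    similarity = [s.structural_difference for s in summaries]
    r, _ = ms.pearson(n_sig, similarity)
    assert r < 0
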