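"""Dependency correlations, codependency expansion, mutation association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telomaint.dependency import (
    AssociationResult,
    cluster_codependency,
    codependency_expand,
    correlate,
    filter_exon_inclusion,
    filter_expression,
    filter_methylation,
    mutation_association,
    pairwise_r2,
    rank_biserial,
    signed_q,
)


def brute_force_expand(seed, matrix, top_k=5, iterations=4):
    """Independent mutual-top-k oracle: explicit pair enumeration with
    per-row sorting, no shared code with the implementation."""
    genes = list(matrix.index)
    x = matrix.to_numpy(dtype=float)
    n = len(genes)
    r = np.corrcoef(x)
    r2 = np.round(r * r, 12)  # same tie-stabilizing precision as the package
    cutoffs = []
    for i in range(n):
        row = sorted((r2[i, j] for j in range(n) if j != i), reverse=True)
        cutoffs.append(row[top_k - 1] if top_k <= len(row) else -np.inf)
    members = set(seed)
    for _ in range(iterations):
        new = set(members)
        for xi in range(n):
            if genes[xi] not in members:
                continue
            for yi in range(n):
                if yi == xi:
                    continue
                if r2[xi, yi] >= cutoffs[xi] and r2[xi, yi] >= cutoffs[yi]:
                    new.add(genes[yi])
        if new == members:
            break
        members = new
    return members


class TestCorrelate:
    def test_self_correlation(self, dependency_sim):
        dep = dependency_sim["dependency"]
        target = dep.iloc[0]
        res = {r.feature: r for r in correlate(dep, target)}
        top = res[dep.index[0]]
        assert top.effect == pytest.approx(1.0)
        assert top.p == 0.0

    def test_orthogonal_rows_r_zero(self):
        dep = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0]], index=["g"], columns=list("abcd")
        )
        target = pd.Series([1.0, 1.0, -1.0, -1.0], index=list("abcd"))
        res = correlate(dep, target)[0]
        assert res.effect == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_scipy_pearsonr(self, rng):
        dep = pd.DataFrame(
            rng.normal(size=(5, 30)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        target = pd.Series(rng.normal(size=30), index=dep.columns)
        for res in correlate(dep, target):
            r, p = stats.pearsonr(dep.loc[res.feature], target)
            assert res.effect == pytest.approx(r, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_zero_variance_flagged(self):
        dep = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g"],
                           columns=list("abcd"))
        target = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = correlate(dep, target)[0]
        assert np.isnan(res.effect)


class TestCodependencyExpand:
    def test_planted_module_matches_oracle(self, dependency_sim):
        dep = dependency_sim["dependency"]
        module = dependency_sim["truth"]["module_genes"]
        got = codependency_expand(sorted(module)[:3], dep)
        oracle = brute_force_expand(sorted(module)[:3], dep)
        assert got == oracle

    def test_oracle_equality_on_random_matrices(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            dep = pd.DataFrame(
                local.normal(size=(20, 60)),
                index=[f"g{i}" for i in range(20)],
                columns=[f"s{i}" for i in range(60)],
            )
            seed_genes = ["g0", "g1"]
            assert codependency_expand(seed_genes, dep, top_k=3) == \
                brute_force_expand(seed_genes, dep, top_k=3)

    def test_zero_iterations_is_seed(self, dependency_sim):
        dep = dependency_sim["dependency"]
        assert codependency_expand(["G00000"], dep, iterations=0) == {"G00000"}

    def test_missing_seed_gene_named(self, dependency_sim):
        with pytest.raises(KeyError, match="NOPE"):
            codependency_expand(["NOPE"], dependency_sim["dependency"])

    def test_isolated_seed_fixed_point(self, rng):
        # block of 6 correlated genes + isolated seed gene of pure noise
        latent = rng.normal(size=100)
        block = 0.95 * latent + 0.3 * rng.normal(size=(6, 100))
        lone = rng.normal(size=(1, 100))
        dep = pd.DataFrame(
            np.vstack([block, lone]),
            index=[f"b{i}" for i in range(6)] + ["lone"],
            columns=[f"s{i}" for i in range(100)],
        )
        assert codependency_expand(["lone"], dep, top_k=2) == {"lone"}


class TestMutationAssociation:
    def mk(self, dep_values, mut_flags, min_mutants=2):
        samples = [f"s{i}" for i in range(len(dep_values))]
        return mutation_association(
            pd.Series(dep_values, index=samples),
            pd.Series(mut_flags, index=samples),
            min_mutants=min_mutants,
        )

    def test_complete_separation(self):
        res = self.mk([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])
        assert res.effect == -1.0
        assert res.p == pytest.approx(0.2, abs=1e-12)  # exact 2/10

    def test_too_few_mutants_excluded(self):
        assert self.mk([1, 2, 3, 4, 5], [1, 0, 0, 0, 0], min_mutants=5) is None

    def test_all_mutant_excluded(self):
        assert self.mk([1, 2, 3], [1, 1, 1]) is None

    def test_identical_distributions_near_zero(self, rng):
        values = np.tile(rng.normal(size=50), 2)
        flags = np.r_[np.ones(50), np.zeros(50)]
        res = self.mk(list(values), list(flags), min_mutants=5)
        assert abs(res.effect) < 1e-12

    def test_rank_biserial_extremes(self):
        assert rank_biserial(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == -1.0
        assert rank_biserial(np.array([3.0, 4.0]), np.array([1.0, 2.0])) == 1.0


class TestSignedQ:
    def test_bh_step_up_oracle(self):
        results = [
            AssociationResult(f"g{i}", effect, p, n=10)
            for i, (p, effect) in enumerate(
                [(0.001, 1.0), (0.02, -1.0), (0.03, 1.0), (0.9, -0.5)]
            )
        ]
        out = signed_q(results).set_index("feature")
        assert out.loc["g0", "q"] == pytest.approx(0.004)
        assert out.loc["g1", "q"] == pytest.approx(0.04)
        assert out.loc["g2", "q"] == pytest.approx(0.04)
        assert out.loc["g3", "q"] == pytest.approx(0.9)

    def test_signed_q_arithmetic(self):
        results = [AssociationResult("g", -0.8, 0.01, n=5)]
        out = signed_q(results)
        assert out.loc[0, "signed_q"] == pytest.approx(-2.0)

    def test_all_p_one(self):
        results = [AssociationResult(f"g{i}", 0.1, 1.0, n=5) for i in range(3)]
        out = signed_q(results)
        assert (out["q"] == 1.0).all()
        assert (out["signed_q"] == 0.0).all()

    def test_monotone_in_p(self, rng):
        ps = rng.uniform(size=40)
        results = [AssociationResult(f"g{i}", 1.0, p, n=5)
                   for i, p in enumerate(ps)]
        out = signed_q(results).set_index("feature")
        order_p = np.argsort([r.p for r in results])
        qs = out.loc[[f"g{i}" for i in order_p], "q"].to_numpy()
        assert (np.diff(qs) >= -1e-15).all()

    def test_empty_family_error(self):
        with pytest.raises(ValueError):
            signed_q([AssociationResult("g", 1.0, float("nan"), n=2)])


class TestClusterCodependency:
    def test_two_blocks_split_at_top(self, rng):
        latent_a, latent_b = rng.normal(size=(2, 120))
        rows = np.vstack(
            [0.95 * latent_a + 0.3 * rng.normal(size=(4, 120)),
             0.95 * latent_b + 0.3 * rng.normal(size=(4, 120))]
        )
        dep = pd.DataFrame(rows, index=[f"a{i}" for i in range(4)]
                           + [f"b{i}" for i in range(4)],
                           columns=[f"s{i}" for i in range(120)])
        corr, z, order = cluster_codependency(list(dep.index), dep)
        # leaf order keeps the two planted blocks contiguous
        kinds = [g[0] for g in order]
        assert sorted({"".join(kinds[:4]), "".join(kinds[4:])}) == ["aaaa", "bbbb"]
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_requires_three_genes(self, dependency_sim):
        with pytest.raises(ValueError):
            cluster_codependency(["G00000", "G00001"],
                                 dependency_sim["dependency"])


class TestFeatureFilters:
    def test_expression_log_and_sd_filter(self):
        tpm = pd.DataFrame(
            {"s1": [0.0, 0.0, 10.0], "s2": [0.0, 0.0, 300.0]},
            index=["const", "zero", "varying"],
        )
        out = filter_expression(tpm)
        assert "varying" in out.index and "const" not in out.index
        # pseudocount: TPM 0 -> log2(1) = 0
        assert filter_expression(tpm, min_sd=0.0).loc["zero", "s1"] == 0.0

    def test_exon_missingness_and_sd(self):
        inc = pd.DataFrame(
            np.r_[[np.r_[np.full(5, np.nan), [0.1, 0.9, 0.5, 0.2, 0.8]]],
                  [np.full(10, 0.5)],
                  [np.tile([0.1, 0.9], 5)]],
            index=["missing", "flat", "ok"],
        )
        out = filter_exon_inclusion(inc, max_missing=4)
        assert list(out.index) == ["ok"]

    def test_methylation_sd_filter(self):
        regions = pd.DataFrame(
            {"s1": [0.5, 0.2], "s2": [0.52, 0.8]}, index=["flat", "var"]
        )
        out = filter_methylation(regions)
        assert list(out.index) == ["var"]


class TestPlantedMutationEffect:
    def test_planted_effect_detected(self, dependency_sim):
        dep = dependency_sim["dependency"]
        mut = dependency_sim["mutation"]
        gene = dependency_sim["truth"]["mutation_genes"][0]
        res = mutation_association(dep.loc[gene], mut.loc[gene], feature=gene)
        assert res.effect < 0  # mutants more dependent
        assert res.p < 0.01

    def test_pairwise_r2_of_module(self, dependency_sim):
        dep = dependency_sim["dependency"]
        module = dependency_sim["truth"]["module_genes"]
        r2 = pairwise_r2(dep).loc[module, module].to_numpy()
        off_diag = r2[~np.eye(len(module), dtype=bool)]
        assert off_diag.mean() == pytest.approx(0.81, abs=0.05)
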