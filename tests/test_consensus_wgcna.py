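"""Network construction oracles and planted-module recovery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ccf1tx import (
    NetworkConfig,
    bicor_matrix,
    consensus_tom,
    detect_modules,
    module_trait_cor,
    signed_tom,
)
from ccf1tx.consensus_wgcna import UNASSIGNED, encode_traits, module_eigengene

from conftest import planted_expression


def scalar_bicor(x, y):
    """Independent scalar implementation of the biweight midcorrelation."""
    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w
    xt, yt = transform(np.asarray(x, float)), transform(np.asarray(y, float))
    return float(np.sum(xt * yt) / (np.linalg.norm(xt) * np.linalg.norm(yt)))


def brute_force_tom(cor, beta):
    """Triple-loop TOM oracle."""
    n = cor.shape[0]
    a = ((1 + cor) / 2) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestBicor:
    def test_self_correlation_is_one(self):
        df, _ = planted_expression(n_genes=10, n_samples=12, modules=(), seed=1)
        C = bicor_matrix(df)
        assert np.allclose(np.diag(C.values), 1.0)

    def test_negated_vector_gives_minus_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        df = pd.DataFrame([x, -x], index=["a", "b"])
        C = bicor_matrix(df)
        assert C.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scalar_formula_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 8))
        C = bicor_matrix(pd.DataFrame(X))
        for i in range(6):
            for j in range(i + 1, 6):
                assert C.iloc[i, j] == pytest.approx(
                    scalar_bicor(X[i], X[j]), abs=1e-12
                )

    def test_symmetric_and_bounded(self):
        df, _ = planted_expression(n_genes=40, n_samples=20, seed=4)
        C = bicor_matrix(df).values
        assert np.allclose(C, C.T)
        assert C.min() >= -1.0 and C.max() <= 1.0

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5, 10)))
        df.iloc[2] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            C = bicor_matrix(df)
        assert C.shape == (4, 4)


class TestSignedTom:
    def test_two_gene_closed_form(self):
        # with no shared neighbors: tom_12 = a_12 / (1 - a_12) * ... verify
        # against direct scalar evaluation of the formula
        cor = np.array([[1.0, 0.6], [0.6, 1.0]])
        beta = 4
        a12 = ((1 + 0.6) / 2) ** beta
        expected = a12 / (a12 + 1 - a12)  # k_1 = k_2 = a12; min(k)+1-a12
        tom = signed_tom(cor, beta).values
        assert tom[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_perfect_module_saturates_at_one(self):
        cor = np.ones((5, 5))
        tom = signed_tom(cor, beta=7).values
        assert np.allclose(tom, 1.0)

    @pytest.mark.parametrize("n,seed", [(6, 0), (8, 1), (10, 2)])
    def test_matches_brute_force_triple_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 12))
        cor = np.corrcoef(X)
        tom = signed_tom(cor, beta=6).values
        oracle = brute_force_tom(cor, beta=6)
        assert np.abs(tom - oracle).max() < 1e-12

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(6)
        cor = np.corrcoef(rng.normal(size=(20, 15)))
        tom = signed_tom(cor, beta=16).values
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)


class TestConsensusTom:
    def _toms(self, n_sets=3, n=10, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(n)]
        return [
            signed_tom(pd.DataFrame(np.corrcoef(rng.normal(size=(n, 20))),
                                    index=idx, columns=idx), beta=6)
            for _ in range(n_sets)
        ]

    def test_single_dataset_identity(self):
        (tom,) = self._toms(n_sets=1)
        cons = consensus_tom([tom])
        pd.testing.assert_frame_equal(cons, tom)

    def test_identical_datasets_identity(self):
        (tom,) = self._toms(n_sets=1)
        cons = consensus_tom([tom, tom.copy(), tom.copy()])
        np.testing.assert_allclose(cons.values, tom.values, atol=1e-12)

    def test_consensus_below_each_scaled_tom(self):
        toms = self._toms(n_sets=3)
        cons = consensus_tom(toms, quantile=0.2)
        # consensus equals the element-wise min of the quantile-scaled TOMs
        mask = ~np.eye(len(cons), dtype=bool)
        qs = [np.quantile(t.values[mask], 0.2) for t in toms]
        scaled = [toms[0].values]
        for t, q in zip(toms[1:], qs[1:]):
            scaled.append(t.values ** (np.log(qs[0]) / np.log(q)))
        oracle = np.minimum.reduce(scaled)
        np.testing.assert_allclose(cons.values[mask], oracle[mask], atol=1e-12)
        for s in scaled:
            assert (cons.values[mask] <= s[mask] + 1e-12).all()

    def test_scaling_aligns_quantiles(self):
        toms = self._toms(n_sets=2, seed=3)
        mask = ~np.eye(len(toms[0]), dtype=bool)
        q1 = np.quantile(toms[0].values[mask], 0.2)
        q2 = np.quantile(toms[1].values[mask], 0.2)
        scaled = toms[1].values ** (np.log(q1) / np.log(q2))
        # power scaling maps q2 to q1 exactly; the empirical quantile of the
        # scaled matrix matches up to interpolation between order statistics
        assert q2 ** (np.log(q1) / np.log(q2)) == pytest.approx(q1, rel=1e-12)
        assert np.quantile(scaled[mask], 0.2) == pytest.approx(q1, rel=0.05)


def _planted_datasets(n_modules=5, module_size=120, n_samples=60, noise=0.4,
                      seeds=(1, 2)):
    sets = []
    for seed in seeds:
        df, truth = planted_expression(
            n_genes=n_modules * module_size,
            n_samples=n_samples,
            modules=tuple((module_size, 1.0) for _ in range(n_modules)),
            noise_sd=noise,
            seed=seed,
        )
        sets.append(df)
    return sets, truth


class TestDetectModules:
    def test_planted_module_recovery(self):
        datasets, truth = _planted_datasets()
        cfg = NetworkConfig()
        toms = [signed_tom(bicor_matrix(d), cfg.beta) for d in datasets]
        cons = consensus_tom(toms, cfg.consensus_quantile)
        assignment = detect_modules(cons, cfg, datasets)
        ari = adjusted_rand_score(truth, assignment.labels.values)
        assert ari >= 0.9

    def test_pure_noise_leaves_genes_unassigned(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(600, 60)),
                          index=[f"g{i}" for i in range(600)])
        cfg = NetworkConfig()
        tom = signed_tom(bicor_matrix(df), cfg.beta)
        with pytest.warns(UserWarning):
            assignment = detect_modules(tom, cfg, df)
        assert (assignment.labels == UNASSIGNED).mean() >= 0.95

    def test_correlated_modules_merge(self):
        # two planted modules driven by factors correlated at ~0.95 merge
        # under the default threshold (1 - 0.95 < 0.25)
        rng = np.random.default_rng(12)
        n_samples = 80
        f = rng.normal(size=n_samples)
        f2 = 0.95 * f + np.sqrt(1 - 0.95**2) * rng.normal(size=n_samples)
        X = rng.normal(scale=0.3, size=(240, n_samples))
        X[:120] += f
        X[120:] += f2
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(240)])
        cfg = NetworkConfig(min_module_size=50)
        tom = signed_tom(bicor_matrix(df), cfg.beta)
        assignment = detect_modules(tom, cfg, df)
        labels = assignment.labels[assignment.labels != UNASSIGNED]
        assert labels.nunique() == 1

    def test_kme_of_retained_genes_above_threshold(self):
        datasets, _ = _planted_datasets(n_modules=3, module_size=110)
        cfg = NetworkConfig()
        toms = [signed_tom(bicor_matrix(d), cfg.beta) for d in datasets]
        cons = consensus_tom(toms, cfg.consensus_quantile)
        assignment = detect_modules(cons, cfg, datasets)
        for color in assignment.eigengenes.index:
            members = assignment.genes_in(color)
            assert (assignment.kme.loc[members, color] >= cfg.kme_min).all()

    def test_eigengenes_unit_norm(self):
        datasets, _ = _planted_datasets(n_modules=2, module_size=110)
        cfg = NetworkConfig()
        toms = [signed_tom(bicor_matrix(d), cfg.beta) for d in datasets]
        cons = consensus_tom(toms, cfg.consensus_quantile)
        assignment = detect_modules(cons, cfg, datasets)
        norms = np.linalg.norm(assignment.eigengenes.values, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_gene_order_invariance(self):
        datasets, truth = _planted_datasets(n_modules=3, module_size=110,
                                            seeds=(5, 6))
        cfg = NetworkConfig()
        rng = np.random.default_rng(13)
        perm = rng.permutation(datasets[0].index)
        permuted = [d.loc[perm] for d in datasets]

        def run(ds):
            toms = [signed_tom(bicor_matrix(d), cfg.beta) for d in ds]
            cons = consensus_tom(toms, cfg.consensus_quantile)
            return detect_modules(cons, cfg, ds)

        a1, a2 = run(datasets), run(permuted)
        ari = adjusted_rand_score(
            a1.labels.loc[datasets[0].index].values,
            a2.labels.loc[datasets[0].index].values,
        )
        assert ari >= 0.98


class TestModuleTraitCor:
    def _assignment_with_planted_trait(self, seed=14):
        rng = np.random.default_rng(seed)
        n_samples = 80
        age = rng.choice([0.0, 1.0], size=n_samples)
        f_age = age + rng.normal(scale=0.3, size=n_samples)
        f_null = rng.normal(size=n_samples)
        X = rng.normal(scale=0.3, size=(300, n_samples))
        X[:120] += f_age
        X[120:240] += f_null
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(300)],
                          columns=[f"s{j}" for j in range(n_samples)])
        cfg = NetworkConfig()
        tom = signed_tom(bicor_matrix(df), cfg.beta)
        assignment = detect_modules(tom, cfg, df)
        traits = pd.DataFrame(
            {"age_months": age, "sex": rng.choice([0.0, 1.0], size=n_samples)},
            index=[f"s{j}" for j in range(n_samples)],
        )
        return assignment, traits, f_age

    def test_trait_equal_to_eigengene_gives_r_one(self):
        assignment, traits, _ = self._assignment_with_planted_trait()
        me0 = assignment.eigengenes.iloc[0]
        traits = traits.copy()
        # eigengene columns are dataset-prefixed; same sample order as traits
        traits["self"] = me0.values
        table = module_trait_cor(assignment, traits)
        r = table.loc[(assignment.eigengenes.index[0], "self"), "r"]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_planted_age_module_flagged(self):
        assignment, traits, f_age = self._assignment_with_planted_trait()
        table = module_trait_cor(assignment, traits)
        # exactly the age-driven module is flagged for age
        age_rows = table.xs("age_months", level="trait")
        flagged = age_rows[age_rows["significant"]]
        assert len(flagged) == 1
        # and it is the module containing the planted age genes
        mod = flagged.index[0]
        members = set(assignment.genes_in(mod))
        assert len(members & {f"g{i}" for i in range(120)}) > 100

    def test_constant_trait_rejected(self):
        assignment, traits, _ = self._assignment_with_planted_trait()
        traits = traits.copy()
        traits["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            module_trait_cor(assignment, traits)

    def test_null_trait_significance_rate_controlled(self):
        # traits independent of the eigengenes: flagged fraction stays small
        assignment, traits, _ = self._assignment_with_planted_trait()
        rng = np.random.default_rng(15)
        null_traits = pd.DataFrame(
            rng.normal(size=(len(traits), 20)),
            index=traits.index,
            columns=[f"t{j}" for j in range(20)],
        )
        table = module_trait_cor(assignment, null_traits)
        assert table["significant"].mean() <= 0.05


class TestTraitEncoding:
    def test_standard_codes(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "age_months": [4, 12],
             "sex": ["F", "M"], "genotype": ["WT", "5x"]}
        )
        enc = encode_traits(meta)
        assert enc.loc["a"].tolist() == [0.0, 0.0, 0.0]
        assert enc.loc["b"].tolist() == [1.0, 1.0, 1.0]
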