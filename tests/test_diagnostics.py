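"""PR2 coordinates, ENC-GC3 residuals, skew correlations and usage PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from codonusage import (
    SyntheticCohortSpec,
    count_codons,
    enc_gc3_table,
    generate_cohort,
    pca_usage,
    pr2_point,
    rscu,
    rscu_matrix,
    skew_correlation_table,
)
from codonusage.composition import SCOPES, SKEW_TYPES, SkewProfile


def make_profile(values_by_cell):
    return SkewProfile(values=dict(values_by_cell))


def random_profiles(rng, n):
    out = []
    for _ in range(n):
        vals = {
            (t, s): float(rng.uniform(-1, 1)) for t in SKEW_TYPES for s in SCOPES
        }
        out.append(make_profile(vals))
    return out


class TestPR2:
    def test_balanced_fourfold_is_centered(self, counts_from):
        p = pr2_point(counts_from({"GCA": 3, "GCT": 3, "GCG": 3, "GCC": 3}))
        assert (p.at_bias, p.gc_bias) == (0.5, 0.5)

    def test_direct_ratios(self, counts_from):
        p = pr2_point(counts_from({"GCA": 3, "GCT": 1, "GCG": 1, "GCC": 3}))
        assert p.at_bias == pytest.approx(0.75)
        assert p.gc_bias == pytest.approx(0.25)

    def test_only_g_ending(self, counts_from):
        p = pr2_point(counts_from({"GCG": 4, "GGG": 2}))
        assert p.gc_bias == 1.0
        assert math.isnan(p.at_bias)

    def test_sixfold_fourfold_subsets_excluded(self, counts_from):
        # CTN (Leu) and TCN (Ser) are fourfold subsets of sixfold families:
        # they must not enter the PR2 tallies
        p = pr2_point(counts_from({"CTA": 9, "TCA": 9, "GCA": 1, "GCT": 1}))
        assert p.a3 == 1 and p.t3 == 1

    def test_invariant_to_count_scaling(self, counts_from):
        base = {"GCA": 3, "GCT": 1, "GGG": 2, "CCC": 5}
        p1 = pr2_point(counts_from(base))
        p2 = pr2_point(counts_from({c: 7 * v for c, v in base.items()}))
        assert p1.at_bias == pytest.approx(p2.at_bias)
        assert p1.gc_bias == pytest.approx(p2.gc_bias)


class TestEncGc3Table:
    def test_residual_arithmetic(self, small_cohort):
        seqs, _ = small_cohort
        table = enc_gc3_table((s.id, count_codons(s)) for s in seqs)
        assert len(table) == len(seqs)
        for _, row in table.iterrows():
            assert row["residual"] == pytest.approx(row["enc"] - row["expected_enc"])

    def test_known_residual(self):
        # gc3 = 0.5 -> expected 60.5; a gene at ENC 55 sits 5.5 below the curve
        from codonusage import expected_enc

        assert 55 - expected_enc(0.5) == pytest.approx(-5.5)

    def test_selection_cohort_falls_below_curve(self):
        spec = SyntheticCohortSpec(
            n_species=10, protein_length=800, bias_model="selection",
            concentration=0.2, seed=7,
        )
        seqs, _ = generate_cohort(spec)
        table = enc_gc3_table((s.id, count_codons(s)) for s in seqs)
        assert table["residual"].median() < 0


def brute_force_pearson(x, y):
    """Explicit sum-formula Pearson r and two-tailed p via the t transform."""
    from scipy import stats

    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, p


class TestSkewCorrelations:
    def test_shape_and_labels(self, rng):
        table = skew_correlation_table(random_profiles(rng, 30))
        assert len(table) == 18
        assert set(table["skew_type"]) == set(SKEW_TYPES)
        assert set(table["position"]) == {1, 2, 3}

    def test_perfect_and_anti_correlation(self, rng):
        profiles = []
        for _ in range(20):
            v = float(rng.uniform(-1, 1))
            vals = {}
            for t in SKEW_TYPES:
                for s in SCOPES:
                    vals[(t, s)] = v if s in ("overall", "pos1") else -v
            profiles.append(make_profile(vals))
        table = skew_correlation_table(profiles).set_index(["skew_type", "position"])
        assert table.loc[("AT", 1), "r"] == pytest.approx(1.0)
        assert table.loc[("AT", 2), "r"] == pytest.approx(-1.0)

    def test_matches_brute_force_sums(self, rng):
        profiles = random_profiles(rng, 50)
        table = skew_correlation_table(profiles).set_index(["skew_type", "position"])
        for t in SKEW_TYPES:
            x = [p.get(t, "overall") for p in profiles]
            for pos in (1, 2, 3):
                y = [p.get(t, f"pos{pos}") for p in profiles]
                r, p_val = brute_force_pearson(x, y)
                assert table.loc[(t, pos), "r"] == pytest.approx(r, abs=1e-12)
                assert table.loc[(t, pos), "p_value"] == pytest.approx(p_val, abs=1e-12)

    def test_null_type_one_error_rate(self, rng):
        # independent overall/positional skews: p-values should be uniform,
        # so about 5% fall below 0.05
        hits = total = 0
        for _ in range(100):
            table = skew_correlation_table(random_profiles(rng, 200))
            hits += int((table["p_value"] < 0.05).sum())
            total += len(table)
        assert 0.02 < hits / total < 0.09

    def test_constant_column_reported_missing(self):
        vals = {(t, s): 0.3 for t in SKEW_TYPES for s in SCOPES}
        table = skew_correlation_table([make_profile(vals)] * 10)
        assert table["r"].isna().all()
        assert (table["significance"] == "NA").all()

    def test_nan_cells_use_pairwise_deletion(self, rng):
        profiles = random_profiles(rng, 25)
        broken = dict(profiles[0].values)
        broken[("AT", "pos1")] = float("nan")
        profiles[0] = make_profile(broken)
        table = skew_correlation_table(profiles).set_index(["skew_type", "position"])
        assert table.loc[("AT", 1), "n"] == 24
        assert table.loc[("AT", 2), "n"] == 25

    def test_gc3_gradient_drives_third_position_correlation(self):
        # species with different compositional pressure at synonymous sites:
        # overall GC skew should track the third position far more than 1/2
        from codonusage import nucleotide_composition, skew_profile

        profiles = []
        for i, target in enumerate(np.linspace(0.25, 0.75, 24)):
            spec = SyntheticCohortSpec(
                n_species=1, protein_length=600, gc3_target=float(target), seed=100 + i
            )
            (seq,), _ = generate_cohort(spec)
            profiles.append(skew_profile(nucleotide_composition(seq)))
        table = skew_correlation_table(profiles).set_index(["skew_type", "position"])
        r3 = abs(table.loc[("GC", 3), "r"])
        assert r3 > abs(table.loc[("GC", 1), "r"])
        assert r3 > abs(table.loc[("GC", 2), "r"])


def brute_force_pca(matrix):
    """Oracle: eigendecomposition of the covariance matrix."""
    x = matrix - matrix.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class TestPCA:
    def test_identical_genes_identical_coordinates(self, code):
        mat = pd.DataFrame([[1.0] * 59, [1.0] * 59, [2.0] * 59],
                           columns=list(code.rscu_codons))
        res = pca_usage(mat)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1])

    def test_single_feature_variance(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame({"a": rng.normal(size=10), "b": 0.0, "c": 0.0})
        res = pca_usage(mat, "aa20")
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_nonincreasing_and_centered(self, small_cohort, code):
        seqs, _ = small_cohort
        mat = rscu_matrix([(s.id, rscu(count_codons(s)).values) for s in seqs], code)
        res = pca_usage(mat)
        evr = res.explained_variance_ratio
        assert all(a >= b - 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1 + 1e-9
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_reconstruction(self, small_cohort, code):
        seqs, _ = small_cohort
        mat = rscu_matrix([(s.id, rscu(count_codons(s)).values) for s in seqs], code)
        res = pca_usage(mat)
        imputed = mat.fillna(mat.mean(axis=0))
        recon = res.coordinates.to_numpy() @ res.loadings.to_numpy().T + res.column_means.to_numpy()
        assert np.allclose(recon, imputed.to_numpy(), atol=1e-8)

    def test_duplicated_cohort_same_variance_ratios(self, rng):
        mat = pd.DataFrame(rng.normal(size=(8, 5)))
        doubled = pd.concat([mat, mat], ignore_index=True)
        r1 = pca_usage(mat, "aa20", n_components=4)
        r2 = pca_usage(doubled, "aa20", n_components=4)
        assert np.allclose(r1.explained_variance_ratio, r2.explained_variance_ratio, atol=1e-10)
        # and both agree with the covariance eigensolve
        w, _ = brute_force_pca(mat.to_numpy())
        assert np.allclose(
            r1.explained_variance_ratio, (w / w.sum())[:4], atol=1e-10
        )

    def test_fewer_than_two_genes_raises(self, code):
        mat = pd.DataFrame([[1.0] * 59], columns=list(code.rscu_codons))
        with pytest.raises(ValueError):
            pca_usage(mat)

    def test_imputation_preserves_column_means(self, code, rng):
        mat = pd.DataFrame(rng.uniform(0, 2, size=(10, 59)), columns=list(code.rscu_codons))
        mat.iloc[0, 0] = np.nan
        res = pca_usage(mat)
        assert res.column_means["AAA"] == pytest.approx(mat["AAA"].mean())
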