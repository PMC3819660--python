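import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orgflow import (
    AbundanceMatrix,
    CountMatrix,
    TMMNormalization,
    TrimBounds,
    ValidationError,
    build_reference,
    clean_counts,
    compute_ma,
    estimate_abundance,
    normalization_factor,
    normalize,
    trim_genes,
)
from orgflow.tmm import MAStatistics
from orgflow.counts import ValidationError as VErr
from orgflow.synthetic import SimulationSpec, simulate

from .oracle import oracle_factors


def _ab(Y):
    idx = pd.Index([f"g{i}" for i in range(Y.shape[0])])
    cols = [f"S{j+1}" for j in range(Y.shape[1])]
    return AbundanceMatrix(Y=pd.DataFrame(Y, index=idx, columns=cols))


class TestReference:
    def test_mean_of_commonly_expressed(self):
        ab = _ab(np.array([[0.4, 0.6], [0.4, 0.0], [1.0, 3.0]]))
        ref = build_reference(ab)
        assert list(ref.genes) == ["g0", "g2"]
        assert ref.y_ref["g0"] == pytest.approx(0.5)
        assert ref.n_ref == pytest.approx(0.5 + 2.0)

    def test_membership_rule_three_samples(self):
        Y = np.array([
            [1.0, 2.0, 3.0],
            [2.0, 0.0, 1.0],   # zero in one sample: out
            [4.0, 4.0, 4.0],
            [0.5, 1.5, 2.5],
        ])
        ref = build_reference(_ab(Y))
        assert list(ref.genes) == ["g0", "g2", "g3"]
        assert ref.n_ref == pytest.approx(2.0 + 4.0 + 1.5)

    def test_no_common_genes_is_an_error(self):
        with pytest.raises(ValidationError, match="no commonly expressed"):
            build_reference(_ab(np.array([[1.0, 0.0], [0.0, 1.0]])))


class TestMAStatistics:
    def test_equal_relative_abundance_gives_zero_m(self):
        ab = _ab(np.array([[1.0, 2.0], [3.0, 6.0]]))  # S2 = 2*S1
        ref = build_reference(ab)
        stats = compute_ma(ab, ref, "S1")
        np.testing.assert_allclose(stats.m.to_numpy(), 0.0, atol=1e-12)

    def test_fourfold_relative_abundance_gives_m_two(self):
        # g0 takes 4x the relative share in S1 vs the reference profile
        ab = _ab(np.array([[4.0, 0.4], [1.0, 1.9]]))
        ref = build_reference(ab)
        rel = ab.Y["S1"] / ab.N["S1"]
        rel_ref = ref.y_ref / ref.n_ref
        stats = compute_ma(ab, ref, "S1")
        assert stats.m["g0"] == pytest.approx(np.log2(rel["g0"] /
                                                      rel_ref["g0"]))

    def test_approximate_weight_value(self):
        ab = _ab(np.array([[0.01, 0.03], [0.5, 0.5]]))
        ref = build_reference(ab)
        stats = compute_ma(ab, ref, "S1")
        # w = 1/Y_gk + 1/Y_ref with Y_gk = 0.01, Y_ref = 0.02
        assert stats.w["g0"] == pytest.approx(1 / 0.01 + 1 / 0.02)

    def test_exact_weight_form(self):
        ab = _ab(np.array([[0.01, 0.03], [0.5, 0.5]]))
        ref = build_reference(ab)
        stats = compute_ma(ab, ref, "S1", exact_weights=True)
        n_k, y = ab.N["S1"], 0.01
        expected = (n_k - y) / (n_k * y) \
            + (ref.n_ref - 0.02) / (ref.n_ref * 0.02)
        assert stats.w["g0"] == pytest.approx(expected, rel=1e-12)

    def test_six_gene_table_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(7)
        Y = rng.uniform(0.1, 5.0, size=(6, 3))
        ab = _ab(Y)
        ref = build_reference(ab)
        stats = compute_ma(ab, ref, "S2")
        y_ref = Y.mean(axis=1)
        n_ref = y_ref.sum()
        rel_k = Y[:, 1] / Y[:, 1].sum()
        rel_r = y_ref / n_ref
        np.testing.assert_allclose(stats.m.to_numpy(),
                                   np.log2(rel_k / rel_r), rtol=1e-12)
        np.testing.assert_allclose(stats.a.to_numpy(),
                                   0.5 * np.log2(rel_k * rel_r), rtol=1e-12)
        np.testing.assert_allclose(stats.w.to_numpy(),
                                   1 / Y[:, 1] + 1 / y_ref, rtol=1e-12)


def _stats(m, a, w=None):
    idx = pd.Index([f"g{i}" for i in range(len(m))])
    w = np.ones(len(m)) if w is None else np.asarray(w, dtype=float)
    return MAStatistics(sample="S1",
                        m=pd.Series(np.asarray(m, dtype=float), index=idx),
                        a=pd.Series(np.asarray(a, dtype=float), index=idx),
                        w=pd.Series(w, index=idx))


class TestTrimming:
    def test_eleven_gene_enumeration(self):
        # M and A both 0..10; windows (0.3, 0.7) and (0.2, 0.8) keep the
        # intersection {4,5,6} of the strict M-window with the A-window
        stats = _stats(range(11), range(11))
        kept = trim_genes(stats, TrimBounds())
        assert list(kept) == ["g4", "g5", "g6"]

    def test_boundary_positions_are_excluded(self):
        # g1 sits exactly at the 0.3 position of the M range: excluded
        stats = _stats([0, 3, 5, 10], [5, 5, 5, 5])
        kept = trim_genes(stats, TrimBounds())
        assert list(kept) == ["g2"]

    def test_degenerate_ranges_pass_everyone(self):
        stats = _stats([1, 1, 1], [2, 2, 2])
        assert len(trim_genes(stats, TrimBounds())) == 3

    def test_empty_trim_advises_wider_bounds(self):
        stats = _stats([0, 10], [0, 10])
        with pytest.raises(ValidationError, match="widen"):
            trim_genes(stats, TrimBounds())

    def test_quantile_mode_discards_rank_tails(self):
        # 10 genes: ranks 4..7 lie strictly inside (0.3, 0.7) by quantile
        stats = _stats(range(10), [5] * 10)
        kept = trim_genes(stats, TrimBounds(), mode="quantile")
        assert list(kept) == ["g3", "g4", "g5", "g6"]


class TestFactor:
    def test_identical_to_reference_gives_unity(self):
        stats = _stats([0, 0, 0], [1, 2, 3])
        log_tmm, r = normalization_factor(stats, stats.m.index)
        assert (log_tmm, r) == (0.0, 1.0)

    def test_constant_m_gives_its_power_of_two(self):
        stats = _stats([1, 1], [1, 2], w=[5, 1])
        assert normalization_factor(stats, stats.m.index)[1] == \
            pytest.approx(2.0)

    def test_weighted_mean_hand_value(self):
        stats = _stats([1, 3], [1, 2], w=[3, 1])
        log_tmm, r = normalization_factor(stats, stats.m.index)
        assert log_tmm == pytest.approx(1.5)
        assert r == pytest.approx(2 ** 1.5)


class TestNormalizePipeline:
    def test_duplicated_samples_all_unity(self):
        col = np.array([1.0, 2.0, 5.0, 0.25])
        ab = _ab(np.tile(col[:, None], (1, 4)))
        res, normalized = normalize(ab)
        np.testing.assert_allclose(res.factors.to_numpy(), 1.0, atol=1e-12)
        for j in range(1, 4):
            np.testing.assert_allclose(normalized.iloc[:, j],
                                       normalized.iloc[:, 0], rtol=1e-12)

    def test_scale_invariance_of_counts(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(2, 1000, size=(30, 3))
        idx = pd.Index([f"g{i}" for i in range(30)])
        lengths = pd.Series(rng.integers(200, 3000, size=30), index=idx)
        cm1 = CountMatrix(pd.DataFrame(counts, index=idx,
                                       columns=["A", "B", "C"]), lengths)
        scaled = counts.copy()
        scaled[:, 2] *= 10
        cm2 = CountMatrix(pd.DataFrame(scaled, index=idx,
                                       columns=["A", "B", "C"]), lengths)
        r1, n1 = normalize(estimate_abundance(clean_counts(cm1)))
        r2, n2 = normalize(estimate_abundance(clean_counts(cm2)))
        np.testing.assert_allclose(r1.factors.to_numpy(),
                                   r2.factors.to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy(), rtol=1e-10)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_row_permutation_never_changes_factors(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.uniform(0.05, 4.0, size=(12, 3))
        ab = _ab(Y)
        perm = rng.permutation(12)
        ab2 = AbundanceMatrix(Y=ab.Y.iloc[perm])
        try:
            res, _ = normalize(ab)
        except ValidationError:
            with pytest.raises(ValidationError):
                normalize(ab2)
            return
        res2, _ = normalize(ab2)
        np.testing.assert_allclose(res.factors.to_numpy(),
                                   res2.factors.to_numpy(), rtol=1e-12)

    def test_gstar_subset_and_factor_consistency(self, sim_abundance):
        res, _ = normalize(sim_abundance)
        for k, sf in res.per_sample.items():
            assert sf.g_star.isin(res.reference.genes).all()
            w = sf.stats.w.loc[sf.g_star]
            m = sf.stats.m.loc[sf.g_star]
            assert sf.log_tmm == pytest.approx(float((w * m).sum() / w.sum()),
                                               abs=0.0)
            assert np.log2(sf.r) == pytest.approx(sf.log_tmm, rel=1e-12)

    def test_matches_independent_oracle_on_random_tables(self):
        """Full pipeline vs plain-Python evaluation of every formula."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            n_g = int(rng.integers(4, 21))
            n_s = int(rng.integers(2, 5))
            counts = rng.integers(0, 400, size=(n_g, n_s))
            counts[rng.random(counts.shape) < 0.15] = 0
            counts[0, :] = rng.integers(2, 400, size=n_s)  # keep G nonempty
            lengths = rng.integers(100, 3000, size=n_g)
            genes = [f"g{i}" for i in range(n_g)]
            samples = [f"S{j}" for j in range(n_s)]
            expected = oracle_factors(
                {s: {g: int(counts[i, j]) for i, g in enumerate(genes)}
                 for j, s in enumerate(samples)},
                {g: int(lengths[i]) for i, g in enumerate(genes)})
            cm = CountMatrix(pd.DataFrame(counts, index=genes,
                                          columns=samples),
                             pd.Series(lengths, index=genes))
            if expected is None:
                with pytest.raises(ValidationError):
                    normalize(estimate_abundance(clean_counts(cm)))
                continue
            res, _ = normalize(estimate_abundance(clean_counts(cm)))
            for s in samples:
                assert res.factors[s] == pytest.approx(expected[s],
                                                       abs=1e-10)
            checked += 1
        assert checked >= 20

    def test_rank_trimmed_factor_recovery_on_planted_design(self):
        """Rank trimming recovers the planted factors of the reference
        synthetic study (5% one-sided 8-fold DE) within 5%."""
        data = simulate(SimulationSpec(seed=915))
        cm = CountMatrix(data.counts, data.lengths)
        res, _ = normalize(estimate_abundance(clean_counts(cm)),
                           trim_mode="quantile")
        rel_err = np.abs(res.factors.to_numpy() /
                         data.truth.true_factors.to_numpy() - 1)
        assert rel_err.max() < 0.05

    def test_no_signal_factors_near_unity(self):
        """With no DE and equal depths the factors sit near 1; the rank
        trim is tighter than the printed min-max trim, whose window
        wobbles with the sample extremes."""
        spec = SimulationSpec(seed=424, de_fraction=0.0,
                              library_sizes=[2e7] * 3, plant_pathway=False)
        data = simulate(spec)
        ab = estimate_abundance(clean_counts(CountMatrix(data.counts,
                                                         data.lengths)))
        r_minmax, _ = normalize(ab)
        r_rank, _ = normalize(ab, trim_mode="quantile")
        assert np.abs(r_minmax.factors.to_numpy() - 1).max() < 0.05
        assert np.abs(r_rank.factors.to_numpy() - 1).max() < 0.02

    def test_rank_trim_more_robust_to_asymmetric_de_than_untrimmed(self):
        """With 30% asymmetric DE, the rank-trimmed factor stays closer
        to the DE-excluded factor than the untrimmed weighted mean does,
        in at least 90% of seeded replicates."""
        wins = trials = 0
        for seed in range(60):
            spec = SimulationSpec(n_genes=400, seed=seed, de_fraction=0.3,
                                  plant_pathway=False)
            data = simulate(spec)
            ab = estimate_abundance(clean_counts(
                CountMatrix(data.counts, data.lengths)))
            ref = build_reference(ab)
            stats = compute_ma(ab, ref, "S1")
            ideal = normalization_factor(
                stats, stats.m.index.difference(data.truth.de_genes))[0]
            untrimmed = normalization_factor(stats, stats.m.index)[0]
            trimmed = normalization_factor(
                stats, trim_genes(stats, TrimBounds(), mode="quantile"))[0]
            trials += 1
            wins += abs(trimmed - ideal) < abs(untrimmed - ideal)
        assert wins / trials >= 0.9


class TestModelFrontEnd:
    def test_fit_summary_and_tables(self, sim_default):
        cm = CountMatrix(sim_default.counts, sim_default.lengths)
        res = TMMNormalization.from_counts(cm).fit()
        assert set(res.factors.index) == set(sim_default.counts.columns)
        tbl = res.factor_table()
        assert {"n_common", "n_trimmed", "log2_tmm", "R"} <= set(tbl.columns)
        text = res.summary()
        assert "Trimmed-mean normalization" in text
        audit = res.audit()
        assert audit["bounds"]["m_lower"] == 0.3
        assert set(audit["samples"]) == set(res.factors.index)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            TrimBounds(m_lower=0.7, m_upper=0.3)
        with pytest.raises(ValueError):
            TrimBounds(a_lower=-0.1)
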