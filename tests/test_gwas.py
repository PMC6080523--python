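"""SNP back-solving, weight iteration, window partition and variances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wssgwas.grm import build_G
from wssgwas.gwas import (
    Window,
    backsolve_snp_effects,
    define_windows,
    normalize_weights,
    run_wssgwas,
    update_weights,
    window_variance_percentages,
)
from wssgwas.model import VarianceComponents
from wssgwas.pedigree import RelationshipMatrix
from wssgwas.qc import apply_qc
from wssgwas.simulate import SimulationConfig, simulate_dataset


def snp_map(positions_by_chrom):
    rows = []
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            rows.append((f"s_{chrom}_{p}", str(chrom), int(p)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


class TestBacksolve:
    def test_two_animal_one_snp_toy_reproduces_gebv(self):
        """Z=(-1,1), D=I, lambda=2: u from the conversion formula satisfies
        Z u = a_g (minimum-norm solve; this tiny G is rank one)."""
        Z = np.array([[-1.0], [1.0]])
        G = build_G(Z, np.ones(1), 2.0, ["a", "b"])
        a_g = np.array([-1.0, 1.0])
        u = backsolve_snp_effects(Z, np.ones(1), 2.0, G, a_g, allow_singular=True)
        assert np.allclose(Z @ u, a_g, atol=1e-12)
        assert u[0] == pytest.approx(1.0)

    def test_singular_G_raises_without_flag(self):
        Z = np.array([[-1.0], [1.0]])
        G = build_G(Z, np.ones(1), 2.0, ["a", "b"])
        with pytest.raises(np.linalg.LinAlgError, match="blend"):
            backsolve_snp_effects(Z, np.ones(1), 2.0, G, np.array([-1.0, 1.0]))

    def test_linearity_in_gebv(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(6, 20))
        w = rng.uniform(0.5, 2.0, 20)
        lam = 0.1
        G = build_G(Z, w, lam, [f"a{i}" for i in range(6)])
        Gr = RelationshipMatrix(G.values + np.eye(6) * 0.01, G.ids, "G")
        a_g = rng.normal(size=6)
        u1 = backsolve_snp_effects(Z, w, lam, Gr, a_g)
        u2 = backsolve_snp_effects(Z, w, lam, Gr, 2 * a_g)
        u0 = backsolve_snp_effects(Z, w, lam, Gr, np.zeros(6))
        assert np.allclose(u2, 2 * u1)
        assert np.allclose(u0, 0.0)


class TestWeights:
    def test_formula_arithmetic(self):
        u = np.array([0.0, 0.1, -0.1])
        p = np.array([0.3, 0.25, 0.25])
        d = update_weights(u, p)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(0.01 * 0.375)
        assert d[1] == d[2]  # sign-invariant

    def test_normalize_examples(self):
        assert np.allclose(normalize_weights(np.ones(7)), np.ones(7))
        assert np.allclose(
            normalize_weights(np.array([2.0, 0, 0, 0])), [4.0, 0, 0, 0]
        )
        with pytest.raises(ValueError):
            normalize_weights(np.zeros(3))

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.one_of(
                st.just(0.0), st.floats(1e-9, 1e6, allow_subnormal=False)
            ),
            min_size=1,
            max_size=50,
        ).filter(lambda xs: sum(xs) > 0)
    )
    def test_normalized_trace_equals_snp_count(self, raw):
        d = normalize_weights(np.array(raw))
        assert d.sum() == pytest.approx(len(raw), rel=1e-12)


class TestWindows:
    def test_greedy_partition_hand_example(self):
        """Positions 0.0/0.1/0.3/0.45/0.9 Mb split into {first three},
        {0.45}, {0.9} under a 0.4 Mb span."""
        m = snp_map({"1": [0, 100_000, 300_000, 450_000, 900_000]})
        wins = define_windows(m, span_bp=400_000)
        assert [list(w.snp_indices) for w in wins] == [[0, 1, 2], [3], [4]]
        assert wins[0].midpoint == pytest.approx(150_000)

    def test_one_snp_per_chromosome(self):
        m = snp_map({"1": [5], "2": [5], "3": [5]})
        assert len(define_windows(m)) == 3

    def test_all_snps_in_one_window(self):
        m = snp_map({"1": [0, 100_000, 399_999]})
        wins = define_windows(m)
        assert len(wins) == 1
        assert wins[0].n_snps if hasattr(wins[0], "n_snps") else len(wins[0].snp_indices) == 3

    def test_unsorted_map_rejected(self):
        m = snp_map({"1": [5, 3]})
        with pytest.raises(ValueError, match="sorted"):
            define_windows(m)

    def test_window_span_never_exceeds_limit(self):
        rng = np.random.default_rng(0)
        m = snp_map({"1": sorted(rng.integers(0, 5_000_000, 200).tolist())})
        m = m.drop_duplicates("pos").reset_index(drop=True)
        for w in define_windows(m):
            assert w.end_pos - w.start_pos < 400_000


class TestWindowVariance:
    def test_zero_effects_give_zero_percent(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(10, 5))
        wins = [Window("1:1", "1", 0, 100, np.arange(5))]
        res = window_variance_percentages(wins, np.zeros(5), Z, 0.5)
        assert res[0].pct_variance == 0.0

    def test_single_window_equals_total(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(20, 8))
        u = rng.normal(size=8)
        wins = [Window("1:1", "1", 0, 100, np.arange(8))]
        res = window_variance_percentages(wins, u, Z, 0.4)
        total = 100 * np.var(Z @ u) / 0.4
        assert res[0].pct_variance == pytest.approx(total)

    def test_zero_effect_snp_does_not_change_window(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(15, 6))
        u = rng.normal(size=6)
        u[5] = 0.0
        w_small = [Window("1:1", "1", 0, 100, np.arange(5))]
        w_big = [Window("1:1", "1", 0, 120, np.arange(6))]
        a = window_variance_percentages(w_small, u, Z, 0.3)[0].pct_variance
        b = window_variance_percentages(w_big, u, Z, 0.3)[0].pct_variance
        assert a == pytest.approx(b)

    def test_nonpositive_genetic_variance_rejected(self):
        with pytest.raises(ValueError):
            window_variance_percentages([], np.zeros(1), np.zeros((2, 1)), 0.0)


@pytest.fixture(scope="module")
def loop_dataset():
    cfg = SimulationConfig(
        seed=23, n_founders=80, n_generations=2, n_animals_target=220,
        n_snps=600, n_chromosomes=3, chrom_length_bp=8_000_000,
        n_qtl=1, qtl_variance_fractions=(0.25,), h2=0.30, rep=0.50,
        prop_phenotyped=1.0, prop_genotyped=1.0,
    )
    data = simulate_dataset(cfg)
    panel, _ = apply_qc(data.panel)
    vc = VarianceComponents(
        data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
    )
    return data, panel, vc


class TestLoop:
    def test_trace_conserved_every_iteration(self, loop_dataset):
        data, panel, vc = loop_dataset
        res = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            blend_alpha=0.0, freq_source="base",
        )
        M = panel.n_snps
        for state in res.states:
            assert state.weights.sum() == pytest.approx(M, abs=1e-9 * M)

    def test_decomposition_identity_unblended(self, loop_dataset):
        data, panel, vc = loop_dataset
        res = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            blend_alpha=0.0, freq_source="base",
        )
        for state in res.states:
            assert state.identity_gap < 1e-8

    def test_first_iteration_is_unweighted(self, loop_dataset):
        data, panel, vc = loop_dataset
        res = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            n_iterations=1, blend_alpha=0.0, freq_source="base",
        )
        assert len(res.states) == 1
        assert np.allclose(res.states[0].weights, 1.0)

    def test_percentages_invariant_to_chromosome_labels(self, loop_dataset):
        data, panel, vc = loop_dataset
        res1 = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            blend_alpha=0.0, freq_source="base",
        )
        relabeled = panel.subset_snps(np.arange(panel.n_snps))
        relabeled.snp_map = relabeled.snp_map.assign(
            chrom="c" + relabeled.snp_map["chrom"].astype(str),
            snp="x" + relabeled.snp_map["snp"].astype(str),
        )
        res2 = run_wssgwas(
            data.phenotypes, data.pedigree, relabeled, vc,
            blend_alpha=0.0, freq_source="base",
        )
        p1 = sorted(w.pct_variance for w in res1.final_windows)
        p2 = sorted(w.pct_variance for w in res2.final_windows)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_qtl_weight_grows_across_iterations(self):
        """The true QTL SNP's variance weight is non-decreasing over the
        three iterations in at least 8 of 10 seeds."""
        good = 0
        for seed in range(1, 11):
            cfg = SimulationConfig(
                seed=seed, n_founders=80, n_generations=2, n_animals_target=220,
                n_snps=600, n_chromosomes=3, chrom_length_bp=8_000_000,
                n_qtl=1, qtl_variance_fractions=(0.25,), h2=0.30, rep=0.50,
                prop_phenotyped=1.0, prop_genotyped=1.0,
            )
            data = simulate_dataset(cfg)
            panel, _ = apply_qc(data.panel)
            snp_name = data.truth.qtl_map.iloc[0]["snp"]
            where = np.where(panel.snp_map["snp"] == snp_name)[0]
            if len(where) == 0:
                continue
            j = int(where[0])
            vc = VarianceComponents(
                data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
            )
            res = run_wssgwas(
                data.phenotypes, data.pedigree, panel, vc,
                blend_alpha=0.0, freq_source="base",
            )
            w = [state.weights[j] for state in res.states]
            if w[0] <= w[1] <= w[2]:
                good += 1
        assert good >= 8
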