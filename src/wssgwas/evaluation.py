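"""Reproducible evaluation studies for the method's key guarantees.

Each function runs the package end to end on freshly simulated data and
returns plain numbers: the exactness of the GEBV -> SNP-effect
decomposition, conservation of the weight trace, degenerate-limit
equivalences against pedigree BLUP, oracle agreement for the
relationship matrices and filters, REML parameter recovery, and the
power/calibration of QTL-window localization.  The studies are what
``scripts/acceptance.py`` and the acceptance test suite execute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import grm
from .gwas import define_windows, run_wssgwas
from .model import VarianceComponents, build_model, estimate_reml, solve_mme
from .pedigree import (
    Pedigree,
    build_A,
    build_A_inverse,
    extract_A22,
)
from .qc import apply_qc, hwe_chi2
from .regions import GeneAnnotation, QtlRegion, genes_in_region
from .simulate import SimulationConfig, simulate_dataset


def _seed_for(base_seed: int, offset: int) -> int:
    return int((base_seed * 1000 + offset) % (2**31 - 1))


def worked_example_thresholds(n_windows: int = 4223) -> dict:
    """Per-window equal-contribution expectation and the 50x selection
    threshold for a chip-scale genome (printed to two decimals)."""
    expectation = round(100.0 / n_windows, 2)
    return {
        "expected_window_pct": expectation,
        "selection_threshold_pct": expectation * 50.0,
        "n_windows": n_windows,
    }


def decomposition_identity_study(
    seed: int, n_animals: int = 200, n_snps: int = 1000, n_iterations: int = 3
) -> dict:
    """Z u = a_g exactness and trace conservation over the weighting loop,
    run unblended on a fresh simulation."""
    cfg = SimulationConfig(
        seed=_seed_for(seed, 1),
        n_founders=80,
        n_generations=2,
        n_animals_target=n_animals,
        n_snps=n_snps,
        n_chromosomes=4,
        chrom_length_bp=15_000_000,
        prop_phenotyped=1.0,
        prop_genotyped=1.0,
    )
    data = simulate_dataset(cfg)
    panel, _ = apply_qc(data.panel)
    vc = VarianceComponents(
        data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
    )
    res = run_wssgwas(
        data.phenotypes, data.pedigree, panel, vc,
        n_iterations=n_iterations, blend_alpha=0.0, freq_source="base",
    )
    M = panel.n_snps
    return {
        "identity_max_rel_err": max(s.identity_gap for s in res.states),
        "trace_max_abs_err": max(
            abs(float(s.weights.sum()) - M) for s in res.states
        ),
        "n_animals": len(panel.ids),
        "n_snps": M,
    }


def pedigree_equivalence_study(seed: int) -> dict:
    """Degenerate limits: with no genotyped animals the single-step GEBV
    equal pedigree BLUP, and G = A22 collapses the H inverse onto the A
    inverse exactly."""
    cfg = SimulationConfig(
        seed=_seed_for(seed, 2),
        n_founders=60,
        n_generations=2,
        n_animals_target=180,
        n_snps=300,
        n_chromosomes=2,
        chrom_length_bp=8_000_000,
        prop_phenotyped=0.8,
    )
    data = simulate_dataset(cfg)
    A = build_A(data.pedigree)
    A_inv = build_A_inverse(data.pedigree)
    vc = VarianceComponents(
        data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
    )
    # empty genotype set
    from .pedigree import RelationshipMatrix

    empty = RelationshipMatrix(np.zeros((0, 0)), [], "G")
    empty22 = RelationshipMatrix(np.zeros((0, 0)), [], "A22_inverse")
    H_empty = grm.build_H_inverse(A_inv, empty22, empty, [])
    sol_ped = solve_mme(build_model(data.phenotypes, A_inv), vc)
    sol_h = solve_mme(build_model(data.phenotypes, H_empty), vc)
    gebv_diff = float(
        np.max(np.abs(sol_ped.gebv.to_numpy() - sol_h.gebv.to_numpy()))
    )
    # G set equal to A22
    genotyped = data.truth.genotyped_ids
    A22 = extract_A22(A, genotyped)
    A22_inv = grm.invert_relationship(A22, "A22_inverse")
    G_inv = RelationshipMatrix(A22_inv.values.copy(), list(genotyped), "G")
    H_cancel = grm.build_H_inverse(A_inv, A22_inv, G_inv, genotyped)
    h_diff = float(np.max(np.abs(H_cancel.values - A_inv.values)))
    return {
        "pedigree_blup_gebv_max_diff": gebv_diff,
        "h_inverse_reduction_max_diff": h_diff,
        "n_animals": len(data.pedigree),
    }


def relationship_oracle_study(seed: int, sizes=(50, 200, 500)) -> dict:
    """A times its inverse against the identity on random pedigrees, and
    tabular A against a 1e5-replicate gene-drop IBD estimate."""
    rng = np.random.default_rng(_seed_for(seed, 3))
    worst = 0.0
    largest = 0
    for n in sizes:
        animals = [f"a{i}" for i in range(n)]
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(max(2, n // 4), n):
            sire[i], dam[i] = sorted(rng.choice(i, size=2, replace=False))
        ped = Pedigree(animals, sire, dam)
        A = build_A(ped).values
        Ainv = build_A_inverse(ped).values
        worst = max(worst, float(np.max(np.abs(A @ Ainv - np.eye(n)))))
        largest = max(largest, n)

    # gene-drop oracle on a half-sib pedigree with an inbred mating
    ped = Pedigree(
        ["s", "d1", "d2", "o1", "o2", "g"],
        np.array([-1, -1, -1, 0, 0, 3]),
        np.array([-1, -1, -1, 1, 2, 4]),
    )
    A = build_A(ped).values
    n_rep = 100_000
    n = len(ped.animals)
    alleles = np.zeros((n_rep, n, 2), dtype=np.int64)
    for i in range(n):
        if ped.sire[i] == -1:
            alleles[:, i, 0] = 2 * i
            alleles[:, i, 1] = 2 * i + 1
        else:
            ps = rng.integers(0, 2, n_rep)
            pd_ = rng.integers(0, 2, n_rep)
            alleles[:, i, 0] = alleles[np.arange(n_rep), ped.sire[i], ps]
            alleles[:, i, 1] = alleles[np.arange(n_rep), ped.dam[i], pd_]
    drop_err = 0.0
    for i in range(n):
        for j in range(i, n):
            shared = sum(
                (alleles[:, i, x] == alleles[:, j, y]).mean()
                for x in (0, 1)
                for y in (0, 1)
            )
            expected = (
                shared / 2
                if i != j
                else 1 + (alleles[:, i, 0] == alleles[:, i, 1]).mean()
            )
            drop_err = max(drop_err, abs(A[i, j] - expected))
    return {
        "a_inverse_identity_max_err": worst,
        "gene_drop_a_max_abs_diff": float(drop_err),
        "largest_pedigree": largest,
        "gene_drop_replicates": n_rep,
    }


def hwe_oracle_study(seed: int, n_triples: int = 500) -> dict:
    """hwe_chi2 against term-by-term expected-count arithmetic."""
    rng = np.random.default_rng(_seed_for(seed, 4))
    worst = 0.0
    for _ in range(n_triples):
        naa, nab, nbb = rng.integers(0, 400, 3)
        n = naa + nab + nbb
        if n == 0:
            continue
        p = (2 * naa + nab) / (2 * n)
        q = 1 - p
        if p in (0.0, 1.0):
            oracle = 0.0
        else:
            exp = [n * p * p, 2 * n * p * q, n * q * q]
            oracle = sum(
                (o - e) ** 2 / e for o, e in zip([naa, nab, nbb], exp)
            )
        worst = max(worst, abs(hwe_chi2(int(naa), int(nab), int(nbb)) - oracle))
    return {"hwe_chi2_oracle_max_diff": worst, "n_triples": n_triples}


def gene_lookup_oracle_study(seed: int, n_genes: int = 100, n_regions: int = 100) -> dict:
    """Interval-tree gene lookup against brute-force all-pairs intersection."""
    rng = np.random.default_rng(_seed_for(seed, 5))
    genes = pd.DataFrame(
        {
            "chrom": rng.choice(["1", "2", "3"], n_genes),
            "start": rng.integers(0, 2_000_000, n_genes),
        }
    )
    genes["end"] = genes["start"] + rng.integers(1, 100_000, n_genes)
    genes["gene_id"] = [f"g{i}" for i in range(n_genes)]
    genes["name"] = genes["gene_id"]
    ann = GeneAnnotation(genes)
    mismatches = 0
    for _ in range(n_regions):
        chrom = str(rng.choice(["1", "2", "3"]))
        start = int(rng.integers(1, 2_000_000))
        end = start + int(rng.integers(1, 150_000))
        region = QtlRegion(chrom=chrom, start=start, end=end)
        hits = {h.gene_id for h in genes_in_region(region, ann)}
        brute = {
            row.gene_id
            for row in genes.itertuples()
            if row.chrom == chrom and row.start < end and row.end > start - 1
        }
        mismatches += hits != brute
    return {"gene_lookup_mismatches": mismatches, "n_regions": n_regions}


def reml_recovery_study(seed: int, n_seeds: int = 5) -> dict:
    """REML heritability recovery at h2 = 0.30, repeatability 0.50,
    500 recorded boars with 10 records each, pedigree relationships."""
    h2s = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=_seed_for(seed, 10 + k),
            n_founders=100,
            n_generations=3,
            n_animals_target=600,
            n_snps=200,
            n_chromosomes=2,
            chrom_length_bp=8_000_000,
            h2=0.30,
            rep=0.50,
            records_per_animal=(10, 10),
            prop_phenotyped=500 / 600,
            prop_genotyped=0.5,
        )
        data = simulate_dataset(cfg)
        model = build_model(data.phenotypes, build_A_inverse(data.pedigree))
        h2s.append(estimate_reml(model).h2)
    mean_h2 = float(np.mean(h2s))
    return {
        "reml_h2_mean": mean_h2,
        "reml_h2_mean_abs_error": abs(mean_h2 - 0.30),
        "n_seeds": n_seeds,
        "n_boars": 500,
    }


def _power_config(seed: int, null: bool) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_founders=200,
        n_generations=2,
        n_animals_target=500,
        n_snps=2000,
        n_chromosomes=5,
        chrom_length_bp=24_000_000,
        n_qtl=0 if null else 1,
        qtl_variance_fractions=() if null else (0.10,),
        h2=0.30,
        rep=0.50,
        prop_phenotyped=1.0,
        prop_genotyped=1.0,
    )


def qtl_power_study(
    seed: int, n_seeds: int = 10, seeds: list[int] | None = None
) -> dict:
    """Is a QTL explaining 10% of the genetic variance inside one of the
    three top-variance 0.4 Mb windows?"""
    seeds = seeds if seeds is not None else [
        _seed_for(seed, 20 + k) for k in range(n_seeds)
    ]
    n_seeds = len(seeds)
    hits = 0
    for rep_seed in seeds:
        cfg = _power_config(rep_seed, null=False)
        data = simulate_dataset(cfg)
        panel, _ = apply_qc(data.panel)
        vc = VarianceComponents(
            data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
        )
        res = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            blend_alpha=0.0, freq_source="base",
        )
        top3 = sorted(
            res.final_windows,
            key=lambda w: (-w.pct_variance, w.chrom, w.start_pos),
        )[:3]
        chrom = str(data.truth.qtl_map.iloc[0]["chrom"])
        pos = int(data.truth.qtl_map.iloc[0]["pos"])
        hits += any(
            w.chrom == chrom and w.start_pos <= pos <= w.end_pos for w in top3
        )
    return {
        "qtl_top3_hit_rate": hits / n_seeds,
        "qtl_top3_hits": hits,
        "n_seeds": n_seeds,
    }


def null_calibration_study(
    seed: int, n_seeds: int = 10, seeds: list[int] | None = None
) -> dict:
    """Concentration of window percentages under a marker-mediated pure
    polygene: how often does the largest window stay below five times the
    equal-contribution expectation at the final iteration?"""
    seeds = seeds if seeds is not None else [
        _seed_for(seed, 40 + k) for k in range(n_seeds)
    ]
    n_seeds = len(seeds)
    passes = 0
    worst_ratio = 0.0
    for rep_seed in seeds:
        cfg = _power_config(rep_seed, null=True)
        data = simulate_dataset(cfg)
        panel, _ = apply_qc(data.panel)
        vc = VarianceComponents(
            data.truth.sigma2_a, data.truth.sigma2_p, data.truth.sigma2_e
        )
        res = run_wssgwas(
            data.phenotypes, data.pedigree, panel, vc,
            blend_alpha=0.0, freq_source="base",
        )
        expectation = 100.0 / len(res.final_windows)
        ratio = max(w.pct_variance for w in res.final_windows) / expectation
        worst_ratio = max(worst_ratio, ratio)
        passes += ratio < 5.0
    return {
        "null_calibration_pass_rate": passes / n_seeds,
        "null_max_window_ratio": worst_ratio,
        "n_seeds": n_seeds,
    }


def window_determinism_study() -> dict:
    """Hand-computable window partition, boundary merges and flank clipping."""
    from .gwas import WindowResult
    from .regions import overlap_windows, top_windows_with_flanks

    snp_map = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(5)],
            "chrom": ["1"] * 5,
            "pos": [0, 100_000, 300_000, 450_000, 900_000],
        }
    )
    windows = define_windows(snp_map, span_bp=400_000)
    partition = [len(w.snp_indices) for w in windows]

    def wr(start, end, pct, trait):
        return WindowResult(
            window_id=f"1:{start}", chrom="1", start_pos=start, end_pos=end,
            snp_indices=np.array([0]), pct_variance=pct, trait=trait, n_snps=1,
        )

    merged = overlap_windows(
        {"t1": [wr(9_900_000, 10_100_000, 2.0, "t1")],
         "t2": [wr(10_200_000, 10_400_000, 1.5, "t2")]}
    )
    apart = overlap_windows(
        {"t1": [wr(9_950_000, 10_050_000, 2.0, "t1")],
         "t2": [wr(10_350_000, 10_450_000, 1.5, "t2")]}
    )
    clipped = top_windows_with_flanks(
        [wr(50_000, 150_000, 2.0, "t1")], k=1, flank_bp=400_000
    )[0]
    return {
        "greedy_partition_sizes": partition,
        "greedy_window_count": len(windows),
        "boundary_merge_region_count": len(merged),
        "boundary_nonmerge_region_count": len(apart),
        "clipped_flank_start_bp": clipped.start,
        "clipped_flank_end_bp": clipped.end,
    }
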