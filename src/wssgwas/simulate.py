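"""Synthetic pig-breeding-like data with the structure the analysis assumes.

The generator emulates a commercial boar line: a shallow multi-generation
pedigree, SNP genotypes with haplotype-block linkage disequilibrium on a
~0.4 Mb scale, a handful of large QTL on top of a polygenic background,
and repeated ejaculate records per boar under a repeatability model
(contemporary-group fixed effects, two record-level covariates, a
permanent-environment effect, and low-to-moderate heritability).

Defaults target desk scale: a few hundred animals and a few thousand
SNPs, with per-window SNP counts comparable to a 60K chip on a 2.3 Gb
genome (one SNP per ~60 kb, ~7 SNPs per 0.4 Mb window).

One integer seed governs all stages through ``numpy.random.SeedSequence``
spawning, so each stage is reproducible in isolation and the whole
dataset is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree
from .qc import GenotypePanel

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]

# Sub-stream indices of the master SeedSequence, fixed so each stage can
# be re-run independently of the others.
_STREAM_PEDIGREE = 0
_STREAM_GENOTYPES = 1
_STREAM_PHENOTYPES = 2
_STREAM_SAMPLING = 3


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with study-like defaults.

    ``h2`` is narrow-sense heritability sigma2_a / sigma2_total and
    ``rep`` the repeatability (sigma2_a + sigma2_p) / sigma2_total of the
    simulated trait; total random variance is scaled to 1.  QTL variance
    fractions are fractions of sigma2_a; the remainder is a marker-
    mediated polygenic background spread over all non-QTL SNPs.
    """

    seed: int = 0
    n_founders: int = 60
    n_generations: int = 3
    n_animals_target: int = 420
    n_chromosomes: int = 5
    chrom_length_bp: int = 24_000_000
    n_snps: int = 2000
    block_size_bp: int = 400_000
    n_qtl: int = 3
    qtl_variance_fractions: tuple[float, ...] = (0.10, 0.08, 0.05)
    h2: float = 0.20
    rep: float = 0.45
    records_per_animal: tuple[int, int] = (10, 50)
    mean_records: float = 25.0
    n_fixed_groups: int = 12
    covariate_effects: tuple[float, float] = (0.20, 0.10)  # interval days, age months
    prop_genotyped: float = 0.6
    prop_phenotyped: float = 0.6
    ancestral_haplotypes: int = 8
    haplotype_diversity: float = 0.0  # per-SNP deviation rate from the pool haplotype
    inject_qc_failures: bool = False
    qtl_snp_override: tuple[int, ...] | None = None  # plant QTL at fixed SNP indices

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= self.rep < 1.0):
            raise ValueError("need 0 < h2 <= rep < 1")
        if sum(self.qtl_variance_fractions) > 1.0 + 1e-12:
            raise ValueError("QTL variance fractions must sum to <= 1")
        if len(self.qtl_variance_fractions) != self.n_qtl:
            raise ValueError("qtl_variance_fractions length must equal n_qtl")
        if self.block_size_bp <= 0:
            raise ValueError("block_size_bp must be positive")
        for p in (self.prop_genotyped, self.prop_phenotyped):
            if not (0.0 < p <= 1.0):
                raise ValueError("prop_genotyped/prop_phenotyped must be in (0, 1]")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if self.records_per_animal[0] < 1:
            raise ValueError("records_per_animal lower bound must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        child = np.random.SeedSequence(self.seed).spawn(max(stream + 1, 4))[stream]
        return np.random.default_rng(child)


@dataclass
class TrueValues:
    """Ground truth kept for recovery tests."""

    tbv: pd.Series  # per animal
    pe: pd.Series  # per phenotyped animal
    qtl_snp_indices: np.ndarray
    qtl_effects: np.ndarray
    sigma2_a: float
    sigma2_p: float
    sigma2_e: float
    group_effects: np.ndarray
    phenotyped_ids: list[str] = field(default_factory=list)
    genotyped_ids: list[str] = field(default_factory=list)
    qtl_map: pd.DataFrame = field(default_factory=pd.DataFrame)  # chrom, pos per QTL
    snp_effects: np.ndarray | None = None  # true per-SNP effects (QTL + background)


@dataclass
class SimulatedData:
    config: SimulationConfig
    pedigree: Pedigree
    panel: GenotypePanel
    phenotypes: pd.DataFrame
    truth: TrueValues


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random-mating pedigree: founders plus ``n_generations`` cohorts.

    Sires and dams are drawn from all earlier generations; sexes are
    assigned at random but each cohort is forced to contain both, so
    mating never becomes impossible downstream.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config.n_generations < 1:
        raise ValueError("need at least 1 generation")
    rng = config.rng(_STREAM_PEDIGREE)
    animals: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[int] = []  # 0 male, 1 female

    for i in range(config.n_founders):
        animals.append(f"F{i + 1:04d}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        sex.append(i % 2)  # alternate so both sexes always exist
    if len(set(sex)) < 2:
        raise ValueError("founder cohort contains a single sex; mating impossible")

    n_offspring_total = max(config.n_animals_target - config.n_founders, 0)
    per_gen = _split_counts(n_offspring_total, config.n_generations)
    for g, n_off in enumerate(per_gen, start=1):
        males = [i for i, s in enumerate(sex) if s == 0]
        females = [i for i, s in enumerate(sex) if s == 1]
        if not males or not females:
            raise ValueError(f"generation {g}: single sex available, mating impossible")
        new_sex = rng.integers(0, 2, size=n_off)
        if n_off >= 2:  # keep both sexes present for later cohorts
            new_sex[0], new_sex[1] = 0, 1
        for k in range(n_off):
            animals.append(f"G{g}{k + 1:04d}")
            sire.append(int(rng.choice(males)))
            dam.append(int(rng.choice(females)))
            sex.append(int(new_sex[k]))
    return Pedigree(animals, np.array(sire), np.array(dam))


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _block_edges(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """SNP map and per-SNP block index; blocks tile each chromosome."""
    rng = config.rng(_STREAM_GENOTYPES)
    per_chrom = _split_counts(config.n_snps, config.n_chromosomes)
    rows = []
    block_of = []
    block_id = 0
    for c, n_c in enumerate(per_chrom, start=1):
        pos = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=n_c))
        pos = np.unique(pos)
        while len(pos) < n_c:  # regenerate collisions, rare
            extra = rng.integers(1, config.chrom_length_bp + 1, size=n_c - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        blocks = (pos - 1) // config.block_size_bp
        # renumber blocks consecutively genome-wide
        uniq, local = np.unique(blocks, return_inverse=True)
        block_of.append(local + block_id)
        block_id += len(uniq)
        for j, p in enumerate(pos):
            rows.append((f"snp_c{c}_{j + 1}", str(c), int(p)))
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    return snp_map, np.concatenate(block_of)


def simulate_genotypes(ped: Pedigree, config: SimulationConfig) -> GenotypePanel:
    """Haplotype-block genotypes by gene dropping through the pedigree.

    Founder haplotypes are mosaics of a small per-block pool of
    ancestral haplotypes (strong LD within a block, none across blocks);
    each meiosis places one crossover per chromosome uniformly over
    block boundaries.  The returned panel covers *all* pedigree animals;
    downstream code subsets to the genotyped set.
    """
    rng = config.rng(_STREAM_GENOTYPES)
    snp_map, block_of = _block_edges(config)
    M = len(snp_map)
    n_blocks = int(block_of.max()) + 1
    K = config.ancestral_haplotypes

    # ancestral pool: per block, K haplotypes; each SNP's pool count is
    # anchored between 1 and K-1 so every SNP stays polymorphic
    pool = np.zeros((K, M), dtype=np.int8)
    target_p = rng.uniform(0.05, 0.5, size=M)
    base_freqs = np.zeros(M)
    for j in range(M):
        k = int(np.clip(np.round(K * target_p[j]), 1, K - 1))
        carriers = rng.choice(K, size=k, replace=False)
        pool[carriers, j] = 1
        base_freqs[j] = k / K

    n = len(ped)
    hap = np.zeros((n, 2, M), dtype=np.int8)
    chrom_codes = snp_map["chrom"].to_numpy()
    chroms = list(dict.fromkeys(chrom_codes))
    chrom_slices = [np.where(chrom_codes == c)[0] for c in chroms]
    # block boundaries within each chromosome (cut points in SNP index space)
    block_cuts = []
    for sl in chrom_slices:
        b = block_of[sl]
        cuts = np.where(np.diff(b) != 0)[0] + 1  # positions between blocks
        block_cuts.append(cuts)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for h, parent in enumerate((s, d)):
            if parent == UNKNOWN:
                # founder haplotype: one ancestral haplotype per block, with
                # per-SNP deviations so blocks carry realistic internal
                # diversity (chip-scale r2 well below 1 within a block)
                choice = rng.integers(0, K, size=n_blocks)
                h_new = pool[choice[block_of], np.arange(M)]
                dev = rng.random(M) < config.haplotype_diversity
                if dev.any():
                    h_new = h_new.copy()
                    h_new[dev] = (
                        rng.random(int(dev.sum())) < base_freqs[dev]
                    ).astype(np.int8)
                hap[i, h] = h_new
            else:
                hap[i, h] = _gamete(hap[parent], chrom_slices, block_cuts, rng)

    geno = (hap[:, 0, :] + hap[:, 1, :]).astype(np.int8)
    if config.inject_qc_failures:
        geno = _inject_failures(geno, rng)
    return GenotypePanel(
        genotypes=geno,
        ids=list(ped.animals),
        snp_map=snp_map,
        base_freqs=base_freqs,
    )


def _gamete(parent_hap: np.ndarray, chrom_slices, block_cuts, rng) -> np.ndarray:
    """One crossover per chromosome, placed uniformly over block boundaries."""
    M = parent_hap.shape[1]
    out = np.empty(M, dtype=np.int8)
    for sl, cuts in zip(chrom_slices, block_cuts):
        start_hap = int(rng.integers(0, 2))
        # crossover position: 0..len(cuts); endpoints mean no visible crossover
        k = int(rng.integers(0, len(cuts) + 1))
        cut = cuts[k - 1] if k >= 1 else 0
        if k == 0:
            out[sl] = parent_hap[start_hap, sl]
        else:
            local = np.concatenate(
                [parent_hap[start_hap, sl[:cut]], parent_hap[1 - start_hap, sl[cut:]]]
            )
            out[sl] = local
    return out


def _inject_failures(geno: np.ndarray, rng) -> np.ndarray:
    """Plant low-MAF, low-call-rate and HWE-violating SNPs plus one bad animal."""
    geno = geno.copy()
    n, M = geno.shape
    if M >= 10 and n >= 10:
        geno[:, 0] = 0
        geno[rng.integers(0, n), 0] = 1  # MAF ~ 1/(2n) < 0.01 for n >= 50
        miss = rng.choice(n, size=max(1, int(0.1 * n)), replace=False)
        geno[miss, 1] = -1  # call rate < 0.95 when >5% missing
        geno[:, 2] = rng.choice([0, 2], size=n)  # no heterozygotes: HWE blown
        bad = rng.integers(0, n)
        cols = rng.choice(M, size=max(1, int(0.08 * M)), replace=False)
        geno[bad, cols] = -1
    return geno


def _record_counts(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Ejaculate counts per boar: rounded negative-binomial, clipped to range."""
    lo, hi = config.records_per_animal
    if lo == hi:
        return np.full(n, lo, dtype=np.int64)
    mean = float(np.clip(config.mean_records, lo, hi))
    disp = 3.0  # overdispersion typical of per-boar collection counts
    p = disp / (disp + mean)
    counts = rng.negative_binomial(disp, p, size=n)
    return np.clip(counts, lo, hi).astype(np.int64)


def _scale_exact(x: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Center and rescale a sample to an exact variance; returns (sample, factor)."""
    x = x - x.mean()
    v = float(x @ x) / len(x)
    if v == 0:
        return x, 0.0
    f = np.sqrt(target_var / v)
    return x * f, f


def simulate_phenotypes(
    ped: Pedigree, panel: GenotypePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, TrueValues]:
    """Repeated records under y = group + covariates + TBV + PE + residual.

    TBV = QTL effects x gene content + pedigree polygenic term.  The
    realized TBV and PE samples over phenotyped animals, and the
    residual sample over records, are rescaled to their exact target
    variances, so heritability and repeatability hold exactly in-sample.
    """
    if config.h2 <= 0:
        raise ValueError("h2 = 0 makes the genetic model unidentifiable")
    rng = config.rng(_STREAM_PHENOTYPES)
    samp = config.rng(_STREAM_SAMPLING)
    n = len(ped)
    sigma2_a = config.h2
    sigma2_p = config.rep - config.h2
    sigma2_e = 1.0 - config.rep

    geno = panel.genotypes.astype(np.float64)
    geno[geno < 0] = np.nan
    freqs = np.nanmean(geno, axis=0) / 2.0
    var_g = np.nanvar(geno, axis=0)

    # QTL are planted at common SNPs (MAF >= 0.2): chip markers are
    # ascertained for common variation, and a stated variance fraction at
    # a rare variant would concentrate in a handful of carriers that the
    # surrounding haplotype block tags poorly
    eligible = np.where((freqs >= 0.2) & (freqs <= 0.8))[0]
    if len(eligible) < config.n_qtl:
        eligible = np.arange(panel.n_snps)
    if config.qtl_snp_override is not None:
        qtl_idx = np.sort(np.asarray(config.qtl_snp_override, dtype=np.int64))
        if len(qtl_idx) != config.n_qtl:
            raise ValueError("qtl_snp_override length must equal n_qtl")
    else:
        qtl_idx = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
    fracs = np.asarray(config.qtl_variance_fractions, dtype=float)
    effects = np.zeros(config.n_qtl)
    for k, j in enumerate(qtl_idx):
        effects[k] = np.sqrt(fracs[k] * sigma2_a / max(var_g[j], 1e-12))
        effects[k] *= rng.choice([-1.0, 1.0])

    qtl_part = np.zeros(n)
    for k, j in enumerate(qtl_idx):
        g = np.nan_to_num(geno[:, j], nan=2 * freqs[j])
        qtl_part += effects[k] * (g - g.mean())

    # polygenic background: small effects at every non-QTL SNP, inherited
    # through the pedigree with the genotypes (genomic infinitesimal model)
    sigma2_poly = sigma2_a * max(1.0 - fracs.sum(), 0.0)
    poly = np.zeros(n)
    snp_effects = np.zeros(panel.n_snps)
    snp_effects[qtl_idx] = effects
    if sigma2_poly > 0:
        bg = np.ones(panel.n_snps, dtype=bool)
        bg[qtl_idx] = False
        beta_bg = rng.normal(0.0, 1.0, size=int(bg.sum()))
        g_bg = np.nan_to_num(geno[:, bg], nan=0.0)
        poly = (g_bg - g_bg.mean(axis=0)) @ beta_bg
        v = float(np.var(poly))
        if v > 0:
            beta_bg *= np.sqrt(sigma2_poly / v)
            poly *= np.sqrt(sigma2_poly / v)
        snp_effects[bg] = beta_bg
    tbv = qtl_part + poly

    # choose genotyped / phenotyped sets; overlap left to chance so many
    # animals carry only one kind of information, as in the study design
    ids = np.array(ped.animals)
    n_geno = max(2, int(round(config.prop_genotyped * n)))
    n_phen = max(2, int(round(config.prop_phenotyped * n)))
    genotyped = np.sort(samp.choice(n, size=n_geno, replace=False))
    phenotyped = np.sort(samp.choice(n, size=n_phen, replace=False))

    # Exact-variance scaling over the phenotyped animals.  The sample
    # variance of breeding values among related animals is not sigma2_a
    # but sigma2_a * (tr(A)/n - 1'A1/n^2); scaling to that target keeps
    # the base-population variance (what REML estimates) on target.
    from .pedigree import build_A

    A_ph = build_A(ped).values[np.ix_(phenotyped, phenotyped)]
    n_ph = len(phenotyped)
    drift = float(np.trace(A_ph) / n_ph - A_ph.sum() / n_ph**2)
    tbv_ph = tbv[phenotyped]
    centred = tbv_ph - tbv_ph.mean()
    v = float(centred @ centred) / n_ph
    f = np.sqrt(sigma2_a * drift / v) if v > 0 else 0.0
    tbv = (tbv - tbv_ph.mean()) * f
    effects = effects * f
    snp_effects = snp_effects * f

    pe = np.zeros(n)
    pe_raw = rng.normal(0.0, 1.0, size=len(phenotyped))
    pe_scaled, _ = _scale_exact(pe_raw, sigma2_p) if sigma2_p > 0 else (pe_raw * 0, 0)
    pe[phenotyped] = pe_scaled

    counts = _record_counts(config, len(phenotyped), rng)
    group_effects = rng.normal(0.0, 0.5, size=config.n_fixed_groups)
    b_interval, b_age = config.covariate_effects

    rows = []
    resid_all = []
    for ai, ct in zip(phenotyped, counts):
        for r in range(ct):
            rows.append((ids[ai], ai))
    n_rec = len(rows)
    groups = rng.integers(0, config.n_fixed_groups, size=n_rec)
    interval = rng.normal(0.0, 1.0, size=n_rec)
    age = rng.normal(0.0, 1.0, size=n_rec)
    resid, _ = _scale_exact(rng.normal(0.0, 1.0, size=n_rec), sigma2_e)

    records = pd.DataFrame(
        {
            "animal": [r[0] for r in rows],
            "record_id": [f"r{k + 1:06d}" for k in range(n_rec)],
            "trait": "trait",
            "fixed_group": [f"g{g + 1:02d}" for g in groups],
            "interval_days": interval,
            "age_months": age,
        }
    )
    a_idx = np.array([r[1] for r in rows])
    records["value"] = (
        group_effects[groups]
        + b_interval * interval
        + b_age * age
        + tbv[a_idx]
        + pe[a_idx]
        + resid
    )

    truth = TrueValues(
        tbv=pd.Series(tbv, index=ids),
        pe=pd.Series(pe[phenotyped], index=ids[phenotyped]),
        qtl_snp_indices=qtl_idx,
        qtl_effects=effects,
        sigma2_a=sigma2_a,
        sigma2_p=sigma2_p,
        sigma2_e=sigma2_e,
        group_effects=group_effects,
        phenotyped_ids=list(ids[phenotyped]),
        genotyped_ids=list(ids[genotyped]),
        qtl_map=panel.snp_map.iloc[qtl_idx][["snp", "chrom", "pos"]].reset_index(
            drop=True
        ),
        snp_effects=snp_effects,
    )
    return records, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Run all stages and subset the panel to the genotyped animals."""
    ped = simulate_pedigree(config)
    panel_all = simulate_genotypes(ped, config)
    records, truth = simulate_phenotypes(ped, panel_all, config)
    panel = panel_all.subset_animals(truth.genotyped_ids)
    return SimulatedData(config, ped, panel, records, truth)


# ---------------------------------------------------------------------------
# writers for the pipeline's own input formats

def write_inputs(data: SimulatedData, outdir) -> dict[str, str]:
    """Write pedigree/phenotype CSVs, PLINK-style text, and a fake gene BED."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ped_path = outdir / "pedigree.csv"
    data.pedigree.to_csv(ped_path)
    paths["pedigree"] = str(ped_path)

    phen_path = outdir / "phenotypes.csv"
    data.phenotypes.to_csv(phen_path, index=False)
    paths["phenotypes"] = str(phen_path)

    from .qc import write_plink_text

    geno_prefix = outdir / "genotypes"
    write_plink_text(data.panel, geno_prefix)
    paths["genotypes"] = str(geno_prefix)

    bed_path = outdir / "genes.bed"
    write_fake_gene_bed(data, bed_path)
    paths["annotation"] = str(bed_path)
    return paths


def write_fake_gene_bed(data: SimulatedData, path, gene_span_bp: int = 50_000) -> None:
    """Synthetic gene annotation: one interval around every 20th SNP (and each
    QTL), BED 0-based half-open, for exercising interval lookup."""
    snp_map = data.panel.snp_map
    take = sorted(set(range(0, len(snp_map), 20)) | set(data.truth.qtl_snp_indices))
    with open(path, "w") as fh:
        for k, j in enumerate(take):
            chrom = snp_map.iloc[j]["chrom"]
            pos = int(snp_map.iloc[j]["pos"])
            start = max(pos - 1 - gene_span_bp // 2, 0)
            end = pos - 1 + gene_span_bp // 2
            tag = "QTLGENE" if j in set(data.truth.qtl_snp_indices) else "GENE"
            fh.write(f"{chrom}\t{start}\t{end}\t{tag}{k + 1:04d}\n")
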