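"""SNP and animal quality control, allele frequencies, centered gene content.

Filters mirror standard chip QC for pig 60K data: drop unmapped and
sex-chromosome SNPs, SNP call rate >= 0.95, minor allele frequency >=
0.01, Hardy-Weinberg goodness-of-fit chi2 <= 600, then animals with more
than 5% missing genotypes.  The filter order is fixed and logged so
removal counts are reproducible.  Remaining missing genotypes are
mean-imputed (filled with 2p per SNP) and every SNP is recoded so the
counted allele is the minor one, making the centering frequency equal
the minor allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING = -1
SEX_CHROMOSOMES = {"X", "Y", "XY", "MT", "23", "24", "25", "26"}


@dataclass
class GenotypePanel:
    """Gene contents (0/1/2, ``-1`` missing) with a sorted SNP map.

    ``freqs`` is the counted-allele frequency per SNP, populated after
    QC (where it equals the minor allele frequency).  ``base_freqs``
    optionally carries base-population allele frequencies — the
    simulator records its founder-pool frequencies there — used when the
    genomic relationship matrix should be centered on base rather than
    observed frequencies.
    """

    genotypes: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame  # columns: snp, chrom, pos
    freqs: np.ndarray | None = None
    base_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        n, m = self.genotypes.shape
        if n != len(self.ids):
            raise ValueError("genotype rows do not match animal ids")
        if m != len(self.snp_map):
            raise ValueError("genotype columns do not match SNP map")
        sm = self.snp_map
        for chrom, grp in sm.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP map not sorted by position on chromosome {chrom}")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def observed_freqs(self) -> np.ndarray:
        """Counted-allele frequency per SNP from non-missing calls."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def subset_animals(self, ids) -> "GenotypePanel":
        pos = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in pos]
        if missing:
            raise KeyError(f"animals not in panel: {missing}")
        take = np.array([pos[a] for a in ids])
        return replace(
            self,
            genotypes=self.genotypes[take].copy(),
            ids=list(ids),
            snp_map=self.snp_map.reset_index(drop=True),
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            genotypes=self.genotypes[:, keep].copy(),
            ids=list(self.ids),
            snp_map=self.snp_map.iloc[keep].reset_index(drop=True),
            freqs=None if self.freqs is None else self.freqs[keep].copy(),
            base_freqs=None if self.base_freqs is None else self.base_freqs[keep].copy(),
        )


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    max_hwe_chi2: float = 600.0
    max_animal_missing: float = 0.05
    drop_unmapped: bool = True
    drop_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must lie in [0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.max_hwe_chi2 < 0 or not (0.0 <= self.max_animal_missing <= 1.0):
            raise ValueError("invalid QC thresholds")


@dataclass
class QcReport:
    """Per-rule removal tally, in application order."""

    snps_unmapped_or_sex: int = 0
    snps_call_rate: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    animals_missingness: int = 0
    snps_in: int = 0
    snps_out: int = 0
    animals_in: int = 0
    animals_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("1_unmapped_or_sex_chromosome", "snp", self.snps_unmapped_or_sex),
            ("2_call_rate", "snp", self.snps_call_rate),
            ("3_minor_allele_frequency", "snp", self.snps_maf),
            ("4_hardy_weinberg_chi2", "snp", self.snps_hwe),
            ("5_animal_missingness", "animal", self.animals_missingness),
        ]
        return pd.DataFrame(rows, columns=["rule", "unit", "removed"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df goodness-of-fit chi2 against Hardy-Weinberg expected counts.

    Expected counts are n*p^2, 2n*p*q, n*q^2 with p estimated from the
    sample.  Monomorphic input returns 0 by convention (such SNPs are
    removed by the MAF filter, not this one).
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("no genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    return float(np.sum((observed - expected) ** 2 / expected))


def apply_qc(
    panel: GenotypePanel, thresholds: QcThresholds | None = None
) -> tuple[GenotypePanel, QcReport]:
    """Apply the SNP/animal filters in fixed order and finalize the panel.

    Order: (1) unmapped / sex-chromosome SNPs, (2) SNP call rate,
    (3) MAF, (4) HWE chi2, (5) animal missingness.  Afterwards allele
    frequencies are recomputed on survivors, missing entries mean-imputed,
    and codes flipped so the counted allele is the minor one.
    """
    th = thresholds or QcThresholds()
    report = QcReport(snps_in=panel.n_snps, animals_in=panel.n_animals)
    geno = panel.genotypes.astype(np.int8).copy()
    snp_map = panel.snp_map.reset_index(drop=True)
    base = panel.base_freqs.copy() if panel.base_freqs is not None else None

    keep = np.ones(geno.shape[1], dtype=bool)
    chrom = snp_map["chrom"].astype(str).str.upper()
    rule1 = np.zeros(geno.shape[1], dtype=bool)
    if th.drop_unmapped:
        rule1 |= (chrom == "0") | (chrom == "") | snp_map["pos"].isna().to_numpy()
    if th.drop_sex_chromosomes:
        rule1 |= chrom.isin(SEX_CHROMOSOMES).to_numpy()
    report.snps_unmapped_or_sex = int(rule1.sum())
    keep &= ~rule1

    miss = geno == MISSING
    call_rate = 1.0 - miss.mean(axis=0)
    rule2 = keep & (call_rate < th.min_call_rate)
    report.snps_call_rate = int(rule2.sum())
    keep &= ~rule2

    g = geno.astype(float)
    g[miss] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    maf = np.minimum(freq, 1.0 - freq)
    rule3 = keep & (maf < th.min_maf)
    report.snps_maf = int(rule3.sum())
    keep &= ~rule3

    chi2 = np.zeros(geno.shape[1])
    for j in np.where(keep)[0]:
        col = geno[:, j]
        chi2[j] = hwe_chi2(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    rule4 = keep & (chi2 > th.max_hwe_chi2)
    report.snps_hwe = int(rule4.sum())
    keep &= ~rule4

    if not keep.any():
        raise ValueError(
            "QC removed every SNP; per-rule removals: "
            + report.to_frame().to_string(index=False)
        )

    geno = geno[:, keep]
    snp_map = snp_map.loc[keep].reset_index(drop=True)
    if base is not None:
        base = base[keep]

    animal_missing = (geno == MISSING).mean(axis=1)
    keep_animals = animal_missing <= th.max_animal_missing
    report.animals_missingness = int((~keep_animals).sum())
    geno = geno[keep_animals]
    ids = [a for a, k in zip(panel.ids, keep_animals) if k]

    # finalize: frequencies on survivors, mean fill, flip to minor allele
    g = geno.astype(float)
    g[g == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    flip = freq > 0.5
    geno = geno.copy()
    nonmiss = geno != MISSING
    geno[:, flip] = np.where(nonmiss[:, flip], 2 - geno[:, flip], MISSING)
    freq = np.where(flip, 1.0 - freq, freq)
    if base is not None:
        base = np.where(flip, 1.0 - base, base)

    filled = geno.astype(np.float64)
    for j in np.where(~nonmiss.all(axis=0))[0]:
        filled[filled[:, j] == MISSING, j] = 2.0 * freq[j]

    out = GenotypePanel(
        genotypes=filled,
        ids=ids,
        snp_map=snp_map,
        freqs=freq,
        base_freqs=base,
    )
    report.snps_out = out.n_snps
    report.animals_out = out.n_animals
    return out, report


def center_gene_content(
    panel: GenotypePanel, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Z matrix: gene content minus twice the allele frequency, per SNP.

    Uses the panel's QC frequencies unless ``freqs`` overrides them
    (e.g. base-population frequencies).  Missing entries must have been
    filled by QC first.
    """
    if np.any(panel.genotypes == MISSING):
        raise ValueError("panel contains missing genotypes; run apply_qc first")
    p = panel.freqs if freqs is None else np.asarray(freqs, dtype=float)
    if p is None:
        raise ValueError("no allele frequencies available; run apply_qc first")
    if len(p) != panel.n_snps:
        raise ValueError("frequency vector length does not match SNP count")
    return panel.genotypes.astype(np.float64) - 2.0 * p


# ---------------------------------------------------------------------------
# plain-text genotype formats

def write_plink_text(panel: GenotypePanel, prefix) -> None:
    """PLINK-style .ped/.map text pair (counted allele written as 'B')."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for _, row in panel.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{int(row['pos'])}\n")
    code = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    geno = np.rint(panel.genotypes).astype(int)
    with open(prefix + ".ped", "w") as fh:
        for i, animal in enumerate(panel.ids):
            alleles = " ".join(code[int(v)] for v in geno[i])
            fh.write(f"FAM {animal} 0 0 0 -9 {alleles}\n")


def read_plink_text(prefix) -> GenotypePanel:
    """Read a PLINK-style .ped/.map text pair written by this package
    (or any biallelic A/B-coded pair)."""
    prefix = str(prefix)
    snp_map = pd.read_csv(
        prefix + ".map",
        sep="\t",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str},
    )[["snp", "chrom", "pos"]]
    ids = []
    rows = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            a = np.array(alleles[0::2])
            b = np.array(alleles[1::2])
            g = (a == "B").astype(np.int8) + (b == "B").astype(np.int8)
            g[(a == "0") | (b == "0")] = MISSING
            rows.append(g)
    return GenotypePanel(np.vstack(rows), ids, snp_map)


def write_additive_text(panel: GenotypePanel, path) -> None:
    """Transposed additive-coded text: one row per animal, 0/1/2 codes."""
    geno = np.rint(panel.genotypes).astype(int)
    with open(path, "w") as fh:
        fh.write("animal\t" + "\t".join(panel.snp_map["snp"]) + "\n")
        for i, animal in enumerate(panel.ids):
            fh.write(animal + "\t" + "\t".join(str(v) for v in geno[i]) + "\n")


def read_additive_text(path, snp_map: pd.DataFrame) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    geno = df.to_numpy(dtype=np.int8)
    return GenotypePanel(geno, list(df.index.astype(str)), snp_map)
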