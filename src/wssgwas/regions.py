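"""QTL-region selection: thresholding, midpoint merging, flanks, gene lookup.

Windows explaining at least 1% of the genetic variance (50x the
equal-contribution expectation for a ~4000-window genome) are selected
per trait; selected windows whose midpoints lie strictly less than
0.4 Mb apart on the same chromosome are merged into QTL regions by
single linkage, within a population across its traits and across
populations for the same trait.  The three highest-variance windows per
trait are additionally reported with 0.4 Mb flanks on either side of
their midpoints.  Genes are attached by interval intersection against a
BED/GFF3 annotation.

Coordinates are 0-based half-open internally; report output is 1-based
inclusive bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gwas import WindowResult

DEFAULT_GAP_BP = 400_000
DEFAULT_FLANK_BP = 400_000


@dataclass
class GeneHit:
    gene_id: str
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int


@dataclass
class QtlRegion:
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    members: list[WindowResult] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)
    pct_by_trait: dict[str, float] = field(default_factory=dict)
    flanked: bool = False
    gene_hits: list[GeneHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start exceeds end")

    @property
    def n_snps(self) -> int:
        return sum(w.n_snps for w in self.members)


def expected_window_pct(n_windows: int) -> float:
    """Equal-contribution expectation: each of n windows explains 100/n %."""
    if n_windows <= 0:
        raise ValueError("need at least one window")
    return 100.0 / n_windows


def threshold_from_expectation(n_windows: int, multiple: float = 50.0,
                               digits: int = 2) -> float:
    """Selection threshold as a multiple of the (rounded) expectation."""
    return round(expected_window_pct(n_windows), digits) * multiple


def select_windows(
    results: list[WindowResult], threshold_pct: float = 1.0
) -> list[WindowResult]:
    """Windows explaining ``threshold_pct`` percent of variance or more."""
    return [w for w in results if w.pct_variance >= threshold_pct]


def _single_linkage_clusters(
    windows: list[tuple[WindowResult, str, str]], max_gap_bp: float
) -> list[list[tuple[WindowResult, str, str]]]:
    """Cluster (window, trait, population) triples by the strict midpoint rule."""
    by_chrom: dict[str, list] = {}
    for item in windows:
        by_chrom.setdefault(item[0].chrom, []).append(item)
    clusters = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda it: (it[0].midpoint, it[1], it[2]))
        current = [items[0]]
        for it in items[1:]:
            if it[0].midpoint - current[-1][0].midpoint < max_gap_bp:
                current.append(it)
            else:
                clusters.append(current)
                current = [it]
        clusters.append(current)
    return clusters


def overlap_windows(
    selected_by_trait: dict[str, list[WindowResult]],
    max_midpoint_gap_bp: float = DEFAULT_GAP_BP,
    population: str = "pop",
) -> list[QtlRegion]:
    """Merge selected windows across traits of one population into regions.

    Windows on the same chromosome whose midpoints are strictly less
    than ``max_midpoint_gap_bp`` apart join the same region (single
    linkage, so chains merge transitively).  The region spans the
    minimum start to the maximum end of its member windows.
    """
    items = [
        (w, trait, population)
        for trait, ws in selected_by_trait.items()
        for w in ws
    ]
    if not items:
        return []
    regions = []
    for cluster in _single_linkage_clusters(items, max_midpoint_gap_bp):
        ws = [c[0] for c in cluster]
        traits = sorted({c[1] for c in cluster})
        pct = {}
        for w, trait, _ in cluster:
            pct[trait] = max(pct.get(trait, 0.0), w.pct_variance)
        regions.append(
            QtlRegion(
                chrom=ws[0].chrom,
                start=min(w.start_pos for w in ws),
                end=max(w.end_pos for w in ws),
                members=ws,
                traits=traits,
                populations=[population],
                pct_by_trait=pct,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def top_windows_with_flanks(
    results: list[WindowResult],
    k: int = 3,
    flank_bp: int = DEFAULT_FLANK_BP,
    population: str = "pop",
) -> list[QtlRegion]:
    """The k highest-variance windows with flanks either side of the midpoint.

    Ties at rank k break deterministically by (chromosome, start
    position).  Fewer than k windows returns them all.  Regions are
    clipped at position 1 (1-based inclusive output).
    """
    if len(results) < k:
        import warnings

        warnings.warn(
            f"only {len(results)} windows available for top-{k} selection",
            RuntimeWarning,
            stacklevel=2,
        )
    ranked = sorted(
        results, key=lambda w: (-w.pct_variance, w.chrom, w.start_pos)
    )[:k]
    regions = []
    for w in ranked:
        mid = w.midpoint
        regions.append(
            QtlRegion(
                chrom=w.chrom,
                start=int(max(mid - flank_bp, 1)),
                end=int(mid + flank_bp),
                members=[w],
                traits=[w.trait],
                populations=[population],
                pct_by_trait={w.trait: w.pct_variance},
                flanked=True,
            )
        )
    return regions


def cross_population_overlap(
    selected_pop1: list[WindowResult],
    selected_pop2: list[WindowResult],
    max_midpoint_gap_bp: float = DEFAULT_GAP_BP,
) -> list[tuple[WindowResult, WindowResult]]:
    """All cross-population window pairs for one trait meeting the midpoint
    rule; an empty list is a valid, reportable outcome."""
    pairs = []
    for w1 in selected_pop1:
        for w2 in selected_pop2:
            if w1.chrom == w2.chrom and abs(w1.midpoint - w2.midpoint) < max_midpoint_gap_bp:
                pairs.append((w1, w2))
    return pairs


# ---------------------------------------------------------------------------
# gene annotation

def read_bed(path) -> pd.DataFrame:
    """BED 3+ columns -> (chrom, start, end, gene_id, name); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["gene_id"] = df[3] if 3 in df.columns else [
        f"feature{i + 1}" for i in range(len(df))
    ]
    df["name"] = df["gene_id"]
    return df[["chrom", "start", "end", "gene_id", "name"]]


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """GFF3 genes -> the same schema as ``read_bed`` (converted to 0-based
    half-open)."""
    import pyranges

    gr = pyranges.read_gff3(str(path)).df
    if "Feature" in gr.columns and feature is not None:
        gr = gr[gr["Feature"] == feature]
    out = pd.DataFrame(
        {
            "chrom": gr["Chromosome"].astype(str),
            "start": gr["Start"].astype(int),
            "end": gr["End"].astype(int),
        }
    )
    for col in ("ID", "gene_id", "Name"):
        if col in gr.columns:
            out["gene_id"] = gr[col].astype(str).to_numpy()
            break
    else:
        out["gene_id"] = [f"gene{i + 1}" for i in range(len(out))]
    out["name"] = gr["Name"].astype(str).to_numpy() if "Name" in gr.columns else out["gene_id"]
    return out.reset_index(drop=True)


class GeneAnnotation:
    """Interval-tree index over gene intervals for fast region lookup."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.table.groupby("chrom", sort=False):
            tree = IntervalTree()
            for _, row in grp.iterrows():
                if row["end"] > row["start"]:
                    tree[int(row["start"]) : int(row["end"])] = (
                        str(row["gene_id"]),
                        str(row["name"]),
                    )
            self._trees[str(chrom)] = tree

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def query(self, chrom: str, start_1based: int, end_1based: int) -> list[GeneHit]:
        tree = self._trees.get(str(chrom))
        if tree is None:
            return []
        lo = start_1based - 1  # to 0-based half-open
        hi = end_1based
        hits = [
            GeneHit(iv.data[0], iv.data[1], str(chrom), iv.begin, iv.end)
            for iv in tree.overlap(lo, hi)
        ]
        hits.sort(key=lambda h: (h.start, h.gene_id))
        return hits


def genes_in_region(
    region: QtlRegion, annotation: GeneAnnotation, panel_chroms: set[str] | None = None
) -> list[GeneHit]:
    """Genes whose interval intersects the region (inclusive bp in reports)."""
    if panel_chroms is not None:
        mismatched = annotation.chromosomes - set(map(str, panel_chroms))
        if mismatched and str(region.chrom) not in annotation.chromosomes:
            raise ValueError(
                "annotation chromosome names do not match the panel: "
                f"{sorted(mismatched)}"
            )
    return annotation.query(region.chrom, region.start, region.end)


def region_report(regions: list[QtlRegion], traits: list[str]) -> pd.DataFrame:
    """Tabular report: chromosome, region (1-based inclusive bp and Mb),
    SNP count, per-trait variance %, candidate genes."""
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom,
            "start_bp": r.start,
            "end_bp": r.end,
            "region_mb": f"{r.start / 1e6:.2f}-{r.end / 1e6:.2f}",
            "n_snps": r.n_snps,
            "flanked": r.flanked,
            "populations": ";".join(r.populations),
        }
        for t in traits:
            row[f"pct_{t}"] = r.pct_by_trait.get(t, np.nan)
        row["genes"] = ";".join(h.gene_id for h in r.gene_hits)
        rows.append(row)
    return pd.DataFrame(rows)
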