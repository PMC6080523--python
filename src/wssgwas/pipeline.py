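"""End-to-end orchestration: simulate/load -> QC -> REML -> WssGWAS -> regions.

Every run writes its resolved configuration (with a content hash) next
to its outputs; all output files carry the hash in a header comment, and
nothing time-dependent is written, so a re-run with the same
configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gwas import WssGwasResult, run_wssgwas
from .model import VarianceComponents, build_model, estimate_reml
from .pedigree import Pedigree, build_A_inverse, prune_pedigree
from .qc import (
    GenotypePanel,
    QcThresholds,
    apply_qc,
    read_plink_text,
)
from .regions import (
    GeneAnnotation,
    genes_in_region,
    overlap_windows,
    read_bed,
    read_gff3,
    region_report,
    select_windows,
    top_windows_with_flanks,
)
from .simulate import SimulationConfig, simulate_dataset, write_inputs


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class PipelineConfig:
    """Defaults mirror the analysis conventions this package implements:
    0.4 Mb windows, a 1% selection threshold, three weighting iterations,
    and standard chip QC thresholds."""

    pedigree_path: str | None = None
    genotype_prefix: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    traits: tuple[str, ...] = ("trait",)
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_iterations: int = 3
    window_bp: int = 400_000
    selection_threshold_pct: float = 1.0
    top_k: int = 3
    flank_bp: int = 400_000
    blend_alpha: float = 0.05
    freq_source: str = "observed"
    seed: int = 0
    outdir: str = "wssgwas_out"
    simulate: bool = False
    simulation: SimulationConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # where results land is not what they are
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config_hash": self.config_hash(), **self.to_dict()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("config_hash", None)
        if raw.get("qc"):
            raw["qc"] = QcThresholds(**raw["qc"])
        if raw.get("simulation"):
            sim = raw["simulation"]
            for key in ("qtl_variance_fractions", "records_per_animal",
                        "covariate_effects"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if isinstance(raw.get("traits"), list):
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wssgwas {__version__} config_hash={config_hash}\n")
        fh.write("# positions are 1-based inclusive bp\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    pedigree: Pedigree
    panel: GenotypePanel
    variance_components: dict[str, VarianceComponents]
    gwas: dict[str, WssGwasResult]
    regions: list
    top_regions: dict[str, list]
    outputs: dict[str, str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle.

    Stage failures abort with the stage name and a machine-readable
    error record (``PipelineError.record``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.resolved.yaml")
    log_lines = [f"wssgwas {__version__}", f"config_hash={chash}",
                 f"seed={config.seed}"]
    outputs: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
        data = simulate_dataset(sim_cfg)
        write_inputs(data, outdir / "inputs")
        ped, panel_raw, records = data.pedigree, data.panel, data.phenotypes
        truth = data.truth
        log_lines.append(f"simulated: {len(ped)} animals, {panel_raw.n_snps} SNPs")
    else:
        for name, path in (("pedigree", config.pedigree_path),
                           ("phenotypes", config.phenotype_path)):
            if path is None or not Path(path).exists():
                raise PipelineError("input", f"missing {name} file: {path}")
        if config.genotype_prefix is None or not Path(
            str(config.genotype_prefix) + ".ped"
        ).exists():
            raise PipelineError(
                "input", f"missing genotype files: {config.genotype_prefix}.ped/.map"
            )
        ped = Pedigree.from_csv(config.pedigree_path, reorder=True)
        panel_raw = read_plink_text(config.genotype_prefix)
        records = pd.read_csv(config.phenotype_path)

    # ---- QC ---------------------------------------------------------------
    try:
        panel, qc_report = apply_qc(panel_raw, config.qc)
    except ValueError as exc:
        raise PipelineError("qc", str(exc)) from exc
    _write_tsv(qc_report.to_frame(), outdir / "qc_report.tsv", chash)
    outputs["qc_report"] = str(outdir / "qc_report.tsv")

    # ---- pedigree pruning -------------------------------------------------
    keep = set(panel.ids) | set(records["animal"].astype(str))
    ped_pruned = prune_pedigree(ped, keep)
    log_lines.append(
        f"pedigree pruned: {len(ped)} -> {len(ped_pruned)} animals"
    )

    # ---- per-trait REML at D = I, then the weighting loop -----------------
    A_inv = build_A_inverse(ped_pruned)
    vcs: dict[str, VarianceComponents] = {}
    gwas: dict[str, WssGwasResult] = {}
    vc_rows = []
    manhattan_frames = []
    for trait in config.traits:
        try:
            model = build_model(records, A_inv, trait=trait)
            vc = estimate_reml(model)
        except Exception as exc:
            raise PipelineError("reml", f"trait {trait!r}: {exc}") from exc
        vcs[trait] = vc
        frame = vc.to_frame()
        frame.insert(0, "trait", trait)
        vc_rows.append(frame)
        try:
            res = run_wssgwas(
                records,
                ped_pruned,
                panel,
                vc,
                trait=trait,
                n_iterations=config.n_iterations,
                blend_alpha=config.blend_alpha,
                freq_source=config.freq_source,
                window_bp=config.window_bp,
            )
        except Exception as exc:
            raise PipelineError("gwas", f"trait {trait!r}: {exc}") from exc
        gwas[trait] = res
        manhattan_frames.append(res.manhattan_frame())
    _write_tsv(pd.concat(vc_rows), outdir / "variance_components.tsv", chash)
    outputs["variance_components"] = str(outdir / "variance_components.tsv")
    _write_tsv(pd.concat(manhattan_frames), outdir / "manhattan.tsv", chash)
    outputs["manhattan"] = str(outdir / "manhattan.tsv")

    # ---- selection and regions -------------------------------------------
    selected = {
        t: select_windows(gwas[t].final_windows, config.selection_threshold_pct)
        for t in config.traits
    }
    regions = overlap_windows(selected, population="pop")
    top = {
        t: top_windows_with_flanks(
            gwas[t].final_windows, k=config.top_k, flank_bp=config.flank_bp
        )
        for t in config.traits
    }

    annotation = None
    if config.annotation_path:
        path = Path(config.annotation_path)
        if not path.exists():
            raise PipelineError("select", f"missing annotation file: {path}")
        table = read_gff3(path) if path.suffix.lower() in {".gff", ".gff3"} else read_bed(path)
        annotation = GeneAnnotation(table)
        chroms = set(panel.snp_map["chrom"].astype(str))
        for region in regions + [r for rs in top.values() for r in rs]:
            region.gene_hits = genes_in_region(region, annotation, chroms)

    _write_tsv(
        region_report(regions, list(config.traits)),
        outdir / "qtl_regions.tsv",
        chash,
    )
    outputs["qtl_regions"] = str(outdir / "qtl_regions.tsv")
    top_all = [r for rs in top.values() for r in rs]
    _write_tsv(
        region_report(top_all, list(config.traits)),
        outdir / "top_windows.tsv",
        chash,
    )
    outputs["top_windows"] = str(outdir / "top_windows.tsv")

    log_lines.append(f"windows per trait: {len(next(iter(gwas.values())).windows)}")
    log_lines.append(f"regions selected: {len(regions)}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    outputs["log"] = str(outdir / "run.log")

    result = PipelineResult(
        config=config,
        pedigree=ped_pruned,
        panel=panel,
        variance_components=vcs,
        gwas=gwas,
        regions=regions,
        top_regions=top,
        outputs=outputs,
    )
    result.truth = truth
    return result
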