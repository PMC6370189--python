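"""End-to-end orchestration: simulate/load -> preprocess -> DE -> overlap -> GSEA.

A single :class:`RunConfig` drives the whole analysis.  All randomness fans
out from one root seed (separate deterministic streams per stage), so one
integer reproduces a complete run.  The run report is a pydantic model
serialised to JSON; its schema is published in ``schemas/run_report.schema.json``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel

from . import diffexpr, expression, gsea, io, overlap, simulate
from .errors import ConfigurationError

log = logging.getLogger("trmsig")

# per-stage rng stream tags hung off the root seed
_SEED_BOOTSTRAP = 10  # + comparison index
_SEED_GSEA = 20


@dataclass
class RunConfig:
    """Paths, thresholds and resampling settings for a full run."""

    out_dir: Path
    matrix_path: Path | None = None
    design_path: Path | None = None
    signature_path: Path | None = None
    gmt_path: Path | None = None
    simulation: simulate.SimulationConfig | None = None
    fpkm_cutoff: float = 0.3
    alpha: float = 0.05
    log2fc_tiers: tuple[float, ...] = (0.0, 1.0, 2.0)
    min_set_size: int = 15
    q_cutoff: float = gsea.FDR_Q_CUTOFF
    bootstraps: int = 10_000
    n_perm: int = 1000
    perm_mode: str = "gene_set"
    universe: str = "expressed"  # or "annotated" (pre-filter gene list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.fpkm_cutoff < 0 or self.alpha <= 0 or self.min_set_size <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.universe not in ("expressed", "annotated"):
            raise ConfigurationError("universe must be 'expressed' or 'annotated'")
        if self.simulation is None and (self.matrix_path is None or self.design_path is None):
            raise ConfigurationError(
                "either a simulation config or matrix and design paths are required"
            )


class TierRow(BaseModel):
    comparison: str
    min_abs_log2fc: float
    total: int
    up: int
    down: int


class OverlapRecord(BaseModel):
    comparison: str
    o_obs: int
    k: int
    m: int
    universe_size: int
    percentage: float
    bootstraps: int
    pvalue: float
    concordant_pct: float
    discordant_pct: float
    not_de_pct: float
    not_measured_pct: float


class GseaRow(BaseModel):
    gene_set: str
    size: int
    es: float
    nes: float | None
    pvalue: float | None
    fdr_q: float | None
    significant: bool


class PcaRecord(BaseModel):
    variance_fraction: list[float]
    top3_variance_pct: float


class ClusterRecord(BaseModel):
    linkage: str
    distance: str
    leaf_order: list[str]
    two_cut: dict[str, int]
    tgfb_purity: float


class RunReport(BaseModel):
    """Machine-readable record of one complete pipeline run."""

    seed: int
    fpkm_cutoff: float
    alpha: float
    bootstraps: int
    n_perm: int
    perm_mode: str
    universe: str
    n_genes_input: int
    n_genes_expressed: int
    common_de_up: list[str]
    common_de_down: list[str]
    pca: PcaRecord
    clustering: ClusterRecord
    tier_table: list[TierRow]
    overlaps: list[OverlapRecord]
    gsea_table: list[GseaRow]
    gsea_excluded: dict[str, str]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        log.info("simulating study data (seed %d)", config.simulation.seed)
        matrix, design, signature, sets, truth = simulate.simulate_study(config.simulation)
        out = config.out_dir
        out.mkdir(parents=True, exist_ok=True)
        expression.write_expression_tsv(matrix, out / "expression_fpkm.tsv")
        expression.write_design_tsv(design, out / "design.tsv")
        io.write_signature_tsv(signature, out / "signature.tsv")
        io.write_gmt(sets, out / "gene_sets.gmt")
        labels = [
            "TGFb_treated" if design.tgfb_treated(s) else "TGFb_untreated"
            for s in matrix.samples
        ]
        io.write_cls(labels, out / "phenotype.cls")
        truth.to_json(out / "truth.json")
        return matrix, design, signature, sets
    for path, kind in ((config.matrix_path, "matrix"), (config.design_path, "design")):
        if not Path(path).exists():
            raise ConfigurationError(f"{kind} file not found: {path}")
    matrix = expression.read_expression_tsv(config.matrix_path)
    design = expression.read_design_tsv(config.design_path)
    signature = (
        io.read_signature_tsv(config.signature_path) if config.signature_path else None
    )
    sets = io.read_gmt(config.gmt_path) if config.gmt_path else None
    return matrix, design, signature, sets


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in order and write the run report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    matrix, design, signature, sets = _load_inputs(config)
    design.validate_against(matrix)
    n_input = matrix.shape[0]

    # preprocess: filter -> log2 -> standardise, exactly in that order
    expressed = expression.filter_low_expression(matrix, cutoff=config.fpkm_cutoff)
    logged = expression.log2_transform(expressed)
    standardised = expression.standardise(logged)
    log.info("%d of %d genes pass FPKM > %g", expressed.shape[0], n_input, config.fpkm_cutoff)

    # exploratory stage; clustering runs on log2 values because the
    # "maximum" (Chebyshev) metric degenerates on z-scored genes, where
    # every per-gene range is capped and noise extremes dominate
    pca_summary = expression.pca(standardised, design)
    pca_summary.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    tree = expression.hierarchical_clustering(logged)
    np.savetxt(out / "cluster_merges.tsv", tree.merges, delimiter="\t")
    treatment = {
        s: ("TGFb_treated" if design.tgfb_treated(s) else "TGFb_untreated")
        for s in matrix.samples
    }
    purity = expression.cluster_purity(tree, treatment, n_clusters=2)

    # differential expression over the four pairwise comparisons
    tier_rows: list[TierRow] = []
    de_results: dict[str, diffexpr.DEResult] = {}
    for spec in diffexpr.study_comparisons():
        de = diffexpr.differential_expression(logged, design, spec, alpha=config.alpha)
        de_results[spec.name] = de
        de.table.to_csv(out / f"de_{spec.name}.tsv", sep="\t")
        tiers = diffexpr.tier_counts(de, tiers=config.log2fc_tiers)
        tier_rows.extend(TierRow(**row) for row in tiers.to_dict("records"))
    common = diffexpr.intersect_comparisons(
        [de_results[n] for n in diffexpr.SIGNATURE_COMPARISONS]
    )

    # signature overlap with bootstrap null, three signature comparisons
    overlap_records: list[OverlapRecord] = []
    if signature is not None:
        universe_size = (
            expressed.shape[0] if config.universe == "expressed" else n_input
        )
        for i, name in enumerate(diffexpr.SIGNATURE_COMPARISONS):
            obs = overlap.directional_overlap(signature, de_results[name])
            boot = overlap.bootstrap_enrichment(
                obs,
                universe_size=universe_size,
                bootstraps=config.bootstraps,
                seed=int(np.random.SeedSequence((config.seed, _SEED_BOOTSTRAP + i)).generate_state(1)[0] % (2**31)),
            )
            boot.table.to_csv(out / f"overlap_{name}.tsv", sep="\t")
            overlap_records.append(
                OverlapRecord(
                    comparison=name,
                    o_obs=boot.o_obs,
                    k=boot.k,
                    m=boot.m,
                    universe_size=boot.universe_size,
                    percentage=boot.percentage,
                    bootstraps=boot.bootstraps,
                    pvalue=boot.pvalue,
                    **boot.summary(),
                )
            )

    # GSEA of the gene-set collection, TGF-beta-treated vs -untreated
    gsea_rows: list[GseaRow] = []
    excluded: dict[str, str] = {}
    if sets is not None:
        result = gsea.run_gsea(
            logged,
            design,
            sets,
            expression.TGFB_CONDITIONS,
            ("Untreated", "IL2"),
            min_size=config.min_set_size,
            mode=config.perm_mode,
            n_perm=config.n_perm,
            seed=int(np.random.SeedSequence((config.seed, _SEED_GSEA)).generate_state(1)[0] % (2**31)),
        )
        result.table.to_csv(out / "gsea_results.tsv", sep="\t")
        excluded = result.excluded
        for name, row in result.table.iterrows():
            gsea_rows.append(
                GseaRow(
                    gene_set=name,
                    size=int(row["size"]),
                    es=float(row["es"]),
                    nes=None if np.isnan(row["nes"]) else float(row["nes"]),
                    pvalue=None if np.isnan(row["pvalue"]) else float(row["pvalue"]),
                    fdr_q=None if np.isnan(row["fdr_q"]) else float(row["fdr_q"]),
                    significant=bool(row["significant"]),
                )
            )

    report = RunReport(
        seed=config.seed,
        fpkm_cutoff=config.fpkm_cutoff,
        alpha=config.alpha,
        bootstraps=config.bootstraps,
        n_perm=config.n_perm,
        perm_mode=config.perm_mode,
        universe=config.universe,
        n_genes_input=n_input,
        n_genes_expressed=expressed.shape[0],
        common_de_up=common["up"],
        common_de_down=common["down"],
        pca=PcaRecord(
            variance_fraction=[float(v) for v in pca_summary.variance_fraction],
            top3_variance_pct=float(100 * pca_summary.variance_fraction[:3].sum()),
        ),
        clustering=ClusterRecord(
            linkage=tree.linkage_name,
            distance=tree.distance_name,
            leaf_order=list(tree.leaf_order),
            two_cut=tree.cut(2),
            tgfb_purity=purity,
        ),
        tier_table=tier_rows,
        overlaps=overlap_records,
        gsea_table=gsea_rows,
        gsea_excluded=excluded,
    )
    (out / "report.json").write_text(report.model_dump_json(indent=2))
    return report


def report_schema() -> dict:
    """JSON schema of the run report (shipped at schemas/run_report.schema.json)."""
    return RunReport.model_json_schema()
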