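"""End-to-end orchestration: ingest → cluster → partition → trees →
screen → primers → in-silico validation → qPCR analysis.

Every stage writes its artifact as TSV/Newick/FASTA under the run's output
directory, the configuration is echoed verbatim as YAML, and a run summary
collects the headline numbers.  Stage artifacts are individually
re-loadable (see :func:`load_clustering`), so stages can be re-run from a
previous run's directory.  All randomness is seeded through the config.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import clustering as cl
from . import pangenome as pg
from . import phylogeny as ph
from . import primers as pr
from . import qpcr as qp
from . import screen as sc
from . import simulate as sim
from .genome_io import GenomeSet, load_genome_set_dir, write_genome_set


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    target_species: str = "species_01"
    input_dir: Optional[str] = None        # genome FASTAs + species.tsv
    simulate: bool = True                  # generate a synthetic community
    community: dict = field(default_factory=dict)  # CommunitySpec overrides
    seed: int = 0
    cutoff: float = 0.50
    space: str = "protein"
    within_identity_min: float = 0.94
    cross_identity_max: float = 0.50
    homology_report_floor: float = 0.30
    pcr_tolerance: int = 2
    build_trees: bool = True
    tree_metric: str = "jaccard"
    tree_n_core_clusters: int = 20
    qpcr_true_slope: float = -3.530
    qpcr_true_intercept: float = 36.906
    qpcr_noise_sd: float = 0.1
    qpcr_log10_concs: tuple = (3, 4, 5, 6, 7, 8, 9)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    summary: dict
    artifacts: dict[str, str]
    genome_set: GenomeSet
    clustering: cl.ClusteringResult
    pan: pg.PanMatrix
    partition: pg.PanPartition
    screen_report: sc.ScreenReport
    primer_pair: pr.PrimerPair
    specificity: pr.SpecificityReport
    curve_fit: qp.StandardCurveFit
    truth: Optional[sim.GroundTruth] = None


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> str:
    df.to_csv(path, sep="\t", index=index)
    return str(path)


def load_clustering(table: pd.DataFrame, cutoff: float,
                    space: str) -> cl.ClusteringResult:
    """Rebuild a ClusteringResult from the cluster-table artifact."""
    clusters = []
    assignment: dict[cl.GeneKey, str] = {}
    for cid, grp in table.groupby("cluster_id", sort=True):
        rep_genome, rep_gene = grp.iloc[0]["representative"].split(":", 1)
        members, idents = [], {}
        for _, row in grp.iterrows():
            key = cl.GeneKey(row["genome_id"], row["gene_id"])
            members.append(key)
            idents[key] = float(row["identity_to_rep"])
            assignment[key] = cid
        clusters.append(cl.GeneCluster(
            cluster_id=cid, representative=cl.GeneKey(rep_genome, rep_gene),
            members=members, identity_to_rep=idents))
    return cl.ClusteringResult(clusters=clusters, cutoff=cutoff,
                               space=space, assignment=assignment)


@dataclass
class AssayResult:
    """In-memory result of the discovery stages (cluster → validate)."""

    clustering: cl.ClusteringResult
    pan: pg.PanMatrix
    partition: pg.PanPartition
    screen_report: sc.ScreenReport
    marker_seq: str
    primer_pair: pr.PrimerPair
    specificity: pr.SpecificityReport


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
            raise PipelineError(name, exc) from exc
    return wrap


def discover_assay(genome_set: GenomeSet, *, cutoff: float = 0.50,
                   space: str = "protein",
                   screen_config: Optional[sc.ScreenConfig] = None,
                   constraints: Optional[pr.PrimerConstraints] = None,
                   pcr_tolerance: int = 2) -> AssayResult:
    """Run the discovery stages on an in-memory genome set:
    cluster → pan matrix/partition → clade screen → primer design on
    clade-conserved windows → in-silico PCR validation."""
    screen_config = screen_config or sc.ScreenConfig(
        target_species=genome_set.target_species)
    clustering = _stage("cluster")(cl.greedy_cluster, genome_set,
                                   cutoff=cutoff, space=space)
    pan = _stage("partition")(pg.build_pan_matrix, clustering, genome_set)
    part = _stage("partition")(pg.partition, pan)
    report = _stage("screen")(sc.run_screen, genome_set, clustering, pan,
                              screen_config)
    if not report.ranked:
        raise PipelineError("screen", ValueError(
            "no clade-specific marker found"))
    selected = report.selected
    marker_seq = cl.representative_seq(clustering, genome_set,
                                       selected.cluster_id)
    member_seqs = [
        genome_set.genome(m.genome_id).gene(m.gene_id).seq
        for m in clustering.cluster(selected.cluster_id).members
    ]
    mask = pr.conservation_mask(marker_seq, member_seqs)
    pairs = _stage("primers")(pr.design_primers, marker_seq,
                              constraints=constraints, conserved_mask=mask)
    pair = pairs[0]
    spec_report = _stage("validate")(pr.insilico_pcr, pair, genome_set,
                                     pcr_tolerance)
    return AssayResult(clustering=clustering, pan=pan, partition=part,
                       screen_report=report, marker_seq=marker_seq,
                       primer_pair=pair, specificity=spec_report)


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    artifacts["config"] = str(outdir / "config.yaml")

    stage = _stage

    # -- ingest -----------------------------------------------------------
    truth = None
    if config.simulate:
        spec = sim.CommunitySpec(seed=config.seed,
                                 target_species=config.target_species,
                                 **config.community)
        genome_set, truth = stage("simulate")(sim.generate_community, spec)
        write_genome_set(genome_set, outdir / "community")
        assign, classes = sim.truth_tables(truth)
        artifacts["truth_assignment"] = _tsv(assign, outdir / "truth_assignment.tsv")
        artifacts["truth_classes"] = _tsv(classes, outdir / "truth_classes.tsv")
        (outdir / "species_tree.nwk").write_text(truth.species_tree_newick + "\n")
        artifacts["species_tree"] = str(outdir / "species_tree.nwk")
    else:
        if not config.input_dir:
            raise PipelineError("ingest", ValueError(
                "simulate=false requires input_dir"))
        genome_set = stage("ingest")(load_genome_set_dir, config.input_dir,
                                     config.target_species)

    # -- discovery stages (cluster → screen → primers → validation) ------
    screen_cfg = sc.ScreenConfig(
        target_species=config.target_species,
        within_identity_min=config.within_identity_min,
        cross_identity_max=config.cross_identity_max,
        homology_report_floor=config.homology_report_floor)
    assay = discover_assay(genome_set, cutoff=config.cutoff,
                           space=config.space, screen_config=screen_cfg,
                           pcr_tolerance=config.pcr_tolerance)
    clustering, pan, part = assay.clustering, assay.pan, assay.partition
    report, pair = assay.screen_report, assay.primer_pair
    spec_report, marker_seq = assay.specificity, assay.marker_seq
    selected = report.selected

    artifacts["clusters"] = _tsv(cl.clustering_table(clustering, genome_set),
                                 outdir / "clusters.tsv")
    artifacts["pan_matrix"] = _tsv(pan.to_frame(), outdir / "pan_matrix.tsv",
                                   index=True)
    artifacts["partition"] = _tsv(part.to_frame(), outdir / "partition.tsv")

    # -- trees ------------------------------------------------------------
    trees = {}
    if config.build_trees:
        dm = stage("tree")(ph.pan_matrix_distance, pan, config.tree_metric)
        artifacts["pan_distance"] = _tsv(dm.to_frame(),
                                         outdir / "pan_distance.tsv",
                                         index=True)
        pan_tree = stage("tree")(ph.neighbor_joining, dm)
        (outdir / "pan_tree.nwk").write_text(pan_tree.to_newick() + "\n")
        artifacts["pan_tree"] = str(outdir / "pan_tree.nwk")
        trees["pan"] = pan_tree
        try:
            cdm = ph.core_concat_distance(genome_set, clustering,
                                          n_clusters=config.tree_n_core_clusters,
                                          seed=config.seed)
            artifacts["core_distance"] = _tsv(cdm.to_frame(),
                                              outdir / "core_distance.tsv",
                                              index=True)
            core_tree = ph.neighbor_joining(cdm)
            (outdir / "core_tree.nwk").write_text(core_tree.to_newick() + "\n")
            artifacts["core_tree"] = str(outdir / "core_tree.nwk")
            trees["core"] = core_tree
        except ValueError:
            trees["core"] = None  # too few single-copy core clusters

    # -- screen / primer / validation artifacts --------------------------
    artifacts["screen"] = _tsv(report.to_frame(), outdir / "screen_report.tsv")
    with open(outdir / "marker.fasta", "w") as fh:
        fh.write(f">{selected.cluster_id}\n{marker_seq}\n")
    artifacts["marker"] = str(outdir / "marker.fasta")
    artifacts["primers"] = _tsv(
        pr.primer_table([pair], species=config.target_species),
        outdir / "primers.tsv")
    artifacts["specificity"] = _tsv(spec_report.to_frame(),
                                    outdir / "specificity.tsv")

    # -- qPCR -------------------------------------------------------------
    obs = stage("qpcr")(qp.simulate_ct, config.qpcr_true_slope,
                        config.qpcr_true_intercept,
                        config.qpcr_log10_concs, config.qpcr_noise_sd,
                        config.seed)
    fit = stage("qpcr")(qp.fit_standard_curve, obs)
    artifacts["qpcr_fit"] = _tsv(qp.fit_table(fit), outdir / "qpcr_fit.tsv")

    summary = {
        "n_genomes": len(genome_set.genomes),
        "n_genes": genome_set.n_genes,
        "pan_size": part.pan_size,
        "core": len(part.core),
        "accessory": len(part.accessory),
        "unique": len(part.unique),
        "shared_target_clusters": len(report.shared_in_target),
        "passed_homology": len(report.passed_homology),
        "selected_marker": selected.cluster_id,
        "max_cross_identity": (None if selected.below_floor
                               else round(selected.max_cross_identity, 4)),
        "forward_primer": pair.forward_seq,
        "reverse_primer": pair.reverse_seq,
        "product_size_bp": pair.product_size,
        "target_amplified": spec_report.n_target_amplified,
        "nontarget_amplified": spec_report.n_nontarget_amplified,
        "specific": spec_report.specific,
        "curve_slope": round(fit.slope, 4),
        "curve_intercept": round(fit.intercept, 4),
        "curve_r_squared": round(fit.r_squared, 4),
        "efficiency_pct": round(fit.efficiency_pct, 1),
        "high_efficiency": fit.high_efficiency,
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    artifacts["summary"] = str(outdir / "summary.yaml")

    return RunReport(summary=summary, artifacts=artifacts,
                     genome_set=genome_set, clustering=clustering, pan=pan,
                     partition=part, screen_report=report, primer_pair=pair,
                     specificity=spec_report, curve_fit=fit, truth=truth)
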