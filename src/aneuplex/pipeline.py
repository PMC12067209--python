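"""Simulate -> analyze -> size pipeline with file outputs and provenance.

Every run is driven by a :class:`RunConfig` that round-trips losslessly
through YAML, and all randomness flows from its single seed via spawned
sub-seeds, so two runs with the same config produce byte-identical output
trees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import EffectAssignment, assign_effect_classes
from .genome import ConfigurationError, DEFAULT_ARM_TABLE, GenomeModel, Genotype, build_genome
from .matrix import CountMatrix
from .ratios import (
    average_replicates,
    normalize_rpkm,
    partition_cis_trans,
    partition_distributions,
    partition_medians,
    ratio_table,
    scatter_table,
)
from .simulate import (
    DdpcrPanel,
    N_CDNA,
    N_GDNA,
    SimulationConfig,
    simulate_counts,
    simulate_ddpcr,
)
from .stats import bartlett_test, call_de, ks_two_sample, summarize_modulation
from .size import transcriptome_size

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_size", "run_report"]

log = logging.getLogger("aneuplex")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with the analysis defaults baked in.

    Thresholds carry their standard values: low-expression filter 1 (summed
    group means on the normalised scale), q-value cutoff 0.05, ratio bin
    width 0.05, outlier multiplier 2 SD.  The default genotype is the
    monosomy 3L + trisomy 4L combination; the default effect mixtures put
    most cis genes on a dosage effect with a compensated minority, and a
    mostly-unchanged trans genome with inverse modulation the most common
    response.
    """

    # simulation
    n_genes: int = 2000
    arm_table: dict = field(default_factory=lambda: dict(DEFAULT_ARM_TABLE))
    baseline_params: dict = field(default_factory=dict)
    genotype: dict = field(default_factory=lambda: {"3L": 1, "4L": 3})
    cis_mixture: dict = field(default_factory=lambda: {"dosage_effect": 0.6, "compensation": 0.4})
    trans_mixture: dict = field(
        default_factory=lambda: {"inverse": 0.3, "direct": 0.1, "no_change": 0.6}
    )
    composition_mode: str = "multiplicative"
    size_scale: float = 1.0  #: extra uniform scaling of aneuploid abundances
    library_size: float = 2e7
    n_replicates: int = 3
    dispersion: float = 0.05
    ddpcr_cv: float = 0.1
    # analysis thresholds
    filter_threshold: float = 1.0
    q_threshold: float = 0.05
    bin_width: float = 0.05
    bin_cap: float = 3.0
    outlier_multiplier: float = 2.0
    # plumbing
    seed: int = 0
    outdir: str = "aneuplex_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def genotype_obj(self) -> Genotype:
        return Genotype({a: int(d) for a, d in self.genotype.items()})

    def sub_seeds(self) -> dict[str, int]:
        """Stage seeds derived from the single run seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genome", "assignment", "counts", "ddpcr")
        return {
            name: int(c.generate_state(1, np.uint32)[0] % (2**31 - 1))
            for name, c in zip(names, children)
        }


def _pick_panel(genome: GenomeModel, genotype: Genotype) -> tuple[list[str], list[str]]:
    """Default ddPCR panel: the ten highest-expressed trans genes, and six
    unvaried arms for the gDNA amplicons (dose-neutral placement)."""
    partition = partition_cis_trans(genome, genotype)
    trans_genes = genome.genes.loc[partition == "trans"]
    if len(trans_genes) < N_CDNA:
        raise ConfigurationError("not enough trans genes for the ddPCR panel")
    panel = list(trans_genes.sort_values("baseline_mu", ascending=False).index[:N_CDNA])
    unvaried = [a for a in genome.arms if genotype.dose(a) == genotype.background_ploidy]
    if len(unvaried) < N_GDNA:
        raise ConfigurationError("fewer than six unvaried arms for gDNA amplicons")
    return panel, unvaried[:N_GDNA]


def run_simulate(config: RunConfig, outdir=None) -> dict:
    """Generate and write the full synthetic dataset with its ground truth.

    Writes gene table, arm BED, counts + sample sheet, paired ddPCR panels,
    a per-gene truth table (partition, class, expected and realised
    abundance ratios) and a manifest carrying the true size factor, stage
    seeds and a config hash.
    """
    outdir = Path(outdir if outdir is not None else config.outdir) / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.sub_seeds()
    genotype = config.genotype_obj()

    genome = build_genome(
        config.n_genes, config.arm_table, config.baseline_params, seed=seeds["genome"]
    )
    assignment = assign_effect_classes(
        genome,
        genotype,
        config.cis_mixture,
        config.trans_mixture,
        seed=seeds["assignment"],
        composition_mode=config.composition_mode,
    ).with_global_scale(config.size_scale)
    sim_cfg = SimulationConfig(
        library_size=config.library_size,
        n_replicates=config.n_replicates,
        dispersion=config.dispersion,
        composition_mode=config.composition_mode,
        seed=seeds["counts"],
    )
    sim = simulate_counts(genome, assignment, genotype, sim_cfg)
    panel_genes, gdna_arms = _pick_panel(genome, genotype)
    panel_aneu, panel_ctl = simulate_ddpcr(
        genome,
        assignment,
        genotype,
        panel_genes,
        gdna_arms,
        cv=config.ddpcr_cv,
        seed=seeds["ddpcr"],
    )

    genome.to_gene_table(outdir / "gene_table.tsv")
    genome.to_arm_bed(outdir / "arms.bed")
    sim.matrix.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    panel_aneu.to_csv(outdir / "ddpcr_aneuploid.csv")
    panel_ctl.to_csv(outdir / "ddpcr_control.csv")

    truth = assignment.table.copy()
    truth["abundance_ratio"] = assignment.abundance_ratios
    truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)

    manifest = {
        "config_hash": config.config_hash(),
        "genotype": config.genotype,
        "genotype_name": genotype.name,
        "size_factor": sim.size_factor,
        "global_scale": config.size_scale,
        "panel_genes": panel_genes,
        "gdna_arms": gdna_arms,
        "seeds": seeds,
        "n_genes": genome.n_genes,
        "samples": {g: sim.matrix.samples_in(g) for g in ("aneuploid", "control")},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("simulated %d genes, %s, T=%.4f -> %s", genome.n_genes, genotype.name,
             sim.size_factor, outdir)
    return {"outdir": outdir, "manifest": manifest, "genome": genome,
            "assignment": assignment, "sim": sim,
            "panels": (panel_aneu, panel_ctl)}


def _load_sim(sim_dir: Path) -> tuple[GenomeModel, CountMatrix, dict]:
    genome = GenomeModel.from_gene_table(sim_dir / "gene_table.tsv")
    matrix = CountMatrix.from_tsv(sim_dir / "counts.tsv", sim_dir / "samples.tsv")
    manifest = json.loads((sim_dir / "manifest.json").read_text())
    return genome, matrix, manifest


def run_analyze(config: RunConfig, sim_dir=None, outdir=None) -> dict:
    """Ratio distributions, medians, K-S/Bartlett tests, DE calls,
    modulation summary and scatter table, written as TSV/JSON."""
    base = Path(outdir if outdir is not None else config.outdir)
    sim_dir = Path(sim_dir) if sim_dir is not None else base / "sim"
    outdir = base / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    genome, raw, manifest = _load_sim(sim_dir)
    genotype = Genotype({a: int(d) for a, d in manifest["genotype"].items()})

    table = ratio_table(raw, genome, genotype, threshold=config.filter_threshold)
    medians = partition_medians(table)
    dists = partition_distributions(table, width=config.bin_width, cap=config.bin_cap)

    # Pairwise distribution comparisons: each cis arm against trans, and
    # cis arms against each other in combinations.
    finite = table[table["finite"]]
    groups = {p: sub["ratio"].to_numpy(float) for p, sub in finite.groupby("partition")}
    tests = {}
    labels = sorted(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            key = f"{a}|{b}"
            tests[key] = {
                "ks": ks_two_sample(groups[a], groups[b]).to_dict(),
                "bartlett": bartlett_test(groups[a], groups[b]).to_dict(),
            }

    normalized = normalize_rpkm(raw, genome.genes["length"])
    retained = normalized.subset(table.index)
    calls = call_de(retained, q_threshold=config.q_threshold)
    modulation = summarize_modulation(calls, table["partition"])
    scatter = scatter_table(average_replicates(retained), calls)

    table.to_csv(outdir / "ratio_table.tsv", sep="\t", index_label="gene_id",
                 float_format=_FLOAT_FMT)
    pd.concat([d.to_frame() for _, d in sorted(dists.items())]).to_csv(
        outdir / "ratio_distribution.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    calls.to_csv(outdir / "de_calls.tsv", sep="\t", index_label="gene_id",
                 float_format=_FLOAT_FMT)
    scatter.to_csv(outdir / "scatter_table.tsv", sep="\t", index_label="gene_id",
                   float_format=_FLOAT_FMT)
    (outdir / "medians.json").write_text(json.dumps(medians, indent=2, sort_keys=True) + "\n")
    (outdir / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True) + "\n")
    (outdir / "modulation.json").write_text(
        json.dumps(modulation.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    log.info("analyzed %d retained genes (%s) -> %s", len(table),
             manifest["genotype_name"], outdir)
    return {"outdir": outdir, "ratio_table": table, "medians": medians,
            "distributions": dists, "tests": tests, "calls": calls,
            "modulation": modulation, "scatter": scatter}


def run_size(config: RunConfig, sim_dir=None, outdir=None) -> dict:
    """Genome-normalised transcriptome-size estimate from the panel pair."""
    base = Path(outdir if outdir is not None else config.outdir)
    sim_dir = Path(sim_dir) if sim_dir is not None else base / "sim"
    outdir = base / "size"
    outdir.mkdir(parents=True, exist_ok=True)
    genome, raw, manifest = _load_sim(sim_dir)
    panel_aneu = DdpcrPanel.from_csv(sim_dir / "ddpcr_aneuploid.csv")
    panel_ctl = DdpcrPanel.from_csv(sim_dir / "ddpcr_control.csv")
    normalized = normalize_rpkm(raw, genome.genes["length"])
    estimate = transcriptome_size(
        panel_aneu, panel_ctl, normalized, sd_multiplier=config.outlier_multiplier
    )

    report = estimate.to_dict()
    report["genotype"] = manifest["genotype_name"]
    (outdir / "size_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    bar = pd.DataFrame(
        [
            {
                "combination": manifest["genotype_name"],
                "mean": estimate.mean,
                "se": estimate.se,
                "p_value": estimate.p_value,
                "n_retained": estimate.n_retained,
            }
        ]
    )
    bar.to_csv(outdir / "size_table.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    log.info("size estimate %.4f +/- %.4f (p=%.3g) -> %s", estimate.mean, estimate.se,
             estimate.p_value, outdir)
    return {"outdir": outdir, "estimate": estimate, "report": report}


def run_report(config: RunConfig, outdir=None, plots: bool = False) -> dict:
    """Collect analysis and size outputs into one report (optionally with
    figures)."""
    base = Path(outdir if outdir is not None else config.outdir)
    report_dir = base / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((base / "sim" / "manifest.json").read_text())
    medians = json.loads((base / "analysis" / "medians.json").read_text())
    tests = json.loads((base / "analysis" / "tests.json").read_text())
    modulation = json.loads((base / "analysis" / "modulation.json").read_text())
    size = json.loads((base / "size" / "size_report.json").read_text())
    report = {
        "config_hash": config.config_hash(),
        "genotype": manifest["genotype_name"],
        "true_size_factor": manifest["size_factor"],
        "medians": medians,
        "size": {k: size[k] for k in ("mean", "se", "p_value", "n_retained")},
        "modulation": modulation,
        "tests": tests,
    }
    (report_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    if plots:
        from . import plotting

        dist = pd.read_csv(base / "analysis" / "ratio_distribution.tsv", sep="\t")
        plotting.plot_ratio_distribution(dist, report_dir / "ratio_distribution.png")
        scatter = pd.read_csv(base / "analysis" / "scatter_table.tsv", sep="\t",
                              index_col="gene_id")
        plotting.plot_scatter(scatter, report_dir / "scatter.png")
    return {"outdir": report_dir, "report": report}
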