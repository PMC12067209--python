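"""Synthetic genome models and aneuploid genotypes.

A :class:`GenomeModel` is the gene universe of the simulation: every gene
lives on exactly one chromosome-arm segment (the unit that B-A-translocation
style aneuploidy varies), has a transcript length in bases, and a baseline
expression level ``baseline_mu`` in transcripts-per-cell equivalents for the
diploid control.  A :class:`Genotype` assigns an integer dose (1-4) to a
small number of varied arms on a background ploidy of 2, encoding monosomy,
trisomy, tetrasomy and their combinations.

The varied unit is deliberately the *arm segment*, not the whole chromosome:
genes on the other arm of the same chromosome are in trans, because an
arm translocation varies only the one arm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataQualityWarning",
    "GenomeModel",
    "Genotype",
    "DEFAULT_ARM_TABLE",
    "build_genome",
    "partition_cis_trans",
    "arms_from_bed",
]


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


class DataQualityWarning(UserWarning):
    """Emitted when an analysis step hits a suspicious data pattern."""


#: Twenty maize-style chromosome arms (10 chromosomes x short/long), each
#: holding an equal share of the gene universe.  A single arm therefore
#: carries ~5% of genes, a realistic share for one arm of a 10-chromosome
#: genome.
DEFAULT_ARM_TABLE: dict[str, float] = {
    f"{c}{a}": 0.05 for c in range(1, 11) for a in ("S", "L")
}

_ARM_RE = re.compile(r"^(\d+)([SL])$")


@dataclass(frozen=True)
class GenomeModel:
    """Gene universe with arm assignment, length and baseline expression.

    Parameters
    ----------
    genes:
        DataFrame indexed by unique ``gene_id`` with columns ``arm`` (str),
        ``length`` (bases, > 0) and ``baseline_mu`` (expected transcripts
        per cell in the control, finite and > 0).  Optional ``chrom``,
        ``start``, ``end`` columns give synthetic genomic coordinates used
        for the BED interface.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.genes
        missing = {"arm", "length", "baseline_mu"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"gene table is missing columns {sorted(missing)}")
        if df.index.has_duplicates:
            raise ConfigurationError("gene_ids must be unique")
        if df["arm"].isna().any():
            raise ConfigurationError("every gene must map to exactly one arm")
        if not (df["length"] > 0).all():
            raise ConfigurationError("gene lengths must be positive")
        mu = df["baseline_mu"].to_numpy(float)
        if not (np.isfinite(mu).all() and (mu > 0).all()):
            raise ConfigurationError("baseline_mu must be finite and positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def arms(self) -> list[str]:
        return sorted(self.genes["arm"].unique())

    @property
    def arm_of(self) -> pd.Series:
        """Series mapping gene_id -> arm label."""
        return self.genes["arm"]

    # ---- external interfaces -------------------------------------------------

    def to_gene_table(self, path) -> None:
        """Write the gene table TSV (gene_id, arm, length, baseline_mu, ...)."""
        self.genes.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def from_gene_table(cls, path) -> "GenomeModel":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df)

    def arm_intervals(self) -> pd.DataFrame:
        """BED-style (0-based, half-open) arm intervals: chrom, start, end, arm."""
        if not {"chrom", "start", "end"} <= set(self.genes.columns):
            raise ConfigurationError("genome has no coordinates; build it with build_genome")
        rows = []
        for arm, sub in self.genes.groupby("arm", sort=True):
            rows.append(
                {
                    "chrom": sub["chrom"].iloc[0],
                    "start": int(sub["start"].min()),
                    "end": int(sub["end"].max()),
                    "arm": arm,
                }
            )
        bed = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
        return bed.reset_index(drop=True)

    def to_arm_bed(self, path) -> None:
        self.arm_intervals().to_csv(path, sep="\t", header=False, index=False)


def _read_bed(path, names: tuple[str, ...]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=list(names))


def arms_from_bed(gene_positions: pd.DataFrame, arm_bed: pd.DataFrame) -> pd.Series:
    """Assign each gene to the arm interval containing its midpoint.

    ``gene_positions`` needs ``chrom``, ``start``, ``end`` columns and a
    gene_id index; ``arm_bed`` is BED-style with ``chrom``, ``start``,
    ``end``, ``arm``.  Raises if any gene falls outside every interval.
    """
    out = pd.Series(index=gene_positions.index, dtype=object)
    mid = (gene_positions["start"] + gene_positions["end"]) // 2
    for chrom, sub in gene_positions.groupby("chrom"):
        arms = arm_bed[arm_bed["chrom"] == chrom].sort_values("start")
        if arms.empty:
            raise ConfigurationError(f"no arm intervals on {chrom}")
        idx = np.searchsorted(arms["start"].to_numpy(), mid.loc[sub.index].to_numpy(), side="right") - 1
        bad = (idx < 0) | (mid.loc[sub.index].to_numpy() >= arms["end"].to_numpy()[np.clip(idx, 0, None)])
        if bad.any():
            missing = sub.index[bad][0]
            raise ConfigurationError(f"gene {missing} falls outside every arm interval")
        out.loc[sub.index] = arms["arm"].to_numpy()[idx]
    if out.isna().any():
        raise ConfigurationError("some genes received no arm assignment")
    return out


@dataclass(frozen=True)
class Genotype:
    """Per-arm integer dose on a diploid background.

    Arms absent from ``arm_doses`` carry the background ploidy (2).  Doses
    are restricted to 1-4: monosomy, disomy, trisomy, tetrasomy.
    """

    arm_doses: Mapping[str, int] = field(default_factory=dict)
    background_ploidy: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm_doses", dict(self.arm_doses))
        for arm, dose in self.arm_doses.items():
            if int(dose) != dose or not 1 <= int(dose) <= 4:
                raise ConfigurationError(f"dose for arm {arm} must be an integer in 1..4, got {dose}")
        if self.background_ploidy != 2:
            raise ConfigurationError("only diploid background (ploidy 2) is supported")

    def dose(self, arm: str) -> int:
        return int(self.arm_doses.get(arm, self.background_ploidy))

    @property
    def varied_arms(self) -> tuple[str, ...]:
        return tuple(sorted(a for a, d in self.arm_doses.items() if d != self.background_ploidy))

    @property
    def name(self) -> str:
        """Human-readable label, e.g. ``mono3L+tri4L`` or ``euploid``."""
        kinds = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}
        parts = [f"{kinds[self.dose(a)]}{a}" for a in self.varied_arms]
        return "+".join(parts) if parts else "euploid"


def build_genome(
    n_genes: int,
    arm_table: Mapping[str, float] | None = None,
    baseline_params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> GenomeModel:
    """Draw a synthetic genome: arm assignments, lengths, baseline expression.

    Genes are allocated to arms proportionally to the requested fractions
    (largest-remainder rounding).  Transcript lengths and baseline expression
    are lognormal; defaults give median length ~2 kb and a right-skewed
    expression distribution typical of bulk RNA-seq.  Deterministic for a
    fixed seed.
    """
    arm_table = dict(arm_table) if arm_table is not None else dict(DEFAULT_ARM_TABLE)
    if not arm_table:
        raise ConfigurationError("arm_table must name at least one arm")
    total = float(sum(arm_table.values()))
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"arm fractions must sum to 1, got {total}")
    if n_genes < len(arm_table):
        raise ConfigurationError(
            f"n_genes={n_genes} is smaller than the number of arms ({len(arm_table)})"
        )
    params = {
        "mu_meanlog": 3.0,
        "mu_sdlog": 1.0,
        "length_meanlog": 7.6,
        "length_sdlog": 0.6,
    }
    if baseline_params:
        unknown = set(baseline_params) - set(params)
        if unknown:
            raise ConfigurationError(f"unknown baseline parameters {sorted(unknown)}")
        params.update(baseline_params)

    # Largest-remainder allocation of genes to arms, in arm-table order.
    arms = list(arm_table)
    fracs = np.array([arm_table[a] for a in arms], float)
    counts = np.floor(fracs * n_genes).astype(int)
    remainder = n_genes - counts.sum()
    if remainder:
        order = np.argsort(-(fracs * n_genes - counts), kind="stable")
        counts[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    arm_col = np.repeat(arms, counts)
    lengths = np.maximum(
        np.round(rng.lognormal(params["length_meanlog"], params["length_sdlog"], n_genes)),
        200.0,
    )
    mu = rng.lognormal(params["mu_meanlog"], params["mu_sdlog"], n_genes)

    genes = pd.DataFrame(
        {
            "arm": arm_col,
            "length": lengths,
            "baseline_mu": mu,
        },
        index=pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id"),
    )

    # Synthetic coordinates: arms of one chromosome laid out S then L with
    # 100 bp gaps, so the BED interface can be exercised end to end.
    chrom = genes["arm"].map(_chrom_of_arm)
    genes["chrom"] = chrom
    starts = np.zeros(n_genes, dtype=int)
    ends = np.zeros(n_genes, dtype=int)
    for c in chrom.unique():
        mask = (chrom == c).to_numpy()
        sub_arms = genes.loc[mask, "arm"]
        # short arm first, then long arm, preserving gene order within arms
        order = np.argsort([0 if a.endswith("S") else 1 for a in sub_arms], kind="stable")
        pos = 0
        idx = np.where(mask)[0][order]
        for i in idx:
            starts[i] = pos
            ends[i] = pos + int(genes["length"].iloc[i])
            pos = ends[i] + 100
    genes["start"] = starts
    genes["end"] = ends
    return GenomeModel(genes)


def _chrom_of_arm(arm: str) -> str:
    m = _ARM_RE.match(arm)
    return f"chr{m.group(1)}" if m else f"chr_{arm}"


def partition_cis_trans(genome: GenomeModel, genotype: Genotype) -> pd.Series:
    """Label every gene ``cis:<arm>`` (on a varied arm) or ``trans``.

    Cis labels are kept separate per varied arm so combination aneuploidies
    can be summarised per arm; trans is the remainder of the genome with the
    cis genes of *every* varied arm excluded.  The partition is exhaustive
    and exclusive by construction.
    """
    varied = genotype.varied_arms
    if not varied:
        raise ConfigurationError("genotype names no varied arm; cis/trans partition undefined")
    unknown = set(varied) - set(genome.arms)
    if unknown:
        raise ConfigurationError(f"varied arms {sorted(unknown)} are absent from the genome")
    arm = genome.arm_of
    labels = pd.Series("trans", index=genome.gene_ids, name="partition", dtype=object)
    for a in varied:
        labels[arm == a] = f"cis:{a}"
    return labels
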