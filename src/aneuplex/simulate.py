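"""Ground-truth simulators for RNA-seq counts and paired ddPCR panels.

The count simulator encodes the central measurement fact of aneuploid
transcriptomics: sequencing reads are a *relative* measure.  True per-cell
abundances are ``A_g = baseline_mu_g * r_g`` (times any global scale), but
each sample yields ``L`` reads allocated proportionally to ``A_g / sum A``,
so a uniform rescaling of the whole transcriptome leaves the counts —
and every ratio computed from them — unchanged.  The true size factor
``T = sum A / sum baseline_mu`` is recorded alongside the counts so that
downstream estimators can be scored against it.

The ddPCR simulator produces the complementary *absolute* measurement:
cDNA amplicon concentrations proportional to per-cell transcript abundance
and gDNA amplicon concentrations proportional to genome copy number, from
a co-extracted nucleic-acid pool, so the mRNA/gDNA ratio retains the
transcriptome-size information that counts lose.  Droplet Poisson
statistics are not modelled; concentrations carry mean-one lognormal
multiplicative noise with a stated coefficient of variation, because the
downstream analysis consumes concentrations, not droplet counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import EffectAssignment
from .genome import ConfigurationError, GenomeModel, Genotype
from .matrix import CountMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedCounts",
    "DdpcrPanel",
    "simulate_counts",
    "simulate_ddpcr",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the count simulator.

    ``dispersion`` is the gamma-Poisson overdispersion phi in
    ``var = mu + phi * mu**2``; 0 makes counts equal their expectations
    exactly (bitwise-reproducible oracles).  ``library_size`` is reads per
    sample; 2e7 gene-mapped reads approximates a 50M-read-pair library
    after filtering.  ``composition_mode`` is how multi-arm trans effects
    compose (see :func:`aneuplex.effects.compose_trans_ratio`).
    """

    library_size: float = 2e7
    n_replicates: int = 3
    dispersion: float = 0.05
    composition_mode: str = "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        if self.composition_mode not in ("multiplicative", "additive", "dominant"):
            raise ConfigurationError(f"unknown composition mode {self.composition_mode!r}")


@dataclass(frozen=True)
class SimulatedCounts:
    """A simulated count matrix plus its ground truth."""

    matrix: CountMatrix
    size_factor: float  #: true T = sum(mu * r * scale) / sum(mu)
    true_abundance: pd.Series  #: per-cell A_g in the aneuploid, scale included


def _draw_counts(rng: np.random.Generator, expected: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson counts with mean ``expected`` and var mu + phi mu^2."""
    if phi == 0:
        return expected.copy()
    lam = rng.gamma(shape=1.0 / phi, scale=expected * phi)
    return rng.poisson(lam).astype(float)


def simulate_counts(
    genome: GenomeModel,
    assignment: EffectAssignment,
    genotype: Genotype,
    config: SimulationConfig,
) -> SimulatedCounts:
    """Simulate library-normalised RNA-seq counts for aneuploid and control.

    Expected count of gene g in an aneuploid sample is
    ``L * A_g / sum(A)`` with ``A_g = baseline_mu_g * r_g * scale``;
    control samples use ``r_g = 1`` (and no scale — the control defines
    the reference transcriptome).  At ``dispersion == 0`` counts equal
    these expectations exactly; otherwise they are gamma-Poisson draws.
    """
    if not assignment.gene_ids.equals(genome.gene_ids):
        raise ConfigurationError("assignment does not cover the genome's genes")
    mu = genome.genes["baseline_mu"].to_numpy(float)
    abundance = mu * assignment.abundance_ratios.to_numpy(float)
    size_factor = float(abundance.sum() / mu.sum())

    p_aneu = abundance / abundance.sum()
    p_ctl = mu / mu.sum()
    L = float(config.library_size)

    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {}
    sheet: list[tuple[str, str, int]] = []
    for rep in range(1, config.n_replicates + 1):
        name = f"aneuploid_{rep}"
        cols[name] = _draw_counts(rng, L * p_aneu, config.dispersion)
        sheet.append((name, "aneuploid", rep))
    for rep in range(1, config.n_replicates + 1):
        name = f"control_{rep}"
        cols[name] = _draw_counts(rng, L * p_ctl, config.dispersion)
        sheet.append((name, "control", rep))

    values = pd.DataFrame(cols, index=genome.gene_ids)
    groups = pd.DataFrame(
        [(g, r) for _, g, r in sheet],
        index=pd.Index([s for s, _, _ in sheet], name="sample_id"),
        columns=["group", "replicate"],
    )
    matrix = CountMatrix(values, groups)
    true_abundance = pd.Series(abundance, index=genome.gene_ids, name="abundance")
    return SimulatedCounts(matrix=matrix, size_factor=size_factor, true_abundance=true_abundance)


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------

#: Panel sizes fixed by the assay design: ten cDNA amplicons (one per
#: panel gene) normalised against six gDNA amplicons.
N_CDNA = 10
N_GDNA = 6


@dataclass(frozen=True)
class DdpcrPanel:
    """Long-format ddPCR panel: one row per (sample, amplicon).

    Columns: ``sample``, ``amplicon_id``, ``type`` (``cDNA``/``gDNA``),
    ``concentration`` (copies/uL, >= 0).  Every sample carries exactly
    ten cDNA and six gDNA amplicons.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample", "amplicon_id", "type", "concentration"}
        if set(self.data.columns) < need:
            raise ConfigurationError(f"ddPCR panel needs columns {sorted(need)}")
        if (self.data["concentration"] < 0).any():
            raise ConfigurationError("concentrations must be non-negative")
        bad_type = set(self.data["type"]) - {"cDNA", "gDNA"}
        if bad_type:
            raise ConfigurationError(f"unknown amplicon types {sorted(bad_type)}")
        counts = self.data.groupby(["sample", "type"]).size().unstack(fill_value=0)
        if not ((counts.get("cDNA", 0) == N_CDNA) & (counts.get("gDNA", 0) == N_GDNA)).all():
            raise ConfigurationError(
                f"every sample must carry exactly {N_CDNA} cDNA and {N_GDNA} gDNA amplicons"
            )

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    @property
    def cdna_amplicons(self) -> list[str]:
        return sorted(self.data.loc[self.data["type"] == "cDNA", "amplicon_id"].unique())

    @property
    def gdna_amplicons(self) -> list[str]:
        return sorted(self.data.loc[self.data["type"] == "gDNA", "amplicon_id"].unique())

    def wide(self, amp_type: str) -> pd.DataFrame:
        """amplicon x sample concentration table for one amplicon type."""
        sub = self.data[self.data["type"] == amp_type]
        return sub.pivot(index="amplicon_id", columns="sample", values="concentration")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "DdpcrPanel":
        return cls(pd.read_csv(path))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def simulate_ddpcr(
    genome: GenomeModel,
    assignment: EffectAssignment,
    genotype: Genotype,
    panel_genes: Sequence[str],
    gdna_arms: Sequence[str],
    cv: float = 0.1,
    seed: int = 0,
    n_samples: int = 1,
) -> tuple[DdpcrPanel, DdpcrPanel]:
    """Simulate a paired (aneuploid, control) ddPCR panel.

    cDNA concentration of panel gene g is proportional to its per-cell
    abundance (``mu_g * r_g * scale`` in the aneuploid, ``mu_g`` in the
    control); gDNA concentration of an amplicon on arm a is proportional
    to the arm's copy number per cell.  Per-amplicon efficiencies differ
    between amplicons but are identical in the two panels, as for a shared
    primer pair, so they cancel in aneuploid/control ratios.  gDNA
    amplicons must sit on arms unvaried in the genotype so that
    per-genome normalisation is dose-neutral.
    """
    panel_genes = list(panel_genes)
    gdna_arms = list(gdna_arms)
    if len(panel_genes) != N_CDNA:
        raise ConfigurationError(f"panel must name exactly {N_CDNA} genes, got {len(panel_genes)}")
    if len(set(panel_genes)) != N_CDNA:
        raise ConfigurationError("panel genes must be distinct")
    if len(gdna_arms) != N_GDNA or len(set(gdna_arms)) != N_GDNA:
        raise ConfigurationError(f"exactly {N_GDNA} distinct gDNA arms are required")
    missing = set(panel_genes) - set(genome.gene_ids)
    if missing:
        raise ConfigurationError(f"panel genes {sorted(missing)} are absent from the genome")
    unknown_arms = set(gdna_arms) - set(genome.arms)
    if unknown_arms:
        raise ConfigurationError(f"gDNA arms {sorted(unknown_arms)} are absent from the genome")
    varied = set(genotype.varied_arms)
    on_varied = sorted(set(gdna_arms) & varied)
    if on_varied:
        raise ConfigurationError(
            f"gDNA amplicons on varied arms {on_varied}: per-genome normalisation "
            "would no longer be dose-neutral"
        )
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")

    mu = genome.genes.loc[panel_genes, "baseline_mu"].to_numpy(float)
    if not (mu > 0).all():
        raise ConfigurationError("panel genes must be expressed (baseline_mu > 0)")
    r = assignment.abundance_ratios.loc[panel_genes].to_numpy(float)
    ploidy = genotype.background_ploidy

    rng = np.random.default_rng(seed)
    # Per-amplicon efficiencies: drawn once, shared by both panels.
    cdna_eff = rng.lognormal(0.0, 0.2, N_CDNA)
    gdna_eff = rng.lognormal(0.0, 0.2, N_GDNA)

    gdna_ids = [f"gDNA_{a}" for a in gdna_arms]
    # Unvaried arms carry the background ploidy in both genotypes.
    gdna_copies = np.full(N_GDNA, float(ploidy))

    def one_panel(cdna_base: np.ndarray, label: str) -> DdpcrPanel:
        rows = []
        for s in range(1, n_samples + 1):
            sample = f"{label}_{s}"
            cdna = cdna_base * cdna_eff * _lognormal_noise(rng, cv, N_CDNA)
            gdna = gdna_copies * gdna_eff * _lognormal_noise(rng, cv, N_GDNA)
            rows.extend(
                {"sample": sample, "amplicon_id": g, "type": "cDNA", "concentration": c}
                for g, c in zip(panel_genes, cdna)
            )
            rows.extend(
                {"sample": sample, "amplicon_id": a, "type": "gDNA", "concentration": c}
                for a, c in zip(gdna_ids, gdna)
            )
        return DdpcrPanel(pd.DataFrame(rows))

    panel_aneu = one_panel(mu * r, "aneuploid")
    panel_ctl = one_panel(mu, "control")
    return panel_aneu, panel_ctl
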