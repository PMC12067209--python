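"""Shared fixtures and scenario builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import aneuplex as ax


@pytest.fixture(scope="session")
def small_genome() -> ax.GenomeModel:
    """400 genes over the default 20 arms (20 genes per arm)."""
    return ax.build_genome(400, seed=7)


@pytest.fixture(scope="session")
def trisomy_3l() -> ax.Genotype:
    return ax.Genotype({"3L": 3})


def simulate_scenario(
    doses: dict[str, int],
    cis_mixture: dict[str, float],
    trans_mixture: dict[str, float],
    n_genes: int = 2000,
    dispersion: float = 0.0,
    n_replicates: int = 3,
    seed: int = 101,
    scale: float = 1.0,
    library_size: float = 2e7,
):
    """Build genome -> assignment -> counts for a named dosage scenario.

    Returns (genome, genotype, assignment, simulated_counts).
    """
    rng = np.random.default_rng(seed)
    s_genome, s_assign, s_counts = rng.integers(0, 2**31 - 1, 3)
    genome = ax.build_genome(n_genes, seed=int(s_genome))
    genotype = ax.Genotype(doses)
    assignment = ax.assign_effect_classes(
        genome, genotype, cis_mixture, trans_mixture, seed=int(s_assign)
    ).with_global_scale(scale)
    sim = ax.simulate_counts(
        genome,
        assignment,
        genotype,
        ax.SimulationConfig(
            dispersion=dispersion,
            n_replicates=n_replicates,
            library_size=library_size,
            seed=int(s_counts),
        ),
    )
    return genome, genotype, assignment, sim


def size_experiment(
    scale: float,
    cv: float,
    dispersion: float,
    seed: int,
    doses: dict[str, int] | None = None,
    n_genes: int = 2000,
) -> ax.SizeEstimate:
    """Full transcriptome-size measurement on one simulated dataset.

    The aneuploid transcriptome carries a uniform abundance scaling of
    ``scale`` on top of a compensated/unchanged effect assignment, so the
    true size factor T equals ``scale`` exactly.
    """
    doses = doses if doses is not None else {"3L": 3}
    rng = np.random.default_rng(seed)
    s_genome, s_assign, s_counts, s_ddpcr = rng.integers(0, 2**31 - 1, 4)
    genome = ax.build_genome(n_genes, seed=int(s_genome))
    genotype = ax.Genotype(doses)
    assignment = ax.assign_effect_classes(
        genome, genotype, {"compensation": 1.0}, {"no_change": 1.0}, seed=int(s_assign)
    ).with_global_scale(scale)
    sim = ax.simulate_counts(
        genome,
        assignment,
        genotype,
        ax.SimulationConfig(dispersion=dispersion, seed=int(s_counts)),
    )
    partition = ax.partition_cis_trans(genome, genotype)
    trans = genome.genes.loc[partition == "trans"]
    panel = list(trans.sort_values("baseline_mu", ascending=False).index[:10])
    unvaried = [a for a in genome.arms if genotype.dose(a) == genotype.background_ploidy][:6]
    panel_aneu, panel_ctl = simulate_panels(
        genome, assignment, genotype, panel, unvaried, cv, int(s_ddpcr)
    )
    normalized = ax.normalize_rpkm(sim.matrix, genome.genes["length"])
    return ax.transcriptome_size(panel_aneu, panel_ctl, normalized)


def simulate_panels(genome, assignment, genotype, panel, gdna_arms, cv, seed):
    return ax.simulate_ddpcr(
        genome, assignment, genotype, panel, gdna_arms, cv=cv, seed=seed
    )
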