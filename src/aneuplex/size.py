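"""Genome-normalised estimation of transcriptome size.

Library-normalised RNA-seq ratios are blind to a uniform rescaling of the
whole transcriptome.  The genome-normalised approach recovers that scale by
comparing, for a small panel of genes, two ratios:

* *relative expression per genome* — each panel gene's cDNA concentration
  normalised against six gDNA amplicons from a co-extracted nucleic-acid
  pool (ddPCR), aneuploid over control; and
* *relative expression per transcriptome* — the same gene's
  aneuploid/control ratio of normalised RNA-seq counts.

Their quotient ``E_g`` is, gene by gene, an independent estimate of the
transcriptome-size factor ``T`` (total mRNA per genome copy, aneuploid
relative to control): the per-genome ratio measures ``r_g * T``-per-genome
while the per-transcriptome ratio measures ``r_g / T``... more precisely,
per-genome = ``r_g`` on the per-cell scale and per-transcriptome =
``r_g / T``, so ``E_g = T`` exactly in the noiseless limit, whatever the
gene's own dosage response ``r_g``.  The ten estimates are cleaned with a
two-standard-deviation outlier rule and summarised as mean +/- SE with a
two-sided test against 1.0 (no size change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import ConfigurationError, DataQualityWarning
from .matrix import CountMatrix
from .ratios import average_replicates
from .simulate import DdpcrPanel

__all__ = [
    "SizeEstimate",
    "per_genome_expression",
    "per_transcriptome_expression",
    "size_estimates",
    "filter_outlier_estimates",
    "estimate_size",
    "transcriptome_size",
]

#: Relative spread below which a set of estimates is treated as exactly
#: equal (guards the noiseless limit against float rounding).
_DEGENERATE_REL_SD = 1e-12


def _panel_norms(panel: DdpcrPanel) -> pd.Series:
    """Per-gene cDNA signal normalised to the six gDNA amplicons.

    For each sample, ``norm_g = mean over gDNA amplicons j of
    (cDNA_g / gDNA_j)``; with several samples the per-sample norms are
    averaged.  Averaging over the six amplicons *before* any between-
    genotype division damps per-primer amplification-efficiency noise.
    """
    cdna = panel.wide("cDNA")
    gdna = panel.wide("gDNA")
    if (gdna.to_numpy() <= 0).any():
        raise ConfigurationError("zero or negative gDNA signal; cannot normalise per genome")
    inv_gdna = (1.0 / gdna).mean(axis=0)  # per-sample mean of 1/gDNA_j
    norms = cdna.mul(inv_gdna, axis=1)  # norm_g per sample
    return norms.mean(axis=1)


def per_genome_expression(panel_aneu: DdpcrPanel, panel_ctl: DdpcrPanel) -> pd.Series:
    """Relative expression per genome, aneuploid over control, per panel gene."""
    if panel_aneu.cdna_amplicons != panel_ctl.cdna_amplicons:
        raise ConfigurationError("cDNA amplicon sets differ between the two panels")
    if panel_aneu.gdna_amplicons != panel_ctl.gdna_amplicons:
        raise ConfigurationError("gDNA amplicon sets differ between the two panels")
    norm_a = _panel_norms(panel_aneu)
    norm_c = _panel_norms(panel_ctl)
    out = norm_a / norm_c
    out.name = "per_genome"
    return out


def per_transcriptome_expression(matrix: CountMatrix, panel_genes) -> pd.Series:
    """Relative expression per transcriptome from normalised RNA-seq counts.

    Mean aneuploid over mean control for each panel gene.  ``matrix`` must
    already be on the normalised scale used for the ratio distributions and
    must still contain every panel gene (a filtered-out gene is an error
    naming the gene, not a silent drop).
    """
    panel_genes = list(panel_genes)
    missing = [g for g in panel_genes if g not in matrix.gene_ids]
    if missing:
        raise ConfigurationError(
            f"panel genes {missing} are not in the count matrix (filtered out?)"
        )
    means = average_replicates(matrix.subset(panel_genes))
    out = means["mean_aneuploid"] / means["mean_control"]
    out.name = "per_transcriptome"
    return out


def size_estimates(per_genome: pd.Series, per_transcriptome: pd.Series) -> pd.Series:
    """Per-gene transcriptome-size estimates E_g = per-genome / per-transcriptome."""
    if set(per_genome.index) != set(per_transcriptome.index):
        raise ConfigurationError("per-genome and per-transcriptome gene sets differ")
    pt = per_transcriptome.reindex(per_genome.index)
    pg = per_genome
    for name, s in (("per-genome", pg), ("per-transcriptome", pt)):
        vals = s.to_numpy(float)
        if not (np.isfinite(vals).all() and (vals > 0).all()):
            raise ConfigurationError(f"{name} expression must be finite and positive")
    est = pg / pt
    est.name = "size_estimate"
    return est


def filter_outlier_estimates(estimates: pd.Series, sd_multiplier: float = 2.0) -> pd.Series:
    """Single-pass outlier removal by the two-SD rule.

    Compute the mean ``m`` and (n-1) sample SD ``s`` of all estimates once;
    remove ``E_g`` iff ``|m - E_g| >= sd_multiplier * s``.  With ``s = 0``
    (all estimates equal) nothing is removed.  Removing everything, or
    more than half the panel, signals a pathological panel: the former is
    an error, the latter a data-quality warning.
    """
    est = pd.Series(estimates, dtype=float)
    if len(est) < 2:
        raise ValueError("need at least two estimates to filter outliers")
    m = float(est.mean())
    s = float(est.std(ddof=1))
    if s == 0.0:
        return est
    keep = (est - m).abs() < sd_multiplier * s
    if not keep.any():
        raise ValueError("outlier rule removed every estimate; degenerate panel")
    n_removed = int((~keep).sum())
    if n_removed > len(est) // 2:
        warnings.warn(
            f"outlier rule removed {n_removed}/{len(est)} estimates",
            DataQualityWarning,
            stacklevel=2,
        )
    return est[keep]


@dataclass(frozen=True)
class SizeEstimate:
    """Transcriptome-size estimate: per-gene values, retention, mean, SE, p.

    ``estimates`` holds all per-gene estimates, ``retained`` flags the ones
    surviving the outlier rule; ``mean`` and ``se`` are computed over the
    retained set, and ``p_value`` is a two-sided one-sample location test
    against a size factor of 1.0 (no change).
    """

    estimates: pd.Series
    retained: pd.Series
    mean: float
    se: float
    p_value: float

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def to_dict(self) -> dict:
        return {
            "estimates": {g: float(v) for g, v in self.estimates.items()},
            "retained": {g: bool(v) for g, v in self.retained.items()},
            "mean": float(self.mean),
            "se": float(self.se),
            "p_value": float(self.p_value),
            "n_retained": self.n_retained,
        }


def estimate_size(retained: pd.Series, all_estimates: pd.Series | None = None) -> SizeEstimate:
    """Mean, standard error and significance of the retained estimates.

    The location test against 1.0 is a one-sample t-test on the log
    estimates (multiplicative measurement noise makes the log scale the
    natural one for a ratio-of-ratios); the reported mean and SE stay on
    the natural scale, matching how size factors are quoted.  A spread
    within float rounding of zero is treated as exact: p = 1 when the
    mean is 1, else p = 0.
    """
    retained = pd.Series(retained, dtype=float)
    if len(retained) < 2:
        raise ValueError("need at least two retained estimates")
    mean = float(retained.mean())
    se = float(retained.std(ddof=1) / np.sqrt(len(retained)))
    logs = np.log(retained.to_numpy(float))
    if np.std(logs, ddof=1) <= _DEGENERATE_REL_SD * max(1.0, abs(float(np.mean(logs)))):
        p = 1.0 if abs(float(np.mean(logs))) <= _DEGENERATE_REL_SD else 0.0
    else:
        p = float(sps.ttest_1samp(logs, 0.0).pvalue)
    if all_estimates is None:
        all_estimates = retained
        flags = pd.Series(True, index=retained.index)
    else:
        all_estimates = pd.Series(all_estimates, dtype=float)
        flags = pd.Series(all_estimates.index.isin(retained.index), index=all_estimates.index)
    return SizeEstimate(
        estimates=all_estimates, retained=flags, mean=mean, se=se, p_value=p
    )


def transcriptome_size(
    panel_aneu: DdpcrPanel,
    panel_ctl: DdpcrPanel,
    matrix: CountMatrix,
    sd_multiplier: float = 2.0,
) -> SizeEstimate:
    """End-to-end size estimation from a paired panel and normalised counts.

    The panel's cDNA amplicon ids name the panel genes; the count matrix
    must be on the normalised scale and still contain them.
    """
    pg = per_genome_expression(panel_aneu, panel_ctl)
    pt = per_transcriptome_expression(matrix, list(pg.index))
    est = size_estimates(pg, pt)
    retained = filter_outlier_estimates(est, sd_multiplier=sd_multiplier)
    return estimate_size(retained, all_estimates=est)
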