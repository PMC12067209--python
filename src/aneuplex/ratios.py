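"""Per-gene aneuploid/control expression ratios, cis/trans partition,
binning and medians.

This is the ratio-distribution analysis used to read dosage responses off
bulk RNA-seq: normalise to RPKM, average biological replicates within each
group, drop lowly expressed genes (summed group means below 1 on the
normalised scale), form the per-gene aneuploid/control ratio, partition
genes into cis (per varied arm) and trans, then summarise each partition
as a binned distribution (width 0.05) and a median.  On this scale a cis
ratio of d/2 is a dosage effect and 1.0 is full compensation; a trans
ratio of 2/d is the inverse effect.

Because the input is library-normalised, these ratios are compositional:
they measure each gene *relative to the transcriptome of its own sample*,
so a genome-wide rescaling (a transcriptome-size change) cancels out
entirely.  Absolute statements need the genome-normalised estimator in
:mod:`aneuplex.size`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeModel, Genotype, partition_cis_trans
from .matrix import CountMatrix

__all__ = [
    "REFERENCE_RATIOS",
    "RatioDistribution",
    "normalize_rpkm",
    "average_replicates",
    "filter_low_expression",
    "compute_ratios",
    "partition_cis_trans",
    "bin_ratios",
    "median_ratio",
    "partition_medians",
    "ratio_table",
    "scatter_table",
]

#: Reference ratio guide lines drawn on scatter plots: monosomy dosage
#: effect (0.5), trisomy inverse effect (2/3), no change (1.0), trisomy
#: dosage effect (1.5) and monosomy inverse effect / disomy-in-haploid (2.0).
REFERENCE_RATIOS = (0.5, 0.67, 1.0, 1.5, 2.0)


def normalize_rpkm(
    raw: CountMatrix,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> CountMatrix:
    """Reads Per Kilobase per Million mapped reads.

    ``value = raw * 1e9 / (library_size * length)``.  Library sizes default
    to the per-sample column totals.
    """
    lengths = gene_lengths.reindex(raw.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ConfigurationError("every gene needs a positive length")
    if library_sizes is None:
        library_sizes = raw.library_sizes()
    else:
        library_sizes = library_sizes.reindex(raw.values.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ConfigurationError("library sizes must be positive for all samples")
    values = raw.values * 1e9
    values = values.div(library_sizes, axis=1).div(lengths, axis=0)
    return CountMatrix(values, raw.groups)


def average_replicates(matrix: CountMatrix) -> pd.DataFrame:
    """Arithmetic mean over replicates within each group.

    Returns a DataFrame indexed by gene with ``mean_aneuploid`` and
    ``mean_control`` columns.
    """
    return pd.DataFrame(
        {
            "mean_aneuploid": matrix.aneuploid.mean(axis=1),
            "mean_control": matrix.control.mean(axis=1),
        }
    )


def filter_low_expression(means: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Retain genes whose summed group means reach ``threshold``.

    A gene is lowly expressed, and removed, iff
    ``mean_aneuploid + mean_control < threshold`` (strict, so a sum exactly
    at the threshold is retained).  The sums are taken on the same
    normalised scale that the ratios use.
    """
    total = means["mean_aneuploid"] + means["mean_control"]
    return means.index[total >= threshold]


def compute_ratios(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene aneuploid/control ratio with a finiteness flag.

    Genes with a zero control mean but positive aneuploid mean get an
    infinite ratio: they are flagged non-finite, excluded from medians and
    counted in the overflow bin rather than dropped silently.
    """
    ma = means["mean_aneuploid"].to_numpy(float)
    mc = means["mean_control"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ma / mc
    finite = np.isfinite(ratio) & (ratio > 0)
    out = means.copy()
    out["ratio"] = ratio
    out["finite"] = finite
    return out


@dataclass(frozen=True)
class RatioDistribution:
    """Binned ratio distribution for one partition.

    Half-open, left-closed bins ``[k*w, (k+1)*w)`` of width ``w`` cover
    ``[0, cap)``; ratios at or above ``cap`` (including flagged infinite
    ratios) are pooled in a single overflow bin.  Bin counts plus overflow
    equal the number of ratios submitted.
    """

    partition: str
    width: float
    cap: float
    edges: np.ndarray  #: bin left edges, length n_bins
    counts: np.ndarray  #: per-bin gene counts, length n_bins
    overflow: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: bin_left, bin_right, count, partition.

        The overflow bin is the final row, right-bounded by ``inf``.
        """
        df = pd.DataFrame(
            {
                "bin_left": np.append(self.edges, self.cap),
                "bin_right": np.append(self.edges + self.width, np.inf),
                "count": np.append(self.counts, self.overflow),
            }
        )
        df["partition"] = self.partition
        return df


def bin_ratios(
    ratios, width: float = 0.05, cap: float = 3.0, partition: str = ""
) -> RatioDistribution:
    """Bin ratios into half-open 0.05-wide bins with an overflow pool."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    if cap <= 0:
        raise ValueError("cap must be positive")
    r = np.asarray(ratios, float)
    if (np.isfinite(r) & (r < 0)).any():
        raise ValueError("ratios must be non-negative")
    n_bins = int(np.ceil(cap / width))
    edges = np.arange(n_bins) * width
    in_range = np.isfinite(r) & (r < cap)
    idx = np.floor(r[in_range] / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    overflow = int(r.size - in_range.sum())
    return RatioDistribution(
        partition=partition,
        width=float(width),
        cap=float(cap),
        edges=edges,
        counts=counts,
        overflow=overflow,
    )


def median_ratio(ratios) -> float:
    """Sample median (mean of the central pair for even n) of finite ratios."""
    r = np.asarray(ratios, float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("median of an empty ratio set is undefined")
    return float(np.median(r))


def ratio_table(
    raw: CountMatrix,
    genome: GenomeModel,
    genotype: Genotype,
    threshold: float = 1.0,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """The full ratio pipeline: normalise, average, filter, ratio, partition.

    Returns the RatioTable: one row per retained gene with group means,
    ratio, finiteness flag and partition label (``cis:<arm>``/``trans``).
    """
    normalized = normalize_rpkm(raw, genome.genes["length"], library_sizes)
    means = average_replicates(normalized)
    retained = filter_low_expression(means, threshold)
    table = compute_ratios(means.loc[retained])
    table["partition"] = partition_cis_trans(genome, genotype).reindex(table.index)
    return table


def partition_medians(table: pd.DataFrame) -> dict[str, float]:
    """Median of the finite ratios of each partition in a RatioTable."""
    out: dict[str, float] = {}
    for part, sub in table.groupby("partition", sort=True):
        finite = sub.loc[sub["finite"], "ratio"]
        if len(finite):
            out[str(part)] = median_ratio(finite)
    return out


def partition_distributions(
    table: pd.DataFrame, width: float = 0.05, cap: float = 3.0
) -> dict[str, RatioDistribution]:
    """Binned ratio distribution per partition; infinite ratios overflow."""
    out: dict[str, RatioDistribution] = {}
    for part, sub in table.groupby("partition", sort=True):
        out[str(part)] = bin_ratios(
            sub["ratio"].to_numpy(float), width=width, cap=cap, partition=str(part)
        )
    return out


def scatter_table(means: pd.DataFrame, de_calls: pd.DataFrame) -> pd.DataFrame:
    """MA-style scatter data: log2 fold change vs mean normalised count.

    ``x = log2(mean_aneuploid / mean_control)``, ``y`` the average of the
    two group means, and a significance class taken from the differential
    expression calls (``up``/``down``/``ns`` at q < 0.05).  Rows with a
    non-finite fold change are flagged rather than dropped.  Reference
    vertical lines at ratios 0.5, 0.67, 1.0, 1.5 and 2.0 are exposed as
    :data:`REFERENCE_RATIOS`.
    """
    common = means.index.intersection(de_calls.index)
    ma = means.loc[common, "mean_aneuploid"].to_numpy(float)
    mc = means.loc[common, "mean_control"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.log2(ma / mc)
    out = pd.DataFrame(
        {
            "log2_fold_change": x,
            "mean_expression": (ma + mc) / 2.0,
            "call": de_calls.loc[common, "call"],
            "finite": np.isfinite(x),
        },
        index=common,
    )
    out.attrs["reference_ratios"] = REFERENCE_RATIOS
    return out
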