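"""Distribution comparisons and differential-expression modulation summaries.

Two-sample Kolmogorov-Smirnov tests compare ratio distributions between
aneuploidies; Bartlett's test asks whether their variances (the spread of
modulation) differ.  A per-gene differential-expression caller — Welch's
unequal-variance t on log-transformed normalised counts with
Benjamini-Hochberg adjustment — provides the q < 0.05 decision surface
from which cis compensation (% unchanged) and trans modulation (%SU, %SD,
%DE) are summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome import ConfigurationError, DataQualityWarning
from .matrix import CountMatrix

__all__ = [
    "TestResult",
    "ModulationSummary",
    "ks_two_sample",
    "bartlett_test",
    "adjust_bh",
    "call_de",
    "summarize_modulation",
]


@dataclass(frozen=True)
class TestResult:
    """A two-sample (or k-sample) test outcome."""

    statistic: float
    p_value: float
    sample_sizes: tuple[int, ...]
    test: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "sample_sizes": list(self.sample_sizes),
        }


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of |ECDF_x - ECDF_y| over the merged sample points
    (evaluating right-continuous ECDFs at every observed point attains the
    supremum, ties included).  The p-value uses the asymptotic Kolmogorov
    distribution with effective size n m / (n + m) — adequate at the
    thousands-of-genes sizes of ratio sets.
    """
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / n
    fy = np.searchsorted(y, grid, side="right") / m
    d = float(np.max(np.abs(fx - fy)))
    en = n * m / (n + m)
    p = float(sps.kstwobign.sf(np.sqrt(en) * d))
    return TestResult(statistic=d, p_value=min(max(p, 0.0), 1.0), sample_sizes=(n, m), test="ks")


def bartlett_test(*groups) -> TestResult:
    """Bartlett's test for equal variances across k >= 2 groups.

    Classical chi-square statistic with k - 1 degrees of freedom and its
    upper-tail p-value.  A group with fewer than two observations or zero
    variance leaves the statistic undefined and raises.
    """
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two observations")
        if np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance; the statistic is undefined")
    stat, p = sps.bartlett(*arrays)
    return TestResult(
        statistic=float(stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        sample_sizes=tuple(g.size for g in arrays),
        test="bartlett",
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    p = np.asarray(p_values, float)
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    matrix: CountMatrix,
    q_threshold: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene differential-expression calls between aneuploid and control.

    Welch's unequal-variance two-sample t-test on
    ``log2(normalised + pseudocount)``, Benjamini-Hochberg step-up over all
    tested genes, and a call of ``up``/``down``/``ns`` by q < threshold
    and the sign of the log fold change.  The fold change is the
    difference of group means on the log scale, so its sign always agrees
    with the test direction.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means are equal and p = 0 when they differ — the noiseless
    limits of the t-test.  With fewer than two replicates in a group no
    p-value exists: every gene is called ``ns`` and a warning is emitted.
    """
    loga = np.log2(matrix.aneuploid.to_numpy(float) + pseudocount)
    logc = np.log2(matrix.control.to_numpy(float) + pseudocount)
    lfc = loga.mean(axis=1) - logc.mean(axis=1)

    if loga.shape[1] < 2 or logc.shape[1] < 2:
        warnings.warn(
            "fewer than two replicates in a group: no p-values, all calls 'ns'",
            DataQualityWarning,
            stacklevel=2,
        )
        out = pd.DataFrame(
            {"lfc": lfc, "p": np.nan, "q": np.nan, "call": "ns"}, index=matrix.gene_ids
        )
        return out

    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(loga, logc, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = p.copy()
        p[degenerate] = np.where(lfc[degenerate] == 0.0, 1.0, 0.0)

    q = adjust_bh(p)
    call = np.full(len(lfc), "ns", dtype=object)
    call[(q < q_threshold) & (lfc > 0)] = "up"
    call[(q < q_threshold) & (lfc < 0)] = "down"
    return pd.DataFrame({"lfc": lfc, "p": p, "q": q, "call": call}, index=matrix.gene_ids)


@dataclass(frozen=True)
class ModulationSummary:
    """Percent-unchanged cis and %SU/%SD/%DE trans, with their counts.

    ``cis`` maps each varied arm to its gene count, DE count and percent
    unchanged ``100 * (n - n_de) / n``; ``trans`` holds the significantly
    up-/down-regulated counts against the trans total.  All percentages
    recompute exactly from the counts.
    """

    cis: dict[str, dict] = field(default_factory=dict)
    trans: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"cis": self.cis, "trans": self.trans}


def summarize_modulation(calls: pd.DataFrame, partition: pd.Series) -> ModulationSummary:
    """Summarise DE calls per partition.

    For each cis arm: percent unchanged = 100 * (total cis - cis DE) /
    total cis.  For trans: %SU and %SD are the significantly up- and
    down-regulated counts over the trans total, and %DE is their sum.
    """
    if not calls.index.equals(partition.index):
        partition = partition.reindex(calls.index)
        if partition.isna().any():
            raise ConfigurationError("partition labels do not cover the called gene set")
    cis_arms = sorted(p for p in partition.unique() if str(p).startswith("cis:"))
    if not cis_arms:
        raise ConfigurationError("no cis partition present")
    if not (partition == "trans").any():
        raise ConfigurationError("trans partition is empty")

    cis: dict[str, dict] = {}
    for label in cis_arms:
        mask = partition == label
        n = int(mask.sum())
        n_de = int((calls.loc[mask, "call"] != "ns").sum())
        cis[label.removeprefix("cis:")] = {
            "n": n,
            "n_de": n_de,
            "pct_unchanged": 100.0 * (n - n_de) / n,
        }

    t = calls.loc[partition == "trans", "call"]
    n_trans = int(len(t))
    n_su = int((t == "up").sum())
    n_sd = int((t == "down").sum())
    trans = {
        "n": n_trans,
        "n_su": n_su,
        "n_sd": n_sd,
        "pct_su": 100.0 * n_su / n_trans,
        "pct_sd": 100.0 * n_sd / n_trans,
        "pct_de": 100.0 * (n_su + n_sd) / n_trans,
    }
    return ModulationSummary(cis=cis, trans=trans)
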