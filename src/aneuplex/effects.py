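"""Effect classes and per-gene expected expression ratios.

Aneuploidy modulates expression in a small set of canonical ways, expressed
as the expected aneuploid/control ratio of a gene:

* ``dosage_effect`` (cis): expression proportional to copy number, ratio
  d/p — 1.5 in trisomy, 0.5 in monosomy on a diploid background.
* ``compensation`` (cis): expression unchanged despite the dose change,
  ratio 1.
* ``inverse`` (trans): modulation opposite to the dose change, ratio p/d —
  2/3 in trisomy, 1/2 in tetrasomy, 2 in monosomy.
* ``direct`` (trans): modulation in the same direction as the dose change,
  ratio d/p.
* ``no_change`` (trans): ratio 1.

When two or more arms are varied at once, a trans gene feels one ratio per
varied arm; how these compose (cumulatively, multiplicatively, or with one
arm dominating) is an empirical question, so the composition rule is an
explicit, selectable mode rather than a fixed law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeModel, Genotype, partition_cis_trans

__all__ = [
    "EffectClass",
    "CIS_CLASSES",
    "TRANS_CLASSES",
    "EffectAssignment",
    "expected_ratio",
    "compose_trans_ratio",
    "assign_effect_classes",
]


class EffectClass(str, Enum):
    DOSAGE_EFFECT = "dosage_effect"
    COMPENSATION = "compensation"
    INVERSE = "inverse"
    DIRECT = "direct"
    NO_CHANGE = "no_change"


#: Classes a cis gene (on the varied arm) may carry.
CIS_CLASSES = frozenset({EffectClass.DOSAGE_EFFECT, EffectClass.COMPENSATION})
#: Classes a trans gene may carry.
TRANS_CLASSES = frozenset({EffectClass.INVERSE, EffectClass.DIRECT, EffectClass.NO_CHANGE})

#: Floor for composed ratios so additive composition cannot go non-positive.
RATIO_FLOOR = 1e-6


def expected_ratio(effect_class: EffectClass | str, dose: int, ploidy: int = 2) -> float:
    """Expected aneuploid/control expression ratio for one varied arm.

    ``dosage_effect`` and ``direct`` give d/p, ``inverse`` gives p/d,
    ``compensation`` and ``no_change`` give 1.  At the unvaried dose
    (d == p) every class gives 1.
    """
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if int(dose) != dose or not 1 <= int(dose) <= 4:
        raise ValueError(f"dose must be an integer in 1..4, got {dose}")
    effect_class = EffectClass(effect_class)
    d, p = float(dose), float(ploidy)
    if effect_class in (EffectClass.DOSAGE_EFFECT, EffectClass.DIRECT):
        return d / p
    if effect_class == EffectClass.INVERSE:
        return p / d
    return 1.0


def compose_trans_ratio(
    per_arm_ratios: Sequence[float],
    mode: str = "multiplicative",
    floor: float = RATIO_FLOOR,
) -> float:
    """Compose the per-arm trans ratios of a multi-arm aneuploidy.

    Modes
    -----
    ``multiplicative``
        Product of the per-arm ratios: each arm's modulation acts on the
        output of the other.
    ``additive``
        Cumulative deviations from 1: ``1 + sum(r_a - 1)``, floored at a
        small positive value so the composed ratio stays positive.
    ``dominant``
        The single per-arm ratio with the largest \\|log r\\| wins
        (rebalancing by the strongest effect).
    """
    ratios = [float(r) for r in per_arm_ratios]
    if not ratios:
        raise ValueError("per_arm_ratios must be non-empty")
    if any(r <= 0 for r in ratios):
        raise ValueError("per-arm ratios must be positive")
    if mode == "multiplicative":
        return float(np.prod(ratios))
    if mode == "additive":
        return max(1.0 + sum(r - 1.0 for r in ratios), floor)
    if mode == "dominant":
        return max(ratios, key=lambda r: abs(math.log(r)))
    raise ConfigurationError(f"unknown composition mode {mode!r}")


@dataclass(frozen=True)
class EffectAssignment:
    """Per-gene effect classes and expected ratios, with an optional
    genome-wide scale.

    ``table`` is indexed by gene_id with columns ``partition``
    (``cis:<arm>``/``trans``), ``effect_class`` and ``expected_ratio`` (the
    class-derived ratio, already composed across varied arms for trans
    genes).  ``global_scale`` is a uniform multiplier on all true
    abundances: it models a pure transcriptome-size change, which is real
    on the per-cell scale but invisible to library-normalised counts.
    """

    table: pd.DataFrame
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        missing = {"partition", "effect_class", "expected_ratio"} - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"assignment table is missing columns {sorted(missing)}")
        if not np.isfinite(self.global_scale) or self.global_scale <= 0:
            raise ConfigurationError("global_scale must be a positive finite number")
        r = self.table["expected_ratio"].to_numpy(float)
        if not (np.isfinite(r).all() and (r > 0).all()):
            raise ConfigurationError("expected ratios must be finite and positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def expected_ratios(self) -> pd.Series:
        """Class-derived expected ratios r_g (without the global scale)."""
        return self.table["expected_ratio"]

    @property
    def abundance_ratios(self) -> pd.Series:
        """True per-cell abundance ratios: r_g times the global scale."""
        return self.table["expected_ratio"] * self.global_scale

    def with_global_scale(self, factor: float) -> "EffectAssignment":
        """Return a copy whose abundances are uniformly scaled by ``factor``."""
        return replace(self, global_scale=self.global_scale * float(factor))


def _validate_mixture(
    mixture: Mapping[EffectClass | str, float],
    legal: frozenset[EffectClass],
    partition_name: str,
) -> dict[EffectClass, float]:
    out: dict[EffectClass, float] = {}
    for cls, frac in mixture.items():
        cls = EffectClass(cls)
        if cls not in legal:
            raise ConfigurationError(
                f"class {cls.value!r} is not legal for the {partition_name} partition"
            )
        if frac < 0:
            raise ConfigurationError(f"mixture fraction for {cls.value!r} is negative")
        out[cls] = float(frac)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-8:
        raise ConfigurationError(f"{partition_name} mixture must sum to 1, got {total}")
    return out


def assign_effect_classes(
    genome: GenomeModel,
    genotype: Genotype,
    cis_mixture: Mapping[EffectClass | str, float],
    trans_mixture: Mapping[EffectClass | str, float],
    seed: int = 0,
    composition_mode: str = "multiplicative",
) -> EffectAssignment:
    """Sample a per-gene effect class and compute its expected ratio.

    Cis genes (on each varied arm) draw from ``cis_mixture`` over
    {dosage_effect, compensation} and respond to their own arm's dose.
    Trans genes draw from ``trans_mixture`` over {inverse, direct,
    no_change}; with two or more varied arms their per-arm ratios are
    composed with ``composition_mode``.
    """
    cis_mix = _validate_mixture(cis_mixture, CIS_CLASSES, "cis")
    trans_mix = _validate_mixture(trans_mixture, TRANS_CLASSES, "trans")
    partition = partition_cis_trans(genome, genotype)
    rng = np.random.default_rng(seed)

    classes = pd.Series(index=genome.gene_ids, dtype=object)
    ratios = pd.Series(np.ones(genome.n_genes), index=genome.gene_ids)

    varied = genotype.varied_arms
    is_trans = partition == "trans"

    t_classes = list(trans_mix)
    t_probs = np.array([trans_mix[c] for c in t_classes])
    n_trans = int(is_trans.sum())
    if n_trans:
        draw = rng.choice(len(t_classes), size=n_trans, p=t_probs)
        classes[is_trans] = [t_classes[i].value for i in draw]
        per_class = {
            cls: compose_trans_ratio(
                [expected_ratio(cls, genotype.dose(a), genotype.background_ploidy) for a in varied],
                composition_mode,
            )
            for cls in t_classes
        }
        ratios[is_trans] = [per_class[t_classes[i]] for i in draw]

    c_classes = list(cis_mix)
    c_probs = np.array([cis_mix[c] for c in c_classes])
    for arm in varied:
        mask = partition == f"cis:{arm}"
        n_cis = int(mask.sum())
        if not n_cis:
            continue
        draw = rng.choice(len(c_classes), size=n_cis, p=c_probs)
        classes[mask] = [c_classes[i].value for i in draw]
        dose = genotype.dose(arm)
        per_class = {
            cls: expected_ratio(cls, dose, genotype.background_ploidy) for cls in c_classes
        }
        ratios[mask] = [per_class[c_classes[i]] for i in draw]

    table = pd.DataFrame(
        {"partition": partition, "effect_class": classes, "expected_ratio": ratios}
    )
    return EffectAssignment(table)
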