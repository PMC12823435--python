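"""Functional classing of annotated coding variants.

Variants arrive with a transcript consequence, a loss-of-function (LOF)
prediction flag and, for missense variants, an MPC deleteriousness score.
They are collapsed to a single most-severe consequence, assigned a
functional category (PTV / severe or moderate damaging missense /
synonymous / other) and a burden class:

* class I  — protein-truncating variants (stop-gained, frameshift,
  essential splice-site, each requiring the LOF flag) together with
  severe damaging missense variants (MPC > 3);
* class II — moderate damaging missense variants (2 <= MPC <= 3);
* synonymous variants are kept as a calibration category.

Rarity is a cross-dataset allele-count threshold (default AC <= 5 on
autosomes and X PAR). On the X non-PAR region, where males are
hemizygous, the threshold is rescaled by the effective number of X
chromosomes per individual and floored to an integer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Consequence",
    "FunctionalCategory",
    "BurdenClass",
    "Zone",
    "VariantRecord",
    "SEVERITY_ORDER",
    "most_severe_annotation",
    "classify_variant",
    "to_burden_class",
    "x_nonpar_threshold",
    "default_zone_thresholds",
    "is_rare",
    "is_ultra_rare",
]


class Consequence(str, enum.Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class FunctionalCategory(str, enum.Enum):
    PTV = "PTV"
    SEVERE_DMV = "severeDMV"
    MODERATE_DMV = "moderateDMV"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class BurdenClass(str, enum.Enum):
    CLASS_I = "class_I"
    CLASS_II = "class_II"
    SYNONYMOUS = "synonymous"
    NONE = "none"


class Zone(str, enum.Enum):
    AUTOSOME = "autosome"
    X_PAR = "x_par"
    X_NONPAR = "x_nonpar"


# Total severity order; the order among PTV subtypes does not affect
# classing but a fixed order keeps most_severe_annotation deterministic.
SEVERITY_ORDER: tuple[Consequence, ...] = (
    Consequence.STOP_GAINED,
    Consequence.FRAMESHIFT,
    Consequence.SPLICE_SITE,
    Consequence.MISSENSE,
    Consequence.SYNONYMOUS,
    Consequence.OTHER,
)

_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}
_PTV_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAINED, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


@dataclass
class VariantRecord:
    """One annotated alternate allele.

    ``allele_counts`` maps a dataset label (e.g. ``"cohort"``,
    ``"external"``) to the allele count observed in that dataset; rarity
    is judged on the sum over datasets.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: Consequence
    lof_flag: bool = False
    mpc: float | None = None
    zone: Zone = Zone.AUTOSOME
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        self.zone = Zone(self.zone)
        if self.mpc is not None and self.mpc < 0:
            raise ValueError(f"negative MPC for {self.variant_id}")
        for label, ac in self.allele_counts.items():
            if ac < 0:
                raise ValueError(f"negative allele count {label}={ac} for {self.variant_id}")


def most_severe_annotation(annotations: Sequence) -> object:
    """Collapse multiple transcript annotations to the most severe one.

    ``annotations`` is a non-empty sequence of objects with a
    ``consequence`` attribute (or plain :class:`Consequence` values).
    Ties on consequence keep the first-listed record.
    """
    if len(annotations) == 0:
        raise ValueError("most_severe_annotation requires a non-empty annotation list")

    def rank(a) -> int:
        cons = a if isinstance(a, Consequence) else Consequence(getattr(a, "consequence", a))
        return _SEVERITY_RANK[cons]

    return min(annotations, key=rank)


def classify_variant(v: VariantRecord) -> FunctionalCategory:
    """Assign the functional category from consequence, LOF flag and MPC.

    PTV requires both a truncating consequence and the LOF flag; a
    truncating consequence without the flag is demoted to ``other``.
    Missense with MPC > 3 is severe, MPC in [2, 3] moderate (both ends
    inclusive, so MPC = 3 is moderate), anything lower or missing is
    ``other``.
    """
    if v.consequence in _PTV_CONSEQUENCES:
        return FunctionalCategory.PTV if v.lof_flag else FunctionalCategory.OTHER
    if v.consequence is Consequence.MISSENSE:
        if v.mpc is None:
            return FunctionalCategory.OTHER
        if v.mpc > 3:
            return FunctionalCategory.SEVERE_DMV
        if 2 <= v.mpc <= 3:
            return FunctionalCategory.MODERATE_DMV
        return FunctionalCategory.OTHER
    if v.consequence is Consequence.SYNONYMOUS:
        return FunctionalCategory.SYNONYMOUS
    return FunctionalCategory.OTHER


_CATEGORY_TO_CLASS = {
    FunctionalCategory.PTV: BurdenClass.CLASS_I,
    FunctionalCategory.SEVERE_DMV: BurdenClass.CLASS_I,
    FunctionalCategory.MODERATE_DMV: BurdenClass.CLASS_II,
    FunctionalCategory.SYNONYMOUS: BurdenClass.SYNONYMOUS,
    FunctionalCategory.OTHER: BurdenClass.NONE,
}


def to_burden_class(category: FunctionalCategory) -> BurdenClass:
    """Map a functional category to its burden class (I, II, synonymous, none)."""
    return _CATEGORY_TO_CLASS[FunctionalCategory(category)]


def x_nonpar_threshold(
    autosomal_threshold: int, n_males: int, n_females: int
) -> tuple[float, int]:
    """Rescale the autosomal rarity threshold for the X non-PAR region.

    Males carry one X chromosome in non-PAR regions, so the number of
    chromosomes an allele can appear on is ``n_males + 2 n_females``
    rather than ``2 (n_males + n_females)``. The autosomal allele-count
    threshold is scaled by that ratio and floored to an integer
    threshold ("three or less" for the default 5 at typical male-biased
    psychiatric cohorts).

    Returns ``(scale, threshold)`` where ``threshold = floor(scale)``.
    """
    if autosomal_threshold <= 0:
        raise ValueError("autosomal threshold must be positive")
    if n_males < 0 or n_females < 0:
        raise ValueError("sample counts must be non-negative")
    total = n_males + n_females
    if total == 0:
        raise ValueError("n_males + n_females must be positive")
    scale = autosomal_threshold * (n_males + 2 * n_females) / (2 * total)
    return scale, math.floor(scale)


def default_zone_thresholds(
    autosomal_threshold: int = 5,
    n_males: int | None = None,
    n_females: int | None = None,
) -> dict[Zone, int]:
    """Per-zone rarity thresholds: autosome and X PAR use the autosomal
    threshold; X non-PAR uses the hemizygosity-scaled one (3 when no
    sample counts are supplied, the floored scaled value otherwise)."""
    if n_males is None or n_females is None:
        nonpar = 3
    else:
        _, nonpar = x_nonpar_threshold(autosomal_threshold, n_males, n_females)
    return {
        Zone.AUTOSOME: autosomal_threshold,
        Zone.X_PAR: autosomal_threshold,
        Zone.X_NONPAR: nonpar,
    }


def is_rare(v: VariantRecord, thresholds: Mapping[Zone, int]) -> bool:
    """True iff the cross-dataset allele count is at or below the
    threshold for the variant's chromosome zone."""
    zone = Zone(v.zone)
    if zone not in thresholds:
        raise KeyError(f"no rarity threshold configured for zone {zone.value}")
    total_ac = sum(v.allele_counts.values())
    return total_ac <= thresholds[zone]


def is_ultra_rare(
    v: VariantRecord,
    cohort_label: str,
    reference_counts: Mapping[str, int] | None = None,
) -> bool:
    """True iff the variant is a cohort singleton absent from the
    external reference panel (reference count 0 or not listed)."""
    if cohort_label not in v.allele_counts:
        raise KeyError(f"cohort label {cohort_label!r} missing from allele_counts")
    if v.allele_counts[cohort_label] != 1:
        return False
    ref_ac = 0 if reference_counts is None else reference_counts.get(v.variant_id, 0)
    return ref_ac == 0
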