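"""Nitrogen-balance protein-quality metrics: TD, BV and PDCAAS.

True digestibility (TD) is the fraction of ingested nitrogen absorbed,
after crediting the metabolic faecal nitrogen that does not originate
from the diet:

    TD = (N_intake - (N_faeces - N_metabolic)) / N_intake

Biological value (BV) is the fraction of absorbed nitrogen retained,
after crediting endogenous urinary nitrogen:

    BV = (N_intake - (N_faeces - N_metabolic) - (N_urine - N_endogenous))
         / (N_intake - (N_faeces - N_metabolic))

Both are reported on the x100 (percentage) scale. N_metabolic scales with
dry matter actually consumed (default 1.01 mg N/g DM); N_endogenous with
balance days (default 15.2 mg N/day, growing rat). Protein mass is
nitrogen x 6.38 (milk proteins).

PDCAAS scores a protein's essential-amino-acid adequacy: each of the nine
scoring categories is the test protein's content divided by an age-specific
reference requirement, times TD. The overall PDCAAS is the limiting
(minimum) category, capped at 100 by FAO convention; uncapped per-category
scores are reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .presets import N_ENDOGENOUS_RATE, N_METABOLIC_RATE, N_TO_PROTEIN

__all__ = [
    "NitrogenBalance",
    "AminoAcidProfile",
    "ReferencePattern",
    "PDCAASResult",
    "nitrogen_to_protein",
    "true_digestibility",
    "biological_value",
    "pdcaas",
    "summarize_groups",
]

#: The nine PDCAAS scoring categories (sulphur and aromatic AAs pooled).
SCORING_CATEGORIES = (
    "his", "ile", "leu", "lys", "met+cys", "phe+tyr", "thr", "trp", "val",
)


@dataclass(frozen=True)
class NitrogenBalance:
    """One animal's nitrogen bookkeeping over a balance period.

    Masses are totals over the whole period, in mg N; ``dm_feed`` is total
    dry matter consumed in g; correction rates default to the growing-rat
    constants.
    """

    n_intake: float
    n_faeces: float
    n_urine: float
    dm_feed: float
    days: int
    n_metabolic_rate: float = N_METABOLIC_RATE
    n_endogenous_rate: float = N_ENDOGENOUS_RATE

    def __post_init__(self) -> None:
        for name in ("n_intake", "n_faeces", "n_urine", "dm_feed"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")

    @property
    def n_metabolic(self) -> float:
        """Metabolic faecal N over the period, mg."""
        return self.n_metabolic_rate * self.dm_feed

    @property
    def n_endogenous(self) -> float:
        """Endogenous urinary N over the period, mg."""
        return self.n_endogenous_rate * self.days


def nitrogen_to_protein(n_mass: float) -> float:
    """Convert a nitrogen mass to protein mass using the 6.38 milk factor."""
    if n_mass < 0:
        raise ValueError(f"nitrogen mass must be >= 0, got {n_mass}")
    return n_mass * N_TO_PROTEIN


def true_digestibility(b: NitrogenBalance) -> float:
    """True digestibility as a percentage; uncapped.

    Values above 100 can occur when faecal N falls below the metabolic
    credit; they are returned as-is with a warning, never clipped.
    """
    if b.n_intake <= 0:
        raise ValueError("true digestibility requires n_intake > 0")
    td = (b.n_intake - (b.n_faeces - b.n_metabolic)) / b.n_intake * 100.0
    if td > 100.0 or td < 0.0:
        warnings.warn(
            f"true digestibility {td:.2f}% outside [0, 100] "
            "(metabolic correction exceeded faecal N, or faecal N exceeded intake)",
            stacklevel=2,
        )
    return td


def biological_value(b: NitrogenBalance) -> float:
    """Biological value as a percentage; uncapped, warned if outside [0, 100]."""
    absorbed = b.n_intake - (b.n_faeces - b.n_metabolic)
    if absorbed == 0:
        raise ValueError("biological value undefined: absorbed nitrogen is zero")
    retained = absorbed - (b.n_urine - b.n_endogenous)
    bv = retained / absorbed * 100.0
    if bv > 100.0 or bv < 0.0:
        warnings.warn(f"biological value {bv:.2f}% outside [0, 100]", stacklevel=2)
    return bv


@dataclass(frozen=True)
class AminoAcidProfile:
    """Amino-acid composition of a protein, mg AA per g total protein.

    ``composition`` is keyed by lowercase 3-letter codes; the pooled
    scoring categories met+cys and phe+tyr are derived by summation (an
    explicit pooled entry, if present, takes precedence).
    """

    label: str
    composition: dict[str, float]

    def __post_init__(self) -> None:
        for aa, v in self.composition.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.label}: entry {aa!r} must be >= 0, got {v!r}")

    def scoring_amount(self, category: str) -> float:
        """mg/g for one scoring category, pooling sulphur/aromatic pairs."""
        comp = self.composition
        if category in comp:
            return comp[category]
        if "+" in category:
            parts = category.split("+")
            if all(p in comp for p in parts):
                return sum(comp[p] for p in parts)
        raise KeyError(
            f"profile {self.label!r} is missing scoring category {category!r}"
        )


@dataclass(frozen=True)
class ReferencePattern:
    """An EAA requirement pattern (mg per g protein) for PDCAAS scoring."""

    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SCORING_CATEGORIES if c not in self.values]
        extra = [c for c in self.values if c not in SCORING_CATEGORIES]
        if missing or extra:
            raise ValueError(
                f"reference pattern must cover exactly {SCORING_CATEGORIES}; "
                f"missing {missing}, unexpected {extra}"
            )
        for c, v in self.values.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"reference entry {c!r} must be > 0, got {v!r}")


@dataclass(frozen=True)
class PDCAASResult:
    """Per-category uncapped PDCAAS scores plus the capped overall score."""

    label: str
    scores: dict[str, float] = field(repr=False)
    limiting_category: str
    limiting_score: float
    overall: float


def pdcaas(
    profile: AminoAcidProfile, ref: ReferencePattern, td_percent: float
) -> PDCAASResult:
    """PDCAAS = AA_feedstuff / AA_reference x TD, per scoring category.

    ``td_percent`` is the true digestibility on the x100 scale. Returns
    uncapped per-category scores, the limiting (minimum) category, and the
    overall score capped at 100 per the FAO convention.
    """
    if td_percent < 0:
        raise ValueError(f"td_percent must be >= 0, got {td_percent}")
    scores = {
        c: profile.scoring_amount(c) / ref.values[c] * td_percent
        for c in SCORING_CATEGORIES
    }
    limiting = min(scores, key=scores.__getitem__)
    return PDCAASResult(
        label=profile.label,
        scores=scores,
        limiting_category=limiting,
        limiting_score=scores[limiting],
        overall=min(scores[limiting], 100.0),
    )


def summarize_groups(values_by_group: dict[str, list[float]]) -> dict[str, tuple[float, float]]:
    """Mean and SEM per group, for per-animal TD/BV summaries."""
    out = {}
    for g, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        out[g] = (float(arr.mean()), float(sem))
    return out
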