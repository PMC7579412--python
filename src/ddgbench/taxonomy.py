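"""Residue classes, mutation-category assignment, and stability classification.

A point mutation is described by its wild-type and mutant residues, and
optionally by the burial of the mutated site.  Categories are multi-label:
an E→K mutation is simultaneously "Negative to positive", "Same size" (both
residues are large) and part of "Everything".

The nine residue classes and their combinations into mutation categories,
the ±1 kcal/mol stabilizing/destabilizing thresholds, and the ordinal
0/1/2 classification-error score are the scoring scheme this package
implements; see docs/methods.md for the rationale behind each boundary.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The nine residue classes, one-letter membership sets.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "Small": frozenset("GAVSTC"),
    "Large": frozenset("FYWKRHQE"),
    "Negative": frozenset("DE"),
    "Positive": frozenset("RK"),
    "Polar": frozenset("YTSHKREDQN"),
    "NonChargedPolar": frozenset("YTSNQH"),
    "Hydrophobic": frozenset("FILVAGMW"),
    "Cysteine": frozenset("C"),
    "Proline": frozenset("P"),
}

#: The four mutually disjoint polarity classes used for directional pairs.
POLARITY_CLASSES = ("Positive", "Negative", "NonChargedPolar", "Hydrophobic")


class ValidationError(ValueError):
    """Raised for non-canonical residues or non-finite energies."""


def _check_aa(aa: str) -> str:
    if not isinstance(aa, str) or aa.upper() not in CANONICAL_AA:
        raise ValidationError(f"non-canonical amino-acid code: {aa!r}")
    return aa.upper()


def residue_classes(aa: str) -> frozenset[str]:
    """Return the set of class names whose membership sets contain ``aa``."""
    aa = _check_aa(aa)
    return frozenset(name for name, members in RESIDUE_CLASSES.items() if aa in members)


class CategoryLabel(enum.Enum):
    """Mutation-type categories; values are the report row-label strings."""

    POSITIVE_TO_NEGATIVE = "Positive to negative"
    NEGATIVE_TO_POSITIVE = "Negative to positive"
    POSITIVE_TO_NONCHARGED_POLAR = "Positive to non-charged polar"
    NEGATIVE_TO_NONCHARGED_POLAR = "Negative to non-charged polar"
    NONCHARGED_POLAR_TO_POSITIVE = "Non-charged polar to positive"
    NONCHARGED_POLAR_TO_NEGATIVE = "Non-charged polar to negative"
    NEGATIVE_TO_HYDROPHOBIC = "Negative to hydrophobic"
    HYDROPHOBIC_TO_NEGATIVE = "Hydrophobic to negative"
    POSITIVE_TO_HYDROPHOBIC = "Positive to hydrophobic"
    HYDROPHOBIC_TO_POSITIVE = "Hydrophobic to positive"
    NONCHARGED_POLAR_TO_HYDROPHOBIC = "Non-charged polar to hydrophobic"
    HYDROPHOBIC_TO_NONCHARGED_POLAR = "Hydrophobic to non-charged polar"
    NONCHARGED_POLAR_TO_NONCHARGED_POLAR = "Non-charged polar to non-charged polar"
    HYDROPHOBIC_TO_HYDROPHOBIC = "Hydrophobic to hydrophobic"
    LIKE_TO_LIKE_CHARGE = "Charge to charge"
    INVOLVES_PROLINE = "Involves proline"
    INVOLVES_CYSTEINE = "Involves cysteine"
    SMALL_TO_LARGE = "Small to large"
    LARGE_TO_SMALL = "Large to small"
    SAME_SIZE = "Same size"
    BURIED = "Buried"
    SURFACE = "Surface"
    EVERYTHING = "Everything"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Narrowly defined categories, each filled to the cap during balancing.
#: Small to large / Large to small / Buried / Surface are supersets that
#: receive no dedicated fill; Same size and Everything are pure aggregates.
NARROW_CATEGORIES: tuple[CategoryLabel, ...] = (
    CategoryLabel.POSITIVE_TO_NEGATIVE,
    CategoryLabel.NEGATIVE_TO_POSITIVE,
    CategoryLabel.POSITIVE_TO_NONCHARGED_POLAR,
    CategoryLabel.NEGATIVE_TO_NONCHARGED_POLAR,
    CategoryLabel.NONCHARGED_POLAR_TO_POSITIVE,
    CategoryLabel.NONCHARGED_POLAR_TO_NEGATIVE,
    CategoryLabel.NEGATIVE_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_NEGATIVE,
    CategoryLabel.POSITIVE_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_POSITIVE,
    CategoryLabel.NONCHARGED_POLAR_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_NONCHARGED_POLAR,
    CategoryLabel.NONCHARGED_POLAR_TO_NONCHARGED_POLAR,
    CategoryLabel.HYDROPHOBIC_TO_HYDROPHOBIC,
    CategoryLabel.LIKE_TO_LIKE_CHARGE,
    CategoryLabel.INVOLVES_PROLINE,
    CategoryLabel.INVOLVES_CYSTEINE,
)

#: Fixed report row order (directional pairs, aggregates, burial, total).
TABLE_ORDER: tuple[CategoryLabel, ...] = (
    CategoryLabel.SMALL_TO_LARGE,
    CategoryLabel.LARGE_TO_SMALL,
    CategoryLabel.POSITIVE_TO_NEGATIVE,
    CategoryLabel.NEGATIVE_TO_POSITIVE,
    CategoryLabel.NEGATIVE_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_NEGATIVE,
    CategoryLabel.POSITIVE_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_POSITIVE,
    CategoryLabel.NONCHARGED_POLAR_TO_POSITIVE,
    CategoryLabel.POSITIVE_TO_NONCHARGED_POLAR,
    CategoryLabel.NONCHARGED_POLAR_TO_NEGATIVE,
    CategoryLabel.NEGATIVE_TO_NONCHARGED_POLAR,
    CategoryLabel.NONCHARGED_POLAR_TO_HYDROPHOBIC,
    CategoryLabel.HYDROPHOBIC_TO_NONCHARGED_POLAR,
    CategoryLabel.NONCHARGED_POLAR_TO_NONCHARGED_POLAR,
    CategoryLabel.HYDROPHOBIC_TO_HYDROPHOBIC,
    CategoryLabel.LIKE_TO_LIKE_CHARGE,
    CategoryLabel.INVOLVES_CYSTEINE,
    CategoryLabel.INVOLVES_PROLINE,
    CategoryLabel.SAME_SIZE,
    CategoryLabel.BURIED,
    CategoryLabel.SURFACE,
    CategoryLabel.EVERYTHING,
)

LABEL_BY_STRING = {label.value: label for label in CategoryLabel}

_POLARITY_PAIR_LABEL: dict[tuple[str, str], CategoryLabel] = {
    ("Positive", "Negative"): CategoryLabel.POSITIVE_TO_NEGATIVE,
    ("Negative", "Positive"): CategoryLabel.NEGATIVE_TO_POSITIVE,
    ("Positive", "NonChargedPolar"): CategoryLabel.POSITIVE_TO_NONCHARGED_POLAR,
    ("Negative", "NonChargedPolar"): CategoryLabel.NEGATIVE_TO_NONCHARGED_POLAR,
    ("NonChargedPolar", "Positive"): CategoryLabel.NONCHARGED_POLAR_TO_POSITIVE,
    ("NonChargedPolar", "Negative"): CategoryLabel.NONCHARGED_POLAR_TO_NEGATIVE,
    ("Negative", "Hydrophobic"): CategoryLabel.NEGATIVE_TO_HYDROPHOBIC,
    ("Hydrophobic", "Negative"): CategoryLabel.HYDROPHOBIC_TO_NEGATIVE,
    ("Positive", "Hydrophobic"): CategoryLabel.POSITIVE_TO_HYDROPHOBIC,
    ("Hydrophobic", "Positive"): CategoryLabel.HYDROPHOBIC_TO_POSITIVE,
    ("NonChargedPolar", "Hydrophobic"): CategoryLabel.NONCHARGED_POLAR_TO_HYDROPHOBIC,
    ("Hydrophobic", "NonChargedPolar"): CategoryLabel.HYDROPHOBIC_TO_NONCHARGED_POLAR,
    ("NonChargedPolar", "NonChargedPolar"): CategoryLabel.NONCHARGED_POLAR_TO_NONCHARGED_POLAR,
    ("Hydrophobic", "Hydrophobic"): CategoryLabel.HYDROPHOBIC_TO_HYDROPHOBIC,
}


def classify_mutation(
    wt: str, mut: str, burial: CategoryLabel | str | None = None
) -> frozenset[CategoryLabel]:
    """Assign the multi-label category set of a wt→mut point mutation.

    Parameters
    ----------
    wt, mut
        One-letter codes of the wild-type and mutant residue; must differ.
    burial
        Optional ``CategoryLabel.BURIED`` / ``CategoryLabel.SURFACE`` (or the
        strings "Buried"/"Surface") copied through from a structural burial
        call; sequence alone cannot determine it.
    """
    wt, mut = _check_aa(wt), _check_aa(mut)
    if wt == mut:
        raise ValidationError(f"not a mutation: {wt}→{mut}")

    labels = {CategoryLabel.EVERYTHING}
    wt_classes = residue_classes(wt)
    mut_classes = residue_classes(mut)

    for x in POLARITY_CLASSES:
        if x not in wt_classes:
            continue
        for y in POLARITY_CLASSES:
            if y in mut_classes and (x, y) in _POLARITY_PAIR_LABEL:
                labels.add(_POLARITY_PAIR_LABEL[(x, y)])

    same_sign = {wt, mut} in ({"K", "R"}, {"D", "E"})
    if same_sign:
        labels.add(CategoryLabel.LIKE_TO_LIKE_CHARGE)
    if "P" in (wt, mut):
        labels.add(CategoryLabel.INVOLVES_PROLINE)
    if "C" in (wt, mut):
        labels.add(CategoryLabel.INVOLVES_CYSTEINE)

    small, large = RESIDUE_CLASSES["Small"], RESIDUE_CLASSES["Large"]
    if wt in small and mut in large:
        labels.add(CategoryLabel.SMALL_TO_LARGE)
    if wt in large and mut in small:
        labels.add(CategoryLabel.LARGE_TO_SMALL)
    if (wt in small and mut in small) or (wt in large and mut in large):
        labels.add(CategoryLabel.SAME_SIZE)

    if burial is not None:
        if isinstance(burial, str):
            burial = LABEL_BY_STRING.get(burial, burial)
        if burial not in (CategoryLabel.BURIED, CategoryLabel.SURFACE):
            raise ValidationError(f"burial must be Buried or Surface, got {burial!r}")
        labels.add(burial)

    return frozenset(labels)


class StabilityClass(enum.IntEnum):
    """Ordinal stability classes; the ordinal gap scores prediction errors."""

    DESTABILIZING = 0
    NEUTRAL = 1
    STABILIZING = 2


def classify_ddg(ddg: float) -> StabilityClass:
    """Classify a ΔΔG (kcal/mol, positive = destabilizing).

    ΔΔG ≤ −1 is stabilizing, ΔΔG ≥ +1 destabilizing, in between neutral;
    both boundaries are inclusive.
    """
    if not math.isfinite(ddg):
        raise ValidationError(f"ΔΔG must be finite, got {ddg!r}")
    if ddg <= -1.0:
        return StabilityClass.STABILIZING
    if ddg >= 1.0:
        return StabilityClass.DESTABILIZING
    return StabilityClass.NEUTRAL


def classification_error(ddg_exp: float, ddg_pred: float) -> int:
    """Ordinal classification error: 0 correct, 1 moderate, 2 egregious."""
    return abs(int(classify_ddg(ddg_exp)) - int(classify_ddg(ddg_pred)))


def rescale(values: Iterable[float], slope: float = 1.0, intercept: float = 0.0):
    """Linear rescale of predictor output onto the kcal/mol scale.

    Predictor energies (e.g. Rosetta Energy Units) are not guaranteed to be
    on the experimental scale; default is the identity.
    """
    return [slope * v + intercept for v in values]
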