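"""Strand-folded classification of base substitutions and spectrum tallies.

A genome assembly carries no information about which physical strand a
mutation arose on, so a substitution observed as ``T->C`` on the reference
strand is the same mutational event as ``A->G`` on its complement. The twelve
ordered base changes therefore fold two-to-one onto six event classes, named
here by the source base pair of the reference (``A:T`` or ``G:C``) — the
convention used when reporting mutation spectra of mutation-accumulation
experiments.

The six classes::

    A:T->G:C   transition
    A:T->C:G   transversion
    A:T->T:A   transversion
    G:C->A:T   transition
    G:C->T:A   transversion
    G:C->C:G   transversion
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "AmbiguousBaseError",
    "MutationClass",
    "MutationCall",
    "SpectrumCounts",
    "GC_GAINING",
    "AT_GAINING",
    "COMPLEMENT",
    "classify_substitution",
    "count_spectrum",
    "codon_position_fraction",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_VALID_BASES = frozenset(COMPLEMENT)


class AmbiguousBaseError(ValueError):
    """Raised for bases outside {A, C, G, T}, including IUPAC ambiguity codes."""


class MutationClass(enum.Enum):
    """One of the six strand-folded base-substitution classes."""

    AT_TO_GC = "A:T->G:C"
    AT_TO_CG = "A:T->C:G"
    AT_TO_TA = "A:T->T:A"
    GC_TO_AT = "G:C->A:T"
    GC_TO_TA = "G:C->T:A"
    GC_TO_CG = "G:C->C:G"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def label(self) -> str:
        """Human-readable class label, e.g. ``"A:T->G:C"``."""
        return self.value

    @property
    def source_pair(self) -> str:
        """``"AT"`` or ``"GC"``: the base pair the mutation starts from.

        Rates for a class are normalised by the number of callable sites
        whose reference base belongs to this pair.
        """
        return "AT" if self.name.startswith("AT") else "GC"

    @property
    def is_transition(self) -> bool:
        """True for purine<->purine / pyrimidine<->pyrimidine changes."""
        return self in (MutationClass.AT_TO_GC, MutationClass.GC_TO_AT)

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown mutation class label: {label!r}")


#: Classes gaining a G:C pair — the numerator of the G/C-direction rate u.
GC_GAINING = (MutationClass.AT_TO_GC, MutationClass.AT_TO_CG)
#: Classes gaining an A:T pair — the numerator of the A/T-direction rate v.
AT_GAINING = (MutationClass.GC_TO_AT, MutationClass.GC_TO_TA)


def classify_substitution(ref: str, alt: str) -> MutationClass:
    """Fold a single-base substitution onto its event class.

    Pyrimidine reference bases are complemented onto the A/G strand, so
    ``classify_substitution("T", "C")`` and ``classify_substitution("A", "G")``
    both return :attr:`MutationClass.AT_TO_GC`. Transition/transversion status
    is available from the returned class (:attr:`MutationClass.is_transition`).

    Raises
    ------
    AmbiguousBaseError
        If either base is not one of A, C, G, T.
    ValueError
        If ``ref == alt``.
    """
    ref = ref.upper()
    alt = alt.upper()
    for base in (ref, alt):
        if base not in _VALID_BASES:
            raise AmbiguousBaseError(
                f"base {base!r} is not one of A/C/G/T (ambiguity codes are rejected)"
            )
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a substitution")
    if ref in "TC":  # fold onto the complementary strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    if ref == "A":
        return {
            "G": MutationClass.AT_TO_GC,
            "C": MutationClass.AT_TO_CG,
            "T": MutationClass.AT_TO_TA,
        }[alt]
    return {
        "A": MutationClass.GC_TO_AT,
        "T": MutationClass.GC_TO_TA,
        "C": MutationClass.GC_TO_CG,
    }[alt]


@dataclass(frozen=True)
class MutationCall:
    """One homozygous base substitution detected in one MA line.

    Positions are 1-based, matching VCF. ``coding`` and ``codon_position``
    are optional annotations filled from a GFF3 (see :mod:`mamut.io`).
    """

    line_id: str
    scaffold: str
    position: int
    ref_base: str
    alt_base: str
    coding: Optional[bool] = None
    codon_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
            raise AmbiguousBaseError(
                f"{self.ref_base!r}->{self.alt_base!r}: bases must be A/C/G/T"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref == alt at {self.scaffold}:{self.position}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based and >= 1, got {self.position}")
        if self.codon_position not in (None, 1, 2, 3):
            raise ValueError(f"codon_position must be 1, 2 or 3, got {self.codon_position}")

    @property
    def mutation_class(self) -> MutationClass:
        return classify_substitution(self.ref_base, self.alt_base)

    def with_annotation(self, coding: bool, codon_position: Optional[int]) -> "MutationCall":
        return replace(self, coding=coding, codon_position=codon_position)


@dataclass(frozen=True)
class SpectrumCounts:
    """Folded six-class mutation counts with transition/transversion totals."""

    counts: Mapping[MutationClass, int]

    def __post_init__(self) -> None:
        full = {cls: int(self.counts.get(cls, 0)) for cls in MutationClass}
        for cls, n in full.items():
            if n < 0:
                raise ValueError(f"negative count for {cls.label}: {n}")
        object.__setattr__(self, "counts", full)

    def __getitem__(self, cls: MutationClass) -> int:
        return self.counts[cls]

    @classmethod
    def zero(cls) -> "SpectrumCounts":
        return cls({})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_transitions(self) -> int:
        return self.counts[MutationClass.AT_TO_GC] + self.counts[MutationClass.GC_TO_AT]

    @property
    def n_transversions(self) -> int:
        return self.total - self.n_transitions

    @property
    def ts_tv_ratio(self) -> Optional[float]:
        """Transition/transversion ratio; ``None`` when no transversions."""
        tv = self.n_transversions
        if tv == 0:
            return None
        return self.n_transitions / tv

    def __add__(self, other: "SpectrumCounts") -> "SpectrumCounts":
        return SpectrumCounts(
            {cls: self.counts[cls] + other.counts[cls] for cls in MutationClass}
        )


def count_spectrum(calls: Iterable[MutationCall]) -> SpectrumCounts:
    """Tally calls into the six folded classes.

    The tally is permutation-invariant and additive over concatenation of
    call lists; every call lands in exactly one class.
    """
    tally = Counter(classify_substitution(c.ref_base, c.alt_base) for c in calls)
    return SpectrumCounts(tally)


def codon_position_fraction(
    calls: Iterable[MutationCall], position: int
) -> Optional[float]:
    """Fraction of coding calls that hit the given codon position (1, 2 or 3).

    Only calls annotated ``coding=True`` with a ``codon_position`` enter the
    denominator. Returns ``None`` (explicitly undefined, not zero) when there
    are no such calls.
    """
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    coding = [
        c for c in calls if c.coding and c.codon_position is not None
    ]
    if not coding:
        return None
    return sum(1 for c in coding if c.codon_position == position) / len(coding)
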