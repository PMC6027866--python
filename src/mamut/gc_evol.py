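"""Genome composition, mutational equilibrium G/C, and selection at
fourfold-degenerate sites.

Under mutation pressure alone, the expected equilibrium G/C content is
p_n = u/(u+v), where u and v are the conditional rates toward G/C and toward
A/T. The observed G/C fraction at fourfold-degenerate third-codon positions,
p4, can be displaced from p_n by selection and/or GC-biased gene conversion;
the population-scaled strength of that force is the log odds-ratio

    S = ln[ (p4/(1-p4)) / (p_n/(1-p_n)) ],

which inverts the selection-mutation equilibrium
p4 = p_n e^S / (p_n e^S + 1 - p_n). Under neutrality the diversity at
fourfold sites satisfies pi_s = 4 Ne mu, giving a back-calculated effective
population size Ne = pi_s / (4 mu).

Fourfold-degenerate codons are found under a configurable translation table;
the default is NCBI table 6 (ciliate nuclear code), in which TAA and TAG
encode glutamine rather than stop — relevant for *Paramecium*.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

from Bio.Data import CodonTable
from scipy import stats

from .rates import ConditionalRates, RateEstimate
from .spectra import SpectrumCounts

__all__ = [
    "GenomeComposition",
    "SelectionEstimate",
    "SpeciesSummary",
    "CorrelationResult",
    "genome_composition",
    "equilibrium_gc",
    "selection_strength",
    "effective_population_size",
    "fourfold_codons",
    "fourfold_degenerate_sites",
    "p4_gc",
    "pearson_r",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class GenomeComposition:
    """Base counts of a genome with the binomial SE of its G/C fraction."""

    base_counts: Dict[str, int]
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        """Number of unambiguous (A/C/G/T) bases counted."""
        return sum(self.base_counts.values())

    @property
    def gc_fraction(self) -> float:
        return (self.base_counts["G"] + self.base_counts["C"]) / self.length

    @property
    def gc_se(self) -> float:
        """Binomial standard error sqrt(p(1-p)/L) of the G/C fraction."""
        p = self.gc_fraction
        return math.sqrt(p * (1.0 - p) / self.length)


def genome_composition(sequences: Union[str, Iterable[str]]) -> GenomeComposition:
    """Count A/C/G/T over one or more sequences.

    Ambiguity codes (N etc.) are excluded from the denominator and their
    count is logged and kept on the result.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = Counter()
    total_len = 0
    for seq in sequences:
        seq = str(seq).upper()
        total_len += len(seq)
        for base in _BASES:
            counts[base] += seq.count(base)
    n_acgt = sum(counts.values())
    n_ambiguous = total_len - n_acgt
    if n_acgt == 0:
        raise ValueError("no unambiguous A/C/G/T bases in input")
    if n_ambiguous:
        logger.info("genome_composition: excluded %d ambiguous bases", n_ambiguous)
    return GenomeComposition(
        base_counts={b: counts[b] for b in _BASES}, n_ambiguous=n_ambiguous
    )


def equilibrium_gc(u: float, v: float) -> float:
    """Equilibrium G/C content under mutation pressure alone: u/(u+v).

    Expressed through the bias m = u/v this is m/(1+m).
    """
    if u < 0 or v < 0:
        raise ValueError("rates must be nonnegative")
    if u + v == 0:
        raise ValueError("u + v must be positive")
    return u / (u + v)


def selection_strength(p4: float, p_n: float) -> float:
    """Population-scaled selection/conversion strength favouring G/C.

    Log odds-ratio displacement of the observed fourfold-site G/C fraction
    from the mutational equilibrium; zero iff p4 == p_n.
    """
    for name, value in (("p4", p4), ("p_n", p_n)):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {value}")
    return math.log((p4 / (1.0 - p4)) / (p_n / (1.0 - p_n)))


def effective_population_size(pi_s: float, mu: float) -> float:
    """Ne = pi_s / (4 mu) from neutral diversity at fourfold sites."""
    if pi_s <= 0 or mu <= 0:
        raise ValueError("pi_s and mu must be positive")
    return pi_s / (4.0 * mu)


@lru_cache(maxsize=None)
def fourfold_codons(code_id: int = 6) -> frozenset:
    """All codons whose third position is fourfold degenerate under a table.

    A codon prefix XY is fourfold when XYA, XYC, XYG, XYT all translate to
    the same amino acid (and none is a stop).
    """
    table = CodonTable.unambiguous_dna_by_id[code_id]
    out = set()
    for first in _BASES:
        for second in _BASES:
            amino_acids = {
                table.forward_table.get(first + second + third)
                for third in _BASES
            }
            if len(amino_acids) == 1 and None not in amino_acids:
                out.update(first + second + third for third in _BASES)
    return frozenset(out)


def fourfold_degenerate_sites(cds: str, code_id: int = 6) -> List[int]:
    """0-based positions of fourfold-degenerate third-codon sites in a CDS.

    The CDS must be in frame (length divisible by 3). Stop codons are
    skipped; an internal stop is logged as a warning since it suggests a
    mis-annotated frame or the wrong translation table. Codons containing
    ambiguity codes are skipped silently from the scan.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(table.stop_codons)
    fourfold = fourfold_codons(code_id)
    n_codons = len(cds) // 3
    sites: List[int] = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in stops:
            if i < n_codons - 1:
                logger.warning(
                    "internal stop codon %s at codon %d (table %d); skipping",
                    codon, i, code_id,
                )
            continue
        if codon in fourfold:
            sites.append(3 * i + 2)
    return sites


def p4_gc(cds_set: Union[str, Iterable[str]], code_id: int = 6) -> float:
    """G/C fraction over all fourfold-degenerate sites of a CDS collection."""
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    n_gc = 0
    n_total = 0
    for cds in cds_set:
        cds = str(cds).upper()
        for pos in fourfold_degenerate_sites(cds, code_id):
            n_total += 1
            if cds[pos] in "GC":
                n_gc += 1
    if n_total == 0:
        raise ValueError("no fourfold-degenerate sites found")
    return n_gc / n_total


class CorrelationResult(NamedTuple):
    r: float
    p_value: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the t-test p-value (n-2 df)."""
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation test")
    import numpy as np

    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    result = stats.pearsonr(x, y)
    return CorrelationResult(r=float(result.statistic), p_value=float(result.pvalue))


@dataclass(frozen=True)
class SelectionEstimate:
    """p4, p_n and the implied selection strength S."""

    p4: float
    p_n: float

    @property
    def S(self) -> float:
        return selection_strength(self.p4, self.p_n)


@dataclass(frozen=True)
class SpeciesSummary:
    """One species' row of the composition/mutation-parameter table.

    p_n is derived from the summary's own u and v so it can never drift out
    of sync with the conditional rates it is printed beside.
    """

    species: str
    composition: GenomeComposition
    conditional: ConditionalRates
    mu: RateEstimate
    spectrum: SpectrumCounts
    selection: Optional[SelectionEstimate] = None
    pi_s: Optional[float] = None

    @property
    def p_n(self) -> Optional[float]:
        if self.conditional.u + self.conditional.v == 0:
            return None
        return equilibrium_gc(self.conditional.u, self.conditional.v)

    @property
    def ne(self) -> Optional[float]:
        if self.pi_s is None or self.mu.rate <= 0:
            return None
        return effective_population_size(self.pi_s, self.mu.rate)
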