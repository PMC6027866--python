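"""Synthetic mutation-accumulation experiment generator.

Emulates the post-variant-calling data of a germline MA study on a ciliate:
a low-G/C reference genome, a set of lines propagated through single-cell
bottlenecks for a known number of transfers and cell divisions per transfer
cycle, per-line callable masks covering only part of the genome, and
homozygous (post-autogamy) base-substitution calls accumulating as a Poisson
process with a six-class, heavily A/T-biased spectrum.

Defaults reproduce the conditions of a *P. biaurelia*-like experimental arm:
32 analysed lines, 156 transfers at 5.1 cell divisions per culturing cycle
(~800 divisions), 62% of the genome callable, genome G/C 0.25, and a total
rate of 2.44e-11 per site per division split over the six folded classes
with transition/transversion ratio ~1.9 and G/C-direction bias m ~ 0.05.

Approximations, by design: mutations are placed without replacement within a
line (no site is hit twice — at these rates a double hit has probability
~1e-8 per line), exposure enters only as the product transfers x
divisions/cycle, and all calls are emitted homozygous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .rates import LineMeta
from .spectra import MutationCall, MutationClass

__all__ = [
    "SimConfig",
    "TruthSet",
    "default_class_rates",
    "simulate_genome",
    "simulate_ma_experiment",
    "write_truth_set",
]

SCAFFOLD_NAME = "scaffold_1"

#: ref base -> alt base for each folded class, on both strands.
_ALT_FOR_CLASS: Dict[MutationClass, Dict[str, str]] = {
    MutationClass.AT_TO_GC: {"A": "G", "T": "C"},
    MutationClass.AT_TO_CG: {"A": "C", "T": "G"},
    MutationClass.AT_TO_TA: {"A": "T", "T": "A"},
    MutationClass.GC_TO_AT: {"G": "A", "C": "T"},
    MutationClass.GC_TO_TA: {"G": "T", "C": "A"},
    MutationClass.GC_TO_CG: {"G": "C", "C": "G"},
}

#: Relative class weights of the default spectrum (A/T-biased, ts/tv ~ 1.9).
_DEFAULT_CLASS_WEIGHTS: Dict[MutationClass, int] = {
    MutationClass.AT_TO_GC: 2,
    MutationClass.AT_TO_CG: 1,
    MutationClass.AT_TO_TA: 2,
    MutationClass.GC_TO_AT: 17,
    MutationClass.GC_TO_TA: 5,
    MutationClass.GC_TO_CG: 2,
}


def default_class_rates(
    total_rate: float = 2.44e-11, gc_content: float = 0.25
) -> Dict[MutationClass, float]:
    """Per-class per-source-site rates summing to ``total_rate`` genome-wide.

    Class c receives weight w_c of the total; because each class's rate is
    normalised by its source-pair site count, the per-site rate is
    total_rate * (w_c / sum w) / source_fraction, with source fractions
    (1 - gc) for A:T classes and gc for G:C classes. With the genome at
    ``gc_content`` the expected genome-wide rate is then exactly
    ``total_rate``.
    """
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be strictly inside (0, 1) to split rates")
    total_weight = sum(_DEFAULT_CLASS_WEIGHTS.values())
    out = {}
    for cls, weight in _DEFAULT_CLASS_WEIGHTS.items():
        source_fraction = (1.0 - gc_content) if cls.source_pair == "AT" else gc_content
        out[cls] = total_rate * (weight / total_weight) / source_fraction
    return out


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic MA experiment (one species arm)."""

    genome_length: int = 5_000_000
    gc_content: float = 0.25
    n_lines: int = 32
    transfers_per_line: int = 156
    divisions_per_cycle: float = 5.1
    class_rates: Mapping[MutationClass, float] = field(
        default_factory=default_class_rates
    )
    callable_fraction: float = 0.62
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_lines < 0:
            raise ValueError("n_lines must be nonnegative")
        if not 0.0 < self.callable_fraction <= 1.0:
            raise ValueError("callable_fraction must lie in (0, 1]")
        if self.transfers_per_line * self.divisions_per_cycle <= 0:
            raise ValueError("total divisions per line must be positive")
        rates = {cls: float(self.class_rates.get(cls, 0.0)) for cls in MutationClass}
        for cls, rate in rates.items():
            if rate < 0:
                raise ValueError(f"negative rate for {cls.label}")
        object.__setattr__(self, "class_rates", rates)

    @property
    def total_divisions(self) -> float:
        return self.transfers_per_line * self.divisions_per_cycle

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_rates"] = {cls.label: r for cls, r in self.class_rates.items()}
        return d


@dataclass
class TruthSet:
    """A complete synthetic experiment with its generating truth.

    ``masks`` are boolean callable masks over the genome, one per line (a
    single shared array when every site is callable). ``manifest`` records
    the generating config and the realized per-class counts.
    """

    reference: Dict[str, str]
    lines: List[LineMeta]
    mutations: Dict[str, List[MutationCall]]
    masks: Dict[str, np.ndarray]
    manifest: dict


def _as_seed(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_genome(length: int, gc_content: float, seed) -> str:
    """I.i.d. genome with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    rng = np.random.default_rng(_as_seed(seed))
    # order ACGT; inverse-CDF sampling is much faster than rng.choice here
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    edges = np.cumsum(probs)
    idx = np.searchsorted(edges, rng.random(length), side="right")
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def _sample_without_replacement(
    rng: np.random.Generator, pool_size: int, k: int
) -> np.ndarray:
    """k distinct uniform indices in [0, pool_size).

    Rejection sampling when k is tiny relative to the pool (the MA regime);
    a partial permutation otherwise.
    """
    if k > pool_size:
        raise ValueError(f"cannot draw {k} distinct sites from a pool of {pool_size}")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if 20 * k * k < pool_size:
        chosen: set = set()
        while len(chosen) < k:
            chosen.update(rng.integers(0, pool_size, size=k - len(chosen)).tolist())
        return np.fromiter(chosen, dtype=np.int64, count=k)
    return rng.permutation(pool_size)[:k].astype(np.int64)


def simulate_ma_experiment(config: SimConfig) -> TruthSet:
    """Run the generative model: genome, masks, Poisson mutation counts.

    Per line, the count of class c is Poisson with mean
    rate_c x (callable source-pair sites) x total divisions; positions are
    uniform over eligible callable sites, never repeated within a line, and
    every call is homozygous. Line substreams are derived from the root seed
    by spawn key, so adding lines leaves earlier lines' draws unchanged.
    """
    genome = simulate_genome(
        config.genome_length,
        config.gc_content,
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(0,)),
    )
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    is_at = (g == ord("A")) | (g == ord("T"))
    length = config.genome_length
    divisions = config.total_divisions
    full_mask = config.callable_fraction == 1.0
    if full_mask:
        shared_mask = np.ones(length, dtype=bool)
        at_pool_all = np.flatnonzero(is_at)
        gc_pool_all = np.flatnonzero(~is_at)

    at_classes = [c for c in MutationClass if c.source_pair == "AT"]
    gc_classes = [c for c in MutationClass if c.source_pair == "GC"]

    lines: List[LineMeta] = []
    mutations: Dict[str, List[MutationCall]] = {}
    masks: Dict[str, np.ndarray] = {}
    realized: Dict[str, Dict[str, int]] = {}

    for i in range(config.n_lines):
        line_id = f"line_{i + 1:03d}"
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(1, i))
        )
        if full_mask:
            mask = shared_mask
            at_pool, gc_pool = at_pool_all, gc_pool_all
        else:
            k = int(round(config.callable_fraction * length))
            if k == 0:
                raise ValueError(f"{line_id}: callable mask is empty")
            chosen = _sample_without_replacement(rng, length, k)
            mask = np.zeros(length, dtype=bool)
            mask[chosen] = True
            at_pool = np.flatnonzero(is_at & mask)
            gc_pool = np.flatnonzero(~is_at & mask)

        pool_for = {"AT": at_pool, "GC": gc_pool}
        counts = {
            cls: int(
                rng.poisson(
                    config.class_rates[cls] * len(pool_for[cls.source_pair]) * divisions
                )
            )
            for cls in MutationClass
        }
        calls: List[MutationCall] = []
        for pool, classes in ((at_pool, at_classes), (gc_pool, gc_classes)):
            k_total = sum(counts[c] for c in classes)
            if k_total == 0:
                continue
            if len(pool) == 0:
                raise ValueError(
                    f"{line_id}: positive mutation count but empty callable "
                    f"{classes[0].source_pair} pool"
                )
            idx = np.sort(_sample_without_replacement(rng, len(pool), k_total))
            positions = pool[idx]
            rng.shuffle(positions)
            offset = 0
            for cls in classes:
                for pos0 in positions[offset : offset + counts[cls]]:
                    ref = chr(g[pos0])
                    calls.append(
                        MutationCall(
                            line_id=line_id,
                            scaffold=SCAFFOLD_NAME,
                            position=int(pos0) + 1,
                            ref_base=ref,
                            alt_base=_ALT_FOR_CLASS[cls][ref],
                        )
                    )
                offset += counts[cls]
        calls.sort(key=lambda c: c.position)
        lines.append(
            LineMeta(
                line_id=line_id,
                n_transfers=config.transfers_per_line,
                divisions_per_cycle=config.divisions_per_cycle,
                callable_sites_AT=int(len(at_pool)),
                callable_sites_GC=int(len(gc_pool)),
            )
        )
        mutations[line_id] = calls
        masks[line_id] = mask
        realized[line_id] = {cls.label: counts[cls] for cls in MutationClass}

    totals = {
        cls.label: sum(per_line[cls.label] for per_line in realized.values())
        for cls in MutationClass
    }
    manifest = {
        "config": config.to_dict(),
        "scaffold": SCAFFOLD_NAME,
        "realized_counts": realized,
        "total_counts": totals,
        "n_mutations": sum(totals.values()),
    }
    return TruthSet(
        reference={SCAFFOLD_NAME: genome},
        lines=lines,
        mutations=mutations,
        masks=masks,
        manifest=manifest,
    )


def write_truth_set(
    truth: TruthSet, out_dir, overwrite: bool = False
) -> Dict[str, Path]:
    """Serialize a TruthSet: FASTA, per-line VCF + BED, metadata TSV, manifest.

    Refuses to clobber a directory already holding a truth manifest unless
    ``overwrite`` is set. Returns the paths written, keyed by role.
    """
    from . import io as mio  # deferred: io imports pysam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "truth.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )

    paths: Dict[str, Path] = {}
    fasta_path = out / "reference.fasta"
    mio.write_fasta(truth.reference, fasta_path)
    paths["reference"] = fasta_path

    meta_path = out / "lines.tsv"
    mio.write_line_metadata(truth.lines, meta_path)
    paths["metadata"] = meta_path

    contig_lengths = {name: len(seq) for name, seq in truth.reference.items()}
    for line in truth.lines:
        vcf_path = out / f"{line.line_id}.vcf"
        mio.write_vcf(truth.mutations[line.line_id], contig_lengths, line.line_id, vcf_path)
        paths[f"vcf:{line.line_id}"] = vcf_path
        bed_path = out / f"{line.line_id}.callable.bed"
        mio.write_bed_mask(truth.masks[line.line_id], SCAFFOLD_NAME, bed_path)
        paths[f"bed:{line.line_id}"] = bed_path

    manifest_path.write_text(json.dumps(truth.manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
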