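"""End-to-end orchestration: ingest -> validate -> classify -> estimate -> report.

The pipeline consumes post-variant-calling data (per-line VCFs, a line
metadata TSV, the reference FASTA and optionally a GFF3 annotation), applies
the filtering an MA analysis requires — reference-consistency checks,
homozygosity of post-autogamy genotypes, per-line callable-fraction
thresholds, and removal of calls shared between lines (shared calls indicate
ancestral variants or cross-line contamination rather than independent
mutations) — and assembles one summary row per species: G/C composition with
binomial SE, conditional rates u and v with bias m, equilibrium G/C p_n,
fourfold-site G/C p4 with selection strength S when an annotation is given,
the pooled rate mu with its exact Poisson CI, and Ne when a diversity pi_s
is supplied. With two or more species configured it also writes an exact
pairwise rate-comparison table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pysam

from . import io as mio
from .gc_evol import (
    GenomeComposition,
    SelectionEstimate,
    SpeciesSummary,
    genome_composition,
    p4_gc,
)
from .rates import (
    LineMeta,
    RateEstimate,
    compare_rates,
    conditional_rates,
    estimate_rate,
    exposure,
    per_class_rates,
)
from .spectra import MutationCall, MutationClass, SpectrumCounts, count_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesInput",
    "PipelineConfig",
    "PipelineError",
    "ValidationIssue",
    "ValidationReport",
    "validate_inputs",
    "summarize_species",
    "run_pipeline",
    "PipelineResult",
]

# machine-readable reason codes for exclusions / flags
REF_MISMATCH = "REF_MISMATCH"
HET_GENOTYPE = "HET_GENOTYPE"
LOW_CALLABLE = "LOW_CALLABLE"
MISSING_METADATA = "MISSING_METADATA"
SHARED_CALL = "SHARED_CALL"

_HARD_CODES = {REF_MISMATCH}


class PipelineError(RuntimeError):
    """A validation failure that makes the analysis unsafe to run."""


@dataclass(frozen=True)
class SpeciesInput:
    """Input files and per-species constants for one species arm."""

    label: str
    vcf_paths: Tuple[Path, ...]
    metadata_path: Path
    fasta_path: Path
    gff_path: Optional[Path] = None
    pi_s: Optional[float] = None


@dataclass(frozen=True)
class PipelineConfig:
    species: Tuple[SpeciesInput, ...]
    out_dir: Path
    confidence: float = 0.95
    code_table: int = 6
    min_callable_fraction: float = 0.0
    exclude_shared: bool = True
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class ValidationIssue:
    species: str
    line_id: str
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)
    #: per species: line_ids excluded from analysis, with reason code
    excluded_lines: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)
    #: per species and line: record keys excluded (het, shared)
    excluded_records: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    def add(self, issue: ValidationIssue) -> None:
        self.issues.append(issue)
        logger.warning("[%s] %s %s: %s", issue.species, issue.code, issue.line_id, issue.message)

    @property
    def hard_errors(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.code in _HARD_CODES]

    @property
    def ok(self) -> bool:
        return not self.hard_errors


def _line_id_for_vcf(path: Path) -> str:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
    return samples[0] if samples else path.stem


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check VCF/FASTA consistency, genotypes, and metadata completeness.

    Always returns a report; nothing is raised here. Reference-base
    mismatches are hard errors (``report.ok`` is False); heterozygous
    genotypes and below-threshold callable fractions are logged exclusions.
    """
    report = ValidationReport()
    for species in config.species:
        reference = mio.read_fasta(species.fasta_path)
        genome_length = sum(len(s) for s in reference.values())
        meta = {m.line_id: m for m in mio.read_line_metadata(species.metadata_path)}
        excluded: List[Tuple[str, str]] = []
        for vcf_path in species.vcf_paths:
            line_id = _line_id_for_vcf(Path(vcf_path))
            line_meta = meta.get(line_id)
            if line_meta is None:
                report.add(
                    ValidationIssue(
                        species.label, line_id, MISSING_METADATA,
                        f"no metadata row for VCF {vcf_path}",
                    )
                )
                excluded.append((line_id, MISSING_METADATA))
                continue
            callable_fraction = line_meta.callable_sites / genome_length
            if callable_fraction < config.min_callable_fraction:
                report.add(
                    ValidationIssue(
                        species.label, line_id, LOW_CALLABLE,
                        f"callable fraction {callable_fraction:.3f} below "
                        f"threshold {config.min_callable_fraction:.3f}",
                    )
                )
                excluded.append((line_id, LOW_CALLABLE))
                continue
            with pysam.VariantFile(str(vcf_path)) as vcf:
                for record in vcf:
                    key = f"{record.chrom}:{record.pos}"
                    contig = reference.get(record.chrom)
                    if contig is None or not (
                        1 <= record.pos <= len(contig)
                        and contig[record.pos - 1] == record.ref.upper()
                    ):
                        report.add(
                            ValidationIssue(
                                species.label, line_id, REF_MISMATCH,
                                f"record {key} REF={record.ref} disagrees with FASTA",
                            )
                        )
                        continue
                    for sample in record.samples.values():
                        gt = sample.get("GT")
                        if gt is None or len(set(gt)) != 1 or gt[0] is None:
                            report.add(
                                ValidationIssue(
                                    species.label, line_id, HET_GENOTYPE,
                                    f"record {key} genotype {gt} is not homozygous "
                                    "(post-autogamy calls must be)",
                                )
                            )
                            report.excluded_records.setdefault(species.label, []).append(
                                (line_id, key)
                            )
        if excluded:
            report.excluded_lines[species.label] = excluded
            logger.warning(
                "[%s] excluded %d line(s): %s", species.label, len(excluded), excluded
            )
    return report


def drop_shared_calls(
    calls_by_line: Mapping[str, Sequence[MutationCall]]
) -> Tuple[Dict[str, List[MutationCall]], List[MutationCall]]:
    """Remove calls occurring at the same site with the same alleles in >1 line.

    Within an MA design each line accumulates mutations independently, so a
    variant recurring across lines is an ancestral polymorphism or
    contamination, not an independent mutation.
    """
    from collections import Counter

    seen = Counter(
        (c.scaffold, c.position, c.ref_base, c.alt_base)
        for calls in calls_by_line.values()
        for c in calls
    )
    kept: Dict[str, List[MutationCall]] = {}
    dropped: List[MutationCall] = []
    for line_id, calls in calls_by_line.items():
        kept[line_id] = []
        for call in calls:
            if seen[(call.scaffold, call.position, call.ref_base, call.alt_base)] > 1:
                dropped.append(call)
            else:
                kept[line_id].append(call)
    if dropped:
        logger.warning("%s: dropped %d shared call(s)", SHARED_CALL, len(dropped))
    return kept, dropped


def summarize_species(
    label: str,
    calls_by_line: Mapping[str, Sequence[MutationCall]],
    lines: Sequence[LineMeta],
    composition: GenomeComposition,
    *,
    confidence: float = 0.95,
    pi_s: Optional[float] = None,
    p4: Optional[float] = None,
    exclude_shared: bool = True,
) -> Tuple[SpeciesSummary, Dict[MutationClass, RateEstimate]]:
    """The analysis core: spectrum, rates, bias, equilibrium, selection, Ne.

    This is the single path from calls to a summary row; the file-based
    pipeline and any in-memory caller (e.g. simulation studies) both go
    through it, so the summary's mu is by construction the pooled estimate
    over exactly the surviving calls.
    """
    if exclude_shared:
        calls_by_line, _ = drop_shared_calls(calls_by_line)
    all_calls = [c for calls in calls_by_line.values() for c in calls]
    spectrum = count_spectrum(all_calls)
    mu = estimate_rate(spectrum.total, lines, "all", confidence)
    conditional = conditional_rates(spectrum, lines)
    per_class = per_class_rates(spectrum, lines, confidence)
    selection = None
    if p4 is not None:
        p_n = (
            conditional.u / (conditional.u + conditional.v)
            if conditional.u + conditional.v > 0
            else None
        )
        if p_n is not None and 0.0 < p_n < 1.0 and 0.0 < p4 < 1.0:
            selection = SelectionEstimate(p4=p4, p_n=p_n)
    summary = SpeciesSummary(
        species=label,
        composition=composition,
        conditional=conditional,
        mu=mu,
        spectrum=spectrum,
        selection=selection,
        pi_s=pi_s,
    )
    return summary, per_class


# -- report formatting --------------------------------------------------------

def _fmt_optional(value: Optional[float], pattern: str = "{:.2f}") -> str:
    return "NA" if value is None else pattern.format(value)


def summary_table_rows(summaries: Sequence[SpeciesSummary]) -> List[Dict[str, str]]:
    """Rounded report rows: rates scaled x1e11, two decimals throughout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.species,
                "gc": f"{s.composition.gc_fraction:.2f}",
                "gc_se": f"{s.composition.gc_se:.2e}",
                "m": _fmt_optional(s.conditional.m),
                "p_n": _fmt_optional(s.p_n),
                "p4": _fmt_optional(s.selection.p4 if s.selection else None),
                "S": _fmt_optional(s.selection.S if s.selection else None),
                "mu_x1e11": f"{s.mu.rate * 1e11:.2f}",
                "mu_ci_low_x1e11": f"{s.mu.ci_low * 1e11:.2f}",
                "mu_ci_high_x1e11": f"{s.mu.ci_high * 1e11:.2f}",
                "n_mutations": str(s.spectrum.total),
                "pi_s": _fmt_optional(s.pi_s, "{:.4f}"),
                "Ne": _fmt_optional(s.ne, "{:.3e}"),
            }
        )
    return rows


def _summary_json(summary: SpeciesSummary) -> dict:
    return {
        "species": summary.species,
        "gc_fraction": summary.composition.gc_fraction,
        "gc_se": summary.composition.gc_se,
        "u": summary.conditional.u,
        "v": summary.conditional.v,
        "m": summary.conditional.m,
        "p_n": summary.p_n,
        "p4": summary.selection.p4 if summary.selection else None,
        "S": summary.selection.S if summary.selection else None,
        "mu": summary.mu.rate,
        "mu_ci": list(summary.mu.ci),
        "n_mutations": summary.spectrum.total,
        "spectrum": {cls.label: summary.spectrum[cls] for cls in MutationClass},
        "ts_tv_ratio": summary.spectrum.ts_tv_ratio,
        "pi_s": summary.pi_s,
        "Ne": summary.ne,
    }


@dataclass
class PipelineResult:
    summaries: List[SpeciesSummary]
    per_class: Dict[str, Dict[MutationClass, RateEstimate]]
    report: ValidationReport
    paths: Dict[str, Path]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured species through the full analysis and write reports.

    Deterministic for fixed inputs: identical reruns produce byte-identical
    TSV/JSON outputs. Raises :class:`PipelineError` listing offending records
    on reference-base mismatches.
    """
    report = validate_inputs(config)
    if not report.ok:
        details = "; ".join(
            f"{i.species}/{i.line_id}: {i.message}" for i in report.hard_errors
        )
        raise PipelineError(f"reference mismatches: {details}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    summaries: List[SpeciesSummary] = []
    per_class_all: Dict[str, Dict[MutationClass, RateEstimate]] = {}
    totals: Dict[str, Tuple[int, float]] = {}

    for species in config.species:
        reference = mio.read_fasta(species.fasta_path)
        meta = {m.line_id: m for m in mio.read_line_metadata(species.metadata_path)}
        excluded_ids = {lid for lid, _ in report.excluded_lines.get(species.label, [])}
        het_keys = set(report.excluded_records.get(species.label, []))

        calls_by_line: Dict[str, List[MutationCall]] = {}
        surviving: List[LineMeta] = []
        for vcf_path in species.vcf_paths:
            line_id = _line_id_for_vcf(Path(vcf_path))
            if line_id in excluded_ids:
                continue
            calls = [
                c
                for c in mio.read_vcf_calls(vcf_path, line_id)
                if (line_id, f"{c.scaffold}:{c.position}") not in het_keys
            ]
            if species.gff_path is not None:
                calls = mio.annotate_coding(calls, species.gff_path)
            calls_by_line[line_id] = calls
            surviving.append(meta[line_id])
        if not surviving:
            raise PipelineError(f"{species.label}: no lines survived validation")

        composition = genome_composition(reference.values())
        p4 = None
        if species.gff_path is not None:
            cds = mio.extract_cds_sequences(reference, species.gff_path)
            p4 = p4_gc(cds.values(), config.code_table)
        summary, per_class = summarize_species(
            species.label,
            calls_by_line,
            surviving,
            composition,
            confidence=config.confidence,
            pi_s=species.pi_s,
            p4=p4,
            exclude_shared=config.exclude_shared,
        )
        summaries.append(summary)
        per_class_all[species.label] = per_class
        totals[species.label] = (
            summary.spectrum.total,
            exposure(surviving, "all"),
        )

        spectrum_path = out / f"spectrum_{species.label}.tsv"
        mio.write_spectrum_tsv(summary.spectrum, spectrum_path, per_class)
        paths[f"spectrum:{species.label}"] = spectrum_path

    import pandas as pd

    summary_tsv = out / "summary.tsv"
    pd.DataFrame(summary_table_rows(summaries)).to_csv(summary_tsv, sep="\t", index=False)
    paths["summary_tsv"] = summary_tsv

    summary_json = out / "summary.json"
    summary_json.write_text(
        json.dumps([_summary_json(s) for s in summaries], indent=2, sort_keys=True)
    )
    paths["summary_json"] = summary_json

    if len(config.species) >= 2:
        rows = []
        labels = [s.label for s in config.species]
        n_tests = len(MutationClass)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                (n1, e1), (n2, e2) = totals[a], totals[b]
                if n1 + n2 >= 1:
                    rows.append(
                        {
                            "species_a": a, "species_b": b, "class": "total",
                            "n_a": n1, "n_b": n2,
                            "p_value": compare_rates(n1, e1, n2, e2),
                        }
                    )
                for cls in MutationClass:
                    ra, rb = per_class_all[a][cls], per_class_all[b][cls]
                    if ra.n_mutations + rb.n_mutations < 1:
                        continue
                    p = compare_rates(
                        ra.n_mutations, ra.exposure, rb.n_mutations, rb.exposure
                    )
                    row = {
                        "species_a": a, "species_b": b, "class": cls.label,
                        "n_a": ra.n_mutations, "n_b": rb.n_mutations,
                        "p_value": p,
                    }
                    if config.bonferroni:
                        row["p_bonferroni"] = min(1.0, p * n_tests)
                    rows.append(row)
        comparisons = out / "comparisons.tsv"
        pd.DataFrame(rows).to_csv(comparisons, sep="\t", index=False, float_format="%.6g")
        paths["comparisons"] = comparisons

    return PipelineResult(
        summaries=summaries, per_class=per_class_all, report=report, paths=paths
    )
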