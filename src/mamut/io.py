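"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, VCF v4.2 via pysam (plain text, homozygous ``1/1``
genotypes), callable masks as BED (0-based half-open), line metadata and
spectrum tables as TSV via pandas, and CDS extraction / codon annotation
from GFF3 via gffutils.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rates import LineMeta, RateEstimate
from .spectra import COMPLEMENT, MutationCall, MutationClass, SpectrumCounts

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "line_id",
    "n_transfers",
    "divisions_per_cycle",
    "callable_sites_AT",
    "callable_sites_GC",
]


# -- FASTA --------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    return {
        record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(reference: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- VCF ----------------------------------------------------------------------

def write_vcf(
    calls: Sequence[MutationCall],
    contig_lengths: Mapping[str, int],
    line_id: str,
    path,
) -> None:
    """One homozygous-genotype VCF per MA line."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(line_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.scaffold, c.position)):
            record = out.new_record(
                contig=call.scaffold,
                start=call.position - 1,
                stop=call.position,
                alleles=(call.ref_base, call.alt_base),
            )
            record.samples[line_id]["GT"] = (1, 1)
            record.samples[line_id].phased = False
            out.write(record)


def read_vcf_calls(path, line_id: Optional[str] = None) -> List[MutationCall]:
    """Load SNV records as MutationCalls, splitting multi-allelic sites.

    ``line_id`` defaults to the single sample name in the header, or the
    file stem for sample-less VCFs. Non-SNV alleles are skipped with a log
    message. Genotype validation (homozygosity) is the pipeline's job, not
    the reader's.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if line_id is None:
            line_id = samples[0] if samples else path.stem
        calls: List[MutationCall] = []
        for record in vcf:
            if record.alts is None:
                continue
            for alt in record.alts:
                if len(record.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    logger.info(
                        "skipping non-SNV record %s:%d %s>%s",
                        record.chrom, record.pos, record.ref, alt,
                    )
                    continue
                calls.append(
                    MutationCall(
                        line_id=line_id,
                        scaffold=record.chrom,
                        position=record.pos,
                        ref_base=record.ref.upper(),
                        alt_base=alt.upper(),
                    )
                )
    return calls


# -- BED callable masks -------------------------------------------------------

def mask_to_intervals(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Runs of True in a boolean mask as 0-based half-open intervals."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def write_bed_mask(mask: np.ndarray, scaffold: str, path) -> None:
    with open(path, "w") as handle:
        for start, end in mask_to_intervals(mask):
            handle.write(f"{scaffold}\t{start}\t{end}\n")


def read_bed_mask(path, length: int, scaffold: Optional[str] = None) -> np.ndarray:
    """Boolean mask of the given genome length from a BED file."""
    mask = np.zeros(length, dtype=bool)
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if scaffold is not None and fields[0] != scaffold:
                continue
            mask[int(fields[1]) : int(fields[2])] = True
    return mask


# -- line metadata ------------------------------------------------------------

def write_line_metadata(lines: Sequence[LineMeta], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "line_id": l.line_id,
                "n_transfers": l.n_transfers,
                "divisions_per_cycle": l.divisions_per_cycle,
                "callable_sites_AT": l.callable_sites_AT,
                "callable_sites_GC": l.callable_sites_GC,
            }
            for l in lines
        ],
        columns=METADATA_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_line_metadata(path) -> List[LineMeta]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"metadata TSV is missing columns: {sorted(missing)}")
    return [
        LineMeta(
            line_id=str(row.line_id),
            n_transfers=int(row.n_transfers),
            divisions_per_cycle=float(row.divisions_per_cycle),
            callable_sites_AT=int(row.callable_sites_AT),
            callable_sites_GC=int(row.callable_sites_GC),
        )
        for row in frame.itertuples()
    ]


# -- spectrum tables ----------------------------------------------------------

def write_spectrum_tsv(
    spectrum: SpectrumCounts,
    path,
    per_class: Optional[Mapping[MutationClass, RateEstimate]] = None,
) -> None:
    rows = []
    for cls in MutationClass:
        row = {"class": cls.label, "count": spectrum[cls]}
        if per_class is not None:
            est = per_class[cls]
            row["rate"] = est.rate
            row["ci_low"] = est.ci_low
            row["ci_high"] = est.ci_high
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6e")


def read_spectrum_tsv(path) -> SpectrumCounts:
    frame = pd.read_csv(path, sep="\t")
    return SpectrumCounts(
        {MutationClass.from_label(row["class"]): int(row["count"]) for _, row in frame.iterrows()}
    )


# -- GFF3 / coding annotation -------------------------------------------------

@dataclass(frozen=True)
class CdsSegment:
    """One CDS exon, with its offset into the spliced coding sequence."""

    transcript_id: str
    scaffold: str
    start0: int  # 0-based inclusive
    end0: int  # 0-based exclusive
    strand: str
    cds_offset: int  # spliced-CDS length preceding this segment


def _cds_segments_by_transcript(gff_path) -> Dict[str, List[CdsSegment]]:
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: Dict[str, List] = {}
    for feature in db.features_of_type("CDS"):
        parents = feature.attributes.get("Parent", feature.attributes.get("ID", ["?"]))
        grouped.setdefault(parents[0], []).append(feature)

    out: Dict[str, List[CdsSegment]] = {}
    for transcript_id, features in grouped.items():
        strand = features[0].strand
        features.sort(key=lambda f: f.start, reverse=(strand == "-"))
        offset = 0
        segments = []
        for feature in features:
            start0, end0 = feature.start - 1, feature.end
            segments.append(
                CdsSegment(
                    transcript_id=transcript_id,
                    scaffold=feature.seqid,
                    start0=start0,
                    end0=end0,
                    strand=strand,
                    cds_offset=offset,
                )
            )
            offset += end0 - start0
        out[transcript_id] = segments
    return out


def extract_cds_sequences(reference: Mapping[str, str], gff_path) -> Dict[str, str]:
    """Spliced, strand-oriented CDS sequences keyed by transcript id."""
    out: Dict[str, str] = {}
    for transcript_id, segments in sorted(_cds_segments_by_transcript(gff_path).items()):
        parts = []
        for segment in segments:
            piece = reference[segment.scaffold][segment.start0 : segment.end0]
            if segment.strand == "-":
                piece = "".join(COMPLEMENT.get(b, "N") for b in reversed(piece))
            parts.append(piece)
        out[transcript_id] = "".join(parts)
    return out


def annotate_coding(
    calls: Sequence[MutationCall], gff_path
) -> List[MutationCall]:
    """Fill ``coding``/``codon_position`` on calls from a GFF3 annotation.

    A call inside a CDS gets its codon position from the spliced coding
    coordinate; when CDS features of different transcripts overlap a
    position, the first transcript (sorted by id) wins and the ambiguity is
    logged. Calls outside any CDS are marked noncoding.
    """
    from intervaltree import IntervalTree

    trees: Dict[str, IntervalTree] = {}
    for transcript_id, segments in sorted(_cds_segments_by_transcript(gff_path).items()):
        for segment in segments:
            trees.setdefault(segment.scaffold, IntervalTree()).addi(
                segment.start0, segment.end0, segment
            )

    annotated: List[MutationCall] = []
    for call in calls:
        tree = trees.get(call.scaffold)
        hits = sorted(tree[call.position - 1], key=lambda iv: iv.data.transcript_id) if tree else []
        if not hits:
            annotated.append(call.with_annotation(coding=False, codon_position=None))
            continue
        if len(hits) > 1:
            logger.info(
                "position %s:%d overlaps %d CDS features; using transcript %s",
                call.scaffold, call.position, len(hits), hits[0].data.transcript_id,
            )
        segment = hits[0].data
        pos0 = call.position - 1
        if segment.strand == "-":
            cds_pos = segment.cds_offset + (segment.end0 - 1 - pos0)
        else:
            cds_pos = segment.cds_offset + (pos0 - segment.start0)
        annotated.append(
            call.with_annotation(coding=True, codon_position=cds_pos % 3 + 1)
        )
    return annotated
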