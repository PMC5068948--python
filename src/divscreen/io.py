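"""Readers and writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO; VCF through pysam. The tab-separated variant
table is the package's own plain-text exchange format (columns:
``transcript pos ref alt refA altA refB altB qual``; positions 0-based).
Internal coordinates are 0-based half-open everywhere; VCF input/output
converts at the boundary.
"""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import SPECIES, TranscriptRecord, VariantSite

log = logging.getLogger("divscreen")

VARIANT_TSV_COLUMNS = (
    "transcript", "pos", "ref", "alt", "refA", "altA", "refB", "altB", "qual"
)


class FormatError(ValueError):
    """Malformed input file content."""


def _component_from_header(transcript_id: str, isoform_suffix: str) -> str:
    """Unigene/component id: the header token before the isoform suffix.

    ``"comp1_c0_seq2"`` with suffix ``"_seq"`` maps to ``"comp1_c0"``. A
    transcript id without the suffix is its own component (single-isoform
    convention).
    """
    idx = transcript_id.rfind(isoform_suffix)
    if idx <= 0:
        return transcript_id
    return transcript_id[:idx]


def read_fasta(path: str | Path, isoform_suffix: str = "_seq") -> list[TranscriptRecord]:
    """Read transcripts, preserving input order.

    Sequences are upper-cased and U is mapped to T. Symbols outside
    {A,C,G,T,N} (including ambiguity codes) are rejected.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(
                TranscriptRecord(
                    transcript_id=rec.id,
                    component_id=_component_from_header(rec.id, isoform_suffix),
                    sequence=seq,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[TranscriptRecord] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    seqs = []
    for rec in records:
        if isinstance(rec, TranscriptRecord):
            seqs.append(SeqRecord(Seq(rec.sequence), id=rec.transcript_id, description=""))
        else:
            name, seq = rec
            seqs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seqs, str(path), "fasta")


@dataclass
class VariantReadStats:
    """Bookkeeping for records excluded at parse time."""

    n_kept: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    excluded_keys: list[tuple[str, int]] = field(default_factory=list)


def read_variants(
    path: str | Path,
    species_labels: Sequence[str] = SPECIES,
) -> tuple[list[VariantSite], VariantReadStats]:
    """Read a variant table (``.vcf`` by extension, else TSV).

    VCF input must carry per-sample allelic depths (FORMAT/AD) for two
    samples named by ``species_labels``; 1-based VCF positions are converted
    to the internal 0-based convention. Multiallelic and indel records are
    counted and reported, never silently dropped.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_variants_vcf(path, species_labels)
    return _read_variants_tsv(path, species_labels)


def _read_variants_vcf(path: Path, species_labels: Sequence[str]):
    stats = VariantReadStats()
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for label in species_labels:
            if label not in samples:
                raise KeyError(
                    f"species label {label!r} is not a sample in {path} "
                    f"(samples: {samples})"
                )
        if "AD" not in vcf.header.formats:
            raise FormatError(f"{path}: FORMAT/AD (allelic depth) is required")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                stats.n_multiallelic += 1
                stats.excluded_keys.append((rec.chrom, rec.pos - 1))
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1:
                stats.n_indel += 1
                stats.excluded_keys.append((rec.chrom, rec.pos - 1))
                continue
            counts: dict[str, tuple[int, int]] = {}
            for vcf_label, canonical in zip(species_labels, SPECIES):
                ad = rec.samples[vcf_label].get("AD")
                if ad is None:
                    raise FormatError(
                        f"{path}: missing AD for sample {vcf_label!r} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                counts[canonical] = (int(ad[0]), int(ad[1]))
            sites.append(
                VariantSite(
                    transcript_id=rec.chrom,
                    position=rec.pos - 1,
                    ref_allele=rec.ref,
                    alt_allele=alts[0],
                    counts_by_species=counts,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                )
            )
            stats.n_kept += 1
    return sites, stats


def _read_variants_tsv(path: Path, species_labels: Sequence[str]):
    stats = VariantReadStats()
    sites: list[VariantSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != VARIANT_TSV_COLUMNS:
            raise FormatError(
                f"{path}: expected columns {VARIANT_TSV_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(VARIANT_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong field count")
            tid, pos, ref, alt, ra, aa, rb, ab, qual = parts
            if len(ref) != 1 or len(alt) != 1:
                stats.n_indel += 1
                stats.excluded_keys.append((tid, int(pos)))
                continue
            sites.append(
                VariantSite(
                    transcript_id=tid,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    counts_by_species={
                        "A": (int(ra), int(aa)),
                        "B": (int(rb), int(ab)),
                    },
                    quality=float(qual),
                )
            )
            stats.n_kept += 1
    return sites, stats


def write_variants_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    """TSV writer; a write/read round trip reproduces all fields exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_COLUMNS) + "\n")
        for s in sites:
            ra, aa = s.counts_by_species["A"]
            rb, ab = s.counts_by_species["B"]
            qual = f"{s.quality:g}"
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t{ra}\t{aa}\t{rb}\t{ab}\t{qual}\n"
            )


def write_variants_vcf(
    sites: Iterable[VariantSite],
    transcripts: Iterable[TranscriptRecord],
    path: str | Path,
    species_labels: Sequence[str] = SPECIES,
) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for t in transcripts:
        header.contigs.add(t.transcript_id, length=len(t.sequence))
    for label in species_labels:
        header.add_sample(label)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in sites:
            rec = vcf.new_record(
                contig=s.transcript_id,
                start=s.position,
                stop=s.position + 1,
                alleles=(s.ref_allele, s.alt_allele),
                qual=s.quality,
            )
            for vcf_label, canonical in zip(species_labels, SPECIES):
                rec.samples[vcf_label]["AD"] = s.counts_by_species[canonical]
            vcf.write(rec)


def write_report(records: list[dict], path: str | Path, format: str = "tsv") -> None:
    """Write candidate/summary records deterministically.

    Rows are ordered by D-bar descending, then unigene id; re-running on
    identical input yields byte-identical output.
    """
    import json

    if format not in ("tsv", "json"):
        raise ValueError(f"unsupported report format {format!r}")
    ordered = sorted(
        records, key=lambda r: (-float(r.get("dbar", 0.0)), str(r.get("unigene", "")))
    )
    if format == "json":
        with open(path, "w") as fh:
            json.dump(ordered, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    columns: list[str] = []
    for rec in ordered:
        for k in rec:
            if k not in columns:
                columns.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in ordered:
            fh.write("\t".join(_fmt(rec.get(c, "")) for c in columns) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple, set)):
        return ",".join(str(x) for x in sorted(v, key=str))
    return str(v)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
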