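"""End-to-end orchestration of the candidate-gene screen.

Stage order follows the study design: isoform reduction, SNP filtering
and sharing classification, differentiation indices and divergent-set
selection, then the ortholog Ka/Ks branch screen *on the divergent set
only*, and finally the combined candidate report.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import align as _align
from . import differentiation as diff
from .codon import CdsAnnotation, find_orfs, translate_cds
from .config import PipelineConfig
from .io import read_fasta, read_variants, write_report
from .kaks import CandidateCall, OrthologTriple, kaks_candidate_rule
from .records import TranscriptRecord
from .report import (CandidateRecord, SubstitutionEffect, assemble_candidates,
                     classify_substitution, summarize_run)
from .snp_screen import (SharingPartition, UnigeneCatalog, classify_sharing,
                         dedup_longest_isoform)

log = logging.getLogger("divscreen")


@dataclass
class ScreenResult:
    catalog: UnigeneCatalog
    partition: SharingPartition
    records: list[diff.DifferentiationRecord]
    selection: diff.DivergentSelection
    nei_all: diff.GeneticDistanceResult | None
    nei_selected: diff.GeneticDistanceResult | None
    shapiro: tuple[float, float] | None
    kaks_calls: dict[str, CandidateCall] = field(default_factory=dict)
    triples: dict[str, OrthologTriple] = field(default_factory=dict)
    candidates: list[CandidateRecord] = field(default_factory=list)
    exclusions: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def screen_variants(
    transcripts: list[TranscriptRecord],
    sites,
    config: PipelineConfig,
) -> ScreenResult:
    """Stages 1-3: unigene reduction, SNP classification, D/D-bar."""
    t0 = time.perf_counter()
    catalog = dedup_longest_isoform(transcripts)
    on_unigenes = [
        s for s in sites
        if catalog.unigene_for_transcript(s.transcript_id) is not None
    ]
    partition = classify_sharing(on_unigenes, config)
    snp_ds = [d for d in map(diff.compute_d, partition.d_callable()) if d is not None]
    records = diff.compute_dbar(snp_ds, catalog)
    selection = diff.select_divergent(records, config)
    all_snps = [s for r in records for s in r.snps]
    nei_all = diff.nei_identity_distance(all_snps) if all_snps else None
    sel_snps = [s for r in selection.unigenes for s in r.snps]
    nei_sel = diff.nei_identity_distance(sel_snps) if sel_snps else None
    dbars = [r.dbar for r in records]
    shapiro = None
    if len(dbars) >= 3 and len(set(dbars)) > 1:
        shapiro = diff.normality_test(dbars)
    log.info(
        "screen: %d transcripts -> %d unigenes; %d sites -> %d callable, "
        "%d divergent unigenes (%.2fs)",
        len(transcripts), len(catalog.chosen), len(sites), len(snp_ds),
        len(selection.unigenes), time.perf_counter() - t0,
    )
    return ScreenResult(
        catalog=catalog, partition=partition, records=records,
        selection=selection, nei_all=nei_all, nei_selected=nei_sel,
        shapiro=shapiro,
    )


def _primary_orf(seq: str, config: PipelineConfig) -> CdsAnnotation | None:
    orfs = find_orfs(
        "t", seq, min_residues=config.min_orf_residues,
        inclusive=config.orf_min_inclusive,
    )
    return orfs[0] if orfs else None


def _protein_and_cds(seq: str, config: PipelineConfig):
    ann = _primary_orf(seq, config)
    if ann is None:
        return None
    cds = ann.extract_cds(seq)
    prot = translate_cds(cds)
    if "X" in prot:
        return None
    return prot, cds, ann


def kaks_screen(
    result: ScreenResult,
    species_a: dict[str, str],
    species_b: dict[str, str],
    outgroup_cds: dict[str, str],
    config: PipelineConfig,
) -> None:
    """Stage 4: ortholog triples and the Ka/Ks branch rule for the
    divergent unigene set.

    ``species_a``/``species_b`` map unigene transcript id -> transcript
    sequence; ``outgroup_cds`` maps outgroup gene id -> CDS. Orthology to
    the outgroup is called by reciprocal best hit on the ingroup-A
    proteins; the three pairwise Ka/Ks values per gene come from a
    codon-aware alignment merged on the ingroup-A sequence.
    """
    t0 = time.perf_counter()
    aligner = _align.make_aligner()
    prot_a: dict[str, tuple[str, str, CdsAnnotation]] = {}
    prot_b: dict[str, tuple[str, str, CdsAnnotation]] = {}
    for rec in result.selection.unigenes:
        uid = rec.unigene_id
        if uid in species_a and uid in species_b:
            pa = _protein_and_cds(species_a[uid], config)
            pb = _protein_and_cds(species_b[uid], config)
            if pa and pb:
                prot_a[uid] = pa
                prot_b[uid] = pb
    out_prot: dict[str, tuple[str, str]] = {}
    for gid, cds in outgroup_cds.items():
        if len(cds) % 3:
            continue
        prot = translate_cds(cds)
        if prot.endswith("*"):
            prot, cds = prot[:-1], cds[:-3]
        if "*" in prot or "X" in prot or not prot:
            continue
        out_prot[gid] = (prot, cds)
    pairs = _align.reciprocal_best_hits(
        {u: p for u, (p, _, _) in prot_a.items()},
        {g: p for g, (p, _) in out_prot.items()},
        aligner=aligner,
    )
    for uid, gid, _score in pairs:
        pa, cds_a, _ = prot_a[uid]
        pb, cds_b, _ = prot_b[uid]
        po, cds_o = out_prot[gid]
        aln_ab = _align.align_proteins(pa, pb, aligner)
        aln_ao = _align.align_proteins(pa, po, aligner)
        m_a, m_b, m_o = _align.merge_pairwise_on_anchor(
            aln_ab.aligned_a, aln_ab.aligned_b, aln_ao.aligned_a, aln_ao.aligned_b
        )
        triple = OrthologTriple(
            gene_id=uid,
            cds_a=_align.back_translate(m_a, cds_a),
            cds_b=_align.back_translate(m_b, cds_b),
            cds_out=_align.back_translate(m_o, cds_o),
        ).compute()
        result.triples[uid] = triple
        result.kaks_calls[uid] = kaks_candidate_rule(triple, config)
    log.info(
        "kaks: %d/%d divergent unigenes with CDS in both species, "
        "%d ortholog triples (%.2fs)",
        len(prot_a), len(result.selection.unigenes), len(pairs),
        time.perf_counter() - t0,
    )


def effects_for_selected(
    result: ScreenResult, config: PipelineConfig
) -> dict[str, list[SubstitutionEffect]]:
    """NC/S/NS classification of each selected unigene's high-D SNPs
    against the primary coding annotation on the reference transcript."""
    effects: dict[str, list[SubstitutionEffect]] = {}
    for rec in result.selection.unigenes:
        seq = result.catalog.sequences.get(rec.unigene_id)
        if seq is None:
            continue
        ann = _primary_orf(seq, config)
        per_snp = []
        for snp in rec.snps:
            if snp.d < config.d_threshold:
                continue
            if ann is None:
                per_snp.append(SubstitutionEffect("NC"))
                continue
            site = _site_alleles(result, snp)
            if site is None:
                continue
            per_snp.append(
                classify_substitution(snp.position, site[0], site[1], ann, seq)
            )
        effects[rec.unigene_id] = per_snp
    return effects


def _site_alleles(result: ScreenResult, snp: diff.SnpD):
    for freqs in result.partition.d_callable():
        s = freqs.site
        if s.transcript_id == snp.transcript_id and s.position == snp.position:
            return s.ref_allele, s.alt_allele
    return None


def finalize(result: ScreenResult, config: PipelineConfig) -> None:
    """Stage 5: combined candidate list and machine-readable summary."""
    effects = effects_for_selected(result, config)
    result.candidates, result.exclusions = assemble_candidates(
        result.selection.unigenes, result.kaks_calls, effects, config
    )
    result.summary = summarize_run(
        partition_counts=result.partition.counts(),
        records=result.records,
        selected=result.selection.unigenes,
        selected_snps=result.selection.snps,
        nei_all=_nei_dict(result.nei_all),
        nei_selected=_nei_dict(result.nei_selected),
        shapiro=result.shapiro,
        candidates=result.candidates,
    )


def _nei_dict(res: diff.GeneticDistanceResult | None) -> dict | None:
    if res is None:
        return None
    return {
        "mean_identity": res.mean_identity,
        "distance_of_mean": res.distance_of_mean,
        "mean_of_distances": res.mean_of_distances,
        "n_loci": res.n_loci,
        "n_zero_identity": res.n_zero_identity,
    }


def run_all(
    reference_fasta: str | Path,
    variants_path: str | Path,
    species_a_fasta: str | Path,
    species_b_fasta: str | Path,
    outgroup_fasta: str | Path,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> ScreenResult:
    """File-level entry point chaining every stage; optionally writes the
    report files into ``out_dir``."""
    transcripts = read_fasta(reference_fasta)
    sites, _stats = read_variants(variants_path)
    result = screen_variants(transcripts, sites, config)
    sp_a = {r.transcript_id: r.sequence for r in read_fasta(species_a_fasta)}
    sp_b = {r.transcript_id: r.sequence for r in read_fasta(species_b_fasta)}
    outgroup = {r.transcript_id: r.sequence for r in read_fasta(outgroup_fasta)}
    kaks_screen(result, sp_a, sp_b, outgroup, config)
    finalize(result, config)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: ScreenResult, out_dir: str | Path) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report([c.as_row() for c in result.candidates], out / "candidates.tsv")
    write_report(result.exclusions, out / "exclusions.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    with open(out / "unigene_dbar.tsv", "w") as fh:
        fh.write("unigene\tn_snps\tdbar\tselected\n")
        for rec in result.records:
            sel = rec in result.selection.unigenes
            fh.write(f"{rec.unigene_id}\t{rec.n_snps}\t{rec.dbar:.6g}\t{int(sel)}\n")
    with open(out / "snp_d.tsv", "w") as fh:
        fh.write("transcript\tpos\tf_a\tf_b\td\n")
        for rec in result.records:
            for s in rec.snps:
                fh.write(f"{s.transcript_id}\t{s.position}\t{s.f_a:.6g}"
                         f"\t{s.f_b:.6g}\t{s.d:.6g}\n")
    with open(out / "dbar_histogram.tsv", "w") as fh:
        fh.write("low\thigh\tcount\n")
        for lo, hi, count in result.selection.histogram:
            fh.write(f"{lo:g}\t{hi:g}\t{count}\n")
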