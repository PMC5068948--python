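"""Candidate assembly: SNP effect classification and the combined screen.

A unigene enters the candidate list through either rule (or both):
``multi_snp`` — it carries at least three SNPs with D at or above the
per-SNP threshold; ``high_kaks`` — its ortholog triple satisfies the
branch rule (elevated ingroup Ka/Ks, quiet outgroup branches). Candidates
are drawn from the D-bar-selected divergent set; genes whose triple is
missing or degenerate land in an exclusions list, preserving the full
evidence trail.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .codon import CdsAnnotation, translate_codon
from .config import PipelineConfig
from .differentiation import DifferentiationRecord, SnpD
from .kaks import CandidateCall


@dataclass
class SubstitutionEffect:
    effect: str  # "NC" | "S" | "NS" | "undetermined"
    aa_ref: str | None = None
    aa_alt: str | None = None


def classify_substitution(
    position: int,
    ref_allele: str,
    alt_allele: str,
    cds: CdsAnnotation,
    transcript_seq: str,
) -> SubstitutionEffect:
    """NC / S / NS call for a SNP relative to a coding annotation.

    Positions outside the coding span are noncoding (NC). Inside, the alt
    allele is substituted into its codon (strand-aware) and both codons
    translated; an N in the codon makes the effect undeterminable.
    """
    if not (cds.start <= position < cds.end):
        return SubstitutionEffect("NC")
    if transcript_seq[position] != ref_allele:
        raise ValueError(
            f"reference base at {cds.transcript_id}:{position} is "
            f"{transcript_seq[position]!r}, not {ref_allele!r}"
        )
    if cds.strand == "+":
        offset = position - cds.start
        read_ref, read_alt = ref_allele, alt_allele
        reading = transcript_seq[cds.start : cds.end]
    else:
        offset = cds.end - 1 - position
        read_ref = str(Seq(ref_allele).complement())
        read_alt = str(Seq(alt_allele).complement())
        reading = str(Seq(transcript_seq[cds.start : cds.end]).reverse_complement())
    codon_idx, within = divmod(offset, 3)
    codon = reading[3 * codon_idx : 3 * codon_idx + 3]
    assert codon[within] == read_ref
    mutated = codon[:within] + read_alt + codon[within + 1 :]
    if "N" in codon or "N" in mutated:
        return SubstitutionEffect("undetermined")
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutated)
    return SubstitutionEffect(
        "S" if aa_ref == aa_alt else "NS", aa_ref=aa_ref, aa_alt=aa_alt
    )


@dataclass
class CandidateRecord:
    unigene_id: str
    dbar: float
    n_snps: int
    n_high_d_snps: int
    candidate_reasons: set[str] = field(default_factory=set)
    effects: list[SubstitutionEffect] = field(default_factory=list)
    kaks_call: CandidateCall | None = None

    def as_row(self) -> dict:
        return {
            "unigene": self.unigene_id,
            "dbar": self.dbar,
            "n_snps": self.n_snps,
            "n_high_d_snps": self.n_high_d_snps,
            "reasons": sorted(self.candidate_reasons),
            "effects": [e.effect for e in self.effects],
        }


def assemble_candidates(
    selected: list[DifferentiationRecord],
    kaks_calls: dict[str, CandidateCall],
    effects: dict[str, list[SubstitutionEffect]],
    config: PipelineConfig,
) -> tuple[list[CandidateRecord], list[dict]]:
    """Union of the multi-SNP and Ka/Ks rules over the divergent set.

    Returns (candidates, exclusions); exclusions list the selected
    unigenes whose ortholog triple was unavailable or degenerate.
    """
    candidates: list[CandidateRecord] = []
    exclusions: list[dict] = []
    for rec in selected:
        high_d = [s for s in rec.snps if s.d >= config.d_threshold]
        reasons: set[str] = set()
        if len(high_d) >= config.min_snps_for_multi_snp_rule:
            reasons.add("multi_snp")
        call = kaks_calls.get(rec.unigene_id)
        if call is not None and call.candidate:
            reasons.add("high_kaks")
        if call is None:
            exclusions.append(
                {"unigene": rec.unigene_id, "reason": "no_ortholog_triple"}
            )
        elif call.candidate and not call.clean:
            exclusions.append(
                {"unigene": rec.unigene_id,
                 "reason": "degenerate_kaks:" + ";".join(call.rationale)}
            )
        if reasons:
            candidates.append(
                CandidateRecord(
                    unigene_id=rec.unigene_id,
                    dbar=rec.dbar,
                    n_snps=rec.n_snps,
                    n_high_d_snps=len(high_d),
                    candidate_reasons=reasons,
                    effects=effects.get(rec.unigene_id, []),
                    kaks_call=call,
                )
            )
    candidates.sort(key=lambda c: (-c.dbar, c.unigene_id))
    return candidates, exclusions


def summarize_run(
    partition_counts: dict[str, int],
    records: list[DifferentiationRecord],
    selected: list[DifferentiationRecord],
    selected_snps: list[SnpD],
    nei_all: dict | None,
    nei_selected: dict | None,
    shapiro: tuple[float, float] | None,
    candidates: list[CandidateRecord],
) -> dict:
    """Machine-readable run summary (counts, Nei statistics, candidates)."""
    snp_count_breakdown = {"1": 0, "2": 0, "3+": 0}
    for rec in selected:
        if rec.n_snps == 1:
            snp_count_breakdown["1"] += 1
        elif rec.n_snps == 2:
            snp_count_breakdown["2"] += 1
        else:
            snp_count_breakdown["3+"] += 1
    return {
        "snp_classes": dict(partition_counts),
        "n_unigenes_with_snps": len(records),
        "n_selected_unigenes": len(selected),
        "n_selected_snps": len(selected_snps),
        "n_snps_in_selected_unigenes": sum(r.n_snps for r in selected),
        "selected_unigene_snp_breakdown": snp_count_breakdown,
        "nei_all_snps": nei_all,
        "nei_selected_snps": nei_selected,
        "shapiro_wilk": (
            {"W": shapiro[0], "p": shapiro[1]} if shapiro is not None else None
        ),
        "n_candidates": len(candidates),
        "candidates": [c.as_row() for c in candidates],
    }
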