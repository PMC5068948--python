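"""Isoform reduction, SNP filtering and species-sharing classification.

The gene-level unit is the *unigene*: the longest transcript of each
assembly component, used so that isoform-redundant SNPs are counted once.
Filtering retains a site for a species when its minor allele frequency,
site quality and read depth all meet inclusive thresholds. Sharing
classification partitions callable sites into shared (polymorphic in both
species), species-specific, and uncallable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .config import PipelineConfig
from .records import SPECIES, SpeciesAlleleFrequencies, TranscriptRecord, VariantSite


@dataclass
class UnigeneCatalog:
    """component_id -> chosen (longest) transcript, plus discarded isoforms."""

    chosen: dict[str, str] = field(default_factory=dict)  # component -> transcript_id
    lengths: dict[str, int] = field(default_factory=dict)  # transcript_id -> length
    discarded: set[str] = field(default_factory=set)
    sequences: dict[str, str] = field(default_factory=dict)  # chosen transcripts only
    component_of: dict[str, str] = field(default_factory=dict)  # any transcript -> component

    @property
    def unigene_ids(self) -> set[str]:
        return set(self.chosen.values())

    def unigene_for_transcript(self, transcript_id: str) -> str | None:
        """The unigene representing this transcript, or None if discarded."""
        comp = self.component_of.get(transcript_id)
        if comp is None:
            return None
        chosen = self.chosen[comp]
        return chosen if chosen == transcript_id else None


def dedup_longest_isoform(transcripts: list[TranscriptRecord]) -> UnigeneCatalog:
    """Keep one transcript per component: maximal length, ties broken by
    lexicographically smallest transcript id."""
    catalog = UnigeneCatalog()
    by_component: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_component.setdefault(t.component_id, []).append(t)
        catalog.component_of[t.transcript_id] = t.component_id
        catalog.lengths[t.transcript_id] = len(t)
    for comp, members in by_component.items():
        best = min(members, key=lambda t: (-len(t), t.transcript_id))
        catalog.chosen[comp] = best.transcript_id
        catalog.sequences[best.transcript_id] = best.sequence
        for t in members:
            if t.transcript_id != best.transcript_id:
                catalog.discarded.add(t.transcript_id)
    return catalog


def estimate_frequencies(site: VariantSite) -> SpeciesAlleleFrequencies:
    """Alt-allele frequency per species from raw allele depths.

    Zero depth in a species leaves that frequency undefined (None); such a
    site cannot enter the D computation.
    """
    return SpeciesAlleleFrequencies.from_site(site)


def passes_filters(
    freqs: SpeciesAlleleFrequencies, species: str, config: PipelineConfig
) -> bool:
    """Per-species SNP retention: MAF, quality and depth thresholds, all
    inclusive ('at least' / 'minimum')."""
    maf = freqs.maf(species)
    if maf is None:
        return False
    return (
        maf >= config.maf_min
        and freqs.site.quality >= config.qual_min
        and freqs.depth(species) >= config.depth_min
    )


@dataclass
class FilterTally:
    n_input: int = 0
    n_retained_either: int = 0
    rejected_by_rule: Counter = field(default_factory=Counter)  # per-species rule hits


def filter_snps(
    sites: list[VariantSite], config: PipelineConfig
) -> tuple[list[SpeciesAlleleFrequencies], FilterTally]:
    """Retain sites that pass the per-species filters in at least one
    species; tally every rule violation per species (a site may hit
    several rules)."""
    tally = FilterTally(n_input=len(sites))
    retained: list[SpeciesAlleleFrequencies] = []
    for site in sites:
        freqs = estimate_frequencies(site)
        ok_any = False
        for sp in SPECIES:
            maf = freqs.maf(sp)
            ok = True
            if maf is None:
                tally.rejected_by_rule[f"{sp}:no_depth"] += 1
                ok = False
            else:
                if maf < config.maf_min:
                    tally.rejected_by_rule[f"{sp}:maf"] += 1
                    ok = False
                if freqs.depth(sp) < config.depth_min:
                    tally.rejected_by_rule[f"{sp}:depth"] += 1
                    ok = False
            if site.quality < config.qual_min:
                tally.rejected_by_rule[f"{sp}:qual"] += 1
                ok = False
            ok_any = ok_any or ok
        if ok_any:
            retained.append(freqs)
            tally.n_retained_either += 1
    return retained, tally


@dataclass
class SharingPartition:
    """Exhaustive partition of the input sites.

    ``specific_a`` / ``specific_b``: SNP in one species, adequately covered
    but below the MAF floor in the other. ``common``: SNP in both.
    ``uncallable``: inadequate depth in at least one species prevents the
    specific/common call. ``filtered``: everything else (fails the SNP
    definition everywhere, or fixed sites handled separately).
    ``fixed_callable``: oppositely fixed sites admitted to the D screen.
    """

    specific_a: list[SpeciesAlleleFrequencies] = field(default_factory=list)
    specific_b: list[SpeciesAlleleFrequencies] = field(default_factory=list)
    common: list[SpeciesAlleleFrequencies] = field(default_factory=list)
    uncallable: list[SpeciesAlleleFrequencies] = field(default_factory=list)
    filtered: list[SpeciesAlleleFrequencies] = field(default_factory=list)
    fixed_callable: list[SpeciesAlleleFrequencies] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "specificA": len(self.specific_a),
            "specificB": len(self.specific_b),
            "common": len(self.common),
            "uncallable": len(self.uncallable),
            "filtered": len(self.filtered),
            "fixed_callable": len(self.fixed_callable),
        }

    @property
    def n_total(self) -> int:
        return sum(self.counts().values())

    def d_callable(self) -> list[SpeciesAlleleFrequencies]:
        """Sites admitted to the differentiation-index computation: every
        classified SNP plus oppositely fixed sites."""
        return self.specific_a + self.specific_b + self.common + self.fixed_callable


def _depth_qual_ok(freqs: SpeciesAlleleFrequencies, sp: str, config: PipelineConfig) -> bool:
    return (
        freqs.depth(sp) >= config.depth_min
        and freqs.site.quality >= config.qual_min
    )


def _oppositely_fixed(freqs: SpeciesAlleleFrequencies) -> bool:
    fa, fb = freqs.freq.get("A"), freqs.freq.get("B")
    if fa is None or fb is None:
        return False
    return {fa, fb} == {0.0, 1.0}


def classify_sharing(
    sites: list[VariantSite], config: PipelineConfig
) -> SharingPartition:
    """Partition sites by species sharing.

    A site is a SNP in species *s* when it passes MAF/quality/depth in *s*.
    Specificity to *s* additionally requires evaluable coverage in the other
    species (configurable); sites lacking that coverage are set aside as
    uncallable, never counted as specific. Oppositely fixed differences
    (alt frequency 1 vs 0) fail the per-species MAF rule by construction but
    are admitted to the D screen when both species pass depth/quality
    (``fixed_sites_callable``).
    """
    part = SharingPartition()
    for site in sites:
        freqs = estimate_frequencies(site)
        snp_a = passes_filters(freqs, "A", config)
        snp_b = passes_filters(freqs, "B", config)
        cov_a = _depth_qual_ok(freqs, "A", config)
        cov_b = _depth_qual_ok(freqs, "B", config)
        if snp_a and snp_b:
            part.common.append(freqs)
        elif snp_a:
            if cov_b or not config.require_coverage_for_specificity:
                part.specific_a.append(freqs)
            else:
                part.uncallable.append(freqs)
        elif snp_b:
            if cov_a or not config.require_coverage_for_specificity:
                part.specific_b.append(freqs)
            else:
                part.uncallable.append(freqs)
        elif (
            config.fixed_sites_callable
            and cov_a and cov_b
            and _oppositely_fixed(freqs)
        ):
            part.fixed_callable.append(freqs)
        else:
            part.filtered.append(freqs)
    return part
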