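"""Core record types shared across the pipeline.

All coordinates are 0-based half-open on the transcript. Alt-allele
frequencies are always oriented against the shared reference transcriptome
so that the two species' frequencies are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_NUCLEOTIDES = frozenset("ACGTN")

#: canonical species slots used throughout: "A" = first ingroup species,
#: "B" = second ingroup species (the outgroup never carries variants).
SPECIES = ("A", "B")


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript (isoform) with its unigene grouping."""

    transcript_id: str
    component_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for transcript {self.transcript_id!r}")
        bad = set(self.sequence) - VALID_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r} contains non-ACGTN symbols: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV on a transcript with per-species allele depths.

    ``counts_by_species`` maps a species label to ``(ref_count, alt_count)``.
    ``quality`` is a site-level Phred-scaled quality (one value per site,
    matching a VCF QUAL field).
    """

    transcript_id: str
    position: int  # 0-based on the transcript
    ref_allele: str
    alt_allele: str
    counts_by_species: dict[str, tuple[int, int]]
    quality: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"{self.transcript_id}:{self.position}: ref == alt ({self.ref_allele})"
            )
        for allele, name in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if len(allele) != 1 or allele not in "ACGT":
                raise ValueError(
                    f"{self.transcript_id}:{self.position}: {name} allele {allele!r} "
                    "is not a single A/C/G/T base"
                )
        if self.position < 0:
            raise ValueError("negative position")
        if self.quality < 0:
            raise ValueError("negative quality")
        for sp, (r, a) in self.counts_by_species.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative allele count for species {sp!r}")

    def depth(self, species: str) -> int:
        r, a = self.counts_by_species[species]
        return r + a

    def alt_frequency(self, species: str) -> float | None:
        """Alt-allele frequency; ``None`` when the species has zero depth."""
        r, a = self.counts_by_species[species]
        if r + a == 0:
            return None
        return a / (r + a)

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass
class SpeciesAlleleFrequencies:
    """Per-site alt-allele frequencies and screening quantities per species."""

    site: VariantSite
    freq: dict[str, float | None] = field(default_factory=dict)

    @classmethod
    def from_site(cls, site: VariantSite) -> "SpeciesAlleleFrequencies":
        return cls(site=site, freq={sp: site.alt_frequency(sp) for sp in site.counts_by_species})

    def maf(self, species: str) -> float | None:
        f = self.freq.get(species)
        if f is None:
            return None
        return min(f, 1.0 - f)

    def depth(self, species: str) -> int:
        return self.site.depth(species)
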