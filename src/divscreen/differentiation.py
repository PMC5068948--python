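"""Interspecific differentiation indices and Nei identity/distance.

For a biallelic site with alt-allele frequencies F_A and F_B in the two
species (both oriented against the shared reference), the per-SNP
differentiation index is D = |F_A - F_B|; the per-unigene index D-bar is
the arithmetic mean of D over that unigene's callable SNPs. Unigenes with
D-bar at or above the threshold (default 0.94) form the divergent set.

Nei's (1972) genetic identity at one biallelic locus is the normalised
dot product of the two allele-frequency vectors,

    I_l = (x1*y1 + x2*y2) / sqrt((x1^2 + x2^2) * (y1^2 + y2^2)),

with x = (F_A, 1-F_A) and y = (F_B, 1-F_B). Because printed identity /
distance pairs in the source literature are ambiguous about whether the
log is taken of the mean identity or averaged per locus, both conventions
are reported: distance_of_mean = -ln(mean I_l) and mean_of_distances =
mean over loci of -ln(I_l). Jensen's inequality guarantees
distance_of_mean <= mean_of_distances.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .records import SpeciesAlleleFrequencies
from .snp_screen import UnigeneCatalog


@dataclass
class SnpD:
    transcript_id: str
    position: int
    f_a: float
    f_b: float
    d: float


@dataclass
class DifferentiationRecord:
    unigene_id: str
    n_snps: int
    dbar: float
    snps: list[SnpD] = field(default_factory=list)


def compute_d(freqs: SpeciesAlleleFrequencies) -> SnpD | None:
    """Per-SNP D = |F_A - F_B|; None when either frequency is undefined."""
    fa, fb = freqs.freq.get("A"), freqs.freq.get("B")
    if fa is None or fb is None:
        return None
    return SnpD(
        transcript_id=freqs.site.transcript_id,
        position=freqs.site.position,
        f_a=fa,
        f_b=fb,
        d=abs(fa - fb),
    )


def compute_dbar(
    snp_ds: list[SnpD], catalog: UnigeneCatalog | None = None
) -> list[DifferentiationRecord]:
    """Group SNPs by unigene and average D.

    With a catalog, SNPs are grouped by the unigene representing their
    transcript and SNPs on discarded isoforms are excluded; without one,
    the transcript id is the grouping unit. Unigenes with zero callable
    SNPs are omitted.
    """
    groups: dict[str, list[SnpD]] = {}
    for snp in snp_ds:
        if catalog is not None:
            unigene = catalog.unigene_for_transcript(snp.transcript_id)
            if unigene is None:
                continue  # discarded isoform or unknown transcript
        else:
            unigene = snp.transcript_id
        groups.setdefault(unigene, []).append(snp)
    records = [
        DifferentiationRecord(
            unigene_id=uid,
            n_snps=len(snps),
            dbar=float(np.mean([s.d for s in snps])),
            snps=snps,
        )
        for uid, snps in groups.items()
    ]
    records.sort(key=lambda r: (-r.dbar, r.unigene_id))
    return records


@dataclass
class DivergentSelection:
    unigenes: list[DifferentiationRecord]
    snps: list[SnpD]
    histogram: list[tuple[float, float, int]]  # (low, high, count], right-closed


def dbar_histogram(
    dbar_values: list[float], bin_width: float = 0.05
) -> list[tuple[float, float, int]]:
    """Right-closed bins (low, high] of fixed width over [0, 1]; D-bar = 0
    falls in the first bin."""
    n_bins = int(round(1.0 / bin_width))
    counts = [0] * n_bins
    for v in dbar_values:
        idx = min(n_bins - 1, max(0, math.ceil(v / bin_width) - 1))
        counts[idx] += 1
    return [
        (round(i * bin_width, 10), round((i + 1) * bin_width, 10), counts[i])
        for i in range(n_bins)
    ]


def select_divergent(
    records: list[DifferentiationRecord], config: PipelineConfig
) -> DivergentSelection:
    """Inclusive thresholds on D-bar (unigenes) and D (individual SNPs)."""
    selected_unigenes = [r for r in records if r.dbar >= config.dbar_threshold]
    all_snps = [s for r in records for s in r.snps]
    selected_snps = [s for s in all_snps if s.d >= config.d_threshold]
    return DivergentSelection(
        unigenes=selected_unigenes,
        snps=selected_snps,
        histogram=dbar_histogram([r.dbar for r in records]),
    )


@dataclass
class GeneticDistanceResult:
    mean_identity: float
    distance_of_mean: float | None  # -ln(mean identity); None if mean is 0
    mean_of_distances: float | None  # mean of per-locus -ln(I); None if no usable locus
    n_loci: int
    n_zero_identity: int  # loci with I = 0, excluded from the log-mean


def nei_identity_distance(snps: list[SnpD]) -> GeneticDistanceResult:
    """Mean Nei identity over loci and both distance conventions."""
    if not snps:
        raise ValueError("Nei identity is undefined on an empty SNP set")
    identities = []
    for s in snps:
        x = np.array([s.f_a, 1.0 - s.f_a])
        y = np.array([s.f_b, 1.0 - s.f_b])
        denom = math.sqrt(float(x @ x) * float(y @ y))
        identities.append(float(x @ y) / denom)
    identities = np.asarray(identities)
    mean_i = float(identities.mean())
    nonzero = identities[identities > 0.0]
    n_zero = int((identities == 0.0).sum())
    return GeneticDistanceResult(
        mean_identity=mean_i,
        distance_of_mean=(-math.log(mean_i)) if mean_i > 0 else None,
        mean_of_distances=(
            float(np.mean(-np.log(nonzero))) if nonzero.size else None
        ),
        n_loci=len(snps),
        n_zero_identity=n_zero,
    )


def normality_test(dbar_values: list[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for the D-bar distribution (descriptive only)."""
    if len(dbar_values) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(set(dbar_values)) == 1:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(dbar_values)
    return float(w), float(p)
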