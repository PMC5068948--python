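"""Nei-Gojobori (1986) Ka/Ks estimation on codon alignments.

Synonymous and nonsynonymous *sites* are counted fractionally per codon:
at each codon position the synonymous fraction is the share of the
possible single-nucleotide changes that preserve the amino acid, with
changes creating stop codons excluded from the denominator; site counts
are averaged over the two sequences, so S + N = 3 x (compared codons)
holds exactly. Synonymous and nonsynonymous *differences* between two
codons are averaged with equal weight over all minimal mutational
pathways, excluding pathways that pass through a stop codon (weights
renormalised; when every pathway is blocked, all pathways are used).
Proportions are corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p); p >= 3/4 saturates the correction.

The branch screen for candidate genes: a gene is a clean candidate when
the ingroup pairwise ratio is at or above the cutoff (default 0.5) and
both ingroup-outgroup ratios are below the outgroup cutoff, with no
degenerate flag (Ks = 0 or a saturated correction) on any pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from .codon import GENETIC_CODE, STOP_CODONS
from .config import PipelineConfig

_NUCS = "ACGT"


def _codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """Synonymous fraction of possible changes at each codon position."""
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        n_syn = n_tot = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_tot += 1
            n_syn += GENETIC_CODE[mutant] == aa
        out.append(n_syn / n_tot if n_tot else 0.0)
    return tuple(out)


_SITE_CACHE: dict[str, tuple[float, float, float]] = {}


def codon_syn_sites(codon: str) -> float:
    """Fractional synonymous sites in one codon (0..3)."""
    if codon not in _SITE_CACHE:
        _SITE_CACHE[codon] = _codon_site_fractions(codon)
    return sum(_SITE_CACHE[codon])


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged with equal weight over minimal mutational pathways.

    Pathways through stop codons are excluded and the weights
    renormalised; if every pathway is blocked, all pathways count.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if GENETIC_CODE.get(nxt) == GENETIC_CODE.get(current) and nxt not in STOP_CODONS and current not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_avg = sum(p[0] for p in paths) / len(paths)
    nd_avg = sum(p[1] for p in paths) / len(paths)
    return sd_avg, nd_avg


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None  # None when 0/0; inf when Ks = 0 with Ka > 0
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons_compared: int
    n_codons_skipped: int
    flags: set[str] = field(default_factory=set)

    @property
    def defined(self) -> bool:
        return self.ka is not None and self.ks is not None


def jukes_cantor(p: float) -> float | None:
    """JC69-corrected distance; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka, Ks and their ratio for an aligned codon sequence pair.

    Columns containing gaps, N, or a stop codon in either sequence are
    skipped and counted. The statistic is symmetric in its arguments.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_compared = n_skipped = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if (
            "-" in ca or "-" in cb or "N" in ca or "N" in cb
            or ca in STOP_CODONS or cb in STOP_CODONS
        ):
            n_skipped += 1
            continue
        n_compared += 1
        s_codon = (codon_syn_sites(ca) + codon_syn_sites(cb)) / 2.0
        s_sites += s_codon
        n_sites += 3.0 - s_codon
        d_s, d_n = pathway_differences(ca, cb)
        sd += d_s
        nd += d_n

    flags: set[str] = set()
    if n_compared == 0:
        flags.add("no_compared_codons")
        return KaKsResult(None, None, None, 0.0, 0.0, 0.0, 0.0, 0, n_skipped, flags)

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None or ka is None:
        flags.add("jc_saturated")
    ratio: float | None
    if ka is None or ks is None:
        ratio = None
    elif ks == 0.0 and ka == 0.0:
        ratio = None
    elif ks == 0.0:
        flags.add("ks_zero")
        ratio = math.inf
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio,
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        n_codons_compared=n_compared, n_codons_skipped=n_skipped,
        flags=flags,
    )


@dataclass
class OrthologTriple:
    """Codon-aligned ortholog set: two ingroup species and the outgroup."""

    gene_id: str
    cds_a: str
    cds_b: str
    cds_out: str
    result_ab: KaKsResult | None = None
    result_a_out: KaKsResult | None = None
    result_b_out: KaKsResult | None = None

    def __post_init__(self) -> None:
        if not (len(self.cds_a) == len(self.cds_b) == len(self.cds_out)):
            raise ValueError(f"{self.gene_id}: aligned lengths differ")
        if len(self.cds_a) % 3:
            raise ValueError(f"{self.gene_id}: alignment not codon-sized")

    def compute(self) -> "OrthologTriple":
        self.result_ab = ng86_kaks(self.cds_a, self.cds_b)
        self.result_a_out = ng86_kaks(self.cds_a, self.cds_out)
        self.result_b_out = ng86_kaks(self.cds_b, self.cds_out)
        return self


@dataclass
class CandidateCall:
    gene_id: str
    candidate: bool
    clean: bool
    rationale: list[str]


def kaks_candidate_rule(triple: OrthologTriple, config: PipelineConfig) -> CandidateCall:
    """Branch rule: elevated ingroup ratio with a quiet outgroup branch.

    A gene is a candidate iff ratio(A,B) >= ``kaks_candidate_min`` and both
    ratios against the outgroup are < ``kaks_outgroup_max``. Degenerate
    flags on any pair (Ks = 0, saturated correction) keep the gene off the
    clean list while preserving the call and its rationale.
    """
    pairs = {
        "AB": triple.result_ab,
        "A_out": triple.result_a_out,
        "B_out": triple.result_b_out,
    }
    missing = [k for k, v in pairs.items() if v is None]
    if missing:
        raise ValueError(f"{triple.gene_id}: Ka/Ks missing for pairs {missing}")
    rationale: list[str] = []
    flags = set()
    for name, res in pairs.items():
        flags |= {f"{name}:{f}" for f in res.flags}
    ab = pairs["AB"].ratio
    a_out = pairs["A_out"].ratio
    b_out = pairs["B_out"].ratio

    def below(r: float | None, cutoff: float) -> bool:
        return r is not None and not math.isinf(r) and r < cutoff

    ingroup_high = ab is not None and (math.isinf(ab) or ab >= config.kaks_candidate_min)
    out_low = below(a_out, config.kaks_outgroup_max) and below(b_out, config.kaks_outgroup_max)
    candidate = ingroup_high and out_low
    rationale.append(
        f"ratio(A,B)={_fmt_ratio(ab)} {'>=' if ingroup_high else '<'} {config.kaks_candidate_min}"
    )
    rationale.append(
        f"outgroup ratios {_fmt_ratio(a_out)}, {_fmt_ratio(b_out)} "
        f"{'both <' if out_low else 'not both <'} {config.kaks_outgroup_max}"
    )
    rationale.extend(sorted(flags))
    clean = candidate and not flags
    return CandidateCall(
        gene_id=triple.gene_id, candidate=candidate, clean=clean, rationale=rationale
    )


def _fmt_ratio(r: float | None) -> str:
    if r is None:
        return "undef"
    if math.isinf(r):
        return "inf"
    return f"{r:.4f}"
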