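"""ORF prediction and codon-usage statistics.

ORFs are scanned in all six reading frames; maximal stop-to-stop segments
are reported, preferring an ATG start when one exists (otherwise the
segment is flagged incomplete). Codon-usage bias is summarised by Wright's
effective number of codons,

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

where Fk is the average codon homozygosity over the k-fold degenerate
amino-acid families of the standard genetic code. Nc runs from 20 (one
codon per amino acid, maximal bias) to 61 (uniform synonymous usage).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: codon -> amino acid, with "*" for the three stop codons
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
ALL_CODONS = tuple(sorted(GENETIC_CODE))

#: amino acid -> synonymous codon family (stops excluded)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        SYNONYMOUS_FAMILIES.setdefault(_aa, ())
        SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: degeneracy class -> number of amino-acid families (standard code:
#: 2 single, 9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold)
FAMILY_CLASS_SIZES = Counter(len(v) for v in SYNONYMOUS_FAMILIES.values())


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; 'X' when the codon contains N."""
    if "N" in codon:
        return "X"
    return GENETIC_CODE[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class CdsAnnotation:
    """A predicted coding region on a transcript.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the transcript and delimit the protein-coding codons (the
    terminating stop codon, when present, lies just outside ``end`` in
    reading direction).
    """

    transcript_id: str
    frame: int  # 0..2, offset on the reading strand
    strand: str  # "+" or "-"
    start: int
    end: int
    protein_length: int
    has_start_codon: bool
    has_stop_codon: bool
    primary: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("CDS span not divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    def extract_cds(self, transcript_seq: str) -> str:
        region = transcript_seq[self.start : self.end]
        if self.strand == "-":
            region = str(Seq(region).reverse_complement())
        return region


def find_orfs(
    transcript_id: str,
    sequence: str,
    min_residues: int = 100,
    inclusive: bool = True,
) -> list[CdsAnnotation]:
    """Six-frame ORF scan.

    Reports maximal stop-to-stop ORFs with protein length >= (or > when
    ``inclusive`` is False) ``min_residues``. Within each stop-bounded
    segment the first ATG starts the ORF when one exists; otherwise the
    segment itself is reported with ``has_start_codon=False`` (incomplete).
    The longest ORF per transcript is marked primary (ties: + strand first,
    then smallest start).
    """
    sequence = sequence.upper()
    n = len(sequence)
    results: list[CdsAnnotation] = []
    for strand in "+-":
        seq = sequence if strand == "+" else str(Seq(sequence).reverse_complement())
        for frame in range(3):
            codons = [seq[i : i + 3] for i in range(frame, n - 2, 3)]
            seg_start = 0  # codon index where current segment begins
            for idx in range(len(codons) + 1):
                at_end = idx == len(codons)
                if at_end or codons[idx] in STOP_CODONS:
                    seg = codons[seg_start:idx]
                    ann = _segment_to_orf(
                        transcript_id, seg, seg_start, frame, strand, n,
                        has_stop=not at_end,
                        min_residues=min_residues, inclusive=inclusive,
                    )
                    if ann is not None:
                        results.append(ann)
                    seg_start = idx + 1
    if results:
        best = min(
            results,
            key=lambda a: (-a.protein_length, a.strand, a.start),
        )
        results = [
            CdsAnnotation(**{**a.__dict__, "primary": a == best}) for a in results
        ]
    results.sort(key=lambda a: (-a.protein_length, a.strand, a.start))
    return results


def _segment_to_orf(
    transcript_id, seg, seg_start, frame, strand, seq_len,
    has_stop, min_residues, inclusive,
):
    if not seg:
        return None
    atg_offset = next((i for i, c in enumerate(seg) if c == "ATG"), None)
    if atg_offset is not None:
        codon_lo, has_start = seg_start + atg_offset, True
    else:
        codon_lo, has_start = seg_start, False
    n_res = seg_start + len(seg) - codon_lo
    long_enough = n_res >= min_residues if inclusive else n_res > min_residues
    if not long_enough:
        return None
    # coordinates on the reading strand
    lo = frame + 3 * codon_lo
    hi = lo + 3 * n_res
    if strand == "-":  # map back to forward-strand coordinates
        lo, hi = seq_len - hi, seq_len - lo
    return CdsAnnotation(
        transcript_id=transcript_id,
        frame=frame,
        strand=strand,
        start=lo,
        end=hi,
        protein_length=n_res,
        has_start_codon=has_start,
        has_stop_codon=has_stop,
    )


@dataclass
class CodonUsageStats:
    counts: dict[str, int]  # 61 sense codons (+ stops, always 0 here)
    fractions: dict[str, float]  # within-synonymous-family fractions
    family_homozygosity: dict[str, float]  # amino acid -> F
    nc: float


def codon_usage(cds_set: list[str], corrected: bool = False) -> CodonUsageStats:
    """Codon counts, within-family fractions, and Wright's Nc.

    ``corrected`` selects the small-sample homozygosity estimator
    F = (n*sum(p^2) - 1)/(n - 1); the default plug-in form F = sum(p^2)
    attains the analytic bounds (uniform usage -> Nc = 61, one codon per
    amino acid -> Nc = 20) exactly. Degeneracy classes with no usable
    family fall back to the standard averaging rule (the three-fold class
    borrows the mean of the two- and four-fold classes).
    """
    if not cds_set:
        raise ValueError("codon_usage requires at least one CDS")
    counts: Counter[str] = Counter()
    for cds in cds_set:
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            if GENETIC_CODE[codon] == "*":
                raise ValueError(f"internal stop codon {codon} at position {i}")
            counts[codon] += 1

    fractions: dict[str, float] = {}
    f_by_aa: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        n_aa = sum(counts[c] for c in family)
        if n_aa == 0:
            continue
        ps = [counts[c] / n_aa for c in family]
        for c, p in zip(family, ps):
            fractions[c] = p
        sum_p2 = sum(p * p for p in ps)
        if corrected:
            if n_aa < 2:
                continue  # F undefined for a single observation
            f_by_aa[aa] = (n_aa * sum_p2 - 1.0) / (n_aa - 1.0)
        else:
            f_by_aa[aa] = sum_p2

    fbar: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        vals = [
            f for aa, f in f_by_aa.items()
            if len(SYNONYMOUS_FAMILIES[aa]) == k and f > 0
        ]
        if vals:
            fbar[k] = sum(vals) / len(vals)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in fbar]
    if missing:
        raise ValueError(
            f"cannot estimate Nc: no usable families of degeneracy {missing}"
        )
    nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    if corrected:
        nc = min(61.0, max(20.0, nc))
    return CodonUsageStats(
        counts={c: counts[c] for c in ALL_CODONS},
        fractions=fractions,
        family_homozygosity=f_by_aa,
        nc=nc,
    )


def usage_mean_square_difference(
    a: CodonUsageStats, b: CodonUsageStats
) -> float:
    """Mean squared difference of within-family codon fractions between two
    usage tables, over sense codons observed in either table."""
    codons = sorted(set(a.fractions) | set(b.fractions))
    if not codons:
        raise ValueError("no codon fractions to compare")
    return sum((a.fractions.get(c, 0.0) - b.fractions.get(c, 0.0)) ** 2 for c in codons) / len(codons)
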