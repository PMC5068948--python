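"""Pairwise protein alignment, reciprocal-best-hit orthology, and
codon-aware back-translation.

Global alignment uses Needleman-Wunsch with affine gaps and BLOSUM62
(via Bio.Align.PairwiseAligner). Orthologs between two protein sets are
called by reciprocal best hit (RBH): a pair is reported only when each
sequence is the other's unique highest-scoring partner; ties for best are
treated conservatively (no pair). Back-translation expands an aligned
protein to its source codons so downstream Ka/Ks runs on whole-codon
columns.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .codon import translate_cds

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


def make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


@dataclass
class ProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


def _validate_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")


def align_proteins(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> ProteinAlignment:
    """Optimal global alignment; the first optimal alignment in the
    aligner's deterministic enumeration order is returned, which fixes
    gap placement among co-optimal solutions."""
    _validate_protein(a, "sequence a")
    _validate_protein(b, "sequence b")
    if aligner is None:
        aligner = make_aligner()
    aln = next(iter(aligner.align(a, b)))
    sa, sb = str(aln[0]), str(aln[1])
    return ProteinAlignment(aligned_a=sa, aligned_b=sb, score=float(aln.score))


def reciprocal_best_hits(
    set_a: dict[str, str],
    set_b: dict[str, str],
    min_score: float = 0.0,
    aligner: Align.PairwiseAligner | None = None,
) -> list[tuple[str, str, float]]:
    """All-vs-all scored RBH pairs, sorted by id.

    A pair (a, b) is reported iff b is a's unique best-scoring partner and
    vice versa, and the score is >= ``min_score``.
    """
    if not set_a or not set_b:
        return []
    if aligner is None:
        aligner = make_aligner()
    scores: dict[tuple[str, str], float] = {}
    for na, pa in set_a.items():
        for nb, pb in set_b.items():
            scores[(na, nb)] = float(aligner.score(pa, pb))

    def unique_best(name: str, partners: list[str], key) -> str | None:
        vals = [(scores[key(name, p)], p) for p in partners]
        best = max(v for v, _ in vals)
        if best < min_score:
            return None
        top = [p for v, p in vals if v == best]
        return top[0] if len(top) == 1 else None

    pairs = []
    for na in set_a:
        nb = unique_best(na, list(set_b), lambda x, y: (x, y))
        if nb is None:
            continue
        back = unique_best(nb, list(set_a), lambda x, y: (y, x))
        if back == na:
            pairs.append((na, nb, scores[(na, nb)]))
    pairs.sort()
    return pairs


def merge_pairwise_on_anchor(
    anchor1: str, other1: str, anchor2: str, other2: str
) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing an anchor sequence into a
    three-row alignment (anchor, other1, other2).

    Both alignments must contain the same ungapped anchor; columns where
    one alignment inserts relative to the anchor gain gap columns in the
    other rows.
    """
    if anchor1.replace("-", "") != anchor2.replace("-", ""):
        raise ValueError("anchor sequences differ between the two alignments")
    out_a: list[str] = []
    out_1: list[str] = []
    out_2: list[str] = []
    i = j = 0
    while i < len(anchor1) or j < len(anchor2):
        c1 = anchor1[i] if i < len(anchor1) else None
        c2 = anchor2[j] if j < len(anchor2) else None
        if c1 == "-":
            out_a.append("-")
            out_1.append(other1[i])
            out_2.append("-")
            i += 1
        elif c2 == "-":
            out_a.append("-")
            out_1.append("-")
            out_2.append(other2[j])
            j += 1
        else:
            assert c1 == c2
            out_a.append(c1)
            out_1.append(other1[i])
            out_2.append(other2[j])
            i += 1
            j += 1
    return "".join(out_a), "".join(out_1), "".join(out_2)


def back_translate(aligned_protein: str, cds: str) -> str:
    """Expand an aligned (gap-containing) protein to its source codons.

    The ungapped protein must equal the translation of ``cds``; each
    residue column becomes its source codon, each gap becomes ``---``.
    """
    ungapped = aligned_protein.replace("-", "")
    translated = translate_cds(cds)
    if translated.endswith("*") and len(translated) == len(ungapped) + 1:
        translated = translated[:-1]
        cds = cds[:-3]
    if translated != ungapped:
        for i, (x, y) in enumerate(zip(translated, ungapped)):
            if x != y:
                raise ValueError(
                    f"back_translate: residue {i} mismatch "
                    f"(CDS translates to {x!r}, alignment has {y!r})"
                )
        raise ValueError(
            f"back_translate: protein length {len(ungapped)} does not match "
            f"CDS translation length {len(translated)}"
        )
    out = []
    i = 0
    for res in aligned_protein:
        if res == "-":
            out.append("---")
        else:
            out.append(cds[3 * i : 3 * i + 3])
            i += 1
    return "".join(out)
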