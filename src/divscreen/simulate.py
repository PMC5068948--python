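"""Synthetic two-species transcriptome data with planted ground truth.

The generator emulates the structure of a de novo transcriptome screen for
two recently diverged species mapped against one shared reference:

* unigenes with a variable number of isoforms sharing a common exonic
  core, so the longest-isoform reduction is meaningful;
* three planted SNP classes — shared polymorphic (both species segregate),
  species-specific polymorphic, and fixed interspecific differences —
  with per-site read depths drawn from a negative binomial (overdispersed
  RNA-seq-like coverage) and binomially sampled allele counts;
* ortholog CDS triples (two ingroup species plus an outgroup) evolved
  from a common ancestor by a mutation-acceptance process with a
  controlled per-gene dN/dS (omega) and branch lengths in expected
  substitutions per codon.

Every generator is deterministic given the seed. The planted truth
(per-SNP class and true frequencies, per-gene omega) is returned as a
truth table that downstream recovery tests consume.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon import GENETIC_CODE, STOP_CODONS, translate_cds
from .records import TranscriptRecord, VariantSite
from .snp_screen import UnigeneCatalog, dedup_longest_isoform

_NUCS = "ACGT"
_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


@dataclass
class SimulationParams:
    n_unigenes: int = 300
    isoforms_per_unigene: tuple[int, int] = (1, 3)
    transcript_length: tuple[int, int] = (400, 3000)
    n_shared_snps: int = 640
    n_specific_snps: int = 1000
    n_fixed_snps: int = 80
    #: unigenes reserved for fixed differences (disjoint from the
    #: polymorphic pool); default scales the 164-in-2612 proportion
    n_fixed_unigenes: int | None = None
    depth_distribution: tuple[float, float] = (200.0, 10.0)  # (mean, dispersion)
    qual_distribution: tuple[float, float] = (60.0, 10.0)  # Phred (mean, sd)
    omega_per_gene: tuple[float, ...] = (0.1, 0.5, 1.0)
    omega_background: float = 0.1  # outgroup-branch omega
    cds_length_codons: int = 300
    t_ingroup: float = 0.05
    t_outgroup: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_outgroup > self.t_ingroup > 0):
            raise ValueError("need t_outgroup > t_ingroup > 0")
        if any(w <= 0 for w in self.omega_per_gene) or self.omega_background <= 0:
            raise ValueError("omega must be > 0")
        for count in (self.n_shared_snps, self.n_specific_snps, self.n_fixed_snps,
                      self.n_unigenes):
            if count < 0:
                raise ValueError("counts must be >= 0")

    @property
    def fixed_unigene_count(self) -> int:
        if self.n_fixed_unigenes is not None:
            return self.n_fixed_unigenes
        if self.n_fixed_snps == 0:
            return 0
        return max(1, round(self.n_unigenes * 164 / 2612))


@dataclass
class SnpTruth:
    transcript_id: str
    position: int
    snp_class: str  # shared | specificA | specificB | fixed
    f_a: float
    f_b: float


@dataclass
class GeneTruth:
    gene_id: str  # component id of the unigene carrying the CDS
    omega: float
    omega_background: float
    t_ingroup: float
    t_outgroup: float


@dataclass
class TruthTable:
    snps: list[SnpTruth] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)

    def fixed_unigenes(self, catalog: UnigeneCatalog) -> set[str]:
        out = set()
        for s in self.snps:
            if s.snp_class == "fixed":
                comp = catalog.component_of.get(s.transcript_id)
                if comp is not None:
                    out.add(catalog.chosen[comp])
        return out

    def write_tsv(self, snp_path: str | Path, gene_path: str | Path) -> None:
        with open(snp_path, "w") as fh:
            fh.write("transcript\tpos\tclass\tf_a\tf_b\n")
            for s in self.snps:
                fh.write(f"{s.transcript_id}\t{s.position}\t{s.snp_class}"
                         f"\t{s.f_a:.6g}\t{s.f_b:.6g}\n")
        with open(gene_path, "w") as fh:
            fh.write("gene\tomega\tomega_background\tt_ingroup\tt_outgroup\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.omega:.6g}\t{g.omega_background:.6g}"
                         f"\t{g.t_ingroup:.6g}\t{g.t_outgroup:.6g}\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NUCS), size=length))


def simulate_unigenes(params: SimulationParams,
                      rng: np.random.Generator | None = None) -> list[TranscriptRecord]:
    """Transcript isoforms for ``n_unigenes`` components.

    Isoforms of a component share a common exonic core and differ by
    random 5'/3' extensions, so exactly one maximal-length isoform exists
    per component (the later-generated extension is strictly longer).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    lo_iso, hi_iso = params.isoforms_per_unigene
    lo_len, hi_len = params.transcript_length
    records: list[TranscriptRecord] = []
    for u in range(params.n_unigenes):
        comp = f"comp{u}_c0"
        core_len = int(rng.integers(lo_len, hi_len + 1))
        core = _random_sequence(rng, core_len)
        n_iso = int(rng.integers(lo_iso, hi_iso + 1))
        ext_sizes = sorted(
            set(int(x) for x in rng.integers(0, max(1, core_len // 4), size=n_iso))
        )
        while len(ext_sizes) < n_iso:  # force distinct lengths
            ext_sizes.append(ext_sizes[-1] + 1 if ext_sizes else 0)
        for j, ext in enumerate(ext_sizes, start=1):
            suffix = _random_sequence(rng, ext)
            records.append(
                TranscriptRecord(
                    transcript_id=f"{comp}_seq{j}",
                    component_id=comp,
                    sequence=core + suffix,
                )
            )
    if not records:
        import logging
        logging.getLogger("divscreen").warning("simulate_unigenes: zero unigenes requested")
    return records


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # negative binomial parameterised by mean and dispersion k
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_allele_counts(
    catalog: UnigeneCatalog,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantSite], TruthTable]:
    """Plant the three SNP classes on the chosen unigene transcripts.

    Fixed differences go on a dedicated unigene pool disjoint from the
    polymorphic pool (so fixed-unigene recovery is well defined); shared
    SNPs draw both true frequencies uniformly on (0.05, 0.95); specific
    SNPs draw one frequency there and set the other to 0. Observed alt
    counts are Binomial(depth, true F) at a negative-binomial depth.
    """
    if not catalog.chosen:
        raise ValueError("empty catalog")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    unigenes = sorted(catalog.chosen.values())
    n_fixed_uni = min(params.fixed_unigene_count, len(unigenes))
    perm = rng.permutation(len(unigenes))
    fixed_pool = [unigenes[i] for i in perm[:n_fixed_uni]]
    poly_pool = [unigenes[i] for i in perm[n_fixed_uni:]]
    if params.n_fixed_snps > 0 and not fixed_pool:
        raise ValueError("fixed SNPs requested but no unigene available")
    if (params.n_shared_snps + params.n_specific_snps) > 0 and not poly_pool:
        raise ValueError("polymorphic SNPs requested but no unigene available")

    used: dict[str, set[int]] = {u: set() for u in unigenes}

    def pick_position(tid: str) -> int:
        length = catalog.lengths[tid]
        taken = used[tid]
        if len(taken) >= length:
            raise ValueError(f"more SNPs requested than positions on {tid}")
        while True:
            pos = int(rng.integers(0, length))
            if pos not in taken:
                taken.add(pos)
                return pos

    truth = TruthTable()
    sites: list[VariantSite] = []
    qual_mean, qual_sd = params.qual_distribution
    depth_mean, depth_disp = params.depth_distribution

    def plant(tid: str, snp_class: str, f_a: float, f_b: float) -> None:
        pos = pick_position(tid)
        ref = catalog.sequences[tid][pos]
        if ref == "N":
            ref = "A"
        alt = _NUCS[(_NUCS.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        counts = {}
        for sp, f in (("A", f_a), ("B", f_b)):
            depth = _draw_depth(rng, depth_mean, depth_disp)
            alt_n = int(rng.binomial(depth, f)) if depth > 0 else 0
            counts[sp] = (depth - alt_n, alt_n)
        qual = max(0.0, float(rng.normal(qual_mean, qual_sd)))
        sites.append(
            VariantSite(
                transcript_id=tid, position=pos, ref_allele=ref, alt_allele=alt,
                counts_by_species=counts, quality=qual,
            )
        )
        truth.snps.append(SnpTruth(tid, pos, snp_class, f_a, f_b))

    # fixed differences: round-robin so every pool unigene carries >= 1
    for i in range(params.n_fixed_snps):
        tid = fixed_pool[i % len(fixed_pool)]
        if rng.random() < 0.5:
            plant(tid, "fixed", 1.0, 0.0)
        else:
            plant(tid, "fixed", 0.0, 1.0)
    for _ in range(params.n_shared_snps):
        tid = poly_pool[int(rng.integers(0, len(poly_pool)))]
        plant(tid, "shared",
              float(rng.uniform(0.05, 0.95)), float(rng.uniform(0.05, 0.95)))
    for i in range(params.n_specific_snps):
        tid = poly_pool[int(rng.integers(0, len(poly_pool)))]
        f = float(rng.uniform(0.05, 0.95))
        if i % 2 == 0:
            plant(tid, "specificA", f, 0.0)
        else:
            plant(tid, "specificB", 0.0, f)
    return sites, truth


def random_cds(rng: np.random.Generator, n_codons: int, start_codon: bool = False) -> str:
    codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons)]
    if start_codon and codons:
        codons[0] = "ATG"
    return "".join(codons)


def simulate_codon_evolution(
    ancestor_cds: str,
    omega: float,
    t: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a CDS by a mutation-acceptance process.

    The number of accepted substitutions is Poisson with mean
    ``t * n_codons`` (t in expected substitutions per codon). Proposals are
    uniform single-nucleotide changes; synonymous proposals are accepted
    with probability 1 and nonsynonymous with probability min(1, omega)
    (for omega > 1 the synonymous acceptance is down-weighted to 1/omega
    instead); proposals creating stop codons are rejected outright.
    """
    if len(ancestor_cds) % 3:
        raise ValueError("ancestor CDS length not divisible by 3")
    protein = translate_cds(ancestor_cds)
    if "*" in protein:
        raise ValueError("ancestor CDS contains an internal stop codon")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    n_codons = len(ancestor_cds) // 3
    if t < 0:
        raise ValueError("t must be >= 0")
    n_target = int(rng.poisson(t * n_codons)) if t > 0 else 0
    seq = list(ancestor_cds)
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_non = min(1.0, omega)
    accepted = 0
    max_proposals = 1000 * (n_target + 10)
    proposals = 0
    while accepted < n_target:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError("mutation-acceptance process failed to converge")
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = _NUCS[(_NUCS.index(old) + 1 + int(rng.integers(0, 3))) % 4]
        codon_start = 3 * (pos // 3)
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = (
            old_codon[: pos - codon_start] + new + old_codon[pos - codon_start + 1 :]
        )
        if new_codon in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
        p_accept = p_syn if synonymous else p_non
        if rng.random() < p_accept:
            seq[pos] = new
            accepted += 1
    return "".join(seq)


@dataclass
class OrthologTripleSeqs:
    gene_id: str
    cds_a: str
    cds_b: str
    cds_out: str


def simulate_ortholog_triples(
    params: SimulationParams,
    gene_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[OrthologTripleSeqs], list[GeneTruth]]:
    """Evolve one CDS triple per omega value (or per supplied gene id).

    Each ingroup tip receives t_ingroup/2 from the common ancestor, so the
    ingroup pairwise path has length t_ingroup; the outgroup receives
    t_outgroup - t_ingroup/2 under ``omega_background``, making both
    ingroup-outgroup paths t_outgroup long.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 2)
    omegas = list(params.omega_per_gene)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(len(omegas))]
    if len(gene_ids) != len(omegas):
        raise ValueError("gene_ids and omega_per_gene lengths differ")
    half = params.t_ingroup / 2.0
    t_out_branch = params.t_outgroup - half
    triples: list[OrthologTripleSeqs] = []
    truths: list[GeneTruth] = []
    for gid, omega in zip(gene_ids, omegas):
        ancestor = random_cds(rng, params.cds_length_codons)
        cds_a = simulate_codon_evolution(ancestor, omega, half, rng)
        cds_b = simulate_codon_evolution(ancestor, omega, half, rng)
        cds_out = simulate_codon_evolution(
            ancestor, params.omega_background, t_out_branch, rng
        )
        triples.append(OrthologTripleSeqs(gid, cds_a, cds_b, cds_out))
        truths.append(GeneTruth(gid, omega, params.omega_background,
                                params.t_ingroup, params.t_outgroup))
    return triples, truths


def _embed_cds(rng: np.random.Generator, cds: str, utr_max: int = 60) -> str:
    """Wrap a CDS with ATG-free UTRs (alphabet {A,C,T}) plus start/stop."""
    def utr(n: int) -> str:
        return "".join(rng.choice(list("ACT"), size=n))

    utr5 = utr(int(rng.integers(0, utr_max + 1)))
    utr3 = utr(int(rng.integers(0, utr_max + 1)))
    return utr5 + "ATG" + cds + "TAA" + utr3


def emit_dataset(out_dir: str | Path, params: SimulationParams, force: bool = False) -> dict:
    """Write a full synthetic dataset and its manifest.

    Files: reference transcripts (all isoforms), per-species consensus
    transcript FASTAs (gene-bearing unigenes carry embedded evolved CDSs),
    outgroup CDS FASTA, variants as VCF and TSV, SNP and gene truth
    tables, and a JSON manifest recording parameters and seed.
    """
    from .io import write_fasta, write_variants_tsv, write_variants_vcf

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.rng_seed)
    transcripts = simulate_unigenes(params, rng)
    catalog = dedup_longest_isoform(transcripts)
    sites, truth = simulate_allele_counts(catalog, params, rng)

    # CDS genes sit on fixed-pool unigenes first (divergence-gated screen),
    # then on polymorphic unigenes
    fixed_unis = sorted(truth.fixed_unigenes(catalog))
    other_unis = sorted(set(catalog.chosen.values()) - set(fixed_unis))
    hosts = (fixed_unis + other_unis)[: len(params.omega_per_gene)]
    gene_ids = [catalog.component_of[t] for t in hosts]
    triples, gene_truth = simulate_ortholog_triples(params, gene_ids, rng)
    truth.genes = gene_truth

    host_by_gene = dict(zip(gene_ids, hosts))
    species_seqs: dict[str, list[tuple[str, str]]] = {"A": [], "B": []}
    triple_by_gene = {t.gene_id: t for t in triples}
    for comp in sorted(catalog.chosen):
        tid = catalog.chosen[comp]
        if comp in triple_by_gene:
            tr = triple_by_gene[comp]
            species_seqs["A"].append((tid, _embed_cds(rng, tr.cds_a)))
            species_seqs["B"].append((tid, _embed_cds(rng, tr.cds_b)))
        else:
            base = catalog.sequences[tid]
            variants = {"A": list(base), "B": list(base)}
            for s in truth.snps:
                if s.transcript_id != tid:
                    continue
                site = next(
                    x for x in sites
                    if x.transcript_id == tid and x.position == s.position
                )
                for sp, f in (("A", s.f_a), ("B", s.f_b)):
                    if f > 0.5:
                        variants[sp][s.position] = site.alt_allele
            species_seqs["A"].append((tid, "".join(variants["A"])))
            species_seqs["B"].append((tid, "".join(variants["B"])))

    write_fasta(transcripts, out / "reference.fasta")
    write_fasta(species_seqs["A"], out / "species_A.fasta")
    write_fasta(species_seqs["B"], out / "species_B.fasta")
    write_fasta([(t.gene_id, t.cds_out) for t in triples], out / "outgroup_cds.fasta")
    write_variants_vcf(sites, transcripts, out / "variants.vcf")
    write_variants_tsv(sites, out / "variants.tsv")
    truth.write_tsv(out / "truth_snps.tsv", out / "truth_genes.tsv")
    manifest = {
        "params": _params_dict(params),
        "seed": params.rng_seed,
        "n_transcripts": len(transcripts),
        "n_unigenes": len(catalog.chosen),
        "n_sites": len(sites),
        "n_genes": len(triples),
        "gene_hosts": host_by_gene,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _params_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["omega_per_gene"] = list(d["omega_per_gene"])
    for k in ("isoforms_per_unigene", "transcript_length",
              "depth_distribution", "qual_distribution"):
        d[k] = list(d[k])
    return d
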