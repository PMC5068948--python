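"""Synthetic-data generator: determinism, planted truth, codon evolution."""
import math

import numpy as np
import pytest

from divscreen.codon import translate_cds
from divscreen.kaks import ng86_kaks
from divscreen.simulate import (SimulationParams, emit_dataset, random_cds,
                                simulate_allele_counts,
                                simulate_codon_evolution,
                                simulate_ortholog_triples, simulate_unigenes)
from divscreen.snp_screen import dedup_longest_isoform


def params(**kw):
    defaults = dict(n_unigenes=10, n_shared_snps=20, n_specific_snps=10,
                    n_fixed_snps=4, n_fixed_unigenes=2, rng_seed=7)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestSimulateUnigenes:
    def test_seeded_determinism(self):
        assert simulate_unigenes(params()) == simulate_unigenes(params())

    def test_single_isoform_reduction_is_identity(self):
        p = params(isoforms_per_unigene=(1, 1))
        transcripts = simulate_unigenes(p)
        catalog = dedup_longest_isoform(transcripts)
        assert len(transcripts) == p.n_unigenes == len(catalog.chosen)
        assert not catalog.discarded

    def test_component_and_transcript_count_bounds(self):
        p = params(n_unigenes=5, isoforms_per_unigene=(1, 3))
        transcripts = simulate_unigenes(p)
        components = {t.component_id for t in transcripts}
        assert len(components) == 5
        assert 5 <= len(transcripts) <= 15

    def test_isoforms_share_exonic_core(self):
        transcripts = simulate_unigenes(params(isoforms_per_unigene=(2, 3)))
        by_comp = {}
        for t in transcripts:
            by_comp.setdefault(t.component_id, []).append(t.sequence)
        for seqs in by_comp.values():
            shortest = min(seqs, key=len)
            lcp = 0
            while all(len(s) > lcp and s[lcp] == shortest[lcp] for s in seqs):
                lcp += 1
            # extensions are at most a quarter of the core, so the shared
            # prefix covers at least 80% of the shortest isoform
            assert lcp >= 0.8 * len(shortest)


class TestSimulateAlleleCounts:
    def test_seeded_determinism(self):
        def run():
            p = params()
            cat = dedup_longest_isoform(simulate_unigenes(p))
            return simulate_allele_counts(cat, p)

        s1, t1 = run()
        s2, t2 = run()
        assert s1 == s2 and t1.snps == t2.snps

    def test_fixed_snp_is_degenerate_binomial(self):
        p = params(n_shared_snps=0, n_specific_snps=0, n_fixed_snps=6,
                   depth_distribution=(200.0, 1000.0))
        cat = dedup_longest_isoform(simulate_unigenes(p))
        sites, truth = simulate_allele_counts(cat, p)
        for site, t in zip(sites, truth.snps):
            assert t.snp_class == "fixed"
            for sp, f in (("A", t.f_a), ("B", t.f_b)):
                r, a = site.counts_by_species[sp]
                assert (a == 0) if f == 0.0 else (r == 0)

    def test_truth_classes_match_frequencies(self):
        p = params()
        cat = dedup_longest_isoform(simulate_unigenes(p))
        _, truth = simulate_allele_counts(cat, p)
        for t in truth.snps:
            if t.snp_class == "fixed":
                assert {t.f_a, t.f_b} == {0.0, 1.0}
            elif t.snp_class == "shared":
                assert 0.05 < t.f_a < 0.95 and 0.05 < t.f_b < 0.95
            elif t.snp_class == "specificA":
                assert 0.05 < t.f_a < 0.95 and t.f_b == 0.0
            else:
                assert t.f_a == 0.0 and 0.05 < t.f_b < 0.95

    def test_ref_allele_matches_reference_base(self):
        p = params()
        cat = dedup_longest_isoform(simulate_unigenes(p))
        sites, _ = simulate_allele_counts(cat, p)
        for s in sites:
            assert cat.sequences[s.transcript_id][s.position] == s.ref_allele

    def test_oversized_request_raises(self):
        p = params(n_unigenes=1, n_fixed_snps=0, n_specific_snps=0,
                   n_shared_snps=10_000, transcript_length=(400, 500),
                   isoforms_per_unigene=(1, 1), n_fixed_unigenes=0)
        cat = dedup_longest_isoform(simulate_unigenes(p))
        with pytest.raises(ValueError, match="positions"):
            simulate_allele_counts(cat, p)

    def test_mean_frequency_gap_matches_binomial_expectation(self):
        """Planted F_A = F_B = 0.5 at depth 500: the mean observed
        |F_hat_A - F_hat_B| agrees with the exact binomial expectation."""
        n, p_true = 500, 0.5
        rng = np.random.default_rng(31)
        reps = 4000
        xa = rng.binomial(n, p_true, size=reps) / n
        xb = rng.binomial(n, p_true, size=reps) / n
        observed = np.abs(xa - xb).mean()
        # exact E|X - Y|/n via convolution of the two binomial pmfs
        from scipy.stats import binom

        pmf = binom.pmf(np.arange(n + 1), n, p_true)
        diff_pmf = np.convolve(pmf, pmf[::-1])
        diffs = np.arange(-n, n + 1) / n
        expected = float(np.abs(diffs) @ diff_pmf)
        assert observed == pytest.approx(expected, rel=0.05)


class TestCodonEvolution:
    def test_t_zero_is_identity(self, rng):
        anc = random_cds(rng, 100)
        assert simulate_codon_evolution(anc, 0.5, 0.0, rng) == anc

    def test_omega_zero_only_synonymous_changes(self, rng):
        anc = random_cds(rng, 200)
        evolved = simulate_codon_evolution(anc, 0.0, 0.3, rng)
        assert evolved != anc
        assert translate_cds(evolved) == translate_cds(anc)

    def test_no_stop_codons_introduced(self, rng):
        anc = random_cds(rng, 150)
        evolved = simulate_codon_evolution(anc, 2.0, 0.5, rng)
        assert "*" not in translate_cds(evolved)

    def test_internal_stop_in_ancestor_rejected(self, rng):
        with pytest.raises(ValueError, match="stop"):
            simulate_codon_evolution("ATGTAAGGG", 0.5, 0.1, rng)

    def test_seeded_determinism(self):
        anc = random_cds(np.random.default_rng(1), 100)
        e1 = simulate_codon_evolution(anc, 0.5, 0.2, np.random.default_rng(9))
        e2 = simulate_codon_evolution(anc, 0.5, 0.2, np.random.default_rng(9))
        assert e1 == e2

    def test_neutral_evolution_recovers_unit_ratio(self):
        """omega = 1 on a long gene: NG86 estimate close to 1."""
        rng = np.random.default_rng(17)
        ratios = []
        for _ in range(30):
            anc = random_cds(rng, 500)
            evolved = simulate_codon_evolution(anc, 1.0, 0.3, rng)
            r = ng86_kaks(anc, evolved)
            if r.ratio is not None and not math.isinf(r.ratio):
                ratios.append(r.ratio)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.1)


class TestOrthologTriples:
    def test_truth_records_parameters(self):
        p = params(omega_per_gene=(0.2, 1.2), cds_length_codons=100)
        triples, truth = simulate_ortholog_triples(p)
        assert [t.omega for t in truth] == [0.2, 1.2]
        assert all(len(t.cds_a) == 300 for t in triples)

    def test_gene_id_mismatch_rejected(self):
        p = params(omega_per_gene=(0.2, 1.2))
        with pytest.raises(ValueError):
            simulate_ortholog_triples(p, gene_ids=["only_one"])


class TestEmitDataset:
    def test_all_files_present_and_manifest_seed(self, tmp_path):
        p = params(rng_seed=5)
        manifest = emit_dataset(tmp_path / "ds", p)
        for name in ("reference.fasta", "species_A.fasta", "species_B.fasta",
                     "outgroup_cds.fasta", "variants.vcf", "variants.tsv",
                     "truth_snps.tsv", "truth_genes.tsv", "manifest.json"):
            assert (tmp_path / "ds" / name).exists()
        assert manifest["seed"] == 5

    def test_same_seed_byte_identical(self, tmp_path):
        p = params(rng_seed=5)
        emit_dataset(tmp_path / "d1", p)
        emit_dataset(tmp_path / "d2", p)
        for name in ("reference.fasta", "variants.tsv", "truth_snps.tsv"):
            assert (tmp_path / "d1" / name).read_bytes() == \
                (tmp_path / "d2" / name).read_bytes()

    def test_no_fixed_snps_no_fixed_truth_rows(self, tmp_path):
        p = params(n_fixed_snps=0, n_fixed_unigenes=0)
        emit_dataset(tmp_path / "ds", p)
        truth = (tmp_path / "ds" / "truth_snps.tsv").read_text()
        assert "\tfixed\t" not in truth

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "ds"
        out.mkdir()
        (out / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            emit_dataset(out, params())
        emit_dataset(out, params(), force=True)  # explicit override works
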