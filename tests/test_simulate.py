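"""Unit tests for the synthetic-germplasm generator."""

import re

import numpy as np
import pytest

from gbscore import simulate as sim


class TestPopulations:
    def test_single_population_equals_ancestral(self):
        m = sim.simulate_populations(1, 100, fst=0.3, seed=1)
        assert np.array_equal(m.allele_freqs[0], m.ancestral_freqs)

    def test_divergence_grows_with_fst(self):
        """Mean absolute between-population frequency difference must
        increase with the divergence parameter (Monte Carlo over seeds)."""
        def mean_div(fst):
            diffs = []
            for seed in range(10):
                m = sim.simulate_populations(3, 500, fst=fst, seed=seed)
                diffs.append(np.mean(np.abs(
                    m.allele_freqs[0] - m.allele_freqs[1])))
            return np.mean(diffs)

        assert mean_div(0.3) > mean_div(0.05)

    def test_low_fst_limit_collapses_divergence(self):
        m = sim.simulate_populations(3, 500, fst=1e-4, seed=3)
        assert np.var(m.allele_freqs, axis=0).max() < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sim.simulate_populations(0, 10, 0.3, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_populations(2, 10, 1.5, seed=0)

    def test_deterministic(self):
        a = sim.simulate_populations(3, 50, 0.2, seed=9)
        b = sim.simulate_populations(3, 50, 0.2, seed=9)
        assert np.array_equal(a.allele_freqs, b.allele_freqs)


class TestAccessions:
    @pytest.fixture()
    def model(self):
        return sim.simulate_populations(3, 1000, fst=0.3, seed=1)

    def test_zero_somatic_rate_gives_identical_clones(self, model):
        accs = sim.simulate_accessions(model, 30, clone_spec=[4],
                                       somatic_rate=0.0, seed=2)
        members = [a for a in accs if a.clone_group == 0]
        assert len(members) == 4
        for a in members[1:]:
            assert np.array_equal(a.haplotype, members[0].haplotype)

    def test_clone_sizes_honored_exactly(self, model):
        accs = sim.simulate_accessions(model, 60, clone_spec=[2, 53], seed=3)
        sizes = {g: sum(a.clone_group == g for a in accs)
                 for g in (0, 1)}
        assert sorted(sizes.values()) == [2, 53]

    def test_somatic_divergence_matches_binomial_expectation(self, model):
        """Within a clone group, two members each flip loci at rate r, so
        the expected pairwise difference count is ~ 2 r L."""
        rate, L = 0.005, model.n_loci
        diffs = []
        for seed in range(8):
            accs = sim.simulate_accessions(model, 10, clone_spec=[10],
                                           somatic_rate=rate, seed=seed)
            haps = np.array([a.haplotype for a in accs])
            for i in range(len(haps)):
                for j in range(i + 1, len(haps)):
                    diffs.append((haps[i] != haps[j]).sum())
        expected = 2 * rate * L * (1 - rate)  # flips can coincide
        assert np.mean(diffs) == pytest.approx(2 * rate * L, rel=0.25)
        assert expected < 2 * rate * L  # sanity on the approximation

    def test_replicates_are_exact_flagged_copies(self, model):
        accs = sim.simulate_accessions(model, 20, n_replicate_pairs=3, seed=4)
        reps = [a for a in accs if a.is_replicate_of is not None]
        assert len(reps) == 3
        by_id = {a.accession_id: a for a in accs}
        for r in reps:
            assert np.array_equal(r.haplotype, by_id[r.is_replicate_of].haplotype)
            assert r.accession_id.endswith("_rep")

    def test_too_many_clones_rejected(self, model):
        with pytest.raises(ValueError):
            sim.simulate_accessions(model, 10, clone_spec=[8, 8], seed=0)


class TestDigest:
    def test_planted_genome_recovers_exact_inserts(self):
        """A hand-built genome with exactly three valid mixed inserts of
        30, 45 and 60 bp yields a three-fragment library."""
        rng = np.random.default_rng(5)

        def filler(n):
            # random sequence free of all three motifs (rejection sample)
            while True:
                s = "".join(rng.choice(list("ACGT"), size=n))
                ok = ("CTGCAG" not in s and "GGATC" not in s
                      and "GATCC" not in s
                      and not re.search("[AG]CATG[CT]", s))
                if ok:
                    return s

        genome = filler(80)
        for insert_len in (30, 45, 60):
            # distance between motif midpoints = insert length; the 80-bp
            # spacers keep the between-insert spans outside the size window
            genome += "CTGCAG" + filler(insert_len - 6) + "ACATGC" + filler(80)
        lib = sim.digest_genome(genome=genome, n_variants=0, n_pav=0,
                                chloroplast_copy_weight=1.0, seed=1)
        assert sorted(len(f.sequence) for f in lib.fragments) == [30, 45, 60]

    def test_alwI_site_excludes_fragment(self):
        rng = np.random.default_rng(6)
        clean = "TTATTTTATTTATTATTTTTATTTATTTTTTTAATTTAT"
        genome = ("T" * 40 + "CTGCAG" + clean + "ACATGC" + "T" * 40)
        lib = sim.digest_genome(genome=genome, n_variants=0, n_pav=0,
                                chloroplast_copy_weight=1.0, seed=1)
        assert len(lib) == 1
        bad = ("T" * 40 + "CTGCAG" + "GGATC" + clean[5:] + "ACATGC" + "T" * 40)
        with pytest.raises(sim.EmptyLibraryError):
            sim.digest_genome(genome=bad, n_variants=0, n_pav=0, seed=1)

    def test_no_nspI_site_means_no_mixed_fragments(self):
        genome = "T" * 30 + "CTGCAG" + "T" * 40 + "CTGCAG" + "T" * 30
        with pytest.raises(sim.EmptyLibraryError):
            sim.digest_genome(genome=genome, n_variants=0, n_pav=0, seed=0)

    def test_fragment_invariants_on_random_genome(self):
        lib = sim.digest_genome(genome_length=3_000_000, n_variants=15,
                                n_pav=5, seed=11)
        lo, hi = lib.insert_range
        n_decoy = 0
        for f in lib.fragments:
            assert lo <= len(f.sequence) <= hi
            assert f.sequence.startswith("CAG")  # PstI half-site
            assert re.fullmatch(".*[AG]CA", f.sequence)  # NspI half-site
            assert "GGATC" not in f.sequence and "GATCC" not in f.sequence
            n_decoy += f.copy_weight > 1
        assert n_decoy == 1
        for locus, (fid, offset, ref, alt) in lib.variant_map.items():
            frag = lib.get(fid)
            assert frag.sequence[offset] == ref
            assert ref != alt
            assert 3 <= offset <= len(frag.sequence) - 4


class TestReads:
    @pytest.fixture()
    def setup(self, tmp_path):
        model = sim.simulate_populations(2, 15, fst=0.3, seed=1)
        accs = sim.simulate_accessions(model, 4, seed=2)
        lib = sim.digest_genome(genome_length=2_000_000, n_variants=10,
                                n_pav=5, max_fragments=20,
                                chloroplast_copy_weight=5.0, seed=3)
        manifest = sim.make_manifest(accs, seed=4)
        return model, accs, lib, manifest, tmp_path

    def test_noiseless_reads_match_templates_exactly(self, setup):
        model, accs, lib, manifest, tmp = setup
        paths = sim.generate_reads(lib, accs, manifest, tmp / "r",
                                   mean_depth=10, error_rate=0.0, seed=5)
        by_id = {a.accession_id: a for a in accs}
        frag_var = {v[0]: (locus, v) for locus, v in lib.variant_map.items()}
        n_reads = 0
        with open(paths["reads"]) as fh:
            lines = fh.read().splitlines()
        assert len(lines) % 4 == 0
        for i in range(0, len(lines), 4):
            rid, seq = lines[i][1:], lines[i + 1]
            sid, fid, _ = rid.split("|")
            acc = by_id[sid]
            assert len(seq) == 77
            assert seq.startswith(manifest.barcodes[sid])
            frag = lib.get(fid)
            lv = frag_var.get(fid)
            allele = int(acc.haplotype[lv[0]]) if lv else 0
            expect = frag.sequence
            if lv and allele == 1:
                _, (_, off, _, alt) = lv
                expect = expect[:off] + alt + expect[off + 1:]
            body = seq[len(manifest.barcodes[sid]):]
            assert body.startswith(expect)
            n_reads += 1
        # truth table reconciles with the FASTQ
        import csv
        with open(paths["read_counts"]) as fh:
            total = sum(int(r["n_reads"]) for r in csv.DictReader(fh))
        assert total == n_reads

    def test_read_totals_follow_poisson_expectation(self, setup):
        model, accs, lib, manifest, tmp = setup
        paths = sim.generate_reads(lib, accs, manifest, tmp / "r2",
                                   mean_depth=20, error_rate=0.0, seed=7)
        with open(paths["reads"]) as fh:
            n_reads = sum(1 for _ in fh) // 4
        weight = sum(f.copy_weight for f in lib.fragments)
        # presence/absence deletions remove some fragment-sample pairs
        expected_max = len(accs) * 20 * weight
        assert 0.6 * expected_max < n_reads <= 1.1 * expected_max
        sd = np.sqrt(expected_max)
        assert abs(n_reads - expected_max) < 0.4 * expected_max + 6 * sd

    def test_chloroplast_decoy_draws_large_read_share(self, tmp_path):
        model = sim.simulate_populations(1, 5, fst=0.3, seed=1)
        accs = sim.simulate_accessions(model, 3, seed=2)
        lib = sim.digest_genome(genome_length=2_000_000, n_variants=5,
                                n_pav=0, max_fragments=100,
                                chloroplast_copy_weight=40.0, seed=3)
        manifest = sim.make_manifest(accs, seed=4)
        paths = sim.generate_reads(lib, accs, manifest, tmp_path / "r",
                                   mean_depth=10, seed=5)
        decoy = next(f.fragment_id for f in lib.fragments if f.copy_weight > 1)
        n_decoy = n_all = 0
        with open(paths["reads"]) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 0:
                    n_all += 1
                    n_decoy += line.split("|")[1] == decoy
        assert n_decoy / n_all > 0.10

    def test_byte_identical_under_same_seed(self, setup):
        model, accs, lib, manifest, tmp = setup
        p1 = sim.generate_reads(lib, accs, manifest, tmp / "a",
                                mean_depth=5, error_rate=0.01, seed=9)
        p2 = sim.generate_reads(lib, accs, manifest, tmp / "b",
                                mean_depth=5, error_rate=0.01, seed=9)
        assert p1["reads"].read_bytes() == p2["reads"].read_bytes()
        assert p1["genotypes"].read_bytes() == p2["genotypes"].read_bytes()

    def test_unknown_manifest_sample_rejected(self, setup):
        model, accs, lib, manifest, tmp = setup
        bad = sim.BarcodeManifest(barcodes={"GHOST": "ACGTC"})
        with pytest.raises(ValueError):
            sim.generate_reads(lib, accs, bad, tmp / "x", mean_depth=5, seed=0)


class TestManifest:
    def test_barcodes_unique_and_prefix_free(self):
        model = sim.simulate_populations(1, 5, fst=0.2, seed=0)
        accs = sim.simulate_accessions(model, 40, seed=1)
        manifest = sim.make_manifest(accs, seed=2)
        codes = list(manifest.barcodes.values())
        assert len(set(codes)) == len(codes)
        assert {len(c) for c in codes} == {5, 6, 7, 8}
        for a in codes:
            for b in codes:
                assert a == b or not b.startswith(a)

    def test_prefix_collision_rejected(self):
        with pytest.raises(ValueError):
            sim.BarcodeManifest(barcodes={"a": "ACGTC", "b": "ACGTCA"})
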