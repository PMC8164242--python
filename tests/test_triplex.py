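"""Triplex search: trivial Hoogsteen cases, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest

from triplextad.triplex import (TriplexParams, find_tts, merge_tfds,
                                merge_overlapping_matches, revcomp,
                                search_triplexes, select_dominant_isoform)

from oracles import brute_force_triplexes, brute_force_tts


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


class TestFindTTS:
    def test_purine_run_forward(self):
        seq = "T" * 10 + "AG" * 15 + "T" * 10
        tracts = find_tts(seq, TriplexParams())
        assert len(tracts) == 1
        s, e, strand = tracts[0]
        # the full purine run is covered; the 10 % mismatch allowance may
        # extend the tract slightly into the flanks
        assert strand == "+" and s <= 10 and e >= 40

    def test_pyrimidine_run_is_minus_strand(self):
        seq = "G" * 0 + "CT" * 15
        tracts = find_tts(seq, TriplexParams())
        assert [t[2] for t in tracts] == ["-"]

    def test_empty_sequence(self):
        assert find_tts("", TriplexParams()) == []

    def test_matches_brute_force_on_random_sequence(self, rng):
        params = TriplexParams(min_purine_fraction=0.8)  # denser tracts
        for _ in range(5):
            seq = random_seq(rng, 3000)
            got = [(int(s), int(e), st) for s, e, st in find_tts(seq, params)]
            assert got == brute_force_tts(seq, params)


class TestSearchTriplexes:
    def test_perfect_pyrimidine_motif(self):
        # 20 U/T bases read a 20-bp A-run in parallel orientation
        sites = search_triplexes({"r": "T" * 20}, {"c": "G" * 0 + "C" * 25 + "A" * 20 + "C" * 25},
                                 TriplexParams(motifs=("pyrimidine",)))
        assert len(sites) == 1
        row = sites.iloc[0]
        assert row["mismatches"] == 0 and row["motif"] == "pyrimidine"
        assert row["end"] - row["start"] >= 20

    def test_min_length_is_hard_cutoff(self):
        genome = {"c": "C" * 30 + "A" * 19 + "C" * 30}
        sites = search_triplexes({"r": "T" * 19}, genome, TriplexParams())
        assert len(sites) == 0

    def test_purine_motif_antiparallel_coordinates(self):
        # RNA 5'-GGGGGAAAAAAAAAAAAAAA-3' antiparallel on purine strand
        tract = "A" * 15 + "G" * 5
        rna = "G" * 5 + "A" * 15
        genome = {"c": "C" * 30 + tract + "C" * 30}
        sites = search_triplexes({"r": rna}, genome, TriplexParams(motifs=("purine",)))
        assert len(sites) == 1
        row = sites.iloc[0]
        assert row["start"] == 30 and row["end"] == 50
        assert row["rna_start"] == 0 and row["rna_end"] == 20
        assert row["mismatches"] == 0

    def test_id_collision_raises(self):
        with pytest.raises(ValueError, match="collision"):
            search_triplexes({"x": "T" * 30}, {"x": "A" * 30}, TriplexParams())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = TriplexParams()
        dna = list(random_seq(rng, 800))
        # plant a purine tract so the search has something to find
        tract = "".join("AG"[i] for i in rng.integers(0, 2, size=25))
        pos = int(rng.integers(100, 600))
        dna[pos:pos + 25] = tract
        genome = {"chr1": "".join(dna)}
        rna = list(random_seq(rng, 150))
        tfo = tract.translate(str.maketrans("AG", "TC"))  # pyrimidine code, parallel
        rna[40:65] = tfo
        seqs = {"r1": "".join(rna), "r2": random_seq(rng, 120)}
        got = search_triplexes(seqs, genome, params)
        want = brute_force_triplexes(seqs, genome, params)
        pd.testing.assert_frame_equal(got.reset_index(drop=True), want)

    def test_reverse_complement_symmetry(self, rng):
        params = TriplexParams()
        dna = list(random_seq(rng, 600))
        tract = "".join("AG"[i] for i in rng.integers(0, 2, size=24))
        dna[200:224] = tract
        genome = {"c": "".join(dna)}
        rc = {"c": revcomp(genome["c"])}
        rna = {"r": "T" * 10 + tract.translate(str.maketrans("AG", "TC")) + "G" * 10}
        a = search_triplexes(rna, genome, params)
        b = search_triplexes(rna, rc, params)
        assert len(a) == len(b)
        n = len(genome["c"])
        mirrored = sorted((n - e, n - s) for s, e in zip(b["start"], b["end"]))
        assert sorted(zip(a["start"], a["end"])) == mirrored

    def test_monotone_in_min_length_and_error_rate(self, rng):
        dna = list(random_seq(rng, 1000))
        for pos in (100, 400, 700):
            dna[pos:pos + 30] = "".join("AG"[i] for i in rng.integers(0, 2, size=30))
        genome = {"c": "".join(dna)}
        tfo = "".join(dna[400:430]).translate(str.maketrans("AG", "TC"))
        seqs = {"r": random_seq(rng, 50) + tfo + random_seq(rng, 50)}
        n_base = len(search_triplexes(seqs, genome, TriplexParams(min_length=20)))
        n_longer = len(search_triplexes(seqs, genome, TriplexParams(min_length=25)))
        n_strict = len(search_triplexes(
            seqs, genome, TriplexParams(min_length=20, max_error_rate=0.0)))
        assert n_longer <= n_base
        assert n_strict <= n_base


class TestTFDs:
    def _sites(self, intervals):
        return pd.DataFrame([
            {"lncrna_id": "L1", "isoform_id": "L1.1", "chrom": "c", "start": 0,
             "end": 20, "tts_strand": "+", "rna_start": s, "rna_end": e,
             "motif": "pyrimidine", "mismatches": 0}
            for s, e in intervals])

    def test_overlapping_intervals_merge(self):
        doms = merge_tfds(self._sites([(10, 35), (20, 45)]))
        assert len(doms) == 1
        assert (doms[0].rna_start, doms[0].rna_end) == (10, 45)
        assert doms[0].n_supporting_sites == 2

    def test_no_sites_no_domains(self):
        assert merge_tfds(self._sites([])) == []

    def test_matches_boolean_array_union(self, rng):
        intervals = [(int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 300, 40), rng.integers(20, 40, 40))]
        doms = merge_tfds(self._sites(intervals))
        mask = np.zeros(400, dtype=bool)
        for s, e in intervals:
            mask[s:e] = True
        runs = []
        i = 0
        while i < 400:
            if mask[i]:
                j = i
                while j < 400 and mask[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        assert [(d.rna_start, d.rna_end) for d in doms] == runs

    def test_mixed_lncrnas_rejected(self):
        df = self._sites([(0, 25)])
        df.loc[0, "lncrna_id"] = "L1"
        df2 = self._sites([(0, 25)])
        df2.loc[0, "lncrna_id"] = "L2"
        with pytest.raises(ValueError, match="multiple lncRNAs"):
            merge_tfds(pd.concat([df, df2], ignore_index=True))


class TestDominantIsoform:
    @pytest.mark.parametrize("counts,expect", [
        ({"iso1": 5, "iso2": 12}, "iso2"),
        ({"only": 3}, "only"),
        ({"a": 7, "b": 7}, "a"),
    ])
    def test_selection(self, counts, expect):
        assert select_dominant_isoform(counts) == expect

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_dominant_isoform({})


class TestPlantedRecovery:
    def test_every_planted_tfd_is_recovered(self, small_bundle):
        b = small_bundle
        sites = search_triplexes(b.lncrnas, b.genome, TriplexParams(), b.gene_of)
        for _, tfd in b.truth.tfds.iterrows():
            sub = sites[(sites["isoform_id"] == tfd["isoform_id"])
                        & (sites["rna_start"] < tfd["rna_end"])
                        & (sites["rna_end"] > tfd["rna_start"])]
            assert len(sub) > 0, f"planted TFD {tfd.to_dict()} not recovered"

    def test_no_tfds_means_almost_no_hits(self):
        from triplextad.synthetic import SyntheticConfig, simulate
        cfg = SyntheticConfig(seed=11, n_chroms=2, chrom_length=150_000, n_tads=8,
                              tad_length_range=(8_000, 14_000), n_lncrnas=40,
                              n_genes=10, tfd_count_dist=(1.0, 0.0, 0.0, 0.0))
        b = simulate(cfg)
        sites = search_triplexes(b.lncrnas, b.genome, TriplexParams(), b.gene_of)
        frac_with_hit = sites["lncrna_id"].nunique() / cfg.n_lncrnas
        assert frac_with_hit < 0.01
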