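"""Spacer matching, host prediction, benchmarking and the error model."""

import numpy as np
import pytest

from _oracles import brute_force_best, rc
from viromehost._seqs import random_seq
from viromehost.crisprdb import SpacerRecord
from viromehost.hostlink import (MatchThresholds, benchmark_thresholds,
                                 classify_host_range, erroneous_fraction,
                                 expected_false_count, false_multidomain_prob,
                                 map_functions, match_spacer, predict_hosts,
                                 random_null_recall, recall_rate)
from viromehost.synthio import SynthConfig, gen_community, mutate_sequence


def _embed(rng, spacer, contig_len=2000, pos=None, strand="+"):
    pos = int(rng.integers(0, contig_len - len(spacer))) if pos is None else pos
    bg = random_seq(rng, contig_len)
    ins = spacer if strand == "+" else rc(spacer)
    return bg[:pos] + ins + bg[pos + len(ins):]


class TestMatchSpacer:
    def test_exact_full_length_occurrence(self):
        rng = np.random.default_rng(0)
        spacer = random_seq(rng, 32)
        contig = _embed(rng, spacer, pos=700)
        m = match_spacer(spacer, contig)
        assert m is not None
        assert (m.identity, m.coverage, m.mismatches) == (1.0, 1.0, 0)
        assert m.contig_start == 700 and m.strand == "+"
        assert contig[m.contig_start : m.contig_end] == spacer

    def test_one_substitution_in_32mer_fails_identity(self):
        # 31/32 = 0.969 < 0.97, and no >=29 bp window can exclude a central
        # mismatch, so nothing passes
        rng = np.random.default_rng(1)
        spacer = random_seq(rng, 32)
        variant = spacer[:15] + mutate_sequence(spacer[15], 1, 3) + spacer[16:]
        contig = _embed(rng, variant, pos=500)
        assert match_spacer(spacer, contig) is None

    def test_one_substitution_in_40mer_passes(self):
        rng = np.random.default_rng(2)
        spacer = random_seq(rng, 40)
        variant = spacer[:20] + mutate_sequence(spacer[20:21], 1, 7) + spacer[21:]
        contig = _embed(rng, variant, pos=333)
        m = match_spacer(spacer, contig)
        assert m is not None
        assert m.mismatches == 1 and m.length == 40
        assert m.identity == pytest.approx(39 / 40)

    def test_reverse_strand_found_and_flagged(self):
        rng = np.random.default_rng(3)
        spacer = random_seq(rng, 36)
        contig = _embed(rng, spacer, pos=810, strand="-")
        m = match_spacer(spacer, contig)
        assert m is not None and m.strand == "-"
        assert rc(contig[m.contig_start : m.contig_end]) == spacer

    def test_spacer_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            match_spacer("ACGTACGTAC", "ACGT" * 100)

    def test_no_protospacer_means_no_match(self):
        rng = np.random.default_rng(4)
        assert match_spacer(random_seq(rng, 35), random_seq(rng, 3000)) is None

    @pytest.mark.parametrize("n_subs", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, n_subs):
        rng = np.random.default_rng(100 + n_subs)
        for i in range(25):
            length = int(rng.integers(19, 49))
            spacer = random_seq(rng, length)
            planted = mutate_sequence(spacer, min(n_subs, length), rng)
            strand = "+" if rng.random() < 0.5 else "-"
            contig = _embed(rng, planted, contig_len=1500, strand=strand)
            got = match_spacer(spacer, contig)
            want = brute_force_best(spacer, contig)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.matching_bases, got.mismatches, got.length) == want

    def test_relaxed_thresholds_still_match_oracle(self):
        """When loosened thresholds void the seed guarantee the matcher falls
        back to a full diagonal scan and stays oracle-exact."""
        thr = MatchThresholds(min_identity=0.85, min_coverage=0.80, max_mismatches=4)
        rng = np.random.default_rng(55)
        for _ in range(10):
            spacer = random_seq(rng, int(rng.integers(19, 41)))
            planted = mutate_sequence(spacer, 3, rng)
            contig = _embed(rng, planted, contig_len=800)
            got = match_spacer(spacer, contig, thr)
            want = brute_force_best(spacer, contig, 0.85, 0.80, 4)
            if want is None:
                assert got is None
            else:
                assert (got.matching_bases, got.mismatches, got.length) == want


class TestShortSpacerExactness:
    @pytest.mark.parametrize("length", range(19, 34))
    def test_full_length_single_mismatch_always_below_identity(self, length):
        assert (length - 1) / length < 0.97

    def test_central_mismatch_rejected_exact_accepted(self):
        rng = np.random.default_rng(6)
        for length in range(19, 34):
            spacer = random_seq(rng, length)
            mid = length // 2
            variant = spacer[:mid] + mutate_sequence(spacer[mid], 1, 9) + spacer[mid + 1:]
            exact_contig = _embed(rng, spacer, 600)
            variant_contig = _embed(rng, variant, 600)
            assert match_spacer(spacer, exact_contig) is not None
            assert match_spacer(spacer, variant_contig) is None


class TestPredictHosts:
    def test_planted_links_recovered_exactly(self, small_comm, small_spacer_db):
        links = predict_hosts(small_comm.viruses, small_spacer_db)
        predicted = {(l.contig_id, l.genome_id, l.genus) for l in links}
        assert predicted == small_comm.truth.true_links

    def test_primary_flag_unique_per_contig(self, small_comm, small_spacer_db):
        links = predict_hosts(small_comm.viruses, small_spacer_db)
        by_contig = {}
        for l in links:
            by_contig.setdefault(l.contig_id, []).append(l.primary)
        for flags in by_contig.values():
            assert sum(flags) == 1

    def test_shared_spacer_links_both_genomes(self):
        rng = np.random.default_rng(7)
        spacer = random_seq(rng, 34)
        contig = _embed(rng, spacer, 3000)
        db = [SpacerRecord("s1", spacer, "hostA", "Bacteria;g__A"),
              SpacerRecord("s2", spacer, "hostB", "Bacteria;g__B")]
        links = predict_hosts({"v1": contig}, db)
        assert {(l.genome_id, l.genus) for l in links} == {
            ("hostA", "g__A"), ("hostB", "g__B")}

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            predict_hosts({"v": "ACGT" * 100}, [])


class TestBenchmark:
    def _refs_and_db(self, seed=8, n=8, subs=0):
        """Substitutions are planted centrally so they cannot be trimmed off
        the alignment ends within the coverage budget."""
        rng = np.random.default_rng(seed)
        refs, db = {}, []
        for i in range(n):
            genus = f"g__H{i}"
            spacer = random_seq(rng, 40)
            variant = list(spacer)
            for j in range(subs):
                p = 20 + 3 * j - 3 * (subs // 2)
                variant[p] = mutate_sequence(spacer[p], 1, rng)
            contig = _embed(rng, "".join(variant), 2500)
            refs[f"v{i}"] = (contig, genus)
            db.append(SpacerRecord(f"s{i}", spacer, f"host{i}", f"Bacteria;{genus}"))
        return refs, db

    def test_defaults_on_clean_truth_are_perfect(self):
        refs, db = self._refs_and_db(subs=0)
        (res,) = benchmark_thresholds(refs, db, [MatchThresholds()])
        assert res.precision == 100.0 and res.recall == 100.0

    def test_perfect_identity_threshold_kills_mutated_recall(self):
        refs, db = self._refs_and_db(subs=1)
        (res,) = benchmark_thresholds(
            refs, db, [MatchThresholds(min_identity=1.0)])
        assert res.recall == 0.0

    def test_empty_db_reports_missing_precision(self):
        refs, _ = self._refs_and_db()
        (res,) = benchmark_thresholds(refs, [], [MatchThresholds()])
        assert res.recall == 0.0 and res.precision is None

    def test_precision_degrades_with_mutation_load(self):
        """More planted substitutions never help: recall at defaults falls
        monotonically (clean >= 1-sub >= 3-sub) on matched seeds."""
        recalls = []
        for subs in (0, 1, 3):
            refs, db = self._refs_and_db(seed=12, n=10, subs=subs)
            (res,) = benchmark_thresholds(refs, db, [MatchThresholds()])
            recalls.append(res.recall)
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[0] == 100.0


class TestRandomNull:
    def test_empty_db_scores_zero(self):
        assert random_null_recall([], 5, [1000], seed=0) == 0.0

    def test_adversarial_embedding_scores_one(self):
        rng = np.random.default_rng(13)
        spacer = random_seq(rng, 33)
        db = [SpacerRecord("s", spacer, "h", "Bacteria;g__X")]

        def sampler(r, length):
            bg = random_seq(r, length)
            return spacer + bg[len(spacer):]

        assert random_null_recall(db, 4, [500], seed=1, seq_sampler=sampler) == 1.0

    def test_true_random_hit_rate_is_negligible(self, small_spacer_db):
        frac = random_null_recall(small_spacer_db, 10, [10_000], seed=2,
                                  n_replicates=3)
        assert frac < 0.01


class TestErrorModel:
    def test_erroneous_fraction_reference_point(self):
        out = erroneous_fraction(0.70, 11.7)
        assert out.value == pytest.approx(5.983, abs=0.001)
        assert out.rounded == 6

    def test_erroneous_fraction_edges(self):
        assert erroneous_fraction(0.0, 5.0).value == 0.0
        assert erroneous_fraction(3.3, 3.3).value == pytest.approx(100.0)
        with pytest.raises(ValueError):
            erroneous_fraction(1.0, 0.0)

    def test_false_multidomain_probability(self):
        assert false_multidomain_prob(0.06, 2) == pytest.approx(0.1164, abs=1e-12)
        assert false_multidomain_prob(0.0, 5) == 0.0
        assert false_multidomain_prob(0.3, 1) == pytest.approx(0.3)

    def test_expected_false_count(self):
        out = expected_false_count(135, 0.1164)
        assert out.value == pytest.approx(15.714, abs=0.001)
        assert out.rounded == 16
        assert expected_false_count(0, 0.5).rounded == 0
        assert expected_false_count(100, 0.5).rounded == 50

    def test_recall_rate_reference_point(self):
        assert round(recall_rate(5879, 50_037), 1) == 11.7

    def test_consistency_monotone_in_links_and_error(self):
        base = expected_false_count(100, false_multidomain_prob(0.05, 2)).value
        assert expected_false_count(200, false_multidomain_prob(0.05, 2)).value > base
        assert expected_false_count(100, false_multidomain_prob(0.10, 2)).value > base


class _FakeLink:
    def __init__(self, contig, genome, lineage):
        self.contig_id = contig
        self.genome_id = genome
        self.lineage = lineage

    @property
    def genus(self):
        return self.lineage.split(";")[-1]

    @property
    def domain(self):
        return self.lineage.split(";")[0]


class TestHostRangeAndFunctions:
    def _links(self):
        return [
            _FakeLink("v1", "h1", "Bacteria;g__A"),
            _FakeLink("v2", "h1", "Bacteria;g__A"),
            _FakeLink("v2", "h2", "Bacteria;g__B"),
            _FakeLink("v3", "h1", "Bacteria;g__A"),
            _FakeLink("v3", "h3", "Archaea;g__C"),
        ]

    def test_host_range_labels(self):
        out = classify_host_range(self._links())
        assert out == {"v1": "specialist", "v2": "multi-genus", "v3": "cross-domain"}

    def test_function_counts_double_count_per_function(self):
        import pandas as pd

        table = pd.DataFrame([
            {"genus": "g__A", "function": "P-removal"},
            {"genus": "g__B", "function": "S-reduction"},
            {"genus": "g__B", "function": "Nitrification"},
        ])
        counts = map_functions(self._links(), table)
        # g__A linked by v1, v2, v3 -> 3; g__B linked by v2 -> both functions +1
        assert counts["P-removal"] == 3
        assert counts["S-reduction"] == 1 and counts["Nitrification"] == 1
        # g__C missing from the table -> unclassified fallback
        assert counts["unclassified"] == 1

    def test_duplicate_function_rows_rejected(self):
        import pandas as pd

        table = pd.DataFrame([{"genus": "g", "function": "f"},
                              {"genus": "g", "function": "f"}])
        with pytest.raises(ValueError):
            map_functions([], table)
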