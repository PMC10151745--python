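"""LCA consensus assignment: parsing, voting rules, filters, and invariants."""

import numpy as np
import pytest

from hitgen import RANK_DEPTH, fitting_align_oracle, lca_vote_oracle, random_hit_table

from floramap.synthio import ReferenceRecord, make_reference_db, make_taxonomy
from floramap.taxassign import (Assignment, AssignmentConfig, HitRecord,
                                assignment_rate, kingdom_filter, lca_assign,
                                load_hits, search_internal)


def _hit(qid="Q1", sid="r1", lin=("Viridiplantae", "Fam", "Gen", "Gen sp"),
         identity=99.0, alen=100, qlen=100, score=None):
    return HitRecord(query_id=qid, subject_id=sid, kingdom=lin[0], family=lin[1],
                     genus=lin[2], species=lin[3], identity=identity,
                     alignment_length=alen, query_length=qlen,
                     score=identity * alen / 100 if score is None else score)


class TestConfig:
    def test_defaults_valid(self):
        cfg = AssignmentConfig()
        assert cfg.max_hits == 300 and cfg.consensus == 0.51

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            AssignmentConfig(species_id=94.0)

    def test_consensus_range(self):
        with pytest.raises(ValueError):
            AssignmentConfig(consensus=0.3)


class TestLoadHits:
    def _write(self, tmp_path, rows, lineage_rows):
        hits = tmp_path / "hits.tsv"
        hits.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        lin = tmp_path / "lineage.tsv"
        lin.write_text("seq_id\tkingdom\tfamily\tgenus\tspecies\n" +
                       "".join("\t".join(r) + "\n" for r in lineage_rows))
        return hits, lin

    def test_empty_file(self, tmp_path):
        hits, lin = self._write(tmp_path, [], [("r1", "K", "F", "G", "S")])
        records, skipped = load_hits(hits, lin)
        assert records == [] and skipped == 0

    def test_parse_and_sort(self, tmp_path):
        rows = [["Q1", "r2", 96.0, 90, 3, 0, 1, 90, 1, 90, 1e-20, 86.4],
                ["Q1", "r1", 99.0, 95, 1, 0, 1, 95, 1, 95, 1e-30, 94.1]]
        lineage = [("r1", "K", "F", "G", "G s1"), ("r2", "K", "F", "G", "G s2")]
        hits, lin = self._write(tmp_path, rows, lineage)
        records, _ = load_hits(hits, lin, query_lengths={"Q1": 100})
        assert [r.subject_id for r in records] == ["r1", "r2"]
        assert records[0].query_length == 100

    def test_malformed_and_lineage_less_rows_skipped(self, tmp_path):
        rows = [["Q1", "r1", 99.0, 95, 1, 0, 1, 95, 1, 95, 1e-30, 94.1],
                ["Q1", "missing", 98.0, 95, 1, 0, 1, 95, 1, 95, 1e-30, 93.0],
                ["garbage"]]
        hits, lin = self._write(tmp_path, rows, [("r1", "K", "F", "G", "G s1")])
        with pytest.warns(UserWarning):
            records, skipped = load_hits(hits, lin)
        assert len(records) == 1 and skipped == 2


class TestSearchInternal:
    def test_identical_centroid_top_hit_100(self):
        tax = make_taxonomy(2, 2, 2, seed=0)
        db = make_reference_db(tax, seed=0)
        hits = search_internal({"Q1": db[0].sequence}, db)
        assert hits[0].subject_id == db[0].seq_id
        assert hits[0].identity == 100.0

    def test_equidistant_congeners_tie(self):
        seq = "ACGTACGTAC" * 10
        a = "T" + seq[1:]
        b = seq[:-1] + ("T" if seq[-1] != "T" else "A")
        refs = [ReferenceRecord("r1", a, ("K", "F", "G", "G s1")),
                ReferenceRecord("r2", b, ("K", "F", "G", "G s2"))]
        hits = search_internal({"Q1": seq}, refs)
        assert hits[0].score == hits[1].score
        assert {h.identity for h in hits} == {99.0}

    def test_identity_agrees_with_dp_oracle(self):
        rng = np.random.default_rng(50)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            q = "".join(rng.choice(bases, int(rng.integers(40, 100))))
            s = "".join(rng.choice(bases, int(rng.integers(40, 100))))
            hits = search_internal({"Q": q}, [ReferenceRecord("r", s, ("K", "F", "G", "S"))])
            _, matches, cols = fitting_align_oracle(q, s)
            assert hits[0].alignment_length == cols
            assert hits[0].identity == pytest.approx(100 * matches / cols)

    def test_empty_refdb_rejected(self):
        with pytest.raises(ValueError):
            search_internal({"Q": "ACGT"}, [])


class TestLcaAssign:
    def test_single_high_identity_hit_gives_species(self):
        a = lca_assign([_hit(identity=99.0)])
        assert a.resolved_rank == "species"
        assert a.species == "Gen sp" and a.genus == "Gen" and a.family == "Fam"

    def test_96_percent_hits_resolve_to_genus(self):
        """Species needs identity strictly above 97; 96% hits can still carry
        a genus-level consensus."""
        hits = [_hit(sid=f"r{i}", identity=96.0,
                     lin=("Viridiplantae", "Fam", "Gen", f"Gen sp{i}"))
                for i in range(10)]
        a = lca_assign(hits)
        assert a.resolved_rank == "genus"
        assert a.genus == "Gen" and a.species == ""

    def test_consensus_threshold_at_51_percent(self):
        """153 of 300 hits at >=98% on species A is exactly the 51% consensus."""
        hits = [_hit(sid=f"a{i}", identity=98.5,
                     lin=("Viridiplantae", "Fam", "Gen", "Gen spA")) for i in range(153)]
        hits += [_hit(sid=f"b{i}", identity=98.5,
                      lin=("Viridiplantae", "Fam", "Gen", "Gen spB")) for i in range(147)]
        a = lca_assign(hits)
        assert a.resolved_rank == "species" and a.species == "Gen spA"
        rank, lin = lca_vote_oracle(hits)
        assert (rank, lin[-1]) == ("species", "Gen spA")
        # one fewer vote for A drops below 51%: falls back to the shared genus
        b = lca_assign(hits[1:])
        assert b.resolved_rank == "genus"

    def test_low_coverage_hits_excluded(self):
        hits = [_hit(sid="good", identity=90.5, alen=85),
                _hit(sid="short", identity=99.9, alen=80)]  # coverage 0.80 not > 0.80
        a = lca_assign(hits)
        assert a.resolved_rank == "family"
        assert a.n_hits_used == 1

    def test_truncation_keeps_score_ties(self):
        cfg = AssignmentConfig(max_hits=5)
        hits = [_hit(sid=f"a{i}", identity=98.0,
                     lin=("Viridiplantae", "Fam", "Gen", "Gen spA")) for i in range(4)]
        hits += [_hit(sid=f"t{i}", identity=98.0, alen=99,
                      lin=("Viridiplantae", "Fam", "Gen", "Gen spB")) for i in range(3)]
        a = lca_assign(hits, cfg)
        # the three tied B hits share the cutoff score, so all seven vote
        assert a.n_hits_used == 7

    def test_no_rank_satisfied_is_unassigned(self):
        a = lca_assign([_hit(identity=85.0)])
        assert a.resolved_rank == "unassigned"

    def test_oracle_agreement_on_structured_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            hits = random_hit_table(rng)
            a = lca_assign(hits)
            rank, lin = lca_vote_oracle(hits)
            assert a.resolved_rank == rank
            if rank != "unassigned":
                assert a.lineage()[:RANK_DEPTH[rank] + 1] == ("Viridiplantae",) + lin[1:]

    def test_lineage_internally_consistent(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            a = lca_assign(random_hit_table(rng))
            if a.resolved_rank == "species":
                assert a.genus and a.family and a.species.startswith(a.genus)
            elif a.resolved_rank == "genus":
                assert a.family and a.species == "" and a.genus.startswith(a.family)
            elif a.resolved_rank == "family":
                assert a.genus == "" and a.species == ""

    def test_removing_dissenting_hit_never_demotes(self):
        rng = np.random.default_rng(321)
        checked = 0
        for _ in range(150):
            hits = random_hit_table(rng)
            a = lca_assign(hits)
            if a.resolved_rank == "unassigned":
                continue
            depth = RANK_DEPTH[a.resolved_rank]
            assigned = a.lineage()[1:depth + 1]
            dissent = [h for h in hits
                       if (h.family, h.genus, h.species)[:depth] != assigned]
            if not dissent:
                continue
            reduced = [h for h in hits if h is not dissent[0]]
            b = lca_assign(reduced)
            assert RANK_DEPTH[b.resolved_rank] >= depth
            checked += 1
        assert checked > 30


class TestKingdomFilterAndRates:
    def test_all_plants_unchanged(self):
        asg = [Assignment("o1", "species", "Viridiplantae", "F", "G", "G s"),
               Assignment("o2", "family", "Viridiplantae", "F")]
        kept, removed = kingdom_filter(asg)
        assert len(kept) == 2 and removed == {}

    def test_mixed_kingdoms_reported(self):
        asg = ([Assignment(f"o{i}", "species", "Viridiplantae", "F", "G", "G s")
                for i in range(8)]
               + [Assignment("o8", "species", "Fungi", "FF", "FG", "FG s"),
                  Assignment("o9", "unassigned")])
        kept, removed = kingdom_filter(asg)
        assert len(kept) == 8
        assert removed == {"Fungi": 1, "unassigned": 1}

    def test_spikein_truth_recovered(self):
        from floramap.synthio import make_spikein_records
        from floramap.taxassign import assign_all

        tax = make_taxonomy(2, 2, 2, seed=1)
        plants = make_reference_db(tax, seed=1)
        fungi = make_spikein_records(3, "Fungi", seed=2)
        refdb = plants + fungi
        centroids = {f"O{i}": r.sequence for i, r in enumerate(plants[:4] + fungi)}
        hits = search_internal(centroids, refdb)
        kept, removed = kingdom_filter(assign_all(hits))
        assert removed.get("Fungi", 0) == 3
        assert len(kept) == 4

    def test_assignment_rate_examples(self):
        assert assignment_rate(2, 36) == 5.6
        assert assignment_rate(36, 36) == 100.0
        assert assignment_rate(1, 3) == 33.3

    def test_assignment_rate_invalid(self):
        with pytest.raises(ValueError):
            assignment_rate(1, 0)
        with pytest.raises(ValueError):
            assignment_rate(5, 3)
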