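import numpy as np
import pytest
from Bio.Seq import Seq

from plangpcr.io_formats import SequenceRecord
from plangpcr.mining import (
    MiningParams,
    OrfAnnotation,
    ReceptorCandidate,
    Seed,
    SimilarityHit,
    exclusion_filter,
    find_orfs,
    flag_orf_ends,
    mine,
    orf_protein,
    predict_topology,
    search_seeds,
    topology_filter,
)


def _orf(transcript, **kw):
    orfs = find_orfs(transcript, kw.pop("min_aa_len", 2))
    assert orfs
    return max(orfs, key=lambda o: o.end - o.start)


class TestFindOrfs:
    def test_simple_forward_orf(self):
        t = SequenceRecord("t", "ATGAAATAA", "dna")
        (orf,) = find_orfs(t, 2)
        assert (orf.frame, orf.start, orf.end) == (1, 0, 9)

    def test_reverse_frame_orf_found(self):
        # oracle: brute-force scan of all 6 translated frames
        core = "ATGAAACCCTTTGGGTAA"
        rc = str(Seq(core).reverse_complement())
        t = SequenceRecord("t", "CCAG" + rc + "TTCA", "dna")
        orfs = find_orfs(t, 4)
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.frame < 0
        assert orf_protein(t, orf).seq == "MKPFG"
        # brute force: translate all 6 frames, look for MKPFG
        found = []
        for strand_seq in (t.seq, rc_seq := str(Seq(t.seq).reverse_complement())):
            for off in range(3):
                found.append(str(Seq(strand_seq[off:]).translate()))
        assert sum("MKPFG*" in f for f in found) == 1

    def test_all_n_transcript_has_no_orfs(self):
        t = SequenceRecord("t", "N" * 300, "dna")
        assert find_orfs(t, 2) == []

    def test_alphabet_mismatch_rejected(self):
        p = SequenceRecord("p", "MKLV", "protein")
        with pytest.raises(ValueError):
            find_orfs(p, 2)

    def test_min_length_filters(self):
        t = SequenceRecord("t", "ATGAAATAA", "dna")
        assert find_orfs(t, 3) == []


class TestFlagOrfEnds:
    def test_confident_orf_both_flags(self):
        # stop 3 nt before ATG, stop at 3' end
        t = SequenceRecord("t", "GGGTAAATGAAAAAATAA", "dna")
        orf = _orf(t)
        orf = flag_orf_ends(t, orf, 90)
        assert orf.n_term_ok and orf.c_term_ok and orf.orf_confident

    def test_edge_truncated_3prime_not_c_ok(self):
        t = SequenceRecord("t", "GGGTAAATGAAAAAAAAG", "dna")
        orf = _orf(t)
        orf = flag_orf_ends(t, orf, 90)
        assert orf.n_term_ok and not orf.c_term_ok and not orf.orf_confident

    def test_upstream_stop_outside_window(self):
        # in-frame stop 300 nt upstream of the ATG; window 90 -> not ok
        filler = "GGC" * 100
        t = SequenceRecord("t", "TAA" + filler + "ATGAAAAAATAA", "dna")
        orfs = find_orfs(t, 2)
        orf = [o for o in orfs if t.seq[o.start : o.start + 3] == "ATG"][0]
        flagged = flag_orf_ends(t, orf, 90)
        assert not flagged.n_term_ok
        assert flag_orf_ends(t, orf, 400).n_term_ok

    def test_invariant_under_3utr_extension(self):
        t1 = SequenceRecord("t", "GGGTAAATGAAAAAATAA", "dna")
        t2 = SequenceRecord("t", t1.seq + "GCGCGCGCGC", "dna")
        f1 = flag_orf_ends(t1, _orf(t1), 90)
        f2 = flag_orf_ends(t2, _orf(t2), 90)
        assert (f1.n_term_ok, f1.c_term_ok) == (f2.n_term_ok, f2.c_term_ok)

    def test_negative_window_rejected(self):
        t = SequenceRecord("t", "ATGAAATAA", "dna")
        with pytest.raises(ValueError):
            flag_orf_ends(t, _orf(t), -1)


class TestSearchSeeds:
    def test_identical_seed_ranks_first(self, receptor_protein):
        protein, _ = receptor_protein
        other = SequenceRecord("other", "ACDEFGHIKLNPQRSTVWY" * 10, "protein")
        hits = search_seeds(
            [protein], [Seed(protein, "gpcr_seed"), Seed(other, "other")]
        )
        assert hits[0].target_id == protein.id
        assert hits[0].e_value < 1e-50

    def test_shuffled_queries_have_no_significant_hits(self, rng):
        # empirical null: composition-matched shuffles against unrelated seeds
        seed_seq = "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), 300))
        seeds = [Seed(SequenceRecord("s0", seed_seq, "protein"), "gpcr_seed")]
        best = []
        for i in range(200):
            q = "".join(rng.permutation(list("MKWY" + "ACDEFGHILNPQRSTV" * 12)))
            hits = search_seeds([SequenceRecord(f"q{i}", q, "protein")], seeds)
            best.append(hits[0].e_value)
        assert min(best) > 1e-3

    def test_empty_seed_set_gives_no_hits(self, receptor_protein):
        assert search_seeds([receptor_protein[0]], []) == []

    def test_unknown_matrix_rejected(self, receptor_protein):
        with pytest.raises(ValueError):
            search_seeds([receptor_protein[0]], [], matrix_name="NOSUCH75")


def _hits(n_bad, n_good, e_bad=1e-20, e_good=1e-20):
    out = []
    for i in range(n_bad):
        out.append(SimilarityHit("q", f"bad{i}", "non_gpcr_tm", 100, e_bad))
    for i in range(n_good):
        out.append(SimilarityHit("q", f"good{i}", "gpcr_seed", 100, e_good))
    return out


class TestExclusionFilter:
    def test_half_of_top50_excludes(self):
        assert exclusion_filter(_hits(25, 25)) == "exclude"

    def test_just_under_half_keeps(self):
        assert exclusion_filter(_hits(24, 26)) == "keep"

    def test_weak_non_gpcr_hits_do_not_count(self):
        assert exclusion_filter(_hits(30, 20, e_bad=1e-8)) == "keep"

    def test_empty_hits_keep(self):
        assert exclusion_filter([]) == "keep"

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            exclusion_filter([], min_fraction=1.5)


class TestPredictTopology:
    def test_planted_seven_tm_protein(self, receptor_protein):
        protein, segs = receptor_protein
        topo = predict_topology(protein)
        assert topo.n_segments == 7
        assert topo.n_terminus_side == "out" and topo.c_terminus_side == "in"
        for (ps, pe), (ts, te) in zip(segs, topo.tm_segments):
            assert abs(ps - ts) <= 3 and abs(pe - te) <= 3

    def test_hydrophilic_protein_has_no_segments(self):
        p = SequenceRecord("p", "D" * 100, "protein")
        assert predict_topology(p).n_segments == 0

    def test_six_segment_parity(self):
        from plangpcr.synthetic import _receptor_architecture

        r = np.random.RandomState(3)
        seq, _, _ = _receptor_architecture(r, n_tm=6)
        topo = predict_topology(SequenceRecord("p6", seq, "protein"))
        assert topo.n_segments == 6
        assert topo.c_terminus_side == topo.n_terminus_side

    def test_short_protein_gives_zero_segments(self):
        p = SequenceRecord("p", "LLLLL", "protein")
        assert predict_topology(p).n_segments == 0

    def test_even_window_rejected(self, receptor_protein):
        with pytest.raises(ValueError):
            predict_topology(receptor_protein[0], window=18)


class TestTopologyFilter:
    def _candidate(self, confident, n_tm, n_side="out"):
        from plangpcr.synthetic import _receptor_architecture

        r = np.random.RandomState(5)
        seq, _, _ = _receptor_architecture(r, n_tm=n_tm, charged_in=(n_side == "out"))
        protein = SequenceRecord("c", seq, "protein")
        orf = OrfAnnotation(
            "c", 1, 0, 3 * len(seq) + 3,
            n_term_ok=confident, c_term_ok=confident, orf_confident=confident,
        )
        return ReceptorCandidate(
            protein=protein, orf=orf, topology=predict_topology(protein)
        )

    def test_confident_six_tm_excluded(self):
        c = topology_filter(self._candidate(True, 6))
        assert c.status == "excluded_topology"

    def test_non_confident_six_tm_retained(self):
        c = topology_filter(self._candidate(False, 6))
        assert c.status == "retained"

    def test_confident_correct_topology_retained(self):
        c = topology_filter(self._candidate(True, 7))
        assert c.status == "retained"

    def test_wrong_orientation_excluded(self):
        c = topology_filter(self._candidate(True, 7, n_side="in"))
        assert c.status == "excluded_topology"


class TestMine:
    def test_planted_transcriptome_fully_recovered(self, transcriptome):
        records, seeds, truth = transcriptome
        cands = mine(records, seeds)
        retained = {c for c, v in cands.items() if v.status == "retained"}
        assert retained == set(truth.receptor_ids)
        assert {
            c for c, v in cands.items() if v.status == "excluded_similarity"
        } == set(truth.decoy_ids)

    def test_mine_is_idempotent(self, transcriptome):
        records, seeds, truth = transcriptome
        first = mine(records, seeds)
        retained_records = [
            r for r in records
            if first[r.id].status == "retained"
        ] if all(r.id in first for r in records) else [
            r for r in records if r.id in first and first[r.id].status == "retained"
        ]
        second = mine(retained_records, seeds)
        assert {c for c, v in second.items() if v.status == "retained"} == {
            c for c, v in first.items() if v.status == "retained"
        }

    def test_second_round_admits_two_hop_candidate(self, rng):
        # chain: seed ~ bridge's N-domain; target ~ bridge's C-domain only
        from plangpcr.synthetic import _backtranslate, _receptor_architecture

        alpha = list("ACDEFGHIKLNPQRSTVWY")
        domain_x = "".join(rng.choice(alpha, 250))
        core, _, _ = _receptor_architecture(np.random.RandomState(21))
        bridge_protein = domain_x + core
        seeds = [Seed(SequenceRecord("seedX", domain_x, "protein"), "gpcr_seed")]
        r2 = np.random.RandomState(22)
        records = [
            SequenceRecord(
                "bridge", "ATG" + _backtranslate(r2, bridge_protein) + "TAA", "dna"
            ),
            SequenceRecord("target", "ATG" + _backtranslate(r2, core) + "TAA", "dna"),
        ]
        cands = mine(records, seeds)
        assert cands["bridge"].round_admitted == 1
        assert cands["target"].round_admitted == 2
        assert cands["target"].status == "retained"

    def test_empty_transcriptome(self, transcriptome):
        _, seeds, _ = transcriptome
        assert mine([], seeds) == {}

    def test_truncated_receptors_not_topology_excluded(self, transcriptome):
        records, seeds, truth = transcriptome
        cands = mine(records, seeds)
        for rid, comp in truth.completeness.items():
            if comp != "complete":
                assert not cands[rid].orf.orf_confident
                assert cands[rid].status == "retained"
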