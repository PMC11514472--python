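import numpy as np
import pytest

import hic_curator as hc
from hic_curator.errors import ParameterError
from hic_curator.simulate import (
    bin_true_positions,
    chromosome_runs,
    diff_events,
    oracle_detect,
)

from conftest import simulate_case


class TestMakeGenome:
    def test_seeded_determinism(self):
        a_contigs, a_doc = hc.make_genome(3, (100_000, 200_000), seed=1)
        b_contigs, b_doc = hc.make_genome(3, (100_000, 200_000), seed=1)
        assert a_contigs == b_contigs and a_doc == b_doc
        assert all(100_000 <= len(s) <= 200_000 for s in a_contigs.values())

    def test_gc_concentration(self):
        contigs, _ = hc.make_genome(2, (500_000, 500_000), gc=0.5, seed=2)
        gc = hc.gc_content(contigs)
        assert abs(gc - 0.5) < 0.02

    def test_doc_matches_fasta(self):
        contigs, doc = hc.make_genome(3, (100_000, 200_000), seed=3)
        assert doc.total_length == sum(len(s) for s in contigs.values())
        rebuilt = hc.build_fasta(doc, contigs, gap_len=0)
        assert "".join(rebuilt.values()) == "".join(contigs.values())


class TestFragmentAndShuffle:
    def test_zero_fraction_is_identity_permutation(self):
        _, doc = hc.make_genome(2, (200_000, 300_000), seed=4)
        shuffled, truth = hc.fragment_and_shuffle(doc, shuffle_frac=0.0, seed=5)
        n = len(shuffled.fragments)
        assert [s for row in shuffled.layout for s in row] == list(range(1, n + 1))
        assert truth.events == []

    def test_piece_count_bounds_for_one_megabase(self):
        _, doc = hc.make_genome(1, (1_000_000, 1_000_000), seed=6)
        shuffled, _ = hc.fragment_and_shuffle(doc, shuffle_frac=0.0, seed=7)
        # 1 Mb cut into 10-50 kb pieces: between 20 and 100 pieces
        assert 20 <= len(shuffled.fragments) <= 100
        assert all(f.length <= 50_000 for f in shuffled.fragments)

    def test_event_count_follows_rounding_rule(self):
        _, doc = hc.make_genome(2, (500_000, 600_000), seed=8)
        shuffled, truth = hc.fragment_and_shuffle(doc, shuffle_frac=0.6, seed=9)
        n = len(shuffled.fragments)
        assert len(truth.events) == round(0.6 * n)

    def test_total_length_conserved_and_events_disjoint(self):
        _, doc = hc.make_genome(2, (300_000, 400_000), seed=10)
        shuffled, truth = hc.fragment_and_shuffle(doc, seed=11)
        assert shuffled.total_length == doc.total_length
        spans = sorted((ev.start, ev.end) for ev in truth.events)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_bad_fraction_rejected(self):
        _, doc = hc.make_genome(1, (100_000, 100_000), seed=12)
        with pytest.raises(ParameterError):
            hc.fragment_and_shuffle(doc, shuffle_frac=1.5)


class TestSynthContactMap:
    def test_identity_permutation_decays_monotonically(self):
        _, doc = hc.make_genome(1, (300_000, 300_000), seed=13)
        _, truth = hc.fragment_and_shuffle(doc, shuffle_frac=0.0, seed=14)
        store = hc.synth_contact_map(truth, [10_000], hc.ContactModel(noise="none"))
        row0 = store.matrix(10_000)[0]
        assert np.all(np.diff(row0) < 0)

    def test_inverted_block_makes_butterfly_corner(self):
        """The far corner of an inverted block carries near-diagonal signal."""
        _c, _d, _s, truth, store, _p = simulate_case(
            seed=15, n_events=1, categories=("inversion",), n_contigs=1
        )
        ev = truth.events[0]
        res = 5000
        model = hc.ContactModel()
        mat = store.matrix(res)
        lo = ev.start // res + 1
        hi = (ev.end - 1) // res - 1
        if hi <= lo:
            pytest.skip("inverted piece too small at this resolution")
        # corner (lo-1, lo): apparently adjacent, truly ~block-width apart;
        # corner (lo-1, hi): apparently distant, truly adjacent
        apparent_far = mat[lo - 1, hi]
        apparent_near = mat[lo - 1, lo]
        width_bins = hi - lo
        assert apparent_far > apparent_near
        assert apparent_far > model.s0 * (1 + width_bins) ** -model.alpha

    def test_noise_free_maps_are_deterministic(self):
        _c, _d, _s, truth, _store, _p = simulate_case(seed=16, n_events=2)
        m = hc.ContactModel(noise="none")
        a = hc.synth_contact_map(truth, [10_000], m).matrix(10_000)
        b = hc.synth_contact_map(truth, [10_000], m).matrix(10_000)
        np.testing.assert_array_equal(a, b)

    def test_poisson_maps_are_seed_deterministic_and_symmetric(self):
        _c, _d, _s, truth, _store, _p = simulate_case(seed=17, n_events=1)
        m = hc.ContactModel(noise="poisson", seed=99)
        a = hc.synth_contact_map(truth, [10_000], m).matrix(10_000)
        b = hc.synth_contact_map(truth, [10_000], m).matrix(10_000)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a, a.T)

    def test_debris_rows_drop_out(self):
        _, doc = hc.make_genome(1, (400_000, 400_000), seed=18)
        _, truth = hc.fragment_and_shuffle(doc, seed=19, n_events=1, categories=("debris",))
        store = hc.synth_contact_map(truth, [10_000], hc.ContactModel(noise="none"))
        ev = truth.events[0]
        bins = range(ev.start // 10_000 + 1, (ev.end - 1) // 10_000)
        mat = store.matrix(10_000)
        for b in bins:
            assert np.all(mat[b, :] == 0)


class TestBinPermutation:
    def test_permutation_is_bijective_at_every_resolution(self, resolutions):
        _c, _d, _s, truth, _store, _p = simulate_case(seed=20, n_events=3)
        for res in resolutions:
            perm = truth.bin_permutation(res)
            assert sorted(perm) == list(range(len(perm)))

    def test_permutation_applied_then_inverted_is_identity(self, resolutions):
        _c, _d, _s, truth, _store, _p = simulate_case(seed=21, n_events=3)
        for res in resolutions:
            perm = truth.bin_permutation(res)
            inv = np.argsort(perm)
            assert np.array_equal(perm[inv], np.arange(len(perm)))


class TestOracleDetector:
    def test_empty_tile_gives_no_boxes(self):
        tile = hc.Tile(np.zeros((100, 100)), 1000, 0, 100_000, 0, 100_000, 1.0)
        assert oracle_detect(tile, [], []) == []

    def test_event_round_trips_within_one_bin(self, single_inversion_case):
        _c, _d, _shuf, truth, store, _p = single_inversion_case
        ev = truth.events[0]
        res = 5000
        w = next(
            w for w in hc.plan_windows(store.genome_length, res)
            if w.start <= ev.start and ev.end <= w.end
        )
        region = hc.fetch_region(store, res, (w.start, w.end), (w.start, w.end))
        tile = hc.render_tile(region, hc.quantile_threshold(region.values))
        det = hc.OracleDetector(truth)
        boxes = [b for b in det(tile) if b.category == "inversion"]
        assert len(boxes) == 1
        call = hc.box_to_genome(boxes[0], tile)
        assert abs(call.x_start - ev.start) <= res
        assert abs(call.x_end - ev.end) <= res

    def test_event_straddling_tile_edge_is_clipped(self):
        tile = hc.Tile(np.zeros((100, 100)), 1000, 50_000, 150_000, 50_000, 150_000, 1.0)
        boxes = oracle_detect(tile, [hc.Event("debris", 0, 60_000)], [])
        assert len(boxes) == 1
        assert boxes[0].x1 == 0.0 and boxes[0].x2 == pytest.approx(10.0)


class TestDiffEvents:
    def test_clean_document_has_no_events(self):
        _, doc = hc.make_genome(2, (200_000, 300_000), seed=22)
        shuffled, truth = hc.fragment_and_shuffle(doc, shuffle_frac=0.0, seed=23)
        assert diff_events(shuffled, truth.contig_lengths) == []

    def test_recovers_planted_event_intervals(self):
        for cats in [("translocation",), ("inversion",)]:
            _c, _d, shuf, truth, _s, _p = simulate_case(seed=24, n_events=2, categories=cats)
            derived = diff_events(shuf, truth.contig_lengths)
            got = {(ev.category, ev.start, ev.end) for ev in derived}
            want = {(ev.category, ev.start, ev.end) for ev in truth.events}
            assert got == want

    def test_chromosome_runs_merge_contiguous_fragments(self):
        _, doc = hc.make_genome(3, (200_000, 250_000), seed=25)
        shuffled, truth = hc.fragment_and_shuffle(doc, shuffle_frac=0.0, seed=26)
        assert chromosome_runs(shuffled, truth.contig_lengths) == truth.chromosome_spans


def test_end_to_end_identity_over_multiple_seeds():
    """simulate -> oracle detect -> correct restores order and signs exactly."""
    for seed, k in [(30, 1), (31, 2), (32, 5)]:
        _c, _d, shuf, truth, _s, provider = simulate_case(seed=seed, n_events=k)
        det = hc.OracleDetector(truth)
        final, logs = hc.run_iterations(
            shuf, det, provider, hc.CorrectionConfig(error_min_len=1000)
        )
        n = len(final.fragments)
        assert [s for row in final.layout for s in row] == list(range(1, n + 1))
        assert logs[-1].counts["translocation"] + logs[-1].counts["inversion"] == 0
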