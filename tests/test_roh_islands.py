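"""ROH detection, incidence, island calling, and cross-breed intersection."""

import numpy as np
import pytest

from merinoscan.roh_islands import (RohSegment, call_islands,
                                    cross_breed_island_overlaps, detect_roh,
                                    long_island_fraction, snp_roh_incidence)
from merinoscan.reference_tables import ROH_ISLANDS, roh_island_tracks

from conftest import make_dataset, make_map


def oracle_roh(dataset, min_snps=25, min_length=500_000, max_gap=250_000,
               density=100_000):
    """2-D window enumeration oracle: every (i, j) window checked directly."""
    out = []
    sm = dataset.snp_map
    for c in np.unique(sm.chromosome):
        idx = np.flatnonzero(sm.chromosome == c)
        pos = sm.position_bp[idx].astype(int)
        Lc = len(idx)
        gaps = np.diff(pos)
        for s in range(dataset.n_samples):
            g = dataset.dosages[s, idx]
            hom = (g == 0) | (g == 2)
            cum = np.concatenate(([0], np.cumsum(hom)))
            for i in range(Lc):
                for j in range(i, Lc):
                    if cum[j + 1] - cum[i] != j - i + 1:
                        continue                      # not all homozygous
                    if j > i and gaps[i:j].max() > max_gap:
                        continue                      # internal gap too wide
                    # maximality: no valid extension on either side
                    if i > 0 and hom[i - 1] and gaps[i - 1] <= max_gap:
                        continue
                    if j < Lc - 1 and hom[j + 1] and gaps[j] <= max_gap:
                        continue
                    n = j - i + 1
                    span = pos[j] - pos[i]
                    if (n >= min_snps and span >= min_length
                            and n * density >= span):
                        out.append((str(dataset.sample_id[s]), int(c),
                                    int(pos[i]), int(pos[j]), n))
    return sorted(out)


def as_tuples(segments):
    return sorted((s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snps)
                  for s in segments)


def random_roh_instance(rng):
    L = int(rng.integers(30, 200))
    gaps = rng.choice([20_000, 40_000, 80_000, 300_000],
                      p=[0.4, 0.3, 0.2, 0.1], size=L - 1)
    pos = np.concatenate(([rng.integers(1, 1000)], )).astype(np.int64)
    pos = np.concatenate((pos, pos[0] + np.cumsum(gaps)))
    n = int(rng.integers(1, 4))
    d = rng.choice([0.0, 1.0, 2.0, np.nan], p=[0.35, 0.2, 0.35, 0.1],
                   size=(n, L))
    if rng.random() < 0.6:          # plant a long homozygous stretch
        i = int(rng.integers(0, max(1, L - 60)))
        w = int(rng.integers(20, 60))
        d[rng.integers(0, n), i:i + w] = rng.choice([0.0, 2.0])
    return make_dataset(d, snp_map=make_map(pos))


class TestDetectRoh:
    def test_too_few_snps(self):
        d = np.full((1, 24), 2.0)
        ds = make_dataset(d, snp_map=make_map(np.arange(24) * 26_000 + 1))
        assert detect_roh(ds) == []                  # 24 < 25 SNPs

    def test_too_short_span(self):
        d = np.full((1, 30), 0.0)
        ds = make_dataset(d, snp_map=make_map(np.arange(30) * 13_790 + 1))
        assert detect_roh(ds) == []                  # ~400 kb < 500 kb

    def test_qualifying_run_found_exactly_once(self):
        d = np.full((1, 40), 2.0)
        ds = make_dataset(d, snp_map=make_map(np.arange(40) * 25_000 + 1))
        segs = detect_roh(ds)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_snps == 40 and seg.length_bp == 39 * 25_000

    def test_heterozygote_splits_run(self):
        d = np.full((1, 60), 2.0)
        d[0, 30] = 1.0
        ds = make_dataset(d, snp_map=make_map(np.arange(60) * 25_000 + 1))
        segs = detect_roh(ds)
        # halves of 30 and 29 SNPs spanning ~725 kb each qualify separately
        assert len(segs) == 2
        assert segs[0].end_bp < 30 * 25_000 + 1 <= segs[1].start_bp

    def test_wide_gap_splits_run(self):
        pos = np.concatenate([np.arange(30) * 25_000 + 1,
                              np.arange(30) * 25_000 + 1_200_000])
        d = np.full((1, 60), 0.0)
        ds = make_dataset(d, snp_map=make_map(pos))
        segs = detect_roh(ds)
        assert len(segs) == 2 and all(s.n_snps == 30 for s in segs)

    def test_density_rule_enforced(self):
        # 26 SNPs spanning 3 Mb: density 1/115 kb < 1/100 kb
        d = np.full((1, 26), 2.0)
        ds = make_dataset(d, snp_map=make_map(np.arange(26) * 120_000 + 1))
        assert detect_roh(ds) == []

    def test_matches_window_enumeration_oracle(self, rng):
        for _ in range(60):
            ds = random_roh_instance(rng)
            assert as_tuples(detect_roh(ds)) == oracle_roh(ds)

    def test_every_output_satisfies_all_rules(self, rng):
        for _ in range(20):
            ds = random_roh_instance(rng)
            sm = ds.snp_map
            for seg in detect_roh(ds):
                i = int(np.flatnonzero(sm.position_bp == seg.start_bp)[0])
                j = int(np.flatnonzero(sm.position_bp == seg.end_bp)[0])
                s = int(np.flatnonzero(ds.sample_id == seg.sample_id)[0])
                g = ds.dosages[s, i:j + 1]
                assert ((g == 0) | (g == 2)).all()
                assert seg.n_snps == j - i + 1 >= 25
                assert seg.length_bp >= 500_000
                assert np.diff(sm.position_bp[i:j + 1]).max() <= 250_000
                assert seg.n_snps * 100_000 >= seg.length_bp


class TestIncidence:
    def test_no_segments_all_zero(self):
        snp_map = make_map(np.arange(1, 11) * 1000)
        np.testing.assert_array_equal(
            snp_roh_incidence([], snp_map, 5), np.zeros(10))

    def test_shared_segment_gives_unit_incidence(self):
        snp_map = make_map(np.arange(1, 11) * 100_000)
        segs = [RohSegment(f"s{i}", 1, 300_000, 700_000, 5) for i in range(4)]
        inc = snp_roh_incidence(segs, snp_map, 4)
        inside = (snp_map.position_bp >= 300_000) & (snp_map.position_bp <= 700_000)
        assert (inc[inside] == 1.0).all() and (inc[~inside] == 0.0).all()

    def test_matches_per_snp_counting_oracle_and_order_invariance(self, rng):
        snp_map = make_map(np.cumsum(rng.integers(10_000, 200_000, 80)),
                           np.sort(rng.integers(1, 4, 80)))
        segs = []
        for s in range(6):
            for _ in range(rng.integers(0, 4)):
                c = int(rng.integers(1, 4))
                on_c = snp_map.position_bp[snp_map.chromosome == c]
                a, b = sorted(rng.choice(on_c, 2, replace=False).tolist())
                segs.append(RohSegment(f"s{s}", c, int(a), int(b), 0))
        inc = snp_roh_incidence(segs, snp_map, 6)
        expected = np.zeros(80)
        for k in range(80):
            owners = {seg.sample_id for seg in segs
                      if seg.covers(int(snp_map.chromosome[k]),
                                    int(snp_map.position_bp[k]))}
            expected[k] = len(owners) / 6
        np.testing.assert_allclose(inc, expected)
        perm = [segs[i] for i in rng.permutation(len(segs))]
        np.testing.assert_allclose(snp_roh_incidence(perm, snp_map, 6), inc)

    def test_unknown_sample_rejected(self):
        snp_map = make_map([1000])
        with pytest.raises(KeyError):
            snp_roh_incidence([RohSegment("ghost", 1, 1, 1000, 1)], snp_map,
                              1, sample_ids=["s1"])


def oracle_islands(incidence, snp_map, percentile):
    v = np.sort(incidence)
    thr = v[max(1, int(np.ceil(percentile * len(v)))) - 1]
    flagged = (incidence >= thr) & (incidence > 0)
    islands = []
    current = None
    for k in range(len(incidence)):
        if flagged[k]:
            if current and snp_map.chromosome[k] == current[0] \
                    and current[-1] == k - 1:
                current = current[:2] + [k]
                islands[-1] = (current[0], current[1], k)
            else:
                current = [int(snp_map.chromosome[k]), k, k]
                islands.append((current[0], k, k))
        else:
            current = None
    return [(c, int(snp_map.position_bp[i]), int(snp_map.position_bp[j]),
             j - i + 1) for c, i, j in islands]


class TestIslands:
    def test_single_hot_snp_single_island(self):
        snp_map = make_map(np.arange(1, 1001) * 10_000)
        inc = np.zeros(1000)
        inc[123] = 0.9
        track = call_islands(inc, snp_map, "X")
        assert track.islands == [(1, 124 * 10_000, 124 * 10_000, 1)]

    def test_published_single_snp_island_is_legal(self):
        appenninica = dict(roh_island_tracks()[8].islands_frame().iloc[0])
        assert appenninica["start_bp"] == appenninica["end_bp"] == 44_524_519
        assert appenninica["n_snps"] == 1

    def test_matches_threshold_merge_oracle(self, rng):
        for _ in range(40):
            L = int(rng.integers(20, 300))
            snp_map = make_map(np.cumsum(rng.integers(10_000, 100_000, L)),
                               np.sort(rng.integers(1, 4, L)))
            inc = np.round(rng.random(L) ** 3, 3)
            track = call_islands(inc, snp_map, "X", percentile=0.9)
            assert track.islands == oracle_islands(inc, snp_map, 0.9)

    def test_constant_incidence_warns(self):
        snp_map = make_map([1000, 2000])
        with pytest.warns(UserWarning, match="degenerate"):
            call_islands(np.array([0.5, 0.5]), snp_map, "X")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            call_islands(np.array([]), make_map([1000]).subset([]), "X")


class TestCrossBreedOverlaps:
    def test_published_islands_give_three_overlaps(self):
        records = cross_breed_island_overlaps(roh_island_tracks())
        assert len(records) == 3
        by_pair = {frozenset(p): (c, iv) for p, c, iv in records}
        assert by_pair[frozenset(("Chinese Merino", "Appenninica"))] == \
            (16, (30_100_068, 30_670_323))
        assert by_pair[frozenset(("Spanish Merino", "Gentile di Puglia"))] == \
            (12, (47_013_871, 52_019_776))

    def test_disjoint_tracks_empty(self):
        tracks = roh_island_tracks()
        assert cross_breed_island_overlaps([tracks[5], tracks[6]]) == []

    def test_matches_all_pairs_brute_force(self, rng):
        from merinoscan.roh_islands import IslandTrack
        from merinoscan.genotype_io import SnpMap
        empty = SnpMap(np.array([], dtype=object), np.array([], dtype=int),
                       np.array([], dtype=int))
        tracks = []
        for b in range(4):
            islands = []
            for c in range(1, 3):
                pos = 0
                for _ in range(rng.integers(0, 4)):
                    s = pos + int(rng.integers(1, 5_000_000))
                    e = s + int(rng.integers(0, 8_000_000))
                    islands.append((c, s, e, 1))
                    pos = e + 1
            tracks.append(IslandTrack(f"B{b}", empty, np.array([]), 0.1,
                                      islands))
        got = cross_breed_island_overlaps(tracks)
        expected = []
        for x in range(4):
            for y in range(x + 1, 4):
                for ca, sa, ea, _ in tracks[x].islands:
                    for cb, sb, eb, _ in tracks[y].islands:
                        if ca == cb and max(sa, sb) <= min(ea, eb):
                            expected.append(((f"B{x}", f"B{y}"), ca,
                                             (max(sa, sb), min(ea, eb))))
        assert sorted(got) == sorted(expected)


class TestLongIslandFraction:
    def test_published_proportions(self):
        tracks = {t.breed: t for t in roh_island_tracks()}
        assert long_island_fraction(tracks["Gentile di Puglia"]) \
            == pytest.approx(1 / 3, abs=1e-9)
        assert long_island_fraction(tracks["Sopravissana"]) == pytest.approx(0.5)
        assert len(ROH_ISLANDS["Gentile di Puglia"][1]) == 21
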