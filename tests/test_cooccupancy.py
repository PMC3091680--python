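import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from creseq.cooccupancy import (
    DensityMatrix,
    DensityTrack,
    call_specific_loci,
    compute_density,
    extract_matrix,
    kmeans_cluster,
    merge_union,
    venn_counts,
)
from creseq.records import DataError, Read

from .conftest import SEED, make_peak
from .oracles import oracle_density, oracle_kmeans_sse


def _reads(chrom_positions):
    return [Read(chrom=c, pos5=p) for c, p in chrom_positions]


class TestComputeDensity:
    def test_counting(self):
        track = compute_density(
            _reads([("chr1", 0), ("chr1", 10), ("chr1", 30)]),
            {"chr1": 50},
            bin_width=25,
        )
        assert track.bins("chr1").tolist() == [2, 1]

    def test_no_reads_all_zero(self):
        track = compute_density([], {"chr1": 100}, bin_width=25)
        assert track.bins("chr1").sum() == 0

    def test_conserves_reads_exactly(self, default_sim):
        sizes = {c: len(s) for c, s in default_sim.genome.items()}
        track = compute_density(default_sim.reads_A, sizes)
        assert track.library_size == len(default_sim.reads_A)

    def test_read_beyond_chromosome_end_errors(self):
        with pytest.raises(DataError, match="chr1:120"):
            compute_density(_reads([("chr1", 120)]), {"chr1": 100})

    def test_matches_naive_recount(self, rng):
        reads = _reads(
            [("chr1", int(p)) for p in rng.integers(0, 10_000, size=10_000)]
        )
        track = compute_density(reads, {"chr1": 10_000}, bin_width=25)
        assert track.bins("chr1").tolist() == oracle_density(
            reads, "chr1", 400, 25
        )


class TestExtractMatrix:
    def test_column_count(self):
        track = compute_density([], {"chr1": 100_000}, bin_width=25)
        m = extract_matrix(track, [("chr1", 50_000)], flank=5_000)
        assert m.values.shape == (1, 400)

    def test_isolated_pileup_mass_is_central(self):
        reads = _reads([("chr1", 50_000 + d) for d in range(-40, 60)])
        track = compute_density(reads, {"chr1": 100_000})
        m = extract_matrix(track, [("chr1", 50_000)])
        central = m.values[0, m.central_columns()]
        assert central.sum() == 100
        assert m.values[0].sum() == 100  # nothing in the flanks

    def test_edge_locus_zero_padded(self):
        track = compute_density(_reads([("chr1", 10)]), {"chr1": 100_000})
        m = extract_matrix(track, [("chr1", 1_000)], flank=5_000)
        assert m.values[0].sum() == 1  # the read is in-range; rest padded

    def test_rpm_and_log_transform(self):
        reads = _reads([("chr1", 50_000)] * 10)
        track = compute_density(reads, {"chr1": 100_000})
        m = extract_matrix(track, [("chr1", 50_000)], rpm=True, log2=True)
        assert m.transform_label == "rpm+log2"
        assert m.values.max() == pytest.approx(np.log2(1 + 10 * 1e6 / 10))

    def test_unknown_chromosome_errors(self):
        track = compute_density([], {"chr1": 1_000})
        with pytest.raises(DataError):
            extract_matrix(track, [("chrX", 500)])

    def test_row_sums_match_bruteforce_window_recounts(self, rng):
        positions = rng.integers(0, 100_000, size=10_000)
        reads = _reads([("chr1", int(p)) for p in positions])
        track = compute_density(reads, {"chr1": 100_000}, bin_width=25)
        for _ in range(50):
            center = int(rng.integers(5_000, 95_000))
            m = extract_matrix(track, [("chr1", center)], flank=5_000)
            lo_bin = (center - 5_000) // 25
            expected = sum(
                1 for p in positions if lo_bin * 25 <= p < lo_bin * 25 + 10_000
            )
            assert m.values[0].sum() == expected


def _matrix_from_rows(rows):
    rows = np.asarray(rows, dtype=float)
    return DensityMatrix(
        loci=[("chr1", i) for i in range(len(rows))],
        values=rows,
        raw_counts=rows.astype(int),
        bin_width=25,
        flank=rows.shape[1] * 25 // 2,
    )


class TestKmeans:
    def test_separated_clouds_perfectly_split(self, rng):
        a = rng.normal(0, 0.1, size=(20, 8))
        b = rng.normal(10, 0.1, size=(20, 8))
        m = _matrix_from_rows(np.vstack([a, b]))
        result = kmeans_cluster(m, k=2, seed=SEED)
        labels = result.labels
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]
        within = ((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum()
        assert result.sse == pytest.approx(within, rel=1e-9)

    def test_identical_rows_degenerate(self):
        m = _matrix_from_rows(np.ones((10, 6)))
        result = kmeans_cluster(m, k=2, seed=SEED)
        assert result.sse == 0.0

    def test_sse_trace_non_increasing(self, rng):
        m = _matrix_from_rows(rng.normal(0, 1, size=(60, 12)))
        result = kmeans_cluster(m, k=3, seed=SEED)
        trace = np.array(result.sse_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_too_few_rows_errors(self):
        with pytest.raises(DataError):
            kmeans_cluster(_matrix_from_rows(np.ones((1, 4))), k=2, seed=0)

    def test_exactly_one_occupied_cluster_for_k2(self, rng):
        rows = np.vstack([
            np.zeros((10, 40)),
            np.pad(np.full((10, 4), 50.0), ((0, 0), (18, 18))),
        ])
        result = kmeans_cluster(_matrix_from_rows(rows), k=2, seed=SEED)
        assert result.occupied.sum() == 1
        # the occupied cluster is the one holding the high-signal rows
        occupied_cluster = int(np.flatnonzero(result.occupied)[0])
        assert (result.labels[10:] == occupied_cluster).all()

    def test_matches_exhaustive_oracle_in_separated_regime(self, rng):
        rows = np.vstack([
            rng.normal(0, 0.2, size=(6, 4)),
            rng.normal(8, 0.2, size=(6, 4)),
        ])
        result = kmeans_cluster(_matrix_from_rows(rows), k=2, seed=SEED)
        best_sse, _ = oracle_kmeans_sse(rows, k=2)
        assert result.sse >= best_sse - 1e-9  # K-means cannot beat optimum
        assert result.sse == pytest.approx(best_sse, rel=1e-9)

    def test_never_beats_oracle_on_hard_instance(self, rng):
        rows = rng.normal(0, 1, size=(12, 3))
        result = kmeans_cluster(_matrix_from_rows(rows), k=2, seed=SEED)
        best_sse, _ = oracle_kmeans_sse(rows, k=2)
        assert result.sse >= best_sse - 1e-9

    def test_agrees_with_sklearn(self, rng):
        from sklearn.cluster import KMeans

        rows = np.vstack([
            rng.normal(0, 1, size=(30, 10)),
            rng.normal(6, 1, size=(30, 10)),
        ])
        ours = kmeans_cluster(_matrix_from_rows(rows), k=2, seed=SEED)
        sk = KMeans(n_clusters=2, n_init=10, random_state=SEED).fit(rows)
        assert ours.sse == pytest.approx(sk.inertia_, rel=1e-6)
        agree = (ours.labels == sk.labels_).mean()
        assert agree in (0.0, 1.0)  # same partition up to label swap


class TestCallSpecificLoci:
    def test_recovers_planted_shared_vs_specific(self, default_sim):
        from sklearn.metrics import adjusted_rand_score

        sim = default_sim
        sizes = {c: len(s) for c, s in sim.genome.items()}
        track_b = compute_density(sim.reads_B, sizes)
        calls, _, _ = call_specific_loci(sim.peaks_A, track_b, seed=SEED)
        truth_by_pos = dict(zip(sim.truth_sites.pos, sim.truth_sites.occupancy))
        truth = [
            "shared" if truth_by_pos[p.summit] == "shared" else "A_specific"
            for p in sim.peaks_A
        ]
        accuracy = np.mean([c == t for c, t in zip(calls, truth)])
        assert accuracy >= 0.95
        assert adjusted_rand_score(truth, calls) >= 0.9

    def test_b_equals_a_yields_all_shared(self, default_sim):
        sizes = {c: len(s) for c, s in default_sim.genome.items()}
        track_a = compute_density(default_sim.reads_A, sizes)
        calls, _, _ = call_specific_loci(default_sim.peaks_A, track_a, seed=SEED)
        assert set(calls) == {"shared"}

    def test_background_only_b_yields_all_specific(self, default_sim, rng):
        sizes = {c: len(s) for c, s in default_sim.genome.items()}
        bg = _reads([
            ("chr1", int(p)) for p in rng.integers(0, sizes["chr1"], 10_000)
        ] + [
            ("chr2", int(p)) for p in rng.integers(0, sizes["chr2"], 10_000)
        ])
        track = compute_density(bg, sizes)
        calls, _, _ = call_specific_loci(default_sim.peaks_A, track, seed=SEED)
        assert set(calls) == {"A_specific"}

    def test_fewer_loci_than_k_errors(self, default_sim):
        sizes = {c: len(s) for c, s in default_sim.genome.items()}
        track = compute_density([], sizes)
        with pytest.raises(DataError):
            call_specific_loci(default_sim.peaks_A[:1], track, k=2, seed=0)

    def test_accuracy_monotone_in_enrichment(self):
        from creseq.simulate import SimulationConfig, simulate_study

        accuracies = []
        for enrichment in (2.0, 15.0, 60.0):
            sim = simulate_study(
                SimulationConfig(seed=SEED, site_enrichment=enrichment)
            )
            sizes = {c: len(s) for c, s in sim.genome.items()}
            track_b = compute_density(sim.reads_B, sizes)
            calls, _, _ = call_specific_loci(sim.peaks_A, track_b, seed=SEED)
            truth_by_pos = dict(
                zip(sim.truth_sites.pos, sim.truth_sites.occupancy)
            )
            truth = [
                "shared" if truth_by_pos[p.summit] == "shared" else "A_specific"
                for p in sim.peaks_A
            ]
            accuracies.append(np.mean([c == t for c, t in zip(calls, truth)]))
        assert accuracies[0] <= accuracies[1] + 0.05
        assert accuracies[1] <= accuracies[2] + 0.05
        assert accuracies[2] >= 0.95


class TestMergeUnion:
    def test_toy_example(self):
        a = [make_peak("chr1", 100, 200), make_peak("chr1", 500, 600)]
        b = [make_peak("chr1", 150, 250), make_peak("chr2", 100, 200)]
        merged = merge_union(a, b)
        assert len(merged) == 3
        assert venn_counts(merged) == {"A_only": 1, "both": 1, "B_only": 1}
        both = [iv for iv, label in merged if label == "both"]
        assert (both[0].start, both[0].end) == (100, 250)

    def test_disjoint_sets_sum(self):
        a = [make_peak("chr1", i * 1000, i * 1000 + 100) for i in range(5)]
        b = [make_peak("chr2", i * 1000, i * 1000 + 100) for i in range(4)]
        assert len(merge_union(a, b)) == 9

    def test_idempotent_on_identical_inputs(self):
        a = [make_peak("chr1", 100, 200), make_peak("chr1", 150, 300)]
        merged = merge_union(a, a)
        assert len(merged) == 1
        assert all(label == "both" for _, label in merged)

    def test_adjacent_intervals_do_not_merge(self):
        # half-open: [100,200) and [200,300) share no base
        a = [make_peak("chr1", 100, 200)]
        b = [make_peak("chr1", 200, 300)]
        assert len(merge_union(a, b)) == 2

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)),
            min_size=0, max_size=12,
        ),
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)),
            min_size=0, max_size=12,
        ),
    )
    def test_order_invariance_and_count_stability(self, a_spec, b_spec):
        a = [make_peak("chr1", s, s + w) for s, w in a_spec]
        b = [make_peak("chr1", s, s + w) for s, w in b_spec]
        merged = merge_union(a, b)
        shuffled = merge_union(list(reversed(a)), list(reversed(b)))
        assert merged == shuffled
        # merging a pre-merged input is stable
        premerged_a = [
            make_peak(iv.chrom, iv.start, iv.end)
            for iv, _ in merge_union(a, [])
        ]
        assert len(merge_union(premerged_a, b)) == len(merged)
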