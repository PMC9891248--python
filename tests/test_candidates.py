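import numpy as np
import pytest

from dedumi.candidates import (
    CandidateSet,
    UmiCluster,
    admissible_pairs,
    assign_reads_to_umis,
    build_error_clusters,
    denoise_haplotypes,
    denoise_umis,
    initialize_params,
    split_umi_clusters,
)
from dedumi.error_model import ErrorProfile

from conftest import make_readset


class TestDenoiseUmis:
    def test_singleton_neighbor_attributed_to_error(self):
        """One copy of a 1-mismatch neighbor of a 100-copy UMI is explainable
        as a misread and rejected."""
        rs = make_readset([("AAAAAAAAA", "TTTT")] * 100 + [("AAAAAAAAT", "TTTT")])
        U = denoise_umis(rs)
        assert U.sequences == ["AAAAAAAAA"]
        assert list(U.observed_abundance) == [100]

    def test_distant_umis_both_accepted(self):
        rs = make_readset([("AAAAAAAAA", "TTTT")] * 50 + [("TTTTTTTTT", "TTTT")] * 50)
        U = denoise_umis(rs)
        assert sorted(U.sequences) == ["AAAAAAAAA", "TTTTTTTTT"]

    def test_single_distinct_umi(self):
        rs = make_readset([("ACGTACGTA", "TTTT")] * 3)
        U = denoise_umis(rs)
        assert U.sequences == ["ACGTACGTA"]

    def test_well_supported_neighbor_accepted(self):
        # 10 copies cannot be misreads of a 100-copy neighbor at Q40
        rs = make_readset(
            [("AAAAAAAAA", "TTTT")] * 100 + [("AAAAAAAAT", "TTTT")] * 10
        )
        U = denoise_umis(rs)
        assert sorted(U.sequences) == ["AAAAAAAAA", "AAAAAAAAT"]

    def test_error_free_input_keeps_all_distinct(self):
        """Balanced, well-separated UMIs are never falsely rejected."""
        umis = ["AAAAAAAAA", "CCCCCCCCC", "GGGGGGGGG", "ACGTACGTA"]
        rs = make_readset([(u, "TTTT") for u in umis for _ in range(20)])
        U = denoise_umis(rs)
        assert sorted(U.sequences) == sorted(umis)


class TestAssignReads:
    def test_exact_match_dominates(self):
        rs = make_readset([("AAAAA", "TTTT")] * 5 + [("CCCCC", "TTTT")] * 5)
        U = denoise_umis(rs)
        clusters = assign_reads_to_umis(rs, U)
        by_center = {c.center: c.members for c in clusters}
        assert len(by_center["AAAAA"]) == 5 and len(by_center["CCCCC"]) == 5

    def test_emission_beats_abundance(self):
        """A distance-1 UMI with abundance 50 wins over a distance-2 UMI with
        abundance 500: ~(1e-4/3)^1 vs ^2 at Q40."""
        rs = make_readset(
            [("AAAAA", "TTTT")] * 50 + [("AAATT", "TTTT")] * 500 + [("AAAAC", "TTTT")]
        )
        U = CandidateSet(["AAAAA", "AAATT"], [50, 500], role="umi")
        clusters = assign_reads_to_umis(rs, U)
        by_center = {c.center: c.members for c in clusters}
        assert rs.n - 1 in by_center["AAAAA"]  # the query read joins AAAAA

    def test_clusters_partition_reads(self):
        rs = make_readset(
            [("AAAAA", "TTTT")] * 7 + [("AAAAC", "GGGG")] * 3 + [("CCCCC", "GGGG")] * 2
        )
        U = denoise_umis(rs)
        clusters = assign_reads_to_umis(rs, U)
        members = sorted(i for c in clusters for i in c.members)
        assert members == list(range(rs.n))


class TestSplitClusters:
    def _cluster(self, seq_counts):
        triples = []
        for seq, cnt in seq_counts.items():
            triples += [("AAAAA", seq)] * cnt
        rs = make_readset(triples)
        return [UmiCluster("AAAAA", list(range(rs.n)))], rs

    def test_over_half_splits(self):
        clusters, rs = self._cluster({"AAAA": 10, "TTTT": 6})
        out = split_umi_clusters(clusters, rs)
        assert len(out) == 2
        assert {c.seq_center for c in out} == {"AAAA", "TTTT"}
        assert sorted(i for c in out for i in c.members) == list(range(rs.n))

    def test_exactly_half_does_not_split(self):
        clusters, rs = self._cluster({"AAAA": 10, "TTTT": 5})
        out = split_umi_clusters(clusters, rs)
        assert len(out) == 1

    def test_equidistant_member_goes_to_more_abundant_center(self):
        clusters, rs = self._cluster({"AAAA": 10, "TTTT": 6, "AATT": 1})
        out = split_umi_clusters(clusters, rs)
        centers = {c.seq_center: c for c in out}
        # AATT is Hamming-2 from both centers; the top center has count 10
        equidistant_read = rs.n - 1
        assert equidistant_read in centers["AAAA"].members

    def test_single_sequence_cluster_unchanged(self):
        clusters, rs = self._cluster({"AAAA": 4})
        out = split_umi_clusters(clusters, rs)
        assert len(out) == 1 and out[0].members == list(range(4))

    def test_split_preserves_read_multiset(self):
        clusters, rs = self._cluster({"AAAA": 9, "TTTT": 8, "ATTT": 2, "AAAT": 1})
        out = split_umi_clusters(clusters, rs)
        assert sorted(i for c in out for i in c.members) == list(range(rs.n))


class TestErrorClusters:
    def test_unreplicated_centers_dropped(self):
        rs = make_readset([("AAAAA", "TTTT")] * 3 + [("CCCCC", "GGGG")])
        clusters = [UmiCluster("AAAAA", [0, 1, 2]), UmiCluster("CCCCC", [3])]
        out = build_error_clusters(clusters, rs, min_center_abundance=2)
        assert len(out) == 1
        center, members = out[0]
        assert center == "AAAAA" + "TTTT"
        assert len(members) == 3 and members[0][0] == "AAAAATTTT"


class TestDenoiseHaplotypes:
    def test_error_free_two_haplotypes(self):
        rs = make_readset(
            [("AAAAA", "ACGTACGTACGTACGTACGT")] * 20
            + [("CCCCC", "ACGTACGTACGTACGTACGT")] * 20
            + [("GGGGG", "TTTTTTTTTTGGGGGGGGGG")] * 20
        )
        H = denoise_haplotypes(rs, ErrorProfile.phred_default())
        assert sorted(H.sequences) == sorted(
            ["ACGTACGTACGTACGTACGT", "TTTTTTTTTTGGGGGGGGGG"]
        )
        assert dict(zip(H.sequences, H.observed_abundance))["ACGTACGTACGTACGTACGT"] == 40

    def test_replicated_misread_rejected(self):
        """A twice-seen 1-mismatch variant of a 500-copy haplotype is within
        error expectation at Q25 and rejected."""
        hap = "ACGTACGTACGTACGTACGT"
        miss = "ACGTACGTACGTACGTACGA"
        rs = make_readset([("AAAAA", hap, 25)] * 500 + [("AAAAA", miss, 25)] * 2)
        H = denoise_haplotypes(rs, ErrorProfile.phred_default())
        assert H.sequences == [hap]

    def test_k_bounded_by_distinct_sequences(self, sim_tiny_noisy):
        rs = sim_tiny_noisy.readset
        H = denoise_haplotypes(rs, ErrorProfile.phred_default())
        assert len(H) <= len(set(rs.seqs))


class TestAdmissiblePairsAndInit:
    def test_exact_co_observation(self):
        rs = make_readset([("AAA", "CCC")])
        U = CandidateSet(["AAA"], [1], "umi")
        H = CandidateSet(["CCC"], [1], "haplotype")
        assert admissible_pairs(rs, U, H)[0, 0]

    def test_no_co_observation_gives_false_row(self):
        rs = make_readset([("AAA", "CCC"), ("TTT", "GGG")])
        U = CandidateSet(["AAA", "TTT"], [1, 1], "umi")
        H = CandidateSet(["GGG"], [1], "haplotype")
        mask = admissible_pairs(rs, U, H)
        assert not mask[0, 0] and mask[1, 0]

    def test_mask_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        umis = ["AAA", "CCC", "GGG"]
        haps = ["ACGT", "TTTT"]
        triples = [
            (umis[rng.integers(3)], haps[rng.integers(2)]) for _ in range(40)
        ]
        rs = make_readset(triples)
        U = CandidateSet(umis, [1, 1, 1], "umi")
        H = CandidateSet(haps, [1, 1], "haplotype")
        mask = admissible_pairs(rs, U, H)
        pairs = {(u, s) for u, s in triples}
        for s, u in enumerate(umis):
            for k, h in enumerate(haps):
                assert mask[s, k] == ((u, h) in pairs)
        assert mask.sum() == len(pairs)

    def test_initialize_params_definitions(self):
        rs = make_readset(
            [("AAA", "ACGT")] * 3 + [("AAA", "TTTT")] * 3 + [("CCC", "ACGT")] * 4
        )
        U = CandidateSet(["AAA", "CCC"], [6, 4], "umi")
        H = CandidateSet(["ACGT", "TTTT"], [7, 3], "haplotype")
        mask = admissible_pairs(rs, U, H)
        params = initialize_params(rs, U, H, mask)
        assert np.allclose(params.eta, [0.6, 0.4])
        assert np.allclose(params.gamma[0], [0.5, 0.5])
        assert np.allclose(params.gamma[1], [1.0, 0.0])
        params.validate()

    def test_initialize_three_to_one_split(self):
        rs = make_readset([("AAA", "ACGT")] * 3 + [("AAA", "TTTT")])
        U = CandidateSet(["AAA"], [4], "umi")
        H = CandidateSet(["ACGT", "TTTT"], [3, 1], "haplotype")
        params = initialize_params(rs, U, H, admissible_pairs(rs, U, H))
        assert np.allclose(params.gamma[0], [0.75, 0.25])


def test_denoisers_keep_truth_on_error_free_simulation(sim_error_free):
    """On error-free input the denoised pools are exactly the distinct
    observed sequences: nothing is attributable to error."""
    rs = sim_error_free.readset
    U = denoise_umis(rs)
    assert sorted(U.sequences) == sorted(set(rs.umis))
    H = denoise_haplotypes(rs, ErrorProfile.phred_default())
    assert sorted(H.sequences) == sorted(set(rs.seqs))
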