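"""Seed-site scanning: motif construction, subsumption, oracle agreement."""
import pytest
from hypothesis import given, settings, strategies as st

from cerna_scan.mre import (
    MiRNA,
    SITE_RANK,
    scan_sites,
    seed_motifs,
    shared_mres,
    site_report,
)
from cerna_scan.simulate import plant_mres

from _oracles import oracle_scan, random_dna

MIR = MiRNA("mir-test", "UACGGUAACGACUGCUGGAGUU")

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class TestSeedMotifs:
    def test_worked_example(self):
        m = MiRNA("m", "UACGGUAACAAAAAAAAAAAAA")
        motifs = seed_motifs(m)
        assert motifs["8mer"] == "UUACCGUA"
        assert motifs["6mer"] == "UACCGU"
        assert motifs["7mer-m8"] == "UUACCGU"
        assert motifs["7mer-A1"] == "UACCGUA"
        assert motifs["offset-6mer"] == "UUACCG"

    def test_poly_a_mirna(self):
        m = MiRNA("m", "AAAAAAAAAAAAAAAAAAAAAA")
        assert seed_motifs(m)["7mer-m8"] == "UUUUUUU"

    def test_motifs_pair_watson_crick_with_the_seed(self):
        # aligning each motif antiparallel to the miRNA must give WC pairs at
        # exactly the positions the type claims to match
        motifs = seed_motifs(MIR)
        spans = {
            "6mer": (2, 7),
            "7mer-m8": (2, 8),
            "offset-6mer": (3, 8),
        }
        for label, (lo, hi) in spans.items():
            motif = motifs[label]
            mir_part = MIR.sequence[lo - 1 : hi]
            for target_base, mir_base in zip(motif, reversed(mir_part)):
                assert (target_base, mir_base) in _RNA_PAIRS

    def test_a1_anchor_is_adenosine_not_complement_of_position_1(self):
        # miRNA position 1 is C; the 8mer/7mer-A1 motifs still end in A
        m = MiRNA("m", "CACGGUAACAAAAAAAAAAAAA")
        motifs = seed_motifs(m)
        assert motifs["8mer"].endswith("A")
        assert motifs["7mer-A1"].endswith("A")

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match=">=8"):
            MiRNA("m", "UACGGUA")


class TestScanSites:
    def test_absent_motif_gives_no_sites(self):
        assert scan_sites("A" * 100, MIR) == []

    def test_empty_target_gives_no_sites(self):
        assert scan_sites("", MIR) == []

    def test_planted_8mer_reported_once_as_8mer(self):
        motif = seed_motifs(MIR)["8mer"].replace("U", "T")
        target = "C" * 40 + motif + "C" * 40
        sites = scan_sites(target, MIR)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert (sites[0].target_start, sites[0].target_end) == (40, 48)
        assert sites[0].anchor_pos == 47

    @pytest.mark.parametrize("site_type", ["8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer"])
    def test_planted_type_recovered_exactly(self, site_type):
        seq, truths = plant_mres("C" * 120, MIR, site_type, [50])
        sites = scan_sites(seq, MIR)
        assert [(s.anchor_pos, s.site_type) for s in sites] == [
            (truths[0].payload["anchor_pos"], site_type)
        ]

    def test_empty_offsets_leave_sequence_unchanged(self):
        seq, truths = plant_mres("C" * 60, MIR, "8mer", [])
        assert seq == "C" * 60 and truths == []

    def test_overlapping_offsets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            plant_mres("C" * 120, MIR, "8mer", [50, 53])

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="room"):
            plant_mres("C" * 30, MIR, "8mer", [28])

    def test_two_anchors_both_counted(self):
        seq, _ = plant_mres("C" * 200, MIR, "8mer", [30, 120])
        assert len(scan_sites(seq, MIR)) == 2

    def test_t_u_equivalence(self):
        seq, _ = plant_mres("C" * 100, MIR, "7mer-m8", [40])
        assert scan_sites(seq, MIR) == scan_sites(seq.replace("T", "U"), MIR)

    def test_n_matches_nothing(self):
        motif = seed_motifs(MIR)["6mer"].replace("U", "T")
        broken = motif[:3] + "N" + motif[4:]
        assert scan_sites("C" * 20 + broken + "C" * 20, MIR) == []
        assert scan_sites("C" * 20 + broken + "C" * 20, MIR, allow_imperfect=True) == []

    def test_concatenation_with_n_spacer_is_additive(self, rng):
        a = random_dna(rng, 300)
        b = random_dna(rng, 300)
        spacer = "N" * 8
        combined = scan_sites(a + spacer + b, MIR)
        separate = scan_sites(a, MIR)
        shift = len(a) + len(spacer)
        expected = [(s.anchor_pos, s.site_type) for s in separate] + [
            (s.anchor_pos + shift, s.site_type) for s in scan_sites(b, MIR)
        ]
        assert [(s.anchor_pos, s.site_type) for s in combined] == sorted(expected)


class TestImperfectSites:
    def test_single_wobble_reported_only_when_enabled(self):
        motif = list(seed_motifs(MIR)["6mer"].replace("U", "T"))
        # introduce one G:U wobble: target G facing miRNA U, or T facing G
        mir_dna = MIR.sequence.replace("U", "T")
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for i, mir_pos in enumerate(range(7, 1, -1)):
            base = mir_dna[mir_pos - 1]
            if base == "T":
                motif[i] = "G"
                break
            if base == "G":
                motif[i] = "T"
                break
        target = "C" * 30 + "".join(motif) + "C" * 30
        assert scan_sites(target, MIR) == []
        sites = scan_sites(target, MIR, allow_imperfect=True)
        assert [s.site_type for s in sites] == ["imperfect"]

    def test_single_deletion_reported(self):
        motif = seed_motifs(MIR)["6mer"].replace("U", "T")
        target = "C" * 30 + motif[:2] + motif[3:] + "C" * 30
        sites = scan_sites(target, MIR, allow_imperfect=True)
        assert any(s.site_type == "imperfect" for s in sites)
        assert sites[0].target_end - sites[0].target_start == 5

    def test_two_defects_not_reported(self):
        motif = list(seed_motifs(MIR)["6mer"].replace("U", "T"))
        motif[1] = "A" if motif[1] != "A" else "G"
        motif[4] = "A" if motif[4] != "A" else "G"
        target = "C" * 30 + "".join(motif) + "C" * 30
        assert scan_sites(target, MIR, allow_imperfect=True) == []


class TestSubsumption:
    def test_8mer_not_double_reported(self):
        seq, _ = plant_mres("C" * 100, MIR, "8mer", [40])
        sites = scan_sites(seq, MIR)
        anchors = [s.anchor_pos for s in sites]
        assert len(anchors) == len(set(anchors))
        assert [s.site_type for s in sites] == ["8mer"]

    def test_no_anchor_carries_two_perfect_types(self, rng):
        for _ in range(200):
            target = random_dna(rng, 200)
            seen = set()
            for s in scan_sites(target, MIR):
                assert s.anchor_pos not in seen
                seen.add(s.anchor_pos)


class TestOracleAgreement:
    def test_random_and_planted_targets_match_sliding_window_oracle(self, rng):
        types = ["8mer", "7mer-m8", "7mer-A1", "6mer", "offset-6mer"]
        for i in range(300):
            mirna = MiRNA("m", random_dna(rng, 22))
            target = random_dna(rng, int(rng.integers(30, 250)))
            if i % 2 == 0:
                try:
                    target, _ = plant_mres(
                        target, mirna, types[i % len(types)], [int(rng.integers(10, 20))]
                    )
                except ValueError:
                    pass
            imperfect = bool(i % 5 == 0)
            observed = [
                (s.anchor_pos, s.site_type)
                for s in scan_sites(target, mirna, allow_imperfect=imperfect)
            ]
            assert observed == oracle_scan(target, mirna.sequence, imperfect)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120), st.booleans())
    def test_arbitrary_targets_match_oracle(self, target, imperfect):
        observed = [
            (s.anchor_pos, s.site_type)
            for s in scan_sites(target, MIR, allow_imperfect=imperfect)
        ]
        assert observed == oracle_scan(target, MIR.sequence, imperfect)


class TestReports:
    def test_hierarchy_dominates_site_count_in_sorting(self, rng):
        m1 = MiRNA("mir-a", "UACGGUAACGACUGCUGGAGUU")
        m2 = MiRNA("mir-b", "UGGCAUCGAAGACUGCUGGAGU")
        target = "C" * 400
        target, _ = plant_mres(target, m1, "8mer", [40])
        target, _ = plant_mres(target, m2, "6mer", [80])
        target, _ = plant_mres(target, m2, "6mer", [120])
        target, _ = plant_mres(target, m2, "6mer", [160])
        reports = site_report(target, [m2, m1])
        assert [r.mirna_id for r in reports] == ["mir-a", "mir-b"]
        assert reports[0].best_rank < reports[1].best_rank
        assert reports[1].site_count == 3

    def test_no_sites_gives_empty_report(self):
        assert site_report("A" * 50, [MIR]) == []

    def test_duplicate_mirna_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            site_report("A" * 50, [MIR, MIR])

    def test_shared_mres_is_intersection(self):
        seq_a = "C" * 300
        seq_b = "C" * 300
        mx = MiRNA("mir-x", "UACGGUAACGACUGCUGGAGUU")
        my = MiRNA("mir-y", "UGGCAUCGAAGACUGCUGGAGU")
        mz = MiRNA("mir-z", "UCCGAUUGCAAGACUGCUGGAG")
        seq_a, _ = plant_mres(seq_a, mx, "8mer", [40])
        seq_a, _ = plant_mres(seq_a, my, "6mer", [80])
        seq_b, _ = plant_mres(seq_b, my, "7mer-m8", [50])
        seq_b, _ = plant_mres(seq_b, mz, "8mer", [100])
        rep_a = site_report(seq_a, [mx, my, mz], target_id="a")
        rep_b = site_report(seq_b, [mx, my, mz], target_id="b")
        shared = shared_mres(rep_a, rep_b)
        assert [m for m, _, _ in shared] == ["mir-y"]
        assert shared[0][1] == SITE_RANK["6mer"]
        assert shared[0][2] == SITE_RANK["7mer-m8"]

    def test_disjoint_reports_share_nothing(self):
        mx = MiRNA("mir-x", "UACGGUAACGACUGCUGGAGUU")
        my = MiRNA("mir-y", "UGGCAUCGAAGACUGCUGGAGU")
        seq_a, _ = plant_mres("C" * 200, mx, "8mer", [40])
        seq_b, _ = plant_mres("C" * 200, my, "8mer", [40])
        rep_a = site_report(seq_a, [mx, my], target_id="a")
        rep_b = site_report(seq_b, [mx, my], target_id="b")
        assert shared_mres(rep_a, rep_b) == []
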