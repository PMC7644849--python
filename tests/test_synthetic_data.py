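import numpy as np
import pytest

from cisreg.chromatin_filter import (
    ChromatinConfig,
    active_chromatin_filter,
    encode_evidence_filter,
    surviving_hits,
)
from cisreg.motif_model import relative_score
from cisreg.promoter_compare import tf_set, venn_partition
from cisreg.promoter_scan import scan_promoter
from cisreg.quantification import luciferase_fold, relative_expression
from cisreg.synthetic_data import (
    PlantSpec,
    build_promoter_fixture,
    construct_fixture,
    delete_motif,
    demo_pfms,
    demo_pwms,
    expected_surviving_truth,
    three_promoter_fixture,
    make_ct_table,
    make_luciferase_plate,
    sample_site,
)

from .conftest import enumerate_kmers


def run_filters(fixture, gene_id, cfg=ChromatinConfig()):
    promoter = fixture.promoter(gene_id)
    hits = scan_promoter(fixture.pwms, promoter)
    hits = active_chromatin_filter(hits, fixture.histone_track, cfg)
    hits = encode_evidence_filter(hits, fixture.cluster_track, cfg)
    return hits


@pytest.fixture(scope="module")
def smad():
    return next(p for p in demo_pwms() if p.tf_name == "SMAD2/3")


@pytest.fixture(scope="module")
def shared_partition():
    fixture = three_promoter_fixture(seed=42)
    sets = [
        tf_set(surviving_hits(run_filters(fixture, a.gene_id)))
        for a in fixture.anchors
    ]
    return venn_partition(sets)


@pytest.fixture(scope="module")
def construct():
    return construct_fixture(seed=0)


class TestSampleSite:
    def test_full_score_band_returns_consensus(self, smad):
        rng = np.random.default_rng(0)
        assert sample_site(smad, (1.0, 1.0), rng) == smad.consensus

    def test_band_respected_vs_enumeration(self, smad):
        rng = np.random.default_rng(1)
        kmer = sample_site(smad, (0.80, 0.90), rng)
        # verify with exhaustive enumeration that the k-mer really is in band
        in_band = {
            k for k in enumerate_kmers(smad.length)
            if 0.80 <= relative_score(smad, k) <= 0.90
        }
        assert kmer in in_band

    def test_infeasible_band(self, smad):
        rng = np.random.default_rng(2)
        # enumeration confirms no 6-mer sits in this sliver above consensus-1
        with pytest.raises(ValueError, match="infeasible"):
            sample_site(smad, (0.999, 0.9999), rng)

    def test_deterministic_given_seed(self, smad):
        a = sample_site(smad, (0.70, 0.85), np.random.default_rng(5))
        b = sample_site(smad, (0.70, 0.85), np.random.default_rng(5))
        assert a == b


class TestBuildPromoterFixture:
    def test_single_active_site_roundtrip(self):
        spec = PlantSpec("G1", "SMAD2/3", "MA0513.1", n_sites=1)
        fixture = build_promoter_fixture([spec], length=3000, seed=3)
        hits = run_filters(fixture, "G1")
        survivors = surviving_hits(hits)
        (truth,) = fixture.truth
        assert [(h.local_offset, h.hit_strand, h.matrix_id) for h in survivors] == [
            (truth.local_offset, truth.strand, truth.matrix_id)
        ]

    def test_silent_evidence_499_scanned_but_filtered(self):
        spec = PlantSpec("G1", "SMAD2/3", "MA0513.1", evidence_score=499)
        fixture = build_promoter_fixture([spec], length=3000, seed=4)
        hits = run_filters(fixture, "G1")
        assert len(hits) == 1
        assert surviving_hits(hits) == []

    def test_silent_chromatin_filtered(self):
        spec = PlantSpec("G1", "SMAD2/3", "MA0513.1", chromatin_status="silent")
        fixture = build_promoter_fixture([spec], length=3000, seed=5)
        hits = run_filters(fixture, "G1")
        assert len(hits) == 1
        assert hits[0].chromatin_active == "fail"
        assert surviving_hits(hits) == []

    def test_multi_gene_truth_equality(self):
        specs = [
            PlantSpec(f"G{i}", tf, mid, n_sites=2)
            for i in range(3)
            for tf, mid in (("SMAD2/3", "MA0513.1"), ("ATF4", "MA0833.1"))
        ]
        fixture = build_promoter_fixture(specs, length=5000, seed=6)
        surviving_keys = set()
        for i in range(3):
            for h in surviving_hits(run_filters(fixture, f"G{i}")):
                surviving_keys.add((h.gene_id, h.matrix_id, h.local_offset,
                                    h.hit_strand))
        assert surviving_keys == expected_surviving_truth(fixture.truth)

    def test_low_band_decoys_not_scanned(self):
        spec = PlantSpec("G1", "SMAD2/3", "MA0513.1", n_sites=3,
                         relative_score_band=(0.70, 0.85))
        fixture = build_promoter_fixture([spec], length=4000, seed=7)
        promoter = fixture.promoter("G1")
        assert scan_promoter(fixture.pwms, promoter) == []
        assert all(t.relative_score <= 0.85 for t in fixture.truth)

    def test_too_many_sites_is_error(self):
        spec = PlantSpec("G1", "SMAD2/3", "MA0513.1", n_sites=100)
        with pytest.raises(ValueError, match="fit"):
            build_promoter_fixture([spec], length=500, seed=0)

    def test_unknown_matrix_is_error(self):
        with pytest.raises(KeyError):
            build_promoter_fixture(
                [PlantSpec("G1", "X", "NOPE.1")], length=1000, seed=0
            )

    def test_byte_identical_on_reseed(self, tmp_path):
        specs = [PlantSpec("G1", "SMAD2/3", "MA0513.1", n_sites=2),
                 PlantSpec("G2", "ATF4", "MA0833.1")]
        a = build_promoter_fixture(specs, length=3000, seed=11)
        b = build_promoter_fixture(specs, length=3000, seed=11)
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes(), name


class TestThreePromoterFixture:
    def test_beta_gamma_share_four(self, shared_partition):
        assert shared_partition.region("PEX11B", "PEX11G") == {
            "SMAD2/3", "ATF4", "SOX10", "PPARG"
        }

    def test_alpha_beta_share_none(self, shared_partition):
        assert shared_partition.region("PEX11A", "PEX11B") == frozenset()
        assert shared_partition.region("PEX11A", "PEX11B", "PEX11G") == frozenset()

    def test_alpha_gamma_share_ppara(self, shared_partition):
        assert shared_partition.region("PEX11A", "PEX11G") == {"PPARA"}

    def test_private_tfs_present(self, shared_partition):
        assert shared_partition.region("PEX11A") == {"CEBPA"}
        assert shared_partition.region("PEX11B") == {"NRF1"}
        assert shared_partition.region("PEX11G") == {"HNF4A"}


class TestConstructFixture:
    def test_wt_length(self, construct):
        assert len(construct.wt_sequence) == 1302

    def test_mutant_length(self, construct):
        mutant = delete_motif(construct.wt_sequence, construct.site_start,
                              construct.site_end)
        assert len(mutant) == 1296

    def test_wt_has_exactly_one_site(self, construct):
        from cisreg.promoter_scan import PromoterRegion

        region = PromoterRegion("wt", "wt", "+", 0, 1302, construct.wt_sequence)
        hits = scan_promoter([construct.pwm], region, 0.89)
        assert len(hits) == 1
        assert hits[0].local_offset == construct.site_start

    def test_mutant_has_zero_sites(self, construct):
        from cisreg.promoter_scan import PromoterRegion

        mutant = delete_motif(construct.wt_sequence, construct.site_start,
                              construct.site_end)
        region = PromoterRegion("mut", "mut", "+", 0, len(mutant), mutant)
        assert scan_promoter([construct.pwm], region, 0.89) == []

    def test_bad_span_rejected(self, construct):
        with pytest.raises(ValueError):
            delete_motif(construct.wt_sequence, 1300, 1306)


class TestMakeCtTable:
    def test_noise_free_fold_recovered_exactly(self):
        table = make_ct_table(
            {"PEX11B": {6: 1.0, 24: 2.0}}, noise_sd=0.0, seed=0
        )
        profiles = relative_expression(table)
        assert profiles["PEX11B"].amount_at(24) == pytest.approx(2.0)

    def test_all_folds_one_flat(self):
        table = make_ct_table(
            {"G": {6: 1.0, 12: 1.0, 24: 1.0}}, noise_sd=0.0, seed=0
        )
        profiles = relative_expression(table)
        assert profiles["G"].relative_amounts == pytest.approx((1.0, 1.0, 1.0))

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            make_ct_table({"G": {6: 0.0}}, seed=0)

    @pytest.mark.parametrize("k", [2.0, 4.0])
    def test_noisy_recovery_within_ten_percent(self, k):
        # per-seed folds carry ~2^N(0, 0.1) noise, so the 10% bound applies
        # to the recovery aggregated over the 20 seeds
        recovered = []
        for seed in range(20):
            table = make_ct_table(
                {"G": {6: 1.0, 24: k}}, noise_sd=0.1, n_replicates=4, seed=seed
            )
            recovered.append(relative_expression(table)["G"].amount_at(24))
        assert abs(np.mean(recovered) - k) / k <= 0.10


class TestMakeLuciferasePlate:
    def test_noise_free_folds_exact(self):
        plate = make_luciferase_plate({"WT": 3.0, "mut": 1.0}, noise=0.0, seed=0)
        from cisreg.quantification import read_luminescence_table

        records = [
            # build records directly from the frame
        ]
        from cisreg.quantification import LuminescenceRecord

        records = [
            LuminescenceRecord(r.construct, r.treatment, int(r.replicate),
                               (r.fluc1, r.fluc2, r.fluc3), r.rluc)
            for r in plate.itertuples()
        ]
        folds = luciferase_fold(records)
        assert folds["WT"] == pytest.approx(3.0)
        assert folds["mut"] == pytest.approx(1.0)
        assert folds["promoterless"] == pytest.approx(1.0)

    def test_promoterless_near_zero_signal(self):
        plate = make_luciferase_plate({"WT": 3.0}, noise=0.0, seed=0)
        pless = plate[plate.construct == "promoterless"]
        wt = plate[(plate.construct == "WT") & (plate.treatment == "untreated")]
        assert pless.fluc1.max() < 0.05 * wt.fluc1.min()

    def test_noisy_recovery_within_fifteen_percent(self):
        from cisreg.quantification import LuminescenceRecord

        for seed in range(20):
            plate = make_luciferase_plate({"WT": 3.0}, noise=0.05, seed=seed)
            records = [
                LuminescenceRecord(r.construct, r.treatment, int(r.replicate),
                                   (r.fluc1, r.fluc2, r.fluc3), r.rluc)
                for r in plate.itertuples()
            ]
            fold = luciferase_fold(records)["WT"]
            assert abs(fold - 3.0) / 3.0 <= 0.15


class TestPanel:
    def test_panel_consensuses_unique_and_nonpalindromic(self):
        from cisreg.promoter_scan import reverse_complement

        pwms = demo_pwms()
        consensuses = [p.consensus for p in pwms]
        assert len(set(consensuses)) == len(consensuses)
        for c in consensuses:
            assert reverse_complement(c) != c

    def test_panel_writes_and_reparses(self, tmp_path):
        import io

        from cisreg.motif_model import read_jaspar, write_jaspar

        buf = io.StringIO()
        write_jaspar(demo_pfms(), buf)
        back = read_jaspar(io.StringIO(buf.getvalue()))
        assert [p.matrix_id for p in back] == [p.matrix_id for p in demo_pfms()]
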