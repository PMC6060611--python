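import numpy as np
import pytest

from crackle.annotate import (
    TranscriptModel,
    annotate_sites,
    apa_pau,
    interaction_weights,
    metaprofile,
    read_gtf,
)
from crackle.motif import BindingSite


def coding_model(tid="t1", contig="chr1", strand="+", u5=(0, 100), cds=(100, 400),
                 u3=(400, 500), gene=None):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene or tid, contig=contig, strand=strand,
        biotype="protein_coding",
        segments={"5UTR": [u5], "CDS": [cds], "3UTR": [u3]},
        exons=[(u5[0], u3[1])],
    )


def bsite(pos, contig="chr1", strand="+", intensity=1.0, seq="CUUUCUU"):
    return BindingSite(
        contig=contig, pos=pos, strand=strand, window_seq=seq, score=1.0,
        intensity=intensity, del_by_rep=(1, 1), cov_by_rep=(3, 3),
        del_total=intensity, cov_total=6,
    )


GTF_TEXT = """\
chr1\tsrc\texon\t1\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tCDS\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr1\tsrc\tpolyA_site\t500\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding";
chr2\tsrc\texon\t1\t600\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; transcript_biotype "protein_coding";
chr2\tsrc\tCDS\t151\t450\t.\t-\t.\tgene_id "g2"; transcript_id "t2"; transcript_biotype "protein_coding";
chr3\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g3"; transcript_id "t3"; transcript_biotype "ncRNA";
"""


class TestReadGtf:
    @pytest.fixture
    def models(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(GTF_TEXT)
        return read_gtf(path)

    def test_utrs_derived_from_exon_minus_cds(self, models):
        t1 = models["t1"]
        assert t1.segments["5UTR"] == [(0, 100)]
        assert t1.segments["CDS"] == [(100, 400)]
        assert t1.segments["3UTR"] == [(400, 500)]

    def test_minus_strand_utr_orientation(self, models):
        t2 = models["t2"]
        # on the minus strand the genomically-left piece is the 3'UTR
        assert t2.segments["3UTR"] == [(0, 150)]
        assert t2.segments["5UTR"] == [(450, 600)]

    def test_noncoding_exons(self, models):
        assert models["t3"].segments == {"ncRNA_exon": [(0, 100)]}
        assert models["t3"].biotype == "ncRNA"

    def test_polya_site_parsed(self, models):
        assert models["t1"].pA_sites == [499]


class TestAnnotateSites:
    def test_region_assignment(self):
        models = {"t1": coding_model()}
        sites = annotate_sites([bsite(450), bsite(100), bsite(700)], models)
        assert [s.region for s in sites] == ["3UTR", "CDS", "unassigned"]
        assert sites[0].transcript_id == "t1"

    def test_half_open_first_cds_base(self):
        models = {"t1": coding_model()}
        [s] = annotate_sites([bsite(100)], models)
        assert s.region == "CDS"
        [s] = annotate_sites([bsite(99)], models)
        assert s.region == "5UTR"

    def test_overlap_resolved_by_fpkm_then_id(self):
        models = {
            "tA": coding_model(tid="tA"),
            "tB": coding_model(tid="tB"),
        }
        [s] = annotate_sites([bsite(450)], models, expression={"tA": 1.0, "tB": 5.0})
        assert s.transcript_id == "tB"
        [s] = annotate_sites([bsite(450)], models, expression={"tA": 5.0, "tB": 5.0})
        assert s.transcript_id == "tA"

    def test_strand_respected(self):
        models = {"t1": coding_model(strand="-")}
        [s] = annotate_sites([bsite(450, strand="+")], models)
        assert s.region == "unassigned"

    def test_agrees_with_interval_paint_oracle(self, rng):
        # paint a position->region array and compare on random sites
        length = 2000
        models = {}
        paint = np.full(length, "", dtype=object)
        cursor = 0
        for i in range(6):
            u5 = int(rng.integers(20, 60))
            cds = int(rng.integers(60, 200))
            u3 = int(rng.integers(30, 120))
            start = cursor
            models[f"t{i}"] = coding_model(
                tid=f"t{i}", u5=(start, start + u5),
                cds=(start + u5, start + u5 + cds),
                u3=(start + u5 + cds, start + u5 + cds + u3),
            )
            paint[start : start + u5] = "5UTR"
            paint[start + u5 : start + u5 + cds] = "CDS"
            paint[start + u5 + cds : start + u5 + cds + u3] = "3UTR"
            cursor = start + u5 + cds + u3 + int(rng.integers(5, 30))
        positions = rng.integers(0, cursor, size=1000)
        sites = annotate_sites([bsite(int(p)) for p in positions], models)
        for pos, site in zip(positions, sites):
            expected = paint[pos] or "unassigned"
            assert site.region == expected


class TestInteractionWeights:
    def make(self):
        s1 = bsite(10, intensity=70.0)
        s1.transcript_id, s1.biotype = "rnaA", "ncRNA"
        s2 = bsite(20, intensity=30.0)
        s2.transcript_id, s2.biotype = "rnaB", "protein_coding"
        return [s1, s2]

    def test_percentages(self):
        weights = interaction_weights(self.make(), "rna")
        assert weights == {"rnaA": pytest.approx(70.0), "rnaB": pytest.approx(30.0)}

    def test_single_rna_hundred_percent(self):
        weights = interaction_weights(self.make()[:1], "rna")
        assert weights["rnaA"] == pytest.approx(100.0)

    def test_three_equal_groups_sum_100(self):
        sites = []
        for name in ("a", "b", "c"):
            s = bsite(5, intensity=1.0)
            s.transcript_id = name
            sites.append(s)
        weights = interaction_weights(sites, "rna")
        assert sum(weights.values()) == pytest.approx(100.0, abs=1e-6)
        assert weights["a"] == pytest.approx(100 / 3)

    def test_species_grouping(self):
        weights = interaction_weights(self.make(), "species")
        assert weights["ncRNA"] == pytest.approx(70.0)

    def test_zero_intensity_is_hard_error(self):
        s = bsite(10, intensity=0.0)
        with pytest.raises(ValueError):
            interaction_weights([s], "rna")

    def test_partition_sums_100(self, rng):
        sites = []
        for i in range(40):
            s = bsite(i, intensity=float(rng.uniform(0.1, 9)))
            s.transcript_id = f"t{int(rng.integers(5))}"
            sites.append(s)
        assert sum(interaction_weights(sites, "rna").values()) == pytest.approx(100.0, abs=1e-6)


class TestMetaprofile:
    def test_binning_and_normalization(self):
        models = {"t1": coding_model()}
        sites = annotate_sites([bsite(405), bsite(495)], models)
        profile = metaprofile(sites, models, bins=(10, 30, 10))
        utr3 = profile[profile.region == "3UTR"].set_index("bin")["density"]
        assert utr3[0] == pytest.approx(0.5)  # relative position 0.05
        assert utr3[9] == pytest.approx(0.5)
        assert profile["density"].sum() == pytest.approx(1.0)

    def test_all_sites_in_3utr(self):
        models = {"t1": coding_model()}
        sites = annotate_sites([bsite(p) for p in (410, 430, 470)], models)
        profile = metaprofile(sites, models)
        assert profile[profile.region == "3UTR"]["density"].sum() == pytest.approx(1.0)

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            metaprofile([], {"t1": coding_model()})

    def test_invariant_under_length_rescaling(self):
        small = {"t1": coding_model(u5=(0, 50), cds=(50, 200), u3=(200, 250))}
        big = {"t1": coding_model(u5=(0, 100), cds=(100, 400), u3=(400, 500))}
        sites_small = annotate_sites([bsite(210), bsite(240)], small)
        profile_small = metaprofile(sites_small, small)
        sites_big = annotate_sites([bsite(420), bsite(480)], big)
        profile_big = metaprofile(sites_big, big)
        assert np.allclose(profile_small["density"], profile_big["density"])

    def test_minus_strand_relative_position(self):
        models = {"t1": coding_model(strand="-")}
        # genomic 3'UTR of a minus-strand transcript is at low coordinates;
        # model here has 3UTR at (400,500) genomically = 5' end in tx space
        site = bsite(499, strand="-")
        annotated = annotate_sites([site], models)
        profile = metaprofile(annotated, models, bins=(10, 30, 10))
        region = annotated[0].region
        sub = profile[profile.region == region].set_index("bin")["density"]
        assert sub[0] == pytest.approx(1.0)


class TestApaPau:
    def test_window_example(self):
        starts = np.zeros(200, dtype=int)
        for p in (95, 105, 111):
            starts[p] = 1
        assert apa_pau(starts, [100], window=10) == {100: 2}

    def test_exact_position_counted(self):
        starts = np.zeros(200, dtype=int)
        starts[100] = 3
        assert apa_pau(starts, [100]) == {100: 3}

    def test_no_reads(self):
        assert apa_pau(np.zeros(50, dtype=int), [25]) == {25: 0}

    def test_nearest_site_wins(self):
        starts = np.zeros(200, dtype=int)
        starts[104] = 1
        assert apa_pau(starts, [100, 110]) == {100: 1, 110: 0}

    def test_tie_goes_five_prime(self):
        starts = np.zeros(200, dtype=int)
        starts[105] = 1
        assert apa_pau(starts, [100, 110]) == {100: 1, 110: 0}
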