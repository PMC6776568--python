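"""Promoter-capture interaction I/O, classification, and gene-centric queries."""

import math

import pytest

from regulink import (
    ChromSizes,
    FormatError,
    GenomicInterval,
    PeakSet,
    ValidationError,
    classify_interactions,
    factor_enrichment_in_mediated,
    gene_interactions,
    peaks_at_interactions,
    read_bed,
    read_gene_table,
    read_interactions,
    write_interactions,
)
from regulink.enhancers import EnhancerClassCall
from regulink.interactions import InteractionCall
from regulink.peak_state import promoter_regions


def _call(bait_span, oe_span, genes=("g1",), bait_chrom="chr1", oe_chrom="chr1",
          score=5.0):
    return InteractionCall(
        bait=GenomicInterval(bait_chrom, *bait_span),
        bait_genes=tuple(genes),
        other_end=GenomicInterval(oe_chrom, *oe_span),
        score=score,
    )


class TestInteractionIO:
    def test_inter_chromosomal_flag(self):
        assert _call((0, 100), (500, 600)).inter_chromosomal is False
        assert _call((0, 100), (500, 600), oe_chrom="chr2").inter_chromosomal is True

    def test_empty_bait_genes_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            _call((0, 100), (500, 600), genes=())
        p = tmp_path / "i.tsv"
        p.write_text(
            "bait_chrom\tbait_start\tbait_end\tbait_genes\toe_chrom\toe_start\t"
            "oe_end\tscore\nchr1\t0\t100\t\tchr1\t500\t600\t3.5\n")
        with pytest.raises(FormatError, match=":2"):
            read_interactions(p)

    def test_round_trip_identity(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(9)
        calls = []
        for k in range(300):
            b = int(rng.integers(0, 100_000))
            o = int(rng.integers(0, 100_000))
            calls.append(_call((b, b + 1000), (o, o + 800),
                               genes=(f"g{k}", f"h{k}") if k % 3 else (f"g{k}",),
                               oe_chrom="chr2" if k % 7 == 0 else "chr1",
                               score=float(round(rng.uniform(1, 20), 3))))
        p = tmp_path / "i.tsv"
        write_interactions(calls, p)
        assert read_interactions(p) == calls

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("chr1\t0\t100\tg1\tchr1\t500\t600\t3.5\n")
        with pytest.raises(FormatError, match="header"):
            read_interactions(p)


PROMOTERS = PeakSet("prom", [GenomicInterval("chr1", 10_000, 16_000, name="g1"),
                             GenomicInterval("chr1", 50_000, 56_000, name="g2")])
ENH = [EnhancerClassCall(GenomicInterval("chr1", 100_000, 110_000, name="se1"),
                         "super"),
       EnhancerClassCall(GenomicInterval("chr1", 200_000, 202_000, name="te1"),
                         "poised"),
       EnhancerClassCall(GenomicInterval("chr1", 300_000, 302_000, name="u1"),
                         "unclassified")]


class TestClassifyInteractions:
    def test_promoter_takes_precedence_and_enh_subclass(self):
        calls = [
            _call((10_500, 11_500), (51_000, 52_000)),       # P-P
            _call((10_500, 11_500), (100_500, 101_500)),     # P-E super
            _call((10_500, 11_500), (200_100, 200_700)),     # P-E poised
            _call((10_500, 11_500), (400_000, 400_600)),     # other
            _call((10_500, 11_500), (300_100, 300_500)),     # unclassified -> other
        ]
        out, counts = classify_interactions(calls, PROMOTERS, ENH)
        assert [c.iclass for c in out] == [
            "promoter_promoter", "promoter_enhancer", "promoter_enhancer",
            "promoter_other", "promoter_other"]
        assert [c.enh_subclass for c in out] == [None, "super", "poised",
                                                 None, None]
        assert counts == {"promoter_promoter": 1, "promoter_enhancer": 2,
                          "promoter_other": 2}

    def test_other_end_on_promoter_and_enhancer_is_promoter(self):
        enh = [EnhancerClassCall(GenomicInterval("chr1", 50_000, 56_000), "active")]
        calls = [_call((10_500, 11_500), (51_000, 52_000))]
        out, _ = classify_interactions(calls, PROMOTERS, enh)
        assert out[0].iclass == "promoter_promoter"

    def test_order_invariance(self):
        calls = [_call((10_500, 11_500), (51_000, 52_000)),
                 _call((10_500, 11_500), (100_500, 101_500)),
                 _call((10_500, 11_500), (400_000, 400_600))]
        fwd, _ = classify_interactions(calls, PROMOTERS, ENH)
        rev, _ = classify_interactions(list(reversed(calls)), PROMOTERS, ENH)
        assert [c.iclass for c in rev] == [c.iclass for c in reversed(fwd)]

    def test_planted_class_counts_recovered(self, bundle):
        from regulink import classify_enhancers

        calls = read_interactions(bundle.paths["interactions"])
        genes = read_gene_table(bundle.paths["genes"])
        sizes = ChromSizes.read(bundle.paths["chrom_sizes"])
        prom = promoter_regions(genes, sizes=sizes)
        se = read_bed(bundle.paths["se"])
        te = read_bed(bundle.paths["te"])
        regions = PeakSet("r", list(se) + list(te))
        enh_calls, _ = classify_enhancers(
            regions, se, read_bed(bundle.paths["h3k27ac"]),
            read_bed(bundle.paths["h3k4me1"]), read_bed(bundle.paths["h3k27me3"]))
        out, counts = classify_interactions(calls, prom, enh_calls)
        assert counts == bundle.manifest["interaction_class_counts"]
        truth = bundle.manifest["interactions"]
        keys = sorted(truth, key=lambda k: int(k.split("_")[1]))
        for c, k in zip(out, keys):
            assert c.iclass == truth[k]["iclass"]
            assert c.enh_subclass == truth[k]["enh_subclass"]


class TestPeaksAtInteractions:
    def _classified(self):
        calls = [_call((10_500, 11_500), (51_000, 52_000)),
                 _call((50_500, 51_500), (100_500, 101_500)),
                 _call((10_500, 11_500), (400_000, 400_600))]
        out, _ = classify_interactions(calls, PROMOTERS, ENH)
        return out

    def test_blanket_tf_gives_fraction_one(self):
        out = self._classified()
        tf = PeakSet("tf", [GenomicInterval("chr1", 0, 500_000)])
        subset, frac = peaks_at_interactions(out, tf, where="either")
        assert frac == 1.0 and len(subset) == len(out)

    def test_absent_tf_gives_zero(self):
        out = self._classified()
        tf = PeakSet("tf", [GenomicInterval("chr9", 0, 1000)])
        _subset, frac = peaks_at_interactions(out, tf, where="either")
        assert frac == 0.0

    def test_either_superset_of_single_anchors(self):
        out = self._classified()
        tf = PeakSet("tf", [GenomicInterval("chr1", 10_000, 12_000),
                            GenomicInterval("chr1", 400_000, 400_200)])
        s_bait, _ = peaks_at_interactions(out, tf, where="bait")
        s_oe, _ = peaks_at_interactions(out, tf, where="other_end")
        s_either, _ = peaks_at_interactions(out, tf, where="either")
        ids = lambda xs: {id(x) for x in xs}
        assert ids(s_bait) | ids(s_oe) == ids(s_either)

    def test_planted_mediated_fraction_recovered(self, bundle):
        calls = read_interactions(bundle.paths["interactions"])
        genes = read_gene_table(bundle.paths["genes"])
        prom = promoter_regions(genes)
        out, _ = classify_interactions(calls, prom, [])
        tf_a = read_bed(bundle.paths["tf_a"])
        _subset, frac = peaks_at_interactions(out, tf_a, where="either")
        assert frac == pytest.approx(bundle.manifest["mediated_fraction"],
                                     abs=1e-12)


class TestFactorEnrichment:
    def test_identical_universes_give_ratio_one(self):
        calls = [_call((10_500, 11_500), (51_000, 52_000)) for _ in range(10)]
        out, _ = classify_interactions(calls, PROMOTERS, ENH)
        tf2 = PeakSet("tf2", [GenomicInterval("chr1", 0, 200_000)])
        res = factor_enrichment_in_mediated(out, out, tf2)
        assert res.ratio == pytest.approx(1.0)

    def test_absent_factor_is_degenerate(self):
        calls = [_call((10_500, 11_500), (51_000, 52_000)) for _ in range(4)]
        out, _ = classify_interactions(calls, PROMOTERS, ENH)
        tf2 = PeakSet("tf2", [GenomicInterval("chr9", 0, 100)])
        res = factor_enrichment_in_mediated(out, out[:2], tf2)
        assert res.degenerate is True and res.ratio is None

    def test_planted_enrichment_recovered_in_simulation(self):
        """tf2 planted at 80% of mediated vs 40% of all anchors: fractions
        within 0.05 and p < 0.01 across seeded replicates (n = 500)."""
        import numpy as np

        ok = 0
        fr_m, fr_a = [], []
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(20_000 + rep)
            calls, flags = [], []
            for i in range(500):
                b = 10_000 + i * 1500
                o = 2_000_000 + i * 1500
                calls.append(_call((b, b + 1000), (o, o + 600)))
                flags.append(i < 200)  # first 200 are "mediated"
            tf2_ivs = []
            for i, (c, mediated) in enumerate(zip(calls, flags)):
                p_hit = 0.8 if mediated else (0.4 - 0.8 * 200 / 500) / (300 / 500)
                if rng.random() < p_hit:
                    oe = c.other_end
                    tf2_ivs.append(GenomicInterval("chr1", oe.start, oe.start + 100))
            out, _ = classify_interactions(calls, PeakSet("prom", []), [])
            mediated = [c for c, f in zip(out, flags) if f]
            res = factor_enrichment_in_mediated(out, mediated,
                                                PeakSet("tf2", tf2_ivs))
            fr_m.append(res.fraction_mediated)
            fr_a.append(res.fraction_all)
            if res.p_value < 0.01:
                ok += 1
        assert ok >= 0.95 * n_rep
        assert abs(np.mean(fr_m) - 0.8) <= 0.05
        assert abs(np.mean(fr_a) - 0.4) <= 0.05


class TestGeneInteractions:
    def test_unknown_gene_gives_empty_report(self):
        out, _ = classify_interactions(
            [_call((10_500, 11_500), (51_000, 52_000))], PROMOTERS, ENH)
        assert gene_interactions("nope", out) == []

    def test_duplicate_rows_not_deduplicated(self):
        calls = [_call((10_500, 11_500), (51_000, 52_000), genes=("g7",))] * 3
        out, _ = classify_interactions(calls, PROMOTERS, ENH)
        assert len(gene_interactions("g7", out)) == 3

    def test_distance_and_inter_chromosomal_unbounded(self):
        calls = [_call((10_000, 11_000), (51_000, 52_000), genes=("g7",)),
                 _call((10_000, 11_000), (51_000, 52_000), genes=("g7",),
                       oe_chrom="chr2")]
        out, _ = classify_interactions(calls, PROMOTERS, ENH)
        rep = gene_interactions("g7", out)
        assert rep[0].distance == abs(51_500 - 10_500)
        assert math.isinf(rep[1].distance)

    def test_planted_interaction_for_gene_recovered(self, bundle):
        calls = read_interactions(bundle.paths["interactions"])
        genes = read_gene_table(bundle.paths["genes"])
        prom = promoter_regions(genes)
        out, _ = classify_interactions(calls, prom, [])
        gid = calls[0].bait_genes[0]
        rep = gene_interactions(gid, out)
        assert len(rep) >= 1
        assert all(gid in r.call.interaction.bait_genes for r in rep)
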