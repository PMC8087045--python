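"""Adjusted readthrough efficiency, expression filters, grouping, PTC ratios."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_model
from ribore import footprints as fp
from ribore import readthrough as rt
from ribore import transcriptome as tx


def make_estimate(gene="g", rpkm_cds=10.0, rpkm_utr3=1.0, log2_re=-3.0, **kw):
    return rt.ReadthroughEstimate(
        gene=gene, n_f0_cds_trimmed=kw.get("n_cds", 100),
        n_f0_utr3=kw.get("n_utr3", 10), cds_trimmed_len=300, utr3_len_adj=100,
        log2_re=log2_re, rpkm_cds=rpkm_cds, rpkm_utr3=rpkm_utr3,
        passes_filter=kw.get("passes_filter", False),
    )


class TestRpkm:
    def test_zero_count(self):
        assert rt.rpkm(0, 1000, 1_000_000) == 0.0

    def test_reference_value(self):
        assert rt.rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_linearity(self):
        assert rt.rpkm(20, 500, 2_000_000) == 2 * rt.rpkm(10, 500, 2_000_000)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rt.rpkm(5, 0, 1000)


class ReCase:
    """Shared scaffolding: a long-CDS model with controllable frame-0 reads."""

    def setup_method(self):
        self.m = make_model(utr5="ACGUAC", cds="AUG" + "GCU" * 98 + "UAA",
                            utr3="CCACCAUAG" + "ACGU" * 22 + "ACG")
        self.rm = tx.locate_extension(self.m)

    def counts_for(self, psites):
        recs = [fp.FootprintRecord("toy", 0, 28, p, fp.frame_of(self.m, p))
                for p in psites]
        return fp.count_region_frames(recs, {"toy": self.m}, {"toy": self.rm})


class TestComputeRE(ReCase):
    def test_density_ratio_formula(self):
        # 10 frame-0 3'-UTR reads over 94 nt vs 252 over 252 nt:
        # log2[(10/94)/(252/252)] = log2(10/94)
        cds_grid = range(self.m.cds_start + 15, self.m.cds_end - 33)
        cds_psites = [p for p in cds_grid if fp.frame_of(self.m, p) == 0][:252]
        # pad with repeats so the trimmed frame-0 count is exactly 252
        psites = list(cds_psites)
        while len(psites) < 252:
            psites.append(cds_psites[0])
        utr3_psites = [self.m.stop_start + 3 * k for k in range(10)]
        est = rt.compute_readthrough_efficiency(
            self.counts_for(psites + utr3_psites)["toy"], self.m, self.rm)
        assert est.n_f0_cds_trimmed == 252
        assert est.n_f0_utr3 == 10
        expected = math.log2((10 / est.utr3_len_adj) / (252 / est.cds_trimmed_len))
        assert est.log2_re == pytest.approx(expected)

    def test_equal_densities_give_zero(self):
        # one read per frame-0 position in both trimmed CDS and adjusted 3'-UTR
        cds = [p for p in range(self.m.cds_start + 15, self.m.cds_end - 33)
               if fp.frame_of(self.m, p) == 0]
        utr3 = list(range(self.m.stop_start, self.m.length, 3))
        est = rt.compute_readthrough_efficiency(
            self.counts_for(cds + utr3)["toy"], self.m, self.rm)
        # densities 1/3 per nt in both regions up to grid-edge rounding
        assert abs(est.log2_re) < 0.03

    def test_edge_zone_reads_never_change_re(self):
        base_psites = ([p for p in range(self.m.cds_start + 15, self.m.cds_end - 33)
                        if fp.frame_of(self.m, p) == 0]
                       + [self.m.cds_end, self.m.cds_end + 3])
        base = rt.compute_readthrough_efficiency(
            self.counts_for(base_psites)["toy"], self.m, self.rm)
        edges = [self.m.cds_start, self.m.cds_start + 3, self.m.cds_start + 12,
                 self.m.stop_start - 6, self.m.stop_start - 30]
        loaded = rt.compute_readthrough_efficiency(
            self.counts_for(base_psites + edges * 7)["toy"], self.m, self.rm)
        assert loaded.log2_re == base.log2_re

    def test_offframe_reads_never_change_re(self):
        base_psites = ([p for p in range(self.m.cds_start + 15, self.m.cds_end - 33)
                        if fp.frame_of(self.m, p) == 0] + [self.m.cds_end])
        base = rt.compute_readthrough_efficiency(
            self.counts_for(base_psites)["toy"], self.m, self.rm)
        off = [p for p in range(self.m.cds_start, self.m.length)
               if fp.frame_of(self.m, p) != 0]
        loaded = rt.compute_readthrough_efficiency(
            self.counts_for(base_psites + off)["toy"], self.m, self.rm)
        assert loaded.log2_re == base.log2_re

    def test_zero_cds_reads_undefined(self):
        est = rt.compute_readthrough_efficiency(
            self.counts_for([self.m.cds_end])["toy"], self.m, self.rm)
        assert math.isnan(est.log2_re)

    def test_zero_utr3_reads_sentinel(self):
        cds = [p for p in range(self.m.cds_start + 15, self.m.cds_end - 33)
               if fp.frame_of(self.m, p) == 0]
        est = rt.compute_readthrough_efficiency(
            self.counts_for(cds)["toy"], self.m, self.rm)
        assert est.log2_re == -math.inf and not est.finite

    def test_extension_numerator_switch(self):
        psites = ([p for p in range(self.m.cds_start + 15, self.m.cds_end - 33)
                   if fp.frame_of(self.m, p) == 0]
                  + [self.m.cds_end, self.m.cds_end + 30])  # ext + distal read
        est = rt.compute_readthrough_efficiency(
            self.counts_for(psites)["toy"], self.m, self.rm, numerator="extension")
        assert est.n_f0_utr3 == 1  # distal read excluded
        assert est.utr3_len_adj == self.rm.ext[1] - self.rm.ext[0]


class TestExpressionFilters:
    @pytest.mark.parametrize("rpkm_cds,rpkm_utr3,kept", [
        (4.0, 0.4, False),  # both below -> discarded
        (10.0, 0.4, True),  # only 3'-UTR below -> retained (conjunctive)
        (4.0, 0.6, True),   # only CDS below -> retained (conjunctive)
        (10.0, 0.6, True),
    ])
    def test_conjunctive_default(self, rpkm_cds, rpkm_utr3, kept):
        out = rt.apply_expression_filters([make_estimate(rpkm_cds=rpkm_cds,
                                                         rpkm_utr3=rpkm_utr3)])
        assert out[0].passes_filter is kept

    def test_disjunctive_switch(self):
        out = rt.apply_expression_filters(
            [make_estimate(rpkm_cds=10.0, rpkm_utr3=0.4)], conjunctive=False)
        assert not out[0].passes_filter


class TestHighLow:
    def test_exact_group_sizes(self):
        ests = [make_estimate(gene=f"g{i:03d}", log2_re=-5 + i * 0.01,
                              passes_filter=True) for i in range(100)]
        out = rt.classify_high_low(ests)
        groups = {e.group for e in out}
        assert sum(e.group == "High" for e in out) == 15
        assert sum(e.group == "Low" for e in out) == 15
        assert sum(e.group == "Mid" for e in out) == 70
        highs = sorted(e.log2_re for e in out if e.group == "High")
        lows = sorted(e.log2_re for e in out if e.group == "Low")
        assert min(highs) > max(lows)

    def test_identical_values_rejected(self):
        ests = [make_estimate(gene=f"g{i}", log2_re=-3.0, passes_filter=True)
                for i in range(40)]
        with pytest.raises(ValueError):
            rt.classify_high_low(ests)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        ests = [make_estimate(gene=f"g{i:03d}", log2_re=float(v), passes_filter=True)
                for i, v in enumerate(rng.normal(-4, 1, size=80))]
        a = {e.gene: e.group for e in rt.classify_high_low(ests)}
        b = {e.gene: e.group for e in rt.classify_high_low(ests[::-1])}
        assert a == b

    def test_unfiltered_and_infinite_are_na(self):
        ests = [make_estimate(gene=f"g{i:03d}", log2_re=-5 + i * 0.05,
                              passes_filter=True) for i in range(60)]
        ests.append(make_estimate(gene="bad1", log2_re=-1.0, passes_filter=False))
        ests.append(make_estimate(gene="bad2", log2_re=-math.inf, passes_filter=True))
        out = {e.gene: e.group for e in rt.classify_high_low(ests)}
        assert out["bad1"] == "NA" and out["bad2"] == "NA"

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            rt.classify_high_low([make_estimate(passes_filter=True)] * 3,
                                 fraction=0.15)


class TestPTC(ReCase):
    def place(self, psites):
        return [fp.FootprintRecord("toy", 0, 28, p, fp.frame_of(self.m, p))
                for p in psites]

    def test_ratio_arithmetic(self):
        ptc = self.m.cds_start + 150
        up = [self.m.cds_start + 3 * k for k in range(50)]
        down = [ptc + 3 + 3 * k for k in range(5)]
        res = rt.ptc_readthrough(self.place(up + down), self.m, ptc)
        assert res.n_f0_up == 50 and res.n_f0_down == 5
        assert res.ratio == pytest.approx(0.1)

    def test_zero_downstream(self):
        ptc = self.m.cds_start + 150
        res = rt.ptc_readthrough(self.place([self.m.cds_start]), self.m, ptc)
        assert res.ratio == 0.0

    def test_zero_upstream_flagged(self):
        ptc = self.m.cds_start + 150
        res = rt.ptc_readthrough(self.place([ptc + 3]), self.m, ptc)
        assert math.isnan(res.ratio)

    def test_fold_change_between_samples(self):
        ptc = self.m.cds_start + 150
        up = [self.m.cds_start + 3 * k for k in range(50)]
        down_a = [ptc + 3 + 3 * (k % 10) for k in range(16)]
        r_a = rt.ptc_readthrough(self.place(up + down_a), self.m, ptc).ratio
        down_b = [ptc + 3]
        r_b = rt.ptc_readthrough(self.place(up * 2 + down_b), self.m, ptc).ratio
        assert r_a / r_b == pytest.approx(32.0)

    def test_out_of_frame_position_rejected(self):
        with pytest.raises(ValueError):
            rt.ptc_readthrough([], self.m, self.m.cds_start + 151)


class TestParameterRecovery:
    def test_spearman_and_error_on_shared_sim(self, small_sim, small_estimates):
        truth = small_sim["truth"]
        est = {e.gene: e.log2_re for e in small_estimates if e.finite}
        deep = [g for g in truth.index
                if g in est and truth.loc[g, "true_log2_re"] > -5]
        rho = spearmanr(truth.loc[deep, "true_log2_re"],
                        [est[g] for g in deep]).statistic
        errors = np.abs(truth.loc[deep, "true_log2_re"].to_numpy()
                        - np.array([est[g] for g in deep]))
        assert rho >= 0.9
        assert np.median(errors) <= 0.3

    def test_tsv_round_trip(self, tmp_path, small_estimates):
        path = str(tmp_path / "re.tsv")
        finite = [e for e in small_estimates if e.finite]
        rt.write_estimates_tsv(finite, path)
        back = rt.read_estimates_tsv(path)
        assert [e.gene for e in back] == [e.gene for e in finite]
        assert all(b.log2_re == pytest.approx(e.log2_re, rel=1e-4)
                   for b, e in zip(back, finite))
        assert [b.group for b in back] == [e.group for e in finite]
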