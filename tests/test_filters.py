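"""Filter bank: individual predicates, conjunction semantics, report invariants."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnasm.evidence import ABSENT, EvidenceTable, SiteEvidence
from rnasm.filters import (FILTER_ORDER, RNA_SPECIFIC_FILTERS, FilterConfig,
                           FilterResources, apply_filter_bank,
                           filter_dual_alignment, filter_dual_caller,
                           filter_editing_sites, filter_germline,
                           filter_low_mutated_reads, filter_uneven_coverage,
                           _PREDICATES)
from rnasm.io import EditingSiteSet, GermlineSet, VariantCandidate


def _ev(**overrides):
    base = dict(depth_total=60, alt_count=15, ref_count=45, alt_fwd=8, alt_rev=7,
                ref_fwd=22, ref_rev=23, median_bq_alt=35, median_bq_ref=35,
                median_mq_alt=60, median_mq_ref=60, mean_relpos_alt=0.5,
                frac_softclip_alt=0.05, frac_multimap_alt=0.02, mean_nm_alt=1.0,
                dist_to_junction=80, flank_depth_left=60, flank_depth_right=60,
                aligner2_depth=55, aligner2_alt_count=14, caller2_alt_count=14)
    base.update(overrides)
    return SiteEvidence(**base)


def _balance(alt, ref):
    return dict(alt_count=alt, ref_count=ref, alt_fwd=alt // 2,
                alt_rev=alt - alt // 2, ref_fwd=ref // 2, ref_rev=ref - ref // 2,
                depth_total=alt + ref, flank_depth_left=alt + ref,
                flank_depth_right=alt + ref)


CFG = FilterConfig()


class TestIndividualFilters:
    def test_low_alt_reads_fails(self):
        assert filter_low_mutated_reads(None, _ev(**_balance(2, 58)), CFG)

    def test_good_support_passes(self):
        assert not filter_low_mutated_reads(None, _ev(**_balance(5, 20)), CFG)

    def test_low_mutated_grid_matches_formula(self):
        for alt in range(0, 12):
            for depth in range(max(alt, 1), 60, 7):
                ev = _ev(**_balance(alt, depth - alt))
                expected = alt < CFG.min_alt_reads or alt / depth < CFG.min_vaf
                assert filter_low_mutated_reads(None, ev, CFG) == expected

    def test_dual_alignment(self):
        assert filter_dual_alignment(None, _ev(aligner2_alt_count=0), CFG)
        assert not filter_dual_alignment(None, _ev(aligner2_alt_count=10), CFG)

    def test_dual_alignment_inert_when_absent(self):
        ev = _ev(aligner2_depth=ABSENT, aligner2_alt_count=ABSENT)
        assert not filter_dual_alignment(None, ev, CFG)

    def test_dual_caller(self):
        assert filter_dual_caller(None, _ev(caller2_alt_count=0), CFG)
        assert not filter_dual_caller(None, _ev(caller2_alt_count=10), CFG)
        assert not filter_dual_caller(None, _ev(caller2_alt_count=ABSENT), CFG)

    def test_editing_class_restriction(self):
        sites = EditingSiteSet([("chr1", 500)])
        res = FilterResources(editing=sites)
        ag = VariantCandidate("chr1", 500, "A", "G")
        ct = VariantCandidate("chr1", 500, "C", "T")
        assert filter_editing_sites(ag, _ev(), res, CFG)
        assert not filter_editing_sites(ct, _ev(), res, CFG)
        off = VariantCandidate("chr1", 501, "A", "G")
        assert not filter_editing_sites(off, _ev(), res, CFG)

    def test_uneven_coverage_grid(self):
        for depth in (10, 20, 40):
            for flank in (10, 40, 100):
                ev = _ev(**{**_balance(5, depth - 5),
                            "flank_depth_left": flank, "flank_depth_right": flank})
                expected = depth / max(1, flank) < CFG.min_unevenness_ratio
                assert filter_uneven_coverage(None, ev, CFG) == expected

    def test_germline_allele_exact(self):
        germ = GermlineSet([("chr1", 100, "A", "G")])
        res = FilterResources(germline=germ)
        assert filter_germline(VariantCandidate("chr1", 100, "A", "G"), res, CFG)
        assert not filter_germline(VariantCandidate("chr1", 100, "A", "T"), res, CFG)

    def test_strand_bias_extreme_imbalance(self):
        ev = _ev(alt_fwd=15, alt_rev=0, ref_fwd=0, ref_rev=45)
        assert _PREDICATES["strand_bias"](None, ev, None, CFG)


class TestFilterConfig:
    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            FilterConfig(disabled=frozenset({"not_a_filter"}))

    def test_from_dict_unknown_key(self):
        with pytest.raises(ValueError, match="unknown"):
            FilterConfig.from_dict({"min_depht": 5})


class TestFilterBank:
    def test_all_disabled_passes_everything(self, bench, bench_resources):
        cfg = FilterConfig.all_disabled()
        passed, rep = apply_filter_bank(bench.candidates, bench.evidence,
                                        bench_resources, cfg)
        assert len(passed) == rep.n_input == rep.n_pass
        assert all(v == 0 for v in rep.n_rejected_independent.values())

    def test_single_germline_failure_attribution(self):
        cand = VariantCandidate("chr1", 100, "A", "G")
        ev = EvidenceTable({cand.key: _ev()})
        res = FilterResources(germline=GermlineSet([cand.key]))
        passed, rep = apply_filter_bank([cand], ev, res)
        assert not passed
        assert rep.n_rejected_independent["germline"] == 1
        assert rep.n_rejected_attributed["germline"] == 1
        assert sum(rep.n_rejected_independent.values()) == 1

    def test_brute_force_conjunction_oracle(self, bench, bench_resources):
        """Pass set == candidates for which every enabled predicate passes."""
        cfg = FilterConfig()
        passed, rep = apply_filter_bank(bench.candidates, bench.evidence,
                                        bench_resources, cfg)
        pass_keys = {c.key for c in passed}
        from rnasm.filters import _cluster_fail_keys, _NEEDS_EVIDENCE, _SNV_ONLY
        cluster_keys = _cluster_fail_keys(bench.candidates, cfg)
        for cand in bench.candidates:
            ev = bench.evidence.get(cand.key)
            expect_fail = False
            for fid in FILTER_ORDER:
                if fid == "no_evidence":
                    r = ev is None
                elif fid == "cluster":
                    r = cand.is_snv and cand.key in cluster_keys
                elif ev is None and fid in _NEEDS_EVIDENCE:
                    r = False
                elif fid in _SNV_ONLY and not cand.is_snv:
                    r = False
                else:
                    r = bool(_PREDICATES[fid](cand, ev, bench_resources, cfg))
                expect_fail = expect_fail or r
            assert (cand.key not in pass_keys) == expect_fail

    def test_report_conservation(self, bench, bench_resources):
        _, rep = apply_filter_bank(bench.candidates, bench.evidence, bench_resources)
        assert rep.n_pass + len(rep.failures) == rep.n_input
        assert sum(rep.n_rejected_attributed.values()) == rep.n_input - rep.n_pass
        for f in FILTER_ORDER:
            assert rep.n_rejected_independent[f] >= rep.n_rejected_attributed[f]

    def test_order_independence(self, bench, bench_resources):
        shuffled = list(bench.candidates)
        random.Random(99).shuffle(shuffled)
        p1, r1 = apply_filter_bank(bench.candidates, bench.evidence, bench_resources)
        p2, r2 = apply_filter_bank(shuffled, bench.evidence, bench_resources)
        assert {c.key for c in p1} == {c.key for c in p2}
        assert r1.n_rejected_independent == r2.n_rejected_independent
        assert r1.n_rejected_attributed == r2.n_rejected_attributed

    def test_threshold_tightening_monotone(self, bench, bench_resources):
        """Tightening any single threshold never grows the pass set."""
        base_pass = {c.key for c in apply_filter_bank(
            bench.candidates, bench.evidence, bench_resources, FilterConfig())[0]}
        tightened = [
            FilterConfig(min_depth=20), FilterConfig(min_alt_reads=5),
            FilterConfig(min_vaf=0.10), FilterConfig(min_median_bq=30),
            FilterConfig(max_softclip_frac=0.2), FilterConfig(min_unevenness_ratio=0.8),
            FilterConfig(max_junction_dist_reject=10), FilterConfig(cluster_count=2),
            FilterConfig(min_caller2_alt=5), FilterConfig(min_aligner2_alt=5),
        ]
        for cfg in tightened:
            tighter = {c.key for c in apply_filter_bank(
                bench.candidates, bench.evidence, bench_resources, cfg)[0]}
            assert tighter <= base_pass

    def test_no_evidence_pseudo_filter(self, bench_resources):
        cand = VariantCandidate("chr1", 42, "A", "C")
        passed, rep = apply_filter_bank([cand], EvidenceTable({}), bench_resources)
        assert not passed
        assert rep.n_rejected_attributed["no_evidence"] == 1

    def test_rna_specific_filters_raise_precision(self, bench, bench_resources):
        """Qualitative mirror of the published filter-ablation comparison: the
        RNA-specific filters strictly improve precision on truth labels over
        the DNA-generic subset alone."""
        assert len(RNA_SPECIFIC_FILTERS) == 10
        cls = bench.truth_class_of()

        def precision(cfg):
            passed, _ = apply_filter_bank(bench.candidates, bench.evidence,
                                          bench_resources, cfg)
            good = sum(1 for c in passed if cls[c.key] in ("somatic", "germline"))
            return good / len(passed)

        generic_only = FilterConfig(disabled=RNA_SPECIFIC_FILTERS)
        assert precision(FilterConfig()) > precision(generic_only)


@given(st.integers(min_value=0, max_value=30), st.integers(min_value=0, max_value=200))
@settings(max_examples=100, deadline=None)
def test_low_mutated_reads_matches_inequalities(alt, ref):
    if alt + ref == 0:
        ref = 1
    ev = _ev(**_balance(alt, ref))
    vaf = alt / max(1, alt + ref)
    assert filter_low_mutated_reads(None, ev, CFG) == (alt < 3 or vaf < 0.05)
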