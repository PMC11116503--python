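"""Evidence layer: SAM/BAM summarisation, the tabular path, derived ratios."""

import statistics

import numpy as np
import pysam
import pytest

from rnasm.evidence import (ABSENT, SiteEvidence, evidence_from_alignments,
                            flanking_unevenness, junction_distance,
                            read_evidence_table, summarize_site,
                            write_evidence_table)
from rnasm.io import GenomeAccessor, VariantCandidate
from rnasm.synth import write_reads_bam


def _ev(**overrides):
    base = dict(depth_total=40, alt_count=10, ref_count=30, alt_fwd=5, alt_rev=5,
                ref_fwd=15, ref_rev=15, median_bq_alt=35, median_bq_ref=35,
                median_mq_alt=60, median_mq_ref=60, mean_relpos_alt=0.5,
                frac_softclip_alt=0.0, frac_multimap_alt=0.0, mean_nm_alt=1.0,
                dist_to_junction=-1, flank_depth_left=40, flank_depth_right=40)
    base.update(overrides)
    return SiteEvidence(**base)


class TestSiteEvidenceInvariants:
    @pytest.mark.parametrize("overrides", [
        {"alt_fwd": 6},                          # alt_fwd + alt_rev != alt_count
        {"ref_count": 35, "ref_fwd": 20},        # counts exceed depth
        {"frac_softclip_alt": 1.2},
        {"alt_count": -1, "alt_fwd": -1},
    ])
    def test_violations_raise(self, overrides):
        with pytest.raises(ValueError):
            _ev(**overrides)

    def test_vaf(self):
        assert _ev().vaf == 0.25


class TestFlankingUnevenness:
    def test_flat_coverage(self):
        assert flanking_unevenness(_ev()) == 1.0

    def test_coverage_pit(self):
        ev = _ev(depth_total=20, alt_count=5, ref_count=15, alt_fwd=3, alt_rev=2,
                 ref_fwd=8, ref_rev=7)
        assert flanking_unevenness(ev) == 0.5

    def test_sentinel_flanks_convention(self):
        assert flanking_unevenness(_ev(flank_depth_left=ABSENT,
                                       flank_depth_right=ABSENT)) == 1.0

    def test_formula_oracle(self, rng):
        for _ in range(50):
            d = int(rng.integers(1, 200))
            fl, fr = float(rng.integers(0, 200)), float(rng.integers(0, 200))
            ev = _ev(depth_total=d, alt_count=0, ref_count=0, alt_fwd=0,
                     alt_rev=0, ref_fwd=0, ref_rev=0,
                     flank_depth_left=fl, flank_depth_right=fr)
            expected = d / max(1.0, statistics.median([fl, fr]))
            assert flanking_unevenness(ev) == pytest.approx(expected)


class TestJunctionDistance:
    def test_exact_exon_end(self, bench):
        tx = bench.gene_models.transcripts[0]
        chrom = bench.gene_models._tx_chrom.get(tx.transcript_id) or "chr1"
        chrom = bench.gene_models._gene_chrom[tx.gene_id]
        assert junction_distance(bench.gene_models, chrom, tx.exons[0][1]) == 0

    def test_intergenic(self, bench):
        # position 1 lies before the first gene slot's random offset most of the
        # time; search for a guaranteed intergenic position instead
        for pos in range(1, 5000):
            if not bench.gene_models.overlapping_transcripts("chr1", pos):
                assert junction_distance(bench.gene_models, "chr1", pos) == -1
                return
        pytest.skip("no intergenic position found in scan range")

    def test_exhaustive_scan_oracle(self, bench, rng):
        gm = bench.gene_models
        boundaries = {}
        for gid, txs in gm.genes.items():
            chrom = gm._gene_chrom[gid]
            for s, e in txs[0].exons:
                boundaries.setdefault(chrom, []).extend([s, e])
        for pos in rng.integers(1, 200_000, 200):
            pos = int(pos)
            txs = gm.overlapping_transcripts("chr1", pos)
            got = junction_distance(gm, "chr1", pos)
            if not txs:
                assert got == -1
            else:
                spans = [b for tx in txs for se in tx.exons for b in se]
                expected = min(abs(b - pos) for b in spans)
                assert got == expected


class TestSummarizeSite:
    def _bam(self, tmp_path, reads, chrom_len=500):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c1", "LN": chrom_len}]}
        path = tmp_path / "t.bam"
        reads.sort(key=lambda r: r.reference_start)
        with pysam.AlignmentFile(path, "wb", header=header) as fh:
            for r in reads:
                fh.write(r)
        pysam.index(str(path))
        return pysam.AlignmentFile(path)

    def _read(self, name, start0, seq, cigar=None, reverse=False, mapq=60,
              qual=35, dup=False):
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = seq
        a.flag = (16 if reverse else 0) | (1024 if dup else 0)
        a.reference_id = 0
        a.reference_start = start0
        a.mapping_quality = mapq
        a.cigartuples = cigar or [(pysam.CMATCH, len(seq))]
        a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
        a.set_tag("NM", 1)
        return a

    def test_constructed_counts(self, tmp_path):
        # 30 ref reads (15+/15-), 10 alt reads (5+/5-) over a site at pos 101
        reads = []
        for i in range(30):
            reads.append(self._read(f"ref{i}", 60, "A" * 80, reverse=i % 2 == 0))
        for i in range(10):
            seq = list("A" * 80)
            seq[100 - 60] = "G"
            reads.append(self._read(f"alt{i}", 60, "".join(seq), reverse=i % 2 == 0))
        af = self._bam(tmp_path, reads)
        cand = VariantCandidate("c1", 101, "A", "G")
        ev = summarize_site(af, cand)
        assert (ev.depth_total, ev.alt_count, ev.ref_count) == (40, 10, 30)
        assert (ev.alt_fwd, ev.alt_rev, ev.ref_fwd, ev.ref_rev) == (5, 5, 15, 15)
        assert ev.median_bq_alt == 35 and ev.median_mq_alt == 60

    def test_softclipped_alt_not_counted(self, tmp_path):
        # alt base only inside the soft-clipped prefix -> zero alt support
        seq = "G" + "A" * 79
        reads = [self._read("sc", 101, seq, cigar=[(pysam.CSOFT_CLIP, 1),
                                                   (pysam.CMATCH, 79)])]
        af = self._bam(tmp_path, reads)
        ev = summarize_site(af, VariantCandidate("c1", 101, "A", "G"))
        assert ev.alt_count == 0

    def test_low_bq_excluded_from_counts_but_not_depth(self, tmp_path):
        reads = [self._read("lo", 60, "A" * 40 + "G" + "A" * 39, qual=5),
                 self._read("hi", 60, "A" * 80)]
        af = self._bam(tmp_path, reads)
        ev = summarize_site(af, VariantCandidate("c1", 101, "A", "G"))
        assert ev.alt_count == 0 and ev.depth_total == 2

    def test_duplicates_only_in_dup_frac(self, tmp_path):
        reads = [self._read("d", 60, "A" * 80, dup=True),
                 self._read("k", 60, "A" * 80)]
        af = self._bam(tmp_path, reads)
        ev = summarize_site(af, VariantCandidate("c1", 101, "A", "G"))
        assert ev.depth_total == 1 and ev.dup_frac == 0.5

    def test_read_level_tally_oracle(self, bench, tmp_path):
        # generate reads for a handful of SNV truth sites and re-tally by hand
        tdf = bench.truth.table
        sites = tdf[(tdf.ref.str.len() == 1) & (tdf.alt.str.len() == 1)].head(20)
        bam = write_reads_bam(bench.genome, sites, tmp_path / "sites.bam",
                              seed=5, depth=40)
        with pysam.AlignmentFile(bam) as af:
            for row in sites.itertuples(index=False):
                cand = VariantCandidate(row.chrom, int(row.pos), row.ref, row.alt)
                ev = summarize_site(af, cand)
                # independent tally: walk every read covering the column
                n_alt = n_ref = n_depth = 0
                for read in af.fetch(row.chrom, row.pos - 1, row.pos):
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                        if rpos == row.pos - 1:
                            n_depth += 1
                            b = read.query_sequence[qpos]
                            if b == row.alt:
                                n_alt += 1
                            elif b == row.ref:
                                n_ref += 1
                assert ev.depth_total == n_depth
                assert ev.alt_count == n_alt
                assert ev.ref_count == n_ref


class TestEvidenceTableIO:
    def test_roundtrip_benchmark(self, bench, tmp_path):
        p = tmp_path / "ev.tsv"
        write_evidence_table(bench.evidence, p)
        back = read_evidence_table(p)
        assert len(back) == len(bench.evidence)
        for key, ev in bench.evidence.items():
            assert back[key] == ev

    def test_invariant_violation_rejected(self, bench, tmp_path):
        p = tmp_path / "ev.tsv"
        write_evidence_table(bench.evidence, p)
        lines = p.read_text().splitlines()
        cols = lines[0].split("\t")
        row = lines[1].split("\t")
        row[cols.index("alt_fwd")] = str(int(row[cols.index("alt_fwd")]) + 1)
        p.write_text("\n".join([lines[0], "\t".join(row)]) + "\n")
        with pytest.raises(ValueError):
            read_evidence_table(p)

    def test_missing_optional_columns_become_absent(self, bench, tmp_path):
        import pandas as pd
        p = tmp_path / "ev.tsv"
        write_evidence_table(bench.evidence, p)
        df = pd.read_csv(p, sep="\t").drop(
            columns=["aligner2_depth", "aligner2_alt_count", "caller2_alt_count"])
        df.to_csv(p, sep="\t", index=False)
        back = read_evidence_table(p)
        ev = next(iter(back.items()))[1]
        assert not ev.has_aligner2 and not ev.has_caller2

    def test_tabular_path_matches_alignment_path(self, bench, tmp_path):
        """Evidence written then reread drives identical filter outcomes."""
        from rnasm.filters import FilterResources, apply_filter_bank
        p = tmp_path / "ev.tsv"
        write_evidence_table(bench.evidence, p)
        back = read_evidence_table(p)
        res = FilterResources(germline=bench.germline, editing=bench.editing,
                              gene_models=bench.gene_models, genome=bench.genome)
        pass1, rep1 = apply_filter_bank(bench.candidates, bench.evidence, res)
        pass2, rep2 = apply_filter_bank(bench.candidates, back, res)
        assert [c.key for c in pass1] == [c.key for c in pass2]
        assert rep1.n_rejected_independent == rep2.n_rejected_independent
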