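# Evidence table schema

Tab-delimited, one header line, one row per candidate site. This is the
alignment-free input path: any pipeline that can produce these summaries can
drive the filter bank and classifier without BAM access. Key columns plus the
22 evidence fields, 26 columns total.

| # | column | type | meaning |
|---|--------|------|---------|
| 1 | chrom | str | chromosome name, verbatim |
| 2 | pos | int | 1-based position |
| 3 | ref | str | reference allele |
| 4 | alt | str | alternate allele |
| 5 | depth_total | int | reads covering the site (duplicates excluded) |
| 6 | alt_count | int | alt-supporting reads (= alt_fwd + alt_rev) |
| 7 | ref_count | int | ref-supporting reads (= ref_fwd + ref_rev) |
| 8 | alt_fwd | int | alt reads on the forward strand |
| 9 | alt_rev | int | alt reads on the reverse strand |
| 10 | ref_fwd | int | ref reads on the forward strand |
| 11 | ref_rev | int | ref reads on the reverse strand |
| 12 | median_bq_alt | float | median Phred base quality, alt reads |
| 13 | median_bq_ref | float | median Phred base quality, ref reads |
| 14 | median_mq_alt | float | median mapping quality, alt reads |
| 15 | median_mq_ref | float | median mapping quality, ref reads |
| 16 | mean_relpos_alt | float | mean fractional position of the variant base within alt reads, [0, 1] |
| 17 | frac_softclip_alt | float | fraction of alt reads with a soft clip within 10 bp of the site |
| 18 | frac_multimap_alt | float | fraction of alt reads with MQ 0 or secondary flag |
| 19 | mean_nm_alt | float | mean per-read mismatch count among alt reads |
| 20 | dist_to_junction | int | bp to the nearest exon boundary of an overlapping gene; −1 if intergenic |
| 21 | flank_depth_left | float | median depth over the 25 bp left flank |
| 22 | flank_depth_right | float | median depth over the 25 bp right flank |
| 23 | aligner2_depth | int | depth after realignment with the second aligner; −1 = absent |
| 24 | aligner2_alt_count | int | alt support after realignment; −1 = absent |
| 25 | caller2_alt_count | int | alt support reported by the second caller's pileup; −1 = absent |
| 26 | dup_frac | float | fraction of duplicate-flagged reads at the site |

Columns 23–25 may be omitted entirely; readers fill them with the −1
sentinel, which makes the dual-aligner, dual-caller and junction-corroboration
checks inert. Invariants enforced on read: unique (chrom, pos, ref, alt)
keys, stranded counts summing to the allele counts, allele counts not
exceeding depth, fractions within [0, 1].
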