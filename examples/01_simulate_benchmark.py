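"""Generate the synthetic benchmark and look at what it contains.

The generator builds a miniature genome with GC-rich/poor blocks, gene models,
and 2,000 truth-labelled variant candidates spanning six classes: true somatic
mutations, germline variants, A-to-I editing sites, reverse-transcription
noise, and soft-clip / splice-junction alignment artifacts. Each candidate
carries per-site read evidence with a class-specific fingerprint.
"""

import tempfile

from rnasm.synth import make_benchmark

with tempfile.TemporaryDirectory() as td:
    bench = make_benchmark(seed=1, outdir=td, n_sites=2000)

    print("truth class counts:")
    print(bench.truth.class_counts.to_string())
    print(f"\ncandidates: {len(bench.candidates)}")
    print(f"known editing sites in BED: {len(bench.editing)}")
    print(f"germline variants in matched-normal VCF: {len(bench.germline)}")
    ev = bench.evidence[bench.candidates[0].key]
    print(f"\nexample evidence row: depth={ev.depth_total}, alt={ev.alt_count}, "
          f"VAF={ev.vaf:.2f}, softclip={ev.frac_softclip_alt:.2f}")

# The class counts follow the configured mixture (40% somatic, 15% each for
# germline/editing/RT noise, 7.5% per alignment-artifact class); only ~60% of
# editing truths appear in the known-sites BED — the rest must be caught
# downstream by the classifier.
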