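"""Build a 96-channel mutational spectrum, fit signature exposures, and assign
individual mutations to signatures under the 0.75 likelihood rule.

Exposures are fitted by non-negative least squares against a fixed reference
signature matrix and rescaled to mutation counts; a mutation in channel c is
assigned to signature k iff  exposure_k * S[c,k] / sum_j exposure_j * S[c,j]
exceeds 0.75, else it stays "unassigned".
"""

import tempfile
from collections import Counter

import numpy as np

from rnasm.io import VariantCandidate
from rnasm.signatures import (assign_mutations, build_spectrum, class_marginal,
                              fit_exposures, sample_spectrum)
from rnasm.synth import make_benchmark, synthetic_signatures

with tempfile.TemporaryDirectory() as td:
    bench = make_benchmark(seed=1, outdir=td, n_sites=2000)
    tdf = bench.truth.table
    muts = [VariantCandidate(r.chrom, int(r.pos), r.ref, r.alt,
                             sample_id=r.sample_id)
            for r in tdf.itertuples(index=False)]
    spectrum = build_spectrum(muts, bench.genome)
    print("six-class marginal summed over samples:")
    print(class_marginal(spectrum).sum(axis=1).astype(int).to_string())

    sigs = synthetic_signatures()
    mixed = sample_spectrum(sigs, [0.6, 0.4, 0.0], 2000, np.random.default_rng(1))
    exposures, resid = fit_exposures(mixed, sigs)
    print(f"\n60/40/0 mixture refit: {np.round(exposures / exposures.sum(), 3)}")

    sample = spectrum.columns[0]
    smuts = [m for m in muts if m.sample_id == sample and m.is_snv]
    e, _ = fit_exposures(spectrum[sample].to_numpy(), sigs)
    a = assign_mutations(smuts, bench.genome, e, sigs)
    print(f"\nassignments for {sample}: {dict(Counter(a.signature))}")

# The T>C class dominates the raw spectrum (editing truths plus genuine T>C
# somatic mutations); the refitted mixture recovers the 60/40 proportions to
# within a few percent, and only mutations whose channel is strongly owned by
# one signature clear the 0.75 rule — the rest stay unassigned.
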