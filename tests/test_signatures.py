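"""Spectra and signatures: classes, channels, NNLS exposures, assignment rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from rnasm.io import (COMPLEMENT, GenomeAccessor, SBS96_CHANNELS,
                      SignatureMatrix, SUBST_CLASSES, VariantCandidate)
from rnasm.signatures import (assign_mutations, build_spectrum, class_marginal,
                              fit_exposures, sample_spectrum,
                              substitution_class, trinucleotide_context)
from rnasm.synth import synthetic_signatures


class TestSubstitutionClass:
    def test_editing_appearance(self):
        # adenosine deamination reads out as T>C after pyrimidine collapse
        assert substitution_class("A", "G") == "T>C"

    def test_pyrimidine_identity(self):
        assert substitution_class("C", "T") == "C>T"

    def test_exhaustive_two_per_class(self):
        classes = [substitution_class(r, a)
                   for r, a in itertools.permutations("ACGT", 2)]
        assert sorted(set(classes)) == sorted(SUBST_CLASSES)
        for c in SUBST_CLASSES:
            assert classes.count(c) == 2

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_invariance(self, ref, alt):
        if ref == alt:
            return
        assert substitution_class(ref, alt) == substitution_class(
            COMPLEMENT[ref], COMPLEMENT[alt])


@pytest.fixture(scope="module")
def ctx_fasta(tmp_path_factory):
    p = tmp_path_factory.mktemp("ctx") / "ctx.fa"
    p.write_text(">k\nAACAATGTA\n")  # ACA at 2-4, TGT at 5-7 (revcomp pair)
    return GenomeAccessor(p)


class TestTrinucleotideContext:
    def test_direct_convention(self, ctx_fasta):
        idx = trinucleotide_context(ctx_fasta, "k", 3, "C", "T")
        assert SBS96_CHANNELS[idx] == "A[C>T]A"

    def test_strand_collapse(self, ctx_fasta):
        # TGT with G>A at centre is the reverse complement of ACA with C>T
        i1 = trinucleotide_context(ctx_fasta, "k", 3, "C", "T")
        i2 = trinucleotide_context(ctx_fasta, "k", 7, "G", "A")
        assert i1 == i2

    def test_ref_mismatch_raises(self, ctx_fasta):
        with pytest.raises(ValueError, match="ref"):
            trinucleotide_context(ctx_fasta, "k", 3, "G", "A")

    def test_second_implementation_oracle(self, bench, rng):
        """Channel indices match an independent label-table construction."""
        lut = {}
        for ci, cls in enumerate(SUBST_CLASSES):
            for fi, five in enumerate("ACGT"):
                for ti, three in enumerate("ACGT"):
                    lut[(five, cls, three)] = ci * 16 + fi * 4 + ti
        g = bench.genome
        tdf = bench.truth.table
        snvs = tdf[(tdf.ref.str.len() == 1) & (tdf.alt.str.len() == 1)]
        take = snvs.sample(n=min(500, len(snvs)), random_state=11)
        for row in take.itertuples(index=False):
            tri = g.fetch(row.chrom, int(row.pos) - 1, int(row.pos) + 1)
            if row.ref in "CT":
                key = (tri[0], f"{row.ref}>{row.alt}", tri[2])
            else:
                key = (COMPLEMENT[tri[2]],
                       f"{COMPLEMENT[row.ref]}>{COMPLEMENT[row.alt]}",
                       COMPLEMENT[tri[0]])
            assert trinucleotide_context(g, row.chrom, int(row.pos),
                                         row.ref, row.alt) == lut[key]

    def test_spectrum_invariant_under_genome_revcomp(self, tmp_path):
        seq = "ACATTGCAGT"
        rc = "".join(COMPLEMENT[b] for b in reversed(seq))
        (tmp_path / "f.fa").write_text(f">z\n{seq}\n")
        (tmp_path / "r.fa").write_text(f">z\n{rc}\n")
        g1, g2 = GenomeAccessor(tmp_path / "f.fa"), GenomeAccessor(tmp_path / "r.fa")
        n = len(seq)
        for pos in range(2, n):
            ref = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                i1 = trinucleotide_context(g1, "z", pos, ref, alt)
                i2 = trinucleotide_context(g2, "z", n - pos + 1,
                                           COMPLEMENT[ref], COMPLEMENT[alt])
                assert i1 == i2


class TestBuildSpectrum:
    def test_empty(self, bench):
        df = build_spectrum([], bench.genome)
        assert df.shape[0] == 96 and df.shape[1] == 0

    def test_ten_identical_mutations_single_channel(self, bench):
        tdf = bench.truth.table
        row = tdf[(tdf.ref == "A") & (tdf.alt == "G")].iloc[0]
        muts = [VariantCandidate(row.chrom, int(row.pos), "A", "G", sample_id="s")
                for _ in range(10)]
        df = build_spectrum(muts, bench.genome)
        assert df["s"].sum() == 10 and (df["s"] > 0).sum() == 1
        assert df["s"].max() == 10

    def test_channel_sums_equal_snv_counts(self, bench):
        tdf = bench.truth.table
        snvs = tdf[(tdf.ref.str.len() == 1) & (tdf.alt.str.len() == 1)]
        muts = [VariantCandidate(r.chrom, int(r.pos), r.ref, r.alt,
                                 sample_id=r.sample_id)
                for r in tdf.itertuples(index=False)]
        df = build_spectrum(muts, bench.genome)
        assert df.to_numpy().sum() == len(snvs)
        assert df.attrs["n_skipped"] == len(tdf) - len(snvs)
        per_sample = snvs.groupby("sample_id").size()
        for s in df.columns:
            assert df[s].sum() == per_sample[s]

    def test_sampling_consistency_chisquare(self, rng):
        """Spectra drawn from known channel probabilities are not rejected by a
        goodness-of-fit test at alpha = 0.01 (n = 5,000)."""
        sigs = synthetic_signatures()
        p = sigs.values @ np.array([0.5, 0.3, 0.2])
        counts = sample_spectrum(sigs, [0.5, 0.3, 0.2], 5000, rng)
        stat, pval = chisquare(counts, 5000 * p)
        assert pval > 0.01

    def test_class_marginal_collapse(self, rng):
        vec = rng.integers(0, 20, 96)
        m = class_marginal(vec)
        assert m.to_numpy().sum() == vec.sum()
        np.testing.assert_array_equal(
            m.to_numpy().ravel(), vec.reshape(6, 16).sum(axis=1))


class TestFitExposures:
    def test_exact_single_signature(self):
        sigs = synthetic_signatures()
        spec = 1000.0 * sigs.values[:, 1]
        e, rnorm = fit_exposures(spec, sigs)
        assert e[1] == pytest.approx(1000, abs=1e-6)
        assert abs(e[0]) < 1e-6 and abs(e[2]) < 1e-6

    def test_zero_spectrum(self):
        sigs = synthetic_signatures()
        e, rnorm = fit_exposures(np.zeros(96), sigs)
        assert np.all(e == 0) and rnorm == 0

    def test_mixture_recovery(self, rng):
        sigs = synthetic_signatures()
        spec = sample_spectrum(sigs, [0.6, 0.4, 0.0], 2000, rng)
        e, _ = fit_exposures(spec, sigs)
        props = e / e.sum()
        assert props[0] == pytest.approx(0.6, abs=0.05)
        assert props[1] == pytest.approx(0.4, abs=0.05)
        rec = sigs.values @ e
        cos = rec @ spec / (np.linalg.norm(rec) * np.linalg.norm(spec))
        assert cos >= 0.95

    def test_matches_bounded_least_squares_oracle(self, rng):
        """NNLS residual equals an independent bounded-variable solver's."""
        from scipy.optimize import lsq_linear
        sigs = synthetic_signatures()
        for _ in range(5):
            spec = rng.integers(0, 50, 96).astype(float)
            e, rnorm = fit_exposures(spec, sigs)
            sol = lsq_linear(sigs.values, spec, bounds=(0, np.inf), tol=1e-14)
            oracle_res = np.linalg.norm(sigs.values @ sol.x - spec)
            assert rnorm <= oracle_res + 1e-8

    def test_exposures_nonnegative_and_rescaled(self, rng):
        sigs = synthetic_signatures()
        spec = rng.integers(0, 30, 96).astype(float)
        e, _ = fit_exposures(spec, sigs)
        assert (e >= 0).all()
        assert e.sum() == pytest.approx(spec.sum())


def _two_channel_sigs(v0a=0.9, v0b=0.02, v1=0.04):
    """Two signatures with hand-set intensity at channels 0 and 1; channel 2
    carries equal weight in both (for the symmetry case)."""
    vals = np.zeros((96, 2))
    vals[0] = [v0a, v0b]
    vals[1] = [v0b, v0a]
    vals[2] = [v1, v1]
    rest = 1.0 - (v0a + v0b + v1)
    vals[3:, 0] = rest / 93
    vals[3:, 1] = rest / 93
    return SignatureMatrix(vals, ("sigX", "sigY"))


class TestAssignMutations:
    def test_single_signature_likelihood_one(self, tmp_path):
        g = _mini_genome(tmp_path)
        sigs = _two_channel_sigs()
        muts = [VariantCandidate("m", 2, "C", "A")]  # channel A[C>A]A = 0
        a = assign_mutations(muts, g, np.array([100.0, 0.0]), sigs)
        assert a.signature == ["sigX"] and a.likelihood[0] == pytest.approx(1.0)

    def test_symmetric_channel_unassigned(self, tmp_path):
        g = _mini_genome(tmp_path)
        sigs = _two_channel_sigs()
        muts = [VariantCandidate("m", 7, "C", "A")]  # channel A[C>A]G = 2
        a = assign_mutations(muts, g, np.array([50.0, 50.0]), sigs)
        assert a.signature == ["unassigned"]
        assert a.likelihood[0] == pytest.approx(0.5)

    def test_hand_computed_bayes_ratios(self, tmp_path):
        g = _mini_genome(tmp_path)
        sigs = _two_channel_sigs()
        eX, eY = 300.0, 100.0
        a = assign_mutations(
            [VariantCandidate("m", 2, "C", "A"),   # channel 0
             VariantCandidate("m", 4, "C", "A")],  # channel 1 (A[C>A]C)
            g, np.array([eX, eY]), sigs)
        lik0 = eX * 0.9 / (eX * 0.9 + eY * 0.02)
        assert a.likelihood[0] == pytest.approx(lik0)
        assert a.signature[0] == ("sigX" if lik0 > 0.75 else "unassigned")
        lik1 = eY * 0.9 / (eX * 0.02 + eY * 0.9)
        assert a.likelihood[1] == pytest.approx(max(lik1, 1 - lik1))

    def test_rule_boundary_is_strict(self, tmp_path):
        # likelihood exactly 0.75 stays unassigned (> 0.75 required)
        g = _mini_genome(tmp_path)
        sigs = _two_channel_sigs()
        # choose exposures so that posterior at channel 0 is exactly 0.75:
        # eX*0.9 / (eX*0.9 + eY*0.02) = 0.75  =>  eY = eX * 0.9 / (3*0.02)
        eX = 10.0
        eY = eX * 0.9 / (3 * 0.02)
        a = assign_mutations([VariantCandidate("m", 2, "C", "A")], g,
                             np.array([eX, eY]), sigs)
        assert a.likelihood[0] == pytest.approx(0.75)
        assert a.signature == ["unassigned"]

    def test_likelihoods_sum_to_one_over_active_signatures(self, tmp_path, rng):
        g = _mini_genome(tmp_path)
        sigs = synthetic_signatures()
        e = rng.random(3) * 100
        intensity = sigs.values * e[None, :]
        posts = intensity / intensity.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(posts.sum(axis=1), 1.0, atol=1e-12)


def _mini_genome(tmp_path):
    # "ACACCACGT": pos2 (A,C,A) -> channel 0; pos4 (A,C,C) -> channel 1;
    # pos7 (A,C,G) -> channel 2
    p = tmp_path / "mini.fa"
    p.write_text(">m\nACACCACGT\n")
    return GenomeAccessor(p)
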