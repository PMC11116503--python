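"""Substitution classes, 96-channel trinucleotide spectra, reference-signature
exposure fitting, and per-mutation signature assignment.

Substitutions are pyrimidine-collapsed: a purine-reference change is
reverse-complemented together with its flanking context, so every SNV maps to
one of 6 classes x 16 contexts = 96 channels in COSMIC SBS row order.
Exposures are fitted by non-negative least squares against a fixed reference
signature matrix (deterministic supervised refitting; de novo discovery is out
of scope), and each mutation is assigned to the signature whose posterior
likelihood at the mutation's channel exceeds 0.75, else left "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import (COMPLEMENT, SBS96_CHANNELS, SBS96_INDEX, SUBST_CLASSES,
                 GenomeAccessor, SignatureMatrix, VariantCandidate)

__all__ = [
    "substitution_class",
    "trinucleotide_context",
    "channel_label",
    "build_spectrum",
    "class_marginal",
    "fit_exposures",
    "assign_mutations",
    "SignatureAssignment",
    "sample_spectrum",
]

_PYRIMIDINES = {"C", "T"}
_CLASS_INDEX = {c: i for i, c in enumerate(SUBST_CLASSES)}


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-collapsed class of a single-base substitution.

    Purine-reference changes are reverse-complemented, e.g. A>G -> T>C (the
    appearance of A-to-I editing in sequencing data).
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"substitution_class needs single bases, got {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    if ref in _PYRIMIDINES:
        return f"{ref}>{alt}"
    return f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"


def trinucleotide_context(genome: GenomeAccessor, chrom: str, pos: int,
                          ref: str, alt: str) -> int:
    """SBS96 channel index (0-95) of an SNV given its genomic context.

    The genome base at pos must equal ref. When ref is a purine the substitution
    and its 5'/3' flanks are reverse-complemented together (strand collapse).
    """
    n = genome.chrom_lengths[chrom]
    if not (2 <= pos <= n - 1):
        raise ValueError(f"{chrom}:{pos} lacks a flanking base on both sides")
    tri = genome.fetch(chrom, pos - 1, pos + 1)
    if tri[1] != ref:
        raise ValueError(f"genome base {tri[1]} != ref {ref} at {chrom}:{pos}")
    if ref in _PYRIMIDINES:
        five, three, r, a = tri[0], tri[2], ref, alt
    else:
        rc = _revcomp(tri)
        five, three = rc[0], rc[2]
        r, a = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{five}[{r}>{a}]{three}"
    if label not in SBS96_INDEX:
        raise ValueError(f"context contains non-ACGT base at {chrom}:{pos} ({label})")
    return SBS96_INDEX[label]


def channel_label(index: int) -> str:
    return SBS96_CHANNELS[index]


def build_spectrum(mutations: Iterable[VariantCandidate], genome: GenomeAccessor
                   ) -> pd.DataFrame:
    """Per-sample 96-channel count matrix (rows = channels, columns = samples).

    Indels are skipped (their count is recorded in ``df.attrs['n_skipped']``);
    channel sums per sample equal the number of SNVs contributed by that sample.
    """
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for m in mutations:
        if not m.is_snv:
            skipped += 1
            continue
        idx = trinucleotide_context(genome, m.chrom, m.pos, m.ref, m.alt)
        vec = counts.setdefault(m.sample_id, np.zeros(96, dtype=np.int64))
        vec[idx] += 1
    df = pd.DataFrame(counts if counts else {},
                      index=list(SBS96_CHANNELS), dtype=np.int64)
    df.attrs["n_skipped"] = skipped
    return df


def class_marginal(spectrum: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Collapse 96 channels to the 6 substitution classes."""
    arr = np.asarray(spectrum, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    out = arr.reshape(6, 16, -1).sum(axis=1)
    cols = list(spectrum.columns) if isinstance(spectrum, pd.DataFrame) else None
    return pd.DataFrame(out, index=list(SUBST_CLASSES), columns=cols)


def fit_exposures(spectrum: np.ndarray | pd.Series, sigs: SignatureMatrix
                  ) -> tuple[np.ndarray, float]:
    """Nonnegative exposures minimising || spectrum - S @ e ||_2 (NNLS), rescaled
    so the exposures sum to the spectrum's total mutation count.

    Returns (exposures, residual norm of the unrescaled fit). An all-zero
    spectrum yields zero exposures.
    """
    v = np.asarray(spectrum, dtype=float).ravel()
    if v.shape != (96,):
        raise ValueError(f"spectrum must be a 96-vector, got {v.shape}")
    if (v < 0).any():
        raise ValueError("spectrum has negative counts")
    total = v.sum()
    if total == 0:
        return np.zeros(sigs.n_signatures), 0.0
    e, rnorm = nnls(sigs.values, v)
    s = e.sum()
    if s > 0:
        e = e * (total / s)
    return e, float(rnorm)


@dataclass
class SignatureAssignment:
    """Per-mutation signature labels under the 0.75 likelihood rule, plus the
    per-sample exposure vector used to compute them."""

    mutation_keys: list[tuple]
    signature: list[str]         # signature name or "unassigned"
    likelihood: list[float]
    exposures: np.ndarray
    signature_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "key": ["|".join(map(str, k)) for k in self.mutation_keys],
            "signature": self.signature,
            "likelihood": self.likelihood,
        })


def assign_mutations(mutations: Sequence[VariantCandidate], genome: GenomeAccessor,
                     exposures: np.ndarray, sigs: SignatureMatrix,
                     likelihood_floor: float = 0.75) -> SignatureAssignment:
    """Assign each SNV to a reference signature by posterior likelihood.

    For a mutation in channel c, the likelihood of signature k is
    ``exposure_k * S[c, k] / sum_j exposure_j * S[c, j]``; the argmax signature
    is assigned iff its likelihood exceeds ``likelihood_floor`` (default 0.75),
    otherwise the mutation is "unassigned". Channels with zero total intensity
    under the exposures are unassigned with likelihood 0.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (sigs.n_signatures,):
        raise ValueError("exposure vector length != number of signatures")
    keys, labels, liks = [], [], []
    intensity = sigs.values * exposures[None, :]  # (96, K)
    denom = intensity.sum(axis=1)
    for m in mutations:
        keys.append(m.key)
        if not m.is_snv:
            labels.append("unassigned")
            liks.append(0.0)
            continue
        c = trinucleotide_context(genome, m.chrom, m.pos, m.ref, m.alt)
        if denom[c] <= 0:
            labels.append("unassigned")
            liks.append(0.0)
            continue
        post = intensity[c] / denom[c]
        k = int(np.argmax(post))
        if post[k] > likelihood_floor:
            labels.append(sigs.names[k])
        else:
            labels.append("unassigned")
        liks.append(float(post[k]))
    return SignatureAssignment(keys, labels, liks, exposures, sigs.names)


def sample_spectrum(sigs: SignatureMatrix, proportions: Sequence[float], n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw an n-mutation 96-channel count vector from a signature mixture
    (used by simulation experiments and exposure-recovery checks)."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (sigs.n_signatures,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("proportions must be a nonnegative vector summing to 1")
    channel_p = sigs.values @ p
    return rng.multinomial(n, channel_p)
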