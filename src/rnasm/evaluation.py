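"""Validation harness: overlap with DNA-derived mutation sets under the
coverage-exclusion rule, per-patient precision/sensitivity, per-transition-class
FDR, depth/GC-binned validation curves, and the expression-gated input table
for downstream significantly-mutated-gene analysis.

"Validated" means allele-exact membership of a predicted mutation in the union
of DNA reference sets; a position-only mode exists for sensitivity analyses.
Sites covered by fewer than ``min_depth`` reads in *any* platform are excluded
from both numerator and denominator, mirroring cross-platform comparisons that
must not penalise a platform for sites it cannot see.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModelIndex
from .signatures import SUBST_CLASSES, substitution_class

__all__ = [
    "ValidationResult",
    "validate",
    "fdr_by_transition",
    "binned_validation",
    "smg_input_table",
    "lower_median",
]

Key = tuple  # (sample, chrom, pos, ref, alt)


def lower_median(values: Sequence[float]) -> float:
    """Median using the lower of the two middle values for even counts."""
    v = sorted(values)
    if not v:
        return float("nan")
    return float(v[(len(v) - 1) // 2])


@dataclass
class ValidationResult:
    precision: float
    sensitivity: float
    per_patient_precision: dict[str, float]
    per_patient_sensitivity: dict[str, float]
    n_validated: int
    n_compared: int
    n_reference_covered: int
    n_excluded_low_coverage: int
    overlap_counts: dict[str, int] = field(default_factory=dict)

    @property
    def median_precision(self) -> float:
        return lower_median([v for v in self.per_patient_precision.values()
                             if not math.isnan(v)])

    @property
    def median_sensitivity(self) -> float:
        return lower_median([v for v in self.per_patient_sensitivity.values()
                             if not math.isnan(v)])


def _covered(key: Key, depth_lookups: Sequence[Mapping[tuple, int]], min_depth: int) -> bool:
    site = key[:3]  # (sample, chrom, pos)
    for lut in depth_lookups:
        if lut.get(site, 0) < min_depth:
            return False
    return True


def validate(rna_sms: Iterable[Key],
             reference_sets: Sequence[set],
             depth_lookups: Sequence[Mapping[tuple, int]],
             min_depth: int = 10,
             allele_exact: bool = True) -> ValidationResult:
    """Cross-platform validation of predicted mutations against DNA references.

    Keys are (sample, chrom, pos, ref, alt). ``depth_lookups`` maps
    (sample, chrom, pos) -> read depth, one mapping per sequencing platform
    (RNA and each DNA platform); sites under ``min_depth`` in any platform are
    excluded entirely. Precision = validated / compared predictions;
    sensitivity = reference mutations with adequate coverage that were
    recovered. Swapping predictions and the reference swaps the two metrics.
    """
    if not depth_lookups:
        raise ValueError("at least one depth lookup is required")
    preds = set(rna_sms)
    reference = set().union(*reference_sets) if reference_sets else set()

    def match_key(k: Key) -> tuple:
        return k if allele_exact else k[:3]

    ref_match = {match_key(k) for k in reference}

    compared = {k for k in preds if _covered(k, depth_lookups, min_depth)}
    n_excluded = len(preds) - len(compared)
    validated = {k for k in compared if match_key(k) in ref_match}

    ref_covered = {k for k in reference if _covered(k, depth_lookups, min_depth)}
    pred_match = {match_key(k) for k in compared}
    recovered = {k for k in ref_covered if match_key(k) in pred_match}

    per_prec: dict[str, float] = {}
    per_sens: dict[str, float] = {}
    samples = {k[0] for k in compared} | {k[0] for k in ref_covered}
    for s in sorted(samples):
        c = [k for k in compared if k[0] == s]
        v = [k for k in validated if k[0] == s]
        r = [k for k in ref_covered if k[0] == s]
        g = [k for k in recovered if k[0] == s]
        per_prec[s] = len(v) / len(c) if c else float("nan")
        per_sens[s] = len(g) / len(r) if r else float("nan")

    overlap = {"validated": len(validated), "rna_only": len(compared) - len(validated)}
    for i, ref_set in enumerate(reference_sets):
        rm = {match_key(k) for k in ref_set}
        overlap[f"overlap_ref{i}"] = sum(1 for k in compared if match_key(k) in rm)

    return ValidationResult(
        precision=len(validated) / len(compared) if compared else float("nan"),
        sensitivity=len(recovered) / len(ref_covered) if ref_covered else float("nan"),
        per_patient_precision=per_prec,
        per_patient_sensitivity=per_sens,
        n_validated=len(validated),
        n_compared=len(compared),
        n_reference_covered=len(ref_covered),
        n_excluded_low_coverage=n_excluded,
        overlap_counts=overlap,
    )


def fdr_by_transition(predictions: Sequence[tuple[str, str]],
                      truth: Sequence[bool]) -> dict[str, float]:
    """Per-substitution-class false discovery rate.

    ``predictions`` is a sequence of (ref, alt) single-base pairs; ``truth``
    marks each prediction true (DNA-backed) or false. FDR_c = false positives
    of class c / predictions of class c; classes with no predictions map to
    NaN (undefined), never 0.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must align")
    n_pred = {c: 0 for c in SUBST_CLASSES}
    n_fp = {c: 0 for c in SUBST_CLASSES}
    for (ref, alt), ok in zip(predictions, truth):
        cls = substitution_class(ref, alt)
        n_pred[cls] += 1
        if not ok:
            n_fp[cls] += 1
    return {c: (n_fp[c] / n_pred[c] if n_pred[c] else float("nan"))
            for c in SUBST_CLASSES}


def binned_validation(values: Sequence[float], validated: Sequence[bool],
                      bin_edges: Sequence[float],
                      low_support: int = 5) -> pd.DataFrame:
    """Validation fraction per bin of a covariate (read depth or GC content).

    Bins are [edge_i, edge_{i+1}); the last edge may be ``inf``. Bins with fewer
    than ``low_support`` sites are flagged and their fraction is NaN-safe for
    empty bins. The size-weighted mean of per-bin fractions recomposes the
    overall fraction exactly.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(validated, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("values and validated must align")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    idx = np.digitize(values, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n = int(in_bin.sum())
        n_val = int(flags[in_bin].sum())
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "n": n, "n_validated": n_val,
            "fraction": n_val / n if n else float("nan"),
            "low_support": n < low_support,
        })
    return pd.DataFrame(rows)


def smg_input_table(mutations: Sequence[tuple], gene_models: GeneModelIndex,
                    tpm: pd.Series, min_tpm: float = 1.0) -> pd.DataFrame:
    """Per-mutation table restricted to expressed genes, formatted for dN/dS tools.

    ``mutations`` are (sample, chrom, pos, ref, alt). Mutations that map to no
    gene are dropped (count in ``df.attrs['n_unmapped']``); genes with mean TPM
    below ``min_tpm`` are removed. Output columns: sampleID, chr, pos, ref, mut,
    gene, gene_mutation_count.
    """
    rows = []
    n_unmapped = 0
    for sample, chrom, pos, ref, alt in mutations:
        gid = gene_models.gene_at(chrom, pos)
        if gid is None:
            n_unmapped += 1
            continue
        rows.append({"sampleID": sample, "chr": chrom, "pos": pos,
                     "ref": ref, "mut": alt, "gene": gid})
    df = pd.DataFrame(rows, columns=["sampleID", "chr", "pos", "ref", "mut", "gene"])
    expressed = set(tpm[tpm >= min_tpm].index)
    df = df[df["gene"].isin(expressed)].reset_index(drop=True)
    counts = df.groupby("gene")["pos"].transform("size") if len(df) else pd.Series(dtype=int)
    df["gene_mutation_count"] = counts
    df.attrs["n_unmapped"] = n_unmapped
    return df
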