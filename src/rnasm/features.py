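"""Extraction of the 26 mutational features consumed by the stacking classifier.

The feature list is a fixed, named manifest (``FEATURE_NAMES``); its order is
part of the model contract and is stored with every trained model bundle.
Missing optional evidence (second aligner/caller, gene models, expression) is
imputed with documented sentinels so the vector is always finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import ABSENT, EvidenceTable, SiteEvidence, flanking_unevenness
from .filters import FilterResources, strand_bias_pvalue, _EDITING_PAIRS
from .io import VariantCandidate, gc_content, homopolymer_run
from .signatures import substitution_class, trinucleotide_context, SUBST_CLASSES

__all__ = ["FEATURE_NAMES", "FeatureExtractor", "DIST_SENTINEL"]

#: Sentinel for "no gene model overlaps" / "no editing site on chromosome";
#: also the cap on distance-valued features.
DIST_SENTINEL = 10_000.0

FEATURE_NAMES = (
    "vaf",
    "alt_count",
    "depth_total",
    "log_depth",
    "median_bq_alt",
    "bq_delta",
    "median_mq_alt",
    "mq_delta",
    "strand_bias_stat",
    "mean_relpos_alt",
    "frac_softclip_alt",
    "frac_multimap_alt",
    "mean_nm_alt",
    "dist_to_junction",
    "flank_unevenness",
    "gc100",
    "homopolymer_run",
    "trinuc_context_index",
    "subst_class_index",
    "is_tc_class",
    "editing_site_proximity",
    "cluster_density",
    "caller_qual",
    "aligner2_vaf_delta",
    "caller2_alt_count",
    "gene_tpm",
)

_CLASS_INDEX = {c: i for i, c in enumerate(SUBST_CLASSES)}


@dataclass
class FeatureExtractor:
    """Computes the 26-feature vector for candidates given shared resources.

    ``cluster_window`` controls the same-class neighbour count feature
    (hyper-editing density); ``tpm`` maps gene_id -> expression for the
    log1p(TPM) feature (0 when unknown).
    """

    resources: FilterResources
    tpm: Mapping[str, float] | None = None
    cluster_window: int = 150

    def matrix(self, candidates: Sequence[VariantCandidate], evidence: EvidenceTable
               ) -> pd.DataFrame:
        """Feature matrix (rows follow candidate order, columns = FEATURE_NAMES)."""
        cluster_counts = self._cluster_counts(candidates)
        rows = [self.vector(c, evidence.get(c.key), cluster_counts.get(c.key, 0))
                for c in candidates]
        df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
        assert np.isfinite(df.to_numpy()).all(), "feature matrix must be finite"
        return df

    def vector(self, c: VariantCandidate, ev: SiteEvidence | None,
               cluster_density: int = 0) -> list[float]:
        if ev is None:
            ev = _NULL_EVIDENCE
        res = self.resources
        vaf = ev.vaf
        depth = ev.depth_total

        # strand bias as -log10 p, capped (p == 0 cannot occur for finite tables)
        sb = -math.log10(max(strand_bias_pvalue(ev), 1e-30)) if ev.alt_count > 0 else 0.0

        if res.gene_models is not None:
            dist_j = res.gene_models.junction_distance(c.chrom, c.pos)
        else:
            dist_j = ev.dist_to_junction
        dist_j_f = DIST_SENTINEL if dist_j < 0 else min(float(dist_j), DIST_SENTINEL)

        genome_ok = res.genome is not None and c.chrom in res.genome
        gc = gc_content(res.genome, c.chrom, c.pos) if genome_ok else 0.5
        if not math.isfinite(gc):
            gc = 0.5
        hrun = float(homopolymer_run(res.genome, c.chrom, c.pos)) if genome_ok else 1.0

        if c.is_snv:
            cls = substitution_class(c.ref, c.alt)
            cls_idx = float(_CLASS_INDEX[cls])
            is_tc = 1.0 if cls == "T>C" else 0.0
            if genome_ok:
                try:
                    tri = float(trinucleotide_context(res.genome, c.chrom, c.pos, c.ref, c.alt))
                except ValueError:
                    tri = -1.0
            else:
                tri = -1.0
        else:
            cls_idx, is_tc, tri = -1.0, 0.0, -1.0

        if res.editing is not None:
            edist = min(float(res.editing.distance(c.chrom, c.pos,
                                                   cap=int(DIST_SENTINEL))), DIST_SENTINEL)
        else:
            edist = DIST_SENTINEL

        if ev.has_aligner2 and ev.aligner2_depth > 0:
            a2_vaf = ev.aligner2_alt_count / ev.aligner2_depth
            a2_delta = vaf - a2_vaf
        else:
            a2_delta = 0.0
        c2_alt = float(ev.caller2_alt_count) if ev.has_caller2 else 0.0

        tpm = 0.0
        if self.tpm is not None and res.gene_models is not None:
            gid = res.gene_models.gene_at(c.chrom, c.pos)
            if gid is not None:
                tpm = float(self.tpm.get(gid, 0.0))

        return [
            vaf,
            float(ev.alt_count),
            float(depth),
            math.log1p(depth),
            ev.median_bq_alt,
            ev.median_bq_alt - ev.median_bq_ref,
            ev.median_mq_alt,
            ev.median_mq_alt - ev.median_mq_ref,
            sb,
            ev.mean_relpos_alt,
            ev.frac_softclip_alt,
            ev.frac_multimap_alt,
            ev.mean_nm_alt,
            dist_j_f,
            flanking_unevenness(ev),
            gc,
            hrun,
            tri,
            cls_idx,
            is_tc,
            edist,
            float(cluster_density),
            float(c.caller_qual),
            a2_delta,
            c2_alt,
            math.log1p(tpm),
        ]

    def _cluster_counts(self, candidates: Sequence[VariantCandidate]
                        ) -> dict[tuple, int]:
        """Per candidate: number of *other* same-class (A>G/T>C) candidates
        within cluster_window bp on the same chromosome."""
        per_chrom: dict[str, list[VariantCandidate]] = {}
        for c in candidates:
            if c.is_snv and (c.ref, c.alt) in _EDITING_PAIRS:
                per_chrom.setdefault(c.chrom, []).append(c)
        out: dict[tuple, int] = {}
        for chrom, group in per_chrom.items():
            pos = np.array(sorted(c.pos for c in group))
            for c in group:
                n = int(np.searchsorted(pos, c.pos + self.cluster_window, "right")
                        - np.searchsorted(pos, c.pos - self.cluster_window, "left"))
                out[c.key] = n - 1
        return out


_NULL_EVIDENCE = SiteEvidence(
    depth_total=0, alt_count=0, ref_count=0, alt_fwd=0, alt_rev=0,
    ref_fwd=0, ref_rev=0, median_bq_alt=0.0, median_bq_ref=0.0,
    median_mq_alt=0.0, median_mq_ref=0.0, mean_relpos_alt=0.5,
    frac_softclip_alt=0.0, frac_multimap_alt=0.0, mean_nm_alt=0.0,
    dist_to_junction=-1, flank_depth_left=ABSENT, flank_depth_right=ABSENT,
)
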