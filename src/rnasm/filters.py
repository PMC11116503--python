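"""The 18-filter rejection stage for RNA-seq variant candidates.

Each filter is a named, configurable predicate over (candidate, evidence,
resources). Ten of the filters target RNA-specific artifact modes (editing,
splice-junction misalignment, soft clipping, reverse-transcription noise via
caller concordance, coverage pits); the rest are DNA-generic quality gates.
The bank reports, per filter, both an *independent* rejection count (the filter
applied alone to every candidate) and an *attributed* count (first failing
filter in a fixed canonical order), because published per-filter percentages
do not define attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .evidence import ABSENT, EvidenceTable, SiteEvidence, flanking_unevenness
from .io import (EditingSiteSet, GeneModelIndex, GenomeAccessor, GermlineSet,
                 VariantCandidate, homopolymer_run)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "FilterResources",
    "FILTER_ORDER",
    "FILTER_DESCRIPTIONS",
    "apply_filter_bank",
    "strand_bias_pvalue",
    "filter_low_mutated_reads",
    "filter_dual_alignment",
    "filter_dual_caller",
    "filter_editing_sites",
    "filter_uneven_coverage",
    "filter_germline",
]

#: Canonical attribution order of the 18 filters.
FILTER_ORDER = (
    "germline",
    "min_depth",
    "low_mutated_reads",
    "base_quality",
    "mapping_quality",
    "strand_bias",
    "multimap",
    "read_position",
    "soft_clip",
    "junction",
    "uneven_coverage",
    "homopolymer",
    "cluster",
    "editing",
    "population_af",
    "dual_aligner",
    "dual_caller",
    "no_evidence",
)

FILTER_DESCRIPTIONS = {
    "germline": "allele-exact match in the matched-normal germline set (or population AF above ceiling)",
    "min_depth": "total read depth below floor",
    "low_mutated_reads": "too few alt reads or allele fraction below floor",
    "base_quality": "median alt base quality below floor",
    "mapping_quality": "median alt mapping quality below floor or mean per-read mismatches above ceiling",
    "strand_bias": "alt/ref strand counts imbalanced (two-sided Fisher exact)",
    "multimap": "excess fraction of multimapping alt reads",
    "read_position": "variant base sits near read ends on average",
    "soft_clip": "excess fraction of alt reads soft-clipped near the site",
    "junction": "site at an exon boundary without second-aligner corroboration",
    "uneven_coverage": "site depth is a pit relative to flanking depth",
    "homopolymer": "site inside a long homopolymer run",
    "cluster": "dense cluster of same-class A>G/T>C candidates (hyper-editing)",
    "editing": "A>G/T>C substitution at a known RNA-editing site",
    "population_af": "population allele frequency above ceiling",
    "dual_aligner": "no alt support after realignment with the second aligner",
    "dual_caller": "no alt support from the second caller's pileup",
    "no_evidence": "no read evidence available for the candidate",
}

_EDITING_PAIRS = {("A", "G"), ("T", "C")}

#: The ten filters that target RNA-seq-specific artifact modes; the remaining
#: eight are DNA-generic quality gates.
RNA_SPECIFIC_FILTERS = frozenset({
    "editing", "cluster", "junction", "soft_clip", "uneven_coverage",
    "dual_aligner", "dual_caller", "read_position", "multimap", "homopolymer",
})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and enable flags for the filter bank. Disabled filters never reject."""

    min_depth: int = 10
    min_alt_reads: int = 3
    min_vaf: float = 0.05
    min_median_bq: float = 20.0
    min_median_mq: float = 30.0
    max_mean_nm: float = 5.0
    max_strand_bias_p: float = 0.001
    strand_bias_min_alt: int = 5
    max_multimap_frac: float = 0.5
    relpos_margin: float = 0.1
    max_softclip_frac: float = 0.5
    max_junction_dist_reject: int = 3
    min_unevenness_ratio: float = 0.5
    homopolymer_max_run: int = 6
    cluster_window: int = 150
    cluster_count: int = 3
    editing_window: int = 0
    max_population_af: float = 0.001
    min_aligner2_alt: int = 2
    min_caller2_alt: int = 2
    disabled: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.disabled) - set(FILTER_ORDER)
        if unknown:
            raise ValueError(f"unknown filter ids in config: {sorted(unknown)}")
        if not (0.0 <= self.min_vaf <= 1.0 and 0.0 <= self.max_softclip_frac <= 1.0
                and 0.0 <= self.max_multimap_frac <= 1.0
                and 0.0 <= self.max_strand_bias_p <= 1.0
                and 0.0 <= self.max_population_af <= 1.0):
            raise ValueError("fraction/probability thresholds must lie in [0, 1]")

    def enabled(self, filter_id: str) -> bool:
        if filter_id not in FILTER_ORDER:
            raise ValueError(f"unknown filter id {filter_id!r}")
        return filter_id not in self.disabled

    def disable(self, *filter_ids: str) -> "FilterConfig":
        return replace(self, disabled=frozenset(self.disabled) | set(filter_ids))

    @classmethod
    def all_disabled(cls, **kwargs) -> "FilterConfig":
        return cls(disabled=frozenset(FILTER_ORDER), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        d = dict(d)
        disabled = frozenset(d.pop("disabled", []))
        known = set(cls.__dataclass_fields__) - {"disabled"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(disabled=disabled, **d)


@dataclass
class FilterResources:
    """External references the predicates consult."""

    germline: GermlineSet | None = None
    editing: EditingSiteSet | None = None
    gene_models: GeneModelIndex | None = None
    genome: GenomeAccessor | None = None
    population_af: Mapping[tuple[str, int, str, str], float] | None = None


@dataclass
class FilterReport:
    """Per-filter rejection tallies plus per-candidate failure attribution.

    Conservation invariants: n_pass + attributed-rejection total = n_input;
    per filter, independent rejections >= attributed rejections.
    """

    n_input: int
    n_pass: int
    n_evaluated: dict[str, int]
    n_rejected_independent: dict[str, int]
    n_rejected_attributed: dict[str, int]
    failures: dict[tuple[str, int, str, str], tuple[str, ...]]

    def rejection_fraction_independent(self) -> dict[str, float]:
        """Fraction of evaluated candidates each filter rejects when applied alone."""
        return {f: (self.n_rejected_independent[f] / self.n_evaluated[f]
                    if self.n_evaluated[f] else 0.0) for f in FILTER_ORDER}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "filter": list(FILTER_ORDER),
            "n_evaluated": [self.n_evaluated[f] for f in FILTER_ORDER],
            "n_rejected_independent": [self.n_rejected_independent[f] for f in FILTER_ORDER],
            "n_rejected_attributed": [self.n_rejected_attributed[f] for f in FILTER_ORDER],
        })


# ---------------------------------------------------------------------------
# Individual predicates (True = reject)
# ---------------------------------------------------------------------------

def strand_bias_pvalue(ev: SiteEvidence) -> float:
    """Two-sided Fisher exact p on the 2x2 (ref_fwd, ref_rev; alt_fwd, alt_rev)."""
    table = [[ev.ref_fwd, ev.ref_rev], [ev.alt_fwd, ev.alt_rev]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def filter_germline(candidate: VariantCandidate, resources: FilterResources,
                    config: FilterConfig) -> bool:
    if resources.germline is not None and candidate.key in resources.germline:
        return True
    if resources.population_af is not None:
        af = resources.population_af.get(candidate.key, 0.0)
        if af > config.max_population_af:
            return True
    return False


def _filter_min_depth(c, ev, res, cfg):
    return ev.depth_total < cfg.min_depth


def filter_low_mutated_reads(candidate: VariantCandidate, ev: SiteEvidence,
                             config: FilterConfig) -> bool:
    if ev.alt_count < config.min_alt_reads:
        return True
    vaf = ev.alt_count / max(1, ev.alt_count + ev.ref_count)
    return vaf < config.min_vaf


def _filter_base_quality(c, ev, res, cfg):
    return ev.alt_count > 0 and ev.median_bq_alt < cfg.min_median_bq


def _filter_mapping_quality(c, ev, res, cfg):
    if ev.alt_count == 0:
        return False
    return ev.median_mq_alt < cfg.min_median_mq or ev.mean_nm_alt > cfg.max_mean_nm


def _filter_strand_bias(c, ev, res, cfg):
    if ev.alt_count < cfg.strand_bias_min_alt:
        return False
    return strand_bias_pvalue(ev) < cfg.max_strand_bias_p


def _filter_multimap(c, ev, res, cfg):
    return ev.alt_count > 0 and ev.frac_multimap_alt > cfg.max_multimap_frac


def _filter_read_position(c, ev, res, cfg):
    if ev.alt_count == 0:
        return False
    m = cfg.relpos_margin
    return not (m <= ev.mean_relpos_alt <= 1.0 - m)


def _filter_soft_clip(c, ev, res, cfg):
    return ev.alt_count > 0 and ev.frac_softclip_alt > cfg.max_softclip_frac


def _filter_junction(c, ev, res, cfg):
    """Near an exon boundary the aligners disagree most; reject there unless the
    second aligner corroborates the allele."""
    if ev.dist_to_junction < 0 or ev.dist_to_junction > cfg.max_junction_dist_reject:
        return False
    if ev.has_aligner2:
        return ev.aligner2_alt_count < cfg.min_aligner2_alt
    return True


def filter_uneven_coverage(candidate: VariantCandidate, ev: SiteEvidence,
                           config: FilterConfig) -> bool:
    return flanking_unevenness(ev) < config.min_unevenness_ratio


def _filter_homopolymer(c, ev, res, cfg):
    if res.genome is None or c.chrom not in res.genome:
        return False
    return homopolymer_run(res.genome, c.chrom, c.pos) > cfg.homopolymer_max_run


def filter_editing_sites(candidate: VariantCandidate, ev: SiteEvidence,
                         resources: FilterResources, config: FilterConfig) -> bool:
    """A>G / T>C SNVs at (or within editing_window bp of) a known editing site.
    Other substitution classes and indels never fail this filter."""
    if not candidate.is_snv or (candidate.ref, candidate.alt) not in _EDITING_PAIRS:
        return False
    if resources.editing is None:
        return False
    if config.editing_window == 0:
        return (candidate.chrom, candidate.pos) in resources.editing
    return resources.editing.distance(candidate.chrom, candidate.pos) <= config.editing_window


def _filter_population_af(c, ev, res, cfg):
    if res.population_af is None:
        return False
    return res.population_af.get(c.key, 0.0) > cfg.max_population_af


def filter_dual_alignment(candidate: VariantCandidate, ev: SiteEvidence,
                          config: FilterConfig) -> bool:
    """Variant must survive realignment by a second, clipping-strategy-distinct
    aligner. Inert when second-aligner evidence is absent."""
    if not ev.has_aligner2:
        return False
    return ev.aligner2_alt_count < config.min_aligner2_alt


def filter_dual_caller(candidate: VariantCandidate, ev: SiteEvidence,
                       config: FilterConfig) -> bool:
    """Variant must be re-observed by the independent pileup-based caller.
    Inert when second-caller evidence is absent."""
    if not ev.has_caller2:
        return False
    return ev.caller2_alt_count < config.min_caller2_alt


# dispatch table: filter id -> predicate(candidate, evidence, resources, config)
_PREDICATES: dict[str, Callable] = {
    "germline": lambda c, ev, res, cfg: filter_germline(c, res, cfg),
    "min_depth": _filter_min_depth,
    "low_mutated_reads": lambda c, ev, res, cfg: filter_low_mutated_reads(c, ev, cfg),
    "base_quality": _filter_base_quality,
    "mapping_quality": _filter_mapping_quality,
    "strand_bias": _filter_strand_bias,
    "multimap": _filter_multimap,
    "read_position": _filter_read_position,
    "soft_clip": _filter_soft_clip,
    "junction": _filter_junction,
    "uneven_coverage": lambda c, ev, res, cfg: filter_uneven_coverage(c, ev, cfg),
    "homopolymer": _filter_homopolymer,
    "cluster": None,  # batch-level, handled in apply_filter_bank
    "editing": lambda c, ev, res, cfg: filter_editing_sites(c, ev, res, cfg),
    "population_af": _filter_population_af,
    "dual_aligner": lambda c, ev, res, cfg: filter_dual_alignment(c, ev, cfg),
    "dual_caller": lambda c, ev, res, cfg: filter_dual_caller(c, ev, cfg),
}

#: Filters that need read evidence; a no-evidence candidate is never counted as
#: evaluated by them.
_NEEDS_EVIDENCE = frozenset(FILTER_ORDER) - {"germline", "cluster", "homopolymer",
                                             "population_af", "no_evidence"}

#: Indels are exempt from editing-related filters.
_SNV_ONLY = frozenset({"editing", "cluster"})


def _cluster_fail_keys(candidates: Sequence[VariantCandidate],
                       config: FilterConfig) -> set[tuple[str, int, str, str]]:
    """Keys of A>G/T>C SNVs sitting in clusters of >= cluster_count same-class
    candidates within cluster_window bp (hyper-editing fingerprint)."""
    per_chrom: dict[str, list[VariantCandidate]] = {}
    for c in candidates:
        if c.is_snv and (c.ref, c.alt) in _EDITING_PAIRS:
            per_chrom.setdefault(c.chrom, []).append(c)
    fail: set[tuple[str, int, str, str]] = set()
    for chrom, group in per_chrom.items():
        pos = np.array(sorted(c.pos for c in group))
        for c in group:
            n = int(np.searchsorted(pos, c.pos + config.cluster_window, side="right")
                    - np.searchsorted(pos, c.pos - config.cluster_window, side="left"))
            if n >= config.cluster_count:
                fail.add(c.key)
    return fail


def apply_filter_bank(candidates: Sequence[VariantCandidate], evidence: EvidenceTable,
                      resources: FilterResources, config: FilterConfig | None = None
                      ) -> tuple[list[VariantCandidate], FilterReport]:
    """Run every enabled filter over every candidate.

    Returns the pass set (candidates failing zero enabled filters) and a
    :class:`FilterReport`. Outcomes are independent of candidate order; the
    per-candidate failure list records *all* failing filters in canonical
    order, so the first entry is the attributed rejection.
    """
    config = config or FilterConfig()
    cluster_keys = _cluster_fail_keys(candidates, config) \
        if config.enabled("cluster") else set()

    n_eval = {f: 0 for f in FILTER_ORDER}
    n_indep = {f: 0 for f in FILTER_ORDER}
    n_attr = {f: 0 for f in FILTER_ORDER}
    failures: dict[tuple[str, int, str, str], tuple[str, ...]] = {}
    passed: list[VariantCandidate] = []

    for cand in candidates:
        ev = evidence.get(cand.key)
        failed: list[str] = []
        for fid in FILTER_ORDER:
            if not config.enabled(fid):
                continue
            if fid == "no_evidence":
                n_eval[fid] += 1
                rejected = ev is None
            elif fid == "cluster":
                if not cand.is_snv:
                    continue
                n_eval[fid] += 1
                rejected = cand.key in cluster_keys
            else:
                if ev is None and fid in _NEEDS_EVIDENCE:
                    continue
                if fid in _SNV_ONLY and not cand.is_snv:
                    continue
                n_eval[fid] += 1
                rejected = bool(_PREDICATES[fid](cand, ev, resources, config))
            if rejected:
                n_indep[fid] += 1
                failed.append(fid)
        if failed:
            failures[cand.key] = tuple(failed)
            n_attr[failed[0]] += 1
        else:
            passed.append(cand)

    report = FilterReport(
        n_input=len(candidates), n_pass=len(passed),
        n_evaluated=n_eval, n_rejected_independent=n_indep,
        n_rejected_attributed=n_attr, failures=failures,
    )
    return passed, report
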