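"""Per-site read-level evidence: extraction from alignments and the tabular path.

The filter bank and feature extractor consume one structure, :class:`SiteEvidence`,
regardless of whether it was summarised from a BAM/SAM pileup or ingested from the
documented evidence TSV. Optional second-aligner / second-caller columns use the
sentinel -1 ("absent") so concordance filters can run inert when that evidence
was not produced.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .io import GeneModelIndex, VariantCandidate

__all__ = [
    "SiteEvidence",
    "EvidenceTable",
    "ABSENT",
    "summarize_site",
    "read_evidence_table",
    "write_evidence_table",
    "flanking_unevenness",
    "junction_distance",
    "EVIDENCE_COLUMNS",
]

#: Sentinel for optional evidence that was not produced (second aligner/caller).
ABSENT = -1

_BQ_FLOOR_DEFAULT = 10
_FLANK_BP = 25


@dataclass(frozen=True)
class SiteEvidence:
    """Read-level evidence summary at one candidate site.

    Counts obey: alt_count = alt_fwd + alt_rev, ref_count = ref_fwd + ref_rev,
    alt_count + ref_count <= depth_total. Fractions lie in [0, 1].
    ``dist_to_junction`` is -1 when no gene model overlaps the site; the
    ``aligner2_*`` / ``caller2_*`` fields are -1 when that evidence is absent.
    """

    depth_total: int
    alt_count: int
    ref_count: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    median_bq_alt: float
    median_bq_ref: float
    median_mq_alt: float
    median_mq_ref: float
    mean_relpos_alt: float
    frac_softclip_alt: float
    frac_multimap_alt: float
    mean_nm_alt: float
    dist_to_junction: int
    flank_depth_left: float
    flank_depth_right: float
    aligner2_depth: int = ABSENT
    aligner2_alt_count: int = ABSENT
    caller2_alt_count: int = ABSENT
    dup_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.alt_count != self.alt_fwd + self.alt_rev:
            raise ValueError("alt_count != alt_fwd + alt_rev")
        if self.ref_count != self.ref_fwd + self.ref_rev:
            raise ValueError("ref_count != ref_fwd + ref_rev")
        if self.alt_count + self.ref_count > self.depth_total:
            raise ValueError("alt_count + ref_count > depth_total")
        for name in ("frac_softclip_alt", "frac_multimap_alt", "dup_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.alt_count > 0 and not (0.0 <= self.mean_relpos_alt <= 1.0):
            raise ValueError(f"mean_relpos_alt={self.mean_relpos_alt} outside [0, 1]")
        for name in ("depth_total", "alt_count", "ref_count",
                     "alt_fwd", "alt_rev", "ref_fwd", "ref_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    @property
    def vaf(self) -> float:
        return self.alt_count / max(1, self.alt_count + self.ref_count)

    @property
    def has_aligner2(self) -> bool:
        return self.aligner2_alt_count != ABSENT

    @property
    def has_caller2(self) -> bool:
        return self.caller2_alt_count != ABSENT


EVIDENCE_FIELDS = tuple(f.name for f in fields(SiteEvidence))
EVIDENCE_COLUMNS = ("chrom", "pos", "ref", "alt") + EVIDENCE_FIELDS
_INT_FIELDS = {"depth_total", "alt_count", "ref_count", "alt_fwd", "alt_rev",
               "ref_fwd", "ref_rev", "dist_to_junction",
               "aligner2_depth", "aligner2_alt_count", "caller2_alt_count"}


class EvidenceTable:
    """Mapping (chrom, pos, ref, alt) -> SiteEvidence with provenance metadata."""

    def __init__(self, entries: Mapping[tuple[str, int, str, str], SiteEvidence],
                 source: str = "table"):
        self._entries = dict(entries)
        self.source = source

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._entries

    def get(self, key: tuple[str, int, str, str]) -> SiteEvidence | None:
        return self._entries.get(key)

    def __getitem__(self, key: tuple[str, int, str, str]) -> SiteEvidence:
        return self._entries[key]

    def items(self):
        return self._entries.items()

    def keys(self):
        return self._entries.keys()


def flanking_unevenness(ev: SiteEvidence) -> float:
    """Site depth relative to the median flank depth; values well below 1 mark a
    coverage pit at the site (a misalignment fingerprint). Sentinel flanks (<0)
    yield 1.0 by convention."""
    if ev.flank_depth_left < 0 or ev.flank_depth_right < 0:
        return 1.0
    flank = statistics.median([ev.flank_depth_left, ev.flank_depth_right])
    return ev.depth_total / max(1.0, flank)


def junction_distance(gene_models: GeneModelIndex, chrom: str, pos: int) -> int:
    """bp distance from pos to the nearest annotated exon boundary of an
    overlapping gene; -1 when no gene overlaps."""
    return gene_models.junction_distance(chrom, pos)


# ---------------------------------------------------------------------------
# Alignment-path extraction
# ---------------------------------------------------------------------------

def _median(vals: list[float], default: float = 0.0) -> float:
    return float(statistics.median(vals)) if vals else default


def summarize_site(alignments: pysam.AlignmentFile, candidate: VariantCandidate,
                   gene_models: GeneModelIndex | None = None,
                   bq_floor: int = _BQ_FLOOR_DEFAULT,
                   flank_bp: int = _FLANK_BP) -> SiteEvidence:
    """Summarise read evidence at a candidate site from an indexed alignment file.

    Bases inside soft-clipped segments never count as allele support; reads with
    base quality < ``bq_floor`` at the site are excluded from allele counts (but
    still count toward ``depth_total``); duplicate-flagged reads contribute only
    to ``dup_frac``. For indels, alt support means the read's CIGAR places the
    exact indel at the candidate position.
    """
    if candidate.chrom not in alignments.references:
        raise KeyError(f"chromosome {candidate.chrom!r} absent from alignment file")
    pos0 = candidate.pos - 1
    is_snv = candidate.is_snv
    depth_total = 0
    n_dup = 0
    n_total_reads = 0
    alt_reads: list[pysam.AlignedSegment] = []
    alt_relpos: list[float] = []
    alt_bq: list[float] = []
    ref_bq: list[float] = []
    alt_mq: list[float] = []
    ref_mq: list[float] = []
    alt_fwd = alt_rev = ref_fwd = ref_rev = 0

    for col in alignments.pileup(candidate.chrom, pos0, pos0 + 1, truncate=True,
                                 stepper="nofilter", min_base_quality=0):
        for pr in col.pileups:
            read = pr.alignment
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_total_reads += 1
            if read.is_duplicate:
                n_dup += 1
                continue
            depth_total += 1
            if is_snv:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue  # deletion/refskip spanning the site: depth only
                base = read.query_sequence[pr.query_position]
                bq = read.query_qualities[pr.query_position]
                if bq < bq_floor:
                    continue
                if base == candidate.alt:
                    _tally_alt(read, pr.query_position, candidate, alt_reads,
                               alt_relpos, alt_bq, alt_mq)
                    if read.is_reverse:
                        alt_rev += 1
                    else:
                        alt_fwd += 1
                elif base == candidate.ref:
                    ref_bq.append(bq)
                    ref_mq.append(read.mapping_quality)
                    if read.is_reverse:
                        ref_rev += 1
                    else:
                        ref_fwd += 1
            else:
                supports_alt, qpos = _indel_support(pr, candidate)
                if supports_alt:
                    _tally_alt(read, qpos, candidate, alt_reads, alt_relpos, alt_bq, alt_mq)
                    if read.is_reverse:
                        alt_rev += 1
                    else:
                        alt_fwd += 1
                elif pr.query_position is not None and not pr.is_del:
                    bq = read.query_qualities[pr.query_position]
                    if bq < bq_floor:
                        continue
                    ref_bq.append(bq)
                    ref_mq.append(read.mapping_quality)
                    if read.is_reverse:
                        ref_rev += 1
                    else:
                        ref_fwd += 1

    n_alt = alt_fwd + alt_rev
    n_softclip = sum(1 for r in alt_reads if _softclip_near(r, pos0, 10))
    n_multimap = sum(1 for r in alt_reads
                     if r.mapping_quality == 0 or r.is_secondary)
    nm_vals = [float(r.get_tag("NM")) for r in alt_reads if r.has_tag("NM")]

    flank_left, flank_right = _flank_depths(alignments, candidate.chrom, pos0, flank_bp)

    dist = gene_models.junction_distance(candidate.chrom, candidate.pos) \
        if gene_models is not None else -1

    return SiteEvidence(
        depth_total=depth_total,
        alt_count=n_alt,
        ref_count=ref_fwd + ref_rev,
        alt_fwd=alt_fwd, alt_rev=alt_rev, ref_fwd=ref_fwd, ref_rev=ref_rev,
        median_bq_alt=_median(alt_bq), median_bq_ref=_median(ref_bq),
        median_mq_alt=_median(alt_mq), median_mq_ref=_median(ref_mq),
        mean_relpos_alt=float(np.mean(alt_relpos)) if alt_relpos else 0.5,
        frac_softclip_alt=n_softclip / n_alt if n_alt else 0.0,
        frac_multimap_alt=n_multimap / n_alt if n_alt else 0.0,
        mean_nm_alt=float(np.mean(nm_vals)) if nm_vals else 0.0,
        dist_to_junction=dist,
        flank_depth_left=flank_left, flank_depth_right=flank_right,
        dup_frac=n_dup / n_total_reads if n_total_reads else 0.0,
    )


def _tally_alt(read, qpos, candidate, alt_reads, alt_relpos, alt_bq, alt_mq) -> None:
    alt_reads.append(read)
    rl = read.query_length or len(read.query_sequence or "")
    if qpos is not None and rl > 1:
        alt_relpos.append(qpos / (rl - 1))
    if qpos is not None and read.query_qualities is not None:
        alt_bq.append(read.query_qualities[qpos])
    alt_mq.append(read.mapping_quality)


def _indel_support(pr, candidate: VariantCandidate) -> tuple[bool, int | None]:
    """True iff the pileup read carries the exact insertion/deletion at the site."""
    if candidate.variant_type == "insertion":
        ins_len = len(candidate.alt) - len(candidate.ref)
        return (pr.indel == ins_len and not pr.is_del, pr.query_position)
    del_len = len(candidate.ref) - len(candidate.alt)
    return (pr.indel == -del_len and not pr.is_del, pr.query_position)


def _softclip_near(read: pysam.AlignedSegment, pos0: int, window: int) -> bool:
    """Does the read have a soft-clipped segment whose boundary is within
    `window` bp of the site?"""
    cig = read.cigartuples
    if not cig:
        return False
    if cig[0][0] == pysam.CSOFT_CLIP and abs(read.reference_start - pos0) <= window:
        return True
    if cig[-1][0] == pysam.CSOFT_CLIP and abs(read.reference_end - 1 - pos0) <= window:
        return True
    return False


def _flank_depths(alignments: pysam.AlignmentFile, chrom: str, pos0: int,
                  flank_bp: int) -> tuple[float, float]:
    """Median per-column depth over `flank_bp` columns each side (site excluded)."""
    ref_len = alignments.get_reference_length(chrom)
    lo = max(0, pos0 - flank_bp)
    hi = min(ref_len, pos0 + flank_bp + 1)
    cov = np.array(alignments.count_coverage(chrom, lo, hi, quality_threshold=0)).sum(axis=0)
    i_site = pos0 - lo
    left = cov[:i_site]
    right = cov[i_site + 1:]
    return (_median(list(map(float, left))), _median(list(map(float, right))))


# ---------------------------------------------------------------------------
# Tabular path
# ---------------------------------------------------------------------------

def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    rows = []
    for (chrom, pos, ref, alt), ev in sorted(table.items()):
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        row.update({name: getattr(ev, name) for name in EVIDENCE_FIELDS})
        rows.append(row)
    pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_evidence_table(path: str | Path) -> EvidenceTable:
    """Read the documented evidence TSV. Optional aligner2_*/caller2_* columns may
    be omitted entirely; they are filled with the ABSENT sentinel."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = [c for c in EVIDENCE_COLUMNS
                if not c.startswith(("aligner2_", "caller2_"))]
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise ValueError(f"evidence TSV missing columns: {missing}")
    for opt in ("aligner2_depth", "aligner2_alt_count", "caller2_alt_count"):
        if opt not in df.columns:
            df[opt] = ABSENT
    entries: dict[tuple[str, int, str, str], SiteEvidence] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        if key in entries:
            raise ValueError(f"duplicate evidence key {key}")
        kwargs = {}
        for name in EVIDENCE_FIELDS:
            v = d[name]
            kwargs[name] = int(v) if name in _INT_FIELDS else float(v)
        entries[key] = SiteEvidence(**kwargs)  # raises on invariant violations
    return EvidenceTable(entries, source="table")


def evidence_from_alignments(alignments: pysam.AlignmentFile,
                             candidates: Iterable[VariantCandidate],
                             gene_models: GeneModelIndex | None = None,
                             **kwargs) -> EvidenceTable:
    """Summarise every candidate from one alignment source into an EvidenceTable."""
    entries = {c.key: summarize_site(alignments, c, gene_models, **kwargs)
               for c in candidates}
    return EvidenceTable(entries, source="alignments")


def merge_secondary_evidence(table: EvidenceTable,
                             aligner2: Mapping[tuple[str, int, str, str], tuple[int, int]] | None = None,
                             caller2: Mapping[tuple[str, int, str, str], int] | None = None
                             ) -> EvidenceTable:
    """Attach second-aligner (depth, alt_count) and second-caller alt counts."""
    entries = {}
    for key, ev in table.items():
        upd = {}
        if aligner2 is not None:
            dep, alt = aligner2.get(key, (0, 0))
            upd["aligner2_depth"] = dep
            upd["aligner2_alt_count"] = alt
        if caller2 is not None:
            upd["caller2_alt_count"] = caller2.get(key, 0)
        entries[key] = replace(ev, **upd) if upd else ev
    return EvidenceTable(entries, source=table.source)
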