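"""Domain types and readers/writers for the external formats the pipeline touches.

All internal coordinates are 1-based inclusive (VCF convention). BED's 0-based
half-open intervals are converted at the reader boundary and nowhere else.
Chromosome names are preserved as-is; a naming mismatch between inputs (e.g.
``chr1`` vs ``1``) raises rather than silently aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "VariantCandidate",
    "AnnotatedCall",
    "GenomeAccessor",
    "GeneModelIndex",
    "Transcript",
    "EditingSiteSet",
    "GermlineSet",
    "SignatureMatrix",
    "SBS96_CHANNELS",
    "SUBST_CLASSES",
    "read_vcf_candidates",
    "write_candidates_vcf",
    "read_editing_sites",
    "read_germline_vcf",
    "read_gene_models",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_tpm_table",
    "gc_content",
    "homopolymer_run",
    "write_calls",
    "read_calls_tsv",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Pyrimidine-collapsed single-base substitution classes, COSMIC order.
SUBST_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = "ACGT"


def _build_channels() -> tuple[str, ...]:
    chans = []
    for cls in SUBST_CLASSES:
        ref = cls[0]
        for five in _BASES:
            for three in _BASES:
                chans.append(f"{five}[{cls}]{three}")
    return tuple(chans)


#: The 96 trinucleotide channels in canonical COSMIC SBS row order:
#: substitution class major, then 5' base, then 3' base, each A<C<G<T.
SBS96_CHANNELS = _build_channels()
SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


# ---------------------------------------------------------------------------
# Variant candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCandidate:
    """One candidate variant site (single ALT allele; multi-allelics are split)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_type: str = field(init=False)
    caller_qual: float = 0.0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) == 1 and len(self.alt) == 1:
            vt = "SNV"
        elif len(self.alt) > len(self.ref):
            vt = "insertion"
        else:
            vt = "deletion"
        object.__setattr__(self, "variant_type", vt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.variant_type == "SNV"


def read_vcf_candidates(path: str | Path, sample_id: str = "sample") -> list[VariantCandidate]:
    """Read candidate variants from a VCF 4.x file, one candidate per ALT allele.

    Multi-allelic records are split into one candidate each; positions stay
    1-based. Records without an ALT allele are skipped with a warning;
    malformed records raise with the offending record number.
    """
    out: list[VariantCandidate] = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf.fetch() if vf.index is not None else vf, start=1):
            try:
                if rec.alts is None:
                    warnings.warn(f"record {i} at {rec.chrom}:{rec.pos} has no ALT; skipped")
                    continue
                qual = float(rec.qual) if rec.qual is not None else 0.0
                try:
                    sid = rec.info.get("SID", sample_id)
                except (KeyError, ValueError):  # SID not declared in header
                    sid = sample_id
                for alt in rec.alts:
                    if alt in (".", "*", None):
                        continue
                    out.append(
                        VariantCandidate(rec.chrom, rec.pos, rec.ref, str(alt),
                                         caller_qual=qual, sample_id=str(sid))
                    )
            except ValueError as exc:
                raise ValueError(f"malformed VCF record {i} in {path}: {exc}") from exc
    return out


def _vcf_header(contigs: Iterable[str], filters: Mapping[str, str] | None = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c)
    header.info.add("PROB", 1, "Float", "Classifier probability of being DNA-backed")
    header.info.add("TCLASS", 1, "String", "Pyrimidine-collapsed substitution class")
    header.info.add("SID", 1, "String", "Sample identifier")
    for fid, desc in (filters or {}).items():
        if fid != "PASS":
            header.filters.add(fid, None, None, desc)
    return header


def write_candidates_vcf(candidates: Sequence[VariantCandidate], path: str | Path) -> None:
    """Write bare candidates as a minimal VCF (used by the synthetic generator)."""
    contigs = sorted({c.chrom for c in candidates})
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in sorted(candidates, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = vf.new_record(contig=c.chrom, start=c.pos - 1, stop=c.pos - 1 + len(c.ref),
                                alleles=(c.ref, c.alt), qual=c.caller_qual)
            rec.info["SID"] = c.sample_id
            vf.write(rec)


# ---------------------------------------------------------------------------
# Annotated calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedCall:
    """A candidate after filtering/classification, ready to be written out."""

    candidate: VariantCandidate
    failed_filters: tuple[str, ...] = ()
    probability: float | None = None
    subst_class: str | None = None
    region: str | None = None
    gene_id: str | None = None

    @property
    def passed(self) -> bool:
        return not self.failed_filters


def write_calls(calls: Sequence[AnnotatedCall], vcf_path: str | Path,
                tsv_path: str | Path | None = None,
                filter_descriptions: Mapping[str, str] | None = None) -> None:
    """Write annotated calls as VCF (FILTER = PASS or failed-filter ids) plus a TSV mirror."""
    contigs = sorted({c.candidate.chrom for c in calls})
    all_filters = dict(filter_descriptions or {})
    for call in calls:
        for fid in call.failed_filters:
            all_filters.setdefault(fid, "rejection filter")
    header = _vcf_header(contigs, all_filters)
    rows = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda x: (x.candidate.chrom, x.candidate.pos,
                                                 x.candidate.ref, x.candidate.alt)):
            c = call.candidate
            rec = vf.new_record(contig=c.chrom, start=c.pos - 1, stop=c.pos - 1 + len(c.ref),
                                alleles=(c.ref, c.alt), qual=c.caller_qual)
            if call.failed_filters:
                for fid in call.failed_filters:
                    rec.filter.add(fid)
            else:
                rec.filter.add("PASS")
            rec.info["SID"] = c.sample_id
            if call.probability is not None:
                rec.info["PROB"] = float(call.probability)
            if call.subst_class is not None:
                rec.info["TCLASS"] = call.subst_class.replace(">", "_")
            vf.write(rec)
            rows.append({
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                "variant_type": c.variant_type, "sample_id": c.sample_id,
                "caller_qual": c.caller_qual,
                "filter": "PASS" if call.passed else ";".join(call.failed_filters),
                "probability": call.probability if call.probability is not None else np.nan,
                "subst_class": call.subst_class or "", "region": call.region or "",
                "gene_id": call.gene_id or "",
            })
    if tsv_path is not None:
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "variant_type",
                                    "sample_id", "caller_qual", "filter", "probability",
                                    "subst_class", "region", "gene_id"]
                     ).to_csv(tsv_path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

class GenomeAccessor:
    """Sequence lookup over an indexed FASTA; 1-based inclusive coordinates at the API."""

    def __init__(self, fasta_path: str | Path):
        self._fa = Fasta(str(fasta_path), sequence_always_upper=True)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(self._fa[name]) for name in self._fa.keys()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for [start, end], 1-based inclusive."""
        if chrom not in self._fa:
            raise KeyError(
                f"chromosome {chrom!r} absent from FASTA; available: "
                f"{sorted(self._fa.keys())[:5]}... (no silent name aliasing)")
        n = len(self._fa[chrom])
        if start < 1 or end > n or start > end:
            raise ValueError(f"window {chrom}:{start}-{end} outside chromosome (len {n})")
        return str(self._fa[chrom][start - 1:end])

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def gc_content(genome: GenomeAccessor, chrom: str, pos: int, window: int = 100) -> float:
    """GC fraction of the `window` bases centred on pos (default 100: 50 left, 49 right
    plus the site), clipped at chromosome ends; N bases are excluded from the denominator.
    """
    n = genome.chrom_lengths[chrom] if chrom in genome else 0
    if chrom not in genome or not (1 <= pos <= n):
        raise ValueError(f"position {chrom}:{pos} outside chromosome")
    left = window // 2
    right = window - left - 1
    start = max(1, pos - left)
    end = min(n, pos + right)
    seq = genome.fetch(chrom, start, end)
    informative = sum(1 for b in seq if b in "ACGT")
    if informative == 0:
        return float("nan")
    gc = sum(1 for b in seq if b in "GC")
    return gc / informative


def homopolymer_run(genome: GenomeAccessor, chrom: str, pos: int, max_scan: int = 30) -> int:
    """Length of the longest single-base run touching pos (the run containing the
    site base, or the runs starting immediately left/right of it), measured
    within a +/- ``max_scan`` bp window."""
    n = genome.chrom_lengths[chrom]
    start = max(1, pos - max_scan)
    end = min(n, pos + max_scan)
    seq = genome.fetch(chrom, start, end)
    i = pos - start  # index of site within seq
    best = 0
    for anchor in (i - 1, i, i + 1):
        if not (0 <= anchor < len(seq)):
            continue
        b = seq[anchor]
        if b not in "ACGT":
            continue
        lo = anchor
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = anchor
        while hi < len(seq) - 1 and seq[hi + 1] == b:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS {cs}-{ce} not contained in an exon of {self.transcript_id}")


class GeneModelIndex:
    """Interval-queryable gene structures (exons, CDS, strand) from a GTF."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        self._gene_chrom: dict[str, str] = {}
        self.genes: dict[str, list[Transcript]] = {}
        self._boundaries: dict[str, np.ndarray] = {}
        by_chrom_bounds: dict[str, set[int]] = {}
        self._tx_chrom: dict[str, str] = {}

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, Transcript]]) -> "GeneModelIndex":
        """Build from (chrom, Transcript) pairs."""
        idx = cls([])
        bounds: dict[str, set[int]] = {}
        for chrom, tx in records:
            idx.transcripts.append(tx)
            idx.genes.setdefault(tx.gene_id, []).append(tx)
            idx._gene_chrom[tx.gene_id] = chrom
            idx._tx_chrom[tx.transcript_id] = chrom
            tree = idx._trees.setdefault(chrom, IntervalTree())
            span = (tx.exons[0][0], tx.exons[-1][1])
            tree.addi(span[0], span[1] + 1, tx)
            b = bounds.setdefault(chrom, set())
            for s, e in tx.exons:
                b.add(s)
                b.add(e)
        idx._boundaries = {c: np.array(sorted(v), dtype=np.int64) for c, v in bounds.items()}
        return idx

    def overlapping_transcripts(self, chrom: str, pos: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """gene_id of the first gene whose span covers pos (exonic preferred)."""
        txs = self.overlapping_transcripts(chrom, pos)
        if not txs:
            return None
        exonic = [t for t in txs if any(s <= pos <= e for s, e in t.exons)]
        chosen = sorted(exonic or txs, key=lambda t: t.gene_id)[0]
        return chosen.gene_id

    def region(self, chrom: str, pos: int) -> str:
        """One of exon_cds / exon_utr / intron / intergenic."""
        txs = self.overlapping_transcripts(chrom, pos)
        if not txs:
            return "intergenic"
        best = "intron"
        for tx in txs:
            if any(s <= pos <= e for s, e in tx.cds):
                return "exon_cds"
            if any(s <= pos <= e for s, e in tx.exons):
                best = "exon_utr"
        return best

    def junction_distance(self, chrom: str, pos: int) -> int:
        """Min |pos - boundary| over exon starts/ends of genes overlapping pos; -1 if none."""
        if not self.overlapping_transcripts(chrom, pos):
            return -1
        bounds = self._boundaries.get(chrom)
        if bounds is None or len(bounds) == 0:
            return -1
        i = int(np.searchsorted(bounds, pos))
        cand = []
        if i < len(bounds):
            cand.append(abs(int(bounds[i]) - pos))
        if i > 0:
            cand.append(abs(int(bounds[i - 1]) - pos))
        return min(cand)

    def gene_strand(self, gene_id: str) -> str:
        return self.genes[gene_id][0].strand


def read_gene_models(gtf_path: str | Path) -> GeneModelIndex:
    """Load exon/CDS structures from a GTF via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(str(gtf_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="merge",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    records: list[tuple[str, Transcript]] = []
    for tx in db.features_of_type("transcript"):
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        if not exons:
            continue
        records.append((
            tx.seqid,
            Transcript(
                transcript_id=tx.attributes.get("transcript_id", [tx.id])[0],
                gene_id=tx.attributes.get("gene_id", ["?"])[0],
                strand=tx.strand, exons=exons, cds=cds,
            ),
        ))
    return GeneModelIndex.from_records(records)


# ---------------------------------------------------------------------------
# Editing sites / germline variants
# ---------------------------------------------------------------------------

class EditingSiteSet:
    """Known RNA-editing positions with exact (chrom, pos) membership and
    nearest-site distance queries."""

    def __init__(self, sites: Iterable[tuple[str, int]]):
        self._set = set(sites)
        per: dict[str, list[int]] = {}
        for chrom, pos in self._set:
            per.setdefault(chrom, []).append(pos)
        self._sorted = {c: np.array(sorted(v), dtype=np.int64) for c, v in per.items()}

    def __len__(self) -> int:
        return len(self._set)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._set

    def distance(self, chrom: str, pos: int, cap: int = 10_000) -> int:
        """bp to the nearest known site on chrom, capped; cap when chrom has none."""
        arr = self._sorted.get(chrom)
        if arr is None or len(arr) == 0:
            return cap
        i = int(np.searchsorted(arr, pos))
        d = cap
        if i < len(arr):
            d = min(d, abs(int(arr[i]) - pos))
        if i > 0:
            d = min(d, abs(int(arr[i - 1]) - pos))
        return d


def read_editing_sites(path: str | Path) -> EditingSiteSet:
    """Read a BED (0-based half-open) of editing sites; every covered base becomes
    one 1-based site."""
    sites: list[tuple[str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            sites.extend((chrom, p) for p in range(start + 1, end + 1))
    return EditingSiteSet(sites)


class GermlineSet:
    """Allele-exact (chrom, pos, ref, alt) germline variants from a matched normal."""

    def __init__(self, variants: Iterable[tuple[str, int, str, str]]):
        self._set = set(variants)

    def __len__(self) -> int:
        return len(self._set)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._set


def read_germline_vcf(path: str | Path) -> GermlineSet:
    entries: list[tuple[str, int, str, str]] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                entries.append((rec.chrom, rec.pos, rec.ref, str(alt)))
    return GermlineSet(entries)


# ---------------------------------------------------------------------------
# Signature matrix / expression
# ---------------------------------------------------------------------------

@dataclass
class SignatureMatrix:
    """96 x K reference signature matrix, COSMIC SBS channel order, columns sum to 1."""

    values: np.ndarray  # (96, K)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96, len(self.names)):
            raise ValueError(f"expected (96, {len(self.names)}) matrix, got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("signature matrix has negative entries")
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError(f"signature columns must sum to 1 (got {sums})")
        self.values = self.values / sums  # renormalize residual drift

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(SBS96_CHANNELS), columns=list(self.names))


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"signature file must have 96 data rows, got {df.shape[0]}")
    if set(df.index) != set(SBS96_CHANNELS):
        raise ValueError("channel labels do not match the 96 COSMIC SBS channels")
    df = df.loc[list(SBS96_CHANNELS)]
    return SignatureMatrix(df.to_numpy(dtype=float), tuple(df.columns))


def write_signature_matrix(sigs: SignatureMatrix, path: str | Path) -> None:
    sigs.to_frame().rename_axis("channel").to_csv(path, sep="\t")


def read_tpm_table(path: str | Path) -> pd.Series:
    """TSV with columns gene_id, tpm -> Series of TPM indexed by gene_id."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "tpm"}.issubset(df.columns):
        raise ValueError("TPM table needs columns gene_id, tpm")
    return df.set_index("gene_id")["tpm"].astype(float)
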