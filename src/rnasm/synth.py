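"""Seeded synthetic benchmark: a miniature genome, gene models, truth-labelled
variant candidates and per-site evidence exhibiting the artifact classes an
RNA-seq somatic-mutation pipeline must separate.

The generator simulates at the *evidence* level (per-site read summaries, not
individual reads), which exercises every downstream stage without an aligner.
Truth classes and their evidence fingerprints:

- ``somatic``      — true tumor mutation; VAF ~ Beta(2,5); clean evidence,
                     corroborated by the second aligner and second caller.
- ``germline``     — inherited variant, VAF ~ 0.5 or 1.0; present in the
                     matched-normal VCF the germline filter consults.
- ``editing``      — A-to-I editing observed as A>G / T>C on the transcript
                     strand, placed in exons (sometimes in pairs, mimicking
                     hyper-editing); a configurable fraction is recorded in the
                     known-sites BED, the rest must be caught by the classifier.
- ``rt_error``     — reverse-transcription noise: low VAF (Beta(1,20)), low alt
                     base quality, invisible to the pileup-based second caller.
- ``softclip_artifact`` — clipped-alignment artifact: >= 0.8 of alt reads
                     soft-clipped, end-biased read positions, no second-aligner
                     support.
- ``junction_artifact`` — splice-boundary misalignment: within 5 bp of an
                     annotated exon boundary, no second-aligner support, uneven
                     flank coverage.

A small optional read-level writer produces a sorted BAM for a handful of
sites so the alignment-path extractor can be tested against the same truth.

Everything is deterministic under a fixed seed; files written by
:func:`make_benchmark` are byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from . import io as rio
from .evidence import EvidenceTable, SiteEvidence, write_evidence_table
from .io import (EditingSiteSet, GeneModelIndex, GenomeAccessor, GermlineSet,
                 SignatureMatrix, Transcript, VariantCandidate,
                 write_candidates_vcf, write_signature_matrix)

__all__ = [
    "TRUTH_CLASSES",
    "DEFAULT_PROPORTIONS",
    "TruthManifest",
    "Benchmark",
    "simulate_genome",
    "simulate_truth",
    "simulate_evidence",
    "make_benchmark",
    "synthetic_signatures",
    "write_reads_bam",
]

TRUTH_CLASSES = ("somatic", "germline", "editing", "rt_error",
                 "softclip_artifact", "junction_artifact")

#: Study-condition class mix: somatic-dominated with substantial editing and
#: RT noise, smaller alignment-artifact classes.
DEFAULT_PROPORTIONS = {
    "somatic": 0.40,
    "germline": 0.15,
    "editing": 0.15,
    "rt_error": 0.15,
    "softclip_artifact": 0.075,
    "junction_artifact": 0.075,
}

_GTF_ATTRS = 'gene_id "{g}"; transcript_id "{t}";'


# ---------------------------------------------------------------------------
# Genome + gene models
# ---------------------------------------------------------------------------

def simulate_genome(seed: int, outdir: str | Path, n_chrom: int = 2,
                    chrom_len: int = 100_000, n_genes: int = 40,
                    gc_block: int = 5_000) -> tuple[Path, Path]:
    """Write a miniature FASTA + GTF. Sequence is built from alternating blocks
    with GC-rich / balanced / GC-poor composition (so GC-binned analyses have
    spread); genes have 2-8 exons with 20 bp terminal UTRs around the CDS.
    """
    if chrom_len < 1_000:
        raise ValueError("chrom_len must be >= 1000")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "genome.fa"
    gtf_path = outdir / "genes.gtf"

    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs: dict[str, str] = {}
    for chrom in chroms:
        parts = []
        remaining = chrom_len
        while remaining > 0:
            blk = min(gc_block, remaining)
            gc = rng.choice([0.30, 0.50, 0.70])
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
            parts.append("".join(rng.choice(list("ACGT"), size=blk, p=p)))
            remaining -= blk
        seqs[chrom] = "".join(parts)

    with open(fasta_path, "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")

    gtf_lines = []
    genes_per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                       for i in range(n_chrom)]
    gene_no = 0
    for chrom, n_g in zip(chroms, genes_per_chrom):
        if n_g == 0:
            continue
        slot = chrom_len // n_g
        for k in range(n_g):
            gene_no += 1
            gid = f"G{gene_no:04d}"
            tid = f"{gid}.t1"
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 9))
            slot_start = k * slot + 1
            cursor = slot_start + int(rng.integers(0, max(1, slot // 10)))
            exons = []
            for _ in range(n_exons):
                elen = int(rng.integers(120, 401))
                exons.append((cursor, cursor + elen - 1))
                cursor += elen + int(rng.integers(200, 801))
            if exons[-1][1] > (k + 1) * slot - 1 or exons[-1][1] > chrom_len - 1:
                # trim exons that overflow the slot
                limit = min((k + 1) * slot - 1, chrom_len - 1)
                exons = [(s, e) for s, e in exons if e <= limit]
                if len(exons) < 2:
                    continue
            gstart, gend = exons[0][0], exons[-1][1]
            gtf_lines.append(_gtf_line(chrom, "gene", gstart, gend, strand, gid, tid))
            gtf_lines.append(_gtf_line(chrom, "transcript", gstart, gend, strand, gid, tid))
            for i, (s, e) in enumerate(exons):
                gtf_lines.append(_gtf_line(chrom, "exon", s, e, strand, gid, tid))
                cs, ce = s, e
                if i == 0:
                    cs = s + 20
                if i == len(exons) - 1:
                    ce = e - 20
                if cs <= ce:
                    gtf_lines.append(_gtf_line(chrom, "CDS", cs, ce, strand, gid, tid))
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + ("\n" if gtf_lines else ""))
    return fasta_path, gtf_path


def _gtf_line(chrom, feature, start, end, strand, gid, tid) -> str:
    return "\t".join([chrom, "synth", feature, str(start), str(end), ".", strand,
                      ".", _GTF_ATTRS.format(g=gid, t=tid)])


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Truth-labelled candidate sites with their generating parameters."""

    table: pd.DataFrame  # chrom,pos,ref,alt,truth_class,true_vaf,gene_id,known_editing,sample_id
    seed: int
    class_proportions: dict
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def class_counts(self) -> pd.Series:
        return self.table["truth_class"].value_counts()


def simulate_truth(genome: GenomeAccessor, gene_models: GeneModelIndex, seed: int,
                   n_sites: int = 2_000,
                   class_proportions: Mapping[str, float] | None = None,
                   known_editing_frac: float = 0.6,
                   indel_frac: float = 0.03,
                   n_samples: int = 8) -> TruthManifest:
    """Draw truth-labelled variant sites inside exons.

    VAF models: somatic Beta(2,5); rt_error Beta(1,20); germline 0.5 or 1.0;
    editing Beta(2,2); alignment artifacts Beta(2,5). Editing sites sit on the
    transcript strand (genome A on '+', T on '-') and sometimes come in pairs
    within 100 bp (hyper-editing); junction artifacts sit within 5 bp of an
    exon boundary. ``known_editing_frac`` of editing sites are flagged for the
    known-sites BED. A small fraction of somatic/germline sites are indels.
    """
    props = dict(class_proportions or DEFAULT_PROPORTIONS)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    if n_sites == 0:
        return TruthManifest(pd.DataFrame(columns=[
            "chrom", "pos", "ref", "alt", "truth_class", "true_vaf",
            "gene_id", "known_editing", "sample_id"]), seed, props)

    # exonic position pools
    exonic: list[tuple[str, int, str, str]] = []  # chrom,pos,gene,strand
    boundaries: list[tuple[str, int, str, int, int]] = []  # chrom,boundary,gene,exon s,e
    for gid, txs in gene_models.genes.items():
        tx = txs[0]
        chrom = gene_models._gene_chrom[gid]
        for s, e in tx.exons:
            for p in range(s, e + 1):
                exonic.append((chrom, p, gid, tx.strand))
            boundaries.append((chrom, s, gid, s, e))
            boundaries.append((chrom, e, gid, s, e))
    if not exonic:
        raise ValueError("gene models contain no exons")

    counts = rng.multinomial(n_sites, [props.get(c, 0.0) for c in TRUTH_CLASSES])
    used: set[tuple[str, int]] = set()
    rows: list[dict] = []
    order = rng.permutation(len(exonic))
    cursor = 0

    def next_exonic(predicate=None):
        nonlocal cursor
        while cursor < len(order):
            chrom, p, gid, strand = exonic[order[cursor]]
            cursor += 1
            if (chrom, p) in used:
                continue
            base = genome.base(chrom, p)
            if base not in "ACGT":
                continue
            if predicate is None or predicate(base, strand):
                return chrom, p, gid, strand, base
        raise RuntimeError("exhausted exonic positions; increase genome size")

    bases = "ACGT"
    for cls, n in zip(TRUTH_CLASSES, counts):
        i = 0
        while i < n:
            if cls == "editing":
                chrom, p, gid, strand, base = next_exonic(
                    lambda b, s: (b == "A" and s == "+") or (b == "T" and s == "-"))
                ref, alt = (("A", "G") if strand == "+" else ("T", "C"))
                vaf = float(rng.beta(2, 2))
                rows.append(_truth_row(chrom, p, ref, alt, cls, vaf, gid,
                                       bool(rng.random() < known_editing_frac)))
                used.add((chrom, p))
                i += 1
                # hyper-editing partner within 100 bp, same strand preference
                if i < n and rng.random() < 0.5:
                    partner = _find_partner(genome, chrom, p, strand, used, rng)
                    if partner is not None:
                        p2 = partner
                        rows.append(_truth_row(chrom, p2, ref, alt, cls,
                                               float(rng.beta(2, 2)), gid,
                                               bool(rng.random() < known_editing_frac)))
                        used.add((chrom, p2))
                        i += 1
                continue
            if cls == "junction_artifact":
                b = boundaries[int(rng.integers(len(boundaries)))]
                chrom, bpos, gid, es, ee = b
                p = int(np.clip(bpos + int(rng.integers(-5, 6)), es, ee))
                if (chrom, p) in used:
                    continue
                base = genome.base(chrom, p)
                if base not in "ACGT":
                    continue
                ref = base
                alt = bases[int(rng.integers(4))]
                while alt == ref:
                    alt = bases[int(rng.integers(4))]
                rows.append(_truth_row(chrom, p, ref, alt, cls,
                                       float(rng.beta(2, 5)), gid, False))
                used.add((chrom, p))
                i += 1
                continue
            chrom, p, gid, strand, base = next_exonic()
            ref = base
            if cls in ("somatic", "germline") and rng.random() < indel_frac:
                if rng.random() < 0.5:  # insertion
                    ins = bases[int(rng.integers(4))]
                    alt = ref + ins
                else:  # deletion: need the next genome base
                    if p + 1 > genome.chrom_lengths[chrom]:
                        continue
                    nxt = genome.base(chrom, p + 1)
                    if nxt not in "ACGT":
                        continue
                    ref, alt = base + nxt, base
            else:
                alt = bases[int(rng.integers(4))]
                while alt == ref:
                    alt = bases[int(rng.integers(4))]
            if cls == "somatic":
                # Beta(2,5) left-truncated at the caller-emission floor: sites
                # with allele fraction below ~0.05 never reach a caller's
                # candidate list, so the generator does not emit them either.
                vaf = float(rng.beta(2, 5))
                while vaf < 0.05:
                    vaf = float(rng.beta(2, 5))
            elif cls == "germline":
                vaf = 1.0 if rng.random() < 0.3 else 0.5
            elif cls == "rt_error":
                vaf = float(rng.beta(1, 20))
            else:  # softclip_artifact
                vaf = float(rng.beta(2, 5))
            rows.append(_truth_row(chrom, p, ref, alt, cls, vaf, gid, False))
            used.add((chrom, p))
            i += 1

    df = pd.DataFrame(rows)
    df["sample_id"] = [f"S{int(k) + 1:02d}" for k in rng.integers(0, n_samples, len(df))]
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return TruthManifest(df, seed, props,
                         params={"known_editing_frac": known_editing_frac,
                                 "indel_frac": indel_frac, "n_samples": n_samples})


def _truth_row(chrom, pos, ref, alt, cls, vaf, gid, known) -> dict:
    return {"chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
            "truth_class": cls, "true_vaf": min(max(vaf, 0.01), 1.0),
            "gene_id": gid, "known_editing": known}


def _find_partner(genome, chrom, pos, strand, used, rng):
    want = "A" if strand == "+" else "T"
    offsets = rng.permutation(np.arange(5, 101))
    n = genome.chrom_lengths[chrom]
    for off in offsets:
        for p2 in (pos + int(off), pos - int(off)):
            if 1 <= p2 <= n and (chrom, p2) not in used and genome.base(chrom, p2) == want:
                return p2
    return None


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

def simulate_evidence(truth: TruthManifest, gene_models: GeneModelIndex, seed: int,
                      mean_depth: float = 80.0, dispersion: float = 10.0,
                      tpm: pd.Series | None = None,
                      with_secondary: bool = True
                      ) -> tuple[list[VariantCandidate], EvidenceTable]:
    """Draw per-site evidence with class-specific fingerprints (see module
    docstring). Depth ~ NegBin(mean_depth x gene TPM multiplier, dispersion).
    """
    if mean_depth < 10:
        raise ValueError("mean depth must be >= 10")
    rng = np.random.default_rng(seed)
    median_tpm = float(tpm.median()) if tpm is not None and len(tpm) else 10.0
    candidates: list[VariantCandidate] = []
    entries: dict[tuple, SiteEvidence] = {}
    for row in truth.table.itertuples(index=False):
        cls = row.truth_class
        mult = 1.0
        if tpm is not None and row.gene_id in tpm.index:
            mult = float(np.clip(tpm[row.gene_id] / max(median_tpm, 1e-9), 0.5, 2.0))
        mu = mean_depth * mult
        p_nb = dispersion / (dispersion + mu)
        depth = max(8, int(rng.negative_binomial(dispersion, p_nb)))
        alt = max(1, int(rng.binomial(depth, row.true_vaf)))
        alt = min(alt, depth)
        ref_n = depth - alt
        alt_fwd = int(rng.binomial(alt, 0.5))
        ref_fwd = int(rng.binomial(ref_n, 0.5))

        if cls == "rt_error":
            bq_alt = float(np.clip(rng.normal(16, 3), 2, 25))
        else:
            bq_alt = float(np.clip(rng.normal(36, 2), 25, 42))
        bq_ref = float(np.clip(rng.normal(36, 2), 25, 42))
        mq_alt = mq_ref = 60.0

        if cls == "softclip_artifact":
            relpos = float(np.clip(rng.normal(0.85, 0.07), 0.02, 0.98))
            softclip = float(rng.uniform(0.8, 1.0))
            nm = float(np.clip(rng.normal(3.5, 1.0), 0, 8))
        elif cls == "junction_artifact":
            relpos = float(np.clip(rng.normal(0.5, 0.12), 0.02, 0.98))
            softclip = float(rng.beta(2, 6))
            nm = float(np.clip(rng.normal(2.5, 1.0), 0, 8))
        else:
            relpos = float(np.clip(rng.normal(0.5, 0.08), 0.15, 0.85))
            softclip = float(rng.beta(1, 30))
            nm = float(np.clip(rng.normal(1.2, 0.4), 0, 4))
        multimap = float(rng.beta(1, 40))

        if cls in ("softclip_artifact", "junction_artifact"):
            flank_mult = float(rng.uniform(1.2, 2.5))  # site is a coverage pit
        else:
            flank_mult = float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.3))
        flank_l = round(depth * flank_mult * float(np.clip(rng.normal(1, 0.05), 0.85, 1.15)), 1)
        flank_r = round(depth * flank_mult * float(np.clip(rng.normal(1, 0.05), 0.85, 1.15)), 1)

        if with_secondary:
            a2_depth = int(rng.binomial(depth, 0.9))
            if cls in ("softclip_artifact", "junction_artifact"):
                a2_alt, c2_alt = 0, 0
            elif cls == "rt_error":
                a2_alt = int(rng.binomial(alt, 0.85))
                c2_alt = 0  # pileup caller drops low-quality mismatches
            else:
                a2_alt = int(min(rng.binomial(alt, 0.92) + 2, a2_depth))
                c2_alt = int(rng.binomial(alt, 0.95))
        else:
            a2_depth = a2_alt = c2_alt = -1

        if cls in ("somatic", "germline"):
            qual = float(np.clip(rng.normal(250, 50), 30, 600))
        else:
            qual = float(np.clip(rng.normal(120, 50), 10, 600))

        cand = VariantCandidate(row.chrom, int(row.pos), row.ref, row.alt,
                                caller_qual=round(qual, 1), sample_id=row.sample_id)
        entries[cand.key] = SiteEvidence(
            depth_total=depth, alt_count=alt, ref_count=ref_n,
            alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
            ref_fwd=ref_fwd, ref_rev=ref_n - ref_fwd,
            median_bq_alt=round(bq_alt, 1), median_bq_ref=round(bq_ref, 1),
            median_mq_alt=mq_alt, median_mq_ref=mq_ref,
            mean_relpos_alt=round(relpos, 3),
            frac_softclip_alt=round(softclip, 3),
            frac_multimap_alt=round(multimap, 3),
            mean_nm_alt=round(nm, 2),
            dist_to_junction=gene_models.junction_distance(row.chrom, int(row.pos)),
            flank_depth_left=flank_l, flank_depth_right=flank_r,
            aligner2_depth=a2_depth, aligner2_alt_count=a2_alt,
            caller2_alt_count=c2_alt,
            dup_frac=round(float(rng.beta(1, 50)), 3),
        )
        candidates.append(cand)
    return candidates, EvidenceTable(entries, source="synthetic")


# ---------------------------------------------------------------------------
# Reference signatures (synthetic stand-ins, COSMIC SBS layout)
# ---------------------------------------------------------------------------

def synthetic_signatures(seed: int = 7, names: Sequence[str] = ("synthA", "synthB", "synthC")
                         ) -> SignatureMatrix:
    """Deterministic synthetic reference signatures in the 96-channel layout.

    synthA concentrates on C>T channels (aging-like), synthB on T>C channels
    (deamination-like), synthC is broad. These are constructed stand-ins for
    testing and demos, not real catalogue signatures.
    """
    rng = np.random.default_rng(seed)
    K = len(names)
    vals = np.zeros((96, K))
    profiles = [(2, 0.92), (4, 0.92), (None, None)]  # (class block, mass in block)
    for k in range(K):
        cls_block, mass = profiles[k % 3]
        base = rng.gamma(0.4, 1.0, size=96)
        if cls_block is not None:
            block = np.zeros(96)
            block[cls_block * 16:(cls_block + 1) * 16] = rng.gamma(2.0, 1.0, size=16)
            vec = mass * block / block.sum() + (1 - mass) * base / base.sum()
        else:
            vec = base / base.sum()
        vals[:, k] = vec / vec.sum()
    return SignatureMatrix(vals, tuple(names))


# ---------------------------------------------------------------------------
# Benchmark bundle
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    genome: GenomeAccessor
    gene_models: GeneModelIndex
    truth: TruthManifest
    candidates: list[VariantCandidate]
    evidence: EvidenceTable
    germline: GermlineSet
    editing: EditingSiteSet
    tpm: pd.Series
    signatures: SignatureMatrix
    paths: dict[str, Path] = field(default_factory=dict)

    def labels(self) -> np.ndarray:
        """1 = DNA-backed (present in the tumor DNA: somatic or germline),
        0 = RNA-only (editing, RT noise, alignment artifacts)."""
        cls = self.truth.table["truth_class"]
        return cls.isin(["somatic", "germline"]).to_numpy(dtype=int)

    def truth_class_of(self) -> pd.Series:
        return self.truth.table.set_index(
            ["chrom", "pos", "ref", "alt"])["truth_class"]


def make_benchmark(seed: int, outdir: str | Path, n_sites: int = 2_000,
                   n_chrom: int = 4, chrom_len: int = 250_000, n_genes: int = 240,
                   mean_depth: float = 80.0,
                   class_proportions: Mapping[str, float] | None = None,
                   known_editing_frac: float = 0.6) -> Benchmark:
    """One call that produces every file and object the pipeline, the test
    suite and the docs walkthrough need."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s_genome, s_truth, s_ev, s_tpm, s_dna = (int(x) for x in rng.integers(0, 2**31 - 1, 5))

    fasta_path, gtf_path = simulate_genome(s_genome, outdir, n_chrom=n_chrom,
                                           chrom_len=chrom_len, n_genes=n_genes)
    genome = GenomeAccessor(fasta_path)
    gene_models = rio.read_gene_models(gtf_path)

    # gene expression: log-normal TPM, a tail below the TPM<1 gate
    rng_tpm = np.random.default_rng(s_tpm)
    gene_ids = sorted(gene_models.genes)
    tpm = pd.Series(np.round(10 ** rng_tpm.normal(1.0, 1.0, len(gene_ids)), 3),
                    index=gene_ids, name="tpm")

    truth = simulate_truth(genome, gene_models, s_truth, n_sites=n_sites,
                           class_proportions=class_proportions,
                           known_editing_frac=known_editing_frac)
    candidates, evidence = simulate_evidence(truth, gene_models, s_ev,
                                             mean_depth=mean_depth, tpm=tpm)

    tdf = truth.table
    germ = tdf[tdf.truth_class == "germline"]
    germline = GermlineSet((r.chrom, int(r.pos), r.ref, r.alt)
                           for r in germ.itertuples(index=False))
    known_ed = tdf[(tdf.truth_class == "editing") & tdf.known_editing]
    editing = EditingSiteSet((r.chrom, int(r.pos)) for r in known_ed.itertuples(index=False))
    sigs = synthetic_signatures()

    paths = {
        "genome": fasta_path, "gtf": gtf_path,
        "germline_vcf": outdir / "germline.vcf",
        "editing_bed": outdir / "editing.bed",
        "candidates_vcf": outdir / "candidates.vcf",
        "evidence_tsv": outdir / "evidence.tsv",
        "truth_tsv": outdir / "truth.tsv",
        "tpm_tsv": outdir / "tpm.tsv",
        "signatures_tsv": outdir / "signatures.tsv",
        "reference_tsv": outdir / "reference.tsv",
        "dna_depth_tsv": outdir / "dna_depth.tsv",
    }
    # DNA-side reference set (somatic + germline are present in the tumor DNA)
    # and per-site DNA sequencing depth for the cross-platform coverage rule.
    ref_rows = tdf[tdf.truth_class.isin(["somatic", "germline"])]
    ref_rows[["sample_id", "chrom", "pos", "ref", "alt"]].to_csv(
        paths["reference_tsv"], sep="\t", index=False)
    rng_dna = np.random.default_rng(s_dna)
    dna_depth = rng_dna.negative_binomial(8, 8 / (8 + 60.0), size=len(tdf))
    pd.DataFrame({"sample_id": tdf.sample_id, "chrom": tdf.chrom,
                  "pos": tdf.pos, "depth": dna_depth}).to_csv(
        paths["dna_depth_tsv"], sep="\t", index=False)
    _write_simple_vcf(germ, paths["germline_vcf"], genome)
    with open(paths["editing_bed"], "w") as fh:
        for r in known_ed.sort_values(["chrom", "pos"]).itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.pos) - 1}\t{int(r.pos)}\n")
    write_candidates_vcf(candidates, paths["candidates_vcf"])
    write_evidence_table(evidence, paths["evidence_tsv"])
    tdf.to_csv(paths["truth_tsv"], sep="\t", index=False)
    tpm.rename_axis("gene_id").reset_index().to_csv(paths["tpm_tsv"], sep="\t", index=False)
    write_signature_matrix(sigs, paths["signatures_tsv"])

    return Benchmark(genome=genome, gene_models=gene_models, truth=truth,
                     candidates=candidates, evidence=evidence, germline=germline,
                     editing=editing, tpm=tpm, signatures=sigs, paths=paths)


def _write_simple_vcf(df: pd.DataFrame, path: Path, genome: GenomeAccessor) -> None:
    cands = [VariantCandidate(r.chrom, int(r.pos), r.ref, r.alt)
             for r in df.itertuples(index=False)]
    write_candidates_vcf(cands, path)


# ---------------------------------------------------------------------------
# Optional read-level writer (tests the alignment-path extractor)
# ---------------------------------------------------------------------------

def write_reads_bam(genome: GenomeAccessor, sites: pd.DataFrame, bam_path: str | Path,
                    seed: int = 0, depth: int = 40, read_len: int = 80) -> Path:
    """Emit a sorted, indexed BAM with reads covering each truth site.

    Alt reads carry the alt base at the site; ``true_vaf`` sets the expected alt
    fraction. Only SNV rows are supported. Intended for small site sets.
    """
    rng = np.random.default_rng(seed)
    bam_path = Path(bam_path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": n} for c, n in sorted(genome.chrom_lengths.items())]}
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    reads = []
    qn = 0
    for row in sites.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1:
            raise ValueError("write_reads_bam supports SNVs only")
        pos0 = int(row.pos) - 1
        n_alt = int(round(depth * float(row.true_vaf)))
        for i in range(depth):
            offset = int(rng.integers(5, read_len - 5))
            start0 = max(0, pos0 - offset)
            seq = list(genome.fetch(row.chrom, start0 + 1, start0 + read_len))
            is_alt = i < n_alt
            if is_alt:
                seq[pos0 - start0] = row.alt
            a = pysam.AlignedSegment()
            qn += 1
            a.query_name = f"r{qn:06d}"
            a.query_sequence = "".join(seq)
            a.flag = 16 if rng.random() < 0.5 else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = start0
            a.mapping_quality = 60
            a.cigartuples = [(pysam.CMATCH, read_len)]
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            reads.append(a)
    reads.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as fh:
        for r in reads:
            fh.write(r)
    pysam.index(str(bam_path))
    return bam_path
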