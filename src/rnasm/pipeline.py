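"""End-to-end orchestration: ingest -> evidence -> filter bank -> features ->
classify -> annotate -> write, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import EvidenceTable
from .features import FeatureExtractor
from .filters import (FILTER_DESCRIPTIONS, FilterConfig, FilterReport,
                      FilterResources, apply_filter_bank)
from .io import AnnotatedCall, VariantCandidate, write_calls
from .model import StackingModel
from .signatures import substitution_class

__all__ = ["run_call", "config_hash", "write_manifest"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_call(candidates: Sequence[VariantCandidate], evidence: EvidenceTable,
             resources: FilterResources, config: FilterConfig | None = None,
             model: StackingModel | None = None, threshold: float = 0.5,
             tpm: Mapping[str, float] | None = None
             ) -> tuple[list[AnnotatedCall], FilterReport, dict]:
    """Filter candidates, optionally classify the survivors, and annotate.

    Returns (annotated calls for *all* input candidates, filter report,
    manifest of per-stage counts). A call passes iff it fails no enabled filter
    and — when a model is supplied — its classifier probability reaches
    ``threshold``; classifier rejections carry the pseudo-filter id
    ``ml_rna_only``.
    """
    config = config or FilterConfig()
    passed, report = apply_filter_bank(candidates, evidence, resources, config)
    passed_keys = {c.key for c in passed}

    probs: dict[tuple, float] = {}
    if model is not None and passed:
        extractor = FeatureExtractor(resources, tpm=tpm)
        X = extractor.matrix(passed, evidence)
        p = model.predict_proba(X)
        probs = {c.key: float(pi) for c, pi in zip(passed, p)}

    calls: list[AnnotatedCall] = []
    n_ml_rejected = 0
    for cand in candidates:
        failed = list(report.failures.get(cand.key, ()))
        prob = probs.get(cand.key)
        if cand.key in passed_keys and model is not None and prob is not None \
                and prob < threshold:
            failed.append("ml_rna_only")
            n_ml_rejected += 1
        cls = substitution_class(cand.ref, cand.alt) if cand.is_snv else None
        region = gene = None
        if resources.gene_models is not None:
            region = resources.gene_models.region(cand.chrom, cand.pos)
            gene = resources.gene_models.gene_at(cand.chrom, cand.pos)
        calls.append(AnnotatedCall(candidate=cand, failed_filters=tuple(failed),
                                   probability=prob, subst_class=cls,
                                   region=region, gene_id=gene))

    n_final = sum(1 for c in calls if c.passed)
    manifest = {
        "n_input": len(candidates),
        "n_filter_pass": len(passed),
        "n_ml_rejected": n_ml_rejected,
        "n_final": n_final,
        "threshold": threshold,
        "filter_config_hash": config_hash(asdict(config) | {"disabled": sorted(config.disabled)}),
        "rejected_by_filter_attributed": {f: int(n) for f, n
                                          in report.n_rejected_attributed.items()},
    }
    assert manifest["n_filter_pass"] - n_ml_rejected == n_final
    return calls, report, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (Path,)):
        return str(x)
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
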