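"""Per-sample and cohort pipeline stages behind the command-line interface.

``run_sample`` executes parse -> features -> train -> score reads -> junction
scores for one alignment file (one 10x lane or one Smart-seq2 cell: a new
model is fitted per sample, which absorbs batch effects).  ``run_cohort``
reads per-sample junction tables and applies the median combination and the
calling threshold.  All randomness derives from the run seed; outputs are
sorted by junction key so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from splicecall._version import __version__
from splicecall.alignment_io import features_for_records, parse_spliced_alignments
from splicecall.cohort import call_junctions, combine_median
from splicecall.junction_scoring import (
    DEFAULT_ARTIFACT_FRAC,
    DEFAULT_MIN_ARTIFACT_NULL,
    DEFAULT_NULL_BOUNDARY,
    DEFAULT_NULL_REPS,
    FILTER_ENTROPY_MIN,
    FILTER_HOMOPOLYMER_MAX,
    score_junctions,
)
from splicecall.read_model import build_training_set, fit_read_model, score_reads

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

SAMPLE_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand", "N", "P", "P_cum",
    "emp_p", "frac_genomic", "n_distinct_offsets", "mean_longest_run",
    "mean_entropy", "pass_genomic_fraction", "pass_offset_diversity",
    "pass_homopolymer", "pass_entropy", "eligible_for_median", "null_kind",
    "fallback_flag",
]

FEATURE_COLUMNS = [
    "read_id", "sample_id", "cell_barcode", "chrom", "intron_start",
    "intron_end", "strand", "nh", "hi", "nmm", "as_raw", "as_norm",
    "overlap", "max_overlap", "softclip_s", "entropy",
    "has_genomic_alignment", "align_start_offset",
]


@dataclass
class RunConfig:
    mode: str = "single"
    cap: int = 10_000
    null_reps: int = DEFAULT_NULL_REPS
    null_boundary: int = DEFAULT_NULL_BOUNDARY
    artifact_frac_threshold: float = DEFAULT_ARTIFACT_FRAC
    min_artifact_null: int = DEFAULT_MIN_ARTIFACT_NULL
    homopolymer_max: float = FILTER_HOMOPOLYMER_MAX
    entropy_min: float = FILTER_ENTROPY_MIN
    call_threshold: float = 0.15
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _tsv_header(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    params = ";".join(f"{k}={d[k]}" for k in sorted(d))
    return (
        f"# splicecall v{__version__} schema={SCHEMA_VERSION} "
        f"config_hash={config.config_hash()} seed={config.seed}\n"
        f"# {params}\n"
    )


def run_sample(
    alignment_path, config: RunConfig, sample_id: str | None = None
) -> dict:
    """Score one sample; writes junction TSV, feature TSV, and the model.

    Returns a dict with the output paths, the fitted model, and the
    per-junction scores.
    """
    alignment_path = Path(alignment_path)
    sample_id = sample_id or alignment_path.stem
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    parsed = parse_spliced_alignments(
        alignment_path, mode=config.mode, sample_id=sample_id
    )
    if config.mode == "paired":
        records, _genomic, mate_summaries = parsed
        features = features_for_records(records, "paired", mate_summaries)
    else:
        records, _genomic = parsed
        features = features_for_records(records, "single")

    training = build_training_set(records, features, cap=config.cap, seed=config.seed)
    logger.info("sample %s: training sizes %s", sample_id, training.sizes)
    model = fit_read_model(training, mode=config.mode, seed=config.seed)
    p_hats = score_reads(model, records, features)

    scores = score_junctions(
        records,
        p_hats,
        sample_id=sample_id,
        reps=config.null_reps,
        boundary=config.null_boundary,
        artifact_frac=config.artifact_frac_threshold,
        min_artifact_null=config.min_artifact_null,
        homopolymer_max=config.homopolymer_max,
        entropy_min=config.entropy_min,
        seed=config.seed,
    )
    n_artifact = sum(s.frac_genomic >= config.artifact_frac_threshold for s in scores)
    logger.info(
        "sample %s: %d junctions, artifact-null size %d, null regimes %s",
        sample_id, len(scores), n_artifact,
        pd.Series([s.null_kind for s in scores]).value_counts().to_dict(),
    )

    rows = []
    for s in scores:
        rows.append(
            {
                "chrom": s.junction.chrom,
                "intron_start": s.junction.intron_start,
                "intron_end": s.junction.intron_end,
                "strand": s.junction.strand,
                "N": s.N,
                "P": f"{s.P:.6g}",
                "P_cum": f"{s.P_cum:.6g}",
                "emp_p": f"{s.emp_p:.6g}",
                "frac_genomic": f"{s.frac_genomic:.6g}",
                "n_distinct_offsets": s.n_distinct_offsets,
                "mean_longest_run": f"{s.mean_longest_run:.6g}",
                "mean_entropy": f"{s.mean_entropy:.6g}",
                "pass_genomic_fraction": int(s.filters_passed["genomic_fraction"]),
                "pass_offset_diversity": int(s.filters_passed["offset_diversity"]),
                "pass_homopolymer": int(s.filters_passed["homopolymer"]),
                "pass_entropy": int(s.filters_passed["entropy"]),
                "eligible_for_median": int(s.eligible_for_median),
                "null_kind": s.null_kind,
                "fallback_flag": int(s.fallback_flag),
            }
        )
    junc_df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS).sort_values(
        ["chrom", "intron_start", "intron_end"], kind="mergesort"
    )
    junctions_path = out_dir / f"{sample_id}.junctions.tsv"
    with open(junctions_path, "w") as fh:
        fh.write(_tsv_header(config))
        junc_df.to_csv(fh, sep="\t", index=False)

    feat_rows = []
    for r, f in zip(records, features):
        feat_rows.append(
            {
                "read_id": r.read_id,
                "sample_id": r.sample_id,
                "cell_barcode": r.cell_barcode or "",
                "chrom": r.junction.chrom,
                "intron_start": r.junction.intron_start,
                "intron_end": r.junction.intron_end,
                "strand": r.junction.strand,
                "nh": r.nh,
                "hi": r.hi,
                "nmm": r.nmm,
                "as_raw": r.as_raw,
                "as_norm": f"{f.as_norm:.6g}",
                "overlap": f.overlap,
                "max_overlap": f.max_overlap,
                "softclip_s": f.softclip_s,
                "entropy": f"{f.entropy:.6g}",
                "has_genomic_alignment": int(r.has_genomic_alignment),
                "align_start_offset": r.align_start_offset,
            }
        )
    features_path = out_dir / f"{sample_id}.features.tsv"
    with open(features_path, "w") as fh:
        fh.write(_tsv_header(config))
        pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS).to_csv(
            fh, sep="\t", index=False
        )

    model_path = out_dir / f"{sample_id}.model.yaml"
    model_path.write_text(model.to_yaml())

    return {
        "junctions_path": junctions_path,
        "features_path": features_path,
        "model_path": model_path,
        "model": model,
        "scores": scores,
        "records": records,
        "p_hats": p_hats,
    }


@dataclass
class _TsvScore:
    """Per-sample junction score rehydrated from a junction TSV row."""

    junction: object
    sample_id: str
    emp_p: float
    eligible_for_median: bool


def _read_sample_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "splicecall" not in first or f"schema={SCHEMA_VERSION}" not in first:
        raise ValueError(
            f"schema mismatch in {path}: expected splicecall schema "
            f"{SCHEMA_VERSION} header, got {first.strip()!r}"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def run_cohort(sample_tsv_paths, config: RunConfig, out_path=None):
    """Combine per-sample junction tables and call at the threshold."""
    from splicecall.alignment_io import SpliceJunction

    per_junction: dict[tuple, list] = {}
    for path in sample_tsv_paths:
        df = _read_sample_tsv(path)
        sample_id = Path(path).name.replace(".junctions.tsv", "")
        for row in df.itertuples():
            key = (row.chrom, int(row.intron_start), int(row.intron_end))
            per_junction.setdefault(key, []).append(
                _TsvScore(
                    junction=SpliceJunction(*key, strand=str(row.strand)),
                    sample_id=sample_id,
                    emp_p=float(row.emp_p),
                    eligible_for_median=bool(row.eligible_for_median),
                )
            )
    table = combine_median(per_junction)
    call_junctions(table, threshold=config.call_threshold)

    if out_path is not None:
        rows = [
            {
                "chrom": r.junction_key[0],
                "intron_start": r.junction_key[1],
                "intron_end": r.junction_key[2],
                "strand": r.strand,
                "cohort_score": f"{r.cohort_score:.6g}",
                "n_samples_detected": r.n_samples_detected,
                "n_samples_eligible": r.n_samples_eligible,
                "called": int(r.called),
                "reason_flags": r.reason,
            }
        for r in table.rows]
        with open(out_path, "w") as fh:
            fh.write(_tsv_header(config))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    return table
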