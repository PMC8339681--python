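"""Synthetic spliced-alignment generator with known junction truth.

Emits SAM files that exhibit the noise structure the caller targets:
artifact junctions whose reads are built from short tandem repeats (low
5-mer entropy), frequently co-aligned contiguously elsewhere in the genome
(the genomic-alignment signature of mapping artifacts), multimapping
(NH > 1) and mismatch-rich; true junctions whose reads are high-complexity,
uniquely mapping and rarely genomically co-aligned.  Reference sequences
are synthetic and never materialized as FASTA: junction coordinates are
declared, since the statistical method consumes only alignment records.

The junction set is a pure function of the config seed, shared by every
sample of a cohort; read noise is drawn independently per sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
_CHROMS = [("chr1", 200_000), ("chr2", 200_000), ("chr3", 200_000)]


@dataclass
class SimConfig:
    """Generation parameters; per-class dicts are keyed "true"/"artifact".

    AS is generated as read_length - 2*nmm - softclip (a STAR-like linear
    penalty), so the score ordering between classes is exact by construction.
    """

    n_true_junctions: int = 90
    n_artifact_junctions: int = 60
    reads_per_junction: dict = field(
        default_factory=lambda: {"kind": "fixed", "value": 12}
    )
    read_length: int = 60
    # repeat units per class; None = iid uniform bases (high complexity)
    entropy_regime: dict = field(
        default_factory=lambda: {
            "true": None,
            "artifact": ["AC", "AG", "TC", "CT", "ACC", "TCC"],
        }
    )
    p_genomic_coalignment: dict = field(
        default_factory=lambda: {"true": 0.02, "artifact": 0.8}
    )
    nh_distribution: dict = field(
        default_factory=lambda: {
            "true": {"values": [1, 2, 3], "probs": [0.9, 0.07, 0.03]},
            "artifact": {"values": [2, 4, 6, 8, 10], "probs": [0.3, 0.25, 0.2, 0.15, 0.1]},
        }
    )
    mismatch_rate: dict = field(  # Poisson mean of NM per read
        default_factory=lambda: {"true": 0.2, "artifact": 1.2}
    )
    softclip_rate: dict = field(  # probability a read carries a soft clip
        default_factory=lambda: {"true": 0.1, "artifact": 0.4}
    )
    overhang_distribution: dict = field(  # uniform in [min, read_length - min]
        default_factory=lambda: {"min": 10}
    )
    n_samples: int = 2
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        base = cls()
        merged = {**base.to_dict(), **d}
        return cls(**merged)


def _rng_for(config: SimConfig, *streams: int) -> np.random.Generator:
    return np.random.default_rng(
        (int(config.seed) * 99_991 + sum((s + 1) * 7_919 ** i for i, s in enumerate(streams)))
        % 2**31
    )


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _repeat_seq(rng, n: int, unit: str) -> str:
    phase = int(rng.integers(len(unit)))
    s = (unit * (n // len(unit) + 2))[phase : phase + n]
    return s


def _draw_junctions(config: SimConfig) -> pd.DataFrame:
    rng = _rng_for(config, 0)
    rows = []
    used = set()
    classes = ["true"] * config.n_true_junctions + ["artifact"] * config.n_artifact_junctions
    flank = config.read_length + 10
    for i, cls in enumerate(classes):
        while True:
            chrom, ln = _CHROMS[int(rng.integers(len(_CHROMS)))]
            intron_len = int(rng.integers(80, 5001))
            start = int(rng.integers(flank + 1, ln - intron_len - flank))
            key = (chrom, start, start + intron_len - 1)
            if key not in used:
                used.add(key)
                break
        unit_spec = config.entropy_regime[cls]
        if unit_spec is None:
            left = _random_seq(rng, flank)
            right = _random_seq(rng, flank)
        else:
            unit = unit_spec[int(rng.integers(len(unit_spec)))]
            left = _repeat_seq(rng, flank, unit)
            right = _repeat_seq(rng, flank, unit)
        rows.append(
            {
                "junction_id": f"j{i}",
                "chrom": key[0],
                "intron_start": key[1],
                "intron_end": key[2],
                "cls": cls,
                "left_flank": left,
                "right_flank": right,
            }
        )
    return pd.DataFrame(rows)


def _n_reads(config: SimConfig, rng) -> int:
    spec = config.reads_per_junction
    if spec["kind"] == "fixed":
        return int(spec["value"])
    if spec["kind"] == "poisson":
        return max(1, int(rng.poisson(spec["mean"])))
    raise ValueError(f"unknown reads_per_junction kind {spec['kind']!r}")


def _mutate(rng, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    s = list(seq)
    pos = rng.choice(len(s), size=min(n_sub, len(s)), replace=False)
    for p in pos:
        alts = [b for b in "ACGT" if b != s[p]]
        s[p] = alts[int(rng.integers(3))]
    return "".join(s)


def simulate_sample(
    config: SimConfig, sample_index: int = 0
) -> tuple[str, pd.DataFrame]:
    """One sample's SAM text and its read-level truth table.

    Deterministic: identical (config, sample_index) give byte-identical
    output.  Each junctional read carries NH/HI/AS/NM and an N-bearing
    CIGAR consistent with its overhangs; reads drawn for genomic
    co-alignment additionally receive a secondary N-free alignment line.
    """
    junctions = _draw_junctions(config)
    rng = _rng_for(config, 1, sample_index)
    L = config.read_length
    min_ov = config.overhang_distribution["min"]
    if min_ov < 1 or 2 * min_ov >= L:
        raise ValueError(
            f"overhang minimum {min_ov} incompatible with read length {L}"
        )

    lines = []
    truth_rows = []
    for _, j in junctions.iterrows():
        cls = j["cls"]
        nh_spec = config.nh_distribution[cls]
        for k in range(_n_reads(config, rng)):
            rid = f"s{sample_index}_{j['junction_id']}_r{k}"
            softclip = 0
            if rng.random() < config.softclip_rate[cls]:
                softclip = int(rng.integers(1, 9))
            aligned = L - softclip
            a = int(rng.integers(min_ov, aligned - min_ov + 1))
            b = aligned - a
            seq = j["left_flank"][-a:] + j["right_flank"][:b]
            nmm = int(rng.poisson(config.mismatch_rate[cls]))
            nmm = min(nmm, aligned // 4)
            seq = _mutate(rng, seq, nmm)
            clip_left = bool(rng.random() < 0.5) if softclip else False
            if softclip:
                clip_seq = _random_seq(rng, softclip)
                if clip_left:
                    seq = clip_seq + seq
                    cigar = f"{softclip}S{a}M{j['intron_end'] - j['intron_start'] + 1}N{b}M"
                else:
                    seq = seq + clip_seq
                    cigar = f"{a}M{j['intron_end'] - j['intron_start'] + 1}N{b}M{softclip}S"
            else:
                cigar = f"{a}M{j['intron_end'] - j['intron_start'] + 1}N{b}M"
            pos = j["intron_start"] - a
            has_genomic = rng.random() < config.p_genomic_coalignment[cls]
            nh = int(rng.choice(nh_spec["values"], p=nh_spec["probs"]))
            if has_genomic:
                nh = max(nh, 2)
            as_score = L - 2 * nmm - softclip
            mapq = 255 if nh == 1 else 3
            tags = f"NH:i:{nh}\tHI:i:1\tAS:i:{as_score}\tNM:i:{nmm}"
            lines.append(
                f"{rid}\t0\t{j['chrom']}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\t{tags}"
            )
            if has_genomic:
                g_chrom, g_len = _CHROMS[int(rng.integers(len(_CHROMS)))]
                g_pos = int(rng.integers(1, g_len - L))
                g_nmm = int(rng.integers(0, 3))
                g_tags = f"NH:i:{nh}\tHI:i:2\tAS:i:{L - 2 * g_nmm}\tNM:i:{g_nmm}"
                lines.append(
                    f"{rid}\t256\t{g_chrom}\t{g_pos}\t3\t{L}M\t*\t0\t0\t"
                    f"{seq[:L] if len(seq) >= L else seq}\t{'I' * min(len(seq), L)}\t{g_tags}"
                )
            truth_rows.append(
                {
                    "read_id": rid,
                    "junction_id": j["junction_id"],
                    "chrom": j["chrom"],
                    "intron_start": j["intron_start"],
                    "intron_end": j["intron_end"],
                    "cls": cls,
                    "nh": nh,
                    "nmm": nmm,
                    "softclip": softclip,
                    "overhang_left": a,
                    "overhang_right": b,
                    "has_genomic": has_genomic,
                }
            )

    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{c}\tLN:{ln}" for c, ln in _CHROMS
    ]
    sam_text = "\n".join(header + lines) + "\n"
    return sam_text, pd.DataFrame(truth_rows)


def junction_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Collapse a read-level truth table to one row per junction."""
    return (
        truth.groupby(["chrom", "intron_start", "intron_end"], as_index=False)
        .agg(junction_id=("junction_id", "first"), cls=("cls", "first"))
    )


def evaluate_calls(cohort_table, truth: pd.DataFrame) -> dict:
    """Confusion counts at the calling threshold plus an exact pairwise
    ranking statistic: the probability that a random true junction's cohort
    score is below a random artifact junction's (ties count half)."""
    jt = junction_truth(truth)
    truth_by_key = {
        (r.chrom, int(r.intron_start), int(r.intron_end)): r.cls
        for r in jt.itertuples()
    }
    table_keys = {row.junction_key for row in cohort_table.rows}
    orphans = (set(truth_by_key) - table_keys) | (table_keys - set(truth_by_key))
    if orphans:
        raise ValueError(f"junction keys do not match truth: {sorted(orphans)[:5]}")

    tp = fp = tn = fn = 0
    true_scores, artifact_scores = [], []
    for row in cohort_table.rows:
        cls = truth_by_key[row.junction_key]
        if cls == "true":
            true_scores.append(row.cohort_score)
            tp += row.called
            fn += not row.called
        else:
            artifact_scores.append(row.cohort_score)
            fp += row.called
            tn += not row.called
    t = np.asarray(true_scores)[:, None]
    a = np.asarray(artifact_scores)[None, :]
    wins = np.count_nonzero(t < a) + 0.5 * np.count_nonzero(t == a)
    ranking = float(wins / (t.size * a.size)) if t.size and a.size else float("nan")
    return {
        "tp": int(tp), "fp": int(fp), "tn": int(tn), "fn": int(fn),
        "ranking_statistic": ranking,
        "median_true_score": float(np.median(true_scores)) if true_scores else float("nan"),
        "median_artifact_score": float(np.median(artifact_scores)) if artifact_scores else float("nan"),
    }
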