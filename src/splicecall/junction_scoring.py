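"""Junction-level evidence aggregation and per-sample filtering.

Read scores at a junction are combined under a Bayesian two-hypothesis
ratio,

    P = prod(p_i) / (prod(p_i) + prod(1 - p_i))
      = 1 / (1 + exp(sum_i log((1 - p_i) / p_i))),

computed in the log-odds form for numerical stability.  Because P shrinks
with read count N even for confident reads, it is converted to a cumulative
score P_cum against a null built by resampling N read scores from the
sample's pool: an exact resampling null (10,000 draws) for small N, a
Gaussian (CLT) approximation of the summed log-odds for large N.  Junctions
whose reads are frequently co-aligned contiguously elsewhere (>= 10%
genomic fraction) serve as the likely-artifact set; the empirical p-value
emp_p of a junction is the add-one-smoothed right-tail rank of its P_cum in
that artifact distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from splicecall.alignment_io import (
    SplicedAlignmentRecord,
    longest_base_run,
    read_entropy,
)

logger = logging.getLogger(__name__)

DEFAULT_NULL_REPS = 10_000
DEFAULT_NULL_BOUNDARY = 15  # N <= boundary: resampling null; N > boundary: CLT
DEFAULT_ARTIFACT_FRAC = 0.1
DEFAULT_MIN_ARTIFACT_NULL = 50
FILTER_HOMOPOLYMER_MAX = 11
FILTER_ENTROPY_MIN = 3.0


@dataclass
class JunctionReadSet:
    """All scored reads of one junction in one sample, with summaries."""

    junction: object
    sample_id: str
    reads: list  # (SplicedAlignmentRecord, p_hat)
    frac_genomic: float
    n_distinct_offsets: int
    mean_longest_run: float
    mean_entropy: float

    @property
    def N(self) -> int:
        return len(self.reads)

    @property
    def p_hats(self) -> np.ndarray:
        return np.array([p for _, p in self.reads])


@dataclass
class JunctionSampleScore:
    junction: object
    sample_id: str
    N: int
    P: float
    P_cum: float
    emp_p: float
    frac_genomic: float
    n_distinct_offsets: int
    mean_longest_run: float
    mean_entropy: float
    filters_passed: dict  # genomic_fraction, offset_diversity, homopolymer, entropy
    null_kind: str
    fallback_flag: bool = False

    @property
    def eligible_for_median(self) -> bool:
        return all(self.filters_passed.values())


@dataclass
class NullModel:
    """Null distribution of aggregated scores for one read count N."""

    kind: str  # "empirical" or "gaussian"
    N: int
    null_scores: np.ndarray = field(default_factory=lambda: np.array([]))
    mu: float = 0.0  # mean of per-read log-odds over the pool (gaussian kind)
    sigma: float = 0.0  # sd of per-read log-odds over the pool
    reps: int = DEFAULT_NULL_REPS
    seed: int = 0


def log_odds(p_hats: np.ndarray) -> np.ndarray:
    """Per-read log-odds against truth: l_i = log((1 - p_i) / p_i)."""
    p = np.asarray(p_hats, dtype=float)
    return np.log1p(-p) - np.log(p)


def aggregate_score(p_hats) -> float:
    """Aggregated junction score P from its reads' p-hats (log-odds form)."""
    p = np.asarray(p_hats, dtype=float)
    if p.size == 0:
        raise ValueError("aggregate_score requires at least one read score")
    s = log_odds(p).sum()
    return float(np.exp(-np.logaddexp(0.0, s)))  # 1 / (1 + e^s), overflow-safe


def collapse_to_junctions(
    records: list[SplicedAlignmentRecord],
    p_hats,
    sample_id: str = "sample",
) -> list[JunctionReadSet]:
    """Group scored records by junction identity and compute summaries.

    A record contributes to exactly one junction (multi-intron reads were
    already expanded to one record per N operator upstream).
    """
    by_junc: dict[tuple, list] = {}
    for rec, p in zip(records, p_hats):
        by_junc.setdefault(rec.junction.key, []).append((rec, float(p)))
    out = []
    for key in sorted(by_junc):
        reads = by_junc[key]
        recs = [r for r, _ in reads]
        out.append(
            JunctionReadSet(
                junction=recs[0].junction,
                sample_id=sample_id,
                reads=reads,
                frac_genomic=float(
                    np.mean([r.has_genomic_alignment for r in recs])
                ),
                n_distinct_offsets=len({r.align_start_offset for r in recs}),
                mean_longest_run=float(
                    np.mean([longest_base_run(r.read_seq) for r in recs])
                ),
                mean_entropy=float(
                    np.mean([read_entropy(r.read_seq) for r in recs])
                ),
            )
        )
    return out


def build_null(
    sample_p_hats,
    N: int,
    reps: int = DEFAULT_NULL_REPS,
    boundary: int = DEFAULT_NULL_BOUNDARY,
    seed: int = 0,
) -> NullModel:
    """Null distribution of P for read count N from the sample's score pool.

    N <= boundary: ``reps`` draws of N scores sampled uniformly with
    replacement, each aggregated.  N > boundary: Gaussian surrogate for the
    summed log-odds, parameterized by the pool's per-read log-odds mean and
    standard deviation.
    """
    pool = np.asarray(sample_p_hats, dtype=float)
    if pool.size < 2:
        raise ValueError("null requires a pool of at least 2 scored reads")
    ell = log_odds(pool)
    if N <= boundary:
        rng = np.random.default_rng((int(seed) * 10_007 + N) % 2**31)
        draws = rng.choice(ell, size=(reps, N), replace=True)
        null_scores = 1.0 / (1.0 + np.exp(draws.sum(axis=1)))
        return NullModel(
            kind="empirical", N=N, null_scores=null_scores, reps=reps, seed=seed
        )
    return NullModel(
        kind="gaussian",
        N=N,
        mu=float(ell.mean()),
        sigma=float(ell.std(ddof=0)),
        reps=reps,
        seed=seed,
    )


def cumulative_score(jrs_p_hats, null: NullModel) -> float:
    """P_cum: where the observed aggregate falls in the null.

    Empirical kind: mid-rank fraction of null aggregates below the observed
    P (ties get half weight).  Gaussian kind: with observed log-odds sum s,
    P_cum = 1 - Phi((s - N*mu) / (sigma*sqrt(N))); a small s means a large P
    and hence a large P_cum.
    """
    p = np.asarray(jrs_p_hats, dtype=float)
    if p.size != null.N:
        raise ValueError(f"null built for N={null.N}, got {p.size} reads")
    if null.kind == "empirical":
        obs = aggregate_score(p)
        below = np.count_nonzero(null.null_scores < obs)
        ties = np.count_nonzero(null.null_scores == obs)
        return float((below + 0.5 * ties) / null.null_scores.size)
    s = log_odds(p).sum()
    center = null.N * null.mu
    if null.sigma == 0:
        logger.warning("gaussian null with zero spread; sign rule applied")
        return 1.0 if s < center else (0.0 if s > center else 0.5)
    z = (s - center) / (null.sigma * np.sqrt(null.N))
    return float(1.0 - norm.cdf(z))


def empirical_p(
    p_cum: float,
    artifact_null: np.ndarray,
    min_artifact_null: int = DEFAULT_MIN_ARTIFACT_NULL,
) -> tuple[float, bool]:
    """Right-tail empirical p-value of P_cum in the likely-artifact set.

    emp_p = (#{artifact P_cum >= observed} + 1) / (M + 1); the add-one keeps
    emp_p positive when the observation beats the whole null.  Returns
    (emp_p, fallback_flag); with fewer than ``min_artifact_null`` artifact
    junctions the fallback emp_p = 1 - P_cum is used and flagged.
    """
    art = np.asarray(artifact_null, dtype=float)
    if art.size < min_artifact_null:
        logger.warning(
            "artifact null has %d values (< %d); falling back to 1 - P_cum",
            art.size, min_artifact_null,
        )
        return float(1.0 - p_cum), True
    m = art.size
    return float((np.count_nonzero(art >= p_cum) + 1) / (m + 1)), False


def sample_filters(
    jrs: JunctionReadSet,
    genomic_frac_max: float = DEFAULT_ARTIFACT_FRAC,
    homopolymer_max: float = FILTER_HOMOPOLYMER_MAX,
    entropy_min: float = FILTER_ENTROPY_MIN,
) -> dict:
    """The four per-sample junction filters.

    Each is independent evidence of a false positive: a large genomically
    co-aligned fraction, all reads stacked at one alignment offset, long
    homopolymer stretches, or low mean read entropy.  A junction of a single
    read cannot show offset diversity and fails that filter.
    """
    return {
        "genomic_fraction": jrs.frac_genomic < genomic_frac_max,
        "offset_diversity": jrs.n_distinct_offsets >= 2,
        "homopolymer": jrs.mean_longest_run < homopolymer_max,
        "entropy": jrs.mean_entropy > entropy_min,
    }


def score_junctions(
    records: list[SplicedAlignmentRecord],
    p_hats,
    sample_id: str = "sample",
    reps: int = DEFAULT_NULL_REPS,
    boundary: int = DEFAULT_NULL_BOUNDARY,
    artifact_frac: float = DEFAULT_ARTIFACT_FRAC,
    min_artifact_null: int = DEFAULT_MIN_ARTIFACT_NULL,
    homopolymer_max: float = FILTER_HOMOPOLYMER_MAX,
    entropy_min: float = FILTER_ENTROPY_MIN,
    seed: int = 0,
) -> list[JunctionSampleScore]:
    """Full per-sample junction scoring: collapse, aggregate, P_cum, emp_p,
    filters.  Nulls are cached per distinct read count N."""
    junction_sets = collapse_to_junctions(records, p_hats, sample_id)
    pool = np.asarray(p_hats, dtype=float)

    nulls: dict[int, NullModel] = {}
    partial = []
    for jrs in junction_sets:
        n = jrs.N
        if n not in nulls:
            nulls[n] = build_null(pool, n, reps=reps, boundary=boundary, seed=seed)
        p_cum = cumulative_score(jrs.p_hats, nulls[n])
        partial.append((jrs, aggregate_score(jrs.p_hats), p_cum, nulls[n].kind))

    artifact_null = np.array(
        [pc for jrs, _, pc, _ in partial if jrs.frac_genomic >= artifact_frac]
    )
    out = []
    for jrs, P, p_cum, kind in partial:
        emp, fallback = empirical_p(p_cum, artifact_null, min_artifact_null)
        out.append(
            JunctionSampleScore(
                junction=jrs.junction,
                sample_id=sample_id,
                N=jrs.N,
                P=P,
                P_cum=p_cum,
                emp_p=emp,
                frac_genomic=jrs.frac_genomic,
                n_distinct_offsets=jrs.n_distinct_offsets,
                mean_longest_run=jrs.mean_longest_run,
                mean_entropy=jrs.mean_entropy,
                filters_passed=sample_filters(
                    jrs,
                    genomic_frac_max=artifact_frac,
                    homopolymer_max=homopolymer_max,
                    entropy_min=entropy_min,
                ),
                null_kind=kind,
                fallback_flag=fallback,
            )
        )
    return out
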