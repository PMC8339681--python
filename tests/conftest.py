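import re

import numpy as np
import pytest

from splicecall import RunConfig, SimConfig, run_cohort, run_sample, simulate_sample

SAM_HEADER = (
    "@HD\tVN:1.6\tSO:unsorted\n"
    "@SQ\tSN:chr1\tLN:100000\n"
    "@SQ\tSN:chr2\tLN:100000\n"
)


def query_len(cigar: str) -> int:
    return sum(
        int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
        if op in "MIS=X"
    )


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def sam_line(
    qname,
    chrom,
    pos,
    cigar,
    flag=0,
    seq=None,
    nh=1,
    hi=1,
    as_score=None,
    nm=0,
    extra_tags="",
    seq_seed=0,
):
    if seq is None:
        seq = random_seq(query_len(cigar), seed=seq_seed)
    if as_score is None:
        as_score = len(seq) - 2 * nm
    tags = f"NH:i:{nh}\tHI:i:{hi}\tAS:i:{as_score}\tNM:i:{nm}"
    if extra_tags:
        tags += "\t" + extra_tags
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos}\t255\t{cigar}\t*\t0\t0\t"
        f"{seq}\t{'I' * len(seq)}\t{tags}"
    )


@pytest.fixture
def make_sam(tmp_path):
    """Write SAM text (standard two-chromosome header + given lines)."""

    def _write(lines, name="test.sam", header=SAM_HEADER):
        path = tmp_path / name
        path.write_text(header + "\n".join(lines) + "\n")
        return path

    return _write


def run_synthetic_cohort(seed, tmp_path, sample_indices=(0, 1), sim_kwargs=None):
    """Simulate samples under default conditions and run the full pipeline.

    Returns (cohort table, read-level truth of sample 0's junction set)."""
    from splicecall import call_junctions  # noqa: F401  (applied inside run_cohort)

    tmp_path.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=seed, **(sim_kwargs or {}))
    cfg = RunConfig(seed=seed, out_dir=str(tmp_path))
    paths = []
    truth = None
    for i in sample_indices:
        sam_text, tr = simulate_sample(sim, i)
        p = tmp_path / f"sample_{i}.sam"
        p.write_text(sam_text)
        if truth is None:
            truth = tr
        paths.append(run_sample(p, cfg)["junctions_path"])
    table = run_cohort(paths, cfg)
    return table, truth
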