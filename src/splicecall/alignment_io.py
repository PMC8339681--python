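"""Parsing of spliced alignments and per-read sequence/alignment features.

A *junctional read* is a read whose CIGAR contains an ``N`` operator, i.e.
whose alignment spans an intron.  A *genomic alignment* is a contiguous
(N-free) alignment of the same read; its presence marks the junctional
alignment as likely artifactual and defines the negative training class for
the read-level model.

Coordinates are 1-based and inclusive: ``intron_start`` is the first and
``intron_end`` the last intronic base, matching the convention of STAR's
``SJ.out.tab``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S = 0, 1, 2, 3, 4
_CIGAR_EQ, _CIGAR_X = 7, 8
_QUERY_OPS = {_CIGAR_M, _CIGAR_I, _CIGAR_S, _CIGAR_EQ, _CIGAR_X}
_ALIGNED_OPS = {_CIGAR_M, _CIGAR_EQ, _CIGAR_X}
_REF_OPS = {_CIGAR_M, _CIGAR_D, _CIGAR_N, _CIGAR_EQ, _CIGAR_X}

REQUIRED_TAGS = ("NH", "HI", "AS", "NM")


class ParseError(ValueError):
    """Raised for malformed or tag-deficient alignment records."""


@dataclass(frozen=True, eq=False)
class SpliceJunction:
    """An intron: identity is (chrom, intron_start, intron_end); strand is
    annotation only and never part of equality or hashing."""

    chrom: str
    intron_start: int  # 1-based first intronic base
    intron_end: int  # 1-based last intronic base
    strand: str = "unknown"  # "+", "-" or "unknown"

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.intron_start, self.intron_end)

    def __eq__(self, other):
        return isinstance(other, SpliceJunction) and self.key == other.key

    def __hash__(self):
        return hash(self.key)


@dataclass
class SplicedAlignmentRecord:
    """One spliced alignment of one read at one junction, with raw tags."""

    read_id: str
    sample_id: str
    junction: SpliceJunction
    cigar: str
    align_start: int  # 1-based leftmost reference position
    hi: int
    nh: int
    nmm: int  # NM tag: edit distance / mismatches
    as_raw: int  # AS tag: alignment score
    read_length: int
    read_seq: str
    is_reverse: bool
    has_genomic_alignment: bool = False
    mate: str = "unpaired"  # "R1", "R2" or "unpaired"
    cell_barcode: Optional[str] = None
    umi: Optional[str] = None

    @property
    def align_start_offset(self) -> int:
        """Junction-relative alignment start: intron_start - align_start."""
        return self.junction.intron_start - self.align_start

    @property
    def key(self) -> str:
        """Read identity used for the genomic-alignment lookup."""
        return _read_key(self.read_id, self.mate)


@dataclass
class ReadFeatureVector:
    """Predictors of the read-level logistic model.

    ``as_norm`` is AS divided by read length; ``overlap``/``max_overlap`` are
    the shorter/longer aligned overhang flanking the junction in read bases;
    ``softclip_s`` totals the CIGAR S segments; ``entropy`` is the 5-mer
    Shannon entropy of the read sequence in nats.  Paired mode carries the
    mate's copies plus two fragment-compatibility indicators.
    """

    as_norm: float
    nh: int
    nmm: int
    overlap: int
    max_overlap: int
    softclip_s: int
    entropy: float
    mate_as_norm: float = 0.0
    mate_nh: int = 0
    mate_nmm: int = 0
    mate_overlap: int = 0
    mate_max_overlap: int = 0
    mate_softclip_s: int = 0
    mate_entropy: float = 0.0
    location_compatible: int = 0
    strand_compatible: int = 0

    SINGLE_FIELDS = (
        "as_norm", "nh", "nmm", "overlap", "max_overlap", "softclip_s", "entropy",
    )
    PAIRED_EXTRA_FIELDS = (
        "mate_as_norm", "mate_nh", "mate_nmm", "mate_overlap",
        "mate_max_overlap", "mate_softclip_s", "mate_entropy",
        "location_compatible", "strand_compatible",
    )

    def as_row(self, mode: str) -> list:
        names = self.SINGLE_FIELDS if mode == "single" else (
            self.SINGLE_FIELDS + self.PAIRED_EXTRA_FIELDS
        )
        return [getattr(self, n) for n in names]


@dataclass
class KmerProfile:
    """Overlapping k-mer composition of a sequence."""

    k: int
    counts: Counter = field(default_factory=Counter)

    @property
    def n_positions(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)


@dataclass
class ContiguousMateSummary:
    """Features of a contiguous (N-free) mate alignment, for paired mode."""

    as_norm: float
    nh: int
    nmm: int
    softclip_s: int
    entropy: float
    chrom: str
    align_start: int
    is_reverse: bool
    mate: str


def _read_key(read_id: str, mate: str) -> str:
    return read_id if mate == "unpaired" else f"{read_id}/{mate}"


def kmer_profile(seq: str, k: int = 5) -> KmerProfile:
    """Count the overlapping k-mers of ``seq`` left to right."""
    if len(seq) < k:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than minimum length k={k}"
        )
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    return KmerProfile(k=k, counts=counts)


def read_entropy(seq: str, k: int = 5) -> float:
    """Shannon entropy (nats) of the overlapping k-mer composition.

    Frequencies are counts divided by the total number of overlapping k-mer
    positions, so they sum to one.  Low values flag repetitive, artifact-prone
    sequence (PCR stutter and multi-mapping repeats); a read with all k-mers
    distinct attains the maximum ln(L - k + 1).
    """
    prof = kmer_profile(seq, k)
    n_pos = prof.n_positions
    return -sum(
        (c / n_pos) * math.log(c / n_pos) for c in prof.counts.values()
    )


def longest_base_run(seq: str) -> int:
    """Length of the longest maximal run of one repeated base."""
    if not seq:
        raise ValueError("empty sequence")
    best = cur = 1
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def _query_length_from_cigar(cigartuples) -> int:
    return sum(ln for op, ln in cigartuples if op in _QUERY_OPS)


def _junctions_from_alignment(aln, chrom: str) -> list[SpliceJunction]:
    """One junction per N operator, walking reference coordinates."""
    out = []
    ref = aln.reference_start  # 0-based
    strand = "unknown"
    try:
        xs = aln.get_tag("XS")
        if xs in ("+", "-"):
            strand = xs
    except KeyError:
        pass
    for op, ln in aln.cigartuples:
        if op == _CIGAR_N:
            out.append(
                SpliceJunction(chrom, ref + 1, ref + ln, strand)
            )
        if op in _REF_OPS:
            ref += ln
    return out


def _get_required_tags(aln) -> dict:
    tags = {}
    for t in REQUIRED_TAGS:
        try:
            tags[t] = aln.get_tag(t)
        except KeyError:
            raise ParseError(
                f"read {aln.query_name!r}: required tag {t} missing"
            ) from None
    return tags


def _mate_of(aln) -> str:
    if not aln.is_paired:
        return "unpaired"
    return "R1" if aln.is_read1 else "R2"


def parse_spliced_alignments(
    path_or_stream,
    mode: str = "single",
    sample_id: str = "sample",
) -> tuple[list[SplicedAlignmentRecord], set[str]]:
    """Extract spliced-alignment records and the genomic-alignment read set.

    Every non-chimeric alignment line with an ``N`` in its CIGAR is a spliced
    alignment; when a read has several spliced alignments only the one with
    the lowest HI tag is retained, and each N operator of the retained
    alignment yields one record.  Reads with any non-chimeric N-free
    alignment (primary or secondary) form the genomic set, and
    ``has_genomic_alignment`` is set accordingly on every record.

    Supplementary/chimeric lines and unmapped reads are ignored entirely.
    Missing NH/HI/AS/NM tags raise :class:`ParseError`.

    Returns ``(records, genomic_keys)`` where keys are ``read_id`` in single
    mode and ``read_id/R1`` or ``read_id/R2`` in paired mode.
    """
    if mode not in ("single", "paired"):
        raise ValueError(f"mode must be 'single' or 'paired', got {mode!r}")

    spliced: dict[str, tuple] = {}  # key -> (hi, aln-derived payload)
    genomic: set[str] = set()
    mate_summaries: dict[str, ContiguousMateSummary] = {}

    with pysam.AlignmentFile(str(path_or_stream), "r", check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.is_supplementary:
                continue
            if aln.cigartuples is None:
                continue
            mate = _mate_of(aln)
            key = _read_key(aln.query_name, mate)
            has_n = any(op == _CIGAR_N for op, _ in aln.cigartuples)
            if not has_n:
                genomic.add(key)
                if mode == "paired" and key not in mate_summaries:
                    tags = _get_required_tags(aln)
                    seq = aln.query_sequence or ""
                    qlen = _query_length_from_cigar(aln.cigartuples)
                    mate_summaries[key] = ContiguousMateSummary(
                        as_norm=tags["AS"] / qlen if qlen else 0.0,
                        nh=tags["NH"],
                        nmm=tags["NM"],
                        softclip_s=sum(
                            ln for op, ln in aln.cigartuples if op == _CIGAR_S
                        ),
                        entropy=read_entropy(seq) if len(seq) >= 5 else 0.0,
                        chrom=aln.reference_name,
                        align_start=aln.reference_start + 1,
                        is_reverse=aln.is_reverse,
                        mate=mate,
                    )
                continue
            tags = _get_required_tags(aln)
            seq = aln.query_sequence
            if seq is None:
                raise ParseError(f"read {aln.query_name!r}: missing sequence")
            qlen = _query_length_from_cigar(aln.cigartuples)
            if len(seq) != qlen:
                raise ParseError(
                    f"read {aln.query_name!r}: CIGAR implies {qlen} read "
                    f"bases but sequence has {len(seq)}"
                )
            payload = (aln, tags, seq, qlen, mate)
            prev = spliced.get(key)
            if prev is None or tags["HI"] < prev[0]:
                spliced[key] = (tags["HI"], payload)

    records: list[SplicedAlignmentRecord] = []
    for key, (_, (aln, tags, seq, qlen, mate)) in spliced.items():
        cb = None
        umi = None
        for cb_tag in ("CB", "CR"):
            if aln.has_tag(cb_tag):
                cb = aln.get_tag(cb_tag)
                break
        for umi_tag in ("UB", "UR"):
            if aln.has_tag(umi_tag):
                umi = aln.get_tag(umi_tag)
                break
        for junc in _junctions_from_alignment(aln, aln.reference_name):
            records.append(
                SplicedAlignmentRecord(
                    read_id=aln.query_name,
                    sample_id=sample_id,
                    junction=junc,
                    cigar=aln.cigarstring,
                    align_start=aln.reference_start + 1,
                    hi=tags["HI"],
                    nh=tags["NH"],
                    nmm=tags["NM"],
                    as_raw=tags["AS"],
                    read_length=qlen,
                    read_seq=seq,
                    is_reverse=aln.is_reverse,
                    has_genomic_alignment=key in genomic,
                    mate=mate,
                    cell_barcode=cb,
                    umi=umi,
                )
            )
    records.sort(key=lambda r: (r.junction.key, r.read_id, r.mate))
    if mode == "paired":
        return records, genomic, mate_summaries  # type: ignore[return-value]
    return records, genomic


def _overhangs(cigar: str, junction_index: int) -> tuple[int, int]:
    """Aligned read bases (M/=/X) on each side of the ``junction_index``-th N,
    bounded by the read ends and adjacent N operators."""
    ops = _parse_cigar(cigar)
    n_positions = [i for i, (op, _) in enumerate(ops) if op == "N"]
    if junction_index >= len(n_positions):
        raise ValueError(
            f"CIGAR {cigar} has no junction index {junction_index}"
        )
    at = n_positions[junction_index]
    left = right = 0
    for op, ln in reversed(ops[:at]):
        if op == "N":
            break
        if op in "M=X":
            left += ln
    for op, ln in ops[at + 1 :]:
        if op == "N":
            break
        if op in "M=X":
            right += ln
    return left, right


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _junction_index(record: SplicedAlignmentRecord) -> int:
    """Which N operator of the record's CIGAR its junction corresponds to."""
    ops = _parse_cigar(record.cigar)
    ref = record.align_start  # 1-based; next reference base to consume
    idx = 0
    for op, ln in ops:
        if op == "N":
            if ref == record.junction.intron_start:
                return idx
            idx += 1
        if op in "MDN=X":
            ref += ln
    raise ValueError(
        f"junction {record.junction.key} not present in CIGAR "
        f"{record.cigar} at {record.align_start}"
    )


def extract_features(
    record: SplicedAlignmentRecord,
    mate_record: Optional[object] = None,
    max_fragment_span: int = 1_000_000,
) -> ReadFeatureVector:
    """Compute the model predictors for one spliced record.

    ``mate_record`` may be another :class:`SplicedAlignmentRecord`, a
    :class:`ContiguousMateSummary`, or ``None`` (missing mate: mate features
    imputed as zeros, compatibility flags 0).  ``strand_compatible`` is 1 iff
    R1 maps forward and R2 reverse on the same reference;
    ``location_compatible`` additionally requires the leftmost-position gap
    to be at most ``max_fragment_span``.
    """
    ov_left, ov_right = _overhangs(record.cigar, _junction_index(record))
    if ov_left < 1 or ov_right < 1:
        raise ValueError(
            f"read {record.read_id}: junction with empty overhang in "
            f"CIGAR {record.cigar}"
        )
    softclip = sum(ln for op, ln in _parse_cigar(record.cigar) if op == "S")
    fv = ReadFeatureVector(
        as_norm=record.as_raw / record.read_length,
        nh=record.nh,
        nmm=record.nmm,
        overlap=min(ov_left, ov_right),
        max_overlap=max(ov_left, ov_right),
        softclip_s=softclip,
        entropy=read_entropy(record.read_seq),
    )
    if mate_record is None:
        return fv

    if isinstance(mate_record, SplicedAlignmentRecord):
        m_left, m_right = _overhangs(
            mate_record.cigar, _junction_index(mate_record)
        )
        fv.mate_overlap = min(m_left, m_right)
        fv.mate_max_overlap = max(m_left, m_right)
        fv.mate_as_norm = mate_record.as_raw / mate_record.read_length
        fv.mate_nh = mate_record.nh
        fv.mate_nmm = mate_record.nmm
        fv.mate_softclip_s = sum(
            ln for op, ln in _parse_cigar(mate_record.cigar) if op == "S"
        )
        fv.mate_entropy = read_entropy(mate_record.read_seq)
        m_chrom = mate_record.junction.chrom
        m_start = mate_record.align_start
        m_rev = mate_record.is_reverse
    else:  # ContiguousMateSummary
        fv.mate_as_norm = mate_record.as_norm
        fv.mate_nh = mate_record.nh
        fv.mate_nmm = mate_record.nmm
        fv.mate_softclip_s = mate_record.softclip_s
        fv.mate_entropy = mate_record.entropy
        m_chrom = mate_record.chrom
        m_start = mate_record.align_start
        m_rev = mate_record.is_reverse

    if record.mate == "R1":
        r1_rev, r2_rev = record.is_reverse, m_rev
    else:
        r1_rev, r2_rev = m_rev, record.is_reverse
    same_ref = m_chrom == record.junction.chrom
    fv.strand_compatible = int(same_ref and (not r1_rev) and r2_rev)
    fv.location_compatible = int(
        same_ref
        and fv.strand_compatible == 1
        and abs(m_start - record.align_start) <= max_fragment_span
    )
    return fv


def features_for_records(
    records: Iterable[SplicedAlignmentRecord],
    mode: str = "single",
    mate_lookup: Optional[dict] = None,
) -> list[ReadFeatureVector]:
    """Vector of feature vectors, one per record, in input order."""
    out = []
    by_key = {}
    if mode == "paired":
        for r in records:
            by_key.setdefault(r.key, r)
    for r in records:
        mate = None
        if mode == "paired":
            other = "R2" if r.mate == "R1" else "R1"
            mk = _read_key(r.read_id, other)
            mate = by_key.get(mk)
            if mate is None and mate_lookup:
                mate = mate_lookup.get(mk)
        out.append(extract_features(r, mate))
    return out
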