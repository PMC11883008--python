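"""Read QC filtering and a k-mer seed-and-extend ungapped short-read mapper.

Ancient-DNA fragments are short and the downstream thresholds (<= 10
mismatches, >= 95% identity) make gapped alignment unnecessary, so the
mapper is deliberately exhaustive-verifiable: a hit is any ungapped placement
of the full read, on either strand, that shares at least one exact k-mer with
the reference and satisfies both thresholds.  On small instances its output
equals a brute-force scan over every offset and strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import defaultdict

import numpy as np

PHRED_OFFSET = 33

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True)
class ReadRecord:
    """A sequenced fragment with qualities.  ``mate`` is 1/2 for paired data, 0 for single-end."""

    id: str
    sequence: str
    qualities: str
    sample_id: str = ""
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode(), dtype=np.uint8) - PHRED_OFFSET


@dataclass(slots=True)
class AlignmentHit:
    """One ungapped placement of a read on a reference (0-based half-open)."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    mismatches: int  # N counts as mismatch
    identity: float  # matches / read length
    mapq: int | None = None
    mate: int = 0

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def key(self) -> tuple:
        """Placement key used for duplicate removal."""
        return (self.ref_id, self.ref_start, self.ref_end, self.strand, self.mate)


def filter_reads(
    reads: list[ReadRecord],
    min_len: int = 30,
    qual_thresh: int = 20,
    max_unqualified_frac: float = 0.4,
    max_n: int = 3,
) -> list[ReadRecord]:
    """Quality filtering with fastp-style thresholds.

    Keeps reads with length >= ``min_len``, at most ``max_n`` N bases, and a
    fraction of bases below ``qual_thresh`` no greater than
    ``max_unqualified_frac``.  Order is preserved; the filter is idempotent.
    """
    out = []
    for r in reads:
        if len(r) < min_len:
            continue
        if r.sequence.count("N") > max_n:
            continue
        if len(r) and np.mean(r.phred < qual_thresh) > max_unqualified_frac:
            continue
        out.append(r)
    return out


# packed candidate encoding: value = (ref_idx << _SHIFT) | (pos + _POS_OFFSET),
# so subtracting the seed offset within the read stays inside the ref block
_SHIFT = 28
_POS_OFFSET = 1 << 26
_POS_MASK = (1 << _SHIFT) - 1


class KmerIndex:
    """Exact k-mer index over the forward strand of a reference panel.

    Both read orientations are queried at mapping time, which is equivalent
    to indexing both reference strands.
    """

    def __init__(self, refs: dict[str, str], k: int = 13):
        if k < 8:
            raise ValueError("k must be >= 8")
        for rid, seq in refs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"reference {rid} contains non-ACGT characters")
        self.k = k
        self.ref_ids: list[str] = list(refs.keys())
        self.ref_seqs: list[str] = [refs[r] for r in self.ref_ids]
        self.ref_arrays: list[np.ndarray] = [
            np.frombuffer(s.encode(), dtype=np.uint8) for s in self.ref_seqs
        ]
        table: dict[str, list[int]] = defaultdict(list)
        for ridx, seq in enumerate(self.ref_seqs):
            if len(seq) < k:
                warnings.warn(
                    f"reference {self.ref_ids[ridx]} shorter than k={k}: unmappable",
                    stacklevel=2,
                )
                continue
            base = (ridx << _SHIFT) + _POS_OFFSET
            for p in range(len(seq) - k + 1):
                table[seq[p : p + k]].append(base + p)
        self._table: dict[str, np.ndarray] = {
            kmer: np.asarray(v, dtype=np.int64) for kmer, v in table.items()
        }

    def lookup(self, kmer: str) -> np.ndarray | None:
        return self._table.get(kmer)


def _max_mismatch_budget(length: int, max_mismatches: int, min_identity: float) -> int:
    # integer-safe combination of the mismatch cap and the identity floor
    return min(max_mismatches, int(np.floor(length * (1.0 - min_identity) + 1e-9)))


def map_reads(
    reads: list[ReadRecord],
    index: KmerIndex,
    max_mismatches: int = 10,
    min_identity: float = 0.95,
) -> list[AlignmentHit]:
    """Seed-and-extend ungapped mapping of full-length reads, both strands.

    Every candidate diagonal with at least one exact k-mer seed is extended
    across the whole read; hits violating the mismatch or identity threshold
    are discarded.  Hits are reported per read, best (fewest mismatches)
    first.  Reads shorter than k yield no hits.
    """
    k = index.k
    hits: list[AlignmentHit] = []
    ref_lens = [len(a) for a in index.ref_arrays]
    for read in reads:
        L = len(read)
        if L < k:
            continue
        budget = _max_mismatch_budget(L, max_mismatches, min_identity)
        read_hits: list[AlignmentHit] = []
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            chunks = []
            lookup = index.lookup
            for p in range(L - k + 1):
                arr = lookup(seq[p : p + k])
                if arr is not None:
                    chunks.append(arr - p)
            if not chunks:
                continue
            cands = np.unique(np.concatenate(chunks)) if len(chunks) > 1 else np.unique(chunks[0])
            arr_read = np.frombuffer(seq.encode(), dtype=np.uint8)
            for v in cands.tolist():
                ridx = v >> _SHIFT
                start = (v & _POS_MASK) - _POS_OFFSET
                if start < 0 or start + L > ref_lens[ridx]:
                    continue
                mism = int(
                    np.count_nonzero(index.ref_arrays[ridx][start : start + L] != arr_read)
                )
                if mism <= budget:
                    read_hits.append(
                        AlignmentHit(
                            read_id=read.id,
                            ref_id=index.ref_ids[ridx],
                            ref_start=start,
                            ref_end=start + L,
                            strand=strand,
                            mismatches=mism,
                            identity=(L - mism) / L,
                            mate=read.mate,
                        )
                    )
        read_hits.sort(key=lambda h: h.mismatches)
        hits.extend(read_hits)
    return hits


def assign_mapq(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Assign a mapping-quality proxy per read from hit-count and margin.

    Unique hit -> 60; best beats second-best by >= 2 mismatches -> 37; by
    1 -> 25; tied best -> 0 for all tied.  Suboptimal placements get 0.
    This proxy is NOT BWA's formula; downstream thresholds (>= 25 for
    mitogenome profiling, >= 20 for diversity) apply to it as stated.
    """
    grouped: dict[tuple[str, int], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.read_id, h.mate)].append(h)
    for group in grouped.values():
        group.sort(key=lambda h: h.mismatches)
        if len(group) == 1:
            group[0].mapq = 60
            continue
        best, second = group[0].mismatches, group[1].mismatches
        margin = second - best
        for h in group:
            h.mapq = 0
        if margin >= 2:
            group[0].mapq = 37
        elif margin == 1:
            group[0].mapq = 25
        # margin 0: all tied best stay 0
    return hits


def dedupe(hits: list[AlignmentHit], reads: dict[tuple[str, int], ReadRecord]) -> list[AlignmentHit]:
    """Duplicate removal: among hits sharing a placement, keep the read with
    the highest summed base quality (stable tie-break by read id)."""
    best: dict[tuple, AlignmentHit] = {}
    score: dict[tuple, tuple] = {}
    for h in hits:
        read = reads[(h.read_id, h.mate)]
        qsum = int(read.phred.sum())
        key = h.key()
        # maximize quality; among ties prefer the lexicographically smallest id
        rank = (qsum, _Neg(h.read_id))
        if key not in best or rank > score[key]:
            best[key] = h
            score[key] = rank
    keep = set(id(h) for h in best.values())
    return [h for h in hits if id(h) in keep]


class _Neg:
    """Reverses string ordering so max() on (qual, _Neg(id)) prefers small ids."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_Neg") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_Neg") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Neg) and self.s == other.s


def pair_filter(hits: list[AlignmentHit], max_insert: int = 1000) -> list[AlignmentHit]:
    """Keep paired hits only when both mates hit the same reference with a
    plausible insert; single-end hits pass through unchanged."""
    by_read: dict[str, dict[int, list[AlignmentHit]]] = defaultdict(lambda: defaultdict(list))
    for h in hits:
        by_read[h.read_id][h.mate].append(h)
    out: list[AlignmentHit] = []
    for h in hits:
        if h.mate == 0:
            out.append(h)
            continue
        other = 1 if h.mate == 2 else 2
        mates = by_read[h.read_id].get(other, ())
        ok = any(
            m.ref_id == h.ref_id
            and max(m.ref_end, h.ref_end) - min(m.ref_start, h.ref_start) <= max_insert
            for m in mates
        )
        if ok:
            out.append(h)
    return out


def write_hits_tsv(hits: list[AlignmentHit], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "mate": h.mate,
                "ref_id": h.ref_id,
                "ref_start": h.ref_start,
                "ref_end": h.ref_end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "identity": h.identity,
                "mapq": -1 if h.mapq is None else h.mapq,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[AlignmentHit]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentHit(
            read_id=str(r.read_id),
            ref_id=str(r.ref_id),
            ref_start=int(r.ref_start),
            ref_end=int(r.ref_end),
            strand=str(r.strand),
            mismatches=int(r.mismatches),
            identity=float(r.identity),
            mapq=None if int(r.mapq) < 0 else int(r.mapq),
            mate=int(r.mate),
        )
        for r in df.itertuples()
    ]


def write_sam(
    hits: list[AlignmentHit],
    reads: dict[tuple[str, int], ReadRecord],
    refs: dict[str, str],
    path,
) -> None:
    """Export hits as SAM (1-based POS, NM tag) via pysam."""
    import pysam

    ref_ids = list(refs.keys())
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rid, "LN": len(refs[rid])} for rid in ref_ids],
    }
    tid = {rid: i for i, rid in enumerate(ref_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            read = reads[(h.read_id, h.mate)]
            a = pysam.AlignedSegment(out.header)
            a.query_name = h.read_id
            a.reference_id = tid[h.ref_id]
            a.reference_start = h.ref_start
            a.mapping_quality = 255 if h.mapq is None else h.mapq
            a.cigartuples = [(0, len(read))]
            a.flag = 16 if h.strand == "-" else 0
            seq = read.sequence if h.strand == "+" else revcomp(read.sequence)
            qual = read.qualities if h.strand == "+" else read.qualities[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            a.set_tag("NM", h.mismatches)
            out.write(a)
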