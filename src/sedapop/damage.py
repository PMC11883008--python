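"""Position-dependent misincorporation profiling and fragment-length statistics.

Post-mortem cytosine deamination leaves a characteristic excess of C->T
substitutions at the 5' ends of ancient reads (and, for double-stranded
library chemistry, the mirrored G->A excess at 3' ends), decaying with
distance from the fragment terminus.  This module tabulates full substitution
tables per read position, in read orientation, pooled across references, and
extracts the terminal rates used as a damage / authenticity metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .readmap import AlignmentHit, ReadRecord, revcomp

_IDX = {b: i for i, b in enumerate("ACGTN")}
_CODE5 = np.full(256, 4, dtype=np.int64)  # anything unexpected counts as N
for _b, _i in _IDX.items():
    _CODE5[ord(_b)] = _i

A, C, G, T, N = range(5)


@dataclass
class DamageProfile:
    """Substitution counts for positions 1..P from each read end.

    ``counts5[r, b, i]``: number of aligned bases at 5' position i (0-based)
    with reference base r and read base b; ``counts3`` is indexed by distance
    from the 3' end.  Rates with a zero denominator are NaN (undefined).
    """

    sample_id: str
    P: int
    counts5: np.ndarray  # (5, 5, P) ref x read x position
    counts3: np.ndarray
    n_alignments: int = 0

    def _rate(self, counts: np.ndarray, ref: int, read: int) -> np.ndarray:
        denom = counts[ref].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts[ref, read] / denom, np.nan)

    @property
    def ct_rate(self) -> np.ndarray:
        """5' C->T rate per position (index 0 = terminal position 1)."""
        return self._rate(self.counts5, C, T)

    @property
    def ga_rate(self) -> np.ndarray:
        """3' G->A rate per distance from the 3' end."""
        return self._rate(self.counts3, G, A)

    def denominator5(self, ref_base: str) -> np.ndarray:
        return self.counts5[_IDX[ref_base]].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for end, counts in (("5p", self.counts5), ("3p", self.counts3)):
            for r, rb in enumerate("ACGT"):
                denom = counts[r].sum(axis=0)
                for b, qb in enumerate("ACGTN"):
                    for i in range(self.P):
                        if denom[i] == 0 and counts[r, b, i] == 0:
                            continue
                        rows.append(
                            {
                                "end": end,
                                "position": i + 1,
                                "ref_base": rb,
                                "read_base": qb,
                                "count": int(counts[r, b, i]),
                                "denominator": int(denom[i]),
                                "rate": counts[r, b, i] / denom[i] if denom[i] else np.nan,
                            }
                        )
        return pd.DataFrame(rows)


def misincorporation_profile(
    hits: list[AlignmentHit],
    reads: dict[tuple[str, int], ReadRecord],
    refs: dict[str, str],
    P: int = 25,
    sample_id: str = "",
) -> DamageProfile:
    """Tabulate substitutions by position from each read end.

    Counts are accumulated in read orientation: for reverse-strand hits the
    reference slice is reverse-complemented so position 1 is always the 5'
    terminal base as sequenced.  Counts are pooled across references.
    """
    if not hits:
        raise ValueError("no alignments for profile")
    counts5 = np.zeros((5, 5, P), dtype=np.int64)
    counts3 = np.zeros((5, 5, P), dtype=np.int64)
    for h in hits:
        read = reads[(h.read_id, h.mate)]
        ref_slice = refs[h.ref_id][h.ref_start : h.ref_end]
        if h.strand == "-":
            ref_slice = revcomp(ref_slice)
        L = len(read)
        rc = _CODE5[np.frombuffer(ref_slice.encode(), dtype=np.uint8)]
        qc = _CODE5[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
        m = min(P, L)
        np.add.at(counts5, (rc[:m], qc[:m], np.arange(m)), 1)
        np.add.at(counts3, (rc[::-1][:m], qc[::-1][:m], np.arange(m)), 1)
    return DamageProfile(
        sample_id=sample_id, P=P, counts5=counts5, counts3=counts3, n_alignments=len(hits)
    )


def terminal_rates(profile: DamageProfile) -> tuple[float, float]:
    """5' C->T rates at positions 1 and 2 (the damage metrics reported
    per sample; position 2 can exceed position 1 as a library artefact)."""
    r = profile.ct_rate
    return float(r[0]), float(r[1])


def group_terminal_means(profiles: list[DamageProfile]) -> tuple[float, float]:
    """Group means of the position-1 and position-2 terminal rates."""
    if not profiles:
        raise ValueError("empty group")
    r1 = [terminal_rates(p)[0] for p in profiles]
    r2 = [terminal_rates(p)[1] for p in profiles]
    return float(np.mean(r1)), float(np.mean(r2))


@dataclass
class FragmentLengthStats:
    """Per-group read-length histograms with summary statistics."""

    histograms: dict[str, Counter] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for group, hist in self.histograms.items():
            lengths = np.repeat(
                np.fromiter(hist.keys(), dtype=int), np.fromiter(hist.values(), dtype=int)
            )
            rows.append(
                {
                    "group": group,
                    "n": int(lengths.size),
                    "mean": float(lengths.mean()),
                    "median": float(np.median(lengths)),
                }
            )
        return pd.DataFrame(rows)

    @property
    def n(self) -> int:
        return sum(sum(h.values()) for h in self.histograms.values())


def fragment_lengths(
    reads: list[ReadRecord],
    group_of: dict[str, str] | None = None,
) -> FragmentLengthStats:
    """Length distribution of (mapped) reads, grouped by sample or a caller
    supplied sample -> group mapping (e.g. colony-age class)."""
    stats = FragmentLengthStats()
    for r in reads:
        group = (group_of or {}).get(r.sample_id, r.sample_id)
        stats.histograms.setdefault(group, Counter())[len(r)] += 1
    return stats
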