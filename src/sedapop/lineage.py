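"""PLCA mitochondrial control-region lineage assignment for read pairs.

Adelie penguin mitochondrial control-region haplotypes fall into two clades:
the widespread Antarctic (A) lineage and the Ross Sea (RS) lineage.  Short
ancient read pairs cannot be phased into haplotypes, so each pair is voted
against a balanced labelled haplotype database: hits are filtered by
identity, one best hit is kept per reference, pairs touching fewer than a
minimum number of distinct references are left unassigned, and a strict
majority (> 70% of reference votes) decides the lineage; otherwise the pair
is undetermined.  Per-sample lineage proportions are computed over assigned
pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .readmap import AlignmentHit, ReadRecord, KmerIndex, map_reads
from .simdata import LineageReference


@dataclass
class LineageDB:
    """Balanced, nonredundant labelled control-region haplotype panel."""

    references: list[LineageReference]
    seed: int | None = None

    @property
    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = defaultdict(int)
        for r in self.references:
            sizes[r.lineage_label] += 1
        return dict(sizes)

    @property
    def label_of(self) -> dict[str, str]:
        return {r.id: r.lineage_label for r in self.references}

    @property
    def sequences(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.references}


@dataclass
class LineageCall:
    """Vote outcome for one read pair."""

    read_pair_id: str
    n_hits_a: int
    n_hits_rs: int
    n_unique_refs: int
    call: str  # "A", "RS", "undetermined", "unassigned"
    vote_fraction: float


def build_lineage_db(labeled_seqs: list[LineageReference], seed: int) -> LineageDB:
    """Deduplicate and balance a labelled haplotype panel.

    Exact duplicate sequences are removed (first occurrence kept), then the
    larger class is down-sampled without replacement (seeded) to the size of
    the smaller class, mirroring the balancing of a control-region database
    to equal clade sizes.
    """
    seen: set[str] = set()
    nonredundant: list[LineageReference] = []
    for r in labeled_seqs:
        if r.sequence not in seen:
            seen.add(r.sequence)
            nonredundant.append(r)
    by_label: dict[str, list[LineageReference]] = defaultdict(list)
    for r in nonredundant:
        by_label[r.lineage_label].append(r)
    for label in ("A", "RS"):
        if not by_label.get(label):
            raise ValueError(f"no sequences for lineage label {label!r}")
    n_min = min(len(v) for v in by_label.values())
    rng = np.random.default_rng(seed)
    kept: list[LineageReference] = []
    for label in ("A", "RS"):
        members = by_label[label]
        if len(members) > n_min:
            idx = np.sort(rng.choice(len(members), size=n_min, replace=False))
            members = [members[i] for i in idx]
        kept.extend(members)
    return LineageDB(references=kept, seed=seed)


def plca_call(
    read_pair_id: str,
    hits: list[AlignmentHit],
    label_of: dict[str, str],
    min_identity: float = 0.95,
    min_unique_refs: int = 3,
    vote_threshold: float = 0.70,
) -> LineageCall:
    """Vote one read pair into a lineage from its database hits.

    Hits from both mates are pooled and reduced to one best hit per
    reference (highest identity, then fewest mismatches), so a reference is
    counted once regardless of multiple placements.  The call is invariant
    to hit order and mate labelling, and the majority rule is strict:
    exactly 70% is undetermined.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.ref_id)
        if cur is None or (h.identity, -h.mismatches) > (cur.identity, -cur.mismatches):
            best[h.ref_id] = h
    survivors = [h for h in best.values() if h.identity >= min_identity - 1e-12]
    n_refs = len({h.ref_id for h in survivors})
    n_a = sum(1 for h in survivors if label_of[h.ref_id] == "A")
    n_rs = sum(1 for h in survivors if label_of[h.ref_id] == "RS")
    if n_refs < min_unique_refs:
        return LineageCall(read_pair_id, n_a, n_rs, n_refs, "unassigned", 0.0)
    total = n_a + n_rs
    frac = max(n_a, n_rs) / total
    if n_a / total > vote_threshold:
        call = "A"
    elif n_rs / total > vote_threshold:
        call = "RS"
    else:
        call = "undetermined"
    return LineageCall(read_pair_id, n_a, n_rs, n_refs, call, frac)


def assign_read_pairs(
    reads: list[ReadRecord],
    db: LineageDB,
    k: int = 13,
    min_identity: float = 0.95,
    min_unique_refs: int = 3,
    vote_threshold: float = 0.70,
    max_mismatches: int = 10,
) -> list[LineageCall]:
    """Map reads against the lineage database and vote every read (pair).

    Mates sharing a read id are pooled into one pair.  Reads with no hits at
    all are reported as unassigned so callers can account for every input.
    """
    index = KmerIndex(db.sequences, k=k)
    hits = map_reads(reads, index, max_mismatches=max_mismatches, min_identity=min_identity)
    by_pair: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_pair[h.read_id].append(h)
    label_of = db.label_of
    calls = []
    seen_ids = set()
    for r in reads:
        if r.id in seen_ids:
            continue
        seen_ids.add(r.id)
        calls.append(
            plca_call(
                r.id,
                by_pair.get(r.id, []),
                label_of,
                min_identity=min_identity,
                min_unique_refs=min_unique_refs,
                vote_threshold=vote_threshold,
            )
        )
    return calls


def lineage_proportions(calls_by_sample: dict[str, list[LineageCall]]) -> pd.DataFrame:
    """Per-sample lineage proportions over assigned pairs.

    prop_A = n_A / (n_A + n_RS); undetermined and unassigned pairs are
    excluded from the denominator but reported.  Samples with no assigned
    pairs get NaN proportions.
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        n_a = sum(1 for c in calls if c.call == "A")
        n_rs = sum(1 for c in calls if c.call == "RS")
        n_und = sum(1 for c in calls if c.call == "undetermined")
        n_un = sum(1 for c in calls if c.call == "unassigned")
        assigned = n_a + n_rs
        rows.append(
            {
                "sample_id": sample,
                "n_a": n_a,
                "n_rs": n_rs,
                "n_assigned": assigned,
                "n_undetermined": n_und,
                "n_unassigned": n_un,
                "prop_a": n_a / assigned if assigned else np.nan,
                "prop_rs": n_rs / assigned if assigned else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def calls_to_frame(calls: list[LineageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_pair_id": c.read_pair_id,
                "n_hits_a": c.n_hits_a,
                "n_hits_rs": c.n_hits_rs,
                "n_unique_refs": c.n_unique_refs,
                "call": c.call,
                "vote_fraction": c.vote_fraction,
            }
            for c in calls
        ]
    )
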