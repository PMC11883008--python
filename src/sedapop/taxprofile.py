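"""Per-read LCA taxonomic assignment, control-based decontamination, grouping.

Each read's surviving alignments (within the mismatch/identity window) are
reduced to the lowest common ancestor of the taxa they hit, yielding a
conservative per-read assignment.  Sample x taxon count matrices are then
decontaminated against extraction-negative controls with read-count
thresholds, normalised by per-sample totals (pseudo total-sum scaling), and
rolled up into higher taxonomic groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .readmap import AlignmentHit


class TaxonomyTree:
    """A rooted taxonomy: node_id -> (parent_id, rank, name).

    The root has itself (or empty/None) as parent.  The structure is
    validated to be a single-rooted, acyclic in-tree.
    """

    def __init__(self, nodes: dict[str, tuple[str | None, str, str]]):
        self.nodes = dict(nodes)
        roots = [
            n for n, (p, _, _) in self.nodes.items() if p is None or p == "" or p == n
        ]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for node, (parent, _, _) in self.nodes.items():
            if node != self.root and parent not in self.nodes:
                raise ValueError(f"node {node!r} has unknown parent {parent!r}")
        self._paths: dict[str, tuple[str, ...]] = {}
        for node in self.nodes:
            self.path_to_root(node)  # also detects cycles

    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    def parent(self, node: str) -> str | None:
        p = self.nodes[node][0]
        return None if node == self.root else p

    def rank(self, node: str) -> str:
        return self.nodes[node][1]

    def name(self, node: str) -> str:
        return self.nodes[node][2]

    def path_to_root(self, node: str) -> tuple[str, ...]:
        """Path root -> ... -> node (root first)."""
        if node in self._paths:
            return self._paths[node]
        path = [node]
        seen = {node}
        cur = node
        while cur != self.root:
            cur = self.nodes[cur][0]
            if cur in seen:
                raise ValueError(f"taxonomy contains a cycle through {node!r}")
            seen.add(cur)
            path.append(cur)
        result = tuple(reversed(path))
        self._paths[node] = result
        return result

    def lca(self, nodes: list[str]) -> str:
        """Lowest common ancestor by longest shared root-path prefix."""
        if not nodes:
            raise ValueError("lca of empty node set")
        paths = [self.path_to_root(n) for n in set(nodes)]
        shortest = min(len(p) for p in paths)
        anc = self.root
        for depth in range(shortest):
            level = {p[depth] for p in paths}
            if len(level) != 1:
                break
            anc = level.pop()
        return anc

    def is_ancestor(self, anc: str, node: str) -> bool:
        return anc in self.path_to_root(node)

    def by_name(self, name: str) -> list[str]:
        return [n for n, (_, _, nm) in self.nodes.items() if nm == name]

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {
                str(r.node_id): (str(r.parent_id), str(r.rank), str(r.name))
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"node_id": n, "parent_id": p, "rank": r, "name": nm}
                for n, (p, r, nm) in self.nodes.items()
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class TaxonCountMatrix:
    """Samples x taxa read counts with sample metadata and a stage tag."""

    counts: pd.DataFrame  # index: sample_id, columns: node_id
    is_control: pd.Series  # bool per sample
    stage: str = "raw"
    unassigned: pd.Series | None = None

    def copy(self) -> "TaxonCountMatrix":
        return TaxonCountMatrix(
            counts=self.counts.copy(),
            is_control=self.is_control.copy(),
            stage=self.stage,
            unassigned=None if self.unassigned is None else self.unassigned.copy(),
        )

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["sample_id", "node_id", "count"]
        long["stage"] = self.stage
        return long


def lca_assign(
    hits_for_read: list[AlignmentHit],
    ref_to_taxon: dict[str, str],
    taxonomy: TaxonomyTree,
    min_similarity: float = 0.95,
    max_mismatches: int = 10,
) -> str | None:
    """Assign one read to the LCA of the taxa its filtered hits touch.

    Hits outside the mismatch/similarity window are discarded; if none
    survive the read is unassigned (None).
    """
    taxa = []
    for h in hits_for_read:
        if h.mismatches > max_mismatches or h.identity < min_similarity - 1e-12:
            continue
        if h.ref_id not in ref_to_taxon:
            raise ValueError(f"hit references unknown taxon for reference {h.ref_id!r}")
        node = ref_to_taxon[h.ref_id]
        if node not in taxonomy:
            raise ValueError(f"reference {h.ref_id!r} maps to unknown taxonomy node {node!r}")
        taxa.append(node)
    if not taxa:
        return None
    return taxonomy.lca(taxa)


def assign_sample(
    hits: list[AlignmentHit],
    ref_to_taxon: dict[str, str],
    taxonomy: TaxonomyTree,
    n_reads: int | None = None,
    **kwargs,
) -> tuple[dict[str, str], int]:
    """LCA-assign every read in a sample; returns (read_id -> node, n_unassigned).

    ``n_reads``, when given, counts reads with no hits at all as unassigned.
    """
    by_read: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    assignments: dict[str, str] = {}
    unassigned = 0
    for read_id, read_hits in by_read.items():
        node = lca_assign(read_hits, ref_to_taxon, taxonomy, **kwargs)
        if node is None:
            unassigned += 1
        else:
            assignments[read_id] = node
    if n_reads is not None:
        unassigned += n_reads - len(by_read)
    return assignments, unassigned


def count_matrix(
    assignments: dict[str, dict[str, str]],
    is_control: dict[str, bool] | None = None,
    unassigned: dict[str, int] | None = None,
) -> TaxonCountMatrix:
    """Build the raw sample x taxon matrix from per-sample read assignments
    (sample_id -> {read_id -> node_id})."""
    rows = {}
    for sample, amap in assignments.items():
        rows[sample] = pd.Series(list(amap.values()), dtype=object).value_counts()
    counts = pd.DataFrame(rows).T.fillna(0).astype(int)
    counts = counts.reindex(sorted(assignments.keys()))
    counts = counts[sorted(counts.columns)] if len(counts.columns) else counts
    counts = counts.fillna(0).astype(int)
    ctrl = pd.Series(
        {s: bool((is_control or {}).get(s, False)) for s in counts.index}, dtype=bool
    )
    una = pd.Series({s: int((unassigned or {}).get(s, 0)) for s in counts.index}, dtype=int)
    return TaxonCountMatrix(counts=counts, is_control=ctrl, stage="raw", unassigned=una)


def decontaminate(
    matrix: TaxonCountMatrix,
    taxonomy: TaxonomyTree | None = None,
    allowlist: tuple[str, ...] = (),
    min_reads: int = 3,
    min_read_pct: float = 0.0,
    min_sum_controls: int = 50,
    min_sum_final: int = 20,
    remove_taxa: tuple[str, ...] = ("Homo sapiens", "Primates"),
) -> TaxonCountMatrix:
    """Control-based decontamination of a raw count matrix.

    Sequentially: (1) per-cell counts below ``min_reads`` are zeroed (a taxon
    must have >= 3 reads to be considered present in a sample); (2) cells
    below ``min_read_pct`` percent of their sample total are zeroed (default
    0: a no-op, kept as a knob); (3) taxa whose sum across all samples
    (controls included) is below ``min_sum_controls`` are dropped; (4) taxa
    detected in any control sample are removed everywhere unless allowlisted
    (known local fauna are exempted by name or node id); (5) ``remove_taxa``
    and their descendants are removed; (6) controls are dropped and taxa
    whose remaining sum is below ``min_sum_final`` are removed.

    The result is monotone: no cell increases, output taxa are a subset of
    input taxa.
    """
    counts = matrix.counts.copy().astype(float)
    ctrl = matrix.is_control.reindex(counts.index).fillna(False)
    if not ctrl.any():
        warnings.warn("no control samples flagged: control-based removal skipped", stacklevel=2)

    counts[counts < min_reads] = 0
    if min_read_pct > 0:
        totals = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
        counts[pct.fillna(0) < min_read_pct] = 0

    keep = counts.sum(axis=0) >= min_sum_controls
    counts = counts.loc[:, keep]

    allow = set(allowlist)

    def _allowlisted(node: str) -> bool:
        if node in allow:
            return True
        return taxonomy is not None and node in taxonomy and taxonomy.name(node) in allow

    if ctrl.any():
        detected_in_controls = counts.loc[ctrl.values].sum(axis=0) > 0
        contaminants = [
            node
            for node in counts.columns[detected_in_controls.values]
            if not _allowlisted(node)
        ]
        counts = counts.drop(columns=contaminants)

    removed: set[str] = set()
    for node in counts.columns:
        names = {node}
        if taxonomy is not None and node in taxonomy:
            names.update(taxonomy.path_to_root(node))
            names.update(taxonomy.name(n) for n in taxonomy.path_to_root(node))
        if names & set(remove_taxa):
            removed.add(node)
    counts = counts.drop(columns=sorted(removed))

    counts = counts.loc[~ctrl.values]
    keep_final = counts.sum(axis=0) >= min_sum_final
    counts = counts.loc[:, keep_final]

    return TaxonCountMatrix(
        counts=counts.astype(int),
        is_control=matrix.is_control.loc[counts.index],
        stage="decontaminated",
        unassigned=None if matrix.unassigned is None else matrix.unassigned.loc[counts.index],
    )


def normalize_tss(matrix: TaxonCountMatrix) -> TaxonCountMatrix:
    """Pseudo total-sum scaling: each cell divided by its sample's total
    mapped count (row total); all-zero samples stay zero."""
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=1)
    norm = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return TaxonCountMatrix(
        counts=norm,
        is_control=matrix.is_control.copy(),
        stage="normalized",
        unassigned=matrix.unassigned,
    )


def group_counts(
    matrix: TaxonCountMatrix,
    taxonomy: TaxonomyTree,
    groups: list[str],
) -> TaxonCountMatrix:
    """Roll node counts up into named groups (plus "other").

    Each node is assigned to its nearest (deepest) listed group ancestor, so
    groups plus "other" partition the total.  Overlapping group definitions
    (e.g. a kingdom and one of its phyla) are therefore resolved in favour of
    the more specific group; call with a flat group list for disjoint units.
    """
    for g in groups:
        if g not in taxonomy:
            raise ValueError(f"group node {g!r} absent from taxonomy")
    group_set = set(groups)
    out = pd.DataFrame(0.0, index=matrix.counts.index, columns=list(groups) + ["other"])
    for node in matrix.counts.columns:
        path = taxonomy.path_to_root(node) if node in taxonomy else (node,)
        target = "other"
        for anc in reversed(path):  # deepest matching group wins
            if anc in group_set:
                target = anc
                break
        out[target] += matrix.counts[node]
    if matrix.stage != "normalized":
        out = out.astype(int)
    return TaxonCountMatrix(
        counts=out,
        is_control=matrix.is_control.copy(),
        stage=matrix.stage,
        unassigned=matrix.unassigned,
    )


def rank_rollup(matrix: TaxonCountMatrix, taxonomy: TaxonomyTree, rank: str) -> TaxonCountMatrix:
    """Roll counts up to the named rank (nodes above/outside it go to "other")."""
    targets: dict[str, str] = {}
    for node in matrix.counts.columns:
        targets[node] = "other"
        if node in taxonomy:
            for anc in reversed(taxonomy.path_to_root(node)):
                if taxonomy.rank(anc) == rank:
                    targets[node] = anc
                    break
    cols = sorted(set(targets.values()))
    out = pd.DataFrame(0.0, index=matrix.counts.index, columns=cols)
    for node, tgt in targets.items():
        out[tgt] += matrix.counts[node]
    if matrix.stage != "normalized":
        out = out.astype(int)
    return TaxonCountMatrix(
        counts=out, is_control=matrix.is_control.copy(), stage=matrix.stage,
        unassigned=matrix.unassigned,
    )
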