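"""Damage-masked pooled-read nucleotide diversity (pi).

Nucleotide diversity is estimated directly from read-level allele counts
(pooled-sample semantics): terminal C->T / G->A mismatches within a window
of the read ends are recoded to N to remove deamination artefacts, a pileup
of the surviving calls is built from hits passing a mapping-quality
threshold, and per-site pi is the unordered-pair mismatch fraction with the
small-sample correction n/(n-1).  The per-sample mean divides by the number
of sites with data (post-masking depth >= 2), so monomorphic covered sites
contribute zeros to the denominator ("adjusted sample size").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readmap import AlignmentHit, ReadRecord, revcomp

_CODE4 = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE4[_b] = _i
_COMP_IDX = np.array([3, 2, 1, 0, -1], dtype=np.int64)  # A<->T, C<->G; N stays invalid


@dataclass(slots=True)
class MaskedAlignment:
    """An alignment with damage-suspect terminal calls recoded to N.

    ``bases`` is in read orientation; masking only ever converts mismatching
    C->T / G->A read bases within the terminal window to N.
    """

    hit: AlignmentHit
    bases: str


def mask_terminal_transitions(
    hits: list[AlignmentHit],
    reads: dict[tuple[str, int], ReadRecord],
    refs: dict[str, str],
    window: int = 10,
) -> list[MaskedAlignment]:
    """Recode C->T / G->A mismatches within ``window`` nt of either read end to N.

    Applied in read orientation (as sequenced), consistent with the damage
    chemistry: reverse-strand hits are masked on their reverse-complemented
    reference view.  Matching bases are never masked.
    """
    out = []
    for h in hits:
        read = reads[(h.read_id, h.mate)]
        seq = read.sequence
        ref_slice = refs[h.ref_id][h.ref_start : h.ref_end]
        if h.strand == "-":
            ref_slice = revcomp(ref_slice)
        L = len(seq)
        chars = list(seq)
        for i in range(L):
            if i >= window and i < L - window:
                continue
            pair = (ref_slice[i], chars[i])
            if pair == ("C", "T") or pair == ("G", "A"):
                chars[i] = "N"
        out.append(MaskedAlignment(hit=h, bases="".join(chars)))
    return out


@dataclass
class Pileup:
    """Per-reference site allele counts of non-N calls: array (ref_len, 4)."""

    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def depth(self, ref_id: str) -> np.ndarray:
        return self.counts[ref_id].sum(axis=1)

    def to_frame(self, ref_id: str, min_depth: int = 2) -> pd.DataFrame:
        c = self.counts[ref_id]
        depth = c.sum(axis=1)
        pi = pi_per_site(self, ref_id, min_depth=min_depth)
        return pd.DataFrame(
            {
                "ref_id": ref_id,
                "pos": np.arange(len(depth)),
                "A": c[:, 0],
                "C": c[:, 1],
                "G": c[:, 2],
                "T": c[:, 3],
                "depth": depth,
                "pi": pi,
            }
        )


def pileup(
    masked: list[MaskedAlignment],
    refs: dict[str, str],
    min_mapq: int = 20,
) -> Pileup:
    """Build per-site allele counts from masked alignments.

    Only hits with an assigned mapq >= ``min_mapq`` contribute; N calls are
    excluded.  Sites with depth < 2 are treated as having no data downstream.
    """
    counts = {rid: np.zeros((len(seq), 4), dtype=np.int64) for rid, seq in refs.items()}
    for m in masked:
        h = m.hit
        mapq = -1 if h.mapq is None else h.mapq
        if mapq < min_mapq:
            continue
        codes = _CODE4[np.frombuffer(m.bases.encode(), dtype=np.uint8)]
        L = len(m.bases)
        if h.strand == "+":
            pos = h.ref_start + np.arange(L)
        else:
            # read orientation runs 3'->5' along the reference forward strand
            pos = h.ref_start + (L - 1 - np.arange(L))
            codes = np.where(codes >= 0, _COMP_IDX[codes], -1)
        valid = codes >= 0
        np.add.at(counts[h.ref_id], (pos[valid], codes[valid]), 1)
    return Pileup(counts=counts)


def site_pi(counts) -> float:
    """Per-site pi: (n/(n-1)) * (1 - sum p_a^2), the unordered-pair mismatch
    fraction among the n calls at the site.  Requires n >= 2."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("site_pi requires depth >= 2")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def pi_per_site(pile: Pileup, ref_id: str, min_depth: int = 2) -> np.ndarray:
    """Vector of per-site pi; NaN where post-masking depth < min_depth."""
    c = pile.counts[ref_id].astype(float)
    n = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = 1.0 - np.sum((c / n[:, None]) ** 2, axis=1)
        pi = n / (n - 1.0) * het
    pi[n < max(min_depth, 2)] = np.nan
    return pi


@dataclass
class PiEstimate:
    """Mean pi over sites with data, with the variant-sites-only variant
    reported alongside for comparison."""

    mean_pi: float
    n_sites_with_data: int
    scope: str = "whole"
    sample_id: str = ""
    mean_pi_variant_sites: float = float("nan")
    n_variant_sites: int = 0
    per_site: np.ndarray | None = None

    @property
    def defined(self) -> bool:
        return self.n_sites_with_data > 0


def mean_pi(
    site_values: np.ndarray,
    region: tuple[int, int] | None = None,
    scope: str | None = None,
    sample_id: str = "",
) -> PiEstimate:
    """Average per-site pi over sites with data (NaN = no data).

    ``region`` restricts to a 0-based half-open interval (e.g. the
    mitochondrial control region).  Monomorphic covered sites contribute 0 to
    the numerator and 1 to the denominator; with zero sites with data the
    estimate is undefined (NaN, flagged via n_sites_with_data == 0).
    """
    vals = np.asarray(site_values, dtype=float)
    if region is not None:
        lo, hi = region
        vals = vals[lo:hi]
        scope = scope or f"region:{lo}-{hi}"
    scope = scope or "whole"
    data = vals[~np.isnan(vals)]
    n_sites = int(data.size)
    variant = data[data > 0]
    return PiEstimate(
        mean_pi=float(data.mean()) if n_sites else float("nan"),
        n_sites_with_data=n_sites,
        scope=scope,
        sample_id=sample_id,
        mean_pi_variant_sites=float(variant.mean()) if variant.size else float("nan"),
        n_variant_sites=int(variant.size),
        per_site=vals,
    )


def max_upper_pi(
    estimates: pd.DataFrame,
    depth_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Per-colony maximum mean pi among samples within the uppermost sediment.

    ``estimates`` needs columns sample_id, colony, depth_cm, mean_pi.  The
    most recent past is represented by samples with depth <= ``depth_cutoff``
    (cm); colonies with no sample that shallow are flagged missing (NaN).
    """
    required = {"sample_id", "colony", "depth_cm", "mean_pi"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates missing columns: {sorted(missing)}")
    rows = []
    for colony, sub in estimates.groupby("colony"):
        upper = sub[sub["depth_cm"] <= depth_cutoff]
        rows.append(
            {
                "colony": colony,
                "max_upper_pi": float(upper["mean_pi"].max()) if len(upper) else np.nan,
                "n_upper_samples": int(len(upper)),
            }
        )
    return pd.DataFrame(rows).set_index("colony")
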