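"""Synthetic ancient-DNA data: reference panels, lineage haplotypes, damaged reads.

The simulator emulates the salient features of sedimentary ancient DNA from a
cold, well-preserved terrestrial deposit: short lognormal fragment lengths
(30-150 bp), position-dependent terminal cytosine deamination (5' C->T and the
complementary 3' G->A, decaying exponentially into the read), uniform
sequencing error, and multi-taxon read mixtures.  Every emitted read carries a
full truth record so downstream estimators can be validated exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .readmap import ReadRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

DEFAULT_QUALITY_CHAR = "F"  # Phred 37


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    ``d_max`` is the deamination probability at the terminal position and
    ``decay`` the per-position exponential decay rate: at 5' position i
    (1-based) a reference C is read as T with probability
    ``d_max * exp(-decay * (i - 1))``; the mirrored law converts G->A at the
    3' end.  Defaults follow the preservation regime of Holocene Antarctic
    ornithogenic soils: terminal deamination near 2%, fragments mostly
    40-110 bp.
    """

    seed: int
    n_reads: int
    mixture: dict[str, float]
    frag_mean_log: float = 4.2
    frag_sd_log: float = 0.35
    frag_min: int = 30
    frag_max: int = 150
    d_max: float = 0.02
    decay: float = 0.3
    seq_error: float = 0.001
    paired: bool = False
    read_len: int = 100
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        props = np.asarray(list(self.mixture.values()), dtype=float)
        if len(props) == 0:
            raise ValueError("mixture must not be empty")
        if np.any(props < 0):
            raise ValueError("mixture proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {props.sum()}")
        if not 0.0 <= self.d_max <= 1.0:
            raise ValueError("d_max must be in [0, 1]")
        if self.frag_min < 15:
            raise ValueError("frag_min must be >= 15")
        if self.frag_max < self.frag_min:
            raise ValueError("frag_max must be >= frag_min")
        if not 0.0 <= self.seq_error <= 0.25:
            raise ValueError("seq_error must be in [0, 0.25]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be nonnegative")


@dataclass(frozen=True)
class LineageReference:
    """One labelled mitochondrial control-region haplotype."""

    id: str
    sequence: str
    lineage_label: str  # "A" (Antarctic) or "RS" (Ross Sea)

    def __post_init__(self) -> None:
        if self.lineage_label not in ("A", "RS"):
            raise ValueError(f"lineage label must be A or RS, got {self.lineage_label!r}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be over A/C/G/T")


@dataclass
class ReferenceSet:
    """A panel of reference sequences with optional taxonomy / lineage labels.

    ``taxon_of`` maps reference id -> taxonomy leaf node id; ``labels`` maps
    reference id -> lineage label for control-region panels.
    """

    sequences: dict[str, str]
    taxonomy: object | None = None  # TaxonomyTree, kept untyped to avoid a cycle
    taxon_of: dict[str, str] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class TruthRecord:
    source: str
    lineage_label: str | None
    ref_start: int
    ref_end: int  # 0-based half-open on the reference forward strand
    strand: str
    damage_positions: list[int]  # fragment coords, read (as-ligated) orientation
    error_positions: dict[str, list[int]]  # mate key ("0"/"1"/"2") -> positions


@dataclass
class SimTruth:
    """Per-read ground truth, keyed by read id."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def __getitem__(self, read_id: str) -> TruthRecord:
        return self.records[read_id]

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: asdict(v) for k, v in self.records.items()}, fh, indent=0)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: TruthRecord(**v) for k, v in raw.items()})


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-site substitution to one of the three other bases."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit):
        # shift by 1..3 in base space guarantees a different base
        codes = _CODE[out[hit]].astype(np.int64)
        out[hit] = _BASES[(codes + rng.integers(1, 4, size=len(hit))) % 4]
    return out


def generate_references(
    seed: int,
    taxa: list[tuple[str, int]],
    divergence: float,
    genus_of: dict[str, str] | None = None,
) -> ReferenceSet:
    """Generate a panel of related reference genomes plus a star taxonomy.

    The first taxon is a uniform random sequence; every other taxon derives
    from it by independent per-site substitution at rate ``divergence``.  The
    taxonomy is root -> genus nodes -> species leaves; by default each taxon
    gets its own genus, ``genus_of`` groups several species under one genus.
    """
    from .taxprofile import TaxonomyTree

    if not taxa:
        raise ValueError("need at least one taxon")
    for tid, length in taxa:
        if length < 1000:
            raise ValueError(f"reference length must be >= 1000 bp (taxon {tid})")
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")

    rng = np.random.default_rng(seed)
    base = _random_sequence(rng, taxa[0][1])
    seqs: dict[str, str] = {taxa[0][0]: base.tobytes().decode()}
    for tid, length in taxa[1:]:
        if length <= len(base):
            anc = base[:length]
        else:  # tile the base sequence out to the requested length
            reps = -(-length // len(base))
            anc = np.tile(base, reps)[:length]
        seqs[tid] = _mutate(anc, divergence, rng).tobytes().decode()

    genus_of = genus_of or {tid: f"{tid}_genus" for tid, _ in taxa}
    nodes: dict[str, tuple[str, str, str]] = {"root": ("root", "no rank", "root")}
    taxon_of: dict[str, str] = {}
    for tid, _ in taxa:
        genus = genus_of.get(tid, f"{tid}_genus")
        nodes.setdefault(genus, ("root", "genus", genus))
        nodes[tid] = (genus, "species", tid)
        taxon_of[tid] = tid
    return ReferenceSet(sequences=seqs, taxonomy=TaxonomyTree(nodes), taxon_of=taxon_of)


def generate_lineage_haplotypes(
    seed: int,
    n_per_clade: int,
    length: int = 500,
    between_div: float = 0.05,
    within_div: float = 0.005,
) -> list[LineageReference]:
    """Generate two balanced clades of control-region haplotypes.

    Clade ancestors are separated by ~``between_div`` substitutions per site;
    each haplotype mutates from its clade ancestor at ``within_div``.  Labels
    follow the A_/RS_ convention of Adelie penguin control-region panels.
    """
    if n_per_clade < 1:
        raise ValueError("n_per_clade must be >= 1")
    if within_div < 0 or between_div < 0:
        raise ValueError("divergences must be nonnegative")
    if between_div <= within_div:
        warnings.warn(
            "between-clade divergence <= within-clade divergence: "
            "clades may not be separable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    anc_a = _random_sequence(rng, length)
    anc_rs = _mutate(anc_a, between_div, rng)
    out: list[LineageReference] = []
    for label, anc in (("A", anc_a), ("RS", anc_rs)):
        for i in range(n_per_clade):
            hap = _mutate(anc, within_div, rng).tobytes().decode()
            out.append(LineageReference(f"{label}_{i:03d}", hap, label))
    return out


def _truncated_lognormal_lengths(
    rng: np.random.Generator,
    n: int,
    mean_log: float,
    sd_log: float,
    lo: int,
    hi: np.ndarray,
) -> np.ndarray:
    """Rejection-sample integer lognormal lengths into per-read [lo, hi]."""
    lengths = np.zeros(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(200):
        draw = np.rint(rng.lognormal(mean_log, sd_log, size=len(todo))).astype(np.int64)
        ok = (draw >= lo) & (draw <= hi[todo])
        lengths[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            break
    if len(todo):  # pathological bounds: clip rather than loop forever
        draw = np.rint(rng.lognormal(mean_log, sd_log, size=len(todo))).astype(np.int64)
        lengths[todo] = np.clip(draw, lo, hi[todo])
    return lengths


def truncated_lognormal_moments(
    mean_log: float, sd_log: float, lo: int, hi: int, grid: int = 4000
) -> tuple[float, float]:
    """Mean and sd of the integer-rounded truncated lognormal used above."""
    k = np.arange(lo, hi + 1, dtype=float)
    # P(round(X) = k) = CDF(k + .5) - CDF(k - .5)
    from scipy.stats import lognorm

    dist = lognorm(s=sd_log, scale=np.exp(mean_log))
    pmf = dist.cdf(k + 0.5) - dist.cdf(k - 0.5)
    pmf /= pmf.sum()
    mean = float((k * pmf).sum())
    var = float(((k - mean) ** 2 * pmf).sum())
    return mean, float(np.sqrt(var))


def simulate_sample(refs: ReferenceSet, cfg: SimConfig) -> tuple[list[ReadRecord], SimTruth]:
    """Simulate a read set from a mixture of references, with truth.

    Damage is applied to the fragment in its as-ligated orientation first
    (5' C->T, 3' G->A, exponentially decaying), then sequencing error
    overlays each emitted base independently (so an error can revert a
    damaged base); truth records both event lists separately.
    """
    for key in cfg.mixture:
        if key not in refs.sequences:
            raise ValueError(f"mixture key {key!r} not in reference set")
    ref_ids = list(cfg.mixture.keys())
    ref_arrays = {rid: np.frombuffer(refs.sequences[rid].encode(), dtype=np.uint8) for rid in ref_ids}
    for rid in ref_ids:
        if len(ref_arrays[rid]) < cfg.frag_min:
            raise ValueError(f"frag_min exceeds length of reference {rid!r}")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    probs = np.asarray([cfg.mixture[r] for r in ref_ids], dtype=float)
    src_idx = rng.choice(len(ref_ids), size=n, p=probs)
    ref_len = np.asarray([len(ref_arrays[r]) for r in ref_ids])
    hi = np.minimum(cfg.frag_max, ref_len[src_idx])
    lengths = _truncated_lognormal_lengths(
        rng, n, cfg.frag_mean_log, cfg.frag_sd_log, cfg.frag_min, hi
    )
    starts = rng.integers(0, ref_len[src_idx] - lengths + 1)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    reads: list[ReadRecord] = []
    truth = SimTruth()
    c_byte, g_byte, t_byte, a_byte = ord("C"), ord("G"), ord("T"), ord("A")
    for i in range(n):
        rid = ref_ids[src_idx[i]]
        L = int(lengths[i])
        s = int(starts[i])
        frag = ref_arrays[rid][s : s + L]
        if strands[i] == "-":
            frag = np.frombuffer(revcomp(frag.tobytes().decode()).encode(), dtype=np.uint8)
        frag = frag.copy()

        # terminal deamination, decaying into the fragment from both ends
        dmg_positions: list[int] = []
        if cfg.d_max > 0:
            pos = np.arange(L)
            p5 = cfg.d_max * np.exp(-cfg.decay * pos)
            p3 = cfg.d_max * np.exp(-cfg.decay * (L - 1 - pos))
            u = rng.random(L)
            hit5 = (frag == c_byte) & (u < p5)
            hit3 = (frag == g_byte) & (u < p3)
            frag[hit5] = t_byte
            frag[hit3] = a_byte
            dmg_positions = sorted(np.flatnonzero(hit5 | hit3).tolist())

        read_id = f"{cfg.sample_id}_{i:07d}"
        err_positions: dict[str, list[int]] = {}

        def emit(seq_arr: np.ndarray, mate: int) -> None:
            obs = seq_arr[: cfg.read_len].copy()
            errs: list[int] = []
            if cfg.seq_error > 0:
                bad = np.flatnonzero(rng.random(len(obs)) < cfg.seq_error)
                if len(bad):
                    codes = _CODE[obs[bad]].astype(np.int64)
                    obs[bad] = _BASES[(codes + rng.integers(1, 4, size=len(bad))) % 4]
                    errs = bad.tolist()
            err_positions[str(mate)] = errs
            reads.append(
                ReadRecord(
                    id=read_id,
                    sequence=obs.tobytes().decode(),
                    qualities=DEFAULT_QUALITY_CHAR * len(obs),
                    sample_id=cfg.sample_id,
                    mate=mate,
                )
            )

        if cfg.paired:
            emit(frag, 1)
            rc = np.frombuffer(revcomp(frag.tobytes().decode()).encode(), dtype=np.uint8)
            emit(rc, 2)
        else:
            emit(frag, 0)

        truth.records[read_id] = TruthRecord(
            source=rid,
            lineage_label=refs.labels.get(rid),
            ref_start=s,
            ref_end=s + L,
            strand=str(strands[i]),
            damage_positions=dmg_positions,
            error_positions=err_positions,
        )
    return reads, truth
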