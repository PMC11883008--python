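"""Self-contained validation experiments on synthetic data with known truth.

Each function simulates a dataset under stated conditions, runs the relevant
pipeline stages, and returns the measured quantities next to their analytic
or truth-derived expectations.  They are used by the test suite and the
reproducibility script; problem sizes are chosen so each experiment runs in
seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simdata
from .simdata import SimConfig, ReferenceSet, truncated_lognormal_moments
from .readmap import KmerIndex, map_reads, assign_mapq, dedupe
from .io import reads_by_key
from .damage import misincorporation_profile, terminal_rates
from .lineage import build_lineage_db, assign_read_pairs, lineage_proportions
from .diversity import mask_terminal_transitions, pileup, pi_per_site, mean_pi, max_upper_pi
from .report import linear_fit

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def run_mapped_simulation(
    seed: int,
    ref_seed: int = 101,
    ref_len: int = 16000,
    n_reads: int = 50_000,
    d_max: float = 0.04,
    decay: float = 0.3,
    seq_error: float = 0.001,
    min_mapq: int = 25,
) -> dict:
    """Simulate reads from one mitogenome-sized reference and map them back.

    Returns the simulation pieces plus deduplicated hits passing the
    mapping-quality threshold used for damage profiling.
    """
    refs = simdata.generate_references(ref_seed, [("mt", ref_len)], 0.0)
    cfg = SimConfig(
        seed=seed, n_reads=n_reads, mixture={"mt": 1.0},
        d_max=d_max, decay=decay, seq_error=seq_error,
    )
    reads, truth = simdata.simulate_sample(refs, cfg)
    hits = map_reads(reads, KmerIndex(refs.sequences))
    assign_mapq(hits)
    rbk = reads_by_key(reads)
    hits = dedupe(hits, rbk)
    kept = [h for h in hits if h.mapq is not None and h.mapq >= min_mapq]
    return {
        "refs": refs, "cfg": cfg, "reads": reads, "truth": truth,
        "hits": kept, "reads_by_key": rbk,
    }


def damage_recovery_experiment(seed: int, n_reads: int = 50_000) -> dict:
    """Estimate terminal C->T rates for a damaged and an undamaged simulation.

    The damaged run uses d_max=0.04, decay 0.3, sequencing error 1e-3; the
    undamaged run isolates the error floor, whose expected position-1 C->T
    rate is seq_error/3 (a third of substitutions are C->T).
    """
    out = {}
    for tag, d_max, sim_seed in (("damaged", 0.04, seed), ("undamaged", 0.0, seed + 1)):
        sim = run_mapped_simulation(sim_seed, n_reads=n_reads, d_max=d_max)
        prof = misincorporation_profile(
            sim["hits"], sim["reads_by_key"], sim["refs"].sequences
        )
        r1, r2 = terminal_rates(prof)
        denom = int(prof.denominator5("C")[0])
        out[tag] = {
            "ct_rate_pos1": r1,
            "ct_rate_pos2": r2,
            "ct_rate_pos10": float(prof.ct_rate[9]),
            "denominator_pos1": denom,
            "seq_error": sim["cfg"].seq_error,
            "d_max": d_max,
        }
    e3 = out["undamaged"]["seq_error"] / 3.0
    out["undamaged"]["expected_rate"] = e3
    out["undamaged"]["sigma"] = float(
        np.sqrt(e3 * (1 - e3) / out["undamaged"]["denominator_pos1"])
    )
    return out


def plca_recovery_experiment(
    seed: int,
    truth_rs: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5),
    n_pairs: int = 10_000,
    n_per_clade: int = 20,
    length: int = 500,
    between_div: float = 0.05,
    within_div: float = 0.005,
) -> pd.DataFrame:
    """Recover known Ross Sea lineage proportions from simulated read pairs.

    A balanced two-clade haplotype DB is built, read pairs are simulated at
    each truth proportion, voted by PLCA, and the per-mixture recovered
    proportion is returned with its truth.
    """
    haps = simdata.generate_lineage_haplotypes(
        seed, n_per_clade=n_per_clade, length=length,
        between_div=between_div, within_div=within_div,
    )
    db = build_lineage_db(haps, seed=seed + 1)
    refs = ReferenceSet(sequences=db.sequences, labels=db.label_of)
    a_ids = [r.id for r in db.references if r.lineage_label == "A"]
    rs_ids = [r.id for r in db.references if r.lineage_label == "RS"]
    rows = []
    for j, p_rs in enumerate(truth_rs):
        mixture = {rid: (1 - p_rs) / len(a_ids) for rid in a_ids}
        if p_rs > 0:
            mixture.update({rid: p_rs / len(rs_ids) for rid in rs_ids})
        else:
            mixture = {rid: 1 / len(a_ids) for rid in a_ids}
        cfg = SimConfig(
            seed=seed + 10 + j, n_reads=n_pairs, mixture=mixture, paired=True
        )
        reads, _ = simdata.simulate_sample(refs, cfg)
        calls = assign_read_pairs(reads, db)
        props = lineage_proportions({"sim": calls}).loc["sim"]
        rows.append(
            {
                "truth_rs": p_rs,
                "recovered_rs": float(props.prop_rs),
                "n_assigned": int(props.n_assigned),
                "n_undetermined": int(props.n_undetermined),
                "n_unassigned": int(props.n_unassigned),
            }
        )
    return pd.DataFrame(rows)


def _variant_haplotypes(
    rng: np.random.Generator, length: int, n_variants: int
) -> tuple[dict[str, str], float]:
    """Four equifrequent haplotypes: h0 is the reference; each variant site
    carries a complement transversion on exactly one of h1..h3, so each has
    derived-allele frequency 1/4 and masking cannot touch it.  Returns the
    haplotypes and the expected mean pi over the reference."""
    base = "".join(rng.choice(list("ACGT"), size=length))
    sites = np.linspace(length // 40, length - length // 40, n_variants).astype(int)
    haps = {"h0": base}
    arrs = {j: list(base) for j in (1, 2, 3)}
    for m, pos in enumerate(sites):
        j = m % 3 + 1
        arrs[j][pos] = _COMPLEMENT[arrs[j][pos]]
    for j in (1, 2, 3):
        haps[f"h{j}"] = "".join(arrs[j])
    site_het = 1.0 - (0.25**2 + 0.75**2)  # expected unordered-pair mismatch
    return haps, n_variants * site_het / length


def _masked_pi_from_reads(refs_map, reads, window=10, min_mapq=20):
    index = KmerIndex(refs_map)
    hits = map_reads(reads, index)
    assign_mapq(hits)
    rbk = reads_by_key(reads)
    masked = mask_terminal_transitions(hits, rbk, refs_map, window=window)
    pile = pileup(masked, refs_map, min_mapq=min_mapq)
    rid = next(iter(refs_map))
    site = pi_per_site(pile, rid)
    return mean_pi(site), pile, rid


def pi_recovery_experiment(
    seed: int,
    length: int = 1000,
    n_variants: int = 20,
    depth: int = 50,
) -> dict:
    """Masked mean pi for 4 equifrequent haplotypes vs its analytic truth."""
    rng = np.random.default_rng(seed)
    haps, truth_pi = _variant_haplotypes(rng, length, n_variants)
    refs = ReferenceSet(sequences=haps)
    mean_len, _ = truncated_lognormal_moments(4.2, 0.35, 30, 150)
    cfg = SimConfig(
        seed=seed + 1,
        n_reads=int(round(depth * length / mean_len)),
        mixture={h: 0.25 for h in haps},
        d_max=0.02,
        seq_error=1e-4,
        read_len=150,
    )
    reads, _ = simdata.simulate_sample(refs, cfg)
    est, _, _ = _masked_pi_from_reads({"h0": haps["h0"]}, reads)
    return {
        "masked_pi": est.mean_pi,
        "truth_pi": truth_pi,
        "relative_error": abs(est.mean_pi - truth_pi) / truth_pi,
        "n_sites_with_data": est.n_sites_with_data,
    }


def pi_masking_floor_experiment(
    seed: int,
    length: int = 1000,
    depth: int = 50,
    d_max: float = 0.1,
    decay: float = 0.3,
    seq_error: float = 0.001,
    window: int = 10,
) -> dict:
    """Single true haplotype under heavy damage: masking should pull mean pi
    down to the residual floor of sequencing error plus interior damage.

    The floor is computed analytically from the experiment parameters: with
    E expected spurious variant calls among N surviving calls, each creating
    a singleton worth 2/n at its site, the expected mean pi is 2E/N with
    Poisson standard deviation 2*sqrt(E)/N.
    """
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=length))
    refs = ReferenceSet(sequences={"h0": base})
    mean_len, _ = truncated_lognormal_moments(4.2, 0.35, 30, 150)
    cfg = SimConfig(
        seed=seed + 1,
        n_reads=int(round(depth * length / mean_len)),
        mixture={"h0": 1.0},
        d_max=d_max,
        decay=decay,
        seq_error=seq_error,
        read_len=150,
    )
    reads, _ = simdata.simulate_sample(refs, cfg)
    masked_est, pile, rid = _masked_pi_from_reads({"h0": base}, reads, window=window)
    unmasked_est, _, _ = _masked_pi_from_reads({"h0": base}, reads, window=0)

    # analytic expectation of surviving spurious calls
    f_c = base.count("C") / length
    f_g = base.count("G") / length
    f_cg = f_c + f_g
    e_events = 0.0
    for r in reads:
        L = len(r)
        interior = np.arange(window, max(window, L - window))
        decay_sum = float(np.exp(-decay * interior).sum())
        # interior damage survives (5' C->T law and mirrored 3' G->A law)
        e_events += f_cg * d_max * decay_sum
        # sequencing errors: interior always counted; in-window errors are
        # counted unless they mimic damage (C->T or G->A, 1/3 of errors)
        n_window = min(2 * window, L)
        e_events += seq_error * (L - n_window) + seq_error * n_window * (1 - f_cg / 3)
    depths = pile.depth(rid)
    n_calls = float(depths[depths >= 2].sum())
    floor = 2.0 * e_events / n_calls
    sigma = 2.0 * np.sqrt(e_events) / n_calls
    return {
        "masked_pi": masked_est.mean_pi,
        "unmasked_pi": unmasked_est.mean_pi,
        "floor": floor,
        "sigma": sigma,
        "n_sites_with_data": masked_est.n_sites_with_data,
    }


def colony_regression_experiment(
    seed: int,
    variant_counts: tuple[int, ...] = (4, 8, 16, 24),
    pairs_per_variant: int = 5000,
    depth: int = 30,
    length: int = 1000,
) -> dict:
    """End-to-end colony-size vs diversity machinery on synthetic colonies.

    Each synthetic colony's surface sample carries mitochondrial diversity
    proportional to its breeding-pair count (by construction); a deeper,
    low-diversity sample checks that only the uppermost 10 cm enters the
    per-colony maximum before regressing max pi on colony size.
    """
    rows = []
    for c, k in enumerate(variant_counts):
        pairs = k * pairs_per_variant
        for depth_cm, n_var in ((5.0, k), (40.0, 2)):
            rng = np.random.default_rng(seed + 100 * c + int(depth_cm))
            haps, _ = _variant_haplotypes(rng, length, n_var)
            refs = ReferenceSet(sequences=haps)
            mean_len, _ = truncated_lognormal_moments(4.2, 0.35, 30, 150)
            cfg = SimConfig(
                seed=seed + 100 * c + int(depth_cm) + 1,
                n_reads=int(round(depth * length / mean_len)),
                mixture={h: 0.25 for h in haps},
                d_max=0.02,
                seq_error=1e-4,
                read_len=150,
            )
            reads, _ = simdata.simulate_sample(refs, cfg)
            est, _, _ = _masked_pi_from_reads({"h0": haps["h0"]}, reads)
            rows.append(
                {
                    "sample_id": f"colony{c}_d{int(depth_cm)}",
                    "colony": f"colony{c}",
                    "depth_cm": depth_cm,
                    "mean_pi": est.mean_pi,
                    "breeding_pairs": pairs,
                }
            )
    estimates = pd.DataFrame(rows)
    per_colony = max_upper_pi(estimates)
    pairs = estimates.groupby("colony")["breeding_pairs"].first()
    merged = per_colony.join(pairs)
    fit = linear_fit(merged["breeding_pairs"], merged["max_upper_pi"])
    return {
        "estimates": estimates,
        "per_colony": merged,
        "slope": fit.slope,
        "r2": fit.r2,
    }
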