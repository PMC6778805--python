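"""Synthetic GBS data: pedigrees, true genotypes and read counts.

The generator embodies the assumptions under which the mismatch theory is
derived — a randomly mating population in Hardy-Weinberg equilibrium with
independent SNPs — plus optional founder inbreeding and subpopulation
divergence (Balding-Nichols drift of founder frequencies).  Read counts are
drawn under any of the three allele-sampling families; the sequential
Markov simulation of the modified-p model is an implementation independent
of the closed-form ``K``, so empirical single-allele fractions cross-check
the analytic model.

Homozygotes always yield reads of their single allele (no sequencing
error); read depth per cell is Poisson with a configurable mean, allowing
per-individual means to mimic sample-quality variation.  Depth 0 is a
missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlleleCountMatrix, CandidateTable

__all__ = ["SimConfig", "simulate_pedigree_genotypes", "simulate_reads", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for a simulated single-cohort herd.

    Defaults describe a herd of 20 sires, 200 dams and 300 offspring typed
    at 3,000 independent SNPs with founder frequencies uniform on
    [0.05, 0.95] and read depth Poisson with mean 2 — a deliberately
    low-depth panel of the scale used for livestock parentage.
    """

    n_snps: int = 3000
    n_sires: int = 20
    n_dams: int = 200
    n_offspring: int = 300
    freq_range: tuple[float, float] = (0.05, 0.95)
    inbreeding: float = 0.0
    missing_sire_fraction: float = 0.0
    depth_mean: float = 2.0
    depth_mean_sd: float = 0.0
    model_family: str = "binomial"
    model_param: float | None = None
    n_subpops: int = 1
    fst: float = 0.0
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueGenotypes:
    """True dosages plus the pedigree truth table."""

    individual_ids: list[str]
    snp_ids: list[str]
    genotypes: np.ndarray  # (n_ind, n_snp) reference-allele dosage 0/1/2
    freqs: np.ndarray      # founder reference-allele frequency per SNP
    truth: pd.DataFrame    # offspring, true_sire, true_dam, subpop
    subpop: dict[str, str] = field(default_factory=dict)


def _founder_genotypes(rng, p, n, inbreeding):
    """Founder dosages: with probability F the two alleles are IBD."""
    a1 = rng.random((n, p.size)) < p[None, :]
    ibd = rng.random((n, p.size)) < inbreeding
    a2_indep = rng.random((n, p.size)) < p[None, :]
    a2 = np.where(ibd, a1, a2_indep)
    return (a1.astype(np.int8) + a2.astype(np.int8)).astype(np.int8)


def _transmit(rng, parent_g):
    """One gamete per cell from a parent dosage row-matrix."""
    gam = np.where(parent_g == 1, (rng.random(parent_g.shape) < 0.5).astype(np.int8), (parent_g // 2).astype(np.int8))
    return gam


def simulate_pedigree_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> TrueGenotypes:
    """Draw founder and offspring true genotypes with a known pedigree.

    Founders are at HWE (with optional inbreeding) at frequencies drawn from
    ``freq_range``; with several subpopulations, founder frequencies drift
    per subpopulation by a Balding-Nichols beta perturbation of strength
    ``fst`` and individuals split evenly across subpopulations.  Each
    offspring receives one allele from a uniformly drawn sire and dam of its
    own subpopulation.
    """
    rng = rng or config.rng()
    if config.n_offspring > 0 and (config.n_sires == 0 or config.n_dams == 0):
        raise ValueError("offspring requested but no sires or no dams to draw from")
    lo, hi = config.freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)

    subpops = [f"pop{q + 1}" for q in range(max(config.n_subpops, 1))]
    if config.n_subpops > 1 and config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        pop_freqs = {q: np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6) for q in subpops}
    else:
        pop_freqs = {q: p_anc for q in subpops}

    def split(prefix, n):
        ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
        pops = [subpops[i % len(subpops)] for i in range(n)]
        return ids, pops

    sire_ids, sire_pops = split("S", config.n_sires)
    dam_ids, dam_pops = split("D", config.n_dams)
    off_ids, off_pops = split("O", config.n_offspring)

    geno_rows, ids, subpop_map = [], [], {}
    parent_geno: dict[str, np.ndarray] = {}
    for iid, pop in zip(sire_ids + dam_ids, sire_pops + dam_pops):
        g = _founder_genotypes(rng, pop_freqs[pop], 1, config.inbreeding)[0]
        parent_geno[iid] = g
        geno_rows.append(g)
        ids.append(iid)
        subpop_map[iid] = pop

    truth_rows = []
    for iid, pop in zip(off_ids, off_pops):
        pop_sires = [s for s, q in zip(sire_ids, sire_pops) if q == pop] or sire_ids
        pop_dams = [d for d, q in zip(dam_ids, dam_pops) if q == pop] or dam_ids
        sire = pop_sires[rng.integers(len(pop_sires))]
        dam = pop_dams[rng.integers(len(pop_dams))]
        g = _transmit(rng, parent_geno[sire][None, :])[0] + _transmit(rng, parent_geno[dam][None, :])[0]
        geno_rows.append(g.astype(np.int8))
        ids.append(iid)
        subpop_map[iid] = pop
        truth_rows.append({"offspring": iid, "true_sire": sire, "true_dam": dam, "subpop": pop})

    snp_ids = [f"snp{s + 1:05d}" for s in range(config.n_snps)]
    return TrueGenotypes(
        individual_ids=ids,
        snp_ids=snp_ids,
        genotypes=np.array(geno_rows, dtype=np.int8),
        freqs=p_anc,
        truth=pd.DataFrame(truth_rows, columns=["offspring", "true_sire", "true_dam", "subpop"]),
        subpop=subpop_map,
    )


def _het_ref_reads_binomial(rng, k):
    return rng.binomial(k, 0.5)


def _het_ref_reads_beta_binomial(rng, k, alpha):
    q = rng.beta(alpha, alpha, size=k.shape)
    return rng.binomial(k, q)


def _het_ref_reads_modified_p(rng, k, p_prime):
    """Sequential Markov reads: first read fair, later reads repeat the
    previous allele with probability p'.  Only the count of reference reads
    is needed, so reads are generated depth-group by depth-group."""
    out = np.zeros(k.shape, dtype=np.int64)
    for depth in np.unique(k):
        if depth < 1:
            continue
        sel = k == depth
        n = int(sel.sum())
        reads = np.empty((n, depth), dtype=np.int8)
        reads[:, 0] = rng.random(n) < 0.5
        for j in range(1, depth):
            stay = rng.random(n) < p_prime
            reads[:, j] = np.where(stay, reads[:, j - 1], 1 - reads[:, j - 1])
        out[sel] = reads.sum(axis=1)
    return out


def simulate_reads(true_g: TrueGenotypes, config: SimConfig, rng: np.random.Generator | None = None) -> AlleleCountMatrix:
    """Draw per-cell read counts from true genotypes under the configured
    allele-sampling model; depth is Poisson(depth_mean), optionally varying
    the mean per individual (log-normal-free: truncated normal of the mean)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    g = true_g.genotypes
    n_ind, n_snp = g.shape
    if config.depth_mean_sd > 0:
        lam = np.clip(rng.normal(config.depth_mean, config.depth_mean_sd, size=n_ind), 0.1, None)
    else:
        lam = np.full(n_ind, config.depth_mean)
    k = rng.poisson(lam[:, None], size=(n_ind, n_snp))

    ref = np.zeros((n_ind, n_snp), dtype=np.int64)
    ref[g == 2] = k[g == 2]
    het = g == 1
    k_het = k[het]
    if config.model_family == "binomial":
        ref_het = _het_ref_reads_binomial(rng, k_het)
    elif config.model_family == "beta_binomial":
        if config.model_param is None or config.model_param <= 0:
            raise ValueError("beta_binomial simulation requires alpha > 0")
        ref_het = _het_ref_reads_beta_binomial(rng, k_het, config.model_param)
    elif config.model_family == "modified_p":
        if config.model_param is None or not (0.5 <= config.model_param < 1.0):
            raise ValueError("modified_p simulation requires p' in [0.5, 1)")
        ref_het = _het_ref_reads_modified_p(rng, k_het, config.model_param)
    else:
        raise ValueError(f"unknown read-model family {config.model_family!r}")
    ref[het] = ref_het
    alt = k - ref
    return AlleleCountMatrix(list(true_g.individual_ids), list(true_g.snp_ids), ref, alt)


def simulate_dataset(config: SimConfig):
    """Full synthetic dataset: counts, candidate table and truth table.

    ``missing_sire_fraction`` removes that share of sires from both the
    genotype matrix and the candidate set (their offspring keep their
    genomes), emulating unsampled true parents.  Returns
    ``(counts, candidates, truth)``; ``truth`` is the pedigree DataFrame.
    """
    rng = config.rng()
    true_g = simulate_pedigree_genotypes(config, rng)
    counts = simulate_reads(true_g, config, rng)

    sire_ids = [i for i in true_g.individual_ids if i.startswith("S")]
    dam_ids = [i for i in true_g.individual_ids if i.startswith("D")]
    off_ids = [i for i in true_g.individual_ids if i.startswith("O")]

    if config.missing_sire_fraction > 0:
        n_drop = int(round(config.missing_sire_fraction * len(sire_ids)))
        dropped = set(rng.choice(sire_ids, size=n_drop, replace=False).tolist())
        keep = [i for i in counts.individual_ids if i not in dropped]
        counts = counts.subset_individuals(keep)
        sire_ids = [s for s in sire_ids if s not in dropped]

    candidates = CandidateTable(
        offspring_ids=off_ids,
        sire_candidate_ids=sire_ids,
        dam_candidate_ids=dam_ids,
        subpop=dict(true_g.subpop),
        recorded_sire=dict(zip(true_g.truth["offspring"], true_g.truth["true_sire"])),
        recorded_dam=dict(zip(true_g.truth["offspring"], true_g.truth["true_dam"])),
    )
    candidates.flag_ungenotyped(set(counts.individual_ids))
    return counts, candidates, true_g.truth
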