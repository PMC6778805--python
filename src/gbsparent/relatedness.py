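"""Depth-aware genomic relatedness for low-depth sequencing data.

Pairwise relatedness uses the allele-frequency-centered dosage estimator

    r_ij = sum_s (g_is - 2 p_s)(g_js - 2 p_s) / sum_s 2 p_s (1 - p_s)

with naive calls ``g`` (0/1/2 reference-allele dosage of the apparent
genotype) and sums over the SNPs non-missing in *both* individuals
(pair-specific denominators).  Because a true heterozygote's apparent
dosage has expectation equal to the true dosage under any symmetric
read-sampling model, the off-diagonal is unbiased for pedigree relatedness
and does not depend on the read model at all.

Self-relatedness (the diagonal, estimating ``1 + F``) does depend on depth:
a true heterozygote observed all-one-allele at depth ``k`` inflates
``(g - 2p)**2`` by ``2K``.  The diagonal therefore subtracts a per-SNP
correction ``2K/(1 - 2K)`` at apparent-heterozygous cells, restricted to
cells with depth >= 2 (at depth 1, ``K = 0.5`` and a single read carries no
heterozygosity signal), which makes it unbiased under the chosen read
model without assuming Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_model import MISSING, GenotypeCalls, ReadModel

__all__ = [
    "RelatednessMatrix",
    "relatedness_pair",
    "self_relatedness",
    "build_grm",
    "grm_pca",
    "bootstrap_support",
]


@dataclass
class RelatednessMatrix:
    """Pairwise relatedness estimates with self-relatedness on the diagonal.

    Entries are estimates relative to the allele-frequency base population
    and may fall outside pedigree ranges; a pair with no shared SNPs is
    ``nan`` with ``n_snps = 0``.
    """

    individual_ids: list[str]
    r: np.ndarray
    n_snps: np.ndarray

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None

    def inbreeding(self) -> np.ndarray:
        """Estimated inbreeding coefficients F = diagonal - 1."""
        return np.diag(self.r) - 1.0


def _polymorphic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.isfinite(p) & (p > 0.0) & (p < 1.0)


def relatedness_pair(g_i, g_j, p, valid=None) -> tuple[float, int]:
    """Relatedness estimate for one pair; returns ``(r_hat, n_snps)``.

    ``nan`` with 0 SNPs when the pair shares no usable SNP.
    """
    p = np.asarray(p, dtype=float)
    use = _polymorphic(p)
    if valid is not None:
        use &= valid
    both = use & (g_i != MISSING) & (g_j != MISSING)
    n = int(both.sum())
    if n == 0:
        return np.nan, 0
    pc = p[both]
    num = float(np.sum((g_i[both] - 2 * pc) * (g_j[both] - 2 * pc)))
    den = float(np.sum(2 * pc * (1 - pc)))
    return num / den, n


def self_relatedness(g_i, k_i, p, model: ReadModel, valid=None) -> tuple[float, int]:
    """Depth-corrected self-relatedness estimate ``1 + F_hat`` for one
    individual, over non-missing polymorphic SNPs with depth >= 2."""
    p = np.asarray(p, dtype=float)
    use = _polymorphic(p)
    if valid is not None:
        use &= valid
    cells = use & (g_i != MISSING) & (k_i >= 2)
    n = int(cells.sum())
    if n == 0:
        return np.nan, 0
    pc = p[cells]
    g = g_i[cells].astype(float)
    K = model.k_probability(k_i[cells])
    corr = np.where(g_i[cells] == 1, 2 * K / (1 - 2 * K), 0.0)
    num = float(np.sum((g - 2 * pc) ** 2 - corr))
    den = float(np.sum(2 * pc * (1 - pc)))
    return num / den, n


def build_grm(
    calls: GenotypeCalls,
    p: np.ndarray,
    model: ReadModel | None = None,
    individual_ids: list[str] | None = None,
    valid: np.ndarray | None = None,
) -> RelatednessMatrix:
    """Assemble the genomic relatedness matrix for all individuals.

    Off-diagonal entries use pair-specific SNP sets and are identical for
    every read-model family (no ``K`` involved); the diagonal applies the
    depth correction under *model* (binomial by default).
    """
    if calls.n_individuals < 2:
        raise ValueError("GRM requires at least two individuals")
    model = model or ReadModel("binomial")
    p = np.asarray(p, dtype=float)
    use = _polymorphic(p)
    if valid is not None:
        use &= valid

    g = calls.calls.astype(float)
    nonmiss = (calls.calls != MISSING) & use[None, :]
    z = np.where(nonmiss, g - 2 * p[None, :], 0.0)
    w = 2 * p * (1 - p)
    w = np.where(use, w, 0.0)

    num = z @ z.T
    m = nonmiss.astype(float)
    den = (m * w[None, :]) @ m.T
    n_snps = (nonmiss @ nonmiss.T.astype(np.int64)).astype(np.int64)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    for i in range(calls.n_individuals):
        diag, n_diag = self_relatedness(calls.calls[i], calls.depths[i], p, model, valid=valid)
        r[i, i] = diag
        n_snps[i, i] = n_diag

    ids = individual_ids if individual_ids is not None else [f"ind{i}" for i in range(calls.n_individuals)]
    return RelatednessMatrix(list(ids), r, n_snps)


def grm_pca(grm: RelatednessMatrix, n_components: int | None = None):
    """Principal components of the GRM for population-structure diagnostics.

    The matrix is double-centered and eigendecomposed; scores are
    ``eigenvector * sqrt(max(eigenvalue, 0))`` and each component's share of
    variation is its eigenvalue over the sum of positive eigenvalues.

    Returns ``(scores, proportions)`` with components ordered by decreasing
    eigenvalue.
    """
    r = np.asarray(grm.r, dtype=float)
    if not np.isfinite(r).all():
        bad = np.argwhere(~np.isfinite(r))
        pairs = [(grm.individual_ids[i], grm.individual_ids[j]) for i, j in bad[:5]]
        raise ValueError(f"GRM contains non-finite entries, e.g. pairs {pairs}")
    n = r.shape[0]
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    c = centering @ ((r + r.T) / 2.0) @ centering
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos_sum = eigval[eigval > 0].sum()
    proportions = eigval / pos_sum if pos_sum > 0 else np.zeros_like(eigval)
    scores = eigvec * np.sqrt(np.maximum(eigval, 0.0))[None, :]
    if n_components is not None:
        scores = scores[:, :n_components]
        proportions = proportions[:n_components]
    return scores, proportions


def bootstrap_support(
    calls: GenotypeCalls,
    p: np.ndarray,
    offspring: int,
    candidate_best: int,
    candidate_second: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    valid: np.ndarray | None = None,
) -> float:
    """Bootstrap support for the top candidate parent.

    SNPs are resampled with replacement (same panel size) and the two
    offspring-candidate relatedness values recomputed per replicate with
    the original allele frequencies held fixed.  Returns the fraction of
    replicates in which the best candidate remains more related than the
    runner-up; exact ties count 0.5.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    use = _polymorphic(p)
    if valid is not None:
        use &= valid
    n_panel = int(use.sum())
    g_o = calls.calls[offspring]
    for cand in (candidate_best, candidate_second):
        shared = use & (g_o != MISSING) & (calls.calls[cand] != MISSING)
        if not shared.any():
            raise ValueError("candidate shares no usable SNPs with the offspring")

    idx_panel = np.flatnonzero(use)
    pc = p[idx_panel]
    w = 2 * pc * (1 - pc)
    z_o = np.where(g_o[idx_panel] != MISSING, g_o[idx_panel] - 2 * pc, 0.0)

    def per_snp_terms(cand):
        g_c = calls.calls[cand][idx_panel]
        shared = (g_o[idx_panel] != MISSING) & (g_c != MISSING)
        num = np.where(shared, z_o * (g_c - 2 * pc), 0.0)
        den = np.where(shared, w, 0.0)
        return num, den

    num_b, den_b = per_snp_terms(candidate_best)
    num_s, den_s = per_snp_terms(candidate_second)

    wins = 0.0
    chunk = max(1, min(n_boot, int(2e7) // max(n_panel, 1)))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n_panel, size=(m, n_panel))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_b = num_b[idx].sum(axis=1) / den_b[idx].sum(axis=1)
            r_s = num_s[idx].sum(axis=1) / den_s[idx].sum(axis=1)
        wins += np.sum(r_b > r_s) + 0.5 * np.sum(r_b == r_s)
        done += m
    return float(wins / n_boot)
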