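"""Observed and expected mismatch rates for parent-offspring pairs and
parent-pair trios, and the excess mismatch rate (EMM).

A *raw* mismatch treats apparent genotypes as true: a pair mismatches at a
SNP when parent and offspring are opposing homozygotes; a trio mismatches
when the three apparent genotypes are jointly Mendelian-impossible.  With
low-depth data true heterozygotes are sometimes observed homozygous, so
even true parents mismatch at some rate.  The *expected* mismatch rate is
that rate under the hypothesis of parentage, conditional on the offspring's
apparent genotype and on every member's read depth (through ``K`` from the
chosen :class:`~gbsparent.read_model.ReadModel`), assuming a randomly
mating, non-inbred population in Hardy-Weinberg equilibrium with known
allele frequency ``p``.  EMM = observed - expected is near zero for true
parentage and inflated for wrong parents, making it a depth-robust
exclusion statistic.

The conditional probabilities below are evaluated from closed forms in
``p`` and the ``K`` values of offspring (``K_o``), father (``K_f``) and
mother (``K_m``); the probability given an apparent-heterozygous offspring
paired with a single parent is identically zero (a heterozygote never
opposes a homozygote), and the all-alternate case follows from the
all-reference case by ``p -> 1 - p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_model import MISSING, GenotypeCalls, ReadModel

__all__ = [
    "MismatchStats",
    "raw_mismatch_pair",
    "raw_mismatch_trio",
    "expected_mismatch_pair",
    "expected_mismatch_trio",
    "pair_stats",
    "trio_stats",
    "emm",
]


@dataclass
class MismatchStats:
    """Mismatch summary for one putative pair or trio.

    ``n_compared`` counts SNPs where every member has at least one read and
    the SNP is polymorphic; raw and expected rates are averaged over exactly
    that SNP set, and ``emm = raw_rate - expected_rate``.
    """

    n_compared: int
    n_mismatch: int
    raw_rate: float
    expected_rate: float

    @property
    def emm(self) -> float:
        return self.raw_rate - self.expected_rate

    @property
    def defined(self) -> bool:
        return self.n_compared > 0


def raw_mismatch_pair(g_o: np.ndarray, g_p: np.ndarray, valid=None) -> tuple[int, int]:
    """Opposing-homozygote count between offspring and one parent.

    Returns ``(n_mismatch, n_compared)`` over SNPs non-missing in both
    members (and within *valid*, if given).  An apparent-heterozygous
    offspring never mismatches a single parent.
    """
    both = (g_o != MISSING) & (g_p != MISSING)
    if valid is not None:
        both &= valid
    mism = both & (((g_o == 2) & (g_p == 0)) | ((g_o == 0) & (g_p == 2)))
    return int(mism.sum()), int(both.sum())


def raw_mismatch_trio(g_o, g_f, g_m, valid=None) -> tuple[int, int]:
    """Mendelian-impossible apparent-genotype count for a putative trio.

    A SNP (all three members non-missing) mismatches when, reading apparent
    genotypes as true: (a) the offspring opposes either parent as a
    homozygote; (b) the offspring is heterozygous while both parents are
    homozygous for the same allele; or (c) the offspring is homozygous while
    the parents are opposing homozygotes (their offspring must be
    heterozygous; implied by (a) but kept explicit).
    """
    all3 = (g_o != MISSING) & (g_f != MISSING) & (g_m != MISSING)
    if valid is not None:
        all3 &= valid
    opp_f = ((g_o == 2) & (g_f == 0)) | ((g_o == 0) & (g_f == 2))
    opp_m = ((g_o == 2) & (g_m == 0)) | ((g_o == 0) & (g_m == 2))
    het_from_homs = (g_o == 1) & (g_f == g_m) & (g_f != 1)
    hom_from_opp = (g_o != 1) & (g_f != 1) & (g_m != 1) & (g_f != g_m)
    mism = all3 & (opp_f | opp_m | het_from_homs | hom_from_opp)
    return int(mism.sum()), int(all3.sum())


def _check_pk(p, *ks):
    p = np.asarray(p, dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("allele frequency must lie strictly in (0, 1); filter monomorphic SNPs first")
    ks = [np.asarray(k, dtype=float) for k in ks]
    for k in ks:
        if ((k <= 0.0) | (k > 0.5)).any():
            raise ValueError("K values must lie in (0, 0.5]")
    return (p, *ks)


def _pair_aa(p, K_p, K_o):
    return (1 - p) * (p * K_p + K_p * K_o + (1 - p) * K_o) / (p + 2 * (1 - p) * K_o)


def expected_mismatch_pair(p, K_p, K_o, g_class):
    """P(apparent mismatch | offspring apparent class) for one parent.

    *g_class* is the offspring's apparent call (2 = all-reference,
    1 = heterozygous, 0 = all-alternate); broadcastable arrays accepted.
    The all-alternate case is the all-reference case with ``p -> 1 - p``.
    """
    p, K_p, K_o = _check_pk(p, K_p, K_o)
    g_class = np.asarray(g_class)
    out = np.zeros(np.broadcast_shapes(p.shape, K_p.shape, K_o.shape, g_class.shape))
    aa = np.broadcast_to(g_class == 2, out.shape)
    bb = np.broadcast_to(g_class == 0, out.shape)
    full_aa = np.broadcast_to(_pair_aa(p, K_p, K_o), out.shape)
    full_bb = np.broadcast_to(_pair_aa(1 - p, K_p, K_o), out.shape)
    out[aa] = full_aa[aa]
    out[bb] = full_bb[bb]
    return out if out.ndim else float(out)


def _trio_bracket(K_f, K_m, K_o):
    # shared bracketed term of the homozygous-offspring trio equations
    return (
        2 * K_o + K_m + K_f - K_f * K_m
        + 2 * K_m * K_o + 2 * K_f * K_o - 2 * K_f * K_m * K_o
    )


def _trio_aa(p, K_f, K_m, K_o):
    num = (
        p**2 * (1 - p) * (K_m + K_f) * (1 + K_o)
        + p * (1 - p) ** 2 * _trio_bracket(K_f, K_m, K_o)
        + 2 * (1 - p) ** 3 * K_o
    )
    return num / (p + 2 * (1 - p) * K_o)


def expected_mismatch_trio(p, K_f, K_m, K_o, g_class):
    """P(apparent mismatch | offspring apparent class) for a parent pair.

    The heterozygous-offspring case is
    ``((1 - 2p(1-p))(K_m + K_f) + 4p(1-p) K_f K_m) / 2``; homozygous cases
    share a bracketed polynomial in the three ``K`` values, and the
    all-alternate case is the all-reference case with ``p -> 1 - p``.
    """
    p, K_f, K_m, K_o = _check_pk(p, K_f, K_m, K_o)
    g_class = np.asarray(g_class)
    out_shape = np.broadcast_shapes(p.shape, K_f.shape, K_m.shape, K_o.shape, g_class.shape)
    out = np.zeros(out_shape)
    aa = np.broadcast_to(g_class == 2, out_shape)
    ab = np.broadcast_to(g_class == 1, out_shape)
    bb = np.broadcast_to(g_class == 0, out_shape)
    full_aa = np.broadcast_to(_trio_aa(p, K_f, K_m, K_o), out_shape)
    full_bb = np.broadcast_to(_trio_aa(1 - p, K_f, K_m, K_o), out_shape)
    full_ab = np.broadcast_to(
        ((1 - 2 * p * (1 - p)) * (K_m + K_f) + 4 * p * (1 - p) * K_f * K_m) / 2.0,
        out_shape,
    )
    out[aa] = full_aa[aa]
    out[ab] = full_ab[ab]
    out[bb] = full_bb[bb]
    return out if out.ndim else float(out)


def pair_stats(
    calls: GenotypeCalls,
    offspring: int,
    parent: int,
    p: np.ndarray,
    model: ReadModel,
    valid: np.ndarray | None = None,
) -> MismatchStats:
    """Raw and expected mismatch rates for one offspring-parent pair.

    *valid* restricts the SNP panel (e.g. the post-filter polymorphic set);
    SNPs monomorphic in *p* are always excluded.  Raw and expected rates are
    computed over the identical SNP set.
    """
    g_o, g_p = calls.calls[offspring], calls.calls[parent]
    p = np.asarray(p, dtype=float)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    use = poly if valid is None else (poly & valid)
    n_mism, n_comp = raw_mismatch_pair(g_o, g_p, valid=use)
    if n_comp == 0:
        return MismatchStats(0, 0, np.nan, np.nan)
    both = use & (g_o != MISSING) & (g_p != MISSING)
    K_o = model.k_probability(calls.depths[offspring][both])
    K_p = model.k_probability(calls.depths[parent][both])
    probs = expected_mismatch_pair(p[both], K_p, K_o, g_o[both])
    return MismatchStats(n_comp, n_mism, n_mism / n_comp, float(np.mean(probs)))


def trio_stats(
    calls: GenotypeCalls,
    offspring: int,
    father: int,
    mother: int,
    p: np.ndarray,
    model: ReadModel,
    valid: np.ndarray | None = None,
) -> MismatchStats:
    """Raw and expected mismatch rates for one putative trio."""
    g_o, g_f, g_m = calls.calls[offspring], calls.calls[father], calls.calls[mother]
    p = np.asarray(p, dtype=float)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    use = poly if valid is None else (poly & valid)
    n_mism, n_comp = raw_mismatch_trio(g_o, g_f, g_m, valid=use)
    if n_comp == 0:
        return MismatchStats(0, 0, np.nan, np.nan)
    all3 = use & (g_o != MISSING) & (g_f != MISSING) & (g_m != MISSING)
    K_o = model.k_probability(calls.depths[offspring][all3])
    K_f = model.k_probability(calls.depths[father][all3])
    K_m = model.k_probability(calls.depths[mother][all3])
    probs = expected_mismatch_trio(p[all3], K_f, K_m, K_o, g_o[all3])
    return MismatchStats(n_comp, n_mism, n_mism / n_comp, float(np.mean(probs)))


def emm(raw_rate: float, expected_rate: float) -> float:
    """Excess mismatch rate: observed minus expected; may be negative."""
    return raw_rate - expected_rate
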