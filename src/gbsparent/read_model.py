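"""Genotype calling from read counts, allele frequencies, SNP filters, and
the allele-sampling models linking read depth to apparent-genotype error.

At low read depth a true heterozygote may show reads for only one allele
and therefore be called homozygous.  Writing ``k`` for the read depth of a
cell, each model specifies ``K``, the probability that a true heterozygote
shows *only* reference (equivalently, only alternate) reads:

* ``binomial`` — reads sampled independently and fairly: ``K = 1/2**k``.
* ``beta_binomial`` — read proportions overdispersed, ``q ~ Beta(alpha,
  alpha)`` then ``Binomial(k, q)``:
  ``K = Gamma(k+a) Gamma(2a) / (Gamma(k+2a) Gamma(a))``.  Approaches the
  binomial model as ``alpha -> inf``.
* ``modified_p`` — Markovian reads: the first read is fair, each later read
  repeats the previous allele with probability ``p'``:
  ``K = 0.5 * p'**(k-1)``.  ``p' = 0.5`` recovers the binomial model.

All models satisfy ``K(1) = 0.5`` and are non-increasing in ``k``; depth-0
cells are missing and carry no ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import AlleleCountMatrix

__all__ = [
    "GenotypeCalls",
    "ReadModel",
    "call_genotypes",
    "estimate_allele_freqs",
    "hw_disequilibrium",
    "filter_snps",
    "MISSING",
]

#: Sentinel for a missing genotype call (zero read depth).
MISSING = -1

FAMILIES = ("binomial", "beta_binomial", "modified_p")


@dataclass
class GenotypeCalls:
    """Naive genotype calls and read depths derived from allele counts.

    ``calls[i, s]`` counts reference alleles in the apparent genotype:
    2 for all-reference reads, 0 for all-alternate, 1 when both alleles were
    seen, :data:`MISSING` when depth is zero.
    """

    calls: np.ndarray
    depths: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def nonmissing(self) -> np.ndarray:
        return self.calls != MISSING


def call_genotypes(counts: AlleleCountMatrix) -> GenotypeCalls:
    """Call apparent genotypes: homozygous calls are taken at face value,
    a cell is heterozygous only when both alleles were read."""
    ref, alt = counts.ref, counts.alt
    calls = np.full(ref.shape, MISSING, dtype=np.int8)
    calls[(ref > 0) & (alt == 0)] = 2
    calls[(ref == 0) & (alt > 0)] = 0
    calls[(ref > 0) & (alt > 0)] = 1
    return GenotypeCalls(calls=calls, depths=ref + alt)


def estimate_allele_freqs(counts: AlleleCountMatrix, individuals=None) -> np.ndarray:
    """Reference-allele frequency per SNP from pooled read counts.

    Frequencies are estimated as total reference reads over total reads
    across the given individuals (all individuals by default).  SNPs with no
    reads in the subset get ``nan`` (unusable).
    """
    if individuals is not None:
        if len(individuals) == 0:
            raise ValueError("cannot estimate allele frequencies from an empty subset")
        if isinstance(individuals[0], str):
            individuals = [counts.index_of(i) for i in individuals]
        ref = counts.ref[individuals]
        alt = counts.alt[individuals]
    else:
        ref, alt = counts.ref, counts.alt
    tot_ref = ref.sum(axis=0).astype(float)
    tot = (ref + alt).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, tot_ref / np.where(tot > 0, tot, 1.0), np.nan)
    return p


@dataclass(frozen=True)
class ReadModel:
    """Allele-sampling model mapping read depth ``k`` to the heterozygote
    single-allele probability ``K``.

    Parameters
    ----------
    family
        ``"binomial"`` (no parameter), ``"beta_binomial"`` (``param`` is
        ``alpha > 0``) or ``"modified_p"`` (``param`` is ``p'`` in
        ``[0.5, 1)``).
    k_max
        Depths up to ``k_max`` use a precomputed lookup table; larger depths
        fall back to the closed form.
    """

    family: str = "binomial"
    param: float | None = None
    k_max: int = 500

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown read-model family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "beta_binomial":
            if self.param is None or self.param <= 0:
                raise ValueError("beta_binomial requires alpha > 0")
        elif self.family == "modified_p":
            if self.param is None or not (0.5 <= self.param < 1.0):
                raise ValueError("modified_p requires p' in [0.5, 1)")
        elif self.param is not None:
            raise ValueError("binomial model takes no parameter")

    def _closed_form(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        if self.family == "binomial":
            out = np.exp(-k * np.log(2.0))
        elif self.family == "beta_binomial":
            a = float(self.param)
            # log-gamma space: Gamma(k+a)Gamma(2a) / (Gamma(k+2a)Gamma(a))
            out = np.exp(gammaln(k + a) + gammaln(2 * a) - gammaln(k + 2 * a) - gammaln(a))
        else:
            out = 0.5 * float(self.param) ** (k - 1.0)
        # round-off can nudge K(1) above 0.5; deep cells can underflow to 0
        return np.clip(out, np.finfo(float).tiny, 0.5)

    @property
    def _table(self) -> np.ndarray:
        tab = getattr(self, "_table_cache", None)
        if tab is None:
            tab = self._closed_form(np.arange(1, self.k_max + 1))
            object.__setattr__(self, "_table_cache", tab)
        return tab

    def k_probability(self, k) -> np.ndarray | float:
        """``K`` for each depth in *k*; every depth must be >= 1."""
        k_arr = np.asarray(k)
        if (k_arr < 1).any():
            raise ValueError("K is undefined at depth < 1")
        small = k_arr <= self.k_max
        out = np.empty(k_arr.shape, dtype=float)
        out[small] = self._table[k_arr[small] - 1]
        if (~small).any():
            out[~small] = self._closed_form(k_arr[~small])
        return out if out.ndim else float(out)

    def label(self) -> str:
        if self.family == "binomial":
            return "binomial"
        return f"{self.family}({self.param:g})"


def hw_disequilibrium(calls: GenotypeCalls, p: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg disequilibrium per SNP: observed frequency of the
    reference-allele homozygote call minus its HWE expectation ``p**2``.

    Strongly negative values (with high depth) flag collapsed duplicated
    loci.  SNPs with no non-missing calls get ``nan``.
    """
    nonmiss = calls.nonmissing
    n_called = nonmiss.sum(axis=0).astype(float)
    n_hom_ref = (calls.calls == 2).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(n_called > 0, n_hom_ref / np.where(n_called > 0, n_called, 1.0), np.nan)
    return obs - np.asarray(p, dtype=float) ** 2


def filter_snps(
    calls: GenotypeCalls,
    p: np.ndarray,
    hwdis_min: float = -0.05,
    maf_min: float = 0.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """SNP retention mask under the Hardy-Weinberg and MAF filters.

    A SNP is retained when its disequilibrium ``d >= hwdis_min`` (the rule
    excludes values strictly *below* the threshold) and its minor allele
    frequency exceeds ``maf_min`` (the default 0 discards monomorphic SNPs).
    Returns the boolean mask and per-rule exclusion counts.
    """
    if not (-1.0 <= hwdis_min <= 1.0):
        raise ValueError("hwdis_min must lie in [-1, 1]")
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    p = np.asarray(p, dtype=float)
    d = hw_disequilibrium(calls, p)
    usable = np.isfinite(p)
    maf = np.minimum(p, 1.0 - p)
    fail_hw = np.isfinite(d) & (d < hwdis_min)
    fail_maf = usable & ~(maf > maf_min)
    keep = usable & ~fail_hw & ~fail_maf & np.isfinite(d)
    counts = {
        "unusable": int((~usable).sum() + (usable & ~np.isfinite(d)).sum()),
        "hw_disequilibrium": int(fail_hw.sum()),
        "maf": int((fail_maf & ~fail_hw).sum()),
        "retained": int(keep.sum()),
    }
    return keep, counts
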