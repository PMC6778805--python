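"""Independent oracles used by the tests.

Everything here is written from first principles against the probability
model itself — exhaustive enumeration over true genotypes and observation
outcomes, and direct sequential read simulation — deliberately sharing no
code with the package so agreement is evidence, not tautology.
"""

import numpy as np


def hwe(p):
    """True-genotype distribution (reference dosage) at HWE."""
    return {2: p * p, 1: 2 * p * (1 - p), 0: (1 - p) ** 2}


def gametes(g):
    """Distribution of the transmitted allele (1 = reference) from dosage g."""
    return {1: 0.5, 0: 0.5} if g == 1 else {g // 2: 1.0}


def observe(g, K):
    """Apparent-class distribution given true dosage and heterozygote
    single-allele probability K."""
    if g != 1:
        return {g: 1.0}
    return {2: K, 0: K, 1: 1 - 2 * K}


def apparent_pair_mismatch(c_o, c_p):
    """Opposing apparent homozygotes."""
    return (c_o == 2 and c_p == 0) or (c_o == 0 and c_p == 2)


def apparent_trio_mismatch(c_o, c_f, c_m):
    """Mendelian impossibility of the apparent triple read as true."""
    if apparent_pair_mismatch(c_o, c_f) or apparent_pair_mismatch(c_o, c_m):
        return True
    if c_o == 1 and c_f == c_m and c_f != 1:
        return True
    if c_o != 1 and c_f != 1 and c_m != 1 and c_f != c_m:
        return True
    return False


def enumerate_pair(p, K_p, K_o):
    """P(apparent mismatch | offspring apparent class) for a single
    parent-offspring pair, by exhaustive enumeration: parent drawn from
    HWE, offspring = one parental gamete + one population allele."""
    num = {0: 0.0, 1: 0.0, 2: 0.0}
    den = {0: 0.0, 1: 0.0, 2: 0.0}
    for g_p, w_p in hwe(p).items():
        for a_p, w_a in gametes(g_p).items():
            for a_pop, w_pop in {1: p, 0: 1 - p}.items():
                g_o = a_p + a_pop
                w = w_p * w_a * w_pop
                for c_p, w_cp in observe(g_p, K_p).items():
                    for c_o, w_co in observe(g_o, K_o).items():
                        ww = w * w_cp * w_co
                        den[c_o] += ww
                        if apparent_pair_mismatch(c_o, c_p):
                            num[c_o] += ww
    return {c: num[c] / den[c] for c in (0, 1, 2)}


def enumerate_trio(p, K_f, K_m, K_o):
    """P(apparent mismatch | offspring apparent class) for a trio, by
    exhaustive enumeration over both parents' HWE genotypes, Mendelian
    transmission and all observation outcomes."""
    num = {0: 0.0, 1: 0.0, 2: 0.0}
    den = {0: 0.0, 1: 0.0, 2: 0.0}
    for g_f, w_f in hwe(p).items():
        for g_m, w_m in hwe(p).items():
            for a_f, w_af in gametes(g_f).items():
                for a_m, w_am in gametes(g_m).items():
                    g_o = a_f + a_m
                    w = w_f * w_m * w_af * w_am
                    for c_f, w_cf in observe(g_f, K_f).items():
                        for c_m, w_cm in observe(g_m, K_m).items():
                            for c_o, w_co in observe(g_o, K_o).items():
                                ww = w * w_cf * w_cm * w_co
                                den[c_o] += ww
                                if apparent_trio_mismatch(c_o, c_f, c_m):
                                    num[c_o] += ww
    return {c: num[c] / den[c] for c in (0, 1, 2)}


def mendelian_impossible_triples():
    """All (father, mother, offspring) dosage triples impossible under
    Mendelian inheritance, by brute-force enumeration of allele draws."""
    impossible = set()
    for g_f in (0, 1, 2):
        for g_m in (0, 1, 2):
            reachable = set()
            for a_f in ((0, 1) if g_f == 1 else (g_f // 2,)):
                for a_m in ((0, 1) if g_m == 1 else (g_m // 2,)):
                    reachable.add(a_f + a_m)
            for g_o in (0, 1, 2):
                if g_o not in reachable:
                    impossible.add((g_f, g_m, g_o))
    return impossible


def simulate_het_reads_sequential(family, param, k, n, rng):
    """Reference-read counts for n true heterozygotes at depth k, simulated
    read by read (independent of the package's vectorized generator)."""
    out = np.empty(n, dtype=int)
    for i in range(n):
        if family == "binomial":
            reads = rng.random(k) < 0.5
        elif family == "beta_binomial":
            q = rng.beta(param, param)
            reads = rng.random(k) < q
        elif family == "modified_p":
            reads = np.empty(k, dtype=bool)
            reads[0] = rng.random() < 0.5
            for j in range(1, k):
                reads[j] = reads[j - 1] if rng.random() < param else not reads[j - 1]
        else:
            raise ValueError(family)
        out[i] = int(reads.sum())
    return out
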