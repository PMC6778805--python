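"""The parentage assignment strategy.

Per offspring and parent sex: (1) rank the candidate set by estimated
relatedness and provisionally assign the best candidate; (2) veto the
assignment if relatedness is too low or the pair excess mismatch rate (EMM)
too high; (3) if the runner-up's relatedness is within the closeness
window, require high bootstrap support for the ranking; (4) with both
parents provisionally assigned, check the trio jointly — trio EMM, and the
inbreeding consistency ``r_FM - 2 F_O`` (for a true trio the offspring's
inbreeding equals half the parents' relatedness, so a large positive excess
flags a wrong pair); (5) if the best pair fails a trio check, search
combinations of the leading candidates for an alternate pair passing every
check.

Decision codes (one per offspring record):

``Y``
    both parents assigned, best-relatedness pair passed everything.
``A``
    an alternate pair (not the best-relatedness pair) was assigned after
    the best pair failed a trio check.
``E`` / ``I``
    both sexes passed their single-parent checks but every combination
    failed the trio checks; ``E`` when the best pair exceeded the trio EMM
    bound, ``I`` when it failed only the inbreeding consistency bound.
``F`` / ``M``
    only the sire (father) / only the dam (mother) assignment survived the
    single-parent checks.
``N``
    neither parent could be assigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CandidateTable
from .mismatch import pair_stats, trio_stats
from .read_model import GenotypeCalls, ReadModel
from .relatedness import RelatednessMatrix, bootstrap_support

__all__ = ["Thresholds", "AssignmentRecord", "rank_candidates", "apply_pair_thresholds",
           "resolve_close_candidates", "trio_checks", "assign_all"]


@dataclass(frozen=True)
class Thresholds:
    """Assignment thresholds; comparisons are inclusive (``>= rel_min``,
    ``<= emm_max`` pass).

    Defaults follow the working values established for low-depth GBS herds:
    relatedness at least 0.4; pair EMM at most 0.01; trio EMM at most 0.02
    (looser than the pair bound since any of three genotypes can mismatch);
    bootstrap run when the runner-up is within 0.05 relatedness, requiring
    support of at least 0.99; trio rejected when the parents' relatedness
    exceeds twice the offspring inbreeding by more than 0.2.
    """

    rel_min: float = 0.4
    emm_max: float = 0.01
    trio_emm_max: float = 0.02
    closeness_window: float = 0.05
    bootstrap_min: float = 0.99
    inbreeding_diff_max: float = 0.2
    n_boot: int = 1000
    n_alternates: int = 2
    rank_by: str = "relatedness"  # or "emm"

    def __post_init__(self):
        for name in ("emm_max", "trio_emm_max", "closeness_window", "bootstrap_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if not math.isfinite(self.rel_min):
            raise ValueError("rel_min must be finite")
        if self.n_boot < 1 or self.n_alternates < 1:
            raise ValueError("n_boot and n_alternates must be >= 1")
        if self.rank_by not in ("relatedness", "emm"):
            raise ValueError("rank_by must be 'relatedness' or 'emm'")


@dataclass
class ParentResult:
    """Outcome of the single-parent stages for one sex."""

    best: str | None = None
    r: float = float("nan")
    emm: float = float("nan")
    second: str | None = None
    gap: float = float("nan")
    bootstrap: float = float("nan")
    passed: bool = False
    reasons: list[str] = field(default_factory=list)
    tied: bool = False


@dataclass
class AssignmentRecord:
    """Full per-offspring assignment outcome, re-derivable from its metrics
    and the thresholds snapshot."""

    offspring: str
    sire: ParentResult
    dam: ParentResult
    assigned_sire: str | None
    assigned_dam: str | None
    trio_emm: float
    rfm_minus_2fo: float
    code: str
    thresholds: Thresholds

    def to_row(self) -> dict:
        t = self.thresholds
        return {
            "offspring": self.offspring,
            "code": self.code,
            "sire": self.assigned_sire or "",
            "sire_r": self.sire.r,
            "sire_emm": self.sire.emm,
            "sire_second": self.sire.second or "",
            "sire_gap": self.sire.gap,
            "sire_bootstrap": self.sire.bootstrap,
            "dam": self.assigned_dam or "",
            "dam_r": self.dam.r,
            "dam_emm": self.dam.emm,
            "dam_second": self.dam.second or "",
            "dam_gap": self.dam.gap,
            "dam_bootstrap": self.dam.bootstrap,
            "trio_emm": self.trio_emm,
            "rfm_minus_2fo": self.rfm_minus_2fo,
            "rel_min": t.rel_min,
            "emm_max": t.emm_max,
            "trio_emm_max": t.trio_emm_max,
            "closeness_window": t.closeness_window,
            "bootstrap_min": t.bootstrap_min,
            "inbreeding_diff_max": t.inbreeding_diff_max,
        }


def rank_candidates(grm: RelatednessMatrix, offspring: str, candidate_ids: list[str]):
    """Candidates ordered by relatedness to *offspring*, descending, ties
    broken by candidate id (flagged).  Candidates with no shared SNPs or
    identical to the offspring are dropped.

    Returns ``(ordered list of (id, r), tie_flag)``.
    """
    oi = grm.index_of(offspring)
    entries = []
    for cid in candidate_ids:
        if cid == offspring:
            continue
        ci = grm.index_of(cid)
        r = grm.r[oi, ci]
        if grm.n_snps[oi, ci] == 0 or not np.isfinite(r):
            continue
        entries.append((cid, float(r)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    tied = len(entries) >= 2 and entries[0][1] == entries[1][1]
    return entries, tied


def apply_pair_thresholds(r: float, pair_emm: float, thresholds: Thresholds):
    """Single-parent veto: pass iff ``r >= rel_min`` and ``EMM <= emm_max``
    (inclusive); returns ``(passed, reasons)``."""
    reasons = []
    if not (r >= thresholds.rel_min):
        reasons.append(f"relatedness {r:.4g} < {thresholds.rel_min}")
    if not (pair_emm <= thresholds.emm_max):
        reasons.append(f"EMM {pair_emm:.4g} > {thresholds.emm_max}")
    return not reasons, reasons


def resolve_close_candidates(
    calls: GenotypeCalls,
    p: np.ndarray,
    offspring: int,
    best: int,
    second: int,
    gap: float,
    thresholds: Thresholds,
    rng: np.random.Generator,
    valid=None,
):
    """Closeness stage: when the runner-up is within the closeness window,
    keep the assignment only with bootstrap support >= ``bootstrap_min``.

    Returns ``(keep, support)``; support is ``nan`` when no bootstrap ran.
    """
    if gap >= thresholds.closeness_window:
        return True, float("nan")
    support = bootstrap_support(
        calls, p, offspring, best, second,
        n_boot=thresholds.n_boot, seed=rng, valid=valid,
    )
    return support >= thresholds.bootstrap_min, support


def trio_checks(trio_emm: float, r_fm: float, f_o: float, thresholds: Thresholds):
    """Joint consistency checks for a provisional parent pair.

    Fails ``E`` when the trio EMM exceeds its bound and ``I`` when the
    parents' relatedness exceeds twice the offspring's inbreeding by more
    than the inbreeding bound (upper bound only).  An undefined inbreeding
    estimate skips the I-check.
    """
    reasons = []
    if trio_emm > thresholds.trio_emm_max:
        reasons.append("E")
    if math.isfinite(f_o):
        if r_fm - 2.0 * f_o > thresholds.inbreeding_diff_max:
            reasons.append("I")
    return not reasons, reasons


def _parent_stage(
    calls, p, grm, counts_index, offspring, candidate_ids, thresholds, model, rng, valid
) -> ParentResult:
    """Run ranking, pair thresholds and closeness resolution for one sex."""
    res = ParentResult()
    ranked, tied = rank_candidates(grm, offspring, candidate_ids)
    res.tied = tied
    if not ranked:
        res.reasons.append("no usable candidate")
        return res
    best_id, best_r = ranked[0]
    res.best, res.r = best_id, best_r
    oi = counts_index[offspring]
    stats = pair_stats(calls, oi, counts_index[best_id], p, model, valid=valid)
    res.emm = stats.emm if stats.defined else float("nan")
    ok, reasons = apply_pair_thresholds(best_r, res.emm, thresholds)
    res.reasons.extend(reasons)
    if len(ranked) >= 2:
        res.second, second_r = ranked[1][0], ranked[1][1]
        res.gap = best_r - second_r
        if ok:
            keep, support = resolve_close_candidates(
                calls, p, oi, counts_index[best_id], counts_index[res.second],
                res.gap, thresholds, rng, valid=valid,
            )
            res.bootstrap = support
            if not keep:
                ok = False
                res.reasons.append(
                    f"bootstrap support {support:.3f} < {thresholds.bootstrap_min} "
                    f"(gap {res.gap:.4g} within closeness window)"
                )
    res.passed = ok
    return res


def _pair_emm_ok(calls, p, oi, ci, thresholds, model, valid, grm, offspring, cid, cache):
    """Pair-threshold screen for an alternate candidate (cached)."""
    key = cid
    if key not in cache:
        r = grm.r[grm.index_of(offspring), grm.index_of(cid)]
        st = pair_stats(calls, oi, ci, p, model, valid=valid)
        e = st.emm if st.defined else float("nan")
        ok, _ = apply_pair_thresholds(float(r), e, thresholds)
        cache[key] = (ok, float(r), e)
    return cache[key]


def assign_all(
    counts,
    calls: GenotypeCalls,
    p: np.ndarray,
    grm: RelatednessMatrix,
    candidates: CandidateTable,
    thresholds: Thresholds | None = None,
    model: ReadModel | None = None,
    seed: int = 0,
    valid: np.ndarray | None = None,
) -> list[AssignmentRecord]:
    """Run the full assignment strategy for every offspring.

    EMM is evaluated only for the leading candidates per sex (relatedness
    ranks the full set first), keeping all-candidate scans cheap.  With an
    empty candidate set for one sex the trio stages are skipped and only the
    other sex can be assigned.  Per-offspring failures never abort the
    batch.  Deterministic given *seed*.
    """
    thresholds = thresholds or Thresholds()
    model = model or ReadModel("binomial")
    rng = np.random.default_rng(seed)
    counts_index = {iid: i for i, iid in enumerate(counts.individual_ids)}

    sires = [s for s in candidates.genotyped_sires() if s in counts_index]
    dams = [d for d in candidates.genotyped_dams() if d in counts_index]

    records: list[AssignmentRecord] = []
    for off in candidates.offspring_ids:
        if off not in counts_index:
            continue
        oi = counts_index[off]
        sire_res = _parent_stage(calls, p, grm, counts_index, off, sires, thresholds, model, rng, valid)
        dam_res = _parent_stage(calls, p, grm, counts_index, off, dams, thresholds, model, rng, valid)

        assigned_sire = assigned_dam = None
        trio_emm_val = rfm2fo = float("nan")
        f_o = grm.r[grm.index_of(off), grm.index_of(off)] - 1.0

        if sire_res.passed and dam_res.passed and sire_res.best != dam_res.best:
            ts = trio_stats(calls, oi, counts_index[sire_res.best], counts_index[dam_res.best], p, model, valid=valid)
            trio_emm_val = ts.emm if ts.defined else float("nan")
            r_fm = float(grm.r[grm.index_of(sire_res.best), grm.index_of(dam_res.best)])
            rfm2fo = r_fm - 2.0 * f_o
            ok, fail_codes = trio_checks(trio_emm_val, r_fm, f_o, thresholds)
            if ok:
                assigned_sire, assigned_dam = sire_res.best, dam_res.best
                code = "Y"
            else:
                alt = _search_alternates(
                    calls, p, grm, counts_index, off, oi, sires, dams,
                    sire_res, dam_res, thresholds, model, valid, f_o,
                )
                if alt is not None:
                    assigned_sire, assigned_dam, trio_emm_val, rfm2fo = alt
                    code = "A"
                else:
                    code = "E" if "E" in fail_codes else "I"
        elif sire_res.passed and dam_res.passed:
            # same individual topped both sets; cannot be both parents
            code = "N"
            sire_res.reasons.append("best sire and dam are the same individual")
        elif sire_res.passed:
            assigned_sire, code = sire_res.best, "F"
        elif dam_res.passed:
            assigned_dam, code = dam_res.best, "M"
        else:
            code = "N"

        records.append(
            AssignmentRecord(
                offspring=off,
                sire=sire_res,
                dam=dam_res,
                assigned_sire=assigned_sire,
                assigned_dam=assigned_dam,
                trio_emm=trio_emm_val,
                rfm_minus_2fo=rfm2fo,
                code=code,
                thresholds=thresholds,
            )
        )
    return records


def verify_recorded(
    counts,
    calls: GenotypeCalls,
    p: np.ndarray,
    grm: RelatednessMatrix,
    candidates: CandidateTable,
    thresholds: Thresholds | None = None,
    model: ReadModel | None = None,
    seed: int = 0,
    valid: np.ndarray | None = None,
) -> list[AssignmentRecord]:
    """Verification mode: check each offspring against its *recorded*
    parents only.

    Equivalent to assignment with single-candidate sets per offspring, so
    all metrics and codes carry the same meaning (closeness never triggers
    with one candidate).
    """
    records: list[AssignmentRecord] = []
    for off in candidates.offspring_ids:
        single = CandidateTable.__new__(CandidateTable)
        single._allow_overlap = True
        single.offspring_ids = [off]
        rec_s = candidates.recorded_sire.get(off)
        rec_d = candidates.recorded_dam.get(off)
        single.sire_candidate_ids = [rec_s] if rec_s else []
        single.dam_candidate_ids = [rec_d] if rec_d else []
        single.subpop = candidates.subpop
        single.recorded_sire = candidates.recorded_sire
        single.recorded_dam = candidates.recorded_dam
        single.ungenotyped = candidates.ungenotyped
        records.extend(
            assign_all(counts, calls, p, grm, single, thresholds=thresholds,
                       model=model, seed=seed, valid=valid)
        )
    return records


def _search_alternates(
    calls, p, grm, counts_index, off, oi, sires, dams,
    sire_res, dam_res, thresholds, model, valid, f_o,
):
    """Evaluate pairings of the top candidates after a trio-check failure.

    Combinations where either member fails the pair thresholds are skipped;
    among combinations passing all trio checks the one with the lowest trio
    EMM wins.  The best-relatedness pair itself is excluded (it already
    failed).  Returns ``(sire, dam, trio_emm, rfm_minus_2fo)`` or None.
    """
    n_alt = thresholds.n_alternates
    top_sires = [cid for cid, _ in rank_candidates(grm, off, sires)[0][:n_alt]]
    top_dams = [cid for cid, _ in rank_candidates(grm, off, dams)[0][:n_alt]]
    sire_cache: dict = {}
    dam_cache: dict = {}
    best_combo = None
    for s in top_sires:
        for d in top_dams:
            if s == d:
                continue
            if s == sire_res.best and d == dam_res.best:
                continue
            s_ok, _, _ = _pair_emm_ok(calls, p, oi, counts_index[s], thresholds, model, valid, grm, off, s, sire_cache)
            d_ok, _, _ = _pair_emm_ok(calls, p, oi, counts_index[d], thresholds, model, valid, grm, off, d, dam_cache)
            if not (s_ok and d_ok):
                continue
            ts = trio_stats(calls, oi, counts_index[s], counts_index[d], p, model, valid=valid)
            if not ts.defined:
                continue
            r_fm = float(grm.r[grm.index_of(s), grm.index_of(d)])
            ok, _ = trio_checks(ts.emm, r_fm, f_o, thresholds)
            if ok and (best_combo is None or ts.emm < best_combo[2]):
                best_combo = (s, d, ts.emm, r_fm - 2.0 * f_o)
    return best_combo
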