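"""Numerical kernel for the Global Distance Test search.

The GDT score at a distance cutoff j asks for the *maximal* fraction of
corresponding residues that can be brought within j Angstrom by some
rigid superposition.  Finding the true maximum is combinatorial, so — in
the spirit of the LGA family of programs — a deterministic seeded search
is used:

* seed superpositions come from every contiguous window of the common
  residues with lengths 3, 5 and 7, plus the all-common superposition;
  when the common set is small (<= EXHAUSTIVE_N residues) the contiguous
  windows are replaced by *every* residue triple and quadruple, which is
  affordable there and makes the search near-exhaustive;
* each seed is refined per cutoff by alternating (select residues within
  j) / (re-superpose on the selection) for at most MAX_ROUNDS rounds; in
  the exhaustive regime, when fewer than 3 residues fall inside the
  cutoff the 3 nearest residues are selected instead, so tight cutoffs
  can still descend;
* one "peel-off" trajectory starts from the all-common superposition and
  repeatedly discards the farthest residue and re-superposes, which
  reaches balanced subsets that no local seed refines into.

Every superposition examined is a least-squares (Kabsch) fit on some
subset of the common residues, so the search can never exceed the
exhaustive subset-superposition optimum; tests verify near-equality on
small instances.  The kernel is compiled with numba because all-vs-all
consensus scoring evaluates it hundreds of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_ROUNDS = 10
SEED_WINDOW_LENGTHS = (3, 5, 7)
#: below this common-set size, seed from every 3- and 4-subset
EXHAUSTIVE_N = 10


@njit(cache=True)
def _kabsch_rt(P, Q):
    """Least-squares rigid transform (R, t) mapping Q onto P: p ~ R q + t."""
    n = P.shape[0]
    pc = np.zeros(3)
    qc = np.zeros(3)
    for i in range(n):
        for a in range(3):
            pc[a] += P[i, a]
            qc[a] += Q[i, a]
    for a in range(3):
        pc[a] /= n
        qc[a] /= n
    H = np.zeros((3, 3))
    for i in range(n):
        for a in range(3):
            qa = Q[i, a] - qc[a]
            for b in range(3):
                H[a, b] += qa * (P[i, b] - pc[b])
    U, S, Vt = np.linalg.svd(H)
    # proper rotation: flip the smallest singular direction if det < 0
    d = np.linalg.det(Vt.T @ U.T)
    D = np.eye(3)
    if d < 0.0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    return R, t


@njit(cache=True)
def _rmsd_after(P, Q):
    """RMSD of Q onto P after optimal whole-set superposition."""
    R, t = _kabsch_rt(P, Q)
    n = P.shape[0]
    acc = 0.0
    for i in range(n):
        for a in range(3):
            x = R[a, 0] * Q[i, 0] + R[a, 1] * Q[i, 1] + R[a, 2] * Q[i, 2] + t[a]
            dx = x - P[i, a]
            acc += dx * dx
    return np.sqrt(acc / n)


@njit(cache=True)
def _fill_d2(P, Q, R, t, d2):
    """Squared distances of every residue pair under transform (R, t)."""
    n = P.shape[0]
    for i in range(n):
        dd = 0.0
        for a in range(3):
            x = R[a, 0] * Q[i, 0] + R[a, 1] * Q[i, 1] + R[a, 2] * Q[i, 2] + t[a]
            dx = x - P[i, a]
            dd += dx * dx
        d2[i] = dd


@njit(cache=True)
def _count_and_update(d2, thresholds2, best):
    """Update per-threshold best counts from a distance array."""
    n = d2.shape[0]
    for ti in range(thresholds2.shape[0]):
        c = 0
        for i in range(n):
            if d2[i] < thresholds2[ti]:
                c += 1
        if c > best[ti]:
            best[ti] = c


@njit(cache=True)
def _refine_from(P, Q, d2_seed, thresholds2, best, allow_fallback):
    """Per-threshold selection refinement from one seed's distances."""
    n = P.shape[0]
    sel = np.zeros(n, dtype=np.bool_)
    new_sel = np.zeros(n, dtype=np.bool_)
    d2 = np.empty(n, dtype=np.float64)
    for ti in range(thresholds2.shape[0]):
        if best[ti] == n:
            continue
        j2 = thresholds2[ti]
        for i in range(n):
            d2[i] = d2_seed[i]
        for i in range(n):
            sel[i] = False
        have_prev = False
        for _round in range(MAX_ROUNDS):
            cnt = 0
            for i in range(n):
                inside = d2[i] < j2
                new_sel[i] = inside
                if inside:
                    cnt += 1
            if cnt > best[ti]:
                best[ti] = cnt
            if cnt < 3:
                if not allow_fallback:
                    break
                # nearest-3 fallback keeps tight cutoffs descending
                order = np.argsort(d2)
                for i in range(n):
                    new_sel[i] = False
                for k in range(3):
                    new_sel[order[k]] = True
            if have_prev:
                same = True
                for i in range(n):
                    if new_sel[i] != sel[i]:
                        same = False
                        break
                if same:
                    break
            for i in range(n):
                sel[i] = new_sel[i]
            have_prev = True
            R, t = _kabsch_rt(P[sel], Q[sel])
            _fill_d2(P, Q, R, t, d2)
            _count_and_update(d2, thresholds2, best)


@njit(cache=True)
def _peel_off(P, Q, thresholds2, best):
    """Superpose on all residues, then iteratively drop the farthest."""
    n = P.shape[0]
    active = np.ones(n, dtype=np.bool_)
    n_active = n
    d2 = np.empty(n, dtype=np.float64)
    while n_active >= 3:
        R, t = _kabsch_rt(P[active], Q[active])
        _fill_d2(P, Q, R, t, d2)
        _count_and_update(d2, thresholds2, best)
        if n_active == 3:
            break
        worst = -1
        worst_d = -1.0
        for i in range(n):
            if active[i] and d2[i] > worst_d:
                worst_d = d2[i]
                worst = i
        active[worst] = False
        n_active -= 1


@njit(cache=True)
def _all_saturated(best, n):
    for ti in range(best.shape[0]):
        if best[ti] < n:
            return False
    return True


@njit(cache=True)
def _gdt_counts(P, Q, thresholds):
    """Best within-cutoff residue counts for each threshold (Angstrom).

    P, Q: (n, 3) CA coordinates of the common residues, same order.
    Returns an int64 array of counts, one per threshold.  Deterministic:
    no randomness, ties broken by residue order through the fixed seed
    enumeration.
    """
    n = P.shape[0]
    nt = thresholds.shape[0]
    best = np.zeros(nt, dtype=np.int64)
    thresholds2 = thresholds * thresholds
    d2 = np.empty(n, dtype=np.float64)

    # the all-common superposition is always a seed
    exhaustive = n <= EXHAUSTIVE_N
    R, t = _kabsch_rt(P, Q)
    _fill_d2(P, Q, R, t, d2)
    _count_and_update(d2, thresholds2, best)
    _refine_from(P, Q, d2, thresholds2, best, exhaustive)

    if exhaustive:
        sub = np.empty(4, dtype=np.int64)
        for size in (3, 4):
            if size > n or _all_saturated(best, n):
                break
            # lexicographic enumeration of all index subsets of this size
            for a in range(n):
                sub[0] = a
                for b in range(a + 1, n):
                    sub[1] = b
                    for c in range(b + 1, n):
                        sub[2] = c
                        if size == 3:
                            R, t = _kabsch_rt(P[sub[:3]], Q[sub[:3]])
                            _fill_d2(P, Q, R, t, d2)
                            _count_and_update(d2, thresholds2, best)
                            _refine_from(P, Q, d2, thresholds2, best, True)
                        else:
                            for e in range(c + 1, n):
                                sub[3] = e
                                R, t = _kabsch_rt(P[sub], Q[sub])
                                _fill_d2(P, Q, R, t, d2)
                                _count_and_update(d2, thresholds2, best)
                                _refine_from(P, Q, d2, thresholds2, best, True)
    else:
        for L in SEED_WINDOW_LENGTHS:
            if L > n or _all_saturated(best, n):
                break
            for s in range(n - L + 1):
                R, t = _kabsch_rt(P[s : s + L], Q[s : s + L])
                _fill_d2(P, Q, R, t, d2)
                _count_and_update(d2, thresholds2, best)
                _refine_from(P, Q, d2, thresholds2, best, False)
                if _all_saturated(best, n):
                    break

    if not _all_saturated(best, n):
        _peel_off(P, Q, thresholds2, best)
    return best
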