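"""Independent brute-force oracles used to validate the package.

Everything here is deliberately written the slow, obvious way (explicit
enumeration, per-column loops, fractions) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# --- global alignment: exhaustive enumeration -------------------------------


def enumerate_best_alignment_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by enumerating every alignment path.

    Gap cost convention: a run of k gap columns in one sequence costs
    gap_open + (k - 1) * gap_extend. Feasible only for short sequences.
    """
    best = -math.inf

    def walk(i: int, j: int, score: float, prev_op: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + matrix[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev_op == "X" else gap_open
            walk(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if prev_op == "Y" else gap_open
            walk(i, j + 1, score - cost, "Y")

    walk(0, 0, 0.0, "")
    return best


# --- Fisher's exact test: hypergeometric enumeration with exact fractions ---


def fisher_two_sided_exact(table) -> float:
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(aa: int) -> Fraction:
        b_ = r1 - aa
        c_ = c1 - aa
        d_ = n - r1 - c_
        if min(b_, c_, d_) < 0:
            return Fraction(0)
        return Fraction(
            math.comb(r1, aa) * math.comb(n - r1, c_), math.comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p <= p_obs:
            total += p
    return float(total)


# --- rank-sum: full labeling enumeration ------------------------------------


def ranksum_two_sided_exact(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all labelings (no ties)."""
    nx = len(x)
    pooled = sorted(list(x) + list(y))
    n = len(pooled)
    assert len(set(pooled)) == n, "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    mean_w = nx * (n + 1) / 2
    dev = abs(w_obs - mean_w)
    total = extreme = 0
    for combo in itertools.combinations(range(1, n + 1), nx):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-9:
            extreme += 1
    return extreme / total


# --- signed-rank: sign-assignment enumeration -------------------------------


def signed_rank_two_sided_exact(deltas) -> float:
    d = [v for v in deltas if v != 0]
    n = len(d)
    mags = sorted(abs(v) for v in d)
    assert len(set(mags)) == n, "oracle assumes untied magnitudes"
    rank = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(rank[abs(v)] for v in d if v > 0)
    mean_w = n * (n + 1) / 4
    dev = abs(w_obs - mean_w)
    total = extreme = 0
    for signs in itertools.product([0, 1], repeat=n):
        total += 1
        w = sum(rank[mags[i]] for i in range(n) if signs[i])
        if abs(w - mean_w) >= dev - 1e-9:
            extreme += 1
    return extreme / total


# --- conservation profile: naive per-column reimplementation ----------------


def naive_profile(sequences: list[str], window_radius: int, window_weight: float,
                  pseudocount: float, use_weighting: bool, background: dict) -> list[float]:
    """Windowed JSD conservation scores, computed with plain loops.

    ``background`` maps each of the 20 residue letters to its frequency.
    """
    alphabet = sorted(background)
    n = len(sequences)
    ncol = len(sequences[0])

    if use_weighting:
        raw_w = []
        for i in range(n):
            acc = 0.0
            for c in range(ncol):
                col = [s[c] for s in sequences]
                r = len(set(col))
                s_ci = col.count(sequences[i][c])
                acc += 1.0 / (r * s_ci)
            raw_w.append(acc / ncol)
        tot = sum(raw_w)
        weights = [w / tot for w in raw_w]
    else:
        weights = [1.0 / n] * n

    def col_score(c: int) -> float:
        mass = {a: 0.0 for a in alphabet}
        gap_w = 0.0
        for i in range(n):
            ch = sequences[i][c]
            if ch in mass:
                mass[ch] += weights[i]
            else:
                gap_w += weights[i]
        nongap = sum(mass.values())
        if nongap == 0:
            return 0.0
        denom = nongap + 20 * pseudocount
        p = [(mass[a] + pseudocount) / denom for a in alphabet]
        q = [background[a] for a in alphabet]
        m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
        kl_pm = sum(pi * math.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
        kl_qm = sum(qi * math.log2(qi / mi) for qi, mi in zip(q, m) if qi > 0)
        return (0.5 * kl_pm + 0.5 * kl_qm) * (1.0 - gap_w)

    raw = [col_score(c) for c in range(ncol)]
    out = []
    for c in range(ncol):
        neigh = [raw[j] for j in range(max(0, c - window_radius), min(ncol, c + window_radius + 1)) if j != c]
        if neigh:
            out.append((1 - window_weight) * raw[c] + window_weight * sum(neigh) / len(neigh))
        else:
            out.append(raw[c])
    return out
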