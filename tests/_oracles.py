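"""Independent brute-force oracles used by the test suite.

Each function here re-derives an expected answer by direct enumeration or
a closed formula, deliberately sharing no code with the implementation it
checks.
"""

from __future__ import annotations

import itertools
from math import comb, inf

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_merge(seq1: str, seq2: str, min_overlap: int, max_mismatch_rate: float):
    """Char-by-char enumeration of all overlap offsets for tiny reads.

    Returns (sequence, overlap_len, mismatches) or a rejection reason
    string, under the same scoring rules as the merger: best
    matches-minus-mismatches offset, mismatch-rate cap, ties ambiguous.
    """
    b = rc(seq2)
    L1, L2 = len(seq1), len(b)
    scored = []
    for s in range(-(L2 - min_overlap), L1 - min_overlap + 1):
        lo, hi = max(0, s), min(L1, s + L2)
        ov = hi - lo
        if ov < min_overlap:
            continue
        mm = sum(1 for i in range(lo, hi) if seq1[i] != b[i - s])
        scored.append((ov - 2 * mm, s, ov, mm))
    if not scored:
        return "no_overlap"
    best = max(sc for sc, *_ in scored)
    winners = [t for t in scored if t[0] == best]
    _, s, ov, mm = winners[0]
    if mm / ov > max_mismatch_rate:
        return "no_overlap" if best <= 0 else "too_many_mismatches"
    if len(winners) > 1:
        return "tie"
    left = seq1[: max(0, s)]
    mid = "".join(
        seq1[i] for i in range(max(0, s), min(L1, s + L2))
    )  # no quality info: take read 1 in the overlap
    right = b[min(L1, s + L2) - s :]
    return left + mid + right, ov, mm


def exhaustive_segmentation(
    interior: str,
    blocks: dict[str, str],
    caps: dict[str, int],
    unresolved_penalty: float = 1.5,
):
    """Complete enumeration of all tilings of ``interior`` into oriented
    blocks plus unannotated bases; returns (min cost, min unresolved at
    that cost, set of optimal contig strings).

    Feasible only for short interiors (a few blocks).
    """
    oriented = []
    for code, seq in blocks.items():
        oriented.append((code, "+", seq))
        oriented.append((code, "-", rc(seq)))

    best: dict = {"cost": inf, "unres": inf, "contigs": set()}

    def recurse(pos: int, cost: float, unres: int, contig: str):
        if cost > best["cost"] + 1e-9:
            return
        if pos == len(interior):
            key = (round(cost, 6), unres)
            cur = (round(best["cost"], 6) if best["cost"] < inf else inf, best["unres"])
            if key < cur:
                best["cost"], best["unres"] = cost, unres
                best["contigs"] = {contig}
            elif key == cur:
                best["contigs"].add(contig)
            return
        # any block, any admissible segment length (explored before the
        # gap branch so pruning bites early)
        for code, orient, seq in oriented:
            cap = caps[code]
            for ell in range(max(1, len(seq) - cap), len(seq) + cap + 1):
                if pos + ell > len(interior):
                    continue
                d = levenshtein(seq, interior[pos : pos + ell])
                if d <= cap:
                    recurse(pos + ell, cost + d, unres, contig + code)
        # unannotated base
        recurse(pos + 1, cost + unresolved_penalty, unres + 1, contig)

    recurse(0, 0.0, 0, "")
    return best["cost"], best["unres"], best["contigs"]


def gini_pairwise(counts) -> float:
    """Gini via the mean-absolute-difference formula
    sum_ij |x_i - x_j| / (2 n^2 mean)."""
    x = np.asarray([c for c in counts if c > 0], dtype=float)
    n = x.size
    if n == 1:
        return 0.0
    mad = np.abs(x[:, None] - x[None, :]).sum()
    return float(mad / (2 * n * n * x.mean()))


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table by direct hypergeometric enumeration:
    N = a+b+c+d draws, K = a+c feature-positive, n = a+b in-cluster."""
    N, K, n = a + b + c + d, a + c, a + b
    total = comb(N, n)
    num = sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(a, min(K, n) + 1)
        if n - x <= N - K
    )
    return num / total


def brute_select(freq_table, thresholds, pseudo_cpm=0.5):
    """Rule-by-rule reimplementation of the three-rule candidate filter on
    a small dict-of-dicts frequency table {contig: {sample: count}}."""
    contigs = list(freq_table)
    samples = list(next(iter(freq_table.values())))
    totals = {s: sum(freq_table[c][s] for c in contigs) for s in samples}
    cell = [s for s in samples if s not in ("raw", "plasmid", "virus")]

    def cpm(c, s):
        return freq_table[c][s] / totals[s] * 1e6

    selected = set()
    pooled = {
        c: sum(freq_table[c][s] for s in cell) for c in contigs
    }
    pooled_total = sum(pooled.values())
    order = sorted(contigs, key=lambda c: -pooled[c])
    cum = 0.0
    cutoff_freq = None
    for c in order:
        cum += pooled[c] / pooled_total
        cutoff_freq = pooled[c] / pooled_total
        if cum >= thresholds.cumulative_mass:
            break
    in_mass = {c for c in contigs if pooled[c] / pooled_total >= cutoff_freq}

    for c in contigs:
        rule1 = freq_table[c]["virus"] / totals["virus"] >= thresholds.min_baseline_freq
        n_up = sum(
            (cpm(c, s) + pseudo_cpm) / (cpm(c, "virus") + pseudo_cpm)
            > thresholds.min_fold_change
            for s in cell
        )
        rule2 = n_up >= thresholds.min_timepoints_above
        rule3 = c in in_mass
        if rule1 and rule2 and rule3:
            selected.add(c)
    return selected
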