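"""Independent brute-force oracles used to validate the package's algorithms.

Each oracle re-derives its quantity from first principles (exhaustive
enumeration, direct recursion, or a literal re-execution of the published
procedure) without sharing code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = "*"


def _aa(codon: str) -> str:
    return _FORWARD[codon]


# ---------------------------------------------------------------------------
# NG86 brute force


def ng86_sites_brute(codon: str) -> tuple[float, float]:
    syn = nonsyn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) == _aa(codon):
                syn += 1
            else:
                nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


def ng86_pair_brute(codons_a: list[str], codons_b: list[str]):
    """Full NG86 on two equal-length codon lists, by direct enumeration.

    Returns (S, N, Sd, Nd) with pathway averaging over stop-free paths
    (all paths if every one passes through a stop).
    """
    s_sites = n_sites = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, na = ng86_sites_brute(ca)
        sb, nb = ng86_sites_brute(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        positions = [i for i in range(3) if ca[i] != cb[i]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            current = ca
            syn = non = 0
            through_stop = False
            for pos in order:
                nxt = current[:pos] + cb[pos] + current[pos + 1 :]
                if _aa(nxt) == "*":
                    through_stop = True
                if _aa(nxt) == _aa(current):
                    syn += 1
                else:
                    non += 1
                current = nxt
            paths.append((through_stop, syn, non))
        usable = [p for p in paths if not p[0]] or paths
        sd += sum(p[1] for p in usable) / len(usable)
        nd += sum(p[2] for p in usable) / len(usable)
    return s_sites, n_sites, sd, nd


# ---------------------------------------------------------------------------
# alignment brute force


def local_align_score_brute(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Best Smith-Waterman score by recursive enumeration of all local
    alignments (every substring pair, every gapped path).  A gap of length
    L scores gap_open + (L - 1) * gap_extend.  Exponential: tiny inputs only.
    """

    @lru_cache(maxsize=None)
    def best_global(sa: str, sb: str, state: str) -> float:
        # state: last column kind ("m", "a" = gap in a, "b" = gap in b, "s" = start)
        if not sa and not sb:
            return 0.0
        options = []
        if sa and sb:
            sub = match if sa[0] == sb[0] else mismatch
            options.append(sub + best_global(sa[1:], sb[1:], "m"))
        if sb:  # consume from b, gap in a
            cost = gap_extend if state == "a" else gap_open
            options.append(cost + best_global(sa, sb[1:], "a"))
        if sa:
            cost = gap_extend if state == "b" else gap_open
            options.append(cost + best_global(sa[1:], sb, "b"))
        return max(options)

    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1, len(b) + 1):
                    sub_a, sub_b = a[i1:i2], b[j1:j2]
                    if (sub_a == "") != (sub_b == ""):
                        continue  # a local alignment aligns something on both
                    best = max(best, best_global(sub_a, sub_b, "s"))
    best_global.cache_clear()
    return best


def global_align_score_brute(a: str, b: str, score_pair, gap_open, gap_extend):
    """Best global alignment score by recursion over column choices.

    ``score_pair(x, y)`` scores a substitution column; gap runs of length L
    cost gap_open + (L - 1) * gap_extend (as penalties, subtracted).
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score_pair(a[i], b[j]) + rec(i + 1, j + 1, "m"))
        if j < len(b):
            cost = gap_extend if state == "a" else gap_open
            options.append(-cost + rec(i, j + 1, "a"))
        if i < len(a):
            cost = gap_extend if state == "b" else gap_open
            options.append(-cost + rec(i + 1, j, "b"))
        return max(options)

    result = rec(0, 0, "s")
    rec.cache_clear()
    return result


# ---------------------------------------------------------------------------
# collinear chain brute force


def longest_chain_brute(pairs, max_rank_gap):
    """Longest strictly monotone anchor chain by exhaustive subset search.

    ``pairs`` is a list of (rank_a, rank_b).  Both orientations are tried.
    Exponential (2^n): keep n small.
    """
    n = len(pairs)
    best = 0
    indices = list(range(n))
    for size in range(n, 0, -1):
        if size <= best:
            break
        for subset in itertools.combinations(indices, size):
            chosen = sorted(pairs[i] for i in subset)
            for sign in (1, -1):
                ok = True
                for (ra1, rb1), (ra2, rb2) in zip(chosen, chosen[1:]):
                    da = ra2 - ra1
                    db = sign * (rb2 - rb1)
                    if da <= 0 or db <= 0 or da > max_rank_gap or db > max_rank_gap:
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    break
        if best == size:
            break
    return best


def chain_is_valid(ranks, max_rank_gap):
    """Check one chain of (rank_a, rank_b) anchors for strict monotonicity
    and the rank-gap bound in either orientation."""
    for sign in (1, -1):
        ok = True
        for (ra1, rb1), (ra2, rb2) in zip(ranks, ranks[1:]):
            da = ra2 - ra1
            db = sign * (rb2 - rb1)
            if da <= 0 or db <= 0 or da > max_rank_gap or db > max_rank_gap:
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# median-Ks clustering re-execution


def median_ks_cluster_brute(ids, ks):
    """Literal re-execution of the published five-step procedure.

    ``ks[(a, b)]`` (sorted tuple key) holds pairwise Ks or None.  Returns
    the merge list [(members_a, members_b, height)] in merge order, with
    member tuples sorted.
    """

    def pair_ks(a, b):
        return ks.get(tuple(sorted((a, b))))

    clusters = [(g,) for g in ids]
    merges = []
    while len(clusters) > 1:
        candidates = []
        for x, y in itertools.combinations(sorted(clusters), 2):
            values = sorted(
                v
                for v in (pair_ks(a, b) for a in x for b in y)
                if v is not None
            )
            if not values:
                continue
            mid = len(values) // 2
            med = (
                values[mid]
                if len(values) % 2
                else (values[mid - 1] + values[mid]) / 2.0
            )
            candidates.append((med, min(min(x), min(y)), max(min(x), min(y)), x, y))
        if not candidates:
            raise ValueError("stranded clusters")
        med, _, _, x, y = min(candidates)
        clusters.remove(x)
        clusters.remove(y)
        merged = tuple(sorted(x + y))
        clusters.append(merged)
        merges.append((tuple(sorted(x)), tuple(sorted(y)), med))
    return merges
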