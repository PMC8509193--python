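"""Independent oracles used by the MC tests.

Everything here is written from scratch against the process *definitions*
(sequential distance-weighted matching; element classification) and never
calls the package's rejoining or classification code, so it can serve as a
brute-force reference for both.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

Outcome = tuple[frozenset, frozenset]  # (junction pairs, free end indices)


def enumerate_matching(
    end_positions: list[tuple[float, float, float]],
    lesion_of: list[int],
    r0: float,
    c_free: float,
) -> dict[Outcome, float]:
    """Exact outcome distribution of the sequential matching process.

    Enumerates every visit permutation and every categorical draw, returning
    a map from (junction set, free set) to its probability. End indices are
    positions in ``end_positions``; ``lesion_of[i]`` identifies sibling ends
    (same value = born at the same lesion, forbidden to pair).
    """
    n = len(end_positions)
    weight = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            d = math.dist(end_positions[i], end_positions[j])
            weight[i][j] = math.exp(-d / r0)

    outcomes: dict[Outcome, float] = defaultdict(float)

    def walk(perm, k, state, junctions, prob):
        while k < n and state[perm[k]] != 0:
            k += 1
        if k == n:
            free = frozenset(i for i in range(n) if state[i] == 2)
            outcomes[(frozenset(junctions), free)] += prob
            return
        i = perm[k]
        eligible = [
            j for j in range(n)
            if state[j] == 0 and j != i and lesion_of[j] != lesion_of[i]
        ]
        total = c_free + sum(weight[i][j] for j in eligible)
        if total <= 0.0:
            state2 = list(state)
            state2[i] = 2
            walk(perm, k + 1, tuple(state2), junctions, prob)
            return
        for j in eligible:
            state2 = list(state)
            state2[i] = state2[j] = 1
            walk(
                perm, k + 1, tuple(state2),
                junctions + ((min(i, j), max(i, j)),),
                prob * weight[i][j] / total,
            )
        if c_free > 0.0:
            state2 = list(state)
            state2[i] = 2
            walk(perm, k + 1, tuple(state2), junctions, prob * c_free / total)

    perms = list(itertools.permutations(range(n)))
    for perm in perms:
        walk(perm, 0, (0,) * n, (), 1.0 / len(perms))
    return dict(outcomes)


def oracle_classify(
    lesions: list[tuple[int, float]],
    chrom_info: dict[int, tuple[float, float]],
    junctions: frozenset,
    visibility_mbp: float = 3.0,
) -> tuple[int, int, int]:
    """(dicentrics, centric rings, deletions) for one matching outcome.

    ``lesions`` is a list of (chromosome, genomic coordinate); end 2i / 2i+1
    are the left/right ends of lesion i. ``chrom_info`` maps chromosome to
    (length, centromere). Cyclicity is decided by counting open extremities
    (telomeres or unjoined lesion ends): a closed ring has none.
    """
    # fragments per chromosome: (chrom, start, stop, left_end, right_end)
    frags = []
    by_chrom: dict[int, list[int]] = defaultdict(list)
    for idx, (chrom, _) in enumerate(lesions):
        by_chrom[chrom].append(idx)
    for chrom, idxs in by_chrom.items():
        length, _ = chrom_info[chrom]
        idxs = sorted(idxs, key=lambda i: lesions[i][1])
        cuts = [lesions[i][1] for i in idxs]
        bounds = [0.0] + cuts + [length]
        for j in range(len(bounds) - 1):
            left = 2 * idxs[j - 1] + 1 if j > 0 else None
            right = 2 * idxs[j] if j < len(idxs) else None
            frags.append((chrom, bounds[j], bounds[j + 1], left, right))

    end_frag = {}
    for f, (_, _, _, left, right) in enumerate(frags):
        for end in (left, right):
            if end is not None:
                end_frag[end] = f

    joined_ends = set()
    adjacency: dict[int, list[int]] = defaultdict(list)
    for a, b in junctions:
        joined_ends.update((a, b))
        adjacency[end_frag[a]].append(end_frag[b])
        adjacency[end_frag[b]].append(end_frag[a])

    seen = set()
    dic = rings = dels = 0
    for start in range(len(frags)):
        if start in seen:
            continue
        stack = [start]
        component = set()
        while stack:
            f = stack.pop()
            if f in component:
                continue
            component.add(f)
            stack.extend(adjacency[f])
        seen |= component

        open_extremities = 0
        n_cen = 0
        length_sum = 0.0
        for f in component:
            chrom, start_mbp, stop_mbp, left, right = frags[f]
            length_sum += stop_mbp - start_mbp
            chrom_len, cen = chrom_info[chrom]
            if start_mbp < cen <= stop_mbp:
                n_cen += 1
            for end in (left, right):
                if end is None or end not in joined_ends:
                    open_extremities += 1
        cyclic = open_extremities == 0
        if n_cen >= 2:
            dic += n_cen - 1
        elif n_cen == 1 and cyclic:
            rings += 1
        elif n_cen == 0 and length_sum >= visibility_mbp:
            dels += 1
    return dic, rings, dels


def enumerate_tally_distribution(
    lesions: list[tuple[int, float]],
    positions: list[tuple[float, float, float]],
    chrom_info: dict[int, tuple[float, float]],
    r0: float,
    c_free: float,
    visibility_mbp: float = 3.0,
) -> dict[tuple[int, int, int], float]:
    """Exact tally distribution: enumeration composed with the classifier."""
    end_positions = [positions[i // 2] for i in range(2 * len(lesions))]
    lesion_of = [i // 2 for i in range(2 * len(lesions))]
    outcomes = enumerate_matching(end_positions, lesion_of, r0, c_free)
    dist: dict[tuple[int, int, int], float] = defaultdict(float)
    for (junctions, _free), prob in outcomes.items():
        tally = oracle_classify(lesions, chrom_info, junctions, visibility_mbp)
        dist[tally] += prob
    return dict(dist)
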