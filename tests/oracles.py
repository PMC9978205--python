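"""Independent brute-force oracles, deliberately naive.

These re-derive expected results with explicit Python loops and
``math.dist`` so they share no code path with the vectorized
implementations they check.
"""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

CATEGORIES = sorted(
    ["acceptor", "donor", "aromatic", "hydrophobic",
     "negative", "neutral", "positive", "sulfide"]
)


def naive_signature(coords, category_sets, step, limit, mode="cumulative"):
    """Triple loop over (atom pairs x bins x category pairs).

    Returns {(cat1, cat2): [count per bin]} with closed right bin edges.
    """
    n_bins = int(round(limit / step))
    out = {}
    for c1, c2 in combinations_with_replacement(CATEGORIES, 2):
        series = [0] * n_bins
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                s_i, s_j = category_sets[i], category_sets[j]
                if not ((c1 in s_i and c2 in s_j) or (c2 in s_i and c1 in s_j)):
                    continue
                d = math.dist(coords[i], coords[j])
                for k in range(1, n_bins + 1):
                    if mode == "cumulative":
                        if d <= k * step:
                            series[k - 1] += 1
                    else:
                        if (k - 1) * step < d <= k * step:
                            series[k - 1] += 1
        out[(c1, c2)] = series
    return out


def naive_distance_matrix(coords):
    n = len(coords)
    return [
        [math.dist(coords[i], coords[j]) for j in range(n)] for i in range(n)
    ]


def naive_contacts(coords_a, coords_b, cutoff):
    """All (i, j, d) pairs across two coordinate lists with d <= cutoff."""
    pairs = []
    for i, p in enumerate(coords_a):
        for j, q in enumerate(coords_b):
            d = math.dist(p, q)
            if d <= cutoff:
                pairs.append((i, j, d))
    return pairs
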