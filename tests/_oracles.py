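"""Independent brute-force oracles used only by the test suite.

None of these call the implementation paths they check (no scipy, no
ccmkit scoring internals): CCM2 is recomputed character by character,
the Mann-Whitney null is enumerated over rank assignments, and the KS
statistic is a direct ECDF supremum.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

LIMB_PARTITIONS = {"pectoral_girdle", "forelimb", "pelvic_girdle", "hindlimb"}


def brute_ccm2(cmap, elements, limbless):
    """Per-character loop: applicable then scorable, no set algebra."""
    scorable = 0
    applicable = 0
    for cid, req in cmap.characters.items():
        parts = {cmap.element_partition[e] for e in req}
        if limbless and parts & LIMB_PARTITIONS:
            continue
        applicable += 1
        if all(e in elements for e in req):
            scorable += 1
    return scorable, applicable


def mw_u(x, y):
    """U statistic of x by direct pair counting (ties add 1/2)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mw_enum_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating rank assignments.

    Tie-free samples only.  Returns (U_x, p).  The null distribution of U
    is built by assigning every size-|x| subset of the pooled sample to x;
    p = min(1, 2·min(P(U ≤ u), P(U ≥ u))).
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n_x = len(x)
    u_obs = mw_u(x, y)
    us = []
    for subset in combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        us.append(mw_u(xs, ys))
    us = np.array(us)
    total = len(us)
    p_le = np.sum(us <= u_obs) / total
    p_ge = np.sum(us >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def mw_null_distribution(n_x, n_y):
    """Exact null distribution of U by enumerating rank assignments.

    Returns a dict U -> count over all C(n_x+n_y, n_x) equally likely
    assignments of the pooled ranks to x.  Shared across configurations of
    the same sizes; still pure enumeration, independent of scipy.
    """
    n = n_x + n_y
    counts: dict[float, int] = {}
    for subset in combinations(range(n), n_x):
        sset = set(subset)
        xs = [i for i in range(n)]
        u = mw_u([i for i in subset], [i for i in xs if i not in sset])
        counts[u] = counts.get(u, 0) + 1
    return counts


def mw_p_from_null(u_obs, counts):
    total = sum(counts.values())
    p_le = sum(c for u, c in counts.items() if u <= u_obs) / total
    p_ge = sum(c for u, c in counts.items() if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def ks_d_direct(x, y):
    """sup over pooled observed points of |ECDF_x − ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        d = max(d, abs(fx - fy))
    return d


def random_region_map(rng, max_chars=50):
    """A random small CharacterRegionMap for property tests."""
    from ccmkit.charmap import PARTITIONS, CharacterRegionMap

    n_parts = rng.integers(2, len(PARTITIONS) + 1)
    parts = list(rng.choice(PARTITIONS, size=n_parts, replace=False))
    element_partition = {}
    for p in parts:
        for k in range(rng.integers(1, 4)):
            element_partition[f"{p}_el{k}"] = p
    elements = list(element_partition)
    n_chars = int(rng.integers(1, max_chars + 1))
    characters = {}
    for cid in range(1, n_chars + 1):
        size = 1 if rng.random() < 0.8 else int(rng.integers(2, 4))
        size = min(size, len(elements))
        req = rng.choice(elements, size=size, replace=False)
        characters[cid] = frozenset(req.tolist())
    return CharacterRegionMap(
        characters=characters, element_partition=element_partition
    )


def random_record(rng, cmap, species_id="sp"):
    from ccmkit.scoring import PreservationRecord

    elements = sorted(cmap.elements)
    keep = [e for e in elements if rng.random() < rng.uniform(0.1, 0.9)]
    limbless = bool(rng.random() < 0.3)
    if limbless:
        keep = [
            e for e in keep
            if cmap.element_partition[e] not in LIMB_PARTITIONS
        ]
    return PreservationRecord(
        species_id=species_id, elements=frozenset(keep), limbless=limbless
    )
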