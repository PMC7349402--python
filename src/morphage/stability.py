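"""Overlap of selected feature/region sets across harmonization strategies.

The Jaccard index J(A, B) = |A n B| / |A u B| measures how stable the
selected anatomical regions are to the choice of harmonization; its
significance is assessed against a null of size-preserving random subsets
of the region universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom


def jaccard(a, b) -> float:
    """|A n B| / |A u B|; undefined (error) when both sets are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(sa & sb) / len(sa | sb)


@dataclass
class StabilityResult:
    jaccard: float
    p_value: float
    n_permutations: int
    set_a: frozenset
    set_b: frozenset
    universe_size: int
    null_jaccard: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "set_a": sorted(self.set_a),
            "set_b": sorted(self.set_b),
            "shared": sorted(self.set_a & self.set_b),
            "universe_size": self.universe_size,
        }


def jaccard_permutation_test(a, b, universe, n_perm: int = 10_000,
                             seed: int = 0) -> StabilityResult:
    """One-sided permutation test for larger-than-chance overlap.

    The null redraws, ``n_perm`` times, subsets of sizes |A| and |B|
    uniformly without replacement from the universe; the p-value uses the
    add-one correction p = (1 + #{J_null >= J_obs}) / (1 + n_perm).
    """
    sa, sb = set(a), set(b)
    uni = sorted(set(universe))
    if not sa <= set(uni) or not sb <= set(uni):
        raise ValueError("A and B must be subsets of the universe")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    j_obs = jaccard(sa, sb)
    rng = np.random.default_rng(seed)
    u = len(uni)
    na, nb = len(sa), len(sb)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = rng.choice(u, size=na, replace=False)
        pb = rng.choice(u, size=nb, replace=False)
        inter = np.intersect1d(pa, pb, assume_unique=True).size
        null[i] = inter / (na + nb - inter)
    p = (1 + int(np.sum(null >= j_obs))) / (1 + n_perm)
    return StabilityResult(j_obs, p, n_perm, frozenset(sa), frozenset(sb),
                           u, null)


def expected_null_jaccard(n_a: int, n_b: int, universe_size: int) -> float:
    """Exact expectation of J for random subsets, via the hypergeometric
    overlap distribution (an oracle for the permutation null)."""
    ks = np.arange(max(0, n_a + n_b - universe_size), min(n_a, n_b) + 1)
    pmf = hypergeom.pmf(ks, universe_size, n_a, n_b)
    with np.errstate(invalid="ignore"):
        j = np.where(n_a + n_b - ks > 0, ks / (n_a + n_b - ks), 1.0)
    return float(np.sum(pmf * j))
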