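"""Fritz–Purvis D: phylogenetic signal for a binary trait on a dated tree.

The raw quantity is Σd, the sum over internal nodes of the absolute
difference between the estimated trait values of the two sister clades
(Felsenstein-weighted nodal averages, tips at their observed 0/1 values).
Σd is standardized between two null expectations:

* random — the trait shuffled among tips (no signal), and
* Brownian — a continuous Brownian trait thresholded at the observed
  prevalence (clumping under gradual evolution),

giving ``D = (Σd_obs − mean Σd_Brownian) / (mean Σd_random − mean Σd_Brownian)``.
D ≈ 1 means the presences look randomly scattered over the tree, D ≈ 0 means
they are as clumped as Brownian motion predicts; D > 1 is overdispersion and
D < 0 extreme conservatism.  ``p_random`` is the lower tail of the permuted
Σd (clumping gives small Σd); ``p_Brownian`` the upper tail of the Brownian
Σd.  Both carry the (count+1)/(n+1) small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DegenerateNullError, ValidationError
from .phylo import TreeIndex, is_binary, prune_to_labels, resolve_polytomies


@dataclass
class DResult:
    sum_d_obs: float
    mean_sum_d_random: float
    mean_sum_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_perm: int
    n_tips: int
    prevalence: float


def _trait_vector(index: TreeIndex, trait: dict) -> np.ndarray:
    missing = [lab for lab in index.labels if lab not in trait]
    if missing:
        raise ValidationError(f"trait missing for tip(s): {missing[:5]}")
    x = np.array([float(trait[lab]) for lab in index.labels])
    if not np.all((x == 0) | (x == 1)):
        raise ValidationError("trait must be binary 0/1")
    if x.min() == x.max():
        raise ValidationError("trait has no variation among tips")
    return x


def sum_sister_differences(tree_or_index, trait: dict) -> float:
    """Σd for an observed binary trait (see module docstring)."""
    index = (tree_or_index if isinstance(tree_or_index, TreeIndex)
             else TreeIndex(tree_or_index))
    return float(index.sum_sister_diffs(_trait_vector(index, trait)))


def brownian_threshold_trait(tree_or_index, k: int, seed: int) -> dict:
    """Binary trait with exactly *k* ones, clumped like Brownian motion.

    Simulates a Brownian trait (sigma2 = 1; the threshold rank is
    scale-invariant so the rate is irrelevant) and marks the k largest tips.
    """
    index = (tree_or_index if isinstance(tree_or_index, TreeIndex)
             else TreeIndex(tree_or_index))
    n = index.n_tips
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must be in [1, {n - 1}], got {k}")
    rng = np.random.default_rng(seed)
    values = index.brownian_tips(1, 1.0, rng)[:, 0]
    order = np.argsort(values)[::-1]
    trait = dict.fromkeys(index.labels, 0)
    for i in order[:k]:
        trait[index.labels[i]] = 1
    return trait


def _null_sums(index: TreeIndex, x: np.ndarray, n_perm: int,
               rng_shuffle: np.random.Generator,
               rng_brownian: np.random.Generator):
    """Σd under the permutation and Brownian-threshold nulls (vectorized)."""
    n = index.n_tips
    k = int(x.sum())
    shuffled = np.empty((n, n_perm))
    for r in range(n_perm):
        shuffled[:, r] = rng_shuffle.permutation(x)
    sums_random = index.sum_sister_diffs(shuffled)

    bm = index.brownian_tips(n_perm, 1.0, rng_brownian)
    # top-k tips of each replicate get a 1 (ranks break ties arbitrarily)
    order = np.argsort(-bm, axis=0, kind="stable")
    thresh = np.zeros((n, n_perm))
    np.put_along_axis(thresh, order[:k], 1.0, axis=0)
    sums_brownian = index.sum_sister_diffs(thresh)
    return sums_random, sums_brownian


def phylo_d(tree: dendropy.Tree, trait: dict, n_perm: int = 1000,
            seed: int = 0) -> DResult:
    """D statistic with permutation (random) and Brownian-threshold nulls.

    The tree is pruned to the trait's keys and, if needed, polytomies are
    resolved with a seed derived from *seed*, so the run is fully
    deterministic.  Shuffles and Brownian simulations draw from independent
    sub-streams of *seed*.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if set(trait) != tip_labels:
        tree = prune_to_labels(tree, set(trait))
    ss = np.random.SeedSequence(seed)
    child_resolve, child_shuffle, child_brownian = ss.spawn(3)
    if not is_binary(tree):
        tree = resolve_polytomies(
            tree, int(child_resolve.generate_state(1)[0] % (2 ** 31)))
    index = TreeIndex(tree)
    x = _trait_vector(index, trait)

    sum_d_obs = float(index.sum_sister_diffs(x))
    sums_random, sums_brownian = _null_sums(
        index, x, n_perm,
        np.random.default_rng(child_shuffle),
        np.random.default_rng(child_brownian),
    )
    mean_random = float(sums_random.mean())
    mean_brownian = float(sums_brownian.mean())
    if np.isclose(mean_random, mean_brownian):
        raise DegenerateNullError(
            "random and Brownian null means coincide; D undefined "
            "(star-like tree?)")
    d_stat = (sum_d_obs - mean_brownian) / (mean_random - mean_brownian)
    p_random = (np.sum(sums_random <= sum_d_obs) + 1.0) / (n_perm + 1.0)
    p_brownian = (np.sum(sums_brownian >= sum_d_obs) + 1.0) / (n_perm + 1.0)
    return DResult(
        sum_d_obs=sum_d_obs,
        mean_sum_d_random=mean_random,
        mean_sum_d_brownian=mean_brownian,
        D=float(d_stat),
        p_random=float(p_random),
        p_brownian=float(p_brownian),
        n_perm=n_perm,
        n_tips=index.n_tips,
        prevalence=float(x.mean()),
    )
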