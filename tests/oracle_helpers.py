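"""Independent oracles used by the tests.

Everything here is deliberately written without touching the package's
vectorized code paths: recursive tree walks over dendropy nodes and a
zoomed grid search over the binomial likelihood, so agreement with the
package is a genuine two-route check.
"""

import numpy as np


def brute_force_patristic(tree, a: str, b: str) -> float:
    """Path-sum distance via explicit root paths (no PDM, no TreeIndex)."""
    def path_to_root(label):
        node = next(lf for lf in tree.leaf_node_iter()
                    if lf.taxon.label == label)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa, pb = path_to_root(a), path_to_root(b)
    ids_b = {id(n): i for i, n in enumerate(pb)}
    for n in pa:
        if id(n) in ids_b:
            mrca = n
            break
    dist = 0.0
    for path in (pa, pb):
        for node in path:
            if node is mrca:
                break
            dist += float(node.edge.length or 0.0)
    return dist


def recursive_nodal_values(tree, tip_values: dict, eps: float = 1e-9):
    """Felsenstein weighted averages by direct recursion; returns
    (node_value, adjusted_length) maps keyed by id(node)."""
    values, adjusted = {}, {}

    def visit(node):
        if node.is_leaf():
            values[id(node)] = float(tip_values[node.taxon.label])
            adjusted[id(node)] = max(float(node.edge.length or 0.0), eps)
            return
        left, right = node.child_nodes()
        visit(left)
        visit(right)
        bl, br = adjusted[id(left)], adjusted[id(right)]
        values[id(node)] = (values[id(left)] / bl + values[id(right)] / br) \
            / (1.0 / bl + 1.0 / br)
        own = float(node.edge.length or 0.0) if node.parent_node else 0.0
        adjusted[id(node)] = max(own, eps) + bl * br / (bl + br)

    visit(tree.seed_node)
    return values


def recursive_sum_d(tree, tip_values: dict) -> float:
    """Σd by recursion: sum over internal nodes of |left − right| estimates."""
    values = recursive_nodal_values(tree, tip_values)
    total = 0.0
    for node in tree.postorder_internal_node_iter():
        left, right = node.child_nodes()
        total += abs(values[id(left)] - values[id(right)])
    return total


def grid_search_logit_mle(pa, y, span: float = 30.0, n_grid: int = 61,
                          n_zoom: int = 8):
    """Maximum-likelihood (a, b) of the binomial logit by zoomed grid search."""
    pa = np.asarray(pa, float)
    y = np.asarray(y, float)

    def loglik(a_grid, b_grid):
        # (na, nb) log-likelihood surface, numerically stable logistic
        eta = (a_grid[:, None, None] * pa[None, None, :]
               + b_grid[None, :, None])
        return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)

    a_lo, a_hi = -span, span
    b_lo, b_hi = -span, span
    for _ in range(n_zoom):
        a_grid = np.linspace(a_lo, a_hi, n_grid)
        b_grid = np.linspace(b_lo, b_hi, n_grid)
        surface = loglik(a_grid, b_grid)
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        a_step = a_grid[1] - a_grid[0]
        b_step = b_grid[1] - b_grid[0]
        a_lo, a_hi = a_grid[i] - 2 * a_step, a_grid[i] + 2 * a_step
        b_lo, b_hi = b_grid[j] - 2 * b_step, b_grid[j] + 2 * b_step
    return float(a_grid[i]), float(b_grid[j])


def closed_form_ols(x, y):
    """Simple-regression slope/intercept/r² from covariance identities."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sxx = np.var(x)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = sxy ** 2 / (sxx * np.var(y))
    return slope, intercept, r2
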