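"""Independent brute-force oracles used to validate the implementation.

Everything here is written the slow, obvious way (per-site double loops,
explicit transitive closure, textbook formulas) and stays independent of
the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

_ACGT = set("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_brute(a: str, b: str) -> tuple[float, float, float, int]:
    """Per-site K2P: returns (distance in percent, P, Q, compared sites)."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _ACGT and y in _ACGT:
            n += 1
            if x != y:
                if (x, y) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    P, Q = ts / n, tv / n
    arg1, arg2 = 1 - 2 * P - Q, 1 - 2 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.inf, P, Q, n
    return (-0.5 * math.log(arg1) - 0.25 * math.log(arg2)) * 100.0, P, Q, n


def single_linkage_brute(values: np.ndarray, threshold: float) -> list[set[int]]:
    """Clusters by explicit transitive closure of the threshold graph."""
    n = values.shape[0]
    with np.errstate(invalid="ignore"):
        adj = values <= threshold
    adj |= np.eye(n, dtype=bool)
    adj &= ~np.isnan(values) | np.eye(n, dtype=bool)
    reach = adj.copy()
    for _ in range(n):
        new = reach @ reach
        if np.array_equal(new > 0, reach):
            break
        reach = new > 0
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i not in seen:
            comp = set(np.nonzero(reach[i])[0].tolist())
            comps.append(comp)
            seen |= comp
    return comps


def chi_square_brute(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square from hand-built expected counts."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - expected) ** 2 / expected
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, df


def welch_brute(a, b) -> tuple[float, float]:
    """Welch t statistic and Satterthwaite df from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ma, mb = a.mean(), b.mean()
    va = ((a - ma) ** 2).sum() / (len(a) - 1)
    vb = ((b - mb) ** 2).sum() / (len(b) - 1)
    sa, sb = va / len(a), vb / len(b)
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return t, df


def midranks(x) -> np.ndarray:
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    """Rank correlation as the Pearson correlation of mid-ranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def anova_brute(groups: dict) -> tuple[float, float, float]:
    """(ss_between, ss_within, F) from the definition."""
    values = [np.asarray(v, float) for v in groups.values()]
    pooled = np.concatenate(values)
    grand = pooled.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    dfb = len(values) - 1
    dfw = len(pooled) - len(values)
    return ssb, ssw, (ssb / dfb) / (ssw / dfw)


def random_additive_matrix(
    rng: np.random.Generator, n_leaves: int
) -> tuple[list[str], np.ndarray]:
    """Random binary tree with positive branch lengths; returns its exact
    leaf-to-leaf path-length matrix (an additive distance matrix)."""
    import networkx as nx

    g = nx.Graph()
    nodes = [f"L{i}" for i in range(n_leaves)]
    leaves = list(nodes)
    nxt = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = f"I{nxt}"
        nxt += 1
        g.add_edge(new, a, weight=float(rng.uniform(0.5, 5.0)))
        g.add_edge(new, b, weight=float(rng.uniform(0.5, 5.0)))
        nodes = [n for n in nodes if n not in (a, b)] + [new]
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i != j:
                mat[i, j] = lengths[a][b]
    mat = (mat + mat.T) / 2  # exact symmetry against float noise
    return leaves, mat
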