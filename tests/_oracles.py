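"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (nested loops, no shared
code with the package implementation) so disagreement with the package
points at a real defect.
"""

import numpy as np


def bray_curtis_oracle(x, y):
    num = 0.0
    den = 0.0
    for a, b in zip(x, y):
        num += abs(a - b)
        den += a + b
    return num / den


def cophenetic_oracle(tree, taxa):
    """Tip-to-tip path lengths via explicit root paths (min over ancestors)."""

    def root_path(tip):
        dist = {}
        node, acc = tip, 0.0
        while node is not None:
            dist[id(node)] = acc
            acc += node.length or 0.0
            node = node.parent
        return dist

    tips = {t.name: t for t in tree.tips()}
    n = len(taxa)
    out = np.zeros((n, n))
    paths = {name: root_path(tips[name]) for name in taxa}
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[taxa[i]], paths[taxa[j]]
            best = min(pa[k] + pb[k] for k in pa if k in pb)
            out[i, j] = out[j, i] = best
    return out


def bmntd_oracle(x, y, dm, weighted=True):
    ia = [i for i, v in enumerate(x) if v > 0]
    ib = [j for j, v in enumerate(y) if v > 0]
    mins_a = [min(dm[i][j] for j in ib) for i in ia]
    mins_b = [min(dm[i][j] for i in ia) for j in ib]
    if weighted:
        wa = [x[i] for i in ia]
        wb = [y[j] for j in ib]
        part_a = sum(m * w for m, w in zip(mins_a, wa)) / sum(wa)
        part_b = sum(m * w for m, w in zip(mins_b, wb)) / sum(wb)
    else:
        part_a = sum(mins_a) / len(mins_a)
        part_b = sum(mins_b) / len(mins_b)
    return 0.5 * (part_a + part_b)


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values, textbook construction."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adjusted[idx] = running_min
    return adjusted


def zi_pi_oracle(graph, modules):
    """Per-node within-module z-score and participation coefficient."""
    rows = {}
    members = {}
    for v in graph.nodes:
        members.setdefault(modules[v], []).append(v)
    for v in graph.nodes:
        mod = modules[v]
        within = [sum(1 for u in graph.neighbors(w) if modules[u] == mod) for w in members[mod]]
        k_in = sum(1 for u in graph.neighbors(v) if modules[u] == mod)
        mu = sum(within) / len(within)
        sd = (sum((w - mu) ** 2 for w in within) / len(within)) ** 0.5
        zi = 0.0 if sd == 0 else (k_in - mu) / sd
        k = graph.degree(v)
        if k == 0:
            pi = 0.0
        else:
            per_mod = {}
            for u in graph.neighbors(v):
                per_mod[modules[u]] = per_mod.get(modules[u], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        rows[v] = (zi, pi)
    return rows
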