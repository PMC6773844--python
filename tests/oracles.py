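"""Independent oracles the tests check the implementation against.

Everything here is deliberately naive — explicit loops, exhaustive
search, closed-form transfer functions — and shares no code with the
package internals it validates.
"""

from itertools import product

import numpy as np


def tfce_brute_force(values, adjacency, E, H, n_steps):
    """TFCE by looping explicit thresholds and re-discovering connected
    components from scratch with breadth-first search at every step.

    Uses the same midpoint threshold grid as the implementation; the
    component search and accumulation are entirely independent.
    """
    values = np.asarray(values, float)
    n = len(values)
    out = np.zeros(n)
    for signed in (1.0, -1.0):
        v = signed * values
        vmax = v.max(initial=0.0)
        if vmax <= 0:
            continue
        dh = vmax / n_steps
        for k in range(n_steps):
            h = (k + 0.5) * dh
            above = [i for i in range(n) if v[i] > h]
            seen = set()
            for start in above:
                if start in seen:
                    continue
                comp = {start}
                queue = [start]
                while queue:
                    i = queue.pop()
                    for j in range(n):
                        if adjacency[i][j] and v[j] > h and j not in comp:
                            comp.add(j)
                            queue.append(j)
                seen |= comp
                for i in comp:
                    out[i] += signed * len(comp) ** E * h ** H * dh
    return out


def graph_is_connected(n, edges):
    """Breadth-first search connectivity over an explicit edge set."""
    if n == 0:
        return True
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, queue = {0}, [0]
    while queue:
        i = queue.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(j)
                queue.append(j)
    return len(seen) == n


def butter_filtfilt_gain(order, Wn, btype, fs, freq):
    """Magnitude response of a forward-backward Butterworth filter
    (|H|^2 of the one-pass design) at ``freq`` Hz."""
    from scipy import signal

    b, a = signal.butter(order, Wn, btype=btype, fs=fs)
    _, h = signal.freqz(b, a, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


def exact_wilcoxon_two_sided(d):
    """Exact two-sided signed-rank p by enumerating every sign pattern."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = _rank(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2.0**n


def _rank(x):
    """Average ranks, written longhand."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
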