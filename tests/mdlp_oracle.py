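"""Naive reference implementation of MDL-accepted recursive discretization.

Deliberately slow and direct: entropies from Counter tallies with
math.log2, every candidate boundary evaluated by physically splitting the
list, recursion by list slicing.  Shares only the published decision rule
with the package implementation, none of its code paths.
"""

import math
from collections import Counter


def entropy(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def mdlp_cuts(values, labels) -> list[float]:
    pairs = sorted(zip(values, labels), key=lambda t: t[0])
    return sorted(_recurse(pairs))


def _recurse(pairs) -> list[float]:
    n = len(pairs)
    if n < 2:
        return []
    values = [v for v, _ in pairs]
    labels = [l for _, l in pairs]
    candidates = [i for i in range(n - 1) if values[i + 1] > values[i]]
    if not candidates:
        return []
    best_w, best_i = None, None
    for i in candidates:
        left = labels[: i + 1]
        right = labels[i + 1 :]
        w = (len(left) * entropy(left) + len(right) * entropy(right)) / n
        if best_w is None or w < best_w - 1e-12:  # ties keep the lowest cut
            best_w, best_i = w, i
    gain = entropy(labels) - best_w
    left = labels[: best_i + 1]
    right = labels[best_i + 1 :]
    k = len(set(labels))
    k1 = len(set(left))
    k2 = len(set(right))
    delta = math.log2(3**k - 2) - (
        k * entropy(labels) - k1 * entropy(left) - k2 * entropy(right)
    )
    if gain <= (math.log2(n - 1) + delta) / n:
        return []
    cut = (values[best_i] + values[best_i + 1]) / 2
    return _recurse(pairs[: best_i + 1]) + [cut] + _recurse(pairs[best_i + 1 :])


def info_gain(cuts, values, labels) -> float:
    if not cuts:
        return 0.0
    bins = [sum(1 for c in cuts if c < v) for v in values]
    n = len(values)
    total = entropy(labels)
    cond = 0.0
    for b in set(bins):
        sub = [l for bb, l in zip(bins, labels) if bb == b]
        cond += (len(sub) / n) * entropy(sub)
    return total - cond
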