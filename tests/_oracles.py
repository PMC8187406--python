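"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (plain loops and dicts, no shared
code with the package) so that agreement with the package is meaningful.
"""

from __future__ import annotations

import numpy as np


def kofn_oracle(values: np.ndarray, row_names, k: int, floor: float = 0.0):
    """Row-by-row positive-sample counting."""
    kept = set()
    for name, row in zip(row_names, values):
        count = 0
        for v in row:
            if v > floor:
                count += 1
        if count >= k:
            kept.add(name)
    return kept


def consensus_oracle(assertions, universe):
    """Group-by mouse gene, count distinct human partners."""
    partners = {}
    for m, h, _src in assertions:
        partners.setdefault(m, set()).add(h)
    out = {}
    for g in universe:
        hs = partners.get(g, set())
        if len(hs) == 0:
            out[g] = "unmapped"
        elif len(hs) == 1:
            out[g] = "one_to_one"
        else:
            out[g] = "one_to_many"
    return out


def venn_oracle(sets):
    """Per-element membership-pattern enumeration."""
    labels = sorted(sets)
    counts = {}
    for el in set().union(*sets.values()):
        pattern = tuple(l for l in labels if el in sets[l])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def normalize_oracle(values: np.ndarray, standard_row: int) -> np.ndarray:
    """Element-wise division by the standard row, loop form."""
    out = []
    for i in range(values.shape[0]):
        if i == standard_row:
            continue
        out.append([values[i, j] / values[standard_row, j]
                    for j in range(values.shape[1])])
    return np.array(out)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def scan_oracle(seq: str, matrix: np.ndarray, background: np.ndarray,
                threshold: float):
    """Position-by-position log-odds scoring on both strands."""
    lo = np.log2(matrix / background)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(matrix)

    def score_at(s, pos):
        total = 0.0
        for off in range(L):
            b = s[pos + off]
            if b not in base_idx:
                return -np.inf
            total += lo[off, base_idx[b]]
        return total

    hits = []
    for pos in range(len(seq) - L + 1):
        sc = score_at(seq, pos)
        if sc >= threshold:
            hits.append((pos, "+", sc))
    rc = "".join(_COMP[b] for b in reversed(seq))
    for pos in range(len(rc) - L + 1):
        sc = score_at(rc, pos)
        if sc >= threshold:
            hits.append((len(seq) - pos - L, "-", sc))
    return hits
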