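"""Independent reference implementations used only to cross-check the package.

Each oracle recomputes a quantity by a different route than the code under
test: naive window counting for the triad encoder, explicit ancestor walks
for tree inner products, and an L-BFGS-B solve of the no-offset binary SVM
dual for the flat-tree reduction check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_ctf(sequence: str, class_of: dict[str, int]) -> tuple[np.ndarray, int]:
    """Count class triads by direct window enumeration (dict-based)."""
    counts: dict[tuple[int, int, int], int] = {}
    n = 0
    seq = sequence.upper()
    for i in range(len(seq) - 2):
        window = seq[i : i + 3]
        if any(ch not in class_of for ch in window):
            continue
        key = tuple(class_of[ch] for ch in window)
        counts[key] = counts.get(key, 0) + 1
        n += 1
    vec = np.zeros(343)
    for (c1, c2, c3), cnt in counts.items():
        vec[(c1 - 1) * 49 + (c2 - 1) * 7 + (c3 - 1)] = cnt
    return (vec / n if n else vec), n


def ancestor_walk_shared_depth(parent: dict[int, int], a: int, b: int) -> int:
    """Depth of the deepest common ancestor of two leaves (root = depth 0),
    computed by materializing both root paths and walking them in parallel."""

    def root_path(node: int) -> list[int]:
        out = []
        while node != 0:
            out.append(node)
            node = parent[node]
        return out[::-1]

    pa, pb = root_path(a), root_path(b)
    depth = 0
    for x, y in zip(pa, pb):
        if x != y:
            break
        depth += 1
    return depth


def no_offset_svm_predict(
    X_train: np.ndarray,
    signs: np.ndarray,
    X_test: np.ndarray,
    C: float,
    K_train: np.ndarray,
    K_test: np.ndarray,
) -> np.ndarray:
    """Soft-margin binary SVM *without* an offset term, solved independently.

    Dual: max sum(b) - 0.5 b' Q b with Q = (s s') * K, box 0 <= b <= C,
    solved by L-BFGS-B.  Returns the sign of the test decision values
    f(x) = sum_i b_i s_i k(x_i, x)  (+1/-1; zero mapped to +1).
    """
    Q = np.outer(signs, signs) * K_train
    l = len(signs)

    def obj(b: np.ndarray):
        Qb = Q @ b
        return 0.5 * b @ Qb - b.sum(), Qb - 1.0

    res = minimize(
        obj,
        np.zeros(l),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, C)] * l,
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-14},
    )
    beta = np.clip(res.x, 0.0, C)
    decision = (beta * signs) @ K_test
    return np.where(decision >= 0, 1, -1)
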