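"""Hierarchy-aware max-margin classifiers.

Two trainers share one discriminant family.  With the joint feature map
Phi(x, y) = phi(x) (x) Lambda(y) — the input feature map tensored with the
binary path-indicator of label y — scores decompose along the label tree and
joint inner products factorize as

    Phi(x, y) . Phi(x', y') = (Lambda(y) . Lambda(y')) * k(x, x').

* ``train_pmsvmhl_oracle`` solves the full structured-SVM primal: one margin
  constraint per sample per wrong leaf, l*(q-1) constraints in total.  It is
  exact but scales poorly, so it serves as a small-instance oracle (linear
  kernel, explicit weight vector).

* ``train_svmhl`` is the reduced model: each sample keeps a single constraint
  against one *competitor* leaf — the sibling with the largest class size
  (siblings are the labels a classifier most easily confuses, and margining
  against the largest one counters the class-imbalance bias), or the globally
  largest class when the sample's leaf has no sibling.  The dual is then a
  box-constrained QP in only l variables over the modified kernel

      Ktil[i, j] = (Lambda(y_i) - Lambda(yhat_i)) . (Lambda(y_j) - Lambda(yhat_j)) * k(x_i, x_j),

  solved here by cyclic coordinate ascent with a duality-gap stopping rule.
  The printed primal carries no offset term, so the dual has no equality
  constraint — which is exactly what makes coordinate ascent exact per
  coordinate.

A flat one-vs-rest SVM baseline with the same predict surface is provided for
hierarchy-blind comparisons.
"""

from __future__ import annotations

import base64
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, minimize
from scipy.sparse import diags
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .hierarchy import LabelTree, attribute_vector

__all__ = [
    "KernelSpec",
    "kernel_matrix",
    "select_competitor",
    "assign_competitors",
    "joint_kernel",
    "joint_kernel_matrix",
    "SVMHLModel",
    "train_svmhl",
    "score",
    "predict",
    "svmhl_primal_objective",
    "PMSVMHLModel",
    "train_pmsvmhl_oracle",
    "count_dual_variables",
    "grid_search",
    "FlatMulticlassSVM",
    "train_flat_multiclass",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class KernelSpec:
    """Input-space kernel: ``rbf`` with width gamma, or ``linear``."""

    kind: str = "rbf"
    gamma: float | None = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")


def kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if kernel.kind == "rbf":
        return rbf_kernel(X, Y, gamma=kernel.gamma)
    return linear_kernel(X, Y)


# ---------------------------------------------------------------------------
# competitor selection
# ---------------------------------------------------------------------------


def select_competitor(
    tree: LabelTree, class_counts: dict[str, int], y: str
) -> str:
    """The competitor leaf for class ``y``: the sibling leaf with the most
    training samples, or — when ``y`` has no sibling leaf — the largest class
    overall.  Ties break toward the smallest node id."""
    leaf = tree.leaf_id(y)
    siblings = tree.sibling_leaves(leaf)
    pool = siblings if siblings else [n for n in tree.leaves if n != leaf]
    if not pool:
        raise ValueError(f"no eligible competitor leaf for {y!r}")
    # max count, ties -> smallest id (pool is sorted by id)
    best = max(pool, key=lambda n: (class_counts.get(tree.node_names[n], 0), -n))
    return tree.node_names[best]


def assign_competitors(tree: LabelTree, labels: list[str]) -> list[str]:
    """Per-sample competitor assignment from the training class sizes."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    cache = {lab: select_competitor(tree, counts, lab) for lab in set(labels)}
    return [cache[lab] for lab in labels]


# ---------------------------------------------------------------------------
# modified kernel
# ---------------------------------------------------------------------------


def _delta_lambda(tree: LabelTree, y: list[str], yhat: list[str]) -> np.ndarray:
    """Rows Lambda(y_i) - Lambda(yhat_i), shape (l, s)."""
    return np.array(
        [attribute_vector(tree, a) - attribute_vector(tree, b) for a, b in zip(y, yhat)]
    )


def joint_kernel(
    tree: LabelTree,
    xi: np.ndarray,
    yi: str,
    yhat_i: str,
    xj: np.ndarray,
    yj: str,
    yhat_j: str,
    kernel: KernelSpec,
) -> float:
    """One entry of the modified kernel between (x_i, y_i, yhat_i) and
    (x_j, y_j, yhat_j)."""
    di = attribute_vector(tree, yi) - attribute_vector(tree, yhat_i)
    dj = attribute_vector(tree, yj) - attribute_vector(tree, yhat_j)
    k = kernel_matrix(np.atleast_2d(xi), np.atleast_2d(xj), kernel)[0, 0]
    return float(di @ dj) * k


def joint_kernel_matrix(
    tree: LabelTree,
    X: np.ndarray,
    y: list[str],
    yhat: list[str],
    kernel: KernelSpec,
) -> np.ndarray:
    """The full l x l modified-kernel Gram matrix Ktil (elementwise product of
    the label-difference Gram matrix and the input-kernel Gram matrix; the
    Schur product of two PSD matrices, hence PSD)."""
    D = _delta_lambda(tree, y, yhat)
    K = kernel_matrix(X, X, kernel)
    return (D @ D.T) * K


# ---------------------------------------------------------------------------
# box-constrained QP (dual of the reduced model)
# ---------------------------------------------------------------------------


def _qp_gap(K: np.ndarray, C: float, alpha: np.ndarray) -> tuple[float, float]:
    """(dual value, duality gap) of the box QP at ``alpha``.

    The gap compares the dual value with the feasible primal objective
    reconstructed from the same point (kernel-space norm plus hinge slacks),
    so gap <= eps certifies eps-optimality.
    """
    Ka = K @ alpha
    dual = alpha.sum() - 0.5 * alpha @ Ka
    primal = 0.5 * alpha @ Ka + C * np.maximum(0.0, 1.0 - Ka).sum()
    return float(dual), float(primal - dual)


def _solve_box_qp(
    K: np.ndarray, C: float, tol: float = 1e-6, max_sweeps: int = 2000
) -> tuple[np.ndarray, float]:
    """Maximize  sum(a) - 0.5 a'Ka  over the box 0 <= a <= C.

    Two phases: an L-BFGS-B solve of the (smooth, bound-constrained) dual for
    a fast global pass, then cyclic coordinate ascent — each update the exact
    clipped single-variable minimizer, so the dual value is monotone — until
    the duality gap certifies ``tol``-relative optimality.
    """
    from scipy.optimize import minimize as _minimize

    l = K.shape[0]

    def negdual(a: np.ndarray) -> tuple[float, np.ndarray]:
        Ka = K @ a
        return 0.5 * a @ Ka - a.sum(), Ka - 1.0

    res = _minimize(
        negdual,
        np.zeros(l),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, C)] * l,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    alpha = np.clip(res.x, 0.0, C)
    diag = K.diagonal()
    dual, gap = _qp_gap(K, C, alpha)
    for sweep in range(max_sweeps):
        if gap <= tol * (1.0 + abs(dual)):
            break
        grad = 1.0 - K @ alpha
        for i in range(l):
            if diag[i] > 1e-14:
                new = min(C, max(0.0, alpha[i] + grad[i] / diag[i]))
            else:
                # degenerate coordinate: objective linear in alpha_i
                new = C if grad[i] > 0 else 0.0
            step = new - alpha[i]
            if step != 0.0:
                grad -= step * K[:, i]
                alpha[i] = new
        # projected Newton on the free set: coordinate ascent alone creeps
        # when K is near-singular (e.g. vanishing rbf gamma)
        grad = 1.0 - K @ alpha
        eps = 1e-12 * max(1.0, C)
        free = ~(((alpha <= eps) & (grad < 0)) | ((alpha >= C - eps) & (grad > 0)))
        if free.any():
            d = np.zeros(l)
            d[free] = np.linalg.lstsq(K[np.ix_(free, free)], grad[free], rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = np.clip(alpha + t * d, 0.0, C)
                cand_dual, cand_gap = _qp_gap(K, C, cand)
                if cand_dual > dual:
                    alpha, dual, gap = cand, cand_dual, cand_gap
                    break
                t *= 0.5
            else:
                dual, gap = _qp_gap(K, C, alpha)
        else:
            dual, gap = _qp_gap(K, C, alpha)
    else:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"QP solver did not converge in {max_sweeps} sweeps "
            f"(relative gap {gap / (1.0 + abs(dual)):.3e} > {tol:.1e})"
        )
    return alpha, dual


# ---------------------------------------------------------------------------
# the reduced model
# ---------------------------------------------------------------------------


@dataclass
class SVMHLModel:
    """Trained reduced hierarchical-label SVM.

    Stores the l dual coefficients (one per training sample), the training
    inputs, labels and competitor labels, the kernel, and the label tree.  The
    discriminant is f(x) = argmax_y w . Phi(x, y) with
    w = sum_i alpha_i (Phi(x_i, y_i) - Phi(x_i, yhat_i)) kept implicit through
    the kernel expansion.
    """

    alpha: np.ndarray
    C: float
    kernel: KernelSpec
    tree: LabelTree
    X: np.ndarray
    y: list[str]
    comp: list[str]
    objective: float

    def score(self, x: np.ndarray, label: str) -> float:
        return score(self, x, label)

    def predict(self, X: np.ndarray) -> list[str]:
        return predict(self, X)

    def decision_table(self, X: np.ndarray) -> pd.DataFrame:
        """Scores w . Phi(x, y) for every leaf y (columns in leaf-id order)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        D = _delta_lambda(self.tree, self.y, self.comp)  # (l, s)
        K = kernel_matrix(self.X, X, self.kernel)  # (l, m)
        node_scores = (self.alpha[:, None] * D).T @ K  # (s, m)
        L = np.array([attribute_vector(self.tree, n) for n in self.tree.leaves])
        vals = L @ node_scores  # (q, m)
        return pd.DataFrame(vals.T, columns=list(self.tree.leaf_names))


def train_svmhl(
    X: np.ndarray,
    y: list[str],
    tree: LabelTree,
    C: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
    tol: float = 1e-6,
) -> SVMHLModel:
    """Train the reduced model: assign competitors, form the modified kernel,
    and solve the l-variable box QP  max sum(a) - 0.5 a' Ktil a, 0 <= a <= C."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = list(y)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    comp = assign_competitors(tree, y)
    Ktil = joint_kernel_matrix(tree, X, y, comp, kernel)
    scale = max(1.0, float(Ktil.diagonal().max()))
    min_eig = float(np.linalg.eigvalsh(Ktil).min())
    if min_eig < -1e-8 * scale:
        raise ValueError(
            f"modified kernel matrix is not PSD (min eigenvalue {min_eig:.3e})"
        )
    alpha, objective = _solve_box_qp(Ktil, C, tol=tol)
    return SVMHLModel(
        alpha=alpha, C=C, kernel=kernel, tree=tree, X=X, y=y, comp=comp,
        objective=objective,
    )


def score(model: SVMHLModel, x: np.ndarray, label: str) -> float:
    """w . Phi(x, y) = sum_i alpha_i [Lambda(y_i).Lambda(y) -
    Lambda(yhat_i).Lambda(y)] k(x_i, x)."""
    tree = model.tree
    tree.leaf_id(label)  # validates
    table = model.decision_table(np.atleast_2d(x))
    return float(table.iloc[0][label])


def predict(model: SVMHLModel, X: np.ndarray) -> list[str]:
    """Leaf with the highest score; ties break toward the smallest leaf id."""
    table = model.decision_table(X)
    idx = np.argmax(table.to_numpy(), axis=1)  # first max = smallest leaf id
    names = list(model.tree.leaf_names)
    return [names[i] for i in idx]


def svmhl_primal_objective(model: SVMHLModel) -> float:
    """Objective 0.5 ||w||^2 + C sum_i xi_i of the feasible primal point
    reconstructed from the dual solution (w from the kernel expansion, slacks
    from the single active constraint per sample)."""
    Ktil = joint_kernel_matrix(
        model.tree, model.X, model.y, model.comp, model.kernel
    )
    Ka = Ktil @ model.alpha
    margins = Ka  # w . deltaPhi_i(yhat_i)
    xi = np.maximum(0.0, 1.0 - margins)
    return float(0.5 * model.alpha @ Ka + model.C * xi.sum())


# ---------------------------------------------------------------------------
# the full-model oracle
# ---------------------------------------------------------------------------


@dataclass
class PMSVMHLModel:
    """Full structured-SVM primal solution (linear kernel, explicit weights).

    ``w`` has one row per tree node (shape (s, d)); the score of leaf y is
    sum over path(y) of w_node . x.  ``objective`` is evaluated at a feasible
    point: slacks are recomputed from w after the solve, so the reported value
    upper-bounds nothing and lower-bounds only the unconstrained relaxations.
    """

    w: np.ndarray
    xi: np.ndarray
    C: float
    tree: LabelTree
    objective: float
    n_constraints: int

    def decision_table(self, X: np.ndarray) -> pd.DataFrame:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node_scores = self.w @ X.T  # (s, m)
        L = np.array([attribute_vector(self.tree, n) for n in self.tree.leaves])
        return pd.DataFrame((L @ node_scores).T, columns=list(self.tree.leaf_names))

    def predict(self, X: np.ndarray) -> list[str]:
        table = self.decision_table(X)
        idx = np.argmax(table.to_numpy(), axis=1)
        names = list(self.tree.leaf_names)
        return [names[i] for i in idx]


def train_pmsvmhl_oracle(
    X: np.ndarray,
    y: list[str],
    tree: LabelTree,
    C: float = 1.0,
    max_constraints: int = 2000,
) -> PMSVMHLModel:
    """Solve the full primal directly:

        min 0.5 ||w||^2 + C sum_i xi_i
        s.t. w . (Phi(x_i, y_i) - Phi(x_i, y)) >= 1 - xi_i  for all y != y_i,
             xi_i >= 0.

    Linear kernel only, so w lives explicitly in the (s x d) joint space.
    Intended as a small-instance oracle: the constraint count l*(q-1) is
    capped at ``max_constraints``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = list(y)
    l, d = X.shape
    q, s = tree.q, tree.s
    ncon = l * (q - 1)
    if ncon > max_constraints:
        raise ValueError(
            f"{ncon} constraints exceed the oracle cap of {max_constraints}"
        )
    lam = {name: attribute_vector(tree, name) for name in tree.leaf_names}

    nvar = s * d + l
    rows = np.zeros((ncon, nvar))
    r = 0
    for i in range(l):
        for name in tree.leaf_names:
            if name == y[i]:
                continue
            dlam = lam[y[i]] - lam[name]  # (s,)
            rows[r, : s * d] = np.outer(dlam, X[i]).ravel()
            rows[r, s * d + i] = 1.0
            r += 1
    assert r == ncon

    hess_diag = np.concatenate([np.ones(s * d), np.zeros(l)])
    H = diags(hess_diag).tocsc()
    c_lin = np.concatenate([np.zeros(s * d), np.full(l, C)])

    def fun(z: np.ndarray) -> float:
        w = z[: s * d]
        return 0.5 * w @ w + c_lin @ z

    def jac(z: np.ndarray) -> np.ndarray:
        g = z.copy()
        g[s * d:] = C
        return g

    lb = np.concatenate([np.full(s * d, -np.inf), np.zeros(l)])
    res = minimize(
        fun,
        np.zeros(nvar),
        jac=jac,
        hess=lambda z: H,
        method="trust-constr",
        constraints=[LinearConstraint(rows, 1.0, np.inf)],
        bounds=Bounds(lb, np.full(nvar, np.inf)),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 3000},
    )
    if not res.success and res.status not in (1, 2):  # pragma: no cover
        raise RuntimeError(f"oracle QP failed: {res.message}")
    w = res.x[: s * d].reshape(s, d)
    # feasible slacks recomputed from w: xi_i = max(0, 1 - min_y margin_i(y))
    margins = rows[:, : s * d] @ w.ravel()
    xi = np.zeros(l)
    r = 0
    for i in range(l):
        m = margins[r : r + q - 1]
        xi[i] = max(0.0, 1.0 - m.min())
        r += q - 1
    objective = float(0.5 * np.sum(w * w) + C * xi.sum())
    return PMSVMHLModel(
        w=w, xi=xi, C=C, tree=tree, objective=objective, n_constraints=ncon
    )


def count_dual_variables(l: int, q: int, reduced: bool) -> int:
    """Dual-variable count: l*(q-1) for the full model, l for the reduced one."""
    if l < 1 or q < 2:
        raise ValueError("need l >= 1 and q >= 2")
    return l if reduced else l * (q - 1)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** p for p in range(-5, 10, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** p for p in range(-9, 4, 2))


def grid_search(
    X: np.ndarray,
    y: list[str],
    tree: LabelTree,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    folds: int = 3,
    seed: int = 0,
    kernel_kind: str = "rbf",
) -> tuple[float, float | None, pd.DataFrame]:
    """Pick (C, gamma) by stratified k-fold CV accuracy of the reduced model.

    Ties break toward smaller C, then smaller gamma.  When the rarest class
    has fewer members than ``folds`` the fold count is reduced (warning).
    Returns (C, gamma, table of per-point CV accuracies).
    """
    if not C_grid or (kernel_kind == "rbf" and not gamma_grid):
        raise ValueError("empty parameter grid")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = list(y)
    min_class = min(np.unique(y, return_counts=True)[1])
    eff = min(folds, int(min_class))
    if eff < folds:
        warnings.warn(
            f"smallest class has {min_class} member(s); using {eff}-fold CV",
            stacklevel=2,
        )
    if eff < 2:
        raise ValueError("cannot cross-validate with a singleton class")
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    gammas: tuple[float | None, ...] = (
        gamma_grid if kernel_kind == "rbf" else (None,)
    )
    records = []
    for C in C_grid:
        for g in gammas:
            kern = KernelSpec(kind=kernel_kind, gamma=g)
            correct = total = 0
            for tr, te in splits:
                model = train_svmhl(X[tr], [y[i] for i in tr], tree, C, kern)
                pred = model.predict(X[te])
                correct += sum(p == y[i] for p, i in zip(pred, te))
                total += len(te)
            records.append(
                {
                    "C": C,
                    "gamma": np.nan if g is None else g,
                    "cv_accuracy": correct / total,
                }
            )
    table = pd.DataFrame.from_records(records)
    best = table.sort_values(
        ["cv_accuracy", "C", "gamma"], ascending=[False, True, True]
    ).iloc[0]
    best_gamma = None if np.isnan(best["gamma"]) else float(best["gamma"])
    return float(best["C"]), best_gamma, table


# ---------------------------------------------------------------------------
# flat baseline
# ---------------------------------------------------------------------------


class FlatMulticlassSVM:
    """Hierarchy-blind one-vs-rest soft-margin SVM over the leaf labels.

    One binary SVC per leaf; prediction takes the largest decision value,
    ties toward the smallest leaf id.  Shares the predict surface of the
    hierarchical model so the two are interchangeable in evaluation code.
    """

    def __init__(self, tree: LabelTree, C: float = 1.0, kernel: KernelSpec = KernelSpec()):
        self.tree = tree
        self.C = C
        self.kernel = kernel
        self._clfs: dict[str, SVC] = {}

    def fit(self, X: np.ndarray, y: list[str]) -> "FlatMulticlassSVM":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(list(y))
        kwargs = (
            {"kernel": "rbf", "gamma": self.kernel.gamma}
            if self.kernel.kind == "rbf"
            else {"kernel": "linear"}
        )
        for name in self.tree.leaf_names:
            target = (y == name).astype(int)
            if target.sum() in (0, len(y)):
                continue  # class absent (or alone); scored -inf / +inf below
            clf = SVC(C=self.C, **kwargs)
            clf.fit(X, target)
            self._clfs[name] = clf
        if not self._clfs:
            raise ValueError("flat baseline needs >= 2 classes present")
        return self

    def decision_table(self, X: np.ndarray) -> pd.DataFrame:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = {}
        for name in self.tree.leaf_names:
            clf = self._clfs.get(name)
            cols[name] = (
                clf.decision_function(X) if clf is not None else np.full(len(X), -np.inf)
            )
        return pd.DataFrame(cols)

    def predict(self, X: np.ndarray) -> list[str]:
        table = self.decision_table(X)
        idx = np.argmax(table.to_numpy(), axis=1)
        names = list(self.tree.leaf_names)
        return [names[i] for i in idx]


def train_flat_multiclass(
    X: np.ndarray,
    y: list[str],
    tree: LabelTree,
    C: float = 1.0,
    kernel: KernelSpec = KernelSpec(),
) -> FlatMulticlassSVM:
    return FlatMulticlassSVM(tree, C=C, kernel=kernel).fit(X, y)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _array_to_jsonable(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _array_from_jsonable(d: dict) -> np.ndarray:
    buf = base64.b64decode(d["data"])
    return np.frombuffer(buf, dtype=np.float64).reshape(d["shape"]).copy()


def save_model(model: SVMHLModel, path: str | Path) -> None:
    """Serialize a trained model to JSON; arrays are base64-encoded float64,
    so the round trip is bit-exact."""
    payload = {
        "format": "hiersvm-model-v1",
        "C": model.C,
        "kernel": {"kind": model.kernel.kind, "gamma": model.kernel.gamma},
        "tree": model.tree.to_dict(),
        "alpha": _array_to_jsonable(model.alpha),
        "X": _array_to_jsonable(model.X),
        "y": model.y,
        "comp": model.comp,
        "objective": model.objective,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> SVMHLModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "hiersvm-model-v1":
        raise ValueError(f"{path}: not a hiersvm model file")
    return SVMHLModel(
        alpha=_array_from_jsonable(payload["alpha"]),
        C=float(payload["C"]),
        kernel=KernelSpec(
            kind=payload["kernel"]["kind"], gamma=payload["kernel"]["gamma"]
        ),
        tree=LabelTree.from_dict(payload["tree"]),
        X=_array_from_jsonable(payload["X"]),
        y=list(payload["y"]),
        comp=list(payload["comp"]),
        objective=float(payload["objective"]),
    )
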