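"""Regularized and sparse generalized canonical correlation over a block design.

The engine maximizes

    sum_{j,k} C_jk * g( cov(X_j a_j, X_k a_k) )

over per-block weight vectors ``a_j``, subject to either the regularized
constraint ``a_j' M_j a_j <= 1`` with ``M_j = tau_j I + (1 - tau_j) X_j'X_j / n``
or, in sparse mode, ``||a_j||_2 <= 1`` and ``||a_j||_1 <= s_j sqrt(p_j)``.
``C`` is a binary symmetric design matrix encoding which blocks are
hypothesized to be connected (sequential / complete / reversed-sequential
causal hypotheses for the RNA / imaging / diagnosis triplet), and ``g`` is a
scheme function: identity ("horst"), square ("factorial") or absolute value
("centroid").

Optimization is block relaxation: each sweep updates one weight vector at a
time to the exact maximizer of the criterion's linearization over its
constraint set, which for convex ``g`` makes the criterion trace
nondecreasing.  One component is extracted per block (no deflation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

SCHEMES = ("horst", "factorial", "centroid")
DEFAULT_BLOCK_ORDER = ("rna", "imaging", "dx")

NAMED_DESIGNS = {
    # edges among (first, second, third) block in the stated order
    "sequential": [(0, 1), (1, 2)],
    "complete": [(0, 1), (0, 2), (1, 2)],
    "reversed_sequential": [(0, 1), (0, 2)],
}


@dataclass(frozen=True)
class DesignSpec:
    """Block order plus the binary symmetric connection matrix C."""

    block_order: tuple
    C: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        J = len(self.block_order)
        if C.shape != (J, J):
            raise ValueError(f"C must be {J}x{J} for {J} blocks, got {C.shape}")
        if not np.array_equal(C, C.T):
            raise ValueError("design matrix C must be symmetric")
        if np.any(np.diag(C) != 0):
            raise ValueError("design matrix C must have a zero diagonal")
        if not set(np.unique(C)) <= {0.0, 1.0}:
            raise ValueError("design matrix entries must be 0 or 1")
        if C.sum() == 0:
            raise ValueError("design matrix must have at least one connection")
        object.__setattr__(self, "C", C)
        if not self._connected():
            raise ValueError("design graph must be connected for a joint fit")

    def _connected(self) -> bool:
        J = self.C.shape[0]
        seen = {0}
        frontier = [0]
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(self.C[j]):
                if k not in seen:
                    seen.add(int(k))
                    frontier.append(int(k))
        return len(seen) == J


def build_design(name: str,
                 block_order: Sequence[str] = DEFAULT_BLOCK_ORDER) -> DesignSpec:
    """Named three-block design: 'sequential', 'complete' or 'reversed_sequential'.

    With block order (RNA, IMG, DX): sequential connects RNA–IMG and IMG–DX
    (imaging mediates), complete connects all pairs, reversed_sequential
    connects IMG–RNA and RNA–DX (RNA mediates).
    """
    if name not in NAMED_DESIGNS:
        raise ValueError(
            f"unknown design {name!r}; valid names: {sorted(NAMED_DESIGNS)}"
        )
    if len(block_order) != 3:
        raise ValueError("named designs require exactly 3 blocks")
    C = np.zeros((3, 3))
    for j, k in NAMED_DESIGNS[name]:
        C[j, k] = C[k, j] = 1.0
    return DesignSpec(block_order=tuple(block_order), C=C, name=name)


def _scheme_funcs(scheme: str):
    if scheme == "horst":
        return (lambda x: x), (lambda x: np.ones_like(np.asarray(x, dtype=float)))
    if scheme == "factorial":
        return (lambda x: x ** 2), (lambda x: 2.0 * x)
    if scheme == "centroid":
        return np.abs, np.sign
    raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")


def criterion(blocks: Sequence[np.ndarray], weights: Sequence[np.ndarray],
              design: DesignSpec, scheme: str = "centroid") -> float:
    """Value of the generalized canonical criterion (double sum over j,k).

    Each unordered connected pair contributes twice, matching the double sum
    over ordered pairs; covariances use the n - 1 divisor.
    """
    g, _ = _scheme_funcs(scheme)
    C = design.C
    n = blocks[0].shape[0]
    comps = [np.asarray(X, dtype=float) @ np.asarray(a, dtype=float)
             for X, a in zip(blocks, weights)]
    total = 0.0
    for j in range(len(comps)):
        for k in range(len(comps)):
            if C[j, k]:
                cov = comps[j] @ comps[k] / (n - 1)
                total += float(g(cov))
    return total


def project_l1_l2(v: np.ndarray, bound: float) -> np.ndarray:
    """argmax of v'w over the intersection ||w||_2 <= 1, ||w||_1 <= bound.

    Computed by soft-thresholding ``S(v, lam) / ||S(v, lam)||_2`` with the
    threshold found by bisection (``lam = 0`` when the plain unit vector is
    already feasible).  ``bound`` must be >= 1 so the set contains a unit
    vector.
    """
    v = np.asarray(v, dtype=float)
    if bound < 1.0 - 1e-12:
        raise ValueError("L1 bound must be >= 1")
    norm = np.linalg.norm(v)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("cannot project an all-zero (or non-finite) vector")
    u = v / norm
    if np.abs(u).sum() <= bound + 1e-12:
        return u

    absv = np.abs(v)
    lo, hi = 0.0, absv.max()

    def l1_of(lam: float) -> float:
        s = np.maximum(absv - lam, 0.0)
        nrm = np.linalg.norm(s)
        return np.abs(s).sum() / nrm if nrm > 0 else np.inf

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if l1_of(mid) > bound:
            lo = mid
        else:
            hi = mid
    lam = hi
    s = np.sign(v) * np.maximum(absv - lam, 0.0)
    nrm = np.linalg.norm(s)
    if nrm > 0:
        w = s / nrm
        if np.abs(w).sum() <= bound * (1.0 + 1e-6):
            return w
    # tie-degenerate case: several equal maxima; spread the bound over them
    top = absv >= absv.max() - 1e-12
    m = int(top.sum())
    w = np.zeros_like(v)
    w[top] = np.sign(v[top]) * min(bound / m, 1.0 / np.sqrt(m))
    return w


@dataclass
class FitResult:
    """Fitted weights, components and convergence record of one SGCCA run."""

    weights: List[np.ndarray]
    components: List[np.ndarray]
    criterion_trace: List[float]
    converged: bool
    n_iter: int
    design: DesignSpec
    scheme: str
    mode: str  # "regularized" | "sparse"
    spec: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json
        spec = {k: v for k, v in self.spec.items() if not callable(v)}
        spec["design"] = self.design.name
        if isinstance(spec.get("sparsity"), (list, tuple)):
            spec["sparsity"] = [None if s is None else float(s)
                                for s in spec["sparsity"]]
        return json.dumps({
            "weights": [w.tolist() for w in self.weights],
            "criterion_trace": self.criterion_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "block_order": list(self.design.block_order),
            "design_C": self.design.C.tolist(),
            "scheme": self.scheme,
            "mode": self.mode,
            "spec": spec,
        })

    def weight_table(self, variable_names: Dict[str, Sequence[str]]):
        import pandas as pd
        rows = []
        for b, name in enumerate(self.design.block_order):
            names = variable_names.get(name)
            for i, w in enumerate(self.weights[b]):
                var = names[i] if names is not None else f"v{i}"
                rows.append((name, var, float(w)))
        return pd.DataFrame(rows, columns=["block", "variable", "loading"])


class SGCCA(BaseEstimator):
    """Sparse / regularized generalized CCA estimator (one component per block).

    Parameters
    ----------
    design : DesignSpec or str, default "complete"
        Connection structure between blocks; a string is resolved through
        :func:`build_design` using the default (RNA, IMG, DX) order.
    scheme : {"horst", "factorial", "centroid"}, default "centroid"
        Scheme function g applied to each pairwise component covariance.
    tau : float or sequence of float, default 1.0
        Shrinkage per block for regularized mode; ``tau = 1`` constrains the
        weight norm, ``tau = 0`` the component variance.
    sparsity : None or sequence of (float or None), optional
        Per-block sparsity dials ``s_j in [1/sqrt(p_j), 1]``; the L1 bound is
        ``s_j * sqrt(p_j)``.  ``None`` for a block disables its L1 penalty;
        passing ``sparsity=None`` altogether selects regularized mode.
    tol : float, default 1e-8
        Stop when the criterion gain per sweep falls below this.
    max_iter : int, default 1000
    random_state : int, default 0
        Seed for the random initial weight vectors.

    Attributes
    ----------
    weights_ : list of ndarray
        Fitted weight vector per block (canonical sign convention applied).
    components_ : list of ndarray
        Training-data block components ``y_j = X_j a_j``.
    criterion_trace_ : list of float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, design: Union[DesignSpec, str] = "complete",
                 scheme: str = "centroid", tau: Union[float, Sequence[float]] = 1.0,
                 sparsity: Optional[Sequence[Optional[float]]] = None,
                 tol: float = 1e-8, max_iter: int = 1000, random_state: int = 0):
        self.design = design
        self.scheme = scheme
        self.tau = tau
        self.sparsity = sparsity
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _resolve_design(self, J: int) -> DesignSpec:
        design = self.design
        if isinstance(design, str):
            design = build_design(design)
        if design.C.shape[0] != J:
            raise ValueError(
                f"design has {design.C.shape[0]} blocks but {J} were supplied"
            )
        return design

    def _bounds(self, shapes: List[int]) -> Optional[List[float]]:
        if self.sparsity is None:
            return None
        if len(self.sparsity) != len(shapes):
            raise ValueError("sparsity must provide one entry per block")
        bounds = []
        for s, p in zip(self.sparsity, shapes):
            if s is None:
                bounds.append(float(np.sqrt(p)))
                continue
            lo = 1.0 / np.sqrt(p)
            if not (lo - 1e-12 <= s <= 1.0 + 1e-12):
                raise ValueError(
                    f"sparsity dial {s} outside [1/sqrt(p), 1] = [{lo:.4f}, 1] "
                    f"for a block with p={p}"
                )
            bounds.append(float(min(max(s, lo), 1.0) * np.sqrt(p)))
        return bounds

    # -- fitting -----------------------------------------------------------
    def fit(self, blocks: Sequence[np.ndarray], y=None) -> "SGCCA":
        Xs = [np.asarray(X, dtype=float) for X in blocks]
        n = Xs[0].shape[0]
        if any(X.shape[0] != n for X in Xs):
            raise ValueError("all blocks must share the number of rows")
        J = len(Xs)
        design = self._resolve_design(J)
        C = design.C
        g, dg = _scheme_funcs(self.scheme)
        shapes = [X.shape[1] for X in Xs]
        bounds = self._bounds(shapes)
        sparse_mode = bounds is not None

        if sparse_mode:
            taus = [1.0] * J
        else:
            taus = ([float(self.tau)] * J if np.isscalar(self.tau)
                    else [float(t) for t in self.tau])
            if len(taus) != J:
                raise ValueError("tau must be a scalar or one value per block")
            if any(not 0.0 <= t <= 1.0 for t in taus):
                raise ValueError("tau values must lie in [0, 1]")
        Minv = None
        if not sparse_mode:
            Minv = []
            for X, t in zip(Xs, taus):
                p = X.shape[1]
                M = t * np.eye(p) + (1.0 - t) * (X.T @ X) / n
                # guard positive definiteness for tau -> 0 on wide blocks
                jitter = 0.0
                while True:
                    try:
                        Minv.append(np.linalg.inv(M + jitter * np.eye(p)))
                        break
                    except np.linalg.LinAlgError:
                        jitter = max(jitter * 10, 1e-10)

        rng = np.random.default_rng(self.random_state)
        weights = []
        for b, X in enumerate(Xs):
            v = rng.standard_normal(X.shape[1])
            if sparse_mode:
                weights.append(project_l1_l2(v, bounds[b]))
            else:
                Mv = Minv[b] @ v
                weights.append(Mv / np.sqrt(v @ Mv))
        comps = [X @ a for X, a in zip(Xs, weights)]

        def crit() -> float:
            total = 0.0
            for j in range(J):
                for k in range(J):
                    if C[j, k]:
                        total += float(g(comps[j] @ comps[k] / (n - 1)))
            return total

        trace = [crit()]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for j in range(J):
                target = np.zeros(n)
                for k in np.flatnonzero(C[j]):
                    cov = comps[j] @ comps[k] / (n - 1)
                    target += float(dg(cov)) * comps[k]
                grad = Xs[j].T @ target / (n - 1)
                if np.linalg.norm(grad) < 1e-300:
                    continue  # disconnected-in-practice: keep previous weights
                if sparse_mode:
                    weights[j] = project_l1_l2(grad, bounds[j])
                else:
                    Mg = Minv[j] @ grad
                    weights[j] = Mg / np.sqrt(grad @ Mg)
                comps[j] = Xs[j] @ weights[j]
            trace.append(crit())
            if trace[-1] - trace[-2] < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"SGCCA did not converge in {self.max_iter} iterations "
                f"(last gain {trace[-1] - trace[-2]:.3e})", RuntimeWarning)

        weights = self._canonical_signs(weights)
        comps = [X @ a for X, a in zip(Xs, weights)]

        self.design_ = design
        self.weights_ = weights
        self.components_ = comps
        self.criterion_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = it
        self.n_features_in_ = sum(shapes)
        self._shapes = shapes
        self._mode = "sparse" if sparse_mode else "regularized"
        return self

    def _canonical_signs(self, weights: List[np.ndarray]) -> List[np.ndarray]:
        """Largest-|entry| positive; joint flip only for the sign-sensitive scheme."""
        if self.scheme == "horst":
            lead = weights[0]
            if lead[np.argmax(np.abs(lead))] < 0:
                return [-w for w in weights]
            return weights
        out = []
        for w in weights:
            flip = -1.0 if w[np.argmax(np.abs(w))] < 0 else 1.0
            out.append(flip * w)
        return out

    def transform(self, blocks: Sequence[np.ndarray]) -> np.ndarray:
        """Component scores ``y_j = X_j a_j`` for (possibly new) subjects.

        Returns an ``n x J`` array, one column per block in design order.
        """
        check_is_fitted(self, "weights_")
        Xs = [np.asarray(X, dtype=float) for X in blocks]
        if len(Xs) != len(self.weights_):
            raise ValueError("block count does not match the fitted model")
        for X, p in zip(Xs, self._shapes):
            if X.shape[1] != p:
                raise ValueError(
                    f"block width {X.shape[1]} does not match fitted width {p}"
                )
        return np.column_stack([X @ a for X, a in zip(Xs, self.weights_)])

    def fit_transform(self, blocks, y=None) -> np.ndarray:
        return self.fit(blocks).transform(blocks)

    def result(self) -> FitResult:
        check_is_fitted(self, "weights_")
        return FitResult(
            weights=[w.copy() for w in self.weights_],
            components=[c.copy() for c in self.components_],
            criterion_trace=list(self.criterion_trace_),
            converged=self.converged_,
            n_iter=self.n_iter_,
            design=self.design_,
            scheme=self.scheme,
            mode=self._mode,
            spec=self.get_params(deep=False),
        )


def fit(blocks, design="complete", scheme="centroid", tau=1.0, sparsity=None,
        tol=1e-8, max_iter=1000, seed=0) -> FitResult:
    """Functional wrapper over :class:`SGCCA`."""
    est = SGCCA(design=design, scheme=scheme, tau=tau, sparsity=sparsity,
                tol=tol, max_iter=max_iter, random_state=seed)
    return est.fit(blocks).result()


def components(result: FitResult, blocks) -> List[np.ndarray]:
    """Block components ``y_j = X_j a_j`` from a fitted result."""
    Xs = [np.asarray(X, dtype=float) for X in blocks]
    if len(Xs) != len(result.weights):
        raise ValueError("block count does not match the fit")
    out = []
    for X, a in zip(Xs, result.weights):
        if X.shape[1] != a.shape[0]:
            raise ValueError(
                f"block width {X.shape[1]} does not match weight length {a.shape[0]}"
            )
        out.append(X @ a)
    return out
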