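"""Sparse decomposition of a complex sample into raw-ingredient profiles.

A complex mixture (a prepared dish, a microbial community) is modelled as
approximately the *union* of the binary molecular profiles of a few raw
ingredients.  Given a reference matrix ``D`` (features × candidate
ingredients) and a query profile ``c`` (binary vector over the same
features), the abundance vector ``x`` is recovered by minimizing a balanced,
L1-penalized logistic objective

    F(x) = sum_t  CE(c_t, sigmoid((D x)_t)) / b_t  +  lambda * ||x||_1

where ``CE`` is the binary cross-entropy and ``b_t`` is the number of
entries of ``c`` sharing the value ``c_t``.  The ``1/b_t`` weights give the
present (1) and absent (0) feature classes equal total mass, so the huge
majority of absent features cannot drown out the few present ones.  The
penalty weight ``lambda`` is raised until exactly ``k`` (default 5)
coefficients remain non-zero; those coefficients name the predicted
ingredients, ranked by coefficient.

The objective is convex; it is minimized by an accelerated proximal-gradient
method (FISTA with adaptive restart), which handles both the unconstrained
and the nonnegativity-constrained variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io import FeatureMatrix, align_features

_CLIP = 1e-12  # probability floor/ceiling inside cross-entropy
_NONZERO_REL = 1e-6  # |x_i| > _NONZERO_REL * max(1, ||x||_inf) counts as non-zero


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_x: np.ndarray, gap: float):
        super().__init__(message)
        self.best_x = best_x
        self.gap = gap


def sigmoid(z):
    """Logistic function 1 / (1 + exp(-z)), overflow-safe for large |z|."""
    return expit(z)


def cross_entropy(y, yhat):
    """Binary cross-entropy -y log(yhat) - (1-y) log(1-yhat).

    ``yhat`` must lie in [0, 1]; it is clamped away from {0, 1} by 1e-12 so
    the value stays finite.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.any(yhat < 0) or np.any(yhat > 1):
        raise ValueError("predicted probability outside [0, 1]")
    p = np.clip(yhat, _CLIP, 1.0 - _CLIP)
    return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))


def balance_weights(c: np.ndarray) -> np.ndarray:
    """Per-row weights 1 / b_t, with b_t the multiplicity of the value c_t.

    When ``c`` contains both 0s and 1s the weights sum to exactly 2 (one unit
    of mass per value class); for a constant ``c`` they sum to 1.
    """
    c = np.asarray(c)
    n1 = int(c.sum())
    n0 = c.size - n1
    w = np.empty(c.size, dtype=float)
    if n1:
        w[c == 1] = 1.0 / n1
    if n0:
        w[c == 0] = 1.0 / n0
    return w


@dataclass
class DecompositionProblem:
    """A fixed-lambda instance of the balanced decomposition objective."""

    D: np.ndarray  # (n_features, n_ingredients), binary
    c: np.ndarray  # (n_features,), binary
    lam: float
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    ingredient_ids: list[str] = field(default_factory=list)
    nonneg: bool = False

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.D.shape[0] != self.c.size:
            raise ValueError(
                f"D has {self.D.shape[0]} rows but c has {self.c.size} entries"
            )
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.weights is None:
            self.weights = balance_weights(self.c)
        if not self.ingredient_ids:
            self.ingredient_ids = [f"ing{i}" for i in range(self.D.shape[1])]

    @property
    def n_ingredients(self) -> int:
        return self.D.shape[1]

    def is_degenerate(self) -> bool:
        """True when c is constant (single value class; weight mass 1)."""
        return self.c.min() == self.c.max()


def objective(x: np.ndarray, problem: DecompositionProblem) -> float:
    """Balanced cross-entropy + L1 value F(x)."""
    x = np.asarray(x, dtype=float)
    if x.size != problem.n_ingredients:
        raise ValueError(
            f"x has {x.size} entries for {problem.n_ingredients} ingredients"
        )
    z = problem.D @ x
    ce = cross_entropy(problem.c, sigmoid(z))
    return float(problem.weights @ ce + problem.lam * np.abs(x).sum())


def _smooth_grad(x: np.ndarray, problem: DecompositionProblem) -> np.ndarray:
    z = problem.D @ x
    return problem.D.T @ (problem.weights * (expit(z) - problem.c))


def lambda_max(problem: DecompositionProblem) -> float:
    """Smallest penalty at which x = 0 is optimal.

    From the L1 optimality condition at the origin: lambda_max is the
    infinity-norm of the gradient of the smooth (cross-entropy) term at 0.
    """
    g0 = problem.D.T @ (problem.weights * (0.5 - problem.c))
    if problem.nonneg:
        # only negative gradient components pull x off 0 into the feasible set
        return float(max(0.0, (-g0).max(initial=0.0)))
    return float(np.abs(g0).max(initial=0.0))


def _prox(v: np.ndarray, t: float, nonneg: bool) -> np.ndarray:
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    if nonneg:
        np.maximum(out, 0.0, out=out)
    return out


def solve_fixed_lambda(
    problem: DecompositionProblem,
    tol: float = 1e-10,
    max_iter: int = 50000,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize the convex objective at the problem's fixed lambda.

    FISTA with adaptive (function-value) restart; step size 1/L with
    L = ||sqrt(w) D||_2^2 / 4, the Lipschitz constant of the weighted
    cross-entropy gradient.  Deterministic: identical inputs give identical
    iterates.  Convergence is declared when the relative objective decrease
    stays below ``tol`` and the proximal-gradient residual is small; failure
    raises :class:`ConvergenceError` carrying the best iterate.
    """
    D, w, lam = problem.D, problem.weights, problem.lam
    n = problem.n_ingredients
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if problem.nonneg:
        np.maximum(x, 0.0, out=x)

    M = np.sqrt(w)[:, None] * D
    L = 0.25 * float(np.linalg.norm(M, 2)) ** 2
    if L <= 0.0:
        return np.zeros(n)
    step = 1.0 / L

    z = x.copy()
    t_mom = 1.0
    f_x = objective(x, problem)
    stall = 0
    for _ in range(max_iter):
        g = _smooth_grad(z, problem)
        x_new = _prox(z - step * g, step * lam, problem.nonneg)
        f_new = objective(x_new, problem)
        if f_new > f_x:  # adaptive restart: drop momentum
            z = x.copy()
            t_mom = 1.0
            g = _smooth_grad(z, problem)
            x_new = _prox(z - step * g, step * lam, problem.nonneg)
            f_new = objective(x_new, problem)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = x_new + ((t_mom - 1.0) / t_next) * (x_new - x)
        t_mom = t_next
        rel = abs(f_x - f_new) / max(1.0, abs(f_x))
        x, f_x = x_new, f_new
        if rel < tol:
            stall += 1
            if stall >= 3 and _prox_residual(x, problem, step) < 1e-7:
                return x
        else:
            stall = 0
    resid = _prox_residual(x, problem, step)
    if resid < 1e-5:  # converged in practice, just short of the strict test
        return x
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (residual {resid:.2e})",
        best_x=x,
        gap=resid,
    )


def _prox_residual(x: np.ndarray, problem: DecompositionProblem, step: float) -> float:
    g = _smooth_grad(x, problem)
    return float(
        np.abs(x - _prox(x - step * g, step * problem.lam, problem.nonneg)).max(
            initial=0.0
        )
    )


def _nonzero_mask(x: np.ndarray) -> np.ndarray:
    thr = _NONZERO_REL * max(1.0, float(np.abs(x).max(initial=0.0)))
    return np.abs(x) > thr


def _select(x: np.ndarray, ids: Sequence[str]) -> list[str]:
    """Non-zero ingredient IDs ordered by descending coefficient, then ID."""
    mask = _nonzero_mask(x)
    chosen = [(float(-x[i]), ids[i]) for i in np.flatnonzero(mask)]
    return [i for _, i in sorted(chosen)]


@dataclass
class DecompositionResult:
    """Outcome of the lambda-path search for one complex sample.

    ``selected`` lists the predicted ingredient IDs by descending
    coefficient; ``path_log`` records every ``(lambda, nonzero_count)`` the
    search visited.  ``fallback`` marks results where no lambda attained
    exactly ``k`` non-zeros (the count jumped over ``k``) and the documented
    truncation rule was applied; ``degenerate`` marks constant query vectors.
    """

    x: np.ndarray
    ingredient_ids: list[str]
    selected: list[str]
    abundances: list[float]
    lambda_used: float
    objective_value: float
    nonzero_count: int
    path_log: list[tuple[float, int]]
    fallback: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "table": [
                {"ingredient_id": i, "abundance": float(a)}
                for i, a in zip(self.selected, self.abundances)
            ],
            "ingredient_ids": list(self.ingredient_ids),
            "x": [float(v) for v in self.x],
            "lambda_used": float(self.lambda_used),
            "objective_value": float(self.objective_value),
            "nonzero_count": int(self.nonzero_count),
            "path_log": [[float(l), int(c)] for l, c in self.path_log],
            "fallback": bool(self.fallback),
            "degenerate": bool(self.degenerate),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DecompositionResult":
        table = payload.get("table", [])
        return cls(
            x=np.asarray(payload["x"], dtype=float),
            ingredient_ids=list(payload["ingredient_ids"]),
            selected=[row["ingredient_id"] for row in table],
            abundances=[float(row["abundance"]) for row in table],
            lambda_used=float(payload["lambda_used"]),
            objective_value=float(payload["objective_value"]),
            nonzero_count=int(payload["nonzero_count"]),
            path_log=[(float(l), int(c)) for l, c in payload["path_log"]],
            fallback=bool(payload["fallback"]),
            degenerate=bool(payload["degenerate"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecompositionResult):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def summary(self) -> str:
        lines = [
            "Sparse mixture decomposition",
            f"  candidates: {len(self.ingredient_ids)}   "
            f"lambda: {self.lambda_used:.6g}   objective: {self.objective_value:.6g}",
            f"  non-zero coefficients: {self.nonzero_count}"
            + ("   [fallback truncation]" if self.fallback else "")
            + ("   [degenerate input]" if self.degenerate else ""),
            "  rank  ingredient            abundance",
        ]
        for r, (i, a) in enumerate(zip(self.selected, self.abundances), 1):
            lines.append(f"  {r:>4}  {i:<20}  {a:+.4f}")
        return "\n".join(lines)


def lambda_path_to_k(
    problem: DecompositionProblem,
    k: int = 5,
    factor: float = 0.8,
    max_bisect: int = 60,
    tol: float = 1e-10,
) -> DecompositionResult:
    """Search the L1 path for the penalty giving exactly ``k`` non-zeros.

    Strategy: start at the analytic ``lambda_max`` (zero solution), descend
    geometrically (× ``factor``) with warm starts until the non-zero count
    reaches ``k``; if the count jumps past ``k``, bisect (geometric midpoint)
    between the bracketing penalties for at most ``max_bisect`` steps.  If no
    visited penalty attains exactly ``k`` (supports can activate in groups),
    fall back to the visited solution with the smallest count ≥ k, rank its
    coefficients, truncate to ``k``, and flag the result.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > problem.n_ingredients:
        raise ValueError(
            f"k={k} exceeds the {problem.n_ingredients} candidate ingredients"
        )
    ids = problem.ingredient_ids

    if problem.is_degenerate():
        x = np.zeros(problem.n_ingredients)
        prob0 = _with_lambda(problem, lambda_max(problem))
        return DecompositionResult(
            x=x, ingredient_ids=list(ids), selected=[], abundances=[],
            lambda_used=prob0.lam, objective_value=objective(x, prob0),
            nonzero_count=0, path_log=[(prob0.lam, 0)], degenerate=True,
        )

    lam_top = lambda_max(problem)
    if lam_top <= 0:
        lam_top = 1.0
    path_log: list[tuple[float, int]] = []
    solutions: dict[float, np.ndarray] = {}

    def solve_at(lam: float, x0: np.ndarray | None) -> tuple[np.ndarray, int]:
        x = solve_fixed_lambda(_with_lambda(problem, lam), tol=tol, x0=x0)
        cnt = int(_nonzero_mask(x).sum())
        path_log.append((lam, cnt))
        solutions[lam] = x
        return x, cnt

    def finish(lam: float, x: np.ndarray, fallback: bool) -> DecompositionResult:
        sel = _select(x, ids)[:k]
        abund = [float(x[ids.index(i)]) for i in sel]
        return DecompositionResult(
            x=x, ingredient_ids=list(ids), selected=sel, abundances=abund,
            lambda_used=lam,
            objective_value=objective(x, _with_lambda(problem, lam)),
            nonzero_count=int(_nonzero_mask(x).sum()),
            path_log=path_log, fallback=fallback,
        )

    x, cnt = solve_at(lam_top, None)
    hi, lo = lam_top, None
    x_warm = x
    lam = lam_top
    for _ in range(200):
        lam *= factor
        x, cnt = solve_at(lam, x_warm)
        if cnt == k:
            return finish(lam, x, fallback=False)
        if cnt > k:
            lo = lam
            break
        hi, x_warm = lam, x
        if lam < lam_top * 1e-8:
            break
    if lo is None:
        # even a vanishing penalty never activated k coefficients
        best_lam = min(solutions, key=lambda l: (-path_log_count(path_log, l), l))
        return finish(best_lam, solutions[best_lam], fallback=True)

    for _ in range(max_bisect):
        mid = float(np.sqrt(lo * hi))
        x, cnt = solve_at(mid, solutions[lo])
        if cnt == k:
            return finish(mid, x, fallback=False)
        if cnt < k:
            hi = mid
        else:
            lo = mid

    # no exact hit: smallest visited count >= k, at the largest such lambda
    candidates = [(c, -l) for l, c in path_log if c >= k]
    best_cnt, neg_lam = min(candidates)
    best_lam = -neg_lam
    return finish(best_lam, solutions[best_lam], fallback=True)


def path_log_count(path_log: list[tuple[float, int]], lam: float) -> int:
    for l, c in path_log:
        if l == lam:
            return c
    raise KeyError(lam)


def _with_lambda(problem: DecompositionProblem, lam: float) -> DecompositionProblem:
    return DecompositionProblem(
        D=problem.D, c=problem.c, lam=lam, weights=problem.weights,
        ingredient_ids=problem.ingredient_ids, nonneg=problem.nonneg,
    )


class MixtureDecomposer:
    """Model object: decompose one complex sample against a reference library.

    Parameters
    ----------
    library
        Reference matrix of raw-ingredient profiles (features × ingredients).
    sample
        The complex sample: either a plain binary vector over the library's
        feature axis, or a single-column :class:`~metmix.io.FeatureMatrix`
        (then the feature axes are aligned by ID; features unknown to the
        library are zero-filled on the library side and vice versa).
    nonneg
        Constrain abundances to x >= 0.  The default is the unconstrained
        problem, whose selection ranks by signed coefficient (large positive
        = ingredient present).
    """

    def __init__(
        self,
        library: FeatureMatrix,
        sample: FeatureMatrix | np.ndarray,
        nonneg: bool = False,
    ):
        if library.n_samples == 0:
            raise ValueError("empty ingredient library")
        if isinstance(sample, FeatureMatrix):
            if sample.n_samples != 1:
                raise ValueError("sample must be a single column")
            lib_al, sam_al = align_features(library, sample)
            D = lib_al.values.astype(float)
            c = sam_al.values[:, 0].astype(float)
        else:
            c = np.asarray(sample, dtype=float).ravel()
            if c.size != library.n_features:
                raise ValueError(
                    f"sample has {c.size} features, library has "
                    f"{library.n_features}; pass a FeatureMatrix to auto-align"
                )
            D = library.values.astype(float)
        self.problem = DecompositionProblem(
            D=D, c=c, lam=0.0, ingredient_ids=list(library.sample_ids),
            nonneg=nonneg,
        )

    def fit(self, k: int = 5, **path_kwargs) -> DecompositionResult:
        """Run the lambda-path search down to ``k`` non-zero ingredients."""
        return lambda_path_to_k(self.problem, k=k, **path_kwargs)


def predict_ingredients(
    library: FeatureMatrix,
    sample: FeatureMatrix | np.ndarray,
    k: int = 5,
    nonneg: bool = False,
) -> DecompositionResult:
    """Convenience wrapper: align, weight, and search the path to ``k`` IDs."""
    return MixtureDecomposer(library, sample, nonneg=nonneg).fit(k=k)


def overlap_score(predicted: Sequence[str], annotated: Sequence[str]) -> int:
    """|predicted ∩ annotated| — the number of predicted IDs that are correct."""
    predicted = set(predicted)
    if not predicted:
        raise ValueError("empty prediction set")
    return len(predicted & set(annotated))


def random_baseline(library: FeatureMatrix, k: int = 5, seed: int = 0) -> set[str]:
    """k ingredient IDs drawn uniformly without replacement (null predictor)."""
    n = library.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds library size {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return {library.sample_ids[i] for i in idx}
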