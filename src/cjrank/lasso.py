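"""L1-penalized linear scorer for automated quality-of-reasoning assessment.

Fits win percentages (the continuous quality score derived from forced
choices, in [0, 1]) on linguistic feature vectors with the LASSO: the
penalty shrinks coefficients and zeroes most of them out, leaving a small
interpretable feature subset. The solver is cyclic coordinate descent with
soft thresholding on internally standardized predictors, the penalty is
chosen by seeded k-fold cross-validation at the held-out-error minimum
(``lambda.min``), and two train/test regimes are provided:

* ``rationale_split`` — rationales sampled across problems, so every
  problem can contribute to both sides (within-domain generalization);
* ``problem_split`` — whole problems assigned to one side (transfer of
  reasoning across domains).

Objective (glmnet convention): (1/2n)·‖y − Xβ‖² + λ·‖β‖₁.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LassoFit",
    "CvResult",
    "RegimeReport",
    "ConvergenceError",
    "soft_threshold",
    "lambda_max",
    "fit_lasso",
    "cv_lambda_min",
    "evaluate_regime",
]


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within max_iter sweeps."""

    def __init__(self, max_iter: int, delta: float):
        super().__init__(
            f"no convergence after {max_iter} sweeps (last max update {delta:.3g})"
        )
        self.max_iter = max_iter


def soft_threshold(z: float, gamma: float):
    """sign(z)·max(|z| − γ, 0), the coordinate-descent shrinkage primitive."""
    if gamma < 0:
        raise ValueError("threshold must be >= 0")
    return np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)


@dataclass
class LassoFit:
    """A fitted model on the original feature scale; features absent from
    ``coefficients`` (dropped constants) are exactly zero."""

    intercept: float
    coefficients: pd.Series
    lam: float
    n_iter: int
    feature_means: pd.Series
    feature_sds: pd.Series

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0.0).sum())

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        beta = self.coefficients.reindex(X.columns, fill_value=0.0)
        return self.intercept + X.to_numpy(dtype=float) @ beta.to_numpy()


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0 so that (1/n)·xᵀx = 1 exactly
    keep = sd > 0.0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def _descend(
    Xs: np.ndarray,
    yc: np.ndarray,
    lam: float,
    tol: float,
    max_iter: int,
    b0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on standardized predictors and centered
    response; converged when the largest coefficient update < tol."""
    n, p = Xs.shape
    b = np.zeros(p) if b0 is None else b0.copy()
    resid = yc - Xs @ b
    for sweep in range(1, max_iter + 1):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = Xs[:, j] @ resid / n + old
            new = float(soft_threshold(rho, lam))
            if new != old:
                resid -= Xs[:, j] * (new - old)
                step = abs(new - old)
                if step > delta:
                    delta = step
                b[j] = new
        if delta < tol:
            return b, sweep
    raise ConvergenceError(max_iter, delta)


def lambda_max(X, y) -> float:
    """Smallest penalty at which every coefficient is zero:
    max_j |x_jᵀ(y − ȳ)|/n on standardized predictors."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, _, _, _ = _standardize(Xm)
    if Xs.shape[1] == 0:
        return 0.0
    yc = y - y.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / len(y))


def fit_lasso(
    X,
    y,
    lam: float,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> LassoFit:
    """Fit the LASSO at a fixed penalty.

    Predictors are standardized internally (constant features dropped);
    reported coefficients are on the original scale and the intercept
    absorbs the centering, so ``fit.predict`` applies to raw features.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if Xm.ndim != 2 or Xm.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if Xm.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xs, mean, sd, keep = _standardize(Xm)
    yc = y - y.mean()
    b_std, n_iter = _descend(Xs, yc, lam, tolerance, max_iter)
    beta = np.zeros(Xm.shape[1])
    beta[keep] = b_std / sd[keep]
    intercept = float(y.mean() - mean @ beta)
    return LassoFit(
        intercept=intercept,
        coefficients=pd.Series(beta, index=names),
        lam=lam,
        n_iter=n_iter,
        feature_means=pd.Series(mean, index=names),
        feature_sds=pd.Series(sd, index=names),
    )


@dataclass
class CvResult:
    """Cross-validation curve over a penalty grid."""

    lambdas: np.ndarray
    mean_cv_error: np.ndarray
    lambda_min: float
    seed: int
    k: int

    def __post_init__(self) -> None:
        i = int(np.argmin(self.mean_cv_error))
        assert self.lambdas[i] == self.lambda_min


def default_lambda_grid(X, y, n_lambdas: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced descending grid from lambda_max down ``decades`` decades."""
    lmax = lambda_max(X, y)
    if lmax == 0.0:
        return np.array([0.0])
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_lambdas)


def cv_lambda_min(
    X,
    y,
    k: int = 10,
    lambdas: Optional[Sequence[float]] = None,
    seed: int = 0,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
) -> CvResult:
    """Pick the penalty minimizing mean held-out squared error under a
    seeded k-fold split (``lambda.min``). Folds are refit along the grid
    with warm starts."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available rows")
    grid = (
        np.asarray(list(lambdas), dtype=float)
        if lambdas is not None
        else default_lambda_grid(Xm, y)
    )
    grid = np.sort(grid)[::-1]
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n) % k
    errors = np.zeros((k, grid.size))
    for fold in range(k):
        test = fold_of == fold
        Xtr, ytr = Xm[~test], y[~test]
        Xte, yte = Xm[test], y[test]
        Xs, mean, sd, keep = _standardize(Xtr)
        yc = ytr - ytr.mean()
        b = np.zeros(int(keep.sum()))
        for gi, lam in enumerate(grid):
            b, _ = _descend(Xs, yc, lam, tolerance, max_iter, b0=b)
            beta = np.zeros(Xm.shape[1])
            beta[keep] = b / sd[keep]
            pred = ytr.mean() + (Xte - mean) @ beta
            errors[fold, gi] = np.mean((yte - pred) ** 2)
    mean_err = errors.mean(axis=0)
    lam_min = float(grid[int(np.argmin(mean_err))])
    return CvResult(grid, mean_err, lam_min, seed, k)


@dataclass
class RegimeReport:
    """Averages over repeated train/test splits of one evaluation regime."""

    regime: str
    train_fraction: float
    n_reps: int
    n_skipped: int
    mean_n_nonzero: float
    mean_r_win_pct: float
    mean_r_accuracy: Optional[float]
    per_rep: pd.DataFrame = field(repr=False, default=None)


def evaluate_regime(
    problem_ids: pd.Series,
    features: pd.DataFrame,
    win_pct: pd.Series,
    accuracy: Optional[pd.Series] = None,
    regime: str = "rationale_split",
    train_fraction: float = 0.5,
    n_reps: int = 100,
    k: int = 10,
    seed: int = 0,
) -> RegimeReport:
    """Repeatedly train the automated scorer and measure held-out quality.

    Per repetition: draw a training set under the regime
    (``rationale_split`` samples items across problems; ``problem_split``
    assigns whole problems to one side), pick λ by internal CV, refit,
    predict the test win percentages, and record the nonzero-coefficient
    count plus the Pearson correlations of the predictions with the
    held-out win percentages and (optionally) with normalized accuracy.
    Repetitions whose test responses are degenerate (constant) are skipped
    and counted. Averages are over the completed repetitions.
    """
    if regime not in ("rationale_split", "problem_split"):
        raise ValueError("regime must be 'rationale_split' or 'problem_split'")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    idx = features.index
    problem_ids = problem_ids.reindex(idx)
    y = win_pct.reindex(idx).to_numpy(dtype=float)
    acc = accuracy.reindex(idx).to_numpy(dtype=float) if accuracy is not None else None
    Xm = features.to_numpy(dtype=float)
    n = len(idx)
    problems = pd.unique(problem_ids)
    if regime == "problem_split" and len(problems) < 2:
        raise ValueError("problem_split needs at least 2 problems")

    root = np.random.SeedSequence(seed)
    rep_rows = []
    n_skipped = 0
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        if regime == "rationale_split":
            n_train = int(np.clip(round(train_fraction * n), 2, n - 2))
            train_mask = np.zeros(n, dtype=bool)
            train_mask[rng.choice(n, size=n_train, replace=False)] = True
        else:
            n_train_p = int(
                np.clip(round(train_fraction * len(problems)), 1, len(problems) - 1)
            )
            chosen = set(rng.choice(problems, size=n_train_p, replace=False))
            train_mask = problem_ids.isin(chosen).to_numpy()
            assert not (
                set(problem_ids[train_mask]) & set(problem_ids[~train_mask])
            ), "problem leaked across the split"
        test_mask = ~train_mask
        ytr, yte = y[train_mask], y[test_mask]
        if ytr.std() == 0.0 or yte.std() == 0.0 or test_mask.sum() < 3:
            n_skipped += 1
            continue
        kk = min(k, train_mask.sum())
        cv = cv_lambda_min(Xm[train_mask], ytr, k=kk, seed=int(rng.integers(2**31)))
        fit = fit_lasso(
            pd.DataFrame(Xm[train_mask], columns=features.columns),
            ytr,
            cv.lambda_min,
        )
        pred = fit.predict(pd.DataFrame(Xm[test_mask], columns=features.columns))
        if pred.std() == 0.0:
            r_win = 0.0
            r_acc = 0.0 if acc is not None else None
        else:
            r_win = float(np.corrcoef(pred, yte)[0, 1])
            r_acc = (
                float(np.corrcoef(pred, acc[test_mask])[0, 1])
                if acc is not None
                else None
            )
        rep_rows.append(
            {
                "rep": rep,
                "n_nonzero": fit.n_nonzero,
                "r_win_pct": r_win,
                "r_accuracy": r_acc,
                "lambda_min": cv.lambda_min,
            }
        )
    if not rep_rows:
        raise ValueError("every repetition was degenerate")
    per_rep = pd.DataFrame(rep_rows)
    return RegimeReport(
        regime=regime,
        train_fraction=train_fraction,
        n_reps=n_reps,
        n_skipped=n_skipped,
        mean_n_nonzero=float(per_rep["n_nonzero"].mean()),
        mean_r_win_pct=float(per_rep["r_win_pct"].mean()),
        mean_r_accuracy=(
            float(per_rep["r_accuracy"].mean()) if accuracy is not None else None
        ),
        per_rep=per_rep,
    )
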