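"""Plankton community ordination: Hellinger transform, PCA, RDA, selection.

Community matrices (samples x taxa, cell densities or biomass) are
Hellinger-transformed — square root of relative abundance — so that
Euclidean-metric linear ordination is appropriate for species data. PCA
summarises unconstrained structure; redundancy analysis (RDA) is the PCA of
the fitted values of a multivariate linear regression of the community on
standardized environmental predictors, so its constrained eigenvalues can
never exceed the unconstrained ones. Collinear predictors are screened with
variance inflation factors, and a parsimonious constrained model is built by
greedy forward selection under AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OrdinationResult", "hellinger", "pca", "rda", "vif",
    "forward_select_rda", "pc1_env_regression", "richness_summary",
]


@dataclass
class OrdinationResult:
    method: str                      # "PCA" or "RDA"
    eigenvalues: np.ndarray          # non-increasing
    total_variance: float
    scores: np.ndarray               # samples x axes
    loadings: np.ndarray             # variables x axes
    selected_variables: list[str] = field(default_factory=list)
    vifs: dict[str, float] = field(default_factory=dict)
    constrained_proportion: float | None = None
    aic: float | None = None

    @property
    def proportion_explained(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


def hellinger(matrix: np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundance.

    Every transformed row has unit sum of squares. Zero row sums are an
    error (an empty sample cannot be ordinated).
    """
    Y = np.asarray(matrix, dtype=float)
    if np.any(Y < 0):
        raise ValueError("abundances must be non-negative")
    rowsum = Y.sum(axis=1)
    zero = np.flatnonzero(rowsum == 0)
    if zero.size:
        raise ValueError(f"zero row sum for sample index {zero[0]}")
    return np.sqrt(Y / rowsum[:, None])


def _signed_eig(C: np.ndarray, scores_base: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose a covariance matrix; sign: largest |loading| positive."""
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1.0
    scores = scores_base @ evecs
    return evals, evecs, scores


def pca(matrix: np.ndarray) -> OrdinationResult:
    """PCA of the column-centered covariance matrix of ``matrix``."""
    Y = np.asarray(matrix, dtype=float)
    n, m = Y.shape
    if n < 2 or m < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    Yc = Y - Y.mean(axis=0)
    C = Yc.T @ Yc / (n - 1)
    total = float(np.trace(C))
    if total <= 0:
        raise ValueError("matrix has rank 0 after centering")
    evals, evecs, scores = _signed_eig(C, Yc)
    return OrdinationResult(method="PCA", eigenvalues=evals, total_variance=total,
                            scores=scores, loadings=evecs)


def vif(X: np.ndarray, names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j).

    R²_j is from regressing predictor j on all the others (with intercept).
    Perfect collinearity reports ``inf``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    names = names if names is not None else [f"x{j}" for j in range(p)]
    out: dict[str, float] = {}
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _fit_multivariate(Y: np.ndarray, X: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Centered multivariate OLS: fitted values, residuals, total RSS."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    if X.shape[1] == 0:
        fitted = np.zeros_like(Yc)
    else:
        Xc = X - X.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ coef
    resid = Yc - fitted
    return fitted, resid, float(np.sum(resid ** 2))


def rda(Y: np.ndarray, X: np.ndarray,
        var_names: list[str] | None = None) -> OrdinationResult:
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    ``Y`` is the (Hellinger-transformed) community matrix, ``X`` the
    standardized environmental matrix. Constrained eigenvalues are the
    covariance eigenvalues of the fitted community; the constrained
    proportion is their sum over the total community variance.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = Y.shape
    if X.shape[0] != n:
        raise ValueError("Y and X must have the same number of samples")
    if X.shape[1] >= n:
        raise ValueError("need more samples than predictors")
    if X.shape[1] >= 1 and np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "collinear predictors; screen with vif() before the RDA")
    fitted, _, _ = _fit_multivariate(Y, X)
    Yc = Y - Y.mean(axis=0)
    total = float(np.sum(Yc ** 2) / (n - 1))
    C = fitted.T @ fitted / (n - 1)
    evals, evecs, scores = _signed_eig(C, Yc)
    rank = X.shape[1]
    evals = evals[: max(rank, 1)]
    constrained = float(evals.sum() / total) if total > 0 else 0.0
    names = var_names if var_names is not None else [f"x{j}" for j in range(X.shape[1])]
    return OrdinationResult(method="RDA", eigenvalues=evals, total_variance=total,
                            scores=scores[:, : max(rank, 1)],
                            loadings=evecs[:, : max(rank, 1)],
                            selected_variables=list(names),
                            constrained_proportion=constrained)


def _aic(Y: np.ndarray, X: np.ndarray) -> float:
    """AIC of the multivariate regression from the pooled residual SS.

    Convention: n ln(RSS/n) + 2 (q + 1), with RSS the trace of the residual
    cross-product and q the number of predictors. Comparable across nested
    models on the same data.
    """
    n = Y.shape[0]
    _, _, rss = _fit_multivariate(Y, X)
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + 2.0 * (X.shape[1] + 1))


def forward_select_rda(Y: np.ndarray, X: np.ndarray,
                       var_names: list[str] | None = None) -> OrdinationResult:
    """Greedy forward selection of RDA predictors under AIC.

    Starting from the null (intercept-only) model, the predictor whose
    addition lowers AIC the most is added; selection stops when no addition
    lowers AIC. Ties go to the earlier column. Returns the RDA of the
    selected predictors (eigenvalues empty if none selected).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    names = var_names if var_names is not None else [f"x{j}" for j in range(p)]
    selected: list[int] = []
    current_aic = _aic(Y, X[:, []])
    trail = [("null", current_aic)]
    while len(selected) < p:
        best_j, best_aic = None, current_aic
        for j in range(p):
            if j in selected:
                continue
            cand = X[:, selected + [j]]
            if np.linalg.matrix_rank(cand - cand.mean(axis=0)) < cand.shape[1]:
                continue
            a = _aic(Y, cand)
            if a < best_aic - 1e-12:
                best_j, best_aic = j, a
        if best_j is None:
            break
        selected.append(best_j)
        current_aic = best_aic
        trail.append((names[best_j], current_aic))
    if not selected:
        n, m = Y.shape
        Yc = Y - Y.mean(axis=0)
        total = float(np.sum(Yc ** 2) / (n - 1))
        res = OrdinationResult(method="RDA", eigenvalues=np.array([]),
                               total_variance=total,
                               scores=np.zeros((n, 0)), loadings=np.zeros((m, 0)),
                               selected_variables=[],
                               constrained_proportion=0.0, aic=current_aic)
        return res
    res = rda(Y, X[:, selected], var_names=[names[j] for j in selected])
    res.aic = current_aic
    res.vifs = vif(X, names) if p >= 2 else {}
    return res


def pc1_env_regression(pc1_scores: np.ndarray, env_values: np.ndarray
                       ) -> dict[str, float]:
    """OLS of PC1 scores on an environmental variable.

    Returns slope, intercept, r2 (= squared Pearson correlation) and the
    two-sided p-value of the slope.
    """
    x = np.asarray(env_values, dtype=float)
    y = np.asarray(pc1_scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("environmental variable has zero variance")
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue)}


def richness_summary(matrix: np.ndarray, taxa: list[str],
                     seasons: list[str]) -> dict[str, dict[str, int]]:
    """Taxon presence counts per season and counts unique to each season.

    Presence is any positive abundance. Returns
    ``{"present": {season: count}, "unique": {season: count}}``.
    """
    Y = np.asarray(matrix, dtype=float)
    seasons = list(seasons)
    present: dict[str, set] = {}
    for season in sorted(set(seasons)):
        idx = [i for i, s in enumerate(seasons) if s == season]
        mask = (Y[idx] > 0).any(axis=0)
        present[season] = {taxa[j] for j in np.flatnonzero(mask)}
    unique = {
        s: len(present[s] - set().union(*(present[o] for o in present if o != s)))
        if len(present) > 1 else len(present[s])
        for s in present
    }
    return {"present": {s: len(v) for s, v in present.items()}, "unique": unique}
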