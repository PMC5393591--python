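"""Gaussian-subspace dimension estimation via PCA eigenvalue stopping rules.

Six rules are computed on the covariance spectrum of a (residual) data
matrix: Kaiser-Guttman, Joliffe's modified Kaiser-Guttman, the broken-stick
model, the information dimension, Horn's parallel analysis, and the
random-lambda permutation test.  A consensus dimension averages the latter
four (the two Kaiser-Guttman variants are widely criticized and excluded
from the consensus).

All rules except parallel analysis operate on the covariance matrix
``C = Y Y^T / (p - 1)`` of the row-centered data; parallel analysis
standardizes each row first so ``C`` is the correlation matrix, and compares
against the eigenvalues of equally-sized standard-normal null matrices.
Retention is contiguous from the top eigenvalue, so every rule returns a
dimension rather than a scattered index set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "EigenSelection",
    "SubspaceDimension",
    "covariance_eigenvalues",
    "kaiser_guttman",
    "joliffe_kg",
    "broken_stick_lengths",
    "broken_stick",
    "information_dimension",
    "parallel_analysis",
    "random_lambda",
    "consensus_dimension",
    "gaussian_basis",
    "estimate_dimension",
]

#: rules entering the consensus average
CONSENSUS_RULES = (
    "broken_stick",
    "information_dimension",
    "parallel_analysis",
    "random_lambda",
)


@dataclass
class EigenSelection:
    """Eigenvalue spectrum of a residual covariance and per-rule dimensions."""

    eigenvalues: np.ndarray
    fractions: np.ndarray
    rule_dims: dict[str, float]
    consensus_dim: int
    n: int
    p: int


def _center_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least 2 samples (columns)")
    return X - X.mean(axis=1, keepdims=True)


def covariance_eigenvalues(X: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of ``C = Y Y^T / (p-1)``, ``Y`` row-centered."""
    Y = _center_rows(X)
    C = Y @ Y.T / (Y.shape[1] - 1)
    lam = np.linalg.eigvalsh(C)[::-1]
    return np.maximum(lam, 0.0)  # clip tiny negative rounding

def _contiguous_count(keep: np.ndarray) -> int:
    """Length of the initial run of True values."""
    keep = np.asarray(keep, dtype=bool)
    if keep.all():
        return keep.size
    return int(np.argmin(keep))


def kaiser_guttman(lam: np.ndarray) -> int:
    """Retain eigenvalues strictly above the mean eigenvalue."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        raise ValueError("empty spectrum")
    return int(np.sum(lam > lam.mean()))


def joliffe_kg(lam: np.ndarray) -> int:
    """Joliffe's sampling-variance correction: retain above 0.7x the mean."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        raise ValueError("empty spectrum")
    return int(np.sum(lam > 0.7 * lam.mean()))


def broken_stick_lengths(n: int) -> np.ndarray:
    """Expected ordered segment lengths when the unit interval is broken into
    ``n`` random pieces: ``l_k = (1/n) sum_{i=k}^{n} 1/i``.  Sums to 1."""
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1] / n


def broken_stick(lam: np.ndarray) -> int:
    """Retain while the eigenvalue fraction exceeds the broken-stick length,
    counting contiguously from the top."""
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0:
        raise ValueError("empty spectrum")
    total = lam.sum()
    if total <= 0:
        return 0
    f = lam / total
    return _contiguous_count(f > broken_stick_lengths(lam.size))


def information_dimension(lam: np.ndarray, N: int | None = None) -> float:
    """Entropy-based effective dimension ``n0 = N ** Htilde``.

    ``Htilde`` is the spectral entropy of the eigenvalue fractions,
    normalized by ``log2 N`` (``N`` defaults to the matrix order, i.e. the
    spectrum length).  Equal eigenvalues give ``n0 = N``; a single nonzero
    eigenvalue gives ``n0 = 1``.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.size == 0 or np.any(lam < -1e-10 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("spectrum must be nonempty and nonnegative")
    if N is None:
        N = lam.size
    if N == 1:
        return 1.0
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    pk = lam / total
    pk = pk[pk > 0]
    H = -np.sum(pk * np.log2(pk)) / np.log2(N)
    return float(N**H)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Y = _center_rows(X)
    s = Y.std(axis=1, ddof=1, keepdims=True)
    if np.any(s == 0):
        raise ValueError("cannot standardize a constant row")
    return Y / s


def parallel_analysis(
    X: np.ndarray,
    n_null: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> int:
    """Horn's parallel analysis on the correlation matrix.

    Each row of ``X`` is standardized so the covariance becomes the
    correlation matrix.  Per-rank critical values are the ``level`` quantile
    of the eigenvalues of ``n_null`` standard-normal matrices of identical
    dimensions (also on the correlation scale).  Components are retained
    from the top until the data eigenvalue drops below its critical value.
    """
    Ys = _standardize_rows(X)
    n, p = Ys.shape
    lam = np.linalg.eigvalsh(Ys @ Ys.T / (p - 1))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_null, n))
    for b in range(n_null):
        G = rng.standard_normal((n, p))
        G = _standardize_rows(G)
        null[b] = np.linalg.eigvalsh(G @ G.T / (p - 1))[::-1]
    crit = np.quantile(null, level, axis=0)
    return _contiguous_count(lam > crit)


def random_lambda(
    X: np.ndarray,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    contiguous: bool = True,
) -> int:
    """Permutation test for each eigenvalue.

    All entries of the row-centered matrix are shuffled jointly (destroying
    row/column structure) ``n_perm`` times; each rank's permutation p-value
    is ``(n + 1) / (n_perm + 1)`` where ``n`` counts permuted eigenvalues
    exceeding the observed one.  Components with ``p <= alpha`` are retained
    — contiguously from the top by default, or as a total count with
    ``contiguous=False``.  Shuffling the centered values keeps offsets
    between channel baselines (which carry no covariance information) from
    inflating the permutation null.
    """
    Y = _center_rows(X)
    lam = covariance_eigenvalues(Y)
    rng = np.random.default_rng(seed)
    flat = Y.ravel()
    exceed = np.zeros(lam.size)
    for _ in range(n_perm):
        perm = rng.permutation(flat).reshape(Y.shape)
        lam_p = covariance_eigenvalues(perm)
        exceed += lam_p > lam
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    keep = pvals <= alpha
    return _contiguous_count(keep) if contiguous else int(keep.sum())


def consensus_dimension(rule_dims: dict[str, float] | list[float]) -> int:
    """Round the mean of the non-Kaiser-Guttman rules (broken stick,
    information dimension, parallel analysis, random lambda) to the nearest
    integer."""
    if isinstance(rule_dims, dict):
        vals = [rule_dims[r] for r in CONSENSUS_RULES if r in rule_dims]
    else:
        vals = list(rule_dims)
    if not vals:
        raise ValueError("no rule values to combine")
    return int(np.rint(np.mean(vals)))


def gaussian_basis(X: np.ndarray, dim: int) -> np.ndarray:
    """Orthogonal basis sources: projections of the row-centered data onto
    the top ``dim`` covariance eigenvectors (``dim x p``, rows uncorrelated).

    If ``dim`` exceeds the numerical rank, the basis is truncated with a
    warning.
    """
    Y = _center_rows(X)
    n = Y.shape[0]
    if dim > n:
        raise ValueError("dim cannot exceed the number of rows")
    if dim == 0:
        return np.zeros((0, Y.shape[1]))
    C = Y @ Y.T / (Y.shape[1] - 1)
    lam, V = np.linalg.eigh(C)
    lam, V = lam[::-1], V[:, ::-1]
    rank = int(np.sum(lam > max(lam[0], 0.0) * 1e-10))
    if dim > rank:
        warnings.warn(
            f"requested dim {dim} exceeds numerical rank {rank}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        dim = rank
    return V[:, :dim].T @ Y


def estimate_dimension(
    X: np.ndarray,
    n_null: int = 1000,
    n_perm: int = 999,
    alpha: float = 0.05,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> EigenSelection:
    """Run all six stopping rules on a channels-by-samples matrix.

    Thin functional wrapper over :class:`SubspaceDimension`.
    """
    est = SubspaceDimension(
        n_null=n_null, n_perm=n_perm, alpha=alpha, level=level, random_state=seed
    )
    est.fit(np.asarray(X, dtype=float).T)
    return est.selection_


class SubspaceDimension(TransformerMixin, BaseEstimator):
    """Eigenvalue stopping rules as a scikit-learn transformer.

    ``fit(X)`` (samples by features) computes the covariance spectrum and
    all six rule dimensions; ``transform(X)`` projects data onto the top
    ``consensus_dim_`` eigenvectors of the training covariance.

    Attributes
    ----------
    eigenvalues_ : descending covariance spectrum.
    fractions_ : eigenvalue fractions (sum to 1).
    rule_dims_ : dict of per-rule dimensions (information dimension is real).
    consensus_dim_ : rounded mean of the four consensus rules.
    selection_ : EigenSelection with all of the above.
    """

    def __init__(
        self,
        n_null: int = 1000,
        n_perm: int = 999,
        alpha: float = 0.05,
        level: float = 0.95,
        random_state=None,
    ):
        self.n_null = n_null
        self.n_perm = n_perm
        self.alpha = alpha
        self.level = level
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        Xt = X.T
        n, p = Xt.shape
        ss = (
            self.random_state
            if isinstance(self.random_state, np.random.SeedSequence)
            else np.random.SeedSequence(self.random_state)
        )
        seed_pa, seed_rl = ss.spawn(2)
        lam = covariance_eigenvalues(Xt)
        rule_dims = {
            "kaiser_guttman": kaiser_guttman(lam),
            "joliffe_kg": joliffe_kg(lam),
            "broken_stick": broken_stick(lam),
            "information_dimension": information_dimension(lam, n),
            "parallel_analysis": parallel_analysis(
                Xt, self.n_null, self.level, np.random.default_rng(seed_pa)
            ),
            "random_lambda": random_lambda(
                Xt, self.n_perm, self.alpha, np.random.default_rng(seed_rl)
            ),
        }
        self.eigenvalues_ = lam
        self.fractions_ = lam / lam.sum() if lam.sum() > 0 else lam
        self.rule_dims_ = rule_dims
        self.consensus_dim_ = consensus_dimension(rule_dims)
        self.selection_ = EigenSelection(
            eigenvalues=lam,
            fractions=self.fractions_,
            rule_dims=rule_dims,
            consensus_dim=self.consensus_dim_,
            n=n,
            p=p,
        )
        self.mean_ = Xt.mean(axis=1)
        C = (Xt - self.mean_[:, None]) @ (Xt - self.mean_[:, None]).T / (p - 1)
        _, V = np.linalg.eigh(C)
        self.components_ = V[:, ::-1][:, : self.consensus_dim_].T
        self.n_features_in_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ self.components_.T
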