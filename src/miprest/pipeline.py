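"""The mixed ICA/PCA pipeline: reproducibility stability under decimation.

The pipeline decomposes the parent data matrix with RAICAR and again on an
ensemble of random two-fold column decimations.  For every source rank the
decimation-to-decimation change in reproducibility,

    delta_ij = R_i(S_j) - R_0(S_j),

separates three classes of components: true sparse (nongaussian) sources
keep uniformly high reproducibility and near-zero delta; Gaussian-subspace
components can be highly reproducible in any one run but fluctuate strongly
between subsamples; spurious components from overextraction have uniformly
low reproducibility.  The sparse subspace is then projected out of the
parent matrix, ``Xtilde = X - A S``, through the parent decomposition's
averaged mixing columns, and the dimension of the residual Gaussian
subspace is estimated by eigenvalue stopping rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dimension import EigenSelection, SubspaceDimension
from .raicar import RaicarResult, ReproducibleICA

__all__ = [
    "DeltaTable",
    "SourceClassification",
    "MIPReSt",
    "decimate",
    "delta_table",
    "classify_sources",
    "project_out_sparse",
    "run_miprest",
]

SPARSE = "sparse"
GAUSSIAN = "gaussian"
SPURIOUS = "spurious"


@dataclass
class DeltaTable:
    """Reproducibility table over the decimation ensemble.

    ``delta[i, j] = R_dec[i, j] - R0[j]`` holds exactly by construction;
    every entry lies in [-1, 1].
    """

    R0: np.ndarray
    R_dec: np.ndarray
    delta: np.ndarray
    n_ensembles: int
    decimation_factor: int

    def median_R(self) -> np.ndarray:
        """Per-source median decimated reproducibility."""
        return np.median(self.R_dec, axis=0)

    def median_abs_delta(self) -> np.ndarray:
        """Per-source median absolute reproducibility fluctuation."""
        return np.median(np.abs(self.delta), axis=0)


@dataclass
class SourceClassification:
    """Per-source labels in {sparse, gaussian, spurious} with the medians and
    thresholds that produced them."""

    labels: list[str]
    median_R: np.ndarray
    median_abs_delta: np.ndarray
    r_hi: float
    r_lo: float
    d_lo: float

    @property
    def n_sparse(self) -> int:
        return self.labels.count(SPARSE)

    def counts(self) -> dict[str, int]:
        return {k: self.labels.count(k) for k in (SPARSE, GAUSSIAN, SPURIOUS)}

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "counts": self.counts(),
                "median_R": self.median_R.tolist(),
                "median_abs_delta": self.median_abs_delta.tolist(),
                "thresholds": {
                    "r_hi": self.r_hi, "r_lo": self.r_lo, "d_lo": self.d_lo
                },
            },
            indent=2,
        )


def decimate(
    X: np.ndarray, factor: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Uniform random subsample of ``floor(p / factor)`` distinct columns,
    original column order preserved."""
    X = np.asarray(X)
    if factor < 2:
        raise ValueError("decimation factor must be >= 2")
    N, p = X.shape
    m = p // factor
    if m < N:
        raise ValueError(
            f"decimation by {factor} leaves {m} columns for {N} channels"
        )
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(p, size=m, replace=False))
    return X[:, cols]


def delta_table(
    parent: RaicarResult,
    decimated: list[RaicarResult],
    decimation_factor: int = 2,
    match: str = "rank",
) -> DeltaTable:
    """Assemble the delta statistic over a decimation ensemble.

    ``match='rank'`` (default) pairs sources across runs by their descending
    reproducibility rank, the convention under which the delta formula is
    written.  ``match='mixing'`` instead matches each decimated run's groups
    to the parent's by Hungarian assignment on the absolute correlation of
    averaged mixing columns (the sources themselves have different sample
    counts across decimations).
    """
    if match not in ("rank", "mixing"):
        raise ValueError("match must be 'rank' or 'mixing'")
    N_s = parent.n_components
    R0 = np.asarray(parent.R, dtype=float)
    rows = []
    for res in decimated:
        if res.n_components != N_s:
            raise ValueError("all runs must extract the same number of sources")
        R = np.asarray(res.R, dtype=float)
        if match == "mixing":
            R = R[_mixing_assignment(parent.A_avg, res.A_avg)]
        rows.append(R)
    R_dec = np.vstack(rows) if rows else np.zeros((0, N_s))
    return DeltaTable(
        R0=R0,
        R_dec=R_dec,
        delta=R_dec - R0[None, :],
        n_ensembles=len(decimated),
        decimation_factor=decimation_factor,
    )


def _mixing_assignment(A_parent: np.ndarray, A_dec: np.ndarray) -> np.ndarray:
    """Order the decimated run's sources against the parent's by maximal
    absolute correlation of mixing columns (Hungarian assignment)."""

    def _unit(A):
        A = A - A.mean(axis=0, keepdims=True)
        nrm = np.linalg.norm(A, axis=0, keepdims=True)
        nrm[nrm == 0] = 1.0
        return A / nrm

    C = np.abs(_unit(A_parent).T @ _unit(A_dec))
    row, col = linear_sum_assignment(1.0 - C)
    order = np.empty(len(row), dtype=int)
    order[row] = col
    return order


def classify_sources(
    dt: DeltaTable,
    r_hi: float = 0.9,
    r_lo: float = 0.3,
    d_lo: float = 0.1,
) -> SourceClassification:
    """Three-way classification from ensemble medians.

    A source is *sparse* if its median decimated reproducibility is at least
    ``r_hi`` and its median |delta| at most ``d_lo``; *spurious* if the
    median reproducibility is at most ``r_lo`` with median |delta| at most
    ``d_lo``; otherwise it belongs to the *gaussian* subspace.
    """
    if not r_lo < r_hi:
        raise ValueError("thresholds must satisfy r_lo < r_hi")
    med_R = dt.median_R()
    med_d = dt.median_abs_delta()
    labels = []
    for R, d in zip(med_R, med_d):
        if R >= r_hi and d <= d_lo:
            labels.append(SPARSE)
        elif R <= r_lo and d <= d_lo:
            labels.append(SPURIOUS)
        else:
            labels.append(GAUSSIAN)
    return SourceClassification(
        labels=labels,
        median_R=med_R,
        median_abs_delta=med_d,
        r_hi=r_hi,
        r_lo=r_lo,
        d_lo=d_lo,
    )


def project_out_sparse(
    X: np.ndarray, parent: RaicarResult, sparse_idx
) -> np.ndarray:
    """Remove the sparse subspace: ``Xtilde = X - A S`` with the mixing
    columns of the *parent* decomposition restricted to ``sparse_idx``.

    The source coefficients are refit by least squares through the retained
    mixing columns (``S = A^+ (X - M)`` with ``M`` the row means), which
    makes the removal a proper projection: applied to the parent matrix it
    coincides with subtracting the averaged sources (those are themselves
    least-squares consistent with ``A`` up to group-averaging error), data
    built exactly as ``A S`` cancels to zero, and the operation is
    idempotent.  An empty index set returns ``X`` unchanged.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty data matrix")
    sparse_idx = np.asarray(list(sparse_idx), dtype=int)
    if sparse_idx.size == 0:
        return X.copy()
    if sparse_idx.max() >= parent.n_components or sparse_idx.min() < 0:
        raise ValueError("sparse_idx out of range of parent groups")
    A = parent.A_avg[:, sparse_idx]
    M = X.mean(axis=1, keepdims=True)
    S = np.linalg.pinv(A) @ (X - M)
    return X - A @ S


class MIPReSt(TransformerMixin, BaseEstimator):
    """Mixed ICA/PCA via reproducibility stability, as a sklearn estimator.

    ``fit(X)`` (samples by features) runs the full pipeline: parent RAICAR,
    the decimation ensemble, delta statistics, three-way source
    classification, sparse-subspace projection, and the stopping rules on
    the residual.  ``transform(X)`` removes the fitted sparse subspace from
    new data.

    Parameters
    ----------
    n_components : int, optional
        Sources extracted per ICA run (default: number of features).
    n_runs : int, default 30
        FastICA realizations per RAICAR decomposition (``K``).
    n_ensembles : int, default 30
        Number of random decimated copies.
    decimation_factor : int, default 2
        Column decimation order (two-fold by default).
    r_hi, r_lo, d_lo : classification thresholds on ensemble medians.
    match : 'rank' or 'mixing'
        How sources are paired between parent and decimated runs.
    n_null, n_perm, alpha, level : stopping-rule parameters.
    tol, max_iter : FastICA convergence parameters.
    random_state : int or None.

    Attributes
    ----------
    parent_ : RaicarResult for the parent matrix.
    delta_table_ : DeltaTable over the ensemble.
    classification_ : SourceClassification.
    labels_ : ndarray of per-source labels.
    n_sparse_ : number of sparse sources (``N'``).
    sparse_idx_ : indices of the sparse groups in the parent decomposition.
    residual_ : (n_samples, n_features) sparse-removed training data.
    selection_ : EigenSelection of the residual.
    rule_dims_, consensus_dim_ : stopping-rule output.
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_runs: int = 30,
        n_ensembles: int = 30,
        decimation_factor: int = 2,
        r_hi: float = 0.9,
        r_lo: float = 0.3,
        d_lo: float = 0.1,
        match: str = "rank",
        n_null: int = 1000,
        n_perm: int = 999,
        alpha: float = 0.05,
        level: float = 0.95,
        tol: float = 1e-5,
        max_iter: int = 500,
        resample: bool | str = "auto",
        random_state=None,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.n_ensembles = n_ensembles
        self.decimation_factor = decimation_factor
        self.r_hi = r_hi
        self.r_lo = r_lo
        self.d_lo = d_lo
        self.match = match
        self.n_null = n_null
        self.n_perm = n_perm
        self.alpha = alpha
        self.level = level
        self.tol = tol
        self.max_iter = max_iter
        self.resample = resample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        Xt = X.T
        if self.n_ensembles < 1:
            raise ValueError("n_ensembles must be >= 1")
        ss = np.random.SeedSequence(self.random_state)
        seed_parent, *seed_dec = ss.spawn(1 + self.n_ensembles)
        seed_rules = ss.spawn(1)[0]

        raicar_kw = dict(
            n_components=self.n_components,
            n_runs=self.n_runs,
            tol=self.tol,
            max_iter=self.max_iter,
            resample=self.resample,
        )
        parent_est = ReproducibleICA(random_state=seed_parent, **raicar_kw)
        parent_est.fit(X)
        parent = parent_est.result_

        decimated = []
        for sd in seed_dec:
            child_cols, child_ica = sd.spawn(2)
            Xd = decimate(
                Xt, self.decimation_factor, np.random.default_rng(child_cols)
            )
            est = ReproducibleICA(random_state=child_ica, **raicar_kw)
            est.fit(Xd.T)
            decimated.append(est.result_)

        dt = delta_table(
            parent, decimated, self.decimation_factor, match=self.match
        )
        cls = classify_sources(dt, self.r_hi, self.r_lo, self.d_lo)
        sparse_idx = np.flatnonzero(np.asarray(cls.labels) == SPARSE)
        residual = project_out_sparse(Xt, parent, sparse_idx)

        dim_est = SubspaceDimension(
            n_null=self.n_null,
            n_perm=self.n_perm,
            alpha=self.alpha,
            level=self.level,
            random_state=seed_rules,
        )
        dim_est.fit(residual.T)

        self.parent_ = parent
        self.delta_table_ = dt
        self.classification_ = cls
        self.labels_ = np.asarray(cls.labels)
        self.n_sparse_ = cls.n_sparse
        self.sparse_idx_ = sparse_idx
        self.residual_ = residual.T
        self.selection_ = dim_est.selection_
        self.rule_dims_ = dim_est.rule_dims_
        self.consensus_dim_ = dim_est.consensus_dim_
        self.mean_ = Xt.mean(axis=1)
        self.n_features_in_ = Xt.shape[0]
        return self

    def transform(self, X):
        """Project the fitted sparse subspace out of new data (oblique
        projection through the averaged mixing columns)."""
        check_is_fitted(self, "parent_")
        X = check_array(X, dtype=float)
        if self.sparse_idx_.size == 0:
            return X.copy()
        A = self.parent_.A_avg[:, self.sparse_idx_]
        S_est = np.linalg.pinv(A) @ (X.T - self.mean_[:, None])
        return X - (A @ S_est).T


def run_miprest(
    X: np.ndarray,
    n_ensembles: int = 30,
    factor: int = 2,
    K: int = 30,
    seed: int | None = None,
    **kwargs,
) -> tuple[DeltaTable, SourceClassification, np.ndarray, EigenSelection]:
    """End-to-end pipeline on a channels-by-samples matrix.

    Thin functional wrapper over :class:`MIPReSt`; returns the delta table,
    the classification, the sparse-removed residual (channels x samples),
    and the stopping-rule selection.
    """
    est = MIPReSt(
        n_runs=K,
        n_ensembles=n_ensembles,
        decimation_factor=factor,
        random_state=seed,
        **kwargs,
    )
    est.fit(np.asarray(X, dtype=float).T)
    return est.delta_table_, est.classification_, est.residual_.T, est.selection_
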