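"""RAICAR: ranking and averaging independent components by reproducibility.

The data matrix is decomposed ``K`` times by FastICA from independent random
starts.  Components are aligned across realizations by greedy matching on
absolute cross-correlation, producing up to ``N_s`` groups of at most one
member per realization.  Each group's reproducibility ``R`` is the mean
absolute correlation over all member pairs (the unthresholded variant);
groups are ranked by descending ``R`` and averaged — after sign alignment —
into consensus sources and mixing columns.  Missing components (slots the
ICA dropped) leave groups short or empty; empty and singleton groups have
``R = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .ica import ICARealization, fastica_realization

__all__ = [
    "RaicarResult",
    "ReproducibleICA",
    "cross_correlation_matrices",
    "align_components",
    "reproducibility",
    "raicar_decompose",
]


@dataclass
class RaicarResult:
    """Aligned component groups and their reproducibilities.

    ``R`` is sorted descending and always has length ``N_s``; groups whose
    members were never extracted are empty with ``R = 0`` (their rows in
    ``S_avg`` / columns in ``A_avg`` are zero).  Each group is a list of
    ``(realization_index, component_index, sign)`` triples with at most one
    member per realization.
    """

    R: np.ndarray
    groups: list[list[tuple[int, int, float]]]
    S_avg: np.ndarray
    A_avg: np.ndarray
    K: int

    @property
    def n_components(self) -> int:
        return len(self.R)

    def save(self, outdir: str | Path, delimiter: str = "\t") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "reproducibility.tsv", self.R, delimiter=delimiter)
        np.savetxt(outdir / "sources_avg.tsv", self.S_avg, delimiter=delimiter)
        np.savetxt(outdir / "mixing_avg.tsv", self.A_avg, delimiter=delimiter)
        groups = [
            [{"realization": int(k), "component": int(c), "sign": float(s)}
             for k, c, s in grp]
            for grp in self.groups
        ]
        (outdir / "groups.json").write_text(
            json.dumps({"K": self.K, "groups": groups}, indent=2)
        )


def _signed_cross_correlations(
    realizations: list[ICARealization],
) -> dict[tuple[int, int], np.ndarray]:
    """Signed Pearson correlation matrices for every unordered realization pair."""
    K = len(realizations)
    if K < 2:
        raise ValueError("need at least 2 realizations")
    p = None
    for r in realizations:
        if not r.is_empty:
            p = r.S_hat.shape[1]
            break
    if p is None:
        return {(i, j): np.zeros((0, 0)) for i in range(K) for j in range(i + 1, K)}
    centered = []
    for r in realizations:
        if r.is_empty:
            centered.append(np.zeros((0, p)))
            continue
        if r.S_hat.shape[1] != p:
            raise ValueError("realizations have mismatched sample counts")
        S = r.S_hat - r.S_hat.mean(axis=1, keepdims=True)
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        centered.append(S)
    out = {}
    for i in range(K):
        for j in range(i + 1, K):
            out[(i, j)] = centered[i] @ centered[j].T
    return out


def cross_correlation_matrices(
    realizations: list[ICARealization],
) -> dict[tuple[int, int], np.ndarray]:
    """Absolute source-source correlation matrices, one per realization pair
    (``K(K-1)/2`` matrices)."""
    return {k: np.abs(v) for k, v in _signed_cross_correlations(realizations).items()}


def _pair_value(crcm, i, ci, j, cj) -> float:
    """Correlation between component ``ci`` of realization ``i`` and ``cj`` of
    ``j`` (signed if the matrices are signed)."""
    if i < j:
        return crcm[(i, j)][ci, cj]
    return crcm[(j, i)][cj, ci]


def align_components(
    crcm: dict[tuple[int, int], np.ndarray],
    K: int,
    N_s: int,
) -> list[list[tuple[int, int, float]]]:
    """Greedy global alignment of components across realizations.

    Repeatedly seeds a group with the largest remaining absolute correlation
    over all pair matrices, extends the group with the best-matching unused
    component from every other realization (largest mean |corr| to the seed
    pair), and marks members used.  Yields at most ``N_s`` groups, each with
    at most one member per realization, sorted by the reproducibility of the
    eventual grouping later.  Members carry the sign aligning them positively
    with the group's seed member.
    """
    n_comp = np.zeros(K, dtype=int)
    for (i, j), M in crcm.items():
        n_comp[i] = max(n_comp[i], M.shape[0])
        n_comp[j] = max(n_comp[j], M.shape[1])
    used = [np.zeros(n, dtype=bool) for n in n_comp]
    groups: list[list[tuple[int, int, float]]] = []

    def best_remaining():
        best, where = -1.0, None
        for (i, j), M in crcm.items():
            if M.size == 0:
                continue
            A = np.abs(M).copy()
            A[used[i], :] = -1.0
            A[:, used[j]] = -1.0
            idx = np.unravel_index(np.argmax(A), A.shape)
            if A[idx] > best:
                best, where = A[idx], (i, idx[0], j, idx[1])
        return best, where

    while True:
        best, where = best_remaining()
        if where is None or best < 0:
            break
        i, ci, j, cj = where
        sign_j = float(np.sign(_pair_value(crcm, i, ci, j, cj)) or 1.0)
        group = [(i, ci, 1.0), (j, cj, sign_j)]
        used[i][ci] = True
        used[j][cj] = True
        for m in range(K):
            if m == i or m == j:
                continue
            free = ~used[m]
            if not free.any():
                continue
            score = np.full(n_comp[m], -1.0)
            for c in np.flatnonzero(free):
                v1 = _pair_value(crcm, i, ci, m, c)
                v2 = _pair_value(crcm, j, cj, m, c)
                score[c] = (abs(v1) + abs(v2)) / 2.0
            c = int(np.argmax(score))
            sign_m = float(np.sign(_pair_value(crcm, i, ci, m, c)) or 1.0)
            group.append((m, c, sign_m))
            used[m][c] = True
        groups.append(group)

    # leftover never-matched components become singleton groups (R = 0)
    for m in range(K):
        for c in np.flatnonzero(~used[m]):
            groups.append([(m, int(c), 1.0)])
    return groups


def reproducibility(
    group: list[tuple[int, int, float]],
    crcm: dict[tuple[int, int], np.ndarray],
) -> float:
    """Mean absolute correlation over all member pairs of a group
    (unthresholded average); singleton or empty groups score 0."""
    if len(group) < 2:
        return 0.0
    vals = []
    for a in range(len(group)):
        for b in range(a + 1, len(group)):
            i, ci, _ = group[a]
            j, cj, _ = group[b]
            vals.append(abs(_pair_value(crcm, i, ci, j, cj)))
    return float(np.mean(vals))


def raicar_decompose(
    X: np.ndarray,
    n_components: int | None = None,
    n_runs: int = 30,
    seed: int | np.random.SeedSequence | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    resample: bool | str = "auto",
) -> RaicarResult:
    """Run a ``K``-fold FastICA on ``X`` (channels x samples), align, rank.

    Thin functional wrapper over :class:`ReproducibleICA` in the domain
    (channels-by-samples) orientation.
    """
    est = ReproducibleICA(
        n_components=n_components,
        n_runs=n_runs,
        tol=tol,
        max_iter=max_iter,
        resample=resample,
        random_state=seed,
    )
    est.fit(np.asarray(X, dtype=float).T)
    return est.result_


class ReproducibleICA(TransformerMixin, BaseEstimator):
    """RAICAR decomposition as a scikit-learn transformer.

    Parameters
    ----------
    n_components : int, optional
        Number of sources ``N_s`` extracted in each realization; defaults to
        the number of features (extract as many as possible).
    n_runs : int, default 30
        Number ``K`` of FastICA realizations.
    tol, max_iter : FastICA one-unit convergence parameters.
    resample : bool or 'auto', default 'auto'
        Bootstrap-resample the data within each realization so that
        reproducibility reflects sampling stability, not merely the random
        starts; 'auto' enables the bootstrap for sample counts >= 1000.
    random_state : int, SeedSequence, or None
        Seeds all realizations (each gets an independent child stream).

    Attributes
    ----------
    reproducibility_ : ndarray of shape (n_components,)
        Group reproducibilities, sorted descending in [0, 1].
    sources_ : ndarray of shape (n_samples, n_components)
        Sign-aligned, averaged, re-standardized consensus sources for the
        training data.
    mixing_ : ndarray of shape (n_features, n_components)
        Averaged mixing columns.
    mean_ : ndarray of shape (n_features,)
        Per-feature training mean.
    result_ : RaicarResult
        Full result in channels-by-samples orientation.
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_runs: int = 30,
        tol: float = 1e-5,
        max_iter: int = 500,
        resample: bool | str = "auto",
        random_state=None,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.tol = tol
        self.max_iter = max_iter
        self.resample = resample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        Xt = X.T  # channels x samples internally
        N, p = Xt.shape
        n_comp = self.n_components if self.n_components is not None else N
        if n_comp > N:
            raise ValueError("n_components cannot exceed the number of features")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        ss = (
            self.random_state
            if isinstance(self.random_state, np.random.SeedSequence)
            else np.random.SeedSequence(self.random_state)
        )
        realizations = [
            fastica_realization(
                Xt, n_comp, np.random.default_rng(child),
                tol=self.tol, max_iter=self.max_iter, resample=self.resample,
            )
            for child in ss.spawn(self.n_runs)
        ]
        crcm = _signed_cross_correlations(realizations)
        groups = align_components(crcm, self.n_runs, n_comp)
        R = np.array([reproducibility(g, crcm) for g in groups])
        order = np.argsort(-R, kind="stable")[:n_comp]
        groups = [groups[i] for i in order]
        R = R[order]
        # pad to exactly n_comp groups
        while len(groups) < n_comp:
            groups.append([])
            R = np.append(R, 0.0)

        S_avg = np.zeros((n_comp, p))
        A_avg = np.zeros((N, n_comp))
        for gi, grp in enumerate(groups):
            if not grp:
                continue
            s_sum = np.zeros(p)
            a_sum = np.zeros(N)
            for k, c, sign in grp:
                s_sum += sign * realizations[k].S_hat[c]
                a_sum += sign * realizations[k].A_hat[:, c]
            s = s_sum / len(grp)
            sd = s.std(ddof=1)
            if sd > 0:
                s = (s - s.mean()) / sd
            S_avg[gi] = s
            A_avg[:, gi] = a_sum / len(grp)

        self.result_ = RaicarResult(
            R=R, groups=groups, S_avg=S_avg, A_avg=A_avg, K=self.n_runs
        )
        self.realizations_ = realizations
        self.reproducibility_ = R
        self.sources_ = S_avg.T
        self.mixing_ = A_avg
        self.mean_ = Xt.mean(axis=1)
        self.n_features_in_ = N
        return self

    def transform(self, X):
        """Estimate consensus sources for new data via the pseudo-inverse of
        the averaged mixing matrix."""
        check_is_fitted(self, "mixing_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ np.linalg.pinv(self.mixing_).T
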