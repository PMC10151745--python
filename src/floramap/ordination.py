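"""Bray-Curtis distances, principal coordinates, and distance-based RDA.

Community composition (variance-stabilised OTU abundances) is summarised as a
Bray-Curtis distance matrix, embedded by Gower double-centring (PCoA), and the
resulting coordinates are regressed on climate covariates; the constrained
(fitted) inertia is tested against permutations of the covariate rows with the
add-one p-value convention, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
Negative PCoA eigenvalues (Bray-Curtis is semimetric) are reported but their
axes are dropped, so constrained + residual inertia equals the total inertia
carried by the real axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PCoAResult",
    "OrdinationResult",
    "bray_curtis",
    "nonneg_shift",
    "pcoa",
    "dbrda",
    "realm_centroids",
]


def nonneg_shift(matrix):
    """Shift a matrix by its global minimum when any entry is negative.

    Variance-stabilised abundances can dip below zero at low counts while
    Bray-Curtis requires non-negative input; shifting preserves ranking
    within and between samples.
    """
    df = pd.DataFrame(matrix)
    mn = float(df.min().min())
    return df - mn if mn < 0 else df


def bray_curtis(matrix) -> pd.DataFrame:
    """Site x site Bray-Curtis distances, d = sum|x-y| / sum(x+y), in [0, 1]."""
    df = pd.DataFrame(matrix)
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values (see nonneg_shift)")
    if (arr.sum(axis=1) == 0).any():
        bad = df.index[arr.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero rows have undefined Bray-Curtis distance: {bad}")
    D = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(D, index=df.index, columns=df.index)


@dataclass
class PCoAResult:
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be negative)
    coordinates: pd.DataFrame        # site x positive axis, scaled by sqrt(eigenvalue)
    total_inertia: float             # sum of positive eigenvalues
    trace: float                     # trace of the Gower-centred matrix

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(distances) -> PCoAResult:
    """Principal coordinates via Gower double-centring of -D^2/2."""
    df = pd.DataFrame(distances)
    D = df.to_numpy(dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    tol = max(np.abs(vals).max(), 1.0) * 1e-12
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])[None, :]
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        eigenvalues=vals,
        coordinates=pd.DataFrame(coords, index=df.index, columns=axes),
        total_inertia=float(vals[pos].sum()),
        trace=float(np.trace(G)),
    )


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray                 # constrained axes then residual axes
    constrained_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    constrained_inertia: float
    residual_inertia: float
    total_inertia: float
    site_scores: pd.DataFrame               # linear-combination scores on constrained axes
    covariate_scores: pd.DataFrame          # covariate correlations with those axes
    pseudo_f: float
    permutation_p: float | None
    n_perm: int
    dropped_covariates: list[str] = field(default_factory=list)


def _fitted_ss(X: np.ndarray, Y: np.ndarray) -> float:
    """Sum of squares of the least-squares projection of Y onto col(X)."""
    Q, _ = np.linalg.qr(X)
    H = Q @ (Q.T @ Y)
    return float((H ** 2).sum())


def dbrda(distances, covariates: pd.DataFrame, n_perm: int = 999, seed: int = 0
          ) -> OrdinationResult:
    """Distance-based redundancy analysis with a permutation test.

    PCoA site coordinates are regressed jointly on the (centred) covariates;
    the constrained inertia is the fitted sum of squares.  Collinear
    covariates are dropped by pivoted QR with a warning.  The permutation
    test permutes covariate rows over sites.
    """
    pc = pcoa(distances)
    Y = pc.coordinates.to_numpy()
    n = Y.shape[0]
    cov = pd.DataFrame(covariates).loc[pc.coordinates.index]
    if cov.isna().any().any():
        raise ValueError("covariates must be complete")
    names = list(cov.columns)
    X = cov.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)

    dropped: list[str] = []
    if X.shape[1] > 0:
        from scipy.linalg import qr as _qr

        _, Rq, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rq))
        tol = (diag.max() if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum()) if diag.size else 0
        keep = sorted(piv[:rank])
        dropped = [names[i] for i in piv[rank:]]
        if dropped:
            warnings.warn(f"dropping collinear covariates: {dropped}")
        X = X[:, keep]
        names = [names[i] for i in keep]
    q = X.shape[1]

    if q == 0:
        resid_vals = pc.eigenvalues[pc.eigenvalues > 0]
        return OrdinationResult(
            eigenvalues=pc.eigenvalues.copy(),
            constrained_eigenvalues=np.empty(0),
            residual_eigenvalues=resid_vals,
            constrained_inertia=0.0, residual_inertia=pc.total_inertia,
            total_inertia=pc.total_inertia,
            site_scores=pd.DataFrame(index=pc.coordinates.index),
            covariate_scores=pd.DataFrame(),
            pseudo_f=np.nan, permutation_p=None, n_perm=0,
            dropped_covariates=dropped)

    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    Q, _ = np.linalg.qr(X)
    fitted = Q @ (Q.T @ Y)
    resid = Y - fitted
    constrained = float((fitted ** 2).sum())
    residual = float((resid ** 2).sum())
    df_resid = n - 1 - q
    pseudo_f = (constrained / q) / (residual / df_resid) if df_resid > 0 else np.inf

    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    tol = max(S.max(), 1.0) * 1e-10 if S.size else 0.0
    keep_ax = S > tol
    cap_vals = (S[keep_ax] ** 2)
    cap_axes = [f"CAP{i + 1}" for i in range(int(keep_ax.sum()))]
    site_scores = pd.DataFrame(U[:, keep_ax] * S[keep_ax][None, :],
                               index=pc.coordinates.index, columns=cap_axes)
    cov_scores = pd.DataFrame(
        {ax: [float(np.corrcoef(X[:, j], site_scores[ax])[0, 1]) if site_scores[ax].std() > 0
              else 0.0 for j in range(q)] for ax in cap_axes},
        index=names)

    resid_resid = pcoa_eigvals_of_scores(resid)
    eigenvalues = np.concatenate([cap_vals, resid_resid])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss = _fitted_ss(X[perm], Y)
        f_perm = (ss / q) / ((pc.total_inertia - ss) / df_resid) if df_resid > 0 else np.inf
        if f_perm >= pseudo_f:
            count += 1
    p = (1 + count) / (1 + n_perm)

    return OrdinationResult(
        eigenvalues=eigenvalues,
        constrained_eigenvalues=cap_vals,
        residual_eigenvalues=resid_resid,
        constrained_inertia=constrained, residual_inertia=residual,
        total_inertia=pc.total_inertia,
        site_scores=site_scores, covariate_scores=cov_scores,
        pseudo_f=float(pseudo_f), permutation_p=float(p), n_perm=int(n_perm),
        dropped_covariates=dropped)


def pcoa_eigvals_of_scores(Y: np.ndarray) -> np.ndarray:
    """Descending positive eigenvalues of Y Y^T (axis inertias of a score matrix)."""
    s = np.linalg.svd(Y, compute_uv=False)
    vals = s ** 2
    vals = vals[vals > max(vals.max(), 1.0) * 1e-12] if vals.size else vals
    return np.sort(vals)[::-1]


def realm_centroids(site_scores: pd.DataFrame, realm_labels: pd.Series,
                    min_ellipse: int = 3) -> pd.DataFrame:
    """Per-realm centroid and 1-SD ellipse in the first two ordination axes."""
    if site_scores.shape[1] < 2:
        raise ValueError("need at least two ordination axes")
    axes = site_scores.columns[:2]
    labels = pd.Series(realm_labels).reindex(site_scores.index)
    rows = []
    for realm, idx in labels.groupby(labels).groups.items():
        pts = site_scores.loc[idx, axes].to_numpy()
        row = {"realm": realm, "n": len(pts),
               "centroid_1": float(pts[:, 0].mean()), "centroid_2": float(pts[:, 1].mean()),
               "sd_major": np.nan, "sd_minor": np.nan, "angle_deg": np.nan,
               "ellipse": len(pts) >= min_ellipse}
        if len(pts) >= min_ellipse:
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            order = np.argsort(vals)[::-1]
            vals = np.clip(vals[order], 0.0, None)
            row["sd_major"] = float(np.sqrt(vals[0]))
            row["sd_minor"] = float(np.sqrt(vals[1]))
            v = vecs[:, order][:, 0]
            row["angle_deg"] = float(np.degrees(np.arctan2(v[1], v[0])))
        rows.append(row)
    return pd.DataFrame(rows).set_index("realm")
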