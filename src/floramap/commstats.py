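"""Community-matrix normalisation and a parametric variance-stabilising transform.

Sequencing depth varies by orders of magnitude between soil samples, so raw
OTU counts are normalised by median-of-ratios size factors and transformed so
that the variance of an OTU no longer tracks its mean.  The dispersion-mean
trend is the standard negative-binomial parametric form

    alpha(mu) = a0 + a1 / mu,

fitted by method-of-moments per OTU followed by a robust (bisquare-weighted)
regression across OTUs.  Under that trend the NB variance is
v(mu) = (1 + a1) mu + a0 mu^2, and the variance-stabilising transform is the
closed-form antiderivative of 1/sqrt(v):

    vst(x) = log( (2 a0 x + b + 2 sqrt(a0 x (a0 x + b))) / b ) / sqrt(a0),

with b = 1 + a1, which is zero at x = 0, strictly increasing, and tends to
2 sqrt(x / b) in the Poisson limit a0 -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DispersionTrend",
    "size_factors",
    "fit_dispersion_trend",
    "vst",
    "richness_metrics",
]


@dataclass(frozen=True)
class DispersionTrend:
    a0: float   # asymptotic dispersion at large mean
    a1: float   # mean-dependent dispersion coefficient

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be > 0")
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0")

    def alpha(self, mu):
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


def _as_matrix(counts) -> tuple[np.ndarray, list, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (one per sample), geometric mean 1.

    The reference is the per-OTU geometric mean over samples; each sample's
    factor is the median ratio of its counts to the reference, over OTUs
    positive in every sample.  When no OTU is positive everywhere, the
    geometric mean and median fall back to each OTU's/sample's positive
    entries.  Factors are rescaled to geometric mean 1.
    """
    mat, _, samples = _as_matrix(counts)
    if mat.size == 0 or mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_pos = np.isfinite(logs).all(axis=1)
    if all_pos.any():
        ref = logs[all_pos].mean(axis=1)
        ratios = logs[all_pos] - ref[:, None]
        raw = np.exp(np.median(ratios, axis=0))
    else:  # positive-subset fallback
        pos_counts = np.where(np.isfinite(logs), logs, np.nan)
        ref = np.nanmean(pos_counts, axis=1)
        ratios = pos_counts - ref[:, None]
        if np.all(np.isnan(ratios), axis=0).any():
            raise ValueError("could not compute positive size factors (empty sample)")
        raw = np.exp(np.nanmedian(ratios, axis=0))
    if not np.all(np.isfinite(raw)) or (raw <= 0).any():
        raise ValueError("could not compute positive size factors (too many zeros)")
    raw /= np.exp(np.mean(np.log(raw)))
    return pd.Series(raw, index=samples, name="size_factor")


def fit_dispersion_trend(counts, factors: pd.Series | np.ndarray,
                         min_otus: int = 10, n_iter: int = 20) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu across OTUs by robust regression.

    Per-OTU dispersions come from method of moments on normalised counts,
    alpha_hat = (s^2 - mu_bar) / mu_bar^2; OTUs with non-positive alpha_hat do
    not constrain the trend and are excluded from the fit.  The regression on
    [1, 1/mu] uses Tukey-bisquare reweighting against absolute residuals to
    resist the heavy upper tail of moment estimates.
    """
    mat, _, samples = _as_matrix(counts)
    f = np.asarray(factors, dtype=float)
    norm = mat / f[None, :]
    mu = norm.mean(axis=1)
    usable = mu > 0
    if usable.sum() < min_otus:
        raise ValueError(f"need >= {min_otus} OTUs with positive mean, got {int(usable.sum())}")
    var = norm.var(axis=1, ddof=1)
    if np.all(var[usable] == 0):
        raise ValueError("all usable OTUs have zero variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (var - mu) / mu ** 2
    fit_mask = usable & (alpha_hat > 0) & np.isfinite(alpha_hat)
    if fit_mask.sum() < 2:
        # effectively Poisson everywhere
        return DispersionTrend(a0=1e-8, a1=0.0)
    x = 1.0 / mu[fit_mask]
    y = alpha_hat[fit_mask]
    X = np.column_stack([np.ones_like(x), x])
    w = np.ones_like(y)
    beta = np.zeros(2)
    for _ in range(n_iter):
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)
        res = y - X @ beta
        scale = np.median(np.abs(res)) / 0.6745
        if scale <= 0:
            break
        u = res / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() < 2:
            w = np.ones_like(y)
            break
    a0 = max(float(beta[0]), 1e-8)
    a1 = max(float(beta[1]), 0.0)
    return DispersionTrend(a0=a0, a1=a1)


def vst(counts, factors, trend: DispersionTrend):
    """Closed-form variance-stabilising transform of normalised counts."""
    mat, otus, samples = _as_matrix(counts)
    f = np.asarray(factors, dtype=float)
    q = mat / f[None, :]
    a, b = trend.a0, 1.0 + trend.a1
    inner = 2.0 * a * q + b + 2.0 * np.sqrt(a * q * (a * q + b))
    out = np.log(inner / b) / np.sqrt(a)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=otus, columns=samples)
    return out


def richness_metrics(otu_table, assignments=None, cleaned_read_counts=None,
                     trend: DispersionTrend | None = None) -> pd.DataFrame:
    """Per-site eDNA richness metric variants.

    Columns: ``eDNA_reads`` (cleaned reads per site; OTU-table column sums
    unless `cleaned_read_counts` overrides them with pre-clustering totals),
    ``eDNA_c97`` (non-singleton OTUs detected per site), ``eDNA_VST`` (sum of
    variance-stabilised values per site), and ``eDNA_family``/``eDNA_species``
    (distinct families/species assigned among the site's OTUs).
    """
    counts = otu_table.counts if hasattr(otu_table, "counts") else otu_table
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("otu_table must be an OTUTable or a DataFrame")
    samples = list(counts.columns)
    out = pd.DataFrame(index=samples)
    out.index.name = "site"
    if cleaned_read_counts is not None:
        out["eDNA_reads"] = pd.Series(cleaned_read_counts).reindex(samples)
    else:
        out["eDNA_reads"] = counts.sum(axis=0)
    out["eDNA_c97"] = (counts > 0).sum(axis=0)

    if counts.to_numpy().sum() > 0:
        try:
            factors = size_factors(counts)
        except ValueError:
            # e.g. an entirely empty site: fall back to unit depth
            factors = pd.Series(1.0, index=samples)
        if trend is None:
            try:
                trend = fit_dispersion_trend(counts, factors)
            except ValueError:
                trend = DispersionTrend(a0=1e-8, a1=0.0)
        out["eDNA_VST"] = vst(counts, factors, trend).sum(axis=0)
    else:
        out["eDNA_VST"] = 0.0

    fam_by_otu: dict[str, str] = {}
    sp_by_otu: dict[str, str] = {}
    if assignments is not None:
        for a in assignments:
            if a.family:
                fam_by_otu[a.otu_id] = a.family
            if a.resolved_rank == "species":
                sp_by_otu[a.otu_id] = a.species
    fams, sps = [], []
    for sample in samples:
        present = counts.index[counts[sample] > 0]
        fams.append(len({fam_by_otu[o] for o in present if o in fam_by_otu}))
        sps.append(len({sp_by_otu[o] for o in present if o in sp_by_otu}))
    out["eDNA_family"] = fams
    out["eDNA_species"] = sps
    return out
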