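"""Two-group negative-binomial Wald test with trended, shrunken dispersions.

The model for gene g and sample j is

    x_gj ~ NB(mean = s_j * mu_{k(j)}, dispersion = alpha_g),

with Var = mu + alpha * mu^2, sample size factor s_j and a mean per group
k.  Dispersions are estimated in the empirical-Bayes style popularized by
DESeq2: a per-gene Cox-Reid-adjusted maximum-likelihood estimate, a
mean-dispersion trend alpha_tr(mu) = a0 + a1/mu fitted across genes, and a
per-gene maximum a posteriori estimate under a log-normal prior centred on
the trend.  The two-group design admits closed-form group means
(sum of counts over sum of size factors), so no IRLS is needed; the
log2 fold change standard error comes from the NB GLM Fisher information.

Fitting is exposed both functionally (:func:`estimate_dispersions`,
:func:`nb_wald_two_group`) and as a model object (:class:`NBWaldDE`)
whose :meth:`~NBWaldDE.fit` returns :class:`NBWaldDEResults` with a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln
from scipy.stats import norm

from .countdata import CountMatrix
from .normalization import (
    NormalizedMatrix,
    median_of_ratios_factors,
    uq_pgq2_normalize,
)

__all__ = [
    "DispersionModel",
    "DEGCall",
    "estimate_dispersions",
    "nb_wald_two_group",
    "bh_adjust",
    "call_degs",
    "NBWaldDE",
    "NBWaldDEResults",
    "run_de_route",
]

ALPHA_FLOOR = 1e-8
ALPHA_CEIL = 30.0
SIGMA_PRIOR_FLOOR = 0.25
LN2 = np.log(2.0)

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
_INVPHI2 = (3.0 - np.sqrt(5.0)) / 2.0


def _golden_max(f: Callable[[np.ndarray], np.ndarray], lo: float, hi: float,
                size: int, iters: int = 48) -> np.ndarray:
    """Vectorized golden-section maximization of per-gene scalar objectives.

    ``f`` maps a vector of abscissae (one per gene) to a vector of
    objective values; all genes share the bracket [lo, hi].
    """
    a = np.full(size, lo)
    b = np.full(size, hi)
    h = b - a
    c = a + _INVPHI2 * h
    d = a + _INVPHI * h
    fc = f(c)
    fd = f(d)
    for _ in range(iters):
        keep_left = fc > fd
        a = np.where(keep_left, a, c)
        b = np.where(keep_left, d, b)
        h = b - a
        c = a + _INVPHI2 * h
        d = a + _INVPHI * h
        x_eval = np.where(keep_left, c, d)
        known = np.where(keep_left, fc, fd)
        fx = f(x_eval)
        fc = np.where(keep_left, fx, known)
        fd = np.where(keep_left, known, fx)
    return np.where(fc > fd, c, d)


def _nb_loglik(x: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples.

    x, mu: (G, n); alpha: (G,).  mu is floored to keep terms finite; rows
    with structural zeros contribute zero where x = 0.
    """
    r = 1.0 / np.maximum(alpha, 1e-12)[:, None]
    mu = np.maximum(mu, 1e-10)
    return (
        gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
        + r * np.log(r / (r + mu))
        + x * np.log(mu / (r + mu))
    ).sum(axis=1)


def _cr_adjustment(mu: np.ndarray, alpha: np.ndarray,
                   mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Cox-Reid term -1/2 log det(X'WX) for the two-group design."""
    w = mu / (1.0 + alpha[:, None] * mu)
    s1 = np.maximum(w[:, mask1].sum(axis=1), 1e-300)
    s2 = np.maximum(w[:, mask2].sum(axis=1), 1e-300)
    return -0.5 * (np.log(s1) + np.log(s2))


@dataclass
class DispersionModel:
    """Per-gene dispersion estimates and the mean-dispersion trend.

    ``raw`` are Cox-Reid-adjusted per-gene MLEs, ``map`` the final
    trend-shrunken estimates used by the Wald test.  The trend is
    alpha_tr(mu) = a0 + a1/mu (or a constant fallback when too few genes
    support a fit); ``sigma_prior`` is the log-normal prior sd.
    """

    raw: pd.Series
    trend_a0: float
    trend_a1: float
    sigma_prior: float
    map: pd.Series
    base_mean: pd.Series
    trend_is_constant: bool = False

    def trend(self, mu) -> np.ndarray:
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
        return np.maximum(self.trend_a0 + self.trend_a1 / mu, ALPHA_FLOOR)


def _fit_trend(alpha_raw: np.ndarray, base_mean: np.ndarray,
               n_iter: int = 10) -> tuple[float, float]:
    """Gamma-family IRLS fit of alpha ~ a0 + a1/mu with non-negative
    coefficients and one outlier-trim pass on log residuals."""

    def irls(y, bm):
        X = np.column_stack([np.ones_like(bm), 1.0 / bm])
        coef, _ = nnls(X, y)
        for _ in range(n_iter):
            fitted = np.maximum(X @ coef, 1e-10)
            w = 1.0 / fitted**2  # gamma variance ~ mu^2
            sw = np.sqrt(w)[:, None]
            new, _ = nnls(X * sw, y * np.sqrt(w))
            if np.allclose(new, coef, rtol=1e-6, atol=1e-12):
                coef = new
                break
            coef = new
        return coef

    coef = irls(alpha_raw, base_mean)
    fitted = np.maximum(coef[0] + coef[1] / base_mean, 1e-10)
    resid = np.log(alpha_raw) - np.log(fitted)
    mad = np.median(np.abs(resid - np.median(resid)))
    keep = np.abs(resid) <= 2.0 * 1.4826 * max(mad, 1e-12)
    if keep.sum() >= 10 and keep.sum() < keep.size:
        coef = irls(alpha_raw[keep], base_mean[keep])
    return float(coef[0]), float(coef[1])


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series | None = None,
) -> DispersionModel:
    """Estimate per-gene NB dispersions for a two-group design.

    Parameters
    ----------
    counts : DataFrame, genes x samples, integer.
    groups : Series mapping sample ID to one of exactly two labels.
    size_factors : Series of positive per-sample factors; all 1 if None.
    """
    x = counts.to_numpy(dtype=float)
    samples = counts.columns
    missing = [s for s in samples if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    labels = pd.unique(groups.loc[samples])
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(labels)}")
    mask1 = (groups.loc[samples] == labels[0]).to_numpy()
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("need at least two samples per group for dispersion estimation")
    if size_factors is None:
        s = np.ones(len(samples))
    else:
        s = size_factors.loc[samples].to_numpy(dtype=float)
        if np.any(s <= 0):
            raise ValueError("size factors must be positive")

    q = x / s[None, :]
    base_mean = q.mean(axis=1)
    # closed-form fitted group means under the NB GLM with log link
    mu1 = x[:, mask1].sum(axis=1) / s[mask1].sum()
    mu2 = x[:, mask2].sum(axis=1) / s[mask2].sum()
    mu = np.empty_like(x)
    mu[:, mask1] = (mu1[:, None] * s[mask1][None, :])
    mu[:, mask2] = (mu2[:, None] * s[mask2][None, :])

    log_lo, log_hi = np.log(ALPHA_FLOOR), np.log(ALPHA_CEIL)

    def cr_objective(log_alpha: np.ndarray) -> np.ndarray:
        alpha = np.exp(log_alpha)
        return _nb_loglik(x, mu, alpha) + _cr_adjustment(mu, alpha, mask1, mask2)

    raw = np.exp(_golden_max(cr_objective, log_lo, log_hi, x.shape[0]))
    raw = np.maximum(raw, ALPHA_FLOOR)
    # treat estimates pinned to the lower bracket edge as "no overdispersion"
    raw[raw < ALPHA_FLOOR * 1.5] = ALPHA_FLOOR
    # zero within-group variance carries no dispersion information beyond
    # Poisson (method-of-moments estimate 0); pin to the floor so the small
    # Cox-Reid lift near the boundary does not register as overdispersion
    n1, n2 = mask1.sum(), mask2.sum()
    v1 = q[:, mask1].var(axis=1, ddof=1)
    v2 = q[:, mask2].var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    raw[pooled_var == 0] = ALPHA_FLOOR

    usable = (raw > ALPHA_FLOOR) & (base_mean > 0)
    if usable.sum() < 10:
        med = float(np.median(raw[usable])) if usable.any() else ALPHA_FLOOR
        warnings.warn(
            "fewer than 10 genes usable for the dispersion trend; "
            "falling back to a constant trend at the median raw dispersion",
            stacklevel=2,
        )
        a0, a1, constant = max(med, ALPHA_FLOOR), 0.0, True
    else:
        a0, a1 = _fit_trend(raw[usable], base_mean[usable])
        constant = False
        if a0 <= 0 and a1 <= 0:  # degenerate fit
            a0, a1, constant = float(np.median(raw[usable])), 0.0, True

    trend_at = np.maximum(a0 + a1 / np.maximum(base_mean, 1e-10), ALPHA_FLOOR)
    if usable.any():
        resid = np.log(raw[usable]) - np.log(trend_at[usable])
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    else:
        sigma = 0.0
    sigma = max(float(sigma), SIGMA_PRIOR_FLOOR)

    log_prior_mean = np.log(trend_at)

    def map_objective(log_alpha: np.ndarray) -> np.ndarray:
        alpha = np.exp(log_alpha)
        penalty = (log_alpha - log_prior_mean) ** 2 / (2.0 * sigma**2)
        return _nb_loglik(x, mu, alpha) + _cr_adjustment(mu, alpha, mask1, mask2) - penalty

    final = np.exp(_golden_max(map_objective, log_lo, log_hi, x.shape[0]))
    final = np.maximum(final, ALPHA_FLOOR)

    idx = counts.index
    return DispersionModel(
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
        trend_a0=float(a0),
        trend_a1=float(a1),
        sigma_prior=sigma,
        map=pd.Series(final, index=idx, name="dispersion_map"),
        base_mean=pd.Series(base_mean, index=idx, name="base_mean"),
        trend_is_constant=constant,
    )


def nb_wald_two_group(
    counts: pd.DataFrame,
    groups: pd.Series,
    size_factors: pd.Series | None,
    dispersions: DispersionModel,
    test: str,
    ref: str,
    method: str = "nb_wald",
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``test`` versus ``ref`` group.

    Group means are the closed-form GLM fits mu_k = sum(x)/sum(s); the
    log2 fold change is log2(mu_test/mu_ref) with standard error
    sqrt(1/sum w_test + 1/sum w_ref)/ln 2, w_j = mu_gj/(1 + alpha mu_gj).
    Genes with a zero group mean have the mean floored at
    0.5/median(size factor) and are flagged.  Returns a DataFrame with
    columns base_mean, log2fc, lfc_se, wald_stat, pvalue, padj, flagged.
    """
    samples = counts.columns
    glab = groups.loc[samples]
    for name in (test, ref):
        if (glab == name).sum() == 0:
            raise ValueError(f"group {name!r} has no samples")
    mask_t = (glab == test).to_numpy()
    mask_r = (glab == ref).to_numpy()
    if not (mask_t | mask_r).all():
        extra = sorted(set(glab) - {test, ref})
        raise ValueError(f"unexpected extra groups: {extra}")
    x = counts.to_numpy(dtype=float)
    s = (np.ones(len(samples)) if size_factors is None
         else size_factors.loc[samples].to_numpy(dtype=float))

    mu_t = x[:, mask_t].sum(axis=1) / s[mask_t].sum()
    mu_r = x[:, mask_r].sum(axis=1) / s[mask_r].sum()
    floor = 0.5 / np.median(s)
    flagged = (mu_t <= 0) | (mu_r <= 0)
    mu_t_f = np.where(mu_t <= 0, floor, mu_t)
    mu_r_f = np.where(mu_r <= 0, floor, mu_r)

    log2fc = np.log2(mu_t_f / mu_r_f)

    alpha = dispersions.map.loc[counts.index].to_numpy()
    mu_mat_t = mu_t_f[:, None] * s[mask_t][None, :]
    mu_mat_r = mu_r_f[:, None] * s[mask_r][None, :]
    w_t = (mu_mat_t / (1.0 + alpha[:, None] * mu_mat_t)).sum(axis=1)
    w_r = (mu_mat_r / (1.0 + alpha[:, None] * mu_mat_r)).sum(axis=1)
    lfc_se = np.sqrt(1.0 / w_t + 1.0 / w_r) / LN2
    wald = log2fc / lfc_se
    pvalue = 2.0 * norm.sf(np.abs(wald))

    base_mean = (x / s[None, :]).mean(axis=1)
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "lfc_se": lfc_se,
            "wald_stat": wald,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
            "flagged": flagged,
        },
        index=counts.index,
    )
    res.attrs["method"] = method
    res.attrs["test"] = test
    res.attrs["ref"] = ref
    return res


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN-propagating.

    padj_(i) = min_{k >= i} m * p_(k) / k over the m non-missing p-values,
    capped at 1; the original order is restored and NaNs stay NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


@dataclass(frozen=True)
class DEGCall:
    """Genes passing padj <= fdr and |log2fc| >= lfc_cutoff (inclusive)."""

    genes: pd.Index
    direction: pd.Series  # "up" / "down" per called gene
    fdr: float
    lfc_cutoff: float

    @property
    def n_up(self) -> int:
        return int((self.direction == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.direction == "down").sum())

    def __len__(self) -> int:
        return len(self.genes)


def call_degs(res: pd.DataFrame, fdr: float = 0.05, lfc_cutoff: float = 0.0) -> DEGCall:
    """Threshold a test result table into a DEG call.

    Both thresholds are inclusive: padj <= fdr and |log2fc| >= lfc_cutoff.
    """
    if lfc_cutoff < 0:
        raise ValueError("lfc_cutoff must be >= 0")
    padj = res["padj"].to_numpy()
    lfc = res["log2fc"].to_numpy()
    called = (~np.isnan(padj)) & (padj <= fdr) & (np.abs(lfc) >= lfc_cutoff)
    genes = res.index[called]
    direction = pd.Series(
        np.where(lfc[called] > 0, "up", "down"), index=genes, name="direction"
    )
    return DEGCall(genes=genes, direction=direction, fdr=fdr, lfc_cutoff=lfc_cutoff)


class NBWaldDE:
    """Two-group NB Wald differential-expression model.

    Statsmodels-style: construct from a count matrix and sample metadata,
    then :meth:`fit` estimates dispersions and the per-gene test,
    returning :class:`NBWaldDEResults`.

    Parameters
    ----------
    counts : DataFrame, genes x samples, integer counts (raw, or rounded
        UQ-pgQ2 values with unit size factors).
    groups : Series mapping sample ID to condition label.
    test, ref : the two condition labels to contrast (test over ref).
    size_factors : optional per-sample positive factors; None means 1.
    """

    def __init__(self, counts: pd.DataFrame, groups: pd.Series, test: str,
                 ref: str, size_factors: pd.Series | None = None,
                 method: str = "nb_wald"):
        keep = groups[groups.isin([test, ref])].index
        keep = [s for s in counts.columns if s in set(keep)]
        self.counts = counts.loc[:, keep]
        self.groups = groups.loc[keep]
        self.test = test
        self.ref = ref
        self.size_factors = (
            size_factors.loc[keep] if size_factors is not None else None
        )
        self.method = method

    @classmethod
    def from_count_matrix(cls, m: CountMatrix, sheet: pd.DataFrame, test: str,
                          ref: str, size_factors: pd.Series | None = None,
                          method: str = "nb_wald") -> "NBWaldDE":
        groups = sheet.set_index("sample_id")["group"]
        return cls(m.counts, groups, test, ref, size_factors, method)

    @classmethod
    def from_normalized(cls, norm: NormalizedMatrix, groups: pd.Series,
                        test: str, ref: str) -> "NBWaldDE":
        """Model on rounded normalized values with unit size factors."""
        return cls(norm.rounded_counts(), groups, test, ref, None,
                   method=norm.method)

    def fit(self) -> "NBWaldDEResults":
        disp = estimate_dispersions(self.counts, self.groups, self.size_factors)
        table = nb_wald_two_group(
            self.counts, self.groups, self.size_factors, disp,
            self.test, self.ref, method=self.method,
        )
        return NBWaldDEResults(model=self, dispersions=disp, table=table)


@dataclass
class NBWaldDEResults:
    """Fitted per-gene estimates, uncertainties and significance."""

    model: NBWaldDE
    dispersions: DispersionModel
    table: pd.DataFrame

    def call(self, fdr: float = 0.05, lfc_cutoff: float = 0.0) -> DEGCall:
        return call_degs(self.table, fdr=fdr, lfc_cutoff=lfc_cutoff)

    def summary(self, n: int = 10) -> str:
        t = self.table.sort_values("padj")
        lines = [
            f"NB Wald two-group test: {self.model.test} vs {self.model.ref} "
            f"({self.model.method})",
            f"genes: {len(t)}   samples: {self.model.counts.shape[1]}",
            (
                "dispersion trend: "
                + (f"constant {self.dispersions.trend_a0:.4g}"
                   if self.dispersions.trend_is_constant
                   else f"{self.dispersions.trend_a0:.4g} + "
                        f"{self.dispersions.trend_a1:.4g}/mu")
                + f"   prior sd: {self.dispersions.sigma_prior:.3g}"
            ),
            "",
            t.head(n).to_string(
                float_format=lambda v: f"{v:.4g}",
                columns=["base_mean", "log2fc", "lfc_se", "wald_stat",
                         "pvalue", "padj"],
            ),
        ]
        return "\n".join(lines)


def run_de_route(
    m: CountMatrix,
    groups: pd.Series,
    test: str,
    ref: str,
    route: str,
    scale_constant: float = 100.0,
) -> NBWaldDEResults:
    """Run one normalization-plus-test route end to end.

    ``uq-pgq2``: UQ-pgQ2 normalize, round half-to-even, unit size factors.
    ``deseq-mor``: raw counts with median-of-ratios size factors.
    """
    keep = groups[groups.isin([test, ref])].index
    sub = m.select_samples([s for s in m.sample_ids if s in set(keep)])
    if route == "uq-pgq2":
        norm = uq_pgq2_normalize(sub, scale_constant=scale_constant)
        model = NBWaldDE.from_normalized(norm, groups, test, ref)
    elif route == "deseq-mor":
        sf = median_of_ratios_factors(sub)
        model = NBWaldDE(sub.counts, groups, test, ref, size_factors=sf,
                         method="deseq_mor")
    else:
        raise ValueError(f"unknown route {route!r}; expected 'uq-pgq2' or 'deseq-mor'")
    return model.fit()
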