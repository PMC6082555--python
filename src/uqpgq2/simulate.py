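"""Synthetic negative-binomial count simulator.

Generates gene-by-sample count matrices with the structure the pipeline
assumes: NB-distributed counts around log-normal baseline means, a
mean-dispersion trend (or constant dispersion), unequal library sizes,
optionally spiked differentially expressed genes, and a small minority of
extreme high-count "contaminant" genes (emulating residual rRNA) whose
inflated means and dispersions are exactly what per-gene median scaling
is meant to tame.  A truth table of per-gene log2 fold changes is emitted
alongside the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .countdata import CountMatrix

__all__ = ["SimulationConfig", "simulate_counts"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Baseline means mu_g are log-normal (meanlog 4, sdlog 2 by default,
    spanning ~1 to ~10^5 counts).  Dispersion is either the trend
    a0 + a1/mu (default a0=0.05, a1=5) or a constant ``alpha`` when set.
    Per-sample size factors are drawn uniformly from
    ``size_factor_range`` unless ``size_factors`` gives them explicitly.
    ``de_fraction`` of genes (an exact count, rounded) receive a true
    log2 fold change drawn from ``lfc_magnitudes`` with ``up_fraction``
    of positive signs, applied to group 2.  ``skew_fraction`` of non-DE
    genes become contaminants: mean times ``skew_mean_multiplier``,
    dispersion times ``skew_dispersion_multiplier``.
    """

    n_genes: int = 20000
    n1: int = 21
    n2: int = 21
    meanlog: float = 4.0
    sdlog: float = 2.0
    trend_a0: float = 0.05
    trend_a1: float = 5.0
    alpha: float | None = None
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    size_factors: tuple | None = None
    de_fraction: float = 0.0
    lfc_magnitudes: tuple = (1.5, 2.0, 3.0)
    up_fraction: float = 0.5
    skew_fraction: float = 0.01
    skew_mean_multiplier: float = 50.0
    skew_dispersion_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n1 < 1 or self.n2 < 0:
            raise ValueError("group sizes must be positive (n2 may be 0)")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in [0, 1)")
        if not 0.0 <= self.skew_fraction < 1.0:
            raise ValueError("skew_fraction must lie in [0, 1)")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must lie in [0, 1]")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ValueError("size_factor_range must be 0 < lo <= hi")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if sf.size != self.n1 + self.n2 or np.any(sf <= 0):
                raise ValueError(
                    "size_factors must give one positive value per sample"
                )
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.de_fraction > 0 and not self.lfc_magnitudes:
            raise ValueError("lfc_magnitudes empty but de_fraction > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("size_factor_range", "size_factors", "lfc_magnitudes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _nb_draws(rng: np.random.Generator, mean: np.ndarray,
              alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) samples; dispersion 0 degenerates to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha <= 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its truth table from the configured model.

    Counts are x_gj ~ NB(mean = s_j * mu_g * 2^(beta_g * [j in group 2]),
    dispersion alpha_g).  The truth table lists every gene's true
    log2 fold change (0 for nulls) and contaminant status.  Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n1 + cfg.n2
    gene_ids = pd.Index(
        [f"gene{g:06d}" for g in range(cfg.n_genes)], name="gene_id"
    )
    sample_ids = pd.Index(
        [f"s{j + 1:03d}_g1" for j in range(cfg.n1)]
        + [f"s{j + 1:03d}_g2" for j in range(cfg.n2)]
    )

    mu = rng.lognormal(cfg.meanlog, cfg.sdlog, size=cfg.n_genes)
    if cfg.alpha is not None:
        alpha = np.full(cfg.n_genes, float(cfg.alpha))
    else:
        alpha = cfg.trend_a0 + cfg.trend_a1 / mu

    if cfg.size_factors is not None:
        s = np.asarray(cfg.size_factors, dtype=float)
    else:
        s = rng.uniform(*cfg.size_factor_range, size=n_samples)

    beta = np.zeros(cfg.n_genes)
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    if n_de:
        mags = rng.choice(np.asarray(cfg.lfc_magnitudes, dtype=float), size=n_de)
        n_up = int(round(cfg.up_fraction * n_de))
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        rng.shuffle(signs)
        beta[de_idx] = mags * signs

    is_contaminant = np.zeros(cfg.n_genes, dtype=bool)
    n_skew = int(round(cfg.skew_fraction * cfg.n_genes))
    if n_skew:
        null_pool = np.setdiff1d(np.arange(cfg.n_genes), de_idx)
        skew_idx = rng.choice(null_pool, size=min(n_skew, null_pool.size),
                              replace=False)
        is_contaminant[skew_idx] = True
        mu[skew_idx] *= cfg.skew_mean_multiplier
        alpha[skew_idx] *= cfg.skew_dispersion_multiplier

    in_g2 = np.zeros(n_samples, dtype=bool)
    in_g2[cfg.n1:] = True
    mean = s[None, :] * mu[:, None] * np.power(
        2.0, beta[:, None] * in_g2[None, :]
    )
    counts = _nb_draws(rng, mean, np.broadcast_to(alpha[:, None], mean.shape).copy())

    m = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    truth = pd.DataFrame(
        {
            "true_log2fc": beta,
            "is_contaminant": is_contaminant,
            "baseline_mean": mu,
            "dispersion": alpha,
        },
        index=gene_ids,
    )
    truth.attrs["size_factors"] = s
    return m, truth
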