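"""Slope-difference test for adaptive crop migration versus niche expansion.

The statistic is Theta = beta_o - beta_c: the difference between the warm-bound
temperature trend the crop actually experienced (quantile regression weighted
by dynamic rainfed areas) and the counterfactual trend with areas frozen at
the reference window. Theta significantly below zero indicates adaptive
migration toward cooler conditions; significantly above zero indicates
expansion into warmer conditions.

Inference is by cluster bootstrap: grid cells are resampled with replacement,
each sampled cell contributing its entire year series, and both models are
refit on the *same* resample so the two slopes stay paired. P-values are the
proportions of the bootstrap distribution of Theta on either side of zero
(samples exactly at zero count toward both sides, a conservative choice).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .quantile_trend import QuantileFit, fit_pair, fit_weighted_quantile

__all__ = [
    "AdaptationResult",
    "theta",
    "bootstrap_theta",
    "classify",
    "run_adaptation_test",
    "derive_seed",
]

LABEL_MIGRATION = "adaptive_migration"
LABEL_EXPANSION = "niche_expansion"
LABEL_NONE = "no_evidence"

DEFAULT_N_BOOT = 500
DEFAULT_ALPHA = 0.05
_MAX_REDRAWS = 100


@dataclass
class AdaptationResult:
    """Outcome of the slope-difference test for one crop and quantile level."""

    theta: float
    theta_samples: np.ndarray = field(repr=False)
    p_adapt: float
    p_expand: float
    label: str
    alpha: float
    seed: int | None = None
    beta_observed: float = float("nan")
    beta_counterfactual: float = float("nan")
    tau: float = float("nan")


def theta(beta_o: float, beta_c: float) -> float:
    """Slope difference Theta = beta_o - beta_c (degC per year)."""
    if not (np.isfinite(beta_o) and np.isfinite(beta_c)):
        raise ValueError("slopes must be finite")
    return float(beta_o - beta_c)


def derive_seed(master_seed: int, crop: str, tau: float) -> int:
    """Stable per-(crop, tau) stream seed derived from a master seed."""
    tag = zlib.crc32(f"{crop}|{tau:.6f}".encode())
    return int(np.random.SeedSequence([int(master_seed), tag]).generate_state(1)[0] % (2**31))


def _panel_arrays(panel, dynamic, static):
    """Flatten to (years, cells): temperatures, dynamic weights, static weights."""
    years = panel.years
    temp = panel.data.transpose("year", "lat", "lon").values.reshape(len(years), -1)
    wd = (
        dynamic.for_years(years)
        .transpose("year", "lat", "lon")
        .values.reshape(len(years), -1)
    )
    ws = static.for_years(years).transpose("year", "lat", "lon").values.reshape(len(years), -1)
    wd = np.nan_to_num(wd, nan=0.0)
    ws = np.nan_to_num(ws, nan=0.0)
    return years.astype(float), temp, wd, ws


def _fit_slope(years, temp, w, tau) -> QuantileFit:
    t = np.broadcast_to(years[:, None], temp.shape).ravel()
    return fit_weighted_quantile(year=t, temperature=temp.ravel(), weight=w.ravel(), tau=tau)


def bootstrap_theta(
    panel,
    dynamic,
    static,
    tau: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    paired: bool = True,
    return_slopes: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster-bootstrap distribution of Theta.

    Each replicate draws grid cells with replacement; a sampled cell carries
    its whole year series, and its weight is multiplied by its sampling
    multiplicity. With ``paired=True`` (default) the observed and
    counterfactual models are fit on the identical resample; ``paired=False``
    draws an independent resample for the counterfactual. Replicates whose
    resample is degenerate (a single distinct year with positive weight, or
    zero total weight in either model) are redrawn up to 100 times.

    With ``return_slopes=True`` also returns the bootstrap beta_o and beta_c.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    years, temp, wd, ws = _panel_arrays(panel, dynamic, static)
    ncell = temp.shape[1]
    rng = np.random.default_rng(seed)

    def degenerate(tempsub, w) -> bool:
        pos = (w > 0) & np.isfinite(tempsub)
        return int(pos.any(axis=1).sum()) < 2  # < 2 distinct years usable

    samples = np.empty(n_boot)
    bo = np.empty(n_boot)
    bc = np.empty(n_boot)
    for rep in range(n_boot):
        for attempt in range(_MAX_REDRAWS):
            idx = rng.integers(0, ncell, ncell)
            mult = np.bincount(idx, minlength=ncell).astype(float)
            sel = mult > 0
            m = mult[sel]
            tsub = temp[:, sel]
            wdsub = wd[:, sel] * m
            if paired:
                wssub = ws[:, sel] * m
            else:
                idx2 = rng.integers(0, ncell, ncell)
                mult2 = np.bincount(idx2, minlength=ncell).astype(float)
                sel2 = mult2 > 0
                wssub = ws[:, sel2] * mult2[sel2]
                tsub2 = temp[:, sel2]
            if degenerate(tsub, wdsub):
                continue
            if degenerate(tsub if paired else tsub2, wssub):
                continue
            fo = _fit_slope(years, tsub, wdsub, tau)
            fc = _fit_slope(years, tsub if paired else tsub2, wssub, tau)
            samples[rep] = fo.slope - fc.slope
            bo[rep] = fo.slope
            bc[rep] = fc.slope
            break
        else:
            raise RuntimeError("bootstrap resample degenerate after 100 redraws")
    if return_slopes:
        return samples, bo, bc
    return samples


def classify(
    theta_samples: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    theta_hat: float = float("nan"),
    seed: int | None = None,
) -> AdaptationResult:
    """Label the bootstrap Theta distribution.

    ``p_adapt`` is the proportion of samples >= 0 (small means the slope
    difference is credibly negative: adaptive migration); ``p_expand`` is the
    proportion <= 0. Samples exactly at zero count in both.
    """
    samples = np.asarray(theta_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty bootstrap sample")
    n = samples.size
    p_adapt = float(np.sum(samples >= 0.0)) / n
    p_expand = float(np.sum(samples <= 0.0)) / n
    if p_adapt < alpha and p_expand < alpha:
        raise AssertionError("both one-sided p-values below alpha: inconsistent sample")
    if p_adapt < alpha:
        label = LABEL_MIGRATION
    elif p_expand < alpha:
        label = LABEL_EXPANSION
    else:
        label = LABEL_NONE
    return AdaptationResult(
        theta=float(theta_hat) if np.isfinite(theta_hat) else float(np.mean(samples)),
        theta_samples=samples,
        p_adapt=p_adapt,
        p_expand=p_expand,
        label=label,
        alpha=alpha,
        seed=seed,
    )


def run_adaptation_test(
    panel,
    dynamic,
    static,
    tau: float = 0.95,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
    paired: bool = True,
) -> AdaptationResult:
    """Point fits plus cluster bootstrap plus classification, in one call."""
    observed, counterfactual = fit_pair(panel, dynamic, static, tau)
    samples = bootstrap_theta(
        panel, dynamic, static, tau, n_boot=n_boot, seed=seed, paired=paired
    )
    result = classify(
        samples, alpha=alpha, theta_hat=theta(observed.slope, counterfactual.slope), seed=seed
    )
    result.beta_observed = observed.slope
    result.beta_counterfactual = counterfactual.slope
    result.tau = tau
    return result
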