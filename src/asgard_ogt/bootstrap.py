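"""Bootstrap confidence intervals for the peak GDP-binding temperature.

For each of ``n_boot`` bootstrap datasets, the replicate values at every
temperature are resampled with replacement (size-preserving, independently
per temperature), the peak model is refit, and the confidence interval is
read off the percentiles of the resulting peak-temperature distribution —
for the default 90% level, the 5th and 95th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .peak_model import DEFAULT_W, PeakParams, fit_peak
from .profiles import FluorescenceProfile


class BootstrapQualityError(RuntimeError):
    """Raised when too many bootstrap refits fail to converge."""


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap distribution of the peak temperature and its percentile CI."""

    protein_id: str
    point_estimate: float
    samples: np.ndarray
    ci_lower: float
    ci_upper: float
    level: float
    n_boot: int
    seed: int
    n_failed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.ci_lower > self.ci_upper:
            raise ValueError("ci_lower must be <= ci_upper")
        if len(self.samples) != self.n_boot - self.n_failed:
            raise ValueError("sample count must equal n_boot - n_failed")


def resample_profile(profile: FluorescenceProfile, rng: np.random.Generator) -> FluorescenceProfile:
    """One bootstrap replicate of a profile.

    For each temperature independently, draws ``n_replicates`` values with
    replacement from that temperature's observed replicates ("three out of
    three, sampled with return" on the standard design). Temperatures and
    assay kind are unchanged.
    """
    n_rep, n_t = profile.fluorescence.shape
    idx = rng.integers(0, n_rep, size=(n_rep, n_t))
    resampled = np.take_along_axis(profile.fluorescence, idx, axis=0)
    return profile.with_fluorescence(resampled)


def percentile(values: Sequence[float], p: float) -> float:
    """Order-statistic percentile with linear interpolation ("type 7").

    The sorted sample is indexed at ``1 + p*(n-1)`` with linear interpolation
    between adjacent order statistics, so ``p=0`` is the minimum and ``p=1``
    the maximum. This is numpy's default rule.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(np.quantile(arr, p, method="linear"))


def bootstrap_peak_ci(
    profile: FluorescenceProfile,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int = 0,
    fit_range: Optional[tuple] = None,
    w: float = DEFAULT_W,
    max_fail_fraction: float = 0.10,
) -> BootstrapResult:
    """Percentile bootstrap CI for the peak temperature.

    The point estimate always comes from the full, un-resampled profile.
    Bootstrap refits are started from the full-data solution (no multi-start
    jitter), which stabilises refits of the multimodal objective; refits that
    fail to converge or are non-identifiable are dropped and counted in
    ``n_failed``. More than ``max_fail_fraction`` failures raises
    :class:`BootstrapQualityError`.

    Randomness: the root ``seed`` is expanded into one deterministic
    substream per bootstrap replicate via :class:`numpy.random.SeedSequence`,
    so results do not depend on execution order.
    """
    full = fit_peak(profile, fit_range=fit_range, w=w, seed=seed)
    if not full.identifiable:
        raise ValueError(
            f"profile {profile.protein_id!r}: peak not identifiable; cannot bootstrap"
        )
    point = full.params.t_star
    init: PeakParams = full.params

    streams = np.random.SeedSequence(seed).spawn(n_boot)
    samples = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        boot = resample_profile(profile, rng)
        try:
            # refits warm-start at the full-data solution; peak-temperature
            # precision far below the CI resolution is not needed
            fit = fit_peak(boot, fit_range=fit_range, init=init, w=w, n_restarts=1, xatol=1e-4)
        except ValueError:
            n_failed += 1
            continue
        if not (fit.converged and fit.identifiable):
            n_failed += 1
            continue
        samples.append(fit.params.t_star)

    if n_failed > max_fail_fraction * n_boot:
        raise BootstrapQualityError(
            f"{n_failed} of {n_boot} bootstrap fits failed for {profile.protein_id!r}"
        )

    arr = np.asarray(samples, dtype=float)
    alpha = (1.0 - level) / 2.0
    return BootstrapResult(
        protein_id=profile.protein_id,
        point_estimate=point,
        samples=arr,
        ci_lower=percentile(arr, alpha),
        ci_upper=percentile(arr, 1.0 - alpha),
        level=level,
        n_boot=n_boot,
        seed=seed,
        n_failed=n_failed,
    )
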