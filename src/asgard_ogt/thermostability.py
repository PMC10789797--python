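"""Thermal-stability (ThermoFluor) analysis: unfolding transition and stable range.

In a ThermoFluor melt, the SYPRO-Orange signal rises as the protein unfolds;
the grid temperature with the highest replicate-mean fluorescence marks the
transition from partial to complete unfolding. The protein is treated as
stable from the lowest assayed temperature up to one grid step below the
transition — on the standard 0-100 deg C / 10 deg C design, a transition at
70 deg C gives a stable range of 0-60 deg C. The upper bound is therefore
grid-resolution-limited: an approximate upper temperature limit, not a
fitted melting temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import FluorescenceProfile


@dataclass(frozen=True)
class StabilityResult:
    """Unfolding transition and derived stable temperature range (deg C)."""

    protein_id: str
    t_transition: float
    stable_min: float
    stable_max: float
    grid_step: float

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not self.stable_min <= self.stable_max < self.t_transition:
            raise ValueError("stable range must satisfy stable_min <= stable_max < t_transition")

    @property
    def fit_range(self) -> tuple:
        return (self.stable_min, self.stable_max)


def melting_transition(profile: FluorescenceProfile) -> float:
    """Grid temperature of maximal replicate-mean fluorescence.

    Ties at the maximum resolve to the lowest tied temperature (the
    conservative choice for the downstream stable range).
    """
    if profile.assay_kind != "stability":
        raise ValueError("melting_transition requires a stability-assay profile")
    if profile.n_temperatures < 3:
        raise ValueError("need at least 3 temperatures to locate a transition")
    mean = profile.mean_curve()
    if np.allclose(mean, mean[0]):
        raise ValueError(
            f"profile {profile.protein_id!r} is flat: no unfolding transition detectable"
        )
    # np.argmax returns the first (lowest-temperature) index among ties
    return float(profile.temperatures[int(np.argmax(mean))])


def infer_grid_step(temperatures: np.ndarray) -> float:
    """Minimal spacing between consecutive grid temperatures."""
    return float(np.min(np.diff(np.asarray(temperatures, dtype=float))))


def stable_range(profile: FluorescenceProfile) -> StabilityResult:
    """Stable temperature range from a melt profile.

    ``stable_min`` is the lowest assayed temperature; ``stable_max`` is the
    last grid point before the transition, i.e. ``t_transition - grid_step``.
    A transition at the lowest grid point leaves no stable range and raises.
    """
    t_trans = melting_transition(profile)
    step = infer_grid_step(profile.temperatures)
    t_min = float(profile.temperatures[0])
    if t_trans <= t_min:
        raise ValueError(
            f"profile {profile.protein_id!r}: transition at the lowest assayed "
            f"temperature ({t_trans} degC); no stable range"
        )
    return StabilityResult(
        protein_id=profile.protein_id,
        t_transition=t_trans,
        stable_min=t_min,
        stable_max=t_trans - step,
        grid_step=step,
    )


def restrict_to_stable(
    binding: FluorescenceProfile, stability: StabilityResult
) -> FluorescenceProfile:
    """Binding profile filtered to temperatures within the stable range.

    Order is preserved and no datapoint is duplicated; the result is a
    sub-profile of the input. Fewer than 3 surviving temperatures make the
    downstream peak fit infeasible and raise.
    """
    if binding.assay_kind != "binding":
        raise ValueError("restrict_to_stable expects a binding-assay profile")
    mask = (binding.temperatures >= stability.stable_min) & (
        binding.temperatures <= stability.stable_max
    )
    if int(mask.sum()) < 3:
        raise ValueError(
            f"profile {binding.protein_id!r}: only {int(mask.sum())} temperatures fall "
            f"inside the stable range [{stability.stable_min}, {stability.stable_max}]; "
            "peak fit infeasible"
        )
    return binding.subset(mask)
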