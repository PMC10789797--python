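"""Replicate fluorescence-vs-temperature profiles and their tabular I/O.

A :class:`FluorescenceProfile` holds the raw measurements of one assay for one
protein: either Mant-GDP binding fluorescence (``assay_kind="binding"``) or
SYPRO-Orange ThermoFluor unfolding fluorescence (``assay_kind="stability"``),
as a replicate x temperature matrix over a strictly increasing temperature
grid in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

ASSAY_KINDS = ("binding", "stability")


@dataclass(frozen=True)
class FluorescenceProfile:
    """Replicate fluorescence measurements across an ordered temperature grid.

    Parameters
    ----------
    protein_id
        Label of the protein (extant organism or reconstructed ancestor).
    temperatures
        Strictly increasing assay temperatures in deg C (length m >= 2).
    fluorescence
        Array of shape (n_replicates, m); arbitrary units, finite, >= 0.
    assay_kind
        Either ``"binding"`` (Mant-GDP binding) or ``"stability"``
        (ThermoFluor melt).
    """

    protein_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    assay_kind: str = "binding"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if self.assay_kind not in ASSAY_KINDS:
            raise ValueError(f"assay_kind must be one of {ASSAY_KINDS}, got {self.assay_kind!r}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least 2 temperatures in a 1-D grid")
        if not np.all(np.isfinite(t)):
            raise ValueError("temperatures must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if f.ndim != 2 or f.shape[0] < 1:
            raise ValueError("fluorescence must be a (replicate, temperature) matrix")
        if f.shape[1] != t.size:
            raise ValueError(
                f"fluorescence has {f.shape[1]} columns but grid has {t.size} temperatures"
            )
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("every intensity must be finite and >= 0")

    @property
    def n_replicates(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_temperatures(self) -> int:
        return self.temperatures.size

    @property
    def n_points(self) -> int:
        """Total datapoint count (replicates x temperatures)."""
        return self.fluorescence.size

    def mean_curve(self) -> np.ndarray:
        """Replicate-mean fluorescence at each grid temperature."""
        return self.fluorescence.mean(axis=0)

    def pooled_replicate_sd(self) -> float:
        """Pooled within-temperature replicate standard deviation.

        Zero when there is a single replicate.
        """
        if self.n_replicates < 2:
            return 0.0
        per_t_var = self.fluorescence.var(axis=0, ddof=1)
        return float(np.sqrt(per_t_var.mean()))

    def subset(self, mask: np.ndarray) -> "FluorescenceProfile":
        """Profile restricted to the grid columns selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return FluorescenceProfile(
            protein_id=self.protein_id,
            temperatures=self.temperatures[mask],
            fluorescence=self.fluorescence[:, mask],
            assay_kind=self.assay_kind,
        )

    def with_fluorescence(self, f: np.ndarray) -> "FluorescenceProfile":
        """Copy of this profile with a replaced intensity matrix."""
        return FluorescenceProfile(
            protein_id=self.protein_id,
            temperatures=self.temperatures,
            fluorescence=f,
            assay_kind=self.assay_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: protein_id, temperature_C, replicate, fluorescence."""
        rows = []
        for r in range(self.n_replicates):
            for j, t in enumerate(self.temperatures):
                rows.append((self.protein_id, float(t), r + 1, float(self.fluorescence[r, j])))
        return pd.DataFrame(
            rows, columns=["protein_id", "temperature_C", "replicate", "fluorescence"]
        )


def _sep_for(path: Union[str, Path]) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def profiles_from_frame(df: pd.DataFrame, assay_kind: str = "binding") -> list[FluorescenceProfile]:
    """Build profiles from a long-format table.

    Required columns: ``protein_id``, ``temperature_C``, ``replicate``,
    ``fluorescence``. An optional ``assay_kind`` column overrides the
    argument per row-group.
    """
    required = {"protein_id", "temperature_C", "replicate", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("protein_id", sort=False):
        kind = assay_kind
        if "assay_kind" in grp.columns:
            kinds = grp["assay_kind"].unique()
            if len(kinds) != 1:
                raise ValueError(f"protein {pid!r} mixes assay kinds {kinds}")
            kind = str(kinds[0])
        wide = grp.pivot_table(
            index="replicate", columns="temperature_C", values="fluorescence", aggfunc="first"
        )
        if wide.isna().any().any():
            raise ValueError(f"protein {pid!r}: missing replicate/temperature combinations")
        temps = np.array(sorted(wide.columns), dtype=float)
        out.append(
            FluorescenceProfile(
                protein_id=str(pid),
                temperatures=temps,
                fluorescence=wide[sorted(wide.columns)].to_numpy(dtype=float),
                assay_kind=kind,
            )
        )
    return out


def read_profiles(path: Union[str, Path], assay_kind: str = "binding") -> list[FluorescenceProfile]:
    """Read profiles from a CSV/TSV file (extension decides the delimiter)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return profiles_from_frame(df, assay_kind=assay_kind)


def write_profiles(profiles: Iterable[FluorescenceProfile], path: Union[str, Path]) -> None:
    """Write profiles as one long-format CSV/TSV table, with assay_kind."""
    frames = []
    for p in profiles:
        df = p.to_frame()
        df["assay_kind"] = p.assay_kind
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=_sep_for(path), index=False)
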