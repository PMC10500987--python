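"""Plain-text tables: free-energy profiles, summaries, temperature series."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fep import FreeEnergyProfile
from .thermo import TemperatureSeries

__all__ = ["write_profile", "read_profile", "read_temperature_table"]


def write_profile(profile: FreeEnergyProfile, path) -> None:
    """Tab-separated profile: bin center (gap, kcal/mol), dG (kcal/mol),
    configuration count, valid flag."""
    lines = ["# gap_kcal\tdG_kcal\tcount\tvalid"]
    for c, g, n, v in zip(profile.bin_centers, profile.delta_g,
                          profile.counts, profile.valid):
        lines.append(f"{c:.6f}\t{g:.6f}\t{n:.1f}\t{int(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path) -> FreeEnergyProfile:
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return FreeEnergyProfile(bin_centers=data[:, 0], delta_g=data[:, 1],
                             counts=data[:, 2], valid=data[:, 3].astype(bool))


def read_temperature_table(path) -> TemperatureSeries:
    """Two-column (T in K, dG_act in kcal/mol) whitespace/tab table;
    '#' lines are comments."""
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need two columns (T, dG_act)")
    return TemperatureSeries(temperatures=data[:, 0], dg_act=data[:, 1])
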