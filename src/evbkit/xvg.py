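"""Reading and writing per-window energy series in XVG dialect.

The files mirror what an MD engine's energy tool emits after end-point
recalculation: one row per saved frame with the reactant-state energy
eps1, the product-state energy eps2 (no gas shift) and optionally the
mapping energy V and a coordinate column.  Lines starting with ``#`` or
``@`` are metadata; data rows are whitespace-separated numbers.  File
energies default to kJ/mol (GROMACS convention) and are converted to
kcal/mol at the boundary; everything in memory is kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import KJ_PER_KCAL
from .toy import WindowTrajectory

__all__ = ["EnergySeriesFile", "XVGParseError", "read_energy_series",
           "write_energy_series"]

_DEFAULT_COLUMNS = {"time": 0, "eps1": 1, "eps2": 2}


class XVGParseError(ValueError):
    """Malformed energy-series file; message carries the line number."""


@dataclass(frozen=True)
class EnergySeriesFile:
    """Description of an on-disk energy series.

    ``columns`` maps the roles ``eps1``, ``eps2`` (required) and
    ``time``, ``v``, ``r`` (optional) to 0-based column indices.
    ``units`` is ``"kJ"`` or ``"kcal"`` for the energy columns.
    """

    path: str
    columns: dict = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    units: str = "kJ"
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.units not in ("kJ", "kcal"):
            raise ValueError(f"units must be 'kJ' or 'kcal', not {self.units!r}")
        for role in ("eps1", "eps2"):
            if role not in self.columns:
                raise ValueError(f"column map must declare {role!r}")


def read_energy_series(source) -> WindowTrajectory:
    """Parse an XVG energy series into a window trajectory (kcal/mol).

    ``source`` is an :class:`EnergySeriesFile` or a bare path (default
    column layout, kJ/mol).  The window's lambda comes from the
    description or from a ``# lambda = <x>`` metadata line.  Ragged rows,
    non-numeric cells and missing columns raise :class:`XVGParseError`
    naming the offending line.
    """
    if not isinstance(source, EnergySeriesFile):
        source = EnergySeriesFile(path=str(source))
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(path)

    lam = source.lam
    rows = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith(("#", "@")):
            if "lambda" in text and "=" in text and lam is None:
                try:
                    lam = float(text.split("=", 1)[1].strip().strip('"'))
                except ValueError:
                    pass
            continue
        cells = text.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise XVGParseError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {width})")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as err:
            raise XVGParseError(f"{path}:{lineno}: non-numeric cell: {err}") from err

    if not rows:
        raise XVGParseError(f"{path}: no data rows")
    if lam is None:
        raise XVGParseError(f"{path}: no lambda given or found in metadata")
    data = np.asarray(rows)
    needed = max(source.columns.values())
    if data.shape[1] <= needed:
        raise XVGParseError(
            f"{path}: column map needs {needed + 1} columns, file has {data.shape[1]}")

    scale = 1.0 / KJ_PER_KCAL if source.units == "kJ" else 1.0
    eps1 = data[:, source.columns["eps1"]] * scale
    eps2 = data[:, source.columns["eps2"]] * scale
    r = data[:, source.columns["r"]] if "r" in source.columns else None
    return WindowTrajectory(lam=float(lam), eps1=eps1, eps2=eps2, r=r)


def write_energy_series(traj: WindowTrajectory, path, units: str = "kJ",
                        delta_alpha: float = 0.0) -> None:
    """Write a window trajectory as an XVG energy series.

    Emits time (frame index), eps1, eps2, the mapping energy V at the
    window's lambda, and the coordinate when present.  Energies are
    written in ``units`` with 12 significant digits so read-then-write
    round-trips are lossless at that precision.
    """
    if units not in ("kJ", "kcal"):
        raise ValueError(f"units must be 'kJ' or 'kcal', not {units!r}")
    scale = KJ_PER_KCAL if units == "kJ" else 1.0
    v = traj.mapping_energy(delta_alpha) * scale
    eps1 = traj.eps1 * scale
    eps2 = traj.eps2 * scale
    have_r = traj.r is not None

    lines = [
        "# evbkit energy series",
        f"# lambda = {traj.lam:.12g}",
        f"# units = {units}/mol",
        '@ title "EVB end-point energies"',
        '@ xaxis label "frame"',
        '@ s0 legend "eps1"',
        '@ s1 legend "eps2"',
        '@ s2 legend "V(lambda)"',
    ]
    if have_r:
        lines.append('@ s3 legend "coordinate"')
    for i in range(traj.n_frames):
        row = f"{i:10d} {eps1[i]:.12e} {eps2[i]:.12e} {v[i]:.12e}"
        if have_r:
            row += f" {traj.r[i]:.12e}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
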