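"""Configuration files and tabular output.

Two plain-text contracts:

* configs are flat ``key = value`` files whose keys are exactly the field
  names of :class:`~fibriltip.model.RateSet` and
  :class:`~fibriltip.model.Conditions` (plus run keys such as ``mode``,
  ``n_runs``, ``t_end``, ``rng_seed``);
* tables are tab-separated with ``#``-prefixed metadata comment lines that
  embed the resolved rate set, conditions and package version, so every
  artifact is self-describing.
"""

from __future__ import annotations


import warnings
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, InvalidParameterError
from .kmc import Trajectory
from .model import Conditions, RateSet, unit_convert

__all__ = [
    "read_config",
    "write_config",
    "rates_from_config",
    "conditions_from_config",
    "write_table",
    "read_table",
    "write_trajectories",
    "read_velocity_table",
]

_RATE_KEYS = ("k_p_cc", "k_d_cc", "k_p_bc", "k_d_bc", "s_cb", "s_bc", "k_d_bb")
_COND_KEYS = ("conc", "force", "alpha", "rise", "kBT")


def read_config(path_or_file: Union[str, TextIO]) -> dict:
    """Parse a flat ``key = value`` config into a dict of floats/strings."""
    if isinstance(path_or_file, str):
        with open(path_or_file) as fh:
            return read_config(fh)
    out: dict = {}
    for lineno, raw in enumerate(path_or_file, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not key:
            raise ConfigError(f"line {lineno}: empty key")
        try:
            out[key] = float(val)
        except ValueError:
            out[key] = val
    return out


def write_config(path: str, **sections) -> None:
    """Write RateSet/Conditions/extra keys as a flat key-value file."""
    with open(path, "w") as fh:
        fh.write(f"# fibriltip {__version__} configuration\n")
        for obj in sections.values():
            d = obj.as_dict() if hasattr(obj, "as_dict") else dict(obj)
            for k, v in d.items():
                fh.write(f"{k} = {v}\n")


def rates_from_config(cfg: dict) -> RateSet:
    missing = [k for k in _RATE_KEYS[:5] if k not in cfg]
    if missing:
        raise ConfigError(f"missing rate key(s): {', '.join(missing)}")
    try:
        return RateSet(**{k: float(cfg[k]) for k in _RATE_KEYS if k in cfg})
    except (TypeError, ValueError, InvalidParameterError) as e:
        raise ConfigError(f"bad rate value: {e}") from e


def conditions_from_config(cfg: dict) -> Conditions:
    if "conc" not in cfg:
        raise ConfigError("missing key: conc")
    try:
        return Conditions(**{k: float(cfg[k]) for k in _COND_KEYS if k in cfg})
    except (TypeError, ValueError, InvalidParameterError) as e:
        raise ConfigError(f"bad condition value: {e}") from e


def _metadata_lines(
    rates: Optional[RateSet] = None,
    cond: Optional[Conditions] = None,
    extra: Optional[dict] = None,
) -> list[str]:
    lines = [f"# fibriltip {__version__}"]
    if rates is not None:
        lines.append(
            "# rates: "
            + " ".join(f"{k}={v}" for k, v in rates.as_dict().items())
        )
    if cond is not None:
        lines.append(
            "# conditions: "
            + " ".join(f"{k}={v}" for k, v in cond.as_dict().items())
        )
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_table(
    path: str,
    df: pd.DataFrame,
    rates: Optional[RateSet] = None,
    cond: Optional[Conditions] = None,
    extra: Optional[dict] = None,
) -> None:
    """Write a DataFrame as TSV with '#' metadata header lines."""
    with open(path, "w") as fh:
        for line in _metadata_lines(rates, cond, extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_trajectories(path: str, trajs: Sequence[Trajectory], **meta) -> None:
    """Dump trajectories as TSV (time_hr, filament_id, length, n_beta, cap_k)."""
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "time_hr": tr.times,
                    "filament_id": tr.filament_id,
                    "length_monomers": tr.length,
                    "n_beta": tr.n_beta,
                    "cap_k": tr.cap_k,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    extra = {"mode": trajs[0].mode, "rng_seed": trajs[0].rng_seed, **meta}
    write_table(path, df, extra=extra)


def read_velocity_table(
    path_or_file: Union[str, TextIO], rise: float = 0.5
) -> list[tuple[float, float]]:
    """Read a two-column (concentration, velocity) TSV for rate estimation.

    An optional comment line ``# units: <velocity unit>`` (e.g. ``nm/hr``)
    triggers conversion to monomers/hr via the axial rise.  Rows are sorted
    by concentration; duplicate concentrations are averaged with a warning.
    """
    if isinstance(path_or_file, str):
        with open(path_or_file) as fh:
            return read_velocity_table(fh, rise)
    unit = "monomers/hr"
    rows = []
    for lineno, raw in enumerate(path_or_file, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("units:"):
                unit = body.split(":", 1)[1].strip()
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ConfigError(f"line {lineno}: expected two columns, got {raw!r}")
        try:
            c, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise ConfigError(
                f"line {lineno}: non-numeric row {raw!r}"
            ) from None
        rows.append((c, unit_convert(v, unit, "monomers/hr", rise=rise)))
    if not rows:
        raise ConfigError("empty velocity table")
    rows.sort()
    concs = np.array([r[0] for r in rows])
    if np.unique(concs).size < concs.size:
        warnings.warn("duplicate concentrations averaged", stacklevel=2)
        merged = {}
        for c, v in rows:
            merged.setdefault(c, []).append(v)
        rows = [(c, float(np.mean(vs))) for c, vs in sorted(merged.items())]
    return rows
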