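"""Plain-text I/O: time-course TSV, the experiment-block dataset dialect,
and flat key=value model configuration files.

Dataset dialect (shared by the estimation and synthetic-data modules): one
block per experiment, blocks separated by blank lines.  Each block starts
with header lines carrying the initial conditions (dynamic species) and any
constant-concentration overrides, followed by a tab-separated table whose
first column is time in minutes and whose remaining columns are named
species concentrations in mM::

    # ic	GSH=1.0	MGO=1.0	HTA=0.0	SDLGS=0.0
    # const	E_GLOI=4e-07	E_GLOII=0.0
    time	SDLGS
    0.0	0.0
    10.0	0.0213
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import Dataset, Experiment
from .models import KineticModel, TimeCourse, TimeGrid, build_glyoxalase_model

__all__ = [
    "write_timecourse",
    "read_timecourse",
    "write_dataset",
    "read_dataset",
    "write_model_config",
    "read_model_config",
]


# ---------------------------------------------------------------------------
# Time-course TSV (simulate output)
# ---------------------------------------------------------------------------


def write_timecourse(path: str | Path, tc: TimeCourse) -> None:
    """Write a simulated time course as a TSV with a leading time column."""
    df = pd.DataFrame({"time": tc.grid.times})
    for i, s in enumerate(tc.species):
        df[s] = tc.values[i]
    df.to_csv(path, sep="\t", index=False)


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time course written by :func:`write_timecourse`.

    The time column must be equidistant.
    """
    df = pd.read_csv(path, sep="\t")
    t = df["time"].to_numpy(dtype=float)
    dts = np.diff(t)
    if len(t) < 2 or not np.allclose(dts, dts[0]):
        raise ValueError("time column is not an equidistant grid")
    grid = TimeGrid(float(t[0]), float(dts[0]), len(t))
    species = tuple(c for c in df.columns if c != "time")
    values = df[list(species)].to_numpy(dtype=float).T
    return TimeCourse(grid=grid, species=species, values=values)


# ---------------------------------------------------------------------------
# Experiment-block dataset dialect
# ---------------------------------------------------------------------------


def _format_map(m: Mapping[str, float]) -> str:
    return "\t".join(f"{k}={v!r}" for k, v in m.items())


def _parse_map(line: str) -> dict[str, float]:
    out = {}
    for tok in line.split("\t"):
        tok = tok.strip()
        if not tok:
            continue
        k, v = tok.split("=", 1)
        out[k.strip()] = float(v)
    return out


def write_dataset(path: str | Path, data: Dataset) -> None:
    """Write a dataset in the experiment-block TSV dialect."""
    blocks = []
    for exp in data:
        lines = [f"# ic\t{_format_map(exp.initial_conditions)}"]
        if exp.constants:
            lines.append(f"# const\t{_format_map(exp.constants)}")
        lines.append("\t".join(["time", *exp.observed]))
        for j, t in enumerate(exp.times):
            row = [repr(float(t))] + [repr(float(v)) for v in exp.values[:, j]]
            lines.append("\t".join(row))
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset written by :func:`write_dataset` (lossless round trip)."""
    text = Path(path).read_text()
    experiments = []
    for block in text.split("\n\n"):
        block = block.strip("\n")
        if not block.strip():
            continue
        ic: dict[str, float] = {}
        const: dict[str, float] = {}
        table_lines = []
        for line in block.splitlines():
            if line.startswith("# ic\t"):
                ic = _parse_map(line[len("# ic\t"):])
            elif line.startswith("# const\t"):
                const = _parse_map(line[len("# const\t"):])
            elif line.strip():
                table_lines.append(line)
        df = pd.read_csv(
            _io.StringIO("\n".join(table_lines)), sep="\t",
            float_precision="round_trip",
        )
        observed = tuple(c for c in df.columns if c != "time")
        experiments.append(
            Experiment(
                initial_conditions=ic,
                observed=observed,
                times=df["time"].to_numpy(dtype=float),
                values=df[list(observed)].to_numpy(dtype=float).T,
                constants=const,
            )
        )
    return Dataset(experiments)


# ---------------------------------------------------------------------------
# Model configuration (flat key=value INI)
# ---------------------------------------------------------------------------


def write_model_config(path: str | Path, model: KineticModel, variant: int | None = None) -> None:
    """Serialize a glyoxalase model to an INI config.

    Sections: ``[model]`` with ``name`` and (for the shipped glyoxalase
    builders) ``variant``; ``[parameters]`` with kinetic constants;
    ``[enzymes]`` with constant enzyme concentrations (mM).
    """
    cp = configparser.ConfigParser()
    cp["model"] = {"name": model.name}
    if variant is None and model.name.startswith("glyoxalase_model_"):
        variant = int(model.name.rsplit("_", 1)[1])
    if variant is not None:
        cp["model"]["variant"] = str(variant)
    cp["parameters"] = {k: repr(float(v)) for k, v in model.parameters.items()}
    cp["enzymes"] = {k: repr(float(v)) for k, v in model.constants.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def read_model_config(path: str | Path) -> KineticModel:
    """Rebuild a glyoxalase model from an INI config written by
    :func:`write_model_config`."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    variant = cp.getint("model", "variant")
    # configparser lower-cases keys; restore the canonical casing by matching
    # against the shipped parameter names for the variant.
    ref = build_glyoxalase_model(variant)
    canon_p = {k.lower(): k for k in ref.parameters}
    canon_e = {k.lower(): k for k in ref.constants}
    params = {canon_p[k]: float(v) for k, v in cp["parameters"].items()}
    enzymes = {canon_e[k]: float(v) for k, v in cp["enzymes"].items()}
    return build_glyoxalase_model(variant, params=params, enzymes=enzymes)
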