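"""Synthetic noisy time-course datasets for testing the full workflow.

The generator emulates the structure of the estimation data used for the
glyoxalase models: four glyoxalase-I-only time courses (no glyoxalase II,
varying substrate and enzyme levels, ~540 min span) and four
glyoxalase-II-only time courses (SDLGS hydrolysis at varying SDLGS and
enzyme levels), with SDLGS as the single observed species throughout.  The
initial conditions are chosen at the scale of standard glyoxalase assay
protocols (sub-mM substrates, sub-nM to nM enzyme given the ~1e4-1e5 min^-1
turnover numbers); they emulate, not replicate, the original assays.

Noise is additive Gaussian on the sampled concentrations, clipped at zero;
the default SD of 0.005 mM corresponds to ~0.014 absorbance units through
the 2.86 mM^-1 cm^-1 coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .estimation import Dataset, Experiment, predict
from .models import KineticModel, build_glyoxalase_model

__all__ = [
    "NoiseModel",
    "SyntheticSuite",
    "generate_experiment",
    "make_glyoxalase_suite",
    "DEFAULT_NOISE_SD",
]

DEFAULT_NOISE_SD = 0.005  # mM


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise, optionally clipped at zero."""

    sd: float = DEFAULT_NOISE_SD
    kind: str = "additive_gaussian"
    clip_at_zero: bool = True

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.kind != "additive_gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")


@dataclass
class SyntheticSuite:
    """A generated dataset plus the ground truth that produced it."""

    variant: int
    dataset: Dataset
    truth_parameters: dict[str, float]
    noise: NoiseModel
    seed: int | None

    def glyoxalase_i_data(self) -> Dataset:
        """The four glyoxalase-I-only experiments."""
        return Dataset(self.dataset.experiments[:4])

    def glyoxalase_ii_data(self) -> Dataset:
        """The four glyoxalase-II-only (SDLGS hydrolysis) experiments."""
        return Dataset(self.dataset.experiments[4:])


def generate_experiment(
    model: KineticModel,
    ic: Mapping[str, float],
    times: Sequence[float],
    noise: NoiseModel,
    rng: np.random.Generator | int | None = None,
    observed: Sequence[str] = ("SDLGS",),
    constants: Mapping[str, float] | None = None,
) -> Experiment:
    """Simulate, sample at ``times``, add noise, clip at zero.

    Deterministic for a fixed seed/generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    exp = Experiment(
        initial_conditions=dict(ic),
        observed=tuple(observed),
        times=np.asarray(times, dtype=float),
        values=np.zeros((len(observed), len(times))),
        constants=dict(constants or {}),
    )
    clean = predict(model, exp)
    noisy = clean + rng.normal(0.0, noise.sd, size=clean.shape) if noise.sd else clean
    if noise.clip_at_zero:
        noisy = np.clip(noisy, 0.0, None)
    return Experiment(
        initial_conditions=exp.initial_conditions,
        observed=exp.observed,
        times=exp.times,
        values=noisy,
        constants=exp.constants,
    )


#: Assay conditions of the glyoxalase-I suite: (GSH0, MGO0, E_GLOI) in mM.
#: Sub-nM enzyme keeps the ~540-min course enzyme-limited at these kcat.
_GLOI_CONDITIONS = (
    (1.0, 1.0, 4e-7),
    (0.5, 0.3, 8e-7),
    (0.3, 0.6, 2e-7),
    (0.15, 0.15, 8e-7),
)

#: Assay conditions of the glyoxalase-II suite: (SDLGS0, E_GLOII) in mM;
#: SDLGS levels straddle Km_SDLGS for identifiability.
_GLOII_CONDITIONS = (
    (0.5, 2e-4),
    (1.0, 1e-4),
    (3.0, 2e-4),
    (6.0, 4e-4),
)

_GLOI_TIMES = np.arange(0.0, 541.0, 10.0)   # min
_GLOII_TIMES = np.arange(0.0, 241.0, 5.0)   # min


def make_glyoxalase_suite(
    variant: int = 2,
    noise: NoiseModel | None = None,
    seed: int | None = 0,
) -> SyntheticSuite:
    """Generate the eight-experiment glyoxalase estimation suite.

    Experiments 1-4 contain only glyoxalase I (E_GLOII = 0) with varying
    substrate and enzyme levels over 0-540 min; experiments 5-8 contain only
    glyoxalase II hydrolysing SDLGS (no GSH/MGO dynamics).  SDLGS is the
    observed species everywhere, and the generating (truth) parameters are
    recorded for recovery tests.
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    model = build_glyoxalase_model(variant)
    experiments = []
    for gsh, mgo, e_gloi in _GLOI_CONDITIONS:
        experiments.append(
            generate_experiment(
                model,
                {"GSH": gsh, "MGO": mgo, "HTA": 0.0, "SDLGS": 0.0},
                _GLOI_TIMES,
                noise,
                rng,
                constants={"E_GLOI": e_gloi, "E_GLOII": 0.0},
            )
        )
    for sdlgs, e_gloii in _GLOII_CONDITIONS:
        experiments.append(
            generate_experiment(
                model,
                {"GSH": 0.0, "MGO": 0.0, "HTA": 0.0, "SDLGS": sdlgs},
                _GLOII_TIMES,
                noise,
                rng,
                constants={"E_GLOI": 0.0, "E_GLOII": e_gloii},
            )
        )
    return SyntheticSuite(
        variant=variant,
        dataset=Dataset(experiments),
        truth_parameters=dict(model.parameters),
        noise=noise,
        seed=seed,
    )
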