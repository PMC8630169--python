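"""Synthetic mediation panels for power and error studies.

Two families of study design are generated from the same linear structural
model, in the style of the classical single-mediator simulation literature:

    E          exposure (standard normal by default, or a balanced
               two-group indicator mirroring a randomized trial)
    M_g = a_g E + eps_g                      analyte g on the panel
    Y   = c' E + sum_g b_g M_g + eps_Y       clinical outcome

Path coefficients follow the standardized small/medium/large conventions
(0.14 / 0.39 / 0.59) with unit residual standard deviations, so a coefficient
is interpreted per standard deviation of the exposure.  Consistent mediators
carry b_g = +b, inconsistent mediators b_g = -b, exposure-only analytes have
a_g = a but b_g = 0, and null analytes have a_g = b_g = 0.  Analyte residuals
may be correlated through a block or low-rank factor structure (or any
user-supplied correlation root).

The generator is fully deterministic given (config, seed): the same config
regenerates a bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .mediation import Direction

__all__ = [
    "SimConfig",
    "SimDataset",
    "effect_size_preset",
    "make_correlation",
    "correlation_root",
    "simulate_dataset",
    "scenario_config",
    "single_panel_config",
    "PRESET_EFFECTS",
]

# standardized path-coefficient conventions for mediation simulations
PRESET_EFFECTS = {
    "zero": 0.0,
    "small": 0.14,
    "medium": 0.39,
    "large": 0.59,
}

TRUTH_LABELS = ("consistent-mediator", "inconsistent-mediator",
                "exposure-only", "null")


def effect_size_preset(name: str) -> tuple[float, float]:
    """Map a conventional effect-size name to the (a, b) path coefficients."""
    if name not in PRESET_EFFECTS:
        raise ValueError(
            f"unknown effect-size preset {name!r}; choose from "
            f"{sorted(PRESET_EFFECTS)}")
    v = PRESET_EFFECTS[name]
    return v, v


@dataclass
class SimConfig:
    """Full specification of one simulation scenario.

    Fields
    ------
    n, G : sample and analyte counts.
    a, b : exposure->mediator and mediator->outcome coefficients
        (standardized; unit residual SDs).
    c_prime : direct exposure->outcome effect.  Defaults to ``a`` so the
        total-effect direction is well defined even with no mediation.
    n_consistent, n_inconsistent, n_exposure_only : truth composition; the
        remainder of the panel is null.
    exposure_kind : 'standard-normal' (default; matches the standardized
        coefficient conventions) or 'binary-balanced' (0/1 arms of equal
        size, mirroring a randomized trial).
    corr : residual correlation spec for :func:`make_correlation`
        (None = independent).
    noise_sd : residual SD for analytes and outcome (default 1).
    seed : mandatory integer seed (or numpy SeedSequence).
    """

    n: int
    G: int = 1
    a: float = 0.39
    b: float = 0.39
    c_prime: float | None = None
    n_consistent: int = 1
    n_inconsistent: int = 0
    n_exposure_only: int = 0
    exposure_kind: str = "standard-normal"
    corr: object = None
    noise_sd: float = 1.0
    seed: object = None

    def __post_init__(self):
        if self.c_prime is None:
            self.c_prime = self.a
        n_labelled = self.n_consistent + self.n_inconsistent + self.n_exposure_only
        if n_labelled > self.G:
            raise ValueError(
                f"n_consistent + n_inconsistent + n_exposure_only = "
                f"{n_labelled} exceeds G = {self.G}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.exposure_kind not in ("standard-normal", "binary-balanced"):
            raise ValueError("exposure_kind must be 'standard-normal' or "
                             "'binary-balanced'")

    def to_json(self) -> str:
        d = asdict(self)
        if not isinstance(d["seed"], (int, type(None))):
            d["seed"] = None
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if isinstance(d.get("corr"), list):
            d["corr"] = tuple(d["corr"])
        return cls(**d)


@dataclass
class SimDataset:
    """Truth-annotated simulated dataset.

    analytes is the G x n log2-scale abundance matrix (DataFrame, analyte
    rows, sample columns); truth labels every analyte with one of
    consistent-mediator / inconsistent-mediator / exposure-only / null;
    direction carries the true sign of the exposure's total effect.
    """

    exposure: np.ndarray
    analytes: pd.DataFrame
    outcome: np.ndarray
    truth: pd.Series
    direction: Direction
    config: SimConfig = None

    def pheno(self) -> pd.DataFrame:
        """Phenotype table (sample id index, exposure + outcome columns)."""
        return pd.DataFrame(
            {"exposure": self.exposure, "outcome": self.outcome},
            index=self.analytes.columns)


def make_correlation(spec, G: int) -> np.ndarray | None:
    """Build a G x G correlation root L (so L @ z gives correlated noise,
    L L' the requested correlation).

    spec may be
      - None or 'independent': identity (returned as None for speed);
      - ('block', size, rho): contiguous equicorrelated blocks;
      - ('factor', k, loading): k latent factors with equal loadings,
        unit total variance per analyte;
      - an ndarray: a user-supplied root, validated for shape.
    """
    if spec is None or spec == "independent":
        return None
    if isinstance(spec, np.ndarray):
        if spec.shape[0] != G:
            raise ValueError(f"correlation root has {spec.shape[0]} rows, "
                             f"expected {G}")
        return spec
    kind = spec[0]
    if kind == "block":
        _, size, rho = spec
        if not -1 < rho < 1:
            raise ValueError("block correlation requires |rho| < 1")
        size = int(size)
        # equicorrelated block has Cholesky-compatible PSD iff rho > -1/(size-1)
        if size > 1 and rho <= -1.0 / (size - 1):
            raise ValueError("block correlation matrix is not positive definite")
        L = np.zeros((G, G))
        for start in range(0, G, size):
            stop = min(start + size, G)
            m = stop - start
            C = np.full((m, m), rho)
            np.fill_diagonal(C, 1.0)
            L[start:stop, start:stop] = np.linalg.cholesky(C)
        return L
    if kind == "factor":
        _, k, loading = spec
        k = int(k)
        if not 0 <= k * loading**2 < 1:
            raise ValueError("factor loadings imply non-PSD correlation "
                             "(need k * loading^2 < 1)")
        # root is G x (k + G): common factors then idiosyncratic noise
        Lf = np.full((G, k), loading)
        D = np.sqrt(1.0 - k * loading**2) * np.eye(G)
        return np.hstack([Lf, D])
    raise ValueError(f"unrecognized correlation spec: {spec!r}")


def _path_coefficients(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a_g = np.zeros(config.G)
    b_g = np.zeros(config.G)
    labels = np.full(config.G, "null", dtype=object)
    i = 0
    for count, label, a_val, b_val in [
        (config.n_consistent, "consistent-mediator", config.a, config.b),
        (config.n_inconsistent, "inconsistent-mediator", config.a, -config.b),
        (config.n_exposure_only, "exposure-only", config.a, 0.0),
    ]:
        a_g[i:i + count] = a_val
        b_g[i:i + count] = b_val
        labels[i:i + count] = label
        i += count
    return a_g, b_g, labels


def correlation_root(config: SimConfig) -> np.ndarray | None:
    """Correlation root for the non-mediator part of the panel.

    Dependence is modeled on the residuals of non-mediator analytes only:
    a true mediator's residual stays independent of the rest of the panel.
    If mediator residuals were correlated with other analytes, those
    neighbours would carry genuine conditional association with the outcome
    despite their non-mediator truth label, and a label-based false
    discovery rate would not be a meaningful target for any method.
    """
    n_med = config.n_consistent + config.n_inconsistent
    return make_correlation(config.corr, config.G - n_med)


def _draw(config: SimConfig, rng: np.random.Generator, L=None):
    """Array-level draw shared by :func:`simulate_dataset` and the
    Monte-Carlo study loop (which precomputes the correlation root L via
    :func:`correlation_root`)."""
    n, G = config.n, config.G
    if config.exposure_kind == "binary-balanced":
        E = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    else:
        E = rng.standard_normal(n)
    a_g, b_g, labels = _path_coefficients(config)
    n_med = config.n_consistent + config.n_inconsistent
    if L is None:
        eps = rng.standard_normal((G, n))
    else:
        eps = np.vstack([
            rng.standard_normal((n_med, n)),
            L @ rng.standard_normal((L.shape[1], n)),
        ])
    M = a_g[:, None] * E[None, :] + config.noise_sd * eps
    Y = (config.c_prime * E + b_g @ M
         + config.noise_sd * rng.standard_normal(n))
    total = config.c_prime + float(np.sum(a_g * b_g))
    sign = int(np.sign(total)) or 1
    return E, M, Y, labels, sign


def simulate_dataset(config: SimConfig, seed=None) -> SimDataset:
    """Draw one dataset from the structural model in the module docstring.

    ``seed`` overrides ``config.seed``; one of the two is required so every
    dataset is replayable.
    """
    seed = config.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required (in the config or as an argument)")
    rng = np.random.default_rng(seed)
    n, G = config.n, config.G
    E, M, Y, labels, sign = _draw(config, rng, correlation_root(config))
    direction = Direction(sign=sign, gate_mode="ignore")
    width = len(str(G))
    ids = [f"A{i + 1:0{width}d}" for i in range(G)]
    samples = [f"S{j + 1:03d}" for j in range(n)]
    analytes = pd.DataFrame(M, index=ids, columns=samples)
    truth = pd.Series(labels, index=ids, name="truth")
    return SimDataset(exposure=E, analytes=analytes, outcome=Y,
                      truth=truth, direction=direction, config=config)


def single_panel_config(effect: str, n: int, G: int = 500, seed=None) -> SimConfig:
    """Single-mediator panel: one consistent mediator plus G-1 null analytes
    (the nulls give the EB machinery a panel to shrink against)."""
    a, b = effect_size_preset(effect)
    return SimConfig(n=n, G=G, a=a, b=b, n_consistent=1,
                     n_inconsistent=0, n_exposure_only=0, seed=seed)


def scenario_config(scenario: int, n: int, n_mediators: int = 1,
                    effect: str = "medium", G: int = 500,
                    n_exposure_only: int = 200, seed=None) -> SimConfig:
    """Omics simulation scenarios.

    1: independent analytes, consistent mediators only;
    2: dependent analytes (block correlation stand-in), consistent mediators;
    3: dependent analytes, equal numbers of consistent and inconsistent
       mediators of equal effect.
    Each panel carries ``n_exposure_only`` analytes associated with the
    exposure but not the outcome; the remainder is null.
    """
    a, b = effect_size_preset(effect)
    corr = None if scenario == 1 else ("block", 10, 0.5)
    if scenario in (1, 2):
        n_cons, n_incons = n_mediators, 0
    elif scenario == 3:
        n_cons = n_incons = n_mediators
    else:
        raise ValueError("scenario must be 1, 2 or 3")
    return SimConfig(n=n, G=G, a=a, b=b, n_consistent=n_cons,
                     n_inconsistent=n_incons, n_exposure_only=n_exposure_only,
                     corr=corr, seed=seed)
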