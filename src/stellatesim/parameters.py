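"""Model parameter table, validation bounds, and the uniform parameter sampler.

The 55 parameters (conductances, gating half-voltages and slopes,
time-constant scale factors, passive and calcium-handling constants) ship as
a versioned YAML table together with their sampling ranges; the ten
validation bounds ship as a second YAML file. Code never hard-codes these
numbers elsewhere.

A parameter vector is represented as a ``pandas.Series`` indexed by parameter
name, which keeps named access, ordered 55-vector semantics, and cheap CSV
round-tripping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

N_PARAMETERS = 55
N_CRITERIA = 10

MEASUREMENT_NAMES = (
    "v_rmp", "v_sd", "sag", "r_in", "q_r", "f_r", "f_osc", "n100", "n400", "v_ap",
)


def _load_packaged_yaml(filename: str) -> dict:
    ref = importlib.resources.files("stellatesim.data").joinpath(filename)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ParameterSpace:
    """The per-parameter record of name, unit, base value and sampling range."""

    table: pd.DataFrame  # columns: unit, description, base, min, max; index: name

    def __post_init__(self):
        t = self.table
        if len(t) != N_PARAMETERS:
            raise ValueError(f"expected {N_PARAMETERS} parameters, got {len(t)}")
        if t.index.duplicated().any():
            raise ValueError("parameter names must be unique")
        bad = t[(t["min"] > t["base"]) | (t["base"] > t["max"])]
        if len(bad):
            raise ValueError(f"min <= base <= max violated for {list(bad.index)}")

    @property
    def names(self) -> list[str]:
        return list(self.table.index)

    @property
    def lower(self) -> pd.Series:
        return self.table["min"]

    @property
    def upper(self) -> pd.Series:
        return self.table["max"]

    def base_vector(self) -> pd.Series:
        """The hand-tuned base model: the 'base' column as a 55-vector."""
        return self.table["base"].copy()

    def unit(self, name: str) -> str:
        return str(self.table.loc[name, "unit"])


@dataclass(frozen=True)
class ValidationBounds:
    """Inclusive admissible interval per intrinsic measurement (None = open side)."""

    table: pd.DataFrame  # columns: unit, description, lower, upper; index: name

    def __post_init__(self):
        if len(self.table) != N_CRITERIA:
            raise ValueError(f"expected {N_CRITERIA} bounds, got {len(self.table)}")
        if list(self.table.index) != list(MEASUREMENT_NAMES):
            raise ValueError("bounds must cover the ten intrinsic measurements")
        for col in ("lower", "upper"):
            vals = self.table[col].dropna()
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValueError("bounds must be finite where given")

    def interval(self, name: str) -> tuple[float | None, float | None]:
        lo = self.table.loc[name, "lower"]
        hi = self.table.loc[name, "upper"]
        return (None if pd.isna(lo) else float(lo), None if pd.isna(hi) else float(hi))


def load_parameter_space() -> ParameterSpace:
    raw = _load_packaged_yaml("parameters.yaml")["parameters"]
    table = pd.DataFrame(raw).set_index("name")
    return ParameterSpace(table[["unit", "description", "base", "min", "max"]])


def load_validation_bounds() -> ValidationBounds:
    raw = _load_packaged_yaml("bounds.yaml")["bounds"]
    table = pd.DataFrame(raw).set_index("name")
    return ValidationBounds(table[["unit", "description", "lower", "upper"]])


def base_parameter_vector() -> pd.Series:
    """All 55 base-model parameter values, indexed by name."""
    return load_parameter_space().base_vector()


def model_rng(seed: int, model_id: int) -> np.random.Generator:
    """Independent substream for model ``model_id`` under a global ``seed``.

    Counter-based splitting via ``SeedSequence(seed, spawn_key=(model_id,))``:
    model k's stream is reproducible regardless of batch size or evaluation
    order, so interrupted searches can resume exactly.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(model_id,)))


def sample_parameters(
    space: ParameterSpace, rng: np.random.Generator
) -> pd.Series:
    """Draw one parameter vector, each coordinate uniform on its [min, max]."""
    lo = space.lower.to_numpy(dtype=float)
    hi = space.upper.to_numpy(dtype=float)
    vals = rng.uniform(lo, hi)
    return pd.Series(vals, index=space.names)


def sample_population(
    space: ParameterSpace, n: int, seed: int, start_id: int = 0
) -> pd.DataFrame:
    """Sample ``n`` parameter vectors on per-model substreams of ``seed``.

    Returns a DataFrame with one row per model, indexed by model id.
    """
    rows = []
    ids = range(start_id, start_id + n)
    for model_id in ids:
        rows.append(sample_parameters(space, model_rng(seed, model_id)))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="model_id"))
    if n == 0:
        df = pd.DataFrame(columns=space.names, index=pd.Index([], name="model_id"))
    return df
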