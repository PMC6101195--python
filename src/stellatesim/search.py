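"""Multiparametric multiobjective stochastic search (rejection sampling).

Parameter vectors are drawn uniformly within their tabulated ranges, each
candidate model is run through the measurement battery, and the ten
measurements are compared against the physiological validation bounds; a
model passing all ten criteria is valid. Per-model RNG substreams make the
search resumable and order-independent; failed simulations are recorded as
invalid rather than aborting the batch.

For throughput the battery short-circuits: protocols run cheapest-first
(rest, current steps, sag, V-I, chirp, and the 105-s oscillation scan last)
and stop at the first failed criterion, which cannot change any validity
decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stellatesim import measurements as meas
from stellatesim.parameters import (
    MEASUREMENT_NAMES,
    ParameterSpace,
    ValidationBounds,
    load_parameter_space,
    load_validation_bounds,
    model_rng,
    sample_parameters,
)
from stellatesim.simulator import (
    DEFAULT_DT,
    SETTLE_DURATION,
    ModelConfig,
    SimulationError,
    build_model,
    make_chirp,
    make_step,
    settle,
    simulate,
)

_MEAS_COLUMNS = list(MEASUREMENT_NAMES) + ["phi_l"]


@dataclass
class ValidityReport:
    """Pass/fail per criterion; overall validity iff all ten pass."""

    criteria: dict[str, bool]
    reasons: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return all(self.criteria.get(name, False) for name in MEASUREMENT_NAMES)

    def as_series(self) -> pd.Series:
        s = pd.Series({f"pass_{k}": bool(v) for k, v in self.criteria.items()})
        s["valid"] = self.valid
        s["reason"] = ";".join(self.reasons)
        return s


def _within(value: float, lo: float | None, hi: float | None) -> bool:
    if value is None or not np.isfinite(value):
        return False
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def validate(m: meas.MeasurementSet, bounds: ValidationBounds | None = None) -> ValidityReport:
    """Inclusive-bound comparison of the ten measurements; an absent (NaN)
    measurement fails its criterion."""
    bounds = bounds or load_validation_bounds()
    criteria = {}
    reasons = []
    values = m.as_series()
    for name in MEASUREMENT_NAMES:
        lo, hi = bounds.interval(name)
        ok = _within(values[name], lo, hi)
        criteria[name] = ok
        if not ok:
            reasons.append(f"{name}={values[name]:.4g} outside [{lo}, {hi}]")
    return ValidityReport(criteria, reasons)


@dataclass
class Population:
    """Sampled models with their measurements and validity reports."""

    params: pd.DataFrame  # one row per model, 55 columns, indexed by model id
    measurements: pd.DataFrame
    validity: pd.DataFrame  # pass_<criterion> booleans + valid + reason
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.params)

    @property
    def n_valid(self) -> int:
        return int(self.validity["valid"].sum()) if len(self.validity) else 0

    @property
    def valid_ids(self) -> pd.Index:
        return self.validity.index[self.validity["valid"]]

    def valid_params(self) -> pd.DataFrame:
        return self.params.loc[self.valid_ids]

    def valid_measurements(self) -> pd.DataFrame:
        return self.measurements.loc[self.valid_ids]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".h5":
            with pd.HDFStore(path, "w") as store:
                store.put("params", self.params)
                store.put("measurements", self.measurements)
                store.put("validity", self.validity)
                store.get_storer("params").attrs.meta = json.dumps(self.meta)
            return
        path.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(path / "params.csv")
        self.measurements.to_csv(path / "measurements.csv")
        self.validity.to_csv(path / "validity.csv")
        (path / "meta.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Population":
        path = Path(path)
        if path.suffix == ".h5":
            with pd.HDFStore(path, "r") as store:
                params = store["params"]
                measurements = store["measurements"]
                validity = store["validity"]
                meta = json.loads(store.get_storer("params").attrs.meta)
            return cls(params, measurements, validity, meta)
        read = lambda name: pd.read_csv(path / name, index_col=0)
        meta = json.loads((path / "meta.json").read_text())
        return cls(read("params.csv"), read("measurements.csv"),
                   read("validity.csv"), meta)


def evaluate_model(
    params: pd.Series,
    bounds: ValidationBounds | None = None,
    dt: float = DEFAULT_DT,
    short_circuit: bool = True,
    config: ModelConfig | None = None,
) -> tuple[meas.MeasurementSet, ValidityReport]:
    """Measure one candidate and validate it, optionally stopping at the
    first failed criterion (validity decisions are unaffected)."""
    bounds = bounds or load_validation_bounds()
    m = meas.MeasurementSet()

    def report() -> ValidityReport:
        return validate(m, bounds)

    def failed(*names: str) -> bool:
        rep = validate(m, bounds)
        return not all(rep.criteria[n] for n in names)

    try:
        model = build_model(params, config)
        rest_trace, state = settle(model, SETTLE_DURATION, dt)
        m.v_rmp, m.v_sd = meas.measure_rmp(
            rest_trace, (SETTLE_DURATION - 1000.0, SETTLE_DURATION)
        )
        if short_circuit and failed("v_rmp", "v_sd"):
            return m, report()

        tr100, _ = simulate(model, state, make_step(100.0, 0.0, 500.0, 500.0, dt))
        m.n100 = meas.count_spikes(tr100, 0.0, 500.0)
        tr400, _ = simulate(model, state, make_step(400.0, 0.0, 500.0, 500.0, dt))
        m.n400 = meas.count_spikes(tr400, 0.0, 500.0)
        if m.n400 > 0:
            m.v_ap = meas.measure_vap(tr400, m.v_rmp)
        if short_circuit and failed("n100", "n400", "v_ap"):
            return m, report()

        tr_sag, _ = simulate(model, state, make_step(-200.0, 100.0, 1000.0, 1200.0, dt))
        m.sag = meas.measure_sag(tr_sag, 100.0, 1000.0)
        if short_circuit and failed("sag"):
            return m, report()

        m.r_in, rin_spiked = meas.measure_rin(model, state, m.v_rmp, dt)
        if short_circuit and (rin_spiked or failed("r_in")):
            return m, report()

        tr_chirp, _ = simulate(model, state, make_chirp(dt=dt))
        if meas.count_spikes(tr_chirp) == 0:
            prof = meas.impedance_profile(tr_chirp)
            m.f_r, m.q_r = prof.resonance()
            m.phi_l = prof.inductive_phase()
        if short_circuit and failed("f_r", "q_r"):
            return m, report()

        m.mpo_table = meas.mpo_scan(model, state, dt)
        m.f_osc = meas.perithreshold_frequency(m.mpo_table)
        return m, report()
    except SimulationError as err:
        rep = report()
        rep.reasons.append(f"simulation-error: {err}")
        return m, rep


def _evaluate_one(model_id: int, seed: int, space: ParameterSpace,
                  bounds: ValidationBounds, dt: float, short_circuit: bool):
    p = sample_parameters(space, model_rng(seed, model_id))
    mset, rep = evaluate_model(p, bounds, dt, short_circuit)
    return model_id, p, mset.as_series()[_MEAS_COLUMNS], rep.as_series()


def run_search(
    n_models: int,
    seed: int,
    space: ParameterSpace | None = None,
    bounds: ValidationBounds | None = None,
    dt: float = DEFAULT_DT,
    short_circuit: bool = True,
    n_jobs: int = 1,
    resume: Population | None = None,
    progress: bool = False,
) -> Population:
    """Sample, measure and validate ``n_models`` candidates.

    Deterministic for fixed (seed, dt): model k is generated on substream k
    regardless of batch size, worker count or interruption. With ``resume``,
    models already present are not recomputed and the merged population is
    identical to an uninterrupted run.
    """
    if n_models < 0:
        raise ValueError("n_models must be non-negative")
    space = space or load_parameter_space()
    bounds = bounds or load_validation_bounds()
    done_ids = set(resume.params.index) if resume is not None else set()
    todo = [i for i in range(n_models) if i not in done_ids]

    if n_jobs != 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_one)(i, seed, space, bounds, dt, short_circuit)
            for i in todo
        )
    else:
        results = []
        iterator = todo
        if progress:
            try:
                from tqdm import tqdm

                iterator = tqdm(todo, desc="search")
            except ImportError:
                pass
        for i in iterator:
            results.append(_evaluate_one(i, seed, space, bounds, dt, short_circuit))

    results.sort(key=lambda r: r[0])
    ids = [r[0] for r in results]
    params = pd.DataFrame([r[1] for r in results],
                          index=pd.Index(ids, name="model_id"))
    measurements = pd.DataFrame([r[2] for r in results],
                                index=pd.Index(ids, name="model_id"))
    validity = pd.DataFrame([r[3] for r in results],
                            index=pd.Index(ids, name="model_id"))
    if n_models == 0:
        params = pd.DataFrame(columns=space.names)
        measurements = pd.DataFrame(columns=_MEAS_COLUMNS)
        validity = pd.DataFrame(
            columns=[f"pass_{n}" for n in MEASUREMENT_NAMES] + ["valid", "reason"]
        )
    pop = Population(
        params, measurements, validity,
        meta={"n_models": n_models, "seed": seed, "dt": dt,
              "short_circuit": short_circuit},
    )
    if resume is not None and len(resume):
        pop = Population(
            pd.concat([resume.params, params]).sort_index(),
            pd.concat([resume.measurements, measurements]).sort_index(),
            pd.concat([resume.validity, validity]).sort_index(),
            pop.meta,
        )
    return pop


def run_independent_sets(
    seeds: list[int],
    n_each: int,
    **kwargs,
) -> list[Population]:
    """Independent searches (one per seed) for cross-set statistics."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    return [run_search(n_each, seed, **kwargs) for seed in seeds]
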