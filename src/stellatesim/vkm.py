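"""Virtual knockout models: zero one channel per valid model, re-measure,
and quantify per-measurement sensitivity across the population.

A knockout sets exactly one maximal conductance to zero (for HCN, the slow
conductance, which carries the fast component through the fixed fast/slow
ratio). Knockouts that fire spontaneously at rest or enter
depolarization-induced block during the step protocols are excluded from
sensitivity statistics, since their full measurement set cannot be obtained.
Changes are percentages of the pre-knockout value except N100, reported as
an absolute count change (its baseline is 0 in every valid model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stellatesim import measurements as meas
from stellatesim.search import Population
from stellatesim.simulator import (
    DEFAULT_DT,
    SETTLE_DURATION,
    ModelConfig,
    SimulationError,
    build_model,
    make_step,
    settle,
    simulate,
)

KNOCKOUT_CHANNELS = ("NaF", "KDR", "HCN", "NaP", "KA", "LVA", "HVA", "KM", "SK")

_CHANNEL_TO_PARAM = {
    "NaF": "g_naf", "KDR": "g_kdr", "HCN": "g_hcn", "NaP": "g_nap",
    "KA": "g_ka", "LVA": "g_lva", "HVA": "g_hva", "KM": "g_km", "SK": "g_sk",
}

PERCENT_MEASUREMENTS = ("v_rmp", "sag", "r_in", "q_r", "f_r", "f_osc",
                        "n400", "v_ap")
COUNT_MEASUREMENTS = ("n100",)

DEPOL_BLOCK_LEVEL = -20.0  # mV
DEPOL_BLOCK_MIN_MS = 100.0  # contiguous time above level without spiking


@dataclass
class KnockoutResult:
    model_id: int
    channel: str
    excluded: str | None  # "spontaneous-firing" | "depolarization-block" | None
    changes: dict[str, float] = field(default_factory=dict)
    mpo_lost: bool | None = None  # perithreshold oscillations absent post-KO

    def as_series(self) -> pd.Series:
        s = pd.Series(self.changes, dtype=float)
        s["model_id"] = self.model_id
        s["channel"] = self.channel
        s["excluded"] = self.excluded or ""
        s["mpo_lost"] = self.mpo_lost
        return s


def knockout(params: pd.Series, channel: str) -> pd.Series:
    """Copy of ``params`` with the named channel's conductance set to zero."""
    if channel not in _CHANNEL_TO_PARAM:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {KNOCKOUT_CHANNELS}"
        )
    out = params.copy()
    out[_CHANNEL_TO_PARAM[channel]] = 0.0
    return out


def detect_depolarization_block(trace, window: tuple[float, float]) -> bool:
    """Sustained depolarized plateau: a contiguous stretch above -20 mV
    longer than 100 ms within the stimulus window (a spike spends ~1-2 ms
    there, so trains never trigger this)."""
    sel = (trace.t > window[0]) & (trace.t <= window[1])
    above = trace.v[sel] > DEPOL_BLOCK_LEVEL
    if not above.any():
        return False
    # longest run of True
    changes = np.diff(above.astype(int))
    starts = np.flatnonzero(changes == 1) + 1
    ends = np.flatnonzero(changes == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    longest = (ends - starts).max() * trace.dt
    return bool(longest > DEPOL_BLOCK_MIN_MS)


def screen_exclusions(model, dt: float = DEFAULT_DT):
    """Exclusion screen for a knockout model: spontaneous firing during the
    6-s zero-current settle, or depolarization block in the 100/400-pA steps.

    Returns (exclusion reason or None, settled (trace, state) or None).
    """
    try:
        rest_trace, state = settle(model, SETTLE_DURATION, dt)
    except SimulationError:
        return "depolarization-block", None
    # ignore the first second: the synthetic initial condition (gates
    # equilibrated at the passive rest) can produce an onset transient with
    # a spike or two even in perfectly quiescent models
    if meas.count_spikes(rest_trace, t0=1000.0) > 0:
        return "spontaneous-firing", None
    for amp in (100.0, 400.0):
        try:
            tr, _ = simulate(model, state, make_step(amp, 0.0, 500.0, 500.0, dt))
        except SimulationError:
            return "depolarization-block", None
        if detect_depolarization_block(tr, (0.0, 500.0)):
            return "depolarization-block", None
    return None, (rest_trace, state)


def knockout_changes(
    baseline: pd.Series, post: pd.Series
) -> tuple[dict[str, float], bool]:
    """Per-measurement change: percent of baseline, or count change for N100.

    Measurements undefined after knockout (NaN, e.g. V_AP when no spike is
    fired) stay NaN. Returns (changes, mpo_lost flag).
    """
    changes: dict[str, float] = {}
    for name in PERCENT_MEASUREMENTS:
        pre, after = baseline.get(name, np.nan), post.get(name, np.nan)
        if not np.isfinite(after) or not np.isfinite(pre) or pre == 0:
            changes[name] = np.nan
        else:
            changes[name] = 100.0 * (after - pre) / pre
    for name in COUNT_MEASUREMENTS:
        pre, after = baseline.get(name, np.nan), post.get(name, np.nan)
        changes[name] = (after - pre) if np.isfinite(after) and np.isfinite(pre) else np.nan
    # absolute RMP shift in mV: percent of a negative baseline inverts sign,
    # so directionality is read from this column
    changes["d_v_rmp"] = float(post.get("v_rmp", np.nan) - baseline.get("v_rmp", np.nan))
    mpo_lost = not np.isfinite(post.get("f_osc", np.nan))
    return changes, mpo_lost


ALL_STAGES = ("rest", "steps", "sag", "rin", "chirp", "mpo")


def knockout_model(
    params: pd.Series,
    channel: str,
    baseline: pd.Series,
    model_id: int = -1,
    dt: float = DEFAULT_DT,
    config: ModelConfig | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> KnockoutResult:
    """Knock one channel out of one model and measure the changes.

    ``stages`` restricts which protocols are re-run post-knockout (the
    exclusion screen always runs); unmeasured changes stay NaN.
    """
    ko_params = knockout(params, channel)
    model = build_model(ko_params, config)
    excluded, settled = screen_exclusions(model, dt)
    if excluded is not None:
        return KnockoutResult(model_id, channel, excluded)
    mset = meas.measure_all(model, dt=dt, stages=stages, settled=settled)
    changes, mpo_lost = knockout_changes(baseline, mset.as_series())
    if "mpo" not in stages:
        mpo_lost = None
    return KnockoutResult(model_id, channel, None, changes, mpo_lost)


def screen(
    pop: Population,
    channel: str,
    dt: float = DEFAULT_DT,
    model_ids=None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> pd.DataFrame:
    """Knockout screen of one channel over the valid models of a population.

    Returns a long-format frame with one row per model: measurement changes,
    exclusion flags, and whether perithreshold oscillations were lost.
    """
    ids = list(pop.valid_ids if model_ids is None else model_ids)
    rows = []
    for mid in ids:
        res = knockout_model(
            pop.params.loc[mid], channel, pop.measurements.loc[mid], mid, dt,
            stages=stages,
        )
        rows.append(res.as_series())
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("model_id")
    return df


def test_changes(
    results: pd.DataFrame | pd.Series,
    measurement: str | None = None,
    min_n: int = 6,
    rank_sum_vs_zero: bool = False,
) -> float:
    """Two-sided test of knockout-induced changes against "no change".

    Default: one-sample Wilcoxon signed-rank test of the changes against 0
    (the coherent reading of a comparison to a no-change scenario); with
    ``rank_sum_vs_zero`` the changes are rank-sum-tested against an equal-
    size zero vector instead. Excluded models (NaN changes) are dropped.
    """
    if isinstance(results, pd.DataFrame):
        if measurement is None:
            raise ValueError("measurement required with a results frame")
        sub = results[results["excluded"] == ""] if "excluded" in results else results
        values = sub[measurement].astype(float)
    else:
        values = results.astype(float)
    values = values.dropna().to_numpy()
    if len(values) < min_n:
        raise ValueError(f"need at least {min_n} non-excluded results, got {len(values)}")
    if np.all(values == 0):
        return 1.0
    if rank_sum_vs_zero:
        _, p = stats.mannwhitneyu(values, np.zeros_like(values),
                                  alternative="two-sided")
        return float(p)
    _, p = stats.wilcoxon(values, alternative="two-sided")
    return float(p)
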