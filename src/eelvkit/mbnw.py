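"""End-expiratory lung volume by multiple-breaths nitrogen washin-washout.

The maneuver steps FiO2 by ~10%, holds until a new steady state, then steps
back. Between two steady states the nitrogen store of the ventilated lung
changes by ``EELV * dFN2``, and all of that nitrogen crosses the airway
opening, so

    EELV = cumulative net N2 volume / dFN2

with dFN2 the end-tidal nitrogen-fraction difference between the steady
states. The washout (FiO2 up) and washin (FiO2 back down) estimates are
averaged and the instrumental dead space (apparatus gas between the sensor
and the tube tip, which washes out along with the lung) is subtracted.

The estimate measures the lung volume that participates in gas mixing:
unventilated (e.g., overinflated) regions do not wash out and bias the
estimate low relative to an anatomical (CT) reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breaths import breath_table, segment_breaths
from .errors import (
    DegenerateManeuverError,
    EstimationFailedError,
    ManeuverIncompleteError,
)
from .simkit import GasWaveform

__all__ = [
    "ManeuverPhases",
    "MBNWResult",
    "detect_phases",
    "estimate_eelv",
    "estimate_from_waveform",
    "replicate_maneuver",
    "K_SS",
    "EPS_SS",
    "EPS_FN2",
    "TAU_STAB",
]

K_SS = 5          # breaths in a steady-state window
EPS_SS = 0.001    # max rolling-mean end-tidal FN2 change per breath at steady state
EPS_FN2 = 0.02    # minimum usable dFN2 (a 10% FiO2 step gives ~0.10)
TAU_STAB = 0.10   # max relative VO2/VCO2 drift for the stability flag
_STEP_FIO2 = 0.02  # minimum between-breath inspired-O2 jump read as an FiO2 step


@dataclass(frozen=True)
class ManeuverPhases:
    """Breath-index ranges (half-open) of one washin-washout maneuver.

    Three steady-state windows (baseline, post-step, post-return) and the
    two transition ranges between them.
    """

    baseline_window: tuple[int, int]
    post_step_window: tuple[int, int]
    post_return_window: tuple[int, int]
    washout_range: tuple[int, int]
    washin_range: tuple[int, int]


@dataclass(frozen=True)
class MBNWResult:
    """Per-maneuver EELV estimates and diagnostics (volumes in mL)."""

    eelv_washout_ml: float
    eelv_washin_ml: float
    eelv_ml: float
    cum_n2_out_ml: float
    cum_n2_in_ml: float
    delta_fn2: float
    vd_instr_ml: float
    vo2_stability: float
    vco2_stability: float
    stable: bool


def _steady_window(et_fn2: np.ndarray, start: int, stop: int, k_ss: int,
                   eps_ss: float, label: str) -> tuple[int, int]:
    """Last ``k_ss`` breaths of a plateau, verified against the steady criterion.

    The plateau [start, stop) is steady when the rolling mean of end-tidal
    FN2 over ``k_ss`` breaths changes by < ``eps_ss`` between consecutive
    breaths across the window.
    """
    if stop - start < 2 * k_ss:
        raise ManeuverIncompleteError(
            f"plateau '{label}' has {stop - start} breaths; need >= {2 * k_ss}"
        )
    window = (stop - k_ss, stop)
    roll = np.convolve(et_fn2[start:stop], np.ones(k_ss) / k_ss, mode="valid")
    tail = np.abs(np.diff(roll))[-(k_ss + 1):]
    if tail.size == 0 or np.any(tail >= eps_ss):
        raise ManeuverIncompleteError(
            f"steady state never reached on plateau '{label}'"
        )
    return window


def detect_phases(
    table: pd.DataFrame,
    k_ss: int = K_SS,
    eps_ss: float = EPS_SS,
) -> ManeuverPhases:
    """Classify breaths of a single maneuver into steady states and transitions.

    FiO2 steps are inferred from jumps in the per-breath mean inspired O2
    fraction; exactly two steps (up then back) are required. Steady-state
    windows are the last ``k_ss`` breaths of each plateau and must satisfy
    the rolling-mean criterion, otherwise a maneuver-incomplete error names
    the failing plateau.
    """
    fi = table["fi_o2"].to_numpy()
    et = table["et_fn2"].to_numpy()
    steps = np.flatnonzero(np.abs(np.diff(fi)) > _STEP_FIO2) + 1
    if steps.size < 2:
        raise ManeuverIncompleteError(
            f"found {steps.size} FiO2 step(s); a maneuver needs 2 (up and back)"
        )
    if steps.size > 2:
        raise ManeuverIncompleteError(
            f"found {steps.size} FiO2 steps; use replicate_maneuver for multiples"
        )
    s1, s2 = int(steps[0]), int(steps[1])
    n = len(table)
    baseline = _steady_window(et, 0, s1, k_ss, eps_ss, "baseline")
    post_step = _steady_window(et, s1, s2, k_ss, eps_ss, "post-step")
    post_return = _steady_window(et, s2, n, k_ss, eps_ss, "post-return")
    return ManeuverPhases(
        baseline_window=baseline,
        post_step_window=post_step,
        post_return_window=post_return,
        washout_range=(s1, s2),
        washin_range=(s2, n),
    )


def _phase_estimate(net_out: np.ndarray, baseline_window: tuple[int, int],
                    rng: tuple[int, int], sign: float) -> float:
    """Baseline-corrected cumulative N2 volume over one transition (mL).

    ``sign`` +1 integrates net export (washout), -1 net uptake (washin).
    The sum runs over the full plateau following the step so the slow tail
    of the exponential approach is captured; breaths at steady state
    contribute ~0 after baseline subtraction.
    """
    baseline = float(np.mean(net_out[slice(*baseline_window)]))
    return float(np.sum(sign * (net_out[slice(*rng)] - baseline)))


def estimate_eelv(
    table: pd.DataFrame,
    phases: ManeuverPhases,
    vd_instr_ml: float = 0.0,
    eps_fn2: float = EPS_FN2,
    tau_stab: float = TAU_STAB,
) -> MBNWResult:
    """Cumulative-nitrogen-balance EELV estimate for one maneuver.

    Washout: cumulative (net N2 export - baseline flux) divided by the
    end-tidal FN2 drop between the baseline and post-step steady states.
    Washin is symmetric with signs flipped; the two are averaged and
    ``vd_instr_ml`` subtracted. VO2/VCO2 stability between the baseline and
    final steady states is reported and flagged against ``tau_stab``.
    """
    net_out = table["n2_net_out_ml"].to_numpy()
    et = table["et_fn2"].to_numpy()

    fn2_base = float(np.mean(et[slice(*phases.baseline_window)]))
    fn2_step = float(np.mean(et[slice(*phases.post_step_window)]))
    fn2_ret = float(np.mean(et[slice(*phases.post_return_window)]))

    delta_out = fn2_base - fn2_step
    delta_in = fn2_ret - fn2_step
    delta_fn2 = 0.5 * (delta_out + delta_in)
    if delta_out <= eps_fn2 or delta_in <= eps_fn2:
        raise DegenerateManeuverError(
            f"end-tidal FN2 change too small (washout {delta_out:.4f}, "
            f"washin {delta_in:.4f}; need > {eps_fn2})"
        )

    cum_out = _phase_estimate(net_out, phases.baseline_window,
                              phases.washout_range, +1.0)
    cum_in = _phase_estimate(net_out, phases.post_step_window,
                             phases.washin_range, -1.0)
    eelv_washout = cum_out / delta_out - vd_instr_ml
    eelv_washin = cum_in / delta_in - vd_instr_ml
    eelv = 0.5 * (eelv_washout + eelv_washin)

    def _rel_change(col: str) -> float:
        a = float(np.mean(table[col].to_numpy()[slice(*phases.baseline_window)]))
        b = float(np.mean(table[col].to_numpy()[slice(*phases.post_return_window)]))
        return abs(b - a) / abs(a) if a != 0 else np.inf

    vo2_stab = _rel_change("vo2_ml")
    vco2_stab = _rel_change("vco2_ml")

    if eelv <= 0:
        raise EstimationFailedError(
            "EELV non-positive after dead-space subtraction",
            diagnostics={
                "cum_n2_out_ml": cum_out,
                "cum_n2_in_ml": cum_in,
                "delta_fn2": delta_fn2,
                "vd_instr_ml": vd_instr_ml,
            },
        )
    return MBNWResult(
        eelv_washout_ml=eelv_washout,
        eelv_washin_ml=eelv_washin,
        eelv_ml=eelv,
        cum_n2_out_ml=cum_out,
        cum_n2_in_ml=cum_in,
        delta_fn2=delta_fn2,
        vd_instr_ml=vd_instr_ml,
        vo2_stability=vo2_stab,
        vco2_stability=vco2_stab,
        stable=bool(vo2_stab <= tau_stab and vco2_stab <= tau_stab),
    )


def estimate_from_waveform(
    w: GasWaveform, vd_instr_ml: float = 0.0, **kwargs
) -> MBNWResult:
    """Convenience pipeline: segment breaths, detect phases, estimate EELV."""
    table = breath_table(w, segment_breaths(w))
    phases = detect_phases(table)
    return estimate_eelv(table, phases, vd_instr_ml=vd_instr_ml, **kwargs)


def replicate_maneuver(
    w: GasWaveform, vd_instr_ml: float = 0.0, **kwargs
) -> tuple[MBNWResult, MBNWResult]:
    """Estimate EELV independently for two back-to-back maneuvers.

    The waveform must contain four FiO2 steps (up/back, up/back); the
    plateau between the maneuvers serves as both the post-return steady
    state of the first and the baseline of the second.
    """
    table = breath_table(w, segment_breaths(w))
    fi = table["fi_o2"].to_numpy()
    steps = np.flatnonzero(np.abs(np.diff(fi)) > _STEP_FIO2) + 1
    if steps.size < 4:
        raise ManeuverIncompleteError(
            f"found {steps.size} FiO2 steps; two maneuvers need 4"
        )
    split = int(steps[1]) + (int(steps[2]) - int(steps[1])) // 2
    results = []
    for sub in (table.iloc[:split], table.iloc[split:]):
        sub = sub.reset_index(drop=True)
        phases = detect_phases(sub)
        results.append(estimate_eelv(sub, phases, vd_instr_ml=vd_instr_ml, **kwargs))
    return results[0], results[1]
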