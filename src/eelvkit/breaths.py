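"""Breath segmentation and breath-by-breath volumetric gas exchange.

Breaths are delimited by flow zero-crossings with hysteresis; per breath the
inspired/expired volumes of O2, CO2 and N2 are obtained by trapezoidal
integration of the flow x fraction product, with the nitrogen fraction taken
as ``1 - f_o2 - f_co2`` sample by sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .simkit import GasWaveform

__all__ = [
    "BreathSegment",
    "BreathGasVolumes",
    "segment_breaths",
    "breath_gas_volumes",
    "breath_table",
    "DEFAULT_MIN_VT_ML",
]

DEFAULT_MIN_VT_ML = 10.0  # rejects noise artifacts at pig/human scale
HYSTERESIS_FRAC = 0.02  # of the 95th-percentile flow magnitude


@dataclass(frozen=True)
class BreathSegment:
    """One breath as a half-open sample interval [i_start, i_end).

    ``i_start`` is the first inspiratory sample, ``i_exp_start`` the first
    expiratory sample.
    """

    i_start: int
    i_exp_start: int
    i_end: int
    vt_insp_ml: float
    vt_exp_ml: float


@dataclass(frozen=True)
class BreathGasVolumes:
    """Per-breath inspired/expired volumes of each gas species (mL)."""

    v_o2_in: float
    v_o2_out: float
    v_co2_in: float
    v_co2_out: float
    v_n2_in: float
    v_n2_out: float

    @property
    def vo2(self) -> float:
        return self.v_o2_in - self.v_o2_out

    @property
    def vco2(self) -> float:
        return self.v_co2_out - self.v_co2_in

    @property
    def n2_net_out(self) -> float:
        return self.v_n2_out - self.v_n2_in


def _signed_trapz(y: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(y, dx=dt))


def segment_breaths(
    w: GasWaveform, min_vt_ml: float = DEFAULT_MIN_VT_ML
) -> list[BreathSegment]:
    """Split a waveform into complete breaths.

    A breath starts when flow rises above the hysteresis threshold
    (+2% of the 95th-percentile flow magnitude), switches to expiration when
    flow falls below the negative threshold, and ends at the next
    inspiration onset. Candidate breaths with an inspired volume below
    ``min_vt_ml`` are discarded. Incomplete leading/trailing breaths are
    dropped; an empty list is returned when no complete breath exists.
    """
    flow = np.asarray(w.flow_mls, dtype=float)
    if flow.size == 0:
        return []
    if not np.all(np.isfinite(flow)):
        raise DataError("non-finite flow samples")
    thr = HYSTERESIS_FRAC * np.percentile(np.abs(flow), 95)
    if thr == 0.0:
        return []  # flat (e.g., all-zero) flow: no breaths
    dt = 1.0 / w.sample_rate_hz

    insp_on = flow > thr
    exp_on = flow < -thr
    # phase state machine: 0 unknown, 1 inspiration, -1 expiration
    starts: list[int] = []
    exp_starts: list[int] = []
    phase = 0
    for i in range(flow.size):
        if insp_on[i] and phase != 1:
            phase = 1
            starts.append(i)
        elif exp_on[i] and phase == 1:
            phase = -1
            exp_starts.append(i)

    segments: list[BreathSegment] = []
    for k, i_start in enumerate(starts):
        i_end = starts[k + 1] if k + 1 < len(starts) else None
        if i_end is None:
            break  # trailing incomplete breath
        i_exp = next((j for j in exp_starts if i_start < j < i_end), None)
        if i_exp is None:
            continue
        pos = np.clip(flow[i_start:i_end], 0.0, None)
        neg = np.clip(-flow[i_start:i_end], 0.0, None)
        vt_insp = _signed_trapz(pos, dt)
        vt_exp = _signed_trapz(neg, dt)
        if vt_insp < min_vt_ml or vt_exp <= 0.0:
            continue
        segments.append(BreathSegment(i_start, i_exp, i_end, vt_insp, vt_exp))
    return segments


def breath_gas_volumes(w: GasWaveform, seg: BreathSegment) -> BreathGasVolumes:
    """Integrate flow x fraction over one breath for O2, CO2 and N2.

    Inspired volumes integrate over samples with positive flow, expired over
    negative flow (magnitude); by construction of ``f_n2`` the three species
    sum exactly to the tidal volumes.
    """
    if not (0 <= seg.i_start < seg.i_end <= w.n_samples):
        raise IndexError("segment indices out of waveform bounds")
    sl = slice(seg.i_start, seg.i_end)
    flow = np.asarray(w.flow_mls[sl], dtype=float)
    fo2 = np.asarray(w.f_o2[sl], dtype=float)
    fco2 = np.asarray(w.f_co2[sl], dtype=float)
    if not (np.all(np.isfinite(fo2)) and np.all(np.isfinite(fco2))):
        raise DataError("non-finite gas-fraction samples")
    fn2 = 1.0 - fo2 - fco2
    dt = 1.0 / w.sample_rate_hz
    pos = np.clip(flow, 0.0, None)
    neg = np.clip(-flow, 0.0, None)
    return BreathGasVolumes(
        v_o2_in=_signed_trapz(pos * fo2, dt),
        v_o2_out=_signed_trapz(neg * fo2, dt),
        v_co2_in=_signed_trapz(pos * fco2, dt),
        v_co2_out=_signed_trapz(neg * fco2, dt),
        v_n2_in=_signed_trapz(pos * fn2, dt),
        v_n2_out=_signed_trapz(neg * fn2, dt),
    )


def breath_table(
    w: GasWaveform, segments: list[BreathSegment] | None = None,
    min_vt_ml: float = DEFAULT_MIN_VT_ML,
) -> pd.DataFrame:
    """Per-breath summary table feeding the EELV estimator.

    Columns: start time, tidal volumes, per-species volumes, net exchange,
    volume-weighted mean inspired O2 fraction (``fi_o2``) and end-tidal
    nitrogen fraction (``et_fn2``, averaged over the final quarter of the
    expiration — the alveolar plateau — for noise robustness).
    """
    if segments is None:
        segments = segment_breaths(w, min_vt_ml=min_vt_ml)
    rows = []
    fn2 = w.f_n2
    for seg in segments:
        n_tail = max(1, (seg.i_end - seg.i_exp_start) // 4)
        g = breath_gas_volumes(w, seg)
        rows.append(
            {
                "t_start_s": seg.i_start / w.sample_rate_hz,
                "vt_insp_ml": seg.vt_insp_ml,
                "vt_exp_ml": seg.vt_exp_ml,
                "v_o2_in": g.v_o2_in,
                "v_o2_out": g.v_o2_out,
                "v_co2_in": g.v_co2_in,
                "v_co2_out": g.v_co2_out,
                "v_n2_in": g.v_n2_in,
                "v_n2_out": g.v_n2_out,
                "vo2_ml": g.vo2,
                "vco2_ml": g.vco2,
                "n2_net_out_ml": g.n2_net_out,
                "fi_o2": g.v_o2_in / seg.vt_insp_ml,
                "et_fn2": float(np.mean(fn2[seg.i_end - n_tail : seg.i_end])),
            }
        )
    return pd.DataFrame(rows)
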