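"""Synthetic ground-truth generators.

Three generators cover the three kinds of input the package analyses:

* :func:`simulate_maneuver` — respiratory waveforms (flow, airway pressure,
  O2/CO2 fractions at the airway opening) during an FiO2-step nitrogen
  washin-washout maneuver, from a single perfectly mixed alveolar compartment
  with a series dead-space plug and an optional unventilated gas pocket.
* :func:`generate_phantom` — CT phantoms (HU grid + lung mask) with exactly
  known per-compartment gas and tissue volumes.
* :func:`generate_paired_series` / :func:`generate_replicates` — per-subject
  paired method-comparison tables with a configurable linear bias structure.

Every generator records its exact ground truth so downstream estimators can
be validated without experimental data.

Model sketch
------------
At end-expiration the gas distal to the gas sensor is: a mixing (alveolar)
volume ``V_mix = eelv_ml - unventilated_ml - vd_airway_ml``, the anatomical
airway dead space ``vd_airway_ml``, the instrumental dead space
``vd_instr_ml`` (apparatus between sensor and tube tip), and the
unventilated pocket. Dead space is a plug: during inspiration its content
(previously expired alveolar gas) is pushed back into the alveoli ahead of
``vt_ml - vd`` of fresh gas; during expiration the sensor first sees the
fresh gas that filled the plug, then the alveolar plateau. Per breath the
alveolar compartment mixes perfectly, loses ``vo2`` and gains ``vco2``.
Nitrogen is conserved, so between two steady states the net N2 volume
crossing the sensor equals ``(V_mix + vd) * dFN2`` — the basis of the
washout EELV estimate, which therefore sees ``eelv - unventilated +
vd_instr`` and recovers the ventilated EELV after instrumental dead-space
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "LungConfig",
    "GasWaveform",
    "SimTruth",
    "PhantomConfig",
    "simulate_maneuver",
    "generate_phantom",
    "generate_paired_series",
    "generate_replicates",
    "default_fio2_schedule",
]


def default_fio2_schedule(
    fio2_base: float = 0.5,
    fio2_step: float = 0.1,
    t_baseline_s: float = 60.0,
    t_hold_s: float = 120.0,
) -> list[tuple[float, float]]:
    """Washout-then-washin FiO2 schedule: step up by ``fio2_step``, hold, step back, hold."""
    return [
        (0.0, fio2_base),
        (t_baseline_s, fio2_base + fio2_step),
        (t_baseline_s + t_hold_s, fio2_base),
        (t_baseline_s + 2.0 * t_hold_s, fio2_base),
    ]


@dataclass
class LungConfig:
    """Ground-truth lung and maneuver parameters.

    Parameters
    ----------
    eelv_ml : float
        True end-expiratory gas volume (mL), inclusive of airway gas and any
        unventilated pocket.
    unventilated_ml : float
        Gas volume excluded from ventilation/mixing (mL). Part of
        ``eelv_ml``; models overinflated regions that do not take part in
        nitrogen mixing.
    vt_ml : float
        Tidal volume (mL).
    vd_airway_ml : float
        Anatomical series dead space (mL), part of ``eelv_ml``.
    vd_instr_ml : float
        Instrumental dead space between the gas sensor and the tracheal tube
        tip (mL); apparatus volume, *not* part of ``eelv_ml``.
    rr_min : float
        Respiratory rate (breaths/min).
    fio2_schedule : sequence of (time_s, fio2)
        Ordered FiO2 step schedule; the last entry marks the end of the run.
    vo2_mlmin, vco2_mlmin : float
        O2 consumption and CO2 production (mL/min), applied per breath.
    sample_rate_hz : float
        Waveform sample rate (Hz); 100 Hz mirrors mainstream gas sensors.
    noise_sd_frac : float
        SD of i.i.d. Gaussian noise added to the gas-fraction signals.
    noise_sd_flow : float
        SD of i.i.d. Gaussian noise added to flow (mL/s).
    peep_cmh2o, pplat_cmh2o : float
        Airway-pressure plateau levels used to draw the pressure trace
        (cosmetic; the gas model is pressure-independent).
    seed : int
        RNG seed for the noise.
    """

    eelv_ml: float = 500.0
    unventilated_ml: float = 0.0
    vt_ml: float = 180.0
    vd_airway_ml: float = 30.0
    vd_instr_ml: float = 0.0
    rr_min: float = 25.0
    fio2_schedule: Sequence[tuple[float, float]] = field(
        default_factory=default_fio2_schedule
    )
    vo2_mlmin: float = 100.0
    vco2_mlmin: float = 85.0
    sample_rate_hz: float = 100.0
    noise_sd_frac: float = 0.0
    noise_sd_flow: float = 0.0
    peep_cmh2o: float = 5.0
    pplat_cmh2o: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if not self.eelv_ml > self.unventilated_ml >= 0.0:
            raise InvalidConfigError("need eelv_ml > unventilated_ml >= 0")
        if min(self.vt_ml, self.rr_min, self.sample_rate_hz) <= 0:
            raise InvalidConfigError("vt_ml, rr_min and sample_rate_hz must be > 0")
        if self.vd_airway_ml < 0 or self.vd_instr_ml < 0:
            raise InvalidConfigError("dead spaces must be >= 0")
        if self.vt_ml <= self.vd_airway_ml + self.vd_instr_ml:
            raise InvalidConfigError("vt_ml must exceed total series dead space")
        sched = list(self.fio2_schedule)
        if len(sched) < 2:
            raise InvalidConfigError("fio2_schedule needs at least start and end times")
        times = [t for t, _ in sched]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidConfigError("fio2_schedule times must be strictly increasing")
        if any(not 0.0 < f < 1.0 for _, f in sched):
            raise InvalidConfigError("FiO2 values must lie in (0, 1)")
        if times[-1] - times[0] < 60.0 / self.rr_min:
            raise InvalidConfigError("schedule shorter than one breath")
        if self.mixing_volume_ml <= 0:
            raise InvalidConfigError(
                "eelv_ml - unventilated_ml - vd_airway_ml must be > 0"
            )
        if self.vo2_mlmin < 0 or self.vco2_mlmin < 0:
            raise InvalidConfigError("metabolic rates must be >= 0")

    @property
    def ventilated_eelv_ml(self) -> float:
        return self.eelv_ml - self.unventilated_ml

    @property
    def mixing_volume_ml(self) -> float:
        """Alveolar mixing volume: ventilated EELV minus airway dead space."""
        return self.eelv_ml - self.unventilated_ml - self.vd_airway_ml


@dataclass
class GasWaveform:
    """Synchronized airway-opening signals at a fixed sample rate.

    Flow is positive during inspiration. Gas composition is expressed as dry
    fractions in [0, 1]; nitrogen is everything that is neither O2 nor CO2,
    ``f_n2 = 1 - f_o2 - f_co2``.
    """

    sample_rate_hz: float
    flow_mls: np.ndarray
    paw_cmh2o: np.ndarray
    f_o2: np.ndarray
    f_co2: np.ndarray

    def __post_init__(self):
        n = len(self.flow_mls)
        if not (len(self.paw_cmh2o) == len(self.f_o2) == len(self.f_co2) == n):
            raise InvalidConfigError("waveform arrays must have equal length")
        if self.sample_rate_hz <= 0:
            raise InvalidConfigError("sample_rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.flow_mls)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def f_n2(self) -> np.ndarray:
        return 1.0 - self.f_o2 - self.f_co2


@dataclass
class SimTruth:
    """Exact ground truth recorded alongside a simulated maneuver."""

    eelv_ml: float
    unventilated_ml: float
    ventilated_eelv_ml: float
    mixing_volume_ml: float
    vd_airway_ml: float
    vd_instr_ml: float
    breath_times_s: np.ndarray
    alveolar_fn2: np.ndarray
    fi_o2: np.ndarray
    cum_n2_out_ml: np.ndarray
    # net N2 volume exported across the sensor per breath (mL)
    n2_net_out_ml: np.ndarray


def _fio2_at(schedule: list[tuple[float, float]], t: float) -> float:
    fio2 = schedule[0][1]
    for t_step, f in schedule:
        if t >= t_step:
            fio2 = f
        else:
            break
    return fio2


def simulate_maneuver(config: LungConfig) -> tuple[GasWaveform, SimTruth]:
    """Simulate airway-opening waveforms for an FiO2-step washin-washout maneuver.

    Breath-by-breath perfect-mixing mass balance on the alveolar compartment
    with plug-flow dead space (see module docstring). Within a breath the
    waveform is the simplest shape with the right volumetric integrals:
    constant inspiratory flow for a third of the cycle, passive exponential
    expiratory flow, and expired composition that is dead-space (fresh) gas
    until the plug volume has passed, then the alveolar plateau.

    Returns the waveform (with configured Gaussian noise added) and the
    exact noise-free :class:`SimTruth`.
    """
    config.validate()
    sched = list(config.fio2_schedule)
    fs = config.sample_rate_hz
    dt = 1.0 / fs
    period_s = 60.0 / config.rr_min
    n_per_breath = int(round(period_s * fs))
    n_insp = max(3, int(round(n_per_breath / 3.0)))
    n_exp = n_per_breath - n_insp
    if n_exp < 4:
        raise InvalidConfigError("sample rate too low to resolve a breath")
    te = n_exp / fs
    t_total = sched[-1][0] - sched[0][0]
    n_breaths = int(np.floor(t_total / period_s))
    if n_breaths < 1:
        raise InvalidConfigError("schedule shorter than one breath")

    v_mix = config.mixing_volume_ml
    vd = config.vd_airway_ml + config.vd_instr_ml
    vt = config.vt_ml
    vo2_b = config.vo2_mlmin / config.rr_min
    vco2_b = config.vco2_mlmin / config.rr_min
    vt_exp = vt - vo2_b + vco2_b
    if vt_exp <= vd:
        raise InvalidConfigError("expired tidal volume does not clear the dead space")

    # initial alveolar composition: steady state at the first FiO2 level
    fi_o2_0 = sched[0][1]
    fa = np.empty(3)  # order: O2, CO2, N2
    fa[1] = vco2_b / (vt_exp - vd)
    fa[0] = ((vt - vd) * fi_o2_0 - vo2_b) / (vt_exp - vd)
    fa[2] = 1.0 - fa[0] - fa[1]
    if fa[0] <= 0:
        raise InvalidConfigError("vo2 exceeds inspired O2 supply per breath")
    f_ds = fa.copy()  # dead-space plug content at end-expiration

    flow = np.zeros(n_breaths * n_per_breath)
    f_o2 = np.zeros_like(flow)
    f_co2 = np.zeros_like(flow)
    paw = np.full_like(flow, config.peep_cmh2o)

    # Within a breath the signals are piecewise linear with zero-flow knots
    # on sample points at every phase and composition boundary, and phase
    # amplitudes calibrated so that trapezoidal integration of the sampled
    # signal reproduces the model's volumetric exchange exactly. Layout
    # (sample index within breath): 0 zero knot | 1..n_insp-1 constant
    # inspiratory flow | n_insp zero knot | dead-space plug outflow |
    # zero knot at the composition switch | alveolar outflow decaying into
    # the next breath's leading zero knot.
    insp_flow = vt / ((n_insp - 1.5) * dt)
    m_ds = 0
    if vd > 0:
        m_ds = int(np.clip(round(n_exp * vd / vt_exp), 1, n_exp - 3))
        ds_flow = vd / (m_ds * dt)
    i_alv0 = n_insp + m_ds + 1  # zero knot where composition switches
    m_alv = n_per_breath - i_alv0 - 1
    if m_alv < 1:
        raise InvalidConfigError("breath too short for the expiratory phases")
    tau = (m_alv * dt) / 5.0
    shape = np.exp(-np.arange(1, m_alv + 1) * dt / tau)
    knotted = np.concatenate(([0.0], shape, [0.0]))
    alv_scale = (vt_exp - vd) / np.trapezoid(knotted, dx=dt)
    alv_flow = alv_scale * shape

    breath_times = np.empty(n_breaths)
    alv_fn2 = np.empty(n_breaths)
    fi_o2_per_breath = np.empty(n_breaths)
    n2_net_out = np.empty(n_breaths)

    for k in range(n_breaths):
        t0 = sched[0][0] + k * period_s
        fio2 = _fio2_at(sched, t0 + 1e-9)
        fi = np.array([fio2, 0.0, 1.0 - fio2])

        # alveolar mass balance over the breath
        amounts = v_mix * fa + vd * f_ds + (vt - vd) * fi
        amounts[0] -= vo2_b
        amounts[1] += vco2_b
        total = v_mix + vt - vo2_b + vco2_b
        fa_new = amounts / total
        if fa_new[0] < 0:
            raise InvalidConfigError("vo2 exceeds alveolar O2 content")

        i0 = k * n_per_breath
        # leading zero knot keeps the previous breath's end-expiratory gas
        f_o2[i0] = fa[0]
        f_co2[i0] = fa[1]
        flow[i0 + 1 : i0 + n_insp] = insp_flow
        f_o2[i0 + 1 : i0 + n_insp + 1] = fi[0]
        f_co2[i0 + 1 : i0 + n_insp + 1] = fi[1]
        paw[i0 + 1 : i0 + n_insp + 1] = config.pplat_cmh2o

        j0 = i0 + n_insp  # zero knot between inspiration and expiration
        if m_ds > 0:
            flow[j0 + 1 : j0 + 1 + m_ds] = -ds_flow
            f_o2[j0 + 1 : j0 + 1 + m_ds] = fi[0]
            f_co2[j0 + 1 : j0 + 1 + m_ds] = fi[1]
        a0 = i0 + i_alv0
        flow[a0 + 1 : a0 + 1 + m_alv] = -alv_flow
        f_o2[a0 : a0 + 1 + m_alv] = fa_new[0]
        f_co2[a0 : a0 + 1 + m_alv] = fa_new[1]

        n2_net_out[k] = (vt_exp - vd) * fa_new[2] - (vt - vd) * fi[2]
        breath_times[k] = t0
        alv_fn2[k] = fa_new[2]
        fi_o2_per_breath[k] = fio2

        f_ds = fa_new.copy()
        fa = fa_new

    if config.noise_sd_frac > 0 or config.noise_sd_flow > 0:
        rng = np.random.default_rng(config.seed)
        if config.noise_sd_flow > 0:
            flow = flow + rng.normal(0.0, config.noise_sd_flow, flow.shape)
        if config.noise_sd_frac > 0:
            f_o2 = f_o2 + rng.normal(0.0, config.noise_sd_frac, f_o2.shape)
            f_co2 = f_co2 + rng.normal(0.0, config.noise_sd_frac, f_co2.shape)
            f_o2 = np.clip(f_o2, 0.0, 1.0)
            f_co2 = np.clip(f_co2, 0.0, 1.0)
            over = f_o2 + f_co2
            bad = over > 1.0
            if np.any(bad):
                f_o2[bad] /= over[bad]
                f_co2[bad] /= over[bad]

    waveform = GasWaveform(
        sample_rate_hz=fs, flow_mls=flow, paw_cmh2o=paw, f_o2=f_o2, f_co2=f_co2
    )
    truth = SimTruth(
        eelv_ml=config.eelv_ml,
        unventilated_ml=config.unventilated_ml,
        ventilated_eelv_ml=config.ventilated_eelv_ml,
        mixing_volume_ml=v_mix,
        vd_airway_ml=config.vd_airway_ml,
        vd_instr_ml=config.vd_instr_ml,
        breath_times_s=breath_times,
        alveolar_fn2=alv_fn2,
        fi_o2=fi_o2_per_breath,
        cum_n2_out_ml=np.cumsum(n2_net_out),
        n2_net_out_ml=n2_net_out,
    )
    return waveform, truth


# ---------------------------------------------------------------------------
# CT phantoms


@dataclass
class PhantomConfig:
    """CT phantom layout: homogeneous HU regions of known volume inside a mask.

    ``regions`` is a list of ``(mean_hu, volume_ml)`` pairs; each region is
    realized as a slab of whole voxels along the first grid axis, so the
    realized volume matches the target up to voxel discretization.
    """

    shape: tuple[int, int, int] = (40, 20, 20)
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    regions: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(-700.0, 100.0), (-300.0, 50.0)]
    )
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.shape) or any(d <= 0 for d in self.voxel_dims_mm):
            raise InvalidConfigError("shape and voxel dims must be positive")
        if not self.regions:
            raise InvalidConfigError("at least one region required")
        for hu, vol in self.regions:
            if not -1000.0 <= hu <= 100.0:
                raise InvalidConfigError(f"region HU {hu} outside [-1000, 100]")
            if vol <= 0:
                raise InvalidConfigError("region volumes must be > 0")
        voxel_ml = float(np.prod(self.voxel_dims_mm)) / 1000.0
        total_vox = sum(int(round(v / voxel_ml)) for _, v in self.regions)
        if total_vox > int(np.prod(self.shape)):
            raise InvalidConfigError("regions exceed grid volume")


def generate_phantom(config: PhantomConfig):
    """Build an HU grid + lung mask with exactly known aeration ground truth.

    Voxels outside the regions are air at -1000 HU and excluded from the
    mask. Returns ``(CTImage, AerationReport)``; the truth report is
    computed by applying the voxel gas/tissue formulas to the constructed
    grid, so it is exact by construction.
    """
    from .ctquant import CTImage, aeration_report

    config.validate()
    hu = np.full(config.shape, -1000.0)
    mask = np.zeros(config.shape, dtype=bool)
    voxel_ml = float(np.prod(config.voxel_dims_mm)) / 1000.0
    flat_hu = hu.reshape(-1)
    flat_mask = mask.reshape(-1)
    pos = 0
    for mean_hu, vol_ml in config.regions:
        n_vox = int(round(vol_ml / voxel_ml))
        flat_hu[pos : pos + n_vox] = mean_hu
        flat_mask[pos : pos + n_vox] = True
        pos += n_vox
    img = CTImage(
        hu=hu,
        voxel_dims_mm=config.voxel_dims_mm,
        mask=mask,
        phase="end-expiration",
    )
    truth = aeration_report(img)
    return img, truth


# ---------------------------------------------------------------------------
# Paired method-comparison series


def generate_paired_series(
    n_subjects: int = 7,
    n_obs: int = 32,
    ref_range: tuple[float, float] = (254.0, 1200.0),
    slope: float = 0.92,
    intercept: float = 36.0,
    noise_sd: float = 40.0,
    seed: int = 0,
):
    """Paired (test, reference) observations with a linear bias structure.

    Reference values are uniform on ``ref_range``; test values follow
    ``test = slope * ref + intercept + N(0, noise_sd)``. Observations are
    dealt round-robin to ``n_subjects`` subjects with a per-subject
    condition order, emulating repeated measurements across PEEP steps.

    Returns a DataFrame with columns ``subject, order, value_test,
    value_ref``.
    """
    import pandas as pd

    if n_subjects < 1 or n_obs < 1:
        raise InvalidConfigError("need at least one subject and one observation")
    rng = np.random.default_rng(seed)
    ref = rng.uniform(ref_range[0], ref_range[1], n_obs)
    test = slope * ref + intercept + rng.normal(0.0, noise_sd, n_obs)
    subject = np.arange(n_obs) % n_subjects
    order = np.arange(n_obs) // n_subjects
    return pd.DataFrame(
        {
            "subject": subject,
            "order": order,
            "value_test": test,
            "value_ref": ref,
        }
    ).sort_values(["subject", "order"], ignore_index=True)


def generate_replicates(
    n_pairs: int = 27,
    mean_range: tuple[float, float] = (300.0, 1100.0),
    cv: float = 0.03,
    seed: int = 0,
):
    """Duplicate measurements with a configured within-pair coefficient of variation.

    Each pair's two values are ``mean * (1 +/- d/2)`` with ``d`` drawn so the
    two-value sample SD over the mean has expectation ``cv``.

    Returns a DataFrame with columns ``subject, condition, value_1, value_2``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    means = rng.uniform(mean_range[0], mean_range[1], n_pairs)
    # |x1-x2|/sqrt(2)/mean has expectation cv when the half-difference is
    # drawn as cv * mean * sqrt(2)/2 * |N(0,1)| * sqrt(pi/2) ... keep it
    # simple: draw signed relative difference with SD cv*sqrt(2).
    d = rng.normal(0.0, cv * np.sqrt(2.0), n_pairs)
    v1 = means * (1.0 + d / 2.0)
    v2 = means * (1.0 - d / 2.0)
    return pd.DataFrame(
        {
            "subject": np.arange(n_pairs) % 7,
            "condition": np.arange(n_pairs),
            "value_1": v1,
            "value_2": v2,
        }
    )
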