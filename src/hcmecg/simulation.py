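"""Desk-scale monodomain tissue simulation with a virtual-electrode pseudo-ECG.

A 1D strand (transmural cable or endo-to-apex surrogate) solves the
monodomain reaction-diffusion equation

    du/dt = d/dx( D(x) du/dx ) + I_ion(u, w) + I_stim(x, t)

with no-flux ends, using the two-variable Mitchell-Schaeffer membrane model
(dimensionless potential ``u`` in [0, 1], gate ``w``):

    I_ion = w u^2 (1 - u) / tau_in  -  u / tau_out
    dw/dt = (1 - w) / tau_open   if u < u_gate,   else  -w / tau_close

``u`` is mapped affinely to millivolts for reporting (rest -84 mV, peak
about +20 mV).  The model has an explicit action-potential-duration control
(``tau_close``), which is how ionic remodeling enters: the conductance
multipliers of :class:`CellScaling` (late sodium, L-type calcium, aggregate
potassium) map to a monotone APD factor

    apd_factor = s_NaL**0.15 * s_CaL**0.3 / s_K

so increased inward plateau current or reduced repolarizing current
prolongs APD, as it does in the hypertrophied myocardium.  The exponents
are package configuration; the contract is the monotone direction, not a
specific magnitude.

A virtual electrode beyond the cable end records the pseudo-ECG

    phi(t) = -K * integral  (dVm/dx) * d/dx(1/r(x))  dx ,   r = |x - x_e|

so a depolarization front travelling toward the electrode writes a positive
deflection and a repolarization sequence finishing near the electrode writes
a negative (inverted) T-like wave.

Scenario presets reproduce the two mechanism experiments qualitatively:
``purkinje_decoupled`` (a fast endocardial segment resistively decoupled
from a late-activating myocardial patch) yields a deep terminal negative
deflection, while ``ionic_remodeling`` in the electrode-facing region flips
the T-like sign without materially changing the QRS-like complex.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellScaling",
    "Stimulus",
    "TissueConfig",
    "CableState",
    "PseudoEcg",
    "SCENARIOS",
    "simulate_cable",
    "apply_ionic_remodeling",
    "pseudo_ecg",
    "run_scenario",
    "single_cell_apd90",
    "conduction_velocity",
]

# Mitchell-Schaeffer defaults (ms); give APD90 ~ 250 ms and CV ~ 0.6 mm/ms
# at D = 0.1 mm^2/ms
TAU_IN = 0.3
TAU_OUT = 6.0
TAU_OPEN = 120.0
TAU_CLOSE = 150.0
U_GATE = 0.13
V_REST_MV = -84.0
V_AMP_MV = 104.0
ACT_THRESHOLD_U = 0.5   # upstroke detection
REPOL_THRESHOLD_U = 0.1  # 90% repolarization in u-units
# activation-repolarization coupling: tissue activated later shortens its
# APD (electrotonic memory), tau_close *= clip(1 - t_act/AR_SLOPE_MS, ...).
# This keeps the repolarization sequence opposite to the activation sequence
# (concordant upright T) even when conduction is slowed, so only a genuine
# APD-prolonging intervention can invert the T-like deflection.
AR_SLOPE_MS = 450.0
AR_FLOOR = 0.05


@dataclass(frozen=True)
class CellScaling:
    """Ionic-remodeling multipliers; (1, 1, 1) is the healthy baseline."""

    s_NaL: float = 1.0   # late sodium conductance multiplier
    s_CaL: float = 1.0   # L-type calcium multiplier
    s_K: float = 1.0     # aggregate repolarizing-potassium multiplier

    def __post_init__(self):
        if min(self.s_NaL, self.s_CaL, self.s_K) <= 0:
            raise ValueError("CellScaling multipliers must be positive")

    @property
    def apd_factor(self) -> float:
        """Monotone map of conductance scalings to an APD multiplier."""
        return self.s_NaL ** 0.15 * self.s_CaL ** 0.3 / self.s_K


@dataclass(frozen=True)
class Stimulus:
    position_mm: float
    start_ms: float = 5.0
    duration_ms: float = 1.0
    amplitude: float = 2.0     # in u-units per ms
    width_mm: float = 1.0


@dataclass
class TissueConfig:
    """Declarative description of the 1D tissue.

    ``endo_layer`` models a fast endocardial conduction (Purkinje surrogate)
    segment: within (start, stop) the diffusivity is multiplied by
    ``d_factor`` and at the segment borders the interface diffusivity is
    multiplied by ``coupling_factor`` in (0, 1] — the resistive junction to
    the working myocardium.
    """

    length_mm: float = 50.0
    dx_mm: float = 0.25
    diffusion_mm2_per_ms: float = 0.1
    stim_sites: list = field(default_factory=lambda: [Stimulus(0.0)])
    d_scale_regions: list = field(default_factory=list)  # (start, stop, factor)
    endo_layer: dict | None = None  # {start, stop, d_factor, coupling_factor}
    remodeling: list = field(default_factory=list)       # (start, stop, CellScaling)
    apd_gradient: tuple = (1.0, 1.0)  # tau_close factor, proximal -> distal

    def __post_init__(self):
        if self.dx_mm <= 0 or self.length_mm <= 0:
            raise ValueError("dx_mm and length_mm must be positive")
        if self.diffusion_mm2_per_ms <= 0:
            raise ValueError("diffusion must be positive")
        for start, stop, fac in self.d_scale_regions:
            if fac <= 0:
                raise ValueError("diffusion scale factors must be positive")
            self._check_interval(start, stop)
        if self.endo_layer is not None:
            cf = self.endo_layer.get("coupling_factor", 1.0)
            if not (0 < cf <= 1):
                raise ValueError("coupling_factor must be in (0, 1]")
            self._check_interval(self.endo_layer["start"], self.endo_layer["stop"])
        for start, stop, _ in self.remodeling:
            self._check_interval(start, stop)

    def _check_interval(self, start, stop):
        if not (0 <= start < stop <= self.length_mm):
            raise ValueError(f"interval ({start}, {stop}) outside the domain")

    # -- discretized parameter fields ------------------------------------
    def grids(self):
        n = int(round(self.length_mm / self.dx_mm)) + 1
        x = np.arange(n) * self.dx_mm
        D = np.full(n, self.diffusion_mm2_per_ms)
        for start, stop, fac in self.d_scale_regions:
            D[(x >= start) & (x <= stop)] *= fac
        if self.endo_layer is not None:
            el = self.endo_layer
            D[(x >= el["start"]) & (x <= el["stop"])] *= el.get("d_factor", 1.0)
        # interface diffusivities (harmonic mean)
        g = 2.0 * D[:-1] * D[1:] / (D[:-1] + D[1:])
        if self.endo_layer is not None:
            el = self.endo_layer
            cf = el.get("coupling_factor", 1.0)
            if cf < 1.0:
                # resistive junction: a short zone of reduced interface
                # diffusivity at each interior border of the fast layer
                width = el.get("junction_width_mm", 1.0)
                xi = 0.5 * (x[:-1] + x[1:])   # interface positions
                for border in (el["start"], el["stop"]):
                    if 0.0 < border < self.length_mm:
                        g[np.abs(xi - border) <= width / 2.0] *= cf
        # per-node tau_close (APD gradient x remodeling)
        frac = x / self.length_mm
        tc = TAU_CLOSE * (self.apd_gradient[0]
                          + (self.apd_gradient[1] - self.apd_gradient[0]) * frac)
        for start, stop, scaling in self.remodeling:
            tc[(x >= start) & (x <= stop)] *= scaling.apd_factor
        return x, D, g, tc


@dataclass
class CableState:
    """Membrane-potential field and derived per-node quantities."""

    x_mm: np.ndarray
    t_ms: np.ndarray
    vm: np.ndarray               # [n_nodes, n_frames] in mV
    activation_time_ms: np.ndarray   # NaN where never activated
    apd90_ms: np.ndarray             # NaN where undefined


@dataclass
class PseudoEcg:
    electrode_position_mm: float
    t_ms: np.ndarray
    trace: np.ndarray    # arbitrary units
    dt_ms: float


class SimulationError(RuntimeError):
    pass


def simulate_cable(config: TissueConfig, duration_ms: float = 500.0,
                   dt_ms: float = 0.02, save_every_ms: float = 1.0) -> CableState:
    """Integrate the monodomain cable (explicit Euler, no-flux ends).

    Raises :class:`SimulationError` when ``dt`` violates the explicit
    diffusion stability bound ``dt <= dx^2 / (2 max D)`` or the solution
    diverges.
    """
    x, D, g, tc = config.grids()
    n = x.size
    dx2 = config.dx_mm ** 2
    bound = dx2 / (2.0 * g.max())
    if dt_ms > bound:
        raise SimulationError(
            f"dt={dt_ms} ms violates the diffusion stability bound "
            f"dx^2/(2 max D) = {bound:.4g} ms"
        )

    stim_masks = []
    for s in config.stim_sites:
        if not (0 <= s.position_mm <= config.length_mm):
            raise ValueError("stimulus outside the domain")
        mask = np.abs(x - s.position_mm) <= s.width_mm
        stim_masks.append((s, mask))

    u = np.zeros(n)
    w = np.ones(n)
    n_steps = int(round(duration_ms / dt_ms))
    save_stride = max(int(round(save_every_ms / dt_ms)), 1)
    frames, frame_t = [], []
    act = np.full(n, np.nan)
    repol = np.full(n, np.nan)

    inv_tau_open = 1.0 / TAU_OPEN
    inv_tc = 1.0 / tc
    for step in range(n_steps + 1):
        t = step * dt_ms
        if step % save_stride == 0:
            frames.append(u.copy())
            frame_t.append(t)
        # reaction
        ion = w * u * u * (1.0 - u) / TAU_IN - u / TAU_OUT
        stim = np.zeros(n)
        for s, mask in stim_masks:
            if s.start_ms <= t < s.start_ms + s.duration_ms:
                stim[mask] += s.amplitude
        dw = np.where(u < U_GATE, (1.0 - w) * inv_tau_open, -w * inv_tc)
        # diffusion (flux form, no-flux boundaries)
        flux = g * (u[1:] - u[:-1])
        lap = np.zeros(n)
        lap[:-1] += flux
        lap[1:] -= flux
        u_new = u + dt_ms * (ion + stim + lap / dx2)
        w = w + dt_ms * dw
        # fiducials tracked at full time resolution
        crossed_up = np.isnan(act) & (u_new >= ACT_THRESHOLD_U)
        act[crossed_up] = t
        if np.any(crossed_up):
            # activation-repolarization coupling fixes tau_close at upstroke
            factor = float(np.clip(1.0 - t / AR_SLOPE_MS, AR_FLOOR, 1.0))
            inv_tc[crossed_up] = 1.0 / (tc[crossed_up] * factor)
        crossed_down = (~np.isnan(act)) & np.isnan(repol) \
            & (u < REPOL_THRESHOLD_U + 1e-12) & (u_new < REPOL_THRESHOLD_U) \
            & (t > act + 1.0)
        # only count down-crossings after the upstroke has passed the peak
        crossed_down &= u_new <= u
        repol[crossed_down] = t
        u = u_new
        if step % 500 == 0 and (not np.all(np.isfinite(u)) or np.abs(u).max() > 5):
            raise SimulationError("solution diverged; reduce dt or check parameters")

    vm = V_REST_MV + V_AMP_MV * np.asarray(frames).T
    apd = repol - act
    return CableState(x_mm=x, t_ms=np.asarray(frame_t), vm=vm,
                      activation_time_ms=act, apd90_ms=apd)


def apply_ionic_remodeling(config: TissueConfig, region: tuple,
                           scaling: CellScaling) -> TissueConfig:
    """Return a copy of ``config`` with ``scaling`` applied in ``region`` only."""
    start, stop = region
    cfg = copy.deepcopy(config)
    cfg._check_interval(start, stop)
    if scaling == CellScaling():
        return cfg
    cfg.remodeling = list(cfg.remodeling) + [(start, stop, scaling)]
    return cfg


def pseudo_ecg(state: CableState, electrode_position_mm: float,
               k_const: float = 1.0) -> PseudoEcg:
    """Virtual-electrode potential from the Vm field.

    ``phi(t) = -K * sum_i dVm/dx|_i * d/dx(1/r)|_i * dx`` with
    ``r = |x - x_e|``; the electrode must lie strictly outside the cable.
    """
    x = state.x_mm
    xe = float(electrode_position_mm)
    if x.min() <= xe <= x.max():
        raise ValueError("electrode must lie strictly outside the cable")
    dx = float(x[1] - x[0])
    r = np.abs(x - xe)
    dinv_r = (xe - x) / r ** 3          # d/dx (1/r)
    dvm = np.gradient(state.vm, dx, axis=0)
    trace = -k_const * (dvm * dinv_r[:, None]).sum(axis=0) * dx
    dt = float(state.t_ms[1] - state.t_ms[0]) if state.t_ms.size > 1 else 0.0
    return PseudoEcg(xe, state.t_ms, trace, dt)


def single_cell_apd90(scaling: CellScaling = CellScaling(),
                      dt_ms: float = 0.02, duration_ms: float = 600.0) -> float:
    """APD90 of an isolated cell under ``scaling`` (0-D oracle for sweeps)."""
    tc = TAU_CLOSE * scaling.apd_factor
    u, w = 0.0, 1.0
    act = repol = None
    t = 0.0
    n = int(duration_ms / dt_ms)
    for step in range(n):
        stim = 2.0 if 5.0 <= t < 6.0 else 0.0
        du = w * u * u * (1 - u) / TAU_IN - u / TAU_OUT + stim
        dw = (1 - w) / TAU_OPEN if u < U_GATE else -w / tc
        u_new = u + dt_ms * du
        w += dt_ms * dw
        if act is None and u_new >= ACT_THRESHOLD_U:
            act = t
            # same activation-repolarization coupling rule as in tissue
            tc *= float(np.clip(1.0 - t / AR_SLOPE_MS, AR_FLOOR, 1.0))
        if act is not None and repol is None and u_new < REPOL_THRESHOLD_U \
                and u_new <= u and t > act + 1.0:
            repol = t
            break
        u = u_new
        t += dt_ms
    if act is None or repol is None:
        raise SimulationError("cell did not complete an action potential")
    return repol - act


def conduction_velocity(state: CableState, x_lo_frac: float = 0.25,
                        x_hi_frac: float = 0.75) -> float:
    """CV (mm/ms) from a linear fit of activation time over the middle span."""
    x = state.x_mm
    mask = (x >= x_lo_frac * x.max()) & (x <= x_hi_frac * x.max())
    at = state.activation_time_ms[mask]
    if np.any(np.isnan(at)):
        raise SimulationError("propagation failed inside the fitted span")
    slope = np.polyfit(x[mask], at, 1)[0]
    return 1.0 / slope


# ---------------------------------------------------------------------------
# scenario library
# ---------------------------------------------------------------------------

def _baseline_config() -> TissueConfig:
    # proximal stimulus, electrode-facing distal end; the tau_close gradient
    # (longer proximal APD, steeper than the activation delay) gives the
    # concordant upright T of a normal precordial lead
    return TissueConfig(
        length_mm=50.0,
        dx_mm=0.25,
        diffusion_mm2_per_ms=0.3,
        stim_sites=[Stimulus(position_mm=0.0, start_ms=5.0)],
        apd_gradient=(1.25, 0.75),
    )


def _scenario_configs() -> dict:
    base = _baseline_config()

    # regional conduction slowing (fibrosis / fiber-disarray surrogate)
    slow = copy.deepcopy(base)
    slow.d_scale_regions = [(15.0, 35.0, 0.3)]

    # near-complete local conduction block: a thin, severely slowed band
    block = copy.deepcopy(base)
    block.d_scale_regions = [(22.0, 26.0, 0.02)]

    # fast endocardial (Purkinje-surrogate) layer, resistively decoupled
    # from a slow-conducting myocardial patch at the far end from the
    # electrode: the patch activates late and its retrograde front writes
    # the deep terminal S
    purk = copy.deepcopy(base)
    purk.endo_layer = {"start": 15.0, "stop": 50.0, "d_factor": 4.0,
                       "coupling_factor": 0.006, "junction_width_mm": 2.5}
    purk.d_scale_regions = [(0.0, 13.0, 0.3)]
    purk.stim_sites = [Stimulus(position_mm=17.0, start_ms=5.0)]

    # ionic remodeling in the electrode-facing (hypertrophied) region, with
    # severity increasing toward the tip (apical hypertrophy pattern): the
    # region repolarizes last and tip-last, reversing the repolarization
    # sequence seen by the electrode while leaving activation untouched
    remod = apply_ionic_remodeling(base, (30.0, 50.0),
                                   CellScaling(s_NaL=2.0, s_CaL=1.1, s_K=0.65))
    remod = apply_ionic_remodeling(remod, (37.0, 50.0), CellScaling(s_K=0.8))
    remod = apply_ionic_remodeling(remod, (44.0, 50.0), CellScaling(s_K=0.8))
    return {
        "baseline": base,
        "slow_conduction": slow,
        "activation_block": block,
        "purkinje_decoupled": purk,
        "ionic_remodeling": remod,
    }


SCENARIOS = tuple(_scenario_configs())

ELECTRODE_MM = 70.0   # 20 mm beyond the distal end; precordial surrogate


def summarize_trace(state: CableState, ecg: PseudoEcg) -> dict:
    """QRS-like/T-like summary of a pseudo-ECG trace.

    The QRS-like window runs to 30 ms past the latest activation; its
    duration is the span where |phi| exceeds 5% of the window maximum.  The
    terminal deflection is the most negative excursion after the main peak
    within that window; the T-like sign is the sign of the largest |phi| in
    the remainder of the trace.
    """
    t = ecg.t_ms
    phi = ecg.trace
    latest = float(np.nanmax(state.activation_time_ms))
    qrs_end_t = latest + 30.0
    qw = t <= qrs_end_t
    phi_q = phi[qw]
    amp = np.abs(phi_q).max()
    above = np.nonzero(np.abs(phi_q) > 0.05 * amp)[0]
    qrs_dur = float(t[qw][above[-1]] - t[qw][above[0]]) if above.size else 0.0
    i_main = int(np.argmax(np.abs(phi_q)))
    tail = phi_q[i_main:]
    term_min = float(tail.min()) if tail.size else 0.0
    s_depth = max(0.0, -term_min)
    tw = t > qrs_end_t
    if np.any(tw):
        phi_t = phi[tw]
        # polarity by signed area (same convention as the T-wave biomarker):
        # robust when repolarization is multiphasic
        area = float(np.trapezoid(phi_t))
        t_sign = -1 if area < 0 else +1
        t_amp = float(np.max(np.abs(phi_t)))
    else:
        t_sign, t_amp = +1, 0.0
    return {
        "qrs_like_duration_ms": qrs_dur,
        "terminal_deflection_depth": s_depth,
        "terminal_deflection_sign": -1 if s_depth > 0 else +1,
        "t_like_sign": t_sign,
        "t_like_amplitude": t_amp,
        "latest_activation_ms": latest,
    }


def run_scenario(name: str, overrides: dict | None = None,
                 duration_ms: float = 900.0, dt_ms: float = 0.02,
                 save_every_ms: float = 1.0):
    """Run a named mechanism scenario; returns (CableState, PseudoEcg, summary).

    ``overrides`` are attribute overrides applied to the preset
    :class:`TissueConfig` (e.g. ``{"remodeling": [...]}``).
    """
    configs = _scenario_configs()
    if name not in configs:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(configs)}")
    cfg = configs[name]
    for key, val in (overrides or {}).items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown TissueConfig field {key!r}")
        setattr(cfg, key, val)
    state = simulate_cable(cfg, duration_ms=duration_ms, dt_ms=dt_ms,
                           save_every_ms=save_every_ms)
    ecg = pseudo_ecg(state, ELECTRODE_MM)
    summary = {"scenario": name, **summarize_trace(state, ecg)}
    return state, ecg, summary
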