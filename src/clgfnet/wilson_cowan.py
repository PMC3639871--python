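"""Delayed Wilson-Cowan oscillator networks.

Each oscillator is a mean-field pair of excitatory (E) and inhibitory (I)
populations,

    dE/dt = -alpha*E + beta_E * (1 - r*E) * f_E(s_E)
    dI/dt = -alpha*I + beta_I * (1 - r*I) * f_I(s_I)

with the threshold-centred sigmoid ``f(s) = 1/(1+exp(-a(s-theta))) -
1/(1+exp(a*theta))`` (so that f(0)=0 and the quiescent state E=I=0 is a
fixed point for zero input).  The within-oscillator inputs are

    s_E = w_ee*E - w_ie*I + P      (w_ie: inhibitory -> excitatory)
    s_I = w_ei*E - w_ii*I + Q      (w_ei: excitatory -> inhibitory)

i.e. weights are named source->target.  Oscillators couple through their
excitatory populations with conduction delays: a coupling (src -> tgt,
weight w, delay tau) adds ``w * E_src(t - tau)`` to the target's s_E.
Time is in milliseconds throughout, so the default parameter set produces
limit cycles near 100 Hz (period ~10 ms).

The delay equations are integrated by the method of steps with classical
RK4 and 4-point (cubic Lagrange) interpolation of the stored excitatory
history, compiled with numba.  All delays must exceed a few integration
steps, which holds comfortably for the physiological delays used here
(6-25 ms at dt <= 0.1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "WCParams",
    "Coupling",
    "WCNetworkSpec",
    "WCTrajectory",
    "HyperExcitationError",
    "simulate",
    "dominant_frequency",
    "is_hyper_excited",
    "calibrate_input",
    "calibrate_global_coupling",
    "single_oscillator",
    "two_node_circuit",
    "clgf_circuit",
    "sweep_local_coupling",
    "SWEEP_P_DEFAULT",
    "SWEEP_W_GLOBAL_DEFAULT",
]

#: default conduction delays (ms): inter-regional (global) and
#: intra-regional (local) feedback loops
TAU_GLOBAL_DEFAULT = 21.0
TAU_LOCAL_DEFAULT = 6.0


class HyperExcitationError(RuntimeError):
    """Raised when every requested simulation lands in the runaway
    high-activity regime and no spectral readout is possible."""


@dataclass(frozen=True)
class WCParams:
    """Parameters of one Wilson-Cowan oscillator.

    Defaults are the estimate set used throughout: a single oscillator
    shows a stable limit cycle from ~80 Hz up to ~150 Hz as the constant
    excitatory drive P moves across [1.2, 3], and hyper-excitation or
    quiescence outside that window.
    """

    alpha: float = 0.35       # natural decay rate (1/ms)
    beta_e: float = 1.0       # maximal firing rate, excitatory
    beta_i: float = 1.0       # maximal firing rate, inhibitory
    r: float = 0.65           # refractory constant
    a_e: float = 1.3          # sigmoid slope, excitatory
    a_i: float = 2.0          # sigmoid slope, inhibitory
    theta_e: float = 4.5      # threshold, excitatory
    theta_i: float = 3.5      # threshold, inhibitory
    w_ee: float = 16.0        # E -> E synaptic weight
    w_ei: float = 15.0        # E -> I
    w_ie: float = 12.0        # I -> E
    w_ii: float = 3.0         # I -> I
    p: float = 0.0            # constant external excitatory input
    q: float = 0.0            # constant external inhibitory input

    def as_row(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta_e, self.beta_i, self.r,
             self.a_e, self.a_i, self.theta_e, self.theta_i,
             self.w_ee, self.w_ei, self.w_ie, self.w_ii,
             self.p, self.q],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class Coupling:
    """Directed delayed excitatory coupling ``w * E_source(t - tau)``
    added to the target's s_E."""

    source: int
    target: int
    weight: float
    tau: float  # ms, must be positive

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"coupling delay must be positive, got {self.tau}")
        if self.source == self.target:
            raise ValueError("self-coupling is not allowed")


@dataclass
class WCNetworkSpec:
    """A network of delayed Wilson-Cowan oscillators.

    ``params`` holds one :class:`WCParams` per oscillator (external drives
    P, Q live there); ``couplings`` the delayed E->E links.
    """

    params: list[WCParams]
    couplings: list[Coupling] = field(default_factory=list)

    @property
    def n_oscillators(self) -> int:
        return len(self.params)

    def __post_init__(self) -> None:
        n = self.n_oscillators
        for c in self.couplings:
            if not (0 <= c.source < n and 0 <= c.target < n):
                raise ValueError(f"coupling {c} references a missing oscillator")

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        Path(path).write_text(json.dumps(
            {"params": [asdict(p) for p in self.params],
             "couplings": [asdict(c) for c in self.couplings]}, indent=2))

    @classmethod
    def from_json(cls, path) -> "WCNetworkSpec":
        import json
        from pathlib import Path

        raw = json.loads(Path(path).read_text())
        return cls(params=[WCParams(**p) for p in raw["params"]],
                   couplings=[Coupling(**c) for c in raw["couplings"]])


@dataclass
class WCTrajectory:
    """Simulated activity: E and I of shape (n_oscillators, n_steps+1)
    sampled every ``dt`` ms starting at t=0."""

    E: np.ndarray
    I: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.E.shape[1]) * self.dt

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt

    def resample(self, fs: float) -> np.ndarray:
        """Decimate E to an integer-stride grid at ``fs`` Hz."""
        stride = int(round(self.fs / fs))
        if stride < 1 or abs(self.fs / stride - fs) > 1e-9:
            raise ValueError(f"{fs} Hz is not an integer decimation of {self.fs} Hz")
        return self.E[:, ::stride]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("E", data=self.E)
            f.create_dataset("I", data=self.I)
            f.create_dataset("dt", data=self.dt)

    @classmethod
    def from_hdf5(cls, path) -> "WCTrajectory":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["E"][()], f["I"][()], float(f["dt"][()]))


@njit(cache=True)
def _interp_history(hist, pos, osc):
    """Cubic Lagrange interpolation of hist[:, osc] at fractional row pos."""
    i0 = int(np.floor(pos))
    u = pos - i0
    if u < 1e-12:
        return hist[i0, osc]
    y0 = hist[i0 - 1, osc]
    y1 = hist[i0, osc]
    y2 = hist[i0 + 1, osc]
    y3 = hist[i0 + 2, osc]
    w0 = -u * (u - 1.0) * (u - 2.0) / 6.0
    w1 = (u + 1.0) * (u - 1.0) * (u - 2.0) / 2.0
    w2 = -(u + 1.0) * u * (u - 2.0) / 2.0
    w3 = (u + 1.0) * u * (u - 1.0) / 6.0
    return w0 * y0 + w1 * y1 + w2 * y2 + w3 * y3


@njit(cache=True)
def _sigmoid(s, a, theta):
    return 1.0 / (1.0 + np.exp(-a * (s - theta))) - 1.0 / (1.0 + np.exp(a * theta))


@njit(cache=True)
def _derivs(E, I, par, c_src, c_tgt, c_w, c_dsteps, hist, gpos, drive, dE, dI):
    n = E.shape[0]
    # s_E accumulator: start from within-oscillator terms + external drive
    for i in range(n):
        s_e = par[i, 8] * E[i] - par[i, 10] * I[i] + par[i, 12] + drive[i]
        s_i = par[i, 9] * E[i] - par[i, 11] * I[i] + par[i, 13]
        dE[i] = s_e
        dI[i] = s_i
    for k in range(c_src.shape[0]):
        dE[c_tgt[k]] += c_w[k] * _interp_history(hist, gpos - c_dsteps[k], c_src[k])
    for i in range(n):
        fe = _sigmoid(dE[i], par[i, 4], par[i, 6])
        fi = _sigmoid(dI[i], par[i, 5], par[i, 7])
        dE[i] = -par[i, 0] * E[i] + par[i, 1] * (1.0 - par[i, 3] * E[i]) * fe
        dI[i] = -par[i, 0] * I[i] + par[i, 2] * (1.0 - par[i, 3] * I[i]) * fi


@njit(cache=True)
def _integrate(par, c_src, c_tgt, c_w, c_dsteps, n_steps, dt, hist_len,
               noise, kick_amp, kick_steps, kick_mask, E0, I0):
    n = par.shape[0]
    E_hist = np.zeros((hist_len + n_steps + 1, n))
    I_out = np.zeros((n_steps + 1, n))
    E = E0.copy()
    I = I0.copy()
    E_hist[hist_len, :] = E
    I_out[0, :] = I
    drive = np.zeros(n)
    k1E = np.zeros(n); k1I = np.zeros(n)
    k2E = np.zeros(n); k2I = np.zeros(n)
    k3E = np.zeros(n); k3I = np.zeros(n)
    k4E = np.zeros(n); k4I = np.zeros(n)
    Et = np.zeros(n); It = np.zeros(n)
    have_noise = noise.shape[1] > 0
    for step in range(n_steps):
        for i in range(n):
            drive[i] = 0.0
            if have_noise:
                drive[i] += noise[i, step]
            if step < kick_steps:
                drive[i] += kick_amp * kick_mask[i]
        g = float(hist_len + step)
        _derivs(E, I, par, c_src, c_tgt, c_w, c_dsteps, E_hist, g, drive, k1E, k1I)
        for i in range(n):
            Et[i] = E[i] + 0.5 * dt * k1E[i]
            It[i] = I[i] + 0.5 * dt * k1I[i]
        _derivs(Et, It, par, c_src, c_tgt, c_w, c_dsteps, E_hist, g + 0.5, drive, k2E, k2I)
        for i in range(n):
            Et[i] = E[i] + 0.5 * dt * k2E[i]
            It[i] = I[i] + 0.5 * dt * k2I[i]
        _derivs(Et, It, par, c_src, c_tgt, c_w, c_dsteps, E_hist, g + 0.5, drive, k3E, k3I)
        for i in range(n):
            Et[i] = E[i] + dt * k3E[i]
            It[i] = I[i] + dt * k3I[i]
        _derivs(Et, It, par, c_src, c_tgt, c_w, c_dsteps, E_hist, g + 1.0, drive, k4E, k4I)
        for i in range(n):
            E[i] += dt / 6.0 * (k1E[i] + 2.0 * k2E[i] + 2.0 * k3E[i] + k4E[i])
            I[i] += dt / 6.0 * (k1I[i] + 2.0 * k2I[i] + 2.0 * k3I[i] + k4I[i])
            E_hist[hist_len + step + 1, i] = E[i]
            I_out[step + 1, i] = I[i]
    return E_hist[hist_len:, :], I_out


def simulate(
    spec: WCNetworkSpec,
    duration: float,
    dt: float = 0.05,
    kick: float = 0.5,
    kick_duration: float = 2.0,
    kick_oscillators: list[int] | None = None,
    input_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> WCTrajectory:
    """Integrate a delayed Wilson-Cowan network.

    Parameters
    ----------
    duration
        Simulated time in ms.
    dt
        Integration step in ms (<= 0.1 required; delays must exceed 3*dt).
    kick, kick_duration, kick_oscillators
        A brief constant boost to the excitatory input over the first
        ``kick_duration`` ms, to leave the basin of the trivial fixed
        point; the initial history is the quiescent state (E,I)=(0,0).
        By default every oscillator is kicked; passing an index list
        restricts it (circuit sweeps kick the hub only, which selects
        the slow delayed-loop rhythm in multistable circuits).
    input_noise_sd
        If > 0, independent white Gaussian noise (per oscillator, held
        constant over each dt step) added to s_E — used by the synthetic
        cohort generator to give the dynamics broadband content.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > 0.1:
        raise ValueError(f"dt={dt} ms too coarse; need dt <= 0.1 ms")
    n_steps = int(round(duration / dt))
    n = spec.n_oscillators
    par = np.vstack([p.as_row() for p in spec.params]) if n else np.zeros((0, 14))
    n_c = len(spec.couplings)
    c_src = np.array([c.source for c in spec.couplings], dtype=np.int64)
    c_tgt = np.array([c.target for c in spec.couplings], dtype=np.int64)
    c_w = np.array([c.weight for c in spec.couplings], dtype=np.float64)
    c_dsteps = np.array([c.tau / dt for c in spec.couplings], dtype=np.float64)
    if n_c and c_dsteps.min() < 3.0:
        raise ValueError("all delays must exceed 3 integration steps")
    max_delay = int(np.ceil(c_dsteps.max())) + 2 if n_c else 0
    hist_len = max_delay + 2
    if input_noise_sd > 0:
        if rng is None:
            raise ValueError("input_noise_sd > 0 requires an rng")
        # white noise held per step; sd scaled so that band-level power is
        # roughly dt-independent (like a discretized white-noise drive)
        noise = rng.normal(0.0, input_noise_sd, size=(n, n_steps))
    else:
        noise = np.zeros((n, 0))
    kick_steps = int(round(kick_duration / dt)) if kick != 0.0 else 0
    kick_mask = np.ones(n)
    if kick_oscillators is not None:
        kick_mask = np.zeros(n)
        kick_mask[list(kick_oscillators)] = 1.0
    E, I = _integrate(
        par, c_src, c_tgt, c_w, c_dsteps, n_steps, dt, hist_len,
        noise, kick, kick_steps, kick_mask, np.zeros(n), np.zeros(n),
    )
    return WCTrajectory(E=E.T.copy(), I=I.T.copy(), dt=dt)


def is_hyper_excited(traj: WCTrajectory, oscillator: int,
                     transient: float = 200.0) -> bool:
    """Runaway positive-feedback regime: activity saturated high with at
    most residual micro-oscillation after the transient (normal limit
    cycles swing by >0.1)."""
    seg = traj.E[oscillator, int(round(transient / traj.dt)):]
    return bool(seg.mean() > 0.6 and np.ptp(seg) < 0.05)


def dominant_frequency(
    traj: WCTrajectory,
    oscillator: int = 0,
    transient: float = 200.0,
    min_amplitude: float = 1e-4,
) -> float | None:
    """Spectral peak (Hz) of E(t) after discarding the transient.

    Returns None for a flat (fixed-point or saturated) trajectory.
    """
    start = int(round(transient / traj.dt))
    seg = traj.E[oscillator, start:]
    if seg.size < 16 or np.ptp(seg) < min_amplitude:
        return None
    seg = seg - seg.mean()
    spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
    freqs = np.fft.rfftfreq(seg.size, d=traj.dt / 1000.0)
    # ignore the DC bin
    return float(freqs[1:][np.argmax(spec[1:])])


def single_oscillator(p: float, params: WCParams | None = None) -> WCNetworkSpec:
    base = params or WCParams()
    return WCNetworkSpec(params=[replace(base, p=p)])


def two_node_circuit(
    p: float,
    w_global: float,
    tau_global: float = TAU_GLOBAL_DEFAULT,
    params: WCParams | None = None,
    drive_partner: bool = True,
) -> WCNetworkSpec:
    """Oscillators a and b reciprocally coupled through a delayed global
    positive feedback loop (w_ab = w_ba).

    Both oscillators model principal populations of *distinct* cortical
    regions, so each receives the external drive P by default (an
    undriven partner cannot be ignited by couplings in the explored 0-4
    range: its sigmoid input stays far below threshold).
    """
    base = params or WCParams()
    return WCNetworkSpec(
        params=[replace(base, p=p), replace(base, p=p if drive_partner else 0.0)],
        couplings=[
            Coupling(source=1, target=0, weight=w_global, tau=tau_global),
            Coupling(source=0, target=1, weight=w_global, tau=tau_global),
        ],
    )


def clgf_circuit(
    p: float,
    w_global: float,
    w_local: float,
    tau_global: float = TAU_GLOBAL_DEFAULT,
    tau_local: float = TAU_LOCAL_DEFAULT,
    params: WCParams | None = None,
) -> WCNetworkSpec:
    """Three-oscillator coupled local-and-global feedback circuit.

    Hub a holds a long-delay reciprocal loop with b (global partner in a
    distant region) and a short-delay reciprocal loop with c (local
    partner inside a's own region).  External drive reaches one
    oscillator per region: a and b are driven, c is not — c participates
    only through the local loop.
    """
    base = params or WCParams()
    spec = two_node_circuit(p, w_global, tau_global, params=base)
    spec.params.append(replace(base, p=0.0))
    if w_local != 0.0:
        spec.couplings += [
            Coupling(source=2, target=0, weight=w_local, tau=tau_local),
            Coupling(source=0, target=2, weight=w_local, tau=tau_local),
        ]
    return spec


def calibrate_input(
    target_hz: float = 100.0,
    p_grid: np.ndarray | None = None,
    duration: float = 1200.0,
    dt: float = 0.05,
    params: WCParams | None = None,
) -> float:
    """Grid-search the constant drive P whose single-oscillator dominant
    frequency is nearest ``target_hz`` (default 100 Hz)."""
    grid = np.arange(1.2, 3.0001, 0.05) if p_grid is None else np.asarray(p_grid)
    best_p, best_err = None, np.inf
    for p in grid:
        traj = simulate(single_oscillator(p, params), duration, dt=dt)
        f = dominant_frequency(traj)
        if f is None:
            continue
        err = abs(f - target_hz)
        if err < best_err:
            best_p, best_err = float(p), err
    if best_p is None:
        raise HyperExcitationError("no oscillatory point found on the P grid")
    return best_p


#: circuit operating point for coupling sweeps: constant drive of the two
#: regional (driven) oscillators.  Chosen once by grid calibration so the
#: two-node global loop settles into its beta-dominant relaxation rhythm:
#: the hub must sit in the lower part of its oscillatory range (~85 Hz
#: solo) to leave the delayed feedback room to restructure the rhythm
#: without tipping into hyper-excitation.
SWEEP_P_DEFAULT = 1.25
#: global coupling strength for CLGF sweeps: the smallest grid strength
#: at which the two-node circuit is beta-dominant (see
#: calibrate_global_coupling)
SWEEP_W_GLOBAL_DEFAULT = 2.6


def _circuit_band_powers(traj: WCTrajectory, transient: float,
                         readout_fs: float):
    from .signals import SignalSet
    from .spectral import band_power, morlet_tf
    from .synchrony import bandpass, hilbert_phase, plv

    n_trans = int(round(transient * readout_fs / 1000.0))
    sig = SignalSet(traj.resample(readout_fs)[:, n_trans:], fs=readout_fs)
    bp = band_power(morlet_tf(sig, average_channels=False).channel_sum())
    phases = hilbert_phase(bandpass(sig, (13.0, 30.0)), band="beta")
    res = plv(phases[:2])
    return bp, float(res.matrix[0, 1])


def calibrate_global_coupling(
    grid: np.ndarray | None = None,
    p: float = SWEEP_P_DEFAULT,
    tau_global: float = TAU_GLOBAL_DEFAULT,
    duration: float = 2400.0,
    dt: float = 0.05,
    transient: float = 400.0,
) -> float:
    """Smallest global coupling strength at which the two-node circuit is
    beta-dominant (the regime the CLGF sweep starts from)."""
    grid = np.arange(0.0, 4.01, 0.2) if grid is None else np.asarray(grid)
    for w in grid:
        spec = two_node_circuit(p, float(w), tau_global)
        traj = simulate(spec, duration, dt=dt, kick_oscillators=[0])
        if is_hyper_excited(traj, 0):
            continue
        bp, _ = _circuit_band_powers(traj, transient, 1000.0)
        if bp.beta_scalar > max(bp.gamma_scalar, 0.05):
            return float(w)
    raise HyperExcitationError("no beta-dominant two-node regime on the grid")


def sweep_local_coupling(
    local_grid: np.ndarray,
    w_global: float = SWEEP_W_GLOBAL_DEFAULT,
    p: float = SWEEP_P_DEFAULT,
    tau_global: float = TAU_GLOBAL_DEFAULT,
    tau_local: float = TAU_LOCAL_DEFAULT,
    duration: float = 2400.0,
    dt: float = 0.05,
    transient: float = 400.0,
    readout_fs: float = 1000.0,
    params: WCParams | None = None,
):
    """Sweep the local coupling strength of the CLGF circuit and read out
    band powers and beta phase locking.

    For each grid value the three-node circuit is simulated (asymmetric
    ignition: the brief excitatory kick goes to the hub only, which
    selects the slow loop rhythm over in-phase modes), the excitatory
    outputs are decimated to ``readout_fs``, total beta (13-30 Hz) and
    gamma (30-80 Hz) band powers are computed from the Morlet transform
    summed over the three oscillators, and the beta-band PLV between hub
    a and global partner b is evaluated.  Beta harmonics falling in the
    gamma band are deliberately not removed.  Hyper-excitatory grid
    points are flagged and excluded from the band-power readouts.

    Returns a pandas DataFrame with columns ``strength, beta_power,
    gamma_power, beta_plv, hyper`` and (as ``df.attrs['crossover']``) the
    first grid strength where gamma power exceeds beta power, or None.
    """
    import pandas as pd

    rows = []
    n_hyper = 0
    for w_local in np.asarray(local_grid, dtype=float):
        spec = clgf_circuit(p, w_global, w_local, tau_global, tau_local,
                            params=params)
        traj = simulate(spec, duration, dt=dt, kick_oscillators=[0])
        if is_hyper_excited(traj, 0):
            n_hyper += 1
            rows.append((w_local, np.nan, np.nan, np.nan, True))
            continue
        bp, beta_plv = _circuit_band_powers(traj, transient, readout_fs)
        rows.append((w_local, bp.beta_scalar, bp.gamma_scalar, beta_plv, False))
    if n_hyper == len(rows):
        raise HyperExcitationError("every grid point is hyper-excitatory")
    df = pd.DataFrame(rows, columns=["strength", "beta_power", "gamma_power",
                                     "beta_plv", "hyper"])
    ok = df[~df.hyper & (df.gamma_power > df.beta_power)]
    df.attrs["crossover"] = float(ok.strength.iloc[0]) if len(ok) else None
    return df
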