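"""Whole-cell voltage-clamp analysis for low-voltage-activated Ca2+ currents.

Operates on ensembles of current sweeps recorded under step protocols:

* peak current-voltage extraction (signed extremum after baseline
  subtraction; inward currents are negative),
* Boltzmann fits of the activation curve from the peak I-V with a linear
  driving force,
* mono-exponential fits of inactivation (current decay) and recovery from
  inactivation (envelope protocols),
* fraction of non-inactivated channels from paired pre/post peaks,
* window current (overlap of activation and steady-state inactivation),
* current density, and
* non-stationary noise analysis: across repeated identical sweeps the
  isochronal variance and mean obey ``sigma^2 = i <I> - <I>^2 / N`` for N
  channels of unitary current i; the initial slope of variance against mean
  yields i even when the curvature (hence N and the open probability) is not
  resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

__all__ = [
    "VoltageProtocol",
    "TraceEnsemble",
    "BoltzmannFit",
    "ExpFit",
    "NoiseFit",
    "boltzmann_act",
    "boltzmann_inact",
    "peak_iv",
    "fit_activation",
    "fit_inactivation_curve",
    "fit_decay_tau",
    "fraction_noninactivated",
    "fit_recovery",
    "window_current",
    "current_density",
    "noise_analysis",
    "read_traces_tsv",
    "write_traces_tsv",
]


def boltzmann_act(v, v_half: float, k: float):
    """Rising Boltzmann: 0 at hyperpolarized, 1 at depolarized potentials."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


def boltzmann_inact(v, v_half: float, k: float):
    """Falling Boltzmann (steady-state availability)."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / k))


@dataclass
class VoltageProtocol:
    """Step protocol: ordered (voltage mV, duration ms) segments.

    For step families, exactly one segment varies across sweeps
    (``varying_segment``), taking the voltages in ``sweep_voltages``.
    """

    segments: list[tuple[float, float]]
    sampling_interval: float
    varying_segment: int | None = None
    sweep_voltages: list[float] | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if self.varying_segment is not None and not (
            0 <= self.varying_segment < len(self.segments)
        ):
            raise ValueError("varying segment index out of range")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.sampling_interval))

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval

    def segment_bounds(self) -> list[tuple[float, float]]:
        """(start, end) time in ms of each segment."""
        edges = np.concatenate([[0.0], np.cumsum([d for _, d in self.segments])])
        return list(zip(edges[:-1], edges[1:]))

    def segment_slice(self, index: int) -> slice:
        t0, t1 = self.segment_bounds()[index]
        dt = self.sampling_interval
        return slice(int(round(t0 / dt)), int(round(t1 / dt)))

    def voltage_trace(self, sweep: int = 0) -> np.ndarray:
        v = np.empty(self.n_samples)
        for i, (volt, _) in enumerate(self.segments):
            if i == self.varying_segment and self.sweep_voltages is not None:
                volt = self.sweep_voltages[sweep]
            v[self.segment_slice(i)] = volt
        return v

    @property
    def n_sweeps(self) -> int:
        return 1 if self.sweep_voltages is None else len(self.sweep_voltages)

    def to_yaml(self, path) -> None:
        payload = {
            "segments": [[float(v), float(d)] for v, d in self.segments],
            "sampling_interval_ms": float(self.sampling_interval),
            "varying_segment": self.varying_segment,
            "sweep_voltages_mV": None
            if self.sweep_voltages is None
            else [float(v) for v in self.sweep_voltages],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "VoltageProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            segments=[tuple(s) for s in d["segments"]],
            sampling_interval=d["sampling_interval_ms"],
            varying_segment=d.get("varying_segment"),
            sweep_voltages=d.get("sweep_voltages_mV"),
        )


@dataclass
class TraceEnsemble:
    """Time-aligned current sweeps (pA) under one protocol.

    ``currents`` has shape (n_samples, n_sweeps).  ``sweep_voltages`` holds
    the step voltage of the varying segment per sweep (equal-length for
    repeated-identical-sweep ensembles used in noise analysis).
    """

    time: np.ndarray
    currents: np.ndarray
    protocol: VoltageProtocol
    sweep_voltages: np.ndarray | None = None
    capacitance: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        if self.currents.shape[0] != self.time.size:
            raise ValueError("current matrix rows must match the time vector")
        dt = np.diff(self.time)
        if self.time.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("time vector must be uniformly sampled")
        if self.sweep_voltages is not None:
            self.sweep_voltages = np.asarray(self.sweep_voltages, dtype=float)
            if self.sweep_voltages.size != self.currents.shape[1]:
                raise ValueError("one step voltage per sweep required")

    @property
    def n_sweeps(self) -> int:
        return self.currents.shape[1]

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else math.nan


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann activation fit of a peak I-V relation."""

    v_half: float
    k: float
    g_max: float  # nS
    v_rev: float
    residual_norm: float
    converged: bool

    def activation(self, v) -> np.ndarray:
        """Normalized activation curve at voltage(s) ``v``."""
        return boltzmann_act(v, self.v_half, self.k)


@dataclass(frozen=True)
class ExpFit:
    """Mono-exponential fit ``y(t) = amplitude * exp(-t/tau) + offset``."""

    tau: float
    amplitude: float
    offset: float
    window: tuple[float, float]
    converged: bool
    monotone: bool = True


@dataclass
class NoiseFit:
    """Result of non-stationary noise analysis at a fixed voltage."""

    i_fA: float
    background_var_pA2: float
    fit_fraction: float
    n_points_fit: int
    slope_pA: float
    intercept_pA2: float
    mean_pA: np.ndarray = field(repr=False)
    var_pA2: np.ndarray = field(repr=False)
    n_channels: float | None = None
    p_open_max: float | None = None
    curvature_resolved: bool = False


def _holding_segment(protocol: VoltageProtocol) -> int:
    """Index of the holding segment preceding the varying (or last) segment."""
    ref = protocol.varying_segment
    if ref is None or ref == 0:
        return 0
    return ref - 1


def peak_iv(ensemble: TraceEnsemble, baseline_ms: float = 50.0) -> pd.DataFrame:
    """Peak current per sweep: signed extremum within the step window.

    Baseline is the mean current over (up to) the final ``baseline_ms`` of
    the holding segment preceding the step.  Returns a DataFrame with
    columns ``voltage_mV, peak_pA, t_peak_ms``.
    """
    prot = ensemble.protocol
    if prot.varying_segment is None:
        raise ValueError("protocol must define a varying step segment")
    step = prot.segment_slice(prot.varying_segment)
    if step.stop > ensemble.currents.shape[0]:
        raise ValueError("step window extends beyond the recorded traces")
    hold = prot.segment_slice(_holding_segment(prot))
    n_base = max(1, int(round(baseline_ms / prot.sampling_interval)))
    base_slice = slice(max(hold.start, hold.stop - n_base), hold.stop)

    voltages = (
        ensemble.sweep_voltages
        if ensemble.sweep_voltages is not None
        else np.array([prot.sweep_voltages[i] for i in range(ensemble.n_sweeps)])
    )
    rows = []
    for s in range(ensemble.n_sweeps):
        trace = ensemble.currents[:, s]
        baseline = trace[base_slice].mean()
        seg = trace[step] - baseline
        k = int(np.argmax(np.abs(seg)))
        rows.append(
            {
                "voltage_mV": float(voltages[s]),
                "peak_pA": float(seg[k]),
                "t_peak_ms": float(ensemble.time[step][k]),
            }
        )
    return pd.DataFrame(rows)


def fit_activation(
    iv: pd.DataFrame, v_rev: float = 60.0, mode: str = "current"
) -> BoltzmannFit:
    """Boltzmann fit of the activation curve from a peak I-V table.

    In ``"current"`` mode (default) the fit is performed jointly with the
    linear driving force, ``I(V) = G_max (V - V_rev) / (1 + exp((V_half -
    V)/k))``; in ``"conductance"`` mode peaks are first converted to
    ``G = I/(V - V_rev)`` and a plain Boltzmann is fitted.
    """
    v = iv["voltage_mV"].to_numpy(dtype=float)
    i = iv["peak_pA"].to_numpy(dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 voltages spanning the rising phase")
    g_scale = np.abs(i).max() / max(1e-12, np.abs(v - v_rev).min())
    # data-driven start: half-max crossing of |I| on the rising limb
    imax_idx = int(np.argmax(np.abs(i)))
    rising_v, rising_i = v[: imax_idx + 1], np.abs(i[: imax_idx + 1])
    half = rising_i.max() / 2.0
    above = np.nonzero(rising_i >= half)[0]
    v_half0 = float(rising_v[above[0]]) if above.size else float(v[imax_idx])
    p0 = [v_half0, 6.0, g_scale]

    if mode == "current":

        def model(vv, v_half, k, g_max):
            return g_max * (vv - v_rev) * boltzmann_act(vv, v_half, k)

        y = i
    elif mode == "conductance":

        def model(vv, v_half, k, g_max):
            return g_max * boltzmann_act(vv, v_half, k)

        y = i / (v - v_rev)
    else:
        raise ValueError("mode must be 'current' or 'conductance'")

    converged = True
    try:
        popt, _ = optimize.curve_fit(model, v, y, p0=p0, maxfev=20000)
    except RuntimeError:
        popt, converged = p0, False
    v_half, k, g_max = (float(x) for x in popt)
    if k < 0:  # slope-sign degeneracy: fold back to the k > 0 branch
        converged = False
    resid = float(np.linalg.norm(y - model(v, *popt)))
    return BoltzmannFit(
        v_half=v_half,
        k=abs(k),
        g_max=g_max,
        v_rev=v_rev,
        residual_norm=resid,
        converged=converged,
    )


def fit_inactivation_curve(voltages, availability) -> BoltzmannFit:
    """Falling-Boltzmann fit of steady-state inactivation (availability vs V)."""
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(availability, dtype=float)
    half = (y.max() + y.min()) / 2.0
    v_half0 = float(v[np.argmin(np.abs(y - half))])

    def model(vv, v_half, k, top):
        return top * boltzmann_inact(vv, v_half, k)

    converged = True
    try:
        popt, _ = optimize.curve_fit(model, v, y, p0=[v_half0, 6.0, y.max()], maxfev=20000)
    except RuntimeError:
        popt, converged = [v_half0, 6.0, y.max()], False
    resid = float(np.linalg.norm(y - model(v, *popt)))
    return BoltzmannFit(
        v_half=float(popt[0]),
        k=abs(float(popt[1])),
        g_max=float(popt[2]),
        v_rev=math.nan,
        residual_norm=resid,
        converged=converged,
    )


def _fit_monoexp(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Fit ``y = A exp(-t'/tau) + C`` with log-linear initialization.

    ``t`` is shifted to start at 0.  Returns (tau, A, C, converged).
    """
    t = np.asarray(t, dtype=float) - t[0]
    y = np.asarray(y, dtype=float)
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    dev = (y - c0) / a0 if a0 != 0 else np.zeros_like(y)
    pos = (dev > 1e-3) & (t > 0)
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(dev[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else t[-1] / 3.0
    else:
        tau0 = t[-1] / 3.0
    tau0 = min(max(tau0, 1e-6), 100 * t[-1])

    def model(tt, tau, a, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[tau0, a0, c0], maxfev=20000, xtol=1e-12, ftol=1e-12
        )
        tau, a, c = (float(x) for x in popt)
        converged = tau > 0
    except RuntimeError:
        tau, a, c, converged = tau0, a0, c0, False
    return abs(tau), a, c, converged


def fit_decay_tau(
    ensemble: TraceEnsemble,
    voltage_range: tuple[float, float] = (-50.0, 30.0),
    baseline_ms: float = 50.0,
) -> pd.DataFrame:
    """Inactivation time constants from the current decay after the peak.

    For every sweep whose step voltage lies in ``voltage_range``, fits a
    mono-exponential from the time of peak to the end of the step.  Returns
    a DataFrame (voltage_mV, tau_ms, amplitude_pA, offset_pA, converged,
    monotone); a sweep whose decay is not monotone within the fit window is
    flagged, not dropped.
    """
    prot = ensemble.protocol
    iv = peak_iv(ensemble, baseline_ms=baseline_ms)
    step = prot.segment_slice(prot.varying_segment)
    rows = []
    for s in range(ensemble.n_sweeps):
        v = iv.loc[s, "voltage_mV"]
        if not voltage_range[0] <= v <= voltage_range[1]:
            continue
        trace = ensemble.currents[step, s]
        t = ensemble.time[step]
        k = int(np.argmin(np.abs(t - iv.loc[s, "t_peak_ms"])))
        if k >= len(t) - 3:
            continue
        tau, a, c, conv = _fit_monoexp(t[k:], trace[k:])
        dev = np.abs(trace[k:] - c)
        coarse = dev[:: max(1, len(dev) // 20)]
        monotone = bool(np.all(np.diff(coarse) <= np.abs(a) * 0.05))
        rows.append(
            {
                "voltage_mV": float(v),
                "tau_ms": tau,
                "amplitude_pA": a,
                "offset_pA": c,
                "converged": conv,
                "monotone": monotone,
            }
        )
    return pd.DataFrame(rows)


def fraction_noninactivated(
    pre_peaks, post_peaks, prepulse_voltages=None
) -> pd.DataFrame:
    """Percent of current remaining after long inactivating prepulses.

    ``100 * |post| / |pre|`` per prepulse voltage.  The summary value is the
    row at the most depolarized prepulse (where inactivation is maximal).
    """
    pre = np.atleast_1d(np.asarray(pre_peaks, dtype=float))
    post = np.atleast_1d(np.asarray(post_peaks, dtype=float))
    if np.any(pre == 0):
        raise ValueError("pre-pulse peak of 0: fraction undefined")
    frac = 100.0 * np.abs(post) / np.abs(pre)
    if prepulse_voltages is None:
        prepulse_voltages = np.arange(len(pre))
    return pd.DataFrame(
        {
            "prepulse_mV": np.asarray(prepulse_voltages, dtype=float),
            "percent_noninactivated": frac,
        }
    )


def fit_recovery(intervals_ms, relative_peaks) -> ExpFit:
    """Time constant of recovery from inactivation from an envelope protocol.

    Fits ``y(t) = y_inf - (y_inf - y_0) exp(-t/tau)`` to relative peak
    amplitude versus the time spent at the recovery potential.
    """
    t = np.asarray(intervals_ms, dtype=float)
    y = np.asarray(relative_peaks, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 recovery intervals")
    order = np.argsort(t)
    t, y = t[order], y[order]
    tau, a, c, conv = _fit_monoexp(t, y)
    return ExpFit(
        tau=tau,
        amplitude=a,
        offset=c,
        window=(float(t[0]), float(t[-1])),
        converged=conv,
    )


def window_current(
    act: BoltzmannFit,
    inact: BoltzmannFit,
    v_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Overlap of activation and steady-state inactivation curves.

    Integrates ``min(act(V), inact(V))`` over the voltage grid (trapezoid
    rule) on normalized curves.  Returns (area in mV-units of normalized
    probability, voltage of maximal overlap).
    """
    if v_grid is None:
        v_grid = np.linspace(-100.0, 20.0, 1201)
    v_grid = np.asarray(v_grid, dtype=float)
    a = boltzmann_act(v_grid, act.v_half, act.k)
    h = boltzmann_inact(v_grid, inact.v_half, inact.k)
    overlap = np.minimum(a, h)
    area = float(np.trapezoid(overlap, v_grid))
    return area, float(v_grid[np.argmax(overlap)])


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Peak current normalized to cell capacitance (pA/pF)."""
    if capacitance_pF is None or not capacitance_pF > 0:
        raise ValueError("capacitance must be positive")
    return peak_pA / capacitance_pF


def noise_analysis(
    ensemble: TraceEnsemble,
    analysis_segment: int | None = None,
    fit_fraction: float = 0.3,
    background_ms: float = 50.0,
    min_sweeps: int = 100,
    curvature_z: float = 3.0,
) -> NoiseFit:
    """Non-stationary noise analysis of repeated identical sweeps.

    Computes the isochronal ensemble mean and variance over the analysis
    segment (default: the final segment, i.e. the repolarization tail),
    subtracts the background variance measured over the final
    ``background_ms`` of the holding segment, and fits the initial slope of
    variance against mean current restricted to ``|<I>| <= fit_fraction *
    max |<I>|``.  The slope magnitude is the unitary current.  The channel
    count ``N = -1/b`` from the quadratic term ``b`` is reported only when
    the curvature is resolved (``b`` negative and ``|b| > curvature_z *
    SE(b)``); otherwise ``n_channels`` and ``p_open_max`` stay ``None``.
    """
    if ensemble.n_sweeps < min_sweeps:
        raise ValueError(
            f"noise analysis requires >= {min_sweeps} sweeps, got {ensemble.n_sweeps}"
        )
    prot = ensemble.protocol
    if analysis_segment is None:
        analysis_segment = len(prot.segments) - 1
    seg = prot.segment_slice(analysis_segment)
    hold = prot.segment_slice(0)
    n_bg = max(1, int(round(background_ms / prot.sampling_interval)))
    bg = slice(max(hold.start, hold.stop - n_bg), hold.stop)

    mean_t = ensemble.currents.mean(axis=1)
    var_t = ensemble.currents.var(axis=1, ddof=1)
    scale = float(np.abs(ensemble.currents).max())
    if var_t.max() <= 1e-12 * max(1.0, scale**2):
        raise ValueError("deterministic input: ensemble variance is zero")
    background_var = float(var_t[bg].mean())
    baseline = float(mean_t[bg].mean())

    mean_seg = mean_t[seg] - baseline
    var_seg = var_t[seg] - background_var

    x = np.abs(mean_seg)
    y = var_seg
    cut = fit_fraction * x.max()
    sel = x <= cut
    if sel.sum() < 3:
        raise ValueError("too few points below the fit-fraction cutoff")
    # initial-slope fit: OLS pass, then one inverse-variance reweighted pass
    # (Var of a sample variance scales with the squared true variance, so
    # high-current isochrones are noisier and are downweighted)
    slope, intercept = np.polyfit(x[sel], y[sel], 1)
    n_sw = ensemble.n_sweeps
    pred = np.abs(slope) * x[sel] + max(intercept, 0.0) + background_var
    w = 1.0 / (2.0 * pred**2 / (n_sw - 1))
    design1 = np.column_stack([x[sel], np.ones(sel.sum())])
    wsqrt = np.sqrt(w)
    coef1, *_ = np.linalg.lstsq(design1 * wsqrt[:, None], y[sel] * wsqrt, rcond=None)
    slope, intercept = float(coef1[0]), float(coef1[1])

    # curvature check on the full parabola sigma^2 = i x + b x^2
    design = np.column_stack([x, x**2, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    b = coef[1]
    dof = max(1, len(x) - 3)
    sigma2 = (res[0] / dof) if len(res) else float(np.var(y - design @ coef))
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se_b = math.sqrt(cov[1, 1])
    resolved = bool(b < 0 and abs(b) > curvature_z * se_b)
    n_channels = p_open = None
    if resolved:
        n_channels = -1.0 / b
        p_open = float(x.max() / (abs(coef[0]) * n_channels))

    return NoiseFit(
        i_fA=float(abs(slope)) * 1e3,
        background_var_pA2=background_var,
        fit_fraction=fit_fraction,
        n_points_fit=int(sel.sum()),
        slope_pA=float(slope),
        intercept_pA2=float(intercept),
        mean_pA=mean_seg,
        var_pA2=var_seg,
        n_channels=n_channels,
        p_open_max=p_open,
        curvature_resolved=resolved,
    )


def read_traces_tsv(path, protocol: VoltageProtocol, **kwargs) -> TraceEnsemble:
    """Read a trace ensemble from TSV (column 1 time ms, one column per sweep)."""
    df = pd.read_csv(path, sep="\t")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    currents = df.iloc[:, 1:].to_numpy(dtype=float)
    return TraceEnsemble(time=time, currents=currents, protocol=protocol, **kwargs)


def write_traces_tsv(path, ensemble: TraceEnsemble) -> None:
    cols = {"time_ms": ensemble.time}
    for s in range(ensemble.n_sweeps):
        cols[f"sweep_{s}"] = ensemble.currents[:, s]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_traces_h5(path, ensemble: TraceEnsemble) -> None:
    """HDF5 container with the same schema as the TSV dialect."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=ensemble.time)
        fh.create_dataset("currents_pA", data=ensemble.currents)
        if ensemble.sweep_voltages is not None:
            fh.create_dataset("sweep_voltages_mV", data=ensemble.sweep_voltages)
        if ensemble.capacitance is not None:
            fh.attrs["capacitance_pF"] = ensemble.capacitance


def read_traces_h5(path, protocol: VoltageProtocol) -> TraceEnsemble:
    import h5py

    with h5py.File(path, "r") as fh:
        time = fh["time_ms"][:]
        currents = fh["currents_pA"][:]
        volts = fh["sweep_voltages_mV"][:] if "sweep_voltages_mV" in fh else None
        cap = fh.attrs.get("capacitance_pF")
    return TraceEnsemble(
        time=time,
        currents=currents,
        protocol=protocol,
        sweep_voltages=volts,
        capacitance=None if cap is None else float(cap),
    )
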