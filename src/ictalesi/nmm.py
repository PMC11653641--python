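"""Modified Jansen-Rit (Wendling-type) neural mass model of ictal dynamics.

A single cortical region is modeled by four interacting neural
subpopulations: pyramidal cells, excitatory interneurons, slow (dendritic)
inhibitory interneurons and fast (somatic) inhibitory interneurons.  Each
synapse turns a presynaptic firing rate into a postsynaptic membrane
potential through the impulse response ``h(t) = Q q t exp(-q t)`` and each
population turns its mean membrane potential into a firing rate through a
static sigmoid.  Depending on the synaptic gains (A, B, G) and the synaptic
rate constants (a, b, g) the model produces background activity, sporadic or
sustained epileptic spikes, rhythmic discharges, low-voltage fast activity
or quasi-sinusoidal oscillations -- the waveform families seen at seizure
onset in intracranial recordings.

This module simulates the model, extracts waveform features, classifies
traces into the six regime types, explores parameter grids and builds
balanced banks of ictal parameter sets used to synthesize training data for
the inverse network.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "SigmoidParams",
    "NMMParams",
    "NMMTrace",
    "WaveformFeatures",
    "RegimeLabel",
    "ClassifierThresholds",
    "GridSpec",
    "BankEntry",
    "ParameterBank",
    "NMMDivergenceError",
    "psp_kernel",
    "sigmoid_rate",
    "simulate_nmm",
    "simulate_nmm_batch",
    "simulate_nmm_switch",
    "waveform_features",
    "classify_regime",
    "explore_parameter_grid",
    "balance_parameter_sets",
]

#: internal integration step (s); traces are decimated to the output rate
DT = 1.0e-3

ICTAL_TYPES = (2, 3, 4, 5, 6)

REGIME_NAMES = {
    1: "normal activity",
    2: "sporadic spikes",
    3: "sustained discharge of spikes",
    4: "rhythmic activity",
    5: "low voltage rapid activity",
    6: "quasi-sinusoidal activity",
}


class NMMDivergenceError(RuntimeError):
    """Raised when the state of the neural mass model becomes non-finite."""


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the firing-rate sigmoid ``S(v) = 2 e0 / (1 + exp(r (v0 - v)))``.

    Attributes
    ----------
    e0 : float
        Half of the maximum firing rate (s^-1).
    v0 : float
        Potential of half activation (mV).
    r : float
        Steepness (mV^-1).
    """

    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56

    def __post_init__(self) -> None:
        if not (self.e0 > 0 and self.v0 > 0 and self.r > 0):
            raise ValueError("sigmoid parameters must be strictly positive")


@dataclass(frozen=True)
class NMMParams:
    """One parameter set of the modified Jansen-Rit unit.

    Gains are in mV, rate constants in ms^-1 as conventionally printed;
    they are converted to s^-1 internally.  ``C`` and ``c1..c7`` set the
    intrinsic connectivity, ``p_mean``/``p_sd`` the extrinsic white-noise
    drive (s^-1).
    """

    A: float = 5.5
    B: float = 22.0
    G: float = 10.0
    a: float = 0.1
    b: float = 0.05
    g: float = 0.5
    C: float = 135.0
    c1: float = 1.0
    c2: float = 0.8
    c3: float = 0.25
    c4: float = 0.25
    c5: float = 0.3
    c6: float = 0.1
    c7: float = 0.8
    p_mean: float = 90.0
    p_sd: float = 30.0
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0 and self.G > 0):
            raise ValueError("gains A, B, G must be strictly positive")
        if not (self.a > 0 and self.b > 0 and self.g > 0):
            raise ValueError("rate constants a, b, g must be strictly positive")
        if any(getattr(self, f"c{i}") < 0 for i in range(1, 8)):
            raise ValueError("connectivity multipliers c1..c7 must be >= 0")
        if self.p_sd < 0:
            raise ValueError("p_sd must be >= 0")

    def replace(self, **kw) -> "NMMParams":
        return dataclasses.replace(self, **kw)


@dataclass
class NMMTrace:
    """A simulated membrane-potential time series (mV) after burn-in removal."""

    values: np.ndarray
    sample_rate: float
    burn_in: float
    params: NMMParams
    seed: int

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar waveform descriptors used by the regime classifier.

    ``line_length`` is the mean absolute first difference scaled to mV/s,
    ``major_frequency`` the frequency of maximum power of the detrended
    trace (NaN for a constant trace), ``baseline_voltage`` the median,
    ``spectral_concentration`` the fraction of 0.5-45 Hz power within
    +-1 Hz of the major frequency and ``amplitude`` the 95th percentile of
    the absolute detrended trace.  ``spike_rate``/``spike_isi_cv`` are
    auxiliary statistics of transient peaks exceeding the baseline by three
    median absolute deviations.
    """

    line_length: float
    major_frequency: float
    baseline_voltage: float
    spectral_concentration: float
    amplitude: float
    spike_rate: float = 0.0
    spike_isi_cv: float = np.inf

    def as_tuple(self) -> tuple:
        return (
            self.line_length,
            self.major_frequency,
            self.baseline_voltage,
            self.spectral_concentration,
            self.amplitude,
        )


@dataclass(frozen=True)
class RegimeLabel:
    label: int
    features: WaveformFeatures

    def __post_init__(self) -> None:
        if self.label not in range(1, 7):
            raise ValueError("regime label must be in 1..6")

    @property
    def name(self) -> str:
        return REGIME_NAMES[self.label]

    @property
    def is_ictal(self) -> bool:
        return self.label in ICTAL_TYPES


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the regime classifier (config-exposed).

    The classifier is a fixed decision table: a trace is *normal* (type 1)
    below ``amplitude_min``; otherwise *low-voltage rapid* (type 5) above
    ``fast_frequency``; otherwise *quasi-sinusoidal* (type 6) above
    ``concentration_min``; otherwise spikes above baseline +
    ``mad_factor`` x MAD split *sporadic* (type 2, rate below
    ``sustained_rate``) from *sustained* discharges (type 3, regular
    inter-spike intervals); everything else is *rhythmic* (type 4).
    """

    amplitude_min: float = 2.0  # mV
    fast_frequency: float = 12.0  # Hz
    concentration_min: float = 0.85
    sustained_rate: float = 2.0  # Hz
    isi_cv_max: float = 0.3
    mad_factor: float = 3.0


def psp_kernel(Q: float, q: float, t) -> np.ndarray:
    """Postsynaptic impulse response ``h(t) = Q q t exp(-q t)`` for t >= 0.

    ``Q`` is the synaptic gain (mV) and ``q`` the rate constant (same time
    unit as ``t``).  The kernel peaks at ``t = 1/q`` with value ``Q/e`` and
    integrates to ``Q``.
    """
    if Q <= 0 or q <= 0:
        raise ValueError("Q and q must be strictly positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("psp_kernel is defined for t >= 0 only")
    return Q * q * t * np.exp(-q * t)


def sigmoid_rate(v, s: SigmoidParams = SigmoidParams()) -> np.ndarray:
    """Firing-rate sigmoid ``S(v) = 2 e0 / (1 + exp(r (v0 - v)))`` (s^-1)."""
    v = np.asarray(v, dtype=float)
    return 2.0 * s.e0 / (1.0 + np.exp(np.clip(s.r * (s.v0 - v), -500.0, 500.0)))


def _as_arrays(params: Sequence[NMMParams]):
    """Stack per-parameter-set scalars into arrays, converting ms^-1 -> s^-1."""
    get = lambda name: np.array([getattr(p, name) for p in params], dtype=float)
    A, B, G = get("A"), get("B"), get("G")
    a, b, g = get("a") * 1e3, get("b") * 1e3, get("g") * 1e3
    C = get("C")
    cs = {f"c{i}": get(f"c{i}") for i in range(1, 8)}
    return A, B, G, a, b, g, C, cs


def _integrate(
    params: Sequence[NMMParams],
    duration: float,
    sample_rate: float,
    seeds: Sequence[int],
    burn_in: float,
    params2: Sequence[NMMParams] | None = None,
    switch_steps: np.ndarray | None = None,
    raise_on_divergence: bool = True,
):
    """Euler-Maruyama integration of the 10-state system, batched over sets.

    Returns ``(traces, finite_mask)`` with ``traces`` of shape
    ``(n_sets, n_samples)`` holding the pyramidal-population potential
    ``y1 - y2 - y3`` after burn-in removal, decimated to ``sample_rate``.
    When ``params2``/``switch_steps`` are given, set *i* switches to its
    second parameter set at integration step ``switch_steps[i]`` with the
    state carried over (continuous trace).
    """
    n = len(params)
    decim = 1.0 / (DT * sample_rate)
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(
            f"sample_rate {sample_rate} must divide the internal rate {1 / DT:.0f} Hz"
        )
    decim = int(round(decim))
    n_steps = int(round((duration + burn_in) * sample_rate)) * decim
    burn_steps = int(round(burn_in * sample_rate)) * decim

    A, B, G, a, b, g, C, cs = _as_arrays(params)
    if params2 is not None:
        A2, B2, G2, a2, b2, g2, _, _ = _as_arrays(params2)
    sig = params[0].sigmoid
    if any(p.sigmoid != sig for p in params):
        raise ValueError("batched simulation requires a shared sigmoid")
    e0x2, v0, r = 2.0 * sig.e0, sig.v0, sig.r
    p_mean = np.array([p.p_mean for p in params], dtype=float)
    p_sd = np.array([p.p_sd for p in params], dtype=float)

    c1C, c2C = cs["c1"] * C, cs["c2"] * C
    c3C, c4C = cs["c3"] * C, cs["c4"] * C
    c5C, c6C, c7C = cs["c5"] * C, cs["c6"] * C, cs["c7"] * C

    # per-set white-noise drive, one draw per integration step
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    noise = np.empty((n, n_steps))
    for i, rng in enumerate(rngs):
        noise[i] = rng.standard_normal(n_steps)
    p_drive = p_mean[:, None] + p_sd[:, None] * noise

    y = np.zeros((10, n))  # y0..y4 and their derivatives y5..y9
    out = np.empty((n, n_steps // decim))
    finite = np.ones(n, dtype=bool)

    def S(v):
        return e0x2 / (1.0 + np.exp(np.clip(r * (v0 - v), -500.0, 500.0)))

    Aa, Bb, Gg = A * a, B * b, G * g
    for step in range(n_steps):
        if switch_steps is not None:
            sw = step >= switch_steps
            if np.any(sw):
                A = np.where(sw, A2, A)
                B = np.where(sw, B2, B)
                G = np.where(sw, G2, G)
                a = np.where(sw, a2, a)
                b = np.where(sw, b2, b)
                g = np.where(sw, g2, g)
                Aa, Bb, Gg = A * a, B * b, G * g
        y0, y1, y2, y3, y4, y5, y6, y7, y8, y9 = y
        vpyr = y1 - y2 - y3
        d5 = Aa * S(vpyr) - 2.0 * a * y5 - a * a * y0
        d6 = Aa * (p_drive[:, step] + c2C * S(c1C * y0)) - 2.0 * a * y6 - a * a * y1
        d7 = Bb * c4C * S(c3C * y0) - 2.0 * b * y7 - b * b * y2
        d8 = Gg * c7C * S(c5C * y0 - c6C * y4) - 2.0 * g * y8 - g * g * y3
        d9 = Bb * S(c3C * y0) - 2.0 * b * y9 - b * b * y4
        y[0] += DT * y5
        y[1] += DT * y6
        y[2] += DT * y7
        y[3] += DT * y8
        y[4] += DT * y9
        y[5] += DT * d5
        y[6] += DT * d6
        y[7] += DT * d7
        y[8] += DT * d8
        y[9] += DT * d9
        if step % decim == decim - 1:
            out[:, step // decim] = y[1] - y[2] - y[3]

    finite = np.all(np.isfinite(out), axis=1)
    if raise_on_divergence and not np.all(finite):
        bad = int(np.flatnonzero(~finite)[0])
        raise NMMDivergenceError(
            f"neural mass model diverged for parameter set {params[bad]}"
        )
    return out[:, burn_steps // decim :], finite


def simulate_nmm(
    params: NMMParams,
    duration: float = 5.0,
    sample_rate: float = 500.0,
    seed: int = 0,
    burn_in: float = 2.0,
) -> NMMTrace:
    """Simulate one unit and return its output potential after burn-in.

    The output is the net postsynaptic potential at the pyramidal
    population (excitatory minus slow- and fast-inhibitory PSPs), the
    quantity that drives the equivalent current dipole of the region.
    Identical ``(params, seed)`` give identical traces.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    traces, _ = _integrate([params], duration, sample_rate, [seed], burn_in)
    return NMMTrace(traces[0], sample_rate, burn_in, params, seed)


def simulate_nmm_batch(
    params: Sequence[NMMParams],
    duration: float = 5.0,
    sample_rate: float = 500.0,
    seeds: Sequence[int] | None = None,
    burn_in: float = 2.0,
    raise_on_divergence: bool = True,
):
    """Vectorized :func:`simulate_nmm` over many parameter sets.

    Returns ``(traces, finite_mask)`` with one row per parameter set.
    """
    if seeds is None:
        seeds = range(len(params))
    return _integrate(
        list(params), duration, sample_rate, list(seeds), burn_in,
        raise_on_divergence=raise_on_divergence,
    )


def simulate_nmm_switch(
    params_pre: Sequence[NMMParams],
    params_post: Sequence[NMMParams],
    switch_times: Sequence[float],
    duration: float = 5.0,
    sample_rate: float = 500.0,
    seeds: Sequence[int] | None = None,
    burn_in: float = 2.0,
):
    """Batched simulation with an instantaneous parameter swap per trace.

    ``switch_times`` are seconds relative to the start of the *output*
    window (after burn-in); the state is carried over, so the trace is
    continuous through the regime change.
    """
    if seeds is None:
        seeds = range(len(params_pre))
    steps = np.array(
        [int(round((burn_in + t) / DT)) for t in switch_times], dtype=int
    )
    return _integrate(
        list(params_pre), duration, sample_rate, list(seeds), burn_in,
        params2=list(params_post), switch_steps=steps,
    )


# ---------------------------------------------------------------------------
# waveform features and regime classification
# ---------------------------------------------------------------------------

def waveform_features(
    trace, sample_rate: float | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> WaveformFeatures:
    """Compute the scalar descriptors used for regime classification."""
    if isinstance(trace, NMMTrace):
        values, fs = trace.values, trace.sample_rate
    else:
        values = np.asarray(trace, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        fs = float(sample_rate)
    if values.size < 2 * fs:
        raise ValueError("need at least 2 s of signal for waveform features")

    line_length = float(np.mean(np.abs(np.diff(values))) * fs)
    baseline = float(np.median(values))
    detrended = sp_signal.detrend(values)
    amplitude = float(np.percentile(np.abs(detrended), 95))

    if np.ptp(values) == 0:
        return WaveformFeatures(0.0, np.nan, baseline, 0.0, 0.0)

    nper = min(values.size, int(round(2 * fs)))
    freqs, psd = sp_signal.welch(detrended, fs=fs, nperseg=nper)
    band = (freqs >= 0.5) & (freqs <= 45.0)
    if not np.any(band) or np.all(psd[band] == 0):
        major, concentration = np.nan, 0.0
    else:
        fb, pb = freqs[band], psd[band]
        major = float(fb[np.argmax(pb)])
        near = np.abs(fb - major) <= 1.0
        concentration = float(pb[near].sum() / pb.sum())

    # transient spikes: strict local maxima above baseline + k * MAD
    mad = float(np.median(np.abs(values - baseline)))
    height = baseline + thresholds.mad_factor * mad
    peaks, _ = sp_signal.find_peaks(values, height=height)
    duration = values.size / fs
    spike_rate = peaks.size / duration
    if peaks.size >= 3:
        isi = np.diff(peaks) / fs
        cv = float(np.std(isi) / np.mean(isi)) if np.mean(isi) > 0 else np.inf
    else:
        cv = np.inf
    return WaveformFeatures(
        line_length, major, baseline, concentration, amplitude,
        float(spike_rate), cv,
    )


def classify_regime(
    features: WaveformFeatures,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> RegimeLabel:
    """Label a feature tuple with one of the six regime types (total function)."""
    t = thresholds
    if not np.isfinite(features.amplitude) or features.amplitude < t.amplitude_min:
        label = 1
    elif np.isfinite(features.major_frequency) and features.major_frequency > t.fast_frequency:
        label = 5
    elif features.spectral_concentration > t.concentration_min:
        label = 6
    elif 0.0 < features.spike_rate < t.sustained_rate:
        label = 2
    elif features.spike_rate >= t.sustained_rate and features.spike_isi_cv < t.isi_cv_max:
        label = 3
    else:
        label = 4
    return RegimeLabel(label, features)


# ---------------------------------------------------------------------------
# grid exploration and parameter banks
# ---------------------------------------------------------------------------

def _grid_values(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass(frozen=True)
class GridSpec:
    """Inclusive arithmetic ranges ``(start, stop, step)`` for each parameter.

    Defaults are the full exploration grid: B 2..60 by 2 mV, G 2..30 by
    2 mV, a 0.05..0.15 by 0.01 ms^-1, b 0.025..0.075 by 0.005 ms^-1,
    g 0.2..1.6 by 0.2 ms^-1, with A fixed.
    """

    A: float = 5.5
    B: tuple = (2.0, 60.0, 2.0)
    G: tuple = (2.0, 30.0, 2.0)
    a: tuple = (0.05, 0.15, 0.01)
    b: tuple = (0.025, 0.075, 0.005)
    g: tuple = (0.2, 1.6, 0.2)

    def values(self, name: str) -> np.ndarray:
        return _grid_values(*getattr(self, name))

    def thin(self, every: int) -> "GridSpec":
        """Keep every ``every``-th value per axis (reduced grid)."""
        def sub(rng):
            v = _grid_values(*rng)[::every]
            return (float(v[0]), float(v[-1]), float(rng[2] * every))
        return GridSpec(self.A, sub(self.B), sub(self.G), sub(self.a),
                        sub(self.b), sub(self.g))

    @property
    def shape(self) -> tuple:
        return tuple(len(self.values(k)) for k in "BGabg")


@dataclass
class BankEntry:
    params: NMMParams
    label: RegimeLabel
    seed: int
    split: str = ""  # "", "train" or "test"


@dataclass
class ParameterBank:
    """Labeled collection of NMM parameter sets with train/test tags."""

    entries: list
    grid: GridSpec | None = None
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> np.ndarray:
        return np.array([e.label.label for e in self.entries])

    def subset(self, split: str) -> list:
        return [e for e in self.entries if e.split == split]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(A=e.params.A, B=e.params.B, G=e.params.G, a=e.params.a,
                 b=e.params.b, g=e.params.g, seed=e.seed,
                 label=e.label.label, split=e.split)
            for e in self.entries
        ]
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        """Write a CSV table plus a JSON sidecar with grid and thresholds."""
        from . import __version__

        path = str(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "version": __version__,
            "grid": dataclasses.asdict(self.grid) if self.grid else None,
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ParameterBank":
        path = str(path)
        frame = pd.read_csv(path)
        try:
            with open(path + ".json") as fh:
                sidecar = json.load(fh)
        except FileNotFoundError:
            sidecar = {}
        thr = ClassifierThresholds(**sidecar.get("thresholds", {}) or {})
        grid = GridSpec(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in (sidecar.get("grid") or {}).items()}) \
            if sidecar.get("grid") else None
        entries = []
        for row in frame.itertuples(index=False):
            params = NMMParams(A=row.A, B=row.B, G=row.G, a=row.a, b=row.b, g=row.g)
            feat = WaveformFeatures(np.nan, np.nan, np.nan, np.nan, np.nan)
            entries.append(BankEntry(params, RegimeLabel(int(row.label), feat),
                                     int(row.seed), str(row.split or "")))
        return cls(entries, grid, thr)


def _classify_traces(traces, sample_rate, thresholds):
    return [
        classify_regime(waveform_features(tr, sample_rate, thresholds), thresholds)
        for tr in traces
    ]


def explore_parameter_grid(
    grid: GridSpec = GridSpec(),
    seed: int = 0,
    duration: float = 5.0,
    sample_rate: float = 500.0,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    prescreen_abg: tuple = (0.1, 0.05, 0.8),
    batch_size: int = 512,
    progress: bool = False,
) -> ParameterBank:
    """Two-stage exploration of the synaptic-gain / rate-constant grid.

    Stage 1 classifies every (B, G) pair at the prescreen rate constants
    and removes pairs producing normal activity (type 1).  Stage 2 runs the
    full (a, b, g) grid search for the surviving pairs.  Every simulated
    set is classified and stored with its seed.
    """
    ss = np.random.SeedSequence(seed)
    Bv, Gv = grid.values("B"), grid.values("G")
    av, bv, gv = grid.values("a"), grid.values("b"), grid.values("g")
    a0, b0, g0 = prescreen_abg

    pairs = [(float(B), float(G)) for B in Bv for G in Gv]
    pre_params = [
        NMMParams(A=grid.A, B=B, G=G, a=a0, b=b0, g=g0) for B, G in pairs
    ]
    pre_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(pairs))]
    survivors = []
    for lo in range(0, len(pre_params), batch_size):
        hi = min(lo + batch_size, len(pre_params))
        traces, finite = simulate_nmm_batch(
            pre_params[lo:hi], duration, sample_rate, pre_seeds[lo:hi],
            raise_on_divergence=False,
        )
        labels = [
            _classify_traces([tr], sample_rate, thresholds)[0] if ok else None
            for tr, ok in zip(traces, finite)
        ]
        for k, lab in enumerate(labels):
            if lab is not None and lab.label != 1:
                survivors.append(pairs[lo + k])
    if not survivors:
        raise RuntimeError(
            "no (B, G) pair survived the normal-activity prescreen; "
            f"thresholds were {thresholds}"
        )

    combos = [
        NMMParams(A=grid.A, B=B, G=G, a=float(a), b=float(b), g=float(g))
        for B, G in survivors for a in av for b in bv for g in gv
    ]
    combo_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(combos))
    ]
    entries = []
    iterator = range(0, len(combos), batch_size)
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(list(iterator))  # pragma: no cover
    for lo in iterator:
        hi = min(lo + batch_size, len(combos))
        traces, finite = simulate_nmm_batch(
            combos[lo:hi], duration, sample_rate, combo_seeds[lo:hi],
            raise_on_divergence=False,
        )
        for k in range(hi - lo):
            if not finite[k]:
                continue
            lab = _classify_traces([traces[k]], sample_rate, thresholds)[0]
            entries.append(BankEntry(combos[lo + k], lab, combo_seeds[lo + k]))
    return ParameterBank(entries, grid, thresholds)


def balance_parameter_sets(
    bank: ParameterBank,
    per_type: int = 10_000,
    train_count: int = 40_000,
    test_count: int = 10_000,
    seed: int = 0,
) -> ParameterBank:
    """Resample the bank to ``per_type`` entries per ictal type and split it.

    Candidate parameter sets of each type are first divided between the
    train and test pools (so the two splits share no parameter set), then
    each pool is resampled to its quota -- with replacement when a pool has
    fewer candidates than its quota, without otherwise.  Per-type quotas
    follow the train/test proportion with largest-remainder rounding, so
    the split sizes are exact.  A type with a single candidate necessarily
    appears in both splits.  Deterministic under ``seed``.
    """
    if train_count + test_count != per_type * len(ICTAL_TYPES):
        raise ValueError("train_count + test_count must equal 5 * per_type")
    rng = np.random.default_rng(seed)
    labels = bank.labels()
    per_type_idx = {}
    for t in ICTAL_TYPES:
        idx = np.flatnonzero(labels == t)
        if idx.size == 0:
            raise ValueError(
                f"ictal type {t} ({REGIME_NAMES[t]}) is absent from the bank"
            )
        per_type_idx[t] = rng.permutation(idx)

    # largest-remainder allocation of the train quota across types
    frac = train_count / (train_count + test_count)
    raw = {t: per_type * frac for t in ICTAL_TYPES}
    quota_train = {t: int(np.floor(raw[t])) for t in ICTAL_TYPES}
    short = train_count - sum(quota_train.values())
    for t in sorted(ICTAL_TYPES, key=lambda t: raw[t] - np.floor(raw[t]),
                    reverse=True)[:short]:
        quota_train[t] += 1

    entries = []
    for t in ICTAL_TYPES:
        idx = per_type_idx[t]
        qt = quota_train[t]
        qs = per_type - qt
        if idx.size >= 2:
            n_tr = int(np.clip(round(frac * idx.size), 1, idx.size - 1))
            pools = {"train": idx[:n_tr], "test": idx[n_tr:]}
        else:
            pools = {"train": idx, "test": idx}
        for split, quota in (("train", qt), ("test", qs)):
            pool = pools[split]
            chosen = rng.choice(pool, size=quota, replace=pool.size < quota)
            entries.extend(
                BankEntry(bank.entries[i].params, bank.entries[i].label,
                          bank.entries[i].seed, split)
                for i in chosen
            )
    order = rng.permutation(len(entries))
    return ParameterBank([entries[i] for i in order], bank.grid, bank.thresholds)
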