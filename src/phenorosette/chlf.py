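"""PAM chlorophyll-fluorescence protocols, level extraction and parameters.

Two saturation-pulse protocols are modelled:

* **quenching kinetics** — dark-adapted Fo/Fm, then 70 s of actinic light at
  210 µmol m⁻² s⁻¹ with saturation pulses 8, 18, 28, 48 and 68 s after light
  onset (states L1–L4, Lss), then 100 s of dark relaxation with pulses at
  30, 60 and 90 s (states D1–D3);
* **light curve** — dark-adapted Fo/Fm, then four 60 s actinic steps at 95,
  210, 320 and 440 µmol m⁻² s⁻¹ (states L1–L4) with one saturation pulse at
  the end of each step.

From the measured levels (Fo, Fm, Fp, Ft, Fm′) the module derives the
standard quantum-yield and quenching parameters, using the Oxborough–Baker
relation for Fo′ and the lake/puddle-model energy partition
ΦP + ΦNPQ + ΦNO = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: parameter columns emitted per light/dark state
STATE_TRAITS = ("Ft", "FmPrime", "FoPrime", "FvpFmp", "PhiP", "qP", "qL", "qN", "NPQ", "PhiNO", "PhiNPQ")
#: the eight traits used for accession clustering
CLUSTER_TRAITS = ("FvFm", "FvpFmp", "PhiP", "qP", "PhiNO", "PhiNPQ", "qN", "NPQ")

_EPS = 1e-6  # window-membership slack, far below any sampling interval


def in_window(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Half-open window membership [t0, t1) with float slack."""
    t = np.asarray(t)
    return (t >= t0 - _EPS) & (t < t1 - _EPS)


class ProtocolError(ValueError):
    """A trace does not match the protocol it is analysed against."""


@dataclass(frozen=True)
class LightState:
    name: str
    pulse_start_s: float  # absolute trace time of the saturation-pulse start
    phase: str  # "light" or "dark"
    t_phase_s: float  # time since actinic onset (light) or light-off (dark)
    irradiance: float  # µmol m⁻² s⁻¹ of the actinic background (0 in dark)


@dataclass(frozen=True)
class ChlFProtocol:
    """Timing skeleton of a saturation-pulse measurement."""

    kind: str
    dark_adaptation_s: float = 900.0
    fo_window_s: float = 5.0
    sat_pulse_s: float = 0.8
    sat_pulse_irradiance: float = 1200.0
    dark_relax_s: float = 17.0
    states: tuple[LightState, ...] = ()
    actinic_end_s: float = 0.0
    duration_s: float = 0.0
    ft_window_s: float = 0.2

    @property
    def fm_pulse_start_s(self) -> float:
        return self.fo_window_s

    @property
    def actinic_onset_s(self) -> float:
        return self.fo_window_s + self.sat_pulse_s + self.dark_relax_s

    @property
    def steady_state(self) -> str:
        """State used as the steady-state reference for Rfd."""
        return "Lss" if self.kind == "quenching" else "L4"

    def event_windows(self) -> dict[str, tuple[float, float]]:
        ev = {
            "FoWin": (0.0, self.fo_window_s),
            "FmPulse": (self.fm_pulse_start_s, self.fm_pulse_start_s + self.sat_pulse_s),
        }
        for s in self.states:
            ev[s.name] = (s.pulse_start_s, s.pulse_start_s + self.sat_pulse_s)
        return ev

    def state(self, name: str) -> LightState:
        for s in self.states:
            if s.name == name:
                return s
        raise ProtocolError(f"unknown state {name!r} for {self.kind} protocol")


def quenching_protocol(
    *,
    actinic_irradiance: float = 210.0,
    light_pulse_times_s: tuple[float, ...] = (8.0, 18.0, 28.0, 48.0, 68.0),
    actinic_len_s: float = 70.0,
    dark_pulse_times_s: tuple[float, ...] = (30.0, 60.0, 90.0),
    dark_len_s: float = 100.0,
) -> ChlFProtocol:
    """Quenching-kinetics protocol: constant actinic light, then dark relaxation."""
    base = ChlFProtocol(kind="quenching")
    on = base.actinic_onset_s
    names = [f"L{i}" for i in range(1, len(light_pulse_times_s))] + ["Lss"]
    states = [
        LightState(n, on + t, "light", t, actinic_irradiance)
        for n, t in zip(names, light_pulse_times_s)
    ]
    off = on + actinic_len_s
    states += [
        LightState(f"D{i + 1}", off + t, "dark", t, 0.0)
        for i, t in enumerate(dark_pulse_times_s)
    ]
    _check_increasing(states)
    return ChlFProtocol(
        kind="quenching",
        states=tuple(states),
        actinic_end_s=off,
        duration_s=off + dark_len_s,
    )


def light_curve_protocol(
    *,
    irradiances: tuple[float, ...] = (95.0, 210.0, 320.0, 440.0),
    step_len_s: float = 60.0,
) -> ChlFProtocol:
    """Light-curve protocol: stepped irradiance, one pulse at each step's end."""
    base = ChlFProtocol(kind="light_curve")
    on = base.actinic_onset_s
    states = []
    for i, irr in enumerate(irradiances):
        t_end = (i + 1) * step_len_s
        states.append(
            LightState(f"L{i + 1}", on + t_end - base.sat_pulse_s, "light", t_end - base.sat_pulse_s, irr)
        )
    _check_increasing(states)
    end = on + len(irradiances) * step_len_s
    return ChlFProtocol(kind="light_curve", states=tuple(states), actinic_end_s=end, duration_s=end + 2.0)


def _check_increasing(states) -> None:
    times = [s.pulse_start_s for s in states]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ProtocolError(f"pulse times not strictly increasing: {times}")
    if len({s.name for s in states}) != len(states):
        raise ProtocolError("state names not unique")


def get_protocol(kind: str) -> ChlFProtocol:
    if kind == "quenching":
        return quenching_protocol()
    if kind == "light_curve":
        return light_curve_protocol()
    raise ProtocolError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# traces and levels


@dataclass
class FluorTrace:
    """A fluorescence time series with per-event window annotations."""

    time_s: np.ndarray
    signal: np.ndarray
    events: dict[str, tuple[float, float]]
    plant_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.signal = np.asarray(self.signal, float)
        if self.time_s.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("fluorescence signal must be non-negative")

    def window(self, t0: float, t1: float) -> np.ndarray:
        sel = in_window(self.time_s, t0, t1)
        return self.signal[sel]

    def event_signal(self, name: str) -> np.ndarray:
        if name not in self.events:
            raise ProtocolError(f"{name} window not found in trace annotations")
        return self.window(*self.events[name])


@dataclass
class FluorLevels:
    """Measured fluorescence levels for one plant and protocol run (a.u.)."""

    fo: float
    fm: float
    fp: float
    ft: dict[str, float] = field(default_factory=dict)
    fm_prime: dict[str, float] = field(default_factory=dict)
    fo_prime: dict[str, float] = field(default_factory=dict)
    protocol_kind: str = "quenching"
    steady_state: str = "Lss"

    @property
    def fv(self) -> float:
        return self.fm - self.fo


def fo_prime(fo: float, fm: float, fm_prime: float) -> float:
    """Minimum fluorescence in the light-adapted state (Oxborough–Baker).

    Fo′ = Fo / (Fv/Fm + Fo/Fm′).  Requires Fm > Fo > 0 and Fm′ > 0; when
    there is no quenching (Fm′ = Fm) this reduces to Fo′ = Fo.
    """
    if not (fm > fo > 0):
        raise ValueError(f"need Fm > Fo > 0, got Fo={fo}, Fm={fm}")
    if fm_prime <= 0:
        raise ValueError(f"Fm' must be positive, got {fm_prime}")
    return fo / ((fm - fo) / fm + fo / fm_prime)


def smoothed_peak(x: np.ndarray, width: int) -> float:
    """Maximum of the ``width``-sample moving average (peak of a noisy rise)."""
    x = np.asarray(x, float)
    w = int(max(1, min(width, x.size)))
    return float(np.convolve(x, np.full(w, 1.0 / w), mode="valid").max())


#: moving-average width (s) for locating the Fp peak on the actinic rise
FP_SMOOTH_S = 1.0


def extract_levels(
    trace: FluorTrace, protocol: ChlFProtocol, *, level_estimator: str = "mean"
) -> FluorLevels:
    """Pull Fo, Fm, Fp, Ft(s), Fm′(s), Fo′(s) out of an annotated trace.

    Fo is the mean over the measuring-flash window; Fm and every Fm′ the
    mean of the samples inside the corresponding 800 ms saturation-pulse
    plateau (``level_estimator="max"`` switches to the window maximum, which
    is noise-biased upward but robust to a rising flank inside the window);
    Ft(s) the mean of the 200 ms immediately before pulse s; Fp the peak of
    the 1 s moving-average-smoothed signal during the actinic rise before
    the first light pulse.
    """
    est = {"mean": np.mean, "max": np.max}[level_estimator]
    fo = float(np.mean(trace.event_signal("FoWin")))
    fm_win = trace.event_signal("FmPulse")
    if fm_win.size == 0:
        raise ProtocolError("Fm window not found (no samples in pulse window)")
    fm = float(est(fm_win))
    if fm <= fo:
        raise ProtocolError(f"degenerate trace: Fm={fm:.4g} <= Fo={fo:.4g}")

    first_pulse = protocol.states[0].pulse_start_s
    fp_win = trace.window(protocol.actinic_onset_s, first_pulse - protocol.ft_window_s)
    if fp_win.size == 0:
        raise ProtocolError("no samples in the actinic-rise (Fp) window")
    dt = float(np.median(np.diff(trace.time_s)))
    fp = smoothed_peak(fp_win, round(FP_SMOOTH_S / dt))

    levels = FluorLevels(
        fo=fo, fm=fm, fp=fp, protocol_kind=protocol.kind, steady_state=protocol.steady_state
    )
    for s in protocol.states:
        pulse = trace.event_signal(s.name)
        if pulse.size == 0:
            raise ProtocolError(f"{s.name} window not found (no samples)")
        fmp = float(est(pulse))
        ft_win = trace.window(s.pulse_start_s - protocol.ft_window_s, s.pulse_start_s)
        if ft_win.size == 0:
            raise ProtocolError(f"no Ft samples before pulse {s.name}")
        ft = float(np.mean(ft_win))
        levels.fm_prime[s.name] = fmp
        levels.ft[s.name] = ft
        levels.fo_prime[s.name] = fo_prime(fo, fm, fmp)
    return levels


def integrate_image_stack(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Whole-rosette signal per frame: mean over mask minus background level.

    Background is the mean of mask-false pixels of the same frame, so a
    constant offset added to every pixel cancels out exactly.
    """
    frames = np.asarray(frames, float)
    mask = np.asarray(mask, bool)
    if frames.ndim != 3 or frames.shape[1:] != mask.shape:
        raise ValueError(f"frames {frames.shape} do not align with mask {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask: no rosette pixels to integrate")
    plant = frames[:, mask].mean(axis=1)
    if (~mask).any():
        plant = plant - frames[:, ~mask].mean(axis=1)
    return np.maximum(plant, 0.0)


# ---------------------------------------------------------------------------
# derived parameters


@dataclass
class ChlFParameters:
    """Quantum-yield and quenching parameters for one protocol run.

    ``per_state`` maps state name -> {trait: value}; division-guarded values
    come back as NaN with the offending state recorded in ``flags``.
    """

    fvfm: float
    rfd: float
    per_state: dict[str, dict[str, float]]
    protocol_kind: str
    flags: list[str] = field(default_factory=list)

    def to_long(self, plant_id: str = "", day: int = 0) -> pd.DataFrame:
        rows = [
            {"plant_id": plant_id, "day": day, "state": "dark", "trait": "FvFm", "value": self.fvfm},
            {"plant_id": plant_id, "day": day, "state": "whole", "trait": "Rfd", "value": self.rfd},
        ]
        for state, traits in self.per_state.items():
            for trait, value in traits.items():
                rows.append(
                    {"plant_id": plant_id, "day": day, "state": state, "trait": trait, "value": value}
                )
        return pd.DataFrame(rows)


def derive_parameters(levels: FluorLevels) -> ChlFParameters:
    """Compute the PSII parameter set from measured levels.

    Per state s:  Fv′/Fm′ = (Fm′−Fo′)/Fm′;  ΦP = (Fm′−Ft)/Fm′;
    qP = (Fm′−Ft)/(Fm′−Fo′);  qL = qP·Fo′/Ft;  qN = (Fm−Fm′)/(Fm−Fo′);
    NPQ = Fm/Fm′ − 1;  ΦNO = Ft/Fm;  ΦNPQ = Ft/Fm′ − Ft/Fm.
    Whole trace:  Fv/Fm = (Fm−Fo)/Fm;  Rfd = (Fp−Ft_ss)/Ft_ss against the
    steady state (Lss for quenching, L4 for the light curve).
    """
    fo, fm = levels.fo, levels.fm
    if not (fm > fo > 0):
        raise ValueError(f"invalid levels: need Fm > Fo > 0 (Fo={fo}, Fm={fm})")
    fvfm = (fm - fo) / fm

    flags: list[str] = []
    per_state: dict[str, dict[str, float]] = {}
    for state, fmp in levels.fm_prime.items():
        ft = levels.ft[state]
        fop = levels.fo_prime.get(state)
        if fop is None:
            fop = fo_prime(fo, fm, fmp)
        d: dict[str, float] = {"Ft": ft, "FmPrime": fmp, "FoPrime": fop}
        if fmp <= 0 or ft <= 0 or not math.isfinite(fmp - fop) or abs(fmp - fop) < 1e-12:
            # degenerate state: record NaNs rather than aborting the plant
            for k in ("FvpFmp", "PhiP", "qP", "qL", "qN", "NPQ", "PhiNO", "PhiNPQ"):
                d[k] = float("nan")
            flags.append(state)
            per_state[state] = d
            continue
        d["FvpFmp"] = (fmp - fop) / fmp
        d["PhiP"] = (fmp - ft) / fmp
        d["qP"] = (fmp - ft) / (fmp - fop)
        d["qL"] = d["qP"] * fop / ft
        d["qN"] = (fm - fmp) / (fm - fop)
        d["NPQ"] = fm / fmp - 1.0
        d["PhiNO"] = ft / fm
        d["PhiNPQ"] = ft / fmp - ft / fm
        per_state[state] = d

    ss = levels.steady_state
    ft_ss = levels.ft.get(ss, float("nan"))
    if not math.isfinite(ft_ss) or ft_ss <= 0:
        rfd = float("nan")
        flags.append(f"Rfd({ss})")
    else:
        rfd = (levels.fp - ft_ss) / ft_ss
    return ChlFParameters(
        fvfm=fvfm, rfd=rfd, per_state=per_state, protocol_kind=levels.protocol_kind, flags=flags
    )


def relative_trait_table(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Divide every value by the overall (grand) mean of its trait.

    Long-format input; grouping is per (trait, state) when a state column is
    present so that, e.g., NPQ at L1 and NPQ at Lss are normalised
    separately.  The grand mean of every normalised group is 1 by
    construction.
    """
    if table.empty:
        raise ValueError("empty trait table")
    keys = [c for c in ("trait", "state") if c in table.columns]
    if not keys:
        raise ValueError("table needs a 'trait' column")
    out = table.copy()
    means = out.groupby(keys)[value_col].transform("mean")
    if np.any(np.isclose(means, 0.0)):
        bad = out.loc[np.isclose(means, 0.0), keys].drop_duplicates()
        raise ValueError(f"zero grand mean for trait group(s): {bad.to_dict('records')}")
    out[value_col] = out[value_col] / means
    return out
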