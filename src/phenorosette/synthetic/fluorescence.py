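"""Synthetic PAM fluorescence traces with closed-form ground truth.

The simulator drives the two measurement protocols with a minimal quenching
model: non-photochemical quenching builds up mono-exponentially under
actinic light, NPQ(t) = NPQ_max·(1 − e^(−t/τ)), and relaxes exponentially
in the dark; the fraction of open PSII centres qP relaxes from 1 (all open
after dark adaptation) towards a steady-state value with a fast time
constant.  From (Fo, Fm, NPQ(t), qP(t)) every fluorescence level follows in
closed form:

    Fm′(t) = Fm / (1 + NPQ(t))
    Fo′(t) = Fo / (Fv/Fm + Fo/Fm′(t))          (Oxborough–Baker)
    Ft(t)  = Fm′(t) − qP(t)·(Fm′(t) − Fo′(t))

so the generator can hand every downstream extractor an exact oracle.
Within each saturation-pulse window (and the 200 ms Ft window before it)
the model clock is frozen at the pulse start: the pulse perturbs the
photosystem, and holding the state fixed there makes the window statistics
(mean/max) equal the model value exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chlf import (
    FP_SMOOTH_S,
    ChlFParameters,
    ChlFProtocol,
    FluorLevels,
    FluorTrace,
    fo_prime,
    in_window,
    smoothed_peak,
)


@dataclass(frozen=True)
class ChlFTrueParams:
    """Generating parameters of the quenching model (fluorescence in a.u.)."""

    fo: float = 0.2
    fm: float = 1.0
    npq_max: float = 1.2
    tau_npq_s: float = 20.0
    tau_relax_s: float = 60.0
    qp_ss: float = 0.55  # steady-state open fraction under constant actinic light
    qp_ss_steps: tuple[float, ...] = (0.88, 0.72, 0.58, 0.48)  # per light-curve step
    tau_qp_s: float = 2.5

    def __post_init__(self) -> None:
        if not (self.fm > self.fo > 0):
            raise ValueError(f"need Fm > Fo > 0, got Fo={self.fo}, Fm={self.fm}")
        if self.npq_max < 0:
            raise ValueError(f"NPQ_max must be >= 0, got {self.npq_max}")
        for tau in (self.tau_npq_s, self.tau_relax_s, self.tau_qp_s):
            if tau <= 0:
                raise ValueError(f"time constants must be positive, got {tau}")

    # -- model trajectories -------------------------------------------------

    def npq_at(self, t_light: float) -> float:
        """NPQ after ``t_light`` seconds of actinic illumination."""
        return self.npq_max * (1.0 - np.exp(-t_light / self.tau_npq_s))

    def npq_dark(self, npq_end: float, t_dark: float) -> float:
        return npq_end * np.exp(-t_dark / self.tau_relax_s)

    def qp_at(self, t_light: float, qp_ss: float, qp0: float = 1.0) -> float:
        return qp_ss + (qp0 - qp_ss) * np.exp(-t_light / self.tau_qp_s)

    def qp_dark(self, qp_end: float, t_dark: float) -> float:
        return 1.0 + (qp_end - 1.0) * np.exp(-t_dark / self.tau_qp_s)

    def levels_from(self, npq: float, qp: float) -> tuple[float, float, float]:
        """(Ft, Fm′, Fo′) for an instantaneous (NPQ, qP)."""
        fmp = self.fm / (1.0 + npq)
        fop = fo_prime(self.fo, self.fm, fmp)
        ft = fmp - qp * (fmp - fop)
        return ft, fmp, fop


def _state_model(params: ChlFTrueParams, protocol: ChlFProtocol):
    """(npq, qp) of every protocol state, evaluated at its pulse start."""
    out = {}
    if protocol.kind == "quenching":
        actinic_len = protocol.actinic_end_s - protocol.actinic_onset_s
        npq_off = params.npq_at(actinic_len)
        qp_off = params.qp_at(actinic_len, params.qp_ss)
        for s in protocol.states:
            if s.phase == "light":
                out[s.name] = (params.npq_at(s.t_phase_s), params.qp_at(s.t_phase_s, params.qp_ss))
            else:
                out[s.name] = (
                    params.npq_dark(npq_off, s.t_phase_s),
                    params.qp_dark(qp_off, s.t_phase_s),
                )
    else:  # light curve: qP target changes per step, continuous across steps
        light_states = [s for s in protocol.states if s.phase == "light"]
        step_edges = [0.0] + [s.t_phase_s + protocol.sat_pulse_s for s in light_states]
        qp0 = 1.0
        for i, s in enumerate(light_states):
            target = params.qp_ss_steps[min(i, len(params.qp_ss_steps) - 1)]
            dt = s.t_phase_s - step_edges[i]
            out[s.name] = (params.npq_at(s.t_phase_s), params.qp_at(dt, target, qp0))
            qp0 = out[s.name][1]
    return out


def _continuous_ft(params: ChlFTrueParams, protocol: ChlFProtocol, t_rel: np.ndarray, phase: str, npq_off=0.0, qp_off=1.0):
    """Vectorised Ft trajectory between pulses."""
    if phase == "light":
        if protocol.kind == "quenching":
            npq = params.npq_max * (1.0 - np.exp(-t_rel / params.tau_npq_s))
            qp = params.qp_ss + (1.0 - params.qp_ss) * np.exp(-t_rel / params.tau_qp_s)
        else:
            npq = params.npq_max * (1.0 - np.exp(-t_rel / params.tau_npq_s))
            light_states = [s for s in protocol.states if s.phase == "light"]
            edges = [0.0] + [s.t_phase_s + protocol.sat_pulse_s for s in light_states]
            qp = np.empty_like(t_rel)
            qp0 = 1.0
            for i, s in enumerate(light_states):
                target = params.qp_ss_steps[min(i, len(params.qp_ss_steps) - 1)]
                lo, hi = edges[i], edges[i + 1]
                sel = (t_rel >= lo) & (t_rel < hi)
                qp[sel] = target + (qp0 - target) * np.exp(-(t_rel[sel] - lo) / params.tau_qp_s)
                qp0 = target + (qp0 - target) * np.exp(-(s.t_phase_s - lo) / params.tau_qp_s)
            qp[t_rel >= edges[-1]] = qp0
    else:
        npq = npq_off * np.exp(-t_rel / params.tau_relax_s)
        qp = 1.0 + (qp_off - 1.0) * np.exp(-t_rel / params.tau_qp_s)
    fmp = params.fm / (1.0 + npq)
    fvfm = (params.fm - params.fo) / params.fm
    fop = params.fo / (fvfm + params.fo / fmp)
    return fmp - qp * (fmp - fop)


def simulate_chlf_trace(
    true_params: ChlFTrueParams,
    protocol: ChlFProtocol,
    *,
    noise_sd: float = 0.0,
    seed=0,
    sample_hz: float = 50.0,  # frame rate of the fluorescence camera
    plant_id: str = "",
    day: int = 0,
) -> tuple[FluorTrace, "ChlFGroundTruth"]:
    """Synthesise one annotated fluorescence trace plus its ground truth."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(protocol.duration_s * sample_hz)) + 1
    t = np.arange(n) / sample_hz
    sig = np.full(n, true_params.fo)

    on, off = protocol.actinic_onset_s, protocol.actinic_end_s
    state_npq_qp = _state_model(true_params, protocol)
    npq_off = qp_off = None
    if protocol.kind == "quenching":
        npq_off = true_params.npq_at(off - on)
        qp_off = true_params.qp_at(off - on, true_params.qp_ss)

    # continuous trajectory under/after actinic light
    light_sel = in_window(t, on, off)
    sig[light_sel] = _continuous_ft(true_params, protocol, t[light_sel] - on, "light")
    if protocol.kind == "quenching":
        dark_sel = t >= off - 1e-9
        sig[dark_sel] = _continuous_ft(
            true_params, protocol, t[dark_sel] - off, "dark", npq_off, qp_off
        )

    # frozen pulse neighbourhoods: Ft window then the saturating pulse itself
    events = protocol.event_windows()
    sig[in_window(t, *events["FmPulse"])] = true_params.fm
    for s in protocol.states:
        npq, qp = state_npq_qp[s.name]
        ft, fmp, _ = true_params.levels_from(npq, qp)
        sig[in_window(t, s.pulse_start_s - protocol.ft_window_s, s.pulse_start_s)] = ft
        sig[in_window(t, s.pulse_start_s, s.pulse_start_s + protocol.sat_pulse_s)] = fmp

    truth = _ground_truth(true_params, protocol, state_npq_qp, t, sig)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, n)
    trace = FluorTrace(time_s=t, signal=np.maximum(sig, 0.0), events=events, plant_id=plant_id, day=day)
    return trace, truth


def assign_chlf_truth(
    design,
    *,
    base: ChlFTrueParams | None = None,
    salt_npq_factor: float = 1.6,
    salt_qp_factor: float = 0.8,
    salt_fo_factor: float = 1.15,
    accession_cv: float = 0.05,
    plant_cv: float = 0.02,
    seed: int = 0,
) -> dict[str, ChlFTrueParams]:
    """Per-plant generating parameters with accession and treatment effects.

    Salt raises NPQ_max, lowers the steady-state open fraction qP and
    raises Fo (photoinactivation depresses Fv/Fm), all scaled linearly with
    the NaCl dose (factors apply per 100 mM).  Accession-level
    multiplicative effects are drawn once per accession so that accessions
    form real groups; small per-plant jitter sits on top.
    """
    base = base or ChlFTrueParams()
    rng = np.random.default_rng(seed)
    acc_eff = {a: rng.normal(1.0, accession_cv, size=3) for a in design.accessions}
    out: dict[str, ChlFTrueParams] = {}
    for p in design.plants.itertuples():
        dose = p.nacl_mm / 100.0
        npq_mult = 1.0 + dose * (salt_npq_factor - 1.0)
        qp_mult = 1.0 - dose * (1.0 - salt_qp_factor)
        fo_mult = 1.0 + dose * (salt_fo_factor - 1.0)
        ea, eb, ec = acc_eff[p.accession]
        ja, jb, jc = rng.normal(1.0, plant_cv, size=3)
        npq_max = max(base.npq_max * npq_mult * ea * ja, 0.0)
        scale_qp = np.clip(qp_mult * eb * jb, 0.05, 1.6)
        fo = float(np.clip(base.fo * fo_mult * (1.0 + (ec - 1.0) * 0.5) * jc, 0.02, 0.8 * base.fm))
        out[p.plant_id] = ChlFTrueParams(
            fo=fo,
            fm=base.fm,
            npq_max=npq_max,
            tau_npq_s=base.tau_npq_s,
            tau_relax_s=base.tau_relax_s,
            qp_ss=float(np.clip(base.qp_ss * scale_qp, 0.02, 0.98)),
            qp_ss_steps=tuple(float(np.clip(q * scale_qp, 0.02, 0.98)) for q in base.qp_ss_steps),
            tau_qp_s=base.tau_qp_s,
        )
    return out


@dataclass
class ChlFGroundTruth:
    """Noise-free levels and parameters implied by the generating model."""

    levels: FluorLevels
    parameters: ChlFParameters


def _ground_truth(params, protocol, state_npq_qp, t, noiseless_sig) -> ChlFGroundTruth:
    first_pulse = protocol.states[0].pulse_start_s
    fp_sel = in_window(t, protocol.actinic_onset_s, first_pulse - protocol.ft_window_s)
    dt = float(np.median(np.diff(t)))
    # Fp is defined operationally as the peak of the 1 s smoothed rise, so
    # the extractor's estimator agrees with the truth exactly at zero noise
    fp = smoothed_peak(noiseless_sig[fp_sel], round(FP_SMOOTH_S / dt))

    levels = FluorLevels(
        fo=params.fo,
        fm=params.fm,
        fp=fp,
        protocol_kind=protocol.kind,
        steady_state=protocol.steady_state,
    )
    fvfm = (params.fm - params.fo) / params.fm
    per_state: dict[str, dict[str, float]] = {}
    for s in protocol.states:
        npq, qp = state_npq_qp[s.name]
        ft, fmp, fop = params.levels_from(npq, qp)
        levels.ft[s.name] = ft
        levels.fm_prime[s.name] = fmp
        levels.fo_prime[s.name] = fop
        fvpfmp = (fmp - fop) / fmp
        phip = qp * fvpfmp  # = (Fm' - Ft)/Fm' by construction of Ft
        per_state[s.name] = {
            "Ft": ft,
            "FmPrime": fmp,
            "FoPrime": fop,
            "FvpFmp": fvpfmp,
            "PhiP": phip,
            "qP": qp,
            "qL": qp * fop / ft,
            "qN": (params.fm - fmp) / (params.fm - fop),
            "NPQ": npq,
            "PhiNO": ft / params.fm,
            "PhiNPQ": 1.0 - phip - ft / params.fm,
        }
    ss = protocol.steady_state
    rfd = (fp - levels.ft[ss]) / levels.ft[ss]
    pars = ChlFParameters(fvfm=fvfm, rfd=rfd, per_state=per_state, protocol_kind=protocol.kind)
    return ChlFGroundTruth(levels=levels, parameters=pars)
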