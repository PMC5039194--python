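import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenorosette as pr
from phenorosette.chlf import ProtocolError, relative_trait_table
from phenorosette.synthetic import ChlFTrueParams, simulate_chlf_trace

QUENCH = pr.quenching_protocol()
LIGHT = pr.light_curve_protocol()


def test_quenching_protocol_schedule():
    on = QUENCH.actinic_onset_s
    names = [s.name for s in QUENCH.states]
    assert names == ["L1", "L2", "L3", "L4", "Lss", "D1", "D2", "D3"]
    light_times = [s.pulse_start_s - on for s in QUENCH.states[:5]]
    np.testing.assert_allclose(light_times, [8, 18, 28, 48, 68], atol=1e-9)
    off = QUENCH.actinic_end_s
    assert off - on == pytest.approx(70)
    np.testing.assert_allclose([s.pulse_start_s - off for s in QUENCH.states[5:]], [30, 60, 90], atol=1e-9)


def test_light_curve_protocol_schedule():
    irr = [s.irradiance for s in LIGHT.states]
    assert irr == [95, 210, 320, 440]
    # one pulse ends exactly at each 60 s step boundary
    ends = [s.pulse_start_s + LIGHT.sat_pulse_s - LIGHT.actinic_onset_s for s in LIGHT.states]
    np.testing.assert_allclose(ends, [60, 120, 180, 240], atol=1e-9)
    assert LIGHT.steady_state == "L4"


def test_zero_noise_levels_recovered_exactly():
    tr, truth = simulate_chlf_trace(ChlFTrueParams(fo=0.2, fm=1.0), QUENCH, noise_sd=0)
    lev = pr.extract_levels(tr, QUENCH)
    assert lev.fo == pytest.approx(0.2, abs=1e-12)
    assert lev.fm == pytest.approx(1.0, abs=1e-12)
    assert (lev.fm - lev.fo) / lev.fm == pytest.approx(0.8, abs=1e-12)
    for s in truth.levels.ft:
        assert lev.ft[s] == pytest.approx(truth.levels.ft[s], abs=1e-9)
        assert lev.fm_prime[s] == pytest.approx(truth.levels.fm_prime[s], abs=1e-9)


def test_npq_max_zero_means_no_quenching():
    p = ChlFTrueParams(npq_max=0.0)
    tr, truth = simulate_chlf_trace(p, QUENCH, noise_sd=0)
    lev = pr.extract_levels(tr, QUENCH)
    for s in lev.fm_prime:
        assert lev.fm_prime[s] == pytest.approx(p.fm, abs=1e-12)


def test_extracted_npq_matches_generator_formula():
    """NPQ at Lss (68 s of light) follows NPQ_max*(1 - exp(-t/tau))."""
    p = ChlFTrueParams(npq_max=0.5, tau_npq_s=20.0)
    tr, _ = simulate_chlf_trace(p, QUENCH, noise_sd=0)
    par = pr.derive_parameters(pr.extract_levels(tr, QUENCH))
    expected = 0.5 * (1 - np.exp(-68 / 20))
    assert par.per_state["Lss"]["NPQ"] == pytest.approx(expected, abs=1e-9)


def test_invalid_generator_parameters_rejected():
    with pytest.raises(ValueError):
        ChlFTrueParams(npq_max=-0.1)
    with pytest.raises(ValueError):
        ChlFTrueParams(tau_npq_s=0)
    with pytest.raises(ValueError):
        ChlFTrueParams(fo=1.0, fm=0.5)


def test_missing_annotation_names_the_event():
    tr, _ = simulate_chlf_trace(ChlFTrueParams(), QUENCH, noise_sd=0)
    del tr.events["FmPulse"]
    with pytest.raises(ProtocolError, match="FmPulse"):
        pr.extract_levels(tr, QUENCH)


def test_degenerate_trace_rejected():
    tr, _ = simulate_chlf_trace(ChlFTrueParams(), QUENCH, noise_sd=0)
    tr.signal = np.full_like(tr.signal, 0.3)  # flat: Fm == Fo
    with pytest.raises(ProtocolError, match="degenerate"):
        pr.extract_levels(tr, QUENCH)


def test_noisy_fo_estimate_is_accurate():
    errs = []
    for i in range(20):
        tr, truth = simulate_chlf_trace(ChlFTrueParams(), QUENCH, noise_sd=0.005, seed=i)
        errs.append(abs(pr.extract_levels(tr, QUENCH).fo - truth.levels.fo))
    assert np.mean(errs) < 0.005


def test_fo_prime_hand_values_and_monotonicity():
    assert pr.fo_prime(0.2, 1.0, 1.0) == pytest.approx(0.2, abs=1e-12)
    assert pr.fo_prime(0.2, 1.0, 0.8) == pytest.approx(0.2 / (0.8 + 0.25), abs=1e-12)
    assert pr.fo_prime(0.2, 1.0, 0.8) < 0.2  # quenching lowers Fo'
    with pytest.raises(ValueError):
        pr.fo_prime(0.2, 0.1, 0.8)


def make_levels(fo, fm, fmp, ft):
    lev = pr.FluorLevels(fo=fo, fm=fm, fp=ft * 2, steady_state="L1")
    lev.ft["L1"] = ft
    lev.fm_prime["L1"] = fmp
    lev.fo_prime["L1"] = pr.fo_prime(fo, fm, fmp)
    return lev


def test_dark_equivalent_state_parameters():
    par = pr.derive_parameters(make_levels(0.2, 1.0, 1.0, 0.2))
    d = par.per_state["L1"]
    assert d["NPQ"] == pytest.approx(0.0, abs=1e-12)
    assert d["qN"] == pytest.approx(0.0, abs=1e-12)
    assert d["qP"] == pytest.approx(1.0, abs=1e-12)


def test_hand_evaluated_parameter_set():
    par = pr.derive_parameters(make_levels(0.2, 1.0, 0.8, 0.4))
    d = par.per_state["L1"]
    fop = 0.2 / (0.8 + 0.25)
    assert d["PhiP"] == pytest.approx(0.5, abs=1e-12)
    assert d["PhiNO"] == pytest.approx(0.4, abs=1e-12)
    assert d["PhiNPQ"] == pytest.approx(0.1, abs=1e-12)
    assert d["NPQ"] == pytest.approx(0.25, abs=1e-12)
    assert d["qP"] == pytest.approx((0.8 - 0.4) / (0.8 - fop), abs=1e-12)
    assert d["qL"] == pytest.approx(d["qP"] * fop / 0.4, abs=1e-12)
    assert d["qN"] == pytest.approx((1.0 - 0.8) / (1.0 - fop), abs=1e-12)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    fo=st.floats(0.05, 0.5),
    fm_extra=st.floats(0.1, 2.0),
    npq=st.floats(0.0, 3.0),
    qp=st.floats(0.0, 1.0),
)
def test_energy_partition_closes(fo, fm_extra, npq, qp):
    """PhiP + PhiNPQ + PhiNO = 1 for any valid level set."""
    fm = fo + fm_extra
    fmp = fm / (1 + npq)
    fop = pr.fo_prime(fo, fm, fmp)
    ft = fmp - qp * (fmp - fop)
    par = pr.derive_parameters(make_levels(fo, fm, fmp, ft))
    d = par.per_state["L1"]
    assert d["PhiP"] + d["PhiNPQ"] + d["PhiNO"] == pytest.approx(1.0, abs=1e-9)


def test_degenerate_state_flagged_not_raised():
    lev = make_levels(0.2, 1.0, 0.8, 0.4)
    lev.ft["L1"] = 0.0
    par = pr.derive_parameters(lev)
    assert "L1" in par.flags
    assert np.isnan(par.per_state["L1"]["qL"])


def test_increasing_npq_max_monotone_effects():
    npq_lss, phinpq_lss, fmp_lss = [], [], []
    for npq_max in (0.3, 0.8, 1.5, 2.5):
        tr, _ = simulate_chlf_trace(ChlFTrueParams(npq_max=npq_max), QUENCH, noise_sd=0)
        par = pr.derive_parameters(pr.extract_levels(tr, QUENCH))
        npq_lss.append(par.per_state["Lss"]["NPQ"])
        phinpq_lss.append(par.per_state["Lss"]["PhiNPQ"])
        fmp_lss.append(par.per_state["Lss"]["FmPrime"])
    assert npq_lss == sorted(npq_lss)
    assert phinpq_lss == sorted(phinpq_lss)
    assert fmp_lss == sorted(fmp_lss, reverse=True)


def test_integrate_image_stack_contract():
    mask = np.zeros((8, 8), bool)
    mask[:, :4] = True
    frames = np.zeros((3, 8, 8))
    frames[:, mask] = [[5.0], [6.0], [7.0]]
    sig = pr.integrate_image_stack(frames, mask)
    np.testing.assert_allclose(sig, [5, 6, 7])
    # constant offset on every pixel cancels
    np.testing.assert_allclose(pr.integrate_image_stack(frames + 11.0, mask), sig)
    with pytest.raises(ValueError, match="empty mask"):
        pr.integrate_image_stack(frames, np.zeros((8, 8), bool))
    with pytest.raises(ValueError, match="align"):
        pr.integrate_image_stack(frames, np.ones((4, 4), bool))


def test_relative_trait_table_normalisation():
    df = pd.DataFrame({"trait": ["a", "a", "b", "b"], "value": [1.0, 3.0, 5.0, 5.0]})
    out = relative_trait_table(df)
    assert list(out.value) == [0.5, 1.5, 1.0, 1.0]
    assert out.groupby("trait").value.mean().tolist() == pytest.approx([1.0, 1.0])
    with pytest.raises(ValueError, match="zero grand mean"):
        relative_trait_table(pd.DataFrame({"trait": ["a"], "value": [0.0]}))
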