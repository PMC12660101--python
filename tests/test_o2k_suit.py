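"""SUIT derivation: window means, correction arithmetic, exclusions."""

import numpy as np
import pytest

from respiroflux import o2k_suit, synth_data, trace_io
from respiroflux.errors import DerivationError
from respiroflux.o2k_suit import SuitConfig


def make_chamber(states, fiber_bg=1.5, instr=1.0, wet=(2.0, 2.0), vol=2.0,
                 group="control", chamber_id="C1", animal_id="M001"):
    """Hand-built chamber whose steady plateaus encode the given per-mg
    states exactly (piecewise-constant flux, no approach transient)."""
    schedule = synth_data._MARK_SCHEDULE
    k = float(np.mean(wet)) / vol
    pre = states.get("pre_adp", 0.9 * states["l"])
    targets = {
        "blebbistatin": instr,
        "fiber_in": instr + fiber_bg,
        "pyruvate": instr + fiber_bg + (states["rox"] + 0.6 * pre) * k,
        "malate": instr + fiber_bg + (states["rox"] + 0.8 * pre) * k,
        "glutamate": instr + fiber_bg + (states["rox"] + pre) * k,
        "ADP_0.5mM": instr + fiber_bg + (states["rox"] + 0.55 * states["ci"]) * k,
        "ADP_5mM": instr + fiber_bg + (states["rox"] + 0.85 * states["ci"]) * k,
        "ADP_15mM": instr + fiber_bg + (states["rox"] + states["ci"]) * k,
        "cytochrome_c": instr + fiber_bg + (states["rox"] + states["ci_cytc"]) * k,
        "succinate": instr + fiber_bg + (states["rox"] + states["p"]) * k,
        "oligomycin": instr + fiber_bg + (states["rox"] + states["l"]) * k,
        "antimycin_rotenone": instr + fiber_bg + states["rox"] * k,
    }
    times = np.arange(0.0, 2040.0, 2.0)
    flux = np.full(times.size, float(instr))
    for name, mt in schedule:
        flux[times >= mt] = targets[name]
    o2 = 390.0 - np.cumsum(flux) * 2.0 / 1000.0
    return trace_io.ChamberRun(
        chamber_id=chamber_id, animal_id=animal_id, group_label=group,
        wet_weight_mg_rep1=wet[0], wet_weight_mg_rep2=wet[1],
        ticks=np.column_stack([times, o2, flux]),
        marks=[(n, t) for n, t in schedule],
        instrumental_background=instr, fiber_background_window=(180.0, 350.0),
    )


def brute_force_suit(states, fiber_bg, wet_mean, vol=2.0):
    """Independent evaluation of the correction/derivation formulas."""
    ci, cytc, p, l, rox = (states["ci"], states["ci_cytc"], states["p"],
                           states["l"], states["rox"])
    return dict(
        ci=ci, cytc=cytc, p=p, l=l, rox=rox,
        atp=p - l, ce=100 * (p - l) / p, rcr=p / l,
        cytc_frac=(cytc - ci) / ci, cytc_gain=cytc - ci, succ_gain=p - cytc,
        fce_cytc=(cytc - ci) / cytc, fce_succ=(p - cytc) / p,
    )


class TestSteadyStateFlux:
    def test_constant_window(self):
        run = make_chamber(dict(ci=20, ci_cytc=21, p=28, l=7, rox=2))
        pm = trace_io.segment_phases(run)
        sf = o2k_suit.steady_state_flux(run, pm["succinate"])
        assert sf.n_used == 40 and not sf.short

    def test_linear_ramp_tail_mean(self):
        run = make_chamber(dict(ci=20, ci_cytc=21, p=28, l=7, rox=2))
        run.ticks[:80, 2] = np.arange(80.0)
        sf = o2k_suit.steady_state_flux(run, (0, 79))
        assert sf.value == pytest.approx(np.mean(np.arange(40, 80)))  # 59.5
        assert sf.value == pytest.approx(59.5)

    def test_short_window_warns(self):
        run = make_chamber(dict(ci=20, ci_cytc=21, p=28, l=7, rox=2))
        sf = o2k_suit.steady_state_flux(run, (0, 19))
        assert sf.short and sf.n_used == 20

    def test_random_windows_match_tail_mean(self, rng):
        run = make_chamber(dict(ci=20, ci_cytc=21, p=28, l=7, rox=2))
        run.ticks[:, 2] = rng.normal(size=run.ticks.shape[0])
        n = run.ticks.shape[0]
        for _ in range(50):
            a = int(rng.integers(0, n - 1))
            b = int(rng.integers(a, n))
            sf = o2k_suit.steady_state_flux(run, (a, b))
            assert sf.value == pytest.approx(
                float(np.mean(run.ticks[a : b + 1, 2][-40:])), abs=1e-12)


class TestCorrectAndNormalize:
    def test_forced_arithmetic(self):
        # measured 50, background 5, rox 5, 2 mL chamber, 2 mg bundle
        assert o2k_suit.correct_and_normalize(50, 5, 5, 2.0, 2.0) == pytest.approx(40.0)
        assert o2k_suit.correct_and_normalize(10, 5, 5, 2.0) == pytest.approx(0.0)

    def test_fuzzed_triples_match_formula(self, rng):
        for _ in range(100):
            m, b, r = rng.uniform(-10, 60, 3)
            w = rng.uniform(0.5, 4.0)
            v = rng.uniform(1.0, 3.0)
            assert o2k_suit.correct_and_normalize(m, b, r, w, v) == pytest.approx(
                (m - b - r) * v / w, abs=1e-12)


class TestDeriveSuit:
    STATES = dict(ci=20.0, ci_cytc=21.0, p=28.0, l=7.0, rox=2.0)

    def test_forced_example(self):
        run = make_chamber(self.STATES)
        r = o2k_suit.derive_suit(run)
        assert r.ci_oxphos == pytest.approx(20.0, abs=1e-9)
        assert r.ci_oxphos_cytc == pytest.approx(21.0, abs=1e-9)
        assert r.p_oxphos == pytest.approx(28.0, abs=1e-9)
        assert r.leak_l == pytest.approx(7.0, abs=1e-9)
        assert r.atp_linked == pytest.approx(21.0, abs=1e-9)
        assert r.ce_pct == pytest.approx(75.0, abs=1e-9)
        assert r.rcr == pytest.approx(4.0, abs=1e-9)
        assert r.cytc_response_frac == pytest.approx(0.05, abs=1e-9)
        assert r.fce_cytc == pytest.approx(1 / 21, abs=1e-9)
        assert r.fce_succinate == pytest.approx(0.25, abs=1e-9)

    def test_p_equals_l_boundary(self):
        run = make_chamber(dict(ci=20.0, ci_cytc=21.0, p=28.0, l=28.0, rox=2.0))
        r = o2k_suit.derive_suit(run)
        assert r.atp_linked == pytest.approx(0.0, abs=1e-9)
        assert r.ce_pct == pytest.approx(0.0, abs=1e-9)
        assert r.rcr == pytest.approx(1.0, abs=1e-9)

    def test_200_random_chambers_match_brute_force(self, rng):
        for _ in range(200):
            states = dict(
                ci=rng.uniform(5, 40), ci_cytc=rng.uniform(5, 45),
                p=rng.uniform(10, 60), l=rng.uniform(1, 20), rox=rng.uniform(0.2, 5),
            )
            fb = rng.uniform(0.2, 3.0)
            wet = tuple(rng.uniform(1.0, 3.5, 2))
            run = make_chamber(states, fiber_bg=fb, wet=wet)
            r = o2k_suit.derive_suit(run)
            ref = brute_force_suit(states, fb, np.mean(wet))
            for got, want in [(r.ci_oxphos, ref["ci"]), (r.p_oxphos, ref["p"]),
                              (r.leak_l, ref["l"]), (r.rox, ref["rox"]),
                              (r.atp_linked, ref["atp"]), (r.ce_pct, ref["ce"]),
                              (r.rcr, ref["rcr"]), (r.cytc_abs_gain, ref["cytc_gain"]),
                              (r.succinate_abs_gain, ref["succ_gain"]),
                              (r.fce_cytc, ref["fce_cytc"]),
                              (r.fce_succinate, ref["fce_succ"])]:
                assert got == pytest.approx(want, abs=1e-9)

    def test_ce_rcr_identity(self, rng):
        for _ in range(50):
            states = dict(ci=rng.uniform(5, 40), ci_cytc=rng.uniform(5, 45),
                          p=rng.uniform(10, 60), l=rng.uniform(1, 20),
                          rox=rng.uniform(0.2, 5))
            r = o2k_suit.derive_suit(make_chamber(states))
            assert r.ce_pct == pytest.approx(100 * (1 - 1 / r.rcr), abs=1e-9)
            assert r.p_oxphos == pytest.approx(r.atp_linked + r.leak_l, abs=1e-9)
            assert r.fce_cytc == pytest.approx(
                r.cytc_abs_gain / r.ci_oxphos_cytc, abs=1e-9)
            assert np.sign(r.fce_succinate) == np.sign(r.succinate_abs_gain)

    def test_translation_invariance_of_correction(self):
        states = self.STATES
        base = o2k_suit.derive_suit(make_chamber(states, fiber_bg=1.5))
        shifted_run = make_chamber(states, fiber_bg=1.5)
        shifted_run.ticks[:, 2] += 4.0  # raises measured flux and background alike
        shifted = o2k_suit.derive_suit(shifted_run)
        assert shifted.p_oxphos == pytest.approx(base.p_oxphos, abs=1e-9)
        assert shifted.leak_l == pytest.approx(base.leak_l, abs=1e-9)
        assert shifted.rox == pytest.approx(base.rox, abs=1e-9)

    def test_missing_mark_raises_named_error(self):
        run = make_chamber(self.STATES)
        run.marks = [(n, t) for n, t in run.marks if n != "succinate"]
        with pytest.raises(DerivationError, match="succinate"):
            o2k_suit.derive_suit(run)

    def test_deterministic(self):
        run = make_chamber(self.STATES)
        assert o2k_suit.derive_suit(run) == o2k_suit.derive_suit(run)

    def test_wet_weight_is_mean_of_duplicates(self):
        run = make_chamber(self.STATES, wet=(1.8, 2.2))
        r = o2k_suit.derive_suit(run)
        assert r.wet_weight_mg == pytest.approx(2.0)


class TestExclusions:
    def test_cytc_cutoff_applied_and_policy_exempt(self):
        states = dict(ci=20.0, ci_cytc=25.0, p=28.0, l=7.0, rox=2.0)  # response 0.25
        ctrl = o2k_suit.derive_suit(make_chamber(states, group="control"))
        assert o2k_suit.CYTC_EXCEEDS_CUTOFF in ctrl.qc_flags
        assert ctrl.excluded
        dis = o2k_suit.derive_suit(make_chamber(states, group="disease"))
        assert o2k_suit.CYTC_EXCEEDS_CUTOFF not in dis.qc_flags
        assert "CYTC_RESPONSE_HIGH" in dis.qc_flags
        assert not dis.excluded

    def test_cytc_boundary_is_strict(self):
        states = dict(ci=20.0, ci_cytc=24.0, p=28.0, l=7.0, rox=2.0)  # exactly 0.20
        r = o2k_suit.derive_suit(make_chamber(states, group="control"))
        assert o2k_suit.CYTC_EXCEEDS_CUTOFF not in r.qc_flags

    def test_negative_background_flagged(self):
        run = make_chamber(self.cytc_states(), fiber_bg=-0.5)
        flags = o2k_suit.exclude_background_and_adp(run)
        assert o2k_suit.NEG_BACKGROUND in flags

    def test_adp_nonresponse_threshold(self):
        # post-ADP barely above pre-ADP -> non-responsive at 10% minimum gain
        states = dict(ci=9.5, ci_cytc=10.0, p=28.0, l=10.0, rox=2.0, pre_adp=9.0)
        run = make_chamber(states)
        flags = o2k_suit.exclude_background_and_adp(run)
        assert o2k_suit.ADP_NONRESPONSIVE in flags
        good = make_chamber(dict(ci=30.0, ci_cytc=31.0, p=40.0, l=10.0, rox=2.0))
        assert o2k_suit.ADP_NONRESPONSIVE not in o2k_suit.exclude_background_and_adp(good)

    def test_fccp_before_oligomycin_nulls_leak_branch(self):
        run = make_chamber(self.cytc_states())
        # plant an FCCP mark between succinate and oligomycin
        marks = dict(run.marks)
        run.marks = sorted(list(marks.items()) + [("fccp", 1600.0)], key=lambda m: m[1])
        r = o2k_suit.derive_suit(run)
        assert o2k_suit.FCCP_PROTOCOL_ERROR in r.qc_flags
        assert r.leak_l is None and r.atp_linked is None and r.ce_pct is None
        assert r.p_oxphos is not None and r.ci_oxphos is not None

    @staticmethod
    def cytc_states():
        return dict(ci=20.0, ci_cytc=21.0, p=28.0, l=7.0, rox=2.0)


class TestReconcile:
    def make_pair(self, rcr_a=3.0, rcr_b=4.0):
        st = dict(ci=20.0, ci_cytc=21.0, p=28.0, rox=2.0)
        a = o2k_suit.derive_suit(make_chamber(st | dict(l=28.0 / rcr_a), chamber_id="A"))
        b = o2k_suit.derive_suit(make_chamber(st | dict(l=28.0 / rcr_b), chamber_id="B"))
        return a, b

    def test_both_valid_mean(self):
        a, b = self.make_pair()
        m = o2k_suit.reconcile_duplicates(a, b)
        assert m.rcr == pytest.approx(3.5, abs=1e-9)
        assert m.p_oxphos == pytest.approx(28.0, abs=1e-9)

    def test_one_excluded_survivor_verbatim(self):
        a, b = self.make_pair()
        a.qc_flags.add(o2k_suit.NEG_BACKGROUND)
        m = o2k_suit.reconcile_duplicates(a, b)
        assert m is b

    def test_both_excluded_dropped(self):
        a, b = self.make_pair()
        a.qc_flags.add(o2k_suit.NEG_BACKGROUND)
        b.qc_flags.add(o2k_suit.ADP_NONRESPONSIVE)
        assert o2k_suit.reconcile_duplicates(a, b) is None

    def test_animal_mismatch_is_error(self):
        a, b = self.make_pair()
        b.animal_id = "OTHER"
        with pytest.raises(DerivationError, match="mismatch"):
            o2k_suit.reconcile_duplicates(a, b)
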