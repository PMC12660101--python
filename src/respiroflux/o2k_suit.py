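"""Chamber respirometry (SUIT protocol) parameter derivation for
permeabilized muscle fiber bundles.

The titration sequence — complex-I substrates (pyruvate/malate/glutamate),
an ADP titration to saturation (0.5, 5, 15 mM), exogenous cytochrome c,
succinate, oligomycin, antimycin A + rotenone — yields the respiratory
states:

    CI OXPHOS   complex-I-supported OXPHOS at saturating ADP (15 mM step)
    CI + CytC   the same after exogenous cytochrome c
    P           complex I + II OXPHOS (after succinate)
    L           LEAK respiration (after oligomycin)
    Rox         residual (non-mitochondrial) O2 consumption (after AA/Rot)

Every state is the mean flux over the last 40 acquisition ticks of its
titration window (an 80 s plateau at 2-s sampling), corrected as

    flux_corrected = flux_measured - fiber_background - Rox

in pmol/s/mL, then normalized to bundle mass via the chamber volume:
pmol/s/mg wet weight = pmol/s/mL * volume_mL / wet_weight_mg.  Rox itself
is background-corrected only.  Derived quantities: ATP-linked = P - L,
CE% = 100*(P - L)/P, RCR = P/L, the cytochrome-c membrane-integrity
response, and flux control efficiencies (FCE = gain / post-step flux) for
cytochrome c and succinate.

Chamber-level exclusions mirror field practice: negative fiber-bundle
background after instrumental correction, non-responsiveness to ADP,
a >20% cytochrome-c response (group-level policy: the cutoff is usually
not applied to disease groups whose elevated response is a phenotype, not
an artifact), and a protocol error where FCCP precedes oligomycin (which
invalidates L and its derivatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import DerivationError
from .trace_io import ChamberRun, PhaseMap, segment_phases

NEG_BACKGROUND = "NEG_BACKGROUND"
ADP_NONRESPONSIVE = "ADP_NONRESPONSIVE"
CYTC_EXCEEDS_CUTOFF = "CYTC_EXCEEDS_CUTOFF"
FCCP_PROTOCOL_ERROR = "FCCP_PROTOCOL_ERROR"
SHORT_WINDOW = "SHORT_WINDOW"
O2_REGIME = "O2_REGIME"

#: Flags that exclude a chamber from downstream analysis.
EXCLUSION_FLAGS = (NEG_BACKGROUND, ADP_NONRESPONSIVE, CYTC_EXCEEDS_CUTOFF)

_STATE_FIELDS = (
    "ci_oxphos", "ci_oxphos_cytc", "p_oxphos", "leak_l", "atp_linked", "rox",
    "ce_pct", "rcr", "cytc_response_frac", "cytc_abs_gain", "succinate_abs_gain",
    "fce_cytc", "fce_succinate", "fiber_background", "wet_weight_mg", "e_capacity",
)


@dataclass
class SuitConfig:
    """Tunable constants of the chamber derivation."""

    equilibration_delay_s: float = 60.0   # post-titration mixing transient excluded
    n_steady_points: int = 40             # 80 s plateau at 2-s acquisition
    chamber_volume_ml: float = 2.0        # pmol/s/mL -> per-bundle conversion
    cytc_cutoff_frac: float = 0.20        # strict >20% response excludes
    cytc_apply_groups: tuple[str, ...] = ("control",)  # disease kept by policy
    adp_min_gain: float = 0.10            # required fractional rise over pre-ADP flux
    rox_only_correction: bool = False     # sensitivity switch: skip fiber background
    o2_window_uM: tuple[float, float] = (180.0, 400.0)
    emit_e: bool = False                  # post-FCCP capacity parsed, not reported


@dataclass
class SUITResult:
    """Derived SUIT parameters for one chamber (pmol O2/s/mg wet wt unless
    dimensionless); ratio fields are None when undefined."""

    chamber_id: str
    animal_id: str
    group_label: str
    ci_oxphos: float | None = None
    ci_oxphos_cytc: float | None = None
    p_oxphos: float | None = None
    leak_l: float | None = None
    atp_linked: float | None = None
    rox: float | None = None
    ce_pct: float | None = None
    rcr: float | None = None
    cytc_response_frac: float | None = None
    cytc_abs_gain: float | None = None
    succinate_abs_gain: float | None = None
    fce_cytc: float | None = None
    fce_succinate: float | None = None
    fiber_background: float | None = None  # pmol/s/mL, net of instrumental
    wet_weight_mg: float | None = None
    e_capacity: float | None = None       # post-FCCP, reported only on request
    adp_step_fluxes: dict[str, float] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags & set(EXCLUSION_FLAGS))


class SteadyFlux(NamedTuple):
    value: float
    n_used: int
    short: bool


def steady_state_flux(
    run: ChamberRun,
    phase_window: tuple[int, int],
    n_points: int = 40,
) -> SteadyFlux:
    """Mean flux over the last ``n_points`` ticks of a titration window.

    The tail of the window is the steady plateau just before the next
    titration.  Windows shorter than ``n_points`` are averaged over the
    available ticks and marked SHORT_WINDOW.
    """
    first, last = phase_window
    if last < first:
        raise DerivationError(f"chamber {run.chamber_id}: empty phase window")
    flux = run.ticks[first : last + 1, 2]
    short = flux.size < n_points
    tail = flux[-n_points:]
    return SteadyFlux(float(np.mean(tail)), int(tail.size), short)


def correct_and_normalize(
    measured: float,
    fiber_background: float,
    rox: float,
    wet_weight_mg: float,
    chamber_volume_ml: float = 2.0,
) -> float:
    """Background- and Rox-correct a measured flux and normalize to mass.

    All inputs are pmol/s/mL (``measured`` net of instrumental background);
    the result is pmol/s/mg wet weight.
    """
    if wet_weight_mg <= 0:
        raise DerivationError("wet weight must be > 0")
    corrected_per_ml = measured - fiber_background - rox
    return corrected_per_ml * chamber_volume_ml / wet_weight_mg


def _mark_names(run: ChamberRun) -> list[str]:
    return [name for name, _ in run.marks]


def fiber_background_net(run: ChamberRun, config: SuitConfig | None = None) -> float:
    """Fiber-bundle background flux (pmol/s/mL) net of instrumental
    background, measured over the pre-substrate window."""
    t0, t1 = run.fiber_background_window
    t = run.ticks[:, 0]
    sel = (t >= t0) & (t <= t1)
    if not np.any(sel):
        raise DerivationError(f"chamber {run.chamber_id}: empty fiber background window")
    return float(np.mean(run.ticks[sel, 2])) - run.instrumental_background


def exclude_background_and_adp(
    run: ChamberRun,
    phases: PhaseMap | None = None,
    config: SuitConfig | None = None,
) -> set[str]:
    """Chamber-level exclusion flags for negative background and ADP
    non-response (post-saturating-ADP flux not exceeding the pre-ADP flux
    by at least ``adp_min_gain``)."""
    cfg = config or SuitConfig()
    if phases is None:
        phases = segment_phases(run, cfg.equilibration_delay_s)
    flags: set[str] = set()
    if fiber_background_net(run, cfg) < 0:
        flags.add(NEG_BACKGROUND)
    pre_name = "glutamate" if "glutamate" in phases else "malate"
    if pre_name in phases and "ADP_15mM" in phases:
        pre = steady_state_flux(run, phases[pre_name], cfg.n_steady_points).value
        post = steady_state_flux(run, phases["ADP_15mM"], cfg.n_steady_points).value
        if post <= (1.0 + cfg.adp_min_gain) * pre:
            flags.add(ADP_NONRESPONSIVE)
    return flags


def exclude_cytc(
    result: SUITResult,
    cutoff_frac: float = 0.20,
    apply: bool = True,
) -> SUITResult:
    """Apply (or merely record) the cytochrome-c membrane-integrity cutoff.

    A fractional response strictly above ``cutoff_frac`` marks the chamber;
    with ``apply=False`` (the usual policy for a disease group whose
    elevated response is phenotype) the chamber is flagged
    ``CYTC_RESPONSE_HIGH`` but retained.
    """
    if result.cytc_response_frac is None:
        return result
    if result.cytc_response_frac > cutoff_frac:
        flags = set(result.qc_flags)
        flags.add(CYTC_EXCEEDS_CUTOFF if apply else "CYTC_RESPONSE_HIGH")
        return replace(result, qc_flags=flags)
    return result


def derive_suit(run: ChamberRun, config: SuitConfig | None = None) -> SUITResult:
    """Derive all SUIT parameters for one chamber.

    Raises a named error when a canonical mark needed for a state is
    absent.  Ratio fields are nulled (with a flag) when P <= 0.
    """
    cfg = config or SuitConfig()
    phases = segment_phases(run, cfg.equilibration_delay_s)
    required = ("ADP_15mM", "cytochrome_c", "succinate", "oligomycin", "antimycin_rotenone")
    for name in required:
        if name not in phases:
            raise DerivationError(f"chamber {run.chamber_id}: required mark {name!r} missing")
        if name in phases.empty_phases:
            raise DerivationError(f"chamber {run.chamber_id}: phase {name!r} is empty")

    res = SUITResult(chamber_id=run.chamber_id, animal_id=run.animal_id,
                     group_label=run.group_label, qc_flags=set(run.flags))
    res.wet_weight_mg = run.wet_weight_mg

    fiber_bg = fiber_background_net(run, cfg)
    res.fiber_background = fiber_bg
    bg = 0.0 if cfg.rox_only_correction else fiber_bg

    def raw(name: str) -> float:
        sf = steady_state_flux(run, phases[name], cfg.n_steady_points)
        if sf.short:
            res.qc_flags.add(SHORT_WINDOW)
        self_o2 = run.ticks[phases[name][0] : phases[name][1] + 1, 1]
        lo, hi = cfg.o2_window_uM
        if self_o2.size and (self_o2.min() < lo or self_o2.max() > hi):
            res.qc_flags.add(O2_REGIME)
        return sf.value - run.instrumental_background

    rox_net = raw("antimycin_rotenone") - bg  # Rox: background-corrected only
    w = run.wet_weight_mg
    vol = cfg.chamber_volume_ml

    def corrected(name: str) -> float:
        return correct_and_normalize(raw(name), bg, rox_net, w, vol)

    res.rox = rox_net * vol / w
    res.ci_oxphos = corrected("ADP_15mM")
    res.ci_oxphos_cytc = corrected("cytochrome_c")
    res.p_oxphos = corrected("succinate")
    res.leak_l = corrected("oligomycin")
    for step in ("ADP_0.5mM", "ADP_5mM", "ADP_15mM"):
        if step in phases and step not in phases.empty_phases:
            res.adp_step_fluxes[step] = correct_and_normalize(raw(step), bg, rox_net, w, vol)

    # FCCP parsed if present; reported only on request, and a titration
    # order with FCCP before oligomycin invalidates L and its derivatives.
    fccp_names = [n for n in phases if "fccp" in n.lower()]
    if fccp_names:
        e_val = corrected(fccp_names[0])
        if cfg.emit_e:
            res.e_capacity = e_val
        names = _mark_names(run)
        if "oligomycin" in names and names.index(fccp_names[0]) < names.index("oligomycin"):
            res.qc_flags.add(FCCP_PROTOCOL_ERROR)

    ci, cytc, p = res.ci_oxphos, res.ci_oxphos_cytc, res.p_oxphos
    res.cytc_abs_gain = cytc - ci
    res.succinate_abs_gain = p - cytc
    if ci > 0:
        res.cytc_response_frac = (cytc - ci) / ci
    if cytc != 0:
        res.fce_cytc = (cytc - ci) / cytc

    if FCCP_PROTOCOL_ERROR in res.qc_flags:
        res.leak_l = None
        res.atp_linked = None
        res.ce_pct = None
        res.rcr = None
    else:
        l = res.leak_l
        if p > 0:
            res.atp_linked = p - l
            res.ce_pct = 100.0 * (p - l) / p
            res.rcr = p / l if l > 0 else None
        else:
            res.qc_flags.add("NONPOSITIVE_P")
    if p > 0:
        res.fce_succinate = (p - cytc) / p
    elif "NONPOSITIVE_P" not in res.qc_flags:
        res.qc_flags.add("NONPOSITIVE_P")

    res.qc_flags |= exclude_background_and_adp(run, phases, cfg)
    apply_cutoff = run.group_label in cfg.cytc_apply_groups
    res = exclude_cytc(res, cfg.cytc_cutoff_frac, apply=apply_cutoff)
    return res


def reconcile_duplicates(a: SUITResult, b: SUITResult) -> SUITResult | None:
    """Merge duplicate chambers of one animal.

    Both unexcluded: per-parameter mean.  One excluded: the survivor is
    used verbatim.  Both excluded: ``None`` (the animal is dropped; the
    caller logs it).
    """
    if a.animal_id != b.animal_id:
        raise DerivationError(f"duplicate reconcile: animal mismatch {a.animal_id} vs {b.animal_id}")
    if a.excluded and b.excluded:
        return None
    if a.excluded:
        return b
    if b.excluded:
        return a
    out = SUITResult(chamber_id=f"{a.chamber_id}+{b.chamber_id}",
                     animal_id=a.animal_id, group_label=a.group_label)
    for f in _STATE_FIELDS:
        va, vb = getattr(a, f), getattr(b, f)
        vals = [v for v in (va, vb) if v is not None and np.isfinite(v)]
        if vals:
            setattr(out, f, float(np.mean(vals)))
    out.qc_flags = a.qc_flags | b.qc_flags
    return out


def suit_result_fields() -> list[str]:
    """Names of the numeric parameter fields of :class:`SUITResult`."""
    return list(_STATE_FIELDS)
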