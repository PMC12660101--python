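"""Synthetic cohort and raw-trace generator.

Emulates a two-group mouse study (healthy controls vs a leptin-receptor-
null type-II-diabetes model) in which the same animals contribute
platelet plate-based stress-test traces and permeabilized-muscle chamber
respirometry, so that every pipeline stage — parsing, phase segmentation,
parameter derivation, QC, exclusion rules, group statistics and the
cross-tissue correlation analysis — can be exercised without any
measured data.

Truth model
-----------
Each animal draws a latent metabolic factor u ~ N(0, latent_sd) that
loads positively on platelet respiration and negatively on muscle
complex-I-supported respiration.  The opposite loadings induce the
negative platelet-basal vs muscle-OXPHOS correlation; the loadings are
sized so the population correlation between platelet basal OCR and
muscle CI+CII OXPHOS (P) equals ``cross_tissue_r`` exactly.  Group effect
sizes default to the printed control-vs-disease mean differences for the
independent states (platelet ATP-linked, leak, max; muscle P, L, Rox,
cytochrome-c gain, with a small non-significant CI shift); composite
quantities (basal, coupling efficiency, RCR, flux control efficiencies,
succinate gain) are derived from these so that the bioenergetic
identities basal = ATP + leak and P = ATP-linked + L hold exactly in the
truth, making the pipeline identities testable end to end.  Baseline
(control-group) means are not anchored to any report — only differences
are — and are documented, arbitrary, and fully configurable.

Trace rendering
---------------
Plate wells get 3 basal + 3 cycles per post-injection phase with
phase-appropriate OCR plus iid noise, and per-cycle O2-level ticks that
decline during the measure period in proportion to OCR and recover
during mixing.  Chamber runs get 2-s ticks whose flux steps
exponentially toward each titration's target and whose O2 concentration
integrates the flux (with re-oxygenation to stay inside the working
window).  Scenario flags plant the pathologies the QC stage must catch:
O2 exhaustion at high seeding density (J-shaped post-FCCP O2), an
oligomycin injection artifact, a fragile-membrane cytochrome-c response,
ADP non-response, and negative fiber background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .trace_io import (
    ANTIMYCIN_ROTENONE, FCCP, OLIGOMYCIN,
    ChamberRun, Cycle, InjectionEvent, PlateRun, WellSeries,
)

CONTROL = "control"
DISEASE = "disease"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """Disease-minus-control shifts for the independent truth states.

    Units: platelet shifts pmol O2/min/10^6 platelets; muscle shifts
    pmol O2/s/mg wet weight.  ``platelet_basal`` and ``muscle_atp_linked``
    may be supplied only as consistency checks: they must equal the sums
    implied by the identities basal = ATP + leak and ATP-linked = P - L.
    """

    platelet_atp: float = 7.923
    platelet_leak: float = 1.136
    platelet_max: float = 14.12
    platelet_nonmito: float = 0.0
    muscle_ci: float = -1.5           # non-significant in the source data
    muscle_cytc_gain: float = 5.337
    muscle_p: float = -7.722
    muscle_l: float = -5.955
    muscle_rox: float = -0.9542
    platelet_basal: float | None = None     # derived unless asserted
    muscle_atp_linked: float | None = None  # derived unless asserted

    def validate(self) -> None:
        derived_basal = self.platelet_atp + self.platelet_leak
        if self.platelet_basal is not None and not math.isclose(
            self.platelet_basal, derived_basal, abs_tol=1e-9
        ):
            raise ConfigError(
                f"effect table violates basal = ATP + leak: "
                f"{self.platelet_basal} != {derived_basal}"
            )
        derived_atp = self.muscle_p - self.muscle_l
        if self.muscle_atp_linked is not None and not math.isclose(
            self.muscle_atp_linked, derived_atp, abs_tol=1e-9
        ):
            raise ConfigError(
                f"effect table violates ATP-linked = P - L: "
                f"{self.muscle_atp_linked} != {derived_atp}"
            )

    @property
    def basal_shift(self) -> float:
        return self.platelet_atp + self.platelet_leak

    @property
    def succ_gain_shift(self) -> float:
        # P = CI + cytc_gain + succ_gain, so the succinate-gain shift is
        # fixed by the P, CI and cytochrome-c shifts.
        return self.muscle_p - self.muscle_ci - self.muscle_cytc_gain


@dataclass
class Baselines:
    """Control-group truth means (documented arbitrary; only differences
    are anchored to reported values)."""

    platelet_atp: float = 24.0        # pmol/min/1e6; basal = atp + leak = 30
    platelet_leak: float = 6.0
    platelet_rescap_gain: float = 15.0  # max = basal + rescap_gain = 45
    platelet_nonmito: float = 8.0
    muscle_ci: float = 20.0           # pmol/s/mg
    muscle_cytc_gain: float = 1.0
    muscle_succ_gain: float = 12.5    # P = ci + cytc + succ = 33.5
    muscle_l: float = 12.0
    muscle_rox: float = 2.0
    muscle_pre_adp_frac: float = 0.9  # PMG leak-state flux as fraction of L


@dataclass
class NoiseModel:
    """Animal-level (biological) SDs and well/chamber measurement SDs."""

    latent_sd: float = 1.0
    platelet_basal_sd: float = 8.0    # total SD of basal (latent + residual)
    platelet_leak_loading: float = 1.4
    platelet_leak_resid_sd: float = 0.6
    platelet_rescap_sd: float = 8.0
    platelet_nonmito_sd: float = 1.5
    muscle_p_sd: float = 6.5          # total SD of P (latent + components)
    muscle_ci_resid_sd: float = 2.5
    muscle_cytc_sd: float = 1.0
    muscle_l_sd: float = 2.2
    muscle_rox_sd: float = 0.5
    well_ocr_sd: float = 3.0          # pmol/min per cycle, raw plate scale
    chamber_flux_sd: float = 0.35     # pmol/s/mL per tick
    weighing_cv: float = 0.03         # duplicate wet-weight readout CV
    fiber_background_mean: float = 1.2  # pmol/s/mL net of instrumental
    fiber_background_sd: float = 0.3

    def zeroed(self) -> "NoiseModel":
        """Copy with every stochastic SD set to 0 (noiseless render)."""
        kw = asdict(self)
        for k in kw:
            if k.endswith(("_sd", "_cv")):
                kw[k] = 0.0
        return NoiseModel(**kw)


@dataclass
class Scenarios:
    """Pathology scenarios planted by the renderers (with labels returned
    so detector sensitivity/specificity is measurable)."""

    o2_exhaustion: bool = False        # high-density plate, J-shaped O2
    oligo_artifact: bool = False
    oligo_artifact_fraction: float = 0.25
    cytc_fragile: bool = False
    cytc_fragile_fraction: float = 0.5
    adp_nonresponsive: bool = False
    adp_nonresponsive_fraction: float = 0.25
    neg_background: bool = False
    neg_background_fraction: float = 0.25


@dataclass
class CohortConfig:
    n_control: int = 23
    n_disease: int = 12
    cross_tissue_r: float = -0.5
    effects: EffectTable = field(default_factory=EffectTable)
    baselines: Baselines = field(default_factory=Baselines)
    noise: NoiseModel = field(default_factory=NoiseModel)
    scenarios: Scenarios = field(default_factory=Scenarios)
    seeding_count: float = 20e6        # platelets per well
    exhaustion_seeding_count: float = 25e6
    body_mass_g: tuple[float, float] = (21.7, 45.0)   # control, disease means
    body_mass_sd_g: float = 1.5
    blood_ml_per_kg: float = 72.0
    platelet_yield_per_ml: float = 5e7  # usable platelets per mL blood
    instrumental_background: float = 1.0  # pmol/s/mL
    chamber_volume_ml: float = 2.0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_disease < 2:
            raise ConfigError("group sizes must be >= 2")
        if not -1 < self.cross_tissue_r < 1:
            raise ConfigError("|cross_tissue_r| must be < 1")
        for name, v in asdict(self.noise).items():
            if name.endswith(("_sd", "_cv")) and v < 0:
                raise ConfigError(f"noise SD {name} must be >= 0")
        self.effects.validate()
        _loadings(self)  # raises if the variance budget is inconsistent
        if self.baselines.muscle_l <= 0 or self.baselines.muscle_rox <= 0:
            raise ConfigError("muscle baselines must be positive")


@dataclass
class AnimalTruth:
    """Noise-free parameter vector for one animal (before measurement)."""

    animal_id: str
    group: str
    latent: float
    platelet: dict[str, float]   # per 1e6 platelets: atp, leak, basal, max, nonmito
    muscle: dict[str, float]     # per mg: ci, cytc_gain, succ_gain, p, l, rox, atp_linked
    body_mass_g: float
    blood_volume_ml: float
    n_wells: int


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def estimate_blood_volume(body_mass_g: float, ml_per_kg: float = 72.0) -> float:
    """Circulating blood volume (mL, 1 dp) from body mass and the standard
    per-kg blood volume of the mouse."""
    if body_mass_g <= 0:
        raise ConfigError("body mass must be > 0")
    return round(body_mass_g / 1000.0 * ml_per_kg, 1)


def _loadings(config: CohortConfig) -> dict[str, float]:
    """Latent-factor loadings sized so corr(platelet basal, muscle P) equals
    cross_tissue_r in the population (latent variance share |r| on each
    side).  With latent_sd = 0 the latent channel vanishes and the full
    variance budget goes to the residual terms."""
    nm = config.noise
    r = config.cross_tissue_r
    ls = nm.latent_sd
    lat_share = abs(r) if ls > 0 else 0.0
    # loadings are per unit of u, so divide the latent SD contribution out
    a_total = math.sqrt(lat_share) * nm.platelet_basal_sd / ls if ls > 0 else 0.0
    b_total = math.sqrt(lat_share) * nm.muscle_p_sd / ls if ls > 0 else 0.0
    a_leak = min(nm.platelet_leak_loading, a_total)
    a_atp = a_total - a_leak
    atp_resid_var = (nm.platelet_basal_sd ** 2 * (1.0 - lat_share)
                     - nm.platelet_leak_resid_sd ** 2)
    succ_resid_var = (nm.muscle_p_sd ** 2 * (1.0 - lat_share)
                      - nm.muscle_ci_resid_sd ** 2 - nm.muscle_cytc_sd ** 2)
    if atp_resid_var < -1e-12:
        raise ConfigError("leak residual variance exceeds the basal variance budget")
    if succ_resid_var < -1e-12:
        raise ConfigError("muscle component variances exceed total P variance")
    sign = -1.0 if r < 0 else 1.0
    return dict(
        a_atp=a_atp, a_leak=a_leak, b_ci=sign * b_total,
        atp_resid_sd=math.sqrt(max(atp_resid_var, 0.0)),
        succ_resid_sd=math.sqrt(max(succ_resid_var, 0.0)),
    )


def simulate_cohort(
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> list[AnimalTruth]:
    """Draw per-animal truths; reproducible from (config, seed)."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ld = _loadings(config)
    bl, ef, nm = config.baselines, config.effects, config.noise
    truths: list[AnimalTruth] = []
    groups = [(CONTROL, config.n_control, 0.0), (DISEASE, config.n_disease, 1.0)]
    counter = 0
    for group, n, dose in groups:
        for _ in range(n):
            counter += 1
            aid = f"M{counter:03d}"
            u = rng.normal(0.0, nm.latent_sd)
            atp = (bl.platelet_atp + dose * ef.platelet_atp + ld["a_atp"] * u
                   + rng.normal(0.0, ld["atp_resid_sd"]))
            leak = (bl.platelet_leak + dose * ef.platelet_leak + ld["a_leak"] * u
                    + rng.normal(0.0, nm.platelet_leak_resid_sd))
            leak = max(leak, 0.2)
            basal = atp + leak
            rescap = (bl.platelet_rescap_gain
                      + dose * (ef.platelet_max - ef.basal_shift)
                      + rng.normal(0.0, nm.platelet_rescap_sd))
            rescap = max(rescap, 0.5)
            nonmito = max(bl.platelet_nonmito + dose * ef.platelet_nonmito
                          + rng.normal(0.0, nm.platelet_nonmito_sd), 0.5)
            ci = (bl.muscle_ci + dose * ef.muscle_ci + ld["b_ci"] * u
                  + rng.normal(0.0, nm.muscle_ci_resid_sd))
            ci = max(ci, 1.0)
            cytc_gain = (bl.muscle_cytc_gain + dose * ef.muscle_cytc_gain
                         + rng.normal(0.0, nm.muscle_cytc_sd))
            succ_gain = (bl.muscle_succ_gain + dose * ef.succ_gain_shift
                         + rng.normal(0.0, ld["succ_resid_sd"]))
            p = ci + cytc_gain + succ_gain
            l = max(bl.muscle_l + dose * ef.muscle_l + rng.normal(0.0, nm.muscle_l_sd), 0.8)
            rox = max(bl.muscle_rox + dose * ef.muscle_rox + rng.normal(0.0, nm.muscle_rox_sd),
                      0.05)
            mass = max(rng.normal(config.body_mass_g[int(dose)], config.body_mass_sd_g), 10.0)
            blood_ml = estimate_blood_volume(mass, config.blood_ml_per_kg)
            # platelet yield caps how many wells the animal can seed
            yield_factor = math.exp(rng.normal(0.0, 0.5))
            usable = blood_ml * config.platelet_yield_per_ml * yield_factor
            n_wells = 2 if usable >= 2 * config.seeding_count else 1
            truths.append(AnimalTruth(
                animal_id=aid, group=group, latent=float(u),
                platelet=dict(atp=atp, leak=leak, basal=basal, max=basal + rescap,
                              nonmito=nonmito),
                muscle=dict(ci=ci, cytc_gain=cytc_gain, succ_gain=succ_gain, p=p,
                            l=l, rox=rox, atp_linked=p - l),
                body_mass_g=float(mass), blood_volume_ml=blood_ml, n_wells=n_wells,
            ))
    return truths


def truths_to_table(truths: list[AnimalTruth]):
    """Animal x true-parameter table (pandas), for cohort-level checks."""
    import pandas as pd

    rows = []
    for t in truths:
        rows.append(dict(
            animal_id=t.animal_id, group=t.group,
            plt_basal=t.platelet["basal"], plt_atp=t.platelet["atp"],
            plt_leak=t.platelet["leak"], plt_max=t.platelet["max"],
            plt_nonmito=t.platelet["nonmito"],
            plt_rescap=t.platelet["max"] - t.platelet["basal"],
            plt_ce_pct=100.0 * t.platelet["atp"] / t.platelet["basal"],
            sm_ci=t.muscle["ci"], sm_p=t.muscle["p"], sm_l=t.muscle["l"],
            sm_atp_linked=t.muscle["atp_linked"], sm_rox=t.muscle["rox"],
            sm_cytc_gain=t.muscle["cytc_gain"], sm_succ_gain=t.muscle["succ_gain"],
            sm_ce_pct=100.0 * t.muscle["atp_linked"] / t.muscle["p"],
            sm_rcr=t.muscle["p"] / t.muscle["l"],
            sm_fce_cytc=t.muscle["cytc_gain"] / (t.muscle["ci"] + t.muscle["cytc_gain"]),
            sm_fce_succ=t.muscle["succ_gain"] / t.muscle["p"],
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate rendering
# ---------------------------------------------------------------------------

_BASAL_CYCLE_S = 960.0    # 3-min mix + 10-min wait + 3-min measure
_POST_CYCLE_S = 360.0     # 3-min mix + 3-min measure
_MEASURE_S = 180.0
_AMBIENT_MMHG = 152.0
_O2_TICKS_PER_CYCLE = 10
_DEPLETION_MMHG_PER_PMOL_MIN = 0.05


def _plate_schedule() -> tuple[list[float], list[InjectionEvent]]:
    """Cycle midpoint times and the injection schedule (3 cycles/phase)."""
    t_mid = []
    for i in range(1, 4):  # basal cycles end-of-measure midpoints
        t_mid.append(i * _BASAL_CYCLE_S - _MEASURE_S / 2)
    t0 = 3 * _BASAL_CYCLE_S
    inj = [
        InjectionEvent(OLIGOMYCIN, "A", t0, "2.5 uM"),
        InjectionEvent(FCCP, "B", t0 + 3 * _POST_CYCLE_S, "0.4 uM"),
        InjectionEvent(ANTIMYCIN_ROTENONE, "C", t0 + 6 * _POST_CYCLE_S, "5 uM each"),
    ]
    for k in range(9):
        t_mid.append(t0 + (k + 1) * _POST_CYCLE_S - _MEASURE_S / 2)
    return t_mid, inj


def render_plate(
    truths: list[AnimalTruth],
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
    wells_per_plate: int = 20,
) -> tuple[list[PlateRun], dict[str, set[str]]]:
    """Render plate stress-test traces for every animal.

    Returns the plate runs and, per well id, the set of planted scenario
    labels (``{"oligo_artifact"}``, ``{"o2_exhaustion"}``, or empty).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sc = config.scenarios
    nm = config.noise
    t_mid, injections = _plate_schedule()
    seeding = (config.exhaustion_seeding_count if sc.o2_exhaustion
               else config.seeding_count)
    depletion = _DEPLETION_MMHG_PER_PMOL_MIN * (2.2 if sc.o2_exhaustion else 1.0)
    recovery = 0.3 if sc.o2_exhaustion else 1.0

    wells: list[WellSeries] = []
    labels: dict[str, set[str]] = {}
    for t in truths:
        k = seeding / 1e6
        phase_raw = {
            "basal": (t.platelet["basal"] + t.platelet["nonmito"]) * k,
            "oligo": (t.platelet["leak"] + t.platelet["nonmito"]) * k,
            "fccp": (t.platelet["max"] + t.platelet["nonmito"]) * k,
            "aarot": t.platelet["nonmito"] * k,
        }
        for w_idx in range(t.n_wells):
            well_id = f"{t.animal_id}_w{w_idx + 1}"
            planted: set[str] = set()
            if sc.o2_exhaustion:
                planted.add("o2_exhaustion")
            if sc.oligo_artifact and rng.random() < sc.oligo_artifact_fraction:
                planted.add("oligo_artifact")
            labels[well_id] = planted

            per_cycle = []
            for i, tm in enumerate(t_mid):
                phase = ("basal", "oligo", "fccp", "aarot")[min(i // 3, 3)]
                ocr = phase_raw[phase]
                if "oligo_artifact" in planted and phase == "oligo":
                    ocr = phase_raw["basal"] * 1.2  # injection failed to suppress
                per_cycle.append(ocr + rng.normal(0.0, nm.well_ocr_sd))

            cycles = []
            start_level = _AMBIENT_MMHG
            for i, (tm, ocr) in enumerate(zip(t_mid, per_cycle)):
                tick_t = np.linspace(tm - _MEASURE_S / 2, tm + _MEASURE_S / 2,
                                     _O2_TICKS_PER_CYCLE)
                frac = (tick_t - tick_t[0]) / _MEASURE_S
                drop = depletion * max(ocr, 0.0)
                levels = np.maximum(start_level - drop * frac, 0.5)
                cycles.append(Cycle(i + 1, float(tm), float(ocr),
                                    list(zip(tick_t.tolist(), levels.tolist()))))
                # mixing restores O2; exhausted wells fail to recover (J shape)
                end_level = float(levels[-1])
                start_level = end_level + recovery * (_AMBIENT_MMHG - end_level)
            wells.append(WellSeries(
                well_id=well_id, group_label=t.group, animal_id=t.animal_id,
                seeding_count=seeding, cycles=cycles, injections=list(injections),
            ))

    runs = []
    for i in range(0, len(wells), wells_per_plate):
        runs.append(PlateRun(run_id=f"plate{i // wells_per_plate + 1:02d}",
                             wells=wells[i : i + wells_per_plate]))
    return runs, labels


# ---------------------------------------------------------------------------
# chamber rendering
# ---------------------------------------------------------------------------

_MARK_SCHEDULE = (
    ("blebbistatin", 30.0),
    ("fiber_in", 60.0),
    ("pyruvate", 360.0),
    ("malate", 480.0),
    ("glutamate", 600.0),
    ("ADP_0.5mM", 780.0),
    ("ADP_5mM", 960.0),
    ("ADP_15mM", 1140.0),
    ("cytochrome_c", 1320.0),
    ("succinate", 1500.0),
    ("oligomycin", 1680.0),
    ("antimycin_rotenone", 1860.0),
)
_RUN_END_S = 2040.0
_TICK_DT_S = 2.0
_APPROACH_TAU_S = 10.0
_APPROACH_CUT_S = 40.0    # flux reaches its target before the steady window
_BG_WINDOW = (180.0, 350.0)
_O2_START_UM = 390.0
_O2_REOX_AT_UM = 185.0
_O2_REOX_TO_UM = 395.0
_ADP_STEP_FRACTIONS = {"ADP_0.5mM": 0.55, "ADP_5mM": 0.85, "ADP_15mM": 1.0}


def render_chamber(
    truths: list[AnimalTruth],
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ChamberRun], dict[str, set[str]]]:
    """Render duplicate chamber runs (two per animal) with 2-s ticks.

    Returns the runs and, per chamber id, the planted scenario labels
    (subsets of {"cytc_fragile", "adp_nonresponsive", "neg_background"}).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sc, nm = config.scenarios, config.noise
    runs: list[ChamberRun] = []
    labels: dict[str, set[str]] = {}
    for t in truths:
        for rep in ("A", "B"):
            cid = f"{t.animal_id}_{rep}"
            planted: set[str] = set()
            if sc.cytc_fragile and rng.random() < sc.cytc_fragile_fraction:
                planted.add("cytc_fragile")
            if sc.adp_nonresponsive and rng.random() < sc.adp_nonresponsive_fraction:
                planted.add("adp_nonresponsive")
            if sc.neg_background and rng.random() < sc.neg_background_fraction:
                planted.add("neg_background")
            labels[cid] = planted
            runs.append(_render_one_chamber(t, cid, planted, config, rng))
    return runs, labels


def _render_one_chamber(
    t: AnimalTruth,
    chamber_id: str,
    planted: set[str],
    config: CohortConfig,
    rng: np.random.Generator,
) -> ChamberRun:
    nm = config.noise
    wet_true = max(rng.normal(2.0, 0.25), 1.0)
    rep1 = wet_true * (1.0 + rng.normal(0.0, nm.weighing_cv))
    rep2 = wet_true * (1.0 + rng.normal(0.0, nm.weighing_cv))
    wet_recorded = (rep1 + rep2) / 2.0
    k = wet_recorded / config.chamber_volume_ml   # per-mg -> per-mL factor
    instr = config.instrumental_background

    fb = rng.normal(nm.fiber_background_mean, nm.fiber_background_sd)
    if "neg_background" in planted:
        fb = -abs(fb) - 0.3

    mus = dict(t.muscle)
    if "cytc_fragile" in planted:
        mus["cytc_gain"] = max(0.30 * mus["ci"], mus["cytc_gain"])
        mus["p"] = mus["ci"] + mus["cytc_gain"] + mus["succ_gain"]
    if "adp_nonresponsive" in planted:
        pre = config.baselines.muscle_pre_adp_frac * mus["l"]
        mus["ci"] = 1.02 * pre
        mus["p"] = mus["ci"] + mus["cytc_gain"] + mus["succ_gain"]

    pre_adp = config.baselines.muscle_pre_adp_frac * mus["l"]
    targets = {
        "blebbistatin": instr,
        "fiber_in": instr + fb,
        "pyruvate": instr + fb + (mus["rox"] + 0.6 * pre_adp) * k,
        "malate": instr + fb + (mus["rox"] + 0.8 * pre_adp) * k,
        "glutamate": instr + fb + (mus["rox"] + pre_adp) * k,
        "cytochrome_c": instr + fb + (mus["rox"] + mus["ci"] + mus["cytc_gain"]) * k,
        "succinate": instr + fb + (mus["rox"] + mus["p"]) * k,
        "oligomycin": instr + fb + (mus["rox"] + mus["l"]) * k,
        "antimycin_rotenone": instr + fb + mus["rox"] * k,
    }
    for step, frac in _ADP_STEP_FRACTIONS.items():
        targets[step] = instr + fb + (mus["rox"] + frac * mus["ci"]) * k

    times = np.arange(0.0, _RUN_END_S, _TICK_DT_S)
    flux = np.full(times.size, instr)
    prev_target = instr
    for name, mark_t in _MARK_SCHEDULE:
        target = targets[name]
        seg = times >= mark_t
        dt = times[seg] - mark_t
        approach = np.where(
            dt >= _APPROACH_CUT_S, target,
            target + (prev_target - target) * np.exp(-dt / _APPROACH_TAU_S),
        )
        flux[seg] = approach
        prev_target = target
    flux = flux + rng.normal(0.0, nm.chamber_flux_sd, size=flux.size)

    # O2 concentration integrates -flux (1 uM = 1000 pmol/mL), re-oxygenated
    # whenever it approaches the lower edge of the working window.
    o2 = np.empty_like(flux)
    level = _O2_START_UM
    for i in range(flux.size):
        o2[i] = level
        level -= flux[i] * _TICK_DT_S / 1000.0
        if level < _O2_REOX_AT_UM:
            level = _O2_REOX_TO_UM

    return ChamberRun(
        chamber_id=chamber_id, animal_id=t.animal_id, group_label=t.group,
        wet_weight_mg_rep1=float(rep1), wet_weight_mg_rep2=float(rep2),
        ticks=np.column_stack([times, o2, flux]),
        marks=[(n, mt) for n, mt in _MARK_SCHEDULE],
        instrumental_background=instr,
        fiber_background_window=_BG_WINDOW,
    )
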