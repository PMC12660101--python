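"""Platelet mitochondrial stress-test parameter derivation and plate QC.

The stress test partitions oxygen consumption with three sequential
effectors: oligomycin blocks ATP synthase (leaving proton-leak-driven
respiration), FCCP uncouples the electron transport chain (maximal
uncoupled respiration), and antimycin A + rotenone block complexes III/I
(non-mitochondrial respiration).  From the raw per-cycle OCR the module
derives, per well:

    OCR_non-mito = OCR after antimycin A + rotenone
    OCR_ATP      = OCR_basal - OCR_leak
    ResCap       = OCR_max - OCR_basal
    ResCap%      = 100 * OCR_max / OCR_basal
    CE%          = 100 * OCR_ATP / OCR_basal

with OCR_non-mito subtracted from basal, leak and max before the derived
quantities are formed, and everything scaled to pmol O2/min per 10^6
platelets seeded pre-assay.  Subtraction and scaling commute; both are
applied in raw pmol/min and scaled once at the end.

QC mirrors plate-level practice: an O2-exhaustion detector (chamber O2
approaching 0 mmHg or failing to recover after FCCP), a basal-stability
check (CV of basal cycles), and an oligomycin-artifact detector (e.g. an
injected air bubble leaves post-oligomycin OCR at or above basal); the
artifact invalidates only the oligomycin-dependent parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DerivationError
from .trace_io import BASAL, PhaseMap, WellSeries

O2_EXHAUSTION = "O2_EXHAUSTION"
UNSTABLE_BASELINE = "UNSTABLE_BASELINE"
OLIGO_ARTIFACT = "OLIGO_ARTIFACT"
UNEVALUABLE = "UNEVALUABLE"

#: MSTResult fields that are per-10^6-platelet rates (aggregatable means).
_RATE_FIELDS = (
    "ocr_basal", "ocr_leak", "ocr_atp", "ocr_max", "ocr_nonmito",
    "rescap_abs", "rescap_pct", "rescap_pct_diff", "ce_pct",
)


@dataclass
class MSTResult:
    """Derived stress-test parameters for one well (or one animal after
    duplicate aggregation).  Rates are pmol O2/min per 10^6 platelets,
    non-mito-corrected except ``ocr_nonmito`` itself; ``rescap_pct`` is the
    ratio reading 100*max/basal and ``rescap_pct_diff`` the alternative
    difference-as-percent reading 100*(max-basal)/basal, emitted side by
    side because printed conventions differ."""

    well_id: str
    animal_id: str
    group_label: str
    ocr_basal: float | None = None
    ocr_leak: float | None = None
    ocr_atp: float | None = None
    ocr_max: float | None = None
    ocr_nonmito: float | None = None
    rescap_abs: float | None = None
    rescap_pct: float | None = None
    rescap_pct_diff: float | None = None
    ce_pct: float | None = None
    qc_flags: set[str] = field(default_factory=set)
    provenance: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class QCDiagnostics:
    flagged: bool
    flag: str | None
    cycle: int | None = None
    detail: str = ""
    value: float | None = None


def _phase_values(well: WellSeries, phases: PhaseMap, name: str) -> np.ndarray:
    if name not in phases:
        raise DerivationError(f"well {well.well_id}: phase {name!r} missing")
    first, last = phases[name]
    if last < first:
        raise DerivationError(f"well {well.well_id}: phase {name!r} is empty")
    return well.ocr()[first - 1 : last]


def derive_mst(
    well: WellSeries,
    phases: PhaseMap,
    state_selection: str = "vendor",
    oligo_artifact: bool = False,
) -> MSTResult:
    """Derive stress-test parameters for one well.

    ``state_selection="vendor"`` follows the instrument vendor's report
    convention — last basal cycle, minimum post-oligomycin, maximum
    post-FCCP, minimum post-antimycin/rotenone; ``"mean"`` uses the phase
    mean for every state.  ``oligo_artifact=True`` (typically from
    :func:`qc_oligo_artifact`) nulls the oligomycin-dependent parameters
    (ATP, leak, CE%) while retaining basal, max and non-mito.
    """
    if well.seeding_count is None or well.seeding_count <= 0:
        raise DerivationError(f"well {well.well_id}: seeding count required for normalization")
    if state_selection not in ("vendor", "mean"):
        raise DerivationError(f"unknown state_selection {state_selection!r}")

    basal_v = _phase_values(well, phases, BASAL)
    oligo_v = _phase_values(well, phases, "post_oligomycin")
    fccp_v = _phase_values(well, phases, "post_fccp")
    aarot_v = _phase_values(well, phases, "post_aa_rot")

    if state_selection == "vendor":
        raw_basal = float(basal_v[-1])
        raw_leak = float(np.min(oligo_v))
        raw_max = float(np.max(fccp_v))
        raw_nonmito = float(np.min(aarot_v))
    else:
        raw_basal = float(np.mean(basal_v))
        raw_leak = float(np.mean(oligo_v))
        raw_max = float(np.mean(fccp_v))
        raw_nonmito = float(np.mean(aarot_v))

    res = MSTResult(well_id=well.well_id, animal_id=well.animal_id,
                    group_label=well.group_label, qc_flags=set(well.flags))
    scale = well.seeding_count / 1e6

    basal = raw_basal - raw_nonmito
    leak = raw_leak - raw_nonmito
    mx = raw_max - raw_nonmito
    if min(basal, leak, mx) < 0:
        res.qc_flags.add("NEGATIVE_CORRECTED_STATE")  # retained, not clipped

    res.ocr_nonmito = raw_nonmito / scale
    res.ocr_basal = basal / scale
    res.ocr_max = mx / scale
    res.rescap_abs = (mx - basal) / scale
    if basal > 0:
        res.rescap_pct = 100.0 * mx / basal
        res.rescap_pct_diff = 100.0 * (mx - basal) / basal
    else:
        res.qc_flags.add("NONPOSITIVE_BASAL")

    if oligo_artifact or not np.isfinite(raw_leak):
        res.qc_flags.add(OLIGO_ARTIFACT)
    else:
        res.ocr_leak = leak / scale
        res.ocr_atp = (basal - leak) / scale
        if basal > 0:
            res.ce_pct = 100.0 * (basal - leak) / basal
    return res


def qc_o2_exhaustion(
    well: WellSeries,
    floor_mmHg: float = 10.0,
    recovery_fraction: float = 0.5,
    phases: PhaseMap | None = None,
) -> QCDiagnostics:
    """Detect O2 exhaustion in the measurement microchamber.

    Flags when the minimum O2 during any measure period drops below
    ``floor_mmHg``, or when a post-FCCP measure period shows the J-shape
    signature: O2 fails to recover to at least ``recovery_fraction`` of the
    pre-measure level by the start of the following mix/measure cycle.
    Wells without O2 ticks are UNEVALUABLE, never a silent pass.
    """
    if not any(c.o2_ticks for c in well.cycles):
        return QCDiagnostics(True, UNEVALUABLE, detail="no O2 ticks recorded")
    for c in well.cycles:
        if not c.o2_ticks:
            continue
        levels = np.array([v for _, v in c.o2_ticks], dtype=float)
        if levels.min() < floor_mmHg:
            return QCDiagnostics(True, O2_EXHAUSTION, cycle=c.index,
                                 detail="measure-period O2 below floor",
                                 value=float(levels.min()))
    if phases is not None and "post_fccp" in phases and "post_fccp" not in phases.empty_phases:
        first, last = phases["post_fccp"]
        for i in range(first - 1, last):
            cur = well.cycles[i]
            if i + 1 >= len(well.cycles):
                break
            nxt = well.cycles[i + 1]
            if not cur.o2_ticks or not nxt.o2_ticks:
                continue
            pre_level = cur.o2_ticks[0][1]
            recovered = nxt.o2_ticks[0][1]
            if pre_level > 0 and recovered < recovery_fraction * pre_level:
                return QCDiagnostics(True, O2_EXHAUSTION, cycle=cur.index,
                                     detail="post-FCCP O2 failed to recover (J-shape)",
                                     value=float(recovered))
    return QCDiagnostics(False, None)


def qc_baseline_stability(
    well: WellSeries,
    max_cv: float = 0.15,
    phases: PhaseMap | None = None,
) -> QCDiagnostics:
    """Flag UNSTABLE_BASELINE when the CV of basal-cycle OCR exceeds ``max_cv``."""
    if phases is not None:
        basal = _phase_values(well, phases, BASAL)
    else:
        inj0 = min(e.time_s for e in well.injections)
        basal = np.array([c.ocr_pmol_per_min for c in well.cycles if c.t_mid_s < inj0])
    if basal.size < 2:
        return QCDiagnostics(True, UNEVALUABLE, detail="fewer than 2 basal cycles")
    mean = float(np.mean(basal))
    if mean == 0:
        return QCDiagnostics(True, UNEVALUABLE, detail="zero-mean baseline")
    cv = float(np.std(basal, ddof=1) / abs(mean))
    if cv > max_cv:
        return QCDiagnostics(True, UNSTABLE_BASELINE, detail=f"basal CV {cv:.3f} > {max_cv}",
                             value=cv)
    return QCDiagnostics(False, None, value=cv)


def qc_oligo_artifact(well: WellSeries, phases: PhaseMap) -> QCDiagnostics:
    """Flag OLIGO_ARTIFACT when oligomycin failed to suppress respiration
    (post-oligomycin minimum OCR at or above the last basal cycle, or any
    post-oligomycin cycle non-finite) — e.g. an injected air bubble."""
    basal_v = _phase_values(well, phases, BASAL)
    oligo_v = _phase_values(well, phases, "post_oligomycin")
    if not np.all(np.isfinite(oligo_v)):
        return QCDiagnostics(True, OLIGO_ARTIFACT, detail="non-finite post-oligomycin OCR")
    if float(np.min(oligo_v)) >= float(basal_v[-1]):
        return QCDiagnostics(True, OLIGO_ARTIFACT,
                             detail="post-oligomycin OCR did not fall below basal",
                             value=float(np.min(oligo_v)))
    return QCDiagnostics(False, None)


def aggregate_animal(results: list[MSTResult]) -> MSTResult:
    """Average duplicate wells into one per-animal result.

    Each parameter is the arithmetic mean over the wells where it is
    non-null, so a partial exclusion (e.g. an oligomycin artifact in one
    replicate) removes only that well's oligomycin-dependent parameters
    from the average.  Provenance records the wells used per parameter.
    """
    if not results:
        raise DerivationError("aggregate_animal: no results")
    animals = {r.animal_id for r in results}
    if len(animals) != 1:
        raise DerivationError(f"aggregate_animal: mixed animals {sorted(animals)}")
    out = MSTResult(
        well_id="+".join(r.well_id for r in results),
        animal_id=results[0].animal_id,
        group_label=results[0].group_label,
    )
    for f in _RATE_FIELDS:
        vals, wells = [], []
        for r in results:
            v = getattr(r, f)
            if v is not None and np.isfinite(v):
                vals.append(v)
                wells.append(r.well_id)
        if vals:
            setattr(out, f, float(np.mean(vals)))
            out.provenance[f] = wells
    out.qc_flags = set().union(*(r.qc_flags for r in results))
    return out


def mst_result_fields() -> list[str]:
    """Names of the numeric parameter fields of :class:`MSTResult`."""
    return list(_RATE_FIELDS)
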