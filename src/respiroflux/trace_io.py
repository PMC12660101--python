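"""Trace data model and delimited-text IO for plate and chamber respirometry.

Two instrument families are supported:

* plate-based extracellular-flux runs: per-well oxygen consumption rate
  (OCR, pmol O2/min) per measurement cycle, with per-tick O2 level (mmHg)
  and injection annotations (oligomycin / FCCP / antimycin A + rotenone);
* chamber-based high-resolution respirometry: a 2-s time series of chamber
  O2 concentration (uM) and O2 flux (pmol/s/mL) with titration marks.

The canonical interchange dialect is UTF-8 comma-delimited text with a
header row and one file per table.  Column names encode their units
(``ocr_pmol_per_min``, ``o2_mmHg``, ``o2_conc_uM``, ``flux_pmol_per_s_per_mL``)
so that parsers never silently coerce units: a file with a differently
named rate column is rejected, not reinterpreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

# Canonical stress-test effector labels, in injection order.
OLIGOMYCIN = "OLIGOMYCIN"
FCCP = "FCCP"
ANTIMYCIN_ROTENONE = "ANTIMYCIN_ROTENONE"
STRESS_TEST_LABELS = (OLIGOMYCIN, FCCP, ANTIMYCIN_ROTENONE)

#: Phase name used for the pre-injection cycles of a plate run.
BASAL = "basal"
#: Map from effector label to the name of the phase that follows it.
PHASE_AFTER = {
    OLIGOMYCIN: "post_oligomycin",
    FCCP: "post_fccp",
    ANTIMYCIN_ROTENONE: "post_aa_rot",
}

#: Canonical chamber titration order (SUIT protocol).
CANONICAL_MARKS = (
    "blebbistatin",
    "fiber_in",
    "pyruvate",
    "malate",
    "glutamate",
    "ADP_0.5mM",
    "ADP_5mM",
    "ADP_15mM",
    "cytochrome_c",
    "succinate",
    "oligomycin",
    "antimycin_rotenone",
)

_PLATE_RATE_COLS = ["well", "group", "animal_id", "cycle", "t_mid_s", "ocr_pmol_per_min"]
_PLATE_O2_COLS = ["well", "cycle", "t_s", "o2_mmHg"]
_PLATE_INJ_COLS = ["label", "port", "time_s", "concentration"]
_PLATE_META_COLS = ["well", "animal_id", "group", "seeding_count"]
_CHAMBER_TICK_COLS = ["chamber_id", "t_s", "o2_conc_uM", "flux_pmol_per_s_per_mL"]
_CHAMBER_MARK_COLS = ["chamber_id", "name", "t_s"]
_CHAMBER_META_COLS = [
    "chamber_id",
    "animal_id",
    "group",
    "wet_weight_mg_rep1",
    "wet_weight_mg_rep2",
    "instrumental_background_pmol_per_s_per_mL",
    "bg_window_start_s",
    "bg_window_end_s",
]


@dataclass(frozen=True)
class InjectionEvent:
    """A port injection (plate) or titration event (chamber)."""

    label: str
    port: str
    time_s: float
    concentration: str = ""  # documentation only, e.g. "2.5 uM"


@dataclass
class Cycle:
    """One measurement cycle of a plate well."""

    index: int  # 1-based, matching instrument reports
    t_mid_s: float
    ocr_pmol_per_min: float
    o2_ticks: list[tuple[float, float]] = field(default_factory=list)  # (t_s, mmHg)


@dataclass
class WellSeries:
    """Kinetic series for a single plate well."""

    well_id: str
    group_label: str
    animal_id: str
    seeding_count: float | None  # absolute platelet count; None carries a flag
    cycles: list[Cycle]
    injections: list[InjectionEvent]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        idx = [c.index for c in self.cycles]
        if idx != list(range(1, len(idx) + 1)):
            raise DataError(f"well {self.well_id}: cycle_index not contiguous from 1: {idx}")
        times = [c.t_mid_s for c in self.cycles]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataError(f"well {self.well_id}: non-monotone cycle times")
        if not all(np.isfinite(c.ocr_pmol_per_min) for c in self.cycles):
            self.flags.add("NONFINITE_OCR")
        if self.seeding_count is None:
            self.flags.add("MISSING_SEEDING_COUNT")
        elif self.seeding_count <= 0:
            raise DataError(f"well {self.well_id}: seeding_count must be > 0")
        t = [e.time_s for e in self.injections]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise DataError(f"well {self.well_id}: injection times not strictly increasing")
        stress = [e.label for e in self.injections if e.label in STRESS_TEST_LABELS]
        if len(stress) != len(set(stress)):
            raise DataError(f"well {self.well_id}: duplicate stress-test effector labels")

    def ocr(self) -> np.ndarray:
        return np.array([c.ocr_pmol_per_min for c in self.cycles], dtype=float)


@dataclass
class PlateRun:
    """A plate of wells sharing one injection schedule and cycle structure."""

    run_id: str
    wells: list[WellSeries]

    def __post_init__(self) -> None:
        if not self.wells:
            return
        ref = self.wells[0]
        for w in self.wells[1:]:
            if len(w.cycles) != len(ref.cycles):
                raise DataError(f"run {self.run_id}: wells differ in cycle count")
            if [e.time_s for e in w.injections] != [e.time_s for e in ref.injections]:
                raise DataError(f"run {self.run_id}: wells differ in injection times")


@dataclass
class ChamberRun:
    """A chamber respirometry time series with titration marks."""

    chamber_id: str
    animal_id: str
    group_label: str
    wet_weight_mg_rep1: float | None
    wet_weight_mg_rep2: float | None
    ticks: np.ndarray  # shape (n, 3): t_s, o2_conc_uM, flux_pmol_per_s_per_mL
    marks: list[tuple[str, float]]  # (name, t_s), ordered by time
    instrumental_background: float  # pmol/s/mL
    fiber_background_window: tuple[float, float]  # (t_start, t_end), pre-substrate
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=float)
        if self.ticks.ndim != 2 or self.ticks.shape[1] != 3:
            raise DataError(f"chamber {self.chamber_id}: ticks must be (n, 3)")
        if np.any(np.diff(self.ticks[:, 0]) <= 0):
            raise DataError(f"chamber {self.chamber_id}: tick times not increasing")
        if self.wet_weight_mg_rep1 is None and self.wet_weight_mg_rep2 is None:
            raise DataError(f"chamber {self.chamber_id}: both wet weights missing")
        for w in (self.wet_weight_mg_rep1, self.wet_weight_mg_rep2):
            if w is not None and w <= 0:
                raise DataError(f"chamber {self.chamber_id}: wet weight must be > 0")
        self.marks = sorted(self.marks, key=lambda m: m[1])
        known = [m[0] for m in self.marks if m[0] in CANONICAL_MARKS]
        order = [CANONICAL_MARKS.index(n) for n in known]
        if order != sorted(order):
            self.flags.add("MARKS_OUT_OF_ORDER")

    @property
    def wet_weight_mg(self) -> float:
        """Mean of the duplicate weighings (single weighing used verbatim)."""
        reps = [w for w in (self.wet_weight_mg_rep1, self.wet_weight_mg_rep2) if w is not None]
        return float(np.mean(reps))

    def tick_spacing_s(self) -> float:
        return float(np.median(np.diff(self.ticks[:, 0])))


class PhaseMap(dict):
    """Phase name -> (first_index, last_index), inclusive, over cycles or ticks.

    An empty phase is stored as ``(first, first - 1)``; names of empty
    phases are listed in :attr:`empty_phases`.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.empty_phases: set[str] = set()

    def indices(self, name: str) -> range:
        first, last = self[name]
        return range(first, last + 1)

    def validate_partition(self, n_total: int, start: int = 1) -> None:
        """Check phases are non-overlapping, ordered and exhaustive."""
        spans = sorted(self.values())
        cursor = start
        for first, last in spans:
            if first < cursor:
                raise DataError("phases overlap")
            if first > cursor:
                raise DataError("phases leave a gap")
            cursor = last + 1
        if cursor != start + n_total:
            raise DataError("phases do not cover all indices")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def _read_csv(path: Path, what: str) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"{what}: file not found: {path}")
    return pd.read_csv(path)


def read_plate_rates(path: str | Path, dialect: str = "long") -> PlateRun:
    """Read a plate run from its canonical delimited-text tables.

    ``path`` is a directory containing ``plate_rates.csv`` plus the sidecar
    tables ``plate_o2.csv`` (optional), ``plate_injections.csv`` and
    ``plate_meta.csv``.  ``dialect`` is ``"long"`` (one row per well x cycle)
    or ``"wide"`` (one row per cycle, one OCR column per well).
    """
    if dialect not in ("long", "wide"):
        raise FormatError(f"unknown plate dialect {dialect!r}")
    base = Path(path)
    rates = _read_csv(base / "plate_rates.csv", "plate rates")
    inj_df = _read_csv(base / "plate_injections.csv", "plate injections")
    meta = _read_csv(base / "plate_meta.csv", "plate metadata")
    o2_path = base / "plate_o2.csv"
    o2 = pd.read_csv(o2_path) if o2_path.exists() else None

    _require_columns(inj_df, _PLATE_INJ_COLS, "plate injections")
    _require_columns(meta, _PLATE_META_COLS, "plate metadata")
    if o2 is not None:
        _require_columns(o2, _PLATE_O2_COLS, "plate O2 levels")

    if dialect == "wide":
        _require_columns(rates, ["cycle", "t_mid_s"], "plate rates (wide)")
        well_cols = [c for c in rates.columns if c not in ("cycle", "t_mid_s")]
        if not well_cols:
            raise FormatError("plate rates (wide): no well columns")
        rates = rates.melt(
            id_vars=["cycle", "t_mid_s"], value_vars=well_cols,
            var_name="well", value_name="ocr_pmol_per_min",
        )
        rates = rates.merge(meta[["well", "animal_id", "group"]], on="well", how="left")
    _require_columns(rates, _PLATE_RATE_COLS, "plate rates")

    injections = [
        InjectionEvent(str(r.label), str(r.port), float(r.time_s), str(r.concentration))
        for r in inj_df.itertuples()
    ]
    meta_by_well = meta.set_index(meta["well"].astype(str))

    wells: list[WellSeries] = []
    for well_id, sub in rates.groupby("well", sort=True):
        sub = sub.sort_values("cycle")
        if not np.all(np.diff(sub["t_mid_s"].to_numpy()) > 0):
            raise DataError(f"well {well_id}: non-monotone cycle times in rates table")
        o2_by_cycle: dict[int, list[tuple[float, float]]] = {}
        if o2 is not None:
            wo2 = o2[o2["well"].astype(str) == str(well_id)]
            for cyc, ticks in wo2.groupby("cycle"):
                ticks = ticks.sort_values("t_s")
                o2_by_cycle[int(cyc)] = list(
                    zip(ticks["t_s"].astype(float), ticks["o2_mmHg"].astype(float))
                )
        cycles = [
            Cycle(int(r.cycle), float(r.t_mid_s), float(r.ocr_pmol_per_min),
                  o2_by_cycle.get(int(r.cycle), []))
            for r in sub.itertuples()
        ]
        m = meta_by_well.loc[str(well_id)]
        seeding = None if pd.isna(m["seeding_count"]) else float(m["seeding_count"])
        wells.append(
            WellSeries(
                well_id=str(well_id),
                group_label=str(m["group"]),
                animal_id=str(m["animal_id"]),
                seeding_count=seeding,
                cycles=cycles,
                injections=list(injections),
            )
        )
    return PlateRun(run_id=base.name or "plate", wells=wells)


def write_plate_run(run: PlateRun, path: str | Path) -> Path:
    """Write a plate run in the canonical long dialect (inverse of the reader)."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    rate_rows, o2_rows, meta_rows = [], [], []
    for w in run.wells:
        meta_rows.append(
            dict(well=w.well_id, animal_id=w.animal_id, group=w.group_label,
                 seeding_count=w.seeding_count)
        )
        for c in w.cycles:
            rate_rows.append(
                dict(well=w.well_id, group=w.group_label, animal_id=w.animal_id,
                     cycle=c.index, t_mid_s=c.t_mid_s, ocr_pmol_per_min=c.ocr_pmol_per_min)
            )
            for t, mmhg in c.o2_ticks:
                o2_rows.append(dict(well=w.well_id, cycle=c.index, t_s=t, o2_mmHg=mmhg))
    pd.DataFrame(rate_rows, columns=_PLATE_RATE_COLS).to_csv(base / "plate_rates.csv", index=False)
    pd.DataFrame(meta_rows, columns=_PLATE_META_COLS).to_csv(base / "plate_meta.csv", index=False)
    inj = run.wells[0].injections if run.wells else []
    pd.DataFrame(
        [dict(label=e.label, port=e.port, time_s=e.time_s, concentration=e.concentration)
         for e in inj],
        columns=_PLATE_INJ_COLS,
    ).to_csv(base / "plate_injections.csv", index=False)
    if o2_rows:
        pd.DataFrame(o2_rows, columns=_PLATE_O2_COLS).to_csv(base / "plate_o2.csv", index=False)
    return base


def read_chamber_export(path: str | Path, dialect: str = "canonical") -> list[ChamberRun]:
    """Read chamber runs from ``chamber_ticks.csv`` / ``chamber_marks.csv`` /
    ``chamber_meta.csv`` under ``path``.  Unknown mark names are preserved
    verbatim; marks out of canonical order set a warning flag, not an error.
    """
    if dialect != "canonical":
        raise FormatError(f"unknown chamber dialect {dialect!r}")
    base = Path(path)
    ticks = _read_csv(base / "chamber_ticks.csv", "chamber ticks")
    marks = _read_csv(base / "chamber_marks.csv", "chamber marks")
    meta = _read_csv(base / "chamber_meta.csv", "chamber metadata")
    _require_columns(ticks, _CHAMBER_TICK_COLS, "chamber ticks")
    _require_columns(marks, _CHAMBER_MARK_COLS, "chamber marks")
    _require_columns(meta, _CHAMBER_META_COLS, "chamber metadata")

    runs: list[ChamberRun] = []
    for m in meta.itertuples():
        cid = str(m.chamber_id)
        sub = ticks[ticks["chamber_id"].astype(str) == cid].sort_values("t_s")
        msub = marks[marks["chamber_id"].astype(str) == cid].sort_values("t_s")
        w1 = None if pd.isna(m.wet_weight_mg_rep1) else float(m.wet_weight_mg_rep1)
        w2 = None if pd.isna(m.wet_weight_mg_rep2) else float(m.wet_weight_mg_rep2)
        run = ChamberRun(
            chamber_id=cid,
            animal_id=str(m.animal_id),
            group_label=str(m.group),
            wet_weight_mg_rep1=w1,
            wet_weight_mg_rep2=w2,
            ticks=sub[["t_s", "o2_conc_uM", "flux_pmol_per_s_per_mL"]].to_numpy(float),
            marks=[(str(r.name), float(r.t_s)) for r in msub.itertuples(index=False)],
            instrumental_background=float(m.instrumental_background_pmol_per_s_per_mL),
            fiber_background_window=(float(m.bg_window_start_s), float(m.bg_window_end_s)),
        )
        if "MARKS_OUT_OF_ORDER" in run.flags:
            warnings.warn(f"chamber {cid}: titration marks out of canonical order")
        runs.append(run)
    return runs


def write_chamber_runs(runs: Iterable[ChamberRun], path: str | Path) -> Path:
    """Write chamber runs in the canonical dialect (inverse of the reader)."""
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    tick_frames, mark_rows, meta_rows = [], [], []
    for r in runs:
        df = pd.DataFrame(r.ticks, columns=["t_s", "o2_conc_uM", "flux_pmol_per_s_per_mL"])
        df.insert(0, "chamber_id", r.chamber_id)
        tick_frames.append(df)
        for name, t in r.marks:
            mark_rows.append(dict(chamber_id=r.chamber_id, name=name, t_s=t))
        meta_rows.append(
            dict(
                chamber_id=r.chamber_id, animal_id=r.animal_id, group=r.group_label,
                wet_weight_mg_rep1=r.wet_weight_mg_rep1, wet_weight_mg_rep2=r.wet_weight_mg_rep2,
                instrumental_background_pmol_per_s_per_mL=r.instrumental_background,
                bg_window_start_s=r.fiber_background_window[0],
                bg_window_end_s=r.fiber_background_window[1],
            )
        )
    pd.concat(tick_frames, ignore_index=True).to_csv(base / "chamber_ticks.csv", index=False)
    pd.DataFrame(mark_rows, columns=_CHAMBER_MARK_COLS).to_csv(base / "chamber_marks.csv", index=False)
    pd.DataFrame(meta_rows, columns=_CHAMBER_META_COLS).to_csv(base / "chamber_meta.csv", index=False)
    return base


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def segment_phases(
    run: PlateRun | ChamberRun | WellSeries,
    equilibration_delay_s: float = 60.0,
) -> PhaseMap:
    """Partition a run into protocol phases.

    Plate (or single well): ``basal`` covers every cycle before the first
    injection; each subsequent phase covers the cycles between successive
    injections (1-based cycle indices, inclusive).  Chamber: one window per
    titration mark, from ``mark_time + equilibration_delay_s`` to the last
    tick before the next mark (0-based tick indices, inclusive); the delay
    excludes mixing transients after titration.
    """
    if isinstance(run, ChamberRun):
        return _segment_chamber(run, equilibration_delay_s)
    well = run.wells[0] if isinstance(run, PlateRun) else run
    if not well.injections:
        raise DataError("cannot segment phases: no injections recorded")
    times = [c.t_mid_s for c in well.cycles]
    n = len(times)
    bounds = [e.time_s for e in well.injections]
    names = [BASAL] + [PHASE_AFTER.get(e.label, f"post_{e.label}") for e in well.injections]
    edges = [-np.inf] + bounds + [np.inf]
    pm = PhaseMap()
    cursor = 1
    for name, lo, hi in zip(names, edges[:-1], edges[1:]):
        # inclusive range of cycles whose midpoint falls in (lo, hi]
        in_phase = [i + 1 for i, t in enumerate(times) if lo < t <= hi]
        if in_phase:
            first, last = in_phase[0], in_phase[-1]
            cursor = last + 1
        else:
            first, last = cursor, cursor - 1
            pm.empty_phases.add(name)
        pm[name] = (first, last)
    return pm


def _segment_chamber(run: ChamberRun, delay_s: float) -> PhaseMap:
    t = run.ticks[:, 0]
    pm = PhaseMap()
    mark_times = [mt for _, mt in run.marks] + [np.inf]
    for (name, mt), next_t in zip(run.marks, mark_times[1:]):
        lo = mt + delay_s
        idx = np.nonzero((t >= lo) & (t < next_t))[0]
        if idx.size:
            pm[name] = (int(idx[0]), int(idx[-1]))
        else:
            pm[name] = (0, -1)
            pm.empty_phases.add(name)
    return pm
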