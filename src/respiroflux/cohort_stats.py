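"""Cohort assembly, robust outlier removal, normality-gated group tests,
and the cross-tissue correlation analysis.

The analysis pipeline applies, in a fixed and logged order: upstream QC
flags (handled in the derivation modules) -> ROUT outlier removal per
parameter per group -> Shapiro-Wilk normality gate -> Welch t or
Mann-Whitney for group differences and Pearson or Spearman for
correlations.  Re-running any stage on its own output is idempotent.

ROUT here is the robust-fit + FDR residual test on a constant-location
model (the published procedure targets regression; a column of scalars is
its constant special case): a location minimizing the Lorentzian merit
function, a robust scale (RSDR) from the 68.27th percentile of absolute
residuals with a small-sample df adjustment, per-point two-tailed
t-distribution p-values, and Benjamini-Hochberg step-up control at rate Q
scanning points from most to least extreme.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError
from .xf_mst import MSTResult, mst_result_fields
from .o2k_suit import SUITResult, suit_result_fields

NORMAL = "normal"
NON_NORMAL = "non_normal"

#: platelet-side (plate) and muscle-side (chamber) column prefixes
PLT_PREFIX = "plt_"
SM_PREFIX = "sm_"

_PLT_MAP = {
    "ocr_basal": "plt_basal", "ocr_leak": "plt_leak", "ocr_atp": "plt_atp",
    "ocr_max": "plt_max", "ocr_nonmito": "plt_nonmito", "rescap_abs": "plt_rescap",
    "rescap_pct": "plt_rescap_pct", "ce_pct": "plt_ce_pct",
}
_SM_MAP = {
    "ci_oxphos": "sm_ci", "ci_oxphos_cytc": "sm_ci_cytc", "p_oxphos": "sm_p",
    "leak_l": "sm_l", "atp_linked": "sm_atp_linked", "ce_pct": "sm_ce_pct",
    "rcr": "sm_rcr", "rox": "sm_rox", "cytc_abs_gain": "sm_cytc_gain",
    "succinate_abs_gain": "sm_succ_gain", "fce_cytc": "sm_fce_cytc",
    "fce_succinate": "sm_fce_succ",
}


@dataclass
class RoutDiagnostics:
    location: float
    rsdr: float
    p_values: np.ndarray
    removed_indices: np.ndarray


@dataclass
class ComparisonResult:
    parameter: str
    test: str                      # "welch_t" | "mann_whitney"
    statistic: float
    p_two_tailed: float
    difference: float              # disease - control; mean (Welch) or HL median
    difference_se: float | None
    n_control: int
    n_disease: int
    gate: str
    outliers_removed: int = 0

    @property
    def significance(self) -> str:
        if self.p_two_tailed < 0.01:
            return "**"
        if self.p_two_tailed < 0.05:
            return "*"
        return "ns"


@dataclass
class CorrelationResult:
    x_parameter: str
    y_parameter: str
    method: str                    # "pearson" | "spearman"
    estimate: float | None
    ci95_low: float | None
    ci95_high: float | None
    p_two_tailed: float | None
    n: int
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# cohort table assembly
# ---------------------------------------------------------------------------

def assemble_cohort_table(
    mst_by_animal: dict[str, MSTResult] | None = None,
    suit_by_animal: dict[str, SUITResult] | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the animal x parameter table from per-animal derived results.

    Platelet parameters get the ``plt_`` prefix, muscle parameters ``sm_``.
    Cells are NaN where a parameter was excluded for that animal.
    """
    animals: dict[str, dict] = {}

    def row(animal_id: str, group: str) -> dict:
        if animal_id not in animals:
            animals[animal_id] = {"animal_id": animal_id, "group": group}
        return animals[animal_id]

    for res in (mst_by_animal or {}).values():
        r = row(res.animal_id, res.group_label)
        for f in mst_result_fields():
            if f in _PLT_MAP:
                v = getattr(res, f)
                r[_PLT_MAP[f]] = np.nan if v is None else v
    for res in (suit_by_animal or {}).values():
        r = row(res.animal_id, res.group_label)
        for f in suit_result_fields():
            if f in _SM_MAP:
                v = getattr(res, f)
                r[_SM_MAP[f]] = np.nan if v is None else v
    if groups:
        for aid, g in groups.items():
            row(aid, g)
    table = pd.DataFrame(list(animals.values()))
    if table.empty:
        raise DataError("cohort table is empty")
    if table["animal_id"].duplicated().any():
        raise DataError("cohort table must have one row per animal")
    if table["group"].isna().any() or (table["group"] == "").any():
        raise DataError("group labels must be non-empty")
    return table.sort_values("animal_id").reset_index(drop=True)


def parameter_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith((PLT_PREFIX, SM_PREFIX))]


# ---------------------------------------------------------------------------
# ROUT outlier removal (constant-location model)
# ---------------------------------------------------------------------------

def _lorentzian_location(x: np.ndarray, n_iter: int = 60) -> tuple[float, float]:
    """Location minimizing the Lorentzian merit sum(log1p((res/s)^2)),
    iterating the scale s as the 68.27th percentile of |residuals|."""
    m = float(np.median(x))
    s = float(np.percentile(np.abs(x - m), 68.27))
    if s == 0:
        return m, 0.0
    lo, hi = float(np.min(x)), float(np.max(x))
    for _ in range(n_iter):
        res = optimize.minimize_scalar(
            lambda mu: float(np.sum(np.log1p(((x - mu) / s) ** 2))),
            bounds=(lo, hi), method="bounded",
        )
        m_new = float(res.x)
        s_new = float(np.percentile(np.abs(x - m_new), 68.27))
        if s_new == 0:
            return m_new, 0.0
        if abs(m_new - m) < 1e-12 * max(1.0, abs(m)) and abs(s_new - s) < 1e-12 * s:
            m, s = m_new, s_new
            break
        m, s = m_new, s_new
    return m, s


def rout_outliers(
    values: np.ndarray | list[float],
    q: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, RoutDiagnostics]:
    """ROUT outlier detection on a column of scalars at FDR rate ``q``.

    Returns (kept, removed, diagnostics); indices in the diagnostics refer
    to the input order.  With all values identical there is no scale and
    nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DataError("ROUT needs at least 3 values")
    if not np.all(np.isfinite(x)):
        raise DataError("ROUT input must be finite")
    if not 0 < q <= 0.10:
        raise DataError("Q must be in (0, 0.10]")
    n = x.size
    m, s68 = _lorentzian_location(x)
    resid = x - m
    if s68 == 0:
        nonzero = np.abs(resid) > 0
        removed_idx = np.nonzero(nonzero)[0] if nonzero.any() else np.array([], dtype=int)
        # >68% of points coincide exactly; any point off that value is
        # infinitely many robust SDs away.
        p = np.where(nonzero, 0.0, 1.0)
        keep = np.setdiff1d(np.arange(n), removed_idx)
        return x[keep], x[removed_idx], RoutDiagnostics(m, 0.0, p, removed_idx)
    rsdr = s68 * n / (n - 1)  # small-sample df adjustment, K=1 parameter
    t = np.abs(resid) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    # BH step-up from most to least extreme
    order = np.argsort(p)
    thresholds = q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresholds
    k = int(np.nonzero(below)[0].max() + 1) if below.any() else 0
    removed_idx = np.sort(order[:k])
    keep = np.setdiff1d(np.arange(n), removed_idx)
    return x[keep], x[removed_idx], RoutDiagnostics(m, rsdr, p, removed_idx)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(
    values: np.ndarray | list[float],
    groups: np.ndarray | list | None = None,
    alpha: float = 0.05,
    mode: str = "pooled_centered",
) -> tuple[str, dict]:
    """Shapiro-Wilk gate deciding parametric vs non-parametric treatment.

    Default mode centers each group at its mean and tests the pooled
    residuals; ``mode="per_group"`` tests each group separately and any
    non-normal group gates the parameter non-normal.  Degenerate inputs
    (n < 3, constant values) gate non-normal with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)] if groups is None else x
    info: dict = {"mode": mode, "alpha": alpha}
    if x.size < 3:
        info["warning"] = "fewer than 3 values"
        return NON_NORMAL, info
    if np.ptp(x) == 0:
        info["warning"] = "constant values"
        return NON_NORMAL, info
    if groups is not None:
        g = np.asarray(groups)
        if mode == "per_group":
            ps = []
            for lvl in pd.unique(g):
                sub = x[g == lvl]
                if sub.size < 3 or np.ptp(sub) == 0:
                    info["warning"] = f"group {lvl!r} degenerate"
                    return NON_NORMAL, info
                ps.append(stats.shapiro(sub).pvalue)
            info["p_values"] = ps
            return (NORMAL if all(p > alpha for p in ps) else NON_NORMAL), info
        resid = np.concatenate([x[g == lvl] - x[g == lvl].mean() for lvl in pd.unique(g)])
    else:
        resid = x
    if np.ptp(resid) == 0:
        info["warning"] = "constant residuals"
        return NON_NORMAL, info
    stat = stats.shapiro(resid)
    info["statistic"], info["p_value"] = float(stat.statistic), float(stat.pvalue)
    return (NORMAL if stat.pvalue > alpha else NON_NORMAL), info


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _hodges_lehmann(a: np.ndarray, b: np.ndarray) -> float:
    """Median of all pairwise differences a_i - b_j."""
    return float(np.median(a[:, None] - b[None, :]))


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    control_label: str = "control",
    disease_label: str | None = None,
    rout_q: float | None = 0.01,
    gate: str | None = None,
    alpha_gate: float = 0.05,
) -> ComparisonResult:
    """Compare disease vs control for one parameter.

    Values are cleaned by ROUT per group (``rout_q=None`` skips), gated by
    Shapiro-Wilk on pooled within-group-centered residuals (unless ``gate``
    is forced), then tested by Welch t (normal) or Mann-Whitney with a
    Hodges-Lehmann median difference (non-normal).  The difference is
    disease - control.
    """
    if parameter not in table.columns:
        raise DataError(f"unknown parameter {parameter!r}")
    labels = [l for l in pd.unique(table["group"]) if l != control_label]
    if disease_label is None:
        if len(labels) != 1:
            raise DataError(f"cannot infer disease group from {labels}")
        disease_label = labels[0]
    ctrl = table.loc[table["group"] == control_label, parameter].dropna().to_numpy(float)
    dis = table.loc[table["group"] == disease_label, parameter].dropna().to_numpy(float)
    if ctrl.size == 0 or dis.size == 0:
        raise DataError(f"parameter {parameter!r}: a group is empty")
    removed = 0
    if rout_q is not None:
        if ctrl.size >= 3:
            ctrl, rem_c, _ = rout_outliers(ctrl, rout_q)
            removed += rem_c.size
        if dis.size >= 3:
            dis, rem_d, _ = rout_outliers(dis, rout_q)
            removed += rem_d.size
    if ctrl.size < 2 or dis.size < 2:
        raise DataError(f"parameter {parameter!r}: fewer than 2 values per group after cleaning")
    if gate is None:
        pooled = np.concatenate([ctrl, dis])
        glab = np.array(["c"] * ctrl.size + ["d"] * dis.size)
        gate, _ = normality_gate(pooled, glab, alpha=alpha_gate)
    if gate == NORMAL:
        t, p = stats.ttest_ind(dis, ctrl, equal_var=False)
        se = float(np.sqrt(np.var(dis, ddof=1) / dis.size + np.var(ctrl, ddof=1) / ctrl.size))
        return ComparisonResult(parameter, "welch_t", float(t), float(p),
                                float(dis.mean() - ctrl.mean()), se,
                                ctrl.size, dis.size, gate, removed)
    ties = np.unique(np.concatenate([ctrl, dis])).size < ctrl.size + dis.size
    method = "exact" if (max(ctrl.size, dis.size) <= 8 and not ties) else "asymptotic"
    u, p = stats.mannwhitneyu(dis, ctrl, alternative="two-sided", method=method)
    return ComparisonResult(parameter, "mann_whitney", float(u), float(p),
                            _hodges_lehmann(dis, ctrl), None,
                            ctrl.size, dis.size, gate, removed)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _fisher_ci(est: float, n: int, se_scale: float = 1.0) -> tuple[float, float]:
    if abs(est) >= 1.0:
        return est, est
    z = math.atanh(est)
    half = stats.norm.ppf(0.975) * se_scale / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    statistic: str = "pearson",
    max_exact_n: int = 8,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p for a correlation statistic.

    Enumerates all n! pairings when n <= ``max_exact_n`` (exact), otherwise
    Monte-Carlo resamples.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    def stat(yy: np.ndarray) -> float:
        if statistic == "pearson":
            return float(stats.pearsonr(x, yy).statistic)
        return float(stats.spearmanr(x, yy).statistic)

    obs = abs(stat(y))
    if n <= max_exact_n:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(stat(y[list(perm)])) >= obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = sum(abs(stat(rng.permutation(y))) >= obs - 1e-12 for _ in range(reps))
    return (count + 1) / (reps + 1)


def correlate(
    table: pd.DataFrame,
    x_param: str,
    y_param: str,
    method: str | None = None,
    gates: dict[str, str] | None = None,
    p_method: str = "analytic",
) -> CorrelationResult:
    """Correlate two parameters over pairwise-complete animals.

    The method follows the normality gate of both parameters (Pearson when
    both normal, else Spearman) unless forced.  Pearson CIs use the Fisher
    z transform; Spearman CIs use Fisher z with the adjusted standard
    error 1.03/sqrt(n-3).  ``p_method="permutation"`` replaces the analytic
    p-value (exact enumeration for n <= 8).
    """
    for p in (x_param, y_param):
        if p not in table.columns:
            raise DataError(f"unknown parameter {p!r}")
    sub = table[[x_param, y_param]].dropna()
    n = len(sub)
    if n < 4:
        raise DataError(f"{x_param} vs {y_param}: fewer than 4 complete pairs")
    x = sub[x_param].to_numpy(float)
    y = sub[y_param].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_param, y_param, method or "pearson",
                                 None, None, None, None, n, {"ZERO_VARIANCE"})
    if method is None:
        if gates is not None:
            both_normal = gates.get(x_param) == NORMAL and gates.get(y_param) == NORMAL
        else:
            both_normal = (normality_gate(x)[0] == NORMAL and normality_gate(y)[0] == NORMAL)
        method = "pearson" if both_normal else "spearman"
    if method == "pearson":
        r = stats.pearsonr(x, y)
        est, p = float(r.statistic), float(r.pvalue)
        lo, hi = _fisher_ci(est, n)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
        est, p = float(r.statistic), float(r.pvalue)
        lo, hi = _fisher_ci(est, n, se_scale=1.03)
    else:
        raise DataError(f"unknown correlation method {method!r}")
    if p_method == "permutation":
        p = permutation_p(x, y, statistic=method)
    return CorrelationResult(x_param, y_param, method, est, lo, hi, p, n)


def clean_table(
    table: pd.DataFrame,
    rout_q: float | None = 0.01,
    gate_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str], list[dict]]:
    """ROUT-clean every parameter column per group and gate each parameter.

    Returns (cleaned table with outliers set to NaN, per-parameter gate,
    removal log).  Applying it to its own output removes nothing further.
    """
    out = table.copy()
    log: list[dict] = []
    gates: dict[str, str] = {}
    for col in parameter_columns(out):
        if rout_q is not None:
            for lvl in pd.unique(out["group"]):
                mask = (out["group"] == lvl) & out[col].notna()
                vals = out.loc[mask, col].to_numpy(float)
                if vals.size < 3:
                    continue
                _, removed, diag = rout_outliers(vals, rout_q)
                if removed.size:
                    idx = out.index[mask][diag.removed_indices]
                    for i in idx:
                        log.append(dict(parameter=col, group=lvl,
                                        animal_id=out.loc[i, "animal_id"],
                                        value=float(out.loc[i, col]), rule="ROUT"))
                    out.loc[idx, col] = np.nan
        vals = out[col].dropna().to_numpy(float)
        grp = out.loc[out[col].notna(), "group"].to_numpy()
        gates[col], _ = normality_gate(vals, grp, alpha=gate_alpha)
    return out, gates, log


def correlation_matrix(
    table: pd.DataFrame,
    x_params: list[str] | None = None,
    y_params: list[str] | None = None,
    cohort: str = "pooled",
    control_label: str = "control",
    rout_q: float | None = 0.01,
    min_pairs: int = 4,
) -> tuple[list[CorrelationResult], dict[str, pd.DataFrame], list[dict]]:
    """All platelet x muscle correlations, method chosen per the gate.

    ``cohort="control"`` restricts to the control group before
    correlating; ``"pooled"`` uses every animal.  Returns the result list,
    matrices (estimate, p, n) as DataFrames, and a report of skipped
    pairs/columns.
    """
    if cohort == "control":
        table = table[table["group"] == control_label]
    elif cohort != "pooled":
        raise DataError(f"unknown cohort restriction {cohort!r}")
    cleaned, gates, removal_log = clean_table(table, rout_q)
    if x_params is None:
        x_params = [c for c in parameter_columns(cleaned) if c.startswith(PLT_PREFIX)]
    if y_params is None:
        y_params = [c for c in parameter_columns(cleaned) if c.startswith(SM_PREFIX)]
    report = list(removal_log)
    for axis, params in (("x", list(x_params)), ("y", list(y_params))):
        for c in params:
            if c not in cleaned.columns or cleaned[c].notna().sum() == 0:
                report.append(dict(parameter=c, rule="ALL_NULL_COLUMN_OMITTED"))
                (x_params if axis == "x" else y_params).remove(c)
    results: list[CorrelationResult] = []
    est = pd.DataFrame(index=x_params, columns=y_params, dtype=float)
    pmat = pd.DataFrame(index=x_params, columns=y_params, dtype=float)
    nmat = pd.DataFrame(index=x_params, columns=y_params, dtype=float)
    for xp in x_params:
        for yp in y_params:
            pairs = cleaned[[xp, yp]].dropna()
            if len(pairs) < min_pairs:
                report.append(dict(parameter=f"{xp}~{yp}", rule="TOO_FEW_PAIRS"))
                continue
            res = correlate(cleaned, xp, yp, gates=gates)
            results.append(res)
            est.loc[xp, yp] = res.estimate
            pmat.loc[xp, yp] = res.p_two_tailed
            nmat.loc[xp, yp] = res.n
    return results, {"estimate": est, "p": pmat, "n": nmat}, report
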