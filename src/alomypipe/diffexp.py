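"""Fold-change regulation calls, response sets, outlier testing and profiles.

Differential regulation between two modalities is called from RPKM alone:
up when A/B >= 2 with max(A, B) >= 1.8, down symmetrically, else stable (the
pooled, no-replicate design leaves fold/expression thresholds as the operative
criteria). Response sets compare each herbicide-treated modality with the
untreated (UT) modality of the same phenotype and partition regulated contigs
into common and phenotype-specific sets; time-points flagged by modality QC
are excluded. A two-sided Grubbs test covers both the modality QC and the
admission test for the late time-point sampled in a separate experiment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import Modality, TREATED_TIME_POINTS

EPSILON = 0.1  # RPKM pseudocount for zero denominators


@dataclass(frozen=True)
class RegulationCall:
    contig_id: str
    comparison: tuple[str, str]
    fold: float
    call: str  # up | down | stable


def _fold(a: float, b: float, eps: float = EPSILON) -> float:
    return a / b if b > 0 else a / eps


def regulation_call(
    rpkm_a: float,
    rpkm_b: float,
    fold_min: float = 2.0,
    rpkm_min: float = 1.8,
    contig_id: str = "",
    comparison: tuple[str, str] = ("A", "B"),
) -> RegulationCall:
    """Call A vs B: up iff A/B >= fold_min and max >= rpkm_min; antisymmetric."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("negative RPKM")
    hi = max(rpkm_a, rpkm_b)
    fwd = _fold(rpkm_a, rpkm_b)
    rev = _fold(rpkm_b, rpkm_a)
    if hi >= rpkm_min and fwd >= fold_min:
        call = "up"
        fold = fwd
    elif hi >= rpkm_min and rev >= fold_min:
        call = "down"
        fold = fwd
    else:
        call = "stable"
        fold = fwd
    return RegulationCall(contig_id, comparison, fold, call)


def _call_columns(
    rpkm: pd.DataFrame, col_a: str, col_b: str, fold_min: float, rpkm_min: float
) -> pd.Series:
    """Vectorized regulation_call over a contig column pair -> 'up'/'down'/'stable'."""
    a = rpkm[col_a].to_numpy(dtype=float)
    b = rpkm[col_b].to_numpy(dtype=float)
    hi = np.maximum(a, b)
    fwd = np.where(b > 0, a / np.where(b > 0, b, 1.0), a / EPSILON)
    rev = np.where(a > 0, b / np.where(a > 0, a, 1.0), b / EPSILON)
    call = np.where(
        (hi >= rpkm_min) & (fwd >= fold_min),
        "up",
        np.where((hi >= rpkm_min) & (rev >= fold_min), "down", "stable"),
    )
    return pd.Series(call, index=rpkm.index)


@dataclass
class ResponseSets:
    """Per-phenotype regulated sets (each treated time-point vs the phenotype's
    UT) and the derived common / phenotype-specific partitions."""

    up: dict[str, dict[str, set[str]]]  # phenotype -> time-point -> contigs
    down: dict[str, dict[str, set[str]]]
    retained_time_points: tuple[str, ...]
    common_up: set[str] = field(default_factory=set)
    common_down: set[str] = field(default_factory=set)
    R_only_up: set[str] = field(default_factory=set)
    R_only_down: set[str] = field(default_factory=set)
    S_only_up: set[str] = field(default_factory=set)
    S_only_down: set[str] = field(default_factory=set)
    all_treated_up: dict[str, set[str]] = field(default_factory=dict)
    all_treated_down: dict[str, set[str]] = field(default_factory=dict)

    def any_up(self, phenotype: str) -> set[str]:
        return set().union(*self.up[phenotype].values()) if self.up[phenotype] else set()

    def any_down(self, phenotype: str) -> set[str]:
        return (
            set().union(*self.down[phenotype].values()) if self.down[phenotype] else set()
        )


def build_response_sets(
    rpkm: pd.DataFrame,
    design: tuple[Modality, ...],
    qc_flags: tuple[str, ...] = (),
    fold_min: float = 2.0,
    rpkm_min: float = 1.8,
) -> ResponseSets:
    """Compare each treated modality with its phenotype's UT and derive the
    common / specific partitions.

    A whole time-point is dropped when either phenotype's modality at that
    time-point is QC-flagged. A contig is common_up when it is up in both
    phenotypes in at least one retained treated modality each (not necessarily
    the same time-point); the "all treated" sets require the call at every
    retained treated time-point.
    """
    by_name = {m.name: m for m in design}
    phenos = sorted({m.phenotype for m in design})
    for p in phenos:
        if f"{p}_UT" not in by_name or f"{p}_UT" not in rpkm.columns:
            raise ValueError(f"missing UT modality for phenotype {p}")
    flagged_tp = {by_name[f].time_point for f in qc_flags if f in by_name}
    retained = tuple(
        t
        for t in TREATED_TIME_POINTS
        if t not in flagged_tp
        and all(f"{p}_{t}" in rpkm.columns for p in phenos)
    )
    up: dict[str, dict[str, set[str]]] = {p: {} for p in phenos}
    down: dict[str, dict[str, set[str]]] = {p: {} for p in phenos}
    for p in phenos:
        ut = f"{p}_UT"
        for t in retained:
            calls = _call_columns(rpkm, f"{p}_{t}", ut, fold_min, rpkm_min)
            up[p][t] = set(calls.index[calls == "up"])
            down[p][t] = set(calls.index[calls == "down"])
    rs = ResponseSets(up=up, down=down, retained_time_points=retained)
    if {"R", "S"} <= set(phenos):
        r_up, s_up = rs.any_up("R"), rs.any_up("S")
        r_dn, s_dn = rs.any_down("R"), rs.any_down("S")
        rs.common_up = r_up & s_up
        rs.common_down = r_dn & s_dn
        rs.R_only_up = r_up - s_up
        rs.S_only_up = s_up - r_up
        rs.R_only_down = r_dn - s_dn
        rs.S_only_down = s_dn - r_dn
    for p in phenos:
        sets_u = [up[p][t] for t in retained]
        sets_d = [down[p][t] for t in retained]
        rs.all_treated_up[p] = set.intersection(*sets_u) if sets_u else set()
        rs.all_treated_down[p] = set.intersection(*sets_d) if sets_d else set()
    return rs


# ---------------------------------------------------------------------------
# Grubbs outlier test


@dataclass(frozen=True)
class GrubbsResult:
    is_outlier: bool
    index: int
    statistic: float
    critical: float


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test: G = max|x - mean| / sd."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation; no outlier detectable")
        return GrubbsResult(False, 0, 0.0, grubbs_critical(len(x), alpha))
    dev = np.abs(x - x.mean())
    i = int(dev.argmax())
    g = dev[i] / sd
    crit = grubbs_critical(len(x), alpha)
    return GrubbsResult(bool(g > crit), i, float(g), float(crit))


# ---------------------------------------------------------------------------
# Expression-profile classification (time-course patterns)

PROFILE_TIME_ORDER = TREATED_TIME_POINTS


def classify_profile(
    rpkm_by_time: dict[str, float],
    log2_threshold: float = 1.0,
    eps: float = EPSILON,
) -> str:
    """Label a phenotype's time-course against its UT value.

    Uses r_t = log2((rpkm_t + eps) / (UT + eps)) and a threshold of one
    (the 2-fold convention): UP_ALL / DOWN_ALL / STABLE / UP_THEN_DOWN(t*) /
    DOWN_THEN_UP(t*) / PEAK(t*), else COMPLEX; missing time-points -> UNKNOWN.
    """
    if "UT" not in rpkm_by_time:
        return "UNKNOWN"
    times = [t for t in PROFILE_TIME_ORDER if t in rpkm_by_time]
    if not times:
        return "UNKNOWN"
    ut = rpkm_by_time["UT"]
    r = np.array(
        [np.log2((rpkm_by_time[t] + eps) / (ut + eps)) for t in times]
    )
    sign = np.where(r >= log2_threshold, 1, np.where(r <= -log2_threshold, -1, 0))
    if (sign == 1).all():
        return "UP_ALL"
    if (sign == -1).all():
        return "DOWN_ALL"
    if (sign == 0).all():
        return "STABLE"
    for i in range(len(sign) - 1):
        if (sign[: i + 1] == 1).all() and (sign[i + 1 :] == -1).all():
            return f"UP_THEN_DOWN({times[i]})"
        if (sign[: i + 1] == -1).all() and (sign[i + 1 :] == 1).all():
            return f"DOWN_THEN_UP({times[i]})"
    if (sign == 1).sum() == 1 and (sign == 0).sum() == len(sign) - 1:
        return f"PEAK({times[int(np.argmax(sign))]})"
    return "COMPLEX"


# ---------------------------------------------------------------------------
# Marker-signature concordance


def marker_concordance(
    rpkm: pd.DataFrame,
    marker_table: pd.DataFrame,
    time_point: str,
    fold_min: float = 2.0,
    rpkm_min: float = 1.8,
) -> pd.DataFrame:
    """Score reference transcriptional markers against both phenotype pools.

    marker_table columns: marker_id, group (1 or 2), direction (up/down),
    contig_id (empty/NaN for markers without a mapped homolog). A marker
    agrees in a pool when the homolog's regulation call (time_point vs UT)
    matches the reference direction. Adds a `status` column:
    agree_both / agree_one / disagree / no_homolog.
    """
    rows = []
    for rec in marker_table.itertuples(index=False):
        cid = getattr(rec, "contig_id", None)
        if cid is None or (isinstance(cid, float) and np.isnan(cid)) or cid == "" or cid not in rpkm.index:
            status, calls = "no_homolog", {}
        else:
            calls = {}
            for p in ("R", "S"):
                c = regulation_call(
                    rpkm.at[cid, f"{p}_{time_point}"],
                    rpkm.at[cid, f"{p}_UT"],
                    fold_min,
                    rpkm_min,
                )
                calls[p] = c.call
            n_agree = sum(calls[p] == rec.direction for p in ("R", "S"))
            status = {2: "agree_both", 1: "agree_one", 0: "disagree"}[n_agree]
        rows.append(
            {
                "marker_id": rec.marker_id,
                "group": rec.group,
                "direction": rec.direction,
                "contig_id": cid if status != "no_homolog" else "",
                "call_R": calls.get("R", ""),
                "call_S": calls.get("S", ""),
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def concordance_counts(concordance: pd.DataFrame) -> pd.DataFrame:
    """Per-group counts of agree_both / agree_one / disagree / no_homolog."""
    return (
        concordance.groupby(["group", "status"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["agree_both", "agree_one", "disagree", "no_homolog"], fill_value=0)
    )
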