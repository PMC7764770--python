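"""Censored-contaminant statistics: ROS imputation of non-detects,
wet/dry-weight basis corrections, PCB aggregates and TCDD toxic
equivalents, congener fingerprints, guideline exceedances, and the
rank-based group comparison and correlation contracts.

Concentrations below an analytical detection limit ("non-detects") are
left-censored at that limit. Before computing summary statistics they are
imputed by log-normal regression on order statistics (ROS): plotting
positions are computed with censoring-aware exceedance probabilities
(Hirsch–Stedinger recursion), the log of the detected values is regressed
on the corresponding normal quantiles, and the fitted line is evaluated at
the non-detects' plotting positions. With fewer than three detected values
the fit is not identifiable and the module falls back to limit/2
substitution with a prominent warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContaminantTable",
    "CongenerProfile",
    "PCBSummary",
    "WHO2005_TEF",
    "EU_PCB6",
    "DL_CONGENERS",
    "ros_impute",
    "convert_basis",
    "pcb_aggregates",
    "congener_fingerprint",
    "age_dichotomize",
    "group_compare",
    "rank_correlation_matrix",
    "guideline_exceedance",
]

#: WHO 2005 mammalian toxic equivalency factors for the 12 dioxin-like PCBs.
#: Editable defaults; supply your own mapping to override.
WHO2005_TEF: dict[int, float] = {
    77: 0.0001, 81: 0.0003, 105: 0.00003, 114: 0.00003, 118: 0.00003,
    123: 0.00003, 126: 0.1, 156: 0.00003, 157: 0.00003, 167: 0.00003,
    169: 0.03, 189: 0.00003,
}

#: EU indicator ("PCB6") congeners.
EU_PCB6: frozenset[int] = frozenset({28, 52, 101, 138, 153, 180})

#: Dioxin-like congener ids (keys of the TEF table).
DL_CONGENERS: frozenset[int] = frozenset(WHO2005_TEF)

#: Diagnostic congeners of the Aroclor 1254/1260 fingerprint.
DIAGNOSTIC_CONGENERS: frozenset[int] = frozenset({110, 153, 118, 138})


@dataclass
class ContaminantTable:
    """Per-fish covariates plus censored measurements and congener profiles.

    ``fish`` has one row per fish (fish_id, species, site_id,
    geographic_group, age, weight, length, pct_lipid, pct_moisture);
    ``measurements`` is long-format (fish_id, analyte, value, basis,
    detected, detection_limit); ``congeners`` likewise (fish_id, congener,
    value, detected, detection_limit). Non-detect rows carry the detection
    limit in ``value``.
    """

    fish: pd.DataFrame
    measurements: pd.DataFrame
    congeners: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.fish["fish_id"].duplicated().any():
            raise ValueError("duplicate fish_id in fish table")
        m = self.measurements
        if (m["value"] < 0).any():
            raise ValueError("negative concentrations")
        nd = m[~m["detected"].astype(bool)]
        if (nd["detection_limit"] <= 0).any():
            raise ValueError("non-detect rows must carry detection_limit > 0")

    def analyte(self, name: str) -> pd.DataFrame:
        """Measurement rows for one analyte, joined to fish covariates."""
        rows = self.measurements[self.measurements["analyte"] == name]
        return rows.merge(self.fish, on="fish_id", how="left")

    def congener_profile(self, fish_id: str) -> "CongenerProfile":
        if self.congeners is None:
            raise ValueError("table has no congener block")
        rows = self.congeners[self.congeners["fish_id"] == fish_id]
        return CongenerProfile(
            fish_id=fish_id,
            concentrations=dict(zip(rows["congener"].astype(int),
                                    rows["value"].astype(float))),
            detected=dict(zip(rows["congener"].astype(int),
                              rows["detected"].astype(bool))),
            limits=dict(zip(rows["congener"].astype(int),
                            rows["detection_limit"].astype(float))),
        )


@dataclass
class CongenerProfile:
    """One fish's PCB congener concentrations (ug/kg), keyed by IUPAC number."""

    fish_id: str
    concentrations: dict[int, float]
    detected: dict[int, bool] = field(default_factory=dict)
    limits: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.detected:
            self.detected = {c: True for c in self.concentrations}


@dataclass
class PCBSummary:
    """Per-fish PCB aggregates (concentrations in ug/kg unless noted)."""

    fish_id: str
    total_pcb: float
    t_pcb_lip: float | None     # ug/kg lipid weight; None if lipid unknown
    dl_pcb_teq: float           # ug TCDD-TEQ/kg
    non_dl_pcb: float
    pcb6: float


# ---------------------------------------------------------------------------
# ROS


def _hc_plotting_positions(values: np.ndarray, detected: np.ndarray,
                           limits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helsel–Cohn plotting positions for left-censored data.

    Returns (pp_detected_sorted_order, pp_censored) along with implicit
    ordering: detected positions are returned aligned to the *sorted*
    detected values; callers handle the mapping.
    """
    det_vals = values[detected]
    cen_lims = limits[~detected]
    thresholds = np.unique(cen_lims)
    # Interval j spans [T_j, T_{j+1}); T_0 = 0 sentinel below all data.
    tj = np.concatenate([[0.0], thresholds])
    k = len(tj)
    A = np.zeros(k)  # detects within [T_j, T_{j+1})
    B = np.zeros(k)  # observations (any kind) strictly below T_j
    upper = np.concatenate([tj[1:], [np.inf]])
    for j in range(k):
        A[j] = np.sum((det_vals >= tj[j]) & (det_vals < upper[j]))
        B[j] = np.sum(det_vals < tj[j]) + np.sum(cen_lims <= tj[j])

    # exceedance probability of each threshold, from the top down
    pe = np.zeros(k + 1)
    for j in range(k - 1, -1, -1):
        denom = A[j] + B[j]
        frac = A[j] / denom if denom > 0 else 0.0
        pe[j] = pe[j + 1] + frac * (1.0 - pe[j + 1])

    pp_det = np.empty(det_vals.size)
    order = np.argsort(det_vals, kind="stable")
    sorted_det = det_vals[order]
    for j in range(k):
        in_j = (sorted_det >= tj[j]) & (sorted_det < upper[j])
        idx = np.flatnonzero(in_j)
        aj = idx.size
        for r, i in enumerate(idx, start=1):
            pp_det[order[i]] = ((1 - pe[j])
                                + (pe[j] - pe[j + 1]) * r / (aj + 1))

    pp_cen = np.empty(cen_lims.size)
    for j, t in enumerate(thresholds, start=1):
        idx = np.flatnonzero(cen_lims == t)
        cj = idx.size
        for r, i in enumerate(idx, start=1):
            pp_cen[i] = (1 - pe[j]) * r / (cj + 1)
    return pp_det, pp_cen


def ros_impute(values, detected, limits=None, seed: int | None = None):
    """Log-normal regression on order statistics for left-censored data.

    Parameters
    ----------
    values : array-like
        Concentrations; non-detect entries hold their detection limit.
    detected : array-like of bool
        True where the value is a real measurement.
    limits : array-like, optional
        Detection limits; defaults to ``values`` at non-detect positions.
    seed : int, optional
        Accepted for interface uniformity; the procedure is deterministic.

    Returns
    -------
    imputed : ndarray
        Detected values unchanged; non-detects replaced by ROS predictions,
        clipped at their detection limit (with a warning if clipping fired).
    mu, sigma : float
        Log-scale location and scale of the fitted distribution. With no
        censoring these are the sample mean and SD (ddof=1) of the logs.
    """
    values = np.asarray(values, dtype=float)
    detected = np.asarray(detected, dtype=bool)
    if limits is None:
        limits = values.copy()
    limits = np.asarray(limits, dtype=float)
    if values.shape != detected.shape or values.shape != limits.shape:
        raise ValueError("values, detected and limits must align")
    if (values[detected] <= 0).any():
        raise ValueError("detected concentrations must be > 0")

    n_det = int(detected.sum())
    if n_det == detected.size:
        logs = np.log(values)
        sigma = float(np.std(logs, ddof=1)) if n_det > 1 else 0.0
        return values.copy(), float(np.mean(logs)), sigma

    det_vals = values[detected]
    if n_det < 3 or np.unique(det_vals).size < 2:
        warnings.warn(
            "fewer than 3 (distinct) detected values: falling back to "
            "limit/2 substitution; treat results with caution",
            stacklevel=2,
        )
        out = values.copy()
        out[~detected] = limits[~detected] / 2.0
        logs = np.log(out)
        return out, float(np.mean(logs)), float(np.std(logs, ddof=1))

    pp_det, pp_cen = _hc_plotting_positions(values, detected, limits)
    q_det = stats.norm.ppf(pp_det)
    slope, intercept, *_ = stats.linregress(q_det, np.log(det_vals))
    pred = np.exp(intercept + slope * stats.norm.ppf(pp_cen))
    lim_cen = limits[~detected]
    clipped = pred > lim_cen
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} ROS predictions exceeded their detection "
            "limit and were clipped", stacklevel=2,
        )
        pred = np.minimum(pred, lim_cen)
    out = values.copy()
    out[~detected] = pred
    return out, float(intercept), float(abs(slope))


# ---------------------------------------------------------------------------
# Basis conversion and PCB aggregates


def convert_basis(value: float, from_basis: str, to_basis: str,
                  moisture: float | None = None) -> float:
    """Convert a concentration between dry-weight and wet-weight bases.

    ww = dw * (1 - moisture); dw = ww / (1 - moisture). Same-basis
    conversion is the identity (moisture then unused).
    """
    for b in (from_basis, to_basis):
        if b not in ("dw", "ww"):
            raise ValueError(f"basis must be 'dw' or 'ww', got {b!r}")
    if from_basis == to_basis:
        return value
    if moisture is None:
        raise ValueError("moisture fraction required for dw<->ww conversion")
    if not (0.0 <= moisture < 1.0):
        raise ValueError("moisture must be in [0, 1); moisture = 1 makes "
                         "the dry-weight basis undefined")
    if from_basis == "dw":
        return value * (1.0 - moisture)
    return value / (1.0 - moisture)


def pcb_aggregates(p: CongenerProfile, pct_lipid: float | None,
                   tef: dict[int, float] | None = None,
                   pcb6_set: frozenset[int] = EU_PCB6) -> PCBSummary:
    """Total PCBs, lipid-normalised total, DL-PCB TEQ, non-DL sum and PCB6.

    TEQ weights each dioxin-like congener by its toxic equivalency factor
    relative to TCDD. A zero or missing lipid fraction leaves t_pcb_lip
    undefined (None).
    """
    tef = WHO2005_TEF if tef is None else tef
    if any(v <= 0 for v in tef.values()):
        raise ValueError("TEFs must be > 0")
    conc = p.concentrations
    total = float(sum(conc.values()))
    dl_sum = float(sum(v for c, v in conc.items() if c in tef))
    teq = float(sum(v * tef[c] for c, v in conc.items() if c in tef))
    pcb6 = float(sum(v for c, v in conc.items() if c in pcb6_set))
    t_lip = (total / pct_lipid) if pct_lipid else None
    return PCBSummary(
        fish_id=p.fish_id, total_pcb=total, t_pcb_lip=t_lip,
        dl_pcb_teq=teq, non_dl_pcb=total - dl_sum, pcb6=pcb6,
    )


def congener_fingerprint(p: CongenerProfile,
                         diagnostic: frozenset[int] = DIAGNOSTIC_CONGENERS,
                         k: int = 5) -> tuple[bool, list[int]]:
    """Top-k congeners by concentration and the legacy-mixture flag.

    The flag is True when at least three of the diagnostic congeners
    (default 110, 153, 118, 138 — the dominant peaks of Aroclor 1254/1260)
    sit among the k highest peaks. Ties break by ascending congener id.
    """
    items = list(p.concentrations.items())
    if len(items) < k:
        warnings.warn(
            f"profile has only {len(items)} congeners (< k={k}); flag "
            "computed over all of them"
        )
    items.sort(key=lambda cv: (-cv[1], cv[0]))
    top = [c for c, _ in items[:k]]
    flag = len(set(top) & diagnostic) >= 3
    return flag, top


# ---------------------------------------------------------------------------
# Group comparisons, correlations, exceedances


def age_dichotomize(ages, scope=None) -> np.ndarray:
    """Label each fish Y (younger than the scope mean) or O (at/above it).

    ``scope`` groups fish (e.g. by species) so each group is split at its
    own mean age; omitted, all fish share one mean. Missing ages yield a
    missing label (None).
    """
    ages = pd.Series(np.asarray(ages, dtype=float))
    if scope is None:
        scope = pd.Series(np.zeros(len(ages)))
    else:
        scope = pd.Series(np.asarray(scope, dtype=object))
    out = np.empty(len(ages), dtype=object)
    for _, idx in ages.groupby(scope).groups.items():
        grp = ages[idx]
        mean = grp.mean()
        for i in idx:
            a = ages[i]
            out[i] = None if np.isnan(a) else ("Y" if a < mean else "O")
    return out


@dataclass
class GroupCompareResult:
    statistic: float
    df: int
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, pvalue


def group_compare(values, groups) -> GroupCompareResult:
    """Kruskal–Wallis rank test with tie correction plus Dunn pairwise z.

    All-identical values return H = 0, p = 1 (no evidence of difference).
    Pairwise comparisons use Dunn's z on mean ranks with the tie-corrected
    variance; p-values are two-sided and unadjusted.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = ~np.isnan(values) & ~pd.isna(groups)
    values, groups = values[keep], groups[keep]
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs >= 1 value")
    df = len(labels) - 1

    if np.unique(values).size == 1:
        pairwise = pd.DataFrame(
            [(a, b, 0.0, 1.0) for a, b in combinations(labels, 2)],
            columns=["group1", "group2", "z", "pvalue"])
        return GroupCompareResult(0.0, df, 1.0, pairwise)

    h, p = stats.kruskal(*samples)

    # Dunn pairwise on pooled ranks
    n = values.size
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n_g = {g: int((groups == g).sum()) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / n_g[a] + 1.0 / n_g[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        rows.append((a, b, z, 2 * stats.norm.sf(abs(z))))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "z", "pvalue"])
    return GroupCompareResult(float(h), df, float(p), pairwise)


def rank_correlation_matrix(table: pd.DataFrame,
                            variables: list[str],
                            min_pairs: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p per variable pair, pairwise-complete.

    Returns (rho, p) DataFrames, symmetric with unit diagonal. Cells with
    fewer than ``min_pairs`` complete pairs, or a constant variable, are
    NaN.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, vi in enumerate(variables):
        for j in range(i + 1, k):
            vj = variables[j]
            sub = table[[vi, vj]].dropna()
            if (len(sub) < min_pairs or sub[vi].nunique() < 2
                    or sub[vj].nunique() < 2):
                r = p = np.nan
            else:
                r, p = stats.spearmanr(sub[vi], sub[vj])
            rho.loc[vi, vj] = rho.loc[vj, vi] = r
            pval.loc[vi, vj] = pval.loc[vj, vi] = p
    return rho, pval


@dataclass
class ExceedanceReport:
    n_exceeding: int
    n_total: int
    fraction: float
    flags: np.ndarray


def guideline_exceedance(values, threshold: float, value_basis: str,
                         threshold_basis: str,
                         moisture=None) -> ExceedanceReport:
    """Count values strictly above a guideline threshold.

    Values are converted to the threshold's basis before comparison (strict
    '>': a value exactly at the guideline does not exceed it). ``moisture``
    may be a scalar or per-value array; it is required whenever the bases
    differ.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    values = np.asarray(values, dtype=float)
    if value_basis != threshold_basis:
        if moisture is None:
            raise ValueError("moisture required to convert basis")
        moisture = np.broadcast_to(np.asarray(moisture, dtype=float),
                                   values.shape)
        values = np.array([
            convert_basis(v, value_basis, threshold_basis, m)
            for v, m in zip(values, moisture)
        ])
    flags = values > threshold
    n = int(flags.size)
    return ExceedanceReport(int(flags.sum()), n,
                            float(flags.sum()) / n if n else float("nan"),
                            flags)
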