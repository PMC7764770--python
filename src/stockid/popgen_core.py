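"""Allele frequencies, per-locus Weir–Cockerham F_ST, marker ranking, and
allele-frequency imputation of missing genotypes.

The F_ST estimator is the Weir & Cockerham (1984) per-locus theta computed
from genotype counts, with the among-group (a), among-individual-within-
group (b) and within-individual (c) variance components; theta = a/(a+b+c).
Per-locus values (rather than a ratio-of-averages across loci) are required
because markers are ranked individually when building assignment panels.
Negative estimates are retained as computed — ranking only needs order —
and loci where the components sum to zero (monomorphic within the groups
considered) are flagged undefined and excluded from ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

#: The published panel ladder: top-k marker counts at which assignment
#: accuracy is evaluated. The final rung is replaced by the total number of
#: defined loci at ranking time.
DEFAULT_LADDER: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128, 200, 500,
                                   1000, 2000, 3055)

__all__ = [
    "DEFAULT_LADDER",
    "FreqTable",
    "FstVector",
    "MarkerPanels",
    "group_allele_frequencies",
    "wc_fst_per_locus",
    "rank_markers",
    "impute_by_group_frequency",
]


@dataclass
class FreqTable:
    """Alt-allele sample frequencies per (group, locus).

    ``freq`` is NaN where ``count`` (called-allele count, i.e. 2 x called
    samples) is zero.
    """

    locus_ids: list[str]
    group_labels: list[str]
    freq: np.ndarray   # (n_groups, n_loci) float64, NaN where undefined
    count: np.ndarray  # (n_groups, n_loci) int64, called alleles

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        shape = (len(self.group_labels), len(self.locus_ids))
        if self.freq.shape != shape or self.count.shape != shape:
            raise ValueError("freq/count shape mismatch")

    def restrict(self, loci: list[str]) -> "FreqTable":
        """Column-subset to ``loci`` (in the given order)."""
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        idx = np.array([pos[l] for l in loci], dtype=int)
        return FreqTable(list(loci), list(self.group_labels),
                         self.freq[:, idx], self.count[:, idx])

    @property
    def smoothed_freq(self) -> np.ndarray:
        """(x + 0.5) / (n + 1) smoothing of the alt-allele frequency.

        Keeps probabilities strictly inside (0, 1) so that a holdout
        individual carrying an allele unseen in training never scores
        -inf. Undefined cells (count 0) smooth to 0.5.
        """
        x = np.where(np.isnan(self.freq), 0.0, self.freq) * self.count
        return (x + 0.5) / (self.count + 1.0)


@dataclass
class FstVector:
    """Per-locus Weir–Cockerham variance components and theta."""

    locus_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray     # NaN where undefined
    defined: np.ndarray   # bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.locus_ids, "a": self.a, "b": self.b,
            "c": self.c, "theta": self.theta, "defined": self.defined,
        })


@dataclass
class MarkerPanels:
    """Loci ranked by descending training theta, sliced at a panel ladder.

    Panels are nested prefixes of the ranking, so panel k is always a
    subset of panel k' for k < k'.
    """

    ranked_locus_ids: list[str]
    ladder: list[int]
    theta: np.ndarray = field(default=None)  # aligned to ranked_locus_ids

    def panel(self, size: int) -> list[str]:
        if size not in self.ladder:
            raise ValueError(f"panel size {size} not in ladder {self.ladder}")
        return self.ranked_locus_ids[:size]

    @property
    def panels(self) -> dict[int, list[str]]:
        return {k: self.ranked_locus_ids[:k] for k in self.ladder}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.ranked_locus_ids,
            "theta": (self.theta if self.theta is not None
                      else np.full(len(self.ranked_locus_ids), np.nan)),
            "rank": np.arange(1, len(self.ranked_locus_ids) + 1),
        })


def _group_indices(g: GenotypeMatrix, labels: SampleTable,
                   by: str) -> tuple[list[str], list[np.ndarray]]:
    lab = labels.labels_for(g.sample_ids, by=by)
    if pd.isna(lab).any():
        bad = [s for s, v in zip(g.sample_ids, lab) if pd.isna(v)]
        raise ValueError(
            f"{len(bad)} samples lack a {by} label (e.g. {bad[:5]})"
        )
    groups = sorted(set(lab))
    idx = [np.flatnonzero(lab == grp) for grp in groups]
    keep_groups, keep_idx = [], []
    for grp, ix in zip(groups, idx):
        if ix.size == 0:
            warnings.warn(f"group {grp!r} has no samples; omitted")
            continue
        keep_groups.append(grp)
        keep_idx.append(ix)
    return keep_groups, keep_idx


def group_allele_frequencies(g: GenotypeMatrix, labels: SampleTable,
                             by: str = "cluster") -> FreqTable:
    """Alt-allele frequency and called-allele count per group per locus.

    Missing calls are excluded from both numerator and denominator:
    freq = sum(dosages among called) / (2 * called samples).
    """
    groups, idx = _group_indices(g, labels, by)
    n_loci = g.n_loci
    freq = np.full((len(groups), n_loci), np.nan)
    count = np.zeros((len(groups), n_loci), dtype=np.int64)
    for gi, ix in enumerate(idx):
        sub = g.calls[ix, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        count[gi] = 2 * n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[gi] = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return FreqTable(list(g.locus_ids), groups, freq, count)


def wc_fst_per_locus(g: GenotypeMatrix, labels: SampleTable,
                     by: str = "cluster") -> FstVector:
    """Per-locus Weir & Cockerham (1984) theta from genotype counts.

    Uses the full genotypic estimator with observed heterozygosity; groups
    with zero called samples at a locus are dropped for that locus, and a
    locus needs >= 2 contributing groups to be defined.
    """
    groups, idx = _group_indices(g, labels, by)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")

    n_loci = g.n_loci
    r_total = len(groups)
    # per-group per-locus: n_i (called samples), p_i, h_i (obs het prop)
    n = np.zeros((r_total, n_loci))
    p = np.zeros((r_total, n_loci))
    h = np.zeros((r_total, n_loci))
    for gi, ix in enumerate(idx):
        sub = g.calls[ix, :]
        called = sub != MISSING
        n[gi] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[gi] = np.where(called, sub, 0).sum(axis=0) / (2.0 * n[gi])
            h[gi] = np.where(called, sub == 1, False).sum(axis=0) / n[gi]

    contributes = n > 0
    r = contributes.sum(axis=0).astype(float)          # groups per locus
    ok = r >= 2
    n = np.where(contributes, n, 0.0)
    p = np.where(contributes, p, 0.0)
    h = np.where(contributes, h, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n.sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - (n ** 2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    defined = ok & np.isfinite(theta)
    theta = np.where(defined, theta, np.nan)
    for arr in (a, b, c):
        arr[~ok] = np.nan
    return FstVector(list(g.locus_ids), a, b, c, theta, defined)


def rank_markers(f: FstVector, ladder: list[int] | None = None) -> MarkerPanels:
    """Sort loci by descending theta and slice nested panels at the ladder.

    Undefined loci are excluded; ties break by ascending input locus index
    (stable sort). Ladder entries exceeding the defined-locus count are
    clamped to it and deduplicated; the default ladder's final rung is
    always the total defined-locus count.
    """
    if len(f.locus_ids) == 0:
        raise ValueError("empty FstVector")
    defined_idx = np.flatnonzero(f.defined)
    if defined_idx.size == 0:
        raise ValueError("no defined loci to rank")
    order = defined_idx[np.argsort(-f.theta[defined_idx], kind="stable")]
    ranked = [f.locus_ids[i] for i in order]
    n_def = len(ranked)

    if ladder is None:
        ladder = list(DEFAULT_LADDER[:-1]) + [n_def]
    if any(k <= 0 for k in ladder):
        raise ValueError("ladder entries must be positive")
    clamped: list[int] = []
    for k in sorted(ladder):
        k = min(int(k), n_def)
        if k not in clamped:
            clamped.append(k)
    return MarkerPanels(ranked, clamped, theta=f.theta[order])


def impute_by_group_frequency(g: GenotypeMatrix, labels: SampleTable,
                              seed: int, by: str = "cluster") -> GenotypeMatrix:
    """Replace missing calls with binomial(2, p_hat) draws.

    p_hat is the sample's own group alt-allele frequency at that locus;
    where the group frequency is undefined the overall frequency is used.
    Observed calls are never altered. A locus undefined everywhere is left
    missing with a warning. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    freqs = group_allele_frequencies(g, labels, by=by)
    lab = labels.labels_for(g.sample_ids, by=by)
    group_pos = {grp: i for i, grp in enumerate(freqs.group_labels)}

    calls = g.calls.copy()
    called = calls != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        overall = np.where(
            n_called > 0,
            np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called),
            np.nan,
        )

    never_defined = 0
    miss_s, miss_l = np.nonzero(~called)
    # per-cell p_hat: group freq, falling back to overall
    p_hat = freqs.freq[[group_pos[lab[i]] for i in miss_s], miss_l]
    p_hat = np.where(np.isnan(p_hat), overall[miss_l], p_hat)
    drawable = ~np.isnan(p_hat)
    never_defined = int((~drawable).sum())
    draws = rng.binomial(2, p_hat[drawable]).astype(np.int8)
    calls[miss_s[drawable], miss_l[drawable]] = draws
    if never_defined:
        warnings.warn(
            f"{never_defined} missing calls had no defined frequency in any "
            "group or overall; left missing"
        )
    return GenotypeMatrix(list(g.sample_ids), list(g.locus_ids), calls)
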