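"""Likelihood-based population assignment and the replicated
training/holdout cross-validation protocol over F_ST-ranked marker panels.

Assignment uses the standard genetic-stock-identification likelihood:
independent loci in Hardy–Weinberg proportions within each candidate
group, so for smoothed group frequency q the genotype probabilities are
P(0) = (1-q)^2, P(1) = 2q(1-q), P(2) = q^2, and a sample's log-likelihood
for a group is the sum over its called panel loci. Frequencies are
smoothed as q = (x + 0.5)/(n + 1) (x alt-allele count, n called alleles in
training) so an allele unseen in training never produces -inf. Posteriors
are the softmax of the log-likelihoods under equal priors.

The cross-validation protocol, per replicate: (1, population mode only)
subsample every group to the smallest group size; then per iteration
(2) split each group 50/50 into training and holdout (odd counts give the
extra sample to training), (3) rank markers by per-locus F_ST computed on
the training half only, (4) assign the holdout samples at every rung of
the panel ladder, (5) repeat for the configured number of iterations, and
(6) repeat the whole block over replicates with fresh subsamples; (7)
accuracies are aggregated per panel per group. Site-level runs skip the
equalisation and use a single replicate. Training and holdout are disjoint
by construction and holdout data never enter the ranking or the frequency
estimates of their own iteration.

Randomness derives from one master seed: the stream for replicate r's
subsampling is seeded with the entropy tuple (seed, r, 0) and iteration
i of replicate r with (seed, r, i + 1), so any single iteration can be
re-run in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable
from .popgen_core import (DEFAULT_LADDER, FreqTable,
                          group_allele_frequencies,
                          impute_by_group_frequency, rank_markers,
                          wc_fst_per_locus)

__all__ = [
    "AssignmentResult",
    "CVConfig",
    "CVSummary",
    "assignment_loglik",
    "assign_holdout",
    "run_cv",
    "summarize_assignment_matrix",
    "accuracy_by_panel",
]


@dataclass
class AssignmentResult:
    """One holdout sample's assignment outcome over a fixed panel."""

    sample_id: str
    log_likelihoods: dict[str, float]
    posteriors: dict[str, float]
    assigned_group: str
    true_group: str | None = None
    n_loci_used: int = 0
    unassignable: bool = False
    ambiguous: bool = False


@dataclass
class CVConfig:
    """Cross-validation protocol parameters.

    ``equalize`` and ``n_replicates`` default by mode: population mode
    equalises group sizes and uses 3 replicates; site mode keeps observed
    sizes and is forced to a single replicate.
    """

    mode: str = "population"  # or "site"
    ladder: list[int] | None = None
    n_iterations: int = 30
    n_replicates: int = 3
    equalize: bool | None = None
    train_fraction: float = 0.5
    impute: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("population", "site"):
            raise ValueError("mode must be 'population' or 'site'")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.mode == "site":
            self.n_replicates = 1
            if self.equalize is None:
                self.equalize = False
        elif self.equalize is None:
            self.equalize = True

    @property
    def grouping(self) -> str:
        return "cluster" if self.mode == "population" else "site"


@dataclass
class CVSummary:
    """Per-(replicate, iteration, panel, group) accuracy and confusion.

    ``records`` columns: replicate, iteration, panel_size, group,
    n_correct, n_total. ``confusion`` columns: replicate, iteration,
    panel_size, true_group, assigned_group, n.
    """

    mode: str
    group_labels: list[str]
    ladder: list[int]
    records: pd.DataFrame
    confusion: pd.DataFrame
    seed: int = 0

    def to_tsv(self, records_path, confusion_path=None) -> None:
        self.records.to_csv(records_path, sep="\t", index=False)
        if confusion_path is not None:
            self.confusion.to_csv(confusion_path, sep="\t", index=False)

    def records_bytes(self) -> bytes:
        """Canonical serialisation, for determinism checks."""
        return self.records.to_csv(sep="\t", index=False).encode()


# ---------------------------------------------------------------------------
# Likelihood core


def _log_genotype_probs(q: np.ndarray) -> np.ndarray:
    """(3, n_groups, n_loci) log genotype probabilities under HWE."""
    with np.errstate(divide="ignore"):
        return np.stack([
            2.0 * np.log1p(-q),
            np.log(2.0) + np.log(q) + np.log1p(-q),
            2.0 * np.log(q),
        ])


def _panel_logliks(calls: np.ndarray, q: np.ndarray,
                   cut_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative log-likelihoods at nested panel cuts.

    ``calls``: (n_samples, n_loci) dosages over loci already in rank order;
    ``q``: (n_groups, n_loci) smoothed training frequencies in the same
    order; ``cut_sizes``: increasing panel sizes. Returns
    (loglik[(n_samples, n_cuts, n_groups)], n_used[(n_samples, n_cuts)]).
    """
    n_samples, n_loci = calls.shape
    n_groups = q.shape[0]
    called = calls != MISSING
    d = np.where(called, calls, 0)
    lp = _log_genotype_probs(q)  # (3, n_groups, n_loci)
    cuts = np.asarray(cut_sizes, dtype=int) - 1
    loglik = np.empty((n_samples, len(cuts), n_groups))
    cols = np.arange(n_loci)
    for gi in range(n_groups):
        contrib = np.where(called, lp[d, gi, cols], 0.0)
        loglik[:, :, gi] = np.cumsum(contrib, axis=1)[:, cuts]
    n_used = np.cumsum(called, axis=1)[:, cuts]
    return loglik, n_used


def _posteriors(loglik: np.ndarray) -> np.ndarray:
    """Softmax over the last axis (equal priors)."""
    shifted = loglik - loglik.max(axis=-1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=-1, keepdims=True)


def assignment_loglik(dosages: np.ndarray, freqs: FreqTable,
                      sample_id: str = "sample",
                      true_group: str | None = None) -> AssignmentResult:
    """Assign one sample from its dosages over a panel.

    ``dosages`` align with ``freqs.locus_ids`` (the panel); missing calls
    (MISSING) are skipped. Ties go to the first group in label order with
    the ambiguity flag set; a sample with zero called panel loci is
    flagged unassignable with equal posteriors.
    """
    dosages = np.asarray(dosages, dtype=np.int8).reshape(1, -1)
    if dosages.shape[1] != len(freqs.locus_ids):
        raise ValueError("dosage vector does not match panel size")
    q = freqs.smoothed_freq
    loglik, n_used = _panel_logliks(dosages, q, np.array([dosages.shape[1]]))
    ll = loglik[0, 0]
    post = _posteriors(ll[None, :])[0]
    best = int(np.argmax(ll))
    ambiguous = bool(np.sum(ll == ll[best]) > 1)
    return AssignmentResult(
        sample_id=sample_id,
        log_likelihoods=dict(zip(freqs.group_labels, ll.tolist())),
        posteriors=dict(zip(freqs.group_labels, post.tolist())),
        assigned_group=freqs.group_labels[best],
        true_group=true_group,
        n_loci_used=int(n_used[0, 0]),
        unassignable=bool(n_used[0, 0] == 0),
        ambiguous=ambiguous,
    )


def assign_holdout(g_holdout: GenotypeMatrix, freqs_training: FreqTable,
                   panel: list[str],
                   true_groups: np.ndarray | None = None) -> list[AssignmentResult]:
    """Assign every holdout sample over ``panel`` using training frequencies.

    Only training-derived frequencies enter the likelihood; holdout data
    contribute nothing beyond their own genotypes.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    pos = {l: j for j, l in enumerate(g_holdout.locus_ids)}
    try:
        idx = np.array([pos[l] for l in panel], dtype=int)
    except KeyError as exc:
        raise ValueError(f"panel locus missing from holdout matrix: {exc}")
    freqs = freqs_training.restrict(list(panel))
    calls = g_holdout.calls[:, idx]
    results = []
    for i, sid in enumerate(g_holdout.sample_ids):
        tg = None if true_groups is None else true_groups[i]
        results.append(assignment_loglik(calls[i], freqs, sample_id=sid,
                                         true_group=tg))
    return results


# ---------------------------------------------------------------------------
# Cross-validation protocol


def _iteration_rng(seed: int, replicate: int, iteration: int) -> np.random.Generator:
    """Documented stream-splitting: entropy tuple (seed, replicate, iter+1)."""
    return np.random.default_rng(
        np.random.SeedSequence((seed, replicate, iteration + 1)))


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, replicate, 0)))


@dataclass
class _IterationOutput:
    """Internals of one training/holdout iteration (testing hook)."""

    train_idx: np.ndarray
    hold_idx: np.ndarray
    hold_true: np.ndarray
    ranked_locus_ids: list[str]
    training_freqs: FreqTable
    cuts: np.ndarray          # actual panel cut sizes, aligned to ladder
    loglik: np.ndarray        # (n_hold, n_cuts, n_groups)
    n_used: np.ndarray        # (n_hold, n_cuts)
    assigned: np.ndarray      # group indices, (n_hold, n_cuts)


def _run_iteration(g: GenotypeMatrix, labels: SampleTable, by: str,
                   groups: list[str], rep_members: dict[str, np.ndarray],
                   ladder_req: list[int], seed: int, rep: int,
                   it: int, train_fraction: float = 0.5) -> _IterationOutput:
    """Split, rank on training only, and score holdout at every rung.

    Training-derived quantities (marker ranking, allele frequencies) are
    computed exclusively on the training rows; holdout genotypes enter
    only through their own likelihood terms.
    """
    it_rng = _iteration_rng(seed, rep, it)
    train_parts, hold_parts, hold_labels = [], [], []
    for grp in groups:
        members = rep_members[grp]
        perm = it_rng.permutation(members)
        n_train = int(np.ceil(train_fraction * members.size))
        train_parts.append(perm[:n_train])
        hold_parts.append(perm[n_train:])
        hold_labels.extend([grp] * (members.size - n_train))
    train_idx = np.concatenate(train_parts)
    hold_idx = np.concatenate(hold_parts)
    hold_true = np.array(hold_labels, dtype=object)

    g_train = g.subset_samples(train_idx)
    fst = wc_fst_per_locus(g_train, labels, by=by)
    panels = rank_markers(fst, ladder_req)
    freqs = group_allele_frequencies(g_train, labels, by=by)

    locus_pos = {l: j for j, l in enumerate(g.locus_ids)}
    rank_cols = np.array([locus_pos[l] for l in panels.ranked_locus_ids])
    q = freqs.smoothed_freq[:, rank_cols]
    hold_calls = g.calls[hold_idx][:, rank_cols]

    n_ranked = len(panels.ranked_locus_ids)
    cuts = np.array([min(k, n_ranked) for k in ladder_req])
    loglik, n_used = _panel_logliks(hold_calls, q, cuts)
    assigned = np.argmax(loglik, axis=2)  # ties -> first label in order
    return _IterationOutput(train_idx, hold_idx, hold_true,
                            panels.ranked_locus_ids, freqs, cuts,
                            loglik, n_used, assigned)


def run_cv(g: GenotypeMatrix, labels: SampleTable,
           cfg: CVConfig) -> CVSummary:
    """Run the full replicated cross-validation over the panel ladder.

    Returns a CVSummary with one accuracy record per (replicate,
    iteration, panel size, true group) and the matching confusion counts.
    Unassignable holdout samples (no called panel loci) are excluded from
    both numerator and denominator. Deterministic given ``cfg.seed``.
    """
    by = cfg.grouping
    lab = labels.labels_for(g.sample_ids, by=by)
    if pd.isna(lab).any():
        raise ValueError(f"every sample needs a {by} label in {cfg.mode} mode")

    if cfg.impute:
        impute_seed = int(np.random.SeedSequence((cfg.seed, 0, 0))
                          .generate_state(1)[0])
        g = impute_by_group_frequency(g, labels, seed=impute_seed, by=by)

    groups = sorted(set(lab))
    group_idx = {grp: np.flatnonzero(lab == grp) for grp in groups}
    small = [grp for grp, ix in group_idx.items() if ix.size < 2]
    if small:
        if cfg.mode == "population":
            raise ValueError(f"groups with < 2 samples: {small}")
        warnings.warn(f"site mode: excluding groups with < 2 samples: {small}")
        for grp in small:
            del group_idx[grp]
        groups = [grp for grp in groups if grp not in small]
    if len(groups) < 2:
        raise ValueError("need >= 2 usable groups")

    ladder_req = (list(cfg.ladder) if cfg.ladder is not None
                  else list(DEFAULT_LADDER[:-1]) + [g.n_loci])
    ladder_req = sorted({int(k) for k in ladder_req if 0 < k <= g.n_loci}
                        | {min(max(ladder_req), g.n_loci)})

    rec_rows: list[tuple] = []
    conf_rows: list[tuple] = []
    ladder_seen: list[int] = []

    for rep in range(cfg.n_replicates):
        rep_rng = _replicate_rng(cfg.seed, rep)
        if cfg.equalize:
            n_min = min(ix.size for ix in group_idx.values())
            rep_members = {
                grp: np.sort(rep_rng.choice(ix, size=n_min, replace=False))
                for grp, ix in group_idx.items()
            }
        else:
            rep_members = {grp: ix.copy() for grp, ix in group_idx.items()}

        for it in range(cfg.n_iterations):
            res = _run_iteration(g, labels, by, groups, rep_members,
                                 ladder_req, cfg.seed, rep, it,
                                 cfg.train_fraction)
            ladder_seen = ladder_req
            hold_true = res.hold_true
            assignable = res.n_used > 0

            for ci, k in enumerate(ladder_req):
                ok = assignable[:, ci]
                pred = np.array([groups[a] for a in res.assigned[:, ci]],
                                dtype=object)
                for grp in groups:
                    in_grp = (hold_true == grp) & ok
                    n_total = int(in_grp.sum())
                    n_correct = int((pred[in_grp] == grp).sum())
                    rec_rows.append((rep, it, k, grp, n_correct, n_total))
                for tg in groups:
                    for ag in groups:
                        n = int(((hold_true == tg) & ok & (pred == ag)).sum())
                        if n:
                            conf_rows.append((rep, it, k, tg, ag, n))

    records = pd.DataFrame(
        rec_rows, columns=["replicate", "iteration", "panel_size", "group",
                           "n_correct", "n_total"])
    confusion = pd.DataFrame(
        conf_rows, columns=["replicate", "iteration", "panel_size",
                            "true_group", "assigned_group", "n"])
    return CVSummary(mode=cfg.mode, group_labels=groups,
                     ladder=list(ladder_seen), records=records,
                     confusion=confusion, seed=cfg.seed)


def summarize_assignment_matrix(results: CVSummary,
                                panel_size: int) -> pd.DataFrame:
    """Pooled (true group x assigned group) counts at one panel size."""
    if panel_size not in results.ladder:
        raise ValueError(
            f"panel size {panel_size} was not run (ladder: {results.ladder})")
    sub = results.confusion[results.confusion["panel_size"] == panel_size]
    mat = (sub.pivot_table(index="true_group", columns="assigned_group",
                           values="n", aggfunc="sum", fill_value=0)
           .reindex(index=results.group_labels,
                    columns=results.group_labels, fill_value=0))
    return mat


def accuracy_by_panel(results: CVSummary) -> pd.DataFrame:
    """Mean and SD of accuracy per panel size per group plus overall.

    The mean is over (replicate, iteration) pairs; each pair's overall
    accuracy pools correct counts over groups. A single iteration reports
    SD 0. Ordered by the ladder.
    """
    if results.records.empty:
        raise ValueError("empty CVSummary")
    rec = results.records.copy()
    per_group = (rec.assign(acc=lambda d: d.n_correct / d.n_total.where(
                     d.n_total > 0))
                 .groupby(["panel_size", "group"])["acc"]
                 .agg(["mean", "std", "count"]).reset_index())
    overall = (rec.groupby(["panel_size", "replicate", "iteration"])
               [["n_correct", "n_total"]].sum().reset_index()
               .assign(acc=lambda d: d.n_correct / d.n_total)
               .groupby("panel_size")["acc"]
               .agg(["mean", "std", "count"]).reset_index()
               .assign(group="overall"))
    out = pd.concat([per_group, overall], ignore_index=True)
    out["std"] = out["std"].fillna(0.0)
    out["panel_order"] = out["panel_size"].map(
        {k: i for i, k in enumerate(results.ladder)})
    out = (out.sort_values(["panel_order", "group"])
           .drop(columns="panel_order").reset_index(drop=True))
    return out.rename(columns={"mean": "accuracy_mean", "std": "accuracy_sd",
                               "count": "n_runs"})
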