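"""Age-adaptive binary classification from shape.

Each case is scored by its projection onto the axis joining the two groups'
expected heads *at that case's age*, normalized by half the distance between
them: a score of −1 sits at the negative group's expected head, +1 at the
positive group's, 0 midway (an "androgynous" head in the sex-difference
setting).  Geometrically this is the signed distance from a discriminating
plane orthogonal to the inter-mean axis, whose position and orientation adapt
to age.

Performance is assessed by repeated stratified k-fold cross-validation:
expected heads are refitted on the training folds for every held-out case,
and fold-level AUC and threshold-zero correct-classification rates are
aggregated within age brackets.

Group-to-anchor convention: the two labels are sorted; the first maps to −1
and the second to +1 (so with labels ``F``/``M``, girls anchor at −1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import Cohort
from .trajectory import KernelSpec, TrajectoryModel, expected_at, fit_trajectory

__all__ = [
    "DEFAULT_BRACKETS",
    "CVReport",
    "dimorphism_score",
    "stratified_folds",
    "repeated_cv",
    "auc",
    "classification_rates",
    "bracket_report",
]

#: Reporting age brackets (years): [0, 5), [5, 10), [10, 15), [15, 20).
DEFAULT_BRACKETS = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0))


def dimorphism_score(x, m_neg, m_pos) -> float:
    """Projection score of ``x`` on the axis from ``m_neg`` to ``m_pos``.

    ``score = <x - (m_neg + m_pos)/2, u> / (||m_pos - m_neg|| / 2)`` with
    ``u`` the unit vector from the negative to the positive expected head.
    Scores of −1/+1 coincide with the expected heads, 0 with their midpoint;
    values beyond ±1 are more extreme than either group average.
    """
    x = np.asarray(x, dtype=float).ravel()
    m_neg = np.asarray(m_neg, dtype=float).ravel()
    m_pos = np.asarray(m_pos, dtype=float).ravel()
    delta = m_pos - m_neg
    norm = np.linalg.norm(delta)
    if norm < 1e-300:
        raise ValueError("expected heads coincide; score direction undefined")
    u = delta / norm
    return float((x - 0.5 * (m_neg + m_pos)) @ u / (0.5 * norm))


def stratified_folds(cohort: Cohort, k: int, seed: int = 0) -> np.ndarray:
    """Fold assignment stratified by group and integer-year age bin.

    Within every (group, floor(age)) stratum the members are shuffled and
    dealt round-robin, so per-stratum fold counts differ by at most one and
    each fold mirrors the sample's age-by-group composition.  Strata smaller
    than ``k`` are distributed with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    strata = pd.MultiIndex.from_arrays(
        [cohort.groups, np.floor(cohort.ages).astype(int)]
    )
    folds = np.empty(cohort.n_cases, dtype=int)
    offset = 0
    small = 0
    for key in strata.unique().sortlevel()[0]:
        members = np.flatnonzero(strata == key)
        if members.size < k:
            small += 1
        members = rng.permutation(members)
        folds[members] = (offset + np.arange(members.size)) % k
        offset += members.size
    if small:
        warnings.warn(
            f"{small} strata have fewer than {k} cases; they cannot appear in "
            "every fold",
            RuntimeWarning,
        )
    return folds


def repeated_cv(
    cohort: Cohort,
    k: int = 10,
    repetitions: int = 100,
    spec: KernelSpec | None = None,
    seed: int = 0,
    support_threshold: float = 0.4,
) -> pd.DataFrame:
    """Repeated stratified k-fold cross-validation of the age-adaptive score.

    For every repetition × fold, the two groups' expected heads are refitted
    on the other k−1 folds and each held-out case scored at its own age.
    Cases whose age falls outside a training evaluation range are scored at
    the nearest in-range age and flagged (``clipped=True``).

    Returns a tidy frame with one row per (repetition, fold, case):
    columns ``id, age, true_group, score, repetition, fold, clipped``.
    """
    if spec is None:
        spec = KernelSpec(width=2.75)
    neg_label, pos_label = cohort.labels
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=repetitions)
    rows = []
    for rep in range(repetitions):
        folds = stratified_folds(cohort, k, int(rep_seeds[rep]))
        for f in range(k):
            test_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            train = cohort.subset(train_idx)
            for lab in (neg_label, pos_label):
                if not np.any(train.groups == lab):
                    raise ValueError(
                        f"training folds for repetition {rep}, fold {f} contain "
                        f"no cases of group {lab!r}"
                    )
            m_neg = fit_trajectory(train, neg_label, "shape", spec.width, support_threshold)
            m_pos = fit_trajectory(train, pos_label, "shape", spec.width, support_threshold)
            for i in test_idx:
                a = float(cohort.ages[i])
                a_neg = m_neg.eval_range.clip(a)
                a_pos = m_pos.eval_range.clip(a)
                clipped = (a_neg != a) or (a_pos != a)
                e_neg = expected_at(m_neg, a_neg, warn_outside=False)
                e_pos = expected_at(m_pos, a_pos, warn_outside=False)
                score = dimorphism_score(cohort.coords[i], e_neg, e_pos)
                rows.append(
                    (cohort.ids[i], a, cohort.groups[i], score, rep, f, clipped)
                )
    return pd.DataFrame(
        rows, columns=["id", "age", "true_group", "score", "repetition", "fold", "clipped"]
    )


def auc(scores, labels, pos_label=None) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute 1/2.

    ``pos_label`` defaults to the larger of the two labels (the +1 anchor).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("AUC needs both classes present")
    if pos_label is None:
        pos_label = sorted(present.tolist())[-1]
    return float(roc_auc_score(labels == pos_label, scores))


def classification_rates(scores, labels, threshold: float = 0.0,
                         pos_label=None, neg_label=None) -> tuple[float, float]:
    """Percent correct per group at a score threshold (default zero).

    Positive cases are correct when ``score > threshold``, negative cases
    when ``score < threshold``; a score exactly at the threshold counts as
    incorrect for either group.  Returns ``(positive %, negative %)``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = sorted(np.unique(labels).tolist())
    if neg_label is None:
        neg_label = present[0]
    if pos_label is None:
        pos_label = present[-1]
    pos = labels == pos_label
    neg = labels == neg_label
    pos_rate = 100.0 * (scores[pos] > threshold).mean() if pos.any() else np.nan
    neg_rate = 100.0 * (scores[neg] < threshold).mean() if neg.any() else np.nan
    return float(pos_rate), float(neg_rate)


@dataclass
class CVReport:
    """Bracketed cross-validation performance summary."""

    brackets: tuple
    metrics: pd.DataFrame     # one row per bracket: mean AUC / rates with CIs
    fold_values: pd.DataFrame  # one row per (repetition, fold, bracket)
    case_scores: pd.DataFrame  # per-case mean score over repetitions


def bracket_report(records: pd.DataFrame, brackets=DEFAULT_BRACKETS,
                   threshold: float = 0.0) -> CVReport:
    """Aggregate fold-level metrics within age brackets.

    For every repetition × fold, AUC and per-group correct-classification
    rates are computed over the held-out cases falling in each bracket
    ``[lo, hi)``; bracket summaries are the mean and 2.5/97.5 percentiles of
    those fold values.  Brackets with no cases (or folds with one class,
    for AUC) are reported as missing.  Also returns each case's mean score
    over repetitions, for score-distribution histograms.
    """
    neg_label, pos_label = sorted(records["true_group"].unique().tolist())
    fold_rows = []
    for (rep, fold), part in records.groupby(["repetition", "fold"]):
        for lo, hi in brackets:
            sel = part[(part["age"] >= lo) & (part["age"] < hi)]
            if sel.empty:
                continue
            s = sel["score"].to_numpy()
            lab = sel["true_group"].to_numpy()
            try:
                a = auc(s, lab, pos_label)
            except ValueError:
                a = np.nan
            pr, nr = classification_rates(s, lab, threshold, pos_label, neg_label)
            fold_rows.append((rep, fold, f"{lo:g}-{hi:g}", a, pr, nr))
    fold_values = pd.DataFrame(
        fold_rows,
        columns=["repetition", "fold", "bracket", "auc", "pos_correct", "neg_correct"],
    )
    rows = []
    for lo, hi in brackets:
        name = f"{lo:g}-{hi:g}"
        part = fold_values[fold_values["bracket"] == name]
        row = {"bracket": name, "n_folds": len(part)}
        for col in ("auc", "pos_correct", "neg_correct"):
            vals = part[col].dropna().to_numpy()
            if vals.size:
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_lo"] = float(np.percentile(vals, 2.5))
                row[f"{col}_hi"] = float(np.percentile(vals, 97.5))
            else:
                row[f"{col}_mean"] = row[f"{col}_lo"] = row[f"{col}_hi"] = np.nan
        rows.append(row)
    metrics = pd.DataFrame(rows)
    case_scores = (
        records.groupby(["id", "age", "true_group"], as_index=False)["score"]
        .mean()
        .rename(columns={"score": "mean_score"})
    )
    return CVReport(brackets=tuple(brackets), metrics=metrics,
                    fold_values=fold_values, case_scores=case_scores)
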