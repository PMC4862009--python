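"""Label <-> chemistry linkage statistics.

The evaluation protocol: a randomized-tree ensemble is trained on a
random two-thirds subsample of the instances and scored on the held-out
third, repeated 15 times.  Backward prediction is scored by the area
under the ROC curve (Mann-Whitney form, ties counted one half), forward
prediction by Pearson's r between held-out predictions and observations.
The contribution of a single mass is assessed by leave-one-mass-out:
the same splits and model seeds are re-run with all of that mass's lag
columns removed, and the paired per-repeat AUC differences are tested
with the corrected resampled paired t-test, whose variance term
``(1/k + n_test/n_train)`` accounts for the overlap between training
sets across repeats.  A final report filters (label, mass) rows to
AUC > 0.5 and p < 0.05; no multiple-testing correction is applied, the
rows being screening indications rather than confirmatory tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .windows import WindowedInstances

__all__ = [
    "EvaluationPlan",
    "MassAblation",
    "LinkageResult",
    "ForwardResult",
    "CoherenceResult",
    "auc",
    "pearson_r",
    "repeated_eval_backward",
    "repeated_eval_forward",
    "corrected_paired_ttest",
    "leave_one_mass_out",
    "coherence_check",
    "build_linkage_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def auc(scores, truths) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outranks the negative, ties counted one half.  Requires both classes
    present.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    if scores.shape != truths.shape:
        raise ValueError("scores and truths must have equal length")
    pos = truths == 1
    n_pos = int(pos.sum())
    n_neg = len(truths) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def pearson_r(predicted, observed) -> float:
    """Product-moment correlation; errors on constant input."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    return float(stats.pearsonr(predicted, observed).statistic)


def corrected_paired_ttest(diffs, n_train: int, n_test: int,
                           ) -> tuple[float, float]:
    """Corrected resampled paired t-test over k repeated random splits.

    t = mean(d) / sqrt(var(d) * (1/k + n_test/n_train)), df = k - 1,
    two-sided p.  The extra n_test/n_train term inflates the variance to
    compensate for the dependence between repeats induced by overlapping
    training sets.  Degenerate zero-variance cases: p = 1 when the mean
    is also zero, p = 0 otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    k = len(d)
    if k < 2:
        raise ValueError("corrected paired t-test needs k >= 2 repeats")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("split sizes must be positive")
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (np.inf * np.sign(mean), 0.0)
    t = mean / np.sqrt(var * (1.0 / k + n_test / n_train))
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return float(t), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# evaluation plan and repeated subsampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationPlan:
    """Repeated random-subsampling protocol.

    Defaults follow the study protocol: 15 repeats, train on two thirds,
    evaluate on the remaining third, a 100-tree randomized forest scored
    by class probabilities.  ``split_unit`` chooses whether the random
    subsample is drawn over instances (literal protocol) or whole
    screenings (stricter, leakage-free variant).
    """

    n_repeats: int = 15
    train_fraction: float = 2.0 / 3.0
    n_trees: int = 100
    seed: int = 0
    split_unit: str = "instance"        # "instance" | "screening"
    max_resample: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats (paired t-test)")
        if self.split_unit not in ("instance", "screening"):
            raise ValueError("split_unit must be 'instance' or 'screening'")

    def split_sizes(self, n: int) -> tuple[int, int]:
        n_train = int(round(self.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        return n_train, n - n_train


def _screening_ids(inst: WindowedInstances) -> np.ndarray:
    if inst.anchors:
        return np.array([a[0] for a in inst.anchors])
    return np.zeros(inst.n_instances, dtype=int)


def _draw_split(rng: np.random.Generator, inst: WindowedInstances,
                plan: EvaluationPlan) -> tuple[np.ndarray, np.ndarray]:
    n = inst.n_instances
    if plan.split_unit == "instance":
        perm = rng.permutation(n)
        n_train, _ = plan.split_sizes(n)
        return perm[:n_train], perm[n_train:]
    sids = _screening_ids(inst)
    uniq = np.unique(sids)
    if len(uniq) < 2:
        raise ValueError("screening-level splits need >= 2 screenings")
    perm = rng.permutation(len(uniq))
    n_train_s = max(1, min(len(uniq) - 1,
                           int(round(plan.train_fraction * len(uniq)))))
    train_s = set(uniq[perm[:n_train_s]])
    mask = np.isin(sids, list(train_s))
    return np.where(mask)[0], np.where(~mask)[0]


def make_splits(inst: WindowedInstances, plan: EvaluationPlan,
                require_both_classes: bool = True,
                ) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Deterministic per-repeat (train_idx, test_idx, model_seed) list.

    Splits whose train or test part is single-class are redrawn (logged),
    up to ``plan.max_resample`` attempts each.  The same list is reused
    between the all-masses and reduced models so that leave-one-mass-out
    differences isolate the removed channel.
    """
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(plan.n_repeats)
    splits = []
    y = inst.y
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        model_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(plan.max_resample):
            train, test = _draw_split(rng, inst, plan)
            if not require_both_classes:
                break
            if (len(np.unique(y[train])) == 2
                    and len(np.unique(y[test])) == 2):
                break
            log.info("repeat %d: single-class split, redrawing (%d)",
                     r, attempt + 1)
        else:
            raise ValueError(
                f"repeat {r}: no split with both classes in train and "
                f"test after {plan.max_resample} draws")
        splits.append((train, test, model_seed))
    return splits


def _positive_scores(model: RandomForestClassifier,
                     X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    idx = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, idx]


def repeated_eval_backward(instances: WindowedInstances,
                           plan: EvaluationPlan,
                           splits: list | None = None) -> np.ndarray:
    """Held-out AUC per repeat for backward (label) prediction."""
    y = instances.y.astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("backward target must contain both classes")
    if splits is None:
        splits = make_splits(instances, plan)
    aucs = np.empty(len(splits))
    for r, (train, test, model_seed) in enumerate(splits):
        model = RandomForestClassifier(
            n_estimators=plan.n_trees, random_state=model_seed, n_jobs=1)
        model.fit(instances.X[train], y[train])
        scores = _positive_scores(model, instances.X[test])
        aucs[r] = auc(scores, y[test])
    return aucs


def repeated_eval_forward(instances: WindowedInstances,
                          plan: EvaluationPlan,
                          splits: list | None = None) -> np.ndarray:
    """Held-out Pearson r per repeat for forward (channel) regression."""
    if splits is None:
        splits = make_splits(instances, plan, require_both_classes=False)
    rs = np.empty(len(splits))
    for r, (train, test, model_seed) in enumerate(splits):
        model = RandomForestRegressor(
            n_estimators=plan.n_trees, random_state=model_seed, n_jobs=1)
        model.fit(instances.X[train], instances.y[train])
        pred = model.predict(instances.X[test])
        rs[r] = pearson_r(pred, instances.y[test])
    return rs


# ---------------------------------------------------------------------------
# leave-one-mass-out significance
# ---------------------------------------------------------------------------

@dataclass
class MassAblation:
    """One leave-one-mass-out row: reduced-model AUC and its p-value."""

    mass: str
    auc: float                 # mean held-out AUC with the mass removed
    p_value: float
    t_statistic: float
    mean_delta: float          # mean (baseline - reduced) AUC difference
    per_repeat_auc: np.ndarray = field(repr=False, default=None)
    formula: str = ""
    identity: str = ""


@dataclass
class LinkageResult:
    """Machine-readable linkage report for one label."""

    label: str
    baseline_auc: float        # mean AUC, all masses ("none" row)
    per_repeat_baseline: np.ndarray
    ablations: list[MassAblation]
    n_train: int
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": self.label, "mass": "none", "sig": np.nan,
                 "auc": self.baseline_auc, "formula": "",
                 "possible_id": ""}]
        for ab in self.ablations:
            rows.append({"label": self.label, "mass": ab.mass,
                         "sig": ab.p_value, "auc": ab.auc,
                         "formula": ab.formula, "possible_id": ab.identity})
        return pd.DataFrame(rows)


@dataclass
class ForwardResult:
    """Forward-prediction summary for one chemical channel."""

    mass: str
    per_repeat_r: np.ndarray

    @property
    def summary_r(self) -> float:
        return float(np.mean(self.per_repeat_r))


def leave_one_mass_out(instances: WindowedInstances,
                       plan: EvaluationPlan,
                       channels: list[str] | None = None,
                       annotations: dict[str, dict] | None = None,
                       ) -> LinkageResult:
    """Baseline vs reduced-model AUC per mass with paired significance.

    The baseline model uses every channel; each reduced model drops all
    lag columns of one channel while reusing the baseline's exact splits
    and model seeds.  Per Table-2 convention the reported AUC of a mass
    is the mean *reduced*-model AUC, and its p-value comes from the
    corrected resampled paired t-test on per-repeat
    (baseline - reduced) differences.
    """
    chans = channels if channels is not None else instances.channels
    if len(instances.channels) < 2:
        raise ValueError("leave-one-mass-out needs at least 2 channels")
    splits = make_splits(instances, plan)
    n_train, n_test = len(splits[0][0]), len(splits[0][1])
    baseline = repeated_eval_backward(instances, plan, splits=splits)
    ablations = []
    meta = annotations or {}
    for ch in chans:
        reduced_inst = instances.without_channel(ch)
        reduced = repeated_eval_backward(reduced_inst, plan, splits=splits)
        diffs = baseline - reduced
        t, p = corrected_paired_ttest(diffs, n_train, n_test)
        info = meta.get(ch, {})
        ablations.append(MassAblation(
            mass=ch, auc=float(reduced.mean()), p_value=p, t_statistic=t,
            mean_delta=float(diffs.mean()), per_repeat_auc=reduced,
            formula=info.get("formula", ""),
            identity=info.get("identity", "")))
    return LinkageResult(
        label=instances.target, baseline_auc=float(baseline.mean()),
        per_repeat_baseline=baseline, ablations=ablations,
        n_train=n_train, n_test=n_test)


# ---------------------------------------------------------------------------
# forward -> backward coherence
# ---------------------------------------------------------------------------

@dataclass
class CoherenceResult:
    """Backward AUC on measured vs forward-predicted chemistry."""

    auc_measured: np.ndarray     # per repeat
    auc_predicted: np.ndarray    # per repeat

    @property
    def difference(self) -> float:
        return float(self.auc_measured.mean() - self.auc_predicted.mean())


def coherence_check(measured: WindowedInstances,
                    predicted: WindowedInstances,
                    plan: EvaluationPlan) -> CoherenceResult:
    """Feed forward-model output into the backward model.

    ``predicted`` must mirror ``measured`` instance-for-instance, its
    feature windows holding forward-model chemistry predictions instead
    of measurements.  The backward classifier is trained on measured
    training windows; each repeat is then scored twice on the held-out
    anchors — once with measured windows, once with predicted ones — and
    the difference of the two AUCs is the coherence metric (0 when the
    forward model is perfect).
    """
    if measured.n_instances != predicted.n_instances:
        raise ValueError("measured/predicted instances must align")
    if measured.feature_names != predicted.feature_names:
        raise ValueError("measured/predicted features must align")
    y = measured.y.astype(int)
    splits = make_splits(measured, plan)
    a_meas = np.empty(len(splits))
    a_pred = np.empty(len(splits))
    for r, (train, test, model_seed) in enumerate(splits):
        model = RandomForestClassifier(
            n_estimators=plan.n_trees, random_state=model_seed, n_jobs=1)
        model.fit(measured.X[train], y[train])
        a_meas[r] = auc(_positive_scores(model, measured.X[test]), y[test])
        a_pred[r] = auc(_positive_scores(model, predicted.X[test]), y[test])
    return CoherenceResult(a_meas, a_pred)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def build_linkage_table(results, auc_min: float = 0.5,
                        p_max: float = 0.05,
                        keep_filtered: bool = False) -> pd.DataFrame:
    """Final linkage report: one row per retained (label, mass) pair.

    Mass rows failing AUC > ``auc_min`` or p < ``p_max`` are excluded
    (or kept with ``passed_filter`` flags when ``keep_filtered``);
    baseline "none" rows are always kept.  Mass rows sort by p ascending
    within each label.
    """
    frames = [res.to_frame() for res in results]
    if not frames:
        return pd.DataFrame(columns=["label", "mass", "sig", "auc",
                                     "formula", "possible_id"])
    table = pd.concat(frames, ignore_index=True)
    is_baseline = table["mass"] == "none"
    passed = (~is_baseline & (table["auc"] > auc_min)
              & (table["sig"] < p_max))
    if keep_filtered:
        table["passed_filter"] = passed | is_baseline
    else:
        table = table[passed | is_baseline]
    table = (table
             .sort_values(["label", "sig"], na_position="first",
                          kind="mergesort")
             .reset_index(drop=True))
    return table
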