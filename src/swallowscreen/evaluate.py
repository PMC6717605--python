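"""Monte-Carlo repeated random sub-sampling evaluation.

Each iteration draws a participant-stratified 80/20 train/validation split
(all boluses of a participant stay on one side, strata defined by the
participant-level reference status), refits the discriminant on the
training boluses, and measures on the validation side:

* bolus-level ROC AUC of the predicted impairment probabilities,
* participant-level ROC AUC of capped mean probabilities (first four
  boluses for thin, first three otherwise) against roll-up labels,
* sensitivity and specificity at a threshold fixed on the *training*
  participants to reach a target specificity (default 60%).

Metrics are averaged across iterations and reported on the percent scale
as mean +/- SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, Consistency, DataError, PipelineConfig
from .rlda import fit_rlda, predict_proba
from .vfss import participant_statuses

__all__ = [
    "SplitPlan",
    "EvalResult",
    "UndefinedAUCError",
    "make_split",
    "participant_score",
    "roc_auc",
    "operating_point",
    "monte_carlo_evaluate",
    "run_suite",
    "suite_tasks",
    "tables_report",
    "validation_sample_size",
    "SampleSizeResult",
]

log = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """Raised when ROC AUC is requested with only one class present."""


@dataclass(frozen=True)
class SplitPlan:
    iteration: int
    training: frozenset
    validation: frozenset

    def __post_init__(self):
        if self.training & self.validation:
            raise DataError("training and validation participants overlap")


def make_split(
    participant_status: dict[str, int],
    fraction: float,
    rng: np.random.Generator,
    iteration: int = 0,
) -> SplitPlan:
    """Stratified random participant partition, reproducible from ``rng``.

    Within each status stratum, ``round(fraction * n)`` participants go to
    validation.  A stratum with a single participant is kept in training.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigError(f"validation fraction must be in (0, 1), got {fraction}")
    train: set[str] = set()
    val: set[str] = set()
    by_status: dict[int, list[str]] = {}
    for pid in sorted(participant_status):
        by_status.setdefault(participant_status[pid], []).append(pid)
    for status in sorted(by_status):
        pids = by_status[status]
        if len(pids) == 1:
            log.warning("stratum %s has a single participant; kept in training", status)
            train.update(pids)
            continue
        n_val = int(math.floor(fraction * len(pids) + 0.5))
        n_val = min(max(n_val, 1), len(pids) - 1)
        order = rng.permutation(len(pids))
        chosen = {pids[i] for i in order[:n_val]}
        val.update(chosen)
        train.update(set(pids) - chosen)
    return SplitPlan(iteration=iteration, training=frozenset(train), validation=frozenset(val))


def participant_score(
    probabilities: Sequence[float],
    consistency: Consistency,
    config: PipelineConfig,
) -> Optional[float]:
    """Mean predicted probability over the first ``cap`` boluses.

    ``probabilities`` must be in protocol order; the cap is 4 for thin and
    3 for other consistencies.  Returns ``None`` with zero boluses.
    """
    probs = list(probabilities)
    if not probs:
        return None
    cap = config.bolus_cap(consistency)
    return float(np.mean(probs[:cap]))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Tie-aware (Mann-Whitney) area under the ROC curve."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = stats.rankdata(s)
    r_pos = float(ranks[y == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def operating_point(
    scores: Sequence[float], labels: Sequence[int], target_specificity: float = 0.6
) -> float:
    """Smallest decision threshold reaching the target training specificity.

    A score >= threshold is called screen-positive; specificity is the
    fraction of reference-negative scores below the threshold.  Choosing
    the smallest qualifying threshold maximizes sensitivity at that
    specificity.  The threshold is then applied unchanged to validation
    data.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    neg = s[y == 0]
    if len(neg) == 0 or np.sum(y == 1) == 0:
        raise DataError("operating point needs both classes in training data")
    candidates = np.concatenate([np.unique(s), [np.inf]])
    for t in candidates:
        if np.mean(neg < t) >= target_specificity:
            return float(t)
    log.warning("no threshold reaches specificity %.2f; using max", target_specificity)
    return float(candidates[-1])


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    return float(np.mean(pred[pos])), float(np.mean(~pred[neg]))


@dataclass
class EvalResult:
    consistency: str
    outcome: str
    bolus_auc_mean: float
    bolus_auc_sd: float
    participant_auc_mean: float
    participant_auc_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_iterations: int
    n_skipped: int = 0
    training_consistencies: tuple = ()
    validation_consistencies: tuple = ()

    def as_row(self) -> dict:
        fmt = lambda m, s: f"{m:.1f} ± {s:.1f}"  # noqa: E731
        return {
            "consistency": self.consistency,
            "outcome": self.outcome,
            "bolus_auc": fmt(self.bolus_auc_mean, self.bolus_auc_sd),
            "participant_auc": fmt(self.participant_auc_mean, self.participant_auc_sd),
            "sensitivity": fmt(self.sensitivity_mean, self.sensitivity_sd),
            "specificity": fmt(self.specificity_mean, self.specificity_sd),
            "n_iterations": self.n_iterations,
        }


def _label_column(outcome: str) -> str:
    if outcome not in ("safety", "efficiency"):
        raise ConfigError(f"outcome must be safety or efficiency, got {outcome!r}")
    return f"{outcome}_label"


def monte_carlo_evaluate(
    table: pd.DataFrame,
    outcome: str,
    config: PipelineConfig,
    consistency: Consistency,
    participant_status: Optional[dict[str, int]] = None,
    extra_training: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> EvalResult:
    """Repeated random sub-sampling evaluation of one classification task.

    ``table`` is a feature table (see ``build_feature_table``) restricted to
    the task's consistency and is the validation pool.  ``extra_training``
    rows (e.g. the thickest consistency for the moderately-thick safety
    task) join the training side only, and only for participants not drawn
    into the current validation set.  ``participant_status`` supplies the
    roll-up reference label per participant; by default it is derived from
    all rateable labels in ``table``.

    Iterations whose training split lacks two classes or whose validation
    split is single-class (bolus or participant level) are skipped and
    counted; a warning is emitted if more than 20% are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    label_col = _label_column(outcome)
    feat_cols = [c for c in table.columns if c not in (
        "participant_id", "consistency", "bolus_index",
        "safety_label", "efficiency_label", "n_segments",
    )]
    work = table.dropna(subset=[label_col]).copy()
    if participant_status is None:
        participant_status = {
            pid: int(grp[label_col].max())
            for pid, grp in work.groupby("participant_id")
        }
    eligible = {p: s for p, s in participant_status.items() if s is not None}
    extra = None
    if extra_training is not None and len(extra_training):
        extra = extra_training.dropna(subset=[label_col])

    bolus_aucs, part_aucs, sens, spec = [], [], [], []
    train_consistencies: set[str] = set()
    val_consistencies: set[str] = set()
    n_skipped = 0
    for it in range(config.n_iterations):
        plan = make_split(eligible, config.validation_fraction, rng, iteration=it)
        train_rows = work[work["participant_id"].isin(plan.training)]
        if extra is not None:
            safe_extra = extra[~extra["participant_id"].isin(plan.validation)]
            train_rows = pd.concat([train_rows, safe_extra], ignore_index=True)
        val_rows = work[work["participant_id"].isin(plan.validation)]
        y_train = train_rows[label_col].to_numpy(dtype=int)
        y_val = val_rows[label_col].to_numpy(dtype=int)
        if len(np.unique(y_train)) < 2 or np.bincount(y_train).min() < 2:
            n_skipped += 1
            continue
        val_status = np.array([eligible[p] for p in sorted(plan.validation)])
        if len(np.unique(y_val)) < 2 or len(np.unique(val_status)) < 2:
            n_skipped += 1
            continue
        model = fit_rlda(
            train_rows[feat_cols].to_numpy(),
            y_train,
            shrinkage=config.shrinkage,
            priors=config.priors,
            feature_names=feat_cols,
        )
        probs_val = predict_proba(model, val_rows[feat_cols].to_numpy())
        bolus_aucs.append(roc_auc(probs_val, y_val))

        def scores_for(rows, probs, pids):
            by_pid = {}
            for pid, p, b in zip(rows["participant_id"], probs, rows["bolus_index"]):
                by_pid.setdefault(pid, []).append((b, p))
            out = []
            for pid in pids:
                entries = sorted(by_pid.get(pid, []))
                out.append(
                    participant_score([p for _, p in entries], consistency, config)
                )
            return out

        val_pids = sorted(plan.validation)
        pscores = scores_for(val_rows, probs_val, val_pids)
        keep = [i for i, s in enumerate(pscores) if s is not None]
        pscores_arr = np.array([pscores[i] for i in keep])
        pstatus_arr = np.array([eligible[val_pids[i]] for i in keep])
        if len(np.unique(pstatus_arr)) < 2:
            bolus_aucs.pop()
            n_skipped += 1
            continue
        part_aucs.append(roc_auc(pscores_arr, pstatus_arr))

        train_table_rows = work[work["participant_id"].isin(plan.training)]
        probs_train = predict_proba(model, train_table_rows[feat_cols].to_numpy())
        train_pids = sorted(set(train_table_rows["participant_id"]))
        tscores = scores_for(train_table_rows, probs_train, train_pids)
        tkeep = [i for i, s in enumerate(tscores) if s is not None]
        threshold = operating_point(
            [tscores[i] for i in tkeep],
            [eligible[train_pids[i]] for i in tkeep],
            config.specificity_target,
        )
        se, sp = _sens_spec(pscores_arr, pstatus_arr, threshold)
        sens.append(se)
        spec.append(sp)
        train_consistencies.update(train_rows["consistency"].unique())
        val_consistencies.update(val_rows["consistency"].unique())

    if n_skipped > 0.2 * config.n_iterations:
        log.warning(
            "%d/%d iterations skipped (degenerate splits)", n_skipped, config.n_iterations
        )
    if not bolus_aucs:
        raise DataError("all Monte-Carlo iterations were degenerate")

    to_pct = lambda xs: (100.0 * float(np.mean(xs)), 100.0 * float(np.std(xs)))  # noqa: E731
    b_m, b_s = to_pct(bolus_aucs)
    p_m, p_s = to_pct(part_aucs)
    se_m, se_s = to_pct(sens)
    sp_m, sp_s = to_pct(spec)
    return EvalResult(
        consistency=consistency.name,
        outcome=outcome,
        bolus_auc_mean=b_m,
        bolus_auc_sd=b_s,
        participant_auc_mean=p_m,
        participant_auc_sd=p_s,
        sensitivity_mean=se_m,
        sensitivity_sd=se_s,
        specificity_mean=sp_m,
        specificity_sd=sp_s,
        n_iterations=len(bolus_aucs),
        n_skipped=n_skipped,
        training_consistencies=tuple(sorted(train_consistencies)),
        validation_consistencies=tuple(sorted(val_consistencies)),
    )


def suite_tasks() -> list[tuple[Consistency, str, bool]]:
    """The six (consistency, outcome, combined-training) classifier tasks."""
    tasks = []
    for consistency in (
        Consistency.thin,
        Consistency.mildly_thick,
        Consistency.moderately_thick,
    ):
        for outcome in ("safety", "efficiency"):
            combined = (
                consistency == Consistency.moderately_thick and outcome == "safety"
            )
            tasks.append((consistency, outcome, combined))
    return tasks


def run_suite(
    cohort,
    config: PipelineConfig,
    feature_table: Optional[pd.DataFrame] = None,
) -> list[EvalResult]:
    """Evaluate all six per-consistency safety/efficiency classifiers.

    ``feature_table`` may be precomputed (all consistencies in one frame);
    otherwise it is built from the cohort's recordings.  The moderately
    thick safety task trains on combined moderately + extremely thick rows
    while validating on moderately thick rows only; if no extremely thick
    rows exist the task degrades gracefully to moderate-only training.
    Tasks without both classes are skipped with a notice.
    """
    from .features import build_feature_table

    if feature_table is None:
        feature_table = build_feature_table(cohort, config)
    rng = np.random.default_rng(config.seed)
    results = []
    for consistency, outcome, combined in suite_tasks():
        sub = feature_table[feature_table["consistency"] == consistency.name]
        extra = None
        if combined:
            extra = feature_table[
                feature_table["consistency"] == Consistency.extremely_thick.name
            ]
            if not len(extra):
                log.warning(
                    "no extremely thick rows available; moderately thick safety "
                    "task trains on moderate rows only"
                )
                extra = None
        status = None
        if cohort is not None:
            st = participant_statuses(cohort, consistency)
            attr = "safety_impaired" if outcome == "safety" else "efficiency_impaired"
            status = {
                pid: getattr(s, attr)
                for pid, s in st.items()
                if getattr(s, attr) is not None and pid in set(sub["participant_id"])
            }
        try:
            results.append(
                monte_carlo_evaluate(
                    sub,
                    outcome,
                    config,
                    consistency=consistency,
                    participant_status=status,
                    extra_training=extra,
                    rng=rng,
                )
            )
        except DataError as exc:
            log.warning("task %s/%s skipped: %s", consistency.name, outcome, exc)
    return results


def tables_report(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Render suite results in the published accuracy-table layout."""
    return pd.DataFrame([r.as_row() for r in results])


@dataclass(frozen=True)
class SampleSizeResult:
    n_required: int
    n_required_sensitivity: int
    n_required_specificity: int
    evaluable_positive_fraction: float
    assumptions: dict = field(hash=False)


def _binomial_power_n(p_alt: float, p_null: float, power: float, alpha: float) -> int:
    """Smallest n so a one-sided exact binomial test of H0: p <= p_null
    rejects with probability >= power when the true rate is p_alt."""
    if p_alt <= p_null:
        raise ConfigError(
            f"performance target {p_alt} must exceed the null bound {p_null}"
        )
    for n in range(2, 200_000):
        k_crit = int(stats.binom.isf(alpha, n, p_null)) + 1
        if k_crit > n:
            continue
        if stats.binom.sf(k_crit - 1, n, p_alt) >= power:
            return n
    raise ConfigError("no feasible sample size below 200000")


def validation_sample_size(
    prevalence: float,
    per_swallow_display_rate: float,
    n_boluses: int,
    sens_target: float,
    spec_target: float,
    power: float = 0.9,
    alpha: float = 0.05,
    margin: float = 0.1,
) -> SampleSizeResult:
    """Participants needed to demonstrate both accuracy targets.

    Method (an explicit design choice; the figure it informs was published
    without a stated method, so equality with it is not claimed): for each
    arm, find the smallest group size for which a one-sided exact binomial
    test of H0 ``rate <= target - margin`` at level ``alpha`` attains the
    requested power when the true rate equals the target.  The positive
    group is discounted by prevalence and by the chance that an impaired
    participant displays the problem on at least one of ``n_boluses``
    swallows (``1 - (1 - display_rate)**n_boluses``); the negative group is
    discounted by ``1 - prevalence``.  All assumptions are logged and
    returned.
    """
    for name, v in (
        ("prevalence", prevalence),
        ("per_swallow_display_rate", per_swallow_display_rate),
        ("sens_target", sens_target),
        ("spec_target", spec_target),
        ("power", power),
    ):
        if not (0.0 < v < 1.0):
            raise ConfigError(f"{name} must be in (0, 1), got {v}")
    if n_boluses < 1:
        raise ConfigError("n_boluses must be >= 1")
    p_display = 1.0 - (1.0 - per_swallow_display_rate) ** n_boluses
    n_pos = _binomial_power_n(sens_target, sens_target - margin, power, alpha)
    n_neg = _binomial_power_n(spec_target, spec_target - margin, power, alpha)
    n_sens = math.ceil(n_pos / (prevalence * p_display))
    n_spec = math.ceil(n_neg / (1.0 - prevalence))
    assumptions = {
        "prevalence": prevalence,
        "per_swallow_display_rate": per_swallow_display_rate,
        "n_boluses": n_boluses,
        "evaluable_positive_fraction": p_display,
        "sens_target": sens_target,
        "spec_target": spec_target,
        "power": power,
        "alpha": alpha,
        "null_margin": margin,
        "positives_needed": n_pos,
        "negatives_needed": n_neg,
    }
    log.info("sample-size assumptions: %s", assumptions)
    return SampleSizeResult(
        n_required=max(n_sens, n_spec),
        n_required_sensitivity=n_sens,
        n_required_specificity=n_spec,
        evaluable_positive_fraction=p_display,
        assumptions=assumptions,
    )
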