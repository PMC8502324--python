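"""Model/Results layer: constrained bootstrap selection of stay-length nets.

The estimation procedure mirrors how such networks are selected in
practice-oriented clinical prediction work:

1. stratified 2/3–1/3 split into training and validation samples (the
   training set must represent both outcome classes);
2. a fixed number of bootstrap replications (default 100) — each resamples
   the training rows with replacement, re-initializes the weights from a
   fresh seeded draw, and trains by back-propagation;
3. among replications whose training-sample sensitivity and specificity
   clear the ex-ante floors (defaults 0.80 / 0.70), the one maximizing the
   chosen orientation (sensitivity or specificity) is selected; if none
   clears both floors the overall oriented maximum is returned with
   ``floors_met = False`` and a warning;
4. the untouched validation third yields the reported evaluation.

:class:`LOSOutcomeModel` is the data-bound model object (constructed via
``from_records``); ``fit()`` returns a :class:`LOSOutcomeResults` carrying
the selected network, the validation evaluation report, Garson importances
with contribution signs, and a ``summary()`` table.  ``fit_macro`` /
``fit_micro`` are thin functional entry points over the class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from losnet import mlp
from losnet.evaluation import EvaluationReport, confusion, evaluate
from losnet.interpretation import importance_report
from losnet.outcomes import label_all
from losnet.records import (
    DRGReference,
    EncodingSpec,
    HospitalizationRecord,
    MICRO_UNITS,
    encode_design_matrix,
    select_top_diagnoses,
)

logger = logging.getLogger(__name__)

ORIENTATIONS = ("maximize_sensitivity", "maximize_specificity")


@dataclass
class SelectionPolicy:
    """Ex-ante constraints and orientation of the bootstrap selection."""

    orientation: str = "maximize_sensitivity"
    sens_floor: float = 0.80
    spec_floor: float = 0.70
    n_replications: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        for name in ("sens_floor", "spec_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")


@dataclass
class ReplicationResult:
    replication_id: int
    sens: float
    spec: float
    params: mlp.NetworkParameters


def split_train_validation(
    y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 2/3–1/3 split by outcome.

    Training takes ⌈2n/3⌉ rows with ⌈2·n_pos/3⌉ positives, so both classes
    appear on both sides.  Deterministic given the seed.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"each outcome class needs >= 2 members (got {len(pos)} positive, "
            f"{len(neg)} negative)"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_train = int(np.ceil(2 * n / 3))
    n_pos_train = min(int(np.ceil(2 * len(pos) / 3)), len(pos) - 1)
    n_neg_train = n_train - n_pos_train
    if not 1 <= n_neg_train <= len(neg) - 1:
        n_neg_train = min(max(n_neg_train, 1), len(neg) - 1)
        n_pos_train = n_train - n_neg_train
    train_idx = np.sort(np.concatenate([pos[:n_pos_train], neg[:n_neg_train]]))
    valid_idx = np.sort(np.concatenate([pos[n_pos_train:], neg[n_neg_train:]]))
    return train_idx, valid_idx


def _training_rates(params, X, y, cutoff=0.5) -> tuple[float, float]:
    pred = mlp.predict(params, X, cutoff)
    tp, fp, tn, fn = confusion(y, pred)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec


def bootstrap_replications(
    X_train: np.ndarray,
    y_train: np.ndarray,
    hp: mlp.TrainingHyperparameters,
    policy: SelectionPolicy,
    activation: str = "tansig",
) -> list[ReplicationResult]:
    """Run the R bootstrap training replications.

    Each replication draws its randomness from a generator keyed by
    (policy seed, replication id), so the first R replications are identical
    whatever the total — growing R only extends the pool.  Sensitivity and
    specificity are measured on the full training sample.  A resample
    missing a class is redrawn up to 10 times, then the replication is
    skipped with a warning.
    """
    n = len(y_train)
    results: list[ReplicationResult] = []
    for r in range(1, policy.n_replications + 1):
        rng = np.random.default_rng([policy.seed, r])
        for _ in range(10):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y_train[idx])) == 2:
                break
        else:
            logger.warning("replication %d: bootstrap sample single-class, skipped", r)
            continue
        params = mlp.train(X_train[idx], y_train[idx], hp, activation=activation, rng=rng)
        sens, spec = _training_rates(params, X_train, y_train)
        results.append(ReplicationResult(r, sens, spec, params))
    if not results:
        raise ValueError("no usable bootstrap replication (labels too imbalanced)")
    return results


def select_replication(
    replications: list[ReplicationResult], policy: SelectionPolicy
) -> tuple[ReplicationResult, bool]:
    """Oriented maximization under the sensitivity/specificity floors.

    Ties go to the smaller replication id (list order); when no replication
    clears both floors the overall oriented maximum is returned with a
    warning and ``floors_met = False``.
    """
    metric = (lambda r: r.sens) if policy.orientation == "maximize_sensitivity" \
        else (lambda r: r.spec)
    eligible = [r for r in replications
                if r.sens >= policy.sens_floor and r.spec >= policy.spec_floor]
    pool, floors_met = (eligible, True) if eligible else (replications, False)
    if not floors_met:
        logger.warning(
            "no replication met the floors (sens >= %.2f, spec >= %.2f); "
            "returning the oriented maximum", policy.sens_floor, policy.spec_floor)
    best = max(pool, key=metric)   # max keeps the first (smallest id) on ties
    return best, floors_met


@dataclass
class LOSOutcomeResults:
    """Fit results: the selected network and everything read off it."""

    model: "LOSOutcomeModel"
    params: mlp.NetworkParameters
    replication_id: int
    training_metrics: tuple[float, float]          # (sens, spec) on training sample
    floors_met: bool
    validation_report: EvaluationReport
    replication_table: list[ReplicationResult] = field(repr=False, default_factory=list)

    @property
    def importance(self) -> list[dict]:
        """Garson percentage contributions and signs, importance-descending."""
        return importance_report(self.params, self.model.column_names)

    def predict(self, X=None, cutoff: float = 0.5):
        if X is None:
            X = self.model.X
        return mlp.predict(self.params, np.asarray(X, dtype=float), cutoff)

    def predict_records(self, records, drg_ref=None, cutoff: float = 0.5):
        """Apply the frozen network to new records via the model's encoding."""
        X = encode_design_matrix(records, self.model.spec).to_numpy(dtype=float)
        return mlp.predict(self.params, X, cutoff)

    def save(self, path) -> None:
        mlp.save_parameters(self.params, path)

    def summary(self) -> str:
        rep = self.validation_report
        m = self.model
        lines = [
            "Length-of-stay outcome network",
            "=" * 46,
            f"outcome: {m.outcome}   mode: {m.spec.mode}"
            + (f"   unit: {m.spec.unit}" if m.spec.unit else ""),
            f"architecture: {self.params.hidden_activation}, "
            f"{self.params.n_hidden} hidden neurons, {self.params.n_inputs} inputs",
            f"selected replication: {self.replication_id}"
            f"   floors met: {self.floors_met}",
            f"training sens/spec: {self.training_metrics[0]:.4f} / "
            f"{self.training_metrics[1]:.4f}",
            "-" * 46,
            f"validation n: {rep.n}   occurrence: {rep.occurrence}",
            f"incorrect classification: {rep.incorrect_classification:.2%}",
            f"sensitivity: {rep.sensitivity:.2%}  (SE {rep.sens_se:.3f}, "
            f"95% CI {rep.sens_ci[0]:.3f}-{rep.sens_ci[1]:.3f})",
            f"specificity: {rep.specificity:.2%}  (SE {rep.spec_se:.3f}, "
            f"95% CI {rep.spec_ci[0]:.3f}-{rep.spec_ci[1]:.3f})",
            f"false positive rate: {rep.fpr:.2%}   false negative rate: {rep.fnr:.2%}",
            f"LR+: {rep.lr_pos:.2f}   LR-: {rep.lr_neg:.2f}   AUC: {rep.auc_binary:.2f}",
            "-" * 46,
            "top contributions (Garson % / sign):",
        ]
        for row in self.importance[:5]:
            lines.append(f"  {row['column']:<24s} {row['garson_pct']:6.2f}  {row['sign']}")
        return "\n".join(lines)


class LOSOutcomeModel:
    """A stay-length outcome model bound to encoded data.

    Constructed from records via :meth:`from_records` (which labels against
    the DRG reference and encodes the design matrix) or directly from an
    (X, y, column_names) triple.  ``fit`` runs the split + bootstrap
    selection and returns :class:`LOSOutcomeResults`.
    """

    def __init__(self, X, y, column_names, outcome="long", spec=None,
                 activation="tansig"):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        self.column_names = list(column_names)
        self.outcome = outcome
        self.spec = spec if spec is not None else EncodingSpec(
            mode="macro", diagnosis_dummies=())
        self.activation = activation

    @classmethod
    def from_records(
        cls,
        records: list[HospitalizationRecord],
        drg_ref: dict[str, DRGReference],
        outcome: str = "long",
        mode: str = "macro",
        unit: str | None = None,
        activation: str = "tansig",
        top_k_diagnoses: int = 10,
    ) -> "LOSOutcomeModel":
        if outcome not in ("long", "outlier"):
            raise ValueError("outcome must be 'long' or 'outlier'")
        if mode == "micro":
            if unit is None:
                raise ValueError("micro mode requires a unit")
            records = [r for r in records if r.unit == unit]
            if len(records) < 30:
                raise ValueError(
                    f"unit {unit!r}: only {len(records)} records after filtering; "
                    "too few to fit"
                )
        spec = EncodingSpec(
            mode=mode,
            unit=unit,
            diagnosis_dummies=select_top_diagnoses(records, k=top_k_diagnoses),
        )
        X = encode_design_matrix(records, spec)
        labels = label_all(records, drg_ref)
        y = [getattr(l, outcome) for l in labels]
        m = cls(X.to_numpy(dtype=float), y, X.columns, outcome=outcome, spec=spec,
                activation=activation)
        m.records = records
        return m

    def fit(
        self,
        hp: mlp.TrainingHyperparameters | None = None,
        policy: SelectionPolicy | None = None,
    ) -> LOSOutcomeResults:
        hp = hp if hp is not None else mlp.TrainingHyperparameters()
        policy = policy if policy is not None else SelectionPolicy()
        train_idx, valid_idx = split_train_validation(self.y, policy.seed)
        assert not set(train_idx) & set(valid_idx)
        X_tr, y_tr = self.X[train_idx], self.y[train_idx]
        X_va, y_va = self.X[valid_idx], self.y[valid_idx]
        if hp.n_hidden is None:
            hp = mlp.TrainingHyperparameters(
                n_hidden=choose_n_hidden(X_tr, y_tr, X_va, y_va, hp),
                learning_rate=hp.learning_rate, max_epochs=hp.max_epochs,
                error_threshold=hp.error_threshold, seed=hp.seed)
        reps = bootstrap_replications(X_tr, y_tr, hp, policy,
                                      activation=self.activation)
        best, floors_met = select_replication(reps, policy)
        scores = mlp.forward(best.params, X_va)
        report = evaluate(y_va, (scores >= 0.5).astype(int), scores=scores)
        return LOSOutcomeResults(
            model=self,
            params=best.params,
            replication_id=best.replication_id,
            training_metrics=(best.sens, best.spec),
            floors_met=floors_met,
            validation_report=report,
            replication_table=reps,
        )


def choose_n_hidden(
    X_train, y_train, X_valid, y_valid, hp: mlp.TrainingHyperparameters
) -> int:
    """Empirical hidden-layer size: grid {⌈p/2⌉, p, 2p+1} by validation
    balanced accuracy (ties to the smaller network)."""
    p = X_train.shape[1]
    grid = sorted({max(1, int(np.ceil(p / 2))), p, 2 * p + 1})
    best_size, best_score = grid[0], -1.0
    for h in grid:
        hp_h = mlp.TrainingHyperparameters(
            n_hidden=h, learning_rate=hp.learning_rate, max_epochs=hp.max_epochs,
            error_threshold=hp.error_threshold, seed=hp.seed)
        params = mlp.train(X_train, y_train, hp_h)
        sens, spec = _training_rates(params, X_valid, y_valid)
        score = (sens + spec) / 2
        if score > best_score + 1e-12:
            best_size, best_score = h, score
    return best_size


# ---------------------------------------------------------------------------
# Functional entry points

def fit_macro(
    records, drg_ref, outcome="long",
    hp: mlp.TrainingHyperparameters | None = None,
    policy: SelectionPolicy | None = None,
    activation: str = "tansig",
) -> LOSOutcomeResults:
    """Whole-department model: macro encoding, labeling, split, selection."""
    model = LOSOutcomeModel.from_records(
        records, drg_ref, outcome=outcome, mode="macro", activation=activation)
    return model.fit(hp, policy)


def fit_micro(
    records, drg_ref, unit, outcome="long",
    hp: mlp.TrainingHyperparameters | None = None,
    policy: SelectionPolicy | None = None,
    activation: str = "tansig",
    allowed_units: tuple = MICRO_UNITS,
) -> LOSOutcomeResults:
    """Per-unit model: unit filter, micro encoding (transfer + unit top-10)."""
    if unit not in allowed_units:
        raise ValueError(f"unit {unit!r} not among micro-analysis units {allowed_units}")
    model = LOSOutcomeModel.from_records(
        records, drg_ref, outcome=outcome, mode="micro", unit=unit,
        activation=activation)
    return model.fit(hp, policy)
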