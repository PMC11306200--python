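"""Utterance-level depression classification and the gender-fairness audit.

Pipeline, per cross-validation fold (folds are blocks of 10 participants;
all of a participant's utterances travel together):

1. z-score features on training utterances,
2. optionally debias (drop gender-separable features and/or apply the
   adversarial transformation, both fitted on the training fold only),
3. optionally keep the K features most correlated with the PHQ-8 score,
4. train a small feedforward classifier (input → 32 → 32 → 2 softmax) on
   utterances, each inheriting its participant's binary label,
5. score held-out participants as the **maximum** positive-class
   probability over their utterances, thresholded at 0.5.

Out-of-fold participant decisions are pooled and audited per gender:
TPR, TNR, balanced accuracy BA = (TPR + TNR)/2, predicted positive rate
PPR, the classification equality of opportunity

    EO = 1 − |TPR(male) − TPR(female)|,

and a pooled two-proportion Z-test of each gender's PPR against its base
depression rate (a significant z means the model systematically over- or
under-diagnoses that gender relative to the labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anxiety import FoldAssignment
from .cohort import CohortTable
from .debias import (
    AdversarialConfig,
    DebiasConfig,
    K_GRID,
    M_GRID,
    drop_gender_features,
    train_adversarial_transformer,
)
from .errors import ValidationError
from .nn import Adam, Dense, ReLU, Sequential, Standardizer, parameter_checksum, softmax, softmax_xent
from .stats import TestResult, rank_by_gender_separability, rank_by_outcome_correlation, two_proportion_z


@dataclass
class ClassifierConfig:
    """Feedforward depression classifier hyperparameters.

    Two ReLU hidden layers of 32 units, 2-way softmax output, cross-entropy
    loss, Adam (lr 1e-3), minibatch 32, at most 100 epochs with early
    stopping monitored on a held-out 10% of *training participants*
    (holding out utterances of seen participants would leak speaker
    identity into the stopping rule).
    """

    hidden: tuple[int, int] = (32, 32)
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    validation_fraction: float = 0.1
    patience: int = 10
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if any(w < 1 for w in self.hidden):
            raise ValidationError("hidden widths must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")


def participant_folds(participant_ids, fold_size: int = 10, seed: int = 0) -> FoldAssignment:
    """Shuffle participants and cut into consecutive blocks of ``fold_size``.

    The last block may be smaller. All utterances of a participant share
    its fold, so evaluation is speaker-independent.
    """
    ids = list(dict.fromkeys(participant_ids))
    if len(ids) < 2:
        raise ValidationError("need >= 2 participants")
    if fold_size < 1:
        raise ValidationError("fold_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = []
    for start in range(0, len(order), fold_size):
        test = tuple(order[start:start + fold_size])
        train = tuple(i for i in order if i not in test)
        folds.append((test, train))
    return FoldAssignment(tuple(folds))


class DepressionClassifier:
    """Fitted feedforward network with a stable predict_proba surface."""

    def __init__(self, net: Sequential, standardizer: Standardizer | None, config: ClassifierConfig):
        self.net = net
        self.standardizer = standardizer
        self.config = config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        return softmax(self.net.forward(X))[:, 1]

    def parameter_checksum(self) -> float:
        return parameter_checksum([self.net])


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig | None = None,
    participant_ids=None,
    standardize: bool = True,
) -> DepressionClassifier:
    """Train the utterance-level classifier with participant-aware early stopping.

    ``y`` holds per-utterance binary labels inherited from the participant.
    When ``participant_ids`` is given, a seeded 10% of training participants
    is held out and validation cross-entropy is monitored with the
    configured patience; training restores the best-epoch weights.
    """
    config = config or ClassifierConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)

    std = Standardizer().fit(X) if standardize else None
    Z = std.transform(X) if std is not None else X

    # participant-level validation split for early stopping
    val_mask = np.zeros(len(y), dtype=bool)
    if participant_ids is not None and config.validation_fraction > 0:
        ids = list(dict.fromkeys(participant_ids))
        n_val = max(1, int(round(config.validation_fraction * len(ids))))
        if len(ids) - n_val >= 2:
            chosen = set(np.array(ids, dtype=object)[rng.permutation(len(ids))[:n_val]])
            val_mask = np.array([p in chosen for p in participant_ids])
            if len(np.unique(y[~val_mask])) < 2:  # split must keep both classes trainable
                val_mask[:] = False
    Zt, yt = Z[~val_mask], y[~val_mask]
    Zv, yv = Z[val_mask], y[val_mask]

    dims = [Z.shape[1], *config.hidden]
    layers = []
    for a, b in zip(dims[:-1], dims[1:]):
        layers += [Dense(a, b, rng), ReLU()]
    layers.append(Dense(dims[-1], 2, rng))
    net = Sequential(*layers)
    opt = Adam([p for l in net.dense_layers for p in l.params], lr=config.learning_rate)

    best_loss, best_weights, since_best = np.inf, None, 0
    n = len(yt)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            net.zero_grad()
            loss, grad = softmax_xent(net.forward(Zt[idx]), yt[idx])
            net.backward(grad)
            opt.step()
        if len(yv):
            val_loss, _ = softmax_xent(net.forward(Zv), yv)
            if val_loss < best_loss - 1e-6:
                best_loss, since_best = val_loss, 0
                best_weights = [(l.W.copy(), l.b.copy()) for l in net.dense_layers]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_weights is not None:
        for l, (W, b) in zip(net.dense_layers, best_weights):
            l.W[...], l.b[...] = W, b
    return DepressionClassifier(net, std, config)


def classify_participants(
    classifier: DepressionClassifier,
    features: np.ndarray,
    participant_ids,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Max-aggregate utterance probabilities into per-participant decisions.

    A participant is flagged depressed iff the maximum positive-class
    probability over their utterances exceeds the threshold. (Equivalent to
    "any utterance decided positive" at the same fixed threshold.)
    """
    threshold = classifier.config.threshold if threshold is None else threshold
    probs = classifier.predict_proba(features)
    frame = pd.DataFrame({"participant_id": list(participant_ids), "prob": probs})
    agg = frame.groupby("participant_id", sort=False)["prob"].max().reset_index()
    agg["decision"] = np.where(agg["prob"] > threshold, "depressed", "healthy")
    return agg


@dataclass
class ClassificationAuditReport:
    """Per-gender fairness metrics of pooled out-of-fold decisions.

    ``per_gender`` maps gender → dict with confusion counts and tpr / tnr /
    ba / ppr; ``eo`` is 1 − |TPR(male) − TPR(female)|; ``ppr_vs_base``
    maps gender → TestResult of predicted positives vs actual positives.
    """

    per_gender: dict
    eo: float | None
    ppr_vs_base: dict[str, TestResult]
    config_label: str = "original"
    seed: int | None = None

    def to_row(self) -> dict:
        row: dict = {"config": self.config_label, "seed": self.seed, "eo": self.eo}
        for g, m in self.per_gender.items():
            for k in ("tpr", "tnr", "ba", "ppr"):
                row[f"{k}_{g}"] = m[k]
            t = self.ppr_vs_base.get(g)
            if t is not None:
                row[f"z_{g}"], row[f"p_{g}"] = t.statistic, t.p_value
        return row


def classification_fairness(
    decisions: pd.DataFrame,
    labels: pd.DataFrame,
    gender: pd.DataFrame,
    config_label: str = "original",
    seed: int | None = None,
) -> ClassificationAuditReport:
    """Audit pooled participant decisions against labels, per gender.

    ``decisions``: participant_id, decision; ``labels``: participant_id,
    depression_class; ``gender``: participant_id, gender.
    """
    merged = decisions.merge(labels, on="participant_id").merge(gender, on="participant_id")
    if set(merged["participant_id"]) != set(labels["participant_id"]):
        raise ValidationError("decisions do not cover every labeled participant")
    genders = sorted(merged["gender"].unique())
    if len(genders) != 2:
        raise ValidationError("audit requires exactly the two gender groups")

    per_gender: dict[str, dict] = {}
    ppr_tests: dict[str, TestResult] = {}
    for g in genders:
        grp = merged[merged["gender"] == g]
        actual_pos = grp["depression_class"] == "depressed"
        pred_pos = grp["decision"] == "depressed"
        tp = int((actual_pos & pred_pos).sum())
        fn = int((actual_pos & ~pred_pos).sum())
        tn = int((~actual_pos & ~pred_pos).sum())
        fp = int((~actual_pos & pred_pos).sum())
        n = len(grp)
        metrics: dict = {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "n": n,
                         "ppr": (tp + fp) / n}
        if tp + fn > 0:
            metrics["tpr"] = tp / (tp + fn)
        else:
            warnings.warn(f"no actual positives for gender {g!r}; TPR undefined", stacklevel=2)
            metrics["tpr"] = np.nan
        metrics["tnr"] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        metrics["ba"] = (metrics["tpr"] + metrics["tnr"]) / 2.0
        per_gender[g] = metrics
        try:
            ppr_tests[g] = two_proportion_z(tp + fp, n, tp + fn, n)
        except ValidationError:
            pass  # degenerate pooled proportion (e.g. no positives at all)

    tprs = [per_gender[g]["tpr"] for g in genders]
    eo = None if any(np.isnan(t) for t in tprs) else 1.0 - abs(tprs[0] - tprs[1])
    return ClassificationAuditReport(per_gender=per_gender, eo=eo, ppr_vs_base=ppr_tests,
                                     config_label=config_label, seed=seed)


def default_grid(adversarial: AdversarialConfig | None = None,
                 k_grid=K_GRID, m_grid=M_GRID) -> list[DebiasConfig]:
    """The audit's 27 configurations: original features, top-K selection and
    drop-M removal, each with and without the adversarial transformation."""
    adv = adversarial or AdversarialConfig()
    grid = [DebiasConfig(mode="none", adversarial=adv)]
    for use_adv in (False, True):
        for k in k_grid:
            grid.append(DebiasConfig(mode="select_top_k_depression", k=k,
                                     apply_adversarial=use_adv, adversarial=adv))
        for m in m_grid:
            grid.append(DebiasConfig(mode="remove_top_m_gender", m=m,
                                     apply_adversarial=use_adv, adversarial=adv))
    return grid


def _prepare_fold_features(
    train_feats: pd.DataFrame,
    test_feats: pd.DataFrame,
    train_meta: pd.DataFrame,
    debias_cfg: DebiasConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the configured debiasing to one fold, fitted on train rows only.

    Ordering mirrors the audit design: for top-K selection the adversarial
    transformation (if any) runs first and Pearson selection operates on
    the transformed features; for drop-M removal the gender-separable
    features are removed first and the transformation runs on the reduced
    space.
    """
    std = Standardizer().fit(train_feats.to_numpy(dtype=float))
    train = pd.DataFrame(std.transform(train_feats.to_numpy(dtype=float)),
                         columns=train_feats.columns, index=train_feats.index)
    test = pd.DataFrame(std.transform(test_feats.to_numpy(dtype=float)),
                        columns=test_feats.columns, index=test_feats.index)

    def adversarial(tr: pd.DataFrame, te: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = AdversarialConfig(**{**debias_cfg.adversarial.__dict__, "seed": seed})
        transformer = train_adversarial_transformer(
            tr, train_meta["gender"], train_meta["depression_class"], cfg)
        return transformer.transform(tr), transformer.transform(te)

    if debias_cfg.mode == "remove_top_m_gender":
        ranking = rank_by_gender_separability(train, train_meta["gender"])
        train = drop_gender_features(train, ranking, debias_cfg.m)
        test = test[train.columns]
        if debias_cfg.apply_adversarial:
            train, test = adversarial(train, test)
    else:
        if debias_cfg.apply_adversarial:
            train, test = adversarial(train, test)
        if debias_cfg.mode == "select_top_k_depression":
            ranking = rank_by_outcome_correlation(train, train_meta["phq8"])
            keep = sorted(ranking.top(min(debias_cfg.k, train.shape[1])),
                          key=list(train.columns).index)
            train, test = train[keep], test[keep]
    return train, test


def run_audit(
    cohort: CohortTable,
    debias_cfg: DebiasConfig | None = None,
    classifier_cfg: ClassifierConfig | None = None,
    fold_size: int = 10,
    seed: int = 0,
) -> ClassificationAuditReport:
    """Run the full cross-validated audit for one debiasing configuration."""
    if cohort.schema_tag != "depression":
        raise ValidationError("run_audit requires a depression cohort")
    debias_cfg = debias_cfg or DebiasConfig()
    debias_cfg.validate()
    classifier_cfg = classifier_cfg or ClassifierConfig()

    rows = cohort.rows
    labels = cohort.labels
    meta = rows[["participant_id", "gender"]].merge(labels, on="participant_id")
    feats = rows[cohort.feature_columns]

    folds = participant_folds(rows["participant_id"], fold_size=fold_size, seed=seed)
    decisions = []
    for fold_i, (test_units, train_units) in enumerate(folds):
        test_mask = rows["participant_id"].isin(test_units).to_numpy()
        train_mask = ~test_mask
        train_meta = meta[train_mask]
        tr, te = _prepare_fold_features(
            feats[train_mask], feats[test_mask], train_meta, debias_cfg, seed)
        y = (train_meta["depression_class"] == "depressed").to_numpy(dtype=int)
        cfg = ClassifierConfig(**{**classifier_cfg.__dict__, "seed": seed * 1009 + fold_i})
        clf = train_classifier(tr.to_numpy(dtype=float), y, cfg,
                               participant_ids=train_meta["participant_id"].tolist(),
                               standardize=False)
        decisions.append(classify_participants(
            clf, te.to_numpy(dtype=float), rows.loc[test_mask, "participant_id"].tolist()))
    pooled = pd.concat(decisions, ignore_index=True)[["participant_id", "decision"]]

    gender_map = rows[["participant_id", "gender"]].drop_duplicates()
    return classification_fairness(
        pooled, labels[["participant_id", "depression_class"]], gender_map,
        config_label=debias_cfg.label(), seed=seed)


def run_audit_grid(
    cohort: CohortTable,
    grid: list[DebiasConfig] | None = None,
    classifier_cfg: ClassifierConfig | None = None,
    seeds=(0,),
    fold_size: int = 10,
) -> list[ClassificationAuditReport]:
    """Audit every debiasing configuration for every seed.

    Returns one report per (grid point, seed); ``pd.DataFrame(r.to_row()
    for r in reports)`` gives the flat results table.
    """
    grid = grid if grid is not None else default_grid()
    reports = []
    for seed in seeds:
        for cfg in grid:
            reports.append(run_audit(cohort, cfg, classifier_cfg,
                                     fold_size=fold_size, seed=seed))
    return reports
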