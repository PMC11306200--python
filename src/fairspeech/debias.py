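"""Debiasing of acoustic feature representations.

Two methods are provided, mirroring the two families most used for
sensitive-attribute removal in tabular speech features:

1. **Gender-feature removal** — rank features by gender separability
   (two-sample t-test p-value) and drop the M most separable ones.
2. **Adversarial autoencoder transformation** — an autoencoder
   (input → 256 → bottleneck → 128 → input, ReLU) with two softmax heads on
   the bottleneck, one predicting the depression outcome and one the
   speaker's gender. The training objective is

       L = MSE(reconstruction) + λ_d · CE(depression) − λ_g · CE(gender),

   with the gender term realised by gradient reversal: the gender head
   itself is trained to predict gender as well as it can, while the encoder
   receives the *negated* gender gradient and learns a representation the
   adversary cannot exploit. (Literally ascending the adversary's loss is
   unstable; gradient reversal is the standard stable formulation.)
   The transformed feature vector is the reconstruction-layer output, so
   the transformation preserves dimensionality and downstream feature
   selection still operates on the full feature grid.

Inputs are z-scored with parameters fitted on the training rows only; raw
eGeMAPS features have wildly different ranges and would otherwise dominate
the reconstruction loss. Fit the transformer on training folds only and
apply it to held-out rows — never fit on pooled data.

A :func:`leakage_probe` quantifies how much linearly-decodable evidence of
a binary attribute remains in a representation, as the cross-validated AUC
of an L2-regularized logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .nn import Adam, Dense, ReLU, Sequential, Standardizer, mse, softmax, softmax_xent
from .stats import FeatureRanking

#: Feature-count grids explored by the audit.
K_GRID = (5, 10, 15, 20, 30, 60, 88)
M_GRID = (5, 10, 15, 20, 30, 60)


@dataclass
class AdversarialConfig:
    """Hyperparameters of the adversarial autoencoder.

    ``bottleneck`` defaults to the input dimensionality (set at fit time
    when left as ``None``). λ_d and λ_g weight the depression and gender
    cross-entropy terms against the reconstruction MSE.
    """

    encoder_width: int = 256
    decoder_width: int = 128
    bottleneck: int | None = None
    lambda_depression: float = 1.0
    lambda_gender: float = 1.0
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    adversary_lr: float = 1e-3
    adversary_steps: int = 3
    seed: int = 0

    def validate(self) -> None:
        for w in (self.encoder_width, self.decoder_width):
            if w < 1:
                raise ValidationError("network widths must be positive")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValidationError("bottleneck width must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")


@dataclass
class DebiasConfig:
    """One point of the debiasing grid.

    ``mode`` chooses the feature-selection strategy: keep the K features
    most correlated with the outcome (``select_top_k_depression``), drop
    the M most gender-separable (``remove_top_m_gender``), or leave the set
    untouched (``none``). ``apply_adversarial`` additionally passes the
    (possibly reduced) features through the adversarial transformation.
    """

    mode: str = "none"
    k: int | None = None
    m: int | None = None
    apply_adversarial: bool = False
    adversarial: AdversarialConfig = field(default_factory=AdversarialConfig)

    def validate(self) -> None:
        if self.mode not in ("none", "select_top_k_depression", "remove_top_m_gender"):
            raise ValidationError(f"unknown debias mode {self.mode!r}")
        if self.mode == "select_top_k_depression" and self.k is None:
            raise ValidationError("select_top_k_depression requires k")
        if self.mode == "remove_top_m_gender" and self.m is None:
            raise ValidationError("remove_top_m_gender requires m")
        self.adversarial.validate()

    def label(self) -> str:
        base = {"none": "original", "select_top_k_depression": f"top_k={self.k}",
                "remove_top_m_gender": f"drop_m={self.m}"}[self.mode]
        return base + ("+adv" if self.apply_adversarial else "")


def drop_gender_features(features: pd.DataFrame, ranking: FeatureRanking, m: int) -> pd.DataFrame:
    """Remove the ``m`` most gender-separable features; survivor order kept."""
    if m < 0 or m >= features.shape[1]:
        raise ValidationError(f"m={m} must satisfy 0 <= m < {features.shape[1]}")
    doomed = set(ranking.top(m))
    keep = [c for c in features.columns if c not in doomed]
    return features[keep]


class FeatureTransformer:
    """A fitted adversarial autoencoder: standardize → encode → reconstruct.

    ``transform`` is a pure function of its input after fitting; output
    columns match input columns (reconstruction space).
    """

    def __init__(self, feature_names, standardizer: Standardizer,
                 encoder: Sequential, decoder: Sequential, loss_history: list[float]):
        self.feature_names = list(feature_names)
        self.standardizer = standardizer
        self.encoder = encoder
        self.decoder = decoder
        self.loss_history = loss_history

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if list(features.columns) != self.feature_names:
            raise SchemaError("feature columns do not match the fitted transformer")
        Z = self.standardizer.transform(features.to_numpy(dtype=float))
        out = self.decoder.forward(self.encoder.forward(Z))
        return pd.DataFrame(out, columns=self.feature_names, index=features.index)


def _as_binary(labels, name: str) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"{name} labels must have exactly 2 classes, got {list(classes)}")
    return (labels == classes[1]).astype(int)


def train_adversarial_transformer(
    features: pd.DataFrame,
    gender,
    depression,
    config: AdversarialConfig | None = None,
) -> FeatureTransformer:
    """Fit the adversarial autoencoder on training rows.

    The encoder/decoder minimize reconstruction MSE plus λ_d × depression
    cross-entropy; the gender head minimizes its own cross-entropy but its
    gradient is *reversed* (scaled by −λ_g) before entering the encoder.
    Minibatch Adam, seeded init and shuffling; deterministic given config.
    """
    config = config or AdversarialConfig()
    config.validate()
    g = _as_binary(gender, "gender")
    d = _as_binary(depression, "depression")
    X = features.to_numpy(dtype=float)
    n, dim = X.shape
    bottleneck = config.bottleneck or dim

    rng = np.random.default_rng(config.seed)
    encoder = Sequential(Dense(dim, config.encoder_width, rng), ReLU(),
                         Dense(config.encoder_width, bottleneck, rng), ReLU())
    decoder = Sequential(Dense(bottleneck, config.decoder_width, rng), ReLU(),
                         Dense(config.decoder_width, dim, rng))
    dep_head = Sequential(Dense(bottleneck, 2, rng))
    gen_head = Sequential(Dense(bottleneck, 2, rng))

    std = Standardizer()
    Z = std.fit_transform(X)

    main_params = [p for net in (encoder, decoder, dep_head) for l in net.dense_layers for p in l.params]
    opt = Adam(main_params, lr=config.learning_rate)
    # the adversary needs to stay near-optimal for the reversed gradient to
    # point at genuine gender evidence, so it gets its own faster optimizer
    # and several updates per main step
    opt_adv = Adam([p for l in gen_head.dense_layers for p in l.params], lr=config.adversary_lr)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, gb, db = Z[idx], g[idx], d[idx]
            for net in (encoder, decoder, dep_head, gen_head):
                net.zero_grad()

            h = encoder.forward(xb)
            for _ in range(config.adversary_steps):  # adversary catch-up
                gen_head.zero_grad()
                _, grad_lg = softmax_xent(gen_head.forward(h), gb)
                gen_head.backward(grad_lg)
                opt_adv.step()

            recon = decoder.forward(h)
            loss_r, grad_recon = mse(recon, xb)
            grad_h = decoder.backward(grad_recon)

            logits_d = dep_head.forward(h)
            loss_d, grad_ld = softmax_xent(logits_d, db)
            grad_h = grad_h + dep_head.backward(config.lambda_depression * grad_ld)

            gen_head.zero_grad()
            loss_g, grad_lg = softmax_xent(gen_head.forward(h), gb)
            # encoder sees the reversed gradient of the refreshed adversary
            grad_h_gender = gen_head.backward(grad_lg)
            gen_head.zero_grad()  # this pass trains the encoder, not the head
            grad_h = grad_h - config.lambda_gender * grad_h_gender

            encoder.backward(grad_h)
            opt.step()
            epoch_loss += loss_r + config.lambda_depression * loss_d - config.lambda_gender * loss_g
        total = epoch_loss / max(1, int(np.ceil(n / config.batch_size)))
        if not np.isfinite(total):
            raise ValidationError(f"adversarial training diverged at epoch {epoch}")
        history.append(total)

    return FeatureTransformer(features.columns, std, encoder, decoder, history)


def apply_transform(transformer: FeatureTransformer, features: pd.DataFrame) -> pd.DataFrame:
    """Pure application of a fitted transformer (columns must match)."""
    return transformer.transform(features)


def leakage_probe(features, labels, seed: int = 0, n_splits: int = 5) -> float:
    """Cross-validated AUC of a linear probe for a binary attribute.

    Logistic regression (L2, lbfgs) in stratified K-fold CV; AUC 0.5 means
    the representation carries no linearly decodable evidence of the
    attribute, 1.0 means it is fully exposed. Deterministic given seed.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = _as_binary(labels, "probe")
    n_splits = min(n_splits, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValidationError("too few samples in the rarer class for a CV probe")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for train_idx, test_idx in cv.split(X, y):
        std = Standardizer().fit(X[train_idx])
        clf = LogisticRegression(max_iter=2000)
        clf.fit(std.transform(X[train_idx]), y[train_idx])
        scores[test_idx] = clf.predict_proba(std.transform(X[test_idx]))[:, 1]
    return float(roc_auc_score(y, scores))
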