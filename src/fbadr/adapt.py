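"""Conditional Wasserstein adversarial domain adaptation of tangent features.

Per band, an adaptor network learns to map source-domain feature vectors
into target-domain-like vectors while a critic scores how target-like a
vector is.  Training alternates critic and adaptor updates on the
objective

    min_AD max_D  E[D(x_a | y)] - E[D(AD(r) | y)] - lambda * GP

where GP is the gradient penalty ``E[(||grad_xhat D(xhat|y)||_2 - 1)^2]``
on points interpolated uniformly between target and adapted-source
batches.  Label conditioning is realized by training one adaptor/critic
pair per emotion class (default), which keeps the published layer shapes
exact; a one-hot-concatenation variant is available via
``AdaptTrainConfig.conditioning = "one_hot"``.

Because the adaptor's tanh output is bounded, features are mapped into
[-1, 1] per dimension by an affine scaler fitted on target training
features and applied identically to both domains (and inverted on the
adaptor outputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from threadpoolctl import threadpool_limits

from .autodiff import Tensor, grad
from .config import AdaptTrainConfig
from .nn import Adam, Adaptor, Critic

__all__ = [
    "FeatureScaler",
    "gradient_penalty",
    "DomainBundle",
    "AdapterModel",
    "train_adaptation",
    "adapt_features",
    "domain_classifier_accuracy",
]


class FeatureScaler:
    """Invertible per-dimension affine map onto [-1, 1].

    Fitted on target training features only.  Constant dimensions map to
    0 with a unit inverse slope so the inverse is always defined.
    """

    def __init__(self) -> None:
        self.center: np.ndarray | None = None
        self.half_range: np.ndarray | None = None

    def fit(self, features: np.ndarray) -> "FeatureScaler":
        x = np.asarray(features, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("need a nonempty 2-D feature matrix")
        lo, hi = x.min(axis=0), x.max(axis=0)
        self.center = (hi + lo) / 2.0
        half = (hi - lo) / 2.0
        half[half == 0.0] = 1.0
        self.half_range = half
        return self

    def _check(self) -> None:
        if self.center is None:
            raise RuntimeError("scaler is not fitted")

    def transform(self, features: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(features, dtype=np.float64) - self.center) / self.half_range

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(features, dtype=np.float64) * self.half_range + self.center


def gradient_penalty(critic_fn, x_target_batch, x_adapted_batch,
                     rng: np.random.Generator, labels=None) -> Tensor:
    """Mean squared deviation of the critic's input-gradient norm from 1.

    Interpolation points are ``u * x_target + (1-u) * x_adapted`` with
    ``u ~ Uniform(0, 1)`` drawn per sample.  The returned scalar tensor
    is differentiable with respect to the critic's parameters.
    """
    x_t = np.asarray(x_target_batch)
    x_s = np.asarray(x_adapted_batch)
    if x_t.shape != x_s.shape:
        raise ValueError("target and adapted batches must share a shape")
    u = rng.uniform(size=(x_t.shape[0], 1))
    mix = (u * x_t + (1.0 - u) * x_s).astype(x_t.dtype if x_t.dtype == np.float32 else np.float64)
    xhat = Tensor(mix, requires_grad=True)
    d = critic_fn(xhat)
    (g,) = grad(d.sum(), [xhat])
    grad_norm = ((g**2).sum(axis=1) + 1e-16) ** 0.5
    return ((grad_norm - 1.0) ** 2).mean()


@dataclass
class DomainBundle:
    """Features for one band of one leave-one-sensory-out configuration."""

    target_train: np.ndarray
    target_train_labels: np.ndarray
    source: np.ndarray
    source_labels: np.ndarray
    band: int = 0
    target_val: np.ndarray | None = None
    target_val_labels: np.ndarray | None = None
    target_test: np.ndarray | None = None
    target_test_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.target_train.shape[1] != self.source.shape[1]:
            raise ValueError("feature dimensionality differs across domains")


@dataclass
class AdapterModel:
    """Trained adaptor/critic pairs for one band plus the feature scaler."""

    band: int
    scaler: FeatureScaler
    adaptors: dict
    critics: dict
    classes: list
    config: AdaptTrainConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


def _one_hot(labels: np.ndarray, classes: list) -> np.ndarray:
    idx = np.searchsorted(np.asarray(classes), labels)
    out = np.zeros((len(labels), len(classes)))
    out[np.arange(len(labels)), idx] = 1.0
    return out


def _train_pair(x_target: np.ndarray, x_source: np.ndarray,
                cond_target: np.ndarray | None, cond_source: np.ndarray | None,
                config: AdaptTrainConfig, rng: np.random.Generator,
                n_features: int):
    """Alternating WGAN-GP optimization for one adaptor/critic pair."""
    n_extra = 0 if cond_source is None else cond_source.shape[1]
    # networks train in single precision; feature scale is [-1, 1] anyway
    x_target = np.asarray(x_target, dtype=np.float32)
    x_source = np.asarray(x_source, dtype=np.float32)
    if cond_source is not None:
        cond_source = np.asarray(cond_source, dtype=np.float32)
        cond_target = np.asarray(cond_target, dtype=np.float32)
    adaptor = Adaptor(n_features, rng, n_extra_in=n_extra, dtype=np.float32)
    critic = Critic(n_features + n_extra, rng, sigmoid=config.critic_sigmoid,
                    norm=config.critic_norm, dtype=np.float32)
    opt_a = Adam(adaptor.params(), lr=config.learning_rate)
    opt_c = Adam(critic.params(), lr=config.learning_rate)

    def critic_in(x: Tensor, cond: np.ndarray | None) -> Tensor:
        if cond is None:
            return x
        from .autodiff import concat

        return concat([x, Tensor(cond)], axis=1)

    n_s, n_t = len(x_source), len(x_target)
    batch = min(config.batch_size, n_s)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n_s)
        c_losses, a_losses = [], []
        for start in range(0, n_s, batch):
            idx_s = perm[start : start + batch]
            zs = x_source[idx_s]
            cond_s = None if cond_source is None else cond_source[idx_s]
            z_in = zs if cond_source is None else np.hstack([zs, cond_s])

            for _ in range(config.critic_steps):
                idx_t = rng.choice(n_t, size=len(idx_s))
                xt = x_target[idx_t]
                cond_t = None if cond_target is None else cond_target[idx_t]
                fake = adaptor(Tensor(z_in), training=True).detach()
                d_real = critic(critic_in(Tensor(xt), cond_t), training=True).mean()
                d_fake = critic(critic_in(fake, cond_s), training=True).mean()
                gp = gradient_penalty(
                    lambda v: critic(critic_in(v, cond_t), training=True),
                    xt, fake.data, rng)
                loss_c = d_fake - d_real + config.lambda_gp * gp
                opt_c.step(grad(loss_c, critic.params()))
                c_losses.append(float(loss_c.data))

            fake = adaptor(Tensor(z_in), training=True)
            loss_a = -critic(critic_in(fake, cond_s), training=True).mean()
            opt_a.step(grad(loss_a, adaptor.params()))
            a_losses.append(float(loss_a.data))
        history.append(
            {"epoch": epoch, "critic_loss": float(np.mean(c_losses)),
             "adaptor_loss": float(np.mean(a_losses))}
        )
    return adaptor, critic, history


def train_adaptation(bundle: DomainBundle, config: AdaptTrainConfig) -> AdapterModel:
    """Train the conditional adversarial adapter for one band.

    Returns the fitted :class:`AdapterModel` with a per-epoch loss
    history (one row per epoch and conditioning unit).  Deterministic
    given ``config.seed``.
    """
    classes = sorted(np.unique(bundle.source_labels).tolist())
    target_classes = set(np.unique(bundle.target_train_labels).tolist())
    missing = [c for c in classes if c not in target_classes]
    if missing:
        raise ValueError(
            f"classes {missing} present in source but absent in target; "
            "conditional distribution undefined"
        )
    scaler = FeatureScaler().fit(bundle.target_train)
    x_t = scaler.transform(bundle.target_train)
    x_s = scaler.transform(bundle.source)
    n_features = x_t.shape[1]

    adaptors, critics, frames = {}, {}, []
    # single-threaded BLAS: bit-reproducible training across machines
    with threadpool_limits(limits=1):
        _run_training(bundle, config, x_t, x_s, n_features,
                      adaptors, critics, frames)

    return AdapterModel(
        band=bundle.band, scaler=scaler, adaptors=adaptors, critics=critics,
        classes=sorted(np.unique(bundle.source_labels).tolist()),
        config=config, history=pd.concat(frames, ignore_index=True),
    )


def _run_training(bundle, config, x_t, x_s, n_features,
                  adaptors, critics, frames):
    classes = sorted(np.unique(bundle.source_labels).tolist())
    if config.conditioning == "per_class":
        for ci, cls in enumerate(classes):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), int(bundle.band), ci])
            )
            xt_c = x_t[bundle.target_train_labels == cls]
            xs_c = x_s[bundle.source_labels == cls]
            if len(xt_c) == 0 or len(xs_c) == 0:
                raise ValueError(f"empty class {cls!r} in one domain")
            adaptor, critic, hist = _train_pair(
                xt_c, xs_c, None, None, config, rng, n_features)
            adaptors[cls], critics[cls] = adaptor, critic
            frames.append(pd.DataFrame(hist).assign(unit=str(cls)))
    else:  # one_hot
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), int(bundle.band), 999])
        )
        cond_t = _one_hot(bundle.target_train_labels, classes)
        cond_s = _one_hot(bundle.source_labels, classes)
        adaptor, critic, hist = _train_pair(
            x_t, x_s, cond_t, cond_s, config, rng, n_features)
        adaptors["__all__"], critics["__all__"] = adaptor, critic
        frames.append(pd.DataFrame(hist).assign(unit="one_hot"))


def adapt_features(model: AdapterModel, source_features: np.ndarray,
                   labels: np.ndarray, return_scaled: bool = False) -> np.ndarray:
    """Map source features through the trained adaptor (inference mode).

    Outputs are returned in the original feature scale unless
    ``return_scaled`` is set, in which case they stay in the tanh-bounded
    [-1, 1] scaled space.
    """
    x = model.scaler.transform(source_features).astype(np.float32)
    out = np.empty_like(x, dtype=np.float64)
    if model.config.conditioning == "per_class":
        for cls in model.classes:
            mask = np.asarray(labels) == cls
            if not mask.any():
                continue
            adapted = model.adaptors[cls](Tensor(x[mask]), training=False)
            out[mask] = adapted.data
    else:
        cond = _one_hot(np.asarray(labels), model.classes)
        adapted = model.adaptors["__all__"](
            Tensor(np.hstack([x, cond])), training=False)
        out[:] = adapted.data
    return out if return_scaled else model.scaler.inverse_transform(out)


def domain_classifier_accuracy(x_a: np.ndarray, x_b: np.ndarray, seed: int = 0,
                               test_fraction: float = 0.5) -> float:
    """Held-out accuracy of a linear two-sample domain classifier.

    0.5 means the two feature sets are indistinguishable to the probe;
    used to quantify how much residual domain shift adaptation leaves.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    x = np.vstack([x_a, x_b])
    y = np.concatenate([np.zeros(len(x_a)), np.ones(len(x_b))])
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=y)
    clf = LogisticRegression(max_iter=2000).fit(x_tr, y_tr)
    return float(clf.score(x_te, y_te))
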