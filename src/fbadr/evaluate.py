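"""Leave-one-sensory-out evaluation protocol, ablation variants and the
SNR robustness sweep.

One sensory modality is the target domain; the two others are labeled
source domains.  Per subject, target epochs are split into five
stratified subsets; fold k uses subset k as test, subset (k+1) mod 5 as
validation and the remaining three as training (the 60/20/20 split).
Source data are training-only.  Variants:

* ``RIE``    broadband (1-50 Hz) tangent features, single SVM, no adaptation
* ``ADR``    broadband features, single SVM, adversarial adaptation
* ``FBR``    six-band features, SVM ensemble + meta-LR, no adaptation
* ``FBADR``  six-band features, adaptation, SVM ensemble + meta-LR

Passing ``adapt_config=None`` disables adaptation, making FBADR
reproduce FBR (and ADR reproduce RIE) bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify
from .adapt import DomainBundle, adapt_features, train_adaptation
from .config import AdaptTrainConfig, ProtocolConfig
from .containers import BandedEpochs, EpochSet
from .filterbank import apply_filter_bank
from .preprocess import drop_reference, epoch_recordings, preprocess_recording
from .riemann import band_covariances, extract_features, fit_references
from .synthetic import realized_snr

__all__ = [
    "EvalReport",
    "make_folds",
    "prepare_epochs",
    "run_variant",
    "robustness_sweep",
]


@dataclass
class EvalReport:
    """Long-format per-fold results plus aggregate helpers."""

    table: pd.DataFrame

    @property
    def mean_accuracy(self) -> float:
        return float(self.table["accuracy"].mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.table["accuracy"].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        keys = [k for k in ("variant", "snr") if k in self.table.columns]
        return (
            self.table.groupby(keys, dropna=False)["accuracy"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def make_folds(labels, seed: int, n_folds: int = 5) -> list[dict[str, np.ndarray]]:
    """Stratified fold assignments: per fold, 3 subsets train / 1 val / 1 test.

    Labels are shuffled per class and dealt round-robin into ``n_folds``
    equal subsets (remainders spread deterministically), so every subset
    serves as the test set exactly once and the validation subset for
    fold k is subset (k+1) mod n_folds.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    subsets: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples; need >= {n_folds}"
            )
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            subsets[j % n_folds].append(int(i))
    subsets = [np.sort(np.array(s)) for s in subsets]
    folds = []
    for k in range(n_folds):
        val = (k + 1) % n_folds
        train = np.concatenate(
            [subsets[j] for j in range(n_folds) if j not in (k, val)]
        )
        folds.append(
            {"train": np.sort(train), "val": subsets[val], "test": subsets[k]}
        )
    return folds


def prepare_epochs(recordings, window_s: float = 5.0,
                   span_s: tuple[float, float] = (0.0, 30.0),
                   reference_channel: str = "FCz") -> EpochSet:
    """Full preprocessing front end: filter, notch, baseline, epoch, drop ref."""
    processed = (preprocess_recording(r) for r in recordings)
    epochs = epoch_recordings(processed, window_s=window_s, span_s=span_s)
    return drop_reference(epochs, reference_channel)


def _derived_seed(*key: int) -> int:
    return int(
        np.random.SeedSequence(list(key)).generate_state(1, dtype=np.uint32)[0]
        & 0x7FFFFFFF
    )


def _variant_flags(variant: str) -> tuple[bool, bool]:
    multiband = variant in ("FBR", "FBADR")
    adapting = variant in ("ADR", "FBADR")
    return multiband, adapting


def _subject_fold_accuracies(
    sub_epochs: EpochSet,
    protocol: ProtocolConfig,
    adapt_config: AdaptTrainConfig | None,
    subject: int,
) -> list[float]:
    multiband, adapting = _variant_flags(protocol.variant)
    if adapt_config is None:
        adapting = False

    if multiband:
        covs = band_covariances(apply_filter_bank(sub_epochs))
    else:  # broadband 1-50 Hz treated as a single band 0
        covs = band_covariances(BandedEpochs(bands={0: sub_epochs}))

    labels = sub_epochs.labels
    target_mask = (labels["modality"] == protocol.target_modality).to_numpy()
    target_idx = np.flatnonzero(target_mask)
    source_idx = np.flatnonzero(~target_mask)
    y = labels["emotion"].to_numpy()
    y_target, y_source = y[target_idx], y[source_idx]

    mod_code = ["audio", "visual", "audiovisual"].index(protocol.target_modality)
    fold_seed = _derived_seed(protocol.seed, int(subject), mod_code, 1)
    folds = make_folds(y_target, fold_seed, protocol.n_folds)

    accs = []
    for k, fold in enumerate(folds):
        tr, va, te = (target_idx[fold[part]] for part in ("train", "val", "test"))
        # references from training data only (target-train + source)
        refs = fit_references(
            {b: np.concatenate([c[tr], c[source_idx]]) for b, c in covs.items()}
        )
        feats = {
            part: extract_features({b: c[idx] for b, c in covs.items()}, refs)
            for part, idx in (("train", tr), ("val", va), ("test", te),
                              ("source", source_idx))
        }
        if adapting:
            source_feats = {}
            for b in covs:
                cfg = dataclasses.replace(
                    adapt_config,
                    seed=_derived_seed(adapt_config.seed, int(subject),
                                       mod_code, k, int(b), 2),
                )
                bundle = DomainBundle(
                    target_train=feats["train"][b],
                    target_train_labels=y[tr],
                    source=feats["source"][b],
                    source_labels=y_source,
                    band=int(b),
                )
                model = train_adaptation(bundle, cfg)
                source_feats[b] = adapt_features(model, feats["source"][b], y_source)
        else:
            source_feats = feats["source"]

        train_feats = {
            b: np.vstack([feats["train"][b], source_feats[b]]) for b in covs
        }
        train_labels = np.concatenate([y[tr], y_source])

        if multiband:
            model = classify.train_ensemble(
                train_feats, train_labels, feats["val"], y[va],
                kernel=protocol.kernel, c=protocol.svm_c, gamma=protocol.svm_gamma)
            preds = classify.predict_ensemble(model, feats["test"])
        else:
            svm = classify.make_svm(protocol.kernel, protocol.svm_c,
                                    protocol.svm_gamma)
            svm.fit(train_feats[0], train_labels)
            preds = svm.predict(feats["test"][0])
        accs.append(classify.accuracy(preds, y[te]))
    return accs


def run_variant(epochs: EpochSet, protocol: ProtocolConfig,
                adapt_config: AdaptTrainConfig | None = None,
                subjects=None, snr_label=None) -> EvalReport:
    """Run one ablation variant over subjects for one target modality.

    ``epochs`` are preprocessed broadband epochs (reference dropped).
    ``adapt_config=None`` disables adversarial adaptation regardless of
    the variant name.
    """
    if subjects is None:
        subjects = sorted(epochs.labels["subject"].unique())
    rows = []
    for subject in subjects:
        sub = epochs.select((epochs.labels["subject"] == subject).to_numpy())
        accs = _subject_fold_accuracies(sub, protocol, adapt_config, int(subject))
        for k, acc in enumerate(accs):
            rows.append(
                {
                    "subject": int(subject),
                    "modality": protocol.target_modality,
                    "variant": protocol.variant,
                    "fold": k,
                    "snr": snr_label,
                    "accuracy": acc,
                }
            )
    return EvalReport(table=pd.DataFrame(rows))


def robustness_sweep(epochs: EpochSet, protocol: ProtocolConfig,
                     adapt_config: AdaptTrainConfig | None = None,
                     snr_levels=(30.0, 20.0, 10.0, 1.0, -0.1),
                     subjects=None, noise_seed: int = 0) -> EvalReport:
    """Clean baseline plus one evaluation per SNR level.

    Calibrated Gaussian noise is injected into the preprocessed
    broadband epochs (before the filter bank), per epoch, with signal
    power taken over that epoch.  One Gaussian draw per epoch is shared
    across all levels and rescaled to each target SNR (common random
    numbers), so the sweep is path-wise nested in noise power.  The
    realized SNR of each level is recorded alongside the accuracies;
    the clean baseline is labeled with an infinite SNR.
    """
    reports = [
        run_variant(epochs, protocol, adapt_config, subjects, snr_label=np.inf)
    ]
    reports[0].table["realized_snr"] = np.inf
    rng = np.random.default_rng(np.random.SeedSequence([int(noise_seed), 71]))
    unit_noise = rng.standard_normal(epochs.epochs.shape)
    epoch_power = np.mean(epochs.epochs**2, axis=(1, 2), keepdims=True)
    for snr in snr_levels:
        sigma = np.sqrt(epoch_power / 10.0 ** (snr / 10.0))
        noised = epochs.epochs + sigma * unit_noise
        realized = float(
            np.mean(
                [realized_snr(c, n) for c, n in zip(epochs.epochs, noised)]
            )
        )
        noisy = EpochSet(
            epochs=noised, fs=epochs.fs, labels=epochs.labels,
            channel_names=list(epochs.channel_names),
        )
        rep = run_variant(noisy, protocol, adapt_config, subjects, snr_label=snr)
        rep.table["realized_snr"] = realized
        reports.append(rep)
    return EvalReport(table=pd.concat([r.table for r in reports],
                                      ignore_index=True))
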