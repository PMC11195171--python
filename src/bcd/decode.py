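"""Classification of baseline spectrograms and its statistical controls.

For every (session, nucleus) pair the spectrograms of all that nucleus'
channels are pooled into one two-class dataset (airflow vs. touch). The
data are split 80/10/10 into train/validation/test, the minority class is
bootstrap-resampled to parity within each fold (equal class representation
without leaking duplicated trials across folds), a min–max scaler is fit
on the training set only, and a classifier — the small CNN or an
RBF-kernel SVM — is trained. Repeating the whole procedure
with fresh splits and initializations yields a distribution of test
accuracies (50 repeats in the full protocol); re-running it with the
*training* labels shuffled (evaluation stays on true-labelled test data)
yields the matched null distribution that calibrates chance performance
under correlated noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import _cnn
from .timefreq import Spectrogram, SpectrogramScaler, restrict_rows

__all__ = [
    "CNNClassifier",
    "SVMClassifier",
    "TrainingProtocol",
    "SpectrogramDataset",
    "build_dataset",
    "balance_fold",
    "stratified_split",
    "train_once",
    "AccuracyDistribution",
    "accuracy_distribution",
    "band_ablation",
    "cross_nucleus_test",
]

LABELS = ("airflow", "touch")  # class 0, class 1


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional network for two-class spectrogram images.

    Layers: conv 3×3 ×24 + ReLU, batch norm, conv 3×3 ×48 + ReLU, max pool
    2×2 (stride 1), batch norm, fully connected 64 + ReLU, dropout, fully
    connected 2. Trained with Adam on cross-entropy in mini-batches; when
    validation data are supplied to :meth:`fit`, the parameters with the
    best validation accuracy across epochs are kept for prediction.

    Parameters
    ----------
    n_epochs, batch_size, lr : training schedule (defaults 40 / 20 / 1e-3).
    dropout : dropout probability before the output layer.
    pool_stride : stride of the 2×2 max pool (default 1; 2 available).
    random_state : seed for initialization, batching and dropout.
    """

    def __init__(
        self,
        n_filters1: int = 24,
        n_filters2: int = 48,
        kernel_size: int = 3,
        pool_size: int = 2,
        pool_stride: int = 1,
        n_hidden: int = 64,
        dropout: float = 0.5,
        lr: float = 1e-3,
        batch_size: int = 20,
        n_epochs: int = 40,
        random_state: int | None = None,
    ):
        self.n_filters1 = n_filters1
        self.n_filters2 = n_filters2
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.n_hidden = n_hidden
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y, validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        X = np.asarray(X, np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_freqs, n_times)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes are required")
        rng = np.random.default_rng(self.random_state)
        params = _cnn.init_params(
            rng, X.shape[1:], self.n_filters1, self.n_filters2, self.kernel_size,
            self.pool_size, self.pool_stride, self.n_hidden,
        )
        bn = _cnn.init_bn_state(params)
        opt = _cnn.Adam(params, lr=self.lr)
        n = X.shape[0]
        best_val, best_snapshot = -np.inf, None
        history = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            hits = 0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                logits, cache = _cnn.forward(
                    params, bn, X[idx], train=True, rng=rng, dropout=self.dropout,
                    pool=self.pool_size, pool_stride=self.pool_stride,
                )
                hits += int((logits.argmax(axis=1) == y_idx[idx]).sum())
                _, dlogits = _cnn.softmax_xent(logits, y_idx[idx])
                grads = _cnn.backward(params, cache, dlogits, self.pool_size, self.pool_stride)
                opt.step(params, grads)
            # running train-mode accuracy, tracked for the history only
            # (model selection uses validation accuracy)
            train_acc = hits / n
            if validation_data is not None:
                Xv, yv = validation_data
                yv_idx = np.searchsorted(self.classes_, np.asarray(yv))
                val_acc = self._accuracy(params, bn, np.asarray(Xv, np.float32), yv_idx)
                if val_acc > best_val:
                    best_val = val_acc
                    best_snapshot = (
                        {k: v.copy() for k, v in params.items()},
                        {k: v.copy() for k, v in bn.items()},
                    )
            else:
                val_acc = np.nan
            history.append((train_acc, val_acc))
        if best_snapshot is not None:
            params, bn = best_snapshot
        self.params_, self.bn_ = params, bn
        self.history_ = np.asarray(history)
        return self

    def _accuracy(self, params, bn, X, y_idx, chunk: int = 256) -> float:
        preds = np.concatenate(
            [
                _cnn.forward(
                    params, bn, X[s : s + chunk], train=False,
                    pool=self.pool_size, pool_stride=self.pool_stride,
                )[0].argmax(axis=1)
                for s in range(0, X.shape[0], chunk)
            ]
        )
        return float((preds == y_idx).mean())

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, np.float32)
        logits = np.concatenate(
            [
                _cnn.forward(
                    self.params_, self.bn_, X[s : s + 256], train=False,
                    pool=self.pool_size, pool_stride=self.pool_stride,
                )[0]
                for s in range(0, X.shape[0], 256)
            ]
        )
        return logits[:, 1] - logits[:, 0]

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, np.float32)
        logits = np.concatenate(
            [
                _cnn.forward(
                    self.params_, self.bn_, X[s : s + 256], train=False,
                    pool=self.pool_size, pool_stride=self.pool_stride,
                )[0]
                for s in range(0, X.shape[0], 256)
            ]
        )
        return self.classes_[logits.argmax(axis=1)]


class SVMClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel support-vector machine on flattened spectrograms.

    A thin wrapper around :class:`sklearn.svm.SVC` (dual soft-margin
    formulation). ``gamma='median'`` sets the kernel width by the median
    heuristic: gamma = 1 / median ``||x_i - x_j||^2`` over a subsample of
    training pairs.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "median", random_state: int | None = None):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    @staticmethod
    def _flatten(X) -> np.ndarray:
        X = np.asarray(X, np.float64)
        return X.reshape(X.shape[0], -1)

    def fit(self, X, y, validation_data=None):  # validation unused; protocol parity
        Xf = self._flatten(X)
        if isinstance(self.gamma, str) and self.gamma == "median":
            from scipy.spatial.distance import pdist

            rng = np.random.default_rng(self.random_state)
            idx = rng.permutation(Xf.shape[0])[:200]
            med = np.median(pdist(Xf[idx], metric="sqeuclidean"))
            gamma = 1.0 / med if med > 0 else "scale"
        else:
            gamma = self.gamma
        self.gamma_ = gamma
        self.svc_ = SVC(C=self.C, kernel="rbf", gamma=gamma, random_state=self.random_state)
        self.svc_.fit(Xf, np.asarray(y))
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self._flatten(X))

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(self._flatten(X))


@dataclass(frozen=True)
class TrainingProtocol:
    """Split fractions, repeat count and quantiles of the training protocol."""

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    n_repeats: int = 50
    quantiles: tuple[float, float, float] = (5.0, 50.0, 95.0)

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SpectrogramDataset:
    """Pooled labelled spectrograms for one (session, nucleus)."""

    X: np.ndarray  # (n, n_freqs, n_times)
    y: np.ndarray  # labels from LABELS
    freqs: np.ndarray
    session: int = 0
    nucleus: str = ""

    def class_counts(self) -> dict[str, int]:
        u, c = np.unique(self.y, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))


def build_dataset(
    specs: Sequence[Spectrogram],
    session: int = 0,
    nucleus: str | None = None,
    min_per_class: int = 20,
    max_per_class: int | None = 300,
    rng: np.random.Generator | int | None = None,
) -> SpectrogramDataset:
    """Pool spectrograms of one nucleus (or all channels) into a dataset.

    ``max_per_class`` caps the number of windows per class (random
    subsample) to keep training tractable; a few hundred training trials
    per dataset is the intended scale of the protocol.
    """
    if nucleus is not None:
        specs = [s for s in specs if s.nucleus == nucleus]
    if not specs:
        raise ValueError(f"no spectrograms for nucleus {nucleus!r}")
    X = np.stack([s.power for s in specs])
    y = np.asarray([s.label for s in specs])
    counts = {lab: int((y == lab).sum()) for lab in LABELS}
    for lab, c in counts.items():
        if c == 0:
            raise ValueError(f"class {lab!r} absent from dataset")
        if c < min_per_class:
            raise ValueError(f"class {lab!r} has {c} < {min_per_class} trials")
    if max_per_class is not None:
        rng = np.random.default_rng(rng)
        keep = []
        for lab in LABELS:
            idx = np.nonzero(y == lab)[0]
            if idx.size > max_per_class:
                idx = rng.choice(idx, size=max_per_class, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        X, y = X[keep], y[keep]
    return SpectrogramDataset(X=X, y=y, freqs=specs[0].freqs.copy(), session=session, nucleus=nucleus or "all")


def stratified_split(
    y: np.ndarray, protocol: TrainingProtocol, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """80/10/10 split of each class's (unique) items."""
    tr, va, te = [], [], []
    for lab in np.unique(y):
        idx = rng.permutation(np.nonzero(y == lab)[0])
        n = idx.size
        n_tr = int(protocol.train_frac * n)
        n_va = int(protocol.val_frac * n)
        tr.append(idx[:n_tr])
        va.append(idx[n_tr : n_tr + n_va])
        te.append(idx[n_tr + n_va :])
    return (np.concatenate(tr), np.concatenate(va), np.concatenate(te))


def balance_fold(
    idx: np.ndarray, y: np.ndarray, rng: np.random.Generator, evaluation: bool = False
) -> np.ndarray:
    """Equalize class counts *within one fold*.

    Balancing after the split keeps every physical trial in exactly one of
    train/validation/test: resampling the pooled dataset to parity before
    splitting would scatter duplicated minority trials across folds and
    leak training items into the test set.

    Training folds (``evaluation=False``) bootstrap the minority class up
    to parity (on a tie the touch class is the one resampled —
    identity-distribution — keeping the resampling step in the protocol
    even for balanced inputs). Evaluation folds instead subsample the
    majority class down: duplicated items in a validation or test fold
    would re-weight it for the whole run and bias the accuracy estimate.
    """
    counts = {lab: int((y[idx] == lab).sum()) for lab in LABELS}
    minority = min(LABELS, key=lambda l: (counts[l], l != "touch"))
    min_idx = idx[y[idx] == minority]
    maj_idx = idx[y[idx] != minority]
    if evaluation:
        if maj_idx.size > min_idx.size:
            maj_idx = rng.choice(maj_idx, size=min_idx.size, replace=False)
        return np.concatenate([maj_idx, min_idx])
    boot = rng.choice(min_idx, size=max(counts.values()), replace=True)
    return np.concatenate([maj_idx, boot])


def train_once(
    ds: SpectrogramDataset,
    model: BaseEstimator,
    protocol: TrainingProtocol,
    rng: np.random.Generator | int | None = None,
    shuffle_labels: bool = False,
    scaler: SpectrogramScaler | None = None,
) -> float:
    """One protocol repeat: balance, split, scale, train, test accuracy.

    With ``shuffle_labels=True`` the *training* (and validation) labels are
    permuted while the test set keeps its true labels — the null protocol.
    The scaler is fit on the training subset only.
    """
    rng = np.random.default_rng(rng)
    s_tr, s_va, s_te = stratified_split(ds.y, protocol, rng)
    i_tr = balance_fold(s_tr, ds.y, rng)
    i_va = balance_fold(s_va, ds.y, rng, evaluation=True)
    i_te = balance_fold(s_te, ds.y, rng, evaluation=True)
    y_tr, y_va = ds.y[i_tr], ds.y[i_va]
    if shuffle_labels:
        y_tr = y_tr[rng.permutation(y_tr.size)]
        y_va = y_va[rng.permutation(y_va.size)]
    scaler = scaler if scaler is not None else SpectrogramScaler()
    scaler.fit(ds.X[i_tr])
    X_tr = scaler.transform(ds.X[i_tr])
    X_va = scaler.transform(ds.X[i_va])
    X_te = scaler.transform(ds.X[i_te])
    clf = clone(model)
    clf.set_params(random_state=int(rng.integers(2**31 - 1)))
    clf.fit(X_tr, y_tr, validation_data=(X_va, y_va))
    return float((clf.predict(X_te) == ds.y[i_te]).mean())


@dataclass
class AccuracyDistribution:
    """Repeat-level test accuracies and their shuffled-label null."""

    accuracies: np.ndarray
    null_accuracies: np.ndarray | None
    session: int = 0
    nucleus: str = ""
    classifier: str = ""
    band: str = "full"
    quantile_levels: tuple[float, float, float] = (5.0, 50.0, 95.0)

    @property
    def quantiles(self) -> np.ndarray:
        return np.percentile(self.accuracies, self.quantile_levels)

    @property
    def null_quantiles(self) -> np.ndarray | None:
        if self.null_accuracies is None:
            return None
        return np.percentile(self.null_accuracies, self.quantile_levels)

    def separated_from_null(self) -> bool:
        """True when the real 5th percentile exceeds the null 95th — the
        "no overlap with the null distribution" criterion."""
        if self.null_accuracies is None:
            raise ValueError("no null sample stored")
        lo = np.percentile(self.accuracies, self.quantile_levels[0])
        hi = np.percentile(self.null_accuracies, self.quantile_levels[2])
        return bool(lo > hi)


def accuracy_distribution(
    ds: SpectrogramDataset,
    model: BaseEstimator,
    protocol: TrainingProtocol = TrainingProtocol(),
    rng: np.random.Generator | int | None = None,
    with_null: bool = True,
    band: str = "full",
) -> AccuracyDistribution:
    """Repeat ``train_once`` with fresh splits/initializations, plus the null."""
    rng = np.random.default_rng(rng)
    acc = np.array([train_once(ds, model, protocol, rng) for _ in range(protocol.n_repeats)])
    null = (
        np.array(
            [train_once(ds, model, protocol, rng, shuffle_labels=True) for _ in range(protocol.n_repeats)]
        )
        if with_null
        else None
    )
    return AccuracyDistribution(
        accuracies=acc,
        null_accuracies=null,
        session=ds.session,
        nucleus=ds.nucleus,
        classifier=type(model).__name__,
        band=band,
        quantile_levels=protocol.quantiles,
    )


def band_ablation(
    ds: SpectrogramDataset,
    model: BaseEstimator,
    protocol: TrainingProtocol = TrainingProtocol(),
    bands: Sequence[tuple[float, float]] = ((10.0, 17.0), (17.0, 25.0), (10.0, 25.0)),
    rng: np.random.Generator | int | None = None,
    include_full: bool = True,
    with_null: bool = False,
) -> dict[str, AccuracyDistribution]:
    """Re-train on spectrograms restricted to frequency bands.

    Returns a mapping band-name → accuracy distribution; ``"full"`` is the
    unrestricted model for comparison.
    """
    rng = np.random.default_rng(rng)
    out: dict[str, AccuracyDistribution] = {}
    if include_full:
        out["full"] = accuracy_distribution(ds, model, protocol, rng, with_null=with_null)
    for lo, hi in bands:
        Xb, fb = restrict_rows(ds.X, ds.freqs, lo, hi)
        sub = replace_dataset(ds, Xb, fb)
        name = f"{lo:g}-{hi:g}"
        out[name] = accuracy_distribution(sub, model, protocol, rng, with_null=with_null, band=name)
    return out


def replace_dataset(ds: SpectrogramDataset, X: np.ndarray, freqs: np.ndarray) -> SpectrogramDataset:
    return SpectrogramDataset(X=X, y=ds.y, freqs=freqs, session=ds.session, nucleus=ds.nucleus)


def cross_nucleus_test(
    distributions: dict[str, np.ndarray | AccuracyDistribution],
    channel_counts: dict[str, int] | None = None,
) -> dict:
    """Kruskal–Wallis H-test of accuracy across nuclei.

    Optionally also reports the Spearman rank correlation between each
    nucleus' median accuracy and its recording-contact count.
    """
    if len(distributions) < 2:
        raise ValueError("need accuracy samples from at least 2 nuclei")
    samples = {
        k: (v.accuracies if isinstance(v, AccuracyDistribution) else np.asarray(v, float))
        for k, v in distributions.items()
    }
    groups = list(samples.values())
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    report = {"H": float(h), "p": float(p), "n_groups": len(groups)}
    if channel_counts is not None:
        common = [k for k in samples if k in channel_counts]
        med = [float(np.median(samples[k])) for k in common]
        cnt = [channel_counts[k] for k in common]
        if len(set(cnt)) > 1 and len(set(med)) > 1:
            rho, rp = stats.spearmanr(cnt, med)
            report["spearman_rho"] = float(rho)
            report["spearman_p"] = float(rp)
        else:
            report["spearman_rho"] = None
            report["spearman_p"] = None
    return report
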