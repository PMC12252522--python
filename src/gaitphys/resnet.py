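"""1-D residual network benchmark for raw gait waveforms.

A compact numpy implementation (manual backpropagation, Adam) of the
standard residual network for time-series classification: three residual
blocks of three convolutions each (kernel sizes 8/5/3), so 11 layers in
total — 9 convolutional, then global average pooling over time, then a
softmax classifier.  Identity shortcuts connect block input to block
output, with a 1x1 projection where the channel count changes (projection
shortcuts are conventionally not counted towards depth).

The network consumes cycles resampled to a fixed length, stacked as
channels (one channel per series), and provides the reference score the
per-cycle entropy/irreversibility features are compared against.  Scoring
uses subject-grouped 5-fold cross-validation with balanced groups —
leave-one-out retraining of a deep model is deliberately avoided — and
aggregates a subject's cycle predictions by majority vote, exactly as the
feature-based protocol does.

Desk-scale defaults (16/32/32 filters, input length 100, few epochs) keep
training to seconds per fold on one core; this is a reference benchmark,
not a clinical-scale model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Cohort, resample_cycle
from .classify import ScoreSummary, TaskSpec, _summarise

__all__ = ["ResNetSpec", "ResNet1D", "build_model", "resnet_score"]


@dataclass(frozen=True)
class ResNetSpec:
    """Architecture and training hyper-parameters."""

    input_length: int = 100
    n_channels: int = 1
    n_classes: int = 2
    n_filters: tuple[int, int, int] = (16, 32, 32)
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_length < 8:
            raise ValueError("input_length must be >= 8")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if min(self.n_filters) < 1 or min(self.kernel_sizes) < 1:
            raise ValueError("invalid filter/kernel configuration")


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-d convolution. x: (B, C, L); W: (F, C, k)."""
    k = W.shape[2]
    pl, pr = (k - 1) // 2, k // 2
    xpad = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    L = x.shape[2]
    out = np.zeros((x.shape[0], W.shape[0], L))
    for j in range(k):
        out += np.einsum("bcl,fc->bfl", xpad[:, :, j : j + L], W[:, :, j])
    return out + b[None, :, None], xpad


def _conv_backward(dout: np.ndarray, xpad: np.ndarray, W: np.ndarray):
    k = W.shape[2]
    L = dout.shape[2]
    dW = np.empty_like(W)
    for j in range(k):
        dW[:, :, j] = np.einsum("bfl,bcl->fc", dout, xpad[:, :, j : j + L])
    db = dout.sum(axis=(0, 2))
    dxpad = np.zeros_like(xpad)
    for j in range(k):
        dxpad[:, :, j : j + L] += np.einsum("bfl,fc->bcl", dout, W[:, :, j])
    pl = (k - 1) // 2
    dx = dxpad[:, :, pl : pl + L]
    return dx, dW, db


class ResNet1D:
    """The 11-layer residual classifier (9 conv + GAP + softmax)."""

    def __init__(self, spec: ResNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = spec.n_channels
        for bi, (f, _) in enumerate(zip(spec.n_filters, [0, 0, 0])):
            for ci, k in enumerate(spec.kernel_sizes):
                cin = c_in if ci == 0 else f
                fan_in = cin * k
                self.params[f"W{bi}{ci}"] = rng.normal(
                    0, np.sqrt(2.0 / fan_in), size=(f, cin, k)
                )
                self.params[f"b{bi}{ci}"] = np.zeros(f)
            if c_in != f:
                self.params[f"Ws{bi}"] = rng.normal(
                    0, np.sqrt(2.0 / c_in), size=(f, c_in, 1)
                )
                self.params[f"bs{bi}"] = np.zeros(f)
            c_in = f
        self.params["Wfc"] = rng.normal(
            0, np.sqrt(1.0 / c_in), size=(c_in, spec.n_classes)
        )
        self.params["bfc"] = np.zeros(spec.n_classes)

    # -- architecture census ------------------------------------------------
    def layer_census(self) -> dict[str, int]:
        """Counts of depth-contributing layers (shortcuts excluded)."""
        n_conv = sum(1 for name in self.params if name.startswith("W")
                     and name not in ("Wfc",) and not name.startswith("Ws"))
        return {"conv": n_conv, "global_average_pooling": 1, "softmax": 1}

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        """Return class probabilities (B, n_classes) and a backprop cache."""
        spec = self.spec
        cache = {"block_in": [], "xpads": [], "acts": [], "shortcut": []}
        h = x
        for bi in range(3):
            block_in = h
            cache["block_in"].append(block_in)
            xpads, acts = [], []
            z = block_in
            for ci in range(3):
                z, xpad = _conv_forward(
                    z, self.params[f"W{bi}{ci}"], self.params[f"b{bi}{ci}"]
                )
                xpads.append(xpad)
                if ci < 2:
                    acts.append(z > 0)
                    z = np.maximum(z, 0)
            if f"Ws{bi}" in self.params:
                sc, sc_pad = _conv_forward(
                    block_in, self.params[f"Ws{bi}"], self.params[f"bs{bi}"]
                )
                cache["shortcut"].append(sc_pad)
            else:
                sc = block_in
                cache["shortcut"].append(None)
            z = z + sc
            acts.append(z > 0)
            h = np.maximum(z, 0)
            cache["xpads"].append(xpads)
            cache["acts"].append(acts)
        g = h.mean(axis=2)  # global average pooling
        logits = g @ self.params["Wfc"] + self.params["bfc"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache["gap_in_len"] = h.shape[2]
        cache["gap"] = g
        cache["probs"] = probs
        return probs, cache

    def backward(self, cache, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        B = y_onehot.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / B
        grads["Wfc"] = cache["gap"].T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        dg = dlogits @ self.params["Wfc"].T
        L = cache["gap_in_len"]
        dh = np.repeat(dg[:, :, None], L, axis=2) / L
        for bi in reversed(range(3)):
            acts = cache["acts"][bi]
            xpads = cache["xpads"][bi]
            dz = dh * acts[2]  # through the post-add ReLU
            dsc = dz
            d = dz
            for ci in reversed(range(3)):
                if ci < 2:
                    d = d * acts[ci]
                d, dW, db = _conv_backward(d, xpads[ci], self.params[f"W{bi}{ci}"])
                grads[f"W{bi}{ci}"] = dW
                grads[f"b{bi}{ci}"] = db
            if cache["shortcut"][bi] is not None:
                dsc_in, dWs, dbs = _conv_backward(
                    dsc, cache["shortcut"][bi], self.params[f"Ws{bi}"]
                )
                grads[f"Ws{bi}"] = dWs
                grads[f"bs{bi}"] = dbs
                dh = d + dsc_in
            else:
                dh = d + dsc
        return grads

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        """Adam on mean cross-entropy; returns the final-epoch mean loss."""
        spec = self.spec
        mom = {k: np.zeros_like(v) for k, v in self.params.items()}
        vel = {k: np.zeros_like(v) for k, v in self.params.items()}
        onehot = np.eye(spec.n_classes)[y]
        n = X.shape[0]
        step = 0
        last_loss = np.inf
        b1, b2, eps = 0.9, 0.999, 1e-8
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            losses = []
            for i0 in range(0, n, spec.batch_size):
                idx = order[i0 : i0 + spec.batch_size]
                probs, cache = self.forward(X[idx])
                losses.append(
                    -np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12))
                )
                grads = self.backward(cache, onehot[idx])
                step += 1
                for kname, g in grads.items():
                    mom[kname] = b1 * mom[kname] + (1 - b1) * g
                    vel[kname] = b2 * vel[kname] + (1 - b2) * g * g
                    mhat = mom[kname] / (1 - b1**step)
                    vhat = vel[kname] / (1 - b2**step)
                    self.params[kname] -= (
                        spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    )
            last_loss = float(np.mean(losses))
        return last_loss

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(X)
        return probs


def build_model(spec: ResNetSpec) -> ResNet1D:
    """Construct an initialised (untrained) network from its spec."""
    return ResNet1D(spec)


def _cohort_tensor(cohort: Cohort, series: list[str], length: int):
    """Stack cycles as (rows, channels, length) with subject bookkeeping."""
    by_key: dict[tuple, dict[str, np.ndarray]] = {}
    for cyc in cohort.cycles:
        if cyc.series_name not in series:
            continue
        key = (cyc.subject_id, cyc.side, cyc.cycle_index)
        by_key.setdefault(key, {})[cyc.series_name] = resample_cycle(
            cyc, length
        ).samples
    keys = sorted(k for k, v in by_key.items() if len(v) == len(series))
    X = np.stack(
        [np.stack([by_key[k][s] for s in series]) for k in keys]
    )
    subjects = np.array([k[0] for k in keys])
    return X, subjects


def resnet_score(
    cohort: Cohort,
    task: TaskSpec,
    spec: ResNetSpec | None = None,
    series_set: str | list[str] = "all",
    n_realisations: int = 3,
    n_folds: int = 5,
) -> ScoreSummary:
    """Subject-level accuracy of the residual network on a group pair.

    Per realisation: balance the groups by subject subsampling, split the
    subjects into ``n_folds`` grouped folds, train one network per fold
    and classify each held-out subject by majority vote over its cycles.
    Channels are z-scored with training-fold statistics.
    """
    from .synthetic import SERIES_FAMILIES

    if isinstance(series_set, str):
        series = [s for s in SERIES_FAMILIES[series_set]
                  if s in cohort.series_names]
    else:
        series = list(series_set)
    if not series:
        raise ValueError("no series selected")
    if spec is None:
        # adopt the cohort's native cycle length so resolution sweeps see
        # the resampled series as-is
        native = len(cohort.cycles[0])
        spec = ResNetSpec(input_length=native, n_channels=len(series))
    if spec.n_channels != len(series):
        raise ValueError(
            f"spec.n_channels={spec.n_channels} but {len(series)} series selected"
        )
    X, subjects = _cohort_tensor(cohort, series, spec.input_length)
    group_of = {s.subject_id: s.group for s in cohort.subjects.values()}
    labels = {task.group_a: 0, task.group_b: 1}

    rng_master = np.random.default_rng(np.random.SeedSequence(task.seed,
                                                              spawn_key=(99,)))
    scores, seeds = [], []
    for r in range(n_realisations):
        rng = np.random.default_rng(rng_master.integers(0, 2**31 - 1))
        a = sorted(s for s, g in group_of.items() if g == task.group_a)
        b = sorted(s for s, g in group_of.items() if g == task.group_b)
        n = min(len(a), len(b))
        if len(a) > n:
            a = sorted(rng.choice(a, size=n, replace=False))
        if len(b) > n:
            b = sorted(rng.choice(b, size=n, replace=False))
        selected = np.array(a + b)
        perm = rng.permutation(len(selected))
        folds = np.array_split(selected[perm], n_folds)
        correct, total = 0, 0
        for fold in folds:
            if len(fold) == 0:
                continue
            test_mask = np.isin(subjects, fold)
            train_mask = np.isin(subjects, selected) & ~test_mask
            assert not np.any(train_mask & test_mask)
            y_tr = np.array([labels[group_of[s]] for s in subjects[train_mask]])
            if y_tr.min() == y_tr.max():
                continue
            mu = X[train_mask].mean(axis=(0, 2), keepdims=True)
            sd = X[train_mask].std(axis=(0, 2), keepdims=True) + 1e-8
            model = ResNet1D(
                ResNetSpec(**{**spec.__dict__,
                              "seed": int(rng.integers(0, 2**31 - 1))})
            )
            loss = model.fit((X[train_mask] - mu) / sd, y_tr, rng)
            if not np.isfinite(loss):  # rare blow-up: retry once, new seed
                model = ResNet1D(
                    ResNetSpec(**{**spec.__dict__,
                                  "seed": int(rng.integers(0, 2**31 - 1))})
                )
                model.fit((X[train_mask] - mu) / sd, y_tr, rng)
            proba = model.predict_proba((X[test_mask] - mu) / sd)
            for s in fold:
                rows = subjects[test_mask] == s
                votes = (proba[rows, 1] > 0.5).mean()
                pred = 1 if votes > 0.5 else 0 if votes < 0.5 else int(
                    proba[rows, 1].mean() > 0.5
                )
                correct += int(pred == labels[group_of[s]])
                total += 1
        scores.append(correct / total)
        seeds.append(r)
    return _summarise(scores, seeds)
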