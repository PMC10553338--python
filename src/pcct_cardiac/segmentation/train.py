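"""Training, loss, augmentation, threshold selection and evaluation.

The training loss is the sum of binary cross entropy and one minus the soft
Dice coefficient (smoothing constant 1).  Dice is differentiable on
probabilities during training; evaluation binarizes the prediction at the
selected threshold.  The decision threshold is the grid point (0.01..0.99,
step 0.01) minimizing |precision - recall| on the training set, ties going
to the lowest threshold.  Training uses Adam (default learning rate 5e-4)
with the plateau rule: the learning rate drops by 10x after five consecutive
epochs without validation improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .data import SegmentationSample, normalize_image
from .unet import UNet2D, UNetConfig

__all__ = ["composite_loss", "binary_cross_entropy", "soft_dice", "augment",
           "TrainReport", "train", "select_threshold", "evaluate",
           "predict", "run_input_kind_comparison"]

EPS = 1e-7
THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


def _clamp_probs(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        warnings.warn("probabilities clamped to (eps, 1 - eps)")
    return np.clip(p, EPS, 1 - EPS)


def binary_cross_entropy(pred, truth) -> float:
    p = _clamp_probs(pred)
    t = np.asarray(truth, dtype=float)
    return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))


def soft_dice(pred, truth, smooth: float = 1.0) -> float:
    """Differentiable Dice on probabilities, mean over leading batch axis."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.ndim == 2:
        p, t = p[None], t[None]
    b = p.shape[0]
    p2, t2 = p.reshape(b, -1), t.reshape(b, -1)
    num = 2 * (p2 * t2).sum(axis=1) + smooth
    den = p2.sum(axis=1) + t2.sum(axis=1) + smooth
    return float(np.mean(num / den))


def composite_loss(pred, truth, return_grad: bool = False):
    """BCE + (1 - soft Dice); optionally the gradient w.r.t. probabilities."""
    p = _clamp_probs(pred)
    t = np.asarray(truth, dtype=float)
    loss = binary_cross_entropy(p, t) + (1.0 - soft_dice(p, t))
    if not return_grad:
        return loss
    pb = p if p.ndim > 2 else p[None]
    tb = t if t.ndim > 2 else t[None]
    b = pb.shape[0]
    n = pb[0].size
    g_bce = (pb - tb) / (pb * (1 - pb)) / (b * n)
    p2, t2 = pb.reshape(b, -1), tb.reshape(b, -1)
    num = 2 * (p2 * t2).sum(axis=1) + 1.0
    den = p2.sum(axis=1) + t2.sum(axis=1) + 1.0
    g_dice = -(2 * t2 * den[:, None] - num[:, None]) / den[:, None] ** 2 / b
    grad = (g_bce.reshape(b, -1) + g_dice).reshape(pb.shape)
    return loss, grad.reshape(np.asarray(pred).shape)


def augment(sample: SegmentationSample, seed: int,
            max_shift: float = 0.15, max_zoom: float = 0.15,
            max_rotate_deg: float = 20.0) -> SegmentationSample:
    """Random intensity shift, zoom and rotation; mask follows the image.

    The mask uses nearest-neighbor interpolation; the image is re-normalized
    afterwards.  Zero-magnitude settings return the sample unchanged.
    """
    if max_shift == 0 and max_zoom == 0 and max_rotate_deg == 0:
        return sample
    rng = np.random.default_rng(seed)
    img = sample.image.astype(float).copy()
    mask = sample.mask.astype(float)

    angle = rng.uniform(-max_rotate_deg, max_rotate_deg)
    if angle:
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="nearest")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="nearest")
    zoom = 1.0 + rng.uniform(-max_zoom, max_zoom)
    if zoom != 1.0:
        img = _zoom_same(img, zoom, order=1)
        mask = _zoom_same(mask, zoom, order=0)
    img = img + rng.uniform(-max_shift, max_shift) * img.std()
    return SegmentationSample(normalize_image(img), mask >= 0.5,
                              sample.subject_id, sample.phase_label,
                              sample.input_kind)


def _zoom_same(img, zoom, order):
    """Zoom about the center, cropping/padding back to the original shape."""
    out = ndimage.zoom(img, zoom, order=order, mode="nearest")
    n = img.shape[0]
    m = out.shape[0]
    if m >= n:
        a = (m - n) // 2
        return out[a:a + n, a:a + n]
    pad = (n - m) // 2
    return np.pad(out, ((pad, n - m - pad), (pad, n - m - pad)),
                  mode="edge")


@dataclass
class TrainReport:
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    lr_events: list = field(default_factory=list)  # epochs where LR dropped
    threshold: float = 0.5
    split_sizes: tuple = ()
    seed: int = 0
    epochs: int = 0


def _stack_batch(samples):
    x = np.stack([s.image for s in samples])[:, None]
    t = np.stack([s.mask for s in samples])[:, None].astype(float)
    return x, t


def predict(model: UNet2D, samples, batch: int = 16) -> np.ndarray:
    probs = []
    for i in range(0, len(samples), batch):
        x, _ = _stack_batch(samples[i:i + batch])
        probs.append(model.forward(x, train=False))
    return np.concatenate(probs)[:, 0]


def _mean_loss(model, samples, batch=16):
    total, count = 0.0, 0
    for i in range(0, len(samples), batch):
        x, t = _stack_batch(samples[i:i + batch])
        p = model.forward(x, train=False)
        total += composite_loss(p, t) * len(x)
        count += len(x)
    return total / count


def train(model_config: UNetConfig | None, train_set, val_set, seed: int = 0,
          epochs: int = 14, max_epochs: int = 50, lr: float = 5e-4,
          batch_size: int = 4, plateau_patience: int = 5,
          plateau_factor: float = 0.1, use_augment: bool = True,
          verbose: bool = False):
    """Train a U-Net; returns (model with best-validation weights, report).

    Deterministic given ``seed`` (and a fixed BLAS thread count).  The
    learning rate decays by ``plateau_factor`` after ``plateau_patience``
    consecutive epochs without a validation-loss improvement.
    """
    from .nn import Adam

    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    epochs = min(epochs, max_epochs)
    size = train_set[0].image.shape[0]
    config = model_config or UNetConfig(image_size=size)
    rng = np.random.default_rng(seed)
    model = UNet2D(config, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(model.params, lr=lr)

    report = TrainReport(seed=seed,
                         split_sizes=(len(train_set), len(val_set)))
    best_val = np.inf
    best_state = model.state_dict()
    best_thr_probs = None
    plateau = 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train_set))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), batch_size):
            batch = [train_set[j] for j in order[i:i + batch_size]]
            if use_augment:
                batch = [augment(s, int(rng.integers(2**31 - 1)))
                         for s in batch]
            x, t = _stack_batch(batch)
            p = model.forward(x, train=True)
            loss, grad = composite_loss(p, t, return_grad=True)
            grads = model.backward(grad)
            opt.step(grads)
            ep_loss += loss
            nb += 1
        val_loss = _mean_loss(model, val_set)
        report.train_losses.append(ep_loss / nb)
        report.val_losses.append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {ep_loss / nb:.4f} val {val_loss:.4f}"
                  f" lr {opt.lr:.2e}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            plateau = 0
        else:
            plateau += 1
            if plateau >= plateau_patience:
                opt.lr *= plateau_factor
                report.lr_events.append(epoch)
                plateau = 0
    report.epochs = len(report.train_losses)
    model.load_state_dict(best_state)

    probs = predict(model, train_set)
    masks = np.stack([s.mask for s in train_set]).astype(bool)
    report.threshold = select_threshold(probs, masks)
    return model, report


def select_threshold(pred_probs, truth_masks,
                     grid=THRESHOLD_GRID) -> float:
    """Threshold minimizing |precision - recall| on the given predictions.

    Exhaustive scan over the fixed grid; undefined precision (no positive
    predictions) counts as 0; ties break to the lowest threshold.
    """
    p = np.asarray(pred_probs).ravel()
    t = np.asarray(truth_masks).ravel().astype(bool)
    best_t, best_gap = None, np.inf
    n_pos = t.sum()
    for thr in grid:
        pred = p >= thr
        tp = np.count_nonzero(pred & t)
        npred = np.count_nonzero(pred)
        if npred == 0:  # degenerate: no positive predictions at all
            continue
        precision = tp / npred
        recall = tp / n_pos if n_pos else 0.0
        gap = abs(precision - recall)
        if gap < best_gap - 1e-15:
            best_gap = gap
            best_t = float(thr)
    return best_t if best_t is not None else float(grid[0])


def evaluate(pred_probs, truth_mask, threshold: float, auc_subsample: int = 10**6,
             seed: int = 0) -> dict:
    """Dice, precision, recall on the binarized prediction, plus voxel AUC."""
    p = np.asarray(pred_probs).ravel()
    t = np.asarray(truth_mask).ravel().astype(bool)
    pred = p >= threshold
    tp = np.count_nonzero(pred & t)
    fp = np.count_nonzero(pred & ~t)
    fn = np.count_nonzero(~pred & t)
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if len(p) > auc_subsample:
        idx = np.random.default_rng(seed).choice(len(p), auc_subsample,
                                                 replace=False)
        p_auc, t_auc = p[idx], t[idx]
    else:
        p_auc, t_auc = p, t
    auc = roc_auc_score(t_auc, p_auc) if 0 < t_auc.sum() < len(t_auc) else np.nan
    return {"dice": float(dice), "precision": float(precision),
            "recall": float(recall), "auc": float(auc)}


def run_input_kind_comparison(n_samples: int = 200, size: int = 64,
                              seed: int = 0, epochs: int = 20,
                              **train_kwargs) -> dict:
    """Train two identically structured networks, one per input kind.

    Mirrors the CT-image vs iodine-map comparison: same architecture and
    schedule, labels always the CT-derived masks.  Returns per-kind test
    metrics and reports.
    """
    from .data import make_lv_dataset, split_dataset

    results = {}
    for kind in ("ct", "iodine"):
        data = make_lv_dataset(n_samples, size, input_kind=kind, seed=seed)
        tr, va, te = split_dataset(data, seed=seed)
        model, report = train(None, tr, va, seed=seed, epochs=epochs,
                              **train_kwargs)
        probs = predict(model, te)
        masks = np.stack([s.mask for s in te]).astype(bool)
        metrics = evaluate(probs, masks, report.threshold)
        results[kind] = {"metrics": metrics, "report": report,
                         "model": model}
    return results
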