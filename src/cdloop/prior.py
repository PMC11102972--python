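"""Pre-trained conditional mean estimator: a LeNet5-style window classifier.

The network maps a 2w x 2w contact-map window to a two-class probability
vector (background, loop).  Its output is the *prior* that conditions the
diffusion model: it shifts the forward-process endpoint away from zero and
enters the reverse-process posterior mean.

Windows are ``log1p``-transformed before entering the network; contact
counts are heavy-tailed and the compression stabilises training.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["PriorNet", "build_prior_net", "train_prior", "predict_prior", "prepare_windows"]


def prepare_windows(x: np.ndarray) -> np.ndarray:
    """(N, 2w, 2w) raw windows -> (N, 1, 2w, 2w) log1p float32 tensor."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    return np.log1p(x)[:, None, :, :]


class PriorNet:
    """Two conv blocks (conv-BN-ReLU-avgpool) + three dense layers."""

    def __init__(self, w: int = 14, channels: tuple[int, int] = (6, 16),
                 widths: tuple[int, int] = (120, 84), seed: int = 0, dtype=np.float32):
        self.w = w
        self.channels = channels
        self.widths = widths
        self.seed = seed
        rng = np.random.default_rng(seed)
        side = 2 * w
        c1, c2 = channels
        # conv1 pads by 2 so the classic 28 -> 28 -> 14 -> 10 -> 5 LeNet
        # arithmetic holds at the default window size
        s = side  # after conv1 (pad 2, k 5): unchanged
        if s % 2:
            raise ValueError(f"pooling arithmetic fails for window side {side}")
        s //= 2
        s = s - 4  # conv2, k=5, no pad
        if s <= 0 or s % 2:
            raise ValueError(f"pooling arithmetic fails for window side {side}")
        s //= 2
        flat = c2 * s * s
        h1, h2 = widths
        self.net = nn.Sequential(
            nn.Conv2d(1, c1, 5, rng, pad=2, dtype=dtype),
            nn.BatchNorm(c1, dtype=dtype),
            nn.ReLU(),
            nn.AvgPool2d(2),
            nn.Conv2d(c1, c2, 5, rng, pad=0, dtype=dtype),
            nn.BatchNorm(c2, dtype=dtype),
            nn.ReLU(),
            nn.AvgPool2d(2),
            nn.Flatten(),
            nn.Dense(flat, h1, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dense(h1, h2, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dense(h2, 2, rng, dtype=dtype),
        )

    def params(self):
        return self.net.params()

    def logits(self, x4d: np.ndarray, train: bool = False) -> np.ndarray:
        out = x4d
        for layer in self.net.layers:
            if isinstance(layer, nn.BatchNorm):
                # channel-wise batch norm over (N, C, H, W)
                n, c, h, w = out.shape
                flat = out.transpose(0, 2, 3, 1).reshape(-1, c)
                flat = layer.forward(flat, train=train)
                out = flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
            else:
                out = layer.forward(out, train=train)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.net.layers):
            if isinstance(layer, nn.BatchNorm):
                n, c, h, w = self._bn_shapes.pop()
                flat = grad.transpose(0, 2, 3, 1).reshape(-1, c)
                flat = layer.backward(flat)
                grad = flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
            else:
                grad = layer.backward(grad)
        return grad

    def _forward_backward(self, x4d, labels):
        """One training forward/backward pass; returns (loss, accuracy)."""
        self._bn_shapes = []
        out = x4d
        for layer in self.net.layers:
            if isinstance(layer, nn.BatchNorm):
                n, c, h, w = out.shape
                self._bn_shapes.append((n, c, h, w))
                flat = out.transpose(0, 2, 3, 1).reshape(-1, c)
                flat = layer.forward(flat, train=True)
                out = flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
            else:
                out = layer.forward(out, train=True)
        loss, grad = nn.cross_entropy(out, labels)
        acc = float(np.mean(out.argmax(axis=1) == labels))
        self.backward(grad)
        return loss, acc

    def state_dict(self):
        d = self.net.state_dict()
        d["_meta"] = np.array([self.w, *self.channels, *self.widths, self.seed])
        return d

    def save(self, path):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path) -> "PriorNet":
        with np.load(path) as data:
            meta = data["_meta"]
            net = cls(w=int(meta[0]), channels=(int(meta[1]), int(meta[2])),
                      widths=(int(meta[3]), int(meta[4])), seed=int(meta[5]))
            net.net.load_state_dict({k: data[k] for k in data.files if k != "_meta"})
        return net


def build_prior_net(w: int = 14, channels=(6, 16), widths=(120, 84), seed: int = 0) -> PriorNet:
    return PriorNet(w=w, channels=channels, widths=widths, seed=seed)


def train_prior(net: PriorNet, train_x: np.ndarray, train_y: np.ndarray,
                val_x: np.ndarray | None = None, val_y: np.ndarray | None = None,
                lr: float = 1e-3, batch: int = 128, epochs: int = 50,
                seed: int = 0) -> tuple[PriorNet, list[dict]]:
    """Train with cross-entropy + Adam; returns the best-on-validation
    parameters (best-on-train when no validation set is given) and a
    per-epoch history of losses and accuracies."""
    if len(train_x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    x = prepare_windows(train_x)
    y = np.asarray(train_y, dtype=np.int64)
    has_val = val_x is not None and len(val_x) > 0
    opt = nn.Adam(net.params(), lr=lr)
    history: list[dict] = []
    best_metric = -np.inf
    best_state = None
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        losses, accs = [], []
        for k in range(0, len(x), batch):
            idx = order[k:k + batch]
            opt.zero_grad()
            loss, acc = net._forward_backward(x[idx], y[idx])
            opt.step()
            losses.append(loss)
            accs.append(acc)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_acc": float(np.mean(accs))}
        if has_val:
            vp = predict_prior(net, val_x)
            vacc = float(np.mean(vp.argmax(axis=1) == np.asarray(val_y)))
            rec["val_acc"] = vacc
            metric = vacc
        else:
            metric = rec["train_acc"]
        history.append(rec)
        if metric >= best_metric:
            best_metric = metric
            best_state = {k: v.copy() for k, v in net.net.state_dict().items()}
    if best_state is not None:
        net.net.load_state_dict(best_state)
    return net, history


def predict_prior(net: PriorNet, windows: np.ndarray) -> np.ndarray:
    """Class-probability vectors f(x), shape (N, 2); rows sum to one.

    Column 0 is the background class, column 1 the loop class.
    """
    x = prepare_windows(windows)
    logits = net.logits(x, train=False)
    return nn.softmax(logits.astype(np.float64))
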