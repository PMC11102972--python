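"""Prior-conditioned classification diffusion over two-class label vectors.

The forward process interpolates a one-hot label ``y0`` toward the prior
probability vector ``f = f(x)`` produced by the pre-trained window
classifier, instead of toward zero as in a standard DDPM:

    q(y_t | y0, f) = N( sqrt(abar_t) y0 + (1 - sqrt(abar_t)) f, (1 - abar_t) I )

so the endpoint is ``N(f, I)``.  The reverse posterior mean is a convex-like
combination ``gamma0 y0 + gamma1 y_t + gamma2 f`` whose coefficients sum to
one exactly; setting ``f = 0`` recovers the standard DDPM formulas.  An
epsilon-prediction network conditioned on the window, the noisy label, the
prior and the timestep is trained with the simplified (MSE) ELBO surrogate;
classification repeats the reverse chain ``n_draws`` times and summarises
the draws as a mean score with a normal 95% CI and a one-sample two-tailed
t-test against 0.5.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import nn
from .prior import PriorNet, predict_prior, prepare_windows

__all__ = [
    "DiffusionSchedule",
    "make_schedule",
    "forward_sample",
    "posterior_step",
    "EpsNet",
    "train_diffusion",
    "reverse_classify",
    "reverse_classify_batch",
    "ScoredPrediction",
]


@dataclasses.dataclass
class DiffusionSchedule:
    """Per-timestep noise schedule and posterior coefficients.

    Arrays are indexed so that entry ``t-1`` belongs to timestep ``t``
    (t = 1..T).  The convention ``abar_0 = 1`` makes ``beta_tilde[1] = 0``,
    so the final reverse step is deterministic.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    beta_tilde: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    gamma2: np.ndarray

    def at(self, t: int | np.ndarray, arr: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        if np.any(t < 1) or np.any(t > self.T):
            raise ValueError(f"timestep {t} outside 1..{self.T}")
        return arr[t - 1]


def make_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02,
                  kind: str = "linear") -> DiffusionSchedule:
    """Build a linear beta schedule with its posterior-mean coefficients.

    gamma0 = beta_t sqrt(abar_{t-1}) / (1 - abar_t)
    gamma1 = (1 - abar_{t-1}) sqrt(alpha_t) / (1 - abar_t)
    gamma2 = 1 + (sqrt(abar_t) - 1)(sqrt(alpha_t) + sqrt(abar_{t-1})) / (1 - abar_t)

    and gamma0 + gamma1 + gamma2 = 1 identically.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    if not (0 < beta_start < 1 and 0 < beta_end < 1):
        raise ValueError("beta bounds must be in (0, 1)")
    beta = np.linspace(beta_start, beta_end, T, dtype=np.float64)
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    alpha_bar_prev = np.concatenate([[1.0], alpha_bar[:-1]])
    one_m = 1.0 - alpha_bar
    beta_tilde = (1.0 - alpha_bar_prev) / one_m * beta
    sqrt_a = np.sqrt(alpha)
    sqrt_ab = np.sqrt(alpha_bar)
    sqrt_ab_prev = np.sqrt(alpha_bar_prev)
    gamma0 = beta * sqrt_ab_prev / one_m
    gamma1 = (1.0 - alpha_bar_prev) * sqrt_a / one_m
    gamma2 = 1.0 + (sqrt_ab - 1.0) * (sqrt_a + sqrt_ab_prev) / one_m
    return DiffusionSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar,
                             beta_tilde=beta_tilde, gamma0=gamma0, gamma1=gamma1,
                             gamma2=gamma2)


def forward_sample(y0: np.ndarray, f: np.ndarray, t, sched: DiffusionSchedule,
                   noise: np.ndarray) -> np.ndarray:
    """Closed-form forward draw:
    y_t = sqrt(abar_t) y0 + (1 - sqrt(abar_t)) f + sqrt(1 - abar_t) eps."""
    y0 = np.asarray(y0, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if y0.shape != f.shape or y0.shape != noise.shape:
        raise ValueError("y0, f and noise must share a shape")
    ab = sched.at(t, sched.alpha_bar)
    sq = np.sqrt(ab)
    if np.ndim(sq) and y0.ndim > 1:
        sq = np.reshape(sq, (-1,) + (1,) * (y0.ndim - 1))
        ab = np.reshape(ab, (-1,) + (1,) * (y0.ndim - 1))
    return sq * y0 + (1.0 - sq) * f + np.sqrt(1.0 - ab) * noise


def posterior_step(y_t: np.ndarray, y0_hat: np.ndarray, f: np.ndarray, t: int,
                   sched: DiffusionSchedule, noise: np.ndarray | None = None) -> np.ndarray:
    """One reverse step: mean gamma0 y0_hat + gamma1 y_t + gamma2 f plus
    sqrt(beta_tilde_t) noise; at t = 1 the noise term vanishes."""
    y_t = np.asarray(y_t, dtype=np.float64)
    y0_hat = np.asarray(y0_hat, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if y_t.shape != y0_hat.shape or y_t.shape != f.shape:
        raise ValueError("y_t, y0_hat and f must share a shape")
    g0 = sched.at(t, sched.gamma0)
    g1 = sched.at(t, sched.gamma1)
    g2 = sched.at(t, sched.gamma2)
    mu = g0 * y0_hat + g1 * y_t + g2 * f
    bt = sched.at(t, sched.beta_tilde)
    if noise is None or bt == 0:
        return mu
    noise = np.asarray(noise, dtype=np.float64)
    return mu + np.sqrt(bt) * noise


# ---------------------------------------------------------------------------
# epsilon-prediction network

class EpsNet:
    """Noise predictor eps(x, y_t, f, t).

    Image branch: three dense layers on the flattened window to a ``width``
    embedding.  Response branch: a dense layer on the concatenation
    ``y_t (+) f``, Hadamard-multiplied by a learned timestep embedding.  The
    two branches fuse by Hadamard product; two further dense layers follow,
    each preceded by a timestep-embedding Hadamard product; batch norm and
    Softplus sit after every hidden dense layer.
    """

    def __init__(self, w: int = 14, width: int = 2048, t_dim: int = 64,
                 seed: int = 0, dtype=np.float32):
        self.w, self.width, self.t_dim, self.seed = w, width, t_dim, seed
        rng = np.random.default_rng(seed)
        d_in = (2 * w) ** 2
        wd = width
        mk = lambda a, b: nn.Dense(a, b, rng, dtype=dtype)
        self.g1x, self.bn1x, self.a1x = mk(d_in, wd), nn.BatchNorm(wd, dtype=dtype), nn.Softplus()
        self.g2x, self.bn2x, self.a2x = mk(wd, wd), nn.BatchNorm(wd, dtype=dtype), nn.Softplus()
        self.g3x, self.bn3x = mk(wd, wd), nn.BatchNorm(wd, dtype=dtype)
        self.g1y, self.bn1y, self.a1y = mk(4, wd), nn.BatchNorm(wd, dtype=dtype), nn.Softplus()
        self.g1b = mk(t_dim, wd)
        self.g2a, self.bn2a, self.a2a = mk(wd, wd), nn.BatchNorm(wd, dtype=dtype), nn.Softplus()
        self.g2b = mk(t_dim, wd)
        self.g3a, self.bn3a, self.a3a = mk(wd, wd), nn.BatchNorm(wd, dtype=dtype), nn.Softplus()
        self.g3b = mk(t_dim, wd)
        self.g4 = mk(wd, 2)
        self._blocks = [self.g1x, self.bn1x, self.a1x, self.g2x, self.bn2x, self.a2x,
                        self.g3x, self.bn3x, self.g1y, self.bn1y, self.a1y, self.g1b,
                        self.g2a, self.bn2a, self.a2a, self.g2b,
                        self.g3a, self.bn3a, self.a3a, self.g3b, self.g4]

    def params(self):
        return [p for b in self._blocks for p in b.params()]

    def t_embed(self, t: np.ndarray) -> np.ndarray:
        return nn.sinusoidal_embedding(t, self.t_dim).astype(np.float32)

    def image_embedding(self, x_flat: np.ndarray, train: bool = False) -> np.ndarray:
        """l3x: the timestep-independent image-branch output (N, width)."""
        h = self.a1x.forward(self.bn1x.forward(self.g1x.forward(x_flat, train), train), train)
        h = self.a2x.forward(self.bn2x.forward(self.g2x.forward(h, train), train), train)
        return self.bn3x.forward(self.g3x.forward(h, train), train)

    def head(self, l3x: np.ndarray, y_t: np.ndarray, f: np.ndarray, t: np.ndarray,
             train: bool = False) -> np.ndarray:
        """Everything downstream of the image embedding."""
        te = self.t_embed(t)
        c = np.concatenate([y_t, f], axis=1).astype(np.float32)
        resp = self.a1y.forward(self.bn1y.forward(self.g1y.forward(c, train), train), train)
        e1 = self.g1b.forward(te, train)
        l1y = resp * e1
        l1 = l3x * l1y
        e2 = self.g2b.forward(te, train)
        l2 = self.a2a.forward(self.bn2a.forward(self.g2a.forward(l1 * e2, train), train), train)
        e3 = self.g3b.forward(te, train)
        l3 = self.a3a.forward(self.bn3a.forward(self.g3a.forward(l2 * e3, train), train), train)
        self._cache = (l3x, resp, e1, e2, e3, l1y, l1, l2)
        return self.g4.forward(l3, train)

    def forward(self, x_flat: np.ndarray, y_t: np.ndarray, f: np.ndarray,
                t: np.ndarray, train: bool = False) -> np.ndarray:
        l3x = self.image_embedding(x_flat, train=train)
        return self.head(l3x, y_t, f, t, train=train)

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate through head and image branch; gradients w.r.t. the
        sinusoidal timestep features are discarded (they are not trained)."""
        l3x, resp, e1, e2, e3, l1y, l1, l2 = self._cache
        g = self.g4.backward(grad)
        g_u3 = self.g3a.backward(self.bn3a.backward(self.a3a.backward(g)))
        self.g3b.backward(g_u3 * l2)
        g_l2 = g_u3 * e3
        g_u2 = self.g2a.backward(self.bn2a.backward(self.a2a.backward(g_l2)))
        self.g2b.backward(g_u2 * l1)
        g_l1 = g_u2 * e2
        g_l3x = g_l1 * l1y
        g_l1y = g_l1 * l3x
        self.g1b.backward(g_l1y * resp)
        g_resp = g_l1y * e1
        self.g1y.backward(self.bn1y.backward(self.a1y.backward(g_resp)))
        g = self.bn3x.backward(g_l3x)
        g = self.g3x.backward(g)
        g = self.g2x.backward(self.bn2x.backward(self.a2x.backward(g)))
        self.g1x.backward(self.bn1x.backward(self.a1x.backward(g)))

    def state_dict(self):
        d = {}
        for i, b in enumerate(self._blocks):
            for k, v in b.state_dict().items():
                d[f"b{i}.{k}"] = v
        d["_meta"] = np.array([self.w, self.width, self.t_dim, self.seed])
        return d

    def save(self, path):
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path) -> "EpsNet":
        with np.load(path) as data:
            meta = data["_meta"]
            net = cls(w=int(meta[0]), width=int(meta[1]), t_dim=int(meta[2]), seed=int(meta[3]))
            for i, b in enumerate(net._blocks):
                prefix = f"b{i}."
                b.load_state_dict({k[len(prefix):]: data[k] for k in data.files
                                   if k.startswith(prefix)})
        return net


@dataclasses.dataclass
class ScoredPrediction:
    """Summary of repeated reverse-diffusion draws for one candidate."""

    score: float
    ci_low: float
    ci_high: float
    t_pvalue: float
    n_draws: int


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), 2), dtype=np.float64)
    y[np.arange(len(labels)), labels] = 1.0
    return y


def train_diffusion(eps_net: EpsNet, prior_net: PriorNet, train_x: np.ndarray,
                    train_y: np.ndarray, sched: DiffusionSchedule,
                    lr: float = 1e-3, batch: int = 128, epochs: int = 40,
                    seed: int = 0) -> tuple[EpsNet, list[dict]]:
    """Train the noise predictor with the simplified ELBO (MSE on eps).

    Per batch: t ~ Uniform{1..T}, eps ~ N(0, I), y_t from the closed-form
    forward kernel with y0 the one-hot label and f the (frozen) prior output;
    minimise ||eps - eps_net(x, y_t, f, t)||^2.
    """
    if len(train_x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    x_img = prepare_windows(train_x)
    x_flat = x_img.reshape(len(x_img), -1)
    f_all = predict_prior(prior_net, train_x)
    y0_all = _one_hot(np.asarray(train_y, dtype=np.int64))
    opt = nn.Adam(eps_net.params(), lr=lr)
    history: list[dict] = []
    n = len(x_flat)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for k in range(0, n, batch):
            idx = order[k:k + batch]
            nb = len(idx)
            t = rng.integers(1, sched.T + 1, size=nb)
            eps = rng.standard_normal((nb, 2))
            y_t = forward_sample(y0_all[idx], f_all[idx], t, sched, eps)
            opt.zero_grad()
            pred = eps_net.forward(x_flat[idx], y_t.astype(np.float32),
                                   f_all[idx].astype(np.float32), t, train=True)
            diff = pred - eps
            loss = float(np.mean(diff ** 2))
            eps_net.backward((2.0 / diff.size) * diff.astype(np.float32))
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses))})
    return eps_net, history


def _summarise_draws(scores: np.ndarray) -> ScoredPrediction:
    n = len(scores)
    mean = float(np.mean(scores))
    if n < 2:
        return ScoredPrediction(score=mean, ci_low=np.nan, ci_high=np.nan,
                                t_pvalue=np.nan, n_draws=n)
    se = float(np.std(scores, ddof=1)) / np.sqrt(n)
    half = 1.959963984540054 * se
    if se == 0:
        pval = 0.0 if mean != 0.5 else 1.0
    else:
        tstat = (mean - 0.5) / se
        pval = float(2.0 * stats.t.sf(abs(tstat), df=n - 1))
    return ScoredPrediction(score=mean, ci_low=mean - half, ci_high=mean + half,
                            t_pvalue=pval, n_draws=n)


def reverse_classify_batch(x: np.ndarray, prior_net: PriorNet, eps_net: EpsNet,
                           sched: DiffusionSchedule, n_draws: int = 10,
                           seed: int = 0) -> list[ScoredPrediction]:
    """Score many windows at once with the full reverse chain.

    The image-branch embedding is timestep-independent, so it is computed
    once per window; the per-timestep cost is only the response head.
    """
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None]
    n_win = len(x)
    if n_win == 0:
        return []
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    f = predict_prior(prior_net, x)  # (n_win, 2)
    x_flat = prepare_windows(x).reshape(n_win, -1)
    l3x = eps_net.image_embedding(x_flat, train=False)  # (n_win, width)
    # tile windows across draws: sample axis = draw-major
    nd = max(n_draws, 1)
    big = n_win * nd
    f_big = np.tile(f, (nd, 1))
    l3x_big = np.tile(l3x, (nd, 1))
    y = f_big + rng.standard_normal((big, 2))  # y_T ~ N(f, I)
    for t in range(sched.T, 0, -1):
        ab = sched.alpha_bar[t - 1]
        sq = np.sqrt(ab)
        t_vec = np.full(big, t)
        eps_hat = eps_net.head(l3x_big, y.astype(np.float32), f_big.astype(np.float32),
                               t_vec, train=False).astype(np.float64)
        y0_hat = (y - (1.0 - sq) * f_big - np.sqrt(1.0 - ab) * eps_hat) / sq
        noise = rng.standard_normal((big, 2)) if t > 1 else None
        y = posterior_step(y, y0_hat, f_big, t, sched, noise)
    # at t=1 the gamma coefficients collapse to (1, 0, 0), so y is exactly
    # the final y0 estimate of the chain
    probs = nn.softmax(y)
    pos = np.clip(probs[:, 1], 0.0, 1.0).reshape(nd, n_win)
    return [_summarise_draws(pos[:, k]) for k in range(n_win)]


def reverse_classify(x: np.ndarray, prior_net: PriorNet, eps_net: EpsNet,
                     sched: DiffusionSchedule, n_draws: int = 10,
                     seed: int = 0) -> ScoredPrediction:
    """Score a single window (see :func:`reverse_classify_batch`)."""
    return reverse_classify_batch(np.asarray(x)[None] if np.asarray(x).ndim == 2 else x,
                                  prior_net, eps_net, sched, n_draws=n_draws, seed=seed)[0]
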