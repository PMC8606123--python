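"""Generator, discriminator and the perceptual-adversarial objective.

The generator is a U-Net (encoder/decoder cascade with skip connections):
strided 4x4 convolutions with LeakyReLU on the way down, transposed
convolutions with ReLU on the way up, batch normalization on the hidden
levels and a tanh output affinely mapped to [0, 1]. Its input is the
two-channel (amplitude, phase) stack of a discontinuous-spectrum B-scan;
its output is the reconstructed broadband amplitude image.

The discriminator is a strided conv stack with F = 5 hidden layers whose
activation maps d_1..d_F feed the perceptual adversarial loss, topped by a
global-average-pool + linear + sigmoid head producing the real/fake
probability.

Objective, with default weights lambda_G = 100, theta_G = 1, theta_D = -1,
margin m = 50, lambda_j = (5.0, 1.5, 1.5, 1.5, 1.0):

* perceptual loss  L_P = sum_j lambda_j * mean_batch ||d_j(y_real) - d_j(y_recon)||_1
* discriminator    L_D = theta_D * 1/2 (L_real + L_recon) + max(0, m - L_P)
* generator        L_G = theta_G * L_recon_as_real + lambda_G * mean|y_real - y_recon|

The per-label terms L_* are cross-entropies. During optimization the
discriminator descends 1/2(BCE(1, D(real)) + BCE(0, D(fake))) + max(0, m - L_P)
— the direction the min/max objective prescribes once the per-label terms
are written as positive cross-entropies — and the generator uses the
non-saturating target label 1 on its own outputs; see docs/methods.md for
the sign-convention discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossConfig", "DiscriminatorOutput",
    "Generator", "Discriminator",
    "perceptual_loss", "bce_loss", "discriminator_loss", "generator_loss",
    "discriminator_train_step", "generator_train_step",
]

BCE_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """All weights of the objective (study defaults)."""

    lambda_g: float = 100.0
    theta_g: float = 1.0
    theta_d: float = -1.0
    margin: float = 50.0
    lambda_j: tuple = (5.0, 1.5, 1.5, 1.5, 1.0)

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin m must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net geometry. Channel width at level i is min(base * 2^i, max)."""

    in_channels: int = 2
    out_channels: int = 1
    n_levels: int = 6
    base_width: int = 64
    max_width: int = 512

    def widths(self) -> list:
        return [min(self.base_width * 2**i, self.max_width)
                for i in range(self.n_levels)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Strided conv stack; ``n_hidden`` = F hidden feature layers."""

    in_channels: int = 1
    n_hidden: int = 5
    base_width: int = 64
    max_width: int = 512

    def widths(self) -> list:
        return [min(self.base_width * 2**i, self.max_width)
                for i in range(self.n_hidden)]


@dataclass
class DiscriminatorOutput:
    """Prediction plus the F hidden feature maps used by the perceptual loss."""

    label_prob: np.ndarray        # (N,), strictly inside (0, 1) after clamping
    features: list                # F arrays (N, C_j, H_j, W_j)
    cache: object = None          # layer caches for the backward pass


class Generator:
    """U-Net generator mapping a channel stack to a [0, 1] amplitude image."""

    def __init__(self, spec: GeneratorSpec = GeneratorSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.widths()
        L = spec.n_levels
        self.enc = []
        cin = spec.in_channels
        for i in range(L):
            conv = nn.Conv2d(cin, w[i], rng=rng)
            bn = nn.BatchNorm2d(w[i]) if 0 < i < L - 1 else None
            self.enc.append((conv, bn, nn.LeakyReLU(0.2)))
            cin = w[i]
        self.dec = []
        for i in range(L - 1, 0, -1):
            cin_i = w[i] if i == L - 1 else 2 * w[i]
            deconv = nn.ConvTranspose2d(cin_i, w[i - 1], rng=rng)
            self.dec.append((deconv, nn.BatchNorm2d(w[i - 1]), nn.ReLU()))
        self.final = nn.ConvTranspose2d(2 * w[0], spec.out_channels, rng=rng)
        self.tanh = nn.Tanh()

    # -- parameter plumbing -------------------------------------------------
    def named_params(self):
        out = []
        for i, (conv, bn, _) in enumerate(self.enc):
            out += [(f"enc{i}.{n}", p) for n, p in conv.params()]
            if bn:
                out += [(f"enc{i}.bn.{n}", p) for n, p in bn.params()]
        for i, (deconv, bn, _) in enumerate(self.dec):
            out += [(f"dec{i}.{n}", p) for n, p in deconv.params()]
            out += [(f"dec{i}.bn.{n}", p) for n, p in bn.params()]
        out += [(f"final.{n}", p) for n, p in self.final.params()]
        return out

    def params(self):
        return [p for _, p in self.named_params()]

    # -- forward / backward -------------------------------------------------
    def _pad(self, x: np.ndarray):
        div = 2 ** self.spec.n_levels
        h, w = x.shape[2], x.shape[3]
        ph, pw = (-h) % div, (-w) % div
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    def forward(self, x: np.ndarray):
        """Return (y01, cache); y01 in [0, 1] with the input's spatial shape."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, "
                f"got {x.shape[1]}")
        xp, orig_hw = self._pad(x)
        caches = {"orig_hw": orig_hw, "pad_shape": xp.shape, "enc": [],
                  "dec": [], "skips_shape": []}
        h = xp
        skips = []
        for conv, bn, act in self.enc:
            h, c_conv = conv.forward(h)
            c_bn = None
            if bn:
                h, c_bn = bn.forward(h)
            h, c_act = act.forward(h)
            caches["enc"].append((c_conv, c_bn, c_act))
            skips.append(h)
        u = skips[-1]
        L = self.spec.n_levels
        for idx, (deconv, bn, act) in enumerate(self.dec):
            skip = skips[L - 2 - idx]
            if idx > 0:
                u = np.concatenate([u, skips[L - 1 - idx]], axis=1)
            u, c_d = deconv.forward(u)
            u, c_bn = bn.forward(u)
            u, c_act = act.forward(u)
            caches["dec"].append((c_d, c_bn, c_act))
        u = np.concatenate([u, skips[0]], axis=1)
        y, c_f = self.final.forward(u)
        y, c_t = self.tanh.forward(y)
        caches["final"] = (c_f, c_t)
        caches["concat_channels"] = [s.shape[1] for s in skips]
        y01 = (y + 1.0) * 0.5
        y01 = y01[:, :, : orig_hw[0], : orig_hw[1]]
        return y01, caches

    def backward(self, dy01: np.ndarray, caches):
        """Backpropagate d(loss)/d(y01); accumulates parameter gradients."""
        L = self.spec.n_levels
        oh, ow = caches["orig_hw"]
        n, _, hp, wp = caches["pad_shape"]
        full = np.zeros((dy01.shape[0], self.spec.out_channels, hp, wp),
                        dtype=np.float32)
        full[:, :, :oh, :ow] = dy01.astype(np.float32) * 0.5  # d y01/dy
        c_f, c_t = caches["final"]
        g = self.tanh.backward(full, c_t)
        g = self.final.backward(g, c_f)
        widths = caches["concat_channels"]
        # split the final concat(u_1, e_0)
        g_u, skip_grads = g[:, : -widths[0]], [None] * L
        skip_grads[0] = g[:, -widths[0]:]
        for idx in range(len(self.dec) - 1, -1, -1):
            deconv, bn, act = self.dec[idx]
            c_d, c_bn, c_act = caches["dec"][idx]
            g_u = act.backward(g_u, c_act)
            g_u = bn.backward(g_u, c_bn)
            g_u = deconv.backward(g_u, c_d)
            if idx > 0:
                c_skip = widths[L - 1 - idx]
                skip_grads[L - 1 - idx] = g_u[:, -c_skip:]
                g_u = g_u[:, : -c_skip]
        # g_u is now the grad at e_{L-1}; fold into skip grads and descend
        grad_h = g_u
        for i in range(L - 1, -1, -1):
            if skip_grads[i] is not None and i != L - 1:
                grad_h = grad_h + skip_grads[i]
            elif i == L - 1 and skip_grads[i] is not None:
                grad_h = grad_h + skip_grads[i]
            conv, bn, act = self.enc[i]
            c_conv, c_bn, c_act = caches["enc"][i]
            grad_h = act.backward(grad_h, c_act)
            if bn:
                grad_h = bn.backward(grad_h, c_bn)
            grad_h = conv.backward(grad_h, c_conv)
        return grad_h[:, :, :oh, :ow]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Inference: reconstructed amplitude image(s) in [0, 1]."""
        y, _ = self.forward(x)
        return y


class Discriminator:
    """Conv stack exposing F hidden feature maps plus a real/fake probability."""

    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(),
                 seed: int = 1):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.widths()
        self.layers = []
        cin = spec.in_channels
        for j in range(spec.n_hidden):
            conv = nn.Conv2d(cin, w[j], rng=rng)
            bn = nn.BatchNorm2d(w[j]) if j > 0 else None
            self.layers.append((conv, bn, nn.LeakyReLU(0.2)))
            cin = w[j]
        self.head = nn.Linear(w[-1], 1, rng=rng)
        self.sigmoid = nn.Sigmoid()

    def named_params(self):
        out = []
        for j, (conv, bn, _) in enumerate(self.layers):
            out += [(f"hidden{j}.{n}", p) for n, p in conv.params()]
            if bn:
                out += [(f"hidden{j}.bn.{n}", p) for n, p in bn.params()]
        out += [(f"head.{n}", p) for n, p in self.head.params()]
        return out

    def params(self):
        return [p for _, p in self.named_params()]

    def forward(self, x: np.ndarray) -> DiscriminatorOutput:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        feats, caches = [], []
        h = x
        for conv, bn, act in self.layers:
            h, c_conv = conv.forward(h)
            c_bn = None
            if bn:
                h, c_bn = bn.forward(h)
            h, c_act = act.forward(h)
            caches.append((c_conv, c_bn, c_act))
            feats.append(h)
        pooled = h.mean(axis=(2, 3))
        logits, c_lin = self.head.forward(pooled)
        prob, c_sig = self.sigmoid.forward(logits[:, 0])
        prob = np.clip(prob, BCE_EPS, 1.0 - BCE_EPS)
        return DiscriminatorOutput(
            label_prob=prob, features=feats,
            cache=(caches, c_lin, c_sig, h.shape))

    def backward(self, out: DiscriminatorOutput, dprob: np.ndarray,
                 feature_grads: list | None = None) -> np.ndarray:
        """Backprop d(loss)/d(label_prob) and optional per-feature grads."""
        caches, c_lin, c_sig, top_shape = out.cache
        g = self.sigmoid.backward(np.asarray(dprob, dtype=np.float32), c_sig)
        g = self.head.backward(g[:, None], c_lin)
        n, c, h, w = top_shape
        g = np.broadcast_to(g[:, :, None, None], top_shape) / (h * w)
        g = np.ascontiguousarray(g, dtype=np.float32)
        for j in range(len(self.layers) - 1, -1, -1):
            if feature_grads is not None and feature_grads[j] is not None:
                g = g + feature_grads[j].astype(np.float32)
            conv, bn, act = self.layers[j]
            c_conv, c_bn, c_act = caches[j]
            g = act.backward(g, c_act)
            if bn:
                g = bn.backward(g, c_bn)
            g = conv.backward(g, c_conv)
        return g


# ---------------------------------------------------------------------------
# Loss functions (pure)
# ---------------------------------------------------------------------------

def bce_loss(l_true, l_pred, eps: float = BCE_EPS) -> float:
    """Binary cross-entropy, mean over the batch, always >= 0."""
    t = np.atleast_1d(np.asarray(l_true, dtype=np.float64))
    p = np.clip(np.atleast_1d(np.asarray(l_pred, dtype=np.float64)),
                eps, 1.0 - eps)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def _feature_l1(a: np.ndarray, b: np.ndarray) -> float:
    """L1 norm of the feature difference per sample, averaged over the batch."""
    d = np.abs(np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64))
    return float(d.reshape(d.shape[0], -1).sum(axis=1).mean())


def perceptual_loss(out_real: DiscriminatorOutput,
                    out_recon: DiscriminatorOutput,
                    cfg: LossConfig = LossConfig()) -> float:
    """L_P: lambda_j-weighted L1 feature distances across the F hidden layers."""
    fr, fg = out_real.features, out_recon.features
    if len(fr) != len(fg):
        raise ValueError("feature lists must align")
    if len(fr) != len(cfg.lambda_j):
        raise ValueError(
            f"need {len(cfg.lambda_j)} feature layers, got {len(fr)}")
    lp = 0.0
    for lam, a, b in zip(cfg.lambda_j, fr, fg):
        if a.shape != b.shape:
            raise ValueError("feature shapes must match")
        lp += lam * _feature_l1(a, b)
    return lp


def discriminator_loss(bce_real: float, bce_recon: float, lp: float,
                       cfg: LossConfig = LossConfig()) -> float:
    """L_D = theta_D * 1/2 (L_real + L_recon) + max(0, m - L_P)."""
    return (cfg.theta_d * 0.5 * (bce_real + bce_recon)
            + max(0.0, cfg.margin - lp))


def generator_loss(bce_recon_as_real: float, yreal: np.ndarray,
                   yrecon: np.ndarray,
                   cfg: LossConfig = LossConfig()) -> float:
    """L_G = theta_G * BCE(real-label on generated) + lambda_G * mean|y - y^|."""
    l1 = float(np.mean(np.abs(np.asarray(yreal, dtype=np.float64)
                              - np.asarray(yrecon, dtype=np.float64))))
    return cfg.theta_g * bce_recon_as_real + cfg.lambda_g * l1


# ---------------------------------------------------------------------------
# Optimization steps
# ---------------------------------------------------------------------------

def _perceptual_grads(out_real, out_recon, cfg):
    """Grads of L_P w.r.t. the real- and recon-branch features."""
    n = out_real.features[0].shape[0]
    gr, gg = [], []
    for lam, a, b in zip(cfg.lambda_j, out_real.features, out_recon.features):
        s = np.sign(a - b).astype(np.float32) * (lam / n)
        gr.append(s)
        gg.append(-s)
    return gr, gg


def discriminator_train_step(disc: Discriminator, opt: nn.Adam,
                             yreal: np.ndarray, yfake: np.ndarray,
                             cfg: LossConfig) -> dict:
    """One discriminator update on a (real, fake) image pair.

    Descends 1/2(BCE(1, D(real)) + BCE(0, D(fake))) + max(0, m - L_P): the
    head learns to separate real from generated while the hinge pushes the
    hidden representations of the two apart until the perceptual distance
    reaches the margin m.
    """
    opt.zero_grad()
    out_r = disc.forward(yreal)
    out_f = disc.forward(yfake)
    b_r = bce_loss(1.0, out_r.label_prob)
    b_f = bce_loss(0.0, out_f.label_prob)
    lp = perceptual_loss(out_r, out_f, cfg)
    n = out_r.label_prob.shape[0]
    d_br = -1.0 / (out_r.label_prob * n) * 0.5
    d_bf = (1.0 / ((1.0 - out_f.label_prob) * n)) * 0.5
    if lp < cfg.margin:
        gr, gf = _perceptual_grads(out_r, out_f, cfg)
        gr = [-g for g in gr]      # d hinge/d feat = -d L_P/d feat
        gf = [-g for g in gf]
    else:
        gr = gf = [None] * len(out_r.features)
    disc.backward(out_r, d_br, gr)
    disc.backward(out_f, d_bf, gf)
    opt.step()
    return {"bce_real": b_r, "bce_recon": b_f, "lp": lp,
            "ld": discriminator_loss(b_r, b_f, lp, cfg)}


def generator_train_step(gen: Generator, disc: Discriminator, opt: nn.Adam,
                         x: np.ndarray, yreal: np.ndarray,
                         cfg: LossConfig) -> dict:
    """One generator update: adversarial BCE (label 1) + lambda_G * L1."""
    opt.zero_grad()
    for p in disc.params():
        p.grad[...] = 0.0
    yrecon, g_cache = gen.forward(x)
    out_f = disc.forward(yrecon)
    b_adv = bce_loss(1.0, out_f.label_prob)
    yreal = np.asarray(yreal, dtype=np.float32)
    if yreal.ndim == 3:
        yreal = yreal[None]
    diff = yrecon - yreal
    l1 = float(np.mean(np.abs(diff)))
    n = out_f.label_prob.shape[0]
    d_adv = cfg.theta_g * (-1.0 / (out_f.label_prob * n))
    dy = disc.backward(out_f, d_adv)
    dy = dy + cfg.lambda_g * np.sign(diff) / diff.size
    gen.backward(dy, g_cache)
    opt.step()
    # discard discriminator grads incurred while routing the adversarial term
    for p in disc.params():
        p.grad[...] = 0.0
    return {"bce_adv": b_adv, "l1": l1,
            "lg": cfg.theta_g * b_adv + cfg.lambda_g * l1,
            "yrecon": yrecon}
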