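"""GAN-side computations: AdaIN, adversarial losses, FID, and a mini-GAN.

These are the generic building blocks of GAN-based data augmentation for
medical imaging, implemented independently of any particular generator
family and exercised by a desk-scale mini-GAN:

* adaptive instance normalization (AdaIN) of a feature-map channel;
* logistic (non-saturating) discriminator losses, mean-feature-matching
  loss, and the gradient penalty enforcing a Lipschitz-like constraint;
* the Frechet distance between Gaussians fitted to image embeddings (FID),
  with a pluggable embedding — raw pixels by default, or the classifier's
  encoder — so no pretrained reference network is required; FID values are
  therefore on the embedding's own scale and are not comparable to
  Inception-based FID numbers.

The mini-GAN (``train_mini_gan``) is a small convolutional
generator/discriminator pair for images up to 64x64 that trains with the
full loss L_D + lambda_FM * L_FM + lambda_GP * L_GP, fully seeded.  The
gradient penalty's parameter gradients are obtained by an exact
(almost everywhere) second backward pass; see :mod:`dsunet._nn`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import (Adam, AvgPool2, BilinearUp2, Dense, DepthwiseConv3x3,
                  GlobalAvgPool, PointwiseConv, ReLU, Sigmoid)
from .errors import InvalidInputError, NumericError, ShapeError

__all__ = [
    "adain",
    "discriminator_losses",
    "discriminator_probability",
    "feature_matching_loss",
    "gradient_penalty",
    "GaussianStats",
    "fid_score",
    "embed_images",
    "MiniGANConfig",
    "MiniGANBundle",
    "train_mini_gan",
]

_LOG_CLAMP = 1e-12   # lower clamp on log arguments
_PSD_TOL = 1e-10     # relative clamp for tiny negative eigenvalues


# ---------------------------------------------------------------------------
# style modulation and losses
# ---------------------------------------------------------------------------

def adain(x: np.ndarray, ys: float | np.ndarray, yb: float | np.ndarray,
          sigma_eps: float = 1e-8) -> np.ndarray:
    """Adaptive instance normalization of one feature-map channel.

    Standardizes ``x`` to zero mean and unit variance, then rescales by the
    style scale ``ys`` and shifts by the style bias ``yb``.  A constant
    channel is stabilized by ``sigma_eps`` (the standardized values become
    0, so the output is uniformly ``yb``).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise InvalidInputError("adain needs a channel with >= 2 elements")
    mu = x.mean()
    sigma = x.std()
    return ys * (x - mu) / (sigma + sigma_eps) + yb


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def discriminator_probability(logits: np.ndarray) -> np.ndarray:
    """Elementwise logistic map of discriminator scores to (0, 1)."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise InvalidInputError("logits must be finite")
    return _sigmoid(logits)


def discriminator_losses(d_real_logits: np.ndarray,
                         d_fake_logits: np.ndarray) -> tuple[float, float, float]:
    """Logistic discriminator losses (L_real, L_fake, L_total).

    L_real = E[-log sigma(D(x_real))], L_fake = E[-log(1 - sigma(D(x_fake)))];
    log arguments are clamped at 1e-12.
    """
    pr = discriminator_probability(d_real_logits)
    pf = discriminator_probability(d_fake_logits)
    l_real = float(-np.log(np.clip(pr, _LOG_CLAMP, None)).mean())
    l_fake = float(-np.log(np.clip(1.0 - pf, _LOG_CLAMP, None)).mean())
    return l_real, l_fake, l_real + l_fake


def feature_matching_loss(phi_real_mean: np.ndarray,
                          phi_fake_mean: np.ndarray) -> float:
    """Squared Euclidean distance between mean feature vectors."""
    a = np.asarray(phi_real_mean, dtype=np.float64)
    b = np.asarray(phi_fake_mean, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"feature dims differ: {a.shape} vs {b.shape}")
    return float(np.sum((a - b) ** 2))


def gradient_penalty(grad_norms: np.ndarray) -> float:
    """Mean of (||grad D(x_hat)|| - 1)**2 over interpolated samples."""
    g = np.asarray(grad_norms, dtype=np.float64)
    if (g < 0).any():
        raise InvalidInputError("gradient norms must be >= 0")
    return float(((g - 1.0) ** 2).mean())


# ---------------------------------------------------------------------------
# Frechet distance between embedding Gaussians
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GaussianStats:
    """Mean vector and covariance matrix of an embedding set."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.n < 2:
            raise InvalidInputError("need n >= 2 samples for covariance")
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ShapeError("covariance shape inconsistent with mean")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise InvalidInputError("covariance must be symmetric")

    @classmethod
    def from_embeddings(cls, X: np.ndarray) -> "GaussianStats":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise InvalidInputError("embeddings must be (n >= 2, dim)")
        return cls(mu=X.mean(axis=0), sigma=np.cov(X, rowvar=False, ddof=1),
                   n=X.shape[0])


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, clamping tiny
    negative eigenvalues to zero."""
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    tol = _PSD_TOL * max(1.0, float(np.abs(w).max()))
    if w.min() < -1e3 * tol:
        raise NumericError("matrix is far from positive semidefinite")
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def fid_score(real: GaussianStats, gen: GaussianStats) -> float:
    """Frechet distance between two embedding Gaussians.

    ||mu_r - mu_g||^2 + Tr(Sigma_r + Sigma_g - 2 (Sigma_r Sigma_g)^{1/2});
    the matrix square root is computed as
    sqrt(Sigma_r)^{} via eigendecomposition, then the eigendecomposition of
    the symmetrized product sqrt(Sigma_r) Sigma_g sqrt(Sigma_r), whose trace
    equals Tr((Sigma_r Sigma_g)^{1/2}).  Tiny negative eigenvalues from
    numerical noise are clamped to zero and the result is clamped at 0.
    """
    if real.mu.shape != gen.mu.shape:
        raise ShapeError("embedding dimensions differ")
    if not (np.all(np.isfinite(real.sigma)) and np.all(np.isfinite(gen.sigma))):
        raise NumericError("covariances must be finite")
    diff = real.mu - gen.mu
    sr = _psd_sqrt(real.sigma)
    cross = _psd_sqrt(sr @ gen.sigma @ sr)
    fid = float(diff @ diff + np.trace(real.sigma) + np.trace(gen.sigma)
                - 2.0 * np.trace(cross))
    return max(fid, 0.0)


def embed_images(images: np.ndarray, embedding: str = "pixels",
                 checkpoint=None) -> np.ndarray:
    """Map an (N, H, W) or (N, H, W, C) image stack to embedding vectors.

    ``pixels``: flatten each image (length H*W*C).  ``encoder``: global
    average pool of the classifier bottleneck from ``checkpoint`` (a
    :class:`dsunet.dsconv_net.DSUNetClassifier` or a checkpoint path).
    Deterministic given the embedding choice.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[:, :, :, None]
    if images.ndim != 4:
        raise ShapeError("expected (N, H, W) or (N, H, W, C) images")
    if embedding == "pixels":
        return images.reshape(images.shape[0], -1)
    if embedding == "encoder":
        from .dsconv_net import DSUNetClassifier, load_checkpoint
        if checkpoint is None:
            raise InvalidInputError("encoder embedding requires a checkpoint")
        model = (checkpoint if isinstance(checkpoint, DSUNetClassifier)
                 else load_checkpoint(checkpoint))
        x = np.transpose(images, (0, 3, 1, 2))
        if x.shape[1] != model.config.in_channels:
            x = np.repeat(x[:, :1], model.config.in_channels, axis=1)
        for block, pool in zip(model.encoder, model.pools):
            x = block.forward(x, training=False)
            x = pool.forward(x, training=False)
        x = model.bottleneck.forward(x, training=False)
        return x.mean(axis=(2, 3))
    raise InvalidInputError(f"unknown embedding {embedding!r}")


# ---------------------------------------------------------------------------
# desk-scale mini-GAN
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MiniGANConfig:
    """Hyperparameters of the desk-scale GAN.

    Loss weights are exposed because no canonical weighting exists for the
    combined objective; defaults keep the auxiliary terms an order of
    magnitude below the adversarial term.
    """

    latent_dim: int = 32
    base_channels: int = 8
    steps: int = 500
    batch_size: int = 16
    lr: float = 2e-4
    lambda_fm: float = 0.1
    lambda_gp: float = 1.0
    fid_every: int = 100
    fid_samples: int = 128


class _Generator:
    """latent -> dense -> 4x4 map -> [up2 -> DSConv -> ReLU]* -> sigmoid image."""

    def __init__(self, size: int, cfg: MiniGANConfig, rng: np.random.Generator):
        self.size = size
        c = cfg.base_channels
        self.levels = int(np.log2(size / 4))
        self.dense = Dense(cfg.latent_dim, 2 * c * 4 * 4, rng)
        self.relu0 = ReLU()
        self.blocks = []
        prev = 2 * c
        for _ in range(self.levels):
            self.blocks.append((BilinearUp2(), DepthwiseConv3x3(prev, rng),
                                PointwiseConv(prev, c, rng), ReLU()))
            prev = c
        self.out_pw = PointwiseConv(prev, 1, rng)
        self.sigmoid = Sigmoid()
        self._c0 = 2 * c

    def params(self):
        out = self.dense.params()
        for up, dw, pw, relu in self.blocks:
            out += dw.params() + pw.params()
        return out + self.out_pw.params()

    def forward(self, z: np.ndarray) -> np.ndarray:
        h = self.relu0.forward(self.dense.forward(z))
        x = h.reshape(z.shape[0], self._c0, 4, 4)
        for up, dw, pw, relu in self.blocks:
            x = relu.forward(pw.forward(dw.forward(up.forward(x))))
        return self.sigmoid.forward(self.out_pw.forward(x))

    def backward(self, gimg: np.ndarray) -> None:
        g = self.out_pw.backward(self.sigmoid.backward(gimg))
        for up, dw, pw, relu in reversed(self.blocks):
            g = up.backward(dw.backward(pw.backward(relu.backward(g))))
        g = g.reshape(g.shape[0], -1)
        self.dense.backward(self.relu0.backward(g))


class _Discriminator:
    """Image -> [DSConv -> ReLU -> avgpool]* -> GAP features -> dense logit.

    No batch normalization: ReLU is the only nonlinearity, which keeps the
    gradient-penalty double-backward pass exact almost everywhere.
    """

    def __init__(self, size: int, cfg: MiniGANConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.levels = int(np.log2(size / 4))
        self.layers = []
        prev = 1
        width = c
        for _ in range(self.levels):
            self.layers += [DepthwiseConv3x3(prev, rng),
                            PointwiseConv(prev, width, rng), ReLU(), AvgPool2()]
            prev = width
            width = min(2 * width, 4 * c)
        self.gap = GlobalAvgPool()
        self.head = Dense(prev, 1, rng)
        self.feature_dim = prev

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (logits (N,), GAP features (N, F))."""
        for layer in self.layers:
            x = layer.forward(x)
        phi = self.gap.forward(x)
        return self.head.forward(phi)[:, 0], phi

    def backward(self, dlogits: np.ndarray, dphi: np.ndarray | None = None) -> np.ndarray:
        g = self.head.backward(dlogits[:, None])
        if dphi is not None:
            g = g + dphi
        g = self.gap.backward(g)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def gp_second_pass(self, u0: np.ndarray) -> None:
        """Adjoint pass accumulating d(penalty)/d(weights); ``u0`` is the
        penalty's gradient with respect to the input-gradient map."""
        u = u0
        for layer in self.layers:
            u = layer.gp_forward(u)
        u = self.gap.gp_forward(u)
        self.head.gp_forward(u[:, None] if u.ndim == 1 else u)


@dataclasses.dataclass
class MiniGANBundle:
    """Trained mini-GAN with its loss and FID traces."""

    generator: _Generator
    discriminator: _Discriminator
    config: MiniGANConfig
    losses: list[dict]
    fid_trace: list[tuple[int, float]]
    seed: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.config.latent_dim))
        return self.generator.forward(z)[:, 0]


def train_mini_gan(images, config: MiniGANConfig | None = None,
                   seed: int = 0) -> MiniGANBundle:
    """Adversarial training of the mini-GAN.

    ``images`` is an (N, H, W) stack in [0, 1], or a
    :class:`dsunet.io_preprocess.DatasetManifest` whose training-split PNGs
    are loaded as grayscale.  N >= 100 and the side must be a power of two
    at most 64.  The discriminator minimizes
    L_real + L_fake + lambda_GP * GP; the generator minimizes the
    non-saturating loss -log sigma(D(G(z))) + lambda_FM * L_FM.  Every step
    logs the loss terms; a pixel-embedding FID against the training images
    is recorded every ``fid_every`` steps.  Fully seeded and deterministic.
    """
    config = config or MiniGANConfig()
    from .io_preprocess import DatasetManifest
    if isinstance(images, DatasetManifest):
        from .io_preprocess import load_image
        frame = images.frame
        frame = frame[frame["split"] == "train"]
        stack = []
        for path in frame["path"]:
            arr = np.asarray(load_image(path), dtype=np.float64)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            stack.append(arr / 255.0)
        images = np.asarray(stack)
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ShapeError("expected an (N, H, W) stack")
    n, size, size2 = images.shape
    if n < 100:
        raise InvalidInputError("need >= 100 training images")
    if size != size2 or size > 64 or 2 ** int(np.log2(size)) != size or size < 8:
        raise InvalidInputError("image side must be a power of two in [8, 64]")

    rng = np.random.default_rng(seed)
    G = _Generator(size, config, rng)
    D = _Discriminator(size, config, rng)
    opt_g = Adam(G.params(), lr=config.lr)
    opt_d = Adam(D.params(), lr=config.lr)

    fid_z = rng.standard_normal((config.fid_samples, config.latent_dim))
    real_subset = images[rng.choice(n, size=min(n, config.fid_samples),
                                    replace=False)]
    real_stats = GaussianStats.from_embeddings(embed_images(real_subset))

    def pixel_fid() -> float:
        fake = G.forward(fid_z)[:, 0]
        fake_stats = GaussianStats.from_embeddings(embed_images(fake))
        return fid_score(real_stats, fake_stats)

    losses: list[dict] = []
    fid_trace: list[tuple[int, float]] = [(0, pixel_fid())]
    bs = config.batch_size

    for step in range(1, config.steps + 1):
        # ---------------- discriminator update ----------------
        idx = rng.choice(n, size=bs, replace=False)
        x_real = images[idx][:, None]
        z = rng.standard_normal((bs, config.latent_dim))
        x_fake = G.forward(z)          # generator treated as fixed here

        opt_d.zero_grad()
        d_real, _ = D.forward(x_real)
        # backward for L_real before the fake pass overwrites the caches
        dl_real = (_sigmoid(d_real) - 1.0) / bs
        D.backward(dl_real)
        d_fake, _ = D.forward(x_fake)
        dl_fake = _sigmoid(d_fake) / bs
        D.backward(dl_fake)
        l_real, l_fake, l_total = discriminator_losses(d_real, d_fake)

        # gradient penalty on uniform interpolates between real and fake
        eps = rng.uniform(size=(bs, 1, 1, 1))
        x_hat = eps * x_real + (1.0 - eps) * x_fake
        d_params = D.params()
        saved = [p.grad.copy() for p in d_params]
        D.forward(x_hat)
        g_in = D.backward(np.ones(bs))          # per-sample input gradients
        # that backward probed dD/dx but polluted the weight grads with the
        # gradient of sum(logits); restore, then add the true penalty grads
        for p, s in zip(d_params, saved):
            p.grad[...] = s
        norms = np.sqrt((g_in ** 2).sum(axis=(1, 2, 3)) + 1e-24)
        gp = gradient_penalty(norms)
        u0 = (config.lambda_gp * 2.0 * (norms - 1.0)
              / (norms * bs))[:, None, None, None] * g_in
        D.gp_second_pass(u0)
        opt_d.step()

        # ---------------- generator update ----------------
        opt_g.zero_grad()
        z = rng.standard_normal((bs, config.latent_dim))
        fake = G.forward(z)
        _, phi_real = D.forward(x_real)
        phi_real_mean = phi_real.mean(axis=0)
        logits, phi_fake = D.forward(fake)     # caches now hold the fake pass
        phi_fake_mean = phi_fake.mean(axis=0)
        l_fm = feature_matching_loss(phi_real_mean, phi_fake_mean)
        l_g_adv = float(-np.log(np.clip(_sigmoid(logits), _LOG_CLAMP, None)).mean())
        dlogits = -(1.0 - _sigmoid(logits)) / bs
        dphi = config.lambda_fm * 2.0 * (phi_fake_mean - phi_real_mean) / bs
        dphi = np.broadcast_to(dphi, phi_fake.shape).copy()
        gfake = D.backward(dlogits, dphi)
        G.backward(gfake)
        opt_g.step()

        rec = {"step": step, "d_real": l_real, "d_fake": l_fake,
               "d_total": l_total, "gp": gp, "g_adv": l_g_adv, "fm": l_fm}
        losses.append(rec)
        if not all(np.isfinite(v) for v in rec.values()):
            raise NumericError(f"non-finite loss at step {step}")
        if step % config.fid_every == 0 or step == config.steps:
            fid_trace.append((step, pixel_fid()))

    return MiniGANBundle(generator=G, discriminator=D, config=config,
                         losses=losses, fid_trace=fid_trace, seed=seed)
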