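"""Autoencoder variants (AE, VAE, SWAE) and their loss components.

All three models share one convolutional encoder/decoder backbone
(stride-2 conv blocks with batch normalization and LeakyReLU, mirrored by
transposed convolutions, sigmoid output) and differ only in the latent
head and the training objective:

* **AE** — deterministic bottleneck, L1 reconstruction loss.
* **VAE** — Gaussian posterior ``(mu, sigma)`` via a log-variance head,
  reparameterised sampling, L1 reconstruction + closed-form KL divergence
  to a standard-normal prior.
* **SWAE** — deterministic bottleneck, MSE reconstruction + the empirical
  sliced-Wasserstein distance between the batch of latent codes and an
  equal-size draw from the standard-normal prior.

The sliced-Wasserstein distance is estimated by projecting both sample
sets onto random unit directions and computing the exact 1-D squared
W2 between the projections by sorting (sorting solves 1-D optimal
transport for equal-size sets).

For optimization the summed objectives are divided by the
pixel count, so logged losses are per-pixel means comparable across image
sizes; the relative weighting of reconstruction and regularization terms
is unchanged.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Flatten,
    LeakyReLU,
    Reshape,
    Sequential,
    Sigmoid,
)

__all__ = [
    "ModelConfig",
    "PriorSampler",
    "ReconstructionModel",
    "build_model",
    "load_checkpoint",
    "save_checkpoint",
    "l1_loss",
    "mse_loss",
    "kld_gaussian",
    "vae_loss",
    "reparameterize",
    "sliced_wasserstein_distance",
    "swae_loss",
]


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def _check_same_shape(x: np.ndarray, xhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return x, xhat


def l1_loss(x: np.ndarray, xhat: np.ndarray, reduction: str = "sum") -> float:
    """L1 reconstruction error ``sum |x - xhat|``.

    ``reduction='mean'`` returns the per-pixel mean instead, which is the
    value logged during training (comparable across image sizes; the sum
    is recovered by multiplying by the pixel count).
    """
    x, xhat = _check_same_shape(x, xhat)
    diff = np.abs(x - xhat)
    if reduction == "sum":
        return float(diff.sum())
    if reduction == "mean":
        return float(diff.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def mse_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared error ``(1/n) sum (x - xhat)^2``."""
    x, xhat = _check_same_shape(x, xhat)
    return float(np.mean((x - xhat) ** 2))


def kld_gaussian(mu: np.ndarray, sigma: np.ndarray) -> float | np.ndarray:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    ``-1/2 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2)``; non-negative,
    zero iff mu = 0 and sigma = 1.  For 2-D input ``(N, d)`` a per-sample
    vector of KL divergences is returned.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if mu.shape != sigma.shape:
        raise ValueError(f"shape mismatch: {mu.shape} vs {sigma.shape}")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    per_dim = -0.5 * (1.0 + 2.0 * np.log(sigma) - mu**2 - sigma**2)
    total = per_dim.sum(axis=-1)
    return total if total.ndim else float(total)


def reparameterize(
    mu: np.ndarray, sigma: np.ndarray, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian reparameterization ``z = mu + eps * sigma``, ``eps ~ N(0,1)``."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(mu.shape)
    return mu + eps * sigma


def vae_loss(
    x: np.ndarray, xhat: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
    beta: float = 1.0,
) -> float:
    """VAE objective: L1 reconstruction sum + ``beta`` * Gaussian KLD."""
    kld = kld_gaussian(mu, sigma)
    kld_total = float(np.sum(kld))
    return l1_loss(x, xhat, reduction="sum") + beta * kld_total


def _sample_directions(d: int, n_projections: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform unit directions on S^{d-1}, shape (d, L)."""
    theta = rng.standard_normal((d, n_projections))
    norms = np.linalg.norm(theta, axis=0, keepdims=True)
    # resample degenerate (numerically zero) draws is overkill at float64
    return theta / norms


def _swd_core(
    a: np.ndarray, b: np.ndarray, n_projections: int, rng: np.random.Generator,
    want_grad_a: bool = False,
) -> tuple[float, np.ndarray | None]:
    """Sort-based empirical squared sliced-W2; optional gradient w.r.t. ``a``."""
    n, d = a.shape
    theta = _sample_directions(d, n_projections, rng)
    proj_a = a @ theta  # (n, L)
    proj_b = b @ theta
    idx_a = np.argsort(proj_a, axis=0)
    sorted_a = np.take_along_axis(proj_a, idx_a, axis=0)
    sorted_b = np.sort(proj_b, axis=0)
    diffs = sorted_a - sorted_b
    value = float(np.mean(diffs**2))
    if not want_grad_a:
        return value, None
    dproj = np.empty_like(proj_a)
    np.put_along_axis(dproj, idx_a, 2.0 * diffs / diffs.size, axis=0)
    return value, dproj @ theta.T


def sliced_wasserstein_distance(
    a: np.ndarray, b: np.ndarray, n_projections: int = 50, seed: int = 0,
    power: int = 2, rng: np.random.Generator | None = None,
) -> float:
    """Empirical squared sliced-W2 between two equal-size point sets.

    Averages, over ``n_projections`` uniform unit directions, the exact 1-D
    squared Wasserstein-2 distance between the projected samples (computed
    by sorting, which solves 1-D optimal transport for equal-size sets).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(f"expected (n, d) point sets, got {a.shape} and {b.shape}")
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"equal-size sample sets required, got {a.shape[0]} and {b.shape[0]}"
        )
    if a.shape[0] < 1 or n_projections < 1:
        raise ValueError("need >= 1 sample and >= 1 projection")
    if power != 2:
        raise ValueError("only the squared-W2 form is implemented")
    if rng is None:
        rng = np.random.default_rng(seed)
    value, _ = _swd_core(a, b, n_projections, rng)
    return value


@dataclass(frozen=True)
class PriorSampler:
    """Seeded standard-normal prior over ``dim`` latent dimensions."""

    dim: int
    seed: int = 0

    def sample(self, n: int, seed: int | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed if seed is None else seed)
        return rng.standard_normal((n, self.dim))


def swae_loss(
    x_batch: np.ndarray, xhat_batch: np.ndarray, z_batch: np.ndarray,
    prior: PriorSampler, lam: float = 10.0, n_projections: int = 50,
    seed: int = 0,
) -> float:
    """SWAE objective: batch MSE + ``lam`` * SWD(z_batch, prior draw).

    The prior draw and the projection directions are both derived from
    ``seed`` (prior uses ``seed``, projections ``seed + 1``), so the value
    is reproducible and its components can be recomputed independently.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    z_batch = np.atleast_2d(np.asarray(z_batch, dtype=np.float64))
    p = prior.sample(z_batch.shape[0], seed=seed)
    swd = sliced_wasserstein_distance(z_batch, p, n_projections, seed=seed + 1)
    return mse_loss(x_batch, xhat_batch) + lam * swd


# ---------------------------------------------------------------------------
# model configuration and backbone
# ---------------------------------------------------------------------------

MODEL_KINDS = ("ae", "vae", "swae")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss-weight configuration shared by all variants.

    ``channels`` are the encoder conv widths (one stride-2 block each,
    mirrored in the decoder); ``latent_dim`` is the flattened bottleneck
    size, or the bottleneck channel count when ``spatial_bottleneck`` is
    set (the "no dimension reduction" mode, where the code keeps its
    spatial layout and no flatten/dense head is used).
    """

    kind: str = "ae"
    image_size: tuple[int, int] = (64, 64)
    in_channels: int = 1
    channels: tuple[int, ...] = (16, 32, 64, 64)
    latent_dim: int = 128
    spatial_bottleneck: bool = False
    lrelu_slope: float = 0.2
    beta: float = 1.0
    lam: float = 10.0
    n_projections: int = 50
    vae_recon: str = "l1"  # 'l1' | 'bce'

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        h, w = self.image_size
        f = 2 ** len(self.channels)
        if h % f or w % f:
            raise ValueError(
                f"image size {self.image_size} not divisible by the "
                f"downsampling factor {f}"
            )
        if self.vae_recon not in ("l1", "bce"):
            raise ValueError(f"vae_recon must be 'l1' or 'bce', got {self.vae_recon!r}")

    @property
    def bottleneck_hw(self) -> tuple[int, int]:
        f = 2 ** len(self.channels)
        return self.image_size[0] // f, self.image_size[1] // f


class ReconstructionModel:
    """Shared conv backbone with a kind-specific latent head.

    The encoder is a stack of stride-2 ``Conv -> BatchNorm -> LeakyReLU``
    blocks; the decoder mirrors it with transposed convolutions and ends
    in a sigmoid so reconstructions always lie in (0, 1).  Only the head
    differs between kinds: AE/SWAE map the flattened features to a
    ``latent_dim`` code, the VAE maps them to ``(mu, logvar)``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        slope = config.lrelu_slope

        enc_layers: list = []
        prev = config.in_channels
        for ch in c:
            enc_layers += [Conv2d(prev, ch, 3, 2, 1, rng=rng), BatchNorm2d(ch), LeakyReLU(slope)]
            prev = ch
        self.enc_convs = Sequential(enc_layers)

        hh, ww = config.bottleneck_hw
        feat = c[-1] * hh * ww
        code_mult = 2 if config.kind == "vae" else 1
        if config.spatial_bottleneck:
            self.enc_head = Sequential(
                [Conv2d(c[-1], config.latent_dim * code_mult, 3, 1, 1, rng=rng)]
            )
            self.dec_head = Sequential(
                [Conv2d(config.latent_dim, c[-1], 3, 1, 1, rng=rng), LeakyReLU(slope)]
            )
        else:
            self.enc_head = Sequential(
                [Flatten(), Dense(feat, config.latent_dim * code_mult, rng=rng)]
            )
            self.dec_head = Sequential(
                [Dense(config.latent_dim, feat, rng=rng), Reshape((c[-1], hh, ww))]
            )

        dec_layers: list = []
        rev = list(c[::-1])
        for i in range(len(rev) - 1):
            dec_layers += [
                ConvTranspose2d(rev[i], rev[i + 1], 4, 2, 1, rng=rng),
                BatchNorm2d(rev[i + 1]),
                LeakyReLU(slope),
            ]
        dec_layers += [ConvTranspose2d(rev[-1], config.in_channels, 4, 2, 1, rng=rng), Sigmoid()]
        self.dec_convs = Sequential(dec_layers)

        self._modules = [self.enc_convs, self.enc_head, self.dec_head, self.dec_convs]

    # -- introspection -----------------------------------------------------
    @property
    def kind(self) -> str:
        return self.config.kind

    def conv_stack_param_count(self) -> int:
        """Parameter count of the shared conv backbone (heads excluded)."""
        return self.enc_convs.n_params() + self.dec_convs.n_params()

    def parameter_items(self):
        items = []
        for m in self._modules:
            items.extend(m.parameter_items())
        return items

    def make_optimizer(self, lr: float = 2e-4, beta1: float = 0.9,
                       beta2: float = 0.999) -> Adam:
        return Adam(self.parameter_items(), lr=lr, beta1=beta1, beta2=beta2)

    # -- forward passes ----------------------------------------------------
    def _split_code(self, code: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        axis = 1
        half = code.shape[axis] // 2
        mu = np.take(code, range(half), axis=axis)
        logvar = np.take(code, range(half, 2 * half), axis=axis)
        return mu, logvar

    def encode(self, x: np.ndarray, train: bool = False):
        """Map a batch (N, C, H, W) to latent codes.

        Returns ``z`` for AE/SWAE and ``(mu, sigma)`` for the VAE, where
        ``sigma = exp(logvar / 2)`` is positive by construction.
        """
        x = self._as_batch(x)
        h = self.enc_convs.forward(x, train=train)
        code = self.enc_head.forward(h, train=train)
        if self.kind == "vae":
            mu, logvar = self._split_code(code)
            return mu, np.exp(0.5 * logvar)
        return code

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim == 1:
            z = z[None]
        expected = self.config.latent_dim
        if not self.config.spatial_bottleneck and z.shape[1] != expected:
            raise ValueError(f"latent dimension {z.shape[1]} != configured {expected}")
        g = self.dec_head.forward(z, train=train)
        return self.dec_convs.forward(g, train=train)

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[None]
        h, w = x.shape[-2:]
        if (h, w) != tuple(self.config.image_size) or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} incompatible with configured "
                f"{(self.config.in_channels, *self.config.image_size)}"
            )
        return x

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode reconstruction.

        Batch-norm uses running statistics; the VAE decodes the posterior
        mean (no sampling), so repeated calls are identical.
        """
        single = np.asarray(x).ndim in (2, 3)
        xb = self._as_batch(x)
        if self.kind == "vae":
            mu, _ = self.encode(xb, train=False)
            out = self.decode(mu, train=False)
        else:
            out = self.decode(self.encode(xb, train=False), train=False)
        if single:
            out = out[0]
            if np.asarray(x).ndim == 2:
                out = out[0]
        return out

    # -- training step -----------------------------------------------------
    def train_step(self, x: np.ndarray, rng: np.random.Generator) -> dict[str, float]:
        """One forward/backward pass on a batch; fills parameter gradients.

        Returns the per-pixel-scaled loss and its components.  ``rng``
        drives the VAE's reparameterization noise and the SWAE's prior
        draw and projection directions.
        """
        x = self._as_batch(x)
        n_elem = x.size

        h = self.enc_convs.forward(x, train=True)
        code = self.enc_head.forward(h, train=True)

        if self.kind == "vae":
            mu, logvar = self._split_code(code)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape)
            z = mu + eps * sigma
        else:
            z = code

        g = self.dec_head.forward(z, train=True)
        xhat = self.dec_convs.forward(g, train=True)

        comps: dict[str, float] = {}
        if self.kind == "ae":
            recon = float(np.abs(x - xhat).mean())
            dxhat = np.sign(xhat - x) / n_elem
            total = recon
            comps["recon"] = recon
        elif self.kind == "vae":
            if self.config.vae_recon == "l1":
                recon = float(np.abs(x - xhat).mean())
                dxhat = np.sign(xhat - x) / n_elem
            else:  # Bernoulli cross-entropy
                xc = np.clip(xhat, 1e-7, 1 - 1e-7)
                recon = float(-(x * np.log(xc) + (1 - x) * np.log(1 - xc)).mean())
                dxhat = (xc - x) / (xc * (1 - xc)) / n_elem
            kld_sum = float(np.sum(kld_gaussian(mu, sigma)))
            # KLD scaled by the same 1/n as the reconstruction sum, so the
            # term balance matches the unscaled (summed) objective
            kld_term = self.config.beta * kld_sum / n_elem
            total = recon + kld_term
            comps["recon"] = recon
            comps["kld"] = kld_sum
        else:  # swae
            recon = float(np.mean((x - xhat) ** 2))
            dxhat = 2.0 * (xhat - x) / n_elem
            zf = z.reshape(z.shape[0], -1)
            prior = rng.standard_normal(zf.shape)
            swd, dswd = _swd_core(zf, prior, self.config.n_projections, rng,
                                  want_grad_a=True)
            total = recon + self.config.lam * swd
            comps["recon"] = recon
            comps["swd"] = swd

        if not math.isfinite(total):
            raise FloatingPointError("non-finite training loss")

        dg = self.dec_convs.backward(dxhat)
        dz = self.dec_head.backward(dg)

        if self.kind == "vae":
            dmu = dz + self.config.beta * mu / n_elem
            dlogvar = dz * eps * 0.5 * sigma + self.config.beta * 0.5 * (sigma**2 - 1.0) / n_elem
            dcode = np.concatenate([dmu, dlogvar], axis=1)
        elif self.kind == "swae":
            dcode = dz + self.config.lam * dswd.reshape(z.shape)
        else:
            dcode = dz

        dh = self.enc_head.backward(dcode)
        self.enc_convs.backward(dh)
        comps["loss"] = float(total)
        return comps


def build_model(kind: str, seed: int = 0, **kwargs) -> ReconstructionModel:
    """Convenience constructor: ``build_model('swae', image_size=(64, 64))``."""
    return ReconstructionModel(ModelConfig(kind=kind, **kwargs), seed=seed)


# ---------------------------------------------------------------------------
# checkpoints (architecture config embedded in a single .npz archive)
# ---------------------------------------------------------------------------

def _state_arrays(model: ReconstructionModel) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    flat: list = []
    for m in model._modules:
        flat.extend(m.layers)
    for i, layer in enumerate(flat):
        for name, value in layer.params.items():
            arrays[f"layer{i}.{name}"] = value
        if isinstance(layer, BatchNorm2d):
            arrays[f"layer{i}.running_mean"] = layer.running_mean
            arrays[f"layer{i}.running_var"] = layer.running_var
    return arrays


def save_checkpoint(model: ReconstructionModel, path) -> None:
    """Save parameters + running stats + architecture config to one file."""
    arrays = _state_arrays(model)
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ReconstructionModel:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["image_size"] = tuple(cfg_dict["image_size"])
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        model = ReconstructionModel(ModelConfig(**cfg_dict), seed=0)
        flat: list = []
        for m in model._modules:
            flat.extend(m.layers)
        for i, layer in enumerate(flat):
            for name in layer.params:
                layer.params[name] = data[f"layer{i}.{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = data[f"layer{i}.running_mean"].copy()
                layer.running_var = data[f"layer{i}.running_var"].copy()
    return model
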