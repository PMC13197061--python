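"""Spherical UNet denoiser with anatomical and demographic conditioning.

The network operates on per-vertex feature maps of an icosphere.  Convolution
is defined on the 1-ring neighborhood: each vertex gathers
``[self, 6 ordered ring neighbors]`` (pentagons repeat the center in the pad
slot) into 7 taps contracted with a learned kernel.  Pooling keeps the
coarse-order vertex prefix; up-pooling zero-pads the inserted vertices.

Conditioning follows the conditional-DDPM recipe: the gyral/sulcal
segmentation mask is concatenated to the input channels, while age and sex
each pass through a small perceptron whose output is summed into the
sinusoidal time embedding; ResBlocks inject the combined embedding through a
scale-shift (FiLM) modulation.  Self-attention over vertices is applied at
the two coarsest levels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import IcoSphere, icosphere_hierarchy, n_vertices_at_order
from .nn import Adam, Module, Tensor, concat, group_norm, no_grad

__all__ = [
    "DenoiserConfig",
    "ConditionSet",
    "SphericalUNet",
    "spherical_conv",
    "time_embedding",
    "sinusoidal_embedding",
]


@dataclass
class DenoiserConfig:
    """Architecture hyper-parameters of the spherical UNet.

    ``hidden_dims`` gives one width per level; the full-scale configuration is
    ``(128, 256, 512)`` on an order-6 sphere, while synthetic desk-scale runs
    default to narrow widths on order 2.  ``attention_levels`` indexes levels
    from fine (0) to coarse; the default places attention on the two coarsest.
    """

    base_order: int = 2
    in_channels: int = 1
    out_channels: int = 1
    mask_channels: int = 1
    n_levels: int = 3
    hidden_dims: tuple = (16, 32, 48)
    resblocks_per_level: int = 2
    attention_levels: tuple = (1, 2)
    time_embed_dim: int = 64
    use_mask: bool = True
    use_demographics: bool = True
    groups: int = 8

    def __post_init__(self):
        if len(self.hidden_dims) != self.n_levels:
            raise ValueError("hidden_dims length must equal n_levels")
        if self.n_levels > self.base_order + 1:
            raise ValueError("n_levels may not exceed base_order + 1")

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        d = dict(d)
        for k in ("hidden_dims", "attention_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ConditionSet:
    """Per-subject conditioning inputs.

    ``mask`` is the per-vertex gyral/sulcal segmentation, shape ``(B, V)`` or
    ``(B, V, Cm)``; binary masks are encoded as a single channel in
    ``{-1, +1}``.  ``age`` is in the unit-scaled convention (years / 100) and
    ``sex`` is 0 (female) / 1 (male).
    """

    mask: np.ndarray | None = None
    age: np.ndarray | None = None
    sex: np.ndarray | None = None

    def mask_channels(self, n_batch: int, n_vertices: int) -> np.ndarray | None:
        if self.mask is None:
            return None
        m = np.asarray(self.mask, dtype=np.float32)
        if m.ndim == 1:
            m = np.broadcast_to(m[None], (n_batch, m.shape[0])).copy()
        if m.ndim == 2:
            m = m[:, :, None]
        if set(np.unique(m)) <= {0.0, 1.0}:
            m = 2.0 * m - 1.0
        return m


def sinusoidal_embedding(t, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Standard sinusoidal position encoding of (integer) diffusion steps.

    Frequencies form a geometric ladder from period ``2*pi`` down to
    ``2*pi*max_period``; returns shape ``(B, dim)``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb.astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init=False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)
        self.w = Tensor(w)
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading dims so BLAS sees one large GEMM
        if x.ndim > 2:
            lead = x.shape[:-1]
            flat = x.reshape(int(np.prod(lead)), x.shape[-1])
            return (flat @ self.w + self.b).reshape(*lead, self.w.shape[1])
        return x @ self.w + self.b


class SphConv(Module):
    """1-ring spherical convolution: 7 taps x input channels -> output channels."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init=False):
        fan_in = 7 * n_in
        if zero_init:
            w = np.zeros((fan_in, n_out))
        else:
            w = rng.standard_normal((fan_in, n_out)) / np.sqrt(fan_in)
        self.w = Tensor(w)
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor, gather_idx: np.ndarray) -> Tensor:
        B, V, C = x.shape
        taps = x.gather_vertices(gather_idx)          # (B, V, 7, C)
        flat = taps.reshape(B * V, 7 * C)             # one large GEMM
        out = flat @ self.w + self.b
        return out.reshape(B, V, self.w.shape[1])


def spherical_conv(
    features: np.ndarray, weights: np.ndarray, ico: IcoSphere, bias: np.ndarray | None = None
) -> np.ndarray:
    """Functional 1-ring convolution on numpy arrays.

    ``features`` is ``(V, C_in)`` or ``(B, V, C_in)``; ``weights`` is
    ``(C_out, C_in, 7)`` with tap 0 the center vertex and taps 1..6 the
    canonically ordered ring (pentagon pad repeats the center).
    """
    single = features.ndim == 2
    if single:
        features = features[None]
    if features.shape[1] != ico.n_vertices:
        raise ValueError("features are not at the sphere's order")
    idx = ico.gather_indices()
    taps = features[:, idx, :]                         # (B, V, 7, C_in)
    out = np.einsum("bvkc,ock->bvo", taps, weights)
    if bias is not None:
        out = out + bias
    return out[0] if single else out


class GroupNorm(Module):
    def __init__(self, n_channels: int, groups: int):
        self.gamma = Tensor(np.ones(n_channels))
        self.beta = Tensor(np.zeros(n_channels))
        self.groups = max(1, min(groups, n_channels))
        while n_channels % self.groups:
            self.groups -= 1

    def __call__(self, x: Tensor) -> Tensor:
        return group_norm(x, self.gamma, self.beta, self.groups)


class ResBlock(Module):
    """Two spherical convolutions with FiLM conditioning and a residual path."""

    def __init__(self, n_in, n_out, emb_dim, groups, rng):
        self.norm1 = GroupNorm(n_in, groups)
        self.conv1 = SphConv(n_in, n_out, rng)
        self.film = Linear(emb_dim, 2 * n_out, rng)
        self.norm2 = GroupNorm(n_out, groups)
        self.conv2 = SphConv(n_out, n_out, rng, zero_init=True)
        self.skip = Linear(n_in, n_out, rng) if n_in != n_out else None
        self.n_out = n_out

    def __call__(self, x: Tensor, emb: Tensor, gather_idx: np.ndarray) -> Tensor:
        h = self.conv1(self.norm1(x).silu(), gather_idx)
        scale, shift = self.film(emb.silu()).split_last((self.n_out, self.n_out))
        B = x.shape[0]
        scale = scale.reshape(B, 1, self.n_out)
        shift = shift.reshape(B, 1, self.n_out)
        h = self.norm2(h) * (scale + 1.0) + shift
        h = self.conv2(h.silu(), gather_idx)
        res = x if self.skip is None else self.skip(x)
        return h + res


class Attention(Module):
    """Single-head dot-product self-attention over the vertices of one level."""

    def __init__(self, n_channels, groups, rng):
        self.norm = GroupNorm(n_channels, groups)
        self.qkv = Linear(n_channels, 3 * n_channels, rng)
        self.proj = Linear(n_channels, n_channels, rng, zero_init=True)
        self.c = n_channels

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.qkv(self.norm(x)).split_last((self.c, self.c, self.c))
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.c))
        att = att.softmax(axis=-1)
        return x + self.proj(att @ v)


class SphericalUNet(Module):
    """Conditional v-prediction network on a hierarchical icosphere.

    Encoder: per level, ``resblocks_per_level`` ResBlocks (attention at the
    designated levels) followed by prefix pooling; the decoder mirrors the
    path with zero-pad up-pooling and skip concatenation.  The output head is
    zero-initialized so training starts from the predict-zero baseline.
    """

    def __init__(self, config: DenoiserConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        self.orders = [cfg.base_order - l for l in range(cfg.n_levels)]
        hierarchy = icosphere_hierarchy(cfg.base_order)
        self.gather_idx = {o: hierarchy[o].gather_indices() for o in self.orders}

        emb = cfg.time_embed_dim
        self.time_mlp1 = Linear(emb, emb, rng)
        self.time_mlp2 = Linear(emb, emb, rng)
        if cfg.use_demographics:
            self.age_mlp1 = Linear(1, emb, rng)
            self.age_mlp2 = Linear(emb, emb, rng, zero_init=True)
            self.sex_mlp1 = Linear(1, emb, rng)
            self.sex_mlp2 = Linear(emb, emb, rng, zero_init=True)

        c_in = cfg.in_channels + (cfg.mask_channels if cfg.use_mask else 0)
        self.stem = SphConv(c_in, cfg.hidden_dims[0], rng)

        self.down_blocks, self.down_attn = [], []
        w_prev = cfg.hidden_dims[0]
        for l in range(cfg.n_levels):
            w = cfg.hidden_dims[l]
            blocks = []
            for r in range(cfg.resblocks_per_level):
                blocks.append(ResBlock(w_prev if r == 0 else w, w, emb, cfg.groups, rng))
            self.down_blocks.append(blocks)
            self.down_attn.append(
                Attention(w, cfg.groups, rng) if l in cfg.attention_levels else None
            )
            w_prev = w

        self.up_blocks, self.up_attn = [], []
        for l in reversed(range(cfg.n_levels)):
            w = cfg.hidden_dims[l]
            blocks = []
            for r in range(cfg.resblocks_per_level):
                c0 = (w_prev + w) if r == 0 else w  # skip concatenation
                blocks.append(ResBlock(c0, w, emb, cfg.groups, rng))
            self.up_blocks.append(blocks)
            self.up_attn.append(
                Attention(w, cfg.groups, rng) if l in cfg.attention_levels else None
            )
            w_prev = w

        self.out_norm = GroupNorm(cfg.hidden_dims[0], cfg.groups)
        self.out_conv = SphConv(cfg.hidden_dims[0], cfg.out_channels, rng, zero_init=True)

    def parameters(self):
        # base class collects flat attributes and lists of Modules (the
        # attention lists); the nested ResBlock lists are added here, with a
        # de-dup so no parameter is optimized twice
        params = list(super().parameters())
        for group in (self.down_blocks, self.up_blocks):
            for blocks in group:
                for b in blocks:
                    params.extend(b.parameters())
        seen, out = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def _embedding(self, t, conditions: ConditionSet, n_batch: int) -> Tensor:
        cfg = self.config
        te = Tensor(sinusoidal_embedding(t, cfg.time_embed_dim))
        if te.shape[0] == 1 and n_batch > 1:
            te = Tensor(np.repeat(te.data, n_batch, axis=0))
        emb = self.time_mlp2(self.time_mlp1(te).silu())
        if cfg.use_demographics and conditions is not None:
            if conditions.age is not None:
                age = Tensor(np.asarray(conditions.age, np.float32).reshape(-1, 1))
                emb = emb + self.age_mlp2(self.age_mlp1(age).silu())
            if conditions.sex is not None:
                sex = Tensor(np.asarray(conditions.sex, np.float32).reshape(-1, 1))
                emb = emb + self.sex_mlp2(self.sex_mlp1(sex).silu())
        return emb

    def forward(self, xt: np.ndarray, t, conditions: ConditionSet | None) -> Tensor:
        cfg = self.config
        x = np.asarray(xt, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        B, V, _ = x.shape
        if V != n_vertices_at_order(cfg.base_order):
            raise ValueError("input is not at the configured base order")

        if cfg.use_mask:
            if conditions is None or conditions.mask is None:
                raise ValueError("mask conditioning enabled but no mask provided")
            mc = conditions.mask_channels(B, V)
            x = np.concatenate([x, mc], axis=2)

        emb = self._embedding(t, conditions, B)
        h = self.stem(Tensor(x), self.gather_idx[self.orders[0]])

        skips = []
        for l in range(cfg.n_levels):
            gi = self.gather_idx[self.orders[l]]
            for blk in self.down_blocks[l]:
                h = blk(h, emb, gi)
            if self.down_attn[l] is not None:
                h = self.down_attn[l](h)
            skips.append(h)
            if l < cfg.n_levels - 1:
                h = h.take_vertex_prefix(n_vertices_at_order(self.orders[l + 1]))

        for i, l in enumerate(reversed(range(cfg.n_levels))):
            gi = self.gather_idx[self.orders[l]]
            if i > 0:
                h = h.pad_vertices(n_vertices_at_order(self.orders[l]))
            h = concat([h, skips[l]], axis=-1)
            for blk in self.up_blocks[i]:
                h = blk(h, emb, gi)
            if self.up_attn[i] is not None:
                h = self.up_attn[i](h)

        out = self.out_conv(self.out_norm(h).silu(), self.gather_idx[self.orders[0]])
        return out

    def predict_v(self, xt: np.ndarray, t, conditions: ConditionSet | None) -> np.ndarray:
        """Inference-mode velocity prediction (no gradient tape)."""
        with no_grad():
            out = self.forward(xt, t, conditions).data.astype(np.float64)
        return out if np.asarray(xt).ndim == 3 else out[0]


def time_embedding(t, dim: int, rng_or_net=None) -> np.ndarray:
    """Sinusoidal step embedding followed by the network's two-layer MLP.

    With ``rng_or_net`` absent, a deterministic default MLP (seed 0) is used;
    passing a :class:`SphericalUNet` evaluates that network's own time MLP.
    """
    if isinstance(rng_or_net, SphericalUNet):
        net = rng_or_net
        with no_grad():
            te = Tensor(sinusoidal_embedding(t, net.config.time_embed_dim))
            return net.time_mlp2(net.time_mlp1(te).silu()).data
    rng = np.random.default_rng(0)
    m1, m2 = Linear(dim, dim, rng), Linear(dim, dim, rng)
    with no_grad():
        te = Tensor(sinusoidal_embedding(t, dim))
        return m2(m1(te).silu()).data


def train_denoiser(
    net: SphericalUNet,
    x0: np.ndarray,
    conditions: ConditionSet | None,
    sched,
    n_steps: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    weight_decay: float = 0.0,
    augment_perms: np.ndarray | None = None,
    log_every: int = 0,
) -> list:
    """Train the network with the v-space diffusion objective.

    Per step: draw a batch of subjects, per-item uniform t and fresh noise,
    minimize MSE between the predicted and exact velocity with Adam.  When
    ``augment_perms`` (K, V) is given, each batch item is passed through a
    random one of the K vertex permutations (features and mask jointly) —
    exact augmentation when the training distribution is isotropic on the
    sphere.  Returns the per-step loss history.
    """
    from .diffusion import q_sample, v_target

    n = x0.shape[0]
    opt = Adam(net.parameters(), lr=lr, weight_decay=weight_decay)
    history = []
    for step in range(n_steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        xb = x0[idx]
        mask_b = None if conditions is None or conditions.mask is None else conditions.mask[idx]
        if augment_perms is not None:
            sel = rng.integers(0, len(augment_perms), size=len(idx))
            P = augment_perms[sel]
            xb = np.take_along_axis(xb, P[:, :, None], axis=1)
            if mask_b is not None:
                mask_b = np.take_along_axis(mask_b, P, axis=1)
        t = rng.integers(1, sched.T + 1, size=len(idx))
        eps = rng.standard_normal(xb.shape)
        xt = q_sample(xb, t, eps, sched)
        target = v_target(xb, eps, t, sched)
        cond_b = None
        if conditions is not None:
            cond_b = ConditionSet(
                mask=mask_b,
                age=None if conditions.age is None else conditions.age[idx],
                sex=None if conditions.sex is None else conditions.sex[idx],
            )
        opt.zero_grad()
        v_hat = net.forward(xt, t, cond_b)
        loss = (v_hat - Tensor(target.astype(np.float32))).square().mean()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if log_every and (step + 1) % log_every == 0:
            recent = float(np.mean(history[-log_every:]))
            print(f"step {step + 1:6d}  v-loss {recent:.4f}")
    return history
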