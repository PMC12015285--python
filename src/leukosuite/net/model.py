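"""A scaled-down dual-encoder attention U-shaped classification network.

Two encoders read the same image.  Channel A is a residual encoder: each
stage stacks 3×3 convolutions with an identity (or 1×1-projected) shortcut
and ends in 2×2 max pooling, and its pre-pool feature maps feed the decoder
as skip connections.  Channel B is a dilated encoder: each stage applies
3×3 convolutions at dilation rates (1, 2, 3) in parallel, fuses them by
concatenation and a 1×1 convolution, and pools.  The bottleneck
concatenates both encoders; multiplicative attention over the flattened
bottleneck positions (query = global-average feature) pools a context
vector.  A U-shaped decoder upsamples back to full resolution with the
channel-A skips.  The classification head is a fully connected softmax
layer over the attention context concatenated with the global-average
decoder feature.

Channel widths double per stage from ``base_width``.  Both the attention
pooling and channel B can be switched off for ablations; doing so changes
the parameter count but preserves every output contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import (
    Attention,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    Upsample2,
    softmax,
)

__all__ = ["NetConfig", "ModelBundle", "DualEncoderAttentionUNet", "build_model", "residual_apply", "predict"]


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``stage_convs`` gives the number of 3×3 convolutions per encoder stage
    (the full profile is ``(2, 2, 3, 3, 3)``); the spatial size must be
    divisible by ``2**len(stage_convs)``.  ``loss_weight_v`` weights the
    BCE term of the combined loss.  ``dropout`` is applied before the head
    during training.
    """

    input_size: tuple[int, int, int] = (32, 32, 1)
    n_classes: int = 3
    base_width: int = 8
    stage_convs: tuple[int, ...] = (2, 2, 3, 3, 3)
    dilation_rates: tuple[int, ...] = (1, 2, 3)
    attention: bool = True
    use_channel_b: bool = True
    loss_weight_v: float = 1.0
    dropout: float = 0.4

    def __post_init__(self) -> None:
        h, w, _ = self.input_size
        n = len(self.stage_convs)
        if h % (2**n) or w % (2**n):
            raise ValueError(f"input size {h}x{w} not divisible by 2^{n}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be positive")

    @classmethod
    def small(cls, **kw) -> "NetConfig":
        """Desk-scale profile: 32×32 inputs, two stages, width 8."""
        kw.setdefault("stage_convs", (2, 2))
        return cls(**kw)


def residual_apply(block, x: np.ndarray) -> np.ndarray:
    """Identity-shortcut residual application: ``block(x) + x``.

    ``block`` must preserve the spatial and channel shape; a mismatched
    output is an error (use a projection inside the block instead).
    """
    gx = block(x)
    if gx.shape != x.shape:
        raise ValueError(f"residual shapes differ: {gx.shape} vs {x.shape}")
    return gx + x


class _ResidualStage:
    """Conv stack + shortcut (1×1 projection when channels change) + pool."""

    def __init__(self, cin: int, cout: int, n_convs: int, rng):
        self.convs = []
        self.relus = []
        c = cin
        for _ in range(n_convs):
            self.convs.append(Conv2D(c, cout, 3, rng=rng))
            self.relus.append(ReLU())
            c = cout
        self.proj = Conv2D(cin, cout, 1, rng=rng) if cin != cout else None
        self.layers = self.convs + ([self.proj] if self.proj else [])

    def forward(self, x, train):
        self._x = x
        h = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(h, train), train)
        sc = self.proj.forward(x, train) if self.proj else x
        return h + sc

    def backward(self, dy):
        dx = self.proj.backward(dy) if self.proj else dy.copy()
        dh = dy
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            dh = conv.backward(relu.backward(dh))
        return dx + dh


class _DilatedStage:
    """Parallel dilated convs (rates r) fused by concat + 1×1 conv."""

    def __init__(self, cin: int, cout: int, rates: tuple[int, ...], rng):
        self.branches = [Conv2D(cin, cout, 3, dilation=r, rng=rng) for r in rates]
        self.relu_b = [ReLU() for _ in rates]
        self.fuse = Conv2D(cout * len(rates), cout, 1, rng=rng)
        self.relu_f = ReLU()
        self.layers = self.branches + [self.fuse]

    def forward(self, x, train):
        outs = [r.forward(b.forward(x, train), train) for b, r in zip(self.branches, self.relu_b)]
        cat = np.concatenate(outs, axis=-1)
        self._widths = [o.shape[-1] for o in outs]
        return self.relu_f.forward(self.fuse.forward(cat, train), train)

    def backward(self, dy):
        dcat = self.fuse.backward(self.relu_f.backward(dy))
        dx = 0.0
        start = 0
        for b, r, wdt in zip(self.branches, self.relu_b, self._widths):
            dx = dx + b.backward(r.backward(dcat[..., start : start + wdt]))
            start += wdt
        return dx


class DualEncoderAttentionUNet:
    """The assembled network; see the module docstring for the wiring."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        h, w, cin = cfg.input_size
        widths = [cfg.base_width * 2**i for i in range(len(cfg.stage_convs))]
        self.widths = widths

        self.stages_a, self.pools_a = [], []
        c = cin
        for wd, n in zip(widths, cfg.stage_convs):
            self.stages_a.append(_ResidualStage(c, wd, n, rng))
            self.pools_a.append(MaxPool2())
            c = wd
        if cfg.use_channel_b:
            self.stages_b, self.pools_b = [], []
            c = cin
            for wd in widths:
                self.stages_b.append(_DilatedStage(c, wd, cfg.dilation_rates, rng))
                self.pools_b.append(MaxPool2())
                c = wd
        else:
            self.stages_b, self.pools_b = [], []

        bott_c = widths[-1] * (2 if cfg.use_channel_b else 1)
        self.attn = Attention() if cfg.attention else None

        self.ups, self.dec_convs, self.dec_relus = [], [], []
        c = bott_c
        for wd in reversed(widths):
            self.ups.append(Upsample2())
            self.dec_convs.append(Conv2D(c + wd, wd, 3, rng=rng))
            self.dec_relus.append(ReLU())
            c = wd
        self.gap_dec = GlobalAvgPool()

        head_in = widths[0] + (bott_c if cfg.attention else 0)
        self.dropout = Dropout(cfg.dropout, self.drop_rng)
        self.head = Dense(head_in, cfg.n_classes, rng=rng)

    # -- parameter bookkeeping -------------------------------------------

    def _layer_map(self) -> dict:
        out = {}
        for i, st in enumerate(self.stages_a):
            for j, ly in enumerate(st.layers):
                out[f"enc_a{i}_conv{j}"] = ly
        for i, st in enumerate(self.stages_b):
            for j, ly in enumerate(st.layers):
                out[f"enc_b{i}_conv{j}"] = ly
        for i, ly in enumerate(self.dec_convs):
            out[f"dec{i}_conv"] = ly
        out["head"] = self.head
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, ly in self._layer_map().items()
            for k, v in ly.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, ly in self._layer_map().items()
            for k, v in ly.grads.items()
        }

    def load_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self._layer_map()
        for key, val in params.items():
            name, pname = key.rsplit(".", 1)
            own[name].params[pname] = np.array(val)

    def zero_grad(self) -> None:
        for ly in self._layer_map().values():
            ly.zero_grad()

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities ``(B, n_classes)``; rows sum to 1."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != self.cfg.input_size:
            raise ValueError(f"input shape {x.shape[1:]} != config {self.cfg.input_size}")
        x = 2.0 * x - 1.0  # centre [0,1] intensities for conditioning
        skips = []
        ha = x
        for st, pool in zip(self.stages_a, self.pools_a):
            ha = st.forward(ha, train)
            skips.append(ha)
            ha = pool.forward(ha, train)
        if self.cfg.use_channel_b:
            hb = x
            for st, pool in zip(self.stages_b, self.pools_b):
                hb = pool.forward(st.forward(hb, train), train)
            bott = np.concatenate([ha, hb], axis=-1)
            self._split_b = ha.shape[-1]
        else:
            bott = ha
        self._bott_shape = bott.shape

        z = self.attn.forward(bott, train) if self.attn else None

        hd = bott
        for up, conv, relu, skip in zip(self.ups, self.dec_convs, self.dec_relus, reversed(skips)):
            hd = up.forward(hd, train)
            hd = np.concatenate([hd, skip], axis=-1)
            conv._skip_width = skip.shape[-1]
            hd = relu.forward(conv.forward(hd, train), train)
        g = self.gap_dec.forward(hd, train)

        feat = np.concatenate([z, g], axis=-1) if z is not None else g
        self._feat_split = z.shape[-1] if z is not None else 0
        logits = self.head.forward(self.dropout.forward(feat, train), train)
        self._probs = softmax(logits, axis=-1)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dfeat = self.dropout.backward(self.head.backward(dlogits))
        ns = self._feat_split
        if ns:
            dz, dg = dfeat[:, :ns], dfeat[:, ns:]
        else:
            dz, dg = None, dfeat
        dhd = self.gap_dec.backward(dg)
        dskips = [None] * len(self.stages_a)
        for idx in range(len(self.dec_convs) - 1, -1, -1):
            conv, relu, up = self.dec_convs[idx], self.dec_relus[idx], self.ups[idx]
            dcat = conv.backward(relu.backward(dhd))
            sw = conv._skip_width
            dskips[len(self.stages_a) - 1 - idx] = dcat[..., -sw:]
            dhd = up.backward(dcat[..., :-sw])
        dbott = dhd
        if dz is not None:
            dbott = dbott + self.attn.backward(dz)

        if self.cfg.use_channel_b:
            da, db = dbott[..., : self._split_b], dbott[..., self._split_b :]
            for st, pool in zip(reversed(self.stages_b), reversed(self.pools_b)):
                db = st.backward(pool.backward(db))
        else:
            da = dbott
        for i in range(len(self.stages_a) - 1, -1, -1):
            da = self.pools_a[i].backward(da)
            da = da + dskips[i]
            da = self.stages_a[i].backward(da)


@dataclass
class ModelBundle:
    """Config + parameters + training log; serializable to one ``.npz``."""

    config: NetConfig
    parameters: dict[str, np.ndarray]
    training_log: list[dict] = field(default_factory=list)
    seed: int = 0

    def model(self) -> DualEncoderAttentionUNet:
        net = DualEncoderAttentionUNet(self.config, seed=self.seed)
        net.load_parameters(self.parameters)
        return net

    def save(self, path) -> None:
        cfg = {k: v for k, v in self.config.__dict__.items()}
        cfg["input_size"] = list(cfg["input_size"])
        cfg["stage_convs"] = list(cfg["stage_convs"])
        cfg["dilation_rates"] = list(cfg["dilation_rates"])
        meta = json.dumps({"config": cfg, "log": self.training_log, "seed": self.seed}, sort_keys=True)
        np.savez(Path(path), _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **self.parameters)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            params = {k: data[k] for k in data.files if k != "_meta"}
        cfg = meta["config"]
        cfg["input_size"] = tuple(cfg["input_size"])
        cfg["stage_convs"] = tuple(cfg["stage_convs"])
        cfg["dilation_rates"] = tuple(cfg["dilation_rates"])
        return cls(NetConfig(**cfg), params, meta["log"], meta["seed"])


def build_model(cfg: NetConfig, seed: int = 0) -> ModelBundle:
    """Initialize a network; the parameter set is a pure function of
    (config, seed)."""
    net = DualEncoderAttentionUNet(cfg, seed=seed)
    return ModelBundle(cfg, net.parameters(), [], seed)


def predict(bundle: ModelBundle, images: np.ndarray):
    """Class probabilities and argmax labels for a batch of images."""
    net = bundle.model()
    probs = net.forward(np.asarray(images), train=False)
    return probs, probs.argmax(axis=1)
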