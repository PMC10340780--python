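"""Reference architectures: encoders, decoders, heads, and the ModelBundle.

Two small encoder families are provided, standing in for the CNN and
transformer backbone families at desk scale:

- ``tinyunet-w{W}-l{L}``: a U-shaped convolutional encoder with ``L`` levels
  of width ``W, 2W, ...``; its segmentation decoder uses skip connections.
  The encoder's output stride is ``2**(L-1)``.
- ``pyrattn-w{W}``: a pyramid encoder — a two-stage convolutional stem at
  output stride 4 followed by a single-head self-attention block and an MLP
  block over the token grid.

Every model is a plain composition of :mod:`pslearn.nn.layers` objects with
hand-written backward orchestration, so gradients w.r.t. intermediate
feature maps (needed for Grad-CAM) are available without an autograd tape.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ..errors import ArchMismatchError, ConfigurationError
from .layers import (
    Conv2d,
    GlobalAvgPool,
    GlobalMaxPool,
    LayerNorm,
    Linear,
    MaxPool2,
    ReLU,
    SelfAttention,
    Sequential,
    UpsampleNearest2,
)


def parse_arch_id(arch_id: str) -> tuple[str, dict]:
    m = re.fullmatch(r"tinyunet-w(\d+)-l(\d+)", arch_id)
    if m:
        return "tinyunet", {"width": int(m.group(1)), "levels": int(m.group(2))}
    m = re.fullmatch(r"pyrattn-w(\d+)", arch_id)
    if m:
        return "pyrattn", {"width": int(m.group(1))}
    raise ConfigurationError(f"unknown arch_id {arch_id!r}")


class _Module:
    """Mixin: parameter bookkeeping over an ordered (name, Layer) registry."""

    def named_layers(self) -> list[tuple[str, object]]:
        return self._registry

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._registry:
            for pname, arr in layer.params.items():
                out[f"{name}.{pname}"] = arr
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._registry:
            for pname in layer.params:
                out[f"{name}.{pname}"] = layer.grads.get(pname)
        return out


class TinyUNetEncoder(_Module):
    def __init__(self, width: int, levels: int, in_ch: int = 1, *, rng, dtype=np.float32):
        if levels < 2:
            raise ConfigurationError("tinyunet needs >= 2 levels")
        self.levels = levels
        self.widths = [width * 2**l for l in range(levels)]
        self.out_channels = self.widths[-1]
        self.out_stride = 2 ** (levels - 1)
        self.blocks = []
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        cin = in_ch
        self._registry = []
        for l, cw in enumerate(self.widths):
            c0 = Conv2d(cin, cw, rng=rng, dtype=dtype)
            c1 = Conv2d(cw, cw, rng=rng, dtype=dtype)
            block = Sequential(c0, ReLU(), c1, ReLU())
            self.blocks.append(block)
            self._registry += [(f"b{l}.conv0", c0), (f"b{l}.conv1", c1)]
            cin = cw

    def forward(self, x: np.ndarray):
        skips = []
        h = x
        for l in range(self.levels):
            h = self.blocks[l].forward(h)
            skips.append(h)
            if l < self.levels - 1:
                h = self.pools[l].forward(h)
        return h, skips

    def backward(self, dfeat: np.ndarray, dskips: list | None):
        d = dfeat
        if dskips is not None and dskips[-1] is not None:
            d = d + dskips[-1]
        for l in range(self.levels - 1, -1, -1):
            d = self.blocks[l].backward(d)
            if l > 0:
                d = self.pools[l - 1].backward(d)
                if dskips is not None and dskips[l - 1] is not None:
                    d = d + dskips[l - 1]
        return d


class UNetDecoder(_Module):
    """Upsample + skip-concat decoder ending in a 1x1 conv to one logit map."""

    def __init__(self, encoder: TinyUNetEncoder, *, rng, dtype=np.float32):
        w = encoder.widths
        self.levels = encoder.levels
        self.ups = [UpsampleNearest2() for _ in range(self.levels - 1)]
        self.convs = []
        self.relus = [ReLU() for _ in range(self.levels - 1)]
        self._registry = []
        ch = w[-1]
        for i, l in enumerate(range(self.levels - 2, -1, -1)):
            conv = Conv2d(ch + w[l], w[l], rng=rng, dtype=dtype)
            self.convs.append(conv)
            self._registry.append((f"up{i}.conv", conv))
            ch = w[l]
        self.final = Conv2d(ch, 1, k=1, rng=rng, dtype=dtype)
        self._registry.append(("final", self.final))

    def forward(self, feat: np.ndarray, skips: list) -> np.ndarray:
        h = feat
        self._split = []
        for i, l in enumerate(range(self.levels - 2, -1, -1)):
            h = self.ups[i].forward(h)
            self._split.append(skips[l].shape[1])
            h = np.concatenate([skips[l], h], axis=1)
            h = self.relus[i].forward(self.convs[i].forward(h))
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray):
        d = self.final.backward(dlogits)
        dskips: list = [None] * self.levels
        for i in range(self.levels - 2, -1, -1):
            l = self.levels - 2 - i
            d = self.convs[i].backward(self.relus[i].backward(d))
            sc = self._split[i]
            dskip, dup = d[:, :sc], d[:, sc:]
            if dskips[l] is None:
                dskips[l] = dskip
            else:
                dskips[l] = dskips[l] + dskip
            d = self.ups[i].backward(dup)
        return d, dskips  # d is gradient w.r.t. the deepest feature map


class PyramidAttnEncoder(_Module):
    def __init__(self, width: int, in_ch: int = 1, *, rng, dtype=np.float32):
        c = 2 * width
        self.out_channels = c
        self.out_stride = 4
        s0 = Conv2d(in_ch, width, rng=rng, dtype=dtype)
        s1 = Conv2d(width, c, rng=rng, dtype=dtype)
        self.stem = Sequential(s0, ReLU(), MaxPool2(), s1, ReLU(), MaxPool2())
        self.ln1 = LayerNorm(c, dtype=dtype)
        self.attn = SelfAttention(c, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(c, dtype=dtype)
        self.fc1 = Linear(c, 2 * c, rng=rng, dtype=dtype)
        self.mlp_relu = ReLU()
        self.fc2 = Linear(2 * c, c, rng=rng, dtype=dtype)
        self._registry = [
            ("stem.conv0", s0),
            ("stem.conv1", s1),
            ("ln1", self.ln1),
            ("attn", self.attn),
            ("ln2", self.ln2),
            ("mlp.fc1", self.fc1),
            ("mlp.fc2", self.fc2),
        ]

    def forward(self, x: np.ndarray):
        s = self.stem.forward(x)
        n, c, h, w = s.shape
        self._hw = (h, w)
        t0 = s.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        t1 = t0 + self.attn.forward(self.ln1.forward(t0))
        t2 = t1 + self.fc2.forward(self.mlp_relu.forward(self.fc1.forward(self.ln2.forward(t1))))
        feat = np.ascontiguousarray(t2.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        return feat, None

    def backward(self, dfeat: np.ndarray, daux=None):
        n, c, h, w = dfeat.shape
        dt2 = dfeat.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        dt1 = dt2 + self.ln2.backward(
            self.fc1.backward(self.mlp_relu.backward(self.fc2.backward(dt2)))
        )
        dt0 = dt1 + self.ln1.backward(self.attn.backward(dt1))
        ds = np.ascontiguousarray(dt0.reshape(n, h, w, c).transpose(0, 3, 1, 2))
        return self.stem.backward(ds)


class PlainDecoder(_Module):
    """Skip-free decoder for the pyramid encoder: two upsample-conv stages."""

    def __init__(self, in_channels: int, width: int, *, rng, dtype=np.float32):
        self.up1, self.up2 = UpsampleNearest2(), UpsampleNearest2()
        c0 = Conv2d(in_channels, width, rng=rng, dtype=dtype)
        c1 = Conv2d(width, width, rng=rng, dtype=dtype)
        self.final = Conv2d(width, 1, k=1, rng=rng, dtype=dtype)
        self.c0, self.c1 = c0, c1
        self.r0, self.r1 = ReLU(), ReLU()
        self._registry = [("conv0", c0), ("conv1", c1), ("final", self.final)]

    def forward(self, feat: np.ndarray, skips=None) -> np.ndarray:
        h = self.r0.forward(self.c0.forward(self.up1.forward(feat)))
        h = self.r1.forward(self.c1.forward(self.up2.forward(h)))
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray):
        d = self.final.backward(dlogits)
        d = self.up2.backward(self.c1.backward(self.r1.backward(d)))
        d = self.up1.backward(self.c0.backward(self.r0.backward(d)))
        return d, None


class ClassifierHead(_Module):
    """Global pooling + linear layer.

    Max pooling is the default: a small lesion activates few positions of
    the deepest feature map, and averaging dilutes that signal roughly by
    the map-to-lesion area ratio, whereas the max responds to a single
    strong activation anywhere.
    """

    def __init__(self, in_channels: int, n_classes: int, *, rng, dtype=np.float32,
                 pooling: str = "max"):
        if pooling not in ("max", "avg"):
            raise ConfigurationError(f"pooling must be 'max' or 'avg', got {pooling!r}")
        self.pool = GlobalMaxPool() if pooling == "max" else GlobalAvgPool()
        self.fc = Linear(in_channels, n_classes, rng=rng, dtype=dtype)
        self._registry = [("fc", self.fc)]

    def forward(self, feat: np.ndarray, skips=None) -> np.ndarray:
        return self.fc.forward(self.pool.forward(feat))

    def backward(self, dlogits: np.ndarray):
        return self.pool.backward(self.fc.backward(dlogits)), None


@dataclass
class EncoderState:
    """Transferable encoder weights tagged with their architecture id."""

    arch_id: str
    params: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ModelBundle:
    """Encoder + task head with merged parameter/gradient views.

    ``task`` is ``"segmentation"`` or ``"classification"``.  The bundle's
    state (``get_state``/``set_state``) round-trips bit-exactly; the last
    encoder feature map of a forward pass is cached on ``last_feat`` (used
    by Grad-CAM).
    """

    encoder: object
    head: object
    arch_id: str
    task: str
    n_classes: int | None = None
    class_names: tuple | None = None
    last_feat: np.ndarray | None = field(default=None, repr=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feat, aux = self.encoder.forward(x)
        self.last_feat = feat
        self._aux = aux
        return self.head.forward(feat, aux)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dfeat, daux = self.head.backward(dlogits)
        return self.encoder.backward(dfeat, daux)

    def params(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.params().items()}
        out.update({f"head.{k}": v for k, v in self.head.params().items()})
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.grads().items()}
        out.update({f"head.{k}": v for k, v in self.head.grads().items()})
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise ArchMismatchError(f"state keys do not match architecture: {sorted(missing)[:5]}")
        for k, v in state.items():
            if params[k].shape != v.shape:
                raise ArchMismatchError(f"shape mismatch for {k}: {params[k].shape} vs {v.shape}")
            params[k][...] = v

    def encoder_state(self) -> EncoderState:
        return EncoderState(self.arch_id, {k: v.copy() for k, v in self.encoder.params().items()})

    def load_encoder_state(self, state: EncoderState) -> None:
        if state.arch_id != self.arch_id:
            raise ArchMismatchError(
                f"encoder state arch {state.arch_id!r} != bundle arch {self.arch_id!r}"
            )
        params = self.encoder.params()
        if set(state.params) != set(params):
            raise ArchMismatchError("encoder state keys do not match architecture")
        for k, v in state.params.items():
            if params[k].shape != v.shape:
                raise ArchMismatchError(f"shape mismatch for encoder.{k}")
            params[k][...] = v


def _build_encoder(arch_id: str, rng, dtype):
    family, kw = parse_arch_id(arch_id)
    if family == "tinyunet":
        return TinyUNetEncoder(kw["width"], kw["levels"], rng=rng, dtype=dtype)
    return PyramidAttnEncoder(kw["width"], rng=rng, dtype=dtype)


def build_segmenter(arch_id: str = "tinyunet-w8-l3", seed: int = 0, dtype=np.float32) -> ModelBundle:
    """Construct a randomly initialized segmentation bundle."""
    rng = np.random.default_rng(seed)
    family, kw = parse_arch_id(arch_id)
    encoder = _build_encoder(arch_id, rng, dtype)
    if family == "tinyunet":
        head = UNetDecoder(encoder, rng=rng, dtype=dtype)
    else:
        head = PlainDecoder(encoder.out_channels, kw["width"], rng=rng, dtype=dtype)
    return ModelBundle(encoder, head, arch_id, "segmentation")


def build_classifier(
    arch_id: str = "tinyunet-w8-l3",
    n_classes: int = 2,
    seed: int = 0,
    encoder_state: EncoderState | None = None,
    dtype=np.float32,
) -> ModelBundle:
    """Construct a classification bundle, optionally from pretrained encoder weights.

    Without ``encoder_state`` the encoder keeps its random initialization —
    the "without pretraining" baseline.
    """
    rng = np.random.default_rng(seed)
    encoder = _build_encoder(arch_id, rng, dtype)
    head = ClassifierHead(encoder.out_channels, n_classes, rng=rng, dtype=dtype)
    bundle = ModelBundle(encoder, head, arch_id, "classification", n_classes=n_classes)
    if encoder_state is not None:
        bundle.load_encoder_state(encoder_state)
    return bundle
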