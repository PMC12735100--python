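"""The MACNeXt network: stem, dual-activation main block, downsampling, head.

The network is a compact, fully convolutional ConvNeXt-style classifier:

* **Stem** — 3x3 convolution (48 filters, stride 2) + BN, then a grouped 3x3
  convolution (96 filters, stride 2) + GELU + BN. A 224x224x3 image becomes a
  56x56x96 feature map.
* **Main block** (width F, shape preserving) — parallel grouped 3x3 and 1x1
  convolutions each with BN, concatenated to 2F channels (inverted
  bottleneck); a 1x1 expansion at 2F; GELU; a 1x1 squeeze back to F with BN;
  a residual add with the block input; parallel grouped 1x1 + GELU and
  grouped 1x1 + ReLU branches, summed and batch-normalized; a second
  residual add.
* **Downsampling** — grouped 3x3 stride-2 convolution F -> 2F, then BN;
  halves each spatial side and doubles the channel count.
* **Head** — global average pooling, a fully connected layer to ``n`` logits,
  softmax.

Stages run R = [1, 1, 3, 1] main blocks at widths F = [96, 192, 384, 768],
with downsampling after every stage but the last. No convolution carries a
bias (each is followed by BN, whose shift makes a bias redundant); the FC
layer does. With the reference group convention the network holds 4,436,808
learnable scalars (~4.4 million).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import ConfigError, MACNeXtConfig

__all__ = [
    "ShapeTrace",
    "ParamBreakdown",
    "PredictionBatch",
    "MACNeXt",
    "build_model",
    "trace_shapes",
    "count_parameters",
    "stem_forward",
    "macnext_block_forward",
    "downsample_forward",
    "head_forward",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# Result records
# --------------------------------------------------------------------------

@dataclass
class ShapeTrace:
    """Ordered per-stage output dimensions (label, H, W, C)."""

    entries: list[tuple[str, int, int, int]]

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other):
        return isinstance(other, ShapeTrace) and self.entries == other.entries

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "out_height": h, "out_width": w, "out_channels": c}
            for s, h, w, c in self.entries
        ]

    def __str__(self) -> str:
        width = max(len(s) for s, *_ in self.entries)
        lines = [f"{s:<{width}}  {h} x {w} x {c}" for s, h, w, c in self.entries]
        return "\n".join(lines)


@dataclass
class ParamBreakdown:
    """Per-layer learnable-scalar counts and their total."""

    entries: list[tuple[str, int]]
    total: int = field(init=False)

    def __post_init__(self):
        self.total = int(sum(c for _, c in self.entries))

    @property
    def total_millions(self) -> float:
        return round(self.total / 1e6, 1)

    def __str__(self) -> str:
        width = max(len(s) for s, _ in self.entries)
        lines = [f"{s:<{width}}  {c:>12,}" for s, c in self.entries]
        lines.append(f"{'total':<{width}}  {self.total:>12,}  ({self.total_millions}M)")
        return "\n".join(lines)


@dataclass
class PredictionBatch:
    """Softmax probabilities (N, n) and per-sample argmax labels."""

    probabilities: np.ndarray
    predicted_label: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probabilities)
        if p.ndim != 2:
            raise ValueError("probabilities must be a (samples, classes) array")
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each probability row must be nonnegative and sum to 1")
        self.probabilities = p
        self.predicted_label = p.argmax(axis=1)


# --------------------------------------------------------------------------
# Composite modules
# --------------------------------------------------------------------------

def _check_input(x: np.ndarray, channels: int, who: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"{who}: expected an NCHW tensor, got shape {x.shape}")
    if x.shape[1] != channels:
        raise ValueError(f"{who}: expected {channels} channels, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{who}: input contains non-finite values")
    return x


class Stem:
    """Two stride-2 convolutions: C(48)+BN, then GC(96)+GELU+BN."""

    def __init__(self, config: MACNeXtConfig, rng: np.random.Generator):
        w0, w1 = config.stem_widths
        cin = config.input_channels
        self.config = config
        self.conv1 = nn.Conv2d(cin, w0, 3, stride=2, name="stem.conv1", rng=rng)
        self.bn1 = nn.BatchNorm2d(w0, config.bn_epsilon, config.bn_momentum, name="stem.bn1")
        g = config.groups_for(w0, w1)
        self.conv2 = nn.Conv2d(w0, w1, 3, stride=2, groups=g, name="stem.conv2", rng=rng)
        self.act = nn.GELU()
        self.bn2 = nn.BatchNorm2d(w1, config.bn_epsilon, config.bn_momentum, name="stem.bn2")
        self._order = [self.conv1, self.bn1, self.conv2, self.act, self.bn2]

    def layers(self):
        return list(self._order)

    def forward(self, x, training=False):
        x = _check_input(x, self.config.input_channels, "stem")
        if min(x.shape[2], x.shape[3]) < 4:
            raise ValueError("stem: spatial sides must be >= 4")
        for layer in self._order:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self._order):
            grad = layer.backward(grad)
        return grad


class MACNeXtBlock:
    """Shape-preserving dual-activation residual block at width F."""

    def __init__(self, width: int, config: MACNeXtConfig, rng: np.random.Generator, name: str = "block"):
        f = width
        cfg = config
        eps, mom = cfg.bn_epsilon, cfg.bn_momentum
        self.width = f
        self.name = name
        g_ff = cfg.groups_for(f, f)
        self.conv3 = nn.Conv2d(f, f, 3, groups=g_ff, name=f"{name}.gc3x3", rng=rng)
        self.bn3 = nn.BatchNorm2d(f, eps, mom, name=f"{name}.bn3x3")
        self.conv1 = nn.Conv2d(f, f, 1, groups=g_ff, name=f"{name}.gc1x1", rng=rng)
        self.bn1 = nn.BatchNorm2d(f, eps, mom, name=f"{name}.bn1x1")
        g_exp = cfg.groups_for(2 * f, 2 * f) if cfg.expansion_grouped else 1
        self.expand = nn.Conv2d(2 * f, 2 * f, 1, groups=g_exp, name=f"{name}.expand", rng=rng)
        self.gelu_mid = nn.GELU()
        g_sq = cfg.groups_for(2 * f, f) if cfg.squeeze_grouped else 1
        self.squeeze = nn.Conv2d(2 * f, f, 1, groups=g_sq, name=f"{name}.squeeze", rng=rng)
        self.bn_sq = nn.BatchNorm2d(f, eps, mom, name=f"{name}.bn_squeeze")
        self.conv_g = nn.Conv2d(f, f, 1, groups=g_ff, name=f"{name}.gc_gelu", rng=rng)
        self.gelu_br = nn.GELU()
        self.conv_r = nn.Conv2d(f, f, 1, groups=g_ff, name=f"{name}.gc_relu", rng=rng)
        self.relu_br = nn.ReLU()
        self.bn_fuse = nn.BatchNorm2d(f, eps, mom, name=f"{name}.bn_fuse")

    def layers(self):
        return [
            self.conv3, self.bn3, self.conv1, self.bn1, self.expand, self.gelu_mid,
            self.squeeze, self.bn_sq, self.conv_g, self.gelu_br, self.conv_r,
            self.relu_br, self.bn_fuse,
        ]

    def forward(self, x, training=False):
        x = _check_input(x, self.width, self.name)
        f = self.width
        p1 = self.bn3.forward(self.conv3.forward(x, training), training)
        p2 = self.bn1.forward(self.conv1.forward(x, training), training)
        cat = np.concatenate([p1, p2], axis=1)  # 2F channels
        e = self.gelu_mid.forward(self.expand.forward(cat, training), training)
        s = self.bn_sq.forward(self.squeeze.forward(e, training), training)
        r1 = x + s  # first residual
        gb = self.gelu_br.forward(self.conv_g.forward(r1, training), training)
        rb = self.relu_br.forward(self.conv_r.forward(r1, training), training)
        fused = self.bn_fuse.forward(gb + rb, training)
        return r1 + fused  # second residual

    def backward(self, grad):
        f = self.width
        dr1 = grad.copy()
        dfused = self.bn_fuse.backward(grad)
        dr1 += self.conv_g.backward(self.gelu_br.backward(dfused))
        dr1 += self.conv_r.backward(self.relu_br.backward(dfused))
        dx = dr1.copy()
        de = self.squeeze.backward(self.bn_sq.backward(dr1))
        dcat = self.expand.backward(self.gelu_mid.backward(de))
        dx += self.conv3.backward(self.bn3.backward(dcat[:, :f]))
        dx += self.conv1.backward(self.bn1.backward(dcat[:, f:]))
        return dx


class Downsample:
    """Grouped 3x3 stride-2 convolution F -> 2F, then BN."""

    def __init__(self, width: int, config: MACNeXtConfig, rng: np.random.Generator, name: str = "ds"):
        f = width
        self.width = f
        self.name = name
        g = config.groups_for(f, 2 * f)
        self.conv = nn.Conv2d(f, 2 * f, 3, stride=2, groups=g, name=f"{name}.gc3x3", rng=rng)
        self.bn = nn.BatchNorm2d(2 * f, config.bn_epsilon, config.bn_momentum, name=f"{name}.bn")

    def layers(self):
        return [self.conv, self.bn]

    def forward(self, x, training=False):
        x = _check_input(x, self.width, self.name)
        return self.bn.forward(self.conv.forward(x, training), training)

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(grad))


class Head:
    """Global average pooling, FC to n logits, softmax."""

    def __init__(self, config: MACNeXtConfig, rng: np.random.Generator):
        self.in_channels = config.stage_widths[-1]
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(self.in_channels, config.num_classes, name="head.fc", rng=rng)

    def layers(self):
        return [self.gap, self.fc]

    def forward(self, x, training=False):
        x = _check_input(x, self.in_channels, "head")
        return self.fc.forward(self.gap.forward(x, training), training)

    def backward(self, grad):
        return self.gap.backward(self.fc.backward(grad))


# --------------------------------------------------------------------------
# Full network
# --------------------------------------------------------------------------

class MACNeXt:
    """The composed network. Build via :func:`build_model`."""

    def __init__(self, config: MACNeXtConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.stem = Stem(config, rng)
        self.stages: list[list[MACNeXtBlock]] = []
        self.downsamples: list[Downsample] = []
        n_stages = len(config.stage_widths)
        for s, (f, r) in enumerate(zip(config.stage_widths, config.stage_repeats)):
            blocks = [
                MACNeXtBlock(f, config, rng, name=f"stage{s + 1}.block{b + 1}")
                for b in range(r)
            ]
            self.stages.append(blocks)
            if s < n_stages - 1:
                self.downsamples.append(Downsample(f, config, rng, name=f"ds{s + 1}"))
        self.head = Head(config, rng)

    # -- plumbing ---------------------------------------------------------
    def modules(self):
        mods = [self.stem]
        for s, blocks in enumerate(self.stages):
            mods.extend(blocks)
            if s < len(self.downsamples):
                mods.append(self.downsamples[s])
        mods.append(self.head)
        return mods

    def parameters(self) -> list[nn.Parameter]:
        params = []
        for mod in self.modules():
            for layer in mod.layers():
                params.extend(layer.parameters())
        return params

    def buffers(self) -> dict[str, np.ndarray]:
        bufs: dict[str, np.ndarray] = {}
        for mod in self.modules():
            for layer in mod.layers():
                bufs.update(layer.buffers())
        return bufs

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    # -- compute ----------------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self.stem.forward(x, training)
        for s, blocks in enumerate(self.stages):
            for block in blocks:
                x = block.forward(x, training)
            if s < len(self.downsamples):
                x = self.downsamples[s].forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = self.head.backward(dlogits)
        for s in range(len(self.stages) - 1, -1, -1):
            if s < len(self.downsamples):
                grad = self.downsamples[s].backward(grad)
            for block in reversed(self.stages[s]):
                grad = block.backward(grad)
        return self.stem.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> PredictionBatch:
        """Inference-mode forward over ``x`` in mini-batches."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        probs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i : i + batch_size], training=False)
            probs.append(nn.softmax(logits, axis=1))
        return PredictionBatch(np.concatenate(probs, axis=0))

    def observed_trace(self, batch: np.ndarray | None = None) -> ShapeTrace:
        """Shape trace measured by actually running a batch through the net."""
        cfg = self.config
        if batch is None:
            batch = np.zeros(
                (1, cfg.input_channels, cfg.input_height, cfg.input_width), np.float32
            )
        entries = []
        x = self.stem.forward(batch, training=False)
        entries.append(("stem", x.shape[2], x.shape[3], x.shape[1]))
        for s, blocks in enumerate(self.stages):
            for block in blocks:
                x = block.forward(x, training=False)
            entries.append((f"stage{s + 1}", x.shape[2], x.shape[3], x.shape[1]))
            if s < len(self.downsamples):
                x = self.downsamples[s].forward(x, training=False)
                entries.append((f"ds{s + 1}", x.shape[2], x.shape[3], x.shape[1]))
        return ShapeTrace(entries)


def build_model(config: MACNeXtConfig) -> MACNeXt:
    """Construct the network with deterministic, seed-driven initial weights."""
    return MACNeXt(config)


# --------------------------------------------------------------------------
# Analytic trace and parameter accounting
# --------------------------------------------------------------------------

def trace_shapes(config: MACNeXtConfig) -> ShapeTrace:
    """Analytic per-stage output shapes; no tensor computation."""
    config.validate()
    h, w = config.input_height, config.input_width
    h = nn.conv_out_side(nn.conv_out_side(h, 2), 2)
    w = nn.conv_out_side(nn.conv_out_side(w, 2), 2)
    entries = [("stem", h, w, config.stem_widths[1])]
    n_stages = len(config.stage_widths)
    for s, f in enumerate(config.stage_widths):
        entries.append((f"stage{s + 1}", h, w, f))
        if s < n_stages - 1:
            h, w = nn.conv_out_side(h, 2), nn.conv_out_side(w, 2)
            entries.append((f"ds{s + 1}", h, w, 2 * f))
    return ShapeTrace(entries)


def _closed_form_entries(config: MACNeXtConfig) -> list[tuple[str, int]]:
    """Per-layer algebraic parameter counts.

    Grouped conv: k^2 * channels_per_group * C_out; plain conv: k^2 * C_in *
    C_out; BN: 2 * C; FC: C * n + n. Convolutions carry no bias (each is
    followed by BN).
    """
    cfg = config
    cpg = cfg.channels_per_group
    w0, w1 = cfg.stem_widths
    entries = [
        ("stem.conv1", 9 * cfg.input_channels * w0),
        ("stem.bn1", 2 * w0),
        ("stem.conv2", 9 * cpg * w1),
        ("stem.bn2", 2 * w1),
    ]
    n_stages = len(cfg.stage_widths)
    for s, (f, r) in enumerate(zip(cfg.stage_widths, cfg.stage_repeats)):
        for b in range(r):
            p = f"stage{s + 1}.block{b + 1}"
            exp = cpg * 2 * f if cfg.expansion_grouped else (2 * f) * (2 * f)
            sq = cpg * f if cfg.squeeze_grouped else (2 * f) * f
            entries += [
                (f"{p}.gc3x3", 9 * cpg * f),
                (f"{p}.bn3x3", 2 * f),
                (f"{p}.gc1x1", cpg * f),
                (f"{p}.bn1x1", 2 * f),
                (f"{p}.expand", exp),
                (f"{p}.squeeze", sq),
                (f"{p}.bn_squeeze", 2 * f),
                (f"{p}.gc_gelu", cpg * f),
                (f"{p}.gc_relu", cpg * f),
                (f"{p}.bn_fuse", 2 * f),
            ]
        if s < n_stages - 1:
            entries += [
                (f"ds{s + 1}.gc3x3", 9 * cpg * 2 * f),
                (f"ds{s + 1}.bn", 2 * (2 * f)),
            ]
    n = cfg.num_classes
    entries.append(("head.fc", cfg.stage_widths[-1] * n + n))
    return entries


def count_parameters(config: MACNeXtConfig, mode: str = "closed_form") -> ParamBreakdown:
    """Learnable-scalar breakdown, by algebra or by enumerating a built net."""
    config.validate()
    if mode == "closed_form":
        return ParamBreakdown(_closed_form_entries(config))
    if mode == "built":
        model = build_model(config)
        return ParamBreakdown([(p.name, p.size) for p in model.parameters()])
    raise ValueError(f"mode must be 'closed_form' or 'built', got {mode!r}")


# --------------------------------------------------------------------------
# Functional wrappers (seed-deterministic standalone components)
# --------------------------------------------------------------------------

def stem_forward(image: np.ndarray, config: MACNeXtConfig, stem: Stem | None = None) -> np.ndarray:
    """Run the stem on a batch; builds a seeded stem unless one is supplied."""
    if stem is None:
        stem = Stem(config, np.random.default_rng(config.init_seed))
    return stem.forward(image)


def macnext_block_forward(
    x: np.ndarray, width: int, config: MACNeXtConfig, block: MACNeXtBlock | None = None
) -> np.ndarray:
    """Run one main block at the given width (shape preserving)."""
    if block is None:
        block = MACNeXtBlock(width, config, np.random.default_rng(config.init_seed))
    return block.forward(x)


def downsample_forward(
    x: np.ndarray, width: int, config: MACNeXtConfig, ds: Downsample | None = None
) -> np.ndarray:
    """Run one downsampling layer F -> 2F (spatial sides halve, ceil)."""
    if ds is None:
        ds = Downsample(width, config, np.random.default_rng(config.init_seed))
    return ds.forward(x)


def head_forward(x: np.ndarray, config: MACNeXtConfig, head: Head | None = None) -> PredictionBatch:
    """GAP + FC + softmax on the final feature map."""
    if head is None:
        head = Head(config, np.random.default_rng(config.init_seed))
    logits = head.forward(x)
    return PredictionBatch(nn.softmax(logits, axis=1))


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(model: MACNeXt, path: str | Path) -> None:
    """Single-file serialization: config JSON + every parameter and buffer."""
    arrays = {f"param/{p.name}": p.data for p in model.parameters()}
    arrays.update({f"buffer/{k}": v for k, v in model.buffers().items()})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    buf.seek(0)
    with zipfile.ZipFile(buf, "a") as zf:
        zf.writestr("config.json", json.dumps(model.config.to_dict()))
    path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> MACNeXt:
    """Rebuild a model from :func:`save_checkpoint` output, bit-exactly."""
    with zipfile.ZipFile(path) as zf:
        config = MACNeXtConfig.from_dict(json.loads(zf.read("config.json")))
    model = build_model(config)
    with np.load(path) as data:
        for p in model.parameters():
            p.data[...] = data[f"param/{p.name}"]
        bufs = model.buffers()
        for k, v in bufs.items():
            v[...] = data[f"buffer/{k}"]
    return model
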