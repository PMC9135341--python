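"""Sequence-to-epigenome model architectures.

Three computation graphs:

* a convolutional **meta-feature extractor** — three conv(k=7)/ReLU/maxpool(4)
  stages with channel sizes (320, 480, 960) at full scale, two dense layers,
  emitting one meta-feature per reference epigenomic track (919 at full scale);
* a **residual sequence encoder** — a stem convolution (k=4, 48 channels)
  followed by eight residual blocks with channels (96, 96, 128, 128, 256, 256,
  512, 512) and kernel 7, then two dense layers emitting one value per target
  track (31 at full scale);
* a **joint model** that concatenates both representations and maps them
  through three dense layers and a sigmoid to per-track probabilities.

Blocks whose input channel count differs from their output count downsample
with stride 2 and a width-1 projection shortcut; all convolutions use 'same'
padding, so a 1-kb input traces 1000 → 250 → 62 → 15 positions through the
extractor's pools and 1000 → 500 → 250 → 125 → 63 through the encoder's
strided blocks.

The meta branch feeds its *pre-sigmoid* activations into the concatenation by
default (avoids saturated gradients during joint fine-tuning); a spec flag
switches to post-sigmoid.  Dense hidden widths are architecture parameters
with defaults of the same order as the output widths.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from seqepi.nn import (
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    ReLU,
    ResidualBlock,
    Sequential,
    Sigmoid,
)

__all__ = [
    "MetaFeatSpec",
    "ResNetEncoderSpec",
    "JointModelSpec",
    "MetaFeat",
    "JointModel",
    "build_metafeat",
    "build_resnet_encoder",
    "build_joint",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class MetaFeatSpec:
    """Hyperparameters of the convolutional meta-feature extractor."""

    channels: tuple[int, ...] = (320, 480, 960)
    kernel: int = 7
    pool: int = 4
    hidden: int = 925
    n_meta: int = 919
    input_length: int = 1000

    def __post_init__(self):
        if any(c <= 0 for c in self.channels):
            raise ValueError("conv channels must be strictly positive")
        if self.n_meta < 1:
            raise ValueError("output width must be >= 1")
        if self.kernel < 1 or self.pool < 1 or self.hidden < 1:
            raise ValueError("kernel, pool and hidden width must be positive")

    def spatial_trace(self) -> list[int]:
        """Sequence length after the input and after each pooling stage."""
        trace = [self.input_length]
        length = self.input_length
        for _ in self.channels:
            length //= self.pool      # 'same' conv preserves length
            trace.append(length)
        return trace


@dataclass(frozen=True)
class ResNetEncoderSpec:
    """Hyperparameters of the residual sequence encoder."""

    stem_channels: int = 48
    stem_kernel: int = 4
    block_channels: tuple[int, ...] = (96, 96, 128, 128, 256, 256, 512, 512)
    block_kernel: int = 7
    hidden: int = 256
    n_target: int = 31
    input_length: int = 1000

    def __post_init__(self):
        if len(self.block_channels) != 8:
            raise ValueError("the encoder uses exactly 8 residual blocks")
        if any(b > a for a, b in zip(self.block_channels[1:], self.block_channels)):
            raise ValueError("block channels must be non-decreasing")
        if self.stem_channels < 1 or self.n_target < 1:
            raise ValueError("channel and output widths must be positive")

    def spatial_trace(self) -> list[int]:
        """Length after the stem and after each residual block."""
        trace = [self.input_length]
        length, c_in = self.input_length, self.stem_channels
        for c_out in self.block_channels:
            if c_out != c_in:
                length = -(-length // 2)  # stride-2 'same' conv: ceil(L/2)
            trace.append(length)
            c_in = c_out
        return trace


@dataclass(frozen=True)
class JointModelSpec:
    metafeat: MetaFeatSpec = field(default_factory=MetaFeatSpec)
    encoder: ResNetEncoderSpec = field(default_factory=ResNetEncoderSpec)
    head_hidden: tuple[int, int] = (512, 256)
    n_out: int = 31
    input_length: int = 1000
    meta_post_sigmoid: bool = False
    head_dropout: float = 0.0

    def __post_init__(self):
        if self.n_out != self.encoder.n_target:
            raise ValueError("n_out must equal the encoder output width")
        if self.metafeat.input_length != self.input_length or \
                self.encoder.input_length != self.input_length:
            raise ValueError("component input lengths must match the joint input length")


class MetaFeat:
    """Meta-feature extractor; ``forward`` emits pre-sigmoid logits."""

    def __init__(self, spec: MetaFeatSpec, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        trace = spec.spatial_trace()
        if trace[-1] < 1:
            raise ValueError(
                f"input length {spec.input_length} does not survive "
                f"{len(spec.channels)} pooling stages of size {spec.pool}"
            )
        layers: list = []
        c_in = 4
        for c_out in spec.channels:
            layers += [Conv1d(c_in, c_out, spec.kernel, rng=rng), ReLU(), MaxPool1d(spec.pool)]
            c_in = c_out
        layers += [
            Flatten(),
            Dense(trace[-1] * spec.channels[-1], spec.hidden, rng=rng),
            ReLU(),
            Dense(spec.hidden, spec.n_meta, rng=rng),
        ]
        self.spec = spec
        self.net = Sequential(layers)

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, dy):
        return self.net.backward(dy)

    def parameters(self):
        return self.net.parameters()

    def gradients(self):
        return self.net.gradients()


def build_metafeat(spec: MetaFeatSpec, rng: np.random.Generator | None = None) -> MetaFeat:
    return MetaFeat(spec, rng=rng)


def build_resnet_encoder(spec: ResNetEncoderSpec,
                         rng: np.random.Generator | None = None) -> Sequential:
    """Stem conv → 8 residual blocks → flatten → dense → ReLU → dense."""
    rng = rng if rng is not None else np.random.default_rng()
    layers: list = [Conv1d(4, spec.stem_channels, spec.stem_kernel, rng=rng)]
    c_in = spec.stem_channels
    for c_out in spec.block_channels:
        layers.append(ResidualBlock(c_in, c_out, spec.block_kernel, rng=rng))
        c_in = c_out
    final_len = spec.spatial_trace()[-1]
    if final_len < 1:
        raise ValueError("input length too short for the encoder's downsampling")
    layers += [
        Flatten(),
        Dense(final_len * spec.block_channels[-1], spec.hidden, rng=rng),
        ReLU(),
        Dense(spec.hidden, spec.n_target, rng=rng),
    ]
    return Sequential(layers)


class JointModel:
    """Two-branch model: meta features ⊕ encoded sequence → dense head."""

    def __init__(self, spec: JointModelSpec, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec
        self.metafeat = MetaFeat(spec.metafeat, rng=rng)
        self.encoder = build_resnet_encoder(spec.encoder, rng=rng)
        self._meta_sigmoid = Sigmoid() if spec.meta_post_sigmoid else None
        h1, h2 = spec.head_hidden
        width = spec.metafeat.n_meta + spec.encoder.n_target
        head: list = [Dense(width, h1, rng=rng), ReLU()]
        if spec.head_dropout > 0:
            head.append(Dropout(spec.head_dropout, rng=rng))
        head += [Dense(h1, h2, rng=rng), ReLU(), Dense(h2, spec.n_out, rng=rng)]
        self.head = Sequential(head)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-sigmoid head logits for a ``(batch, L, 4)`` one-hot batch."""
        if x.ndim != 3 or x.shape[1] != self.spec.input_length or x.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (batch, {self.spec.input_length}, 4), got {x.shape}"
            )
        fm = self.metafeat.forward(x, train=train)
        if self._meta_sigmoid is not None:
            fm = self._meta_sigmoid.forward(fm, train=train)
        fs = self.encoder.forward(x, train=train)
        self._n_meta = fm.shape[1]
        return self.head.forward(np.concatenate([fm, fs], axis=1), train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Propagate to the input; returns d(logits)/d(one-hot input)."""
        dcat = self.head.backward(dy)
        dfm, dfs = dcat[:, : self._n_meta], dcat[:, self._n_meta:]
        if self._meta_sigmoid is not None:
            dfm = self._meta_sigmoid.backward(dfm)
        return self.metafeat.backward(dfm) + self.encoder.backward(dfs)

    def parameters(self):
        return self.metafeat.parameters() + self.encoder.parameters() + self.head.parameters()

    def gradients(self):
        return self.metafeat.gradients() + self.encoder.gradients() + self.head.gradients()

    def load_metafeat_weights(self, source: MetaFeat) -> None:
        """Copy pre-trained extractor weights into the meta branch."""
        src, dst = source.parameters(), self.metafeat.parameters()
        if len(src) != len(dst) or any(a.shape != b.shape for a, b in zip(src, dst)):
            raise ValueError("meta-feature extractor specs do not match")
        for a, b in zip(src, dst):
            b[...] = a


def build_joint(spec: JointModelSpec, rng: np.random.Generator | None = None) -> JointModel:
    return JointModel(spec, rng=rng)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict(model, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
    """Per-track probabilities for a batch of one-hot sequences.

    Works for both the joint model and a standalone extractor (whose logits
    are passed through a sigmoid the same way).
    """
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(_sigmoid(model.forward(x[i : i + batch_size], train=False)))
    return np.concatenate(outs, axis=0) if outs else np.empty((0,))


# --------------------------------------------------------------------------
# checkpointing: a JSON spec sidecar plus one flat float64 weight vector,
# so a checkpoint is self-describing and byte-reproducible.

_SPEC_CLASSES = {"MetaFeat": MetaFeatSpec, "JointModel": JointModelSpec}


def _spec_to_dict(spec) -> dict:
    return asdict(spec)


def _spec_from_dict(kind: str, d: dict):
    if kind == "JointModel":
        d = dict(d)
        d["metafeat"] = MetaFeatSpec(**{**d["metafeat"],
                                        "channels": tuple(d["metafeat"]["channels"])})
        enc = dict(d["encoder"])
        enc["block_channels"] = tuple(enc["block_channels"])
        d["encoder"] = ResNetEncoderSpec(**enc)
        d["head_hidden"] = tuple(d["head_hidden"])
        return JointModelSpec(**d)
    d = dict(d)
    d["channels"] = tuple(d["channels"])
    return MetaFeatSpec(**d)


def save_checkpoint(model, path: str | Path) -> None:
    """Write ``spec.json`` and ``weights.npy`` under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kind = "JointModel" if isinstance(model, JointModel) else "MetaFeat"
    params = model.parameters()
    flat = np.concatenate([p.ravel() for p in params])
    meta = {
        "kind": kind,
        "spec": _spec_to_dict(model.spec),
        "shapes": [list(p.shape) for p in params],
    }
    (path / "spec.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    np.save(path / "weights.npy", flat)


def load_checkpoint(path: str | Path):
    """Rebuild a model from a checkpoint directory; predictions round-trip."""
    path = Path(path)
    meta = json.loads((path / "spec.json").read_text())
    spec = _spec_from_dict(meta["kind"], meta["spec"])
    model = JointModel(spec) if meta["kind"] == "JointModel" else MetaFeat(spec)
    flat = np.load(path / "weights.npy")
    offset = 0
    for p, shape in zip(model.parameters(), meta["shapes"]):
        n = int(np.prod(shape))
        p[...] = flat[offset : offset + n].reshape(shape)
        offset += n
    if offset != flat.size:
        raise ValueError("checkpoint weight vector does not match the spec")
    return model
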