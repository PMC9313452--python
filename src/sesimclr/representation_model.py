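"""Encoder F, projection head G and slice classifier H.

The *paper-scale* encoder is a ResNet-50-style trunk adapted to 20x20
single-channel slices: a stride-1 3x3 stem from 1 to 64 channels, then four
residual stages of bottleneck blocks (3, 4, 6, 3 blocks; output channels
256, 512, 1024, 2048; each bottleneck is 1x1 reduce / 3x3 / 1x1 expand with
batch norm after every convolution and ReLU activations), and a global
average pool to a 2048-dimensional feature.  Spatial downsampling (stride 2
at the start of stages 2-4) takes 20 -> 10 -> 5 -> 3, so the representation
never collapses below 1x1 before pooling.

G is a two-layer MLP (2048-2048-128, ReLU hidden activation) whose 128-d
output z is the space in which all contrastive losses live.  H is a
three-layer MLP (128-64-1) with sigmoid activations throughout, emitting a
slice probability; the hard slice label is 1 iff H(z) >= 0.5.

A *tiny* variant preserves the block structure at reduced widths and depths
(one bottleneck per stage, two stages) for desk-scale training and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "EncoderSpec",
    "HeadSpec",
    "build_encoder",
    "build_projection_head",
    "build_classifier_head",
    "RepresentationModel",
    "build_model",
    "project",
    "classify_slice",
    "slice_label",
    "encoder_layout",
]

# (blocks per stage, stage output channels, stage strides)
_PAPER_STAGES = ((3, 256, 1), (4, 512, 2), (6, 1024, 2), (3, 2048, 2))
_TINY_STAGES = ((1, 16, 1), (1, 32, 2))


@dataclass(frozen=True)
class EncoderSpec:
    """Encoder architecture selector: paper scale or tiny test scale."""

    variant: str = "paper"
    input_edge: int = 20

    def __post_init__(self):
        if self.variant not in ("paper", "tiny"):
            raise ValueError("variant must be 'paper' or 'tiny'")

    @property
    def stem_channels(self) -> int:
        return 64 if self.variant == "paper" else 8

    @property
    def stages(self):
        return _PAPER_STAGES if self.variant == "paper" else _TINY_STAGES

    @property
    def feature_dim(self) -> int:
        return self.stages[-1][1]


@dataclass(frozen=True)
class HeadSpec:
    """Widths of G (projection) and H (classifier); H ends in a sigmoid."""

    projection_widths: tuple[int, ...] = (2048, 2048, 128)
    classifier_widths: tuple[int, ...] = (128, 64, 1)

    def __post_init__(self):
        if self.projection_widths[-1] != self.classifier_widths[0]:
            raise ValueError("H input width must equal G output width")
        if self.classifier_widths[-1] != 1:
            raise ValueError("H emits a single probability")

    @classmethod
    def for_encoder(cls, enc: EncoderSpec) -> "HeadSpec":
        if enc.variant == "paper":
            return cls()
        return cls(projection_widths=(enc.feature_dim, enc.feature_dim, 16),
                   classifier_widths=(16, 8, 1))


def build_encoder(spec: EncoderSpec, rng: np.random.Generator) -> nn.Sequential:
    """Construct F; two builds from generators in the same state are identical."""
    layers: list[nn.Module] = [
        nn.Conv2d(1, spec.stem_channels, 3, rng, stride=1, pad=1),
        nn.BatchNorm2d(spec.stem_channels),
        nn.ReLU(),
    ]
    in_ch = spec.stem_channels
    for n_blocks, out_ch, stride in spec.stages:
        mid = out_ch // 4
        for b in range(n_blocks):
            layers.append(nn.Bottleneck(in_ch, mid, out_ch, rng, stride=stride if b == 0 else 1))
            in_ch = out_ch
    layers.append(nn.GlobalAvgPool2d())
    enc = nn.Sequential(*layers)
    enc.feature_dim = spec.feature_dim
    return enc


def _mlp(widths, rng: np.random.Generator, hidden_activation: str,
         final_activation: str | None) -> nn.Sequential:
    layers: list[nn.Module] = []
    act = {"relu": nn.ReLU, "sigmoid": nn.Sigmoid}
    for i in range(len(widths) - 1):
        layers.append(nn.Linear(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2:
            layers.append(act[hidden_activation]())
    if final_activation is not None:
        layers.append(act[final_activation]())
    return nn.Sequential(*layers)


def build_projection_head(spec: HeadSpec, rng: np.random.Generator) -> nn.Sequential:
    """G: MLP from encoder features to the contrastive space (no output activation)."""
    return _mlp(spec.projection_widths, rng, "relu", None)


def build_classifier_head(spec: HeadSpec, rng: np.random.Generator) -> nn.Sequential:
    """H: sigmoid-activated MLP from z to a probability in (0, 1)."""
    return _mlp(spec.classifier_widths, rng, "sigmoid", "sigmoid")


@dataclass
class RepresentationModel:
    """Bundled encoder F + projection head G with convenience passes."""

    encoder: nn.Sequential
    projection: nn.Sequential
    encoder_spec: EncoderSpec
    head_spec: HeadSpec

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, H, W) slices -> (B, feature_dim) encoder features."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return self.encoder.forward(x[:, None, :, :], train=train)

    def project(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        return self.projection.forward(np.atleast_2d(h), train=train)

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        h = self.encode(x, train=train)
        return h, self.project(h, train=train)

    def parameters(self):
        return self.encoder.parameters() + self.projection.parameters()

    def state_dict(self) -> dict:
        enc = self.encoder.state_dict()
        proj = self.projection.state_dict()
        out = {f"enc/{k}": v for k, v in enc.items()}
        out.update({f"proj/{k}": v for k, v in proj.items()})
        out["meta/variant"] = np.array(self.encoder_spec.variant)
        out["meta/input_edge"] = np.array(self.encoder_spec.input_edge)
        return out

    def load_state_dict(self, state: dict) -> None:
        self.encoder.load_state_dict({k[4:]: v for k, v in state.items() if k.startswith("enc/")})
        self.projection.load_state_dict({k[5:]: v for k, v in state.items() if k.startswith("proj/")})


def build_model(encoder_spec: EncoderSpec, seed: int = 0,
                head_spec: HeadSpec | None = None) -> RepresentationModel:
    """Seed-deterministic construction of the F+G pair."""
    rng = np.random.default_rng(seed)
    if head_spec is None:
        head_spec = HeadSpec.for_encoder(encoder_spec)
    if head_spec.projection_widths[0] != encoder_spec.feature_dim:
        raise ValueError("G input width must equal encoder feature_dim")
    encoder = build_encoder(encoder_spec, rng)
    projection = build_projection_head(head_spec, rng)
    return RepresentationModel(encoder, projection, encoder_spec, head_spec)


def project(projection_head: nn.Sequential, h: np.ndarray) -> np.ndarray:
    """Apply G in evaluation mode."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    expected = projection_head.layers[0].w.value.shape[1]
    if h.shape[1] != expected:
        raise ValueError(f"G expects width {expected}, got {h.shape[1]}")
    return projection_head.forward(h, train=False)


def classify_slice(classifier: nn.Sequential, z: np.ndarray) -> np.ndarray:
    """H(z): slice probabilities in (0, 1); accepts a vector or a batch."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    expected = classifier.layers[0].w.value.shape[1]
    if z.shape[1] != expected:
        raise ValueError(f"H expects width {expected}, got {z.shape[1]}")
    return classifier.forward(z, train=False).ravel()


def slice_label(prob) -> np.ndarray:
    """Hard slice label: 1 iff probability >= 0.5 (ties go to 1)."""
    return (np.asarray(prob, dtype=float) >= 0.5).astype(int)


def encoder_layout(spec: EncoderSpec) -> list[dict]:
    """Auditable architecture summary: stem, stages (block counts, channel
    progression), pooling — the contract tests assert against this."""
    rows = [{"stage": "stem", "blocks": 1, "in_channels": 1, "out_channels": spec.stem_channels,
             "kernel": 3}]
    in_ch = spec.stem_channels
    for i, (n_blocks, out_ch, stride) in enumerate(spec.stages, start=1):
        rows.append({"stage": f"res{i}", "blocks": n_blocks, "in_channels": in_ch,
                     "out_channels": out_ch, "stride": stride})
        in_ch = out_ch
    rows.append({"stage": "avgpool", "blocks": 1, "in_channels": in_ch, "out_channels": in_ch})
    return rows
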