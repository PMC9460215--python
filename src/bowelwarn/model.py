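"""Generator and classifier architectures: declarative specs + runnable nets.

The semi-supervised GAN has two networks.  The generator G maps a latent
noise vector through a dense layer to a (2500, 64) feature map, doubles the
length twice with nearest-neighbour upsampling interleaved with k3/s1/p1
convolutions and batch normalization, and ends in a Tanh so fake frames lie
in [-1, 1] like real spectral frames.  The classifier C is a strided 1-D
conv stack (kernel 8, stride 4) that maps a 10,000-sample frame down to a
37-sample map, then a softmax head over K + 1 classes — the K real classes
plus one "generated" class.  With K = 2 the head has 3 neurons: class 0 =
no defecation tendency, 1 = defecation tendency, 2 = fake.

``generator_spec``/``classifier_spec`` are declarative layer lists whose
shape trace is checkable without building a network; ``build_generator`` /
``build_classifier`` construct the runnable numpy networks.  The canonical
generator latent length is 10,000, but the dense layer that implies
(10,000 x 160,000 weights) is far too large to train on commodity
hardware, so runnable generators take a configurable latent length
(default 16).  The latent length is a free parameter that leaves the
generator's output contract unchanged; a short latent also keeps the
generator deliberately weak, which empirically stabilises the
classifier's semi-supervised accuracy — a strong generator competing too
well on the real-vs-fake game is known to degrade K+1-class
semi-supervised classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from . import nn
from .preprocess import WINDOW

__all__ = [
    "LayerSpec", "ArchitectureSpec", "NoiseSpec", "conv_output_length",
    "generator_spec", "classifier_spec", "build_generator",
    "build_classifier", "sample_noise", "forward_generator",
    "forward_classifier", "DEFAULT_LATENT_LENGTH",
]

DEFAULT_LATENT_LENGTH = 16
CANONICAL_NOISE_LENGTH = 10_000


def conv_output_length(l_in: int, kernel: int, stride: int,
                       padding: int = 0) -> int:
    """Output length of a valid strided 1-D convolution.

    ``floor((l_in + 2*padding - kernel) / stride) + 1`` — the number of
    kernel placements that fit in the padded input.
    """
    if kernel < 1 or stride < 1 or padding < 0:
        raise ValueError("need kernel, stride >= 1 and padding >= 0")
    if l_in + 2 * padding < kernel:
        raise ValueError(
            f"kernel {kernel} larger than padded input {l_in + 2 * padding}")
    return (l_in + 2 * padding - kernel) // stride + 1


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table."""

    layer_type: str  # fully_connected | upsample | conv1d | batch_norm
    activation: str = "none"  # ReLU | LeakyReLU | Tanh | Softmax | none
    kernel: Optional[int] = None
    stride: Optional[int] = None
    padding: Optional[int] = None
    out_channels: Optional[int] = None
    upsample_factor: Optional[int] = None
    out_length: Optional[int] = None  # for fully_connected reshapes
    alpha: Optional[float] = None  # LeakyReLU slope
    momentum: Optional[float] = None  # batch-norm momentum

    def __post_init__(self) -> None:
        if self.kernel is not None and self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding is not None and self.padding < 0:
            raise ValueError("padding must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """The generator's latent input contract (canonically 10,000 i.i.d.
    standard-normal values)."""

    length: int = CANONICAL_NOISE_LENGTH
    distribution: str = "standard_normal"


@dataclass
class ArchitectureSpec:
    """Ordered layer list plus the declared per-layer output shapes.

    ``declared_output_shapes`` holds (length, channels) pairs as printed in
    the architecture tables; ``trace()`` recomputes them from the layer
    parameters and ``validate()`` asserts the two agree.
    """

    name: str
    input_shape: tuple[int, int]  # (length, channels)
    layers: list[LayerSpec]
    declared_output_shapes: list[tuple[int, int]] = field(default_factory=list)

    def trace(self) -> list[tuple[int, int]]:
        """Shape-propagate through the layer list (shape-bearing layers
        only; batch-norm and pure activations preserve shape and emit no
        entry, mirroring the tables' '/' cells)."""
        length, channels = self.input_shape
        shapes: list[tuple[int, int]] = []
        for layer in self.layers:
            if layer.layer_type == "fully_connected":
                length = layer.out_length
                channels = layer.out_channels
            elif layer.layer_type == "upsample":
                length = length * layer.upsample_factor
            elif layer.layer_type == "conv1d":
                length = conv_output_length(length, layer.kernel,
                                            layer.stride, layer.padding)
                channels = layer.out_channels
            elif layer.layer_type in ("batch_norm", "activation_only"):
                continue
            else:
                raise ValueError(f"unknown layer type {layer.layer_type!r}")
            shapes.append((length, channels))
        return shapes

    def validate(self) -> None:
        traced = self.trace()
        if traced != [tuple(s) for s in self.declared_output_shapes]:
            raise ValueError(
                f"{self.name}: traced shapes {traced} != declared "
                f"{self.declared_output_shapes}")

    # -- YAML round-trip so a transcription of the tables can be diffed --
    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [
                {k: v for k, v in asdict(l).items() if v is not None
                 and not (k == "activation" and v == "none")}
                for l in self.layers
            ],
            "declared_output_shapes": [list(s) for s
                                       in self.declared_output_shapes],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        payload = yaml.safe_load(text)
        return cls(
            name=payload["name"],
            input_shape=tuple(payload["input_shape"]),
            layers=[LayerSpec(**d) for d in payload["layers"]],
            declared_output_shapes=[tuple(s) for s
                                    in payload["declared_output_shapes"]],
        )


def generator_spec() -> ArchitectureSpec:
    """The generator architecture: noise (10,000) -> FC 160,000 reshaped to
    (2500, 64) -> [upsample x2, conv k3/s1/p1, batch-norm] x2 -> conv to one
    Tanh channel of length 10,000."""
    bn = LayerSpec("batch_norm", momentum=0.8)
    return ArchitectureSpec(
        name="generator",
        input_shape=(CANONICAL_NOISE_LENGTH, 1),
        layers=[
            LayerSpec("fully_connected", out_length=2500, out_channels=64),
            LayerSpec("upsample", upsample_factor=2),
            LayerSpec("conv1d", "ReLU", kernel=3, stride=1, padding=1,
                      out_channels=64),
            bn,
            LayerSpec("upsample", upsample_factor=2),
            LayerSpec("conv1d", "ReLU", kernel=3, stride=1, padding=1,
                      out_channels=32),
            bn,
            LayerSpec("conv1d", "Tanh", kernel=3, stride=1, padding=1,
                      out_channels=1),
        ],
        declared_output_shapes=[(2500, 64), (5000, 64), (5000, 64),
                                (10_000, 64), (10_000, 32), (10_000, 1)],
    )


def classifier_spec(K: int = 2) -> ArchitectureSpec:
    """The (K+1)-way classifier: four k8/s4 LeakyReLU(0.2) convolutions
    (paddings 2, 0, 0, 0) then a softmax head with K + 1 neurons."""
    if K < 1:
        raise ValueError("K must be >= 1")
    conv = lambda pad, ch: LayerSpec("conv1d", "LeakyReLU", kernel=8,
                                     stride=4, padding=pad, out_channels=ch,
                                     alpha=0.2)
    return ArchitectureSpec(
        name="classifier",
        input_shape=(WINDOW, 1),
        layers=[
            conv(2, 64), conv(0, 64), conv(0, 64), conv(0, 1),
            LayerSpec("fully_connected", "Softmax", out_length=1,
                      out_channels=K + 1),
        ],
        declared_output_shapes=[(2500, 64), (624, 64), (155, 64), (37, 1),
                                (1, K + 1)],
    )


# ---------------------------------------------------------------------------
# runnable networks


def build_generator(noise_length: int = DEFAULT_LATENT_LENGTH, *,
                    rng: np.random.Generator,
                    bn_momentum: float = 0.8, dtype=nn.DTYPE) -> nn.Sequential:
    """Instantiate the generator topology of :func:`generator_spec` with a
    configurable latent length (the only free parameter)."""
    return nn.Sequential([
        nn.Dense(noise_length, 2500 * 64, rng=rng, dtype=dtype),
        nn.Reshape((2500, 64)),  # channels-last: (length, channels)
        nn.UpsampleNearest1d(2),
        nn.Conv1d(64, 64, 3, 1, 1, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.BatchNorm1d(64, momentum=bn_momentum, dtype=dtype),
        nn.UpsampleNearest1d(2),
        nn.Conv1d(64, 32, 3, 1, 1, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.BatchNorm1d(32, momentum=bn_momentum, dtype=dtype),
        nn.Conv1d(32, 1, 3, 1, 1, rng=rng, dtype=dtype),
        nn.Tanh(),
    ])


def build_classifier(K: int = 2, *, rng: np.random.Generator,
                     dtype=nn.DTYPE) -> nn.Sequential:
    """Instantiate the classifier trunk + (K+1)-logit head (softmax is
    applied by the loss / prediction code, not stored in the net)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return nn.Sequential([
        nn.Conv1d(1, 64, 8, 4, 2, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv1d(64, 64, 8, 4, 0, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv1d(64, 64, 8, 4, 0, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv1d(64, 1, 8, 4, 0, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Flatten(),
        nn.Dense(37, K + 1, rng=rng, dtype=dtype),
    ])


def sample_noise(rng: np.random.Generator, batch: int,
                 length: int = DEFAULT_LATENT_LENGTH,
                 dtype=nn.DTYPE) -> np.ndarray:
    """Standard-normal latent batch, shape (batch, length)."""
    return rng.standard_normal((batch, length)).astype(dtype)


def forward_generator(generator: nn.Sequential,
                      noise: np.ndarray) -> np.ndarray:
    """Generate fake spectral frames, shape (batch, 10000), in [-1, 1]."""
    expected = generator.layers[0].params["W"].shape[0]
    if noise.ndim != 2 or noise.shape[1] != expected:
        raise ValueError(f"noise must have shape (batch, {expected})")
    return generator.forward(noise.astype(
        generator.layers[0].params["W"].dtype))[:, :, 0]


def forward_classifier(classifier: nn.Sequential,
                       frames: np.ndarray) -> np.ndarray:
    """Class-probability vectors over K + 1 classes for a frame batch.

    Accepts (batch, 10000) or a single (10000,) frame; returns softmax
    probabilities of matching leading shape.
    """
    frames = np.asarray(frames)
    single = frames.ndim == 1
    if single:
        frames = frames[None, :]
    if frames.shape[1] != WINDOW:
        raise ValueError(f"frames must have length {WINDOW}")
    dtype = classifier.layers[0].params["W"].dtype
    logits = classifier.forward(frames[:, :, None].astype(dtype))
    probs = nn.softmax(logits)
    return probs[0] if single else probs
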