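"""Semi-supervised adversarial training.

The classifier C is trained on three batch streams per step: a labeled real
batch (supervised cross-entropy L1 over the K+1 softmax), an unlabeled real
batch and a freshly generated fake batch (unsupervised real-vs-fake term
L2).  Writing q(x) for the probability C assigns to the fake class,

    L1 = -E_{x,y} log p(y | x)
    L2 = -E_real log(1 - q(x)) - E_fake log q(G(z))
    Loss = L1 + L2

The generator step then minimizes -E log(1 - q(G(z))) through the frozen
classifier — the non-saturating direction that rewards G when its output is
assigned to any real class.  Probabilities are clamped to [eps, 1 - eps]
inside every log so all losses stay finite at the simplex boundary.

An epoch is one shuffled pass over the labeled pool; optimization is Adam
(lr 0.002, betas 0.5/0.999) with batch size 10 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import (DEFAULT_LATENT_LENGTH, build_classifier, build_generator,
                    forward_classifier, sample_noise)

__all__ = ["TrainConfig", "LossRecord", "supervised_loss",
           "unsupervised_loss", "generator_loss", "train",
           "cnn_baseline_train"]

CLAMP_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for one reproducible SSGAN run."""

    learning_rate: float = 0.002
    epochs: int = 100
    batch_size: int = 10
    K: int = 2
    noise_length: int = DEFAULT_LATENT_LENGTH
    beta1: float = 0.5
    beta2: float = 0.999
    bn_momentum: float = 0.8
    generator_learning_rate: float | None = None  # None -> learning_rate
    generator_update_interval: int = 1  # G steps once per this many C steps
    seed: int = 0
    device: str = "cpu"
    clamp_eps: float = CLAMP_EPS

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class LossRecord:
    """Per-epoch mean losses; ``loss`` is recorded as L1 + L2 at step time."""

    epoch: int
    L1: float
    L2: float
    loss: float
    generator_loss: float


def _clamp(p: np.ndarray, eps: float = CLAMP_EPS) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def supervised_loss(probabilities: np.ndarray, labels: np.ndarray,
                    eps: float = CLAMP_EPS) -> float:
    """L1: mean negative log-probability of the true (real) label.

    ``probabilities`` are (B, K+1) simplex rows; labels must be real-class
    indices, never the fake index K.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels)
    _check_simplex(p)
    K = p.shape[1] - 1
    if np.any((labels < 0) | (labels >= K)):
        raise ValueError(f"labels must lie in [0, {K}) (fake index {K} "
                         "never appears in real data)")
    return float(-np.mean(np.log(_clamp(p[np.arange(len(labels)), labels],
                                        eps))))


def unsupervised_loss(real_probabilities, fake_probabilities,
                      eps: float = CLAMP_EPS) -> float:
    """L2: real-vs-fake cross-entropy through the fake-class probability.

    Mean over real frames of -log(1 - q) plus mean over fake frames of
    -log q, where q is the last (fake-class) probability.  The real batch
    may be empty (no unlabeled pool), reducing L2 to the fake term.
    """
    fake = np.asarray(fake_probabilities, dtype=np.float64)
    if fake.size == 0:
        raise ValueError("fake batch must be non-empty")
    _check_simplex(fake)
    total = float(-np.mean(np.log(_clamp(fake[:, -1], eps))))
    real = np.asarray(real_probabilities, dtype=np.float64)
    if real.size:
        _check_simplex(real)
        total += float(-np.mean(np.log(_clamp(1.0 - real[:, -1], eps))))
    return total


def generator_loss(fake_probabilities, eps: float = CLAMP_EPS) -> float:
    """-mean log(1 - q(G(z))): low when fakes are classified as real."""
    fake = np.asarray(fake_probabilities, dtype=np.float64)
    if fake.size == 0:
        raise ValueError("fake batch must be non-empty")
    _check_simplex(fake)
    return float(-np.mean(np.log(_clamp(1.0 - fake[:, -1], eps))))


def _check_simplex(p: np.ndarray, tol: float = 1e-4) -> None:
    if np.any(p < -tol) or np.any(p > 1 + tol) or \
            np.any(np.abs(p.sum(axis=-1) - 1.0) > tol):
        raise ValueError("probabilities must be simplex rows in [0, 1]")


# ---------------------------------------------------------------------------
# gradient helpers: d(loss)/d(logits) for each stream


def _grad_supervised(p: np.ndarray, labels: np.ndarray) -> np.ndarray:
    g = p.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return g / len(labels)


def _grad_real_unsup(p: np.ndarray, eps: float) -> np.ndarray:
    # d/dlogits of -log(1-q); dq/dlogit_j = q (delta_jK - p_j)
    q = _clamp(p[:, -1:], eps)
    delta = np.zeros_like(p)
    delta[:, -1] = 1.0
    return q * (delta - p) / (1.0 - q) / len(p)


def _grad_fake_unsup(p: np.ndarray) -> np.ndarray:
    # d/dlogits of -log q
    g = p.copy()
    g[:, -1] -= 1.0
    return g / len(p)


def _softmax_f64(logits: np.ndarray) -> np.ndarray:
    return nn.softmax(logits.astype(np.float64))


@dataclass
class TrainResult:
    classifier: nn.Sequential
    generator: nn.Sequential
    history: list[LossRecord]
    step_records: list[tuple[float, float, float]] = field(default_factory=list)


def train(labeled_frames: np.ndarray, labeled_labels: np.ndarray,
          unlabeled_frames: np.ndarray, config: TrainConfig) -> TrainResult:
    """Run the alternating SSGAN loop; fully reproducible under config.seed.

    Per batch: (i) one classifier Adam step on Loss = L1 + L2 computed from
    a labeled batch, an unlabeled batch (if the pool is non-empty) and a
    fresh fake batch; (ii) one generator Adam step on the generator loss
    through the frozen classifier.
    """
    labeled_frames = np.asarray(labeled_frames, dtype=nn.DTYPE)
    labeled_labels = np.asarray(labeled_labels, dtype=np.int64)
    unlabeled_frames = np.asarray(unlabeled_frames, dtype=nn.DTYPE)
    if len(labeled_frames) == 0:
        raise ValueError("labeled set must be non-empty")
    present = set(np.unique(labeled_labels).tolist())
    if present != set(range(config.K)):
        raise ValueError(
            f"labeled data must cover all {config.K} real classes; "
            f"got {sorted(present)}")

    rng = np.random.default_rng(config.seed)
    classifier = build_classifier(config.K, rng=rng)
    generator = build_generator(config.noise_length, rng=rng,
                                bn_momentum=config.bn_momentum)
    opt_c = nn.Adam(classifier, config.learning_rate, config.beta1,
                    config.beta2)
    g_lr = (config.learning_rate if config.generator_learning_rate is None
            else config.generator_learning_rate)
    opt_g = nn.Adam(generator, g_lr, config.beta1, config.beta2)

    b = config.batch_size
    eps = config.clamp_eps
    history: list[LossRecord] = []
    step_records: list[tuple[float, float, float]] = []
    n_lab = len(labeled_frames)

    global_step = 0
    last_g_loss = 0.0
    for epoch in range(config.epochs):
        order = rng.permutation(n_lab)
        epoch_l1, epoch_l2, epoch_g = [], [], []
        for start in range(0, n_lab, b):
            idx = order[start:start + b]
            xb = labeled_frames[idx][:, :, None]
            yb = labeled_labels[idx]

            # ---- classifier step: Loss = L1 + L2 ----
            # the labeled, unlabeled and fake streams are concatenated into
            # one forward/backward pass; the classifier has no batch-coupled
            # layers, so this is exactly the sum of per-stream gradients
            classifier.zero_grad()
            n_b = len(idx)
            z = sample_noise(rng, n_b, config.noise_length)
            fake = generator.forward(z)
            if len(unlabeled_frames):
                uidx = rng.choice(len(unlabeled_frames), size=n_b,
                                  replace=len(unlabeled_frames) < n_b)
                ub = unlabeled_frames[uidx][:, :, None]
                batch = np.concatenate([xb, ub, fake])
            else:
                batch = np.concatenate([xb, fake])
            logits = classifier.forward(batch)
            p = _softmax_f64(logits)
            p_lab = p[:n_b]
            p_fake = p[-n_b:]
            l1 = supervised_loss(p_lab, yb, eps)
            l2 = float(-np.mean(np.log(_clamp(p_fake[:, -1], eps))))
            dlogits = np.empty_like(p)
            dlogits[:n_b] = _grad_supervised(p_lab, yb)
            dlogits[-n_b:] = _grad_fake_unsup(p_fake)
            if len(unlabeled_frames):
                p_unl = p[n_b:2 * n_b]
                l2 += float(-np.mean(np.log(_clamp(1.0 - p_unl[:, -1], eps))))
                dlogits[n_b:2 * n_b] = _grad_real_unsup(p_unl, eps)
            classifier.backward(dlogits.astype(logits.dtype),
                                need_input_grad=False)
            opt_c.step()

            # ---- generator step through the frozen classifier ----
            # the fake batch (and G's cached activations) are reused: G has
            # not changed since the classifier-step forward pass.  G is
            # updated once every `generator_update_interval` classifier
            # steps; keeping the generator behind the classifier stabilises
            # the semi-supervised accuracy.
            if global_step % config.generator_update_interval == 0:
                classifier.zero_grad()
                generator.zero_grad()
                logits_f = classifier.forward(fake)
                p_f = _softmax_f64(logits_f)
                last_g_loss = generator_loss(p_f, eps)
                dframe = classifier.backward(
                    _grad_real_unsup(p_f, eps).astype(logits_f.dtype))
                generator.backward(dframe, need_input_grad=False)
                opt_g.step()
            global_step += 1

            epoch_l1.append(l1)
            epoch_l2.append(l2)
            epoch_g.append(last_g_loss)
            step_records.append((l1, l2, l1 + l2))

        history.append(LossRecord(
            epoch=epoch,
            L1=float(np.mean(epoch_l1)),
            L2=float(np.mean(epoch_l2)),
            loss=float(np.mean(epoch_l1) + np.mean(epoch_l2)),
            generator_loss=float(np.mean(epoch_g)),
        ))

    classifier.eval()
    generator.eval()
    return TrainResult(classifier, generator, history, step_records)


def save_checkpoint(path, result: TrainResult, config: TrainConfig) -> None:
    """Bundle classifier + generator weights with the training config and
    the declarative architecture specs (npz container)."""
    import json
    from dataclasses import asdict
    from .model import classifier_spec, generator_spec

    arrays = {f"classifier.{k}": v
              for k, v in result.classifier.state_dict().items()}
    arrays.update({f"generator.{k}": v
                   for k, v in result.generator.state_dict().items()})
    meta = {
        "train_config": asdict(config),
        "classifier_spec": classifier_spec(config.K).to_yaml(),
        "generator_spec": generator_spec().to_yaml(),
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[nn.Sequential, nn.Sequential, TrainConfig]:
    """Rebuild (classifier, generator, config) from a checkpoint bundle."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        config = TrainConfig(**meta["train_config"])
        rng = np.random.default_rng(0)  # weights overwritten below
        classifier = build_classifier(config.K, rng=rng)
        generator = build_generator(config.noise_length, rng=rng,
                                    bn_momentum=config.bn_momentum)
        classifier.load_state_dict(
            {k.split(".", 1)[1]: data[k] for k in data.files
             if k.startswith("classifier.")})
        generator.load_state_dict(
            {k.split(".", 1)[1]: data[k] for k in data.files
             if k.startswith("generator.")})
    classifier.eval()
    generator.eval()
    return classifier, generator, config


def cnn_baseline_train(labeled_frames: np.ndarray,
                       labeled_labels: np.ndarray,
                       config: TrainConfig) -> tuple[nn.Sequential,
                                                     list[float]]:
    """Plain supervised CNN baseline: same conv trunk as the classifier but
    with a 2-neuron softmax head, trained with cross-entropy under the same
    optimizer settings.  Returns (model, per-epoch mean losses)."""
    labeled_frames = np.asarray(labeled_frames, dtype=nn.DTYPE)
    labeled_labels = np.asarray(labeled_labels, dtype=np.int64)
    if len(labeled_frames) == 0:
        raise ValueError("labeled set must be non-empty")
    rng = np.random.default_rng(config.seed)
    # K=1 gives the 2-output head; inputs are the same spectral frames
    model = build_classifier(1, rng=rng)
    opt = nn.Adam(model, config.learning_rate, config.beta1, config.beta2)
    b = config.batch_size
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(labeled_frames))
        batch_losses = []
        for start in range(0, len(labeled_frames), b):
            idx = order[start:start + b]
            model.zero_grad()
            logits = model.forward(labeled_frames[idx][:, :, None])
            p = _softmax_f64(logits)
            loss = float(-np.mean(np.log(_clamp(
                p[np.arange(len(idx)), labeled_labels[idx]],
                config.clamp_eps))))
            model.backward(
                _grad_supervised(p, labeled_labels[idx]).astype(logits.dtype),
                need_input_grad=False)
            opt.step()
            batch_losses.append(loss)
        losses.append(float(np.mean(batch_losses)))
    model.eval()
    return model, losses
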