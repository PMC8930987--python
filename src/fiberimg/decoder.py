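"""Waveform -> image decoding, metrics and waveform classification.

The detector trace of one frame is a 1D encoding of the displayed 2D
pattern. Decoders invert that encoding: a five-layer fully connected
network (``fc5``), a small convolutional U-Net operating on the waveform
reshaped to a 64x64 matrix (``unet``), and a ridge-regularised linear
pseudoinverse (``linear``) that serves as the exactly solvable baseline for
the (intensity-linear) incoherent forward model. Image quality is scored by
pixelwise Pearson correlation ("fidelity") and SSIM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .encoder import Waveform
from .nn import MLP, UNet
from .patterns import ImagePattern

__all__ = [
    "DecoderConfig",
    "TrainedDecoder",
    "ReconMetrics",
    "preprocess_waveform",
    "prepare_training_arrays",
    "train_decoder",
    "reconstruct",
    "fidelity",
    "ssim_metric",
    "evaluate_decoder",
    "classify_waveforms",
    "save_decoder",
    "load_decoder",
]

log = logging.getLogger(__name__)


@dataclass
class DecoderConfig:
    """Architecture and training hyperparameters.

    ``input_len`` must reshape to a square for the U-Net (4096 -> 64x64).
    Hidden widths of the fully connected net and the MSE/Adam training
    recipe are repo choices; the five-layer layout (4096 -> 2048 -> 1024 ->
    2048 -> 4096, sigmoid output) is fixed.
    """

    arch: str = "fc5"
    input_len: int = 4096
    output_shape: tuple[int, int] = (64, 64)
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "mse"
    ridge_lambda: float = 1e-2
    unet_base_channels: int = 8

    def __post_init__(self) -> None:
        if self.arch not in ("fc5", "unet", "linear"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.loss != "mse":
            raise ValueError("only MSE loss is supported")
        if self.arch == "unet":
            side = int(round(self.input_len**0.5))
            if side * side != self.input_len:
                raise ValueError(
                    f"input_len={self.input_len} is not a square; unet needs e.g. 4096 -> 64x64"
                )


@dataclass
class TrainedDecoder:
    """A fitted waveform->image inverse with its normalisation statistics."""

    config: DecoderConfig
    model: object
    normalization: dict
    provenance: dict = field(default_factory=dict)


@dataclass
class ReconMetrics:
    fidelity_mean: float
    ssim_mean: float
    per_image: list = field(default_factory=list)


# --------------------------------------------------------------------------
# preprocessing


def _raw_samples(w) -> np.ndarray:
    if isinstance(w, Waveform):
        return np.asarray(w.samples, dtype=float)
    return np.asarray(w, dtype=float)


def _center_crop(samples: np.ndarray, target_len: int) -> np.ndarray:
    """Crop/zero-pad symmetrically about the energy centroid of the support."""
    s = np.clip(samples, 0.0, None)
    total = s.sum()
    if total <= 0:
        centroid = len(samples) // 2
    else:
        centroid = int(round(float(np.arange(len(samples)) @ s / total)))
    start = centroid - target_len // 2
    out = np.zeros(target_len, dtype=float)
    lo = max(start, 0)
    hi = min(start + target_len, len(samples))
    if hi > lo:
        out[lo - start : hi - start] = samples[lo:hi]
    return out


def preprocess_waveform(
    w,
    target_len: int = 4096,
    stats: dict | None = None,
    as_image: bool = False,
) -> np.ndarray:
    """Crop/pad to ``target_len`` about the support centroid and normalise.

    With ``stats`` (training-set scalars ``{"mean", "scale"}``) the
    normalisation is (x - mean)/scale; without, per-waveform zero-mean /
    unit-max-abs. ``as_image=True`` additionally reshapes row-major to the
    square form used by the U-Net.
    """
    samples = _raw_samples(w)
    if len(samples) == 0:
        raise ValueError("waveform has zero length")
    x = _center_crop(samples, target_len)
    if stats is not None:
        x = (x - stats["mean"]) / stats["scale"]
    else:
        if not np.any(samples):
            log.warning("all-zero waveform passed to preprocessing")
        else:
            x = x - x.mean()
            peak = np.abs(x).max()
            if peak > 0:
                x = x / peak
    if as_image:
        side = int(round(target_len**0.5))
        return x.reshape(side, side)
    return x


def _target_image(img) -> np.ndarray:
    arr = img.intensities if isinstance(img, ImagePattern) else np.asarray(img, dtype=float)
    if arr.shape != (64, 64):
        arr = resize(arr, (64, 64), order=1, mode="edge", anti_aliasing=False)
    return np.clip(arr, 0.0, 1.0)


def prepare_training_arrays(
    pairs, config: DecoderConfig
) -> tuple[np.ndarray, np.ndarray, dict]:
    """(waveform, image) pairs -> (X, Y, stats).

    X rows are centred crops normalised by global training statistics
    (scalar mean, scalar max-abs); Y rows are flattened 64x64 bilinear
    targets in [0, 1].
    """
    X = np.stack([_center_crop(_raw_samples(w), config.input_len) for w, _ in pairs])
    mean = float(X.mean())
    scale = float(np.abs(X - mean).max())
    if scale == 0:
        scale = 1.0
    stats = {"mean": mean, "scale": scale}
    X = (X - mean) / scale
    Y = np.stack([_target_image(img).ravel() for _, img in pairs])
    return X, Y, stats


def train_decoder(train_pairs, config: DecoderConfig | None = None) -> TrainedDecoder:
    """Fit a decoder on (waveform, image) pairs.

    ``linear`` solves the ridge normal equations in closed form; ``fc5``
    and ``unet`` are trained with Adam on MSE. Deterministic for a fixed
    config seed.
    """
    config = config or DecoderConfig()
    pairs = list(train_pairs)
    if len(pairs) < 100:
        raise ValueError(f"need at least 100 training pairs, got {len(pairs)}")
    X, Y, stats = prepare_training_arrays(pairs, config)

    if config.arch == "linear":
        model = _fit_ridge(X, Y, config.ridge_lambda)
    elif config.arch == "fc5":
        n_out = int(np.prod(config.output_shape))
        model = MLP([config.input_len, 2048, 1024, 2048, n_out], output="sigmoid",
                    seed=config.seed)
        # long runs get a step decay (x0.3 at 60%, x0.1 at 85%) to sharpen
        # late epochs; short runs keep the base rate throughout
        base = config.learning_rate
        if config.epochs >= 24:
            e1, e2 = int(config.epochs * 0.6), int(config.epochs * 0.85)
            lr_fn = lambda e: base * (1.0 if e < e1 else 0.3 if e < e2 else 0.1)
        else:
            lr_fn = base
        model.fit(X, Y, epochs=config.epochs, batch_size=config.batch_size,
                  lr=lr_fn, seed=config.seed)
    else:  # unet
        side = int(round(config.input_len**0.5))
        model = UNet(base_channels=config.unet_base_channels, seed=config.seed)
        xb = X.reshape(-1, 1, side, side)
        yb = Y.reshape(-1, 1, *config.output_shape)
        model.fit(xb, yb, epochs=config.epochs, batch_size=min(config.batch_size, 16),
                  lr=config.learning_rate, seed=config.seed)
    return TrainedDecoder(
        config=config,
        model=model,
        normalization=stats,
        provenance={"n_train": len(pairs), "seed": config.seed},
    )


def _fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float) -> dict:
    """Ridge least squares with intercept: Y ~ X W + b."""
    Xb = np.hstack([X, np.ones((len(X), 1))])
    gram = Xb.T @ Xb
    reg = lam * np.trace(gram) / max(gram.shape[0], 1)
    gram += reg * np.eye(gram.shape[0])
    coef = np.linalg.solve(gram, Xb.T @ Y)
    return {"W": coef[:-1], "b": coef[-1]}


def _predict(decoder: TrainedDecoder, X: np.ndarray) -> np.ndarray:
    cfg = decoder.config
    if cfg.arch == "linear":
        return X @ decoder.model["W"] + decoder.model["b"]
    if cfg.arch == "fc5":
        return decoder.model.predict(X)
    side = int(round(cfg.input_len**0.5))
    out = decoder.model.predict(X.reshape(-1, 1, side, side))
    return out.reshape(len(X), -1)


def reconstruct(decoder: TrainedDecoder, w) -> ImagePattern:
    """Decode one waveform into a 64x64 image clipped to [0, 1]."""
    x = preprocess_waveform(w, target_len=decoder.config.input_len,
                            stats=decoder.normalization)
    if len(x) != decoder.config.input_len:
        raise ValueError(f"expected input_len={decoder.config.input_len}, got {len(x)}")
    y = _predict(decoder, x[None])[0]
    img = np.clip(y.reshape(decoder.config.output_shape), 0.0, 1.0)
    return ImagePattern(img, kind="glyph", meta={"reconstruction": True})


def reconstruct_batch(decoder: TrainedDecoder, waveforms) -> np.ndarray:
    """(n, *) waveforms -> (n, 64, 64) reconstructions."""
    X = np.stack(
        [
            preprocess_waveform(w, decoder.config.input_len, stats=decoder.normalization)
            for w in waveforms
        ]
    )
    Y = _predict(decoder, X)
    return np.clip(Y.reshape(len(X), *decoder.config.output_shape), 0.0, 1.0)


# --------------------------------------------------------------------------
# metrics


def fidelity(a, b) -> float:
    """Pixelwise Pearson correlation (the '2D correlation' image fidelity).

    Convention: if either image is constant the correlation is undefined
    and reported as 0.
    """
    x = (a.intensities if isinstance(a, ImagePattern) else np.asarray(a, float)).ravel()
    y = (b.intensities if isinstance(b, ImagePattern) else np.asarray(b, float)).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(xc @ yc / (nx * ny))


def ssim_metric(a, b) -> float:
    """SSIM with an 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, L=1.

    Images smaller than the window fall back to a single global window.
    """
    x = a.intensities if isinstance(a, ImagePattern) else np.asarray(a, float)
    y = b.intensities if isinstance(b, ImagePattern) else np.asarray(b, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < 11:
        return _global_ssim(x, y)
    return float(
        structural_similarity(
            x, y, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0, K1=0.01, K2=0.03,
        )
    )


def _global_ssim(x: np.ndarray, y: np.ndarray) -> float:
    c1, c2 = 0.01**2, 0.03**2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def evaluate_decoder(decoder: TrainedDecoder, pairs) -> ReconMetrics:
    """Mean fidelity/SSIM of reconstructions against their targets."""
    pairs = list(pairs)
    recons = reconstruct_batch(decoder, [w for w, _ in pairs])
    per = []
    for i, (rec, (_, img)) in enumerate(zip(recons, pairs)):
        tgt = _target_image(img)
        per.append((i, fidelity(rec, tgt), ssim_metric(rec, tgt)))
    return ReconMetrics(
        fidelity_mean=float(np.mean([p[1] for p in per])),
        ssim_mean=float(np.mean([p[2] for p in per])),
        per_image=per,
    )


# --------------------------------------------------------------------------
# classification


def classify_waveforms(
    train_pairs,
    test_pairs,
    seed: int = 0,
    epochs: int = 30,
    hidden: int = 512,
    input_len: int = 4096,
    return_model: bool = False,
):
    """Train a small classifier directly on preprocessed waveforms.

    ``*_pairs`` are (waveform, integer label) sequences. Architecture:
    input_len -> hidden -> n_classes with softmax/cross-entropy. Returns
    held-out accuracy in [0, 1].
    """
    train_pairs = list(train_pairs)
    test_pairs = list(test_pairs)
    labels = sorted({int(lab) for _, lab in train_pairs})
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    lab_index = {lab: i for i, lab in enumerate(labels)}

    Xtr = np.stack([_center_crop(_raw_samples(w), input_len) for w, _ in train_pairs])
    mean = float(Xtr.mean())
    scale = float(np.abs(Xtr - mean).max()) or 1.0
    Xtr = (Xtr - mean) / scale
    ytr = np.array([lab_index[int(lab)] for _, lab in train_pairs])
    Xte = np.stack([_center_crop(_raw_samples(w), input_len) for w, _ in test_pairs])
    Xte = (Xte - mean) / scale
    yte = np.array([lab_index.get(int(lab), -1) for _, lab in test_pairs])

    net = MLP([input_len, hidden, len(labels)], output="softmax", seed=seed)
    net.fit(Xtr, ytr, epochs=epochs, batch_size=64, lr=1e-3, seed=seed)
    pred = net.predict(Xte).argmax(axis=1)
    acc = float((pred == yte).mean())
    if return_model:
        return acc, net
    return acc


# --------------------------------------------------------------------------
# checkpointing: JSON header + raw little-endian float32 blobs in one file

_MAGIC = b"FIMGDEC1\n"


def save_decoder(decoder: TrainedDecoder, path) -> None:
    cfg = asdict(decoder.config)
    cfg["output_shape"] = list(cfg["output_shape"])
    if decoder.config.arch == "linear":
        weights = [decoder.model["W"], decoder.model["b"]]
    else:
        weights = decoder.model.get_weights()
    header = {
        "config": cfg,
        "normalization": decoder.normalization,
        "provenance": decoder.provenance,
        "shapes": [list(w.shape) for w in weights],
    }
    blob = b"".join(np.ascontiguousarray(w, dtype="<f4").tobytes() for w in weights)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        hb = json.dumps(header).encode()
        fh.write(len(hb).to_bytes(8, "little"))
        fh.write(hb)
        fh.write(blob)


def load_decoder(path) -> TrainedDecoder:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path} is not a decoder checkpoint")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        blob = fh.read()
    cfg_d = dict(header["config"])
    cfg_d["output_shape"] = tuple(cfg_d["output_shape"])
    config = DecoderConfig(**cfg_d)
    weights = []
    off = 0
    for shape in header["shapes"]:
        size = int(np.prod(shape)) * 4
        weights.append(np.frombuffer(blob[off : off + size], dtype="<f4").reshape(shape).copy())
        off += size
    if config.arch == "linear":
        model = {"W": weights[0].astype(float), "b": weights[1].astype(float)}
    elif config.arch == "fc5":
        n_out = int(np.prod(config.output_shape))
        model = MLP([config.input_len, 2048, 1024, 2048, n_out], output="sigmoid",
                    seed=config.seed)
        model.set_weights(weights)
    else:
        model = UNet(base_channels=config.unet_base_channels, seed=config.seed)
        model.set_weights(weights)
    return TrainedDecoder(
        config=config,
        model=model,
        normalization=header["normalization"],
        provenance=header["provenance"],
    )
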