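"""CNN and DAG-CNN classifier models.

Both classifiers use three convolution layers (stride = kernel, no padding,
ReLU) and one fully connected softmax layer mapping to the two class scores
(HC = 0, TLE = 1).  The DAG variant adds an addition layer merging the first
convolution layer's ("subtle") feature maps — channel-projected and
nearest-neighbour resampled — with the third layer's ("coarse") maps before
classification.

The public surface follows the Model/Results convention: a classifier object
is built from a spec and input shape, its :meth:`fit` returns a
:class:`TrainedModel` carrying the fitted parameters, the training history,
prediction and activation access, and a ``summary()``.

Choices the architecture family leaves open are fixed as standard defaults:
ReLU nonlinearities, softmax + cross-entropy, SGD with momentum 0.9, batch
size 16.  All randomness (weight init, batch shuffling) flows from one seeded
generator, so training is bit-reproducible on a fixed thread policy.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import GMSlice, LabeledDataset
from .exceptions import ArchitectureError, ClassBalanceError, ShapeError
from .nnet import ConvNet, SGDMomentum, conv_output_size, softmax


@dataclass(frozen=True)
class CNNSpec:
    """Architecture: three (n_filters, kernel) conv stages + dense classifier.

    The default values are the grid-search optimum reported for the plain CNN
    on real data: 40 filters of 20×20, 10 of 10×10, 15 of 20×20.  Under the
    stride-equals-kernel convention this chain needs very large inputs; for
    small synthetic slices use :meth:`scaled`.
    """

    conv_layers: Tuple[Tuple[int, int], ...] = ((40, 20), (10, 10), (15, 20))
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_layers) != 3:
            raise ArchitectureError("spec requires exactly 3 convolution layers")
        for n_filters, kernel in self.conv_layers:
            if kernel < 2:
                raise ArchitectureError("kernel sizes must be >= 2")
            if n_filters < 1:
                raise ArchitectureError("filter counts must be >= 1")

    @classmethod
    def scaled(cls) -> "CNNSpec":
        """A small chain suited to 64×64 synthetic slices (64 -> 16 -> 8 -> 4)."""
        return cls(conv_layers=((8, 4), (8, 2), (8, 2)))


@dataclass(frozen=True)
class DAGSpec(CNNSpec):
    """As :class:`CNNSpec`, plus the addition layer merging stages 1 and 3.

    Defaults are the reported DAG-CNN optimum: 10 filters 30×30, 40 filters
    15×15, 20 filters 15×15.
    """

    conv_layers: Tuple[Tuple[int, int], ...] = ((10, 30), (40, 15), (20, 15))
    addition_inputs: Tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.addition_inputs != (1, 3):
            raise ArchitectureError("the addition layer merges layers 1 and 3")

    @classmethod
    def scaled(cls) -> "DAGSpec":
        return cls(conv_layers=((8, 4), (8, 2), (8, 2)))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``validation_frequency`` means "validate once every N epochs", so with
    epochs = 160 and frequency 80 the history holds two validation points.
    Defaults are the reported CNN optimum (learning rate 0.0006, 160 epochs);
    the reported DAG optimum uses learning rate 0.0004 and frequency 10.
    """

    learning_rate: float = 0.0006
    epochs: int = 160
    validation_frequency: int = 80
    seed: int = 0
    batch_size: int = 16
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.validation_frequency, self.batch_size) <= 0:
            raise ValueError("learning_rate, epochs, validation_frequency, batch_size must be positive")


def stage_shapes(spec: CNNSpec, input_shape: Tuple[int, int]):
    """Apply the output-size recurrence floor((n - k)/k) + 1 per stage.

    Raises :class:`ArchitectureError` at the first stage whose kernel does
    not fit its input.
    """
    h, w = input_shape
    shapes = []
    for li, (n_filters, kernel) in enumerate(spec.conv_layers, start=1):
        if h < kernel or w < kernel:
            raise ArchitectureError(
                f"layer {li}: kernel {kernel} exceeds feature-map size {h}x{w}"
            )
        h, w = conv_output_size(h, kernel), conv_output_size(w, kernel)
        shapes.append((n_filters, h, w))
    return shapes


def parameter_count(spec: CNNSpec, input_shape: Tuple[int, int]) -> int:
    """Closed-form trainable parameter count for a spec on a given input."""
    shapes = stage_shapes(spec, input_shape)
    total = 0
    in_c = 1
    for n_filters, kernel in spec.conv_layers:
        total += in_c * kernel * kernel * n_filters + n_filters
        in_c = n_filters
    if isinstance(spec, DAGSpec):
        total += spec.conv_layers[0][0] * spec.conv_layers[-1][0]  # 1x1 projection
    f3, h3, w3 = shapes[-1]
    total += f3 * h3 * w3 * spec.n_classes + spec.n_classes
    return total


def _as_pixel_array(images) -> np.ndarray:
    if isinstance(images, LabeledDataset):
        return images.pixel_array()
    if isinstance(images, GMSlice):
        return images.pixels[None]
    if isinstance(images, np.ndarray):
        return images if images.ndim == 3 else images[None]
    return np.stack([im.pixels if isinstance(im, GMSlice) else np.asarray(im) for im in images])


class CNNClassifier:
    """Untrained classifier model: spec + input geometry; ``fit`` trains it."""

    family = "cnn"

    def __init__(self, spec: Optional[CNNSpec] = None, input_shape: Tuple[int, int] = (64, 64)):
        self.spec = spec if spec is not None else CNNSpec.scaled()
        self.input_shape = tuple(input_shape)
        # validate the kernel chain now, at build time
        self.stage_shapes = stage_shapes(self.spec, self.input_shape)

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset, spec: Optional[CNNSpec] = None):
        return cls(spec=spec, input_shape=dataset.images[0].shape)

    def _make_net(self, rng: np.random.Generator) -> ConvNet:
        return ConvNet(
            self.spec.conv_layers,
            self.input_shape,
            rng,
            n_classes=self.spec.n_classes,
            dag=self.family == "dag",
        )

    def fit(
        self,
        train_set: LabeledDataset,
        val_set: Optional[LabeledDataset] = None,
        cfg: Optional[TrainConfig] = None,
    ) -> "TrainedModel":
        """Train with SGD + momentum; returns a :class:`TrainedModel`.

        The training set must contain both classes; the validation set (if
        given) is only ever used to record held-out accuracy at the configured
        frequency — it never influences the gradient steps.
        """
        cfg = cfg or TrainConfig()
        train_set.require_two_classes()
        x = train_set.pixel_array()
        if x.shape[1:] != self.input_shape:
            raise ShapeError(f"training images {x.shape[1:]} != model input {self.input_shape}")
        y = train_set.labels
        rng = np.random.default_rng(cfg.seed)
        net = self._make_net(rng)
        opt = SGDMomentum(net.get_params(), cfg.learning_rate, cfg.momentum)
        params = net.get_params()

        xv = yv = None
        if val_set is not None and len(val_set) > 0:
            xv = val_set.pixel_array()
            yv = val_set.labels

        n = x.shape[0]
        history = []
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = net.loss_and_grads(x[idx], y[idx])
                opt.step(params, grads)
                epoch_loss += loss
                n_batches += 1
            row = {"epoch": epoch, "loss": epoch_loss / n_batches, "val_accuracy": np.nan}
            if xv is not None and epoch % cfg.validation_frequency == 0:
                pred = softmax(net.forward(xv)).argmax(axis=1)
                row["val_accuracy"] = float(np.mean(pred == yv))
            history.append(row)

        return TrainedModel(
            spec=self.spec,
            family=self.family,
            input_shape=self.input_shape,
            net=net,
            cfg=cfg,
            history=pd.DataFrame(history),
            train_subject_ids=list(train_set.subject_ids),
        )


class DAGClassifier(CNNClassifier):
    family = "dag"

    def __init__(self, spec: Optional[DAGSpec] = None, input_shape: Tuple[int, int] = (64, 64)):
        super().__init__(spec if spec is not None else DAGSpec.scaled(), input_shape)
        if not isinstance(self.spec, DAGSpec):
            self.spec = DAGSpec(conv_layers=self.spec.conv_layers)


@dataclass
class TrainedModel:
    """Results object: fitted parameters, history, prediction and activations."""

    spec: CNNSpec
    family: str
    input_shape: Tuple[int, int]
    net: ConvNet
    cfg: TrainConfig
    history: pd.DataFrame
    train_subject_ids: list = field(default_factory=list)

    def predict_scores(self, images) -> np.ndarray:
        """Per-image probability of the TLE class, in [0, 1]."""
        x = _as_pixel_array(images)
        if x.shape[1:] != self.input_shape:
            raise ShapeError(f"images {x.shape[1:]} != model input {self.input_shape}")
        return softmax(self.net.forward(x))[:, 1]

    def predict_labels(self, images) -> np.ndarray:
        """Hard labels with the 0.5 threshold (TLE when score >= 0.5)."""
        return (self.predict_scores(images) >= 0.5).astype(int)

    def layer_activations(self, image, layer: Union[int, str]) -> np.ndarray:
        """Pre-ReLU activation maps of one conv layer for one image.

        Returns an (n_filters, h, w) stack; values may be negative (the
        visualization procedure applies the absolute value afterwards).
        ``layer`` is 1, 2, 3, or "addition" for skip models.
        """
        x = _as_pixel_array(image)
        zs, addition = self.net.conv_outputs(x)
        if layer == "addition":
            if addition is None:
                raise IndexError("addition layer exists only in the DAG model")
            return addition[0]
        if not isinstance(layer, int) or not 1 <= layer <= len(zs):
            raise IndexError(f"layer must be 1..{len(zs)} or 'addition', got {layer!r}")
        return zs[layer - 1][0]

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def summary(self) -> str:
        lines = [
            f"{self.family.upper()} classifier ({self.n_params} parameters)",
            f"input {self.input_shape[0]}x{self.input_shape[1]}",
        ]
        for i, ((f, k), (_, h, w)) in enumerate(
            zip(self.spec.conv_layers, self.net.stage_shapes), start=1
        ):
            lines.append(f"  conv{i}: {f} filters {k}x{k} (stride {k}) -> {f}x{h}x{w}")
        if self.family == "dag":
            f3, h3, w3 = self.net.stage_shapes[-1]
            lines.append(f"  addition: conv1 (projected, resampled) + conv3 -> {f3}x{h3}x{w3}")
        lines.append(f"  dense -> {self.spec.n_classes} class scores (softmax)")
        lines.append(
            f"trained {self.cfg.epochs} epochs, lr {self.cfg.learning_rate}, "
            f"batch {self.cfg.batch_size}, final loss {self.history['loss'].iloc[-1]:.4f}"
        )
        val = self.history["val_accuracy"].dropna()
        if len(val):
            lines.append(f"last validation accuracy {val.iloc[-1]:.3f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Portable archive: spec + config as JSON, parameters as arrays."""
        meta = {
            "family": self.family,
            "input_shape": list(self.input_shape),
            "spec": {"conv_layers": [list(c) for c in self.spec.conv_layers],
                     "n_classes": self.spec.n_classes},
            "cfg": asdict(self.cfg),
            "train_subject_ids": self.train_subject_ids,
        }
        params = {f"param_{i}": p for i, p in enumerate(self.net.get_params())}
        buf = io.StringIO()
        self.history.to_csv(buf, index=False)
        np.savez_compressed(path, meta=json.dumps(meta), history_csv=buf.getvalue(), **params)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            history = pd.read_csv(io.StringIO(str(npz["history_csv"])))
            params = [
                np.asarray(npz[f"param_{i}"])
                for i in range(len([k for k in npz.files if k.startswith("param_")]))
            ]
        spec_kw = dict(
            conv_layers=tuple(tuple(c) for c in meta["spec"]["conv_layers"]),
            n_classes=meta["spec"]["n_classes"],
        )
        spec = DAGSpec(**spec_kw) if meta["family"] == "dag" else CNNSpec(**spec_kw)
        cfg = TrainConfig(**meta["cfg"])
        builder = DAGClassifier if meta["family"] == "dag" else CNNClassifier
        model = builder(spec, tuple(meta["input_shape"]))
        net = model._make_net(np.random.default_rng(0))
        net.set_params(params)
        return cls(
            spec=spec,
            family=meta["family"],
            input_shape=tuple(meta["input_shape"]),
            net=net,
            cfg=cfg,
            history=history,
            train_subject_ids=list(meta["train_subject_ids"]),
        )


# --------------------------------------------------------------------------
# functional facade
# --------------------------------------------------------------------------

def build_cnn(spec: Optional[CNNSpec] = None, input_shape: Tuple[int, int] = (64, 64)) -> CNNClassifier:
    return CNNClassifier(spec, input_shape)


def build_dag_cnn(spec: Optional[DAGSpec] = None, input_shape: Tuple[int, int] = (64, 64)) -> DAGClassifier:
    return DAGClassifier(spec, input_shape)


def train(model: CNNClassifier, train_set, val_set=None, cfg: Optional[TrainConfig] = None) -> TrainedModel:
    return model.fit(train_set, val_set, cfg)


def predict_scores(trained: TrainedModel, images) -> np.ndarray:
    return trained.predict_scores(images)


def layer_activations(trained: TrainedModel, image, layer) -> np.ndarray:
    return trained.layer_activations(image, layer)
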