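"""Uniform interface over the four probability-map producers.

The two-stage ensemble is written for exactly four models (in the
clinical setting: a plain 2D U-Net and U-Nets with VGG-16, ResNet-34 and
EfficientNet-B0 backbones).  Here a producer is anything that maps a
ProcessedSlice to a per-pixel probability map; the bank can hold trained
TinyUNet producers, phantom-simulated producers, or any mix, and the
downstream ensemble/calibration code cannot tell the difference.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from ._unet import TinyUNet
from .phantom import Degradation, PhantomPatient, simulate_model_bank
from .preprocessing import ProcessedSlice, resize_mask

__all__ = [
    "ProbabilityMap",
    "ModelBank",
    "ModelError",
    "SimulatedProducer",
    "SimulatedBank",
    "simulated_bank_for",
    "TinyUNetProducer",
    "train_tiny_unet",
]

N_MODELS = 4  # the ensemble equations are written for four maps


class ModelError(RuntimeError):
    """A producer failed; carries the model id for diagnosis."""

    def __init__(self, model_id: str, cause: Exception):
        super().__init__(f"model {model_id!r} failed: {cause}")
        self.model_id = model_id


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel tumor probability f_{j,i} from model j for slice i."""

    values: np.ndarray
    model_id: str
    slice_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError(
                f"probability map of {self.model_id} outside [0, 1]: "
                f"[{v.min():.3g}, {v.max():.3g}]"
            )
        object.__setattr__(self, "values", v)


class Producer(Protocol):
    model_id: str

    def __call__(self, slc: ProcessedSlice) -> np.ndarray: ...


class ModelBank:
    """Exactly four deterministic ProcessedSlice -> ProbabilityMap producers."""

    def __init__(self, producers: Sequence[Producer]):
        if len(producers) != N_MODELS:
            raise ValueError(
                f"the ensemble requires exactly {N_MODELS} models, "
                f"got {len(producers)}"
            )
        self.producers = list(producers)

    def predict(self, slc: ProcessedSlice) -> list[ProbabilityMap]:
        maps = []
        for prod in self.producers:
            try:
                values = prod(slc)
            except Exception as exc:  # surface which model broke
                raise ModelError(prod.model_id, exc) from exc
            maps.append(
                ProbabilityMap(
                    values=values, model_id=prod.model_id, slice_id=slc.slice_id
                )
            )
        return maps


def predict(bank: ModelBank, slc: ProcessedSlice) -> list[ProbabilityMap]:
    """Functional alias for :meth:`ModelBank.predict`."""
    return bank.predict(slc)


class SimulatedProducer:
    """Phantom-backed producer: corrupts the known truth mask of each
    slice with this model's degradation.

    Deterministic: the noise stream is derived from (seed, model index,
    slice id), so repeated calls on the same slice give identical maps.
    """

    def __init__(
        self,
        index: int,
        degradation: Degradation,
        truth_by_slice: dict[str, np.ndarray],
        seed: int = 0,
    ):
        self.model_id = f"sim-{index}"
        self._index = index
        self.degradation = degradation
        self._truth = truth_by_slice
        self._seed = seed

    def __call__(self, slc: ProcessedSlice) -> np.ndarray:
        truth = self._truth[slc.slice_id]
        # stable per-(model, slice) stream; crc32 is process-independent
        key = zlib.crc32(slc.slice_id.encode())
        rng = np.random.default_rng([self._seed, self._index, key])
        return simulate_model_bank(truth, (self.degradation,), rng)[0]


class SimulatedBank(ModelBank):
    """Bank of four simulated producers sharing one truth lookup."""

    def __init__(
        self,
        truth_by_slice: dict[str, np.ndarray],
        degradations: Sequence[Degradation],
        seed: int = 0,
    ):
        if len(degradations) != N_MODELS:
            raise ValueError(f"need {N_MODELS} degradations")
        self.degradations = tuple(degradations)
        super().__init__(
            [
                SimulatedProducer(i, d, truth_by_slice, seed)
                for i, d in enumerate(degradations)
            ]
        )


def simulated_bank_for(
    patients: Sequence[PhantomPatient],
    degradations: Sequence[Degradation],
    seed: int = 0,
    grid_size: int = 256,
) -> SimulatedBank:
    """Build a simulated bank covering every slice of ``patients``.

    Truth masks are resampled to the processed-slice grid so the
    simulated maps align with what real models would emit.
    """
    truth: dict[str, np.ndarray] = {}
    for pat in patients:
        for slc, mask in zip(pat.slices, pat.masks):
            sid = f"{pat.patient_id}:{slc.slice_index:04d}"
            truth[sid] = resize_mask(mask, grid_size)  # bool; cast at use
    return SimulatedBank(truth, degradations, seed)


class TinyUNetProducer:
    """Wraps a trained TinyUNet as a bank producer."""

    def __init__(self, net: TinyUNet, model_id: str = "tiny-unet"):
        self.net = net
        self.model_id = model_id

    def __call__(self, slc: ProcessedSlice) -> np.ndarray:
        return self.net.predict(slc.pixels)

    # -- persistence: single .npz of weights + JSON descriptor --------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        desc = {
            "model_id": self.model_id,
            "base_width": self.net.base_width,
            "seed": self.net.seed,
            "arch": "tiny-unet-3level",
        }
        path.with_suffix(".json").write_text(json.dumps(desc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TinyUNetProducer":
        path = Path(path)
        desc = json.loads(path.with_suffix(".json").read_text())
        net = TinyUNet(seed=desc["seed"], base_width=desc["base_width"])
        with np.load(path.with_suffix(".npz")) as data:
            for k in net.params:
                net.params[k] = data[k]
        return cls(net, desc["model_id"])


def train_tiny_unet(
    train_slices: Sequence[ProcessedSlice],
    train_masks: Sequence[np.ndarray],
    steps: int = 400,
    seed: int = 0,
    base_width: int = 8,
    lr: float = 3e-3,
    batch_size: int = 2,
) -> TinyUNetProducer:
    """Train the reference tiny U-Net on tumor-bearing slices only.

    Slices whose mask is empty are excluded before training: fitting only
    on images that contain tumor is the imbalance-avoidance rule the
    two-stage design relies on (the *classification* stage, not the
    segmentation models, handles tumor-free slices).

    Returns a producer satisfying the ProbabilityMap contract, plus the
    loss trace on its ``.loss_trace`` attribute.
    """
    if len(train_slices) != len(train_masks):
        raise ValueError("slices and masks must align")
    imgs, msks = [], []
    for slc, mask in zip(train_slices, train_masks):
        m = np.asarray(mask)
        if not np.isin(m, [0, 1]).all():
            raise ValueError("training masks must be binary")
        if m.shape != slc.pixels.shape:
            m = resize_mask(m, slc.pixels.shape[0])
        if m.any():  # train on tumor-bearing slices only
            imgs.append(slc.pixels)
            msks.append(m.astype(float))
    if not imgs:
        raise ValueError("no tumor-bearing slices in the training set")
    net = TinyUNet(seed=seed, base_width=base_width)
    trace = net.fit(
        np.stack(imgs), np.stack(msks), steps=steps, batch_size=batch_size,
        lr=lr, seed=seed,
    )
    producer = TinyUNetProducer(net)
    producer.loss_trace = trace
    return producer
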