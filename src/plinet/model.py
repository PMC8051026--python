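"""Multi-task CNN for protein-ligand interaction prediction.

Architecture: two parallel convolutional feature extractors (protein one-hot
matrix, ligand one-hot matrix), each built from one VGG-style block (two
convolutions + max pooling) followed by two inception-style blocks, then a
dense projection to a fixed embedding per molecule.  The two embeddings are
concatenated and processed by shared dense layers (each followed by ReLU and
a multi-dropout layer); task-specific output heads produce an ensemble of
values in the last dense layer whose mean is the prediction — passed through
a sigmoid for the classification head (binding probability) and left linear
for the regression head (binding affinity on the pK scale).

Convolutions are 1-D along the sequence axis with vocabulary rows as input
channels; inception kernel "sizes" 1/3/5 are widths.  The parameter set is a
flat dict, so per-task snapshots and branch-isolation checks are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .layers import (
    Conv1D,
    Dense,
    Flatten,
    Inception1D,
    MaxPool1D,
    MultiDropout,
    ReLU,
    Sequential,
)

__all__ = ["ModelConfig", "build_extractor", "PLIModel", "multi_dropout"]

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    Defaults follow the reference architecture: ``20 x 1200`` protein and
    ``64 x 200`` ligand inputs, 1024-dimensional molecule embeddings, shared
    dense layers of 512 and 64 units with 5-unit multi-dropout after each,
    and 5-member output ensembles.  Channel counts per block are exposed
    because no canonical values exist; the defaults (32 -> 64 -> 96) keep
    the flattened feature maps small enough to project to the embedding.
    """

    protein_shape: tuple[int, int] = (20, 1200)
    ligand_shape: tuple[int, int] = (64, 200)
    protein_block_channels: tuple[int, int, int] = (32, 64, 96)
    ligand_block_channels: tuple[int, int, int] = (32, 64, 96)
    embedding_dim: int = 1024
    dense_units: tuple[int, ...] = (512, 64, 1)
    dropout_units: int = 5
    dropout_rate_range: tuple[float, float] = (0.1, 0.5)
    ensemble_size: int = 5
    mode: str = "both"  # both | protein_only | ligand_only
    task_heads: tuple[str, ...] = (CLASSIFICATION, REGRESSION)
    l2_lambda: float = 1e-4
    dropout_seed: int = 0

    def __post_init__(self) -> None:
        if self.dense_units[-1] != 1:
            raise ValueError("dense_units must end with 1 (scalar prediction)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.mode not in ("both", "protein_only", "ligand_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        bad = set(self.task_heads) - {CLASSIFICATION, REGRESSION}
        if bad or not self.task_heads:
            raise ValueError(f"task_heads must be a non-empty subset of "
                             f"{{classification, regression}}, got {self.task_heads}")
        lo, hi = self.dropout_rate_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("dropout_rate_range must satisfy 0 <= lo <= hi < 1")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("protein_shape", "ligand_shape", "protein_block_channels",
                    "ligand_block_channels", "dense_units", "dropout_rate_range",
                    "task_heads"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def build_extractor(
    config: ModelConfig,
    input_shape: tuple[int, int],
    name: str,
) -> tuple[Sequential, int]:
    """Build one molecule's feature extractor for a ``rows x cols`` input.

    Block 1 is VGG-style (two width-3 convolutions + width-2/stride-2 max
    pooling); blocks 2-3 are inception-style, each followed by the same
    pooling.  The flattened feature map is projected by a dense layer to
    ``embedding_dim`` and passed through ReLU.  Returns the layer stack and
    the embedding size.
    """
    if input_shape == tuple(config.protein_shape):
        channels = config.protein_block_channels
    elif input_shape == tuple(config.ligand_shape):
        channels = config.ligand_block_channels
    else:
        raise ValueError(
            f"input shape {input_shape} matches neither protein {config.protein_shape} "
            f"nor ligand {config.ligand_shape} input"
        )
    c_in, length = input_shape
    c1, b2, b3 = channels
    layers: list = [
        Conv1D(f"{name}/b1c1", c_in, c1, 3),
        ReLU(),
        Conv1D(f"{name}/b1c2", c1, c1, 3),
        ReLU(),
        MaxPool1D(f"{name}/b1p", width=2, stride=2),
    ]
    length //= 2
    inc2 = Inception1D(f"{name}/b2", c1, b2)
    layers += [inc2, MaxPool1D(f"{name}/b2p", width=2, stride=2)]
    length //= 2
    inc3 = Inception1D(f"{name}/b3", inc2.out_channels, b3)
    layers += [inc3, MaxPool1D(f"{name}/b3p", width=2, stride=2)]
    length //= 2
    if length < 1:
        raise ValueError(f"input length of {input_shape} too short for three pooling stages")
    flat = length * inc3.out_channels
    layers += [Flatten(), Dense(f"{name}/embed", flat, config.embedding_dim), ReLU()]
    return Sequential(name, layers), config.embedding_dim


def multi_dropout(
    vector: np.ndarray,
    units: int,
    rates: Sequence[float],
    weights: Sequence[float],
    training: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Functional multi-dropout on a vector (or batch of vectors).

    Training mode: each of the ``units`` dropout units applies an
    independent mask at its rate with inverted scaling and the output is
    the weighted mean of the unit outputs.  Inference mode: identity.
    """
    if len(rates) != units or len(weights) != units:
        raise ValueError("need exactly `units` rates and weights")
    layer = MultiDropout("md", rates, weights)
    y, _ = layer.forward(np.asarray(vector, dtype=float), {}, training=training, rng=rng)
    return y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PLIModel:
    """The assembled network: extractors, shared trunk, task heads.

    Parameters are held externally in a flat dict (see
    :func:`plinet.training.init_parameters`); the model object itself is a
    stateless description of the computation except for the multi-dropout
    rates, which are drawn once at construction from
    ``config.dropout_rate_range`` using ``config.dropout_seed``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.protein_extractor, _ = build_extractor(config, tuple(config.protein_shape), "prot")
        self.ligand_extractor, _ = build_extractor(config, tuple(config.ligand_shape), "lig")

        drop_rng = np.random.default_rng(config.dropout_seed)
        self.dropout_rates: list[tuple[float, ...]] = []
        trunk_layers: list = []
        n_in = 2 * config.embedding_dim
        for i, units in enumerate(config.dense_units[:-1]):
            trunk_layers.append(Dense(f"trunk/dense{i}", n_in, units))
            trunk_layers.append(ReLU())
            lo, hi = config.dropout_rate_range
            rates = tuple(drop_rng.uniform(lo, hi, size=config.dropout_units))
            self.dropout_rates.append(rates)
            weights = tuple(np.full(config.dropout_units, 1.0 / config.dropout_units))
            trunk_layers.append(MultiDropout(f"trunk/mdrop{i}", rates, weights))
            n_in = units
        self.trunk = Sequential("trunk", trunk_layers)
        self.heads = {
            task: Dense(f"head/{task}", n_in, config.ensemble_size)
            for task in config.task_heads
        }

    # ------------------------------------------------------------------ params

    def param_specs(self) -> dict[str, tuple[tuple[int, ...], int, int]]:
        specs = {}
        specs.update(self.protein_extractor.param_specs())
        specs.update(self.ligand_extractor.param_specs())
        specs.update(self.trunk.param_specs())
        for head in self.heads.values():
            specs.update(head.param_specs())
        return specs

    def head_param_names(self, task: str) -> list[str]:
        return sorted(self.heads[task].param_specs())

    def regression_weight_sqnorm(self, params: dict) -> float:
        """``||w||^2`` of the L2-regularized weight set: the regression
        head's dense-layer weights (biases excluded)."""
        if REGRESSION not in self.heads:
            return 0.0
        key = f"head/{REGRESSION}/W"
        return float(np.sum(params[key] ** 2))

    # ----------------------------------------------------------------- forward

    def forward(
        self,
        Xp: np.ndarray,
        Xl: np.ndarray,
        params: dict,
        task: str,
        training: bool = False,
        rng: np.random.Generator | None = None,
        with_cache: bool = False,
    ):
        """Predict for a batch: ``Xp (B, 20, Lp)``, ``Xl (B, 64, Ll)``.

        Returns predictions ``(B,)`` — probabilities in [0, 1] for the
        classification head, unbounded pK values for regression — and, when
        requested, the cache needed by :meth:`backward`.
        """
        if task not in self.heads:
            raise ValueError(f"model has no {task!r} head (heads: {tuple(self.heads)})")
        B = Xp.shape[0] if self.config.mode != "ligand_only" else Xl.shape[0]
        emb = self.config.embedding_dim
        if self.config.mode != "ligand_only":
            ep, cp = self.protein_extractor.forward(Xp, params, training, rng)
        else:
            ep, cp = np.zeros((B, emb)), None
        if self.config.mode != "protein_only":
            el, cl = self.ligand_extractor.forward(Xl, params, training, rng)
        else:
            el, cl = np.zeros((B, emb)), None
        z = np.concatenate([ep, el], axis=1)
        h, ct = self.trunk.forward(z, params, training, rng)
        members, ch = self.heads[task].forward(h, params, training, rng)
        raw = members.mean(axis=1)  # unweighted mean of the ensemble values
        preds = _sigmoid(raw) if task == CLASSIFICATION else raw
        if with_cache:
            return preds, (task, cp, cl, ct, ch, B)
        return preds

    def backward(self, graw: np.ndarray, cache, params: dict) -> dict:
        """Backpropagate a gradient w.r.t. the pre-activation ensemble mean.

        For classification the caller supplies the combined
        sigmoid-plus-loss gradient (e.g. ``(p - y)/N`` for mean BCE), which
        is both standard and numerically stable.  Returns a dict holding
        gradients only for the parameters the pass actually touched.
        """
        task, cp, cl, ct, ch, B = cache
        grads: dict = {}
        E = self.config.ensemble_size
        gmembers = np.repeat(graw[:, None] / E, E, axis=1)
        gh = self.heads[task].backward(gmembers, ch, params, grads)
        gz = self.trunk.backward(gh, ct, params, grads)
        emb = self.config.embedding_dim
        if cp is not None:
            self.protein_extractor.backward(gz[:, :emb], cp, params, grads)
        if cl is not None:
            self.ligand_extractor.backward(gz[:, emb:], cl, params, grads)
        return grads

    # ------------------------------------------------------------- conveniences

    def predict(
        self,
        Xp: np.ndarray,
        Xl: np.ndarray,
        params: dict,
        task: str,
        batch_size: int = 256,
    ) -> np.ndarray:
        """Inference-mode prediction in batches (dropout disabled)."""
        n = Xp.shape[0]
        out = np.empty(n)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = self.forward(Xp[sl], Xl[sl], params, task, training=False)
        return out

    @staticmethod
    def copy_params(params: dict) -> dict:
        return {k: v.copy() for k, v in params.items()}
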