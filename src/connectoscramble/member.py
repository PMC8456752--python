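"""A single ensemble member: edge-permutation codec + convolutional classifier.

Each member owns a seeded random bijection over the 6670 unique edges of a
116-node connectome. The three bands' upper-triangle values are permuted by
that shared bijection and laid out row-major on a 115x58 grid with bands as
channels, erasing all spatial priors; a convolutional layer whose 256 filters
each span one full grid row (58 columns x 3 bands) then feeds three dense
layers and a two-class softmax. In occlusion mode only a chosen half of the
edges (3335) enters the model and the grid is 115x29.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import edges, nn

GRID_FULL = (115, 58)      # 115 * 58 = 6670 edges
GRID_HALF = (115, 29)      # 115 * 29 = 3335 edges
HALF_EDGES = GRID_HALF[0] * GRID_HALF[1]
N_BANDS = 3


@dataclass(frozen=True)
class PermutationCodec:
    """Seeded bijection from grid positions to edge indices, shared by bands.

    ``permutation[k]`` is the edge whose value sits at flat grid position k
    (row-major). The same permutation applies to all three bands.
    """

    permutation: np.ndarray
    seed: int = 0

    @classmethod
    def random(cls, seed: int, n_edges: int = edges.N_EDGES) -> "PermutationCodec":
        rng = np.random.default_rng(seed)
        return cls(permutation=rng.permutation(n_edges), seed=seed)

    def __post_init__(self):
        perm = np.asarray(self.permutation)
        if not np.array_equal(np.sort(perm), np.arange(len(perm))):
            raise ValueError("permutation must be a bijection on 0..n-1")

    @property
    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(len(self.permutation))
        return inv


def scramble(
    connectome: np.ndarray,
    codec: PermutationCodec,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Scramble (..., 3, 116, 116) stacks into (..., rows, cols, 3) grids.

    Without a mask all 6670 unique edges fill a 115x58 grid. With a mask of
    exactly 3335 edge indices (occlusion mode) only those edges are used,
    taken in sorted-edge order, and the grid is 115x29. The codec must have
    length equal to the number of edges used.
    """
    vals = edges.vectorize(connectome)           # (..., 3, E)
    if mask is not None:
        mask = np.unique(np.asarray(mask))
        if len(mask) != HALF_EDGES:
            raise ValueError(
                f"occlusion mask must contain exactly {HALF_EDGES} edges, "
                f"got {len(mask)}"
            )
        vals = vals[..., mask]
        grid = GRID_HALF
    else:
        grid = GRID_FULL
    n = grid[0] * grid[1]
    if len(codec.permutation) != n:
        raise ValueError(
            f"codec length {len(codec.permutation)} does not match grid size {n}"
        )
    scrambled = vals[..., codec.permutation]     # (..., 3, n)
    reshaped = scrambled.reshape(vals.shape[:-1] + grid)  # (..., 3, R, C)
    return np.moveaxis(reshaped, -3, -1)         # (..., R, C, 3)


def unscramble(grid: np.ndarray, codec: PermutationCodec) -> np.ndarray:
    """Invert :func:`scramble` back to per-band edge vectors (..., 3, n)."""
    bands_first = np.moveaxis(grid, -1, -3)
    flat = bands_first.reshape(bands_first.shape[:-2] + (-1,))
    return flat[..., codec.inverse]


@dataclass(frozen=True)
class MemberConfig:
    """Architecture and training hyperparameters of one member."""

    n_filters: int = 256
    dense_units: tuple[int, ...] = (64, 64, 64)
    dropout: float = 0.5
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    split_ratio: tuple[int, int, int] = (4, 1, 1)
    convolutional: bool = True       # False: fully-connected baseline
    bn_momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_filters < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("n_filters, epochs and batch_size must be positive")
        if len(self.split_ratio) != 3 or any(r <= 0 for r in self.split_ratio):
            raise ValueError("split_ratio must be three positive numbers")


def build_member(config: MemberConfig, grid=GRID_FULL,
                 rng: np.random.Generator | None = None) -> nn.Network:
    """Untrained network for a given grid shape.

    Convolutional variant: row convolution (each filter spans one full grid
    row across the 3 bands) -> BN -> ReLU -> flatten -> 3x [dense -> BN ->
    ReLU -> dropout] -> 2-way softmax head. The fully-connected baseline
    flattens the grid directly into the dense stack.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows, cols = grid
    layers: list[nn.Layer] = []
    conv_relu_index = None
    if config.convolutional:
        layers.append(_GridToRows(cols))
        layers.append(nn.RowConv(cols * N_BANDS, config.n_filters, rng))
        layers.append(nn.BatchNorm(config.n_filters, momentum=config.bn_momentum))
        layers.append(nn.ReLU())
        conv_relu_index = len(layers) - 1
        layers.append(nn.Flatten())
        width = rows * config.n_filters
    else:
        layers.append(nn.Flatten())
        width = rows * cols * N_BANDS
    for units in config.dense_units:
        layers.append(nn.Dense(width, units, rng))
        layers.append(nn.BatchNorm(units, momentum=config.bn_momentum))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout, rng))
        width = units
    layers.append(nn.Dense(width, 2, rng))
    return nn.Network(layers, conv_relu_index=conv_relu_index)


class _GridToRows(nn.Layer):
    """(B, R, C, 3) -> (B, R, C*3): one filter application sees a full row."""

    def __init__(self, cols: int):
        super().__init__()
        self.cols = cols

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._shape)


def split_indices(
    labels: np.ndarray,
    ratio: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test split at the given ratio.

    Val and test sizes are floored per class with the remainder going to
    train; every split must contain both classes.
    """
    total = sum(ratio)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n = len(idx)
        n_val = int(np.floor(n * ratio[1] / total))
        n_test = int(np.floor(n * ratio[2] / total))
        test.extend(idx[:n_test])
        val.extend(idx[n_test:n_test + n_val])
        train.extend(idx[n_test + n_val:])
    out = tuple(np.sort(np.array(part, dtype=np.int64))
                for part in (train, val, test))
    for name, part in zip(("train", "validation", "test"), out):
        if len(np.unique(labels[part])) < 2:
            raise ValueError(
                f"{name} split lacks a class; too few subjects to split "
                f"{ratio[0]}:{ratio[1]}:{ratio[2]}"
            )
    return out


@dataclass
class TrainedMember:
    """A trained member plus everything needed to reuse or audit it."""

    network: nn.Network
    codec: PermutationCodec
    config: MemberConfig
    mask: np.ndarray | None
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    test_probabilities: np.ndarray   # (n_test, 2), columns = class 0/1
    best_epoch: int
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = (set(self.test_ids) & set(self.train_ids)) | (
            set(self.test_ids) & set(self.val_ids)
        )
        if overlap:
            raise ValueError(f"test ids overlap train/val ids: {sorted(overlap)[:5]}")


def save_member(trained: TrainedMember, directory) -> None:
    """Write a member checkpoint: weights, codec permutation, split
    manifest (JSON) and training log (CSV: epoch, loss, val_accuracy)."""
    import csv
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "weights.npz",
        **{f"w{i}": w for i, w in enumerate(trained.network.get_weights())},
    )
    np.save(directory / "codec.npy", trained.codec.permutation)
    if trained.mask is not None:
        np.save(directory / "mask.npy", trained.mask)
    manifest = {
        "config": dataclass_dict(trained.config),
        "codec_seed": trained.codec.seed,
        "train_ids": np.asarray(trained.train_ids).tolist(),
        "val_ids": np.asarray(trained.val_ids).tolist(),
        "test_ids": np.asarray(trained.test_ids).tolist(),
        "best_epoch": trained.best_epoch,
        "test_probabilities": np.asarray(trained.test_probabilities).tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(directory / "training_log.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "loss", "val_accuracy"])
        for e, (loss, acc) in enumerate(
            zip(trained.log.get("loss", []), trained.log.get("val_accuracy", []))
        ):
            writer.writerow([e, loss, acc])


def load_member(directory) -> TrainedMember:
    """Rebuild a member from :func:`save_member` output; predictions of the
    restored network are bit-identical to the saved one's."""
    import json
    from pathlib import Path

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = MemberConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["config"].items()
    })
    perm = np.load(directory / "codec.npy")
    codec = PermutationCodec(permutation=perm, seed=manifest["codec_seed"])
    mask_path = directory / "mask.npy"
    mask = np.load(mask_path) if mask_path.exists() else None
    grid = GRID_HALF if mask is not None else GRID_FULL
    net = build_member(config, grid=grid)
    with np.load(directory / "weights.npz") as data:
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    return TrainedMember(
        network=net, codec=codec, config=config, mask=mask,
        train_ids=np.array(manifest["train_ids"]),
        val_ids=np.array(manifest["val_ids"]),
        test_ids=np.array(manifest["test_ids"]),
        test_probabilities=np.array(manifest["test_probabilities"]),
        best_epoch=manifest["best_epoch"],
    )


def dataclass_dict(config: MemberConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(config)


def train_member(
    connectomes: np.ndarray,
    labels: np.ndarray,
    config: MemberConfig,
    subject_ids: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> TrainedMember:
    """Train one member end to end on (n, 3, 116, 116) stacks.

    Draws a fresh codec and stratified 4:1:1 subject-level split from the
    member seed, scrambles the inputs, trains with Adam restoring the best
    validation-accuracy epoch, and records test-set class probabilities.
    Test data are never seen during training.
    """
    labels = np.asarray(labels)
    if subject_ids is None:
        subject_ids = np.arange(len(labels))
    subject_ids = np.asarray(subject_ids)
    root = np.random.SeedSequence(config.seed)
    ss_codec, ss_split, ss_init, ss_fit = root.spawn(4)

    n_grid = HALF_EDGES if mask is not None else edges.N_EDGES
    codec = PermutationCodec.random(
        seed=int(ss_codec.generate_state(1)[0] % (2 ** 31)), n_edges=n_grid
    )
    grids = scramble(connectomes, codec, mask=mask).astype(nn.DTYPE)
    tr, va, te = split_indices(labels, config.split_ratio,
                               np.random.default_rng(ss_split))
    net = build_member(config, grid=grids.shape[1:3],
                       rng=np.random.default_rng(ss_init))
    log = nn.fit(
        net, grids[tr], labels[tr], grids[va], labels[va],
        epochs=config.epochs, batch_size=config.batch_size,
        rng=np.random.default_rng(ss_fit), lr=config.learning_rate,
    )
    probs = net.predict_proba(grids[te])
    return TrainedMember(
        network=net, codec=codec, config=config, mask=mask,
        train_ids=subject_ids[tr], val_ids=subject_ids[va],
        test_ids=subject_ids[te], test_probabilities=probs,
        best_epoch=log["best_epoch"], log=log,
    )
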