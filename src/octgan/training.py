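"""Training protocol: splits, augmentation, image pool, alternating updates.

Study protocol: Adam (lr 0.0002, betas 0.5/0.999) for both networks, batch
size 1 with batch normalization, three discriminator updates per generator
step drawing fakes through a 50-image history pool with 50% replacement,
per-epoch shuffling, 95:5 train/validation split, and augmentation applied
to each image each epoch with probability 0.5. The checkpoint kept is the
one with the lowest validation L1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .container import read_container, write_container
from .gan import (
    Discriminator, DiscriminatorSpec, Generator, GeneratorSpec, LossConfig,
    discriminator_train_step, generator_train_step,
)
from .phantoms import load_pair
from .processing import to_channels

__all__ = [
    "TrainConfig", "ImagePool", "split_dataset", "augment", "fit",
    "TrainResult", "load_checkpoint", "save_checkpoint", "prepare_samples",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    batch_size: int = 1
    d_steps_per_g_step: int = 3
    pool_size: int = 50
    pool_replace_prob: float = 0.5
    augment_prob: float = 0.5
    val_fraction: float = 0.05
    epochs: int = 10
    seed: int = 0
    use_phase_channel: bool = True
    dyn_range_db: float = 40.0

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("batch_size", "d_steps_per_g_step", "pool_size",
                     "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


class ImagePool:
    """History buffer of generated images for discriminator training.

    Fills to ``capacity`` first; afterwards each offered image has
    probability ``replace_prob`` of swapping out a uniformly chosen stored
    image (the old one is returned for training), otherwise the new image
    is returned unchanged.
    """

    def __init__(self, capacity: int = 50, replace_prob: float = 0.5,
                 rng: np.random.Generator | None = None):
        self.capacity = capacity
        self.replace_prob = replace_prob
        self.rng = rng or np.random.default_rng(0)
        self.images: list = []

    def __len__(self) -> int:
        return len(self.images)

    def offer(self, image: np.ndarray) -> np.ndarray:
        if len(self.images) < self.capacity:
            self.images.append(image)
            return image
        if self.rng.random() < self.replace_prob:
            idx = int(self.rng.integers(len(self.images)))
            old = self.images[idx]
            self.images[idx] = image
            return old
        return image


def split_dataset(manifest: pd.DataFrame, val_fraction: float = 0.05,
                  seed: int = 0):
    """Random, disjoint, exhaustive (train, val) split of a manifest."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    n = len(manifest)
    n_val = int(round(n * val_fraction))
    if n_val == 0:
        n_val = 1 if n > 1 else 0
    if n_val == 0 or n_val >= n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    return manifest.iloc[train_idx].reset_index(drop=True), \
        manifest.iloc[val_idx].reset_index(drop=True)


def augment(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
            prob: float = 0.5, ops: tuple = ("mirror", "roll"),
            max_roll: int = 4):
    """Geometry-preserving augmentation applied identically to both members.

    With probability ``prob`` one operation is drawn: a lateral mirror or a
    circular lateral roll of up to ``max_roll`` pixels. Both keep the pair
    registered, which intensity transforms would not.
    """
    if rng.random() >= prob:
        return x, y
    op = ops[int(rng.integers(len(ops)))]
    if op == "mirror":
        return x[..., ::-1].copy(), y[..., ::-1].copy()
    shift = int(rng.integers(1, max_roll + 1)) * (1 if rng.random() < 0.5 else -1)
    return np.roll(x, shift, axis=-1), np.roll(y, shift, axis=-1)


def prepare_samples(data_dir, manifest: pd.DataFrame, use_phase: bool = True,
                    dyn_range_db: float = 40.0):
    """Load pairs and convert to (x, y) float32 training arrays.

    x is the input's (amplitude, phase) stack — amplitude only under the
    phase-ablation flag — and y the truth amplitude, all in [0, 1].
    """
    data_dir = Path(data_dir)
    xs, ys = [], []
    for fname in manifest["file"]:
        pair = load_pair(data_dir / fname)
        ch_in = to_channels(pair.input_bscan, dyn_range_db)
        ch_tr = to_channels(pair.truth_bscan, dyn_range_db)
        x = ch_in.stacked() if use_phase else ch_in.amplitude[None]
        xs.append(x.astype(np.float32))
        ys.append(ch_tr.amplitude[None].astype(np.float32))
    return xs, ys


@dataclass
class TrainResult:
    checkpoint_path: Path
    log: pd.DataFrame
    best_epoch: int
    best_val_l1: float


def save_checkpoint(path, gen: Generator, disc: Discriminator,
                    loss_cfg: LossConfig, train_cfg: TrainConfig,
                    extra_meta: dict | None = None) -> Path:
    arrays = {f"g/{n}": p.data for n, p in gen.named_params()}
    arrays.update({f"d/{n}": p.data for n, p in disc.named_params()})
    meta = {
        "generator_spec": asdict(gen.spec),
        "discriminator_spec": asdict(disc.spec),
        "loss_config": asdict(loss_cfg),
        "train_config": asdict(train_cfg),
    }
    meta.update(extra_meta or {})
    return write_container(path, arrays, meta)


def load_checkpoint(path):
    """Rebuild (generator, discriminator, meta) from a checkpoint container."""
    arrays, meta = read_container(path)
    gspec = GeneratorSpec(**meta["generator_spec"])
    dspec = DiscriminatorSpec(**meta["discriminator_spec"])
    gen, disc = Generator(gspec), Discriminator(dspec)
    for net, prefix in ((gen, "g"), (disc, "d")):
        for name, p in net.named_params():
            key = f"{prefix}/{name}"
            if key not in arrays:
                raise KeyError(f"checkpoint missing weight {key}")
            p.data = np.ascontiguousarray(arrays[key], dtype=np.float32)
    return gen, disc, meta


def _set_params(net, values):
    for p, v in zip(net.params(), values):
        p.data = v.copy()


def fit(
    data_dir,
    out_dir,
    train_cfg: TrainConfig = TrainConfig(),
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    loss_cfg: LossConfig = LossConfig(),
    manifest: pd.DataFrame | None = None,
) -> TrainResult:
    """Train the cGAN on a generated dataset directory.

    Reads ``manifest.csv`` (rows labelled split == "test" are excluded),
    performs the 95:5 train/validation split, and runs the alternating
    optimization. Emits per-epoch losses to ``training_log.csv`` and the
    best-validation-L1 checkpoint to ``checkpoint.octz``. Fully reproducible
    for a fixed seed on one device.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = pd.read_csv(data_dir / "manifest.csv")
    trainable = manifest[manifest.get("split", "train") != "test"]
    train_df, val_df = split_dataset(trainable, train_cfg.val_fraction,
                                     train_cfg.seed)
    use_phase = train_cfg.use_phase_channel
    x_tr, y_tr = prepare_samples(data_dir, train_df, use_phase,
                                 train_cfg.dyn_range_db)
    x_va, y_va = prepare_samples(data_dir, val_df, use_phase,
                                 train_cfg.dyn_range_db)

    in_ch = 2 if use_phase else 1
    gen_spec = gen_spec or GeneratorSpec(in_channels=in_ch)
    if gen_spec.in_channels != in_ch:
        gen_spec = replace(gen_spec, in_channels=in_ch)
    disc_spec = disc_spec or DiscriminatorSpec()
    if len(loss_cfg.lambda_j) != disc_spec.n_hidden:
        raise ValueError("lambda_j length must equal discriminator depth F")

    ss = np.random.SeedSequence(train_cfg.seed)
    s_init_g, s_init_d, s_loop = (int(c.generate_state(1)[0] % (2**31 - 1))
                                  for c in ss.spawn(3))
    gen = Generator(gen_spec, seed=s_init_g)
    disc = Discriminator(disc_spec, seed=s_init_d)
    opt_g = nn.Adam(gen.params(), lr=train_cfg.lr, betas=train_cfg.adam_betas)
    opt_d = nn.Adam(disc.params(), lr=train_cfg.lr, betas=train_cfg.adam_betas)
    rng = np.random.default_rng(s_loop)
    pool = ImagePool(train_cfg.pool_size, train_cfg.pool_replace_prob, rng)

    def val_l1() -> float:
        if not x_va:
            return float("nan")
        errs = [float(np.mean(np.abs(gen(x)[0, 0] - y[0])))
                for x, y in zip(x_va, y_va)]
        return float(np.mean(errs))

    rows = []
    best = {"val": np.inf, "epoch": -1, "g": None, "d": None}
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(x_tr))
        ep = {"lg": 0.0, "l1": 0.0, "ld": 0.0, "lp": 0.0}
        n_d_updates = n_g_updates = 0
        for i in order:
            x, y = augment(x_tr[i], y_tr[i], rng, train_cfg.augment_prob)
            yrecon = gen(x)
            fakes = [yrecon]
            for _ in range(train_cfg.d_steps_per_g_step - 1):
                fakes.append(pool.offer(yrecon.copy()))
            d_diag = {}
            for fake in fakes:
                d_diag = discriminator_train_step(disc, opt_d, y[None], fake,
                                                  loss_cfg)
                n_d_updates += 1
            g_diag = generator_train_step(gen, disc, opt_g, x, y, loss_cfg)
            n_g_updates += 1
            if not np.isfinite(g_diag["lg"]) or not np.isfinite(d_diag["ld"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {g_diag} {d_diag}")
            ep["lg"] += g_diag["lg"]
            ep["l1"] += g_diag["l1"]
            ep["ld"] += d_diag["ld"]
            ep["lp"] += d_diag["lp"]
        n = max(len(order), 1)
        v = val_l1()
        rows.append({"epoch": epoch, "train_lg": ep["lg"] / n,
                     "train_l1": ep["l1"] / n, "train_ld": ep["ld"] / n,
                     "train_lp": ep["lp"] / n, "val_l1": v,
                     "d_updates": n_d_updates, "g_updates": n_g_updates})
        if v < best["val"]:
            best.update(val=v, epoch=epoch,
                        g=[p.data.copy() for p in gen.params()],
                        d=[p.data.copy() for p in disc.params()])
    if best["g"] is not None:
        _set_params(gen, best["g"])
        _set_params(disc, best["d"])
    log = pd.DataFrame(rows)
    log.to_csv(out_dir / "training_log.csv", index=False)
    ckpt = save_checkpoint(
        out_dir / "checkpoint.octz", gen, disc, loss_cfg, train_cfg,
        {"best_epoch": int(best["epoch"]), "best_val_l1": float(best["val"]),
         "n_train": len(x_tr), "n_val": len(x_va)})
    return TrainResult(ckpt, log, int(best["epoch"]), float(best["val"]))
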