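"""Contrastive 2-D representations of simplified images.

A small convolutional network maps each simplified image to a point in
the plane.  Networks are trained with the normalized-temperature
cross-entropy (NT-Xent) objective on pairs of random dihedral
augmentations (flips and 90-degree rotations), which pulls the two
views of the same simulation together relative to views of other
simulations.  An ensemble of independently seeded networks is trained
on the same data, and the calibration objective is the mean over
members of the Euclidean distance between two images' projections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .imaging import SimplifiedImage
from .nn import Adam, Conv2D, Dense, Flatten, ReLU, Sequential

__all__ = [
    "AugmentationPolicy",
    "EncoderConfig",
    "Encoder",
    "EncoderEnsemble",
    "augment",
    "nt_xent_loss",
    "train_encoder",
    "train_ensemble",
    "project",
    "ensemble_distance",
    "ensemble_distances",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class AugmentationPolicy:
    """Random dihedral transforms; value range and channels untouched."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotate: bool = True  # uniform rotation by a multiple of 90 degrees


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and optimization settings for one projection network."""

    conv_channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    hidden: int = 64
    embed_dim: int = 2
    temperature: float = 0.5
    batch_size: int = 64
    epochs: int = 100
    lr: float = 1e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.embed_dim < 1 or self.embed_dim > 3:
            raise ValueError("embed_dim should stay low (1-3); distances degrade otherwise")


def _as_array(img) -> np.ndarray:
    return img.values if isinstance(img, SimplifiedImage) else np.asarray(img, dtype=float)


def augment(img, policy: AugmentationPolicy, rng: np.random.Generator):
    """One random dihedral transform of ``img`` (values untouched)."""
    arr = _as_array(img)
    if policy.rotate and arr.shape[0] != arr.shape[1]:
        raise ValueError("90-degree rotations require a square image")
    out = arr
    if rng.random() < policy.p_hflip:
        out = out[:, ::-1, :]
    if rng.random() < policy.p_vflip:
        out = out[::-1, :, :]
    if policy.rotate:
        k = int(rng.integers(4))
        out = np.rot90(out, k, axes=(0, 1))
    out = np.ascontiguousarray(out)
    if isinstance(img, SimplifiedImage):
        return SimplifiedImage(values=out, channel_names=img.channel_names)
    return out


def nt_xent_loss(embeddings: np.ndarray, temperature: float, return_grad: bool = False):
    """NT-Xent (SimCLR) loss over consecutively paired projections.

    ``embeddings`` is a (2N, D) array where rows (2i, 2i+1) are the two
    augmented views of input i.  For each view, the loss is the negative
    log-softmax of its cosine similarity (scaled by ``temperature``)
    with its partner against all 2N-2 other views; the mean over the 2N
    views is returned.  With ``return_grad`` the analytic gradient with
    respect to ``embeddings`` is returned as well.
    """
    z = np.asarray(embeddings, dtype=float)
    if z.ndim != 2 or z.shape[0] % 2 != 0:
        raise ValueError("embeddings must be a (2N, D) array of paired rows")
    twoN = z.shape[0]
    if twoN < 4:
        raise ValueError("NT-Xent needs at least N=2 pairs")
    norms = np.sqrt((z**2).sum(axis=1))
    if (norms < 1e-12).any():
        raise ValueError("zero-norm embedding in NT-Xent")
    u = z / norms[:, None]
    S = (u @ u.T) / temperature
    np.fill_diagonal(S, -np.inf)
    partner = np.arange(twoN) ^ 1
    m = S.max(axis=1, keepdims=True)
    expS = np.exp(S - m)
    denom = expS.sum(axis=1)
    logsumexp = m[:, 0] + np.log(denom)
    loss = float(np.mean(logsumexp - S[np.arange(twoN), partner]))
    if not return_grad:
        return loss
    P = expS / denom[:, None]  # softmax over the masked rows
    dS = P.copy()
    dS[np.arange(twoN), partner] -= 1.0
    dS /= twoN
    G = ((dS + dS.T) @ u) / temperature
    dz = (G - u * (G * u).sum(axis=1, keepdims=True)) / norms[:, None]
    return loss, dz


def _build_network(cfg: EncoderConfig, in_channels: int, in_size: int,
                   rng: np.random.Generator) -> Sequential:
    layers: list = []
    c, size = in_channels, in_size
    for cout in cfg.conv_channels:
        layers += [Conv2D(c, cout, k=cfg.kernel, stride=2, pad=cfg.kernel // 2, rng=rng), ReLU()]
        c = cout
        size = (size + 2 * (cfg.kernel // 2) - cfg.kernel) // 2 + 1
    layers.append(Flatten())
    layers += [Dense(size * size * c, cfg.hidden, rng=rng), ReLU()]
    layers.append(Dense(cfg.hidden, cfg.embed_dim, rng=rng))
    return Sequential(layers)


@dataclass
class Encoder:
    """A trained projection network plus its training metadata."""

    net: Sequential
    config: EncoderConfig
    input_shape: tuple[int, int, int]  # (H, W, C)
    meta: dict = field(default_factory=dict)

    def project(self, imgs) -> np.ndarray:
        """Deterministic projection of one image (H, W, C) or a batch."""
        if isinstance(imgs, SimplifiedImage):
            imgs = imgs.values
        elif isinstance(imgs, (list, tuple)):
            imgs = np.stack([_as_array(im) for im in imgs])
        arr = np.asarray(imgs, dtype=float)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        if arr.shape[1:] != self.input_shape:
            raise ValueError(
                f"image shape {arr.shape[1:]} does not match encoder input {self.input_shape}"
            )
        z = self.net.forward(arr)
        return z[0] if single else z


def project(encoder: Encoder, img) -> np.ndarray:
    return encoder.project(img)


def _stack_images(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images.astype(float)
    else:
        arr = np.stack([_as_array(im) for im in images]).astype(float)
    if arr.ndim != 4:
        raise ValueError("images must stack to (N, H, W, C)")
    return arr


def _two_views(X: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    out = np.empty((2 * len(X),) + X.shape[1:])
    for i, img in enumerate(X):
        out[2 * i] = augment(img, policy, rng)
        out[2 * i + 1] = augment(img, policy, rng)
    return out


def train_encoder(images, cfg: EncoderConfig, seed: int,
                  policy: AugmentationPolicy | None = None) -> Encoder:
    """Train one projection network; fully reproducible from ``seed``.

    The per-epoch mean training loss and the NT-Xent loss of a fixed
    held-out batch before/after training are recorded in ``meta``.
    """
    policy = policy or AugmentationPolicy()
    X = _stack_images(images)
    M, H, W, C = X.shape
    if M < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least 2 x batch_size = {2 * cfg.batch_size} images, got {M}"
        )
    rng = np.random.default_rng(seed)
    net = _build_network(cfg, C, H, rng)
    opt = Adam(net.params(), lr=cfg.lr)

    eval_idx = rng.permutation(M)[: cfg.batch_size]
    eval_batch = _two_views(X[eval_idx], policy, rng)
    loss_initial = nt_xent_loss(net.forward(eval_batch), cfg.temperature)

    curve = []
    B = cfg.batch_size
    for _ in range(cfg.epochs):
        perm = rng.permutation(M)
        epoch_losses = []
        for start in range(0, M - B + 1, B):
            batch = X[perm[start : start + B]]
            xb = _two_views(batch, policy, rng)
            z = net.forward(xb)
            loss, dz = nt_xent_loss(z, cfg.temperature, return_grad=True)
            net.zero_grad()
            net.backward(dz)
            opt.step()
            epoch_losses.append(loss)
        curve.append(float(np.mean(epoch_losses)))
    loss_final = nt_xent_loss(net.forward(eval_batch), cfg.temperature)
    meta = {
        "seed": int(seed),
        "loss_curve": curve,
        "heldout_loss_initial": float(loss_initial),
        "heldout_loss_final": float(loss_final),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return Encoder(net=net, config=cfg, input_shape=(H, W, C), meta=meta)


@dataclass
class EncoderEnsemble:
    members: list[Encoder]

    def __post_init__(self) -> None:
        shapes = {m.input_shape for m in self.members}
        if len(shapes) > 1:
            raise ValueError(f"ensemble members disagree on input shape: {shapes}")


def train_ensemble(images, cfg: EncoderConfig, n_members: int, seed: int,
                   policy: AugmentationPolicy | None = None) -> EncoderEnsemble:
    """Train ``n_members`` networks on the same data, differing by seed only."""
    rng = np.random.default_rng(seed)
    member_seeds = rng.integers(0, 2**31 - 1, size=n_members)
    return EncoderEnsemble(
        members=[train_encoder(images, cfg, int(s), policy) for s in member_seeds]
    )


def ensemble_distance(ens: EncoderEnsemble, a, b) -> float:
    """Mean over members of the Euclidean distance between projections."""
    if len(ens.members) == 0:
        raise ValueError("ensemble has no members")
    dists = [float(np.linalg.norm(m.project(a) - m.project(b))) for m in ens.members]
    return float(np.mean(dists))


def ensemble_distances(ens: EncoderEnsemble, target, images) -> np.ndarray:
    """Vector of ensemble distances from ``target`` to each image (batched).

    Equal to ``[ensemble_distance(ens, target, im) for im in images]``.
    """
    if len(ens.members) == 0:
        raise ValueError("ensemble has no members")
    X = _stack_images(images)
    total = np.zeros(len(X))
    for m in ens.members:
        zt = m.project(target)
        Z = m.project(X)
        total += np.sqrt(((Z - zt[None, :]) ** 2).sum(axis=1))
    return total / len(ens.members)


def save_ensemble(ens: EncoderEnsemble, directory) -> None:
    """Serialize members as .npz weight files plus a JSON manifest."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"n_members": len(ens.members), "members": []}
    for i, m in enumerate(ens.members):
        path = directory / f"member_{i:03d}.npz"
        np.savez(path, *(m.net.get_weights()))
        manifest["members"].append(
            {
                "file": path.name,
                "config": dataclasses.asdict(m.config),
                "input_shape": list(m.input_shape),
                "meta": m.meta,
            }
        )
    with open(directory / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)


def load_ensemble(directory) -> EncoderEnsemble:
    directory = pathlib.Path(directory)
    with open(directory / "manifest.json") as f:
        manifest = json.load(f)
    members = []
    for entry in manifest["members"]:
        cfg_dict = dict(entry["config"])
        cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        cfg = EncoderConfig(**cfg_dict)
        H, W, C = entry["input_shape"]
        net = _build_network(cfg, C, H, np.random.default_rng(0))
        with np.load(directory / entry["file"]) as data:
            weights = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
        net.set_weights(weights)
        members.append(Encoder(net=net, config=cfg, input_shape=(H, W, C), meta=entry["meta"]))
    return EncoderEnsemble(members=members)
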