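"""The ES-UNet architecture family.

A 4-level 3D encoder–decoder with full-scale skip connections: every decoder
level j receives feature maps from all encoder levels i <= j (each path
gated by a squeeze-and-excitation channel attention module) and from all
deeper decoder levels i > j.  Four ways of routing a feature map from level
L_i to decoder level L_j:

* encoder, L_i < L_j: attention -> max-pool (kernel = stride = 2^(L_j-L_i))
  -> 3x3x3 conv to C channels;
* encoder, L_i = L_j: attention -> two 3x3x3 convs -> 1x1x1 conv to C;
* decoder, L_i = L_j + 1: 2x2x2 transposed conv (stride 2, bare) ->
  3x3x3 conv to C;
* decoder, L_i > L_j + 1: trilinear upsample x2^(L_i-L_j) -> 3x3x3 conv to C.

Every conv (transposed convs excepted) is followed by batch norm + ReLU.
Each decoder block concatenates its incoming paths (N paths in the full
variant) and applies a 3x3x3 conv whose output width is standardised to
(paths · C).  A deep-supervision head (1x1x1 conv -> trilinear x2^(L_j-1)
-> sigmoid) hangs off every decoder level; the final prediction is the
equally weighted mean of the head outputs.

Ablation variants restrict the skip topology: ``base`` keeps only the
same-level path plus the adjacent up path; ``enc_only`` adds the cross-scale
encoder paths; ``dec_only`` adds the cross-scale decoder paths; ``both`` is
the full network.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn

__all__ = ["NetworkConfig", "ESUNet", "build_network", "fuse_predictions", "VARIANTS"]

VARIANTS = ("base", "enc_only", "dec_only", "both")


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Encoder level i has 2^(i-1) * base_channels channels; skip paths all
    deliver ``path_channels`` (C) channels; ``attention_ratio`` sets the
    squeeze-and-excitation bottleneck width round(ratio * C).
    """

    n_levels: int = 4
    in_channels: int = 2
    base_channels: int = 32
    path_channels: int = 32
    attention_ratio: float = 0.25
    variant: str = "both"
    deep_supervision: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid options: {VARIANTS}")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def encoder_channels(self, level: int) -> int:
        """Channels of the encoder block at 1-based ``level``: doubling per level."""
        return self.base_channels * 2 ** (level - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _conv_bn_relu(c_in: int, c_out: int, kernel: int, rng) -> nn.Sequential:
    # bias omitted: batch norm immediately re-centres, making it redundant
    return nn.Sequential(
        nn.Conv3d(c_in, c_out, kernel, rng, bias=False), nn.BatchNorm3d(c_out), nn.ReLU()
    )


class _EncoderBlock(nn.Module):
    """[max-pool stride 2] + two (conv3 -> BN -> ReLU) units."""

    def __init__(self, c_in: int, c_out: int, pool: bool, rng) -> None:
        self.pool = nn.MaxPool3d(2) if pool else None
        self.body = nn.Sequential(
            *(_conv_bn_relu(c_in, c_out, 3, rng).modules + _conv_bn_relu(c_out, c_out, 3, rng).modules)
        )

    def forward(self, x):
        if self.pool is not None:
            x = self.pool.forward(x)
        return self.body.forward(x)

    def backward(self, dy):
        dy = self.body.backward(dy)
        if self.pool is not None:
            dy = self.pool.backward(dy)
        return dy


class _SkipPath(nn.Module):
    """One routed connection from level ``src_level`` to decoder ``dst_level``."""

    def __init__(self, src_level: int, dst_level: int, source: str, c_in: int,
                 cfg: NetworkConfig, rng) -> None:
        i, j, c = src_level, dst_level, cfg.path_channels
        self.source, self.src_level, self.dst_level = source, i, j
        stages: list[nn.Module] = []
        if source == "encoder":
            if i > j:
                raise ValueError(f"encoder path requires L_i <= L_j, got {i} > {j}")
            stages.append(nn.ChannelAttention(c_in, cfg.attention_ratio, rng))
            if i < j:
                stages.append(nn.MaxPool3d(2 ** (j - i)))
                stages.extend(_conv_bn_relu(c_in, c, 3, rng).modules)
            else:
                stages.extend(_conv_bn_relu(c_in, c_in, 3, rng).modules)
                stages.extend(_conv_bn_relu(c_in, c_in, 3, rng).modules)
                stages.extend(_conv_bn_relu(c_in, c, 1, rng).modules)
        elif source == "decoder":
            if i <= j:
                raise ValueError(f"decoder path requires L_i > L_j, got {i} <= {j}")
            if i == j + 1:
                stages.append(nn.ConvTranspose3d(c_in, c, rng))  # bare: no BN/ReLU
                stages.extend(_conv_bn_relu(c, c, 3, rng).modules)
            else:
                stages.append(nn.TrilinearUp(2 ** (i - j)))
                stages.extend(_conv_bn_relu(c_in, c, 3, rng).modules)
        else:
            raise ValueError(f"source must be 'encoder' or 'decoder', got {source!r}")
        self.body = nn.Sequential(*stages)

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, dy):
        return self.body.backward(dy)


class _DecoderBlock(nn.Module):
    """Concatenate incoming paths and fuse with one conv3 -> BN -> ReLU."""

    def __init__(self, n_paths: int, cfg: NetworkConfig, rng) -> None:
        c = cfg.path_channels
        self.n_paths = n_paths
        self.out_channels = n_paths * c
        self.fuse = _conv_bn_relu(n_paths * c, self.out_channels, 3, rng)
        self._split = None

    def forward(self, inputs: list[np.ndarray]):
        self._split = np.cumsum([t.shape[0] for t in inputs])[:-1]
        return self.fuse.forward(np.concatenate(inputs, axis=0))

    def backward(self, dy) -> list[np.ndarray]:
        dcat = self.fuse.backward(dy)
        return np.split(dcat, self._split, axis=0)


class _AuxHead(nn.Module):
    """Deep-supervision head: conv1 to one channel, upsample, sigmoid."""

    def __init__(self, c_in: int, level: int, rng) -> None:
        self.level = level
        mods: list[nn.Module] = [nn.Conv3d(c_in, 1, 1, rng)]
        if level > 1:
            mods.append(nn.TrilinearUp(2 ** (level - 1)))
        mods.append(nn.Sigmoid())
        self.body = nn.Sequential(*mods)

    def forward(self, x):
        return self.body.forward(x)[0]  # drop the channel axis

    def backward(self, dy):
        return self.body.backward(dy[None])


def _path_plan(cfg: NetworkConfig) -> dict[int, list[tuple[str, int]]]:
    """Incoming (source, src_level) pairs per decoder level, in concat order."""
    n = cfg.n_levels
    plan: dict[int, list[tuple[str, int]]] = {}
    for j in range(1, n + 1):
        enc: list[tuple[str, int]]
        dec: list[tuple[str, int]]
        if cfg.variant in ("both", "enc_only"):
            enc = [("encoder", i) for i in range(1, j + 1)]
        else:
            enc = [("encoder", j)]
        if cfg.variant in ("both", "dec_only"):
            dec = [("decoder", i) for i in range(j + 1, n + 1)]
        else:
            dec = [("decoder", j + 1)] if j < n else []
        plan[j] = enc + dec
    return plan


class ESUNet(nn.Module):
    """Full network: callable image -> (fused probability map, per-head maps)."""

    def __init__(self, cfg: NetworkConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_levels

        self.encoders = [
            _EncoderBlock(
                cfg.in_channels if i == 1 else cfg.encoder_channels(i - 1),
                cfg.encoder_channels(i),
                pool=i > 1,
                rng=rng,
            )
            for i in range(1, n + 1)
        ]

        self.plan = _path_plan(cfg)
        self.decoder_out_channels = {}
        self.paths: dict[int, list[_SkipPath]] = {}
        self.decoders: dict[int, _DecoderBlock] = {}
        # deepest decoder first so decoder-path input widths are known
        for j in range(n, 0, -1):
            mods = []
            for source, i in self.plan[j]:
                c_in = (
                    cfg.encoder_channels(i)
                    if source == "encoder"
                    else self.decoder_out_channels[i]
                )
                mods.append(_SkipPath(i, j, source, c_in, cfg, rng))
            self.paths[j] = mods
            self.decoders[j] = _DecoderBlock(len(mods), cfg, rng)
            self.decoder_out_channels[j] = self.decoders[j].out_channels

        head_levels = list(range(1, n + 1)) if cfg.deep_supervision else [1]
        self.heads = {
            j: _AuxHead(self.decoder_out_channels[j], j, rng) for j in head_levels
        }
        self._modules_for_walk = (
            self.encoders
            + [m for j in self.paths for m in self.paths[j]]
            + list(self.decoders.values())
            + list(self.heads.values())
        )

    # parameter discovery must see the dict-held modules
    def params(self):
        out = []
        for m in self._modules_for_walk:
            out.extend(m.params())
        return out

    def buffers(self):
        out = []
        for m in self._modules_for_walk:
            out.extend(m.buffers())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for m in self._modules_for_walk:
            m.set_training(mode)

    def forward(self, image: np.ndarray):
        """Run the network; returns (fused map, {level: head map}).

        ``image`` is (C, D, H, W) with spatial dims divisible by
        2^(n_levels - 1).
        """
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 4 or image.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected image of shape ({self.cfg.in_channels}, D, H, W), got {image.shape}"
            )
        div = 2 ** (self.cfg.n_levels - 1)
        if any(s % div for s in image.shape[1:]):
            raise ValueError(
                f"spatial dims {image.shape[1:]} must be divisible by {div}"
            )
        n = self.cfg.n_levels
        enc = {}
        x = image
        for i, block in enumerate(self.encoders, start=1):
            x = block.forward(x)
            enc[i] = x
        dec: dict[int, np.ndarray] = {}
        for j in range(n, 0, -1):
            inputs = [
                path.forward(enc[i] if source == "encoder" else dec[i])
                for path, (source, i) in zip(self.paths[j], self.plan[j])
            ]
            dec[j] = self.decoders[j].forward(inputs)
        heads = {j: self.heads[j].forward(dec[j]) for j in self.heads}
        fused = fuse_predictions(list(heads.values()))
        return fused, heads

    def backward(self, head_grads: dict[int, np.ndarray]) -> None:
        """Backpropagate per-head gradients and accumulate parameter grads."""
        n = self.cfg.n_levels
        d_dec = {j: 0.0 for j in range(1, n + 1)}
        for j, g in head_grads.items():
            d_dec[j] = d_dec[j] + self.heads[j].backward(g)
        d_enc = {i: 0.0 for i in range(1, n + 1)}
        for j in range(1, n + 1):  # shallowest first: feeds grads to deeper decoders
            if np.isscalar(d_dec[j]):
                continue
            path_grads = self.decoders[j].backward(d_dec[j])
            for path, (source, i), pg in zip(self.paths[j], self.plan[j], path_grads):
                gi = path.backward(pg)
                if source == "encoder":
                    d_enc[i] = d_enc[i] + gi
                else:
                    d_dec[i] = d_dec[i] + gi
        for i in range(n, 0, -1):
            gi = d_enc[i]
            if np.isscalar(gi):
                continue
            upstream = self.encoders[i - 1].backward(gi)
            if i > 1:
                d_enc[i - 1] = d_enc[i - 1] + upstream

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        self.set_training(False)
        fused, _ = self.forward(image)
        return fused

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        # tie rule: probability >= threshold is foreground
        return (self.predict_proba(image) >= self.cfg.threshold).astype(np.int8)


def fuse_predictions(head_outputs: list[np.ndarray]) -> np.ndarray:
    """Equally weighted arithmetic mean of the deep-supervision outputs."""
    if not head_outputs:
        raise ValueError("need at least one head output")
    shapes = {tuple(h.shape) for h in head_outputs}
    if len(shapes) != 1:
        raise ValueError(f"head outputs have mismatched shapes: {sorted(shapes)}")
    return np.mean(head_outputs, axis=0)


def encoder_forward(image: np.ndarray, cfg: NetworkConfig) -> list[np.ndarray]:
    """Run only the encoder; returns the N-level feature pyramid."""
    net = ESUNet(cfg)
    net.set_training(False)  # no need to cache activations for a shape probe
    div = 2 ** (cfg.n_levels - 1)
    if any(s % div for s in image.shape[1:]):
        raise ValueError(f"spatial dims {image.shape[1:]} must be divisible by {div}")
    feats = []
    x = np.asarray(image, dtype=np.float32)
    for block in net.encoders:
        x = block.forward(x)
        feats.append(x)
    return feats


def build_network(cfg: NetworkConfig) -> ESUNet:
    """Assemble an ES-UNet for the given configuration."""
    return ESUNet(cfg)
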