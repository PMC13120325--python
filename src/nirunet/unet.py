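"""U-Net convolutional autoencoder with additive skip connections.

The reconstruction network x~ = f(g(x)): an encoder ``g`` of convolutional
blocks (two conv->batchnorm->ReLU layers each, then 2x2 max-pooling) whose
channel count grows block by block, a two-convolution bottleneck, and a
decoder ``f`` that mirrors the encoder with 2x upsampling.  Skip connections
*add* the corresponding encoder feature map to the decoder activation at the
same resolution (rather than concatenating channels), which requires the
decoder's channel plan to mirror the encoder's exactly; this is verified
structurally when the model is built.  A final convolution with sigmoid
activation produces a single-channel image in (0, 1).

Registered variants:

========  ====================  ==========  ======
variant   encoder channels      bottleneck  blocks
========  ====================  ==========  ======
main768   64,128,256,512,768    768         5
big1024   64,128,256,512,768    1024        5
small512  128,256               512         2
tiny96    16,32,48,64,96        96          5
========  ====================  ==========  ======

``tiny96`` is a proportionally reduced ``main768`` used for CPU-scale
benchmarks.  Spatial sizes not divisible by ``2**blocks`` are handled by
symmetric zero-padding to the next multiple inside :meth:`UNet.forward`,
with the output cropped back, so the network is shape-preserving for any
input of at least 32 pixels per side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .nn import BatchNorm2d, BilinearUp2, Conv2d, MaxPool2, ReLU, Sigmoid
from .nn.layers import NearestUp2


@dataclass(frozen=True)
class UNetConfig:
    variant: str
    encoder_channels: tuple[int, ...]
    bottleneck_channels: int
    convs_per_block: int = 2
    kernel_size: int = 3
    upsample_mode: str = "bilinear"
    input_size: int = 200

    def __post_init__(self):
        ch = tuple(self.encoder_channels)
        object.__setattr__(self, "encoder_channels", ch)
        if len(ch) < 1 or any(c <= 0 for c in ch):
            raise ConfigurationError("encoder_channels must be positive")
        if any(b <= a for a, b in zip(ch, ch[1:])):
            raise ConfigurationError("encoder_channels must be strictly increasing")
        if self.bottleneck_channels < ch[-1]:
            raise ConfigurationError(
                "bottleneck_channels must be >= last encoder channel")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ConfigurationError(
                f"unknown upsample_mode {self.upsample_mode!r}")
        if self.convs_per_block < 1 or self.kernel_size % 2 != 1:
            raise ConfigurationError("need convs_per_block >= 1 and odd kernel")

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        d = dict(d)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        return cls(**d)


VARIANTS: dict[str, UNetConfig] = {
    "main768": UNetConfig("main768", (64, 128, 256, 512, 768), 768),
    "big1024": UNetConfig("big1024", (64, 128, 256, 512, 768), 1024),
    "small512": UNetConfig("small512", (128, 256), 512),
    "tiny96": UNetConfig("tiny96", (16, 32, 48, 64, 96), 96),
}


def get_config(variant: str, **overrides) -> UNetConfig:
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; registered: {sorted(VARIANTS)}")
    return dataclasses.replace(VARIANTS[variant], **overrides)


class _DecoderStage:
    """up -> conv (channel match) -> BN -> +skip -> ReLU -> conv -> BN -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, k: int, up_mode: str,
                 rng: np.random.Generator):
        self.up = BilinearUp2() if up_mode == "bilinear" else NearestUp2()
        self.conv1 = Conv2d(in_ch, out_ch, k, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, k, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()

    def layers(self):
        return [self.up, self.conv1, self.bn1, self.relu1,
                self.conv2, self.bn2, self.relu2]


class UNet:
    """The reconstruction model; see module docstring for the layout."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        ch = config.encoder_channels

        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2] = []
        in_ch = 1
        for c in ch:
            block = []
            for _ in range(config.convs_per_block):
                block += [Conv2d(in_ch, c, k, rng), BatchNorm2d(c), ReLU()]
                in_ch = c
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2())

        bc = config.bottleneck_channels
        self.bottleneck = [Conv2d(ch[-1], bc, k, rng), BatchNorm2d(bc), ReLU(),
                           Conv2d(bc, bc, k, rng), BatchNorm2d(bc), ReLU()]

        self.dec_stages: list[_DecoderStage] = []
        in_ch = bc
        for c in reversed(ch):
            self.dec_stages.append(
                _DecoderStage(in_ch, c, k, config.upsample_mode, rng))
            in_ch = c

        self.head = [Conv2d(ch[0], 1, k, rng), Sigmoid()]
        # imbalance-aware head init: targets are mostly dark (foreground
        # fraction ~0.1), so start the sigmoid output at that prior instead
        # of 0.5 — saves the first epochs from relearning the background
        self.head[0].params["b"][:] = np.float32(np.log(0.1 / 0.9))
        self._check_additive_skips()

    # ---- structural contract ------------------------------------------
    def _check_additive_skips(self) -> None:
        """Additive skips need encoder stage-s channels == decoder stage-s
        channels at the addition point; verify rather than assume."""
        enc_out = [blk[-3].out_ch for blk in self.enc_blocks]  # last conv
        dec_in = [st.conv1.out_ch for st in reversed(self.dec_stages)]
        if enc_out != dec_in:
            raise ConfigurationError(
                f"additive-skip channel mismatch: encoder {enc_out} vs "
                f"decoder {dec_in}")

    # ---- parameter plumbing -------------------------------------------
    def _named_layers(self):
        for b, block in enumerate(self.enc_blocks):
            for i, lay in enumerate(block):
                yield f"enc{b}.{i}", lay
        for i, lay in enumerate(self.bottleneck):
            yield f"bott.{i}", lay
        for s, stage in enumerate(self.dec_stages):
            for i, lay in enumerate(stage.layers()):
                yield f"dec{s}.{i}", lay
        for i, lay in enumerate(self.head):
            yield f"head.{i}", lay

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{name}.{p}": arr for name, lay in self._named_layers()
                for p, arr in lay.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{name}.{p}": arr for name, lay in self._named_layers()
                for p, arr in lay.grads.items()}

    def param_count(self) -> int:
        return sum(a.size for a in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = dict(self.parameters())
        for name, lay in self._named_layers():
            if isinstance(lay, BatchNorm2d):
                state[f"{name}.running_mean"] = lay.running_mean
                state[f"{name}.running_var"] = lay.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, lay in self._named_layers():
            for p in lay.params:
                lay.params[p][...] = state[f"{name}.{p}"]
            if isinstance(lay, BatchNorm2d):
                lay.running_mean[...] = state[f"{name}.running_mean"]
                lay.running_var[...] = state[f"{name}.running_var"]

    # ---- forward / backward -------------------------------------------
    def _pad(self, x: np.ndarray):
        m = 2 ** self.config.depth
        h, w = x.shape[2], x.shape[3]
        ph, pw = (-h) % m, (-w) % m
        pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (pads[0], pads[1]),
                           (pads[2], pads[3])))
        return x, (h, w, pads)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Reconstruct a batch; accepts (N, H, W) or (N, 1, H, W) in [0, 1].

        In evaluation mode (``train=False``) the pass is deterministic:
        batch normalization uses its running statistics.
        """
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise DomainError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise DomainError("input spatial size must be >= 32")
        # layers run channel-major (C, N, H, W); see nirunet.nn.layers
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        x, self._crop = self._pad(x)

        skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            for lay in block:
                h = lay.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for lay in self.bottleneck:
            h = lay.forward(h, train)
        for stage, skip in zip(self.dec_stages, reversed(skips)):
            h = stage.up.forward(h, train)
            h = stage.conv1.forward(h, train)
            h = stage.bn1.forward(h, train)
            h = h + skip
            h = stage.relu1.forward(h, train)
            h = stage.conv2.forward(h, train)
            h = stage.bn2.forward(h, train)
            h = stage.relu2.forward(h, train)
        for lay in self.head:
            h = lay.forward(h, train)

        hh, ww, (pt, pb, pl, pr) = self._crop
        out = h[:, :, pt:pt + hh, pl:pl + ww]
        return out[0] if squeeze else out.transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); fills layer gradients.

        ``dy`` has the (cropped) output shape; it is zero-padded back to the
        internal padded size, mirroring the forward crop.
        """
        if dy.ndim == 3:
            dy = dy[None]
        else:
            dy = dy.transpose(1, 0, 2, 3)
        hh, ww, (pt, pb, pl, pr) = self._crop
        if pt or pb or pl or pr:
            dy = np.pad(dy, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        dy = np.ascontiguousarray(dy, dtype=np.float32)

        for lay in reversed(self.head):
            dy = lay.backward(dy)
        skip_grads: list[np.ndarray] = []
        for stage in reversed(self.dec_stages):
            dy = stage.relu2.backward(dy)
            dy = stage.bn2.backward(dy)
            dy = stage.conv2.backward(dy)
            dy = stage.relu1.backward(dy)
            skip_grads.append(dy)  # gradient into the added encoder map
            dy = stage.bn1.backward(dy)
            dy = stage.conv1.backward(dy)
            dy = stage.up.backward(dy)
        for lay in reversed(self.bottleneck):
            dy = lay.backward(dy)
        # decoder was walked shallow-to-deep in reverse, so skip_grads is
        # ordered shallowest-first; the encoder walk below is deepest-first.
        first_conv = self.enc_blocks[0][0]
        for block, pool, sg in zip(reversed(self.enc_blocks),
                                   reversed(self.pools),
                                   reversed(skip_grads)):
            dy = pool.backward(dy) + sg
            for lay in reversed(block):
                if lay is first_conv:  # no consumer for the input gradient
                    lay.backward(dy, need_dx=False)
                    return
                dy = lay.backward(dy)


def build_unet(config: UNetConfig | str, seed: int = 0) -> UNet:
    """Construct a seeded, He-uniform-initialized model for ``config``
    (a :class:`UNetConfig` or a registered variant name)."""
    if isinstance(config, str):
        config = get_config(config)
    return UNet(config, seed=seed)
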