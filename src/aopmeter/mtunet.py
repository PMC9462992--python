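"""The multitask encoder–decoder network.

One shared convolutional encoder feeds three task decoders:

* Task1 — standard-plane recognition: two residual blocks on the bottleneck,
  global average pooling, a fully connected layer, softmax over
  {nonstandard, standard};
* Task2 — segmentation of pubic symphysis and fetal head: a U-Net decoder
  with encoder skip connections and a per-pixel 3-class softmax;
* Task3 — endpoint heatmap regression: a parallel decoder whose levels are
  fed by attention-fusion (AFM) gates from the Task2 stream, ending in a
  sigmoid over 3 heatmaps.

The encoder has five blocks of two 3x3 conv+BN+ReLU layers; blocks 1–4 end
with 2x2 max pooling followed by an efficient-channel-attention (ECA) unit,
block 5 is the bottleneck.  Channel widths double per level from
``base_channels``.  Upsampling is bilinear (checkerboard-free) followed by
convolutions.  All convolutions are Kaiming-initialized, batch norms start
as the identity.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from .autodiff import (Tensor, Parameter, Module, Conv2d, BatchNorm2d, Linear,
                       ChannelConv1d, concat)

__all__ = ["NetworkConfig", "NetworkOutput", "MTUnet", "eca_kernel_size",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 5
    n_classes_seg: int = 3
    n_heatmaps: int = 3
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.depth != 5:
            raise ValueError("the architecture is defined for depth 5")


@dataclass
class NetworkOutput:
    """One forward pass: class probabilities, segmentation, heatmaps."""

    class_probs: Tensor     # (N, 2), rows sum to 1
    seg_probs: Tensor       # (N, 3, H, W), per-pixel distribution
    heatmap_preds: Tensor   # (N, 3, H, W) in [0, 1]


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size: k = |(log2 C + b) / gamma|_odd.

    The nearest-odd rule truncates toward zero and adds one when even;
    the result is at least 1.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = (math.log2(channels) + b) / gamma
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class ECAUnit(Module):
    """Efficient channel attention: GAP -> 1-D conv over channels -> sigmoid
    -> per-channel reweighting.  Never zeroes a channel (sigmoid is in (0,1))."""

    def __init__(self, channels: int, gamma: float, b: float, rng):
        self.k = eca_kernel_size(channels, gamma, b)
        self.conv = ChannelConv1d(self.k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.conv(x.global_avg_pool()).sigmoid()       # (N, C)
        n, c = w.shape
        return x * w.reshape(n, c, 1, 1)


class ConvBNReLU(Module):
    def __init__(self, cin, cout, rng):
        self.conv = Conv2d(cin, cout, 3, rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class EncoderBlock(Module):
    def __init__(self, cin, cout, rng):
        self.c1 = ConvBNReLU(cin, cout, rng)
        self.c2 = ConvBNReLU(cout, cout, rng)

    def __call__(self, x):
        return self.c2(self.c1(x))


class ResBlock(Module):
    """conv + BN with identity shortcut, then ReLU (channels preserved)."""

    def __init__(self, c, rng):
        self.conv = Conv2d(c, c, 3, rng, bias=False)
        self.bn = BatchNorm2d(c)

    def __call__(self, x):
        return (self.bn(self.conv(x)) + x).relu()


class UpBlock(Module):
    """Bilinear x2 upsample, concat skip, two 3x3 conv+BN+ReLU."""

    def __init__(self, cin, cskip, cout, rng):
        self.c1 = ConvBNReLU(cin + cskip, cout, rng)
        self.c2 = ConvBNReLU(cout, cout, rng)

    def __call__(self, x, skip):
        x = x.upsample2x()
        x = concat([x, skip], axis=1)
        return self.c2(self.c1(x))


class AFMUnit(Module):
    """Attention fusion: gate the current shared (Task2) features with a mask
    learned from the previous-level shared + landmark features, and bundle
    them with the upsampled landmark stream.

        F = 1x1conv(concat(S_prev, L_prev))
        M = sigmoid(BN(1x1conv(F)))          # single-channel mask in [0, 1]
        W = concat(upsample(L_prev), upsample(M) * S_cur)
    """

    def __init__(self, c_s_prev, c_l_prev, rng):
        mid = max(c_s_prev // 2, 1)
        self.f_conv = Conv2d(c_s_prev + c_l_prev, mid, 1, rng)
        self.m_conv = Conv2d(mid, 1, 1, rng, bias=False)
        self.m_bn = BatchNorm2d(1)
        self.forced_mask: float | None = None  # for diagnostics/tests

    def __call__(self, s_prev, l_prev, s_cur):
        f = self.f_conv(concat([s_prev, l_prev], axis=1))
        m = self.m_bn(self.m_conv(f)).sigmoid()
        if self.forced_mask is not None:
            m = Tensor(np.full_like(m.data, self.forced_mask))
        m_up = m.upsample2x()
        return concat([l_prev.upsample2x(), m_up * s_cur], axis=1)


class Task3Block(Module):
    def __init__(self, cin, cout, rng):
        self.c1 = ConvBNReLU(cin, cout, rng)
        self.c2 = ConvBNReLU(cout, cout, rng)

    def __call__(self, w):
        return self.c2(self.c1(w))


class MTUnet(Module):
    """Shared encoder + three task decoders; input H, W divisible by 16."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        ch = [b, 2 * b, 4 * b, 8 * b, 16 * b]
        self.channels = ch
        cin = config.in_channels
        self.enc = [EncoderBlock(cin if i == 0 else ch[i - 1], ch[i], rng)
                    for i in range(5)]
        self.eca = [ECAUnit(ch[i], config.eca_gamma, config.eca_b, rng)
                    for i in range(4)]
        # Task1: classification head on the bottleneck
        self.res1 = ResBlock(ch[4], rng)
        self.res2 = ResBlock(ch[4], rng)
        self.fc = Linear(ch[4], 2, rng)
        # Task2: U-Net decoder with skips (levels coarse -> fine)
        self.up2 = [UpBlock(ch[4], ch[3], ch[3], rng),
                    UpBlock(ch[3], ch[2], ch[2], rng),
                    UpBlock(ch[2], ch[1], ch[1], rng),
                    UpBlock(ch[1], ch[0], ch[0], rng)]
        self.seg_head = Conv2d(ch[0], config.n_classes_seg, 1, rng)
        # Task3: AFM-fused decoder
        self.afm = [AFMUnit(ch[4], ch[4], rng),
                    AFMUnit(ch[3], ch[3], rng),
                    AFMUnit(ch[2], ch[2], rng),
                    AFMUnit(ch[1], ch[1], rng)]
        self.up3 = [Task3Block(ch[4] + ch[3], ch[3], rng),
                    Task3Block(ch[3] + ch[2], ch[2], rng),
                    Task3Block(ch[2] + ch[1], ch[1], rng),
                    Task3Block(ch[1] + ch[0], ch[0], rng)]
        self.hm_head = Conv2d(ch[0], config.n_heatmaps, 1, rng)
        # rare-positive prior: start the sigmoid near the background rate so
        # the head does not have to spend its update budget desaturating
        self.hm_head.bias.data[...] = -4.0

    # ------------------------------------------------------------------
    def forward(self, x) -> NetworkOutput:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"input spatial size {(h, w)} not divisible by 16")
        skips = []
        f = x
        for i in range(4):
            f = self.enc[i](f)
            skips.append(f)
            f = self.eca[i](f.maxpool2x2())
        bott = self.enc[4](f)

        # Task1
        t1 = self.res2(self.res1(bott))
        class_probs = self.fc(t1.global_avg_pool()).softmax_channels()

        # Task2 + Task3 in lockstep (the AFM taps the Task2 stream)
        s_prev, l_prev = bott, bott
        for i in range(4):
            s_cur = self.up2[i](s_prev, skips[3 - i])
            w_fused = self.afm[i](s_prev, l_prev, s_cur)
            l_cur = self.up3[i](w_fused)
            s_prev, l_prev = s_cur, l_cur
        seg_probs = self.seg_head(s_prev).softmax_channels()
        heatmaps = self.hm_head(l_prev).sigmoid()
        return NetworkOutput(class_probs=class_probs, seg_probs=seg_probs,
                             heatmap_preds=heatmaps)

    __call__ = forward

    def encode_bottleneck(self, x) -> Tensor:
        """Shared-encoder bottleneck features (N, 16b, H/16, W/16)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        f = x
        for i in range(4):
            f = self.eca[i](self.enc[i](f).maxpool2x2())
        return self.enc[4](f)

    def classify_from_bottleneck(self, bott: Tensor) -> Tensor:
        t1 = self.res2(self.res1(bott))
        return self.fc(t1.global_avg_pool()).softmax_channels()

    def classify(self, x) -> Tensor:
        """Encoder + Task1 head only (the stage-2 path): (N, 2) probabilities."""
        return self.classify_from_bottleneck(self.encode_bottleneck(x))

    # ------------------------------------------------------------------
    def encoder_modules(self):
        return [*self.enc, *self.eca]

    def task1_modules(self):
        return [self.res1, self.res2, self.fc]

    def task2_modules(self):
        return [*self.up2, self.seg_head]

    def task3_modules(self):
        return [*self.afm, *self.up3, self.hm_head]

    @staticmethod
    def _params_of(mods):
        out = []
        for m in mods:
            out.extend(p for _, p in _named_params_of(m))
        return out

    def encoder_parameters(self):
        return self._params_of(self.encoder_modules())

    def task1_parameters(self):
        return self._params_of(self.task1_modules())

    def task2_parameters(self):
        return self._params_of(self.task2_modules())

    def task3_parameters(self):
        return self._params_of(self.task3_modules())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _named_params_of(m: Module):
    yield from m.named_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: MTUnet, extra: dict | None = None,
                    rng_state=None) -> None:
    """Archive: weights + BN buffers + config (+ optional RNG state/extras)."""
    arrays = {f"param/{k}": p.data for k, p in model.named_parameters()}
    arrays.update({f"buffer/{k}": v for k, v in model.named_buffers()})
    meta = {"config": asdict(model.config), "extra": extra or {}}
    if rng_state is not None:
        meta["rng_state"] = rng_state
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[MTUnet, dict]:
    """Rebuild the model from an archive; returns (model, metadata)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]))
        model = MTUnet(NetworkConfig(**meta["config"]))
        params = dict(model.named_parameters())
        for key in z.files:
            if key.startswith("param/"):
                params[key[6:]].data[...] = z[key]
            elif key.startswith("buffer/"):
                _assign_buffer(model, key[7:], z[key])
    return model, meta


def _assign_buffer(root: Module, dotted: str, value: np.ndarray) -> None:
    parts = dotted.split(".")
    obj = root
    for p in parts[:-1]:
        obj = obj[int(p)] if isinstance(obj, (list, tuple)) else getattr(obj, p)
    getattr(obj, parts[-1])[...] = value
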