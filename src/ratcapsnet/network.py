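"""The dual-pipeline classifier: encoder stages with a volumetric attention
mechanism (VAM), pyramid feature extractors (PFE) over pre-attention taps, and
a dense decision head.

Composition
-----------
* Compression pipeline: ``num_stages`` encoder stages in series.  Stage ``l``
  applies two same-padded 3x3 conv+LeakyReLU blocks (channel count ``n`` for
  the RGB input, doubling thereafter), the VAM, and a 2x2 max-pool, so the
  spatial dims halve per stage while channels follow n, 2n, 4n, ...
* VAM: a stride-2 conv to half the channels condenses the map spatially, a
  depthwise 3x3 conv re-weights it channel-wise, the two are summed, and a
  transposed convolution restores the input resolution as a single-channel
  sigmoid mask ``m``; the block returns ``x * (1 + m)``.
* Regional correlative pipeline: for each registered stage tap (taken before
  the VAM), four parallel conv blocks with kernels 1/3/5/7 and ``rho``
  channels, pairwise concatenation of adjacent branches, fusion convolutions
  (kernels 8/9/10 by default), and a final kernel-11 fusion down to
  ``2*rho`` channels.
* Decision pipeline: global-average-pooled vectors from the final stage and
  every pyramid output are concatenated and passed through dense layers
  (512, 128 by default) with LeakyReLU, then a softmax (or single sigmoid
  unit for the binary head).

The public functional ops (``conv_block``, ``vam_forward``, ...) accept and
return the HWC container types from :mod:`ratcapsnet.types`; the block classes
work on NCHW batches and carry the backward passes used for training.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .config import ConfigError, NetworkConfig
from .nn.layers import (
    Conv2d,
    ConvTranspose2dDouble,
    Dense,
    DepthwiseConv2d,
    GlobalAvgPool,
    LeakyReLU,
    MaxPool2x2,
    Module,
    Sigmoid,
    softmax,
)
from .types import AttentionMask, ClassProbabilities, FeatureMap, FeatureVector

__all__ = [
    "channel_rule",
    "conv_block",
    "vam_forward",
    "encoder_forward",
    "pfe_forward",
    "global_average_pool",
    "decision_forward",
    "assemble_ratcapsnet",
    "count_parameters",
    "extract_attention_maps",
    "ConvBlock",
    "VAMBlock",
    "EncoderStage",
    "PFEBlock",
    "DecisionHead",
    "RatCapsNet",
]


def channel_rule(c_in: int, base_width_n: int = 32) -> int:
    """Channel count produced by an encoder stage from ``c_in`` input channels:
    the base width for the 3-channel RGB input, twice the input otherwise."""
    if c_in < 1:
        raise ValueError(f"channel count must be >= 1, got {c_in}")
    return base_width_n if c_in == 3 else 2 * c_in


# ---------------------------------------------------------------------------
# blocks (NCHW, with backward)
# ---------------------------------------------------------------------------

class ConvBlock(Module):
    """Same-padded convolution followed by LeakyReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 slope: float = 0.1, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel, stride, rng=rng)
        self.act = LeakyReLU(slope)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def cast(self, dtype) -> None:
        self.conv.cast(dtype)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.conv.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.act.backward(dout))


class VAMBlock(Module):
    """Volumetric attention over a feature map with an even channel count.

    forward(x) -> (f, mask) with f = x * (1 + mask); mask is H x W x 1 in
    [0, 1].  Requires even H and W so the transposed convolution restores the
    input resolution exactly.
    """

    def __init__(self, channels: int, slope: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 2:
            raise ValueError(f"VAM needs an even channel count, got {channels}")
        self.channels = channels
        rng = rng or np.random.default_rng(0)
        half = channels // 2
        self.squeeze = ConvBlock(channels, half, 3, stride=2, slope=slope, rng=rng)
        self.depthwise = DepthwiseConv2d(half, 3, rng=rng)
        self.dw_act = LeakyReLU(slope)
        self.up = ConvTranspose2dDouble(half, 1, 3, rng=rng)
        self.up_act = LeakyReLU(slope)
        self.sigmoid = Sigmoid()
        self._collect()

    def _collect(self):
        self.params = OrderedDict()
        self.grads = OrderedDict()
        for prefix, mod in (("squeeze", self.squeeze),
                            ("depthwise", self.depthwise), ("up", self.up)):
            for k, v in mod.params.items():
                self.params[f"{prefix}.{k}"] = v
                self.grads[f"{prefix}.{k}"] = mod.grads[k]

    def cast(self, dtype) -> None:
        for mod in (self.squeeze, self.depthwise, self.up):
            mod.cast(dtype)
        self._collect()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        _, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"VAM needs even spatial dims, got {h}x{w}")
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        xs = self.squeeze.forward(x)
        xc = self.dw_act.forward(self.depthwise.forward(xs))
        xv = xs + xc
        mask = self.sigmoid.forward(self.up_act.forward(self.up.forward(xv)))
        self._cache = (x, mask)
        f = x * (1.0 + mask)
        return f, mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mask = self._cache
        dx = dout * (1.0 + mask)
        dmask = (dout * x).sum(axis=1, keepdims=True)
        dxv = self.up.backward(
            self.up_act.backward(self.sigmoid.backward(dmask)))
        dxs = dxv + self.depthwise.backward(self.dw_act.backward(dxv))
        dx += self.squeeze.backward(dxs)
        return dx


class EncoderStage(Module):
    """Two 3x3 conv blocks, VAM, 2x2 max-pool; exports the pre-VAM tap."""

    def __init__(self, c_in: int, base_width_n: int, slope: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c_out = channel_rule(c_in, base_width_n)
        self.c_in, self.c_out = c_in, c_out
        self.conv1 = ConvBlock(c_in, c_out, 3, 1, slope, rng)
        self.conv2 = ConvBlock(c_out, c_out, 3, 1, slope, rng)
        self.vam = VAMBlock(c_out, slope, rng)
        self.pool = MaxPool2x2()
        self._collect()

    def _collect(self):
        self.params = OrderedDict()
        self.grads = OrderedDict()
        for prefix, mod in (("conv1", self.conv1), ("conv2", self.conv2),
                            ("vam", self.vam)):
            for k, v in mod.params.items():
                self.params[f"{prefix}.{k}"] = v
                self.grads[f"{prefix}.{k}"] = mod.grads[k]

    def cast(self, dtype) -> None:
        for mod in (self.conv1, self.conv2, self.vam):
            mod.cast(dtype)
        self._collect()

    def forward(self, x: np.ndarray):
        """Returns (pooled output, tap, mask)."""
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"encoder stage needs even spatial dims, got {h}x{w}")
        x_r = self.conv2.forward(self.conv1.forward(x))
        f, mask = self.vam.forward(x_r)
        y = self.pool.forward(f)
        return y, x_r, mask

    def backward(self, dy: np.ndarray, d_tap: np.ndarray | None = None):
        df = self.pool.backward(dy)
        dx_r = self.vam.backward(df)
        if d_tap is not None:
            dx_r = dx_r + d_tap
        return self.conv1.backward(self.conv2.backward(dx_r))


class PFEBlock(Module):
    """Pyramid feature extractor producing a 2*rho-channel map.

    Four parallel conv blocks (kernels 1/3/5/7, rho channels each), adjacent
    pairs concatenated to 2*rho, fused by conv blocks with the configured
    kernels (8/9/10), concatenated to 6*rho, and fused to 2*rho by a
    kernel-11 conv block.  Spatial dims are preserved throughout.
    """

    def __init__(self, c_in: int, rho: int, slope: float = 0.1,
                 fusion_kernels: tuple[int, int, int] = (8, 9, 10),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.rho = c_in, rho
        self.branches = [ConvBlock(c_in, rho, 2 * j + 1, 1, slope, rng)
                         for j in range(4)]
        self.fusions = [ConvBlock(2 * rho, 2 * rho, k, 1, slope, rng)
                        for k in fusion_kernels]
        self.final = ConvBlock(6 * rho, 2 * rho, 11, 1, slope, rng)
        self._collect()

    def _collect(self):
        self.params = OrderedDict()
        self.grads = OrderedDict()
        named = [(f"branch{j}", b) for j, b in enumerate(self.branches)]
        named += [(f"fusion{j}", f) for j, f in enumerate(self.fusions)]
        named.append(("final", self.final))
        for prefix, mod in named:
            for k, v in mod.params.items():
                self.params[f"{prefix}.{k}"] = v
                self.grads[f"{prefix}.{k}"] = mod.grads[k]

    def cast(self, dtype) -> None:
        for mod in (*self.branches, *self.fusions, self.final):
            mod.cast(dtype)
        self._collect()

    def forward(self, x: np.ndarray) -> np.ndarray:
        r = [b.forward(x) for b in self.branches]
        pairs = [np.concatenate([r[j], r[j + 1]], axis=1) for j in range(3)]
        fused = [f.forward(p) for f, p in zip(self.fusions, pairs)]
        return self.final.forward(np.concatenate(fused, axis=1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        rho = self.rho
        dcat = self.final.backward(dout)
        dr = [None] * 4
        for j in range(3):
            dpair = self.fusions[j].backward(dcat[:, 2 * j * rho:(2 * j + 2) * rho])
            for idx, dpart in ((j, dpair[:, :rho]), (j + 1, dpair[:, rho:])):
                dr[idx] = dpart if dr[idx] is None else dr[idx] + dpart
        dx = None
        for b, d in zip(self.branches, dr):
            dxb = b.backward(d)
            dx = dxb if dx is None else dx + dxb
        return dx


class DecisionHead(Module):
    """dense(d1)+LeakyReLU -> dense(d2)+LeakyReLU -> logits."""

    def __init__(self, n_in: int, dense_sizes: tuple[int, int],
                 num_classes: int, head_mode: str, slope: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in = n_in
        self.head_mode = head_mode
        n_out = 1 if head_mode == "sigmoid_binary" else num_classes
        d1, d2 = dense_sizes
        self.fc1 = Dense(n_in, d1, rng)
        self.act1 = LeakyReLU(slope)
        self.fc2 = Dense(d1, d2, rng)
        self.act2 = LeakyReLU(slope)
        self.fc3 = Dense(d2, n_out, rng)
        self._collect()

    def _collect(self):
        self.params = OrderedDict()
        self.grads = OrderedDict()
        for prefix, mod in (("fc1", self.fc1), ("fc2", self.fc2),
                            ("fc3", self.fc3)):
            for k, v in mod.params.items():
                self.params[f"{prefix}.{k}"] = v
                self.grads[f"{prefix}.{k}"] = mod.grads[k]

    def cast(self, dtype) -> None:
        for mod in (self.fc1, self.fc2, self.fc3):
            mod.cast(dtype)
        self._collect()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Returns logits (N, num_classes) or (N, 1)."""
        if x.shape[1] != self.n_in:
            raise ValueError(f"decision head expects {self.n_in} features, "
                             f"got {x.shape[1]}")
        h = self.act1.forward(self.fc1.forward(x))
        h = self.act2.forward(self.fc2.forward(h))
        return self.fc3.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.act2.backward(self.fc3.backward(dlogits))
        dh = self.act1.backward(self.fc2.backward(dh))
        return self.fc1.backward(dh)

    def probabilities(self, logits: np.ndarray) -> np.ndarray:
        if self.head_mode == "sigmoid_binary":
            return 1.0 / (1.0 + np.exp(-logits))
        return softmax(logits)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

class RatCapsNet:
    """The assembled model; forward maps NCHW batches to logits."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stages: list[EncoderStage] = []
        c = 3
        for _ in range(config.num_stages):
            stage = EncoderStage(c, config.base_width_n, config.leaky_slope, rng)
            self.stages.append(stage)
            c = stage.c_out
        self.pfes: dict[int, PFEBlock] = {}
        for l in config.pfe_stages:
            self.pfes[l] = PFEBlock(self.stages[l - 1].c_out,
                                    config.pfe_width_rho, config.leaky_slope,
                                    config.pfe_fusion_kernels, rng)
        self.gap = GlobalAvgPool()
        self.pfe_gaps = {l: GlobalAvgPool() for l in config.pfe_stages}
        self.head = DecisionHead(config.head_input_size, config.dense_sizes,
                                 config.num_classes, config.head_mode,
                                 config.leaky_slope, rng)

    # -- bookkeeping -------------------------------------------------------
    def modules(self) -> "OrderedDict[str, Module]":
        mods: "OrderedDict[str, Module]" = OrderedDict()
        for i, s in enumerate(self.stages, start=1):
            mods[f"stage{i}"] = s
        for l, p in self.pfes.items():
            mods[f"pfe{l}"] = p
        mods["head"] = self.head
        return mods

    def zero_grad(self) -> None:
        for mod in self.modules().values():
            mod.zero_grad()

    def cast(self, dtype) -> None:
        for mod in self.modules().values():
            mod.cast(dtype)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{name}.{key}": p for name, mod in self.modules().items()
                for key, p in mod.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"checkpoint/model parameter mismatch: {sorted(missing)[:5]}")
        for key, arr in state.items():
            if own[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: "
                                 f"{own[key].shape} vs {arr.shape}")
            own[key][...] = arr

    # -- forward / backward ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if tuple(x.shape[2:]) != self.config.input_hw:
            raise ValueError(f"expected spatial dims {self.config.input_hw}, "
                             f"got {tuple(x.shape[2:])}")
        dtype = self.stages[0].params["conv1.W"].dtype
        return x.astype(dtype, copy=False)

    def forward_full(self, x: np.ndarray):
        """Returns (logits, taps, masks, pfe_maps); taps etc. keyed by stage."""
        x = self._check_input(x)
        taps: dict[int, np.ndarray] = {}
        masks: dict[int, np.ndarray] = {}
        h = x
        for l, stage in enumerate(self.stages, start=1):
            h, x_r, mask = stage.forward(h)
            taps[l] = x_r
            masks[l] = mask
        self._y5_shape = h.shape
        y5_vec = self.gap.forward(h)
        pfe_maps: dict[int, np.ndarray] = {}
        p_vecs = []
        for l in self.config.pfe_stages:
            p = self.pfes[l].forward(taps[l])
            pfe_maps[l] = p
            p_vecs.append(self.pfe_gaps[l].forward(p))
        feat = np.concatenate([y5_vec] + p_vecs, axis=1)
        logits = self.head.forward(feat)
        return logits, taps, masks, pfe_maps

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.forward_full(x)[0]

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        dfeat = self.head.backward(dlogits)
        c5 = self.stages[-1].c_out
        dy5_vec = dfeat[:, :c5]
        d_taps: dict[int, np.ndarray] = {}
        off = c5
        width = 2 * cfg.pfe_width_rho
        for l in cfg.pfe_stages:
            dp_vec = dfeat[:, off: off + width]
            off += width
            dp = self.pfe_gaps[l].backward(dp_vec)
            d_taps[l] = self.pfes[l].backward(dp)
        dh = self.gap.backward(dy5_vec)
        for l in range(cfg.num_stages, 0, -1):
            dh = self.stages[l - 1].backward(dh, d_taps.get(l))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.head.probabilities(self.forward(x))

    def count_parameters(self) -> int:
        return sum(mod.n_params() for mod in self.modules().values())


# ---------------------------------------------------------------------------
# functional ops on the HWC container types
# ---------------------------------------------------------------------------

def _to_nchw(fm: FeatureMap) -> np.ndarray:
    # keeps float64 so the single-map functional ops stay at full precision
    return np.ascontiguousarray(fm.values.transpose(2, 0, 1)[None])


def _to_hwc(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr[0].transpose(1, 2, 0), dtype=np.float64)


def conv_block(x: FeatureMap, out_channels: int, kernel: int, stride: int = 1,
               slope: float = 0.1, seed: int = 0,
               block: ConvBlock | None = None) -> FeatureMap:
    """Same-padded conv + LeakyReLU on a single HWC map."""
    if kernel < 1 or stride < 1:
        raise ValueError("kernel and stride must be >= 1")
    if block is None:
        block = ConvBlock(x.shape[2], out_channels, kernel, stride, slope,
                          np.random.default_rng(seed))
    return FeatureMap(_to_hwc(block.forward(_to_nchw(x))))


def vam_forward(x_r: FeatureMap, slope: float = 0.1, seed: int = 0,
                block: VAMBlock | None = None) -> tuple[FeatureMap, AttentionMask]:
    """Attention pass over a tap: returns (enhanced map, mask in [0,1])."""
    h, w, c = x_r.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even, got {h}x{w}")
    if c % 2:
        raise ValueError(f"channel count must be even, got {c}")
    if block is None:
        block = VAMBlock(c, slope, np.random.default_rng(seed))
    f, mask = block.forward(_to_nchw(x_r))
    return FeatureMap(_to_hwc(f)), AttentionMask(_to_hwc(mask))


def encoder_forward(x: FeatureMap, stage: int = 1, base_width_n: int = 32,
                    slope: float = 0.1, seed: int = 0,
                    block: EncoderStage | None = None
                    ) -> tuple[FeatureMap, FeatureMap, AttentionMask]:
    """One encoder stage: returns (pooled output, tap, mask)."""
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even, got {h}x{w}")
    if block is None:
        block = EncoderStage(c, base_width_n, slope, np.random.default_rng(seed))
    y, x_r, mask = block.forward(_to_nchw(x))
    return FeatureMap(_to_hwc(y)), FeatureMap(_to_hwc(x_r)), AttentionMask(_to_hwc(mask))


def pfe_forward(x_r: FeatureMap, pfe_width_rho: int = 16, slope: float = 0.1,
                fusion_kernels: tuple[int, int, int] = (8, 9, 10),
                seed: int = 0, block: PFEBlock | None = None) -> FeatureMap:
    """Pyramid feature extraction producing a 2*rho-channel map."""
    if block is None:
        block = PFEBlock(x_r.shape[2], pfe_width_rho, slope, fusion_kernels,
                         np.random.default_rng(seed))
    return FeatureMap(_to_hwc(block.forward(_to_nchw(x_r))))


def global_average_pool(x: FeatureMap) -> FeatureVector:
    """Per-channel spatial mean of an HWC map."""
    return FeatureVector(np.asarray(x.values, dtype=np.float64).mean(axis=(0, 1)))


def decision_forward(y5_vec: FeatureVector, p_vecs: list[FeatureVector],
                     config: NetworkConfig | None = None,
                     head: DecisionHead | None = None) -> ClassProbabilities:
    """Dense head over the concatenated pooled vectors."""
    config = config or NetworkConfig()
    feat = np.concatenate([y5_vec.values] + [p.values for p in p_vecs])
    if feat.size != config.head_input_size:
        raise ValueError(f"expected {config.head_input_size} concatenated "
                         f"features, got {feat.size}")
    if head is None:
        head = DecisionHead(config.head_input_size, config.dense_sizes,
                            config.num_classes, config.head_mode,
                            config.leaky_slope,
                            np.random.default_rng(config.seed))
    logits = head.forward(feat[None].astype(np.float32))
    return ClassProbabilities(head.probabilities(logits)[0])


def assemble_ratcapsnet(config: NetworkConfig) -> RatCapsNet:
    """Builds the full model; raises ConfigError naming any violated invariant."""
    try:
        config.validate()
    except ConfigError:
        raise
    return RatCapsNet(config)


def count_parameters(model: RatCapsNet) -> int:
    """Exact count of trainable scalar weights."""
    return model.count_parameters()


def extract_attention_maps(model: RatCapsNet, image: np.ndarray
                           ) -> tuple[list[tuple[int, AttentionMask]],
                                      list[tuple[int, FeatureMap]]]:
    """Evaluates the model on one HWC image and returns the per-stage
    attention masks and the per-stage pyramid maps."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    if tuple(img.shape[:2]) != model.config.input_hw:
        raise ValueError(f"image dims {img.shape[:2]} do not match the model "
                         f"input {model.config.input_hw}")
    x = np.ascontiguousarray(img.transpose(2, 0, 1))[None]
    _, _, masks, pfe_maps = model.forward_full(x)
    mask_list = [(l, AttentionMask(_to_hwc(m))) for l, m in sorted(masks.items())]
    pfe_list = [(l, FeatureMap(_to_hwc(p))) for l, p in sorted(pfe_maps.items())]
    return mask_list, pfe_list
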