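"""Network architectures for the two-step missing-wedge model.

* :class:`RRDBGenerator` — residual-in-residual dense-block sinogram inpainter
  (no normalization layers, no pooling, full-resolution throughout, with a
  dilated convolution to widen the receptive field; no upsampling tail).
* :class:`DualPathDiscriminator` — conditional sinogram discriminator with a
  large-receptive-field slow path and a small-receptive-field fast path,
  group normalization, an asymmetric input kernel (sinograms are not square).
* :class:`UNetGenerator` — encoder/decoder with skip connections for tomogram
  artifact removal; predicts a residual correction added to its input.
* :class:`TomoDiscriminator` — dilated convolution stack with batch
  normalization and a max-pool reduction before the scalar score.
"""

from __future__ import annotations

import numpy as np

from .layers import (DTYPE, BatchNorm2d, Conv2d, GlobalAvgPool, GlobalMaxPool,
                     GroupNorm, Layer, LeakyReLU, Linear, MaxPool2x2, Parameter,
                     Sequential, UpsampleNearest2x)


def _iter_layers(layer):
    """Depth-first traversal into composite layers (Sequential and blocks
    exposing ``seq``/``convs``/``blocks`` children)."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
        return
    for attr in ("seq", "convs", "blocks"):
        children = getattr(layer, attr, None)
        if children is not None:
            if isinstance(children, Layer):
                children = [children]
            for sub in children:
                yield from _iter_layers(sub)
            return
    yield layer


class Model:
    """Base class: ordered layer registry, parameter access, npz round trip."""

    def __init__(self):
        self._registry: list[Layer] = []

    def _register(self, layer: Layer) -> Layer:
        self._registry.append(layer)
        return layer

    def parameters(self) -> list[Parameter]:
        return [p for l in self._registry for p in l.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _stat_arrays(self):
        out = []
        for l in self._registry:
            for sub in _iter_layers(l):
                if isinstance(sub, BatchNorm2d):
                    out.extend([sub.running_mean, sub.running_var])
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self._stat_arrays()

    def load_state_arrays(self, arrays) -> None:
        own = self.state_arrays()
        if len(arrays) != len(own):
            raise ValueError("state layout mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def save(self, path) -> None:
        np.savez(path, **{f"a{i}": a for i, a in enumerate(self.state_arrays())})

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state_arrays([z[f"a{i}"] for i in range(len(z.files))])

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, x) -> np.ndarray:
        """Deterministic inference (frozen statistics, no gradient caches kept)."""
        y, _ = self.forward(np.asarray(x, dtype=DTYPE), train=False)
        return y


class _DenseBlock(Layer):
    """5-conv dense block: each conv sees all previous features; 0.2-scaled residual."""

    def __init__(self, nf, gc, rng):
        self.nf, self.gc = nf, gc
        self.convs = [
            Conv2d(nf + i * gc, gc if i < 4 else nf, 3, rng=rng, init_scale=0.1,
                   name=f"rdb.c{i+1}")
            for i in range(5)
        ]
        self.act = LeakyReLU(0.2)

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()]

    def forward(self, x, train=True):
        feats = [x]
        caches = []
        for i, conv in enumerate(self.convs):
            cin = np.concatenate(feats, axis=1)
            y, cc = conv.forward(cin, train)
            if i < 4:
                y, ac = self.act.forward(y, train)
                caches.append((cc, ac))
                feats.append(y)
            else:
                caches.append((cc, None))
                out = x + DTYPE(0.2) * y
        return out, caches

    def backward(self, dy, caches):
        splits = [self.nf] + [self.gc] * 4
        dfeats = [dy.copy()] + [None] * 4  # grads w.r.t. x, x1..x4
        cc, _ = caches[4]
        dcat = self.convs[4].backward(DTYPE(0.2) * dy, cc)
        off = 0
        for k, s in enumerate(splits):
            piece = dcat[:, off:off + s]
            dfeats[k] = dfeats[k] + piece if dfeats[k] is not None else piece.copy()
            off += s
        for i in range(3, -1, -1):
            cc, ac = caches[i]
            dyi = self.act.backward(dfeats[i + 1], ac)
            dcat = self.convs[i].backward(dyi, cc)
            off = 0
            for k, s in enumerate(splits[:i + 1]):
                dfeats[k] += dcat[:, off:off + s]
                off += s
        return dfeats[0]


class _RRDB(Layer):
    """Three chained dense blocks inside an outer 0.2-scaled residual."""

    def __init__(self, nf, gc, rng):
        self.blocks = [_DenseBlock(nf, gc, rng) for _ in range(3)]

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()]

    def forward(self, x, train=True):
        y = x
        caches = []
        for b in self.blocks:
            y, c = b.forward(y, train)
            caches.append(c)
        return x + DTYPE(0.2) * y, caches

    def backward(self, dy, caches):
        d = DTYPE(0.2) * dy
        for b, c in zip(reversed(self.blocks), reversed(caches)):
            d = b.backward(d, c)
        return dy + d


class RRDBGenerator(Model):
    """Sinogram inpainting generator.

    Maps a 1-channel (angles x bins) array to a same-shape array.  Structure:
    feature conv, ``n_blocks`` RRDB blocks with a trunk conv and global
    residual, a dilated conv widening the receptive field, and an output conv.
    No normalization layers and no pooling, so inference is deterministic and
    full-resolution.
    """

    def __init__(self, n_blocks=8, feature_depth=64, growth_channels=32,
                 dilation=2, seed=0):
        super().__init__()
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not (feature_depth >= growth_channels >= 1):
            raise ValueError("need feature_depth >= growth_channels >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.config = dict(n_blocks=n_blocks, feature_depth=feature_depth,
                           growth_channels=growth_channels, dilation=dilation)
        rng = np.random.default_rng(seed)
        nf, gc = feature_depth, growth_channels
        self.conv_first = self._register(Conv2d(1, nf, 3, rng=rng, name="g.first"))
        self.body = [self._register(_RRDB(nf, gc, rng)) for _ in range(n_blocks)]
        self.trunk = self._register(Conv2d(nf, nf, 3, rng=rng, name="g.trunk"))
        self.dilated = self._register(Conv2d(nf, nf, 3, dilation=dilation, rng=rng,
                                             name="g.dilated"))
        self.conv_last = self._register(Conv2d(nf, 1, 3, rng=rng, init_scale=0.1,
                                               name="g.last"))
        self.act = LeakyReLU(0.2)

    def forward(self, x, train=True):
        f0, c_first = self.conv_first.forward(x, train)
        y = f0
        body_caches = []
        for blk in self.body:
            y, c = blk.forward(y, train)
            body_caches.append(c)
        t, c_trunk = self.trunk.forward(y, train)
        feat = f0 + t
        d, c_dil = self.dilated.forward(feat, train)
        d, c_act = self.act.forward(d, train)
        out, c_last = self.conv_last.forward(d, train)
        return out, (c_first, body_caches, c_trunk, c_dil, c_act, c_last)

    def backward(self, dy, cache):
        c_first, body_caches, c_trunk, c_dil, c_act, c_last = cache
        dd = self.conv_last.backward(dy, c_last)
        dd = self.act.backward(dd, c_act)
        dfeat = self.dilated.backward(dd, c_dil)
        dt = self.trunk.backward(dfeat, c_trunk)
        for blk, c in zip(reversed(self.body), reversed(body_caches)):
            dt = blk.backward(dt, c)
        df0 = dfeat + dt
        return self.conv_first.backward(df0, c_first)


class DualPathDiscriminator(Model):
    """Conditional sinogram discriminator with slow (global) and fast (local) paths.

    Input is a 2-channel stack of the candidate sinogram and the masked
    sinogram that conditioned the generator.  The slow path uses more strided
    layers and dilated kernels (large receptive field); the fast path is
    shallower (local detail).  Pooled features from both paths are
    concatenated and reduced to one scalar score per sample.
    """

    def __init__(self, feature_depth=64, group_norm_groups=4, slow_path_depth=5,
                 fast_path_depth=3, dilation=2, input_kernel=(5, 3), seed=0):
        super().__init__()
        if feature_depth % group_norm_groups:
            raise ValueError("group_norm_groups must divide feature_depth")
        if slow_path_depth <= fast_path_depth:
            raise ValueError("slow path must be deeper than the fast path")
        self.config = dict(feature_depth=feature_depth,
                           group_norm_groups=group_norm_groups,
                           slow_path_depth=slow_path_depth,
                           fast_path_depth=fast_path_depth, dilation=dilation,
                           input_kernel=tuple(input_kernel))
        rng = np.random.default_rng(seed)
        nf, g = feature_depth, group_norm_groups
        self.stem = self._register(Sequential(
            Conv2d(2, nf, input_kernel, rng=rng, name="d.stem"),
            GroupNorm(nf, g, name="d.stem"),
            LeakyReLU(0.2),
        ))
        slow_layers, fast_layers = [], []
        for i in range(slow_path_depth):
            slow_layers += [Conv2d(nf, nf, 3, stride=2, dilation=dilation, rng=rng,
                                   name=f"d.slow{i}"),
                            GroupNorm(nf, g, name=f"d.slow{i}"), LeakyReLU(0.2)]
        for i in range(fast_path_depth):
            fast_layers += [Conv2d(nf, nf, 3, stride=2, rng=rng, name=f"d.fast{i}"),
                            GroupNorm(nf, g, name=f"d.fast{i}"), LeakyReLU(0.2)]
        self.slow = self._register(Sequential(*slow_layers))
        self.fast = self._register(Sequential(*fast_layers))
        self.pool = GlobalAvgPool()
        self.head = self._register(Linear(2 * nf, 1, rng=rng, name="d.head"))

    def forward(self, x, train=True):
        h, c_stem = self.stem.forward(x, train)
        s, c_slow = self.slow.forward(h, train)
        f, c_fast = self.fast.forward(h, train)
        sp, c_sp = self.pool.forward(s, train)
        fp, c_fp = self.pool.forward(f, train)
        feat = np.concatenate([sp, fp], axis=1)
        score, c_head = self.head.forward(feat, train)
        return score[:, 0], (c_stem, c_slow, c_fast, c_sp, c_fp, c_head)

    def backward(self, dscore, cache):
        c_stem, c_slow, c_fast, c_sp, c_fp, c_head = cache
        nf = self.config["feature_depth"]
        dfeat = self.head.backward(np.asarray(dscore, dtype=DTYPE)[:, None], c_head)
        ds = self.pool.backward(dfeat[:, :nf], c_sp)
        df = self.pool.backward(dfeat[:, nf:], c_fp)
        dh = self.slow.backward(ds, c_slow) + self.fast.backward(df, c_fast)
        return self.stem.backward(dh, c_stem)


class _ConvBlock(Layer):
    """conv-(BN)-lrelu twice; the U-net building block."""

    def __init__(self, cin, cout, rng, norm=True, name="u"):
        layers = [Conv2d(cin, cout, 3, rng=rng, name=name + ".c1")]
        if norm:
            layers.append(BatchNorm2d(cout, name=name + ".bn1"))
        layers.append(LeakyReLU(0.2))
        layers.append(Conv2d(cout, cout, 3, rng=rng, name=name + ".c2"))
        if norm:
            layers.append(BatchNorm2d(cout, name=name + ".bn2"))
        layers.append(LeakyReLU(0.2))
        self.seq = Sequential(*layers)

    def parameters(self):
        return self.seq.parameters()

    def forward(self, x, train=True):
        return self.seq.forward(x, train)

    def backward(self, dy, cache):
        return self.seq.backward(dy, cache)


class UNetGenerator(Model):
    """U-net tomogram de-artifacter; output = input + learned residual.

    ``depth`` encoder levels with channel doubling, skip connections at every
    level, nearest-neighbour upsampling in the decoder.  Spatial dims must be
    divisible by ``2**depth``.
    """

    def __init__(self, depth=4, base_channels=64, norm=True, seed=0):
        super().__init__()
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.config = dict(depth=depth, base_channels=base_channels, norm=norm)
        rng = np.random.default_rng(seed)
        self.depth = depth
        chans = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = [self._register(_ConvBlock(1 if i == 0 else chans[i - 1], chans[i],
                                              rng, norm, name=f"u.enc{i}"))
                    for i in range(depth)]
        self.pool = MaxPool2x2()
        self.bottleneck = self._register(_ConvBlock(chans[depth - 1], chans[depth],
                                                    rng, norm, name="u.bot"))
        self.up = UpsampleNearest2x()
        self.upconv = [self._register(Conv2d(chans[i + 1], chans[i], 3, rng=rng,
                                             name=f"u.up{i}"))
                       for i in reversed(range(depth))]
        self.dec = [self._register(_ConvBlock(2 * chans[i], chans[i], rng, norm,
                                              name=f"u.dec{i}"))
                    for i in reversed(range(depth))]
        self.out_conv = self._register(Conv2d(chans[0], 1, 1, rng=rng,
                                              init_scale=0.01, name="u.out"))

    def forward(self, x, train=True, ablate: str | None = None):
        """``ablate`` zeroes one internal signal ("bottleneck" or "top_skip");
        an inference-only probe for checking that the skip wiring is live."""
        if x.shape[2] % 2 ** self.depth or x.shape[3] % 2 ** self.depth:
            raise ValueError(f"spatial dims must be divisible by {2 ** self.depth}")
        skips, enc_caches, pool_caches = [], [], []
        h = x
        for blk in self.enc:
            h, c = blk.forward(h, train)
            enc_caches.append(c)
            skips.append(h)
            h, pc = self.pool.forward(h, train)
            pool_caches.append(pc)
        h, c_bot = self.bottleneck.forward(h, train)
        if ablate == "bottleneck":
            h = np.zeros_like(h)
        elif ablate == "top_skip":
            skips[0] = np.zeros_like(skips[0])
        elif ablate is not None:
            raise ValueError(f"unknown ablation {ablate!r}")
        dec_caches = []
        for i in range(self.depth):
            h, cu = self.up.forward(h, train)
            h, cc = self.upconv[i].forward(h, train)
            skip = skips[self.depth - 1 - i]
            h = np.concatenate([skip, h], axis=1)
            h, cb = self.dec[i].forward(h, train)
            dec_caches.append((cu, cc, cb))
        res, c_out = self.out_conv.forward(h, train)
        return x + res, (enc_caches, pool_caches, c_bot, dec_caches, c_out)

    def backward(self, dy, cache):
        enc_caches, pool_caches, c_bot, dec_caches, c_out = cache
        dh = self.out_conv.backward(dy, c_out)
        dskips = [None] * self.depth
        for i in range(self.depth - 1, -1, -1):
            cu, cc, cb = dec_caches[i]
            dcat = self.dec[i].backward(dh, cb)
            lvl = self.depth - 1 - i
            c_skip = dcat.shape[1] // 2
            dskips[lvl] = dcat[:, :c_skip]
            dup = self.upconv[i].backward(dcat[:, c_skip:], cc)
            dh = self.up.backward(dup, cu)
        dh = self.bottleneck.backward(dh, c_bot)
        for lvl in range(self.depth - 1, -1, -1):
            d = self.pool.backward(dh, pool_caches[lvl]) + dskips[lvl]
            dh = self.enc[lvl].backward(d, enc_caches[lvl])
        return dh + dy  # identity branch


class TomoDiscriminator(Model):
    """Conditional tomogram discriminator: dilated conv stack, batch norm,
    global max-pool reduction, scalar score."""

    def __init__(self, feature_depth=64, n_layers=4, dilation=2, seed=0):
        super().__init__()
        self.config = dict(feature_depth=feature_depth, n_layers=n_layers,
                           dilation=dilation)
        rng = np.random.default_rng(seed)
        nf = feature_depth
        layers = [Conv2d(2, nf, 3, rng=rng, name="td.stem"),
                  BatchNorm2d(nf, name="td.stem"), LeakyReLU(0.2)]
        for i in range(n_layers):
            layers += [Conv2d(nf, nf, 3, stride=2, dilation=dilation, rng=rng,
                              name=f"td.c{i}"),
                       BatchNorm2d(nf, name=f"td.c{i}"), LeakyReLU(0.2)]
        self.body = self._register(Sequential(*layers))
        self.pool = GlobalMaxPool()
        self.head = self._register(Linear(nf, 1, rng=rng, name="td.head"))

    def forward(self, x, train=True):
        h, c_body = self.body.forward(x, train)
        p, c_pool = self.pool.forward(h, train)
        score, c_head = self.head.forward(p, train)
        return score[:, 0], (c_body, c_pool, c_head)

    def backward(self, dscore, cache):
        c_body, c_pool, c_head = cache
        dp = self.head.backward(np.asarray(dscore, dtype=DTYPE)[:, None], c_head)
        dh = self.pool.backward(dp, c_pool)
        return self.body.backward(dh, c_body)
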