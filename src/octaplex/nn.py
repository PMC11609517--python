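"""A small, dependency-free convolutional encoder-decoder.

Implements exactly what the plexus segmenter needs, in NumPy: 3x3/1x1
convolutions (im2col + BLAS matmul), leaky ReLU, 2x2 average pooling, nearest
upsampling, skip connections merged by concatenation (``unet_like``) or
addition (``linknet_like``), a per-pixel 3-class softmax head, categorical
cross-entropy, and the Adam optimizer.  Forward and backward passes are
hand-derived for this fixed topology; everything is float32 and fully
deterministic for a given seed, which makes training runs bit-reproducible.

Arrays are NHWC (channels last), which lets im2col run without layout
transposes.  The first layer is a learned 1x1 convolution adapting the
single grayscale channel to the 3 channels the encoder expects.
"""

from __future__ import annotations

import numpy as np

ARCHITECTURES = ("unet_like", "linknet_like")

#: scale presets: (base_channels, n_stages)
SCALE_PRESETS = {"tiny": (8, 2), "paper": (32, 4)}


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d:
    """Same-padding convolution, kernel 1 or 3, stride 1, NHWC."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        if ksize not in (1, 3):
            raise ValueError("supported kernel sizes: 1, 3")
        self.cin, self.cout, self.k = cin, cout, ksize
        self.W = _he(rng, cin * ksize * ksize, (cin * ksize * ksize, cout))
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if self.k == 1:
            cols = np.ascontiguousarray(x).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
            cols = win.reshape(-1, c * 9)  # per-pixel layout: (C, 3, 3)
        y = cols @ self.W + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dyf = np.ascontiguousarray(dy).reshape(-1, self.cout)
        self.dW += self._cols.T @ dyf
        self.db += dyf.sum(axis=0)
        dcols = dyf @ self.W.T
        if self.k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[:, :, :, :, ki, kj]
        return dxp[:, 1:1 + h, 1:1 + w, :]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class LeakyReLU:
    """Leaky rectifier (slope 0.1 below zero).

    The leak matters here: at this parameter count a fully dead rectified
    path can permanently silence one class's logit (observed as a
    zero-Dice class collapse on unlucky seeds); the leak keeps gradient
    flowing and removes that failure mode.
    """

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.where(x > 0, x, self.alpha * x)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


def avg_pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def avg_pool2_backward(dy: np.ndarray) -> np.ndarray:
    return (dy / 4.0).repeat(2, axis=1).repeat(2, axis=2)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the trailing (class) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-pixel categorical cross-entropy and its logits gradient.

    ``logits`` is (N, H, W, K); ``labels`` is (N, H, W) integer classes.
    """
    n, h, w, k = logits.shape
    p = softmax_channels(logits)
    picked = np.clip(np.take_along_axis(p, labels[..., None], axis=-1), 1e-12, None)
    loss = float(-np.log(picked).mean())
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits


class EncoderDecoder:
    """Encoder-decoder segmentation network with a 1x1 input adapter.

    ``unet_like`` merges decoder and encoder features by channel
    concatenation, ``linknet_like`` by element-wise addition; the two are
    otherwise identical.  The head is a 1x1 convolution to ``n_classes``
    logits; ``predict_proba`` appends the softmax.
    """

    def __init__(self, architecture: str = "unet_like", base_channels: int = 8,
                 n_stages: int = 2, n_classes: int = 3, seed: int = 0):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}; "
                             f"choose from {ARCHITECTURES}")
        rng = np.random.default_rng(seed)
        self.architecture = architecture
        self.base_channels = base_channels
        self.n_stages = n_stages
        self.n_classes = n_classes
        c = base_channels
        self.adapter = Conv2d(1, 3, 1, rng)
        self.stem = Conv2d(3, c, 3, rng)
        self.stem_relu = LeakyReLU()
        self.enc = [Conv2d(c * 2 ** i, c * 2 ** (i + 1), 3, rng)
                    for i in range(n_stages)]
        self.enc_relu = [LeakyReLU() for _ in range(n_stages)]
        cb = c * 2 ** n_stages
        self.bott = Conv2d(cb, cb, 3, rng)
        self.bott_relu = LeakyReLU()
        # decoder, deepest stage first: stage k merges encoder level
        # i = n_stages - 1 - k
        self.proj, self.merge, self.merge_relu = [], [], []
        for i in reversed(range(n_stages)):
            ci = c * 2 ** i
            self.proj.append(Conv2d(ci * 2, ci, 1, rng))
            cin = 2 * ci if architecture == "unet_like" else ci
            self.merge.append(Conv2d(cin, ci, 3, rng))
            self.merge_relu.append(LeakyReLU())
        self.head = Conv2d(c, n_classes, 1, rng)

    # -- plumbing -----------------------------------------------------------

    def conv_layers(self) -> list[Conv2d]:
        return ([self.adapter, self.stem] + self.enc + [self.bott]
                + self.proj + self.merge + [self.head])

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.conv_layers())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers():
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.conv_layers():
            layer.W[...] = next(it)
            layer.b[...] = next(it)

    def zero_grad(self) -> None:
        for layer in self.conv_layers():
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N, H, W, n_classes) from input (N, H, W, 1) in [0, 1]."""
        if x.ndim != 4 or x.shape[3] != 1:
            raise ValueError("input must be (N, H, W, 1)")
        if x.shape[1] % (2 ** self.n_stages) or x.shape[2] % (2 ** self.n_stages):
            raise ValueError(
                f"input sides must be divisible by {2 ** self.n_stages}")
        a = self.adapter.forward(x, train)
        e = [self.stem_relu.forward(self.stem.forward(a, train), train)]
        for conv, relu in zip(self.enc, self.enc_relu):
            e.append(relu.forward(conv.forward(avg_pool2(e[-1]), train), train))
        d = self.bott_relu.forward(self.bott.forward(e[-1], train), train)
        for k, i in enumerate(reversed(range(self.n_stages))):
            u = self.proj[k].forward(upsample2(d), train)
            if self.architecture == "unet_like":
                m = np.concatenate([u, e[i]], axis=-1)
            else:
                m = u + e[i]
            d = self.merge_relu[k].forward(self.merge[k].forward(m, train), train)
        return self.head.forward(d, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * (self.n_stages + 1)
        for k in reversed(range(self.n_stages)):
            i = self.n_stages - 1 - k
            dm = self.merge[k].backward(self.merge_relu[k].backward(d))
            if self.architecture == "unet_like":
                ci = self.proj[k].cout
                du, dskip = dm[..., :ci], dm[..., ci:]
                dskips[i] = dskip.copy() if dskips[i] is None else dskips[i] + dskip
            else:
                dskips[i] = dm.copy() if dskips[i] is None else dskips[i] + dm
                du = dm
            d = upsample2_backward(self.proj[k].backward(du))
        # bottleneck input is the deepest encoder activation
        d = self.bott.backward(self.bott_relu.backward(d))
        for i in reversed(range(self.n_stages)):
            d = avg_pool2_backward(
                self.enc[i].backward(self.enc_relu[i].backward(d)))
            if dskips[i] is not None:
                d = d + dskips[i]
        self.adapter.backward(self.stem.backward(self.stem_relu.backward(d)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax_channels(self.forward(x, train=False))


class Adam:
    """Adam with the customary defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, network: EncoderDecoder, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._slots = [(np.zeros_like(p), np.zeros_like(p))
                       for layer in network.conv_layers()
                       for p in (layer.W, layer.b)]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        params_grads = [(p, g) for layer in self.net.conv_layers()
                        for p, g in ((layer.W, layer.dW), (layer.b, layer.db))]
        for (p, g), (m, v) in zip(params_grads, self._slots):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
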