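"""1D full-scale-connected multi-residual encoder–decoder (MultiResUNet3+).

The network marries two ideas from biomedical image segmentation, transposed
to one-dimensional signals:

* **MultiRes blocks** — three chained kernel-3 convolution branches of
  increasing width, concatenated and fused with a kernel-1 residual shortcut.
  A block with total filter budget W splits its branches as
  round(W/6), round(W/3) and the remainder, so the widths always sum to W.

* **Full-scale skip connections** — each decoder level receives a
  resolution-matched feature map from *every* shallower/same-level encoder
  (via max-pooling) and from *every* deeper decoder (via nearest
  interpolation), rather than only its mirror-image encoder.

Instead of direct skips, every connection runs through a **Residual Path**:
a chain of residual-convolutional blocks whose length depends on the origin
level — more blocks for shallower (coarser-semantic-gap) origins.  For depth
d = 5 the encoder→decoder (inter) paths carry 4, 3, 2, 1 blocks from the
shallowest to the deepest origin, and the decoder→decoder (intra) paths carry
1, 2, 3, 4 blocks from the deepest to the shallowest origin.

Each ResPath outputs ``n_base`` channels, so the d concatenated incoming maps
at any decoder give exactly W = n_base × d channels, which a MultiRes block
of budget W fuses.  A final kernel-1 convolution maps decoder 1 to a single
linear output channel; output length equals input length.

Everything here runs on the NumPy autodiff core in :mod:`._autodiff`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Parameter, Tensor

__all__ = [
    "ArchitectureSpec",
    "filter_budget",
    "multires_widths",
    "respath_blocks",
    "ResConvBlock",
    "ResPath",
    "MultiResBlock",
    "MultiResUNet3Plus",
]


# ---------------------------------------------------------------------------
# architecture arithmetic
# ---------------------------------------------------------------------------

def filter_budget(n_base: int, d: int) -> int:
    """Total filter budget W = n × d of a decoder fusion block."""
    if n_base < 1 or d < 1:
        raise ValueError("n_base and d must be positive integers")
    return n_base * d


def multires_widths(W: int):
    """Split a MultiRes budget W into three branch widths.

    (round(W/6), round(W/3), remainder); half-up rounding; widths sum to W.
    E.g. W=320 → (53, 107, 160).
    """
    if W < 6:
        raise ValueError(f"budget W={W} too small: a branch would be empty")
    w1 = int(np.floor(W / 6 + 0.5))
    w2 = int(np.floor(W / 3 + 0.5))
    w3 = W - w1 - w2
    return w1, w2, w3


def respath_blocks(side: str, origin_level: int, d: int) -> int:
    """Number of residual-convolutional blocks on a ResPath.

    ``inter`` paths start at encoder level L (1..d−1) and carry d − L blocks;
    ``intra`` paths start at decoder level L (2..d, level d being the
    bottleneck) and carry d − L + 1 blocks.  Either way, shallower origins get
    more blocks.
    """
    if side == "inter":
        if not 1 <= origin_level <= d - 1:
            raise ValueError(f"inter origin level {origin_level} outside 1..{d - 1}")
        return d - origin_level
    if side == "intra":
        if not 2 <= origin_level <= d:
            raise ValueError(f"intra origin level {origin_level} outside 2..{d}")
        return d - origin_level + 1
    raise ValueError(f"side must be 'inter' or 'intra', got {side!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of one network instance.

    ``d`` is the number of scales, ``n_base`` the per-path channel count n
    (so every decoder fuses W = n×d channels), ``kernel`` the convolution
    length, ``pool`` the downsampling factor between scales.
    """

    d: int = 5
    n_base: int = 64
    kernel: int = 3
    pool: int = 2
    input_length: int = 512
    deep_supervision: bool = False

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("depth d must be at least 2")
        if self.n_base < 1:
            raise ValueError("n_base must be at least 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel length must be odd")
        if self.input_length % self.pool ** (self.d - 1):
            raise ValueError(
                f"input_length {self.input_length} not divisible by "
                f"pool^(d-1) = {self.pool ** (self.d - 1)}"
            )

    @property
    def W(self) -> int:
        return filter_budget(self.n_base, self.d)

    def encoder_budget(self, level: int) -> int:
        """Filter budget of encoder level i: n_base · 2^(i−1).

        Clamped to 6 so the three-branch split is never empty, which only
        matters for toy configurations with very small n_base.
        """
        return max(6, self.n_base * 2 ** (level - 1))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Module:
    """Tiny module base: parameter collection and train/eval mode."""

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, _Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, _Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                yield v
        for m in self.modules():
            for p in m.__dict__.values():
                if isinstance(p, Parameter):
                    yield p

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, _Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, _Module):
                        yield from item.named_parameters(f"{name}.{i}.")


class Conv1d(_Module):
    """Same-padded stride-1 convolution with uniform fan-in initialization."""

    def __init__(self, in_ch, out_ch, kernel, rng, dtype=np.float32):
        bound = np.sqrt(6.0 / (in_ch * kernel))
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))

    def __call__(self, x):
        return ad.conv1d(x, self.weight, self.bias)


class BatchNorm1d(_Module):
    def __init__(self, ch, dtype=np.float32):
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self.training = True

    def __call__(self, x):
        return ad.batchnorm1d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              training=self.training)


class ResConvBlock(_Module):
    """One residual-convolutional unit: conv-k ⊕ conv-1, add, BN, ReLU."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        self.conv = Conv1d(in_ch, out_ch, kernel, rng)
        self.shortcut = Conv1d(in_ch, out_ch, 1, rng)
        self.bn = BatchNorm1d(out_ch)

    def __call__(self, x):
        return ad.relu(self.bn(ad.add(self.conv(x), self.shortcut(x))))


class ResPath(_Module):
    """Resolution-matching op followed by a chain of ResConvBlocks.

    ``scale`` > 0 pools by that factor (inter path to a deeper decoder),
    ``scale`` < 0 nearest-upsamples by |scale| (intra path from a deeper
    decoder), 0 means same resolution.
    """

    def __init__(self, in_ch, out_ch, n_blocks, scale, kernel, rng):
        if n_blocks < 1:
            raise ValueError("a ResPath needs at least one block")
        self.scale = scale
        chans = [in_ch] + [out_ch] * n_blocks
        self.blocks = [ResConvBlock(chans[i], chans[i + 1], kernel, rng)
                       for i in range(n_blocks)]

    def __call__(self, x):
        if self.scale > 1:
            x = ad.maxpool1d(x, self.scale)
        elif self.scale < -1:
            x = ad.upsample_nearest(x, -self.scale)
        for b in self.blocks:
            x = b(x)
        return x


class MultiResBlock(_Module):
    """Three chained conv branches of widths summing to W, plus a conv-1
    residual of W channels, fused by addition, BN and ReLU."""

    def __init__(self, in_ch, W, kernel, rng):
        w1, w2, w3 = multires_widths(W)
        self.widths = (w1, w2, w3)
        self.W = W
        self.branch1 = Conv1d(in_ch, w1, kernel, rng)
        self.branch2 = Conv1d(w1, w2, kernel, rng)
        self.branch3 = Conv1d(w2, w3, kernel, rng)
        self.shortcut = Conv1d(in_ch, W, 1, rng)
        self.bn = BatchNorm1d(W)

    def __call__(self, x):
        b1 = ad.relu(self.branch1(x))
        b2 = ad.relu(self.branch2(b1))
        b3 = ad.relu(self.branch3(b2))
        stacked = ad.concat([b1, b2, b3], axis=1)
        return ad.relu(self.bn(ad.add(stacked, self.shortcut(x))))


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class MultiResUNet3Plus(_Module):
    """Depth-d encoder–decoder with full-scale Residual Paths.

    Encoder level i (1..d) is a MultiRes block of budget n·2^(i−1), with
    pooling between levels; level d doubles as the bottleneck / "decoder d".
    Decoder level M (d−1..1) concatenates d incoming ResPath outputs of
    n channels each and fuses them with a MultiRes block of budget W = n·d.
    A kernel-1 convolution produces the single-channel linear output.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, n, k, pool = spec.d, spec.n_base, spec.kernel, spec.pool

        self.encoders = [MultiResBlock(1 if i == 1 else spec.encoder_budget(i - 1),
                                       spec.encoder_budget(i), k, rng)
                         for i in range(1, d + 1)]

        # source channel counts by level: encoder outputs, and decoder/bottleneck
        enc_ch = {i: spec.encoder_budget(i) for i in range(1, d + 1)}
        dec_ch = {j: spec.W for j in range(1, d)}
        dec_ch[d] = enc_ch[d]  # the bottleneck stands in for "decoder d"

        # inter_paths[M][i]: encoder level i -> decoder M (i = 1..M)
        # intra_paths[M][j]: decoder level j -> decoder M (j = M+1..d)
        self.inter_paths = {}
        self.intra_paths = {}
        for M in range(d - 1, 0, -1):
            inter = {}
            for i in range(1, M + 1):
                inter[i] = ResPath(enc_ch[i], n,
                                   n_blocks=respath_blocks("inter", i, d),
                                   scale=pool ** (M - i) if i < M else 0,
                                   kernel=k, rng=rng)
            intra = {}
            for j in range(M + 1, d + 1):
                intra[j] = ResPath(dec_ch[j], n,
                                   n_blocks=respath_blocks("intra", j, d),
                                   scale=-(pool ** (j - M)),
                                   kernel=k, rng=rng)
            self.inter_paths[M] = inter
            self.intra_paths[M] = intra

        self.fusions = {M: MultiResBlock(spec.W, spec.W, k, rng)
                        for M in range(d - 1, 0, -1)}
        self.head = Conv1d(spec.W, 1, 1, rng)
        if spec.deep_supervision:
            # one side output per decoder level 2..d-1 plus the bottleneck,
            # each nearest-upsampled to full length during the forward pass
            self.side_heads = {M: Conv1d(dec_ch[M], 1, 1, rng)
                               for M in range(d, 1, -1)}
        else:
            self.side_heads = {}

    # -- module plumbing (dict-valued attributes need explicit traversal) --

    def modules(self):
        for enc in self.encoders:
            yield enc
            yield from enc.modules()
        for group in (self.inter_paths, self.intra_paths):
            for paths in group.values():
                for p in paths.values():
                    yield p
                    yield from p.modules()
        for f in self.fusions.values():
            yield f
            yield from f.modules()
        yield self.head
        for h in self.side_heads.values():
            yield h

    def train(self):
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.training = True

    def eval(self):
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.training = False

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward --

    def __call__(self, y, return_side_outputs=False):
        """Map a batch of normalized noisy segments to denoised estimates.

        ``y``: array of shape (N, L) or (N, 1, L) with L = spec.input_length.
        Returns a Tensor of the same shape convention (N, 1, L); with
        ``return_side_outputs`` also a dict of per-decoder side outputs
        upsampled to full length (deep supervision).
        """
        spec = self.spec
        y = np.asarray(y)
        if y.ndim == 2:
            y = y[:, None, :]
        if y.ndim != 3 or y.shape[1] != 1 or y.shape[2] != spec.input_length:
            raise ValueError(
                f"expected input of shape (N, {spec.input_length}) or "
                f"(N, 1, {spec.input_length}), got {y.shape}"
            )
        x = Tensor(y.astype(self.head.weight.data.dtype))

        d = spec.d
        enc_out = {}
        h = x
        for i in range(1, d + 1):
            if i > 1:
                h = ad.maxpool1d(h, spec.pool)
            h = self.encoders[i - 1](h)
            enc_out[i] = h

        dec_out = {d: enc_out[d]}
        for M in range(d - 1, 0, -1):
            incoming = [self.inter_paths[M][i](enc_out[i])
                        for i in range(1, M + 1)]
            incoming += [self.intra_paths[M][j](dec_out[j])
                         for j in range(M + 1, d + 1)]
            dec_out[M] = self.fusions[M](ad.concat(incoming, axis=1))

        out = self.head(dec_out[1])
        if not return_side_outputs:
            return out
        sides = {}
        for M, head in self.side_heads.items():
            s = head(dec_out[M])
            sides[M] = ad.upsample_nearest(s, spec.pool ** (M - 1))
        return out, sides

    def predict(self, y) -> np.ndarray:
        """Inference-mode forward pass returning a (N, L) float array."""
        self.eval()
        out = self(y)
        self.train()
        return np.asarray(out.data[:, 0, :], dtype=np.float64)

    # -- introspection / persistence --

    def describe(self) -> str:
        """Human-readable census of paths, widths and parameters."""
        spec = self.spec
        buf = io.StringIO()
        print(f"MultiResUNet3+ (1D)  d={spec.d}  n={spec.n_base}  "
              f"W={spec.W}  input_length={spec.input_length}", file=buf)
        for i in range(1, spec.d + 1):
            W = spec.encoder_budget(i)
            print(f"  encoder {i}: MultiRes budget {W} widths "
                  f"{multires_widths(W)}", file=buf)
        for M in sorted(self.fusions, reverse=True):
            n_in = len(self.inter_paths[M]) + len(self.intra_paths[M])
            inter = {i: len(p.blocks) for i, p in self.inter_paths[M].items()}
            intra = {j: len(p.blocks) for j, p in self.intra_paths[M].items()}
            print(f"  decoder {M}: {n_in} incoming paths "
                  f"(inter blocks {inter}, intra blocks {intra}), "
                  f"fusion budget {spec.W} widths {multires_widths(spec.W)}",
                  file=buf)
        print(f"  head: 1x1 conv {spec.W} -> 1 (linear)", file=buf)
        if self.side_heads:
            print(f"  deep supervision heads at decoders "
                  f"{sorted(self.side_heads)}", file=buf)
        print(f"  trainable parameters: {self.n_parameters():,}", file=buf)
        return buf.getvalue()

    def state_dict(self) -> dict:
        state = {name: p.data for name, p in self._named_all()}
        return state

    def _named_all(self):
        # stable enumeration over every parameter and BN running stat
        idx = 0
        for m in self.modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    yield f"m{idx}.{k}", v
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    yield f"m{idx}.{k}", v
            idx += 1

    def load_state_dict(self, state: dict):
        for name, arr in self._named_all():
            if name not in state:
                raise KeyError(f"checkpoint missing tensor {name}")
            src = state[name]
            if isinstance(arr, Parameter):
                arr.data = np.array(src, dtype=arr.data.dtype)
            else:
                arr[...] = src

    def save(self, path):
        np.savez(path, **{k: (v.data if isinstance(v, Parameter) else v)
                          for k, v in self._named_all()})

    @classmethod
    def load(cls, path, spec: ArchitectureSpec) -> "MultiResUNet3Plus":
        net = cls(spec)
        with np.load(path) as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return net
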