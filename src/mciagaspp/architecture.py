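"""The volumetric classifier: residual backbone, attention gates, ASPP.

The network is an 18-layer-style 3D residual backbone (stem + four
stages of two basic blocks) over single-channel gray-matter volumes.
The deepest stage output g serves as a gating signal: additive
attention gates compute one coefficient per coarse spatial location
from stage-2 and stage-3 features,

    q_i = psi^T relu(W_x^T x_i + W_g^T g_i + b_xg) + b_psi,
    alpha = sigma2(q),

with sigma2 a softmax over the spatial positions of each sample (so the
coefficients sum to 1) or an elementwise sigmoid.  Gated feature maps
optionally pass an atrous spatial pyramid (parallel dilated
convolutions at several rates, channel-concatenated and projected)
before being pooled onto g's grid, fused with g, and classified.

Three ablation variants are exposed: ``baseline`` (backbone only),
``ag`` (attention gates), and ``ag_aspp`` (attention gates + ASPP).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "AttentionGateParams",
    "effective_kernel_size",
    "dilated_conv",
    "attention_gate",
    "AttentionGate",
    "ASPP",
    "aspp",
    "MCIDetector",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]

MIN_GRID = 16
VARIANTS = ("baseline", "ag", "ag_aspp")


# --------------------------------------------------------------------------
# dilated convolution
# --------------------------------------------------------------------------

def effective_kernel_size(k: int, d: int) -> int:
    """Effective per-side extent of a k-tap kernel dilated at rate d:
    k + (k - 1)(d - 1)."""
    k, d = int(k), int(d)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {k}")
    if d < 1:
        raise ValueError(f"dilation rate must be >= 1, got {d}")
    return k + (k - 1) * (d - 1)


def dilated_conv(x, w, r: int = 1):
    """'Same'-padded dilated convolution of a (B, C, D, H, W) feature map.

    Kernel taps are spaced r voxels apart; rate 1 reproduces ordinary
    convolution exactly.  Accepts numpy arrays or Tensors and returns
    the matching kind.
    """
    was_array = not isinstance(x, Tensor)
    xt = ad.as_tensor(x)
    wt = ad.as_tensor(w)
    if xt.ndim != 5 or wt.ndim != 5:
        raise ValueError("dilated_conv expects rank-5 input and kernel")
    r = int(r)
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    pads = []
    for k in wt.shape[2:]:
        eff = effective_kernel_size(k, r) if k % 2 == 1 else k + (k - 1) * (r - 1)
        if eff % 2 == 0:
            raise ValueError("'same' dilated convolution requires odd kernel sides")
        pads.append((eff - 1) // 2)
    out = ad.conv3d(xt, wt, stride=1, padding=tuple(pads), dilation=r)
    return out.data if was_array else out


# --------------------------------------------------------------------------
# attention gate
# --------------------------------------------------------------------------

@dataclasses.dataclass
class AttentionGateParams:
    """Weights of one additive attention gate.

    W_x maps the F_l local-feature channels and W_g the F_g gating
    channels into F_int intermediate channels (1x1x1 convolutions);
    psi collapses the intermediate channels to one pre-activation
    coefficient per location, with biases b_xg and b_psi.
    """

    F_l: int
    F_g: int
    F_int: int
    W_x: Tensor  # (F_int, F_l)
    W_g: Tensor  # (F_int, F_g)
    psi: Tensor  # (F_int,)
    b_xg: Tensor  # (F_int,)
    b_psi: Tensor  # scalar, shape (1,)
    sigma2: str = "softmax"

    def __post_init__(self):
        if self.F_int < 1:
            raise ValueError("F_int must be >= 1")
        if self.sigma2 not in ("softmax", "sigmoid"):
            raise ValueError(f"sigma2 must be softmax or sigmoid, got {self.sigma2}")
        expect = {
            "W_x": (self.F_int, self.F_l),
            "W_g": (self.F_int, self.F_g),
            "psi": (self.F_int,),
            "b_xg": (self.F_int,),
        }
        for name, shape in expect.items():
            t = getattr(self, name)
            if tuple(t.shape) != shape:
                raise ValueError(f"{name} has shape {tuple(t.shape)}, expected {shape}")

    @classmethod
    def init(
        cls,
        F_l: int,
        F_g: int,
        F_int: int,
        rng: np.random.Generator,
        init_sd: float = 0.1,
        sigma2: str = "softmax",
    ) -> "AttentionGateParams":
        return cls(
            F_l=F_l,
            F_g=F_g,
            F_int=F_int,
            W_x=nn.Parameter(nn.truncated_normal(rng, (F_int, F_l), init_sd)),
            W_g=nn.Parameter(nn.truncated_normal(rng, (F_int, F_g), init_sd)),
            psi=nn.Parameter(nn.truncated_normal(rng, (F_int,), init_sd)),
            b_xg=nn.Parameter(np.zeros(F_int)),
            b_psi=nn.Parameter(np.zeros(1)),
            sigma2=sigma2,
        )


def _projection_strides(x_spatial, g_spatial):
    strides = []
    for nx, ng in zip(x_spatial, g_spatial):
        if ng > nx:
            raise ValueError(
                f"gating grid {tuple(g_spatial)} exceeds local grid {tuple(x_spatial)}"
            )
        s = max(1, math.ceil(nx / ng))
        if (nx - 1) // s + 1 != ng:
            raise ValueError(
                f"cannot map local extent {nx} onto gating extent {ng} with a strided "
                "1x1x1 projection"
            )
        strides.append(s)
    return tuple(strides)


def attention_gate(x_l, g, params: AttentionGateParams):
    """Gate local features x_l with coefficients computed against g.

    x_l is brought onto g's (coarser) grid by applying W_x as a strided
    1x1x1 projection; the additive attention pre-activation is passed
    through sigma2 — softmax over each sample's flattened spatial
    positions (coefficients sum to 1) or sigmoid — then resampled back
    to x_l's grid trilinearly and applied multiplicatively across all
    channels.

    Returns ``(gated, alpha)`` where alpha is the coefficient map on
    g's grid (before resampling), shaped (B, 1, dg, hg, wg).
    """
    x_l = ad.as_tensor(x_l)
    g = ad.as_tensor(g)
    if x_l.shape[1] != params.F_l:
        raise ValueError(f"x_l has {x_l.shape[1]} channels, params expect {params.F_l}")
    if g.shape[1] != params.F_g:
        raise ValueError(f"g has {g.shape[1]} channels, params expect {params.F_g}")
    if x_l.shape[0] != g.shape[0]:
        raise ValueError("x_l and g must share the batch dimension")

    strides = _projection_strides(x_l.shape[2:], g.shape[2:])
    wx = params.W_x.reshape(params.F_int, params.F_l, 1, 1, 1)
    wg = params.W_g.reshape(params.F_int, params.F_g, 1, 1, 1)
    x_proj = ad.conv3d(x_l, wx, params.b_xg, stride=strides)
    g_proj = ad.conv3d(g, wg)
    h = ad.relu(x_proj + g_proj)
    psi_w = params.psi.reshape(1, params.F_int, 1, 1, 1)
    q = ad.conv3d(h, psi_w, params.b_psi)  # (B, 1, dg, hg, wg)

    B = q.shape[0]
    coarse = q.shape[2:]
    if params.sigma2 == "softmax":
        alpha = ad.softmax(q.reshape(B, -1), axis=1).reshape((B, 1) + tuple(coarse))
    else:
        alpha = ad.sigmoid(q)
    alpha_up = ad.upsample_trilinear(alpha, x_l.shape[2:])
    gated = x_l * alpha_up
    return gated, alpha


class AttentionGate(nn.Module):
    """Module wrapper owning one gate's parameters."""

    def __init__(
        self,
        F_l: int,
        F_g: int,
        F_int: int | None = None,
        rng: np.random.Generator | None = None,
        init_sd: float = 0.1,
        sigma2: str = "softmax",
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        F_int = F_int if F_int is not None else max(F_l // 2, 1)
        p = AttentionGateParams.init(F_l, F_g, F_int, rng, init_sd, sigma2)
        self.W_x, self.W_g, self.psi = p.W_x, p.W_g, p.psi
        self.b_xg, self.b_psi = p.b_xg, p.b_psi
        self._dims = (F_l, F_g, F_int)
        self.sigma2 = sigma2

    @property
    def params(self) -> AttentionGateParams:
        F_l, F_g, F_int = self._dims
        return AttentionGateParams(
            F_l=F_l, F_g=F_g, F_int=F_int,
            W_x=self.W_x, W_g=self.W_g, psi=self.psi,
            b_xg=self.b_xg, b_psi=self.b_psi, sigma2=self.sigma2,
        )

    def forward(self, x_l, g):
        return attention_gate(x_l, g, self.params)


# --------------------------------------------------------------------------
# atrous spatial pyramid pooling
# --------------------------------------------------------------------------

class ASPP(nn.Module):
    """Parallel dilated convolutions at several rates.

    One 3-tap-per-axis branch per rate plus a 1x1x1 branch, all 'same'
    padded so the spatial grid is preserved; branch outputs are stacked
    along channels and projected to out_channels by a 1x1x1 convolution.
    """

    def __init__(
        self,
        in_channels: int,
        rates: list[int],
        out_channels: int,
        branch_channels: int | None = None,
        rng: np.random.Generator | None = None,
        init_sd: float = 0.1,
    ):
        super().__init__()
        rates = [int(r) for r in rates]
        if not rates or any(r < 1 for r in rates):
            raise ValueError(f"rates must be a nonempty list of integers >= 1, got {rates}")
        rng = rng if rng is not None else np.random.default_rng(0)
        bc = branch_channels if branch_channels is not None else out_channels
        self.rates = rates
        self.branches = nn.ModuleList(
            nn.Conv3d(in_channels, bc, 3, padding="same", dilation=r, rng=rng, init_sd=init_sd)
            for r in rates
        )
        self.point_branch = nn.Conv3d(in_channels, bc, 1, rng=rng, init_sd=init_sd)
        self.project = nn.Conv3d((len(rates) + 1) * bc, out_channels, 1, rng=rng, init_sd=init_sd)

    def forward(self, x):
        outs = [branch(x) for branch in self.branches]
        outs.append(self.point_branch(x))
        stacked = ad.concat(outs, axis=1)
        return self.project(stacked)


def aspp(x, rates, out_channels, module: ASPP | None = None, rng=None):
    """Functional ASPP; builds a freshly initialized module unless given one."""
    xt = ad.as_tensor(x)
    if module is None:
        module = ASPP(xt.shape[1], list(rates), out_channels, rng=rng)
    out = module(xt)
    return out.data if not isinstance(x, Tensor) else out


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ModelConfig:
    variant: str = "ag_aspp"
    input_grid: tuple[int, int, int] = (84, 102, 84)
    base_channels: int = 64
    aspp_rates: tuple[int, ...] = (1, 2, 3)
    n_classes: int = 2
    sigma2: str = "softmax"
    init_sd: float = 0.1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.input_grid = tuple(int(n) for n in self.input_grid)
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)
        if self.variant == "ag_aspp" and not self.aspp_rates:
            raise ValueError("variant ag_aspp requires nonempty aspp_rates")
        if self.init_sd <= 0:
            raise ValueError("init_sd must be > 0")
        if any(n < MIN_GRID for n in self.input_grid):
            raise ValueError(
                f"input grid {self.input_grid} too small for four downsamplings; "
                f"every axis must be >= {MIN_GRID}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_grid"] = list(self.input_grid)
        d["aspp_rates"] = list(self.aspp_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class BasicBlock(nn.Module):
    """Two 3x3x3 convolutions with an identity (or projected) shortcut."""

    def __init__(self, cin, cout, stride, rng, init_sd):
        super().__init__()
        self.conv1 = nn.Conv3d(cin, cout, 3, stride=stride, padding=1, rng=rng, init_sd=init_sd)
        self.bn1 = nn.GroupNorm3d(cout)
        self.conv2 = nn.Conv3d(cout, cout, 3, padding=1, rng=rng, init_sd=init_sd)
        self.bn2 = nn.GroupNorm3d(cout)
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                nn.Conv3d(cin, cout, 1, stride=stride, bias=False, rng=rng, init_sd=init_sd),
                nn.GroupNorm3d(cout),
            )

    def forward(self, x):
        identity = x if self.downsample is None else self.downsample(x)
        out = ad.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return ad.relu(out + identity)


class MCIDetector(nn.Module):
    """Residual backbone with optional attention gates and ASPP.

    forward: (B, 1, D, H, W) -> class logits (B, n_classes).
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        c = config.base_channels
        sd = config.init_sd
        widths = [c, 2 * c, 4 * c, 8 * c]

        self.stem_conv = nn.Conv3d(1, c, 3, padding=1, rng=rng, init_sd=sd)
        self.stem_bn = nn.GroupNorm3d(c)
        self.pool = nn.MaxPool3d(2)

        def stage(cin, cout, stride):
            return nn.Sequential(
                BasicBlock(cin, cout, stride, rng, sd),
                BasicBlock(cout, cout, 1, rng, sd),
            )

        self.stage1 = stage(c, widths[0], 1)
        self.stage2 = stage(widths[0], widths[1], 2)
        self.stage3 = stage(widths[1], widths[2], 2)
        self.stage4 = stage(widths[2], widths[3], 2)

        if config.variant == "baseline":
            self.fc = nn.Linear(widths[3], config.n_classes, rng=rng, init_sd=sd)
        else:
            self.ag2 = AttentionGate(widths[1], widths[3], rng=rng, init_sd=sd, sigma2=config.sigma2)
            self.ag3 = AttentionGate(widths[2], widths[3], rng=rng, init_sd=sd, sigma2=config.sigma2)
            if config.variant == "ag_aspp":
                self.aspp2 = ASPP(widths[1], list(config.aspp_rates), widths[1], rng=rng, init_sd=sd)
                self.aspp3 = ASPP(widths[2], list(config.aspp_rates), widths[2], rng=rng, init_sd=sd)
            fused = widths[1] + widths[2] + widths[3]
            self.fuse = nn.Conv3d(fused, widths[3], 1, rng=rng, init_sd=sd)
            self.fc = nn.Linear(widths[3], config.n_classes, rng=rng, init_sd=sd)

    # -- forward -------------------------------------------------------------
    def _check_input(self, x: Tensor):
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected input (B, 1, D, H, W), got {tuple(x.shape)}")
        if any(n < MIN_GRID for n in x.shape[2:]):
            raise ValueError(
                f"input grid {tuple(x.shape[2:])} too small; every axis must be >= {MIN_GRID}"
            )

    def features(self, x) -> dict[str, Tensor]:
        """All intermediate stage outputs plus logits (and attention maps)."""
        x = ad.as_tensor(x)
        self._check_input(x)
        feats: dict[str, Tensor] = {}
        h = self.pool(ad.relu(self.stem_bn(self.stem_conv(x))))
        feats["stem"] = h
        h = self.stage1(h)
        feats["stage1"] = h
        s2 = self.stage2(h)
        feats["stage2"] = s2
        s3 = self.stage3(s2)
        feats["stage3"] = s3
        g = self.stage4(s3)
        feats["stage4"] = g

        if self.config.variant == "baseline":
            pooled = g.mean(axis=(2, 3, 4))
            feats["logits"] = self.fc(pooled)
            return feats

        gated2, alpha2 = self.ag2(s2, g)
        gated3, alpha3 = self.ag3(s3, g)
        feats["alpha2"], feats["alpha3"] = alpha2, alpha3
        if self.config.variant == "ag_aspp":
            gated2 = self.aspp2(gated2)
            gated3 = self.aspp3(gated3)
        g_grid = g.shape[2:]
        p2 = ad.adaptive_avg_pool3d(gated2, g_grid)
        p3 = ad.adaptive_avg_pool3d(gated3, g_grid)
        fused = ad.relu(self.fuse(ad.concat([p2, p3, g], axis=1)))
        pooled = fused.mean(axis=(2, 3, 4))
        feats["logits"] = self.fc(pooled)
        return feats

    def forward(self, x) -> Tensor:
        return self.features(x)["logits"]

    @property
    def feature_layers(self) -> list[str]:
        return ["stem", "stage1", "stage2", "stage3", "stage4"]


def build_model(config: ModelConfig, seed: int = 0) -> MCIDetector:
    """Instantiate a variant with truncated-normal(init_sd) weights."""
    return MCIDetector(config, seed=seed)


# --------------------------------------------------------------------------
# checkpoints: weight archive + the config used to build the model
# --------------------------------------------------------------------------

def save_checkpoint(model: MCIDetector, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "weights.npz", **model.state_dict())
    with open(out_dir / "model.yaml", "w") as fh:
        yaml.safe_dump(model.config.to_dict(), fh)
    return out_dir


def load_checkpoint(ckpt_dir) -> MCIDetector:
    ckpt_dir = Path(ckpt_dir)
    with open(ckpt_dir / "model.yaml") as fh:
        config = ModelConfig.from_dict(yaml.safe_load(fh))
    model = build_model(config)
    with np.load(ckpt_dir / "weights.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.eval()
    return model
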