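"""Model assembly: baseline detector, module toggles, budget accounting.

Four independent toggles select the architecture variant:

* A - MEN blocks replace the four CSP backbone stages
* B - BAFE replaces the terminal partial spatial-attention block
* C - EM-BFPN replaces the PAN-style neck
* D - SCAU blocks replace interpolation upsamplers

All 16 combinations are legal.  ``count_params`` reports trainable
parameters in millions; ``count_flops`` reports giga-operations for a
batch-1 forward at the configured input size under the 2x
multiply-accumulate convention.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional, Tuple

import autograd.numpy as anp
import numpy as np
import yaml

from . import nn
from .bafe import BAFEBlock, BAFEConfig
from .baseline import C2PSA, C3k2, DetectHead, SPPF
from .embfpn import EMBFPNNeck, PyramidLevels
from .men import MENBlock, MENConfig, ScaleSet
from .nn import functional as F
from .scau import SCAUBlock, SCAUConfig


def make_divisible(v: float, divisor: int = 8) -> int:
    return max(divisor, int(round(v / divisor) * divisor))


@dataclass
class ModelConfig:
    """Architecture variant description.

    ``men_scales`` lists the MSF pooling grids used in each of the four
    backbone stages (outermost first); grids must not exceed the spatial
    extent of the stage at the configured input size.
    """

    use_men: bool = False        # toggle A
    use_bafe: bool = False       # toggle B
    use_embfpn: bool = False     # toggle C
    use_scau: bool = False       # toggle D
    num_classes: int = 11
    input_size: Tuple[int, int] = (640, 640)
    width_mult: float = 0.25
    reg_max: int = 16
    men_n_units: int = 1
    men_scales: Tuple[Tuple[int, ...], ...] = ((3, 6, 9, 12),) * 4
    bafe_mid: int = 0            # 0 -> 2.25x the P5 width
    bafe_heads: int = 4
    bafe_window: int = 3
    neck_width: int = 0          # 0 -> width of P3
    mscm_expansion: float = 1.0
    mscm_n_blocks: int = 2
    scau_s: int = 1
    scau_g: int = 4
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 32 or w % 32:
            raise ValueError(f"input size must be divisible by 32, got {self.input_size}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def toggles(self) -> Dict[str, bool]:
        return {"A": self.use_men, "B": self.use_bafe,
                "C": self.use_embfpn, "D": self.use_scau}

    def variant_name(self) -> str:
        on = [k for k, v in self.toggles.items() if v]
        return "+".join(on) if on else "baseline"

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "input_size" in raw and isinstance(raw["input_size"], list):
            raw["input_size"] = tuple(raw["input_size"])
        if "men_scales" in raw:
            raw["men_scales"] = tuple(tuple(s) for s in raw["men_scales"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["men_scales"] = [list(s) for s in self.men_scales]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass(frozen=True)
class BudgetReport:
    params_millions: float
    flops_giga: float
    frozen_params: int = 0

    def as_dict(self) -> Dict[str, float]:
        return {"params_millions": self.params_millions,
                "flops_giga": self.flops_giga,
                "frozen_params": self.frozen_params}


class DetectionModel(nn.Module):
    """Backbone -> neck -> three decoupled heads at strides 8/16/32."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        nn.seed_init(cfg.seed)
        self.cfg = cfg
        w = cfg.width_mult
        ch = {b: make_divisible(min(b, 1024) * w) for b in (64, 128, 256, 512, 1024)}
        c1, c2, c3, c4, c5 = ch[64], ch[128], ch[256], ch[512], ch[1024]
        self.stem0 = nn.ConvBNAct(3, c1, 3, stride=2)
        self.stem1 = nn.ConvBNAct(c1, c2, 3, stride=2)

        def stage(idx, cin, cout, c3k, e):
            if cfg.use_men:
                mc = MENConfig(cin, cout, cfg.men_n_units,
                               ScaleSet(cfg.men_scales[idx]), hidden_channels=cout)
                return MENBlock(mc)
            return C3k2(cin, cout, 1, c3k, e)

        self.stage2 = stage(0, c2, c3, False, 0.25)
        self.down3 = nn.ConvBNAct(c3, c3, 3, stride=2)
        self.stage4 = stage(1, c3, c4, False, 0.25)
        self.down5 = nn.ConvBNAct(c4, c4, 3, stride=2)
        self.stage6 = stage(2, c4, c4, True, 0.5)
        self.down7 = nn.ConvBNAct(c4, c5, 3, stride=2)
        self.stage8 = stage(3, c5, c5, True, 0.5)
        self.sppf = SPPF(c5, c5)
        if cfg.use_bafe:
            bafe_mid = cfg.bafe_mid or make_divisible(2.25 * c5)
            self.psa = BAFEBlock(BAFEConfig(c5, c5, bafe_mid,
                                            cfg.bafe_heads, cfg.bafe_window))
        else:
            self.psa = C2PSA(c5, c5, 1)

        self.p_channels = (c4, c4, c5)
        if cfg.use_embfpn:
            neck_w = cfg.neck_width or make_divisible(1.375 * c3)
            self.neck = EMBFPNNeck(self.p_channels, neck_w,
                                   cfg.mscm_expansion, cfg.mscm_n_blocks,
                                   use_scau=cfg.use_scau)
            head_ch = self.neck.out_channels
        else:
            if cfg.use_scau:
                self.up5 = SCAUBlock(SCAUConfig(c5, c5, cfg.scau_s, cfg.scau_g))
                self.up4 = SCAUBlock(SCAUConfig(c4, c4, cfg.scau_s, cfg.scau_g))
            self.td4 = C3k2(c5 + c4, c4, 1, False)
            self.td3 = C3k2(c4 + c4, c3, 1, False)
            self.bu_down3 = nn.ConvBNAct(c3, c3, 3, stride=2)
            self.bu4 = C3k2(c3 + c4, c4, 1, False)
            self.bu_down4 = nn.ConvBNAct(c4, c4, 3, stride=2)
            self.bu5 = C3k2(c4 + c5, c5, 1, True)
            head_ch = (c3, c4, c5)
        self.head = DetectHead(cfg.num_classes, head_ch, cfg.reg_max)
        self.strides = (8, 16, 32)

    # -- forward ----------------------------------------------------------
    def backbone(self, x, p):
        x = self.stem1(self.stem0(x, p["stem0"]), p["stem1"])
        x = self.stage2(x, p["stage2"])
        x = self.stage4(self.down3(x, p["down3"]), p["stage4"])
        p3 = x
        x = self.stage6(self.down5(x, p["down5"]), p["stage6"])
        p4 = x
        x = self.stage8(self.down7(x, p["down7"]), p["stage8"])
        x = self.psa(self.sppf(x, p["sppf"]), p["psa"])
        return PyramidLevels(p3, p4, x)

    def _upsample(self, x, name, p):
        if self.cfg.use_scau:
            return getattr(self, name)(x, p[name])
        B, C, H, W = x.shape
        return F.interpolate(x, (2 * H, 2 * W), mode="nearest")

    def neck_forward(self, levels: PyramidLevels, p):
        if self.cfg.use_embfpn:
            return self.neck(levels, p["neck"])
        p3, p4, p5 = levels
        t4 = self.td4(anp.concatenate([self._upsample(p5, "up5", p), p4], axis=1), p["td4"])
        n3 = self.td3(anp.concatenate([self._upsample(t4, "up4", p), p3], axis=1), p["td3"])
        n4 = self.bu4(anp.concatenate([self.bu_down3(n3, p["bu_down3"]), t4], axis=1), p["bu4"])
        n5 = self.bu5(anp.concatenate([self.bu_down4(n4, p["bu_down4"]), p5], axis=1), p["bu5"])
        return PyramidLevels(n3, n4, n5)

    def forward(self, x, p):
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial dims must be divisible by 32, got {(h, w)}")
        levels = self.backbone(x, p)
        levels = self.neck_forward(levels, p)
        return self.head(list(levels), p["head"])


def build_model(cfg: ModelConfig) -> DetectionModel:
    return DetectionModel(cfg)


def count_params(model: DetectionModel) -> float:
    """Millions of trainable parameters (frozen filters excluded)."""
    return model.num_params() / 1e6


def count_flops(model: DetectionModel, input_size: Optional[Tuple[int, int]] = None) -> float:
    """Giga-operations of a batch-1 forward pass (2 ops per MAC)."""
    hw = input_size or model.cfg.input_size
    x = np.zeros((1, 3, hw[0], hw[1]))
    model.set_training(False)
    with nn.FlopCounter() as fc:
        model(x)
    return fc.total / 1e9


def budget_report(model: DetectionModel, input_size=None) -> BudgetReport:
    return BudgetReport(count_params(model), count_flops(model, input_size),
                        model.frozen_param_count())
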