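"""Data-driven hyperparameter rules.

All penalty weights are set so the objective terms contribute on comparable
scales: the spot term ranges over [0, |I|], the population and gene terms are
bounded by |C'| and |G|, the spatial term by n|P| (base-2 JS on raw columns),
and the abundance term by N = n|I|. The published proportionality constants
differ slightly between single-cell-resolution ("high") and multicell
("low") spatial data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .objective import ObjectiveWeights

__all__ = ["Resolution", "ModelConfig", "infer_capacity", "infer_weights", "infer_theta"]

PLATFORM_CAPACITY = {"visium": 20.0, "st": 200.0}
THETA_BY_MODE = {"high": 0.6, "low": 0.4}


@dataclass
class Resolution:
    """Spatial resolution regime and how to obtain the spot capacity n.

    ``mode`` "high" means single-cell spots (n = 1). For "low", capacity comes
    from the platform (Visium: 20; ST: 200), an explicit override, or a
    user-supplied total cell count N via n = N/|I|.
    """

    mode: str = "low"
    platform: str | None = None
    capacity_override: float | None = None
    total_cells_N: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("high", "low"):
            raise ValueError("resolution mode must be 'high' or 'low'")
        if self.platform is not None and self.platform not in PLATFORM_CAPACITY:
            if self.platform != "other":
                raise ValueError(f"unknown platform {self.platform!r}")


def infer_capacity(res: Resolution, num_spots: int) -> float:
    """Upper bound n on cells per spot."""
    if res.mode == "high":
        return 1.0
    if res.capacity_override is not None:
        if res.capacity_override < 1:
            raise ValueError("capacity override must be >= 1")
        return float(res.capacity_override)
    if res.platform in PLATFORM_CAPACITY:
        return PLATFORM_CAPACITY[res.platform]
    if res.total_cells_N is not None:
        return float(res.total_cells_N) / num_spots
    raise ValueError(
        "cannot infer spot capacity for low-resolution data: provide a "
        "platform (visium/st), a capacity override, or a total cell count N "
        "(no internal estimator of N is provided)"
    )


def infer_weights(
    num_spots: int,
    num_rows: int,
    num_genes: int,
    num_pairs: int,
    n: float,
    mode: str,
    has_prior: bool = False,
) -> ObjectiveWeights:
    """Penalty weights balancing the objective terms; theta set by mode.

    high: lambda_C = 0.5|I|/|C'|, lambda_G = 1.25|I|/|G|, lambda_S = 0.5|I|/|P|
    low:  lambda_C = 0.6|I|/|C'|, lambda_G = 1.5|I|/|G|,  lambda_S = 0.4|I|/(n|P|)
    lambda_A = 1/n when a prior is supplied (scaled to N = n|I|), else 0.
    """
    if min(num_spots, num_rows, num_genes) < 1:
        raise ValueError("spot, population, and gene counts must be >= 1")
    I, C, G, P = float(num_spots), float(num_rows), float(num_genes), float(num_pairs)
    if mode == "high":
        lam_c, lam_g = 0.5 * I / C, 1.25 * I / G
        lam_s = 0.5 * I / P if P > 0 else 0.0
    elif mode == "low":
        lam_c, lam_g = 0.6 * I / C, 1.5 * I / G
        lam_s = 0.4 * I / (n * P) if P > 0 else 0.0
    else:
        raise ValueError("mode must be 'high' or 'low'")
    lam_a = 1.0 / n if has_prior else 0.0
    return ObjectiveWeights(
        lambda_C=lam_c,
        lambda_G=lam_g,
        lambda_S=lam_s,
        lambda_A=lam_a,
        theta=infer_theta(mode),
        nbar=n,
    )


def infer_theta(mode: str) -> float:
    """Sparsity level: 0.6 for single-cell spots, 0.4 for multicell spots."""
    try:
        return THETA_BY_MODE[mode]
    except KeyError:
        raise ValueError("mode must be 'high' or 'low'") from None


@dataclass
class ModelConfig:
    """User-facing run configuration; None means "infer from the data".

    Explicit values always win over inference. ``effective()`` output of a run
    records what was actually used.
    """

    resolution: Resolution = field(default_factory=Resolution)
    kappa: int = 1
    min_fraction: float = 0.01
    lambda_C: float | None = None
    lambda_G: float | None = None
    lambda_S: float | None = None
    lambda_A: float | None = None
    theta: float | None = None
    d_bar: float | None = None
    w_bar: float | None = None
    similarity_floor: float = 0.6
    ref_log_transform: bool = False
    normalize_totals: bool = False
    seed: int = 0
    max_iters: int = 200
    tol: float = 1e-5
    step_rule: str = "backtracking"

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "ModelConfig":
        """Load a flat key=value config file; keyword overrides win."""
        kv: dict[str, Any] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            kv[key.strip()] = _coerce(raw.strip())
        kv.update({k: v for k, v in overrides.items() if v is not None})
        res_kwargs = {
            k: kv.pop(k)
            for k in ("mode", "platform", "capacity_override", "total_cells_N")
            if k in kv
        }
        cfg = cls(**kv)
        if res_kwargs:
            cfg.resolution = Resolution(**res_kwargs)
        return cfg


def _coerce(raw: str) -> Any:
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw
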