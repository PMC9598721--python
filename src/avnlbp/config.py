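"""Run configuration: YAML-backed, validated, with one master seed.

Defaults mirror the standard operating point of the method: descriptor
p=8, R=3 (theta=45 deg); FAM rho=1.0, beta=0.8, alpha=0.001; DE F=1.0,
CR=0.7.  The FAM key ``delta`` (0.2) is carried for completeness but bound
to nothing — it has no defined role in the training dynamics.

A single master seed derives per-stage seeds (data generation, FAM
presentation orders, DE), so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_seed"]


@dataclass
class RunConfig:
    # descriptor
    p: int = 8
    radius: int = 3
    variant: str = "avn"
    lbp_threshold: float = 1.0
    # FAM
    rho: float = 1.0
    alpha: float = 0.001
    beta: float = 0.8
    epsilon: float = 0.001
    epochs: int = 5
    delta: float = 0.2  # unbound; kept for config completeness
    # DE
    F1: float = 1.0
    F2: float = 1.0
    CR: float = 0.7
    generations: int = 30
    neigh_frac: float = 0.5
    catmin: int | None = None
    catmax: int = 30
    n_networks: int = 10
    # retrieval
    distance: str = "l1"
    arp_depth: int = 10
    arr_min_depth: int = 10
    # synthetic data
    n_classes: int = 3
    images_per_class: int = 10
    image_size: int = 64
    family: str = "gratings"
    snr_db: float | None = None
    split_fractions: tuple = (0.4, 0.3, 0.3)
    # bookkeeping
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.p < 2:
            raise ValueError(f"p must be >= 2, got {self.p}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.variant not in ("avn", "classic"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError(f"CR must lie in [0, 1], got {self.CR}")
        if self.catmin is not None and self.catmin > self.catmax:
            raise ValueError(
                f"need catmin <= catmax, got {self.catmin} > {self.catmax}")
        if self.distance not in ("l1", "chi2"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        return self

    @property
    def theta(self) -> float:
        """Sector angular width in degrees (360 / p)."""
        return 360.0 / self.p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["theta"] = self.theta
        return d


def load_config(source) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file, a dict, or
    None (defaults).  Misspelled keys are rejected, never silently
    defaulted."""
    if source is None:
        data = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "split_fractions" in data:
        data["split_fractions"] = tuple(data["split_fractions"])
    return RunConfig(**data).validate()


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the master seed; stable
    across runs and platforms."""
    ss = np.random.SeedSequence([master_seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def hash_stage(stage: str) -> int:
    """Deterministic (non-salted) string hash for stage names."""
    h = 2166136261
    for ch in stage.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 32)
    return h
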