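"""Seeded generators emulating the study's PTR-MS and LC-MS/MS inputs.

All generators are pure functions of (config, seed): labeling time courses
are the closed-form chain curve plus additive Gaussian noise truncated to
[0, 1]; assay progress curves integrate single-substrate Michaelis-Menten
depletion with proportional (constant-CV) noise and a fixed DMADP:IDP
split; pool tables invert the plastidial-fraction arithmetic so noiseless
round trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enzyme_kinetics import ProgressCurve
from .label_model import FluxParams, LabelTimeCourse, PoolSizes, fractional_labeling
from .pool_estimation import METABOLITE_ORDER, MetabolitePoolRecord

__all__ = [
    "LabelingSimConfig",
    "AssaySimConfig",
    "simulate_labeling",
    "simulate_assay",
    "simulate_pool_table",
    "write_fixture_set",
]


@dataclass(frozen=True)
class LabelingSimConfig:
    """Forward-model configuration for a synthetic labeling time course."""

    pools: PoolSizes
    flux_j: float
    plateau_m: float
    times: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        FluxParams(flux_j=self.flux_j, plateau_m=self.plateau_m)  # validate


@dataclass(frozen=True)
class AssaySimConfig:
    """Forward-model configuration for a synthetic HDR assay."""

    km: float
    vmax: float
    substrate_levels: Sequence[float]
    times: np.ndarray
    noise_cv: float = 0.0
    dmadp_idp_ratio: float = 6.0  # r in the 1:r DMADP:IDP split
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "substrate_levels", tuple(float(s) for s in self.substrate_levels))
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("km and vmax must be positive")
        if any(s <= 0 for s in self.substrate_levels):
            raise ValueError("substrate levels must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.dmadp_idp_ratio < 0:
            raise ValueError("dmadp_idp_ratio must be >= 0")


def simulate_labeling(cfg: LabelingSimConfig) -> LabelTimeCourse:
    """Closed-form labeling curve plus truncated additive Gaussian noise."""
    params = FluxParams(flux_j=cfg.flux_j, plateau_m=cfg.plateau_m)
    clean = np.atleast_1d(fractional_labeling(cfg.times, cfg.pools, params))
    rng = np.random.default_rng(cfg.seed)
    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape) if cfg.noise_sd > 0 else clean
    return LabelTimeCourse(times=cfg.times, fractions=np.clip(noisy, 0.0, 1.0))


def _integrate_depletion(s0: float, km: float, vmax: float, times: np.ndarray) -> np.ndarray:
    """Product P(t) = S0 - S(t) under dS/dt = -Vmax*S/(Km+S), fixed small steps."""
    intervals = np.diff(times[times > 0], prepend=0.0)
    dt = float(intervals[intervals > 0].min()) / 100.0
    product = np.empty_like(times)
    s = s0
    t_now = 0.0
    for k, t_target in enumerate(times):
        while t_now < t_target - 1e-15:
            step = min(dt, t_target - t_now)
            s = max(s - step * vmax * s / (km + s), 0.0)
            t_now += step
        product[k] = s0 - s
    return product


def simulate_assay(
    cfg: AssaySimConfig,
) -> tuple[list[ProgressCurve], pd.DataFrame]:
    """Simulate progress curves at each substrate level with a fixed product split.

    Returns the progress curves (noisy combined product) and a tidy table
    with per-point DMADP/IDP amounts whose sum equals the product exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    r = cfg.dmadp_idp_ratio
    curves: list[ProgressCurve] = []
    rows = []
    for s0 in cfg.substrate_levels:
        clean = _integrate_depletion(s0, cfg.km, cfg.vmax, cfg.times)
        if cfg.noise_cv > 0:
            noisy = clean * (1.0 + rng.normal(0.0, cfg.noise_cv, size=clean.shape))
            noisy = np.clip(noisy, 0.0, None)
        else:
            noisy = clean
        dmadp = noisy / (1.0 + r)
        idp = noisy - dmadp
        noisy = dmadp + idp  # redefine product as the sum so the split is exact
        curves.append(ProgressCurve(times=cfg.times, product=noisy, substrate_conc=s0))
        for t, p, d, i in zip(cfg.times, noisy, dmadp, idp):
            rows.append(
                {
                    "substrate_uM": s0,
                    "time_min": t,
                    "product_uM": p,
                    "dmadp_uM": d,
                    "idp_uM": i,
                }
            )
    return curves, pd.DataFrame(rows)


def simulate_pool_table(
    true_pools: PoolSizes,
    isoprene_plateau: float,
    plastidial_fracs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[MetabolitePoolRecord]:
    """Invert pool estimation: build a measurement table from known truth.

    Each metabolite's total pool is the true plastidial pool divided by its
    plastidial fraction; its final labeling fraction is the plastidial
    fraction times the isoprene plateau (plus optional truncated noise).
    Noiseless tables round-trip exactly through build_pool_sizes.
    """
    if not 0 < isoprene_plateau <= 1:
        raise ValueError("isoprene_plateau must be in (0, 1]")
    fracs = np.asarray(plastidial_fracs, dtype=float)
    if fracs.shape != (4,) or np.any((fracs <= 0) | (fracs > 1)):
        raise ValueError("plastidial_fracs must be 4 values in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for name, pool, frac in zip(METABOLITE_ORDER, true_pools.as_array(), fracs):
        final = frac * isoprene_plateau
        if noise_sd > 0:
            final = float(np.clip(final + rng.normal(0.0, noise_sd), 0.0, 1.0))
        records.append(
            MetabolitePoolRecord(name=name, total_pool=pool / frac, final_fraction=final)
        )
    return records


_DEFAULT_MASTER = {
    "labeling": {
        "pools": [1.0, 2.0, 3.0, 4.0],
        "flux_j": 2.0,
        "plateau_m": 0.95,
        "t_max": 20.0,
        "n_points": 25,
        "noise_sd": 0.02,
    },
    "assay": {
        "km": 5.0,
        "vmax": 10.0,
        "substrate_levels": [1.0, 2.0, 5.0, 10.0, 50.0],
        "t_max": 2.0,
        "n_points": 8,
        "noise_cv": 0.05,
        "dmadp_idp_ratio": 6.0,
    },
    "pools": {
        "isoprene_plateau": 0.95,
        "plastidial_fracs": [0.5, 0.8, 0.9, 0.7],
        "noise_sd": 0.0,
    },
    "profile": {"isoprene": 10.0, "GDP": 2.0, "FDP": 1.0, "GGDP": 4.0},
}


def write_fixture_set(outdir: str | Path, master_config: dict | None = None, seed: int = 0) -> dict:
    """Write labeling, assay, pool and profile CSV fixtures plus a manifest.

    Identical (config, seed) pairs produce byte-identical files.  Returns
    the manifest (also written as JSON) recording seeds and true parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {**_DEFAULT_MASTER, **(master_config or {})}

    lab = cfg["labeling"]
    pools = PoolSizes(*lab["pools"])
    times = np.linspace(0.0, lab["t_max"], lab["n_points"])
    tc = simulate_labeling(
        LabelingSimConfig(
            pools=pools,
            flux_j=lab["flux_j"],
            plateau_m=lab["plateau_m"],
            times=times,
            noise_sd=lab["noise_sd"],
            seed=seed,
        )
    )
    pd.DataFrame({"time_min": tc.times, "fraction": tc.fractions}).to_csv(
        outdir / "labeling.csv", index=False, float_format="%.10g"
    )

    asy = cfg["assay"]
    assay_times = np.linspace(0.0, asy["t_max"], asy["n_points"])[1:]  # skip t=0 (product 0)
    _, assay_df = simulate_assay(
        AssaySimConfig(
            km=asy["km"],
            vmax=asy["vmax"],
            substrate_levels=asy["substrate_levels"],
            times=assay_times,
            noise_cv=asy["noise_cv"],
            dmadp_idp_ratio=asy["dmadp_idp_ratio"],
            seed=seed + 1,
        )
    )
    assay_df.to_csv(outdir / "assay.csv", index=False, float_format="%.10g")

    pl = cfg["pools"]
    records = simulate_pool_table(
        pools, pl["isoprene_plateau"], pl["plastidial_fracs"], pl["noise_sd"], seed=seed + 2
    )
    pool_rows = [
        {
            "metabolite": rec.name,
            "total_pool_nmol_per_gfw": rec.total_pool,
            "final_fraction": rec.final_fraction,
        }
        for rec in records
    ]
    pool_rows.append(
        {
            "metabolite": "isoprene",
            "total_pool_nmol_per_gfw": "",
            "final_fraction": pl["isoprene_plateau"],
        }
    )
    pd.DataFrame(pool_rows).to_csv(outdir / "pools.csv", index=False, float_format="%.10g")

    pd.DataFrame(
        [{"class": name, "moles": moles} for name, moles in cfg["profile"].items()]
    ).to_csv(outdir / "profile.csv", index=False, float_format="%.10g")

    manifest = {
        "seed": seed,
        "config": cfg,
        "files": ["labeling.csv", "assay.csv", "pools.csv", "profile.csv"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
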