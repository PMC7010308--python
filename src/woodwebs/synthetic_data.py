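"""Seeded generator of synthetic rearing-experiment datasets.

The generator emulates a four-treatment (season x stratum) wood-baiting
experiment: per treatment, each beetle species has a lognormal
abundance and a Dirichlet host-preference vector whose concentration
``kappa`` controls specialization (small kappa = concentrated,
specialist preferences), up-weighted for hosts of the beetle's latent
module (``n_modules`` modules, ``module_boost``) and for hosts low on a
nestedness gradient (``gamma``); emergence counts are Poisson draws
around abundance x preference.  Treatments retain a fraction ``rho`` of
their species pools from a shared core, so both species turnover and
interaction rewiring arise downstream.  The latent truth (module
labels, parameters) is returned for recovery tests.

All randomness flows from a single seed, with one sub-stream per
treatment so a treatment's data are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    RearingRecord,
    TraitTable,
    TREATMENTS,
    write_records,
    write_traits,
)

__all__ = ["SyntheticConfig", "generate_dataset", "reference_preset", "write_dataset"]

#: per-treatment species counts matching the magnitudes of a tropical
#: dry-forest rearing experiment (rain/dry season x canopy/ground)
_DEFAULT_N_HOSTS = {"Rc": 22, "Rg": 28, "Dc": 47, "Dg": 42}
_DEFAULT_N_BEETLES = {"Rc": 21, "Rg": 22, "Dc": 40, "Dg": 34}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic rearing experiment.

    Defaults reproduce the magnitudes of the reference study design:
    22-47 host and 21-34 beetle species per treatment, ~1,323 total
    emergences, global pools of 65 host and 57 beetle species, high
    specialization and partial cross-treatment species retention.
    """

    n_hosts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_HOSTS))
    n_beetles: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_BEETLES))
    total_emergences: int = 1323
    n_modules: int = 4
    kappa: float = 0.1  # Dirichlet concentration; small = specialists
    module_boost: float = 4.0  # preference up-weight for same-module hosts
    gamma: float = 1.0  # nestedness-gradient weight
    rho: float = 0.75  # cross-treatment species retention
    host_pool: int | None = 65  # global distinct-species caps (None = unlimited)
    beetle_pool: int | None = 57
    abundance_mu: float = 0.0  # lognormal beetle abundance
    abundance_sigma: float = 1.0
    nb_dispersion: float | None = None  # negative-binomial size; None = Poisson
    wood_density_mu: float = -0.43  # ln g/cm^3 (median ~0.65)
    wood_density_sigma: float = 0.25
    pdd_mu: float = -1.9  # ln %/day (median ~0.15)
    pdd_sigma: float = 0.4
    pdd_degree_coupling: float = 0.5  # negative association of PDD with degree
    bsi_mu: float = 4.1  # ln mm^2 (median ~60)
    bsi_sigma: float = 0.6
    with_intervals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for sizes in (self.n_hosts, self.n_beetles):
            if any(n < 2 for n in sizes.values()):
                raise ValueError("each treatment needs >= 2 species per level")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        for pool, sizes, what in (
            (self.host_pool, self.n_hosts, "host"),
            (self.beetle_pool, self.n_beetles, "beetle"),
        ):
            if pool is None:
                continue
            core = max(round(self.rho * n) for n in sizes.values())
            spare = pool - core
            need = max(n - round(self.rho * n) for n in sizes.values())
            if spare < need:
                raise ValueError(
                    f"retention rho={self.rho} infeasible: {what} pool of {pool} "
                    f"cannot host {need} non-core species beside a {core}-species core"
                )


def reference_preset(seed: int = 0) -> SyntheticConfig:
    """Configuration matching the reference study design magnitudes."""
    return SyntheticConfig(seed=seed)


def _pools(
    sizes: dict[str, int],
    rho: float,
    pool: int | None,
    prefix: str,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Per-treatment species pools: the first round(rho*n) species come
    from a shared core (a common prefix of the global pool), the rest
    are drawn from the remainder of the global pool."""
    core_size = max(round(rho * n) for n in sizes.values())
    if pool is None:
        pool = core_size + sum(n - round(rho * n) for n in sizes.values())
    labels = [f"{prefix}{i + 1:03d}" for i in range(pool)]
    spare = labels[core_size:]
    out = {}
    for t in sizes:
        k = round(rho * sizes[t])
        extra = sizes[t] - k
        picked = rng.choice(len(spare), size=extra, replace=False)
        out[t] = sorted(labels[:k] + [spare[i] for i in sorted(picked)])
    return out


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[RearingRecord], TraitTable, dict]:
    """Generate rearing records, a trait table, and the latent truth.

    Returns ``(records, traits, truth)``; ``truth`` holds the module
    labels per treatment and the generating parameters, for parameter-
    recovery tests.
    """
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(cfg.seed)
    pool_ss, trait_ss, *treat_ss = root.spawn(2 + len(cfg.n_hosts))
    pool_rng = np.random.default_rng(pool_ss)

    host_pools = _pools(cfg.n_hosts, cfg.rho, cfg.host_pool, "H", pool_rng)
    beetle_pools = _pools(cfg.n_beetles, cfg.rho, cfg.beetle_pool, "B", pool_rng)

    # persistent module labels for core (retained) species, random for
    # treatment-exclusive species
    def species_index(label: str) -> int:
        return int(label[1:]) - 1

    core_h = max(round(cfg.rho * n) for n in cfg.n_hosts.values())
    core_b = max(round(cfg.rho * n) for n in cfg.n_beetles.values())

    sizes = {t: cfg.n_hosts[t] + cfg.n_beetles[t] for t in cfg.n_hosts}
    total_size = sum(sizes.values())

    records: list[RearingRecord] = []
    truth: dict = {
        "kappa": cfg.kappa,
        "rho": cfg.rho,
        "gamma": cfg.gamma,
        "n_modules": cfg.n_modules,
        "modules": {},
        "abundance": {},
    }

    for t, ss in zip(sorted(cfg.n_hosts), treat_ss):
        rng = np.random.default_rng(ss)
        hosts = host_pools[t]
        beetles = beetle_pools[t]
        n_h, n_b = len(hosts), len(beetles)

        h_mod = np.array(
            [
                species_index(h) % cfg.n_modules
                if species_index(h) < core_h
                else rng.integers(cfg.n_modules)
                for h in hosts
            ]
        )
        b_mod = np.array(
            [
                species_index(b) % cfg.n_modules
                if species_index(b) < core_b
                else rng.integers(cfg.n_modules)
                for b in beetles
            ]
        )
        truth["modules"][t] = {
            "hosts": dict(zip(hosts, h_mod.tolist())),
            "beetles": dict(zip(beetles, b_mod.tolist())),
        }

        lam = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, size=n_b)
        lam /= lam.sum()
        truth["abundance"][t] = dict(zip(beetles, lam.tolist()))
        target_total = cfg.total_emergences * sizes[t] / total_size

        # nestedness gradient: hosts earlier in the (sorted) pool are
        # attractive to every beetle
        gradient = np.exp(-cfg.gamma * np.arange(n_h) / n_h)

        A = np.zeros((n_h, n_b), dtype=np.int64)
        for j in range(n_b):
            base = gradient * (1.0 + cfg.module_boost * (h_mod == b_mod[j]))
            alpha = cfg.kappa * n_h * base / base.sum()
            pref = rng.dirichlet(alpha)
            rate = target_total * lam[j] * pref
            if cfg.nb_dispersion is None:
                A[:, j] = rng.poisson(rate)
            else:
                size = cfg.nb_dispersion
                A[:, j] = rng.negative_binomial(size, size / (size + rate))

        for i in range(n_h):
            for j in range(n_b):
                if A[i, j] > 0:
                    interval = None
                    if cfg.with_intervals:
                        interval = str(rng.choice(["2", "4", "6", "8"]))
                    records.append(
                        RearingRecord(
                            treatment=t,
                            host=hosts[i],
                            beetle=beetles[j],
                            count=int(A[i, j]),
                            interval=interval,
                        )
                    )

    traits = _traits(cfg, records, np.random.default_rng(trait_ss))
    return records, traits, truth


def _traits(
    cfg: SyntheticConfig, records: list[RearingRecord], rng: np.random.Generator
) -> TraitTable:
    hosts = sorted({r.host for r in records})
    beetles = sorted({r.beetle for r in records})
    # realized degree pooled over treatments, for the PDD-degree coupling
    partners: dict[str, set[str]] = {h: set() for h in hosts}
    for r in records:
        partners[r.host].add(r.beetle)
    degree = np.array([len(partners[h]) for h in hosts], dtype=float)
    z = (degree - degree.mean()) / degree.std() if degree.std() > 0 else degree * 0

    density = rng.lognormal(cfg.wood_density_mu, cfg.wood_density_sigma, len(hosts))
    pdd = rng.lognormal(cfg.pdd_mu, cfg.pdd_sigma, len(hosts)) * np.exp(
        -cfg.pdd_degree_coupling * z
    )
    body = rng.lognormal(cfg.bsi_mu, cfg.bsi_sigma, len(beetles))
    rows = [
        {"species": h, "role": "host", "wood_density": d, "pdd": p, "bsi": np.nan}
        for h, d, p in zip(hosts, density, pdd)
    ] + [
        {"species": b, "role": "beetle", "wood_density": np.nan, "pdd": np.nan, "bsi": s}
        for b, s in zip(beetles, body)
    ]
    return TraitTable(pd.DataFrame(rows))


def write_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate a dataset and write records.csv, traits.csv and the
    truth sidecar JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, traits, truth = generate_dataset(config)
    rec_path, trait_path, truth_path = (
        out / "records.csv",
        out / "traits.csv",
        out / "truth.json",
    )
    write_records(records, rec_path)
    write_traits(traits, trait_path)
    truth["config"] = dataclasses.asdict(config)
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return rec_path, trait_path, truth_path
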