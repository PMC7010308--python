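"""End-to-end analysis pipeline.

Reads (or generates) rearing records and traits, builds the
per-treatment interaction networks, and runs every stage: Hill
diversity with bootstrap CIs and significance letters, sample coverage,
compositional and interaction beta-diversity decompositions, network
structure with fixed-marginal null significance, species-level indices,
Kruskal-Wallis treatment comparisons, and per-treatment correlation
PCAs joining indices with traits.  Emits plain-CSV reports plus a JSON
manifest; deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha_diversity import AbundanceVector, compare_treatments, sample_coverage
from .beta_partition import baselga_all_pairs
from .core_data import (
    TraitTable,
    TreatmentNetworkSet,
    build_networks,
    read_records,
    read_traits,
)
from .interaction_beta import interaction_beta_all_pairs
from .network_metrics import network_structure, species_indices
from .null_models import null_report
from .ordination_stats import kruskal_wallis, pca_correlation
from .synthetic_data import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize_structure"]

#: network-level metrics summarized across treatments (mean +/- sample SD)
STRUCTURE_METRICS = (
    "wnodf",
    "Q",
    "h2",
    "niche_overlap_hosts",
    "niche_overlap_beetles",
)

BEETLE_PCA_VARS = ("degree", "d_prime", "effective_partners", "bsi")
HOST_PCA_VARS = ("degree", "d_prime", "species_strength", "wood_density", "pdd")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, treatment: str | None, cause: Exception):
        where = f" (treatment {treatment})" if treatment else ""
        super().__init__(f"stage {stage!r}{where} failed: {cause}")
        self.stage = stage
        self.treatment = treatment


@dataclass
class PipelineConfig:
    """Inputs, replication counts and thresholds of one pipeline run."""

    records_path: str | None = None
    traits_path: str | None = None
    synthetic: SyntheticConfig | None = None
    n_boot: int = 100  # bootstrap replicates for diversity CIs
    n_rand: int = 1000  # fixed-marginal null randomizations
    n_trials: int = 20  # modularity restarts (observed network)
    n_trials_null: int = 5  # modularity restarts per null draw
    alpha: float = 0.01  # p-value threshold for network metrics
    z_threshold: float = 2.0  # modularity z-score threshold
    seed: int = 0
    out_dir: str = "woodwebs_out"

    def __post_init__(self) -> None:
        if min(self.n_boot, self.n_rand, self.n_trials) <= 0:
            raise ValueError("replication counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def summarize_structure(structure: pd.DataFrame) -> pd.DataFrame:
    """Cross-treatment mean and sample SD (ddof=1) of each
    network-level metric present in a per-treatment structure table."""
    metrics = [m for m in STRUCTURE_METRICS if m in structure.columns]
    return pd.DataFrame(
        {
            "metric": metrics,
            "mean": [structure[m].mean() for m in metrics],
            "sd": [
                structure[m].std(ddof=1) if len(structure) > 1 else np.nan
                for m in metrics
            ],
        }
    )


def _load(config: PipelineConfig) -> tuple[TreatmentNetworkSet, TraitTable | None]:
    if config.synthetic is not None:
        records, traits, _ = generate_dataset(config.synthetic)
    elif config.records_path is not None:
        records = read_records(config.records_path)
        traits = read_traits(config.traits_path) if config.traits_path else None
    else:
        raise ValueError("pipeline needs either records_path or a synthetic config")
    return build_networks(records), traits


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle.

    Returns a manifest mapping report names to file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_div, s_null, *_ = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        written[name] = path

    try:
        networks, traits = _load(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", None, exc) from exc

    # -- diversity ---------------------------------------------------------
    try:
        div_tables = []
        for q in (0, 1, 2):
            div_tables.append(
                compare_treatments(
                    networks, q, n_boot=config.n_boot, seed=s_div + q
                )
            )
        diversity = pd.concat(div_tables, ignore_index=True)
        coverage = pd.DataFrame(
            [
                {
                    "treatment": t,
                    "coverage": sample_coverage(
                        AbundanceVector(tuple(networks[t].beetles), networks[t].col_totals)
                    ),
                }
                for t in networks.treatments
            ]
        )
        emit("diversity", diversity)
        emit("coverage", coverage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("alpha_diversity", None, exc) from exc

    # -- beta diversity ----------------------------------------------------
    if len(networks) >= 2:
        try:
            for level in ("beetle", "host"):
                table, summary = baselga_all_pairs(networks, level)
                emit(f"beta_species_{level}", table)
                emit(f"beta_species_{level}_summary", summary)
            table, summary = interaction_beta_all_pairs(networks)
            emit("beta_interactions", table)
            emit("beta_interactions_summary", summary)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("beta_diversity", None, exc) from exc
    else:
        logger.warning("single treatment: beta-diversity stages skipped")

    # -- network structure and nulls ---------------------------------------
    struct_rows, null_rows = [], []
    for t in networks.treatments:
        try:
            st = network_structure(
                networks[t], n_trials=config.n_trials, seed=s_null
            )
            struct_rows.append(
                {
                    "treatment": t,
                    "network_size": st.network_size,
                    "n_hosts": st.n_hosts,
                    "n_beetles": st.n_beetles,
                    "m": st.m,
                    "wnodf": st.wnodf,
                    "Q": st.Q,
                    "h2": st.h2,
                    "niche_overlap_hosts": st.niche_overlap_hosts,
                    "niche_overlap_beetles": st.niche_overlap_beetles,
                }
            )
            rep = null_report(
                networks[t],
                n_rand=config.n_rand,
                seed=s_null,
                n_trials_null=config.n_trials_null,
                n_trials_obs=config.n_trials,
            )
            rep.insert(0, "treatment", t)
            null_rows.append(rep)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("network_structure", t, exc) from exc
    structure = pd.DataFrame(struct_rows)
    emit("structure", structure)
    emit("structure_summary", summarize_structure(structure))
    emit("null_report", pd.concat(null_rows, ignore_index=True))

    # -- species-level indices ---------------------------------------------
    try:
        idx_tables = []
        for t in networks.treatments:
            for level in ("beetle", "host"):
                tab = species_indices(networks[t], level)
                tab.insert(0, "treatment", t)
                idx_tables.append(tab)
        indices = pd.concat(idx_tables, ignore_index=True)
        emit("species_indices", indices)

        beetle = indices[indices["level"] == "beetle"]
        host = indices[indices["level"] == "host"]
        summary_rows = []
        for level_df, level, cols in (
            (beetle, "beetle", ("d_prime", "effective_partners")),
            (host, "host", ("species_strength",)),
        ):
            per_t = level_df.groupby("treatment")
            for col in cols:
                means = per_t[col].mean()
                groups = [g[col].to_numpy() for _, g in per_t]
                kw = kruskal_wallis(*groups) if len(groups) >= 2 else None
                summary_rows.append(
                    {
                        "level": level,
                        "index": col,
                        "mean": means.mean(),
                        "sd": means.std(ddof=1) if len(means) > 1 else np.nan,
                        "kw_H": kw.statistic if kw else np.nan,
                        "kw_p": kw.p_value if kw else np.nan,
                    }
                )
        emit("species_indices_summary", pd.DataFrame(summary_rows))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("species_indices", None, exc) from exc

    # -- trait ordination --------------------------------------------------
    if traits is not None:
        try:
            pca_loadings = []
            for t in networks.treatments:
                for level, vars_, trait_cols in (
                    ("beetle", BEETLE_PCA_VARS, TraitTable.BEETLE_TRAITS),
                    ("host", HOST_PCA_VARS, TraitTable.HOST_TRAITS),
                ):
                    tab = species_indices(networks[t], level).set_index("species")
                    joined = tab.join(traits.for_role(level), how="left")
                    cols = [c for c in vars_ if c in joined.columns]
                    try:
                        res = pca_correlation(joined[cols])
                    except ValueError as err:
                        logger.warning("PCA skipped for %s/%s: %s", t, level, err)
                        continue
                    ld = res.loadings.reset_index(names="variable")
                    ld.insert(0, "level", level)
                    ld.insert(0, "treatment", t)
                    for k, prop in enumerate(res.proportion):
                        ld[f"PC{k + 1}_prop"] = prop
                    pca_loadings.append(ld)
            if pca_loadings:
                emit("pca_loadings", pd.concat(pca_loadings, ignore_index=True))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ordination", None, exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if not isinstance(v, dict)
        },
        "treatments": networks.treatments,
        "reports": {k: str(v) for k, v in written.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written["manifest"] = manifest_path
    return written
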