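"""One-pass network reports and full-study orchestration.

:func:`metric_report` computes every summary a published network-metrics
table carries — species counts, link and association totals, mean degrees
with standard errors, connectance, web asymmetry, H2' and NODF with its
Monte-Carlo p — for one network in a single call.  :func:`run_study`
strings the stages together for a pair of period networks plus the
exclusion-experiment tables, writing machine-readable JSON/TSV outputs.

A single global seed fans out deterministically to per-stage seeds
(SeedSequence spawning) so any stage can be re-run in isolation and the
whole bundle is byte-reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .herbivory import (
    factorial_anova,
    paired_abundance_test,
    per_species_treatment_tests,
    stem_level_means,
    tukey_hsd,
)
from .matrix import (
    InteractionMatrix,
    NetworkMetrics,
    average_degree,
    connectance,
    truncate2,
    web_asymmetry,
)
from .nestedness import nestedness_significance
from .specialization import h2_prime
from .temporal import align_networks

__all__ = ["RunConfig", "metric_report", "run_study", "stage_seed"]

logger = logging.getLogger("antnet")

Precision = Literal["truncate-2", "round-3", "full"]

_STAGES = ("nestedness_a", "nestedness_b", "simulate", "herbivory")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (fixed fan-out)."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    child = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return int(child[_STAGES.index(stage)].generate_state(1)[0] % (2**31))


def _apply_precision(value: float, rule: Precision) -> float:
    if rule == "truncate-2":
        return truncate2(value)
    if rule == "round-3":
        return round(value, 3)
    return value


@dataclass(frozen=True)
class RunConfig:
    """Study-run configuration (defaults reproduce the field procedure)."""

    n_randomizations: int = 1000
    seed: int = 0
    precision: Precision = "full"
    out_dir: str | Path | None = None


def metric_report(
    M: InteractionMatrix, config: RunConfig = RunConfig(), nested_seed: int | None = None
) -> NetworkMetrics:
    """Populate a full metrics record for one network.

    NODF significance uses the Ce null with ``config.n_randomizations``
    draws; H2' needs a quantitative matrix and is skipped (None) when the
    input is already binary with a degenerate entropy range.
    """
    mean_p, se_p = average_degree(M, "plants")
    mean_a, se_a = average_degree(M, "ants")
    W = web_asymmetry(M.n_plants, M.n_ants)
    seed = nested_seed if nested_seed is not None else stage_seed(config.seed, "nestedness_a")
    from .matrix import binarize

    ens = nestedness_significance(
        binarize(M), n_randomizations=config.n_randomizations, seed=seed
    )
    h2 = h2_prime(M)
    rule = config.precision
    report = NetworkMetrics(
        period_label=M.period_label,
        n_ants=M.n_ants,
        n_plants=M.n_plants,
        n_links=M.n_links,
        n_associations=M.grand_total,
        mean_degree_plants=_apply_precision(mean_p, rule),
        se_degree_plants=None if se_p is None else _apply_precision(se_p, rule),
        mean_degree_ants=_apply_precision(mean_a, rule),
        se_degree_ants=None if se_a is None else _apply_precision(se_a, rule),
        connectance_pct=_apply_precision(connectance(M), rule),
        web_asymmetry=_apply_precision(W, rule),
        web_asymmetry_abs=_apply_precision(abs(W), rule),
        h2_prime=_apply_precision(h2.h2_prime, rule),
        nodf=_apply_precision(ens.observed, rule),
        nodf_p=ens.p,
    )
    logger.info(
        "metrics[%s]: L=%d C=%.4f%% |W|=%.4f H2'=%.4f NODF=%.4f (p=%.4g)",
        M.period_label, M.n_links, connectance(M), abs(W), h2.h2_prime,
        ens.observed, ens.p,
    )
    return report


def run_study(
    network_a: InteractionMatrix,
    network_b: InteractionMatrix,
    leaves: pd.DataFrame | None = None,
    abundance: pd.DataFrame | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """Full reproduction bundle: per-period metrics, comparison, experiment.

    When the experiment tables are omitted the network stages still run
    and the experiment section is skipped with a warning.  If
    ``config.out_dir`` is set, JSON/TSV outputs and a run log are written
    there.
    """
    bundle: dict = {
        "config": {
            "n_randomizations": config.n_randomizations,
            "seed": config.seed,
            "precision": config.precision,
        },
        "versions": {"antnet": __version__, "numpy": np.__version__},
    }
    bundle["metrics_a"] = metric_report(
        network_a, config, nested_seed=stage_seed(config.seed, "nestedness_a")
    ).to_dict()
    bundle["metrics_b"] = metric_report(
        network_b, config, nested_seed=stage_seed(config.seed, "nestedness_b")
    ).to_dict()
    bundle["comparison"] = align_networks(network_a, network_b).to_dict()

    if leaves is None:
        logger.warning("no leaf records supplied; experiment stage skipped")
        bundle["experiment"] = None
    else:
        stems = stem_level_means(leaves)
        anova = factorial_anova(stems)
        err = anova.loc["Error"]
        cell_means = stems.groupby("species")["herbivory_pct"].mean()
        sizes = stems.groupby("species").size()
        tukey = tukey_hsd(
            cell_means, float(err["mean_sq"]), int(err["df"]), sizes.to_dict()
        )
        per_species = per_species_treatment_tests(stems)
        experiment = {
            "anova": anova.reset_index().to_dict(orient="records"),
            "tukey_species": tukey.to_dict(orient="records"),
            "per_species_tests": per_species.to_dict(orient="records"),
        }
        if abundance is not None:
            years = sorted(abundance["year"].unique())
            t, p = paired_abundance_test(
                abundance[abundance["year"] == years[0]],
                abundance[abundance["year"] == years[1]],
            )
            experiment["abundance_paired_t"] = {"t": t, "p": p}
        bundle["experiment"] = experiment

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=_jsonify)
        )
        if leaves is not None:
            pd.DataFrame(bundle["experiment"]["anova"]).to_csv(
                out / "anova.tsv", sep="\t", index=False
            )
            pd.DataFrame(bundle["experiment"]["per_species_tests"]).to_csv(
                out / "per_species_tests.tsv", sep="\t", index=False
            )
        logger.info("wrote study bundle to %s", out)
    return bundle


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
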