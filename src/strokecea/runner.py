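"""Orchestration across subgroups: deterministic, probabilistic, and
one-way sensitivity runs, assembled into a results matrix with one row per
(trial, subgroup)."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import decision_tree as dtree
from .econ import EconResult
from .markov import run_strategy
from .owsa import tornado_analysis, tornado_to_frame
from .params import (
    LifeTable,
    ModelSettings,
    MrsDistribution,
    ParameterError,
    ParameterSet,
    StudyConfig,
    SubgroupDefinition,
    load_study,
)
from .psa import PsaResults, run_psa

__all__ = ["SubgroupResult", "StudyResults", "run_subgroup", "run_all"]

log = logging.getLogger(__name__)

DEFAULT_MODES = frozenset({"deterministic"})
CE_THRESHOLDS = (50_000.0, 100_000.0, 150_000.0)


@dataclass
class SubgroupResult:
    """All requested outputs for one (trial, subgroup)."""

    subgroup: SubgroupDefinition
    deterministic: EconResult | None = None
    lifetime: dict | None = None          # per-strategy LifetimeOutcome
    psa: PsaResults | None = None
    tornado: list | None = None

    def row(self, wtp: float = 100_000.0) -> dict:
        """Flatten to one results-table row (NA where a mode was not run)."""
        sg = self.subgroup
        row: dict = {"trial": sg.trial, "subgroup": sg.label}
        if self.deterministic is not None:
            d = self.deterministic
            row.update(delta_cost=d.delta_cost, delta_qaly=d.delta_qaly,
                       icer=d.icer, dominance=d.dominance, nmb=d.nmb)
        if self.psa is not None:
            s = self.psa.summary(wtp)
            row.update(
                delta_cost_mean=s["delta_cost"]["mean"],
                delta_cost_ci_low=s["delta_cost"]["ci_low"],
                delta_cost_ci_high=s["delta_cost"]["ci_high"],
                delta_qaly_mean=s["delta_qaly"]["mean"],
                delta_qaly_ci_low=s["delta_qaly"]["ci_low"],
                delta_qaly_ci_high=s["delta_qaly"]["ci_high"],
                nmb_mean=s["nmb"]["mean"],
                nmb_ci_low=s["nmb"]["ci_low"],
                nmb_ci_high=s["nmb"]["ci_high"],
            )
            for w in CE_THRESHOLDS:
                row[f"prob_ce_{int(w/1000)}k"] = self.psa.prob_cost_effective(w)
        return row


@dataclass
class StudyResults:
    """Results for every configured subgroup, ordered as configured."""

    results: list[SubgroupResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self, wtp: float = 100_000.0) -> pd.DataFrame:
        return pd.DataFrame([r.row(wtp) for r in self.results])


def run_subgroup(
    subgroup: SubgroupDefinition,
    params: ParameterSet,
    settings: ModelSettings,
    life_table: LifeTable,
    reference: MrsDistribution | None = None,
    modes: frozenset[str] | set[str] = DEFAULT_MODES,
    wtp: float = 100_000.0,
    seed: int | None = None,
    n_draws: int | None = None,
) -> SubgroupResult:
    """Run the requested analysis modes for one subgroup."""
    unknown = set(modes) - {"deterministic", "psa", "owsa"}
    if unknown:
        raise ValueError(f"unknown modes {sorted(unknown)}")
    result = SubgroupResult(subgroup=subgroup)

    if "deterministic" in modes or "owsa" in modes:
        acute = dtree.evaluate_decision_tree(subgroup, params, reference)
        rec_cost, rec_util = dtree.recurrence_inputs(subgroup, params, acute)
        lifetime = {}
        for name, arm in subgroup.arms.items():
            _, lifetime[name] = run_strategy(arm, acute[name], params, settings,
                                             life_table, rec_cost[name], rec_util[name])
        result.lifetime = lifetime
        result.deterministic = EconResult.from_deltas(
            lifetime["MT_SMC"].discounted_cost - lifetime["SMC"].discounted_cost,
            lifetime["MT_SMC"].discounted_qaly - lifetime["SMC"].discounted_qaly,
            wtp=wtp,
        )
    if "psa" in modes:
        result.psa = run_psa(subgroup, params, settings, life_table, reference,
                             n_draws=n_draws, seed=seed)
        s = result.psa.summary(wtp)
        if result.deterministic is not None:
            result.deterministic = EconResult.from_deltas(
                result.deterministic.delta_cost, result.deterministic.delta_qaly, wtp=wtp,
                ci={"delta_cost": (s["delta_cost"]["ci_low"], s["delta_cost"]["ci_high"]),
                    "delta_qaly": (s["delta_qaly"]["ci_low"], s["delta_qaly"]["ci_high"]),
                    "nmb": (s["nmb"]["ci_low"], s["nmb"]["ci_high"])},
            )
    if "owsa" in modes:
        result.tornado = tornado_analysis(subgroup, params, settings, life_table,
                                          reference, wtp=wtp)
    return result


def _config_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(
    config: str | Path | StudyConfig,
    out_dir: str | Path | None = None,
    modes: frozenset[str] | set[str] = DEFAULT_MODES,
    wtp: float = 100_000.0,
    seed: int | None = None,
    n_draws: int | None = None,
    subgroup_filter: str | None = None,
    trial_filter: str | None = None,
) -> StudyResults:
    """Run the whole study, optionally writing CSV/JSON reports.

    Failures in individual subgroups are collected and the run continues;
    inspect ``StudyResults.failures`` (the CLI exits non-zero when any
    subgroup failed).
    """
    config_path: Path | None = None
    if not isinstance(config, StudyConfig):
        config_path = Path(config)
        config = load_study(config_path)

    subgroups = [
        sg for sg in config.subgroups
        if (subgroup_filter is None or sg.label == subgroup_filter)
        and (trial_filter is None or sg.trial == trial_filter)
    ]
    if not subgroups:
        log.warning("no subgroups selected; empty results")

    master_seed = seed if seed is not None else config.settings.seed
    study = StudyResults()
    for i, sg in enumerate(subgroups):
        try:
            study.results.append(
                run_subgroup(sg, config.params, config.settings, config.life_table,
                             config.mrs56_reference, modes=modes, wtp=wtp,
                             # decorrelated but reproducible per-subgroup streams,
                             # keyed by identity so execution order is irrelevant
                             seed=_subgroup_seed(master_seed, sg.key), n_draws=n_draws)
            )
        except ParameterError as e:
            log.error("subgroup %s failed: %s", sg.key, e)
            study.failures[sg.key] = str(e)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        study.to_frame(wtp).to_csv(out_dir / "results.csv", index=False)
        for r in study.results:
            stem = f"{r.subgroup.trial}_{r.subgroup.label}".replace(" ", "_")
            if r.psa is not None:
                r.psa.to_frame().to_csv(out_dir / f"psa_{stem}.csv", index=False)
                r.psa.ceac().to_csv(out_dir / f"ceac_{stem}.csv", index=False)
            if r.tornado is not None:
                tornado_to_frame(r.tornado).to_csv(out_dir / f"tornado_{stem}.csv", index=False)
        meta = {
            "seed": master_seed,
            "modes": sorted(modes),
            "wtp": wtp,
            "n_draws": n_draws if n_draws is not None else config.settings.psa_draws,
            "package_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "failures": study.failures,
        }
        if config_path is not None:
            meta["config"] = str(config_path)
            meta["config_sha256_16"] = _config_hash(config_path)
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return study


def _subgroup_seed(master_seed: int, key: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
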