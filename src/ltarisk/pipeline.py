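"""End-to-end analysis pipeline.

Stages mirror the analysis plan: simulate (or load) a cohort, recode raw
responses to 3-category indicators, fit per-wave latent class models over
a range of class counts, fit the two-wave latent transition model with its
invariance comparisons (time and trial arm), then estimate class-specific
intervention effects.  Every stochastic stage receives a child seed derived
deterministically from the master seed, and the serialized configuration
plus its hash are embedded in the report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects, lca, lta, recoding, simulate
from ._utils import child_seeds

log = logging.getLogger("ltarisk")

STAGES = ("simulate", "recode", "lca", "lta", "effects")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    input_path: str | None = None       # raw cohort CSV; None -> simulate
    n: int = 2000
    cohort: str = "trial"
    K: int = 4
    k_min: int = 3
    k_max: int = 5
    n_starts: int = 20
    lta_starts: int = 3
    tol: float = 1e-7
    max_iter: int = 1000
    covariates: tuple = ()
    complete_case: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, child_seeds(cfg.seed, len(STAGES))))
    log.info("child seeds: %s", seeds)
    report: dict = {"config": cfg.to_dict(), "config_hash": _config_hash(cfg),
                    "seed": cfg.seed, "child_seeds": seeds}

    # --- simulate / load -------------------------------------------------
    if cfg.input_path is None:
        gen_cfg = simulate.default_paper_config(n=cfg.n, seed=seeds["simulate"],
                                                cohort=cfg.cohort)
        cohort = simulate.generate(gen_cfg)
        records = cohort.records
        recoding.write_cohort(records, out / "cohort.csv")
        cohort.truth.to_csv(out / "truth.csv", index=False)
    else:
        records = recoding.read_cohort(cfg.input_path)

    # --- recode ----------------------------------------------------------
    ind = {}
    for wave in ("baseline", "m6"):
        if (records["wave"] == wave).any():
            ind[wave] = recoding.build_indicators(records, wave)
            recoding.write_indicators(ind[wave], out / f"indicators_{wave}.csv")

    # --- per-wave latent class selection ---------------------------------
    rng = np.random.default_rng(seeds["lca"])
    lca_tables = {}
    for wave, matrix in ind.items():
        tab = lca.select_model(matrix, K_range=range(cfg.k_min, cfg.k_max + 1),
                               n_starts=cfg.n_starts, tol=cfg.tol,
                               max_iter=cfg.max_iter,
                               seed=int(rng.integers(2**31)))
        tab.to_csv(out / f"lca_fit_{wave}.csv", index=False)
        lca_tables[wave] = tab.to_dict(orient="records")
    report["lca"] = lca_tables

    # --- latent transition models ----------------------------------------
    X1, X2, arm = simulate.two_wave_matrices(records)
    lta_seeds = child_seeds(seeds["lta"], 3)
    inv = lta.fit_lta(X1, X2, arm, K=cfg.K, time_invariant=True,
                      arm_specific_tau=True, n_starts=cfg.lta_starts,
                      tol=cfg.tol, max_iter=cfg.max_iter, seed=lta_seeds[0])
    free = lta.fit_lta(X1, X2, arm, K=cfg.K, time_invariant=False,
                       arm_specific_tau=True, tol=cfg.tol,
                       max_iter=cfg.max_iter, seed=lta_seeds[1], init=inv)
    time_test = lta.lrt_compare(inv, free)
    arm_free = lta.fit_lta(X1, X2, arm, K=cfg.K, time_invariant=True,
                           arm_specific_tau=True, arm_specific_measurement=True,
                           tol=cfg.tol, max_iter=cfg.max_iter,
                           seed=lta_seeds[2], init=inv)
    arm_test = lta.lrt_compare(inv, arm_free)
    w1, w2 = lta.marginal_class_probs(inv)
    report["lta"] = {
        "loglik": inv.loglik, "n_params": inv.n_params,
        "delta": _jsonable(inv.delta),
        "tau": {a: _jsonable(inv.tau_for(a)) for a in inv.arm_labels},
        "marginal_wave1": _jsonable(w1), "marginal_wave2": _jsonable(w2),
        "time_invariance_lrt": _jsonable(time_test),
        "arm_invariance_lrt": _jsonable(arm_test),
        "class_labels": list(simulate.CLASS_LABELS[:cfg.K]),
    }
    post = lta.posterior_lta(inv, X1, X2, arm)
    pd.DataFrame(post.r1, columns=[f"p{k}" for k in range(cfg.K)]).assign(
        modal=post.modal1).to_csv(out / "posterior_wave1.csv", index=False)

    # --- effects ----------------------------------------------------------
    base = records[(records["wave"] == "baseline")
                   & records["randomized"].astype(bool)].reset_index(drop=True)
    # the follow-up outcome needs an observed second wave; the complete-case
    # sensitivity rerun additionally requires every item observed at both waves
    completers = post.has_wave2.copy()
    if cfg.complete_case:
        from ._utils import MISSING
        completers &= (np.asarray(X1) != MISSING).all(axis=1)
        completers &= (np.asarray(X2) != MISSING).all(axis=1)
    arm01 = (np.asarray(arm) == "pei").astype(float)
    low2 = (post.modal2 == 0).astype(float)
    covs = base[list(cfg.covariates)] if cfg.covariates else None
    m = effects.lowrisk_glm(low2[completers], arm01[completers],
                            post.modal1[completers],
                            None if covs is None else covs[completers])
    ames = effects.average_marginal_effects(m)
    ors = [effects.arm_odds_ratio(m, int(k)) for k in m.class_levels]
    high = cfg.K - 1
    in_high = post.modal1 == high
    att = effects.attrition_test(post.has_wave2[in_high], arm01[in_high])
    report["effects"] = {
        "ame": [_jsonable(a) for a in ames],
        "odds_ratios": [_jsonable(o) for o in ors],
        "attrition_high_risk": {"chi2": att[0], "p": att[1]},
        "complete_case": cfg.complete_case,
    }
    if cfg.input_path is None and not base["randomized"].all():
        pass  # trial cohorts are fully randomized; baseline cohorts below
    all_base = records[records["wave"] == "baseline"].reset_index(drop=True)
    if not all_base["randomized"].astype(bool).all():
        bl = recoding.build_indicators(records, "baseline")
        bl_model = lca.em_fit(bl, cfg.K, n_starts=cfg.n_starts, tol=cfg.tol,
                              max_iter=cfg.max_iter, seed=seeds["effects"])
        bl_post = lca.posterior(bl_model, bl)
        stat, df, p = effects.participation_bias_test(
            bl_post.modal, all_base["randomized"].astype(bool).to_numpy())
        report["effects"]["participation_bias"] = {"chi2": stat, "df": df, "p": p}

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    log.info("report written to %s", out / "report.json")
    return report
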