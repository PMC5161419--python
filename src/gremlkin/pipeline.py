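"""End-to-end analysis orchestration.

``run_full_analysis`` takes a config describing (or simulating) a family
cohort, builds the five relationship matrices and PCs, fits the GK and
GKFSC models per trait, runs forward and backward selection, fits the
bivariate model on the consensus model, applies the liability transform,
and returns a machine-readable report.  The consensus rule follows the
majority of the (up to four) per-trait selections, resolving ties toward
the larger model.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

from . import __version__
from .bivariate import fit_bivariate_reml, test_correlation
from .liability import observed_to_liability
from .matrices import build_erm, compute_grm, compute_pcs, threshold_kinship
from .reml import (
    REMLError,
    REMLOptions,
    VarianceComponentSpec,
    fit_reml,
)
from .selection import backward_select, forward_select
from .simulate import SimulationConfig, TraitConfig, generate_cohort

__all__ = ["run_full_analysis", "render_tables", "consensus_model"]

logger = logging.getLogger(__name__)


def consensus_model(selected: list[str]) -> str:
    """Majority model code among selections; ties resolve to the larger model."""
    if not selected:
        return ""
    counts: dict[str, int] = {}
    for code in selected:
        counts[code] = counts.get(code, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    return best[0]


def _component_table(fit, prevalence, labels):
    table = {}
    for lab in labels:
        if fit is None or lab not in fit.labels:
            table[lab] = None
            continue
        est, se = fit.proportion(lab)
        liab, liab_se = observed_to_liability(est, prevalence, se)
        table[lab] = {
            "obs": round(est, 6), "obs_se": round(se, 6),
            "liability": round(liab, 6), "liability_se": round(liab_se, 6),
        }
    return table


def run_full_analysis(config: dict) -> dict:
    """Execute the full variance-partitioning pipeline.

    ``config`` keys: ``simulation`` (kwargs for SimulationConfig, with
    ``traits`` as lists of TraitConfig kwargs), ``seed``, ``alpha``,
    ``n_pcs``, ``reml`` (REMLOptions kwargs), ``grm_maf_min``,
    ``kinship_threshold``.  Any stage failure is recorded in the report
    rather than raised.
    """
    seed = int(config.get("seed", 1))
    sim_kwargs = dict(config.get("simulation", {}))
    trait_cfgs = [TraitConfig(**t) for t in sim_kwargs.pop("traits", [{}])]
    sim = SimulationConfig(seed=sim_kwargs.pop("seed", seed),
                           traits=trait_cfgs, **sim_kwargs)
    alpha = float(config.get("alpha", 0.05))
    n_pcs = int(config.get("n_pcs", 20))
    opts = REMLOptions(**config.get("reml", {}))
    cohort = generate_cohort(sim)

    G = compute_grm(cohort.genotypes, maf_min=float(config.get("grm_maf_min", 0.01)))
    K = threshold_kinship(G, threshold=float(config.get("kinship_threshold", 0.05)))
    erms = {kind: build_erm(cohort.pedigree, kind, sample_ids=cohort.sample_ids)
            for kind in "FSC"}
    n = cohort.n
    pcs = compute_pcs(G, k=min(n_pcs, n - 1))
    X = np.column_stack([np.ones(n), cohort.covariates, pcs])
    by_label = {"G": G, "K": K, **erms}
    full_spec = VarianceComponentSpec([(lab, by_label[lab]) for lab in "GKFSC"])

    report: dict = {
        "provenance": {
            "package": "gremlkin",
            "version": __version__,
            "seed": seed,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        },
        "cohort": {
            "n": n,
            "n_couple_pairs": sum(
                1 for p in cohort.pedigree.couples
                if all(x in set(cohort.sample_ids) for x in p)),
            "n_sib_pairs": sum(
                1 for p in cohort.pedigree.full_sibs
                if all(x in set(cohort.sample_ids) for x in p)),
            "n_family_pairs": sum(
                1 for p in cohort.pedigree.nuclear_family
                if all(x in set(cohort.sample_ids) for x in p)),
        },
        "traits": {},
        "failures": [],
    }

    selections: list[str] = []
    for t, tc in enumerate(trait_cfgs):
        name = f"trait{t + 1}"
        y = cohort.phenotypes[:, t].astype(float)
        entry: dict = {"prevalence": tc.prevalence,
                       "sample_prevalence": round(float(np.mean(y)), 6),
                       "models": {}, "selection": {}}
        for code in ("GK", "GKFSC"):
            spec = VarianceComponentSpec([(lab, by_label[lab]) for lab in code])
            try:
                fit = fit_reml(y, X, spec, sample_ids=cohort.sample_ids, options=opts)
                entry["models"][code] = {
                    "loglik": round(fit.loglik, 6),
                    "converged": fit.converged,
                    "components": _component_table(fit, tc.prevalence, code),
                }
            except REMLError as exc:
                report["failures"].append({"stage": f"{name}:{code}", "error": str(exc)})
        for direction, fn in (("forward", forward_select), ("backward", backward_select)):
            try:
                tr = fn(y, X, full_spec, alpha=alpha,
                        sample_ids=cohort.sample_ids, options=opts)
                entry["selection"][direction] = {
                    "final_model": tr.final_model,
                    "steps": tr.steps,
                }
                selections.append(tr.final_model)
                if tr.final_fit is not None:
                    entry["models"].setdefault(tr.final_model, {
                        "loglik": round(tr.final_fit.loglik, 6),
                        "converged": tr.final_fit.converged,
                        "components": _component_table(
                            tr.final_fit, tc.prevalence, tr.final_model),
                    })
            except REMLError as exc:
                report["failures"].append(
                    {"stage": f"{name}:{direction}_selection", "error": str(exc)})
        report["traits"][name] = entry

    report["consensus_model"] = consensus_model(selections)
    if len(trait_cfgs) < 2:
        report["bivariate"] = {"skipped": "single-trait config"}
        return report

    code = report["consensus_model"] or "GKC"
    spec = VarianceComponentSpec([(lab, by_label[lab]) for lab in code])
    try:
        bfit = fit_bivariate_reml(
            cohort.phenotypes[:, 0].astype(float),
            cohort.phenotypes[:, 1].astype(float),
            X, spec, sample_ids=cohort.sample_ids, options=opts,
        )
        biv: dict = {"model": code, "loglik": round(bfit.loglik, 6),
                     "components": {}}
        for lab in bfit.labels + ["residual"]:
            v1, v2, cv = bfit.blocks[lab]
            r, se = bfit.correlation(lab)
            row = {"v1": round(v1, 6), "v2": round(v2, 6), "cov": round(cv, 6),
                   "r": None if np.isnan(r) else round(r, 6),
                   "r_se": None if np.isnan(se) else round(se, 6)}
            if lab != "residual" and not np.isnan(r):
                for null in (0, 1):
                    wald_p, lrt_p = test_correlation(bfit, lab, null)
                    row[f"wald_p_vs_{null}"] = wald_p and round(wald_p, 8)
                    row[f"lrt_p_vs_{null}"] = lrt_p and round(lrt_p, 8)
            biv["components"][lab] = row
        report["bivariate"] = biv
    except REMLError as exc:
        report["failures"].append({"stage": "bivariate", "error": str(exc)})
        report["bivariate"] = {"failed": str(exc)}
    return report


def render_tables(report: dict, fmt: str = "json") -> str:
    """Serialize the report: json, tsv (component tables), or markdown."""
    if fmt == "json":
        return json.dumps(report, indent=2, default=str)
    rows = [("trait", "model", "component", "obs", "obs_se",
             "liability", "liability_se")]
    for tname, entry in report.get("traits", {}).items():
        for code, model in entry.get("models", {}).items():
            for lab, cell in model.get("components", {}).items():
                if cell is None:
                    continue
                rows.append((tname, code, lab, cell["obs"], cell["obs_se"],
                             cell["liability"], cell["liability_se"]))
    if fmt == "tsv":
        return "\n".join("\t".join(str(x) for x in r) for r in rows) + "\n"
    if fmt == "markdown":
        header, *body = rows
        lines = ["| " + " | ".join(map(str, header)) + " |",
                 "|" + "---|" * len(header)]
        lines += ["| " + " | ".join(map(str, r)) + " |" for r in body]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
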