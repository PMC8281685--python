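"""End-to-end orchestration: expression + clinical + gene list in, fitted
signature and survival evaluation out.

Stages: load/validate inputs, restrict to the immune gene list, build the
binary pair profile, frequency-filter, univariate Cox screen, LASSO-Cox fit,
risk scoring, ROC-derived cutoff, risk-group classification, Kaplan-Meier /
log-rank / Cox evaluation, optional TMB association.  Every stage logs its
survivor count; a fixed config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as pio
from .associations import pearson_corr
from .pairs import build_pair_matrix, filter_pairs
from .signature import (
    classify_samples,
    fit_lasso_cox,
    save_signature,
    score_samples,
    univariate_screen,
)
from .survival import (
    fit_cox,
    km_estimate,
    logrank_test,
    select_cutoff,
    time_dependent_roc,
)
from .tmb import DEFAULT_EXOME_MB, compute_tmb

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger("irgpsig")


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs for :func:`run_full_pipeline`.

    ``expression``/``clinical``/``gene_list``/``maf`` may be file paths or
    already-loaded objects (DataFrame / list).
    """

    expression: object = None
    clinical: object = None
    gene_list: object = None
    maf: object = None
    outdir: str | None = None
    seed: int = 0
    min_minor_freq: float = 0.20
    alpha: float = 0.05
    n_folds: int = 10
    horizons: tuple = (365.0, 1095.0, 1825.0)
    cutoff_horizon: float = 1825.0
    duplicate_policy: str = "max"
    time_column: str = "time"
    event_column: str = "event"
    covariates: tuple = ()
    exome_mb: float = DEFAULT_EXOME_MB


def _load_inputs(cfg: PipelineConfig):
    expr = cfg.expression
    if not isinstance(expr, pd.DataFrame):
        expr = pio.read_expression_matrix(expr, duplicate_policy=cfg.duplicate_policy)
    clin = cfg.clinical
    if not isinstance(clin, pd.DataFrame):
        clin = pio.read_clinical(
            clin, time_column=cfg.time_column, event_column=cfg.event_column
        )
    genes = cfg.gene_list
    if not isinstance(genes, (list, tuple)):
        genes = pio.read_gene_list(genes)
    muts = cfg.maf
    if muts is not None and not isinstance(muts, pd.DataFrame):
        muts = pio.read_maf(muts)
    return expr, clin, list(genes), muts


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full signature-construction and evaluation pipeline.

    Returns a result dictionary (model, tables, stage counts); when
    ``cfg.outdir`` is set, all tables, the signature JSON and a run log are
    also written there.  Raises with the stage name when any filtering stage
    leaves nothing to work with.
    """
    expr, clin, genes, muts = _load_inputs(cfg)
    counts: dict[str, int] = {
        "samples_expression": expr.shape[1],
        "samples_clinical": clin.shape[0],
    }

    surv_samples = expr.columns.intersection(clin.index)
    counts["samples_survival"] = len(surv_samples)
    n_unmatched = expr.shape[1] - len(surv_samples)
    if n_unmatched:
        logger.info(
            "%d expression samples lack clinical data: scored but excluded "
            "from survival fits", n_unmatched,
        )
    if len(surv_samples) == 0:
        raise ValueError("alignment stage: no samples shared between expression and clinical data")
    surv = clin.loc[surv_samples]

    try:
        profile = build_pair_matrix(expr, genes)
    except ValueError as exc:
        raise ValueError(f"pairing stage: {exc}") from exc
    counts["pairs_built"] = profile.shape[0]

    try:
        # frequency filter computed on the training cohort only
        filtered, removed = filter_pairs(profile[surv_samples], cfg.min_minor_freq)
    except ValueError as exc:
        raise ValueError(f"frequency-filter stage: {exc}") from exc
    counts["pairs_after_filter"] = filtered.shape[0]

    screen = univariate_screen(filtered, surv, alpha=cfg.alpha)
    candidates = screen.index[screen["candidate"]]
    counts["pairs_after_screen"] = len(candidates)
    if len(candidates) == 0:
        raise ValueError(
            f"screening stage: no pair reached p < {cfg.alpha} in the univariate Cox screen"
        )

    model = fit_lasso_cox(
        filtered.loc[candidates], surv, n_folds=cfg.n_folds, seed=cfg.seed
    )
    counts["pairs_in_signature"] = len(model.pairs)

    scores = score_samples(model, profile.loc[:, expr.columns])
    surv_scores = scores.loc[surv_samples]

    roc_cut = time_dependent_roc(surv_scores, surv, cfg.cutoff_horizon)
    model.cutoff = select_cutoff(roc_cut)
    groups = classify_samples(scores, model.cutoff)
    surv_groups = groups.loc[surv_samples]
    counts["samples_high_risk"] = int((surv_groups == "high").sum())
    counts["samples_low_risk"] = int((surv_groups == "low").sum())
    if counts["samples_high_risk"] == 0 or counts["samples_low_risk"] == 0:
        raise ValueError("classification stage: one risk group is empty")

    chi2, logrank_p = logrank_test(surv, surv_groups)
    aucs = {
        float(h): time_dependent_roc(surv_scores, surv, h).auc for h in cfg.horizons
    }

    surv_cov = surv.copy()
    surv_cov["risk_score"] = surv_scores
    cox_terms = ["risk_score"] + [c for c in cfg.covariates if c in surv.columns]
    cox_uni = pd.concat(
        [fit_cox(surv_cov, [term]) for term in cox_terms]
    )
    cox_multi = fit_cox(surv_cov, cox_terms) if len(cox_terms) > 1 else None

    tmb_table = None
    tmb_assoc = None
    if muts is not None:
        tmb_table = compute_tmb(muts, samples=expr.columns, exome_length_mb=cfg.exome_mb)
        common = surv_scores.index.intersection(tmb_table.index)
        r, p = pearson_corr(surv_scores.loc[common], tmb_table.loc[common, "tmb"])
        tmb_assoc = {"r": r, "p": p, "n": len(common)}

    result = {
        "model": model,
        "profile": profile,
        "screen": screen,
        "scores": scores,
        "groups": groups,
        "logrank": {"chi2": chi2, "p": logrank_p},
        "auc": aucs,
        "cox_univariate": cox_uni,
        "cox_multivariable": cox_multi,
        "tmb": tmb_table,
        "tmb_association": tmb_assoc,
        "counts": counts,
    }

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(profile, outdir / "pair_profile.tsv")
        pio.write_tsv(screen, outdir / "screen.tsv")
        save_signature(model, outdir / "signature.json")
        table = pd.DataFrame({"risk_score": scores, "risk_group": groups})
        table.index.name = "sample"
        pio.write_tsv(table, outdir / "risk_scores.tsv")
        for label in ("high", "low"):
            km = km_estimate(surv[surv_groups == label])
            pio.write_tsv(
                pd.DataFrame(
                    {
                        "time": km.times,
                        "survival": km.survival,
                        "n_at_risk": km.n_at_risk,
                        "n_events": km.n_events,
                    }
                ),
                outdir / f"km_{label}.tsv",
                index=False,
            )
        evaluation = pd.DataFrame(
            [("logrank_chi2", chi2), ("logrank_p", logrank_p)]
            + [(f"auc_{int(h)}", a) for h, a in aucs.items()],
            columns=["metric", "value"],
        )
        pio.write_tsv(evaluation, outdir / "evaluation.tsv", index=False)
        pio.write_tsv(cox_uni, outdir / "cox_univariate.tsv")
        if cox_multi is not None:
            pio.write_tsv(cox_multi, outdir / "cox_multivariable.tsv")
        if tmb_table is not None:
            pio.write_tsv(tmb_table, outdir / "tmb.tsv")
        run_log = {
            "seed": cfg.seed,
            "min_minor_freq": cfg.min_minor_freq,
            "alpha": cfg.alpha,
            "n_folds": cfg.n_folds,
            "horizons": list(cfg.horizons),
            "cutoff_horizon": cfg.cutoff_horizon,
            "lambda": model.lambda_,
            "cutoff": model.cutoff,
            "counts": counts,
            "logrank_p": logrank_p,
            "tmb_association": tmb_assoc,
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    return result
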