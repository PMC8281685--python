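"""Cox-based signature construction, scoring and serialization.

Pipeline stages: univariate Cox screening of binary pair indicators,
L1-penalized (LASSO) Cox fitting with the penalty chosen by K-fold
cross-validated partial-likelihood deviance (lambda.min convention),
linear risk scoring, and cutoff-based risk-group classification.

The package ships a fitted 30-pair bladder-cancer signature
(``blca_irgp30.json``, trained on TCGA-BLCA) loadable via
:func:`load_packaged_signature`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import CoxSeparationError, breslow_loglik, newton_cox
from .pairs import pair_id, split_pair_id

__all__ = [
    "SignatureModel",
    "univariate_screen",
    "fit_lasso_cox",
    "lasso_path",
    "score_samples",
    "classify_samples",
    "save_signature",
    "load_signature",
    "load_packaged_signature",
    "PACKAGED_SIGNATURE",
]

PACKAGED_SIGNATURE = "blca_irgp30.json"


@dataclass
class SignatureModel:
    """A fitted gene-pair risk signature.

    The risk score of a sample is the linear form sum_p beta_p * x_{p,s}
    over the signature's pair indicators (no intercept); samples with score
    strictly above ``cutoff`` are called high-risk.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    cutoff: float | None = None
    lambda_: float | None = None
    provenance: str = ""

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError(
                f"{len(self.pairs)} pairs but {len(self.coefficients)} coefficients"
            )
        if len(self.pairs) == 0:
            raise ValueError("signature must contain at least one pair")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficient in signature")
        unordered = {frozenset(p) for p in self.pairs}
        if len(unordered) != len(self.pairs):
            raise ValueError("duplicate gene pair in signature")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b in self.pairs]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


def univariate_screen(
    profile: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Univariate Cox screen of every pair indicator.

    Fits one proportional-hazards model per pair with the 0/1 indicator as
    sole covariate and reports the hazard ratio, normal-approximation 95% CI
    and two-sided Wald p-value.  Pairs with p < ``alpha`` are flagged as
    candidates.  Pairs that are constant among the survival-complete samples,
    or whose fit separates, are flagged inestimable and excluded from the
    candidate set (not fatal).
    """
    common = profile.columns.intersection(surv.index)
    if len(common) == 0:
        raise ValueError("no samples shared between pair profile and survival data")
    x_all = profile[common].to_numpy(dtype=float)
    sub = surv.loc[common]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    rows = []
    for i, pid in enumerate(profile.index):
        x = x_all[i]
        if x.std() == 0:
            rows.append((pid, np.nan, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        try:
            beta, se, _ = newton_cox(x[:, None], time, event)
        except (CoxSeparationError, RuntimeError):
            rows.append((pid, np.nan, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        b, s = float(beta[0]), float(se[0])
        p = 2 * stats.norm.sf(abs(b / s))
        rows.append(
            (
                pid,
                b,
                np.exp(b),
                np.exp(b - 1.959963984540054 * s),
                np.exp(b + 1.959963984540054 * s),
                p,
                bool(p < alpha),
                True,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["pair", "coef", "hr", "hr_lower", "hr_upper", "p", "candidate", "estimable"],
    ).set_index("pair")
    return out


def _surv_y(surv: pd.DataFrame):
    return Surv.from_arrays(
        surv["event"].to_numpy(dtype=bool), surv["time"].to_numpy(dtype=float)
    )


def lasso_path(
    profile: pd.DataFrame,
    surv: pd.DataFrame,
    lambda_grid=None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.001,
):
    """L1-penalized Cox coefficient path over a descending lambda grid.

    Returns ``(lambdas, coefs)`` with ``coefs`` of shape (n_pairs, n_lambdas).
    Binary pair covariates are not standardized.  The default grid is
    glmnet-style: ``n_lambdas`` log-spaced values from the smallest
    all-zero-coefficient penalty down to ``lambda_min_ratio`` times it.
    """
    common = profile.columns.intersection(surv.index)
    X = profile[common].to_numpy(dtype=float).T
    y = _surv_y(surv.loc[common])
    if lambda_grid is not None:
        lambda_grid = np.asarray(
            [max(l, 1e-9) for l in np.atleast_1d(lambda_grid)], dtype=float
        )
        lambda_grid = np.sort(lambda_grid)[::-1]
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambda_grid,
                                       normalize=False, tol=1e-9)
    else:
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            n_alphas=n_lambdas,
            alpha_min_ratio=lambda_min_ratio,
            normalize=False,
            tol=1e-9,
        )
    model.fit(X, y)
    return np.asarray(model.alphas_, dtype=float), np.asarray(model.coef_, dtype=float)


def _path_coefs_at(fit_lambdas, fit_coefs, lambdas):
    """Column of a fitted path at each requested lambda (nearest grid point)."""
    cols = np.empty((fit_coefs.shape[0], len(lambdas)))
    for j, lam in enumerate(lambdas):
        cols[:, j] = fit_coefs[:, int(np.argmin(np.abs(fit_lambdas - lam)))]
    return cols


def fit_lasso_cox(
    profile: pd.DataFrame,
    surv: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    lambda_grid=None,
) -> SignatureModel:
    """Fit a LASSO-Cox signature with cross-validated penalty selection.

    The penalty is chosen as the grid value minimizing the mean K-fold
    cross-validated partial-likelihood deviance
    ``-2 * [pl(all; beta_-k) - pl(train_k; beta_-k)]`` (the lambda.min
    convention), folds stratified by event status and derived
    deterministically from ``seed``; the model is then refit on all samples
    at the chosen penalty and pairs with exactly-zero coefficient are
    dropped.  The returned model's ``cutoff`` is unset; derive one with
    :func:`irgpsig.survival.select_cutoff`.
    """
    common = profile.columns.intersection(surv.index)
    if len(common) == 0:
        raise ValueError("no samples shared between pair profile and survival data")
    sub = surv.loc[common]
    events = int(sub["event"].sum())
    if events == 0:
        raise ValueError("no events in survival data; cannot fit")
    if events < n_folds:
        raise ValueError(f"{events} events < {n_folds} folds")

    lambdas, full_coefs = lasso_path(profile[common], sub, lambda_grid=lambda_grid)

    if len(lambdas) == 1:
        warnings.warn("single-lambda grid: skipping cross-validation")
        chosen_idx = 0
        cv_dev = np.array([np.nan])
    else:
        X = profile[common].to_numpy(dtype=float).T
        time = sub["time"].to_numpy(dtype=float)
        event = sub["event"].to_numpy(dtype=int)
        y = _surv_y(sub)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        dev = np.zeros((n_folds, len(lambdas)))
        for k, (tr, _) in enumerate(skf.split(X, event)):
            fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambdas,
                                          normalize=False, tol=1e-9)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fold.fit(X[tr], y[tr])
            coefs = _path_coefs_at(
                np.asarray(fold.alphas_), np.asarray(fold.coef_), lambdas
            )
            for j in range(len(lambdas)):
                beta = coefs[:, j]
                pl_all = breslow_loglik(beta, X, time, event)
                pl_tr = breslow_loglik(beta, X[tr], time[tr], event[tr])
                dev[k, j] = -2.0 * (pl_all - pl_tr)
        cv_dev = dev.mean(axis=0)
        chosen_idx = int(np.argmin(cv_dev))

    chosen = float(lambdas[chosen_idx])
    beta = full_coefs[:, chosen_idx]
    nonzero = np.flatnonzero(beta != 0.0)
    if len(nonzero) == 0:
        raise ValueError("empty signature: all coefficients shrunk to zero")
    pairs = [split_pair_id(profile.index[i]) for i in nonzero]
    return SignatureModel(
        pairs=pairs,
        coefficients=beta[nonzero],
        cutoff=None,
        lambda_=chosen,
        provenance=(
            f"LASSO-Cox fit: n={len(common)} samples, {events} events, "
            f"{profile.shape[0]} candidate pairs, {n_folds}-fold CV (seed {seed}), "
            f"lambda.min={chosen:.8g}"
        ),
    )


def score_samples(model: SignatureModel, data: pd.DataFrame) -> pd.Series:
    """Per-sample risk score ``sum_p beta_p * x_{p,s}`` (no intercept).

    ``data`` may be a binary pair profile containing every model pair, or a
    raw genes x samples expression matrix, in which case each pair indicator
    is built on the fly from the strict within-sample ordering.
    """
    pids = model.pair_ids
    if all(p in data.index for p in pids):
        x = data.loc[pids].to_numpy(dtype=float)
    else:
        missing = sorted(
            {g for pair in model.pairs for g in pair if g not in data.index}
        )
        if missing:
            raise ValueError(f"genes required by the signature are missing: {missing}")
        x = np.stack(
            [
                (data.loc[a].to_numpy(float) > data.loc[b].to_numpy(float)).astype(float)
                for a, b in model.pairs
            ]
        )
    scores = model.coefficients @ x
    return pd.Series(scores, index=data.columns, name="risk_score")


def classify_samples(scores: pd.Series, cutoff: float) -> pd.Series:
    """Risk-group labels: ``"high"`` iff score > cutoff (strict), else ``"low"``."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return pd.Series(
        np.where(np.asarray(scores, dtype=float) > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )


def save_signature(model: SignatureModel, path) -> None:
    """Serialize a signature to JSON (exact round trip)."""
    payload = {
        "pairs": [
            {"gene_a": a, "gene_b": b, "coefficient": float(c)}
            for (a, b), c in zip(model.pairs, model.coefficients)
        ],
        "cutoff": model.cutoff,
        "lambda": model.lambda_,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _model_from_payload(payload: dict) -> SignatureModel:
    try:
        pairs = [(p["gene_a"], p["gene_b"]) for p in payload["pairs"]]
        coefs = [p["coefficient"] for p in payload["pairs"]]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed signature file: {exc}") from exc
    return SignatureModel(
        pairs=pairs,
        coefficients=np.asarray(coefs, dtype=float),
        cutoff=payload.get("cutoff"),
        lambda_=payload.get("lambda"),
        provenance=payload.get("provenance", ""),
    )


def load_signature(path) -> SignatureModel:
    """Load and validate a signature JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    return _model_from_payload(payload)


def load_packaged_signature() -> SignatureModel:
    """The shipped 30-pair TCGA-BLCA bladder-cancer signature (cutoff 0.538)."""
    ref = resources.files("irgpsig").joinpath("data", PACKAGED_SIGNATURE)
    return _model_from_payload(json.loads(ref.read_text()))
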