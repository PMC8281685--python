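"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what the signature method needs from real tumor
cohorts: per-gene log-normal expression, survival driven by a Cox
proportional-hazards model whose covariates are within-sample gene-pair
orientation indicators (exponential baseline hazard, independent uniform
right-censoring calibrated to a target censoring fraction), and per-sample
somatic mutation counts whose log-mean is linear in the true risk so that
TMB correlates with the risk score at a controllable level.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .pairs import build_pair_matrix, pair_id

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "apply_monotone_distortion",
    "simulate_mutations",
    "make_candidate_profile",
    "DISTORTION_FAMILIES",
]

DISTORTION_FAMILIES = (
    "identity",
    "affine-positive",
    "log1p",
    "power",
    "rank-preserving-random",
)


@dataclass
class SimulationConfig:
    """Cohort-generator settings.

    Defaults describe the reference evaluation cohort: 300 tumors, 90 genes,
    5 gene-disjoint signal pairs with log-hazard effects of magnitude 0.8
    and alternating sign, a baseline hazard of 1e-3 per day (median survival
    just under two years at zero risk), and ~30% censoring.
    """

    n_samples: int = 300
    n_genes: int = 90
    n_signal_pairs: int = 5
    betas: tuple = (0.8, -0.8, 0.8, -0.8, 0.8)
    baseline_hazard: float = 1e-3
    censoring_fraction: float = 0.30
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.n_signal_pairs > self.n_genes // 2:
            raise ValueError("too many signal pairs for gene-disjoint selection")
        if len(self.betas) != self.n_signal_pairs:
            raise ValueError(
                f"{len(self.betas)} betas for {self.n_signal_pairs} signal pairs"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0, 1)")


def _uniform_censoring_max(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting a target censoring
    fraction for exponential event times with per-subject ``rates``.

    P(censored | rate L) = (1 - exp(-L c)) / (L c); solved for c by root
    finding on the cohort mean.
    """

    def frac(c):
        x = rates * c
        return float(np.mean(-np.expm1(-x) / x)) - target

    lo, hi = 1e-9, 1.0
    while frac(hi) > 0 and hi < 1e12:
        hi *= 10.0
    return float(optimize.brentq(frac, lo, hi, xtol=1e-10, rtol=1e-12))


def _select_disjoint_pairs(expr: pd.DataFrame, genes, k: int, rng,
                           freq_range=(0.3, 0.7)):
    """Up to ``k`` gene-disjoint ordered pairs whose orientation frequency
    lies in ``freq_range``, chosen greedily in shuffled order."""
    genes = list(genes)
    values = expr.loc[genes].to_numpy(dtype=float)
    n = expr.shape[1]
    ia, ib = np.triu_indices(len(genes), k=1)
    freq = (values[ia] > values[ib]).sum(axis=1) / n
    ok = np.flatnonzero((freq >= freq_range[0]) & (freq <= freq_range[1]))
    rng.shuffle(ok)
    chosen, used = [], set()
    for idx in ok:
        a, b = genes[ia[idx]], genes[ib[idx]]
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) == k:
            break
    return chosen


def simulate_cohort(cfg: SimulationConfig):
    """Generate ``(expression, survival, truth)`` for one synthetic cohort.

    Expression is log-normal per gene (gene-specific location, shared scale
    ``noise_scale``).  Signal pairs are drawn gene-disjoint among pairs whose
    orientation frequency lands in [0.3, 0.7] (so they are informative and
    survive the minor-frequency filter); survival times follow
    h(t|s) = h0 * exp(sum_p beta_p x_{p,s}) with an exponential baseline,
    censored by an independent Uniform(0, c_max) with c_max calibrated to
    the target censoring fraction.

    The truth record holds the signal pair IDs, their effects, each sample's
    linear predictor, and the censoring bound.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    mu = rng.normal(0.0, 1.0, size=cfg.n_genes)
    log_expr = mu[:, None] + cfg.noise_scale * rng.normal(
        size=(cfg.n_genes, cfg.n_samples)
    )
    expr = pd.DataFrame(np.exp(log_expr), index=pd.Index(genes, name="gene"),
                        columns=samples)

    signal = _select_disjoint_pairs(expr, genes, cfg.n_signal_pairs, rng)
    if len(signal) < cfg.n_signal_pairs:
        raise ValueError(
            "degenerate configuration: could not find enough informative "
            f"gene-disjoint signal pairs (found {len(signal)})"
        )
    x = np.stack(
        [
            (expr.loc[a].to_numpy(float) > expr.loc[b].to_numpy(float)).astype(float)
            for a, b in signal
        ]
    )
    betas = np.asarray(cfg.betas, dtype=float)
    eta = betas @ x
    rates = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(scale=1.0 / rates)
    if cfg.censoring_fraction > 0:
        c_max = _uniform_censoring_max(rates, cfg.censoring_fraction)
        t_cens = rng.uniform(0.0, c_max, size=cfg.n_samples)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        c_max = np.inf
        time = t_event
        event = np.ones(cfg.n_samples, dtype=int)
    surv = pd.DataFrame(
        {"time": np.maximum(time, 1e-9), "event": event},
        index=pd.Index(samples, name="sample"),
    )
    truth = {
        "signal_pairs": [pair_id(a, b) for a, b in signal],
        "betas": betas.tolist(),
        "eta": pd.Series(eta, index=samples, name="eta"),
        "baseline_hazard": cfg.baseline_hazard,
        "censoring_max": float(c_max),
        "seed": cfg.seed,
    }
    return expr, surv, truth


def apply_monotone_distortion(expr: pd.DataFrame, family: str, seed: int = 0):
    """Distort expression with a strictly increasing map, independently per
    sample.

    Families: ``identity``; ``affine-positive`` (a*x + b, a > 0); ``log1p``;
    ``power`` (x^gamma, gamma > 0, nonnegative data); and
    ``rank-preserving-random`` (a random strictly increasing piecewise map of
    each sample's observed values).  Within every sample the ordering of gene
    values is preserved exactly, so any rank-based transform of the output
    equals that of the input.
    """
    if family not in DISTORTION_FAMILIES:
        raise ValueError(
            f"unknown distortion family {family!r}; choose from {DISTORTION_FAMILIES}"
        )
    if family == "identity":
        return expr.copy()
    rng = np.random.default_rng(seed)
    out = expr.to_numpy(dtype=float).copy()
    n_samples = out.shape[1]
    if family == "affine-positive":
        a = rng.uniform(0.5, 3.0, size=n_samples)
        b = rng.uniform(0.0, 5.0, size=n_samples)
        out = out * a + b
    elif family == "log1p":
        if (out < 0).any():
            raise ValueError("log1p distortion requires nonnegative expression")
        out = np.log1p(out)
    elif family == "power":
        if (out < 0).any():
            raise ValueError("power distortion requires nonnegative expression")
        gamma = rng.uniform(0.3, 2.5, size=n_samples)
        out = out ** gamma
    elif family == "rank-preserving-random":
        for j in range(n_samples):
            col = out[:, j]
            uniq, inverse = np.unique(col, return_inverse=True)
            new_vals = np.cumsum(rng.uniform(0.1, 1.0, size=len(uniq)))
            out[:, j] = new_vals[inverse]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _poisson_corr_slope(target: float, mean_count: float) -> float:
    """Slope b such that corr(N, z) hits ``target`` for N | z ~
    Poisson(exp(a + b z)), z ~ N(0, 1), E[N] = mean_count."""
    m = mean_count

    def corr(b):
        var = m + m * m * np.expm1(b * b)
        return b * m / np.sqrt(var)

    t = abs(target)
    if t < 1e-12:
        return 0.0
    hi = 1e-3
    while corr(hi) < t:
        hi *= 1.5
        if hi > 10:
            raise ValueError(f"target correlation {target} unreachable at mean {m}")
    b = optimize.brentq(lambda b: corr(b) - t, 1e-12, hi, xtol=1e-12)
    return float(np.sign(target) * b)


_CLASS_PROBS = {
    "Missense_Mutation": 0.60,
    "Silent": 0.25,
    "Nonsense_Mutation": 0.05,
    "Splice_Site": 0.05,
    "Frame_Shift_Del": 0.025,
    "Frame_Shift_Ins": 0.025,
}


def simulate_mutations(
    truth: dict,
    target_corr: float = -0.11,
    mean_count: float = 150.0,
    seed: int = 0,
) -> pd.DataFrame:
    """MAF-lite somatic-variant records whose per-sample counts correlate
    with the cohort's true risk at approximately ``target_corr``.

    Counts are Poisson with log-mean linear in the standardized true linear
    predictor; the slope is solved so the marginal count-risk correlation
    matches the target (negative by default: higher mutation burden in
    lower-risk tumors).  Gene symbols, classes and positions are
    placeholders drawn from a fixed coding-class mix.
    """
    if not abs(target_corr) < 1:
        raise ValueError("|target_corr| must be < 1")
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    rng = np.random.default_rng(seed)
    eta = np.asarray(truth["eta"], dtype=float)
    samples = list(truth["eta"].index)
    z = (eta - eta.mean()) / eta.std() if eta.std() > 0 else np.zeros_like(eta)
    b = _poisson_corr_slope(target_corr, mean_count)
    a = np.log(mean_count) - b * b / 2.0
    counts = rng.poisson(np.exp(a + b * z))
    classes = list(_CLASS_PROBS)
    probs = np.asarray(list(_CLASS_PROBS.values()))
    records = []
    for sid, c in zip(samples, counts):
        if c == 0:
            continue
        genes = rng.integers(1, 20000, size=c)
        cls = rng.choice(classes, size=c, p=probs)
        pos = rng.integers(1, 250_000_000, size=c)
        records.append(
            pd.DataFrame(
                {
                    "sample": sid,
                    "gene": [f"GENE{g}" for g in genes],
                    "variant_class": cls,
                    "position": pos,
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["sample", "gene", "variant_class", "position"])
    return pd.concat(records, ignore_index=True)


def make_candidate_profile(
    expr: pd.DataFrame, truth: dict, n_pairs: int = 40, seed: int = 0
) -> pd.DataFrame:
    """Candidate pair profile for signature-recovery experiments: the
    cohort's true signal pairs plus gene-disjoint null pairs, ``n_pairs``
    rows in total.

    Null pairs are drawn from genes unused by the signal pairs, with
    orientation frequency in [0.3, 0.7], and share no gene with each other
    or with the signal pairs, so their indicators are independent of the
    hazard by construction.
    """
    rng = np.random.default_rng(seed)
    signal_ids = list(truth["signal_pairs"])
    used = {g for pid in signal_ids for g in pid.split("|")}
    n_null = n_pairs - len(signal_ids)
    if n_null < 0:
        raise ValueError("n_pairs smaller than the number of signal pairs")
    free = [g for g in expr.index if g not in used]
    null_pairs = _select_disjoint_pairs(expr, free, n_null, rng)
    if len(null_pairs) < n_null:
        raise ValueError(
            f"only {len(null_pairs)} gene-disjoint null pairs available; "
            "increase n_genes"
        )
    ordered_genes: list[str] = []
    for pid in signal_ids:
        ordered_genes.extend(pid.split("|"))
    for a, b in null_pairs:
        ordered_genes.extend((a, b))
    profile = build_pair_matrix(expr, ordered_genes)
    wanted = signal_ids + [pair_id(a, b) for a, b in null_pairs]
    return profile.loc[wanted]
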