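"""Synthetic questionnaire cohorts with known ground-truth network structure.

The generative model is a latent Gaussian copula: each participant has a
16-dimensional standard-normal latent vector for the GAD-7/PHQ-9 symptoms,
drawn from the correlation matrix implied by a planted partial-correlation
network, and each latent score is cut into ordered Likert categories by
fixed per-item thresholds.  This is the model under which rank/polychoric
network estimation is consistent, so parameter-recovery tests against the
planted network are meaningful.

CTQ-SF trauma items are generated from a separate one-general-plus-subscale
factor model, independent of the symptom network; a per-subscale severity
parameter sets (approximately) the probability that the subscale's
moderate-severity cut-off is exceeded, solved deterministically by
Gauss–Hermite quadrature.  Demographic covariates are drawn per sex from
category probabilities defaulting to the composition of the emulated survey.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .reference import (
    DEMOGRAPHIC_COUNTS,
    GAD_ITEM_MEANS,
    PHQ_ITEM_MEANS,
)
from .scales import ctq_sf

__all__ = [
    "ANXIETY_NODES",
    "DEPRESSION_NODES",
    "NETWORK_NODES",
    "STRONG_EDGES",
    "SyntheticSpec",
    "default_true_partial",
    "default_female_partial",
    "default_spec",
    "default_thresholds",
    "generate_cohort",
    "inject_missing",
    "node_to_column",
    "partial_to_latent_correlation",
    "set_edge",
    "thresholds_from_mean",
    "write_cohort",
]

ANXIETY_NODES = tuple(f"GAD{i}" for i in range(1, 8))
DEPRESSION_NODES = tuple(f"PHQ{i}" for i in range(1, 10))
NETWORK_NODES = ANXIETY_NODES + DEPRESSION_NODES

#: Planted strong edges: the three strongest within-instrument associations
#: plus the strongest anxiety–depression bridge of the emulated study.
STRONG_EDGES = (
    ("GAD2", "GAD3"),
    ("PHQ1", "PHQ2"),
    ("PHQ3", "PHQ4"),
    ("GAD5", "PHQ8"),
)

_CTQ_SUBSCALES = ctq_sf().subscales
_CTQ_ITEMS = ctq_sf().items

# CTQ factor loadings: shared trauma factor (induces comorbid abuse),
# subscale factor, unique noise; variances sum to 1.
_CTQ_GENERAL_LOADING = 0.35
_CTQ_SUBSCALE_LOADING = 0.60
# Base thresholds on the latent scale for the 5-category CTQ items; the
# per-subscale severity shift moves the latent mean toward them.
_CTQ_BASE_THRESHOLDS = np.array([1.0, 1.9, 2.5, 3.1])


def node_to_column(node: str) -> str:
    """Map a network node label (GAD1..PHQ9) to its CSV column (GAD01..)."""
    prefix = node[:3]
    return f"{prefix}{int(node[3:]):02d}"


def partial_to_latent_correlation(true_partial: np.ndarray) -> np.ndarray:
    """Correlation matrix whose partial correlations equal ``true_partial``.

    Builds the standardized precision matrix (unit diagonal, off-diagonal
    minus the partials), inverts it, and rescales to unit variance.  Partial
    correlations are invariant to that rescaling, so the round trip is exact.

    Raises
    ------
    ValueError
        If the matrix is not symmetric/zero-diagonal/in (-1, 1), or if the
        implied precision matrix is not positive definite (the smallest
        eigenvalue is reported).
    """
    P = np.asarray(true_partial, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("true_partial must be square")
    if not np.allclose(P, P.T, atol=1e-10):
        raise ValueError("true_partial must be symmetric")
    if np.any(np.abs(np.diag(P)) > 1e-12):
        raise ValueError("true_partial must have a zero diagonal")
    if np.any(np.abs(P) >= 1.0):
        raise ValueError("partial correlations must lie in (-1, 1)")
    K = np.eye(P.shape[0]) - P
    eigvals = np.linalg.eigvalsh(K)
    if eigvals[0] <= 0:
        raise ValueError(
            "implied precision matrix is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.6g}); reduce edge weights"
        )
    Sigma = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(Sigma))
    R = Sigma * np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def set_edge(P: np.ndarray, nodes, i: str, j: str, w: float) -> np.ndarray:
    """Return a copy of partial matrix ``P`` with edge (i, j) set to ``w``."""
    P = np.array(P, dtype=np.float64, copy=True)
    nodes = list(nodes)
    a, b = nodes.index(i), nodes.index(j)
    P[a, b] = P[b, a] = w
    return P


def default_true_partial() -> np.ndarray:
    """Default planted 16-node partial-correlation network.

    A chain within each instrument (GAD1–…–GAD7, PHQ1–…–PHQ9) with
    staggered weights in 0.10–0.19, the three strong within-instrument
    edges of :data:`STRONG_EDGES` at 0.26–0.30, and the GAD5–PHQ8 bridge
    at 0.22.  The weights are deliberately all distinct so that the
    planted edge ranking is strict and rank-based recovery checks are
    sharp (a tied ranking bounds the achievable rank correlation well
    below 1 even for a perfect estimator).
    """
    p = len(NETWORK_NODES)
    P = np.zeros((p, p))
    chain_weights = iter(
        [0.10, 0.13, 0.16, 0.19, 0.11, 0.14,  # GAD chain (6 edges)
         0.17, 0.12, 0.15, 0.18, 0.105, 0.135, 0.165, 0.185]  # PHQ chain (8)
    )
    for block in (ANXIETY_NODES, DEPRESSION_NODES):
        for a, b in zip(block[:-1], block[1:]):
            P = set_edge(P, NETWORK_NODES, a, b, next(chain_weights))
    for (a, b), w in zip(STRONG_EDGES[:3], (0.30, 0.28, 0.26)):
        P = set_edge(P, NETWORK_NODES, a, b, w)
    P = set_edge(P, NETWORK_NODES, *STRONG_EDGES[3], 0.22)
    partial_to_latent_correlation(P)  # validates positive definiteness
    return P


def default_female_partial(delta: float = 0.20) -> np.ndarray:
    """Female-stratum variant of the default network.

    Mirrors the sex differences of the emulated study qualitatively: the
    guilt–suicide edge (PHQ6–PHQ9) is present only in the male/pooled
    network, while control worry–suicide (GAD2–PHQ9) appears only in the
    female network, each at ``delta``.
    """
    P = default_true_partial()
    male = set_edge(P, NETWORK_NODES, "PHQ6", "PHQ9", delta)  # noqa: F841
    female = set_edge(P, NETWORK_NODES, "GAD2", "PHQ9", delta)
    partial_to_latent_correlation(female)
    return female


def thresholds_from_mean(mean: float, n_categories: int) -> np.ndarray:
    """Latent-normal thresholds giving a target mean for scores 0..K-1.

    Category probabilities follow a geometric decay p_k ∝ q^k with q solved
    by bisection so that the discretized mean matches ``mean`` — the
    right-skewed shape typical of symptom screeners.  Returns K-1 strictly
    increasing thresholds on the standard-normal scale.
    """
    K = n_categories
    if not (0.0 < mean < K - 1):
        raise ValueError(f"mean must be in (0, {K - 1})")
    k = np.arange(K)

    def mean_at(log_q: float) -> float:
        w = np.exp(k * log_q)
        return float((k * w).sum() / w.sum())

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < mean:
            lo = mid
        else:
            hi = mid
    w = np.exp(k * 0.5 * (lo + hi))
    probs = w / w.sum()
    return ndtri(np.cumsum(probs)[:-1])


def _default_covariate_model() -> dict:
    model: dict = {}
    for var, spec in DEMOGRAPHIC_COUNTS.items():
        male = np.asarray(spec["male"], dtype=float)
        female = np.asarray(spec["female"], dtype=float)
        model[var] = {
            "labels": list(spec["labels"]),
            "male": (male / male.sum()).tolist(),
            "female": (female / female.sum()).tolist(),
        }
    return model


def default_thresholds() -> dict[str, np.ndarray]:
    """Per-item thresholds for the 16 symptom items, calibrated so that the
    default marginal means approximate the emulated study's item means."""
    thresholds = {}
    for node, m in zip(ANXIETY_NODES, GAD_ITEM_MEANS):
        thresholds[node] = thresholds_from_mean(m, 4)
    for node, m in zip(DEPRESSION_NODES, PHQ_ITEM_MEANS):
        thresholds[node] = thresholds_from_mean(m, 4)
    return thresholds


@dataclass
class SyntheticSpec:
    """Full description of one synthetic cohort.

    Parameters
    ----------
    n_participants
        Number of rows to generate (>= 2).
    true_partial
        Planted 16x16 partial-correlation matrix over the symptom nodes.
    thresholds
        Node -> strictly increasing latent cut-points (3 values for the
        4-category symptom items).
    sex_effect
        Optional partial matrix used for the female stratum; ``None`` means
        both sexes share ``true_partial``.
    ctq_marginals
        Subscale -> target probability of exceeding the subscale cut-off.
    covariate_model
        Variable -> {labels, male probs, female probs}.
    p_female
        Probability a participant is female.
    female_latent_shift
        Mean shift added to female symptom latents (severity difference).
    seed
        Integer seed; generation is deterministic given the spec.
    """

    n_participants: int
    true_partial: np.ndarray = field(default_factory=default_true_partial)
    thresholds: dict[str, np.ndarray] = field(default_factory=default_thresholds)
    sex_effect: np.ndarray | None = None
    ctq_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "sexual_abuse": 0.036,
            "emotional_abuse": 0.040,
            "physical_abuse": 0.030,
            "emotional_neglect": 0.060,
            "physical_neglect": 0.050,
        }
    )
    covariate_model: dict = field(default_factory=_default_covariate_model)
    p_female: float = 0.5
    female_latent_shift: float = 0.20
    age_mean: float = 19.6
    age_sd: float = 1.74
    include_ctq: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")
        self.true_partial = np.asarray(self.true_partial, dtype=np.float64)
        partial_to_latent_correlation(self.true_partial)
        if self.sex_effect is not None:
            self.sex_effect = np.asarray(self.sex_effect, dtype=np.float64)
            partial_to_latent_correlation(self.sex_effect)
        for node, t in self.thresholds.items():
            t = np.asarray(t, dtype=np.float64)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds for {node} must be strictly increasing")
            self.thresholds[node] = t

    def ground_truth(self) -> dict:
        """JSON-serializable record of the planted structure."""
        return {
            "nodes": list(NETWORK_NODES),
            "true_partial": self.true_partial.tolist(),
            "sex_effect": None
            if self.sex_effect is None
            else self.sex_effect.tolist(),
            "thresholds": {k: v.tolist() for k, v in self.thresholds.items()},
            "ctq_marginals": dict(self.ctq_marginals),
            "seed": int(self.seed),
        }


def default_spec(n: int, seed: int = 0, **kwargs) -> SyntheticSpec:
    return SyntheticSpec(n_participants=n, seed=seed, **kwargs)


@lru_cache(maxsize=64)
def _ctq_severity_shift(target: float, cutoff: int, n_items: int = 5) -> float:
    """Latent mean shift giving subscale P(score >= cutoff) ~= target.

    The subscale items share a general and a subscale factor; conditional on
    those, items are independent, so the subscale-score distribution is a
    5-fold convolution integrated over a 2-D Gauss–Hermite grid.  The
    exceedance probability is monotone in the shift; solved by bisection.
    """
    a, b = _CTQ_GENERAL_LOADING, _CTQ_SUBSCALE_LOADING
    c = np.sqrt(1.0 - a * a - b * b)
    nodes, weights = np.polynomial.hermite_e.hermegauss(24)
    wnorm = weights / np.sqrt(2.0 * np.pi)
    g, u = np.meshgrid(nodes, nodes, indexing="ij")
    wq = np.outer(wnorm, wnorm).ravel()
    base_loc = (a * g + b * u).ravel()  # (576,)
    n_cat = _CTQ_BASE_THRESHOLDS.size + 1

    def exceedance(delta: float) -> float:
        loc = base_loc + delta
        upper = ndtr((_CTQ_BASE_THRESHOLDS[None, :] - loc[:, None]) / c)
        cum = np.concatenate(
            [np.zeros((loc.size, 1)), upper, np.ones((loc.size, 1))], axis=1
        )
        probs = np.diff(cum, axis=1)  # (576, 5) per-item category probs
        dist = np.ones((loc.size, 1))
        for _ in range(n_items):
            new = np.zeros((loc.size, dist.shape[1] + n_cat - 1))
            for j in range(n_cat):
                new[:, j : j + dist.shape[1]] += probs[:, j : j + 1] * dist
            dist = new
        # scores run n_items..5*n_items; index by score - n_items
        return float(wq @ dist[:, cutoff - n_items :].sum(axis=1))

    lo, hi = -6.0, 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if exceedance(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _discretize(z: np.ndarray, thresholds: np.ndarray, offset: int = 0) -> np.ndarray:
    return np.searchsorted(thresholds, z, side="left").astype(np.int64) + offset


def generate_cohort(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw one cohort table from a :class:`SyntheticSpec`.

    Returns a wide DataFrame with ``participant_id``, demographics
    (``sex``, ``residence``, ``ethnicity``, ``family_type``, ``income_band``,
    ``only_child``, ``age``), CTQ01..CTQ28 (1-5), GAD01..GAD07 and
    PHQ01..PHQ09 (0-3).  Deterministic under a fixed spec (same seed twice
    gives identical tables); no missing values.
    """
    n = spec.n_participants
    rng = np.random.default_rng(spec.seed)
    female = rng.random(n) < spec.p_female
    sex = np.where(female, "female", "male")

    data: dict[str, np.ndarray] = {
        "participant_id": np.arange(1, n + 1),
        "sex": sex,
    }
    for var, model in spec.covariate_model.items():
        labels = np.asarray(model["labels"], dtype=object)
        out = np.empty(n, dtype=object)
        for stratum, probs in (("male", model["male"]), ("female", model["female"])):
            mask = sex == stratum
            if mask.any():
                out[mask] = rng.choice(labels, size=int(mask.sum()), p=probs)
        data[var] = out
    age = np.round(rng.normal(spec.age_mean, spec.age_sd, size=n)).astype(np.int64)
    data["age"] = np.clip(age, 16, 60)

    if spec.include_ctq:
        g = rng.standard_normal(n)
        c = np.sqrt(1.0 - _CTQ_GENERAL_LOADING**2 - _CTQ_SUBSCALE_LOADING**2)
        for sub, items in _CTQ_SUBSCALES.items():
            delta = _ctq_severity_shift(
                spec.ctq_marginals.get(sub, 0.05), ctq_sf().cutoffs[sub]
            )
            u = rng.standard_normal(n)
            for item in items:
                z = (
                    _CTQ_GENERAL_LOADING * g
                    + _CTQ_SUBSCALE_LOADING * u
                    + c * rng.standard_normal(n)
                    + delta
                )
                data[item] = _discretize(z, _CTQ_BASE_THRESHOLDS, offset=1)
        # minimization/denial items (unscored): mostly floor responses
        scored = {i for its in _CTQ_SUBSCALES.values() for i in its}
        for item in (i for i in _CTQ_ITEMS if i not in scored):
            z = rng.standard_normal(n)
            data[item] = _discretize(z, _CTQ_BASE_THRESHOLDS, offset=1)

    R_male = partial_to_latent_correlation(spec.true_partial)
    R_female = (
        R_male
        if spec.sex_effect is None
        else partial_to_latent_correlation(spec.sex_effect)
    )
    L_male = np.linalg.cholesky(R_male)
    L_female = np.linalg.cholesky(R_female)
    z = rng.standard_normal((n, len(NETWORK_NODES)))
    latents = np.empty_like(z)
    m = ~female
    # the sex severity difference is centered so pooled marginals stay on
    # the calibrated thresholds
    latents[m] = z[m] @ L_male.T - 0.5 * spec.female_latent_shift
    latents[female] = z[female] @ L_female.T + 0.5 * spec.female_latent_shift
    for j, node in enumerate(NETWORK_NODES):
        data[node_to_column(node)] = _discretize(latents[:, j], spec.thresholds[node])

    columns = (
        ["participant_id", "sex"]
        + list(spec.covariate_model)
        + ["age"]
        + (list(_CTQ_ITEMS) if spec.include_ctq else [])
        + [node_to_column(nd) for nd in NETWORK_NODES]
    )
    return pd.DataFrame(data)[columns]


def inject_missing(
    table: pd.DataFrame, rate: float, seed: int, columns: list[str] | None = None
) -> pd.DataFrame:
    """Set a fraction of item cells to NA (off by default in the pipeline)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = table.copy()
    cols = columns or [c for c in out.columns if c[:3] in {"CTQ", "GAD", "PHQ"}]
    for c in cols:
        mask = rng.random(len(out)) < rate
        out.loc[mask, c] = pd.NA
    return out


def write_cohort(spec: SyntheticSpec, csv_path: str | Path, truth_path: str | Path | None = None) -> pd.DataFrame:
    """Generate, write the cohort CSV and (optionally) ground-truth JSON."""
    table = generate_cohort(spec)
    table.to_csv(csv_path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(spec.ground_truth(), indent=2))
    return table
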