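"""Outcome discrimination: feature fusion, NIPALS PLS-DA, and the
small-sample association tests.

Clinical variables, the LSC gating readout, and the zebrafish behavioral
summary are fused into a standardized patient-by-feature matrix with the
binary response y = 1 for successful morphological remission after
induction chemotherapy and y = 0 otherwise (patients with unknown
remission are excluded from supervised fits).

The discrimination layer is PLS1 fitted by NIPALS on the 0/1 response
(the classical PLS-DA construction): per component the weight vector is
w ∝ Xᵀy (unit norm), scores t = Xw, x-loading p = Xᵀt/(tᵀt), y-loading
q = yᵀt/(tᵀt), after which X and y are deflated.  Explained Y-variance
after k components is 1 − SS(y residual)/SS(y initial).  Feature
influence is reported both as |w₁| and as VIP scores.

The association-test toolbox mirrors what a small pilot cohort supports:
an exact two-sided Wilcoxon rank-sum test (full enumeration over rank
assignments, midranks on ties), the Yates continuity-corrected
chi-square for 2x2 tables, and a univariate logistic fit by IRLS with
McFadden / Cox-Snell / Nagelkerke pseudo-R² variants and a
likelihood-ratio p-value.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .atlas import REGION_NAMES
from .behavior import BehaviorSummary
from .lsc_flow import GateResult

# Documented integer codes for categorical features.
RISK_CODES = {"favorable": 0, "standard": 0, "favorable/standard": 0,
              "intermediate": 1, "adverse": 2}
PATTERN_CODES = {"rare": 0, "numerous": 1}
DISPERSION_CODES = {"random": 0, "clumped": 1}


@dataclass
class ClinicalRecord:
    """One diagnostic record: subtype, blood counts, cytogenetics, risk
    stratification and the remission outcome after induction."""

    sample_id: str
    age_band: str  # e.g. "40-45"
    subtype: str  # FAB/WHO label
    pct_blasts: float
    platelets: float  # K/ul
    leukocytes: float  # K/ul
    cytogenetics: str
    risk: str  # favorable/standard | intermediate | adverse
    remission: str  # yes | no | NA


def age_band_midpoint(band: str) -> float:
    nums = [float(t) for t in re.findall(r"\d+\.?\d*", band)]
    if not nums:
        raise ValueError(f"cannot parse age band {band!r}")
    return float(np.mean(nums))


@dataclass
class FeatureMatrix:
    """Standardized patient-by-feature matrix with the remission label."""

    X: np.ndarray  # standardized (mean 0, sd 1 per column)
    y: np.ndarray  # 1 = successful remission, 0 = unsuccessful
    feature_names: list[str]
    sample_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)


def build_feature_matrix(
    clinical: list[ClinicalRecord],
    gates: dict[str, GateResult],
    behavior: dict[str, BehaviorSummary],
) -> FeatureMatrix:
    """Fuse the three evidence layers into one standardized matrix.

    One row per patient with a known remission outcome; categorical
    fields are integer-coded by the documented maps and age enters as
    the band midpoint.  Columns that are constant across patients are
    dropped with a warning; sample-id mismatches are an error naming
    the orphans.
    """
    usable = [c for c in clinical if c.remission.lower() in ("yes", "no")]
    if not usable:
        raise ValueError("no patients with a known remission outcome")
    orphans = [c.sample_id for c in usable if c.sample_id not in gates or c.sample_id not in behavior]
    if orphans:
        raise ValueError(f"missing gate or behavior results for samples: {orphans}")

    rows, ids, ys = [], [], []
    for c in usable:
        g = gates[c.sample_id]
        b = behavior[c.sample_id]
        if b.tropism is None or b.ellipse is None:
            raise ValueError(f"behavior summary for {c.sample_id!r} has no foci-based readouts")
        surv = b.survival.get(1)
        row = {
            "age": age_band_midpoint(c.age_band),
            "pct_blasts": c.pct_blasts,
            "platelets": c.platelets,
            "leukocytes": c.leukocytes,
            "risk_code": RISK_CODES[c.risk.lower()],
            "pct_aldh_bright_ssclow": g.pct_aldh_bright_ssclow,
            "pct_cd34_within": g.pct_cd34_within,
            "pct_lsc_combined": g.pct_lsc_combined,
            "pattern_code": PATTERN_CODES[g.pattern],
            "engraftment_pct": b.engraftment_pct,
            "survival_mean": surv.mean if surv else float("nan"),
            "dispersion_code": DISPERSION_CODES[b.tropism.classification],
            "ellipse_area": b.ellipse.area,
            "mean_ap_migration": b.mean_ap,
            "mean_dv_migration": b.mean_dv,
        }
        for name, p in zip(REGION_NAMES, b.tropism.prob_mean):
            row[f"p_{name}"] = p
        rows.append(row)
        ids.append(c.sample_id)
        ys.append(1 if c.remission.lower() == "yes" else 0)

    df = pd.DataFrame(rows, index=ids)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"feature matrix has missing values in columns {bad}")
    sds = df.std(axis=0, ddof=1)
    constant = sds[sds < 1e-12].index.tolist()
    if len(constant) == len(df.columns):
        raise ValueError("all features are constant; nothing to standardize")
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}")
        df = df.drop(columns=constant)
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    X = ((df - means) / sds).to_numpy(dtype=float)
    return FeatureMatrix(
        X=X, y=np.asarray(ys, dtype=float), feature_names=df.columns.tolist(),
        sample_ids=ids, means=means.to_numpy(), sds=sds.to_numpy(), dropped=constant,
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1 / PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    n_components: int
    W: np.ndarray  # (p, k) unit-norm weight vectors
    P: np.ndarray  # (p, k) x-loadings
    q: np.ndarray  # (k,) y-loadings
    T: np.ndarray  # (n, k) scores
    explained_y_variance: np.ndarray  # per component
    feature_names: list[str]
    y_mean: float
    centroids: tuple[float, float] | None = None  # component-1 score centroids (class 0, 1)


def pls_da_fit(X: np.ndarray, y: np.ndarray, n_components: int = 2,
               feature_names: list[str] | None = None) -> PLSModel:
    """NIPALS PLS1 on a standardized X and binary y (centered internally)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    y_mean = float(y.mean())
    Xk = X.copy()
    yk = y - y_mean
    ss_y0 = float(yk @ yk)
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    explained = np.zeros(n_components)
    for k in range(n_components):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(f"component {k + 1}: no covariance left between X and y")
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        pk = Xk.T @ t / tt
        qk = float(yk @ t) / tt
        Xk = Xk - np.outer(t, pk)
        yk = yk - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        explained[k] = 1.0 - float(yk @ yk) / ss_y0
    t1 = T[:, 0]
    centroids = (float(t1[y == 0].mean()), float(t1[y == 1].mean())) if (
        (y == 0).any() and (y == 1).any()
    ) else None
    return PLSModel(
        n_components=n_components, W=W, P=P, q=q, T=T,
        explained_y_variance=explained,
        feature_names=feature_names or [f"x{j}" for j in range(p)],
        y_mean=y_mean, centroids=centroids,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection over the fitted components."""
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("nk,nk->k", model.T, model.T)  # q_k^2 * t_k't_k
    num = (model.W**2) @ ssy
    return np.sqrt(p * num / ssy.sum())


def variable_weights(model: PLSModel) -> pd.DataFrame:
    """Features ranked by |w1|, with the VIP score alongside."""
    vip = vip_scores(model)
    df = pd.DataFrame(
        {
            "feature": model.feature_names,
            "w1": model.W[:, 0],
            "abs_w1": np.abs(model.W[:, 0]),
            "vip": vip,
        }
    )
    return df.sort_values("abs_w1", ascending=False, ignore_index=True)


def predict_outcome(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Class per row by the nearest class centroid along component-1
    scores; exact ties break toward class 0."""
    if model.centroids is None:
        raise ValueError("model was fitted without both classes; cannot predict")
    t1 = np.asarray(X, dtype=float) @ model.W[:, 0]
    c0, c1 = model.centroids
    d0, d1 = np.abs(t1 - c0), np.abs(t1 - c1)
    return np.where(d1 < d0, 1, 0)


# ---------------------------------------------------------------------------
# Association tests
# ---------------------------------------------------------------------------


def _ranksum_distribution(ranks2: np.ndarray, n_a: int) -> dict[int, int]:
    """Counts of all C(n, n_a) subset rank-sums (ranks doubled so that
    midranks stay integral)."""
    # dp[k] maps doubled-sum -> number of k-subsets achieving it
    dp: list[dict[int, int]] = [dict() for _ in range(n_a + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n_a, len(dp) - 1), 0, -1):
            upd = dp[k]
            for s, c in dp[k - 1].items():
                upd[s + r] = upd.get(s + r, 0) + c
    return dp[n_a]


def wilcoxon_exact(group_a, group_b) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value.

    The p-value is the doubled smaller tail probability of the rank sum
    over all C(nA+nB, nA) equally likely rank assignments, capped at 1.
    Ties are handled with midranks (all position assignments enumerated),
    with a warning that the exactness is conditional on the tie pattern.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    if np.unique(combined).size < combined.size:
        warnings.warn("ties present; using midranks over distinguishable arrangements")
    ranks2 = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
    w2 = int(ranks2[: a.size].sum())
    dist = _ranksum_distribution(ranks2, a.size)
    total = sum(dist.values())
    p_le = sum(c for s, c in dist.items() if s <= w2) / total
    p_ge = sum(c for s, c in dist.items() if s >= w2) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


@dataclass
class ChiSquareResult:
    statistic: float
    p: float
    undefined: bool = False


def chisq_yates(table) -> ChiSquareResult:
    """Yates continuity-corrected chi-square for a 2x2 count table.

    chi2 = n (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d)), with the
    continuity term floored at zero; p from chi-square with 1 df.  A zero
    marginal makes the statistic undefined (flagged, not raised).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    n = t.sum()
    if n < 1:
        raise ValueError("table must contain at least one observation")
    (a, b), (c, d) = t
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return ChiSquareResult(float("nan"), float("nan"), undefined=True)
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    chi2 = n * num / np.prod(margins)
    return ChiSquareResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    mcfadden_r2: float
    cox_snell_r2: float
    nagelkerke_r2: float
    lr_p: float
    converged: bool
    separation: bool


def logistic_fit(x, y, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Univariate logistic regression by iteratively reweighted least
    squares, with separation detection and pseudo-R² variants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("logistic_fit needs n >= 3")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    # quasi-complete separation for a single monotone predictor
    separation = bool(x[y == 1].min() >= x[y == 0].max() or x[y == 0].min() >= x[y == 1].max())
    if separation:
        warnings.warn("quasi-complete separation detected; coefficients diverge")
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    p1 = y.mean()
    ll0 = float(n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1)))
    mcfadden = 1.0 - ll / ll0
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
    lr_p = float(stats.chi2.sf(2.0 * (ll - ll0), df=1))
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        mcfadden_r2=float(mcfadden), cox_snell_r2=float(cox_snell),
        nagelkerke_r2=float(nagelkerke), lr_p=lr_p,
        converged=converged, separation=separation,
    )
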