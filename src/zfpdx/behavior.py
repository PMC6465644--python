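"""Quantification of xenograft behavior in zebrafish embryos.

Given per-embryo tables of fluorescent foci (coordinates in micrometres
relative to the injection site), this module computes the four behavioral
readouts used to phenotype a patient-derived xenograft:

* engraftment efficiency — percentage of injected embryos with at least
  one focus at 1 day post-injection (dpi);
* survival rate — foci counts per scored embryo, summarized by a
  conjugate Gamma-Poisson posterior over the mean count, compared between
  samples through 95% highest-density intervals (HDIs);
* dispersion — mean absolute migration along each axis and the standard
  deviational ellipse of the foci cloud, with bootstrap confidence
  intervals; two samples differ when their bootstrap intervals are
  disjoint;
* tropism — foci counts over ten anatomical regions, with a conjugate
  Dirichlet-multinomial posterior; a sample is "clumped" when at least
  one pair of regions has disjoint 95% marginal HDIs and "random"
  otherwise, and "preferred" regions are those whose HDI sits entirely
  above the uniform expectation of 0.1.

All credible intervals are highest-density intervals: the shortest
interval holding the requested posterior mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .atlas import REGION_NAMES, RegionAtlas

# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class FocusRecord:
    """One fluorescent focus in the embryo frame (micrometres from the
    injection site; +x caudal, +y dorsal)."""

    embryo_id: str
    sample_id: str
    dpi: int
    x_um: float
    y_um: float
    region: str | None = None


@dataclass
class EmbryoRecord:
    embryo_id: str
    engrafted: bool
    scored: bool = False
    foci: dict[int, list[FocusRecord]] = field(default_factory=dict)

    def n_foci(self, dpi: int) -> int:
        return len(self.foci.get(dpi, []))


@dataclass
class EmbryoCohort:
    """All embryos injected with one sample."""

    sample_id: str
    embryos: list[EmbryoRecord]
    n_injected: int

    def __post_init__(self) -> None:
        if self.n_injected < len(self.embryos):
            raise ValueError(
                f"n_injected ({self.n_injected}) smaller than number of embryo "
                f"records ({len(self.embryos)}) for sample {self.sample_id!r}"
            )

    def all_foci(self, dpi: int | None = None) -> list[FocusRecord]:
        out: list[FocusRecord] = []
        for e in self.embryos:
            for d, recs in e.foci.items():
                if dpi is None or d == dpi:
                    out.extend(recs)
        return out

    def scored_embryos(self) -> list[EmbryoRecord]:
        scored = [e for e in self.embryos if e.scored]
        return scored if scored else self.embryos


@dataclass
class SurvivalSummary:
    """Gamma posterior over the mean foci count per embryo at one dpi."""

    sample_id: str
    dpi: int
    counts: np.ndarray
    a: float  # posterior shape
    b: float  # posterior rate
    hdi95: tuple[float, float]

    @property
    def mean(self) -> float:
        return self.a / self.b


@dataclass
class DeviationalEllipse:
    """One-standard-deviation dispersion ellipse of a 2-D foci cloud."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    theta: float  # radians from +x, in [0, pi)
    ci: dict[str, tuple[float, float]] | None = None  # bootstrap 95% CIs

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)


@dataclass
class TropismProfile:
    """Dirichlet posterior over the 10-region occupancy probabilities."""

    sample_id: str
    counts: np.ndarray  # per region, canonical order
    alpha: np.ndarray  # posterior Dirichlet parameters
    prob_mean: np.ndarray
    hdi95: list[tuple[float, float]]
    classification: str | None = None  # "random" | "clumped"
    preferred: tuple[str, ...] = ()

    regions: tuple[str, ...] = REGION_NAMES


# ---------------------------------------------------------------------------
# Highest-density intervals
# ---------------------------------------------------------------------------


def hdi(dist_or_samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of a distribution.

    Accepts a frozen scipy distribution (unimodal; multimodal shapes get a
    warning and still return the shortest single interval) or an array of
    at least 1,000 posterior samples.  For a flat density, where every
    interval of the right mass has equal width, the central interval is
    returned.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    if isinstance(dist_or_samples, (np.ndarray, list, tuple)):
        return _hdi_samples(np.asarray(dist_or_samples, dtype=float), mass)
    return _hdi_dist(dist_or_samples, mass)


def _hdi_dist(dist, mass: float) -> tuple[float, float]:
    if mass == 1.0:
        return float(dist.ppf(0.0)), float(dist.ppf(1.0))

    def width(a: float) -> float:
        return float(dist.ppf(a + mass) - dist.ppf(a))

    res = optimize.minimize_scalar(
        width, bounds=(0.0, 1.0 - mass), method="bounded", options={"xatol": 1e-12}
    )
    a_opt, w_opt = float(res.x), float(res.fun)
    # boundary solutions (mode at the edge of the support, e.g. Gamma(1, b))
    for a_edge in (0.0, 1.0 - mass):
        w_edge = width(a_edge)
        # prefer an edge solution when it ties the interior optimum
        if np.isfinite(w_edge) and w_edge <= w_opt + 1e-9 * max(1.0, abs(w_opt)):
            a_opt, w_opt = a_edge, min(w_edge, w_opt)
    # flat density: all widths equal -> report the central interval
    probes = np.linspace(0.0, 1.0 - mass, 7)
    widths = np.array([width(p) for p in probes])
    if np.all(np.isfinite(widths)) and np.ptp(widths) <= 1e-9 * max(1.0, widths.mean()):
        a_opt = (1.0 - mass) / 2.0
    _warn_if_multimodal(dist, a_opt, mass)
    return float(dist.ppf(a_opt)), float(dist.ppf(a_opt + mass))


def _warn_if_multimodal(dist, a: float, mass: float) -> None:
    try:
        lo, hi = dist.ppf(max(a, 1e-9)), dist.ppf(min(a + mass, 1 - 1e-9))
        grid = np.linspace(lo, hi, 256)
        pdf = dist.pdf(grid)
    except Exception:  # discrete or pdf-less objects: skip the check
        return
    d = np.sign(np.diff(pdf))
    d = d[d != 0]
    n_modes = int(np.sum((d[:-1] > 0) & (d[1:] < 0))) + int(bool(len(d)) and d[0] < 0)
    if n_modes > 1:
        warnings.warn("density looks multimodal; returning shortest single interval")


def _hdi_samples(x: np.ndarray, mass: float) -> tuple[float, float]:
    x = np.sort(x[np.isfinite(x)])
    n = x.size
    if n < 1000:
        raise ValueError(f"sample-based HDI needs >= 1,000 draws, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def compare_hdi(a: tuple[float, float], b: tuple[float, float]) -> str:
    """'different' iff the two closed intervals are disjoint."""
    (a0, a1), (b0, b1) = a, b
    if a1 < a0 or b1 < b0:
        raise ValueError("intervals must be ordered (lo, hi)")
    return "different" if (a1 < b0 or b1 < a0) else "not-different"


# ---------------------------------------------------------------------------
# Engraftment and survival
# ---------------------------------------------------------------------------


def assign_regions(cohort: EmbryoCohort, atlas: RegionAtlas) -> EmbryoCohort:
    """Label every focus with the atlas region containing it (in place)."""
    foci = cohort.all_foci()
    if foci:
        labels = atlas.assign([f.x_um for f in foci], [f.y_um for f in foci])
        for f, lab in zip(foci, labels):
            f.region = str(lab)
    return cohort


def engraftment_efficiency(cohort: EmbryoCohort) -> float:
    """Percent of injected embryos with >= 1 focus at 1 dpi."""
    if cohort.n_injected <= 0:
        raise ValueError("cohort has n_injected = 0; engraftment undefined")
    n_pos = sum(1 for e in cohort.embryos if e.n_foci(1) >= 1)
    return 100.0 * n_pos / cohort.n_injected


def survival_posterior(
    counts,
    a0: float = 1.0,
    b0: float = 1.0,
    sample_id: str = "",
    dpi: int = 1,
    mass: float = 0.95,
) -> SurvivalSummary:
    """Conjugate Gamma-Poisson posterior over the mean foci count.

    With prior Gamma(a0, b0) (shape/rate) and n observed counts, the
    posterior over the Poisson mean is Gamma(a0 + sum(counts), b0 + n);
    its 95% HDI is the interval reported for between-sample comparison.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("survival_posterior needs at least one scored embryo")
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("foci counts must be non-negative integers")
    a = a0 + float(counts.sum())
    b = b0 + counts.size
    interval = hdi(stats.gamma(a, scale=1.0 / b), mass)
    return SurvivalSummary(sample_id=sample_id, dpi=dpi, counts=counts.astype(int),
                           a=a, b=b, hdi95=interval)


# ---------------------------------------------------------------------------
# Dispersion: migration and the standard deviational ellipse
# ---------------------------------------------------------------------------


def mean_migration(
    points, n_boot: int = 9999, seed: int | None = None, mass: float = 0.95
):
    """Mean |x| and |y| displacement with percentile-bootstrap CIs.

    Returns ``(mean_ap, mean_dv, ci_ap, ci_dv)``; CIs are None when
    n_boot == 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("mean_migration needs at least one focus")
    ax = np.abs(pts[:, 0])
    ay = np.abs(pts[:, 1])
    m_ap, m_dv = float(ax.mean()), float(ay.mean())
    if n_boot <= 0:
        return m_ap, m_dv, None, None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pts), size=(n_boot, len(pts)))
    lo, hi = 100 * (1 - mass) / 2, 100 * (1 + mass) / 2
    ci_ap = tuple(np.percentile(ax[idx].mean(axis=1), [lo, hi]))
    ci_dv = tuple(np.percentile(ay[idx].mean(axis=1), [lo, hi]))
    return m_ap, m_dv, ci_ap, ci_dv


def _ellipse_params(xx: np.ndarray, yy: np.ndarray, xy: np.ndarray):
    """Eigen-decomposition of 2x2 covariance(s) in closed form.

    Semi-axes are sqrt(2 * eigenvalue) (one-standard-deviation ellipse);
    theta is the major-axis angle from +x, reduced to [0, pi).
    """
    tr = (xx + yy) / 2.0
    disc = np.sqrt(((xx - yy) / 2.0) ** 2 + xy**2)
    lam_max = tr + disc
    lam_min = np.maximum(tr - disc, 0.0)
    theta = 0.5 * np.arctan2(2.0 * xy, xx - yy)
    theta = np.mod(theta, np.pi)
    return np.sqrt(2.0 * lam_max), np.sqrt(2.0 * lam_min), theta


def deviational_ellipse(points) -> DeviationalEllipse:
    """Standard deviational ellipse of a 2-D point cloud.

    Center at the coordinate means; axes and orientation from the
    eigen-decomposition of the sample covariance (ddof=1); collinear
    clouds give a zero minor axis.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("deviational_ellipse needs at least 2 points")
    center = pts.mean(axis=0)
    d = pts - center
    n = pts.shape[0]
    xx = float((d[:, 0] ** 2).sum() / (n - 1))
    yy = float((d[:, 1] ** 2).sum() / (n - 1))
    xy = float((d[:, 0] * d[:, 1]).sum() / (n - 1))
    smaj, smin, theta = _ellipse_params(np.array(xx), np.array(yy), np.array(xy))
    return DeviationalEllipse(
        center=(float(center[0]), float(center[1])),
        semi_major=float(smaj), semi_minor=float(smin), theta=float(theta),
    )


def _bootstrap_ellipse_draws(pts: np.ndarray, n_boot: int, rng: np.random.Generator):
    n = pts.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    sam = pts[idx]  # (B, n, 2)
    centers = sam.mean(axis=1)
    d = sam - centers[:, None, :]
    xx = (d[..., 0] ** 2).sum(axis=1) / (n - 1)
    yy = (d[..., 1] ** 2).sum(axis=1) / (n - 1)
    xy = (d[..., 0] * d[..., 1]).sum(axis=1) / (n - 1)
    smaj, smin, theta = _ellipse_params(xx, yy, xy)
    return centers, smaj, smin, theta


def _theta_ci(theta: np.ndarray, mass: float) -> tuple[float, float]:
    """Percentile CI for the ellipse angle on the doubled-angle circle.

    Orientation is only defined modulo pi, so 2*theta lives on the full
    circle; deviations are taken around the circular mean there and the
    percentile band is mapped back.
    """
    phi = 2.0 * theta
    m = np.arctan2(np.sin(phi).mean(), np.cos(phi).mean())
    dev = np.mod(phi - m + np.pi, 2 * np.pi) - np.pi
    lo, hi = np.percentile(dev, [100 * (1 - mass) / 2, 100 * (1 + mass) / 2])
    return float(np.mod(m + lo, 2 * np.pi) / 2.0), float(np.mod(m + hi, 2 * np.pi) / 2.0)


def bootstrap_ellipse(
    points, n_boot: int = 9999, seed: int | None = None, mass: float = 0.95
) -> DeviationalEllipse:
    """Deviational ellipse with per-parameter percentile bootstrap CIs.

    ``n_boot`` resamples with replacement; CIs are stored under keys
    ``center_x``, ``center_y``, ``semi_major``, ``semi_minor``, ``theta``
    (the last on the doubled-angle circular scale).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 5:
        raise ValueError("bootstrap_ellipse needs at least 5 points")
    est = deviational_ellipse(pts)
    rng = np.random.default_rng(seed)
    centers, smaj, smin, theta = _bootstrap_ellipse_draws(pts, n_boot, rng)
    lo, hi = 100 * (1 - mass) / 2, 100 * (1 + mass) / 2
    pct = lambda v: tuple(float(q) for q in np.percentile(v, [lo, hi]))
    est.ci = {
        "center_x": pct(centers[:, 0]),
        "center_y": pct(centers[:, 1]),
        "semi_major": pct(smaj),
        "semi_minor": pct(smin),
        "theta": _theta_ci(theta, mass),
    }
    return est


def compare_dispersion(
    points_a,
    points_b,
    n_boot: int = 9999,
    seed: int | None = None,
    method: str = "bootstrap",
) -> str:
    """Compare two dispersion patterns via their bootstrap ellipses.

    'different' iff the 95% bootstrap CIs of BOTH semi-axis lengths are
    pairwise disjoint (the clouds spread differently), or the CI of at
    least one center coordinate is (the clouds sit in different places —
    a shift along a single axis already separates them).  The
    alternative ``method='permutation'`` runs a two-sample permutation
    test on the center distance and on each semi-axis difference.
    """
    if method == "permutation":
        return _compare_dispersion_permutation(points_a, points_b, n_boot, seed)
    rng = np.random.default_rng(seed)
    ea = bootstrap_ellipse(points_a, n_boot, int(rng.integers(2**31)))
    eb = bootstrap_ellipse(points_b, n_boot, int(rng.integers(2**31)))
    disjoint = lambda key: compare_hdi(ea.ci[key], eb.ci[key]) == "different"
    axes_diff = disjoint("semi_major") and disjoint("semi_minor")
    center_diff = disjoint("center_x") or disjoint("center_y")
    return "different" if (axes_diff or center_diff) else "not-different"


def _compare_dispersion_permutation(points_a, points_b, n_perm, seed) -> str:
    a = np.atleast_2d(np.asarray(points_a, float))
    b = np.atleast_2d(np.asarray(points_b, float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("permutation comparison needs >= 5 points per sample")
    rng = np.random.default_rng(seed)
    ea, eb = deviational_ellipse(a), deviational_ellipse(b)
    obs = (
        float(np.hypot(ea.center[0] - eb.center[0], ea.center[1] - eb.center[1])),
        abs(ea.semi_major - eb.semi_major),
        abs(ea.semi_minor - eb.semi_minor),
    )
    pooled = np.vstack([a, b])
    n_a = len(a)
    hits = np.zeros(3)
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        e1, e2 = deviational_ellipse(pa), deviational_ellipse(pb)
        stat = (
            float(np.hypot(e1.center[0] - e2.center[0], e1.center[1] - e2.center[1])),
            abs(e1.semi_major - e2.semi_major),
            abs(e1.semi_minor - e2.semi_minor),
        )
        hits += [s >= o for s, o in zip(stat, obs)]
    p = (hits + 1) / (n_perm + 1)
    different = p[0] < 0.05 or (p[1] < 0.05 and p[2] < 0.05)
    return "different" if different else "not-different"


# ---------------------------------------------------------------------------
# Tropism
# ---------------------------------------------------------------------------


def region_counts(foci: list[FocusRecord]) -> np.ndarray:
    counts = np.zeros(len(REGION_NAMES), dtype=int)
    index = {name: i for i, name in enumerate(REGION_NAMES)}
    for f in foci:
        if f.region is None:
            raise ValueError(f"focus {f.embryo_id}/{f.sample_id} has no region label")
        counts[index[f.region]] += 1
    return counts


def region_probabilities(
    counts_or_foci, prior: np.ndarray | None = None, sample_id: str = "", mass: float = 0.95
) -> TropismProfile:
    """Dirichlet-multinomial posterior over region occupancy.

    With a uniform Dirichlet(1,...,1) prior the posterior is
    Dirichlet(1 + counts); marginal HDIs come from the Beta marginals
    Beta(alpha_i, alpha_total - alpha_i).
    """
    if isinstance(counts_or_foci, (list, tuple)) and counts_or_foci and isinstance(
        counts_or_foci[0], FocusRecord
    ):
        counts = region_counts(counts_or_foci)
    else:
        counts = np.asarray(counts_or_foci, dtype=float)
    if counts.shape != (len(REGION_NAMES),):
        raise ValueError(f"expected a {len(REGION_NAMES)}-vector of counts")
    if counts.sum() < 1:
        raise ValueError("region_probabilities needs at least one labeled focus")
    alpha0 = np.ones(len(REGION_NAMES)) if prior is None else np.asarray(prior, dtype=float)
    alpha = alpha0 + counts
    total = alpha.sum()
    prob_mean = alpha / total
    intervals = [hdi(stats.beta(a, total - a), mass) for a in alpha]
    return TropismProfile(
        sample_id=sample_id,
        counts=counts.astype(int),
        alpha=alpha,
        prob_mean=prob_mean,
        hdi95=intervals,
    )


def classify_distribution(profile: TropismProfile) -> str:
    """'clumped' iff any two regions have disjoint 95% marginal HDIs."""
    iv = profile.hdi95
    for i in range(len(iv)):
        for j in range(i + 1, len(iv)):
            if compare_hdi(iv[i], iv[j]) == "different":
                return "clumped"
    return "random"


def preferred_regions(profile: TropismProfile, baseline: float = 0.1) -> tuple[str, ...]:
    """Regions whose 95% HDI lies entirely above the uniform share."""
    return tuple(
        name for name, (lo, _hi) in zip(profile.regions, profile.hdi95) if lo > baseline
    )


# ---------------------------------------------------------------------------
# Per-sample summary
# ---------------------------------------------------------------------------


@dataclass
class BehaviorSummary:
    """All behavioral readouts for one sample's cohort."""

    sample_id: str
    engraftment_pct: float
    survival: dict[int, SurvivalSummary]
    mean_ap: float
    mean_dv: float
    ci_ap: tuple[float, float] | None
    ci_dv: tuple[float, float] | None
    ellipse: DeviationalEllipse | None
    tropism: TropismProfile | None


def summarize_cohort(
    cohort: EmbryoCohort,
    atlas: RegionAtlas,
    n_boot: int = 9999,
    seed: int | None = None,
    gamma_prior: tuple[float, float] = (1.0, 1.0),
    dirichlet_prior: np.ndarray | None = None,
) -> BehaviorSummary:
    """Run the full behavioral readout for one cohort.

    Survival and migration use the scored embryo subset (all embryos when
    none is flagged scored); engraftment uses all injected embryos.  Set
    ``n_boot=0`` to skip bootstrap CIs (point estimates only).
    """
    assign_regions(cohort, atlas)
    eff = engraftment_efficiency(cohort)
    scored = cohort.scored_embryos()
    survival = {}
    for dpi in (1, 2):
        counts = np.array([e.n_foci(dpi) for e in scored])
        if counts.size:
            survival[dpi] = survival_posterior(
                counts, *gamma_prior, sample_id=cohort.sample_id, dpi=dpi
            )
    foci1 = [f for e in scored for f in e.foci.get(1, [])]
    pts = np.array([[f.x_um, f.y_um] for f in foci1]) if foci1 else np.empty((0, 2))
    if len(pts):
        m_ap, m_dv, ci_ap, ci_dv = mean_migration(pts, n_boot=n_boot, seed=seed)
    else:
        m_ap = m_dv = float("nan")
        ci_ap = ci_dv = None
    ellipse = None
    if len(pts) >= 5 and n_boot > 0:
        ellipse = bootstrap_ellipse(pts, n_boot=n_boot, seed=seed)
    elif len(pts) >= 2:
        ellipse = deviational_ellipse(pts)
    tropism = None
    if foci1:
        tropism = region_probabilities(foci1, prior=dirichlet_prior, sample_id=cohort.sample_id)
        tropism.classification = classify_distribution(tropism)
        tropism.preferred = preferred_regions(tropism)
    return BehaviorSummary(
        sample_id=cohort.sample_id,
        engraftment_pct=eff,
        survival=survival,
        mean_ap=m_ap,
        mean_dv=m_dv,
        ci_ap=ci_ap,
        ci_dv=ci_dv,
        ellipse=ellipse,
        tropism=tropism,
    )
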