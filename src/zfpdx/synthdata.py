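"""Synthetic-study generator with controllable ground truth.

Raw per-embryo and per-event data for pilot xenograft studies of this
kind are rarely deposited, so the package ships a generator that
emulates all three evidence layers — per-embryo foci tables, paired
flow-cytometry event tables, and clinical records — from explicit
generative parameters.  Every downstream stage can then be tested
against known truth.

Generative model (all distributions are documented stand-ins; the
measured studies report only raw counts and coordinates):

* an injected embryo engrafts with probability ``engraft_prob``; an
  engrafted embryo carries Poisson(``foci_mean``) foci at 1 dpi and
  Poisson(``foci_mean`` x ``survival_decay``) at 2 dpi (an optional
  negative-binomial switch adds overdispersion);
* each focus draws an anatomical region from ``tropism_weights`` (forced
  uniform when ``dispersion_mode='random'``), then a coordinate uniform
  in that region's atlas rectangle plus Gaussian jitter (default 10 um);
* flow events mix a log-normal main population, low-FSC debris (default
  5%), FSC-H ~ FSC-A/2 doublets (default 2%), and — in the DEAB- tube
  only — an ALDH-bright/SSC-low subpopulation of expected fraction
  ``aldh_bright_frac`` (of singlet-like events) whose CD34 channel is
  positive with probability ``cd34_frac_within``.  The DEAB+ control
  shares the background FITC distribution exactly (idealized complete
  inhibition).

A fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import REGION_NAMES, RegionAtlas, default_atlas
from .behavior import EmbryoCohort, EmbryoRecord, FocusRecord
from .integrate import ClinicalRecord
from .lsc_flow import DEAB_NEG, DEAB_POS, CHANNELS, FlowSample

# Arbitrary-unit scales of the synthetic cytometer.  The viability and
# singlet gate defaults in lsc_flow are tuned to this geometry.
_FSC_MAIN = (np.log(50_000.0), 0.25)
_SSC_MAIN = (np.log(30_000.0), 0.35)
_FSC_DEBRIS = (np.log(6_600.0), 0.5)
_SSC_DEBRIS = (np.log(4_000.0), 0.5)
_SSC_BRIGHT = (np.log(12_000.0), 0.30)
_FITC_BACKGROUND = (np.log(300.0), 0.5)
_FITC_BRIGHT = (np.log(8_000.0), 0.3)
_CD34_NEG = (np.log(150.0), 0.5)
_CD34_POS = (np.log(5_000.0), 0.4)
_SINGLET_RATIO_SD = 0.03
_DOUBLET_RATIO = 0.5


def uniform_tropism() -> np.ndarray:
    return np.full(len(REGION_NAMES), 1.0 / len(REGION_NAMES))


@dataclass
class SampleProfile:
    """Generative ground truth for one patient sample or cell line."""

    sample_id: str
    lineage: str = "AML"  # AML | ALL | non-leukemic | cell-line
    fab_subtype: str = ""
    engraft_prob: float = 0.8
    foci_mean: float = 8.0
    survival_decay: float = 0.8
    dispersion_mode: str = "clumped"  # clumped | random
    tropism_weights: np.ndarray = field(default_factory=uniform_tropism)
    aldh_bright_frac: float = 0.05
    cd34_frac_within: float = 0.5
    outcome: str = "unknown"  # remission | no-remission | unknown
    # optional extras
    coordinate_jitter_um: float = 10.0
    foci_nb_dispersion: float | None = None  # neg-binomial shape; None = Poisson
    cd34_frac_background: float = 0.2
    doublet_frac: float = 0.02
    debris_frac: float = 0.05
    # clinical side (copied into the clinical table)
    age_band: str = "40-45"
    pct_blasts: float = 50.0
    platelets: float = 150.0
    leukocytes: float = 20.0
    cytogenetics: str = "Normal"
    risk: str = "intermediate"

    def validate(self) -> None:
        probs = {
            "engraft_prob": self.engraft_prob,
            "aldh_bright_frac": self.aldh_bright_frac,
            "cd34_frac_within": self.cd34_frac_within,
            "cd34_frac_background": self.cd34_frac_background,
            "doublet_frac": self.doublet_frac,
            "debris_frac": self.debris_frac,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.sample_id}: {name} must be in [0, 1], got {v}")
        if self.foci_mean < 0:
            raise ValueError(f"{self.sample_id}: foci_mean must be >= 0")
        w = np.asarray(self.tropism_weights, dtype=float)
        if w.shape != (len(REGION_NAMES),) or np.any(w < 0):
            raise ValueError(f"{self.sample_id}: tropism_weights must be a non-negative 10-vector")
        s = float(w.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(
                f"{self.sample_id}: tropism_weights must sum to 1, got sum = {s!r}"
            )
        if self.dispersion_mode not in ("clumped", "random"):
            raise ValueError(f"{self.sample_id}: bad dispersion_mode {self.dispersion_mode!r}")


@dataclass
class StudyConfig:
    profiles: list[SampleProfile]
    n_embryos_per_sample: int = 24
    n_embryos_scored: int = 6
    n_flow_events: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_embryos_scored > self.n_embryos_per_sample:
            raise ValueError("n_embryos_scored cannot exceed n_embryos_per_sample")
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        for p in self.profiles:
            p.validate()


# ---------------------------------------------------------------------------
# Embryo cohorts
# ---------------------------------------------------------------------------


def _draw_foci_count(mean: float, nb_shape: float | None, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if nb_shape is None:
        return int(rng.poisson(mean))
    p = nb_shape / (nb_shape + mean)
    return int(rng.negative_binomial(nb_shape, p))


def gen_embryo_cohort(
    profile: SampleProfile,
    config: StudyConfig,
    rng: np.random.Generator,
    atlas: RegionAtlas | None = None,
) -> EmbryoCohort:
    """Simulate one cohort of injected embryos for a sample.

    Foci keep their generative region in ``FocusRecord.region`` as ground
    truth for label-recovery tests; analyses re-assign labels from
    coordinates.
    """
    profile.validate()
    atlas = atlas or default_atlas()
    weights = (
        uniform_tropism() if profile.dispersion_mode == "random"
        else np.asarray(profile.tropism_weights, dtype=float)
    )
    n = config.n_embryos_per_sample
    scored_idx = set(rng.choice(n, size=min(config.n_embryos_scored, n), replace=False).tolist())
    embryos = []
    for i in range(n):
        embryo_id = f"{profile.sample_id}_e{i + 1:03d}"
        engrafted = bool(rng.random() < profile.engraft_prob)
        foci: dict[int, list[FocusRecord]] = {1: [], 2: []}
        if engrafted:
            for dpi, mean in ((1, profile.foci_mean),
                              (2, profile.foci_mean * profile.survival_decay)):
                k = _draw_foci_count(mean, profile.foci_nb_dispersion, rng)
                if k == 0:
                    continue
                regions = rng.choice(len(REGION_NAMES), size=k, p=weights)
                for ridx in regions:
                    name = REGION_NAMES[ridx]
                    x, y = atlas.sample_point(name, rng)
                    x += rng.normal(0.0, profile.coordinate_jitter_um)
                    y += rng.normal(0.0, profile.coordinate_jitter_um)
                    foci[dpi].append(
                        FocusRecord(embryo_id=embryo_id, sample_id=profile.sample_id,
                                    dpi=dpi, x_um=x, y_um=y, region=name)
                    )
        embryos.append(
            EmbryoRecord(embryo_id=embryo_id, engrafted=engrafted,
                         scored=i in scored_idx, foci=foci)
        )
    return EmbryoCohort(sample_id=profile.sample_id, embryos=embryos, n_injected=n)


# ---------------------------------------------------------------------------
# Flow events
# ---------------------------------------------------------------------------


def _lognormal(params, size, rng):
    mu, sd = params
    return rng.lognormal(mu, sd, size)


def gen_flow_events(
    profile: SampleProfile, config: StudyConfig, rng: np.random.Generator
) -> tuple[FlowSample, FlowSample]:
    """Paired (DEAB+ control, DEAB- test) event tables for one sample."""
    profile.validate()
    if config.n_flow_events < 1000:
        warnings.warn(
            f"{profile.sample_id}: n_flow_events={config.n_flow_events} < 1000; "
            "gate fractions will be unstable"
        )
    control = _gen_tube(profile, config.n_flow_events, rng, deab_inhibited=True)
    test = _gen_tube(profile, config.n_flow_events, rng, deab_inhibited=False)
    return (
        FlowSample(events=control, tube=DEAB_POS, sample_id=profile.sample_id),
        FlowSample(events=test, tube=DEAB_NEG, sample_id=profile.sample_id),
    )


def _gen_tube(profile: SampleProfile, n: int, rng: np.random.Generator,
              deab_inhibited: bool) -> pd.DataFrame:
    n_debris = int(rng.binomial(n, profile.debris_frac))
    n_rest = n - n_debris
    n_doublet = int(rng.binomial(n_rest, profile.doublet_frac))
    n_clean = n_rest - n_doublet
    n_bright = 0 if deab_inhibited else int(rng.binomial(n_clean, profile.aldh_bright_frac))
    n_main = n_clean - n_bright

    parts = []

    def block(count, fsc_params, ssc_params, ratio, fitc_params, cd34_pos_frac):
        fsc = _lognormal(fsc_params, count, rng)
        fsc_h = fsc * ratio * (1.0 + rng.normal(0.0, _SINGLET_RATIO_SD, count))
        ssc = _lognormal(ssc_params, count, rng)
        fitc = _lognormal(fitc_params, count, rng)
        pos = rng.random(count) < cd34_pos_frac
        cd34 = np.where(pos, _lognormal(_CD34_POS, count, rng),
                        _lognormal(_CD34_NEG, count, rng))
        parts.append(np.column_stack([fsc, fsc_h, ssc, fitc, cd34]))

    block(n_main, _FSC_MAIN, _SSC_MAIN, 1.0, _FITC_BACKGROUND, profile.cd34_frac_background)
    if n_bright:
        block(n_bright, _FSC_MAIN, _SSC_BRIGHT, 1.0, _FITC_BRIGHT, profile.cd34_frac_within)
    if n_doublet:
        block(n_doublet, _FSC_MAIN, _SSC_MAIN, _DOUBLET_RATIO, _FITC_BACKGROUND,
              profile.cd34_frac_background)
    if n_debris:
        block(n_debris, _FSC_DEBRIS, _SSC_DEBRIS, 1.0, _FITC_BACKGROUND,
              profile.cd34_frac_background)

    events = np.vstack(parts)
    events = events[rng.permutation(len(events))]
    return pd.DataFrame(events, columns=list(CHANNELS))


# ---------------------------------------------------------------------------
# Clinical table and whole studies
# ---------------------------------------------------------------------------

_OUTCOME_TO_REMISSION = {"remission": "yes", "no-remission": "no", "unknown": "NA"}


def gen_clinical_table(profiles: list[SampleProfile]) -> list[ClinicalRecord]:
    """One diagnostic record per profile; remission copied from the
    profile outcome.  Duplicate sample ids are rejected."""
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    return [
        ClinicalRecord(
            sample_id=p.sample_id,
            age_band=p.age_band,
            subtype=p.fab_subtype or p.lineage,
            pct_blasts=p.pct_blasts,
            platelets=p.platelets,
            leukocytes=p.leukocytes,
            cytogenetics=p.cytogenetics,
            risk=p.risk,
            remission=_OUTCOME_TO_REMISSION[p.outcome],
        )
        for p in profiles
    ]


@dataclass
class SyntheticStudy:
    config: StudyConfig
    cohorts: dict[str, EmbryoCohort]
    flow: dict[str, tuple[FlowSample, FlowSample]]
    clinical: list[ClinicalRecord]
    ground_truth: dict


def gen_study(config: StudyConfig, atlas: RegionAtlas | None = None) -> SyntheticStudy:
    """Generate a full study (cohorts + flow pairs + clinical table) plus
    a ground-truth sidecar listing every generative parameter."""
    config.validate()
    atlas = atlas or default_atlas()
    rng = np.random.default_rng(config.seed)
    cohorts, flow = {}, {}
    for p in config.profiles:
        cohorts[p.sample_id] = gen_embryo_cohort(p, config, rng, atlas)
        flow[p.sample_id] = gen_flow_events(p, config, rng)
    clinical = gen_clinical_table(config.profiles)
    truth = {
        "seed": config.seed,
        "n_embryos_per_sample": config.n_embryos_per_sample,
        "n_embryos_scored": config.n_embryos_scored,
        "n_flow_events": config.n_flow_events,
        "profiles": {
            p.sample_id: {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(p).items()
            }
            for p in config.profiles
        },
    }
    return SyntheticStudy(config=config, cohorts=cohorts, flow=flow,
                          clinical=clinical, ground_truth=truth)


# ---------------------------------------------------------------------------
# Outcome-driven studies for discrimination-recovery experiments
# ---------------------------------------------------------------------------


def outcome_driven_profiles(
    n_patients: int,
    rng: np.random.Generator,
    lsc_separation: float = 3.0,
    tropism_separation: float = 3.0,
    driver_region: str = "PHBC",
) -> list[SampleProfile]:
    """Profiles whose remission outcome is driven by the combined LSC
    fraction and by tropism toward one region (default PHBC, whose
    migration the pilot cohort reported as a favorable-outcome
    predictor; an anterior region also keeps the tropism driver
    unconfounded with the mean migration distance, unlike the far-caudal
    CHT).

    Two latent axes, separated by the stated effect size (in latent SD)
    between outcome groups, drive the generative parameters: the LSC axis
    moves the ALDH-bright and CD34+ gate fractions through a shared
    factor with anticorrelated idiosyncratic noise — so their product
    (the combined LSC burden) carries the outcome signal while each gate
    percentage alone is attenuated — and the tropism axis moves the
    driver region's weight, with the remaining mass spread over the
    other nine regions through a Dirichlet draw that decorrelates them
    individually.  Clinical covariates are pure noise.
    """
    base = {"PCS": 0.18, "Yolk": 0.09, "CHT": 0.12, "CF": 0.06, "ISV": 0.08,
            "PHBC": 0.10, "PCV": 0.13, "PMBC": 0.10, "DLAV": 0.07, "AA1": 0.07}
    cht_idx = REGION_NAMES.index(driver_region)
    base_other = np.array([base[r] for r in REGION_NAMES])
    base_other[cht_idx] = 0.0
    base_other = base_other / base_other.sum()
    profiles = []
    for i in range(n_patients):
        y = i % 2  # 1 = remission
        u = (1 - 2 * y) * lsc_separation / 2.0 + 0.6 * rng.normal()  # high u -> no remission
        v = (2 * y - 1) * tropism_separation / 2.0 + 0.6 * rng.normal()  # high v -> remission
        e = rng.normal()
        aldh = float(np.clip(0.10 * np.exp(0.20 * u + 0.50 * e + 0.10 * rng.normal()),
                             1e-3, 0.45))
        cd34 = float(np.clip(0.35 * np.exp(0.20 * u - 0.50 * e + 0.10 * rng.normal()),
                             0.01, 0.95))
        cht = float(np.clip(0.30 + 0.09 * v, 0.03, 0.72))
        others = rng.dirichlet(20.0 * np.delete(base_other, cht_idx))
        weights = np.insert(others * (1.0 - cht), cht_idx, cht)
        profiles.append(
            SampleProfile(
                sample_id=f"SYN{i + 1:03d}",
                lineage="AML",
                fab_subtype=f"M{rng.integers(0, 6)}",
                engraft_prob=0.85,
                foci_mean=10.0,
                survival_decay=0.8,
                dispersion_mode="clumped",
                tropism_weights=weights,
                aldh_bright_frac=aldh,
                cd34_frac_within=cd34,
                outcome="remission" if y == 1 else "no-remission",
                age_band=f"{30 + 5 * int(rng.integers(0, 8))}-{35 + 5 * int(rng.integers(0, 8))}",
                pct_blasts=float(rng.uniform(5, 95)),
                platelets=float(rng.uniform(20, 300)),
                leukocytes=float(rng.uniform(2, 100)),
                cytogenetics="Normal",
                risk=("favorable", "intermediate", "adverse")[int(rng.integers(0, 3))],
            )
        )
    return profiles
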