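"""Leukemic-stem-cell quantification by sequential flow-cytometry gating.

The LSC compartment is operationalized as ALDH-bright / SSC-low / CD34+
events, measured with the ALDEFLUOR assay (FITC channel) and a
PerCP-Cy5.5 CD34 stain.  Each sample contributes two tubes: a DEAB+
control, in which diethylaminobenzaldehyde inhibits ALDH so the FITC
channel shows only background fluorescence, and the DEAB- test tube.

The gating chain is:

1. viability — drop debris/dead events below an FSC-A floor;
2. singlets — keep events whose FSC-H/FSC-A ratio sits within a band
   around the median ratio (doublets ride at roughly half the ratio);
3. ALDH-bright/SSC-low — FITC above a quantile of the gated DEAB+
   control (default the 99.9th percentile, the standard ALDEFLUOR
   background-allowance convention) and SSC-A below a cutoff (default
   the singlet median);
4. CD34+ — PerCP-Cy5.5 above a cutoff, by default the valley of the
   bimodal intensity density.

All reported percentages are relative to singlet events; the combined
LSC percentage is the product of the ALDH-bright/SSC-low percentage and
the CD34+ percentage within that gate, divided by 100.  Samples with
more than 1.9% ALDH-bright/SSC-low events are called "numerous", the
rest "rare" (the boundary itself maps to rare).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

#: Canonical channel names (CSV column headers, matched case-insensitively).
CHANNELS = ("FSC-A", "FSC-H", "SSC-A", "FITC-A", "PerCP-Cy5.5-A")

DEAB_POS = "DEAB+"
DEAB_NEG = "DEAB-"

# Gate defaults, expressed in the arbitrary-unit scale of the synthetic
# generator; every one of them is a keyword argument downstream.
DEFAULT_MIN_FSC = 26_000.0
DEFAULT_SINGLET_BAND = 0.15
DEFAULT_DEAB_QUANTILE = 0.999
THRESHOLD_NUMEROUS = 1.9


@dataclass
class FlowSample:
    """Raw cytometry events for one tube of one sample."""

    events: pd.DataFrame
    tube: str  # DEAB_POS or DEAB_NEG
    sample_id: str

    def __post_init__(self) -> None:
        cols = {c.lower(): c for c in self.events.columns}
        rename = {}
        for want in CHANNELS:
            if want in self.events.columns:
                continue
            if want.lower() in cols:
                rename[cols[want.lower()]] = want
            else:
                raise ValueError(
                    f"flow sample {self.sample_id!r} tube {self.tube!r} is missing "
                    f"channel {want!r}"
                )
        if rename:
            self.events = self.events.rename(columns=rename)
        if self.events[list(CHANNELS)].isna().any().any():
            raise ValueError(f"flow sample {self.sample_id!r} has missing channel values")
        if self.tube not in (DEAB_POS, DEAB_NEG):
            raise ValueError(f"tube must be {DEAB_POS!r} or {DEAB_NEG!r}, got {self.tube!r}")


@dataclass
class GateResult:
    """Fractions surviving each sequential gate, as % of the stage input."""

    sample_id: str
    pct_viable: float
    pct_singlet: float
    pct_aldh_bright_ssclow: float
    pct_cd34_within: float
    pct_lsc_combined: float
    pattern: str
    cd34_undefined: bool = False
    fitc_cutoff: float = float("nan")
    ssc_cutoff: float = float("nan")
    cd34_cutoff: float = float("nan")
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Individual gates
# ---------------------------------------------------------------------------


def gate_viable(events: pd.DataFrame, min_fsc: float = DEFAULT_MIN_FSC):
    """Drop debris/dead events below the FSC-A floor.

    Returns ``(subset, pct_retained)``; an empty result is an error that
    names the offending threshold.
    """
    if len(events) == 0:
        raise ValueError("viability gate received no events")
    kept = events[events["FSC-A"] >= min_fsc]
    if len(kept) == 0:
        raise ValueError(f"viability gate at FSC-A >= {min_fsc} removed every event")
    return kept, 100.0 * len(kept) / len(events)


def gate_singlets(events: pd.DataFrame, band_halfwidth: float = DEFAULT_SINGLET_BAND):
    """Keep events whose FSC-H/FSC-A ratio is within +-band of the median."""
    ratio = events["FSC-H"].to_numpy() / events["FSC-A"].to_numpy()
    med = np.median(ratio)
    keep = np.abs(ratio - med) <= band_halfwidth
    return events[keep], 100.0 * keep.mean()


def aldh_threshold_from_deab(
    control: FlowSample,
    q: float = DEFAULT_DEAB_QUANTILE,
    min_fsc: float = DEFAULT_MIN_FSC,
    band_halfwidth: float = DEFAULT_SINGLET_BAND,
) -> float:
    """FITC cutoff = q-th quantile of the gated DEAB+ control tube."""
    if control.tube != DEAB_POS:
        raise ValueError(
            f"ALDH background threshold must come from a {DEAB_POS} control tube, "
            f"got {control.tube!r}"
        )
    viable, _ = gate_viable(control.events, min_fsc)
    singlets, _ = gate_singlets(viable, band_halfwidth)
    return float(np.quantile(singlets["FITC-A"].to_numpy(), q))


def gate_aldh_bright_ssclow(
    events: pd.DataFrame, fitc_cutoff: float, ssc_cutoff: float | None = None
):
    """ALDH-bright/SSC-low gate on singlet events.

    Default SSC cutoff is the singlet median, mirroring the graphical
    low-side-scatter gate.  Returns ``(subset, pct_of_input, ssc_cutoff)``.
    """
    if ssc_cutoff is None:
        ssc_cutoff = float(np.median(events["SSC-A"].to_numpy()))
    keep = (events["FITC-A"].to_numpy() > fitc_cutoff) & (
        events["SSC-A"].to_numpy() < ssc_cutoff
    )
    return events[keep], 100.0 * keep.mean(), ssc_cutoff


def cd34_cutoff_from_density(values, max_points: int = 5000) -> float:
    """CD34 cutoff at the valley of the bimodal log-intensity density.

    A Gaussian KDE of log(1+x) is scanned for its two tallest modes; the
    cutoff is the density minimum between them.  Unimodal channels fall
    back to the midpoint (log scale) of the 5th/95th percentiles.
    """
    x = np.log1p(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    if x.size < 10 or np.ptp(x) < 1e-9:
        raise ValueError("cd34_cutoff_from_density needs >= 10 spread-out events")
    if x.size > max_points:  # deterministic thinning keeps the KDE cheap
        x = np.sort(x)[:: int(np.ceil(x.size / max_points))]
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    peaks = [
        i for i in range(1, len(grid) - 1) if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
    ]
    if len(peaks) >= 2:
        p1, p2 = sorted(sorted(peaks, key=lambda i: dens[i])[-2:])
        valley = p1 + int(np.argmin(dens[p1:p2 + 1]))
        return float(np.expm1(grid[valley]))
    lo, hi = np.percentile(x, [5, 95])
    return float(np.expm1((lo + hi) / 2.0))


def cd34_fraction(gated: pd.DataFrame, cd34_cutoff: float):
    """Percent CD34+ of the gated events; empty gates are flagged
    undefined rather than reported as 0."""
    if len(gated) == 0:
        return float("nan"), True
    frac = 100.0 * float((gated["PerCP-Cy5.5-A"].to_numpy() > cd34_cutoff).mean())
    return frac, False


def combined_lsc_fraction(pct_aldh: float, pct_cd34_within: float) -> float:
    """Combined LSC % of singlet events = product of the two gate
    percentages / 100, rounded to two decimals for reporting."""
    for name, v in (("pct_aldh", pct_aldh), ("pct_cd34_within", pct_cd34_within)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return round(pct_aldh * pct_cd34_within / 100.0, 2)


def classify_aldh_pattern(
    pct_aldh_bright_ssclow: float, threshold: float = THRESHOLD_NUMEROUS
) -> str:
    """'numerous' iff strictly above the threshold (default 1.9%)."""
    if not 0.0 <= pct_aldh_bright_ssclow <= 100.0:
        raise ValueError(f"percentage out of range: {pct_aldh_bright_ssclow}")
    return "numerous" if pct_aldh_bright_ssclow > threshold else "rare"


def product_identity_mismatch(
    pct_aldh: float, pct_cd34_within: float, reported_combined: float, tol: float = 0.011
) -> bool:
    """True when a reported combined LSC % disagrees with the product of
    its two gate percentages beyond printed-rounding tolerance."""
    return abs(combined_lsc_fraction(pct_aldh, pct_cd34_within) - reported_combined) > tol


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def gate_sample(
    control: FlowSample,
    test: FlowSample,
    min_fsc: float = DEFAULT_MIN_FSC,
    band_halfwidth: float = DEFAULT_SINGLET_BAND,
    deab_quantile: float = DEFAULT_DEAB_QUANTILE,
    ssc_cutoff: float | None = None,
    cd34_cutoff: float | None = None,
    threshold_numerous: float = THRESHOLD_NUMEROUS,
) -> GateResult:
    """Run the sequential gating chain on a DEAB+/DEAB- tube pair."""
    if test.tube != DEAB_NEG:
        raise ValueError(f"test tube must be {DEAB_NEG!r}, got {test.tube!r}")
    notes: list[str] = []
    if len(test.events) < 1000:
        msg = f"sample {test.sample_id!r}: <1000 events; gate fractions unstable"
        warnings.warn(msg)
        notes.append(msg)

    viable, pct_viable = gate_viable(test.events, min_fsc)
    singlets, pct_singlet = gate_singlets(viable, band_halfwidth)
    fitc_cutoff = aldh_threshold_from_deab(control, deab_quantile, min_fsc, band_halfwidth)
    gated, pct_aldh, ssc_used = gate_aldh_bright_ssclow(singlets, fitc_cutoff, ssc_cutoff)
    if cd34_cutoff is None:
        cd34_cutoff = cd34_cutoff_from_density(singlets["PerCP-Cy5.5-A"].to_numpy())
    pct_cd34, undefined = cd34_fraction(gated, cd34_cutoff)
    if undefined:
        notes.append(f"sample {test.sample_id!r}: empty ALDH-bright gate; CD34% undefined")
        combined = float("nan")
    else:
        combined = combined_lsc_fraction(pct_aldh, pct_cd34)
    return GateResult(
        sample_id=test.sample_id,
        pct_viable=pct_viable,
        pct_singlet=pct_singlet,
        pct_aldh_bright_ssclow=pct_aldh,
        pct_cd34_within=pct_cd34,
        pct_lsc_combined=combined,
        pattern=classify_aldh_pattern(pct_aldh, threshold_numerous),
        cd34_undefined=undefined,
        fitc_cutoff=fitc_cutoff,
        ssc_cutoff=ssc_used,
        cd34_cutoff=cd34_cutoff,
        warnings=notes,
    )
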