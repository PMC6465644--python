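"""Published summary values for the pilot acute-leukemia cohort.

These are the worked-example inputs the package's documentation and
acceptance checks compute from: per-sample flow-cytometry gate
percentages (ALDH-bright/SSC-low %, CD34+ % within that gate, the
reported combined LSC % and ALDH pattern call) and the diagnostic table
for the seven patients (samples LPZ6-LPZ21) plus the K562 and U937 cell
lines.  Raw per-embryo and per-event data for the cohort are not
publicly deposited; the synthetic generator stands in for them, and
:func:`table1_like_profiles` builds generator profiles that mirror this
cohort's structure.
"""

from __future__ import annotations

import numpy as np

from .atlas import REGION_NAMES
from .integrate import ClinicalRecord
from .synthdata import SampleProfile

#: sample -> (pct_aldh_bright_ssclow, pct_cd34_within, reported_combined, reported_pattern)
REFERENCE_GATES: dict[str, tuple[float, float, float, str]] = {
    "LPZ6": (25.6, 51.1, 13.08, "numerous"),
    "LPZ12": (0.27, 11.3, 0.03, "rare"),
    "LPZ13": (37.9, 45.6, 17.28, "numerous"),
    "LPZ15": (1.58, 29.7, 0.47, "rare"),
    "LPZ14": (1.74, 68.0, 1.18, "rare"),
    "LPZ21": (24.96, 24.83, 23.78, "numerous"),
    "K562": (31.3, 0.19, 0.06, "numerous"),
    "U937": (0.96, 26.4, 0.25, "rare"),
}

#: Diagnostic records for the seven patients.
REFERENCE_CLINICAL: list[ClinicalRecord] = [
    ClinicalRecord("LPZ6", "76-80", "M4", 16.0, 42.0, 16.0, "Complex", "adverse", "no"),
    ClinicalRecord("LPZ10", "76-80", "M4Eos", 42.0, 282.0, 2.2, "Normal", "intermediate", "NA"),
    ClinicalRecord("LPZ12", "40-45", "M3", 2.0, 35.0, 2.0, "t(15:17)", "favorable", "yes"),
    ClinicalRecord("LPZ13", "30-35", "M1", 84.6, 207.0, 90.0, "Normal", "intermediate", "no"),
    ClinicalRecord("LPZ15", "40-45", "M5B", 6.0, 29.0, 104.9, "47, XY, +6", "intermediate", "no"),
    ClinicalRecord("LPZ14", "30-35", "ALL-B", 91.34, 26.0, 5.7, "Normal", "standard", "yes"),
    ClinicalRecord("LPZ21", "46-50", "ALL-B", 76.0, 231.0, 67.4,
                   "47,XXY, t(9;22)(q34;qll)", "adverse", "no"),
]

#: Cohort-level engraftment efficiencies (%) by lineage, for context.
REFERENCE_ENGRAFTMENT = {"AML": 87.8, "ALL": 72.5, "non-leukemic": 66.0}

#: Remission-by-dispersion contingency table observed in the cohort
#: (rows: clumped, random; columns: remission yes, no).
REFERENCE_DISPERSION_TABLE = np.array([[0, 3], [2, 1]])


def _cht_heavy(weight_cht: float) -> np.ndarray:
    """CHT-dominant tropism vector; remaining mass spread evenly."""
    w = np.full(len(REGION_NAMES), (1.0 - weight_cht) / (len(REGION_NAMES) - 1))
    w[REGION_NAMES.index("CHT")] = weight_cht
    return w


def table1_like_profiles() -> list[SampleProfile]:
    """Generator profiles mirroring the seven-patient cohort.

    Gate fractions come from :data:`REFERENCE_GATES`; engraftment
    probabilities use the lineage-level efficiencies; tropism follows the
    qualitative report (CHT-clumped for remitting patients, random for
    most non-remitting ones).  LPZ10 has no published gate row and gets
    mid-range placeholders.
    """
    out = []
    dispersion = {
        "LPZ6": "random", "LPZ10": "clumped", "LPZ12": "clumped", "LPZ13": "clumped",
        "LPZ15": "random", "LPZ14": "clumped", "LPZ21": "random",
    }
    outcome = {"yes": "remission", "no": "no-remission", "NA": "unknown"}
    for rec in REFERENCE_CLINICAL:
        lineage = "ALL" if rec.subtype.startswith("ALL") else "AML"
        aldh, cd34, _, _ = REFERENCE_GATES.get(rec.sample_id, (5.0, 40.0, 2.0, "numerous"))
        out.append(
            SampleProfile(
                sample_id=rec.sample_id,
                lineage=lineage,
                fab_subtype=rec.subtype,
                engraft_prob=REFERENCE_ENGRAFTMENT[lineage] / 100.0,
                foci_mean=8.0,
                survival_decay=0.8,
                dispersion_mode=dispersion[rec.sample_id],
                tropism_weights=_cht_heavy(0.4),
                aldh_bright_frac=aldh / 100.0,
                cd34_frac_within=cd34 / 100.0,
                outcome=outcome[rec.remission],
                age_band=rec.age_band,
                pct_blasts=rec.pct_blasts,
                platelets=rec.platelets,
                leukocytes=rec.leukocytes,
                cytogenetics=rec.cytogenetics,
                risk=rec.risk,
            )
        )
    return out
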