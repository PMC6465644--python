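"""Readers and writers for the pipeline's tabular formats.

All tables are UTF-8, comma-separated CSV with a header row and '.' as
the decimal mark.  Flow-cytometry events use the canonical channel
column names (matched case-insensitively on read); foci tables follow
the schema ``embryo_id, sample_id, dpi, x_um, y_um[, region]`` with a
companion embryo table carrying per-embryo flags so that cohorts
round-trip losslessly.  Every writer has a reader such that
``read(write(x)) == x``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorSummary, EmbryoCohort, EmbryoRecord, FocusRecord
from .integrate import ClinicalRecord
from .lsc_flow import CHANNELS, FlowSample, GateResult

FOCI_COLUMNS = ["embryo_id", "sample_id", "dpi", "x_um", "y_um"]
EMBRYO_COLUMNS = ["embryo_id", "sample_id", "engrafted", "scored", "n_injected"]
CLINICAL_COLUMNS = [
    "sample_id", "age_band", "subtype", "pct_blasts", "platelets",
    "leukocytes", "cytogenetics", "risk", "remission",
]


# ---------------------------------------------------------------------------
# Foci / cohort tables
# ---------------------------------------------------------------------------


def cohorts_to_tables(cohorts: list[EmbryoCohort]) -> tuple[pd.DataFrame, pd.DataFrame]:
    foci_rows, embryo_rows = [], []
    for c in cohorts:
        for e in c.embryos:
            embryo_rows.append(
                dict(embryo_id=e.embryo_id, sample_id=c.sample_id,
                     engrafted=e.engrafted, scored=e.scored, n_injected=c.n_injected)
            )
            for dpi, recs in sorted(e.foci.items()):
                for f in recs:
                    foci_rows.append(
                        dict(embryo_id=f.embryo_id, sample_id=f.sample_id, dpi=f.dpi,
                             x_um=f.x_um, y_um=f.y_um, region=f.region or "")
                    )
    foci = pd.DataFrame(foci_rows, columns=FOCI_COLUMNS + ["region"])
    embryos = pd.DataFrame(embryo_rows, columns=EMBRYO_COLUMNS)
    return foci, embryos


def write_foci_csv(cohorts: list[EmbryoCohort], foci_path, embryos_path=None) -> None:
    foci, embryos = cohorts_to_tables(cohorts)
    foci.to_csv(foci_path, index=False, float_format="%.17g")
    if embryos_path is not None:
        embryos.to_csv(embryos_path, index=False)


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-base
        raise ValueError(f"{path}: non-numeric {col!r} at line {line}: {df[col][bad.idxmax()]!r}")
    return converted


def read_foci_csv(foci_path, embryos_path=None) -> list[EmbryoCohort]:
    """Load foci (and optionally the embryo sidecar) back into cohorts.

    Without the sidecar, embryos are inferred from the foci table
    (embryos with zero foci are then invisible and n_injected equals the
    number of embryos seen).
    """
    foci_path = Path(foci_path)
    df = pd.read_csv(foci_path, dtype={"embryo_id": str, "sample_id": str},
                     float_precision="round_trip")
    missing = [c for c in FOCI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{foci_path}: missing required columns {missing}")
    if len(df):
        df["x_um"] = _check_numeric(df, "x_um", foci_path)
        df["y_um"] = _check_numeric(df, "y_um", foci_path)
        df["dpi"] = _check_numeric(df, "dpi", foci_path).astype(int)

    if embryos_path is not None:
        emb = pd.read_csv(embryos_path, dtype={"embryo_id": str, "sample_id": str})
    else:
        emb = (
            df[["embryo_id", "sample_id"]].drop_duplicates().assign(scored=True)
            if len(df) else pd.DataFrame(columns=EMBRYO_COLUMNS)
        )
        if len(emb):
            counts = emb.groupby("sample_id")["embryo_id"].transform("count")
            emb = emb.assign(engrafted=True, n_injected=counts)

    cohorts: list[EmbryoCohort] = []
    for sample_id, g in emb.groupby("sample_id", sort=True):
        embryos = []
        sample_foci = df[df["sample_id"] == sample_id] if len(df) else df
        for _, row in g.iterrows():
            mine = sample_foci[sample_foci["embryo_id"] == row["embryo_id"]] if len(df) else df
            foci: dict[int, list[FocusRecord]] = {}
            for _, fr in mine.iterrows():
                region = fr.get("region", "")
                foci.setdefault(int(fr["dpi"]), []).append(
                    FocusRecord(
                        embryo_id=fr["embryo_id"], sample_id=fr["sample_id"],
                        dpi=int(fr["dpi"]), x_um=float(fr["x_um"]), y_um=float(fr["y_um"]),
                        region=str(region) if isinstance(region, str) and region else None,
                    )
                )
            embryos.append(
                EmbryoRecord(embryo_id=row["embryo_id"], engrafted=bool(row["engrafted"]),
                             scored=bool(row["scored"]), foci=foci)
            )
        cohorts.append(EmbryoCohort(sample_id=sample_id, embryos=embryos,
                                    n_injected=int(g["n_injected"].iloc[0])))
    return cohorts


# ---------------------------------------------------------------------------
# Flow tables
# ---------------------------------------------------------------------------


def write_flow_csv(sample: FlowSample, path) -> None:
    df = sample.events[list(CHANNELS)].copy()
    df.insert(0, "sample_id", sample.sample_id)
    df.insert(1, "tube", sample.tube)
    df.to_csv(path, index=False, float_format="%.17g")


def read_flow_csv(path, sample_id: str | None = None, tube: str | None = None) -> FlowSample:
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = {c.lower(): c for c in df.columns}
    if sample_id is None:
        if "sample_id" not in meta_cols:
            raise ValueError(f"{path}: no sample_id column and none given")
        sample_id = str(df[meta_cols["sample_id"]].iloc[0])
    if tube is None:
        if "tube" not in meta_cols:
            raise ValueError(f"{path}: no tube column and none given")
        tube = str(df[meta_cols["tube"]].iloc[0])
    events = df.drop(columns=[meta_cols[c] for c in ("sample_id", "tube") if c in meta_cols])
    return FlowSample(events=events, tube=tube, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def write_clinical_csv(records: list[ClinicalRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CLINICAL_COLUMNS).to_csv(
        path, index=False
    )


def read_clinical_csv(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"sample_id": str, "age_band": str, "remission": str},
                     keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    return [
        ClinicalRecord(
            sample_id=r.sample_id, age_band=r.age_band, subtype=r.subtype,
            pct_blasts=float(r.pct_blasts), platelets=float(r.platelets),
            leukocytes=float(r.leukocytes), cytogenetics=str(r.cytogenetics),
            risk=str(r.risk), remission=str(r.remission),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Results serialization
# ---------------------------------------------------------------------------


def gate_results_to_frame(results: list[GateResult]) -> pd.DataFrame:
    rows = []
    for g in results:
        d = dataclasses.asdict(g)
        d["warnings"] = "; ".join(d["warnings"])
        rows.append(d)
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def behavior_summary_to_dict(summary: BehaviorSummary) -> dict:
    d = _jsonable(summary)
    d.pop("counts", None)
    return d


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
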