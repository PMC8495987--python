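"""PDV carrier classification from per-subject variant annotation tables.

A subject is a carrier of a potentially damaging variant (PDV) if they
have at least one qualifying record: a protein-truncating variant (PTV)
in a risk gene, a missense variant in a risk gene with MPC > 2 (strict),
or a damaging CNV. Subjects with a trisomy record or any large/multiple
CNV record are set to ``undetermined`` and drop out of carrier versus
non-carrier contrasts (they remain cases for case-control contrasts).
Among carriers the most severe class is assigned by the ranking
CNV > PTV > MIS. Subjects with no annotation records are non-carriers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("PTV", "MIS", "CNV", "TRISOMY")
SEVERITY_ORDER = ("CNV", "PTV", "MIS")  # most to least severe
MPC_THRESHOLD = 2.0

RECORD_COLUMNS = ["subject_id", "gene", "var_class", "mpc", "cnv_damaging", "cnv_large_or_multiple"]


def _validate_records(records: pd.DataFrame, known_subjects: set[str]) -> pd.DataFrame:
    if records.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    missing_cols = [c for c in ("subject_id", "gene", "var_class") if c not in records.columns]
    if missing_cols:
        raise ValueError(f"variant records missing columns: {missing_cols}")
    records = records.copy()
    for col, default in (("mpc", np.nan), ("cnv_damaging", False), ("cnv_large_or_multiple", False)):
        if col not in records.columns:
            records[col] = default
    bad_class = ~records["var_class"].isin(VARIANT_CLASSES)
    if bad_class.any():
        raise ValueError(
            f"malformed variant classes: {sorted(records.loc[bad_class, 'var_class'].unique())}"
        )
    unknown = set(records["subject_id"].astype(str)) - known_subjects
    if unknown:
        raise ValueError(f"records reference unknown subjects: {sorted(unknown)[:10]}")
    mis = records["var_class"] == "MIS"
    if mis.any() and records.loc[mis, "mpc"].isna().any():
        raise ValueError("MIS records must carry an MPC score")
    return records


def classify_carriers(
    records: pd.DataFrame,
    subject_ids,
    risk_genes,
) -> pd.DataFrame:
    """Per-subject carrier calls from variant annotation records.

    Returns a table with columns subject_id, status
    (carrier / non-carrier / undetermined) and most_severe (CNV/PTV/MIS
    for carriers, missing otherwise).
    """
    risk_genes = set(risk_genes)
    if not risk_genes:
        raise ValueError("risk gene set is empty")
    subject_ids = [str(s) for s in subject_ids]
    records = _validate_records(records, set(subject_ids))

    qualifying_class = {}
    undetermined = set()
    for _, rec in records.iterrows():
        sid = str(rec["subject_id"])
        cls = rec["var_class"]
        if cls == "TRISOMY" or bool(rec["cnv_large_or_multiple"]):
            undetermined.add(sid)
            continue
        qualifies = (
            (cls == "PTV" and rec["gene"] in risk_genes)
            or (cls == "MIS" and rec["gene"] in risk_genes and float(rec["mpc"]) > MPC_THRESHOLD)
            or (cls == "CNV" and bool(rec["cnv_damaging"]))
        )
        if qualifies:
            qualifying_class.setdefault(sid, []).append(cls)

    severity_rank = {cls: i for i, cls in enumerate(SEVERITY_ORDER)}
    rows = []
    for sid in subject_ids:
        if sid in undetermined:
            rows.append({"subject_id": sid, "status": "undetermined", "most_severe": pd.NA})
        elif sid in qualifying_class:
            most = min(qualifying_class[sid], key=severity_rank.__getitem__)
            rows.append({"subject_id": sid, "status": "carrier", "most_severe": most})
        else:
            rows.append({"subject_id": sid, "status": "non-carrier", "most_severe": pd.NA})
    calls = pd.DataFrame(rows)
    logger.info(
        "carrier calls: %d carriers, %d non-carriers, %d undetermined",
        (calls["status"] == "carrier").sum(),
        (calls["status"] == "non-carrier").sum(),
        (calls["status"] == "undetermined").sum(),
    )
    return calls


def severity_table(calls: pd.DataFrame) -> pd.Series:
    """Counts of most-severe PDV class plus non-carrier and undetermined."""
    counts = {cls: int(((calls["status"] == "carrier") & (calls["most_severe"] == cls)).sum())
              for cls in SEVERITY_ORDER}
    counts["non-carrier"] = int((calls["status"] == "non-carrier").sum())
    counts["undetermined"] = int((calls["status"] == "undetermined").sum())
    return pd.Series(counts, name="count")
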