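"""Compound-table parsing, hypothesis serialization, dataset design checks.

Compound tables are delimited text (comma or tab) or spreadsheets with the
header columns ``id, name, smiles, activity, unit, partition`` (``name``,
``unit``, ``partition`` optional).  Activities are converted to
pEC50 = -log10(EC50 in molar); rows already given as pEC50 pass through.

Hypotheses use a small line-oriented text format (one header block, one
``point`` record per feature sphere) that round-trips at full float
precision.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    PARTITIONS,
    CompoundRecord,
    DatasetDesignReport,
    Hypothesis,
    PharmacophorePoint,
    check_kind,
)

logger = logging.getLogger(__name__)

#: Molar scale factor per accepted activity unit.
_UNIT_SCALE = {"M": 1.0, "uM": 1e-6, "nM": 1e-9}


def ec50_to_pec50(ec50: float, unit: str = "M") -> float:
    """Convert an EC50 in the given unit to pEC50 (-log10 molar)."""
    if unit == "pEC50":
        return float(ec50)
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown activity unit {unit!r}")
    if not ec50 > 0:
        raise ValueError(f"EC50 must be positive, got {ec50}")
    return -math.log10(ec50 * _UNIT_SCALE[unit])


def pec50_to_ec50(pec50: float, unit: str = "M") -> float:
    """Inverse of :func:`ec50_to_pec50`."""
    if unit == "pEC50":
        return float(pec50)
    return 10.0 ** (-pec50) / _UNIT_SCALE[unit]


def _smiles_ok(smiles: str) -> bool:
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles) is not None


def _load_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path)
    # sniff comma vs tab from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_compound_table(
    path,
    ec50_unit: str = "uM",
    validate_smiles: bool = True,
) -> list:
    """Parse a compound/activity table into :class:`CompoundRecord` objects.

    ``ec50_unit`` is the default unit for the ``activity`` column (one of
    ``M``, ``uM``, ``nM``, ``pEC50``); a per-row ``unit`` column overrides
    it.  Rows with non-positive EC50 or unparsable SMILES are rejected with
    a logged reason.  Duplicate ids are collapsed to a single record whose
    pEC50 is the arithmetic mean of the individual pEC50 values (averaging
    is done in log space); duplicates with conflicting partition labels are
    a hard error.
    """
    df = _load_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "id" not in df.columns or "activity" not in df.columns:
        raise ValueError(f"table {path} must have 'id' and 'activity' columns")

    rows = []
    for idx, row in df.iterrows():
        cid = str(row["id"]).strip()
        unit = str(row["unit"]).strip() if "unit" in df.columns and pd.notna(row.get("unit")) else ec50_unit
        try:
            act = float(row["activity"])
            if not np.isfinite(act):
                raise ValueError("non-finite activity")
            pec50 = ec50_to_pec50(act, unit)
        except (TypeError, ValueError) as exc:
            logger.warning("rejecting row %s (id=%s): %s", idx, cid, exc)
            continue
        smiles = str(row["smiles"]).strip() if "smiles" in df.columns and pd.notna(row.get("smiles")) else ""
        if smiles and validate_smiles and not _smiles_ok(smiles):
            logger.warning("rejecting row %s (id=%s): unparsable SMILES %r", idx, cid, smiles)
            continue
        partition = (
            str(row["partition"]).strip()
            if "partition" in df.columns and pd.notna(row.get("partition"))
            else "unassigned"
        )
        if partition not in PARTITIONS:
            raise ValueError(f"row {idx} (id={cid}): unknown partition {partition!r}")
        name = str(row["name"]).strip() if "name" in df.columns and pd.notna(row.get("name")) else ""
        source = str(row["source"]).strip() if "source" in df.columns and pd.notna(row.get("source")) else ""
        rows.append(CompoundRecord(cid, name, smiles, pec50, partition, source))

    # collapse duplicate ids: mean pEC50 in log space
    by_id: dict = {}
    order: list = []
    for rec in rows:
        if rec.id not in by_id:
            by_id[rec.id] = [rec]
            order.append(rec.id)
        else:
            by_id[rec.id].append(rec)
    out = []
    for cid in order:
        group = by_id[cid]
        parts = {g.partition for g in group if g.partition != "unassigned"} or {"unassigned"}
        if len(parts) > 1:
            raise ValueError(f"duplicate id {cid} with conflicting partitions {sorted(parts)}")
        first = group[0]
        mean_p = float(np.mean([g.pec50_obs for g in group]))
        out.append(
            CompoundRecord(cid, first.name, first.smiles, mean_p, parts.pop(), first.source)
        )
    return out


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    """Write records back out as a CSV with the canonical header."""
    recs = list(records)
    df = pd.DataFrame(
        {
            "id": [r.id for r in recs],
            "name": [r.name for r in recs],
            "smiles": [r.smiles for r in recs],
            "activity": [r.pec50_obs for r in recs],
            "unit": ["pEC50"] * len(recs),
            "partition": [r.partition for r in recs],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Hypothesis serialization (package text format)
# ---------------------------------------------------------------------------

_MAGIC = "# phesvm hypothesis v1"


def write_hypothesis(h: Hypothesis, path) -> None:
    """Serialize a hypothesis to the package text format."""
    lines = [_MAGIC, f"id\t{h.id}"]
    if h.provenance:
        lines.append(f"provenance\t{h.provenance}")
    a, b = (float(v) for v in h.activity_map)
    lines.append(f"activity_map\t{a!r}\t{b!r}")
    for p in h.points:
        x, y, z = (float(v) for v in p.position)
        lines.append(
            f"point\t{p.kind}\t{x!r}\t{y!r}\t{z!r}\t{float(p.tolerance)!r}\t{float(p.weight)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_hypothesis(path) -> Hypothesis:
    """Parse a hypothesis file written by :func:`write_hypothesis`."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _MAGIC:
        raise ValueError(f"{path}: not a phesvm hypothesis file (bad magic line)")
    hid, prov, amap = "", "", None
    points = []
    for ln, raw in enumerate(text[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        try:
            if key == "id":
                hid = parts[1]
            elif key == "provenance":
                prov = parts[1] if len(parts) > 1 else ""
            elif key == "activity_map":
                amap = (float(parts[1]), float(parts[2]))
            elif key == "point":
                kind = check_kind(parts[1])
                x, y, z, tol, w = (float(v) for v in parts[2:7])
                if not tol > 0:
                    raise ValueError(f"tolerance must be > 0, got {tol}")
                points.append(PharmacophorePoint(kind, np.array([x, y, z]), tol, w))
            else:
                raise ValueError(f"unknown record type {key!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{ln}: field error in {key!r} record: {exc}") from exc
    if amap is None:
        raise ValueError(f"{path}: missing activity_map record")
    return Hypothesis(hid, points, amap, prov)


# ---------------------------------------------------------------------------
# Training-set design diagnostics
# ---------------------------------------------------------------------------

def dataset_design_check(records: Iterable[CompoundRecord]) -> DatasetDesignReport:
    """Check a training set against standard pharmacophore design guidelines.

    Guidelines (warnings, never hard failures): at least 16 molecules; an
    activity span of at least 4 orders of magnitude; at least 2 compounds
    in every occupied order-of-magnitude bin.
    """
    recs = list(records)
    vals = [r.pec50_obs for r in recs]
    if any(v is None for v in vals):
        raise ValueError("all records must carry an observed pEC50")
    vals = np.asarray(vals, dtype=float)
    n = len(vals)
    span = float(vals.max() - vals.min()) if n else 0.0
    bins: dict = {}
    for v in vals:
        bins[int(math.floor(v))] = bins.get(int(math.floor(v)), 0) + 1
    warnings = []
    if n < 16:
        warnings.append(f"n < 16 (got {n})")
    if span < 4:
        warnings.append(f"activity span < 4 orders of magnitude (got {span:.2f})")
    for b, c in sorted(bins.items()):
        if c < 2:
            warnings.append(f"order-of-magnitude bin {b} has only {c} compound(s)")
    return DatasetDesignReport(n=n, activity_span=span, per_order_counts=bins, warnings=warnings)
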