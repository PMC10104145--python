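"""Multiplex cytokine plate cleaning.

Raw bead-based multiplex plates arrive as long tables of per-well readings
(pg/mL) with bead counts, in technical triplicate.  Cleaning proceeds in a
fixed order:

1. drop replicates read from fewer than 20 beads;
2. censor readings below the detection limit (3.2 pg/mL) to 0;
3. resolve each sample x cytokine triplicate — a replicate is discarded
   when its distance to the other two exceeds twice their spread — and
   average the survivors;
4. drop whole cytokines that are zero in more than half of all samples in
   a pattern that does not partition between experimental groups.

Every removal is logged so the provenance of each cell in the final
samples x cytokines matrix can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QcError

__all__ = [
    "PLATE_COLUMNS",
    "CytokineMatrix",
    "censor_lod",
    "filter_bead_count",
    "resolve_triplicates",
    "drop_sparse_cytokines",
    "clean_plate",
]

#: required columns of a long-format plate table
PLATE_COLUMNS = [
    "sample_id",
    "genotype",
    "sex",
    "timepoint_days",
    "cytokine",
    "replicate",
    "value_pg_ml",
    "bead_count",
]

METADATA_COLUMNS = ["genotype", "sex", "timepoint_days"]


def _check_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise QcError(f"plate table missing columns {missing}")
    v = plate["value_pg_ml"].to_numpy()
    if not np.all(np.isfinite(v)) or (v < 0).any():
        raise QcError("plate values must be finite and >= 0")
    n_rep = plate.groupby(["sample_id", "cytokine"]).size()
    if (n_rep > 3).any():
        raise QcError("more than 3 replicates for some sample x cytokine")


@dataclass
class CytokineMatrix:
    """Cleaned samples x cytokines concentration table with provenance."""

    values: pd.DataFrame  # samples x cytokines, index = sample_id
    metadata: pd.DataFrame  # per-sample genotype / sex / timepoint_days
    provenance: pd.DataFrame  # per (sample, cytokine): replicate bookkeeping
    dropped: dict = field(default_factory=dict)  # cytokine -> reason

    def __post_init__(self):
        overlap = set(self.dropped) & set(self.values.columns)
        if overlap:
            raise QcError(f"dropped cytokines still present: {sorted(overlap)}")

    def to_csv(self, path) -> None:
        out = self.metadata.join(self.values)
        out.to_csv(path, index_label="sample_id")


def censor_lod(plate: pd.DataFrame, lod: float = 3.2) -> pd.DataFrame:
    """Set readings strictly below the detection limit to exactly 0 pg/mL.

    Adds/updates a boolean ``lod_censored`` column; values at or above the
    limit pass through unchanged.
    """
    if lod <= 0:
        raise QcError("lod must be > 0")
    out = plate.copy()
    below = out["value_pg_ml"] < lod
    out["lod_censored"] = below
    out.loc[below, "value_pg_ml"] = 0.0
    return out


def filter_bead_count(plate: pd.DataFrame, min_beads: int = 20):
    """Remove replicates read from fewer than ``min_beads`` beads.

    Returns ``(filtered_plate, removals)`` where ``removals`` lists the
    discarded rows (for the provenance log).
    """
    low = plate["bead_count"] < min_beads
    removals = plate.loc[low, ["sample_id", "cytokine", "replicate", "bead_count"]]
    return plate.loc[~low].copy(), removals.reset_index(drop=True)


def resolve_triplicates(values):
    """Outlier rule for one cell's technical replicates.

    With three values, a candidate is removed when its smaller distance to
    the other two exceeds twice the absolute difference between those two;
    at most one replicate is removed (if two candidates qualify, the one
    with the larger such distance goes; an exact tie removes none and
    warns).  With one or two values the rule does not apply.

    Returns ``(mean_of_survivors, removed_position_or_None)`` where the
    position indexes into ``values``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise QcError("no surviving replicates")
    if vals.size > 3:
        raise QcError("more than 3 replicates in one cell")
    if not np.all(np.isfinite(vals)):
        raise QcError("non-finite replicate value")
    if vals.size < 3:
        return float(vals.mean()), None
    dists = np.empty(3)
    qualifies = np.empty(3, dtype=bool)
    for i in range(3):
        r = vals[i]
        s, u = vals[[j for j in range(3) if j != i]]
        d = min(abs(r - s), abs(r - u))
        dists[i] = d
        qualifies[i] = d > 2.0 * abs(s - u)
    if not qualifies.any():
        return float(vals.mean()), None
    cand = np.flatnonzero(qualifies)
    if len(cand) > 1:
        best = dists[cand].max()
        top = cand[dists[cand] == best]
        if len(top) > 1:
            warnings.warn(
                "triplicate outlier rule: tie between candidates, none removed"
            )
            return float(vals.mean()), None
        removed = int(top[0])
    else:
        removed = int(cand[0])
    keep = [j for j in range(3) if j != removed]
    return float(vals[keep].mean()), removed


def drop_sparse_cytokines(
    matrix: CytokineMatrix, grouping=("genotype", "timepoint_days")
) -> CytokineMatrix:
    """Drop cytokines mostly at zero unless the zeros track a group.

    A cytokine is dropped iff its zero fraction over all samples exceeds
    one half AND the zeros are not group-partitioned.  "Group-partitioned"
    means some level of a grouping variable has zero-fraction <= 0.5 while
    the remaining samples have zero-fraction > 0.5 — i.e. the cytokine is
    genuinely measurable in at least one experimental group (as with a
    chemokine absent from wild-type animals but present in disease).
    """
    for g in grouping:
        if g not in matrix.metadata.columns:
            raise QcError(f"grouping key {g!r} absent from sample metadata")
    vals = matrix.values
    dropped = dict(matrix.dropped)
    keep = []
    for cyt in vals.columns:
        col = vals[cyt]
        zero_frac = float((col == 0).mean())
        if zero_frac <= 0.5:
            keep.append(cyt)
            continue
        partitioned = False
        for g in grouping:
            for level in matrix.metadata[g].unique():
                in_level = matrix.metadata[g] == level
                zf_in = float((col[in_level.values] == 0).mean())
                rest = col[~in_level.values]
                zf_out = float((rest == 0).mean()) if len(rest) else 1.0
                if zf_in <= 0.5 and zf_out > 0.5:
                    partitioned = True
                    break
            if partitioned:
                break
        if partitioned:
            keep.append(cyt)
        else:
            dropped[cyt] = (
                f"zero in {zero_frac:.0%} of samples, not partitioned by "
                f"{'/'.join(grouping)}"
            )
    return CytokineMatrix(
        values=vals[keep],
        metadata=matrix.metadata,
        provenance=matrix.provenance,
        dropped=dropped,
    )


def clean_plate(
    plate: pd.DataFrame,
    lod: float = 3.2,
    min_beads: int = 20,
    grouping=("genotype", "timepoint_days"),
) -> CytokineMatrix:
    """Full plate-cleaning pipeline: bead filter, LOD censoring, triplicate
    resolution, sparse-cytokine removal.

    Raises :class:`QcError` if any retained cytokine has a sample cell with
    zero surviving replicates (all lost to the bead filter).
    """
    _check_plate(plate)
    filtered, bead_removals = filter_bead_count(plate, min_beads)
    censored = censor_lod(filtered, lod)

    records = []
    for (sid, cyt), grp in censored.groupby(["sample_id", "cytokine"], sort=True):
        vals = grp["value_pg_ml"].to_numpy()
        mean, removed = resolve_triplicates(vals)
        records.append(
            {
                "sample_id": sid,
                "cytokine": cyt,
                "value": mean,
                "n_replicates_in": len(vals),
                "n_replicates_used": len(vals) - (removed is not None),
                "outlier_removed": removed is not None,
                "n_lod_censored": int(grp["lod_censored"].sum()),
            }
        )
    prov = pd.DataFrame.from_records(records)

    meta = (
        plate[["sample_id"] + METADATA_COLUMNS]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .sort_index()
    )
    values = prov.pivot(index="sample_id", columns="cytokine", values="value")
    values = values.reindex(meta.index)
    # preserve the plate's cytokine ordering
    order = [c for c in plate["cytokine"].unique() if c in values.columns]
    values = values[order]
    values.columns.name = None

    all_cells = pd.MultiIndex.from_product(
        [meta.index, order], names=["sample_id", "cytokine"]
    )
    have = pd.MultiIndex.from_frame(prov[["sample_id", "cytokine"]])
    empty = all_cells.difference(have)

    matrix = CytokineMatrix(
        values=values, metadata=meta, provenance=prov,
        dropped={},
    )
    matrix.bead_removals = bead_removals
    matrix = drop_sparse_cytokines(matrix, grouping)
    matrix.bead_removals = bead_removals

    bad = [
        (s, c) for (s, c) in empty if c in matrix.values.columns
    ] + [
        (s, c)
        for c in matrix.values.columns
        for s in matrix.values.index[matrix.values[c].isna()]
    ]
    if bad:
        raise QcError(
            f"cells with zero surviving replicates for retained cytokines: "
            f"{sorted(set(bad))}"
        )
    return matrix
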