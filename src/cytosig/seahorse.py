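"""Mito Stress Test metrics from extracellular-flux OCR traces.

A Mito Stress Test trace has four phases — basal, post-oligomycin,
post-FCCP, post-rotenone/antimycin — from which five mitochondrial
parameters are computed:

=========================  ==================================================
non-mitochondrial          median OCR after rotenone/antimycin A
basal respiration          (median OCR before oligomycin) − non-mito
ATP production             basal respiration − (min OCR after oligomycin)
maximal respiration        (max OCR after FCCP) − non-mito
proton leak                (min OCR after oligomycin) − non-mito
=========================  ==================================================

Two ATP conventions are carried: ``table1_literal`` applies the formulas
above verbatim (ATP + leak = basal − non-mito), while ``pre_oligo_raw``
uses the raw pre-oligomycin median in the ATP formula, restoring the
instrument vendor's identity ATP + leak = basal.  Both are exact algebraic
identities and are asserted in tests.

Well QC excludes non-viable wells (near-zero OCR) and wells where FCCP
failed to raise oxygen consumption.  Per-well traces are protein-
normalized, averaged within each biological replicate (an independent
plate of 5–10 wells), and finally scaled by the replicate's
non-mitochondrial respiration to remove batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, QcError

__all__ = [
    "MitoMetrics",
    "compute_well_metrics",
    "qc_wells",
    "aggregate_and_normalize",
    "compare_groups",
]

PHASES = ["basal", "oligomycin", "fccp", "rotenone_antimycin"]
METRIC_NAMES = ["non_mito", "basal", "atp_production", "maximal", "proton_leak"]
CONVENTIONS = ("table1_literal", "pre_oligo_raw")


@dataclass
class MitoMetrics:
    non_mito: float
    basal: float
    atp_production: float
    maximal: float
    proton_leak: float
    convention: str = "table1_literal"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _phase_values(trace) -> dict:
    """Accept a long DataFrame (phase, ocr) or a dict phase -> values."""
    if isinstance(trace, pd.DataFrame):
        out = {ph: trace.loc[trace["phase"] == ph, "ocr"].to_numpy()
               for ph in PHASES}
    else:
        out = {ph: np.asarray(trace[ph], dtype=float) for ph in PHASES}
    for ph, v in out.items():
        if v.size == 0:
            raise QcError(f"empty {ph} phase")
    return out


def compute_well_metrics(trace, convention: str = "table1_literal") -> MitoMetrics:
    """Five mitochondrial parameters for one well (see module docstring)."""
    if convention not in CONVENTIONS:
        raise ConfigError(f"unknown convention {convention!r}")
    ph = _phase_values(trace)
    non_mito = float(np.median(ph["rotenone_antimycin"]))
    pre_oligo = float(np.median(ph["basal"]))
    min_oligo = float(np.min(ph["oligomycin"]))
    basal = pre_oligo - non_mito
    maximal = float(np.max(ph["fccp"])) - non_mito
    leak = min_oligo - non_mito
    if convention == "table1_literal":
        atp = basal - min_oligo
    else:
        atp = pre_oligo - min_oligo
    m = MitoMetrics(non_mito, basal, atp, maximal, leak, convention)
    if min(basal, maximal, leak, atp) < 0:
        warnings.warn(
            f"negative mitochondrial metric(s) in well trace: {m.as_dict()}"
        )
    return m


def qc_wells(plate: pd.DataFrame, dead_threshold: float = None,
             responder_rule: bool = True):
    """Flag non-viable and FCCP-non-responding wells.

    A well is excluded as "not viable" when its basal-phase median falls
    below ``dead_threshold`` (default: 5% of the plate-wide median basal),
    and as "FCCP non-response" when its maximum post-FCCP OCR does not
    exceed its minimum post-oligomycin OCR.  Returns ``(kept_well_ids,
    exclusions)`` where exclusions is a well -> reason mapping.
    """
    basal_med = (
        plate[plate["phase"] == "basal"].groupby("well")["ocr"].median()
    )
    if dead_threshold is None:
        dead_threshold = 0.05 * float(basal_med.median())
    exclusions = {}
    for well, grp in plate.groupby("well"):
        if basal_med[well] < dead_threshold:
            exclusions[well] = "not viable (near-zero OCR)"
            continue
        if responder_rule:
            fccp_max = grp.loc[grp["phase"] == "fccp", "ocr"].max()
            oligo_min = grp.loc[grp["phase"] == "oligomycin", "ocr"].min()
            if fccp_max <= oligo_min:
                exclusions[well] = "FCCP non-response"
    kept = [w for w in plate["well"].unique() if w not in exclusions]
    if not kept:
        raise QcError("all wells excluded by QC")
    return kept, exclusions


def aggregate_and_normalize(
    plate: pd.DataFrame,
    kept_wells=None,
    convention: str = "table1_literal",
    min_wells: int = 3,
) -> pd.DataFrame:
    """Per-biological-replicate metrics, protein- and batch-normalized.

    Each kept well's OCR is divided by its total protein (µg) before the
    metrics are computed; per-replicate metrics are the means over that
    replicate's kept wells; finally every metric is divided by the
    replicate's non-mitochondrial respiration (which becomes 1), removing
    between-experiment batch effects.  Replicates left with fewer than
    ``min_wells`` wells are flagged (column ``low_n``) with a warning.

    Returns one row per (arm, replicate_id).
    """
    if kept_wells is not None:
        plate = plate[plate["well"].isin(kept_wells)]
    if plate.empty:
        raise QcError("no wells to aggregate")
    rows = []
    for (arm, rep), grp in plate.groupby(["arm", "replicate_id"]):
        well_metrics = []
        for well, wg in grp.groupby("well"):
            wg = wg.assign(ocr=wg["ocr"] / wg["protein_ug"])
            well_metrics.append(compute_well_metrics(wg, convention).as_dict())
        wm = pd.DataFrame(well_metrics)
        n_wells = len(well_metrics)
        if n_wells < min_wells:
            warnings.warn(
                f"replicate {rep} ({arm}): only {n_wells} kept wells"
            )
        agg = wm.mean(axis=0)
        if agg["non_mito"] <= 0:
            raise QcError(
                f"replicate {rep} ({arm}): non-positive non-mitochondrial "
                f"respiration; cannot batch-normalize"
            )
        final = agg / agg["non_mito"]
        rows.append(
            {
                "arm": arm,
                "replicate_id": rep,
                "n_wells": n_wells,
                "low_n": n_wells < min_wells,
                **final.to_dict(),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    replicate_metrics: pd.DataFrame,
    metric: str,
    equal_var: bool = True,
):
    """Two-sided two-sample t-test (pooled-variance by default) on one
    metric between treated and vehicle replicates.

    Returns ``(t, p)``; degenerate input (zero variance in both arms with
    equal means) returns ``(0.0, 1.0)`` with a warning rather than NaN.
    """
    if metric not in replicate_metrics.columns:
        raise ConfigError(f"unknown metric {metric!r}")
    a = replicate_metrics.loc[
        replicate_metrics["arm"] == "treated", metric
    ].to_numpy(dtype=float)
    b = replicate_metrics.loc[
        replicate_metrics["arm"] == "vehicle", metric
    ].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise QcError("need >= 2 biological replicates per arm")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn(f"{metric}: identical degenerate arms; p set to 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
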