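"""nCounter-style count normalization and differential-expression filtering.

The processing chain mirrors the standard digital-counting workflow:
background thresholding (raw counts below 20 raised to 20), housekeeping
gene selection (drop genes with any count under 100, keep those with a
coefficient of variation of 10% or less), a two-step scale-factor
normalization driven first by the positive-control probes and then by the
kept housekeeping genes, and a filtered fold-change table: two-sided
t-test p <= 0.05 on log2 counts, excluding genes whose mean normalized
counts in both arms sit below 30 (too close to the background threshold
to trust).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FitError

__all__ = [
    "CountMatrix",
    "threshold_background",
    "select_housekeepers",
    "normalize_two_step",
    "differential_expression",
    "run_de",
]

GENE_CLASSES = ("endogenous", "housekeeping", "positive", "negative")


@dataclass
class CountMatrix:
    """Genes x samples counts plus probe-class and sample annotations."""

    counts: pd.DataFrame  # genes x samples
    gene_class: pd.Series  # per gene, one of GENE_CLASSES
    samples: pd.DataFrame  # per sample: arm (treated/vehicle), cell_type

    def __post_init__(self):
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.issubdtype(c.dtype, np.number):
            raise ConfigError("counts must be nonnegative numbers")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ConfigError(f"unknown gene classes {sorted(bad)}")
        for cls in ("housekeeping", "positive"):
            if (self.gene_class == cls).sum() < 1:
                raise ConfigError(f"need at least one {cls} probe")

    def genes_of(self, cls: str) -> list:
        return self.gene_class.index[self.gene_class == cls].tolist()

    @classmethod
    def from_csv(cls, counts_path, samples_path) -> "CountMatrix":
        """Load from a genes x samples CSV carrying a ``gene_class`` column
        and a per-sample annotation CSV (index, arm, cell_type)."""
        df = pd.read_csv(counts_path, index_col=0)
        gene_class = df.pop("gene_class")
        samples = pd.read_csv(samples_path, index_col=0)
        return cls(counts=df, gene_class=gene_class, samples=samples)

    def to_csv(self, counts_path, samples_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_class", self.gene_class)
        out.to_csv(counts_path, index_label="gene")
        if samples_path is not None:
            self.samples.to_csv(samples_path, index_label="sample")


def threshold_background(counts: pd.DataFrame, floor: int = 20) -> pd.DataFrame:
    """Raise every raw count below ``floor`` to exactly ``floor``.

    Applied before normalization so fold changes of unexpressed genes are
    computed against a common baseline.  Idempotent.
    """
    return counts.clip(lower=floor)


def select_housekeepers(
    hk_counts: pd.DataFrame, min_count: float = 100, max_cv: float = 0.10
) -> list:
    """Pick stable housekeeping genes for normalization.

    Genes with any sample count below ``min_count`` are removed first;
    among the rest, genes whose coefficient of variation (sample SD over
    mean, across samples) is at most ``max_cv`` are kept.
    """
    ok = hk_counts.index[(hk_counts >= min_count).all(axis=1)]
    sub = hk_counts.loc[ok]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    kept = cv.index[cv <= max_cv].tolist()
    if not kept:
        raise FitError(
            "no housekeeping genes survived selection; relax min_count/max_cv "
            "or supply a manual list"
        )
    return kept


def _geomean(df: pd.DataFrame) -> pd.Series:
    vals = df.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise FitError("geometric mean undefined: zero or negative count")
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=df.columns)


def _scale_factors(ref_counts: pd.DataFrame) -> pd.Series:
    # per-sample factor = (geometric mean over samples of the per-sample
    # reference geomeans) / (this sample's reference geomean); the factors'
    # geometric mean is 1 by construction
    g = _geomean(ref_counts)
    target = float(np.exp(np.log(g).mean()))
    return target / g


def normalize_two_step(counts: CountMatrix, kept_hk: list) -> pd.DataFrame:
    """Positive-control then housekeeping scale-factor normalization.

    Step 1 scales each sample by the ratio of the across-sample average
    positive-control geometric mean to its own; step 2 repeats the
    construction with the kept housekeeping genes on the step-1 output.
    Returns the normalized genes x samples table (floats).
    """
    raw = counts.counts.astype(float)
    f1 = _scale_factors(raw.loc[counts.genes_of("positive")])
    step1 = raw.mul(f1, axis=1)
    f2 = _scale_factors(step1.loc[kept_hk])
    return step1.mul(f2, axis=1)


def differential_expression(
    norm_counts: pd.DataFrame,
    arms: pd.Series,
    gene_class: pd.Series = None,
    p_max: float = 0.05,
    min_mean: float = 30.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and significance filters.

    For each endogenous gene: log2FC = log2(mean treated / mean vehicle)
    of normalized counts; p from a two-sided t-test on log2 counts (Welch
    by default; ``equal_var=True`` for the classical pooled test).  A gene
    is reported significant when p <= ``p_max`` and NOT both arm means are
    below ``min_mean``.

    Returns a table with log2fc, pvalue, arm means, per-filter booleans
    and a human-readable ``reason`` for every excluded gene.
    """
    arms = arms.reindex(norm_counts.columns)
    t_cols = arms.index[arms == "treated"]
    v_cols = arms.index[arms == "vehicle"]
    if len(t_cols) < 2 or len(v_cols) < 2:
        raise FitError("each arm needs >= 2 samples for a t-test")
    sub = norm_counts
    if gene_class is not None:
        sub = norm_counts.loc[gene_class == "endogenous"]
    mt = sub[t_cols].mean(axis=1)
    mv = sub[v_cols].mean(axis=1)
    log2fc = np.log2(mt / mv)
    lt = np.log2(sub[t_cols].to_numpy(dtype=float))
    lv = np.log2(sub[v_cols].to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(lt, lv, axis=1, equal_var=equal_var)
    pvals = pd.Series(pvals, index=sub.index)
    pass_p = (pvals <= p_max) & pvals.notna()
    pass_mean = ~((mt < min_mean) & (mv < min_mean))
    reasons = pd.Series("", index=sub.index, dtype=object)
    reasons[~pass_p] = f"p > {p_max} (or undefined)"
    reasons[pass_p & ~pass_mean] = f"both arm means < {min_mean}"
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "mean_treated": mt,
            "mean_vehicle": mv,
            "pass_p": pass_p,
            "pass_mean": pass_mean,
            "significant": pass_p & pass_mean,
            "reason": reasons,
        }
    )
    out.index.name = "gene"
    return out


def run_de(
    counts: CountMatrix,
    cell_type: str = None,
    floor: int = 20,
    hk_min: float = 100,
    hk_cv: float = 0.10,
    p_max: float = 0.05,
    min_mean: float = 30.0,
    equal_var: bool = False,
):
    """Full chain: threshold -> housekeeping selection -> normalize -> DE.

    Normalization and testing are confined to one ``cell_type`` (required
    when the matrix mixes several).  Returns ``(de_table, normalized,
    kept_housekeepers)``.
    """
    samples = counts.samples
    if cell_type is not None:
        keep = samples.index[samples["cell_type"] == cell_type]
        if len(keep) == 0:
            raise ConfigError(f"no samples with cell_type {cell_type!r}")
        counts = CountMatrix(
            counts=counts.counts[keep],
            gene_class=counts.gene_class,
            samples=samples.loc[keep],
        )
    elif samples["cell_type"].nunique() > 1:
        raise ConfigError(
            "matrix mixes cell types; pass cell_type to normalize separately"
        )
    thresholded = threshold_background(counts.counts, floor)
    work = CountMatrix(
        counts=thresholded, gene_class=counts.gene_class, samples=counts.samples
    )
    kept_hk = select_housekeepers(
        thresholded.loc[counts.genes_of("housekeeping")], hk_min, hk_cv
    )
    norm = normalize_two_step(work, kept_hk)
    de = differential_expression(
        norm,
        counts.samples["arm"],
        counts.gene_class,
        p_max=p_max,
        min_mean=min_mean,
        equal_var=equal_var,
    )
    return de, norm, kept_hk
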