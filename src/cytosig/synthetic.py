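"""Synthetic datasets with known ground truth for every pipeline stage.

Three generators emulate the structure of the study's three data streams:

* a bead-based multiplex cytokine plate over a 2-genotype x 4-timepoint x
  2-sex design with technical triplicates, detection-limit censoring, and
  occasional low-bead or outlier replicates;
* an nCounter-style count matrix with endogenous, housekeeping, positive-
  and negative-control probes and planted differentially expressed genes;
* extracellular-flux oxygen-consumption traces with the four Mito Stress
  Test phases, planted dead wells and FCCP non-responders.

Cytokine concentrations follow a log-normal model: a per-cytokine baseline,
an aging slope shared by both genotypes, a disease slope applied only to
transgenic animals for the planted signature cytokines, one shared latent
"immune activation" factor that induces the inter-cytokine correlation a
latent-variable model exploits, and i.i.d. log-scale noise.  Univariate
effects are therefore modest while the multivariate signal is strong.

All randomness flows through one ``numpy.random.Generator`` constructed
from the seed; identical configuration and seed give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "PANEL_32",
    "CytokineSimConfig",
    "GroundTruth",
    "gen_cytokine_study",
    "gen_nanostring_counts",
    "gen_ocr_traces",
]

#: 32-plex mouse cytokine/chemokine panel analyte names
PANEL_32 = [
    "Eotaxin", "G-CSF", "GM-CSF", "IFN-g", "IL-1a", "IL-1b", "IL-2", "IL-3",
    "IL-4", "IL-5", "IL-6", "IL-7", "IL-9", "IL-10", "IL-12p40", "IL-12p70",
    "IL-13", "IL-15", "IL-17", "IP-10", "KC", "LIF", "LIX", "MCP-1",
    "M-CSF", "MIG", "MIP-1a", "MIP-1b", "MIP-2", "RANTES", "TNF-a", "VEGF",
]

OCR_PHASES = ["basal", "oligomycin", "fccp", "rotenone_antimycin"]


@dataclass
class CytokineSimConfig:
    """Study-design and noise parameters for the cytokine-plate generator.

    ``effect_size`` is the log-scale slope, per unit scaled time (t/180
    days), added to (up) or subtracted from (down) signature cytokines in
    transgenic animals only.  ``aging_effects`` are per-cytokine log-slopes
    applied to all animals.  ``latent_loadings`` couple every cytokine to
    one shared standard-normal per-animal factor.
    """

    n_cytokines: int = 32
    timepoints: Sequence[int] = (30, 60, 120, 180)
    n_per_group: int = 10  # animals per genotype x timepoint
    signature_up: Optional[Sequence[str]] = None  # default: IFN-g, IP-10, IL-9
    signature_down: Optional[Sequence[str]] = None  # default: IL-2, IL-1a
    effect_size: float = 1.0
    aging_effects: Optional[dict] = None  # cytokine -> log-slope, default none
    latent_loadings: float | dict = 0.5
    noise_sd: float = 0.3
    lod: float = 3.2
    triplicate_cv: float = 0.05
    p_low_bead: float = 0.01
    p_outlier: float = 0.01
    baseline_log_mean: float = np.log(50.0)
    baseline_log_sd: float = 0.5
    seed: int = 0

    def cytokine_names(self) -> list:
        if self.n_cytokines == len(PANEL_32):
            return list(PANEL_32)
        return [f"CYT{j + 1:02d}" for j in range(self.n_cytokines)]

    def validate(self) -> None:
        names = set(self.cytokine_names())
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.lod <= 0:
            raise ConfigError("lod must be > 0")
        for f in ("p_low_bead", "p_outlier"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigError(f"{f} must lie in [0, 1]")
        up = set(self.resolved_signature()[0])
        down = set(self.resolved_signature()[1])
        if up & down:
            raise ConfigError(
                f"signature_up and signature_down overlap: {sorted(up & down)}"
            )
        if not (up | down) <= names:
            raise ConfigError(
                f"signature names not on the panel: {sorted((up | down) - names)}"
            )

    def resolved_signature(self):
        names = self.cytokine_names()
        up = self.signature_up
        down = self.signature_down
        if up is None:
            up = ["IFN-g", "IP-10", "IL-9"] if "IFN-g" in names else names[:3]
        if down is None:
            down = ["IL-2", "IL-1a"] if "IL-2" in names else names[3:5]
        return list(up), list(down)


@dataclass
class GroundTruth:
    """What was planted, for checking recovery downstream."""

    signature: dict = field(default_factory=dict)  # cytokine -> +1 / -1
    latent_factors: Optional[pd.Series] = None  # per sample
    replicate_flags: Optional[pd.DataFrame] = None  # low_bead / outlier rows
    de_genes: dict = field(default_factory=dict)  # gene -> true log2 FC
    ocr_wells: Optional[pd.DataFrame] = None  # per-well flags + phase means

    def to_json(self, path) -> None:
        d = {"signature": self.signature, "de_genes": self.de_genes}
        if self.latent_factors is not None:
            d["latent_factors"] = self.latent_factors.to_dict()
        if self.replicate_flags is not None:
            d["replicate_flags"] = self.replicate_flags.to_dict(orient="records")
        if self.ocr_wells is not None:
            d["ocr_wells"] = self.ocr_wells.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def gen_cytokine_study(config: CytokineSimConfig):
    """Simulate one multiplex plate for the full longitudinal design.

    Returns ``(plate, truth)``: a long-format table (one row per
    sample x cytokine x replicate, with bead counts and metadata) and the
    planted ground truth.  Readings below the detection limit are reported
    as simulated — censoring is the cleaning pipeline's job.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.cytokine_names()
    p = config.n_cytokines
    up, down = config.resolved_signature()
    sig_slope = np.zeros(p)
    for c in up:
        sig_slope[names.index(c)] = config.effect_size
    for c in down:
        sig_slope[names.index(c)] = -config.effect_size
    aging = np.zeros(p)
    for c, v in (config.aging_effects or {}).items():
        aging[names.index(c)] = v
    if isinstance(config.latent_loadings, dict):
        load = np.array([config.latent_loadings.get(c, 0.0) for c in names])
    else:
        load = np.full(p, float(config.latent_loadings))

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, p)

    rows_meta = []
    for genotype in ("AD", "WT"):
        for t in config.timepoints:
            for k in range(config.n_per_group):
                rows_meta.append(
                    {
                        "sample_id": f"{genotype}_{t:03d}d_{k + 1:02d}",
                        "genotype": genotype,
                        "sex": "F" if k % 2 else "M",
                        "timepoint_days": t,
                    }
                )
    meta = pd.DataFrame(rows_meta)
    n = len(meta)
    ts = meta["timepoint_days"].to_numpy() / 180.0
    is_ad = (meta["genotype"] == "AD").to_numpy().astype(float)
    factor = rng.normal(0.0, 1.0, n)
    noise = rng.normal(0.0, config.noise_sd, (n, p))
    log_x = (
        baseline
        + np.outer(ts, aging)
        + np.outer(is_ad * ts, sig_slope)
        + np.outer(factor, load)
        + noise
    )
    true_conc = np.exp(log_x)

    # technical triplicates: multiplicative log-normal replicate noise
    sigma_rep = (
        np.sqrt(np.log1p(config.triplicate_cv**2)) if config.triplicate_cv > 0 else 0.0
    )
    n_rep = 3
    rep_noise = (
        np.exp(rng.normal(0.0, sigma_rep, (n, p, n_rep))) if sigma_rep > 0
        else np.ones((n, p, n_rep))
    )
    values = true_conc[:, :, None] * rep_noise

    low_bead = rng.random((n, p, n_rep)) < config.p_low_bead
    outlier = (rng.random((n, p, n_rep)) < config.p_outlier) & ~low_bead
    out_factor = rng.choice([3.0, 1.0 / 3.0], size=(n, p, n_rep))
    values = np.where(outlier, values * out_factor, values)

    # bead counts: Poisson(50) floored at the QC limit normally, Poisson(8)
    # capped just below it for planted low-bead replicates, so planted flags
    # and the <20-bead rule coincide exactly
    beads = np.maximum(rng.poisson(50, (n, p, n_rep)), 20)
    beads_low = np.minimum(rng.poisson(8, (n, p, n_rep)), 19)
    beads = np.where(low_bead, beads_low, beads)

    si, ci, ri = np.meshgrid(np.arange(n), np.arange(p), np.arange(n_rep),
                             indexing="ij")
    plate = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy()[si.ravel()],
            "genotype": meta["genotype"].to_numpy()[si.ravel()],
            "sex": meta["sex"].to_numpy()[si.ravel()],
            "timepoint_days": meta["timepoint_days"].to_numpy()[si.ravel()],
            "cytokine": np.array(names)[ci.ravel()],
            "replicate": ri.ravel() + 1,
            "value_pg_ml": values.ravel(),
            "bead_count": beads.ravel(),
        }
    )

    flags = pd.DataFrame(
        {
            "sample_id": plate["sample_id"],
            "cytokine": plate["cytokine"],
            "replicate": plate["replicate"],
            "low_bead": low_bead.ravel(),
            "outlier": outlier.ravel(),
        }
    )
    flags = flags[flags["low_bead"] | flags["outlier"]].reset_index(drop=True)

    truth = GroundTruth(
        signature={**{c: 1 for c in up}, **{c: -1 for c in down}},
        latent_factors=pd.Series(factor, index=meta["sample_id"].to_numpy()),
        replicate_flags=flags,
    )
    return plate, truth


#: fixed positive-control concentration series (arbitrary units), standard
#: six-step fourfold design
POS_CONTROL_CONC = [128.0, 32.0, 8.0, 2.0, 0.5, 0.125]


def gen_nanostring_counts(
    n_genes: int = 40,
    n_hk: int = 10,
    n_pos: int = 6,
    n_neg: int = 6,
    n_samples_per_arm: int = 3,
    de_genes: Optional[dict] = None,
    dispersion: float = 0.005,
    scale_sd: float = 0.05,
    cell_type: str = "neuron",
    seed: int = 0,
):
    """Simulate an nCounter-style count matrix with planted DE genes.

    ``de_genes`` maps endogenous gene indices (0-based) to true log2 fold
    changes (treated vs vehicle).  Endogenous and housekeeping counts are
    negative-binomial around per-sample-scaled means (variance
    m + dispersion·m²; the Poisson limit is used when dispersion is ~0);
    positive-control probes follow the fixed geometric concentration
    series.  Returns ``(CountMatrix, GroundTruth)``.
    """
    from .nanostring import CountMatrix  # deferred: avoid import cycle

    if min(n_genes, n_hk, n_pos, n_neg) <= 0:
        raise ConfigError("all probe-class counts must be positive")
    if n_samples_per_arm < 2:
        raise ConfigError(
            "n_samples_per_arm must be >= 2 (DE p-values undefined otherwise)"
        )
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    de_genes = dict(de_genes or {})

    genes = (
        [f"GENE{j + 1:04d}" for j in range(n_genes)]
        + [f"HK{j + 1:02d}" for j in range(n_hk)]
        + [f"POS_{chr(65 + j % 26)}{j // 26 or ''}" for j in range(n_pos)]
        + [f"NEG{j + 1:02d}" for j in range(n_neg)]
    )
    gene_class = (
        ["endogenous"] * n_genes + ["housekeeping"] * n_hk
        + ["positive"] * n_pos + ["negative"] * n_neg
    )
    samples = [f"T{i + 1}" for i in range(n_samples_per_arm)] + [
        f"V{i + 1}" for i in range(n_samples_per_arm)
    ]
    arms = ["treated"] * n_samples_per_arm + ["vehicle"] * n_samples_per_arm
    n_s = len(samples)

    base = rng.lognormal(np.log(200.0), 1.0, n_genes)
    hk_mean = rng.lognormal(np.log(1000.0), 0.5, n_hk)
    scale = rng.lognormal(0.0, scale_sd, n_s) if scale_sd > 0 else np.ones(n_s)

    lfc = np.zeros(n_genes)
    for g, v in de_genes.items():
        lfc[int(g)] = float(v)

    def draw(mean):
        mean = np.maximum(mean, 1e-9)
        if dispersion <= 1e-8:
            return rng.poisson(mean)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mean))

    mu_endo = np.empty((n_genes, n_s))
    for i in range(n_s):
        arm_shift = 2.0 ** lfc if arms[i] == "treated" else np.ones(n_genes)
        mu_endo[:, i] = base * arm_shift * scale[i]
    counts = np.vstack(
        [
            draw(mu_endo),
            draw(np.outer(hk_mean, scale)),
            draw(np.outer(
                np.resize(POS_CONTROL_CONC, n_pos), scale) * 100.0),
            draw(np.full((n_neg, n_s), 5.0)),
        ]
    )
    mat = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples, dtype=int),
        gene_class=pd.Series(gene_class, index=genes, name="gene_class"),
        samples=pd.DataFrame(
            {"arm": arms, "cell_type": cell_type}, index=samples
        ),
    )
    truth = GroundTruth(
        de_genes={genes[int(g)]: float(v) for g, v in de_genes.items()}
    )
    return mat, truth


def gen_ocr_traces(
    n_wells_per_arm: int = 8,
    phase_means: Optional[dict] = None,
    n_meas_per_phase: int = 3,
    noise_sd: float = 2.0,
    p_dead: float = 0.0,
    p_nonresponder: float = 0.0,
    protein_cv: float = 0.1,
    n_replicates_per_arm: int = 1,
    protein_mean_ug: float = 10.0,
    seed: int = 0,
):
    """Simulate a Mito Stress Test plate.

    ``phase_means`` maps arm ("treated"/"vehicle") to the four true phase
    means (basal, post-oligomycin, post-FCCP, post-rotenone/antimycin) in
    pmol O2/min.  Each well's trace is scaled by its protein factor
    (protein / mean protein) plus Gaussian noise.  Dead wells read
    near-zero everywhere; non-responder wells have their FCCP phase pulled
    below the oligomycin phase.  Wells are assigned round-robin to
    ``n_replicates_per_arm`` biological replicates.

    Returns ``(plate, truth)`` — a long table (well, arm, replicate_id,
    phase, measurement_index, ocr, protein_ug) plus per-well truth flags.
    """
    if phase_means is None:
        phase_means = {
            "vehicle": (100.0, 40.0, 150.0, 20.0),
            "treated": (75.0, 32.0, 110.0, 20.0),
        }
    for arm, pm in phase_means.items():
        if len(pm) != 4:
            raise ConfigError(f"phase_means[{arm!r}] must have 4 entries")
        if min(pm) < 0:
            raise ConfigError(f"phase_means[{arm!r}] contains a negative mean")
    for nm, v in (("p_dead", p_dead), ("p_nonresponder", p_nonresponder)):
        if not 0 <= v <= 1:
            raise ConfigError(f"{nm} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for arm in sorted(phase_means):
        pm = np.asarray(phase_means[arm], dtype=float)
        for w in range(n_wells_per_arm):
            well = f"{arm[:1].upper()}{w + 1:02d}"
            rep = f"{arm[:1].upper()}R{w % n_replicates_per_arm + 1}"
            protein = protein_mean_ug * max(
                1.0 + protein_cv * rng.normal(), 0.05
            )
            pfac = protein / protein_mean_ug
            dead = rng.random() < p_dead
            nonresp = (not dead) and rng.random() < p_nonresponder
            means = pm.copy()
            if nonresp:
                means[2] = 0.8 * means[1]  # FCCP fails to uncouple
            if dead:
                means = np.full(4, 0.2)
            idx = 0
            for ph, m in zip(OCR_PHASES, means):
                for _ in range(n_meas_per_phase):
                    idx += 1
                    ocr = m * pfac + noise_sd * rng.normal()
                    if dead:
                        ocr = abs(0.2 + 0.05 * rng.normal())
                    rows.append(
                        {
                            "well": well,
                            "arm": arm,
                            "replicate_id": rep,
                            "phase": ph,
                            "measurement_index": idx,
                            "ocr": ocr,
                            "protein_ug": protein,
                        }
                    )
            truth_rows.append(
                {
                    "well": well,
                    "arm": arm,
                    "dead": dead,
                    "nonresponder": nonresp,
                    **{f"mean_{ph}": m for ph, m in zip(OCR_PHASES, means)},
                }
            )
    plate = pd.DataFrame(rows)
    truth = GroundTruth(ocr_wells=pd.DataFrame(truth_rows))
    return plate, truth
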