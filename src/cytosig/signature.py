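"""Signed cytokine-signature extraction and cross-model comparison.

The signature of a model is the set of cytokines whose VIP score strictly
exceeds 1 (an above-average contribution, since mean squared VIP is 1 by
construction), each reported with its loading on the first latent variable
of the orthogonalized model.  Under the fixed orientation — the positive
LV1 pole is the older timepoint / disease class — a positive loading reads
"up-regulated with the outcome" and a negative loading "down-regulated".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError
from .pls import PlsModel, vip_scores

__all__ = ["Signature", "extract_signature", "compare_signatures"]


@dataclass
class Signature:
    """Ordered signature members plus provenance of the model behind them."""

    members: pd.DataFrame  # cytokine, lv1_loading, vip, direction
    panel: list  # full predictor panel of the source model
    provenance: dict = field(default_factory=dict)  # response, A, p, score...

    @property
    def up(self) -> list:
        return self.members.loc[
            self.members["direction"] == "up", "cytokine"
        ].tolist()

    @property
    def down(self) -> list:
        return self.members.loc[
            self.members["direction"] == "down", "cytokine"
        ].tolist()

    def directions(self) -> dict:
        return dict(
            zip(self.members["cytokine"], np.where(
                self.members["direction"] == "up", 1, -1))
        )

    def __len__(self) -> int:
        return len(self.members)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "members": self.members.to_dict(orient="records"),
                    "panel": self.panel,
                    "provenance": self.provenance,
                },
                fh,
                indent=1,
                default=str,
            )


def extract_signature(
    model: PlsModel,
    vip: np.ndarray = None,
    threshold: float = 1.0,
    provenance: dict = None,
) -> Signature:
    """Cytokines with VIP strictly above ``threshold``, with signed LV1 loadings.

    The model must be orthogonalized (or have a single latent variable, in
    which case there is nothing to rotate) so its LV1 loadings carry the
    response-predictive covariance.  Members are sorted by |LV1 loading|,
    descending.  An empty signature is allowed but warned about.
    """
    if not model.orthogonalized and model.n_lv > 1:
        raise FitError(
            "extract_signature requires an orthogonalized model (or A=1)"
        )
    if vip is None:
        vip = vip_scores(model)
    vip = np.asarray(vip, dtype=float)
    lv1 = model.x_loadings[:, 0]
    mask = vip > threshold
    df = pd.DataFrame(
        {
            "cytokine": np.asarray(model.predictors, dtype=object)[mask],
            "lv1_loading": lv1[mask],
            "vip": vip[mask],
        }
    )
    df["direction"] = np.where(df["lv1_loading"] >= 0, "up", "down")
    df = df.reindex(
        df["lv1_loading"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    if df.empty:
        warnings.warn("empty signature: no predictor exceeded the VIP threshold")
    return Signature(
        members=df, panel=list(model.predictors), provenance=provenance or {}
    )


def compare_signatures(a: Signature, b: Signature) -> dict:
    """Overlap report between two signatures on a shared panel.

    Reports shared and unique members, and splits the shared ones into
    direction agreements and reversals (up in one model, down in the
    other).  Disjoint panels indicate the models were not built on the
    same assay and raise.
    """
    if not set(a.panel) & set(b.panel):
        raise FitError("signatures come from disjoint cytokine panels")
    da, db = a.directions(), b.directions()
    shared = sorted(set(da) & set(db))
    return {
        "shared": shared,
        "only_a": sorted(set(da) - set(db)),
        "only_b": sorted(set(db) - set(da)),
        "agreements": [c for c in shared if da[c] == db[c]],
        "reversals": [c for c in shared if da[c] != db[c]],
    }
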