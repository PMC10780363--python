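"""Significance-based feature screening into the four input combinations.

Each parameter class (empirical, dual-band, trilateral) is screened
independently against a leaf layer's nitrogen vector by the two-sided
Pearson test; members with p < alpha survive, ordered by descending
|r|.  The mixed combination is the union of the three class selections,
preserving class order.  Display labels: Combination 1 = empirical,
2 = dual-band, 3 = trilateral, 4 = mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LAYERS, PARAMETER_CLASSES, ParameterMatrix
from .bandsearch import pearson_r_with_p

logger = logging.getLogger(__name__)

COMBINATION_LABELS = {
    "empirical": "Combination 1",
    "dualband": "Combination 2",
    "trilateral": "Combination 3",
    "mixed": "Combination 4",
}
#: Class order used when forming the mixed combination.
MIXED_ORDER = ("empirical", "dualband", "trilateral")


@dataclass
class CombinationSpec:
    """One screened input combination for one leaf layer."""

    name: str  # empirical | dualband | trilateral | mixed
    layer: str
    members: list[str]
    alpha: float = 0.05
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)  # member, r, p

    @property
    def label(self) -> str:
        return COMBINATION_LABELS[self.name]

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "label": self.label,
            "layer": self.layer,
            "alpha": self.alpha,
            "members": list(self.members),
            "r": {m: float(r) for m, r in zip(self.stats["member"], self.stats["r"])},
            "p": {m: float(p) for m, p in zip(self.stats["member"], self.stats["p"])},
        }


def screen_class(
    params: ParameterMatrix,
    target: np.ndarray,
    class_tag: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Members of one class with p < alpha, sorted by descending |r|."""
    if class_tag not in PARAMETER_CLASSES:
        raise ValueError(f"unknown class tag {class_tag!r}")
    target = np.asarray(target, dtype=float)
    if target.size != len(params.sample_ids):
        raise ValueError("target must align with parameter rows")
    rows = []
    for name in params.columns_of(class_tag):
        r, p = pearson_r_with_p(params.values[name].to_numpy(), target)
        if np.isfinite(p) and p < alpha:
            rows.append({"member": name, "r": r, "p": p})
    if not rows:
        logger.warning(
            "screening selected no %s parameters at alpha=%g", class_tag, alpha
        )
        return pd.DataFrame(columns=["member", "r", "p"])
    frame = pd.DataFrame(rows)
    return (
        frame.reindex(frame["r"].abs().sort_values(ascending=False, kind="stable").index)
        .reset_index(drop=True)
    )


def layer_target(lnc: pd.DataFrame, layer: str, sample_ids: list[str]) -> np.ndarray:
    """Nitrogen vector for one layer, aligned to the given sample order."""
    sub = lnc[lnc["layer"] == layer].set_index("sample_id")["lnc"]
    missing = [s for s in sample_ids if s not in sub.index]
    if missing:
        raise ValueError(f"layer {layer} missing for samples {missing[:5]}")
    return sub.loc[sample_ids].to_numpy(dtype=float)


def build_combinations(
    params_by_layer: dict[str, ParameterMatrix],
    lnc: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CombinationSpec]:
    """All 12 combinations: 4 strategies x 3 leaf layers.

    ``params_by_layer`` maps each layer to the parameter matrix whose
    dual-band columns were optimized for that layer (a single shared
    matrix may be passed for every layer to emulate shared pairs).
    """
    combos: list[CombinationSpec] = []
    for layer in LAYERS:
        params = params_by_layer[layer]
        target = layer_target(lnc, layer, params.sample_ids)
        per_class: dict[str, pd.DataFrame] = {}
        for tag in MIXED_ORDER:
            stats = screen_class(params, target, tag, alpha=alpha)
            per_class[tag] = stats
            combos.append(
                CombinationSpec(
                    name=tag,
                    layer=layer,
                    members=list(stats["member"]),
                    alpha=alpha,
                    stats=stats,
                )
            )
        mixed_stats = pd.concat(
            [per_class[tag] for tag in MIXED_ORDER], ignore_index=True
        )
        combos.append(
            CombinationSpec(
                name="mixed",
                layer=layer,
                members=list(mixed_stats["member"]) if len(mixed_stats) else [],
                alpha=alpha,
                stats=mixed_stats,
            )
        )
    return combos
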