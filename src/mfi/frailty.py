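"""Frailty-index scoring and categorization.

The multimorbidity frailty index (mFI) of a person is the unweighted
proportion of catalog deficits present::

    mFI = (number of deficits present) / (number of catalog items)

so it lies in [0, 1] and larger values indicate a frailer state. The primary
categorization uses fixed cut points at 0.0625, 0.125 and 0.1875 — the 2/32,
4/32 and 6/32 multiples of a 32-item catalog — with right-closed intervals:
fit = [0, 0.0625], mild = (0.0625, 0.125], moderate = (0.125, 0.1875],
severe = (0.1875, 1]. Only the severe boundary is unambiguous in the
field's usual phrasing ("> 0.1875"), which implies cut points belong to the
lower category; we apply that rule uniformly. Quantile categorization
(tertile/quartile/quintile) is available as a sensitivity scheme, with ties
at a cut point assigned to the lower group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deficits import DeficitCatalog

logger = logging.getLogger(__name__)

DEFAULT_CUT_POINTS = (0.0625, 0.125, 0.1875)
CATEGORY_LABELS = ("fit", "mild", "moderate", "severe")


@dataclass(frozen=True)
class CategoryScheme:
    """Fixed-threshold or quantile categorization of mFI scores."""

    kind: str = "fixed_thresholds"  # or "quantile"
    cut_points: tuple[float, ...] = DEFAULT_CUT_POINTS
    n_groups: int = 4

    def __post_init__(self):
        if self.kind not in ("fixed_thresholds", "quantile"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "fixed_thresholds":
            cuts = self.cut_points
            if any(not 0 < c < 1 for c in cuts) or any(
                a >= b for a, b in zip(cuts, cuts[1:])
            ):
                raise ValueError("cut_points must be strictly increasing within (0,1)")
        elif self.n_groups < 2:
            raise ValueError("quantile scheme needs n_groups >= 2")


def compute_mfi(presence: pd.DataFrame, catalog: DeficitCatalog) -> pd.DataFrame:
    """Score every presence-matrix row against the catalog.

    Columns outside the catalog are ignored; all catalog roots must be
    present as columns. Returns ``person_id, deficit_count, total_items,
    mfi`` with ``mfi = deficit_count / total_items`` exactly.
    """
    if catalog.total_items == 0:
        raise ValueError("cannot score against an empty deficit catalog")
    missing = [r for r in catalog.selected_roots if r not in presence.columns]
    if missing:
        raise ValueError(f"presence matrix lacks catalog roots: {missing[:5]}")
    counts = presence[catalog.selected_roots].to_numpy().sum(axis=1)
    return pd.DataFrame(
        {
            "person_id": presence.index.to_numpy(),
            "deficit_count": counts.astype(int),
            "total_items": catalog.total_items,
            "mfi": counts / catalog.total_items,
        }
    )


def categorize_fixed(mfi, cut_points=DEFAULT_CUT_POINTS) -> pd.Categorical:
    """Assign fit/mild/moderate/severe with right-closed intervals.

    A score exactly at a cut point belongs to the lower category; with the
    default cut points, severe <=> mfi > 0.1875.
    """
    if len(cut_points) != 3:
        raise ValueError("fixed-threshold scheme uses 3 cut points for 4 categories")
    idx = np.searchsorted(np.asarray(cut_points), np.asarray(mfi, dtype=float), side="left")
    return pd.Categorical.from_codes(
        idx, categories=list(CATEGORY_LABELS), ordered=True
    )


def categorize_quantile(scores, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Ordinal group 0..k-1 per score from empirical quantile cut points.

    Ties at a cut point go to the lower group; with heavy ties (e.g. many
    zero scores) duplicate cut points are collapsed — the number of distinct
    groups may then be below ``n_groups`` and group sizes unbalanced, which
    is logged. Returns ``(group_codes, cut_points_used)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute quantiles of an empty score set")
    qs = np.arange(1, n_groups) / n_groups
    cuts = np.unique(np.quantile(scores, qs))
    if len(cuts) < n_groups - 1:
        logger.warning(
            "quantile categorization collapsed to %d group boundaries "
            "(heavy ties); group sizes will be unbalanced",
            len(cuts),
        )
    codes = np.searchsorted(cuts, scores, side="left")
    sizes = np.bincount(codes, minlength=len(cuts) + 1)
    logger.info("quantile group sizes: %s", sizes.tolist())
    return codes, cuts


def score_frailty(
    presence: pd.DataFrame,
    catalog: DeficitCatalog,
    scheme: CategoryScheme = CategoryScheme(),
) -> pd.DataFrame:
    """Convenience: mFI scores plus a ``category`` column under ``scheme``."""
    scores = compute_mfi(presence, catalog)
    if scheme.kind == "fixed_thresholds":
        scores["category"] = categorize_fixed(scores["mfi"], scheme.cut_points)
    else:
        codes, _ = categorize_quantile(scores["mfi"].to_numpy(), scheme.n_groups)
        scores["category"] = pd.Categorical.from_codes(
            codes,
            categories=[f"group_{g}" for g in range(int(codes.max()) + 1)],
            ordered=True,
        )
    return scores
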