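"""Cell-type enrichment in spatial communities and histology groups.

For each category (community or histopathological label) and cell type, a
one-sided Welch t-test asks whether the type's per-spot weights are greater
inside the category than in the background spots. The parenchymal
background rule removes spots of other parenchymal subgroups from the
background when the category itself is parenchymal, to counteract the
over-representation of parenchyma. Reported enrichments use adjusted
p < 0.05 ('heatmap' mode); the map constraining the signaling network uses
p < 0.01 ('constraint' mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .colocalization import adjust_bh

ALPHA_HEATMAP = 0.05
ALPHA_CONSTRAINT = 0.01


def _one_sided_welch(x, y, pooled=False):
    if np.nanmax(x) == np.nanmin(x) and np.nanmax(y) == np.nanmin(y):
        return 0.0, 1.0  # both groups constant: no evidence either way
    res = stats.ttest_ind(x, y, equal_var=pooled, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def enrich(
    weights: pd.DataFrame,
    categories: pd.Series,
    mode: str = "heatmap",
    background_rule: str = "default",
    parenchymal_labels: set | None = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per (category, cell type): one-sided t-test of in-category vs
    background weights. Masked (NaN) weights are treated as zero abundance.

    With `background_rule='parenchyma'`, categories in `parenchymal_labels`
    exclude spots of the *other* parenchymal labels from their background.
    BH adjustment spans all (category, type) pairs of the run.
    """
    alpha = {"heatmap": ALPHA_HEATMAP, "constraint": ALPHA_CONSTRAINT}.get(mode)
    if alpha is None:
        raise ValueError(f"unknown mode {mode!r}")
    if background_rule not in ("default", "parenchyma"):
        raise ValueError(f"unknown background_rule {background_rule!r}")
    parenchymal_labels = set(parenchymal_labels or ())
    W = weights.fillna(0.0)
    categories = categories.reindex(W.index)
    rows = []
    for cat in sorted(categories.dropna().unique()):
        inside = (categories == cat).to_numpy()
        background = ~inside
        if background_rule == "parenchyma" and cat in parenchymal_labels:
            other_par = categories.isin(parenchymal_labels - {cat}).to_numpy()
            background = background & ~other_par
        if inside.sum() < 2 or background.sum() < 2:
            raise ValueError(f"category {cat!r}: need >=2 spots in and out")
        for ct in W.columns:
            x, y = W.loc[inside, ct], W.loc[background, ct]
            t, p = _one_sided_welch(x.to_numpy(), y.to_numpy(), pooled=pooled)
            rows.append(
                {"category": cat, "cell_type": ct,
                 "mean_in": float(x.mean()), "mean_out": float(y.mean()),
                 "n_in": int(inside.sum()), "n_out": int(background.sum()),
                 "t": t, "p": p}
            )
    res = pd.DataFrame(rows)
    res["p_adj"] = adjust_bh(res["p"])
    res["enriched"] = (res["p_adj"] < alpha) & (res["mean_in"] > res["mean_out"])
    res.attrs["alpha"] = alpha
    return res


def constrain_communities(enrichment: pd.DataFrame) -> dict:
    """Community → list of enriched cell types (constraint mode, adjusted
    p < 0.01), for the communication module. Communities with no enriched
    type map to an empty list."""
    if enrichment.attrs.get("alpha") != ALPHA_CONSTRAINT:
        raise ValueError("constrain_communities requires enrichment run in "
                         "constraint mode (alpha=0.01)")
    out = {str(c): [] for c in enrichment["category"].unique()}
    hits = enrichment[enrichment["enriched"]]
    for _, r in hits.iterrows():
        out[str(r["category"])].append(r["cell_type"])
    return {c: sorted(v) for c, v in out.items()}
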