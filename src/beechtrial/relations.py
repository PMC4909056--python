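"""Pooled Pearson correlations between traits.

Correlations are computed either at the tree level (observations pooled
across provenances — note these mix between- and within-provenance variation
and carry inflated degrees of freedom, which the output flags) or at the
provenance-mean level (n = number of provenances).  Deletion is
pairwise-complete because each trait has its own missing pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_matrix", "significance_stars"]

ID_COLUMNS = ("tree_id", "provenance", "block")


def significance_stars(p: float) -> str:
    """Conventional star coding: *** <0.001, ** <0.01, * <0.05, ns otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_matrix(
    table: pd.DataFrame,
    level: str = "tree",
    traits: list[str] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations in long format.

    Returns one row per unordered trait pair with columns
    ``trait_x, trait_y, r, p, n, stars, level, inflated_df`` (the latter set
    at tree level, where pooled observations inflate the degrees of freedom).
    ``level="provenance_mean"`` averages each trait per provenance first.
    Pairs with fewer than 3 complete observations or a zero-variance member
    get ``r = NaN``.  ``holm`` applies a Holm step-down correction to the
    p-values (off by default, matching the conventional uncorrected report).
    """
    if level not in ("tree", "provenance_mean"):
        raise ValueError(f"level must be 'tree' or 'provenance_mean', got {level!r}")
    if traits is None:
        traits = [
            c
            for c in table.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]
    data = table[["provenance", *traits]] if "provenance" in table else table[traits]
    if level == "provenance_mean":
        data = data.groupby("provenance", observed=True)[traits].mean()
    values = data[traits]

    rows = []
    for i, tx in enumerate(traits):
        for ty in traits[i + 1 :]:
            pair = values[[tx, ty]].dropna()
            n = len(pair)
            if n < 3 or pair[tx].nunique() < 2 or pair[ty].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(pair[tx], pair[ty])
            rows.append(
                {
                    "trait_x": tx,
                    "trait_y": ty,
                    "r": float(r),
                    "p": float(p),
                    "n": n,
                    "level": level,
                    "inflated_df": level == "tree",
                }
            )
    out = pd.DataFrame(rows)
    if holm and len(out):
        mask = out["p"].notna()
        p = out.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[mask, "p"] = adj
    out["stars"] = out["p"].map(significance_stars)
    return out


def wide_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric r matrix (unit diagonal) from the long-format output."""
    traits = pd.unique(long[["trait_x", "trait_y"]].to_numpy().ravel())
    wide = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in long.iterrows():
        wide.loc[row["trait_x"], row["trait_y"]] = row["r"]
        wide.loc[row["trait_y"], row["trait_x"]] = row["r"]
    return wide
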