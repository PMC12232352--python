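"""Regimen-flow tables and an optional Sankey-style figure.

The tested surface is the node/flow tables; figure rendering is headless-safe
and never asserted on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pathways import RegimenCode, TimelineSet, pathway_prevalence

__all__ = ["flow_table", "render_pathway_sankey"]


def flow_table(timelines: TimelineSet,
               years: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yearly regimen-category nodes and year-to-year flows.

    Nodes: (year, category, count, proportion) among individuals at risk at
    that year's quarter (proportions per year sum to 1, matching
    :func:`pathway_prevalence`).  Flows: (year_from, category_from,
    category_to, count) among individuals at risk in both years; each
    year_from's flow total equals the number at risk in both years.
    """
    if len(timelines) == 0:
        raise ValueError("empty timeline collection")
    if years is None:
        years = (timelines.n_quarters - 1) // 4
    node_rows, flow_rows = [], []
    for y in range(years + 1):
        q = 4 * y
        prev = pathway_prevalence(timelines, q)
        n_risk = prev.attrs["n_at_risk"]
        for cat, prop in prev.items():
            if prop > 0:
                node_rows.append({"year": y, "category": cat,
                                  "count": int(round(prop * n_risk)),
                                  "proportion": float(prop)})
    for y in range(years):
        q0, q1 = 4 * y, 4 * (y + 1)
        both = timelines.at_risk(q0) & timelines.at_risk(q1)
        if not both.any():
            continue
        src = timelines.regimens[both, q0]
        dst = timelines.regimens[both, q1]
        pairs, counts = np.unique(np.stack([src, dst]), axis=1,
                                  return_counts=True)
        for (s, d), c in zip(pairs.T, counts):
            flow_rows.append({"year_from": y,
                              "category_from": RegimenCode(int(s)).name,
                              "category_to": RegimenCode(int(d)).name,
                              "count": int(c)})
    return pd.DataFrame(node_rows), pd.DataFrame(flow_rows)


def render_pathway_sankey(timelines: TimelineSet, path=None,
                          years: int | None = None):
    """Write a stacked band figure of yearly regimen-category membership and
    return the (nodes, flows) tables it is drawn from."""
    nodes, flows = flow_table(timelines, years)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        pivot = (nodes.pivot(index="year", columns="category",
                             values="proportion")
                 .fillna(0.0).sort_index())
        order = pivot.sum().sort_values(ascending=False).index
        fig, ax = plt.subplots(figsize=(9, 5))
        ax.stackplot(pivot.index, [pivot[c] for c in order],
                     labels=list(order))
        ax.set_xlabel("years since second-line initiation")
        ax.set_ylabel("proportion of individuals under follow-up")
        ax.set_ylim(0, 1)
        ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return nodes, flows
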