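"""Local/global edge classification and the CLGF motif census.

Positive feedback edges are *local* when both endpoints lie in the same
cortical subregion (short conduction delay) and *global* otherwise.  A
coupled local-and-global feedback (CLGF) motif is an unordered channel
triple (hub a, global partner b, local partner c) where {a,b} is a
positive global feedback and {a,c} a positive local feedback — the hub is
the shared endpoint, so a hub with g global and l local positive
feedbacks contributes g*l motif instances.  The instance count is the
default statistic; a per-hub count (number of hubs participating in at
least one motif) is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import FeedbackNetwork
from .stats import TestResult, welch_t

__all__ = [
    "REGION_NAMES",
    "make_default_region_map",
    "classify_edges",
    "MotifCensus",
    "count_clgf",
    "group_motif_stats",
]

#: the 10 cortical subregions: 5 lobes x 2 hemispheres
REGION_NAMES = [
    f"{lobe}-{hemi}"
    for lobe in ("prefrontal", "middle-frontal", "temporal", "parietal", "occipital")
    for hemi in ("L", "R")
]


def make_default_region_map(channel_names: list[str],
                            n_regions: int = 10) -> dict[str, str]:
    """Partition channels into contiguous, near-equal region blocks.

    At full scale (102 channels) this yields the 10 subregions in blocks
    of 10 or 11.  The true sensor->region assignment of a real helmet is
    a user input; this generated map is the synthetic-data counterpart.
    For small channel counts the number of regions is reduced so every
    region holds at least two channels (a local edge needs a pair).
    """
    n = len(channel_names)
    n_regions = min(n_regions, max(1, n // 2), len(REGION_NAMES))
    sizes = np.full(n_regions, n // n_regions)
    sizes[: n % n_regions] += 1
    rmap: dict[str, str] = {}
    pos = 0
    for region, size in zip(REGION_NAMES[:n_regions], sizes):
        for ch in channel_names[pos:pos + int(size)]:
            rmap[ch] = region
        pos += int(size)
    return rmap


def classify_edges(net: FeedbackNetwork, rmap: dict[str, str]) -> FeedbackNetwork:
    """Label every edge local (same region) or global (across regions)."""
    edges = []
    for e in net.edges:
        for ch in e.pair:
            if ch not in rmap:
                raise KeyError(f"channel {ch!r} is not in the region map")
        scope = "local" if rmap[e.ch_a] == rmap[e.ch_b] else "global"
        edges.append(replace(e, scope=scope))
    return net.with_edges(edges)


@dataclass
class MotifCensus:
    n_pos_fb_total: int
    n_pos_fb_local: int
    n_pos_fb_global: int
    n_neg_fb: int
    n_clgf: int
    per_hub: dict[str, int] = field(default_factory=dict)

    @property
    def n_clgf_hubs(self) -> int:
        """Alternative statistic: hubs participating in >= 1 motif."""
        return len(self.per_hub)

    def as_row(self) -> dict[str, int]:
        return {
            "n_pos_fb_total": self.n_pos_fb_total,
            "n_pos_fb_local": self.n_pos_fb_local,
            "n_pos_fb_global": self.n_pos_fb_global,
            "n_neg_fb": self.n_neg_fb,
            "n_clgf": self.n_clgf,
            "n_clgf_hubs": self.n_clgf_hubs,
        }


def count_clgf(net: FeedbackNetwork) -> MotifCensus:
    """Census of positive feedbacks and CLGF motif instances.

    Requires classified edges (every edge carries a local/global scope).
    ``n_clgf`` counts unordered (hub, global partner, local partner)
    triples once each; with the hub as the shared endpoint this is
    sum over hubs of (global degree x local degree) among positive
    edges.  The partner channels of a motif are necessarily distinct
    because one lies outside the hub's region and the other inside it.
    """
    g_deg: dict[str, int] = {}
    l_deg: dict[str, int] = {}
    n_local = n_global = n_neg = 0
    for e in net.edges:
        if e.scope not in ("local", "global"):
            raise ValueError(f"edge {e.pair} lacks a local/global label")
        if e.sign < 0:
            n_neg += 1
            continue
        if e.scope == "local":
            n_local += 1
            for ch in e.pair:
                l_deg[ch] = l_deg.get(ch, 0) + 1
        else:
            n_global += 1
            for ch in e.pair:
                g_deg[ch] = g_deg.get(ch, 0) + 1
    per_hub = {ch: g_deg[ch] * l_deg[ch]
               for ch in set(g_deg) & set(l_deg)}
    per_hub = {ch: k for ch, k in per_hub.items() if k > 0}
    return MotifCensus(
        n_pos_fb_total=n_local + n_global,
        n_pos_fb_local=n_local,
        n_pos_fb_global=n_global,
        n_neg_fb=n_neg,
        n_clgf=sum(per_hub.values()),
        per_hub=per_hub,
    )


def motif_instances(net: FeedbackNetwork) -> pd.DataFrame:
    """Explicit (hub, global_partner, local_partner) instance list."""
    g_nb: dict[str, list[str]] = {}
    l_nb: dict[str, list[str]] = {}
    for e in net.positive_edges():
        nb = l_nb if e.scope == "local" else g_nb
        nb.setdefault(e.ch_a, []).append(e.ch_b)
        nb.setdefault(e.ch_b, []).append(e.ch_a)
    rows = [(hub, b, c)
            for hub in sorted(set(g_nb) & set(l_nb))
            for b in sorted(g_nb[hub]) for c in sorted(l_nb[hub])]
    return pd.DataFrame(rows, columns=["hub", "global_partner", "local_partner"])


def group_motif_stats(
    census_a: list[MotifCensus],
    census_b: list[MotifCensus],
    labels: tuple[str, str] = ("control", "patient"),
) -> dict:
    """Per-group mean +/- SE and Welch t for every census field.

    Degenerate comparisons (all counts identical, e.g. empty networks
    everywhere) are reported with t = 0 / p = 1 when means agree and are
    flagged ``degenerate`` when the variance vanishes.
    """
    if len(census_a) < 2 or len(census_b) < 2:
        raise ValueError("each group needs at least two subjects")
    fields = ["n_pos_fb_total", "n_pos_fb_local", "n_pos_fb_global",
              "n_neg_fb", "n_clgf", "n_clgf_hubs"]
    out: dict = {}
    for f in fields:
        a = np.array([c.as_row()[f] for c in census_a], dtype=float)
        b = np.array([c.as_row()[f] for c in census_b], dtype=float)
        degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
        if degenerate and a.mean() == b.mean():
            res = TestResult(0.0, float(a.size + b.size - 2), 1.0, "welch_t")
        else:
            res = welch_t(a, b)
        out[f] = {
            labels[0]: {"mean": float(a.mean()),
                        "se": float(np.std(a, ddof=1) / np.sqrt(a.size))},
            labels[1]: {"mean": float(b.mean()),
                        "se": float(np.std(b, ddof=1) / np.sqrt(b.size))},
            "t": res.statistic, "df": res.df, "p": res.p,
            "degenerate": bool(degenerate),
        }
    return out
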