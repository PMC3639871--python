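"""Signed feedback-network container shared by inference and census.

A feedback edge is an *unordered* channel pair — feedback is inherently
bidirectional in this framework — carrying a sign (+1 excitatory-loop /
-1), the dominant causal and non-causal lags of the underlying impulse
response (ms), and, once classified against a region map, a scope label
("local" within one cortical subregion, "global" between subregions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["FeedbackEdge", "FeedbackNetwork"]


@dataclass(frozen=True)
class FeedbackEdge:
    ch_a: str
    ch_b: str
    sign: int  # +1 or -1
    causal_lag_ms: float = float("nan")
    noncausal_lag_ms: float = float("nan")
    scope: str | None = None  # "local" | "global" once classified
    supporting_windows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ch_a == self.ch_b:
            raise ValueError("self-feedback is not allowed")
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        # canonical unordered representation
        if self.ch_a > self.ch_b:
            a, b = self.ch_a, self.ch_b
            object.__setattr__(self, "ch_a", b)
            object.__setattr__(self, "ch_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.ch_a, self.ch_b)

    @property
    def key(self) -> tuple[str, str, int]:
        """Identity used by the all-window consistency intersection."""
        return (self.ch_a, self.ch_b, self.sign)


@dataclass
class FeedbackNetwork:
    """Edge set over named channels."""

    channels: list[str]
    edges: list[FeedbackEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.channels)
        for e in self.edges:
            if e.ch_a not in known or e.ch_b not in known:
                raise ValueError(f"edge {e.pair} references unknown channel")

    def positive_edges(self) -> list[FeedbackEdge]:
        return [e for e in self.edges if e.sign > 0]

    def with_edges(self, edges: list[FeedbackEdge]) -> "FeedbackNetwork":
        return FeedbackNetwork(list(self.channels), edges)

    # ------------------------------------------------------------------ IO
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.ch_a, e.ch_b, e.sign, e.causal_lag_ms, e.noncausal_lag_ms,
              e.scope or "") for e in self.edges],
            columns=["ch_a", "ch_b", "sign", "causal_lag_ms",
                     "noncausal_lag_ms", "scope"],
        )

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_text(cls, path: str | Path, channels: list[str] | None = None,
                  sep: str = "\t") -> "FeedbackNetwork":
        df = pd.read_csv(path, sep=sep, keep_default_na=False)
        edges = [
            FeedbackEdge(str(r.ch_a), str(r.ch_b), int(r.sign),
                         float(r.causal_lag_ms), float(r.noncausal_lag_ms),
                         str(r.scope) or None)
            for r in df.itertuples()
        ]
        if channels is None:
            channels = sorted({c for e in edges for c in e.pair})
        return cls(channels, edges)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.channels)
        for e in self.edges:
            g.add_edge(e.ch_a, e.ch_b, sign=e.sign, scope=e.scope or "",
                       causal_lag_ms=e.causal_lag_ms,
                       noncausal_lag_ms=e.noncausal_lag_ms)
        nx.write_graphml(g, path)

    def relabel(self, mapping: dict[str, str]) -> "FeedbackNetwork":
        """Consistently rename channels (census counts are invariant)."""
        return FeedbackNetwork(
            [mapping[c] for c in self.channels],
            [replace(e, ch_a=mapping[e.ch_a], ch_b=mapping[e.ch_b])
             for e in self.edges],
        )
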