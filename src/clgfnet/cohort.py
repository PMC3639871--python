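"""Synthetic two-group cohorts with known feedback ground truth.

The generator emulates the study conditions this package analyses:
102-channel recordings at 1000 Hz over 80 s, partitioned into 10
cortical subregions, from two group archetypes — a control-like
archetype rich in local positive feedbacks and coupled local-and-global
feedback (CLGF) motifs, and a patient-like archetype with strictly fewer
of both (global feedback counts barely differ).  Every subject carries a
ground-truth topology whose census is exact by construction, signals are
Wilson-Cowan oscillator outputs coupled along that topology with
physiological conduction delays (global 15-25 ms, local 6-10 ms), and a
synthetic "negative symptom" clinical score is drawn linearly and
negatively related to the subject's CLGF count with a configurable
generating correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .motifs import classify_edges, count_clgf, make_default_region_map
from .network import FeedbackEdge, FeedbackNetwork
from .signals import SignalSet
from .wilson_cowan import Coupling, WCNetworkSpec, WCParams, simulate

__all__ = [
    "MotifAbundance",
    "CohortSpec",
    "GroundTruthTopology",
    "TopologyInfeasibleError",
    "build_topology",
    "make_topology",
    "synthesize_signals",
    "draw_scores",
    "count_distribution_moments",
    "Subject",
    "Cohort",
    "make_cohort",
]


class TopologyInfeasibleError(ValueError):
    """An abundance request cannot be realised on the given layout."""


@dataclass(frozen=True)
class MotifAbundance:
    """Expected positive-feedback abundances of one group archetype.

    Per-subject counts are integers drawn as a rounded normal around each
    mean (sd ``count_sd``), clipped to feasibility (clgf <= local,
    global >= number of hubs needed).
    """

    local_mean: float
    global_mean: float
    clgf_mean: float
    count_sd: float = 1.0
    n_negative: int = 2


#: archetype defaults: the control-like group is CLGF-rich, the
#: patient-like group has fewer local feedbacks and CLGF motifs while the
#: global feedback count barely differs (mirroring the group contrasts
#: this generator emulates)
CONTROL_ARCHETYPE = MotifAbundance(local_mean=8, global_mean=6, clgf_mean=6)
PATIENT_ARCHETYPE = MotifAbundance(local_mean=4, global_mean=5, clgf_mean=2)


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic cohort."""

    n_subjects_per_group: tuple[int, int] = (17, 15)  # (control, patient)
    n_channels: int = 102
    duration: float = 80.0          # seconds
    fs: float = 1000.0              # Hz
    noise_sd: float = 0.5           # measurement noise, relative to signal SD
    input_noise_sd: float = 0.3     # broadband drive noise inside the dynamics
    coupling_strength: float = 2.0  # per-edge weight scale (/= sqrt degree)
    drive_compensation: float = 0.15  # drive reduction per unit incoming weight
    p_range: tuple[float, float] = (1.6, 2.3)  # per-channel drive jitter
    tau_global_range: tuple[float, float] = (15.0, 25.0)  # ms
    tau_local_range: tuple[float, float] = (6.0, 10.0)    # ms
    archetypes: dict[str, MotifAbundance] = field(default_factory=lambda: {
        "control": CONTROL_ARCHETYPE, "patient": PATIENT_ARCHETYPE})
    score_r: float = -0.5           # generating corr(negative score, n_clgf)
    score_mean: float = 16.0
    score_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_subjects_per_group, int):
            self.n_subjects_per_group = (self.n_subjects_per_group,
                                         self.n_subjects_per_group)
        else:
            self.n_subjects_per_group = tuple(self.n_subjects_per_group)
        # allow plain mappings (e.g. from a YAML config)
        self.archetypes = {k: (v if isinstance(v, MotifAbundance)
                               else MotifAbundance(**v))
                           for k, v in self.archetypes.items()}
        n_samples = self.duration * self.fs
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration x rate must be an integer sample count")
        c, p = self.archetypes["control"], self.archetypes["patient"]
        if not (p.local_mean < c.local_mean and p.clgf_mean < c.clgf_mean):
            raise ValueError("patient archetype must have strictly fewer "
                             "local feedbacks and CLGF motifs than control")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruthTopology:
    """Known feedback structure of one synthetic subject."""

    channel_names: list[str]
    region_map: dict[str, str]
    edges: list[FeedbackEdge]
    requested: dict[str, int] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def network(self) -> FeedbackNetwork:
        return FeedbackNetwork(list(self.channel_names), list(self.edges))

    def census(self):
        return count_clgf(classify_edges(self.network(), self.region_map))

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        self.network().to_text(path, sep=sep)

    def to_graphml(self, path: str | Path) -> None:
        self.network().to_graphml(path)


def count_distribution_moments(mean: float, sd: float,
                               k_max: int = 200) -> tuple[float, float]:
    """Exact mean and SD of the integer count ``max(0, round(N(mean, sd)))``.

    Used to set the generating slope of the score model so that the true
    score-count correlation equals the requested value.
    """
    k = np.arange(0, k_max + 1)
    upper = norm.cdf((k + 0.5 - mean) / sd)
    lower = np.r_[0.0, upper[:-1]]
    pmf = upper - lower
    pmf[0] = norm.cdf((0.5 - mean) / sd)
    pmf = pmf / pmf.sum()
    mu = float((k * pmf).sum())
    var = float(((k - mu) ** 2 * pmf).sum())
    return mu, float(np.sqrt(var))


def _draw_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(max(0, round(rng.normal(mean, sd))))


def build_topology(
    channel_names: list[str],
    region_map: dict[str, str],
    n_local: int,
    n_global: int,
    n_clgf: int,
    rng: np.random.Generator,
    n_negative: int = 0,
    tau_global_range: tuple[float, float] = (15.0, 25.0),
    tau_local_range: tuple[float, float] = (6.0, 10.0),
) -> GroundTruthTopology:
    """Construct a topology whose positive-feedback census is exactly
    (n_local, n_global, n_clgf).

    CLGF motifs are planted as hub channels carrying one global feedback
    and a batch of local feedbacks (one hub contributes its local degree
    to the motif count); the remaining local and global edges are placed
    on channels that cannot form additional motifs (extra local edges
    avoid every globally-connected channel and vice versa).  Raises
    :class:`TopologyInfeasibleError` naming the binding constraint.
    """
    if min(n_local, n_global, n_clgf) < 0:
        raise TopologyInfeasibleError("counts must be non-negative")
    if n_clgf > 0 and n_local < 1:
        raise TopologyInfeasibleError("CLGF motifs need at least one local feedback")
    if n_clgf > n_local:
        raise TopologyInfeasibleError(
            f"n_clgf={n_clgf} exceeds n_local={n_local}: each planted hub "
            "contributes one motif per local feedback")
    regions: dict[str, list[str]] = {}
    for ch in channel_names:
        regions.setdefault(region_map[ch], []).append(ch)
    for r in regions.values():
        rng.shuffle(r)
    region_names = sorted(regions)
    if n_local > 0 and max(len(v) for v in regions.values()) < 2:
        raise TopologyInfeasibleError("local feedback needs a region with >= 2 channels")
    if n_global > 0 and len(regions) < 2:
        raise TopologyInfeasibleError("global feedback needs >= 2 regions")

    has_global: set[str] = set()
    has_local: set[str] = set()
    hubs: set[str] = set()
    used_pairs: set[tuple[str, str]] = set()
    edges: list[FeedbackEdge] = []

    def free(ch: str) -> bool:
        return ch not in has_global and ch not in has_local

    def lag(scope: str) -> float:
        lo, hi = tau_local_range if scope == "local" else tau_global_range
        return float(rng.uniform(lo, hi))

    def add_edge(a: str, b: str, sign: int, scope: str) -> None:
        pair = (min(a, b), max(a, b))
        used_pairs.add(pair)
        edges.append(FeedbackEdge(a, b, sign, causal_lag_ms=lag(scope),
                                  noncausal_lag_ms=-1.0, scope=scope))

    # --- plant hubs: one global + a batch of locals each -----------------
    remaining_c = n_clgf
    n_hubs = 0
    while remaining_c > 0:
        # pick the region with the most completely-free channels
        cand = max(region_names, key=lambda r: sum(free(c) for c in regions[r]))
        free_here = [c for c in regions[cand] if free(c)]
        if len(free_here) < 2:
            raise TopologyInfeasibleError(
                "no region has two free channels left to plant a hub "
                f"(need {remaining_c} more motif instances)")
        partners_other = [c for r in region_names if r != cand
                          for c in regions[r] if free(c)]
        if not partners_other:
            raise TopologyInfeasibleError(
                "no free channel outside the hub region for a global partner")
        hub = free_here[0]
        n_loc = min(remaining_c, len(free_here) - 1)
        gpartner = partners_other[int(rng.integers(len(partners_other)))]
        add_edge(hub, gpartner, +1, "global")
        has_global.update((hub, gpartner))
        for c in free_here[1:1 + n_loc]:
            add_edge(hub, c, +1, "local")
            has_local.update((hub, c))
        hubs.add(hub)
        n_hubs += 1
        remaining_c -= n_loc
    if n_hubs > n_global:
        raise TopologyInfeasibleError(
            f"planting {n_clgf} motifs needed {n_hubs} hubs/global edges but "
            f"only n_global={n_global} were requested")

    # --- extra local edges away from any globally-connected channel ------
    for _ in range(n_local - n_clgf):
        placed = False
        for r in rng.permutation(region_names):
            elig = [c for c in regions[r]
                    if c not in has_global and c not in hubs]
            rng.shuffle(elig)
            for i in range(len(elig)):
                for j in range(i + 1, len(elig)):
                    pair = (min(elig[i], elig[j]), max(elig[i], elig[j]))
                    if pair not in used_pairs:
                        add_edge(elig[i], elig[j], +1, "local")
                        has_local.update(pair)
                        placed = True
                        break
                if placed:
                    break
            if placed:
                break
        if not placed:
            raise TopologyInfeasibleError(
                "no region offers an unused channel pair without global "
                "edges for an extra local feedback")

    # --- extra global edges away from any locally-connected channel ------
    for _ in range(n_global - n_hubs):
        elig = [c for c in channel_names
                if c not in has_local and c not in hubs]
        rng.shuffle(elig)
        placed = False
        for i in range(len(elig)):
            for j in range(i + 1, len(elig)):
                a, b = elig[i], elig[j]
                if region_map[a] == region_map[b]:
                    continue
                pair = (min(a, b), max(a, b))
                if pair not in used_pairs:
                    add_edge(a, b, +1, "global")
                    has_global.update(pair)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise TopologyInfeasibleError(
                "no cross-region channel pair without local edges left for "
                "an extra global feedback")

    # --- negative feedbacks (do not affect the positive census) ----------
    for _ in range(n_negative):
        for _try in range(200):
            a, b = rng.choice(channel_names, size=2, replace=False)
            pair = (min(a, b), max(a, b))
            if pair not in used_pairs:
                scope = "local" if region_map[a] == region_map[b] else "global"
                add_edge(str(a), str(b), -1, scope)
                break

    topo = GroundTruthTopology(
        channel_names=list(channel_names),
        region_map=dict(region_map),
        edges=edges,
        requested={"n_local": n_local, "n_global": n_global,
                   "n_clgf": n_clgf, "n_negative": n_negative},
    )
    census = topo.census()
    if (census.n_pos_fb_local, census.n_pos_fb_global, census.n_clgf) != \
            (n_local, n_global, n_clgf):
        raise RuntimeError(
            f"internal construction error: census {census.as_row()} does not "
            f"match request {topo.requested}")
    return topo


def make_topology(spec: CohortSpec, archetype: str,
                  seed: int | np.random.Generator) -> GroundTruthTopology:
    """Draw per-subject abundances from an archetype and build the
    corresponding exact topology."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ab = spec.archetypes[archetype]
    names = [f"ch{i:03d}" for i in range(spec.n_channels)]
    rmap = make_default_region_map(names)
    # a hub hosts at most (its region size - 1) local partners, so small
    # layouts may need several hubs (hence several global edges) per motif
    from collections import Counter
    max_region = max(Counter(rmap.values()).values())
    last_err: TopologyInfeasibleError | None = None
    for _attempt in range(50):
        n_clgf = _draw_count(rng, ab.clgf_mean, ab.count_sd)
        n_local = n_clgf + _draw_count(rng, ab.local_mean - ab.clgf_mean,
                                       ab.count_sd)
        hubs_needed = int(np.ceil(n_clgf / max(1, max_region - 1)))
        n_global = max(hubs_needed,
                       _draw_count(rng, ab.global_mean, ab.count_sd))
        try:
            return build_topology(names, rmap, n_local, n_global, n_clgf, rng,
                                  n_negative=ab.n_negative,
                                  tau_global_range=spec.tau_global_range,
                                  tau_local_range=spec.tau_local_range)
        except TopologyInfeasibleError as err:
            # a draw can overflow a small layout; redraw (deterministic
            # given the rng stream)
            last_err = err
    raise TopologyInfeasibleError(
        f"archetype {archetype!r} abundances repeatedly infeasible for "
        f"n_channels={spec.n_channels}: {last_err}")


def synthesize_signals(
    topology: GroundTruthTopology,
    spec: CohortSpec,
    rng: np.random.Generator,
    transient: float = 500.0,
    dt: float = 0.05,
) -> SignalSet:
    """One Wilson-Cowan oscillator per channel, coupled per topology.

    Every channel is the excitatory output E(t) of its own oscillator
    with a jittered constant drive (so intrinsic frequencies differ and
    uncoupled channels do not phase-lock), a broadband noise drive inside
    the dynamics, and additive white measurement noise on top.  Feedback
    edges become reciprocal delayed couplings with the edge's lag and
    sign.  The first ``transient`` ms are discarded.
    """
    max_lag = max((e.causal_lag_ms for e in topology.edges), default=0.0)
    if max_lag >= spec.duration * 1000.0:
        raise ValueError("coupling lag exceeds the record duration")
    stride = (1000.0 / spec.fs) / dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"fs={spec.fs} Hz is not an integer decimation of dt={dt} ms")
    n = topology.n_channels
    idx = {ch: i for i, ch in enumerate(topology.channel_names)}
    p_lo, p_hi = spec.p_range
    params = [replace(WCParams(), p=float(rng.uniform(p_lo, p_hi)))
              for _ in range(n)]
    # per-edge weight shrinks as 1/sqrt(degree) (edges at hubs stay strong
    # enough to be identifiable) and the constant drive of multi-edge
    # channels is reduced in proportion to their total incoming weight — a
    # synaptic-scaling-like compensation that keeps hubs out of the
    # runaway high-activity regime
    degree: dict[int, int] = {}
    for e in topology.edges:
        for ch in e.pair:
            degree[idx[ch]] = degree.get(idx[ch], 0) + 1
    couplings = []
    total_w = np.zeros(n)
    for e in topology.edges:
        a, b = idx[e.ch_a], idx[e.ch_b]
        for src, tgt in ((a, b), (b, a)):
            w = spec.coupling_strength / np.sqrt(degree[tgt])
            couplings.append(Coupling(source=src, target=tgt,
                                      weight=w * e.sign, tau=e.causal_lag_ms))
            total_w[tgt] += w
    for i in range(n):
        if total_w[i] > 0:
            p_adj = max(1.3, params[i].p - spec.drive_compensation * total_w[i])
            params[i] = replace(params[i], p=p_adj)
    net = WCNetworkSpec(params=params, couplings=couplings)
    duration_ms = spec.duration * 1000.0 + transient
    traj = simulate(net, duration_ms, dt=dt,
                    input_noise_sd=spec.input_noise_sd, rng=rng)
    data = traj.resample(spec.fs)[:, int(round(transient * spec.fs / 1000.0)):]
    data = data[:, :spec.n_samples]
    if spec.noise_sd > 0:
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape) * sd
    return SignalSet(data, spec.fs, list(topology.channel_names))


def draw_scores(
    counts: np.ndarray,
    rng: np.random.Generator,
    r: float,
    count_mean: float,
    count_sd: float,
    score_mean: float = 16.0,
    score_sd: float = 5.0,
) -> np.ndarray:
    """Synthetic clinical scores linearly related to motif counts.

    ``score = mean + r*sd*(count - mu_c)/sigma_c + sqrt(1-r^2)*sd*z`` so
    the *generating* (population) correlation equals ``r`` exactly when
    ``(mu_c, sigma_c)`` are the true count moments.  With r = -1 the
    scores are a noiseless decreasing line in the count.
    """
    counts = np.asarray(counts, dtype=float)
    z = rng.standard_normal(counts.size)
    return (score_mean + r * score_sd * (counts - count_mean) / count_sd
            + np.sqrt(max(0.0, 1.0 - r ** 2)) * score_sd * z)


@dataclass
class Subject:
    subject_id: str
    group: str
    topology: GroundTruthTopology
    signals: SignalSet | None = None


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]
    table: pd.DataFrame
    score_model: dict = field(default_factory=dict)

    def group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == label]


def make_cohort(spec: CohortSpec, with_signals: bool = True) -> Cohort:
    """Generate a full two-group cohort.

    Per-subject randomness is fanned out from ``spec.seed`` through a
    SeedSequence spawn, so cohorts are reproducible subject-by-subject.
    The returned table is the skeleton (ids, groups, ground-truth counts,
    synthetic clinical scores); derived signal measures are appended by
    the analysis stages.  ``score_model`` records the generating
    correlation, slope and noise SD of the score model for
    parameter-recovery checks.
    """
    n_control, n_patient = spec.n_subjects_per_group
    if min(n_control, n_patient) < 2:
        raise ValueError("need at least two subjects per group")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(n_control + n_patient + 1)
    score_rng = np.random.default_rng(children[-1])

    subjects: list[Subject] = []
    rows = []
    k = 0
    for group, n_sub in (("control", n_control), ("patient", n_patient)):
        for _ in range(n_sub):
            rng = np.random.default_rng(children[k])
            sid = f"{group[:3]}{k:03d}"
            topo = make_topology(spec, group, rng)
            sig = synthesize_signals(topo, spec, rng) if with_signals else None
            subjects.append(Subject(sid, group, topo, sig))
            census = topo.census()
            rows.append({"subject_id": sid, "group": group, **{
                f"truth_{key}": val for key, val in census.as_row().items()}})
            k += 1
    table = pd.DataFrame(rows)

    pat_ab = spec.archetypes["patient"]
    mu_c, sd_c = count_distribution_moments(pat_ab.clgf_mean, pat_ab.count_sd)
    pat = table.group == "patient"
    counts = table.loc[pat, "truth_n_clgf"].to_numpy(float)
    for col in ("panss_positive", "panss_negative", "panss_general", "panss_total"):
        table[col] = np.nan
    table.loc[pat, "panss_negative"] = draw_scores(
        counts, score_rng, spec.score_r, mu_c, sd_c,
        spec.score_mean, spec.score_sd)
    table.loc[pat, "panss_positive"] = score_rng.normal(15.0, 4.0, counts.size)
    table.loc[pat, "panss_general"] = score_rng.normal(30.0, 6.0, counts.size)
    table.loc[pat, "panss_total"] = (table.loc[pat, "panss_positive"]
                                     + table.loc[pat, "panss_negative"]
                                     + table.loc[pat, "panss_general"])
    slope = spec.score_r * spec.score_sd / sd_c
    noise = float(np.sqrt(max(0.0, 1.0 - spec.score_r ** 2)) * spec.score_sd)
    return Cohort(spec, subjects, table,
                  score_model={"r": spec.score_r, "slope": slope,
                               "noise_sd": noise, "count_mean": mu_c,
                               "count_sd": sd_c})
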