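"""Topographically constrained probabilistic wiring.

Axon terminal fields are modeled as truncated Gaussian densities along the
septo-temporal axis (sigma = extent / 4, support limited to +/- extent / 2
around the field center).  The field center is the presynaptic soma position
for intrinsic cells, or the topographically mapped dentate position for
entorhinal axons (a uniform band mapping of the EC axis onto the DG axis).
Mossy cell field extents vary linearly with soma position: about 2/3 of the
axis for septal cells down to 1/3 for temporal cells.

For each postsynaptic cell a convergence count is drawn uniformly from the
pathway's range and that many synapses are allocated among presynaptic
candidates with probability proportional to the candidate's terminal-field
density at the postsynaptic position.  Multiple synapses onto the same pair
are allowed (and expected at reduced scale); they are stored as one edge
with a synapse count.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import ConfigurationError, WiringError
from .params import PATHWAYS, load_network_config, load_synapse_table
from .populations import PopulationLayout

logger = logging.getLogger(__name__)

#: Granule-cell compartment index per region tag.
GC_REGIONS = {"soma": 0, "GCL": 1, "inner": 2, "middle": 3, "outer": 4}


@dataclass(frozen=True)
class PathwaySpec:
    """Static description of one projection."""

    name: str                 # e.g. "MEC_GC"
    pre: str
    post: str
    target_region: str        # soma | GCL | inner | middle | outer
    convergence: tuple[int, int]
    weight: float
    tau_rise: float
    tau_fall: float
    e_rev: float
    velocity_m_per_s: float = 0.25
    synaptic_latency_ms: float = 0.8

    def __post_init__(self):
        lo, hi = self.convergence
        if lo > hi:
            raise ConfigurationError(f"{self.name}: convergence min > max")
        if self.post == "GC" and self.target_region not in GC_REGIONS:
            raise ConfigurationError(
                f"{self.name}: invalid GC target region {self.target_region!r}"
            )
        if self.post in ("BC", "MC") and self.target_region != "soma":
            raise ConfigurationError(
                f"{self.name}: point cells only accept somatic synapses"
            )


class TerminalField:
    """Normalized axon terminal-field density along the septo-temporal axis."""

    def __init__(self, center_mm: float, extent_mm: float, axis_length_mm: float):
        if extent_mm <= 0:
            raise ConfigurationError("terminal field extent must be > 0")
        self.center = center_mm
        self.extent = extent_mm
        self.sigma = extent_mm / 4.0
        lo = max(0.0, center_mm - extent_mm / 2.0)
        hi = min(axis_length_mm, center_mm + extent_mm / 2.0)
        self.lo, self.hi = lo, hi
        s2 = self.sigma * math.sqrt(2.0)
        # Mass of the (truncated) Gaussian over [lo, hi] for normalization.
        self._mass = (
            0.5 * (erf((hi - center_mm) / s2) - erf((lo - center_mm) / s2))
            * self.sigma * math.sqrt(2.0 * math.pi)
        )

    def density(self, x):
        """Probability density over post positions (integrates to 1)."""
        x = np.asarray(x, dtype=float)
        g = np.exp(-0.5 * ((x - self.center) / self.sigma) ** 2)
        g = np.where((x >= self.lo) & (x <= self.hi), g, 0.0)
        return g / self._mass


def mossy_cell_extent(pre_pos_mm: float, axis_length_mm: float, cfg=None) -> float:
    """Septo-temporal extent of a mossy cell's axon terminal field.

    Interpolates linearly from ~2/3 of the axis at the septal pole (x = 0)
    to ~1/3 at the temporal pole (x = axis length).
    """
    cfg = cfg or load_network_config()
    tf = cfg["terminal_fields"]
    f0 = tf["MC_extent_fraction_septal"]
    f1 = tf["MC_extent_fraction_temporal"]
    u = pre_pos_mm / axis_length_mm
    return axis_length_mm * (f0 + (f1 - f0) * u)


def terminal_field_density(
    pre_type: str,
    pre_pos_mm: float,
    axis_length_mm: float,
    cfg: dict | None = None,
) -> TerminalField:
    """Terminal field of one presynaptic cell.

    ``pre_type`` is one of MEC, LEC, GC, BC, MC.  Raises if the position is
    outside the axis.
    """
    if not (0.0 <= pre_pos_mm <= axis_length_mm):
        raise ConfigurationError(
            f"position {pre_pos_mm} mm outside axis [0, {axis_length_mm}]"
        )
    cfg = cfg or load_network_config()
    tf = cfg["terminal_fields"]
    if pre_type in ("MEC", "LEC"):
        extent = tf["EC_extent_mm"]
    elif pre_type == "GC":
        extent = tf["GC_extent_mm"]
    elif pre_type == "BC":
        extent = tf["BC_extent_mm"]
    elif pre_type == "MC":
        extent = mossy_cell_extent(pre_pos_mm, axis_length_mm, cfg)
    else:
        raise ConfigurationError(f"unknown presynaptic type {pre_type!r}")
    return TerminalField(pre_pos_mm, extent, axis_length_mm)


def conduction_delay(
    pre_pos_mm,
    post_pos_mm,
    velocity_m_per_s: float = 0.25,
    synaptic_latency_ms: float = 0.8,
):
    """Propagation delay: septo-temporal path length / velocity + latency.

    mm / (m/s) == ms, so this is ``|dx| / v + latency`` directly.
    """
    if velocity_m_per_s <= 0:
        raise ConfigurationError("conduction velocity must be > 0")
    d = np.abs(np.asarray(pre_pos_mm, dtype=float) - np.asarray(post_pos_mm, dtype=float))
    return d / velocity_m_per_s + synaptic_latency_ms


@dataclass
class PathwayEdges:
    """Realized, aggregated edge list for one pathway.

    ``n_syn[k]`` synapses connect ``pre_idx[k] -> post_idx[k]`` with a shared
    conduction delay.  Realized in-degree of a post cell is the sum of its
    synapse counts.
    """

    spec: PathwaySpec
    pre_idx: np.ndarray     # int32
    post_idx: np.ndarray    # int32
    n_syn: np.ndarray       # int32
    delay_ms: np.ndarray    # float64
    n_pre: int
    n_post: int
    fallback_count: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.pre_idx)

    @property
    def total_synapses(self) -> int:
        return int(self.n_syn.sum())

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.post_idx, weights=self.n_syn, minlength=self.n_post).astype(int)

    def out_degree(self) -> np.ndarray:
        return np.bincount(self.pre_idx, weights=self.n_syn, minlength=self.n_pre).astype(int)


@dataclass
class ConnectivityGraph:
    """All realized pathways of one network build."""

    pathways: dict[str, PathwayEdges] = field(default_factory=dict)
    seed: int = 0

    def __getitem__(self, name: str) -> PathwayEdges:
        return self.pathways[name]

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def __iter__(self):
        return iter(self.pathways.values())


def _pathway_rng(seed: int, name: str, salt: int = 0) -> np.random.Generator:
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key, salt))
    )


def wire_pathway(
    layout: PopulationLayout,
    spec: PathwaySpec,
    seed: int = 0,
    cfg: dict | None = None,
) -> PathwayEdges:
    """Realize one pathway's edges.

    For each postsynaptic cell: draw convergence c ~ Uniform[min, max]
    (integer), then allocate c synapses over presynaptic candidates with
    probability proportional to each candidate's terminal-field density at
    the post position.  If the truncated fields of every candidate miss the
    post cell (possible at strongly reduced scale), the nearest presynaptic
    cell is used and counted in ``fallback_count``.
    """
    cfg = cfg or load_network_config()
    L = layout.scale.axis_length_mm
    pre_pos = layout.septotemporal(spec.pre)
    post_pos = layout.septotemporal(spec.post)
    n_pre, n_post = len(pre_pos), len(post_pos)
    if n_pre == 0:
        raise WiringError(f"{spec.name}: presynaptic population {spec.pre} is empty")

    rng = _pathway_rng(seed, spec.name)
    order = np.argsort(pre_pos, kind="stable")
    sorted_pos = pre_pos[order]

    # Per-pre field parameters (extent varies only for MC).
    if spec.pre == "MC":
        extents = np.array([mossy_cell_extent(p, L, cfg) for p in pre_pos])
    else:
        fld = terminal_field_density(spec.pre, float(pre_pos[0] if n_pre else 0.0), L, cfg)
        extents = np.full(n_pre, fld.extent)
    sigmas = extents / 4.0
    half = extents / 2.0
    max_half = float(half.max())

    lo_c, hi_c = spec.convergence
    conv = rng.integers(lo_c, hi_c + 1, size=n_post)

    pre_out, post_out, nsyn_out, delay_out = [], [], [], []
    fallbacks = 0
    for j in range(n_post):
        x = post_pos[j]
        a = np.searchsorted(sorted_pos, x - max_half, side="left")
        b = np.searchsorted(sorted_pos, x + max_half, side="right")
        cand = order[a:b]
        d = np.abs(pre_pos[cand] - x)
        inside = d <= half[cand]
        cand = cand[inside]
        if cand.size == 0:
            # truncated fields miss this cell; fall back to nearest pre
            fallbacks += 1
            cand = np.array([order[np.argmin(np.abs(sorted_pos - x))]])
            w = np.ones(1)
        else:
            d = np.abs(pre_pos[cand] - x)
            sig = sigmas[cand]
            w = np.exp(-0.5 * (d / sig) ** 2) / sig
        p = w / w.sum()
        counts = rng.multinomial(conv[j], p)
        nz = counts > 0
        pres = cand[nz]
        pre_out.append(pres)
        post_out.append(np.full(pres.size, j, dtype=np.int32))
        nsyn_out.append(counts[nz])
        delay_out.append(
            conduction_delay(
                pre_pos[pres], x, spec.velocity_m_per_s, spec.synaptic_latency_ms
            )
        )
    if fallbacks:
        logger.warning(
            "%s: %d/%d post cells had no presynaptic candidate within the "
            "truncated field; used nearest cell",
            spec.name, fallbacks, n_post,
        )
    edges = PathwayEdges(
        spec=spec,
        pre_idx=np.concatenate(pre_out).astype(np.int32),
        post_idx=np.concatenate(post_out).astype(np.int32),
        n_syn=np.concatenate(nsyn_out).astype(np.int32),
        delay_ms=np.concatenate(delay_out),
        n_pre=n_pre,
        n_post=n_post,
        fallback_count=fallbacks,
    )
    _assert_in_degrees(edges)
    return edges


def _assert_in_degrees(edges: PathwayEdges):
    lo, hi = edges.spec.convergence
    deg = edges.in_degree()
    if deg.min() < lo or deg.max() > hi:
        raise WiringError(
            f"{edges.spec.name}: realized in-degree outside [{lo}, {hi}]"
        )


def randomize_topography(
    edges: PathwayEdges,
    layout: PopulationLayout,
    seed: int = 0,
) -> PathwayEdges:
    """Distance-independent resampling of presynaptic partners.

    Keeps each post cell's realized in-degree (synapse count) but draws the
    presynaptic partners uniformly over the whole presynaptic population;
    delays are recomputed from the new somatic distances.
    """
    spec = edges.spec
    pre_pos = layout.septotemporal(spec.pre)
    post_pos = layout.septotemporal(spec.post)
    n_pre = edges.n_pre
    rng = _pathway_rng(seed, spec.name, salt=1)
    in_deg = edges.in_degree()

    pre_out, post_out, nsyn_out, delay_out = [], [], [], []
    p = np.full(n_pre, 1.0 / n_pre)
    for j in range(edges.n_post):
        c = int(in_deg[j])
        if c == 0:
            continue
        counts = rng.multinomial(c, p)
        nz = counts > 0
        pres = np.nonzero(nz)[0]
        pre_out.append(pres.astype(np.int32))
        post_out.append(np.full(pres.size, j, dtype=np.int32))
        nsyn_out.append(counts[nz].astype(np.int32))
        delay_out.append(
            conduction_delay(
                pre_pos[pres], post_pos[j],
                spec.velocity_m_per_s, spec.synaptic_latency_ms,
            )
        )
    return PathwayEdges(
        spec=spec,
        pre_idx=np.concatenate(pre_out),
        post_idx=np.concatenate(post_out),
        n_syn=np.concatenate(nsyn_out),
        delay_ms=np.concatenate(delay_out),
        n_pre=n_pre,
        n_post=edges.n_post,
    )


def default_pathway_specs(include_mc: bool = True, cfg: dict | None = None) -> dict[str, PathwaySpec]:
    """PathwaySpec for every wired projection, from the parameter tables."""
    cfg = cfg or load_network_config()
    table = load_synapse_table()
    cond = cfg["conduction"]
    specs = {}
    for pw in PATHWAYS:
        pre, post = pw.split("_")
        if not include_mc and ("MC" in (pre, post)):
            continue
        row = table[pw]
        specs[pw] = PathwaySpec(
            name=pw,
            pre=pre,
            post=post,
            target_region=cfg["targets"][pw],
            convergence=tuple(row["convergence"]),
            weight=row["weight"],
            tau_rise=row["tau_rise"],
            tau_fall=row["tau_fall"],
            e_rev=row["e_rev"],
            velocity_m_per_s=cond["velocity_m_per_s"],
            synaptic_latency_ms=cond["synaptic_latency_ms"],
        )
    return specs


def build_connectivity(
    layout: PopulationLayout,
    include_mc: bool = True,
    seed: int = 0,
    cfg: dict | None = None,
) -> ConnectivityGraph:
    """Wire all pathways of the network (7 projections, 9 keyed by EC split).

    Each pathway uses an independent RNG substream keyed by its name, so
    wiring one pathway never perturbs another.
    """
    specs = default_pathway_specs(include_mc=include_mc, cfg=cfg)
    graph = ConnectivityGraph(seed=seed)
    for name, spec in specs.items():
        graph.pathways[name] = wire_pathway(layout, spec, seed=seed, cfg=cfg)
    return graph


def export_edges_tsv(graph: ConnectivityGraph, path) -> None:
    """Write all edges as columnar text (one row per aggregated edge)."""
    import pandas as pd

    frames = []
    for edges in graph:
        frames.append(
            pd.DataFrame(
                {
                    "pathway": edges.spec.name,
                    "pre_id": edges.pre_idx,
                    "post_id": edges.post_idx,
                    "compartment": edges.spec.target_region,
                    "delay_ms": edges.delay_ms,
                    "weight": edges.spec.weight,
                    "n_syn": edges.n_syn,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def import_edges_tsv(path, layout: PopulationLayout, cfg: dict | None = None) -> ConnectivityGraph:
    """Rebuild a ConnectivityGraph from ``export_edges_tsv`` output.

    Pathway specs are reconstructed from the parameter tables; population
    sizes come from ``layout``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    specs = default_pathway_specs(include_mc=True, cfg=cfg)
    graph = ConnectivityGraph()
    for name, sub in df.groupby("pathway"):
        if name not in specs:
            raise ConfigurationError(f"unknown pathway {name!r} in edge file")
        spec = specs[name]
        graph.pathways[name] = PathwayEdges(
            spec=spec,
            pre_idx=sub["pre_id"].to_numpy(np.int32),
            post_idx=sub["post_id"].to_numpy(np.int32),
            n_syn=sub["n_syn"].to_numpy(np.int32),
            delay_ms=sub["delay_ms"].to_numpy(float),
            n_pre=layout.counts[spec.pre],
            n_post=layout.counts[spec.post],
        )
    return graph
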