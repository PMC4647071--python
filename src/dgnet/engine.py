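"""Clock-driven network simulation producing spike rasters.

``simulate`` assembles the numba kernel's inputs from a population layout, a
connectivity graph and a stimulus spec, runs the integration, and returns a
:class:`SimulationResult` whose raster holds every somatic spike (GC/BC/MC)
plus the entorhinal afferent spikes (MEC/LEC).  All randomness (stimulus)
derives from the ``seed`` argument; the integration itself is deterministic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .cells import GATES, CellModel, build_granule_cell, build_point_cell, build_rate_tables, resting_state
from .connectivity import GC_REGIONS, ConnectivityGraph, PathwayEdges
from .errors import ConfigurationError, NumericalInstabilityError, ResourceError
from .params import load_network_config, load_synapse_table
from .populations import PopulationLayout
from .stimulus import StimulusSpec, population_trains

POP_CODES = {"GC": 0, "BC": 1, "MC": 2, "MEC": 3, "LEC": 4}
POP_NAMES = {v: k for k, v in POP_CODES.items()}

#: Synaptic channel slots per population block (pathway, target comp).
GC_CHANNELS = (("BC_GC", 0), ("MC_GC", 2), ("MEC_GC", 3), ("LEC_GC", 4))
BC_CHANNELS = (("GC_BC", 0), ("MEC_BC", 0), ("MC_BC", 0))  # slot 1 = EC merged
MC_CHANNELS = (("GC_MC", 0),)


@dataclass
class SpikeRaster:
    """Spike records: (population, cell id, septo-temporal position, time)."""

    population: np.ndarray   # int8 codes, see POP_CODES
    cell_id: np.ndarray      # int32
    position_mm: np.ndarray  # float64
    t_ms: np.ndarray         # float64
    duration_ms: float

    def __len__(self) -> int:
        return len(self.t_ms)

    def for_population(self, name: str) -> "SpikeRaster":
        m = self.population == POP_CODES[name]
        return SpikeRaster(
            self.population[m], self.cell_id[m], self.position_mm[m],
            self.t_ms[m], self.duration_ms,
        )

    def to_dataframe(self) -> pd.DataFrame:
        order = np.argsort(self.t_ms, kind="stable")
        return pd.DataFrame(
            {
                "population": [POP_NAMES[p] for p in self.population[order]],
                "cell_id": self.cell_id[order],
                "position_mm": self.position_mm[order],
                "t_ms": self.t_ms[order],
            }
        )

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path, duration_ms: float | None = None) -> "SpikeRaster":
        df = pd.read_csv(path, sep="\t")
        dur = duration_ms if duration_ms is not None else float(df["t_ms"].max())
        return cls(
            population=np.array([POP_CODES[p] for p in df["population"]], dtype=np.int8),
            cell_id=df["cell_id"].to_numpy(np.int32),
            position_mm=df["position_mm"].to_numpy(float),
            t_ms=df["t_ms"].to_numpy(float),
            duration_ms=dur,
        )


@dataclass
class SimulationResult:
    raster: SpikeRaster
    counts: dict[str, int]
    layout: PopulationLayout
    duration_ms: float
    dt_ms: float
    seed: int
    config: dict = field(default_factory=dict)
    wall_s: float = 0.0
    probe_t: np.ndarray | None = None
    probe_v: np.ndarray | None = None


def total_spikes(result: SimulationResult, population: str, window=None) -> int:
    """Spike count of one population, optionally within [t0, t1) ms."""
    r = result.raster.for_population(population)
    if window is None:
        return len(r)
    t0, t1 = window
    if not (0 <= t0 <= t1 <= result.duration_ms):
        raise ConfigurationError("window outside simulation duration")
    return int(((r.t_ms >= t0) & (r.t_ms < t1)).sum())


def _empty_csr(n_pre: int):
    return (
        np.zeros(n_pre + 1, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.float64),
        np.empty(0, dtype=np.int64),
    )


def _csr_from_edges(edges: PathwayEdges | None, n_pre: int, unit_w: float, dt: float):
    """CSR by presynaptic cell; edge weight = n_syn * unit weight."""
    if edges is None or edges.n_edges == 0:
        return _empty_csr(n_pre)
    order = np.argsort(edges.pre_idx, kind="stable")
    pre = edges.pre_idx[order].astype(np.int64)
    post = edges.post_idx[order].astype(np.int64)
    w = edges.n_syn[order].astype(np.float64) * unit_w
    dstep = np.maximum(1, np.rint(edges.delay_ms[order] / dt)).astype(np.int64)
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, post, w, dstep


def _block_arrays(model: CellModel | None, n: int, channels, syn_table, dt, v0=None):
    """All kernel arrays for one population block."""
    if model is None or n == 0:
        ncomp = 1
        V = np.zeros((0, ncomp))
        G = np.zeros((0, ncomp, len(GATES)))
        CA = np.zeros((0, ncomp))
        zeros = np.zeros(ncomp)
        block = [V, G, CA, zeros + 1.0, zeros + 1.0, -65.0,
                 np.zeros((9, ncomp)), np.zeros(0), zeros, 1.0, 0.0]
    else:
        V, G, CA = resting_state(model, n, v0)
        block = [
            V, G, CA, model.cm_nF, model.g_leak_uS, model.e_leak,
            model.g_chan_uS, model.g_axial_uS, model.k_ca,
            float(np.exp(-dt / model.ca_tau_ms)), model.ca_steady,
        ]
    # BC slot 1 is the merged EC channel; parameters from the MEC_BC row.
    nch = len(channels)
    A = np.zeros((nch, n))
    B = np.zeros((nch, n))
    chcomp = np.zeros(nch, dtype=np.int64)
    cherev = np.zeros(nch)
    decA = np.ones(nch)
    decB = np.ones(nch)
    norm = np.ones(nch)
    ncomp = block[0].shape[1] if block[0].shape[0] else 1
    for k, (pw, comp) in enumerate(channels):
        row = syn_table[pw]
        tr, tf = row["tau_rise"], row["tau_fall"]
        tp = tr * tf / (tf - tr) * np.log(tf / tr)
        chcomp[k] = min(comp, ncomp - 1)
        cherev[k] = row["e_rev"]
        decA[k] = np.exp(-dt / tf)
        decB[k] = np.exp(-dt / tr)
        norm[k] = 1.0 / (np.exp(-tp / tf) - np.exp(-tp / tr))
    return block, [A, B, chcomp, cherev, decA, decB, norm]


def _ring_buffer(n_post: int, *dsteps_arrays) -> np.ndarray:
    slots = 4
    for d in dsteps_arrays:
        if len(d):
            slots = max(slots, int(d.max()) + 2)
    return np.zeros((slots, max(n_post, 1)))


def _events_from_trains(trains, dt, nsteps):
    steps, cells = [], []
    for i, tr in enumerate(trains):
        s = (np.asarray(tr) / dt).astype(np.int64)
        s = s[s < nsteps]
        steps.append(s)
        cells.append(np.full(len(s), i, dtype=np.int64))
    if not steps:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    steps = np.concatenate(steps)
    cells = np.concatenate(cells)
    order = np.argsort(steps, kind="stable")
    return steps[order], cells[order]


def simulate(
    layout: PopulationLayout,
    graph: ConnectivityGraph,
    stimulus: StimulusSpec | None = None,
    duration_ms: float = 4000.0,
    dt_ms: float = 0.1,
    seed: int = 0,
    gains: dict[str, float] | None = None,
    weight_multipliers: dict[str, float] | None = None,
    weight_scale: float | None = None,
    ec_trains: tuple[list, list] | None = None,
    mc_volley_times: list[float] | None = None,
    injection: tuple[str, int, int, float, float, float] | None = None,
    probes: list[tuple[str, int, int]] | None = None,
    spike_cap: int | None = None,
    cells: dict[str, CellModel] | None = None,
) -> SimulationResult:
    """Run the network.

    ``weight_multipliers`` scale individual pathways on top of the
    calibrated gains (the experiment knobs); ``mc_volley_times`` forces a
    synchronous volley through the mossy-cell efferents at the given times
    (commissural/associational activation); ``injection`` is
    (population, cell, compartment, amplitude nA, t0 ms, t1 ms).
    """
    if dt_ms <= 0 or dt_ms > 0.1 + 1e-12:
        raise ConfigurationError("require 0 < dt <= 0.1 ms")
    cfg = load_network_config()
    syn_table = load_synapse_table()
    base_gains = dict(cfg["gains"])
    if gains:
        base_gains.update(gains)
    mult = dict.fromkeys(base_gains, 1.0)
    if weight_multipliers:
        for pw, m in weight_multipliers.items():
            if pw == "EC_BC":
                mult["MEC_BC"] = mult["LEC_BC"] = m
            elif pw == "EC_GC":
                mult["MEC_GC"] = mult["LEC_GC"] = m
            else:
                if pw not in mult:
                    raise ConfigurationError(f"unknown pathway {pw!r}")
                mult[pw] = m
    wscale = cfg["weight_scale"] if weight_scale is None else weight_scale

    def unit_w(pw):
        return syn_table[pw]["weight"] * base_gains[pw] * mult[pw] * wscale

    n = layout.counts
    ng, nb, nm = n.get("GC", 0), n.get("BC", 0), n.get("MC", 0)
    nmec, nlec = n.get("MEC", 0), n.get("LEC", 0)
    models = cells or {}
    gc_model = models.get("GC") or build_granule_cell()
    bc_model = models.get("BC") or build_point_cell("BC")
    mc_model = (models.get("MC") or build_point_cell("MC")) if nm else None

    nsteps = int(round(duration_ms / dt_ms))
    inf_tab, dec_tab = build_rate_tables(dt_ms)

    blk_g, ch_g = _block_arrays(gc_model, ng, GC_CHANNELS, syn_table, dt_ms)
    blk_b, ch_b = _block_arrays(bc_model, nb, BC_CHANNELS, syn_table, dt_ms)
    blk_m, ch_m = _block_arrays(mc_model, nm if mc_model else 0, MC_CHANNELS, syn_table, dt_ms)
    # BC slot 1 merges MEC->BC and LEC->BC (identical kinetics in the table)

    def csr(pw, n_pre):
        edges = graph.pathways.get(pw)
        return _csr_from_edges(edges, n_pre, unit_w(pw), dt_ms)

    mecgc = csr("MEC_GC", nmec)
    lecgc = csr("LEC_GC", nlec)
    mecbc = csr("MEC_BC", nmec)
    lecbc = csr("LEC_BC", nlec)
    gcbc = csr("GC_BC", ng)
    gcmc = csr("GC_MC", ng)
    bcgc = csr("BC_GC", nb)
    mcgc = csr("MC_GC", nm)
    mcbc = csr("MC_BC", nm)

    buf_g0 = _ring_buffer(ng, bcgc[3])
    buf_g1 = _ring_buffer(ng, mcgc[3])
    buf_g2 = _ring_buffer(ng, mecgc[3])
    buf_g3 = _ring_buffer(ng, lecgc[3])
    buf_b0 = _ring_buffer(nb, gcbc[3])
    buf_b1 = _ring_buffer(nb, mecbc[3], lecbc[3])
    buf_b2 = _ring_buffer(nb, mcbc[3])
    buf_m0 = _ring_buffer(nm, gcmc[3])

    # entorhinal drive
    if ec_trains is not None:
        mec_trains, lec_trains = ec_trains
    else:
        spec = stimulus or StimulusSpec(seed=seed)
        if spec.seed != seed:
            spec = StimulusSpec(spec.rate_hz, spec.ramp_ms, spec.duration_ms, seed)
        mec_trains = population_trains(spec, nmec, "MEC")
        lec_trains = population_trains(spec, nlec, "LEC")
    mec_step, mec_cell = _events_from_trains(mec_trains, dt_ms, nsteps)
    lec_step, lec_cell = _events_from_trains(lec_trains, dt_ms, nsteps)

    if mc_volley_times:
        vsteps = np.array(
            [int(t / dt_ms) for t in mc_volley_times for _ in range(nm)],
            dtype=np.int64,
        )
        vcells = np.array(
            [c for _ in mc_volley_times for c in range(nm)], dtype=np.int64
        )
        order = np.argsort(vsteps, kind="stable")
        fmc_step, fmc_cell = vsteps[order], vcells[order]
    else:
        fmc_step = np.empty(0, dtype=np.int64)
        fmc_cell = np.empty(0, dtype=np.int64)

    # injection / probes
    if injection is not None:
        pop, cell, comp, amp, t0, t1 = injection
        inj = (POP_CODES[pop], int(cell), int(comp), float(amp),
               int(round(t0 / dt_ms)), int(round(t1 / dt_ms)))
    else:
        inj = (-1, -1, 0, 0.0, 0, 0)
    probes = probes or []
    probe_pop = np.array([POP_CODES[p] for p, _, _ in probes], dtype=np.int64)
    probe_cell = np.array([c for _, c, _ in probes], dtype=np.int64)
    probe_comp = np.array([k for _, _, k in probes], dtype=np.int64)
    vrec = np.zeros((len(probes), nsteps + 1))
    for q, (p, c, k) in enumerate(probes):
        v0 = {0: blk_g, 1: blk_b, 2: blk_m}[POP_CODES[p]][0]
        vrec[q, 0] = v0[c, k]

    cap = spike_cap or max(1_000_000, int(20 * (ng + nb + nm) * duration_ms / 1000.0))
    out_pop = np.zeros(cap, dtype=np.int8)
    out_cell = np.zeros(cap, dtype=np.int32)
    out_step = np.zeros(cap, dtype=np.int32)
    last_g = np.full(max(ng, 1), -10**9, dtype=np.int64)
    last_b = np.full(max(nb, 1), -10**9, dtype=np.int64)
    last_m = np.full(max(nm, 1), -10**9, dtype=np.int64)
    refr_steps = max(1, int(round(1.0 / dt_ms)))  # 1 ms refractory

    t_start = time.perf_counter()
    n_spk, err, err_pop, err_cell, err_step = _kernel.run_net(
        nsteps, dt_ms, refr_steps, inf_tab, dec_tab,
        *blk_g, *ch_g, buf_g0, buf_g1, buf_g2, buf_g3,
        *blk_b, *ch_b, buf_b0, buf_b1, buf_b2,
        *blk_m, *ch_m, buf_m0,
        *mecgc, *lecgc, *mecbc, *lecbc,
        *gcbc, *gcmc, *bcgc, *mcgc, *mcbc,
        mec_step, mec_cell, lec_step, lec_cell, fmc_step, fmc_cell,
        *inj,
        probe_pop, probe_cell, probe_comp, vrec,
        out_pop, out_cell, out_step, last_g, last_b, last_m,
    )
    wall = time.perf_counter() - t_start
    if err == _kernel.ERR_NONFINITE:
        raise NumericalInstabilityError(
            POP_NAMES[err_pop], int(err_cell), err_step * dt_ms
        )
    if err == _kernel.ERR_OVERFLOW:
        raise ResourceError(
            f"spike store overflow (> {cap} events) at t={err_step * dt_ms:.1f} ms"
        )

    # assemble raster: internal somatic spikes + afferent EC spikes
    pops = [out_pop[:n_spk].copy()]
    cids = [out_cell[:n_spk].copy()]
    times = [(out_step[:n_spk].astype(float) + 0.5) * dt_ms]
    pos_map = {
        0: layout.septotemporal("GC") if ng else np.empty(0),
        1: layout.septotemporal("BC") if nb else np.empty(0),
        2: layout.septotemporal("MC") if nm else np.empty(0),
    }
    positions = [np.empty(n_spk)]
    for code, pos in pos_map.items():
        m = pops[0] == code
        if m.any():
            positions[0][m] = pos[cids[0][m]]
    for name, trains in (("MEC", mec_trains), ("LEC", lec_trains)):
        if not trains:
            continue
        code = POP_CODES[name]
        pos = layout.septotemporal(name)
        cc = np.concatenate(
            [np.full(len(tr), i, dtype=np.int32) for i, tr in enumerate(trains)]
        ) if trains else np.empty(0, np.int32)
        tt = np.concatenate([np.asarray(tr, float) for tr in trains])
        keep = tt < duration_ms
        pops.append(np.full(keep.sum(), code, dtype=np.int8))
        cids.append(cc[keep])
        times.append(tt[keep])
        positions.append(pos[cc[keep]])

    raster = SpikeRaster(
        population=np.concatenate(pops).astype(np.int8),
        cell_id=np.concatenate(cids).astype(np.int32),
        position_mm=np.concatenate(positions),
        t_ms=np.concatenate(times),
        duration_ms=duration_ms,
    )
    counts = {
        name: int((raster.population == code).sum())
        for name, code in POP_CODES.items()
    }
    config = {
        "gains": base_gains,
        "multipliers": mult,
        "weight_scale": wscale,
        "dt_ms": dt_ms,
        "duration_ms": duration_ms,
        "counts": dict(layout.counts),
        "scale_factor": layout.scale.scale_factor,
    }
    return SimulationResult(
        raster=raster, counts=counts, layout=layout,
        duration_ms=duration_ms, dt_ms=dt_ms, seed=seed,
        config=config, wall_s=wall,
        probe_t=np.arange(nsteps + 1) * dt_ms if probes else None,
        probe_v=vrec if probes else None,
    )


def simulate_single_cell(
    model: CellModel,
    duration_ms: float,
    dt_ms: float = 0.1,
    i_step: tuple[float, float, float] | None = None,
    v0: float | None = None,
):
    """Integrate one isolated cell; returns (t ms, somatic V mV).

    Used for passive measurements and current-injection protocols.
    """
    syn_table = load_synapse_table()
    nsteps = int(round(duration_ms / dt_ms))
    inf_tab, dec_tab = build_rate_tables(dt_ms)
    blk, ch = _block_arrays(model, 1, GC_CHANNELS, syn_table, dt_ms, v0=v0)
    blk_b, ch_b = _block_arrays(None, 0, BC_CHANNELS, syn_table, dt_ms)
    blk_m, ch_m = _block_arrays(None, 0, MC_CHANNELS, syn_table, dt_ms)
    e = np.empty(0, dtype=np.int64)
    empty_csr1 = _empty_csr(1)
    empty_csr0 = _empty_csr(0)
    buf1 = np.zeros((4, 1))
    buf0 = np.zeros((4, 1))
    if i_step is not None:
        amp, t0, t1 = i_step
        inj = (0, 0, 0, float(amp), int(round(t0 / dt_ms)), int(round(t1 / dt_ms)))
    else:
        inj = (-1, -1, 0, 0.0, 0, 0)
    vrec = np.zeros((1, nsteps + 1))
    vrec[0, 0] = blk[0][0, 0]
    out_pop = np.zeros(100_000, dtype=np.int8)
    out_cell = np.zeros(100_000, dtype=np.int32)
    out_step = np.zeros(100_000, dtype=np.int32)
    last1 = np.full(1, -10**9, dtype=np.int64)
    n_spk, err, err_pop, err_cell, err_step = _kernel.run_net(
        nsteps, dt_ms, max(1, int(round(1.0 / dt_ms))), inf_tab, dec_tab,
        *blk, *ch, buf1, buf1.copy(), buf1.copy(), buf1.copy(),
        *blk_b, *ch_b, buf0, buf0.copy(), buf0.copy(),
        *blk_m, *ch_m, buf0.copy(),
        *empty_csr0, *empty_csr0, *empty_csr0, *empty_csr0,
        *empty_csr1, *empty_csr1, *empty_csr0, *empty_csr0, *empty_csr0,
        e, e, e, e, e, e,
        *inj,
        np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
        np.zeros(1, dtype=np.int64), vrec,
        out_pop, out_cell, out_step, last1, last1.copy(), last1.copy(),
    )
    if err == _kernel.ERR_NONFINITE:
        raise NumericalInstabilityError(model.cell_type, 0, err_step * dt_ms)
    t = np.arange(nsteps + 1) * dt_ms
    return t, vrec[0]


def count_somatic_spikes(model: CellModel, duration_ms: float, dt_ms: float = 0.1,
                         i_step=None) -> int:
    """Number of somatic action potentials under a current-step protocol."""
    t, v = simulate_single_cell(model, duration_ms, dt_ms, i_step)
    up = (v[1:] >= 0.0) & (v[:-1] < 0.0)
    return int(up.sum())
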