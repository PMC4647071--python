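"""Conductance-based membrane models.

Granule cells use a reduced 5-region scheme -- soma, granule cell layer
(GCL) segment, and inner/middle/outer molecular-layer thirds -- connected as
a cable, with region-specific channel densities from the biophysics table
(Na, slow/fast delayed-rectifier K, A-type K, L/N/T-type Ca, SK, BK, leak).
Each dendritic region stands for two parallel equivalent branches folded
into one section.  Basket cells and mossy cells are single-compartment
somata.

Gating kinetics are not constrained by the densities table; this package
uses a parametric Boltzmann steady state with a Gaussian-bump time constant
per gate (one table below, swappable), chosen so that every channel is
essentially closed at the tabulated resting potentials and the cells fire
conventional action potentials.  SK and BK gates are instantaneous functions
of intracellular Ca (and voltage for BK).  The Ca pool relaxes to its steady
state with tau = 10 ms and is charged by Ca-channel current.

Integration is exponential Euler per compartment with tabulated gate
updates (steady state and per-step decay factor precomputed on a 0.25 mV
voltage grid), deterministic for a given state and dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DgnetError
from .params import load_biophysics

REGIONS = ("soma", "GCL", "inner", "middle", "outer")

#: Channel order used everywhere (rows of density matrices).
CHANNELS = (
    "sodium", "kdr_slow", "kdr_fast", "ka",
    "ca_l", "ca_n", "ca_t", "sk", "bk",
)

#: Biophysics-table row name per channel.
_CHANNEL_ROWS = {
    "sodium": "Sodium (S/cm2)",
    "kdr_slow": "Delayed rectifier K (slow)",
    "kdr_fast": "Delayed rectifier K (fast)",
    "ka": "A-type K (S/cm2)",
    "ca_l": "L-type Ca (S/cm2)",
    "ca_n": "N-type Ca (S/cm2)",
    "ca_t": "T-type Ca (S/cm2)",
    "sk": "Ca-dependent K (SK)",
    "bk": "Ca- and V- dependent K (BK)",
}

#: Reversal potentials (mV).
E_NA, E_K, E_CA = 50.0, -90.0, 80.0

#: Gate order: Na m/h, KDR-slow s, KDR-fast n, KA a/b, CaL c, CaN cn/dn, CaT e/f.
GATES = ("m", "h", "s", "n", "a", "b", "c", "cn", "dn", "e", "f")

#: Parametric kinetics: inf = 1 / (1 + exp(-(V - vh) / k));
#: tau = tau0 + tauA * exp(-((V - vtau) / sigtau)^2)  [ms].
GATE_PARAMS = {
    "m":  dict(vh=-38.0, k=6.0,   tau0=0.04, tauA=0.30, vtau=-40.0, sigtau=25.0),
    "h":  dict(vh=-58.0, k=-7.0,  tau0=0.60, tauA=6.0,  vtau=-55.0, sigtau=20.0),
    "s":  dict(vh=-40.0, k=11.0,  tau0=6.0,  tauA=20.0, vtau=-40.0, sigtau=30.0),
    "n":  dict(vh=-35.0, k=10.0,  tau0=0.8,  tauA=4.0,  vtau=-30.0, sigtau=30.0),
    "a":  dict(vh=-35.0, k=8.0,   tau0=0.5,  tauA=1.0,  vtau=-35.0, sigtau=30.0),
    "b":  dict(vh=-70.0, k=-6.0,  tau0=10.0, tauA=30.0, vtau=-60.0, sigtau=30.0),
    "c":  dict(vh=-25.0, k=5.0,   tau0=1.0,  tauA=2.0,  vtau=-25.0, sigtau=20.0),
    "cn": dict(vh=-28.0, k=6.0,   tau0=1.5,  tauA=3.0,  vtau=-28.0, sigtau=20.0),
    "dn": dict(vh=-60.0, k=-7.0,  tau0=40.0, tauA=0.0,  vtau=-60.0, sigtau=30.0),
    "e":  dict(vh=-52.0, k=5.5,   tau0=2.0,  tauA=6.0,  vtau=-52.0, sigtau=20.0),
    "f":  dict(vh=-72.0, k=-5.0,  tau0=25.0, tauA=60.0, vtau=-70.0, sigtau=30.0),
}

#: SK half-activation [Ca] and BK Ca factor / voltage gate.
SK_KD = 5.0e-4
BK_KD = 2.0e-3
BK_VH, BK_K = -20.0, 10.0

#: Ca pool influx scaling (pool units per mA/cm2 per ms).
CA_PHI = 0.007

#: Voltage grid for tabulated gate updates.
V_MIN, V_MAX, V_STEP = -120.0, 60.0, 0.25
N_V = int(round((V_MAX - V_MIN) / V_STEP)) + 1


def gate_inf(name: str, v):
    p = GATE_PARAMS[name]
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - p["vh"]) / p["k"]))


def gate_tau(name: str, v):
    p = GATE_PARAMS[name]
    v = np.asarray(v, float)
    return p["tau0"] + p["tauA"] * np.exp(-(((v - p["vtau"]) / p["sigtau"]) ** 2))


def build_rate_tables(dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """(inf, dec) tables of shape [n_gates + 1, N_V]; dec = exp(-dt/tau).

    The extra final row is the instantaneous BK voltage gate (inf only).
    """
    v = V_MIN + V_STEP * np.arange(N_V)
    inf = np.empty((len(GATES) + 1, N_V))
    dec = np.zeros((len(GATES) + 1, N_V))
    for i, g in enumerate(GATES):
        inf[i] = gate_inf(g, v)
        dec[i] = np.exp(-dt_ms / gate_tau(g, v))
    inf[len(GATES)] = 1.0 / (1.0 + np.exp(-(v - BK_VH) / BK_K))
    return inf, dec


# --------------------------------------------------------------------------
# Reduced granule-cell geometry.
#
# Cylindrical equivalent sections (diameter um, length um, parallel
# branches).  Dimensions are electrical equivalents, chosen so the somatic
# input resistance matches the tabulated 185.86 MOhm with the tabulated leak
# densities and the cell is electrotonically compact (laminar synapses see
# the soma); they are not anatomical lengths.
GC_GEOMETRY = {
    "soma":   (9.772, 9.772, 1),
    "GCL":    (2.0, 23.87, 1),
    "inner":  (1.6, 29.57, 2),
    "middle": (1.6, 29.57, 2),
    "outer":  (1.6, 29.57, 2),
}


@dataclass
class CompartmentScheme:
    """Ordered compartments with areas (cm^2) and axial couplings (uS)."""

    regions: tuple[str, ...]
    area_cm2: np.ndarray
    g_axial_uS: np.ndarray  # between adjacent compartments, len = n - 1

    @property
    def n_comp(self) -> int:
        return len(self.regions)


def granule_scheme(geometry: dict | None = None, ra_ohm_cm: float = 210.0) -> CompartmentScheme:
    geo = geometry or GC_GEOMETRY
    regions = tuple(geo)
    if regions != REGIONS:
        raise ConfigurationError(f"granule scheme must have regions {REGIONS}")
    areas, half_r = [], []
    for d_um, l_um, n_br in geo.values():
        d, l = d_um * 1e-4, l_um * 1e-4  # cm
        areas.append(math.pi * d * l * n_br)
        cross = math.pi * d * d / 4.0 * n_br
        half_r.append(ra_ohm_cm * (l / 2.0) / cross)  # Ohm
    g_ax = np.array(
        [1e6 / (half_r[i] + half_r[i + 1]) for i in range(len(regions) - 1)]
    )  # uS
    return CompartmentScheme(regions=regions, area_cm2=np.array(areas), g_axial_uS=g_ax)


@dataclass
class ChannelDensityTable:
    """Per-region maximal conductances (S/cm^2), rows ordered as CHANNELS."""

    densities: np.ndarray         # [n_channels, n_regions]
    leak: np.ndarray              # [n_regions]
    cm_uF_cm2: np.ndarray         # [n_regions]
    e_leak: float
    ca_tau_ms: float = 10.0
    ca_steady: float = 5.0e-6

    def __post_init__(self):
        if (self.densities < 0).any() or (self.leak <= 0).any():
            raise ConfigurationError("conductance densities must be >= 0 (leak > 0)")


def _as_region_vector(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if len(arr) != n:
        raise ConfigurationError(f"expected {n} region values, got {len(arr)}")
    return arr


def density_table_from_config(block: dict, n_regions: int) -> ChannelDensityTable:
    dens = np.zeros((len(CHANNELS), n_regions))
    for i, ch in enumerate(CHANNELS):
        row = block.get(_CHANNEL_ROWS[ch], 0.0)
        dens[i] = _as_region_vector(row if row is not None else 0.0, n_regions)
    missing = [k for k in ("Leak (S/cm2)", "Cm (uF/cm2)", "R.M.P. (mV)") if k not in block]
    if missing:
        raise ConfigurationError(f"biophysics block missing {missing}")
    return ChannelDensityTable(
        densities=dens,
        leak=_as_region_vector(block["Leak (S/cm2)"], n_regions),
        cm_uF_cm2=_as_region_vector(block["Cm (uF/cm2)"], n_regions),
        e_leak=float(block["R.M.P. (mV)"]),
        ca_tau_ms=float(block.get("Tau for decay of Ca (ms)", 10.0)),
        ca_steady=float(block.get("Steady-state Ca (mol)", 5.0e-6)),
    )


@dataclass
class CellModel:
    """Arrays the engine needs for one cell type (shared by all its cells)."""

    cell_type: str
    regions: tuple[str, ...]
    area_cm2: np.ndarray
    cm_nF: np.ndarray            # per compartment
    g_leak_uS: np.ndarray
    e_leak: float
    g_chan_uS: np.ndarray        # [n_channels, n_comp]
    g_axial_uS: np.ndarray       # [n_comp - 1]
    k_ca: np.ndarray             # Ca pool charge factor per compartment
    ca_tau_ms: float
    ca_steady: float
    rmp_target: float | None = None

    @property
    def n_comp(self) -> int:
        return len(self.regions)


def _make_model(cell_type, scheme: CompartmentScheme, table: ChannelDensityTable,
                rmp_target=None) -> CellModel:
    area = scheme.area_cm2
    g_chan = table.densities * area[None, :] * 1e6          # S -> uS
    # dCa/dt = -k_ca * I_Ca[nA] - (Ca - ca0)/tau; k_ca converts nA to
    # (mA/cm^2) * CA_PHI for the compartment area.
    k_ca = CA_PHI * 1e-6 / area
    return CellModel(
        cell_type=cell_type,
        regions=scheme.regions,
        area_cm2=area,
        cm_nF=table.cm_uF_cm2 * area * 1e3,                 # uF -> nF
        g_leak_uS=table.leak * area * 1e6,
        e_leak=table.e_leak,
        g_chan_uS=g_chan,
        g_axial_uS=scheme.g_axial_uS,
        k_ca=k_ca,
        ca_tau_ms=table.ca_tau_ms,
        ca_steady=table.ca_steady,
        rmp_target=rmp_target,
    )


def build_granule_cell(
    table: ChannelDensityTable | None = None,
    scheme: CompartmentScheme | None = None,
) -> CellModel:
    """Granule cell: cable-connected soma-GCL-inner-middle-outer chain.

    Sodium is absent from the outer third, A-type K from all dendrites, per
    the densities table.
    """
    bio = load_biophysics()["granule_cell"]
    if table is None:
        table = density_table_from_config(bio, len(REGIONS))
    if table.densities.shape[1] != len(REGIONS):
        raise ConfigurationError("granule cell table must cover all 5 regions")
    if scheme is None:
        scheme = granule_scheme(ra_ohm_cm=float(bio.get("Ra (ohm-cm)", 210.0)))
    return _make_model("GC", scheme, table, rmp_target=bio.get("R.M.P. (mV)"))


def build_point_cell(cell_type: str, params: dict | None = None) -> CellModel:
    """Single-compartment basket or mossy cell from its biophysics block."""
    key = {"BC": "basket_cell", "MC": "mossy_cell"}.get(cell_type)
    if key is None:
        raise ConfigurationError(f"unknown point-cell type {cell_type!r}")
    block = dict(load_biophysics()[key])
    if params:
        block.update(params)
    table = density_table_from_config(block, 1)
    area = float(block["Soma S.A. (cm2)"])
    scheme = CompartmentScheme(
        regions=("soma",),
        area_cm2=np.array([area]),
        g_axial_uS=np.empty(0),
    )
    return _make_model(cell_type, scheme, table, rmp_target=block.get("R.M.P. (mV)"))


def resting_state(model: CellModel, n_cells: int, v0: float | None = None):
    """Initial (V, gates, Ca) arrays at the leak reversal steady state."""
    v = model.e_leak if v0 is None else v0
    V = np.full((n_cells, model.n_comp), float(v))
    gates = np.empty((n_cells, model.n_comp, len(GATES)))
    for i, g in enumerate(GATES):
        gates[:, :, i] = gate_inf(g, v)
    ca = np.full((n_cells, model.n_comp), model.ca_steady)
    return V, gates, ca


def measure_passive(
    model: CellModel,
    dt_ms: float = 0.1,
    rest_ms: float = 500.0,
    step_ms: float = 600.0,
    step_nA: float = -0.005,
) -> dict:
    """Measure RMP, input resistance and membrane time constant.

    Holds the cell at rest for ``rest_ms`` (error if the somatic potential
    still drifts > 0.5 mV over the last 100 ms), then applies a small
    hyperpolarizing somatic current step.  Rin is the steady-state voltage
    deflection over current; tau_m comes from a single-exponential fit to
    the charging curve.
    """
    from scipy.optimize import curve_fit

    from .engine import simulate_single_cell

    t, v = simulate_single_cell(
        model, duration_ms=rest_ms + step_ms, dt_ms=dt_ms,
        i_step=(step_nA, rest_ms, rest_ms + step_ms),
    )
    pre = v[(t > rest_ms - 100.0) & (t <= rest_ms)]
    if abs(pre[-1] - pre[0]) > 0.5:
        raise DgnetError(
            f"cell did not reach rest: drift {abs(pre[-1] - pre[0]):.2f} mV "
            "over final 100 ms"
        )
    rmp = float(pre[-50:].mean())
    tail = v[t > rest_ms + step_ms - 100.0]
    v_inf = float(tail.mean())
    rin = (v_inf - rmp) / step_nA  # mV / nA = MOhm

    sel = (t >= rest_ms) & (t <= rest_ms + 250.0)
    ts = t[sel] - rest_ms
    vs = v[sel]

    def charging(x, tau):
        return v_inf + (rmp - v_inf) * np.exp(-x / tau)

    (tau,), _ = curve_fit(charging, ts, vs, p0=[30.0])
    return {"rmp_mV": rmp, "rin_MOhm": float(rin), "tau_m_ms": float(tau)}
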