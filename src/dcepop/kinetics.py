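"""Linear multi-compartment kinetics.

The amount vector ``A`` [umol] obeys ``dA/dt = K A`` with a compartmental
(Metzler) rate matrix ``K`` built from first-order transfer constants
[1/s].  A bolus dose enters the central compartment at the (per-dataset)
injection lag, and the system is solved analytically through the matrix
exponential — the published rate estimates span almost seven orders of
magnitude (2.3e-5 to 300 1/s), which makes fixed-step integration useless
and an analytic solution the only numerically sane route.

Concentrations follow from apparent distribution volumes: the central volume
is fixed by the literature clearance through ``V_c = Cl / k_C0`` and the
remaining volumes are propagated outward over every bidirectional exchange
using flow balance, ``Q = k_ij V_i = k_ji V_j``.  The observed concentration
in a compartment is then ``C = A / V`` (umol/ml == mM).

Units throughout: seconds, millilitres, micromoles, millimolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, DerivationError, NumericError, StateError
from .graphs import CompartmentGraph, DEFAULT_CLEARANCE

__all__ = [
    "KineticParameters",
    "AmountTrajectory",
    "VolumeSet",
    "build_rate_matrix",
    "solve_amounts",
    "simulate_amounts",
    "derive_volumes",
    "predict_concentrations",
    "central_curve",
]


@dataclass
class KineticParameters:
    """Transfer constants [1/s] plus the fixed plasma clearance [ml/s]."""

    rates: dict[str, float]
    clearance: float = DEFAULT_CLEARANCE

    def __post_init__(self) -> None:
        for name, value in self.rates.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(f"rate {name!r} must be positive and finite, got {value}")
        if not np.isfinite(self.clearance) or self.clearance <= 0:
            raise ConfigurationError(f"clearance must be positive, got {self.clearance}")

    def require(self, graph: CompartmentGraph) -> None:
        """Raise if any rate of the bound graph is missing a value."""
        for name in graph.rate_names():
            if name not in self.rates:
                raise ConfigurationError(f"missing value for rate {name!r}")


@dataclass
class AmountTrajectory:
    """Per-compartment amounts [umol] on a time grid [s]."""

    times: np.ndarray
    amounts: np.ndarray  # shape (n_compartments, n_times)
    compartments: tuple[str, ...]

    def amount(self, label: str) -> np.ndarray:
        return self.amounts[self.compartments.index(label)]


@dataclass
class VolumeSet:
    """Apparent distribution volumes [ml] and inter-compartmental flows [ml/s]."""

    volumes: dict[str, float]
    flows: dict[tuple[str, str], float] = field(default_factory=dict)

    def normalized(self) -> dict[str, float]:
        total = sum(self.volumes.values())
        return {c: v / total for c, v in self.volumes.items()}


def build_rate_matrix(graph: CompartmentGraph, params: KineticParameters) -> np.ndarray:
    """Assemble the compartmental rate matrix K such that dA/dt = K A.

    Off-diagonal entry (to, from) carries the transfer constant of the edge
    from -> to; each diagonal entry carries minus the total outflow of its
    compartment, including elimination.
    """
    params.require(graph)
    n = graph.n_compartments
    K = np.zeros((n, n))
    for (frm, to), name in graph.edges.items():
        k = params.rates[name]
        i, j = graph.index(to), graph.index(frm)
        K[i, j] += k
        K[j, j] -= k
    if graph.elimination is not None:
        comp, name = graph.elimination
        j = graph.index(comp)
        K[j, j] -= params.rates[name]
    return K


class MatrixPropagator:
    """Analytic propagator for ``dA/dt = K A``.

    Diagonalizes K once and evaluates ``expm(K t) a0`` on arbitrary time
    grids.  Compartmental matrices are generically diagonalizable with
    well-separated real eigenvalues; if the eigenbasis is ill-conditioned
    (near-defective K) the propagator falls back to scaling-and-squaring
    matrix exponentials per time point.
    """

    _COND_LIMIT = 1e10

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if not np.all(np.isfinite(matrix)):
            raise NumericError("rate matrix has non-finite entries")
        self.matrix = matrix
        self._use_eig = True
        try:
            w, V = np.linalg.eig(matrix)
            cond = np.linalg.cond(V)
            if not np.isfinite(cond) or cond > self._COND_LIMIT:
                raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
            self._w = w
            self._V = V
        except np.linalg.LinAlgError:
            self._use_eig = False

    def propagate(self, a0: np.ndarray, dts: np.ndarray) -> np.ndarray:
        """Return amounts with shape (n, len(dts)); dts must be >= 0."""
        dts = np.asarray(dts, dtype=float)
        if self._use_eig:
            c = np.linalg.solve(self._V, a0.astype(complex))
            # clip the decaying exponents to avoid harmless underflow warnings
            expo = np.clip((self._w[:, None] * dts[None, :]).real, -745.0, 50.0) \
                + 1j * (self._w[:, None] * dts[None, :]).imag
            out = (self._V @ (c[:, None] * np.exp(expo))).real
        else:
            out = np.empty((len(a0), len(dts)))
            for k, dt in enumerate(dts):
                out[:, k] = scipy.linalg.expm(self.matrix * dt) @ a0
        if not np.all(np.isfinite(out)):
            raise NumericError("propagation produced non-finite amounts")
        # wipe round-off negatives (amounts are non-negative by construction)
        tiny = 1e-10 * float(np.max(np.abs(a0)))
        out[(out < 0) & (out > -tiny)] = 0.0
        return out


def solve_amounts(matrix: np.ndarray, dose_amount: float, lag: float,
                  times, dose_index: int = 0,
                  compartments: tuple[str, ...] | None = None) -> AmountTrajectory:
    """Solve the bolus problem analytically on a time grid.

    Amounts are identically zero before the injection lag; at ``t = lag`` the
    full dose sits in the dose compartment; afterwards ``A(t) =
    expm(K (t - lag)) a0``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ConfigurationError("times must be a 1-d ascending array")
    if dose_amount <= 0:
        raise ConfigurationError("dose_amount must be positive")
    n = matrix.shape[0]
    a0 = np.zeros(n)
    a0[dose_index] = dose_amount
    amounts = np.zeros((n, len(times)))
    after = times >= lag
    if np.any(after):
        prop = MatrixPropagator(matrix)
        amounts[:, after] = prop.propagate(a0, times[after] - lag)
    if compartments is None:
        compartments = tuple(f"X{i}" for i in range(n))
    return AmountTrajectory(times=times, amounts=amounts, compartments=compartments)


def simulate_amounts(graph: CompartmentGraph, params: KineticParameters,
                     dose_amount: float, lag: float, times) -> AmountTrajectory:
    """Graph-aware convenience wrapper around :func:`solve_amounts`."""
    K = build_rate_matrix(graph, params)
    return solve_amounts(K, dose_amount, lag, times,
                         dose_index=graph.index(graph.dose_compartment),
                         compartments=graph.compartments)


def derive_volumes(graph: CompartmentGraph, params: KineticParameters) -> VolumeSet:
    """Apparent volumes and flows from the flow-balance chain.

    ``V_c = Cl / k_C0`` anchors the central volume; walking outward from the
    dose compartment, every bidirectional pair (i <-> j) yields ``Q = k_ij
    V_i`` and ``V_j = Q / k_ji``.  The topology must be a tree of
    bidirectional exchanges rooted at the dose compartment (true for all
    shipped presets); a unidirectional edge makes the volume underdetermined
    and raises.
    """
    params.require(graph)
    if graph.elimination is None:
        raise DerivationError("volume derivation requires an elimination rate to anchor V_c")
    root = graph.dose_compartment
    k_el = params.rates[graph.elimination[1]]
    volumes = {root: params.clearance / k_el}
    flows: dict[tuple[str, str], float] = {}
    pairs = graph.bidirectional_pairs()
    paired = set()
    for frm, to, _, _ in pairs:
        paired.update([(frm, to), (to, frm)])
    for edge in graph.edges:
        if edge not in paired:
            raise DerivationError(f"edge {edge} has no return rate; volumes are underdetermined")
    # breadth-first walk over the bidirectional pairs
    remaining = list(pairs)
    while remaining:
        progressed = False
        for pair in list(remaining):
            frm, to, fwd, back = pair
            if frm in volumes and to not in volumes:
                src, dst, k_out, k_in = frm, to, fwd, back
            elif to in volumes and frm not in volumes:
                src, dst, k_out, k_in = to, frm, back, fwd
            elif frm in volumes and to in volumes:
                remaining.remove(pair)
                progressed = True
                continue
            else:
                continue
            q = params.rates[k_out] * volumes[src]
            volumes[dst] = q / params.rates[k_in]
            flows[(src, dst)] = q
            remaining.remove(pair)
            progressed = True
        if not progressed:  # pragma: no cover - unreachable for connected graphs
            raise DerivationError("volume walk stalled; graph is not a rooted exchange tree")
    return VolumeSet(volumes=volumes, flows=flows)


def predict_concentrations(traj: AmountTrajectory, volumes: VolumeSet,
                           observed=None) -> dict[str, np.ndarray]:
    """Concentrations C = A / V in mM for the requested compartments."""
    labels = traj.compartments if observed is None else tuple(observed)
    out = {}
    for label in labels:
        v = volumes.volumes.get(label)
        if v is None:
            raise DerivationError(f"no volume available for compartment {label!r}")
        if not np.isfinite(v) or v <= 0:
            raise NumericError(f"non-positive volume for compartment {label!r}: {v}")
        out[label] = traj.amount(label) / v
    return out


def central_curve(fit, times, interval: float = 0.95, max_draws: int = 200):
    """Posterior summary of the central-compartment concentration curve.

    The central curve is the model-based surrogate for an arterial input
    function: it is inferred from the peripheral tissue data rather than
    measured.  For each retained posterior draw the population-typical curve
    is computed (typical rates, posterior-mean lag across datasets for that
    draw) and summarized pointwise by the median and an equal-tailed
    interval.

    Returns a dict with keys ``time``, ``median``, ``lower``, ``upper``.
    """
    theta = np.asarray(fit.theta)
    if theta.size == 0:
        raise StateError("fit contains no posterior draws")
    times = np.asarray(times, dtype=float)
    n_samples = theta.shape[0]
    idx = np.linspace(0, n_samples - 1, min(max_draws, n_samples)).astype(int)
    graph = fit.graph
    names = fit.rate_names
    curves = np.empty((len(idx), len(times)))
    for row, s in enumerate(idx):
        rates = {name: theta[s, j] for j, name in enumerate(names)}
        params = KineticParameters(rates, clearance=fit.clearance)
        lag = float(np.mean(fit.lag[s]))
        traj = simulate_amounts(graph, params, fit.dose_amount, lag, times)
        v_c = params.clearance / rates[graph.elimination[1]]
        curves[row] = traj.amount(graph.dose_compartment) / v_c
    alpha = (1.0 - interval) / 2.0
    return {
        "time": times,
        "median": np.median(curves, axis=0),
        "lower": np.quantile(curves, alpha, axis=0),
        "upper": np.quantile(curves, 1 - alpha, axis=0),
    }
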