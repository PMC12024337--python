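"""ODE assembly and time integration of the lumped circulation.

State vector (CGS pressures, dyn/cm²):

    y = [P_c,  P_ca^1, P_cim^1,  P_ca^2, P_cim^2, ...]

where P_c is the systemic Windkessel capacitor pressure and each coronary
branch contributes its arterial-compliance node P_ca and intramyocardial
node P_cim.  The aortic root pressure P_ao is algebraic: at every instant it
solves flow balance between the prescribed inflow, the systemic outlet and
the (possibly nonlinear, stenotic) coronary branches.  The intramyocardial
pressure waveform Pim(t) enters the Cim node as an external source, so the
node equation integrates d(P_cim − Pim)/dt.

Branch flow obeys ΔP = R·q + K·q·|q| (series conduit + stenosis), inverted
in closed form, which keeps the root solve for P_ao a fast scalar Newton
iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import (FluidProperties, NetworkSpec, StenosisSpec,
                      chain_resistance, poiseuille_resistance,
                      stenosis_coefficients)
from .units import DYN_CM2_TO_MMHG, MMHG_TO_DYN_CM2


def stenosis_dp(q: float, sten: StenosisSpec, fluid: FluidProperties | None = None) -> float:
    """Trans-stenotic pressure drop, mmHg, for flow ``q`` in cm³/s.

    Viscous (Poiseuille through the throat) plus turbulent-expansion term,
    odd in q so the drop always opposes the flow:
    ΔP = R_visc·q + kt·rho/(2A0²)·(A0/As − 1)²·q·|q|.
    """
    fluid = fluid or FluidProperties()
    r_visc, k_turb = stenosis_coefficients(sten, fluid)
    return (r_visc * q + k_turb * q * abs(q)) * DYN_CM2_TO_MMHG


@dataclass
class ODESystem:
    """Assembled right-hand side plus bookkeeping for one network."""

    network: NetworkSpec
    period: float
    rp: float
    rd: float
    c: float
    p_ref: float                       # dyn/cm²
    r_lin: np.ndarray                  # per-branch series resistance incl. Ra
    k_turb: np.ndarray                 # per-branch quadratic coefficient
    ra_micro: np.ndarray
    rv: np.ndarray
    ca: np.ndarray
    cim: np.ndarray
    pim_grid: np.ndarray               # (n_branches, n_t) dyn/cm²
    dpim_grid: np.ndarray
    q_in_grid: np.ndarray
    t_grid: np.ndarray

    @property
    def n_branches(self) -> int:
        return len(self.network.branches)

    @property
    def dim(self) -> int:
        return 1 + 2 * self.n_branches

    # -- periodic table lookups ------------------------------------------
    def _lookup(self, grid: np.ndarray, t: float) -> float:
        tm = math.fmod(t, self.period)
        x = tm / (self.t_grid[1] - self.t_grid[0])
        i = int(x)
        if i >= grid.shape[-1] - 1:
            i = grid.shape[-1] - 2
        f = x - i
        return grid[..., i] * (1.0 - f) + grid[..., i + 1] * f

    def branch_flows(self, p_ao, p_ca):
        """Invert ΔP = R q + K q|q| per branch (vectorized over branches)."""
        dp = p_ao - p_ca
        q = np.empty_like(self.r_lin)
        for i in range(self.r_lin.size):
            k = self.k_turb[i]
            d = dp[i] if np.ndim(dp) else dp
            if k == 0.0:
                q[i] = d / self.r_lin[i]
            else:
                r = self.r_lin[i]
                q[i] = math.copysign(
                    (-r + math.sqrt(r * r + 4.0 * k * abs(d))) / (2.0 * k), d)
        return q

    def solve_p_ao(self, t: float, y: np.ndarray, p_guess: float) -> float:
        """Scalar Newton solve of instantaneous flow balance for P_ao."""
        q_in = self._lookup(self.q_in_grid, t)
        p_c = y[0]
        p_ca = y[1::2]
        p = p_guess
        for _ in range(60):
            dp = p - p_ca
            q_cor = 0.0
            dq = 0.0
            for i in range(self.r_lin.size):
                k = self.k_turb[i]
                r = self.r_lin[i]
                d = dp[i]
                if k == 0.0:
                    q_cor += d / r
                    dq += 1.0 / r
                else:
                    s = math.sqrt(r * r + 4.0 * k * abs(d))
                    q_cor += math.copysign((s - r) / (2.0 * k), d)
                    dq += 1.0 / s
            f = (p - p_c) / self.rp + q_cor - q_in
            fp = 1.0 / self.rp + dq
            step = f / fp
            p -= step
            if abs(step) < 1.0e-7 * MMHG_TO_DYN_CM2:
                break
        return p

    def make_rhs(self):
        cell = {"p_ao": 100.0 * MMHG_TO_DYN_CM2}

        def rhs(t, y):
            p_ao = self.solve_p_ao(t, y, cell["p_ao"])
            cell["p_ao"] = p_ao
            p_c = y[0]
            p_ca = y[1::2]
            p_cim = y[2::2]
            q = self.branch_flows(p_ao, p_ca)
            q_m = (p_ca - p_cim) / self.ra_micro
            q_v = p_cim / self.rv
            dpim = self._lookup(self.dpim_grid, t)
            dy = np.empty_like(y)
            dy[0] = ((p_ao - p_c) / self.rp - (p_c - self.p_ref) / self.rd) / self.c
            dy[1::2] = (q - q_m) / self.ca
            dy[2::2] = dpim + (q_m - q_v) / self.cim
            return dy

        return rhs


def assemble(network: NetworkSpec) -> ODESystem:
    """Build the ODE system for a network (one algebraic aortic node, one
    systemic capacitor state, two capacitor states per coronary branch)."""
    fluid = network.fluid
    period = network.inflow.period
    t_grid = network.inflow.times
    nb = len(network.branches)
    r_lin = np.empty(nb)
    k_turb = np.empty(nb)
    ra_micro = np.empty(nb)
    rv = np.empty(nb)
    ca = np.empty(nb)
    cim = np.empty(nb)
    pim_grid = np.empty((nb, t_grid.size))
    dpim_grid = np.empty((nb, t_grid.size))
    for i, b in enumerate(network.branches):
        r = chain_resistance(b, fluid) + b.outlet.ra
        k = 0.0
        if b.stenosis is not None:
            rv_s, k = stenosis_coefficients(b.stenosis, fluid)
            r += rv_s
        r_lin[i] = r
        k_turb[i] = k
        ra_micro[i] = max(b.outlet.ra_micro, 1.0)
        rv[i] = max(b.outlet.rv + b.outlet.rv_micro, 1.0)
        ca[i] = b.outlet.ca
        cim[i] = b.outlet.cim
        if abs(b.outlet.pim.period - period) > 1e-9:
            raise ValueError("Pim waveform period must match the inflow period")
        pim = np.interp(t_grid, b.outlet.pim.times, b.outlet.pim.values) * MMHG_TO_DYN_CM2
        pim_grid[i] = pim
        dpim_grid[i] = np.gradient(pim, t_grid)
    q_in_grid = np.interp(t_grid, network.inflow.times, network.inflow.values)
    return ODESystem(
        network=network, period=period,
        rp=network.systemic.rp, rd=network.systemic.rd, c=network.systemic.c,
        p_ref=network.systemic.p_ref * MMHG_TO_DYN_CM2,
        r_lin=r_lin, k_turb=k_turb, ra_micro=ra_micro, rv=rv, ca=ca, cim=cim,
        pim_grid=pim_grid, dpim_grid=dpim_grid, q_in_grid=q_in_grid,
        t_grid=t_grid)


@dataclass
class BranchSeries:
    q: np.ndarray        # cm³/s at the ostium
    p_prox: np.ndarray   # mmHg just proximal to the lesion-bearing vessel
    p_dist: np.ndarray   # mmHg immediately distal to the stenosis element
    p_ca: np.ndarray     # mmHg
    p_cim: np.ndarray    # mmHg


@dataclass
class SimulationResult:
    """Time-resolved pressures and flows over all simulated cycles."""

    time: np.ndarray
    p_aorta: np.ndarray              # mmHg
    q_inflow: np.ndarray             # cm³/s
    q_systemic: np.ndarray           # cm³/s
    branches: dict                   # name -> BranchSeries
    cycle_index: np.ndarray
    n_cycles: int
    period: float
    network: NetworkSpec
    mode: str
    state: str

    def cycle_slice(self, k: int) -> slice:
        """Samples of cycle ``k`` (1-based), endpoint inclusive."""
        if not 1 <= k <= self.n_cycles:
            raise ValueError(f"cycle {k} outside 1..{self.n_cycles}")
        idx = np.nonzero((self.time >= (k - 1) * self.period - 1e-12)
                         & (self.time <= k * self.period + 1e-12))[0]
        return slice(idx[0], idx[-1] + 1)

    def cycle_mean(self, series: np.ndarray, k: int | None = None) -> float:
        k = self.n_cycles if k is None else k
        s = self.cycle_slice(k)
        return float(np.trapezoid(series[s], self.time[s]) / (self.time[s][-1] - self.time[s][0]))

    def coronary_outflow_mean(self, k: int | None = None) -> float:
        return sum(self.cycle_mean(b.q, k) for b in self.branches.values())

    def mass_balance_error(self, k: int | None = None) -> float:
        """Relative cycle-mean imbalance of inflow vs the distal outflows.

        Outflow is measured where it actually leaves the network (through Rd
        and each branch's Rv), so capacitor storage must net to zero over the
        cycle for the balance to close — a genuine periodicity check.
        """
        q_in = self.cycle_mean(self.q_inflow, k)
        sysp = self.network.systemic
        # p_aorta − q_systemic·rp recovers the capacitor node pressure
        p_c = self.p_aorta - self.q_systemic * sysp.rp * (1.0 / 1333.22)
        q_out = self.cycle_mean((p_c - sysp.p_ref) * 1333.22 / sysp.rd, k)
        for name, b in self.branches.items():
            rv = self.network.branch(name).outlet.rv
            q_out += self.cycle_mean(b.p_cim * 1333.22 / max(rv, 1.0), k)
        return abs(q_in - q_out) / abs(q_in)


def _reconstruct(system: ODESystem, t: np.ndarray, y: np.ndarray):
    """Vectorized recovery of P_ao and branch flows on the output grid."""
    net = system.network
    nb = system.n_branches
    nt = t.size
    p_ao = np.empty(nt)
    q = np.empty((nb, nt))
    guess = 100.0 * MMHG_TO_DYN_CM2
    for j in range(nt):
        p = system.solve_p_ao(t[j], y[:, j], guess)
        guess = p
        p_ao[j] = p
        q[:, j] = system.branch_flows(p, y[1::2, j])
    q_sys = (p_ao - y[0]) / system.rp
    branches = {}
    for i, b in enumerate(net.branches):
        fluid = net.fluid
        # resistance of shared upstream trunk(s) before the named vessel
        r_up = sum(poiseuille_resistance(s.radius, s.length, fluid)
                   for s in b.chain[:-1])
        r_own = poiseuille_resistance(b.vessel.radius, b.vessel.length, fluid)
        frac = min(b.lesion_start_cm / b.vessel.length, 1.0)
        p_prox = p_ao - r_up * q[i]
        p_dist = p_prox - frac * r_own * q[i]
        if b.stenosis is not None:
            rv_s, k = stenosis_coefficients(b.stenosis, fluid)
            p_dist = p_dist - rv_s * q[i] - k * q[i] * np.abs(q[i])
        branches[b.name] = BranchSeries(
            q=q[i],
            p_prox=p_prox * DYN_CM2_TO_MMHG,
            p_dist=p_dist * DYN_CM2_TO_MMHG,
            p_ca=y[1 + 2 * i] * DYN_CM2_TO_MMHG,
            p_cim=y[2 + 2 * i] * DYN_CM2_TO_MMHG,
        )
    return p_ao, q_sys, branches


def initial_state(system: ODESystem, init: str = "warm") -> np.ndarray:
    """Initial condition: 'zero' starts every capacitor at 0; 'warm' starts
    near the expected periodic state (diastolic aortic pressure)."""
    y0 = np.zeros(system.dim)
    if init == "warm":
        # start at the quasi-static periodic means: the systemic capacitor
        # sits at P_ao·Rd/(Rp+Rd) with P_ao ≈ (systemic share of mean
        # inflow)·(Rp+Rd); coronary nodes at their resistive dividers
        q_mean = float(np.trapezoid(system.q_in_grid, system.t_grid) / system.period)
        p_ao_est = 0.96 * q_mean * (system.rp + system.rd)
        # t = 0 is the onset of systole: capacitors start near their
        # end-diastolic (minimum) values, not their cycle means
        y0[0] = 0.88 * p_ao_est * system.rd / (system.rp + system.rd)
        for i in range(system.n_branches):
            r_up = system.r_lin[i]
            ram = system.ra_micro[i]
            rv = system.rv[i]
            q_br = p_ao_est / (r_up + ram + rv)
            y0[1 + 2 * i] = 0.95 * (p_ao_est - q_br * r_up)
            # the Cim node rides on Pim: offset its instantaneous start value
            # by the (mean) hydraulic divider minus the mean of Pim
            pim_mean = float(np.trapezoid(system.pim_grid[i], system.t_grid)
                             / system.period)
            y0[2 + 2 * i] = system.pim_grid[i, 0] + (q_br * rv - pim_mean)
    elif init != "zero":
        raise ValueError("init must be 'warm' or 'zero'")
    return y0


def simulate(system: ODESystem, n_cycles: int = 7, dt: float = 1.0e-3,
             init: str = "warm", y0: np.ndarray | None = None,
             rtol: float = 1.0e-6, atol: float = 1.0) -> SimulationResult:
    """Integrate the network over ``n_cycles`` cardiac cycles.

    A stiffness-tolerant adaptive scheme (LSODA) integrates the capacitor
    states; output is interpolated onto a fixed ``dt`` grid.  Results are
    conventionally read from the final cycle.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    period = system.period
    t_end = n_cycles * period
    n_per = int(round(period / dt))
    t_eval = np.linspace(0.0, t_end, n_cycles * n_per + 1)
    if y0 is None:
        y0 = initial_state(system, init)
    sol = solve_ivp(system.make_rhs(), (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol, max_step=period / 20.0)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad = np.nonzero(~np.all(np.isfinite(sol.y), axis=0))[0]
        t_bad = sol.t[bad[0]] if bad.size else sol.t[-1]
        raise RuntimeError(f"integration failed near t={t_bad:.4f} s: {sol.message}")
    p_ao, q_sys, branches = _reconstruct(system, sol.t, sol.y)
    cycle_index = np.minimum((sol.t / period).astype(int) + 1, n_cycles)
    return SimulationResult(
        time=sol.t, p_aorta=p_ao * DYN_CM2_TO_MMHG, q_inflow=np.array(
            [system._lookup(system.q_in_grid, t) for t in sol.t]),
        q_systemic=q_sys, branches=branches, cycle_index=cycle_index,
        n_cycles=n_cycles, period=period, network=system.network,
        mode=system.network.mode, state=system.network.state)


def periodicity_residual(result: SimulationResult, k: int) -> float:
    """Max over monitored nodes of the relative change in cycle-mean pressure
    between cycle ``k`` and cycle ``k − 1``."""
    if k < 2:
        raise ValueError("periodicity residual needs k >= 2")
    if k > result.n_cycles:
        raise ValueError(f"cycle {k} beyond the simulated {result.n_cycles}")
    res = 0.0
    series = [result.p_aorta]
    for b in result.branches.values():
        series.extend([b.p_ca, b.p_cim])
    for s in series:
        m_k = result.cycle_mean(s, k)
        m_p = result.cycle_mean(s, k - 1)
        if m_k != 0:
            res = max(res, abs(m_k - m_p) / abs(m_k))
    return res


def cycles_to_converge(result: SimulationResult, tol: float = 0.01) -> int:
    """First cycle k ≥ 2 whose periodicity residual falls below ``tol``."""
    for k in range(2, result.n_cycles + 1):
        if periodicity_residual(result, k) < tol:
            return k
    return result.n_cycles + 1
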