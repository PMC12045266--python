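"""Asymptotic pore-density kinetics and electroporated membrane conductivity.

The membrane is described by the asymptotic reduction of the Smoluchowski
pore-energy model: a single ordinary differential equation for the areal
density of hydrophilic pores,

    dN/dt = alpha * exp((Vm/Vep)^2) * (1 - (N/N0) * exp(-q (Vm/Vep)^2)),

together with a pore-mediated membrane conductivity

    sigma_m(Vm, N) = sigma_m0 + N * pi * rp^2 * sigma_p * K(Vm),

where K is the dimensionless voltage-dependent pore conductance factor
accounting for pore-entrance effects and ionic partitioning (energy barrier
``w0`` in units of kT, relative entrance length ``n_rel``).

All quantities are SI.  The defaults are the classical parameter set for
mammalian cell membranes (DC-3F-type fibroblasts): alpha = 1e9 m^-2 s^-1,
N0 = 1.5e9 m^-2, Vep = 0.258 V, q = 2.46, rp = 0.76 nm, w0 = 2.65,
n_rel = 0.15, sigma_p = 1.3 S/m, T = 295 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

EPS0 = 8.854e-12  # vacuum permittivity, F/m

# exp() overflows double precision slightly above 709
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class PoreModelParams:
    """Parameters of the pore-creation ODE and pore conductance.

    Attributes
    ----------
    alpha : float
        Pore creation-rate coefficient (m^-2 s^-1).
    N0 : float
        Equilibrium pore density at Vm = 0 (m^-2).
    Vep : float
        Characteristic electroporation voltage (V).
    q : float
        Electroporation constant (dimensionless).
    rp : float
        Fixed pore radius (m).
    w0 : float
        Pore energy barrier in units of kT (dimensionless).
    n_rel : float
        Relative pore entrance length (dimensionless).
    sigma_p : float
        Conductivity of the solution filling a pore (S/m).
    T : float
        Temperature (K).
    R_gas : float
        Gas constant (J K^-1 mol^-1).
    F : float
        Faraday constant (C mol^-1).
    """

    alpha: float = 1.0e9
    N0: float = 1.5e9
    Vep: float = 0.258
    q: float = 2.46
    rp: float = 0.76e-9
    w0: float = 2.65
    n_rel: float = 0.15
    sigma_p: float = 1.3
    T: float = 295.0
    R_gas: float = 8.314
    F: float = 9.65e4

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"PoreModelParams.{name} must be positive, got {value!r}")

    def with_sigma_p_from_bulk(self, sigma_e: float, sigma_i: float) -> "PoreModelParams":
        """Return a copy whose pore conductivity is the harmonic-mean value
        2*sigma_e*sigma_i/(sigma_e+sigma_i) instead of the tabulated default."""
        from dataclasses import replace

        return replace(self, sigma_p=sigma_p_from_bulk(sigma_e, sigma_i))


@dataclass(frozen=True)
class MembraneProperties:
    """Passive electrical properties of one membrane, as a thin sheet.

    The membrane of thickness ``d`` is represented in the field solver as a
    zero-thickness interface with specific capacitance Cm = eps0*eps_r/d and
    resting surface conductance g0 = sigma_m0/d.
    """

    sigma_m0: float  # resting membrane conductivity, S/m
    eps_r: float  # relative permittivity
    d: float  # physical thickness, m

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("membrane thickness d must be positive")
        if not self.sigma_m0 > 0 or not self.eps_r > 0:
            raise ValueError("sigma_m0 and eps_r must be positive")

    @property
    def g0(self) -> float:
        """Resting surface conductance sigma_m0/d (S/m^2)."""
        return self.sigma_m0 / self.d

    @property
    def Cm(self) -> float:
        """Specific capacitance eps0*eps_r/d (F/m^2)."""
        return EPS0 * self.eps_r / self.d


#: Default membrane property set: plasma/ER membranes 10 nm thick with
#: sigma_m0 = 1.1e-7 S/m, nuclear envelope 40 nm thick with 1.1e-5 S/m,
#: relative permittivity 5 for all.
DEFAULT_MEMBRANES: dict[str, MembraneProperties] = {
    "plasma": MembraneProperties(sigma_m0=1.1e-7, eps_r=5.0, d=0.01e-6),
    "nucleus": MembraneProperties(sigma_m0=1.1e-5, eps_r=5.0, d=0.04e-6),
    "er": MembraneProperties(sigma_m0=1.1e-7, eps_r=5.0, d=0.01e-6),
}


def sigma_p_from_bulk(sigma_e: float, sigma_i: float) -> float:
    """Pore conductivity as the harmonic mean of extra/intracellular bulk
    conductivities: sigma_p = 2*sigma_e*sigma_i/(sigma_e + sigma_i)."""
    if sigma_e <= 0 or sigma_i <= 0:
        raise ValueError("bulk conductivities must be positive")
    return 2.0 * sigma_e * sigma_i / (sigma_e + sigma_i)


def _s_of(Vm, params: PoreModelParams):
    """Dimensionless squared reduced voltage s = (Vm/Vep)^2, clipped so that
    exp(s), exp(q*s) and N0*exp(q*s) all stay representable (physically Vm
    never gets there; transient nonlinear-solver iterates may)."""
    s = np.square(np.asarray(Vm, dtype=float) / params.Vep)
    return np.minimum(s, 600.0 / max(params.q, 1.0))


def pore_rate(Vm, N, params: PoreModelParams = PoreModelParams()):
    """Pore creation rate dN/dt (m^-2 s^-1) at transmembrane potential Vm.

    Vanishes at the voltage-dependent equilibrium density N0*exp(q*(Vm/Vep)^2);
    at rest (Vm = 0, N = N0) the membrane is in equilibrium.
    """
    s = _s_of(Vm, params)
    N = np.asarray(N, dtype=float)
    return params.alpha * np.exp(s) * (1.0 - (N / params.N0) * np.exp(-params.q * s))


def equilibrium_density(Vm, params: PoreModelParams = PoreModelParams()):
    """Steady-state pore density N0*exp(q*(Vm/Vep)^2) for constant Vm (m^-2)."""
    s = _s_of(Vm, params)
    return params.N0 * np.exp(params.q * s)


def advance_pore_density(N, Vm_frozen, dt: float, params: PoreModelParams = PoreModelParams()):
    """Advance the pore density by ``dt`` with the voltage frozen.

    For frozen Vm the kinetics are linear in N, dN/dt = a - b*N with
    a = alpha*exp(s) and b = (alpha/N0)*exp((1-q)*s), so the update is the
    exact exponential integrator

        N(t+dt) = a/b + (N - a/b) * exp(-b*dt).

    This is unconditionally stable and exactly composable over sub-steps,
    which matters because a reaches ~1e18 m^-2 s^-1 near 1.5 V where any
    explicit scheme at field-solver time steps would blow up.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = _s_of(Vm_frozen, params)
    b = (params.alpha / params.N0) * np.exp((1.0 - params.q) * s)
    n_inf = params.N0 * np.exp(params.q * s)  # = a/b, finite thanks to the clip in _s_of
    # N' = N + (n_inf - N)(1 - e^(-b dt)); the expm1 form avoids the
    # catastrophic cancellation of n_inf + (N - n_inf) e^(-b dt) when
    # n_inf >> N and b*dt << 1 (the usual suprathreshold regime)
    return np.asarray(N, dtype=float) + (n_inf - np.asarray(N, dtype=float)) * (-np.expm1(-b * dt))


def pore_conductance_factor(Vm, params: PoreModelParams = PoreModelParams()):
    """Voltage-dependent pore conductance factor K(Vm), dimensionless.

    Standard asymptotic-model expression with dimensionless voltage
    vm = F*Vm/(R*T):

        K = (e^vm - 1) / ( A(vm) e^vm - B(vm) ),
        A = (w0 e^(w0 - n vm) - n vm) / (w0 - n vm),
        B = (w0 e^(w0 + n vm) + n vm) / (w0 + n vm).

    K is even in Vm, tends to exp(-w0) as Vm -> 0 and to 1 as |Vm| -> inf.
    The removable singularities at vm = 0 and n*vm = +/- w0 are handled by
    their analytic limits; for large vm the expression is evaluated in a
    form with exp(vm) divided out to avoid overflow.
    """
    w0 = params.w0
    n = params.n_rel
    vm = np.abs(np.asarray(Vm, dtype=float)) * params.F / (params.R_gas * params.T)
    vm = np.atleast_1d(vm)

    x = w0 - n * vm
    y = w0 + n * vm
    # limit of (w0*e^x - (w0 - x))/x-type brackets as the denominator -> 0 is w0 + 1
    A = np.where(np.abs(x) > 1e-8, (w0 * np.exp(np.minimum(x, _EXP_CLIP)) - n * vm) / np.where(x == 0, 1.0, x), w0 + 1.0)
    B = np.where(np.abs(y) > 1e-8, (w0 * np.exp(np.minimum(y, _EXP_CLIP)) + n * vm) / np.where(y == 0, 1.0, y), w0 + 1.0)

    # divide numerator and denominator by e^vm: K = (1 - e^-vm)/(A - B e^-vm)
    emv = np.exp(-vm)
    denom = A - B * emv
    K = np.where(vm > 1e-3, (1.0 - emv) / np.where(denom == 0, 1.0, denom), np.exp(-w0))
    if np.isscalar(Vm) or np.ndim(Vm) == 0:
        return float(K[0])
    return K


def membrane_conductivity(N, Vm, pore_params: PoreModelParams, mem_props: MembraneProperties):
    """Electroporated membrane conductivity sigma_m = sigma_m0 + N pi rp^2 sigma_p K(Vm) (S/m).

    The field solver uses the surface conductance g = sigma_m/d.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("pore density N must be nonnegative")
    K = pore_conductance_factor(Vm, pore_params)
    sigma = mem_props.sigma_m0 + N * np.pi * pore_params.rp**2 * pore_params.sigma_p * K
    if np.ndim(N) == 0 and np.ndim(Vm) == 0:
        return float(sigma)
    return sigma
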