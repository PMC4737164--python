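"""Finite-lattice nonspecific binding isotherm and SPR response transforms.

A protein that occludes ``n`` base pairs binds a linear DNA duplex of ``N``
base pairs without sequence preference.  For an infinite lattice the
McGhee-von Hippel closed form relates the binding density ``v`` (bound
proteins per base pair) to the free protein concentration ``L``::

    v/L = Ka * (1 - n*v) * ((1 - n*v) / (1 - (n-1)*v))**(n-1)

The finite-lattice (Tsodikov) end correction multiplies the right-hand side
by ``(N - n + 1) / N``, accounting for the reduced number of start positions
available to an ``n``-mer on a short duplex.  The relation is implicit in
``v``; :func:`solve_binding_density` inverts it numerically.

:func:`exact_lattice_density` is an independent oracle: the grand-partition
sum over all arrangements of non-overlapping ``n``-mers on a finite lattice,
evaluated with exact binomial coefficients.  The corrected closed form is an
end-effect *approximation*; the two agree exactly only at ``n = 1`` and
converge as ``N`` grows.

SPR observes mass on the chip surface, not ``v`` directly.  Because protein
and DNA have similar refractive-index increments, the equilibrium response
``R_eq`` relative to the DNA-immobilization response ``R_L`` approximates the
bound-protein to immobilized-DNA mass ratio, giving the transform

    v = (M_DNA / (N * M_protein)) * (R_eq / R_L)

implemented by :func:`response_to_density` / :func:`density_to_response`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LatticeModel",
    "MassContext",
    "LatticeDomainError",
    "isotherm_rhs",
    "solve_binding_density",
    "exact_lattice_density",
    "response_to_density",
    "density_to_response",
]

#: largest lattice supported by the exact combinatorial oracle
EXACT_N_MAX = 400


class LatticeDomainError(ValueError):
    """Binding density outside the physically meaningful range [0, 1/n)."""


@dataclass(frozen=True)
class LatticeModel:
    """Nonspecific lattice-binding model parameters.

    Parameters
    ----------
    Ka : float
        Association constant, per molar.  ``Kd = 1 / Ka``.
    n : int
        Site size: base pairs occluded by one bound protein.
    N : int
        Lattice (duplex) length in base pairs, ``N >= n``.
    """

    Ka: float
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Ka) and self.Ka > 0):
            raise ValueError(f"Ka must be finite and > 0, got {self.Ka}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"site size n must be a positive integer, got {self.n}")
        if int(self.N) != self.N or self.N < self.n:
            raise ValueError(f"lattice length N must be an integer >= n, got N={self.N}, n={self.n}")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "N", int(self.N))

    @property
    def Kd(self) -> float:
        """Dissociation constant (molar)."""
        return 1.0 / self.Ka

    @property
    def v_max(self) -> float:
        """Saturating binding density, 1/n proteins per bp."""
        return 1.0 / self.n

    @property
    def end_correction(self) -> float:
        """Finite-lattice factor (N - n + 1) / N."""
        return (self.N - self.n + 1) / self.N


@dataclass(frozen=True)
class MassContext:
    """Masses and immobilization level linking SPR responses to densities.

    Parameters
    ----------
    M_protein, M_DNA : float
        Molar masses of protein and immobilized duplex (g/mol).
    N : int
        Duplex length (bp).
    R_L : float
        DNA immobilization response (RU).
    """

    M_protein: float
    M_DNA: float
    N: int
    R_L: float

    def __post_init__(self) -> None:
        for name in ("M_protein", "M_DNA"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and > 0, got {val}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"duplex length N must be a positive integer, got {self.N}")
        if self.R_L == 0:
            raise ZeroDivisionError("R_L (DNA immobilization response) is zero; cannot normalize binding responses")
        if not (math.isfinite(self.R_L) and self.R_L > 0):
            raise ValueError(f"R_L must be finite and > 0, got {self.R_L}")
        object.__setattr__(self, "N", int(self.N))


def _rhs_unchecked(v: np.ndarray, model: LatticeModel) -> np.ndarray:
    """Vectorized isotherm right-hand side without domain validation."""
    n = model.n
    free = 1.0 - n * v
    if n == 1:
        occ = np.ones_like(free)
    else:
        occ = (free / (1.0 - (n - 1) * v)) ** (n - 1)
    return model.Ka * free * occ * model.end_correction


def isotherm_rhs(v: float, model: LatticeModel) -> float:
    """Ratio v/L predicted by the finite-lattice isotherm at density ``v``.

    Returns ``Ka * (1-nv) * ((1-nv)/(1-(n-1)v))**(n-1) * (N-n+1)/N``,
    per molar.  Strictly decreasing in ``v`` on ``[0, 1/n)``.

    Raises
    ------
    LatticeDomainError
        If ``v < 0`` (unphysical) or ``v >= 1/n`` (lattice oversaturated).
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise LatticeDomainError(f"binding density must be >= 0, got {v}")
    if np.any(v_arr >= 1.0 / model.n):
        raise LatticeDomainError(
            f"binding density {v} oversaturates the lattice (v must be < 1/n = {1.0 / model.n:g})"
        )
    out = _rhs_unchecked(v_arr, model)
    return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


# 1/n * 2**-80 ~ 1e-25: bisection reaches float64 resolution well within budget
_BISECT_ITERS = 80
_V_CEIL = 1.0 - 1e-12


def solve_binding_density(L, model: LatticeModel):
    """Invert the isotherm: binding density ``v`` at free concentration ``L``.

    Solves ``v / L = isotherm_rhs(v)`` for the unique root in ``[0, 1/n)``
    by bisection on ``g(v) = L * rhs(v) - v`` (strictly decreasing, so the
    bracket is guaranteed).  Accepts a scalar or array of concentrations
    (molar); vectorized over ``L``.
    """
    L_arr = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L_arr)):
        raise ValueError("concentrations must be finite")
    if np.any(L_arr < 0):
        raise ValueError("concentrations must be >= 0")

    shape = L_arr.shape
    flat = np.atleast_1d(L_arr).astype(float)
    lo = np.zeros_like(flat)
    hi = np.full_like(flat, model.v_max * _V_CEIL)
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        g = flat * _rhs_unchecked(mid, model) - mid
        take_hi = g > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    v = 0.5 * (lo + hi)
    v[flat == 0.0] = 0.0
    if shape == ():
        return float(v[0])
    return v.reshape(shape)


def exact_lattice_density(L: float, model: LatticeModel) -> float:
    """Exact binding density from the finite-lattice grand partition function.

    With ``x = Ka * L`` and ``c_k = C(N - k*n + k, k)`` the number of ways to
    place ``k`` non-overlapping ``n``-mers on ``N`` sites,

        v = (1/N) * sum_k k * c_k * x**k / sum_k c_k * x**k

    summed over ``k = 0 .. floor(N/n)``.  Binomial coefficients are exact
    integers; the sums are evaluated in log space for stability.  This is the
    independent oracle against which the approximate closed-form isotherm is
    checked.
    """
    if not (math.isfinite(L) and L >= 0):
        raise ValueError(f"concentration must be finite and >= 0, got {L}")
    if model.N > EXACT_N_MAX:
        raise ValueError(
            f"exact enumeration supports N <= {EXACT_N_MAX}; use solve_binding_density for longer lattices"
        )
    if L == 0.0:
        return 0.0
    x = model.Ka * L
    n, N = model.n, model.N
    k_max = N // n
    log_x = math.log(x)
    log_terms = np.array(
        [math.log(math.comb(N - k * n + k, k)) + k * log_x for k in range(k_max + 1)]
    )
    # numerator sum_k k*c_k*x^k: drop the k=0 term (weight 0)
    ks = np.arange(1, k_max + 1)
    log_num = logsumexp(log_terms[1:] + np.log(ks))
    log_den = logsumexp(log_terms)
    return float(math.exp(log_num - log_den) / N)


def response_to_density(R_eq, ctx: MassContext):
    """Convert an equilibrium SPR response (RU) to binding density ``v``.

    ``v = (M_DNA / (N * M_protein)) * (R_eq / R_L)`` — the mass-ratio
    approximation valid for matched refractive-index increments.  Vectorized
    over ``R_eq``; may return small negative values for slightly negative
    double-referenced responses (callers decide whether to clamp).
    """
    scale = ctx.M_DNA / (ctx.N * ctx.M_protein * ctx.R_L)
    out = np.asarray(R_eq, dtype=float) * scale
    return float(out) if np.ndim(R_eq) == 0 else out


def density_to_response(v, ctx: MassContext):
    """Exact inverse of :func:`response_to_density`.

    ``R_eq = R_L * (M_protein / M_DNA) * N * v`` (RU).
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise ValueError("binding density must be >= 0")
    out = v_arr * (ctx.R_L * ctx.M_protein * ctx.N / ctx.M_DNA)
    return float(out) if np.ndim(v) == 0 else out
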