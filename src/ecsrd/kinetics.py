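"""Species and reaction kinetics.

Reactions are specified as stoichiometry plus symbolic rate expressions over
species names.  Expressions are parsed into sympy trees and compiled to
vectorized numpy callables, so the same reaction right-hand side is evaluated
simultaneously over every voxel of the grid.  By default mass-action kinetics
apply: the net rate of ``a A + b B <-> c C`` is

    rate = kf * [A]^a * [B]^b  -  kb * [C]^c        (mM/ms)

and each species' time derivative receives ``-stoich * rate`` on the left
side and ``+stoich * rate`` on the right.  With ``mass_action=False`` the
expressions are taken as the full forward/backward rates and
``rate = kf - kb``.  Rate constants may themselves be expressions of the
concentrations, e.g. the sigmoidal astrocyte uptake rate
``kf = kb / (1 + exp(-([K] - kth) / 1.15))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "RateExpression",
    "parse_rate_expression",
    "Reaction",
    "RateTerm",
    "ReactionSystem",
    "numerical_jacobian",
]


@dataclass
class Species:
    """A diffusing extracellular quantity.

    Parameters
    ----------
    name : identifier used in rate expressions.
    d : free diffusion coefficient in um^2/ms (scalar, or 3-tuple for
        anisotropic diffusion).  Immobile species (e.g. buffer sites) use 0.
    charge : signed valence in elementary charges.
    initial : initial concentration in mM relative to free volume; scalar,
        per-voxel array, or function of the voxel-center coordinates.
    boundary : ``"neumann"`` for zero flux (default), or a number for a
        Dirichlet boundary held at that concentration in mM.
    """

    name: str
    d: float | tuple[float, float, float] = 0.0
    charge: int = 0
    initial: object = 0.0
    boundary: object = "neumann"
    conc: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not str(self.name).isidentifier():
            raise ValueError(f"species name {self.name!r} is not an identifier")
        d_arr = np.asarray(self.d, dtype=float)
        if np.any(d_arr < 0):
            raise ValueError(f"species {self.name}: d must be >= 0")
        if isinstance(self.boundary, str):
            if self.boundary.lower() != "neumann":
                raise ValueError(
                    f"species {self.name}: boundary must be 'neumann' or a number"
                )
            self.boundary = "neumann"
        else:
            self.boundary = float(self.boundary)

    @property
    def d_tuple(self) -> tuple[float, float, float]:
        d_arr = np.broadcast_to(np.asarray(self.d, dtype=float), (3,))
        return tuple(float(v) for v in d_arr)

    @property
    def is_mobile(self) -> bool:
        return any(v > 0 for v in self.d_tuple)


_ALLOWED_FUNCS = {
    name: getattr(sp, name)
    for name in (
        "exp log sqrt sin cos tan asin acos atan sinh cosh tanh "
        "asinh acosh atanh Abs Min Max floor ceiling atan2 sign"
    ).split()
}
_ALLOWED_FUNCS["abs"] = sp.Abs
_ALLOWED_FUNCS["pow"] = sp.Pow
_ALLOWED_FUNCS["pi"] = sp.pi
_ALLOWED_FUNCS["E"] = sp.E


class RateExpression:
    """An evaluable expression tree over species symbols.

    Wraps a sympy expression together with the ordered species list it is
    evaluated against; compiled once to a numpy callable and broadcast over
    arbitrarily-shaped concentration arrays.
    """

    def __init__(self, expr: sp.Expr, species_names: Sequence[str]):
        self.expr = sp.sympify(expr)
        self.species_names = list(species_names)
        free = {str(s) for s in self.expr.free_symbols}
        unknown = free - set(self.species_names)
        if unknown:
            raise ValueError(
                f"rate expression uses undeclared symbols: {sorted(unknown)}"
            )
        syms = [sp.Symbol(n) for n in self.species_names]
        self._fn: Callable = sp.lambdify(syms, self.expr, modules="numpy")

    def __call__(self, conc):
        """Evaluate at ``conc``: mapping name -> value, or an array whose
        leading axis indexes species in declaration order."""
        if isinstance(conc, Mapping):
            args = [np.asarray(conc[n], dtype=float) for n in self.species_names]
        else:
            arr = np.asarray(conc, dtype=float)
            args = [arr[i] for i in range(len(self.species_names))]
        out = self._fn(*args)
        return np.asarray(out, dtype=float) + np.zeros_like(args[0]) if args else out

    def __repr__(self):
        return f"RateExpression({self.expr})"


def parse_rate_expression(source, species_names: Sequence[str]) -> RateExpression:
    """Parse a rate expression from a string, number, or sympy tree.

    Symbols must be declared species names; the elementary function set of a
    standard math library (exp, log, sqrt, trig, ...) is available.
    """
    if isinstance(source, RateExpression):
        return RateExpression(source.expr, species_names)
    if isinstance(source, str):
        local = {n: sp.Symbol(n) for n in species_names}
        local.update(_ALLOWED_FUNCS)
        try:
            expr = sp.sympify(source, locals=local)
        except (sp.SympifyError, SyntaxError, TypeError) as exc:
            raise ValueError(f"malformed rate expression {source!r}: {exc}") from exc
    else:
        expr = sp.sympify(source)
    return RateExpression(expr, species_names)


def _as_stoich(side) -> dict[str, int]:
    """Normalize a reaction side to {species_name: positive int coefficient}.

    Accepts a mapping name -> coefficient, a sequence of names (with
    repetition), or a string like ``"k + A"`` / ``"2 A + AK"``.
    """
    if isinstance(side, str):
        terms = []
        for part in side.split("+"):
            part = part.replace("*", " ").strip()
            if not part:
                raise ValueError(f"empty term in reaction side {side!r}")
            fields = part.split()
            if len(fields) == 2 and fields[0].isdigit():
                terms.extend([fields[1]] * int(fields[0]))
            elif len(fields) == 1 and fields[0][0].isdigit():
                # forms like "2A"
                i = 0
                while i < len(fields[0]) and fields[0][i].isdigit():
                    i += 1
                terms.extend([fields[0][i:]] * int(fields[0][:i]))
            elif len(fields) == 1:
                terms.append(fields[0])
            else:
                raise ValueError(f"cannot parse reaction term {part!r}")
        side = terms
    if isinstance(side, Mapping):
        items = dict(side)
    else:
        items = {}
        for name in side:
            items[name] = items.get(name, 0) + 1
    out = {}
    for name, coeff in items.items():
        c = int(coeff)
        if c != coeff or c <= 0:
            raise ValueError(
                f"stoichiometric coefficient for {name} must be a positive integer"
            )
        out[str(name)] = c
    return out


@dataclass
class Reaction:
    """Stoichiometry plus forward/backward rate expressions.

    ``lhs``/``rhs`` are species names (a name, a sequence with repetition, or
    a mapping name -> coefficient).  ``kf``/``kb`` are numbers or expression
    sources.  With ``mass_action=True`` the stoichiometry is implicit in the
    rate law; otherwise kf and kb are the full rates.
    """

    lhs: object
    rhs: object
    kf: object
    kb: object = 0.0
    mass_action: bool = True

    def __post_init__(self):
        self.lhs = _as_stoich(self.lhs)
        self.rhs = _as_stoich(self.rhs)


@dataclass
class RateTerm:
    """A direct contribution ``expr`` (mM/ms) to d[species]/dt."""

    species: str
    expr: object


class ReactionSystem:
    """All reactions and rate terms over an ordered species list.

    Provides the vectorized reaction right-hand side and its numerically
    approximated Jacobian, evaluated per voxel.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        reactions: Sequence[Reaction] = (),
        rate_terms: Sequence[RateTerm] = (),
    ):
        self.species_names = list(species_names)
        self.index = {n: i for i, n in enumerate(self.species_names)}
        self.reactions = list(reactions)
        self.rate_terms = list(rate_terms)
        for r in self.reactions:
            for name in {**r.lhs, **r.rhs}:
                if name not in self.index:
                    raise ValueError(f"reaction references undeclared species {name!r}")
        for t in self.rate_terms:
            if t.species not in self.index:
                raise ValueError(f"rate term references undeclared species {t.species!r}")
        self._compiled = []
        for r in self.reactions:
            kf = parse_rate_expression(r.kf, self.species_names)
            kb = parse_rate_expression(r.kb, self.species_names)
            self._compiled.append((r, kf, kb))
        self._terms = [
            (self.index[t.species], parse_rate_expression(t.expr, self.species_names))
            for t in self.rate_terms
        ]
        involved: set[str] = set()
        for r, kf, kb in self._compiled:
            involved |= set(r.lhs) | set(r.rhs)
            involved |= {str(s) for s in kf.expr.free_symbols}
            involved |= {str(s) for s in kb.expr.free_symbols}
        for t in self.rate_terms:
            involved.add(t.species)
            involved |= {
                str(s)
                for s in parse_rate_expression(t.expr, self.species_names).expr.free_symbols
            }
        #: names of species that appear in any reaction or rate term; only
        #: these can have a nonzero reaction rhs or Jacobian row/column
        self.participating = [n for n in self.species_names if n in involved]

    def __len__(self):
        return len(self.reactions) + len(self.rate_terms)

    def reaction_rate(self, reaction_i: int, conc: np.ndarray) -> np.ndarray:
        """Net rate of one reaction (mM/ms) at concentrations ``conc`` with
        species on the leading axis."""
        r, kf, kb = self._compiled[reaction_i]
        return self._rate(r, kf, kb, np.asarray(conc, dtype=float))

    def _rate(self, r: Reaction, kf, kb, conc: np.ndarray) -> np.ndarray:
        fwd = kf(conc)
        bwd = kb(conc)
        if not r.mass_action:
            return fwd - bwd
        for name, s in r.lhs.items():
            fwd = fwd * conc[self.index[name]] ** s
        for name, s in r.rhs.items():
            bwd = bwd * conc[self.index[name]] ** s
        return fwd - bwd

    def rhs(self, conc: np.ndarray) -> np.ndarray:
        """d[conc]/dt from reactions and rate terms, shape of ``conc``.

        Each reaction's rate is computed once and added with opposite signs
        to both sides, so linear conservation sums cancel exactly in floating
        point.
        """
        conc = np.asarray(conc, dtype=float)
        out = np.zeros_like(conc)
        for r, kf, kb in self._compiled:
            rate = self._rate(r, kf, kb, conc)
            for name, s in r.lhs.items():
                out[self.index[name]] -= s * rate
            for name, s in r.rhs.items():
                out[self.index[name]] += s * rate
        for i, expr in self._terms:
            out[i] += expr(conc)
        return out

    def jacobian(self, conc: np.ndarray, eps: float = 1e-8) -> np.ndarray:
        """Finite-difference Jacobian of :meth:`rhs`; see
        :func:`numerical_jacobian`."""
        return numerical_jacobian(self.rhs, conc, eps)


def numerical_jacobian(
    rhs: Callable[[np.ndarray], np.ndarray], conc: np.ndarray, eps: float = 1e-8
) -> np.ndarray:
    """Forward-difference Jacobian J[i, j] = d rhs_i / d conc_j.

    ``conc`` has species on the leading axis (length n); the result has shape
    ``(n, n) + conc.shape[1:]``.  The per-species step is
    ``max(eps, 1e-6 * |c_j|)``.
    """
    conc = np.asarray(conc, dtype=float)
    n = conc.shape[0]
    f0 = rhs(conc)
    if not np.all(np.isfinite(f0)):
        raise FloatingPointError("reaction rhs is non-finite at the base state")
    J = np.zeros((n,) + f0.shape, dtype=float)
    for j in range(n):
        h = np.maximum(eps, 1e-6 * np.abs(conc[j]))
        pert = conc.copy()
        pert[j] = pert[j] + h
        J[:, j] = (rhs(pert) - f0) / h
    return J
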