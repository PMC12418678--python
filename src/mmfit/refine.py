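"""Constrained least-squares multipole refinement against structure factors.

The refinable vector is the packed parameter set of
:func:`mmfit.model.parameter_packing` (ties collapsed, fixed excluded).
Populations enter the structure factors linearly, so their Jacobian
columns are exactly the per-atom basis functions; kappa and kappa' get
central finite-difference columns.  Steps are damped Gauss-Newton with a
backtracking line search, so the accepted residual sequence is monotone.

The agreement statistic is the conventional crystallographic R factor

    R = sum | |F_obs| - k |F_calc| | / sum |F_obs|

with the scale k fixed (default 1, as appropriate for theoretical static
data).  Two residual modes are provided: ``complex`` fits Re/Im of
F_target - k F_model (theoretical phases are known), ``modulus`` fits
|F_target| - k |F_model| (the convention of experimental refinement
programs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (AlignmentError, DegenerateInputError,
                     RankDeficiencyError, ValidationError)
from .model import MoleculeModel, parameter_packing
from .scattering import (HklGeometryCache, StructureFactorSet,
                         atom_form_factors, slater_jl_transform,
                         _spherical_form_factor)

__all__ = ["RefinementConfig", "RefinementResult", "r_factor",
           "fit_multipole_model"]

KAPPA_BOUNDS = (0.5, 2.0)


@dataclass
class RefinementConfig:
    mode: str = "complex"               # "complex" | "modulus"
    scale_k: float = 1.0
    max_iterations: int = 100
    gradient_tolerance: float = 1e-9    # on ||J^T r||_inf, electrons^2 scale
    step_damping: float = 0.5           # backtracking factor in (0, 1]
    kappa_bounds: tuple[float, float] = KAPPA_BOUNDS
    fd_step: float = 1e-6               # finite-difference step for kappas
    electroneutrality: bool = False     # optional sum-P_val constraint

    def __post_init__(self):
        if self.scale_k <= 0:
            raise ValidationError("scale factor must be positive")
        if not (0 < self.step_damping <= 1):
            raise ValidationError("step_damping must be in (0, 1]")
        if self.mode not in ("complex", "modulus"):
            raise ValidationError(f"unknown residual mode {self.mode!r}")


@dataclass
class RefinementResult:
    model: MoleculeModel
    r_factor: float
    iterations: int
    converged: bool
    residual_norm: float
    history: list[tuple[float, float]] = field(default_factory=list)  # (|r|, R)


def r_factor(F_obs: StructureFactorSet, F_calc: StructureFactorSet,
             k: float = 1.0) -> float:
    """R = sum| |F_obs| - k |F_calc| | / sum |F_obs| (dimensionless)."""
    if not F_obs.hkl.same_lattice(F_calc.hkl):
        raise AlignmentError("F_obs and F_calc are on different hkl sets")
    ao = F_obs.amplitudes()
    denom = ao.sum()
    if denom == 0:
        raise DegenerateInputError("sum |F_obs| is zero")
    return float(np.abs(ao - k * F_calc.amplitudes()).sum() / denom)


class _Engine:
    """Caches per-atom basis structure factors for one target/model pair."""

    def __init__(self, target: StructureFactorSet, model: MoleculeModel,
                 config: RefinementConfig):
        self.target = target
        self.config = config
        self.include_core = not target.valence_only
        self.packing = parameter_packing(model)
        self.cache = HklGeometryCache(target.hkl, model)
        self.nrefl = len(target.hkl)

    # -- model structure factors and per-slot bases ---------------------------

    def _atom_F(self, model, i):
        atom = model.pseudo_atoms[i]
        entry = model.databank[atom.databank_element]
        return self.cache.phase(i) * atom_form_factors(
            self.cache, atom, entry, self.include_core)

    def model_F(self, model) -> np.ndarray:
        F = np.zeros(self.nrefl, dtype=complex)
        for i in range(len(model.pseudo_atoms)):
            F += self._atom_F(model, i)
        return F

    def _basis_column(self, model, ref) -> np.ndarray:
        """dF/d(parameter) for one model reference (complex array)."""
        i, key = ref
        atom = model.pseudo_atoms[i]
        entry = model.databank[atom.databank_element]
        qu = self.cache.q_unique
        phase = self.cache.phase(i)
        nv = entry.n_val
        if key == "P_val":
            if nv == 0:
                return np.zeros(self.nrefl, dtype=complex)
            f = self.cache.expand(
                _spherical_form_factor(entry.valence_terms, qu / atom.kappa)) / nv
            return phase * f
        if key == "kappa":
            if nv == 0:
                return np.zeros(self.nrefl, dtype=complex)
            h = self.config.fd_step
            fp = _spherical_form_factor(entry.valence_terms, qu / (atom.kappa + h))
            fm = _spherical_form_factor(entry.valence_terms, qu / (atom.kappa - h))
            return phase * ((atom.P_val / nv)
                            * self.cache.expand((fp - fm) / (2 * h)))
        if key == "kappa_prime":
            h = self.config.fd_step
            col = np.zeros(self.nrefl, dtype=complex)
            for (l, m), p in atom.P_lm.items():
                if p == 0.0:
                    continue
                n_l, zeta_l = entry.deformation[l]
                jp = slater_jl_transform(l, n_l, zeta_l, qu / (atom.kappa_prime + h))
                jm = slater_jl_transform(l, n_l, zeta_l, qu / (atom.kappa_prime - h))
                col += p * (4 * math.pi * 1j ** l) \
                    * self.cache.expand((jp - jm) / (2 * h)) \
                    * self.cache.dlm(i, l, m)
            return phase * col
        l, m = key
        n_l, zeta_l = entry.deformation[l]
        jl = self.cache.expand(
            slater_jl_transform(l, n_l, zeta_l, qu / atom.kappa_prime))
        return phase * (4 * math.pi * 1j ** l) * jl * self.cache.dlm(i, l, m)

    def jacobian_and_F(self, model) -> tuple[np.ndarray, np.ndarray]:
        """Complex Jacobian dF/dx (nrefl x nslots) and F_model."""
        J = np.zeros((self.nrefl, self.packing.nslots), dtype=complex)
        for slot, refs in enumerate(self.packing.slot_refs):
            for ref in refs:
                J[:, slot] += self._basis_column(model, ref)
        return J, self.model_F(model)

    # -- residuals -------------------------------------------------------------

    def residual(self, F_model) -> np.ndarray:
        k = self.config.scale_k
        if self.config.mode == "complex":
            d = self.target.F - k * F_model
            return np.concatenate([d.real, d.imag])
        return self.target.amplitudes() - k * np.abs(F_model)

    def real_jacobian(self, J_complex, F_model) -> np.ndarray:
        """Real residual Jacobian dr/dx (note r = F_t - k F_m => -k dF/dx)."""
        k = self.config.scale_k
        if self.config.mode == "complex":
            return -k * np.concatenate([J_complex.real, J_complex.imag])
        amp = np.abs(F_model)
        safe = np.where(amp > 0, amp, 1.0)
        # d|F|/dx = Re(conj(F) dF/dx)/|F|
        damp = (np.conj(F_model)[:, None] * J_complex).real / safe[:, None]
        return -k * damp


def fit_multipole_model(F_target: StructureFactorSet, start: MoleculeModel,
                        config: RefinementConfig | None = None) -> RefinementResult:
    """Damped Gauss-Newton fit of the packed multipole parameters.

    Constraints (ties, fixed parameters, hydrogen conventions) are enforced
    structurally through the packing, so tied parameters remain exactly
    equal after every iteration.  Non-convergence within ``max_iterations``
    is reported via ``converged=False``, not an exception; a singular
    normal matrix raises :class:`RankDeficiencyError` naming the null-space
    parameters.
    """
    config = config or RefinementConfig()
    engine = _Engine(F_target, start, config)
    packing = engine.packing
    kappa_slots = [k for k in range(packing.nslots) if packing.is_kappa_slot(k)]
    lo, hi = config.kappa_bounds

    model = start.copy()
    x = packing.pack(model)
    F_model = engine.model_F(model)
    r = engine.residual(F_model)
    rnorm = float(np.linalg.norm(r))
    history: list[tuple[float, float]] = []
    converged = False
    iterations = 0

    extra_row = None
    if config.electroneutrality:
        # sum over P_val slots (weighted by multiplicity) kept at start value
        w = np.zeros(packing.nslots)
        for slot, refs in enumerate(packing.slot_refs):
            w[slot] = sum(1 for ref in refs if ref[1] == "P_val")
        extra_row = (w, float(w @ x))

    for iterations in range(1, config.max_iterations + 1):
        Jc, F_model = engine.jacobian_and_F(model)
        r = engine.residual(F_model)
        rnorm = float(np.linalg.norm(r))
        J = engine.real_jacobian(Jc, F_model)
        g = J.T @ r
        gnorm = float(np.max(np.abs(g))) if g.size else 0.0
        history.append((rnorm, _quick_r(engine, F_model)))
        if gnorm <= config.gradient_tolerance:
            converged = True
            break

        JTJ = J.T @ J
        # slots with (structurally) zero columns -- e.g. kappa' while all of
        # an atom's multipoles are still zero -- are frozen this iteration
        diag = np.sqrt(np.maximum(np.diag(JTJ), 0.0))
        active = diag > 1e-14 * max(diag.max(), 1e-300)
        step = np.zeros(packing.nslots)
        A = JTJ[np.ix_(active, active)]
        rhs = -g[active]
        if extra_row is not None:
            w, _ = extra_row
            wa = w[active]
            na = A.shape[0]
            K = np.zeros((na + 1, na + 1))
            K[:na, :na] = A
            K[:na, na] = wa
            K[na, :na] = wa
            try:
                step[active] = np.linalg.solve(
                    K, np.concatenate([rhs, [0.0]]))[:na]
            except np.linalg.LinAlgError:
                _raise_rank_deficiency(JTJ, packing)
        else:
            try:
                step[active] = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                _raise_rank_deficiency(JTJ, packing)

        # backtracking line search; kappa-type slots stay inside their box
        accepted = False
        alpha = 1.0
        for _ in range(30):
            x_new = x + alpha * step
            for k in kappa_slots:
                x_new[k] = min(max(x_new[k], lo + 1e-9), hi - 1e-9)
            model_new = packing.unpack(model, x_new)
            F_new = engine.model_F(model_new)
            r_new = engine.residual(F_new)
            rnorm_new = float(np.linalg.norm(r_new))
            if rnorm_new <= rnorm:
                accepted = True
                break
            alpha *= config.step_damping
        if not accepted:
            break                       # no descent direction left
        moved = float(np.max(np.abs(x_new - x))) if x.size else 0.0
        x, model, F_model, rnorm = x_new, model_new, F_new, rnorm_new
        if moved == 0.0:
            break

    F_final = engine.model_F(model)
    final_sf = StructureFactorSet(F_target.hkl, F_final,
                                  valence_only=F_target.valence_only)
    R = r_factor(F_target, final_sf, config.scale_k)
    return RefinementResult(model=model, r_factor=R, iterations=iterations,
                            converged=converged,
                            residual_norm=float(
                                np.linalg.norm(engine.residual(F_final))),
                            history=history)


def _quick_r(engine, F_model) -> float:
    ao = engine.target.amplitudes()
    return float(np.abs(ao - engine.config.scale_k * np.abs(F_model)).sum()
                 / ao.sum())


def _raise_rank_deficiency(JTJ, packing):
    vals, vecs = np.linalg.eigh(JTJ)
    scale = max(vals.max(), 1e-300)
    null = []
    for idx in np.where(vals < 1e-12 * scale)[0]:
        involved = np.where(np.abs(vecs[:, idx]) > 1e-3)[0]
        null.extend(packing.slot_names[j] for j in involved)
    raise RankDeficiencyError(
        "singular normal matrix in multipole refinement",
        null_parameters=sorted(set(null)))
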