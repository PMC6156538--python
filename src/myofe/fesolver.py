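"""Material-point protocols and a minimal static total-Lagrangian FE solver.

Two drivers exercise the constitutive law:

* :func:`run_protocol` evaluates a prescribed deformation-gradient history
  at a single material point and reports stresses and effective strains —
  the verification path for the constitutive and injury models.
* :func:`solve_static` solves the static balance of momentum
  ``Div P + rho_0 g = 0`` on a linear-tetrahedral mesh with Newton
  iterations on the total-Lagrangian residual, using the analytic
  constitutive tangent.  Elements use single-point integration (the shape
  gradients of linear tets are constant).  Loads are ramped in equal
  increments; within each increment Newton iterates until the free-DoF
  residual norm drops below ``tol`` times the larger of the external-force
  norm and the increment's initial residual.

The element-level constitutive evaluation is vectorised over all elements
(batched re-statement of the same law as :mod:`myofe.material`); the FE
patch test pins it against the material-point implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, DataError
from .injury import effective_strain
from .material import DeformationState, MaterialParams, evaluate, von_mises
from .meshkit import TetMesh

__all__ = [
    "LoadCase",
    "SolveResult",
    "ProtocolStep",
    "run_protocol",
    "solve_static",
    "convergence_study",
]

log = logging.getLogger(__name__)

_EYE = np.eye(3)


@dataclass
class LoadCase:
    """Static load case for :func:`solve_static`.

    ``dirichlet`` maps node index -> prescribed displacement (mm), with
    ``nan`` components left free.  ``body_force`` maps part label -> an
    acceleration vector (mm/ms^2, e.g. gravity) applied through the part
    density.  ``nodal_loads`` maps node index -> force vector.  Loads and
    prescribed displacements are ramped together in ``ramp_steps`` equal
    increments.
    """

    dirichlet: dict = field(default_factory=dict)
    body_force: dict = field(default_factory=dict)
    nodal_loads: dict = field(default_factory=dict)
    ramp_steps: int = 10


@dataclass
class ProtocolStep:
    state: DeformationState
    S: np.ndarray
    T: np.ndarray
    von_mises: float
    eps_eff: float


@dataclass
class SolveResult:
    displacements: np.ndarray  # (n_nodes, 3)
    F: np.ndarray  # (n_elements, 3, 3)
    S: np.ndarray
    T: np.ndarray
    von_mises: np.ndarray
    eps_eff: np.ndarray
    residual_history: list  # per-increment lists of Newton residual norms


def run_protocol(F_history, a0, params: MaterialParams) -> list:
    """Evaluate a deformation-gradient history at one material point."""
    steps = []
    for F in F_history:
        state = DeformationState(F, a0)
        res = evaluate(state, params)
        steps.append(
            ProtocolStep(
                state,
                res.S,
                res.T,
                von_mises(res.T),
                effective_strain(state.green_strain),
            )
        )
    return steps


# ---------------------------------------------------------------------------
# Batched constitutive evaluation (vectorised over elements)
# ---------------------------------------------------------------------------


def _batch_kinematics(F):
    C = np.einsum("eki,ekj->eij", F, F)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ConvergenceError(
            "element inversion (det F <= 0); reduce the load increment",
            residual=None,
        )
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=1, axis2=2)
    I2 = 0.5 * (I1**2 - np.einsum("eij,eji->e", C, C))
    I3 = J**2
    return C, Cinv, J, I1, I2, I3


def _batch_iso_coeffs(p: MaterialParams, I1, I2, I3):
    B1 = 2 * p.c1 * I3 ** (-1 / 3) + 2 * p.c2 * I3 ** (-2 / 3) * I1
    B2 = -2 * p.c2 * I3 ** (-2 / 3)
    B3 = -(2 / 3) * p.c1 * I3 ** (-1 / 3) * I1 - (4 / 3) * p.c2 * I3 ** (-2 / 3) * I2
    return B1, B2, B3


def _batch_fibre_scalars(lam, p: MaterialParams):
    """(s, ds/dLambda) of the fibre stress scalar, vectorised."""
    s_pas = np.where(lam >= 1.0, p.c3 * (lam**p.c4 - 1.0) / lam**2, 0.0)
    ds_pas = np.where(
        lam >= 1.0,
        p.c3 * ((p.c4 - 2.0) * lam ** (p.c4 - 3.0) + 2.0 * lam**-3.0),
        0.0,
    )
    asc = lam <= p.lambda_opt
    dw = np.where(asc, p.dw_asc, p.dw_dsc)
    nu = np.where(asc, p.nu_asc, p.nu_dsc)
    x = (lam / p.lambda_opt - 1.0) / dw
    E = np.exp(-np.abs(x) ** nu)
    with np.errstate(divide="ignore", invalid="ignore"):
        dE = np.where(
            x != 0.0,
            -nu * np.abs(x) ** (nu - 1.0) * np.sign(x) / (dw * p.lambda_opt) * E,
            0.0,
        )
    s_act = p.s_max / lam**2 * E
    ds_act = p.s_max * (-2.0 * lam**-3.0 * E + lam**-2.0 * dE)
    s = s_pas + p.alpha * s_act
    ds = ds_pas + p.alpha * ds_act
    return s, ds


def _batch_stress_tangent(F, p: MaterialParams, a0=None):
    """Second PK stress and material tangent for a batch of F tensors."""
    C, Cinv, J, I1, I2, I3 = _batch_kinematics(F)
    B1, B2, B3 = _batch_iso_coeffs(p, I1, I2, I3)
    B3v = B3 + p.bulk_k * (I3 - np.sqrt(I3))

    S = (
        B1[:, None, None] * _EYE
        + B2[:, None, None] * C
        + B3v[:, None, None] * Cinv
    )

    dI1 = np.broadcast_to(_EYE, C.shape)
    dI2 = I1[:, None, None] * _EYE - C
    dI3 = I3[:, None, None] * Cinv
    dB1_dI1 = 2 * p.c2 * I3 ** (-2 / 3)
    dB1_dI3 = -(2 / 3) * p.c1 * I3 ** (-4 / 3) - (4 / 3) * p.c2 * I3 ** (-5 / 3) * I1
    dB2_dI3 = (4 / 3) * p.c2 * I3 ** (-5 / 3)
    dB3v_dI1 = -(2 / 3) * p.c1 * I3 ** (-1 / 3)
    dB3v_dI2 = -(4 / 3) * p.c2 * I3 ** (-2 / 3)
    dB3v_dI3 = (
        (2 / 9) * p.c1 * I3 ** (-4 / 3) * I1
        + (8 / 9) * p.c2 * I3 ** (-5 / 3) * I2
        + p.bulk_k * (1.0 - 0.5 * I3**-0.5)
    )
    dB1 = dB1_dI1[:, None, None] * dI1 + dB1_dI3[:, None, None] * dI3
    dB2 = dB2_dI3[:, None, None] * dI3
    dB3v = (
        dB3v_dI1[:, None, None] * dI1
        + dB3v_dI2[:, None, None] * dI2
        + dB3v_dI3[:, None, None] * dI3
    )
    isym = 0.5 * (
        np.einsum("ik,jl->ijkl", _EYE, _EYE) + np.einsum("il,jk->ijkl", _EYE, _EYE)
    )
    dCinv = -0.5 * (
        np.einsum("eik,ejl->eijkl", Cinv, Cinv)
        + np.einsum("eil,ejk->eijkl", Cinv, Cinv)
    )
    tangent = 2.0 * (
        np.einsum("ij,ekl->eijkl", _EYE, dB1)
        + np.einsum("eij,ekl->eijkl", C, dB2)
        + np.einsum("eij,ekl->eijkl", Cinv, dB3v)
        + B2[:, None, None, None, None] * isym
        + B3v[:, None, None, None, None] * dCinv
    )

    if p.gamma == 0:
        if a0 is None:
            raise DataError(
                "anisotropic material (gamma=0) needs per-element fibre directions"
            )
        M = np.einsum("ei,ej->eij", a0, a0)
        lam = np.sqrt(np.einsum("eij,eij->e", M, C))
        s, ds = _batch_fibre_scalars(lam, p)
        S = S + s[:, None, None] * M
        tangent = tangent + (ds / lam)[:, None, None, None, None] * np.einsum(
            "eij,ekl->eijkl", M, M
        )
    return S, tangent, J


# ---------------------------------------------------------------------------
# Static solver
# ---------------------------------------------------------------------------


class _Model:
    """Precomputed element data: shape gradients, volumes, material groups."""

    def __init__(self, mesh, fibre_field, materials):
        self.mesh = mesh
        x = mesh.nodes[mesh.elements]  # (m, 4, 3)
        D = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))  # columns X_a - X_0
        Dinv = np.linalg.inv(D)
        G = np.empty((mesh.n_elements, 4, 3))
        G[:, 1:, :] = Dinv  # rows = grad N_a, a = 1..3
        G[:, 0, :] = -Dinv.sum(axis=1)
        self.G = G
        self.V = mesh.element_volumes()

        self.groups = []  # (element indices, params, a0 per element or None)
        labels = mesh.part_labels.astype(str)
        for label in dict.fromkeys(labels):
            idx = np.where(labels == label)[0]
            try:
                params = materials[label]
            except (KeyError, TypeError):
                if isinstance(materials, MaterialParams):
                    params = materials
                else:
                    raise DataError(f"no material assigned to part {label!r}")
            a0 = None
            if params.gamma == 0:
                if fibre_field is None:
                    raise DataError(
                        f"part {label!r} is anisotropic but no fibre field given"
                    )
                a0 = fibre_field.directions[idx]
                if np.isnan(a0).any():
                    raise DataError(
                        f"part {label!r} has elements with missing fibre "
                        "directions; smooth the field first"
                    )
            self.groups.append((idx, params, a0))

    def deformation_gradients(self, u):
        ue = u[self.mesh.elements]  # (m, 4, 3)
        return _EYE + np.einsum("eai,eaJ->eiJ", ue, self.G)

    def stress_tangent(self, F):
        m = self.mesh.n_elements
        S = np.empty((m, 3, 3))
        A = np.empty((m, 3, 3, 3, 3))
        for idx, params, a0 in self.groups:
            Se, Cm, _ = _batch_stress_tangent(F[idx], params, a0)
            S[idx] = Se
            Fi = F[idx]
            # A_iJkL = d P_iJ / d F_kL with P = F S
            A[idx] = np.einsum("ik,eJL->eiJkL", _EYE, Se) + np.einsum(
                "eiM,eMJLP,ekP->eiJkL", Fi, Cm, Fi, optimize=True
            )
        return S, A

    def internal_forces(self, F, S):
        P = np.einsum("eiM,eMJ->eiJ", F, S)
        fe = np.einsum("e,eaJ,eiJ->eai", self.V, self.G, P)
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.elements, fe)
        return f

    def stiffness(self, F, A):
        mesh = self.mesh
        Ke = np.einsum(
            "e,eaJ,eiJkL,ebL->eaibk", self.V, self.G, A, self.G, optimize=True
        )
        dof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = sp.coo_matrix(
            (Ke.reshape(-1), (rows, cols)),
            shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes),
        )
        return K.tocsr()


def _external_forces(model: _Model, load: LoadCase):
    mesh = model.mesh
    f = np.zeros((mesh.n_nodes, 3))
    for node, force in load.nodal_loads.items():
        f[int(node)] += np.asarray(force, float)
    if load.body_force:
        labels = mesh.part_labels.astype(str)
        for label, accel in load.body_force.items():
            sel = labels == str(label)
            params = next(
                (p for idx, p, _ in model.groups if labels[idx[0]] == str(label)),
                None,
            )
            if params is None:
                raise DataError(f"body force on unknown part {label!r}")
            fe = (
                params.density
                * model.V[sel, None]
                / 4.0
                * np.asarray(accel, float)[None, :]
            )
            np.add.at(f, mesh.elements[sel].ravel(), np.repeat(fe, 4, axis=0))
    return f


def _dirichlet_arrays(load: LoadCase, n_nodes):
    fixed = np.zeros(3 * n_nodes, dtype=bool)
    values = np.zeros(3 * n_nodes)
    for node, disp in load.dirichlet.items():
        disp = np.asarray(disp, float)
        for i in range(3):
            if not np.isnan(disp[i]):
                fixed[3 * int(node) + i] = True
                values[3 * int(node) + i] = disp[i]
    if not np.any(fixed):
        raise DataError("load case constrains no degrees of freedom")
    return fixed, values


def solve_static(
    mesh: TetMesh,
    fibre_field,
    materials,
    load_case: LoadCase,
    tol: float = 1e-8,
    max_newton: int = 30,
) -> SolveResult:
    """Newton solution of the static total-Lagrangian problem.

    Parameters
    ----------
    fibre_field : ElementFibreField or None
        Needed only for anisotropic parts (gamma = 0).
    materials : MaterialParams or dict part-label -> MaterialParams
    """
    model = _Model(mesh, fibre_field, materials)
    fixed, bc_values = _dirichlet_arrays(load_case, mesh.n_nodes)
    free = ~fixed
    f_ext_full = _external_forces(model, load_case).ravel()

    u = np.zeros(3 * mesh.n_nodes)
    history = []
    nsteps = max(int(load_case.ramp_steps), 1)
    for step in range(1, nsteps + 1):
        lam = step / nsteps
        u[fixed] = lam * bc_values[fixed]
        f_ext = lam * f_ext_full
        ref_ext = np.linalg.norm(f_ext[free])
        inc_hist = []
        ref = None
        for it in range(max_newton):
            F = model.deformation_gradients(u.reshape(-1, 3))
            S, A = model.stress_tangent(F)
            r = f_ext - model.internal_forces(F, S).ravel()
            rnorm = np.linalg.norm(r[free])
            inc_hist.append(rnorm)
            if ref is None:
                ref = max(ref_ext, rnorm, 1e-30)
            if rnorm <= tol * ref:
                break
            K = model.stiffness(F, A)
            Kff = K[free][:, free]
            try:
                du = spla.spsolve(Kff.tocsc(), r[free])
            except RuntimeError as exc:
                raise ConvergenceError(
                    "singular tangent system; the load case likely leaves "
                    "rigid-body modes unconstrained",
                    residual=rnorm,
                    step=step,
                ) from exc
            if not np.all(np.isfinite(du)):
                raise ConvergenceError(
                    "singular tangent system; the load case likely leaves "
                    "rigid-body modes unconstrained",
                    residual=rnorm,
                    step=step,
                )
            u[free] += du
        else:
            raise ConvergenceError(
                f"Newton failed to converge in {max_newton} iterations "
                f"at load increment {step}/{nsteps}",
                residual=inc_hist[-1],
                step=step,
            )
        history.append(inc_hist)

    F = model.deformation_gradients(u.reshape(-1, 3))
    S, _ = model.stress_tangent(F)
    J = np.linalg.det(F)
    T = np.einsum("eiM,eMN,ejN->eij", F, S, F) / J[:, None, None]
    dev = T - np.trace(T, axis1=1, axis2=2)[:, None, None] / 3.0 * _EYE
    vm = np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))
    C = np.einsum("eki,ekj->eij", F, F)
    E = 0.5 * (C - _EYE)
    eps = np.sqrt((2.0 / 3.0) * np.einsum("eij,eij->e", E, E))
    return SolveResult(u.reshape(-1, 3), F, S, T, vm, eps, history)


def convergence_study(meshes, load_case_fn, materials, fibre_fields=None):
    """Volume-normalised von Mises stress per refinement level.

    Parameters
    ----------
    meshes : sequence of TetMesh, coarsest to finest
    load_case_fn : callable mesh -> LoadCase
    fibre_fields : optional sequence matching ``meshes``

    Returns
    -------
    sigma_bar : list of float
        One volume-weighted mean von Mises stress per mesh.
    """
    from .injury import normalised_stress

    out = []
    for i, mesh in enumerate(meshes):
        ff = None if fibre_fields is None else fibre_fields[i]
        res = solve_static(mesh, ff, materials, load_case_fn(mesh))
        out.append(normalised_stress(mesh, res.von_mises))
    return out
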