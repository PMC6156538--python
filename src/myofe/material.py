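"""Transversely isotropic hyperelastic skeletal-muscle constitutive law.

The second Piola-Kirchhoff stress is split as

    S = S_iso + (1 - gamma) * (S_pas + alpha * S_act)

where the isotropic matrix response is a compressible Mooney-Rivlin-type
law

    S_iso = B1 I + B2 C + B3 C^-1 + k (J - 1) J C^-1,
    B1 =  2 C1 I3^(-1/3) + 2 C2 I3^(-2/3) I1,
    B2 = -2 C2 I3^(-2/3),
    B3 = -(2/3) C1 I3^(-1/3) I1 - (4/3) C2 I3^(-2/3) I2,

with invariants I1, I2, I3 of C = F^T F, J = det F and bulk modulus k, and
the fibre response acts along the structural tensor M = a0 (x) a0 through
the fibre stretch Lambda = sqrt(I4), I4 = M : C:

    S_pas = C3 (Lambda^C4 - 1) / Lambda^2 * M       for Lambda >= 1, else 0
    S_act = S_max / Lambda^2
            * exp(-|(Lambda/Lambda_opt - 1) / dW|^nu) * M

with the ascending branch (dW_asc, nu_asc) for Lambda <= Lambda_opt and
the descending branch (dW_dsc, nu_dsc) above.  gamma in {0, 1} switches
the fibre contribution off for isotropic tissues (fat/skin), alpha in
[0, 1] is the constant activation level.

Derived quantities: Cauchy stress T = J^-1 F S F^T, the analytic material
tangent  C_mat = 2 dS/dC  and its spatial push-forward
B_ijkl = J^-1 F_iM F_jN F_kO F_lP C_MNOP.

Units are mm-MPa-ms-g throughout.  The reference configuration is
stress-free for every admissible parameter set (the B coefficients cancel
at C = I) and both fibre branches are continuous at their switch points
(Lambda = 1 and Lambda = Lambda_opt).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError

__all__ = [
    "MaterialParams",
    "DeformationState",
    "StressState",
    "MUSCLE",
    "SKIN_FAT",
    "LINER",
    "iso_stress",
    "aniso_stress",
    "second_pk",
    "cauchy",
    "material_tangent",
    "spatial_tangent",
    "von_mises",
    "evaluate",
    "active_envelope",
    "strain_energy",
    "read_material_file",
    "write_material_file",
]

#: Default bulk modulus (MPa).  The tissue is quasi-incompressible; the
#: published parameter set states no bulk value, so a penalty stiffness
#: roughly 17x the C2 shear-scale coefficient is used and exposed as a knob.
DEFAULT_BULK_K = 0.1


@dataclass(frozen=True)
class MaterialParams:
    """Parameter set of the constitutive law (MPa where dimensional)."""

    c1: float = 2.5e-6
    c2: float = 6e-3
    bulk_k: float = DEFAULT_BULK_K
    c3: float = 1e-3
    c4: float = 6.0
    s_max: float = 0.1
    dw_asc: float = 0.15
    dw_dsc: float = 0.16
    nu_asc: float = 2.0
    nu_dsc: float = 4.0
    lambda_opt: float = 1.3
    gamma: int = 0
    alpha: float = 0.0
    density: float = 1e-3  # g/mm^3

    def __post_init__(self):
        if self.s_max < 0:
            raise DataError("s_max must be >= 0")
        if self.lambda_opt <= 1:
            raise DataError("lambda_opt must exceed 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise DataError("alpha must lie in [0, 1]")
        if self.gamma not in (0, 1):
            raise DataError("gamma must be 0 or 1")

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


#: Skeletal muscle: anisotropic, passive by default (alpha = 0).
MUSCLE = MaterialParams(gamma=0, alpha=0.0)
#: Skin/fat: same matrix, fibre contribution switched off.
SKIN_FAT = MaterialParams(gamma=1, alpha=0.0)
#: Prosthetic liner: stiff isotropic rubber-like material.
LINER = MaterialParams(c1=0.33, c2=0.01, gamma=1, alpha=0.0, bulk_k=5.0)


class DeformationState:
    """Deformation gradient F plus its derived kinematic quantities.

    ``a0`` is the reference unit fibre direction; isotropic evaluations
    (gamma = 1) may omit it.
    """

    def __init__(self, F, a0=None):
        self.F = np.asarray(F, float)
        if self.F.shape != (3, 3):
            raise DataError(f"F must be 3x3, got {self.F.shape}")
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise DataError(f"det F must be positive, got {self.J}")
        self.C = self.F.T @ self.F
        self.b = self.F @ self.F.T
        self.Cinv = np.linalg.inv(self.C)
        self.I1 = float(np.trace(self.C))
        self.I2 = 0.5 * (self.I1**2 - float(np.trace(self.C @ self.C)))
        self.I3 = float(np.linalg.det(self.C))
        if a0 is not None:
            a0 = np.asarray(a0, float)
            n = np.linalg.norm(a0)
            if n == 0:
                raise DataError("a0 must be a nonzero vector")
            self.a0 = a0 / n
            self.M = np.outer(self.a0, self.a0)
            self.I4 = float(np.tensordot(self.M, self.C))
            self.fibre_stretch = float(np.sqrt(self.I4))
        else:
            self.a0 = None
            self.M = None
            self.I4 = None
            self.fibre_stretch = None

    @property
    def green_strain(self) -> np.ndarray:
        """Green-Lagrange strain E = (C - I) / 2."""
        return 0.5 * (self.C - np.eye(3))


@dataclass
class StressState:
    """Evaluation bundle: stresses and tangents at one deformation state."""

    S: np.ndarray
    T: np.ndarray
    C_mat: np.ndarray
    C_spatial: np.ndarray


def _iso_coefficients(params, I1, I2, I3):
    c1, c2 = params.c1, params.c2
    B1 = 2 * c1 * I3 ** (-1 / 3) + 2 * c2 * I3 ** (-2 / 3) * I1
    B2 = -2 * c2 * I3 ** (-2 / 3)
    B3 = -(2 / 3) * c1 * I3 ** (-1 / 3) * I1 - (4 / 3) * c2 * I3 ** (-2 / 3) * I2
    return B1, B2, B3


def iso_stress(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """Isotropic matrix part of the second Piola-Kirchhoff stress."""
    B1, B2, B3 = _iso_coefficients(params, state.I1, state.I2, state.I3)
    k = params.bulk_k
    vol = k * (state.J - 1.0) * state.I3**0.5
    return B1 * np.eye(3) + B2 * state.C + (B3 + vol) * state.Cinv


def _passive_scalar(lam, params):
    if lam < 1.0:
        return 0.0
    return params.c3 * (lam**params.c4 - 1.0) / lam**2


def _active_scalar(lam, params):
    if lam <= params.lambda_opt:
        dw, nu = params.dw_asc, params.nu_asc
    else:
        dw, nu = params.dw_dsc, params.nu_dsc
    x = (lam / params.lambda_opt - 1.0) / dw
    return params.s_max / lam**2 * np.exp(-(abs(x) ** nu))


def active_envelope(lam, params: MaterialParams = MUSCLE) -> float:
    """The exponential force-length envelope exp(-|...|^nu) alone.

    This is the active fibre stress without its 1/Lambda^2 prefactor and
    without S_max; it peaks at Lambda = Lambda_opt.
    """
    if params.lambda_opt is None:
        raise DataError("params lack active-fibre constants")
    return float(_active_scalar(lam, params) * lam**2 / params.s_max)


def aniso_stress(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """Fibre part (1 - gamma)(S_pas + alpha S_act) of the stress."""
    if params.gamma == 1:
        return np.zeros((3, 3))
    if state.M is None:
        raise DataError("anisotropic evaluation needs a fibre direction a0")
    lam = state.fibre_stretch
    s = _passive_scalar(lam, params) + params.alpha * _active_scalar(lam, params)
    return (1 - params.gamma) * s * state.M


def second_pk(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """Total second Piola-Kirchhoff stress S = S_iso + S_aniso."""
    return iso_stress(state, params) + aniso_stress(state, params)


def cauchy(state: DeformationState, S: np.ndarray) -> np.ndarray:
    """Push-forward to the true (Cauchy) stress T = J^-1 F S F^T."""
    return state.F @ S @ state.F.T / state.J


# ---------------------------------------------------------------------------
# Tangents
# ---------------------------------------------------------------------------

_I = np.eye(3)
# symmetric fourth-order identity: dC_ij/dC_kl for symmetric C
_ISYM = 0.5 * (
    np.einsum("ik,jl->ijkl", _I, _I) + np.einsum("il,jk->ijkl", _I, _I)
)


def _dCinv_dC(Cinv):
    return -0.5 * (
        np.einsum("ik,jl->ijkl", Cinv, Cinv) + np.einsum("il,jk->ijkl", Cinv, Cinv)
    )


def material_tangent(state: DeformationState, params: MaterialParams) -> np.ndarray:
    """Analytic material tangent C_mat = 2 dS/dC (full major/minor symmetry)."""
    c1, c2, k = params.c1, params.c2, params.bulk_k
    I1, I2, I3 = state.I1, state.I2, state.I3
    C, Cinv = state.C, state.Cinv

    B1, B2, B3 = _iso_coefficients(params, I1, I2, I3)
    # volumetric scalar merged into the C^-1 coefficient
    B3v = B3 + k * (I3 - I3**0.5)

    # invariant derivatives wrt C
    dI1 = _I
    dI2 = I1 * _I - C
    dI3 = I3 * Cinv

    dB1_dI1 = 2 * c2 * I3 ** (-2 / 3)
    dB1_dI3 = -(2 / 3) * c1 * I3 ** (-4 / 3) - (4 / 3) * c2 * I3 ** (-5 / 3) * I1
    dB2_dI3 = (4 / 3) * c2 * I3 ** (-5 / 3)
    dB3v_dI1 = -(2 / 3) * c1 * I3 ** (-1 / 3)
    dB3v_dI2 = -(4 / 3) * c2 * I3 ** (-2 / 3)
    dB3v_dI3 = (
        (2 / 9) * c1 * I3 ** (-4 / 3) * I1
        + (8 / 9) * c2 * I3 ** (-5 / 3) * I2
        + k * (1.0 - 0.5 * I3**-0.5)
    )

    dB1 = dB1_dI1 * dI1 + dB1_dI3 * dI3
    dB2 = dB2_dI3 * dI3
    dB3v = dB3v_dI1 * dI1 + dB3v_dI2 * dI2 + dB3v_dI3 * dI3

    tangent = 2.0 * (
        np.einsum("ij,kl->ijkl", _I, dB1)
        + np.einsum("ij,kl->ijkl", C, dB2)
        + np.einsum("ij,kl->ijkl", Cinv, dB3v)
        + B2 * _ISYM
        + B3v * _dCinv_dC(Cinv)
    )

    if params.gamma == 0 and state.M is not None:
        lam = state.fibre_stretch
        ds = _passive_scalar_derivative(lam, params)
        ds += params.alpha * _active_scalar_derivative(lam, params)
        # S_fib = s(Lambda) M, dLambda/dC = M / (2 Lambda)
        tangent += (ds / lam) * np.einsum("ij,kl->ijkl", state.M, state.M)
    return tangent


def _passive_scalar_derivative(lam, params):
    if lam < 1.0:
        return 0.0
    c3, c4 = params.c3, params.c4
    return c3 * ((c4 - 2.0) * lam ** (c4 - 3.0) + 2.0 * lam**-3.0)


def _active_scalar_derivative(lam, params):
    if lam <= params.lambda_opt:
        dw, nu = params.dw_asc, params.nu_asc
    else:
        dw, nu = params.dw_dsc, params.nu_dsc
    x = (lam / params.lambda_opt - 1.0) / dw
    E = np.exp(-(abs(x) ** nu))
    dE = 0.0
    if x != 0.0:
        dE = -nu * abs(x) ** (nu - 1.0) * np.sign(x) / (dw * params.lambda_opt) * E
    return params.s_max * (-2.0 * lam**-3.0 * E + lam**-2.0 * dE)


def spatial_tangent(state: DeformationState, C_mat: np.ndarray) -> np.ndarray:
    """Push-forward B_ijkl = J^-1 F_iM F_jN F_kO F_lP C_MNOP."""
    F = state.F
    return (
        np.einsum("iM,jN,kO,lP,MNOP->ijkl", F, F, F, F, C_mat, optimize=True)
        / state.J
    )


def von_mises(T: np.ndarray) -> float:
    """Von Mises stress of a symmetric Cauchy stress tensor."""
    T = np.asarray(T, float)
    dev = T - np.trace(T) / 3.0 * np.eye(3)
    return float(np.sqrt(1.5 * np.tensordot(dev, dev)))


def evaluate(state: DeformationState, params: MaterialParams) -> StressState:
    """Full evaluation: S, Cauchy stress and both tangents at one state."""
    S = second_pk(state, params)
    T = cauchy(state, S)
    C_mat = material_tangent(state, params)
    return StressState(S, T, C_mat, spatial_tangent(state, C_mat))


def strain_energy(state: DeformationState, params: MaterialParams) -> float:
    """Strain energy of the isotropic matrix (per reference volume, MPa).

    W = C1 I3^(-1/3) I1 + C2 I3^(-2/3) I2 + k/2 (J-1)^2 - 3(C1 + C2),
    shifted so W(I) = 0.  ``S_iso = 2 dW/dC`` — useful as a
    finite-difference oracle for the stress.  The fibre terms are not
    included here.
    """
    c1, c2, k = params.c1, params.c2, params.bulk_k
    I1, I2, I3, J = state.I1, state.I2, state.I3, state.J
    return (
        c1 * I3 ** (-1 / 3) * I1
        + c2 * I3 ** (-2 / 3) * I2
        + 0.5 * k * (J - 1.0) ** 2
        - 3.0 * (c1 + c2)
    )


# ---------------------------------------------------------------------------
# Parameter file I/O: flat "block.key = value" text
# ---------------------------------------------------------------------------

_FIELDS = [f for f in MaterialParams.__dataclass_fields__]


def write_material_file(materials: dict, path) -> None:
    """Write named parameter blocks as flat ``name.key = value`` lines."""
    with open(path, "w") as fh:
        fh.write("# material parameter blocks (mm-MPa-ms-g units)\n")
        for name, params in materials.items():
            for key in _FIELDS:
                fh.write(f"{name}.{key} = {getattr(params, key):.12g}\n")


def read_material_file(path) -> dict:
    blocks: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = (t.strip() for t in line.split("=", 1))
                name, field_name = key.rsplit(".", 1)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed line {line!r}") from exc
            if field_name not in _FIELDS:
                raise DataError(f"{path}:{lineno}: unknown parameter {field_name!r}")
            blocks.setdefault(name, {})[field_name] = float(value)
    out = {}
    for name, kv in blocks.items():
        if "gamma" in kv:
            kv["gamma"] = int(kv["gamma"])
        out[name] = MaterialParams(**kv)
    return out
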