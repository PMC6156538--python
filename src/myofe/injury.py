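"""Strain-time deep-tissue-injury model and volume-aggregated metrics.

Sustained compressive loading kills muscle cells once the effective Green
strain exceeds a time-decaying critical threshold.  The threshold follows
a Boltzmann-type sigmoid

    eps_crit(t) = K / (1 + exp(beta (t - t0))) + C

so short loads tolerate strains up to K + C = 0.6 while long loads are
damaging beyond the asymptote C = 0.332.  The effective strain is the full
tensor contraction

    eps_eff = sqrt(2/3 * eps : eps)

of the symmetric Green(-Lagrange) strain.  An element is flagged injured
at the first instant its effective strain exceeds the threshold and never
reverts; injury extent is reported as the injured volume fraction of the
tracked (muscle) parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .meshkit import TetMesh

__all__ = [
    "InjuryState",
    "INJURY_K",
    "INJURY_T0_MS",
    "INJURY_BETA_PER_MS",
    "INJURY_C",
    "DEFAULT_WINDOW_MS",
    "effective_strain",
    "critical_strain",
    "classify",
    "damage_volume_fraction",
    "normalised_stress",
]

# Empirical constants of the critical-strain sigmoid (strain-time cell-death
# data; t in ms from load onset).
INJURY_K = 0.268
INJURY_T0_MS = 9.78e6
INJURY_BETA_PER_MS = 5.83e-7
INJURY_C = 0.332

#: Default analysis window: 2 h of loading.
DEFAULT_WINDOW_MS = 7.2e6


@dataclass
class InjuryState:
    """Injury flags over time plus the damage-volume-fraction series.

    ``injured`` has shape ``(n_times, n_elements)`` and is monotone along
    the time axis (flags never revert); ``damage_fraction`` is the injured
    percent of the tracked volume at each instant.
    """

    times: np.ndarray
    injured: np.ndarray
    damage_fraction: np.ndarray | None = None

    @property
    def final_injured(self) -> np.ndarray:
        return self.injured[-1]


def effective_strain(E) -> float:
    """``sqrt((2/3) eps : eps)`` of a symmetric Green strain tensor."""
    E = np.asarray(E, float)
    return float(np.sqrt((2.0 / 3.0) * np.tensordot(E, E)))


def critical_strain(
    t,
    K: float = INJURY_K,
    t0: float = INJURY_T0_MS,
    beta: float = INJURY_BETA_PER_MS,
    C: float = INJURY_C,
):
    """Critical strain threshold at loading time ``t`` (ms).

    Strictly decreasing in t, from K + C (short loads) to C (sustained
    loads); the midpoint C + K/2 sits at t = t0.
    """
    t = np.asarray(t, float)
    arg = np.clip(beta * (t - t0), -700.0, 700.0)  # avoid exp overflow
    out = K / (1.0 + np.exp(arg)) + C
    return float(out) if out.ndim == 0 else out


def classify(times, strain_history) -> InjuryState:
    """Flag elements injured from their effective-strain histories.

    Parameters
    ----------
    times : array, shape (n_times,)
        Evaluation instants in ms, strictly increasing, from load onset.
    strain_history : array, shape (n_times, n_elements)
        Per-element effective strain at each instant.

    An element turns injured at the first instant with
    ``eps_eff(t) > eps_crit(t)``; the flag is irreversible.
    """
    times = np.asarray(times, float)
    hist = np.atleast_2d(np.asarray(strain_history, float))
    if hist.shape[0] != len(times):
        raise DataError(
            f"strain history has {hist.shape[0]} rows for {len(times)} times"
        )
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise DataError("times must be strictly increasing")
    crit = critical_strain(times)
    exceed = hist > crit[:, None]
    injured = np.logical_or.accumulate(exceed, axis=0)
    return InjuryState(times, injured)


def damage_volume_fraction(
    mesh: TetMesh, injury: InjuryState, tracked_parts=None
) -> np.ndarray:
    """Injured volume percent of the tracked parts over time.

    By default every part whose label is not one of the structural
    non-muscle labels (``bone``, ``femur``, ``liner``, ``socket``, ``fat``,
    ``skin``) is tracked, i.e. injury is reported for muscle tissue.
    """
    if tracked_parts is None:
        excluded = {"bone", "femur", "liner", "socket", "fat", "skin"}
        tracked_parts = [
            p
            for p in np.unique(mesh.part_labels.astype(str))
            if p.lower() not in excluded
        ]
    sel = mesh.part_mask(tracked_parts)
    if not np.any(sel):
        raise DataError(f"no elements belong to tracked parts {tracked_parts}")
    vols = mesh.element_volumes()
    vtot = vols[sel].sum()
    injured = np.atleast_2d(injury.injured)
    if injured.shape[1] != mesh.n_elements:
        raise DataError(
            f"injury flags cover {injured.shape[1]} elements, "
            f"mesh has {mesh.n_elements}"
        )
    frac = 100.0 * (injured[:, sel] * vols[sel]).sum(axis=1) / vtot
    injury.damage_fraction = frac
    return frac


def normalised_stress(mesh: TetMesh, von_mises_per_element, subset=None) -> float:
    """Volume-normalised mean von Mises stress sigma_bar = (1/V) sum sigma_e v_e."""
    sigma = np.asarray(von_mises_per_element, float)
    if len(sigma) != mesh.n_elements:
        raise DataError(
            f"{len(sigma)} stresses for {mesh.n_elements} elements"
        )
    vols = mesh.element_volumes()
    if subset is not None:
        subset = np.asarray(subset)
        sigma, vols = sigma[subset], vols[subset]
    return float(np.sum(sigma * vols) / np.sum(vols))
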