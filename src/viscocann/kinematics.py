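"""Uniaxial incompressible kinematics and quasi-elastic stress evaluation.

A cylindrical specimen loaded along its axis with stretch ``lambda`` and
free lateral surfaces deforms (for an incompressible, isotropic material)
with the diagonal deformation gradient ``F = diag(lam, lam**-1/2,
lam**-1/2)``, so that ``det F = 1`` exactly.  All constitutive information
enters through the first and second principal invariants of the right
Cauchy-Green tensor ``C = F.T @ F``::

    I1 = tr C            = lam**2 + 2/lam
    I2 = ((tr C)**2 - tr(C @ C)) / 2 = 2*lam + 1/lam**2

Strain-energy functions ``Psi(I1, I2)`` expose exact partial derivatives,
and the axial nominal (first Piola-Kirchhoff) stress follows from the
chain rule with the hydrostatic pressure eliminated by the traction-free
lateral boundary::

    P = 2 * (lam - lam**-2) * (dPsi/dI1 + dPsi/dI2 / lam)

which vanishes identically at ``lam = 1`` through the kinematic factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeformationState",
    "SpecimenGeometry",
    "deformation_gradient",
    "invariants",
    "deformation_state",
    "uniaxial_nominal_stress",
    "NeoHookean",
    "MooneyRivlin",
    "Ogden",
]


def _validate_stretch(lam: np.ndarray, sample: str | None) -> None:
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0.0):
        bad = int(np.argmax(~(np.isfinite(lam) & (lam > 0.0))))
        who = f" in sample {sample!r}" if sample else ""
        raise ValueError(
            f"non-positive stretch {np.ravel(lam)[bad]!r} at time index {bad}{who}; "
            "stretches must be finite and > 0"
        )


@dataclass(frozen=True)
class DeformationState:
    """Uniaxial incompressible deformation at one or more stretches.

    ``stretch`` may be a scalar or 1-d array; ``I1`` and ``I2`` have the
    same shape.  ``I1 = I2 = 3`` holds iff ``stretch == 1``.
    """

    stretch: np.ndarray
    I1: np.ndarray
    I2: np.ndarray

    @property
    def shifted(self) -> np.ndarray:
        """Invariants shifted by their undeformed value, ``(I1-3, I2-3)``.

        The undeformed configuration maps to the zero vector, which is the
        form the energy network consumes.
        """
        return np.stack([self.I1 - 3.0, self.I2 - 3.0], axis=-1)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical test-specimen geometry (heights in mm, area in mm^2)."""

    height_mm: float
    area_mm2: float = np.pi * 4.0**2  # 8 mm biopsy punch

    def stretch(self, displacement_mm: np.ndarray) -> np.ndarray:
        """lam = (H + dz) / H; compression dz < 0, tension dz > 0."""
        return (self.height_mm + np.asarray(displacement_mm, float)) / self.height_mm

    def nominal_stress_kpa(self, force_mn: np.ndarray) -> np.ndarray:
        """P = f_z / A; mN / mm^2 = kPa."""
        return np.asarray(force_mn, float) / self.area_mm2


def deformation_gradient(lam: float) -> np.ndarray:
    """Full 3x3 deformation gradient diag(lam, lam**-1/2, lam**-1/2)."""
    lam = float(lam)
    _validate_stretch(np.asarray([lam]), None)
    return np.diag([lam, lam**-0.5, lam**-0.5])


def invariants(lam, *, sample: str | None = None):
    """First and second principal invariants of C for uniaxial stretch.

    Parameters
    ----------
    lam : array_like
        Axial stretch(es), > 0.
    sample : str, optional
        Specimen label used in the error message when a non-positive
        stretch is encountered.
    """
    lam = np.asarray(lam, dtype=float)
    _validate_stretch(lam, sample)
    I1 = lam**2 + 2.0 / lam
    I2 = 2.0 * lam + lam**-2
    return I1, I2


def deformation_state(lam, *, sample: str | None = None) -> DeformationState:
    lam = np.asarray(lam, dtype=float)
    I1, I2 = invariants(lam, sample=sample)
    return DeformationState(stretch=lam, I1=I1, I2=I2)


def uniaxial_nominal_stress(energy, lam, *, sample: str | None = None):
    """Axial nominal stress of an incompressible isotropic energy.

    ``energy`` must provide exact invariant derivatives through a
    ``derivatives(state) -> (dPsi_dI1, dPsi_dI2)`` method (analytic or via
    algorithmic differentiation); a plain callable without that capability
    is a configuration error, because finite differencing would break the
    stress-by-differentiation contract.
    """
    if not hasattr(energy, "derivatives"):
        raise TypeError(
            f"energy object {energy!r} has no 'derivatives' method; uniaxial stress "
            "requires exact dPsi/dI1 and dPsi/dI2"
        )
    state = deformation_state(lam, sample=sample)
    d1, d2 = energy.derivatives(state)
    lam = state.stretch
    return 2.0 * (lam - lam**-2) * (d1 + d2 / lam)


# --------------------------------------------------------------------------
# Reference strain-energy functions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeoHookean:
    """Psi = mu/2 (I1 - 3), shear modulus mu in kPa."""

    mu: float = 1.0

    def energy(self, state: DeformationState):
        return 0.5 * self.mu * (state.I1 - 3.0)

    def derivatives(self, state: DeformationState):
        shape = np.shape(state.I1)
        return 0.5 * self.mu * np.ones(shape), np.zeros(shape)


@dataclass(frozen=True)
class MooneyRivlin:
    """Psi = c1 (I1 - 3) + c2 (I2 - 3), moduli in kPa."""

    c1: float = 0.5
    c2: float = 0.25

    def energy(self, state: DeformationState):
        return self.c1 * (state.I1 - 3.0) + self.c2 * (state.I2 - 3.0)

    def derivatives(self, state: DeformationState):
        shape = np.shape(state.I1)
        return self.c1 * np.ones(shape), self.c2 * np.ones(shape)


@dataclass(frozen=True)
class Ogden:
    """One-term Ogden energy, Psi = 2 mu / alpha**2 * (sum_a lam_a**alpha - 3).

    Negative exponents (``alpha`` around -20) reproduce the pronounced
    compression-tension asymmetry of brain tissue; ``alpha = 2`` recovers
    the neo-Hookean model.

    On the uniaxial incompressible branch the principal stretches are
    ``(lam, lam**-1/2, lam**-1/2)``, and the invariant derivatives follow
    from the 2x2 linear system the chain rule implies for a repeated
    transverse stretch::

        w'(lam) = 2 lam dPsi/dI1 + 4 dPsi/dI2
        w'(m)   = 2 m  dPsi/dI1 + 2 m (lam**2 + 1/lam) dPsi/dI2,   m = lam**-1/2

    with ``w(x) = 2 mu / alpha**2 * (x**alpha - 1)``.  The system is
    singular at ``lam = 1``, where the analytic limit
    ``dPsi/dI1 = mu (alpha - 1) / alpha``, ``dPsi/dI2 = mu (2 - alpha) / (2 alpha)``
    is substituted.
    """

    mu: float = 1.0
    alpha: float = -20.0

    def energy(self, state: DeformationState):
        lam = state.stretch
        a = self.alpha
        return 2.0 * self.mu / a**2 * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)

    def derivatives(self, state: DeformationState):
        lam = np.atleast_1d(np.asarray(state.stretch, float))
        a = self.alpha
        mu = self.mu

        def wp(x):
            return 2.0 * mu / a * x ** (a - 1.0)

        m = lam**-0.5
        near_one = np.abs(lam - 1.0) < 1e-7
        safe = np.where(near_one, 2.0, lam)  # placeholder away from singularity
        ms = safe**-0.5
        d2 = (wp(ms) - (ms / safe) * wp(safe)) / (2.0 * ms * (safe**2 - 1.0 / safe))
        d1 = (wp(safe) - 4.0 * d2) / (2.0 * safe)
        d1 = np.where(near_one, mu * (a - 1.0) / a, d1)
        d2 = np.where(near_one, mu * (2.0 - a) / (2.0 * a), d2)
        if np.isscalar(state.stretch) or np.ndim(state.stretch) == 0:
            return float(d1[0]), float(d2[0])
        return d1, d2

    def uniaxial_stress(self, lam):
        """Closed-form nominal stress (2 mu / alpha)(lam**(a-1) - lam**(-a/2-1))."""
        lam = np.asarray(lam, float)
        a = self.alpha
        return 2.0 * self.mu / a * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
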