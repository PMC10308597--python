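"""Lumped-element circuit models of a Coulter-type microaperture sensor.

The sensing zone of a square microaperture filled with conductive buffer is
modelled as a fluid resistance ``R_f`` shunted by a parasitic electrode
capacitance ``C_p``, with a small series lead inductance ``L_s``::

    Z_base(w) = j*w*L_s + R_f / (1 + j*w*R_f*C_p)

A transiting bead perturbs the slab of fluid it occupies (a fraction
``eta_slab`` of ``R_f``).  A nonconductive polystyrene bead adds the
displaced-volume resistance ``delta_R`` (Coulter principle) together with a
small effective bead capacitance ``C_b`` in parallel.  A silver-metallized
bead additionally carries a shell branch -- a resistor ``R_sh`` in series
with a metal/electrolyte interface capacitance ``C_sh`` -- in parallel with
the nonconductive bead element.  At frequencies where the interface
capacitance conducts, the shell short-circuits the displaced slab and the
net impedance change turns *negative*, which is the electrical fingerprint
of metallization.  A conformal, purely conductive layer (``C_sh -> inf``)
instead produces a negative change at every frequency; the distinction
between the two is what makes the frequency-specific dip diagnostic.

Impedances use the ``exp(+j*w*t)`` convention, so capacitive phase is
negative.  All quantities are SI (ohm, farad, henry, metre, hertz) except
where a function states otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError

__all__ = [
    "ApertureModel",
    "BeadModel",
    "BindingParams",
    "ShellLink",
    "baseline_spectrum",
    "bead_element",
    "coulter_delta_r",
    "default_aperture",
    "default_bead_capacitance",
    "dose_to_metallization",
    "metallization_to_shell",
    "peak_spectrum",
    "total_impedance",
]

#: Effective bead capacitance per displaced volume (F/m^3).  Calibrated so an
#: 8.2 um bead contributes 1 fF, small enough that the impedance-magnitude
#: change of a nonconductive bead stays positive across the whole 45 kHz -
#: 35 MHz band while still pulling the phase capacitive.
BEAD_CAPACITANCE_PER_VOLUME = 1.8136e0


@dataclass(frozen=True)
class ApertureModel:
    """Electrical description of the sensing zone.

    Parameters
    ----------
    side_length
        Side of the square aperture at its narrowest point (m).
    sensing_length
        Axial extent of the sensing zone (m); sets the fluid resistance.
    fluid_conductivity
        Buffer conductivity (S/m).  1.6 S/m approximates 1x PBS.
    R_f
        Sensing-zone fluid resistance (ohm).  If omitted it is derived as
        ``rho * sensing_length / side_length**2``.
    eta_slab
        Fraction of ``R_f`` attributable to the bead-occupied slab.
    C_p
        Parasitic/electrode capacitance (F).
    L_s
        Series parasitic inductance (H).
    """

    side_length: float = 30e-6
    sensing_length: float = 30e-6
    fluid_conductivity: float = 1.6
    R_f: float | None = None
    eta_slab: float = 0.3
    C_p: float = 2.5465e-12
    L_s: float = 1e-7

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ConfigError("aperture side_length must be positive")
        if self.sensing_length <= 0:
            raise ConfigError("sensing_length must be positive")
        if self.fluid_conductivity <= 0:
            raise ConfigError("fluid_conductivity must be positive")
        if not 0 < self.eta_slab < 1:
            raise ConfigError("eta_slab must lie strictly between 0 and 1")
        if self.C_p < 0 or self.L_s < 0:
            raise ConfigError("C_p and L_s must be non-negative")
        if self.R_f is None:
            rho = 1.0 / self.fluid_conductivity
            object.__setattr__(
                self, "R_f", rho * self.sensing_length / self.side_length**2
            )
        if self.R_f <= 0:
            raise ConfigError("R_f must be positive")

    @property
    def resistivity(self) -> float:
        """Fluid resistivity (ohm m)."""
        return 1.0 / self.fluid_conductivity

    @property
    def d_eff(self) -> float:
        """Equal-area circular diameter of the square aperture (m)."""
        return 2.0 * self.side_length / math.sqrt(math.pi)

    @property
    def r_slab(self) -> float:
        """Resistance of the bead-occupied slab, ``eta_slab * R_f`` (ohm)."""
        return self.eta_slab * self.R_f


def default_aperture() -> ApertureModel:
    """The default 30 um square aperture in 1x PBS."""
    return ApertureModel()


@dataclass(frozen=True)
class ShellLink:
    """Calibration of the metallization-density -> shell-element link.

    ``R_sh = r0 / m`` and ``C_sh = c0 * m`` for metallization density ``m``,
    so the shell vanishes (open circuit) as ``m -> 0``.
    """

    r0: float = 625.0
    c0: float = 50e-12

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.c0 <= 0:
            raise ConfigError("shell link parameters must be positive")


def default_shell_link(aperture: ApertureModel) -> ShellLink:
    """Shell link with ``r0 = 0.1 * R_slab`` and the default 50 pF interface."""
    return ShellLink(r0=0.1 * aperture.r_slab, c0=50e-12)


def metallization_to_shell(
    m_density: float, link: ShellLink | None = None
) -> tuple[float, float]:
    """Map a metallization density in [0, 1] to shell parameters (R_sh, C_sh).

    ``m = 0`` returns ``(inf, 0)`` -- an electrically absent shell.  R_sh is
    strictly decreasing and C_sh strictly increasing in ``m``.
    """
    if not 0 <= m_density <= 1:
        raise ConfigError(f"m_density must lie in [0, 1], got {m_density}")
    link = link or ShellLink()
    if m_density == 0:
        return math.inf, 0.0
    return link.r0 / m_density, link.c0 * m_density


def default_bead_capacitance(diameter: float) -> float:
    """Volume-scaled effective bead capacitance (F)."""
    return BEAD_CAPACITANCE_PER_VOLUME * diameter**3


@dataclass(frozen=True)
class BeadModel:
    """One bead's physical and circuit parameters."""

    diameter: float
    kind: str  # "nonmetallized" | "metallized"
    delta_R: float
    C_b: float
    R_sh: float = math.inf
    C_sh: float = 0.0
    m_density: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigError("bead diameter must be positive")
        if self.kind not in ("nonmetallized", "metallized"):
            raise ConfigError(f"unknown bead kind {self.kind!r}")
        if self.delta_R <= 0:
            raise ConfigError("delta_R must be positive")
        if self.C_b <= 0:
            raise ConfigError("C_b must be positive")
        if self.R_sh <= 0:
            raise ConfigError("R_sh must be positive (inf for nonmetallized)")
        if self.C_sh < 0:
            raise ConfigError("C_sh must be non-negative")
        if not 0 <= self.m_density <= 1:
            raise ConfigError("m_density must lie in [0, 1]")
        bare = self.m_density == 0
        if bare != (self.kind == "nonmetallized") or bare != (
            math.isinf(self.R_sh) and self.C_sh == 0
        ):
            raise ConfigError(
                "kind, m_density and shell parameters are inconsistent: "
                "nonmetallized <=> m_density = 0 <=> (R_sh = inf, C_sh = 0)"
            )

    @classmethod
    def nonmetallized(
        cls, diameter: float, aperture: ApertureModel
    ) -> "BeadModel":
        return cls(
            diameter=diameter,
            kind="nonmetallized",
            delta_R=coulter_delta_r(diameter, aperture),
            C_b=default_bead_capacitance(diameter),
        )

    @classmethod
    def metallized(
        cls,
        diameter: float,
        m_density: float,
        aperture: ApertureModel,
        link: ShellLink | None = None,
    ) -> "BeadModel":
        if m_density == 0:
            return cls.nonmetallized(diameter, aperture)
        link = link or default_shell_link(aperture)
        r_sh, c_sh = metallization_to_shell(m_density, link)
        return cls(
            diameter=diameter,
            kind="metallized",
            delta_R=coulter_delta_r(diameter, aperture),
            C_b=default_bead_capacitance(diameter),
            R_sh=r_sh,
            C_sh=c_sh,
            m_density=m_density,
        )

    def with_conformal_shell(self) -> "BeadModel":
        """Purely conductive shell variant (``C_sh -> inf``).

        Models the metallization as a conformal conductive layer instead of a
        nanostructured metal/electrolyte mesh; the shell branch degenerates to
        the bare resistor ``R_sh`` at every frequency.
        """
        if self.kind != "metallized":
            raise ConfigError("conformal shell only applies to metallized beads")
        return replace(self, C_sh=math.inf)


def coulter_delta_r(diameter: float, aperture: ApertureModel) -> float:
    """Resistive-pulse amplitude of a nonconductive sphere (ohm).

    DeBlois-Bean small-particle form with the square aperture replaced by a
    circle of equal cross-sectional area (diameter ``D_eff``)::

        dR = 4 rho d^3 / (pi D_eff^4) * [1 - 0.8 (d/D_eff)^3]^-1

    ``dR`` is strictly increasing in ``d`` and tends to the pure d^3 law for
    ``d << D_eff``.
    """
    if diameter < 0:
        raise ConfigError("diameter must be non-negative")
    d_eff = aperture.d_eff
    if diameter >= d_eff:
        raise ConfigError(
            f"bead diameter {diameter} must be below the effective aperture "
            f"diameter {d_eff:.3g}"
        )
    rho = aperture.resistivity
    ratio3 = (diameter / d_eff) ** 3
    return 4.0 * rho * diameter**3 / (math.pi * d_eff**4) / (1.0 - 0.8 * ratio3)


def _parallel(*impedances: np.ndarray) -> np.ndarray:
    admittance = sum(1.0 / z for z in impedances)
    return 1.0 / admittance


def baseline_spectrum(aperture: ApertureModel, freqs) -> np.ndarray:
    """Complex baseline impedance of the empty aperture at ``freqs`` (Hz).

    Flat and resistive (~``R_f``) below the RC corner ``1/(2 pi R_f C_p)``,
    capacitive above it, with the inductive term taking over at the very top
    of the band.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ConfigError("frequencies must be positive")
    w = 2.0 * np.pi * f
    return 1j * w * aperture.L_s + aperture.R_f / (
        1.0 + 1j * w * aperture.R_f * aperture.C_p
    )


def bead_element(bead: BeadModel, aperture: ApertureModel, f) -> np.ndarray:
    """Perturbation ``dB(w)`` of the sensing-zone series impedance (ohm).

    The displaced slab ``R_slab + delta_R`` in parallel with the bead
    capacitance and, for metallized beads, the R_sh-C_sh shell branch, minus
    the unperturbed slab::

        dB(w) = (R_slab + dR) || 1/(jwC_b) [|| (R_sh + 1/(jwC_sh))] - R_slab

    Nonmetallized beads give ``Re dB > 0`` everywhere; a metallized bead with
    ``R_sh < R_slab`` turns negative once its interface capacitance conducts.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ConfigError("frequencies must be positive")
    w = 2.0 * np.pi * f
    r_slab = aperture.r_slab
    branches = [
        np.broadcast_to(r_slab + bead.delta_R, w.shape).astype(complex),
        1.0 / (1j * w * bead.C_b),
    ]
    if not math.isinf(bead.R_sh) and bead.C_sh > 0:
        if math.isinf(bead.C_sh):  # conformal conductive layer
            shell = np.broadcast_to(bead.R_sh, w.shape).astype(complex)
        else:
            shell = bead.R_sh + 1.0 / (1j * w * bead.C_sh)
        branches.append(shell)
    return _parallel(*branches) - r_slab


def total_impedance(
    aperture: ApertureModel, bead_element_value, s, f
) -> np.ndarray:
    """Sensing-zone impedance with the bead element scaled by ``s``.

    ``s`` is the pulse-shape scalar: 0 at baseline, 1 with the bead centred
    in the sensing zone (up to 1.5 to admit off-centre amplitude factors)::

        Z(w) = j w L_s + (1/(j w C_p)) || (R_f + s * dB(w))
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1.5):
        raise ConfigError("pulse-shape scalar s must lie in [0, 1.5]")
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ConfigError("frequencies must be positive")
    w = 2.0 * np.pi * f
    series = aperture.R_f + s * np.asarray(bead_element_value)
    # same algebraic form as baseline_spectrum so s = 0 reproduces it exactly
    z_par = series / (1.0 + 1j * w * series * aperture.C_p)
    return 1j * w * aperture.L_s + z_par


def peak_spectrum(
    bead: BeadModel, aperture: ApertureModel, freqs, s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free peak signature (dZp, dPhip) of one transit.

    dZp is the change in impedance magnitude (ohm) and dPhip the change in
    phase (degrees) between the bead centred (``s``) and the empty aperture,
    per frequency.
    """
    f = np.asarray(freqs, dtype=float)
    z0 = baseline_spectrum(aperture, f)
    z1 = total_impedance(aperture, bead_element(bead, aperture, f), s, f)
    dzp = np.abs(z1) - np.abs(z0)
    dphip = np.degrees(np.angle(z1) - np.angle(z0))
    return dzp, dphip


@dataclass(frozen=True)
class BindingParams:
    """Saturable binding curve mapping probe concentration to metallization.

    A four-parameter-logistic-shaped link: ``floor`` is the residual
    (background) metallization of a blank, ``ceiling`` the saturation level,
    ``c50`` (nM) the half-effect concentration and ``hill`` the slope.
    """

    floor: float = 0.002
    ceiling: float = 0.85
    c50: float = 20.0
    hill: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.floor < self.ceiling <= 1:
            raise ConfigError("need 0 <= floor < ceiling <= 1")
        if self.c50 <= 0 or self.hill <= 0:
            raise ConfigError("c50 and hill must be positive")


def dose_to_metallization(
    conc_nm: float, params: BindingParams | None = None
) -> float:
    """Mean metallization density produced by a probe concentration (nM)."""
    if conc_nm < 0:
        raise ConfigError("concentration must be non-negative")
    p = params or BindingParams()
    if conc_nm == 0:
        return p.floor
    frac = 1.0 / (1.0 + (p.c50 / conc_nm) ** p.hill)
    return p.floor + (p.ceiling - p.floor) * frac
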