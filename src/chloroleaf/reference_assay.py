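"""Spectrophotometric reference assay for leaf chlorophyll content.

Ground-truth chlorophyll contents come from a destructive wet-chemistry
assay: a weighed piece of leaf (0.02-0.04 g) is extracted in 80%
acetone made up to a fixed volumetric-flask volume (5 mL by default),
and the extract's absorbance is read at 645 and 663 nm against an 80%
acetone blank in a 1 cm cuvette.  Beer-Lambert linearity (A = K*C*L)
then gives pigment concentrations through the classical Arnon
simultaneous equations for 80% acetone:

    Ca = (12.7*A663 - 2.69*A645) / L      [mg/L]
    Cb = (22.9*A645 - 4.68*A663) / L
    Ct = (20.2*A645 + 8.02*A663) / L

with L the optical path in cm.  By coefficient algebra
``Ct - (Ca + Cb) = -0.01*A645`` exactly (22.9 - 2.69 = 20.21 against
the rounded 20.2 in the total), so the total tracks the sum of the
components up to print rounding of the classical coefficients.  Content per fresh mass follows from the mass balance
``content = C * V/1000 / m`` (V in mL, m in g).

The coefficient set is configurable so a national-standard variant can
be swapped in without touching the code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidAssayError

__all__ = [
    "AbsorbanceRecord",
    "ChlorophyllReference",
    "ArnonCoefficients",
    "ARNON_80_ACETONE",
    "arnon_concentrations",
    "content_per_mass",
    "reference_from_absorbances",
]


@dataclass(frozen=True)
class ArnonCoefficients:
    """Linear coefficients of the two-wavelength chlorophyll equations.

    ``ca = ca_663*A663 - ca_645*A645``; ``cb = cb_645*A645 - cb_663*A663``;
    ``ct = ct_645*A645 + ct_663*A663`` (all per unit path length).
    """

    ca_663: float = 12.7
    ca_645: float = 2.69
    cb_645: float = 22.9
    cb_663: float = 4.68
    ct_645: float = 20.2
    ct_663: float = 8.02


#: Canonical 645/663 nm coefficients for 80% acetone extracts.
ARNON_80_ACETONE = ArnonCoefficients()


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One assay measurement: two absorbances plus the mass balance.

    Parameters
    ----------
    a645, a663 : float
        Absorbances (dimensionless) of the extract at 645 and 663 nm.
    extract_volume : float
        Final volumetric-flask volume in mL (default 5).  Intermediate
        dilution steps of the protocol collapse into this final volume;
        only it enters the mass balance.
    leaf_mass : float
        Fresh leaf mass in g (protocol range 0.02-0.04 g).
    path_length : float
        Cuvette optical path in cm (default 1).
    """

    a645: float
    a663: float
    leaf_mass: float
    extract_volume: float = 5.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if self.a645 < 0 or self.a663 < 0:
            raise InvalidAssayError("absorbances must be >= 0")
        if self.leaf_mass <= 0:
            raise InvalidAssayError("leaf mass must be > 0 g")
        if self.extract_volume <= 0:
            raise InvalidAssayError("extract volume must be > 0 mL")
        if self.path_length <= 0:
            raise InvalidAssayError("path length must be > 0 cm")


@dataclass(frozen=True)
class ChlorophyllReference:
    """Reference contents in mg per g fresh leaf."""

    cla: float
    clb: float
    tcl: float


def arnon_concentrations(
    a645: float,
    a663: float,
    path_length: float = 1.0,
    coefficients: ArnonCoefficients = ARNON_80_ACETONE,
) -> tuple[float, float, float]:
    """Pigment concentrations (mg/L) from the two absorbances.

    Returns ``(ca, cb, ct)``.  A negative result is possible for
    absorbance pairs outside the pigment model's domain (e.g. dominant
    non-chlorophyll absorbers); such values are returned as-is for the
    caller to flag rather than silently clipped.

    Raises
    ------
    InvalidAssayError
        If an absorbance is negative or the path length non-positive.
    """
    if a645 < 0 or a663 < 0:
        raise InvalidAssayError("absorbances must be >= 0")
    if path_length <= 0:
        raise InvalidAssayError("path length must be > 0 cm")
    k = coefficients
    ca = (k.ca_663 * a663 - k.ca_645 * a645) / path_length
    cb = (k.cb_645 * a645 - k.cb_663 * a663) / path_length
    ct = (k.ct_645 * a645 + k.ct_663 * a663) / path_length
    return (ca, cb, ct)


def content_per_mass(conc_mg_per_l: float, extract_volume_ml: float, leaf_mass_g: float) -> float:
    """Convert extract concentration (mg/L) to content per fresh mass (mg/g).

    Mass balance: the pigment in ``extract_volume_ml`` of extract all
    came from ``leaf_mass_g`` of leaf, so
    ``content = conc * volume/1000 / mass``.

    Raises
    ------
    InvalidAssayError
        If volume or mass is non-positive.
    """
    if extract_volume_ml <= 0:
        raise InvalidAssayError("extract volume must be > 0 mL")
    if leaf_mass_g <= 0:
        raise InvalidAssayError("leaf mass must be > 0 g")
    return conc_mg_per_l * (extract_volume_ml / 1000.0) / leaf_mass_g


def reference_from_absorbances(
    record: AbsorbanceRecord,
    coefficients: ArnonCoefficients = ARNON_80_ACETONE,
) -> ChlorophyllReference:
    """Full assay computation: absorbances -> contents in mg/g."""
    ca, cb, ct = arnon_concentrations(
        record.a645, record.a663, record.path_length, coefficients
    )
    return ChlorophyllReference(
        cla=content_per_mass(ca, record.extract_volume, record.leaf_mass),
        clb=content_per_mass(cb, record.extract_volume, record.leaf_mass),
        tcl=content_per_mass(ct, record.extract_volume, record.leaf_mass),
    )
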