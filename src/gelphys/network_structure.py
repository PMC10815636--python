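"""Network structural parameters from equilibrium swelling.

The chain of estimates, all driven by the measured equilibrium swelling
degree Q of a gel:

1. Polymer volume fraction in the swollen state,

       v2s = rho_s / (Q * rho_p + rho_s)

   with rho_p the dry-polymer density and rho_s the solvent density.

2. Number-average molar mass between crosslinks Mc by the modified
   Flory–Rehner relation for a network crosslinked in the absence of
   solvent,

       1/Mc = 2/Mn - (nu1/V1) * [ln(1 - v2s) + v2s + chi1 * v2s^2]
                               / [v2s^(1/3) - (2/phi) * v2s]

   where Mn is the pre-crosslinking molar mass of the backbone polymer,
   nu1 its specific volume, V1 the solvent molar volume, chi1 the
   Flory–Huggins polymer–solvent interaction parameter and phi the
   crosslinker functionality.

3. Mesh size (correlation length) following Canal and Peppas:

       N  = 2 * Mc / Mr                (links per network chain)
       r0 = l * sqrt(Cn * N)           (unperturbed end-to-end distance, Å)
       xi = v2s^(-1/3) * r0            (mesh size, Å)

   with Mr the repeat-unit molar mass, Cn the Flory characteristic ratio
   and l the mean backbone bond length.

Default constants describe PSA-g-mPEG gels crosslinked with disuccinyl PEG
swollen in water; the densities are assumed values (the measurement is not
available) and are deliberately configurable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "NetworkParams",
    "StructureResult",
    "polymer_volume_fraction",
    "molar_mass_between_crosslinks",
    "mesh_size",
    "characterize_network",
    "stretched_peg_length",
    "EO_UNIT_MOLAR_MASS",
    "EO_UNIT_LENGTH_ANGSTROM",
]

# ethylene-oxide repeat unit: -CH2-CH2-O-
EO_UNIT_MOLAR_MASS = 44.05  # g/mol
EO_UNIT_LENGTH_ANGSTROM = 1.5  # per unit, fully stretched helical conformation


@dataclass(frozen=True)
class NetworkParams:
    """Physical constants of the swelling → structure chain.

    Units: Mn, Mr in g·mol⁻¹; V1 in mL·mol⁻¹; nu1 in mL·g⁻¹; densities in
    g·cm⁻³; l_bond in Å; chi1, phi, Cn dimensionless.

    ``nu1 = 0`` is accepted as a degenerate setting that switches the
    solvent-mixing/elastic term off entirely (useful for testing the
    phantom 1/Mc = 2/Mn limit); every other field must be positive.
    """

    mn: float = 17_500.0
    chi1: float = 0.426
    v1: float = 18.1
    nu1: float = 1.0 / 1.2
    phi: float = 2.0
    rho_p: float = 1.2
    rho_s: float = 1.0
    cn: float = 6.1
    l_bond: float = 1.51
    mr: float = 640.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "nu1":
                if v < 0:
                    raise ValueError(f"nu1 must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if self.chi1 >= 0.5:
            raise ValueError(
                f"chi1 must be < 0.5 (good-solvent regime), got {self.chi1}"
            )
        if self.nu1 > 0 and abs(self.nu1 * self.rho_p - 1.0) > 0.05:
            raise ValueError(
                "nu1 and rho_p are inconsistent: specific volume times density "
                f"is {self.nu1 * self.rho_p:.4f}, expected 1 within 0.05"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkParams":
        """Load constants from a YAML or JSON mapping.

        Recognised keys (all optional, defaults above): ``Mn, chi1, V1, nu1,
        phi, rho_p, rho_s, Cn, l_bond, Mr``.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a key-value mapping")
        keymap = {
            "Mn": "mn", "chi1": "chi1", "V1": "v1", "nu1": "nu1", "phi": "phi",
            "rho_p": "rho_p", "rho_s": "rho_s", "Cn": "cn", "l_bond": "l_bond",
            "Mr": "mr",
        }
        unknown = set(data) - set(keymap)
        if unknown:
            raise ValueError(f"{path}: unknown parameter key(s) {sorted(unknown)}")
        return replace(cls(), **{keymap[k]: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class StructureResult:
    """Derived network descriptors for one formulation.

    q and v2s dimensionless, mc in g·mol⁻¹, n_links dimensionless, r0 and
    xi in Å.  Always satisfies 0 < v2s <= 1 and xi >= r0.
    """

    q: float
    v2s: float
    mc: float
    n_links: float
    r0: float
    xi: float


def polymer_volume_fraction(q: float, rho_p: float, rho_s: float) -> float:
    """Polymer volume fraction in the swollen state.

    v2s = rho_s / (Q rho_p + rho_s); equals 1 in the dry limit Q = 0 and
    decreases monotonically as the gel takes up solvent.
    """
    if q < 0:
        raise ValueError(f"swelling degree must be >= 0, got {q}")
    if rho_p <= 0 or rho_s <= 0:
        raise ValueError("densities must be positive")
    return rho_s / (q * rho_p + rho_s)


def molar_mass_between_crosslinks(v2s: float, params: NetworkParams) -> float:
    """Molar mass between crosslinks Mc (g·mol⁻¹) by modified Flory–Rehner.

    Raises
    ------
    ValueError
        If ``v2s`` is outside (0, 1), or if the computed 1/Mc is not
        positive (parameters outside the validity of the model).
    """
    if not 0 < v2s < 1:
        raise ValueError(f"v2s must lie strictly between 0 and 1, got {v2s}")
    mixing = math.log1p(-v2s) + v2s + params.chi1 * v2s * v2s
    elastic = v2s ** (1.0 / 3.0) - (2.0 / params.phi) * v2s
    inv_mc = 2.0 / params.mn - (params.nu1 / params.v1) * mixing / elastic
    if inv_mc <= 0:
        raise ValueError(
            f"parameters outside validity: computed 1/Mc = {inv_mc:.3e} <= 0"
        )
    return 1.0 / inv_mc


def mesh_size(
    mc: float, v2s: float, params: NetworkParams
) -> tuple[float, float, float]:
    """Links per chain N, end-to-end distance r0 (Å) and mesh size xi (Å).

    N = 2 Mc/Mr, r0 = l sqrt(Cn N), xi = v2s^(-1/3) r0.
    """
    if mc <= 0:
        raise ValueError(f"Mc must be positive, got {mc}")
    if not 0 < v2s <= 1:
        raise ValueError(f"v2s must lie in (0, 1], got {v2s}")
    n_links = 2.0 * mc / params.mr
    r0 = params.l_bond * math.sqrt(params.cn * n_links)
    xi = v2s ** (-1.0 / 3.0) * r0
    return n_links, r0, xi


def characterize_network(q: float, params: NetworkParams | None = None) -> StructureResult:
    """Full swelling → structure chain for one equilibrium swelling degree.

    Chains :func:`polymer_volume_fraction`,
    :func:`molar_mass_between_crosslinks` and :func:`mesh_size`.
    """
    if params is None:
        params = NetworkParams()
    if q <= 0:
        raise ValueError(f"swelling degree must be positive, got {q}")
    v2s = polymer_volume_fraction(q, params.rho_p, params.rho_s)
    mc = molar_mass_between_crosslinks(v2s, params)
    n_links, r0, xi = mesh_size(mc, v2s, params)
    return StructureResult(q=q, v2s=v2s, mc=mc, n_links=n_links, r0=r0, xi=xi)


def stretched_peg_length(
    n_units: float | None = None, peg_molar_mass: float | None = None
) -> float:
    """Length (Å) of a fully stretched helical PEG chain.

    One ethylene-oxide unit contributes 1.5 Å; a PEG of molar mass M has
    M/44.05 units (not rounded).  Exactly one of ``n_units`` and
    ``peg_molar_mass`` must be given.  No display rounding is applied.
    """
    if (n_units is None) == (peg_molar_mass is None):
        raise ValueError("supply exactly one of n_units or peg_molar_mass")
    if n_units is not None:
        if n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {n_units}")
    else:
        if peg_molar_mass <= 0:
            raise ValueError(f"peg_molar_mass must be positive, got {peg_molar_mass}")
        n_units = peg_molar_mass / EO_UNIT_MOLAR_MASS
    return EO_UNIT_LENGTH_ANGSTROM * n_units
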