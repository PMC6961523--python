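"""Three-layer bed nutrient and oxygen dynamics.

The bed is split into an oxic layer (down to the oxygen penetration depth
D1), a nitrate transition layer (D1..D2) and an anoxic layer (D2..z_bed).
Nutrients are carried as total (pore water + adsorbed) contents per layer;
the dissolved share is a fixed, possibly layer-dependent partition
coefficient (instantaneous sorption equilibrium). Oxygen is not a state
variable: D1 follows a quasi-steady closed form (zero-order volumetric
consumption balancing diffusion), which gives the square-root dependence on
diffusivity and bottom-water oxygen that lets ripple-driven pore-water
exchange deepen the oxic layer.

Exchange with the overlying water relaxes the surface layer toward the
content it would hold in equilibrium with bottom-water concentrations;
interlayer transport is diffusive mixing of dissolved concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MMOL_C_PER_G

NUTRIENTS = ("NO3", "NH4", "PO4", "Si")

#: moles of O2 consumed per mole of N nitrified (NH4+ -> NO3-).
O2_PER_N_NITRIFIED = 2.0

_LAYER_FLOOR = 1.0e-4   # m, numerical floor on layer thickness


@dataclass
class LayerStructure:
    """Bed layering: oxic (0..D1), transition (D1..D2), anoxic (D2..z_bed)."""

    D1: float = 0.02
    D2: float = 0.05
    z_bed: float = 0.25
    porosity: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.D1 <= self.D2 <= self.z_bed):
            raise ValueError("need 0 <= D1 <= D2 <= z_bed")
        if not (0.0 < self.porosity < 1.0):
            raise ValueError("porosity must lie in (0, 1)")

    def thicknesses(self) -> np.ndarray:
        """Layer thicknesses (m) with a small numerical floor."""
        th = np.array([self.D1, self.D2 - self.D1, self.z_bed - self.D2])
        return np.maximum(th, _LAYER_FLOOR)

    def bounds(self) -> np.ndarray:
        return np.array([0.0, self.D1, self.D2, self.z_bed])


def oxygen_penetration(
    K_eff: float,
    bw_O2: float,
    volumetric_demand: float,
    z_bed: float = 0.25,
) -> float:
    """Oxygen penetration depth from a quasi-steady zero-order balance.

    ``D1 = sqrt(2 K_eff [O2]_bw / R)`` with ``K_eff`` in m^2 s^-1, bottom
    water oxygen in mmol m^-3 and volumetric demand ``R`` in
    mmol O2 m^-3 s^-1; capped at the modelled bed depth. Zero bottom-water
    oxygen gives D1 = 0; zero demand hits the cap.
    """
    if K_eff <= 0:
        raise ValueError("K_eff must be > 0")
    if bw_O2 < 0 or volumetric_demand < 0:
        raise ValueError("oxygen and demand must be >= 0")
    if bw_O2 == 0.0:
        return 0.0
    if volumetric_demand == 0.0:
        return z_bed
    return min(np.sqrt(2.0 * K_eff * bw_O2 / volumetric_demand), z_bed)


def total_oxygen_uptake(
    aerobic_respiration_C: float,
    nitrification_flux: float,
    reoxidation_flux: float,
) -> float:
    """Total benthic oxygen uptake (mmol O2 m^-2 day^-1, positive into bed).

    Aerobic respiration carbon converts at 1 mol O2 : 1 mol C; nitrification
    costs 2 mol O2 per mol N; reduced products of anaerobic metabolism that
    are reoxidised add their O2 demand directly.
    """
    if min(aerobic_respiration_C, nitrification_flux, reoxidation_flux) < 0:
        raise ValueError("fluxes must be >= 0")
    return (
        aerobic_respiration_C * MMOL_C_PER_G
        + O2_PER_N_NITRIFIED * nitrification_flux
        + reoxidation_flux
    )


def nitrification(
    nh4_mean_conc: float, rate_const: float, oxic_volume: float
) -> float:
    """First-order nitrification flux (mmol N m^-2 day^-1).

    Proportional to the depth-averaged dissolved ammonium concentration in
    the oxic layer times the oxic pore volume per unit area.
    """
    if min(nh4_mean_conc, rate_const, oxic_volume) < 0:
        raise ValueError("inputs must be >= 0")
    return rate_const * nh4_mean_conc * oxic_volume


def denitrification(
    anaerobic_biomass: float, no3_content: float, rate_const: float
) -> float:
    """Denitrification flux (mmol N m^-2 day^-1).

    Bilinear in anaerobic bacterial biomass (g C m^-2) and bed nitrate
    content (mmol m^-2); collapses when anaerobic biomass is low, which is
    what lets nitrate build up in the bed over winter.
    """
    if min(anaerobic_biomass, no3_content, rate_const) < 0:
        raise ValueError("inputs must be >= 0")
    return rate_const * anaerobic_biomass * no3_content


def silicate_dissolution(pom_si_content: float, rate_const: float) -> float:
    """First-order dissolution of particulate silicate (mmol Si m^-2 d^-1)."""
    if pom_si_content < 0 or rate_const < 0:
        raise ValueError("inputs must be >= 0")
    return rate_const * pom_si_content


def phosphate_partition(
    po4_total: float, partition_coefficient: float
) -> tuple[float, float]:
    """Split total phosphate into (dissolved, adsorbed).

    ``dissolved = coefficient * total``; the oxic-layer coefficient should
    be smaller than the anoxic one (adsorption is stronger when oxygenated).
    """
    if po4_total < 0:
        raise ValueError("total must be >= 0")
    if not (0.0 < partition_coefficient <= 1.0):
        raise ValueError("partition coefficient must lie in (0, 1]")
    dissolved = partition_coefficient * po4_total
    return dissolved, po4_total - dissolved


def relax_exchange(
    content: float, equilibrium_content: float, tau_relax: float, dt: float
) -> tuple[float, float]:
    """Relax a layer content toward equilibrium; return (content', flux out).

    ``content' = C_eq + (C - C_eq) exp(-dt/tau)``; the benthic-pelagic flux
    is the content change per unit time, positive out of the bed.
    """
    if tau_relax <= 0:
        raise ValueError("tau_relax must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    new = equilibrium_content + (content - equilibrium_content) * np.exp(-dt / tau_relax)
    flux_out = (content - new) / dt
    return float(new), float(flux_out)


def nitrate_penetration(
    no3_conc_at_D1: float,
    transition_consumption: float,
    K: float,
    D1: float,
    z_bed: float = 0.25,
) -> float:
    """Nitrate penetration depth D2 >= D1.

    Same quasi-steady construction as the oxygen depth, seeded at D1 with
    the local nitrate concentration: ``D2 = D1 + sqrt(2 K c / R)`` with the
    volumetric consumption ``R`` (mmol m^-3 s^-1) from denitrification; a
    vanishing consumption pushes D2 to the bed-depth cap.
    """
    if min(no3_conc_at_D1, transition_consumption, K) < 0 or D1 < 0:
        raise ValueError("inputs must be >= 0")
    if no3_conc_at_D1 == 0.0:
        return min(D1, z_bed)
    if transition_consumption == 0.0:
        return z_bed
    return min(D1 + np.sqrt(2.0 * K * no3_conc_at_D1 / transition_consumption), z_bed)


def porewater_profile(
    dissolved_layer_contents: np.ndarray,
    structure: LayerStructure,
    grid: np.ndarray,
) -> np.ndarray:
    """Piecewise-constant dissolved concentration (mmol m^-3) on a depth grid.

    Layer concentration = dissolved content / (porosity * thickness); a
    zero-thickness layer reports the adjacent (deeper) layer's value.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > structure.z_bed + 1e-12):
        raise ValueError("grid must lie within [0, z_bed]")
    th = structure.thicknesses()
    conc = np.asarray(dissolved_layer_contents, float) / (structure.porosity * th)
    bounds = structure.bounds()
    raw = np.array([structure.D1, structure.D2 - structure.D1,
                    structure.z_bed - structure.D2])
    # collapse degenerate layers onto their neighbour's concentration
    for i in range(2):
        if raw[i] <= 0:
            conc[i] = conc[i + 1]
    idx = np.clip(np.searchsorted(bounds, grid, side="right") - 1, 0, 2)
    return conc[idx]


def rebin_layers(
    contents: np.ndarray, old_bounds: np.ndarray, new_bounds: np.ndarray
) -> np.ndarray:
    """Redistribute layer contents when layer boundaries move.

    Treats each old layer as uniformly concentrated, integrates that
    piecewise-constant profile over the new layers; conserves total content
    exactly (up to float rounding).
    """
    old_bounds = np.asarray(old_bounds, float)
    new_bounds = np.asarray(new_bounds, float)
    contents = np.asarray(contents, float)
    old_th = np.diff(old_bounds)
    density = np.where(old_th > 0, contents / np.where(old_th > 0, old_th, 1.0), 0.0)
    out = np.zeros(len(new_bounds) - 1)
    for j in range(len(out)):
        lo, hi = new_bounds[j], new_bounds[j + 1]
        for i in range(len(contents)):
            o_lo, o_hi = old_bounds[i], old_bounds[i + 1]
            overlap = max(0.0, min(hi, o_hi) - max(lo, o_lo))
            out[j] += density[i] * overlap
    # any content stranded in degenerate old layers goes to the matching index
    stranded = contents.sum() - out.sum()
    if abs(stranded) > 0:
        out[np.argmax(np.diff(new_bounds))] += stranded
    return out


@dataclass
class NutrientBedState:
    """Per-nutrient 3-layer total contents (mmol m^-2) plus exchange params."""

    contents: dict = field(
        default_factory=lambda: {n: np.zeros(3) for n in NUTRIENTS}
    )
    #: dissolved fraction per nutrient and layer (oxic, transition, anoxic).
    partition: dict = field(
        default_factory=lambda: {
            "NO3": np.array([1.0, 1.0, 1.0]),
            "NH4": np.array([0.8, 0.9, 0.9]),
            "PO4": np.array([0.2, 0.6, 0.6]),
            "Si": np.array([1.0, 1.0, 1.0]),
        }
    )
    tau_relax: dict = field(
        default_factory=lambda: {n: 1.0 for n in NUTRIENTS}
    )

    def dissolved(self, nutrient: str) -> np.ndarray:
        """Dissolved content per layer (mmol m^-2)."""
        return self.contents[nutrient] * self.partition[nutrient]

    def dissolved_conc(self, nutrient: str, structure: LayerStructure) -> np.ndarray:
        """Dissolved pore-water concentration per layer (mmol m^-3)."""
        return self.dissolved(nutrient) / (structure.porosity * structure.thicknesses())

    def depth_mean_conc(self, nutrient: str, structure: LayerStructure) -> float:
        """Thickness-weighted mean dissolved concentration over the bed."""
        th = structure.thicknesses()
        conc = self.dissolved_conc(nutrient, structure)
        return float((conc * th).sum() / th.sum())

    def total(self, nutrient: str) -> float:
        return float(self.contents[nutrient].sum())

    def rebin(self, old: LayerStructure, new: LayerStructure) -> None:
        """Move all contents onto the new layer boundaries (mass conserving)."""
        for n in NUTRIENTS:
            self.contents[n] = rebin_layers(
                self.contents[n], old.bounds(), new.bounds()
            )

    def equilibrium_content(
        self, nutrient: str, bw_conc: float, structure: LayerStructure
    ) -> float:
        """Surface-layer total content in equilibrium with bottom water.

        At equilibrium the dissolved pore-water concentration matches the
        bottom-water concentration, so the total content is the dissolved
        equilibrium divided by the partition coefficient.
        """
        th1 = structure.thicknesses()[0]
        pc = self.partition[nutrient][0]
        return bw_conc * structure.porosity * th1 / pc

    def mix_interlayer(
        self, structure: LayerStructure, K_day: float, dt: float
    ) -> None:
        """Diffusive mixing of dissolved concentrations between adjacent layers.

        ``K_day`` is the deep (unenhanced, bio-irrigated) diffusivity in
        m^2 day^-1. Fluxes are flux-limited so no layer is overdrawn.
        """
        th = structure.thicknesses()
        por = structure.porosity
        for n in NUTRIENTS:
            cont = self.contents[n]
            pc = self.partition[n]
            conc = cont * pc / (por * th)
            for i in (0, 1):
                dz = 0.5 * (th[i] + th[i + 1])
                flux = K_day * (conc[i] - conc[i + 1]) / dz * por * dt
                donor = i if flux > 0 else i + 1
                avail = cont[donor] * pc[donor]
                flux = np.clip(flux, -avail, avail)
                cont[i] -= flux
                cont[i + 1] += flux
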