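"""Whole-community energy consumption and compensation ratios.

Community energy use (kJ/day) multiplies each species' abundance by a
per-individual field metabolic rate (FMR); shrew FMR is scaled from a
reference species by body mass (mass-specific FMR x mean mass).  Under
zero-sum (compensatory) dynamics the community total should be conserved
when species abundances trade off; the compensation ratio quantifies how
far a later year's total falls relative to a reference year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EnergyBudget",
    "mass_specific_fmr",
    "community_energy",
    "compensation",
]


def mass_specific_fmr(fmr_ref: float, mass_ref: float, mass_target: float) -> float:
    """Scale a reference FMR (kJ/day at ``mass_ref`` g) linearly to ``mass_target`` g."""
    if fmr_ref <= 0 or mass_ref <= 0 or mass_target <= 0:
        raise ValueError("fmr_ref, mass_ref and mass_target must be positive")
    return (fmr_ref / mass_ref) * mass_target


@dataclass
class EnergyBudget:
    """Per habitat x year energy account: species components and the total (kJ/day)."""

    abundances: dict
    fmrs: dict
    species_energy: dict = field(init=False)
    total: float = field(init=False)
    habitat: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if set(self.abundances) != set(self.fmrs):
            raise ValueError("species lists of abundances and FMRs must align")
        for sp, n in self.abundances.items():
            if n < 0:
                raise ValueError(f"negative abundance for {sp}")
            if self.fmrs[sp] < 0:
                raise ValueError(f"negative FMR for {sp}")
        self.species_energy = {
            sp: self.abundances[sp] * self.fmrs[sp] for sp in self.abundances
        }
        self.total = float(sum(self.species_energy.values()))


def community_energy(abundances: dict, fmrs: dict, **tags) -> EnergyBudget:
    """Total community energy consumption: sum over species of N x FMR."""
    return EnergyBudget(abundances=dict(abundances), fmrs=dict(fmrs), **tags)


def compensation(e_t: float, e_ref: float) -> float:
    """Percent of a reference year's community energy reached at time t.

    100% is the zero-sum expectation; returns nan when the reference is zero.
    """
    if e_ref == 0:
        return float("nan")
    if e_ref < 0 or e_t < 0:
        raise ValueError("energy totals must be non-negative")
    return 100.0 * e_t / e_ref
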