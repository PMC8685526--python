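"""Pore-block and agonist pharmacology.

Drugs act as multiplicative factors on maximal conductances.  A channel
blocker follows the simple pore-block law ``G = G0 / (1 + [D]/IC50)``; a
beta-agonist (isoproterenol) scales ICaL up with a saturating law that doubles
the conductance at full receptor occupancy, ``G = G0 * (1 + [D]/([D]+EC50))``
(a linear variant ``1 + [D]/EC50`` is selectable for sensitivity studies).

The shipped drug library mirrors published safety-pharmacology half-maximal
values for three channel targets: peak Nav1.5 (-> gNa), hERG (-> gKr) and
Cav1.2 (-> gCaL).  Concentrations and half-max values are handled in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from .cell_model import BaselineParameters
from .errors import ConfigurationError, RangeError

#: channel label -> BaselineParameters field
CHANNEL_MAP = {
    "Nav1.5-peak": "gNa",
    "hERG": "gKr",
    "Cav1.2": "gCaL",
}

AgonistLaw = Literal["saturating", "linear"]


@dataclass(frozen=True)
class DrugTarget:
    channel: str          # one of CHANNEL_MAP
    half_max: float       # uM; IC50 for block, EC50 for enhance
    mode: Literal["block", "enhance"] = "block"

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_MAP:
            raise ConfigurationError(
                f"unknown channel label {self.channel!r}; expected one of {sorted(CHANNEL_MAP)}"
            )
        if not self.half_max > 0:
            raise RangeError(f"half_max must be > 0, got {self.half_max!r}")


@dataclass(frozen=True)
class DrugSpec:
    name: str
    concentration: float                 # uM
    targets: tuple[DrugTarget, ...] = ()
    agonist_law: AgonistLaw = "saturating"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise RangeError(f"concentration must be >= 0, got {self.concentration!r}")


def pore_block_factor(conc: float, ic50: float) -> float:
    """Fraction of conductance remaining under simple pore block."""
    if conc < 0:
        raise RangeError(f"concentration must be >= 0, got {conc!r}")
    if not ic50 > 0:
        raise RangeError(f"IC50 must be > 0, got {ic50!r}")
    return 1.0 / (1.0 + conc / ic50)


def agonist_factor(conc: float, ec50: float, law: AgonistLaw = "saturating") -> float:
    """Conductance enhancement factor >= 1 for a saturating agonist."""
    if conc < 0:
        raise RangeError(f"concentration must be >= 0, got {conc!r}")
    if not ec50 > 0:
        raise RangeError(f"EC50 must be > 0, got {ec50!r}")
    if law == "saturating":
        return 1.0 + conc / (conc + ec50)
    if law == "linear":
        return 1.0 + conc / ec50
    raise ConfigurationError(f"unknown agonist law {law!r}")


def drug_factors(drug: DrugSpec) -> dict[str, float]:
    """Per-parameter multiplicative factors for a drug at its concentration."""
    factors: dict[str, float] = {}
    for target in drug.targets:
        param = CHANNEL_MAP[target.channel]
        if target.mode == "block":
            f = pore_block_factor(drug.concentration, target.half_max)
        else:
            f = agonist_factor(drug.concentration, target.half_max, drug.agonist_law)
        factors[param] = factors.get(param, 1.0) * f
    return factors


def apply_drug(params: BaselineParameters, drug: DrugSpec) -> BaselineParameters:
    """Scale the targeted conductances; untargeted parameters are unchanged.

    Purely multiplicative, so it commutes with population scaling.
    """
    factors = drug_factors(drug)
    if not factors:
        return params
    return replace(params, **{k: getattr(params, k) * v for k, v in factors.items()})


# ---------------------------------------------------------------------------
# shipped drug library (concentrations converted from mM to uM)
# ---------------------------------------------------------------------------

def default_drug_library(agonist_law: AgonistLaw = "saturating") -> dict[str, DrugSpec]:
    """The three study drugs plus the drug-free control.

    Flecainide 0.2 uM (Nav1.5-peak IC50 6.7, hERG 0.7, Cav1.2 20);
    verapamil 0.5 uM (1.0 / 0.7 / 0.1); isoproterenol 80 uM acting only on
    Cav1.2 with EC50 20 uM as an agonist.
    """
    return {
        "none": DrugSpec("none", 0.0),
        "flecainide": DrugSpec("flecainide", 0.2, (
            DrugTarget("Nav1.5-peak", 6.7),
            DrugTarget("hERG", 0.7),
            DrugTarget("Cav1.2", 20.0),
        )),
        "verapamil": DrugSpec("verapamil", 0.5, (
            DrugTarget("Nav1.5-peak", 1.0),
            DrugTarget("hERG", 0.7),
            DrugTarget("Cav1.2", 0.1),
        )),
        "isoproterenol": DrugSpec("isoproterenol", 80.0, (
            DrugTarget("Cav1.2", 20.0, mode="enhance"),
        ), agonist_law=agonist_law),
    }


#: names used for experiment conditions, in design-table order
CONDITION_ORDER = ("basal", "flecainide", "verapamil", "isoproterenol")


def condition_drug(condition: str, library: dict[str, DrugSpec] | None = None) -> DrugSpec:
    """Map an experiment condition label to its DrugSpec ('basal' -> none)."""
    lib = library if library is not None else default_drug_library()
    key = "none" if condition == "basal" else condition
    if key not in lib:
        raise ConfigurationError(f"unknown condition {condition!r}")
    return lib[key]


def effective_multipliers(multipliers: Sequence[float], drug: DrugSpec,
                          names: Sequence[str]) -> list[float]:
    """Fold drug factors into a profile's nine multipliers (post-drug view).

    Drug factors act on gNa (m_gNa), gKr (not a varied axis; folded nowhere)
    and gCaL (m_gCaL).  hERG block therefore does not alter the feature
    vector; it still acts on the simulated cell via ``apply_drug``.
    """
    factors = drug_factors(drug)
    param_to_mult = {"gNa": "m_gNa", "gCaL": "m_gCaL"}
    out = list(multipliers)
    for param, f in factors.items():
        mname = param_to_mult.get(param)
        if mname is not None:
            out[list(names).index(mname)] *= f
    return out
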