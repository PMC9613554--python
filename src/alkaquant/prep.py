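"""Sample-preparation model: milk <-> final-extract concentration scaling.

The wet-lab protocol extracts 3 mL milk with 30 mL 2% aqueous formic acid,
loads 15 mL of the aqueous raw extract on a cation-exchange cartridge and
reconstitutes the dried eluate in 0.5 mL.  The net effect is a fixed
concentration factor between the milk concentration (ug/L) and the final
measuring-solution concentration (ng/mL); with the default volumes the factor
is (15/33) x 3/0.5 = 2.727.  ug/L and ng/mL are the same numerical scale, so
the factor is a pure ratio.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PrepModel:
    """Volumes of the extraction / clean-up protocol, in mL."""

    v_milk: float = 3.0
    v_acid: float = 30.0
    v_loaded: float = 15.0
    v_reconst: float = 0.5

    def __post_init__(self) -> None:
        for name in ("v_milk", "v_acid", "v_loaded", "v_reconst"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.v_loaded > self.v_milk + self.v_acid:
            raise ValueError("cannot load more extract than was prepared")

    @property
    def concentration_factor(self) -> float:
        """ng/mL in the final extract per ug/L in milk."""
        return (self.v_loaded / (self.v_milk + self.v_acid)) \
            * self.v_milk / self.v_reconst


def milk_to_extract(conc_milk: float, prep: PrepModel = PrepModel()) -> float:
    """Convert a milk concentration (ug/L) to the final-extract one (ng/mL)."""
    if conc_milk < 0:
        raise ValueError("concentration must be non-negative")
    return conc_milk * prep.concentration_factor


def extract_to_milk(conc_extract: float, prep: PrepModel = PrepModel()) -> float:
    """Convert a final-extract concentration (ng/mL) back to milk units (ug/L)."""
    return conc_extract / prep.concentration_factor
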