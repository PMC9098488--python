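"""IVT sgRNA fill-in template design and reaction-mix arithmetic.

The fill-in PCR template for T7 in vitro transcription is assembled from a
52-nt spacer-specific forward oligo (17-nt T7 promoter + 20-nt spacer +
15-nt annealing tail) and an 80-nt universal reverse oligo carrying the
invariant sgRNA scaffold; the overlap of the tail gives a
52 + 80 - 15 = 117 bp product. Spacers beginning 5'GG transcribe with a
100% match to the target; others trigger a warning, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

#: the only 17-nt T7 promoter core consistent with the 17+20+15=52 geometry
T7_PROMOTER = "TAATACGACTCACTATA"
DEFAULT_TAIL = "GTTTTAGAGCTAGAA"  # first 15 nt of the invariant sgRNA scaffold


@dataclass(frozen=True)
class FillinDesign:
    spacer: str
    forward_oligo: str  # T7 promoter + spacer + annealing tail
    tail: str
    universal_oligo_length: int
    gg_start_ok: bool

    @property
    def product_length(self) -> int:
        return len(self.forward_oligo) + self.universal_oligo_length - len(self.tail)


def design_fillin(
    spacer: str,
    tail15: str = DEFAULT_TAIL,
    universal_len: int = 80,
) -> FillinDesign:
    spacer = spacer.upper()
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    if set(spacer) - set("ACGT"):
        raise ValueError(f"spacer contains non-ACGT characters: {spacer!r}")
    if len(tail15) != 15:
        raise ValueError(f"annealing tail must be 15 nt, got {len(tail15)}")
    gg = spacer.startswith("GG")
    if not gg:
        warnings.warn(
            "spacer does not start with 5'GG; the T7 transcript will carry "
            "mismatched 5' bases",
            stacklevel=2,
        )
    return FillinDesign(
        spacer=spacer,
        forward_oligo=T7_PROMOTER + spacer + tail15.upper(),
        tail=tail15.upper(),
        universal_oligo_length=universal_len,
        gg_start_ok=gg,
    )


@dataclass(frozen=True)
class Component:
    name: str
    stock_nM: float
    volume_uL: float


@dataclass
class MixRecipe:
    components: list[Component]
    total_volume_uL: float
    final_nM: dict[str, float]
    molar_ratio: dict[str, float]  # normalized to the smallest nonzero final conc


def mix_concentrations(
    components: Sequence[Component | tuple], total_volume_uL: float
) -> MixRecipe:
    """Exact dilution arithmetic: final_i = stock_i * volume_i / total.

    Water/buffer enter as zero-concentration components; the stated total
    volume must equal the summed volumes.
    """
    comps = [c if isinstance(c, Component) else Component(*c) for c in components]
    if any(c.volume_uL <= 0 for c in comps):
        raise ValueError("component volumes must be positive")
    vol_sum = sum(c.volume_uL for c in comps)
    if abs(vol_sum - total_volume_uL) > 1e-9 * max(1.0, total_volume_uL):
        raise ValueError(
            f"total volume {total_volume_uL} inconsistent with summed volumes {vol_sum}"
        )
    final = {c.name: c.stock_nM * c.volume_uL / total_volume_uL for c in comps}
    nonzero = [v for v in final.values() if v > 0]
    ratio = {}
    if nonzero:
        base = min(nonzero)
        ratio = {name: v / base for name, v in final.items() if v > 0}
    return MixRecipe(
        components=comps,
        total_volume_uL=total_volume_uL,
        final_nM=final,
        molar_ratio=ratio,
    )


def rnp_ratio_check(
    protein_conc: float,
    grna_conc: float,
    target_ratio: float = 1.3,
    tolerance: float = 0.05,
) -> tuple[bool, float]:
    """Check a gRNA:protein molar ratio against the assembly target (1:1.3
    protein:gRNA). Returns (ok, signed relative deviation from target)."""
    if protein_conc <= 0 or grna_conc <= 0:
        raise ValueError("concentrations must be positive")
    ratio = grna_conc / protein_conc
    deviation = (ratio - target_ratio) / target_ratio
    return abs(deviation) <= tolerance, deviation
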