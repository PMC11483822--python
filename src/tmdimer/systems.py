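"""Static descriptions of two-helix transmembrane (TMD) systems.

A :class:`TMDSystem` records, for a pair of identical membrane-embedded
helices, the residue numbering and the residue sub-ranges used by the
individual analyses:

* ``dhh_range`` -- residues whose backbone-bead centroid defines the
  interhelical centre-of-mass distance d_HH,
* ``axis_range`` -- residues used to fit the helical axis for the tilt
  (theta) and crossing (Omega) angles,
* ``core_range`` -- membrane-embedded residues (used for flexibility
  ramps and for the shape classifier's end separations).

Built-in systems cover the insulin receptor (IR) and the insulin-like
growth-factor-1 receptor (IGF1R) TMD constructs: IR residues 940-988 with
d_HH over 953-979, tilt over 957-979 and a helix kink at G960/P961;
IGF1R residues 919-967 with all analysis ranges 937-959 and a kink at
P941.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

__all__ = ["TMDSystem", "ir_system", "igf1r_system", "get_system"]


# Residue identities explicitly named in the structural literature for the
# two constructs; all other positions carry the placeholder "UNK".  Residue
# names are metadata only -- no analysis depends on them.
_IR_KNOWN = {
    953: "ILE", 960: "GLY", 961: "PRO", 964: "PHE", 965: "VAL",
    966: "PHE", 968: "PHE", 979: "LEU", 980: "ARG", 981: "LYS", 982: "ARG",
}
_IGF1R_KNOWN = {
    937: "ILE", 941: "PRO", 950: "GLY", 952: "VAL", 959: "HIS",
    960: "ARG", 961: "LYS", 962: "ARG",
}


@dataclass(frozen=True)
class TMDSystem:
    """Static description of a two-helix TMD system.

    Both chains share identical residue numbering.  All ranges are
    inclusive ``(first, last)`` residue-index pairs and must be
    sub-intervals of ``residue_numbering``.
    """

    receptor_name: str
    chains: Tuple[str, str] = ("A", "B")
    residue_numbering: Tuple[int, int] = (1, 1)
    core_range: Tuple[int, int] = (1, 1)
    axis_range: Tuple[int, int] = (1, 1)
    dhh_range: Tuple[int, int] = (1, 1)
    kink_residues: Tuple[int, ...] = ()
    residue_names: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.residue_numbering
        if hi < lo:
            raise ValueError("residue_numbering must be an increasing interval")
        for name in ("core_range", "axis_range", "dhh_range"):
            a, b = getattr(self, name)
            if a > b or a < lo or b > hi:
                raise ValueError(
                    f"{name}={a}-{b} is not a sub-interval of "
                    f"residue_numbering {lo}-{hi}"
                )
        if len(self.chains) != 2 or self.chains[0] == self.chains[1]:
            raise ValueError("exactly two distinct chain labels required")

    @property
    def residues(self):
        """All residue indices of one chain, N- to C-terminus."""
        import numpy as np

        return np.arange(self.residue_numbering[0], self.residue_numbering[1] + 1)

    @property
    def n_residues(self) -> int:
        return self.residue_numbering[1] - self.residue_numbering[0] + 1

    def residue_name(self, res_id: int) -> str:
        return self.residue_names.get(res_id, "UNK")

    def range_mask(self, which: str):
        """Boolean mask over one chain's residues for a named range."""
        import numpy as np

        a, b = getattr(self, which)
        res = self.residues
        return np.logical_and(res >= a, res <= b)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chains"] = list(self.chains)
        d["kink_residues"] = list(self.kink_residues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TMDSystem":
        d = dict(d)
        for key in ("chains", "residue_numbering", "core_range",
                    "axis_range", "dhh_range", "kink_residues"):
            if key in d:
                d[key] = tuple(d[key])
        if "residue_names" in d:
            d["residue_names"] = {int(k): v for k, v in d["residue_names"].items()}
        return cls(**d)


def ir_system() -> TMDSystem:
    """Insulin-receptor TMD pair (residues 940-988, kink at G960/P961)."""
    return TMDSystem(
        receptor_name="IR",
        chains=("A", "B"),
        residue_numbering=(940, 988),
        core_range=(953, 979),
        axis_range=(957, 979),
        dhh_range=(953, 979),
        kink_residues=(960, 961),
        residue_names=dict(_IR_KNOWN),
    )


def igf1r_system() -> TMDSystem:
    """IGF1R TMD pair (residues 919-967, kink at P941)."""
    return TMDSystem(
        receptor_name="IGF1R",
        chains=("A", "B"),
        residue_numbering=(919, 967),
        core_range=(937, 959),
        axis_range=(937, 959),
        dhh_range=(937, 959),
        kink_residues=(941,),
        residue_names=dict(_IGF1R_KNOWN),
    )


def get_system(name: str) -> TMDSystem:
    """Look up a built-in system by receptor name (case-insensitive)."""
    table = {"ir": ir_system, "igf1r": igf1r_system}
    try:
        return table[name.lower()]()
    except KeyError:
        raise KeyError(
            f"unknown system {name!r}; built-ins: {sorted(table)}"
        ) from None
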