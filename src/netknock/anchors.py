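"""Start/end anchor configuration for the disease network.

Start nodes are the molecular initiating events of fibrogenesis: six
growth-factor ligands and their twelve receptors. End nodes are
extracellular-matrix (ECM) proteins whose deposition is the functional
readout of fibrosis. Paths from any start to any end node represent
disease pathways a therapeutic intervention could interrupt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

# Growth-factor ligands and receptors driving hepatic stellate cell
# activation and fibrogenesis.
DEFAULT_LIGANDS = ("CCL2", "EGF", "FGF21", "LEP", "PDGFB", "TGFB1")
DEFAULT_RECEPTORS = (
    "CCR2",
    "EGFR",
    "LDLR",
    "FGFR1",
    "FGFR2",
    "FGFR3",
    "LEPR",
    "LRP2",
    "PDGFRA",
    "PDGFRB",
    "TGFBR1",
    "TGFBR2",
)
# Eleven ECM end points. Only COL1A2 is anchored in the source analysis;
# the remaining entries are a documented placeholder set of canonical
# fibrotic matrix proteins and should be overridden for real analyses.
DEFAULT_ECM = (
    "COL1A1",
    "COL1A2",
    "COL3A1",
    "COL4A1",
    "COL5A1",
    "FN1",
    "ELN",
    "LAMA1",
    "LAMB1",
    "LOX",
    "SPARC",
)
DEFAULT_PAIRS = (
    ("CCL2", "CCR2"),
    ("EGF", "EGFR"),
    ("FGF21", "FGFR1"),
    ("FGF21", "FGFR2"),
    ("FGF21", "FGFR3"),
    ("LEP", "LEPR"),
    ("PDGFB", "PDGFRA"),
    ("PDGFB", "PDGFRB"),
    ("TGFB1", "TGFBR1"),
    ("TGFB1", "TGFBR2"),
)


@dataclass(frozen=True)
class StartEndConfig:
    """Anchor nodes for path walks: ligands + receptors are starts, ECM are ends."""

    ligands: tuple[str, ...]
    receptors: tuple[str, ...]
    ecm: tuple[str, ...]
    ligand_receptor_pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        groups = (set(self.ligands), set(self.receptors), set(self.ecm))
        for name, grp, raw in zip(
            ("ligands", "receptors", "ecm"), groups, (self.ligands, self.receptors, self.ecm)
        ):
            if not grp:
                raise ValueError(f"anchor list '{name}' is empty")
            if len(grp) != len(raw):
                raise ValueError(f"anchor list '{name}' contains duplicates")
        if groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2]:
            raise ValueError("ligand/receptor/ecm anchor lists must be disjoint")
        for lig, rec in self.ligand_receptor_pairs:
            if lig not in groups[0] or rec not in groups[1]:
                raise ValueError(f"pair ({lig}, {rec}) references an unlisted anchor")

    @property
    def start_nodes(self) -> tuple[str, ...]:
        return self.ligands + self.receptors

    @property
    def end_nodes(self) -> tuple[str, ...]:
        return self.ecm

    def pairs(self) -> list[tuple[str, str]]:
        """All (start, end) combinations walked during path analysis."""
        return [(s, e) for s in self.start_nodes for e in self.end_nodes if s != e]

    def to_dict(self) -> dict:
        return {
            "ligands": list(self.ligands),
            "receptors": list(self.receptors),
            "ecm": list(self.ecm),
            "pairs": [list(p) for p in self.ligand_receptor_pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StartEndConfig":
        for key in ("ligands", "receptors", "ecm"):
            if key not in d:
                raise KeyError(f"anchor config missing required field '{key}'")
        return cls(
            ligands=tuple(d["ligands"]),
            receptors=tuple(d["receptors"]),
            ecm=tuple(d["ecm"]),
            ligand_receptor_pairs=tuple(tuple(p) for p in d.get("pairs", [])),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StartEndConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_anchor_config() -> StartEndConfig:
    """The packaged liver-fibrosis anchor set (6 ligands, 12 receptors, 11 ECM)."""
    return StartEndConfig(
        ligands=DEFAULT_LIGANDS,
        receptors=DEFAULT_RECEPTORS,
        ecm=DEFAULT_ECM,
        ligand_receptor_pairs=DEFAULT_PAIRS,
    )
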