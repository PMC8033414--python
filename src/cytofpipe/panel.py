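"""Panel specification: metal channels, marker names and channel roles.

A CyTOF panel maps mass channels (metal isotopes) to antibody targets and
structural signals (time, Gaussian acquisition parameters, DNA
intercalator, viability stain, normalization beads, palladium barcodes).
Channel names follow the ``metal_Marker`` convention used by acquisition
software, e.g. ``89Y_CD45``; a channel with no marker is named by its metal
alone, e.g. ``155Gd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

ROLES = {
    "phenotyping",
    "gating",
    "barcode",
    "bead",
    "dna",
    "viability",
    "time",
    "gaussian",
    "excluded",
}


@dataclass(frozen=True)
class Channel:
    """One mass channel.

    Parameters
    ----------
    metal:
        Isotope tag, e.g. ``"156Gd"``, or a structural name such as
        ``"Time"`` for non-mass channels.
    marker:
        Antibody target; empty string for unstained/structural channels.
    role:
        One of :data:`ROLES`.
    embed:
        Whether the marker is part of the embedding/MEM input set (the
        "phenotyping markers" used for the t-SNE map). Activation-state
        markers and CD5 are measured and corrected but kept out of the
        embedding to avoid over-representation of activated cells.
    """

    metal: str
    marker: str = ""
    role: str = "phenotyping"
    embed: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def name(self) -> str:
        return f"{self.metal}_{self.marker}" if self.marker else self.metal


@dataclass
class PanelSpec:
    """Ordered channel list plus the arcsinh cofactor.

    Invariants: channel metals are unique, there is exactly one time
    channel, and at least one DNA channel when gating is to be applied.
    """

    channels: list[Channel]
    cofactor: float = 5.0

    def __post_init__(self) -> None:
        metals = [c.metal for c in self.channels]
        if len(set(metals)) != len(metals):
            dupes = sorted({m for m in metals if metals.count(m) > 1})
            raise ValueError(f"duplicate channel metals: {dupes}")
        if sum(c.role == "time" for c in self.channels) != 1:
            raise ValueError("panel must contain exactly one time channel")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")

    # -- lookups -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    def by_name(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"channel {name!r} not in panel")

    def by_marker(self, marker: str) -> Channel:
        for c in self.channels:
            if c.marker == marker:
                return c
        raise KeyError(f"marker {marker!r} not in panel")

    def with_role(self, *roles: str) -> list[Channel]:
        return [c for c in self.channels if c.role in roles]

    @property
    def time_channel(self) -> Channel:
        return self.with_role("time")[0]

    @property
    def barcode_channels(self) -> list[str]:
        return [c.name for c in self.with_role("barcode")]

    def phenotyping_markers(self) -> list[str]:
        """All antibody markers carried through transformation/correction."""
        return [c.marker for c in self.with_role("phenotyping")]

    def embedding_markers(self) -> list[str]:
        """Markers used for the t-SNE map and MEM scores."""
        return [c.marker for c in self.channels if c.embed]

    def correction_markers(self) -> list[str]:
        """Markers to batch correct: all antibodies except the apoptosis
        stain (pre-gating only) and channels with no marker."""
        out = []
        for c in self.channels:
            if c.role in {"phenotyping", "gating"} and c.marker and c.marker != "c-Cas3":
                out.append(c.marker)
        return out

    def transform_channels(self) -> list[str]:
        """Channel names subject to arcsinh transformation: everything but
        the time channel and excluded channels."""
        return [c.name for c in self.channels if c.role not in {"time", "excluded"}]

    def rename(self, old: str, new_metal: str, new_marker: str = "", role: str | None = None) -> "PanelSpec":
        chans = []
        for c in self.channels:
            if c.name == old:
                c = replace(c, metal=new_metal, marker=new_marker, role=role or c.role, embed=False)
            chans.append(c)
        return PanelSpec(chans, self.cofactor)


# The 26 embedding/MEM markers: lineage and phenotype markers spanning the
# myeloid (CD11b, CD11c, F4/80, CD206, Ly6-G, Ly6-C, MHC-II, CD14, CD169,
# Sca-1, Siglec-F, CD64, CD24) and lymphoid (CD19, B220, CD3, TCRb, CD4,
# CD8, NK1.1, GITR, IL-7Ra, CD25) compartments plus PD-L1, ICAM-1 and CD86.
EMBED_MARKERS = (
    "Ly6-G", "CD11c", "GITR", "MHC-II", "CD4", "CD8", "CD11b", "CD19",
    "CD25", "CD64", "CD3", "CD14", "TCRb", "Ly6-C", "F4/80", "CD169",
    "Siglec-F", "CD86", "ICAM-1", "NK1.1", "B220", "IL-7Ra", "CD206",
    "Sca-1", "PD-L1", "CD24",
)


def default_panel(cofactor: float = 5.0) -> PanelSpec:
    """36-antibody immune-focused mouse panel plus structural channels.

    CD45 and c-Cas3 carry the ``gating`` role (pan-leukocyte and apoptosis
    pre-gates); activation/exhaustion markers (PD-1, CTLA-4, TIM-3, LAG-3,
    Ki-67, CD44) and CD5 are measured phenotyping channels excluded from
    the embedding input; 155Gd carries an IRF4 antibody that is dropped
    from analysis when harmonizing with cohorts that were not stained for
    it.
    """
    def ab(metal: str, marker: str, role: str = "phenotyping") -> Channel:
        return Channel(metal, marker, role, embed=marker in EMBED_MARKERS)

    chans = [
        Channel("Time", role="time"),
        Channel("Event_length", role="gaussian"),
        Channel("Center", role="gaussian"),
        Channel("Offset", role="gaussian"),
        Channel("Width", role="gaussian"),
        Channel("Residual", role="gaussian"),
        Channel("140Ce", "Bead", "bead"),
        # palladium barcoding channels (20-plex kit: 3-hot-of-6)
        Channel("102Pd", "BC1", "barcode"),
        Channel("104Pd", "BC2", "barcode"),
        Channel("105Pd", "BC3", "barcode"),
        Channel("106Pd", "BC4", "barcode"),
        Channel("108Pd", "BC5", "barcode"),
        Channel("110Pd", "BC6", "barcode"),
        ab("89Y", "CD45", "gating"),
        ab("141Pr", "Ly6-G"),
        ab("142Nd", "CD11c"),
        ab("143Nd", "GITR"),
        ab("144Nd", "MHC-II"),
        ab("145Nd", "CD4"),
        ab("146Nd", "CD8"),
        ab("147Sm", "CD5"),
        ab("148Nd", "CD11b"),
        ab("149Sm", "CD19"),
        ab("150Nd", "CD25"),
        ab("151Eu", "CD64"),
        ab("152Sm", "CD3"),
        ab("153Eu", "CD14"),
        ab("154Sm", "TCRb"),
        ab("155Gd", "IRF4"),
        ab("156Gd", "Ly6-C"),
        ab("158Gd", "F4/80"),
        ab("159Tb", "PD-1"),
        ab("160Gd", "CD169"),
        ab("161Dy", "Siglec-F"),
        ab("162Dy", "Ki-67"),
        ab("163Dy", "CD86"),
        ab("164Dy", "ICAM-1"),
        ab("165Ho", "NK1.1"),
        ab("166Er", "B220"),
        ab("167Er", "IL-7Ra"),
        ab("168Er", "CD206"),
        ab("169Tm", "Sca-1"),
        ab("170Er", "CTLA-4"),
        ab("171Yb", "CD44"),
        ab("172Yb", "c-Cas3", "gating"),
        ab("173Yb", "TIM-3"),
        ab("174Yb", "PD-L1"),
        ab("175Lu", "CD24"),
        ab("176Yb", "LAG-3"),
        Channel("191Ir", "DNA1", "dna"),
        Channel("193Ir", "DNA2", "dna"),
        Channel("195Pt", "Cisplatin", "viability"),
    ]
    return PanelSpec(chans, cofactor=cofactor)
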