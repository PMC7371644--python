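"""Channel and panel vocabulary for the rat microglia immunophenotyping assay.

Two staining panels share the scatter channels, the viability dye and the three
microglia identification markers (CD45, CD11b/c, P2y12); they differ in the
activation markers: the pro-inflammatory (M1) panel carries CD32 and CD86, the
alternative/anti-inflammatory (M2) panel carries CD200R, RT1B and CD163.
"""

from __future__ import annotations

#: Pulse channels measuring light scatter (linear scale, never compensated or
#: arcsinh-transformed).
SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

#: Amine-reactive live/dead dye channel; dead cells are dye-positive.
VIABILITY_CHANNEL = "Viability"

#: Synthetic flag channel identifying counting-bead events in generated data.
BEAD_CHANNEL = "BeadID"

#: Markers used to identify microglia (CD45+ CD11b/c+ P2y12+).
IDENTIFICATION_MARKERS = ("CD45", "CD11b/c", "P2y12")

M1_MARKERS = ("CD32", "CD86")
M2_MARKERS = ("CD200R", "RT1B", "CD163")

PANELS = {
    "M1": IDENTIFICATION_MARKERS + M1_MARKERS,
    "M2": IDENTIFICATION_MARKERS + M2_MARKERS,
}

GROUPS = ("sham", "CCI")
HEMISPHERES = ("ipsilateral", "contralateral")

#: The four experimental conditions of the 2x2 design.
CONDITIONS = tuple((g, h) for g in GROUPS for h in HEMISPHERES)


def panel_markers(panel: str) -> tuple[str, ...]:
    """Fluorescence markers of a staining panel (identification + activation)."""
    try:
        return PANELS[panel]
    except KeyError:
        raise ValueError(f"unknown panel {panel!r}; expected one of {sorted(PANELS)}")


def panel_channels(panel: str) -> tuple[str, ...]:
    """Full ordered channel list of a panel as acquired (scatter, dye, markers, bead flag)."""
    return SCATTER_CHANNELS + (VIABILITY_CHANNEL,) + panel_markers(panel) + (BEAD_CHANNEL,)


def condition_label(group: str, hemisphere: str) -> str:
    short = {"ipsilateral": "ipsi", "contralateral": "contra"}[hemisphere]
    return f"{group}-{short}"
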