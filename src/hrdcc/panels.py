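"""Antibody panel and population template definitions.

A :class:`PanelDefinition` describes the channels recorded in one cytometer
run (scatter, viability dye, surface markers, and — for the myeloid panels —
the vacant 525/50 nm detector used to pick up eosinophil autofluorescence),
together with a fluorescence spillover matrix.

A :class:`PopulationTemplate` describes one cell population as a per-channel
log-normal intensity model: a central intensity on the linear scale and a
multiplicative (log-scale) spread per channel.  Positive markers sit at least
a configurable separation factor (default >= 10x) above negative markers.

Four built-in panels mirror a bovine blood/milk immunophenotyping design:

* ``blood-5c`` — myeloid blood run: viability, CD45, CD11b, CD14, CD16
  (+ autofluorescence channel).
* ``milk-6c``  — myeloid milk run: adds pan-cytokeratin for mammary
  epithelial cells (MEC).
* ``blood-7c`` / ``milk-7c`` — lymphocyte runs: viability, CD45, CD335,
  gdTCR, CD4, CD8, CD21.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelDef",
    "PanelDefinition",
    "PopulationTemplate",
    "make_panel",
    "default_templates",
    "SCATTER_CHANNELS",
    "SEPARATION_FACTOR",
    "NEGATIVE_LEVEL",
    "POSITIVE_LEVEL",
]

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

#: linear-scale intensity of a marker-negative population (arbitrary units)
NEGATIVE_LEVEL = 60.0
#: default separation between negative and positive marker locations
SEPARATION_FACTOR = 40.0
POSITIVE_LEVEL = NEGATIVE_LEVEL * SEPARATION_FACTOR  # 2400 a.u.

#: CD11b level of the immature (CD11b-dim) neutrophil overlay; still above
#: the negative level but well below the mature positive mode.
DIM_LEVEL = 400.0

# scatter locations (linear a.u.).  Leukocyte FSC-A modes are deliberately
# broad and overlapping so the debris gate sees a single dominant cell mode;
# the three-way compartment separation is carried by SSC-A.
_FSC = {"debris": 7_000.0, "lymph": 70_000.0, "mono": 80_000.0, "gran": 90_000.0, "mec": 82_000.0}
_SSC = {"debris": 4_000.0, "lymph": 12_000.0, "mono": 45_000.0, "gran": 150_000.0, "mec": 40_000.0}

#: viability dye: live cells low, dead cells shifted >= 10x high
VIABILITY_LIVE = 60.0
VIABILITY_DEAD = 3_000.0

ROLE_CHOICES = (
    "scatter-area",
    "scatter-height",
    "side-scatter",
    "viability-dye",
    "marker",
    "autofluorescence",
)


@dataclass(frozen=True)
class ChannelDef:
    """One detector channel: name, role and (optional) marker label."""

    name: str
    role: str
    marker: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLE_CHOICES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class PanelDefinition:
    """An antibody panel: ordered channels plus a spillover matrix.

    The spillover matrix is square over the *fluorescence* channels
    (everything that is not forward/side scatter), rows = true channels,
    columns = detected channels, unit diagonal.
    """

    name: str
    channels: list[ChannelDef]
    spillover: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in panel")
        for required in SCATTER_CHANNELS:
            if required not in names:
                raise ValueError(f"panel {self.name!r} lacks required channel {required}")
        k = len(self.fluorescence_channels)
        if self.spillover is None:
            self.spillover = np.eye(k)
        self.spillover = np.asarray(self.spillover, dtype=float)
        if self.spillover.shape != (k, k):
            raise ValueError("spillover must be square over the fluorescence channels")
        if not np.allclose(np.diag(self.spillover), 1.0):
            raise ValueError("spillover diagonal must be 1.0")
        off = self.spillover[~np.eye(k, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 0.5):
            raise ValueError("off-diagonal spillover must lie in [0, 0.5]")

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def fluorescence_channels(self) -> list[str]:
        return [c.name for c in self.channels if c.role not in ("scatter-area", "scatter-height", "side-scatter")]

    @property
    def marker_channels(self) -> list[str]:
        return [c.name for c in self.channels if c.role == "marker"]


@dataclass
class PopulationTemplate:
    """Log-normal intensity model of one population on one panel.

    ``locations`` maps every panel channel to a central linear-scale
    intensity; ``spreads`` maps channels to the log-normal sigma (defaults
    apply for channels not listed).  ``immune`` distinguishes leukocyte
    populations from non-immune classes (MEC); ``viability_state`` is the
    ground-truth live/dead state of the template itself.
    """

    label: str
    parent_lineage: list[str]
    locations: dict[str, float]
    spreads: dict[str, float] = field(default_factory=dict)
    viability_state: str = "live"
    immune: bool = True
    #: optional CD11b-dim overlay: fraction of events drawn at a dim location
    overlay: dict | None = None

    DEFAULT_MARKER_SIGMA = 0.35
    DEFAULT_SCATTER_SIGMA = 0.13

    def validate(self, panel: PanelDefinition) -> None:
        missing = set(panel.channel_names) - set(self.locations) - {"FSC-H"}
        if missing:
            raise ValueError(f"template {self.label!r} lacks locations for {sorted(missing)}")
        if self.viability_state not in ("live", "dead"):
            raise ValueError("viability_state must be 'live' or 'dead'")

    def sigma(self, channel: str) -> float:
        if channel in self.spreads:
            return self.spreads[channel]
        if channel in SCATTER_CHANNELS:
            return self.DEFAULT_SCATTER_SIGMA
        return self.DEFAULT_MARKER_SIGMA


def _default_spillover(k: int, strength: float, rng_or_none=None) -> np.ndarray:
    """Banded spillover: adjacent detectors bleed ``strength`` into each other."""
    s = np.eye(k)
    for i in range(k - 1):
        s[i, i + 1] = strength
        s[i + 1, i] = strength / 2.0
    return s


_PANEL_MARKERS = {
    "blood-5c": ["CD45", "CD11b", "CD14", "CD16"],
    "milk-6c": ["CD45", "CD11b", "CD14", "CD16", "PanCK"],
    "blood-7c": ["CD45", "CD335", "gdTCR", "CD4", "CD8", "CD21"],
    "milk-7c": ["CD45", "CD335", "gdTCR", "CD4", "CD8", "CD21"],
}


def make_panel(name: str, spillover_strength: float = 0.03) -> PanelDefinition:
    """Build one of the four built-in panels.

    Parameters
    ----------
    name:
        ``"blood-5c"``, ``"milk-6c"``, ``"blood-7c"`` or ``"milk-7c"``.
    spillover_strength:
        Off-diagonal spillover between spectrally adjacent fluorescence
        detectors (fraction of the true signal detected next door).
    """
    if name not in _PANEL_MARKERS:
        raise ValueError(f"unknown panel {name!r}; choose from {sorted(_PANEL_MARKERS)}")
    channels = [
        ChannelDef("FSC-A", "scatter-area"),
        ChannelDef("FSC-H", "scatter-height"),
        ChannelDef("SSC-A", "side-scatter"),
        ChannelDef("Zombie", "viability-dye", "viability"),
    ]
    if name in ("blood-5c", "milk-6c"):
        channels.append(ChannelDef("AF-525/50", "autofluorescence"))
    channels += [ChannelDef(m, "marker", m) for m in _PANEL_MARKERS[name]]
    panel = PanelDefinition(name, channels)
    k = len(panel.fluorescence_channels)
    panel.spillover = _default_spillover(k, spillover_strength)
    return panel


def _tmpl(label, compartment, panel_markers, positive, *, dim=(), immune=True,
          overlay=None, extra=None):
    """Helper building a template from compartment scatter + marker logic."""
    loc = {
        "FSC-A": _FSC[compartment],
        "SSC-A": _SSC[compartment],
        "Zombie": VIABILITY_LIVE,
    }
    for m in panel_markers:
        loc[m] = POSITIVE_LEVEL if m in positive else (DIM_LEVEL if m in dim else NEGATIVE_LEVEL)
    if extra:
        loc.update(extra)
    lineage = {"lymph": ["lymphocytes"], "mono": ["monomac"], "gran": ["granulocytes"],
               "mec": ["cd45neg"], "debris": []}[compartment]
    return PopulationTemplate(label, lineage, loc, immune=immune, overlay=overlay)


def default_templates(panel: PanelDefinition) -> list[PopulationTemplate]:
    """Population templates for one built-in panel.

    The same ten blood (nine milk, + MEC) terminal immune populations exist
    on both the myeloid and the lymphocyte panel of a fluid; each panel only
    *resolves* the subsets its markers can see (lymphocyte subsets all look
    like generic marker-negative lymphocytes on a myeloid panel, and vice
    versa), exactly as in a multi-tube staining design.
    """
    name = panel.name
    myeloid = name in ("blood-5c", "milk-6c")
    fluid = "milk" if name.startswith("milk") else "blood"
    markers = _PANEL_MARKERS[name]
    af = {"AF-525/50": NEGATIVE_LEVEL} if myeloid else {}
    af_pos = {"AF-525/50": POSITIVE_LEVEL} if myeloid else {}

    t = []
    # granulocytes
    t.append(_tmpl("neutrophils", "gran", markers, positive={"CD45", "CD11b"},
                   extra=af, overlay={"channel": "CD11b", "fraction": 0.08, "location": DIM_LEVEL}
                   if myeloid else None))
    t.append(_tmpl("eosinophils", "gran", markers, positive={"CD45", "CD11b"}, extra=af_pos))
    # monocytes / macrophages
    if fluid == "blood":
        t.append(_tmpl("cM", "mono", markers, positive={"CD45", "CD14"}, extra=af))
        t.append(_tmpl("intM", "mono", markers, positive={"CD45", "CD14", "CD16"}, extra=af))
        t.append(_tmpl("ncM", "mono", markers, positive={"CD45", "CD16"}, extra=af))
    else:
        t.append(_tmpl("cMac", "mono", markers, positive={"CD45", "CD14"}, extra=af))
        # ncMac is CD16+ with variable CD14 (CD14+/- CD16+); split evenly
        # between the two CD14 states via a bimodal overlay on CD14.
        t.append(_tmpl("ncMac", "mono", markers, positive={"CD45", "CD16"}, extra=af,
                       overlay={"channel": "CD14", "fraction": 0.5,
                                "location": POSITIVE_LEVEL} if "CD14" in markers else None))
    # lymphocytes
    t.append(_tmpl("NK", "lymph", markers, positive={"CD45", "CD335"}, extra=af))
    t.append(_tmpl("gdT", "lymph", markers, positive={"CD45", "gdTCR"}, extra=af))
    t.append(_tmpl("CD4T", "lymph", markers, positive={"CD45", "CD4"}, extra=af))
    t.append(_tmpl("CD8T", "lymph", markers, positive={"CD45", "CD8"}, extra=af))
    t.append(_tmpl("B", "lymph", markers, positive={"CD45", "CD21"}, extra=af))
    if fluid == "milk" and myeloid:
        t.append(_tmpl("MEC", "mec", markers, positive={"PanCK"}, immune=False, extra=af))
    for tmpl in t:
        tmpl.validate(panel)
    return t


def debris_template(panel: PanelDefinition) -> PopulationTemplate:
    """Sub-cellular debris: low scatter, marker-negative."""
    markers = _PANEL_MARKERS[panel.name]
    af = {"AF-525/50": NEGATIVE_LEVEL} if "AF-525/50" in panel.channel_names else {}
    tm = _tmpl("debris", "debris", markers, positive=set(), immune=False, extra=af)
    tm.spreads = {"FSC-A": 0.30, "SSC-A": 0.30}
    tm.validate(panel)
    return tm
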