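"""The HRDCC gating hierarchies for bovine blood and milk.

Two trees per fluid mirror the two-tube staining design: the *myeloid*
panel resolves granulocyte and monocyte/macrophage subsets (plus MEC in
milk), the *lymphocyte* panel resolves NK, gd T, CD4/CD8 T and B cells.
Both share the upstream backbone debris-exclusion -> singlets -> live ->
CD45/SSC compartments.  Blood yields exactly ten terminal immune
subpopulations; milk merges the monocyte triple into cMac/ncMac and adds
mammary epithelial cells (MEC, CD45- pan-cytokeratin+) as a non-immune
class.  Immature neutrophils are an overlay (the CD11b-dim share of
neutrophils), not an eleventh terminal class.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import panels as P
from .gating import GateNode, GatingResult, GatingTree, apply_gating_tree
from .io import DEFAULT_COFACTOR, EventMatrix, compensate

__all__ = [
    "build_tree",
    "truth_thresholds",
    "blood_terminal_populations",
    "milk_terminal_populations",
    "gate_sample",
    "compute_hrdcc",
    "hrdcc_long_table",
]

MYELOID_TERMINALS = {"blood": ["neutrophils", "eosinophils", "cM", "intM", "ncM"],
                     "milk": ["neutrophils", "eosinophils", "cMac", "ncMac"]}
LYMPHO_TERMINALS = ["NK", "gdT", "CD4T", "CD8T", "B"]


def _gm(a: float, b: float) -> float:
    return math.sqrt(a * b)


def truth_thresholds() -> dict:
    """Generating-model boundaries (linear units) between population modes.

    These are the geometric midpoints between the simulator's negative and
    positive template locations — the oracle placement a perfectly informed
    gater would use.
    """
    marker = _gm(P.NEGATIVE_LEVEL, P.POSITIVE_LEVEL)
    return {
        "fsc_debris": _gm(7_000.0, 70_000.0),
        "viability": _gm(P.VIABILITY_LIVE, P.VIABILITY_DEAD),
        "marker": marker,
        "cd11b_dim": _gm(P.DIM_LEVEL, P.POSITIVE_LEVEL),
        "ssc_lymph_mono": _gm(12_000.0, 45_000.0),
        "ssc_mono_gran": _gm(45_000.0, 150_000.0),
    }


def _fixed(*values):
    return {"method": "fixed", "values": list(values)}


def _valley(fallback_quantile=0.99, floor=None):
    out = {"method": "valley", "fallback_quantile": fallback_quantile}
    if floor is not None:
        out["floor"] = floor
    return out


#: absolute fluorescence floor (linear a.u.) for positive-marker gates: a
#: fallback threshold may never sit inside the marker-negative cloud
MARKER_FLOOR = 300.0


def build_tree(fluid: str, panel: str = "myeloid", placement: str = "auto") -> GatingTree:
    """Build the HRDCC gating tree for one (fluid, panel) pair.

    ``placement="auto"`` places every threshold by valley search on the
    sample at hand; ``placement="truth"`` fixes thresholds at the
    synthetic generating boundaries (reference gating for concordance
    studies).  The structure is identical either way.
    """
    if fluid not in ("blood", "milk"):
        raise ValueError(f"unknown fluid {fluid!r}")
    if panel not in ("myeloid", "lymphocyte"):
        raise ValueError(f"unknown panel {panel!r}")
    if placement not in ("auto", "truth"):
        raise ValueError(f"unknown placement {placement!r}")
    tt = truth_thresholds()
    fx = placement == "truth"

    def thr(channel, side, auto_fq, truth_value, floor=None):
        place = _fixed(truth_value) if fx else _valley(auto_fq, floor)
        return {"kind": "threshold", "channel": channel, "side": side, "placement": place}

    nodes = [
        GateNode("all", None, {"kind": "root"}),
        GateNode("cells", "all", thr("FSC-A", "above", 0.01, tt["fsc_debris"], floor=15_000.0)),
        GateNode("debris", "all", thr("FSC-A", "below", 0.01, tt["fsc_debris"], floor=15_000.0)),
        # 6-MAD band: wide enough that true singlets of the large-scatter
        # populations are essentially never clipped, still ~150 MADs from
        # any summed-area doublet
        GateNode("singlets", "cells", {"kind": "singlet", "area": "FSC-A",
                                       "height": "FSC-H", "band_mads": 6.0}),
        GateNode("doublets", "cells", {"kind": "offband", "area": "FSC-A",
                                       "height": "FSC-H", "band_mads": 6.0}),
        GateNode("live", "singlets", thr("Zombie", "below", 0.995, tt["viability"], floor=600.0)),
        GateNode("dead", "singlets", thr("Zombie", "above", 0.995, tt["viability"], floor=600.0)),
        # leukocyte-dominated fluids may lack a CD45- mode: fall back low
        GateNode("leukocytes", "live", thr("CD45", "above", 0.005, tt["marker"], floor=MARKER_FLOOR)),
        GateNode("cd45neg", "live", thr("CD45", "below", 0.005, tt["marker"], floor=MARKER_FLOOR)),
    ]
    split_place = (_fixed(tt["ssc_lymph_mono"], tt["ssc_mono_gran"]) if fx
                   else {"method": "valley"})
    for part, label in (("low", "lymphocytes"), ("mid", "monomac"), ("high", "granulocytes")):
        nodes.append(GateNode(label, "leukocytes",
                              {"kind": "split3", "channel": "SSC-A", "part": part,
                               "placement": split_place}))

    if panel == "myeloid":
        nodes += [
            GateNode("eosinophils", "granulocytes",
                     thr("AF-525/50", "above", 0.98, tt["marker"], floor=MARKER_FLOOR), terminal_immune=True),
            GateNode("neutrophils", "granulocytes",
                     thr("AF-525/50", "below", 0.98, tt["marker"], floor=MARKER_FLOOR), terminal_immune=True),
            # immature granulocytes: CD11b-dim share of neutrophils (overlay)
            GateNode("immature_neutrophils", "neutrophils",
                     thr("CD11b", "below", 0.15, tt["cd11b_dim"])),
            GateNode("mature_neutrophils", "neutrophils",
                     thr("CD11b", "above", 0.15, tt["cd11b_dim"])),
        ]
        quad_place = ({"method": "fixed", "values": {"x": tt["marker"], "y": tt["marker"]}}
                      if fx else {"method": "valley", "floor": MARKER_FLOOR})
        quad = {"kind": "quadrant", "x": "CD14", "y": "CD16", "placement": quad_place}
        if fluid == "blood":
            nodes += [
                GateNode("cM", "monomac", {**quad, "quadrants": ["+-"]}, terminal_immune=True),
                GateNode("intM", "monomac", {**quad, "quadrants": ["++"]}, terminal_immune=True),
                GateNode("ncM", "monomac", {**quad, "quadrants": ["-+"]}, terminal_immune=True),
                GateNode("mm_dn", "monomac", {**quad, "quadrants": ["--"]}),
            ]
        else:
            nodes += [
                GateNode("cMac", "monomac", {**quad, "quadrants": ["+-"]}, terminal_immune=True),
                # ncMac is CD14+/- CD16+: union of both CD16+ quadrants
                GateNode("ncMac", "monomac", {**quad, "quadrants": ["++", "-+"]},
                         terminal_immune=True),
                GateNode("mac_dn", "monomac", {**quad, "quadrants": ["--"]}),
            ]
            nodes += [
                # MEC dominate CD45- milk events, so the fallback keeps most
                GateNode("MEC", "cd45neg", thr("PanCK", "above", 0.02, tt["marker"], floor=MARKER_FLOOR)),
                GateNode("cd45neg_other", "cd45neg", thr("PanCK", "below", 0.02, tt["marker"], floor=MARKER_FLOOR)),
            ]
    else:
        nodes += [
            GateNode("NK", "lymphocytes", thr("CD335", "above", 0.98, tt["marker"], floor=MARKER_FLOOR),
                     terminal_immune=True),
            GateNode("nk_neg", "lymphocytes", thr("CD335", "below", 0.98, tt["marker"], floor=MARKER_FLOOR)),
            GateNode("gdT", "nk_neg", thr("gdTCR", "above", 0.98, tt["marker"], floor=MARKER_FLOOR),
                     terminal_immune=True),
            GateNode("rest1", "nk_neg", thr("gdTCR", "below", 0.98, tt["marker"], floor=MARKER_FLOOR)),
        ]
        quad_place = ({"method": "fixed", "values": {"x": tt["marker"], "y": tt["marker"]}}
                      if fx else {"method": "valley", "floor": MARKER_FLOOR})
        quad = {"kind": "quadrant", "x": "CD4", "y": "CD8", "placement": quad_place}
        nodes += [
            GateNode("CD4T", "rest1", {**quad, "quadrants": ["+-"]}, terminal_immune=True),
            GateNode("CD8T", "rest1", {**quad, "quadrants": ["-+"]}, terminal_immune=True),
            GateNode("dp", "rest1", {**quad, "quadrants": ["++"]}),
            GateNode("rest2", "rest1", {**quad, "quadrants": ["--"]}),
            # B cells dominate the double-double-negative rest: fall back low
            GateNode("B", "rest2", thr("CD21", "above", 0.02, tt["marker"], floor=MARKER_FLOOR),
                     terminal_immune=True),
            GateNode("rest3", "rest2", thr("CD21", "below", 0.02, tt["marker"], floor=MARKER_FLOOR)),
        ]
    return GatingTree(f"{fluid}-{panel}-{placement}", nodes)


def blood_terminal_populations() -> list:
    """The terminal immune subpopulations of the blood HRDCC scheme (10)."""
    out = []
    for panel in ("myeloid", "lymphocyte"):
        out += build_tree("blood", panel).terminal_immune_labels()
    return out


def milk_terminal_populations() -> list:
    out = []
    for panel in ("myeloid", "lymphocyte"):
        out += build_tree("milk", panel).terminal_immune_labels()
    return out


def gate_sample(sample: EventMatrix, tree: GatingTree,
                cofactor: float = DEFAULT_COFACTOR,
                compensate_first: bool = True) -> GatingResult:
    """Compensate (when a spillover matrix is attached) and gate one sample."""
    if compensate_first and sample.spillover is not None and sample.transform_state == "linear":
        sample = compensate(sample)
    return apply_gating_tree(sample, tree, cofactor)


def _as_event_matrix(sample) -> tuple[EventMatrix, dict]:
    if isinstance(sample, EventMatrix):
        return sample, dict(sample.metadata)
    return sample.events, dict(sample.metadata)  # LabeledSample


def compute_hrdcc(samples: dict, trees: dict | None = None,
                  cofactor: float = DEFAULT_COFACTOR,
                  placement: str = "auto") -> pd.DataFrame:
    """Gate a cohort and merge panel results into per-sample HRDCC records.

    Parameters
    ----------
    samples:
        Mapping (animal, day, fluid, panel_kind) -> LabeledSample or
        EventMatrix, panel_kind in {"myeloid", "lymphocyte"}.
    trees:
        Optional mapping (fluid, panel_kind) -> GatingTree; built with
        ``placement`` when omitted.

    Returns one row per (animal, day, fluid) with viability (% of single
    cells that are live), percent-of-live and percent-of-parent for every
    terminal population, the immature-neutrophil overlay (CD11b-dim share
    of neutrophils), and MEC % of live (milk).  Lymphocyte-panel subsets
    are rescaled to the myeloid panel's live-singlet denominator through
    the shared lymphocyte-compartment percentage, so each record has a
    single denominator.  A missing panel yields an incomplete (flagged)
    record rather than an error.
    """
    if trees is None:
        trees = {}
        for fluid in ("blood", "milk"):
            for kind in ("myeloid", "lymphocyte"):
                trees[(fluid, kind)] = build_tree(fluid, kind, placement)

    by_record: dict = {}
    for (animal, day, fluid, kind), sample in samples.items():
        by_record.setdefault((animal, day, fluid), {})[kind] = sample

    rows = []
    for (animal, day, fluid), per_panel in sorted(by_record.items()):
        row: dict = {"animal": animal, "day": day, "fluid": fluid}
        meta_src = next(iter(per_panel.values()))
        _, meta = _as_event_matrix(meta_src)
        row["group"] = meta.get("group", "")
        row["phase"] = meta.get("phase", "")
        row["complete"] = set(per_panel) >= {"myeloid", "lymphocyte"}

        results = {}
        for kind, sample in per_panel.items():
            ev, _ = _as_event_matrix(sample)
            results[kind] = gate_sample(ev, trees[(fluid, kind)], cofactor)

        my = results.get("myeloid")
        ly = results.get("lymphocyte")
        live_my = my.counts["live"] if my else 0
        if my:
            singlets = my.counts["singlets"]
            row["viability"] = 100.0 * live_my / singlets if singlets else np.nan
            for pop in MYELOID_TERMINALS[fluid]:
                row[f"pct_live_{pop}"] = my.percent_of(pop, "live") if live_my else np.nan
                row[f"pct_parent_{pop}"] = my.percent_of_parent[pop]
            neut = my.counts["neutrophils"]
            row["immature_neutrophil_pct"] = (
                100.0 * my.counts["immature_neutrophils"] / neut if neut else np.nan)
            if fluid == "milk":
                row["pct_live_MEC"] = my.percent_of("MEC", "live") if live_my else np.nan
        else:
            row["viability"] = np.nan
        if ly:
            live_ly = ly.counts["live"]
            lymph_ly = ly.percent_of("lymphocytes", "live") if live_ly else np.nan
            if my and live_my and live_ly and lymph_ly:
                scale = my.percent_of("lymphocytes", "live") / lymph_ly
            else:
                scale = 1.0 if live_ly else np.nan
            for pop in LYMPHO_TERMINALS:
                pct7 = ly.percent_of(pop, "live") if live_ly else np.nan
                row[f"pct_live_{pop}"] = pct7 * scale
                row[f"pct_parent_{pop}"] = ly.percent_of_parent[pop]
        rows.append(row)
    return pd.DataFrame(rows)


def hrdcc_long_table(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy (sample x population) table in the population-table CSV schema."""
    rows = []
    for _, r in records.iterrows():
        sample_id = f"{r['animal']}_d{r['day']}_{r['fluid']}"
        for col in records.columns:
            if not col.startswith("pct_live_"):
                continue
            pop = col[len("pct_live_"):]
            rows.append({
                "sample_id": sample_id,
                "animal": r["animal"],
                "group": r.get("group", ""),
                "day": r["day"],
                "phase": r.get("phase", ""),
                "fluid": r["fluid"],
                "population": pop,
                "percent_of_parent": r.get(f"pct_parent_{pop}", np.nan),
                "percent_of_live": r[col],
                "count": np.nan,
            })
    return pd.DataFrame(rows)
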