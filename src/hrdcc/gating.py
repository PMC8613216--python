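"""Data-driven gate placement and a hierarchical gating-tree engine.

Gate placement follows the minimum-density ("valley") principle used by
template-based auto-gating frameworks: a Gaussian-kernel density estimate
(Silverman's rule bandwidth, 512-point grid) is searched for its most
prominent modes and thresholds are placed at the density minima between
them, with an empirical-quantile fallback when the expected number of modes
is not found.

Scale convention: fluorescence gates are placed on arcsinh-transformed
values (default cofactor 150); scatter gates on linear values.  Events
exactly at a threshold fall on the positive/upper side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import theilslopes

from .io import DEFAULT_COFACTOR, EventMatrix, SCATTER_NAMES

__all__ = [
    "InsufficientDataError",
    "ValleyResult",
    "kde_valley_threshold",
    "singlet_gate",
    "viability_gate",
    "cd45_ssc_partition",
    "quadrant_gate",
    "GateNode",
    "GatingTree",
    "GatingResult",
    "apply_gating_tree",
]


class InsufficientDataError(ValueError):
    """Too few events to place a data-driven gate."""


@dataclass
class ValleyResult:
    """Thresholds found by valley search, with placement provenance."""

    thresholds: list
    fallback: bool
    bandwidth: float
    n_modes_found: int

    def __iter__(self):
        return iter(self.thresholds)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1e-12)
    return 0.9 * spread * n ** (-1 / 5)


GRID_SIZE = 512
#: minimum mode prominence, as a fraction of the density maximum
REL_PROMINENCE = 0.01


def kde_valley_threshold(
    values,
    expected_modes: int = 2,
    bandwidth_rule: str = "silverman",
    fallback_quantile: float = 0.99,
) -> ValleyResult:
    """Place threshold(s) at density minima between the most prominent modes.

    A binned Gaussian-kernel density estimate is computed on a 512-point
    grid.  The ``expected_modes`` (2 or 3) most prominent modes are
    selected; each threshold is the grid minimum between two adjacent
    selected modes.  If fewer modes are found the empirical
    ``fallback_quantile`` threshold(s) are returned with the fallback flag
    set (for three expected modes: the 1/3 and 2/3 quantiles).
    """
    if expected_modes not in (2, 3):
        raise ValueError("expected_modes must be 2 or 3")
    if bandwidth_rule != "silverman":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InsufficientDataError(f"need >= 10 finite values, got {x.size}")

    bw = _silverman_bandwidth(x)
    lo, hi = x.min(), x.max()
    if hi <= lo or bw == 0:
        return _fallback(x, expected_modes, fallback_quantile, bw)
    lo -= 3 * bw
    hi += 3 * bw
    edges = np.linspace(lo, hi, GRID_SIZE + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(x, bins=edges)
    step = edges[1] - edges[0]
    density = gaussian_filter1d(counts.astype(float), sigma=max(bw / step, 0.5))
    # pad so modes at the grid edge register as peaks
    padded = np.concatenate(([0.0], density, [0.0]))
    peaks, props = find_peaks(padded, prominence=REL_PROMINENCE * padded.max())
    peaks = peaks - 1
    if peaks.size < expected_modes:
        return _fallback(x, expected_modes, fallback_quantile, bw)
    top = np.argsort(props["prominences"])[::-1][:expected_modes]
    chosen = np.sort(peaks[top])
    thresholds = []
    for a, b in zip(chosen[:-1], chosen[1:]):
        j = a + int(np.argmin(density[a : b + 1]))
        thresholds.append(float(grid[j]))
    return ValleyResult(thresholds, False, float(bw), int(peaks.size))


def _fallback(x, expected_modes, fallback_quantile, bw) -> ValleyResult:
    if expected_modes == 2:
        thr = [float(np.quantile(x, fallback_quantile))]
    else:
        thr = [float(np.quantile(x, 1 / 3)), float(np.quantile(x, 2 / 3))]
    return ValleyResult(thr, True, float(bw), 1)


def _kmeans3_1d(x: np.ndarray, max_iter: int = 100):
    """Deterministic 1-D 3-means (quantile init, Lloyd updates)."""
    centers = np.quantile(x, [0.2, 0.5, 0.8]).astype(float)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        lab = np.argmin(d, axis=1)
        new = np.array([x[lab == k].mean() if np.any(lab == k) else centers[k] for k in range(3)])
        if np.allclose(new, centers):
            break
        centers = new
    centers = np.sort(centers)
    return [float((centers[0] + centers[1]) / 2), float((centers[1] + centers[2]) / 2)]


# ---------------------------------------------------------------------------
# gate-scale helpers
# ---------------------------------------------------------------------------


def gate_scale_values(sample: EventMatrix, channel: str,
                      cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Channel values on the gating scale: arcsinh for fluorescence, linear
    for scatter.  Respects an already-transformed sample."""
    col = sample.column(channel)
    if channel in SCATTER_NAMES:
        return col
    if sample.transform_state == "linear":
        return np.arcsinh(col / cofactor)
    return col


def to_gate_scale(value: float, channel: str, cofactor: float = DEFAULT_COFACTOR) -> float:
    """Convert a linear-units threshold to the channel's gating scale."""
    if channel in SCATTER_NAMES:
        return float(value)
    return float(np.arcsinh(value / cofactor))


# ---------------------------------------------------------------------------
# gating primitives
# ---------------------------------------------------------------------------


def singlet_gate(
    sample: EventMatrix,
    area_channel: str = "FSC-A",
    height_channel: str = "FSC-H",
    band_width_mads: float = 4.0,
    mask: np.ndarray | None = None,
):
    """Keep events near the robust height-vs-area line (doublet exclusion).

    A Theil–Sen line of height on area is fitted (on a deterministic
    evenly-spaced subsample of at most 1000 events for pair-cost control);
    events whose residual lies within ± ``band_width_mads`` x MAD are kept.
    Returns ``(mask, provenance)``.
    """
    area = sample.column(area_channel)
    height = sample.column(height_channel)
    if mask is not None:
        area, height = area[mask], height[mask]
    n = area.size
    if n < 50:
        raise InsufficientDataError(f"singlet gate needs >= 50 events, got {n}")
    order = np.argsort(area, kind="stable")
    sub = order[np.linspace(0, n - 1, min(n, 1000)).astype(int)]
    slope, intercept, _, _ = theilslopes(height[sub], area[sub])
    resid = height - (slope * area + intercept)
    mad = np.median(np.abs(resid - np.median(resid)))
    band = band_width_mads * mad
    keep = np.abs(resid - np.median(resid)) <= band
    prov = {"slope": float(slope), "intercept": float(intercept),
            "mad": float(mad), "band": float(band)}
    if mask is None:
        return keep, prov
    out = np.zeros(sample.n_events, dtype=bool)
    out[np.flatnonzero(mask)] = keep
    return out, prov


def viability_gate(sample: EventMatrix, viability_channel: str = "Zombie",
                   cofactor: float = DEFAULT_COFACTOR,
                   fallback_quantile: float = 0.995):
    """Split live (dye-low) from dead (dye-high) by a 2-mode valley on the
    arcsinh-transformed viability channel.  Returns (live, dead, provenance)."""
    vals = gate_scale_values(sample, viability_channel, cofactor)
    res = kde_valley_threshold(vals, 2, fallback_quantile=fallback_quantile)
    thr = res.thresholds[0]
    dead = vals >= thr
    live = ~dead
    return live, dead, {"threshold": thr, "fallback": res.fallback}


def cd45_ssc_partition(sample: EventMatrix, cd45_channel: str = "CD45",
                       ssc_channel: str = "SSC-A",
                       cofactor: float = DEFAULT_COFACTOR,
                       cd45_fallback_quantile: float = 0.005,
                       cd45_floor: float = 300.0):
    """CD45/SSC compartment split into four masks that partition the input:
    (cd45_negative, granulocytes, monocytes/macrophages, lymphocytes).

    CD45 threshold: 2-mode valley on arcsinh CD45 (fallback: low quantile,
    because leukocyte-dominated fluids may lack a visible negative mode,
    clipped to an absolute intensity floor so an all-negative input is not
    declared positive).  CD45+ events are split on linear SSC-A by 3-mode
    valley thresholds, falling back to a deterministic 1-D 3-means split.
    """
    cd45 = gate_scale_values(sample, cd45_channel, cofactor)
    res = kde_valley_threshold(cd45, 2, fallback_quantile=cd45_fallback_quantile)
    thr = res.thresholds[0]
    if res.fallback and cd45_floor is not None:
        thr = max(thr, to_gate_scale(cd45_floor, cd45_channel, cofactor))
    pos = cd45 >= thr
    neg = ~pos
    ssc = sample.column(ssc_channel)
    ssc_pos = ssc[pos]
    prov = {"cd45_threshold": thr, "cd45_fallback": res.fallback}
    if ssc_pos.size < 10:
        empty = np.zeros_like(pos)
        prov["ssc_thresholds"] = None
        return neg, empty.copy(), empty.copy(), empty.copy(), prov
    try:
        res3 = kde_valley_threshold(ssc_pos, 3)
        if res3.fallback:
            raise InsufficientDataError("fewer than 3 SSC modes")
        t1, t2 = res3.thresholds
        prov["ssc_fallback"] = False
    except InsufficientDataError:
        t1, t2 = _kmeans3_1d(ssc_pos)
        prov["ssc_fallback"] = True
    prov["ssc_thresholds"] = (t1, t2)
    lymph = pos & (ssc < t1)
    mono = pos & (ssc >= t1) & (ssc < t2)
    gran = pos & (ssc >= t2)
    return neg, gran, mono, lymph, prov


def quadrant_gate(sample: EventMatrix, x_channel: str, y_channel: str,
                  cofactor: float = DEFAULT_COFACTOR,
                  mask: np.ndarray | None = None):
    """Independent 2-mode valley thresholds per axis; returns the four masks
    (x+y-, x+y+, x-y+, x-y-) and provenance.  Masks partition the input."""
    xv = gate_scale_values(sample, x_channel, cofactor)
    yv = gate_scale_values(sample, y_channel, cofactor)
    if mask is not None:
        sel = mask
    else:
        sel = np.ones(sample.n_events, dtype=bool)
    rx = kde_valley_threshold(xv[sel], 2)
    ry = kde_valley_threshold(yv[sel], 2)
    tx, ty = rx.thresholds[0], ry.thresholds[0]
    xp = (xv >= tx) & sel
    yp = (yv >= ty) & sel
    masks = (xp & ~yp, xp & yp, ~xp & yp & sel, ~xp & ~yp & sel)
    prov = {"x_threshold": tx, "y_threshold": ty,
            "x_fallback": rx.fallback, "y_fallback": ry.fallback}
    return masks, prov


# ---------------------------------------------------------------------------
# gating tree
# ---------------------------------------------------------------------------


@dataclass
class GateNode:
    """One node of a gating tree.

    ``gate`` is a dict with a ``kind`` key:

    * ``root``        — all events.
    * ``threshold``   — {channel, side: above|below, placement}.
    * ``singlet``     — {area, height, band_mads}; selects the band.
    * ``offband``     — complement of the sibling singlet band.
    * ``split3``      — {channel, part: low|mid|high, placement}.
    * ``quadrant``    — {x, y, quadrants: list of codes from {"+-","++","-+","--"},
                         placement}.

    ``placement`` is {"method": "valley", "fallback_quantile": q} or
    {"method": "fixed", "values": [...] in linear units} (two values for
    split3, {"x": v, "y": v} for quadrants).  Fixed values are converted to
    the gating scale (arcsinh for fluorescence channels) at evaluation.
    Siblings sharing a channel set share one threshold computation.
    """

    label: str
    parent: str | None
    gate: dict
    terminal_immune: bool = False
    partition: bool = True  # whether this node belongs to a partition of its parent

    def family_key(self):
        g = self.gate
        kind = g["kind"]
        if kind == "threshold":
            return (kind, g["channel"])
        if kind in ("singlet", "offband"):
            return ("singlet", g.get("area", "FSC-A"), g.get("height", "FSC-H"))
        if kind == "split3":
            return (kind, g["channel"])
        if kind == "quadrant":
            return (kind, g["x"], g["y"])
        return (kind, self.label)


@dataclass
class GatingTree:
    """A hierarchy of :class:`GateNode`; labels unique, single root."""

    name: str
    nodes: list

    def __post_init__(self) -> None:
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique within a tree")
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        by_label = {n.label: n for n in self.nodes}
        for n in self.nodes:
            if n.parent is not None and n.parent not in by_label:
                raise ValueError(f"node {n.label!r} has unknown parent {n.parent!r}")
        # acyclicity: walk each node to the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent is not None:
                if cur.label in seen:
                    raise ValueError("gating tree contains a cycle")
                seen.add(cur.label)
                cur = by_label[cur.parent]

    @property
    def root(self) -> GateNode:
        return next(n for n in self.nodes if n.parent is None)

    def children(self, label: str) -> list:
        return [n for n in self.nodes if n.parent == label]

    def node(self, label: str) -> GateNode:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def terminal_immune_labels(self) -> list:
        return [n.label for n in self.nodes if n.terminal_immune]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nodes": [
                {"label": n.label, "parent": n.parent, "gate": n.gate,
                 "terminal_immune": n.terminal_immune, "partition": n.partition}
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingTree":
        nodes = [GateNode(x["label"], x["parent"], x["gate"],
                          x.get("terminal_immune", False), x.get("partition", True))
                 for x in d["nodes"]]
        return cls(d["name"], nodes)


@dataclass
class GatingResult:
    """Per-node masks, counts, percent-of-parent, and placement provenance."""

    tree: GatingTree
    masks: dict
    counts: dict
    percent_of_parent: dict
    provenance: dict
    flags: dict = field(default_factory=dict)

    def count(self, label: str) -> int:
        return self.counts[label]

    def percent_of(self, label: str, ancestor: str) -> float:
        denom = self.counts[ancestor]
        return 100.0 * self.counts[label] / denom if denom else 0.0


def _resolve_thresholds(kind, gate, sample, parent_mask, cofactor, prov):
    """Compute (or take fixed) thresholds for one gate family on the parent."""
    placement = gate.get("placement", {"method": "valley"})
    method = placement.get("method", "valley")

    def _floored(thr, ch):
        floor = placement.get("floor")
        if floor is None:
            return thr
        return max(thr, to_gate_scale(floor, ch, cofactor))

    if kind == "threshold":
        ch = gate["channel"]
        if method == "fixed":
            thr = to_gate_scale(placement["values"][0], ch, cofactor)
            prov.update({"channel": ch, "threshold": thr, "fallback": False, "fixed": True})
            return (thr,)
        vals = gate_scale_values(sample, ch, cofactor)[parent_mask]
        fq = placement.get("fallback_quantile", 0.99)
        if vals.size < 10:
            prov.update({"channel": ch, "threshold": None, "insufficient": True})
            return None
        res = kde_valley_threshold(vals, 2, fallback_quantile=fq)
        thr = _floored(res.thresholds[0], ch)
        prov.update({"channel": ch, "threshold": thr, "fallback": res.fallback})
        return (thr,)
    if kind == "split3":
        ch = gate["channel"]
        if method == "fixed":
            t1, t2 = (to_gate_scale(v, ch, cofactor) for v in placement["values"])
            prov.update({"channel": ch, "thresholds": (t1, t2), "fixed": True})
            return (t1, t2)
        vals = gate_scale_values(sample, ch, cofactor)[parent_mask]
        if vals.size < 10:
            prov.update({"channel": ch, "thresholds": None, "insufficient": True})
            return None
        try:
            res = kde_valley_threshold(vals, 3)
            if res.fallback:
                raise InsufficientDataError("fewer than 3 modes")
            t1, t2 = res.thresholds
            prov.update({"channel": ch, "thresholds": (t1, t2), "fallback": False})
        except InsufficientDataError:
            t1, t2 = _kmeans3_1d(vals)
            prov.update({"channel": ch, "thresholds": (t1, t2), "fallback": True,
                         "fallback_method": "kmeans3"})
        return (t1, t2)
    if kind == "quadrant":
        xc, yc = gate["x"], gate["y"]
        if method == "fixed":
            tx = to_gate_scale(placement["values"]["x"], xc, cofactor)
            ty = to_gate_scale(placement["values"]["y"], yc, cofactor)
            prov.update({"x_threshold": tx, "y_threshold": ty, "fixed": True})
            return (tx, ty)
        xv = gate_scale_values(sample, xc, cofactor)[parent_mask]
        yv = gate_scale_values(sample, yc, cofactor)[parent_mask]
        if xv.size < 10:
            prov.update({"insufficient": True})
            return None
        fqx = placement.get("fallback_quantile_x", placement.get("fallback_quantile", 0.99))
        fqy = placement.get("fallback_quantile_y", placement.get("fallback_quantile", 0.99))
        rx = kde_valley_threshold(xv, 2, fallback_quantile=fqx)
        ry = kde_valley_threshold(yv, 2, fallback_quantile=fqy)
        tx = _floored(rx.thresholds[0], xc)
        ty = _floored(ry.thresholds[0], yc)
        prov.update({"x_threshold": tx, "y_threshold": ty,
                     "x_fallback": rx.fallback, "y_fallback": ry.fallback})
        return (tx, ty)
    raise ValueError(f"unknown gate kind {kind!r}")


def apply_gating_tree(sample: EventMatrix, tree: GatingTree,
                      cofactor: float = DEFAULT_COFACTOR) -> GatingResult:
    """Evaluate a gating tree on a sample.

    Each node's gate is placed on its parent's events only; sibling nodes
    sharing a gate family share one threshold computation, so declared
    partitions conserve counts exactly.  Children of an empty (or
    too-small) parent report zero events with a flag rather than failing.
    """
    for node in tree.nodes:
        for key in ("channel", "x", "y", "area", "height"):
            ch = node.gate.get(key)
            if ch is not None and ch not in sample.channel_names:
                raise ValueError(
                    f"node {node.label!r} references channel {ch!r} absent from sample"
                )
    n = sample.n_events
    masks: dict = {}
    counts: dict = {}
    pct: dict = {}
    provenance: dict = {}
    flags: dict = {}

    root = tree.root
    masks[root.label] = np.ones(n, dtype=bool)
    counts[root.label] = n
    pct[root.label] = 100.0

    queue = [root.label]
    while queue:
        parent_label = queue.pop(0)
        parent_mask = masks[parent_label]
        children = tree.children(parent_label)
        families: dict = {}
        for child in children:
            families.setdefault(child.family_key(), []).append(child)
        for key, members in families.items():
            kind = key[0]
            fam_prov: dict = {}
            if kind == "singlet":
                gate = members[0].gate
                try:
                    band, sp = singlet_gate(
                        sample, gate.get("area", "FSC-A"), gate.get("height", "FSC-H"),
                        gate.get("band_mads", 4.0), mask=parent_mask)
                    fam_prov.update(sp)
                except InsufficientDataError:
                    band = np.zeros(n, dtype=bool)
                    fam_prov["insufficient"] = True
                for child in members:
                    m = band if child.gate["kind"] == "singlet" else (parent_mask & ~band)
                    _record(child, m, masks, counts, pct, flags, parent_mask)
                    provenance[child.label] = fam_prov
                    queue.append(child.label)
                continue
            gate = members[0].gate
            thr = _resolve_thresholds(kind, gate, sample, parent_mask, cofactor, fam_prov)
            if thr is None:
                for child in members:
                    _record(child, np.zeros(n, dtype=bool), masks, counts, pct, flags,
                            parent_mask, flagged=True)
                    provenance[child.label] = dict(fam_prov)
                    queue.append(child.label)
                continue
            if kind == "threshold":
                ch = gate["channel"]
                vals = gate_scale_values(sample, ch, cofactor)
                above = (vals >= thr[0]) & parent_mask
                for child in members:
                    m = above if child.gate["side"] == "above" else (parent_mask & ~above)
                    _record(child, m, masks, counts, pct, flags, parent_mask)
                    provenance[child.label] = fam_prov
                    queue.append(child.label)
            elif kind == "split3":
                ch = gate["channel"]
                vals = gate_scale_values(sample, ch, cofactor)
                t1, t2 = thr
                parts = {
                    "low": parent_mask & (vals < t1),
                    "mid": parent_mask & (vals >= t1) & (vals < t2),
                    "high": parent_mask & (vals >= t2),
                }
                for child in members:
                    _record(child, parts[child.gate["part"]], masks, counts, pct, flags,
                            parent_mask)
                    provenance[child.label] = fam_prov
                    queue.append(child.label)
            elif kind == "quadrant":
                tx, ty = thr
                xv = gate_scale_values(sample, gate["x"], cofactor)
                yv = gate_scale_values(sample, gate["y"], cofactor)
                xp = xv >= tx
                yp = yv >= ty
                quad = {
                    "+-": parent_mask & xp & ~yp,
                    "++": parent_mask & xp & yp,
                    "-+": parent_mask & ~xp & yp,
                    "--": parent_mask & ~xp & ~yp,
                }
                for child in members:
                    m = np.zeros(n, dtype=bool)
                    for code in child.gate["quadrants"]:
                        m |= quad[code]
                    _record(child, m, masks, counts, pct, flags, parent_mask)
                    provenance[child.label] = fam_prov
                    queue.append(child.label)
    return GatingResult(tree, masks, counts, pct, provenance, flags)


def _record(node, mask, masks, counts, pct, flags, parent_mask, flagged=False):
    masks[node.label] = mask
    counts[node.label] = int(mask.sum())
    denom = int(parent_mask.sum())
    if denom == 0:
        pct[node.label] = 0.0
        flags[node.label] = "empty-parent"
    else:
        pct[node.label] = 100.0 * counts[node.label] / denom
        if flagged:
            flags[node.label] = "insufficient-data"
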