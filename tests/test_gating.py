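"""Valley placement, singlet/viability/compartment gates, tree engine."""

import numpy as np
import pytest

from hrdcc.io import EventMatrix
from hrdcc.gating import (
    GateNode,
    GatingTree,
    InsufficientDataError,
    apply_gating_tree,
    cd45_ssc_partition,
    kde_valley_threshold,
    quadrant_gate,
    singlet_gate,
    viability_gate,
)
from hrdcc.panels import default_templates, make_panel
from hrdcc.simulate import BLOOD_PROPORTIONS, simulate_sample
from hrdcc.trees import build_tree, gate_sample


RNG = np.random.default_rng(123)


# ---------------------------------------------------------------------------
# kde_valley_threshold
# ---------------------------------------------------------------------------


def test_valley_two_gaussians():
    """Equal N(0,1) + N(10,1) mixture: the analytic density valley is at 5."""
    x = np.r_[RNG.normal(0, 1, 5000), RNG.normal(10, 1, 5000)]
    res = kde_valley_threshold(x, 2)
    assert not res.fallback
    assert 3.0 <= res.thresholds[0] <= 7.0


def test_valley_three_modes():
    """Equal modes at 0/10/20: analytic valleys at 5 and 15."""
    x = np.r_[RNG.normal(0, 1, 4000), RNG.normal(10, 1, 4000), RNG.normal(20, 1, 4000)]
    res = kde_valley_threshold(x, 3)
    assert not res.fallback
    t1, t2 = res.thresholds
    assert 0.0 < t1 < 10.0 < t2 < 20.0
    assert 3.0 <= t1 <= 7.0 and 13.0 <= t2 <= 17.0


def test_valley_unimodal_fallback():
    x = RNG.normal(0, 1, 10_000)
    res = kde_valley_threshold(x, 2, fallback_quantile=0.99)
    assert res.fallback
    assert res.thresholds[0] == pytest.approx(np.quantile(x, 0.99))


def test_valley_unbalanced_minor_mode():
    """A 5% minor mode must still be detected."""
    x = np.r_[RNG.normal(0, 1, 19_000), RNG.normal(10, 1, 1_000)]
    res = kde_valley_threshold(x, 2)
    assert not res.fallback
    assert 3.0 <= res.thresholds[0] <= 8.0


def test_valley_insufficient_data():
    with pytest.raises(InsufficientDataError):
        kde_valley_threshold([1.0] * 5, 2)


# ---------------------------------------------------------------------------
# singlet gate
# ---------------------------------------------------------------------------


def _scatter_matrix(area, height):
    vals = np.column_stack([area, height])
    return EventMatrix(vals, ["FSC-A", "FSC-H"])


def test_singlet_gate_exact_line_keeps_all():
    area = np.linspace(1e4, 1e5, 200)
    em = _scatter_matrix(area, 0.8 * area)
    keep, prov = singlet_gate(em)
    assert keep.all()
    assert prov["slope"] == pytest.approx(0.8, rel=1e-6)


def test_singlet_gate_excludes_injected_doublet():
    area = 50_000 * np.exp(0.1 * RNG.standard_normal(10_000))
    height = 0.8 * area * np.exp(0.01 * RNG.standard_normal(10_000))
    # doublet: area doubled, height = singlet max
    area = np.r_[area, 100_000.0]
    height = np.r_[height, 0.8 * 50_000.0]
    em = _scatter_matrix(area, height)
    keep, _ = singlet_gate(em, band_width_mads=4.0)
    assert not keep[-1]
    assert keep[:-1].mean() > 0.95


def test_singlet_gate_recovery_against_ground_truth():
    """>= 95% doublet sensitivity and specificity at a 5% doublet rate."""
    pan = make_panel("blood-5c")
    s = simulate_sample(pan, default_templates(pan), BLOOD_PROPORTIONS, 20_000,
                        doublet_rate=0.05, seed=9)
    keep, _ = singlet_gate(s.events, band_width_mads=6.0)
    truth_doublet = s.labels.is_doublet.to_numpy()
    flagged = ~keep
    sensitivity = flagged[truth_doublet].mean()
    specificity = keep[~truth_doublet].mean()
    assert sensitivity >= 0.95
    assert specificity >= 0.95


def test_singlet_gate_needs_events():
    em = _scatter_matrix(np.ones(10) * 1e4, np.ones(10) * 8e3)
    with pytest.raises(InsufficientDataError):
        singlet_gate(em)


# ---------------------------------------------------------------------------
# viability gate
# ---------------------------------------------------------------------------


def test_viability_all_live():
    pan = make_panel("blood-5c")
    s = simulate_sample(pan, default_templates(pan), BLOOD_PROPORTIONS, 10_000,
                        dead_rate=0.0, seed=5)
    live, dead, _ = viability_gate(s.events)
    assert dead.mean() < 0.01
    assert (live ^ dead).all()  # partition


def test_viability_recovers_implanted_dead_fraction():
    pan = make_panel("blood-5c")
    s = simulate_sample(pan, default_templates(pan), BLOOD_PROPORTIONS, 20_000,
                        dead_rate=0.20, seed=6)
    live, dead, prov = viability_gate(s.events)
    assert not prov["fallback"]
    truth = s.labels.is_dead.to_numpy()
    assert abs(dead.mean() - truth.mean()) < 0.02
    assert not (live & dead).any()


# ---------------------------------------------------------------------------
# CD45 / SSC partition
# ---------------------------------------------------------------------------


def test_cd45_ssc_partition_recovers_compartments():
    pan = make_panel("blood-5c")
    s = simulate_sample(pan, default_templates(pan), BLOOD_PROPORTIONS, 30_000, seed=8)
    neg, gran, mono, lymph, prov = cd45_ssc_partition(s.events)
    total = s.events.n_events
    # partition property
    assert neg.sum() + gran.sum() + mono.sum() + lymph.sum() == total
    truth_gran = 0.28 + 0.04
    truth_mono = 0.06 + 0.015 + 0.015
    truth_lymph = 1 - truth_gran - truth_mono
    assert abs(gran.mean() - truth_gran) < 0.02
    assert abs(mono.mean() - truth_mono) < 0.02
    assert abs(lymph.mean() - truth_lymph) < 0.02


def test_cd45_ssc_partition_all_negative():
    rng = np.random.default_rng(1)
    n = 5000
    vals = np.column_stack([
        60 * np.exp(0.35 * rng.standard_normal(n)),   # CD45 negative
        30_000 * np.exp(0.2 * rng.standard_normal(n)),  # SSC
    ])
    em = EventMatrix(vals, ["CD45", "SSC-A"])
    neg, gran, mono, lymph, _ = cd45_ssc_partition(em)
    assert neg.all()
    assert not (gran.any() or mono.any() or lymph.any())


# ---------------------------------------------------------------------------
# quadrant gate
# ---------------------------------------------------------------------------


def test_quadrant_gate_recovers_proportions():
    rng = np.random.default_rng(2)
    n = 20_000
    counts = rng.multinomial(n, [0.5, 0.2, 0.2, 0.1])
    lo, hi = 60.0, 2400.0
    blocks = []
    for (cx, cy), c in zip([(hi, lo), (hi, hi), (lo, hi), (lo, lo)], counts):
        blocks.append(np.column_stack([
            cx * np.exp(0.35 * rng.standard_normal(c)),
            cy * np.exp(0.35 * rng.standard_normal(c)),
        ]))
    vals = np.vstack(blocks)
    em = EventMatrix(vals, ["CD14", "CD16"])
    masks, prov = quadrant_gate(em, "CD14", "CD16")
    fracs = [m.mean() for m in masks]
    for f, target in zip(fracs, [0.5, 0.2, 0.2, 0.1]):
        assert abs(f - target) < 0.02
    assert sum(m.sum() for m in masks) == n  # conservation


def test_quadrant_gate_all_double_negative_conserves():
    rng = np.random.default_rng(3)
    vals = 60 * np.exp(0.35 * rng.standard_normal((3000, 2)))
    em = EventMatrix(vals, ["CD14", "CD16"])
    masks, _ = quadrant_gate(em, "CD14", "CD16")
    assert sum(m.sum() for m in masks) == 3000


# ---------------------------------------------------------------------------
# gating tree engine
# ---------------------------------------------------------------------------


def test_tree_pass_through_root(small_matrix):
    tree = GatingTree("t", [GateNode("all", None, {"kind": "root"})])
    res = apply_gating_tree(small_matrix, tree)
    assert res.percent_of_parent["all"] == 100.0
    assert res.counts["all"] == small_matrix.n_events


def test_tree_partition_conservation(blood_sample):
    tree = build_tree("blood", "myeloid", "auto")
    res = gate_sample(blood_sample.events, tree)
    c = res.counts
    assert c["cells"] + c["debris"] == c["all"]
    assert c["singlets"] + c["doublets"] == c["cells"]
    assert c["live"] + c["dead"] == c["singlets"]
    assert c["leukocytes"] + c["cd45neg"] == c["live"]
    assert c["granulocytes"] + c["monomac"] + c["lymphocytes"] == c["leukocytes"]
    assert c["eosinophils"] + c["neutrophils"] == c["granulocytes"]
    assert c["cM"] + c["intM"] + c["ncM"] + c["mm_dn"] == c["monomac"]


def test_tree_determinism(blood_sample):
    tree = build_tree("blood", "myeloid", "auto")
    r1 = gate_sample(blood_sample.events, tree)
    r2 = gate_sample(blood_sample.events, tree)
    assert r1.counts == r2.counts
    for k in r1.masks:
        np.testing.assert_array_equal(r1.masks[k], r2.masks[k])


def test_truth_tree_per_event_accuracy(blood_sample):
    """Thresholds fixed at the generating boundaries classify >= 99.9% of
    live singlet immune events into their true population."""
    tree = build_tree("blood", "myeloid", "truth")
    res = gate_sample(blood_sample.events, tree)
    lab = blood_sample.labels
    clean = (~lab.is_doublet & ~lab.is_dead & ~lab.is_debris).to_numpy()
    myeloid = {"neutrophils", "eosinophils", "cM", "intM", "ncM"}
    correct = np.zeros(len(lab), dtype=bool)
    for pop in myeloid:
        correct |= (lab.population == pop).to_numpy() & res.masks[pop]
    # lymphocyte-panel subsets resolve only to the lymphocyte compartment here
    lymph_pops = {"NK", "gdT", "CD4T", "CD8T", "B"}
    correct |= lab.population.isin(lymph_pops).to_numpy() & res.masks["lymphocytes"]
    acc = correct[clean].mean()
    assert acc >= 0.999


def test_auto_thresholds_between_generating_means(blood_sample):
    """Oracle equivalence: every auto-placed 1-D fluorescence threshold
    falls between the generating component locations."""
    tree = build_tree("blood", "myeloid", "auto")
    res = gate_sample(blood_sample.events, tree)
    lo, hi = np.arcsinh(60 / 150), np.arcsinh(2400 / 150)
    for label in ("leukocytes", "eosinophils"):
        thr = res.provenance[label]["threshold"]
        assert lo < thr < hi
    zlo, zhi = np.arcsinh(60 / 150), np.arcsinh(3000 / 150)
    assert zlo < res.provenance["live"]["threshold"] < zhi


def test_tree_debris_robustness(blood_myeloid_panel, blood_myeloid_templates):
    """Adding pure sub-scatter debris changes downstream percentages by no
    more than the debris gate's leakage."""
    base = simulate_sample(blood_myeloid_panel, blood_myeloid_templates,
                           BLOOD_PROPORTIONS, 15_000, debris_rate=0.0, seed=21)
    heavy = simulate_sample(blood_myeloid_panel, blood_myeloid_templates,
                            BLOOD_PROPORTIONS, 15_000, debris_rate=0.25, seed=21)
    tree = build_tree("blood", "myeloid", "auto")
    r0 = gate_sample(base.events, tree)
    r1 = gate_sample(heavy.events, tree)
    for pop in ("neutrophils", "cM", "lymphocytes"):
        p0 = r0.percent_of(pop, "live")
        p1 = r1.percent_of(pop, "live")
        assert abs(p0 - p1) < 1.5  # percentage points


def test_tree_unresolved_channel_errors(small_matrix):
    tree = GatingTree("t", [
        GateNode("all", None, {"kind": "root"}),
        GateNode("x", "all", {"kind": "threshold", "channel": "NOPE", "side": "above",
                              "placement": {"method": "valley"}}),
    ])
    with pytest.raises(ValueError, match="NOPE"):
        apply_gating_tree(small_matrix, tree)


def test_tree_empty_parent_flagged():
    rng = np.random.default_rng(4)
    vals = np.column_stack([rng.uniform(100, 200, 50), rng.uniform(100, 200, 50)])
    em = EventMatrix(vals, ["FSC-A", "CD45"])
    tree = GatingTree("t", [
        GateNode("all", None, {"kind": "root"}),
        GateNode("high", "all", {"kind": "threshold", "channel": "FSC-A", "side": "above",
                                 "placement": {"method": "fixed", "values": [1e9]}}),
        GateNode("child", "high", {"kind": "threshold", "channel": "CD45", "side": "above",
                                   "placement": {"method": "valley"}}),
    ])
    res = apply_gating_tree(em, tree)
    assert res.counts["high"] == 0
    assert res.counts["child"] == 0
    assert res.percent_of_parent["child"] == 0.0
    assert res.flags["child"] == "empty-parent"


def test_tree_serialization_round_trip():
    tree = build_tree("milk", "myeloid", "auto")
    d = tree.to_dict()
    back = GatingTree.from_dict(d)
    assert back.to_dict() == d
    assert back.terminal_immune_labels() == tree.terminal_immune_labels()
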