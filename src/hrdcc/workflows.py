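"""End-to-end study workflows shared by the test suite, the CLI and the
reproduction script.

Three desk-scale experiments, each built entirely from the package's own
simulator and pipeline:

* :func:`gating_concordance_experiment` — the automated-vs-reference gating
  agreement study: gate every sample of a full three-group cohort once with
  auto-placed valley thresholds and once with thresholds fixed at the
  generating boundaries, and pool all per-sample per-population
  percentages into one paired concordance analysis.
* :func:`late_phase_discrimination_experiment` — the supervised phase
  discrimination study: one group with strong implanted late-phase shifts,
  leave-one-out sparse PLS-DA (3 components, keepX = 5), one-vs-rest AUROC.
* :func:`friedman_power_experiment` — repeated-seed power of the Friedman
  test for the within-animal post-vaccination intermediate-monocyte shift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import bland_altman, friedman_test, linreg_concordance
from .multivar import auroc_one_vs_rest, build_feature_table, splsda_fit
from .simulate import CohortDesign, EffectSpec, GroupDesign, default_cohort_design, iter_cohort_samples
from .trees import LYMPHO_TERMINALS, MYELOID_TERMINALS, build_tree, compute_hrdcc

__all__ = [
    "gating_concordance_experiment",
    "late_phase_discrimination_experiment",
    "friedman_power_experiment",
    "group_c_design",
    "group_a_design",
]


def _stream_records(design, effects, seed, n_events, trees, panels=("myeloid", "lymphocyte"),
                    fluids=None, spillover_strength=0.03):
    """Gate a cohort sample-by-sample (constant memory) into HRDCC records.

    ``trees`` maps a run name to a {(fluid, kind): GatingTree} dict; one
    record table per run is returned, all runs gating the same events.
    """
    buffers: dict = {}
    records: dict = {name: [] for name in trees}
    current_key = None
    for key, samp in iter_cohort_samples(design, effects, seed, n_events, panels,
                                         spillover_strength):
        animal, day, fluid, kind = key
        rec_key = (animal, day, fluid)
        if current_key is not None and rec_key != current_key:
            _flush(buffers, current_key, trees, records)
            buffers = {}
        current_key = rec_key
        buffers[kind] = samp
    if buffers:
        _flush(buffers, current_key, trees, records)
    return {name: pd.concat(frames, ignore_index=True) for name, frames in records.items()}


def _flush(buffers, rec_key, trees, records):
    animal, day, fluid = rec_key
    samples = {(animal, day, fluid, kind): s for kind, s in buffers.items()}
    for name, tree_map in trees.items():
        records[name].append(compute_hrdcc(samples, tree_map))


def _tree_map(placement: str) -> dict:
    return {(fluid, kind): build_tree(fluid, kind, placement)
            for fluid in ("blood", "milk") for kind in ("myeloid", "lymphocyte")}


def gating_concordance_experiment(seed: int = 0, n_events: int = 50_000,
                                  n_animals: int = 5) -> dict:
    """Automated vs reference gating over a full synthetic cohort.

    Simulates the default three-group design (``n_animals`` per group, six
    sampling days, both fluids, both panels, ``n_events`` per acquisition),
    gates every sample with auto-placed and with generating-boundary
    thresholds, pools every per-sample per-population percentage
    (percent-of-live and percent-of-parent) as paired vectors, and runs the
    linear-regression and Bland–Altman concordance analyses.
    """
    design = default_cohort_design(n_animals)
    runs = _stream_records(design, (), seed, n_events,
                           {"auto": _tree_map("auto"), "truth": _tree_map("truth")})
    auto, truth = runs["auto"], runs["truth"]
    keys = ["animal", "day", "fluid"]
    merged = auto.merge(truth, on=keys, suffixes=("_auto", "_truth"))
    xs, ys = [], []
    for _, row in merged.iterrows():
        pops = MYELOID_TERMINALS[row["fluid"]] + LYMPHO_TERMINALS
        for pop in pops:
            for kind in ("pct_live", "pct_parent"):
                a = row.get(f"{kind}_{pop}_auto")
                t = row.get(f"{kind}_{pop}_truth")
                if a is not None and t is not None and np.isfinite(a) and np.isfinite(t):
                    xs.append(a)
                    ys.append(t)
    conc = linreg_concordance(xs, ys)
    ba = bland_altman(xs, ys)
    return {"concordance": conc, "bland_altman": ba, "r": conc.r, "n_pairs": conc.n,
            "records_auto": auto, "records_truth": truth}


def group_c_design(n_animals: int = 4, days_per_phase: int = 3) -> CohortDesign:
    """Single-vaccination group with pre/post/late phases, blood only."""
    phase_days = {}
    day_sets = {"pre": (-7, -5, -3), "post": (2, 4, 6), "late": (14, 16, 18)}
    for phase, days in day_sets.items():
        for d in days[:days_per_phase]:
            phase_days[d] = phase
    g = GroupDesign("C", n_animals, (0,), phase_days)
    return CohortDesign([g], fluids=("blood",))


LATE_EFFECTS = (
    EffectSpec("intM", "C", ("late",), 2.5),
    EffectSpec("CD8T", "C", ("late",), 2.5),
    EffectSpec("eosinophils", "C", ("late",), 2.5),
)


def late_phase_discrimination_experiment(seed: int = 0, n_events: int = 12_000,
                                         n_animals: int = 4,
                                         effects=LATE_EFFECTS) -> dict:
    """Leave-one-out sPLS-DA discrimination of the late treatment phase.

    A single-group pre/post/late cohort carries 2.5-fold implanted late-
    phase shifts in intermediate monocytes, CD8 T cells and eosinophils;
    HRDCC blood features are modeled with sparse PLS-DA (3 components,
    keepX = 5) and scored one-vs-rest under leave-one-out.
    """
    design = group_c_design(n_animals)
    runs = _stream_records(design, effects, seed, n_events, {"auto": _tree_map("auto")})
    records = runs["auto"]
    table = build_feature_table(records, feature_set="blood")
    feats = [c for c in table.columns if c not in ("animal", "group", "day", "phase")]
    x = table[feats].to_numpy(dtype=float)
    y = table["phase"].to_numpy()
    model = splsda_fit(x, y, n_components=3, keep_x=(5, 5, 5))
    roc = auroc_one_vs_rest(model, x, y, loo=True)
    return {"auroc": roc.auroc, "late_auroc": roc.auroc["late"], "model": model,
            "feature_names": feats, "table": table, "n_samples": len(table)}


def group_a_design(n_animals: int = 4) -> CohortDesign:
    """Two-vaccination group, four cows, blood only (intM time course)."""
    g = GroupDesign("A", n_animals, (0, 14),
                    {-7: "pre1", 2: "post1", 3: "post1", 10: "pre2", 16: "post2", 17: "post2"})
    return CohortDesign([g], fluids=("blood",))


def friedman_power_experiment(n_seeds: int = 50, seed: int = 0,
                              effect_size: float = 2.5, decay: float = 0.7,
                              n_events: int = 6_000) -> dict:
    """Power of the Friedman test for the post-vaccination intM shift.

    For each of ``n_seeds`` cohort replicates (four group-A cows, six
    sampling days, myeloid blood panel only) with an implanted intM
    increase on post-vaccination days (attenuated after the second
    vaccination), the auto-gated intM percent-of-live series is tested
    across days with animals as blocks.  Returns the fraction of replicates
    significant at alpha = 0.05 with a post > pre group-level direction.
    """
    design = group_a_design()
    effects = (EffectSpec("intM", "A", ("post1", "post2"), effect_size, decay),)
    tree = {("blood", "myeloid"): build_tree("blood", "myeloid", "auto")}
    root = np.random.SeedSequence(seed)
    hits = 0
    pvals = []
    for child in root.spawn(n_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        runs = _stream_records(design, effects, sub_seed, n_events, {"auto": tree},
                               panels=("myeloid",))
        rec = runs["auto"]
        wide = rec.pivot(index="animal", columns="day", values="pct_live_intM")
        wide = wide.sort_index(axis=1)
        res = friedman_test(wide.to_numpy())
        post_days = [d for d, p in design.groups[0].phase_of_day.items() if p.startswith("post")]
        pre_days = [d for d, p in design.groups[0].phase_of_day.items() if p.startswith("pre")]
        direction = wide[post_days].mean(axis=1).mean() > wide[pre_days].mean(axis=1).mean()
        pvals.append(res.p)
        if res.p < 0.05 and direction:
            hits += 1
    return {"power": hits / n_seeds, "n_seeds": n_seeds, "pvals": pvals}
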