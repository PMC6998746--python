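"""Simulated technical-validation studies for the CNV flagging assay.

Assembles the three study designs used to qualify the assay on synthetic
coverage: (1) a sensitivity study spiking the 18 known positive
specimens, replicated as in the validation cohort, into otherwise-null
batches for 42 positive trials; (2) a specificity study of 457
CNV-negative trials; (3) an inter-assay precision study of 94 specimens
(9 event carriers) drawn three times each with fresh noise.  All three
score against one model trained on a simulated null cohort at the
standard operating point (mean depth 380x, batches of 92).
"""

from __future__ import annotations

import numpy as np

from .metrics import (
    classify_calls,
    inter_assay_precision,
    sensitivity,
    trial_specificity,
)
from .model import CnvModelResults, ReadDepthCnvModel
from .panel import Panel
from .simulate import (
    CnvEvent,
    SimulationConfig,
    simulate_depth,
    simulate_trial_cohort,
    table3_fixture,
    table3_trial_plan,
)

__all__ = [
    "train_null_model",
    "sensitivity_study",
    "specificity_study",
    "precision_study",
]


def train_null_model(
    panel: Panel,
    seed: int,
    n_training: int = 300,
    training_batch: int = 75,
    mean_depth: float = 380.0,
    target_specificity: float = 0.98,
    n_components: int = 5,
) -> CnvModelResults:
    """Fit the flagging model on a simulated CNV-free training cohort."""
    cfg = SimulationConfig(
        n_specimens=n_training, batch_size=training_batch, mean_depth=mean_depth,
        seed=seed,
    )
    depth, _ = simulate_depth(cfg, panel)
    return ReadDepthCnvModel(
        depth, panel, n_components=n_components,
        target_specificity=target_specificity,
    ).fit(meta={"seed": seed, "n_training": n_training})


def sensitivity_study(
    results: CnvModelResults,
    panel: Panel,
    seed: int,
    n_batches: int = 5,
    batch_size: int = 92,
    mean_depth: float = 380.0,
) -> dict:
    """Spike the 18 positive specimens (42 trials) into null batches; call.

    Returns detection counts overall and split by event size (single-exon
    events are the hard class for targeted read-depth assays).
    """
    events = table3_fixture()
    plan = table3_trial_plan(events, n_batches=n_batches, batch_size=batch_size,
                             seed=seed)
    cfg = SimulationConfig(batch_size=batch_size, mean_depth=mean_depth,
                           seed=seed + 1_000_000)
    depth, truth = simulate_trial_cohort(panel, cfg, plan)
    callset = results.call(depth)
    trial_ids = [t for t, _ in plan]
    table = classify_calls(callset.calls, truth, trial_ids)
    pos = table[table["n_truth"] > 0]
    detected = int((pos["n_detected"] == pos["n_truth"]).sum())
    single_exon_ids = {
        f"{e.specimen_id}_r{r}"
        for e in events if e.is_single_exon
        for r in range(1, e.replications + 1)
    }
    missed = [t for t in pos.index if pos.loc[t, "n_detected"] < pos.loc[t, "n_truth"]]
    missed_multi = [t for t in missed if t not in single_exon_ids]
    return {
        "n_positive_trials": int(len(pos)),
        "detected_positive_trials": detected,
        "sensitivity": detected / len(pos),
        "missed_trials": missed,
        "missed_multi_exon_trials": missed_multi,
        "fp_trials": int((table["n_fp_calls"] > 0).sum()),
        "n_trials": len(trial_ids),
    }


def specificity_study(
    results: CnvModelResults,
    panel: Panel,
    seed: int,
    n_trials: int = 457,
    batch_size: int = 92,
    mean_depth: float = 380.0,
) -> dict:
    """Score CNV-negative trials only; specificity = clean trials / trials."""
    trials = [(f"null{i + 1:04d}", None) for i in range(n_trials)]
    cfg = SimulationConfig(batch_size=batch_size, mean_depth=mean_depth,
                           seed=seed + 2_000_000)
    depth, truth = simulate_trial_cohort(panel, cfg, trials)
    callset = results.call(depth)
    trial_ids = [t for t, _ in trials]
    spec = trial_specificity(callset.calls, truth, trial_ids)
    return {
        "n_trials": n_trials,
        "fp_trials": int(round((1.0 - spec) * n_trials)),
        "specificity": spec,
    }


def precision_study(
    results: CnvModelResults,
    panel: Panel,
    seed: int,
    n_specimens: int = 94,
    n_positive: int = 9,
    n_replicates: int = 3,
    mean_depth: float = 380.0,
) -> dict:
    """Replicate-concordance study: each specimen drawn independently
    ``n_replicates`` times; the event carriers are the first ``n_positive``
    specimens of the positive fixture."""
    events = table3_fixture()[:n_positive]
    spec_ids = [f"P{i + 1:03d}" for i in range(n_specimens)]
    assignment: dict[str, CnvEvent | None] = {s: None for s in spec_ids}
    for s, e in zip(spec_ids, events):
        assignment[s] = e
    replicate_calls: dict[str, list] = {s: [] for s in spec_ids}
    for r in range(n_replicates):
        cfg = SimulationConfig(
            batch_size=n_specimens, mean_depth=mean_depth,
            seed=seed + 3_000_000 + 1000 * r,
        )
        trials = [(s, assignment[s]) for s in spec_ids]
        depth, _ = simulate_trial_cohort(panel, cfg, trials)
        callset = results.call(depth)
        for s in spec_ids:
            replicate_calls[s].append(callset.calls_for(s))
    precision = inter_assay_precision(replicate_calls)
    discordant = [
        s for s in spec_ids
        if not all(
            _concordant(replicate_calls[s][0], rep) for rep in replicate_calls[s][1:]
        )
    ]
    return {
        "n_specimens": n_specimens,
        "n_positive": n_positive,
        "n_replicates": n_replicates,
        "concordant_specimens": n_specimens - len(discordant),
        "discordant_specimens": discordant,
        "precision": precision,
    }


def _concordant(a, b):
    from .metrics import _call_sets_concordant

    return _call_sets_concordant(a, b)
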