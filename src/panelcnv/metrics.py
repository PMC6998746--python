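"""Validation metrics: sensitivity, trial-level specificity, precision.

Conventions follow clinical panel validation practice: a *trial* is one
sequencing run of one specimen.  A truth event counts as detected in a
trial when a call of the correct type in the correct gene overlaps at
least one of the event's assayable bins.  A false-positive trial is any
trial containing at least one call that matches no truth event.
Specificity is tallied per trial (not per target); inter-assay precision
is the fraction of replicated specimens whose replicate call sets are
fully concordant.  Flagged calls can carry an orthogonal confirmation
status (aCGH reflex); refuted calls are not reported, which is what the
confirmation-adjusted specificity quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass



import pandas as pd

from .score import CnvCall

__all__ = [
    "ValidationResult",
    "truth_events_by_trial",
    "sensitivity",
    "trial_specificity",
    "classify_calls",
    "inter_assay_precision",
    "intra_assay_precision",
    "confirmation_adjusted_specificity",
    "summarize_cohort",
    "format_rate",
]


def format_rate(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Display a rate the way validation reports print it, e.g. '98.0%'."""
    if denominator == 0:
        return "undefined"
    return f"{100.0 * numerator / denominator:.{decimals}f}%"


@dataclass
class ValidationResult:
    """Confusion-count summary of a validation run.

    Constructable directly from printed confusion counts, or via
    :func:`evaluate_trials`.  Rates are plain fractions in [0, 1];
    ``summary()`` prints them with the conventional rounding.
    """

    n_trials: int
    n_positive_trials: int
    detected_positive_trials: int
    false_positive_trials: int
    n_replicated_specimens: int = 0
    discordant_specimens: int = 0
    refuted_fp_trials: int = 0

    def __post_init__(self) -> None:
        if self.detected_positive_trials > self.n_positive_trials:
            raise ValueError("detected cannot exceed positive trials")
        if self.false_positive_trials > self.n_trials:
            raise ValueError("false-positive trials cannot exceed total trials")

    @property
    def sensitivity(self) -> float | None:
        if self.n_positive_trials == 0:
            return None
        return self.detected_positive_trials / self.n_positive_trials

    @property
    def specificity(self) -> float:
        return (self.n_trials - self.false_positive_trials) / self.n_trials

    @property
    def post_confirmation_specificity(self) -> float:
        remaining = self.false_positive_trials - self.refuted_fp_trials
        return (self.n_trials - remaining) / self.n_trials

    @property
    def inter_assay_precision(self) -> float | None:
        if self.n_replicated_specimens == 0:
            return None
        return (
            self.n_replicated_specimens - self.discordant_specimens
        ) / self.n_replicated_specimens

    def summary(self) -> str:
        lines = [
            "CNV validation summary",
            "----------------------",
            f"trials: {self.n_trials} ({self.n_positive_trials} positive)",
        ]
        if self.sensitivity is not None:
            lines.append(
                "sensitivity: "
                + format_rate(self.detected_positive_trials, self.n_positive_trials)
                + f" ({self.detected_positive_trials}/{self.n_positive_trials})"
            )
        else:
            lines.append("sensitivity: undefined (no positive trials)")
        ok = self.n_trials - self.false_positive_trials
        lines.append(f"specificity: {format_rate(ok, self.n_trials)} ({ok}/{self.n_trials})")
        if self.refuted_fp_trials:
            ok2 = self.n_trials - self.false_positive_trials + self.refuted_fp_trials
            lines.append(
                "post-confirmation specificity: "
                + format_rate(ok2, self.n_trials)
                + f" ({ok2}/{self.n_trials})"
            )
        if self.n_replicated_specimens:
            conc = self.n_replicated_specimens - self.discordant_specimens
            lines.append(
                "inter-assay precision: "
                + format_rate(conc, self.n_replicated_specimens)
                + f" ({conc}/{self.n_replicated_specimens})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "n_trials": self.n_trials,
            "n_positive_trials": self.n_positive_trials,
            "detected_positive_trials": self.detected_positive_trials,
            "false_positive_trials": self.false_positive_trials,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "post_confirmation_specificity": self.post_confirmation_specificity,
        }
        if self.n_replicated_specimens:
            d["n_replicated_specimens"] = self.n_replicated_specimens
            d["discordant_specimens"] = self.discordant_specimens
            d["inter_assay_precision"] = self.inter_assay_precision
        return d


# ---------------------------------------------------------------------------
# call/truth matching
# ---------------------------------------------------------------------------

def truth_events_by_trial(truth: pd.DataFrame) -> dict[str, list[dict]]:
    """Index a truth table (one row per event) by trial/specimen id."""
    out: dict[str, list[dict]] = {}
    for _, row in truth.iterrows():
        ev = {
            "gene": row["gene"],
            "cnv_type": row["cnv_type"],
            "bins": set(str(row["bins"]).split(",")) if row["bins"] else set(),
        }
        out.setdefault(str(row["specimen_id"]), []).append(ev)
    return out


def _call_matches(call: CnvCall, event: dict) -> bool:
    return (
        call.gene == event["gene"]
        and call.cnv_type == event["cnv_type"]
        and bool(event["bins"].intersection(call.bins))
    )


def classify_calls(
    calls: list[CnvCall], truth: pd.DataFrame, trial_ids: list[str]
) -> pd.DataFrame:
    """Per-trial confusion bookkeeping.

    Returns one row per trial: number of truth events, events detected,
    and calls matching no truth event (false positives).  The matching
    rule is gene + type + >= 1 overlapping assayable bin.
    """
    by_trial = truth_events_by_trial(truth)
    calls_by_trial: dict[str, list[CnvCall]] = {}
    for c in calls:
        calls_by_trial.setdefault(c.specimen_id, []).append(c)
    rows = []
    for tid in trial_ids:
        events = by_trial.get(tid, [])
        tcalls = calls_by_trial.get(tid, [])
        detected = sum(
            1 for ev in events if any(_call_matches(c, ev) for c in tcalls)
        )
        fp = sum(1 for c in tcalls if not any(_call_matches(c, ev) for ev in events))
        rows.append(
            {
                "trial_id": tid,
                "n_truth": len(events),
                "n_detected": detected,
                "n_fp_calls": fp,
            }
        )
    return pd.DataFrame(rows).set_index("trial_id")


def sensitivity(
    calls: list[CnvCall], truth: pd.DataFrame, trial_ids: list[str] | None = None
) -> float | None:
    """Detected positive trials / positive trials (None if no positives).

    A positive trial counts as detected only when every truth event in it
    is detected; wrong-type overlaps do not count.
    """
    if trial_ids is None:
        trial_ids = sorted(set(truth["specimen_id"].astype(str)))
    table = classify_calls(calls, truth, trial_ids)
    pos = table[table["n_truth"] > 0]
    if len(pos) == 0:
        return None
    return float((pos["n_detected"] == pos["n_truth"]).mean())


def trial_specificity(
    calls: list[CnvCall], truth: pd.DataFrame, trial_ids: list[str]
) -> float:
    """(trials - false-positive trials) / trials, per the trial convention."""
    table = classify_calls(calls, truth, trial_ids)
    fp_trials = int((table["n_fp_calls"] > 0).sum())
    return (len(trial_ids) - fp_trials) / len(trial_ids)


def confirmation_adjusted_specificity(
    calls: list[CnvCall], truth: pd.DataFrame, trial_ids: list[str]
) -> float:
    """Specificity after orthogonal confirmation: refuted calls drop out.

    Every call must have been adjudicated (confirmed or refuted); a call
    still pending confirmation raises, mirroring the reflex workflow in
    which nothing is reported before confirmation resolves.
    """
    for c in calls:
        if c.status == "flagged_pending_confirmation":
            raise ValueError(
                f"call {c.specimen_id}/{c.gene} is pending confirmation; adjudicate first"
            )
    kept = [c for c in calls if c.status != "refuted"]
    return trial_specificity(kept, truth, trial_ids)


def _call_sets_concordant(a: list[CnvCall], b: list[CnvCall]) -> bool:
    """Identical call sets under gene + type + span-overlap matching."""
    if len(a) != len(b):
        return False
    unmatched = list(b)
    for ca in a:
        hit = None
        for cb in unmatched:
            if (
                ca.gene == cb.gene
                and ca.cnv_type == cb.cnv_type
                and set(ca.bins).intersection(cb.bins)
            ):
                hit = cb
                break
        if hit is None:
            return False
        unmatched.remove(hit)
    return True


def inter_assay_precision(replicate_calls: dict[str, list[list[CnvCall]]]) -> float:
    """Fraction of specimens whose replicate call sets are all concordant.

    ``replicate_calls`` maps specimen -> list of per-replicate call lists
    (empty lists are concordant negatives).  Specimens with < 2 replicates
    are ignored.
    """
    n = 0
    concordant = 0
    for specimen, reps in replicate_calls.items():
        if len(reps) < 2:
            continue
        n += 1
        if all(_call_sets_concordant(reps[0], r) for r in reps[1:]):
            concordant += 1
    if n == 0:
        raise ValueError("no specimens with >= 2 replicates")
    return concordant / n


#: Intra-assay precision is the same concordance computation restricted to
#: within-run replicates.
intra_assay_precision = inter_assay_precision


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(
    records: pd.DataFrame, n_patients: int, patients_with_finding: int
) -> dict:
    """Summarize a clinical cohort's pathogenic/likely pathogenic variants.

    ``records`` has columns gene / variant / var_type / classification /
    n_detected (one row per unique variant).  Per-gene shares are rounded
    to integer percent as such tables conventionally print them, and the
    patient-level positive rate to one decimal.
    """
    total = int(records["n_detected"].sum())
    by_gene = (
        records.groupby("gene", sort=False)["n_detected"].sum().sort_values(
            ascending=False, kind="stable"
        )
    )
    gene_percent = {g: round(100.0 * n / total) for g, n in by_gene.items()}
    by_type = records.groupby("var_type", sort=False)["n_detected"].sum().to_dict()
    by_class = records.groupby("classification", sort=False)["n_detected"].sum().to_dict()
    return {
        "total_variants": total,
        "unique_variants": int(len(records)),
        "by_gene": {g: int(n) for g, n in by_gene.items()},
        "gene_percent": gene_percent,
        "by_type": {k: int(v) for k, v in by_type.items()},
        "by_classification": {k: int(v) for k, v in by_class.items()},
        "n_patients": n_patients,
        "patients_with_finding": patients_with_finding,
        "positive_rate": patients_with_finding / n_patients,
        "positive_rate_display": format_rate(patients_with_finding, n_patients),
    }
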