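"""Synthetic capture-coverage simulator with CNV spike-ins.

Generates bin x specimen depth matrices with the structure a read-depth
CNV caller has to cope with: per-specimen library-size factors, a fixed
per-bin capture-efficiency profile, low-rank multiplicative technical
(batch) effects, and negative-binomial counting noise.  CNV events
multiply the expected depth of the affected bins by the germline copy
ratio (0.5 het del, 0 hom del, 1.5 dup) and re-draw those cells under the
same noise law, so spike-ins are exact in expectation and non-event bins
are preserved bit-for-bit.

Expected depth of specimen s at bin b:

    m(s, b) = D * d_s * e_b * exp(sum_k u_{sk} v_{bk}) * c_{sb}

with D the grand mean depth, d_s ~ lognormal size factors, e_b ~ lognormal
capture efficiencies (fixed per panel per seed), (u, v) the low-rank
technical term and c the copy ratio (1 outside events).  Counts are
NegBinom(mean=m, size=1/dispersion), i.e. var = m + dispersion * m^2.

The module also ships the printed validation fixtures: the 18 CNV-positive
specimens with their replication counts, and the 53 pathogenic/likely
pathogenic variants reported across the first 500 clinical specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import DepthMatrix
from .panel import Panel

__all__ = [
    "SimulationConfig",
    "CnvEvent",
    "SimTruth",
    "simulate_depth",
    "spike_cnvs",
    "simulate_trial_cohort",
    "table3_fixture",
    "table3_trial_plan",
    "table4_fixture",
    "COPY_RATIOS",
]

COPY_RATIOS = {"het_del": 0.5, "hom_del": 0.0, "dup": 1.5}

# internal rng stream tags (kept below 2**31 together with user seeds)
_STREAM_EFFICIENCY = 101
_STREAM_SIZE_FACTORS = 102
_STREAM_TECHNICAL = 103
_STREAM_COUNTS = 104
_STREAM_SPIKE = 105
_STREAM_PLAN = 106


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the coverage generator.

    Defaults mirror the validated assay's operating point: batches of 92
    specimens at ~380x mean coverage.  ``dispersion`` is the negative-
    binomial overdispersion (var = m + dispersion * m^2); 0.002 puts the
    residual per-bin coefficient of variation at ~7% for 380x coverage,
    typical of a well-tuned clinical capture panel.
    """

    n_specimens: int = 92
    batch_size: int = 92
    mean_depth: float = 380.0
    specimen_sd_log: float = 0.15
    efficiency_sd_log: float = 0.40
    n_technical_factors: int = 2
    technical_sd: float = 0.05
    dispersion: float = 0.002
    seed: int = 0
    assay_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("specimen_sd_log", "efficiency_sd_log", "technical_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CnvEvent:
    """A germline copy-number event to spike into one specimen.

    ``exon_range`` is 1-based inclusive (first, last), or None for a
    whole-gene event.  ``replications`` is the number of independent
    sequencing trials of the carrier specimen.
    """

    specimen_id: str
    gene: str
    exon_range: tuple[int, int] | None
    copy_state: str
    replications: int = 1
    note: str = ""

    def __post_init__(self) -> None:
        if self.copy_state not in COPY_RATIOS:
            raise ValueError(f"unknown copy_state {self.copy_state!r}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")

    @property
    def ratio(self) -> float:
        return COPY_RATIOS[self.copy_state]

    @property
    def cnv_type(self) -> str:
        return "DUP" if self.ratio > 1 else "DEL"

    @property
    def is_single_exon(self) -> bool:
        return self.exon_range is not None and self.exon_range[0] == self.exon_range[1]


@dataclass
class SimTruth:
    """Generator-side truth: expected means and the latent factors."""

    expected_mean: pd.DataFrame  # bins x specimens
    size_factors: pd.Series
    efficiency: pd.Series
    config: SimulationConfig
    events: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_depth(config: SimulationConfig, panel: Panel) -> tuple[DepthMatrix, SimTruth]:
    """Simulate a null (event-free) bin x specimen depth matrix.

    Deterministic given (config, panel).  Assay-level structure — the
    capture-efficiency profile e_b and the technical-factor *loadings*
    v_bk (which bins covary) — is a property of the bait design, so it is
    drawn from an assay-level stream fixed per panel (override with
    ``assay_seed``): training cohorts and production batches of the same
    panel share it, which is precisely what makes a training-fixed PCA
    basis and trained sigmas transferable.  Cohort-level randomness —
    size factors d_s, factor *scores* u_sk and counting noise — comes
    from ``seed``.
    """
    bins = panel.bins()
    if not bins:
        raise ValueError("panel has no bins; run make_bins first")
    bin_ids = [b.target_id for b in bins]
    n_b, n_s = len(bins), config.n_specimens

    assay_seed = config.assay_seed
    if assay_seed is None:
        assay_seed = int(panel.fingerprint()[:8], 16) % (2**31)
    rng_e = np.random.default_rng([assay_seed, _STREAM_EFFICIENCY])
    efficiency = np.exp(rng_e.normal(0.0, config.efficiency_sd_log, size=n_b))
    rng_d = np.random.default_rng([config.seed, _STREAM_SIZE_FACTORS])
    size_factors = np.exp(rng_d.normal(0.0, config.specimen_sd_log, size=n_s))
    k = config.n_technical_factors
    if k > 0:
        rng_v = np.random.default_rng([assay_seed, _STREAM_TECHNICAL])
        v = rng_v.normal(0.0, config.technical_sd, size=(k, n_b))
        rng_u = np.random.default_rng([config.seed, _STREAM_TECHNICAL])
        u = rng_u.normal(0.0, 1.0, size=(n_s, k))
        tech = np.exp(u @ v)  # specimens x bins
    else:
        tech = np.ones((n_s, n_b))

    mean = config.mean_depth * size_factors[:, None] * efficiency[None, :] * tech
    rng_c = np.random.default_rng([config.seed, _STREAM_COUNTS])
    counts = _nb_sample(rng_c, mean, config.dispersion)

    specimens = [f"spec{i + 1:04d}" for i in range(n_s)]
    batches = pd.Series(
        [f"batch{i // config.batch_size + 1}" for i in range(n_s)], index=specimens
    )
    values = pd.DataFrame(counts.T, index=bin_ids, columns=specimens)
    truth = SimTruth(
        expected_mean=pd.DataFrame(mean.T, index=bin_ids, columns=specimens),
        size_factors=pd.Series(size_factors, index=specimens),
        efficiency=pd.Series(efficiency, index=bin_ids),
        config=config,
    )
    return DepthMatrix(values=values, batch_labels=batches), truth


def event_bins(panel: Panel, event: CnvEvent, include_masked: bool = True) -> list[str]:
    """Bin ids of the panel covered by an event (genomic biology, mask-blind
    by default; pass include_masked=False for the NGS-testable truth set)."""
    out = []
    for b in panel.bins(event.gene, include_masked=include_masked):
        if b.exon_index is None:
            continue
        if event.exon_range is None or (
            event.exon_range[0] <= b.exon_index <= event.exon_range[1]
        ):
            out.append(b.target_id)
    return out


def spike_cnvs(
    matrix: DepthMatrix,
    events: list[CnvEvent],
    panel: Panel,
    truth: SimTruth,
    seed: int | None = None,
) -> tuple[DepthMatrix, pd.DataFrame]:
    """Spike CNV events into a simulated matrix, re-drawing event cells.

    Events multiply the expected depth of the affected bins by the copy
    ratio and re-sample those cells under the generator's noise law; all
    other cells are untouched.  Returns the spiked matrix and a truth
    table (one row per event: specimen, gene, exon range, ratio, type,
    and the NGS-testable bin ids).  An event whose bins are all masked is
    rejected — it cannot be assayed at all.
    """
    if seed is None:
        seed = truth.config.seed
    rng = np.random.default_rng([seed, _STREAM_SPIKE])
    values = matrix.values.copy()
    rows = []
    for ev in events:
        if ev.specimen_id not in values.columns:
            raise ValueError(f"event references unknown specimen {ev.specimen_id!r}")
        all_bins = event_bins(panel, ev, include_masked=True)
        testable = event_bins(panel, ev, include_masked=False)
        if not all_bins:
            raise ValueError(f"event on {ev.gene} {ev.exon_range} covers no panel bins")
        if not testable:
            raise ValueError(
                f"event on {ev.gene} {ev.exon_range} lies entirely in masked bins"
            )
        mean = truth.expected_mean.loc[all_bins, ev.specimen_id].to_numpy() * ev.ratio
        values.loc[all_bins, ev.specimen_id] = _nb_sample(
            rng, mean, truth.config.dispersion
        )
        rows.append(
            {
                "specimen_id": ev.specimen_id,
                "gene": ev.gene,
                "first_exon": ev.exon_range[0] if ev.exon_range else None,
                "last_exon": ev.exon_range[1] if ev.exon_range else None,
                "ratio": ev.ratio,
                "cnv_type": ev.cnv_type,
                "bins": ",".join(testable),
            }
        )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "gene", "first_exon", "last_exon", "ratio", "cnv_type", "bins",
        ],
    )
    spiked = DepthMatrix(
        values=values,
        batch_labels=matrix.batch_labels.copy(),
        specimen_qc_pass=matrix.specimen_qc_pass.copy(),
        target_qc_pass=matrix.target_qc_pass.copy(),
    )
    return spiked, truth_table


def simulate_trial_cohort(
    panel: Panel,
    config: SimulationConfig,
    trials: list[tuple[str, CnvEvent | None]],
) -> tuple[DepthMatrix, pd.DataFrame]:
    """Simulate one sequencing trial per entry of ``trials``.

    Each trial is an independent noise draw; entries carrying an event get
    it spiked in.  Trial ids become specimen column names; batches are
    assigned sequentially in trial order (``config.batch_size`` per batch).
    """
    cfg = SimulationConfig(
        n_specimens=len(trials),
        batch_size=config.batch_size,
        mean_depth=config.mean_depth,
        specimen_sd_log=config.specimen_sd_log,
        efficiency_sd_log=config.efficiency_sd_log,
        n_technical_factors=config.n_technical_factors,
        technical_sd=config.technical_sd,
        dispersion=config.dispersion,
        seed=config.seed,
        assay_seed=config.assay_seed,
    )
    depth, truth = simulate_depth(cfg, panel)
    rename = dict(zip(depth.specimen_ids, [t[0] for t in trials]))
    depth.values.columns = [rename[c] for c in depth.values.columns]
    depth.batch_labels.index = depth.values.columns
    depth.specimen_qc_pass.index = depth.values.columns
    truth.expected_mean.columns = depth.values.columns
    truth.size_factors.index = depth.values.columns
    events = [
        CnvEvent(tid, ev.gene, ev.exon_range, ev.copy_state, 1, ev.note)
        for tid, ev in trials
        if ev is not None
    ]
    return spike_cnvs(depth, events, panel, truth, seed=cfg.seed)


def table3_trial_plan(
    events: list[CnvEvent] | None = None,
    n_batches: int = 5,
    batch_size: int = 92,
    seed: int = 0,
) -> list[tuple[str, CnvEvent | None]]:
    """Expand replicated positive specimens into a shuffled trial list.

    Each replication of each positive specimen becomes one trial
    (``S7_r2`` etc.); the remainder of ``n_batches * batch_size`` trials
    are CNV-negative.  Trials are shuffled deterministically so positives
    spread across batches, as in a production run.
    """
    if events is None:
        events = table3_fixture()
    trials: list[tuple[str, CnvEvent | None]] = []
    for ev in events:
        for r in range(1, ev.replications + 1):
            trials.append((f"{ev.specimen_id}_r{r}", ev))
    n_total = n_batches * batch_size
    if len(trials) > n_total:
        raise ValueError("too many positive trials for the requested batches")
    for i in range(n_total - len(trials)):
        trials.append((f"neg{i + 1:04d}", None))
    rng = np.random.default_rng([seed, _STREAM_PLAN])
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# ---------------------------------------------------------------------------
# printed fixtures
# ---------------------------------------------------------------------------

# The 18 CNV-positive specimens of the validation study, with replication
# counts: (specimen, gene, first_exon, last_exon or None=whole gene,
# copy_state, replications).  S12's PMS2 exon 11-15 portion could not be
# assayed by NGS (pseudogene mask) — noted on the event.
_TABLE3 = (
    ("S1", "CDH1", (4, 9), "het_del", 3, ""),
    ("S2", "BRCA2", None, "dup", 3, ""),
    ("S3", "BRCA1", None, "het_del", 3, ""),
    ("S4", "TP53", None, "het_del", 3, ""),
    ("S5", "BRCA1", (16, 17), "het_del", 3, ""),
    ("S6", "BRCA1", (1, 2), "dup", 3, ""),
    ("S7", "BRCA1", (9, 12), "het_del", 3, ""),
    ("S8", "BRCA1", (21, 23), "het_del", 5, ""),
    ("S9", "BRCA1", (13, 13), "dup", 3, ""),
    ("S10", "BRCA1", (9, 12), "het_del", 5, ""),
    ("S11", "MLH1", (16, 19), "het_del", 1, ""),
    ("S12", "PMS2", None, "het_del", 1, "exon 11-15 CNV status not tested by NGS"),
    ("S13", "MLH1", (16, 19), "het_del", 1, ""),
    ("S14", "PMS2", (8, 8), "het_del", 1, ""),
    ("S15", "CDH1", None, "dup", 1, ""),
    ("S16", "BRCA1", (1, 22), "dup", 1, ""),
    ("S17", "PALB2", (9, 10), "het_del", 1, ""),
    ("S18", "BRCA1", (22, 22), "het_del", 1, ""),
)


def table3_fixture() -> list[CnvEvent]:
    """The 18 CNV-positive validation specimens (42 trials in total)."""
    return [
        CnvEvent(sid, gene, rng, state, reps, note)
        for sid, gene, rng, state, reps, note in _TABLE3
    ]


# Pathogenic / likely pathogenic variants reported across the first 500
# consecutive clinical specimens: (gene, variant, type, classification,
# number detected).  42 unique variants; detection counts sum to 53.
_TABLE4 = (
    ("BRCA1", "c.68_69del (p.Glu23Valfs*17)", "DEL", "P", 1),
    ("BRCA1", "c.211A>G (p.Arg71Gly)", "SNV", "P", 1),
    ("BRCA1", "c.406dupA (p.Arg136Lysfs*6)", "INS", "P", 1),
    ("BRCA1", "c.427G>T (p.Glu143*)", "SNV", "P", 1),
    ("BRCA1", "c.1960A>T (p.Lys654*)", "SNV", "P", 1),
    ("BRCA1", "c.3193dup (p.Asp1065Glyfs*2)", "INS", "P", 1),
    ("BRCA1", "c.4327C>T (p.Arg1443*)", "SNV", "P", 2),
    ("BRCA1", "c.5266dup (p.Gln1756Profs*74)", "INS", "P", 1),
    ("BRCA1", "c.5353C>T (p.Gln1785*)", "SNV", "P", 1),
    ("BRCA1", "c.3598C>T (p.Gln1200*)", "SNV", "P", 1),
    ("BRCA1", "Exon 13 Duplication", "CNV", "P", 1),
    ("BRCA2", "c.755_758del (p.Asp252Valfs*24)", "DEL", "P", 1),
    ("BRCA2", "c.1265del (p.Asn422Ilefs*8)", "DEL", "P", 1),
    ("BRCA2", "c.3922G>T (p.Glu1308*)", "SNV", "P", 1),
    ("BRCA2", "c.4284dup (p.Gln1429Serfs*9)", "INS", "P", 1),
    ("BRCA2", "c.4631dup (p.Asn1544Lysfs*4)", "INS", "P", 1),
    ("BRCA2", "c.5290_5291del (p.Ser1764Lysfs*3)", "DEL", "P", 1),
    ("BRCA2", "c.5385dup (p.Asp1796Argfs*11)", "INS", "P", 1),
    ("BRCA2", "c.5681dup (p.Tyr1894*)", "INS", "P", 1),
    ("BRCA2", "c.5682C>G (p.Tyr1894*)", "SNV", "P", 1),
    ("BRCA2", "c.5946del (p.Ser1982Argfs*22)", "DEL", "P", 2),
    ("BRCA2", "c.6373dup (p.Thr2125Asnfs*4)", "INS", "P", 1),
    ("MUTYH", "c.536A>G (p.Tyr179Cys)", "SNV", "P", 1),
    ("MUTYH", "c.1187G>A (p.Gly396Asp)", "SNV", "P", 6),
    ("MUTYH", "c.1214C>T (p.Pro405Leu)", "SNV", "P", 1),
    ("MUTYH", "c.1477G>T (p.Val493Phe)", "SNV", "P", 1),
    ("CHEK2", "c.444+1G>A", "SNV", "P", 1),
    ("CHEK2", "c.793-1G>A", "SNV", "P", 1),
    ("CHEK2", "c.1100delC (p.Thr367Metfs*15)", "DEL", "P", 5),
    ("CHEK2", "c.1169A>C (p.Tyr390Ser)", "SNV", "LP", 1),
    ("ATM", "c.7638_7646del (p.Arg2547_Ser2549del)", "DEL", "P", 1),
    ("ATM", "c.8395_8404del (p.Phe2799Lysfs*4)", "DEL", "P", 1),
    ("PALB2", "c.2642_2645dup (p.Cys882Trpfs*3)", "INS", "P", 1),
    ("PALB2", "c.3256C>T (p.Arg1086*)", "SNV", "P", 1),
    ("PMS2", "c.809C>G (p.Ser270*)", "SNV", "P", 1),
    ("PMS2", "Exon 7-8 deletion", "CNV", "P", 1),
    ("CDH1", "c.1565+1G>C", "SNV", "P", 1),
    ("BARD1", "c.1690C>T (p.Gln564*)", "SNV", "P", 1),
    ("CDKN2A", "c.301G>T (p.Gly101Trp)", "SNV", "P", 1),
    ("MLH1", "c.793C>T (p.Arg265Cys)", "SNV", "P", 1),
    ("RAD51C", "c.773G>A (p.Arg258His)", "SNV", "LP", 1),
    ("RET", "c.2410G>A (p.Val804Met)", "SNV", "P", 1),
)


def table4_fixture() -> pd.DataFrame:
    """Variant records of the first-500-specimens cohort summary."""
    return pd.DataFrame(
        list(_TABLE4),
        columns=["gene", "variant", "var_type", "classification", "n_detected"],
    )
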