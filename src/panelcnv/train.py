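"""Training: per-group sigma (scaled MAD), cutoff calibration, model I/O.

sigma(g) is the median absolute deviation of X(., g) across the training
cohort, scaled by 1.4826 so that Z is in approximate standard-normal
units for Gaussian-like noise (disable with ``mad_scale=False``).
Cutoffs are calibrated to a target trial-level specificity: the training
cohort is replayed batch by batch exactly as production would score it
(within-batch median mu, training sigma), per-stratum quantiles of the
per-specimen max |Z| and |Z.adj| form a cutoff template, and a single
multiplier >= 1 is searched so that the replayed fraction of specimens
with any flag does not exceed 1 - target_specificity.  Because roughly
1 in 100 clinical specimens genuinely carries a CNV, an optional robust
iteration (on by default) drops first-pass flagged specimens and refits
sigma and cutoffs once.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import DepthMatrix
from .normalize import (
    NormalizedMatrix,
    PcaBasis,
    compute_rdr,
    fit_pca,
    apply_pca,
    group_depth,
    median_normalize,
)
from .panel import Panel
from .score import Cutoffs, score_matrix, z_adj, z_score, batch_mu

__all__ = [
    "TrainingModel",
    "fit_sigma",
    "calibrate_cutoffs",
    "train_model",
    "save_model",
    "load_model",
    "MAD_SCALE",
]

#: Normal-consistency constant for the MAD.
MAD_SCALE = 1.4826


@dataclass
class TrainingModel:
    """Everything needed to score a production batch."""

    panel_fingerprint: str
    pca_basis: PcaBasis | None
    sigma: pd.Series
    cutoffs: Cutoffs
    n_training: int
    target_specificity: float
    flag_rule: str = "either"
    meta: dict = field(default_factory=dict)

    def check_panel(self, panel: Panel) -> None:
        if panel.fingerprint() != self.panel_fingerprint:
            raise ValueError(
                "panel fingerprint mismatch: the model was trained on a different "
                f"panel geometry (model {self.panel_fingerprint}, "
                f"panel {panel.fingerprint()})"
            )


def fit_sigma(
    training_X: NormalizedMatrix, mad_scale: bool = True, min_specimens: int = 30
) -> pd.Series:
    """Per-group sigma = (1.4826 x) MAD of X across training specimens.

    Groups with sigma = 0 are unscorable and recorded as such downstream.
    """
    n = training_X.values.shape[1]
    if n < min_specimens:
        warnings.warn(
            f"only {n} training specimens (< {min_specimens}); sigma will be noisy",
            stacklevel=2,
        )
    x = training_X.values.to_numpy()
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    if mad_scale:
        mad = MAD_SCALE * mad
    return pd.Series(mad, index=training_X.values.index, name="sigma")


def _per_specimen_max(scores: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Per-specimen max |score| per stratum -> DataFrame strata x specimens."""
    strata = strata.reindex(scores.index)
    out = {}
    for stratum in strata.unique():
        rows = (strata == stratum).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            out[stratum] = np.nanmax(np.abs(scores.to_numpy()[rows]), axis=0)
    df = pd.DataFrame(out, index=scores.columns).T
    return df.fillna(0.0)


_EULER_GAMMA = 0.5772156649015329


def _gumbel_quantile(values: np.ndarray, p: float, confidence: float = 0.95) -> float:
    """Moment-fit Gumbel tail quantile of a sample of per-specimen maxima.

    The max of many near-independent scores is approximately Gumbel;
    fitting location/scale from the sample moments uses the whole replay
    distribution to extrapolate tail quantiles a few hundred specimens
    cannot pin down empirically.  ``confidence`` adds a one-sided upper
    confidence allowance for the quantile-estimation error, so the
    calibration errs toward specificity when the training cohort is
    small.
    """
    n = len(values)
    m, s = float(np.mean(values)), float(np.std(values, ddof=1))
    beta = s * math.sqrt(6.0) / math.pi
    mu = m - _EULER_GAMMA * beta
    k = -math.log(-math.log(p))
    q = mu + beta * k
    if confidence and n > 1:
        from scipy.stats import norm

        se = beta * math.sqrt((0.60793 * k * k + 0.51404 * k + 1.10866) / n)
        q += float(norm.ppf(confidence)) * se
    return q


def calibrate_cutoffs(
    training_X: NormalizedMatrix,
    sigma: pd.Series,
    batch_labels: pd.Series,
    target_specificity: float = 0.98,
    qc_pass: pd.Series | None = None,
) -> Cutoffs:
    """Calibrate per-stratum cutoffs to a specimen-level false-flag budget.

    The training cohort is replayed exactly as production is scored
    (within-batch median mu, training sigma); per stratum and statistic
    the per-specimen max |Z| and |Z.adj| are collected.  The specimen-
    level budget alpha = 1 - target_specificity is split across the
    stat-strata (Bonferroni) and each cutoff is placed at the
    corresponding Gumbel tail quantile of its replayed max distribution.
    A Gumbel fit is used because a training cohort of a few hundred
    specimens cannot resolve a ~2% family-wise tail across a dozen
    dependent max-statistics empirically; the positive dependence among
    strata makes the Bonferroni split conservative, which costs nothing —
    real events sit far above any plausible cutoff — and keeps the
    realized false-flag rate at or under budget on fresh batches.
    The empirical replay acts as a floor: cutoffs are raised further if
    the replayed flag rate still exceeds alpha.  target_specificity=1
    puts every cutoff strictly above all observed null scores.
    """
    if not 0 < target_specificity <= 1:
        raise ValueError("target_specificity must be in (0, 1]")
    alpha = 1.0 - target_specificity
    mu = batch_mu(training_X, batch_labels, qc_pass)
    Z = z_score(training_X, mu, batch_labels.loc[training_X.values.columns], sigma)
    Zadj = z_adj(Z, training_X.strata)
    mz = _per_specimen_max(Z, training_X.strata)  # strata x specimens
    ma = _per_specimen_max(Zadj, training_X.strata)
    strata = list(mz.index)
    n_tests = 2 * len(strata)
    eps = 1e-9

    cut_z: dict[str, float] = {}
    cut_a: dict[str, float] = {}
    for s in strata:
        if alpha == 0.0:
            cut_z[s] = float(mz.loc[s].max()) + eps
            cut_a[s] = float(ma.loc[s].max()) + eps
        else:
            p = 1.0 - alpha / n_tests
            cut_z[s] = max(_gumbel_quantile(mz.loc[s].to_numpy(), p), eps)
            cut_a[s] = max(_gumbel_quantile(ma.loc[s].to_numpy(), p), eps)

    mzv, mav = mz.to_numpy(), ma.to_numpy()

    def replay_rate(t: float) -> float:
        qz = np.array([cut_z[s] for s in strata])[:, None]
        qa = np.array([cut_a[s] for s in strata])[:, None]
        flagged = ((mzv > t * qz) | (mav > t * qa)).any(axis=0)
        return float(flagged.mean())

    t = 1.0
    if replay_rate(t) > alpha:
        hi = 1.0
        while replay_rate(hi) > alpha and hi < 1e6:
            hi *= 2.0
        lo = hi / 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if replay_rate(mid) > alpha:
                lo = mid
            else:
                hi = mid
        t = hi
        if replay_rate(t) > alpha:
            warnings.warn(
                "target specificity unattainable on the training replay; cutoffs "
                "set above all observed scores",
                stacklevel=2,
            )
    return Cutoffs(
        z={s: float(t * cut_z[s]) for s in strata},
        zadj={s: float(t * cut_a[s]) for s in strata},
    )


def train_model(
    depth: DepthMatrix,
    panel: Panel,
    n_components: int = 5,
    target_specificity: float = 0.98,
    mad_scale: bool = True,
    robust: bool = True,
    flag_rule: str = "either",
    meta: dict | None = None,
) -> TrainingModel:
    """Fit the full model from a training cohort depth matrix.

    Pipeline: group depth -> RDr -> PCA basis (k = ``n_components``, capped
    by explained variance) -> X -> sigma (scaled MAD) -> cutoff
    calibration.  With ``robust=True``, specimens flagged on the first
    pass (putative event carriers; ~1 in 100 clinical specimens) are
    dropped and sigma/cutoffs refit once.  The PCA basis is kept — a
    handful of carriers does not move a dense component — and the refit
    carries over the unspent false-flag budget rather than re-quantiling
    the truncated cohort, which would silently tighten the cutoffs.
    """
    gd = group_depth(depth, panel)
    rdr = compute_rdr(gd, panel)
    if n_components > 0:
        basis = fit_pca(rdr, n_components=n_components)
        rdrp = apply_pca(rdr, basis)
    else:
        basis = fit_pca(rdr, n_components=0)
        rdrp = NormalizedMatrix("RDrp", rdr.values, rdr.strata, rdr.unscorable_specimens)
    X = median_normalize(rdrp)
    labels = depth.batch_labels
    qc = depth.specimen_qc_pass
    sigma = fit_sigma(X, mad_scale=mad_scale)
    cutoffs = calibrate_cutoffs(X, sigma, labels, target_specificity, qc)
    n_used = X.values.shape[1]
    if robust:
        scores = score_matrix(X, labels, sigma, cutoffs, qc, rule=flag_rule)
        flagged = scores.flag.to_numpy().any(axis=0)
        keep = [c for c, f in zip(X.values.columns, flagged) if not f]
        n_drop = int(flagged.sum())
        if 0 < n_drop and len(keep) >= 10:
            Xc = NormalizedMatrix(
                "X", X.values[keep], X.strata, X.unscorable_specimens
            )
            # batches may shrink below the mu minimum; fall back if so
            try:
                sigma = fit_sigma(Xc, mad_scale=mad_scale, min_specimens=10)
                cutoffs = calibrate_cutoffs(
                    Xc, sigma, labels.loc[keep], target_specificity, qc.loc[keep]
                )
                n_used = len(keep)
            except ValueError:
                pass
    return TrainingModel(
        panel_fingerprint=panel.fingerprint(),
        pca_basis=basis,
        sigma=sigma,
        cutoffs=cutoffs,
        n_training=n_used,
        target_specificity=target_specificity,
        flag_rule=flag_rule,
        meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# model JSON round-trip
# ---------------------------------------------------------------------------

def _model_doc(model: TrainingModel) -> dict:
    basis = model.pca_basis
    return {
        "format": "panelcnv-model-1",
        "panel_fingerprint": model.panel_fingerprint,
        "n_training": model.n_training,
        "target_specificity": model.target_specificity,
        "flag_rule": model.flag_rule,
        "meta": model.meta,
        "sigma": {
            "group_ids": list(model.sigma.index),
            "values": [float(v) for v in model.sigma.to_numpy()],
        },
        "cutoffs": {"z": model.cutoffs.z, "zadj": model.cutoffs.zadj},
        "pca_basis": None
        if basis is None
        else {
            "group_ids": list(basis.group_ids),
            "mean": [float(v) for v in basis.mean],
            "components": [[float(v) for v in row] for row in basis.components],
            "explained_variance_ratio": [float(v) for v in basis.explained_variance_ratio],
            "scale": None if basis.scale is None else [float(v) for v in basis.scale],
            "clip_mads": basis.clip_mads,
        },
    }


def save_model(model: TrainingModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_doc(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path, panel: Panel | None = None) -> TrainingModel:
    """Load a model JSON; verifies the panel fingerprint when given one."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "panelcnv-model-1":
        raise ValueError(f"{path}: not a panelcnv model file")
    bdoc = doc["pca_basis"]
    basis = None
    if bdoc is not None:
        basis = PcaBasis(
            group_ids=tuple(bdoc["group_ids"]),
            mean=np.asarray(bdoc["mean"], dtype=float),
            components=np.asarray(bdoc["components"], dtype=float).reshape(
                len(bdoc["components"]), len(bdoc["group_ids"])
            )
            if bdoc["components"]
            else np.empty((0, len(bdoc["group_ids"]))),
            explained_variance_ratio=np.asarray(
                bdoc["explained_variance_ratio"], dtype=float
            ),
            scale=None
            if bdoc.get("scale") is None
            else np.asarray(bdoc["scale"], dtype=float),
            clip_mads=float(bdoc.get("clip_mads", 3.0)),
        )
    model = TrainingModel(
        panel_fingerprint=doc["panel_fingerprint"],
        pca_basis=basis,
        sigma=pd.Series(
            doc["sigma"]["values"], index=doc["sigma"]["group_ids"], name="sigma"
        ),
        cutoffs=Cutoffs(z=dict(doc["cutoffs"]["z"]), zadj=dict(doc["cutoffs"]["zadj"])),
        n_training=int(doc["n_training"]),
        target_specificity=float(doc["target_specificity"]),
        flag_rule=doc.get("flag_rule", "either"),
        meta=dict(doc.get("meta", {})),
    )
    if panel is not None:
        model.check_panel(panel)
    return model
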