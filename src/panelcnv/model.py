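"""High-level Model/Results interface for read-depth CNV flagging.

`ReadDepthCnvModel` is constructed from a training-cohort depth matrix
and a panel; `fit()` learns the denoising basis, per-group dispersions
and flagging cutoffs and returns a `CnvModelResults`, which carries the
fitted parameters, prints a `summary()`, serializes to JSON, and calls
CNVs on production batches via `call()`.

    >>> panel = demo_panel()
    >>> depth, _ = simulate_depth(SimulationConfig(n_specimens=300, seed=7), panel)
    >>> results = ReadDepthCnvModel(depth, panel).fit()
    >>> calls = results.call(production_batch).calls
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import DepthMatrix, qc_matrix
from .normalize import normalize_to_x
from .panel import Panel
from .score import CnvCall, ScoreMatrix, merge_calls, score_matrix
from .train import TrainingModel, load_model, save_model, train_model

__all__ = ["ReadDepthCnvModel", "CnvModelResults", "CallSet"]


@dataclass
class CallSet:
    """Output of scoring one cohort: merged calls plus the score matrices."""

    calls: list[CnvCall]
    scores: ScoreMatrix

    def calls_for(self, specimen_id: str) -> list[CnvCall]:
        return [c for c in self.calls if c.specimen_id == specimen_id]

    def to_frame(self) -> pd.DataFrame:
        from .score import calls_to_frame

        return calls_to_frame(self.calls)


class ReadDepthCnvModel:
    """Read-depth CNV flagging model for a targeted capture panel.

    Parameters
    ----------
    training_depth
        Bin x specimen depth matrix of an (assumed CNV-free) training
        cohort, with batch labels.
    panel
        Binned + grouped panel; its geometry is fingerprinted into the
        fitted model.
    n_components
        Principal components removed from relative read depth (capped at
        the count explaining 90% of training variance).
    target_specificity
        Specimen-level specificity the flagging cutoffs are calibrated to.
    robust
        Drop first-pass flagged training specimens and refit once.
    min_depth, qc
        Apply the minimum-coverage QC rule before training.
    """

    def __init__(
        self,
        training_depth: DepthMatrix,
        panel: Panel,
        n_components: int = 5,
        target_specificity: float = 0.98,
        mad_scale: bool = True,
        robust: bool = True,
        flag_rule: str = "either",
        qc: bool = True,
        min_depth: float = 20.0,
    ) -> None:
        self.panel = panel
        self.n_components = n_components
        self.target_specificity = target_specificity
        self.mad_scale = mad_scale
        self.robust = robust
        self.flag_rule = flag_rule
        self.training_depth = (
            qc_matrix(training_depth, panel, min_depth=min_depth) if qc else training_depth
        )

    @classmethod
    def from_tsv(cls, depth_path, panel: Panel, **kwargs) -> "ReadDepthCnvModel":
        from .coverage import read_depth_matrix

        return cls(read_depth_matrix(depth_path), panel, **kwargs)

    def fit(self, meta: dict | None = None) -> "CnvModelResults":
        trained = train_model(
            self.training_depth,
            self.panel,
            n_components=self.n_components,
            target_specificity=self.target_specificity,
            mad_scale=self.mad_scale,
            robust=self.robust,
            flag_rule=self.flag_rule,
            meta=meta,
        )
        return CnvModelResults(model=self, trained=trained, panel=self.panel)


@dataclass
class CnvModelResults:
    """Fitted flagging model: denoising basis, sigmas, cutoffs."""

    model: ReadDepthCnvModel | None
    trained: TrainingModel
    panel: Panel

    # -- accessors ---------------------------------------------------------
    @property
    def sigma(self) -> pd.Series:
        return self.trained.sigma

    @property
    def cutoffs(self):
        return self.trained.cutoffs

    @property
    def pca_basis(self):
        return self.trained.pca_basis

    # -- scoring -----------------------------------------------------------
    def call(
        self,
        depth: DepthMatrix,
        qc: bool = True,
        min_depth: float = 20.0,
    ) -> CallSet:
        """Score a production cohort and merge flags into CNV calls."""
        self.trained.check_panel(self.panel)
        if qc:
            depth = qc_matrix(depth, self.panel, min_depth=min_depth)
        X = normalize_to_x(depth, self.panel, self.trained.pca_basis)
        scores = score_matrix(
            X,
            depth.batch_labels,
            self.trained.sigma,
            self.trained.cutoffs,
            depth.specimen_qc_pass,
            rule=self.trained.flag_rule,
        )
        return CallSet(calls=merge_calls(scores, self.panel), scores=scores)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        t = self.trained
        sig = t.sigma.to_numpy()
        sig = sig[np.isfinite(sig) & (sig > 0)]
        k = t.pca_basis.n_components if t.pca_basis is not None else 0
        lines = [
            "Read-depth CNV flagging model",
            "=============================",
            f"panel:               {self.panel.name} "
            f"({len(self.panel.genes)} genes, {len(self.panel.bins())} bins, "
            f"{len(self.panel.groups)} target groups)",
            f"panel fingerprint:   {t.panel_fingerprint}",
            f"training specimens:  {t.n_training}",
            f"PCA components:      {k}",
            f"target specificity:  {t.target_specificity:.3f}",
            f"flag rule:           {t.flag_rule} (|Z| and/or |Z.adj| over cutoff)",
            f"sigma (scaled MAD):  median {np.median(sig):.4f}, "
            f"IQR [{np.percentile(sig, 25):.4f}, {np.percentile(sig, 75):.4f}]",
            "cutoffs per stratum:",
        ]
        for stratum in sorted(t.cutoffs.z):
            lines.append(
                f"  {stratum:<12} |Z| > {t.cutoffs.z[stratum]:6.2f}   "
                f"|Z.adj| > {t.cutoffs.zadj[stratum]:6.2f}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.trained, path)

    @classmethod
    def load(cls, path, panel: Panel) -> "CnvModelResults":
        trained = load_model(path, panel)
        return cls(model=None, trained=trained, panel=panel)

    # -- plotting ----------------------------------------------------------
    def plot_scores(self, callset: CallSet, specimen_id: str, ax=None):
        """Plot single-bin X values of one specimen along the panel, with
        flagged bins highlighted.  Requires matplotlib."""
        import matplotlib.pyplot as plt

        sb = callset.scores.strata == "single_bin"
        x = callset.scores.X.loc[sb.to_numpy(), specimen_id]
        flagged = callset.scores.flag.loc[sb.to_numpy(), specimen_id]
        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        pos = np.arange(len(x))
        ax.scatter(pos, x, s=4, c="grey", label="bins")
        if flagged.any():
            ax.scatter(pos[flagged.to_numpy()], x[flagged.to_numpy()], s=10, c="red",
                       label="flagged")
        ax.axhline(1.0, lw=0.5, c="black")
        ax.axhline(0.5, lw=0.5, ls="--", c="steelblue")
        ax.axhline(1.5, lw=0.5, ls="--", c="darkorange")
        ax.set_xlabel("bin (panel order)")
        ax.set_ylabel("normalized depth X")
        ax.set_title(specimen_id)
        ax.legend(loc="upper right", fontsize=8)
        return ax
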